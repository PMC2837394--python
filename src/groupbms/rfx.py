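"""Random-effects (RFX) group Bayesian model selection.

RFX inference treats the model that generated each subject's data as a draw
from unknown population frequencies ``r`` (a point on the M-simplex).  The
generative model is Dirichlet-multinomial:

    r ~ Dirichlet(alpha_0)                     (prior model frequencies)
    a_n | r ~ Multinomial(1, r)                (subject n's assignation vector)
    Y_n | a_nm = 1 ~ p(Y_n | m)                (the supplied model evidence)

Inference targets the posterior p(r | Y), from which the expected frequencies
<r_m> and the exceedance probability of each model (the posterior belief that
its frequency exceeds all others') are computed.

The reference sampler is a Gibbs chain alternating between

1. per-subject posterior model weights  g_nm ∝ exp(L_nm) * r_m   (log-space),
2. a one-hot assignment draw a_n ~ Multinomial(1, g_n) per subject,
3. model counts beta_m = sum_n a_nm,
4. a frequency draw r ~ Dirichlet(alpha_0 + beta),

with the chain initialised from the prior.  A variational (VB) fixed-point
alternative is provided for speed; it is accurate for prior counts
alpha_0 >= 1 but biased for the very small counts that family-uniform priors
require, so it warns and recommends Gibbs whenever min(alpha_0) < 1.

Family-level inference aggregates each retained frequency draw over the
partition (s_k = sum of member r_m), giving posterior expectations and
exceedance probabilities over families.  A uniform family-level prior with
unequal family sizes is obtained by setting alpha_m = 1/N_k for every model
in family k, making each family's total prior count exactly one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma

from .evidence import LogEvidenceMatrix
from .model_space import FamilyPartition

__all__ = [
    "DirichletParams",
    "RandomEffectsBMS",
    "RandomEffectsResults",
    "FamilyRfxResults",
    "VariationalResults",
    "default_model_prior",
    "family_uniform_prior",
    "gibbs_sample",
    "vb_update",
    "exceedance_from_samples",
    "family_posterior",
    "batch_means_mcse",
]

DEFAULT_N_TOTAL = 30_000
DEFAULT_BURN_IN = 10_000


@dataclass(frozen=True)
class DirichletParams:
    """Strictly positive Dirichlet prior counts over the comparison set."""

    alpha: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 1 or a.size < 1 or (a <= 0).any() or not np.isfinite(a).all():
            raise ValueError("alpha must be a 1-D vector of finite positives")
        object.__setattr__(self, "alpha", a)

    def __len__(self) -> int:
        return self.alpha.size


def default_model_prior(M: int) -> DirichletParams:
    """The default symmetric prior: one prior count per model (alpha_m = 1)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    return DirichletParams(np.ones(M))


def family_uniform_prior(partition: FamilyPartition) -> DirichletParams:
    """Prior counts alpha_m = 1/N_k, giving each family a total prior count of 1.

    Aggregated over the partition this is a symmetric Dirichlet(1, ..., 1) on
    family frequencies, i.e. a uniform prior at the family level even when
    family sizes differ.  The per-model counts can be well below one (1/64 for
    a 64-model family); use Gibbs sampling with such priors, not VB.
    """
    sizes = partition.sizes
    return DirichletParams(1.0 / sizes[np.asarray(partition.membership)])


def _dirichlet_logspace(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet draw that is safe for shape parameters far below one.

    Uses the shape-boosting identity Gamma(a) = Gamma(a+1) * U^(1/a) entirely
    in log space, so small shapes cannot underflow to exact zeros before
    normalisation.
    """
    g = rng.gamma(alpha + 1.0)
    np.maximum(g, np.finfo(float).tiny, out=g)
    log_x = np.log(g) + np.log1p(-rng.random(alpha.shape)) / alpha
    x = np.exp(log_x - log_x.max())
    np.maximum(x, np.finfo(float).tiny, out=x)
    return x / x.sum()


def exceedance_from_samples(samples: np.ndarray) -> np.ndarray:
    """Fraction of posterior draws in which each column is the strict maximum.

    For two alternatives this reduces to P(s_1 > s_2) and the pair sums to 1.
    Rows tied at the maximum (possible only for degenerate duplicated draws)
    contribute to no column.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[0] == 0:
        raise ValueError("need a non-empty 2-D sample matrix")
    is_max = s == s.max(axis=1, keepdims=True)
    strict = is_max & (is_max.sum(axis=1, keepdims=True) == 1)
    return strict.mean(axis=0)


def batch_means_mcse(samples: np.ndarray, n_batches: int = 30) -> np.ndarray:
    """Monte-Carlo standard error of the sample mean via batch means.

    Splits the (possibly autocorrelated) chain into contiguous batches and
    uses the variance of batch means; no thinning is applied to the chain.
    """
    s = np.atleast_2d(np.asarray(samples, dtype=float))
    if s.shape[0] < 2 * n_batches:
        n_batches = max(2, s.shape[0] // 2)
    usable = (s.shape[0] // n_batches) * n_batches
    batches = s[:usable].reshape(n_batches, -1, s.shape[1]).mean(axis=1)
    return batches.std(axis=0, ddof=1) / np.sqrt(n_batches)


def gibbs_sample(
    L: LogEvidenceMatrix | np.ndarray,
    alpha0: DirichletParams | np.ndarray,
    n_total: int = DEFAULT_N_TOTAL,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
) -> "RandomEffectsResults":
    """Gibbs-sample the posterior over population model frequencies.

    Parameters
    ----------
    L : LogEvidenceMatrix or array
        N x M log evidences.
    alpha0 : DirichletParams or array
        Prior counts (length M).
    n_total, burn_in : int
        Total sweeps and discarded initial sweeps; ``n_total - burn_in``
        frequency draws are retained.
    seed : int
        Seed for the single RNG stream; recorded in the result for exact
        reproducibility.
    """
    vals = L.values if isinstance(L, LogEvidenceMatrix) else np.asarray(L, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("log evidences must be finite")
    if not isinstance(alpha0, DirichletParams):
        alpha0 = DirichletParams(np.asarray(alpha0, dtype=float))
    N, M = vals.shape
    if len(alpha0) != M:
        raise ValueError("alpha0 length does not match the number of models")
    n_total = int(n_total)
    burn_in = int(burn_in)
    if burn_in < 0 or n_total <= burn_in:
        raise ValueError("need n_total > burn_in >= 0")

    rng = np.random.default_rng(seed)
    a0 = alpha0.alpha
    r = _dirichlet_logspace(rng, a0)  # initial draw from the prior
    log_r = np.log(r)

    n_keep = n_total - burn_in
    r_samples = np.empty((n_keep, M))
    g_sum = np.zeros((N, M))
    rows = np.arange(N)
    for sweep in range(n_total):
        log_u = vals + log_r  # N x M unnormalised log weights
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        # one-hot assignment per subject via inverse-CDF on the weight rows
        cum = np.cumsum(g, axis=1)
        cum[:, -1] = 1.0
        choice = (rng.random((N, 1)) > cum).sum(axis=1)
        beta = np.bincount(choice, minlength=M).astype(float)
        r = _dirichlet_logspace(rng, a0 + beta)
        log_r = np.log(r)
        if sweep >= burn_in:
            r_samples[sweep - burn_in] = r
            g_sum += g

    g_mean = g_sum / n_keep
    return RandomEffectsResults(
        r_samples=r_samples,
        g=g_mean,
        alpha0=a0,
        seed=int(seed),
        burn_in=burn_in,
        n_total=n_total,
        subject_ids=getattr(L, "subject_ids", tuple(str(n) for n in range(N))),
        model_labels=getattr(L, "model_labels", tuple(f"m{m + 1}" for m in range(M))),
    )


def vb_update(
    L: LogEvidenceMatrix | np.ndarray,
    alpha0: DirichletParams | np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> "VariationalResults":
    """Variational fixed-point alternative to Gibbs sampling.

    Iterates responsibilities g_nm ∝ exp(L_nm + digamma(alpha_m) -
    digamma(sum alpha)) and counts alpha = alpha0 + sum_n g_n until the counts
    change by less than ``tol``.  Accurate for alpha0 >= 1; for the small
    prior counts of family-uniform priors it is known to be biased, so a
    prominent warning recommending Gibbs is emitted whenever min(alpha0) < 1.
    """
    vals = L.values if isinstance(L, LogEvidenceMatrix) else np.asarray(L, dtype=float)
    if not isinstance(alpha0, DirichletParams):
        alpha0 = DirichletParams(np.asarray(alpha0, dtype=float))
    N, M = vals.shape
    if len(alpha0) != M:
        raise ValueError("alpha0 length does not match the number of models")
    if alpha0.alpha.min() < 1.0:
        warnings.warn(
            "Variational inference is inaccurate for prior counts below 1 "
            f"(min alpha0 = {alpha0.alpha.min():.4g}); use the Gibbs sampler "
            "for family-uniform priors.",
            UserWarning,
            stacklevel=2,
        )
    alpha = alpha0.alpha.copy()
    converged = False
    g = np.full((N, M), 1.0 / M)
    for _ in range(int(max_iter)):
        log_u = vals + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        g = np.exp(log_u)
        g /= g.sum(axis=1, keepdims=True)
        alpha_new = alpha0.alpha + g.sum(axis=0)
        if np.abs(alpha_new - alpha).max() < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        warnings.warn(
            f"VB fixed point did not converge in {max_iter} iterations; "
            "returning the best iterate.",
            UserWarning,
            stacklevel=2,
        )
    return VariationalResults(alpha=alpha, alpha0=alpha0.alpha, g=g, converged=converged)


@dataclass
class VariationalResults:
    """Approximate Dirichlet posterior counts from the VB fixed point."""

    alpha: np.ndarray
    alpha0: np.ndarray
    g: np.ndarray
    converged: bool

    @property
    def expected_r(self) -> np.ndarray:
        return self.alpha / self.alpha.sum()

    def sample_r(self, n_samples: int = 20_000, seed: int = 0) -> np.ndarray:
        """Draw frequency samples from the fitted Dirichlet (for exceedance)."""
        rng = np.random.default_rng(seed)
        return rng.dirichlet(self.alpha, size=int(n_samples))

    @property
    def exceedance(self) -> np.ndarray:
        return exceedance_from_samples(self.sample_r())


@dataclass
class RandomEffectsResults:
    """Retained Gibbs draws of model frequencies plus per-subject posteriors.

    Attributes
    ----------
    r_samples : (S, M) array
        Retained posterior draws of the population frequency vector.
    g : (N, M) array
        Per-subject posterior model probabilities, averaged over retained
        sweeps; these feed Bayesian model averaging.
    expected_r, exceedance : (M,) arrays
        Posterior expected frequencies and strict-max exceedance
        probabilities.
    """

    r_samples: np.ndarray
    g: np.ndarray
    alpha0: np.ndarray
    seed: int
    burn_in: int
    n_total: int
    subject_ids: tuple[str, ...] = field(default_factory=tuple)
    model_labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def expected_r(self) -> np.ndarray:
        return self.r_samples.mean(axis=0)

    @property
    def exceedance(self) -> np.ndarray:
        return exceedance_from_samples(self.r_samples)

    @property
    def mcse(self) -> np.ndarray:
        """Batch-means Monte-Carlo standard error of expected_r."""
        return batch_means_mcse(self.r_samples)

    @property
    def best_model(self) -> int:
        return int(np.argmax(self.expected_r))

    def family(self, partition: FamilyPartition) -> "FamilyRfxResults":
        return family_posterior(self, partition)

    def to_dict(self, include_samples: bool = False) -> dict:
        out = {
            "method": "rfx-gibbs",
            "model_labels": list(self.model_labels),
            "expected_r": self.expected_r.tolist(),
            "exceedance": self.exceedance.tolist(),
            "mcse": self.mcse.tolist(),
            "g": self.g.tolist(),
            "alpha0": self.alpha0.tolist(),
            "seed": self.seed,
            "burn_in": self.burn_in,
            "n_total": self.n_total,
        }
        if include_samples:
            out["r_samples"] = self.r_samples.tolist()
        return out

    def summary(self) -> str:
        labels = self.model_labels or [f"m{m + 1}" for m in range(self.r_samples.shape[1])]
        df = pd.DataFrame(
            {"expected_r": self.expected_r, "exceedance": self.exceedance, "mcse": self.mcse},
            index=list(labels),
        )
        head = (
            "Random-effects Bayesian model selection (Gibbs)\n"
            f"  sweeps: {self.n_total} (burn-in {self.burn_in}), seed {self.seed}\n"
        )
        return head + df.to_string(float_format=lambda x: f"{x:.4f}")

    def plot_frequencies(self, ax=None, bins: int = 50):
        """Histogram the posterior frequency draws, one panel per model."""
        import matplotlib.pyplot as plt

        M = self.r_samples.shape[1]
        if ax is None:
            _, axes = plt.subplots(1, M, figsize=(3 * M, 2.5), sharey=True)
        else:
            axes = np.atleast_1d(ax)
        labels = self.model_labels or [f"m{m + 1}" for m in range(M)]
        for m, a in enumerate(np.ravel(axes)[:M]):
            a.hist(self.r_samples[:, m], bins=bins, density=True)
            a.set_xlabel(f"r[{labels[m]}]")
        return axes


def family_posterior(
    post: RandomEffectsResults, partition: FamilyPartition
) -> "FamilyRfxResults":
    """Aggregate retained frequency draws over a family partition.

    Each retained draw r is mapped to family frequencies s_k = sum of member
    r_m; posterior expectations and exceedance probabilities are then computed
    from the aggregated draws.
    """
    M = post.r_samples.shape[1]
    if partition.n_models != M:
        raise ValueError("partition does not cover the model space")
    s_samples = post.r_samples @ partition.indicator().T
    return FamilyRfxResults(s_samples=s_samples, family_names=partition.family_names)


@dataclass
class FamilyRfxResults:
    """Posterior draws of family frequencies and derived summaries."""

    s_samples: np.ndarray
    family_names: tuple[str, ...]

    @property
    def expected_s(self) -> np.ndarray:
        return self.s_samples.mean(axis=0)

    @property
    def exceedance(self) -> np.ndarray:
        return exceedance_from_samples(self.s_samples)

    @property
    def mcse(self) -> np.ndarray:
        return batch_means_mcse(self.s_samples)

    def to_dict(self) -> dict:
        return {
            "family_names": list(self.family_names),
            "expected_s": self.expected_s.tolist(),
            "exceedance": self.exceedance.tolist(),
            "mcse": self.mcse.tolist(),
        }

    def summary(self) -> str:
        df = pd.DataFrame(
            {"expected_s": self.expected_s, "exceedance": self.exceedance, "mcse": self.mcse},
            index=list(self.family_names),
        )
        return "Family-level random-effects inference\n" + df.to_string(
            float_format=lambda x: f"{x:.4f}"
        )


class RandomEffectsBMS:
    """Random-effects group model selection fitted to a log-evidence matrix.

    Parameters
    ----------
    log_evidence : LogEvidenceMatrix or pandas.DataFrame
    prior : DirichletParams, {"flat", "family-uniform"}, optional
        ``"flat"`` is alpha_m = 1 for all m; ``"family-uniform"`` (requires
        ``partition``) is alpha_m = 1/N_k.
    partition : FamilyPartition, optional
    """

    def __init__(self, log_evidence, prior="flat", partition: FamilyPartition | None = None):
        if isinstance(log_evidence, pd.DataFrame):
            log_evidence = LogEvidenceMatrix.from_dataframe(log_evidence)
        self.log_evidence = log_evidence
        self.partition = partition
        if partition is not None and partition.n_models != log_evidence.n_models:
            raise ValueError("partition size does not match the number of models")
        if isinstance(prior, str):
            if prior == "flat":
                prior = default_model_prior(log_evidence.n_models)
            elif prior == "family-uniform":
                if partition is None:
                    raise ValueError("family-uniform prior requires a partition")
                prior = family_uniform_prior(partition)
            else:
                raise ValueError(f"unknown prior {prior!r}")
        if not isinstance(prior, DirichletParams):
            prior = DirichletParams(np.asarray(prior, dtype=float))
        if len(prior) != log_evidence.n_models:
            raise ValueError("prior length does not match the number of models")
        self.prior = prior

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RandomEffectsBMS":
        return cls(LogEvidenceMatrix.from_dataframe(df), **kwargs)

    def fit(
        self,
        method: str = "gibbs",
        n_total: int = DEFAULT_N_TOTAL,
        burn_in: int = DEFAULT_BURN_IN,
        seed: int = 0,
        **kwargs,
    ):
        """Run the sampler (``method="gibbs"``) or the VB fixed point (``"vb"``)."""
        if method == "gibbs":
            return gibbs_sample(
                self.log_evidence, self.prior, n_total=n_total, burn_in=burn_in, seed=seed
            )
        if method == "vb":
            return vb_update(self.log_evidence, self.prior, **kwargs)
        raise ValueError(f"unknown method {method!r}")
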