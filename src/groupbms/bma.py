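"""Bayesian model averaging (BMA) of parameter posteriors within a family.

Each subject n and model m carries a Gaussian approximation to the parameter
posterior, with a free-parameter mask: parameters a model fixes to zero a
priori contribute a point mass (delta function) at zero to the model-averaged
density.  Averaging over models inside a chosen family, weighted by model
posteriors, therefore yields a mixture of Gaussians and delta functions —
multimodal in general, so it is represented by samples.

One group-average sample is produced by: drawing a model per subject (RFX:
from that subject's own posterior model probabilities g_n; FFX: one shared
model draw from the group posterior, applied to every subject), drawing a
parameter vector from the chosen subject/model Gaussian with zeros on masked
parameters, and averaging the per-subject vectors.  Low-probability models
are pruned beforehand with Occam's window (posterior odds against the best
model above a minimal ratio pi_occ); under RFX the window is applied per
subject, so subjects can retain different model sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GaussianPosterior",
    "SubjectPosteriorSet",
    "OccamWindow",
    "BmaDensity",
    "occams_window",
    "bma_sample_group",
    "bma_subject_density",
    "summarize_density",
    "DEFAULT_PI_OCC",
]

DEFAULT_PI_OCC = 1.0 / 20.0


@dataclass(frozen=True)
class GaussianPosterior:
    """Gaussian parameter posterior for one subject under one model.

    ``free_mask[p] = 0`` means the model fixes parameter ``p`` at zero a
    priori; the corresponding mean entry and covariance row/column must be
    zero.  Units are those of the underlying coupling parameters (Hz for
    rate-modulation parameters in dynamic causal models).
    """

    mean: np.ndarray
    covariance: np.ndarray
    free_mask: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        mask = np.asarray(self.free_mask, dtype=bool)
        P = mu.size
        if cov.shape != (P, P) or mask.shape != (P,):
            raise ValueError("mean, covariance and free_mask sizes disagree")
        if np.abs(cov - cov.T).max(initial=0.0) > 1e-10:
            raise ValueError("covariance must be symmetric")
        fixed = ~mask
        if np.abs(mu[fixed]).max(initial=0.0) > 0:
            raise ValueError("masked-out parameters must have zero mean")
        if np.abs(cov[fixed, :]).max(initial=0.0) > 0 or np.abs(cov[:, fixed]).max(initial=0.0) > 0:
            raise ValueError("masked-out parameters must have zero covariance rows/columns")
        object.__setattr__(self, "mean", mu)
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "free_mask", mask)

    @property
    def n_params(self) -> int:
        return self.mean.size

    def sqrt_free(self) -> np.ndarray:
        """Symmetric square root of the free-parameter covariance block.

        Variational covariances can be numerically indefinite; eigenvalues
        below 1e-10 times the largest are clamped to zero.
        """
        sub = self.covariance[np.ix_(self.free_mask, self.free_mask)]
        if sub.size == 0:
            return np.zeros((0, 0))
        w, v = np.linalg.eigh(sub)
        tol = 1e-10 * max(w.max(initial=0.0), 0.0)
        if w.min(initial=0.0) < -max(tol, 1e-12):
            raise ValueError("covariance is not positive semi-definite")
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w) @ v.T

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """``size`` draws; masked parameters are exactly zero."""
        out = np.zeros((size, self.n_params))
        k = int(self.free_mask.sum())
        if k:
            z = rng.standard_normal((size, k))
            out[:, self.free_mask] = self.mean[self.free_mask] + z @ self.sqrt_free().T
        return out


@dataclass(frozen=True)
class SubjectPosteriorSet:
    """Complete N x M grid of Gaussian posteriors over shared parameter names."""

    posteriors: tuple[tuple[GaussianPosterior, ...], ...]  # [subject][model]
    parameter_names: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()
    model_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        posts = tuple(tuple(row) for row in self.posteriors)
        object.__setattr__(self, "posteriors", posts)
        object.__setattr__(self, "parameter_names", tuple(self.parameter_names))
        if not posts or not posts[0]:
            raise ValueError("posterior grid must be non-empty")
        M = len(posts[0])
        P = len(self.parameter_names)
        for row in posts:
            if len(row) != M:
                raise ValueError("posterior grid is ragged")
            for cell in row:
                if cell.n_params != P:
                    raise ValueError("all cells must share the parameter naming")
        if not self.subject_ids:
            object.__setattr__(self, "subject_ids", tuple(f"sub{n + 1}" for n in range(len(posts))))
        if not self.model_labels:
            object.__setattr__(self, "model_labels", tuple(f"m{m + 1}" for m in range(M)))

    @property
    def n_subjects(self) -> int:
        return len(self.posteriors)

    @property
    def n_models(self) -> int:
        return len(self.posteriors[0])

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)


@dataclass(frozen=True)
class OccamWindow:
    """Models retained for averaging: posterior odds vs the best above pi_occ."""

    included: np.ndarray  # indices into the candidate set
    pi_occ: float

    @property
    def window_size(self) -> int:
        """Number of retained models; small windows indicate peaky posteriors."""
        return int(self.included.size)


def occams_window(post_probs: np.ndarray, pi_occ: float = DEFAULT_PI_OCC) -> OccamWindow:
    """Prune low-probability models before averaging.

    Model j is retained iff p_j / max(p) > pi_occ; the (tied) maximal models
    are always retained, so pi_occ = 1 keeps exactly the argmax set and
    pi_occ near 0 keeps every model with non-zero probability.
    """
    p = np.asarray(post_probs, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty probability vector")
    if not (0 < pi_occ <= 1):
        raise ValueError("pi_occ must be in (0, 1]")
    best = p.max()
    keep = (p / best > pi_occ) | (p == best)
    return OccamWindow(np.flatnonzero(keep), float(pi_occ))


def _normalise_weights(
    weights: np.ndarray, n_subjects: int, n_models: int, mode: str, family: np.ndarray
) -> np.ndarray:
    """Restrict weights to the family, renormalise, return an N x len(family) grid."""
    w = np.asarray(weights, dtype=float)
    if mode == "ffx":
        if w.ndim != 1 or w.size != n_models:
            raise ValueError("FFX weights must be a length-M model posterior")
        w = np.tile(w, (n_subjects, 1))
    elif mode == "rfx":
        if w.ndim != 2 or w.shape != (n_subjects, n_models):
            raise ValueError("RFX weights must be the N x M per-subject posterior g")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    fam = w[:, family]
    tot = fam.sum(axis=1, keepdims=True)
    if (tot <= 0).any():
        raise ValueError("a subject has zero posterior mass on the requested family")
    return fam / tot


def _windowed_rows(fam_weights: np.ndarray, pi_occ: float) -> np.ndarray:
    """Apply Occam's window row-wise and renormalise; returns same-shape grid."""
    out = np.zeros_like(fam_weights)
    for n in range(fam_weights.shape[0]):
        win = occams_window(fam_weights[n], pi_occ)
        row = np.zeros(fam_weights.shape[1])
        row[win.included] = fam_weights[n, win.included]
        out[n] = row / row.sum()
    return out


@dataclass
class BmaDensity:
    """Sample-based model-averaged posterior with explicit zero mass.

    ``zero_mass[p]`` is the posterior probability that parameter ``p`` is
    exactly zero — the height of the delta function at zero, i.e. the
    realised probability that every contributing model draw fixed it.  It is
    tracked analytically from the model-draw indicators, not by testing
    floating-point samples against zero.
    """

    theta_samples: np.ndarray
    zero_mass: np.ndarray
    parameter_names: tuple[str, ...]
    window_sizes: np.ndarray = field(default_factory=lambda: np.array([]))
    seed: int | None = None

    @property
    def n_samples(self) -> int:
        return self.theta_samples.shape[0]

    def summary(self, levels=(0.95,)) -> pd.DataFrame:
        return summarize_density(self, levels=levels)

    def plot(self, params=None, bins: int = 60):
        """Histogram the averaged posterior for chosen parameters."""
        import matplotlib.pyplot as plt

        names = list(self.parameter_names)
        idx = range(len(names)) if params is None else [names.index(p) for p in params]
        fig, axes = plt.subplots(1, len(list(idx)), figsize=(3 * len(list(idx)), 2.5))
        for a, p in zip(np.ravel(np.atleast_1d(axes)), idx):
            a.hist(self.theta_samples[:, p], bins=bins, density=True)
            a.set_xlabel(names[p])
        return fig


def _grid_draw(
    posts: SubjectPosteriorSet,
    subject_rows: np.ndarray,
    weights: np.ndarray,
    family: np.ndarray,
    S: int,
    rng: np.random.Generator,
    shared_draw: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw S parameter vectors per listed subject.

    Returns ``theta`` of shape (S, n_rows, P) and the boolean free indicator
    of shape (S, n_rows, P) recording which drawn models freed each parameter.
    """
    P = posts.n_params
    n_rows = subject_rows.size
    theta = np.zeros((S, n_rows, P))
    free = np.zeros((S, n_rows, P), dtype=bool)
    if shared_draw:
        # one model index per sample, applied to every subject
        m_draw = rng.choice(family.size, size=S, p=weights[0])
        m_grid = np.tile(m_draw[:, None], (1, n_rows))
    else:
        m_grid = np.empty((S, n_rows), dtype=int)
        for r in range(n_rows):
            m_grid[:, r] = rng.choice(family.size, size=S, p=weights[r])
    for r, n in enumerate(subject_rows):
        for local_m in np.unique(m_grid[:, r]):
            cell = posts.posteriors[n][family[local_m]]
            sel = np.flatnonzero(m_grid[:, r] == local_m)
            theta[sel, r, :] = cell.draw(rng, sel.size)
            free[sel, r, :] = cell.free_mask
    return theta, free


def bma_sample_group(
    posts: SubjectPosteriorSet,
    weights: np.ndarray,
    mode: str,
    family: np.ndarray | list[int] | None = None,
    S: int = 10_000,
    pi_occ: float = DEFAULT_PI_OCC,
    seed: int = 0,
) -> BmaDensity:
    """Sample the group-average ('average subject') model-averaged posterior.

    Parameters
    ----------
    posts : SubjectPosteriorSet
    weights : array
        ``mode="ffx"``: length-M group model posterior (shared by subjects);
        ``mode="rfx"``: N x M per-subject posterior model probabilities g.
    family : index array, optional
        Models to average within (default: the whole comparison set).
    S : int
        Number of group-average samples.
    pi_occ : float
        Occam's-window minimal posterior odds ratio; under RFX the window is
        applied separately to each subject's weight row.
    """
    if S < 1:
        raise ValueError("need at least one sample")
    N, M = posts.n_subjects, posts.n_models
    family = np.arange(M) if family is None else np.asarray(sorted(family), dtype=int)
    if family.size == 0:
        raise ValueError("family must contain at least one model")
    fam_w = _normalise_weights(weights, N, M, mode, family)
    fam_w = _windowed_rows(fam_w, pi_occ)
    if mode == "ffx" and not np.allclose(fam_w, fam_w[0]):
        raise ValueError("FFX weights must be identical across subjects")
    rng = np.random.default_rng(seed)
    theta, free = _grid_draw(
        posts, np.arange(N), fam_w, family, int(S), rng, shared_draw=(mode == "ffx")
    )
    group = theta.mean(axis=1)
    # the average is exactly zero only when no subject's drawn model freed it
    zero_mass = 1.0 - free.any(axis=1).mean(axis=0)
    window_sizes = (fam_w > 0).sum(axis=1)
    return BmaDensity(group, zero_mass, posts.parameter_names, window_sizes, int(seed))


def bma_subject_density(
    posts: SubjectPosteriorSet,
    weights: np.ndarray,
    subject: int,
    family: np.ndarray | list[int] | None = None,
    S: int = 10_000,
    pi_occ: float = DEFAULT_PI_OCC,
    seed: int = 0,
) -> BmaDensity:
    """Within-subject model-averaged posterior (no across-subject averaging).

    Summary statistics of these densities can be exported per subject and
    entered into standard group-level random-effects tests.
    """
    N, M = posts.n_subjects, posts.n_models
    if not 0 <= subject < N:
        raise IndexError("subject index out of range")
    family = np.arange(M) if family is None else np.asarray(sorted(family), dtype=int)
    fam_w = _normalise_weights(weights, N, M, "rfx" if np.ndim(weights) == 2 else "ffx", family)
    fam_w = _windowed_rows(fam_w, pi_occ)
    rng = np.random.default_rng(seed)
    theta, free = _grid_draw(
        posts, np.array([subject]), fam_w[[subject]], family, int(S), rng, shared_draw=False
    )
    zero_mass = 1.0 - free[:, 0, :].mean(axis=0)
    window_sizes = (fam_w[[subject]] > 0).sum(axis=1)
    return BmaDensity(theta[:, 0, :], zero_mass, posts.parameter_names, window_sizes, int(seed))


def summarize_density(d: BmaDensity, levels=(0.95,)) -> pd.DataFrame:
    """Per-parameter posterior mean, credible intervals, zero mass and P(>0)."""
    if d.n_samples < 100:
        raise ValueError("need at least 100 samples for stable summaries")
    t = d.theta_samples
    out = {
        "mean": t.mean(axis=0),
        "zero_mass": d.zero_mass,
        "p_positive": (t > 0).mean(axis=0),
    }
    for lev in levels:
        lo, hi = (1 - lev) / 2, 1 - (1 - lev) / 2
        out[f"ci{int(round(lev * 100))}_low"] = np.quantile(t, lo, axis=0)
        out[f"ci{int(round(lev * 100))}_high"] = np.quantile(t, hi, axis=0)
    return pd.DataFrame(out, index=list(d.parameter_names))
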