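"""Fixed-effects (FFX) group Bayesian model selection.

FFX inference assumes every subject's data were generated by the same model.
Because subjects are conditionally independent, the group log evidence for a
model is the sum of per-subject log evidences, and the group-level posterior
over models follows from Bayes' rule with a chosen model prior.  Family-level
posteriors are obtained by summing member-model posteriors; a family-uniform
model prior (p(m) = 1/(K * N_k) for a model in family k of size N_k) removes
the bias that unequal family sizes would otherwise induce.

All evidence arithmetic is carried out in natural-log space (log-sum-exp);
probabilities are materialised only at the end, so log-evidence differences of
order hundreds or thousands neither overflow nor underflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .evidence import LogEvidenceMatrix
from .model_space import FamilyPartition

__all__ = [
    "ModelPrior",
    "FixedEffectsBMS",
    "FixedEffectsResults",
    "joint_log_evidence",
    "model_posterior",
    "log_model_posterior",
    "bayes_factor",
    "group_bayes_factor",
    "posterior_odds",
    "family_uniform_model_prior",
    "ffx_family_posterior",
]


@dataclass(frozen=True)
class ModelPrior:
    """Prior probability over the comparison set; strictly positive, sums to 1."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or (p <= 0).any():
            raise ValueError("prior probabilities must be a 1-D vector of positives")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"prior must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "probs", p)

    @classmethod
    def flat(cls, M: int) -> "ModelPrior":
        return cls(np.full(M, 1.0 / M))

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


def joint_log_evidence(L: LogEvidenceMatrix | np.ndarray) -> np.ndarray:
    """Group log evidence per model: the sum over subjects of log p(Y_n|m)."""
    vals = L.values if isinstance(L, LogEvidenceMatrix) else np.asarray(L, dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("log evidences must be finite")
    return vals.sum(axis=0)


def log_model_posterior(joint_log_ev: np.ndarray, prior: ModelPrior) -> np.ndarray:
    """Log posterior over models: log-softmax of joint log evidence + log prior."""
    lev = np.asarray(joint_log_ev, dtype=float)
    if lev.shape != prior.probs.shape:
        raise ValueError("joint log evidence and prior lengths differ")
    unnorm = lev + prior.log_probs
    return unnorm - logsumexp(unnorm)


def model_posterior(joint_log_ev: np.ndarray, prior: ModelPrior) -> np.ndarray:
    """Posterior model probabilities under the FFX assumption (sums to 1)."""
    return np.exp(log_model_posterior(joint_log_ev, prior))


def bayes_factor(log_ev_i: float, log_ev_j: float) -> tuple[float, float]:
    """Bayes factor of model i over model j and its natural log.

    BF_ij = p(Y|i) / p(Y|j) = exp(log_ev_i - log_ev_j).  A BF above 20 is
    conventionally labelled 'strong' evidence.
    """
    if not (np.isfinite(log_ev_i) and np.isfinite(log_ev_j)):
        raise ValueError("log evidences must be finite")
    log_bf = float(log_ev_i) - float(log_ev_j)
    return float(np.exp(log_bf)), log_bf


def group_bayes_factor(L: LogEvidenceMatrix, i: int, j: int) -> tuple[float, float]:
    """Group Bayes factor: the product over subjects of individual Bayes factors."""
    M = L.n_models
    if not (0 <= i < M and 0 <= j < M):
        raise IndexError("model index out of range")
    if i == j:
        warnings.warn("comparing a model with itself; GBF is trivially 1", stacklevel=2)
    log_gbf = float((L.values[:, i] - L.values[:, j]).sum())
    return float(np.exp(log_gbf)), log_gbf


def posterior_odds(prior_odds: float, bf: float) -> float:
    """Posterior odds = Bayes factor x prior odds."""
    if prior_odds <= 0 or bf <= 0:
        raise ValueError("prior odds and Bayes factor must be positive")
    return float(bf * prior_odds)


def family_uniform_model_prior(partition: FamilyPartition) -> ModelPrior:
    """Model prior giving every family the same marginal prior probability 1/K.

    Within family k of size N_k each member gets p(m) = 1/(K * N_k), so the
    family marginals are uniform regardless of family sizes.  This counters
    dilution: without it, large families of similar models would soak up prior
    mass in proportion to their size.
    """
    K = partition.n_families
    sizes = partition.sizes
    probs = 1.0 / (K * sizes[np.asarray(partition.membership)])
    return ModelPrior(probs)


def ffx_family_posterior(
    model_post: np.ndarray, partition: FamilyPartition
) -> tuple[np.ndarray, np.ndarray]:
    """Family posterior (sum of member-model posteriors) and alternative probability.

    The alternative probability 1 - p(family | Y) is the combined posterior
    probability of all competing families; it is the quantity quoted when a
    family posterior is very close to one.
    """
    p = np.asarray(model_post, dtype=float)
    if p.shape[0] != partition.n_models:
        raise ValueError("partition does not cover the posterior vector")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("model posterior must sum to 1")
    fam = partition.indicator() @ p
    return fam, 1.0 - fam


class FixedEffectsBMS:
    """Fixed-effects group model selection fitted to a log-evidence matrix.

    Parameters
    ----------
    log_evidence : LogEvidenceMatrix or pandas.DataFrame
        Per-subject, per-model natural-log evidence approximations.
    prior : ModelPrior, {"flat", "family-uniform"}, optional
        Model prior.  ``"family-uniform"`` requires ``partition`` and assigns
        p(m) = 1/(K * N_k).  Default flat.
    partition : FamilyPartition, optional
        Family structure for family-level posteriors.
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
                prior = ModelPrior.flat(log_evidence.n_models)
            elif prior == "family-uniform":
                if partition is None:
                    raise ValueError("family-uniform prior requires a partition")
                prior = family_uniform_model_prior(partition)
            else:
                raise ValueError(f"unknown prior {prior!r}")
        if prior.probs.shape[0] != log_evidence.n_models:
            raise ValueError("prior length does not match the number of models")
        self.prior = prior

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FixedEffectsBMS":
        return cls(LogEvidenceMatrix.from_dataframe(df), **kwargs)

    def fit(self) -> "FixedEffectsResults":
        jle = joint_log_evidence(self.log_evidence)
        log_post = log_model_posterior(jle, self.prior)
        return FixedEffectsResults(self, jle, log_post)


class FixedEffectsResults:
    """Posterior quantities from a fixed-effects analysis.

    Attributes
    ----------
    joint_log_evidence : np.ndarray
        Length-M group log evidences (sums over subjects).
    model_posterior : np.ndarray
        Length-M posterior model probabilities.
    family_posterior, family_alternative_prob : np.ndarray or None
        Length-K family posteriors and their complements (if a partition was
        supplied).
    family_log_posterior : np.ndarray or None
        Log family posteriors shifted so the best family is 0 — the
        conventional display scale, since raw values can be hundreds of log
        units apart.
    """

    def __init__(self, model: FixedEffectsBMS, jle: np.ndarray, log_post: np.ndarray):
        self.model = model
        self.joint_log_evidence = jle
        self.log_model_posterior = log_post
        self.model_posterior = np.exp(log_post)
        part = model.partition
        if part is not None:
            ind = part.indicator().astype(bool)
            log_fam = np.array([logsumexp(log_post[row]) for row in ind])
            self.family_log_posterior = log_fam - log_fam.max()
            self.family_posterior = np.exp(log_fam - logsumexp(log_fam))
            self.family_alternative_prob = 1.0 - self.family_posterior
        else:
            self.family_log_posterior = None
            self.family_posterior = None
            self.family_alternative_prob = None

    @property
    def best_model(self) -> int:
        return int(np.argmax(self.joint_log_evidence + self.model.prior.log_probs))

    def group_bayes_factor(self, i: int, j: int) -> tuple[float, float]:
        return group_bayes_factor(self.model.log_evidence, i, j)

    def family_table(self) -> pd.DataFrame:
        if self.family_posterior is None:
            raise ValueError("no family partition was supplied")
        part = self.model.partition
        return pd.DataFrame(
            {
                "posterior": self.family_posterior,
                "log_posterior": self.family_log_posterior,
                "alternative_prob": self.family_alternative_prob,
                "n_models": part.sizes,
            },
            index=list(part.family_names),
        )

    def to_dict(self) -> dict:
        out = {
            "method": "ffx",
            "model_labels": list(self.model.log_evidence.model_labels),
            "joint_log_evidence": self.joint_log_evidence.tolist(),
            "model_posterior": self.model_posterior.tolist(),
        }
        if self.family_posterior is not None:
            out["family_names"] = list(self.model.partition.family_names)
            out["family_posterior"] = self.family_posterior.tolist()
            out["family_log_posterior"] = self.family_log_posterior.tolist()
            out["family_alternative_prob"] = self.family_alternative_prob.tolist()
        return out

    def summary(self) -> str:
        L = self.model.log_evidence
        lines = [
            "Fixed-effects Bayesian model selection",
            f"  subjects: {L.n_subjects}   models: {L.n_models}",
            f"  best model: {L.model_labels[self.best_model]} "
            f"(posterior {self.model_posterior[self.best_model]:.4f})",
        ]
        if self.family_posterior is not None:
            lines.append("")
            lines.append(self.family_table().to_string(float_format=lambda x: f"{x:.4f}"))
        return "\n".join(lines)
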