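"""Discrete model spaces for effective-connectivity studies and their family partitions.

A model space enumerates candidate network architectures over ``R`` brain
regions.  Each model is defined by (i) an *input pattern* — which regions
receive the driving experimental input (the C-matrix of a dynamic causal
model) — and (ii) a *modulation pattern* — which directed inter-regional
connections are allowed to be modulated by the experimental factor (the
B-matrix).  Endogenous (A-matrix) connectivity is taken as all-to-all and is
not enumerated; it is carried only as metadata.

Families are disjoint, exhaustive, named subsets of the model space.  Two
scientifically standard partitions are provided: by input pattern, and by the
predominance of forward versus backward modulated connections relative to a
cortical hierarchy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "ModelSpace",
    "FamilyPartition",
    "enumerate_input_patterns",
    "enumerate_modulation_patterns",
    "build_model_space",
    "partition_by_input",
    "partition_by_flow",
    "complete_partition",
]


@dataclass(frozen=True)
class ModelSpec:
    """A single network architecture.

    Parameters
    ----------
    input_pattern : np.ndarray
        Binary vector of length ``R``; entry ``r`` is 1 if region ``r``
        receives the driving input.  At least one entry must be 1.
    modulation_pattern : np.ndarray
        Binary ``R x R`` matrix with zero diagonal.  Entry ``(i, j)`` is 1 if
        the connection *from region j to region i* is modulated (column =
        source, row = destination, the usual connectivity-matrix convention).
        User-facing I/O always names connections as ``"src->dst"`` strings.
    label : str
        Unique text identifier.
    """

    input_pattern: np.ndarray
    modulation_pattern: np.ndarray
    label: str

    def __post_init__(self) -> None:
        inp = np.asarray(self.input_pattern, dtype=int)
        mod = np.asarray(self.modulation_pattern, dtype=int)
        if inp.ndim != 1 or not np.isin(inp, (0, 1)).all():
            raise ValueError("input_pattern must be a binary vector")
        if inp.sum() < 1:
            raise ValueError("at least one region must receive input")
        R = inp.size
        if mod.shape != (R, R) or not np.isin(mod, (0, 1)).all():
            raise ValueError(f"modulation_pattern must be a binary {R}x{R} matrix")
        if np.diagonal(mod).any():
            raise ValueError("modulation_pattern must have a zero diagonal")
        object.__setattr__(self, "input_pattern", inp)
        object.__setattr__(self, "modulation_pattern", mod)

    @property
    def n_regions(self) -> int:
        return self.input_pattern.size

    def input_regions(self, region_labels: list[str]) -> list[str]:
        return [region_labels[r] for r in np.flatnonzero(self.input_pattern)]

    def modulated_connections(self, region_labels: list[str]) -> list[str]:
        """Modulated connections as ``"src->dst"`` strings (row-major order)."""
        out = []
        for dst, src in zip(*np.nonzero(self.modulation_pattern)):
            out.append(f"{region_labels[src]}->{region_labels[dst]}")
        return out


@dataclass(frozen=True)
class ModelSpace:
    """An ordered comparison set of :class:`ModelSpec` over named regions."""

    models: tuple[ModelSpec, ...]
    region_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "models", tuple(self.models))
        object.__setattr__(self, "region_labels", tuple(self.region_labels))
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValueError("model labels must be unique")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> ModelSpec:
        return self.models[i]

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.models]

    def to_table(self):
        """Export as a DataFrame: label, input regions, modulated connections."""
        import pandas as pd

        rows = []
        for m in self.models:
            rows.append(
                {
                    "label": m.label,
                    "input_pattern": "".join(m.input_regions(list(self.region_labels))),
                    "modulated": ";".join(m.modulated_connections(list(self.region_labels))),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FamilyPartition:
    """A disjoint, exhaustive split of model indices into named families."""

    family_names: tuple[str, ...]
    membership: tuple[int, ...]  # model index -> family index

    def __post_init__(self) -> None:
        object.__setattr__(self, "family_names", tuple(self.family_names))
        object.__setattr__(self, "membership", tuple(int(k) for k in self.membership))
        K = len(self.family_names)
        if len(set(self.family_names)) != K:
            raise ValueError("family names must be unique")
        seen = set(self.membership)
        if not seen:
            raise ValueError("partition must cover at least one model")
        if seen - set(range(K)):
            raise ValueError("membership refers to an unknown family index")
        if set(range(K)) - seen:
            missing = [self.family_names[k] for k in sorted(set(range(K)) - seen)]
            raise ValueError(f"empty families not allowed: {missing}")

    @property
    def n_models(self) -> int:
        return len(self.membership)

    @property
    def n_families(self) -> int:
        return len(self.family_names)

    @property
    def sizes(self) -> np.ndarray:
        """Number of models per family, aligned with ``family_names``."""
        return np.bincount(self.membership, minlength=self.n_families)

    def members(self, family: int | str) -> np.ndarray:
        """Model indices belonging to a family (by index or name)."""
        k = self.family_names.index(family) if isinstance(family, str) else int(family)
        return np.flatnonzero(np.asarray(self.membership) == k)

    def indicator(self) -> np.ndarray:
        """K x M binary membership matrix (families in rows)."""
        ind = np.zeros((self.n_families, self.n_models), dtype=int)
        ind[np.asarray(self.membership), np.arange(self.n_models)] = 1
        return ind

    @classmethod
    def from_members(
        cls, named_members: dict[str, list[int]], n_models: int
    ) -> "FamilyPartition":
        membership = np.full(n_models, -1, dtype=int)
        names = list(named_members)
        for k, name in enumerate(names):
            idx = np.asarray(named_members[name], dtype=int)
            if (membership[idx] != -1).any():
                raise ValueError(f"family {name!r} overlaps an earlier family")
            membership[idx] = k
        if (membership == -1).any():
            raise ValueError("partition does not cover all models")
        return cls(tuple(names), tuple(membership))


def enumerate_input_patterns(R: int) -> list[np.ndarray]:
    """All non-empty binary input patterns over ``R`` regions.

    There are ``2**R - 1`` patterns (models with no driving input are
    discounted), returned in binary-counting order with region 0 as the least
    significant bit.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    patterns = []
    for code in range(1, 2**R):
        patterns.append(np.array([(code >> r) & 1 for r in range(R)], dtype=int))
    return patterns


def enumerate_modulation_patterns(R: int) -> list[np.ndarray]:
    """All binary modulation patterns over the ``R*(R-1)`` directed connections.

    There are ``2**(R*(R-1))`` patterns including the empty one, returned in
    binary-counting order over a row-major flattening of the off-diagonal
    entries (least significant bit first).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    offdiag = [(i, j) for i in range(R) for j in range(R) if i != j]
    patterns = []
    for code in range(2 ** len(offdiag)):
        mat = np.zeros((R, R), dtype=int)
        for bit, (i, j) in enumerate(offdiag):
            mat[i, j] = (code >> bit) & 1
        patterns.append(mat)
    return patterns


def build_model_space(
    R: int, region_labels: list[str] | None = None
) -> ModelSpace:
    """Cross every non-empty input pattern with every modulation pattern.

    The space has ``(2**R - 1) * 2**(R*(R-1))`` models: 448 for three regions.
    Ordering is canonical — input patterns outermost, modulation patterns
    innermost, each in binary-counting order — so model indices are stable
    across runs and file round-trips.
    """
    if region_labels is None:
        region_labels = [f"R{r}" for r in range(R)]
    if len(region_labels) != R:
        raise ValueError("need one label per region")
    models = []
    for idx, (inp, mod) in enumerate(
        itertools.product(enumerate_input_patterns(R), enumerate_modulation_patterns(R))
    ):
        models.append(ModelSpec(inp, mod, label=f"m{idx + 1}"))
    return ModelSpace(tuple(models), tuple(region_labels))


def partition_by_input(space: ModelSpace) -> FamilyPartition:
    """One family per distinct input pattern, named by its input regions."""
    if len(space) == 0:
        raise ValueError("model space is empty")
    names: list[str] = []
    keys: dict[tuple, int] = {}
    membership = []
    for m in space.models:
        key = tuple(m.input_pattern)
        if key not in keys:
            keys[key] = len(names)
            names.append("".join(m.input_regions(list(space.region_labels))))
        membership.append(keys[key])
    return FamilyPartition(tuple(names), tuple(membership))


def count_flow(
    model: ModelSpec, region_labels: list[str], hierarchy: list[str]
) -> tuple[int, int]:
    """Count modulated forward (low->high) and backward (high->low) connections."""
    rank = {lab: h for h, lab in enumerate(hierarchy)}
    f = b = 0
    for dst, src in zip(*np.nonzero(model.modulation_pattern)):
        if rank[region_labels[src]] < rank[region_labels[dst]]:
            f += 1
        else:
            b += 1
    return f, b


def partition_by_flow(space: ModelSpace, hierarchy: list[str]) -> FamilyPartition:
    """Partition by predominance of forward versus backward modulation.

    ``hierarchy`` orders the region labels from the bottom of the cortical
    hierarchy to the top.  A model is family ``"F"`` if it modulates strictly
    more forward (low-to-high) than backward connections, ``"B"`` if strictly
    more backward, ``"BAL"`` if equal counts with at least one modulated
    connection, and ``"None"`` if nothing is modulated.
    """
    if sorted(hierarchy) != sorted(space.region_labels):
        raise ValueError("hierarchy must be a permutation of the region labels")
    names = ("F", "B", "BAL", "None")
    membership = []
    for m in space.models:
        f, b = count_flow(m, list(space.region_labels), list(hierarchy))
        if f > b:
            membership.append(0)
        elif b > f:
            membership.append(1)
        elif f + b > 0:
            membership.append(2)
        else:
            membership.append(3)
    present = sorted(set(membership))
    # drop names for families that never occur in a restricted sub-space
    remap = {old: new for new, old in enumerate(present)}
    return FamilyPartition(
        tuple(names[k] for k in present), tuple(remap[k] for k in membership)
    )


def complete_partition(
    partial: dict[str, list[int]],
    space: ModelSpace | int,
    remainder_name: str = "other",
) -> FamilyPartition:
    """Complete a partial named grouping into a full partition.

    Models not covered by any of the named subsets are collected into an
    appended remainder family.  Overlapping subsets are rejected.
    """
    M = len(space) if isinstance(space, ModelSpace) else int(space)
    membership = np.full(M, -1, dtype=int)
    names = []
    for name, idx in partial.items():
        idx = np.asarray(sorted(idx), dtype=int)
        if idx.size == 0:
            raise ValueError(f"family {name!r} is empty")
        if idx.min() < 0 or idx.max() >= M:
            raise ValueError(f"family {name!r} refers to a model outside the space")
        if (membership[idx] != -1).any():
            raise ValueError(f"family {name!r} overlaps another family")
        membership[idx] = len(names)
        names.append(name)
    rest = np.flatnonzero(membership == -1)
    if rest.size:
        if remainder_name in names:
            raise ValueError(f"remainder name {remainder_name!r} already used")
        membership[rest] = len(names)
        names.append(remainder_name)
    return FamilyPartition(tuple(names), tuple(membership))
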