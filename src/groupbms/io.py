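"""Readers and writers for evidence matrices, family configs and posterior archives.

Formats are deliberately plain: delimited text for matrices, JSON/YAML for
configuration and results, a JSON container for subject/model parameter
posteriors.  Numbers are serialised with shortest-round-trip precision so
write-then-read is lossless; parsing is locale-independent (decimal point
only).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bma import GaussianPosterior, SubjectPosteriorSet
from .evidence import LogEvidenceMatrix
from .model_space import FamilyPartition, complete_partition

__all__ = [
    "read_evidence",
    "write_evidence",
    "read_families",
    "write_families",
    "read_posterior_archive",
    "write_posterior_archive",
    "write_json",
]

REMAINDER_KEY = "__remainder__"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_evidence(path: str | Path) -> LogEvidenceMatrix:
    """Read a delimited evidence table (header = model labels, col 1 = subject ids).

    Malformed cells are rejected with a diagnostic naming the subject and
    model of the offending entry.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: need at least one subject row and one model column")
    vals = np.empty(df.shape)
    for i, sub in enumerate(df.index):
        for j, mod in enumerate(df.columns):
            cell = df.iat[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("blank")
                vals[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: bad log evidence for subject {sub!r}, model {mod!r}: {cell!r}"
                ) from None
    return LogEvidenceMatrix(vals, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def write_evidence(L: LogEvidenceMatrix, path: str | Path) -> None:
    path = Path(path)
    L.to_dataframe().to_csv(path, sep=_sep_for(path), float_format="%.17g")


def _load_structured(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)


def read_families(path: str | Path, model_labels: list[str]) -> FamilyPartition:
    """Read a family config mapping family name -> list of model labels.

    The reserved key ``"__remainder__"`` names a family that automatically
    collects all models not listed elsewhere.  Unknown labels, overlaps, and
    non-exhaustive configs without a remainder are configuration errors.
    """
    path = Path(path)
    raw = _load_structured(path)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"{path}: expected a non-empty mapping of family -> model labels")
    label_idx = {lab: i for i, lab in enumerate(model_labels)}
    remainder_name = raw.pop(REMAINDER_KEY, None)
    partial: dict[str, list[int]] = {}
    for fam, labs in raw.items():
        if not isinstance(labs, (list, tuple)) or not labs:
            raise ValueError(f"{path}: family {fam!r} must list at least one model label")
        idx = []
        for lab in labs:
            if lab not in label_idx:
                raise ValueError(f"{path}: family {fam!r} names unknown model {lab!r}")
            idx.append(label_idx[lab])
        partial[str(fam)] = idx
    covered = [i for idx in partial.values() for i in idx]
    if len(set(covered)) != len(covered):
        raise ValueError(f"{path}: families overlap")
    if remainder_name is None and len(set(covered)) != len(model_labels):
        missing = [model_labels[i] for i in range(len(model_labels)) if i not in set(covered)]
        raise ValueError(
            f"{path}: models {missing} belong to no family; add them or set "
            f"'{REMAINDER_KEY}' to a remainder family name"
        )
    return complete_partition(
        partial, len(model_labels), remainder_name=str(remainder_name or "other")
    )


def write_families(
    partition: FamilyPartition, model_labels: list[str], path: str | Path
) -> None:
    path = Path(path)
    data = {
        name: [model_labels[i] for i in partition.members(k)]
        for k, name in enumerate(partition.family_names)
    }
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def write_posterior_archive(posts: SubjectPosteriorSet, path: str | Path) -> None:
    """Write a subject/model Gaussian posterior grid as a JSON container."""
    cells = {}
    for n, sub in enumerate(posts.subject_ids):
        cells[sub] = {}
        for m, lab in enumerate(posts.model_labels):
            g = posts.posteriors[n][m]
            cells[sub][lab] = {
                "mean": g.mean.tolist(),
                "covariance": g.covariance.tolist(),
                "free_mask": g.free_mask.astype(int).tolist(),
            }
    payload = {
        "parameter_names": list(posts.parameter_names),
        "subject_ids": list(posts.subject_ids),
        "model_labels": list(posts.model_labels),
        "posteriors": cells,
    }
    Path(path).write_text(json.dumps(payload))


def read_posterior_archive(path: str | Path) -> SubjectPosteriorSet:
    """Read a posterior archive, validating that the subject x model grid is complete."""
    path = Path(path)
    raw = json.loads(path.read_text())
    try:
        names = tuple(raw["parameter_names"])
        subs = tuple(raw["subject_ids"])
        mods = tuple(raw["model_labels"])
        cells = raw["posteriors"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing archive key {exc}") from None
    grid = []
    for sub in subs:
        if sub not in cells:
            raise ValueError(f"{path}: no posteriors for subject {sub!r}")
        row = []
        for mod in mods:
            if mod not in cells[sub]:
                raise ValueError(f"{path}: subject {sub!r} missing model {mod!r}")
            c = cells[sub][mod]
            row.append(
                GaussianPosterior(
                    np.asarray(c["mean"], dtype=float),
                    np.asarray(c["covariance"], dtype=float),
                    np.asarray(c["free_mask"], dtype=bool),
                )
            )
        grid.append(tuple(row))
    return SubjectPosteriorSet(tuple(grid), names, subs, mods)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2))
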