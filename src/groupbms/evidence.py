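"""The subjects x models log-evidence matrix — the sole data input to inference.

Each cell holds an approximation to the natural-log model evidence
``log p(Y_n | m)`` for subject ``n`` under model ``m`` (typically a
variational free energy computed upstream during model fitting).  Every model
must have been fitted to every subject: missing cells are an error, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LogEvidenceMatrix"]


@dataclass(frozen=True)
class LogEvidenceMatrix:
    """N x M matrix of per-subject, per-model log evidences (natural log)."""

    values: np.ndarray
    subject_ids: tuple[str, ...]
    model_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D array (subjects x models)")
        if vals.shape[0] < 1 or vals.shape[1] < 1:
            raise ValueError("need at least one subject and one model")
        if not np.isfinite(vals).all():
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                "non-finite log evidence for subject "
                f"{self.subject_ids[bad[0]]!r}, model {self.model_labels[bad[1]]!r}"
            )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "model_labels", tuple(str(m) for m in self.model_labels))
        if vals.shape != (len(self.subject_ids), len(self.model_labels)):
            raise ValueError("shape of values does not match the id/label lists")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        if len(set(self.model_labels)) != len(self.model_labels):
            raise ValueError("model labels must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LogEvidenceMatrix":
        """Build from a DataFrame with subjects in the index, models in columns."""
        return cls(df.to_numpy(dtype=float), tuple(map(str, df.index)), tuple(map(str, df.columns)))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.subject_ids), columns=list(self.model_labels))
        df.index.name = "subject"
        return df

    def select_models(self, labels_or_indices) -> "LogEvidenceMatrix":
        """Restrict the comparison set to a subset of models (order preserved as given)."""
        idx = [
            self.model_labels.index(x) if isinstance(x, str) else int(x)
            for x in labels_or_indices
        ]
        return LogEvidenceMatrix(
            self.values[:, idx],
            self.subject_ids,
            tuple(self.model_labels[i] for i in idx),
        )
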