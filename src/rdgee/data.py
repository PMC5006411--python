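"""Data model for clustered binary trial data.

Two representations are supported:

* :class:`TrialData` — one record per subject: center, binary treatment
  indicator, optional binary baseline covariate, binary outcome.
* :class:`CenterCountTable` — the aggregated two-arm form (events/total per
  center per arm), the shape in which multicenter results are usually
  printed; it expands losslessly to subject level.

Center labels are opaque; internally they are encoded as integers in order
of first appearance.  Under an exchangeable correlation structure every
estimator in this package is invariant to center relabeling and to record
order within a center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, SchemaError

__all__ = [
    "TrialData",
    "CenterCountTable",
    "read_subject_csv",
    "read_count_csv",
    "expand_counts",
    "aggregate_counts",
    "summarize_2x2",
]

#: default column names for subject-level CSV files
DEFAULT_MAPPING = {
    "center": "center",
    "treatment": "treatment",
    "covariate": "covariate",
    "outcome": "outcome",
}


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    try:
        num = arr.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"column '{name}' is not numeric") from exc
    bad = ~np.isin(num, (0.0, 1.0))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(
            f"non-binary value {arr[row]!r} in '{name}' at row {row}"
        )
    return num.astype(np.int8)


@dataclass(frozen=True)
class TrialData:
    """Subject-level clustered binary trial data.

    Parameters
    ----------
    center
        Per-record center label (any hashable dtype).
    treatment
        Binary treatment indicator, 1 = active arm.
    outcome
        Binary outcome.
    covariate
        Optional binary baseline covariate; ``None`` when the analysis
        model carries no covariate.
    """

    center: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    covariate: np.ndarray | None = None
    # integer encoding of centers in first-appearance order (derived)
    center_codes: np.ndarray = field(init=False, repr=False, compare=False)
    center_labels: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        center = np.asarray(self.center)
        if center.ndim != 1 or center.size == 0:
            raise DataError("center must be a non-empty 1-d array")
        n = center.size
        treatment = _as_binary(self.treatment, "treatment")
        outcome = _as_binary(self.outcome, "outcome")
        if treatment.size != n or outcome.size != n:
            raise DataError("center/treatment/outcome lengths differ")
        covariate = self.covariate
        if covariate is not None:
            covariate = _as_binary(covariate, "covariate")
            if covariate.size != n:
                raise DataError("covariate length differs from center")
        codes, labels = pd.factorize(center)
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "treatment", treatment)
        object.__setattr__(self, "outcome", outcome)
        object.__setattr__(self, "covariate", covariate)
        object.__setattr__(self, "center_codes", codes.astype(np.int64))
        object.__setattr__(self, "center_labels", np.asarray(labels))

    # -- basic structure -------------------------------------------------
    @property
    def n(self) -> int:
        """Total number of subjects."""
        return int(self.center_codes.size)

    @property
    def n_centers(self) -> int:
        return int(self.center_labels.size)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.center_codes, minlength=self.n_centers)

    @property
    def has_covariate(self) -> bool:
        return self.covariate is not None

    def require_multicenter(self) -> "TrialData":
        if self.n_centers < 2:
            raise DataError(
                f"at least 2 distinct centers required, found {self.n_centers}"
            )
        return self

    def drop_centers(self, labels: Sequence) -> "TrialData":
        """Return a copy excluding the given center labels (sensitivity analyses)."""
        drop = set(labels)
        keep = np.array([c not in drop for c in self.center.tolist()])
        if not keep.any():
            raise DataError("dropping these centers leaves no data")
        return TrialData(
            center=self.center[keep],
            treatment=self.treatment[keep],
            outcome=self.outcome[keep],
            covariate=None if self.covariate is None else self.covariate[keep],
        )

    # -- conversions -----------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        cols = {"center": self.center, "treatment": self.treatment}
        if self.covariate is not None:
            cols["covariate"] = self.covariate
        cols["outcome"] = self.outcome
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, mapping: Mapping[str, str] | None = None
    ) -> "TrialData":
        m = dict(DEFAULT_MAPPING)
        if mapping:
            m.update(mapping)
        for key in ("center", "treatment", "outcome"):
            if m[key] not in df.columns:
                raise SchemaError(f"missing required column '{m[key]}'")
        cov = None
        if m.get("covariate") and m["covariate"] in df.columns:
            cov = df[m["covariate"]].to_numpy()
        return cls(
            center=df[m["center"]].to_numpy(),
            treatment=df[m["treatment"]].to_numpy(),
            outcome=df[m["outcome"]].to_numpy(),
            covariate=cov,
        )


@dataclass(frozen=True)
class CenterCountTable:
    """Center-aggregated two-arm counts: (center, arm, events, total) rows."""

    table: pd.DataFrame

    def __post_init__(self):
        df = self.table.copy()
        for col in ("center", "arm", "events", "total"):
            if col not in df.columns:
                raise SchemaError(f"count table missing column '{col}'")
        df["arm"] = df["arm"].astype(str).str.strip().str.lower()
        bad_arm = ~df["arm"].isin(["active", "control"])
        if bad_arm.any():
            raise DataError(
                f"unknown arm label {df.loc[bad_arm, 'arm'].iloc[0]!r}; "
                "expected 'active' or 'control'"
            )
        df["events"] = df["events"].astype(np.int64)
        df["total"] = df["total"].astype(np.int64)
        if (df["events"] < 0).any() or (df["total"] <= 0).any():
            raise DataError("events must be >= 0 and total > 0")
        if (df["events"] > df["total"]).any():
            i = df.index[df["events"] > df["total"]][0]
            raise DataError(
                f"events > total for center {df.loc[i, 'center']!r}, "
                f"arm {df.loc[i, 'arm']!r}"
            )
        if df.duplicated(["center", "arm"]).any():
            raise DataError("duplicate (center, arm) row in count table")
        object.__setattr__(self, "table", df.reset_index(drop=True))

    @property
    def n(self) -> int:
        return int(self.table["total"].sum())


def read_subject_csv(path, mapping: Mapping[str, str] | None = None) -> TrialData:
    """Read subject-level trial data from CSV (header required).

    Column names default to ``center,treatment,covariate,outcome`` and can be
    remapped via ``mapping``.  The covariate column is optional.  Requires at
    least two distinct centers.
    """
    df = pd.read_csv(path, comment="#")
    return TrialData.from_dataframe(df, mapping).require_multicenter()


def read_count_csv(path) -> CenterCountTable:
    """Read a center-aggregated count table (columns center,arm,events,total)."""
    return CenterCountTable(pd.read_csv(path, comment="#"))


def expand_counts(table: CenterCountTable) -> TrialData:
    """Expand a count table to subject level.

    Each (center, arm) cell of ``events``/``total`` becomes ``events`` records
    with outcome 1 and ``total - events`` with outcome 0; active-arm records
    get treatment 1.  The expansion carries no covariate.
    """
    center, treatment, outcome = [], [], []
    for row in table.table.itertuples(index=False):
        t = 1 if row.arm == "active" else 0
        center.extend([row.center] * row.total)
        treatment.extend([t] * row.total)
        outcome.extend([1] * row.events + [0] * (row.total - row.events))
    return TrialData(
        center=np.asarray(center),
        treatment=np.asarray(treatment),
        outcome=np.asarray(outcome),
    )


def aggregate_counts(data: TrialData) -> CenterCountTable:
    """Aggregate subject-level data back to the per-center two-arm count form."""
    df = data.to_dataframe()
    g = (
        df.groupby(["center", "treatment"], sort=False)["outcome"]
        .agg(events="sum", total="count")
        .reset_index()
    )
    g["arm"] = np.where(g["treatment"] == 1, "active", "control")
    return CenterCountTable(g[["center", "arm", "events", "total"]])


def summarize_2x2(data: TrialData) -> tuple[int, int, int, int]:
    """Pool over centers into (n1, e1, n0, e0): active size/events, control size/events."""
    t = data.treatment == 1
    n1, n0 = int(t.sum()), int((~t).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("both arms must be non-empty for a 2x2 summary")
    e1 = int(data.outcome[t].sum())
    e0 = int(data.outcome[~t].sum())
    return n1, e1, n0, e0
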