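"""Cohort container, train/test splitting and sampling-balance diagnostics.

A :class:`Cohort` is a rectangular patient-by-variable table plus a binary
outcome vector (1 = adverse event, "morbid"; 0 = normal).  Candidate
predictor columns are either *dichotomous* (all non-missing values in
{0, 1}) or *continuous* (anything else numeric).  Missing cells are NaN;
downstream operations use complete cases per variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.weightstats import ztest

__all__ = ["Cohort", "read_cohort", "stratified_split", "balance_report"]


@dataclass(frozen=True)
class Cohort:
    """Patient cohort: predictor table ``X`` and 0/1 outcome ``y``."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError(
                f"predictor table has {len(self.X)} rows but outcome has "
                f"{len(self.y)}"
            )
        if len(self.y) < 1:
            raise ValueError("empty cohort")
        vals = pd.unique(self.y.dropna())
        if self.y.isna().any() or not set(vals).issubset({0, 1}):
            bad = self.y.index[~self.y.isin([0, 1])][:1]
            raise ValueError(
                f"outcome column {self.y.name!r} must contain only 0/1; "
                f"offending row index {bad.tolist()[0] if len(bad) else '?'}"
            )
        object.__setattr__(self, "y", self.y.astype(int))

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_morbid(self) -> int:
        return int(self.y.sum())

    @property
    def outcome_name(self) -> str:
        return str(self.y.name)

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)

    def variable_types(self) -> dict[str, str]:
        """Classify each column: {0,1}-only -> 'dichotomous', else 'continuous'."""
        out = {}
        for col in self.X.columns:
            vals = self.X[col].dropna().unique()
            out[col] = "dichotomous" if set(vals).issubset({0, 1}) else "continuous"
        return out

    def has_both_classes(self) -> bool:
        return 0 < self.n_morbid < self.n

    def require_both_classes(self) -> None:
        if not self.has_both_classes():
            raise ValueError(
                "cohort must contain at least one morbid and one normal "
                "patient for modelling"
            )

    def subset(self, index) -> "Cohort":
        return Cohort(self.X.loc[index], self.y.loc[index])

    def to_frame(self) -> pd.DataFrame:
        frame = self.X.copy()
        frame[self.outcome_name] = self.y
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, outcome_column: str) -> "Cohort":
        if outcome_column not in frame.columns:
            raise ValueError(f"outcome column {outcome_column!r} not found")
        X = frame.drop(columns=[outcome_column])
        return cls(X, frame[outcome_column])


def read_cohort(path, outcome_column: str) -> Cohort:
    """Read a comma-delimited cohort table with a header row.

    Every cell must be numeric or empty (empty = missing).  The outcome
    column must be strictly 0/1 with no missing entries.
    """
    frame = pd.read_csv(path)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError(f"{path}: empty table")
    if outcome_column not in frame.columns:
        raise ValueError(f"{path}: outcome column {outcome_column!r} not found")
    for col in frame.columns:
        if frame[col].dtype == object:
            coerced = pd.to_numeric(frame[col], errors="coerce")
            bad = frame.index[coerced.isna() & frame[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value {frame.loc[bad[0], col]!r} in "
                    f"column {col!r}, row {bad[0]}"
                )
            frame[col] = coerced
    y = frame[outcome_column]
    if y.isna().any() or not y.isin([0, 1]).all():
        bad = frame.index[~y.isin([0, 1])][0]
        raise ValueError(
            f"{path}: outcome column {outcome_column!r} has value "
            f"{y.loc[bad]!r} outside {{0,1}} at row {bad}"
        )
    return Cohort.from_frame(frame, outcome_column)


def stratified_split(
    cohort: Cohort, fraction: float = 0.5, seed: int | None = None
) -> tuple[Cohort, Cohort]:
    """Random split preserving outcome prevalence as closely as integers allow.

    Morbid and normal patients are partitioned independently: a fraction
    ``fraction`` of each stratum (rounded up, so the larger half of an odd
    stratum goes to training) is assigned to the training set.  Deterministic
    for a fixed seed; train and test partition the cohort exactly.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    cohort.require_both_classes()
    rng = np.random.default_rng(seed)
    train_idx: list = []
    test_idx: list = []
    for cls in (1, 0):
        stratum = cohort.y.index[cohort.y == cls].to_numpy()
        n_s = len(stratum)
        n_train = math.ceil(fraction * n_s)
        if n_train == 0 or n_train == n_s:
            raise ValueError(
                f"fraction {fraction} yields an empty stratum "
                f"(class {cls}, size {n_s})"
            )
        perm = rng.permutation(n_s)
        train_idx.extend(stratum[perm[:n_train]])
        test_idx.extend(stratum[perm[n_train:]])
    # preserve original row order within each set
    order = {idx: pos for pos, idx in enumerate(cohort.y.index)}
    train_idx.sort(key=order.__getitem__)
    test_idx.sort(key=order.__getitem__)
    return cohort.subset(train_idx), cohort.subset(test_idx)


def _normalish(values: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk normality gate used to pick z-test vs Mann-Whitney."""
    if len(values) < 3 or np.ptp(values) == 0:
        return False
    return stats.shapiro(values).pvalue > alpha


def _compare_continuous(a: np.ndarray, b: np.ndarray, alpha: float) -> tuple[str, float]:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # no variation at all: distributions identical by construction
        return "mann-whitney", 1.0
    if _normalish(a, alpha) and _normalish(b, alpha):
        _, p = ztest(a, b, usevar="pooled")
        return "z-test", float(min(p, 1.0))
    p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return "mann-whitney", float(min(p, 1.0))


def balance_report(train: Cohort, test: Cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Check that a random train/test allocation is free of systematic bias.

    Each shared variable is compared between the two sets: Fisher's exact
    test for dichotomous variables, a two-sample z-test for continuous
    variables passing the normality gate in both sets, Mann-Whitney
    otherwise.  Returns a table (variable, test, p_value, significant).
    """
    if list(train.X.columns) != list(test.X.columns):
        raise ValueError("train and test cohorts have different column schemas")
    types_tr = train.variable_types()
    types_te = test.variable_types()
    records = []
    for col in train.X.columns:
        a = train.X[col].dropna().to_numpy(dtype=float)
        b = test.X[col].dropna().to_numpy(dtype=float)
        dichotomous = types_tr[col] == "dichotomous" and types_te[col] == "dichotomous"
        if dichotomous:
            table = [
                [int((a == 1).sum()), int((a == 0).sum())],
                [int((b == 1).sum()), int((b == 0).sum())],
            ]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
            used = "fisher-exact"
        else:
            used, p = _compare_continuous(a, b, alpha)
        records.append(
            {"variable": col, "test": used, "p_value": p, "significant": p < alpha}
        )
    return pd.DataFrame.from_records(records)
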