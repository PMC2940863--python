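"""Dichotomization of candidate predictors and odds-ratio screening.

Continuous variables are turned into binary risk indicators by the ROC
cutoff closest to the upper-left corner (sensitivity = specificity = 1);
intrinsically dichotomous variables are oriented so level 1 is the risk
side.  A candidate passes the screen when the Woolf 95% confidence
interval of its odds ratio lies entirely above 1 — the confidence-interval
form of "odds ratio significantly greater than 1 at p < 0.05".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort

__all__ = [
    "BinaryPredictor",
    "closest_corner_cutoff",
    "odds_ratio_ci",
    "screen_predictors",
    "screening_table",
]

AT_OR_ABOVE = "at-or-above"
BELOW = "below"
INTRINSIC = "intrinsic"


@dataclass(frozen=True)
class BinaryPredictor:
    """A dichotomized risk indicator with its training-set screening stats.

    ``direction`` is ``at-or-above``/``below`` for continuous sources
    (value on the risk side of ``cutoff`` scores 1) and ``intrinsic`` for
    natively binary variables, where ``risk_level`` names the risk-positive
    level (0 or 1).
    """

    name: str
    direction: str
    cutoff: float | None = None
    risk_level: int = 1
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    odds_ratio: float = float("nan")
    or_low: float = float("nan")
    or_high: float = float("nan")
    passed_screen: bool = False
    n_used: int = 0
    note: str = ""

    def indicator(self, values) -> np.ndarray:
        """Map raw values to the 0/1 risk indicator (NaN propagates as NaN)."""
        v = np.asarray(values, dtype=float)
        out = np.full(v.shape, np.nan)
        ok = ~np.isnan(v)
        if self.direction == AT_OR_ABOVE:
            out[ok] = (v[ok] >= self.cutoff).astype(float)
        elif self.direction == BELOW:
            out[ok] = (v[ok] < self.cutoff).astype(float)
        elif self.direction == INTRINSIC:
            out[ok] = (v[ok] == self.risk_level).astype(float)
        else:  # pragma: no cover - constructor guards direction
            raise ValueError(f"unknown direction {self.direction!r}")
        return out

    def describe_rule(self) -> str:
        if self.direction == AT_OR_ABOVE:
            return f"{self.name} >= {self.cutoff:g}"
        if self.direction == BELOW:
            return f"{self.name} < {self.cutoff:g}"
        return f"{self.name} == {self.risk_level}"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "direction": self.direction,
            "cutoff": self.cutoff,
            "risk_level": self.risk_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryPredictor":
        return cls(
            name=d["name"],
            direction=d["direction"],
            cutoff=d.get("cutoff"),
            risk_level=int(d.get("risk_level", 1)),
        )


def closest_corner_cutoff(values, outcome) -> tuple[float, str, float, float]:
    """ROC cutoff closest (squared Euclidean) to the (1, 1) corner.

    Candidate cutoffs are midpoints between consecutive sorted distinct
    values; both risk directions (``at-or-above`` and ``below``) are
    searched.  Ties are broken toward higher sensitivity, then the lower
    cutoff, then ``at-or-above``.

    Returns ``(cutoff, direction, sensitivity, specificity)``.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if v.shape != y.shape:
        raise ValueError("values and outcome must have equal length")
    ok = ~np.isnan(v)
    v, y = v[ok], y[ok]
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required to build a ROC curve")
    distinct, inverse = np.unique(v, return_inverse=True)
    if len(distinct) < 2:
        raise ValueError(f"no ROC curve: variable is constant ({distinct!r})")
    # per-distinct-value outcome counts, then cumulative counts below cutoff
    pos = np.bincount(inverse, weights=y, minlength=len(distinct))
    tot = np.bincount(inverse, minlength=len(distinct))
    cum1 = np.cumsum(pos)[:-1]          # morbid with value <= distinct[k]
    cum0 = np.cumsum(tot - pos)[:-1]    # normal with value <= distinct[k]
    mids = (distinct[:-1] + distinct[1:]) / 2.0

    cands = []
    # at-or-above: risk side is value >= midpoint
    sens_hi = (n1 - cum1) / n1
    spec_hi = cum0 / n0
    cands.append((mids, np.full(len(mids), 0), sens_hi, spec_hi))
    # below: risk side is value < midpoint
    sens_lo = cum1 / n1
    spec_lo = (n0 - cum0) / n0
    cands.append((mids, np.full(len(mids), 1), sens_lo, spec_lo))

    mid_all = np.concatenate([c[0] for c in cands])
    dir_all = np.concatenate([c[1] for c in cands])
    sens_all = np.concatenate([c[2] for c in cands])
    spec_all = np.concatenate([c[3] for c in cands])
    d2 = (1.0 - sens_all) ** 2 + (1.0 - spec_all) ** 2
    # lexicographic: distance asc, sensitivity desc, cutoff asc, at-or-above first
    best = np.lexsort((dir_all, mid_all, -sens_all, d2))[0]
    direction = AT_OR_ABOVE if dir_all[best] == 0 else BELOW
    return float(mid_all[best]), direction, float(sens_all[best]), float(spec_all[best])


def odds_ratio_ci(
    exposed_morbid: int,
    exposed_normal: int,
    unexposed_morbid: int,
    unexposed_normal: int,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Odds ratio with the Woolf (logit) confidence interval.

    ``OR = (a*d)/(b*c)`` for the 2x2 table ``[[a, b], [c, d]]`` of
    (exposed, unexposed) x (morbid, normal).  Any zero cell triggers the
    Haldane-Anscombe correction (+0.5 to all four cells) before both the
    point estimate and the interval.
    """
    cells = [exposed_morbid, exposed_normal, unexposed_morbid, unexposed_normal]
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - (1 - level) / 2)
    low = math.exp(math.log(or_) - z * se)
    high = math.exp(math.log(or_) + z * se)
    return or_, low, high


def _table_from_indicator(ind: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    a = int(((ind == 1) & (y == 1)).sum())
    b = int(((ind == 1) & (y == 0)).sum())
    c = int(((ind == 0) & (y == 1)).sum())
    d = int(((ind == 0) & (y == 0)).sum())
    return a, b, c, d


def screen_predictors(train: Cohort, level: float = 0.95) -> list[BinaryPredictor]:
    """Dichotomize every candidate variable and apply the odds-ratio screen.

    Returns one :class:`BinaryPredictor` per column with its screening
    verdict; callers should model only with the ``passed_screen`` subset.
    Constant columns are reported as screened-out, not fatal.
    """
    train.require_both_classes()
    types = train.variable_types()
    out: list[BinaryPredictor] = []
    for col in train.X.columns:
        vals = train.X[col].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        v, y = vals[ok], train.y.to_numpy()[ok]
        if len(np.unique(v)) < 2 or y.sum() in (0, len(y)):
            out.append(
                BinaryPredictor(
                    name=col,
                    direction=INTRINSIC if types[col] == "dichotomous" else AT_OR_ABOVE,
                    note="screened out: constant or single outcome class "
                    "among complete cases",
                )
            )
            continue
        if types[col] == "dichotomous":
            pred = BinaryPredictor(name=col, direction=INTRINSIC, risk_level=1)
            ind = pred.indicator(v)
            a, b, c, d = _table_from_indicator(ind, y)
            point = odds_ratio_ci(a, b, c, d, level)[0]
            if point < 1.0:
                pred = replace(pred, risk_level=0)
                ind = pred.indicator(v)
        else:
            cutoff, direction, _, _ = closest_corner_cutoff(v, y)
            pred = BinaryPredictor(name=col, direction=direction, cutoff=cutoff)
            ind = pred.indicator(v)
        a, b, c, d = _table_from_indicator(ind, y)
        or_, low, high = odds_ratio_ci(a, b, c, d, level)
        sens = a / (a + c) if a + c else float("nan")
        spec = d / (b + d) if b + d else float("nan")
        out.append(
            replace(
                pred,
                sensitivity=sens,
                specificity=spec,
                odds_ratio=or_,
                or_low=low,
                or_high=high,
                passed_screen=low > 1.0,
                n_used=len(v),
            )
        )
    return out


def screening_table(predictors: list[BinaryPredictor]) -> pd.DataFrame:
    """Tabulate screening results (TSV-ready)."""
    return pd.DataFrame.from_records(
        [
            {
                "variable": p.name,
                "cutoff": p.cutoff,
                "direction": p.direction,
                "risk_level": p.risk_level,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "odds_ratio": p.odds_ratio,
                "or_ci_low": p.or_low,
                "or_ci_high": p.or_high,
                "passed": p.passed_screen,
                "note": p.note,
            }
            for p in predictors
        ]
    )
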