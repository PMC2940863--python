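"""Pooling of score classes with overlapping confidence intervals.

When the confidence intervals of adjacent score classes overlap, the
classes carry no statistically distinguishable risk and can be united
into a single stratum (e.g. scores 5 and 6 becoming ">=5").  The greedy
strategy merges from the top of the score range downwards — where classes
are sparsest — re-estimating intervals after every merge; tiny classes
(below a configurable fraction of the training set) are merge candidates
even without overlap.  A manual plan applies a user's judgment verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .cohort import Cohort
from .model import ScoreModel, rank_auc

if TYPE_CHECKING:  # pragma: no cover
    from .bootstrap import ScoreClassStats

__all__ = [
    "PoolingPlan",
    "identity_plan",
    "find_overlaps",
    "pool_scores",
    "PoolingResult",
]


@dataclass(frozen=True)
class PoolingPlan:
    """Partition of raw scores 0..max_score into ordered contiguous classes.

    ``bounds`` lists inclusive (lo, hi) score ranges; they must tile
    [0, max_score] in order.  Labels: a single score is its number, the
    top class is ">=lo" when it spans to max_score, interior ranges are
    "lo-hi".
    """

    bounds: tuple[tuple[int, int], ...]
    max_score: int

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("plan needs at least one class")
        expect = 0
        for lo, hi in self.bounds:
            if lo != expect or hi < lo:
                raise ValueError(
                    f"classes must be contiguous non-empty score ranges "
                    f"covering 0..{self.max_score}; got {self.bounds}"
                )
            expect = hi + 1
        if expect != self.max_score + 1:
            raise ValueError(
                f"classes must cover 0..{self.max_score}; got {self.bounds}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.bounds)

    @property
    def labels(self) -> list[str]:
        out = []
        for i, (lo, hi) in enumerate(self.bounds):
            if lo == hi:
                out.append(str(lo))
            elif i == len(self.bounds) - 1 and hi == self.max_score:
                out.append(f">={lo}")
            else:
                out.append(f"{lo}-{hi}")
        return out

    def assign(self, scores) -> np.ndarray:
        """Class index per raw score value."""
        s = np.asarray(scores, dtype=int)
        if (s < 0).any() or (s > self.max_score).any():
            raise ValueError("score outside [0, max_score]")
        lut = np.empty(self.max_score + 1, dtype=int)
        for i, (lo, hi) in enumerate(self.bounds):
            lut[lo : hi + 1] = i
        return lut[s]

    def merge(self, i: int) -> "PoolingPlan":
        """Merge class i with class i+1."""
        if not 0 <= i < self.n_classes - 1:
            raise ValueError("no adjacent class to merge")
        b = list(self.bounds)
        b[i] = (b[i][0], b[i + 1][1])
        del b[i + 1]
        return PoolingPlan(tuple(b), self.max_score)

    def to_dict(self) -> dict[str, str]:
        labels = self.labels
        return {
            str(s): labels[i]
            for i, (lo, hi) in enumerate(self.bounds)
            for s in range(lo, hi + 1)
        }

    @classmethod
    def from_mapping(cls, mapping: dict, max_score: int | None = None) -> "PoolingPlan":
        """Build from a {raw score -> class label} mapping; classes must be
        contiguous score ranges."""
        items = sorted((int(k), str(v)) for k, v in mapping.items())
        if max_score is None:
            max_score = items[-1][0] if items else -1
        seen: dict[str, list[int]] = {}
        for s, lab in items:
            seen.setdefault(lab, []).append(s)
        bounds = []
        for lab, ss in seen.items():
            lo, hi = min(ss), max(ss)
            if sorted(ss) != list(range(lo, hi + 1)):
                raise ValueError(f"class {lab!r} maps a non-contiguous score set {ss}")
            bounds.append((lo, hi))
        bounds.sort()
        return cls(tuple(bounds), max_score)

    @classmethod
    def identity(cls, max_score: int) -> "PoolingPlan":
        return cls(tuple((s, s) for s in range(max_score + 1)), max_score)


def identity_plan(observed_scores, max_score: int) -> PoolingPlan:
    """One class per observed score value; unobserved scores fold into the
    class of the nearest lower observed score (so every class is non-empty
    on the data that defined it)."""
    obs = np.unique(np.asarray(observed_scores, dtype=int))
    if len(obs) == 0:
        raise ValueError("no scores observed")
    bounds = []
    for j, s in enumerate(obs):
        lo = 0 if j == 0 else s
        hi = (obs[j + 1] - 1) if j + 1 < len(obs) else max_score
        bounds.append((int(lo), int(hi)))
    return PoolingPlan(tuple(bounds), max_score)


def find_overlaps(stats: "list[ScoreClassStats]") -> list[tuple[int, int]]:
    """Adjacent class pairs whose closed CIs intersect (shared endpoints count)."""
    pairs = []
    for i in range(len(stats) - 1):
        lo_i, hi_i = stats[i].ci_low, stats[i].ci_high
        lo_j, hi_j = stats[i + 1].ci_low, stats[i + 1].ci_high
        if lo_j <= hi_i and lo_i <= hi_j:
            pairs.append((i, i + 1))
    return pairs


def _merge_candidates(
    stats: "list[ScoreClassStats]", n_train: int, min_class_frac: float
) -> list[tuple[int, int]]:
    pairs = set(find_overlaps(stats))
    if min_class_frac > 0:
        for i, s in enumerate(stats):
            if s.n < min_class_frac * n_train:
                pairs.add((i - 1, i) if i > 0 else (0, 1))
    return sorted(p for p in pairs if 0 <= p[0] < p[1] <= len(stats) - 1)


@dataclass(frozen=True)
class PoolingResult:
    plan: PoolingPlan
    stats: "list[ScoreClassStats]"
    train_auc_before: float
    train_auc_after: float
    test_auc_before: float | None = None
    test_auc_after: float | None = None
    merges: tuple[str, ...] = ()


def pool_scores(
    train: Cohort,
    model: ScoreModel,
    stats: "list[ScoreClassStats]",
    strategy: str = "greedy-top-down",
    manual_plan: PoolingPlan | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed=None,
    test: Cohort | None = None,
    min_class_frac: float = 0.02,
) -> PoolingResult:
    """Pool score classes and re-estimate their statistics and AUC.

    ``greedy-top-down`` repeatedly merges the highest-score adjacent pair
    that either overlaps in CI or contains an undersized class, rerunning
    :func:`scoreboot.bootstrap.score_class_cis` after each merge, until no
    such pair remains or one class is left.  ``manual`` applies
    ``manual_plan`` verbatim.  AUC before/after is computed on class ranks.
    """
    from .bootstrap import score_class_cis  # local import to avoid a cycle

    if strategy not in ("greedy-top-down", "manual"):
        raise ValueError("strategy must be 'greedy-top-down' or 'manual'")
    plan = PoolingPlan(
        tuple((s.lo_score, s.hi_score) for s in stats), model.max_score
    )
    scores_train = model.score(train.X)
    y_train = train.y.to_numpy()
    auc_before = rank_auc(plan.assign(scores_train), y_train)
    test_before = test_after = None
    if test is not None:
        scores_test = model.score(test.X)
        test_before = rank_auc(plan.assign(scores_test), test.y.to_numpy())

    merges: list[str] = []
    if strategy == "manual":
        if manual_plan is None:
            raise ValueError("manual strategy requires manual_plan")
        plan = manual_plan
        stats = score_class_cis(train, model, plan, B=B, level=level, seed=seed, test=test)
    else:
        while plan.n_classes > 1:
            cands = _merge_candidates(stats, train.n, min_class_frac)
            if not cands:
                break
            i, _ = cands[-1]  # highest-score pair first
            merges.append(f"{stats[i].label}+{stats[i + 1].label}")
            plan = plan.merge(i)
            stats = score_class_cis(
                train, model, plan, B=B, level=level, seed=seed, test=test
            )
    auc_after = rank_auc(plan.assign(scores_train), y_train)
    if test is not None:
        test_after = rank_auc(plan.assign(scores_test), test.y.to_numpy())
    return PoolingResult(
        plan=plan,
        stats=stats,
        train_auc_before=auc_before,
        train_auc_after=auc_after,
        test_auc_before=test_before,
        test_auc_after=test_after,
        merges=tuple(merges),
    )
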