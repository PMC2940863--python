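"""Additive integer scoring model and AUC-driven forward selection.

A scoring system assigns each patient the integer

    s = sum_i  lambda_i * s_i

over the model's d predictors, where lambda_i is 1 when the patient lies
on the risk side of predictor i's cutoff (or risk level) and s_i is the
predictor's integer weight.  Weights above 1 arise from re-entry: the
forward algorithm may re-select an already-entered predictor, adding its
binary value again.

Selection is greedy on the training-set AUC of the integer score; a soft
stopping rule halts when five consecutive steps cumulatively gain less
than 0.01 AUC.  Test-set AUC is recorded per step but never used for
selection — choosing the step that generalizes best is a separate,
explicit act (:meth:`ForwardSelectionResults.final_step`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .screening import BinaryPredictor

__all__ = [
    "ScoreModel",
    "SelectionStep",
    "SelectionTrace",
    "rank_auc",
    "forward_select",
    "ForwardScoreSelection",
    "ForwardSelectionResults",
]


def rank_auc(scores, outcome) -> float:
    """Area under the ROC curve of a (possibly tied) score.

    Mann-Whitney form: the probability that a random morbid patient
    outscores a random normal patient, counting ties one-half; identical
    to the trapezoidal area under the empirical ROC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and outcome must have equal length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes required for AUC")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass(frozen=True)
class ScoreModel:
    """Ordered predictor entries with integer weights (the scoring system)."""

    entries: tuple[tuple[BinaryPredictor, int], ...]
    outcome_name: str = "outcome"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        names = [p.name for p, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("each predictor may appear in entries only once")
        if any(int(w) < 1 or int(w) != w for _, w in self.entries):
            raise ValueError("weights must be integers >= 1")

    @property
    def d(self) -> int:
        """Number of distinct predictors."""
        return len(self.entries)

    @property
    def max_score(self) -> int:
        return int(sum(w for _, w in self.entries))

    @property
    def predictor_names(self) -> list[str]:
        return [p.name for p, _ in self.entries]

    def weights(self) -> dict[str, int]:
        return {p.name: int(w) for p, w in self.entries}

    def indicators(self, X: pd.DataFrame) -> np.ndarray:
        """(n, d) 0/1 indicator matrix; missing values raise, naming the predictor."""
        cols = []
        for pred, _ in self.entries:
            if pred.name not in X.columns:
                raise ValueError(f"missing value column for predictor {pred.name!r}")
            ind = pred.indicator(X[pred.name].to_numpy(dtype=float))
            if np.isnan(ind).any():
                row = int(np.flatnonzero(np.isnan(ind))[0])
                raise ValueError(
                    f"missing value for predictor {pred.name!r} (row {row}); "
                    "patients must supply every model predictor"
                )
            cols.append(ind)
        return np.column_stack(cols) if cols else np.zeros((len(X), 0))

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Integer score per patient row."""
        w = np.array([wt for _, wt in self.entries], dtype=int)
        if len(w) == 0:
            return np.zeros(len(X), dtype=int)
        return (self.indicators(X) @ w).astype(int)

    def score_patient(self, values: dict) -> int:
        """Score a single patient given a name -> raw value mapping."""
        row = pd.DataFrame([values])
        for pred, _ in self.entries:
            if pred.name not in values or pd.isna(values.get(pred.name)):
                raise ValueError(f"missing value for predictor {pred.name!r}")
        return int(self.score(row)[0])

    def to_dict(self) -> dict:
        return {
            "predictors": [
                dict(p.to_dict(), weight=int(w)) for p, w in self.entries
            ],
            "outcome_name": self.outcome_name,
            "created_from": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreModel":
        entries = tuple(
            (BinaryPredictor.from_dict(e), int(e["weight"]))
            for e in d["predictors"]
        )
        return cls(entries, d.get("outcome_name", "outcome"), d.get("created_from", {}))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SelectionStep:
    step: int
    action: str  # 'enter' | 'increment-weight'
    variable: str
    train_auc: float
    test_auc: float | None = None


@dataclass(frozen=True)
class SelectionTrace:
    steps: tuple[SelectionStep, ...]
    stop_step: int
    stop_reason: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "step": s.step,
                    "action": s.action,
                    "variable": s.variable,
                    "train_auc": s.train_auc,
                    "test_auc": s.test_auc,
                }
                for s in self.steps
            ]
        )


_TIE_EPS = 1e-12


def _complete_case_matrix(
    cohort: Cohort, candidates: list[BinaryPredictor]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Indicator arrays per candidate, on rows complete for all candidates."""
    inds = {p.name: p.indicator(cohort.X[p.name].to_numpy(dtype=float)) for p in candidates}
    mask = np.ones(cohort.n, dtype=bool)
    for arr in inds.values():
        mask &= ~np.isnan(arr)
    dropped = int((~mask).sum())
    if dropped:
        warnings.warn(
            f"{dropped} rows with missing candidate values dropped from "
            "selection", stacklevel=3
        )
    return {k: v[mask] for k, v in inds.items()}, cohort.y.to_numpy()[mask]


def forward_select(
    train: Cohort,
    candidates: list[BinaryPredictor],
    window: int = 5,
    min_cum_increment: float = 0.01,
    test: Cohort | None = None,
    max_steps: int = 1000,
) -> tuple[SelectionTrace, list[ScoreModel]]:
    """Greedy forward selection of weighted binary predictors by train AUC.

    At each step every candidate is evaluated — unseen candidates by entry
    with weight 1, already-entered ones by incrementing their weight — and
    the action with the largest resulting training AUC is applied (ties:
    prefer a new entry, then the lexicographically first name).  Stops when
    the cumulative AUC gain over ``window`` consecutive completed steps
    falls below ``min_cum_increment``, or when no action strictly improves
    the training AUC.

    Returns the per-step trace and the model after each step.
    """
    passers = list(candidates)
    if not passers:
        raise ValueError("no candidate predictors to select from")
    train.require_both_classes()
    ind_train, y_train = _complete_case_matrix(train, passers)
    if y_train.sum() in (0, len(y_train)):
        raise ValueError("complete-case training rows contain a single outcome class")
    have_test = test is not None
    if have_test:
        ind_test, y_test = _complete_case_matrix(test, passers)

    by_name = {p.name: p for p in passers}
    order: list[str] = []          # entry order of distinct predictors
    weights: dict[str, int] = {}
    cur_train = np.zeros(len(y_train))
    cur_test = np.zeros(len(y_test)) if have_test else None
    aucs = [0.5]                    # step 0: empty model, all scores tied
    steps: list[SelectionStep] = []
    models: list[ScoreModel] = []
    stop_reason = "max-steps"
    stop_step = 0

    names_sorted = sorted(by_name)
    for step in range(1, max_steps + 1):
        best = None  # (auc, is_new, name)
        for name in names_sorted:
            auc = rank_auc(cur_train + ind_train[name], y_train)
            is_new = name not in weights
            if best is None or auc > best[0] + _TIE_EPS:
                best = (auc, is_new, name)
            elif abs(auc - best[0]) <= _TIE_EPS and is_new and not best[1]:
                # tie: prefer entering a new variable over a weight increment;
                # names iterate in lexicographic order, so first tie wins
                best = (auc, is_new, name)
        auc, is_new, name = best
        if auc <= aucs[-1] + _TIE_EPS:
            stop_reason = "no-improvement"
            stop_step = step - 1
            break
        cur_train = cur_train + ind_train[name]
        if have_test:
            cur_test = cur_test + ind_test[name]
        if is_new:
            order.append(name)
            weights[name] = 1
            action = "enter"
        else:
            weights[name] += 1
            action = "increment-weight"
        aucs.append(auc)
        test_auc = None
        if have_test and 0 < y_test.sum() < len(y_test):
            test_auc = rank_auc(cur_test, y_test)
        steps.append(SelectionStep(step, action, name, auc, test_auc))
        models.append(
            ScoreModel(
                tuple((by_name[n], weights[n]) for n in order),
                outcome_name=train.outcome_name,
                meta={"n_train": int(len(y_train)), "step": step},
            )
        )
        if step > window and aucs[step] - aucs[step - window] < min_cum_increment:
            stop_reason = "window"
            stop_step = step
            break
    else:
        stop_step = len(steps)
    if stop_reason == "no-improvement":
        stop_step = len(steps)
    trace = SelectionTrace(tuple(steps), stop_step, stop_reason)
    return trace, models


class ForwardScoreSelection:
    """Forward-selection model builder over a screened candidate set.

    Parameters
    ----------
    train : Cohort
        Training cohort; all selection decisions use it exclusively.
    candidates : list of BinaryPredictor, optional
        Screened candidates (only screen-passers are used).  When omitted,
        :func:`scoreboot.screening.screen_predictors` is run on ``train``.
    test : Cohort, optional
        Held-out cohort; its per-step AUC is recorded for generalization
        assessment only.
    window, min_increment :
        Soft stopping rule: stop when ``window`` consecutive steps gain
        less than ``min_increment`` AUC cumulatively.
    """

    def __init__(
        self,
        train: Cohort,
        candidates: list[BinaryPredictor] | None = None,
        test: Cohort | None = None,
        window: int = 5,
        min_increment: float = 0.01,
    ) -> None:
        if candidates is None:
            from .screening import screen_predictors

            candidates = screen_predictors(train)
        self.train = train
        self.test = test
        self.candidates = [p for p in candidates if p.passed_screen]
        if not self.candidates:
            raise ValueError("no screen-passing candidate predictors")
        self.window = window
        self.min_increment = min_increment

    def fit(self, max_steps: int = 1000) -> "ForwardSelectionResults":
        trace, models = forward_select(
            self.train,
            self.candidates,
            window=self.window,
            min_cum_increment=self.min_increment,
            test=self.test,
            max_steps=max_steps,
        )
        return ForwardSelectionResults(self, trace, models)


class ForwardSelectionResults:
    """Results of a fitted forward selection: trace, per-step models."""

    def __init__(
        self,
        model: ForwardScoreSelection,
        trace: SelectionTrace,
        models: list[ScoreModel],
    ) -> None:
        self.selection = model
        self.trace = trace
        self.models = models

    @property
    def n_steps(self) -> int:
        return len(self.models)

    def model_at(self, step: int) -> ScoreModel:
        """Scoring system after the given 1-based step."""
        if not 1 <= step <= self.n_steps:
            raise ValueError(f"step must be in [1, {self.n_steps}]")
        return self.models[step - 1]

    def final_step(self, criterion: str = "test-auc") -> int:
        """Pick the conclusive step.

        ``test-auc`` (default, requires a test cohort): the earliest step
        maximizing test AUC — discrimination on data not used for training.
        ``last``: the step where the stopping rule fired.
        """
        if criterion == "last":
            return self.n_steps
        if criterion != "test-auc":
            raise ValueError("criterion must be 'test-auc' or 'last'")
        test_aucs = [s.test_auc for s in self.trace.steps]
        if any(a is None for a in test_aucs):
            raise ValueError("test-auc criterion requires a test cohort")
        return int(np.argmax(test_aucs)) + 1

    def final_model(self, criterion: str = "test-auc") -> ScoreModel:
        return self.model_at(self.final_step(criterion))

    def summary(self) -> str:
        frame = self.trace.to_frame()
        lines = ["Forward AUC-driven score selection", "=" * 50]
        lines.append(frame.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
        lines.append(
            f"stopped at step {self.trace.stop_step} ({self.trace.stop_reason})"
        )
        if self.models:
            final = self.models[-1]
            lines.append(
                f"final-step model: {final.d} predictors, max score {final.max_score}"
            )
            lines.append(
                "weights: "
                + ", ".join(f"{k}={v}" for k, v in final.weights().items())
            )
        return "\n".join(lines)
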