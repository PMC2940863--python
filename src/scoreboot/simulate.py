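"""Synthetic patient cohorts with planted binary risk structure.

The generator emulates the statistical skeleton a scoring system assumes:
a handful of binary risk indicators with set prevalences drive a
Bernoulli outcome through an additive logit, surrounded by noise
variables carrying no signal.  Continuous "carrier" variables hide an
indicator behind a two-component Gaussian mixture straddling an intended
cutoff, so cutoff recovery can be tested at controlled difficulty.  All
ground truth (baseline logit, per-predictor effects, latent indicators)
is exposed for oracle-based testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohort import Cohort
from .model import ScoreModel
from .pooling import PoolingPlan
from .screening import AT_OR_ABOVE, BELOW, INTRINSIC, BinaryPredictor

__all__ = [
    "PredictorSpec",
    "SyntheticSpec",
    "GroundTruth",
    "calibrate_baseline_logit",
    "generate_cohort",
    "true_class_probabilities",
    "true_model",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class PredictorSpec:
    """One planted risk indicator.

    ``carrier='binary'`` emits the 0/1 indicator itself;
    ``carrier='continuous'`` emits a continuous value drawn from
    N(cutoff +/- separation/2, sd), the component chosen by the latent
    indicator so that the risk side of ``cutoff`` (per ``direction``)
    corresponds to indicator 1.
    """

    name: str
    prevalence: float
    beta: float
    carrier: str = "binary"
    cutoff: float | None = None
    direction: str = AT_OR_ABOVE
    separation: float = 3.0
    sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"{self.name}: prevalence must be in (0, 1)")
        if self.beta < 0:
            raise ValueError(f"{self.name}: beta must be >= 0")
        if self.carrier not in ("binary", "continuous"):
            raise ValueError(f"{self.name}: carrier must be binary or continuous")
        if self.carrier == "continuous":
            if self.cutoff is None:
                raise ValueError(f"{self.name}: continuous carrier needs a cutoff")
            if self.direction not in (AT_OR_ABOVE, BELOW):
                raise ValueError(f"{self.name}: direction must be at-or-above/below")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a synthetic cohort; everything needed to rebuild it."""

    n: int
    predictors: tuple[PredictorSpec, ...]
    n_noise: int = 20
    target_prevalence: float | None = 0.207
    baseline_logit: float | None = None
    outcome_name: str = "morbidity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.target_prevalence is None and self.baseline_logit is None:
            raise ValueError("give either target_prevalence or baseline_logit")
        if self.target_prevalence is not None and not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must be in (0, 1)")

    def resolved_baseline(self) -> float:
        if self.baseline_logit is not None:
            return self.baseline_logit
        return calibrate_baseline_logit(self.predictors, self.target_prevalence)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "predictors": [
                {
                    "name": p.name,
                    "prevalence": p.prevalence,
                    "beta": p.beta,
                    "carrier": p.carrier,
                    "cutoff": p.cutoff,
                    "direction": p.direction,
                    "separation": p.separation,
                    "sd": p.sd,
                }
                for p in self.predictors
            ],
            "n_noise": self.n_noise,
            "target_prevalence": self.target_prevalence,
            "baseline_logit": self.baseline_logit,
            "outcome_name": self.outcome_name,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        preds = tuple(PredictorSpec(**p) for p in d.get("predictors", []))
        return cls(
            n=int(d["n"]),
            predictors=preds,
            n_noise=int(d.get("n_noise", 20)),
            target_prevalence=d.get("target_prevalence"),
            baseline_logit=d.get("baseline_logit"),
            outcome_name=d.get("outcome_name", "morbidity"),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted."""

    baseline_logit: float
    betas: dict[str, float]
    prevalences: dict[str, float]
    indicators: pd.DataFrame  # latent 0/1 indicators, one column per predictor
    event_probability: pd.Series  # per-patient P(outcome = 1)


def _pattern_iter(predictors: tuple[PredictorSpec, ...]):
    """(probability, beta-sum) over all 2^d indicator patterns."""
    d = len(predictors)
    for mask in range(1 << d):
        prob = 1.0
        bsum = 0.0
        for j, p in enumerate(predictors):
            if mask >> j & 1:
                prob *= p.prevalence
                bsum += p.beta
            else:
                prob *= 1.0 - p.prevalence
        yield mask, prob, bsum


def calibrate_baseline_logit(
    predictors: tuple[PredictorSpec, ...], target_prevalence: float
) -> float:
    """Baseline logit beta0 such that the population outcome prevalence
    equals ``target_prevalence`` exactly.

    With independent Bernoulli indicators the prevalence is the finite sum
    sum_patterns P(pattern) * logistic(beta0 + sum beta_j x_j), a strictly
    increasing function of beta0, solved by Brent root-finding.
    """
    if len(predictors) > 20:
        raise ValueError("calibration enumerates 2^d patterns; d <= 20 required")
    terms = [(prob, bsum) for _, prob, bsum in _pattern_iter(predictors)]

    def prev(b0: float) -> float:
        return sum(prob * expit(b0 + bsum) for prob, bsum in terms) - target_prevalence

    return float(brentq(prev, -40.0, 40.0, xtol=1e-12))


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort from the spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    beta0 = spec.resolved_baseline()
    n = spec.n
    columns: dict[str, np.ndarray] = {}
    indicators: dict[str, np.ndarray] = {}
    logit = np.full(n, beta0)
    for p in spec.predictors:
        x = (rng.random(n) < p.prevalence).astype(int)
        indicators[p.name] = x
        logit = logit + p.beta * x
        if p.carrier == "binary":
            columns[p.name] = x.astype(float)
        else:
            sign = 1.0 if p.direction == AT_OR_ABOVE else -1.0
            centre = p.cutoff + sign * p.separation / 2.0 * (2 * x - 1)
            columns[p.name] = centre + rng.normal(0.0, p.sd, size=n)
    # noise variables: alternating intrinsic-binary / continuous, no signal
    noise_prevs = [0.1, 0.2, 0.3, 0.4, 0.5]
    for j in range(spec.n_noise):
        name = f"noise_{j + 1:02d}"
        if j % 2 == 0:
            prev = noise_prevs[(j // 2) % len(noise_prevs)]
            columns[name] = (rng.random(n) < prev).astype(float)
        else:
            columns[name] = rng.normal(0.0, 1.0, size=n)
    p_event = expit(logit)
    y = (rng.random(n) < p_event).astype(int)
    frame = pd.DataFrame(columns)
    cohort = Cohort(frame, pd.Series(y, name=spec.outcome_name))
    truth = GroundTruth(
        baseline_logit=beta0,
        betas={p.name: p.beta for p in spec.predictors},
        prevalences={p.name: p.prevalence for p in spec.predictors},
        indicators=pd.DataFrame(indicators),
        event_probability=pd.Series(p_event, name="p_event"),
    )
    return cohort, truth


def true_model(spec: SyntheticSpec, weights: dict[str, int] | None = None) -> ScoreModel:
    """The planted scoring system: each predictor at its intended rule.

    Default weights are the planted effects scaled to smallest integers
    (beta proportional weights, unit = min positive beta).
    """
    informative = [p for p in spec.predictors if p.beta > 0]
    if weights is None:
        unit = min(p.beta for p in informative)
        weights = {p.name: max(1, round(p.beta / unit)) for p in informative}
    entries = []
    for p in informative:
        if p.name not in weights:
            continue
        if p.carrier == "binary":
            bp = BinaryPredictor(name=p.name, direction=INTRINSIC, risk_level=1)
        else:
            bp = BinaryPredictor(name=p.name, direction=p.direction, cutoff=p.cutoff)
        entries.append((bp, int(weights[p.name])))
    return ScoreModel(tuple(entries), outcome_name=spec.outcome_name)


def true_class_probabilities(
    spec: SyntheticSpec,
    model: ScoreModel | None = None,
    plan: PoolingPlan | None = None,
) -> pd.DataFrame:
    """Exact per-class occupancy and outcome probability by enumeration.

    Enumerates all 2^d latent indicator patterns of the spec's planted
    predictors (d <= 20), scoring each pattern with ``model`` (default:
    the planted true-weight model).  Returns a table with P(class) and
    P(outcome | class).
    """
    if len(spec.predictors) > 20:
        raise ValueError("enumeration limited to d <= 20; use a Monte-Carlo oracle")
    if model is None:
        model = true_model(spec)
    names = [p.name for p in spec.predictors]
    missing = [nm for nm in model.predictor_names if nm not in names]
    if missing:
        raise ValueError(f"model predictors {missing} not in the spec")
    beta0 = spec.resolved_baseline()
    w = model.weights()
    # map each pattern to its integer score via the latent indicators
    score_w = np.array([w.get(nm, 0) for nm in names])
    if plan is None:
        plan = PoolingPlan.identity(model.max_score)
    k = plan.n_classes
    p_class = np.zeros(k)
    p_joint = np.zeros(k)
    for mask, prob, bsum in _pattern_iter(spec.predictors):
        bits = np.array([(mask >> j) & 1 for j in range(len(names))])
        cls = int(plan.assign([int(bits @ score_w)])[0])
        p_class[cls] += prob
        p_joint[cls] += prob * expit(beta0 + bsum)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cond = np.where(p_class > 0, p_joint / p_class, np.nan)
    return pd.DataFrame(
        {
            "class_label": plan.labels,
            "p_class": p_class,
            "p_outcome_given_class": p_cond,
        }
    )


def default_cohort_spec(
    n: int = 1090, seed: int = 0, n_noise: int = 73
) -> SyntheticSpec:
    """Cohort emulating the CABG morbidity study design.

    Five planted predictors named and prevalence-matched to the source
    cohort's selected variables, the oxygen extraction ratio carrying
    twice the unit effect; 20.7% overall outcome prevalence; enough noise
    variables to reach 78 candidate columns by default.
    """
    preds = (
        PredictorSpec(
            "O2ER", prevalence=0.213, beta=2.0, carrier="continuous",
            cutoff=40.0, direction=AT_OR_ABOVE, separation=15.0, sd=5.0,
        ),
        PredictorSpec("CardID", prevalence=0.136, beta=1.0),
        PredictorSpec("PVD", prevalence=0.213, beta=1.0),
        PredictorSpec("EM", prevalence=0.083, beta=1.0),
        PredictorSpec(
            "CPBt", prevalence=0.409, beta=1.0, carrier="continuous",
            cutoff=2.0, direction=AT_OR_ABOVE, separation=1.2, sd=0.4,
        ),
    )
    return SyntheticSpec(
        n=n,
        predictors=preds,
        n_noise=n_noise,
        target_prevalence=0.207,
        seed=seed,
    )
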