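"""Score calibration, HRD classification, and assay-agreement statistics.

Raw GIS scores from a laboratory pipeline sit on a slightly different scale
from the commercial reference assay they are validated against.  A linear
regression fitted on paired training samples (reference score on raw score)
supplies the correction ``corrected = m * raw + b``; the corrected score is
kept continuous and classified HRD-positive at the clinically accepted
threshold of 42 (inclusive).

Concordance between two binary assays is summarised by positive, negative
and overall percent agreement (PPA/NPA/OPA) with Wilson score 95%
confidence intervals.  PPA and NPA are margined on the test assay (the
laboratory-developed test), i.e. PPA = both-positive / test-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CalibrationModel",
    "ClassificationConfig",
    "AgreementReport",
    "fit_calibration",
    "apply_calibration",
    "display_score",
    "classify_hrd",
    "wilson_interval",
    "agreement",
    "proportion_pct",
]


@dataclass
class CalibrationModel:
    """corrected = m * raw + b, fitted by ordinary least squares."""

    m: float
    b: float
    n_train: int
    residual_mean: float = 0.0
    residual_sd: float = 0.0
    residual_max_abs: float = 0.0

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "b": self.b,
            "n_train": self.n_train,
            "residual_mean": self.residual_mean,
            "residual_sd": self.residual_sd,
            "residual_max_abs": self.residual_max_abs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(**{k: d[k] for k in ("m", "b", "n_train")},
                   **{k: d.get(k, 0.0) for k in
                      ("residual_mean", "residual_sd", "residual_max_abs")})


@dataclass(frozen=True)
class ClassificationConfig:
    """HRD call rule: positive iff corrected score >= threshold (default 42)."""

    threshold: float = 42.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """OLS of reference score on raw score over (raw, reference) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (raw, reference) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("raw scores are constant; slope is undefined")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return CalibrationModel(
        m=float(res.slope),
        b=float(res.intercept),
        n_train=len(x),
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std(ddof=1)) if len(x) > 2 else 0.0,
        residual_max_abs=float(np.abs(resid).max()),
    )


def apply_calibration(raw_score: float, model: CalibrationModel) -> float:
    """Continuous corrected score; classification consumes this unrounded."""
    return model.m * raw_score + model.b


def display_score(score: float) -> int:
    """Integer display value, rounded half away from zero."""
    return int(math.floor(abs(score) + 0.5) * (1 if score >= 0 else -1))


def classify_hrd(corrected_score: float, config: ClassificationConfig = ClassificationConfig()) -> str:
    """"POS" iff the corrected score reaches the threshold (inclusive)."""
    if not np.isfinite(corrected_score):
        raise ValueError("corrected score must be finite")
    return "POS" if corrected_score >= config.threshold else "NEG"


def wilson_interval(successes: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion (fractions)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - confidence, method="wilson")
    # the exact Wilson bounds at the boundary counts are 0 and 1
    if successes == 0:
        lo = 0.0
    if successes == n:
        hi = 1.0
    return float(min(max(lo, 0.0), 1.0)), float(min(max(hi, 0.0), 1.0))


def proportion_pct(successes: int, n: int, decimals: int = 1) -> float:
    """A percentage rounded for reporting, e.g. 271/654 -> 41.4."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return round(100.0 * successes / n, decimals)


@dataclass
class AgreementReport:
    """2x2 agreement between a reference assay and the test assay.

    Counts: both_pos, ref_pos_test_neg, ref_neg_test_pos, both_neg.
    Statistics are percentages in [0, 100] with Wilson 95% CIs; a statistic
    with a zero denominator is reported as None with no CI.
    """

    both_pos: int
    ref_pos_test_neg: int
    ref_neg_test_pos: int
    both_neg: int
    ppa: float | None = None
    npa: float | None = None
    opa: float | None = None
    ppa_ci: tuple[float, float] | None = None
    npa_ci: tuple[float, float] | None = None
    opa_ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return self.both_pos + self.ref_pos_test_neg + self.ref_neg_test_pos + self.both_neg

    def to_dict(self) -> dict:
        return {
            "counts": {
                "both_pos": self.both_pos,
                "ref_pos_test_neg": self.ref_pos_test_neg,
                "ref_neg_test_pos": self.ref_neg_test_pos,
                "both_neg": self.both_neg,
                "n": self.n,
            },
            "ppa": self.ppa, "ppa_ci": self.ppa_ci,
            "npa": self.npa, "npa_ci": self.npa_ci,
            "opa": self.opa, "opa_ci": self.opa_ci,
        }


def agreement(
    both_pos: int, ref_pos_test_neg: int, ref_neg_test_pos: int, both_neg: int,
    confidence: float = 0.95,
) -> AgreementReport:
    """PPA/NPA/OPA with Wilson CIs from a 2x2 assay-concordance table.

    PPA = both_pos / (test-positive margin), NPA = both_neg /
    (test-negative margin), OPA = concordant / n.  All as percentages.
    """
    counts = (both_pos, ref_pos_test_neg, ref_neg_test_pos, both_neg)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("empty table")
    rep = AgreementReport(*counts)
    test_pos = both_pos + ref_neg_test_pos
    test_neg = ref_pos_test_neg + both_neg
    if test_pos > 0:
        rep.ppa = 100.0 * both_pos / test_pos
        rep.ppa_ci = tuple(100.0 * v for v in wilson_interval(both_pos, test_pos, confidence))
    if test_neg > 0:
        rep.npa = 100.0 * both_neg / test_neg
        rep.npa_ci = tuple(100.0 * v for v in wilson_interval(both_neg, test_neg, confidence))
    rep.opa = 100.0 * (both_pos + both_neg) / n
    rep.opa_ci = tuple(100.0 * v for v in wilson_interval(both_pos + both_neg, n, confidence))
    return rep
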