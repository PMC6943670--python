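"""External-validation statistics and robustness checks for QSAR models.

Implements the conventional battery for judging true external predictivity
of a regression QSAR model on a held-out test set:

* ``rpred² = 1 - PRESS/SD`` with PRESS the test-set squared prediction error
  and SD the squared deviation of test observations from the *training*
  mean;
* the Golbraikh–Tropsha statistics — the Pearson R² between observed and
  predicted, the through-origin slopes k and k', the through-origin
  determination coefficients R0² and R'0² evaluated at those slopes, and
  Roy's ``rm² = R²(1 - sqrt(R² - R0²))``;
* the threshold battery over those statistics (R² > 0.6, slopes within
  0.85–1.15, through-origin R² close to R², |R0² - R'0²| < 0.3, rm² > 0.5);
* Y-randomization: refitting after seeded permutations of the activities to
  show the original q²/r² are not chance correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

__all__ = [
    "q2_statistic",
    "rpred2_statistic",
    "golbraikh_tropsha",
    "tropsha_criteria",
    "y_randomization",
    "ExternalValidationReport",
    "TropshaCheck",
    "YRandomizationResult",
]


def _pair(y, yhat, min_n=2):
    y = np.asarray(y, dtype=float).reshape(-1)
    yhat = np.asarray(yhat, dtype=float).reshape(-1)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {y.shape[0]}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("non-finite values in observed/predicted pairs")
    return y, yhat


def q2_statistic(y, y_pred_cv, y_mean: Optional[float] = None) -> float:
    """Cross-validated determination coefficient
    ``1 - sum((y - yhat)^2) / sum((y - ybar)^2)``; ybar defaults to the mean
    of ``y`` (the training set)."""
    y, yhat = _pair(y, y_pred_cv)
    if y_mean is None:
        y_mean = float(y.mean())
    denom = float(np.sum((y - y_mean) ** 2))
    if denom == 0:
        raise ValueError("degenerate data: zero variance around y_mean")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def rpred2_statistic(y_test, y_pred_test, train_mean: float) -> Tuple[float, float, float]:
    """(PRESS, SD, rpred²) for a test set against the training mean."""
    y, yhat = _pair(y_test, y_pred_test)
    press = float(np.sum((y - yhat) ** 2))
    sd = float(np.sum((y - train_mean) ** 2))
    if sd == 0:
        raise ValueError("SD is zero: test activities all equal the training mean")
    return press, sd, 1.0 - press / sd


@dataclass(frozen=True)
class ExternalValidationReport:
    """The Golbraikh–Tropsha statistics for one observed/predicted pairing.

    ``rm2`` is ``R²(1 - sqrt(R² - R0²))``; when R0² exceeds R² (the radicand
    would be negative) it is reported as NaN and ``rm2_defined`` is False.
    """

    n: int
    r2: float
    k: float
    k_prime: float
    r0_2: float
    r0_prime_2: float
    rm2: float
    y_obs_mean: float
    y_pred_mean: float
    press: Optional[float] = None
    sd: Optional[float] = None
    rpred2: Optional[float] = None

    @property
    def rm2_defined(self) -> bool:
        return math.isfinite(self.rm2)


def golbraikh_tropsha(
    y_test, y_pred_test, train_mean: Optional[float] = None
) -> ExternalValidationReport:
    """Compute the full external-validation report on test-set pairs.

    Through-origin statistics use the regression-through-origin slopes
    ``k = sum(yo*yp)/sum(yp²)`` (observed on predicted) and
    ``k' = sum(yo*yp)/sum(yo²)`` (predicted on observed).  When
    ``train_mean`` is given, PRESS/SD/rpred² are attached as well.
    """
    yo, yp = _pair(y_test, y_pred_test, min_n=3)
    if np.ptp(yo) == 0 or np.ptp(yp) == 0:
        raise ValueError("degenerate variance: observed or predicted values constant")
    r2 = float(np.corrcoef(yo, yp)[0, 1] ** 2)
    k = float(np.sum(yo * yp) / np.sum(yp**2))
    k_prime = float(np.sum(yo * yp) / np.sum(yo**2))
    r0_2 = 1.0 - float(np.sum((yo - k * yp) ** 2) / np.sum((yo - yo.mean()) ** 2))
    r0_prime_2 = 1.0 - float(np.sum((yp - k_prime * yo) ** 2) / np.sum((yp - yp.mean()) ** 2))
    radicand = r2 - r0_2
    if -1e-12 < radicand < 0:  # exact-prediction float dust
        radicand = 0.0
    if radicand < 0:
        warnings.warn(
            f"rm2 undefined: R0² ({r0_2:.4f}) exceeds R² ({r2:.4f})", stacklevel=2
        )
        rm2 = float("nan")
    else:
        rm2 = r2 * (1.0 - math.sqrt(radicand))
    press = sd = rpred2 = None
    if train_mean is not None:
        press, sd, rpred2 = rpred2_statistic(yo, yp, train_mean)
    return ExternalValidationReport(
        n=len(yo),
        r2=r2,
        k=k,
        k_prime=k_prime,
        r0_2=r0_2,
        r0_prime_2=r0_prime_2,
        rm2=rm2,
        y_obs_mean=float(yo.mean()),
        y_pred_mean=float(yp.mean()),
        press=press,
        sd=sd,
        rpred2=rpred2,
    )


@dataclass(frozen=True)
class TropshaCheck:
    """Per-condition verdicts of the external-validation battery.

    overall = 1 ∧ (2a ∨ 2b) ∧ (3a ∨ 3b) ∧ (4a ∨ 4b) ∧ 5 ∧ 6, where the
    'close to R²' conditions 2a/2b are operationalised through the relative
    gaps 4a/4b.
    """

    cond1_r2: bool
    cond3a_k: bool
    cond3b_k_prime: bool
    cond4a_gap: bool
    cond4b_gap_prime: bool
    cond5_r0_diff: bool
    cond6_rm2: bool
    values: dict

    @property
    def cond2a(self) -> bool:
        return self.cond4a_gap

    @property
    def cond2b(self) -> bool:
        return self.cond4b_gap_prime

    @property
    def overall(self) -> bool:
        return (
            self.cond1_r2
            and (self.cond2a or self.cond2b)
            and (self.cond3a_k or self.cond3b_k_prime)
            and (self.cond4a_gap or self.cond4b_gap_prime)
            and self.cond5_r0_diff
            and self.cond6_rm2
        )

    def as_rows(self) -> List[tuple]:
        v = self.values
        return [
            ("1", "R2", ">0.6", v["r2"], self.cond1_r2),
            ("2a/4a", "(R2-R02)/R2", "<0.1", v["gap"], self.cond4a_gap),
            ("2b/4b", "(R2-R'02)/R2", "<0.1", v["gap_prime"], self.cond4b_gap_prime),
            ("3a", "k", "0.85<k<1.15", v["k"], self.cond3a_k),
            ("3b", "k'", "0.85<k'<1.15", v["k_prime"], self.cond3b_k_prime),
            ("5", "|R02-R'02|", "<0.3", v["r0_diff"], self.cond5_r0_diff),
            ("6", "rm2", ">0.5", v["rm2"], self.cond6_rm2),
        ]


def tropsha_criteria(report: ExternalValidationReport) -> TropshaCheck:
    """Evaluate the standard thresholds on an external-validation report."""
    gap = (report.r2 - report.r0_2) / report.r2
    gap_prime = (report.r2 - report.r0_prime_2) / report.r2
    r0_diff = abs(report.r0_2 - report.r0_prime_2)
    return TropshaCheck(
        cond1_r2=report.r2 > 0.6,
        cond3a_k=0.85 < report.k < 1.15,
        cond3b_k_prime=0.85 < report.k_prime < 1.15,
        cond4a_gap=gap < 0.1,
        cond4b_gap_prime=gap_prime < 0.1,
        cond5_r0_diff=r0_diff < 0.3,
        cond6_rm2=(report.rm2 > 0.5) if report.rm2_defined else False,
        values={
            "r2": report.r2,
            "k": report.k,
            "k_prime": report.k_prime,
            "r0_2": report.r0_2,
            "r0_prime_2": report.r0_prime_2,
            "gap": gap,
            "gap_prime": gap_prime,
            "r0_diff": r0_diff,
            "rm2": report.rm2,
        },
    )


@dataclass
class YRandomizationResult:
    """Shuffled-activity refits next to the original statistics."""

    iterations: List[Tuple[float, float]]  # (q2, r2) per shuffle
    failures: List[int]
    seed: int
    original_q2: Optional[float] = None
    original_r2: Optional[float] = None

    @property
    def max_shuffled_q2(self) -> float:
        return max(q for q, _ in self.iterations) if self.iterations else float("nan")

    @property
    def max_shuffled_r2(self) -> float:
        return max(r for _, r in self.iterations) if self.iterations else float("nan")


def y_randomization(
    fit_fn: Callable[[np.ndarray, np.ndarray], Tuple[float, float]],
    X,
    y,
    n_iter: int = 10,
    seed: int = 0,
    original: Optional[Tuple[float, float]] = None,
) -> YRandomizationResult:
    """Refit after permuting the activity vector ``n_iter`` times.

    ``fit_fn(X, y_shuffled)`` must return ``(q2, r2)``.  A per-iteration fit
    failure is recorded, not fatal.  The permutation stream is driven by a
    dedicated seeded generator so runs are reproducible.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    rng = np.random.default_rng(seed)
    iterations: List[Tuple[float, float]] = []
    failures: List[int] = []
    for it in range(n_iter):
        y_shuf = rng.permutation(y)
        try:
            q2, r2 = fit_fn(X, y_shuf)
            iterations.append((float(q2), float(r2)))
        except Exception:
            failures.append(it)
    orig_q2, orig_r2 = (original if original is not None else (None, None))
    return YRandomizationResult(
        iterations=iterations,
        failures=failures,
        seed=seed,
        original_q2=orig_q2,
        original_r2=orig_r2,
    )
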