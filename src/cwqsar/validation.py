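"""Validation statistics for QSAR models.

Implements the regression-quality panel conventionally reported for
correlation-weight and MLR QSAR models: r², standard error of estimation,
RMSE, MAE, Fisher ratio, leave-one-out q², Lin's concordance correlation
coefficient (CCC), the index of ideality of correlation (IIC), the Roy
r²m pair, an MAE-based quality class, and Y-randomization.

All metrics operate on plain observed/predicted vectors and are invariant to
sample ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class YScrambleSummary:
    n_scrambles: int
    mean_scrambled_r2: float
    max_scrambled_r2: float
    true_r2: float
    crp2: float


@dataclass
class ValidationReport:
    """One column of the conventional QSAR statistics table."""

    set_name: str
    n: int
    r2: float
    q2_loo: float | None
    s: float
    rmse: float
    mae: float
    F: float
    ccc: float
    iic: float
    iic_warning: bool
    rm2_avg: float
    rm2_delta: float
    mae_class: str | None = None
    y_scramble: YScrambleSummary | None = None

    def as_dict(self) -> dict:
        d = {
            "set": self.set_name, "n": self.n, "r2": self.r2,
            "q2": self.q2_loo, "s": self.s, "rmse": self.rmse,
            "mae": self.mae, "F": self.F, "ccc": self.ccc, "iic": self.iic,
            "rm2_avg": self.rm2_avg, "rm2_delta": self.rm2_delta,
            "mae_class": self.mae_class,
        }
        return d


def _as_arrays(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be equal-length vectors")
    return o, p


def basic_stats(observed, predicted) -> tuple[float, float, float, float, float]:
    """(r², s, RMSE, MAE, F) for one observed/predicted pair.

    r² is the squared Pearson correlation; s is the residual standard error
    of the one-predictor calibration line (n − 2 denominator); F is the
    regression F-ratio of that line.
    """
    o, p = _as_arrays(observed, predicted)
    n = o.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(o) == 0 or np.var(p) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(o, p)[0, 1])
    r2 = r * r
    resid = o - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    # residuals about the fitted o-on-p line, 2 estimated parameters
    slope, intercept = np.polyfit(p, o, 1)
    line_resid = o - (intercept + slope * p)
    s = float(np.sqrt(np.sum(line_resid**2) / (n - 2)))
    F = float((r2 / 1.0) / ((1.0 - r2) / (n - 2))) if r2 < 1.0 else float("inf")
    return r2, s, rmse, mae, F


def q2_loo(x, y) -> float:
    """Leave-one-out cross-validated determination coefficient.

    Refits the calibration line y ~ x on each leave-one-out subset, predicts
    the held-out point and returns 1 − PRESS/SS_total.
    """
    x, y = _as_arrays(x, y)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 points for LOO")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, yi = x[mask], y[mask]
        if np.var(xi) == 0:
            raise ValueError("degenerate LOO refit: constant predictor")
        slope, intercept = np.polyfit(xi, yi, 1)
        press += (y[i] - (intercept + slope * x[i])) ** 2
    ss_total = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss_total


def ccc(observed, predicted) -> float:
    """Lin's concordance correlation coefficient (sample moments)."""
    o, p = _as_arrays(observed, predicted)
    vo, vp = np.var(o), np.var(p)
    if vo == 0 and vp == 0:
        raise ValueError("both vectors constant")
    cov = float(np.mean((o - o.mean()) * (p - p.mean())))
    return 2.0 * cov / (vo + vp + (o.mean() - p.mean()) ** 2)


def iic(observed, predicted) -> tuple[float, bool]:
    """Index of ideality of correlation and an empty-group warning flag.

    Residuals (observed − predicted) are split by sign; the index is the
    Pearson correlation scaled by min(MAE⁻, MAE⁺)/max(MAE⁻, MAE⁺), where
    MAE⁻/MAE⁺ are the mean absolute residuals of the negative/positive
    groups.  If either group is empty the index is reported as 0 with the
    warning flag set.
    """
    o, p = _as_arrays(observed, predicted)
    resid = o - p
    neg = resid[resid < 0]
    pos = resid[resid >= 0]
    # zero residuals count to the positive group; an all-zero residual
    # vector is a degenerate perfect fit handled by the empty-group rule
    if neg.size == 0 or pos.size == 0 or np.var(o) == 0 or np.var(p) == 0:
        return 0.0, True
    mae_neg = float(np.mean(np.abs(neg)))
    mae_pos = float(np.mean(np.abs(pos)))
    r = float(np.corrcoef(o, p)[0, 1])
    hi, lo = max(mae_neg, mae_pos), min(mae_neg, mae_pos)
    if hi == 0:
        return 0.0, True
    return r * lo / hi, False


def rm2_metrics(observed, predicted) -> tuple[float, float]:
    """Roy's r²m validation pair (average, absolute difference).

    r²m = r²(1 − sqrt(r² − r₀²)) with r₀² the determination coefficient of
    the through-origin regression, computed in both axis orientations.
    """
    o, p = _as_arrays(observed, predicted)
    if o.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(o) == 0 or np.var(p) == 0:
        raise ValueError("zero variance input")

    def _rm2(y, x):
        r2 = float(np.corrcoef(y, x)[0, 1]) ** 2
        k = float(np.sum(x * y) / np.sum(x * x))
        ss_res0 = float(np.sum((y - k * x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r02 = 1.0 - ss_res0 / ss_tot
        return r2 * (1.0 - np.sqrt(max(r2 - r02, 0.0)))

    rm2_fwd = _rm2(o, p)
    rm2_rev = _rm2(p, o)
    return (rm2_fwd + rm2_rev) / 2.0, abs(rm2_fwd - rm2_rev)


#: (good_mae, good_mae3s, bad_mae, bad_mae3s) as fractions of training range
MAE_CLASS_THRESHOLDS = (0.10, 0.20, 0.15, 0.25)


def mae_class(
    observed,
    predicted,
    training_range: float,
    thresholds: tuple[float, float, float, float] = MAE_CLASS_THRESHOLDS,
) -> str:
    """MAE-based quality class GOOD / MODERATE / BAD.

    GOOD when MAE ≤ t₁·range and MAE + 3σ ≤ t₂·range; BAD when MAE >
    t₃·range or MAE + 3σ > t₄·range; MODERATE otherwise.  Boundary values go
    to the better class.
    """
    o, p = _as_arrays(observed, predicted)
    if training_range <= 0:
        raise ValueError("training range must be positive")
    abs_err = np.abs(o - p)
    m = float(np.mean(abs_err))
    m3s = m + 3.0 * float(np.std(abs_err))
    t1, t2, t3, t4 = (t * training_range for t in thresholds)
    if m <= t1 and m3s <= t2:
        return "GOOD"
    if m > t3 or m3s > t4:
        return "BAD"
    return "MODERATE"


def crp2(true_r2: float, mean_scrambled_r2: float) -> float:
    """cRp² chance-correlation statistic √(r²·(r² − mean scrambled r²)).

    Zero when the model does no better than its scrambled counterparts
    (negative excess is clamped to zero).
    """
    excess = true_r2 - mean_scrambled_r2
    return float(np.sqrt(true_r2 * max(excess, 0.0)))


def y_scramble(split, T: int, n_epoch: int, n_scrambles: int, seed: int,
               move_scale: float = 0.1) -> YScrambleSummary:
    """Y-randomization of the correlation-weight model.

    Training activities are permuted (identity permutations are rejected and
    redrawn), the full optimize+calibrate cycle is rerun per permutation, and
    the scrambled test-set r² distribution is summarised together with the
    cRp² statistic of the unscrambled model.
    """
    from .mc_model import evaluate_r2, optimize

    if n_scrambles < 1:
        raise ValueError("need at least one scramble")
    rng = np.random.default_rng(seed)

    model = optimize(split, T=T, n_epoch=n_epoch,
                     seed=int(rng.integers(2**31)), move_scale=move_scale)
    true_r2 = evaluate_r2(model, split.test)

    scrambled = []
    y = np.array([rec.activity for rec in split.training], dtype=float)
    for _ in range(n_scrambles):
        perm = rng.permutation(y.size)
        while np.all(perm == np.arange(y.size)):
            perm = rng.permutation(y.size)
        shuffled = split.with_training_activities(y[perm])
        m = optimize(shuffled, T=T, n_epoch=n_epoch,
                     seed=int(rng.integers(2**31)), move_scale=move_scale)
        scrambled.append(evaluate_r2(m, shuffled.test))

    mean_scr = float(np.mean(scrambled))
    return YScrambleSummary(
        n_scrambles=n_scrambles,
        mean_scrambled_r2=mean_scr,
        max_scrambled_r2=float(np.max(scrambled)),
        true_r2=true_r2,
        crp2=crp2(true_r2, mean_scr),
    )


def validation_report(
    set_name: str,
    observed,
    predicted,
    training_range: float | None = None,
    with_q2: bool = True,
) -> ValidationReport:
    """Assemble the full statistics panel for one molecule set."""
    o, p = _as_arrays(observed, predicted)
    r2, s, rmse, mae, F = basic_stats(o, p)
    q2 = q2_loo(p, o) if with_q2 and o.size >= 4 else None
    iic_val, iic_warn = iic(o, p)
    rm2_avg, rm2_delta = rm2_metrics(o, p)
    cls = (
        mae_class(o, p, training_range) if training_range else None
    )
    return ValidationReport(
        set_name=set_name, n=int(o.size), r2=r2, q2_loo=q2, s=s, rmse=rmse,
        mae=mae, F=F, ccc=ccc(o, p), iic=iic_val, iic_warning=iic_warn,
        rm2_avg=rm2_avg, rm2_delta=rm2_delta, mae_class=cls,
    )
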