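"""Coccosphere-diameter to cell-diameter calibration.

For placolith-bearing coccolithophores the coccosphere (the calcite
exoskeleton) diameter is a linear proxy for the cell diameter it once
enclosed; the published pooled relationship across typical placolith
species has slope ~0.836 (95% CI half-width ~0.01) with R^2 ~0.956.
This module fits such calibrations by ordinary least squares, tests
whether per-species slopes differ (the ANCOVA-style F decomposition),
predicts cell diameter with a prediction interval, and compares two
diameter populations with an unpaired t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidInputError, InvalidParameterError

X_COL = "coccosphere_d_um"
Y_COL = "cell_d_um"

#: Pooled placolith calibration slope (dimensionless, um cell per um
#: coccosphere), published for the Coccolithaceae / Calcidiscaceae /
#: Noelaerhabdaceae families; used by the no-intercept preset.
POOLED_PLACOLITH_SLOPE = 0.836


@dataclass
class CalibrationModel:
    """An OLS coccosphere->cell size calibration.

    ``x_mean``/``x_ss`` carry the design information needed for prediction
    intervals (for a no-intercept fit ``x_ss`` is the uncentered sum of
    squares and ``x_mean`` is 0).
    """

    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    r_squared: float
    n: int
    residual_sd: float | None
    with_intercept: bool = True
    x_mean: float = 0.0
    x_ss: float | None = None
    per_species: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slope_ci95"] = list(self.slope_ci95)
        d["per_species"] = {k: v.to_dict() for k, v in self.per_species.items()}
        return d


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome (t or F)."""

    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def pooled_placolith_model() -> CalibrationModel:
    """The published pooled placolith calibration (slope 0.836, intercept 0).

    A convenience preset for predicting cell size when no sample-specific
    calibration is available; carries no residual information, so
    :func:`predict_cell_diameter` returns point estimates only.
    """
    return CalibrationModel(
        slope=POOLED_PLACOLITH_SLOPE,
        intercept=0.0,
        slope_ci95=(POOLED_PLACOLITH_SLOPE - 0.01, POOLED_PLACOLITH_SLOPE + 0.01),
        r_squared=0.956,
        n=0,
        residual_sd=None,
        with_intercept=False,
    )


def _validate_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(pairs, pd.DataFrame):
        raise InvalidInputError("pairs must be a DataFrame")
    missing = [c for c in (X_COL, Y_COL) if c not in pairs.columns]
    if missing:
        raise InvalidInputError(f"pairs missing column(s): {missing}")
    if not np.isfinite(pairs[[X_COL, Y_COL]].to_numpy()).all():
        raise InvalidInputError("pairs contain non-finite values")
    return pairs


def fit_calibration(
    pairs: pd.DataFrame, with_intercept: bool = True, *, fit_species: bool = True
) -> CalibrationModel:
    """OLS fit of cell diameter on coccosphere diameter.

    The slope CI is the 95% t interval. When a ``species`` column is
    present, per-species sub-models (each needing >= 3 pairs) are fitted
    and attached. Note the usual caveat for ``with_intercept=False``:
    statsmodels reports the uncentered R^2.
    """
    pairs = _validate_pairs(pairs)
    x = pairs[X_COL].to_numpy(dtype=float)
    y = pairs[Y_COL].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise InvalidInputError(f"need >= 3 pairs, got {n}")
    if np.ptp(x) == 0:
        raise InvalidInputError("zero variance in coccosphere diameters")

    design = sm.add_constant(x) if with_intercept else x[:, None]
    res = sm.OLS(y, design).fit()
    slope_idx = 1 if with_intercept else 0
    ci = res.conf_int(alpha=0.05)
    residual_sd = float(np.sqrt(res.mse_resid))

    per_species: dict[str, CalibrationModel] = {}
    if fit_species and "species" in pairs.columns:
        for name, grp in pairs.groupby("species", sort=True):
            if len(grp) >= 3 and np.ptp(grp[X_COL].to_numpy()) > 0:
                per_species[str(name)] = fit_calibration(
                    grp, with_intercept, fit_species=False
                )

    return CalibrationModel(
        slope=float(res.params[slope_idx]),
        intercept=float(res.params[0]) if with_intercept else 0.0,
        slope_ci95=(float(ci[slope_idx, 0]), float(ci[slope_idx, 1])),
        r_squared=float(res.rsquared),
        n=n,
        residual_sd=residual_sd,
        with_intercept=with_intercept,
        x_mean=float(x.mean()) if with_intercept else 0.0,
        x_ss=float(((x - x.mean()) ** 2).sum()) if with_intercept else float((x**2).sum()),
        per_species=per_species,
    )


def slope_heterogeneity_test(pairs_by_species: pd.DataFrame) -> TestResult:
    """ANCOVA-style test that per-species calibration slopes are equal.

    Compares the common-slope model (separate intercepts, one slope) with
    the separate-slopes model::

        F = [(SSE_common - SSE_separate) / (k - 1)] / [SSE_separate / (n - 2k)]

    with k species and n total pairs; the p-value is from F(k-1, n-2k).
    """
    pairs = _validate_pairs(pairs_by_species)
    if "species" not in pairs.columns:
        raise InvalidInputError("pairs must carry a 'species' column")
    groups = list(pairs.groupby("species", sort=True))
    k = len(groups)
    if k < 2:
        raise InvalidInputError(f"need >= 2 species, got {k}")

    sxx = np.empty(k)
    sxy = np.empty(k)
    syy = np.empty(k)
    for i, (name, grp) in enumerate(groups):
        if len(grp) < 3:
            raise InvalidInputError(f"species {name!r} has < 3 pairs")
        x = grp[X_COL].to_numpy(dtype=float)
        y = grp[Y_COL].to_numpy(dtype=float)
        xc, yc = x - x.mean(), y - y.mean()
        sxx[i] = (xc**2).sum()
        if sxx[i] == 0:
            raise InvalidInputError(f"species {name!r} has zero x-variance")
        sxy[i] = (xc * yc).sum()
        syy[i] = (yc**2).sum()

    n = len(pairs)
    sse_separate = float((syy - sxy**2 / sxx).sum())
    b_common = sxy.sum() / sxx.sum()
    sse_common = float((syy - 2 * b_common * sxy + b_common**2 * sxx).sum())
    df1, df2 = k - 1, n - 2 * k
    if df2 <= 0:
        raise InvalidInputError("too few pairs for the separate-slopes model")
    if sse_separate == 0:
        f_stat = math.inf if sse_common > sse_separate else 0.0
    else:
        f_stat = ((sse_common - sse_separate) / df1) / (sse_separate / df2)
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, df1, df2))
    return TestResult(
        statistic=float(f_stat),
        df=(float(df1), float(df2)),
        p_value=p,
        details={
            "sse_common_slope": sse_common,
            "sse_separate_slopes": sse_separate,
            "common_slope": float(b_common),
            "n_species": k,
            "n_pairs": n,
        },
    )


def predict_cell_diameter(
    model: CalibrationModel, coccosphere_d, *, alpha: float = 0.05
):
    """Predict cell diameter (um) with a 95% prediction interval.

    Returns ``(point, (low, high))``; the interval is ``None`` when the
    model carries no residual information (e.g. the published preset).
    Accepts a scalar or an array of diameters.
    """
    d = np.asarray(coccosphere_d, dtype=float)
    if np.any(d <= 0):
        raise InvalidParameterError("coccosphere diameter must be > 0")
    point = model.intercept + model.slope * d
    if model.residual_sd is None or model.x_ss in (None, 0) or model.n < 3:
        out_pi = None
    else:
        p = 2 if model.with_intercept else 1
        tcrit = stats.t.ppf(1 - alpha / 2, model.n - p)
        leverage = (d - model.x_mean) ** 2 / model.x_ss
        if model.with_intercept:
            leverage = leverage + 1.0 / model.n
        half = tcrit * model.residual_sd * np.sqrt(1.0 + leverage)
        out_pi = (point - half, point + half)
    if np.ndim(coccosphere_d) == 0:
        point = float(point)
        if out_pi is not None:
            out_pi = (float(out_pi[0]), float(out_pi[1]))
    return point, out_pi


def compare_diameter_populations(
    a, b, *, equal_var: bool = True
) -> TestResult:
    """Two-sided unpaired t-test between two diameter populations.

    Student's pooled-variance test by default; Welch via
    ``equal_var=False``. Group means and standard errors of the mean are
    reported in ``details``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = float(res.df)
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        details={
            "mean_a": float(a.mean()),
            "mean_b": float(b.mean()),
            "sem_a": float(stats.sem(a)),
            "sem_b": float(stats.sem(b)),
            "n_a": int(a.size),
            "n_b": int(b.size),
            "mean_difference": float(a.mean() - b.mean()),
        },
    )
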