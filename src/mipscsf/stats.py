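"""Cross-modality synchronization and the correlation battery.

The phase-shift recording and the MR acquisitions are asynchronous
(different rooms), so the two modalities are aligned on injected blood
volume, which the constant-rate infusion makes a shared clock.  The
statistical battery on the aligned nine-point cross-animal means
comprises: multiple regression of mean phase on mean CSF volume and
injected blood with the classical ANOVA summary (R, R^2, adjusted R^2,
F with its tail p); first-order partial correlations of phase with CSF
controlling blood and vice versa; and the Pearson correlation of the
fitted derivative curves of the two mean trajectories.

The nine cross-animal means are the regression sample (n = 9): the
ANOVA degrees of freedom (2, 6, 8) of the study this emulates force
that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .processing import BlockSeries, detect_reversal, fit_polynomial
from .processing import DEFAULT_FIT_DEGREE, first_derivative
from .schedule import InjectionSchedule

__all__ = [
    "AlignedDataset",
    "MultipleRegressionResult",
    "PartialCorrelationResult",
    "DerivativeCorrelationResult",
    "synchronize",
    "multiple_regression",
    "partial_correlation",
    "derivative_correlation",
    "build_report",
]


@dataclass
class AlignedDataset:
    """Phase and CSF tables aligned on the injected-blood axis."""

    blood_ml: np.ndarray  # (T,)
    time_min: np.ndarray  # (T,)
    mips: np.ndarray  # (T, n_rabbits)
    csf_ml: np.ndarray  # (T, n_rabbits)

    def __post_init__(self) -> None:
        self.blood_ml = np.asarray(self.blood_ml, dtype=float)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.mips = np.atleast_2d(np.asarray(self.mips, dtype=float))
        self.csf_ml = np.atleast_2d(np.asarray(self.csf_ml, dtype=float))
        t = self.blood_ml.size
        if np.any(np.diff(self.blood_ml) <= 0):
            raise ValueError("blood_ml must be strictly increasing")
        if self.time_min.shape != (t,):
            raise ValueError("time_min must match blood_ml")
        if self.mips.shape[0] != t or self.csf_ml.shape != self.mips.shape:
            raise ValueError("mips and csf_ml must be (time points x rabbits) and agree")

    @property
    def n_rabbits(self) -> int:
        return self.mips.shape[1]

    @property
    def mips_mean(self) -> np.ndarray:
        return self.mips.mean(axis=1)

    @property
    def csf_mean(self) -> np.ndarray:
        return self.csf_ml.mean(axis=1)


def _table_to_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cols = [c for c in table.columns if c.startswith("rabbit_")]
    if not cols:
        raise ValueError("table has no rabbit_* columns")
    cols = sorted(cols, key=lambda c: int(c.split("_")[1]))
    return (
        table["blood_ml"].to_numpy(float),
        table["time_min"].to_numpy(float),
        table[cols].to_numpy(float),
    )


def synchronize(
    mips_table: pd.DataFrame,
    csf_table: pd.DataFrame,
    schedule: InjectionSchedule | None = None,
) -> AlignedDataset:
    """Align the two cohort tables on injected blood volume.

    Both tables must carry ``time_min``, ``blood_ml`` and matching
    ``rabbit_*`` columns on the same blood grid (the schedule's, when
    one is given).
    """
    b1, t1, m1 = _table_to_matrix(mips_table)
    b2, _, m2 = _table_to_matrix(csf_table)
    if b1.shape != b2.shape or not np.allclose(b1, b2, atol=1e-9):
        raise ValueError("the two tables are on different blood grids")
    if m1.shape[1] != m2.shape[1]:
        raise ValueError("the two tables have different rabbit columns")
    if schedule is not None and not np.allclose(b1, schedule.sample_blood, atol=1e-9):
        raise ValueError("table blood grid does not match the schedule")
    return AlignedDataset(blood_ml=b1, time_min=t1, mips=m1, csf_ml=m2)


@dataclass(frozen=True)
class MultipleRegressionResult:
    """OLS fit with the classical ANOVA summary (SPSS-style model table)."""

    R: float
    R_squared: float
    adj_R_squared: float
    se_estimate: float
    ss_regression: float
    ss_residual: float
    ss_total: float
    df_regression: int
    df_residual: int
    df_total: int
    ms_regression: float
    ms_residual: float
    F: float
    p_value: float
    coefficients: tuple[float, ...]
    intercept: float
    n: int


def multiple_regression(y: np.ndarray, X: np.ndarray) -> MultipleRegressionResult:
    """OLS of ``y`` on predictor columns ``X`` with an intercept.

    Returns the model-summary and ANOVA quantities: R = sqrt(R^2),
    adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1), the standard error of the
    estimate sqrt(SS_res / (n-p-1)), and F = MS_reg/MS_res with its
    upper-tail p on (p, n-p-1) degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < p + 1:
        raise np.linalg.LinAlgError("predictors are collinear (rank-deficient design)")
    fit = sm.OLS(y, design).fit()
    ss_res = float(fit.ssr)
    ss_reg = float(fit.ess)
    ss_tot = ss_reg + ss_res
    df_reg, df_res = p, n - p - 1
    return MultipleRegressionResult(
        R=float(np.sqrt(fit.rsquared)),
        R_squared=float(fit.rsquared),
        adj_R_squared=float(fit.rsquared_adj),
        se_estimate=float(np.sqrt(ss_res / df_res)),
        ss_regression=ss_reg,
        ss_residual=ss_res,
        ss_total=ss_tot,
        df_regression=df_reg,
        df_residual=df_res,
        df_total=n - 1,
        ms_regression=ss_reg / df_reg,
        ms_residual=ss_res / df_res,
        F=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        coefficients=tuple(float(c) for c in fit.params[1:]),
        intercept=float(fit.params[0]),
        n=n,
    )


@dataclass(frozen=True)
class PartialCorrelationResult:
    """First-order partial correlation with a two-sided t-test."""

    r: float
    control: str
    p_value: float
    n: int


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, control: str = "z"
) -> PartialCorrelationResult:
    """Correlation of x and y with the linear effect of z removed.

    Uses the first-order recursion
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    with the two-sided p from t = r sqrt((n-3)/(1-r^2)) on n-3 degrees
    of freedom.  Equivalent to the Pearson correlation of the OLS
    residuals of x|z and y|z.
    """
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    n = x.size
    if not (y.size == n == z.size) or n < 4:
        raise ValueError("x, y, z must have equal length n >= 4")
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom <= 1e-24 or max(abs(rxz), abs(ryz)) >= 1.0 - 1e-12:
        raise ValueError("partial correlation undefined: a marginal correlation is +-1")
    r = float((rxy - rxz * ryz) / np.sqrt(denom))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 3) / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 3))
    return PartialCorrelationResult(r=r, control=control, p_value=p, n=n)


@dataclass(frozen=True)
class DerivativeCorrelationResult:
    """Pearson correlation of the two fitted derivative curves."""

    r: float
    p_value: float
    degree: int
    r_finite_difference: float
    p_finite_difference: float


def derivative_correlation(
    mips_series: BlockSeries,
    csf_series: BlockSeries,
    degree: int = DEFAULT_FIT_DEGREE,
) -> DerivativeCorrelationResult:
    """Correlate the rate-of-change curves of the two mean trajectories.

    Both series are fitted with a degree-``degree`` polynomial in blood
    volume; the analytic derivatives are evaluated on the shared blood
    grid and correlated (primary result).  The finite-difference
    variant is reported alongside.
    """
    if mips_series.blood_ml.shape != csf_series.blood_ml.shape or not np.allclose(
        mips_series.blood_ml, csf_series.blood_ml
    ):
        raise ValueError("series must share the same blood grid")
    dm = fit_polynomial(mips_series, degree).derivative_values
    dc = fit_polynomial(csf_series, degree).derivative_values
    r, p = sps.pearsonr(dm, dc)
    fdm = first_derivative(mips_series)
    fdc = first_derivative(csf_series)
    rf, pf = sps.pearsonr(fdm, fdc)
    return DerivativeCorrelationResult(
        r=float(r), p_value=float(p), degree=degree,
        r_finite_difference=float(rf), p_finite_difference=float(pf),
    )


def build_report(aligned: AlignedDataset, degree: int = DEFAULT_FIT_DEGREE) -> dict:
    """The full correlation battery on an aligned dataset, as one dict.

    Contains the multiple-regression model summary and ANOVA of mean
    phase on (mean CSF, blood), both first-order partial correlations,
    the derivative-curve correlation, and the reversal analysis of the
    mean phase trajectory.  Deterministic and JSON-serializable.
    """
    y = aligned.mips_mean
    c = aligned.csf_mean
    b = aligned.blood_ml
    reg = multiple_regression(y, np.column_stack([c, b]))
    p_csf = partial_correlation(y, c, b, control="injected_blood")
    p_blood = partial_correlation(y, b, c, control="csf")
    mseries = BlockSeries(blood_ml=b, time_min=aligned.time_min, value=y)
    cseries = BlockSeries(blood_ml=b, time_min=aligned.time_min, value=c)
    dcorr = derivative_correlation(mseries, cseries, degree=degree)
    rev = detect_reversal(mseries, degree=degree)
    return {
        "n_rabbits": aligned.n_rabbits,
        "n_time_points": int(aligned.blood_ml.size),
        "blood_ml": aligned.blood_ml.tolist(),
        "mips_mean": y.tolist(),
        "csf_mean": c.tolist(),
        "multiple_regression": {
            "R": reg.R,
            "R_squared": reg.R_squared,
            "adj_R_squared": reg.adj_R_squared,
            "se_estimate": reg.se_estimate,
            "ss_regression": reg.ss_regression,
            "ss_residual": reg.ss_residual,
            "ss_total": reg.ss_total,
            "df": [reg.df_regression, reg.df_residual, reg.df_total],
            "ms_regression": reg.ms_regression,
            "ms_residual": reg.ms_residual,
            "F": reg.F,
            "p_value": reg.p_value,
            "coefficients": list(reg.coefficients),
            "intercept": reg.intercept,
        },
        "partial_correlation": {
            "mips_csf_given_blood": {"r": p_csf.r, "p_value": p_csf.p_value, "n": p_csf.n},
            "mips_blood_given_csf": {"r": p_blood.r, "p_value": p_blood.p_value, "n": p_blood.n},
        },
        "derivative_correlation": {
            "r": dcorr.r,
            "p_value": dcorr.p_value,
            "degree": dcorr.degree,
            "r_finite_difference": dcorr.r_finite_difference,
            "p_finite_difference": dcorr.p_finite_difference,
        },
        "reversal": {
            "reversal_blood_ml": rev.reversal_blood_ml,
            "zero_crossing_blood_ml": rev.zero_crossing_blood_ml,
            "derivative_max_index": rev.derivative_max_index,
            "reversal_section": [rev.reversal_section.start, rev.reversal_section.stop],
        },
        "config": {"polynomial_degree": degree},
    }
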