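"""Volume-biomass allometry and method-comparison statistics.

Regressions relate a per-plot volumetric estimate (m^3) to oven-dry
biomass (g), either linearly or on ln-ln axes (a power law).  Reported
fits are screened by Cohen's f^2 effect size with a noncentral-F power
analysis: a fit counts as significant only when the achieved power at
the sample size reaches the minimum threshold (default 90%).

Also here: paired Wilcoxon signed-rank comparisons of voxel-volume
distributions across voxel sizes (Holm-corrected), Lin's concordance
correlation coefficient, and total-least-squares (orthogonal) line fits
for method-agreement plots.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RegressionResult:
    """One fitted allometric model.

    form: 'linear' (biomass = a + b*V), 'log' (ln biomass = a + b*ln V)
    or 'semilog' (biomass = a + b*ln V).  r_squared is on the fitting
    scale; rmse_g is always on the original gram scale (log fits are
    back-transformed before computing residuals).  f_squared =
    R^2/(1-R^2); achieved_power and significant are filled in by
    power_screen.
    """

    form: str
    slope: float
    intercept: float
    r_squared: float
    rmse_g: float
    n: int
    f_squared: float = np.nan
    achieved_power: float = np.nan
    significant: bool = False
    degenerate: bool = False


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R^2 by ordinary least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("zero variance in predictor")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(((y - (intercept + slope * x)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return slope, intercept, r2


def fit_linear(volume: np.ndarray, biomass_g: np.ndarray) -> RegressionResult:
    """OLS biomass = a + b * volume; RMSE in grams on the observed scale."""
    volume = np.asarray(volume, dtype=float)
    biomass_g = np.asarray(biomass_g, dtype=float)
    n = len(volume)
    if n < 3 or n != len(biomass_g):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(volume) == 0:
        raise ValueError("zero variance in volume")
    if np.ptp(biomass_g) == 0:
        # constant response: no explainable variance, flagged rather than fatal
        return RegressionResult("linear", 0.0, float(biomass_g[0]), 0.0, 0.0, n,
                                degenerate=True)
    slope, intercept, r2 = _ols(volume, biomass_g)
    rmse = float(np.sqrt(np.mean((biomass_g - (intercept + slope * volume)) ** 2)))
    return RegressionResult("linear", slope, intercept, r2, rmse, n)


def fit_log(volume: np.ndarray, biomass_g: np.ndarray, semilog: bool = False) -> RegressionResult:
    """Power-law fit by OLS on ln-ln axes (or biomass vs ln volume if semilog).

    R^2 is reported on the fitting (log) scale; RMSE is back-transformed
    to grams so linear and log models are directly comparable.
    """
    volume = np.asarray(volume, dtype=float)
    biomass_g = np.asarray(biomass_g, dtype=float)
    n = len(volume)
    if n < 3 or n != len(biomass_g):
        raise ValueError("need >= 3 paired observations")
    bad_v = np.flatnonzero(volume <= 0)
    if bad_v.size:
        raise ValueError(f"nonpositive volumes at indices {bad_v.tolist()}")
    if not semilog:
        bad_b = np.flatnonzero(biomass_g <= 0)
        if bad_b.size:
            raise ValueError(f"nonpositive biomass at indices {bad_b.tolist()}")
    lx = np.log(volume)
    if np.ptp(lx) == 0:
        raise ValueError("zero variance in log volume")
    if semilog:
        slope, intercept, r2 = _ols(lx, biomass_g)
        fitted_g = intercept + slope * lx
        form = "semilog"
    else:
        slope, intercept, r2 = _ols(lx, np.log(biomass_g))
        fitted_g = np.exp(intercept + slope * lx)
        form = "log"
    rmse = float(np.sqrt(np.mean((biomass_g - fitted_g) ** 2)))
    return RegressionResult(form, slope, intercept, r2, rmse, n)


def power_screen(
    result: RegressionResult, alpha: float = 0.05, min_power: float = 0.90
) -> RegressionResult:
    """Attach Cohen's f^2 and the achieved power of the slope test.

    f^2 = R^2/(1-R^2); power from the noncentral F distribution with
    df = (1, n-2) and noncentrality f^2 * n at test size alpha.  A fit is
    'significant' when achieved power >= min_power.
    """
    r2 = result.r_squared
    n = result.n
    if r2 >= 1.0:
        f2, power = np.inf, 1.0
    else:
        f2 = r2 / (1.0 - r2)
        crit = stats.f.isf(alpha, 1, n - 2)
        nc = f2 * n
        power = float(stats.ncf.sf(crit, 1, n - 2, nc)) if nc > 0 else alpha
    return dataclasses.replace(
        result, f_squared=f2, achieved_power=power,
        significant=bool(power >= min_power),
    )


def compare_voxel_distributions(
    volumes: pd.DataFrame | np.ndarray,
    edge_labels: list | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise paired Wilcoxon signed-rank tests across voxel sizes.

    ``volumes`` is plots x edge-lengths (same plots in every column).
    Exact null distribution for n <= 25 pairs, normal approximation with
    continuity correction above.  P-values are Holm-corrected across the
    pair family.  A pair with all-zero differences gets p = 1 (tie).
    """
    if isinstance(volumes, pd.DataFrame):
        mat = volumes.to_numpy(dtype=float)
        labels = list(volumes.columns) if edge_labels is None else edge_labels
    else:
        mat = np.asarray(volumes, dtype=float)
        labels = edge_labels if edge_labels is not None else list(range(mat.shape[1]))
    n_plots, n_edges = mat.shape
    if n_edges < 2:
        raise ValueError("need at least two edge lengths")
    if n_plots < 6:
        raise ValueError("need at least six plots")
    pairs = [(i, j) for i in range(n_edges) for j in range(i + 1, n_edges)]
    raw = []
    for i, j in pairs:
        diff = mat[:, i] - mat[:, j]
        if np.all(diff == 0):
            raw.append(1.0)
            continue
        method = "exact" if n_plots <= 25 else "approx"
        res = stats.wilcoxon(mat[:, i], mat[:, j], zero_method="wilcox",
                             correction=True, method=method)
        raw.append(float(res.pvalue))
    adjusted = multipletests(raw, alpha=alpha, method="holm")[1]
    table = pd.DataFrame(np.ones((n_edges, n_edges)), index=labels, columns=labels)
    for (i, j), p in zip(pairs, adjusted):
        table.iloc[i, j] = p
        table.iloc[j, i] = p
    return table


def lins_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 cov(x,y) / (var(x) + var(y) + (mean(x) - mean(y))^2), using
    n-denominator moments.  Penalises both scale and location departures
    from the identity line; |CCC| <= |Pearson r|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired vectors of length >= 2")
    vx, vy = x.var(), y.var()
    dm = x.mean() - y.mean()
    denom = vx + vy + dm**2
    if denom == 0:
        raise ValueError("both vectors constant with equal means: CCC undefined")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * cov / denom)


class TlsLine(NamedTuple):
    slope: float
    intercept: float
    vertical: bool  # data vary only in y: slope is infinite, axes should be flipped


def tls_fit(x: np.ndarray, y: np.ndarray) -> TlsLine:
    """Total-least-squares (orthogonal distance) line through the means.

    The line direction is the principal eigenvector of the centred 2x2
    covariance — appropriate when both variables carry error, as in
    method-agreement comparisons.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both variables")
    cov = np.cov(np.vstack([x, y]), bias=True)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] - evals[0] <= 1e-12 * np.trace(cov):
        raise ValueError("isotropic scatter: orthogonal line direction is ambiguous")
    v = evecs[:, np.argmax(evals)]
    if abs(v[0]) < 1e-12:
        return TlsLine(np.inf, np.nan, True)
    slope = float(v[1] / v[0])
    intercept = float(y.mean() - slope * x.mean())
    return TlsLine(slope, intercept, False)
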