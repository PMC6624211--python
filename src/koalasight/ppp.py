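"""Point-process inference against spatial covariates.

The statistical core of the pipeline.  Sighting locations are treated
as a realisation of an inhomogeneous Poisson point process whose
intensity may depend on a distance covariate Z(u):

* :func:`rhohat` — nonparametric ratio estimate of rho(z), the
  intensity as a function of covariate value, with pointwise 95%
  confidence bands;
* :func:`berman_test` — the Berman Z1 test of covariate dependence,
  comparing the sum of covariate values at events against its CSR
  null distribution;
* :func:`roc_auc` — discrimination of event locations by the
  covariate, as an area-ranked ROC curve and its AUC;
* :func:`fit_loglinear_ppm` — maximum-likelihood fit of the
  log-linear model lambda(u) = exp(alpha + beta Z(u)) via the
  Berman–Turner quadrature device and a weighted Poisson GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grid import PointPattern, Raster, StudyWindow

__all__ = [
    "RhoEstimate",
    "BermanTestResult",
    "RocCurve",
    "PpmFit",
    "rhohat",
    "berman_test",
    "roc_auc",
    "fit_loglinear_ppm",
    "intensity_multiplier",
]


def _window_covariate(
    raster: Raster, window: StudyWindow
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate values over window cells with clipped-area weights."""
    ref = StudyWindow(window.width_km, window.height_km, cellsize=raster.cellsize)
    areas = ref.cell_areas()
    ny = min(areas.shape[0], raster.ny)
    nx = min(areas.shape[1], raster.nx)
    vals = raster.values[:ny, :nx].ravel()
    w = areas[:ny, :nx].ravel()
    ok = np.isfinite(vals) & (w > 0)
    return vals[ok], w[ok]


# ---------------------------------------------------------------------------
# rhohat
# ---------------------------------------------------------------------------

@dataclass
class RhoEstimate:
    """Nonparametric intensity-vs-covariate estimate rho(z).

    ``rho`` is events per km² at covariate value z; ``lo``/``hi`` are
    pointwise 95% bands from the Poisson delta method on the ratio
    estimator.  ``g_density`` is the covariate's (area-weighted)
    density over the window, kept so that the mass-balance identity
    integral rho(z) g(z) |W| dz ≈ n can be checked.
    """

    z_grid: np.ndarray
    rho: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    baseline: float
    smoothing_bandwidth: float
    g_density: np.ndarray = field(repr=False, default=None)
    n: int = 0
    window_area: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"z": self.z_grid, "rho": self.rho, "lo": self.lo, "hi": self.hi}
        )


def _gauss_kernel(u: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * u * u) / np.sqrt(2.0 * np.pi)


def _window_covariate_refined(
    raster: Raster, window: StudyWindow, refine: int
) -> tuple[np.ndarray, np.ndarray]:
    """Covariate sampled on a refine-x finer subgrid, area-weighted.

    The estimators see the covariate through (bilinear) point
    sampling; the covariate's *distribution over the window* must
    describe that same interpolated surface, not the bare cell-centre
    values, which collapse onto a few discrete levels when features
    align with the cell lattice.
    """
    ref = StudyWindow(
        window.width_km, window.height_km, cellsize=raster.cellsize / refine
    )
    xx, yy = ref.cell_centers()
    vals = raster.sample(xx.ravel(), yy.ravel(), mode="bilinear")
    w = ref.cell_areas().ravel()
    ok = np.isfinite(vals) & (w > 0)
    return vals[ok], w[ok]


def rhohat(
    pattern: PointPattern,
    covariate: Raster,
    window: StudyWindow | None = None,
    n_grid: int = 512,
    bandwidth: float | None = None,
    sample_mode: str = "bilinear",
    conf_level: float = 0.95,
    g_refine: int = 4,
) -> RhoEstimate:
    """Ratio estimate of intensity as a function of a covariate.

    rho_hat(z) = baseline * f_hat(z) / g_hat(z), where f_hat is a
    Gaussian KDE of covariate values at the events, g_hat the
    (area-weighted) KDE of the covariate's values over the window,
    both with the same bandwidth (Scott's 1-D rule on the event values
    unless given), and baseline = n/|W|.  g_hat is evaluated on a
    ``g_refine``-times finer subgrid of the interpolated surface so
    numerator and denominator describe the same covariate.  The
    pointwise variance follows from treating the kernel-weighted event
    count at each z as Poisson:

        Var rho_hat(z) ~= sum_i K_h(z - Z_i)^2 / (|W| g_hat(z))^2.
    """
    window = window or pattern.window
    if pattern.n < 20:
        raise ValueError(
            f"rhohat needs at least 20 events for a meaningful band, got {pattern.n}"
        )
    z_events = covariate.sample(pattern.x, pattern.y, mode=sample_mode)
    if sample_mode == "bilinear":
        z_cells, w_cells = _window_covariate_refined(covariate, window, g_refine)
    else:
        z_cells, w_cells = _window_covariate(covariate, window)
    z_lo, z_hi = float(z_cells.min()), float(z_cells.max())
    if z_hi - z_lo <= 0:
        raise ValueError("covariate is constant over the window; rho(z) undefined")
    if bandwidth is None:
        sd = float(np.std(z_events, ddof=1))
        if sd == 0:
            sd = (z_hi - z_lo) / 10.0
        bandwidth = sd * pattern.n ** (-1.0 / 5.0)
    h = float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")

    zg = np.linspace(z_lo, z_hi, n_grid)

    def reflected_kernel(values: np.ndarray) -> np.ndarray:
        """K_h with reflection at both range boundaries.

        The covariate lives on [z_lo, z_hi]; without reflection both
        densities lose up to half their kernel mass at the edges and
        the mass-balance identity integral rho g |W| dz = n breaks.
        """
        k = _gauss_kernel((zg[:, None] - values[None, :]) / h)
        k += _gauss_kernel((zg[:, None] - (2 * z_lo - values)[None, :]) / h)
        k += _gauss_kernel((zg[:, None] - (2 * z_hi - values)[None, :]) / h)
        return k / h

    # K_h matrices: grid x events, and grid x (binned) window values;
    # window values are first binned finely so the cost stays
    # independent of the refinement factor (bin width << h)
    ke = reflected_kernel(z_events)
    n_bins = 4096
    bin_w, bin_edges = np.histogram(
        z_cells, bins=n_bins, range=(z_lo, z_hi), weights=w_cells
    )
    bin_mid = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    kc = reflected_kernel(bin_mid)
    g_hat = (kc * bin_w[None, :]).sum(axis=1) / w_cells.sum()
    g_hat = np.maximum(g_hat, 1e-300)
    area = window.area
    baseline = pattern.n / area
    numer = ke.sum(axis=1)  # sum_i K_h(z - Z_i)
    rho = numer / (area * g_hat)
    var = (ke**2).sum(axis=1) / (area * g_hat) ** 2
    zcrit = stats.norm.ppf(0.5 + conf_level / 2.0)
    sd_rho = np.sqrt(var)
    return RhoEstimate(
        z_grid=zg,
        rho=rho,
        lo=np.maximum(rho - zcrit * sd_rho, 0.0),
        hi=rho + zcrit * sd_rho,
        baseline=baseline,
        smoothing_bandwidth=h,
        g_density=g_hat,
        n=pattern.n,
        window_area=area,
    )


# ---------------------------------------------------------------------------
# Berman test
# ---------------------------------------------------------------------------

@dataclass
class BermanTestResult:
    statistic_z1: float
    p_value: float
    n: int
    covariate_mean: float
    covariate_var: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Berman Z1 = {self.statistic_z1:.3f}, two-sided p = {self.p_value:.4g} "
            f"(n = {self.n})"
        )


def berman_test(
    pattern: PointPattern,
    covariate: Raster,
    window: StudyWindow | None = None,
    sample_mode: str = "bilinear",
) -> BermanTestResult:
    """Berman Z1 test of dependence of event locations on a covariate.

    Under CSR the covariate values at events are an i.i.d. sample from
    the covariate's distribution over the window, so the standardised
    sum Z1 = (S - n mu) / sqrt(n sigma²) is asymptotically standard
    normal.  A negative Z1 means events sit at lower covariate values
    than the window average (for distance covariates: closer to the
    feature).  Two-sided p-value.
    """
    window = window or pattern.window
    if pattern.n < 1:
        raise ValueError("Berman test needs at least one event")
    z_cells, w_cells = _window_covariate(covariate, window)
    wsum = w_cells.sum()
    mu = float((z_cells * w_cells).sum() / wsum)
    var = float(((z_cells - mu) ** 2 * w_cells).sum() / wsum)
    if var <= 0:
        raise ValueError("covariate has zero variance over the window")
    z_events = covariate.sample(pattern.x, pattern.y, mode=sample_mode)
    s = float(z_events.sum())
    z1 = (s - pattern.n * mu) / np.sqrt(pattern.n * var)
    p = 2.0 * stats.norm.sf(abs(z1))
    return BermanTestResult(
        statistic_z1=float(z1),
        p_value=float(min(p, 1.0)),
        n=pattern.n,
        covariate_mean=mu,
        covariate_var=var,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    """Area-ranked ROC of a covariate against event locations."""

    thresholds: np.ndarray
    area_fraction: np.ndarray
    point_fraction: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "area_fraction": self.area_fraction,
                "point_fraction": self.point_fraction,
            }
        )


def _rank_auc(
    s_events: np.ndarray, s_cells: np.ndarray, w_cells: np.ndarray
) -> float:
    """AUC in its probability-integral form.

    AUC = P(S_event < S_cell) + 0.5 P(S_event = S_cell) with cell
    values weighted by area share — exactly the trapezoid area under
    the ROC built on the union of all thresholds, and exactly
    antisymmetric under orientation reversal.
    """
    order = np.argsort(s_events, kind="mergesort")
    se = s_events[order]
    n = se.size
    less = np.searchsorted(se, s_cells, side="left") / n
    leq = np.searchsorted(se, s_cells, side="right") / n
    frac = less + 0.5 * (leq - less)
    return float((frac * w_cells).sum() / w_cells.sum())


def roc_auc(
    pattern: PointPattern,
    covariate: Raster,
    window: StudyWindow | None = None,
    high_intensity_at: str = "low",
    sample_mode: str = "bilinear",
) -> RocCurve:
    """ROC curve of the covariate's ability to rank event locations.

    Thresholds sweep the covariate so that predicted-high-intensity
    area is accumulated first — ascending covariate values for
    ``high_intensity_at="low"`` (the natural orientation for distance
    covariates), descending for ``"high"``.  x is the cumulative area
    fraction inside the threshold, y the fraction of events captured;
    AUC = 0.5 means the covariate carries no information about where
    events fall, AUC near 1 strong discrimination.
    """
    window = window or pattern.window
    if pattern.n < 1:
        raise ValueError("ROC needs at least one event")
    if high_intensity_at not in {"low", "high"}:
        raise ValueError("high_intensity_at must be 'low' or 'high'")
    z_events = covariate.sample(pattern.x, pattern.y, mode=sample_mode)
    z_cells, w_cells = _window_covariate(covariate, window)
    sign = 1.0 if high_intensity_at == "low" else -1.0
    s_events = sign * z_events
    s_cells = sign * z_cells
    auc = _rank_auc(s_events, s_cells, w_cells)

    thresholds = np.unique(s_cells)
    order_c = np.argsort(s_cells, kind="mergesort")
    cum_area = np.cumsum(w_cells[order_c]) / w_cells.sum()
    idx = np.searchsorted(s_cells[order_c], thresholds, side="right") - 1
    area_frac = cum_area[idx]
    se_sorted = np.sort(s_events)
    point_frac = np.searchsorted(se_sorted, thresholds, side="right") / pattern.n
    return RocCurve(
        thresholds=sign * thresholds,
        area_fraction=np.concatenate([[0.0], area_frac]),
        point_fraction=np.concatenate([[0.0], point_frac]),
        auc=auc,
    )


# ---------------------------------------------------------------------------
# log-linear Poisson point-process model
# ---------------------------------------------------------------------------

@dataclass
class PpmFit:
    """Fitted log-linear inhomogeneous Poisson model.

    lambda(u) = exp(alpha + sum_k beta_k Z_k(u)); for the single
    covariate case ``multiplier_per_km = exp(beta)`` is the factor by
    which intensity changes per km of covariate, and
    ``percent_change_per_km = 100 (1 - exp(beta))`` the per-km percent
    decrease when beta < 0.
    """

    intercept_alpha: float
    slope_beta: np.ndarray
    se_alpha: float
    se_beta: np.ndarray
    covariate_names: list[str]
    loglik: float
    auc: float
    n: int
    n_dummy: int
    converged: bool

    @property
    def beta(self) -> float:
        return float(self.slope_beta[0])

    @property
    def multiplier_per_km(self) -> float:
        return float(np.exp(self.beta))

    @property
    def percent_change_per_km(self) -> float:
        return 100.0 * (1.0 - self.multiplier_per_km)

    def ci_beta(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return (self.beta - z * self.se_beta[0], self.beta + z * self.se_beta[0])

    def summary(self) -> dict:
        return {
            "alpha": self.intercept_alpha,
            "beta": [float(b) for b in self.slope_beta],
            "se_beta": [float(s) for s in self.se_beta],
            "multiplier_per_km": self.multiplier_per_km,
            "percent_change_per_km": self.percent_change_per_km,
            "loglik": self.loglik,
            "auc": self.auc,
            "n": self.n,
            "covariates": self.covariate_names,
        }


def fit_loglinear_ppm(
    pattern: PointPattern,
    covariates: Raster | list[Raster],
    window: StudyWindow | None = None,
    n_dummy: int = 80,
    sample_mode: str = "bilinear",
) -> PpmFit:
    """Maximum-likelihood fit of lambda(u) = exp(alpha + beta·Z(u)).

    Uses the Berman–Turner device: the Poisson point-process
    log-likelihood

        sum_i log lambda(x_i) - integral_W lambda(u) du

    is approximated on quadrature points (the data plus an
    ``n_dummy`` x ``n_dummy`` dummy grid) with counting weights
    w_j = (tile area)/(points in tile), which turns maximisation into
    a weighted Poisson GLM with log link on responses 1/w_j (data) and
    0 (dummy).  Standard errors come from the Fisher information of
    that GLM, which coincides with the point-process information.
    """
    window = window or pattern.window
    if pattern.n < 10:
        raise ValueError(f"ppm fit needs at least 10 events, got {pattern.n}")
    rasters = [covariates] if isinstance(covariates, Raster) else list(covariates)
    names = [r.feature_class or f"z{k}" for k, r in enumerate(rasters)]

    w_km, h_km = window.width_km, window.height_km
    dx, dy = w_km / n_dummy, h_km / n_dummy
    gx = (np.arange(n_dummy) + 0.5) * dx
    gy = (np.arange(n_dummy) + 0.5) * dy
    dxx, dyy = np.meshgrid(gx, gy)
    qx = np.concatenate([pattern.x, dxx.ravel()])
    qy = np.concatenate([pattern.y, dyy.ravel()])
    is_data = np.zeros(qx.size, dtype=bool)
    is_data[: pattern.n] = True

    # counting weights from the dummy-grid tessellation
    ix = np.clip((qx / dx).astype(int), 0, n_dummy - 1)
    iy = np.clip((qy / dy).astype(int), 0, n_dummy - 1)
    tile = iy * n_dummy + ix
    counts = np.bincount(tile, minlength=n_dummy * n_dummy)
    w = (dx * dy) / counts[tile]

    Z = np.column_stack(
        [r.sample(qx, qy, mode=sample_mode) for r in rasters]
    )
    if np.ptp(Z, axis=0).min() <= 0:
        raise ValueError("a covariate is constant over the quadrature points")
    X = sm.add_constant(Z, has_constant="add")
    y = np.where(is_data, 1.0 / w, 0.0)
    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    try:
        res = model.fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - separation diagnostics
        raise RuntimeError(
            f"ppm fit failed to converge: {exc}; n={pattern.n}, "
            f"n_dummy={n_dummy}, covariates={names}"
        ) from exc
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    alpha, beta = float(params[0]), params[1:]

    # point-process log-likelihood at the fit (quadrature approximation)
    eta = X @ params
    lam = np.exp(eta)
    loglik = float(eta[is_data].sum() - (w * lam).sum())

    # discriminant AUC of the fitted intensity surface
    base = rasters[0]
    eta_grid = np.full(base.values.shape, params[0])
    for r, b in zip(rasters, beta):
        eta_grid = eta_grid + b * r.values
    eta_raster = Raster(
        values=eta_grid, cellsize=base.cellsize, origin=base.origin,
        feature_class="fitted_log_intensity",
    )
    auc = roc_auc(
        pattern, eta_raster, window, high_intensity_at="high", sample_mode=sample_mode
    ).auc
    return PpmFit(
        intercept_alpha=alpha,
        slope_beta=np.asarray(beta, dtype=float),
        se_alpha=float(bse[0]),
        se_beta=np.asarray(bse[1:], dtype=float),
        covariate_names=names,
        loglik=loglik,
        auc=auc,
        n=pattern.n,
        n_dummy=n_dummy,
        converged=bool(getattr(res, "converged", True)),
    )


def intensity_multiplier(
    fit: PpmFit,
    delta_km: float = 1.0,
    sanity_bound: float = 50.0,
) -> tuple[float, float]:
    """Intensity multiplier over a covariate change of ``delta_km``.

    Returns (multiplier, percent_change) where percent_change is the
    percent *decrease* (positive when intensity falls with distance;
    a negative value means an increase).  A slope magnitude above
    ``sanity_bound`` per km almost certainly means the covariate was
    fitted in metres, and is rejected.
    """
    beta = fit.beta
    if abs(beta) > sanity_bound:
        raise ValueError(
            f"|beta| = {abs(beta):.3g} per km exceeds the sanity bound "
            f"{sanity_bound}; check covariate units (expected km)"
        )
    multiplier = float(np.exp(beta * delta_km))
    percent_change = 100.0 * (1.0 - multiplier)
    return multiplier, percent_change
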