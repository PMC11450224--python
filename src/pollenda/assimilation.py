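"""Season-total 4D-VAR inversion of the pollen release correction field.

The control variable is one unitless multiplier xi per grid cell and
year, applied to the climatological seasonal release N_tot.  It is
assimilated in log form zeta = ln(xi) (background zeta_b = 0, i.e.
xi_b = 1), which removes the positivity constraint.  The cost function
is the standard misfit-plus-background form

    J(zeta) = 1/2 (y - G xi)^T Phi^-1 (y - G xi)
            + 1/2 (zeta - zeta_b)^T B^-1 (zeta - zeta_b),

where G is the linear chain emission(xi) -> transport -> station
sampling -> 2-day binning, Phi is a scalar diagonal observation
covariance, and B = background_scale * C with C a Gaussian spatial
correlation over great-circle distance (length scale rho ~ 250 km).
Because the forward chain is exactly linear in xi, the gradient is one
adjoint transport sweep chained with d(xi)/d(zeta) = xi.

Regularization is by truncated iterations: a limited-memory
quasi-Newton descent is monitored with an L-curve (J_obs against J_bg
per iteration), a hyperbola is fitted to the accepted points, and the
iterations are cut where the fitted slope has dropped 20-fold (to 5% of
its initial value) — the over-fitting watchdog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_solve
from scipy.optimize import curve_fit, minimize, minimize_scalar

from .grid import GridSpec, haversine_km
from .observations import StationSeries
from .transport import LinearTransport

log = logging.getLogger(__name__)


@dataclass
class CovarianceConfig:
    """Observation / background error covariance settings.

    Only the ratio of the two magnitudes matters for the location of the
    cost minimum; both are exposed.  ``obs_variance`` is the diagonal of
    Phi in (grains m-3)^2-consistent units; ``background_scale`` is the
    multiplier of the spatial correlation matrix, B = scale * C.
    """

    rho_km: float = 250.0
    background_scale: float = 1000.0
    obs_variance: float = 6.0
    nugget: float = 1e-6

    def __post_init__(self) -> None:
        if self.rho_km <= 0 or self.background_scale <= 0 or self.obs_variance <= 0:
            raise ValueError("covariance scales must be positive")


@dataclass
class StopConfig:
    """Truncated-iteration watchdog settings."""

    max_iterations: int = 40
    slope_fraction: float = 0.05       # stop where L-curve slope <= 5% of initial
    cosine_threshold: float = 0.0      # exclude direction-reversing steps from the fit
    gtol: float = 1e-9


def background_correlation(lon1, lat1, lon2, lat2, rho_km: float):
    """Gaussian correlation exp(-d^2 / rho^2) over great-circle distance."""
    d = haversine_km(lon1, lat1, lon2, lat2)
    return np.exp(-((d / rho_km) ** 2))


def correlation_matrix(grid: GridSpec, rho_km: float, nugget: float = 1e-6) -> np.ndarray:
    """Dense cell-to-cell Gaussian correlation matrix with a small nugget
    on the diagonal (the Gaussian kernel is numerically rank-deficient
    when many cells sit within one correlation length)."""
    lon2d, lat2d = grid.mesh()
    lon = lon2d.ravel()
    lat = lat2d.ravel()
    c = background_correlation(lon[:, None], lat[:, None], lon[None, :], lat[None, :], rho_km)
    return c + nugget * np.eye(grid.n_cells)


class ObsOperator:
    """The linear map from the per-cell correction xi to the 2-day-binned
    model values at a station set, with the co-located observation vector.

    Holds the unit-xi emission field (the season run with xi = 1), the
    assembled transport, and a sparse matrix W mapping the stacked
    concentration history to the observation bins.  Bins use only days
    on which the observation is valid, so model and data are co-located
    in time by construction.
    """

    def __init__(
        self,
        transport: LinearTransport,
        unit_emission_rate: np.ndarray,
        stations: list[StationSeries],
        window: tuple[pd.Timestamp, pd.Timestamp],
    ):
        self.transport = transport
        self.grid = transport.grid
        self.e0 = unit_emission_rate
        self.window = window
        nt = len(transport.times)
        n = self.grid.n_cells
        day_of_step = transport.times.normalize()
        day_to_steps: dict[pd.Timestamp, list[int]] = {}
        for t, d in enumerate(day_of_step):
            day_to_steps.setdefault(d, []).append(t)

        rows, cols, vals = [], [], []
        y = []
        bin_station = []
        r = 0
        for st in stations:
            idx, wgt = self.grid.bilinear_weights(st.lon, st.lat)
            o = st.window(*window)
            if len(o.values) == 0:
                continue
            offset = (o.values.index - window[0]).days.to_numpy()
            ok = o.valid.to_numpy().astype(bool) & (offset >= 0)
            bins = offset // 2
            for b in np.unique(bins[ok]):
                sel_days = o.values.index[ok & (bins == b)]
                y.append(float(o.values[sel_days].mean()))
                for day in sel_days:
                    t_idx = day_to_steps.get(day, [])
                    if not t_idx:
                        continue
                    w_day = wgt / (len(sel_days) * len(t_idx))
                    for t in t_idx:
                        rows.extend([r] * len(idx))
                        cols.extend(t * n + idx)
                        vals.extend(w_day)
                bin_station.append(st.station_id)
                r += 1
        self.W = sp.csr_matrix((vals, (rows, cols)), shape=(r, nt * n))
        self.y = np.asarray(y)
        self.bin_station = np.asarray(bin_station)
        self.n_bins = r

    def apply(self, xi) -> np.ndarray:
        """Model values at the observation bins for correction field xi."""
        xi2d = np.broadcast_to(np.asarray(xi, float), self.grid.shape)
        conc = self.transport.forward(self.e0 * xi2d[None, :, :])
        return self.W @ conc.reshape(-1)

    def adjoint(self, w: np.ndarray) -> np.ndarray:
        """(d apply / d xi)^T w, shape (ny, nx)."""
        nt = len(self.transport.times)
        field = np.asarray(self.W.T @ w).reshape(nt, *self.grid.shape)
        sens = self.transport.adjoint(field)
        return (sens * self.e0).sum(axis=0)

    def matrix(self) -> np.ndarray:
        """Explicit source-receptor matrix A with apply(xi) = A xi.ravel();
        feasible on small grids only (one forward run per cell)."""
        n = self.grid.n_cells
        a = np.empty((self.n_bins, n))
        basis = np.zeros(n)
        for c in range(n):
            basis[:] = 0.0
            basis[c] = 1.0
            conc = self.transport.forward(self.e0 * basis.reshape(self.grid.shape)[None])
            a[:, c] = self.W @ conc.reshape(-1)
        return a

    def rmse(self, xi) -> float:
        return float(np.sqrt(np.mean((self.y - self.apply(xi)) ** 2)))


@dataclass
class LCurveDiagnostics:
    """Per-iteration deviation pairs and the fitted stopping point.

    Iteration 0 is the background state.
    """

    j_obs: np.ndarray
    j_bg: np.ndarray
    grad_norm: np.ndarray
    cosine: np.ndarray             # cos of angle between successive steps (nan at 0, 1)
    accepted: np.ndarray           # used for the hyperbola fit
    fit_params: tuple | None       # (a, b, c) of j_obs = a + b/(j_bg + c)
    initial_slope: float
    stop_index: int
    eval_rmse: np.ndarray | None = None


@dataclass
class AssimilationResult:
    xi: np.ndarray                 # (ny, nx), at the stopping iteration
    zeta: np.ndarray
    diagnostics: LCurveDiagnostics
    rmse_ratio_assim: float        # RMSE(stop) / RMSE(iter 0), assimilation stations
    rmse_ratio_eval: float | None  # same for evaluation stations
    xi_final: np.ndarray | None = None   # at the last iteration (no truncation)
    zeta_path: list | None = None        # per-iteration flattened control states


def cost_and_gradient(
    zeta: np.ndarray,
    op: ObsOperator,
    cov: CovarianceConfig,
    chol_L: np.ndarray,
) -> tuple[float, np.ndarray, float, float]:
    """J, dJ/dzeta, and the two cost terms, for a flattened zeta.

    ``chol_L`` is the lower Cholesky factor of the background correlation
    matrix.  The observation-term gradient is one adjoint transport sweep
    chained with d(xi)/d(zeta) = xi; missing observation bins simply do
    not appear in the residual.
    """
    with np.errstate(over="raise"):
        try:
            xi = np.exp(zeta)
        except FloatingPointError:
            bad = np.nonzero(zeta > 700)[0]
            raise FloatingPointError(f"exp overflow in control variable at cells {bad[:10]}")
    resid = op.y - op.apply(xi.reshape(op.grid.shape))
    j_obs = 0.5 * float(resid @ resid) / cov.obs_variance
    g_obs_xi = -op.adjoint(resid / cov.obs_variance).ravel()
    binv_z = cho_solve((chol_L, True), zeta) / cov.background_scale
    j_bg = 0.5 * float(zeta @ binv_z)
    grad = g_obs_xi * xi + binv_z
    j = j_obs + j_bg
    if not np.isfinite(j):
        raise FloatingPointError("non-finite cost function")
    return j, grad, j_obs, j_bg


def fit_lcurve(
    j_bg: np.ndarray, j_obs: np.ndarray, slope_fraction: float = 0.05
) -> tuple[tuple | None, float, int]:
    """Least-squares hyperbola fit to accepted (J_bg, J_obs) points.

    Returns (params, initial_slope, stop_position) where stop_position
    indexes the input arrays: the point nearest (in J_bg) to where the
    fitted slope falls to ``slope_fraction`` of its value at the first
    point.  With fewer than 3 points, returns the last index with a
    warning.
    """
    j_bg = np.asarray(j_bg, float)
    j_obs = np.asarray(j_obs, float)
    if len(j_bg) < 3:
        log.warning("fewer than 3 L-curve points; stopping at the last iteration")
        return None, np.nan, len(j_bg) - 1

    def hyperbola(x, a, b, c):
        return a + b / (x + c)

    x0 = j_bg[0]
    span = max(j_bg[-1] - j_bg[0], 1e-12 * max(j_bg[-1], 1.0), 1e-300)
    p0 = (max(j_obs[-1], 1e-12), (j_obs[0] - j_obs[-1]) * span, span)
    try:
        params, _ = curve_fit(
            hyperbola,
            j_bg,
            j_obs,
            p0=p0,
            bounds=([0.0, 1e-300, 1e-300], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except Exception:
        log.warning("L-curve fit failed; stopping at the last iteration")
        return None, np.nan, len(j_bg) - 1
    a, b, c = params
    # initial slope of the L-curve: the observed descent rate over the first
    # accepted step (the fitted slope evaluated *at* the background point is
    # numerically fragile because the background sits at J_bg = 0)
    slope0 = (j_obs[1] - j_obs[0]) / max(j_bg[1] - j_bg[0], 1e-300)
    # fitted slope magnitude decays as b/(x+c)^2; find where it reaches
    # slope_fraction of the initial slope
    target = slope_fraction * abs(slope0)
    x_stop = np.sqrt(b / target) - c
    stop = int(np.argmin(np.abs(j_bg - x_stop)))
    return (a, b, c), float(slope0), stop


def background_cholesky(grid: GridSpec, cov: CovarianceConfig) -> np.ndarray:
    """Lower Cholesky factor L of the background correlation matrix,
    C = L L^T; also usable with ``cho_solve((L, True), .)``."""
    return np.linalg.cholesky(correlation_matrix(grid, cov.rho_km, cov.nugget))


def minimize_truncated(
    op: ObsOperator,
    cov: CovarianceConfig,
    stop: StopConfig | None = None,
    eval_op: ObsOperator | None = None,
    chol_L: np.ndarray | None = None,
) -> AssimilationResult:
    """Quasi-Newton minimization from the background with L-curve
    truncation; returns xi at the stopping iteration.

    The descent runs in the preconditioned variable w with
    zeta = sqrt(scale) * L w (so the prior term is 1/2 ||w||^2): with an
    identity prior Hessian the quasi-Newton iterations reduce the
    well-constrained large-scale directions first, which is the regime
    the truncated-iteration watchdog is designed for.
    """
    stop = stop or StopConfig()
    grid = op.grid
    n = grid.n_cells
    if op.n_bins == 0 or not np.any(op.e0 > 0):
        xi1 = np.ones(grid.shape)
        diag = LCurveDiagnostics(
            j_obs=np.zeros(1), j_bg=np.zeros(1), grad_norm=np.zeros(1),
            cosine=np.full(1, np.nan), accepted=np.zeros(1, bool),
            fit_params=None, initial_slope=np.nan, stop_index=0,
        )
        return AssimilationResult(xi1, np.zeros(grid.shape), diag, 1.0, None, xi1)
    L = chol_L if chol_L is not None else background_cholesky(grid, cov)
    sb = np.sqrt(cov.background_scale)

    w_iterates = [np.zeros(n)]

    def fun(w):
        zeta = sb * (L @ w)
        with np.errstate(over="raise"):
            try:
                xi = np.exp(zeta)
            except FloatingPointError:
                raise FloatingPointError("exp overflow in control variable")
        resid = op.y - op.apply(xi.reshape(grid.shape))
        jo = 0.5 * float(resid @ resid) / cov.obs_variance
        g_obs_zeta = -op.adjoint(resid / cov.obs_variance).ravel() * xi
        jb = 0.5 * float(w @ w)
        grad = sb * (L.T @ g_obs_zeta) + w
        return jo + jb, grad

    minimize(
        fun,
        np.zeros(n),
        jac=True,
        method="L-BFGS-B",
        callback=lambda w: w_iterates.append(w.copy()),
        options={"maxiter": stop.max_iterations, "gtol": stop.gtol, "ftol": 1e-14},
    )
    iterates = [sb * (L @ w) for w in w_iterates]

    n_it = len(iterates)
    j_obs = np.empty(n_it)
    j_bg = np.empty(n_it)
    gnorm = np.empty(n_it)
    eval_rmse = np.empty(n_it) if eval_op is not None else None
    for k, w in enumerate(w_iterates):
        j, g = fun(w)
        j_bg[k] = 0.5 * float(w @ w)
        j_obs[k] = j - j_bg[k]
        gnorm[k] = np.linalg.norm(g)
        if eval_op is not None:
            eval_rmse[k] = eval_op.rmse(np.exp(iterates[k]).reshape(grid.shape))

    # step-direction cosine between successive iteration steps
    cosine = np.full(n_it, np.nan)
    steps = [iterates[k + 1] - iterates[k] for k in range(n_it - 1)]
    for k in range(1, len(steps)):
        na, nb = np.linalg.norm(steps[k - 1]), np.linalg.norm(steps[k])
        if na > 0 and nb > 0:
            cosine[k + 1] = float(steps[k - 1] @ steps[k]) / (na * nb)

    # accepted L-curve points: optimizer-stable steps (no direction
    # reversal) that still reduce the observation misfit
    accepted = np.zeros(n_it, bool)
    last_jo = np.inf
    for k in range(n_it):
        if k >= 2 and not (np.isnan(cosine[k]) or cosine[k] >= stop.cosine_threshold):
            continue
        if j_obs[k] < last_jo:
            accepted[k] = True
            last_jo = j_obs[k]

    acc_idx = np.nonzero(accepted)[0]
    fit_params, slope0, pos = fit_lcurve(
        j_bg[acc_idx], j_obs[acc_idx], stop.slope_fraction
    )
    stop_index = int(acc_idx[pos]) if len(acc_idx) else 0

    diag = LCurveDiagnostics(
        j_obs=j_obs, j_bg=j_bg, grad_norm=gnorm, cosine=cosine, accepted=accepted,
        fit_params=fit_params, initial_slope=slope0, stop_index=stop_index,
        eval_rmse=eval_rmse,
    )
    z_stop = iterates[stop_index]
    xi_stop = np.exp(z_stop).reshape(grid.shape)
    xi_last = np.exp(iterates[-1]).reshape(grid.shape)
    rmse0 = op.rmse(np.ones(grid.shape))
    ratio_assim = op.rmse(xi_stop) / rmse0 if rmse0 > 0 else 1.0
    ratio_eval = None
    if eval_op is not None and eval_rmse is not None and eval_rmse[0] > 0:
        ratio_eval = float(eval_rmse[stop_index] / eval_rmse[0])
    return AssimilationResult(
        xi=xi_stop,
        zeta=z_stop.reshape(grid.shape),
        diagnostics=diag,
        rmse_ratio_assim=float(ratio_assim),
        rmse_ratio_eval=ratio_eval,
        xi_final=xi_last,
        zeta_path=iterates,
    )


def xi_opt_closed_form(y_bar: float, z_bar: float, mu_nu_bar: float, mu_sq_bar: float) -> float:
    """Analytic single-station optimum of the simplified scalar problem.

    For observations y = y_bar (1 + nu) and unit-correction model
    z = z_bar (1 + mu) with zero-mean normalized anomalies, the scalar
    correction minimizing the season RMSE is
    (y_bar / z_bar) * (1 + mean(mu*nu)) / (1 + mean(mu^2)): perfectly
    correlated anomalies give the pure ratio of means, decorrelation
    biases the optimum low.
    """
    if z_bar == 0:
        raise ValueError("z_bar must be non-zero")
    return (y_bar / z_bar) * (1.0 + mu_nu_bar) / (1.0 + mu_sq_bar)


def scalar_station_assimilate(
    y: np.ndarray, z: np.ndarray, obs_variance: float = 1.0, background_variance: float = 1e8
) -> float:
    """Single-station, scalar-xi assimilation through the log-transformed
    machinery: minimize 1/2 sum((y - xi z)^2)/Phi + 1/2 zeta^2/B over
    zeta = ln(xi).  A weak background makes this the empirical twin of
    :func:`xi_opt_closed_form`."""
    y = np.asarray(y, float)
    z = np.asarray(z, float)

    def j(zeta):
        xi = np.exp(zeta)
        r = y - xi * z
        return 0.5 * float(r @ r) / obs_variance + 0.5 * zeta**2 / background_variance

    res = minimize_scalar(j, bounds=(-10.0, 10.0), method="bounded",
                          options={"xatol": 1e-12})
    return float(np.exp(res.x))
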