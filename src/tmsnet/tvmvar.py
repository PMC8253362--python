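"""Time-varying multivariate adaptive autoregressive (tv-MVAAR) estimation.

The model is X(t) = Σ_{i=1}^{p} A(i,t) X(t−i) + E(t) with E(t) multivariate
white noise.  The model order p is selected on a stationary least-squares fit
by the Akaike information criterion AIC(p) = ln det(χ) + 2 M² p / N (M
channels, N pooled time points, χ the innovation covariance); the coefficient
trajectory A(i,t) is then estimated recursively by a Kalman filter with a
random-walk state model.

Implementation of the filter: because every target channel regresses on the
same lagged-regressor vector φ(t) ∈ R^{Mp}, the state is kept as the Mp × M
coefficient matrix with a single shared Mp × Mp state covariance P.  Process
noise is the fixed random-walk term uc · I per step, so the update constant
uc directly trades smoothness against adaptation speed; measurement noise is
a fixed scalar estimated from the data variance.  In ensemble mode all trials enter each time step as
simultaneous observations, which is the default — single-trial trajectories
on short epochs are hopelessly noisy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import EpochSet

__all__ = [
    "ModelOrderSelection",
    "TVMVARFit",
    "aic",
    "least_squares_var",
    "select_order",
    "fit_kalman",
]


def aic(det_chi: float, m: int, p: int, n: int) -> float:
    """AIC(p) = ln det(χ) + 2 M² p / N."""
    return float(np.log(det_chi) + 2.0 * m * m * p / n)


@dataclass
class ModelOrderSelection:
    """AIC values over the candidate order range and the chosen argmin."""

    orders: np.ndarray
    aic_values: np.ndarray
    chosen: int
    n_channels: int
    n_obs: int
    innovation_cov: dict[int, np.ndarray] = field(default_factory=dict)


@dataclass
class TVMVARFit:
    """Fitted time-varying VAR coefficient trajectory.

    ``coeffs[t, i, target, source]`` is the lag-(i+1) coefficient at time
    index t; ``sigma[t]`` the time-resolved innovation covariance.  The first
    ``order`` time points are filter warm-up and excluded from downstream
    statistics.
    """

    coeffs: np.ndarray  # (n_times, p, M, M)
    sigma: np.ndarray  # (n_times, M, M)
    order: int
    uc: float
    fs: float
    ensemble: bool

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[0]

    @property
    def warmup(self) -> int:
        return self.order


def _as_trials(data: np.ndarray | EpochSet) -> tuple[np.ndarray, float]:
    if isinstance(data, EpochSet):
        return data.data, data.fs
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("data must be (trials, channels, time) or (channels, time)")
    return arr, float("nan")


def _pooled_design(x: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design over pooled trials; rows never straddle a trial boundary."""
    n_trials, m, t = x.shape
    if t <= p:
        raise ValueError(f"epoch length {t} must exceed order {p}")
    blocks_x, blocks_y = [], []
    for k in range(n_trials):
        xi = x[k]
        cols = [xi[:, p - i: t - i].T for i in range(1, p + 1)]  # (t-p, M) each
        blocks_x.append(np.concatenate(cols, axis=1))
        blocks_y.append(xi[:, p:].T)
    return np.concatenate(blocks_x), np.concatenate(blocks_y)


def least_squares_var(data: np.ndarray | EpochSet, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stationary VAR(p) fit by pooled least squares.

    Returns ``(coeffs, chi)`` with ``coeffs`` of shape (p, M, M) such that
    X(t) ≈ Σ_i coeffs[i-1] X(t−i), and ``chi`` the innovation covariance.
    """
    x, _ = _as_trials(data)
    m = x.shape[1]
    phi, y = _pooled_design(x, p)
    rank = np.linalg.matrix_rank(phi)
    if rank < phi.shape[1]:
        raise ValueError(
            f"rank-deficient regression (rank {rank} < {phi.shape[1]}); "
            "check for constant or duplicated channels"
        )
    b, *_ = np.linalg.lstsq(phi, y, rcond=None)
    resid = y - phi @ b
    chi = resid.T @ resid / resid.shape[0]
    coeffs = b.reshape(p, m, m).transpose(0, 2, 1)  # b rows: lag-major regressors
    return coeffs, chi


def select_order(
    data: np.ndarray | EpochSet,
    p_min: int = 2,
    p_max: int = 20,
) -> ModelOrderSelection:
    """Choose the VAR order by AIC on a stationary pooled least-squares fit.

    Candidates are the full integer range [p_min, p_max]; ties break toward
    the smaller order.  N in the penalty term is the number of pooled
    regression rows at each candidate order.
    """
    x, _ = _as_trials(data)
    n_trials, m, t = x.shape
    if t <= p_max:
        raise ValueError(f"epoch length {t} must exceed p_max={p_max}")
    if (t - p_max) * n_trials <= p_max * m:
        import warnings

        warnings.warn(
            "few observations relative to p_max*channels; AIC may be unreliable",
            stacklevel=2,
        )
    orders = np.arange(p_min, p_max + 1)
    values = np.empty(orders.size)
    covs: dict[int, np.ndarray] = {}
    for k, p in enumerate(orders):
        _, chi = least_squares_var(x, int(p))
        n_obs = (t - p) * n_trials
        sign, logdet = np.linalg.slogdet(chi)
        det = sign * np.exp(logdet) if sign > 0 else np.finfo(float).tiny
        values[k] = aic(det, m, int(p), n_obs)
        covs[int(p)] = chi
    chosen = int(orders[int(np.argmin(values))])  # argmin takes the first = smallest p
    return ModelOrderSelection(
        orders=orders, aic_values=values, chosen=chosen,
        n_channels=m, n_obs=(t - chosen) * n_trials, innovation_cov=covs,
    )


def fit_kalman(
    data: np.ndarray | EpochSet,
    p: int,
    uc: float = 1e-3,
    ensemble: bool = True,
    fs: float | None = None,
    init_cov: float = 0.01,
) -> TVMVARFit:
    """Estimate the tv-MVAAR coefficient trajectory by Kalman filtering.

    Parameters
    ----------
    data : EpochSet or array (trials, channels, time)
        Input epochs; in ensemble mode (default) all trials update the shared
        state at every time step, otherwise trials are averaged fits.
    p : int
        Model order (lags).
    uc : float
        Update constant in (0, 1): the random-walk process-noise variance
        added per step.
    init_cov : float
        Initial state covariance scale.  The default 0.01 encodes a
        shrinkage prior (coefficients a priori small, std 0.1), which
        suppresses the large first-update transient a diffuse prior causes.
    """
    x, data_fs = _as_trials(data)
    if fs is None:
        fs = data_fs
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in input")
    if p < 1:
        raise ValueError("order p must be >= 1")
    if not 0.0 < uc < 1.0:
        raise ValueError("uc must lie in (0, 1)")
    n_trials, m, t = x.shape
    if t <= p:
        raise ValueError(f"epoch length {t} must exceed order {p}")
    if not ensemble and n_trials > 1:
        fits = [
            fit_kalman(x[k:k + 1], p, uc, ensemble=True, fs=fs, init_cov=init_cov)
            for k in range(n_trials)
        ]
        coeffs = np.mean([f.coeffs for f in fits], axis=0)
        sigma = np.mean([f.sigma for f in fits], axis=0)
        return TVMVARFit(coeffs, sigma, p, uc, fs, ensemble=False)

    d = m * p
    state = np.zeros((d, m))  # regressor-weight matrix, shared across targets
    pcov = init_cov * np.eye(d)
    r = float(np.mean(np.var(x, axis=2)))  # fixed scalar measurement noise
    if r <= 0:
        r = 1.0
    coeffs = np.zeros((t, p, m, m))
    sigma = np.zeros((t, m, m))
    sigma[:p] = r * np.eye(m)
    for tt in range(p, t):
        # regressors per trial: [x(t-1); ...; x(t-p)] flattened lag-major
        phi = np.concatenate([x[:, :, tt - i] for i in range(1, p + 1)], axis=1)
        y = x[:, :, tt]
        innov = y - phi @ state
        sigma[tt] = innov.T @ innov / n_trials
        s = phi @ pcov @ phi.T + r * np.eye(n_trials)
        try:
            gain = pcov @ phi.T @ np.linalg.inv(s)
        except np.linalg.LinAlgError:
            raise ValueError(f"innovation covariance collapse at time index {tt}") from None
        state = state + gain @ innov
        pcov = pcov - gain @ phi @ pcov
        pcov = 0.5 * (pcov + pcov.T)
        if not np.isfinite(pcov).all() or np.trace(pcov) < 0:
            raise ValueError(f"state covariance collapse at time index {tt}")
        pcov += uc * np.eye(d)
        # state rows are lag-major source blocks; column = target channel
        coeffs[tt] = state.reshape(p, m, m).transpose(0, 2, 1)
    coeffs[:p] = coeffs[p]
    return TVMVARFit(coeffs, sigma, p, uc, fs, ensemble=True)
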