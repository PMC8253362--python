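"""Adaptive directed transfer function (ADTF) from a tv-MVAAR fit.

The fitted model X(t) = Σ_i A(i,t) X(t−i) + E(t) is moved to the frequency
domain via A(f,t) = Σ_{k=0}^{p} A_k(t) e^{−j2πfk/fs} with A_0 = +I and
A_k = −(fitted lag-k coefficients) — the only sign assignment under which
A(f,t)X(f,t) = E(f,t) matches the time-domain regression.  The transfer
matrix is H(f,t) = A(f,t)^{-1}; the normalized ADTF

    γ²_ij(f,t) = |H_ij(f,t)|² / Σ_m |H_im(f,t)|²

describes the directed flow from node j to node i, row-normalized so that
Σ_j γ²_ij(f,t) = 1.  Band integration averages γ² over in-band frequency grid
points, keeping Q²_ij(t) ∈ [0, 1]; the normalized total outflow of node j is
Q²_j(t) = Σ_{k≠j} Q²_kj(t) / (n−1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tvmvar import TVMVARFit, least_squares_var

__all__ = [
    "SpectralTransfer",
    "ADTFResult",
    "default_freq_grid",
    "spectral_transfer",
    "normalized_adtf",
    "integrate_band",
    "total_outflow",
    "adtf_from_fit",
    "classical_dtf",
]

#: analysis band of interest (Hz)
DEFAULT_BAND = (0.5, 14.5)


def default_freq_grid(band: tuple[float, float] = DEFAULT_BAND, step: float = 0.5) -> np.ndarray:
    """Frequency grid covering ``band`` inclusive, in ``step`` Hz increments."""
    f1, f2 = band
    n = int(round((f2 - f1) / step)) + 1
    return f1 + step * np.arange(n)


@dataclass
class SpectralTransfer:
    """Frequency-domain coefficient matrix A(f,t) and transfer matrix H(f,t).

    ``missing`` flags (freq, time) cells where A(f,t) was singular; H is NaN
    there and every consumer must honor the flag.
    """

    freqs: np.ndarray
    a: np.ndarray  # (F, T, n, n) complex
    h: np.ndarray  # (F, T, n, n) complex
    missing: np.ndarray  # (F, T) bool
    fs: float


@dataclass
class ADTFResult:
    """Normalized γ²(f,t), band-integrated Q²_ij(t), and node outflow Q²_j(t)."""

    gamma2: np.ndarray  # (F, T, n, n)
    q2: np.ndarray  # (T, n, n)
    outflow: np.ndarray  # (T, n)
    freqs: np.ndarray
    band: tuple[float, float]
    n_nodes: int
    warmup: int = 0


def spectral_transfer(fit: TVMVARFit, freqs: np.ndarray | None = None) -> SpectralTransfer:
    """Assemble A(f,t) and H(f,t) = A(f,t)^{-1} on a frequency grid.

    Lag k enters as e^{−j2πfk/fs} (k in samples of the fitted rate).  Cells
    with singular A(f,t) are flagged missing and set NaN in H rather than
    pseudo-inverted, so silent distortion is impossible.
    """
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    fs = fit.fs
    if not np.isfinite(fs) or fs <= 0:
        raise ValueError("fit carries no valid sampling rate")
    if np.any(freqs <= 0) or np.any(freqs > fs / 2):
        raise ValueError("frequencies must lie in (0, fs/2]")
    if not np.isfinite(fit.coeffs).all():
        raise ValueError("non-finite coefficients in fit")
    p = fit.order
    m = fit.n_channels
    t = fit.n_times
    f = freqs.size
    # phase factors e^{-j 2 pi f k / fs}, k = 1..p
    k = np.arange(1, p + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * k[None, :] / fs)  # (F, p)
    a = np.tile(np.eye(m, dtype=complex), (f, t, 1, 1))
    # A(f,t) = I - sum_k coeffs[t,k] * phase[f,k]
    a -= np.einsum("fk,tkij->ftij", phase, fit.coeffs.astype(complex))
    h = np.full_like(a, np.nan + 0j)
    missing = np.zeros((f, t), dtype=bool)
    try:
        h = np.linalg.inv(a)
    except np.linalg.LinAlgError:
        for fi in range(f):
            for ti in range(t):
                try:
                    h[fi, ti] = np.linalg.inv(a[fi, ti])
                except np.linalg.LinAlgError:
                    missing[fi, ti] = True
    bad = ~np.isfinite(h).all(axis=(2, 3))
    missing |= bad
    h[missing] = np.nan
    return SpectralTransfer(freqs=freqs, a=a, h=h, missing=missing, fs=fs)


def normalized_adtf(st: SpectralTransfer) -> np.ndarray:
    """Row-normalized ADTF γ²_ij(f,t) = |H_ij|² / Σ_m |H_im|².

    Rows with zero denominator, and missing (f,t) cells, are NaN.
    """
    if st.missing.all():
        raise ValueError("all (f,t) cells are missing; nothing to normalize")
    power = np.abs(st.h) ** 2  # (F, T, i, m)
    denom = power.sum(axis=3, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma2 = power / denom
    gamma2[np.broadcast_to(denom == 0, gamma2.shape)] = np.nan
    return gamma2


def integrate_band(
    gamma2: np.ndarray,
    freqs: np.ndarray,
    band: tuple[float, float] = DEFAULT_BAND,
    convention: str = "mean",
) -> np.ndarray:
    """Integrate γ² over the band of interest: Q²_ij(t).

    ``convention="mean"`` (default) averages over in-band grid points, keeping
    Q² ∈ [0, 1].  ``convention="printed"`` divides the in-band sum by
    (f2 − f1) in Hz instead — not bin-count normalized, can exceed 1, provided
    for comparability only.
    """
    freqs = np.asarray(freqs, dtype=float)
    f1, f2 = band
    sel = (freqs >= f1) & (freqs <= f2)
    if not sel.any():
        raise ValueError(f"band [{f1:g}, {f2:g}] Hz contains no grid points")
    g = gamma2[sel]
    if convention == "mean":
        return np.nanmean(g, axis=0)
    if convention == "printed":
        if f2 <= f1:
            raise ValueError("printed convention needs f2 > f1")
        return np.nansum(g, axis=0) / (f2 - f1)
    raise ValueError(f"unknown convention {convention!r}")


def total_outflow(q2: np.ndarray) -> np.ndarray:
    """Normalized total information outflow Q²_j(t) = Σ_{k≠j} Q²_kj(t)/(n−1)."""
    n = q2.shape[-1]
    if n < 2:
        raise ValueError("outflow needs at least 2 nodes")
    if q2.shape[-2] != n:
        raise ValueError("q2 must be (..., n, n)")
    off = q2.copy()
    idx = np.arange(n)
    off[..., idx, idx] = 0.0
    return off.sum(axis=-2) / (n - 1)


def adtf_from_fit(
    fit: TVMVARFit,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
    convention: str = "mean",
) -> ADTFResult:
    """Full chain fit → H(f,t) → γ² → Q²_ij(t) → outflow Q²_j(t)."""
    if freqs is None:
        freqs = default_freq_grid(band)
    st = spectral_transfer(fit, freqs)
    gamma2 = normalized_adtf(st)
    q2 = integrate_band(gamma2, st.freqs, band, convention)
    out = total_outflow(q2)
    return ADTFResult(
        gamma2=gamma2, q2=q2, outflow=out, freqs=st.freqs, band=band,
        n_nodes=fit.n_channels, warmup=fit.warmup,
    )


def classical_dtf(
    data: np.ndarray,
    p: int,
    fs: float,
    freqs: np.ndarray | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> np.ndarray:
    """Classical (stationary) directed transfer function from an LS VAR fit.

    Returns the band-integrated Q²_ij from a single least-squares fit — the
    stationary limit against which the time-averaged ADTF is validated.
    """
    coeffs, _ = least_squares_var(data, p)
    fit = TVMVARFit(
        coeffs=coeffs[None].repeat(1, axis=0), sigma=np.zeros((1, coeffs.shape[1], coeffs.shape[1])),
        order=p, uc=0.5, fs=fs, ensemble=True,
    )
    res = adtf_from_fit(fit, freqs, band)
    return res.q2[0]
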