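"""Per-pixel biexponential TCSPC decay fitting.

Every sufficiently bright pixel's photon-arrival histogram is fitted with

    f(t) = a1·exp(-t/τ1) + a2·exp(-t/τ2)

convolved with the (normalized) instrument response function, with a fixed
time shift and bounded lifetimes.  Pixels whose maximum bin falls below an
intensity threshold are excluded, mirroring how TCSPC software discards
dim pixels.  Two estimators are provided: a Poisson maximum-likelihood fit
(the default — photon counts are Poisson) and a weighted least-squares fit
with variable-projection amplitudes, used as an internal cross-check.

The amplitude-weighted mean lifetime is

    τm = (a1·τ1 + a2·τ2) / (a1 + a2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize

from .phantom import TCSPCCube

__all__ = [
    "FitConfig",
    "FitMaps",
    "PixelFit",
    "FIT_OK",
    "FIT_BELOW_THRESHOLD",
    "FIT_FAILED",
    "model_decay",
    "fit_pixel",
    "fit_image",
    "mean_lifetime",
]

logger = logging.getLogger(__name__)

FIT_OK = 0
FIT_BELOW_THRESHOLD = 1
FIT_FAILED = 2


@dataclass
class FitConfig:
    """Fitting options.

    ``threshold_counts`` is the minimum count in the histogram's maximum
    bin for a pixel to be fitted (200 by default; raise it for dim,
    plasma-like samples).  ``shift`` is a *fixed* IRF time shift in ps —
    it is never fitted.  Lifetime bounds are in ps.
    """

    threshold_counts: float = 200.0
    shift: float = 0.0
    estimator: str = "poisson_mle"  # or "weighted_ls"
    tau_bounds: tuple[float, float] = (20.0, 10_000.0)
    max_iterations: int = 200
    tolerance: float = 1e-9

    def validate(self) -> None:
        if self.threshold_counts < 0:
            raise ValueError("threshold_counts must be >= 0")
        lo, hi = self.tau_bounds
        if not (0 < lo < hi):
            raise ValueError("tau_bounds must satisfy 0 < lo < hi")
        if self.estimator not in ("poisson_mle", "weighted_ls"):
            raise ValueError("estimator must be 'poisson_mle' or 'weighted_ls'")


class PixelFit(NamedTuple):
    tau1: float
    tau2: float
    a1: float
    a2: float
    chi2: float
    status: int  # FIT_OK / FIT_BELOW_THRESHOLD / FIT_FAILED


@dataclass
class FitMaps:
    """Per-pixel decay-fit results.

    All images share the cube's spatial shape; invalid pixels are NaN.
    On valid pixels τ1 ≤ τ2 (components are sorted), τm lies in
    [τ1, τ2], and a1_pct = 100·a1/(a1+a2) lies in [0, 100].
    """

    tau1: np.ndarray
    tau2: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a1_pct: np.ndarray
    amp_ratio: np.ndarray
    tau_m: np.ndarray
    chi2: np.ndarray
    valid: np.ndarray
    status: np.ndarray = field(default=None)


# ---------------------------------------------------------------------------
# forward model


def _kernel(irf: np.ndarray) -> tuple[np.ndarray, int]:
    """Trim the normalized IRF to its support; return (kernel, offset)."""
    irf = np.asarray(irf, float)
    if irf.ndim != 1:
        raise ValueError("irf must be 1-D")
    total = irf.sum()
    if total <= 0 or (irf < 0).any():
        raise ValueError("IRF must be non-negative with positive sum")
    irf = irf / total
    nz = np.nonzero(irf > 1e-12 * irf.max())[0]
    s, e = int(nz[0]), int(nz[-1]) + 1
    return irf[s:e], s


def _convolve(decay: np.ndarray, kernel: np.ndarray, offset: int) -> np.ndarray:
    n = decay.size
    full = np.convolve(decay, kernel)
    out = np.zeros(n)
    out[offset:] = full[: n - offset]
    return out


def _shift_irf(irf: np.ndarray, t: np.ndarray, shift: float) -> np.ndarray:
    """Shift the IRF along the time axis by ``shift`` ps (linear interp)."""
    if shift == 0.0:
        return irf
    return np.interp(t - shift, t, irf, left=0.0, right=0.0)


def model_decay(
    tau1: float,
    tau2: float,
    a1: float,
    a2: float,
    irf: np.ndarray,
    bin_axis: np.ndarray,
    shift: float = 0.0,
) -> np.ndarray:
    """Expected histogram: biexponential ⊛ normalized IRF at bin centers.

    ``bin_axis`` holds the bin-center times (ps).  The IRF is normalized
    to unit sum and optionally shifted by the fixed ``shift``.
    """
    if tau1 <= 0 or tau2 <= 0:
        raise ValueError("lifetimes must be positive")
    t = np.asarray(bin_axis, float)
    kernel, offset = _kernel(_shift_irf(np.asarray(irf, float), t, shift))
    decay = a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)
    return _convolve(decay, kernel, offset)


# ---------------------------------------------------------------------------
# initialization (seed-free): two-segment log-linear fit


def _loglin_tau(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Lifetime and amplitude from a log-linear fit; (nan, nan) if hopeless."""
    pos = y > 0
    if pos.sum() < 3:
        return np.nan, np.nan
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    if slope >= 0:
        return np.nan, np.nan
    return -1.0 / slope, float(np.exp(intercept))


def _initial_guess(
    y: np.ndarray, t: np.ndarray, tau_bounds: tuple[float, float]
) -> tuple[float, float, float, float]:
    lo, hi = tau_bounds
    n = y.size
    peak = int(np.argmax(y))
    # Smooth lightly to stabilise the log fits on noisy tails.
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same")

    tail_start = peak + max((n - peak) // 3, 4)
    tau2_0, amp_tail = _loglin_tau(t[tail_start:], ys[tail_start:])
    if not np.isfinite(tau2_0):
        tau2_0, amp_tail = 2000.0, max(ys[min(tail_start, n - 1)], 1e-3)
    tau2_0 = float(np.clip(tau2_0, 5 * lo, hi))

    slow = amp_tail * np.exp(-t / tau2_0)
    early_end = peak + max((n - peak) // 6, 4)
    resid = np.clip(ys[peak:early_end] - slow[peak:early_end], 0.0, None)
    tau1_0, amp_fast = _loglin_tau(t[peak:early_end], resid)
    if not np.isfinite(tau1_0):
        tau1_0, amp_fast = 200.0, max(y.max() - slow[peak], 0.1 * y.max())
    tau1_0 = float(np.clip(tau1_0, lo, 0.9 * tau2_0))

    a2_0 = max(amp_tail, 1e-3 * y.max())
    a1_0 = max(amp_fast, 1e-3 * y.max())
    return tau1_0, tau2_0, a1_0, a2_0


def _best_start(y, t, kernel, offset, tau_bounds):
    """Pick the best (τ1, τ2) start among a coarse log grid and the
    two-segment log-linear guess, scoring each by weighted-LS cost with
    NNLS amplitudes.  Deterministic and seed-free."""
    lo, hi = tau_bounds
    guess = _initial_guess(y, t, tau_bounds)
    cands = [(guess[0], guess[1])]
    tau1_grid = [g for g in (40.0, 80.0, 150.0, 300.0, 600.0) if lo <= g <= hi]
    tau2_grid = [g for g in (500.0, 1000.0, 2000.0, 4000.0) if lo <= g <= hi]
    cands += [(t1, t2) for t1 in tau1_grid for t2 in tau2_grid if t2 >= 1.5 * t1]

    w = 1.0 / np.sqrt(np.maximum(y, 1.0))
    yw = y * w
    best, best_cost = cands[0], np.inf
    for t1, t2 in cands:
        D = _design(t, t1, t2, kernel, offset)
        amps, rnorm = optimize.nnls(D * w[:, None], yw)
        if rnorm < best_cost:
            best, best_cost = (t1, t2), rnorm
    return best[0], best[1], guess[2], guess[3]


# ---------------------------------------------------------------------------
# estimators


def _design(t: np.ndarray, tau1: float, tau2: float, kernel: np.ndarray, offset: int) -> np.ndarray:
    return np.column_stack(
        [
            _convolve(np.exp(-t / tau1), kernel, offset),
            _convolve(np.exp(-t / tau2), kernel, offset),
        ]
    )


def _fit_wls(y, t, kernel, offset, x0, tau_bounds, config):
    """Variable-projection weighted LS: nonlinear in (log τ1, log τ2),
    non-negative amplitudes solved linearly at each step."""
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))
    lo, hi = tau_bounds

    def amplitudes(tau1, tau2):
        D = _design(t, tau1, tau2, kernel, offset)
        amps, _ = optimize.nnls(D * w[:, None], y * w)
        return amps, D

    def residuals(p):
        tau1, tau2 = np.exp(p)
        amps, D = amplitudes(tau1, tau2)
        return (D @ amps - y) * w

    res = optimize.least_squares(
        residuals,
        np.log([x0[0], x0[1]]),
        bounds=(np.log([lo, lo]), np.log([hi, hi])),
        xtol=config.tolerance,
        ftol=config.tolerance,
        gtol=config.tolerance,
        max_nfev=4 * config.max_iterations,
    )
    tau1, tau2 = np.exp(res.x)
    amps, _ = amplitudes(tau1, tau2)
    ok = np.isfinite(res.cost) and np.isfinite(amps).all()
    return (tau1, tau2, amps[0], amps[1]), ok


def _poisson_nll_grad(p, y, t, kernel, offset):
    tau1, tau2, a1, a2 = p
    e1 = np.exp(-t / tau1)
    e2 = np.exp(-t / tau2)
    c1 = _convolve(e1, kernel, offset)
    c2 = _convolve(e2, kernel, offset)
    m = np.maximum(a1 * c1 + a2 * c2, 1e-12)
    nll = float(np.sum(m - y * np.log(m)))
    r = 1.0 - y / m
    d_tau1 = a1 * _convolve(t / tau1**2 * e1, kernel, offset)
    d_tau2 = a2 * _convolve(t / tau2**2 * e2, kernel, offset)
    grad = np.array(
        [np.dot(r, d_tau1), np.dot(r, d_tau2), np.dot(r, c1), np.dot(r, c2)]
    )
    return nll, grad


def _fit_mle(y, t, kernel, offset, x0, tau_bounds, config):
    """Bounded Poisson maximum-likelihood fit of (τ1, τ2, a1, a2)."""
    lo, hi = tau_bounds
    # Polish the amplitude start: NNLS at the initial lifetimes.
    w = 1.0 / np.sqrt(np.maximum(y, 1.0))
    D = _design(t, x0[0], x0[1], kernel, offset)
    amps, _ = optimize.nnls(D * w[:, None], y * w)
    a_floor = 1e-6 * max(y.max(), 1.0)
    p0 = np.array([x0[0], x0[1], max(amps[0], a_floor), max(amps[1], a_floor)])

    res = optimize.minimize(
        _poisson_nll_grad,
        p0,
        args=(y, t, kernel, offset),
        jac=True,
        method="L-BFGS-B",
        bounds=[(lo, hi), (lo, hi), (0.0, None), (0.0, None)],
        options={"maxiter": config.max_iterations, "ftol": config.tolerance},
    )
    p = res.x
    ok = np.isfinite(p).all() and np.isfinite(res.fun)
    return (p[0], p[1], p[2], p[3]), ok


def _order_components(tau1, tau2, a1, a2):
    """Sort so τ1 ≤ τ2; on a tie all amplitude goes to component 1."""
    if tau1 > tau2:
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    if np.isclose(tau1, tau2, rtol=1e-9, atol=1e-9):
        a1, a2 = a1 + a2, 0.0
    return tau1, tau2, a1, a2


def fit_pixel(
    histogram: np.ndarray,
    irf: np.ndarray,
    bin_width: float,
    config: FitConfig | None = None,
) -> PixelFit:
    """Fit one pixel's TCSPC histogram with the IRF-convolved biexponential.

    Returns lifetimes in ps, amplitudes in counts-per-bin units, a reduced
    chi-square, and a status code; pixels below the intensity threshold or
    failed fits are flagged, never raised.
    """
    if config is None:
        config = FitConfig()
    config.validate()
    y = np.asarray(histogram, float)
    irf = np.asarray(irf, float)
    if y.shape != irf.shape:
        raise ValueError("histogram and IRF lengths differ")
    nan = float("nan")
    if y.max(initial=0.0) < config.threshold_counts or not np.isfinite(y).all():
        return PixelFit(nan, nan, nan, nan, nan, FIT_BELOW_THRESHOLD)

    t = (np.arange(y.size) + 0.5) * bin_width
    kernel, offset = _kernel(_shift_irf(irf, t, config.shift))

    try:
        x0 = _best_start(y, t, kernel, offset, config.tau_bounds)
        if config.estimator == "weighted_ls":
            (tau1, tau2, a1, a2), ok = _fit_wls(
                y, t, kernel, offset, x0, config.tau_bounds, config
            )
        else:
            (tau1, tau2, a1, a2), ok = _fit_mle(
                y, t, kernel, offset, x0, config.tau_bounds, config
            )
    except Exception:  # pragma: no cover - single-pixel failures must not abort
        logger.debug("pixel fit raised", exc_info=True)
        return PixelFit(nan, nan, nan, nan, nan, FIT_FAILED)

    if not ok or not np.isfinite([tau1, tau2, a1, a2]).all() or (a1 + a2) <= 0:
        return PixelFit(nan, nan, nan, nan, nan, FIT_FAILED)

    tau1, tau2, a1, a2 = _order_components(tau1, tau2, a1, a2)
    model = a1 * _convolve(np.exp(-t / tau1), kernel, offset) + a2 * _convolve(
        np.exp(-t / tau2), kernel, offset
    )
    dof = max(y.size - 4, 1)
    chi2 = float(np.sum((y - model) ** 2 / np.maximum(model, 1.0)) / dof)
    return PixelFit(float(tau1), float(tau2), float(a1), float(a2), chi2, FIT_OK)


def mean_lifetime(a1, tau1, a2, tau2):
    """Amplitude-weighted mean lifetime τm = (a1·τ1 + a2·τ2)/(a1 + a2).

    Vectorized; where a1 + a2 == 0 the result is NaN (undefined).
    """
    a1 = np.asarray(a1, float)
    a2 = np.asarray(a2, float)
    tau1 = np.asarray(tau1, float)
    tau2 = np.asarray(tau2, float)
    total = a1 + a2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (a1 * tau1 + a2 * tau2) / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def fit_image(cube: TCSPCCube, config: FitConfig | None = None) -> FitMaps:
    """Fit every pixel of a TCSPC cube; per-pixel failures are masked.

    Derived maps: a1_pct = 100·a1/(a1+a2), amp_ratio = a1/a2 (NaN where
    a2 ≈ 0), and the amplitude-weighted mean lifetime τm.
    """
    if config is None:
        config = FitConfig()
    config.validate()
    cube.validate()
    h, w_, nt = cube.counts.shape
    shape = (h, w_)
    tau1 = np.full(shape, np.nan)
    tau2 = np.full(shape, np.nan)
    a1 = np.full(shape, np.nan)
    a2 = np.full(shape, np.nan)
    chi2 = np.full(shape, np.nan)
    status = np.full(shape, FIT_BELOW_THRESHOLD, dtype=np.int8)

    # Pre-screen the threshold in one vectorized pass.
    bright = cube.counts.max(axis=2) >= config.threshold_counts
    rows, cols = np.nonzero(bright)
    for r, c in zip(rows, cols):
        fit = fit_pixel(cube.counts[r, c], cube.irf, cube.bin_width, config)
        status[r, c] = fit.status
        if fit.status == FIT_OK:
            tau1[r, c] = fit.tau1
            tau2[r, c] = fit.tau2
            a1[r, c] = fit.a1
            a2[r, c] = fit.a2
            chi2[r, c] = fit.chi2

    valid = status == FIT_OK
    total = a1 + a2
    with np.errstate(invalid="ignore", divide="ignore"):
        a1_pct = np.where(total > 0, 100.0 * a1 / total, np.nan)
        amp_ratio = np.where(a2 > 1e-8 * total, a1 / a2, np.nan)
    tau_m = mean_lifetime(a1, tau1, a2, tau2)

    logger.info(
        "fit_image: %d/%d pixels valid (%d below threshold, %d failed)",
        int(valid.sum()),
        valid.size,
        int((status == FIT_BELOW_THRESHOLD).sum()),
        int((status == FIT_FAILED).sum()),
    )
    return FitMaps(
        tau1=tau1,
        tau2=tau2,
        a1=a1,
        a2=a2,
        a1_pct=a1_pct,
        amp_ratio=amp_ratio,
        tau_m=tau_m,
        chi2=chi2,
        valid=valid,
        status=status,
    )
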