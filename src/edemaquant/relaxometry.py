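"""Pixel-wise proton-density and T2 estimation from multi-echo data.

Each voxel's echo train is fit to the monoexponential decay

    SI(TE) = A * exp(-TE / T2)

by Levenberg-Marquardt least squares in linear signal space.  ``A`` is
the PD-weighted amplitude: the scanner gain K and the T1 saturation
factor (1 - exp(-TR/T1)) are constant across the echo train and are
absorbed into it rather than estimated, so A is proportional to proton
density and every downstream quantity is a ratio in which the
proportionality cancels.

A log-linear ordinary-least-squares fit of ln(SI) on TE provides the
starting point; the nonlinear fit is done in linear space because taking
logs reweights the noise toward the late, low-SNR echoes.  The solver is
vectorized across voxels (the 2x2 normal equations are solved in closed
form), so whole masked volumes fit in one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionParams, MultiEchoVolume

__all__ = ["ParameterMap", "loglinear_init", "fit_pixel", "fit_decay", "fit_volume"]

logger = logging.getLogger(__name__)

#: Relative RSS-change convergence tolerance.
FTOL = 1e-10
#: Relative parameter-step convergence tolerance.
XTOL = 1e-8
#: Iteration cap per voxel.
MAX_ITER = 200

_T2_MIN, _T2_MAX = 1e-3, 1e7  # ms; T2 kept in a physically meaningful range


@dataclass
class ParameterMap:
    """Per-pixel fit results on the acquisition grid.

    ``amplitude`` estimates K*PD*(1-exp(-TR/T1)) and is referred to as
    "PD" throughout the pipeline.  Pixels outside the fitted mask, or
    whose fit failed, carry ``converged=False`` and NaN parameters (the
    all-zero-signal case carries amplitude 0).
    """

    amplitude: np.ndarray
    t2: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    subject_id: str = ""
    time_min: float = 0.0
    params: AcquisitionParams | None = field(default=None, repr=False)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.amplitude.shape


def loglinear_init(signal: np.ndarray, echo_times: np.ndarray):
    """Log-linear starting values: OLS of ln(signal) on TE.

    Works on a single echo train or a stack ``(..., n_echoes)``.  Echoes
    with non-positive signal are excluded.  Returns ``(amplitude0, t2_0,
    ok)``; pixels with fewer than two usable echoes get NaN and
    ``ok=False``; a non-decaying (zero or positive) log-slope yields a
    ``t2_0 = +inf`` sentinel with ``ok=False``.
    """
    s = np.asarray(signal, dtype=float)
    tes = np.asarray(echo_times, dtype=float)
    scalar = s.ndim == 1
    s = np.atleast_2d(s)
    if s.shape[-1] != tes.size:
        raise ValueError("signal last axis must match echo_times")

    usable = s > 0
    n = usable.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(usable, np.log(np.where(usable, s, 1.0)), 0.0)
        x = np.where(usable, tes, 0.0)
        sx = x.sum(-1)
        sy = y.sum(-1)
        sxx = (x * x).sum(-1)
        sxy = (x * y).sum(-1)
        denom = n * sxx - sx * sx
        slope = np.where(denom > 0, (n * sxy - sx * sy) / np.where(denom > 0, denom, 1.0), np.nan)
        intercept = np.where(n > 0, (sy - slope * sx) / np.where(n > 0, n, 1.0), np.nan)

    amp0 = np.exp(intercept)
    ok = (n >= 2) & np.isfinite(slope)
    t2_0 = np.full(slope.shape, np.nan)
    neg = ok & (slope < 0)
    t2_0[neg] = -1.0 / slope[neg]
    flat = ok & (slope >= 0)
    t2_0[flat] = np.inf
    ok = neg  # only a decaying fit is a valid initialization
    amp0 = np.where(n >= 2, amp0, np.nan)

    if scalar:
        return float(amp0[0]), float(t2_0[0]), bool(ok[0])
    return amp0, t2_0, ok


def fit_decay(
    signals: np.ndarray,
    echo_times: np.ndarray,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    ftol: float = FTOL,
    xtol: float = XTOL,
    max_iter: int = MAX_ITER,
):
    """Levenberg-Marquardt monoexponential fit, vectorized over pixels.

    Minimizes sum_e (A*exp(-TE_e/T2) - signal_e)^2 for each row of
    ``signals`` (shape ``(n_pixels, n_echoes)``).  Convergence when the
    relative RSS change drops below ``ftol`` or the relative parameter
    step below ``xtol``; pixels that hit ``max_iter`` are flagged
    unconverged rather than raising.  Returns arrays ``(amplitude, t2,
    rss, converged, n_iter)``.
    """
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    tes = np.asarray(echo_times, dtype=float)
    npix = s.shape[0]

    amp = np.full(npix, np.nan)
    t2 = np.full(npix, np.nan)
    rss = np.full(npix, np.nan)
    converged = np.zeros(npix, dtype=bool)
    n_iter = np.zeros(npix, dtype=np.int32)

    allzero = ~np.any(s != 0.0, axis=1)
    amp[allzero] = 0.0
    rss[allzero] = 0.0

    fit_idx = np.flatnonzero(~allzero)
    if fit_idx.size == 0:
        return amp, t2, rss, converged, n_iter

    if init is None:
        a0, t0, ok = loglinear_init(s[fit_idx], tes)
    else:
        a0 = np.broadcast_to(np.asarray(init[0], dtype=float), (npix,))[fit_idx].copy()
        t0 = np.broadcast_to(np.asarray(init[1], dtype=float), (npix,))[fit_idx].copy()
        ok = np.isfinite(a0) & np.isfinite(t0) & (a0 > 0) & (t0 > 0)

    # fall back to a generic start where the log-linear step degenerated
    a0 = np.where(ok & np.isfinite(a0), a0, np.maximum(np.abs(s[fit_idx]).max(axis=1), 1.0))
    t0 = np.where(ok & np.isfinite(t0), t0, float(np.median(tes)))
    a0 = np.clip(a0, 0.0, None)
    t0 = np.clip(t0, _T2_MIN, _T2_MAX)

    A = a0.copy()
    T2 = t0.copy()
    sub = s[fit_idx]

    def residual_rss(Av, T2v):
        e = np.exp(-tes / T2v[:, None])
        r = Av[:, None] * e - sub
        return e, r, (r * r).sum(axis=1)

    e, r, cur_rss = residual_rss(A, T2)
    lam = np.full(fit_idx.size, 1e-3)
    active = np.ones(fit_idx.size, dtype=bool)
    iters = np.zeros(fit_idx.size, dtype=np.int32)
    conv = np.zeros(fit_idx.size, dtype=bool)
    tiny = np.finfo(float).tiny

    for _ in range(max_iter):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        eA = e[ai]
        rA = r[ai]
        Aa, T2a = A[ai], T2[ai]
        j2 = Aa[:, None] * (tes / (T2a**2)[:, None]) * eA  # d model / d T2
        a11 = (eA * eA).sum(1)
        a12 = (eA * j2).sum(1)
        a22 = (j2 * j2).sum(1)
        g1 = (eA * rA).sum(1)
        g2 = (j2 * rA).sum(1)

        la = lam[ai]
        m11 = a11 * (1.0 + la)
        m22 = a22 * (1.0 + la)
        det = m11 * m22 - a12 * a12
        det = np.where(np.abs(det) > tiny, det, tiny)
        dA = -(m22 * g1 - a12 * g2) / det
        dT2 = -(m11 * g2 - a12 * g1) / det

        A_new = np.clip(Aa + dA, 0.0, None)
        T2_new = np.clip(T2a + dT2, _T2_MIN, _T2_MAX)
        e_new = np.exp(-tes / T2_new[:, None])
        r_new = A_new[:, None] * e_new - sub[ai]
        rss_new = (r_new * r_new).sum(1)

        improved = rss_new <= cur_rss[ai]
        iters[ai] += 1

        imp_idx = ai[improved]
        rel_drss = np.abs(cur_rss[imp_idx] - rss_new[improved]) / np.maximum(
            cur_rss[imp_idx], tiny
        )
        step_rel = np.maximum(
            np.abs(dA[improved]) / np.maximum(np.abs(A_new[improved]), tiny),
            np.abs(dT2[improved]) / np.maximum(np.abs(T2_new[improved]), tiny),
        )
        A[imp_idx] = A_new[improved]
        T2[imp_idx] = T2_new[improved]
        e[imp_idx] = e_new[improved]
        r[imp_idx] = r_new[improved]
        cur_rss[imp_idx] = rss_new[improved]
        lam[imp_idx] = np.maximum(lam[imp_idx] / 3.0, 1e-12)

        done = imp_idx[(rel_drss < ftol) | (step_rel < xtol)]
        conv[done] = True
        active[done] = False

        rej_idx = ai[~improved]
        lam[rej_idx] = np.minimum(lam[rej_idx] * 4.0, 1e12)
        # a fully damped step that still cannot improve means we are at
        # a (possibly constrained) minimum
        stuck = rej_idx[lam[rej_idx] >= 1e12]
        conv[stuck] = True
        active[stuck] = False

    amp[fit_idx] = A
    t2[fit_idx] = T2
    rss[fit_idx] = cur_rss
    converged[fit_idx] = conv
    n_iter[fit_idx] = iters
    return amp, t2, rss, converged, n_iter


def fit_pixel(
    signal: np.ndarray,
    echo_times: np.ndarray,
    init: tuple[float, float] | None = None,
    **kwargs,
):
    """Fit a single echo train; see :func:`fit_decay`.

    Returns ``(amplitude, t2, rss, converged, n_iter)`` as scalars.
    """
    s = np.asarray(signal, dtype=float)[None, :]
    ini = None
    if init is not None:
        ini = (np.atleast_1d(init[0]), np.atleast_1d(init[1]))
    amp, t2, rss, conv, nit = fit_decay(s, echo_times, init=ini, **kwargs)
    return float(amp[0]), float(t2[0]), float(rss[0]), bool(conv[0]), int(nit[0])


def fit_volume(
    volume: MultiEchoVolume,
    mask: np.ndarray | None = None,
    **kwargs,
) -> ParameterMap:
    """Fit every masked voxel of a multi-echo volume.

    Voxels outside ``mask`` are flagged (``converged=False``, NaN
    parameters) rather than silently zeroed.  Voxels are independent, so
    the result does not depend on the mask except through which voxels
    are fitted.  Deterministic.
    """
    grid = volume.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != volume grid {grid}")

    amp = np.full(grid, np.nan)
    t2 = np.full(grid, np.nan)
    rss = np.full(grid, np.nan)
    conv = np.zeros(grid, dtype=bool)
    nit = np.zeros(grid, dtype=np.int32)

    tes = np.asarray(volume.params.echo_times)
    for sl in range(grid[0]):
        m = mask[sl]
        if not m.any():
            continue
        sig = volume.intensities[sl][m]
        a, t, q, c, n = fit_decay(sig, tes, **kwargs)
        amp[sl][m] = a
        t2[sl][m] = t
        rss[sl][m] = q
        conv[sl][m] = c
        nit[sl][m] = n
        logger.debug(
            "slice %d: fitted %d voxels, %d unconverged",
            sl, int(m.sum()), int((~c).sum()),
        )

    n_masked = int(mask.sum())
    n_bad = int((mask & ~conv).sum())
    if n_bad:
        logger.info("fit_volume: %d/%d masked voxels unconverged", n_bad, n_masked)
    return ParameterMap(
        amplitude=amp, t2=t2, rss=rss, converged=conv, n_iter=nit,
        subject_id=volume.subject_id, time_min=volume.time_min,
        params=volume.params,
    )
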