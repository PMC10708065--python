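"""Compiled hot loop for the condensed kinetic model.

This is the same auto-adaptive Euler algorithm as
:func:`placond.integrator.integrate`, specialized to the three-variable
condensed system and compiled with numba so that 200 h runs at a 1 s base
step (~7e5 steps) and multi-start least-squares fits stay interactive.
A test asserts that this path and the generic pure-Python path agree to
machine precision.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["condensed_euler"]


@njit(cache=True)
def condensed_euler(
    a0,
    c0,
    w0,
    S,
    C,
    k1,
    kneg1,
    kw,
    fw_mono,
    variant_enabled,
    me_threshold,
    k1_reduction,
    base_step,
    frac_threshold,
    h_min,
    abs_floor,
    max_steps,
    sample_times,
):  # pragma: no cover - exercised via placond.condensed.simulate
    """Adaptive-Euler trajectory of (a, c, w) recorded at sample times.

    Returns ``(out, stable, n_steps, n_clamped, n_floored)`` where ``out``
    has one row per sample time holding (a, c, w, t_of_recording_step);
    rows never reached on an unstable run stay NaN.
    """
    n = sample_times.shape[0]
    out = np.full((n, 4), np.nan)
    stable = True
    n_steps = 0
    n_clamped = 0
    n_floored = 0
    t = 0.0
    a = a0
    c = c0
    w = w0
    idx = 0
    while idx < n and sample_times[idx] <= 0.0:
        out[idx, 0] = a
        out[idx, 1] = c
        out[idx, 2] = w
        out[idx, 3] = t
        idx += 1
    while idx < n:
        if n_steps >= max_steps:
            stable = False
            break
        k1_eff = k1
        if variant_enabled and a > 0.0 and (c / a) * fw_mono > me_threshold:
            k1_eff = k1 * k1_reduction
        r = k1_eff * a * a - kneg1 * c * w
        xw = w / (2.0 * a + c + w + S + C)
        da = -r
        dc = r
        dw = r - kw * xw
        if not (np.isfinite(da) and np.isfinite(dc) and np.isfinite(dw)):
            stable = False
            break
        lim_a = max(frac_threshold * abs(a), abs_floor)
        lim_c = max(frac_threshold * abs(c), abs_floor)
        lim_w = max(frac_threshold * abs(w), abs_floor)
        h = base_step
        while True:
            if abs(h * da) <= lim_a and abs(h * dc) <= lim_c and abs(h * dw) <= lim_w:
                break
            if h * 0.5 < h_min:
                n_floored += 1
                break
            h *= 0.5
        a_new = a + h * da
        c_new = c + h * dc
        w_new = w + h * dw
        if not (np.isfinite(a_new) and np.isfinite(c_new) and np.isfinite(w_new)):
            stable = False
            break
        if a_new <= 0.0:
            stable = False
            break
        if c_new < 0.0:
            c_new = 0.0
            n_clamped += 1
        if w_new < 0.0:
            w_new = 0.0
            n_clamped += 1
        t = t + h
        a = a_new
        c = c_new
        w = w_new
        n_steps += 1
        while idx < n and sample_times[idx] <= t + 1e-9:
            out[idx, 0] = a
            out[idx, 1] = c
            out[idx, 2] = w
            out[idx, 3] = t
            idx += 1
    return out, stable, n_steps, n_clamped, n_floored
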