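"""Numba kernel of the hybrid stochastic-deterministic birth-death stepper.

The three-type logistic branching process is advanced on a fixed micro-step
(dt <= 1/30 month).  Compartments at or below the hybrid threshold ``C``
take Poisson tau-leaping steps (division/death/mutation counts drawn per
step; with r*dt <= ~0.04 the leap closely approximates the exact process
and preserves its mean); compartments above ``C`` are integrated
deterministically -- the primary pair (w, x) by RK4 on the coupled logistic
birth-death ODEs, each metastatic colony by the exact one-step solution of
its logistic ODE.  New type-1 lineages and new metastatic colonies arrive
as Poisson streams with intensities u*max(0, r0*(1-(w+x)/LAI))*w and q*x
per month.

Division rates are clamped at zero when the logistic factor (or an
on-treatment rate) is negative; the negative part is carried as additional
death so the net drift matches the ODE in both regimes.

The kernel uses numba's own global RNG; seed it per virtual case via
:func:`seed_kernel`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by advance_span
REACHED_END = 0
CROSSED = 1
EXTINCT = 2
COLONY_OVERFLOW = 3


@njit(cache=True)
def seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _bd_quad_step(y, a, c2, dt):
    """Exact step of dy/dt = a*y - c2*y^2 over dt (logistic birth-death)."""
    if y <= 0.0:
        return 0.0
    if abs(a) < 1e-12:
        return y / (1.0 + c2 * y * dt)
    ea = np.exp(a * dt)
    kk = a / c2 if c2 != 0.0 else 0.0
    if c2 == 0.0:
        return y * ea
    return kk * y * ea / (kk + y * (ea - 1.0))


@njit(cache=True, inline="always")
def _prim_deriv(w, x, r0t, r1t, u, d0, d1, lai):
    dens = 1.0 - (w + x) / lai
    b0 = r0t * dens
    b1 = r1t * dens
    mut = u * (b0 if b0 > 0.0 else 0.0) * w
    dw = (b0 - d0) * w - mut
    dx = (b1 - d1) * x + mut
    return dw, dx


@njit(cache=True)
def advance_span(
    t0,
    t1,
    state,  # float64[4]: w, x, total_prev (scratch), first_x_time (-1 if none)
    y,
    mai,
    tbirth,
    n_col,
    # process parameters
    u,
    q,
    d0,
    d1,
    d2,
    lai,
    chyb,
    det_force,  # force deterministic updates everywhere (oracle mode)
    # rates, linearly interpolated over [t0, t1]
    r0a,
    r0b,
    r1a,
    r1b,
    r2a,
    r2b,
    # MAI sampler: 0 -> lognormal(mu, sig); 1 -> empirical array
    mai_mode,
    mai_mu,
    mai_sig,
    mai_emp,
    dt_max,
    stop_total,
):
    """Advance the tumor from t0 to t1 or until total cells >= stop_total.

    Returns (status, t_reached, t_cross, n_col).  ``state`` and the colony
    arrays are updated in place; ``t_cross`` is the threshold crossing time
    located by linear interpolation within the crossing step (NaN when no
    crossing occurred).
    """
    w = state[0]
    x = state[1]
    first_x = state[3]
    span = t1 - t0
    t = t0
    status = REACHED_END
    t_cross = np.nan

    ysum = 0.0
    for i in range(n_col):
        ysum += y[i]
    total_prev = w + x + ysum

    while t < t1 - 1e-12:
        dt = dt_max
        if t + dt > t1:
            dt = t1 - t
        frac = (t + 0.5 * dt - t0) / span if span > 0.0 else 0.0
        r0t = r0a + (r0b - r0a) * frac
        r1t = r1a + (r1b - r1a) * frac
        r2t = r2a + (r2b - r2a) * frac

        dens = 1.0 - (w + x) / lai
        b0 = r0t * dens
        b1 = r1t * dens
        w_det = det_force or w > chyb
        x_det = det_force or x > chyb

        muts = 0.0
        if w_det and x_det:
            k1w, k1x = _prim_deriv(w, x, r0t, r1t, u, d0, d1, lai)
            k2w, k2x = _prim_deriv(w + 0.5 * dt * k1w, x + 0.5 * dt * k1x, r0t, r1t, u, d0, d1, lai)
            k3w, k3x = _prim_deriv(w + 0.5 * dt * k2w, x + 0.5 * dt * k2x, r0t, r1t, u, d0, d1, lai)
            k4w, k4x = _prim_deriv(w + dt * k3w, x + dt * k3x, r0t, r1t, u, d0, d1, lai)
            w_new = w + dt * (k1w + 2 * k2w + 2 * k3w + k4w) / 6.0
            x_new = x + dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
            if w_new < 0.0:
                w_new = 0.0
            if x_new < 0.0:
                x_new = 0.0
            w, x = w_new, x_new
        else:
            # type-0 compartment
            if w > 0.0:
                if w_det:
                    # logistic step in w with x frozen within the step
                    a = r0t * (1.0 - x / lai) * (1.0 - u) - d0
                    c2 = r0t * (1.0 - u) / lai
                    w_new = _bd_quad_step(w, a, c2, dt)
                    bmid = r0t * (1.0 - (0.5 * (w + w_new) + x) / lai)
                    intensity = u * (bmid if bmid > 0.0 else 0.0) * 0.5 * (w + w_new)
                    if x_det:
                        muts = intensity * dt
                    else:
                        muts = float(np.random.poisson(intensity * dt))
                    w = w_new
                else:
                    lam_div = (b0 if b0 > 0.0 else 0.0) * w * dt
                    extra_d = -b0 if b0 < 0.0 else 0.0
                    nd = np.random.poisson(lam_div) if lam_div > 0.0 else 0
                    nmut = 0
                    if nd > 0 and u > 0.0:
                        nmut = np.random.binomial(nd, u)
                    ndeath = np.random.poisson((d0 + extra_d) * w * dt)
                    w = w + nd - nmut - ndeath
                    if w < 0.0:
                        w = 0.0
                    muts = float(nmut)
            # type-1 compartment
            if x > 0.0 or muts > 0.0:
                if x_det:
                    a = r1t * (1.0 - w / lai) - d1
                    c2 = r1t / lai
                    x = _bd_quad_step(x, a, c2, dt) + muts
                else:
                    if x > 0.0:
                        lam_b = (b1 if b1 > 0.0 else 0.0) * x * dt
                        extra_d = -b1 if b1 < 0.0 else 0.0
                        nb = np.random.poisson(lam_b) if lam_b > 0.0 else 0
                        ndeath = np.random.poisson((d1 + extra_d) * x * dt)
                        x = x + nb - ndeath
                        if x < 0.0:
                            x = 0.0
                    x = x + muts

        # metastatic colonies (independent given their MAI)
        ysum = 0.0
        for i in range(n_col):
            yi = y[i]
            if yi <= 0.0:
                continue
            ki = mai[i]
            if det_force or yi > chyb:
                a = r2t - d2
                c2 = r2t / ki
                yi = _bd_quad_step(yi, a, c2, dt)
            else:
                dens2 = 1.0 - yi / ki
                b2 = r2t * dens2
                bb = b2 if b2 > 0.0 else 0.0
                dd = d2 + (-b2 if b2 < 0.0 else 0.0)
                nb = np.random.poisson(bb * yi * dt) if bb > 0.0 else 0
                ndeath = np.random.poisson(dd * yi * dt) if dd > 0.0 else 0
                yi = yi + nb - ndeath
                if yi < 0.0:
                    yi = 0.0
            y[i] = yi
            ysum += yi

        # metastasis seeding: Poisson stream with intensity q*x per month
        if q > 0.0 and x > 0.0:
            ns = np.random.poisson(q * x * dt)
            for _ in range(ns):
                if n_col >= y.shape[0]:
                    status = COLONY_OVERFLOW
                    break
                y[n_col] = 1.0
                if mai_mode == 0:
                    m = np.exp(mai_mu + mai_sig * np.random.standard_normal())
                else:
                    m = mai_emp[np.random.randint(0, mai_emp.shape[0])]
                mai[n_col] = m
                tbirth[n_col] = t + dt
                ysum += 1.0
                n_col += 1
            if status == COLONY_OVERFLOW:
                break

        t += dt
        if first_x < 0.0 and x > 0.0:
            first_x = t
        total = w + x + ysum
        if total >= stop_total:
            status = CROSSED
            if total > total_prev:
                t_cross = t - dt + dt * (stop_total - total_prev) / (total - total_prev)
                if t_cross < t - dt:
                    t_cross = t - dt
                if t_cross > t:
                    t_cross = t
            else:
                t_cross = t
            break
        if total <= 0.0:
            status = EXTINCT
            break
        total_prev = total

    state[0] = w
    state[1] = x
    state[2] = w + x + ysum
    state[3] = first_x
    return status, t, t_cross, n_col
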