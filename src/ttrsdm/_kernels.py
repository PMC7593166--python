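"""Compiled batch simulator for the transport-resistance growth model.

The inverse-estimation loop evaluates whole optimizer populations against
hundreds of grid cells, so the steady-state integration is compiled with
numba and runs each (candidate, cell) pair to its own convergence.  The
pure-Python ``ttr.step`` implements the identical update rule and is tested
against this kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _trap(x, p1, p2, p3, p4):
    if x < p1 or x > p4:
        return 0.0
    if p2 <= x <= p3:
        return 1.0
    if x < p2:
        return (x - p1) / (p2 - p1)
    return (p4 - x) / (p4 - p3)


@njit(cache=True, inline="always")
def _ramp(x, s1, s2):
    if x <= s1:
        return 0.0
    if x >= s2:
        return 1.0
    return (x - s1) / (s2 - s1)


@njit(cache=True)
def steady_state_batch(params, tday, tsoil, W, R, nsoil, fphoto_ext, use_ext,
                       substeps, tol, max_years, floor, resp_frac, fc, fn,
                       init_mass):
    """Steady-state total biomass for each (parameter row, cell) pair.

    params : (S, 29) full ordered parameter matrix
    tday, tsoil, W, R : (C, 12) monthly forcing
    nsoil : (C,) month-constant soil nitrogen
    fphoto_ext : (C, 12) externally supplied photosynthesis modifier
        (Farquhar variant); ignored unless ``use_ext``.
    Returns (biomass, converged): two (S, C) arrays.
    """
    S = params.shape[0]
    C = tday.shape[0]
    biomass = np.empty((S, C))
    converged = np.zeros((S, C), np.bool_)
    dt = 1.0 / substeps

    fp = np.empty(12)
    fN = np.empty(12)
    fG = np.empty(12)
    loss = np.empty(12)

    for s in range(S):
        b1, b2, b3, b4 = params[s, 0], params[s, 1], params[s, 2], params[s, 3]
        b5, b6, b7, b8 = params[s, 4], params[s, 5], params[s, 6], params[s, 7]
        g1, g2, g3, g4 = params[s, 8], params[s, 9], params[s, 10], params[s, 11]
        g5, g6, g7, g8 = params[s, 12], params[s, 13], params[s, 14], params[s, 15]
        d1, d2, d3, d4 = params[s, 16], params[s, 17], params[s, 18], params[s, 19]
        r1, r2 = params[s, 20], params[s, 21]
        sig_c, sig_n = params[s, 22], params[s, 23]
        g_rate, k_m = params[s, 24], params[s, 25]
        m_turn, r_tr = params[s, 26], params[s, 27]

        for c in range(C):
            for m in range(12):
                if use_ext:
                    fp[m] = fphoto_ext[c, m]
                else:
                    a = _trap(tday[c, m], b1, b2, b3, b4)
                    b = _ramp(R[c, m], b5, b6)
                    d = _ramp(W[c, m], b7, b8)
                    fp[m] = min(a, min(b, d))
                a = _trap(W[c, m], g1, g2, g3, g4)
                b = _ramp(nsoil[c], g5, g6)
                d = _ramp(tsoil[c, m], g7, g8)
                fN[m] = min(a, min(b, d))
                fG[m] = _trap(tday[c, m], d1, d2, d3, d4)
                loss[m] = m_turn + resp_frac * _ramp(tday[c, m], r1, r2)

            ms = init_mass
            mr = init_mass
            cs = 0.1 * init_mass
            cr = 0.1 * init_mass
            ns = 0.01 * init_mass
            nr = 0.01 * init_mass

            prev = -1.0
            mean_b = 0.0
            for year in range(max_years):
                acc = 0.0
                for m in range(12):
                    fpm = fp[m]
                    fnm = fN[m]
                    fgm = fG[m]
                    lm = loss[m]
                    for _ in range(substeps):
                        uc = sig_c * fpm * ms / (1.0 + ms / k_m)
                        un = sig_n * fnm * mr / (1.0 + mr / k_m)
                        gs = g_rate * fgm * cs * ns / ms
                        gr = g_rate * fgm * cr * nr / mr
                        denom = r_tr * (1.0 / ms + 1.0 / mr)
                        tc = (cs / ms - cr / mr) / denom
                        tn = (nr / mr - ns / ms) / denom
                        ms = ms + dt * (gs - lm * ms)
                        mr = mr + dt * (gr - lm * mr)
                        cs = cs + dt * (uc - fc * gs - tc)
                        cr = cr + dt * (tc - fc * gr)
                        ns = ns + dt * (tn - fn * gs)
                        nr = nr + dt * (un - fn * gr - tn)
                        if ms < floor:
                            ms = floor
                        if mr < floor:
                            mr = floor
                        if cs < floor:
                            cs = floor
                        if cr < floor:
                            cr = floor
                        if ns < floor:
                            ns = floor
                        if nr < floor:
                            nr = floor
                        # substrate pools cannot exceed structural mass
                        if cs > ms:
                            cs = ms
                        if cr > mr:
                            cr = mr
                        if ns > ms:
                            ns = ms
                        if nr > mr:
                            nr = mr
                    acc += ms + mr
                mean_b = acc / 12.0
                if prev >= 0.0:
                    ref = prev if prev > 1e-12 else 1e-12
                    if abs(mean_b - prev) / ref < tol:
                        converged[s, c] = True
                        break
                prev = mean_b
            biomass[s, c] = mean_b
    return biomass, converged
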