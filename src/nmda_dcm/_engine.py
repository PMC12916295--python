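"""Numba integration engine for the two-region conductance microcircuit.

State vector layout (length 40): V[0:8], gAMPA[8:16], gGABA[16:24],
gNMDA[24:32], gLEAK[32:40]; populations ordered ss, sp, ii, dp for the left
then the right region.  All functions take the positional parameter pack
produced by :func:`nmda_dcm.params.compile_trial`.  Inner loops are written
allocation-free because the inversion evaluates tens of thousands of trials.
"""
from __future__ import annotations

import numpy as np
from numba import njit

N = 8  # populations across the network


@njit(cache=True)
def _deriv(y, t, dy, sig, aff,
           EA, EN, GI, alpha, tA, tG, tN, tauL, C, gLbase,
           vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp):
    z = (t - onset) / width
    u = amp * np.exp(-0.5 * z * z)
    for i in range(N):
        sig[i] = 1.0 / (1.0 + np.exp(-slope * (y[i] - vthr)))
    for i in range(N):
        sa = 0.0
        sg = 0.0
        sn = 0.0
        for j in range(N):
            sa += EA[i, j] * sig[j]
            sg += GI[i, j] * sig[j]
            sn += EN[i, j] * sig[j]
        aff[i] = sa
        aff[N + i] = sg
        aff[2 * N + i] = sn
    for i in range(N):
        V = y[i]
        m = mgnum / (1.0 + 0.33 * np.exp(-0.06 * alpha[i] * V))
        ui = u * umask[i]
        dy[i] = (y[4 * N + i] * (vL - V) + y[N + i] * (vA - V)
                 + y[2 * N + i] * (vG - V) + y[3 * N + i] * m * (vN - V)) / C + ui
        dy[N + i] = (aff[i] - y[N + i]) / tA[i] + ui * u2g
        dy[2 * N + i] = (aff[N + i] - y[2 * N + i]) / tG[i] + ui * u2g
        dy[3 * N + i] = (aff[2 * N + i] - y[3 * N + i]) / tN[i] + ui * u2g
        # leak channel relaxes to its baseline conductance
        dy[4 * N + i] = (gLbase - y[4 * N + i]) / tauL + ui * u2g


@njit(cache=True)
def drift(y, t, EA, EN, GI, alpha, tA, tG, tN, tauL, C, gLbase,
          vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp):
    """Time derivative of the full state at time ``t`` (ms)."""
    dy = np.empty(5 * N)
    sig = np.empty(N)
    aff = np.empty(3 * N)
    _deriv(y, t, dy, sig, aff, EA, EN, GI, alpha, tA, tG, tN, tauL, C, gLbase,
           vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp)
    return dy


@njit(cache=True)
def integrate(y0, nsteps, dt, bound, EA, EN, GI, alpha, tA, tG, tN, tauL, C,
              gLbase, vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g,
              onset, width, amp):
    """Fixed-step RK4.  Returns (V trajectory (nsteps+1, 8), ok flag)."""
    Vout = np.empty((nsteps + 1, N))
    y = y0.copy()
    yt = np.empty(5 * N)
    k1 = np.empty(5 * N)
    k2 = np.empty(5 * N)
    k3 = np.empty(5 * N)
    k4 = np.empty(5 * N)
    sig = np.empty(N)
    aff = np.empty(3 * N)
    for i in range(N):
        Vout[0, i] = y[i]
    for s in range(nsteps):
        t = s * dt
        _deriv(y, t, k1, sig, aff, EA, EN, GI, alpha, tA, tG, tN, tauL, C,
               gLbase, vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp)
        for i in range(5 * N):
            yt[i] = y[i] + 0.5 * dt * k1[i]
        _deriv(yt, t + 0.5 * dt, k2, sig, aff, EA, EN, GI, alpha, tA, tG, tN, tauL,
               C, gLbase, vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp)
        for i in range(5 * N):
            yt[i] = y[i] + 0.5 * dt * k2[i]
        _deriv(yt, t + 0.5 * dt, k3, sig, aff, EA, EN, GI, alpha, tA, tG, tN, tauL,
               C, gLbase, vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp)
        for i in range(5 * N):
            yt[i] = y[i] + dt * k3[i]
        _deriv(yt, t + dt, k4, sig, aff, EA, EN, GI, alpha, tA, tG, tN, tauL,
               C, gLbase, vL, vA, vG, vN, mgnum, slope, vthr, umask, u2g, onset, width, amp)
        ok = True
        for i in range(5 * N):
            y[i] = y[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        for i in range(N):
            if not np.isfinite(y[i]) or np.abs(y[i]) > bound:
                ok = False
        if not ok:
            for r in range(s + 1, nsteps + 1):
                for i in range(N):
                    Vout[r, i] = y[i]
            return Vout, False
        for i in range(N):
            Vout[s + 1, i] = y[i]
    return Vout, True


@njit(cache=True)
def fixed_point(EA, EN, GI, alpha, tA, tG, tN, tauL, C, gLbase,
                vL, vA, vG, vN, mgnum, slope, vthr,
                damping=0.5, tol=1e-13, maxit=20000):
    """Damped Picard iteration for the u=0 equilibrium of the drift.

    Returns (state vector (40,), converged flag).  At the fixed point each
    conductance equals its afferent drive and the voltage solves the quasi-
    static current-balance equation; the equilibrium does not depend on the
    time constants.
    """
    V = np.full(N, vL)
    gA = np.zeros(N)
    gG = np.zeros(N)
    gNm = np.zeros(N)
    sig = np.empty(N)
    ok = False
    for _ in range(maxit):
        for i in range(N):
            sig[i] = 1.0 / (1.0 + np.exp(-slope * (V[i] - vthr)))
        dmax = 0.0
        for i in range(N):
            sa = 0.0
            sg = 0.0
            sn = 0.0
            for j in range(N):
                sa += EA[i, j] * sig[j]
                sg += GI[i, j] * sig[j]
                sn += EN[i, j] * sig[j]
            m = mgnum / (1.0 + 0.33 * np.exp(-0.06 * alpha[i] * V[i]))
            num = gLbase * vL + gA[i] * vA + gG[i] * vG + gNm[i] * m * vN
            den = gLbase + gA[i] + gG[i] + gNm[i] * m
            Vt = num / den
            for d in (Vt - V[i], sa - gA[i], sg - gG[i], sn - gNm[i]):
                if np.abs(d) > dmax:
                    dmax = np.abs(d)
            V[i] += damping * (Vt - V[i])
            gA[i] += damping * (sa - gA[i])
            gG[i] += damping * (sg - gG[i])
            gNm[i] += damping * (sn - gNm[i])
        if dmax < tol:
            ok = True
            break
    y = np.empty(5 * N)
    for i in range(N):
        y[i] = V[i]
        y[N + i] = gA[i]
        y[2 * N + i] = gG[i]
        y[3 * N + i] = gNm[i]
        y[4 * N + i] = gLbase
    return y, ok
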