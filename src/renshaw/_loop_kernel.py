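"""Fixed-step integration kernel for the recurrent-inhibition loop model.

Units inside the kernel: millivolts, milliseconds, nanosiemens, picofarads
(so currents are in picoamperes and dV/dt = I/C is in mV/ms). The Renshaw
cells are exponential integrate-and-fire; synaptic conductances are alpha
functions implemented as the exact two-state linear update

    h(t+dt) = h(t) * exp(-dt/tau)
    g(t+dt) = exp(-dt/tau) * (g(t) + dt * h(t) / tau)

which makes g an alpha function peaking ``jump/e`` at ``tau`` after a jump in
h; event jumps are therefore scaled by e so the conductance peak equals the
configured value. The recorded motoneuron is a passive two-compartment cell
with glycinergic input on the dendrite. Euler integration for the membrane
equations at dt = 20 µs.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_loop"]


@njit(cache=True)
def run_loop(
    n_steps,
    dt,                 # ms
    stim_steps,         # int64[:] EPSP-onset steps (axon delay already applied)
    epsp_tau,           # ms, alpha time-to-peak (= EPSP conductance rise time)
    epsp_jump,          # nS, compound per-volley conductance peak (x e applied here)
    rc_c,
    rc_gl,
    rc_el,
    rc_vt,              # float64[:] per-cell threshold (jittered)
    rc_dt_mv,
    rc_vcut,
    rc_vreset,
    rc_refr_steps,
    rc_ee,
    gly_tau,
    gly_jump,           # nS, unitary conductance peak per Renshaw spike
    gly_delay_steps,
    gly_erev,
    cs, gls, cd, gld, gc, el,
    discard_steps,
    decim,
    vm_out,             # float64[:] preallocated somatic output
    gly_sched,          # float64[:] length n_steps scratch, zeros
    spike_cells,        # int64[:] preallocated
    spike_steps,        # int64[:]
):
    n_rc = rc_vt.shape[0]
    h_e = np.zeros(n_rc)
    g_e = np.zeros(n_rc)
    v_rc = np.full(n_rc, rc_el)
    refr = np.zeros(n_rc, dtype=np.int64)
    h_g = 0.0
    g_g = 0.0
    vs = el
    vd = el
    eh = math.exp(-dt / epsp_tau)
    eg = math.exp(-dt / gly_tau)
    e_epsp = epsp_jump * math.e
    e_gly = gly_jump * math.e
    cap = spike_cells.shape[0]
    ptr = 0
    n_stim = stim_steps.shape[0]
    k_out = 0
    n_out = vm_out.shape[0]
    nsp = 0
    for i in range(n_steps):
        while ptr < n_stim and stim_steps[ptr] == i:
            for j in range(n_rc):
                h_e[j] += e_epsp
            ptr += 1
        if i >= discard_steps and (i - discard_steps) % decim == 0 and k_out < n_out:
            vm_out[k_out] = vs
            k_out += 1
        if gly_sched[i] != 0.0:
            h_g += gly_sched[i]
        for j in range(n_rc):
            g_e[j] = eh * (g_e[j] + dt * h_e[j] / epsp_tau)
            h_e[j] = eh * h_e[j]
            if refr[j] > 0:
                refr[j] -= 1
                v_rc[j] = rc_vreset
            else:
                arg = (v_rc[j] - rc_vt[j]) / rc_dt_mv
                if arg > 20.0:
                    arg = 20.0
                i_ion = (
                    -rc_gl * (v_rc[j] - rc_el)
                    + rc_gl * rc_dt_mv * math.exp(arg)
                    + g_e[j] * (rc_ee - v_rc[j])
                )
                v_rc[j] += dt * i_ion / rc_c
                if v_rc[j] >= rc_vcut:
                    if nsp < cap:
                        spike_cells[nsp] = j
                        spike_steps[nsp] = i
                        nsp += 1
                    v_rc[j] = rc_vreset
                    refr[j] = rc_refr_steps
                    tgt = i + gly_delay_steps
                    if tgt < n_steps:
                        gly_sched[tgt] += e_gly
        g_g = eg * (g_g + dt * h_g / gly_tau)
        h_g = eg * h_g
        dvs = (-gls * (vs - el) + gc * (vd - vs)) / cs
        dvd = (-gld * (vd - el) + gc * (vs - vd) + g_g * (gly_erev - vd)) / cd
        vs += dt * dvs
        vd += dt * dvd
        if vs > 200.0 or vs < -200.0 or vs != vs:
            return -1
    return nsp
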