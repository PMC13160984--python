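"""Numba-compiled inner loop for long simulations.

Semantics are identical to the per-step reference functions in
:mod:`osteonet.discrete_core` / :mod:`osteonet.cell_dynamics` (tested for
equivalence); this kernel exists purely so 400-day runs at dt = 1e-5 day
(4e7 steps) finish in seconds.

Step ordering per update: (1) occupancy update and outgoing-flux
accounting, (2) cell populations from the fluxes, (3) boundary motion,
(4) osteocyte creation/removal.  Molecules freed by a resorbed osteocyte
are credited to the cumulative counters immediately and therefore appear in
the flux read at the next occupancy update.

Event codes: 0 left-created, 1 left-removed, 2 right-created, 3 right-removed.
Status codes: 0 completed, 1 fully resorbed, 2 lattice capacity exceeded,
3 record/event buffer overflow.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_COMPLETED = 0
STATUS_RESORBED = 1
STATUS_CAPACITY = 2
STATUS_OVERFLOW = 3


@njit(cache=True)
def run_epoch(  # noqa: PLR0913 - flat scalar signature keeps numba dispatch cheap
    occ, lo, istate, fstate, tmp,
    step0, n_steps, sample_stride,
    dt, dx, q_left, q_stay, q_right,
    lam1, lam2, W, sigma_ref, psi_ref, E,
    J0, kf, kr, vf, vr, a_ob, a_oc, A_ob, A_oc,
    F_base, F_x, sed_mode, instantaneous,
    rec_t, rec_f, rec_i, n_rec,
    ev_t, ev_code, ev_index, ev_freed, n_ev,
):
    i_minus = istate[0]
    i_plus = istate[1]
    b_minus = fstate[0]
    b_plus = fstate[1]
    cum_m = fstate[2]
    cum_p = fstate[3]
    last_m = fstate[4]
    last_p = fstate[5]
    ob_m = fstate[6]
    ob_p = fstate[7]
    oc_m = fstate[8]
    oc_p = fstate[9]

    status = STATUS_COMPLETED
    steps_done = 0
    for s in range(n_steps):
        L = b_plus - b_minus
        nsite = i_plus - i_minus + 1
        k0 = i_minus - lo
        # (1) occupancy update; absorbing ghost sites beyond the extremes
        coef = 1.0e6 / (L * W)  # N/um^2 -> MPa
        for k in range(nsite):
            x = (i_minus + k) * dx
            sigma = (F_base + F_x * x) * coef
            if sed_mode:
                drive = sigma * sigma / (2.0 * E) / psi_ref
            else:
                drive = sigma / sigma_ref
            Nk = occ[k0 + k]
            left = occ[k0 + k - 1] if k > 0 else 0.0
            right = occ[k0 + k + 1] if k < nsite - 1 else 0.0
            val = (
                q_right * left + q_left * right + q_stay * Nk
                + (lam1 * drive - lam2 * Nk) * dt
            )
            if val < 0.0:
                val = 0.0
            tmp[k] = val
        cum_m += q_left * occ[k0]
        cum_p += q_right * occ[k0 + nsite - 1]
        for k in range(nsite):
            occ[k0 + k] = tmp[k]
        Jm = (cum_m - last_m) / dt
        Jp = (cum_p - last_p) / dt
        last_m = cum_m
        last_p = cum_p

        # (2) cell populations
        relm = (Jm - J0) / J0
        relp = (Jp - J0) / J0
        if instantaneous:
            ob_m = max(relm, 0.0) * vf / kf
            ob_p = max(relp, 0.0) * vf / kf
            oc_m = max(-relm, 0.0) * vr / kr
            oc_p = max(-relp, 0.0) * vr / kr
        else:
            ob_m += (a_ob * max(relm, 0.0) - A_ob * ob_m) * dt
            ob_p += (a_ob * max(relp, 0.0) - A_ob * ob_p) * dt
            oc_m += (a_oc * max(-relm, 0.0) - A_oc * oc_m) * dt
            oc_p += (a_oc * max(-relp, 0.0) - A_oc * oc_p) * dt

        # (3) boundary motion
        b_minus -= (kf * ob_m - kr * oc_m) * dt
        b_plus += (kf * ob_p - kr * oc_p) * dt
        gstep = step0 + s + 1
        t = gstep * dt
        steps_done = s + 1

        had_event = False
        if b_minus >= b_plus:
            for k in range(nsite):
                cum_m += occ[k0 + k]
                occ[k0 + k] = 0.0
            i_plus = i_minus - 1
            status = STATUS_RESORBED
        else:
            # (4) topology events, re-applied until no condition holds
            while True:
                moved = False
                if i_plus >= i_minus and b_plus > (i_plus + 1) * dx:
                    if i_plus + 1 - lo >= occ.shape[0]:
                        status = STATUS_CAPACITY
                        break
                    if n_ev >= ev_t.shape[0]:
                        status = STATUS_OVERFLOW
                        break
                    i_plus += 1
                    occ[i_plus - lo] = 0.0
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 2
                    ev_index[n_ev] = i_plus
                    ev_freed[n_ev] = 0.0
                    n_ev += 1
                    moved = True
                    had_event = True
                elif i_plus >= i_minus and b_plus <= i_plus * dx:
                    if n_ev >= ev_t.shape[0]:
                        status = STATUS_OVERFLOW
                        break
                    freed = occ[i_plus - lo]
                    cum_p += freed
                    ev_t[n_ev] = t
                    ev_code[n_ev] = 3
                    ev_index[n_ev] = i_plus
                    ev_freed[n_ev] = freed
                    n_ev += 1
                    i_plus -= 1
                    moved = True
                    had_event = True
                if i_plus >= i_minus:
                    if b_minus < (i_minus - 1) * dx:
                        if i_minus - 1 - lo <= 0:
                            status = STATUS_CAPACITY
                            break
                        if n_ev >= ev_t.shape[0]:
                            status = STATUS_OVERFLOW
                            break
                        i_minus -= 1
                        occ[i_minus - lo] = 0.0
                        ev_t[n_ev] = t
                        ev_code[n_ev] = 0
                        ev_index[n_ev] = i_minus
                        ev_freed[n_ev] = 0.0
                        n_ev += 1
                        moved = True
                        had_event = True
                    elif b_minus >= i_minus * dx:
                        if n_ev >= ev_t.shape[0]:
                            status = STATUS_OVERFLOW
                            break
                        freed = occ[i_minus - lo]
                        cum_m += freed
                        ev_t[n_ev] = t
                        ev_code[n_ev] = 1
                        ev_index[n_ev] = i_minus
                        ev_freed[n_ev] = freed
                        n_ev += 1
                        i_minus += 1
                        moved = True
                        had_event = True
                if i_plus < i_minus:
                    status = STATUS_RESORBED
                    break
                if not moved:
                    break

        if status != STATUS_COMPLETED or had_event or gstep % sample_stride == 0 or s == n_steps - 1:
            if n_rec < rec_t.shape[0]:
                rec_t[n_rec] = t
                rec_f[n_rec, 0] = b_minus
                rec_f[n_rec, 1] = b_plus
                rec_f[n_rec, 2] = Jm
                rec_f[n_rec, 3] = Jp
                rec_f[n_rec, 4] = ob_m
                rec_f[n_rec, 5] = ob_p
                rec_f[n_rec, 6] = oc_m
                rec_f[n_rec, 7] = oc_p
                rec_i[n_rec, 0] = i_minus
                rec_i[n_rec, 1] = i_plus
                n_rec += 1
            elif status == STATUS_COMPLETED:
                status = STATUS_OVERFLOW
        if status != STATUS_COMPLETED:
            break

    fstate[0] = b_minus
    fstate[1] = b_plus
    fstate[2] = cum_m
    fstate[3] = cum_p
    fstate[4] = last_m
    fstate[5] = last_p
    fstate[6] = ob_m
    fstate[7] = ob_p
    fstate[8] = oc_m
    fstate[9] = oc_p
    istate[0] = i_minus
    istate[1] = i_plus
    return n_rec, n_ev, status, steps_done
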