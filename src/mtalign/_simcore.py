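"""Numba event loop for the microtubule growth simulation.

Everything here operates on flat numpy arrays so the continuous-time Markov
chain (one dimer added or removed per event) and the per-dimer collision
detection run at compiled speed.  The RNG is an in-array xorshift128+ stream,
which keeps runs bit-reproducible and lets the Python layer single-step the
same kernel that full runs use.

State encoding (per microtubule):
  state: 0 = growing, 1 = shrinking (rescuable), 2 = paused (stabilized at
  the boundary), 3 = collapsing (depolymerizing with no rescue, an optional
  fate of a collision-induced catastrophe), 4 = waiting at zero length
  (state B_0 of the chain: nothing left to depolymerize, so the only
  transition out is a rescue at rate alpha_prime)
  ndim:  length in tubulin dimers (the CTMC coordinate)
  segments: polyline pieces (origin, unit direction, length in nm); a new
  piece starts whenever the tip zips onto an obstacle.

Collision outcome codes: 0 = zip, 1 = cross, 2 = catastrophe, 3 = stabilize.
Target codes: 0 = cell boundary, 1 = another microtubule.
Rule-set codes: 0 = stabilize_no_cross, 1 = cross_stabilize,
2 = cross_boundary_cat, 3 = angle_dependent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAXSEG = 384

GROW, SHRINK, PAUSE, COLLAPSE, WAIT = 0, 1, 2, 3, 4
T_BOUNDARY, T_MT = 0, 1
ZIP, CROSS, CAT, STAB = 0, 1, 2, 3
R_STAB_NO_CROSS, R_CROSS_STAB, R_CROSS_BCAT, R_ANGLE_DEP = 0, 1, 2, 3

_S_EPS = 1e-9       # nm; minimum hit distance along a growth step
_CROSS_ADV = 1e-6   # nm; overshoot past a crossed obstacle
_PAR_TOL = 1e-10    # parallel-collision rejection on the unit cross product


@njit(cache=True, inline="always")
def _rng_u(s):
    """xorshift128+ uniform double in [0, 1); state s is a (2,) uint64 array."""
    x = s[0]
    y = s[1]
    s[0] = y
    x = x ^ (x << np.uint64(23))
    x = x ^ (x >> np.uint64(17))
    x = x ^ (y ^ (y >> np.uint64(26)))
    s[1] = x
    return np.float64((x + y) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def resolve_collision_code(angle, target, rule, u, p_cat, theta_c):
    """Collision outcome as a pure function of (angle, target, rule, u).

    angle: acute axial collision angle in (0, 90], degrees.
    Returns one of ZIP/CROSS/CAT/STAB.
    """
    if rule == R_STAB_NO_CROSS:
        return CAT if target == T_MT else STAB
    if rule == R_CROSS_STAB:
        return CROSS if target == T_MT else STAB
    if rule == R_CROSS_BCAT:
        return CROSS if target == T_MT else CAT
    # angle-dependent rules
    if angle >= theta_c:
        if target == T_BOUNDARY:
            return CAT
        return CAT if u < p_cat else CROSS
    p = angle / theta_c * p_cat
    return CAT if u < p else ZIP


@njit(cache=True)
def _reset_mt(i, redraw, wait, seed_dx0, seed_dy0,
              seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
              state, ndim, nseg, sox, soy, sdx, sdy, slen,
              tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng):
    """Return MT i to zero length at its seed.

    With ``redraw`` a fresh uniformly random inward angle is drawn; otherwise
    the seed keeps the (quenched) angle drawn at setup, stored in
    ``seed_dx0/seed_dy0``.  With ``wait`` the chain parks in state B_0 until
    a rescue event regrows it; otherwise it re-enters the growing state
    immediately.
    """
    if redraw:
        u = _rng_u(rng)
        phi = u * np.pi
        if phi <= 0.0:
            phi = 0.5 * np.pi
        c = np.cos(phi)
        s = np.sin(phi)
        dx = c * seed_tx[i] + s * seed_nx[i]
        dy = c * seed_ty[i] + s * seed_ny[i]
        seed_dx0[i] = dx
        seed_dy0[i] = dy
    else:
        dx = seed_dx0[i]
        dy = seed_dy0[i]
    state[i] = WAIT if wait else GROW
    ndim[i] = 0
    nseg[i] = 1
    sox[i, 0] = seed_x[i]
    soy[i, 0] = seed_y[i]
    sdx[i, 0] = dx
    sdy[i, 0] = dy
    slen[i, 0] = 0.0
    tipx[i] = seed_x[i]
    tipy[i] = seed_y[i]
    dirx[i] = dx
    diry[i] = dy
    bminx[i] = seed_x[i]
    bmaxx[i] = seed_x[i]
    bminy[i] = seed_y[i]
    bmaxy[i] = seed_y[i]


@njit(cache=True, inline="always")
def _bbox_include(i, x, y, bminx, bmaxx, bminy, bmaxy):
    if x < bminx[i]:
        bminx[i] = x
    if x > bmaxx[i]:
        bmaxx[i] = x
    if y < bminy[i]:
        bminy[i] = y
    if y > bmaxy[i]:
        bmaxy[i] = y


@njit(cache=True)
def _shrink_one(i, dimer_len, redraw, wait, seed_dx0, seed_dy0,
                seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                state, ndim, nseg, sox, soy, sdx, sdy, slen,
                tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng):
    """Remove one dimer's worth of polymer from the tip, consuming polyline
    segments in reverse; a fully depolymerized MT re-nucleates."""
    h = dimer_len
    while h > 1e-12 and nseg[i] > 0:
        k = nseg[i] - 1
        if slen[i, k] > h + 1e-12:
            slen[i, k] -= h
            h = 0.0
        else:
            h -= slen[i, k]
            slen[i, k] = 0.0
            nseg[i] -= 1
    ndim[i] -= 1
    if nseg[i] == 0 or ndim[i] <= 0:
        _reset_mt(i, redraw, wait, seed_dx0, seed_dy0,
                  seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                  state, ndim, nseg, sox, soy, sdx, sdy, slen,
                  tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng)
    else:
        k = nseg[i] - 1
        dirx[i] = sdx[i, k]
        diry[i] = sdy[i, k]
        tipx[i] = sox[i, k] + sdx[i, k] * slen[i, k]
        tipy[i] = soy[i, k] + sdy[i, k] * slen[i, k]


@njit(cache=True)
def _grow_step(i, t, rule, p_cat, theta_c, dimer_len, collapse,
               edge_x1, edge_y1, edge_x2, edge_y2, edge_len, edge_tx, edge_ty,
               seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
               state, ndim, nseg, sox, soy, sdx, sdy, slen,
               tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng,
               ev_t, ev_mt, ev_target, ev_angle, ev_outcome, ev_count):
    """Advance MT i by one dimer along its tip direction, resolving any
    collisions along the traversed path.  Returns the updated event count."""
    n = state.shape[0]
    m = edge_x1.shape[0]
    remaining = dimer_len
    guard = 0
    completed = True
    while remaining > _S_EPS:
        guard += 1
        if guard > 64:
            state[i] = COLLAPSE if collapse else SHRINK
            completed = False
            break
        px = tipx[i]
        py = tipy[i]
        dx = dirx[i]
        dy = diry[i]
        qx = px + dx * remaining
        qy = py + dy * remaining
        lox = px if px < qx else qx
        hix = px if px > qx else qx
        loy = py if py < qy else qy
        hiy = py if py > qy else qy

        best_s = 1e300
        best_tx = 0.0
        best_ty = 0.0
        best_target = -1
        bnd_s = 1e300
        bnd_tx = 0.0
        bnd_ty = 0.0

        for e in range(m):
            ex = edge_x2[e] - edge_x1[e]
            ey = edge_y2[e] - edge_y1[e]
            denom = dx * ey - dy * ex
            if abs(denom) <= _PAR_TOL * edge_len[e]:
                continue
            # only outward motion can cross this edge (outward normal of a
            # CCW polygon is (ty, -tx)); this also admits s = 0 hits when the
            # tip sits exactly on the wall (e.g. regrowth from a zip crease)
            # without tripping on the seed's own wall at nucleation
            if dx * edge_ty[e] - dy * edge_tx[e] <= 0.0:
                continue
            rx = edge_x1[e] - px
            ry = edge_y1[e] - py
            s = (rx * ey - ry * ex) / denom
            if s <= -_S_EPS or s > remaining:
                continue
            if s < 0.0:
                s = 0.0
            v = (rx * dy - ry * dx) / denom
            if v < -1e-9 or v > 1.0 + 1e-9:
                continue
            if s < bnd_s:
                bnd_s = s
                bnd_tx = edge_tx[e]
                bnd_ty = edge_ty[e]

        for j in range(n):
            if j == i or nseg[j] == 0:
                continue
            if bminx[j] > hix or bmaxx[j] < lox or bminy[j] > hiy or bmaxy[j] < loy:
                continue
            for k in range(nseg[j]):
                L = slen[j, k]
                if L <= 1e-12:
                    continue
                ex = sdx[j, k] * L
                ey = sdy[j, k] * L
                denom = dx * ey - dy * ex
                if abs(denom) <= _PAR_TOL * L:
                    continue
                rx = sox[j, k] - px
                ry = soy[j, k] - py
                s = (rx * ey - ry * ex) / denom
                if s <= -_S_EPS or s > remaining:
                    continue
                if s < 0.0:
                    s = 0.0
                v = (rx * dy - ry * dx) / denom
                if v < -1e-9 or v > 1.0 + 1e-9:
                    continue
                if s < best_s:
                    best_s = s
                    best_tx = sdx[j, k]
                    best_ty = sdy[j, k]
                    best_target = T_MT

        # the boundary wins ties: a cross-overshoot past an obstacle lying on
        # (or within the overshoot distance of) the wall must not tunnel out
        if bnd_s < 1e299 and bnd_s <= best_s + 2.0 * _CROSS_ADV:
            best_s = bnd_s
            best_tx = bnd_tx
            best_ty = bnd_ty
            best_target = T_BOUNDARY

        if best_target == -1:
            k = nseg[i] - 1
            slen[i, k] += remaining
            tipx[i] = px + dx * remaining
            tipy[i] = py + dy * remaining
            _bbox_include(i, tipx[i], tipy[i], bminx, bmaxx, bminy, bmaxy)
            remaining = 0.0
            break

        dot = dx * best_tx + dy * best_ty
        c = abs(dot)
        if c > 1.0:
            c = 1.0
        angle = np.degrees(np.arccos(c))
        angle = 90.0 - abs(90.0 - angle)  # clamp into (0, 90]
        u = _rng_u(rng)
        outcome = resolve_collision_code(angle, best_target, rule, u, p_cat, theta_c)

        if ev_count < ev_t.shape[0]:
            ev_t[ev_count] = t
            ev_mt[ev_count] = i
            ev_target[ev_count] = best_target
            ev_angle[ev_count] = angle
            ev_outcome[ev_count] = outcome
        ev_count += 1

        if outcome == CROSS:
            adv = best_s + _CROSS_ADV
            if adv > remaining:
                adv = remaining
            slen[i, nseg[i] - 1] += adv
            tipx[i] = px + dx * adv
            tipy[i] = py + dy * adv
            _bbox_include(i, tipx[i], tipy[i], bminx, bmaxx, bminy, bmaxy)
            remaining -= adv
        elif outcome == ZIP:
            slen[i, nseg[i] - 1] += best_s
            hx = px + dx * best_s
            hy = py + dy * best_s
            tipx[i] = hx
            tipy[i] = hy
            _bbox_include(i, hx, hy, bminx, bmaxx, bminy, bmaxy)
            remaining -= best_s
            if dot > 0.0:
                ndx = best_tx
                ndy = best_ty
            elif dot < 0.0:
                ndx = -best_tx
                ndy = -best_ty
            else:  # exact 90-degree tie: keep the positive-orientation sign
                if best_ty > 0.0 or (best_ty == 0.0 and best_tx > 0.0):
                    ndx = best_tx
                    ndy = best_ty
                else:
                    ndx = -best_tx
                    ndy = -best_ty
            if nseg[i] >= MAXSEG:
                state[i] = COLLAPSE if collapse else SHRINK
                completed = False
                break
            k = nseg[i]
            sox[i, k] = hx
            soy[i, k] = hy
            sdx[i, k] = ndx
            sdy[i, k] = ndy
            slen[i, k] = 0.0
            nseg[i] += 1
            dirx[i] = ndx
            diry[i] = ndy
        elif outcome == CAT:
            state[i] = COLLAPSE if collapse else SHRINK
            completed = False
            break
        else:  # STAB: tip reaches the wall and pauses
            slen[i, nseg[i] - 1] += best_s
            tipx[i] = px + dx * best_s
            tipy[i] = py + dy * best_s
            _bbox_include(i, tipx[i], tipy[i], bminx, bmaxx, bminy, bmaxy)
            state[i] = PAUSE
            completed = False
            break

    if completed:
        ndim[i] += 1
    return ev_count


@njit(cache=True)
def _sample_hist(row, nseg, sdx, sdy, slen):
    """Length-weighted axial direction histogram (1-degree bins, 180 bins)."""
    n = nseg.shape[0]
    for b in range(180):
        row[b] = 0.0
    for i in range(n):
        for k in range(nseg[i]):
            L = slen[i, k]
            if L <= 0.0:
                continue
            ang = np.degrees(np.arctan2(sdy[i, k], sdx[i, k])) % 180.0
            b = int(ang)
            if b > 179:
                b = 179
            row[b] += L
    return row


@njit(cache=True)
def run_core(edge_x1, edge_y1, edge_x2, edge_y2, edge_len, edge_tx, edge_ty,
             seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
             seed_dx0, seed_dy0, redraw, wait_renuc,
             state, ndim, nseg, sox, soy, sdx, sdy, slen,
             tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng,
             alpha, beta, alpha_p, beta_p, p_cat, theta_c, dimer_len,
             rule, collapse, t0, t_end, max_events,
             sample_dt, hist, sample_idx0,
             ev_t, ev_mt, ev_target, ev_angle, ev_outcome, ev_count0):
    """Exact Gillespie loop over the aggregate transition rate.

    Runs until ``t_end`` or ``max_events`` applied events, filling the
    per-sample histograms and the collision-event log.  Returns
    (t, sample_idx, ev_count, n_events_applied).
    """
    n = state.shape[0]
    rg = alpha + beta_p
    rs = alpha_p + beta
    rp = beta_p
    rc = beta
    rw = alpha_p

    n_grow = 0
    n_shrink = 0
    n_pause = 0
    n_coll = 0
    n_wait = 0
    for i in range(n):
        if state[i] == GROW:
            n_grow += 1
        elif state[i] == SHRINK:
            n_shrink += 1
        elif state[i] == PAUSE:
            n_pause += 1
        elif state[i] == COLLAPSE:
            n_coll += 1
        else:
            n_wait += 1

    t = t0
    sample_idx = sample_idx0
    n_samples = hist.shape[0]
    ev_count = ev_count0
    n_applied = 0

    while t < t_end and n_applied < max_events:
        total = n_grow * rg + n_shrink * rs + n_pause * rp + n_coll * rc + n_wait * rw
        if total <= 0.0:
            break
        u = _rng_u(rng)
        if u >= 1.0:
            u = 0.9999999999999999
        dt = -np.log(1.0 - u) / total
        t_new = t + dt

        lim = t_new if t_new < t_end else t_end
        while sample_idx < n_samples and (sample_idx + 1) * sample_dt <= lim + 1e-12:
            _sample_hist(hist[sample_idx], nseg, sdx, sdy, slen)
            sample_idx += 1

        if t_new >= t_end:
            t = t_end
            break
        t = t_new

        # pick the microtubule: first its state class, then uniformly within
        pick = _rng_u(rng) * total
        if pick < n_grow * rg:
            cls = GROW
            member = int(pick / rg)
            if member >= n_grow:
                member = n_grow - 1
        elif pick < n_grow * rg + n_shrink * rs:
            cls = SHRINK
            member = int((pick - n_grow * rg) / rs)
            if member >= n_shrink:
                member = n_shrink - 1
        elif pick < n_grow * rg + n_shrink * rs + n_pause * rp:
            cls = PAUSE
            member = int((pick - n_grow * rg - n_shrink * rs) / rp)
            if member >= n_pause:
                member = n_pause - 1
        elif pick < n_grow * rg + n_shrink * rs + n_pause * rp + n_coll * rc:
            cls = COLLAPSE
            member = int((pick - n_grow * rg - n_shrink * rs - n_pause * rp) / rc)
            if member >= n_coll:
                member = n_coll - 1
        else:
            cls = WAIT
            member = int((pick - n_grow * rg - n_shrink * rs - n_pause * rp - n_coll * rc) / rw)
            if member >= n_wait:
                member = n_wait - 1
        i = -1
        seen = -1
        for jj in range(n):
            if state[jj] == cls:
                seen += 1
                if seen == member:
                    i = jj
                    break
        if i < 0:
            i = 0  # unreachable; guards compiled code

        old_state = state[i]
        if cls == GROW:
            if _rng_u(rng) < alpha / rg:
                ev_count = _grow_step(
                    i, t, rule, p_cat, theta_c, dimer_len, collapse,
                    edge_x1, edge_y1, edge_x2, edge_y2, edge_len, edge_tx, edge_ty,
                    seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                    state, ndim, nseg, sox, soy, sdx, sdy, slen,
                    tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng,
                    ev_t, ev_mt, ev_target, ev_angle, ev_outcome, ev_count)
            else:  # spontaneous catastrophe: A_n -> B_(n-1)
                state[i] = SHRINK
                _shrink_one(i, dimer_len, redraw, wait_renuc, seed_dx0, seed_dy0,
                            seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                            state, ndim, nseg, sox, soy, sdx, sdy, slen,
                            tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng)
        elif cls == SHRINK:
            if _rng_u(rng) < beta / rs:
                _shrink_one(i, dimer_len, redraw, wait_renuc, seed_dx0, seed_dy0,
                            seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                            state, ndim, nseg, sox, soy, sdx, sdy, slen,
                            tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng)
            else:  # rescue: B_n -> A_(n+1)
                state[i] = GROW
                ev_count = _grow_step(
                    i, t, rule, p_cat, theta_c, dimer_len, collapse,
                    edge_x1, edge_y1, edge_x2, edge_y2, edge_len, edge_tx, edge_ty,
                    seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                    state, ndim, nseg, sox, soy, sdx, sdy, slen,
                    tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng,
                    ev_t, ev_mt, ev_target, ev_angle, ev_outcome, ev_count)
        elif cls == PAUSE:  # paused: only spontaneous catastrophe applies
            state[i] = SHRINK
            _shrink_one(i, dimer_len, redraw, wait_renuc, seed_dx0, seed_dy0,
                        seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                        state, ndim, nseg, sox, soy, sdx, sdy, slen,
                        tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng)
        elif cls == COLLAPSE:  # depolymerize with no rescue until zero
            _shrink_one(i, dimer_len, redraw, wait_renuc, seed_dx0, seed_dy0,
                        seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                        state, ndim, nseg, sox, soy, sdx, sdy, slen,
                        tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng)
        else:  # waiting at zero length: rescue regrows from the seed
            state[i] = GROW
            ev_count = _grow_step(
                i, t, rule, p_cat, theta_c, dimer_len, collapse,
                edge_x1, edge_y1, edge_x2, edge_y2, edge_len, edge_tx, edge_ty,
                seed_x, seed_y, seed_tx, seed_ty, seed_nx, seed_ny,
                state, ndim, nseg, sox, soy, sdx, sdy, slen,
                tipx, tipy, dirx, diry, bminx, bmaxx, bminy, bmaxy, rng,
                ev_t, ev_mt, ev_target, ev_angle, ev_outcome, ev_count)

        new_state = state[i]
        if new_state != old_state:
            if old_state == GROW:
                n_grow -= 1
            elif old_state == SHRINK:
                n_shrink -= 1
            elif old_state == PAUSE:
                n_pause -= 1
            elif old_state == COLLAPSE:
                n_coll -= 1
            else:
                n_wait -= 1
            if new_state == GROW:
                n_grow += 1
            elif new_state == SHRINK:
                n_shrink += 1
            elif new_state == PAUSE:
                n_pause += 1
            elif new_state == COLLAPSE:
                n_coll += 1
            else:
                n_wait += 1
        n_applied += 1

    if t >= t_end:
        while sample_idx < n_samples and (sample_idx + 1) * sample_dt <= t_end + 1e-12:
            _sample_hist(hist[sample_idx], nseg, sdx, sdy, slen)
            sample_idx += 1

    return t, sample_idx, ev_count, n_applied
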