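"""Compiled (numba) inner loops of the membrane and cleft simulations.

The kernels implement exactly the per-step rules of the reference NumPy
operations in :mod:`synaptrap.brownian` and :mod:`synaptrap.reactions`:
a Gaussian step, the toroidal wrap, the one-way PSD rim, end-of-step
capture inside the binding radius, and single-jump first-order kinetics.

One optimisation is used in the membrane kernel: while a receptor is
far from the PSD rim (and hence provably outside the reach of any
scaffold or rim interaction), consecutive free Gaussian steps are
aggregated into one Gaussian jump with variance summed.  This is an
exact identity for free Brownian motion on the torus; aggregation is
suspended within a conservative 8-standard-deviation margin of the rim
so that capture and reflection are still resolved step by step.
Sampling times are always respected (jumps never cross a sample
boundary).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["incorporation_kernel", "signalling_kernel"]


@njit(cache=True)
def incorporation_kernel(rx, ry, bound_to, sx, sy, s_taken,
                         half_L, r_psd, sigma, s_step, p_reflect,
                         n_steps, sample_every, start_step, seed,
                         bound_counts, freepsd_counts,
                         ev_step, ev_rec, ev_scaf, n_events_in,
                         sweep_capture):
    """Advance one replicate of the membrane diffusion-trap model.

    Arrays ``rx, ry, bound_to, s_taken`` are mutated in place, allowing
    continuation runs.  Binding events are appended to ``ev_*`` starting
    at index ``n_events_in`` with global step numbers offset by
    ``start_step``.  Counts are recorded every ``sample_every`` steps.
    With ``sweep_capture`` the whole straight displacement segment of a
    step is tested against the capture radius (continuous-path
    detection); otherwise only the step endpoint is tested.
    Returns the total number of events.
    """
    np.random.seed(seed)
    n_rec = rx.shape[0]
    n_scaf = sx.shape[0]
    sig2 = sigma * sigma
    r_psd2 = r_psd * r_psd
    reach = r_psd + sigma
    reach2 = reach * reach
    L = 2.0 * half_L

    n_events = n_events_in
    n_bound = 0
    for i in range(n_rec):
        if bound_to[i] >= 0:
            n_bound += 1
    n_free_scaf = 0
    for j in range(n_scaf):
        if not s_taken[j]:
            n_free_scaf += 1

    n_samples = n_steps // sample_every
    for samp in range(n_samples):
        step0 = samp * sample_every
        if n_bound < n_rec:
            for i in range(n_rec):
                if bound_to[i] >= 0:
                    continue
                t = 0
                while t < sample_every:
                    x = rx[i]
                    y = ry[i]
                    interacting = n_free_scaf > 0 or p_reflect > 0.0
                    if interacting:
                        # margin to anything reactive: the PSD rim
                        d = math.sqrt(x * x + y * y) - reach
                    else:
                        d = 1e30
                    remaining = sample_every - t
                    if d > 8.0 * s_step:
                        ratio2 = (d / (8.0 * s_step)) ** 2
                        k = remaining if ratio2 >= remaining else int(ratio2)
                    else:
                        k = 1
                    if k > 1:
                        sd = s_step * math.sqrt(k)
                        x += sd * np.random.standard_normal()
                        y += sd * np.random.standard_normal()
                        # toroidal wrap (aggregate jumps can exceed L)
                        x = (x + half_L) % L - half_L
                        y = (y + half_L) % L - half_L
                        rx[i] = x
                        ry[i] = y
                        t += k
                        continue
                    # single fully-resolved step
                    px = x
                    py = y
                    x += s_step * np.random.standard_normal()
                    y += s_step * np.random.standard_normal()
                    if x > half_L:
                        x -= L
                    elif x < -half_L:
                        x += L
                    if y > half_L:
                        y -= L
                    elif y < -half_L:
                        y += L
                    r2 = x * x + y * y
                    if p_reflect > 0.0 and r2 >= r_psd2:
                        x0 = rx[i]
                        y0 = ry[i]
                        if x0 * x0 + y0 * y0 < r_psd2:
                            if np.random.random() < p_reflect:
                                rr = math.sqrt(r2)
                                rn = 2.0 * r_psd - rr
                                if rn < 0.0:
                                    rn = 0.0
                                f = rn / rr
                                x *= f
                                y *= f
                                r2 = rn * rn
                    rx[i] = x
                    ry[i] = y
                    t += 1
                    # swept-path capture for an unwrapped displacement;
                    # a wrapped step (far from the PSD anyway) and a
                    # rim-folded step use the endpoint/chord test
                    seg = (sweep_capture
                           and abs(x - px) < 5.0 * s_step + 1.0
                           and abs(y - py) < 5.0 * s_step + 1.0)
                    near = r2 < reach2 or (seg and px * px + py * py
                                           < reach2)
                    if n_free_scaf > 0 and near:
                        vx = x - px
                        vy = y - py
                        c2 = vx * vx + vy * vy
                        best = -1
                        bestd = sig2
                        margin = sigma + (math.sqrt(c2) if seg else 0.0)
                        for j in range(n_scaf):
                            if s_taken[j]:
                                continue
                            dx = x - sx[j]
                            if dx > margin or dx < -margin:
                                continue
                            dy = y - sy[j]
                            if dy > margin or dy < -margin:
                                continue
                            if seg:
                                wx = sx[j] - px
                                wy = sy[j] - py
                                c1 = wx * vx + wy * vy
                                if c1 <= 0.0:
                                    d2 = wx * wx + wy * wy
                                elif c1 >= c2:
                                    d2 = dx * dx + dy * dy
                                else:
                                    tt = c1 / c2
                                    ex = wx - tt * vx
                                    ey = wy - tt * vy
                                    d2 = ex * ex + ey * ey
                            else:
                                d2 = dx * dx + dy * dy
                            if d2 < bestd:
                                bestd = d2
                                best = j
                        if best >= 0:
                            bound_to[i] = best
                            s_taken[best] = True
                            rx[i] = sx[best]
                            ry[i] = sy[best]
                            n_bound += 1
                            n_free_scaf -= 1
                            ev_step[n_events] = start_step + step0 + t
                            ev_rec[n_events] = i
                            ev_scaf[n_events] = best
                            n_events += 1
                            break
        nf = 0
        for i in range(n_rec):
            if bound_to[i] < 0 and rx[i] * rx[i] + ry[i] * ry[i] < r_psd2:
                nf += 1
        bound_counts[samp] = n_bound
        freepsd_counts[samp] = nf
    return n_events


@njit(cache=True)
def signalling_kernel(rec_x, rec_y, rec_state, is_new,
                      gx, gy, gz, n_glu,
                      half_L, half_D, height, s_glu,
                      sig_bind, dest_bind, sig_unbind,
                      p_leave, dest_cum, release_flag,
                      n_steps, seed,
                      open_total, open_new, ever_open, counters):
    """Advance one replicate of the cleft glutamate-signalling model.

    Receptors are static points on the floor (z = 0) inside the PSD.
    Per step: free 3D Gaussian glutamate displacement, mirror at floor
    and ceiling, absorption at the side walls, capture within the
    state-dependent binding radius, then first-order gating/unbinding
    with at most one transition per receptor per step.  Glutamate
    released by unbinding is placed at the unbinding radius in a random
    direction and folded back into the cleft.

    ``rec_state`` and the glutamate arrays are mutated in place;
    returns the number of free glutamate molecules left.
    """
    np.random.seed(seed)
    n_rec = rec_x.shape[0]
    n_states = sig_bind.shape[0]
    sig_max = 0.0
    for s in range(n_states):
        if sig_bind[s] > sig_max:
            sig_max = sig_bind[s]

    for step in range(n_steps):
        # -- glutamate diffusion, walls, capture --
        g = 0
        while g < n_glu:
            x = gx[g] + s_glu * np.random.standard_normal()
            y = gy[g] + s_glu * np.random.standard_normal()
            z = gz[g] + s_glu * np.random.standard_normal()
            # mirror at floor and ceiling (repeated reflection)
            z = z % (2.0 * height)
            z = height - abs(height - z)
            if x > half_L or x < -half_L or y > half_D or y < -half_D:
                n_glu -= 1
                gx[g] = gx[n_glu]
                gy[g] = gy[n_glu]
                gz[g] = gz[n_glu]
                counters[0] += 1
                continue
            gx[g] = x
            gy[g] = y
            gz[g] = z
            if z < sig_max:
                captured = False
                for r in range(n_rec):
                    sig = sig_bind[rec_state[r]]
                    if sig <= z:
                        continue
                    dx = x - rec_x[r]
                    if dx > sig or dx < -sig:
                        continue
                    dy = y - rec_y[r]
                    if dy > sig or dy < -sig:
                        continue
                    if dx * dx + dy * dy + z * z < sig * sig:
                        rec_state[r] = dest_bind[rec_state[r]]
                        n_glu -= 1
                        gx[g] = gx[n_glu]
                        gy[g] = gy[n_glu]
                        gz[g] = gz[n_glu]
                        counters[1] += 1
                        captured = True
                        break
                if captured:
                    continue
            g += 1

        # -- first-order receptor transitions --
        for r in range(n_rec):
            s = rec_state[r]
            if p_leave[s] <= 0.0:
                continue
            if np.random.random() < p_leave[s]:
                u = np.random.random()
                dest = n_states - 1
                for j in range(n_states):
                    if u < dest_cum[s, j]:
                        dest = j
                        break
                if release_flag[s, dest]:
                    # place freed glutamate at the unbinding radius
                    su = sig_unbind[s]
                    cz = 2.0 * np.random.random() - 1.0
                    phi = 2.0 * math.pi * np.random.random()
                    st = math.sqrt(1.0 - cz * cz)
                    x = rec_x[r] + su * st * math.cos(phi)
                    y = rec_y[r] + su * st * math.sin(phi)
                    z = abs(su * cz)
                    if z > height:
                        z = height
                    if x > half_L:
                        x = half_L
                    elif x < -half_L:
                        x = -half_L
                    if y > half_D:
                        y = half_D
                    elif y < -half_D:
                        y = -half_D
                    gx[n_glu] = x
                    gy[n_glu] = y
                    gz[n_glu] = z
                    n_glu += 1
                    counters[2] += 1
                rec_state[r] = dest

        # -- record open channels (state index 3) --
        tot = 0
        new = 0
        for r in range(n_rec):
            if rec_state[r] == 3:
                tot += 1
                ever_open[r] = True
                if is_new[r]:
                    new += 1
        open_total[step] = tot
        open_new[step] = new
    return n_glu
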