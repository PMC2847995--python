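"""Compound model: receptor incorporation interleaved with glutamate
signalling, measuring the contribution of newly trapped receptors to
the synaptic signal.

Each cycle simulates 100 ms of membrane diffusion-trapping; the set of
mobile receptors scaffold-bound by 90 ms into the segment joins the
immobile signalling pool at the scaffold positions (the spine PSD disk
and the cleft PSD disk share the same origin, so positions carry over
directly).  A 10 ms glutamate-release simulation is then run over the
100 permanently resident receptors plus all receptors incorporated so
far, carrying every receptor's kinetic state from cycle to cycle.  The
per-cycle observables are the peak-time contribution of newly
incorporated receptors to the open count and the lateral distance of
the contributing new receptors from the release axis.

Mobile receptors that are still unbound lie in the extra-synaptic
membrane, outside the cleft footprint, and therefore do not interact
with glutamate during the signalling segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .incorporation import IncorporationConfig, _SEED_MOD
from .placement import (sample_disk_uniform, sample_receptor_positions,
                        sample_scaffold_positions)
from .signalling import (SignalTrace, SignallingConfig, prepare_tables,
                         run_signalling_replicate)

__all__ = ["CompoundConfig", "CompoundResult", "run_compound",
           "contribution_metrics"]


@dataclass(frozen=True)
class CompoundConfig:
    """55 mobile receptors + 55 scaffolds in the spine membrane, 100
    static receptors in the PSD; 100 ms incorporation segments
    (snapshot at 90 ms) alternating with 10 ms signalling segments."""

    incorporation: IncorporationConfig = field(
        default_factory=lambda: IncorporationConfig(t_end=0.1))
    signalling: SignallingConfig = field(
        default_factory=lambda: SignallingConfig())
    n_static: int = 100
    n_cycles: int = 8
    segment_t: float = 0.1     # s of membrane diffusion per cycle
    snapshot_t: float = 0.09   # s into the segment at which the pool is taken
    n_replicates: int = 30
    base_seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.snapshot_t <= self.segment_t):
            raise ValueError("snapshot time must lie within the segment")
        if self.n_cycles < 1 or self.n_replicates < 1:
            raise ValueError("need at least one cycle and one replicate")


@dataclass
class CompoundResult:
    """Per-cycle ensemble summaries plus the underlying traces."""

    cycle_end_time: np.ndarray      # (n_cycles,) s of membrane time
    bound_mean: np.ndarray          # (n_cycles,) receptors in the pool
    percent_new: np.ndarray         # (n_cycles,) peak-time contribution, %
    mean_distance: np.ndarray       # (n_cycles,) nm, contributing new rec.
    sd_distance: np.ndarray         # (n_cycles,) nm
    traces: list[SignalTrace]       # one ensemble trace per cycle
    config: CompoundConfig


def contribution_metrics(trace: SignalTrace,
                         ) -> tuple[float | None, float | None, float | None]:
    """Contribution of tagged-new receptors to the ensemble peak.

    ``percent_new`` is 100 x (mean open count among new receptors at the
    peak of the ensemble-mean total) / (mean total at the peak); the
    distance statistics are taken over every new receptor that opened at
    least once during the segment (pooled across replicates), measured
    from the release axis (x = y = 0).

    Returns ``(percent_new, mean_distance, sd_distance)``; the
    percentage is None when the total peak is zero, the distances are
    None when no new receptor opened.
    """
    mean_total = trace.mean_open
    if mean_total.size == 0 or mean_total.max() <= 0:
        return None, None, None
    i_peak = int(np.argmax(mean_total))
    percent = 100.0 * trace.mean_open_new[i_peak] / mean_total[i_peak]
    new_opened = trace.is_new & trace.ever_open
    if not np.any(new_opened):
        return float(percent), None, None
    xy = trace.receptor_xy[new_opened]
    dist = np.hypot(xy[:, 0], xy[:, 1])
    return float(percent), float(dist.mean()), float(dist.std(ddof=0))


def run_compound(config: CompoundConfig) -> CompoundResult:
    inc = config.incorporation
    sig = config.signalling
    geom = inc.geometry
    seg_steps = int(round(config.segment_t / inc.dt))
    snap_steps = int(round(config.snapshot_t / inc.dt))
    sig_steps = sig.n_steps
    tables = prepare_tables(sig)
    n_mob = inc.n_receptors
    n_stat = config.n_static
    n_rep = config.n_replicates
    n_cyc = config.n_cycles

    open_tot = np.zeros((n_cyc, n_rep, sig_steps), dtype=np.int64)
    open_new = np.zeros((n_cyc, n_rep, sig_steps), dtype=np.int64)
    ever_new = [[None] * n_rep for _ in range(n_cyc)]
    pool_sizes = np.zeros((n_cyc, n_rep))
    xy_cycles = [[None] * n_rep for _ in range(n_cyc)]
    tags_cycles = [[None] * n_rep for _ in range(n_cyc)]
    states_cycles = [[None] * n_rep for _ in range(n_cyc)]

    for rep in range(n_rep):
        rep_seed = (config.base_seed + rep) % _SEED_MOD
        rng = np.random.default_rng(rep_seed)
        seg_seeds = rng.integers(_SEED_MOD, size=2 * n_cyc)
        rec = sample_receptor_positions(inc.receptor_placement, n_mob,
                                        geom, rng)
        scaf = sample_scaffold_positions(inc.scaffold_placement,
                                         inc.n_scaffolds, geom, rng)
        static_xy = sample_disk_uniform(n_stat, sig.cleft.r_PSD, rng,
                                        sig.receptor_disk_mode)
        rx = np.ascontiguousarray(rec[:, 0])
        ry = np.ascontiguousarray(rec[:, 1])
        sx = np.ascontiguousarray(scaf[:, 0])
        sy = np.ascontiguousarray(scaf[:, 1])
        bound_to = np.full(n_mob, -1, dtype=np.int64)
        s_taken = np.zeros(inc.n_scaffolds, dtype=np.bool_)
        ev_step = np.zeros(max(min(n_mob, inc.n_scaffolds), 1), np.int64)
        ev_rec = np.zeros_like(ev_step)
        ev_scaf = np.zeros_like(ev_step)
        n_events = 0
        mobile_states = np.zeros(n_mob, dtype=np.int64)  # kinetic states
        static_states = np.zeros(n_stat, dtype=np.int64)
        b_cnt = np.zeros(max(seg_steps // seg_steps, 1), dtype=np.int64)
        f_cnt = np.zeros_like(b_cnt)

        for cyc in range(n_cyc):
            start = cyc * seg_steps
            n_events = _kernels.incorporation_kernel(
                rx, ry, bound_to, sx, sy, s_taken,
                geom.L_side / 2.0, geom.r_PSD,
                inc.sigma_bind, inc.step_sd, inc.p_reflect,
                seg_steps, seg_steps, start, int(seg_seeds[2 * cyc]),
                b_cnt, f_cnt, ev_step, ev_rec, ev_scaf, n_events,
                inc.capture_mode == "segment")
            cutoff = start + snap_steps
            in_pool = np.array([ev_rec[k] for k in range(n_events)
                                if ev_step[k] <= cutoff], dtype=np.int64)
            pool_xy = np.concatenate(
                [static_xy,
                 np.column_stack((rx[in_pool], ry[in_pool]))])
            pool_states = np.concatenate(
                [static_states, mobile_states[in_pool]])
            tags = np.zeros(len(pool_xy), dtype=bool)
            tags[n_stat:] = True
            ot, on, ev, fin, _, _ = run_signalling_replicate(
                sig, int(seg_seeds[2 * cyc + 1]), pool_xy, pool_states,
                tags, tables)
            open_tot[cyc, rep] = ot
            open_new[cyc, rep] = on
            ever_new[cyc][rep] = ev
            xy_cycles[cyc][rep] = pool_xy
            tags_cycles[cyc][rep] = tags
            states_cycles[cyc][rep] = fin
            pool_sizes[cyc, rep] = len(in_pool)
            # carry kinetic states back for the next cycle
            static_states = fin[:n_stat].copy()
            mobile_states[in_pool] = fin[n_stat:]

    time = np.arange(1, sig_steps + 1) * sig.dt
    traces: list[SignalTrace] = []
    percent = np.full(n_cyc, np.nan)
    mean_d = np.full(n_cyc, np.nan)
    sd_d = np.full(n_cyc, np.nan)
    for cyc in range(n_cyc):
        n_max = max(len(x) for x in xy_cycles[cyc])
        xy = np.zeros((n_rep, n_max, 2))
        tags = np.zeros((n_rep, n_max), dtype=bool)
        ever = np.zeros((n_rep, n_max), dtype=bool)
        fins = np.zeros((n_rep, n_max), dtype=np.int64)
        for rep in range(n_rep):
            m = len(xy_cycles[cyc][rep])
            xy[rep, :m] = xy_cycles[cyc][rep]
            tags[rep, :m] = tags_cycles[cyc][rep]
            ever[rep, :m] = ever_new[cyc][rep]
            fins[rep, :m] = states_cycles[cyc][rep]
        tr = SignalTrace(time=time, open=open_tot[cyc], open_new=open_new[cyc],
                         ever_open=ever, final_states=fins,
                         glu_left=np.zeros(n_rep, dtype=np.int64),
                         glu_counters=np.zeros((n_rep, 3), dtype=np.int64),
                         receptor_xy=xy, is_new=tags, n_receptors=n_stat,
                         seeds=[], config=sig)
        traces.append(tr)
        p, md, sd = contribution_metrics(tr)
        percent[cyc] = np.nan if p is None else p
        mean_d[cyc] = np.nan if md is None else md
        sd_d[cyc] = np.nan if sd is None else sd

    return CompoundResult(
        cycle_end_time=(np.arange(1, n_cyc + 1) * config.segment_t),
        bound_mean=pool_sizes.mean(axis=1),
        percent_new=percent, mean_distance=mean_d, sd_distance=sd_d,
        traces=traces, config=config)
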