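"""The membrane diffusion-trap experiment: mobile receptors in the ESM
binding static scaffolds in the PSD.

``run_incorporation`` executes an ensemble of replicates of the
reference model (or any variant reachable through
:class:`IncorporationConfig`) and returns bound / free-in-PSD /
free-in-ESM time series.  ``run_sweep`` repeats the run across a
parameter range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .geometry import SpineGeometry, derive_spine_geometry
from .placement import (PlacementSpec, sample_receptor_positions,
                        sample_scaffold_positions)

__all__ = ["IncorporationConfig", "TimeSeriesResult", "run_incorporation",
           "run_sweep", "SWEEPABLE"]

_SEED_MOD = 2 ** 31


@dataclass(frozen=True)
class IncorporationConfig:
    """Configuration of the diffusion-trap run.

    Defaults are the reference model: a 0.5 µm³ spine with a 9% PSD,
    55 receptors at D = 0.45 µm²/s starting uniformly in the ESM, 55
    uniformly placed scaffolds, binding radius 0.5 nm, open PSD rim,
    1 µs steps for 5 s, 30 replicates.
    """

    geometry: SpineGeometry = field(
        default_factory=lambda: derive_spine_geometry(0.5, 0.09))
    n_receptors: int = 55
    n_scaffolds: int = 55
    scaffold_ratio: float | None = None   # overrides n_scaffolds if set
    D_AMPAR: float = 0.45                 # µm²/s
    sigma_bind: float = 0.5               # nm
    p_reflect: float = 0.0
    scaffold_placement: PlacementSpec = field(
        default_factory=lambda: PlacementSpec("scaffold_uniform"))
    receptor_placement: PlacementSpec = field(
        default_factory=lambda: PlacementSpec("esm_uniform"))
    dt: float = 1e-6                      # s
    t_end: float = 5.0                    # s
    n_replicates: int = 30
    base_seed: int = 1
    sample_interval: int = 1000           # steps between samples (1 ms)
    #: capture detection: 'segment' tests the whole straight step path
    #: against the binding radius, 'endpoint' only the step's end
    capture_mode: str = "segment"

    def __post_init__(self) -> None:
        if self.n_receptors < 0 or self.n_scaffolds < 0:
            raise ValueError("particle counts must be non-negative")
        if self.scaffold_ratio is not None:
            if self.scaffold_ratio < 0:
                raise ValueError("scaffold_ratio must be non-negative")
            object.__setattr__(self, "n_scaffolds",
                               int(round(self.scaffold_ratio
                                         * self.n_receptors)))
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        n_steps = self.t_end / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("t_end must be an integer number of steps")
        if not (0.0 <= self.p_reflect <= 1.0):
            raise ValueError("p_reflect must lie in [0, 1]")
        if self.sigma_bind < 0 or self.D_AMPAR < 0:
            raise ValueError("sigma_bind and D_AMPAR must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if self.capture_mode not in ("segment", "endpoint"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))

    @property
    def step_sd(self) -> float:
        """Per-axis rms step length in nm."""
        return math.sqrt(2.0 * self.D_AMPAR * 1e6 * self.dt)


@dataclass
class TimeSeriesResult:
    """Ensemble bound / free-in-PSD counts on a regular time grid.

    ``bound`` and ``free_psd`` have shape (n_replicates, n_samples);
    the grid includes t = 0.  ``free_esm`` follows from receptor
    conservation.
    """

    time: np.ndarray
    bound: np.ndarray
    free_psd: np.ndarray
    n_receptors: int
    n_scaffolds: int
    seeds: list[int]
    config: IncorporationConfig

    @property
    def free_esm(self) -> np.ndarray:
        return self.n_receptors - self.bound - self.free_psd

    @property
    def bound_mean(self) -> np.ndarray:
        return self.bound.mean(axis=0)

    @property
    def occupied_fraction_mean(self) -> np.ndarray:
        """Ensemble-mean fraction of the limiting species that is bound
        (the denominator of the half-saturation time)."""
        denom = min(self.n_receptors, self.n_scaffolds)
        if denom == 0:
            return np.zeros_like(self.bound_mean)
        return self.bound_mean / denom

    @property
    def bound_fraction_mean(self) -> np.ndarray:
        if self.n_receptors == 0:
            return np.zeros_like(self.bound_mean)
        return self.bound_mean / self.n_receptors


def _replicate_state(config: IncorporationConfig, seed: int):
    rng = np.random.default_rng(seed)
    rec = sample_receptor_positions(config.receptor_placement,
                                    config.n_receptors, config.geometry, rng)
    scaf = sample_scaffold_positions(config.scaffold_placement,
                                     config.n_scaffolds, config.geometry, rng)
    return rec, scaf


def run_incorporation(config: IncorporationConfig) -> TimeSeriesResult:
    """Run the ensemble and return counts sampled every
    ``config.sample_interval`` steps (plus the t = 0 sample)."""
    n_steps = config.n_steps
    every = config.sample_interval
    n_samples = n_steps // every
    time = np.concatenate(([0.0],
                           (np.arange(1, n_samples + 1) * every * config.dt)))
    bound = np.zeros((config.n_replicates, n_samples + 1), dtype=np.int64)
    free_psd = np.zeros_like(bound)
    seeds = [(config.base_seed + i) % _SEED_MOD
             for i in range(config.n_replicates)]

    for rep, seed in enumerate(seeds):
        rec, scaf = _replicate_state(config, seed)
        rx = np.ascontiguousarray(rec[:, 0]) if len(rec) else np.empty(0)
        ry = np.ascontiguousarray(rec[:, 1]) if len(rec) else np.empty(0)
        sx = np.ascontiguousarray(scaf[:, 0]) if len(scaf) else np.empty(0)
        sy = np.ascontiguousarray(scaf[:, 1]) if len(scaf) else np.empty(0)
        bound_to = np.full(len(rec), -1, dtype=np.int64)
        s_taken = np.zeros(len(scaf), dtype=np.bool_)
        b_counts = np.zeros(n_samples, dtype=np.int64)
        f_counts = np.zeros(n_samples, dtype=np.int64)
        n_max = min(len(rec), len(scaf)) if len(scaf) else 0
        ev_step = np.zeros(max(n_max, 1), dtype=np.int64)
        ev_rec = np.zeros(max(n_max, 1), dtype=np.int64)
        ev_scaf = np.zeros(max(n_max, 1), dtype=np.int64)
        if len(rec):
            _kernels.incorporation_kernel(
                rx, ry, bound_to, sx, sy, s_taken,
                config.geometry.L_side / 2.0, config.geometry.r_PSD,
                config.sigma_bind, config.step_sd, config.p_reflect,
                n_steps, every, 0, seed,
                b_counts, f_counts, ev_step, ev_rec, ev_scaf, 0,
                config.capture_mode == "segment")
            # count of free receptors inside the PSD at t = 0
            free_psd[rep, 0] = int(((rec ** 2).sum(axis=1)
                                    < config.geometry.r_PSD ** 2).sum())
        bound[rep, 1:] = b_counts
        free_psd[rep, 1:] = f_counts

    return TimeSeriesResult(time=time, bound=bound, free_psd=free_psd,
                            n_receptors=config.n_receptors,
                            n_scaffolds=config.n_scaffolds,
                            seeds=seeds, config=config)


SWEEPABLE = ("sigma_bind", "D_AMPAR", "p_reflect", "scaffold_ratio",
             "scaffold_placement", "receptor_placement")


def run_sweep(base: IncorporationConfig, parameter: str,
              values: list) -> list[TimeSeriesResult]:
    """Run one ensemble per value of ``parameter`` (a field name from
    ``SWEEPABLE``), all other settings held at ``base``."""
    if parameter not in SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; one of {SWEEPABLE}")
    return [run_incorporation(replace(base, **{parameter: v}))
            for v in values]
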