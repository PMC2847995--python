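"""Structured run configuration (YAML) and tab-delimited text output.

The configuration is a flat set of per-experiment blocks; unknown keys
are rejected with the offending key path.  Units follow the package
conventions: lengths nm, times s, diffusion coefficients µm²/s (except
``D_glu`` in µm²/ms), volumes µm³, rates M⁻¹s⁻¹.

Every emitted file starts with ``#``-prefixed header lines recording
the package version, a hash of the configuration, and the seeds used,
so that any output can be traced back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .compound import CompoundConfig
from .geometry import build_cleft_geometry, derive_spine_geometry
from .incorporation import IncorporationConfig, TimeSeriesResult
from .placement import PlacementSpec
from .reactions import jonas_scheme
from .signalling import SignallingConfig

__all__ = ["RunConfig", "load_config", "write_timeseries", "config_hash"]

EXPERIMENTS = ("incorporation", "signalling", "compound", "sweep", "rates",
               "analyze")


@dataclass
class RunConfig:
    experiment: str = "incorporation"
    base_seed: int = 1
    n_replicates: int | None = None
    out_dir: str = "results"
    log_level: str = "info"
    incorporation: IncorporationConfig = field(
        default_factory=IncorporationConfig)
    signalling: SignallingConfig = field(default_factory=SignallingConfig)
    compound: CompoundConfig | None = None
    sweep_parameter: str | None = None
    sweep_values: list | None = None
    rates: dict = field(default_factory=dict)


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    for key in block:
        if key not in allowed:
            raise ValueError(f"unknown configuration key {path}.{key!r}")


def _placement_from(block: dict, default_kind: str, path: str) -> PlacementSpec:
    allowed = {"kind", "disk_mode", "segment_probs", "patch_radius",
               "patch_offset", "batch_sizes"}
    _check_keys(block, allowed, path)
    kw = dict(block)
    kw.setdefault("kind", default_kind)
    if "segment_probs" in kw:
        kw["segment_probs"] = tuple(kw["segment_probs"])
    if "batch_sizes" in kw and kw["batch_sizes"] is not None:
        kw["batch_sizes"] = tuple(kw["batch_sizes"])
    return PlacementSpec(**kw)


def load_config(path: str | Path | None = None,
                data: dict | None = None) -> RunConfig:
    """Load and validate a run configuration.

    An empty configuration yields the reference model (0.5 µm³ spine,
    9% PSD, D = 0.45 µm²/s, σ = 0.5 nm, 55 receptors / 55 scaffolds,
    1 µs steps).  Validation errors name the offending key path.
    """
    if data is None:
        data = {}
        if path is not None:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    top_allowed = {"experiment", "seed", "replicates", "out_dir", "log_level",
                   "geometry", "incorporation", "signalling", "compound",
                   "sweep", "rates"}
    _check_keys(data, top_allowed, "")
    experiment = data.get("experiment", "incorporation")
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}; "
                         f"one of {EXPERIMENTS}")

    geo_block = dict(data.get("geometry") or {})
    _check_keys(geo_block, {"V_spine", "psd_fraction", "d_neck"}, "geometry")
    geometry = derive_spine_geometry(
        geo_block.get("V_spine", 0.5), geo_block.get("psd_fraction", 0.09),
        d_neck=geo_block.get("d_neck", 872.5))

    inc_block = dict(data.get("incorporation") or {})
    inc_allowed = {"n_receptors", "n_scaffolds", "scaffold_ratio", "D_AMPAR",
                   "sigma_bind", "p_reflect", "dt", "t_end", "n_replicates",
                   "sample_interval", "scaffold_placement",
                   "receptor_placement"}
    _check_keys(inc_block, inc_allowed, "incorporation")
    if "scaffold_placement" in inc_block:
        inc_block["scaffold_placement"] = _placement_from(
            inc_block["scaffold_placement"], "scaffold_uniform",
            "incorporation.scaffold_placement")
    if "receptor_placement" in inc_block:
        inc_block["receptor_placement"] = _placement_from(
            inc_block["receptor_placement"], "esm_uniform",
            "incorporation.receptor_placement")
    incorporation = IncorporationConfig(geometry=geometry,
                                        base_seed=data.get("seed", 1),
                                        **inc_block)

    sig_block = dict(data.get("signalling") or {})
    sig_allowed = {"n_receptors", "dt", "t_end", "n_replicates",
                   "temperature_adjusted", "floor_correction",
                   "sigma_unbind_scale", "receptor_disk_mode", "cleft"}
    _check_keys(sig_block, sig_allowed, "signalling")
    cleft_block = dict(sig_block.pop("cleft", {}) or {})
    _check_keys(cleft_block, {"length", "depth", "height", "r_PSD",
                              "n_glutamate", "D_glu"}, "signalling.cleft")
    cleft = build_cleft_geometry(**cleft_block)
    adjusted = sig_block.pop("temperature_adjusted", True)
    signalling = SignallingConfig(cleft=cleft,
                                  scheme=jonas_scheme(adjusted),
                                  base_seed=data.get("seed", 1), **sig_block)

    comp_block = dict(data.get("compound") or {})
    _check_keys(comp_block, {"n_static", "n_cycles", "segment_t",
                             "snapshot_t", "n_replicates"}, "compound")
    compound = None
    if experiment == "compound" or comp_block:
        compound = CompoundConfig(
            incorporation=incorporation, signalling=signalling,
            base_seed=data.get("seed", 1), **comp_block)

    sweep_block = dict(data.get("sweep") or {})
    _check_keys(sweep_block, {"parameter", "values"}, "sweep")
    rates_block = dict(data.get("rates") or {})
    _check_keys(rates_block, {"D_mutual", "dt", "sigmas", "rate_constants"},
                "rates")

    return RunConfig(
        experiment=experiment, base_seed=data.get("seed", 1),
        n_replicates=data.get("replicates"),
        out_dir=data.get("out_dir", "results"),
        log_level=data.get("log_level", "info"),
        incorporation=incorporation, signalling=signalling,
        compound=compound,
        sweep_parameter=sweep_block.get("parameter"),
        sweep_values=sweep_block.get("values"), rates=rates_block)


def config_hash(obj) -> str:
    """Short stable hash of a configuration's repr (provenance echo)."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _header_lines(config, seeds, extra: dict | None = None) -> list[str]:
    from . import __version__
    lines = [f"# synaptrap {__version__}",
             f"# config_hash: {config_hash(config)}",
             f"# seeds: {json.dumps(list(map(int, seeds)))}"]
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(f"# config: {config!r}")
    return lines


def write_timeseries(result: TimeSeriesResult, path: str | Path,
                     quantity: str = "bound") -> Path:
    """Write a tab-delimited ensemble time series.

    Columns: time (s), one column per replicate, ensemble mean.
    ``quantity`` selects bound counts (default), ``free_psd`` or
    ``free_esm``.  Fixed 6-significant-digit formatting keeps repeated
    runs byte-identical.
    """
    data = getattr(result, quantity)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_rep = data.shape[0]
    with open(path, "w") as fh:
        for line in _header_lines(result.config, result.seeds,
                                  {"quantity": quantity}):
            fh.write(line + "\n")
        cols = ["time_s"] + [f"rep{i}" for i in range(n_rep)] + ["mean"]
        fh.write("\t".join(cols) + "\n")
        mean = data.mean(axis=0)
        for j, t in enumerate(result.time):
            row = [f"{t:.6g}"] + [f"{data[i, j]:.6g}" for i in range(n_rep)]
            row.append(f"{mean[j]:.6g}")
            fh.write("\t".join(row) + "\n")
    return path


def write_signal_trace(trace, path: str | Path) -> Path:
    """Tab-delimited open-count trace: time, per-replicate, mean."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n_rep = trace.open.shape[0]
    with open(path, "w") as fh:
        for line in _header_lines(trace.config, trace.seeds,
                                  {"quantity": "open_count"}):
            fh.write(line + "\n")
        cols = ["time_s"] + [f"rep{i}" for i in range(n_rep)] + ["mean"]
        fh.write("\t".join(cols) + "\n")
        mean = trace.open.mean(axis=0)
        for j, t in enumerate(trace.time):
            row = [f"{t:.6g}"] + [f"{trace.open[i, j]:d}"
                                  for i in range(n_rep)]
            row.append(f"{mean[j]:.6g}")
            fh.write("\t".join(row) + "\n")
    return path


def write_compound_summary(result, path: str | Path) -> Path:
    """Per-cycle summary table of the compound model."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _header_lines(result.config, [result.config.base_seed]):
            fh.write(line + "\n")
        fh.write("cycle_end_s\tbound_mean\tpercent_new\t"
                 "mean_distance_nm\tsd_distance_nm\n")
        for c in range(len(result.cycle_end_time)):
            fh.write(f"{result.cycle_end_time[c]:.6g}\t"
                     f"{result.bound_mean[c]:.6g}\t"
                     f"{result.percent_new[c]:.6g}\t"
                     f"{result.mean_distance[c]:.6g}\t"
                     f"{result.sd_distance[c]:.6g}\n")
    return path


def read_timeseries(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a file written by :func:`write_timeseries`; returns
    ``(time, per_replicate_data)`` (mean column excluded)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("time_s"):
                continue
            rows.append([float(x) for x in line.split("\t")])
    arr = np.asarray(rows)
    return arr[:, 0], arr[:, 1:-1].T
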