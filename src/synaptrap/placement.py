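"""Initial-position samplers for scaffolds (inside the PSD disk) and
receptors (in the extra-synaptic membrane).

Scaffold distributions
----------------------
``scaffold_uniform``
    Polar sampling of the PSD disk: an angle from U(0, 2*pi) and a
    radius ``sqrt(R) * r_PSD`` with R ~ U(0, 1) (``mode='area'``, the
    default: uniform per unit area) or ``R * r_PSD`` (``mode='radial'``,
    which concentrates density toward the centre).  The reproduced
    half-saturation observables of the membrane model identify the
    area-uniform convention; the centre-biased variant is kept because
    the static cleft receptors of the signalling model follow it.
``scaffold_annular``
    The disk is divided into five concentric rings of equal thickness;
    a ring is chosen according to ``segment_probs`` and the point placed
    uniformly (radially) within it.  The ring weights estimated from
    immunogold labelling are not publicly tabulated, so the default is
    a flat placeholder and results that depend on it are indicative
    only.
``scaffold_patch``
    Points are drawn as for the uniform distribution and kept only if
    they fall inside one of five disks of radius 96 nm whose centres
    sit 194.4 nm from the PSD centre at the vertices of a pentagon.

Receptor sources
----------------
``esm_uniform``
    Uniform on the square membrane with rejection of points inside the
    PSD disk.
``esm_ring``
    Uniform on the circle of radius ``d_neck`` (spine-neck contact).
``esm_point_sources``
    Three release points drawn once on the circle of radius ``d_half``;
    the receptors are split into three co-located batches (18 + 18 + 19
    for the default 55).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import SpineGeometry

__all__ = [
    "PlacementSpec",
    "SCAFFOLD_KINDS",
    "RECEPTOR_KINDS",
    "sample_scaffold_positions",
    "sample_receptor_positions",
    "sample_disk_uniform",
]

SCAFFOLD_KINDS = ("scaffold_uniform", "scaffold_annular", "scaffold_patch")
RECEPTOR_KINDS = ("esm_uniform", "esm_ring", "esm_point_sources")

PATCH_RADIUS_NM = 96.0
PATCH_CENTRE_OFFSET_NM = 194.4
_FLAT_SEGMENTS = (0.2, 0.2, 0.2, 0.2, 0.2)


@dataclass(frozen=True)
class PlacementSpec:
    """A named initial-position distribution plus its parameters."""

    kind: str
    #: 'area' places points uniformly per unit area (r = sqrt(R) * r_PSD),
    #: the default for the membrane model; 'radial' is the literal polar
    #: transform r = R * r_PSD, which concentrates density toward the centre
    disk_mode: str = "area"
    #: five ring weights for the annular distribution (must sum to 1)
    segment_probs: tuple[float, ...] = _FLAT_SEGMENTS
    patch_radius: float = PATCH_RADIUS_NM
    patch_offset: float = PATCH_CENTRE_OFFSET_NM
    #: receptor batch sizes for point sources; None splits n evenly in 3
    batch_sizes: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCAFFOLD_KINDS + RECEPTOR_KINDS:
            raise ValueError(f"unknown placement kind {self.kind!r}")
        if self.disk_mode not in ("radial", "area"):
            raise ValueError(f"unknown disk_mode {self.disk_mode!r}")
        p = np.asarray(self.segment_probs, dtype=float)
        if p.size != 5 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(
                "segment_probs must be 5 non-negative weights summing to 1")


def sample_disk_uniform(n: int, radius: float, rng: np.random.Generator,
                        mode: str = "radial") -> np.ndarray:
    """Sample n points in a disk by the polar transform.

    ``mode='radial'`` : r = R * radius with R ~ U(0,1)  (centre biased,
    mean radial distance radius/2);
    ``mode='area'``   : r = sqrt(R) * radius  (area uniform, mean radial
    distance 2*radius/3).
    """
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    R = rng.uniform(0.0, 1.0, n)
    r = radius * (R if mode == "radial" else np.sqrt(R))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi)))


def _patch_centres(offset: float) -> np.ndarray:
    ang = 2.0 * math.pi * np.arange(5) / 5.0
    return np.column_stack((offset * np.cos(ang), offset * np.sin(ang)))


def sample_scaffold_positions(spec: PlacementSpec, n: int,
                              geom: SpineGeometry,
                              rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` scaffold positions (nm, shape (n, 2)) inside the PSD."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if spec.kind not in SCAFFOLD_KINDS:
        raise ValueError(f"{spec.kind!r} is not a scaffold distribution")
    if n == 0:
        return np.empty((0, 2))
    r_psd = geom.r_PSD

    if spec.kind == "scaffold_uniform":
        return sample_disk_uniform(n, r_psd, rng, spec.disk_mode)

    if spec.kind == "scaffold_annular":
        edges = np.linspace(0.0, r_psd, 6)
        seg = rng.choice(5, size=n, p=np.asarray(spec.segment_probs))
        lo, hi = edges[seg], edges[seg + 1]
        if spec.disk_mode == "radial":
            r = rng.uniform(lo, hi)
        else:  # area-uniform within the ring
            r = np.sqrt(rng.uniform(lo ** 2, hi ** 2))
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        return np.column_stack((r * np.cos(phi), r * np.sin(phi)))

    # patch: rejection of the uniform sampler into the five pentagon disks
    centres = _patch_centres(spec.patch_offset)
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = sample_disk_uniform(max(2 * (n - got), 64), r_psd, rng,
                                   spec.disk_mode)
        d2 = ((cand[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
        ok = (d2 < spec.patch_radius ** 2).any(axis=1)
        cand = cand[ok]
        take = min(len(cand), n - got)
        out[got:got + take] = cand[:take]
        got += take
    return out


def _split_batches(n: int, batch_sizes: tuple[int, ...] | None) -> list[int]:
    if batch_sizes is not None:
        if sum(batch_sizes) != n:
            raise ValueError(
                f"batch sizes {batch_sizes} do not sum to n={n}")
        return list(batch_sizes)
    k = n // 3
    return [k, k, n - 2 * k]


def sample_receptor_positions(spec: PlacementSpec, n: int,
                              geom: SpineGeometry,
                              rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` receptor positions (nm, shape (n, 2)) in the ESM."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if spec.kind not in RECEPTOR_KINDS:
        raise ValueError(f"{spec.kind!r} is not a receptor source")
    if n == 0:
        return np.empty((0, 2))
    if geom.A_ESM <= 0:
        raise ValueError("geometry has no extra-synaptic membrane area")
    half = geom.L_side / 2.0

    if spec.kind == "esm_uniform":
        out = np.empty((n, 2))
        got = 0
        while got < n:
            cand = rng.uniform(-half, half, size=(max(2 * (n - got), 64), 2))
            ok = (cand ** 2).sum(axis=1) >= geom.r_PSD ** 2
            cand = cand[ok]
            take = min(len(cand), n - got)
            out[got:got + take] = cand[:take]
            got += take
        return out

    if spec.kind == "esm_ring":
        phi = rng.uniform(0.0, 2.0 * math.pi, n)
        return geom.d_neck * np.column_stack((np.cos(phi), np.sin(phi)))

    # three co-located point-source batches at radius d_half
    batches = _split_batches(n, spec.batch_sizes)
    phi = rng.uniform(0.0, 2.0 * math.pi, len(batches))
    pts = geom.d_half * np.column_stack((np.cos(phi), np.sin(phi)))
    return np.repeat(pts, batches, axis=0)
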