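"""Geometry of the dendritic-spine membrane model and the synaptic cleft.

The spine is treated as a sphere whose surface is unrolled onto a flat
square with periodic (toroidal) boundaries.  The postsynaptic density
(PSD) is a disk at the centre of the square; the remainder of the square
is the extra-synaptic membrane (ESM).  All lengths are carried in
nanometres, areas in µm² and volumes in µm³ so that the derived values
can be compared directly with the commonly quoted magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SpineGeometry",
    "CleftGeometry",
    "derive_spine_geometry",
    "build_cleft_geometry",
]

#: printed distance (nm) from the PSD centre to the point of contact with
#: the spine neck in the reference spine; the unrounded value derived from
#: the sphere area is ~872.7 nm.
D_NECK_REFERENCE_NM = 872.5


@dataclass(frozen=True)
class SpineGeometry:
    """Derived geometric constants of the flattened spine membrane.

    Attributes
    ----------
    V_spine : float
        Spine volume in µm³.
    A_spine : float
        Total membrane area in µm² (surface of the sphere of volume
        ``V_spine``).
    A_PSD : float
        Area of the PSD disk in µm².
    r_PSD : float
        Radius of the PSD disk in nm.
    A_ESM : float
        Extra-synaptic membrane area in µm², ``A_spine - A_PSD``.
    L_side : float
        Side of the square membrane in nm, ``sqrt(A_spine)``.
    psd_fraction : float
        ``A_PSD / A_spine``.
    d_neck : float
        Distance (nm) from the PSD centre to the point of contact with
        the spine neck (half the square side).  The reference model uses
        the conventionally quoted 872.5 nm.
    d_half : float
        Midpoint (nm) between the PSD edge and the neck contact point.
    """

    V_spine: float
    A_spine: float
    A_PSD: float
    r_PSD: float
    A_ESM: float
    L_side: float
    psd_fraction: float
    d_neck: float
    d_half: float


@dataclass(frozen=True)
class CleftGeometry:
    """Synaptic-cleft box used for the glutamate signalling model.

    The cleft is a cuboid; the floor (z = 0) is the postsynaptic
    membrane carrying the PSD disk centred at the origin, the ceiling is
    the presynaptic bouton.  Transmitter is released from a point source
    just below the centre of the ceiling.
    """

    length: float = 700.0      # nm, x extent
    depth: float = 700.0       # nm, y extent
    height: float = 22.5       # nm, z extent
    r_PSD: float = 295.4       # nm
    release_point: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]
    n_glutamate: int = 4000
    D_glu: float = 0.2         # µm²/ms

    def __post_init__(self) -> None:
        if self.release_point is None:
            object.__setattr__(self, "release_point",
                               (0.0, 0.0, self.height - 1.0))

    @property
    def half_length(self) -> float:
        return self.length / 2.0

    @property
    def half_depth(self) -> float:
        return self.depth / 2.0


def derive_spine_geometry(V_spine: float, psd_fraction: float = 0.09,
                          *, d_neck: float | None = D_NECK_REFERENCE_NM,
                          ) -> SpineGeometry:
    """Derive all membrane-model constants from the spine volume.

    The membrane area is that of a sphere of volume ``V_spine``,
    ``A = (36 π V²)^(1/3)``, and the PSD disk takes ``psd_fraction`` of
    it.  Values are kept unrounded; rounding happens only on display.

    Parameters
    ----------
    V_spine : float
        Spine volume in µm³ (> 0).
    psd_fraction : float
        Fraction of the membrane area occupied by the PSD, in (0, 1).
    d_neck : float or None, keyword only
        Distance from the PSD centre to the spine-neck contact point in
        nm.  ``None`` recomputes it as half the square side; the default
        is the conventional 872.5 nm of the reference spine so that
        release-location experiments use the standard figure.

    Returns
    -------
    SpineGeometry
    """
    if not (V_spine > 0.0):
        raise ValueError(f"V_spine must be positive, got {V_spine!r}")
    if not (0.0 < psd_fraction < 1.0):
        raise ValueError(
            f"psd_fraction must lie strictly in (0, 1), got {psd_fraction!r}")

    A_spine = (36.0 * math.pi * V_spine ** 2) ** (1.0 / 3.0)   # µm²
    A_PSD = psd_fraction * A_spine
    r_PSD = math.sqrt(A_PSD / math.pi) * 1e3                   # nm
    A_ESM = A_spine - A_PSD
    L_side = math.sqrt(A_spine) * 1e3                          # nm
    if d_neck is None:
        d_neck = L_side / 2.0
    d_half = (r_PSD + d_neck) / 2.0
    return SpineGeometry(
        V_spine=V_spine, A_spine=A_spine, A_PSD=A_PSD, r_PSD=r_PSD,
        A_ESM=A_ESM, L_side=L_side, psd_fraction=psd_fraction,
        d_neck=d_neck, d_half=d_half,
    )


def build_cleft_geometry(length: float = 700.0, depth: float = 700.0,
                         height: float = 22.5, r_PSD: float = 295.4,
                         n_glutamate: int = 4000, D_glu: float = 0.2,
                         release_point: tuple[float, float, float] | None = None,
                         ) -> CleftGeometry:
    """Build the synaptic-cleft box with the reference defaults.

    Defaults: 700 × 700 × 22.5 nm cleft, PSD radius 295.4 nm, 4000
    glutamate molecules released 1 nm below the centre of the ceiling,
    glutamate diffusion coefficient 0.2 µm²/ms.
    """
    if min(length, depth, height) <= 0.0:
        raise ValueError("cleft dimensions must be positive")
    if not (r_PSD > 0.0):
        raise ValueError("r_PSD must be positive")
    if r_PSD >= min(length, depth) / 2.0:
        raise ValueError(
            f"PSD radius {r_PSD} nm does not fit inside the "
            f"{length} x {depth} nm cleft floor")
    if n_glutamate < 0:
        raise ValueError("n_glutamate must be non-negative")
    if D_glu < 0:
        raise ValueError("D_glu must be non-negative")
    if release_point is None:
        release_point = (0.0, 0.0, height - 1.0)
    x, y, z = release_point
    if not (abs(x) < length / 2 and abs(y) < depth / 2 and 0 <= z <= height):
        raise ValueError(f"release point {release_point} outside the cleft")
    return CleftGeometry(length=length, depth=depth, height=height,
                         r_PSD=r_PSD, release_point=release_point,
                         n_glutamate=n_glutamate, D_glu=D_glu)
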