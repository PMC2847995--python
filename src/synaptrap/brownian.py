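"""Fixed-timestep Brownian propagation and boundary policies.

These are the reference (vectorised NumPy) implementations of the three
propagation primitives: the Gaussian step, the toroidal membrane with a
one-way partially reflective PSD rim, and the synaptic-cleft box with a
reflective floor/ceiling and absorbing side walls.  The production
simulation loops use compiled kernels that apply exactly the same
rules step by step (see ``_kernels``); the functions here serve the
analysis tools, small-scale experiments and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CleftGeometry, SpineGeometry

__all__ = [
    "ParticleEnsemble",
    "BoundaryPolicy",
    "gaussian_step",
    "apply_membrane_boundaries",
    "apply_cleft_boundaries",
    "wrap_toroidal",
]


@dataclass
class ParticleEnsemble:
    """Positions plus per-particle bookkeeping flags.

    ``positions`` is (n, 2) or (n, 3) in nm.  ``mobile`` particles are
    propagated; immobile ones (scaffold-bound receptors, scaffolds)
    never move.  ``alive`` is cleared for absorbed particles.  ``state``
    is a free-form discrete label (kinetic state for receptors,
    bound/free for scaffolds).
    """

    positions: np.ndarray
    species: np.ndarray
    mobile: np.ndarray
    alive: np.ndarray
    state: np.ndarray

    @classmethod
    def create(cls, positions: np.ndarray, species: str | np.ndarray,
               mobile: bool = True) -> "ParticleEnsemble":
        n = len(positions)
        if isinstance(species, str):
            species = np.full(n, species, dtype=object)
        return cls(positions=np.array(positions, dtype=float),
                   species=np.asarray(species),
                   mobile=np.full(n, mobile, dtype=bool),
                   alive=np.ones(n, dtype=bool),
                   state=np.zeros(n, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class BoundaryPolicy:
    """Boundary rules of the membrane model.

    The square membrane is toroidal (periodic).  The PSD rim is one-way:
    inward crossings always stand, while an outward crossing is folded
    back radially with probability ``p_reflect``.
    """

    p_reflect: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_reflect <= 1.0):
            raise ValueError(
                f"p_reflect must lie in [0, 1], got {self.p_reflect!r}")


def gaussian_step(positions: np.ndarray, D: float, dt: float,
                  rng: np.random.Generator,
                  mobile: np.ndarray | None = None) -> np.ndarray:
    """Propose free Brownian displacements.

    Each mobile particle moves by independent Gaussian increments of
    per-axis standard deviation ``sqrt(2 D dt)`` with ``D`` in µm²/s and
    ``dt`` in s (positions in nm).  ``D = 0`` degenerates to no motion.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if D < 0:
        raise ValueError("D must be non-negative")
    positions = np.asarray(positions, dtype=float)
    sd = np.sqrt(2.0 * D * 1e6 * dt)  # nm
    step = rng.normal(0.0, sd, size=positions.shape) if sd > 0 else 0.0
    out = positions + step
    if mobile is not None:
        out = np.where(np.asarray(mobile)[:, None], out, positions)
    return out


def wrap_toroidal(positions: np.ndarray, L_side: float) -> np.ndarray:
    """Periodic wrap of coordinates onto the centred square of side
    ``L_side`` (applied coordinate-wise)."""
    half = L_side / 2.0
    return (positions + half) % L_side - half


def apply_membrane_boundaries(prev: np.ndarray, proposed: np.ndarray,
                              policy: BoundaryPolicy, geom: SpineGeometry,
                              rng: np.random.Generator) -> np.ndarray:
    """Apply the toroidal wrap, then the one-way PSD rim rule.

    A particle that starts a step inside the PSD disk and would end it
    outside is reflected back with probability ``policy.p_reflect`` by
    folding the radial overshoot: r_final = 2 r_PSD - r_proposed along
    the same bearing.  Inward crossings always stand.
    """
    prev = np.atleast_2d(np.asarray(prev, dtype=float))
    out = wrap_toroidal(np.atleast_2d(np.asarray(proposed, dtype=float)).copy(),
                        geom.L_side)
    if policy.p_reflect > 0.0:
        r_psd = geom.r_PSD
        r2_prev = (prev ** 2).sum(axis=1)
        r2_new = (out ** 2).sum(axis=1)
        crossing = (r2_prev < r_psd ** 2) & (r2_new >= r_psd ** 2)
        if np.any(crossing):
            refl = crossing & (rng.random(len(out)) < policy.p_reflect)
            idx = np.nonzero(refl)[0]
            r_new = np.sqrt(r2_new[idx])
            r_fold = np.clip(2.0 * r_psd - r_new, 0.0, None)
            out[idx] *= (r_fold / r_new)[:, None]
    return out


def apply_cleft_boundaries(prev: np.ndarray, proposed: np.ndarray,
                           cleft: CleftGeometry,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Resolve one glutamate step inside the cleft box.

    The z coordinate is mirrored at the floor (z = 0) and the ceiling
    (z = height), repeatedly until inside; a particle whose proposed x
    or y coordinate leaves the box is flagged absorbed (its position is
    left at the proposal for inspection).

    Returns ``(final_positions, absorbed)``.
    """
    out = np.atleast_2d(np.asarray(proposed, dtype=float)).copy()
    H = cleft.height
    # triangle-wave fold implements repeated mirroring at z=0 and z=H
    z = np.mod(out[:, 2], 2.0 * H)
    out[:, 2] = H - np.abs(H - z)
    absorbed = ((np.abs(out[:, 0]) > cleft.half_length)
                | (np.abs(out[:, 1]) > cleft.half_depth))
    return out, absorbed
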