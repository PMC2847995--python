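"""Reaction machinery: binding-radius calibration, bimolecular capture,
and the seven-state AMPAR gating scheme.

Fixed-timestep Brownian-dynamics simulators implement a bimolecular
reaction by absorbing any reactant pair that ends a step closer than a
binding radius sigma.  Because a finite timestep lets pairs jump over
the contact zone, sigma is not the Smoluchowski encounter radius: it
must be calibrated so that the discrete-step pair process reproduces
the desired macroscopic rate constant.  ``rate_from_binding_radius``
performs that calibration by solving the steady state of the radial
pair-density profile of the discrete process; ``binding_radius_from_rate``
inverts it.

Unit conventions: lengths in nm, times in s, diffusion coefficients in
µm²/s, bimolecular rates in M⁻¹s⁻¹, first-order rates in s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve as _dense_solve
from scipy.optimize import brentq
from scipy.spatial import cKDTree

__all__ = [
    "AVOGADRO",
    "ReactionSpec",
    "KineticScheme",
    "rate_from_binding_radius",
    "binding_radius_from_rate",
    "smoluchowski_rate",
    "q10_adjust",
    "jonas_scheme",
    "JONAS_RATES_25C",
    "bind_bimolecular",
    "step_first_order",
    "GLU_PER_STATE",
]

AVOGADRO = 6.02214076e23
# 1 nm^3/s per molecule pair == this many M^-1 s^-1
_NM3_S_TO_M_S = AVOGADRO * 1e-24


def smoluchowski_rate(sigma_nm: float, D_mutual: float) -> float:
    """Diffusion-limited rate 4*pi*D*sigma*N_A for a perfectly absorbing
    sphere of radius ``sigma_nm`` (nm) at mutual diffusion ``D_mutual``
    (µm²/s), in M⁻¹s⁻¹.  This is the dt -> 0 limit of the discrete-step
    calibration."""
    D_nm = D_mutual * 1e6  # nm²/s
    return 4.0 * math.pi * D_nm * sigma_nm * _NM3_S_TO_M_S


def _pair_absorbed_per_step(sigma: float, s: float, b: float) -> float:
    """Absorbed pair volume (nm³) in one step of the discrete pair
    process, with the far field pinned to the continuum steady profile
    rho = 1 - b/r beyond the boundary layer.

    One step is a 3D Gaussian relative displacement with per-axis sd
    ``s`` (nm) followed by absorption of all pairs inside ``sigma``.
    The radial density u(r) (pairs per nm of radius; far field
    u = 4*pi*r² for unit number density) is propagated by the exact
    radial Gaussian kernel and the steady state of "absorb, then
    diffuse" is obtained by a direct linear solve on the deviation
    v = u - 4*pi*r².  Free Gaussian steps are exact continuum diffusion,
    so outside a boundary layer of a few ``s`` around the absorber the
    steady profile is exactly harmonic, v = -4*pi*b*r; that form is
    imposed in a ghost region beyond ``sigma + 10 s``.
    """
    # grid: cell edges aligned with sigma so the absorbing region is exact
    m_in = 10 if s > 2.0 * sigma else 25
    dr0 = min(sigma, s) / float(m_in)
    m = max(int(math.ceil(sigma / dr0)), 4)
    dr = sigma / m
    r_edge = sigma + 10.0 * s          # unknown region ends here
    r_max = r_edge + 6.0 * s           # ghost region: fixed continuum tail
    n = int(math.ceil(r_max / dr))
    r = (np.arange(n) + 0.5) * dr      # cell centres
    inside = r < sigma                 # first m cells exactly
    ghost = r >= r_edge
    free = ~inside & ~ghost

    # radial propagator P(r_j | r_i) * dr, column i = source
    rj = r[:, None]
    ri = r[None, :]
    gauss = np.exp(-((rj - ri) ** 2) / (2.0 * s * s))
    mix = -np.expm1(-2.0 * rj * ri / (s * s))
    M = (rj / (ri * s * math.sqrt(2.0 * math.pi))) * gauss * mix * dr
    # enforce exact mass conservation for non-ghost sources (their true
    # leakage past r_max is exponentially small); outer ghost sources do
    # lose mass outward, which is physical
    colsum = M.sum(axis=0)
    keep = ~ghost
    M[:, keep] /= colsum[None, keep]

    # post-absorption deviation: fixed inside and in the ghost tail
    v_in = -4.0 * math.pi * r[inside] ** 2
    v_ghost = -4.0 * math.pi * b * r[ghost]
    A = np.eye(int(free.sum())) - M[np.ix_(free, free)]
    rhs = M[np.ix_(free, inside)] @ v_in + M[np.ix_(free, ghost)] @ v_ghost
    v_free = _dense_solve(A, rhs)

    # one diffusion step applied to the post-absorption profile
    v_full = np.empty(n)
    v_full[inside] = v_in
    v_full[free] = v_free
    v_full[ghost] = v_ghost
    v_new_in = M[inside, :] @ v_full
    return 4.0 * math.pi * sigma ** 3 / 3.0 + float(v_new_in.sum() * dr)


def rate_from_binding_radius(sigma_bind: float, D_mutual: float,
                             dt: float) -> float:
    """Macroscopic bimolecular rate (M⁻¹s⁻¹) realised by a fixed-timestep
    Brownian pair process that absorbs any pair ending a step closer
    than ``sigma_bind`` (nm), at mutual diffusion ``D_mutual`` (µm²/s)
    and timestep ``dt`` (s).

    Monotone non-decreasing in both sigma and D.  For dt -> 0 it
    converges to the Smoluchowski rate 4*pi*D*sigma*N_A; for rms steps
    much larger than sigma it approaches the well-mixed per-step sweep
    (4/3)*pi*sigma³/dt.
    """
    if sigma_bind < 0:
        raise ValueError("sigma_bind must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if sigma_bind == 0.0 or D_mutual <= 0.0:
        return 0.0
    D_nm = D_mutual * 1e6                      # nm²/s
    s = math.sqrt(2.0 * D_nm * dt)             # per-axis rms step, nm
    # the steady-state flux fixes the far-field depletion amplitude b
    # through 4*pi*D*b = k; both the flux and the solved profile are
    # affine in b, so two solves determine the self-consistent pair
    k0 = _pair_absorbed_per_step(sigma_bind, s, 0.0) / dt   # nm³/s at b=0
    k1 = _pair_absorbed_per_step(sigma_bind, s, 1.0) / dt
    c = k1 - k0                                             # dk/db
    fourpid = 4.0 * math.pi * D_nm
    b = k0 / (fourpid - c)
    k_nm3 = fourpid * b
    return max(k_nm3, 0.0) * _NM3_S_TO_M_S


def binding_radius_from_rate(rate_k: float, D_mutual: float,
                             dt: float, *, rtol: float = 1e-6) -> float:
    """Binding radius sigma (nm) whose discrete-step pair process has
    steady-state absorption rate ``rate_k`` (M⁻¹s⁻¹); exact inverse of
    :func:`rate_from_binding_radius` by monotone root finding."""
    if rate_k < 0:
        raise ValueError("rate_k must be non-negative")
    if rate_k == 0.0:
        return 0.0
    if D_mutual <= 0:
        raise ValueError("D_mutual must be positive for a non-zero rate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_nm3 = rate_k / _NM3_S_TO_M_S
    # both limits overestimate the achievable rate at a given sigma,
    # so each yields a lower bound on sigma
    sig_ball = (3.0 * k_nm3 * dt / (4.0 * math.pi)) ** (1.0 / 3.0)
    sig_smol = k_nm3 / (4.0 * math.pi * D_mutual * 1e6)
    lo = max(sig_ball, sig_smol) * 0.98
    hi = lo * 1.5
    f = lambda sig: rate_from_binding_radius(sig, D_mutual, dt) - rate_k
    flo = f(lo)
    for _ in range(60):
        if f(hi) > 0.0:
            break
        lo, flo = hi, None
        hi *= 1.5
    else:
        raise ValueError(
            f"rate {rate_k} M^-1 s^-1 not attainable at dt={dt}")
    return brentq(f, lo, hi, rtol=rtol)


def q10_adjust(rate: float, Q10: float = 3.0, dT: float = 15.0) -> float:
    """Temperature-adjust a rate constant: ``rate * Q10**(dT/10)``.

    ``dT`` is the temperature increase in °C.  The reference gating
    constants measured at room temperature are brought to physiological
    temperature with Q10 = 3 over a 15 °C span (factor 3^1.5)."""
    if Q10 <= 0:
        raise ValueError("Q10 must be positive")
    return rate * Q10 ** (dT / 10.0)


# ---------------------------------------------------------------------------
# AMPAR gating scheme
# ---------------------------------------------------------------------------

#: state order used throughout: index 0..6
STATE_NAMES = ("C0", "C1", "C2", "O", "C3", "C4", "C5")
C0, C1, C2, O, C3, C4, C5 = range(7)

#: glutamate molecules bound in each state (for conservation accounting)
GLU_PER_STATE = np.array([0, 1, 2, 2, 1, 2, 2], dtype=np.int64)

#: room-temperature gating constants of the hippocampal AMPAR scheme of
#: Jonas et al.; bimolecular constants in M⁻¹s⁻¹, the rest in s⁻¹.
JONAS_RATES_25C: dict[str, float] = {
    "k_plus1": 4.59e6,
    "k_minus1": 4.26e3,
    "k_plus2": 28.4e6,
    "k_minus2": 3.26e3,
    "k_plus3": 1.27e6,
    "k_minus3": 45.7,
    "alpha": 4.24e3,
    "beta": 900.0,
    "alpha1": 2.89e3,
    "beta1": 39.2,
    "alpha2": 172.0,
    "beta2": 0.727,
    "alpha3": 17.7,
    "beta3": 4.0,
    "alpha4": 16.8,
    "beta4": 190.4,
}

_BIMOLECULAR = ("k_plus1", "k_plus2", "k_plus3")

#: (from, to, symbol, kind); kind is "bind" (consumes one glutamate),
#: "release" (frees one glutamate) or "gate" (conformational only)
_TRANSITIONS: tuple[tuple[int, int, str, str], ...] = (
    (C0, C1, "k_plus1", "bind"),
    (C1, C0, "k_minus1", "release"),
    (C1, C2, "k_plus2", "bind"),
    (C2, C1, "k_minus2", "release"),
    (C3, C4, "k_plus3", "bind"),
    (C4, C3, "k_minus3", "release"),
    (C2, O, "alpha", "gate"),     # channel opening, needs two glutamate
    (O, C2, "beta", "gate"),
    (C1, C3, "alpha1", "gate"),   # desensitisation, single bound
    (C3, C1, "beta1", "gate"),
    (C2, C4, "alpha2", "gate"),   # desensitisation, double bound
    (C4, C2, "beta2", "gate"),
    (C4, C5, "alpha3", "gate"),
    (C5, C4, "beta3", "gate"),
    (O, C5, "alpha4", "gate"),    # desensitisation from the open state
    (C5, O, "beta4", "gate"),
)


@dataclass(frozen=True)
class ReactionSpec:
    """A bimolecular channel: macroscopic rate, calibrated binding
    radius, unbinding radius, mutual diffusion coefficient and timestep.

    ``from_rate``/``from_radius`` construct a mutually consistent spec
    via the calibration."""

    rate_k: float        # M^-1 s^-1
    sigma_bind: float    # nm
    sigma_unbind: float  # nm
    D_mutual: float      # µm²/s
    dt: float            # s

    @classmethod
    def from_rate(cls, rate_k: float, D_mutual: float, dt: float,
                  sigma_unbind: float | None = None) -> "ReactionSpec":
        sigma = binding_radius_from_rate(rate_k, D_mutual, dt)
        return cls(rate_k=rate_k, sigma_bind=sigma,
                   sigma_unbind=sigma if sigma_unbind is None else sigma_unbind,
                   D_mutual=D_mutual, dt=dt)

    @classmethod
    def from_radius(cls, sigma_bind: float, D_mutual: float, dt: float,
                    sigma_unbind: float | None = None) -> "ReactionSpec":
        rate = rate_from_binding_radius(sigma_bind, D_mutual, dt)
        return cls(rate_k=rate, sigma_bind=sigma_bind,
                   sigma_unbind=(sigma_bind if sigma_unbind is None
                                 else sigma_unbind),
                   D_mutual=D_mutual, dt=dt)


@dataclass(frozen=True)
class KineticScheme:
    """The seven-state AMPAR gating graph.

    States: C0 (unbound, closed), C1 (single bound, closed), C2 (double
    bound, closed), O (open), C3/C4 (desensitised single/double bound),
    C5 (desensitised from the open state).  Three transitions consume a
    glutamate molecule (C0->C1, C1->C2, C3->C4); their reverses release
    one.  Opening requires both binding sites occupied (C2 <-> O).
    """

    constants: dict[str, float]
    label: str = "scheme"

    @property
    def n_states(self) -> int:
        return len(STATE_NAMES)

    def transitions(self):
        """Yield (from, to, rate, kind) with rates in s⁻¹ or M⁻¹s⁻¹."""
        for i, j, sym, kind in _TRANSITIONS:
            yield i, j, self.constants[sym], kind

    def binding_transitions(self) -> list[tuple[int, int, float]]:
        """Glutamate-consuming transitions as (from, to, k in M⁻¹s⁻¹)."""
        return [(i, j, self.constants[sym])
                for i, j, sym, kind in _TRANSITIONS if kind == "bind"]

    def first_order_matrix(self) -> np.ndarray:
        """Off-diagonal matrix R[i, j] of first-order rates i -> j (s⁻¹),
        excluding the glutamate-binding steps (handled by capture)."""
        R = np.zeros((7, 7))
        for i, j, sym, kind in _TRANSITIONS:
            if kind != "bind":
                R[i, j] = self.constants[sym]
        return R

    def release_mask(self) -> np.ndarray:
        """Boolean M[i, j]: transition i -> j frees one glutamate."""
        M = np.zeros((7, 7), dtype=bool)
        for i, j, sym, kind in _TRANSITIONS:
            if kind == "release":
                M[i, j] = True
        return M

    def rate_matrix(self, glu_conc: float = 0.0) -> np.ndarray:
        """Full off-diagonal rate matrix (s⁻¹) with the bimolecular steps
        folded in as pseudo-first-order rates at a fixed glutamate
        concentration ``glu_conc`` (molar).  This is the generator of the
        well-mixed master equation, used as the reference against which
        the particle simulation is validated."""
        R = self.first_order_matrix()
        for i, j, k in self.binding_transitions():
            R[i, j] += k * glu_conc
        return R


def jonas_scheme(temperature_adjusted: bool = False, *, Q10: float = 3.0,
                 dT: float = 15.0) -> KineticScheme:
    """Build the AMPAR gating scheme, optionally Q10-adjusted from room
    temperature to physiological temperature (factor Q10**(dT/10) on
    every constant)."""
    if temperature_adjusted:
        consts = {k: q10_adjust(v, Q10, dT) for k, v in JONAS_RATES_25C.items()}
        return KineticScheme(constants=consts, label="temperature_adjusted")
    return KineticScheme(constants=dict(JONAS_RATES_25C), label="original")


# ---------------------------------------------------------------------------
# Particle-level reaction operations (vectorised reference implementations)
# ---------------------------------------------------------------------------

def bind_bimolecular(pos_a: np.ndarray, pos_b: np.ndarray, sigma: float,
                     *, order: str = "nearest",
                     rng: np.random.Generator | None = None,
                     ) -> list[tuple[int, int]]:
    """Match A particles to B particles closer than ``sigma``.

    Each particle reacts at most once per step.  ``order='nearest'``
    resolves competing candidates greedily by increasing pair distance
    (deterministic given positions); ``order='random'`` shuffles the
    candidate pairs instead.

    Returns a list of (index into A, index into B) bound pairs.
    """
    if len(pos_a) == 0 or len(pos_b) == 0 or sigma <= 0:
        return []
    tree_b = cKDTree(np.atleast_2d(pos_b))
    pairs = cKDTree(np.atleast_2d(pos_a)).query_ball_tree(tree_b, r=sigma)
    cand: list[tuple[float, int, int]] = []
    pa = np.atleast_2d(pos_a)
    pb = np.atleast_2d(pos_b)
    for ia, lst in enumerate(pairs):
        for ib in lst:
            d = float(np.linalg.norm(pa[ia] - pb[ib]))
            if d < sigma:
                cand.append((d, ia, ib))
    if order == "nearest":
        cand.sort()
    elif order == "random":
        if rng is None:
            rng = np.random.default_rng()
        rng.shuffle(cand)
    else:
        raise ValueError(f"unknown matching order {order!r}")
    used_a: set[int] = set()
    used_b: set[int] = set()
    out: list[tuple[int, int]] = []
    for _, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        out.append((ia, ib))
    return out


def step_first_order(states: np.ndarray, scheme: KineticScheme, dt: float,
                     rng: np.random.Generator, glu_conc: float = 0.0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Advance receptor states by one timestep of the gating scheme.

    Each receptor leaves its state with probability 1 - exp(-K dt),
    K the total outgoing rate, and the destination is drawn proportional
    to the individual rates (single-jump approximation; a warning is
    emitted when K dt exceeds 0.1).  With ``glu_conc`` > 0 (molar) the
    bimolecular binding steps are folded in as pseudo-first-order rates,
    which models a well-mixed glutamate bath; in the particle simulation
    they are handled instead by explicit capture.

    Returns ``(new_states, released)`` where ``released`` flags the
    receptors whose transition freed one glutamate molecule.
    """
    R = scheme.rate_matrix(glu_conc)
    K = R.sum(axis=1)
    if np.max(K) * dt > 0.1:
        import warnings
        warnings.warn(
            f"K*dt = {np.max(K) * dt:.3g} > 0.1; the single-transition "
            "approximation degrades, reduce the timestep", RuntimeWarning)
    p_leave = -np.expm1(-K * dt)
    states = np.asarray(states, dtype=np.int64)
    new_states = states.copy()
    released = np.zeros(states.shape, dtype=bool)
    rel = scheme.release_mask()
    u = rng.random(states.shape)
    jump = u < p_leave[states]
    if np.any(jump):
        idx = np.nonzero(jump)[0]
        for i in idx:
            s = states[i]
            rates = R[s]
            dest = rng.choice(7, p=rates / rates.sum())
            new_states[i] = dest
            if rel[s, dest]:
                released[i] = True
    return new_states, released
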