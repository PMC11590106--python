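"""Exact two-ligand/one-receptor competitive-binding equilibrium.

A fluorescently labeled mannose ligand (M) and glucose (G) compete for a
single lectin receptor (C, the ConA tetramer counted as one binding
entity).  Mass action gives

    K_M * [CM] = [M][C],      K_G * [CG] = [G][C]

with conservation [C]0 = [C] + [CM] + [CG], [M]0 = [M] + [CM],
[G]0 = [G] + [CG].  Substituting the bound-species expressions into the
receptor balance yields a cubic polynomial in the free-receptor
concentration [C]; the physical root lies in [0, [C]0] and is unique
because the combined mass-balance function is strictly increasing in [C].

All concentrations are molar throughout this module; glucose unit
conversion helpers are provided at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLUCOSE_MW",
    "BindingConstants",
    "AssayMixture",
    "EquilibriumState",
    "IntensityReading",
    "EquilibriumError",
    "SolverError",
    "cubic_coefficients",
    "solve_equilibrium",
    "free_ligand_fraction",
    "fraction_difference",
    "anisotropy",
    "g_factor",
    "mgdl_to_molar",
    "molar_to_mgdl",
]

#: Molecular weight of D-glucose, g/mol.
GLUCOSE_MW = 180.156

#: Relative tolerance for mass-balance and dissociation-identity checks.
BALANCE_RTOL = 1e-9
#: Absolute concentration floor (molar) below which balances are not scored.
BALANCE_ATOL = 1e-18


class EquilibriumError(ValueError):
    """Invalid input to an equilibrium computation."""


class SolverError(RuntimeError):
    """The cubic solve produced no acceptable physical root."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise EquilibriumError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class BindingConstants:
    """Dissociation constants of the two competing ligands (molar).

    K_M : labeled mannose ligand vs receptor (e.g. 5.4e-8 M for
        Cy5.5-mannotetraose / PEG-ConA).
    K_G : glucose vs receptor (2.5e-3 M for ConA).
    """

    K_M: float
    K_G: float

    def __post_init__(self) -> None:
        for name in ("K_M", "K_G"):
            v = _require_finite(name, getattr(self, name))
            if v <= 0:
                raise EquilibriumError(f"{name} must be > 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class AssayMixture:
    """Total (analytical) concentrations of the mixture, molar.

    M0 : total labeled ligand; C0 : total receptor (tetramer counted as
    one entity); G0 : total glucose.
    """

    M0: float
    C0: float
    G0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("M0", "C0", "G0"):
            v = _require_finite(name, getattr(self, name))
            if v < 0:
                raise EquilibriumError(f"{name} must be >= 0, got {v}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class EquilibriumState:
    """Free and bound species concentrations at equilibrium (molar)."""

    C_free: float
    M_free: float
    G_free: float
    CM: float
    CG: float


@dataclass(frozen=True)
class IntensityReading:
    """Polarized fluorescence intensities (arbitrary units).

    I_VV : vertical excitation / vertical emission.
    I_VH : vertical excitation / horizontal emission.
    G    : instrument correction factor applied to I_VH.
    """

    I_VV: float
    I_VH: float
    G: float = 1.0

    def __post_init__(self) -> None:
        for name in ("I_VV", "I_VH", "G"):
            _require_finite(name, getattr(self, name))
        if self.I_VV < 0 or self.I_VH < 0:
            raise EquilibriumError("intensities must be >= 0")
        if self.G <= 0:
            raise EquilibriumError("G factor must be > 0")


def cubic_coefficients(
    constants: BindingConstants, mixture: AssayMixture
) -> np.ndarray:
    """Monic cubic in the free receptor concentration C.

    Substituting CM = C*M0/(K_M + C) and CG = C*G0/(K_G + C) into the
    receptor balance C0 = C + CM + CG and clearing denominators gives

        C^3 + a2*C^2 + a1*C + a0 = 0

    with
        a2 = K_M + K_G + M0 + G0 - C0
        a1 = K_M*K_G + K_G*(M0 - C0) + K_M*(G0 - C0)
        a0 = -K_M*K_G*C0

    Returns
    -------
    ndarray of shape (4,), coefficients highest degree first.
    """
    K_M, K_G = constants.K_M, constants.K_G
    M0, C0, G0 = mixture.M0, mixture.C0, mixture.G0
    a2 = K_M + K_G + M0 + G0 - C0
    a1 = K_M * K_G + K_G * (M0 - C0) + K_M * (G0 - C0)
    a0 = -K_M * K_G * C0
    return np.array([1.0, a2, a1, a0])


def _mass_balance_residual(
    C: float, constants: BindingConstants, mixture: AssayMixture
) -> float:
    """C + C*M0/(K_M+C) + C*G0/(K_G+C) - C0, strictly increasing in C."""
    return (
        C
        + C * mixture.M0 / (constants.K_M + C)
        + C * mixture.G0 / (constants.K_G + C)
        - mixture.C0
    )


def solve_equilibrium(
    constants: BindingConstants, mixture: AssayMixture
) -> EquilibriumState:
    """Solve the competitive-binding equilibrium exactly.

    The cubic is solved via the polynomial companion matrix, the unique
    real root in [0, C0] is selected (roots within 1e-12*C0 of a boundary
    are clamped onto it), and a few Newton steps on the monotone
    mass-balance function polish the root against the cancellation the
    companion solve suffers when K_M << C0.  Free-ligand and
    free-glucose concentrations are then recovered from the individual
    mass-action expressions.

    Raises
    ------
    SolverError
        If no real root, or more than one distinct real root, lies in
        [0, C0].
    """
    M0, C0, G0 = mixture.M0, mixture.C0, mixture.G0
    if C0 == 0.0:
        return EquilibriumState(0.0, M0, G0, 0.0, 0.0)

    coeffs = cubic_coefficients(constants, mixture)
    roots = np.roots(coeffs)
    scale = max(C0, constants.K_M, constants.K_G, M0, G0)
    real = roots[np.abs(roots.imag) <= 1e-9 * scale].real

    clamp = 1e-12 * C0
    candidates = []
    for r in real:
        if -clamp <= r <= C0 + clamp:
            candidates.append(float(min(max(r, 0.0), C0)))
    # dedupe roots that coincide to tolerance
    candidates.sort()
    unique: list[float] = []
    for r in candidates:
        if not unique or abs(r - unique[-1]) > 1e-9 * C0:
            unique.append(r)

    if not unique:
        residuals = {float(r): _mass_balance_residual(float(r), constants, mixture)
                     for r in real}
        raise SolverError(
            f"no real root in [0, C0={C0:g}]; real-root residuals: {residuals}"
        )
    if len(unique) > 1:
        raise SolverError(
            f"multiple distinct roots in [0, C0={C0:g}]: {unique} "
            "(mass balance should be monotone; inputs may be degenerate)"
        )

    C = unique[0]
    # Newton polish on the mass-balance function itself: its derivative is
    # >= 1, so the update is stable even when the cubic coefficients span
    # many decades and the companion roots carry cancellation error
    K_M, K_G = constants.K_M, constants.K_G
    for _ in range(3):
        f = _mass_balance_residual(C, constants, mixture)
        df = 1.0 + M0 * K_M / (K_M + C) ** 2 + G0 * K_G / (K_G + C) ** 2
        C_new = C - f / df
        if not (0.0 <= C_new <= C0):
            break
        if C_new == C:
            C = C_new
            break
        C = float(C_new)

    # free and bound recovered from the exact ratios (not by subtraction,
    # which cancels catastrophically when one species dominates the total)
    M_free = M0 * K_M / (K_M + C)
    CM = M0 * C / (K_M + C)
    G_free = G0 * K_G / (K_G + C)
    CG = G0 * C / (K_G + C)
    state = EquilibriumState(C_free=C, M_free=M_free, G_free=G_free, CM=CM, CG=CG)
    _check_state(state, constants, mixture)
    return state


def _check_state(
    state: EquilibriumState, constants: BindingConstants, mixture: AssayMixture
) -> None:
    def ok(lhs: float, rhs: float, scale: float) -> bool:
        return abs(lhs - rhs) <= BALANCE_RTOL * max(scale, 0.0) + BALANCE_ATOL

    balances = [
        (state.C_free + state.CM + state.CG, mixture.C0, mixture.C0),
        (state.M_free + state.CM, mixture.M0, mixture.M0),
        (state.G_free + state.CG, mixture.G0, mixture.G0),
    ]
    for lhs, rhs, scale in balances:
        if not ok(lhs, rhs, scale):
            raise SolverError(
                f"mass balance violated: {lhs:g} != {rhs:g} "
                f"(rel err {abs(lhs - rhs) / max(scale, BALANCE_ATOL):g})"
            )
    for K, bound, free in (
        (constants.K_M, state.CM, state.M_free),
        (constants.K_G, state.CG, state.G_free),
    ):
        if bound > BALANCE_ATOL:
            lhs, rhs = K * bound, free * state.C_free
            if not ok(lhs, rhs, max(lhs, rhs)):
                raise SolverError("dissociation identity violated after solve")


def free_ligand_fraction(state: EquilibriumState, mixture: AssayMixture) -> float:
    """Fraction of the labeled ligand unbound from the receptor, M_free/M0."""
    if mixture.M0 <= 0:
        raise EquilibriumError("free ligand fraction undefined for M0 = 0")
    return state.M_free / mixture.M0


def fraction_difference(
    constants: BindingConstants,
    M0: float,
    C0: float,
    G_low: float,
    G_high: float,
) -> float:
    """Assay-design objective: free-ligand fraction gain between two
    glucose levels.

    Delta F = f_free(G_high) - f_free(G_low).  Glucose displaces the
    labeled ligand, so Delta F >= 0 whenever G_high >= G_low.
    """
    if G_high < G_low:
        raise EquilibriumError("G_high must be >= G_low")
    if C0 == 0.0:
        return 0.0
    lo = solve_equilibrium(constants, AssayMixture(M0=M0, C0=C0, G0=G_low))
    hi = solve_equilibrium(constants, AssayMixture(M0=M0, C0=C0, G0=G_high))
    mix = AssayMixture(M0=M0, C0=C0)
    return free_ligand_fraction(hi, mix) - free_ligand_fraction(lo, mix)


def anisotropy(reading: IntensityReading) -> float:
    """Steady-state anisotropy r = (I_VV - G*I_VH) / (I_VV + 2*G*I_VH)."""
    denom = reading.I_VV + 2.0 * reading.G * reading.I_VH
    if denom <= 0.0:
        raise EquilibriumError("anisotropy undefined: I_VV + 2*G*I_VH <= 0")
    return (reading.I_VV - reading.G * reading.I_VH) / denom


def g_factor(I_VH: float, I_VV: float) -> float:
    """Instrument correction factor G = I_VH / I_VV.

    Note this is the ratio as used with vertically polarized excitation;
    G may equally be supplied directly as a calibrated constant.
    """
    if I_VV <= 0:
        raise EquilibriumError("g_factor undefined for I_VV <= 0")
    if I_VH < 0:
        raise EquilibriumError("I_VH must be >= 0")
    return I_VH / I_VV


def mgdl_to_molar(value: float, molecular_weight: float = GLUCOSE_MW) -> float:
    """Convert mg/dL to molar (mg/dL * 0.01 = g/L, divided by MW)."""
    value = _require_finite("value", value)
    if value < 0:
        raise EquilibriumError("concentration must be >= 0")
    return value * 0.01 / molecular_weight


def molar_to_mgdl(value: float, molecular_weight: float = GLUCOSE_MW) -> float:
    """Inverse of :func:`mgdl_to_molar`."""
    value = _require_finite("value", value)
    if value < 0:
        raise EquilibriumError("concentration must be >= 0")
    return value * molecular_weight * 100.0
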