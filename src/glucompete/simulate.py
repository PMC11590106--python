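"""Synthetic spectrofluorometer data with the structure the fits assume.

Generates titration curves, glucose-response curves, and raw polarized
intensity pairs.  Anisotropy of a mixed free/bound ligand population is
modeled as the population-fraction-weighted average

    r = r_free + (r_bound - r_free) * f_bound

(equal quantum yield and lifetime in both states).  Noise is additive
Gaussian on r by default, with optional multiplicative noise on the raw
intensities; one integer seed drives a single pseudorandom stream per
generator call, so identical inputs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import GlucoseResponseCurve
from .equilibrium import (
    AssayMixture,
    BindingConstants,
    IntensityReading,
    mgdl_to_molar,
    solve_equilibrium,
)
from .titration import TitrationCurve, boltzmann, isotherm_bound_fraction

__all__ = [
    "NoiseSpec",
    "OpticalParams",
    "simulate_titration",
    "simulate_glucose_response",
    "simulate_intensities",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the generators.

    r_noise_sd : additive Gaussian sd on anisotropy (default 0.003, a
        fixture choice for a bench spectrofluorometer, not a claim about
        any instrument).
    intensity_noise_cv : multiplicative coefficient of variation on raw
        polarized intensities.
    seed : pseudorandom stream seed.
    """

    r_noise_sd: float = 0.003
    intensity_noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_noise_sd < 0 or self.intensity_noise_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class OpticalParams:
    """Photophysics of the labeled ligand.

    r_free / r_bound : anisotropy of the unbound and receptor-bound
        ligand (free < bound: binding slows tumbling).
    total_intensity : I_VV + 2*G*I_VH budget for raw readings.
    G : instrument correction factor.
    """

    r_free: float = 0.05
    r_bound: float = 0.25
    total_intensity: float = 3.0
    G: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_free < self.r_bound <= 1.0):
            raise ValueError("need 0 <= r_free < r_bound <= 1")
        if self.total_intensity <= 0 or self.G <= 0:
            raise ValueError("total_intensity and G must be > 0")

    def mix(self, f_bound) -> np.ndarray:
        """Population-weighted anisotropy at bound fraction f_bound."""
        return self.r_free + (self.r_bound - self.r_free) * np.asarray(f_bound)


NOISELESS = NoiseSpec(r_noise_sd=0.0, intensity_noise_cv=0.0, seed=0)


def simulate_titration(
    K_d: float,
    ligand_total: float,
    protein_concs,
    optics: OpticalParams = OpticalParams(),
    noise: NoiseSpec = NOISELESS,
    model: str = "mechanistic",
) -> TitrationCurve:
    """Anisotropy titration of fixed ligand with increasing protein.

    model="mechanistic" computes the bound fraction from the exact
    two-component isotherm; model="boltzmann" samples the idealized
    sigmoid with midpoint at log10(K_d) (useful for self-consistency
    round-trips).
    """
    protein = np.asarray(protein_concs, dtype=float)
    if protein.size == 0:
        raise ValueError("protein_concs must not be empty")
    if model == "mechanistic":
        f_bound = np.array(
            [isotherm_bound_fraction(K_d, ligand_total, p) for p in protein]
        )
        r = optics.mix(f_bound)
    elif model == "boltzmann":
        r = boltzmann(
            np.log10(protein), optics.r_free, optics.r_bound, np.log10(K_d), 0.25
        )
    else:
        raise ValueError("model must be 'mechanistic' or 'boltzmann'")
    if noise.r_noise_sd > 0:
        r = r + noise.rng().normal(0.0, noise.r_noise_sd, size=r.shape)
    return TitrationCurve(
        ligand_total=ligand_total, protein_concs=protein, r_values=r
    )


def simulate_glucose_response(
    constants: BindingConstants,
    mixture: AssayMixture,
    glucose_mgdl,
    optics: OpticalParams = OpticalParams(),
    noise: NoiseSpec = NOISELESS,
) -> GlucoseResponseCurve:
    """Anisotropy of a fixed assay across glucose levels (mg/dL).

    The G0 field of `mixture` is ignored; each glucose level is
    converted to molar and the full competitive equilibrium solved.
    Noiseless output is monotone nonincreasing in glucose.
    """
    glucose = np.asarray(glucose_mgdl, dtype=float)
    if glucose.size == 0:
        raise ValueError("glucose_mgdl must not be empty")
    f_bound = np.empty(glucose.shape)
    for i, g in enumerate(glucose):
        mix = AssayMixture(M0=mixture.M0, C0=mixture.C0, G0=mgdl_to_molar(g))
        state = solve_equilibrium(constants, mix)
        f_bound[i] = state.CM / mixture.M0 if mixture.M0 > 0 else 0.0
    r = optics.mix(f_bound)
    if noise.r_noise_sd > 0:
        r = r + noise.rng().normal(0.0, noise.r_noise_sd, size=r.shape)
    return GlucoseResponseCurve(glucose_mgdl=glucose, r_values=r)


def simulate_intensities(
    r: float,
    optics: OpticalParams = OpticalParams(),
    noise: NoiseSpec = NOISELESS,
) -> IntensityReading:
    """Raw polarized intensity pair whose anisotropy is exactly r.

    Inverts the anisotropy formula at the configured total intensity
    T = I_VV + 2*G*I_VH:  I_VV = T*(1 + 2r)/3,  G*I_VH = T*(1 - r)/3.
    Multiplicative noise (if any) is applied per channel afterwards.
    """
    if not (-0.5 < r <= 1.0):
        raise ValueError("anisotropy must lie in (-0.5, 1] to invert")
    T = optics.total_intensity
    I_VV = T * (1.0 + 2.0 * r) / 3.0
    I_VH = T * (1.0 - r) / (3.0 * optics.G)
    if noise.intensity_noise_cv > 0:
        rng = noise.rng()
        I_VV *= 1.0 + rng.normal(0.0, noise.intensity_noise_cv)
        I_VH *= 1.0 + rng.normal(0.0, noise.intensity_noise_cv)
        I_VV, I_VH = max(I_VV, 0.0), max(I_VH, 0.0)
    return IntensityReading(I_VV=I_VV, I_VH=I_VH, G=optics.G)
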