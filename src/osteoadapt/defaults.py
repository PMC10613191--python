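"""Reference parameter set for trabecular bone, as printed in the source data.

Values are stored verbatim in their printed units (GPa for the first-gradient
moduli, N for second-gradient stiffnesses, SI elsewhere) so that serialized
configurations round-trip exactly; unit conversion to Pa happens in the
loaders (:func:`osteoadapt.constitutive.ModuliSet.from_gpa`,
:func:`osteoadapt.scenarios.ScenarioConfig.build_moduli`).
"""

from __future__ import annotations

#: First-gradient orthotropic moduli [GPa].
REFERENCE_MODULI_GPA: dict[str, float] = {
    "K": 17.84,
    "mu": 7.32,
    "alpha1": -2.87,
    "alpha2": -2.25,
    "mu1": -1.71,
    "mu2": -1.09,
    "beta1": 2.97,
    "beta2": 1.47,
    "beta3": 2.14,
}

#: Common value of the four second-gradient stiffnesses [N].
SECOND_GRADIENT_STIFFNESS_N: float = 1.5

#: Reorientation evolution parameters: viscosity [Pa s] and restoring
#: coefficient [Pa] of the misalignment angle.
REORIENTATION_PARAMS: dict[str, float] = {
    "c_gamma": 6.048e5,
    "tau_gamma": 1.0e-3,
}

#: Stiffness-adaptation parameters per evolving modulus: viscosity c_p [Pa s],
#: gain tau_p [Pa], homeostatic reference stimulus S0 [Pa].
STIFFNESS_EVOLUTION_PARAMS: dict[str, dict[str, float]] = {
    "mu": {"c_p": 6.048e12, "tau_p": 1.0e4, "S0": 3660.0},
    "beta1": {"c_p": 6.048e12, "tau_p": 1.0e4, "S0": 1484.8},
    "beta2": {"c_p": 6.048e12, "tau_p": 1.0e4, "S0": 734.29},
}

#: Stimulus reaction-diffusion parameters per evolving modulus: damping d
#: [Pa s], diffusivity kappa [N], absorption R [Pa].
STIMULUS_PARAMS: dict[str, dict[str, float]] = {
    "mu": {"d": 3.024e6, "kappa": 1.0e-4, "R": 0.35e2},
    "beta1": {"d": 6.048e6, "kappa": 1.0e-4, "R": 0.35e2},
    "beta2": {"d": 6.048e6, "kappa": 1.0e-4, "R": 0.35e2},
}

#: Specimen dimensions [m] (modeled domain; for the three-point test this is
#: the half specimen, the full sample being twice as long).
GEOMETRY_M: dict[str, float] = {"Lx": 0.075, "Ly": 0.025}

#: Cantilever edge shear-force line density amplitude [N/m].
TRACTION_AMPLITUDE: float = 1.25e5

#: Assumed out-of-plane thickness of the slab [m] over which edge line
#: densities act (not printed in the source data; chosen equal to the
#: specimen depth, i.e. a square cross section, which places the working
#: strains in the physiological range the homeostatic setpoints imply).
SECTION_THICKNESS: float = 0.025

#: Duration of the smooth loading ramp [s].
RAMP_DURATION: float = 60480.0

#: Assigned loading-pin displacement amplitude for the flexure test [m].
PIN_DISPLACEMENT_AMPLITUDE: float = 2.0e-3

#: Support span / modeled (half) length ratio for the three-point test; with
#: Lx = 75 mm this yields a full center-to-center span of 137.5 mm.
SPAN_RATIO: float = 11.0 / 6.0
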