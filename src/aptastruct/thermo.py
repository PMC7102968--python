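"""Binding thermodynamics: identities, fold changes, ITC model, isotherm fits.

Conventions
-----------
* K_d in molar, ΔH in kJ·mol⁻¹, ΔS in J·mol⁻¹·K⁻¹, T in kelvin.
* Concentrations are per protein *dimer* (the binding unit): stoichiometry
  n = 1 means one dimer per nucleic-acid molecule.
* T defaults to 298 K, the evaluation temperature that reproduces tabulated
  −TΔS values at 0.1 kJ·mol⁻¹ precision.

The ITC model is the exact single-site (Wiseman) isotherm: the bound
concentration after each injection follows from the 1:1 mass-balance
quadratic, with the instantaneous-overflow dilution correction applied to
both components, and the differential heat of injection k is
V₀·ΔH·([PL]ₖ − [PL]ₖ₋₁·(1 − dVₖ/V₀)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "R_GAS", "BindingParameters", "DerivedThermo", "ITCProtocol", "ITCExperiment",
    "derive_thermo", "fold_change", "present_fold", "simulate_itc", "fit_itc",
    "fit_fraction_bound",
]

R_GAS = 8.314          # J mol^-1 K^-1
DEFAULT_TEMPERATURE = 298.0   # K


@dataclass(frozen=True)
class BindingParameters:
    """Equilibrium binding parameters of a 1:1 dimer-ligand interaction."""

    k_d: float                      # molar
    delta_h: float                  # kJ mol^-1
    n: float = 1.0                  # sites (nucleic molecules per dimer cell unit)
    delta_s: float | None = None    # J mol^-1 K^-1
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise ValueError("K_d must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class DerivedThermo:
    delta_g: float          # kJ mol^-1, ΔH − TΔS
    t_delta_s: float        # kJ mol^-1
    minus_t_delta_s: float  # kJ mol^-1
    delta_g_from_kd: float  # kJ mol^-1, RT ln K_d
    residual: float         # ΔG − ΔG_from_Kd (printed-precision bookkeeping)


def derive_thermo(p: BindingParameters) -> DerivedThermo:
    """ΔG/TΔS identities plus the independent ΔG from K_d.

    The residual between ΔH − TΔS and RT·ln(K_d) is reported, never hidden:
    tabulated values rounded to printing precision propagate into it.
    """
    if p.delta_s is None:
        raise ValueError("delta_s required to derive TΔS and ΔG")
    t_delta_s = p.temperature * p.delta_s / 1000.0
    delta_g = p.delta_h - t_delta_s
    delta_g_from_kd = R_GAS * p.temperature * math.log(p.k_d) / 1000.0
    return DerivedThermo(
        delta_g=delta_g,
        t_delta_s=t_delta_s,
        minus_t_delta_s=-t_delta_s,
        delta_g_from_kd=delta_g_from_kd,
        residual=delta_g - delta_g_from_kd,
    )


def fold_change(k_d_variant: float, k_d_reference: float) -> float:
    """Affinity-loss ratio of a variant relative to a reference."""
    if k_d_variant <= 0 or k_d_reference <= 0:
        raise ValueError("dissociation constants must be positive")
    return k_d_variant / k_d_reference


def present_fold(ratio: float) -> str:
    """Two-significant-figure presentation, e.g. 2482 -> \"2500-fold\"."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    exponent = math.floor(math.log10(abs(ratio)))
    rounded = round(ratio, -exponent + 1)
    if rounded == int(rounded):
        text = f"{int(rounded):d}"
    else:
        text = f"{rounded:g}"
    return f"{text}-fold"


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ITCProtocol:
    """Instrument protocol: what is in the cell and what is injected.

    The macromolecule (here: the nucleic acid) sits in the cell; the titrant
    (protein dimer) is injected.  All concentrations molar.
    """

    cell_volume: float = 1.0e-3            # L (1 ml working cell)
    cell_concentration: float = 15e-6      # M macromolecule in the cell
    syringe_concentration: float = 175e-6  # M titrant in the syringe
    injection_volumes: tuple[float, ...] = (2e-6,) + (5e-6,) * 34  # L
    temperature: float = DEFAULT_TEMPERATURE
    discard_first: bool = True

    def __post_init__(self) -> None:
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")


@dataclass
class ITCExperiment:
    protocol: ITCProtocol
    heats: np.ndarray                     # µJ per injection
    molar_ratios: np.ndarray              # titrant:cell molar ratio after each injection
    saturation_warning: bool = False


def _bound_concentration(m_tot: float, l_tot: float, k_d: float, n: float) -> float:
    """Exact 1:1 bound complex concentration from the mass-balance quadratic.

    ``m_tot`` is total macromolecule (cell), ``l_tot`` total titrant; ``n``
    scales the macromolecule's effective site concentration.
    """
    sites = n * m_tot
    b = sites + l_tot + k_d
    disc = b * b - 4.0 * sites * l_tot
    return (b - math.sqrt(max(disc, 0.0))) / 2.0


def simulate_itc(
    params: BindingParameters,
    protocol: ITCProtocol | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> ITCExperiment:
    """Per-injection heats (µJ) for a 1:1 titration under the given protocol.

    ``noise_sigma`` is an absolute Gaussian noise level in µJ, applied with a
    fixed seed for reproducibility.  A warning flag is set when the final
    molar ratio does not reach 1.5× the stoichiometry (saturation unreachable).
    """
    if params.n <= 0:
        raise ValueError("stoichiometry n must be positive")
    protocol = protocol or ITCProtocol()
    v0 = protocol.cell_volume
    m_tot = protocol.cell_concentration
    l_tot = 0.0
    bound_prev = 0.0
    heats = np.zeros(len(protocol.injection_volumes))
    ratios = np.zeros_like(heats)
    for k, dv in enumerate(protocol.injection_volumes):
        dilution = 1.0 - dv / v0
        m_tot *= dilution
        l_tot = l_tot * dilution + protocol.syringe_concentration * dv / v0
        bound = _bound_concentration(m_tot, l_tot, params.k_d, params.n)
        # ΔH kJ/mol * mol -> kJ; report µJ
        heats[k] = params.delta_h * v0 * (bound - bound_prev * dilution) * 1e9
        bound_prev = bound
        ratios[k] = l_tot / m_tot
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sigma, size=heats.shape)
    warn = ratios[-1] < 1.5 * params.n
    return ITCExperiment(protocol=protocol, heats=heats, molar_ratios=ratios,
                         saturation_warning=bool(warn))


def fit_itc(experiment: ITCExperiment, params0: BindingParameters | None = None) -> dict:
    """Nonlinear least-squares fit of (K_d, ΔH, n) to per-injection heats.

    The first injection is excluded when the protocol flags it discarded.
    ΔS is derived from the fitted K_d and ΔH at the protocol temperature.
    Returns fitted :class:`BindingParameters`, standard errors and
    convergence diagnostics.
    """
    proto = experiment.protocol
    usable = np.arange(len(experiment.heats))
    if proto.discard_first:
        usable = usable[1:]
    if len(usable) < 10:
        raise ValueError("need at least 10 usable injections")
    y = experiment.heats[usable]

    scale = max(np.max(np.abs(y)), 1e-9)
    if params0 is None:
        params0 = BindingParameters(
            k_d=proto.cell_concentration / 10.0,
            delta_h=float(np.sum(experiment.heats)) / (
                proto.cell_concentration * proto.cell_volume) * 1e-9,
            n=1.0,
            temperature=proto.temperature,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, dh, n = theta
        sim = simulate_itc(
            BindingParameters(k_d=math.exp(log_kd), delta_h=dh, n=n,
                              temperature=proto.temperature),
            proto,
        )
        return (sim.heats[usable] - y) / scale

    theta0 = np.array([math.log(params0.k_d), params0.delta_h, params0.n])
    result = optimize.least_squares(
        residuals, theta0, method="trf",
        bounds=([-60.0, -1e6, 1e-3], [5.0, 1e6, 1e3]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not result.success:
        raise RuntimeError(f"ITC fit did not converge: {result.message}")

    log_kd, dh, n = result.x
    k_d = math.exp(log_kd)
    # ΔS from ΔG(K_d) = ΔH − TΔS
    delta_g = R_GAS * proto.temperature * math.log(k_d) / 1000.0
    delta_s = (dh - delta_g) / proto.temperature * 1000.0

    # covariance from the Jacobian at the solution
    dof = max(len(usable) - 3, 1)
    jtj = result.jac.T @ result.jac
    try:
        cov = np.linalg.inv(jtj) * 2.0 * result.cost / dof
        errs = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        stderr = {"k_d": k_d * errs[0], "delta_h": errs[1], "n": errs[2]}
    except np.linalg.LinAlgError:
        stderr = {"k_d": float("nan"), "delta_h": float("nan"), "n": float("nan")}

    fitted = BindingParameters(k_d=k_d, delta_h=float(dh), n=float(n),
                               delta_s=float(delta_s), temperature=proto.temperature)
    return {
        "params": fitted,
        "stderr": stderr,
        "cost": float(result.cost),
        "n_injections_used": int(len(usable)),
        "converged": bool(result.success),
    }


# ---------------------------------------------------------------------------
# Fraction-bound isotherm (mobility-shift style data)
# ---------------------------------------------------------------------------

def fit_fraction_bound(concentrations: np.ndarray, fractions: np.ndarray) -> dict:
    """Fit f = [P] / (K_d + [P]) to fraction-bound data (protein in excess).

    Requires >= 4 concentration points that actually sample the transition.
    """
    conc = np.asarray(concentrations, float)
    frac = np.asarray(fractions, float)
    if conc.shape != frac.shape or conc.size < 4:
        raise ValueError("need >= 4 matched concentration/fraction points")
    if np.all(frac < 0.1) or np.all(frac > 0.9):
        raise ValueError("no transition sampled: fractions all near 0 or all near 1")

    def model(c, log_kd):
        kd = np.exp(log_kd)
        return c / (kd + c)

    guess = np.log(np.median(conc[conc > 0]))
    popt, pcov = optimize.curve_fit(model, conc, frac, p0=[guess], maxfev=10000)
    k_d = float(np.exp(popt[0]))
    k_d_err = k_d * float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return {"k_d": k_d, "stderr": k_d_err}
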