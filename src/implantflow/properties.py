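"""Material constants and constitutive laws for the blood model.

Whole blood is treated as two continuum phases: blood plasma (primary,
carrying dissolved fibrinogen) and red blood cells (secondary).  The
plasma-fibrinogen mixture density follows a volume-weighted (harmonic in
mass fraction) mixing law, and the plasma viscosity is a piecewise
function of fibrinogen concentration fitted from rheological data.
Per-cell properties blend the two phases arithmetically by the plasma
volume fraction (the standard VOF mixture rule).

Units: SI throughout (kg/m^3, Pa.s, m^2/s, N/m), except fibrinogen
concentration ``C`` which follows clinical convention, g/100 mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Piecewise plasma viscosity law: (C_lo, C_hi, evaluate(C) -> mPa.s).
#: Linear below 1.0 g/100 mL, quadratic above; the fit has a small (<1%)
#: printed discontinuity at C = 0.40 which is kept as published.
_VISCOSITY_PIECES = (
    (0.00, 0.40, (0.0, 1.16, 0.53)),   # a*C^2 + b*C + c, in mPa.s
    (0.40, 1.00, (0.0, 0.37, 0.85)),
    (1.00, np.inf, (0.19, 0.0, 1.03)),
)


@dataclass(frozen=True)
class FluidProperties:
    """Material constants of the plasma / RBC / fibrinogen system."""

    rho_plasma: float = 1025.0       # fibrinogen-free plasma density, kg/m^3
    rho_fibrinogen: float = 1400.0   # fibrinogen (dense protein) density, kg/m^3
    rho_rbc: float = 1125.0          # red-blood-cell phase density, kg/m^3
    mu_rbc: float = 0.0050           # RBC phase dynamic viscosity, Pa.s
    sigma: float = 0.021             # plasma-RBC interfacial tension, N/m
    D_fib: float = 0.23e-10          # fibrinogen diffusion coefficient, m^2/s
    viscosity_pieces: tuple = _VISCOSITY_PIECES

    def __post_init__(self) -> None:
        for name in ("rho_plasma", "rho_fibrinogen", "rho_rbc", "mu_rbc"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("sigma", "D_fib"):
            # zero disables surface tension / diffusion (benchmark cases)
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")
        lo = 0.0
        for c_lo, c_hi, _ in self.viscosity_pieces:
            if c_lo != lo:
                raise ValueError("viscosity law has a gap or overlap in C")
            lo = c_hi
        if lo != np.inf:
            raise ValueError("viscosity law must cover all C >= 0")

    # -- constitutive laws ----------------------------------------------

    def mixture_density(self, Y0):
        """Plasma-fibrinogen mixture density (kg/m^3), harmonic in Y0.

        ``rho_m = 1 / (Y0/rho_fib + (1-Y0)/rho_plasma)`` — the
        volume-weighted mixing law for mass fractions.
        """
        Y0 = np.asarray(Y0, dtype=float)
        if np.any(Y0 < 0.0) or np.any(Y0 > 1.0):
            raise ValueError("mass fraction Y0 must lie in [0, 1]")
        out = 1.0 / (Y0 / self.rho_fibrinogen + (1.0 - Y0) / self.rho_plasma)
        return out if out.ndim else float(out)

    def plasma_viscosity(self, C):
        """Plasma dynamic viscosity (Pa.s) at fibrinogen concentration C (g/100 mL)."""
        C = np.asarray(C, dtype=float)
        if np.any(C < 0.0):
            raise ValueError("concentration C must be non-negative")
        mu = np.empty_like(C)
        for c_lo, c_hi, (a, b, c) in self.viscosity_pieces:
            m = (C >= c_lo) & (C < c_hi)
            mu[m] = a * C[m] ** 2 + b * C[m] + c
        mu *= 1e-3
        return mu if mu.ndim else float(mu)

    def concentration_from_mass_fraction(self, Y0, rho_m):
        """C (g/100 mL) of fibrinogen at mass fraction Y0 in a mixture of
        density rho_m (kg/m^3); 1 kg/m^3 = 0.1 g/100 mL."""
        out = 0.1 * np.asarray(Y0, dtype=float) * np.asarray(rho_m, dtype=float)
        return out if out.ndim else float(out)

    def mass_fraction_from_concentration(self, C, rho_m):
        """Inverse of :meth:`concentration_from_mass_fraction`."""
        out = np.asarray(C, dtype=float) / (0.1 * np.asarray(rho_m, dtype=float))
        return out if out.ndim else float(out)

    def cell_mixture_properties(self, alpha_p, Y0):
        """Per-cell (density, viscosity) blended arithmetically by the
        plasma volume fraction ``alpha_p`` between the plasma-fibrinogen
        mixture and the RBC phase."""
        alpha_p = np.asarray(alpha_p, dtype=float)
        if np.any(alpha_p < -1e-12) or np.any(alpha_p > 1.0 + 1e-12):
            raise ValueError("alpha_p must lie in [0, 1]")
        alpha_p = np.clip(alpha_p, 0.0, 1.0)
        rho_m = self.mixture_density(Y0)
        C = self.concentration_from_mass_fraction(Y0, rho_m)
        mu_m = self.plasma_viscosity(C)
        rho = alpha_p * rho_m + (1.0 - alpha_p) * self.rho_rbc
        mu = alpha_p * mu_m + (1.0 - alpha_p) * self.mu_rbc
        if rho.ndim:
            return rho, mu
        return float(rho), float(mu)


def inlet_mass_fraction(serum_fib: float = 3.0, serum_density: float = 1024.0) -> float:
    """Inlet fibrinogen mass fraction: serum fibrinogen concentration
    (kg/m^3) over blood-serum density (kg/m^3), rounded to 2 significant
    figures (the convention of the reference boundary condition).

    Defaults: 300 mg/dL = 3 kg/m^3 fibrinogen in 1024 kg/m^3 serum -> 0.0029.
    """
    if serum_density <= 0.0:
        raise ValueError("serum_density must be positive")
    if serum_fib < 0.0:
        raise ValueError("serum_fib must be non-negative")
    q = serum_fib / serum_density
    if q == 0.0:
        return 0.0
    exponent = int(np.floor(np.log10(abs(q))))
    return float(round(q, -exponent + 1))


def reynolds_number(rho: float, speed: float, length: float, mu: float) -> float:
    """Re = rho * v * L / mu."""
    if mu <= 0.0:
        raise ValueError("viscosity must be strictly positive")
    return rho * speed * length / mu


def inlet_reynolds_number(props: FluidProperties | None = None,
                          speed: float = 0.01, width_mm: float = 1.5,
                          hematocrit: float = 0.45,
                          inlet_Y0: float = 0.0029) -> float:
    """Reynolds number of the inlet whole-blood stream.

    Uses the channel width as the length scale and the inlet-composition
    arithmetic phase blend (hematocrit RBC + plasma at the inlet
    fibrinogen load) for density and viscosity; with the defaults this
    evaluates to ~5.9, i.e. 6 to the nearest integer — deep in the
    laminar regime (turbulence onset ~2800).
    """
    props = props or FluidProperties()
    rho, mu = props.cell_mixture_properties(1.0 - hematocrit, inlet_Y0)
    return reynolds_number(rho, speed, width_mm * 1e-3, mu)
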