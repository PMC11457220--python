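"""Photolysis rate coefficients from cross-section, quantum yield and flux.

The first-order photolysis rate coefficient over the actinic window
(280–400 nm, the tropospheric sunlight region) is

    J = ∫ φ(λ) σ(λ) F(λ) dλ   [s⁻¹],

with φ the photolysis quantum yield, σ the photoabsorption
cross-section (cm²·molecule⁻¹) and F the actinic flux
(photons·cm⁻²·s⁻¹·nm⁻¹).  The integrand j(λ) = φσF is retained in the
result so its wavelength profile can be inspected.

Three standardized flux presets are shipped, parameterized by solar
zenith angle and overhead ozone column: high (0°, 200 DU), medium
(60°, 350 DU) and low (90°, 500 DU), all at 0 km ground elevation.
The packaged tables are generated by an analytic radiative-transfer
surrogate (Planck photon irradiance at the solar effective temperature,
attenuated by Beer–Lambert ozone Hartley-band absorption and Rayleigh
scattering along a Kasten–Young airmass path); they are replaceable and
non-authoritative — supply a measured or modelled flux CSV for
quantitative atmospheric work.

Numerical choices: σ is resampled onto the flux wavelength grid by
linear interpolation and treated as zero outside its computed grid
(conservative for J); J is evaluated by trapezoidal quadrature on the
tabulated grid, since flux tables are data, not smooth functions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .core_io import ActinicFlux, CrossSection, ev_to_nm, read_flux_csv

logger = logging.getLogger("neaspec")

ACTINIC_WINDOW_NM = (280.0, 400.0)

#: Preset label → (solar zenith angle in degrees, ozone column in Dobson units)
FLUX_PRESETS: dict[str, tuple[float, float]] = {
    "high": (0.0, 200.0),
    "medium": (60.0, 350.0),
    "low": (90.0, 500.0),
}

# ---- analytic flux surrogate (documents how the packaged tables were made) --

_SOLAR_T_K = 5772.0            # solar effective temperature
_SUN_SOLID = 2.1635e-5         # (R_sun / 1 AU)²
_DU_CM2 = 2.6867e16            # molecules·cm⁻² per Dobson unit
_O3_PEAK_CM2 = 1.13e-17        # Hartley-band peak cross-section
_O3_CENTER_NM = 255.0
_O3_WIDTH_NM = 23.0
_RAYLEIGH_EFF = 0.5            # fraction of Rayleigh extinction not recovered
                               # as downwelling scattered (actinic) light


def _airmass(zenith_deg: float) -> float:
    """Kasten–Young airmass; finite at the horizon (≈ 38 at 90°)."""
    z = zenith_deg
    return 1.0 / (math.cos(math.radians(z)) + 0.50572 * (96.07995 - z) ** -1.6364)


def surrogate_flux(zenith_deg: float, ozone_du: float,
                   wavelengths_nm: np.ndarray | None = None) -> ActinicFlux:
    """Analytic surrogate actinic flux on a 1 nm grid over 280–400 nm.

    Top-of-atmosphere photon irradiance from a 5772 K Planck spectrum scaled
    by the solar solid angle, attenuated by exp(−(τ_O3 + 0.5·τ_Rayleigh)·m)
    with m the Kasten–Young airmass.  The ozone cross-section is a Gaussian
    model of the Hartley band (peak 1.13e-17 cm² at 255 nm).
    """
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(ACTINIC_WINDOW_NM[0], ACTINIC_WINDOW_NM[1] + 0.5, 1.0)
    lam_m = wavelengths_nm * 1e-9
    h, c, kb = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    # photon spectral irradiance at 1 AU: π (R/d)² · (2c/λ⁴) / (exp(hc/λkT)−1)
    planck = (2.0 * c / lam_m**4) / np.expm1(h * c / (lam_m * kb * _SOLAR_T_K))
    f0 = math.pi * _SUN_SOLID * planck          # photons m⁻² s⁻¹ m⁻¹
    f0 = f0 * 1e-4 * 1e-9                       # → photons cm⁻² s⁻¹ nm⁻¹

    m = _airmass(zenith_deg)
    sigma_o3 = _O3_PEAK_CM2 * np.exp(-(((wavelengths_nm - _O3_CENTER_NM) / _O3_WIDTH_NM) ** 2))
    tau_o3 = sigma_o3 * ozone_du * _DU_CM2
    tau_ray = 0.00877 * (wavelengths_nm / 1000.0) ** -4.05
    flux = f0 * np.exp(-(tau_o3 + _RAYLEIGH_EFF * tau_ray) * m)
    label = f"surrogate zenith={zenith_deg:g}, O3={ozone_du:g}DU, 0 km a.s.l."
    return ActinicFlux(wavelengths_nm, flux, label)


def standard_actinic_flux(label: str) -> ActinicFlux:
    """Load a packaged standardized actinic flux preset (high|medium|low).

    The tables live in ``neaspec/data/flux_<label>.csv`` and were generated
    once by :func:`surrogate_flux` (see ``scripts/make_flux_tables.py``);
    their metadata records the zenith-angle/ozone parameters.
    """
    if label not in FLUX_PRESETS:
        raise ValueError(
            f"unknown flux preset {label!r}; valid labels: {sorted(FLUX_PRESETS)}"
        )
    zen, o3 = FLUX_PRESETS[label]
    ref = resources.files("neaspec").joinpath(f"data/flux_{label}.csv")
    with resources.as_file(ref) as path:
        flux = read_flux_csv(path, label=f"{label} (zenith={zen:g}, O3={o3:g}DU)")
    return flux


# ---------------------------------------------------------------------------
# Quantum yield and J
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantumYieldModel:
    """Photolysis quantum yield φ(λ): constant or tabulated vs wavelength.

    ``phi`` is a scalar for ``kind='constant'`` or an (N, 2) table of
    (wavelength nm, φ) for ``kind='tabulated'`` (linearly interpolated,
    end values extended).  φ must lie in [0, 1] everywhere.
    """

    kind: str = "constant"
    phi: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        if self.kind == "constant":
            if not 0.0 <= float(self.phi) <= 1.0:
                raise ValueError(f"quantum yield must be in [0, 1], got {self.phi}")
        elif self.kind == "tabulated":
            tab = np.asarray(self.phi, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2:
                raise ValueError("tabulated quantum yield must be (N, 2): (nm, phi)")
            if np.any((tab[:, 1] < 0) | (tab[:, 1] > 1)):
                raise ValueError("quantum yield values must be in [0, 1]")
            if np.any(np.diff(tab[:, 0]) <= 0):
                raise ValueError("quantum-yield wavelengths must be strictly increasing")
            object.__setattr__(self, "phi", tab)
        else:
            raise ValueError(f"kind must be constant|tabulated, got {self.kind!r}")

    def evaluate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if self.kind == "constant":
            return np.full_like(wl, float(self.phi))
        tab = self.phi
        return np.interp(wl, tab[:, 0], tab[:, 1])


@dataclass(frozen=True)
class PhotolysisResult:
    """J (s⁻¹) with its integrand j(λ) = φσF and integration window."""

    J: float
    wavelengths: np.ndarray
    integrand: np.ndarray
    window: tuple[float, float]
    flux_label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        j = np.asarray(self.integrand, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "integrand", j)
        if self.J < 0:
            raise ValueError("J must be ≥ 0")
        quad = float(np.trapezoid(j, wl))
        if abs(quad - self.J) > 1e-12 * max(abs(self.J), 1e-300):
            raise ValueError("stored J does not equal the quadrature of its integrand")


def photolysis_rate(cs: CrossSection,
                    qy: QuantumYieldModel | float = 1.0,
                    flux: ActinicFlux | str = "high",
                    window: tuple[float, float] = ACTINIC_WINDOW_NM) -> PhotolysisResult:
    """Photolysis rate coefficient J = ∫φσF dλ over ``window`` (nm).

    ``qy`` may be a :class:`QuantumYieldModel` or a constant φ; ``flux`` an
    :class:`ActinicFlux` or a preset label.  The cross-section's energy grid
    is converted to wavelength (λ = hc/E) and σ linearly interpolated onto
    the flux grid; wavelengths outside σ's coverage contribute zero (with a
    logged warning).  Units: cm² · photons·cm⁻²·s⁻¹·nm⁻¹ · nm = s⁻¹.
    """
    if isinstance(qy, (int, float)):
        qy = QuantumYieldModel("constant", float(qy))
    if isinstance(flux, str):
        flux = standard_actinic_flux(flux)
    lo, hi = float(min(window)), float(max(window))

    inside = (flux.wavelengths >= lo) & (flux.wavelengths <= hi)
    if not np.any(inside):
        raise ValueError(
            f"window {window} nm has no overlap with the flux grid "
            f"[{flux.wavelengths[0]:g}, {flux.wavelengths[-1]:g}] nm"
        )
    wl = flux.wavelengths[inside]
    # include exact window endpoints so J is additive over sub-windows
    if wl[0] > lo and lo >= flux.wavelengths[0]:
        wl = np.concatenate([[lo], wl])
    if wl[-1] < hi and hi <= flux.wavelengths[-1]:
        wl = np.concatenate([wl, [hi]])
    f = np.interp(wl, flux.wavelengths, flux.flux)

    # σ on the wavelength grid: energy grid increasing ⇒ nm grid decreasing
    cs_nm = ev_to_nm(cs.grid)[::-1]
    cs_vals = cs.values[::-1]
    sigma = np.interp(wl, cs_nm, cs_vals, left=0.0, right=0.0)
    if wl[0] < cs_nm[0] or wl[-1] > cs_nm[-1]:
        logger.warning(
            "cross-section grid [%.1f, %.1f] nm does not cover the window "
            "[%g, %g] nm; σ treated as 0 outside its coverage",
            cs_nm[0], cs_nm[-1], lo, hi,
        )

    phi = qy.evaluate(wl)
    integrand = phi * sigma * f
    J = float(np.trapezoid(integrand, wl))
    meta = {"phi_kind": qy.kind,
            "phi": float(qy.phi) if qy.kind == "constant" else "tabulated"}
    return PhotolysisResult(J, wl, integrand, (lo, hi), flux.label, meta)


def write_photolysis_json(result: PhotolysisResult, path: str | Path) -> None:
    """Write the J result as a small JSON record (deterministic formatting)."""
    import json

    rec = {
        "J_s1": result.J,
        "window_nm": list(result.window),
        "flux_label": result.flux_label,
        "phi": result.meta.get("phi"),
    }
    Path(path).write_text(json.dumps(rec, indent=1, sort_keys=True) + "\n")
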