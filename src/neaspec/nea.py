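"""Nuclear-ensemble photoabsorption cross-sections and conformer weighting.

The nuclear ensemble approach (NEA) estimates the absolute
photoabsorption cross-section by averaging broadened vertical
transitions over N_p geometries sampled from the ground-state nuclear
density:

    σ(E) = C · (1/N_p) Σ_j Σ_I  f_0I(R_j) · g_δ(E − ΔE_0I(R_j)),

where f_0I is the oscillator strength of transition 0→I at geometry R_j,
g_δ a unit-area lineshape of width δ in energy, and
C = πe²ħ/(2 m_e c ε₀) ≈ 1.0976e-16 cm²·eV the integrated cross-section
of a unit-oscillator-strength transition.  The band-area sum rule
∫σ dE = C·⟨Σ_I f⟩ is the normative contract of this module and is what
makes the cross-section absolute.

Width convention: δ is the Gaussian standard deviation and the
Lorentzian half-width at half-maximum.  Both lineshapes integrate to 1
over energy, so band area is conserved across lineshape choices.

When a molecule populates several conformers, each conformer's spectrum
is computed separately and the total is the Boltzmann-weighted sum
σ_total(E) = Σ_i w_i σ_i(E).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import (
    HARTREE_EV,
    R_KJ_MOL_K,
    SIGMA_PREFACTOR_CM2_EV,
    CrossSection,
    ExcitationTable,
)

logger = logging.getLogger("neaspec")

DEFAULT_DELTA_EV = 0.05
DEFAULT_GRID_POINTS = 4096
GRID_PADDING_DELTAS = 6.0


@dataclass(frozen=True)
class LineshapeSpec:
    """Broadening applied to each vertical transition.

    ``kind`` is ``gaussian`` (δ = standard deviation) or ``lorentzian``
    (δ = HWHM); either way the lineshape has unit area in energy so that
    the band-area sum rule holds.
    """

    kind: str = "gaussian"
    delta: float = DEFAULT_DELTA_EV

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "lorentzian"):
            raise ValueError(f"lineshape kind must be gaussian|lorentzian, got {self.kind!r}")
        if self.delta <= 0:
            raise ValueError(f"broadening width delta must be > 0 eV, got {self.delta}")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Unit-area lineshape g_δ(x) at energy offsets ``x`` (eV)."""
        if self.kind == "gaussian":
            return np.exp(-0.5 * (x / self.delta) ** 2) / (self.delta * math.sqrt(2 * math.pi))
        return (self.delta / math.pi) / (x * x + self.delta * self.delta)


def oscillator_strength(energy_ev: float, tdm_au: Sequence[float]) -> float:
    """Oscillator strength f = (2/3)·ΔE[Hartree]·|μ|²[a.u.] of a transition."""
    if energy_ev <= 0:
        raise ValueError(f"excitation energy must be > 0 eV, got {energy_ev}")
    mu2 = float(np.dot(tdm_au, tdm_au))
    return (2.0 / 3.0) * (energy_ev / HARTREE_EV) * mu2


def _table_arrays(table: ExcitationTable) -> tuple[np.ndarray, np.ndarray]:
    """(N_p, N_s) arrays of transition energies (eV) and oscillator strengths."""
    energies = np.empty((table.n_geometries, table.n_states))
    fosc = np.empty_like(energies)
    for j, rec in enumerate(table.records):
        for i, exc in enumerate(rec):
            energies[j, i] = exc.energy
            fosc[j, i] = (exc.fosc if exc.fosc is not None
                          else oscillator_strength(exc.energy, exc.tdm))
    return energies, fosc


def default_grid(table: ExcitationTable, shape: LineshapeSpec,
                 n_points: int = DEFAULT_GRID_POINTS) -> np.ndarray:
    """Energy grid spanning [min ΔE − 6δ, max ΔE + 6δ] with ``n_points`` points."""
    energies, _ = _table_arrays(table)
    lo = energies.min() - GRID_PADDING_DELTAS * shape.delta
    hi = energies.max() + GRID_PADDING_DELTAS * shape.delta
    lo = max(lo, 1e-6)  # photon energies are positive
    return np.linspace(lo, hi, n_points)


def compute_cross_section(table: ExcitationTable,
                          grid: np.ndarray | None = None,
                          shape: LineshapeSpec | None = None,
                          meta: dict | None = None) -> CrossSection:
    """NEA cross-section: ensemble average of broadened transitions.

    Oscillator strengths are used directly where the table supplies them and
    derived from the transition dipole otherwise.  The per-point Monte-Carlo
    standard error (std-dev across geometry contributions / √N_p) is stored
    in ``meta['stderr_cm2']`` so ensemble convergence can be judged.

    Warnings (recorded in ``meta['warnings']``): a grid that does not cover
    all transitions ± 5δ truncates band area; fewer than 8 grid points per δ
    under-resolves the lineshape.
    """
    shape = shape or LineshapeSpec()
    if grid is None:
        grid = default_grid(table, shape)
    grid = np.asarray(grid, dtype=float)
    energies, fosc = _table_arrays(table)
    n_p = table.n_geometries

    warnings = []
    if grid[0] > energies.min() - 5 * shape.delta or grid[-1] < energies.max() + 5 * shape.delta:
        warnings.append("grid does not span all transitions ± 5δ: band area truncated")
    if np.max(np.diff(grid)) > shape.delta / 8:
        warnings.append("grid coarser than 8 points per δ: lineshape under-resolved")
    for w in warnings:
        logger.warning(w)

    # per-geometry contribution σ_j(E) = C Σ_I f_jI g_δ(E − E_jI), shape (N_p, G)
    contrib = np.zeros((n_p, grid.size))
    for i in range(table.n_states):
        g = shape.evaluate(grid[None, :] - energies[:, i, None])
        contrib += fosc[:, i, None] * g
    contrib *= SIGMA_PREFACTOR_CM2_EV

    values = contrib.mean(axis=0)
    stderr = (contrib.std(axis=0, ddof=1) / math.sqrt(n_p) if n_p > 1
              else np.zeros_like(values))

    full_meta = {
        "n_geometries": n_p,
        "n_states": table.n_states,
        "stderr_cm2": stderr,
        "sum_fosc_mean": float(fosc.sum(axis=1).mean()),
        "warnings": warnings,
    }
    if meta:
        full_meta.update(meta)
    return CrossSection(grid, values, shape.delta, shape.kind, full_meta)


# ---------------------------------------------------------------------------
# Conformer combination
# ---------------------------------------------------------------------------

def boltzmann_weights(rel_energies_kj_mol: Sequence[float],
                      temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann populations w_i ∝ exp(−ΔE_i/RT).

    Energies are shifted by their minimum before exponentiation, which is
    overflow-safe and leaves the normalized weights unchanged.
    R = 8.31446e-3 kJ·mol⁻¹·K⁻¹.
    """
    e = np.asarray(rel_energies_kj_mol, dtype=float)
    if e.size == 0:
        raise ValueError("empty relative-energy array")
    if temperature <= 0:
        raise ValueError("temperature must be > 0 K")
    x = np.exp(-(e - e.min()) / (R_KJ_MOL_K * temperature))
    return x / x.sum()


@dataclass(frozen=True)
class ConformerSet:
    """Conformer spectra with Boltzmann populations at a temperature.

    ``conformers`` is a list of (label, relative energy in kJ/mol,
    CrossSection); relative energies are re-referenced to their minimum so
    the most stable conformer sits at 0.
    """

    conformers: tuple[tuple[str, float, CrossSection], ...]
    temperature: float = 298.15
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        confs = tuple((str(l), float(e), cs) for l, e, cs in self.conformers)
        if not confs:
            raise ValueError("conformer set is empty")
        e = np.array([c[1] for c in confs])
        confs = tuple((l, en - e.min(), cs) for (l, _, cs), en in zip(confs, e))
        object.__setattr__(self, "conformers", confs)
        if self.weights is None:
            w = boltzmann_weights(e, self.temperature)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(confs),):
                raise ValueError("weights/spectra count mismatch")
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("weights must be ≥ 0 and sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.conformers)


def combine_conformer_spectra(conformer_set: ConformerSet) -> CrossSection:
    """Boltzmann-weighted total spectrum σ_total(E) = Σ_i w_i σ_i(E).

    Spectra are combined on the first conformer's grid; others are resampled
    by linear interpolation if their grids differ (recorded in meta).  The
    per-conformer weighted contributions are retained in
    ``meta['conformer_contributions']`` so each conformer's share of the
    total band can be displayed.
    """
    confs = conformer_set.conformers
    weights = conformer_set.weights
    grid = confs[0][2].grid
    resampled = False
    contributions = {}
    total = np.zeros_like(grid)
    for (label, _, cs), w in zip(confs, weights):
        if cs.grid.shape == grid.shape and np.array_equal(cs.grid, grid):
            vals = cs.values
        else:
            vals = cs.interp(grid)
            resampled = True
        contributions[label] = w * vals
        total = total + w * vals
    first = confs[0][2]
    meta = {
        "conformer_labels": list(conformer_set.labels),
        "conformer_weights": [float(w) for w in weights],
        "temperature_K": conformer_set.temperature,
        "conformer_contributions": contributions,
        "resampled": resampled,
    }
    if resampled:
        logger.info("conformer spectra were on different grids; resampled by "
                    "linear interpolation onto the first conformer's grid")
    return CrossSection(grid, total, first.delta, first.lineshape, meta)


def band_moments(cs: CrossSection,
                 deconvolve_delta: bool = True) -> tuple[float, float]:
    """Intensity-weighted band mean and standard deviation (eV).

    With ``deconvolve_delta`` the Gaussian broadening variance δ² is
    subtracted from the measured band variance, recovering the moments of
    the underlying vertical-excitation distribution (a Gaussian convolution
    adds variances).  Only meaningful for Gaussian lineshapes.
    """
    area = np.trapezoid(cs.values, cs.grid)
    if area <= 0:
        raise ValueError("cannot compute band moments of an empty spectrum")
    mean = np.trapezoid(cs.grid * cs.values, cs.grid) / area
    var = np.trapezoid((cs.grid - mean) ** 2 * cs.values, cs.grid) / area
    if deconvolve_delta and cs.lineshape == "gaussian":
        var = max(var - cs.delta ** 2, 0.0)
    return float(mean), float(math.sqrt(var))
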