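"""Harmonic Wigner sampling of ground-state nuclear geometries.

The position marginal of the harmonic-oscillator Wigner function is a
Gaussian in each mass-weighted normal coordinate Q_k with

    Var(Q_k) = (ħ / 2ω_k) · coth(ħω_k / 2k_B T),

which reduces to the zero-point value ħ/2ω_k at T = 0.  The momentum
marginal is Gaussian with Var(P_k) = (ħω_k/2)·coth(ħω_k/2k_B T).
Sampling N_p geometries from this distribution and computing vertical
excitations at each is the "Wigner sampling" step of the nuclear
ensemble approach; the same samples can serve as initial conditions for
excited-state dynamics, which is why momenta are optionally drawn even
though the spectrum pipeline uses positions only.

All internal arithmetic is in atomic units (ħ = 1; frequencies converted
cm⁻¹ → Hartree, masses amu → electron masses), so sigmas are in
mass-weighted atomic units sqrt(m_e)·bohr.  Cartesian displacements are
converted back to Å at the end.

Caveat: the harmonic approximation is unreliable for soft, anharmonic
low-frequency modes (< 200 cm⁻¹); sampling them can generate
unphysically distorted geometries and spurious spectral tails.  Such
modes can be excluded with ``freq_cutoff``; a warning is logged whenever
they are sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    AMU_ME,
    BOHR_ANGSTROM,
    CM1_HARTREE,
    KB_HARTREE,
    MolecularGeometry,
    NormalModeSet,
    write_xyz_frames,
)

logger = logging.getLogger("neaspec")

#: Below this wavenumber the harmonic Wigner density is a poor model of the
#: true (anharmonic) nuclear density; sampling such modes risks artifacts.
SOFT_MODE_WARN_CM1 = 200.0


@dataclass(frozen=True)
class WignerDistribution:
    """Per-mode Gaussian widths of the harmonic Wigner position/momentum marginals.

    ``sigmaQ``/``sigmaP`` are in mass-weighted atomic units; ``active_mask``
    flags the modes that survived the frequency cutoff — masked modes
    contribute zero displacement.
    """

    modes: NormalModeSet
    temperature: float
    sigmaQ: np.ndarray
    sigmaP: np.ndarray
    active_mask: np.ndarray
    freq_cutoff: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigmaQ", "sigmaP", "active_mask"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))

    @property
    def n_active(self) -> int:
        return int(np.sum(self.active_mask))


@dataclass(frozen=True)
class WignerEnsemble:
    """N_p geometries (and optional momenta) drawn from a Wigner distribution."""

    geometries: tuple[MolecularGeometry, ...]
    momenta: np.ndarray | None
    seed: int
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.geometries) < 1:
            raise ValueError("ensemble must contain at least one geometry")
        n_atoms = self.geometries[0].n_atoms
        if any(g.n_atoms != n_atoms for g in self.geometries):
            raise ValueError("all ensemble geometries must share the parent atom list")

    @property
    def n_samples(self) -> int:
        return len(self.geometries)

    def write_xyz(self, path: str | Path) -> None:
        """Write the ensemble as multi-frame XYZ, one frame per sample."""
        comments = [f"wigner sample {i} seed {self.seed}"
                    for i in range(self.n_samples)]
        write_xyz_frames(self.geometries, path, comments)


def thermal_variance_factor(freq_cm1: np.ndarray | float,
                            temperature: float) -> np.ndarray | float:
    """coth(ħω/2k_BT): ratio of thermal to zero-point variance (→ 1 as T → 0)."""
    omega = np.asarray(freq_cm1, dtype=float) * CM1_HARTREE
    if temperature <= 0:
        return np.ones_like(omega) if omega.ndim else 1.0
    return 1.0 / np.tanh(omega / (2.0 * KB_HARTREE * temperature))


def build_wigner_distribution(modes: NormalModeSet,
                              temperature: float = 0.0,
                              freq_cutoff: float = 0.0) -> WignerDistribution:
    """Build the harmonic Wigner distribution for a normal-mode set.

    Parameters
    ----------
    modes
        Equilibrium geometry + vibrational frequencies + mass-weighted modes.
    temperature
        Kelvin; 0 gives the zero-point (ground-state) Wigner distribution.
    freq_cutoff
        Modes with ω < ``freq_cutoff`` (cm⁻¹) are masked out of the sampling
        (they then contribute zero displacement).
    """
    if temperature < 0:
        raise ValueError("temperature must be ≥ 0 K")
    if freq_cutoff < 0:
        raise ValueError("freq_cutoff must be ≥ 0 cm⁻¹")
    freqs = modes.frequencies
    active = freqs >= freq_cutoff
    n_masked = int(np.sum(~active))
    if n_masked:
        logger.info("frequency cutoff %g cm⁻¹ masked %d of %d modes",
                    freq_cutoff, n_masked, len(freqs))
    if not np.any(active):
        raise ValueError(
            f"frequency cutoff {freq_cutoff} cm⁻¹ masks all {len(freqs)} modes: "
            "nothing to sample"
        )
    soft = active & (freqs < SOFT_MODE_WARN_CM1)
    if np.any(soft):
        logger.warning(
            "sampling %d low-frequency mode(s) < %g cm⁻¹ (%s); the harmonic "
            "Wigner density is a poor model for such soft modes and may produce "
            "unphysically distorted geometries — consider a frequency cutoff",
            int(np.sum(soft)), SOFT_MODE_WARN_CM1,
            np.array2string(freqs[soft], precision=1),
        )

    omega = freqs * CM1_HARTREE  # Hartree (ħ=1 ⇒ also angular frequency a.u.)
    coth = np.asarray(thermal_variance_factor(freqs, temperature))
    sigmaQ = np.sqrt(coth / (2.0 * omega))
    sigmaP = np.sqrt(coth * omega / 2.0)
    sigmaQ = np.where(active, sigmaQ, 0.0)
    sigmaP = np.where(active, sigmaP, 0.0)
    return WignerDistribution(modes, float(temperature), sigmaQ, sigmaP,
                              active, float(freq_cutoff))


def sample_wigner(dist: WignerDistribution, n_samples: int, seed: int,
                  with_momenta: bool = False) -> WignerEnsemble:
    """Draw ``n_samples`` geometries (and optionally momenta).

    Reproducibility contract: a single ``numpy.random.default_rng(seed)``
    stream is consumed in a fixed order — all position deviates first
    (sample-by-sample, mode-major within each sample), then, if requested,
    all momentum deviates in the same order.  The same seed therefore yields
    a bit-identical ensemble regardless of platform.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be ≥ 1")
    nm = dist.modes
    eq = nm.equilibrium
    rng = np.random.default_rng(seed)

    # deviates: (n_samples, n_modes); masked modes have sigma 0 ⇒ no displacement
    dQ = rng.standard_normal((n_samples, nm.n_modes)) * dist.sigmaQ  # mw a.u.

    masses_me = eq.masses * AMU_ME
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses_me), 3)  # per Cartesian component
    # Cartesian displacement (bohr): Δx = Σ_k L_k / sqrt(m) · ΔQ_k
    dx_bohr = dQ @ (nm.modes * inv_sqrt_m[None, :])
    dx_ang = dx_bohr * BOHR_ANGSTROM

    eq_flat = eq.coords.reshape(-1)
    geometries = tuple(
        MolecularGeometry(eq.symbols, eq.masses,
                          (eq_flat + dx_ang[j]).reshape(-1, 3))
        for j in range(n_samples)
    )

    momenta = None
    if with_momenta:
        dP = rng.standard_normal((n_samples, nm.n_modes)) * dist.sigmaP
        sqrt_m = np.repeat(np.sqrt(masses_me), 3)
        # Cartesian momenta (a.u.): p = Σ_k sqrt(m) L_k P_k
        momenta = (dP @ (nm.modes * sqrt_m[None, :])).reshape(n_samples, -1, 3)

    provenance = {
        "seed": int(seed),
        "temperature_K": dist.temperature,
        "freq_cutoff_cm1": dist.freq_cutoff,
        "n_modes_active": dist.n_active,
    }
    return WignerEnsemble(geometries, momenta, int(seed), provenance)


def mass_weighted_projection(ensemble_or_geom, modes: NormalModeSet,
                             mode_index: int = 0) -> np.ndarray | float:
    """Project Cartesian displacements onto mass-weighted mode k.

    Returns Q_k = Σ_a sqrt(m_a) (r_a − r_eq,a) · L_{k,a} in mass-weighted
    atomic units — the inverse of the transform used by :func:`sample_wigner`.
    Accepts a single geometry or a :class:`WignerEnsemble`.
    """
    eq = modes.equilibrium
    sqrt_m = np.repeat(np.sqrt(eq.masses * AMU_ME), 3)
    L = modes.modes[mode_index]

    def _project(geom: MolecularGeometry) -> float:
        dx_bohr = (geom.coords - eq.coords).reshape(-1) / BOHR_ANGSTROM
        return float(np.dot(dx_bohr * sqrt_m, L))

    if isinstance(ensemble_or_geom, WignerEnsemble):
        return np.array([_project(g) for g in ensemble_or_geom.geometries])
    return _project(ensemble_or_geom)
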