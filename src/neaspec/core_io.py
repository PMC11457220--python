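"""Domain types and file I/O for the nuclear-ensemble spectroscopy pipeline.

Defines the shared containers (molecular geometries, normal-mode sets,
vertical-excitation tables, cross-sections, actinic fluxes) and the
plain-text readers/writers that move them in and out of the package:
XYZ geometries, frequency records (a neutral JSON dialect and a
Molden-style dialect), CSV excitation tables, CSV spectra and CSV flux
tables.

Unit conventions
----------------
Coordinates are stored in Å, masses in amu (unified atomic mass units),
vibrational frequencies in cm⁻¹, excitation energies in eV, transition
dipoles in atomic units, cross-sections in cm²·molecule⁻¹ and actinic
fluxes in photons·cm⁻²·s⁻¹·nm⁻¹.  The energy/wavelength conversion uses
a fixed hc = 1239.841984 eV·nm so that written spectra are
bit-reproducible.  A cross-section is a point function of photon energy:
relabelling the axis in nm applies no Jacobian.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("neaspec")

# ---------------------------------------------------------------------------
# Physical constants (CODATA 2018 via scipy where rounding is immaterial;
# hc is pinned to a fixed literal so CSV axes never drift between releases).
# ---------------------------------------------------------------------------

#: Energy–wavelength conversion, eV·nm (λ[nm] = HC_EV_NM / E[eV]).
HC_EV_NM = 1239.841984
#: Hartree in eV.
HARTREE_EV = 27.211386245981
#: 1 cm⁻¹ in Hartree.
CM1_HARTREE = 4.5563352529132e-06
#: 1 amu in electron masses.
AMU_ME = 1822.888486
#: Boltzmann constant in Hartree / K.
KB_HARTREE = 3.1668115634564068e-06
#: Bohr radius in Å.
BOHR_ANGSTROM = 0.529177210903
#: Gas constant in kJ·mol⁻¹·K⁻¹.
R_KJ_MOL_K = 8.31446e-3

#: Integrated cross-section of a unit-oscillator-strength transition,
#: πe²ħ/(2 m_e c ε₀), in cm²·eV.  Computed from CODATA constants.
SIGMA_PREFACTOR_CM2_EV = 1.0976098670810204e-16

#: Threshold below which a frequency entry is treated as a translation or
#: rotation and dropped when reading frequency records (cm⁻¹).
NEAR_ZERO_FREQ_CM1 = 1.0

# Standard atomic weights (amu), elements 1-86, abridged IUPAC 2021 values.
STANDARD_ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Nb": 92.906, "Mo": 95.95, "Tc": 97.0, "Ru": 101.07, "Rh": 102.91,
    "Pd": 106.42, "Ag": 107.87, "Cd": 112.41, "In": 114.82, "Sn": 118.71,
    "Sb": 121.76, "Te": 127.60, "I": 126.90, "Xe": 131.29, "Cs": 132.91,
    "Ba": 137.33, "La": 138.91, "Ce": 140.12, "Pr": 140.91, "Nd": 144.24,
    "Pm": 145.0, "Sm": 150.36, "Eu": 151.96, "Gd": 157.25, "Tb": 158.93,
    "Dy": 162.50, "Ho": 164.93, "Er": 167.26, "Tm": 168.93, "Yb": 173.05,
    "Lu": 174.97, "Hf": 178.49, "Ta": 180.95, "W": 183.84, "Re": 186.21,
    "Os": 190.23, "Ir": 192.22, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
    "Tl": 204.38, "Pb": 207.2, "Bi": 208.98, "Po": 209.0, "At": 210.0,
    "Rn": 222.0,
}


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def ev_to_nm(energy_ev: np.ndarray | float) -> np.ndarray | float:
    """Convert photon energy (eV) to wavelength (nm); an involution."""
    return HC_EV_NM / np.asarray(energy_ev, dtype=float)


nm_to_ev = ev_to_nm  # the map λ = hc/E is its own inverse


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MolecularGeometry:
    """A molecular geometry: element symbols, masses (amu), coordinates (Å)."""

    symbols: tuple[str, ...]
    masses: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "coords", coords)
        n = len(self.symbols)
        if masses.shape != (n,) or coords.shape != (n, 3):
            raise ValueError(
                f"inconsistent atom count: {n} symbols, {masses.shape[0]} masses, "
                f"{coords.shape[0]} coordinate triples"
            )
        if not np.all(masses > 0):
            raise ValueError("atomic masses must be positive")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_symbols(cls, symbols: Sequence[str],
                     coords: np.ndarray) -> "MolecularGeometry":
        """Build a geometry, filling masses from the standard-weight table."""
        masses = np.array([atomic_mass(s) for s in symbols])
        return cls(tuple(symbols), masses, np.asarray(coords, dtype=float))


def atomic_mass(symbol: str) -> float:
    """Standard atomic weight (amu) for an element symbol."""
    try:
        return STANDARD_ATOMIC_WEIGHTS[symbol]
    except KeyError:
        raise ParseError(f"unknown element symbol {symbol!r}") from None


@dataclass(frozen=True)
class NormalModeSet:
    """Equilibrium geometry plus harmonic frequencies and mass-weighted modes.

    ``modes[k]`` is the unit-norm mass-weighted displacement 3N-vector of
    vibrational mode k; ``frequencies[k]`` its wavenumber in cm⁻¹.  Together
    with a temperature these define the harmonic Wigner distribution of the
    ground-state nuclear density.  Imaginary/negative frequencies are
    rejected: sampling presupposes a minimum on the ground-state surface.
    """

    equilibrium: MolecularGeometry
    frequencies: np.ndarray
    modes: np.ndarray
    provenance: dict = field(default_factory=dict, compare=False)

    _NORM_TOL = 1e-6
    _ORTHO_TOL = 1e-6

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        modes = np.asarray(self.modes, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        object.__setattr__(self, "modes", modes)
        if modes.ndim != 2 or modes.shape[0] != freqs.shape[0]:
            raise ValueError(
                f"{freqs.shape[0]} frequencies but {modes.shape[0] if modes.ndim == 2 else '?'} mode vectors"
            )
        if modes.shape[1] != 3 * self.equilibrium.n_atoms:
            raise ValueError(
                f"mode vectors have length {modes.shape[1]}, expected 3N = {3 * self.equilibrium.n_atoms}"
            )
        if np.any(freqs <= 0) or np.any(~np.isreal(freqs)):
            bad = freqs[freqs <= 0]
            raise ValueError(
                f"imaginary/negative frequencies {bad} cm⁻¹: Wigner sampling requires "
                "a true minimum (all real, positive vibrational frequencies)"
            )
        gram = modes @ modes.T
        if np.any(np.abs(np.diag(gram) - 1.0) > self._NORM_TOL):
            raise ValueError("mode vectors must have unit Euclidean norm")
        off = gram - np.diag(np.diag(gram))
        if np.any(np.abs(off) > self._ORTHO_TOL):
            raise ValueError(
                "mode vectors are not mutually orthogonal; supply mass-weighted "
                "normal modes (Cartesian displacement modes are not orthogonal)"
            )

    @property
    def n_modes(self) -> int:
        return int(self.frequencies.shape[0])


@dataclass(frozen=True)
class VerticalExcitation:
    """One vertical transition: state index I, gap ΔE_0I (eV), intensity.

    Intensity is carried either as the transition dipole vector ``tdm``
    (atomic units) or directly as the oscillator strength ``fosc``;
    at least one must be present.
    """

    state: int
    energy: float
    tdm: tuple[float, float, float] | None = None
    fosc: float | None = None

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError(f"excitation energy must be > 0 eV, got {self.energy}")
        if self.tdm is None and self.fosc is None:
            raise ValueError("provide at least one of tdm / fosc")
        if self.fosc is not None and self.fosc < 0:
            raise ValueError(f"oscillator strength must be ≥ 0, got {self.fosc}")
        if self.tdm is not None:
            object.__setattr__(self, "tdm", tuple(float(x) for x in self.tdm))


@dataclass(frozen=True)
class ExcitationTable:
    """Vertical excitations for N_p sampled geometries × N_s states.

    ``records[j]`` lists the N_s excitations of geometry j.  Rectangularity
    (the same N_s states, with distinct indices, for every geometry) is
    enforced so the ensemble average is well defined.
    """

    records: tuple[tuple[VerticalExcitation, ...], ...]
    geometry_ids: tuple = ()

    def __post_init__(self) -> None:
        records = tuple(tuple(r) for r in self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise ValueError("excitation table has no geometries")
        ids = self.geometry_ids or tuple(range(len(records)))
        object.__setattr__(self, "geometry_ids", tuple(ids))
        n_states = len(records[0])
        for gid, rec in zip(self.geometry_ids, records):
            if len(rec) != n_states:
                raise ValueError(
                    f"geometry {gid!r} has {len(rec)} states, expected {n_states} "
                    "(every geometry must carry the same N_s states)"
                )
            states = [e.state for e in rec]
            if len(set(states)) != len(states):
                raise ValueError(f"geometry {gid!r} has duplicate state indices {states}")

    @property
    def n_geometries(self) -> int:
        return len(self.records)

    @property
    def n_states(self) -> int:
        return len(self.records[0])


@dataclass(frozen=True)
class CrossSection:
    """Photoabsorption cross-section σ(E) on a photon-energy grid.

    ``grid`` is in eV, strictly increasing; ``values`` in cm²·molecule⁻¹.
    ``delta``/``lineshape`` record the broadening applied; ``meta`` carries
    provenance (seed, N_p, N_s, conformer weights, per-point Monte-Carlo
    standard error, ...).
    """

    grid: np.ndarray
    values: np.ndarray
    delta: float
    lineshape: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.size == 0:
            raise ValueError("cross-section grid is empty")
        if grid.shape != values.shape:
            raise ValueError("grid and values must have the same length")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("cross-section values must be ≥ 0")

    def interp(self, energies_ev: np.ndarray) -> np.ndarray:
        """σ linearly interpolated at ``energies_ev``; zero outside the grid."""
        return np.interp(energies_ev, self.grid, self.values, left=0.0, right=0.0)


@dataclass(frozen=True)
class ActinicFlux:
    """Actinic flux F(λ): wavelengths (nm) vs photons·cm⁻²·s⁻¹·nm⁻¹."""

    wavelengths: np.ndarray
    flux: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        fx = np.asarray(self.flux, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "flux", fx)
        if wl.shape != fx.shape or wl.size == 0:
            raise ValueError("wavelength and flux arrays must be equal-length, non-empty")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(fx < 0):
            raise ValueError("flux values must be ≥ 0")


# ---------------------------------------------------------------------------
# XYZ geometries
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> MolecularGeometry:
    """Read a single-frame XYZ file (count line, comment line, atom lines)."""
    lines = Path(path).read_text().splitlines()
    geoms = list(_iter_xyz_frames(lines, path))
    if len(geoms) != 1:
        raise ParseError(f"{path}: expected a single XYZ frame, found {len(geoms)}")
    return geoms[0]


def read_xyz_frames(path: str | Path) -> list[MolecularGeometry]:
    """Read a multi-frame (trajectory/ensemble) XYZ file."""
    lines = Path(path).read_text().splitlines()
    return list(_iter_xyz_frames(lines, path))


def _iter_xyz_frames(lines: list[str], path) -> Iterable[MolecularGeometry]:
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}")
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        symbols, coords = [], []
        for k in range(natoms):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(
                    f"{path}:{i + 1}: header declares {natoms} atoms but the file "
                    f"ends after {k}"
                )
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{ln + 1}: malformed atom line {lines[ln]!r}")
            sym = parts[0].capitalize()
            try:
                xyz = [float(p) for p in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path}:{ln + 1}: non-numeric coordinate in {lines[ln]!r}")
            symbols.append(sym)
            coords.append(xyz)
        yield MolecularGeometry.from_symbols(symbols, np.array(coords))
        i += 2 + natoms


def write_xyz(geometry: MolecularGeometry, path: str | Path,
              comment: str = "") -> None:
    """Write a single-frame XYZ file."""
    write_xyz_frames([geometry], path, comments=[comment])


def write_xyz_frames(geometries: Sequence[MolecularGeometry], path: str | Path,
                     comments: Sequence[str] | None = None) -> None:
    """Write a multi-frame XYZ file (one frame per geometry)."""
    if comments is None:
        comments = ["" for _ in geometries]
    out = []
    for geom, comment in zip(geometries, comments):
        out.append(f"{geom.n_atoms}")
        out.append(comment)
        for sym, (x, y, z) in zip(geom.symbols, geom.coords):
            out.append(f"{sym:<3s} {x:20.12f} {y:20.12f} {z:20.12f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Frequency records
# ---------------------------------------------------------------------------

def read_frequency_record(path: str | Path,
                          dialect: str = "json") -> NormalModeSet:
    """Read a frequency-calculation record into a :class:`NormalModeSet`.

    Two dialects are accepted.  ``json`` (canonical): an object with keys
    ``symbols``, ``coords_angstrom``, ``frequencies_cm1``, ``modes`` and
    optionally ``masses_amu``.  ``molden``: a Molden-style file with
    ``[FREQ]``, ``[FR-COORD]`` (bohr) and ``[FR-NORM-COORD]`` sections whose
    mode vectors are expected to be mass-weighted.

    Modes are renormalized to unit norm (factors recorded in provenance);
    entries with \\|ν\\| < 1 cm⁻¹ (translations/rotations) are dropped with a
    logged count; any remaining negative frequency is an error.
    """
    if dialect == "json":
        symbols, masses, coords, freqs, modes = _read_freq_json(path)
    elif dialect == "molden":
        symbols, masses, coords, freqs, modes = _read_freq_molden(path)
    else:
        raise ValueError(f"unknown frequency-record dialect {dialect!r}")

    if masses is None:
        geometry = MolecularGeometry.from_symbols(symbols, coords)
    else:
        geometry = MolecularGeometry(tuple(symbols), masses, coords)

    freqs = np.asarray(freqs, dtype=float)
    modes = np.asarray(modes, dtype=float)
    if modes.ndim != 2 or modes.shape[0] != freqs.shape[0]:
        raise ParseError(
            f"{path}: {freqs.shape[0]} frequencies but "
            f"{modes.shape[0] if modes.ndim == 2 else 0} mode vectors"
        )

    keep = np.abs(freqs) >= NEAR_ZERO_FREQ_CM1
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("%s: dropped %d near-zero-frequency entries (|ν| < %g cm⁻¹, "
                    "translations/rotations)", path, n_dropped, NEAR_ZERO_FREQ_CM1)
    freqs, modes = freqs[keep], modes[keep]
    if np.any(freqs < 0):
        raise ParseError(
            f"{path}: imaginary frequency present ({freqs[freqs < 0]} cm⁻¹): the "
            "record describes a saddle point, not an equilibrium geometry"
        )

    norms = np.linalg.norm(modes, axis=1)
    if np.any(norms == 0):
        raise ParseError(f"{path}: zero-length mode vector")
    modes = modes / norms[:, None]
    gram_off = modes @ modes.T - np.eye(len(freqs))
    if np.any(np.abs(gram_off) > NormalModeSet._ORTHO_TOL):
        raise ParseError(
            f"{path}: mode vectors are not mutually orthogonal after "
            "normalization; supply mass-weighted normal modes"
        )
    provenance = {
        "source": str(path),
        "dialect": dialect,
        "normalization_factors": norms.tolist(),
        "n_dropped_near_zero": n_dropped,
    }
    return NormalModeSet(geometry, freqs, modes, provenance)


def _read_freq_json(path):
    with open(path) as fh:
        rec = json.load(fh)
    try:
        symbols = rec["symbols"]
        coords = np.asarray(rec["coords_angstrom"], dtype=float)
        freqs = rec["frequencies_cm1"]
        modes = np.asarray(rec["modes"], dtype=float)
    except KeyError as exc:
        raise ParseError(f"{path}: frequency record missing key {exc}") from None
    masses = np.asarray(rec["masses_amu"], dtype=float) if "masses_amu" in rec else None
    return symbols, masses, coords, freqs, modes


def _read_freq_molden(path):
    """Parse the [FREQ]/[FR-COORD]/[FR-NORM-COORD] sections of a Molden-style file."""
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith("["):
            current = stripped.strip("[]").upper()
            sections[current] = []
        elif current is not None and stripped:
            sections[current].append(stripped)

    for needed in ("FREQ", "FR-COORD", "FR-NORM-COORD"):
        if needed not in sections:
            raise ParseError(f"{path}: missing Molden section [{needed}]")

    freqs = [float(ln.split()[0]) for ln in sections["FREQ"]]
    symbols, coords = [], []
    for ln in sections["FR-COORD"]:
        parts = ln.split()
        symbols.append(parts[0].capitalize())
        coords.append([float(p) * BOHR_ANGSTROM for p in parts[1:4]])

    # vibration blocks: "vibration N" header followed by one line per atom
    modes, cur = [], None
    for ln in sections["FR-NORM-COORD"]:
        if ln.lower().startswith("vibration"):
            if cur is not None:
                modes.append(cur)
            cur = []
        else:
            cur.extend(float(p) for p in ln.split())
    if cur is not None:
        modes.append(cur)
    return symbols, None, np.asarray(coords), freqs, np.asarray(modes, dtype=float)


def write_frequency_record(modes: NormalModeSet, path: str | Path) -> None:
    """Write a NormalModeSet in the canonical JSON dialect."""
    rec = {
        "symbols": list(modes.equilibrium.symbols),
        "masses_amu": modes.equilibrium.masses.tolist(),
        "coords_angstrom": modes.equilibrium.coords.tolist(),
        "frequencies_cm1": modes.frequencies.tolist(),
        "modes": modes.modes.tolist(),
    }
    Path(path).write_text(json.dumps(rec, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Excitation tables
# ---------------------------------------------------------------------------

_EXC_COLUMNS = ("geometry_id", "state", "energy_eV")


def read_excitation_table(path: str | Path) -> ExcitationTable:
    """Read a CSV/JSON excitation table.

    Expected columns: ``geometry_id``, ``state``, ``energy_eV`` and then
    either ``mu_x,mu_y,mu_z`` or ``fosc`` (or both).  Rows are grouped by
    geometry_id (first-appearance order) and rectangularity is enforced.
    """
    import pandas as pd

    path = Path(path)
    if path.suffix.lower() == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in _EXC_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    has_tdm = {"mu_x", "mu_y", "mu_z"}.issubset(df.columns)
    has_fosc = "fosc" in df.columns
    if not has_tdm and not has_fosc:
        raise ParseError(f"{path}: need either mu_x,mu_y,mu_z or fosc columns")

    records, gids = [], []
    for gid, group in df.groupby("geometry_id", sort=False):
        excs = []
        for row in group.itertuples(index=False):
            tdm = ((row.mu_x, row.mu_y, row.mu_z) if has_tdm
                   and not any(math.isnan(v) for v in (row.mu_x, row.mu_y, row.mu_z))
                   else None)
            fosc = None
            if has_fosc and not math.isnan(row.fosc):
                fosc = float(row.fosc)
            try:
                excs.append(VerticalExcitation(int(row.state), float(row.energy_eV),
                                               tdm=tdm, fosc=fosc))
            except ValueError as exc:
                raise ParseError(f"{path}: geometry {gid!r}: {exc}") from None
        records.append(tuple(excs))
        gids.append(gid)
    try:
        return ExcitationTable(tuple(records), tuple(gids))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_excitation_table(table: ExcitationTable, path: str | Path) -> None:
    """Write an excitation table as CSV (geometry_id,state,energy_eV,mu_*,fosc)."""
    rows = ["geometry_id,state,energy_eV,mu_x,mu_y,mu_z,fosc"]
    for gid, rec in zip(table.geometry_ids, table.records):
        for exc in rec:
            mu = exc.tdm if exc.tdm is not None else ("", "", "")
            mu_s = ",".join("" if m == "" else f"{m:.12e}" for m in mu)
            fosc_s = "" if exc.fosc is None else f"{exc.fosc:.12e}"
            rows.append(f"{gid},{exc.state},{exc.energy:.12e},{mu_s},{fosc_s}")
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Cross-section CSV
# ---------------------------------------------------------------------------

def write_cross_section_csv(cs: CrossSection, path: str | Path,
                            unit: str = "eV") -> None:
    """Write a two-column spectrum CSV (axis, sigma_cm2), increasing axis.

    ``unit`` selects the abscissa: photon energy in eV, or wavelength in nm
    via λ = 1239.841984/E.  The header comment embeds the broadening width,
    lineshape, ensemble size and seed for provenance.
    """
    if unit not in ("eV", "nm"):
        raise ValueError(f"unit must be 'eV' or 'nm', got {unit!r}")
    axis = cs.grid if unit == "eV" else ev_to_nm(cs.grid)
    values = cs.values
    order = np.argsort(axis)
    axis, values = axis[order], values[order]
    meta = cs.meta or {}
    header = (
        f"# photoabsorption cross-section; delta={cs.delta:g} eV; "
        f"lineshape={cs.lineshape}; n_geometries={meta.get('n_geometries', 'NA')}; "
        f"seed={meta.get('seed', 'NA')}\n"
        f"{'energy_eV' if unit == 'eV' else 'wavelength_nm'},sigma_cm2\n"
    )
    body = "\n".join(f"{a:.12e},{v:.12e}" for a, v in zip(axis, values))
    Path(path).write_text(header + body + "\n")


def read_cross_section_csv(path: str | Path) -> CrossSection:
    """Re-read a spectrum CSV written by :func:`write_cross_section_csv`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    delta, lineshape = 0.05, "gaussian"
    for ln in lines:
        if ln.startswith("#") and "delta=" in ln:
            for part in ln.lstrip("# ").split(";"):
                part = part.strip()
                if part.startswith("delta="):
                    delta = float(part.split("=")[1].split()[0])
                elif part.startswith("lineshape="):
                    lineshape = part.split("=")[1]
    data = [ln for ln in lines if ln and not ln.startswith("#")]
    unit = "nm" if data[0].startswith("wavelength") else "eV"
    arr = np.array([[float(x) for x in ln.split(",")] for ln in data[1:]])
    axis, values = arr[:, 0], arr[:, 1]
    if unit == "nm":
        axis = nm_to_ev(axis)
        order = np.argsort(axis)
        axis, values = axis[order], values[order]
    return CrossSection(axis, values, delta, lineshape, {"source": str(path)})


# ---------------------------------------------------------------------------
# Flux CSV
# ---------------------------------------------------------------------------

def read_flux_csv(path: str | Path, label: str | None = None) -> ActinicFlux:
    """Read a two-column flux CSV (wavelength_nm, flux_photons_cm2_s_nm)."""
    path = Path(path)
    wl, fx = [], []
    for i, ln in enumerate(path.read_text().splitlines()):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.replace(",", " ").split()
        try:
            wl.append(float(parts[0]))
            fx.append(float(parts[1]))
        except (ValueError, IndexError):
            if i == 0 or ln.lower().startswith("wavelength"):
                continue  # header row
            raise ParseError(f"{path}:{i + 1}: malformed flux row {ln!r}")
    return ActinicFlux(np.array(wl), np.array(fx), label or path.stem)


def write_flux_csv(flux: ActinicFlux, path: str | Path,
                   header_comment: str = "") -> None:
    lines = []
    if header_comment:
        lines.extend("# " + ln for ln in header_comment.splitlines())
    lines.append(f"# label: {flux.label}")
    lines.append("wavelength_nm,flux_photons_cm2_s_nm")
    lines.extend(f"{w:.6f},{f:.12e}" for w, f in zip(flux.wavelengths, flux.flux))
    Path(path).write_text("\n".join(lines) + "\n")
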