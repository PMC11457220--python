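"""Excitation and conformer providers.

Two pluggable contracts live here:

* **Excitation backends** map a molecular geometry to a list of vertical
  excitations.  External electronic-structure engines (TDDFT, ADC(2), …)
  plug in behind this contract; the package itself ships only an
  analytic **mock model** — a harmonic ground state whose single
  excitation gap varies linearly along one mass-weighted normal
  coordinate, ΔE(Q) = ΔE₀ + κQ, with a constant transition dipole.
  Under Wigner sampling Q is Gaussian with std-dev σ_Q, so the exact
  NEA band in the N_p → ∞, δ → 0 limit is a Gaussian centred at ΔE₀
  with std-dev |κ|·σ_Q (the reflection-principle closed form).  This
  makes every stage of the pipeline testable offline against a known
  answer.

* **Conformer providers** map a SMILES string to candidate conformers
  with relative energies.  The reference provider delegates to RDKit
  (ETKDG distance-geometry embedding followed by MMFF94 force-field
  optimization); a fixtures provider returns canned conformer sets for
  tests.  Conformer generation is deliberately not re-implemented here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Protocol, Sequence

import numpy as np

from .core_io import MolecularGeometry, NormalModeSet, VerticalExcitation
from .wigner import mass_weighted_projection

logger = logging.getLogger("neaspec")

#: Smallest excitation energy the mock model will report (eV); the linear
#: gap model can go nonpositive for extreme displacements and is floored
#: here (with a warning) rather than erroring, so stress tests stay runnable.
MOCK_ENERGY_FLOOR_EV = 0.01


@dataclass(frozen=True)
class MockModelSpec:
    """Parameters of the analytic one-mode, one-state mock molecule.

    omega: ground-state harmonic frequency (cm⁻¹); deltaE0: vertical gap at
    equilibrium (eV); kappa: gap gradient along the mass-weighted coordinate
    (eV per mass-weighted a.u.); mu0: transition dipole magnitude (a.u.);
    fosc_mode: ``constant_f`` reports fosc = (2/3)·ΔE₀[Ha]·mu0² for every
    geometry (a Condon-like constant-intensity band), ``from_tdm`` reports
    the dipole so the oscillator strength varies with the sampled gap.
    """

    omega: float = 1500.0
    deltaE0: float = 4.5
    kappa: float = 0.1
    mu0: float = 1.0
    fosc_mode: str = "constant_f"
    n_states: int = 1

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("mock mode frequency must be > 0 cm⁻¹")
        if self.deltaE0 <= 0:
            raise ValueError("mock equilibrium gap must be > 0 eV")
        if self.fosc_mode not in ("constant_f", "from_tdm"):
            raise ValueError("fosc_mode must be constant_f|from_tdm")
        if self.n_states != 1:
            raise ValueError("the mock model defines a single excited state")


def mock_excitations(spec: MockModelSpec, Q: float) -> list[VerticalExcitation]:
    """Vertical excitations of the mock model at mass-weighted coordinate Q.

    The single transition has energy ΔE₀ + κQ (floored at 0.01 eV with a
    warning if the linear form goes nonpositive) and intensity per
    ``spec.fosc_mode``.
    """
    energy = spec.deltaE0 + spec.kappa * float(Q)
    if energy < MOCK_ENERGY_FLOOR_EV:
        logger.warning("mock gap %.3f eV at Q=%.3f is nonphysical; floored at %g eV",
                       energy, Q, MOCK_ENERGY_FLOOR_EV)
        energy = MOCK_ENERGY_FLOOR_EV
    if spec.fosc_mode == "constant_f":
        from .nea import oscillator_strength
        f0 = oscillator_strength(spec.deltaE0, (spec.mu0, 0.0, 0.0))
        return [VerticalExcitation(1, energy, fosc=f0)]
    return [VerticalExcitation(1, energy, tdm=(spec.mu0, 0.0, 0.0))]


def mock_normal_modes(spec: MockModelSpec) -> NormalModeSet:
    """A minimal one-mode molecule realizing the mock model.

    Two unit-mass pseudo-atoms 1 Å apart on the z axis with a single
    stretching mode of frequency ``spec.omega``; the mass-weighted mode
    vector is the antisymmetric z displacement.  Element symbols are H
    (masses overridden to exactly 1 amu for clean arithmetic).
    """
    geom = MolecularGeometry(("H", "H"), np.array([1.0, 1.0]),
                             np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]))
    mode = np.array([[0.0, 0.0, 1.0 / np.sqrt(2.0),
                      0.0, 0.0, -1.0 / np.sqrt(2.0)]])
    return NormalModeSet(geom, np.array([spec.omega]), mode,
                         {"source": "mock model"})


class ExcitationBackend(Protocol):
    """Contract for excitation providers: deterministic geometry → excitations."""

    n_states: int
    provides: str  # "tdm", "fosc" or "both"

    def excitations(self, geometry: MolecularGeometry) -> list[VerticalExcitation]:
        ...


@dataclass(frozen=True)
class MockBackend:
    """ExcitationBackend adapter for the mock model.

    Projects each geometry onto the mock mode to obtain Q, then evaluates
    the linear gap model.  Same geometry in ⇒ same excitations out.
    """

    spec: MockModelSpec
    modes: NormalModeSet = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.modes is None:
            object.__setattr__(self, "modes", mock_normal_modes(self.spec))

    @property
    def n_states(self) -> int:
        return 1

    @property
    def provides(self) -> str:
        return "fosc" if self.spec.fosc_mode == "constant_f" else "tdm"

    def excitations(self, geometry: MolecularGeometry) -> list[VerticalExcitation]:
        Q = mass_weighted_projection(geometry, self.modes, mode_index=0)
        return mock_excitations(self.spec, Q)


# ---------------------------------------------------------------------------
# Conformer providers
# ---------------------------------------------------------------------------

ConformerProvider = Callable[[str], Sequence[tuple[MolecularGeometry, float]]]

_PROVIDERS: dict[str, ConformerProvider] = {}


def register_provider(name: str, provider: ConformerProvider) -> None:
    _PROVIDERS[name] = provider


def get_provider(name: str) -> ConformerProvider:
    try:
        return _PROVIDERS[name]
    except KeyError:
        raise ValueError(
            f"no conformer provider registered under {name!r}; "
            f"available: {sorted(_PROVIDERS)}"
        ) from None


def _validate_smiles(smiles: str) -> None:
    """Light syntactic screen used when RDKit is unavailable."""
    allowed = set("ABCDEFGHIKLMNOPRSTUVWXYZabcdefghiklmnoprstuy0123456789"
                  "()[]=#+-@/\\.%")
    if not smiles or any(ch not in allowed for ch in smiles) or " " in smiles:
        raise ValueError(f"unparsable SMILES {smiles!r}")


def enumerate_conformers(smiles: str, backend: str = "rdkit",
                         rmsd_threshold: float = 0.1,
                         ) -> list[tuple[MolecularGeometry, float]]:
    """Candidate conformers for a SMILES, with energies relative to the minimum.

    Delegates generation to the registered provider named ``backend``, then
    normalizes: energies shifted so the minimum is 0, and near-duplicate
    conformers pruned by heavy-atom RMSD < ``rmsd_threshold`` Å after optimal
    alignment.
    """
    if backend != "fixtures":  # fixtures keys may be molecule names, not SMILES
        try:
            from rdkit import Chem
            if Chem.MolFromSmiles(smiles) is None:
                raise ValueError(f"unparsable SMILES {smiles!r}")
        except ImportError:
            _validate_smiles(smiles)

    provider = get_provider(backend)
    try:
        raw = list(provider(smiles))
    except ValueError:
        raise
    except Exception as exc:
        raise RuntimeError(f"conformer provider {backend!r} failed: {exc}") from exc
    if not raw:
        raise RuntimeError(f"conformer provider {backend!r} returned no conformers")

    raw.sort(key=lambda pair: pair[1])
    e0 = raw[0][1]
    kept: list[tuple[MolecularGeometry, float]] = []
    for geom, energy in raw:
        if any(_heavy_atom_rmsd(geom, prev) < rmsd_threshold for prev, _ in kept):
            continue
        kept.append((geom, energy - e0))
    return kept


def _heavy_atom_rmsd(a: MolecularGeometry, b: MolecularGeometry) -> float:
    """Heavy-atom RMSD after optimal rigid alignment (Kabsch)."""
    sel_a = [i for i, s in enumerate(a.symbols) if s != "H"]
    sel_b = [i for i, s in enumerate(b.symbols) if s != "H"]
    if len(sel_a) != len(sel_b) or [a.symbols[i] for i in sel_a] != [b.symbols[i] for i in sel_b]:
        return np.inf
    P = a.coords[sel_a] - a.coords[sel_a].mean(axis=0)
    Q = b.coords[sel_b] - b.coords[sel_b].mean(axis=0)
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    diff = P @ R.T - Q
    return float(np.sqrt((diff ** 2).sum() / len(sel_a)))


def rdkit_conformers(smiles: str, n_candidates: int = 50,
                     seed: int = 2024) -> list[tuple[MolecularGeometry, float]]:
    """Reference provider: ETKDG embedding + MMFF94 optimization via RDKit.

    Returns (geometry, MMFF94 energy in kJ/mol) per embedded conformer; the
    force-field energies serve as an initial estimate of relative stability
    and can be refined by the user in a conformer manifest.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_candidates, params=params)
    if not ids:
        raise RuntimeError(f"ETKDG embedding produced no conformers for {smiles!r}")
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    symbols = [atom.GetSymbol() for atom in mol.GetAtoms()]
    out = []
    KCAL_TO_KJ = 4.184
    for cid, (converged, energy) in zip(ids, results):
        if converged != 0:
            continue
        coords = mol.GetConformer(cid).GetPositions()
        out.append((MolecularGeometry.from_symbols(symbols, np.asarray(coords)),
                    energy * KCAL_TO_KJ))
    if not out:
        raise RuntimeError(f"MMFF94 optimization failed for all conformers of {smiles!r}")
    return out


def fixtures_conformers(key: str) -> list[tuple[MolecularGeometry, float]]:
    """Fixtures provider: canned conformer sets from packaged JSON.

    Keys are molecule names or their SMILES.  The packaged geometries are
    synthetic stand-ins constructed for testing (see
    ``data/synthetic_conformers.json``), not quantum-chemistry results.
    """
    ref = resources.files("neaspec").joinpath("data/synthetic_conformers.json")
    data = json.loads(ref.read_text())
    entry = None
    for name, rec in data.items():
        if key == name or key == rec.get("smiles"):
            entry = rec
            break
    if entry is None:
        raise ValueError(f"no canned conformer set for {key!r}; known: {sorted(data)}")
    out = []
    for conf in entry["conformers"]:
        geom = MolecularGeometry.from_symbols(conf["symbols"], np.array(conf["coords"]))
        out.append((geom, float(conf["energy_kj_mol"])))
    return out


register_provider("rdkit", rdkit_conformers)
register_provider("fixtures", fixtures_conformers)
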