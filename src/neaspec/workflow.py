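"""Config-driven orchestration of the full NEA pipeline.

Runs the four stages — conformers → Wigner sampling → vertical
excitations → spectrum — followed by the photolysis-rate integration,
writing each stage's artifact as a plain file in a run directory:

    run_dir/
      ensemble_<conformer>.xyz       sampled geometries (multi-frame XYZ)
      excitations_<conformer>.csv    vertical-excitation tables
      spectrum_<conformer>.csv       per-conformer cross-sections
      spectrum_combined.csv          Boltzmann-weighted total
      photolysis.json                J and its inputs
      run.json                       provenance (config echo, seeds, version)

Every random stage derives its stream from the single configured seed
(per-conformer child seeds via ``numpy.random.SeedSequence``), so a rerun
with the same config reproduces all numeric artifacts byte-for-byte.
``n_samples = 0`` short-circuits sampling: excitations are evaluated at
the equilibrium geometry only ("single-point mode"), giving the pure
lineshape at the equilibrium gap.  In resume mode existing stage
artifacts are loaded instead of recomputed, so e.g. a deleted combined
spectrum is rebuilt from the stored per-conformer spectra without
re-sampling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .backends import MockBackend, MockModelSpec, enumerate_conformers, mock_normal_modes
from .core_io import (
    CrossSection,
    ExcitationTable,
    NormalModeSet,
    read_cross_section_csv,
    read_excitation_table,
    read_frequency_record,
    read_flux_csv,
    read_xyz,
    write_cross_section_csv,
    write_excitation_table,
)
from .nea import (
    ConformerSet,
    LineshapeSpec,
    boltzmann_weights,
    combine_conformer_spectra,
    compute_cross_section,
)
from .photolysis import (
    ACTINIC_WINDOW_NM,
    PhotolysisResult,
    photolysis_rate,
    standard_actinic_flux,
    write_photolysis_json,
)
from .wigner import build_wigner_distribution, sample_wigner

logger = logging.getLogger("neaspec")


@dataclass
class WorkflowConfig:
    """Declarative description of one NEA run.

    Exactly one of ``smiles`` / ``xyz`` identifies the molecule; a conformer
    ``manifest`` (list of {label, energy_kj_mol, excitation_table|
    frequency_record}) overrides conformer generation.  ``n_samples = 0``
    selects single-point mode.  ``temperature`` is used for conformer
    Boltzmann weighting; ``sampling_temperature`` (default 0 K: zero-point
    Wigner) for the nuclear sampling itself.
    """

    smiles: str | None = None
    xyz: str | None = None
    manifest: list[dict] | None = None
    frequency_record: str | None = None
    n_samples: int = 500
    temperature: float = 298.15
    sampling_temperature: float = 0.0
    freq_cutoff: float = 0.0
    lineshape: str = "gaussian"
    delta: float = 0.05
    backend: str = "mock"
    backend_params: dict = field(default_factory=dict)
    conformer_provider: str = "rdkit"
    flux: str = "high"
    phi: float = 1.0
    window: tuple[float, float] = ACTINIC_WINDOW_NM
    seed: int = 42
    output_dir: str = "nea_run"

    def __post_init__(self) -> None:
        if (self.smiles is None) == (self.xyz is None) and self.manifest is None:
            raise ValueError("exactly one of smiles/xyz must be set (or a manifest given)")
        if self.n_samples < 0:
            raise ValueError("n_samples must be ≥ 0 (0 = single-point mode)")
        self.window = (float(self.window[0]), float(self.window[1]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass(frozen=True)
class WorkflowResult:
    """All artifacts of one run, with the run directory they were written to."""

    conformer_spectra: tuple[tuple[str, float, CrossSection], ...]
    weights: np.ndarray
    combined: CrossSection
    photolysis: PhotolysisResult
    provenance: dict
    output_dir: Path


@dataclass(frozen=True)
class _Conformer:
    label: str
    energy_kj_mol: float
    modes: NormalModeSet | None
    excitation_table_path: str | None = None


def _resolve_conformers(config: WorkflowConfig) -> list[_Conformer]:
    """Stage 1: determine the conformers and their normal-mode sets."""
    mock_spec = MockModelSpec(**config.backend_params) if config.backend == "mock" else None

    def modes_for(freq_record: str | None) -> NormalModeSet | None:
        if freq_record:
            dialect = "molden" if str(freq_record).endswith((".molden", ".freq")) else "json"
            return read_frequency_record(freq_record, dialect)
        if mock_spec is not None:
            return mock_normal_modes(mock_spec)
        return None

    if config.manifest is not None:
        out = []
        for entry in config.manifest:
            out.append(_Conformer(
                label=str(entry["label"]),
                energy_kj_mol=float(entry.get("energy_kj_mol", 0.0)),
                modes=modes_for(entry.get("frequency_record")),
                excitation_table_path=entry.get("excitation_table"),
            ))
        return out

    if config.xyz is not None:
        read_xyz(config.xyz)  # validate the file; mock modes carry their own geometry
        return [_Conformer("conf0", 0.0, modes_for(config.frequency_record))]

    confs = enumerate_conformers(config.smiles, backend=config.conformer_provider)
    return [
        _Conformer(f"conf{i}", energy, modes_for(config.frequency_record))
        for i, (_, energy) in enumerate(confs)
    ]


def _conformer_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-conformer child seeds below 2³¹."""
    return [int(s) for s in
            (np.random.SeedSequence(seed).generate_state(n) % (2 ** 31))]


def _make_backend(config: WorkflowConfig, modes: NormalModeSet | None):
    if config.backend == "mock":
        spec = MockModelSpec(**config.backend_params)
        return MockBackend(spec, modes) if modes is not None else MockBackend(spec)
    raise ValueError(
        f"unknown excitation backend {config.backend!r} (external engines must "
        "supply excitation tables via the conformer manifest)"
    )


def run_nea_workflow(config: WorkflowConfig, resume: bool = False) -> WorkflowResult:
    """Execute the full workflow, writing stage artifacts to the run directory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = LineshapeSpec(config.lineshape, config.delta)

    conformers = _resolve_conformers(config)
    seeds = _conformer_seeds(config.seed, len(conformers))
    logger.info("stage conformers: %d conformer(s): %s",
                len(conformers), [c.label for c in conformers])

    # stages 2+3 per conformer: sampling and excitations
    tables: list[tuple[_Conformer, ExcitationTable]] = []
    for conf, child_seed in zip(conformers, seeds):
        exc_path = out_dir / f"excitations_{conf.label}.csv"
        if conf.excitation_table_path:
            table = read_excitation_table(conf.excitation_table_path)
            logger.info("stage excitations [%s]: loaded table from %s",
                        conf.label, conf.excitation_table_path)
        elif resume and exc_path.exists():
            table = read_excitation_table(exc_path)
            logger.info("stage excitations [%s]: resumed from %s", conf.label, exc_path)
        else:
            if conf.modes is None:
                raise FileNotFoundError(
                    f"stage sampling [{conf.label}]: no frequency record available "
                    "(expected a 'frequency_record' path in the config or manifest)"
                )
            backend = _make_backend(config, conf.modes)
            if config.n_samples == 0:
                logger.info("stage sampling [%s]: n_samples=0, single-point mode",
                            conf.label)
                geometries = [conf.modes.equilibrium]
            else:
                dist = build_wigner_distribution(
                    conf.modes, config.sampling_temperature, config.freq_cutoff)
                ensemble = sample_wigner(dist, config.n_samples, child_seed)
                ensemble.write_xyz(out_dir / f"ensemble_{conf.label}.xyz")
                geometries = list(ensemble.geometries)
                logger.info("stage sampling [%s]: %d Wigner samples (seed %d)",
                            conf.label, config.n_samples, child_seed)
            records = [tuple(backend.excitations(g)) for g in geometries]
            table = ExcitationTable(tuple(records))
            write_excitation_table(table, exc_path)
            logger.info("stage excitations [%s]: %d geometries × %d states",
                        conf.label, table.n_geometries, table.n_states)
        tables.append((conf, table))

    # stage 4: spectra on a common grid
    all_e = [exc.energy for _, t in tables for rec in t.records for exc in rec]
    lo = max(min(all_e) - 6 * shape.delta, 1e-6)
    hi = max(all_e) + 6 * shape.delta
    grid = np.linspace(lo, hi, 4096)

    spectra: list[tuple[str, float, CrossSection]] = []
    for (conf, table), child_seed in zip(tables, seeds):
        spec_path = out_dir / f"spectrum_{conf.label}.csv"
        if resume and spec_path.exists():
            cs = read_cross_section_csv(spec_path)
            logger.info("stage spectrum [%s]: resumed from %s", conf.label, spec_path)
        else:
            cs = compute_cross_section(table, grid, shape,
                                       meta={"seed": child_seed, "label": conf.label})
            write_cross_section_csv(cs, spec_path, unit="eV")
            logger.info("stage spectrum [%s]: σ_max = %.3e cm²", conf.label,
                        float(cs.values.max()))
        spectra.append((conf.label, conf.energy_kj_mol, cs))

    weights = boltzmann_weights([s[1] for s in spectra], config.temperature)
    combined_path = out_dir / "spectrum_combined.csv"
    if resume and combined_path.exists():
        combined = read_cross_section_csv(combined_path)
        logger.info("stage combine: resumed from %s", combined_path)
    else:
        conf_set = ConformerSet(tuple(spectra), config.temperature)
        combined = combine_conformer_spectra(conf_set)
        write_cross_section_csv(combined, combined_path, unit="eV")
        logger.info("stage combine: weights %s", np.array2string(weights, precision=4))

    # stage 5: photolysis rate
    if config.flux.startswith("file:"):
        flux = read_flux_csv(config.flux[5:])
    else:
        flux = standard_actinic_flux(config.flux)
    result_j = photolysis_rate(combined, config.phi, flux, config.window)
    write_photolysis_json(result_j, out_dir / "photolysis.json")
    logger.info("stage photolysis: J = %.4e s⁻¹ (%s)", result_j.J, flux.label)

    provenance = {
        "config": _config_echo(config),
        "conformer_seeds": seeds,
        "conformer_weights": [float(w) for w in weights],
        "conformer_populations_percent": [round(100 * float(w), 4) for w in weights],
        "version": __version__,
    }
    (out_dir / "run.json").write_text(json.dumps(provenance, indent=1, sort_keys=True) + "\n")

    return WorkflowResult(tuple(spectra), weights, combined, result_j,
                          provenance, out_dir)


def _config_echo(config: WorkflowConfig) -> dict:
    echo = asdict(config)
    echo["window"] = list(echo["window"])
    return echo
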