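"""End-to-end workflow orchestration, determinism, resume, CLI."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from neaspec import (
    WorkflowConfig,
    read_cross_section_csv,
    run_nea_workflow,
    write_frequency_record,
)
from neaspec.backends import MockModelSpec, mock_normal_modes
from neaspec.cli import main as cli_main
from neaspec.core_io import SIGMA_PREFACTOR_CM2_EV
from neaspec.nea import LineshapeSpec


def mock_config(tmp_path, **overrides):
    base = dict(
        xyz=str(tmp_path / "mol.xyz"),
        n_samples=200,
        backend="mock",
        backend_params={"omega": 1000.0, "deltaE0": 4.5, "kappa": 0.05},
        delta=0.05,
        flux="high",
        phi=1.0,
        seed=7,
        output_dir=str(tmp_path / "run"),
    )
    base.update(overrides)
    # the mock backend supplies its own modes; the xyz just names the molecule
    from neaspec import write_xyz
    write_xyz(mock_normal_modes(MockModelSpec()).equilibrium, tmp_path / "mol.xyz")
    return WorkflowConfig(**base)


class TestWorkflow:
    def test_stage_artifacts_written(self, tmp_path):
        config = mock_config(tmp_path)
        result = run_nea_workflow(config)
        out = result.output_dir
        for name in ("ensemble_conf0.xyz", "excitations_conf0.csv",
                     "spectrum_conf0.csv", "spectrum_combined.csv",
                     "photolysis.json", "run.json"):
            assert (out / name).exists(), name
        assert result.photolysis.J >= 0

    def test_rerun_byte_identical(self, tmp_path):
        config_a = mock_config(tmp_path, output_dir=str(tmp_path / "a"))
        config_b = mock_config(tmp_path, output_dir=str(tmp_path / "b"))
        ra = run_nea_workflow(config_a)
        rb = run_nea_workflow(config_b)
        for name in ("ensemble_conf0.xyz", "spectrum_conf0.csv",
                     "spectrum_combined.csv", "photolysis.json"):
            assert (ra.output_dir / name).read_bytes() == \
                (rb.output_dir / name).read_bytes(), name

    def test_single_point_mode_is_pure_lineshape(self, tmp_path):
        """n_samples = 0 evaluates the equilibrium geometry only, so the
        spectrum is C·f·g_δ(E − ΔE₀)."""
        config = mock_config(tmp_path, n_samples=0)
        result = run_nea_workflow(config)
        cs = result.combined
        f0 = result.conformer_spectra[0][2].meta["sum_fosc_mean"]
        shape = LineshapeSpec("gaussian", 0.05)
        expected = SIGMA_PREFACTOR_CM2_EV * f0 * shape.evaluate(cs.grid - 4.5)
        np.testing.assert_allclose(cs.values, expected, rtol=1e-10)
        assert not (result.output_dir / "ensemble_conf0.xyz").exists()

    def test_two_conformer_manifest_populations(self, tmp_path):
        # energy gap chosen so populations are 99.4% / 0.6% at 298.15 K
        gap = 8.31446e-3 * 298.15 * np.log(0.994 / 0.006)
        manifest = [
            {"label": "major", "energy_kj_mol": 0.0},
            {"label": "minor", "energy_kj_mol": float(gap)},
        ]
        config = mock_config(tmp_path, manifest=manifest, xyz=None,
                             n_samples=50, temperature=298.15)
        result = run_nea_workflow(config)
        np.testing.assert_allclose(result.weights, [0.994, 0.006], atol=1e-12)
        assert result.provenance["conformer_populations_percent"] == [99.4, 0.6]
        # combined spectrum == weighted pointwise sum of stored spectra
        w = result.weights
        stacked = np.stack([cs.values for _, _, cs in result.conformer_spectra])
        np.testing.assert_allclose(result.combined.values, w @ stacked,
                                   rtol=1e-12, atol=1e-300)

    def test_combined_csv_matches_per_conformer_csvs(self, tmp_path):
        manifest = [{"label": "a", "energy_kj_mol": 0.0},
                    {"label": "b", "energy_kj_mol": 4.0}]
        config = mock_config(tmp_path, manifest=manifest, xyz=None, n_samples=30)
        result = run_nea_workflow(config)
        a = read_cross_section_csv(result.output_dir / "spectrum_a.csv")
        b = read_cross_section_csv(result.output_dir / "spectrum_b.csv")
        combined = read_cross_section_csv(result.output_dir / "spectrum_combined.csv")
        w = result.weights
        np.testing.assert_allclose(combined.values,
                                   w[0] * a.values + w[1] * b.values,
                                   rtol=1e-11)

    def test_resume_regenerates_combined_without_resampling(self, tmp_path):
        config = mock_config(tmp_path)
        first = run_nea_workflow(config)
        combined_path = first.output_dir / "spectrum_combined.csv"
        original = combined_path.read_bytes()
        combined_path.unlink()
        # also remove the ensemble: resume must not need to re-sample
        (first.output_dir / "ensemble_conf0.xyz").unlink()
        second = run_nea_workflow(config, resume=True)
        assert combined_path.read_bytes() == original
        assert not (first.output_dir / "ensemble_conf0.xyz").exists()
        np.testing.assert_allclose(second.combined.values, first.combined.values,
                                   rtol=1e-12)

    def test_missing_frequency_record_names_stage(self, tmp_path):
        config = mock_config(tmp_path, backend_params={}, n_samples=10)
        config.backend = "none"
        with pytest.raises((FileNotFoundError, ValueError)):
            run_nea_workflow(config)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="smiles/xyz"):
            WorkflowConfig(smiles="O=CCO", xyz="mol.xyz")
        with pytest.raises(ValueError, match="n_samples"):
            WorkflowConfig(smiles="O=CCO", n_samples=-1)

    def test_manifest_with_excitation_table(self, tmp_path):
        from conftest import make_table
        from neaspec import write_excitation_table
        table = make_table([[4.2]], [[0.05]])
        path = tmp_path / "table.csv"
        write_excitation_table(table, path)
        manifest = [{"label": "ext", "energy_kj_mol": 0.0,
                     "excitation_table": str(path)}]
        config = mock_config(tmp_path, manifest=manifest, xyz=None)
        result = run_nea_workflow(config)
        peak = result.combined.grid[np.argmax(result.combined.values)]
        assert peak == pytest.approx(4.2, abs=0.01)


class TestCLI:
    def test_run_and_j_commands(self, tmp_path):
        nm = mock_normal_modes(MockModelSpec())
        from neaspec import write_xyz
        write_xyz(nm.equilibrium, tmp_path / "mol.xyz")
        config = {
            "xyz": str(tmp_path / "mol.xyz"),
            "n_samples": 50,
            "backend": "mock",
            "backend_params": {"omega": 1000.0, "deltaE0": 4.5, "kappa": 0.05},
            "seed": 3,
            "output_dir": str(tmp_path / "run"),
        }
        cfg_path = tmp_path / "config.yaml"
        cfg_path.write_text(yaml.safe_dump(config))
        runner = CliRunner()
        res = runner.invoke(cli_main, ["run", str(cfg_path)])
        assert res.exit_code == 0, res.output
        assert "J =" in res.output

        res = runner.invoke(cli_main, [
            "j", "--spectrum", str(tmp_path / "run" / "spectrum_combined.csv"),
            "--flux", "medium", "--phi", "0.5",
            "-o", str(tmp_path / "j.json")])
        assert res.exit_code == 0, res.output
        rec = json.loads((tmp_path / "j.json").read_text())
        assert rec["J_s1"] >= 0
        assert rec["phi"] == 0.5

    def test_sample_and_spectrum_commands(self, tmp_path, water_modes):
        freq_path = tmp_path / "freq.json"
        write_frequency_record(water_modes, freq_path)
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "sample", "--freq-record", str(freq_path), "-n", "5",
            "--seed", "1", "-o", str(tmp_path / "ens.xyz")])
        assert res.exit_code == 0, res.output
        from neaspec import read_xyz_frames
        assert len(read_xyz_frames(tmp_path / "ens.xyz")) == 5

        exc_path = tmp_path / "exc.csv"
        exc_path.write_text("geometry_id,state,energy_eV,fosc\n"
                            "0,1,4.0,0.01\n0,2,4.5,0.02\n")
        res = runner.invoke(cli_main, [
            "spectrum", "--excitations", str(exc_path),
            "--delta", "0.1", "-o", str(tmp_path / "spec.csv")])
        assert res.exit_code == 0, res.output
        cs = read_cross_section_csv(tmp_path / "spec.csv")
        assert np.all(cs.values >= 0)
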