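"""Domain-type invariants and file-format round-trips."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neaspec import (
    CrossSection,
    MolecularGeometry,
    NormalModeSet,
    VerticalExcitation,
    read_cross_section_csv,
    read_excitation_table,
    read_frequency_record,
    read_xyz,
    read_xyz_frames,
    write_cross_section_csv,
    write_excitation_table,
    write_frequency_record,
    write_xyz,
    write_xyz_frames,
)
from neaspec.core_io import HC_EV_NM, ParseError, ev_to_nm, nm_to_ev

WATER_XYZ = """3
water
O   0.000000   0.000000   0.117300
H   0.000000   0.757200  -0.469200
H   0.000000  -0.757200  -0.469200
"""


class TestXYZ:
    def test_read_water(self, tmp_path):
        path = tmp_path / "water.xyz"
        path.write_text(WATER_XYZ)
        geom = read_xyz(path)
        assert geom.symbols == ("O", "H", "H")
        assert geom.coords.shape == (3, 3)
        assert geom.masses[0] == pytest.approx(15.999)

    def test_header_count_mismatch(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("4\ncomment\n" + "\n".join(WATER_XYZ.splitlines()[2:]))
        with pytest.raises(ParseError, match="declares 4 atoms"):
            read_xyz(path)

    def test_unknown_element(self, tmp_path):
        path = tmp_path / "xx.xyz"
        path.write_text("1\n\nXx 0 0 0\n")
        with pytest.raises(ParseError, match="Xx"):
            read_xyz(path)

    def test_malformed_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad2.xyz"
        path.write_text("1\n\nO 0 zero 0\n")
        with pytest.raises(ParseError, match=":3:"):
            read_xyz(path)

    def test_roundtrip_coordinates(self, tmp_path, water_geometry):
        path = tmp_path / "rt.xyz"
        write_xyz(water_geometry, path, comment="rt")
        back = read_xyz(path)
        np.testing.assert_allclose(back.coords, water_geometry.coords, atol=1e-6)
        assert back.symbols == water_geometry.symbols

    def test_multiframe_roundtrip(self, tmp_path, water_geometry):
        path = tmp_path / "frames.xyz"
        shifted = MolecularGeometry(water_geometry.symbols, water_geometry.masses,
                                    water_geometry.coords + 0.5)
        write_xyz_frames([water_geometry, shifted], path)
        frames = read_xyz_frames(path)
        assert len(frames) == 2
        np.testing.assert_allclose(frames[1].coords, shifted.coords, atol=1e-6)


class TestGeometryInvariants:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="atom count"):
            MolecularGeometry(("H", "H"), np.array([1.0]), np.zeros((2, 3)))

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            MolecularGeometry(("H",), np.array([1.0]), np.array([[0, np.inf, 0.0]]))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            MolecularGeometry(("H",), np.array([0.0]), np.zeros((1, 3)))


def _freq_record(tmp_path, freqs, modes, symbols=("H", "H"),
                 coords=((0, 0, 0), (0, 0, 0.74))):
    rec = {
        "symbols": list(symbols),
        "coords_angstrom": [list(c) for c in coords],
        "frequencies_cm1": list(freqs),
        "modes": np.asarray(modes).tolist(),
    }
    path = tmp_path / "freq.json"
    path.write_text(json.dumps(rec))
    return path


class TestFrequencyRecord:
    def test_diatomic_single_mode(self, tmp_path):
        mode = np.array([[0, 0, 1, 0, 0, -1]]) / np.sqrt(2)
        nm = read_frequency_record(_freq_record(tmp_path, [4400.0], mode))
        assert nm.n_modes == 1
        assert nm.frequencies[0] == 4400.0

    def test_near_zero_entries_dropped(self, tmp_path):
        # nonlinear triatomic: 3 vibrations kept, 6 translations/rotations dropped
        rng = np.random.default_rng(3)
        q, _ = np.linalg.qr(rng.standard_normal((9, 9)))
        freqs = [0.0, 0.0, 0.0, 1e-3, -1e-3, 0.0, 1600.0, 3650.0, 3750.0]
        path = _freq_record(tmp_path, freqs, q.T, symbols=("O", "H", "H"),
                            coords=((0, 0, 0.1), (0, 0.76, -0.47), (0, -0.76, -0.47)))
        nm = read_frequency_record(path)
        assert nm.n_modes == 3
        assert nm.provenance["n_dropped_near_zero"] == 6

    def test_imaginary_frequency_rejected(self, tmp_path):
        mode = np.array([[0, 0, 1, 0, 0, -1]]) / np.sqrt(2)
        path = _freq_record(tmp_path, [-350.0], mode)
        with pytest.raises(ParseError, match="saddle point"):
            read_frequency_record(path)

    def test_count_mismatch(self, tmp_path):
        mode = np.array([[0, 0, 1, 0, 0, -1]]) / np.sqrt(2)
        path = _freq_record(tmp_path, [1000.0, 2000.0], mode)
        with pytest.raises(ParseError, match="frequencies but"):
            read_frequency_record(path)

    def test_non_orthogonal_modes_rejected(self, tmp_path):
        modes = np.array([[0, 0, 1, 0, 0, -1], [0, 0, 1, 0, 0, 0]])
        path = _freq_record(tmp_path, [1000.0, 2000.0], modes)
        with pytest.raises(ParseError, match="mass-weighted"):
            read_frequency_record(path)

    def test_modes_renormalized_with_recorded_factors(self, tmp_path):
        mode = np.array([[0, 0, 3.0, 0, 0, -3.0]])  # norm 3*sqrt(2)
        nm = read_frequency_record(_freq_record(tmp_path, [2000.0], mode))
        assert np.linalg.norm(nm.modes[0]) == pytest.approx(1.0, abs=1e-12)
        assert nm.provenance["normalization_factors"][0] == pytest.approx(3 * np.sqrt(2))

    def test_molden_dialect(self, tmp_path, water_modes):
        # write a Molden-style file from the canonical record and re-read it
        bohr = 1.0 / 0.529177210903
        lines = ["[Molden Format]", "[FREQ]"]
        lines += [f"{f:.4f}" for f in water_modes.frequencies]
        lines.append("[FR-COORD]")
        for s, xyz in zip(water_modes.equilibrium.symbols,
                          water_modes.equilibrium.coords):
            lines.append(f"{s} {xyz[0]*bohr:.8f} {xyz[1]*bohr:.8f} {xyz[2]*bohr:.8f}")
        lines.append("[FR-NORM-COORD]")
        for k, mode in enumerate(water_modes.modes):
            lines.append(f"vibration {k+1}")
            for a in range(0, 9, 3):
                lines.append(f" {mode[a]:.10f} {mode[a+1]:.10f} {mode[a+2]:.10f}")
        path = tmp_path / "water.molden"
        path.write_text("\n".join(lines))
        nm = read_frequency_record(path, dialect="molden")
        np.testing.assert_allclose(nm.frequencies, water_modes.frequencies, atol=1e-3)
        np.testing.assert_allclose(np.abs(nm.modes), np.abs(water_modes.modes), atol=1e-7)
        np.testing.assert_allclose(nm.equilibrium.coords,
                                   water_modes.equilibrium.coords, atol=1e-6)

    def test_json_roundtrip(self, tmp_path, water_modes):
        path = tmp_path / "rt.json"
        write_frequency_record(water_modes, path)
        back = read_frequency_record(path)
        np.testing.assert_allclose(back.modes, water_modes.modes, atol=1e-12)


class TestExcitationTable:
    def _write_csv(self, tmp_path, rows, header="geometry_id,state,energy_eV,fosc"):
        path = tmp_path / "exc.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_fosc_table(self, tmp_path):
        rows = [f"{g},{s},{4.0 + 0.1 * s},0.01"
                for g in (0, 1) for s in (1, 2, 3)]
        table = read_excitation_table(self._write_csv(tmp_path, rows))
        assert table.n_geometries == 2
        assert table.n_states == 3

    def test_tdm_table(self, tmp_path):
        path = self._write_csv(tmp_path, ["0,1,4.0,1.0,0.0,0.0"],
                               header="geometry_id,state,energy_eV,mu_x,mu_y,mu_z")
        table = read_excitation_table(path)
        assert table.records[0][0].tdm == (1.0, 0.0, 0.0)

    def test_rectangularity_names_geometry(self, tmp_path):
        rows = ["0,1,4.0,0.01", "0,2,4.1,0.01", "0,3,4.2,0.01",
                "7,1,4.0,0.01", "7,2,4.1,0.01"]
        with pytest.raises(ParseError, match="7"):
            read_excitation_table(self._write_csv(tmp_path, rows))

    def test_negative_energy_rejected(self, tmp_path):
        with pytest.raises(ParseError, match="> 0"):
            read_excitation_table(self._write_csv(tmp_path, ["0,1,-0.1,0.01"]))

    def test_missing_intensity_columns(self, tmp_path):
        path = tmp_path / "exc.csv"
        path.write_text("geometry_id,state,energy_eV\n0,1,4.0\n")
        with pytest.raises(ParseError, match="fosc"):
            read_excitation_table(path)

    def test_write_read_roundtrip(self, tmp_path, single_transition_table):
        path = tmp_path / "rt.csv"
        write_excitation_table(single_transition_table, path)
        back = read_excitation_table(path)
        assert back.records[0][0].energy == pytest.approx(4.0, rel=1e-12)
        assert back.records[0][0].fosc == pytest.approx(0.01, rel=1e-12)

    def test_requires_intensity(self):
        with pytest.raises(ValueError, match="tdm / fosc"):
            VerticalExcitation(1, 4.0)


class TestCrossSectionCSV:
    def _cs(self):
        grid = np.array([4.0, 5.0])
        return CrossSection(grid, np.array([1e-18, 2e-18]), 0.05, "gaussian",
                            {"n_geometries": 1, "seed": 0})

    def test_ev_axis_echo(self, tmp_path):
        path = tmp_path / "s.csv"
        write_cross_section_csv(self._cs(), path, unit="eV")
        rows = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        assert rows[0] == "energy_eV,sigma_cm2"
        assert float(rows[1].split(",")[0]) == 4.0

    def test_nm_axis_converted_and_increasing(self, tmp_path):
        path = tmp_path / "s.csv"
        write_cross_section_csv(self._cs(), path, unit="nm")
        rows = [ln for ln in path.read_text().splitlines() if not ln.startswith("#")]
        axis = [float(r.split(",")[0]) for r in rows[1:]]
        assert axis[0] == pytest.approx(HC_EV_NM / 5.0)  # 247.968... nm first
        assert axis[1] == pytest.approx(HC_EV_NM / 4.0)  # 309.960... nm
        assert axis == sorted(axis)

    @pytest.mark.parametrize("unit", ["eV", "nm"])
    def test_roundtrip_to_1e12(self, tmp_path, unit):
        cs = self._cs()
        path = tmp_path / "s.csv"
        write_cross_section_csv(cs, path, unit=unit)
        back = read_cross_section_csv(path)
        np.testing.assert_allclose(back.grid, cs.grid, rtol=1e-12)
        np.testing.assert_allclose(back.values, cs.values, rtol=1e-12)
        assert back.delta == cs.delta and back.lineshape == cs.lineshape

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CrossSection(np.array([]), np.array([]), 0.05, "gaussian")

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="≥ 0"):
            CrossSection(np.array([1.0, 2.0]), np.array([1e-18, -1e-20]),
                         0.05, "gaussian")


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.5, 50.0), min_size=1, max_size=20, unique=True))
def test_axis_conversion_involution(energies):
    grid = np.sort(np.array(energies))
    np.testing.assert_allclose(nm_to_ev(ev_to_nm(grid)), grid, rtol=1e-10)
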