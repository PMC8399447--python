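"""Interchange I/O, mock QC-log parsing, packaged reference tables."""

import json

import numpy as np
import pytest

from bzraman.ensemble_io import (
    filter_by_energy_window,
    read_ensemble,
    read_qc_frequency_block,
    read_xyz,
    write_ensemble,
    write_xyz,
)
from bzraman.models import (
    Conformer,
    Ensemble,
    NormalMode,
    ValidationError,
    reference_energies,
)
from bzraman.synthetic import write_mock_log


class TestInterchangeRoundTrip:
    def test_write_read_is_identity(self, synthetic_ensemble, tmp_path):
        path = write_ensemble(synthetic_ensemble, tmp_path / "e.json")
        back = read_ensemble(path)
        assert back.fragment == synthetic_ensemble.fragment
        assert back.temperature == synthetic_ensemble.temperature
        for a, b in zip(synthetic_ensemble.conformers, back.conformers):
            assert (a.id, a.sequence, a.protonated_terminus) == \
                   (b.id, b.sequence, b.protonated_terminus)
            assert a.relative_energy == b.relative_energy
            assert np.array_equal(a.coordinates(), b.coordinates())
            assert [x.natural_electron_density for x in a.atoms] == \
                   [x.natural_electron_density for x in b.atoms]
            for ma, mb in zip(a.modes, b.modes):
                assert ma.frequency == mb.frequency
                assert ma.raman_activity == mb.raman_activity
                assert np.array_equal(ma.displacements, mb.displacements)
            assert [(h.donor_atom, h.hydrogen_atom, h.acceptor_atom, h.delta_q)
                    for h in a.hbonds] == \
                   [(h.donor_atom, h.hydrogen_atom, h.acceptor_atom, h.delta_q)
                    for h in b.hbonds]
            bma, bmb = a.backbone_map, b.backbone_map
            assert [(r.n, r.ca, r.c, r.o, r.cb) for r in bma.residues] == \
                   [(r.n, r.ca, r.c, r.o, r.cb) for r in bmb.residues]
            assert (bma.cterm_c, bma.cterm_o1, bma.cterm_o2) == \
                   (bmb.cterm_c, bmb.cterm_o1, bmb.cterm_o2)

    def test_energies_rereferenced_to_zero_minimum(self, tmp_path):
        doc = {
            "schema": "bzr-1", "fragment": "EG",
            "conformers": [{"id": "EG-A", "sequence": "EG",
                            "relative_energy": 3.0}],
        }
        path = tmp_path / "one.json"
        path.write_text(json.dumps(doc))
        ensemble = read_ensemble(path)
        assert ensemble.conformers[0].relative_energy == 0.0

    def test_rereferencing_is_idempotent(self):
        ensemble = Ensemble("X", [
            Conformer(id="X-A", sequence="EG", relative_energy=2.0),
            Conformer(id="X-B", sequence="EG", relative_energy=5.0),
        ])
        reference_energies(ensemble)
        first = [c.relative_energy for c in ensemble.conformers]
        reference_energies(ensemble)
        assert [c.relative_energy for c in ensemble.conformers] == first == [0.0, 3.0]

    @pytest.mark.parametrize(
        "mutate,match",
        [
            (lambda d: d["conformers"].append(dict(d["conformers"][0])),
             "duplicate"),
            (lambda d: d.update(conformers=[]), "no conformers"),
            (lambda d: d.update(schema="bzr-0"), "schema"),
            (lambda d: d["conformers"][0].pop("sequence"), "sequence"),
        ],
    )
    def test_schema_violations_name_the_problem(self, tmp_path, mutate, match):
        doc = {
            "schema": "bzr-1", "fragment": "EG",
            "conformers": [{"id": "EG-A", "sequence": "EG",
                            "relative_energy": 0.0}],
        }
        mutate(doc)
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match=match):
            read_ensemble(path)

    def test_displacement_length_mismatch_rejected(self, tmp_path):
        doc = {
            "schema": "bzr-1", "fragment": "EG",
            "conformers": [{
                "id": "EG-A", "sequence": "EG", "relative_energy": 0.0,
                "atoms": [{"element": "O", "position": [0, 0, 0]},
                          {"element": "H", "position": [1, 0, 0]}],
                "modes": [{"frequency": 1650.0, "raman_activity": 1.0,
                           "displacements": [[1, 0, 0]]}],  # 1 row, 2 atoms
            }],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValidationError, match="displacement"):
            read_ensemble(path)


class TestXyzAndCsvRoute:
    def test_xyz_round_trip(self, helical_hexapeptide, tmp_path):
        path = write_xyz(helical_hexapeptide, tmp_path / "c.xyz")
        elements, coords = read_xyz(path)
        assert elements == [a.element for a in helical_hexapeptide.atoms]
        assert coords == pytest.approx(helical_hexapeptide.coordinates(), abs=1e-9)

    def test_directory_manifest_route(self, helical_hexapeptide, tmp_path):
        write_xyz(helical_hexapeptide, tmp_path / "a.xyz")
        write_xyz(helical_hexapeptide, tmp_path / "b.xyz")
        (tmp_path / "conformers.csv").write_text(
            "id,sequence,relative_energy,xyz_file\n"
            "EGEDEA-A,EGEDEA,1.0,a.xyz\n"
            "EGEDEA-B,EGEDEA,3.5,b.xyz\n")
        ensemble = read_ensemble(tmp_path, format="xyz+csv")
        assert [c.id for c in ensemble.conformers] == ["EGEDEA-A", "EGEDEA-B"]
        # re-referenced on read
        assert [c.relative_energy for c in ensemble.conformers] == [0.0, 2.5]


class TestMockLogParser:
    def test_minimal_two_mode_log(self, tmp_path):
        conformer = Conformer(
            id="tiny", sequence="EG", relative_energy=0.0,
            modes=[
                NormalMode(0, 1650.0, 10.0, np.zeros((0, 3))),
                NormalMode(1, 1700.0, 5.0, np.zeros((0, 3))),
            ],
        )
        path = write_mock_log(conformer, tmp_path / "tiny.log")
        modes, _ = read_qc_frequency_block(path)
        assert [(m.frequency, m.raman_activity) for m in modes] == \
               [(1650.0, 10.0), (1700.0, 5.0)]

    def test_generator_log_round_trips_bit_exactly(self, synthetic_ensemble, tmp_path):
        conformer = synthetic_ensemble.conformers[0]
        path = write_mock_log(conformer, tmp_path / "c.log")
        modes, atoms = read_qc_frequency_block(path)
        assert [m.frequency for m in modes] == [m.frequency for m in conformer.modes]
        assert [m.raman_activity for m in modes] == \
               [m.raman_activity for m in conformer.modes]
        for parsed, original in zip(modes, conformer.modes):
            assert np.array_equal(parsed.displacements, original.displacements)
        assert [a.natural_electron_density for a in atoms] == \
               [a.natural_electron_density for a in conformer.atoms]

    def test_log_without_frequency_block_rejected(self, tmp_path):
        conformer = Conformer(id="bare", sequence="EG", relative_energy=0.0)
        path = write_mock_log(conformer, tmp_path / "bare.log")
        with pytest.raises(ValidationError, match="no frequency block"):
            read_qc_frequency_block(path)

    def test_truncated_log_reports_line_number(self, synthetic_ensemble, tmp_path):
        path = write_mock_log(synthetic_ensemble.conformers[0], tmp_path / "c.log")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[: len(lines) // 2]))
        with pytest.raises(ValidationError, match=r":\d+:|truncated"):
            read_qc_frequency_block(path)

    def test_ir_only_log_rejected(self, tmp_path):
        path = tmp_path / "ir.log"
        path.write_text("\n".join([
            "bzraman mock quantum-chemistry log (dialect v1)",
            "natoms 0",
            "begin frequency job",
            "mode 0",
            " frequency 1650.0",
            " ir intensity 1.0",
            "end frequency job",
        ]))
        with pytest.raises(ValidationError, match="Raman"):
            read_qc_frequency_block(path)


class TestReferenceTables:
    def test_sixty_six_tabulated_rows_and_documented_absences(self, table1):
        assert len(table1.df) == 66
        assert len(table1.fragments) == 11
        # three protonated minima exist upstream but were never tabulated
        assert set(table1.untabulated_protonated) == {"EG", "EGED", "EGEDEA"}

    def test_lowest_energy_row_carries_absolute_positions(self, table1):
        row = table1.row("EG-A")
        assert row["delta_e_kcal"] == 0.0
        assert row["ni"] == pytest.approx(0.974)
        assert row["qt_weighted_e"] == pytest.approx(0.594)
        assert row["amide_I_position"] == 1655
        assert row["acoo_position"] == 1645

    def test_shift_rows_resolve_against_the_minimum(self, table1):
        row = table1.row("EGEDEA-B")
        assert row["delta_e_kcal"] == pytest.approx(1.44)
        assert row["amide_I_position"] == 1658 - 1
        assert row["acoo_position"] == 1610 + 1
        # ED-B: +34 shift on the 1631 base
        assert table1.row("ED-B")["amide_I_position"] == 1665

    def test_printed_populations_sum_to_one_per_fragment(self, table1):
        for fragment in table1.fragments:
            assert table1.weights(fragment).sum() == pytest.approx(1.0, abs=5e-4)


class TestEnergyWindow:
    def test_default_window_keeps_every_tabulated_conformer(self, table1):
        ensemble = table1.to_ensemble("EDEA")  # reaches 47.14 kcal/mol
        assert len(filter_by_energy_window(ensemble, 50.0).conformers) == 6

    def test_tighter_window_drops_high_minima(self, table1):
        ensemble = table1.to_ensemble("EDEA")
        kept = filter_by_energy_window(ensemble, 10.0).conformers
        assert [c.relative_energy for c in kept] == [0.00, 1.53, 7.87]

    def test_narrow_window_keeps_only_the_minimum(self, table1):
        for fragment in table1.fragments:
            kept = filter_by_energy_window(table1.to_ensemble(fragment), 0.5)
            assert [c.relative_energy for c in kept.conformers][:1] == [0.0]
            assert all(c.relative_energy <= 0.5 for c in kept.conformers)

    def test_empty_result_is_an_error(self, table1):
        ensemble = table1.to_ensemble("EG")
        for c in ensemble.conformers:
            c.relative_energy += 100.0
        with pytest.raises(ValidationError, match="every conformer"):
            filter_by_energy_window(ensemble, 50.0)
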