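"""Hydrogen-bond detection, charge-transfer derivation, and ensemble totals."""

import numpy as np
import pytest

from bzraman.boltzmann import WeightedEnsemble
from bzraman.hbonds import (
    HBondCriteria,
    charge_transfer_from_weighted_qt,
    charge_transfer_report,
    detect_hbonds,
    hbond_delta_q,
)
from bzraman.models import (
    AtomRecord,
    Conformer,
    Ensemble,
    HBondRecord,
    ValidationError,
)
from bzraman.synthetic import HBondPlan, SyntheticSpec, synthesize_ensemble
from bzraman.synthetic import _build_full


def _three_atoms(angle_deg):
    """O-H covalent pair plus an acceptor O at H...O = 1.8 A and the given
    D-H...A angle."""
    theta = np.radians(180.0 - angle_deg)
    acceptor = np.array([0.97 + 1.8 * np.cos(theta), 1.8 * np.sin(theta), 0.0])
    atoms = [
        AtomRecord(0, "O", [0.0, 0.0, 0.0]),
        AtomRecord(1, "H", [0.97, 0.0, 0.0]),
        AtomRecord(2, "O", acceptor),
    ]
    return Conformer(id="probe", sequence="EG", relative_energy=0.0, atoms=atoms)


class TestDetection:
    def test_ideal_linear_contact_detected(self):
        bonds = detect_hbonds(_three_atoms(180.0))
        assert [(b.donor_atom, b.hydrogen_atom, b.acceptor_atom)
                for b in bonds] == [(0, 1, 2)]

    def test_bent_contact_fails_angle_cut(self):
        assert detect_hbonds(_three_atoms(90.0)) == []

    def test_distance_cut(self):
        conformer = _three_atoms(180.0)
        conformer.atoms[2].position = np.array([0.97 + 3.0, 0.0, 0.0])
        assert detect_hbonds(conformer) == []
        assert detect_hbonds(
            conformer, HBondCriteria(max_h_acceptor_distance=3.2,
                                     max_donor_acceptor_distance=4.5)) != []

    def test_helical_backbone_contacts_are_the_i_to_i_plus_4_bonds(self):
        # the ideal alpha-helical build places amide H(i+4)...O(i) at ~2.0 A
        built = _build_full("EGEDEA", (-57.0, -47.0))
        conformer = built.conformer
        bm = conformer.backbone_map
        bonds = detect_hbonds(conformer)
        triples = {(b.donor_atom, b.hydrogen_atom, b.acceptor_atom) for b in bonds}
        expected = {
            (bm.residues[4].n, built.amide_hydrogens[5], bm.residues[0].o),
            (bm.residues[5].n, built.amide_hydrogens[6], bm.residues[1].o),
        }
        assert expected <= triples

    def test_missing_coordinates_is_an_error(self):
        with pytest.raises(ValidationError, match="no coordinates"):
            detect_hbonds(Conformer(id="x", sequence="EG", relative_energy=0.0))


class TestDeltaQ:
    def _conformer_with_densities(self, rho_h, rho_a):
        atoms = [
            AtomRecord(0, "O", [0, 0, 0], natural_electron_density=8.5),
            AtomRecord(1, "H", [0.97, 0, 0], natural_electron_density=rho_h),
            AtomRecord(2, "O", [2.77, 0, 0], natural_electron_density=rho_a),
        ]
        return Conformer(id="dq", sequence="EG", relative_energy=0.0, atoms=atoms)

    def test_equal_densities_transfer_nothing(self):
        conformer = self._conformer_with_densities(0.55, 0.55)
        assert hbond_delta_q(conformer, HBondRecord(0, 1, 2)) == 0.0

    def test_density_difference_is_the_transfer_magnitude(self):
        # 0.273 e-: the stabilizing bond at the hexapeptide's E2-D junction
        conformer = self._conformer_with_densities(0.500, 0.773)
        assert hbond_delta_q(conformer, HBondRecord(0, 1, 2)) == pytest.approx(0.273)

    def test_stored_value_read_back(self):
        # 0.401 e-: the strongest tabulated bond magnitude
        conformer = self._conformer_with_densities(0.5, 0.6)
        bond = HBondRecord(0, 1, 2, delta_q=0.401)
        assert hbond_delta_q(conformer, bond) == 0.401

    def test_missing_density_names_the_atom(self):
        conformer = self._conformer_with_densities(0.5, 0.6)
        conformer.atoms[2].natural_electron_density = None
        with pytest.raises(ValidationError, match="atom 2"):
            hbond_delta_q(conformer, HBondRecord(0, 1, 2))


class TestChargeTransferReport:
    def _weighted_with_bonds(self, bond_sets, weights):
        conformers = []
        for i, deltas in enumerate(bond_sets):
            atoms = [
                AtomRecord(0, "N", [0, 0, 0]),
                AtomRecord(1, "H", [1, 0, 0]),
                AtomRecord(2, "O", [2.8, 0, 0]),
                AtomRecord(3, "O", [0, 2.8, 0]),
            ]
            bonds = [HBondRecord(0, 1, 2 + (j % 2), delta_q=d)
                     for j, d in enumerate(deltas)]
            conformers.append(Conformer(
                id=f"Q-{i}", sequence="EG", relative_energy=float(i),
                atoms=atoms, hbonds=bonds))
        ensemble = Ensemble("Q", conformers)
        return WeightedEnsemble.from_weights(ensemble, weights)

    def test_single_conformer_totals_its_bonds(self):
        weighted = self._weighted_with_bonds([[0.1, 0.2]], [1.0])
        report = charge_transfer_report(weighted)
        assert report.rows[0].qt_raw == pytest.approx(0.3)
        assert report.q_bt == pytest.approx(0.3)

    def test_total_is_convex_combination_of_conformer_totals(self):
        weighted = self._weighted_with_bonds([[0.3, 0.1], [0.05]], [0.8, 0.2])
        report = charge_transfer_report(weighted)
        raw = report.qt_raw_values()
        assert raw.min() - 1e-12 <= report.q_bt <= raw.max() + 1e-12

    def test_zero_transfer_bond_changes_nothing(self):
        base = self._weighted_with_bonds([[0.3, 0.1]], [1.0])
        padded = self._weighted_with_bonds([[0.3, 0.1, 0.0]], [1.0])
        assert charge_transfer_report(padded).q_bt == \
            charge_transfer_report(base).q_bt

    def test_negligible_weight_conformer_is_negligible(self):
        base = self._weighted_with_bonds([[0.3]], [1.0])
        eps = 1e-7
        extended = self._weighted_with_bonds([[0.3], [0.45]], [1.0 - eps, eps])
        diff = abs(charge_transfer_report(extended).q_bt -
                   charge_transfer_report(base).q_bt)
        assert diff < 1e-5 * 0.45

    def test_planted_bond_magnitudes_recovered_through_pipeline(self):
        plans = [[HBondPlan("nterm", "cterm", 0.36),
                  HBondPlan(3, 1, 0.05)]] * 2
        ensemble = synthesize_ensemble(SyntheticSpec(
            sequence="EGEDEA", n_conformers=2, seed=8,
            relative_energies=[0.0, 1.0], hbond_plan=plans,
            mode_plan=[[], []]))
        weighted = WeightedEnsemble.from_weights(ensemble, [0.75, 0.25])
        report = charge_transfer_report(weighted)
        assert report.qt_raw_values() == pytest.approx([0.41, 0.41])
        assert report.q_bt == pytest.approx(0.41, abs=1e-9)


class TestPublishedTotals:
    def test_all_fragment_totals_within_a_centielectron(self, table1, table2):
        for fragment in table1.fragments:
            report = charge_transfer_from_weighted_qt(
                fragment,
                table1.rows(fragment).index,
                table1.weighted_qt(fragment),
                table1.hb_counts(fragment))
            assert report.q_bt == pytest.approx(
                table2.loc[fragment]["q_bt_e"], abs=0.01), fragment

    def test_charge_transfer_grows_along_the_ed_growth_path(self, table1):
        totals = [
            charge_transfer_from_weighted_qt(
                f, table1.rows(f).index, table1.weighted_qt(f)).q_bt
            for f in ("ED", "DEA", "EDEA", "GEDEA", "EGEDEA")
        ]
        assert np.all(np.diff(totals) >= 0)

    def test_glycine_interruption_breaks_monotone_growth(self, table1):
        """Along EG -> EGE -> EGED -> EGEDE -> EGEDEA the totals grow
        except at the EGED step, where the nonpolar glycine interrupts the
        acidic side chains and reduces the hydrogen-bond network."""
        totals = [
            charge_transfer_from_weighted_qt(
                f, table1.rows(f).index, table1.weighted_qt(f)).q_bt
            for f in ("EG", "EGE", "EGED", "EGEDE", "EGEDEA")
        ]
        steps = np.diff(totals)
        assert steps[0] > 0 and steps[2] > 0 and steps[3] > 0
        assert steps[1] < 0  # the documented EGE -> EGED dip
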