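"""Intramolecular hydrogen bonds: geometric detection, per-bond charge
transfer from natural electron densities, and ensemble aggregation.

Charge-transfer convention
--------------------------
Each hydrogen bond carries a magnitude Δq (e⁻) describing the charge
transferred through the donor–H···acceptor contact.  When Δq values are
supplied in the interchange file (the normal case — the natural-population
analysis runs upstream) they are consumed as-is; :func:`hbond_delta_q`
otherwise derives Δq as the absolute difference between the natural
electron densities of the bridging hydrogen and the acceptor atom.  That
convention is deliberately isolated in one function so it can be swapped.

A conformer's total is qT_raw = Σ Δq over its bonds; the population-
weighted per-conformer value is N_i·qT_raw, and the ensemble total is
q_B_T = Σ_i N_i·qT_raw — a convex combination (after weight
renormalization), hence bounded by the extreme conformer totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .boltzmann import WeightedEnsemble
from .models import Conformer, HBondRecord, ValidationError

__all__ = [
    "HBondCriteria",
    "ChargeTransferRow",
    "ChargeTransferReport",
    "detect_hbonds",
    "hbond_delta_q",
    "charge_transfer_report",
    "charge_transfer_from_weighted_qt",
    "write_charge_transfer_csv",
]

#: Donor/acceptor elements considered for hydrogen bonding.
_DONOR_ACCEPTOR_ELEMENTS = {"N", "O"}
#: Covalent D-H bond cutoff, Å.
_COVALENT_DH = 1.2


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (common structural-biology
    practice; the physical model itself fixes no cutoffs, so all three are
    configurable)."""

    max_donor_acceptor_distance: float = 3.5  # Å
    min_dha_angle: float = 120.0  # degrees
    max_h_acceptor_distance: float = 2.7  # Å

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0 or self.max_h_acceptor_distance <= 0:
            raise ValidationError("hydrogen-bond distance cutoffs must be > 0")
        if not (0 < self.min_dha_angle <= 180):
            raise ValidationError("min_dha_angle must be in (0, 180]")


def detect_hbonds(
    conformer: Conformer,
    criteria: HBondCriteria | None = None,
) -> list[HBondRecord]:
    """Geometric detection of intramolecular donor–H···acceptor triples.

    Donors are N/O with a covalently bound hydrogen (D–H < 1.2 Å);
    acceptors are N/O other than the donor and not covalently bound to the
    hydrogen.  A triple qualifies if H···A and D···A distances and the
    D–H···A angle all meet the criteria.  Returned records have ``delta_q``
    unset; an empty list is a valid result.
    """
    criteria = criteria or HBondCriteria()
    if not conformer.atoms:
        raise ValidationError(f"{conformer.id}: no coordinates")
    coords = conformer.coordinates()
    elements = [a.element for a in conformer.atoms]

    heavies = [i for i, el in enumerate(elements) if el in _DONOR_ACCEPTOR_ELEMENTS]
    hydrogens = [i for i, el in enumerate(elements) if el == "H"]

    # covalent assignment: each H belongs to its nearest heavy donor within cutoff
    dh_pairs = []
    for h in hydrogens:
        dists = [(float(np.linalg.norm(coords[h] - coords[d])), d) for d in heavies]
        if not dists:
            continue
        dist, donor = min(dists)
        if dist < _COVALENT_DH:
            dh_pairs.append((donor, h))

    bonds: list[HBondRecord] = []
    for donor, h in dh_pairs:
        for acceptor in heavies:
            if acceptor == donor:
                continue
            ha = float(np.linalg.norm(coords[h] - coords[acceptor]))
            if ha < _COVALENT_DH or ha > criteria.max_h_acceptor_distance:
                continue
            da = float(np.linalg.norm(coords[donor] - coords[acceptor]))
            if da > criteria.max_donor_acceptor_distance:
                continue
            v1 = coords[donor] - coords[h]
            v2 = coords[acceptor] - coords[h]
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < criteria.min_dha_angle:
                continue
            bonds.append(HBondRecord(donor_atom=donor, hydrogen_atom=h,
                                     acceptor_atom=acceptor))
    return bonds


def hbond_delta_q(conformer: Conformer, bond: HBondRecord) -> float:
    """Charge transferred through one bond, |ρ(acceptor) − ρ(hydrogen)| e⁻.

    When the interchange file already carries ``delta_q`` for the bond this
    validates (and returns) the stored value instead of recomputing.
    """
    if bond.delta_q is not None:
        if bond.delta_q < 0:
            raise ValidationError(f"{conformer.id}: stored delta_q < 0")
        return float(bond.delta_q)
    for idx, role in ((bond.hydrogen_atom, "hydrogen"), (bond.acceptor_atom, "acceptor")):
        atom = conformer.atoms[idx]
        if atom.natural_electron_density is None:
            raise ValidationError(
                f"{conformer.id}: atom {idx} ({role}, {atom.element}) has no "
                f"natural electron density; cannot derive delta_q")
    rho_h = conformer.atoms[bond.hydrogen_atom].natural_electron_density
    rho_a = conformer.atoms[bond.acceptor_atom].natural_electron_density
    return abs(float(rho_a) - float(rho_h))


@dataclass
class ChargeTransferRow:
    conformer_id: str
    hb_count: int
    qt_raw: float      # sum of delta_q over bonds, e-
    weight: float      # N_i (renormalized)
    qt_weighted: float  # N_i * qt_raw, e-


@dataclass
class ChargeTransferReport:
    fragment: str
    rows: list[ChargeTransferRow]
    q_bt: float  # ensemble total, e-

    def qt_raw_values(self) -> np.ndarray:
        return np.array([r.qt_raw for r in self.rows])


def charge_transfer_report(weighted: WeightedEnsemble) -> ChargeTransferReport:
    """Aggregate per-conformer charge transfer into the ensemble total.

    Every conformer must carry hydrogen bonds with Δq either stored or
    derivable from atomic densities.  Weights are renormalized so reports
    built from rounded published populations stay consistent.
    """
    w = np.asarray(weighted.weights, float)
    w = w / w.sum()
    rows = []
    for conformer, n_i in zip(weighted.ensemble.conformers, w):
        qt_raw = float(sum(hbond_delta_q(conformer, b) for b in conformer.hbonds))
        rows.append(ChargeTransferRow(
            conformer_id=conformer.id,
            hb_count=len(conformer.hbonds),
            qt_raw=qt_raw,
            weight=float(n_i),
            qt_weighted=float(n_i * qt_raw),
        ))
    q_bt = float(sum(r.qt_weighted for r in rows))
    return ChargeTransferReport(fragment=weighted.ensemble.fragment,
                                rows=rows, q_bt=round(q_bt, 3))


def charge_transfer_from_weighted_qt(
    fragment: str,
    conformer_ids: Sequence[str],
    weighted_qt: Sequence[float],
    hb_counts: Optional[Sequence[int]] = None,
) -> ChargeTransferReport:
    """Build a report from per-conformer values that are *already*
    population-weighted (N_i·qT_raw), as published per-conformer tables
    print them.  q_B_T is then the plain sum — weighting is never applied
    twice."""
    qt = np.asarray(weighted_qt, float)
    if np.any(qt < 0):
        raise ValidationError("weighted qT values must be >= 0")
    counts = list(hb_counts) if hb_counts is not None else [0] * len(qt)
    rows = [
        ChargeTransferRow(conformer_id=str(cid), hb_count=int(n),
                          qt_raw=float("nan"), weight=float("nan"),
                          qt_weighted=float(q))
        for cid, q, n in zip(conformer_ids, qt, counts)
    ]
    return ChargeTransferReport(fragment=fragment, rows=rows,
                                q_bt=round(float(qt.sum()), 3))


def write_charge_transfer_csv(
    reports: Sequence[ChargeTransferReport], path: str | Path
) -> Path:
    lines = ["fragment,conformer,hb_count,qt_raw_e,weight,qt_weighted_e,q_bt_e"]
    for r in reports:
        for row in r.rows:
            lines.append(
                f"{r.fragment},{row.conformer_id},{row.hb_count},"
                f"{row.qt_raw:.6g},{row.weight:.6g},{row.qt_weighted:.6g},"
                f"{r.q_bt:.3f}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
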