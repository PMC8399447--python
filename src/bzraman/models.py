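"""Domain containers for conformer-ensemble Raman analysis.

A :class:`Conformer` bundles everything the pipeline needs about one
optimized peptide geometry: its relative electronic energy (kcal/mol,
referenced to the ensemble minimum), Cartesian coordinates with per-atom
natural electron densities, harmonic normal modes with Raman activities,
intramolecular hydrogen bonds with their charge-transfer magnitudes, and a
map of backbone atom indices used for band assignment and phi/psi analysis.
An :class:`Ensemble` is a fragment's set of conformers plus the temperature
at which Boltzmann populations are evaluated.

Containers are plain dataclasses; full invariant checking lives in
:func:`validate_conformer` / :func:`validate_ensemble` and is invoked by the
I/O layer and the synthetic generator, so partially-populated objects (e.g.
fixture-driven conformers with no geometry) remain cheap to construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "AtomRecord",
    "NormalMode",
    "HBondRecord",
    "ResidueBackbone",
    "BackboneMap",
    "Conformer",
    "Ensemble",
    "validate_conformer",
    "validate_ensemble",
]

#: Chemical symbols accepted in peptide models (H plus common heavy atoms).
VALID_ELEMENTS = {
    "H", "C", "N", "O", "S",
}


class ValidationError(ValueError):
    """Raised when a record violates a documented invariant."""


@dataclass
class AtomRecord:
    """One atom: 0-based index, element symbol, position (Å) and, when a
    natural population analysis is available, the total natural electron
    density residing on the atom (e⁻)."""

    index: int
    element: str
    position: np.ndarray
    natural_electron_density: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class NormalMode:
    """A harmonic normal mode: unscaled frequency (cm⁻¹), Raman activity
    (Å⁴/amu) and normalized per-atom displacement vectors."""

    index: int
    frequency: float
    raman_activity: float
    displacements: np.ndarray  # shape (n_atoms, 3)

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)


@dataclass
class HBondRecord:
    """Donor–H···acceptor triple (atom indices) with the magnitude of
    charge transferred through the bond, Δq (e⁻). ``delta_q`` is ``None``
    for geometrically detected bonds whose NBO data are not yet attached."""

    donor_atom: int
    hydrogen_atom: int
    acceptor_atom: int
    delta_q: Optional[float] = None


@dataclass
class ResidueBackbone:
    """Backbone atom indices of one residue: amide N, Cα, carbonyl C and
    carbonyl O.  ``cb`` is the Cβ stub (absent for glycine)."""

    n: int
    ca: int
    c: int
    o: int
    cb: Optional[int] = None


@dataclass
class BackboneMap:
    """Index map of the peptide backbone, 1-based residue numbering from the
    αNH₃⁺ terminus.  The C-terminal carboxylate carbon and its two oxygens
    are stored explicitly; ``residues[-1].c``/``.o`` alias the carboxylate
    carbon and its first oxygen."""

    residues: list[ResidueBackbone]
    nterm_n: int
    cterm_c: int
    cterm_o1: int
    cterm_o2: int

    @property
    def n_residues(self) -> int:
        return len(self.residues)


@dataclass
class Conformer:
    id: str
    sequence: str
    relative_energy: float
    atoms: list[AtomRecord] = field(default_factory=list)
    modes: list[NormalMode] = field(default_factory=list)
    hbonds: list[HBondRecord] = field(default_factory=list)
    backbone_map: Optional[BackboneMap] = None
    protonated_terminus: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Ensemble:
    """A fragment's conformer set.  ``temperature`` (K) is the temperature
    used for all Boltzmann statistics downstream (default 298 K, the
    room-temperature condition the simulated spectra target)."""

    fragment: str
    conformers: list[Conformer]
    temperature: float = 298.0


# ---------------------------------------------------------------------------
# invariant checking


def _fail(msg: str) -> None:
    raise ValidationError(msg)


def validate_conformer(c: Conformer) -> None:
    """Check all documented invariants of a single conformer.

    Raises :class:`ValidationError` naming the offending field.
    """
    if not c.id:
        _fail("conformer id must be non-empty")
    if not np.isfinite(c.relative_energy) or c.relative_energy < 0:
        _fail(f"{c.id}: relative_energy must be finite and >= 0, "
              f"got {c.relative_energy}")
    n_atoms = len(c.atoms)
    for a in c.atoms:
        if a.element not in VALID_ELEMENTS:
            _fail(f"{c.id}: atom {a.index} has invalid element {a.element!r}")
        if a.position.shape != (3,) or not np.all(np.isfinite(a.position)):
            _fail(f"{c.id}: atom {a.index} position must be a finite 3-vector")
        if a.natural_electron_density is not None and a.natural_electron_density < 0:
            _fail(f"{c.id}: atom {a.index} natural_electron_density < 0")
    for m in c.modes:
        if m.frequency <= 0:
            _fail(f"{c.id}: mode {m.index} frequency must be > 0")
        if m.raman_activity < 0:
            _fail(f"{c.id}: mode {m.index} raman_activity must be >= 0")
        if m.displacements.shape != (n_atoms, 3):
            _fail(f"{c.id}: mode {m.index} displacement list length "
                  f"{m.displacements.shape[0] if m.displacements.ndim == 2 else '?'} "
                  f"does not match atom count {n_atoms}")
    for hb in c.hbonds:
        trio = (hb.donor_atom, hb.hydrogen_atom, hb.acceptor_atom)
        if len(set(trio)) != 3:
            _fail(f"{c.id}: hydrogen bond atoms must be three distinct indices, got {trio}")
        if hb.delta_q is not None and hb.delta_q < 0:
            _fail(f"{c.id}: hydrogen bond delta_q must be >= 0")
        if c.atoms:
            for idx in trio:
                if not (0 <= idx < n_atoms):
                    _fail(f"{c.id}: hydrogen bond atom index {idx} out of range")
            if c.atoms[hb.hydrogen_atom].element != "H":
                _fail(f"{c.id}: hydrogen bond bridging atom {hb.hydrogen_atom} "
                      f"is {c.atoms[hb.hydrogen_atom].element}, expected H")
    if c.backbone_map is not None:
        bm = c.backbone_map
        if bm.n_residues != len(c.sequence):
            _fail(f"{c.id}: backbone_map has {bm.n_residues} residues but "
                  f"sequence {c.sequence!r} has {len(c.sequence)}")
        if c.atoms:
            all_idx = [bm.nterm_n, bm.cterm_c, bm.cterm_o1, bm.cterm_o2]
            for r in bm.residues:
                all_idx += [r.n, r.ca, r.c, r.o]
                if r.cb is not None:
                    all_idx.append(r.cb)
            for idx in all_idx:
                if not (0 <= idx < n_atoms):
                    _fail(f"{c.id}: backbone_map index {idx} out of range")


def validate_ensemble(e: Ensemble, *, zero_tol: float = 1e-9) -> None:
    """Check ensemble-level invariants (non-empty, unique ids, temperature,
    at least one conformer at the energy reference 0).

    Degenerate global minima (two conformers at ΔE = 0) are permitted; the
    Boltzmann layer splits their zero-temperature weight uniformly.
    """
    if not e.conformers:
        _fail(f"ensemble {e.fragment!r} is empty")
    if e.temperature <= 0:
        _fail(f"ensemble {e.fragment!r}: temperature must be > 0")
    ids = [c.id for c in e.conformers]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        _fail(f"ensemble {e.fragment!r}: duplicate conformer ids {dupes}")
    for c in e.conformers:
        validate_conformer(c)
    if min(c.relative_energy for c in e.conformers) > zero_tol:
        _fail(f"ensemble {e.fragment!r}: no conformer at relative_energy 0 "
              f"(energies not re-referenced?)")


def reference_energies(e: Ensemble) -> Ensemble:
    """Shift all relative energies so the ensemble minimum is exactly 0.

    Idempotent; returns the same ensemble object.
    """
    e_min = min(c.relative_energy for c in e.conformers)
    if e_min != 0.0:
        for c in e.conformers:
            c.relative_energy -= e_min
    return e
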