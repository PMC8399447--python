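"""Synthetic conformer ensembles with the statistical and structural
features the analysis pipeline assumes.

Electronic-structure calculations (geometry optimization, harmonic
frequencies, natural population analysis) sit upstream of this package and
are expensive; this module fabricates their *outputs* so every pipeline
stage is testable end-to-end.  It emulates:

* conformer relative-energy ladders (exponential draw, truncated at the
  50 kcal/mol analysis window, minimum forced to 0 — the dominant-minimum
  regime where the lowest conformer carries most of the population),
* C=O-localized normal modes placed on chosen bonds with a planted
  localization fraction, raw frequencies near the amide I region,
* zwitterionic (αNH₃⁺ / αCOO⁻) or self-protonated termini,
* 2–7 intramolecular hydrogen bonds per conformer with Δq in the
  0.001–0.401 e⁻ range,
* backbone geometry at requested (φ, ψ) torsions.

Geometries are *constructed* from ideal internal coordinates (see
``BOND_LENGTHS``), not energy-minimized; side chains are reduced to a Cβ
stub (glycine has none) because no analysis stage reads side-chain atoms.
All randomness flows through one seeded generator per spec — same seed,
bit-identical ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .models import (
    AtomRecord,
    BackboneMap,
    Conformer,
    Ensemble,
    HBondRecord,
    NormalMode,
    ResidueBackbone,
    ValidationError,
    validate_ensemble,
)

__all__ = [
    "BOND_LENGTHS",
    "BOND_ANGLES",
    "SUPPORTED_RESIDUES",
    "ModePlan",
    "HBondPlan",
    "SyntheticSpec",
    "build_peptide",
    "synthesize_ensemble",
    "write_mock_log",
]

SUPPORTED_RESIDUES = set("ADEG")

#: Ideal bond lengths used by the builder, Å.
BOND_LENGTHS = {
    ("N", "CA"): 1.46,
    ("CA", "C"): 1.52,
    ("C", "N"): 1.33,   # peptide bond
    ("C", "O"): 1.23,   # backbone carbonyl
    ("C", "OX"): 1.25,  # carboxylate C-O (both oxygens)
    ("CA", "CB"): 1.53,
    ("N", "H"): 1.01,   # amide N-H
    ("N", "H3"): 1.03,  # ammonium N-H
    ("O", "H"): 0.97,   # carboxylic acid O-H (protonated terminus)
}

#: Ideal bond angles, degrees.
BOND_ANGLES = {
    "N-CA-C": 110.4,
    "CA-C-N": 116.6,
    "C-N-CA": 121.7,
    "CA-C-O": 120.8,
    "CA-C-OX": 117.0,
    "N-CA-CB": 110.5,
    "C-N-H": 119.0,
    "CA-N-H": 109.5,
    "C-O-H": 106.0,
}

_OMEGA = 180.0  # planar trans peptide bond


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement: return point d with
    |cd| = bond, angle(b,c,d) = angle, torsion(a,b,c,d) = torsion."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValidationError("degenerate reference frame (collinear a, b, c)")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class _BuiltPeptide:
    conformer: Conformer
    nterm_hydrogens: list[int]
    amide_hydrogens: dict[int, int]  # residue (1-based, >= 2) -> H index
    carboxyl_hydrogen: Optional[int]


def _normalize_phi_psi(sequence: str, phi_psi) -> list[tuple[float, float]]:
    n = len(sequence)
    if phi_psi is None:
        phi_psi = (180.0, 180.0)
    if isinstance(phi_psi, tuple) and len(phi_psi) == 2 and np.isscalar(phi_psi[0]):
        return [(float(phi_psi[0]), float(phi_psi[1]))] * n
    pairs = [(float(p[0]), float(p[1])) for p in phi_psi]
    if len(pairs) != n:
        raise ValidationError(
            f"phi_psi list length {len(pairs)} does not match sequence length {n}")
    return pairs


def _build_full(sequence: str, phi_psi=None, zwitterionic: bool = True,
                conformer_id: str = "built") -> _BuiltPeptide:
    sequence = sequence.upper()
    for letter in sequence:
        if letter not in SUPPORTED_RESIDUES:
            raise ValidationError(
                f"unsupported residue {letter!r}; supported: "
                f"{''.join(sorted(SUPPORTED_RESIDUES))}")
    if len(sequence) < 2:
        raise ValidationError("build_peptide requires at least two residues")
    targets = _normalize_phi_psi(sequence, phi_psi)

    atoms: list[AtomRecord] = []

    def add(element: str, position) -> int:
        idx = len(atoms)
        atoms.append(AtomRecord(index=idx, element=element,
                                position=np.asarray(position, float)))
        return idx

    n_res = len(sequence)
    res_n, res_ca, res_c, res_o, res_cb = [], [], [], [], []

    # first residue backbone: N at origin, CA on x, C in the xy plane
    i_n = add("N", [0.0, 0.0, 0.0])
    i_ca = add("C", [BOND_LENGTHS[("N", "CA")], 0.0, 0.0])
    ang = math.radians(180.0 - BOND_ANGLES["N-CA-C"])
    i_c = add("C", atoms[i_ca].position + BOND_LENGTHS[("CA", "C")] *
              np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0]))
    res_n.append(i_n); res_ca.append(i_ca); res_c.append(i_c)
    res_o.append(-1); res_cb.append(-1)

    for i in range(1, n_res):
        psi_prev = targets[i - 1][1]
        phi_i = targets[i][0]
        p_n = _place_atom(atoms[res_n[i - 1]].position,
                          atoms[res_ca[i - 1]].position,
                          atoms[res_c[i - 1]].position,
                          BOND_LENGTHS[("C", "N")], BOND_ANGLES["CA-C-N"],
                          psi_prev)
        i_n = add("N", p_n)
        p_ca = _place_atom(atoms[res_ca[i - 1]].position,
                           atoms[res_c[i - 1]].position,
                           atoms[i_n].position,
                           BOND_LENGTHS[("N", "CA")], BOND_ANGLES["C-N-CA"],
                           _OMEGA)
        i_ca = add("C", p_ca)
        p_c = _place_atom(atoms[res_c[i - 1]].position,
                          atoms[i_n].position,
                          atoms[i_ca].position,
                          BOND_LENGTHS[("CA", "C")], BOND_ANGLES["N-CA-C"],
                          phi_i)
        i_c = add("C", p_c)
        # carbonyl O of the previous residue, anti to the new N across C
        p_o = _place_atom(atoms[i_n].position,
                          atoms[res_ca[i - 1]].position,
                          atoms[res_c[i - 1]].position,
                          BOND_LENGTHS[("C", "O")], BOND_ANGLES["CA-C-O"],
                          180.0)
        res_o[i - 1] = add("O", p_o)
        res_n.append(i_n); res_ca.append(i_ca); res_c.append(i_c)
        res_o.append(-1); res_cb.append(-1)

    # C-terminal carboxylate oxygens
    last = n_res - 1
    o1 = add("O", _place_atom(atoms[res_n[last]].position,
                              atoms[res_ca[last]].position,
                              atoms[res_c[last]].position,
                              BOND_LENGTHS[("C", "OX")],
                              BOND_ANGLES["CA-C-OX"], 0.0))
    o2 = add("O", _place_atom(atoms[res_n[last]].position,
                              atoms[res_ca[last]].position,
                              atoms[res_c[last]].position,
                              BOND_LENGTHS[("C", "OX")],
                              BOND_ANGLES["CA-C-OX"], 180.0))
    res_o[last] = o1

    # C-beta stubs (improper torsion fixes L-chirality)
    for i, letter in enumerate(sequence):
        if letter == "G":
            continue
        res_cb[i] = add("C", _place_atom(atoms[res_c[i]].position,
                                         atoms[res_n[i]].position,
                                         atoms[res_ca[i]].position,
                                         BOND_LENGTHS[("CA", "CB")],
                                         BOND_ANGLES["N-CA-CB"], -122.6))

    # amide hydrogens (residues 2..n), anti to the carbonyl O
    amide_h: dict[int, int] = {}
    for i in range(1, n_res):
        amide_h[i + 1] = add("H", _place_atom(atoms[res_o[i - 1]].position,
                                              atoms[res_c[i - 1]].position,
                                              atoms[res_n[i]].position,
                                              BOND_LENGTHS[("N", "H")],
                                              BOND_ANGLES["C-N-H"], 180.0))

    # N-terminal hydrogens: three for the ammonium, two for neutral NH2
    nterm_h: list[int] = []
    n_h = 3 if zwitterionic else 2
    for k in range(n_h):
        nterm_h.append(add("H", _place_atom(atoms[res_c[0]].position,
                                            atoms[res_ca[0]].position,
                                            atoms[res_n[0]].position,
                                            BOND_LENGTHS[("N", "H3")],
                                            BOND_ANGLES["CA-N-H"],
                                            60.0 + 120.0 * k)))

    carboxyl_h: Optional[int] = None
    if not zwitterionic:
        # the self-protonated form: the terminal carboxylate picked up the
        # ammonium proton
        carboxyl_h = add("H", _place_atom(atoms[res_ca[last]].position,
                                          atoms[res_c[last]].position,
                                          atoms[o2].position,
                                          BOND_LENGTHS[("O", "H")],
                                          BOND_ANGLES["C-O-H"], 180.0))

    backbone_map = BackboneMap(
        residues=[
            ResidueBackbone(n=res_n[i], ca=res_ca[i], c=res_c[i], o=res_o[i],
                            cb=None if res_cb[i] < 0 else res_cb[i])
            for i in range(n_res)
        ],
        nterm_n=res_n[0],
        cterm_c=res_c[last],
        cterm_o1=o1,
        cterm_o2=o2,
    )
    conformer = Conformer(
        id=conformer_id,
        sequence=sequence,
        relative_energy=0.0,
        atoms=atoms,
        backbone_map=backbone_map,
        protonated_terminus=not zwitterionic,
    )
    return _BuiltPeptide(conformer=conformer, nterm_hydrogens=nterm_h,
                         amide_hydrogens=amide_h, carboxyl_hydrogen=carboxyl_h)


def build_peptide(sequence: str, phi_psi=None, zwitterionic: bool = True,
                  conformer_id: str = "built") -> Conformer:
    """Construct a peptide backbone at the requested (φ, ψ) torsions.

    ``phi_psi`` is either one ``(phi, psi)`` pair applied to every residue
    or a per-residue list (terminal φ/ψ entries are ignored — those
    torsions do not exist).  Default is the fully extended chain
    (180°, 180°).  Peptide bonds are planar trans (ω = 180°); bond lengths
    and angles come from the documented ``BOND_LENGTHS`` / ``BOND_ANGLES``
    tables.  ``zwitterionic=True`` gives αNH₃⁺ / αCOO⁻ termini; ``False``
    gives the self-protonated form (αNH₂ + terminal COOH).
    """
    return _build_full(sequence, phi_psi, zwitterionic, conformer_id).conformer


# ---------------------------------------------------------------------------
# ensemble synthesis


@dataclass
class ModePlan:
    """One planned normal mode: which bond it sits on (``amide_I``,
    ``alphaCOO`` or ``other``), raw (unscaled) frequency in cm⁻¹, Raman
    activity in Å⁴/amu, and the fraction of squared displacement norm
    placed on the target atoms."""

    target: str
    frequency: float
    activity: float
    localization: float = 0.9

    def __post_init__(self) -> None:
        if not (0 < self.localization <= 1):
            raise ValidationError("localization fraction must be in (0, 1]")
        if self.frequency <= 0 or self.activity < 0:
            raise ValidationError("mode plan needs frequency > 0, activity >= 0")


@dataclass
class HBondPlan:
    """One planned hydrogen bond in abstract roles: donor is ``"nterm"``
    (the αNH₃⁺/αNH₂ group) or a 1-based residue number (that residue's
    amide N–H); acceptor is ``"cterm"`` (carboxylate O) or a residue number
    (that residue's carbonyl O)."""

    donor: Union[int, str]
    acceptor: Union[int, str]
    delta_q: float

    def __post_init__(self) -> None:
        if not (0 <= self.delta_q <= 0.5):
            raise ValidationError("delta_q must be in [0, 0.5] e-")


@dataclass
class SyntheticSpec:
    """Recipe for a mock ensemble.  Leave the plan fields ``None`` to let
    the seeded generator draw study-like defaults: an exponential ΔE ladder
    (scale ``energy_spread`` kcal/mol, truncated at 50), one localized
    amide I and one αCOO⁻ mode per conformer in the 1600–1700 cm⁻¹ scaled
    region plus background modes, and 2–7 hydrogen bonds with Δq up to
    0.401 e⁻."""

    sequence: str = "EGEDEA"
    n_conformers: int = 6
    seed: int = 0
    energy_spread: float = 4.0
    temperature: float = 298.0
    fragment: Optional[str] = None
    relative_energies: Optional[Sequence[float]] = None
    phi_psi_targets: Optional[Sequence] = None        # per conformer
    mode_plan: Optional[Sequence[Sequence[ModePlan]]] = None
    hbond_plan: Optional[Sequence[Sequence[HBondPlan]]] = None
    zwitterionic: bool = True

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValidationError("n_conformers must be >= 1")
        if self.energy_spread <= 0:
            raise ValidationError("energy_spread must be > 0")


def _draw_energies(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.relative_energies is not None:
        e = np.asarray(spec.relative_energies, float)
        if len(e) != spec.n_conformers:
            raise ValidationError("relative_energies length mismatch")
    else:
        # inverse-CDF sample of an exponential truncated at the 50 kcal/mol
        # analysis window
        u = rng.random(spec.n_conformers)
        cap = 1.0 - math.exp(-50.0 / spec.energy_spread)
        e = -spec.energy_spread * np.log1p(-u * cap)
    e = e - e.min()
    return np.sort(e)


def _mode_targets(conformer: Conformer, target: str) -> list[tuple[int, int]]:
    bm = conformer.backbone_map
    assert bm is not None
    if target == "amide_I":
        first = bm.residues[0]
        return [(first.c, first.o)]
    if target == "alphaCOO":
        return [(bm.cterm_c, bm.cterm_o1), (bm.cterm_c, bm.cterm_o2)]
    if target == "other":
        return []
    raise ValidationError(f"unknown mode target {target!r}")


def _plant_mode(conformer: Conformer, plan: ModePlan, index: int,
                rng: np.random.Generator) -> NormalMode:
    """Build a displacement field with ``plan.localization`` of its squared
    norm as a stretch on the target bond(s), the remainder spread over the
    other atoms as random directions."""
    n_atoms = conformer.n_atoms
    coords = conformer.coordinates()
    disp = np.zeros((n_atoms, 3))
    pairs = _mode_targets(conformer, plan.target)
    target_atoms: set[int] = set()
    f = plan.localization if pairs else 0.0
    if pairs:
        t = math.sqrt(f / (2.0 * len(pairs)))
        for k, (c_idx, o_idx) in enumerate(pairs):
            axis = coords[o_idx] - coords[c_idx]
            axis = axis / np.linalg.norm(axis)
            sign = 1.0 if k == 0 else -1.0  # antisymmetric across pairs
            disp[o_idx] += sign * t * axis
            disp[c_idx] -= sign * t * axis
            target_atoms.update((c_idx, o_idx))
    rest = [i for i in range(n_atoms) if i not in target_atoms]
    remainder = 1.0 - f
    if rest and remainder > 0:
        noise = rng.normal(size=(len(rest), 3))
        noise *= math.sqrt(remainder) / np.linalg.norm(noise)
        for row, i in enumerate(rest):
            disp[i] = noise[row]
    return NormalMode(index=index, frequency=plan.frequency,
                      raman_activity=plan.activity, displacements=disp)


def _default_mode_plan(rng: np.random.Generator) -> list[ModePlan]:
    plans = [
        ModePlan("amide_I", rng.uniform(1680.0, 1730.0),
                 rng.uniform(5.0, 15.0), 0.9),
        ModePlan("alphaCOO", rng.uniform(1645.0, 1675.0),
                 rng.uniform(5.0, 15.0), 0.9),
    ]
    for _ in range(3):
        plans.append(ModePlan("other", rng.uniform(600.0, 1500.0),
                              rng.uniform(1.0, 8.0), 1.0))
    return plans


def _default_hbond_plan(sequence: str, rng: np.random.Generator) -> list[HBondPlan]:
    n_res = len(sequence)
    count = int(rng.integers(2, 8))
    plans = [HBondPlan("nterm", "cterm", float(rng.uniform(0.2, 0.401)))]
    for _ in range(count - 1):
        donor = int(rng.integers(2, n_res + 1)) if n_res >= 2 else "nterm"
        acceptor = int(rng.integers(1, n_res))  # carbonyl O of residues 1..n-1
        plans.append(HBondPlan(donor, acceptor,
                               float(rng.uniform(0.001, 0.1))))
    return plans


def _resolve_hbond(built: _BuiltPeptide, plan: HBondPlan) -> Optional[HBondRecord]:
    bm = built.conformer.backbone_map
    assert bm is not None
    if plan.donor == "nterm":
        donor, hydrogen = bm.nterm_n, built.nterm_hydrogens[0]
    else:
        res = int(plan.donor)
        if res not in built.amide_hydrogens:
            raise ValidationError(f"hbond plan: residue {res} has no amide H")
        donor, hydrogen = bm.residues[res - 1].n, built.amide_hydrogens[res]
    if plan.acceptor == "cterm":
        acceptor = bm.cterm_o1
    else:
        res = int(plan.acceptor)
        acceptor = bm.residues[res - 1].o
    if len({donor, hydrogen, acceptor}) != 3:
        return None  # degenerate plan entry (donor == acceptor role)
    return HBondRecord(donor_atom=donor, hydrogen_atom=hydrogen,
                       acceptor_atom=acceptor, delta_q=plan.delta_q)


_HELICAL = (-57.0, -47.0)
_EXTENDED = (-120.0, 130.0)


def synthesize_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Generate a validated mock ensemble from a :class:`SyntheticSpec`.

    Deterministic: the same spec (including seed) yields a bit-identical
    ensemble.
    """
    rng = np.random.default_rng(spec.seed)
    fragment = spec.fragment or spec.sequence
    energies = _draw_energies(spec, rng)
    conformers = []
    for i in range(spec.n_conformers):
        letter = chr(ord("A") + i) if i < 26 else f"Z{i}"
        if spec.phi_psi_targets is not None:
            phi_psi = spec.phi_psi_targets[i]
        else:
            base = _HELICAL if rng.random() < 0.5 else _EXTENDED
            phi_psi = [
                (base[0] + rng.uniform(-10, 10), base[1] + rng.uniform(-10, 10))
                for _ in spec.sequence
            ]
        built = _build_full(spec.sequence, phi_psi, spec.zwitterionic,
                            conformer_id=f"{fragment}-{letter}")
        conformer = built.conformer
        conformer.relative_energy = float(energies[i])

        mode_plans = (spec.mode_plan[i] if spec.mode_plan is not None
                      else _default_mode_plan(rng))
        conformer.modes = [
            _plant_mode(conformer, plan, k, rng)
            for k, plan in enumerate(mode_plans)
        ]

        hbond_plans = (spec.hbond_plan[i] if spec.hbond_plan is not None
                       else _default_hbond_plan(spec.sequence, rng))
        bonds = []
        seen = set()
        for plan in hbond_plans:
            record = _resolve_hbond(built, plan)
            if record is None:
                continue
            key = (record.donor_atom, record.hydrogen_atom, record.acceptor_atom)
            if key in seen:
                continue
            seen.add(key)
            bonds.append(record)
        conformer.hbonds = bonds
        # mild mock natural populations so delta_q derivation is exercisable
        for atom in conformer.atoms:
            base_density = {"H": 0.6, "C": 6.1, "N": 7.6, "O": 8.6}[atom.element]
            atom.natural_electron_density = float(
                base_density + rng.uniform(-0.05, 0.05))
        conformers.append(conformer)

    ensemble = Ensemble(fragment=fragment, conformers=conformers,
                        temperature=spec.temperature)
    validate_ensemble(ensemble)
    return ensemble


# ---------------------------------------------------------------------------
# mock quantum-chemistry log writer


def _fmt(v: float) -> str:
    return repr(float(v))


def write_mock_log(obj: Union[Conformer, Ensemble], path: str | Path) -> Path:
    """Emit the supported plain-text log dialect.

    For a :class:`Conformer`, ``path`` is the log file; for an
    :class:`Ensemble`, ``path`` is a directory receiving one
    ``<conformer id>.log`` per conformer.  Frequencies and activities are
    written with ``repr`` precision so the parser round-trips them
    bit-exactly.
    """
    path = Path(path)
    if isinstance(obj, Ensemble):
        path.mkdir(parents=True, exist_ok=True)
        for conformer in obj.conformers:
            write_mock_log(conformer, path / f"{conformer.id}.log")
        return path

    c = obj
    lines = [
        "bzraman mock quantum-chemistry log (dialect v1)",
        f"conformer {c.id}",
        f"natoms {c.n_atoms}",
        "geometry (angstrom)",
    ]
    for a in c.atoms:
        x, y, z = a.position
        lines.append(f" {a.element} {_fmt(x)} {_fmt(y)} {_fmt(z)}")
    if any(a.natural_electron_density is not None for a in c.atoms):
        lines.append("natural populations (e-)")
        for a in c.atoms:
            rho = a.natural_electron_density
            lines.append(f" {a.element} {a.index} {_fmt(rho if rho is not None else 0.0)}")
    if c.modes:
        lines.append("begin frequency job")
        lines.append(f"nmodes {len(c.modes)}")
        for m in c.modes:
            lines.append(f"mode {m.index}")
            lines.append(f" frequency {_fmt(m.frequency)}")
            lines.append(f" raman activity {_fmt(m.raman_activity)}")
            if m.displacements.size:
                lines.append("displacements")
                for row in m.displacements:
                    lines.append(" " + " ".join(_fmt(v) for v in row))
        lines.append("end frequency job")
    path.write_text("\n".join(lines) + "\n")
    return path
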