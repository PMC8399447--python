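"""Ensemble I/O: interchange JSON, XYZ+CSV, mock quantum-chemistry logs,
and the packaged per-conformer / ensemble-sum reference tables.

The interchange format (schema tag ``bzr-1``) is one JSON file per
ensemble: coordinates in Å, energies in kcal/mol, frequencies unscaled
harmonic cm⁻¹, charge transfer in e⁻.  A machine-readable schema ships at
``bzraman/data/bzr-1.schema.json``.

Only one quantum-chemistry log dialect is supported — the plain-text mock
dialect emitted by :func:`bzraman.synthetic.write_mock_log`.  Output from
real electronic-structure codes must be converted to the interchange format
first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .models import (
    AtomRecord,
    BackboneMap,
    Conformer,
    Ensemble,
    HBondRecord,
    NormalMode,
    ResidueBackbone,
    ValidationError,
    reference_energies,
    validate_ensemble,
)

__all__ = [
    "SCHEMA_VERSION",
    "read_ensemble",
    "write_ensemble",
    "read_xyz",
    "write_xyz",
    "read_qc_frequency_block",
    "Table1Fixture",
    "load_table1_fixture",
    "load_table2_fixture",
    "filter_by_energy_window",
]

SCHEMA_VERSION = "bzr-1"

#: Band labels used throughout the pipeline.
AMIDE_I = "amide_I"
ALPHA_COO = "alphaCOO"


# ---------------------------------------------------------------------------
# interchange JSON


def _conformer_to_dict(c: Conformer) -> dict:
    d: dict = {
        "id": c.id,
        "sequence": c.sequence,
        "relative_energy": c.relative_energy,
        "protonated_terminus": c.protonated_terminus,
        "atoms": [
            {
                "element": a.element,
                "position": list(a.position),
                **(
                    {"natural_electron_density": a.natural_electron_density}
                    if a.natural_electron_density is not None
                    else {}
                ),
            }
            for a in c.atoms
        ],
        "modes": [
            {
                "frequency": m.frequency,
                "raman_activity": m.raman_activity,
                "displacements": [list(row) for row in m.displacements],
            }
            for m in c.modes
        ],
        "hbonds": [
            {
                "donor": hb.donor_atom,
                "hydrogen": hb.hydrogen_atom,
                "acceptor": hb.acceptor_atom,
                **({"delta_q": hb.delta_q} if hb.delta_q is not None else {}),
            }
            for hb in c.hbonds
        ],
    }
    if c.backbone_map is not None:
        bm = c.backbone_map
        d["backbone_map"] = {
            "residues": [
                {"n": r.n, "ca": r.ca, "c": r.c, "o": r.o,
                 **({"cb": r.cb} if r.cb is not None else {})}
                for r in bm.residues
            ],
            "nterm_n": bm.nterm_n,
            "cterm_c": bm.cterm_c,
            "cterm_o1": bm.cterm_o1,
            "cterm_o2": bm.cterm_o2,
        }
    return d


def _require(d: dict, key: str, ctx: str):
    if key not in d:
        raise ValidationError(f"{ctx}: missing required field {key!r}")
    return d[key]


def _conformer_from_dict(d: dict) -> Conformer:
    cid = _require(d, "id", "conformer")
    ctx = f"conformer {cid!r}"
    atoms = [
        AtomRecord(
            index=i,
            element=_require(a, "element", f"{ctx} atom {i}"),
            position=np.asarray(_require(a, "position", f"{ctx} atom {i}"), float),
            natural_electron_density=a.get("natural_electron_density"),
        )
        for i, a in enumerate(d.get("atoms", []))
    ]
    modes = [
        NormalMode(
            index=i,
            frequency=float(_require(m, "frequency", f"{ctx} mode {i}")),
            raman_activity=float(_require(m, "raman_activity", f"{ctx} mode {i}")),
            displacements=np.asarray(
                _require(m, "displacements", f"{ctx} mode {i}"), float),
        )
        for i, m in enumerate(d.get("modes", []))
    ]
    hbonds = [
        HBondRecord(
            donor_atom=int(_require(h, "donor", f"{ctx} hbond {i}")),
            hydrogen_atom=int(_require(h, "hydrogen", f"{ctx} hbond {i}")),
            acceptor_atom=int(_require(h, "acceptor", f"{ctx} hbond {i}")),
            delta_q=h.get("delta_q"),
        )
        for i, h in enumerate(d.get("hbonds", []))
    ]
    backbone_map = None
    if "backbone_map" in d:
        bm = d["backbone_map"]
        backbone_map = BackboneMap(
            residues=[
                ResidueBackbone(n=r["n"], ca=r["ca"], c=r["c"], o=r["o"],
                                cb=r.get("cb"))
                for r in _require(bm, "residues", f"{ctx} backbone_map")
            ],
            nterm_n=_require(bm, "nterm_n", f"{ctx} backbone_map"),
            cterm_c=_require(bm, "cterm_c", f"{ctx} backbone_map"),
            cterm_o1=_require(bm, "cterm_o1", f"{ctx} backbone_map"),
            cterm_o2=_require(bm, "cterm_o2", f"{ctx} backbone_map"),
        )
    return Conformer(
        id=cid,
        sequence=_require(d, "sequence", ctx),
        relative_energy=float(_require(d, "relative_energy", ctx)),
        atoms=atoms,
        modes=modes,
        hbonds=hbonds,
        backbone_map=backbone_map,
        protonated_terminus=bool(d.get("protonated_terminus", False)),
    )


def write_ensemble(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as interchange JSON (schema ``bzr-1``)."""
    path = Path(path)
    doc = {
        "schema": SCHEMA_VERSION,
        "fragment": ensemble.fragment,
        "temperature": ensemble.temperature,
        "conformers": [_conformer_to_dict(c) for c in ensemble.conformers],
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")
    return path


def read_ensemble(path: str | Path, format: str = "interchange-json") -> Ensemble:
    """Read and validate a conformer ensemble.

    ``format="interchange-json"`` reads a single ``bzr-1`` JSON file.
    ``format="xyz+csv"`` reads a directory holding ``conformers.csv``
    (columns: id, sequence, relative_energy, xyz_file[, protonated])
    plus one XYZ file per conformer — geometry-only ensembles for the
    dihedral/H-bond stages.

    Relative energies are re-referenced so the minimum is exactly 0; all
    invariants are checked.
    """
    path = Path(path)
    if format == "interchange-json":
        ensemble = _read_interchange(path)
    elif format == "xyz+csv":
        ensemble = _read_xyz_csv(path)
    else:
        raise ValidationError(f"unknown ensemble format {format!r}")
    reference_energies(ensemble)
    validate_ensemble(ensemble)
    return ensemble


def _read_interchange(path: Path) -> Ensemble:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"{path}: not valid JSON ({exc})") from exc
    schema = doc.get("schema")
    if schema != SCHEMA_VERSION:
        raise ValidationError(
            f"{path}: schema field is {schema!r}, expected {SCHEMA_VERSION!r}")
    conformers = [_conformer_from_dict(c) for c in _require(doc, "conformers", str(path))]
    if not conformers:
        raise ValidationError(f"{path}: ensemble has no conformers")
    return Ensemble(
        fragment=_require(doc, "fragment", str(path)),
        conformers=conformers,
        temperature=float(doc.get("temperature", 298.0)),
    )


def _read_xyz_csv(directory: Path) -> Ensemble:
    manifest = directory / "conformers.csv"
    if not manifest.exists():
        raise ValidationError(f"{directory}: missing conformers.csv manifest")
    table = pd.read_csv(manifest)
    for col in ("id", "sequence", "relative_energy", "xyz_file"):
        if col not in table.columns:
            raise ValidationError(f"{manifest}: missing column {col!r}")
    conformers = []
    for _, row in table.iterrows():
        elements, coords = read_xyz(directory / row["xyz_file"])
        atoms = [
            AtomRecord(index=i, element=el, position=xyz)
            for i, (el, xyz) in enumerate(zip(elements, coords))
        ]
        conformers.append(
            Conformer(
                id=str(row["id"]),
                sequence=str(row["sequence"]),
                relative_energy=float(row["relative_energy"]),
                atoms=atoms,
                protonated_terminus=bool(row.get("protonated", False)),
            )
        )
    if not conformers:
        raise ValidationError(f"{manifest}: empty ensemble")
    return Ensemble(fragment=str(table["id"].iloc[0]).split("-")[0],
                    conformers=conformers)


# ---------------------------------------------------------------------------
# XYZ


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a single-frame XYZ file → (element symbols, (N,3) coordinates Å)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValidationError(f"{path}: malformed XYZ atom count line") from exc
    body = lines[2:2 + n]
    if len(body) < n:
        raise ValidationError(f"{path}: truncated XYZ ({len(body)}/{n} atoms)")
    elements, coords = [], []
    for ln in body:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.asarray(coords, float)


def write_xyz(conformer: Conformer, path: str | Path, comment: str = "") -> Path:
    path = Path(path)
    lines = [str(conformer.n_atoms), comment or conformer.id]
    for a in conformer.atoms:
        x, y, z = a.position
        lines.append(f"{a.element:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# mock quantum-chemistry log parser (single documented dialect)


def read_qc_frequency_block(path: str | Path) -> tuple[list[NormalMode], list[AtomRecord]]:
    """Parse the frequency/Raman-activity/natural-population blocks of the
    supported plain-text log dialect.

    Floats in the dialect are written with ``repr`` precision, so parsed
    frequencies and activities round-trip bit-exactly against the writer.

    Raises
    ------
    ValidationError
        If the file holds no completed frequency block, if a block is
        truncated (the message carries the line number), or if Raman
        activities are absent (IR-only jobs are unsupported).
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    def err(lineno: int, msg: str):
        raise ValidationError(f"{path}:{lineno + 1}: {msg}")

    atoms: list[AtomRecord] = []
    modes: list[NormalMode] = []
    n_atoms = None
    i = 0
    saw_freq_block = False
    saw_freq_end = False
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("natoms"):
            n_atoms = int(line.split()[1])
        elif line == "geometry (angstrom)":
            if n_atoms is None:
                err(i, "geometry block before natoms declaration")
            if i + n_atoms >= len(lines):
                err(len(lines) - 1, "truncated geometry block")
            for k in range(n_atoms):
                parts = lines[i + 1 + k].split()
                atoms.append(AtomRecord(index=k, element=parts[0],
                                        position=[float(x) for x in parts[1:4]]))
            i += n_atoms
        elif line == "natural populations (e-)":
            if n_atoms is None or len(atoms) != n_atoms:
                err(i, "natural population block before geometry")
            for k in range(n_atoms):
                if i + 1 + k >= len(lines):
                    err(len(lines) - 1, "truncated natural population block")
                parts = lines[i + 1 + k].split()
                atoms[int(parts[1])].natural_electron_density = float(parts[2])
            i += n_atoms
        elif line == "begin frequency job":
            saw_freq_block = True
        elif line.startswith("mode "):
            if not saw_freq_block:
                err(i, "mode entry outside a frequency job")
            idx = int(line.split()[1])
            if i + 2 >= len(lines):
                err(i, "truncated mode block")
            freq_line = lines[i + 1].strip()
            act_line = lines[i + 2].strip()
            if not freq_line.startswith("frequency"):
                err(i + 1, f"expected frequency line, got {freq_line!r}")
            if not act_line.startswith("raman activity"):
                err(i + 2, "missing Raman activity (IR-only jobs unsupported)")
            frequency = float(freq_line.split()[-1])
            activity = float(act_line.split()[-1])
            disp = np.zeros((n_atoms or 0, 3))
            j = i + 3
            if j < len(lines) and lines[j].strip() == "displacements":
                if n_atoms is None:
                    err(j, "displacement block before natoms declaration")
                if j + n_atoms >= len(lines):
                    err(len(lines) - 1, "truncated displacement block")
                disp = np.array(
                    [[float(x) for x in lines[j + 1 + k].split()]
                     for k in range(n_atoms)]
                )
                j += 1 + n_atoms
            modes.append(NormalMode(index=idx, frequency=frequency,
                                    raman_activity=activity, displacements=disp))
            i = j - 1
        elif line == "end frequency job":
            saw_freq_end = True
        i += 1

    if not saw_freq_block or not modes:
        raise ValidationError(f"{path}: no frequency block found")
    if not saw_freq_end:
        raise ValidationError(
            f"{path}:{len(lines)}: frequency job not terminated (truncated log?)")
    return modes, atoms


# ---------------------------------------------------------------------------
# packaged reference tables


@dataclass
class Table1Fixture:
    """Per-conformer reference table for the 11 peptide fragments.

    Sixty-six tabulated rows (6 per fragment).  Three fragments — EG, EGED
    and EGEDEA — each have a seventh, protonated energetic minimum in the
    source's appendix whose row was never tabulated; those geometries are
    documented as absent (``untabulated_protonated``) rather than invented.

    Band columns are stored as printed: the lowest-energy (``-A``) row of
    each fragment carries the absolute scaled position in cm⁻¹ and the other
    rows carry signed shifts relative to it.  Absolute positions are
    resolved on load into ``amide_I_position`` / ``acoo_position``.
    Populations keep the printed three-significant-figure rounding.
    """

    df: pd.DataFrame
    untabulated_protonated: tuple[str, ...] = ("EG", "EGED", "EGEDEA")

    @property
    def fragments(self) -> list[str]:
        return list(dict.fromkeys(self.df["fragment"]))

    def rows(self, fragment: str) -> pd.DataFrame:
        sub = self.df[self.df["fragment"] == fragment]
        if sub.empty:
            raise KeyError(f"unknown fragment {fragment!r}")
        return sub

    def row(self, structure: str) -> pd.Series:
        return self.df.loc[structure]

    def energies(self, fragment: str) -> np.ndarray:
        return self.rows(fragment)["delta_e_kcal"].to_numpy()

    def weights(self, fragment: str) -> np.ndarray:
        """Populations N_i as printed (3 significant figures)."""
        return self.rows(fragment)["ni"].to_numpy()

    def positions(self, fragment: str, band: str) -> np.ndarray:
        """Absolute scaled band positions, cm⁻¹ (shifts already resolved)."""
        col = {AMIDE_I: "amide_I_position", ALPHA_COO: "acoo_position"}[band]
        return self.rows(fragment)[col].to_numpy()

    def weighted_qt(self, fragment: str) -> np.ndarray:
        """Per-conformer total charge transfer, already Boltzmann-weighted
        (N_i · qT_raw), e⁻ — as printed."""
        return self.rows(fragment)["qt_weighted_e"].to_numpy()

    def hb_counts(self, fragment: str) -> np.ndarray:
        return self.rows(fragment)["hb_count"].to_numpy()

    def to_ensemble(self, fragment: str) -> Ensemble:
        """Geometry-less ensemble carrying the fragment's ΔE ladder, for the
        population / aggregation stages."""
        conformers = [
            Conformer(id=str(s), sequence=fragment, relative_energy=float(r["delta_e_kcal"]))
            for s, r in self.rows(fragment).iterrows()
        ]
        return Ensemble(fragment=fragment, conformers=conformers)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("bzraman").joinpath("data", name)))


def load_table1_fixture() -> Table1Fixture:
    """Load the packaged per-conformer table and resolve band shifts to
    absolute positions."""
    df = pd.read_csv(_data_path("table1.csv"), index_col="structure")
    for raw, resolved in (("amide_I_band", "amide_I_position"),
                          ("acoo_band", "acoo_position")):
        out = np.empty(len(df), dtype=float)
        for frag, sub in df.groupby("fragment", sort=False):
            base = float(sub[raw].iloc[0])
            vals = sub[raw].to_numpy(dtype=float)
            resolved_vals = np.concatenate([[base], base + vals[1:]])
            out[df.index.get_indexer(sub.index)] = resolved_vals
        df[resolved] = out
    return Table1Fixture(df=df)


def load_table2_fixture() -> pd.DataFrame:
    """Ensemble-level reference sums (q_B_T, band Boltzmann sums, and the
    experimental band positions where measured), indexed by fragment."""
    return pd.read_csv(_data_path("table2.csv"), index_col="fragment")


# ---------------------------------------------------------------------------
# energy window


def filter_by_energy_window(ensemble: Ensemble, max_delta_e: float) -> Ensemble:
    """Retain conformers with relative energy ≤ ``max_delta_e`` kcal/mol.

    The default analysis window of 50 kcal/mol keeps every tabulated
    conformer (the largest tabulated ΔE is 47.14 kcal/mol); tighter windows
    are useful for quick population screens.  Order is preserved.
    """
    if max_delta_e <= 0:
        raise ValidationError("filter_by_energy_window: max_delta_e must be > 0")
    kept = [c for c in ensemble.conformers if c.relative_energy <= max_delta_e]
    if not kept:
        raise ValidationError(
            f"filter_by_energy_window: window {max_delta_e} kcal/mol removes "
            f"every conformer of {ensemble.fragment!r}")
    return Ensemble(fragment=ensemble.fragment, conformers=kept,
                    temperature=ensemble.temperature)
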