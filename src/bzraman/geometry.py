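"""Backbone torsions, Ramachandran tabulation, and Boltzmann-weighted
circular angle summaries.

φᵢ is the C(i−1)–N(i)–Cα(i)–C(i) torsion and ψᵢ the N(i)–Cα(i)–C(i)–N(i+1)
torsion, IUPAC sign convention, reported in (−180°, 180°].  φ is undefined
at the N-terminal residue and ψ at the C-terminal residue.

Population-weighted angle summaries use the weighted *circular* mean
(angles mapped to unit vectors, vectors averaged, atan2 back): an
arithmetic mean of angles breaks at the ±180° seam — two equally weighted
conformers at 170° and −170° average to 180°, not 0°.  The arithmetic mean
remains available behind a flag for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .boltzmann import WeightedEnsemble
from .models import Conformer, ValidationError

__all__ = [
    "dihedral",
    "phi_psi",
    "DihedralSet",
    "RamachandranPoint",
    "RamachandranSummary",
    "ramachandran_summary",
    "classify_region",
    "write_ramachandran_csv",
    "plot_ramachandran",
    "write_pdb",
]

_COLLINEAR_TOL = 1e-10


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1–p2–p3–p4 in degrees, range (−180, 180].

    Uses the atan2 formulation (numerically stable near 0° and 180°).
    Raises if three consecutive points are collinear, where the torsion is
    undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.dot(n1, n1) < _COLLINEAR_TOL or np.dot(n2, n2) < _COLLINEAR_TOL or b2n == 0:
        raise ValidationError("dihedral undefined: collinear points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    angle = math.degrees(math.atan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return 180.0 if angle <= -180.0 + 1e-12 else angle


@dataclass
class DihedralSet:
    """Per-residue (φ, ψ) in degrees; ``None`` marks the undefined terminal
    entries.  Residue indices are 1-based from the αNH₃⁺ terminus."""

    residues: list[int]
    phi: list[Optional[float]]
    psi: list[Optional[float]]


def phi_psi(conformer: Conformer) -> DihedralSet:
    """Backbone φ/ψ for every residue of a conformer with a backbone map."""
    bm = conformer.backbone_map
    if bm is None:
        raise ValidationError(f"{conformer.id}: phi/psi requires a backbone_map")
    if not conformer.atoms:
        raise ValidationError(f"{conformer.id}: no coordinates")
    coords = conformer.coordinates()

    def pos(idx: Optional[int], residue: int, name: str) -> np.ndarray:
        if idx is None or not (0 <= idx < len(coords)):
            raise ValidationError(
                f"{conformer.id}: residue {residue} missing backbone atom {name}")
        return coords[idx]

    n_res = bm.n_residues
    phis: list[Optional[float]] = []
    psis: list[Optional[float]] = []
    for i, res in enumerate(bm.residues, start=1):
        if i == 1:
            phis.append(None)
        else:
            prev = bm.residues[i - 2]
            phis.append(dihedral(pos(prev.c, i - 1, "C"), pos(res.n, i, "N"),
                                 pos(res.ca, i, "CA"), pos(res.c, i, "C")))
        if i == n_res:
            psis.append(None)
        else:
            nxt = bm.residues[i]
            psis.append(dihedral(pos(res.n, i, "N"), pos(res.ca, i, "CA"),
                                 pos(res.c, i, "C"), pos(nxt.n, i + 1, "N")))
    return DihedralSet(residues=list(range(1, n_res + 1)), phi=phis, psi=psis)


@dataclass
class RamachandranPoint:
    conformer_id: str
    residue: int
    phi: Optional[float]
    psi: Optional[float]
    weight: float


@dataclass
class RamachandranSummary:
    """All per-conformer (φ, ψ) points with their populations, plus the
    population-weighted circular-mean angles per residue (``None`` where an
    antipodal tie leaves the mean undefined, or at termini)."""

    fragment: str
    points: list[RamachandranPoint]
    residues: list[int]
    weighted_phi: list[Optional[float]]
    weighted_psi: list[Optional[float]]


def _circular_mean(angles: Sequence[float], weights: Sequence[float]) -> Optional[float]:
    a = np.radians(np.asarray(angles, float))
    w = np.asarray(weights, float)
    w = w / w.sum()
    x = float(np.dot(w, np.cos(a)))
    y = float(np.dot(w, np.sin(a)))
    if math.hypot(x, y) < 1e-9:  # antipodal tie: zero resultant
        return None
    mean = math.degrees(math.atan2(y, x))
    return 180.0 if mean <= -180.0 + 1e-12 else mean


def ramachandran_summary(
    weighted: WeightedEnsemble,
    arithmetic: bool = False,
) -> RamachandranSummary:
    """Boltzmann-weighted Ramachandran summary of an ensemble.

    All conformers must yield dihedral sets over the same residues.  With
    ``arithmetic=True`` the (seam-unsafe) plain weighted mean is used
    instead of the circular mean, for comparison against tabulations that
    averaged raw angle values.
    """
    sets = [phi_psi(c) for c in weighted.ensemble.conformers]
    residues = sets[0].residues
    for c, s in zip(weighted.ensemble.conformers, sets):
        if s.residues != residues:
            raise ValidationError(
                f"{c.id}: residue range differs from the rest of the ensemble")
    points = [
        RamachandranPoint(conformer_id=c.id, residue=r,
                          phi=s.phi[j], psi=s.psi[j], weight=float(w))
        for c, s, w in zip(weighted.ensemble.conformers, sets, weighted.weights)
        for j, r in enumerate(residues)
    ]
    weighted_phi: list[Optional[float]] = []
    weighted_psi: list[Optional[float]] = []
    for j in range(len(residues)):
        for out, get in ((weighted_phi, lambda s: s.phi[j]),
                         (weighted_psi, lambda s: s.psi[j])):
            vals = [get(s) for s in sets]
            if any(v is None for v in vals):
                out.append(None)
                continue
            if arithmetic:
                w = np.asarray(weighted.weights, float)
                out.append(float(np.dot(w, vals) / w.sum()))
            else:
                out.append(_circular_mean(vals, weighted.weights))
    return RamachandranSummary(
        fragment=weighted.ensemble.fragment,
        points=points,
        residues=residues,
        weighted_phi=weighted_phi,
        weighted_psi=weighted_psi,
    )


def classify_region(phi: float, psi: float, residue_letter: str = "") -> str:
    """Label a (φ, ψ) point for reporting (never used for filtering).

    ``alpha`` marks the right-handed helical region (φ ∈ (−90, −30),
    ψ ∈ (−77, −17)); ``restricted`` marks the sparsely populated
    (+120°, −120°) quadrant, from which glycine is exempt (no Cβ, hence a
    flexible backbone); everything else is ``other``.
    """
    if -90 < phi < -30 and -77 < psi < -17:
        return "alpha"
    if residue_letter != "G" and 60 <= phi <= 180 and -180 <= psi <= -60:
        return "restricted"
    return "other"


def write_ramachandran_csv(summary: RamachandranSummary, path: str | Path) -> Path:
    lines = ["fragment,conformer,residue,phi_deg,psi_deg,weight"]
    fmt = lambda v: "" if v is None else f"{v:.4f}"
    for p in summary.points:
        lines.append(f"{summary.fragment},{p.conformer_id},{p.residue},"
                     f"{fmt(p.phi)},{fmt(p.psi)},{p.weight:.6g}")
    for r, phi, psi in zip(summary.residues, summary.weighted_phi, summary.weighted_psi):
        lines.append(f"{summary.fragment},boltzmann_sum,{r},{fmt(phi)},{fmt(psi)},")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def plot_ramachandran(summary: RamachandranSummary, path: str | Path) -> Path:
    """Scatter of all conformer (φ, ψ) points (marker size ∝ population)
    with the Boltzmann-weighted means overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.2, 4.2))
    pts = [(p.phi, p.psi, p.weight) for p in summary.points
           if p.phi is not None and p.psi is not None]
    if pts:
        phi, psi, w = zip(*pts)
        ax.scatter(phi, psi, s=8 + 120 * np.asarray(w), alpha=0.5,
                   color="tab:blue", label="conformers")
    means = [(f, s) for f, s in zip(summary.weighted_phi, summary.weighted_psi)
             if f is not None and s is not None]
    if means:
        mphi, mpsi = zip(*means)
        ax.scatter(mphi, mpsi, marker="x", color="tab:red", s=50,
                   label="Boltzmann sum")
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    ax.axhline(0, lw=0.5, color="0.7")
    ax.axvline(0, lw=0.5, color="0.7")
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel(r"$\psi$ (deg)")
    ax.set_title(summary.fragment)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_pdb(conformer: Conformer, path: str | Path) -> Path:
    """Minimal PDB export (ATOM records, single chain) for visual
    inspection of built or loaded geometries."""
    lines = []
    for a in conformer.atoms:
        x, y, z = a.position
        name = a.element[:2].rjust(2)
        lines.append(
            f"ATOM  {a.index + 1:5d} {name:>4s} UNK A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element:>2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
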