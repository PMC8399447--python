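"""Band assignment: which normal mode is the amide I ν(C=O) of the first
peptide bond, and which is the C-terminal αCOO⁻ ν(C=O).

Assignment convention
---------------------
"Amide I" here always means the carbonyl stretch of the *first* peptide
bond counted from the αNH₃⁺ terminus (the bond physically furthest from the
carboxylate terminus).  The αCOO⁻ band targets the antisymmetric-stretch-
dominated carboxylate mode, so both C–O pairs of the terminal carboxylate
are projected.

Among the modes whose scaled frequency falls in the search window (default
1550–1750 cm⁻¹, wide enough for the large outlier shifts seen in strained
conformers), the assigned mode is the one maximizing the bond-stretch
amplitude: the relative displacement of each target C/O pair projected on
its C→O axis, magnitudes summed over the pair(s).  A localization score —
the fraction of the squared displacement norm residing on the target C and
O atoms — flags delocalized or coupled modes (score < 0.2 attaches a
warning but the assignment is still returned; coupled amide modes are a
known limit of the uncoupled-oscillator picture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .boltzmann import WeightedEnsemble, weighted_mean
from .models import Conformer, ValidationError
from .spectra import BroadeningConfig

__all__ = [
    "AMIDE_I",
    "ALPHA_COO",
    "DEFAULT_BAND_WINDOW",
    "BandAssignment",
    "BandReport",
    "assign_band",
    "band_report",
    "band_report_from_positions",
    "round_half_away",
    "write_band_report_csv",
]

AMIDE_I = "amide_I"
ALPHA_COO = "alphaCOO"

DEFAULT_BAND_WINDOW = (1550.0, 1750.0)
LOCALIZATION_WARNING_THRESHOLD = 0.2


@dataclass
class BandAssignment:
    band_label: str
    mode_index: int
    position: float  # scaled cm-1
    localization_score: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class BandReport:
    """Per-conformer positions and the Boltzmann-summed position of one
    band across a fragment's ensemble.  The sum is the renormalized
    population-weighted mean, rounded to the nearest integer cm⁻¹ (ties
    away from zero) — rounding is applied only to the final sum."""

    fragment: str
    band_label: str
    positions: dict[str, float]
    boltzmann_sum: int
    experimental_position: Optional[float] = None


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (so 0.5 → 1, −0.5 → −1);
    banker's rounding would bias integer band positions."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _target_pairs(conformer: Conformer, band_label: str) -> list[tuple[int, int]]:
    bm = conformer.backbone_map
    if bm is None:
        raise ValidationError(
            f"{conformer.id}: band assignment requires a backbone_map")
    if band_label == AMIDE_I:
        if bm.n_residues < 2:
            raise ValidationError(
                f"{conformer.id}: amide I undefined for a single residue")
        first = bm.residues[0]
        return [(first.c, first.o)]
    if band_label == ALPHA_COO:
        return [(bm.cterm_c, bm.cterm_o1), (bm.cterm_c, bm.cterm_o2)]
    raise ValidationError(f"unknown band label {band_label!r}")


def _stretch_projection(conformer: Conformer, mode, pairs) -> tuple[float, float]:
    """(summed |C→O stretch amplitude|, localization score) for one mode."""
    coords = conformer.coordinates()
    disp = mode.displacements
    total_norm_sq = float(np.sum(disp**2))
    if total_norm_sq == 0:
        return 0.0, 0.0
    amplitude = 0.0
    target_atoms: set[int] = set()
    for c_idx, o_idx in pairs:
        axis = coords[o_idx] - coords[c_idx]
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValidationError(
                f"{conformer.id}: degenerate C=O bond between atoms "
                f"{c_idx} and {o_idx}")
        axis = axis / norm
        rel = disp[o_idx] - disp[c_idx]
        amplitude += abs(float(np.dot(rel, axis)))
        target_atoms.update((c_idx, o_idx))
    on_target = float(sum(np.sum(disp[a] ** 2) for a in target_atoms))
    score = min(1.0, on_target / total_norm_sq)
    return amplitude, score


def assign_band(
    conformer: Conformer,
    band_label: str,
    config: BroadeningConfig | None = None,
    window: tuple[float, float] = DEFAULT_BAND_WINDOW,
) -> BandAssignment:
    """Pick the normal mode carrying the requested C=O stretch.

    Raises ``ValidationError("no candidate band ...")`` when no mode's
    scaled frequency falls inside the window.
    """
    config = config or BroadeningConfig()
    pairs = _target_pairs(conformer, band_label)
    lo, hi = window
    best = None
    for mode in conformer.modes:
        position = mode.frequency * config.scaling_factor
        if not (lo <= position <= hi):
            continue
        amplitude, score = _stretch_projection(conformer, mode, pairs)
        if best is None or amplitude > best[0]:
            best = (amplitude, mode, position, score)
    if best is None:
        raise ValidationError(
            f"no candidate band: {conformer.id} has no mode with scaled "
            f"frequency in [{lo}, {hi}] cm-1 for {band_label}")
    amplitude, mode, position, score = best
    warnings = []
    if score < LOCALIZATION_WARNING_THRESHOLD:
        warnings.append(
            f"localization score {score:.3f} < {LOCALIZATION_WARNING_THRESHOLD}: "
            f"mode {mode.index} is delocalized/coupled")
    if band_label == ALPHA_COO and conformer.protonated_terminus:
        warnings.append(
            "protonated terminus: assigned band is the neutral C-terminal "
            "C=O stretch, not a carboxylate mode")
    return BandAssignment(
        band_label=band_label,
        mode_index=mode.index,
        position=position,
        localization_score=score,
        warnings=warnings,
    )


def band_report(
    weighted: WeightedEnsemble,
    band_label: str,
    config: BroadeningConfig | None = None,
    window: tuple[float, float] = DEFAULT_BAND_WINDOW,
    experimental_position: Optional[float] = None,
) -> BandReport:
    """Assign the band in every conformer and Boltzmann-sum the positions.

    Assignment failures are collected and re-raised together, naming every
    failing conformer.
    """
    positions: dict[str, float] = {}
    failures: list[str] = []
    for conformer in weighted.ensemble.conformers:
        try:
            positions[conformer.id] = assign_band(
                conformer, band_label, config, window).position
        except ValidationError as exc:
            failures.append(f"{conformer.id}: {exc}")
    if failures:
        raise ValidationError(
            f"band_report({band_label}): assignment failed for "
            f"{len(failures)} conformer(s):\n  " + "\n  ".join(failures))
    return band_report_from_positions(
        weighted, band_label, positions, experimental_position)


def band_report_from_positions(
    weighted: WeightedEnsemble,
    band_label: str,
    positions: Mapping[str, float],
    experimental_position: Optional[float] = None,
) -> BandReport:
    """Build a report from externally supplied per-conformer positions
    (e.g. a published per-conformer table), bypassing mode assignment."""
    ids = weighted.conformer_ids
    missing = [i for i in ids if i not in positions]
    if missing:
        raise ValidationError(f"band_report: missing positions for {missing}")
    values = [positions[i] for i in ids]
    mean = weighted_mean(values, weighted.weights, renormalize=True)
    return BandReport(
        fragment=weighted.ensemble.fragment,
        band_label=band_label,
        positions={i: float(positions[i]) for i in ids},
        boltzmann_sum=round_half_away(mean),
        experimental_position=experimental_position,
    )


def write_band_report_csv(reports: Sequence[BandReport], path: str | Path) -> Path:
    """Flat CSV mirror: fragment, band, conformer, position, boltzmann sum,
    experimental position."""
    lines = ["fragment,band,conformer,position_cm,boltzmann_sum_cm,experimental_cm"]
    for r in reports:
        exp = "" if r.experimental_position is None else f"{r.experimental_position:g}"
        for cid, pos in r.positions.items():
            lines.append(
                f"{r.fragment},{r.band_label},{cid},{pos:g},{r.boltzmann_sum},{exp}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
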