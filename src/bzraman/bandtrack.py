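"""Cross-fragment band-position series and blue/red-shift trend
classification.

As the peptide fragment grows from dipeptide (n = 2) to hexapeptide
(n = 6), the Boltzmann-summed amide I and αCOO⁻ ν(C=O) positions shift in
ways that report on side-chain polarity and intramolecular hydrogen
bonding.  A series is an ordered list of fragments with their band
positions and ensemble charge-transfer totals; a trend report gives the
signed step between consecutive fragments and an overall classification:

* ``blue_shift`` — every step ≥ +tolerance (toward higher wavenumber),
* ``red_shift``  — every step ≤ −tolerance,
* ``flat``       — every |step| < tolerance,
* ``mixed``      — anything else.

The default tolerance of 2 cm⁻¹ sits just above the integer-rounding
granularity of reported band positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .assignment import ALPHA_COO, AMIDE_I, BandReport
from .hbonds import ChargeTransferReport
from .models import ValidationError

__all__ = [
    "SeriesEntry",
    "FragmentSeries",
    "TrendReport",
    "build_series",
    "classify_trend",
    "write_series_csv",
    "plot_series",
]

#: The two linear growth paths through the fragment family.
ED_FAMILY = ("ED", "EDE", "EDEA", "GEDEA", "EGEDEA")
EG_FAMILY = ("EG", "EGE", "EGED", "EGEDE", "EGEDEA")


@dataclass
class SeriesEntry:
    fragment: str
    n_residues: int
    amide_I: float
    alphaCOO: float
    q_bt: float
    amide_I_exp: Optional[float] = None
    alphaCOO_exp: Optional[float] = None

    def position(self, band_label: str) -> float:
        if band_label == AMIDE_I:
            return self.amide_I
        if band_label == ALPHA_COO:
            return self.alphaCOO
        raise ValidationError(f"unknown band label {band_label!r}")


@dataclass
class FragmentSeries:
    name: str
    entries: list[SeriesEntry]

    def positions(self, band_label: str) -> np.ndarray:
        return np.array([e.position(band_label) for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TrendReport:
    series_name: str
    band_label: str
    steps: list[float]           # signed, later minus earlier, cm-1
    classification: str          # blue_shift | red_shift | flat | mixed
    tolerance: float


def build_series(
    band_reports: Mapping[str, Mapping[str, BandReport]],
    charge_reports: Mapping[str, ChargeTransferReport],
    order: Sequence[str],
    name: str = "series",
) -> FragmentSeries:
    """Assemble an ordered series from per-fragment reports.

    ``band_reports[fragment]`` maps band label → :class:`BandReport`;
    ``charge_reports[fragment]`` supplies q_B_T.  Every fragment named in
    ``order`` must have all three reports.
    """
    entries = []
    for frag in order:
        if frag not in band_reports or frag not in charge_reports:
            raise ValidationError(f"build_series: missing reports for {frag!r}")
        bands = band_reports[frag]
        for label in (AMIDE_I, ALPHA_COO):
            if label not in bands:
                raise ValidationError(
                    f"build_series: fragment {frag!r} missing {label} report")
        am, ac = bands[AMIDE_I], bands[ALPHA_COO]
        entries.append(SeriesEntry(
            fragment=frag,
            n_residues=len(frag),
            amide_I=float(am.boltzmann_sum),
            alphaCOO=float(ac.boltzmann_sum),
            q_bt=float(charge_reports[frag].q_bt),
            amide_I_exp=am.experimental_position,
            alphaCOO_exp=ac.experimental_position,
        ))
    return FragmentSeries(name=name, entries=entries)


def classify_trend(
    series: FragmentSeries,
    band_label: str,
    tolerance: float = 2.0,
) -> TrendReport:
    """Classify the step pattern of one band along the series."""
    if len(series) < 2:
        raise ValidationError("classify_trend: series must have >= 2 fragments")
    pos = series.positions(band_label)
    steps = np.diff(pos)
    if np.all(steps >= tolerance):
        cls = "blue_shift"
    elif np.all(steps <= -tolerance):
        cls = "red_shift"
    elif np.all(np.abs(steps) < tolerance):
        cls = "flat"
    else:
        cls = "mixed"
    return TrendReport(series_name=series.name, band_label=band_label,
                       steps=[float(s) for s in steps], classification=cls,
                       tolerance=tolerance)


def write_series_csv(series: FragmentSeries, path: str | Path,
                     trends: Sequence[TrendReport] = ()) -> Path:
    lines = ["fragment,n_residues,amide_I_cm,alphaCOO_cm,q_bt_e,"
             "amide_I_exp_cm,alphaCOO_exp_cm"]
    fmt = lambda v: "" if v is None else f"{v:g}"
    for e in series.entries:
        lines.append(f"{e.fragment},{e.n_residues},{e.amide_I:g},{e.alphaCOO:g},"
                     f"{e.q_bt:g},{fmt(e.amide_I_exp)},{fmt(e.alphaCOO_exp)}")
    for t in trends:
        steps = ";".join(f"{s:+g}" for s in t.steps)
        lines.append(f"# trend {t.series_name} {t.band_label}: "
                     f"{t.classification} (steps {steps}, tol {t.tolerance:g})")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def plot_series(series: FragmentSeries, path: str | Path) -> Path:
    """Band position vs fragment length for both bands, with q_B_T on a
    twin axis."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 3.4))
    x = np.arange(len(series))
    labels = [e.fragment for e in series.entries]
    ax.plot(x, series.positions(AMIDE_I), "o-", color="tab:blue",
            label="amide I")
    ax.plot(x, series.positions(ALPHA_COO), "s-", color="tab:green",
            label=r"$\alpha$COO$^-$")
    ax.set_xticks(x, labels, rotation=30, fontsize=8)
    ax.set_ylabel(r"band position (cm$^{-1}$)")
    ax2 = ax.twinx()
    ax2.plot(x, [e.q_bt for e in series.entries], "^--", color="tab:red",
             alpha=0.6, label=r"$q_{B_T}$")
    ax2.set_ylabel(r"$q_{B_T}$ (e$^-$)", color="tab:red")
    ax.legend(frameon=False, fontsize=8, loc="upper left")
    ax.set_title(series.name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
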