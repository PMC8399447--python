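"""Pipeline configuration and stage wiring shared by the CLI, the test
suite, and the reproduction script.

Two input routes exist:

* the **fixture route** — the packaged per-conformer table supplies ΔE
  ladders, printed populations, resolved band positions and weighted
  charge-transfer values, and the pipeline aggregates them into ensemble
  sums, series and trend classifications (no geometry, so no spectra or
  Ramachandran stages);
* the **ensemble route** — interchange JSON files or a synthetic spec
  supply full conformers, and every stage runs: populations → broadened
  spectra → band assignment → charge transfer → Ramachandran → reports.

Every run writes a manifest (config, package version, input hashes, seed)
sufficient to reproduce it; CSV outputs are byte-stable for a fixed
config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .assignment import (
    ALPHA_COO,
    AMIDE_I,
    BandReport,
    band_report,
    band_report_from_positions,
    write_band_report_csv,
)
from .bandtrack import (
    ED_FAMILY,
    EG_FAMILY,
    build_series,
    classify_trend,
    write_series_csv,
)
from .boltzmann import WeightedEnsemble, boltzmann_weights, weigh_ensemble
from .ensemble_io import (
    Table1Fixture,
    filter_by_energy_window,
    load_table1_fixture,
    load_table2_fixture,
    read_ensemble,
)
from .geometry import ramachandran_summary, write_ramachandran_csv
from .hbonds import (
    ChargeTransferReport,
    charge_transfer_from_weighted_qt,
    charge_transfer_report,
    write_charge_transfer_csv,
)
from .models import Ensemble, ValidationError
from .spectra import BroadeningConfig, ensemble_spectrum, write_spectrum_csv
from .synthetic import SyntheticSpec, synthesize_ensemble

__all__ = [
    "PipelineConfig",
    "FragmentResult",
    "fixture_fragment_result",
    "run_fixture_pipeline",
    "run_ensemble_pipeline",
    "load_synthetic_spec",
]


@dataclass
class PipelineConfig:
    """All tunables in one place.  Defaults match the reference study
    conditions where it states them: T = 298 K, frequency scaling 0.97,
    0–50 kcal/mol energy window."""

    temperature: float = 298.0
    scaling_factor: float = 0.97
    fwhm: float = 10.0
    energy_window: float = 50.0
    band_window: tuple[float, float] = (1550.0, 1750.0)
    grid_min: float = 400.0
    grid_max: float = 4000.0
    grid_step: float = 1.0
    trend_tolerance: float = 2.0
    ed_family: tuple[str, ...] = ED_FAMILY
    eg_family: tuple[str, ...] = EG_FAMILY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError(
                f"config: temperature must be > 0, got {self.temperature}")
        if self.energy_window <= 0:
            raise ValidationError("config: energy_window must be > 0")
        self.band_window = tuple(self.band_window)  # type: ignore[assignment]
        # delegate broadening checks
        self.broadening()

    def broadening(self) -> BroadeningConfig:
        return BroadeningConfig(
            scaling_factor=self.scaling_factor, fwhm=self.fwhm,
            grid_min=self.grid_min, grid_max=self.grid_max,
            grid_step=self.grid_step)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_window"] = list(self.band_window)
        d["ed_family"] = list(self.ed_family)
        d["eg_family"] = list(self.eg_family)
        return d


@dataclass
class FragmentResult:
    fragment: str
    weights: np.ndarray
    band_reports: dict[str, BandReport]
    charge_report: ChargeTransferReport


# ---------------------------------------------------------------------------
# fixture route


def fixture_fragment_result(
    fixture: Table1Fixture,
    fragment: str,
    config: PipelineConfig | None = None,
    table2=None,
    use_printed_weights: bool = True,
) -> FragmentResult:
    """Aggregate one fragment of the packaged table into ensemble sums.

    ``use_printed_weights=True`` aggregates with the populations as
    printed (three significant figures); ``False`` recomputes them from
    the ΔE column at the configured temperature.
    """
    config = config or PipelineConfig()
    ensemble = fixture.to_ensemble(fragment)
    ensemble = filter_by_energy_window(ensemble, config.energy_window)
    if use_printed_weights:
        weighted = WeightedEnsemble.from_weights(
            ensemble, fixture.weights(fragment), config.temperature)
    else:
        weighted = weigh_ensemble(ensemble, config.temperature)

    exp_amide = exp_acoo = None
    if table2 is not None and fragment in table2.index:
        row = table2.loc[fragment]
        exp_amide = None if np.isnan(row["amide_I_exp"]) else float(row["amide_I_exp"])
        exp_acoo = None if np.isnan(row["acoo_exp"]) else float(row["acoo_exp"])

    ids = weighted.conformer_ids
    reports = {
        AMIDE_I: band_report_from_positions(
            weighted, AMIDE_I,
            dict(zip(ids, fixture.positions(fragment, AMIDE_I))),
            experimental_position=exp_amide),
        ALPHA_COO: band_report_from_positions(
            weighted, ALPHA_COO,
            dict(zip(ids, fixture.positions(fragment, ALPHA_COO))),
            experimental_position=exp_acoo),
    }
    charge = charge_transfer_from_weighted_qt(
        fragment, ids, fixture.weighted_qt(fragment),
        fixture.hb_counts(fragment))
    return FragmentResult(fragment=fragment, weights=weighted.weights,
                          band_reports=reports, charge_report=charge)


def _write_manifest(outdir: Path, config: PipelineConfig, inputs: dict) -> Path:
    manifest = {
        "package": "bzraman",
        "version": __version__,
        "config": config.to_dict(),
        "inputs": inputs,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_fixture_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    fragments: Optional[Sequence[str]] = None,
) -> dict[str, FragmentResult]:
    """Fixture route over all (or selected) fragments: weights, band sums,
    charge transfer, both fragment-family series and trend reports."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture = load_table1_fixture()
    table2 = load_table2_fixture()
    fragments = list(fragments) if fragments else fixture.fragments

    results = {
        frag: fixture_fragment_result(fixture, frag, config, table2)
        for frag in fragments
    }

    # weights: printed vs recomputed from the energy ladder
    lines = ["structure,fragment,delta_e_kcal,ni_printed,ni_recomputed"]
    for frag in fragments:
        energies = fixture.energies(frag)
        printed = fixture.weights(frag)
        recomputed = boltzmann_weights(energies, config.temperature)
        for sid, de, p, r in zip(fixture.rows(frag).index, energies,
                                 printed, recomputed):
            lines.append(f"{sid},{frag},{de:g},{p:.3e},{r:.6e}")
    (outdir / "weights.csv").write_text("\n".join(lines) + "\n")

    write_band_report_csv(
        [r.band_reports[b] for r in results.values() for b in (AMIDE_I, ALPHA_COO)],
        outdir / "band_reports.csv")
    write_charge_transfer_csv(
        [r.charge_report for r in results.values()],
        outdir / "charge_transfer.csv")

    for name, order in (("ED_family", config.ed_family),
                        ("EG_family", config.eg_family)):
        if not all(f in results for f in order):
            continue
        series = build_series(
            {f: results[f].band_reports for f in order},
            {f: results[f].charge_report for f in order},
            order, name=name)
        trends = [classify_trend(series, b, config.trend_tolerance)
                  for b in (AMIDE_I, ALPHA_COO)]
        write_series_csv(series, outdir / f"series_{name}.csv", trends)

    _write_manifest(outdir, config, {"fixture": "table1", "fragments": fragments})
    return results


# ---------------------------------------------------------------------------
# ensemble route


def run_ensemble_pipeline(
    config: PipelineConfig,
    ensemble: Ensemble,
    outdir: str | Path,
    input_path: Optional[Path] = None,
) -> FragmentResult:
    """Full-computation route for one ensemble: populations, Boltzmann-
    summed spectrum, band assignment, charge transfer, Ramachandran."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ensemble = filter_by_energy_window(ensemble, config.energy_window)
    weighted = weigh_ensemble(ensemble, config.temperature)
    broadening = config.broadening()

    lines = ["conformer,delta_e_kcal,ni"]
    for c, w in zip(ensemble.conformers, weighted.weights):
        lines.append(f"{c.id},{c.relative_energy:g},{w:.6e}")
    (outdir / "weights.csv").write_text("\n".join(lines) + "\n")

    spectrum = ensemble_spectrum(weighted, broadening)
    write_spectrum_csv(spectrum, outdir / f"spectrum_{ensemble.fragment}.csv")

    reports = {
        band: band_report(weighted, band, broadening, config.band_window)
        for band in (AMIDE_I, ALPHA_COO)
    }
    write_band_report_csv(list(reports.values()), outdir / "band_reports.csv")

    charge = charge_transfer_report(weighted)
    write_charge_transfer_csv([charge], outdir / "charge_transfer.csv")

    if all(c.backbone_map is not None for c in ensemble.conformers):
        summary = ramachandran_summary(weighted)
        write_ramachandran_csv(summary, outdir / "ramachandran.csv")

    inputs: dict = {"fragment": ensemble.fragment,
                    "n_conformers": len(ensemble.conformers)}
    if input_path is not None:
        inputs["file"] = str(input_path)
        inputs["sha256"] = _sha256(Path(input_path))
    _write_manifest(outdir, config, inputs)
    return FragmentResult(fragment=ensemble.fragment, weights=weighted.weights,
                          band_reports=reports, charge_report=charge)


def load_synthetic_spec(path: str | Path) -> SyntheticSpec:
    """Read a synthetic-ensemble recipe from YAML.  Plan fields use the
    flat forms documented in :mod:`bzraman.synthetic`."""
    from .synthetic import HBondPlan, ModePlan

    data = yaml.safe_load(Path(path).read_text()) or {}
    if "mode_plan" in data and data["mode_plan"] is not None:
        data["mode_plan"] = [
            [ModePlan(**m) for m in conformer_plans]
            for conformer_plans in data["mode_plan"]
        ]
    if "hbond_plan" in data and data["hbond_plan"] is not None:
        data["hbond_plan"] = [
            [HBondPlan(**h) for h in conformer_plans]
            for conformer_plans in data["hbond_plan"]
        ]
    return SyntheticSpec(**data)
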