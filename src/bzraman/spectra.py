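"""Simulated Raman spectra: frequency scaling, Lorentzian broadening, and
the Boltzmann-summed ensemble spectrum.

A conformer's spectrum is the activity-weighted sum of unit-area Lorentzian
profiles centred on the scaled harmonic frequencies,

    I(v) = sum_k A_k * (1/pi) * (g/2) / ((v - s*v_k)^2 + (g/2)^2)

with s the anharmonicity scaling factor (0.97 by default) and g the FWHM.
Unit-area (rather than unit-height) profiles mean the Raman activity
controls the integrated band intensity, the standard convention.  The
ensemble spectrum is the population-weighted pointwise sum over conformers,
B_T(v) = sum_i N_i * W_i(v): a convex combination, so it inherits
non-negativity and is bounded by the conformer spectra.

Intensities are in arbitrary units; v^4 / Bose cross-section prefactors are
deliberately omitted — modes are weighted by raw activity only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .boltzmann import WeightedEnsemble
from .models import NormalMode, ValidationError

__all__ = [
    "BroadeningConfig",
    "RamanSpectrum",
    "scale_frequencies",
    "conformer_spectrum",
    "ensemble_spectrum",
    "write_spectrum_csv",
    "plot_overlay",
]

#: Harmonic-frequency scaling factor partially correcting for anharmonicity.
DEFAULT_SCALING_FACTOR = 0.97

#: Lorentzian FWHM in cm⁻¹.  Not fixed by the physical model; 10 cm⁻¹ is a
#: typical condensed-phase simulation width and is configurable.
DEFAULT_FWHM = 10.0


@dataclass
class BroadeningConfig:
    """Broadening and grid parameters for simulated spectra.

    Inputs already carrying scaled frequencies should use
    ``scaling_factor=1.0`` — the pipeline never applies the factor twice.
    """

    scaling_factor: float = DEFAULT_SCALING_FACTOR
    fwhm: float = DEFAULT_FWHM
    grid_min: float = 400.0
    grid_max: float = 4000.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.scaling_factor <= 1.1):
            raise ValidationError(
                f"scaling_factor must be in (0, 1.1], got {self.scaling_factor}")
        if self.fwhm <= 0:
            raise ValidationError(f"fwhm must be > 0, got {self.fwhm}")
        if self.grid_min >= self.grid_max:
            raise ValidationError("grid_min must be < grid_max")
        if self.grid_step <= 0:
            raise ValidationError("grid_step must be > 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass
class RamanSpectrum:
    """Intensity (arbitrary units, ≥ 0) on a uniform wavenumber grid."""

    grid: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.grid.shape != self.intensities.shape:
            raise ValidationError("grid and intensities must have equal length")

    def argmax_position(self, window: Optional[tuple[float, float]] = None) -> float:
        """Wavenumber of maximum intensity, optionally within a window."""
        mask = np.ones_like(self.grid, dtype=bool)
        if window is not None:
            mask = (self.grid >= window[0]) & (self.grid <= window[1])
            if not mask.any():
                raise ValidationError(f"window {window} outside spectral grid")
        idx = np.flatnonzero(mask)[np.argmax(self.intensities[mask])]
        return float(self.grid[idx])

    def max_normalized(self) -> "RamanSpectrum":
        peak = self.intensities.max()
        scaled = self.intensities / peak if peak > 0 else self.intensities
        return RamanSpectrum(self.grid, scaled, dict(self.metadata))


def scale_frequencies(
    modes: Sequence[NormalMode] | Sequence[float],
    scaling_factor: float = DEFAULT_SCALING_FACTOR,
) -> np.ndarray:
    """Multiply harmonic frequencies by the scaling factor, order preserved."""
    if scaling_factor <= 0:
        raise ValidationError("scaling_factor must be > 0")
    freqs = np.array(
        [m.frequency if isinstance(m, NormalMode) else float(m) for m in modes]
    )
    return scaling_factor * freqs


def _lorentzian(grid: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    half = fwhm / 2.0
    return (half / np.pi) / ((grid - center) ** 2 + half**2)


def conformer_spectrum(
    modes: Sequence[NormalMode],
    config: BroadeningConfig | None = None,
    **metadata,
) -> RamanSpectrum:
    """Broaden one conformer's modes into a spectrum.

    Modes whose scaled centres fall outside the grid window still contribute
    their Lorentzian tails.  An empty mode list yields the zero spectrum.
    """
    config = config or BroadeningConfig()
    grid = config.grid()
    intensities = np.zeros_like(grid)
    for mode, center in zip(modes, scale_frequencies(modes, config.scaling_factor)):
        if mode.raman_activity < 0:
            raise ValidationError(f"mode {mode.index}: negative Raman activity")
        intensities += mode.raman_activity * _lorentzian(grid, center, config.fwhm)
    meta = {
        "scaling_factor": config.scaling_factor,
        "fwhm": config.fwhm,
        **metadata,
    }
    return RamanSpectrum(grid=grid, intensities=intensities, metadata=meta)


def ensemble_spectrum(
    weighted: WeightedEnsemble,
    config: BroadeningConfig | None = None,
) -> RamanSpectrum:
    """Boltzmann sum of the conformer spectra, B_T(v) = sum_i N_i W_i(v).

    All conformers are broadened on the shared config grid, so the pointwise
    sum is always well defined.
    """
    config = config or BroadeningConfig()
    grid = config.grid()
    total = np.zeros_like(grid)
    for conformer, n_i in zip(weighted.ensemble.conformers, weighted.weights):
        w_i = conformer_spectrum(conformer.modes, config, conformer=conformer.id)
        total += n_i * w_i.intensities
    meta = {
        "fragment": weighted.ensemble.fragment,
        "conformer": "ensemble",
        "temperature": weighted.temperature,
        "scaling_factor": config.scaling_factor,
        "fwhm": config.fwhm,
    }
    return RamanSpectrum(grid=grid, intensities=total, metadata=meta)


# ---------------------------------------------------------------------------
# export


def write_spectrum_csv(spectrum: RamanSpectrum, path: str | Path) -> Path:
    """Two-column CSV (wavenumber_cm, intensity_au) plus a JSON metadata
    sidecar at ``<path>.meta.json``."""
    path = Path(path)
    lines = ["wavenumber_cm,intensity_au"]
    lines += [f"{v:.6f},{i:.10e}" for v, i in zip(spectrum.grid, spectrum.intensities)]
    path.write_text("\n".join(lines) + "\n")
    Path(str(path) + ".meta.json").write_text(
        json.dumps(spectrum.metadata, indent=1, default=str) + "\n")
    return path


def plot_overlay(
    simulated: RamanSpectrum,
    experimental_csv: Optional[str | Path] = None,
    path: str | Path = "overlay.png",
    window: Optional[tuple[float, float]] = None,
) -> Path:
    """Export a simulated-vs-experimental overlay figure.

    Each trace is max-normalized independently (the physically arbitrary
    intensity units make a shared scale meaningless).  The experimental
    input is a two-column CSV (wavenumber, intensity) with a header line.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.2))
    sim = simulated.max_normalized()
    ax.plot(sim.grid, sim.intensities, label="simulated (Boltzmann sum)",
            color="tab:blue")
    if experimental_csv is not None:
        data = np.loadtxt(experimental_csv, delimiter=",", skiprows=1)
        exp_i = data[:, 1] / data[:, 1].max() if data[:, 1].max() > 0 else data[:, 1]
        ax.plot(data[:, 0], exp_i, label="experimental", color="tab:red",
                alpha=0.7)
    if window:
        ax.set_xlim(*window)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("intensity (a.u., max-normalized)")
    ax.legend(frameon=False, fontsize=8)
    title = simulated.metadata.get("fragment", "")
    if title:
        ax.set_title(str(title))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
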