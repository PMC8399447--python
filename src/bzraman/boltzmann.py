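"""Maxwell–Boltzmann conformer populations and weighted aggregation.

The equilibrium population of conformer *i* at temperature *T* is

    N_i = exp(-E_i / kT) / sum_j exp(-E_j / kT)

with E_i the electronic energy relative to the ensemble minimum (kcal/mol)
and kT expressed per mole through the gas constant R.  Energies are
max-subtracted before exponentiation so ensembles spanning the full 0–50
kcal/mol window stay numerically stable (a 50 kcal/mol conformer at 298 K
has a weight near 10⁻³⁷).

``weighted_mean`` is the scalar form of the Boltzmann sum used for band
positions and charge-transfer totals; with ``renormalize=True`` (the
default) it divides by the weight sum, so populations printed to three
significant figures (summing to ≈0.9995–1.0002) aggregate consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import Ensemble, ValidationError, validate_ensemble

__all__ = [
    "R_KCAL_PER_MOL_K",
    "DEFAULT_TEMPERATURE",
    "boltzmann_weights",
    "weighted_mean",
    "zero_and_infinite_T_limits",
    "WeightedEnsemble",
    "weigh_ensemble",
]

#: Gas constant in kcal mol⁻¹ K⁻¹ (per-mole counterpart of k_B, matching the
#: kcal/mol scale of conformer relative energies).
R_KCAL_PER_MOL_K = 1.987204e-3

#: Room temperature, K — the condition under which the reference Raman
#: spectra were acquired and all populations are evaluated.
DEFAULT_TEMPERATURE = 298.0


def boltzmann_weights(
    relative_energies: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
    *,
    gas_constant: float = R_KCAL_PER_MOL_K,
) -> np.ndarray:
    """Boltzmann populations N_i for relative energies in kcal/mol.

    Parameters
    ----------
    relative_energies:
        Conformer energies relative to the minimum, kcal/mol.  Finite and
        non-negative after re-referencing (the minimum is subtracted here
        regardless, which also makes the result invariant under adding a
        constant to all energies).
    temperature:
        Equilibrium temperature in K, > 0.
    gas_constant:
        kcal mol⁻¹ K⁻¹; override for full-precision CODATA work.

    Returns
    -------
    np.ndarray of probabilities summing to 1, in input order.
    """
    energies = np.asarray(relative_energies, dtype=float)
    if energies.size == 0:
        raise ValidationError("boltzmann_weights: empty energy list")
    if not np.all(np.isfinite(energies)):
        raise ValidationError("boltzmann_weights: energies must be finite")
    if temperature <= 0:
        raise ValidationError(
            f"boltzmann_weights: temperature must be > 0, got {temperature}")
    kt = gas_constant * temperature
    shifted = energies - energies.min()
    factors = np.exp(-shifted / kt)
    return factors / factors.sum()


def weighted_mean(
    values: Sequence[float],
    weights: Sequence[float],
    renormalize: bool = True,
) -> float:
    """Boltzmann-weighted scalar sum Σ w_i v_i, optionally / Σ w_i.

    ``renormalize=True`` is the default so that populations rounded to the
    printed precision still aggregate to the correct band position.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValidationError(
            f"weighted_mean: length mismatch ({v.size} values, {w.size} weights)")
    if np.any(w < 0):
        raise ValidationError("weighted_mean: weights must be >= 0")
    total = w.sum()
    if total <= 0:
        raise ValidationError("weighted_mean: weights sum to zero")
    s = float(np.dot(w, v))
    return s / total if renormalize else s


def zero_and_infinite_T_limits(ensemble: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    """Analytic population limits: T→0⁺ (indicator on the minimum, ties
    split uniformly) and T→∞ (uniform 1/N)."""
    energies = np.array([c.relative_energy for c in ensemble.conformers])
    if energies.size == 0:
        raise ValidationError("zero_and_infinite_T_limits: empty ensemble")
    n = energies.size
    ground = np.isclose(energies, energies.min(), rtol=0.0, atol=1e-12)
    low = ground.astype(float) / ground.sum()
    high = np.full(n, 1.0 / n)
    return low, high


@dataclass
class WeightedEnsemble:
    """An ensemble with its Boltzmann populations attached.

    ``weights[i]`` corresponds to ``ensemble.conformers[i]``; they sum to 1
    to within 1e-12 when computed by :func:`weigh_ensemble`.  Printed
    (rounded) populations from a published table may also be attached via
    :meth:`from_weights`; downstream aggregation renormalizes, so a weight
    sum of e.g. 0.9995 is handled consistently.
    """

    ensemble: Ensemble
    weights: np.ndarray
    temperature: float
    kT: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.ensemble.conformers),):
            raise ValidationError(
                "WeightedEnsemble: weight count does not match conformer count")
        if np.any(self.weights < 0) or np.any(self.weights > 1 + 1e-9):
            raise ValidationError("WeightedEnsemble: weights must lie in [0, 1]")

    @classmethod
    def from_weights(
        cls,
        ensemble: Ensemble,
        weights: Sequence[float],
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "WeightedEnsemble":
        return cls(
            ensemble=ensemble,
            weights=np.asarray(weights, dtype=float),
            temperature=temperature,
            kT=R_KCAL_PER_MOL_K * temperature,
        )

    @property
    def conformer_ids(self) -> list[str]:
        return [c.id for c in self.ensemble.conformers]


def weigh_ensemble(
    ensemble: Ensemble,
    temperature: float | None = None,
    *,
    validate: bool = True,
    gas_constant: float = R_KCAL_PER_MOL_K,
) -> WeightedEnsemble:
    """Compute Boltzmann populations for an ensemble at its (or a given)
    temperature and return the weighted ensemble."""
    if validate:
        validate_ensemble(ensemble)
    temp = ensemble.temperature if temperature is None else temperature
    w = boltzmann_weights(
        [c.relative_energy for c in ensemble.conformers],
        temp,
        gas_constant=gas_constant,
    )
    return WeightedEnsemble(
        ensemble=ensemble, weights=w, temperature=temp,
        kT=gas_constant * temp,
    )
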