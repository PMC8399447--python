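# Methods

## Model

The package treats a peptide fragment as a canonical ensemble of discrete
conformers in thermal equilibrium. Each conformer *i* carries an
electronic energy `E_i` (kcal/mol) relative to the lowest minimum, and its
equilibrium population is

    N_i = exp(−E_i / kT) / Σ_j exp(−E_j / kT)

Energies are re-referenced to a zero minimum and max-subtracted before
exponentiation, so ensembles spanning the full analysis window (0–50
kcal/mol; a 47 kcal/mol conformer has a weight near 10⁻³⁵) never overflow.
Populations are evaluated with the molar gas constant
R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, matching the kcal/mol energy scale; the
constant is an explicit argument for callers who want full CODATA
precision. Only electronic relative energies enter the weights — no
zero-point, vibrational or rotational partition-function corrections —
because the upstream data provide exactly that, and the dominant-minimum
regime (ground-state weight ≥ 0.92 in all eleven reference ensembles)
makes such corrections second-order for the aggregated observables.

Every ensemble observable is then a population-weighted aggregate:

* a **spectrum** `B_T(ν) = Σ_i N_i W_i(ν)`, where `W_i` is the conformer's
  simulated Raman spectrum — a sum of *unit-area* Lorentzians of FWHM γ at
  the scaled harmonic frequencies, each weighted by its Raman activity.
  Unit area (not unit height) means activity controls integrated band
  intensity, and makes the broadening test an exact analytic statement.
  Intensities are arbitrary units; ν⁴/Bose cross-section prefactors are
  deliberately not applied, so the spectra are comparable across
  temperature settings and match the plain activity-weighted convention.
* a **band position**: the weighted mean of per-conformer positions,
  rounded to integer cm⁻¹ only at the end (ties away from zero);
* a **charge-transfer total** `q_B_T = Σ_i N_i qT_i` with
  `qT_i = Σ_bonds Δq`;
* **Ramachandran angles**: weighted circular means per residue.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| temperature | 298 | K | room-temperature acquisition conditions of the reference spectra |
| frequency scaling | 0.97 | – | standard single-factor anharmonicity correction for the reference level of theory; applied exactly once, never to pre-scaled inputs |
| Lorentzian FWHM | 10 | cm⁻¹ | not fixed by the model; typical for condensed-phase simulation, configurable |
| spectral grid | 400–4000, step 1 | cm⁻¹ | covers the fingerprint through X–H stretch region; the amide I window is a view, not a truncation |
| energy window | 50 | kcal/mol | retains every tabulated conformer (max 47.14) while keeping the distribution fully representative |
| band search window | 1550–1750 | cm⁻¹ | wide enough for outlier shifts up to +81 cm⁻¹ in strained minima |
| localization warning threshold | 0.2 | – | flags delocalized/coupled C=O modes without rejecting them |
| H-bond criteria | 3.5 Å (D···A), 2.7 Å (H···A), 120° (D–H···A) | | common structural-biology practice; the model itself fixes no cutoffs |
| trend tolerance | 2 | cm⁻¹ | just above the integer-rounding granularity of reported positions |

## Aggregation conventions

**Renormalized weighted means.** Published per-conformer populations are
rounded to three significant figures and sum to 0.9995–1.0002 per
fragment. `weighted_mean(..., renormalize=True)` (the default) divides by
the actual weight sum, so rounded and exact populations aggregate
consistently. With this convention, 19 of the 22 published ensemble band
sums are reproduced exactly from the published per-conformer positions;
three differ by exactly 1 cm⁻¹ (EG amide I: computed 1655 vs published
1656; EG αCOO⁻: 1645 vs 1644; EDEA αCOO⁻: 1604 vs 1605 — values computed
by this package's test suite). No weighting or rounding variant we
examined reproduces all 22 simultaneously; plausible causes are the
seventh (untabulated, protonated) EG minimum participating in the original
sums, or positions read off the summed spectra rather than averaged. The
three divergences are documented in the tests rather than patched over.

**Population round-trips.** Recomputing populations from the tabulated
energy ladders reproduces every dominant (ground-state) population to the
printed precision, but not every small one: the tabulated energies are
rounded to 0.01 kcal/mol, and dN/N = dE/kT ≈ 1.7% per 0.01 kcal/mol at
298 K — roughly ten units in the third significant figure. Sensitivity to
input rounding, not an arithmetic discrepancy.

**Charge transfer.** Δq per bond is consumed from the interchange file
when present (the natural-population analysis runs upstream); otherwise it
is derived as |ρ(acceptor) − ρ(bridging H)| from atomic natural electron
densities. That derivation convention is isolated in one function
(`hbonds.hbond_delta_q`) so it can be swapped without touching the
aggregation. Per-conformer values in the packaged table are stored
*already population-weighted*, exactly as printed; the report type keeps
raw and weighted forms separate so weighting is never applied twice. All
magnitudes are reported in electrons (the packaged data span 0.001–0.401
e⁻). Along the ED→DEA→EDEA→GEDEA→EGEDEA growth path q_B_T increases
monotonically; along the EG family it dips at EGED (1.030 → 1.016 e⁻),
where the nonpolar glycine interrupts the acidic side chains — a real
feature of the data, asserted as such in the tests.

**Band assignment.** Within the search window, the assigned mode
maximizes the summed |C→O stretch amplitude| — the relative displacement
of each target C/O pair projected on its bond axis. Amide I always means
the first peptide bond from the αNH₃⁺ terminus; the αCOO⁻ band projects
both carboxylate C–O pairs (antisymmetric-stretch convention). The
localization score is the fraction of squared displacement norm on the
target atoms, a frame-invariant quantity in [0, 1]; scores below 0.2
attach a warning because coupled amide modes are outside the uncoupled
single-oscillator picture this assignment assumes (transition-dipole
coupling corrections are explicitly out of scope). For self-protonated
termini the "αCOO⁻" assignment falls back to the neutral C-terminal C=O
and flags the protonation.

**Circular angle means.** Boltzmann-weighted φ/ψ summaries use the
weighted circular mean (unit vectors → weighted resultant → atan2):
an arithmetic mean breaks at the ±180° seam (170° and −170° average to
180°, not 0°). The arithmetic mean is available behind a flag for
comparison with tabulations that averaged raw values. A zero resultant
(antipodal tie) is reported as undefined rather than picking a side.
Region labels (α-helical box φ ∈ (−90, −30), ψ ∈ (−77, −17); restricted
(+120°, −120°) quadrant with glycine exempt) are used only for reporting,
never for filtering.

## The synthetic generator

`bzraman.synthetic` emulates the *statistical shape* of upstream
electronic-structure output: exponential ΔE ladders (default scale 4
kcal/mol — the median spacing between the two lowest minima across the
eleven reference ensembles — truncated at the 50 kcal/mol window, minimum
forced to 0), backbone geometries built from ideal internal coordinates
(documented bond tables, planar trans peptide bonds, Cβ side-chain stubs),
C=O-localized modes with a planted localization fraction, zwitterionic or
self-protonated termini, and 2–7 hydrogen bonds per conformer with Δq up
to 0.401 e⁻. One seeded generator drives every draw; a spec is bit-for-bit
reproducible.

It deliberately does **not** emulate: real force fields or energy
minimization (geometries are constructed, not optimized), mode coupling
and delocalization across neighbouring carbonyls, realistic Raman activity
patterns, solvent or crystal-packing effects. Passing recovery tests
therefore demonstrate that the *pipeline arithmetic* is faithful — planted
energies reappear as exact populations, planted frequencies as band
positions, planted torsions to 10⁻⁶ degrees — not that the physical
approximations hold for real spectra; that evidence comes from the
packaged reference tables.

## Numerical choices

* Max-subtraction before exponentiation in the Boltzmann weights;
  normalization exact to 10⁻¹².
* Torsions via the atan2 formulation, range (−180°, 180°], cross-checked
  in the tests against an independent arccos-plus-sign formula to 10⁻⁹
  degrees; collinear triples raise rather than returning garbage.
* Integer rounding of band sums: nearest integer, ties away from zero,
  applied only to the final ensemble sum.
* Degenerate global minima (two conformers at ΔE = 0) are accepted;
  zero-temperature limits split their weight uniformly.
* Lorentzian tails are never truncated at the window edge; modes outside
  the grid still contribute.

## Problem sizes

The packaged analyses are desk-scale: 11 fragments × 6 conformers, spectra
on a 3601-point grid, synthetic ensembles of 1–6 conformers with ~40–70
atoms. The distributional-sanity test draws 1000 seeded energy ladders.
The full test suite and the reproduction script each run in seconds on one
CPU.

## Known limitations

* Only one quantum-chemistry log dialect (the package's own mock dialect)
  is parsed; real logs must be converted to the interchange JSON first.
* Hydrogen-bond geometric detection uses fixed distance/angle cutoffs and
  a nearest-heavy-atom covalency assignment; bifurcated bonds appear as
  multiple records.
* The amide I assignment tracks a single bond's stretch; strongly coupled
  amide modes are flagged (localization < 0.2) but not decomposed.
* The three 1 cm⁻¹ band-sum divergences and the rounded-energy population
  sensitivity described above are inherent to reproducing printed tables
  from printed inputs and are left visible in the test suite.
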