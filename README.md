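# bzraman

Boltzmann-weighted conformer-ensemble analysis of simulated peptide Raman
spectra, built around the glutamate-rich C-terminal "E-hook" fragments of
β-tubulin (EG, ED, EA, EGE, EDE, DEA, EGED, EDEA, EGEDE, GEDEA, EGEDEA).

Short acidic peptides are conformationally flexible: a single optimized
geometry rarely explains a measured solid-state Raman spectrum. Given a set
of energetic minima per fragment — relative electronic energies, harmonic
normal modes with Raman activities, natural-population electron densities
and intramolecular hydrogen bonds, all computed upstream by an
electronic-structure code — this package derives the ensemble-level
observables a vibrational study reports, for people who run such studies:

* **Conformer populations.** Maxwell–Boltzmann weights
  `N_i = exp(−E_i/kT) / Σ_j exp(−E_j/kT)` at T = 298 K (configurable),
  with energies in kcal/mol re-referenced so the minimum is 0.
* **Simulated spectra.** Each mode becomes a unit-area Lorentzian (default
  FWHM 10 cm⁻¹) at its scaled frequency (anharmonicity factor 0.97),
  weighted by Raman activity; the ensemble spectrum is the Boltzmann sum
  `B_T(ν) = Σ_i N_i·W_i(ν)`.
* **Band assignment and tracking.** The amide I ν(C=O) of the first
  peptide bond from the αNH₃⁺ terminus and the C-terminal αCOO⁻ ν(C=O) are
  located by projecting mode displacements on the C→O bond axes; ensemble
  band positions are population-weighted means, and cross-fragment series
  are classified as blue/red shifts.
* **Hydrogen-bond charge transfer.** Per-conformer totals `qT = Σ Δq` over
  intramolecular hydrogen bonds (Δq in electrons, from natural population
  differences) and the ensemble total `q_B_T = Σ_i N_i·qT_i`.
* **Ramachandran statistics.** Backbone φ/ψ torsions with
  population-weighted circular means.

A synthetic-ensemble generator (`bzraman.synthetic`) builds peptide
backbones at requested φ/ψ, plants localized C=O modes and hydrogen bonds
with known magnitudes, and emits both the interchange JSON format and a
mock quantum-chemistry log dialect — so the entire pipeline is testable
without any electronic-structure software. The per-conformer and
ensemble-level reference tables for all 11 fragments ship as packaged CSV
fixtures.

## Worked example

```python
>>> import bzraman as bz
>>> fx = bz.load_table1_fixture()
>>> bz.boltzmann_weights(fx.energies("EGEDEA"), temperature=298.0).round(4)
array([0.9192, 0.0808, 0.    , 0.    , 0.    , 0.    ])
```

The hexapeptide's ensemble is dominated by two conformers 1.44 kcal/mol
apart (populations 0.92 and 0.08); the four remaining minima above
11 kcal/mol are thermally irrelevant at room temperature.

```python
>>> from bzraman.pipeline import PipelineConfig, fixture_fragment_result
>>> res = fixture_fragment_result(fx, "EGEDEA", PipelineConfig())
>>> res.band_reports["amide_I"].boltzmann_sum
1658
>>> res.band_reports["alphaCOO"].boltzmann_sum
1610
>>> res.charge_report.q_bt
1.651
```

The amide I band of the hexapeptide lands at 1658 cm⁻¹ — the helical-range
position that, together with the φ/ψ statistics, points to local helical
structure in the E-hook tail — with 1.651 e⁻ of charge moved through its
seven intramolecular hydrogen bonds.

The same numbers are available from the command line, along with the
cross-fragment trend classification:

```text
$ bzraman trends --out out --quiet
ED_family	amide_I	blue_shift	[+3, +6, +14, +4]
ED_family	alphaCOO	mixed	[+0, -5, +3, +3]
EG_family	amide_I	mixed	[-38, +59, -26, +8]
EG_family	alphaCOO	red_shift	[-4, -21, -6, -4]
```

Growing the chain along ED → EDE → EDEA → GEDEA → EGEDEA steadily
blue-shifts the amide I band while the carboxylate band barely moves
(|step| ≤ 5 cm⁻¹); along EG → EGE → EGED → EGEDE → EGEDEA the carboxylate
band steadily red-shifts.

A full synthetic run (generation → populations → spectrum → bands →
charge transfer → Ramachandran) from a three-line YAML recipe:

```sh
printf 'sequence: EGEDEA\nn_conformers: 4\nseed: 11\n' > demo.yaml
bzraman all --synthetic demo.yaml --out demo_out
```

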