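# embedshield

Embedded-cluster (QM1/QM2/MM) models for predicting solid-state NMR
chemical shifts of molecular crystals, with the statistics layer used to
benchmark computed shieldings against experiment.

## Who this is for

Computational chemists predicting ¹H/¹³C solid-state NMR spectra of
organic molecular crystals (e.g. amino acids, pharmaceuticals) with
molecular electronic-structure codes rather than periodic plane-wave
(GIPAW) programs. The package handles everything *around* the quantum
calculation: building the embedded model from a crystal structure,
converging the electrostatic environment, generating engine inputs,
averaging over snapshots, and evaluating results against experimental
shifts. The quantum calculation itself (SCF, GIAO shieldings, CHELPG
densities, MD propagation) is delegated to an external engine through
generated input decks; a deterministic mock backend lets the entire
pipeline run and be tested at desk scale.

## The model

A crystal is partitioned into three layers:

* **QM1** — the asymmetric unit (one molecule here), the only part whose
  shieldings are reported;
* **QM2** — the first shell of neighbouring molecules, every symmetry
  image with at least one atom within a cutoff (2.5–3.5 Å typical) of
  QM1, treated quantum-mechanically alongside QM1;
* **MM** — a 9×9×9 supercell of point charges at every remaining atom
  position.

The MM charges are determined self-consistently: ESP-fitted (CHELPG)
charges of QM1 are computed first in vacuum, mapped onto every
symmetry-equivalent lattice site, recomputed in that field, and iterated
until the largest per-atom change is ≤ 0.01 e. QM1 hydrogens are then
relaxed in the frozen environment and the whole cluster is rebuilt from
the new positions.

Computed shieldings σ are compared with experimental shifts δ through a
linear fit σ = aδ + b; predicted shifts δ_calc = (σ − b)/a remove each
method's systematic bias, and the residuals give MAE, MaxAE (with the
worst nucleus), SDE (n−1 denominator) and MSE. An MD-based vibrational
correction Δσ = ⟨σ⟩_snapshots − σ_rigid can be added per nucleus.

## Worked example

The packaged benchmark tables hold the experimental ¹H/¹³C shifts of six
amino-acid crystals (α-glycine, l-alanine, l-serine, l-aspartic acid,
l-cysteine, l-threonine) together with embedded-cluster shieldings at
five levels of theory. Reproducing the ¹H correlation table:

```
$ embedshield benchmark --element H
method                  slope intercept      R2   MAE MaxAE                SDE
PBE                     -1.00     30.73  0.9911  0.22  0.72 SH(cys)       0.30
TPSS                    -1.00     31.13  0.9917  0.22  0.65 SH(cys)       0.29
B3LYP                   -1.03     31.14  0.9915  0.21  0.68 SH(cys)       0.30
DLPNO-DSD-PBEP86        -1.04     31.13  0.9907  0.22  0.79 SH(cys)       0.31
DLPNO-MP2               -1.04     31.00  0.9909  0.22  0.78 SH(cys)       0.31
```

Slopes are close to the ideal −1 and the intercept approximates the
reference-compound (TMS) shielding; MAE ≈ 0.22 ppm is the typical
accuracy for ¹H in molecular solids, and the worst-predicted proton in
every method is the hydrogen-bonded thiol of l-cysteine.

The synthetic end-to-end pipeline (toy P2₁ crystal → QM2 shell →
self-consistent mock charges → environment-sensitive mock shieldings →
fit against shifts generated from a planted line):

```
$ embedshield demo --seed 2
crystal toy-P21-2: 2 molecules/cell
charges converged in 1 iterations: -0.800, +0.400, +0.400
mock fit over 3 nuclei: slope -1.000, intercept 30.01 ppm, R2 1.0000
```

Library use mirrors the CLI: see `embedshield.build_cluster`,
`embedshield.converge_charges`, `embedshield.mock_shieldings`,
`embedshield.fit_shieldings`.

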