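# operscan

Tools for predicting the genome-wide regulatory output of a bacterial
transcription factor that binds a **bipartite operator**: two conserved
pentamers (consensus `TTAAG`) separated by an unconstrained 6-bp spacer,
the architecture of the Fe(II)-responsive activator BqsR of
*Pseudomonas aeruginosa*. The package is aimed at regulatory genomicists
who want to go from a genome sequence and a handful of reporter
measurements to quantitative per-promoter expression predictions, and to
ask where and why such sequence-level predictions fail.

## What it computes

**Operator scanning.** Every occurrence of `TTAAG(N)s TTAAG`
(spacer length *s*, default 6, optionally {5, 6, 7}) on either strand
of a linear or circular contig, with up to a configurable number of
mismatches over the 10 pentamer positions. Overlapping operators that
share pentamers are detected as arrays (*n* pentamers at fixed spacing
imply *n* − 1 operators), and a Monte-Carlo null distributes the same
number of operators uniformly to judge cluster enrichment.

**Affinity models.** Two interchangeable sequence-to-affinity models:

- a position weight matrix (PWM) with log₂-odds scores
  `S = Σᵢ log₂ p(bᵢ, i)/q(bᵢ)` and an exponential link
  `strength = exp(a·S + b)` fitted by least squares of ln(fold change)
  on score;
- an additive 16-position **binding energy matrix** in units of
  k_BT, built from reporter fold changes of single-point operator
  mutants via `ΔE = −ln(fc / fc_ref)` (positive ΔE = weaker binding),
  with the underdetermined spacer cells fitted by minimum-norm least
  squares. Sequence energy is the sum of per-position entries;
  predicted fold change is `fc_ref · exp(−ΔE)`.

**Promoter prediction.** Candidate operators (≤ 3 pentamer mismatches,
fully inside the 600-bp window upstream of the CDS or TSS) are
aggregated per promoter: additively (default), strongest-only,
most-downstream-only, or with a two-site thermodynamic occupancy model.
Gene predictions roll up to transcriptional units and are normalized to
a reference gene.

**Evaluation.** Prediction error (predicted/measured fold change,
geometric-mean summaries) stratified by operator count or TSS distance,
top-N secondary-TF site co-occurrence, operator overlap detection, and
an upper-tail hypergeometric test for regulon overlap.

**Synthetic data.** Genomes with planted operators at controlled
mismatch counts and cluster structure, reporter libraries with
lognormal replicate noise generated from a known ground-truth energy
matrix, and regulon pairs with forced overlap — so every stage is
testable against known truth with no downloads.

## Worked example

```python
import numpy as np
from operscan import (BipartiteMotif, scan_bipartite, assign_to_promoters,
                      predict_all_promoters, generate_genome, PlantSpec,
                      random_energy_matrix, generate_library_measurements,
                      single_mutant_library, spacer_single_variants,
                      build_pentamer_energies, fit_spacer_energies,
                      assemble_energy_matrix)

# a 40-kb synthetic genome with 10 planted operators (5 exact, 5 with one
# pentamer mismatch), each upstream of its own gene
genome, truth = generate_genome(
    40_000, plant_spec=PlantSpec(n_per_mismatch={0: 5, 1: 5}), seed=7)

hits = scan_bipartite(genome, BipartiteMotif(max_total_mismatches=3))
print(len(hits), "candidate operators at <= 3 mismatches")

# rebuild the energy matrix from a simulated noiseless reporter library
matrix0 = random_energy_matrix(seed=7)
ref = matrix0.reference_sequence
pent = build_pentamer_energies(
    generate_library_measurements(
        matrix0, single_mutant_library(ref, range(0, 5))
        + single_mutant_library(ref, range(11, 16)), noise_cv=0.0),
    ref, mirror_downstream=False)
sp = fit_spacer_energies(
    generate_library_measurements(
        matrix0, spacer_single_variants(ref, 18), noise_cv=0.0), ref)
# anchor: the reference operator drives a measured 20-fold activation
matrix = assemble_energy_matrix(pent, sp, ref, reference_fold_change=20.0)

preds = predict_all_promoters(
    assign_to_promoters(hits, truth.annotations), truth.annotations, matrix)
for uid, p in sorted(preds.items(),
                     key=lambda kv: -kv[1].predicted_fold_change)[:5]:
    print(uid, len(p.operators), round(p.predicted_fold_change, 3))
```

Output:

```
87 candidate operators at <= 3 mismatches
gene0006 3 2.427
gene0002 3 0.327
gene0010 4 0.193
gene0008 8 0.165
gene0001 3 0.155
```

87 windows pass the 3-mismatch budget: the 10 planted operators plus
near-matches arising by chance in the random background (which is why
several promoters carry 3–8 candidates). Each candidate predicts
`20 · exp(−ΔE)` fold change, and the additive mode sums candidates per
promoter. Under this ground-truth matrix the energy penalties are
deliberately harsh — every pentamer mismatch and every spacer base
differing from the reference costs 0.1–2.5 k_BT — so only the promoter
whose planted operator happens to sit closest to the reference 16-mer
(gene0006) clears a 2-fold prediction, while heavily mismatched
background candidates contribute almost nothing.

The same pipeline is scriptable from the shell:

```sh
operscan run-all --config config.yaml --outdir run/
```

which writes the simulated dataset, hit tables (BED/TSV), the
assembled energy matrix, per-unit predictions and evaluation tables,
each stage with a reproducibility manifest.

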