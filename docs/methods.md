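# Methods

## The regulatory model

The package models a single bacterial transcription activator that
binds a bipartite operator — two conserved 5-bp blocks (consensus
`TTAAG`) separated by a spacer whose length, not sequence, is the key
constraint (6 bp canonical; 5 and 7 bp abolish activity). Expression
output is assumed proportional to regulator occupancy at the operator
(the occupancy hypothesis), so operator affinity maps directly to fold
change in expression between induced and regulator-deleted conditions.

Two sequence-to-affinity models are implemented.

**PWM with exponential link.** A position weight matrix gives each
candidate a log₂-odds score S (base frequency over background, summed
over positions). Predicted strength is `exp(a·S + b)`; a and b are
fitted by ordinary least squares of ln(fold change) on S. The
functional form is a modelling choice: fitting on the log scale makes
the link strictly monotone in S, keeps strengths positive, and makes
the PWM convertible into an energy matrix by an exact algebraic
identity (`ΔE(b,i) = −a·(score(b,i) − score(ref_b,i))`, so strength
ratios equal `exp(−ΔΔE)`). A clamped linear link is available behind
the `form` switch for sensitivity analysis.

**Experimentally derived binding-energy matrix.** Reporter fold
changes of operator variants, measured relative to a reference
construct, convert to binding-energy changes by

    ΔE = −k_BT · ln(fc / fc_ref),   k_BT ≡ 1,

so a variant that lowers expression tenfold costs +2.30 k_BT. The sign
convention (destabilizing = positive) is fixed throughout. The matrix
is additive by construction: the energy of any 16-mer is the sum of its
per-position entries, and the reference sequence scores exactly 0.

Pentamer cells come from single-point mutants (one cell per
construct). Downstream-pentamer cells can mirror the upstream
measurements (`mirror_downstream=True`, the default), reflecting the
assumption that the two pentamers contact the regulator equivalently;
direct downstream measurements always override the mirror. Spacer
cells come from a linear model `X·e = y` over 6 positions × 3
non-reference bases (reference bases are the zero gauge). With few
spacer variants this system is underdetermined; the default solution is
the exact minimum-norm least-squares solution via the Moore–Penrose
pseudoinverse, which reproduces every observation exactly for
consistent data and assigns nothing to unconstrained directions. A
ridge-regularized path (`ridge_lambda > 0`) exists for noisy,
near-collinear designs. Cells whose base never appears in any variant
are reported as missing and default to 0 when scoring — a deliberate
"no evidence, no penalty" policy that callers can inspect via the
`missing` mask.

## Scanning and promoter assignment

The scanner reports every window whose two pentamer blocks jointly
mismatch the consensus at no more than the budget (spacer bases never
count), once per strand per spacer length, in plus-strand 0-based
half-open coordinates. Minus-strand hits are found by scanning the
reverse complement and reflecting coordinates. Circular contigs are
handled by extending the sequence by one window minus one base and
normalizing starts into [0, L); origin-wrapping hits keep
`end = start + width`, which may exceed L. N (from masked ambiguity
codes) never matches a pentamer base.

A hit is assigned to a gene iff its full interval lies in the window
(default 600 bp) immediately upstream of the anchor — CDS start by
default, TSS optionally — respecting strand; one hit can serve several
genes. Candidate filtering for prediction keeps hits with ≤ 3 total
pentamer mismatches (both thresholds configurable). Only 6-bp-spacer
operators carry energy parameters; 5/7-bp hits contribute fold change 1
because the experimental matrix is a 16-mer model and non-canonical
spacers abolish activity.

The cluster null distributes the observed number of operators as
uniform independent start positions (collisions allowed, probability
negligible at genomic scale) and histograms per-window counts over
iterations. Operators are treated as points (start positions), so the
expected per-window count is exactly n·w/L, which the Monte-Carlo mean
must match within its standard error.

## Multi-operator aggregation

Default is the additive model: total fold change is the sum of
per-operator fold changes `fc_ref·exp(−ΔE_i)`. An empty promoter
predicts fold change 1 (no regulation); the literal sum rule applies
from one operator up. The alternative composition `1 + Σ(fc_i − 1)` is
not the default but trivially obtainable from the per-operator list
each prediction carries. Strongest-only and most-downstream-only
variants take the max and the anchor-proximal operator respectively
(distance measured from the operator's gene-proximal end to the anchor,
strand-aware). The two-operator thermodynamic model uses independent
two-site statistical weights `w_i = λ·exp(−ΔE_i)`, occupancy
`p = (w₁+w₂+w₁w₂)/(1+w₁+w₂+w₁w₂)`, and `fc = 1 + (fc_max−1)·p`; λ and
fc_max default to a runtime calibration that makes a lone reference
operator match the additive model, since there is no principled
external value for regulator availability in this formulation.

Transcriptional units take the lead (first-listed, most upstream)
gene's promoter prediction by default — the lead promoter is the one
physically transcribing the unit — with a `max` policy available.
Predictions can be normalized so a designated reference unit equals its
measured expression.

## Evaluation statistics

Prediction error is the ratio predicted/measured; all summaries are
geometric means because ratios are multiplicative and error
distributions span decades. TSS distance is signed from the operator
midpoint, negative upstream. The regulon-overlap test is a one-sided
upper-tail hypergeometric `P[X ≥ k]` with the universe size as an
explicit required argument (no defensible default exists); no
multiple-testing correction is applied by default. Secondary-TF
co-occurrence scores every position on both strands, keeps the top N
(default 100) sites genome-wide — sorted by score, ties broken by
(contig, position, strand) for determinism — and flags units whose
promoter window fully contains a retained site.

## Synthetic data: what it emulates and what it does not

The generator emulates (a) a high-GC (default 0.66, pseudomonad-like)
i.i.d. background genome with operators planted at controlled mismatch
counts, one promoter per slot, strands alternating, including pentamer
arrays (n pentamers at exact 11-bp spacing); (b) reporter libraries
drawn from a ground-truth energy matrix with multiplicative lognormal
replicate noise, σ = √ln(1+CV²) so the CV is exact; (c) expression
tables equal to model predictions times lognormal noise; (d) regulon
pairs with exactly forced overlap, or independent uniform draws
(`forced_overlap=None`) which constitute the null of the overlap test.
A single root seed spawns per-stage substreams, so outputs are
byte-reproducible.

Ground-truth matrices draw non-reference penalties uniformly from
0.1–2.5 k_BT, spanning the roughly tenfold maximal single-mutation
effect seen in reporter data. This gives the spacer as much energetic
weight as the pentamers — harsher than real operators, where spacer
sequence modulates expression only about twofold — so synthetic
predictions are dominated by whole-16-mer identity rather than pentamer
identity alone.

What passing tests therefore show: coordinate and strand bookkeeping,
exactness of the scanning/energy/aggregation algebra, correct
statistical calibration, and faithful parameter recovery under the
stated noise model. What they do not show: performance on real
promoters, where chromatin-free context effects, secondary regulators,
non-additive epistasis between positions, and operator-RNAP overlap
make measured outputs deviate from any occupancy-only model — the
package's evaluation tools exist precisely to quantify that deviation.

## Numerical choices and degenerate inputs

- Internal coordinates are 0-based half-open everywhere; conversions
  happen only at I/O boundaries (GFF3 1-based inclusive, BED native).
- PWM pseudocount default 1 per base per column; background default
  uniform. Pseudocount 0 is allowed at build time (one-hot columns are
  legitimate) but scoring a zero-probability cell raises, directing
  the user to a positive pseudocount.
- Energies and scores are float64 throughout; exact-identity tests
  (reference energy 0, additivity, round trips) hold to 1e-9 or
  better.
- A genome shorter than the minimal window scans to an empty hit list,
  not an error. An empty promoter-window list for the null model is an
  error (the null is undefined).
- MEME-minimal motif files are written with 6-decimal probabilities
  and re-read without quantization, so round trips are stable to 1e-6;
  probability rows must sum to 1 within 1e-4 on read.
- Scanner and hit ordering are deterministic (position, spacer,
  strand); top-N site selection breaks score ties lexicographically.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale inputs
chosen to make every check exact or tightly calibrated: 10-kb random
genomes (20 replicates) for scanner–oracle equivalence, 40-kb planted
genomes for end-to-end identity, 2000 Monte-Carlo iterations for the
placement null, and 1000 null regulon draws for type-I calibration.
Genome-scale applications (megabase chromosomes) use the same code
paths; the scanner is vectorized per strand/spacer and handles a 6-Mb
contig in seconds.

## Known limitations

- The energy model is strictly additive; pairwise epistasis between
  operator positions is out of scope.
- The two-site thermodynamic model ignores cooperativity and
  RNAP-occlusion effects of operators overlapping the −35 element.
- The additive multi-operator rule over-predicts promoters with many
  weak sites (sums of near-1 terms grow without bound); the strongest
  and most-downstream modes and the per-operator output exist to probe
  this.
- Hypergeometric overlap p-values are exact but conditional on the
  chosen universe; the universe size materially changes significance
  and must be justified by the caller.
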