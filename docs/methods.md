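# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design decisions taken where the underlying
protocol left room, and what the synthetic-data validation does and does not
demonstrate.

## Pooled-screen quantification and hit calling

**Model.** Each construct in a pooled lentiviral library marks a cell
subpopulation. Under exponential growth, a construct conferring relative
fitness *w* per day changes its pool share roughly as *w*^(t − t₀), so
barcode counts over time carry the growth phenotype. Sequencing is
compositional: only relative abundances are observable, which is why all
per-sample totals are scaled to a fixed depth before comparison.

**Procedure.**

1. *Depth normalization* — every sample column is scaled so its total equals
   a fixed target reflecting the cell input per PCR: 50,000 reads for
   inhibition (miRZip-type) pools, 20,000 for overexpression (pCDH-type)
   pools. Scaling is floating point; no rounding.
2. *PCR averaging* — arithmetic mean across PCR replicates of each
   (cell line, infection, day).
3. *Representation filter* — constructs whose first-time-point average is
   strictly below `min_reads` (default 50) in **any** infection are dropped
   from the whole pool; low baselines make fold changes unstable, and a
   pool-level exclusion keeps infections comparable.
4. *Adapted fold change* — fold changes *f* versus the baseline day are
   mapped to *a(f) = f − 1* (f ≥ 1) or *1 − 1/f* (f < 1). The transform is
   continuous at 1, antisymmetric under inversion (*a(f) = −a(1/f)*), and
   makes depletion negative, so depleted constructs get negative slopes.
   The "add 1 to decreased fold changes" convention sometimes described for
   this correction is implemented as this sign-symmetric reciprocal form: a
   literal *f + 1* would map depleted constructs to positive scores and
   could not produce the negative slopes the method requires.
5. *Slope* — zero-intercept least squares of score against day offset,
   *b* = Σxy⁄Σx², with the baseline point (0, 0) included; forcing the
   intercept encodes that every construct starts at "no change".
6. *Outlier calling* — per (cell line, infection), Tukey-style bounds
   Q1 − k·IQR and Q3 + k·IQR (default k = 1) over all that infection's
   slopes. Verdicts use strict inequalities (a slope exactly at a bound is
   "within"). A construct is depleted/enriched in a cell line only when
   both infections agree on the out-of-bounds side — duplicate-infection
   consistency is the minimal evidence criterion.

**Numerical choices.** Quartiles use linear interpolation between order
statistics (numpy's default, the common "type 7"), documented so results are
reproducible. Zero counts after the baseline receive a 0.5-read pseudocount
before division so strong depletion stays finite (baseline zeros cannot
occur after the representation filter). The IQR population includes negative
controls and all non-excluded constructs.

## Ago2-RIP-chip target identification

**Model.** mRNAs bound by the miRNA-loaded RISC co-precipitate with Ago2, so
a bound transcript's IP/T expression ratio exceeds its background "RISC
occupancy". Overexpressing one miRNA shifts its direct targets' IP/T ratio
up relative to an empty-vector control, which separates targets of *this*
miRNA from generally RISC-bound transcripts.

**Procedure.** Probes must be flagged present in every total-fraction sample
and sit at or above the 25th expression percentile (computed per sample over
its present probes) — low-intensity probes have unreliable ratios. Per
duplicate, ratio = IP/T; a probe's duplicates must be *consistent*: detected
in both members of each fraction pair and with ratios on the same side of 1
or within 2-fold of each other (the protocol requires "consistent signal in
duplicates" without giving a formula; this rule is conservative and
testable). Probe ratios are averaged over duplicates, then collapsed per
gene by the maximum across the gene's probes — a target need only be
captured by its best probe; `collapse="mean"` is available. A gene is
IP-enriched at ratio ≥ `min_ratio` (default 2) and a candidate target of the
overexpressed miRNA when additionally ratio(miR)/ratio(EV) ≥ `min_fc`
(default 2). With several cell lines, the intersection of per-line target
sets is the high-confidence output.

Enrichment of an annotation (e.g. predicted-target membership) among hits is
tested with a two-cell goodness-of-fit χ² against the background fraction,
on 1 df; outputs are flagged when an expected cell is below 1, where the
approximation is poor.

## Seed-match annotation

From a mature miRNA (≥ 8 nt, RNA), the package derives the canonical site
motifs on the target mRNA sense strand: 7mer-m8 = reverse complement of
miRNA positions 2–8; 8mer = 7mer-m8 followed by A (the position-1 adenine
anchor); 7mer-A1 = reverse complement of positions 2–7 followed by A.
Scanning reports every occurrence, with class precedence
8mer > 7mer-m8 > 7mer-A1 at a shared locus so one locus yields one site;
distinct (possibly overlapping) loci are all reported. Only canonical seed
classes are scanned — no 6mers, wobble sites, 3′-supplementary pairing or
context scoring. Transcripts are scanned full-length; a site spanning a
region boundary is assigned to the region containing its first nucleotide.
Positions are reported 1-based relative to the ORF start (first CDS base
= +1, the base upstream = −1; there is no 0), matching how binding-site
schematics are usually drawn.

## CRISPR-based prioritization

Targets are joined to the gene-level dropout table by case-insensitive
symbol match (no alias resolution). Significance and strength filters use
strict inequalities as printed in such tables: depleted means fc < 0 with
p_adj < 0.001; top candidates require fc < −5.0 and are ranked ascending by
fc, ties broken alphabetically for determinism. Non-coding targets absent
from a protein-coding knockout library simply carry no CRISPR record.

## Synthetic data: what it emulates, what it does not

`simulate_screen` draws counts from a multinomial at fixed depth over
abundances *w*^(day − day₀), with optional gamma overdispersion
(default 0.05, i.e. ~22% extra CV per construct/sample, emulating PCR and
infection variability). Defaults mirror the screen design analysed here:
60 constructs, 2 negative controls, 6 dropout and 3 enriched constructs,
duplicate infections, days 5/7/15/25/40, duplicate PCRs, 50,000 reads, and a
dropout fitness of 0.85/day. It does not model infection-replicate abundance
drift, index hopping, or alignment artifacts.

`simulate_ripchip` draws per-probe expression log-normally (μ = 8, σ = 1.2
in log space), gives every probe a baseline RISC occupancy uniform in
[1, 2], multiplies true targets' IP signal by `enrichment_fc` (default 4) in
the miRNA condition, and applies multiplicative log-normal noise
(σ = 0.25) to the IP measurement — the IP and total fractions come from the
same lysate, so this σ is the dispersion of the ratio itself. Presence flags
come from a fixed detection floor (2 SD below the mean log intensity).
Planted targets are drawn from the well-expressed range of the intensity
distribution, as real miRNA targets detected on arrays are; the
presence/percentile filter's rejection behaviour is exercised by the
low-expressed tail of the background probes. Probes map 1:1 to genes, so the
probe-collapsing rule is exercised by dedicated unit tests rather than by
the simulation. Array-specific artifacts (probe chemistry, spatial effects,
normalization residue) are not modelled.

`simulate_transcripts` builds i.i.d. background sequence at a given GC
content (default 0.45), partitions it 15%/50%/35% into 5′UTR/CDS/3′UTR, and
plants requested sites at recorded positions (kept ≥ 8 nt apart so no motif
window can span two planted loci). By default, background positions that
happen to spell a motif are redrawn until the planted truth is the complete
site list; scrubbing can be disabled to study background hit rates.

Passing the recovery tests therefore shows the pipeline correctly inverts
its own generative assumptions at realistic noise levels — it does not show
robustness to real-data pathologies the generators exclude (pool
composition drift, array batch effects, non-canonical binding).

## Validation strategy and problem sizes

Every analysis primitive is checked against an independent oracle: the site
scanner against exhaustive window enumeration (1,000 random sequences plus
adversarial motif-dense strings), the zero-intercept slope against a refined
grid search finished with a parabolic-vertex step (exact for a quadratic
SSE; agreement to 1e-8), the adapted fold change against its antisymmetry
property, and the IQR rule against hand-computed quartiles. Statistical
recovery uses 200 simulated screens (sensitivity and neutral false-positive
rate), 500 null screens (negative-control call rate), and 100 RIP-chip
replicates (sensitivity and FDR of the differential-enrichment call, scored
per cell line); these sizes keep the whole suite under a minute while
leaving sampling error far from the acceptance margins.

## Known limitations

- Printed probe-level counts from the original microarray analysis are not
  bit-reproducible: the exact duplicate-consistency and probe-collapsing
  rules used there are unrecorded, so those are documented, configurable
  choices here.
- The hit caller assumes a complete (cell line, infection, day) grid;
  unbalanced designs must be subset first.
- Gene symbols are matched textually; withdrawn or aliased symbols are the
  caller's responsibility.
- GSEA itself is not implemented; the package exports preranked lists for
  external tools.
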