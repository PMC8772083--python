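# Methods

## Overview

`cfplasma` models a matched-sample liquid-biopsy study: a germline sample
(buffy-coat equivalent), a tumour tissue sample, and a plasma cfDNA sample
from the same patient, sequenced at roughly 30x / 60x / 100x. Plasma cfDNA
is a mixture: a fraction `tf` (the tumour fraction) of molecules is
tumour-derived, the remainder comes from normal (largely haematopoietic)
turnover. Every analysis stage — somatic calling, shared/unique
classification, signatures, fragmentomics, CNA screening — consumes either
real pileup/fragment tables in the documented TSV dialects or the output of
the bundled simulator.

## The clonal heterozygous mixture model

All allele-fraction arithmetic assumes a diploid genome and fully clonal
heterozygous events:

- germline heterozygous variant: VAF 0.5 in every sample;
- tumour somatic mutation: VAF = purity/2 in the tumour tissue
  (default purity 0.65) and VAF = tf/2 in plasma;
- plasma background mutation (somatic events of non-tumour tissues,
  including clonal haematopoiesis): VAF drawn uniformly from a low range,
  default [0.05, 0.35], absent from the tumour and the germline.

Subclonality is a single optional multiplier (`subclonal_fraction`) rather
than a clone-tree model; this is deliberately the simplest model consistent
with the observation that tumour-shared plasma variants sit at the high end
of the plasma VAF distribution.

## Simulator

`simulate.SimConfig` holds every study parameter. Defaults: 1 Mb genome in
2 chromosomes at GC 0.41, 200 germline variants, 250 tumour and 250
background mutations, depths 30/60/100, base error rate 1e-3 (the post-Q30
regime), tf = 0.30. The tf default is the regime where the caller's
operating characteristics are measurable; sub-percent tf (the clinically
typical regime for early disease) is exercised explicitly in tests and the
analysis scripts. Tumour fraction ground truth for real cohorts of this
design is only bounded ("< 1%"), so the synthetic values are free
parameters, not a calibration to any cohort.

Mutations are drawn from 96-channel signature profiles with probability
proportional to signature weight x genomic availability of the channel's
trinucleotide context, then placed uniformly over positions carrying that
context (pyrimidine-strand convention; purine-centred sites are registered
under the reverse complement). The default tumour profile is C>T-heavy
with a CpG excess and a C>A component; the default background profile is
T>C-heavy — stylised versions of the substitution spectra reported for
breast tumours and for non-tumour plasma mutations respectively. They are
illustrative, not catalogue signatures.

Read sampling at each site is depth ~ Poisson(mean), alt ~ Binomial(depth,
VAF), with sequencing errors adding e/3 per base toward the tracked alt and
2e/3 toward other bases. Pileup quality summaries (base quality ~ N(33,
1.5), mapping quality ~ N(58, 2), balanced strands, read position ~ N(0.5,
0.08)) sit comfortably inside the false-positive filter's pass region, so
that filter fires on injected pathologies, not on simulator noise.

Plasma fragment lengths follow a two-Gaussian mixture truncated to [50,
2000] bp: mono-nucleosome (166, 10) and di-nucleosome (332, 25), weights
0.85/0.15 for background molecules and 0.70/0.30 for tumour-derived ones.
The heavier tumour di-nucleosome component is the mechanism behind the
300–350 bp shared-fraction enrichment; no parametric form is claimed for
real data — the mixture reproduces the qualitative picture only. Fragment
counts default to depth x genome / mean-length (~5 x 10^5 at defaults). A
fragment covering a somatic variant records the allele it carries: tumour
mutations are carried by tumour-origin fragments with probability 1/2;
background mutations by background-origin fragments with probability
v/(1−tf) so the overall plasma VAF equals the assigned v.

A germline fragment table (sheared library, lengths ~ N(350, 50)) is also
emitted so the CNA screen has a matched-normal depth track.

Randomness: one master seed; every stage draws from
`default_rng([seed, stage_offset])`, so stages are reproducible
independently and identical configs give byte-identical outputs.

### What the simulator does not emulate

No read-level errors correlated along fragments, no GC or mappability
bias, no indels/SVs, no contamination, no subclonal structure, no
nucleosome-positioning signal beyond the length mixture. Passing tests
therefore demonstrate correctness of the analysis arithmetic and the
stated statistical behaviour under this idealised generative model — not
performance on real sequencing data.

## Somatic calling

The somatic p-value is the one-tailed Fisher's exact probability of
observing at least the case's alt count under the pooled 2x2 ref/alt
table, computed with exact integer binomial coefficients (cached); scipy's
hypergeometric distribution serves as an independent oracle in the tests.
Classification: Somatic requires the case called (≥ 2 reads, VAF ≥ 0.01,
base quality ≥ 15), normal VAF ≤ 0 and p ≤ 0.05; a heterozygous normal
(VAF ≥ 0.10) with a significant shift to case VAF > 0.9 or < 0.1 is LOH,
without a significant shift Germline. The somatic p threshold (0.05) and
every false-positive-filter constant (base quality 15, mapping quality 20,
strand fraction 0.05 when ≥ 10 alt reads, read position 0.10–0.90, VAF
0.01) follow published VarScan conventions and are individual config keys.
Final thresholds: ≥ 10x in both samples, ≥ 5 alt reads in the case, 0 alt
reads in the normal.

Multi-allelic pileup rows are reduced to the single most-supported alt per
site (ties broken A<C<G<T); the remaining alleles are excluded from
evaluation and counted in the stage report. Pileups are assumed mate-aware
and duplicate-free; the caller never re-corrects counts.

Operating characteristics under the clonal model, measured in the tests at
uniform 100x: at tf = 0.30 (case VAF 0.15) recall of tumour truth ≥ 0.9 at
precision ≥ 0.9; at tf = 0.005 (VAF 0.0025, about one supporting read in
100x) recall collapses below 0.2 — the detection-limit argument for why
sub-percent tumour fractions defeat even deep WGS. At the asymmetric study
design (30x germline), the Fisher test against the shallow normal is the
binding constraint and recall at tf = 0.30 drops to ~0.8; the analysis
scripts show this regime.

## Shared/unique classification and burden

Matching is exact on (chromosome, position, ref, alt) — allele-level, the
stricter reproducible choice. Percentages are relative to each sample's
own total and reported to 1 decimal. Mutational burden divides the SNV
count by a callable genome size of 3000 Mb (whole-genome callable space);
every published per-sample burden in the bundled cohort table equals
count/3000 rounded to 2 decimals, which fixes the default denominator. The
annotator handles single-interval CDS models with strand and frame under
the standard genetic code; it is a toy-model analogue of database
annotation, not a transcript-aware annotator.

## Signatures

Catalog channels are ordered substitution-major (C>A, C>G, C>T, T>A, T>C,
T>G), flanks lexicographic. De novo extraction is multiplicative-update
NMF under the Frobenius objective: stop when the relative objective change
over 10 iterations falls below 1e-6 or at 2000 iterations; best of 20
seeded random restarts; the objective is asserted non-increasing every 10
iterations. Signature columns are normalised to sum to 1 with scale
absorbed into contributions, and ordered by total contribution for
determinism. The rank k is user-specified (no automatic selection).
Refitting is scipy NNLS; relative contributions are h/Σh with the residual
attached. The bundled reference profiles are synthetic illustrative shapes
(CpG-deamination-like, TpC-editing-like, flat, T>C-heavy, C>A-heavy)
generated in code; any real 96 x r reference table can be supplied as a
TSV. Cosine-similarity tables against real catalogue signatures are not
reproducible without the original cohort data; only the machinery is
tested.

## Fragmentomics

Fragment length is the outer template span (|TLEN| semantics); fragments
are capped at 2000 bp. A fragment is somatic iff it covers a final somatic
plasma variant and carries the alt allele. A fragment spanning two
variants counts once per variant for the shared/unique ratios but once in
the somatic total (`multi_variant="per_variant"`); the alternative
(`"once"`, shared takes priority) makes shared + unique = somatic exact.
Enrichment ratios with empty denominators are reported as missing, never
as infinities. The di-nucleosome window is 300–350 bp inclusive. Because
peak location by histogram argmax has a sampling error of a few bp for the
broad di peak (sd 25), tests locate that peak by the mean length in a
symmetric window; the mono peak's argmax is stable to ±2 bp at 1e5
fragments and is reported as-is.

## CNA screen

Fragment starts are counted per half-open bin (1 Mb for real genomes;
10 kb for the megabase-scale synthetic genome, chosen to keep ~100 bins),
keeping mapping quality ≥ 20 when present. Ratios are
log2((c/median c)/(n/median n)); zero-normal bins are masked. The
segmenter flags bins deviating by ≥ 3 robust SDs (1.4826 x MAD) and merges
same-direction runs of ≥ 3 bins — a transparent stand-in for HMM-based
callers, because the question asked here is detectability, not fine
breakpoint placement. Tumour fraction inverts the diploid mixture for the
largest-magnitude segment: tf = 2(2^r − 1) for a gain, 2(1 − 2^r) for a
loss. Power at 10,000 fragments/bin (the scaled-down stand-in for the
~3 x 10^5 reads a 1 Mb bin collects at 100x): a 10-bin single-copy gain is
found in ≥ 9/10 seeds at tf = 0.30 and ≤ 1/10 at tf = 0.005 — the
screen's version of the negative plasma CNA result at sub-percent tumour
fraction. The tf estimator is validated as the simulator's inverse in the
mean over seeds (per-seed estimates at 1000 reads/bin carry a selection
bias of up to ~0.03 because only bins past the z threshold enter a
segment).

## Pipeline

`pipeline.run_all` chains the stages under one YAML config with strict
unknown-key rejection and a single master seed; the normalised config is
echoed next to the outputs and two runs with the same config are
byte-identical (timestamps appear only in logs). The `cfplasma` CLI is a
thin layer over the same functions.

## Problem sizes

Defaults are chosen so the full test suite (including the exhaustive
Fisher check over all 2x2 tables with ≤ 60 reads and four end-to-end
simulated studies) completes in well under two minutes on one CPU:
megabase genomes, hundreds of truth mutations, ~5 x 10^5 fragments, 100
CNA bins, 10-seed power loops. These sizes are the package's own test
design; the algorithms themselves stream over tables and scale to real
whole-genome inputs.

## Known limitations

Single-patient pipeline (no panel of normals, no cross-patient
borrowing); SNVs only; no database annotation; the CNA screen has no
GC/mappability correction and assumes diploidy; signature extraction has
no rank selection or bootstrap stability analysis; the simulator's
idealisations listed above.
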