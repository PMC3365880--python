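# Methods

This note documents the models behind `lairkit`, the parameters that
matter, what the synthetic data does and does not emulate, and the design
choices made where the design was genuinely open.

## Signal model

A tumour sample is treated as a two-component mixture of tumour cells
(fraction `f`) and diploid stromal cells.  For a genomic region in allelic
state `(a, b)` (a copies of the major, b of the minor parental allele), the
expected array signals at a reference-heterozygous SNP are

    R*    = (f·(a+b) + 2·(1−f)) / 2        (diploid-relative total intensity)
    LAIR* = (f·b + (1−f)) / (f·a + (1−f))  (lesser allele intensity ratio)

so `[AB]` gives (1, 1) at any purity, `[A]` gives (0.5, 0) at `f = 1` and
LAIR `1 − f` in general, and `[AAB]` gives LAIR 1/2 at `f = 1` —
intermediate values are the fingerprint of allelic imbalance.  At
reference-homozygous SNPs only R is informative, and LAIR is left
undefined.

The exact ratio definition used here — minimum over maximum of the two
allele intensities after per-allele, per-marker median scaling against a
diploid reference panel — is one of several conventions that satisfy the
qualitative anchors (≈1 balanced, ≈0 LOH, intermediate imbalance); whether
allele scaling is better done per sample is not decidable from desk data
and is noted as a convention.  Reference heterozygosity comes from the
reference panel's genotypes, not from a matched normal, matching an FFPE
workflow in which no matched normal is available.

## Normalization and the scale degeneracy

R is computed marker-by-marker against the median reference intensity and
then rescaled so the sample's autosomal median is 1.  This
self-normalization makes R invariant to the sample's overall intensity
level (hybridization efficiency, DNA input), but deliberately discards the
absolute dosage: an all-`[A]` and an all-`[AA]` genome produce identical
tracks.  Calibration therefore searches an intensity-scale grid `s`
(0.25–3.0, step 0.025) jointly with the state assignment, and the
flow-cytometric DNA index selects among scale-degenerate solutions (see
below).

## Segmentation

Per chromosome, recursive binary splitting maximizes a two-sample t-like
statistic; a split is accepted when its statistic exceeds the permutation
null (1000 seeded permutations of the track, p < 0.01, compared against
the permuted maxima so the selection of the best split is accounted for).
Accepted splits are then pruned by the sd-undo rule: a changepoint survives
only if its flanking segment means differ by at least 3 track-noise units
(noise estimated as 1.4826·median|first differences|/√2, immune to the
segment structure).  The procedure runs independently on the R track and on
the defined-LAIR subsequence; breakpoints are pooled, which is what lets a
copy-neutral LOH boundary — invisible in R — be found through LAIR.
Segments shorter than `min_markers` (default 10) are merged into the
neighbour with the closer mean; summaries are medians, which are robust to
the residual outliers of clipped LAIR values.

## DNA-index-calibrated state assignment

Given segments with summaries (R, LAIR), candidate states up to
`max_copies = 6` (covering the `[AAAA]`/`[AAABBB]` vocabulary), a
tumour-fraction grid, and the measured DNA index `DI`, the caller minimizes

    Σ_seg w_seg·[((s·R − R*)/σ_R)² + ((LAIR − LAIR*)/σ_L)²]
      + λ·|index(assignment) − DI|

with length weights `w_seg` and σ estimated robustly from within-segment
median absolute deviations.  The implied index — the DNA index computed
from the summed allele copies, `Σ w·(a+b) / 2Σw` — is linear in the
assignment, so the coupled problem is solved exactly on each side of the
penalty kink by a Lagrangian sweep over slopes in `[−λ, λ]`, followed by a
single-segment exchange pass on the exact objective; on small instances the
result matches exhaustive enumeration (tested).  Ties break toward fewer
total copies.

The penalty weight is `λ = 5` per unit of DNA index.  The term has one
job: to break the scale degeneracy, for which any positive weight suffices
because degenerate assignments have identical residuals.  A large weight is
actively harmful — the flow DI is printed to two decimals and the implied
index of the true karyotype can legitimately sit a few hundredths away, and
a weight of 50 was observed to buy DI agreement by bumping whole
chromosomes into wrong states (`[AA]` → `[AAA]`), so the default stays
small.  Segments whose accepted state differs from their residual-only
optimum are flagged (`di_resolved`), marking exactly the calls that the DNA
index, not the array, decided.

Bimodal samples (two tumour populations in one DNA extract) are calibrated
once per population DI; the dominant population's result is the primary
output.  Fractional subclonal states are out of scope.

## Flow-cytometry model

Gated DNA histograms are fitted by weighted EM over bin centers with, per
candidate population: a G0/G1 Gaussian (mean μ, sd σ), a paired G2/M
Gaussian pinned at 2μ with sd 2σ (constant CV) and free weight, and a flat
S-phase bridge on [μ, 2μ]; a uniform background absorbs debris.  The
population count (1–3) is selected by BIC over the event total;
populations below 5% of events are dropped.  The G2/M mean is re-estimated
jointly with its G0/G1 partner (G2/M events inform μ at half their
position).  The S-phase component is part of the model because without it
the extra-population models win BIC by misusing a wide Gaussian to fit the
bridge; with it, a 15% G2/M shoulder is correctly absorbed by the one-
population model while a genuine doubled subpopulation (30% of events,
with its own cell cycle) is detected.  The population-significance rule of
the commercial modelling software used in the original workflow is not
public; BIC selection is a replacement, not a reconstruction.

DNA indices are tumour G0/G1 peaks divided by the stromal G0/G1 peak, which
makes them invariant to the fluorescence scale.  The dominant population is
the largest event fraction; at a tie the lower DI wins, a deterministic
convention consistent with reporting the near-haploid population as
dominant.  A `doubling_pairs` check flags a second population within 10% of
twice the lowest DI — the endoreduplication signature.

## Phenotype rules

From calibrated calls: the homozygous fraction is the autosomal length in
states with `b = 0` over the called autosomal length; ≥ 0.5 raises the
near-homozygous umbrella flag; the dominant DI then separates near-haploid
(< 0.9) from endoreduplicated (≥ 0.9) — observed near-haploid DIs span
0.53–0.73 and endoreduplicated dominant DIs 0.98–1.28, and 0.9 bisects the
gap.  Chromosome-7 retention requires more than half of chromosome 7's
length heterozygous; with no chromosome-7 calls it is *undetermined*, never
silently false.  From published summary rows, the chromosome-6 state stands
proxy for genome-wide LOH (these tumours always lose heterozygosity on
chromosomes 3, 6 and 22 when near-homozygous); both routes agree on
simulated data (tested).  Neither 0.9 nor 0.5 is a published cut-off; both
are declared conventions.  Percentages are rounded half-up to whole
percent, matching the reporting style of the source tables.

## Synthetic data: what it emulates and what it does not

`simulate_karyotype` produces whole-chromosome scenario karyotypes
(near-haploid with a retained heterozygous set always containing
chromosome 7, its endoreduplicated double, diploid, chromosome-22-loss,
near-tetraploid), optionally with a partial-chromosome retained segment.
`simulate_array` places markers uniformly at a chosen density (1/Mb
emulates a ~3000-marker genome-wide panel; 10/Mb a high-density one),
draws reference genotypes (heterozygous with p = 0.33), and emits allele
intensities whose derived R and LAIR equal the closed forms exactly at zero
noise — the noise model is Gaussian on R (σ_R = 0.08) and on LAIR
(σ_L = 0.05, clipped to [0, 1]), plus a per-sample log-normal intensity
scale (sd 0.10) and off-allele crosstalk at homozygous markers (2% of the
per-copy gain).  `simulate_flow_histogram` draws multinomial event counts
over G0/G1, S, G2/M and debris components per population (S carries half
the G2/M weight, a fixed convention) with a shared stromal reference at
relative position 1.0.

Not emulated: bead-level intensities, GC waves, batch effects, genotyping
error, marker-density variation along the genome, aggregates and
compensation artefacts in the histograms, and subclonal fractional copy
number.  Passing tests on this generator therefore demonstrate the
correctness of the inference given the stated signal model, not robustness
to every artefact of real arrays; the qualitative anchors of the signal
model (balanced ≈ 1, LOH ≈ 0, imbalance intermediate; DI doubling under
endoreduplication) are the properties the real analysis relies on.

## Problem sizes and numerical choices

Recovery tests run twenty simulated tumours at ~3000 markers each
(density 1/Mb, purities 0.7 and 1.0), a size at which segment medians
pin each chromosome's state while the whole suite stays interactive;
histogram fits use 20000 events and 4% CV, matching a good FFPE
preparation.  Degenerate inputs are handled explicitly: chromosomes with
fewer markers than `min_markers` become single whole-chromosome segments
with a warning rather than failing; LAIR at markers with zero scaled
intensity is flagged missing, not an exception; histograms with all events
in one bin raise a fit error.  All randomness flows through seeded
generators; identical seeds give bit-identical outputs.

## Known limitations

* Purity is searched on a grid, not estimated jointly with a likelihood;
  heavily contaminated samples (f < 0.5) are outside the default grid.
* The caller assigns one integer state per segment; balanced mixtures of
  two populations (e.g. `[A]` + `[B]`) appear as a one-copy heterozygous
  segment and are not deconvolved.
* Male X is intensity-only (LAIR undefined on hemizygous X), and Y is not
  modelled.
* The sd-undo threshold and permutation count trade sensitivity for false
  splits at the default marker density; much sparser panels may need a
  larger `min_markers`.
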