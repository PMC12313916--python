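# Methods

This note records the models, conventions and numerical choices behind
`stopswitch`, and what the simulators do and do not emulate.

## Coordinates and conventions

* Genomic/CDS coordinates are 0-based half-open on the plus strand inside
  the library; reports use 1-based CDS coordinates and 1-based codon
  indices (codon *k* occupies CDS nucleotides 3*k*−2..3*k*).
* Protospacer positions are 1-based from the PAM-distal (5′) end of the
  spacer, so "A7" is an adenine at spacer position 7. The PAM lies
  immediately 3′ of the protospacer on the protospacer strand.
* PAM distance: "*d* bases upstream of the PAM" is read as
  *d* = spacer_length − target_position, i.e. the number of bases strictly
  between the target and the first PAM base. Under this convention a target
  "12–16 bases upstream" of the PAM on a 20-mer sits at protospacer
  positions 4–8; it reproduces the packaged install guide exactly (target
  at position 5, fifteen intervening bases). The inclusive alternative can
  be expressed by overriding a profile's window.
* Guide RNA input may contain U; it is normalized to T on ingest. The
  standard genetic code (stops TAA/TAG/TGA) is used throughout; codons
  containing N translate to X, and an N in a candidate PAM window never
  matches — an unknown base is not assumed to satisfy a constraint.

## Editor profiles

| profile | edit | window | PAM | spacer |
|---|---|---|---|---|
| ABE8e-Sp | A>G | 3–10 | NGG | 20 |
| BE4max-Sp-NG | C>T | 4–8 | NG | 20 |
| BE4max-Sp-NGG | C>T | 4–8 | NGG | 20 |
| SaABE8e | A>G | 4–12* | NNGRRT | 21 |
| SauriABE | A>G | 4–12* | NNGG | 21 |

*The Sa and Sauri windows are package defaults, not experimentally
characterized ranges; they are flagged `window_assumed` on the profile and
in run manifests, and can be overridden per call or via a YAML profile
file. The install screen defaults to the NG-PAM CBE profile (the relaxed-PAM
editor variant), with the NGG profile available; reports state which
profile produced each candidate.

## Stop-switch screen

Only CGA, TGG and CAA/CAG can become a stop through a single C>T edit
(TGG does so via the antisense strand, where the sense G>A change reads as
C>T, and admits two products, TAG and TGA). The screen considers every such
edit at every codon, retains candidates with at least one install guide
under the chosen profile, and designs reversion guides against the derived
mutant: the installed T's complementary adenine is the ABE target, so
reversion guides always sit on the strand opposite the installing edit.
Bystander counting includes every in-window editable base other than the
target regardless of coding consequence; consequences (synonymous /
missense / nonsense / stop-loss) are annotated for reporting only.
Ranking is ascending by the minimum bystander count over the default revert
profile's guides, then by the number of orthologue profiles with a valid
reversion guide, then by 5′-most codon; candidates with no reversion guide
under any profile are retained but ranked last. No hard positional cutoff
("near the 5′ end") is applied; `--max-codon` exposes one.

On the packaged EGFP sequence this screen ranks Q81 (CAG→TAG, CDS 241)
first with zero bystander adenines in the ABE8e window — the three
reversion guides place the target at positions 7, 8 and 9. Codons 70 and
95, although glutamines, have no NG(G) PAM placing their target cytosine in
the 4–8 window under the distance convention above, which is why the screen
reports them only under relaxed constraints.

## Amplicon quantification

Reads are filtered on the arithmetic mean of their integer Phred scores,
kept strictly above the threshold (default Q > 30; a mean of exactly 30 is
removed). Alignment is semi-global — free end gaps on the amplicon
overhangs — with match +2, mismatch −3, gap open −5 (a length-1 gap costs
−5), gap extend −2; both orientations are scored and the better one kept,
preferring the plus strand on ties; a read scoring below 0.4 × 2 × length
is dropped as unalignable. These scoring values are a package choice, fixed
and echoed in result metadata.

The quantification window spans protospacer positions
center ± halfwidth (defaults 10 ± 20) mapped to amplicon coordinates and
clipped; the defaults always cover a full 20-mer protospacer. Reads must
cover the entire clipped window; under the default
`exclude_window_indels` policy reads with an insertion or deletion
overlapping the window are excluded from the substitution tally (so every
window column sums to the quantified-read count), while `count_all` keeps
them. The editing level is the percentage of quantified reads carrying the
converted base at the target position; with zero quantified reads it is
reported as missing, never as 0.

For throughput, substitution-only reads are placed by exact 16-mer seeding
at three read offsets followed by a vectorized mismatch count; the full
affine dynamic program (Biopython's `PairwiseAligner`) is used whenever
seeding fails or the best gap-free placement mismatches more than 10% of
the read. For reads whose optimal alignment is gap-free the two routes give
identical placements; the tests check the DP against an independent Gotoh
implementation on reads with substitutions and indels.

## ddPCR copy number

Each channel's occupancy is Poisson-corrected, λ = −ln(1−p), with
saturation (p = 1) an error rather than a clamped value. The
target:reference ratio cancels partition volume, so volume is not an
input. The 95% CI uses a Wilson score interval on each channel's positive
fraction, mapped through the (monotone) Poisson correction, then combined
on the log-ratio scale by the delta method. The Wilson/delta choice is
stable at low and high occupancy where a Wald interval on p degenerates.
Copies per diploid genome multiply the ratio by the reference gene's copies
per diploid genome (default 2, configurable).

## Activation model

A cell with *n* reporter copies, each independently edited with probability
*q*, is positive when at least one copy is edited:
*f* = 1 − (1−*q*)^*n*, computed via `expm1`/`log1p` with the *n* = 1
identity returned exactly; the inverse is *q* = 1 − (1−*f*)^(1/*n*).
Since *f* ≥ *q* (equality at *n* = 1 or *q* ∈ {0,1}), allele-level editing
measured by sequencing is a lower bound on the positive-cell fraction
measured by flow cytometry for a multi-copy reporter. Independence of
copies within a cell is an assumption: in reality all copies of a cell see
the same editor dose, which correlates outcomes and pulls *f* below the
independent prediction toward *q*; the model therefore brackets the
relationship rather than predicting it exactly. Near *f* → 1 the inverse is
ill-conditioned in floating point (once *f* rounds to 1 the information
about *q* is gone), which matters only above ~*f* = 1 − 1e−9.

## Simulators

`simulate_amplicon_reads` draws read start positions uniformly subject to
covering the full quantification window (amplicon sequencing covers its
locus by design), edit labels i.i.d. Bernoulli(*q*), per-base errors
uniformly at rate ε substituting to one of the three other bases, and
per-base Phred scores Normal(mean, SD) truncated to [2, 41] and rounded.
Defaults: ε = 0.001, quality mean 37 (SD 3), and a 5% share of low-quality
reads with mean 25 that deterministically fail the Q > 30 filter,
exercising the filter path. Read lengths are drawn uniformly from 220–280
cycles unless fixed. Bystander co-edits are independent of the target edit
by default; a linkage option restricts them to edited reads, since
deamination is processive on a single molecule. Not emulated: quality-by-
cycle decay, context-dependent error, PCR duplicates/jackpots, and indel
errors — so passing recovery tests demonstrates estimator correctness under
substitution-type noise, not robustness to indel-rich chemistry.

`simulate_ddpcr` draws each partition's occupancy Poisson(λ) per channel
independently (positive iff ≥ 1); `simulate_cell_population` draws
per-cell, per-copy Bernoulli edits. All generators take a seed, are
byte-reproducible under it, and echo seed and configuration in their truth
manifests.

## Problem sizes in the test suite

The statistical checks run at the sizes the estimators are meant for:
editing-fraction recovery over 20 seeds × {3%, 30%, 98%} editing at 10,000
reads with ε = 0.001 (tolerance 3 binomial SE, ≥ 19/20 seeds); ddPCR CI
coverage over 100 seeds at 20,000 partitions and a true ratio of 2.97
(≥ 90/100); activation-model recovery on 100,000-cell populations at six
copies. Enumeration is verified against brute force on 50 random 300-nt
ORFs, and edit/reversion round trips on random ORFs restore the input
exactly.

## Known limitations

* The screen designs guides from sequence constraints only; it does not
  predict editing efficiency, chromatin accessibility, or off-targets.
* Quantification handles single-base substitutions in single-end reads; no
  paired-end merging, UMIs, or large-variant calling.
* The ddPCR model assumes equal partition volumes and perfect
  classification of positives; threshold calling from raw fluorescence is
  out of scope.
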