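# stopswitch

Design and readout of base-editor-switchable premature stop codons.

`stopswitch` implements the computational workflow behind a "GFP-on" style
fluorescent reporter: a constitutively expressed EGFP transgene is silenced
by installing a premature termination codon (PTC) with a cytosine base
editor (CBE), and fluorescence is restored only when an adenine base editor
(ABE) corrects the nonsense mutation. The package is aimed at genome-editing
labs designing such switchable reporters and quantifying their readouts:

* **Design** (`stopswitch.design`) — screen an ORF for the four sense codons
  one C>T edit away from a stop (CGA, TGG, CAA, CAG), enumerate install
  guides under PAM and editing-window constraints, design the ABE reversion
  guides, annotate bystander bases, and rank candidates by reversion
  cleanliness. Shipped editor profiles: SpCas9 ABE8e (A>G, window 3–10,
  NGG), BE4max-SpCas9 (C>T, window 4–8, NG or NGG), and the single-AAV-sized
  SaCas9 (NNGRRT) and *S. auricularis* Cas9 (NNGG) ABEs.
* **Quantification** (`stopswitch.quant`) — editing frequencies from
  single-end amplicon sequencing: reads are kept when their mean Phred score
  exceeds 30, aligned semi-globally to the amplicon on the better-scoring
  strand, reads with indels overlapping the quantification window are
  excluded, and the editing level is reported as the percentage of
  quantified reads carrying the converted base at the target position.
* **Copy number** (`stopswitch.copynumber`) — digital-PCR Poisson
  correction λ = −ln(1−p) per channel, the volume-free target:reference
  ratio with a Wilson/delta-method 95% CI, and copies per diploid genome.
* **Activation model** (`stopswitch.copynumber`) — for a reporter present in
  *n* copies per cell, each edited independently with probability *q*, the
  positive-cell fraction is *f* = 1 − (1−q)^*n* ≥ *q*: with a multi-copy
  reporter the percentage of edited alleles is generally lower than the
  percentage of fluorescent cells. The inverse *q* = 1 − (1−f)^(1/*n*)
  recovers allele-level editing from flow cytometry.
* **Simulators** (`stopswitch.simulate`) — ground-truthed generators for
  amplicon FASTQs (220–280 nt reads, target and bystander edits, per-base
  error, Phred model), ddPCR partition counts, and multi-copy cell
  populations.

The canonical EGFP CDS, its Q81X (c.241C>T) mutant, and the full printed
oligo set (install spacer, three correction sgRNAs, Sa spacer, ddPCR
primers/probe) are packaged as verified fixtures.

## Worked example

```python
import stopswitch as sw

wt = sw.wt_egfp_cds()
ranked = sw.rank_candidates(
    sw.enumerate_stop_switch_sites(wt, sw.get_profile("be4max-ng"))
)
top = ranked[0]
print(top.codon_index, top.wt_codon, "->", top.installed_codon)
# 81 CAG -> TAG
print(top.install_guides[0].spacer)
# GAAGCAGCACGACTTCTTCA        (target C at protospacer position 5)
for g in top.reversion_guides["ABE8e-Sp"]:
    print(g.spacer, g.target_position, g.pam_seq, len(g.bystander_positions))
# CGTGCTACTTCATGTGGTCG 7 GGG 0
# TCGTGCTACTTCATGTGGTC 8 GGG 0
# GTCGTGCTACTTCATGTGGT 9 CGG 0
```

The best candidate converts glutamine codon 81 (CAG) to TAG via a C>T at
CDS position 241; the three reversion guides place the stop's adenine at
protospacer positions 7, 8 and 9 of the ABE8e window with zero bystander
adenines.

Simulate a 30%-edited amplicon run and quantify it:

```python
mut = sw.q81x_mutant_cds().seq
guide = sw.locate_guide(mut, "CGTGCTACTTCATGTGGTCG", 7)
cfg = sw.AmpliconSimConfig(amplicon=mut, guide=guide,
                           edit_fraction=0.30, n_reads=10_000, seed=1)
reads, truth = sw.simulate_amplicon_reads(cfg)
print(sw.quantify_sample(reads, mut, guide).summary())
# reads total            10000
# pass mean-Q filter     9475
# quantified             9475
# unalignable            0
# window-excluded        0
# target position (1-based amplicon) 241
# editing percent        30.0
```

The estimate (30.0%) matches the simulated truth (29.9% of reads drawn
edited). Copy number from partition counts measuring a 3:1 target:reference
ratio:

```python
cn = sw.copies_per_genome(sw.PartitionCounts(10_000, 4880, 2000))
print(cn.summary())
# lambda(target)    0.6694
# lambda(reference) 0.2231
# ratio             3.000 (95% CI 2.847-3.161)
# copies/diploid    6.00 (x2 reference copies)
```

A homozygous animal carrying three transgene copies per reference-gene copy
holds six copies per diploid genome, so even 5% allele-level editing lights
up `1 - 0.95**6` ≈ 26% of cells (`sw.cell_positive_fraction(0.05, 6)`).

The same operations are available from the shell:

```bash
stopswitch design --cds egfp.fa --install-profile be4max-ng -o candidates.tsv
stopswitch quant --fastq reads.fastq --amplicon q81x.fa \
    --spacer CGTGCTACTTCATGTGGTCG --target-pos 7
stopswitch ddpcr --partitions 10000 --pos-target 4880 --pos-ref 2000
stopswitch model --copies 6 --allele-fraction 0.05
stopswitch dose --a 1e12 --b 2.7e10
stopswitch simulate reads --seed 1 -o simdir
```

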