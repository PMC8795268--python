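# Methods

## The problem and the approach

Hybridization between the endangered buffy-tufted-ear marmoset *Callithrix
aurita* and the invasive congeners *C. jacchus* and *C. penicillata* can be
demonstrated with two uniparental markers that disagree about the species:

* **Patriline (Y chromosome).** The *SRY* amplicon of *C. aurita* carries a
  fixed 9-bp deletion, `117_125delTAAGTATCG` in 1-based amplicon coordinates.
  The deleted allele yields a 196-bp product, the insertion allele 205 bp, so
  the patriline can be read either from the amplicon sequence or from a
  capillary-electrophoresis fragment size.
* **Matriline (mtDNA).** The ~445-bp *COX2* amplicon falls into a small set of
  species-specific haplotypes (HCa — *aurita*; HCj — *jacchus*; HCp, HCp2 and
  the reference-only HCp1 — *penicillata*). Assigning a sample's read to its
  closest panel haplotype identifies the maternal species.

A sample whose patriline and matriline species disagree is a **confirmed
interspecific hybrid**; concordant markers show only that *both uniparental
lineages* trace to one species — with two markers this cannot distinguish a
pure individual from a backcross or hybrid×hybrid offspring, so the category
names say "lineages" and never claim a generation (F1 vs later).
SRY amplification is **never** used to infer sex: marmoset twins exchange
hematopoietic stem cells through placental anastomoses, so females routinely
amplify Y loci (chimerism). Sex always comes from the metadata.

## Marker calling

**In-silico PCR.** A product is reported wherever the forward primer matches
the plus strand and the reverse primer's reverse complement matches
downstream, each with at most `max_mismatches` (default 2) and no mismatch in
the 3'-terminal 3 bases (polymerase extension is intolerant there). Product
sizes include both primer footprints.

**Sequence-based indel call.** The amplicon is globally aligned to the
insertion-type reference (match 2, mismatch −3, gap open −5, extend −0.5,
free end gaps). The call is *deletion* when the alignment contains exactly one
internal gap of exactly the motif length overlapping the variant span —
overlap rather than exact placement, because repeats at an indel boundary make
shifted gap placements sequence-equivalent; *insertion* when the span is fully
covered and equals the motif; otherwise *ambiguous*. Reads below 90% identity
outside the span, or covering less than half of the reference, are rejected as
"not an SRY amplicon".

**Size-based indel call.** A fragment size is matched to the expected peaks
(196/205 bp) within a symmetric tolerance, default 1.5 bp — generous against
sub-bp capillary sizing error yet far below half the 9-bp allele gap. Sizes
are kept real-valued and binned by the window, not rounded first (rounding
then binning double-counts the boundary). The constructor rejects tolerances
of half the gap or more, for which the windows would overlap.

**Haplotype assignment.** Queries are projected onto panel coordinates by
global pairwise alignment to their closest haplotype (free end gaps; ref
positions the query does not cover become `N`), then assigned by minimum
Hamming distance over non-N positions. Both strands are tried and the smaller
distance kept; a strand must reach 85% identity and cover ≥50% of the locus to
be considered (the coverage floor discards the degenerate short alignments a
wrong-strand read produces under free end gaps). Exact distance ties between
labels of one species report the label `ambiguous` but keep the species; ties
across species leave the matriline `undetermined` — never broken arbitrarily.

**Novelty threshold.** A best distance above `novelty_threshold` is reported
as `novel` for manual review instead of being forced into a species. The
default is **10** mismatches: per-read error counts from Sanger-quality data
are roughly Poisson with mean ~2.2 at 0.5% per-base error over 445 bp, so a
cutoff must sit several standard deviations above that mean or a few percent
of perfectly ordinary reads get flagged (a cutoff of 5 flags ~3%); 10 keeps
the false-novel rate below 10⁻⁴ per read while remaining at or below the
smallest between-species haplotype distance in the default panel, so truly
foreign matrilines are still caught.

## Alignment statistics

* Site classes: a column is polymorphic when ≥2 non-missing states occur;
  biallelic columns are typed transition/transversion by the chemical
  definition (two published changes labelled "transversions", A>G and G>A, are
  transitions by that definition and are typed as such here); columns with >2
  states are flagged `multiallelic` and excluded from single-change
  annotation.
* A column is **diagnostic** for species S iff all S sequences share a state
  found in no other species. With exactly two species a fixed difference is
  diagnostic for both; counts are per species, not a partition of columns.
* **Haplotype diversity** Hd = n/(n−1)·(1 − Σpᵢ²), variance by Nei (1987)
  eq. 8.12. **Nucleotide diversity** π = n/(n−1)·Σᵢ<ⱼ 2xᵢxⱼdᵢⱼ per site, with
  pairwise deletion of N/gap positions and variance by Nei (1987) eq. 10.7.
  Both implementations are tested against pair-enumeration oracles to 1e−12.
* Coding effects translate the two allele codons (majority codon among the
  carriers of each allele) under the **vertebrate mitochondrial code**
  (NCBI table 2) — biologically forced for COX2, though never stated in the
  source data. The reading-frame offset is a required input; the simulator
  emits frame 0 by construction. Introduced stop codons are annotated (`*`),
  not fatal. Allele order in `XposY` follows first occurrence in the
  alignment, so it reads reference-first when a reference leads the file.
* The p-distance + neighbor-joining clustering is deliberately lightweight
  plumbing for sanity-checking haplotype groupings (negative NJ branch
  lengths are clamped to zero); it is not a substitute for model-based
  phylogenetic inference, which is out of scope.

## The simulator

`synthetic_data` reproduces the *statistical structure* the analysis assumes,
not molecular evolution:

* Background sequence is i.i.d. uniform over {A,C,G,T}; polymorphic positions
  are sampled without replacement; derived states are transitions with
  probability 0.8 (the observed mutational bias), otherwise a random
  transversion.
* The default panel has 5 haplotypes (HCa, HCj, HCp, HCp2, HCp1) over 445 bp
  with exactly 22/9/1 diagnostic sites for aurita/penicillata/jacchus and 5
  extra non-diagnostic sites placed as private states on HCp2 (3) and HCp1
  (2), totalling 37 polymorphic sites. HCp1 emulates the reference-only
  penicillata haplotype and never appears in cohorts. Consequence: the
  smallest cohort-relevant separation is 2 sites (HCp vs HCp1), which still
  leaves haplotype-assignment errors negligible at the error rates simulated
  (a tie needs a specific base at one of 2 specific sites: ~3·10⁻³ per
  HCp-read at 0.5% error).
* The SRY insertion allele is 205 bp with the primer sequences at its termini
  and the motif at positions 117–125; the deletion allele is that sequence
  with the motif excised (196 bp), an exact constructive identity.
* The default cohort mirrors the study design: 33 samples — 18 putative
  hybrids (15 M/3 F; haplotypes HCj×5, HCp×7, HCp2×4, HCa×2, all with the
  SRY deletion) plus 6/5/4 species controls. Reads get i.i.d. per-base errors
  (default 0), fragment sizes get Gaussian jitter (σ default 0.5 bp), and
  females amplify SRY with a configurable chimerism probability (default 1).
* Everything is driven by one integer seed through independent child streams,
  so panels, alleles and cohorts are individually reproducible.

What the simulator does **not** emulate — and what passing recovery tests
therefore do not show about real data: coalescent genealogies, recombination,
indel polymorphism in COX2, NUMTs, base-composition and codon structure,
alignment artifacts from real Sanger traces, or contamination. Recovery tests
demonstrate that the pipeline is a correct decoder of its own generative
model, with noise robustness quantified under that model only.

## Numerical and design choices

* Coordinates are 1-based inclusive in all user-facing notation (HGVS-style,
  matching `117_125delTAAGTATCG`); internal indexing is 0-based half-open with
  conversion at the boundary.
* `N` is accepted in sample reads, never in panel references.
* The source tables give the COX2 amplicon as "ca. 455 bp" in one place and
  445 bp elsewhere; the package uses 445 throughout and records the
  discrepancy here rather than resolving it.
* One control sample (Cj3) is printed male in the study's table but listed
  among the five female controls in its text; the packaged fixture follows
  the text (Cj3 = F). No cohort-level result depends on this.
* The published diversity values (Hd = 0.8205 ± 0.0356, π = 0.0313 ± 0.0159)
  cannot be recomputed because the underlying 33 sample sequences were never
  deposited and the sample composition entering the estimate is ambiguous.
  Direct evaluation of Nei's Hd on the published haplotype counts
  {HCa: 8, HCj: 10, HCp: 11, HCp2: 4} (n = 33) gives **0.7462**, which the
  tests pin as an oracle value while explicitly noting it differs from the
  printed 0.8205. The printed values are treated as context, not targets.
* Cohort proportions are reported over two denominators (all samples and
  confirmed hybrids only) because the published "almost 60% / 30% / <10%"
  matches neither exactly (11/18 ≈ 61%, 5/18 ≈ 28%, 2/18 ≈ 11%).
* The reciprocal cross (invasive patriline × aurita matriline) is absent from
  the study sample but classified `confirmed_hybrid` too — the rule must be
  total — with a direction string that distinguishes it.

## Problem sizes

The test suite and acceptance script run at the study's own scale: the 33-
sample packaged cohort, 445-bp loci, 5-haplotype panels, plus one 200-sample
simulated cohort for the noise-robustness check and batteries of 20–100
randomized small cases for the brute-force oracles. The full suite completes
in well under a minute on one CPU.

## Known limitations

* Uniparental markers cannot resolve hybrid generation or admixture
  proportion; concordant-marker samples are genuinely undecidable between
  pure and backcrossed.
* The haplotype caller assumes a gap-free panel over the amplified region;
  COX2 indel variation would require extending the projection logic.
* In-silico PCR is combinatorial matching only — no melting temperature,
  dimer or secondary-structure modeling.
* The NJ tree is a clustering diagnostic, not an inference of phylogeny.
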