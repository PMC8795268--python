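# callihyb

Dual uniparental-marker hybrid-ancestry analysis for *Callithrix* marmosets.

Hybridization between the endangered buffy-tufted-ear marmoset *Callithrix
aurita* and the invasive *C. jacchus* / *C. penicillata* can be demonstrated
genetically when a sample's two uniparental markers disagree about the
species. `callihyb` implements that analysis as a tested pipeline for
conservation geneticists and molecular ecologists:

* **Patriline** — genotype the diagnostic 9-bp *SRY* indel
  (`117_125delTAAGTATCG`, fixed in *C. aurita*) from amplicon sequence or
  from capillary fragment size (196 bp deleted vs 205 bp insertion allele),
  including in-silico PCR with the assay's primer pair.
* **Matriline** — assign the ~445-bp mitochondrial *COX2* amplicon to a
  reference haplotype panel (HCa, HCj, HCp, HCp2, …) by minimum Hamming
  distance after pairwise-alignment projection; the winning haplotype's
  species is the maternal lineage.
* **Statistics** — polymorphic and species-diagnostic site counts, Nei's
  haplotype diversity Hd = n/(n−1)·(1 − Σpᵢ²) and nucleotide diversity
  π = n/(n−1)·Σᵢ<ⱼ2xᵢxⱼdᵢⱼ with their standard errors,
  synonymous/nonsynonymous annotation under the vertebrate mitochondrial
  code, and a p-distance/neighbor-joining clustering.
* **Classification** — combine both markers per sample: discordant species ⇒
  `confirmed_hybrid` (with a direction string such as *invasive matriline ×
  aurita patriline*); concordant ⇒ `both_aurita_lineages` /
  `both_invasive_lineages` (pure vs backcross is deliberately not claimed);
  plus cohort summaries of the direction of hybridization.
* **Simulation** — a generator for panels, amplicons and cohorts with ground
  truth, used by the recovery tests.

Females routinely amplify *SRY* through hematopoietic chimerism (marmoset
twins share placental circulation), so the package treats Y-marker presence
strictly as lineage evidence and never infers sex from it.

The package ships the study cohort it was built around: 33 samples — 18
wild-caught putative hybrids plus 6 + 5 + 4 species controls — as small text
tables (metadata, marker states, fragment peak sizes).

## Worked example

Classify the packaged study cohort, summarizing the 18 putative hybrids:

```sh
callihyb run-all --table1 --out-dir results/table1 --group putative_hybrid
cat results/table1/report.txt
```

```
Hybrid-ancestry cohort report
=============================
samples classified:        18
confirmed hybrids:         16
both aurita lineages:      2
both invasive lineages:    0
undetermined:              0

matriline haplotype counts:
  HCa        2
  HCj        5
  HCp        7
  HCp2       4

direction of hybridization (confirmed hybrids):
  invasive matriline x aurita patriline: 16

matriline proportions over all samples / over confirmed hybrids:
  penicillata: 0.611 / 0.688
  jacchus:     0.278 / 0.312
```

Reading this: all 18 putative hybrids carry the *C. aurita*-specific *SRY*
deletion (196-bp peak), but 16 of them carry a *COX2* haplotype of an
invasive species (5 × HCj, 7 × HCp, 4 × HCp2) — each of those 16 is therefore
a confirmed interspecific hybrid, and every one descends from an
invasive-species matriline crossed into the native patriline. The remaining
2 samples (haplotype HCa) carry both uniparental lineages of *C. aurita*,
compatible with backcrossing or hybrid interbreeding.

The same pipeline runs end-to-end on simulated data with ground truth:

```sh
callihyb run-all --seed 7 --out-dir results/sim     # simulate -> genotype -> classify
callihyb simulate --seed 7 --out-dir data/sim       # just the data + manifest
```

Per-stage subcommands (`genotype-sry`, `haplotype-cox2`, `stats`, `tree`,
`classify`, `report`) operate on plain FASTA/TSV/CSV files; see
`callihyb <cmd> --help`. Example input formats:

```
# samples.tsv                                 # fragments.csv
sample_id  sex  group            locality  year        sample_id,size_bp
Csp1       F    putative_hybrid  Biritiba  2004        Csp1,196.2

# panel.yaml
locus_name: COX2
haplotype_labels: [HCa, HCj, HCp, HCp2]
species_of_haplotype: {HCa: aurita, HCj: jacchus, HCp: penicillata, HCp2: penicillata}
fasta_path: panel.fasta
```

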