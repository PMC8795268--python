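"""Simulate reference panels, amplicon sets and cohorts with known ground truth.

The generator reproduces the statistical structure the analysis assumes rather
than evolutionary realism: a ~445-bp mitochondrial locus carrying five
haplotypes (one *C. aurita*, one *C. jacchus*, three *C. penicillata*)
separated by 37 polymorphic sites of which 22/9/1 are species-diagnostic for
aurita/penicillata/jacchus; a 205-bp insertion-type SRY amplicon whose
117_125delTAAGTATCG deletion yields the 196-bp aurita-type allele; and a
33-sample cohort whose genotype composition mirrors the study design (18
putative hybrids plus 6/5/4 species controls). Every sample comes with a
ground-truth row so recovery tests can score the full pipeline.

Randomness: a single integer seed is threaded through independent child
streams per generator, so each output is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

from .cox2_haplotyping import ReferencePanel
from .errors import ConfigurationError
from .hybrid_classifier import BOTH_AURITA, BOTH_INVASIVE, CONFIRMED_HYBRID, UNDETERMINED
from .io_formats import (
    FragmentRecord,
    IndelVariant,
    PanelConfig,
    SampleRecord,
    SequenceRecord,
    write_fasta,
    write_panel_config,
)
from .sry_genotyping import DEFAULT_PRIMERS, DEFAULT_VARIANT, PrimerPair

BASES = np.array(list("ACGT"))
TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS_OF = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

INVASIVE = frozenset({"jacchus", "penicillata"})


@dataclass(frozen=True)
class CohortGroup:
    """One block of identically genotyped simulated samples."""

    group: str
    sry_allele: str  # "del" | "ins"
    haplotype: str
    n_males: int
    n_females: int


# Mirrors the study's Table-1 composition: 18 putative hybrids (15 M / 3 F)
# and 6 aurita + 5 jacchus + 4 penicillata controls.
TABLE1_MIRROR_COHORT = (
    CohortGroup("putative_hybrid", "del", "HCj", 3, 2),
    CohortGroup("putative_hybrid", "del", "HCp", 6, 1),
    CohortGroup("putative_hybrid", "del", "HCp2", 4, 0),
    CohortGroup("putative_hybrid", "del", "HCa", 2, 0),
    CohortGroup("control_aurita", "del", "HCa", 5, 1),
    CohortGroup("control_jacchus", "ins", "HCj", 3, 2),
    CohortGroup("control_penicillata", "ins", "HCp", 2, 2),
)

DEFAULT_SPECIES_HAPLOTYPES = {
    "aurita": ("HCa",),
    "jacchus": ("HCj",),
    # HCp1 emulates the GenBank-only penicillata haplotype: in the panel,
    # never sampled in cohorts
    "penicillata": ("HCp", "HCp2", "HCp1"),
}


@dataclass(frozen=True)
class SimConfig:
    seed: int
    locus_length: int = 445
    diagnostic_counts: Mapping[str, int] = field(
        default_factory=lambda: {"aurita": 22, "penicillata": 9, "jacchus": 1}
    )
    extra_polymorphic_sites: int = 5
    species_haplotypes: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_HAPLOTYPES)
    )
    transition_prob: float = 0.8
    per_base_error: float = 0.0
    fragment_sigma: float = 0.5
    chimerism_prob: float = 1.0
    sry_insertion_product_bp: int = 205
    sry_deletion: IndelVariant = DEFAULT_VARIANT
    primers: PrimerPair = DEFAULT_PRIMERS
    cohort_spec: Tuple[CohortGroup, ...] = TABLE1_MIRROR_COHORT

    def __post_init__(self) -> None:
        unknown = set(self.diagnostic_counts) - set(self.species_haplotypes)
        if unknown:
            raise ConfigurationError(f"diagnostic counts for unknown species {sorted(unknown)}")
        total = sum(self.diagnostic_counts.values()) + self.extra_polymorphic_sites
        if total > self.locus_length:
            raise ConfigurationError(
                f"{total} polymorphic sites do not fit a {self.locus_length}-bp locus"
            )
        if total < 1:
            raise ConfigurationError(
                "all haplotypes would be identical (need at least one polymorphic site)"
            )
        if not 0.0 <= self.per_base_error < 1.0:
            raise ConfigurationError("per_base_error must be in [0, 1)")
        flen = len(self.primers.forward) + len(self.primers.reverse)
        if self.sry_insertion_product_bp < flen + len(self.sry_deletion):
            raise ConfigurationError("SRY product too short for primers plus deletion motif")
        v = self.sry_deletion
        if not (len(self.primers.forward) < v.start and v.end <= self.sry_insertion_product_bp - len(self.primers.reverse)):
            raise ConfigurationError(
                "SRY deletion span must fall between the primer footprints"
            )

    @property
    def n_haplotypes(self) -> int:
        return sum(len(h) for h in self.species_haplotypes.values())

    @property
    def total_polymorphic_sites(self) -> int:
        return sum(self.diagnostic_counts.values()) + self.extra_polymorphic_sites


@dataclass(frozen=True)
class GroundTruth:
    sample_id: str
    true_patriline: str  # aurita | invasive | none
    true_matriline: str  # haplotype label
    true_class: str


@dataclass(frozen=True)
class SimulatedCohort:
    cox2_sequences: tuple
    sry_sequences: tuple
    fragments: tuple
    samples: tuple
    ground_truth: tuple


def _derived_base(ancestral: str, rng: np.random.Generator, transition_prob: float) -> str:
    if rng.random() < transition_prob:
        return TRANSITION_OF[ancestral]
    return TRANSVERSIONS_OF[ancestral][rng.integers(2)]


def simulate_panel(config: SimConfig) -> ReferencePanel:
    """Build a haplotype panel with exact diagnostic-site accounting.

    Diagnostic sites for species S carry a derived state fixed in all S
    haplotypes and absent elsewhere; extra (non-diagnostic) polymorphic sites
    are private derived states on within-species haplotypes, which also
    guarantees pairwise separation of same-species haplotypes.
    """
    rng = np.random.default_rng([config.seed, 11])
    length = config.locus_length
    background = rng.choice(BASES, size=length)

    labels = [h for sp in sorted(config.species_haplotypes) for h in config.species_haplotypes[sp]]
    species_of = {
        h: sp for sp, haps in config.species_haplotypes.items() for h in haps
    }
    seqs = {h: background.copy() for h in labels}

    positions = rng.choice(length, size=config.total_polymorphic_sites, replace=False)
    cursor = 0
    for sp in sorted(config.diagnostic_counts):
        count = config.diagnostic_counts[sp]
        for _ in range(count):
            pos = positions[cursor]
            cursor += 1
            derived = _derived_base(background[pos], rng, config.transition_prob)
            for h in config.species_haplotypes[sp]:
                seqs[h][pos] = derived

    extra_targets = [
        h
        for sp in sorted(config.species_haplotypes)
        if len(config.species_haplotypes[sp]) > 1
        for h in config.species_haplotypes[sp][1:]
    ]
    if config.extra_polymorphic_sites > 0 and not extra_targets:
        raise ConfigurationError(
            "extra polymorphic sites need a species with >1 haplotype to host them"
        )
    for k in range(config.extra_polymorphic_sites):
        pos = positions[cursor]
        cursor += 1
        target = extra_targets[k % len(extra_targets)]
        seqs[target][pos] = _derived_base(background[pos], rng, config.transition_prob)

    haplotypes = tuple(
        SequenceRecord(id=h, sequence="".join(seqs[h]), species_label=species_of[h])
        for h in labels
    )
    if len({h.sequence for h in haplotypes}) != len(haplotypes):
        raise ConfigurationError(
            "configuration yields identical haplotypes (each pair must differ at >=1 site)"
        )
    return ReferencePanel(locus_name="COX2", haplotypes=haplotypes)


def simulate_sry_alleles(config: SimConfig) -> tuple:
    """Insertion- and deletion-type SRY amplicons with primer sites at the termini.

    The insertion allele has the configured product size (default 205 bp) and
    carries the deletion motif at its notated span; removing that motif yields
    the deletion allele (default 196 bp) exactly.
    """
    rng = np.random.default_rng([config.seed, 13])
    fwd = config.primers.forward
    rev_rc = str(
        SequenceRecord(id="rsry", sequence=config.primers.reverse).reverse_complement().sequence
    )
    middle_len = config.sry_insertion_product_bp - len(fwd) - len(rev_rc)
    middle = "".join(rng.choice(BASES, size=middle_len))
    ins = list(fwd + middle + rev_rc)
    v = config.sry_deletion
    ins[v.start - 1 : v.end] = list(v.deleted_motif)
    ins_seq = "".join(ins)
    del_seq = v.apply_to(ins_seq)
    return (
        SequenceRecord(id="SRY_insertion", sequence=ins_seq, species_label="invasive"),
        SequenceRecord(id="SRY_deletion", sequence=del_seq, species_label="aurita"),
    )


def _with_errors(sequence: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return sequence
    seq = list(sequence)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for pos in hits:
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(3)]
    return "".join(seq)


def _true_class(patriline: str, matriline_species: str) -> str:
    if patriline == "aurita" and matriline_species in INVASIVE:
        return CONFIRMED_HYBRID
    if patriline == "invasive" and matriline_species == "aurita":
        return CONFIRMED_HYBRID
    if patriline == "aurita" and matriline_species == "aurita":
        return BOTH_AURITA
    if patriline == "invasive" and matriline_species in INVASIVE:
        return BOTH_INVASIVE
    return UNDETERMINED


def simulate_cohort(config: SimConfig, panel: ReferencePanel) -> SimulatedCohort:
    """Draw a cohort under ``config.cohort_spec`` with full ground truth.

    Per sample: the COX2 read is its haplotype with i.i.d. per-base errors;
    the SRY amplicon/fragment reflects the group's allele, with females
    amplifying only with probability ``chimerism_prob`` (hematopoietic
    chimerism); fragment sizes get Gaussian sizing jitter. SRY presence never
    enters the recorded sex.
    """
    rng = np.random.default_rng([config.seed, 17])
    hap_by_label = {h.id: h for h in panel.haplotypes}
    for block in config.cohort_spec:
        if block.haplotype not in hap_by_label:
            raise ConfigurationError(f"cohort references unknown haplotype {block.haplotype!r}")
        if block.sry_allele not in ("del", "ins"):
            raise ConfigurationError(f"unknown SRY allele {block.sry_allele!r}")

    ins_rec, del_rec = simulate_sry_alleles(config)
    ins_allele, del_allele = ins_rec.sequence, del_rec.sequence
    ins_size = float(len(ins_allele))
    del_size = float(len(del_allele))

    cox2, sry, fragments, samples, truth = [], [], [], [], []
    counter = 0
    for block in config.cohort_spec:
        hap = hap_by_label[block.haplotype]
        for sex in ["M"] * block.n_males + ["F"] * block.n_females:
            counter += 1
            sid = f"sim{counter:03d}"
            samples.append(
                SampleRecord(sample_id=sid, sex=sex, group=block.group, locality="simulated", year=2010)
            )
            cox2.append(
                SequenceRecord(
                    id=f"{sid}_COX2",
                    sequence=_with_errors(hap.sequence, rng, config.per_base_error),
                    sample_id=sid,
                )
            )
            amplifies = sex == "M" or rng.random() < config.chimerism_prob
            if amplifies:
                allele_seq = del_allele if block.sry_allele == "del" else ins_allele
                true_size = del_size if block.sry_allele == "del" else ins_size
                sry.append(
                    SequenceRecord(
                        id=f"{sid}_SRY",
                        sequence=_with_errors(allele_seq, rng, config.per_base_error),
                        sample_id=sid,
                    )
                )
                size = true_size
                if config.fragment_sigma > 0:
                    size += rng.normal(0.0, config.fragment_sigma)
                fragments.append(FragmentRecord(sample_id=sid, size_bp=float(size)))
                patriline = "aurita" if block.sry_allele == "del" else "invasive"
            else:
                patriline = "none"
            truth.append(
                GroundTruth(
                    sample_id=sid,
                    true_patriline=patriline,
                    true_matriline=block.haplotype,
                    true_class=_true_class(patriline, hap.species_label),
                )
            )
    return SimulatedCohort(
        cox2_sequences=tuple(cox2),
        sry_sequences=tuple(sry),
        fragments=tuple(fragments),
        samples=tuple(samples),
        ground_truth=tuple(truth),
    )


def panel_config_for(panel: ReferencePanel, fasta_path) -> PanelConfig:
    return PanelConfig(
        locus_name=panel.locus_name,
        haplotype_labels=tuple(h.id for h in panel.haplotypes),
        species_of_haplotype={h.id: h.species_label for h in panel.haplotypes},
        fasta_path=str(fasta_path),
    )


def write_simulation(out_dir, config: SimConfig, panel: ReferencePanel, cohort: SimulatedCohort) -> dict:
    """Write the simulated dataset in the same formats the pipeline reads.

    Returns a name → path mapping of everything written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "panel_fasta": out / "panel.fasta",
        "panel_config": out / "panel.yaml",
        "cox2_fasta": out / "cox2_samples.fasta",
        "sry_fasta": out / "sry_samples.fasta",
        "fragments_csv": out / "fragments.csv",
        "samples_tsv": out / "samples.tsv",
        "ground_truth_tsv": out / "ground_truth.tsv",
    }
    write_fasta(panel.haplotypes, paths["panel_fasta"])
    write_panel_config(panel_config_for(panel, "panel.fasta"), paths["panel_config"])
    write_fasta(cohort.cox2_sequences, paths["cox2_fasta"])
    write_fasta(cohort.sry_sequences, paths["sry_fasta"])
    with open(paths["fragments_csv"], "w") as fh:
        fh.write("sample_id,size_bp\n")
        for f in cohort.fragments:
            fh.write(f"{f.sample_id},{f.size_bp:.3f}\n")
    with open(paths["samples_tsv"], "w") as fh:
        fh.write("sample_id\tsex\tgroup\tlocality\tyear\n")
        for s in cohort.samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.group}\t{s.locality}\t{s.year}\n")
    with open(paths["ground_truth_tsv"], "w") as fh:
        fh.write("sample_id\ttrue_patriline\ttrue_matriline\ttrue_class\n")
        for g in cohort.ground_truth:
            fh.write(f"{g.sample_id}\t{g.true_patriline}\t{g.true_matriline}\t{g.true_class}\n")
    return {k: str(v) for k, v in paths.items()}
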