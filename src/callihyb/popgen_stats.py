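"""Alignment-level statistics for the COX2 haplotype panel and sample sets.

Covers site classification (monomorphic/polymorphic, transition vs
transversion), species-diagnostic fixed differences, Nei's haplotype and
nucleotide diversity with their standard variance formulas, protein-level
annotation of substitutions under the vertebrate mitochondrial code, and a
lightweight p-distance / neighbor-joining clustering used to sanity-check
haplotype groupings.

Conventions: alignment columns are reported 1-based; positions carrying N or
'-' in a sequence are ignored for that sequence (pairwise deletion); sites
with more than two observed states are counted polymorphic but flagged
``multiallelic`` and excluded from single-change (ts/tv, syn/nonsyn)
annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import nj as _skbio_nj

from .errors import ConfigurationError, ValidationError
from .io_formats import SequenceRecord

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
MISSING = frozenset("N-")

MONOMORPHIC = "monomorphic"
POLYMORPHIC = "polymorphic"
TRANSITION = "transition"
TRANSVERSION = "transversion"
MULTIALLELIC = "multiallelic"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"

VERTEBRATE_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


@dataclass(frozen=True)
class SiteAnnotation:
    """Classification of one alignment column (1-based position)."""

    position: int
    site_class: str
    diagnostic_for: Optional[str] = None
    change_type: Optional[str] = None
    coding_effect: Optional[str] = None
    aa_change: Optional[str] = None


@dataclass(frozen=True)
class DiversityStats:
    n_samples: int
    n_haplotypes: int
    polymorphic_sites: int
    haplotype_diversity: float
    haplotype_diversity_se: float
    nucleotide_diversity_pi: float
    nucleotide_diversity_pi_se: float


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix with zero diagonal."""

    labels: tuple
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValidationError("distance matrix must be symmetric with zero diagonal")
        if (d < 0).any() or (d > 1).any():
            raise ValidationError("p-distances must lie in [0, 1]")


def _check_alignment(alignment: Sequence[SequenceRecord], min_sequences: int = 2) -> int:
    if len(alignment) < min_sequences:
        raise ValidationError(f"need at least {min_sequences} sequences")
    lengths = {len(r.sequence) for r in alignment}
    if len(lengths) != 1:
        raise ValidationError(f"ragged alignment: lengths {sorted(lengths)}")
    return lengths.pop()


def site_classes(alignment: Sequence[SequenceRecord]) -> list:
    """Classify every column as monomorphic or polymorphic, with ts/tv for biallelic sites."""
    length = _check_alignment(alignment)
    annotations = []
    for col in range(length):
        states = {r.sequence[col] for r in alignment} - MISSING
        if len(states) <= 1:
            annotations.append(SiteAnnotation(position=col + 1, site_class=MONOMORPHIC))
            continue
        if len(states) == 2:
            change = TRANSITION if states <= PURINES or states <= PYRIMIDINES else TRANSVERSION
        else:
            change = MULTIALLELIC
        annotations.append(
            SiteAnnotation(position=col + 1, site_class=POLYMORPHIC, change_type=change)
        )
    return annotations


def polymorphic_site_count(alignment: Sequence[SequenceRecord]) -> int:
    return sum(a.site_class == POLYMORPHIC for a in site_classes(alignment))


def diagnostic_site_positions(
    alignment: Sequence[SequenceRecord],
    species_of: Optional[Mapping[str, str]] = None,
) -> dict:
    """Map species → 1-based columns diagnostic for it.

    A column is diagnostic for species S iff every S sequence shares one state
    there and no non-S sequence carries that state. With exactly two species a
    fixed difference is, by this definition, diagnostic for both — the counts
    are per-species, not a partition of columns.
    """
    length = _check_alignment(alignment)
    if species_of is None:
        species_of = {r.id: r.species_label for r in alignment}
    unknown = [r.id for r in alignment if species_of.get(r.id) is None]
    if unknown:
        raise ValidationError(f"sequences without a species label: {unknown}")
    species = sorted({species_of[r.id] for r in alignment})
    if len(species) < 2:
        raise ValidationError("diagnostic sites require at least two species")

    positions = {sp: [] for sp in species}
    for col in range(length):
        by_species = {sp: set() for sp in species}
        for r in alignment:
            base = r.sequence[col]
            if base not in MISSING:
                by_species[species_of[r.id]].add(base)
        for sp in species:
            own = by_species[sp]
            if len(own) != 1:
                continue
            state = next(iter(own))
            others = set().union(*(by_species[o] for o in species if o != sp))
            if state not in others and others:
                positions[sp].append(col + 1)
    return positions


def diagnostic_sites(
    alignment: Sequence[SequenceRecord],
    species_of: Optional[Mapping[str, str]] = None,
) -> dict:
    """Count species-diagnostic columns per species."""
    return {sp: len(cols) for sp, cols in diagnostic_site_positions(alignment, species_of).items()}


def haplotype_diversity(haplotype_counts: Mapping[str, int]) -> tuple:
    """Nei's haplotype diversity Hd = n/(n-1) (1 - Σ p_i²) with its sampling SE.

    The variance is Nei (1987) eq. 8.12:
    V = 2/(n(n-1)) [ 2(n-2)(Σp³ - (Σp²)²) + Σp² - (Σp²)² ].
    """
    counts = np.array([c for c in haplotype_counts.values() if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValidationError("haplotype diversity requires total sample size >= 2")
    p = counts / n
    sum_p2 = float(np.sum(p**2))
    sum_p3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum_p2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2)
    return hd, math.sqrt(max(var, 0.0))


def _pairwise_p_distance(a: str, b: str) -> float:
    pairs = [(x, y) for x, y in zip(a, b) if x not in MISSING and y not in MISSING]
    if not pairs:
        raise ValidationError("no comparable (non-missing) sites between sequences")
    return sum(x != y for x, y in pairs) / len(pairs)


def nucleotide_diversity(
    alignment: Sequence[SequenceRecord],
    counts: Optional[Mapping[str, int]] = None,
) -> tuple:
    """Nei's per-site nucleotide diversity π with its standard error.

    π = n/(n-1) Σ_{i<j} 2 x_i x_j d_ij over distinct sequence types with
    frequencies x_i, where d_ij is the per-site p-distance (pairwise deletion
    of N/- positions). The variance is Nei (1987) eq. 10.7, which combines the
    sampling and stochastic components:
    V(π) = (n+1)/(3(n-1)) · π/L + 2(n²+n+3)/(9n(n-1)) · π².
    """
    length = _check_alignment(alignment)
    if counts is None:
        counts = {r.id: 1 for r in alignment}
    weights = np.array([counts.get(r.id, 0) for r in alignment], dtype=float)
    n = weights.sum()
    if n < 2:
        raise ValidationError("nucleotide diversity requires total sample size >= 2")
    x = weights / n
    pi = 0.0
    for i in range(len(alignment)):
        for j in range(i + 1, len(alignment)):
            if x[i] == 0 or x[j] == 0:
                continue
            d = _pairwise_p_distance(alignment[i].sequence, alignment[j].sequence)
            pi += 2.0 * x[i] * x[j] * d
    pi *= n / (n - 1)
    var = (n + 1) / (3.0 * (n - 1)) * pi / length + 2.0 * (n**2 + n + 3) / (
        9.0 * n * (n - 1)
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def diversity_stats(
    alignment: Sequence[SequenceRecord],
    counts: Optional[Mapping[str, int]] = None,
) -> DiversityStats:
    """Bundle sample-level diversity summaries for an alignment of haplotypes."""
    if counts is None:
        counts = {r.id: 1 for r in alignment}
    hd, hd_se = haplotype_diversity(counts)
    pi, pi_se = nucleotide_diversity(alignment, counts)
    return DiversityStats(
        n_samples=int(sum(counts.values())),
        n_haplotypes=sum(1 for c in counts.values() if c > 0),
        polymorphic_sites=polymorphic_site_count(alignment),
        haplotype_diversity=hd,
        haplotype_diversity_se=hd_se,
        nucleotide_diversity_pi=pi,
        nucleotide_diversity_pi_se=pi_se,
    )


def _translate_codon(codon: str) -> Optional[str]:
    if set(codon) & MISSING or len(codon) != 3:
        return None
    if codon in VERTEBRATE_MITO_TABLE.stop_codons:
        return "*"
    return VERTEBRATE_MITO_TABLE.forward_table[codon]


def _majority_codon(alignment, rows, start: int) -> Optional[str]:
    codons = {}
    for r in rows:
        codon = r.sequence[start : start + 3]
        if not (set(codon) & MISSING) and len(codon) == 3:
            codons[codon] = codons.get(codon, 0) + 1
    if not codons:
        return None
    return max(sorted(codons), key=lambda c: codons[c])


def coding_effect(
    alignment: Sequence[SequenceRecord],
    reading_frame_offset: int,
    annotations: Optional[Sequence[SiteAnnotation]] = None,
) -> list:
    """Annotate biallelic polymorphic sites as synonymous/nonsynonymous.

    For each biallelic site the two allele codons (majority codon among the
    sequences carrying each allele) are translated under the vertebrate
    mitochondrial code; an introduced stop codon is annotated ('*'), not fatal.
    The amino-acid change is formatted "XposY" with pos the 1-based codon
    number in the chosen frame.
    """
    if reading_frame_offset not in (0, 1, 2):
        raise ConfigurationError("reading_frame_offset must be 0, 1 or 2")
    length = _check_alignment(alignment)
    if length < 3:
        raise ValidationError("alignment shorter than one codon")
    if annotations is None:
        annotations = site_classes(alignment)

    out = []
    for ann in annotations:
        if ann.site_class != POLYMORPHIC or ann.change_type == MULTIALLELIC:
            out.append(ann)
            continue
        col = ann.position - 1
        codon_index = (col - reading_frame_offset) // 3
        codon_start = reading_frame_offset + 3 * codon_index
        if col < reading_frame_offset or codon_start + 3 > length:
            out.append(ann)
            continue
        # allele order follows first occurrence in the alignment, so the
        # reported change reads reference-first when a reference leads the file
        alleles = []
        for r in alignment:
            base = r.sequence[col]
            if base not in MISSING and base not in alleles:
                alleles.append(base)
        aas = []
        for allele in alleles:
            rows = [r for r in alignment if r.sequence[col] == allele]
            codon = _majority_codon(alignment, rows, codon_start)
            aas.append(_translate_codon(codon) if codon else None)
        if any(a is None for a in aas):
            out.append(ann)
            continue
        if aas[0] == aas[1]:
            out.append(replace(ann, coding_effect=SYNONYMOUS))
        else:
            aa_change = f"{aas[0]}{codon_index + 1}{aas[1]}"
            out.append(replace(ann, coding_effect=NONSYNONYMOUS, aa_change=aa_change))
    return out


def p_distance_matrix(alignment: Sequence[SequenceRecord]) -> DistanceMatrix:
    """All-pairs per-site p-distance (pairwise deletion of missing positions)."""
    _check_alignment(alignment)
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_p_distance(
                alignment[i].sequence, alignment[j].sequence
            )
    return DistanceMatrix(labels=tuple(r.id for r in alignment), distances=d)


def nj_tree(dm: DistanceMatrix) -> str:
    """Neighbor-joining tree as a newick string.

    Negative branch lengths produced by the NJ formulas are clamped to zero
    (with the excess moved to the adjacent edge), the standard correction.
    """
    if len(dm.labels) < 3:
        raise ValidationError("neighbor joining requires at least 3 taxa")
    tree = _skbio_nj(_SkbioDM(dm.distances, ids=list(dm.labels)))
    return str(tree).strip()
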