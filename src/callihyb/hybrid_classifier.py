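"""Combine patrilineal (SRY) and matrilineal (COX2) calls into hybrid-ancestry categories.

A sample whose two uniparental markers disagree about the species —
*C. aurita* patriline with an invasive (jacchus/penicillata) matriline, or
the reciprocal — is a confirmed interspecific hybrid. Concordant markers mean
only that both uniparental lineages trace to one species; with these markers
alone that is compatible with a pure individual, a backcross, or
hybrid×hybrid offspring, so the category names deliberately speak of
"lineages", not of generations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .cox2_haplotyping import HaplotypeAssignment
from .errors import ValidationError
from .io_formats import SampleRecord
from .sry_genotyping import SryCall

INVASIVE_SPECIES = frozenset({"jacchus", "penicillata"})

CONFIRMED_HYBRID = "confirmed_hybrid"
BOTH_AURITA = "both_aurita_lineages"
BOTH_INVASIVE = "both_invasive_lineages"
UNDETERMINED = "undetermined"

DIRECTION_INVASIVE_MATRILINE = "invasive matriline x aurita patriline"
DIRECTION_AURITA_MATRILINE = "aurita matriline x invasive patriline"


@dataclass(frozen=True)
class HybridCall:
    """Per-sample combined classification."""

    sample_id: str
    patriline: str
    matriline_species: str
    matriline_haplotype: str
    category: str
    direction: Optional[str] = None


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level counts and hybridization-direction breakdown.

    Matriline proportions are reported over two denominators — all classified
    samples and confirmed hybrids only — because neither denominator is
    privileged when summarizing direction of hybridization.
    """

    n_total: int
    n_confirmed_hybrid: int
    n_both_aurita: int
    n_both_invasive: int
    n_undetermined: int
    counts_by_matriline_haplotype: Mapping[str, int]
    proportion_penicillata_matriline: float
    proportion_jacchus_matriline: float
    proportion_penicillata_matriline_of_hybrids: float
    proportion_jacchus_matriline_of_hybrids: float
    direction_breakdown: Mapping[str, int]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_confirmed_hybrid": self.n_confirmed_hybrid,
            "n_both_aurita": self.n_both_aurita,
            "n_both_invasive": self.n_both_invasive,
            "n_undetermined": self.n_undetermined,
            "counts_by_matriline_haplotype": dict(self.counts_by_matriline_haplotype),
            "proportion_penicillata_matriline": self.proportion_penicillata_matriline,
            "proportion_jacchus_matriline": self.proportion_jacchus_matriline,
            "proportion_penicillata_matriline_of_hybrids": self.proportion_penicillata_matriline_of_hybrids,
            "proportion_jacchus_matriline_of_hybrids": self.proportion_jacchus_matriline_of_hybrids,
            "direction_breakdown": dict(self.direction_breakdown),
        }


def classify_sample(sry: SryCall, hap: HaplotypeAssignment) -> HybridCall:
    """Combine one sample's two marker calls into a hybrid category.

    Pure function of (patriline, matriline_species); every combination of the
    two marker states maps to exactly one category.
    """
    if sry.sample_id != hap.sample_id:
        raise ValidationError(
            f"marker calls refer to different samples: {sry.sample_id!r} vs {hap.sample_id!r}"
        )
    patriline = sry.patriline
    matriline = hap.matriline_species

    category = UNDETERMINED
    direction = None
    if patriline == "aurita" and matriline in INVASIVE_SPECIES:
        category = CONFIRMED_HYBRID
        direction = DIRECTION_INVASIVE_MATRILINE
    elif patriline == "invasive" and matriline == "aurita":
        category = CONFIRMED_HYBRID
        direction = DIRECTION_AURITA_MATRILINE
    elif patriline == "aurita" and matriline == "aurita":
        category = BOTH_AURITA
    elif patriline == "invasive" and matriline in INVASIVE_SPECIES:
        category = BOTH_INVASIVE

    return HybridCall(
        sample_id=sry.sample_id,
        patriline=patriline,
        matriline_species=matriline,
        matriline_haplotype=hap.haplotype_label,
        category=category,
        direction=direction,
    )


def summarize_cohort(
    calls: Sequence[HybridCall],
    samples: Optional[Iterable[SampleRecord]] = None,
    group_filter: Optional[str] = None,
) -> CohortSummary:
    """Tabulate per-sample calls into cohort counts and proportions.

    With ``group_filter`` set, only samples of that metadata group are counted
    (``samples`` is then required). Output map keys are sorted for
    deterministic serialization.
    """
    if group_filter is not None:
        if samples is None:
            raise ValidationError("group_filter requires the sample table")
        keep = {s.sample_id for s in samples if s.group == group_filter}
        calls = [c for c in calls if c.sample_id in keep]

    seen = set()
    for c in calls:
        if c.sample_id in seen:
            raise ValidationError(f"duplicate sample_id in calls: {c.sample_id!r}")
        seen.add(c.sample_id)

    n_total = len(calls)
    by_category = {CONFIRMED_HYBRID: 0, BOTH_AURITA: 0, BOTH_INVASIVE: 0, UNDETERMINED: 0}
    hap_counts: dict = {}
    direction: dict = {}
    n_pen = n_jac = 0
    n_pen_hyb = n_jac_hyb = 0
    for c in calls:
        by_category[c.category] += 1
        hap_counts[c.matriline_haplotype] = hap_counts.get(c.matriline_haplotype, 0) + 1
        if c.direction is not None:
            direction[c.direction] = direction.get(c.direction, 0) + 1
        if c.matriline_species == "penicillata":
            n_pen += 1
            n_pen_hyb += c.category == CONFIRMED_HYBRID
        elif c.matriline_species == "jacchus":
            n_jac += 1
            n_jac_hyb += c.category == CONFIRMED_HYBRID

    n_hyb = by_category[CONFIRMED_HYBRID]
    return CohortSummary(
        n_total=n_total,
        n_confirmed_hybrid=n_hyb,
        n_both_aurita=by_category[BOTH_AURITA],
        n_both_invasive=by_category[BOTH_INVASIVE],
        n_undetermined=by_category[UNDETERMINED],
        counts_by_matriline_haplotype=dict(sorted(hap_counts.items())),
        proportion_penicillata_matriline=n_pen / n_total if n_total else 0.0,
        proportion_jacchus_matriline=n_jac / n_total if n_total else 0.0,
        proportion_penicillata_matriline_of_hybrids=n_pen_hyb / n_hyb if n_hyb else 0.0,
        proportion_jacchus_matriline_of_hybrids=n_jac_hyb / n_hyb if n_hyb else 0.0,
        direction_breakdown=dict(sorted(direction.items())),
    )
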