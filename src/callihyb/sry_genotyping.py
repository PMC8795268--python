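"""Patrilineal ancestry: call the 9-bp SRY indel from sequence or fragment size.

The Y-linked SRY amplicon carries a 9-bp deletion (117_125delTAAGTATCG) fixed
in *C. aurita* and absent from the invasive species (*C. jacchus*,
*C. penicillata*), so the indel state of a male's amplicon — or of the
chimeric signal amplifiable from a female twin's blood — identifies the
patriline. Two independent evidence routes are supported: direct sequence
comparison of the amplicon against the insertion-type reference, and
capillary-electrophoresis fragment sizing (196 bp deleted vs 205 bp
insertion). SRY amplification is never used to infer sex: female marmosets
routinely amplify Y loci through hematopoietic chimerism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .cox2_haplotyping import _aligner
from .errors import ConfigurationError, SequenceIdentityError, ValidationError
from .io_formats import FragmentRecord, IndelVariant, SequenceRecord, parse_indel_notation

# Consensus primer pair printed for the SRY assay (5'->3').
FSRY = "TACAGGCCATGCACAGAGAG"
RSRY = "CTAGCGGGTGTTCCATTGTT"

DEFAULT_VARIANT = parse_indel_notation("117_125delTAAGTATCG")
DEFAULT_DEL_SIZE = 196.0
DEFAULT_INS_SIZE = 205.0
DEFAULT_SIZE_TOLERANCE = 1.5
DEFAULT_MAX_MISMATCHES = 2
THREE_PRIME_PROTECTED = 3  # no mismatch tolerated in the primer's 3'-terminal bases
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_COVERAGE = 0.5

DELETION_AURITA = "deletion_aurita"
INSERTION_INVASIVE = "insertion_invasive"
NO_AMPLIFICATION = "no_amplification"
AMBIGUOUS = "ambiguous"

PATRILINE_OF_ALLELE = {
    DELETION_AURITA: "aurita",
    INSERTION_INVASIVE: "invasive",
    NO_AMPLIFICATION: "undetermined",
    AMBIGUOUS: "undetermined",
}


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse PCR primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if len(p) < 15:
                raise ValidationError(f"{name} primer shorter than 15 nt")
            bad = set(p) - set("ACGT")
            if bad:
                raise ValidationError(f"{name} primer contains illegal characters {sorted(bad)}")


DEFAULT_PRIMERS = PrimerPair(forward=FSRY, reverse=RSRY)


@dataclass(frozen=True)
class SryCall:
    """Per-sample SRY indel call with its evidence route."""

    sample_id: str
    allele: str
    evidence: str  # "sequence" | "fragment_size"
    observed_size_bp: Optional[float]
    patriline: str

    def __post_init__(self) -> None:
        if self.allele not in PATRILINE_OF_ALLELE:
            raise ValidationError(f"unknown allele {self.allele!r}")
        expected = PATRILINE_OF_ALLELE[self.allele]
        if self.patriline != expected:
            raise ValidationError(
                f"allele {self.allele!r} implies patriline {expected!r}, got {self.patriline!r}"
            )


def make_call(sample_id: str, allele: str, evidence: str, observed_size_bp: Optional[float] = None) -> SryCall:
    return SryCall(
        sample_id=sample_id,
        allele=allele,
        evidence=evidence,
        observed_size_bp=observed_size_bp,
        patriline=PATRILINE_OF_ALLELE[allele],
    )


@dataclass(frozen=True)
class PcrProduct:
    """One predicted amplicon: the product sequence plus its footprint on the template."""

    sequence: SequenceRecord
    size_bp: int
    start: int  # 0-based on the template, inclusive of the forward primer
    end: int  # 0-based exclusive, inclusive of the reverse primer footprint


def _mismatches_ok(site: str, primer: str, max_mismatches: int, protect_tail: bool) -> bool:
    """Tail = the primer's 3' end; for the reverse primer the caller passes the
    reverse-complemented site so the protected bases sit at the string start."""
    mm = sum(a != b for a, b in zip(site, primer))
    if mm > max_mismatches:
        return False
    tail = slice(-THREE_PRIME_PROTECTED, None) if protect_tail else slice(0, THREE_PRIME_PROTECTED)
    return site[tail] == primer[tail]


def insilico_pcr(
    template: SequenceRecord,
    primers: PrimerPair = DEFAULT_PRIMERS,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list:
    """Predict every plus-strand PCR product of the primer pair on a template.

    The forward primer must match the plus strand and the reverse primer's
    reverse complement must match downstream, each with at most
    ``max_mismatches`` and perfect identity at the 3'-terminal
    ``THREE_PRIME_PROTECTED`` bases. Product sizes include both primer
    footprints. No binding sites simply yields an empty list.
    """
    t = template.sequence
    f, r = primers.forward, primers.reverse
    rc = str(Seq(r).reverse_complement())
    fwd_sites = [
        i
        for i in range(len(t) - len(f) + 1)
        if _mismatches_ok(t[i : i + len(f)], f, max_mismatches, protect_tail=True)
    ]
    # on the plus strand the reverse primer's 3' end faces the forward primer,
    # i.e. the first bases of the reverse-complement site
    rev_sites = [
        j
        for j in range(len(t) - len(rc) + 1)
        if _mismatches_ok(t[j : j + len(rc)], rc, max_mismatches, protect_tail=False)
    ]
    products = []
    for i in fwd_sites:
        for j in rev_sites:
            if j < i + len(f):
                continue
            seq = t[i : j + len(rc)]
            products.append(
                PcrProduct(
                    sequence=SequenceRecord(
                        id=f"{template.id}|product_{i + 1}_{j + len(rc)}",
                        sequence=seq,
                        sample_id=template.sample_id,
                    ),
                    size_bp=len(seq),
                    start=i,
                    end=j + len(rc),
                )
            )
    return products


def call_indel_from_sequence(
    amplicon: SequenceRecord,
    insertion_ref: SequenceRecord,
    variant: IndelVariant = DEFAULT_VARIANT,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> SryCall:
    """Call the indel by global alignment of an amplicon to the insertion-type reference.

    deletion_aurita requires the alignment to place one internal gap of exactly
    the motif length over the variant span (allowing the sequence-equivalent
    shifted placements that repeats around an indel permit);
    insertion_invasive requires the motif to be present at the span; anything
    else (partial gap, wrong-length gap) is ambiguous.
    """
    ref = insertion_ref.sequence
    if not (1 <= variant.start and variant.end <= len(ref)):
        raise ValidationError(
            f"variant span {variant.start}_{variant.end} outside reference of length {len(ref)}"
        )
    aln = _aligner().align(ref, amplicon.sequence)[0]
    covered = [None] * len(ref)  # query base aligned to each ref position, or None
    tblocks, qblocks = aln.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for k in range(te - ts):
            covered[ts + k] = amplicon.sequence[qs + k]

    span = slice(variant.start - 1, variant.end)  # 0-based half-open
    n_outside_total = len(ref) - len(variant)
    outside = [
        (covered[i], ref[i])
        for i in range(len(ref))
        if not (variant.start - 1 <= i < variant.end) and covered[i] is not None
    ]
    if not outside or len(outside) / n_outside_total < min_coverage:
        raise SequenceIdentityError(
            f"{amplicon.id!r} is not an SRY amplicon (covers too little of the reference)"
        )
    identity = sum(q == r for q, r in outside) / len(outside)
    if identity < min_identity:
        raise SequenceIdentityError(
            f"{amplicon.id!r} is not an SRY amplicon "
            f"({identity:.1%} identity outside the variant span, need ≥{min_identity:.0%})"
        )

    sample_id = amplicon.sample_id or amplicon.id
    covered_idx = [i for i, b in enumerate(covered) if b is not None]
    first, last = covered_idx[0], covered_idx[-1]
    # maximal internal gap runs (uncovered ref positions flanked by coverage)
    gap_runs = []
    run_start = None
    for i in range(first, last + 1):
        if covered[i] is None and run_start is None:
            run_start = i
        elif covered[i] is not None and run_start is not None:
            gap_runs.append((run_start, i))  # half-open
            run_start = None
    span_lo, span_hi = variant.start - 1, variant.end  # 0-based half-open
    overlapping = [g for g in gap_runs if g[0] < span_hi and g[1] > span_lo]

    span_bases = covered[span]
    if len(overlapping) == 1 and overlapping[0][1] - overlapping[0][0] == len(variant):
        # one internal gap of exactly the motif length over the span; repeats
        # at the indel boundary can shift an equivalent gap off the nominal span
        allele = DELETION_AURITA
    elif (
        not overlapping
        and all(b is not None for b in span_bases)
        and "".join(span_bases) == variant.deleted_motif
    ):
        allele = INSERTION_INVASIVE
    else:
        allele = AMBIGUOUS
    return make_call(sample_id, allele, evidence="sequence")


def call_indel_from_size(
    fragment: FragmentRecord,
    del_size: float = DEFAULT_DEL_SIZE,
    ins_size: float = DEFAULT_INS_SIZE,
    tolerance_bp: float = DEFAULT_SIZE_TOLERANCE,
) -> SryCall:
    """Call the indel from a capillary fragment size by nearest expected peak.

    The two expected peaks (196 / 205 bp by default) are matched inside a
    symmetric tolerance window; sizes matching neither (or, with a misconfigured
    tolerance, both) come back ambiguous.
    """
    if not del_size < ins_size:
        raise ConfigurationError("del_size must be smaller than ins_size")
    if not tolerance_bp < (ins_size - del_size) / 2:
        raise ConfigurationError(
            f"tolerance {tolerance_bp} must be below half the allele size gap "
            f"({(ins_size - del_size) / 2})"
        )
    near_del = abs(fragment.size_bp - del_size) <= tolerance_bp
    near_ins = abs(fragment.size_bp - ins_size) <= tolerance_bp
    if near_del and not near_ins:
        allele = DELETION_AURITA
    elif near_ins and not near_del:
        allele = INSERTION_INVASIVE
    else:
        allele = AMBIGUOUS
    return make_call(
        fragment.sample_id, allele, evidence="fragment_size", observed_size_bp=fragment.size_bp
    )
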