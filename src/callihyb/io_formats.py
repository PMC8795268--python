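"""External representations: FASTA, sample/fragment tables, indel notation, panel config.

All coordinates exposed here are 1-based inclusive (HGVS-style, matching the
``117_125delTAAGTATCG`` notation used for the SRY deletion); conversion to
0-based half-open indexing happens at module boundaries, never in user-facing
strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import ParseError, ValidationError

SEQUENCE_ALPHABET = frozenset("ACGTN-")

SEXES = ("M", "F")
GROUPS = (
    "putative_hybrid",
    "control_aurita",
    "control_jacchus",
    "control_penicillata",
)
YEAR_RANGE = (1990, 2030)

_INDEL_RE = re.compile(r"^(\d+)_(\d+)del([ACGT]+)$")


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide sequence with optional species/sample annotations."""

    id: str
    sequence: str
    species_label: Optional[str] = None
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"sequence for record {self.id!r} is empty")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r} contains illegal characters {sorted(bad)}; "
                f"allowed alphabet is {{A,C,G,T,N,-}}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        rc = str(Seq(self.sequence).reverse_complement())
        return SequenceRecord(
            id=self.id, sequence=rc, species_label=self.species_label, sample_id=self.sample_id
        )


@dataclass(frozen=True)
class SampleRecord:
    """One row of the sample-metadata table (Table-1 structure)."""

    sample_id: str
    sex: str
    group: str
    locality: str
    year: int

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sample {self.sample_id!r}: unknown sex code {self.sex!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"sample {self.sample_id!r}: unknown group {self.group!r}")
        if not (YEAR_RANGE[0] <= int(self.year) <= YEAR_RANGE[1]):
            raise ValidationError(
                f"sample {self.sample_id!r}: year {self.year} outside {YEAR_RANGE}"
            )


@dataclass(frozen=True)
class IndelVariant:
    """A deletion variant in 1-based inclusive coordinates, e.g. 117_125delTAAGTATCG."""

    start: int
    end: int
    deleted_motif: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"invalid indel span {self.start}_{self.end}")
        if len(self.deleted_motif) != self.end - self.start + 1:
            raise ValidationError(
                f"indel span {self.start}_{self.end} covers {self.end - self.start + 1} "
                f"positions but motif {self.deleted_motif!r} has length "
                f"{len(self.deleted_motif)}"
            )
        bad = set(self.deleted_motif) - set("ACGT")
        if bad:
            raise ValidationError(f"indel motif contains illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.deleted_motif)

    def apply_to(self, sequence: str) -> str:
        """Remove the motif from ``sequence`` (1-based inclusive span).

        The bases at the span must equal the deleted motif.
        """
        if self.end > len(sequence):
            raise ValidationError(
                f"indel span {self.start}_{self.end} exceeds sequence length {len(sequence)}"
            )
        observed = sequence[self.start - 1 : self.end]
        if observed != self.deleted_motif:
            raise ValidationError(
                f"sequence has {observed!r} at {self.start}_{self.end}, "
                f"expected {self.deleted_motif!r}"
            )
        return sequence[: self.start - 1] + sequence[self.end :]


@dataclass(frozen=True)
class FragmentRecord:
    """A capillary-electrophoresis fragment-size estimate for one sample."""

    sample_id: str
    size_bp: float

    def __post_init__(self) -> None:
        if not self.size_bp > 0:
            raise ValidationError(
                f"fragment size for {self.sample_id!r} must be positive, got {self.size_bp}"
            )


@dataclass(frozen=True)
class PanelConfig:
    """Locates a reference haplotype panel: FASTA path + label→species map."""

    locus_name: str
    haplotype_labels: tuple
    species_of_haplotype: Mapping[str, str]
    fasta_path: str

    def __post_init__(self) -> None:
        if len(set(self.haplotype_labels)) != len(self.haplotype_labels):
            raise ValidationError("haplotype labels must be unique")
        missing = [h for h in self.haplotype_labels if h not in self.species_of_haplotype]
        if missing:
            raise ValidationError(f"haplotypes without a species mapping: {missing}")


def read_fasta(path) -> list:
    """Read a FASTA file into :class:`SequenceRecord` objects (uppercased, order kept)."""
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        line_no = next(i for i, ln in enumerate(text.splitlines(), 1) if ln.strip())
        raise ParseError(f"{path}:{line_no}: expected FASTA header starting with '>'")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - SEQUENCE_ALPHABET
        if bad:
            line_no = _locate_bad_character(text, rec.id, bad)
            raise ParseError(
                f"{path}:{line_no}: record {rec.id!r} contains illegal "
                f"character(s) {sorted(bad)}"
            )
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def _locate_bad_character(text: str, rec_id: str, bad: set) -> int:
    in_record = False
    for i, line in enumerate(text.splitlines(), 1):
        if line.startswith(">"):
            in_record = line[1:].split()[0] == rec_id if line[1:].split() else False
        elif in_record and (set(line.strip().upper()) & bad):
            return i
    return 0


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [_BioRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def parse_indel_notation(text: str) -> IndelVariant:
    """Parse ``<start>_<end>del<motif>`` into an :class:`IndelVariant`."""
    m = _INDEL_RE.match(text.strip())
    if m is None:
        raise ParseError(f"cannot parse indel notation {text!r} (expected <start>_<end>del<motif>)")
    return IndelVariant(start=int(m.group(1)), end=int(m.group(2)), deleted_motif=m.group(3))


def format_indel_notation(variant: IndelVariant) -> str:
    return f"{variant.start}_{variant.end}del{variant.deleted_motif}"


def _read_table(path) -> pd.DataFrame:
    """Read a TSV/CSV, auto-detecting the delimiter from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, skip_blank_lines=True)


def read_sample_table(path) -> list:
    """Read the sample-metadata table (sample_id, sex, group, locality, year)."""
    df = _read_table(path)
    required = {"sample_id", "sex", "group", "locality", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    seen = set()
    for _, row in df.iterrows():
        try:
            year = int(row["year"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: non-integer year {row['year']!r}") from None
        rec = SampleRecord(
            sample_id=row["sample_id"],
            sex=row["sex"],
            group=row["group"],
            locality=row["locality"],
            year=year,
        )
        if rec.sample_id in seen:
            raise ValidationError(f"{path}: duplicate sample_id {rec.sample_id!r}")
        seen.add(rec.sample_id)
        records.append(rec)
    return records


def read_fragment_csv(path) -> list:
    """Read fragment-analysis records (sample_id, size_bp)."""
    df = _read_table(path)
    required = {"sample_id", "size_bp"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            size = float(row["size_bp"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: non-numeric size {row['size_bp']!r}") from None
        records.append(FragmentRecord(sample_id=row["sample_id"], size_bp=size))
    return records


def read_panel_config(path) -> PanelConfig:
    """Read a panel configuration from YAML (JSON is a YAML subset and also accepted)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ParseError(f"{path}: panel config must be a mapping")
    try:
        species = dict(data["species_of_haplotype"])
        labels = tuple(data.get("haplotype_labels", sorted(species)))
        fasta = data["fasta_path"]
        locus = data.get("locus_name", "COX2")
    except KeyError as exc:
        raise ParseError(f"{path}: panel config missing key {exc}") from None
    fasta_path = Path(fasta)
    if not fasta_path.is_absolute():
        fasta_path = path.parent / fasta_path
    return PanelConfig(
        locus_name=locus,
        haplotype_labels=labels,
        species_of_haplotype=species,
        fasta_path=str(fasta_path),
    )


def write_panel_config(config: PanelConfig, path) -> None:
    data = {
        "locus_name": config.locus_name,
        "haplotype_labels": list(config.haplotype_labels),
        "species_of_haplotype": dict(config.species_of_haplotype),
        "fasta_path": str(config.fasta_path),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
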