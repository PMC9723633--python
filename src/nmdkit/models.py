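"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All transcript-internal coordinates are 0-based, half-open, measured along
the spliced mRNA in 5'->3' orientation.  Genomic exon intervals are likewise
0-based half-open; GTF I/O converts to and from the 1-based inclusive dialect
at the file boundary.  Sequences are RNA (ACGU) internally; FASTA readers
and writers translate T<->U.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})
START_CODON = "AUG"
RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


class ValidationError(ValueError):
    """A domain object violates one of its structural invariants."""


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: exon structure, CDS boundaries and sequence.

    ``exons`` are genomic (start, end) pairs, 0-based half-open, listed in
    transcript (5'->3') order — i.e. descending genomic coordinate on the
    minus strand.  ``cds_start``/``cds_end`` are transcript coordinates;
    ``cds_end`` is the position just past the stop codon's last base, so
    ``sequence[cds_start:cds_end]`` is AUG...stop.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: no exons")
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty exon ({s},{e})")
        genomic_order = sorted(self.exons)
        if self.strand == "+":
            ordered = list(self.exons) == genomic_order
        else:
            ordered = list(self.exons) == genomic_order[::-1]
        if not ordered:
            raise ValidationError(
                f"{self.transcript_id}: exons not in transcript orientation"
            )
        for (_, e1), (s2, _) in zip(genomic_order, genomic_order[1:]):
            if s2 < e1:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        total = sum(e - s for s, e in self.exons)
        if len(self.sequence) != total:
            raise ValidationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} "
                f"!= exon total {total}"
            )
        if set(self.sequence) - RNA_ALPHABET:
            raise ValidationError(f"{self.transcript_id}: non-ACGU characters")
        cds = self.sequence[self.cds_start : self.cds_end]
        if len(cds) < 6 or len(cds) % 3:
            raise ValidationError(
                f"{self.transcript_id}: CDS length {len(cds)} not a multiple "
                "of 3 and >= 6"
            )
        if cds[:3] != START_CODON:
            raise ValidationError(f"{self.transcript_id}: CDS does not start with AUG")
        if cds[-3:] not in STOP_CODONS:
            raise ValidationError(f"{self.transcript_id}: CDS does not end in a stop")

    @property
    def utr5_len(self) -> int:
        return self.cds_start

    @property
    def utr3_len(self) -> int:
        return len(self.sequence) - self.cds_end

    @property
    def stop_last(self) -> int:
        """Transcript coordinate of the stop codon's last base."""
        return self.cds_end - 1

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)


@dataclass(frozen=True)
class UOrf:
    """An upstream ORF accepted by the Kozak-context scan.

    ``length`` counts from the A of the uAUG through the stop codon's last
    base.  ``kozak_minus3`` is the base three positions 5' of that A (None
    when it falls off the transcript); ``kozak_plus`` is the base
    immediately 3' of the AUG codon.
    """

    start: int
    stop_end: int
    length: int
    kozak_minus3: str | None
    kozak_plus: str | None


@dataclass(frozen=True)
class NmdAnnotation:
    """Per-transcript summary of the three NMD-inducing features."""

    transcript_id: str
    has_dej: bool
    dej_positions: tuple[int, ...]
    uorfs: tuple[UOrf, ...]
    utr5_len: int
    utr3_len: int
    utr3_class: str

    def __post_init__(self) -> None:
        if self.has_dej != bool(self.dej_positions):
            raise ValidationError(
                f"{self.transcript_id}: has_dej inconsistent with dej_positions"
            )


@dataclass(frozen=True)
class PiRna:
    """A PIWI-interacting RNA with its normalized abundance (FPM)."""

    pirna_id: str
    sequence: str
    abundance_fpm: float

    def __post_init__(self) -> None:
        if set(self.sequence) - RNA_ALPHABET:
            raise ValidationError(f"{self.pirna_id}: non-ACGU characters")
        if self.abundance_fpm < 0:
            raise ValidationError(f"{self.pirna_id}: negative abundance")

    @property
    def length(self) -> int:
        return len(self.sequence)


# Pairing rules ordered weakest -> strongest; used for nesting comparisons.
RULE_ORDER = ("seed_plus_8", "seed_plus_10", "seed_plus_12", "seed_plus_14", "full")
RULE_RANK = {r: i for i, r in enumerate(RULE_ORDER)}
SEED_RULE_MIN_MATCHES = {
    "seed_plus_8": 8,
    "seed_plus_10": 10,
    "seed_plus_12": 12,
    "seed_plus_14": 14,
}


@dataclass(frozen=True)
class TargetSite:
    """A predicted piRNA:mRNA duplex site.

    ``t_start`` is the transcript coordinate of the base opposite g1 (the
    piRNA 5' base).  The duplex is antiparallel, so the site occupies
    transcript positions ``t_start - len(piRNA) + 1 .. t_start``.
    ``window_matches`` counts paired positions among g8-g21.
    """

    pirna_id: str
    transcript_id: str
    t_start: int
    rule: str
    window_matches: int

    def __post_init__(self) -> None:
        if self.rule not in RULE_RANK:
            raise ValidationError(f"unknown pairing rule {self.rule!r}")
        if not 0 <= self.window_matches <= 14:
            raise ValidationError("window_matches outside 0..14")
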