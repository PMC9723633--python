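"""Annotation of NMD-inducing features on transcript models.

Three features are scanned, the classic triggers of nonsense-mediated decay:

1. **Downstream exon junctions (dEJ)** — an exon-exon junction located at
   least ``min_dist`` nucleotides (default 50) 3' of the stop codon's last
   base.  A terminating ribosome fails to displace exon-junction complexes
   that far downstream, licensing decay.

2. **Upstream ORFs (uORF)** — AUG-initiated ORFs starting in the 5'UTR that
   are at least 30 nt long and carry a favourable Kozak context: a purine
   three bases upstream of the uAUG, or a G immediately after the AUG
   codon.  Candidates that are in frame with the main ORF and lack an
   in-frame stop before the main AUG read through (and hence contain) the
   main ORF and are rejected; out-of-frame overlap into the CDS is allowed.

3. **3'UTR length class** — short (< 350 nt), medium (350-1500 nt,
   boundaries inclusive) or long (> 1500 nt).  Bin edges are parameters,
   not constants.
"""

from __future__ import annotations

from .models import (
    STOP_CODONS,
    NmdAnnotation,
    TranscriptModel,
    UOrf,
    ValidationError,
)

DEFAULT_DEJ_MIN_DIST = 50
DEFAULT_UORF_MIN_LEN = 30
DEFAULT_UTR3_EDGES = (350, 1500)

PURINES = frozenset("AG")


def exon_junction_positions(tx: TranscriptModel) -> list[int]:
    """Transcript coordinates of exon-exon junctions, 5'->3'.

    Each junction is reported as the coordinate of the first base of the
    downstream exon, i.e. the cumulative length of the exons preceding it.
    A single-exon transcript has no junctions.
    """
    positions = []
    acc = 0
    for length in tx.exon_lengths[:-1]:
        acc += length
        positions.append(acc)
    return positions


def has_downstream_ej(
    tx: TranscriptModel, min_dist: int = DEFAULT_DEJ_MIN_DIST
) -> tuple[bool, list[int]]:
    """Does the transcript carry an exon junction >= ``min_dist`` nt past the stop?

    Distance is measured from the stop codon's last base to the junction
    coordinate, boundary inclusive.  Junctions at or upstream of the stop
    never qualify.
    """
    stop_last = tx.stop_last
    qualifying = [
        j for j in exon_junction_positions(tx) if j - stop_last >= min_dist
    ]
    return bool(qualifying), qualifying


def _kozak_ok(seq: str, aug_start: int) -> tuple[str | None, str | None, bool]:
    """Evaluate the Kozak context of an AUG at ``aug_start``.

    Returns (base at -3 or None if off-transcript, base after the codon or
    None, accepted?).  Acceptance: purine at -3 OR guanine immediately
    following the AUG codon; an unknown -3 fails that half of the test.
    """
    minus3 = seq[aug_start - 3] if aug_start >= 3 else None
    plus = seq[aug_start + 3] if aug_start + 3 < len(seq) else None
    ok = (minus3 in PURINES) or (plus == "G")
    return minus3, plus, ok


def scan_uorfs(
    tx: TranscriptModel, min_len: int = DEFAULT_UORF_MIN_LEN
) -> list[UOrf]:
    """All qualifying upstream ORFs of a transcript, 5'->3' by start.

    A candidate starts at any AUG within the 5'UTR and runs in frame to the
    first stop codon anywhere on the transcript.  It is accepted iff its
    length (AUG through the stop's last base) is >= ``min_len``, its Kozak
    context passes (:func:`_kozak_ok`), and it does not contain the main
    ORF.  A stop-less in-frame candidate reads through the entire main ORF
    and is the one containment case rejected.
    """
    seq = tx.sequence
    main_start = tx.cds_start
    found: list[UOrf] = []
    for i in range(main_start):
        if seq[i : i + 3] != "AUG":
            continue
        # walk in frame to the first stop codon
        stop_end = None
        for j in range(i, len(seq) - 2, 3):
            if seq[j : j + 3] in STOP_CODONS:
                stop_end = j + 3
                break
        in_frame_with_main = (main_start - i) % 3 == 0
        if stop_end is None:
            # no stop at all: not an ORF
            continue
        if in_frame_with_main and stop_end > main_start:
            # no in-frame stop before the main AUG -> contains the main ORF
            continue
        length = stop_end - i
        if length < min_len:
            continue
        minus3, plus, ok = _kozak_ok(seq, i)
        if not ok:
            continue
        found.append(
            UOrf(
                start=i,
                stop_end=stop_end,
                length=length,
                kozak_minus3=minus3,
                kozak_plus=plus,
            )
        )
    return found


def utr3_class(
    utr3_len: int, edges: tuple[int, int] = DEFAULT_UTR3_EDGES
) -> str:
    """Bin a 3'UTR length into short / medium / long.

    The two edges belong to the medium class: short is strictly below the
    lower edge, long strictly above the upper edge.
    """
    lo, hi = edges
    if lo > hi:
        raise ValueError("utr3 edges must be ordered")
    if utr3_len < 0:
        raise ValueError("negative 3'UTR length")
    if utr3_len < lo:
        return "short"
    if utr3_len <= hi:
        return "medium"
    return "long"


def annotate(
    tx: TranscriptModel,
    dej_min_dist: int = DEFAULT_DEJ_MIN_DIST,
    uorf_min_len: int = DEFAULT_UORF_MIN_LEN,
    utr3_edges: tuple[int, int] = DEFAULT_UTR3_EDGES,
) -> NmdAnnotation:
    """Run all three scanners on one transcript.

    The transcript must carry both a 5'UTR and a 3'UTR; use
    :func:`annotate_set` to process a collection and collect the skipped
    ones.
    """
    if tx.utr5_len < 1 or tx.utr3_len < 1:
        raise ValidationError(
            f"{tx.transcript_id}: both UTRs required for NMD-feature annotation"
        )
    dej, positions = has_downstream_ej(tx, dej_min_dist)
    uorfs = scan_uorfs(tx, uorf_min_len)
    return NmdAnnotation(
        transcript_id=tx.transcript_id,
        has_dej=dej,
        dej_positions=tuple(positions),
        uorfs=tuple(uorfs),
        utr5_len=tx.utr5_len,
        utr3_len=tx.utr3_len,
        utr3_class=utr3_class(tx.utr3_len, utr3_edges),
    )


def annotate_set(
    transcripts,
    dej_min_dist: int = DEFAULT_DEJ_MIN_DIST,
    uorf_min_len: int = DEFAULT_UORF_MIN_LEN,
    utr3_edges: tuple[int, int] = DEFAULT_UTR3_EDGES,
) -> tuple[list[NmdAnnotation], list[str]]:
    """Annotate a transcript collection; transcripts lacking either UTR are
    returned as a skipped-id list rather than annotated."""
    annotations, skipped = [], []
    for tx in transcripts:
        if tx.utr5_len < 1 or tx.utr3_len < 1:
            skipped.append(tx.transcript_id)
            continue
        annotations.append(annotate(tx, dej_min_dist, uorf_min_len, utr3_edges))
    return annotations, skipped
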