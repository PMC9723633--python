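"""Shared fixtures: hand-assembled transcripts and small simulations."""

from __future__ import annotations

import numpy as np
import pytest

from nmdkit.models import TranscriptModel

_SENSE = [
    c
    for c in (a + b + d for a in "ACGU" for b in "ACGU" for d in "ACGU")
    if c not in ("UAA", "UAG", "UGA")
]


def filler(n: int, seed: int = 0) -> str:
    """Deterministic AUG-free, stop-free-in-any-frame filler (C/A only)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(["C", "A"], size=n))


def make_transcript(
    utr5: str,
    cds_codons: int = 10,
    utr3: str = "",
    exon_lengths=None,
    transcript_id: str = "tx1",
    gene_id: str = "g1",
    strand: str = "+",
    cds: str | None = None,
) -> TranscriptModel:
    """Assemble a valid transcript from explicit parts.

    ``cds`` overrides the default AUG + (cds_codons-2) CCC codons + UAA.
    ``exon_lengths`` must sum to the total length; default single exon.
    """
    if cds is None:
        cds = "AUG" + "CCC" * (cds_codons - 2) + "UAA"
    seq = utr5 + cds + utr3
    if exon_lengths is None:
        exon_lengths = [len(seq)]
    assert sum(exon_lengths) == len(seq), "exon lengths must tile the sequence"
    exons, cursor = [], 100
    for ln in exon_lengths:
        exons.append((cursor, cursor + ln))
        cursor += ln + 200
    if strand == "-":
        exons = [(10_000 - e, 10_000 - s) for s, e in exons]
    return TranscriptModel(
        transcript_id=transcript_id,
        gene_id=gene_id,
        chromosome="chr1",
        strand=strand,
        exons=tuple(exons),
        cds_start=len(utr5),
        cds_end=len(utr5) + len(cds),
        sequence=seq,
    )


@pytest.fixture
def simple_tx():
    return make_transcript(utr5=filler(100), cds_codons=20, utr3=filler(200, seed=1))
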