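"""File-format boundary: GTF, FASTA and TSV readers and writers.

Internally everything is 0-based half-open RNA; on disk, GTF is 1-based
inclusive and FASTA carries T instead of U.  GTF attribute parsing (via
gffutils) tolerates both GTF2.2 quoting and GFF3 key=value; emitted files
are GTF2.2.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import CountMatrix
from .models import PiRna, TranscriptModel, dna_to_rna, revcomp, rna_to_dna


# ---------------------------------------------------------------- FASTA

def write_transcript_fasta(transcripts, path) -> None:
    records = [
        SeqRecord(
            Seq(rna_to_dna(tx.sequence)),
            id=tx.transcript_id,
            description=f"gene_id={tx.gene_id}",
        )
        for tx in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path) -> dict[str, str]:
    """id -> RNA sequence (T converted to U)."""
    return {
        rec.id: dna_to_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_pirna_fasta(pirnas, fasta_path, abundance_path) -> None:
    records = [
        SeqRecord(Seq(rna_to_dna(p.sequence)), id=p.pirna_id, description="")
        for p in pirnas
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    pd.DataFrame(
        {"pirna_id": [p.pirna_id for p in pirnas],
         "fpm": [p.abundance_fpm for p in pirnas]}
    ).to_csv(abundance_path, sep="\t", index=False)


def read_pirnas(fasta_path, abundance_path) -> list[PiRna]:
    seqs = read_fasta_sequences(fasta_path)
    fpm = pd.read_csv(abundance_path, sep="\t").set_index("pirna_id")["fpm"]
    missing = set(seqs) - set(fpm.index)
    if missing:
        raise ValueError(f"piRNAs without abundance: {sorted(missing)[:5]}")
    return [
        PiRna(pirna_id=pid, sequence=seq, abundance_fpm=float(fpm[pid]))
        for pid, seq in seqs.items()
    ]


# ------------------------------------------------------------------ GTF

def write_gtf(transcripts, path) -> None:
    """Emit exon and CDS features, GTF2.2, 1-based inclusive."""
    lines = []
    for tx in transcripts:
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
        cds_intervals = _transcript_to_genomic(tx, tx.cds_start, tx.cds_end)
        for s, e in sorted(tx.exons):
            lines.append(
                f"chr{tx.chromosome.removeprefix('chr')}\tnmdkit\texon\t"
                f"{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}"
            )
        for s, e in sorted(cds_intervals):
            lines.append(
                f"chr{tx.chromosome.removeprefix('chr')}\tnmdkit\tCDS\t"
                f"{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _transcript_to_genomic(tx: TranscriptModel, t_start: int, t_end: int):
    """Map a transcript interval to genomic intervals (0-based half-open)."""
    out, acc = [], 0
    for gs, ge in tx.exons:  # transcript order
        length = ge - gs
        lo, hi = max(t_start, acc), min(t_end, acc + length)
        if lo < hi:
            if tx.strand == "+":
                out.append((gs + (lo - acc), gs + (hi - acc)))
            else:
                out.append((ge - (hi - acc), ge - (lo - acc)))
        acc += length
    return out


def read_transcripts_gtf(gtf_path, fasta_path) -> list[TranscriptModel]:
    """Assemble TranscriptModels from a GTF plus a transcript FASTA.

    Exon structure and CDS genomic extent come from the GTF; the spliced
    sequence comes from the transcript FASTA keyed by transcript_id.
    """
    text = Path(gtf_path).read_text()
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="create_unique",
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # surface the offending line if recoverable
        raise ValueError(f"malformed GTF {gtf_path}: {exc}") from exc
    sequences = read_fasta_sequences(fasta_path)
    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        rec = by_tx.setdefault(
            tx_id,
            {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
             "exons": [], "cds": []},
        )
        rec["exons" if feat.featuretype == "exon" else "cds"].append(
            (feat.start - 1, feat.end)
        )
    out = []
    for tx_id, rec in by_tx.items():
        if tx_id not in sequences:
            raise ValueError(f"transcript {tx_id} missing from FASTA")
        exons = sorted(rec["exons"])
        if rec["strand"] == "-":
            exons = exons[::-1]
        cds_len = sum(e - s for s, e in rec["cds"])
        # locate CDS start in transcript coordinates
        cds_genomic = sorted(rec["cds"])
        if rec["strand"] == "-":
            cds_genomic = cds_genomic[::-1]
        acc, cds_start = 0, None
        for (gs, ge) in exons:
            if cds_genomic:
                c0, c1 = cds_genomic[0]
                if gs <= c0 and c1 <= ge:
                    offset = (c0 - gs) if rec["strand"] == "+" else (ge - c1)
                    cds_start = acc + offset
                    break
            acc += ge - gs
        if cds_start is None:
            raise ValueError(f"transcript {tx_id}: CDS not within an exon")
        out.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=rec["gene_id"],
                chromosome=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_start + cds_len,
                sequence=sequences[tx_id],
            )
        )
    return out


# ------------------------------------------------------------------ TSV

def write_counts(m: CountMatrix, counts_path, samples_path) -> None:
    m.counts.to_csv(counts_path, sep="\t")
    m.samples.to_csv(samples_path, sep="\t")


def read_counts(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountMatrix(counts, samples)


def annotations_to_frame(annotations) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": a.transcript_id,
                "utr5_len": a.utr5_len,
                "utr3_len": a.utr3_len,
                "utr3_class": a.utr3_class,
                "has_dej": a.has_dej,
                "n_dej": len(a.dej_positions),
                "n_uorf": len(a.uorfs),
            }
            for a in annotations
        ]
    )


def uorfs_to_frame(annotations) -> pd.DataFrame:
    rows = []
    for a in annotations:
        for u in a.uorfs:
            rows.append(
                {
                    "transcript_id": a.transcript_id,
                    "start": u.start,
                    "stop_end": u.stop_end,
                    "length": u.length,
                    "kozak_minus3": u.kozak_minus3 or ".",
                    "kozak_plus": u.kozak_plus or ".",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "start", "stop_end", "length",
                 "kozak_minus3", "kozak_plus"],
    )


def write_tx2gene(transcripts, path) -> None:
    pd.DataFrame(
        {"transcript_id": [t.transcript_id for t in transcripts],
         "gene_id": [t.gene_id for t in transcripts]}
    ).to_csv(path, sep="\t", index=False)


def read_tx2gene(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table.transcript_id, table.gene_id))
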