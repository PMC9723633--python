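"""piRNA target-site prediction on spliced mRNA sequences.

A piRNA engages its target antiparallel: g1, the piRNA 5' base, pairs with
the 3'-most base of the site on the mRNA.  Only Watson-Crick pairs (A:U,
G:C) count; G:U wobble is not treated as paired.  Two families of rules are
evaluated at each candidate offset:

* ``full`` — every position g1..gN paired over the piRNA's entire length;
* ``seed_plus_k`` (k in 8, 10, 12, 14) — perfect pairing of the seed
  g2-g7 plus at least k paired positions within the 14-position window
  g8-g21.  g1 and positions beyond g21 are unconstrained.

Each reported site carries its strongest satisfied rule
(full > seed+14 > seed+12 > seed+10 > seed+8).

Scanning uses a hexamer index over the transcript (the seed g2-g7 must be
perfectly paired under every rule) with a naive position-by-position
fallback; both return identical site sets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .models import (
    RULE_ORDER,
    RULE_RANK,
    SEED_RULE_MIN_MATCHES,
    PiRna,
    TargetSite,
    TranscriptModel,
    revcomp,
)

ALL_RULES = frozenset(RULE_RANK)
WINDOW = (7, 21)  # g8..g21 as 0-based piRNA indices [7, 21)


@dataclass(frozen=True)
class TranscriptSeq:
    """Bare scannable sequence; scanning needs no exon or CDS structure."""

    transcript_id: str
    sequence: str


def filter_pirnas(pirnas, min_fpm: float = 1.0) -> list[PiRna]:
    """Keep piRNAs whose normalized abundance is >= ``min_fpm`` (inclusive)."""
    return [p for p in pirnas if p.abundance_fpm >= min_fpm]


def pair_profile(pirna: PiRna, transcript: TranscriptModel, t_start: int) -> list[bool]:
    """Watson-Crick pairing profile over g1..gN at a given site.

    ``t_start`` is the transcript coordinate opposite g1; position gi is
    checked against transcript base ``t_start - (i - 1)``.
    """
    n = pirna.length
    if t_start - n + 1 < 0 or t_start >= len(transcript.sequence):
        raise ValueError(
            f"site [{t_start - n + 1}, {t_start}] outside transcript "
            f"{transcript.transcript_id}"
        )
    seq = transcript.sequence
    rc = revcomp(pirna.sequence)  # rc[k] is the required base at site 5'+k
    lo = t_start - n + 1
    return [seq[lo + k] == rc[k] for k in range(n)][::-1]


def satisfied_rules(profile: list[bool]) -> tuple[frozenset, int]:
    """Every rule a pairing profile satisfies, plus its g8-g21 match count."""
    window_matches = sum(profile[WINDOW[0] : WINDOW[1]])
    rules = set()
    if all(profile):
        rules.add("full")
    if len(profile) >= 7 and all(profile[1:7]):
        for rule, k in SEED_RULE_MIN_MATCHES.items():
            if window_matches >= k:
                rules.add(rule)
    return frozenset(rules), window_matches


def _sites_for_pair(pirna, tx, offsets, rules) -> list[TargetSite]:
    sites = []
    for t_start in offsets:
        profile = pair_profile(pirna, tx, t_start)
        satisfied, wm = satisfied_rules(profile)
        if satisfied & rules:
            strongest = max(satisfied, key=RULE_RANK.__getitem__)
            sites.append(
                TargetSite(
                    pirna_id=pirna.pirna_id,
                    transcript_id=tx.transcript_id,
                    t_start=t_start,
                    rule=strongest,
                    window_matches=wm,
                )
            )
    return sites


def scan_naive(pirnas, transcripts, rules=ALL_RULES) -> list[TargetSite]:
    """Position-by-position scan of every offset of every transcript."""
    rules = frozenset(rules)
    out = []
    for tx in transcripts:
        length = len(tx.sequence)
        for p in pirnas:
            if p.length > length:
                continue
            offsets = range(p.length - 1, length)
            out.extend(_sites_for_pair(p, tx, offsets, rules))
    return out


def scan(pirnas, transcripts, rules=ALL_RULES) -> list[TargetSite]:
    """Hexamer-indexed scan; identical output to :func:`scan_naive`.

    Every rule requires the seed g2-g7 fully paired (a full-length duplex
    implies it), so candidate offsets are exactly the transcript positions
    whose hexamer equals the reverse complement of the seed.
    """
    rules = frozenset(rules)
    unknown = rules - ALL_RULES
    if unknown:
        raise ValueError(f"unknown rules: {sorted(unknown)}")
    out = []
    for tx in transcripts:
        seq = tx.sequence
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(seq) - 5):
            index[seq[i : i + 6]].append(i)
        for p in pirnas:
            if p.length > len(seq):
                continue
            # seed g2-g7 pairs transcript positions t_start-6 .. t_start-1
            want = revcomp(p.sequence[1:7])
            offsets = [
                i + 6
                for i in index.get(want, ())
                if p.length - 1 <= i + 6 < len(seq)
            ]
            out.extend(_sites_for_pair(p, tx, offsets, rules))
    return out


def aggregate_to_genes(sites, tx2gene: dict[str, str]) -> pd.DataFrame:
    """Collapse transcript-level sites to per-gene target calls.

    A gene is targeted under rule r iff any of its transcripts carries a
    site whose rule is at least as strong as r.  Returns one row per gene
    with the best rule, per-rule site counts, and boolean targeted-at-rule
    flags (cumulative down the rule ordering).
    """
    unmapped = {s.transcript_id for s in sites} - set(tx2gene)
    if unmapped:
        raise ValueError(f"transcripts without a gene mapping: {sorted(unmapped)[:5]}")
    per_gene: dict[str, list[TargetSite]] = defaultdict(list)
    for s in sites:
        per_gene[tx2gene[s.transcript_id]].append(s)
    rows = []
    for gene, gsites in sorted(per_gene.items()):
        best = max(RULE_RANK[s.rule] for s in gsites)
        row = {
            "gene_id": gene,
            "n_sites": len(gsites),
            "best_rule": [r for r, i in RULE_RANK.items() if i == best][0],
        }
        for rule, rank in RULE_RANK.items():
            row[f"n_{rule}"] = sum(s.rule == rule for s in gsites)
            row[f"targeted_{rule}"] = best >= rank
        rows.append(row)
    columns = (
        ["gene_id", "n_sites", "best_rule"]
        + [f"n_{r}" for r in RULE_RANK]
        + [f"targeted_{r}" for r in RULE_RANK]
    )
    return pd.DataFrame(rows, columns=columns)


def sites_to_frame(sites, pirna_lengths: dict[str, int]) -> pd.DataFrame:
    """BED-like table of sites in transcript space (0-based half-open)."""
    rows = [
        {
            "transcript_id": s.transcript_id,
            "start": s.t_start - pirna_lengths[s.pirna_id] + 1,
            "end": s.t_start + 1,
            "pirna_id": s.pirna_id,
            "rule": s.rule,
            "window_matches": s.window_matches,
        }
        for s in sites
    ]
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "start", "end", "pirna_id", "rule", "window_matches"],
    )
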