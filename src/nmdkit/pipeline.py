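"""End-to-end orchestration: simulate -> annotate -> DE -> scan -> enrich.

A run is driven by a :class:`RunConfig` (YAML on disk) and writes every
stage's tables plus a manifest (config hash, package version, seed) into
an output directory.  Stage outputs are pure functions of their inputs, so
re-running with the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diffexpr, features, io, pirna, stats, synthetic

log = logging.getLogger("nmdkit")


@dataclass
class RunConfig:
    """Thresholds and inputs of one pipeline run; defaults are the
    analysis defaults (DE |log2FC| >= 1.5 at padj <= 0.05, dEJ >= 50 nt,
    uORF >= 30 nt, 3'UTR bins at 350/1500 nt, piRNA FPM >= 1)."""

    seed: int = 0
    outdir: str = "nmdkit_run"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    lfc_threshold: float = 1.5
    alpha: float = 0.05
    utr3_edges: tuple[int, int] = (350, 1500)
    dej_min_dist: int = 50
    uorf_min_len: int = 30
    min_fpm: float = 1.0
    pirna_rules: tuple[str, ...] = tuple(sorted(pirna.ALL_RULES))
    gene_filter: tuple[int, int] = (10, 3)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["utr3_edges"] = list(self.utr3_edges)
        d["pirna_rules"] = list(self.pirna_rules)
        d["gene_filter"] = list(self.gene_filter)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("utr3_edges", "pirna_rules", "gene_filter"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def run(config: RunConfig) -> Path:
    """Execute the full pipeline on synthetic data; returns the run dir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = synthetic.SimConfig(seed=config.seed, **config.sim)
    log.info("simulating: %d genes, %d piRNAs", sim_cfg.n_genes, sim_cfg.n_pirnas)
    sim = synthetic.simulate(sim_cfg)

    io.write_gtf(sim.transcripts, out / "transcripts.gtf")
    io.write_transcript_fasta(sim.transcripts, out / "transcripts.fa")
    io.write_counts(sim.counts, out / "counts.tsv", out / "samples.tsv")
    io.write_pirna_fasta(sim.pirnas, out / "pirnas.fa", out / "pirna_fpm.tsv")
    io.write_tx2gene(sim.transcripts, out / "tx2gene.tsv")
    (out / "ground_truth.json").write_text(sim.truth.to_json())

    annotations, skipped = features.annotate_set(
        sim.transcripts,
        dej_min_dist=config.dej_min_dist,
        uorf_min_len=config.uorf_min_len,
        utr3_edges=config.utr3_edges,
    )
    ann = io.annotations_to_frame(annotations)
    ann.to_csv(out / "nmd_features.tsv", sep="\t", index=False)
    io.uorfs_to_frame(annotations).to_csv(out / "uorfs.tsv", sep="\t", index=False)
    if skipped:
        log.warning("%d transcripts lacked a UTR and were skipped", len(skipped))

    filtered = diffexpr.filter_low_counts(sim.counts, *config.gene_filter)
    de_tables = {}
    for ct in synthetic.CELL_TYPES:
        table = diffexpr.classify_de(
            diffexpr.nb_wald_test(filtered, cell_type=ct),
            lfc_threshold=config.lfc_threshold,
            alpha=config.alpha,
        )
        table.to_csv(out / f"de_{ct}.tsv", sep="\t", index=False)
        de_tables[ct] = table
    patterns = diffexpr.partition_patterns(de_tables["spc"], de_tables["rs"])
    patterns.to_csv(out / "patterns.tsv", sep="\t", index=False)

    kept = pirna.filter_pirnas(sim.pirnas, min_fpm=config.min_fpm)
    sites = pirna.scan(kept, sim.transcripts, rules=set(config.pirna_rules))
    lengths = {p.pirna_id: p.length for p in sim.pirnas}
    pirna.sites_to_frame(sites, lengths).to_csv(
        out / "pirna_sites.tsv", sep="\t", index=False
    )
    tx2gene = {t.transcript_id: t.gene_id for t in sim.transcripts}
    gene_targets = pirna.aggregate_to_genes(sites, tx2gene)
    gene_targets.to_csv(out / "pirna_gene_targets.tsv", sep="\t", index=False)

    enrich = _enrichment_report(
        de_tables["rs"], ann, tx2gene, gene_targets, config
    )
    (out / "enrichment.json").write_text(json.dumps(enrich, indent=1, sort_keys=True))

    manifest = {
        "nmdkit_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "n_transcripts": len(sim.transcripts),
        "n_pirnas": len(sim.pirnas),
        "n_sites": len(sites),
        "skipped_transcripts": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _enrichment_report(de_rs, ann, tx2gene, gene_targets, config) -> dict:
    """Feature-proportion and 3'UTR statistics for the round-spermatid DE."""
    # gene-level annotation: a gene carries a feature if any transcript does
    ann_g = ann.assign(gene_id=ann.transcript_id.map(tx2gene))
    gene_feats = (
        ann_g.groupby("gene_id")
        .agg(
            has_dej=("has_dej", "any"),
            has_uorf=("n_uorf", lambda s: bool((s > 0).any())),
            long_utr3=("utr3_class", lambda s: bool((s == "long").any())),
            utr3_len=("utr3_len", "max"),
        )
        .reset_index()
        .rename(columns={"gene_id": "feature_id"})
    )
    targeted = set(gene_targets.gene_id) if len(gene_targets) else set()
    gene_feats["pirna_target"] = gene_feats.feature_id.isin(targeted)
    props, tests = stats.feature_proportions(
        de_rs[["feature_id", "de_class"]], gene_feats
    )
    report = {
        "feature_proportions": props.to_dict(orient="records"),
        "feature_tests": tests.to_dict(orient="records"),
    }
    ann_for_lfc = gene_feats.merge(
        ann_g.groupby("gene_id").utr3_class.first().rename("utr3_class"),
        left_on="feature_id",
        right_index=True,
    )
    try:
        lfc = stats.lfc_by_utr3_class(de_rs, ann_for_lfc)
        report["lfc_by_utr3_class"] = {
            "medians": lfc["medians"],
            "sizes": lfc["sizes"],
            "kw_h": lfc["kw_h"],
            "kw_p": lfc["kw_p"],
            "dunn": lfc["dunn"].to_dict(orient="records"),
        }
    except ValueError as exc:
        report["lfc_by_utr3_class"] = {"skipped": str(exc)}
    utr3 = stats.median_utr3_by_class(de_rs, ann_for_lfc)
    report["utr3_by_de_class"] = {
        "medians": utr3["medians"],
        "sizes": utr3["sizes"],
        "pairwise": utr3["pairwise"].to_dict(orient="records"),
        "excluded": utr3["excluded"],
    }
    return report
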