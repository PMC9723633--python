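"""Synthetic transcriptomes, count matrices and piRNA populations with
machine-readable planted ground truth.

The generator emulates the study design every downstream stage expects:
spliced multi-exon transcripts with annotated CDS and both UTRs; a
two-genotype (control / cko) x two-cell-type (spc / rs) design with
negative-binomial counts and planted per-gene log2 fold changes; a piRNA
population (24-35 nt) with target sites written into transcript 3'UTRs at
controlled pairing-rule strength; and a planted association between
upregulation and long 3'UTRs, implemented as an odds multiplier on the
up-direction that grows with the 3'UTR length class.

Everything planted is re-derivable by scanning the emitted sequences:
5'UTRs contain no AUG other than planted uORF starts, planted uORFs carry
a purine at -3 and stop upstream of the main AUG, non-planted transcripts
carry no exon junction 50 nt or more past the stop, and planted piRNA
sites are exact reverse complements with mismatches only at the positions
that set their recorded rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .diffexpr import CountMatrix
from .models import PiRna, TranscriptModel, revcomp

import pandas as pd

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGU"
    for b in "ACGU"
    for c in "ACGU"
    if a + b + c not in ("UAA", "UAG", "UGA")
)
_STOPS = ("UAA", "UAG", "UGA")
_BASES = "ACGU"
CELL_TYPES = ("spc", "rs")
_UTR3_CLASSES = ("short", "medium", "long")


class ConfigError(ValueError):
    """A SimConfig cannot host the features it asks for."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    n_genes: int = 100
    n_transcripts_per_gene: int = 1
    exon_count_range: tuple[int, int] = (2, 8)
    utr5_length_range: tuple[int, int] = (150, 400)
    cds_codon_range: tuple[int, int] = (40, 200)
    # (probability, (min_len, max_len)) for short / medium / long 3'UTRs
    utr3_length_mixture: tuple = (
        (0.4, (100, 349)),
        (0.4, (350, 1500)),
        (0.2, (1501, 3000)),
    )
    uorf_plant_rate: float = 0.3
    dej_plant_rate: float = 0.3
    nb_mean_range: tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 0.05
    planted_lfc: float = 2.0
    frac_de_up: float = 0.1
    frac_de_down: float = 0.1
    long_utr_up_bias: float = 3.0
    n_pirnas: int = 100
    pirna_length_range: tuple[int, int] = (24, 35)
    target_plant_rate: float = 0.5
    pirna_low_fpm_rate: float = 0.2
    replicates: int = 3

    def __post_init__(self) -> None:
        probs = [
            self.uorf_plant_rate,
            self.dej_plant_rate,
            self.frac_de_up,
            self.frac_de_down,
            self.target_plant_rate,
            self.pirna_low_fpm_rate,
        ] + [p for p, _ in self.utr3_length_mixture]
        if any(not 0 <= p <= 1 for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if abs(sum(p for p, _ in self.utr3_length_mixture) - 1) > 1e-9:
            raise ConfigError("utr3 mixture probabilities must sum to 1")
        if self.frac_de_up + self.frac_de_down > 1:
            raise ConfigError("frac_de_up + frac_de_down must be <= 1")
        for name in (
            "exon_count_range",
            "utr5_length_range",
            "cds_codon_range",
            "nb_mean_range",
            "pirna_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be positive and ordered")
        for _, (lo, hi) in self.utr3_length_mixture:
            if lo <= 0 or hi < lo:
                raise ConfigError("utr3 length ranges must be positive and ordered")
        if self.replicates < 2:
            raise ConfigError("need >= 2 replicates per condition")
        if not (24 <= self.pirna_length_range[0] <= self.pirna_length_range[1] <= 35):
            raise ConfigError("pirna_length_range must lie within [24, 35]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.long_utr_up_bias < 1:
            raise ConfigError("long_utr_up_bias must be >= 1")
        if self.dej_plant_rate > 0:
            if self.exon_count_range[1] < 2:
                raise ConfigError(
                    "dej_plant_rate > 0 needs exon_count_range allowing >= 2 exons"
                )
            if any(lo < 51 for _, (lo, _) in self.utr3_length_mixture):
                raise ConfigError(
                    "dej_plant_rate > 0 needs every 3'UTR class >= 51 nt to host "
                    "a junction >= 50 nt past the stop"
                )
        if self.uorf_plant_rate > 0 and self.utr5_length_range[0] < 70:
            raise ConfigError(
                "uorf_plant_rate > 0 needs 5'UTRs >= 70 nt to host a >= 30 nt "
                "uORF with Kozak context"
            )


@dataclass
class PlantedSite:
    pirna_id: str
    transcript_id: str
    t_start: int
    rule: str
    window_mismatches: int


@dataclass
class GroundTruth:
    """Everything the generator planted, keyed for downstream checking."""

    # tx_id -> dict(gene_id, has_dej, uorf_intervals, utr3_len, utr3_class)
    transcripts: dict = field(default_factory=dict)
    # gene_id -> cell_type -> dict(de_class in {up, down, null}, lfc)
    genes: dict = field(default_factory=dict)
    pirna_sites: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "transcripts": self.transcripts,
            "genes": self.genes,
            "pirna_sites": [asdict(s) for s in self.pirna_sites],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        truth = cls(
            transcripts=payload["transcripts"],
            genes=payload["genes"],
            pirna_sites=[PlantedSite(**s) for s in payload["pirna_sites"]],
        )
        for rec in truth.transcripts.values():
            rec["uorf_intervals"] = [tuple(iv) for iv in rec["uorf_intervals"]]
        return truth


def _random_seq(rng, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, size=n)]


def _destroy_augs(seq: list[str], rng, protected=frozenset()) -> None:
    """Mutate bases in place until no AUG trigram remains outside plants.

    For each offending trigram the first mutable position is set to C; a C
    in any position of a trigram rules out AUG, and prepending C cannot
    complete an AUG in an overlapping frame.
    """
    changed = True
    while changed:
        changed = False
        for i in range(len(seq) - 2):
            if seq[i] == "A" and seq[i + 1] == "U" and seq[i + 2] == "G":
                if i in protected and i + 1 in protected and i + 2 in protected:
                    continue  # the planted uAUG itself
                for j in (i, i + 1, i + 2):
                    if j not in protected:
                        seq[j] = "C"
                        changed = True
                        break


def _build_utr5(rng, config: SimConfig, plant_uorf: bool):
    """Random 5'UTR with at most one (planted) uORF; returns (seq, intervals)."""
    utr5_len = int(rng.integers(*config.utr5_length_range, endpoint=True))
    seq = _random_seq(rng, utr5_len)
    intervals = []
    protected: set[int] = set()
    if plant_uorf:
        n_codons = int(rng.integers(10, 21))  # 30-63 nt incl. stop
        length = 3 * n_codons
        start = int(rng.integers(3, utr5_len - length + 1))
        body = ["A", "U", "G"]
        for _ in range(n_codons - 2):
            body.extend(_SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))])
        body.extend(_STOPS[rng.integers(0, 3)])
        # no stray AUG inside the planted ORF (any frame)
        _destroy_augs(body, rng, protected=frozenset({0, 1, 2}))
        seq[start : start + length] = body
        seq[start - 3] = "AG"[rng.integers(0, 2)]  # Kozak purine at -3
        protected = set(range(start, start + length)) | {start - 3}
        intervals.append((start, start + length))
    _destroy_augs(seq, rng, protected=frozenset(protected))
    return seq, intervals


def _place_exons(rng, config, total_len, stop_last, plant_dej):
    """Exon junction transcript coordinates honouring the dEJ plant flag."""
    n_exons = int(rng.integers(*config.exon_count_range, endpoint=True))
    if plant_dej:
        n_exons = max(n_exons, 2)
    non_dej_max = min(total_len - 1, stop_last + 49)
    junctions: set[int] = set()
    if plant_dej:
        junctions.add(int(rng.integers(stop_last + 50, total_len - 1, endpoint=True)))
    while len(junctions) < n_exons - 1:
        junctions.add(int(rng.integers(1, non_dej_max, endpoint=True)))
    return sorted(junctions)


def generate_transcriptome(config: SimConfig):
    """Generate transcript models plus the ground truth of planted features."""
    transcripts: list[TranscriptModel] = []
    truth = GroundTruth()
    mix_probs = np.array([p for p, _ in config.utr3_length_mixture])
    genome_cursor = 1000
    for g in range(config.n_genes):
        gene_id = f"G{g:05d}"
        rng = np.random.default_rng([config.seed, g])
        cls_idx = int(rng.choice(3, p=mix_probs))
        truth.genes[gene_id] = _assign_de_truth(rng, config, _UTR3_CLASSES[cls_idx])
        for t in range(config.n_transcripts_per_gene):
            tx_id = f"{gene_id}.T{t}"
            plant_uorf = rng.random() < config.uorf_plant_rate
            plant_dej = rng.random() < config.dej_plant_rate
            utr3_lo, utr3_hi = config.utr3_length_mixture[cls_idx][1]
            utr3_len = int(rng.integers(utr3_lo, utr3_hi, endpoint=True))
            utr5, uorf_intervals = _build_utr5(rng, config, plant_uorf)
            n_codons = int(rng.integers(*config.cds_codon_range, endpoint=True))
            cds = ["A", "U", "G"]
            for _ in range(n_codons - 2):
                cds.extend(_SENSE_CODONS[rng.integers(0, len(_SENSE_CODONS))])
            cds.extend(_STOPS[rng.integers(0, 3)])
            utr3 = _random_seq(rng, utr3_len)
            seq = "".join(utr5) + "".join(cds) + "".join(utr3)
            cds_start = len(utr5)
            cds_end = cds_start + len(cds)
            junctions = _place_exons(rng, config, len(seq), cds_end - 1, plant_dej)
            exon_bounds = [0, *junctions, len(seq)]
            tx_lengths = [b - a for a, b in zip(exon_bounds, exon_bounds[1:])]
            strand = "+" if rng.random() < 0.5 else "-"
            # genomic intervals ascend; on the minus strand the transcript's
            # first exon is the genomically last one
            genomic_lengths = tx_lengths if strand == "+" else tx_lengths[::-1]
            ascending, cursor = [], genome_cursor
            for ln in genomic_lengths:
                ascending.append((cursor, cursor + ln))
                cursor += ln + int(rng.integers(50, 500, endpoint=True))
            genome_cursor = cursor + int(rng.integers(100, 1000, endpoint=True))
            exons = ascending if strand == "+" else ascending[::-1]
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx_id,
                    gene_id=gene_id,
                    chromosome="chr1",
                    strand=strand,
                    exons=tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    sequence=seq,
                )
            )
            truth.transcripts[tx_id] = {
                "gene_id": gene_id,
                "has_dej": plant_dej,
                "uorf_intervals": uorf_intervals,
                "utr3_len": utr3_len,
                "utr3_class": _UTR3_CLASSES[cls_idx],
            }
    return transcripts, truth


def generate_de_truth(config: SimConfig) -> GroundTruth:
    """DE ground truth only, skipping sequence assembly.

    Draws the 3'UTR class and per-cell-type DE status for each gene with
    the same per-gene RNG streams as :func:`generate_transcriptome`, so the
    planted DE truth matches what the full generator would plant.  Each
    gene is recorded with a sequence-free transcript entry carrying its
    3'UTR class, enough for count simulation and class-level statistics.
    """
    truth = GroundTruth()
    mix_probs = np.array([p for p, _ in config.utr3_length_mixture])
    for g in range(config.n_genes):
        gene_id = f"G{g:05d}"
        rng = np.random.default_rng([config.seed, g])
        cls_idx = int(rng.choice(3, p=mix_probs))
        truth.genes[gene_id] = _assign_de_truth(rng, config, _UTR3_CLASSES[cls_idx])
        truth.transcripts[f"{gene_id}.T0"] = {
            "gene_id": gene_id,
            "has_dej": None,
            "uorf_intervals": [],
            "utr3_len": None,
            "utr3_class": _UTR3_CLASSES[cls_idx],
        }
    return truth


def _assign_de_truth(rng, config: SimConfig, utr3_class: str) -> dict:
    """Planted DE status per cell type, with class-graded up-direction odds."""
    p_de = config.frac_de_up + config.frac_de_down
    rank = _UTR3_CLASSES.index(utr3_class)
    out = {}
    for ct in CELL_TYPES:
        if rng.random() >= p_de or p_de == 0:
            out[ct] = {"de_class": "null", "lfc": 0.0}
            continue
        if config.frac_de_down == 0:
            p_up = 1.0
        else:
            odds = (config.frac_de_up / config.frac_de_down) * (
                config.long_utr_up_bias ** (rank - 1)
            )
            p_up = odds / (1 + odds)
        if rng.random() < p_up:
            out[ct] = {"de_class": "up", "lfc": config.planted_lfc}
        else:
            out[ct] = {"de_class": "down", "lfc": -config.planted_lfc}
    return out


def generate_counts(truth: GroundTruth, config: SimConfig) -> CountMatrix:
    """NB counts for the 2-genotype x 2-cell-type x replicates design.

    The control mean per gene and cell type is log-uniform over
    ``nb_mean_range``; the cko mean is multiplied by 2^(planted log2FC).
    Dispersion alpha gives Var = mu + alpha mu^2 (alpha = 0 is Poisson).
    """
    rng = np.random.default_rng([config.seed, 2**20 + 1])
    genes = sorted(truth.genes)
    sample_ids, meta = [], []
    for ct in CELL_TYPES:
        for geno in ("control", "cko"):
            for r in range(1, config.replicates + 1):
                sample_ids.append(f"{ct}_{geno}_{r}")
                meta.append({"genotype": geno, "cell_type": ct})
    lo, hi = config.nb_mean_range
    data = np.zeros((len(genes), len(sample_ids)), dtype=np.int64)
    for i, gene in enumerate(genes):
        base = {ct: float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) for ct in CELL_TYPES}
        for j, (sid, m) in enumerate(zip(sample_ids, meta)):
            mu = base[m["cell_type"]]
            if m["genotype"] == "cko":
                mu *= 2.0 ** truth.genes[gene][m["cell_type"]]["lfc"]
            if config.nb_dispersion <= 1e-12:
                data[i, j] = rng.poisson(mu)
            else:
                r_shape = 1.0 / config.nb_dispersion
                data[i, j] = rng.negative_binomial(r_shape, r_shape / (r_shape + mu))
    counts = pd.DataFrame(data, index=pd.Index(genes, name="feature_id"), columns=sample_ids)
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(counts, samples)


_PLANT_RULES = ("full", "seed_plus_14", "seed_plus_12", "seed_plus_10", "seed_plus_8")
_RULE_WINDOW_MISMATCH = {
    "full": 0,
    "seed_plus_14": 0,
    "seed_plus_12": 2,
    "seed_plus_10": 4,
    "seed_plus_8": 6,
}


def generate_pirnas(transcripts, config: SimConfig):
    """piRNA population with planted 3'UTR target sites.

    Returns (pirnas, planted sites, updated transcripts): planting writes
    the reverse complement of each targeting piRNA into a host 3'UTR, with
    mismatches confined to the positions that fix the recorded rule, so the
    scanner recovers every site at exactly that rule.  piRNAs longer than
    every available 3'UTR are skipped (no site planted).  A configurable
    fraction of non-planting piRNAs is emitted below 1 FPM.
    """
    if not transcripts:
        raise ValueError("transcriptome is empty")
    rng = np.random.default_rng([config.seed, 2**20 + 2])
    transcripts = list(transcripts)
    sites: list[PlantedSite] = []
    pirnas: list[PiRna] = []
    # per-transcript list of occupied 3'UTR intervals, to keep plants disjoint
    occupied: dict[int, list[tuple[int, int]]] = {}
    for k in range(config.n_pirnas):
        pid = f"piR{k:05d}"
        length = int(rng.integers(*config.pirna_length_range, endpoint=True))
        pseq = "".join(_random_seq(rng, length))
        plant = rng.random() < config.target_plant_rate
        planted = False
        if plant:
            planted = _plant_site(rng, pid, pseq, transcripts, occupied, sites)
        if planted or rng.random() >= config.pirna_low_fpm_rate:
            fpm = float(np.exp(rng.uniform(0.0, np.log(100.0))))
        else:
            fpm = float(rng.uniform(0.01, 0.99))
        pirnas.append(PiRna(pirna_id=pid, sequence=pseq, abundance_fpm=fpm))
    return pirnas, sites, transcripts


def _plant_site(rng, pid, pseq, transcripts, occupied, sites) -> bool:
    n = len(pseq)
    order = rng.permutation(len(transcripts))
    for ti in order:
        tx = transcripts[ti]
        if tx.utr3_len < n:
            continue
        taken = occupied.setdefault(ti, [])
        free = [
            u
            for u in range(tx.utr3_len - n + 1)
            if all(u + n <= s or u >= e for s, e in taken)
        ]
        if not free:
            continue
        u = int(free[rng.integers(0, len(free))])
        rule = _PLANT_RULES[rng.integers(0, len(_PLANT_RULES))]
        site = list(revcomp(pseq))  # site[k] pairs piRNA position g(n-k)
        n_mm = _RULE_WINDOW_MISMATCH[rule]
        if n_mm:
            g_positions = rng.choice(np.arange(8, 22), size=n_mm, replace=False)
            for g in g_positions:
                site[n - int(g)] = _mismatch_base(rng, pseq[int(g) - 1])
        elif rule == "seed_plus_14":
            # block the full rule outside the seed+window: g1 or g22..gN
            g = int(rng.choice([1, *range(22, n + 1)]))
            site[n - g] = _mismatch_base(rng, pseq[g - 1])
        utr3_start = tx.cds_end
        seq = list(tx.sequence)
        seq[utr3_start + u : utr3_start + u + n] = site
        transcripts[ti] = replace(tx, sequence="".join(seq))
        taken.append((u, u + n))
        sites.append(
            PlantedSite(
                pirna_id=pid,
                transcript_id=tx.transcript_id,
                t_start=utr3_start + u + n - 1,
                rule=rule,
                window_mismatches=n_mm,
            )
        )
        return True
    return False


def _mismatch_base(rng, pirna_base: str) -> str:
    """A target base that does not Watson-Crick pair the given piRNA base."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}[pirna_base]
    choices = [b for b in _BASES if b != comp]
    return choices[rng.integers(0, 3)]


@dataclass
class SimResult:
    config: SimConfig
    transcripts: list
    truth: GroundTruth
    counts: CountMatrix
    pirnas: list


def simulate(config: SimConfig) -> SimResult:
    """Run the full generator: transcriptome, counts, piRNAs with sites."""
    transcripts, truth = generate_transcriptome(config)
    counts = generate_counts(truth, config)
    if transcripts and config.n_pirnas:
        pirnas, sites, transcripts = generate_pirnas(transcripts, config)
        truth.pirna_sites = sites
    else:
        pirnas = []
    return SimResult(config, transcripts, truth, counts, pirnas)
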