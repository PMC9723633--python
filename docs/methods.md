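# Methods

## Transcript model and coordinates

All feature scanning operates on spliced mRNA coordinates: 0-based,
half-open, 5′→3′. A `TranscriptModel` carries genomic exon intervals in
transcript order (descending genomic coordinate on the minus strand), CDS
boundaries in transcript coordinates with `cds_end` one past the stop
codon's last base, and the spliced RNA sequence. Validation enforces an
AUG start, a terminal stop codon, CDS length a multiple of 3 and ≥ 6 nt,
and sequence length equal to the exon total. GTF I/O converts to and from
1-based inclusive coordinates at the file boundary; FASTA I/O converts
T↔U. Transcripts lacking an annotated 5′UTR or 3′UTR are skipped by the
annotator (reported, not silently dropped), since none of the three
features is well defined without both UTRs.

## NMD-inducing features

**dEJ.** Exon junctions are the transcript coordinates of the first base
of each non-initial exon. A junction qualifies as a downstream exon
junction when `junction − stop_last ≥ min_dist`, with `stop_last` the
stop codon's last base and `min_dist` defaulting to 50 nt, boundary
inclusive. Junctions at or upstream of the stop never qualify.

**uORF.** Every AUG in the 5′UTR opens a candidate that runs in frame to
the first stop codon anywhere on the transcript. Acceptance requires all
of: length (AUG through the stop's last base) ≥ 30 nt, i.e. ≥ 10 codons;
a Kozak context — purine three bases upstream of the uAUG **or** guanine
immediately after the AUG codon (the classical +4 when the A of AUG is
+1); and not containing the main ORF. The −3 test fails when the uAUG
sits fewer than 3 nt from the 5′ end (context unknown); the +4 test still
applies. Containment is interpreted strictly: a candidate is rejected iff
it is in frame with the main ORF and no in-frame stop occurs before the
main AUG — such a candidate's first stop is the main ORF's own stop, so
it reads through (and therefore contains) the entire main ORF.
Out-of-frame overlap into the CDS is permitted; such uORFs can still
stall or dissociate ribosomes before the main start. A stop-less
candidate is not an ORF and is ignored.

**3′UTR class.** short < 350 nt, medium 350–1500 nt, long > 1500 nt. The
three verbal ranges only tile the integers if both edges belong to the
medium class, so 350 and 1500 are medium. The edges are configuration;
the defaults reflect the germ-cell analysis this package supports.

The uORF scanner is verified against a brute-force oracle (enumerate
every AUG…stop interval, then filter) on random transcripts, and all
three scanners against planted ground truth with zero tolerated
discrepancies.

## piRNA target prediction

Pairing is Watson–Crick only (A:U, G:C); G:U wobble does not count as
paired. The duplex is antiparallel: g1, the piRNA's 5′ base, faces the
3′-most base of the site, so the site opposite a piRNA of length N at
`t_start` (the base opposite g1) occupies transcript positions
`t_start−N+1 … t_start`. Rules:

- `full`: every position g1…gN paired;
- `seed_plus_k`, k ∈ {8, 10, 12, 14}: seed g2–g7 perfectly paired and at
  least k paired positions in the 14-position window g8–g21. g1 and
  positions beyond g21 are unconstrained, so `seed_plus_14` means a fully
  paired window but tolerates, e.g., a g1 mismatch.

The rules are totally ordered (full > +14 > +12 > +10 > +8 for piRNAs
≥ 21 nt); a site is reported once with its strongest satisfied rule, and
a scan restricted to weak rules still returns strong sites (they satisfy
the weak rule a fortiori). Gene-level aggregation flags a gene under rule
r when any transcript carries a site of rule ≥ r.

Scanning uses a hexamer index: every rule requires the seed paired, so
candidate offsets are exactly the transcript positions whose hexamer is
the reverse complement of g2–g7. A naive every-offset scanner is kept and
tested to return identical sites. piRNAs are pre-filtered at FPM ≥ 1
(fragments per million, boundary inclusive), the abundance floor used for
round-spermatid piRNA populations.

No positional filter relative to predicted cleavage sites is applied, and
genomic (unspliced) scanning is out of scope: sites are predicted on
spliced transcript sequences and combined to genes.

## Differential expression

The DE engine is deliberately small and fully deterministic:

1. **Count filter** — keep features with ≥ `min_count` reads in
   ≥ `min_samples` samples (defaults 10/3 for genes, 20/3 for
   transcripts; both bounds inclusive).
2. **Size factors** — median-of-ratios over the features positive in all
   samples; scale-equivariant by construction.
3. **Dispersion** — per-feature method of moments,
   α̂ = (s² − x̄)/x̄² on normalized counts, estimated per genotype group
   and pooled by residual degrees of freedom, floored at 0 (Poisson).
4. **Wald test** — log2FC = log2((x̄_cko + 0.5)/(x̄_ctrl + 0.5)); the
   delta-method variance of a log2 group mean is (1/μ + α)/(n ln²2). The
   Wald statistic is referred to a t distribution with n₁+n₂−2 degrees of
   freedom rather than the normal: with 3 vs 3 replicates the plug-in
   dispersion makes the normal reference anticonservative, and the t
   reference is the standard small-sample correction. Features with zero
   counts in both groups get p = 1 and log2FC = 0.
5. **BH adjustment** (statsmodels step-up) and classification at
   |log2FC| ≥ 1.5, padj ≤ 0.05, boundaries inclusive. The thresholds are
   parameters (the knockout-overlap comparison, for instance, uses
   log2FC ≥ 1).

This stage omits dispersion shrinkage, fold-change shrinkage and outlier
handling on purpose: the package's value is everything downstream of the
DE call, and tables from a full-featured engine can be supplied as TSV
(`read_de_table`) and flow through classification, patterns and
enrichment unchanged.

**Patterns.** P1/P2/P3 = down in spermatocytes only / both / round
spermatids only; P4/P5/P6 the same for up. Genes significant in opposite
directions across the two cell types do not fit any of the six patterns
and are reported in an explicit `discordant` bucket rather than dropped.
Transition groups classify genes normally downregulated across the
meiotic-to-postmeiotic transition by their fate in the knockout: still
down (1), unchanged (2), up (3).

**Clustering.** Group-mean profiles of normalized counts, z-scaled per
gene (constant genes become zero profiles), complete-linkage
agglomerative clustering with Euclidean distance — the defaults of R's
`hclust`, exposed as parameters since the choice is conventional, not
principled. The dendrogram serializes to Newick.

## Enrichment statistics

Fisher's exact test is computed by exact integer hypergeometric
enumeration: with margins fixed, cell *a* is hypergeometric; one-sided
p-values are tail sums and the two-sided p sums every table whose pmf
does not exceed the observed one, compared on exact integer numerators so
ties are unambiguous. Per-margin weights are cached, making exhaustive
sweeps (every table with total ≤ 60) cheap. scipy's implementation serves
as an independent cross-check in the tests, never as the implementation.

Dunn's post hoc test uses the standard large-sample z on joint mean ranks
with tie correction, Bonferroni-adjusted over the three class pairs by
default (the adjustment is configurable — the original analyses used a
graphics package whose default is unspecified). Kruskal–Wallis carries
scipy's tie correction. The headline overlap enrichment is reported
one-sided (greater), with the two-sided and less-sided p always attached,
since the direction of the claim is enrichment but the convention used in
print is not recoverable.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design downstream stages expect:
2 genotypes × 2 cell types × 3 replicates; NB counts with control means
log-uniform on [20, 500] and dispersion 0.05 (typical of bulk RNA-seq of
sorted germ cells); planted log2FC of ±2 on 10% + 10% of genes; 3′UTR
lengths from a short/medium/long mixture (0.4/0.4/0.2 by default);
uORF and dEJ plant rates of 0.3; 100 piRNAs of 24–35 nt with a target
plant rate of 0.5 and 20% of non-targeting piRNAs below the FPM ≥ 1
filter.

Plants are constructed to be exactly re-derivable: 5′UTRs carry no AUG
except planted uAUGs (offending trigrams are mutated to C, which can
neither create an AUG nor a stop codon); planted uORFs sit wholly within
the 5′UTR with a purine at −3; non-planted transcripts have no junction
≥ 50 nt past the stop; planted piRNA sites are reverse complements
written into 3′UTRs with mismatches confined to the positions that set
the recorded rule (window mismatches 0/2/4/6 for seed+14/12/10/8, with a
g1-or-tail mismatch blocking `full` when the window is intact). Ambiguous
uORF cases (candidates overlapping the main ORF) are exercised by
dedicated adversarial fixtures in the test suite, not by the generator.

The planted association between upregulation and long 3′UTRs is an odds
multiplier on the up-direction of DE genes, graded by class rank (short
×bias⁻¹, medium ×1, long ×bias); with the default bias of 3 and equal
up/down rates the probability a DE gene is up becomes 0.25/0.5/0.75 for
short/medium/long. Grading the bias monotonically in length — rather than
boosting only the long class — matches the observation that the fold-change
shift strengthens with 3′UTR length and yields a strict expected ordering
of class medians.

Determinism: every per-gene stream is seeded as `(seed, gene_index)` and
counts/piRNAs use fixed offsets of the master seed, so identical configs
give byte-identical outputs, and `generate_de_truth` reproduces the DE
truth of the full generator without assembling sequences (used for
count-level simulations where sequences are irrelevant).

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level noise and mapping
ambiguity (counts are drawn, not aligned), isoform quantification
uncertainty (one transcript per gene by default), GC/length biases,
between-replicate dispersion heterogeneity, transposable elements and
piRNA precursors, wobble or bulged piRNA duplexes, and translational
context beyond the Kozak positions scanned.

## Simulation sizes and calibration checks

The shipped checks use: 500 transcripts for scanner recovery (zero false
positives/negatives tolerated); 50 piRNAs × 100 transcripts ≤ 2 kb for
scanner–oracle set equality; 2000 null genes for the false-positive rate
of the DE stage (raw p ≤ 0.05 expected near 0.05); 10 000 genes with
10% + 10% planted ±2 log2FC for power (≥ 0.8 at padj ≤ 0.05) and median
log2FC recovery (±0.25); and 900 genes in three equal 3′UTR classes with
bias 3 for the median-ordering signature (Kruskal–Wallis p < 0.01). DE
genes are planted in both directions so that median-of-ratios
normalization stays identifiable; planting only upregulation would bias
size factors upward in the knockout and shrink every estimated fold
change.

## Known limitations

- The Kozak "+1 guanine" criterion is applied at the base immediately
  after the AUG codon (classical +4); the phrasing of the original rule
  is ambiguous and other readings exist.
- The DE stage's dispersion estimate is per-feature with no sharing
  across genes; at 2–3 replicates its power trails shrinkage-based
  engines, which is why external DE tables are first-class inputs.
- Fisher's two-sided p uses probability-mass summation; engines using
  other two-sided definitions can differ near ties.
- The piRNA scanner treats transcripts as naked sequence: no structure,
  no accessibility, no cleavage-site positional prior.
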