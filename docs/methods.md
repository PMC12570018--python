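# Methods

This note records the models, conventions and numerical choices behind
`metamethyl`, and what its synthetic benchmarks do and do not demonstrate.

## Data model and conventions

All coordinates are 0-based half-open internally; conversion to and from
1-based formats (GFF3) happens only in the parsers and writers. A
methylation record is strand-specific: a palindromic motif like GATC has
one methylatable base on each strand and therefore two records (and two
motif instances) per occurrence window. bedMethyl input is accepted in the
full 18-column pileup dialect (valid coverage in column 10, modified-read
count in column 12) or a minimal 11-column layout, detected by column
count; modified-base codes map m→5mC, a→6mA, 21839→4mC, and unknown codes
are skipped (counted, not fatal) for forward compatibility. We standardise
on *valid* coverage; the read-level confidence filter applied by upstream
callers is treated as provenance, not re-applied.

Reports write motifs with the methylated base bracketed (G[6mA]TC).
Because published occurrence counts do not always state a strand
convention, density reports carry both the double-strand and plus-strand
counts.

## Profiling and categories

A group's methylation fraction at a motif instance is the
coverage-weighted pool Σn_mod/Σvalid_cov over that group's samples —
pooling reads, not averaging per-sample fractions, which is the standard
minimum-variance estimator and makes the result invariant to splitting a
sample in two. Sites below the 5× coverage floor (boundary inclusive) are
excluded from every aggregate; an instance with no surviving site is kept
with category `no_data`, never dropped, so data-sufficiency percentages
are well defined. Categories use fraction < 0.33 → low, 0.33–0.66
(closed) → medium, > 0.66 → high; the boundary assignment is explicit and
configurable. The headline category comes from the pooled set of all
samples unless a reference group is named.

## Motif discovery

Seeds are sites whose pooled fraction strictly exceeds the "high"
threshold (0.66) at ≥5× pooled coverage, per modification type. The ±5 bp
context around each seed is strand-normalised so the methylated base sits
at a fixed index. For every sub-window of length k ≤ 6 containing that
index, each concrete k-mer is tested for enrichment among seed contexts
against the contig's own empirical k-mer counts (both strands) with a 2×2
chi-squared (no continuity correction); the empirical background makes
the test robust to GC and composition skew. BH control runs across all
candidates at α = 0.01. The most significant concrete k-mer (ties: higher
seed count, then lexicographic — deterministic) is generalised position
by position: a Hamming-1 sibling is merged when its enrichment rate
(seed count / background count) reaches 0.5× the parent's, the merged
base set being rewritten as the minimal IUPAC code; the methylated
position itself is never merged. Flanking positions that become N are
trimmed. A candidate whose seed-site set is contained in an
already-reported motif's is redundant and dropped, which is what reduces
the candidate pile (GAT, ATC, xGATC, …) to the single maximal motif.
Fewer than 20 seeds for a type yields no call — this, not the chi-squared,
is the effective false-positive control at realistic background
methylation (≈2%), and null simulations confirm it. Bipartite Type I
motifs are representable only as explicit N-runs (e.g. ACAYNNNNNRTT)
within the 6-mer window limit of the discoverer; longer spacers are a
known limitation.

## Differential methylation

Two views, both BH-corrected across their own test family and flagged at
two levels: α = 0.01 (the correction level used throughout) and the
conventional 0.05 used when declaring per-contig significance — both
levels are reported because the field mixes them, and hiding the
discrepancy would be worse.

*Per contig×motif*: a two-sample two-sided Kolmogorov–Smirnov test
comparing, between groups, the per-instance group means (or the
per-instance standard errors across replicates, a population-
heterogeneity signal). Exact p-values when n·m ≤ 10 000, asymptotic
beyond. Contigs with fewer than 10 instances having data in both groups
are reported as `insufficient_data` rather than tested. We use
per-instance group means rather than concatenated per-sample values:
concatenation inflates the type-I rate, because the replicate values of
one instance share the same true fraction and are not independent draws.
A consequence worth stating: when a minority fraction q of instances is
shifted, the KS d statistic is bounded near q regardless of effect size,
so at q = 0.2 with 100 instances per group even a complete shift cannot
reach p < 0.01 (the exact tail at d = 0.2 sits near 0.04) — such signals
are detectable at the 0.05 level but not at 0.01. Power calibrations
therefore read the 0.05 flag; type-I calibrations use α = 0.01.

*Per instance*: counts are pooled within each group and compared with a
two-proportion chi-squared (Fisher's exact when any expected cell < 5);
delta = fraction(bottom) − fraction(top), so positive values mean more
methylated in the bottom group. Significant instances are annotated with
the nearest flanking gene and a promoter flag.

Promoters are the `window` nucleotides upstream of the start codon:
[start−w, start) for plus-strand genes, [end, end+w) for minus-strand
genes; w defaults to 60, with 70 supported for isolate-style analyses.

## RM balance and orphan methyltransferases

Counting treats a fused restriction-and-modification gene ("combined",
Type I/III) as both an MTase and an REase; a sensitivity report counts
fusions once (they then cancel). Specificity subunits count as "other".
An MTase is orphan within its genome group (MAG/bin when known, else
contig) unless a same-type REase either recognises an IUPAC-compatible
motif (equal-length positional-set intersection, either orientation) or —
when either party's motif is unknown — lies within 5 kb on the same
contig, the operon-linkage heuristic. The surplus statistic assumes each
of N role-assignable genes is independently MTase or REase with
probability ½: z = (n_M − n_R)/√N, two-sided normal p, with a permutation
alternative exposed for auditability. The null is deliberately simple and
declared, since surplus Z-scores in the literature rarely state one.

## Phage–host analyses

Density is occurrences per bp; spacing (bp per occurrence) is displayed
truncated toward zero, matching how such figures are printed (24 047/23 =
1045.5 → "every 1045 bp"), with the exact quotient kept in machine
output. The density comparison treats positions as Bernoulli trials:
Fisher's exact test up to 1000 total occurrences or whenever an expected
cell is below 5 (the chi-squared approximation can drift by a few
hundredths there), chi-squared beyond. Raw densities are reported as-is;
a mononucleotide-composition observed/expected ratio is available because
published "×-fold frequency" figures are sometimes composition-
normalised in ways their text does not specify — we do not attempt to
reproduce such ratios from raw counts.

Host matching scores the overlap between a phage's methylated-motif set
and each host's RM recognition set as a weighted Jaccard index, where two
motifs match if either IUPAC pattern subsumes the other in either
orientation at any alignment offset (so a 4-mer profile motif like ACAY
matches a bipartite recogniser ACAYNNNNNRTT). Weights are uniform or
information content (Σ 2 − log₂|degeneracy set| bits); ties rank by host
id. The score is a screen for candidate infection histories, not a test.

## Genome trends

GC skew is (G−C)/(G+C) per 10 kb window stepped by 1 kb (G+C = 0 windows
contribute 0); under the leading-strand G-excess convention the
cumulative sum attains its minimum at the replication origin and maximum
at the terminus, reported at window centres. A sequence with no skew
signal is degenerate (ori/ter undefined, flagged), not an error. Note
that reverse-complementing a genome reflects ori and ter coordinates but
does not swap them — the reverse complement is the same double-stranded
molecule. The methylation trend is a least-squares polynomial (default
quartic, the conventional shape for a single-extremum trend between ori
and ter) fitted on positions rescaled to [0,1] for conditioning, with
coefficients reported in both scalings and an RMS residual.

## Synthetic data

The generator emulates the statistical structure of a two-horizon
replicate design: i.i.d. contigs at a target GC (default 0.40, in the
range of the cold-water taxa this kind of data comes from), planted IUPAC
motifs whose instances arise by composition (with optional up-sampling to
a floor count), per instance×group true fractions drawn Beta with
concentration 50 (overdispersion comparable to real pileups without
extra parameters), a uniformly chosen differential subset shifted by
+δ in the bottom group (clipped to [0,1]), per-sample Poisson(λ = 30)
coverage with Binomial modified counts, a prophage whose planted-motif
density is thinned to ρ by single-base ablation away from the methylated
positions, non-overlapping gene models with Bernoulli(½) strands, an RM
table with a controlled orphan/paired imbalance, and optionally a
GC-skewed replichore structure with a planted origin. Default conditions:
two 100 kb contigs, G[6mA]TC at site fraction 0.8 over background 0.02,
three samples per group, 20% differential instances at δ = 0.3, a 30 kb
ρ = 0.5 prophage. One global seed drives named substreams so changing one
parameter perturbs only its own stream; the same config and seed produce
a byte-identical bundle.

What the generator does **not** model: read-level error and mapping
artefacts, copy-number and coverage bias along real replichores,
motif-context-dependent caller error, strand-biased coverage, and
community-level strain mixtures. Passing calibrations therefore
demonstrate correctness of the statistics under the declared observation
model, not robustness to caller- or mapping-induced structure in real
pileups.

## Calibration scales

Benchmarks run at desk scale on one CPU: 200 simulations for the KS
type-I/power and prophage-depletion calibrations, 50 per condition for
motif-discovery recovery and null control (150 kb / 100 kb contigs),
1000 draws for the surplus-z null, a 1 Mb genome for origin recovery and
1600 points for the trend fit — sizes chosen so each rate's binomial
uncertainty is small against its acceptance margin.

## Known limitations

- Discovery is limited to motifs expressible within a 6-mer window plus
  N-runs; variable-gap bipartite motifs are out of scope.
- The per-instance differential test assumes independent reads within a
  pooled group; within-sample read correlation would make its p-values
  anticonservative.
- Orphan detection trusts the upstream RM gene table; homology errors
  propagate.
- Contig order within a MAG is taken as given for trend analysis; no
  reordering is attempted.
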