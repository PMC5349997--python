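# Methods

## Coordinates and gene elements

All intervals are 0-based half-open internally. BED is consumed natively;
GTF (1-based closed) is converted on ingest. Overlap is strand-blind
everywhere: MeDIP fragments and peaks carry no usable strand, so every
region-to-element rule inherits that convention. Touching half-open
intervals merge — the candidate-DMR construction needs
union-of-covered-bases semantics, and `[a,b) ∪ [b,c) = [a,c)` under them.

One transcript model per `gene_id`. Elements are derived as: promoter =
2000 bp (configurable) immediately upstream of the strand-aware TSS,
clipped to chromosome bounds; 5'-UTR = exonic sequence between the
transcript start and the coding start (strand-aware), 3'-UTR symmetric;
CDS = exonic ∩ coding span; introns = gaps between consecutive exons. For
a coding gene the exonic bases partition exactly into UTR5 + CDS + UTR3
(property-tested). Non-coding genes (empty coding span) keep promoter and
introns but have no UTR/CDS elements. The promoter length is a convention,
not an estimate; every output header records it.

## Read filtering and QC statistics

A read is removed iff its fraction of undetermined (N) bases exceeds 10%
(strict >) or more than 50% (strict >) of its bases have Phred quality
≤ 20 (inclusive), with Q = −10·log₁₀(error rate), Phred+33 on parsing.
The decision is per-read, so filtering is order-independent.

Cytosine contexts: a C is CpG when followed by G, CHG when the next two
bases are H,G and CHH when both are H (H ∈ {A,C,T}); minus-strand
cytosines (plus-strand G) are read on the reverse complement. One uniform
end rule is applied on both strands: a cytosine lacking two downstream
bases stays unclassified, which keeps the label sets a partition and the
two strands symmetric. N is never a context base.

Depth-of-coverage, CpG-density binning, element distributions and
metagene profiles are computed exactly, per base, rather than by sampling
— correct and affordable at the multi-megabase scale this package
targets. A peak or read counts once in *every* element class it overlaps
(a peak across a CDS/intron junction contributes to both), and coverage
is the number of class bases covered at least once, so it can never
exceed the class's total length.

## DMR calling

Candidate DMRs are the merged union of the pair's two peak sets; each
sample's reads are counted per candidate with a ≥ 1 bp overlap rule
(a read spanning two candidates counts in both; candidates are disjoint by
construction). The test is Pearson's chi-square (1 df, no Yates
correction) on `[[k₁, N₁−k₁], [k₂, N₂−k₂]]` with library sizes N as
margins, evaluated in closed form, upper-tail p. The per-pair candidate
family is FDR-adjusted (Benjamini–Hochberg by default; Benjamini–Yekutieli
via config).

A candidate is a true DMR when raw p ≤ 0.01 **and** q ≤ 0.01 **and** the
normalized fold is strictly > 2, where fold = max(r, 1/r) with
r = (k₁/N₁)/(k₂/N₂). The 2-fold rule is applied to library-normalized
counts — raw-count ratios are not comparable across libraries; a
raw-count variant remains available. When one count is zero, 0.5 is added
to both counts for the fold computation only, keeping fold finite without
touching the test. Regions with zero reads in both samples are untestable
and never true DMRs. Swapping case and control leaves p and fold invariant
and flips the trend.

DMG classification is per (gene, element class): hyper when only uptrend
true DMRs overlap the element, hypo when only downtrend, mixed when both,
unmethylated when none — a pure function of the overlap topology.

## Expression

RPKM = 10⁹·k/(N·L) with N the reads mapped to genes in that sample and L
the gene's exonic length in bp. The pairwise test is the Audic–Claverie
exact conditional test for two sequencing libraries: under equal per-read
rates, conditional on count x in library 1,

    P(y | x) = r^y · (x+y)! / (x!·y!·(1+r)^(x+y+1)),   r = N₂/N₁,

two-sided p = min(1, 2·min(P(Y ≤ y), P(Y ≥ y))). Tails are summed in log
space (gammaln + logsumexp), exact to ~1e-10 relative for x+y ≤ 1e5 and
verified against direct tail summation. A chi-square 2×2 variant is
selectable via config; the test name is echoed in output headers.

Per pair, genes with zero counts in both samples are excluded from
testing and from the FDR family m — they are untestable and would only
dilute the adjustment. The family is adjusted with Benjamini–Yekutieli
(2001), the step-up procedure with harmonic inflation c(m) = Σ 1/i, valid
under arbitrary dependence; BY dominates BH pointwise (property-tested).
A gene is called up/down at FDR ≤ 0.001 with RPKM ratio strictly > 2 in
the corresponding direction. Aggregation counts calls in either direction
per gene across pairs (direction-consistent counts are also emitted) and
keeps genes called in ≥ k pairs (default 5). Call-pattern clustering uses
Euclidean distance with average linkage; the linkage matrix and leaf
order are exported for heatmap rendering.

## Enrichment

Per term with at least one selected member, the hypergeometric upper tail
P(X ≥ k) for a term of K universe members, n selected genes and universe
N. The Bonferroni multiplier m is the number of terms tested in the same
category, and is reported alongside every result for auditability. GO
categories (C/F/P) are flagged at corrected p ≤ 0.01, pathway terms at
≤ 0.05. Universe choice: for DEG enrichment, genes expressed in ≥ 1
sample; for DMG enrichment, all annotated genes; both configurable, since
background choice is a genuine free parameter of enrichment analysis. DMG
enrichment runs separately per gene element.

## Methylation–expression integration

Per (gene, pair, element), the DMG status is joined with
log₂(RPKM case/control). Genes with zero RPKM on either side have no
finite ratio; they are excluded from the distributions and tallied
separately. "Unmethylated" means the element overlaps no true DMR; mixed
elements are reported but sit outside the three-way comparison, which
mirrors the standard three-stratum plot. Distributions use 1-unit bins on
[−10, 10] with out-of-range values clamped into the edge bins; per
stratum the fractions sum to 1 (tolerance 1e-12).

## Synthetic data

The generator emulates the targeted study design: 10 case/control pairs,
single-end 49 bp reads, per-sample peak sets covering ~5% of the genome.
Defaults are the design conditions: 2 chromosomes × 4 Mb, 400 genes,
peak lengths 300–1500 bp, mean 100 reads per peak region, 100 planted
DMRs at 4-fold, 50 planted DEGs at 8-fold (log₂ fold 3), library-size
factors log-uniform within 2× per pair, negative-binomial counts with
dispersion 0.1. The genome sizes are chosen so a pair yields several
hundred candidate regions with planted signal in the minority, while a
full end-to-end run stays in the tens of seconds on one CPU.

Choices that matter:

- **Fold split.** A planted uptrend region at fold f gets case mean
  μ·√f and control mean μ/√f, so its normalized ratio is f while its
  average read mass stays μ; planted DEGs use the same geometric split on
  2^(lfc/2). With a balanced trend mix this also keeps the two library
  sizes equal in expectation.
- **Noise.** Negative binomial (variance μ + 0.1μ²) is the realistic
  default — and it makes the chi-square test visibly anticonservative, as
  it is on real overdispersed data: with default settings roughly a third
  of called DMRs are overdispersion artifacts. Calibration and recovery
  checks therefore run under the Poisson option, where the mean-variance
  relation matches the test's assumptions; that contrast is itself
  informative and deliberate.
- **Library sizes** are the realized read totals of each sample (peak
  reads plus a 20% uniform background component), so normalization code
  paths are exercised with real imbalance.
- **Terms** are random memberships; planted terms draw a configured
  multiple of the background fraction from the planted gene set.

What the generator does **not** emulate: sequencing errors at the read
level, mappability and GC bias, realistic human chromosome structure,
fragment-length effects, or any coupling between methylation and
expression (none is planted, which is exactly what the integration null
check relies on). Passing recovery tests on this generator demonstrates
that the decision rules are implemented correctly and calibrated under
their own assumptions — not that those thresholds are optimal for real
patient data.

## Determinism and numerics

One integer seed drives a single numpy Generator per stage (spawned
streams), so identical config + seed reproduces every output byte for
byte; the run manifest stores paths relative to the run directory and
records wall-clock timestamps only on request, keeping reruns comparable.
Chi-square and hypergeometric p-values come from SciPy distribution
functions; FDR adjustment uses SciPy's step-up implementation, verified
in tests against a direct evaluation of the BH/BY formulas; clustering
uses SciPy's linkage with its deterministic tie handling. Degenerate
inputs (empty peak sets, zero counts, empty strata, single-gene cluster
input) return empty-but-typed results rather than raising, except where
the input is contractually invalid (zero library sizes, inconsistent
hypergeometric arguments, malformed files — which name file and line).

## Pipeline

`run_all` executes simulate → qc → dmr → dmg → deg → enrich → methexpr,
records a manifest with per-stage inputs/outputs and status, aborts on
the first failing stage with its name, and uses exit code 2 for
configuration errors vs. 3 for stage failures. All thresholds live in one
`PipelineConfig` namespace and are echoed into every output header. The
per-base QC statistics (depth, element distribution, metagene, CpG
density) are computed for the first pair's samples; cheap per-peak
summaries cover all samples — a deliberate output-volume choice, the
functions accept any sample.
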