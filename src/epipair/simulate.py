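"""Truth-labeled synthetic data with the structure the analysis assumes.

The generator emulates the study design the pipeline targets: 10 paired
case/control samples, single-end 49 bp MeDIP reads, per-sample peak sets
covering about 5% of the genome, gene-level mRNA count matrices, and
GO/KEGG-style term memberships.  Differential signal is *planted*: a known
subset of peak regions gets a fixed fold difference in expected read count
between case and control, a known subset of genes gets a fixed expression
fold in designated pairs, and a known subset of terms oversamples the
planted genes.  Every planted entity is recorded in a :class:`TruthTable`
so recovery can be scored exactly.

Counts are negative-binomial by default (dispersion 0.1, biological
overdispersion); a Poisson option gives the clean mean-variance relation
needed for type-I-error calibration checks.  Everything is driven by one
integer seed through a single numpy Generator, so identical config + seed
reproduces outputs byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dmr import PeakSet
from .intervals import (
    AnnotationBundle,
    GeneModel,
    GenomicInterval,
    derive_elements,
    merge_intervals,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_genome",
    "simulate_methylome",
    "simulate_expression",
    "simulate_terms",
    "simulate_all",
    "MethylomeSim",
    "ExpressionSim",
]

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Simple_repeat")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_len: int = 4_000_000
    n_genes: int = 400
    max_exons: int = 5
    n_cpg_islands_per_chrom: int = 40
    n_repeats_per_chrom: int = 60
    promoter_len: int = 2000
    # paired design
    n_pairs: int = 10
    read_len: int = 49
    # methylome
    peak_fraction: float = 0.05
    peak_len_range: tuple[int, int] = (300, 1500)
    peak_mean_count: int = 100
    background_read_frac: float = 0.2
    n_planted_dmrs: int = 100
    dmr_fold: float = 4.0
    dmr_uptrend_frac: float = 0.5
    # expression
    expr_median_count: float = 100.0
    expr_log_sd: float = 1.0
    deg_mean_count: float = 200.0
    n_planted_degs: int = 50
    deg_log2_fold: float = 3.0
    deg_pairs_affected: int | None = None  # None -> all pairs
    # noise
    noise: str = "nb"  # "nb" | "poisson"
    nb_dispersion: float = 0.1
    # library sizes: per-pair factors log-uniform within this ratio of each other
    library_ratio_max: float = 2.0
    # terms
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    term_categories: tuple[str, ...] = ("P", "F", "C", "pathway")
    n_planted_terms: int = 1
    term_enrichment_ratio: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.peak_fraction < 1):
            raise ValueError("peak_fraction must be in (0, 1)")
        for name in ("n_chroms", "chrom_len", "n_genes", "n_pairs", "read_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise not in ("nb", "poisson"):
            raise ValueError("noise must be 'nb' or 'poisson'")


@dataclass
class TruthTable:
    """Ground truth of everything planted by the generator."""

    # pair_id -> list of (region, trend, fold)
    dmrs: dict[str, list[tuple[GenomicInterval, str, float]]] = field(
        default_factory=dict
    )
    # gene_id -> (direction, log2_fold, affected pair_ids)
    degs: dict[str, tuple[str, float, tuple[str, ...]]] = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)

    def dmr_regions(self, pair_id: str) -> dict[tuple[str, int, int], str]:
        return {
            (r.chrom, r.start, r.end): trend
            for r, trend, _ in self.dmrs.get(pair_id, [])
        }


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, cfg: SimulationConfig):
    """Counts from the configured noise model (var = mu + disp*mu^2 for NB)."""
    mean = np.asarray(mean, dtype=float)
    if cfg.noise == "poisson":
        return rng.poisson(mean)
    n = 1.0 / cfg.nb_dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, n: int,
                     probs=(0.295, 0.205, 0.205, 0.295)) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=probs)]


def _island_sequence(rng: np.random.Generator, n: int,
                     cpg_rate: float = 0.12) -> np.ndarray:
    """GC-rich sequence with explicit CpG dinucleotides planted at ``cpg_rate``."""
    out = _random_sequence(rng, n, probs=(0.18, 0.32, 0.32, 0.18))
    pos = np.flatnonzero(rng.random(n - 1) < cpg_rate)
    out[pos] = ord("C")
    out[pos + 1] = ord("G")
    return out


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], AnnotationBundle]:
    """Random genome with CpG islands, gene models and labeled repeats.

    Islands are GC/CpG-enriched stretches recorded in the annotation; genes
    are placed non-overlapping with room for their promoters; ~10% of genes
    are non-coding (empty CDS).  Derived elements use
    ``config.promoter_len``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom_sizes = {f"chr{i + 1}": config.chrom_len for i in range(config.n_chroms)}
    genome: dict[str, str] = {}
    cpg_islands: list[GenomicInterval] = []
    repeats: list[GenomicInterval] = []
    genes: dict[str, GeneModel] = {}
    gene_counter = 0
    genes_per_chrom = int(np.ceil(config.n_genes / config.n_chroms))

    for chrom, size in chrom_sizes.items():
        seq = _random_sequence(rng, size)
        # CpG islands: disjoint, sorted
        island_lens = rng.integers(300, 1500, size=config.n_cpg_islands_per_chrom)
        starts = np.sort(
            rng.choice(size // 2000, size=config.n_cpg_islands_per_chrom,
                       replace=False) * 2000
        )
        for s, ln in zip(starts.tolist(), island_lens.tolist()):
            e = min(s + int(ln), size)
            seq[s:e] = _island_sequence(rng, e - s)
            cpg_islands.append(GenomicInterval(chrom, s, e))
        # repeats: random, labeled, may overlap anything
        for _ in range(config.n_repeats_per_chrom):
            ln = int(rng.integers(100, 1000))
            s = int(rng.integers(0, size - ln))
            cls = REPEAT_CLASSES[int(rng.integers(len(REPEAT_CLASSES)))]
            repeats.append(GenomicInterval(chrom, s, s + ln, ".", cls))
        genome[chrom] = seq.tobytes().decode("ascii")

        # gene models: sequential placement with promoter head-room
        cursor = config.promoter_len + int(rng.integers(0, 2000))
        for _ in range(genes_per_chrom):
            if gene_counter >= config.n_genes:
                break
            n_exons = int(rng.integers(1, config.max_exons + 1))
            exons = []
            pos = cursor
            for k in range(n_exons):
                ex_len = int(rng.integers(200, 800))
                exons.append((pos, pos + ex_len))
                pos += ex_len
                if k < n_exons - 1:
                    pos += int(rng.integers(200, 1500))
            tx_start, tx_end = exons[0][0], exons[-1][1]
            if tx_end + config.promoter_len + 2000 > size:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            if rng.random() < 0.10:  # non-coding
                cds_start = cds_end = tx_start
            else:
                first_s, first_e = exons[0]
                last_s, last_e = exons[-1]
                cds_start = first_s + int(rng.integers(30, max(31, (first_e - first_s) // 2)))
                cds_end = last_e - int(rng.integers(30, max(31, (last_e - last_s) // 2)))
                if cds_start >= cds_end:
                    cds_start, cds_end = first_s, last_e
            gene_counter += 1
            gid = f"gene{gene_counter:04d}"
            genes[gid] = GeneModel(gid, chrom, strand, tx_start, tx_end,
                                   cds_start, cds_end, tuple(exons))
            cursor = tx_end + config.promoter_len + int(rng.integers(500, 3000))

    elements = {
        gid: derive_elements(g, config.promoter_len,
                             chrom_length=chrom_sizes[g.chrom])
        for gid, g in genes.items()
    }
    bundle = AnnotationBundle(genes, elements, cpg_islands, repeats, chrom_sizes)
    bundle.validate()
    return genome, bundle


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

@dataclass
class MethylomeSim:
    """Per-pair synthetic MeDIP data: peaks, reads, library sizes."""

    pair_ids: list[str]
    # sample_id -> PeakSet / read intervals
    peak_sets: dict[str, PeakSet]
    reads: dict[str, list[GenomicInterval]]
    # pair_id -> (case_sample, control_sample)
    pairs: dict[str, tuple[str, str]]
    truth: TruthTable


def _peak_scaffold(rng: np.random.Generator, config: SimulationConfig,
                   chrom_sizes: Mapping[str, int]) -> list[GenomicInterval]:
    """Disjoint peak regions covering ~``peak_fraction`` of the genome."""
    lo, hi = config.peak_len_range
    regions = []
    for chrom, size in chrom_sizes.items():
        target = config.peak_fraction * size
        covered = 0
        # lay peaks on a jittered grid so they stay disjoint and separated
        mean_len = (lo + hi) / 2
        n_peaks = int(np.ceil(target / mean_len))
        slot = size // max(n_peaks, 1)
        for i in range(n_peaks):
            ln = int(rng.integers(lo, hi + 1))
            ln = min(ln, slot - config.read_len - 2)
            if ln < config.read_len:
                ln = config.read_len
            max_off = max(slot - ln - config.read_len - 1, 1)
            s = i * slot + int(rng.integers(0, max_off))
            e = min(s + ln, size)
            if e - s >= config.read_len:
                regions.append(GenomicInterval(chrom, s, e))
                covered += e - s
            if covered >= target:
                break
    return merge_intervals(regions)


def simulate_methylome(
    config: SimulationConfig,
    annotation: AnnotationBundle,
    rng: np.random.Generator | None = None,
) -> MethylomeSim:
    """Paired MeDIP peak sets and aligned-read intervals with planted DMRs.

    Each pair shares one peak scaffold; ``n_planted_dmrs`` scaffold regions
    get a ``dmr_fold`` difference in expected read count, split
    geometrically (case mean*sqrt(f), control mean/sqrt(f) for uptrend) so
    the region's average read mass stays at ``peak_mean_count``.  Expected
    counts scale with per-sample library factors drawn log-uniform within
    ``library_ratio_max`` of each other; reads of length ``read_len`` are
    placed uniformly inside their region; background reads (a fixed
    fraction of the in-peak mass) land uniformly genome-wide.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    chrom_sizes = annotation.chrom_sizes
    truth = TruthTable()
    peak_sets: dict[str, PeakSet] = {}
    reads: dict[str, list[GenomicInterval]] = {}
    pairs: dict[str, tuple[str, str]] = {}
    pair_ids = [f"pair{i + 1:02d}" for i in range(config.n_pairs)]

    for pair_id in pair_ids:
        scaffold = _peak_scaffold(rng, config, chrom_sizes)
        n_regions = len(scaffold)
        # fold 1 is no differential signal: nothing to plant
        n_planted = (0 if config.dmr_fold == 1.0
                     else min(config.n_planted_dmrs, n_regions))
        planted_idx = rng.choice(n_regions, size=n_planted, replace=False)
        planted_idx.sort()
        up = rng.random(n_planted) < config.dmr_uptrend_frac
        sqrt_f = np.sqrt(config.dmr_fold)
        mult_case = np.ones(n_regions)
        mult_ctrl = np.ones(n_regions)
        mult_case[planted_idx[up]] *= sqrt_f
        mult_ctrl[planted_idx[up]] /= sqrt_f
        mult_case[planted_idx[~up]] /= sqrt_f
        mult_ctrl[planted_idx[~up]] *= sqrt_f
        truth.dmrs[pair_id] = [
            (scaffold[i], "uptrend" if u else "downtrend", config.dmr_fold)
            for i, u in zip(planted_idx.tolist(), up.tolist())
        ]

        log_ratio = np.log(config.library_ratio_max)
        factors = np.exp(rng.uniform(-log_ratio / 2, log_ratio / 2, size=2))
        sample_ids = (f"{pair_id}_case", f"{pair_id}_control")
        pairs[pair_id] = sample_ids
        for sample_id, factor, mult in zip(
            sample_ids, factors, (mult_case, mult_ctrl)
        ):
            means = config.peak_mean_count * factor * mult
            counts = _draw_counts(rng, means, config)
            sample_reads: list[GenomicInterval] = []
            for region, c in zip(scaffold, counts.tolist()):
                span = region.length - config.read_len
                starts = region.start + rng.integers(0, span + 1, size=int(c))
                sample_reads.extend(
                    GenomicInterval(region.chrom, int(s), int(s) + config.read_len)
                    for s in starts.tolist()
                )
            n_bg = int(config.background_read_frac * len(sample_reads))
            chroms = list(chrom_sizes)
            bg_chrom = rng.integers(0, len(chroms), size=n_bg)
            for ci in bg_chrom.tolist():
                chrom = chroms[ci]
                s = int(rng.integers(0, chrom_sizes[chrom] - config.read_len))
                sample_reads.append(
                    GenomicInterval(chrom, s, s + config.read_len)
                )
            reads[sample_id] = sample_reads
            peak_sets[sample_id] = PeakSet(
                sample_id, list(scaffold), library_size=max(len(sample_reads), 1)
            )
    return MethylomeSim(pair_ids, peak_sets, reads, pairs, truth)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSim:
    gene_ids: list[str]
    gene_lengths: np.ndarray
    counts: np.ndarray  # genes x samples
    sample_ids: list[str]
    pairs: dict[str, tuple[str, str]]
    truth: TruthTable


def simulate_expression(
    config: SimulationConfig,
    annotation: AnnotationBundle | None = None,
    rng: np.random.Generator | None = None,
) -> ExpressionSim:
    """Gene-level count matrices for all pairs with planted DEGs.

    Baseline per-gene rates are log-normal (median ``expr_median_count``);
    planted genes get baseline ``deg_mean_count`` and, in their affected
    pairs, a geometric fold split: case rate * 2^(lfc/2), control rate *
    2^(-lfc/2) for an "up" gene (so the gene's average mass is
    fold-independent).  Library factors are per-sample, log-uniform within
    ``library_ratio_max`` per pair.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if annotation is not None and annotation.genes:
        gene_ids = sorted(annotation.genes)
        gene_lengths = np.array(
            [
                sum(e - s for s, e in annotation.genes[g].exons)
                for g in gene_ids
            ],
            dtype=np.int64,
        )
    else:
        gene_ids = [f"gene{i + 1:04d}" for i in range(config.n_genes)]
        gene_lengths = rng.integers(500, 5000, size=config.n_genes)
    n_genes = len(gene_ids)
    base = np.exp(
        np.log(config.expr_median_count)
        + config.expr_log_sd * rng.standard_normal(n_genes)
    )

    pair_ids = [f"pair{i + 1:02d}" for i in range(config.n_pairs)]
    n_planted = min(config.n_planted_degs, n_genes)
    planted = rng.choice(n_genes, size=n_planted, replace=False)
    planted.sort()
    directions = np.where(rng.random(n_planted) < 0.5, "up", "down")
    base[planted] = config.deg_mean_count
    k_aff = (config.deg_pairs_affected
             if config.deg_pairs_affected is not None else config.n_pairs)
    k_aff = min(k_aff, config.n_pairs)
    truth = TruthTable()
    affected: dict[int, set[str]] = {}
    for gi, direction in zip(planted.tolist(), directions.tolist()):
        pick = rng.choice(config.n_pairs, size=k_aff, replace=False)
        aff = tuple(pair_ids[i] for i in sorted(pick.tolist()))
        affected[gi] = set(aff)
        truth.degs[gene_ids[gi]] = (direction, config.deg_log2_fold, aff)

    log_ratio = np.log(config.library_ratio_max)
    sample_ids: list[str] = []
    pairs: dict[str, tuple[str, str]] = {}
    cols = []
    half = 2.0 ** (config.deg_log2_fold / 2.0)
    for pair_id in pair_ids:
        factors = np.exp(rng.uniform(-log_ratio / 2, log_ratio / 2, size=2))
        case_id, ctrl_id = f"{pair_id}_case", f"{pair_id}_control"
        pairs[pair_id] = (case_id, ctrl_id)
        mult_case = np.ones(n_genes)
        mult_ctrl = np.ones(n_genes)
        for gi, direction in zip(planted.tolist(), directions.tolist()):
            if pair_id not in affected[gi]:
                continue
            if direction == "up":
                mult_case[gi], mult_ctrl[gi] = half, 1.0 / half
            else:
                mult_case[gi], mult_ctrl[gi] = 1.0 / half, half
        for sid, factor, mult in ((case_id, factors[0], mult_case),
                                  (ctrl_id, factors[1], mult_ctrl)):
            cols.append(_draw_counts(rng, base * factor * mult, config))
            sample_ids.append(sid)
    counts = np.stack(cols, axis=1)
    return ExpressionSim(gene_ids, np.asarray(gene_lengths), counts,
                         sample_ids, pairs, truth)


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------

def simulate_terms(
    config: SimulationConfig,
    gene_ids: Sequence[str],
    planted_genes: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, list[str]]], TruthTable]:
    """Random term memberships with planted enriched terms.

    Returns (term rows, truth); each row is (term_id, category, members).
    Planted terms draw a fraction of their members from ``planted_genes``
    elevated ``term_enrichment_ratio``-fold over the background fraction;
    with ratio 1 (or no planted genes) no term is planted.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    truth = TruthTable()
    gene_ids = list(gene_ids)
    planted_set = [g for g in planted_genes if g in set(gene_ids)]
    n = len(gene_ids)
    lo, hi = config.term_size_range
    rows: list[tuple[str, str, list[str]]] = []
    base_frac = len(planted_set) / n if n else 0.0
    plant_frac = min(0.75, config.term_enrichment_ratio * base_frac)
    n_planted_terms = (
        config.n_planted_terms
        if planted_set and config.term_enrichment_ratio > 1
        else 0
    )
    categories = list(config.term_categories)
    for t in range(config.n_terms):
        term_id = f"TERM:{t + 1:04d}"
        category = categories[t % len(categories)]
        size = min(int(rng.integers(lo, hi + 1)), n)
        if t < n_planted_terms:
            k_planted = min(int(round(size * plant_frac)), len(planted_set))
            from_planted = rng.choice(len(planted_set), size=k_planted,
                                      replace=False)
            members = {planted_set[i] for i in from_planted.tolist()}
            rest = [g for g in gene_ids if g not in members]
            n_fill = min(size - len(members), len(rest))
            fill = rng.choice(len(rest), size=n_fill, replace=False)
            members |= {rest[i] for i in fill.tolist()}
            truth.enriched_terms.append(term_id)
        else:
            pick = rng.choice(n, size=min(size, n), replace=False)
            members = {gene_ids[i] for i in pick.tolist()}
        rows.append((term_id, category, sorted(members)))
    return rows, truth


# ---------------------------------------------------------------------------
# Full simulation + serialization
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig):
    """Genome, methylome, expression and terms from one seed."""
    root = np.random.default_rng(config.seed)
    streams = root.spawn(4)
    genome, annotation = simulate_genome(config, streams[0])
    methylome = simulate_methylome(config, annotation, streams[1])
    expression = simulate_expression(config, annotation, streams[2])
    terms, term_truth = simulate_terms(
        config, expression.gene_ids, sorted(expression.truth.degs), streams[3]
    )
    truth = TruthTable(
        dmrs=methylome.truth.dmrs,
        degs=expression.truth.degs,
        enriched_terms=term_truth.enriched_terms,
    )
    return genome, annotation, methylome, expression, terms, truth


def write_simulation(outdir, config: SimulationConfig) -> dict[str, str]:
    """Run simulate_all and write the full input tree; returns path manifest.

    Layout: fasta/, beds/ (peaks, reads, islands, repeats, gene models),
    counts/, terms/, truth/ plus the resolved config as JSON.  All files are
    plain text and deterministically ordered.
    """
    from .intervals import write_bed, write_bed12, write_chrom_sizes, write_fasta

    outdir = Path(outdir)
    for sub in ("fasta", "beds", "counts", "terms", "truth"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    genome, annotation, methylome, expression, terms, truth = simulate_all(config)
    paths: dict[str, str] = {}

    def reg(key: str, path: Path) -> Path:
        paths[key] = str(path)
        return path

    write_fasta(reg("genome", outdir / "fasta" / "genome.fa"), genome)
    write_chrom_sizes(reg("chrom_sizes", outdir / "fasta" / "chrom.sizes"),
                      annotation.chrom_sizes)
    write_bed12(reg("genes", outdir / "beds" / "genes.bed12"),
                [annotation.genes[g] for g in sorted(annotation.genes)])
    write_bed(reg("cpg_islands", outdir / "beds" / "cpg_islands.bed"),
              annotation.cpg_islands)
    write_bed(reg("repeats", outdir / "beds" / "repeats.bed"), annotation.repeats)

    lib_lines = []
    for sid in sorted(methylome.peak_sets):
        ps = methylome.peak_sets[sid]
        write_bed(reg(f"peaks:{sid}", outdir / "beds" / f"{sid}.peaks.bed"),
                  ps.peaks)
        write_bed(reg(f"reads:{sid}", outdir / "beds" / f"{sid}.reads.bed"),
                  methylome.reads[sid])
        lib_lines.append(f"{sid}\t{ps.library_size}\n")
    with open(reg("library_sizes", outdir / "beds" / "library_sizes.tsv"),
              "w") as fh:
        fh.write("sample_id\tlibrary_size\n")
        fh.writelines(lib_lines)

    with open(reg("pair_manifest", outdir / "pairs.tsv"), "w") as fh:
        fh.write("pair_id\tcase_id\tcontrol_id\n")
        for pair_id in methylome.pair_ids:
            case, ctrl = methylome.pairs[pair_id]
            fh.write(f"{pair_id}\t{case}\t{ctrl}\n")

    with open(reg("counts", outdir / "counts" / "gene_counts.tsv"), "w") as fh:
        fh.write("gene_id\tlength\t" + "\t".join(expression.sample_ids) + "\n")
        for i, gid in enumerate(expression.gene_ids):
            row = "\t".join(str(int(c)) for c in expression.counts[i])
            fh.write(f"{gid}\t{int(expression.gene_lengths[i])}\t{row}\n")

    with open(reg("terms", outdir / "terms" / "terms.tsv"), "w") as fh:
        fh.write("term_id\tcategory\tgene_id\tterm_name\n")
        for term_id, category, members in terms:
            for g in members:
                fh.write(f"{term_id}\t{category}\t{g}\t{term_id}\n")

    with open(reg("truth", outdir / "truth" / "truth.json"), "w") as fh:
        json.dump(
            {
                "dmrs": {
                    pair: [
                        {"chrom": r.chrom, "start": r.start, "end": r.end,
                         "trend": trend, "fold": fold}
                        for r, trend, fold in entries
                    ]
                    for pair, entries in truth.dmrs.items()
                },
                "degs": {
                    g: {"direction": d, "log2_fold": f, "pairs": list(p)}
                    for g, (d, f, p) in truth.degs.items()
                },
                "enriched_terms": truth.enriched_terms,
            },
            fh, indent=1, sort_keys=True,
        )
    with open(reg("config", outdir / "config.json"), "w") as fh:
        json.dump(asdict(config), fh, indent=1, sort_keys=True)
    return paths
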