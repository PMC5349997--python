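"""Read filtering, context classification and distribution statistics."""

import numpy as np
import pytest

from epipair import (
    GenomicInterval,
    ReadRecord,
    classify_contexts,
    coverage_by_depth,
    element_distribution,
    filter_reads,
    metagene_profile,
)
from epipair.intervals import AnnotationBundle
from epipair.qc import (
    density_binned_distribution,
    peak_length_distribution,
    read_fastq,
)
from epipair.simulate import SimulationConfig, simulate_genome

from conftest import random_intervals, union_mask


def _read(seq, quals, rid="r"):
    return ReadRecord(rid, seq, tuple(quals))


class TestFilterReads:
    def test_n_rule_removes(self):
        # 6 N in 49 bp = 12.2% > 10%
        seq = "N" * 6 + "A" * 43
        kept, report = filter_reads([_read(seq, [30] * 49)])
        assert kept == [] and report.removed_n_rule == 1

    def test_quality_rule_removes(self):
        # 25 of 49 bases at Q=20 (inclusive) = 51% > 50%
        quals = [20] * 25 + [30] * 24
        kept, report = filter_reads([_read("A" * 49, quals)])
        assert kept == [] and report.removed_quality_rule == 1

    def test_both_below_threshold_kept(self):
        # 4 N (8.2%) and 24 low-quality bases (49%): both within limits
        seq = "N" * 4 + "A" * 45
        quals = [20] * 24 + [30] * 25
        kept, report = filter_reads([_read(seq, quals)])
        assert len(kept) == 1 and report.kept == 1

    def test_boundaries_are_strict(self):
        # exactly 50% low-quality and exactly 10% N on a 50 bp read: kept
        seq = "N" * 5 + "A" * 45
        quals = [20] * 25 + [30] * 25
        kept, _ = filter_reads([_read(seq, quals)])
        assert len(kept) == 1
        # Q=21 does not count as low quality
        kept, _ = filter_reads([_read("A" * 50, [21] * 50)])
        assert len(kept) == 1

    def test_order_independent(self, rng):
        reads = []
        for i in range(200):
            n_n = int(rng.integers(0, 10))
            n_low = int(rng.integers(0, 40))
            seq = "N" * n_n + "A" * (49 - n_n)
            quals = [15] * n_low + [35] * (49 - n_low)
            reads.append(_read(seq, quals, rid=f"r{i}"))
        kept1, _ = filter_reads(reads)
        shuffled = list(reads)
        rng.shuffle(shuffled)
        kept2, _ = filter_reads(shuffled)
        assert {r.id for r in kept1} == {r.id for r in kept2}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _read("ACGT", [30, 30, 30])

    def test_fastq_round_trip(self, tmp_path):
        p = tmp_path / "r.fastq"
        p.write_text("@r1\nACGTN\n+\nIIII#\n")
        (rec,) = list(read_fastq(p))
        assert rec.sequence == "ACGTN"
        assert rec.qualities == (40, 40, 40, 40, 2)


from conftest import context_label_maps as _as_label_maps
from conftest import triplet_oracle as _triplet_oracle


class TestClassifyContexts:
    def test_acgt_is_symmetric_cpg(self):
        sites = classify_contexts({"c": "ACGT"})
        labels = _as_label_maps(sites, "c")
        assert labels["+"] == {1: "CpG"}
        assert labels["-"] == {2: "CpG"}

    def test_cat_is_chh(self):
        sites = classify_contexts({"c": "CAT"})
        assert _as_label_maps(sites, "c")["+"] == {0: "CHH"}

    def test_matches_triplet_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), size=5000,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        sites = classify_contexts({"c": seq})
        assert _as_label_maps(sites, "c") == _triplet_oracle(seq)

    def test_labels_mutually_exclusive(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        sites = classify_contexts({"c": seq})
        for strand in "+-":
            arrs = [set(sites.sites["c"][strand].get(ctx, ()).tolist())
                    for ctx in ("CpG", "CHG", "CHH")]
            assert not (arrs[0] & arrs[1] or arrs[0] & arrs[2]
                        or arrs[1] & arrs[2])


class TestCoverageByDepth:
    def test_small_example(self):
        reads = [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 15)]
        profile = coverage_by_depth(reads, {"c": 20})
        assert profile.frac_ge[1] == 0.75
        assert profile.frac_ge[2] == 0.25
        assert profile.frac_eq[1] == 0.50

    def test_no_reads(self):
        profile = coverage_by_depth([], {"c": 100})
        assert profile.frac_ge == {} and profile.frac_eq == {}

    def test_matches_per_base_oracle(self, rng):
        reads = random_intervals(rng, 200, genome_len=10_000, max_len=60)
        profile = coverage_by_depth(reads, {"chr1": 10_000})
        depth = np.zeros(10_000, dtype=int)
        for r in reads:
            depth[r.start : r.end] += 1
        for d in profile.frac_ge:
            assert profile.frac_ge[d] == (depth >= d).sum() / 10_000
            assert profile.frac_eq[d] == (depth == d).sum() / 10_000

    def test_eq_fractions_sum_to_one(self, rng):
        reads = random_intervals(rng, 150, genome_len=5_000, max_len=80)
        profile = coverage_by_depth(reads, {"chr1": 5_000})
        uncovered = 1.0 - profile.frac_ge.get(1, 0.0)
        assert abs(sum(profile.frac_eq.values()) + uncovered - 1.0) < 1e-12


class TestDensityBinning:
    def test_formula(self):
        sites = classify_contexts({"c": "CG" * 50 + "A" * 1000})
        # 100 bp peak over the CG run: 50 plus- and 49 minus-strand CpGs
        # (the G at offset 1 lacks two upstream bases) -> density 99/100 bp
        peak = GenomicInterval("c", 0, 100)
        hist = density_binned_distribution([peak], sites,
                                           bin_edges=(0, 10, 100, 200))
        assert hist[(10, 100)] == 1

    def test_zero_cpg_lowest_bin(self):
        sites = classify_contexts({"c": "A" * 1000})
        hist = density_binned_distribution(
            [GenomicInterval("c", 0, 100)], sites, bin_edges=(0, 1, 2)
        )
        assert hist[(0, 1)] == 1

    def test_totals_conserved(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        sites = classify_contexts({"chr1": seq})
        peaks = random_intervals(rng, 100, genome_len=20_000, min_len=50)
        hist = density_binned_distribution(peaks, sites)
        assert sum(hist.values()) == len(peaks)


@pytest.fixture(scope="module")
def toy_annotation():
    cfg = SimulationConfig(seed=7, n_chroms=1, chrom_len=100_000, n_genes=12,
                           n_cpg_islands_per_chrom=8, n_repeats_per_chrom=10)
    _, annotation = simulate_genome(cfg)
    return annotation


class TestElementDistribution:
    def test_junction_peak_counts_in_both(self):
        from epipair import GeneModel, derive_elements

        g = GeneModel("g1", "chr1", "+", 1000, 5000, 1000, 5000,
                      ((1000, 2000), (3000, 5000)))
        ann = AnnotationBundle(
            {"g1": g}, {"g1": derive_elements(g, 500)}, [], [], {"chr1": 10_000}
        )
        peak = GenomicInterval("chr1", 1900, 2100)  # spans cds/intron junction
        dist = element_distribution([peak], ann)
        assert dist.counts["cds"] == 1 and dist.counts["intron"] == 1
        assert dist.counts["intergenic"] == 0
        assert dist.coverage_bp["cds"] == 100
        assert dist.coverage_bp["intron"] == 100

    def test_fully_intergenic_peak(self):
        from epipair import GeneModel, derive_elements

        g = GeneModel("g1", "chr1", "+", 1000, 2000, 1000, 2000, ((1000, 2000),))
        ann = AnnotationBundle(
            {"g1": g}, {"g1": derive_elements(g, 200)}, [], [], {"chr1": 10_000}
        )
        peak = GenomicInterval("chr1", 5000, 5200)
        dist = element_distribution([peak], ann)
        assert dist.counts["intergenic"] == 1
        assert all(dist.counts[c] == 0 for c in dist.counts if c != "intergenic")

    def test_matches_per_base_oracle(self, rng, toy_annotation):
        from epipair.qc import _class_intervals

        peaks = random_intervals(rng, 80, genome_len=100_000, min_len=100)
        dist = element_distribution(peaks, toy_annotation)
        classes = _class_intervals(toy_annotation)
        peak_mask = union_mask(peaks, 100_000)
        for cls, ivs in classes.items():
            cls_mask = union_mask(ivs, 100_000)
            assert dist.coverage_bp[cls] == int((cls_mask & peak_mask).sum())
            expected_n = sum(
                1 for p in peaks if cls_mask[p.start : p.end].any()
            )
            assert dist.counts[cls] == expected_n
            assert dist.coverage_bp[cls] <= dist.element_length_bp[cls]


class TestMetagene:
    def test_uniform_coverage_flat_profile(self):
        anchor = GenomicInterval("c", 1000, 2000)
        reads = [GenomicInterval("c", 0, 4000)]
        prof = metagene_profile(reads, [anchor], {"c": 4000}, flank_bp=500,
                                n_body_bins=10, n_flank_bins=5)
        assert np.allclose(prof, 1.0)

    def test_no_reads_zero_profile(self):
        anchor = GenomicInterval("c", 1000, 2000)
        prof = metagene_profile([], [anchor], {"c": 4000})
        assert np.allclose(prof, 0.0)

    def test_minus_strand_reverses(self):
        # coverage only over the downstream flank of a plus anchor
        anchor_plus = GenomicInterval("c", 1000, 2000, "+")
        anchor_minus = GenomicInterval("c", 1000, 2000, "-")
        reads = [GenomicInterval("c", 2000, 2500)]
        kw = dict(flank_bp=500, n_body_bins=4, n_flank_bins=2)
        p_plus = metagene_profile(reads, [anchor_plus], {"c": 4000}, **kw)
        p_minus = metagene_profile(reads, [anchor_minus], {"c": 4000}, **kw)
        assert np.allclose(p_plus, p_minus[::-1])
        assert p_plus[-2:].sum() > 0 and p_plus[:-2].sum() == 0


class TestPeakLengthDistribution:
    def test_examples(self):
        peaks = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300),
                 GenomicInterval("c", 400, 700)]
        hist = peak_length_distribution(peaks, bin_width=100)
        assert hist == {(100, 200): 2, (300, 400): 1}

    def test_empty(self):
        assert peak_length_distribution([]) == {}

    def test_totals_conserved(self, rng):
        peaks = random_intervals(rng, 123, genome_len=50_000, min_len=10)
        hist = peak_length_distribution(peaks)
        assert sum(hist.values()) == 123
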