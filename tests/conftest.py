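import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_intervals(rng, n, genome_len=10_000, chrom="chr1", max_len=500,
                     min_len=1):
    """Random intervals on one toy chromosome."""
    from epipair import GenomicInterval

    starts = rng.integers(0, genome_len - max_len, size=n)
    lengths = rng.integers(min_len, max_len + 1, size=n)
    return [
        GenomicInterval(chrom, int(s), int(min(s + ln, genome_len)))
        for s, ln in zip(starts, lengths)
    ]


def union_mask(intervals, genome_len):
    """Per-base boolean-array oracle for interval unions."""
    mask = np.zeros(genome_len, dtype=bool)
    for iv in intervals:
        mask[iv.start : iv.end] = True
    return mask


def triplet_oracle(seq):
    """Exhaustive two-strand triplet scan for cytosine contexts.

    Independent of the vectorised classifier: walks every position with
    plain string comparisons on both strands.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    H = set("ACT")
    labels = {"+": {}, "-": {}}
    n = len(seq)
    for i in range(n - 2):
        if seq[i] == "C":
            b1, b2 = seq[i + 1], seq[i + 2]
            if b1 == "G":
                labels["+"][i] = "CpG"
            elif b1 in H and b2 == "G":
                labels["+"][i] = "CHG"
            elif b1 in H and b2 in H:
                labels["+"][i] = "CHH"
    for i in range(2, n):
        if seq[i] == "G":  # C on the minus strand
            b1 = comp.get(seq[i - 1], "N")
            b2 = comp.get(seq[i - 2], "N")
            if b1 == "G":
                labels["-"][i] = "CpG"
            elif b1 in H and b2 == "G":
                labels["-"][i] = "CHG"
            elif b1 in H and b2 in H:
                labels["-"][i] = "CHH"
    return labels


def context_label_maps(sites, chrom):
    """Flatten a ContextSiteSet chromosome into {strand: {pos: label}}."""
    out = {"+": {}, "-": {}}
    for strand in "+-":
        for ctx in ("CpG", "CHG", "CHH"):
            for pos in sites.sites[chrom][strand].get(ctx, []):
                out[strand][int(pos)] = ctx
    return out
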