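import numpy as np
import pytest

from mirnet.sites import ClipSample, GenomicInterval, build_pri_regions


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def three_loci():
    entries = [
        ("mirA", GenomicInterval("chr1", 5000, 5080, "+")),
        ("mirB", GenomicInterval("chr1", 12000, 12090, "+")),
        ("mirC", GenomicInterval("chr2", 3000, 3070, "-")),
    ]
    return build_pri_regions(entries, flank=1000)


def random_clip_fixture(rng, loci, n_rbps=2, n_samples=2, n_reads=50, read_len=30):
    """Uniform random reads over the loci's pri regions (plus some misses)."""
    samples = []
    spans = [l.pri for l in loci]
    for r in range(n_rbps):
        for s in range(n_samples):
            reads = []
            for _ in range(n_reads):
                span = spans[rng.integers(len(spans))]
                lo = int(rng.integers(max(0, span.start - 200), span.end + 200))
                reads.append(
                    GenomicInterval(span.chrom, lo, lo + read_len, span.strand)
                )
            samples.append(
                ClipSample(f"RBP{r}", f"RBP{r}_s{s}", "c0", reads)
            )
    return samples
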