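"""CLIP-derived RBP binding sites on miRNA loci.

A miRNA locus is the miRBase hairpin (pre-miRNA) interval; the putative
primary transcript (pri-miRNA) is operationalized as the hairpin extended by
a fixed flank (default 1 kb) on both sides. Consensus binding sites are
called from aligned CLIP reads with a read-support rule (at least
``min_reads`` reads overlapping the locus in each of at least ``min_samples``
samples), then required to concur with at least one external peak set. A
built-in Poisson coverage-enrichment caller is provided as a stand-in peak
caller for when no external peak BEDs are available.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "MiRNALocus",
    "ClipSample",
    "BindingSite",
    "build_pri_regions",
    "consensus_sites",
    "call_peaks_poisson",
    "concurrence_filter",
    "summarize_binding",
]

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval (BED convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: float) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class MiRNALocus:
    """A miRNA's hairpin (pre) interval and derived pri region."""

    mirna_id: str
    pre: GenomicInterval
    pri: GenomicInterval
    mature_ids: tuple = ()

    def __post_init__(self) -> None:
        if not (self.pri.start <= self.pre.start and self.pre.end <= self.pri.end):
            raise ValueError(f"{self.mirna_id}: pri does not contain pre")


@dataclass
class ClipSample:
    """One CLIP-seq sample: aligned (deduplicated) reads for a single RBP."""

    rbp_id: str
    sample_id: str
    condition: str
    reads: list = field(default_factory=list)


@dataclass
class BindingSite:
    """A consensus RBP binding site on a miRNA locus.

    ``read_support`` is the maximum per-sample overlapping-read count;
    ``sample_support`` the number of samples that individually met the read
    threshold; ``region_type`` is 'pre' when the site midpoint lies inside
    the hairpin, else 'pri' (flank)."""

    rbp_id: str
    mirna_id: str
    region_type: str
    interval: GenomicInterval
    read_support: int
    sample_support: int
    concurred: bool = False


def build_pri_regions(pre_loci, flank: int = 1000) -> list:
    """Extend each pre-miRNA interval by ``flank`` bp on both sides.

    The extended interval is the operational pri-miRNA region; the left end
    is clamped at coordinate 0. ``pre_loci`` is an iterable of
    ``(mirna_id, GenomicInterval)`` pairs (optionally with a mature-id list
    as a third element).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    loci = []
    for entry in pre_loci:
        mirna_id, pre = entry[0], entry[1]
        mature_ids = tuple(entry[2]) if len(entry) > 2 else (f"{mirna_id}-mat",)
        if not isinstance(pre, GenomicInterval):
            raise ValueError(f"{mirna_id}: invalid pre interval {pre!r}")
        pri = GenomicInterval(
            pre.chrom, max(0, pre.start - flank), pre.end + flank, pre.strand
        )
        loci.append(MiRNALocus(mirna_id, pre, pri, mature_ids))
    return loci


def _merge_reads(reads) -> list:
    """Merge overlapping reads into clusters: (start, end, n_reads) tuples."""
    ordered = sorted(reads, key=lambda r: (r.start, r.end))
    clusters = []
    cur_lo, cur_hi, cur_n = ordered[0].start, ordered[0].end, 1
    for r in ordered[1:]:
        if r.start < cur_hi:
            cur_hi = max(cur_hi, r.end)
            cur_n += 1
        else:
            clusters.append((cur_lo, cur_hi, cur_n))
            cur_lo, cur_hi, cur_n = r.start, r.end, 1
    clusters.append((cur_lo, cur_hi, cur_n))
    return clusters


def consensus_sites(
    samples,
    loci,
    min_reads: int = 5,
    min_samples: int = 2,
) -> list:
    """Call consensus binding sites from per-sample CLIP reads.

    For each (RBP, miRNA locus) pair a site is emitted iff at least
    ``min_reads`` reads overlap the locus's pri region in each of at least
    ``min_samples`` samples of that RBP. A read overlaps iff it shares >=1 bp
    with the region. RBPs represented by fewer than two samples are excluded
    (logged, not an error). Output order is deterministic (sorted by RBP then
    miRNA id) and independent of input ordering.
    """
    by_rbp: dict = defaultdict(list)
    for s in samples:
        by_rbp[s.rbp_id].append(s)

    sites: list = []
    for rbp_id in sorted(by_rbp):
        rbp_samples = sorted(by_rbp[rbp_id], key=lambda s: s.sample_id)
        if len(rbp_samples) < 2:
            logger.info(
                "RBP %s has %d sample(s); at least two required - excluded",
                rbp_id,
                len(rbp_samples),
            )
            continue
        for locus in sorted(loci, key=lambda l: l.mirna_id):
            per_sample_hits = []
            for s in rbp_samples:
                hits = [r for r in s.reads if r.overlaps(locus.pri)]
                per_sample_hits.append(hits)
            counts = [len(h) for h in per_sample_hits]
            supporting = [c for c in counts if c >= min_reads]
            if len(supporting) < min_samples:
                continue
            support_reads = [
                r
                for hits, c in zip(per_sample_hits, counts)
                if c >= min_reads
                for r in hits
            ]
            # site interval = densest cluster of overlapping supporting reads
            # (ties: leftmost), clipped to the pri region; a lone decoy read
            # far from the stack must not stretch the site across the locus
            clusters = _merge_reads(support_reads)
            best = max(clusters, key=lambda c: (c[2], -c[0]))
            lo = max(locus.pri.start, best[0])
            hi = min(locus.pri.end, best[1])
            interval = GenomicInterval(locus.pri.chrom, lo, hi, locus.pri.strand)
            mid = (lo + hi) / 2.0
            region_type = (
                "pre" if locus.pre.contains_point(locus.pri.chrom, mid) else "pri"
            )
            sites.append(
                BindingSite(
                    rbp_id=rbp_id,
                    mirna_id=locus.mirna_id,
                    region_type=region_type,
                    interval=interval,
                    read_support=max(supporting),
                    sample_support=len(supporting),
                )
            )
    return sites


def call_peaks_poisson(reads, region: GenomicInterval, alpha: float = 0.05) -> list:
    """Poisson coverage-enrichment peak caller.

    Positions whose read coverage exceeds the (1-alpha) quantile of a
    Poisson with mean equal to the region-wide average coverage (total
    covered bases / region length) form peaks; maximal contiguous runs of
    such positions are returned. This is a deliberately simple built-in
    stand-in for an external peak caller; externally produced peak BEDs take
    precedence when supplied.
    """
    if len(region) <= 0:  # pragma: no cover - GenomicInterval forbids this
        raise ValueError("zero-length region")
    reads = [r for r in reads if r.overlaps(region)]
    if not reads:
        return []
    L = len(region)
    cov = np.zeros(L, dtype=np.int64)
    for r in reads:
        lo = max(r.start, region.start) - region.start
        hi = min(r.end, region.end) - region.start
        cov[lo:hi] += 1
    mean_cov = cov.sum() / L
    threshold = stats.poisson.ppf(1.0 - alpha, mean_cov)
    above = cov > threshold
    peaks = []
    i = 0
    while i < L:
        if above[i]:
            j = i
            while j < L and above[j]:
                j += 1
            peaks.append(
                GenomicInterval(
                    region.chrom, region.start + i, region.start + j, region.strand
                )
            )
            i = j
        else:
            i += 1
    return peaks


def concurrence_filter(candidates, peaks_a, peaks_b) -> list:
    """Keep candidate sites overlapping >=1 peak from either caller.

    Survivors are returned as new records with ``concurred=True``; the input
    list is not modified. Idempotent.
    """
    all_peaks = list(peaks_a) + list(peaks_b)
    out = []
    for site in candidates:
        if any(site.interval.overlaps(p) for p in all_peaks):
            out.append(
                BindingSite(
                    rbp_id=site.rbp_id,
                    mirna_id=site.mirna_id,
                    region_type=site.region_type,
                    interval=site.interval,
                    read_support=site.read_support,
                    sample_support=site.sample_support,
                    concurred=True,
                )
            )
    return out


def summarize_binding(sites, n_conditions_per_rbp: dict) -> pd.DataFrame:
    """Per-RBP binding summary.

    Returns a DataFrame indexed by RBP with columns:

    - ``n_pri_targets`` / ``n_pre_targets``: unique miRNAs bound in each
      region type;
    - ``n_targets``: unique miRNAs bound overall;
    - ``targets_per_condition``: unique-target count normalized by the
      number of experimental conditions for that RBP;
    - ``sites_per_mirna``: the per-miRNA site-count distribution (dict).
    """
    by_rbp = defaultdict(list)
    for s in sites:
        by_rbp[s.rbp_id].append(s)
    for rbp in by_rbp:
        if rbp not in n_conditions_per_rbp:
            raise KeyError(f"RBP {rbp!r} missing from the condition map")

    rows = {}
    for rbp in sorted(n_conditions_per_rbp):
        rbp_sites = by_rbp.get(rbp, [])
        n_cond = n_conditions_per_rbp[rbp]
        if n_cond < 1:
            raise ValueError(f"RBP {rbp!r}: condition count must be >= 1")
        pri = {s.mirna_id for s in rbp_sites if s.region_type == "pri"}
        pre = {s.mirna_id for s in rbp_sites if s.region_type == "pre"}
        targets = {s.mirna_id for s in rbp_sites}
        per_mirna: dict = defaultdict(int)
        for s in rbp_sites:
            per_mirna[s.mirna_id] += 1
        rows[rbp] = {
            "n_pri_targets": len(pri),
            "n_pre_targets": len(pre),
            "n_targets": len(targets),
            "targets_per_condition": len(targets) / n_cond,
            "sites_per_mirna": dict(per_mirna),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
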