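"""Poisson local-background peak calling and replicate/master-peak merging.

The caller tests, at every base, the treatment pileup against a local Poisson
rate estimated from the matched input: lambda_local is the maximum of the
genome-wide mean and the 1-kb / 5-kb / 10-kb window means centred on the
position (the dynamic-lambda scheme of model-based ChIP-seq callers).
Positions with upper-tail probability below the cut-off (default 1e-3) are
merged into peaks; peaks must be reproduced in both biological replicates, and
per-genotype master peaks are the interval union across time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fragnorm import CoverageTrack, FragmentSet

log = logging.getLogger(__name__)

LOCAL_WINDOWS = (1_000, 5_000, 10_000)


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    p_value: float
    fold_enrichment: float
    genotype: str | None = None
    zt: str | None = None
    zts: frozenset = field(default_factory=frozenset)  # contributing time points

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError("peak start must precede end")
        if not (self.start <= self.summit < self.end):
            raise ValueError("summit outside peak")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must be in (0, 1]")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PeakSet:
    peaks: list[Peak]
    source: str = "replicate-level"  # replicate-level | concordant | master

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def sorted(self) -> "PeakSet":
        return PeakSet(sorted(self.peaks, key=lambda p: (p.chrom, p.start)),
                       self.source)


def pileup(fs: FragmentSet, genome_length: int) -> CoverageTrack:
    """Per-base fragment coverage: value at x = fragments covering x."""
    cov = np.zeros(genome_length + 1, dtype=np.float64)
    df = fs.fragments
    if len(df):
        starts = np.clip(df["start"].to_numpy(np.int64), 0, genome_length)
        ends = np.clip(df["end"].to_numpy(np.int64), 0, genome_length)
        np.add.at(cov, starts, 1.0)
        np.add.at(cov, ends, -1.0)
    chrom = df["chrom"].iloc[0] if len(df) else "chr1"
    return CoverageTrack(chrom=chrom, bin_size=1,
                         values=np.cumsum(cov)[:genome_length])


def _window_means(x: np.ndarray, w: int) -> np.ndarray:
    """Centred moving average with edge truncation (same length as x)."""
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    half = w // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + (w - half), 0, n)
    return (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1)


def local_lambda(control: np.ndarray,
                 windows: tuple[int, ...] = LOCAL_WINDOWS) -> np.ndarray:
    """max(genome-wide mean, window means) per position."""
    lam = np.full(len(control), control.mean())
    for w in windows:
        np.maximum(lam, _window_means(control, w), out=lam)
    return lam


def poisson_pvalues(treat: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Upper-tail P(X >= treat | lambda) per position."""
    return stats.poisson.sf(np.round(treat) - 1, np.maximum(lam, 1e-12))


def call_peaks(treat: CoverageTrack, control: CoverageTrack,
               p_cut: float = 1e-3, merge_gap: int = 100,
               min_length: int = 150, genotype: str | None = None,
               zt: str | None = None) -> PeakSet:
    """Call enriched intervals from depth-matched treatment/control pileups.

    Contiguous significant positions closer than ``merge_gap`` are merged;
    peaks shorter than ``min_length`` are dropped.  The summit is the leftmost
    treatment-pileup maximum; the peak p-value is the minimum over the peak
    and fold enrichment the summit pileup over its local lambda.
    """
    t = np.asarray(treat.values, dtype=float)
    c = np.asarray(control.values, dtype=float)
    if len(t) != len(c):
        raise ValueError("treatment and control tracks differ in length")
    if c.sum() == 0:
        log.warning("all-zero control track; estimating background from treatment")
        c = t
    lam = local_lambda(c)
    pv = poisson_pvalues(t, lam)
    sig = pv < p_cut
    peaks = []
    for s, e in _merge_runs(sig, merge_gap):
        if e - s < min_length:
            continue
        summit = s + int(np.argmax(t[s:e]))
        peaks.append(Peak(
            chrom=treat.chrom, start=int(s), end=int(e), summit=summit,
            p_value=float(max(pv[s:e].min(), np.nextafter(0, 1))),
            fold_enrichment=float(t[summit] / max(lam[summit], 1e-12)),
            genotype=genotype, zt=zt, zts=frozenset({zt} if zt else ())))
    return PeakSet(peaks, source="replicate-level")


def _merge_runs(mask: np.ndarray, merge_gap: int):
    """Yield (start, end) of True runs, merging runs separated by <= merge_gap."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > merge_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for a, b in zip(starts, ends):
        yield int(idx[a]), int(idx[b]) + 1


def concordant_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Keep rep1 peaks overlapping (>= 1 bp) a rep2 peak, widened to the union
    span of each overlapping pair.  Overlapping results are merged, so the
    output is identical under replicate swap."""
    spans = []
    for p in rep1:
        for q in rep2:
            if p.chrom == q.chrom and p.start < q.end and q.start < p.end:
                spans.append((p.chrom, min(p.start, q.start),
                              max(p.end, q.end), p))
    merged = _merge_spans(spans)
    return PeakSet(merged, source="concordant")


def _merge_spans(spans):
    """Merge (chrom, start, end, template_peak) spans into non-overlapping peaks."""
    out = []
    for chrom in sorted({s[0] for s in spans}):
        group = sorted([s for s in spans if s[0] == chrom], key=lambda s: s[1])
        cur = None
        for _, s, e, p in group:
            if cur is None:
                cur = [s, e, p, p.zts]
            elif s <= cur[1]:
                cur[1] = max(cur[1], e)
                cur[3] = cur[3] | p.zts
                if p.p_value < cur[2].p_value:
                    cur[2] = p
            else:
                out.append(_span_peak(chrom, cur))
                cur = [s, e, p, p.zts]
        if cur is not None:
            out.append(_span_peak(chrom, cur))
    return out


def _span_peak(chrom, cur):
    s, e, p, zts = cur
    summit = min(max(p.summit, s), e - 1)
    return Peak(chrom=chrom, start=s, end=e, summit=summit,
                p_value=p.p_value, fold_enrichment=p.fold_enrichment,
                genotype=p.genotype, zt=p.zt, zts=zts)


def master_peaks(per_zt: dict[str, PeakSet]) -> PeakSet:
    """Interval union of concordant peaks across time points for one genotype.

    Each master peak records the set of contributing ZTs."""
    spans = []
    for zt, ps in per_zt.items():
        for p in ps:
            tagged = Peak(p.chrom, p.start, p.end, p.summit, p.p_value,
                          p.fold_enrichment, p.genotype, p.zt,
                          zts=p.zts | frozenset({zt}))
            spans.append((p.chrom, p.start, p.end, tagged))
    merged = _merge_spans(spans)
    return PeakSet(merged, source="master")


def input_subtracted_track(treat: CoverageTrack,
                           control: CoverageTrack) -> CoverageTrack:
    """Pointwise treatment minus control signal, floored at zero."""
    if len(treat.values) != len(control.values):
        raise ValueError("tracks differ in length")
    return CoverageTrack(chrom=treat.chrom, bin_size=treat.bin_size,
                         values=np.maximum(
                             np.asarray(treat.values, float)
                             - np.asarray(control.values, float), 0.0))
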