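"""Fragment-level normalization: deduplication, depth down-sampling, binning.

Depth comparability across genotypes and time points is achieved by removing
PCR duplicates and then down-sampling every library to the smallest
deduplicated fragment count, so that peak numbers and enrichment abundances
can be compared across samples.  Replicate concordance is quantified as the
Pearson correlation of fragment coverage over consecutive 1-kb bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class FragmentSet:
    """Stranded genomic intervals for one sample.

    ``fragments`` is a DataFrame with columns chrom, start, end, strand
    (0-based half-open coordinates).
    """

    sample_id: str
    genotype: str
    zt: str
    replicate: int
    treatment: str  # "ChIP" or "input"
    fragments: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=FRAGMENT_COLUMNS))

    def __post_init__(self):
        df = self.fragments
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragments missing columns {missing}")
        if len(df) and not (df["start"] < df["end"]).all():
            raise ValueError("fragment with start >= end")

    def __len__(self) -> int:
        return len(self.fragments)

    def with_fragments(self, df: pd.DataFrame) -> "FragmentSet":
        return FragmentSet(self.sample_id, self.genotype, self.zt,
                           self.replicate, self.treatment,
                           df.reset_index(drop=True))


@dataclass
class CoverageTrack:
    """Per-bin fragment counts (midpoint-assigned) or per-base pileup."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")


def deduplicate(fs: FragmentSet) -> FragmentSet:
    """Remove exact-duplicate fragments, keeping first occurrence in order.

    A duplicate is an identical (chrom, start, end, strand) tuple — the
    fragment-space equivalent of paired-end PCR-duplicate removal.
    """
    df = fs.fragments.drop_duplicates(subset=FRAGMENT_COLUMNS, keep="first")
    return fs.with_fragments(df)


def downsample_all(samples: list[FragmentSet], seed: int,
                   chip_only: bool = False) -> list[FragmentSet]:
    """Down-sample every sample to the smallest fragment count.

    All samples (ChIP and input pooled by default; ``chip_only`` restricts the
    minimum to ChIP libraries and leaves inputs scaled to the same count) end
    with exactly the minimum count, drawn uniformly without replacement with a
    seeded generator.  Samples already at the minimum pass through unchanged.
    """
    if not samples:
        return []
    for s in samples:
        if len(s) == 0:
            raise ValueError(f"sample {s.sample_id} is empty; cannot down-sample")
    pool = [s for s in samples if s.treatment == "ChIP"] if chip_only else samples
    if not pool:
        pool = samples
    target = min(len(s) for s in pool)
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        n = len(s)
        if n <= target:  # < only possible for samples outside the pool
            out.append(s)
            continue
        keep = np.sort(rng.choice(n, size=target, replace=False))
        out.append(s.with_fragments(s.fragments.iloc[keep]))
    return out


def bin_coverage(fs: FragmentSet, bin_size: int = 1000,
                 genome_length: int | None = None,
                 weighted: bool = False) -> CoverageTrack:
    """Fragment coverage over consecutive bins.

    Default assigns each fragment to the bin of its midpoint so that bin sums
    conserve fragment count; ``weighted`` instead distributes each fragment
    over bins proportionally to overlap length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    df = fs.fragments
    chrom = df["chrom"].iloc[0] if len(df) else "chr1"
    end_max = int(df["end"].max()) if len(df) else 0
    L = genome_length if genome_length is not None else end_max
    n_bins = max(1, -(-L // bin_size))
    if not weighted:
        mids = ((df["start"].to_numpy(np.int64)
                 + df["end"].to_numpy(np.int64)) // 2) if len(df) else np.array([], int)
        vals = np.bincount(np.minimum(mids // bin_size, n_bins - 1),
                           minlength=n_bins).astype(float)
    else:
        vals = np.zeros(n_bins)
        for s, e in zip(df["start"].to_numpy(), df["end"].to_numpy()):
            flen = e - s
            b0, b1 = s // bin_size, (e - 1) // bin_size
            for b in range(b0, min(b1, n_bins - 1) + 1):
                lo, hi = max(s, b * bin_size), min(e, (b + 1) * bin_size)
                vals[b] += (hi - lo) / flen
    return CoverageTrack(chrom=chrom, bin_size=bin_size, values=vals)


def replicate_correlation(a: CoverageTrack, b: CoverageTrack,
                          qc_threshold: float = 0.9) -> tuple[float, bool]:
    """Pearson r between two same-binning coverage tracks, plus a QC verdict."""
    if a.bin_size != b.bin_size:
        raise ValueError("tracks have different bin sizes")
    x = np.zeros(max(len(a.values), len(b.values)))
    y = x.copy()
    x[:len(a.values)] = a.values
    y[:len(b.values)] = b.values
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance coverage track: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r >= qc_threshold
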