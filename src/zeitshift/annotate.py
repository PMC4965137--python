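"""Peak-to-gene target assignment and genomic-feature classification.

A gene is a binding target when any peak overlaps its span extended by a
window (default 10 kb) on both sides.  Peak summits are classified into
genomic feature categories with the priority promoter (2 kb upstream of TSS,
strand-aware) > 5'UTR > coding > downstream (2 kb past the TES) > intergenic,
and category composition is tested against the genome's base-pair composition
with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .peakcall import Peak, PeakSet

CATEGORIES = ("promoter2kb", "utr5", "coding", "downstream", "intergenic")
_CAT_CODE = {c: i for i, c in enumerate(CATEGORIES)}

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss", "tes",
                "utr5_start", "utr5_end", "cds_start", "cds_end"]


def assign_targets(peaks: PeakSet, genes: pd.DataFrame,
                   window: int = 10_000, tss_only: bool = False,
                   ) -> dict[str, list[Peak]]:
    """Map gene_id -> peaks overlapping the gene span (or TSS) +- window.

    A peak may be assigned to several genes; the non-redundant target set is
    the dict's key set.
    """
    tree = IntervalTree()
    for row in genes.itertuples(index=False):
        if tss_only:
            lo, hi = row.tss - window, row.tss + window
        else:
            lo, hi = min(row.start, row.end) - window, max(row.start, row.end) + window
        tree.addi(lo, hi, (row.gene_id, row.chrom))
    out: dict[str, list[Peak]] = {}
    for p in peaks:
        for iv in tree.overlap(p.start, p.end):
            gid, chrom = iv.data
            if chrom == p.chrom:
                out.setdefault(gid, []).append(p)
    return out


def build_feature_map(genes: pd.DataFrame, genome_length: int,
                      promoter_length: int = 2_000,
                      downstream_length: int = 2_000) -> np.ndarray:
    """Per-base feature category codes for one chromosome.

    Categories are painted in increasing priority so that the highest-priority
    feature wins at each base.
    """
    fmap = np.full(genome_length, _CAT_CODE["intergenic"], dtype=np.int8)

    def paint(lo, hi, cat):
        lo, hi = max(0, int(lo)), min(genome_length, int(hi))
        if lo < hi:
            fmap[lo:hi] = _CAT_CODE[cat]

    for row in genes.itertuples(index=False):
        if row.strand == "+":
            paint(row.tes, row.tes + downstream_length, "downstream")
        else:
            paint(row.tes - downstream_length, row.tes, "downstream")
    for row in genes.itertuples(index=False):
        paint(row.cds_start, row.cds_end, "coding")
    for row in genes.itertuples(index=False):
        paint(row.utr5_start, row.utr5_end, "utr5")
    for row in genes.itertuples(index=False):
        if row.strand == "+":
            paint(row.tss - promoter_length, row.tss, "promoter2kb")
        else:
            paint(row.tss, row.tss + promoter_length, "promoter2kb")
    return fmap


def classify_feature(peak: Peak, feature_map: np.ndarray,
                     by_overlap: bool = False) -> str:
    """Feature category of a peak: its summit's category by default, or the
    highest-priority category the peak overlaps when ``by_overlap``."""
    if by_overlap:
        codes = feature_map[max(0, peak.start):min(len(feature_map), peak.end)]
        return CATEGORIES[int(codes.min())] if codes.size else "intergenic"
    if not (0 <= peak.summit < len(feature_map)):
        raise ValueError(f"summit {peak.summit} outside genome of length "
                         f"{len(feature_map)}")
    return CATEGORIES[int(feature_map[peak.summit])]


@dataclass
class FeatureTable:
    """Per-category peak counts vs genome composition with Fisher tests."""
    table: pd.DataFrame  # category, peak_count, genome_fraction, odds_ratio, fisher_p


def feature_enrichment(peaks: PeakSet, genes: pd.DataFrame,
                       genome_length: int, **map_kwargs) -> FeatureTable:
    """Category composition of peak summits tested against genome bp fractions.

    For each category, a two-sided 2x2 Fisher's exact test compares (peaks in
    category vs not) with the genome composition scaled to the peak total.
    Categories absent from the genome are excluded with a warning.
    """
    import warnings
    if len(peaks) == 0:
        raise ValueError("feature_enrichment requires at least one peak")
    fmap = build_feature_map(genes, genome_length, **map_kwargs)
    counts = {c: 0 for c in CATEGORIES}
    for p in peaks:
        counts[classify_feature(p, fmap)] += 1
    genome_counts = np.bincount(fmap, minlength=len(CATEGORIES))
    fractions = genome_counts / genome_length
    n = len(peaks)
    rows = []
    for cat in CATEGORIES:
        frac = fractions[_CAT_CODE[cat]]
        if frac == 0.0:
            warnings.warn(f"category {cat} absent from genome; excluded",
                          stacklevel=2)
            continue
        k = counts[cat]
        expected = int(round(frac * n))
        table = [[k, n - k], [expected, n - expected]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"category": cat, "peak_count": k,
                     "genome_fraction": frac, "odds_ratio": odds,
                     "fisher_p": p})
    return FeatureTable(pd.DataFrame(rows))
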