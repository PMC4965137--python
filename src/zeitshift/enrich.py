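"""Consensus-motif scanning and GO-term enrichment.

Peak sequences are scanned for known binding-site consensus strings (exact
match on both strands); enrichment of a motif is assessed empirically against
dinucleotide-preserving shuffles of the peak sequences (Altschul–Erickson
Euler-path shuffling, which keeps local composition fixed).  GO enrichment is
an upper-tail hypergeometric test per term over a flat gene→term annotation,
with Benjamini–Hochberg FDR across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peakcall import PeakSet


@dataclass(frozen=True)
class MotifDef:
    name: str
    consensus: str
    class_label: str = ""

    def __post_init__(self):
        if not self.consensus or set(self.consensus) - set("ACGT"):
            raise ValueError("consensus must be a non-empty ACGT string")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def peak_sequences(peaks: PeakSet, genome: dict[str, str]) -> list[str]:
    seqs = []
    for p in peaks:
        chrom = genome.get(p.chrom)
        if chrom is None or p.end > len(chrom) or p.start < 0:
            raise ValueError(f"peak {p.chrom}:{p.start}-{p.end} outside genome")
        seqs.append(chrom[p.start:p.end].upper())
    return seqs


def _count_hits(seq: str, motif: str) -> int:
    """Occurrences of motif or its reverse complement (overlaps counted)."""
    rc = _revcomp(motif)
    total = 0
    for pat in ({motif, rc}):
        i = seq.find(pat)
        while i != -1:
            total += 1
            i = seq.find(pat, i + 1)
    return total


def scan_motifs(peaks: PeakSet, genome: dict[str, str],
                motifs: list[MotifDef]) -> pd.DataFrame:
    """Per-motif hit counts and the fraction of peaks with >= 1 hit.

    Returns a tidy table (motif, peak_index, hits) plus, via groupby, the
    headline per-motif fraction; use :func:`motif_fractions` for the summary.
    """
    seqs = peak_sequences(peaks, genome)
    rows = []
    for m in motifs:
        for i, s in enumerate(seqs):
            rows.append({"motif": m.name, "peak_index": i,
                         "hits": _count_hits(s, m.consensus)})
    return pd.DataFrame(rows, columns=["motif", "peak_index", "hits"])


def motif_fractions(occurrences: pd.DataFrame) -> pd.Series:
    """Fraction of peaks with at least one hit, per motif."""
    return occurrences.assign(hit=occurrences["hits"] > 0) \
        .groupby("motif")["hit"].mean()


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide composition.

    Altschul–Erickson: the sequence is a walk on the digraph of symbol
    transitions; a uniform random Eulerian walk with the same start and end
    symbols yields a shuffle with identical dinucleotide counts.
    """
    if len(seq) <= 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    # choose a random last edge into `last` for each vertex (arborescence
    # toward the end vertex), then shuffle the remaining edges
    ordering = {}
    # Build arborescence by random walks from each vertex to `last`
    # (Wilson-style loop-erased construction is overkill; use the standard
    # trick: walk from each vertex until hitting `last`, record exit edges).
    verts = list(edges)
    rng_order = {v: None for v in verts}
    for v in verts:
        if v == last:
            continue
        walk = v
        seen = {}
        while walk != last:
            nxt = edges[walk][rng.integers(len(edges[walk]))]
            seen[walk] = nxt
            walk = nxt
        for u, w in seen.items():
            rng_order[u] = w
    for v in verts:
        rest = list(edges[v])
        if rng_order[v] is not None:
            rest.remove(rng_order[v])
        rng.shuffle(rest)
        ordering[v] = rest + ([rng_order[v]] if rng_order[v] is not None else [])
    counters = {v: 0 for v in verts}
    out = [seq[0]]
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordering[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment(peaks: PeakSet, genome: dict[str, str],
                     motifs: list[MotifDef], n_shuffles: int = 100,
                     seed: int = 0) -> pd.DataFrame:
    """Empirical per-motif enrichment p against dinucleotide shuffles.

    p = (1 + #shuffled sets with hit-fraction >= observed) / (n_shuffles + 1).
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    seqs = peak_sequences(peaks, genome)
    obs = {m.name: np.mean([_count_hits(s, m.consensus) > 0 for s in seqs])
           for m in motifs}
    ge_counts = {m.name: 0 for m in motifs}
    for _ in range(n_shuffles):
        shuffled = [dinucleotide_shuffle(s, rng) for s in seqs]
        for m in motifs:
            frac = np.mean([_count_hits(s, m.consensus) > 0 for s in shuffled])
            if frac >= obs[m.name]:
                ge_counts[m.name] += 1
    return pd.DataFrame([
        {"motif": m.name, "observed_fraction": obs[m.name],
         "p_empirical": (ge_counts[m.name] + 1) / (n_shuffles + 1)}
        for m in motifs])


@dataclass
class GOResult:
    term_id: str
    k: int   # targets annotated with term
    K: int   # universe genes with term
    n: int   # targets
    N: int   # universe size
    p_hyper: float
    fdr_bh: float


def go_enrichment(target_genes: set, universe_genes: set,
                  annotation: pd.DataFrame, min_term_size: int = 2,
                  ) -> list[GOResult]:
    """Hypergeometric GO enrichment with BH FDR over a flat annotation.

    ``annotation`` has columns gene_id, term_id.  Terms with fewer than
    ``min_term_size`` universe genes are skipped.
    """
    if not universe_genes:
        raise ValueError("empty gene universe")
    if not target_genes <= universe_genes:
        raise ValueError("targets must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe_genes)]
    N, n = len(universe_genes), len(target_genes)
    rows = []
    for term, genes in ann.groupby("term_id")["gene_id"]:
        term_genes = set(genes)
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & target_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    results = [GOResult(term_id=t, k=k, K=K, n=n, N=N, p_hyper=p,
                        fdr_bh=float(q))
               for (t, k, K, p), q in zip(rows, fdr)]
    return sorted(results, key=lambda r: (r.fdr_bh, r.p_hyper))
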