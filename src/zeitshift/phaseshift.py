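"""Binding-phase assignment and genotype-contrast statistics.

Each target gene's per-time-point enrichment abundance (pseudocounted
treatment/control fragment-count ratio over its master peak) is tested with a
one-way ANOVA across zeitgeber times; targets that pass (p < alpha) are
assigned the time point of maximal mean abundance unless the top two time
points are statistically indistinguishable, in which case the target is
excluded from the phase-shift analysis.  Group-level contrasts (hybrids vs
inbreds at one ZT) use two-sided Fisher's exact tests; set overlaps use the
upper-tail hypergeometric distribution with an optional seeded permutation
check for the four-way shared class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ZTS = ("ZT3", "ZT9", "ZT15")
EXCLUDED = "excluded"


def target_abundance(gene_id: str, peak, samples: dict,
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-ZT per-replicate enrichment abundance of one target's master peak.

    ``samples`` maps (zt, replicate, treatment) -> FragmentSet; abundance is
    (treatment fragments overlapping the master-peak interval + pseudocount) /
    (control fragments + pseudocount).  Raises when a replicate is missing.
    """
    zts = sorted({k[0] for k in samples}, key=lambda z: ZTS.index(z))
    reps = sorted({k[1] for k in samples})
    rows = []
    for zt in zts:
        for rep in reps:
            for tr in ("ChIP", "input"):
                if (zt, rep, tr) not in samples:
                    raise ValueError(f"missing sample ({zt}, rep{rep}, {tr}) "
                                     f"for gene {gene_id}")
            t = _count_overlap(samples[(zt, rep, "ChIP")], peak)
            c = _count_overlap(samples[(zt, rep, "input")], peak)
            rows.append({"gene_id": gene_id, "zt": zt, "replicate": rep,
                         "abundance": (t + pseudocount) / (c + pseudocount)})
    return pd.DataFrame(rows)


def _count_overlap(fs, peak) -> int:
    """Fragments overlapping [peak.start, peak.end) on peak.chrom."""
    df = fs.fragments
    sel = df["chrom"] == peak.chrom
    return int(((df["start"] < peak.end) & (df["end"] > peak.start) & sel).sum())


def assign_phase(abundances: dict[str, np.ndarray],
                 alpha: float = 0.05) -> tuple[str, float]:
    """Assign a binding phase from per-ZT replicate abundances.

    Returns ``(phase, anova_p)`` where phase is a ZT label or "excluded".
    A one-way ANOVA across the three ZT groups gates the call (p >= alpha →
    excluded); the phase is the ZT of maximal mean unless a two-sample t-test
    cannot separate the top two means at the same alpha (abundance tie →
    excluded).  Degenerate zero-variance, equal-mean data is excluded.
    """
    groups = [np.asarray(abundances[z], dtype=float) for z in ZTS]
    if any(len(g) < 2 for g in groups):
        raise ValueError("assign_phase needs >= 2 replicates per time point")
    means = np.array([g.mean() for g in groups])
    allvals = np.concatenate(groups)
    if np.ptp(allvals) == 0:
        return EXCLUDED, 1.0
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    if not np.isfinite(p) or p >= alpha:
        return EXCLUDED, float(p) if np.isfinite(p) else 1.0
    order = np.argsort(means)[::-1]  # argsort is stable: leftmost ZT wins ties
    top, runner = order[0], order[1]
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, tp = stats.ttest_ind(groups[top], groups[runner], equal_var=True)
    if not np.isfinite(tp) or tp >= alpha:
        return EXCLUDED, float(p)
    return ZTS[top], float(p)


def assign_phases(abund: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorized phase assignment for a tidy abundance table.

    ``abund`` columns: gene_id, genotype, zt, replicate, abundance, with the
    same replicate count everywhere.  Returns one row per (gene_id, genotype)
    with anova_p and phase.  Implements the same decision rule as
    :func:`assign_phase` with array-valued scipy tests.
    """
    wide = abund.pivot_table(index=["gene_id", "genotype"],
                             columns=["zt", "replicate"], values="abundance")
    reps = sorted({c[1] for c in wide.columns})
    groups = [wide[[(z, r) for r in reps]].to_numpy(float) for z in ZTS]
    arr = np.stack(groups, axis=1)            # (targets, 3, reps)
    means = arr.mean(axis=2)
    flat = np.ptp(arr.reshape(len(wide), -1), axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, anova_p = stats.f_oneway(*[g.T for g in groups], axis=0)
    anova_p = np.where(np.isfinite(anova_p), anova_p, 1.0)
    order = np.argsort(-means, axis=1, kind="stable")
    top, runner = order[:, 0], order[:, 1]
    rows = np.arange(len(wide))
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, tie_p = stats.ttest_ind(arr[rows, top, :], arr[rows, runner, :],
                                   axis=1, equal_var=True)
    tie_p = np.where(np.isfinite(tie_p), tie_p, 1.0)
    phase = np.array([ZTS[i] for i in top], dtype=object)
    excluded = flat | (anova_p >= alpha) | (tie_p >= alpha)
    phase[excluded] = EXCLUDED
    out = wide.index.to_frame(index=False)
    out["anova_p"] = anova_p
    out["phase"] = phase
    return out


def partition_targets(target_sets: dict[str, set],
                      hybrids=("H12", "H21"), inbreds=("P1", "P2"),
                      intersection: bool = False) -> dict[str, set]:
    """Split targets into shared-all, hybrid-specific, inbred-specific, other.

    Default union semantics: a gene is hybrid-specific when it is a target in
    either hybrid and in neither inbred (``intersection`` requires both
    members of the class).  The three named classes are disjoint.
    """
    hyb = [target_sets[g] for g in hybrids]
    inb = [target_sets[g] for g in inbreds]
    shared_all = set.intersection(*(hyb + inb))
    h_pool = set.intersection(*hyb) if intersection else set.union(*hyb)
    i_pool = set.intersection(*inb) if intersection else set.union(*inb)
    hybrid_specific = h_pool - set.union(*inb)
    inbred_specific = i_pool - set.union(*hyb)
    universe = set.union(*(hyb + inb))
    other = universe - shared_all - hybrid_specific - inbred_specific
    return {"shared_all": shared_all, "hybrid_specific": hybrid_specific,
            "inbred_specific": inbred_specific, "other": other}


@dataclass
class ShiftContrast:
    group_a: tuple
    group_b: tuple
    zt: str
    contingency: list  # [[a_at_zt, a_other], [b_at_zt, b_other]]
    odds_ratio: float
    fisher_p: float


def shift_test(phase_table: pd.DataFrame, group_a, group_b, zt: str,
               ) -> ShiftContrast:
    """Two-sided Fisher's exact test of phase==zt frequency between groups.

    ``phase_table`` has columns genotype and phase; excluded targets are
    dropped; genotypes within a group are pooled.
    """
    df = phase_table[phase_table["phase"] != EXCLUDED]
    a = df[df["genotype"].isin(group_a)]
    b = df[df["genotype"].isin(group_b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group in shift_test")
    table = [[int((a["phase"] == zt).sum()), int((a["phase"] != zt).sum())],
             [int((b["phase"] == zt).sum()), int((b["phase"] != zt).sum())]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return ShiftContrast(tuple(group_a), tuple(group_b), zt, table,
                         float(odds), float(p))


def overlap_test(set_a: set, set_b: set, universe_size: int) -> float:
    """Upper-tail hypergeometric p of observing >= |a & b| shared elements."""
    k = len(set_a & set_b)
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("set larger than universe")
    if k > min(len(set_a), len(set_b)):
        raise ValueError("overlap exceeds smaller set")
    return float(stats.hypergeom.sf(k - 1, universe_size, len(set_a),
                                    len(set_b)))


def shared_overlap_permutation(target_sets: dict[str, set], universe: set,
                               n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p for the size of the four-way shared target set.

    Target labels are reshuffled over the universe preserving per-genotype set
    sizes; p is the add-one-corrected fraction of permutations with a shared
    intersection at least as large as observed.
    """
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    observed = len(set.intersection(*target_sets.values()))
    sizes = [len(s) for s in target_sets.values()]
    hits = 0
    for _ in range(n_perm):
        perm_sets = [set(rng.choice(uni, size=sz, replace=False))
                     for sz in sizes]
        if len(set.intersection(*perm_sets)) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1)
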