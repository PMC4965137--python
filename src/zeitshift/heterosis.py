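"""Expression heterosis statistics: delta-Ct expression, MPV, nonadditivity, %BPH.

Relative expression follows the delta-Ct model (2^-(Ct_gene - Ct_reference))
against a reference transcript (18S rRNA in the emulated assays).  The
mid-parent value (MPV) is the additive expectation — the mean of the two
parental means — and a hybrid is called nonadditive at a time point when a
two-sample Student's t-test separates the F1 replicates from replicate-level
MPV pseudo-samples (parental replicate i paired with replicate i).
Better-parent heterosis is %BPH = (hybrid - best parent) / best parent * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def relative_expression(ct_table: pd.DataFrame, reference_gene: str = "18S",
                        ) -> pd.DataFrame:
    """Delta-Ct relative expression per (gene, genotype, time, replicate).

    ``ct_table`` columns: gene_id, genotype, time, replicate, ct.  Every
    sample must carry a reference-gene Ct.
    """
    ref = ct_table[ct_table["gene_id"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not in Ct table")
    ref = ref.set_index(["genotype", "time", "replicate"])["ct"]
    genes = ct_table[ct_table["gene_id"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(genes[["genotype", "time", "replicate"]])
    try:
        ref_ct = ref.loc[key].to_numpy()
    except KeyError as e:
        raise ValueError(f"reference Ct missing for sample {e}") from None
    genes["expression"] = 2.0 ** -(genes["ct"].to_numpy() - ref_ct)
    return genes[["gene_id", "genotype", "time", "replicate", "expression"]]


def rescale_to_mpv(expr: pd.DataFrame, parent1: str, parent2: str,
                   ) -> pd.DataFrame:
    """Rescale each gene so that the MPV at the first time point equals 1."""
    out = []
    for gid, g in expr.groupby("gene_id"):
        t0 = g["time"].min()
        p = g[(g["time"] == t0) & g["genotype"].isin([parent1, parent2])]
        mpv0 = p.groupby("genotype")["expression"].mean().mean()
        if mpv0 <= 0:
            raise ValueError(f"non-positive MPV at first time point for {gid}")
        g = g.copy()
        g["expression"] = g["expression"] / mpv0
        out.append(g)
    return pd.concat(out, ignore_index=True)


def mpv(parent1: pd.DataFrame, parent2: pd.DataFrame) -> pd.DataFrame:
    """Mid-parent value series and replicate-level pseudo-samples.

    Inputs are single-genotype expression frames (time, replicate,
    expression).  Returns a frame (time, replicate, mpv) pairing parental
    replicate i with replicate i; the per-time MPV is the mean over pairs,
    equal to the mean of parental means for matched replicate counts.
    """
    t1 = set(parent1["time"].unique())
    t2 = set(parent2["time"].unique())
    if t1 != t2:
        raise ValueError("parents measured on different time axes")
    a = parent1.set_index(["time", "replicate"])["expression"]
    b = parent2.set_index(["time", "replicate"])["expression"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no matching (time, replicate) pairs between parents")
    vals = (a.loc[common] + b.loc[common]) / 2.0
    out = common.to_frame(index=False)
    out["mpv"] = vals.to_numpy()
    return out


@dataclass
class HeterosisCall:
    gene_id: str
    time: float
    mpv: float
    f1_mean: float
    t_p: float
    mode: str  # additive | nonadditive
    log2_ratio: float
    degenerate: bool = False


def nonadditivity_test(f1: pd.DataFrame, mpv_series: pd.DataFrame,
                       alpha: float = 0.05, gene_id: str = "",
                       welch: bool = False) -> list[HeterosisCall]:
    """Student's t-test of F1 replicates against MPV pseudo-replicates per time.

    Equal-variance (Student's) t by default; ``welch`` switches to unequal
    variances.  Zero variance on both sides with equal means is reported as
    additive with a degeneracy flag.
    """
    calls = []
    for t in sorted(f1["time"].unique()):
        x = f1.loc[f1["time"] == t, "expression"].to_numpy(float)
        y = mpv_series.loc[mpv_series["time"] == t, "mpv"].to_numpy(float)
        if len(x) < 2 or len(y) < 2:
            raise ValueError(f"need >= 2 replicates at time {t}")
        degenerate = x.std() == 0 and y.std() == 0
        if degenerate and x.mean() == y.mean():
            p = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = stats.ttest_ind(x, y, equal_var=not welch)
            p = float(p) if np.isfinite(p) else (0.0 if degenerate else 1.0)
        m, f = float(y.mean()), float(x.mean())
        calls.append(HeterosisCall(
            gene_id=gene_id, time=float(t), mpv=m, f1_mean=f, t_p=p,
            mode="nonadditive" if p < alpha else "additive",
            log2_ratio=float(np.log2(f / m)) if m > 0 and f > 0 else np.nan,
            degenerate=degenerate))
    return calls


def bph(hybrid_values, parent1_values, parent2_values) -> float:
    """Percent better-parent heterosis: (hybrid - best parent)/best parent * 100."""
    h = float(np.mean(hybrid_values))
    best = max(float(np.mean(parent1_values)), float(np.mean(parent2_values)))
    if best <= 0:
        raise ValueError("best-parent mean must be positive")
    return (h - best) / best * 100.0
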