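"""Synthetic diurnal ChIP-seq study generator with known ground truth.

Emulates the experimental design of a diurnal transcription-factor ChIP-seq
study in a maize heterosis setting: two inbred parents (P1, P2) and their
reciprocal F1 hybrids (H12, H21), sampled at three zeitgeber times (ZT3, ZT9,
ZT15) with two ChIP replicates plus matched input controls.  Every generated
object carries a truth table (planted binding phases, occupancies, promoter
motifs, GO labels, expression modes) so each downstream stage of the pipeline
can be validated by parameter recovery rather than against withheld data.

Fragments are emitted directly as genomic intervals on one shared coordinate
system — there is no base-calling or read alignment; the unit of analysis is
the sonicated chromatin fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fragnorm import FragmentSet

GENOTYPES = ("P1", "P2", "H12", "H21")
HYBRIDS = ("H12", "H21")
INBREDS = ("P1", "P2")
ZTS = ("ZT3", "ZT9", "ZT15")

#: Binding-site consensus strings (field-standard names).  EE is the evening
#: element, CBS the CCA1-binding site; the *_variant entries are the hexamer
#: variants recovered in maize; Dof is the Dof-class transcription-factor core.
MOTIFS = {
    "EE": "AAATATCT",
    "CBS": "AAAAATCT",
    "EE_variant": "AAAATA",
    "CBS_variant": "AAGAAA",
    "Dof": "AAAGC",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class TruthInconsistencyError(ValueError):
    """Raised when a truth table contradicts itself (e.g. bound but zero occupancy)."""


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one synthetic study.

    Defaults mirror the emulated design: 4 genotypes x 3 zeitgeber times x 2
    replicates plus inputs, ~400-bp chromatin fragments, hybrid binding phases
    skewed toward early morning (ZT3) relative to the inbreds.
    """

    n_genes: int = 400
    genome_length: int | None = None  # auto: n_genes * (gene_span + gene_spacing)
    gene_span: int = 2_000
    gene_spacing: int = 20_000
    fragment_length_mean: float = 400.0
    fragment_length_sd: float = 60.0
    depth_per_sample: int = 50_000
    duplicate_rate: float = 0.10
    replicates: int = 2
    hybrid_phase_probs: tuple[float, float, float] = (0.65, 0.20, 0.15)
    inbred_phase_probs: tuple[float, float, float] = (0.40, 0.35, 0.25)
    bound_fraction: float = 0.5
    flat_fraction: float = 0.05
    signal_fraction: float = 0.30
    bump_width: float = 400.0  # Gaussian spread (bp) of signal fragment centres
    abundance_gain: float = 3.0
    noise_sd: float = 0.10
    motif_plant_rate: float = 0.8
    planted_motifs: tuple[str, ...] = ("EE",)
    n_go_terms: int = 20
    go_enriched_term: str = "GO:0015979"
    go_enrichment_fold: float = 5.0
    go_base_rate: float = 0.05
    expr_nonadditive_fraction: float = 0.2
    expr_effect_size: float = 2.0
    expr_noise_sd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("duplicate_rate", "bound_fraction", "flat_fraction",
                     "signal_fraction", "motif_plant_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("hybrid_phase_probs", "inbred_phase_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 3-vector of probabilities summing to 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")
        if self.genome_length is not None:
            need = self.n_genes * (self.gene_span + self.gene_spacing)
            if self.genome_length < need:
                raise ValueError(
                    f"genome_length={self.genome_length} too small for "
                    f"{self.n_genes} genes: need at least {need} bp "
                    f"(deficit {need - self.genome_length} bp)"
                )

    @property
    def effective_genome_length(self) -> int:
        if self.genome_length is not None:
            return self.genome_length
        return max(self.n_genes * (self.gene_span + self.gene_spacing), 1_000)

    def with_seed(self, seed: int) -> "SimDesign":
        return replace(self, seed=seed)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_genome(design: SimDesign, seed: int | None = None):
    """Lay out a synthetic gene space on one chromosome.

    Returns ``(genome, genes, truth)`` where ``genome`` maps chromosome name
    to sequence, ``genes`` is a gene-model table (one row per gene: TSS, TES,
    5'UTR, CDS, strand, promoter summit), and ``truth`` the per-gene x
    per-genotype ground-truth table.

    Genes are non-overlapping, evenly spaced, with a 200-bp 5'UTR followed by
    CDS.  Promoters of motif-planted genes contain the requested consensus on
    a random strand within 500 bp upstream of the TSS.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    L = design.effective_genome_length
    chrom = "chr1"
    seq = bytearray(_random_seq(rng, L), "ascii")

    rows = []
    unit = design.gene_span + design.gene_spacing
    margin = design.gene_spacing // 2
    for i in range(design.n_genes):
        start = margin + i * unit
        end = start + design.gene_span
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss, tes = start, end
            utr5 = (start, start + 200)
            cds = (start + 200, end)
            summit = max(0, tss - 200)
        else:
            tss, tes = end, start
            utr5 = (end - 200, end)
            cds = (start, end - 200)
            summit = min(L - 1, tss + 200)
        rows.append({
            "gene_id": f"g{i:05d}", "chrom": chrom, "start": start, "end": end,
            "strand": strand, "tss": tss, "tes": tes,
            "utr5_start": utr5[0], "utr5_end": utr5[1],
            "cds_start": cds[0], "cds_end": cds[1],
            "promoter_summit": summit,
        })
    genes = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "start", "end", "strand", "tss", "tes",
        "utr5_start", "utr5_end", "cds_start", "cds_end", "promoter_summit"])

    # per-gene attributes shared across genotypes
    motifs_planted, go_labels, expr_modes = [], [], []
    go_pool = [f"GO:{7000000 + t}" for t in range(design.n_go_terms)]
    if design.go_enriched_term not in go_pool and design.n_go_terms > 0:
        go_pool[0] = design.go_enriched_term
    n_nonadd = int(round(design.expr_nonadditive_fraction * design.n_genes))
    nonadd_ids = set(rng.choice(design.n_genes, size=n_nonadd, replace=False)) \
        if design.n_genes else set()

    bound_any = {}  # filled below; motif/GO plant decided after binding draw
    truth_rows = []
    for i in range(design.n_genes):
        gid = f"g{i:05d}"
        flat = rng.random() < design.flat_fraction
        per_geno = {}
        for geno in GENOTYPES:
            probs = (design.hybrid_phase_probs if geno in HYBRIDS
                     else design.inbred_phase_probs)
            bound = rng.random() < design.bound_fraction
            if bound:
                if flat:
                    occ = np.ones(3)
                    phase = None
                else:
                    phase_idx = rng.choice(3, p=probs)
                    occ = rng.uniform(0.10, 0.40, size=3)
                    occ[phase_idx] = 1.0
                    phase = ZTS[phase_idx]
            else:
                occ = np.zeros(3)
                phase = None
            per_geno[geno] = (bound, flat and bound, phase, occ)
        bound_any[gid] = any(v[0] for v in per_geno.values())
        for geno, (bound, is_flat, phase, occ) in per_geno.items():
            truth_rows.append({
                "gene_id": gid, "genotype": geno, "bound": bound,
                "flat": is_flat, "planted_phase": phase,
                "occ_ZT3": occ[0], "occ_ZT9": occ[1], "occ_ZT15": occ[2],
            })

    for i in range(design.n_genes):
        gid = f"g{i:05d}"
        if design.planted_motifs and rng.random() < design.motif_plant_rate:
            names = list(design.planted_motifs)
            motifs_planted.append(",".join(names))
            for name in names:
                consensus = MOTIFS[name]
                gi = genes.iloc[i]
                # promoter window 500 bp upstream of TSS, strand-aware
                if gi.strand == "+":
                    lo, hi = max(0, gi.tss - 500), gi.tss
                else:
                    lo, hi = gi.tss, min(L, gi.tss + 500)
                pos = int(rng.integers(lo, hi - len(consensus)))
                planted = consensus if rng.random() < 0.5 else _revcomp(consensus)
                seq[pos:pos + len(consensus)] = planted.encode("ascii")
        else:
            motifs_planted.append("")
        terms = set()
        if go_pool:
            p_enr = min(1.0, design.go_base_rate * design.go_enrichment_fold)
            for term in go_pool:
                rate = design.go_base_rate
                if term == design.go_enriched_term and bound_any[gid]:
                    rate = p_enr
                if rng.random() < rate:
                    terms.add(term)
        go_labels.append(",".join(sorted(terms)))
        expr_modes.append(
            ("nonadditive-up" if rng.random() < 0.5 else "nonadditive-down")
            if i in nonadd_ids else "additive")

    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "genotype", "bound", "flat", "planted_phase",
        "occ_ZT3", "occ_ZT9", "occ_ZT15"])
    per_gene = pd.DataFrame({
        "gene_id": genes["gene_id"],
        "motifs_planted": motifs_planted,
        "go_terms": go_labels,
        "expression_mode": expr_modes,
    })
    truth = truth.merge(per_gene, on="gene_id", how="left") if len(truth) else \
        truth.assign(motifs_planted=[], go_terms=[], expression_mode=[])

    genome = {chrom: seq.decode("ascii")}
    _check_truth(truth)
    return genome, genes, truth


def _check_truth(truth: pd.DataFrame) -> None:
    """Planted-truth consistency: non-flat bound genes peak at their planted phase."""
    occ = truth[["occ_ZT3", "occ_ZT9", "occ_ZT15"]].to_numpy(float)
    bound = truth["bound"].to_numpy(bool)
    if bound.any() and (occ[bound].sum(axis=1) == 0).any():
        raise TruthInconsistencyError("bound gene with all-zero occupancy")
    nonflat = bound & ~truth["flat"].to_numpy(bool)
    if nonflat.any():
        idx = occ[nonflat].argmax(axis=1)
        planted = truth.loc[nonflat, "planted_phase"].map(
            {z: i for i, z in enumerate(ZTS)}).to_numpy()
        if (idx != planted).any():
            raise TruthInconsistencyError("occupancy argmax disagrees with planted phase")


def _fragment_lengths(rng, design, n):
    lens = rng.normal(design.fragment_length_mean, design.fragment_length_sd, n)
    return np.maximum(np.round(lens), 50).astype(np.int64)


def generate_chip_fragments(genes: pd.DataFrame, truth: pd.DataFrame,
                            design: SimDesign, seed: int | None = None,
                            ) -> dict[tuple, FragmentSet]:
    """Simulate fragment sets for every (genotype, ZT, replicate, treatment).

    Input samples are background-only (uniform fragment placement).  ChIP
    samples allocate ``signal_fraction`` of the depth to bound promoters in
    proportion to each gene's occupancy at that time point; signal fragment
    centres are Gaussian around the promoter summit with spread ``bump_width``.
    A ``duplicate_rate`` fraction of extra exact-copy fragments emulates PCR
    duplication.
    """
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    _check_truth(truth)
    L = design.effective_genome_length
    chrom = "chr1"
    out: dict[tuple, FragmentSet] = {}
    summits = genes.set_index("gene_id")["promoter_summit"] if len(genes) else None

    for geno in GENOTYPES:
        sub = truth[truth["genotype"] == geno].set_index("gene_id")
        for zi, zt in enumerate(ZTS):
            occ_col = f"occ_{zt}"
            bound = sub[sub["bound"]]
            weights = bound[occ_col].to_numpy(float)
            bound_ids = bound.index.to_numpy()
            for rep in range(1, design.replicates + 1):
                for treatment in ("ChIP", "input"):
                    n = design.depth_per_sample
                    if treatment == "ChIP" and len(bound_ids) and weights.sum() > 0:
                        n_sig = int(round(design.signal_fraction * n))
                    else:
                        n_sig = 0
                    n_bg = n - n_sig
                    lens = _fragment_lengths(rng, design, n)
                    starts = np.empty(n, dtype=np.int64)
                    starts[:n_bg] = rng.integers(0, np.maximum(L - lens[:n_bg], 1))
                    if n_sig:
                        gene_idx = rng.choice(len(bound_ids), size=n_sig,
                                              p=weights / weights.sum())
                        centres = summits.loc[bound_ids[gene_idx]].to_numpy(float)
                        centres = centres + rng.normal(0, design.bump_width / 2, n_sig)
                        starts[n_bg:] = np.round(centres - lens[n_bg:] / 2)
                    starts = np.clip(starts, 0, None)
                    ends = np.minimum(starts + lens, L)
                    starts = np.minimum(starts, ends - 1)
                    strands = np.where(rng.random(n) < 0.5, "+", "-")
                    df = pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": ends, "strand": strands})
                    n_dup = int(round(design.duplicate_rate * n))
                    if n_dup:
                        dup_idx = rng.choice(n, size=n_dup, replace=False)
                        df = pd.concat([df, df.iloc[dup_idx]], ignore_index=True)
                    sid = f"{geno}_{zt}_rep{rep}_{treatment}"
                    out[(geno, zt, rep, treatment)] = FragmentSet(
                        sample_id=sid, genotype=geno, zt=zt, replicate=rep,
                        treatment=treatment, fragments=df)
    return out


def generate_target_abundances(truth: pd.DataFrame, design: SimDesign,
                               seed: int | None = None) -> pd.DataFrame:
    """Per-gene per-ZT replicate enrichment abundances straight from truth.

    Fast path for parameter-recovery experiments: abundance for a bound gene is
    ``1 + abundance_gain * occupancy(ZT)`` with multiplicative Gaussian noise
    (sd ``noise_sd``); unbound genes sit at background (1).  This bypasses
    fragment simulation and peak calling but preserves the statistical problem
    the phase-assignment stage solves.
    """
    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)
    occ = truth[["occ_ZT3", "occ_ZT9", "occ_ZT15"]].to_numpy(float)
    base = 1.0 + design.abundance_gain * occ  # (rows, 3)
    reps = np.arange(1, design.replicates + 1)
    vals = base[:, :, None] * (1.0 + rng.normal(
        0, design.noise_sd, size=(len(truth), 3, design.replicates)))
    vals = np.maximum(vals, 0.0)
    recs = []
    gene = truth["gene_id"].to_numpy()
    geno = truth["genotype"].to_numpy()
    for zi, zt in enumerate(ZTS):
        for ri, rep in enumerate(reps):
            recs.append(pd.DataFrame({
                "gene_id": gene, "genotype": geno, "zt": zt, "replicate": rep,
                "abundance": vals[:, zi, ri]}))
    return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# expression tables (qPCR-style Ct)

ZT_HOURS = tuple(range(0, 24, 3))
DAP_DAYS = (5, 8, 11, 14)


def _parent_profile(rng, times, diurnal=True):
    """A smooth positive expression profile over the time axis."""
    t = np.asarray(times, dtype=float)
    if diurnal:
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.3, 0.8)
        base = rng.uniform(0.5, 2.0)
        return base * (1.0 + amp * np.cos(2 * np.pi * t / 24.0 + phase))
    return rng.uniform(0.5, 2.0) * np.ones_like(t)


def generate_expression(truth: pd.DataFrame, design: SimDesign,
                        axis: str = "zt", n_replicates: int = 3,
                        nonadditive_times: tuple | None = None,
                        seed: int | None = None) -> pd.DataFrame:
    """Ct tables for P1/P2/H12/H21 over a ZT (0..21 h) or DAP (5/8/11/14 d) axis.

    Additive genes have F1 mean equal to the mid-parent mean; nonadditive genes
    deviate by ``expr_effect_size`` (up or down) at ``nonadditive_times``
    (default: first two time points of the axis).  The reference gene ``18S``
    is emitted with constant Ct so that relative expression can be formed with
    the delta-Ct model downstream.  Noise is multiplicative on the expression
    scale with sd ``expr_noise_sd``.
    """
    rng = np.random.default_rng(design.seed + 3 if seed is None else seed)
    times = ZT_HOURS if axis == "zt" else DAP_DAYS
    if nonadditive_times is None:
        nonadditive_times = times[:2]
    ref_ct = 15.0
    genes = truth.drop_duplicates("gene_id")[["gene_id", "expression_mode"]]
    rows = []
    for gid, mode in genes.itertuples(index=False):
        p1 = _parent_profile(rng, times, diurnal=(axis == "zt"))
        p2 = _parent_profile(rng, times, diurnal=(axis == "zt"))
        mpv = (p1 + p2) / 2.0
        f1 = mpv.copy()
        if mode != "additive":
            mask = np.isin(np.asarray(times), np.asarray(nonadditive_times))
            fac = design.expr_effect_size if mode == "nonadditive-up" \
                else 1.0 / design.expr_effect_size
            f1[mask] = mpv[mask] * fac
        for geno, prof in (("P1", p1), ("P2", p2), ("H12", f1), ("H21", f1)):
            for ti, t in enumerate(times):
                for rep in range(1, n_replicates + 1):
                    expr = prof[ti] * max(
                        1e-9, 1.0 + rng.normal(0, design.expr_noise_sd))
                    rows.append((gid, geno, t, rep,
                                 ref_ct - np.log2(expr)))
                    rows.append(("18S", geno, t, rep, ref_ct))
    df = pd.DataFrame(rows, columns=["gene_id", "genotype", "time",
                                     "replicate", "ct"])
    # one reference row per sample, not per gene
    ref = df[df.gene_id == "18S"].drop_duplicates(
        ["genotype", "time", "replicate"])
    return pd.concat([df[df.gene_id != "18S"], ref], ignore_index=True)


# ---------------------------------------------------------------------------
# luminescence traces

@dataclass(frozen=True)
class TraceDesign:
    """Luminescence time-series generator settings (constant-light recordings)."""
    n_rhythmic: int = 10
    n_arrhythmic: int = 10
    period: float = 24.0
    damping: float = 0.005      # 1/h amplitude decay under constant light
    amplitude: float = 1.0
    baseline: float = 2.0
    noise_sd: float = 0.1
    drift: float = 0.001        # slow linear drift in arrhythmic traces,
                                # kept below the noise floor over a recording
    duration: float = 120.0     # h
    dt: float = 1.0             # h
    seed: int = 0


def generate_traces(tdesign: TraceDesign, seed: int | None = None) -> pd.DataFrame:
    """Damped-cosine-plus-noise traces labelled rhythmic, noise+drift arrhythmic.

    Warns when the recording is shorter than two periods (period unresolvable).
    """
    import warnings
    rng = np.random.default_rng(tdesign.seed if seed is None else seed)
    if tdesign.duration < 2 * tdesign.period:
        warnings.warn("trace duration < 2 periods: period not resolvable",
                      stacklevel=2)
    t = np.arange(0.0, tdesign.duration + 1e-9, tdesign.dt)
    rows = []
    for i in range(tdesign.n_rhythmic):
        phase = rng.uniform(0, 2 * np.pi)
        x = (tdesign.baseline
             + tdesign.amplitude * np.exp(-tdesign.damping * t)
             * np.cos(2 * np.pi * t / tdesign.period + phase)
             + rng.normal(0, tdesign.noise_sd, t.size))
        rows.append(pd.DataFrame({"trace_id": f"rhythmic_{i}", "time_h": t,
                                  "value": x, "label": "rhythmic"}))
    for i in range(tdesign.n_arrhythmic):
        x = (tdesign.baseline + tdesign.drift * t * rng.uniform(-1, 1)
             + rng.normal(0, max(tdesign.noise_sd, 1e-3), t.size))
        rows.append(pd.DataFrame({"trace_id": f"arrhythmic_{i}", "time_h": t,
                                  "value": x, "label": "arrhythmic"}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["trace_id", "time_h", "value", "label"])
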