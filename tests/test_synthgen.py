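"""Generator ground-truth and determinism checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zeitshift import fragnorm, io as zio
from zeitshift.synthgen import (HYBRIDS, MOTIFS, ZTS, SimDesign, TraceDesign,
                                generate_chip_fragments, generate_expression,
                                generate_genome, generate_target_abundances,
                                generate_traces)


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestGenomeGeneration:
    def test_motif_rate_one_plants_in_every_promoter(self):
        d = SimDesign(n_genes=10, motif_plant_rate=1.0, seed=3)
        genome, genes, truth = generate_genome(d)
        seq = genome["chr1"]
        ee = MOTIFS["EE"]
        for row in genes.itertuples(index=False):
            lo, hi = ((row.tss - 500, row.tss) if row.strand == "+"
                      else (row.tss, row.tss + 500))
            prom = seq[max(0, lo):hi]
            assert ee in prom or _revcomp(ee) in prom

    def test_zero_genes_yields_empty_tables(self):
        genome, genes, truth = generate_genome(SimDesign(n_genes=0))
        assert len(genes) == 0 and len(truth) == 0

    def test_seeded_runs_are_byte_identical(self, tmp_path):
        outs = []
        for sub in ("a", "b"):
            genome, genes, _ = generate_genome(SimDesign(n_genes=8, seed=7))
            fa, gff = tmp_path / f"{sub}.fa", tmp_path / f"{sub}.gff3"
            zio.write_fasta(genome, fa)
            zio.write_gff3(genes, gff)
            outs.append((fa.read_bytes(), gff.read_bytes()))
        assert outs[0] == outs[1]

    def test_genes_non_overlapping(self):
        _, genes, _ = generate_genome(SimDesign(n_genes=30, seed=1))
        g = genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_genome_too_small_raises_with_deficit(self):
        with pytest.raises(ValueError, match="deficit"):
            SimDesign(n_genes=100, genome_length=1000)

    def test_planted_phase_is_occupancy_argmax(self):
        _, _, truth = generate_genome(SimDesign(n_genes=50, seed=2))
        occ = truth[["occ_ZT3", "occ_ZT9", "occ_ZT15"]].to_numpy()
        nonflat = truth["bound"] & ~truth["flat"]
        idx = occ[nonflat].argmax(axis=1)
        planted = truth.loc[nonflat, "planted_phase"].map(
            {z: i for i, z in enumerate(ZTS)})
        assert (idx == planted.to_numpy()).all()
        # strict maximum
        top = np.take_along_axis(occ[nonflat.to_numpy()], idx[:, None], 1)
        rest = occ[nonflat.to_numpy()].copy()
        np.put_along_axis(rest, idx[:, None], -np.inf, 1)
        assert (top[:, 0] > rest.max(axis=1)).all()

    def test_phase_composition_matches_probs_within_binomial_bounds(self):
        d = SimDesign(n_genes=300, bound_fraction=1.0, flat_fraction=0.0,
                      seed=11)
        _, _, truth = generate_genome(d)
        z = 2.576  # 99% binomial bound
        for genos, probs in ((HYBRIDS, d.hybrid_phase_probs),
                             (("P1", "P2"), d.inbred_phase_probs)):
            sub = truth[truth["genotype"].isin(genos)]
            n = len(sub)
            for zt, p in zip(ZTS, probs):
                phat = (sub["planted_phase"] == zt).mean()
                assert abs(phat - p) <= z * np.sqrt(p * (1 - p) / n)


class TestChipFragments:
    def test_sample_grid_complete(self, small_design, small_samples):
        assert len(small_samples) == 4 * 3 * small_design.replicates * 2

    def test_totals_near_depth_before_duplication(self, small_design,
                                                  small_samples):
        for fs in small_samples.values():
            dedup = fragnorm.deduplicate(fs)
            assert abs(len(dedup) - small_design.depth_per_sample) \
                <= 0.02 * small_design.depth_per_sample

    def test_zero_duplicate_rate_survives_dedup_unchanged(self):
        d = SimDesign(n_genes=5, depth_per_sample=2000, duplicate_rate=0.0,
                      seed=4)
        _, genes, truth = generate_genome(d)
        samples = generate_chip_fragments(genes, truth, d)
        fs = next(iter(samples.values()))
        assert len(fragnorm.deduplicate(fs)) == len(fs)

    def test_enriched_promoter_dominates_pileup(self, small_design,
                                                small_study, small_samples):
        from tests.oracles import brute_force_pileup

        from zeitshift import peakcall
        genome, genes, truth = small_study
        L = small_design.effective_genome_length
        sub = truth[(truth.genotype == "P1") & truth.bound]
        target = sub.loc[sub["occ_ZT3"].idxmax()]
        summit = int(genes.set_index("gene_id").loc[target.gene_id,
                                                    "promoter_summit"])
        fs = small_samples[("P1", "ZT3", 1, "ChIP")]
        cov = peakcall.pileup(fs, L).values
        window = cov[max(0, summit - 500):summit + 500]
        assert window.max() > 3 * np.median(cov)
        # pileup itself agrees with brute force on a slice of fragments
        df = fs.fragments.head(200)
        sliced = fs.with_fragments(df)
        assert np.array_equal(peakcall.pileup(sliced, L).values,
                              brute_force_pileup(df, L))

    def test_unbound_study_chip_matches_input_distribution(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            d = SimDesign(n_genes=5, bound_fraction=0.0,
                          depth_per_sample=3000, seed=100 + seed)
            _, genes, truth = generate_genome(d)
            samples = generate_chip_fragments(genes, truth, d)
            chip = fragnorm.bin_coverage(samples[("P1", "ZT3", 1, "ChIP")],
                                         1000, d.effective_genome_length)
            inp = fragnorm.bin_coverage(samples[("P1", "ZT3", 1, "input")],
                                        1000, d.effective_genome_length)
            _, p = stats.ks_2samp(chip.values, inp.values)
            hits += p > 0.01
        assert hits >= int(0.95 * n_seeds)

    def test_seeded_fragments_reproducible(self):
        d = SimDesign(n_genes=4, depth_per_sample=500, seed=9)
        _, genes, truth = generate_genome(d)
        a = generate_chip_fragments(genes, truth, d)
        b = generate_chip_fragments(genes, truth, d)
        k = ("H12", "ZT9", 1, "ChIP")
        pd.testing.assert_frame_equal(a[k].fragments, b[k].fragments)


class TestExpression:
    def test_additive_gene_f1_equals_midparent_at_zero_noise(self):
        d = SimDesign(n_genes=6, expr_noise_sd=0.0,
                      expr_nonadditive_fraction=0.0, seed=5)
        _, _, truth = generate_genome(d)
        ct = generate_expression(truth, d)
        from zeitshift.heterosis import relative_expression
        expr = relative_expression(ct)
        piv = expr.pivot_table(index=["gene_id", "time"], columns="genotype",
                               values="expression")
        mpv = (piv["P1"] + piv["P2"]) / 2
        np.testing.assert_allclose(piv["H12"], mpv, rtol=1e-9)

    def test_nonadditive_up_doubles_at_configured_times_only(self):
        d = SimDesign(n_genes=4, expr_noise_sd=0.0,
                      expr_nonadditive_fraction=1.0, expr_effect_size=2.0,
                      seed=6)
        _, _, truth = generate_genome(d)
        truth = truth.assign(expression_mode="nonadditive-up")
        ct = generate_expression(truth, d, nonadditive_times=(0,))
        from zeitshift.heterosis import relative_expression
        expr = relative_expression(ct)
        piv = expr.pivot_table(index=["gene_id", "time"], columns="genotype",
                               values="expression")
        ratio = piv["H12"] / ((piv["P1"] + piv["P2"]) / 2)
        at0 = ratio.xs(0, level="time")
        rest = ratio.drop(0, level="time")
        np.testing.assert_allclose(at0, 2.0, rtol=1e-9)
        np.testing.assert_allclose(rest, 1.0, rtol=1e-9)

    def test_seeded_tables_identical(self):
        d = SimDesign(n_genes=3, seed=8)
        _, _, truth = generate_genome(d)
        pd.testing.assert_frame_equal(generate_expression(truth, d),
                                      generate_expression(truth, d))


class TestTraces:
    def test_noiseless_undamped_trace_is_pure_cosine(self):
        td = TraceDesign(n_rhythmic=1, n_arrhythmic=0, damping=0.0,
                         noise_sd=0.0, seed=1)
        df = generate_traces(td)
        t = df["time_h"].to_numpy()
        x = df["value"].to_numpy()
        resid = x - td.baseline
        # must match a cosine of the configured period at some phase
        c = np.cos(2 * np.pi * t / td.period)
        s = np.sin(2 * np.pi * t / td.period)
        coef, *_ = np.linalg.lstsq(np.c_[c, s], resid, rcond=None)
        np.testing.assert_allclose(np.c_[c, s] @ coef, resid, atol=1e-9)
        assert np.hypot(*coef) == pytest.approx(td.amplitude, rel=1e-6)

    def test_arrhythmic_autocorrelation_low_at_period_lag(self):
        low = 0
        n_seeds = 20
        for seed in range(n_seeds):
            td = TraceDesign(n_rhythmic=0, n_arrhythmic=1, seed=200 + seed)
            df = generate_traces(td)
            x = df["value"].to_numpy()
            lag = int(td.period / td.dt)
            a, b = x[:-lag], x[lag:]
            r = np.corrcoef(a, b)[0, 1]
            low += abs(r) < 0.2
        assert low >= int(0.95 * n_seeds)

    def test_short_trace_warns_about_unresolvable_period(self):
        with pytest.warns(UserWarning, match="not resolvable"):
            generate_traces(TraceDesign(duration=40.0, period=24.0))

    def test_seeded_traces_identical(self):
        td = TraceDesign(seed=3)
        pd.testing.assert_frame_equal(generate_traces(td),
                                      generate_traces(td))


def test_abundance_fast_path_matches_truth_structure():
    d = SimDesign(n_genes=10, seed=13)
    _, _, truth = generate_genome(d)
    ab = generate_target_abundances(truth, d)
    assert len(ab) == len(truth) * 3 * d.replicates
    # bound genes at planted phase sit well above background on average
    merged = ab.merge(truth, on=["gene_id", "genotype"])
    bound = merged[merged.bound & ~merged.flat]
    at_phase = bound[bound.zt == bound.planted_phase]["abundance"].mean()
    background = merged[~merged.bound]["abundance"].mean()
    assert at_phase > 2 * background
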