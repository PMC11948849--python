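import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pollenpop as pp
from conftest import toy_genotable
from pollenpop.genotypes import MISSING
from pollenpop.selscan import Window, XPCLRConfig, estimate_omega


def textbook_wc_fst(calls_a, calls_b):
    """Independent per-site transcription of the two-population
    Weir-Cockerham estimator (oracle; scalar arithmetic, one site)."""
    out = []
    for j in range(calls_a.shape[1]):
        comps = []
        stats = []
        for calls in (calls_a, calls_b):
            col = calls[:, j]
            col = col[col != MISSING]
            n = len(col)
            p = col.sum() / (2 * n)
            h = (col == 1).sum() / n
            stats.append((n, p, h))
        r = 2
        nbar = sum(n for n, _, _ in stats) / r
        nc = (r * nbar - sum(n**2 for n, _, _ in stats) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p, _ in stats) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p, _ in stats) / ((r - 1) * nbar)
        hbar = sum(n * h for n, _, h in stats) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        out.append((a, b, c))
    return out


@pytest.fixture(scope="module")
def sweep_scan():
    cfg = pp.SimConfig(
        seed=0, n_snps=2000, drift_F=0.05, sweep_loci=[(1, 15_000_000, 0.8)]
    )
    geno, truth = pp.simulate_genotypes(cfg)
    lengths = {"1": cfg.chrom_length, "2": cfg.chrom_length}
    df = pp.scan_windows(geno, truth.groups, lengths)
    return geno, truth, df


class TestMakeWindows:
    def test_three_mb_chromosome_tiling(self):
        ws = pp.make_windows({"1": 3_000_000})
        starts = [w.start for w in ws]
        assert starts == [1, 750_001, 1_500_001, 2_250_001]
        assert ws[-1].end == 3_000_000  # truncated

    def test_zero_overlap_tiles_disjointly(self):
        ws = pp.make_windows({"1": 3_000_000}, size=1_000_000, overlap=0)
        assert [(w.start, w.end) for w in ws] == [
            (1, 1_000_000),
            (1_000_001, 2_000_000),
            (2_000_001, 3_000_000),
        ]

    def test_short_chromosome_single_truncated_window(self):
        ws = pp.make_windows({"1": 400_000})
        assert len(ws) == 1
        assert (ws[0].start, ws[0].end) == (1, 400_000)

    def test_overlap_not_smaller_than_size_rejected(self):
        with pytest.raises(ValueError):
            pp.make_windows({"1": 10}, size=100, overlap=100)


class TestWeirFst:
    def test_matches_textbook_transcription(self):
        rng = np.random.default_rng(5)
        calls = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(20, 50)).astype(
            np.int8
        )
        calls[rng.uniform(size=calls.shape) < 0.05] = MISSING
        geno = toy_genotable(calls)
        groups = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        from pollenpop.selscan import weir_cockerham_components

        a, b, c, valid = weir_cockerham_components(geno, groups, ("A", "B"))
        oracle = textbook_wc_fst(calls[:10], calls[10:])
        for j in range(50):
            if not valid[j]:
                continue
            oa, ob, oc = oracle[j]
            assert a[j] == pytest.approx(oa, abs=1e-12)
            assert b[j] == pytest.approx(ob, abs=1e-12)
            assert c[j] == pytest.approx(oc, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        calls = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        geno = toy_genotable(calls)
        groups = {f"s{i}": ("A" if i < 10 else "B") for i in range(20)}
        _, per_site = pp.weir_fst(geno, groups, ("A", "B"))
        assert per_site[0] == pytest.approx(1.0)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(6)
        calls = rng.binomial(2, rng.uniform(0.3, 0.7, 500), size=(200, 500))
        geno = toy_genotable(calls)
        groups = {f"s{i}": ("A" if i < 100 else "B") for i in range(200)}
        fst = pp.genomewide_fst(geno, groups, ("A", "B"))
        assert abs(fst) < 0.02

    def test_windowed_value_is_ratio_of_sums(self, sweep_scan):
        geno, truth, _ = sweep_scan
        windows = pp.make_windows({"1": 30_000_000, "2": 30_000_000})
        df, per_site = pp.weir_fst(
            geno, truth.groups, ("feral", "domesticated"), windows
        )
        # ratio-of-sums lies within [min, max] of defined per-site values
        row = df.dropna(subset=["fst"]).iloc[5]
        w = Window(row.chrom, row.start, row.end, 750_000)
        in_w = (
            (geno.chrom.astype(str) == w.chrom)
            & (geno.pos >= w.start)
            & (geno.pos <= w.end)
        )
        vals = per_site[in_w]
        vals = vals[np.isfinite(vals)]
        assert vals.min() - 1e-12 <= row.fst <= vals.max() + 1e-12

    def test_empty_group_rejected(self):
        geno = toy_genotable([[0, 1], [1, 2]])
        with pytest.raises(ValueError):
            pp.weir_fst(geno, {"s0": "A", "s1": "A"}, ("A", "B"))


class TestWindowedPi:
    def test_monomorphic_window_is_zero(self):
        geno = toy_genotable(np.zeros((10, 5)))
        groups = {f"s{i}": "A" for i in range(10)}
        ws = pp.make_windows({"1": 10_000})
        assert pp.windowed_pi(geno, groups, "A", ws).sum() == 0.0

    def test_single_site_hand_value(self):
        # p = 0.5, 20 called alleles, 1 Mb window
        calls = np.array([[0]] * 5 + [[2]] * 5, dtype=np.int8)
        geno = toy_genotable(calls)
        groups = {f"s{i}": "A" for i in range(10)}
        ws = [Window("1", 1, 1_000_000, 750_000)]
        pi = pp.windowed_pi(geno, groups, "A", ws)
        assert pi[0] == pytest.approx(2 * 0.25 * 20 / 19 / 1e6)

    def test_allele_label_swap_invariance(self, sweep_scan):
        geno, truth, _ = sweep_scan
        ws = pp.make_windows({"1": 30_000_000})
        pi1 = pp.windowed_pi(geno, truth.groups, "feral", ws)
        flipped = toy_genotable(
            np.where(geno.calls == MISSING, MISSING, 2 - geno.calls),
            chrom=geno.chrom, pos=geno.pos,
        )
        flipped.individuals = list(geno.individuals)
        pi2 = pp.windowed_pi(flipped, truth.groups, "feral", ws)
        np.testing.assert_allclose(pi1, pi2)


class TestDri:
    def test_equal_diversity_is_one(self):
        np.testing.assert_allclose(pp.dri([1e-3], [1e-3]), [1.0])

    def test_zero_feral_diversity_is_zero(self):
        assert pp.dri([0.0], [1e-3])[0] == 0.0

    def test_zero_domesticated_diversity_undefined(self):
        assert np.isnan(pp.dri([1e-3], [0.0])[0])

    def test_reciprocal_product_is_one(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1e-4, 1e-2, 20), rng.uniform(1e-4, 1e-2, 20)
        np.testing.assert_allclose(pp.dri(a, b) * pp.dri(b, a), 1.0)

    def test_sweep_windows_have_elevated_dri(self, sweep_scan):
        _, truth, df = sweep_scan
        chrom, lo, hi = truth.sweep_windows[0]
        inside = (df.chrom == chrom) & (df.end >= lo) & (df.start <= hi)
        assert df.loc[inside, "dri"].median() > df["dri"].median()


class TestXpclr:
    def test_neutral_grid_gives_zero_scores(self, sweep_scan):
        geno, truth, _ = sweep_scan
        ws = pp.make_windows({"1": 30_000_000})[:25]
        cfg = XPCLRConfig(sel_coeff_grid=(0.0,))
        scores = pp.xpclr_scan(geno, truth.groups, ws, cfg)
        assert np.nanmax(np.abs(scores)) == 0.0

    def test_scores_nonnegative(self, sweep_scan):
        _, _, df = sweep_scan
        assert (df["xpclr"].dropna() >= 0).all()

    def test_neutral_genome_scores_concentrated_near_zero(self, drift_panel):
        _, geno, truth = drift_panel
        lengths = {"1": 30_000_000, "2": 30_000_000}
        ws = pp.make_windows(lengths)
        scores = pp.xpclr_scan(geno, truth.groups, ws)
        scores = scores[np.isfinite(scores)]
        assert np.median(scores) < np.percentile(scores, 95) / 5

    def test_score_increases_with_sweep_strength(self):
        rhos = []
        for seed in range(5):
            strengths, sweep_scores = [], []
            for s in (0.2, 0.5, 0.8):
                cfg = pp.SimConfig(
                    seed=200 + seed, n_snps=2000, drift_F=0.05,
                    sweep_loci=[(1, 15_000_000, s)],
                )
                geno, truth = pp.simulate_genotypes(cfg)
                ws = pp.make_windows({"1": 30_000_000, "2": 30_000_000})
                scores = pp.xpclr_scan(geno, truth.groups, ws)
                chrom, lo, hi = truth.sweep_windows[0]
                in_sweep = [
                    k
                    for k, w in enumerate(ws)
                    if w.chrom == chrom and w.end >= lo and w.start <= hi
                ]
                strengths.append(s)
                sweep_scores.append(np.nanmax(scores[in_sweep]))
            rhos.append(sps.spearmanr(strengths, sweep_scores).statistic)
        assert np.mean(rhos) > 0.8

    def test_degenerate_drift_variance_rejected(self):
        with pytest.raises(ValueError):
            estimate_omega(np.array([0.5]), np.array([0.5]))


class TestCallSignificant:
    def test_exactly_five_percent_flagged(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(100).astype(float)
        flags, cut = pp.call_significant(vals)
        assert flags.sum() == 5
        assert vals[flags].min() > cut

    def test_constant_values_flag_nothing(self):
        flags, _ = pp.call_significant(np.ones(30))
        assert flags.sum() == 0

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            pp.call_significant(np.arange(10.0))

    def test_z_transform_centers_mean(self):
        vals = np.random.default_rng(2).normal(5, 2, size=50)
        z = pp.z_transform(vals)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert pp.z_transform(np.array([3.0, 5.0, 7.0]))[1] == 0.0


class TestScreenQtl:
    def make_stats(self):
        return pd.DataFrame(
            {
                "chrom": ["1"] * 3,
                "start": [1, 10_000_001, 20_000_001],
                "end": [1_000_000, 11_000_000, 21_000_000],
                "fst_sig": [True, False, False],
                "dri_sig": [False, False, False],
                "xpclr_sig": [False, False, True],
            }
        )

    def test_qtl_inside_flagged_window(self):
        out = pp.screen_qtl([("1", 500_000)], self.make_stats())
        assert out.loc[0, "fst_sig"] and out.loc[0, "any_sig"]

    def test_qtl_far_from_flags(self):
        out = pp.screen_qtl([("1", 10_500_000)], self.make_stats())
        assert not out.loc[0, "fst_sig"]  # flagged window > 5 Mb away
        assert not out.loc[0, "any_sig"]

    def test_recovery_fraction(self):
        stats_df = self.make_stats()
        qtl = [("1", 500_000), ("1", 20_500_000), ("1", 10_500_000), ("2", 1)]
        out = pp.screen_qtl(qtl, stats_df)
        assert out["any_sig"].mean() == pytest.approx(2 / 4)


def test_flags_computed_on_shared_tiling(sweep_scan):
    _, _, df = sweep_scan
    assert {"fst_sig", "dri_sig", "xpclr_sig"} <= set(df.columns)
    assert (df["n_snps"] > 0).all()
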