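import numpy as np
import pandas as pd
import pytest

import pollenpop as pp
from pollenpop.genotypes import MISSING


def pop_freqs(geno, truth):
    """Per-site allele frequencies for each simulated population."""
    out = {}
    for g in ("feral", "domesticated"):
        ids = [s for s in geno.individuals if truth.groups[s] == g]
        sub = geno.take_individuals(ids)
        out[g] = sub.allele_freq()
    return out


class TestSimulateGenotypes:
    def test_deterministic_given_seed(self):
        cfg = pp.SimConfig(seed=42, n_snps=300)
        g1, _ = pp.simulate_genotypes(cfg)
        g2, _ = pp.simulate_genotypes(cfg)
        assert np.array_equal(g1.calls, g2.calls)
        assert np.array_equal(g1.depths, g2.depths)
        assert np.array_equal(g1.pos, g2.pos)

    def test_no_drift_no_mean_frequency_difference(self):
        cfg = pp.SimConfig(seed=2, n_pop_a=100, n_pop_b=100, n_snps=2000, drift_F=0.0)
        geno, truth = pp.simulate_genotypes(cfg)
        f = pop_freqs(geno, truth)
        assert abs(np.nanmean(f["feral"] - f["domesticated"])) < 0.01

    def test_no_drift_frequencies_near_ancestral(self):
        # pooled frequency within 3 binomial SE of the drawn ancestral value
        cfg = pp.SimConfig(seed=9, n_pop_a=100, n_pop_b=100, n_snps=1000,
                           drift_F=0.0, missing_rate=0.0)
        geno, truth = pp.simulate_genotypes(cfg)
        p_hat = geno.allele_freq()
        p_anc = truth.ancestral_freq
        se = np.sqrt(p_anc * (1 - p_anc) / (2 * 200))
        frac_within = np.mean(np.abs(p_hat - p_anc) <= 3 * se)
        assert frac_within > 0.99

    def test_drift_calibration_matches_balding_nichols(self):
        cfg = pp.SimConfig(seed=1, n_pop_a=50, n_pop_b=50, n_snps=2000, drift_F=0.05)
        geno, truth = pp.simulate_genotypes(cfg)
        fst = pp.genomewide_fst(geno, truth.groups, ("feral", "domesticated"))
        assert 0.03 < fst < 0.07

    def test_sweep_differentiation_exceeds_background(self):
        cfg = pp.SimConfig(
            seed=4, n_snps=2000, drift_F=0.05,
            sweep_loci=[(1, 15_000_000, 0.8)],
        )
        geno, truth = pp.simulate_genotypes(cfg)
        f = pop_freqs(geno, truth)
        diff = np.abs(f["feral"] - f["domesticated"])
        chrom, lo, hi = truth.sweep_windows[0]
        inside = (geno.chrom.astype(str) == chrom) & (geno.pos >= lo) & (geno.pos <= hi)
        assert np.nanmean(diff[inside]) > np.nanmean(diff[~inside])

    def test_off_chromosome_sweep_rejected(self):
        with pytest.raises(ValueError, match="pos 99000000"):
            pp.SimConfig(sweep_loci=[(1, 99_000_000, 0.5)])

    def test_depth_and_missingness_honoured(self):
        cfg = pp.SimConfig(seed=6, n_snps=500, depth_mean=19.0, missing_rate=0.1)
        geno, _ = pp.simulate_genotypes(cfg)
        assert geno.depths.mean() == pytest.approx(19.0, rel=0.05)
        assert (geno.calls == MISSING).mean() == pytest.approx(0.1, abs=0.02)


class TestSimulatePhenotypes:
    def test_zero_heritability_decouples_genotype(self):
        cfg = pp.SimConfig(seed=5, n_pop_a=100, n_pop_b=100, n_snps=1000, h2=0.0)
        geno, _ = pp.simulate_genotypes(cfg)
        pheno, truth = pp.simulate_phenotypes(geno, cfg)
        assert truth.realized_h2 == 0.0
        grm = pp.compute_grm(geno).matrix
        y = pheno["trait"].to_numpy()
        y = (y - y.mean()) / y.std()
        # Haseman-Elston style regression of trait products on kinship
        iu = np.triu_indices_from(grm, k=1)
        slope = np.polyfit(grm[iu], np.outer(y, y)[iu], 1)[0]
        assert abs(slope) < 0.3

    def test_realized_heritability_matches_target(self):
        # oracle: variance decomposition from the known effects
        ratios = []
        for seed in range(10):
            cfg = pp.SimConfig(
                seed=seed, n_pop_a=200, n_pop_b=200, n_snps=2000, h2=0.8, n_qtl=200
            )
            geno, _ = pp.simulate_genotypes(cfg)
            pheno, truth = pp.simulate_phenotypes(geno, cfg)
            x = geno.dosage_matrix()
            idx = np.array(sorted(truth.causal_effects))
            beta = np.array([truth.causal_effects[j] for j in idx])
            g = x[:, idx] @ beta
            resid = pheno["trait"].to_numpy() - g
            ratios.append(np.var(g) / (np.var(g) + np.var(resid)))
        assert np.mean(ratios) == pytest.approx(0.8, abs=0.05)

    def test_no_shift_leaves_group_means_equal(self):
        cfg = pp.SimConfig(seed=8, n_snps=500, h2=0.0, group_shift_sd=0.0)
        geno, _ = pp.simulate_genotypes(cfg)
        pheno, truth = pp.simulate_phenotypes(geno, cfg)
        df = pheno.assign(group=[truth.groups[s] for s in pheno["individual_id"]])
        means = df.groupby("group")["trait"].mean()
        sem = df.groupby("group")["trait"].sem().max()
        assert abs(means.diff().iloc[-1]) < 4 * sem

    def test_group_shift_applied_to_domesticated(self):
        cfg = pp.SimConfig(seed=8, n_snps=500, h2=0.3, group_shift_sd=2.0)
        geno, _ = pp.simulate_genotypes(cfg)
        pheno, truth = pp.simulate_phenotypes(geno, cfg)
        df = pheno.assign(group=[truth.groups[s] for s in pheno["individual_id"]])
        means = df.groupby("group")["trait"].mean()
        assert means["domesticated"] - means["feral"] > df["trait"].std()

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            pp.SimConfig(h2=1.5)


class TestSimulateParticles:
    def test_no_contaminants_all_pass_gates(self):
        cfg = pp.SimConfig(seed=3, pollen_per_individual=200, contaminant_rates={})
        particles, truth = pp.simulate_mifc_particles(["a", "b"], cfg)
        assert (truth.particle_labels == "fertile").all()
        kept, _ = pp.apply_gates(particles)
        assert len(kept) == len(particles)

    def test_debris_fail_exactly_the_diameter_gate(self):
        cfg = pp.SimConfig(
            seed=3, pollen_per_individual=500, contaminant_rates={"debris": 0.1}
        )
        particles, truth = pp.simulate_mifc_particles(["a", "b"], cfg)
        d = particles["diameter"].to_numpy()
        out_of_range = (d < 20) | (d > 100)
        assert np.array_equal(out_of_range, truth.particle_labels == "debris")

    def test_pollen_length_span_matches_panel(self):
        cfg = pp.SimConfig(seed=12, pollen_per_individual=300, contaminant_rates={})
        inds = [f"i{k}" for k in range(20)]
        particles, _ = pp.simulate_mifc_particles(inds, cfg)
        medians = particles.groupby("individual_id")["pollen_length"].median()
        assert medians.min() == pytest.approx(39.0, abs=1.5)
        assert medians.max() == pytest.approx(57.0, abs=1.5)

    def test_contaminant_rates_must_sum_below_one(self):
        with pytest.raises(ValueError):
            pp.SimConfig(contaminant_rates={"debris": 0.6, "stacked": 0.5})


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path, drift_panel):
        _, geno, _ = drift_panel
        small = geno.take_sites(np.arange(50))
        path = tmp_path / "g.vcf"
        pp.write_vcf(small, path)
        back = pp.read_vcf(path)
        assert back.individuals == small.individuals
        assert np.array_equal(back.calls, small.calls)
        assert np.array_equal(back.depths, small.depths)
        assert np.array_equal(back.pos, small.pos)

    def test_missing_call_serialized_as_dot_slash_dot(self, tmp_path):
        from conftest import toy_genotable

        geno = toy_genotable([[0, -1], [2, 1]])
        path = tmp_path / "m.vcf"
        pp.write_vcf(geno, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body[1].split("\t")[9].startswith("./.")
        back = pp.read_vcf(path)
        assert back.calls[0, 1] == MISSING

    def test_empty_table_yields_valid_header_only_vcf(self, tmp_path):
        geno = pp.GenotypeTable(
            individuals=["s0"],
            chrom=np.array([], dtype=object),
            pos=np.array([], dtype=np.int64),
            ref=np.array([], dtype=object),
            alt=np.array([], dtype=object),
            calls=np.zeros((1, 0), dtype=np.int8),
            depths=np.zeros((1, 0), dtype=np.int32),
        )
        path = tmp_path / "empty.vcf"
        pp.write_vcf(geno, path)
        back = pp.read_vcf(path)
        assert back.n_sites == 0
        assert back.individuals == ["s0"]
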