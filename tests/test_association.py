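import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bimodalgene import (
    SampleMetadata,
    bonferroni_threshold,
    cis_snp_select,
    eqtl_scan,
    kappa_agreement,
    rank_inverse_normal,
    trait_mode_association,
)
from bimodalgene.datasets import ExpressionDataset, GenotypeDataset
from bimodalgene.exceptions import DataError, DegenerateDataError


class TestRankInverseNormal:
    def test_blom_formula_n3(self):
        out = rank_inverse_normal([10.0, 20.0, 30.0])
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected)
        assert out[1] == pytest.approx(0.0)
        assert abs(out[0]) == pytest.approx(0.8694, abs=5e-4)

    def test_monotone_and_centered(self):
        x = np.random.default_rng(0).normal(size=31)  # odd n, no ties
        y = rank_inverse_normal(x)
        assert np.all(np.diff(y[np.argsort(x)]) > 0)
        assert abs(y.mean()) < 1e-6

    def test_ties_share_rank(self):
        y = rank_inverse_normal([1.0, 1.0, 5.0, 9.0])
        assert y[0] == y[1]

    def test_degenerate(self):
        with pytest.raises(DegenerateDataError):
            rank_inverse_normal(np.ones(5))


class TestCisWindow:
    @pytest.fixture()
    def toy_geno(self):
        snps = pd.DataFrame(
            {"chrom": ["1", "1", "1", "1", "2"],
             "pos": [300_000, 500_001, 710_000, 910_000, 700_000]},
            index=pd.Index([f"s{i}" for i in range(5)], name="snp_id"),
        )
        geno = pd.DataFrame(np.zeros((5, 4)), index=snps.index,
                            columns=list("abcd"))
        genes = pd.DataFrame({"chrom": ["1"], "start": [700_001], "end": [710_000]},
                             index=pd.Index(["g1"], name="gene_id"))
        return GenotypeDataset(genotypes=geno, snps=snps, genes=genes)

    def test_inclusive_boundaries(self, toy_geno):
        # window [start - 200000, end + 200000] = [500001, 910000]
        hits = cis_snp_select(toy_geno.genes.loc["g1"], toy_geno)
        assert hits == ["s1", "s2", "s3"]  # s0 at 300000 and chr2 SNP excluded

    def test_one_bp_outside(self, toy_geno):
        toy_geno.snps.loc["s1", "pos"] = 500_000  # start - 200001
        hits = cis_snp_select(toy_geno.genes.loc["g1"], toy_geno)
        assert "s1" not in hits


def test_bonferroni_threshold():
    assert bonferroni_threshold(0.05, 100) == pytest.approx(5e-4)
    with pytest.raises(DataError):
        bonferroni_threshold(0.05, 0)


def _study(n, seed=0, sibs=False, mode_effect=4.0):
    """Expression driven by one SNP plus covariate noise; singleton sibships
    unless sibs=True."""
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n)]
    g = rng.integers(0, 3, n).astype(float)
    age = rng.uniform(20, 50, n)
    gender = rng.choice(["M", "F"], n)
    expr_vals = mode_effect * (g > 0) + rng.normal(0, 1, n)
    sib = ([f"f{i // 2}" for i in range(n)] if sibs
           else [f"f{i}" for i in range(n)])
    meta = SampleMetadata(table=pd.DataFrame(
        {"batch_group": "A", "gender": gender, "age": age,
         "sibship": sib, "heritage": rng.uniform(0.5, 1, n)},
        index=pd.Index(samples, name="sample_id")))
    expr = ExpressionDataset(values=pd.DataFrame(
        [expr_vals], index=pd.Index(["g1"], name="gene_id"), columns=samples))
    snps = pd.DataFrame({"chrom": ["1"], "pos": [1_050_000]},
                        index=pd.Index(["rs1"], name="snp_id"))
    geno = GenotypeDataset(
        genotypes=pd.DataFrame([g], index=snps.index, columns=samples),
        snps=snps,
        genes=pd.DataFrame({"chrom": ["1"], "start": [1_000_000],
                            "end": [1_020_000]},
                           index=pd.Index(["g1"], name="gene_id")))
    return expr, geno, meta, g


class TestEqtlScan:
    def test_perfect_mode_determining_snp(self):
        """A SNP that fully determines the expression mode: p < 1e-15."""
        expr, geno, meta, g = _study(149, seed=1, mode_effect=6.0)
        labels = {"g1": dict(zip(expr.sample_ids,
                                 np.where(g > 0, "high", "low")))}
        res = eqtl_scan(expr, geno, meta, mode_labels=labels)
        assert len(res) == 1
        assert res[0].p < 1e-15
        assert res[0].kappa == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        """Permuted genotypes give uniform p (Kolmogorov-Smirnov check).

        500 independent null tests (scaled down from 1,000 for runtime,
        KS threshold adjusted to the same test level)."""
        rng = np.random.default_rng(5)
        ps = []
        for i in range(10):
            expr, geno, meta, g = _study(120, seed=100 + i, mode_effect=0.0)
            for j in range(50):
                geno.genotypes.loc["rs1"] = rng.permutation(g)
                ps.append(eqtl_scan(expr, geno, meta)[0].p)
        stat = stats.kstest(ps, "uniform").statistic
        assert stat < 0.07  # 0.05 at n=1000 scales to ~0.07 at n=500

    def test_singleton_sibships_match_ols_oracle(self):
        """All-singleton sibships reduce exactly to least squares."""
        expr, geno, meta, g = _study(80, seed=3, mode_effect=1.0)
        res = eqtl_scan(expr, geno, meta)[0]
        # independent oracle: normal-equation OLS with the t reference
        y = rank_inverse_normal(expr.gene("g1"))
        t = meta.table
        gender_ind = (t["gender"] == "M").to_numpy(float)
        X = np.column_stack([np.ones(80), g, t["age"], gender_ind, t["heritage"]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = 80 - X.shape[1]
        sigma2 = resid @ resid / dof
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        p_oracle = 2 * stats.t.sf(abs(beta[1] / se), dof)
        assert res.effect == pytest.approx(beta[1], abs=1e-8)
        assert res.p == pytest.approx(p_oracle, abs=1e-8)

    def test_missing_genotypes_dropped_pairwise(self):
        expr, geno, meta, _ = _study(60, seed=4)
        geno.genotypes.iloc[0, :10] = np.nan
        res = eqtl_scan(expr, geno, meta)[0]
        assert res.n_used == 50


class TestKappa:
    def test_perfect_dominant_agreement(self):
        g = np.array([0, 0, 1, 2, 0, 1, 2, 0, 2, 1], dtype=float)
        labels = np.where(g > 0, "high", "low")
        assert kappa_agreement(labels, g) == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        # table [[45, 5], [5, 45]]: p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        labels = np.array(["low"] * 50 + ["high"] * 50)
        g = np.r_[np.zeros(45), np.ones(5), np.zeros(5), np.ones(45)]
        assert kappa_agreement(labels, g) == pytest.approx(0.8)

    def test_null_kappa_small(self):
        """Independent genotypes: |kappa| < 0.15 at n=150, and unbiased."""
        rng = np.random.default_rng(0)
        kappas = []
        for _ in range(20):
            labels = np.where(rng.random(150) < 0.5, "low", "high")
            g = rng.integers(0, 3, 150).astype(float)
            kappas.append(kappa_agreement(labels, g))
        assert np.max(np.abs(kappas)) < 0.15

    def test_single_mode_errors(self):
        with pytest.raises(DataError):
            kappa_agreement(["high"] * 10, np.zeros(10))


class TestTraitModeAssociation:
    @staticmethod
    def _meta(n, rng):
        samples = [f"s{i}" for i in range(n)]
        return SampleMetadata(table=pd.DataFrame(
            {"batch_group": "A",
             "gender": rng.choice(["M", "F"], n),
             "age": rng.uniform(20, 50, n),
             "sibship": [f"f{i // 3}" for i in range(n)],
             "heritage": 1.0},
            index=pd.Index(samples, name="sample_id")))

    def test_planted_effect_recovered(self):
        """A 1.78-unit mode effect on a %fat-like trait is recovered.

        20 seeds at n=223 (scaled down from 50 seeds); the mean estimate
        must land within 15% of the planted effect."""
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 223
            meta = self._meta(n, rng)
            mode = np.where(rng.random(n) < 0.4, "low", "high")
            t = meta.table
            trait = (31.8 + 1.78 * (mode == "high")
                     + 0.05 * (t["age"] - 30)
                     + (t["gender"] == "M") * 1.0
                     + rng.normal(0, 4.0, n))
            labels = pd.Series(mode, index=t.index)
            diff, p = trait_mode_association(trait, labels, meta)
            diffs.append(diff)
        assert np.mean(diffs) == pytest.approx(1.78, rel=0.15)

    def test_flipped_labels_negate_difference(self):
        rng = np.random.default_rng(9)
        n = 80
        meta = self._meta(n, rng)
        mode = np.where(rng.random(n) < 0.5, "low", "high")
        trait = pd.Series(rng.normal(30, 3, n) + (mode == "high"),
                          index=meta.table.index)
        labels = pd.Series(mode, index=meta.table.index)
        flipped = pd.Series(np.where(mode == "low", "high", "low"),
                            index=meta.table.index)
        d1, p1 = trait_mode_association(trait, labels, meta)
        d2, p2 = trait_mode_association(trait, flipped, meta)
        assert d2 == pytest.approx(-d1, abs=1e-8)
        assert p2 == pytest.approx(p1, abs=1e-8)

    def test_insufficient_mode_counts(self):
        rng = np.random.default_rng(10)
        meta = self._meta(30, rng)
        mode = pd.Series(["low"] * 5 + ["high"] * 25, index=meta.table.index)
        trait = pd.Series(rng.normal(size=30), index=meta.table.index)
        diff, p = trait_mode_association(trait, mode, meta)
        assert np.isnan(diff) and np.isnan(p)
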