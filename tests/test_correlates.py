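"""Windowed features, genotype LD, CO models, rank-sum enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gametemap import correlates, simcross
from gametemap.containers import GenomeLayout, GenotypeMatrix


@pytest.fixture(scope="module")
def feature_files(tmp_path_factory):
    """Synthetic FASTA/GFF3/BED with the generator's per-window truth."""
    lay = GenomeLayout.test_scale(2, 1_000_000)
    ls = simcross.RecombLandscape.piecewise(lay, n_segments=8, variation=0.8, seed=2)
    outdir = str(tmp_path_factory.mktemp("tracks"))
    out = simcross.simulate_feature_tracks(lay, ls, seed=2, outdir=outdir)
    return lay, out


class TestWindowFeatures:
    def test_counts_match_generator_truth(self, feature_files):
        lay, out = feature_files
        feats = correlates.window_features(
            out["paths"]["fasta"], out["paths"]["gff3"], out["paths"]["bed"],
            lay, window_bp=10_000,
        )
        truth = out["truth"]
        merged = feats.merge(
            truth, left_on=["chrom", "start"], right_on=["chrom", "start0"]
        )
        assert len(merged) == len(feats)
        assert (merged["gene_count"] == merged["n_genes"]).all()
        assert (merged["simple_count"] == merged["n_simple"]).all()
        assert (merged["gypsy_count"] == merged["n_gypsy"]).all()
        assert (merged["copia_count"] == merged["n_copia"]).all()
        # GC per window tracks the generator's target
        assert np.corrcoef(merged["gc"], merged["gc_target"])[0, 1] > 0.9

    def test_gc_of_simple_sequence(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">Chr01\n" + "ATGC" * 250 + "\n")
        lay = GenomeLayout(["Chr01"], [1000])
        genes = tmp_path / "g.gff3"
        genes.write_text("##gff-version 3\n")
        bed = tmp_path / "r.bed"
        bed.write_text("Chr01\t0\t10\tGypsy\n")
        feats = correlates.window_features(str(path), str(genes), str(bed), lay, window_bp=1000)
        assert feats["gc"].iloc[0] == pytest.approx(0.5)

    def test_midpoint_boundary_goes_to_right_window(self, feature_files, tmp_path):
        lay = GenomeLayout(["Chr01"], [2000])
        fasta = tmp_path / "g.fasta"
        fasta.write_text(">Chr01\n" + "A" * 2000 + "\n")
        gff = tmp_path / "g.gff3"
        # 1-based interval [901, 1100]: 0-based midpoint exactly 1000
        gff.write_text("##gff-version 3\nChr01\tx\tgene\t901\t1100\t.\t+\t.\tID=g1\n")
        bed = tmp_path / "r.bed"
        bed.write_text("Chr01\t0\t10\tsimple\n")
        feats = correlates.window_features(str(fasta), str(gff), str(bed), lay, window_bp=1000)
        assert feats["gene_count"].tolist() == [0, 1]

    def test_feature_totals_conserved(self, feature_files):
        lay, out = feature_files
        feats = correlates.window_features(
            out["paths"]["fasta"], out["paths"]["gff3"], out["paths"]["bed"],
            lay, window_bp=250_000,
        )
        assert feats["gene_count"].sum() == len(out["genes"])
        reps = out["repeats"]
        for cls, col in [("Gypsy", "gypsy_count"), ("Copia", "copia_count"), ("simple", "simple_count")]:
            assert feats[col].sum() == int((reps["name"] == cls).sum())


class TestGenoR2:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 1, 0, 2])
        assert correlates.geno_r2(a, a) == pytest.approx(1.0)

    def test_symmetry_and_allele_relabel_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)
        r = correlates.geno_r2(a, b)
        assert r == pytest.approx(correlates.geno_r2(b, a))
        assert r == pytest.approx(correlates.geno_r2(2 - a, b))

    def test_null_expectation_one_over_n_minus_one(self):
        rng = np.random.default_rng(1)
        n = 200
        vals = [
            correlates.geno_r2(rng.integers(0, 3, n), rng.integers(0, 3, n))
            for _ in range(600)
        ]
        assert np.mean(vals) == pytest.approx(1 / (n - 1), rel=0.25)

    def test_constant_vector_gives_nan(self):
        assert np.isnan(correlates.geno_r2(np.zeros(10), np.arange(10) % 3))

    def test_missing_codes_excluded(self):
        a = np.array([0, 1, 2, -1, -1])
        b = np.array([0, 1, 2, 0, 2])
        assert correlates.geno_r2(a, b) == pytest.approx(1.0)


class TestCoModels:
    def _data(self, rng, n=300, noise=0.0, betas=None):
        X = rng.normal(size=(n, 4))
        cols = ["gc", "gene_count", "copia_count", "gypsy_count"]
        if betas is None:
            betas = [-1.0, 2.0, -0.5, -0.8]
        y = X @ np.array(betas) + 10 + noise * rng.normal(size=n)
        df = pd.DataFrame(X, columns=cols)
        df["count"] = y
        return df

    def test_noise_free_linear_response_recovered_exactly(self):
        rng = np.random.default_rng(2)
        df = self._data(rng, noise=0.0)
        res = correlates.fit_co_models(df, model="model2", cv_repeats=2)
        assert res.r2 == pytest.approx(1.0)
        assert res.cv_r2 == pytest.approx(1.0, abs=1e-9)
        # standardised coefficients recover beta * sd(x)
        sds = df[["gc", "gene_count", "copia_count", "gypsy_count"]].std(ddof=0)
        expect = np.array([-1.0, 2.0, -0.5, -0.8]) * sds.to_numpy()
        got = res.coefficients[["gc", "gene_count", "copia_count", "gypsy_count"]].to_numpy()
        assert np.allclose(got, expect, atol=1e-8)
        assert res.coefficients["intercept"] == pytest.approx(df["count"].mean())

    def test_pure_noise_cv_r2_near_zero(self):
        rng = np.random.default_rng(3)
        df = self._data(rng, betas=[0, 0, 0, 0], noise=1.0)
        res = correlates.fit_co_models(df, model="model2", cv_repeats=5, seed=1)
        assert abs(res.cv_r2) < 0.05

    def test_backward_aic_drops_null_covariates(self):
        rng = np.random.default_rng(4)
        df = self._data(rng, betas=[0.0, 2.0, 0.0, 0.0], noise=0.5)
        res = correlates.fit_co_models(df, model="model2", backward_aic=True, cv_repeats=2)
        assert "gene_count" in res.coefficients.index

    def test_constant_covariate_dropped_with_record(self):
        rng = np.random.default_rng(5)
        df = self._data(rng, noise=0.5)
        df["gc"] = 1.0
        res = correlates.fit_co_models(df, model="model2", cv_repeats=2)
        assert res.dropped == ["gc"]


class TestWilcoxon:
    def test_textbook_exact_example(self):
        w, p = correlates.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_multisets(self):
        _, p = correlates.wilcoxon_rank_sum([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert p > 0.6

    def test_all_values_identical_gives_p_one(self):
        w, p = correlates.wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(6)
        x = rng.normal(10, 1, 50)
        y = rng.normal(0, 1, 50)
        _, p = correlates.wilcoxon_rank_sum(x, y)
        assert p < 1e-6

    def test_matches_full_enumeration_oracle(self):
        # exact enumeration of all C(n+m, n) rank assignments, n,m <= 10
        rng = np.random.default_rng(7)
        for nx, ny in [(3, 4), (5, 5), (4, 6)]:
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            w_obs, p_obs = correlates.wilcoxon_rank_sum(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            n = nx + ny
            u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
            lo = hi = 0
            total = 0
            for comb in itertools.combinations(range(n), nx):
                u = ranks[list(comb)].sum() - nx * (nx + 1) / 2
                lo += u <= u_obs
                hi += u >= u_obs
                total += 1
            expected = min(1.0, 2 * min(lo, hi) / total)
            assert p_obs == pytest.approx(expected, rel=1e-9)
            assert w_obs == pytest.approx(u_obs)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            correlates.wilcoxon_rank_sum([], [1.0])


class TestEnrichment:
    def test_null_classes_give_uniformish_p(self):
        rng = np.random.default_rng(8)
        ps = []
        for _ in range(200):
            feats = pd.DataFrame({"gc": rng.normal(size=40)})
            ps.append(correlates.feature_enrichment(feats, np.arange(15), np.arange(15, 40))["p"].iloc[0])
        # calibration: p-values uniform under the null
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_doubled_density_detected(self):
        rng = np.random.default_rng(9)
        base = rng.poisson(20.0, 3000)
        hot = rng.poisson(40.0, 67)
        feats = pd.DataFrame({"simple_count": np.concatenate([hot, base])})
        out = correlates.feature_enrichment(
            feats, np.arange(67), np.arange(67, 3067), feature_cols=["simple_count"]
        )
        assert out["p"].iloc[0] < 0.01

    def test_constant_feature_p_one(self):
        feats = pd.DataFrame({"gc": np.full(30, 0.4)})
        out = correlates.feature_enrichment(feats, np.arange(10), np.arange(10, 30))
        assert out["p"].iloc[0] == 1.0

    def test_overlapping_or_empty_classes_rejected(self):
        feats = pd.DataFrame({"gc": np.arange(10.0)})
        with pytest.raises(ValueError):
            correlates.feature_enrichment(feats, np.arange(5), np.arange(4, 10))
        with pytest.raises(ValueError):
            correlates.feature_enrichment(feats, np.arange(0), np.arange(5))


class TestWindowLd:
    def _panel(self, rng, n_samples=120, n_markers=200, length=1_000_000, decay_bp=20_000):
        # haplotype-copying panel: adjacent markers correlated with
        # distance-dependent persistence -> LD decays with distance
        pos = np.sort(rng.choice(np.arange(1, length), size=n_markers, replace=False))
        h = np.empty((2 * n_samples, n_markers), dtype=np.int8)
        h[:, 0] = rng.integers(0, 2, 2 * n_samples)
        for j in range(1, n_markers):
            keep = rng.uniform(size=2 * n_samples) < np.exp(-(pos[j] - pos[j - 1]) / decay_bp)
            h[:, j] = np.where(keep, h[:, j - 1], rng.integers(0, 2, 2 * n_samples))
        dosage = h[0::2] + h[1::2]
        markers = pd.DataFrame({"chrom": "Chr01", "pos": pos, "ref": "A", "alt": "C"})
        return GenotypeMatrix([f"s{i}" for i in range(n_samples)], markers, dosage)

    def test_mean_r2_decays_with_recombination_proxy(self):
        rng = np.random.default_rng(10)
        lay = GenomeLayout(["Chr01"], [1_000_000])
        fast = self._panel(rng, decay_bp=3_000)
        slow = self._panel(rng, decay_bp=50_000)
        ld_fast = correlates.window_mean_ld(fast, lay, window_bp=1_000_000)
        ld_slow = correlates.window_mean_ld(slow, lay, window_bp=1_000_000)
        assert ld_slow["mean_r2"].iloc[0] > ld_fast["mean_r2"].iloc[0] + 0.1

    def test_spearman_helper(self):
        rho, p = correlates.spearman_ld_vs_co(
            np.array([0.9, 0.7, 0.5, 0.3, 0.1]), np.array([1, 2, 3, 4, 5.0])
        )
        assert rho == pytest.approx(-1.0)
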