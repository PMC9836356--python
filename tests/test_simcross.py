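"""Simulator: determinism, distributional correctness, Mendelian structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gametemap import simcross
from gametemap.containers import GenomeLayout
from gametemap.evaluation import expected_mendelian_violation_rate
from gametemap.pedigree import mendelian_consistent_table


@pytest.fixture(scope="module")
def tiny_layout():
    return GenomeLayout.test_scale(2, 1_000_000)


class TestParentHaplotypes:
    def test_same_seed_is_bit_identical(self, tiny_layout):
        a = simcross.simulate_parent_haplotypes(tiny_layout, 200, seed=11)
        b = simcross.simulate_parent_haplotypes(tiny_layout, 200, seed=11)
        assert a.markers.equals(b.markers)
        for p in a.parents:
            assert np.array_equal(a.haplotypes[p], b.haplotypes[p])

    def test_positions_sorted_unique_and_two_marker_map(self, tiny_layout):
        sim = simcross.simulate_parent_haplotypes(tiny_layout, 2, seed=0)
        for chrom in tiny_layout.chrom_names:
            pos = sim.markers.loc[sim.markers["chrom"] == chrom, "pos"].to_numpy()
            assert len(pos) == 2 and pos[0] < pos[1] and pos[0] >= 1

    def test_het_fraction_at_maf_half(self, tiny_layout):
        # at p = 0.5 each parent is heterozygous with probability 2pq = 0.5
        sim = simcross.simulate_parent_haplotypes(
            tiny_layout, 2000, maf_range=(0.5, 0.5), seed=5
        )
        for p in sim.parents[:4]:
            frac = sim.het_mask(p).mean()
            assert frac == pytest.approx(0.5, abs=4 * np.sqrt(0.25 / 4000))

    @pytest.mark.parametrize("bad", [dict(n_markers_per_chrom=1), dict(maf_range=(0.0, 0.5)), dict(maf_range=(0.2, 0.6))])
    def test_invalid_arguments_raise(self, tiny_layout, bad):
        kwargs = dict(n_markers_per_chrom=10, maf_range=(0.1, 0.5), seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            simcross.simulate_parent_haplotypes(tiny_layout, **kwargs)


class TestMeiosis:
    def test_zero_intensity_returns_parental_haplotype(self, tiny_layout):
        parents = simcross.simulate_parent_haplotypes(tiny_layout, 100, seed=2)
        ls = simcross.RecombLandscape.uniform(
            tiny_layout, co_per_gamete=0.0, obligate_co=False, interference_mode="none"
        )
        g = simcross.simulate_meiosis(parents, "F1", ls, "female", 0)
        assert all(len(b) == 0 for b in g.breakpoints.values())
        for chrom, sl in parents.chrom_slices.items():
            h = g.start_hap[chrom]
            assert np.array_equal(g.alleles[sl], parents.haplotypes["F1"][h, sl])

    def test_poisson_mean_co_count(self, tiny_layout):
        ls = simcross.RecombLandscape.uniform(
            tiny_layout, co_per_gamete=1.2, male_multiplier=1.0, interference_mode="none"
        )
        rng = np.random.default_rng(0)
        n = 10_000
        counts = np.array([len(ls.sample_breakpoints("Chr01", "female", rng)) for _ in range(n)])
        se = np.sqrt(1.2 / n)
        assert counts.mean() == pytest.approx(1.2, abs=3 * se)

    def test_poisson_goodness_of_fit(self, tiny_layout):
        # per-chromosome counts match Poisson(Lambda) without interference
        ls = simcross.RecombLandscape.uniform(
            tiny_layout, co_per_gamete=1.2, male_multiplier=1.0, interference_mode="none"
        )
        rng = np.random.default_rng(1)
        counts = np.array([len(ls.sample_breakpoints("Chr02", "female", rng)) for _ in range(10_000)])
        kmax = counts.max()
        obs = np.bincount(counts, minlength=kmax + 1).astype(float)
        exp = stats.poisson.pmf(np.arange(kmax + 1), 1.2) * len(counts)
        # pool the tail so expected cells stay >= 5
        while exp[-1] < 5 and len(exp) > 2:
            exp[-2] += exp[-1]
            obs[-2] += obs[-1]
            exp, obs = exp[:-1], obs[:-1]
        exp *= obs.sum() / exp.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_hotspot_attracts_expected_co_fraction(self, tiny_layout):
        # multiplier 50 over 1% of the chromosome: 50*0.01/(50*0.01+0.99)
        L = tiny_layout.chrom_lengths_bp[0]
        hs = simcross.Hotspot("Chr01", int(0.40 * L), int(0.41 * L), 50.0)
        ls = simcross.RecombLandscape.uniform(
            tiny_layout, co_per_gamete=1.2, male_multiplier=1.0,
            hotspots=[hs], interference_mode="none",
        )
        rng = np.random.default_rng(2)
        inside = total = 0
        for _ in range(4000):
            bps = ls.sample_breakpoints("Chr01", "female", rng)
            total += len(bps)
            inside += int(((bps >= hs.start_bp) & (bps < hs.end_bp)).sum())
        expected = 50 * 0.01 / (50 * 0.01 + 0.99)
        assert inside / total == pytest.approx(expected, abs=0.03)

    def test_obligate_co_forces_at_least_one(self, tiny_layout):
        ls = simcross.RecombLandscape.uniform(
            tiny_layout, co_per_gamete=0.3, obligate_co=True, interference_mode="none"
        )
        rng = np.random.default_rng(3)
        for _ in range(200):
            assert len(ls.sample_breakpoints("Chr01", "female", rng)) >= 1

    def test_gamma_interference_underdisperses(self, tiny_layout):
        ls = simcross.RecombLandscape.uniform(
            tiny_layout, co_per_gamete=1.2, male_multiplier=1.0,
            interference_mode="gamma", interference_nu=5.0,
        )
        rng = np.random.default_rng(4)
        counts = np.array([len(ls.sample_breakpoints("Chr01", "female", rng)) for _ in range(5000)])
        assert counts.mean() == pytest.approx(1.2, abs=0.05)
        assert counts.var() < 0.8 * counts.mean()  # clearly sub-Poisson

    def test_breakpoints_strictly_increasing_within_bounds(self, tiny_layout):
        ls = simcross.RecombLandscape.uniform(tiny_layout, co_per_gamete=5.0)
        rng = np.random.default_rng(5)
        for _ in range(100):
            bps = ls.sample_breakpoints("Chr01", "female", rng)
            assert np.all(np.diff(bps) > 0)
            assert np.all((bps > 0) & (bps < tiny_layout.chrom_lengths_bp[0]))


class TestFactorialCross:
    def test_default_family_sizes_sum_to_829(self):
        sizes = simcross.default_family_sizes()
        assert sizes.shape == (7, 7)
        assert sizes.sum() == 829
        assert set(np.unique(sizes)) == {16, 17}

    def test_error_free_cross_is_mendelian_consistent(self, errorfree_sim):
        geno, ped = errorfree_sim["geno"], errorfree_sim["ped"]
        tab = mendelian_consistent_table()
        for r in ped.table.itertuples(index=False):
            o = geno.row(r.offspring)
            gm, gf = geno.row(r.mother), geno.row(r.father)
            assert tab[gm, gf, o].all()

    def test_error_rate_matches_detectable_violation_oracle(self, tiny_layout):
        parents = simcross.simulate_parent_haplotypes(tiny_layout, 500, seed=7)
        ls = simcross.RecombLandscape.uniform(tiny_layout)
        err = 0.01
        geno, ped, truth = simcross.simulate_factorial_cross(
            parents, ls, simcross.default_family_sizes(196),
            error_rate=err, missing_rate=0.0, seed=7,
        )
        tab = mendelian_consistent_table()
        n_calls = n_viol = 0
        exp_rates = []
        for r in ped.table.itertuples(index=False):
            o = geno.row(r.offspring)
            gm, gf = geno.row(r.mother), geno.row(r.father)
            n_calls += len(o)
            n_viol += int((~tab[gm, gf, o]).sum())
            gid = f"{r.offspring}:{r.mother}"
            true_m = truth.gametes[gid].alleles
            true_p = truth.gametes[f"{r.offspring}:{r.father}"].alleles
            exp_rates.append(
                expected_mendelian_violation_rate(gm, gf, (true_m + true_p).astype(np.int8), err)
            )
        expected = float(np.mean(exp_rates))
        se = np.sqrt(expected * (1 - expected) / n_calls)
        assert n_viol / n_calls == pytest.approx(expected, abs=4 * se)

    def test_same_seed_is_bit_identical(self, tiny_layout):
        parents = simcross.simulate_parent_haplotypes(tiny_layout, 100, seed=9)
        ls = simcross.RecombLandscape.uniform(tiny_layout)
        fam = simcross.default_family_sizes(49)
        g1, _, t1 = simcross.simulate_factorial_cross(parents, ls, fam, seed=9)
        g2, _, t2 = simcross.simulate_factorial_cross(parents, ls, fam, seed=9)
        assert np.array_equal(g1.dosage, g2.dosage)
        assert t1.breakpoint_table().equals(t2.breakpoint_table())

    def test_offspring_alleles_trace_to_parental_segments(self, errorfree_sim):
        # conservation: each gamete allele equals the active parental
        # haplotype implied by the recorded breakpoints, tiling the chromosome
        parents, truth = errorfree_sim["parents"], errorfree_sim["truth"]
        pos = parents.markers["pos"].to_numpy()
        for gid in list(truth.gametes)[:20]:
            g = truth.gametes[gid]
            hap = parents.haplotypes[g.parent]
            for chrom, sl in parents.chrom_slices.items():
                active = (g.start_hap[chrom] + np.searchsorted(g.breakpoints[chrom], pos[sl])) % 2
                expect = hap[:, sl][active, np.arange(sl.stop - sl.start)]
                assert np.array_equal(g.alleles[sl], expect)

    def test_negative_family_size_rejected(self, tiny_layout):
        parents = simcross.simulate_parent_haplotypes(tiny_layout, 10, seed=0)
        ls = simcross.RecombLandscape.uniform(tiny_layout)
        bad = simcross.default_family_sizes(49).copy()
        bad[0, 0] = -1
        with pytest.raises(ValueError):
            simcross.simulate_factorial_cross(parents, ls, bad, seed=0)


class TestFeatureTracks:
    def test_zero_coupling_decorrelates_features(self, tiny_layout):
        ls = simcross.RecombLandscape.piecewise(tiny_layout, n_segments=10, variation=0.8, seed=1)
        coup = simcross.FeatureCoupling(gene=0.0, simple=0.0, gypsy=0.0, copia=0.0, gc=0.0)
        out = simcross.simulate_feature_tracks(tiny_layout, ls, coup, seed=1)
        truth = out["truth"]
        rho = stats.spearmanr(truth["n_genes"], truth["co_intensity"]).statistic
        assert abs(rho) < 0.15

    def test_positive_gene_coupling_tracks_intensity(self, tiny_layout):
        ls = simcross.RecombLandscape.piecewise(tiny_layout, n_segments=10, variation=0.8, seed=1)
        coup = simcross.FeatureCoupling(gene=1.0, deterministic=True)
        out = simcross.simulate_feature_tracks(tiny_layout, ls, coup, seed=1)
        truth = out["truth"]
        rho = stats.spearmanr(truth["n_genes"], truth["co_intensity"]).statistic
        assert rho > 0.8

    def test_gc_gradient_is_monotone_in_windows(self, tiny_layout, tmp_path):
        ls = simcross.RecombLandscape.uniform(tiny_layout)
        coup = simcross.FeatureCoupling(gc_gradient=(0.30, 0.50))
        out = simcross.simulate_feature_tracks(
            tiny_layout, ls, coup, seed=2, outdir=str(tmp_path)
        )
        seq = out["sequences"]["Chr01"]
        window = 100_000
        gcs = []
        for s in range(0, len(seq) - window, window):
            w = seq[s : s + window]
            gcs.append((w.count("G") + w.count("C")) / len(w))
        assert all(b > a - 0.01 for a, b in zip(gcs, gcs[1:]))
        assert gcs[-1] - gcs[0] > 0.1
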