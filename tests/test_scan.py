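import itertools
import math

import numpy as np
import pytest
from scipy import stats as spstats

import statsmodels.api as sm

from riqtl import simulate as sim
from riqtl.panel import PanelError, TraitVector
from riqtl.scan import (
    LOD_PER_LRS,
    genome_scan,
    lod_from_lrs,
    lrs_from_lod,
    marker_lrs,
    permutation_thresholds,
)


def oracle_lrs(y, is_a):
    """Brute-force two-group Gaussian likelihood ratio.

    Fits the one-mean and two-mean models by explicit maximum likelihood
    (profile sigma) and returns twice the log-likelihood difference.
    Independent of the scan engine's RSS algebra.
    """
    y = np.asarray(y, dtype=float)
    mu0 = y.mean()
    s0 = math.sqrt(np.mean((y - mu0) ** 2))
    ll0 = spstats.norm.logpdf(y, mu0, s0).sum()
    fitted = np.where(is_a, y[is_a].mean(), y[~is_a].mean())
    s1 = math.sqrt(np.mean((y - fitted) ** 2))
    ll1 = spstats.norm.logpdf(y, fitted, s1).sum()
    return 2.0 * (ll1 - ll0)


class TestLodConversion:
    # published LRS/LOD pairs this conversion must reproduce at 2 dp
    PAIRS = [
        (32.52, 7.05),
        (24.21, 5.25),
        (20.19, 4.38),
        (15.08, 3.27),
        (14.10, 3.06),
        (15.11, 3.28),
        (14.52, 3.15),
        (10.45, 2.27),
    ]

    @pytest.mark.parametrize("lrs,lod", PAIRS)
    def test_published_pairs(self, lrs, lod):
        assert round(lod_from_lrs(lrs), 2) == lod

    def test_zero(self):
        assert lod_from_lrs(0.0) == 0.0
        assert lrs_from_lod(0.0) == 0.0

    def test_round_trip_machine_precision(self, rng):
        x = rng.uniform(0, 100, size=100)
        np.testing.assert_allclose(lrs_from_lod(lod_from_lrs(x)), x, rtol=1e-15)

    def test_constant_is_exactly_4_61(self):
        assert LOD_PER_LRS == 4.61

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lod_from_lrs(-1.0)
        with pytest.raises(ValueError):
            lrs_from_lod(-0.1)


class TestMarkerLRS:
    def test_constant_trait(self):
        stat = marker_lrs([5.0] * 6, ["A", "A", "A", "B", "B", "B"])
        assert stat.lrs == 0.0
        assert stat.additive == 0.0

    def test_noise_free_separation(self):
        y = [13.0, 13.0, 13.0, 7.0, 7.0, 7.0]
        stat = marker_lrs(y, ["A", "A", "A", "B", "B", "B"])
        assert stat.additive == pytest.approx(3.0)
        assert stat.separated
        # capped at n * ln(1/eps)
        assert stat.lrs == pytest.approx(6 * math.log(1e12))

    def test_one_class_skipped(self):
        stat = marker_lrs([1.0, 2.0, 3.0, 4.0], ["A", "A", "A", "A"])
        assert stat.lrs is None
        assert "class sizes" in stat.skip_reason

    def test_small_class_skipped(self):
        stat = marker_lrs([1.0, 2.0, 3.0, 4.0], ["A", "B", "B", "B"])
        assert stat.lrs is None

    def test_h_u_drop_strain(self):
        y = [1.0, 2.0, 3.0, 4.0, 5.0, 99.0]
        stat = marker_lrs(y, ["A", "A", "B", "B", "A", "H"])
        ref = marker_lrs(y[:5], ["A", "A", "B", "B", "A"])
        assert stat.n_used == 5
        assert stat.lrs == pytest.approx(ref.lrs)

    def test_oracle_random_26_strain(self, rng):
        for _ in range(1000):
            y = rng.normal(size=26)
            is_a = rng.random(26) < 0.5
            if is_a.sum() < 2 or (~is_a).sum() < 2:
                continue
            stat = marker_lrs(y, np.where(is_a, "A", "B"))
            assert stat.lrs == pytest.approx(oracle_lrs(y, is_a), rel=1e-9)

    def test_oracle_exhaustive_small_panels(self, rng):
        # every genotype assignment of 4..8 strains with two valid classes
        for n in range(4, 9):
            y = rng.normal(size=n)
            for bits in itertools.product([0, 1], repeat=n):
                is_a = np.array(bits, dtype=bool)
                if is_a.sum() < 2 or (~is_a).sum() < 2:
                    continue
                stat = marker_lrs(y, np.where(is_a, "A", "B"))
                assert stat.lrs == pytest.approx(
                    oracle_lrs(y, is_a), rel=1e-9, abs=1e-9
                )

    def test_anova_f_identity(self, rng):
        # LRS = n * ln(1 + F/(n-2)) with F from an OLS regression oracle
        for _ in range(50):
            n = 26
            y = rng.normal(size=n)
            is_a = np.concatenate([np.ones(13, bool), np.zeros(13, bool)])
            rng.shuffle(is_a)
            X = sm.add_constant(is_a.astype(float))
            f = sm.OLS(y, X).fit().fvalue
            stat = marker_lrs(y, np.where(is_a, "A", "B"))
            assert stat.lrs == pytest.approx(n * math.log(1 + f / (n - 2)), rel=1e-8)

    def test_affine_invariance(self, rng):
        y = rng.normal(size=10)
        g = np.where(rng.random(10) < 0.5, "A", "B")
        if (g == "A").sum() < 2 or (g == "B").sum() < 2:
            g[:2] = "A"
            g[2:4] = "B"
        base = marker_lrs(y, g)
        moved = marker_lrs(3.7 * y - 11.0, g)
        assert moved.lrs == pytest.approx(base.lrs, rel=1e-9)
        assert moved.additive == pytest.approx(3.7 * base.additive, rel=1e-9)

    def test_allele_flip_antisymmetry(self, rng):
        y = rng.normal(size=12)
        g = np.array(["A", "B"] * 6)
        base = marker_lrs(y, g)
        flipped = marker_lrs(y, np.where(g == "A", "B", "A"))
        assert flipped.lrs == pytest.approx(base.lrs, rel=1e-12)
        assert flipped.additive == pytest.approx(-base.additive, rel=1e-12)

    def test_weighted_equal_weights_match_unweighted(self, rng):
        y = rng.normal(size=10)
        g = np.array(["A"] * 5 + ["B"] * 5)
        base = marker_lrs(y, g)
        weighted = marker_lrs(y, g, weights=np.full(10, 2.5))
        assert weighted.lrs == pytest.approx(base.lrs, rel=1e-12)


class TestGenomeScan:
    def test_planted_qtl_noise_free(self):
        cfg = sim.axbxa_like_config(
            seed=3,
            qtl=sim.QTLSpec("5", 40.0, 3.0),
            strain_sd=0.0,
            mouse_sd=0.0,
            trait_baseline=10.0,
        )
        panel = sim.simulate_ri_genotypes(cfg)
        table, truth = sim.simulate_trait(panel, cfg)
        result = genome_scan(panel, table.vector("trait"))
        assert truth.qtl_marker in set(result.peak_markers["marker"])

    def test_allele_flip_flips_scan(self, axbxa_panel, qtl_config):
        table, _ = sim.simulate_trait(axbxa_panel, qtl_config)
        vec = table.vector("trait")
        a = genome_scan(axbxa_panel, vec)
        b = genome_scan(axbxa_panel.flip_alleles(), vec)
        np.testing.assert_allclose(
            a.table["lrs"].to_numpy(float), b.table["lrs"].to_numpy(float),
            rtol=1e-9,
        )
        np.testing.assert_allclose(
            a.table["additive"].to_numpy(float),
            -b.table["additive"].to_numpy(float),
            rtol=1e-9,
        )

    def test_determinism(self, axbxa_panel, qtl_config):
        table, _ = sim.simulate_trait(axbxa_panel, qtl_config)
        vec = table.vector("trait")
        a = genome_scan(axbxa_panel, vec)
        b = genome_scan(axbxa_panel, vec)
        assert a.peak_lrs == b.peak_lrs
        assert list(a.peak_markers["marker"]) == list(b.peak_markers["marker"])

    def test_interval_flanks_peak(self, axbxa_panel, qtl_config):
        table, truth = sim.simulate_trait(axbxa_panel, qtl_config)
        result = genome_scan(axbxa_panel, table.vector("trait"))
        lo, hi = result.interval_Mb
        peaks_mb = result.peak_markers["position_Mb"]
        assert lo <= peaks_mb.min() and peaks_mb.max() <= hi

    def test_batch_path_matches_per_marker_path(self, axbxa_panel, qtl_config):
        # the vectorised engine used for permutations must agree with the
        # per-marker scan on the observed trait
        from riqtl.scan import _batch_max_lrs

        table, _ = sim.simulate_trait(axbxa_panel, qtl_config)
        vec = table.vector("trait").align_to(axbxa_panel)
        result = genome_scan(axbxa_panel, vec)
        batch_max = _batch_max_lrs(
            axbxa_panel.genotype_numeric(), vec.values[None, :]
        )[0]
        assert batch_max == pytest.approx(result.peak_lrs, rel=1e-10)

    def test_disjoint_strains_rejected(self, axbxa_panel):
        vec = TraitVector(["Z1", "Z2", "Z3"], [1.0, 2.0, 3.0])
        with pytest.raises(PanelError):
            genome_scan(axbxa_panel, vec)


@pytest.fixture(scope="module")
def scan_inputs(axbxa_panel):
    cfg = sim.axbxa_like_config(
        seed=7, qtl=sim.QTLSpec("5", 40.0, 2.0), strain_sd=1.0
    )
    table, _ = sim.simulate_trait(axbxa_panel, cfg)
    return axbxa_panel, table.vector("trait")


class TestPermutationThresholds:

    def test_bound_case_p(self, scan_inputs):
        panel, vec = scan_inputs
        null = permutation_thresholds(panel, vec, 1000, seed=1)
        huge = null.max_lrs.max() + 1.0
        assert null.genomewide_p(huge) == pytest.approx(1 / 1001)

    def test_threshold_order(self, scan_inputs):
        panel, vec = scan_inputs
        null = permutation_thresholds(panel, vec, 1000, seed=1)
        assert null.significant >= null.suggestive

    def test_seed_stability(self, scan_inputs):
        panel, vec = scan_inputs
        a = permutation_thresholds(panel, vec, 1000, seed=1).significant
        b = permutation_thresholds(panel, vec, 1000, seed=2).significant
        assert abs(a - b) / a < 0.10

    def test_reproducible(self, scan_inputs):
        panel, vec = scan_inputs
        a = permutation_thresholds(panel, vec, 200, seed=9)
        b = permutation_thresholds(panel, vec, 200, seed=9)
        np.testing.assert_array_equal(a.max_lrs, b.max_lrs)

    def test_too_few_rejected(self, scan_inputs):
        panel, vec = scan_inputs
        with pytest.raises(ValueError):
            permutation_thresholds(panel, vec, 5, seed=1)

    def test_under_100_warns(self, scan_inputs):
        panel, vec = scan_inputs
        with pytest.warns(UserWarning):
            permutation_thresholds(panel, vec, 50, seed=1)
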