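"""Coalescent simulator: prior draws, derived quantities, closed-form and
distributional validation (Watterson's E[S], pi = theta, msprime oracle)."""

import io
import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from arowana.simulate import (
    MODEL_IDS,
    DatasetShape,
    HaplotypeDataset,
    PriorConfig,
    ScenarioParams,
    draw_priors,
    read_ms_text,
    simulate_batch,
    simulate_dataset,
    write_ms_text,
)
from arowana.simulate import derived_quantities


class TestDrawPriors:
    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_samples_inside_ranges(self, priors, model_id):
        params = draw_priors(priors, model_id, rng_seed=5)
        assert priors.ne_range[0] <= params.ne <= priors.ne_range[1]
        assert priors.g_range[0] <= params.g <= priors.g_range[1]
        if model_id == 1:
            assert params.dt == 0.0 and params.ct == 0.0
        else:
            assert priors.dt_range[0] <= params.dt <= priors.dt_range[1]
        if model_id in (3, 4):
            assert priors.founder_ratio_range[0] <= params.founder_ratio <= priors.founder_ratio_range[1]
            assert priors.growth_ratio_range[0] <= params.growth_ratio <= priors.growth_ratio_range[1]
        else:
            assert params.founder_ratio is None and params.growth_ratio is None

    def test_derived_formulas(self, priors):
        # DT/(4*Ne*G) on published point values, and theta = 4*Ne*mu*G
        _, ct = derived_quantities(priors, ne=468_195, dt=1_049_955, g=1.0)
        assert ct == pytest.approx(0.56064, abs=2e-5)
        theta, _ = derived_quantities(priors, ne=100_000, dt=0.0, g=2.0)
        assert theta == pytest.approx(1.0e-3)
        # literal per-year reading drops the G factor
        theta_y, _ = derived_quantities(
            PriorConfig(theta_per_year=True), ne=100_000, dt=0.0, g=2.0)
        assert theta_y == pytest.approx(5.0e-4)

    def test_zero_dt_gives_zero_ct(self, priors):
        _, ct = derived_quantities(priors, ne=12_345, dt=0.0, g=1.3)
        assert ct == 0.0

    def test_deterministic_per_seed(self, priors):
        a = draw_priors(priors, 3, rng_seed=99)
        b = draw_priors(priors, 3, rng_seed=99)
        assert a == b

    def test_unknown_model_rejected(self, priors):
        with pytest.raises(ValueError, match="model_id"):
            draw_priors(priors, 5, rng_seed=0)


class TestScenarioParams:
    def test_ratios_required_for_colonization(self):
        with pytest.raises(ValueError, match="founder_ratio"):
            ScenarioParams(model_id=3, ne=1e5, dt=1e5, g=1, theta=1e-3, ct=0.25)

    def test_ratios_rejected_for_panmixia(self):
        with pytest.raises(ValueError):
            ScenarioParams(model_id=1, ne=1e5, dt=0, g=1, theta=1e-3, ct=0.0,
                           founder_ratio=0.05, growth_ratio=0.5)


class TestSimulateDataset:
    def test_minimal_sample_every_site_polymorphic(self, panmictic_params):
        shape = DatasetShape(1, 1, n_sites=5)  # smallest shape: 4 haploids
        ds = simulate_dataset(panmictic_params, shape, rng_seed=0)
        assert ds.matrix.shape == (4, 5)
        counts = ds.matrix.sum(axis=0)
        assert np.all((counts >= 1) & (counts <= 3))

    @pytest.mark.parametrize("unlinked", [True, False])
    def test_fixed_s_columns_all_polymorphic(self, colonization_params, unlinked):
        shape = DatasetShape(4, 2, n_sites=80)
        ds = simulate_dataset(colonization_params, shape, rng_seed=3, unlinked=unlinked)
        assert ds.matrix.shape == (12, 80)
        counts = ds.matrix.sum(axis=0)
        assert np.all((counts > 0) & (counts < 12))
        assert np.all(np.diff(ds.positions) >= 0)

    def test_deterministic_per_seed(self, colonization_params, small_shape):
        a = simulate_dataset(colonization_params, small_shape, rng_seed=7)
        b = simulate_dataset(colonization_params, small_shape, rng_seed=7)
        np.testing.assert_array_equal(a.matrix, b.matrix)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_watterson_expected_segregating_sites(self, panmictic_params):
        """Fixed-theta mode: E[S] = theta * sum_{i<n} 1/i within 1% over 1e4
        panmictic replicates of 26 haploids at per-locus theta 10."""
        shape = DatasetShape(7, 6, n_sites=1)
        rng = np.random.default_rng(11)
        s = [
            simulate_dataset(panmictic_params, shape, rng,
                             mode="fixed_theta", locus_theta=10.0).n_sites
            for _ in range(10_000)
        ]
        expected = 10.0 * sum(1.0 / i for i in range(1, 26))
        assert np.mean(s) == pytest.approx(expected, rel=0.01)

    def test_pi_matches_theta(self, panmictic_params):
        """Mean pairwise diversity per locus ~ theta under panmixia."""
        shape = DatasetShape(7, 6, n_sites=1)
        rng = np.random.default_rng(12)
        pis = [
            simulate_dataset(panmictic_params, shape, rng,
                             mode="fixed_theta", locus_theta=10.0).nucleotide_diversity()
            for _ in range(4_000)
        ]
        se = np.std(pis) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - 10.0) < 3 * se + 0.05

    def test_vicariance_at_zero_ct_is_panmixia(self, priors):
        """Model 2 with ct=0 is distributionally indistinguishable from
        model 1 at matched theta (KS on S and pi over linked replicates)."""
        p1 = ScenarioParams(1, 1e5, 0, 1, theta=5e-4, ct=0.0)
        p2 = ScenarioParams(2, 1e5, 0, 1, theta=5e-4, ct=0.0)
        shape = DatasetShape(4, 2, n_sites=1)
        rng = np.random.default_rng(13)
        def sample(p):
            out = []
            for _ in range(2000):
                ds = simulate_dataset(p, shape, rng, mode="fixed_theta", locus_theta=6.0)
                out.append((ds.n_sites, ds.nucleotide_diversity()))
            return np.asarray(out)
        a, b = sample(p1), sample(p2)
        assert ks_2samp(a[:, 0], b[:, 0]).pvalue > 0.01
        assert ks_2samp(a[:, 1], b[:, 1]).pvalue > 0.01

    def test_founder_bottleneck_strips_diversity(self, colonization_params):
        """Within-deme diversity of the founded deme (TAb, deme 1 in model
        3) is lower than the source deme's on average."""
        shape = DatasetShape(4, 4, n_sites=40)
        rng = np.random.default_rng(14)
        pi1, pi2 = [], []
        for _ in range(1000):
            ds = simulate_dataset(colonization_params, shape, rng)
            for deme, acc in ((0, pi1), (1, pi2)):
                m = ds.matrix[ds.deme_labels == deme]
                p = m.mean(axis=0)
                acc.append(np.sum(2 * p * (1 - p)))
        assert np.mean(pi1) < 0.8 * np.mean(pi2)

    def test_models_3_and_4_are_mirror_images(self, priors):
        """Swapping deme labels maps model 3 onto model 4 (equal-size demes
        so the summary distributions must coincide)."""
        common = dict(ne=1e5, dt=2e5, g=1.0, theta=5e-4, ct=0.4,
                      founder_ratio=0.05, growth_ratio=0.5)
        p3 = ScenarioParams(model_id=3, **common)
        p4 = ScenarioParams(model_id=4, **common)
        shape = DatasetShape(3, 3, n_sites=50)
        rng = np.random.default_rng(15)
        def deme_pis(p, swap):
            out = []
            for _ in range(800):
                ds = simulate_dataset(p, shape, rng)
                if swap:
                    ds = ds.swap_demes()
                m0 = ds.matrix[ds.deme_labels == 0]
                m1 = ds.matrix[ds.deme_labels == 1]
                q0, q1 = m0.mean(axis=0), m1.mean(axis=0)
                out.append((np.sum(2 * q0 * (1 - q0)), np.sum(2 * q1 * (1 - q1))))
            return np.asarray(out)
        a = deme_pis(p3, swap=False)
        b = deme_pis(p4, swap=True)
        assert ks_2samp(a[:, 0], b[:, 0]).pvalue > 0.01
        assert ks_2samp(a[:, 1], b[:, 1]).pvalue > 0.01

    def test_single_haploid_total_rejected(self, panmictic_params):
        with pytest.raises(ValueError):
            DatasetShape(0, 1, 5)

    def test_unlinked_matches_linked_single_site_stacking(self, colonization_params):
        """One unlinked dataset of S sites must be distributed like S
        stacked linked datasets simulated with one site each (the slow
        independent oracle for the jit kernel)."""
        shape = DatasetShape(4, 2, n_sites=200)
        rng = np.random.default_rng(16)
        fast = simulate_dataset(colonization_params, shape, rng, unlinked=True)
        one = DatasetShape(4, 2, n_sites=1)
        slow_cols = np.hstack([
            simulate_dataset(colonization_params, one, rng, unlinked=False).matrix
            for _ in range(200)
        ])
        # compare derived-allele-count spectra of the two site collections
        fast_counts = fast.matrix.sum(axis=0)
        slow_counts = slow_cols.sum(axis=0)
        assert ks_2samp(fast_counts, slow_counts).pvalue > 0.01


class TestAgainstMsprime:
    def test_model3_distributions_match_msprime(self):
        """Two-sample KS on S and within-deme pi against an independent
        coalescent implementation, matched parameters, 2000 replicates."""
        msprime = pytest.importorskip("msprime")
        ct, fr, gr, n_ref = 0.4, 0.05, 0.5, 10_000
        params = ScenarioParams(3, 1e5, 0, 1, theta=1.0, ct=ct,
                                founder_ratio=fr, growth_ratio=gr)
        shape = DatasetShape(11, 2, n_sites=1)
        rng = np.random.default_rng(17)
        mine = []
        for _ in range(2000):
            ds = simulate_dataset(params, shape, rng, mode="fixed_theta",
                                  locus_theta=8.0)
            m1 = ds.matrix[ds.deme_labels == 0]
            m2 = ds.matrix[ds.deme_labels == 1]
            q1, q2 = m1.mean(axis=0), m2.mean(axis=0)
            mine.append((
                ds.n_sites,
                np.sum(2 * q1 * (1 - q1)) * 22 / 21,
                np.sum(2 * q2 * (1 - q2)) * 4 / 3,
            ))
        mine = np.asarray(mine)

        dem = msprime.Demography()
        ct_gen = ct * 4 * n_ref
        dem.add_population(name="TAb", initial_size=gr * n_ref,
                           growth_rate=np.log(gr / fr) / ct_gen)
        dem.add_population(name="AMb", initial_size=n_ref)
        dem.add_population(name="ANC", initial_size=n_ref)
        dem.add_population_split(time=ct_gen, derived=["TAb", "AMb"], ancestral="ANC")
        theirs = []
        reps = msprime.sim_ancestry(samples={"TAb": 11, "AMb": 2}, demography=dem,
                                    ploidy=2, num_replicates=2000, random_seed=18)
        for ts in reps:
            mts = msprime.sim_mutations(ts, rate=8.0 / (4 * n_ref),
                                        model=msprime.BinaryMutationModel(),
                                        discrete_genome=False)
            g = mts.genotype_matrix().T
            seg = (g.sum(axis=0) > 0) & (g.sum(axis=0) < g.shape[0])
            g = g[:, seg]
            q1, q2 = g[:22].mean(axis=0), g[22:].mean(axis=0)
            theirs.append((
                g.shape[1],
                np.sum(2 * q1 * (1 - q1)) * 22 / 21,
                np.sum(2 * q2 * (1 - q2)) * 4 / 3,
            ))
        theirs = np.asarray(theirs)
        for j in range(3):
            assert ks_2samp(mine[:, j], theirs[:, j]).pvalue > 0.01


class TestSimulateBatch:
    def test_counts_and_labels(self, priors):
        shape = DatasetShape(2, 2, n_sites=10)
        out = list(simulate_batch(priors, shape, 10, {1, 2, 3, 4}, rng_seed=1))
        assert len(out) == 40
        labels = [lab for _, lab in out]
        assert all(labels.count(m) == 10 for m in MODEL_IDS)

    def test_reproducible(self, priors, small_shape):
        a = [ds.matrix for ds, _ in simulate_batch(priors, small_shape, 3, {2, 3}, 8)]
        b = [ds.matrix for ds, _ in simulate_batch(priors, small_shape, 3, {2, 3}, 8)]
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma, mb)

    def test_empty_model_set_rejected(self, priors, small_shape):
        with pytest.raises(ValueError, match="empty"):
            next(simulate_batch(priors, small_shape, 1, set(), 0))


class TestMsText:
    def test_round_trip(self, colonization_params, small_shape):
        ds = simulate_dataset(colonization_params, small_shape, rng_seed=4)
        buf = io.StringIO()
        write_ms_text(ds, buf)
        buf.seek(0)
        back, = read_ms_text(buf, deme_labels=ds.deme_labels)
        np.testing.assert_array_equal(back.matrix, ds.matrix)
        np.testing.assert_allclose(back.positions, ds.positions, atol=1e-6)

    def test_block_format(self):
        ds = HaplotypeDataset(np.array([[0, 1], [1, 0]]), np.array([0, 0]),
                              np.array([0.25, 0.75]))
        buf = io.StringIO()
        write_ms_text(ds, buf)
        lines = buf.getvalue().splitlines()
        assert lines[0] == "//"
        assert lines[1] == "segsites: 2"
        assert lines[2].startswith("positions: ")
        assert lines[3:5] == ["01", "10"]

    def test_empty_dataset_rejected(self):
        ds = HaplotypeDataset(np.empty((2, 0), dtype=np.int8), np.array([0, 0]),
                              np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            write_ms_text(ds, io.StringIO())
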