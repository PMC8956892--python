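import numpy as np
import pytest

from conftest import ds_from_alleles, toy_panel
from ystrkit import (
    PPY23,
    AlleleCall,
    Haplotype,
    SimulationConfig,
    amova,
    classical_mds,
    haplotype_distance,
    pairwise_rst,
    simulate_population,
)
from ystrkit.distance import DistanceMatrix


def brute_force_amova(groups, panel, **dist_kw):
    """Independent AMOVA oracle: explicit double loops over the
    squared-distance definitions of the SSD components."""
    samples = [(gi, h) for gi, g in enumerate(groups) for h in g.haplotypes]
    n = len(samples)
    sizes = [g.n for g in groups]
    k = len(groups)
    ssd_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ssd_total += haplotype_distance(samples[i][1], samples[j][1], panel, **dist_kw)
    ssd_total /= n
    ssd_within = 0.0
    for gi, g in enumerate(groups):
        acc = 0.0
        for i in range(g.n):
            for j in range(i + 1, g.n):
                acc += haplotype_distance(g.haplotypes[i], g.haplotypes[j], panel, **dist_kw)
        ssd_within += acc / g.n
    ssd_among = ssd_total - ssd_within
    df_among, df_within = k - 1, n - k
    s2w = ssd_within / df_within
    nbar = (n - sum(s * s for s in sizes) / n) / df_among
    s2a = (ssd_among / df_among - s2w) / nbar
    phi = s2a / (s2a + s2w) if (s2a + s2w) > 0 else 0.0
    return ssd_among, ssd_within, s2a, s2w, phi


class TestHaplotypeDistance:
    def test_identical_is_zero(self, small_population):
        ds, _ = small_population
        h = ds.haplotypes[0]
        assert haplotype_distance(h, h, ds.panel) == 0.0

    def test_single_repeat_difference(self):
        panel = toy_panel(2)
        a = ds_from_alleles([(10, 14)], panel=panel).haplotypes[0]
        b = ds_from_alleles([(10, 15)], panel=panel).haplotypes[0]
        assert haplotype_distance(a, b, panel) == 1.0

    def test_dys385_unordered_pairing(self):
        panel = toy_panel(1, multi=True)
        a = ds_from_alleles([((13, 17),)], panel=panel).haplotypes[0]
        b = ds_from_alleles([((17, 13),)], panel=panel).haplotypes[0]
        assert haplotype_distance(a, b, panel, include_dys385=True) == 0.0

    def test_dys385_min_over_pairings(self):
        panel = toy_panel(1, multi=True)
        a = ds_from_alleles([((13, 17),)], panel=panel).haplotypes[0]
        b = ds_from_alleles([((14, 16),)], panel=panel).haplotypes[0]
        # pairings: (13-14)^2+(17-16)^2 = 2 vs (13-16)^2+(17-14)^2 = 18
        assert haplotype_distance(a, b, panel, include_dys385=True) == 2.0

    def test_dys385_excluded_by_default(self):
        panel = toy_panel(2, multi=True)
        a = ds_from_alleles([(10, (13, 17))], panel=panel).haplotypes[0]
        b = ds_from_alleles([(12, (20, 25))], panel=panel).haplotypes[0]
        assert haplotype_distance(a, b, panel) == 4.0

    def test_micro_variant_weight(self):
        panel = toy_panel(1)
        a = ds_from_alleles([10], panel=panel).haplotypes[0]
        b = Haplotype("x", {"L1": AlleleCall(10, 1)})
        assert haplotype_distance(a, b, panel) == pytest.approx(0.01)

    def test_dys389_subtraction_option(self):
        calls_a = {"DYS389I": AlleleCall(13), "DYS389II": AlleleCall(30)}
        calls_b = {"DYS389I": AlleleCall(14), "DYS389II": AlleleCall(30)}
        panel = [p for p in [PPY23]][0]
        from ystrkit.panels import LocusPanel

        mini = LocusPanel("d389", ("DYS389I", "DYS389II"))
        a, b = Haplotype("a", calls_a), Haplotype("b", calls_b)
        assert haplotype_distance(a, b, mini) == 1.0  # as typed: only DYS389I differs
        # subtracted: DYS389II-DYS389I is 17 vs 16 -> adds another unit
        assert haplotype_distance(a, b, mini, dys389_subtract=True) == 2.0


class TestAmova:
    def test_identical_populations(self):
        rows = [10, 10, 11, 12]
        a = ds_from_alleles(rows, name="a")
        b = ds_from_alleles(rows, name="b", panel=a.panel)
        res = amova([a, b], n_perm=99, seed=0)
        assert res.phi_st <= 0.0 + 1e-12
        assert res.p_value > 0.5

    def test_fixed_populations_one_repeat_apart(self):
        a = ds_from_alleles([10, 10, 10], name="a")
        b = ds_from_alleles([11, 11, 11], name="b", panel=a.panel)
        res = amova([a, b], n_perm=99, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.sigma2_w == 0.0

    def test_matches_brute_force_on_random_small_instances(self):
        rng = np.random.default_rng(123)
        panel = toy_panel(2)
        for _ in range(50):
            n1, n2 = rng.integers(2, 5, size=2)
            rows = [tuple(rng.integers(8, 14, size=2)) for _ in range(n1 + n2)]
            a = ds_from_alleles(rows[:n1], name="a", panel=panel)
            b = ds_from_alleles(rows[n1:], name="b", panel=panel)
            res = amova([a, b], n_perm=1, seed=0)
            ssd_a, ssd_w, s2a, s2w, phi = brute_force_amova([a, b], panel)
            assert res.ssd_among == pytest.approx(ssd_a, abs=1e-9)
            assert res.ssd_within == pytest.approx(ssd_w, abs=1e-9)
            assert res.sigma2_a == pytest.approx(s2a, abs=1e-9)
            assert res.sigma2_w == pytest.approx(s2w, abs=1e-9)
            assert res.phi_st == pytest.approx(phi, abs=1e-9)

    def test_ssd_additivity_and_dfs(self, small_population):
        ds, _ = small_population
        half = ds.n // 2
        import dataclasses

        a = dataclasses.replace(ds, name="a", haplotypes=ds.haplotypes[:half])
        b = dataclasses.replace(ds, name="b", haplotypes=ds.haplotypes[half:])
        res = amova([a, b], n_perm=19, seed=3)
        assert res.ssd_total == pytest.approx(res.ssd_among + res.ssd_within)
        assert res.df_among == 1
        assert res.df_within == ds.n - 2

    def test_rejects_degenerate_inputs(self):
        a = ds_from_alleles([10, 11], name="a")
        b = ds_from_alleles([10], name="b", panel=a.panel)
        with pytest.raises(ValueError):
            amova([a], n_perm=10, seed=0)
        with pytest.raises(ValueError):
            amova([a, b], n_perm=10, seed=0)
        c = ds_from_alleles([10, 11], name="c", panel=a.panel)
        with pytest.raises(ValueError):
            amova([a, c], n_perm=0, seed=0)

    def test_seed_recorded_and_deterministic(self):
        a = ds_from_alleles([10, 11, 12], name="a")
        b = ds_from_alleles([12, 13, 14], name="b", panel=a.panel)
        r1 = amova([a, b], n_perm=200, seed=77)
        r2 = amova([a, b], n_perm=200, seed=77)
        assert r1 == r2
        assert r1.seed == 77


class TestPairwiseRst:
    def test_symmetric_zero_diagonal(self):
        pops = []
        panel = toy_panel(1)
        rng = np.random.default_rng(5)
        for name in "abc":
            rows = [int(x) for x in rng.integers(8, 15, size=6)]
            pops.append(ds_from_alleles(rows, name=name, panel=panel))
        dm = pairwise_rst(pops, n_perm=19, seed=0)
        assert np.allclose(dm.rst, dm.rst.T)
        assert np.all(np.diag(dm.rst) == 0)
        assert np.all((dm.p_values >= 0) & (dm.p_values <= 1))

    def test_duplicated_population_near_zero(self):
        # the estimator has a small negative bias for an exact duplicate,
        # vanishing with sample size
        import dataclasses

        cfg = SimulationConfig(n_samples=50, partial_profile_count=0, seed=6)
        ds, _ = simulate_population(cfg)
        a = dataclasses.replace(ds, name="a")
        b = dataclasses.replace(ds, name="b")
        dm = pairwise_rst([a, b], n_perm=19, seed=0)
        assert abs(dm.rst[0, 1]) < 0.05

    def test_negative_rst_retained_but_clamped_for_mds(self):
        a = ds_from_alleles([10, 11, 10, 11], name="a")
        b = ds_from_alleles([11, 10, 11, 10], name="b", panel=a.panel)
        dm = pairwise_rst([a, b], n_perm=19, seed=0)
        assert dm.rst[0, 1] < 0  # balanced mixing gives a negative estimate
        assert dm.clamped()[0, 1] == 0.0


class TestClassicalMds:
    def test_collinear_points_exact_1d(self):
        d = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = classical_mds(d, dims=1)
        x = res.coordinates[:, 0]
        rec = np.abs(x[:, None] - x[None, :])
        assert np.allclose(rec, d, atol=1e-9)

    def test_planar_points_recovered_up_to_rigid_motion(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(4, 2)) * 3
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = classical_mds(d, dims=2)
        c = res.coordinates
        rec = np.sqrt(((c[:, None, :] - c[None, :, :]) ** 2).sum(-1))
        assert np.allclose(rec, d, atol=1e-9)

    def test_duplicate_population_coincident(self):
        d = np.array(
            [[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]]
        )
        res = classical_mds(d, dims=2)
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_requests_beyond_positive_spectrum_flagged(self, caplog):
        d = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])  # rank-1 configuration
        with caplog.at_level("WARNING", logger="ystrkit.distance"):
            res = classical_mds(d, dims=3)
        assert res.coordinates.shape[1] < 3
        assert any("positive eigenvalue" in r.message for r in caplog.records)

    def test_accepts_distance_matrix_object(self):
        dm = DistanceMatrix(
            labels=("a", "b"),
            rst=np.array([[0.0, 0.2], [0.2, 0.0]]),
            p_values=np.ones((2, 2)),
        )
        res = classical_mds(dm, dims=1)
        assert res.labels == ("a", "b")
        assert abs(abs(res.coordinates[0, 0] - res.coordinates[1, 0]) - 0.2) < 1e-9

    def test_rejects_asymmetric_input(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))
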