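import numpy as np
import pytest
import scipy.stats

import levyforage as lf
from levyforage._kernels import walk_kernel
from levyforage.movement import (
    DIRECTION_ANGLES,
    draws_from_table,
    walk_reference,
)


class TestTruncatedPowerLawPmf:
    def test_uniform_limit_at_u_zero(self):
        pmf = lf.truncated_power_law_pmf(0.0, 1, 500)
        assert np.allclose(pmf, 1 / 500)

    def test_u2_small_support_normalizer(self):
        # normalizer 1 + 1/4 + 1/9 + 1/16 + 1/25
        pmf = lf.truncated_power_law_pmf(2.0, 1, 5)
        assert pmf[0] == pytest.approx(1 / (1 + 1 / 4 + 1 / 9 + 1 / 16 + 1 / 25))
        assert pmf[0] == pytest.approx(0.68324, abs=1e-5)

    @pytest.mark.parametrize("u", [-1.5, 0.0, 0.7, 2.0, 3.0, 6.0])
    def test_normalization_and_support(self, u):
        pmf = lf.truncated_power_law_pmf(u, 1, 500)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(pmf) == 500 and np.all(pmf > 0)

    def test_negative_exponent_mass_increases_with_length(self):
        pmf = lf.truncated_power_law_pmf(-1.0, 1, 100)
        assert np.all(np.diff(pmf) > 0)

    def test_invalid_support(self):
        with pytest.raises(ValueError, match="support"):
            lf.truncated_power_law_pmf(2.0, 5, 3)


class TestMoveTable:
    def test_entries_truncated_to_half_environment(self, rng):
        for u in (-1.0, 0.0, 2.0, 5.0):
            S = lf.build_move_table(u, 1000, rng=rng)
            assert len(S) == 10_000
            assert S.min() >= 1 and S.max() <= 500

    def test_brownian_exponent_mostly_unit_moves(self, rng):
        S = lf.build_move_table(5.0, 1000, rng=rng)
        expected = lf.truncated_power_law_pmf(5.0, 1, 500)[0]  # ~0.964
        assert expected == pytest.approx(0.964, abs=0.001)
        assert np.mean(S == 1) == pytest.approx(expected, abs=0.01)

    def test_levy_exponent_table_matches_pmf(self):
        # chi-square GOF of 1e4 draws at u = 2 against the exact pmf
        from statutil import chisquare_binned

        S = lf.build_move_table(2.0, 1000, rng=np.random.default_rng(5))
        pmf = lf.truncated_power_law_pmf(2.0, 1, 500)
        observed = np.bincount(S, minlength=501)[1:].astype(float)
        stat = chisquare_binned(observed, pmf * len(S))
        assert stat.pvalue > 0.01

    def test_reproducible_under_seed(self):
        a = lf.build_move_table(2.0, 100, rng=np.random.default_rng(9))
        b = lf.build_move_table(2.0, 100, rng=np.random.default_rng(9))
        assert np.array_equal(a, b)


def test_sample_direction_uniform_over_four_axes():
    rng = np.random.default_rng(2)
    draws = [lf.sample_direction(rng) for _ in range(100_000)]
    freqs = [np.mean([d == a for d in draws]) for a in DIRECTION_ANGLES]
    assert all(abs(f - 0.25) < 0.01 for f in freqs)
    again = np.random.default_rng(2)
    assert [lf.sample_direction(again) for _ in range(10)] == draws[:10]


class TestLifespanWalk:
    def test_scripted_walk_hand_trace(self):
        # 5x5 torus, one resource at (0,2), every move length 4 heading +j,
        # start (0,0), s=1, lam=4: the resource truncates the first move
        # after 2 cells
        grid = np.zeros((5, 5), dtype=np.int64)
        grid[0, 2] = 1
        (xi, axi, d, ad), e_log, d_log = walk_reference(
            grid, 5, 4, 1, (0, 0), iter([(4, 0)] * 5)
        )
        assert (xi, axi, d, ad) == (1, 3, 4, 10)
        assert e_log == [0, 0, 1, 0, 0]
        assert d_log == [0, 1, 1, 1, 1]

    def test_empty_environment_counters(self, rng):
        lam = 1000
        env = lf.make_uniform_environment(50, 0, rng)
        dist = lf.MoveLengthDistribution.build(2.0, 50, rng=rng)
        rec = lf.run_lifespan(lf.DigitalOrganism(dist=dist, lam=lam, s=1), env, rng)
        assert rec.xi == 0 and rec.alpha_xi == 0
        assert rec.d == lam
        assert rec.alpha_d == lam * (lam + 1) // 2

    def test_kernel_matches_python_reference_exactly(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            n = int(rng.integers(4, 25))
            lam = int(rng.integers(1, 400))
            s = int(rng.integers(1, 9))
            grid = np.zeros((n, n), dtype=np.int64)
            for _ in range(int(rng.integers(0, 8))):
                grid[rng.integers(0, n), rng.integers(0, n)] += 1
            S = rng.integers(1, max(2, n // 2) + 1, size=64).astype(np.int64)
            start = (int(rng.integers(0, n)), int(rng.integers(0, n)))
            seed = int(rng.integers(1, 2**63))
            e_log = np.zeros(lam + 1, dtype=np.int64)
            d_log = np.zeros(lam + 1, dtype=np.int64)
            out = walk_kernel(grid, n, S, lam, s, start[0], start[1],
                              np.uint64(seed), e_log, d_log, True)
            ref, e_ref, d_ref = walk_reference(grid, n, lam, s, start,
                                               draws_from_table(S, seed))
            assert tuple(int(x) for x in out[:4]) == ref
            assert e_log.tolist() == e_ref and d_log.tolist() == d_ref

    def test_event_sum_identity_for_alpha_xi(self, rng):
        # alpha_xi computed per timestep equals the event-based form
        # sum over encounters of e * (lam - t_event + 1); likewise alpha_d
        env = lf.make_uniform_environment(30, 60, rng)
        dist = lf.MoveLengthDistribution.build(1.5, 30, rng=rng)
        lam = 500
        rec, (e_log, d_log) = lf.run_lifespan(
            lf.DigitalOrganism(dist=dist, lam=lam, s=2), env, rng, record_trace=True
        )
        events = [(t, e_log[t]) for t in range(lam + 1) if e_log[t] > 0]
        assert rec.alpha_xi == sum(e * (lam - t + 1) for t, e in events)
        assert rec.xi == e_log.sum() and rec.d == d_log.sum()

    @pytest.mark.parametrize("s", [1, 2, 8])
    def test_distance_budget(self, s, rng):
        env = lf.make_uniform_environment(40, 10, rng)
        dist = lf.MoveLengthDistribution.build(1.0, 40, rng=rng)
        lam = 300
        rec = lf.run_lifespan(lf.DigitalOrganism(dist=dist, lam=lam, s=s), env, rng)
        assert lam <= rec.d <= s * lam
        if s == 1:
            assert rec.d == lam

    def test_counter_inequalities(self, rng):
        env = lf.make_uniform_environment(30, 40, rng)
        dist = lf.MoveLengthDistribution.build(2.0, 30, rng=rng)
        rec = lf.run_lifespan(lf.DigitalOrganism(dist=dist, lam=200, s=3), env, rng)
        assert rec.alpha_xi <= rec.lam * rec.xi
        assert rec.alpha_d <= rec.lam * rec.d

    def test_removing_resources_never_decreases_distance(self):
        # identical seed and start: truncation can only shorten moves
        rng = np.random.default_rng(17)
        n, lam = 20, 400
        grid = np.zeros((n, n), dtype=np.int64)
        for _ in range(15):
            grid[rng.integers(0, n), rng.integers(0, n)] += 1
        S = rng.integers(1, 11, size=64).astype(np.int64)
        dummy = np.zeros(1, dtype=np.int64)
        for seed in range(1, 20):
            for s in (1, 3):
                with_res = walk_kernel(grid, n, S, lam, s, 0, 0,
                                       np.uint64(seed), dummy, dummy, False)
                without = walk_kernel(np.zeros_like(grid), n, S, lam, s, 0, 0,
                                      np.uint64(seed), dummy, dummy, False)
                assert without[2] >= with_res[2]

    def test_brownian_mean_encounters_near_100(self, brownian_ensemble):
        # u = 5, lam = 1M, density 1e-4: encounters average ~ lam * density
        mean_xi = np.mean([r.xi for r in brownian_ensemble])
        assert mean_xi == pytest.approx(100, abs=15)

    def test_errors(self, rng):
        env = lf.make_uniform_environment(10, 0, rng)
        dist = lf.MoveLengthDistribution.build(2.0, 10, rng=rng)
        empty = lf.MoveLengthDistribution(2.0, 1, 5, np.array([1.0]),
                                          np.array([], dtype=np.int64))
        with pytest.raises(ValueError, match="empty move-length table"):
            lf.run_lifespan(lf.DigitalOrganism(dist=empty, lam=5), env, rng)
        with pytest.raises(ValueError, match="t must be 0"):
            lf.run_lifespan(lf.DigitalOrganism(dist=dist, lam=5, t=3), env, rng)
        with pytest.raises(ValueError, match="lifespan"):
            lf.run_lifespan(lf.DigitalOrganism(dist=dist, lam=0), env, rng)
        with pytest.raises(ValueError, match="speed"):
            lf.run_lifespan(lf.DigitalOrganism(dist=dist, lam=5, s=0), env, rng)
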