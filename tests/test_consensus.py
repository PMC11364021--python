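"""Maximum-likelihood consensus: alignment, binning, combination, checks."""

import numpy as np
import pytest

import saxsbench as sb
from saxsbench.consensus_ml import (AlignmentResult, BinningSpec, align_pair,
                                    apply_alignment, combine_ml,
                                    empirical_error_check, normalize_forward,
                                    run_consensus, truncate_qmin)


def _profile(q, I, sigma, mode="batch", label=""):
    return sb.SASProfile(q=np.asarray(q, float), I=np.asarray(I, float),
                         sigma=np.asarray(sigma, float), mode=mode,
                         label=label)


class TestTruncate:
    def test_identity_below_range(self, gaussian_profile):
        assert truncate_qmin(gaussian_profile, 0.0) is gaussian_profile

    def test_cut_applies_and_is_recorded(self, gaussian_profile):
        out = truncate_qmin(gaussian_profile, 0.08)
        assert out.q[0] >= 0.08
        assert out.meta["q_min_truncated"] == "0.08"

    def test_beyond_range_raises(self, gaussian_profile):
        with pytest.raises(ValueError):
            truncate_qmin(gaussian_profile, 2.0)


class TestAlignPair:
    def test_identity(self, gaussian_profile):
        res = align_pair(gaussian_profile, gaussian_profile)
        assert res.a == pytest.approx(1.0)
        assert res.b == pytest.approx(0.0, abs=1e-12)
        assert res.chi2 == pytest.approx(0.0, abs=1e-18)

    def test_exact_linear_map(self, gaussian_profile):
        target = gaussian_profile.copy(I=2.0 * gaussian_profile.I + 0.5)
        res = align_pair(gaussian_profile, target)
        assert res.a == pytest.approx(2.0, rel=1e-10)
        assert res.b == pytest.approx(0.5, rel=1e-10)
        # and apply_alignment inverts the map
        back = apply_alignment(target, res.a, res.b)
        np.testing.assert_allclose(back.I, gaussian_profile.I, rtol=1e-10)

    def test_matches_grid_search_oracle(self):
        """5-point toy with unequal sigma vs brute-force (a, b) scan."""
        ref = _profile([1, 2, 3, 4, 5], [1.0, 2.0, 2.5, 3.5, 5.0],
                       [1] * 5)
        tgt = _profile([1, 2, 3, 4, 5], [2.2, 4.9, 5.6, 8.1, 10.5],
                       [0.1, 0.2, 0.5, 0.3, 0.8])
        res = align_pair(ref, tgt)
        a_grid = np.linspace(1.5, 2.5, 2001)
        b_grid = np.linspace(-0.5, 1.0, 1501)
        w = 1.0 / tgt.sigma ** 2
        chi = ((tgt.I[None, None, :] - a_grid[:, None, None]
                * ref.I[None, None, :] - b_grid[None, :, None]) ** 2
               * w).sum(axis=2)
        ia, ib = np.unravel_index(chi.argmin(), chi.shape)
        assert res.a == pytest.approx(a_grid[ia], abs=1e-3)
        assert res.b == pytest.approx(b_grid[ib], abs=1e-3)

    def test_insufficient_overlap_raises(self):
        ref = _profile([0.01, 0.02, 0.03], [1, 2, 3], [0.1] * 3)
        tgt = _profile([0.5, 0.6, 0.7], [1, 2, 3], [0.1] * 3)
        with pytest.raises(ValueError):
            align_pair(ref, tgt)

    def test_negative_scale_rejected(self, gaussian_profile):
        with pytest.raises(ValueError):
            apply_alignment(gaussian_profile, -1.0, 0.0)


class TestCombine:
    def test_single_input_identity(self, gaussian_profile):
        spec = BinningSpec(mode="linear", n_bins=800)
        out = combine_ml([gaussian_profile], spec)
        np.testing.assert_allclose(out.q, gaussian_profile.q)
        np.testing.assert_allclose(out.I, gaussian_profile.I)
        np.testing.assert_allclose(out.sigma, gaussian_profile.sigma)

    def test_two_points_one_bin_hand_values(self):
        """I = {1, 3} with sigma = {1, 0.5} -> I = 2.6, sigma = 5^-1/2."""
        p1 = _profile([0.10, 0.9], [1.0, 1.0], [1.0, 1.0])
        p2 = _profile([0.12, 0.9], [3.0, 1.0], [0.5, 1.0])
        out = combine_ml([p1, p2], BinningSpec(mode="linear", n_bins=2,
                                               q_lo=0.05, q_hi=1.0))
        assert out.I[0] == pytest.approx(2.6)
        assert out.sigma[0] == pytest.approx(5 ** -0.5)

    def test_equal_sigma_q_weighted_mean(self):
        p1 = _profile([0.10, 0.9], [1.0, 1.0], [1.0, 1.0])
        p2 = _profile([0.12, 0.9], [1.0, 1.0], [1.0, 1.0])
        out = combine_ml([p1, p2], BinningSpec(mode="linear", n_bins=2,
                                               q_lo=0.05, q_hi=1.0))
        assert out.q[0] == pytest.approx(0.11)

    def test_sigma_never_inflated_and_q_within_bins(self, gaussian_profile):
        rng = np.random.default_rng(5)
        spec = sb.ReplicaSpec(truth=gaussian_profile, K=6,
                              scales=rng.uniform(0.5, 2, 6), seed=2)
        reps = sb.make_replicas(spec)
        aligned = [apply_alignment(p, align_pair(reps[0], p).a,
                                   align_pair(reps[0], p).b) for p in reps]
        binning = BinningSpec(mode="log", n_bins=150)
        out, edges, idx, occupied = combine_ml(aligned, binning,
                                               return_assignment=True)
        sig = np.concatenate([p.sigma for p in aligned])
        for j, qj in zip(np.flatnonzero(occupied), out.q):
            assert edges[j] <= qj < edges[j + 1] or qj == edges[-1]
        min_sig = np.full(edges.size - 1, np.inf)
        np.minimum.at(min_sig, idx, sig)
        assert np.all(out.sigma <= min_sig[occupied] + 1e-15)

    def test_disjoint_ranges_raise(self):
        p1 = _profile([0.01, 0.02], [1, 1], [0.1, 0.1])
        p2 = _profile([0.5, 0.6], [1, 1], [0.1, 0.1])
        with pytest.raises(ValueError):
            combine_ml([p1, p2], BinningSpec(mode="linear", n_bins=2,
                                             q_lo=0.1, q_hi=0.2))


class TestNormalize:
    def test_first5_and_floor(self):
        q = np.linspace(0.01, 0.1, 10)
        intensity = np.full(10, 10.0)
        intensity[-1] = 0.1
        p = _profile(q, intensity, np.full(10, 0.2))
        out = normalize_forward(p)
        # divide by 10 (first-five mean), then shift 0.01 -> 0.001
        assert out.I.min() == pytest.approx(0.001)
        assert out.I[:5].mean() == pytest.approx(0.991, rel=1e-12)
        np.testing.assert_allclose(out.sigma, p.sigma / 10.0)

    def test_guinier_method_divides_by_i0(self, gaussian_profile):
        out = normalize_forward(gaussian_profile, method="guinier", floor=0.0)
        shift = out.meta["norm_shift"]
        assert float(out.meta["norm_scale"]) == pytest.approx(5.0, rel=1e-5)
        assert float(shift) <= 0 or np.isclose(float(shift), 0, atol=1e-12)


class TestRunConsensus:
    def test_identical_copies_reproduce_profile(self, gaussian_profile):
        reps = [gaussian_profile.copy() for _ in range(4)]
        res = run_consensus(reps, BinningSpec(mode="linear", n_bins=800))
        assert res.converged
        # consensus is an affine transform of the input with the fixed-point
        # normalization (first-five mean 1, min at the floor)
        assert res.profile.I[:5].mean() == pytest.approx(1.0, abs=1e-5)
        assert res.profile.I.min() == pytest.approx(0.001, abs=1e-6)
        for diag in res.per_input:
            assert diag.chi2 == pytest.approx(0.0, abs=1e-9)
        # same shape: correlate against the input
        y = np.interp(res.profile.q, gaussian_profile.q, gaussian_profile.I)
        a = np.polyfit(y, res.profile.I, 1)
        np.testing.assert_allclose(res.profile.I, a[0] * y + a[1],
                                   atol=1e-10)

    def test_replica_recovery_monte_carlo(self, gaussian_profile):
        """K = 10 noisy replicas: consensus within its errors of the truth,
        per-input reduced chi2 near 1."""
        rng = np.random.default_rng(42)
        spec = sb.ReplicaSpec(truth=gaussian_profile, K=10,
                              scales=rng.uniform(0.5, 2.0, 10),
                              offsets=rng.normal(0, 0.02, 10) * 5.0,
                              rel_sigma=0.01, seed=7)
        reps = sb.make_replicas(spec)
        res = run_consensus(reps, BinningSpec(mode="log", n_bins=450))
        assert res.converged
        cons = res.profile
        ytruth = np.interp(cons.q, gaussian_profile.q, gaussian_profile.I)
        model = sb.SASProfile(q=cons.q, I=ytruth,
                              sigma=np.zeros_like(cons.q), mode="model")
        scale, const, _ = sb.scale_const_fit(model, cons)
        z = (cons.I - scale * ytruth - const) / cons.sigma
        assert np.mean(np.abs(z) < 4.0) >= 0.999
        m = np.mean([d.alignment.M for d in res.per_input])
        assert abs(res.mean_chi2 - 1.0) < 3.0 * np.sqrt(2.0 / m)

    def test_scale_offset_equivariance(self, gaussian_profile):
        rng = np.random.default_rng(1)
        spec = sb.ReplicaSpec(truth=gaussian_profile, K=5,
                              scales=rng.uniform(0.8, 1.2, 5), seed=3)
        reps = sb.make_replicas(spec)
        res1 = run_consensus(reps, BinningSpec(mode="log", n_bins=300))
        mod = [reps[0].copy(I=3.7 * reps[0].I + 0.9,
                            sigma=3.7 * reps[0].sigma)] + reps[1:]
        res2 = run_consensus(mod, BinningSpec(mode="log", n_bins=300))
        np.testing.assert_allclose(res2.profile.I, res1.profile.I,
                                   atol=1e-8)

    def test_reference_independence(self, gaussian_profile):
        rng = np.random.default_rng(9)
        spec = sb.ReplicaSpec(truth=gaussian_profile, K=6,
                              scales=rng.uniform(0.5, 2.0, 6), seed=11)
        reps = sb.make_replicas(spec)
        res1 = run_consensus(reps, BinningSpec(mode="log", n_bins=300))
        res2 = run_consensus(reps[::-1], BinningSpec(mode="log", n_bins=300))
        rel = np.abs(res2.profile.I - res1.profile.I) / np.abs(res1.profile.I)
        assert rel.max() < 1e-6

    def test_fewer_than_two_usable_inputs_raises(self, gaussian_profile):
        with pytest.raises(ValueError):
            run_consensus([gaussian_profile])


class TestEmpiricalErrorCheck:
    def test_identical_inputs_zero(self, gaussian_profile):
        ratio = empirical_error_check([gaussian_profile.copy()
                                       for _ in range(4)])
        assert np.all(ratio == 0)

    def test_calibrated_replicas_near_one(self, gaussian_profile):
        means = []
        for seed in range(40):
            spec = sb.ReplicaSpec(truth=gaussian_profile, K=8, seed=seed)
            ratio = empirical_error_check(sb.make_replicas(spec))
            means.append(ratio.mean())
        # E[ratio] ~ c4(K) < 1 (SD bias); allow the standard-error band
        assert np.mean(means) == pytest.approx(0.97, abs=0.03)

    def test_understated_sigma_detected(self, gaussian_profile):
        means = []
        for seed in range(20):
            spec = sb.ReplicaSpec(truth=gaussian_profile, K=8, seed=seed)
            reps = [p.copy(sigma=p.sigma / 2.0) for p in sb.make_replicas(spec)]
            means.append(empirical_error_check(reps).mean())
        assert np.mean(means) == pytest.approx(1.94, abs=0.12)

    def test_fewer_than_three_raises(self, gaussian_profile):
        with pytest.raises(ValueError):
            empirical_error_check([gaussian_profile, gaussian_profile])
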