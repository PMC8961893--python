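"""LD decay: r², distance binning, the 1/ln(x) model fit, and pruning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lcpopgen import (
    GenotypePanel,
    bin_ld_by_distance,
    fit_decay,
    pairwise_r2,
    prune,
    solve_crossing,
)
from lcpopgen.lddecay import LDProfile

BIN_MIDPOINTS = 500 * (np.arange(1, 41) - 0.5)


def profile_from_curve(y, se=None, n_pairs=None):
    return LDProfile(
        bin_midpoints=BIN_MIDPOINTS,
        mean_r2=np.asarray(y, dtype=float),
        se_r2=np.zeros(40) if se is None else se,
        n_pairs=np.full(40, 100) if n_pairs is None else n_pairs,
    )


def panel_from_positions(positions, calls, chroms=None):
    calls = np.asarray(calls, dtype=np.int8)
    n_v = len(positions)
    return GenotypePanel(
        sample_ids=[f"S{i}" for i in range(calls.shape[0])],
        variants=pd.DataFrame(
            {
                "chrom": ["c1"] * n_v if chroms is None else chroms,
                "pos": positions,
                "ref": ["A"] * n_v,
                "alt": ["T"] * n_v,
            }
        ),
        calls=calls,
        dp=np.full_like(calls, 30, dtype=np.int32),
        gq=np.full_like(calls, 99, dtype=np.int32),
        pl=np.zeros(calls.shape + (3,), dtype=np.int32),
    )


class TestPairwiseR2:
    def test_identical_vectors(self):
        assert pairwise_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert pairwise_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        a = np.array([0, 1, 2, 2, 0], dtype=float)
        b = np.array([0, 1, 1, 2, 0], dtype=float)
        r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert pairwise_r2(a, b) == pytest.approx(r**2)

    def test_constant_vector_undefined(self):
        assert np.isnan(pairwise_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    def test_missing_restricts_to_complete_pairs(self):
        a = [0, 1, 2, -1, 0, 2]
        b = [-1, 1, 2, 1, 0, 2]
        expected = pairwise_r2([1, 2, 0, 2], [1, 2, 0, 2])
        assert pairwise_r2(a, b) == pytest.approx(expected)


class TestBinning:
    def test_bin_assignment(self, rng):
        calls = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        panel = panel_from_positions([1000, 1750], calls)
        profile = bin_ld_by_distance(panel)
        assert profile.n_pairs[1] == 1  # 750 bp -> bin 2 (501-1000]
        assert profile.n_pairs.sum() == 1

    def test_boundary_distance_in_lower_bin(self, rng):
        calls = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        panel = panel_from_positions([1, 501], calls)
        profile = bin_ld_by_distance(panel)
        assert profile.n_pairs[0] == 1  # 500 bp is in bin 1 under (lo, hi]

    def test_pair_beyond_20kb_excluded(self, rng):
        calls = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        panel = panel_from_positions([1, 20_002], calls)
        profile = bin_ld_by_distance(panel)
        assert profile.n_pairs.sum() == 0

    def test_cross_scaffold_pairs_excluded(self, rng):
        calls = rng.integers(0, 3, size=(30, 2)).astype(np.int8)
        panel = panel_from_positions([100, 600], calls, chroms=["c1", "c2"])
        profile = bin_ld_by_distance(panel)
        assert profile.n_pairs.sum() == 0

    def test_matches_all_pairs_oracle(self, rng):
        """Bin means equal a direct recomputation over every eligible pair,
        including panels with missing calls."""
        n_snps = 40
        positions = np.sort(rng.choice(np.arange(1, 15_000), n_snps, replace=False))
        calls = rng.integers(0, 3, size=(25, n_snps)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.15] = -1
        panel = panel_from_positions(positions, calls)
        profile = bin_ld_by_distance(panel)

        sums = np.zeros(40)
        counts = np.zeros(40, dtype=int)
        for i, j in itertools.combinations(range(n_snps), 2):
            d = abs(int(positions[j]) - int(positions[i]))
            if d == 0 or d > 20_000:
                continue
            v = pairwise_r2(calls[:, i], calls[:, j])
            if np.isnan(v):
                continue
            b = int(np.ceil(d / 500)) - 1
            sums[b] += v
            counts[b] += 1
        assert np.array_equal(profile.n_pairs, counts)
        defined = counts > 0
        assert np.allclose(
            profile.mean_r2[defined], sums[defined] / counts[defined]
        )
        assert np.all(np.isnan(profile.mean_r2[~defined]))


class TestFitDecay:
    def test_exact_recovery_from_noiseless_curve(self):
        beta0, beta1 = -0.40, 4.76
        y = beta0 + beta1 / np.log(BIN_MIDPOINTS)
        fit = fit_decay(profile_from_curve(y))
        assert fit.beta0 == pytest.approx(beta0, abs=1e-10)
        assert fit.beta1 == pytest.approx(beta1, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_flat_data(self):
        fit = fit_decay(profile_from_curve(np.full(40, 0.2)))
        assert fit.beta1 == pytest.approx(0.0, abs=1e-10)
        assert fit.beta0 == pytest.approx(0.2, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        y = -0.3 + 3.5 / np.log(BIN_MIDPOINTS) + rng.normal(0, 0.01, 40)
        fit = fit_decay(profile_from_curve(y))
        z = 1.0 / np.log(BIN_MIDPOINTS)
        X = np.column_stack([np.ones(40), z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.beta0 == pytest.approx(beta[0], abs=1e-10)
        assert fit.beta1 == pytest.approx(beta[1], abs=1e-10)

    def test_invariant_to_bin_order(self, rng):
        y = -0.3 + 3.5 / np.log(BIN_MIDPOINTS) + rng.normal(0, 0.01, 40)
        fit = fit_decay(profile_from_curve(y))
        perm = rng.permutation(40)
        shuffled = LDProfile(
            bin_midpoints=BIN_MIDPOINTS[perm],
            mean_r2=y[perm],
            se_r2=np.zeros(40),
            n_pairs=np.full(40, 100),
        )
        fit2 = fit_decay(shuffled)
        assert fit2.beta0 == pytest.approx(fit.beta0)
        assert fit2.beta1 == pytest.approx(fit.beta1)

    def test_nan_bins_dropped_and_minimum_enforced(self):
        y = np.full(40, np.nan)
        y[:2] = 0.5
        with pytest.raises(ValueError):
            fit_decay(profile_from_curve(y))

    def test_lower_band_below_point_estimate(self, rng):
        y = -0.3 + 3.5 / np.log(BIN_MIDPOINTS) + rng.normal(0, 0.02, 40)
        fit = fit_decay(profile_from_curve(y))
        assert np.all(fit.lower_band < fit.predict(BIN_MIDPOINTS))


class TestSolveCrossing:
    @pytest.fixture()
    def printed_fit(self):
        y = -0.40 + 4.76 / np.log(BIN_MIDPOINTS)
        return fit_decay(profile_from_curve(y))

    def test_closed_form_from_printed_coefficients(self, printed_fit):
        x = solve_crossing(printed_fit, 0.1)
        assert x == pytest.approx(np.exp(4.76 / 0.5), rel=1e-9)
        assert 13_000 < x < 14_000

    def test_inversion_identity(self, printed_fit):
        threshold = printed_fit.beta0 + printed_fit.beta1 / np.log(2.0)
        assert solve_crossing(printed_fit, threshold) == pytest.approx(2.0, rel=1e-9)

    def test_composition_returns_threshold(self, printed_fit):
        x = solve_crossing(printed_fit, 0.1)
        assert printed_fit.predict(x) == pytest.approx(0.1, abs=1e-9)

    def test_threshold_below_asymptote_rejected(self, printed_fit):
        with pytest.raises(ValueError):
            solve_crossing(printed_fit, -0.5)

    def test_lower_band_crossing_left_of_point(self, rng):
        y = -0.40 + 4.76 / np.log(BIN_MIDPOINTS) + rng.normal(0, 0.01, 40)
        fit = fit_decay(profile_from_curve(y))
        x_point = solve_crossing(fit, 0.1)
        x_band = solve_crossing(fit, 0.1, use_lower_band=True)
        assert 0 < x_band < x_point
        assert fit.lower_curve(x_band) == pytest.approx(0.1, abs=1e-9)


class TestPrune:
    def test_duplicate_snp_within_window_removed(self, rng):
        col = rng.integers(0, 3, size=30).astype(np.int8)
        calls = np.column_stack([col, col])
        panel = panel_from_positions([1000, 2000], calls)
        kept = prune(panel, window=14_000, r2_max=0.1)
        assert list(kept) == [0]

    def test_duplicate_snp_beyond_window_retained(self, rng):
        col = rng.integers(0, 3, size=30).astype(np.int8)
        calls = np.column_stack([col, col])
        panel = panel_from_positions([1000, 16_001], calls)
        kept = prune(panel, window=14_000, r2_max=0.1)
        assert list(kept) == [0, 1]

    def test_independent_snps_all_retained(self, rng):
        calls = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        panel = panel_from_positions(np.arange(1, 21) * 700, calls)
        kept = prune(panel, window=14_000, r2_max=0.3)
        assert len(kept) == 20

    def test_matches_greedy_oracle_on_small_instances(self, rng):
        """Greedy scan equals step-by-step simulation of the rule on random
        small panels."""
        for trial in range(10):
            n_snps = 8
            positions = np.sort(
                rng.choice(np.arange(1, 6000), n_snps, replace=False)
            )
            base = rng.integers(0, 3, size=(40, n_snps)).astype(np.int8)
            # induce correlation: some columns copy earlier ones
            for j in range(1, n_snps):
                if rng.random() < 0.5:
                    base[:, j] = base[:, j - 1]
            panel = panel_from_positions(positions, base)
            kept = prune(panel, window=2000, r2_max=0.1)

            expected = []
            for j in range(n_snps):
                ok = True
                for k in expected:
                    if positions[j] - positions[k] <= 2000:
                        r2 = pairwise_r2(base[:, k], base[:, j])
                        if not np.isnan(r2) and r2 > 0.1:
                            ok = False
                            break
                expected.append(j) if ok else None
            assert list(kept) == expected, trial

    def test_retained_set_audit(self):
        """After pruning, no retained pair within the window exceeds r2_max."""
        from lcpopgen import SimulationConfig, simulate_panel

        cfg = SimulationConfig(
            n_subpops=1,
            samples_per_subpop=(100,),
            n_snps=250,
            mean_depth=30.0,
            n_scaffolds=3,
            scaffold_length=25_000,
            ld_decay_rate=3e-4,
            seed=44,
        )
        panel, _ = simulate_panel(cfg)
        kept = prune(panel, window=5000, r2_max=0.1)
        pos = panel.variants["pos"].to_numpy()
        chrom = panel.variants["chrom"].to_numpy()
        for a, b in itertools.combinations(kept, 2):
            if chrom[a] != chrom[b] or abs(int(pos[b]) - int(pos[a])) > 5000:
                continue
            r2 = pairwise_r2(panel.calls[:, a], panel.calls[:, b])
            assert np.isnan(r2) or r2 <= 0.1
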