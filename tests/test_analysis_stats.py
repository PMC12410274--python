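"""d', permutation nulls, eccentricity binning, exponential fits, Wilcoxon/FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from afield.analysis_stats import (
    EccBinSeries,
    bin_by_independent_ecc,
    default_bin_edges,
    dprime,
    dprime_from_counts,
    dprime_permutation,
    fit_exponential,
    wilcoxon_fdr,
)
from afield.exceptions import DataMismatchError, InvalidParameterError
from afield.synthetic_data import BehavioralRun, simulate_behavior


class TestDprime:
    def test_zero_when_rates_match(self):
        assert dprime_from_counts(30, 60, 20, 40) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        d = dprime_from_counts(15, 20, 5, 80)
        assert d == pytest.approx(norm.ppf(0.75) - norm.ppf(0.0625), abs=1e-12)
        assert d == pytest.approx(2.2086, abs=1e-4)

    def test_extreme_rates_corrected_to_finite(self):
        d = dprime_from_counts(20, 20, 5, 80)
        assert np.isfinite(d)
        assert d == pytest.approx(norm.ppf(20.5 / 21) - norm.ppf(5.5 / 81), abs=1e-12)

    def test_requires_both_trial_types(self):
        with pytest.raises(InvalidParameterError):
            dprime_from_counts(0, 0, 5, 80)
        run = BehavioralRun(is_target=np.ones(10, bool), responded=np.ones(10, bool))
        with pytest.raises(InvalidParameterError):
            dprime(run)


class TestDprimePermutation:
    def test_seed_reproducibility(self):
        run = simulate_behavior(2000, seed=0)
        a = dprime_permutation(run, n_perm=150, seed=5)
        b = dprime_permutation(run, n_perm=150, seed=5)
        assert np.array_equal(a.null, b.null)

    def test_null_centered_for_random_observer(self):
        run = simulate_behavior(4000, true_dprime=0.0, seed=1)
        res = dprime_permutation(run, n_perm=400, seed=2)
        assert abs(res.null.mean()) < 2 * res.null.std() / np.sqrt(400)

    def test_real_sensitivity_beats_every_permutation(self):
        run = simulate_behavior(10_000, true_dprime=2.7, seed=3)
        res = dprime_permutation(run, n_perm=300, seed=4)
        assert res.p_value <= 1 / 301 + 1e-12

    def test_minimum_permutations_enforced(self):
        run = simulate_behavior(100, seed=0)
        with pytest.raises(InvalidParameterError):
            dprime_permutation(run, n_perm=10)


def _long_values(participants, voxels, focused, distributed):
    rows = []
    for p in participants:
        for v, f, d in zip(voxels, focused, distributed):
            rows.append({"participant": p, "voxel_id": v, "condition": "focused", "value": f})
            rows.append({"participant": p, "voxel_id": v, "condition": "distributed", "value": d})
    return pd.DataFrame(rows)


class TestBinning:
    def _indep(self, participants, voxels, eccs):
        return pd.DataFrame(
            [
                {"participant": p, "voxel_id": v, "eccentricity": e}
                for p in participants
                for v, e in zip(voxels, eccs)
            ]
        )

    def test_identical_conditions_give_zero_differences(self):
        voxels = [0, 1, 2, 3]
        eccs = [0.2, 1.0, 2.0, 4.0]
        vals = [1.0, 2.0, 3.0, 4.0]
        series = bin_by_independent_ecc(
            self._indep([0], voxels, eccs), _long_values([0], voxels, vals, vals)
        )
        means = series.participant_mean()
        assert np.all((means == 0) | np.isnan(means))

    def test_interior_edge_joins_upper_bin(self):
        edges = np.array([0.0, 1.0, 2.0])
        series = bin_by_independent_ecc(
            self._indep([0], [0], [1.0]),
            _long_values([0], [0], [5.0], [7.0]),
            bin_edges=edges,
        )
        assert np.isnan(series.values.loc[0, 0])
        assert series.values.loc[0, 1] == pytest.approx(2.0)

    def test_empty_bins_are_missing_not_zero(self):
        series = bin_by_independent_ecc(
            self._indep([0], [0, 1], [0.5, 0.6]),
            _long_values([0], [0, 1], [1.0, 1.0], [2.0, 2.0]),
            bin_edges=np.array([0.0, 1.0, 2.0, 3.0]),
        )
        assert np.isnan(series.values.loc[0, 1])
        assert np.isnan(series.values.loc[0, 2])
        assert series.n.loc[0, 1] == 0

    def test_missing_independent_estimate_raises(self):
        with pytest.raises(DataMismatchError):
            bin_by_independent_ecc(
                self._indep([0], [0], [1.0]),
                _long_values([0], [0, 99], [1.0, 1.0], [2.0, 2.0]),
            )

    def test_bin_centers_track_member_eccentricities(self):
        series = bin_by_independent_ecc(
            self._indep([0], [0, 1], [0.4, 0.6]),
            _long_values([0], [0, 1], [1.0, 1.0], [2.0, 2.0]),
            bin_edges=np.array([0.0, 1.0, 2.0]),
        )
        assert series.bin_centers[0] == pytest.approx(0.5)
        assert series.bin_centers[1] == pytest.approx(1.5)  # empty bin keeps midpoint


def _series_from_curve(centers, curve, n_participants=8, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    table = np.tile(curve, (n_participants, 1)) + rng.normal(0, noise_sd, (n_participants, curve.size))
    edges = np.concatenate([[0.0], (centers[1:] + centers[:-1]) / 2, [centers[-1] + 0.5]])
    return EccBinSeries(
        roi_label="V1",
        bin_edges=edges,
        values=pd.DataFrame(table),
        n=pd.DataFrame(np.ones_like(table, dtype=int)),
        bin_centers=centers,
    )


class TestExponentialFit:
    CENTERS = np.array([0.15, 0.5, 1.0, 1.6, 2.4, 3.4, 4.5])

    def test_exact_recovery_of_generating_parameters(self):
        curve = 2.0 * np.exp(-self.CENTERS / 1.5) + 0.1
        fit = fit_exponential(_series_from_curve(self.CENTERS, curve), n_boot=50, seed=0)
        assert fit.amp == pytest.approx(2.0, abs=1e-6)
        assert fit.decay_const == pytest.approx(1.5, abs=1e-6)
        assert fit.asymptote == pytest.approx(0.1, abs=1e-6)

    def test_constant_data_collapses_to_asymptote(self):
        curve = np.full_like(self.CENTERS, 0.7)
        fit = fit_exponential(_series_from_curve(self.CENTERS, curve), n_boot=50, seed=0)
        assert fit.curve(self.CENTERS) == pytest.approx(curve, abs=1e-6)

    def test_band_contains_point_fit(self):
        curve = 1.5 * np.exp(-self.CENTERS / 1.2) + 0.2
        series = _series_from_curve(self.CENTERS, curve, noise_sd=0.1, seed=3)
        fit = fit_exponential(series, n_boot=300, seed=4)
        point = fit.curve(fit.eval_grid)
        assert np.all(fit.ci_low <= point + 1e-9)
        assert np.all(fit.ci_high >= point - 1e-9)

    def test_band_covers_generating_curve(self):
        """Across noisy replicates of a ten-participant study the 95% band
        covers the truth at >= 90% of grid points (aggregate over 200
        replicates)."""
        truth = lambda e: 1.0 * np.exp(-e / 1.5) + 0.1
        curve = truth(self.CENTERS)
        covered = total = 0
        for rep in range(200):
            series = _series_from_curve(
                self.CENTERS, curve, n_participants=10, noise_sd=0.15, seed=rep
            )
            fit = fit_exponential(series, n_boot=300, seed=rep)
            t = truth(fit.eval_grid)
            covered += np.sum((fit.ci_low <= t) & (t <= fit.ci_high))
            total += fit.eval_grid.size
        assert covered / total >= 0.90

    def test_too_few_bins_rejected(self):
        series = _series_from_curve(np.array([0.5, 1.0, 2.0]), np.array([1.0, 0.5, 0.2]))
        with pytest.raises(InvalidParameterError):
            fit_exponential(series, n_boot=10, seed=0)


def exact_signed_rank_p(diffs):
    """Brute-force two-sided signed-rank p by enumerating all sign patterns."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
    w_obs = ranks[diffs > 0].sum()
    n = diffs.size
    total = w_all = 0
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(ranks[np.array(signs, bool)].sum())
    stats = np.array(stats)
    mean = stats.mean()
    # two-sided: as or more extreme in distance from the null mean
    p = np.mean(np.abs(stats - mean) >= np.abs(w_obs - mean) - 1e-9)
    return p


class TestWilcoxonFDR:
    def test_exact_p_for_unanimous_signs(self):
        out = wilcoxon_fdr({"V1": np.arange(1.0, 11.0)})
        assert out.loc[0, "p"] == pytest.approx(2 / 2**10, abs=1e-12)

    def test_exact_null_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            d = rng.normal(0.3, 1.0, 10)
            while pd.Series(np.abs(d)).duplicated().any() or np.any(d == 0):
                d = rng.normal(0.3, 1.0, 10)
            out = wilcoxon_fdr({"roi": d})
            assert out.loc[0, "p"] == pytest.approx(exact_signed_rank_p(d), abs=1e-9)

    def test_symmetric_differences_never_reject(self):
        d = np.array([1, -1.1, 2, -2.1, 3, -3.1, 4, -4.1, 5, -5.1])
        out = wilcoxon_fdr({"roi": d})
        assert out.loc[0, "p"] > 0.8
        assert not out.loc[0, "reject"]

    def test_identical_pvalues_unchanged_by_bh(self):
        d = np.arange(1.0, 9.0)
        out = wilcoxon_fdr({f"roi{i}": d for i in range(10)})
        assert np.allclose(out["p_adj"], out["p"])

    def test_all_zero_differences_flagged(self):
        out = wilcoxon_fdr({"dead": np.zeros(8), "live": np.arange(1.0, 9.0)})
        dead = out.set_index("roi").loc["dead"]
        assert np.isnan(dead["p"])
        assert "undefined" in dead["note"]
        assert np.isfinite(out.set_index("roi").loc["live", "p_adj"])

    def test_paired_input_form(self):
        a, b = np.arange(1.0, 9.0), np.zeros(8)
        da = wilcoxon_fdr({"roi": (a, b)})
        db = wilcoxon_fdr({"roi": a - b})
        assert da.loc[0, "p"] == db.loc[0, "p"]

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InvalidParameterError):
            wilcoxon_fdr({"roi": np.array([1.0, 2.0, 3.0])})
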