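"""Developmental calling criteria and the time-scrambling FDR estimator."""

import numpy as np
import pandas as pd
import pytest

import tempomod as tm
from tempomod.errors import DesignError, UndefinedStatisticError
from tempomod.regulation import CLASSES


def _et_from_tensors(counts, rpkm, times=None):
    """ExpressionTable from genes × times × 2 tensors."""
    counts = np.asarray(counts, float)
    rpkm = np.asarray(rpkm, float)
    g, t, r = counts.shape
    times = list(times) if times is not None else list(range(t))
    cols = pd.MultiIndex.from_product([times, list(range(1, r + 1))],
                                      names=["time_h", "replicate"])
    idx = pd.Index([f"g{i}" for i in range(g)], name="gene_id")
    cdf = pd.DataFrame(counts.reshape(g, t * r), index=idx, columns=cols)
    rdf = pd.DataFrame(rpkm.reshape(g, t * r), index=idx, columns=cols)
    merged = rdf.T.groupby(level="time_h").mean().T[times]
    return tm.ExpressionTable(cdf, rdf, merged, pd.Series(1e6, index=cols))


def _single(rep1, rep2, counts1=None, counts2=None):
    rep1, rep2 = np.asarray(rep1, float), np.asarray(rep2, float)
    c1 = np.asarray(counts1, float) if counts1 is not None else np.full_like(rep1, 1000)
    c2 = np.asarray(counts2, float) if counts2 is not None else np.full_like(rep2, 1000)
    return _et_from_tensors(np.stack([c1, c2], -1)[None],
                            np.stack([rep1, rep2], -1)[None])


class TestCallRegulation:
    def test_strong_pulse_is_developmental(self):
        traj = [10, 10, 10, 40, 10, 10, 10]
        calls = tm.call_regulation(_single(traj, traj))
        row = calls.iloc[0]
        assert row["class"] == "developmental"
        assert row["fold_change"] == pytest.approx(4.0)
        assert row["gene_r2"] == pytest.approx(1.0)

    def test_small_reproducible_change_is_constitutive(self):
        traj = [10, 11, 12, 13, 12, 11, 10]
        row = tm.call_regulation(_single(traj, traj)).iloc[0]
        assert row["class"] == "constitutive"
        assert row["fold_change"] == pytest.approx(1.3)

    def test_49_reads_at_one_time_point_is_filtered_low(self):
        traj = [10, 10, 10, 40, 10, 10, 10]
        counts1 = [1000, 1000, 1000, 49, 1000, 1000, 1000]
        calls = tm.call_regulation(_single(traj, traj, counts1=counts1))
        assert calls.iloc[0]["class"] == "filtered_low"
        # pooled mode instead sums replicates: 49 + 1000 passes
        thr = tm.RegulationThresholds(low_filter="pooled")
        assert tm.call_regulation(_single(traj, traj, counts1=counts1),
                                  thr).iloc[0]["class"] == "developmental"

    def test_uncorrelated_replicates_are_filtered_discordant(self):
        # hand-constructed pair with Pearson r^2 ~= 0.25 < 0.7
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = np.array([4.0, 1.0, 6.0, 2.0, 7.0, 3.0, 5.0])
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert r2 < 0.7
        calls = tm.call_regulation(_single(a, b))
        assert calls.iloc[0]["class"] == "filtered_discordant"
        assert calls.iloc[0]["gene_r2"] == pytest.approx(r2)

    def test_flat_zero_variance_trajectory_warns_and_is_discordant(self):
        flat = [5.0] * 7
        with pytest.warns(UserWarning, match="zero-variance"):
            calls = tm.call_regulation(_single(flat, flat))
        assert calls.iloc[0]["class"] == "filtered_discordant"

    def test_missing_cell_is_filtered_missing(self):
        traj = [10, 10, 10, 40, 10, 10, 10]
        et = _single(traj, traj)
        et.counts.iloc[0, 3] = np.nan
        assert tm.call_regulation(et).iloc[0]["class"] == "filtered_missing"

    def test_zero_minimum_gives_infinite_fold_and_developmental(self):
        traj = [0.0, 1, 2, 8, 2, 1, 1]
        thr = tm.RegulationThresholds(min_reads=0)
        row = tm.call_regulation(_single(traj, traj), thr).iloc[0]
        assert row["class"] == "developmental"
        assert np.isinf(row["fold_change"])

    def test_fewer_than_three_time_points_raises(self):
        with pytest.raises(DesignError):
            tm.call_regulation(_single([1, 2], [1, 2]))

    def test_partition_into_exactly_one_class(self, small_calls, small_bundle):
        counts = small_calls["class"].value_counts()
        assert set(counts.index) == set(CLASSES)
        assert counts.sum() == len(small_bundle.counts)

    @pytest.mark.parametrize("field,higher", [
        ("min_reads", 100), ("min_r2", 0.9), ("min_fold", 4.0)])
    def test_raising_any_threshold_never_adds_developmental(
            self, small_et, small_calls, field, higher):
        base = (small_calls["class"] == "developmental").sum()
        stricter = tm.call_regulation(small_et,
                                      tm.RegulationThresholds(**{field: higher}))
        assert (stricter["class"] == "developmental").sum() <= base

    def test_matches_straight_line_oracle_on_small_instances(self):
        thr = tm.RegulationThresholds()
        rng = np.random.default_rng(123)
        for _ in range(25):
            g = rng.integers(1, 11)
            counts = rng.integers(0, 400, (g, 7, 2)).astype(float)
            rpkm = rng.uniform(0.1, 50, (g, 7, 2))
            et = _et_from_tensors(counts, rpkm)
            with np.errstate(all="ignore"):
                got = tm.call_regulation(et, thr)
            for i in range(g):
                expected = _oracle_call(counts[i], rpkm[i], thr)
                assert got.iloc[i]["class"] == expected, f"gene {i}"


def _oracle_call(counts, rpkm, thr):
    """Straight-line reimplementation of the three criteria for one gene."""
    if np.isnan(counts).any() or np.isnan(rpkm).any():
        return "filtered_missing"
    if (counts < thr.min_reads).any():
        return "filtered_low"
    a, b = rpkm[:, 0], rpkm[:, 1]
    if np.std(a) == 0 or np.std(b) == 0:
        return "filtered_discordant"
    r2 = np.corrcoef(a, b)[0, 1] ** 2
    if not r2 > thr.min_r2:
        return "filtered_discordant"
    merged = rpkm.mean(axis=1)
    lo = max(merged.min(), thr.fold_floor)
    fold = np.inf if lo == 0 else merged.max() / lo
    return "developmental" if fold > thr.min_fold else "constitutive"


class TestScrambleFdr:
    def test_identical_permutation_of_both_replicates_changes_nothing(self):
        """Shared time scrambles preserve r2 and fold; only independent
        per-replicate scrambles perturb the concordance criterion."""
        rng = np.random.default_rng(7)
        counts = rng.integers(60, 800, (30, 7, 2)).astype(float)
        rpkm = rng.uniform(1, 40, (30, 7, 2))
        et = _et_from_tensors(counts, rpkm)
        perm = rng.permutation(7)
        et_p = _et_from_tensors(counts[:, perm, :], rpkm[:, perm, :])
        a = tm.call_regulation(et)
        b = tm.call_regulation(et_p)
        assert (a["class"].to_numpy() == b["class"].to_numpy()).all()
        np.testing.assert_allclose(a["gene_r2"], b["gene_r2"])
        np.testing.assert_allclose(a["fold_change"], b["fold_change"])

    def test_deterministic_under_seed(self, small_et):
        f1 = tm.scramble_fdr(small_et, n_sims=3, seed=9)
        f2 = tm.scramble_fdr(small_et, n_sims=3, seed=9)
        assert f1 == f2
        assert len(f1.scrambled_pass_per_sim) == 3
        assert f1.fdr_pct == pytest.approx(
            100 * np.mean(f1.scrambled_pass_per_sim) / f1.observed_pass)

    def test_planted_signal_keeps_fdr_low(self, small_et):
        f = tm.scramble_fdr(small_et, n_sims=5, seed=2)
        assert f.fdr_pct < 50

    def test_no_observed_developmental_raises(self):
        flat = _single([10, 11, 10, 11, 10, 11, 10], [10, 11, 10, 11, 10, 11, 10])
        with pytest.raises(UndefinedStatisticError):
            tm.scramble_fdr(flat, n_sims=2, seed=1)
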