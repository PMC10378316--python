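"""SAM testing against exhaustive-permutation oracles and selection rules."""

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from mirepos.containers import ExpressionMatrix, ExpressionStudy, ValidationError
from mirepos.diffexpr import (
    SamConfig,
    detection_filter,
    fold_change,
    marker_table,
    sam_test,
    select_markers,
)
from mirepos.synthdata import SynthConfig, gen_mirna_study


def _matrix(values, feature_prefix="f"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values,
        index=[f"{feature_prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])]))


def _annotation(conditions, patients=None):
    frame = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(conditions))],
        "condition": conditions,
    })
    if patients is not None:
        frame["patient_id"] = patients
    return frame


class TestDetectionFilter:
    def _controls(self, n_samples, bg_sd=2.0, nc_mean=30.0):
        """Background probes with per-array SD bg_sd, negative controls whose
        10% trimmed mean is nc_mean."""
        bg = np.tile(np.array([-bg_sd, bg_sd] * 5)[:, None], (1, n_samples))
        bg = bg * np.sqrt(10 / 9.0) / np.sqrt(10 / 9.0)  # ddof=1 handled below
        # 10 values with mean 0 and sample SD exactly bg_sd:
        vals = np.array([-1.0, 1.0] * 5)
        vals = vals / vals.std(ddof=1) * bg_sd
        bg = np.tile(vals[:, None], (1, n_samples))
        nc = np.tile(np.full((10, 1), nc_mean), (1, n_samples))
        return bg, nc

    def _build(self, meas_values, bg_sd=2.0, nc_mean=30.0):
        meas = np.asarray(meas_values, dtype=float)
        n_samples = meas.shape[1]
        bg, nc = self._controls(n_samples, bg_sd, nc_mean)
        values = np.vstack([meas, nc, bg])
        ids = ([f"m{i}" for i in range(meas.shape[0])]
               + [f"nc{i}" for i in range(10)] + [f"bg{i}" for i in range(10)])
        classes = (["measurement"] * meas.shape[0]
                   + ["negative_control"] * 10 + ["background"] * 10)
        return ExpressionMatrix(
            pd.DataFrame(values, index=ids, columns=[f"s{i}" for i in range(n_samples)]),
            pd.Series(classes, index=ids))

    def test_threshold_formula(self):
        raw = self._build([[50.0, 50.0]], bg_sd=2.0, nc_mean=30.0)
        _, thresholds = detection_filter(raw)
        for t in thresholds:
            assert t.threshold == pytest.approx(5 * 2.0 + 30.0)

    def test_probe_above_threshold_retained_and_controls_dropped(self):
        raw = self._build([[50.0, 50.0], [10.0, 10.0]])
        filtered, _ = detection_filter(raw)
        assert filtered.feature_ids == ["m0"]
        assert filtered.probe_class is None

    def test_low_fraction_rule(self):
        # below threshold (40) on 2 of 3 arrays
        raw = self._build([[10.0, 10.0, 50.0]])
        kept_all, _ = detection_filter(raw, low_fraction=1.0)
        assert kept_all.feature_ids == ["m0"]
        kept_half, _ = detection_filter(raw, low_fraction=0.5)
        assert kept_half.feature_ids == []

    def test_missing_controls_rejected(self):
        mat = _matrix([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            detection_filter(ExpressionMatrix(
                mat.values, pd.Series(["measurement"], index=mat.feature_ids)))

    def test_bad_low_fraction_rejected(self):
        raw = self._build([[50.0, 50.0]])
        with pytest.raises(ValidationError):
            detection_filter(raw, low_fraction=0.0)


def _oracle_unpaired(X, n_a, s0):
    """Brute-force SAM p/q by enumerating all group-A label assignments."""
    n = X.shape[1]
    d_obs = None
    d_perms = []
    for assign in combinations(range(n), n_a):
        idx_a = list(assign)
        idx_b = [i for i in range(n) if i not in assign]
        A, B = X[:, idx_a], X[:, idx_b]
        ma, mb = A.mean(1), B.mean(1)
        ss = ((A - ma[:, None]) ** 2).sum(1) + ((B - mb[:, None]) ** 2).sum(1)
        s = np.sqrt((1 / len(idx_a) + 1 / len(idx_b)) * ss / (n - 2))
        d = (ma - mb) / (s + s0)
        d_perms.append(d)
        if assign == tuple(range(n_a)):
            d_obs = d
    d_perms = np.array(d_perms)
    B = len(d_perms)
    m = X.shape[0]
    p = np.array([
        (np.abs(d_perms[:, i]) >= abs(d_obs[i]) - 1e-12).sum() / B
        for i in range(m)
    ])
    # pooled FDR at each observed |d| threshold, then running min over
    # thresholds below
    abs_obs = np.abs(d_obs)
    fdr = np.empty(m)
    for i in range(m):
        v = (abs_obs >= abs_obs[i] - 1e-12).sum()
        e = (np.abs(d_perms) >= abs_obs[i] - 1e-12).sum() / B
        fdr[i] = min(1.0, e / v)
    q = np.array([fdr[abs_obs <= abs_obs[i] + 1e-12].min() for i in range(m)])
    return p, q


class TestSamOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_three_vs_three_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(12, 6))
        X[:3, :3] += 2.0  # some real structure
        mat = _matrix(X)
        ann = _annotation(["tumor"] * 3 + ["normal"] * 3)
        res = sam_test(mat, ann, SamConfig(n_perm=1000, seed=seed))
        s0 = float(res["s0"].iloc[0])
        p_oracle, q_oracle = _oracle_unpaired(X, 3, s0)
        np.testing.assert_allclose(res["p_value"].to_numpy(), p_oracle,
                                   atol=1e-12)
        np.testing.assert_allclose(res["q_value"].to_numpy(), q_oracle,
                                   atol=1e-12)

    def test_null_data_rarely_yields_discoveries(self):
        bad_seeds = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = rng.normal(0, 1, size=(100, 10))
            mat = _matrix(X)
            ann = _annotation(["tumor"] * 5 + ["normal"] * 5)
            res = sam_test(mat, ann, SamConfig(n_perm=300, seed=seed))
            bad_seeds += (res["q_value"] < 0.05).any()
        assert bad_seeds <= 0.05 * 50 + 1

    def test_planted_shift_recall(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, size=(200, 40))
        planted = np.arange(20)
        X[np.ix_(planted, np.arange(20))] += 4.0
        mat = _matrix(X)
        ann = _annotation(["tumor"] * 20 + ["normal"] * 20)
        res = sam_test(mat, ann, SamConfig(n_perm=300, seed=5))
        hits = set(np.flatnonzero(res["q_value"].to_numpy() < 0.05))
        assert len(hits & set(planted)) / len(planted) >= 0.9

    def test_constant_feature_flagged_not_crashing(self):
        X = np.vstack([np.ones(8), np.random.default_rng(0).normal(size=(3, 8))])
        mat = _matrix(X)
        ann = _annotation(["tumor"] * 4 + ["normal"] * 4)
        res = sam_test(mat, ann, SamConfig(n_perm=200, seed=0))
        assert bool(res["constant"].iloc[0])
        assert np.isfinite(res["d_stat"]).all()

    def test_degenerate_group_rejected(self):
        mat = _matrix(np.zeros((3, 3)))
        ann = _annotation(["tumor", "normal", "normal"])
        with pytest.raises(ValidationError):
            sam_test(mat, ann, SamConfig(n_perm=200, seed=0))

    def test_paired_mode_sign_flip_null(self):
        rng = np.random.default_rng(2)
        X = rng.normal(8, 1, size=(50, 8))
        ann = _annotation(
            ["tumor", "normal"] * 4,
            patients=[f"P{i // 2}" for i in range(8)],
        )
        res = sam_test(_matrix(X), ann, SamConfig(n_perm=500, seed=2,
                                                  paired=True))
        assert (res["q_value"] < 0.05).sum() == 0


class TestFoldChange:
    def test_equal_means_give_unity(self):
        mat = _matrix([[2.0, 2.0, 2.0, 2.0]])
        ann = _annotation(["tumor", "tumor", "normal", "normal"])
        assert fold_change(mat, ann)[0] == pytest.approx(1.0)

    def test_two_log2_units_give_fourfold(self):
        mat = _matrix([[3.0, 3.0, 1.0, 1.0]])
        ann = _annotation(["tumor", "tumor", "normal", "normal"])
        assert fold_change(mat, ann)[0] == pytest.approx(4.0)

    def test_paired_difference_of_one_gives_twofold(self):
        mat = _matrix([[4.0, 3.0, 6.0, 5.0]])
        ann = _annotation(["tumor", "normal", "tumor", "normal"],
                          patients=["P0", "P0", "P1", "P1"])
        assert fold_change(mat, ann, paired=True)[0] == pytest.approx(2.0)

    def test_incomplete_pair_skipped_with_warning(self):
        mat = _matrix([[4.0, 3.0, 6.0]])
        ann = _annotation(["tumor", "normal", "tumor"],
                          patients=["P0", "P0", "P1"])
        with pytest.warns(UserWarning, match="P1"):
            fc = fold_change(mat, ann, paired=True)
        assert fc[0] == pytest.approx(2.0)


class TestSelectMarkers:
    def _results(self, fc, p, q):
        return pd.DataFrame({"fc": fc, "p_value": p, "q_value": q},
                            index=[f"f{i}" for i in range(len(fc))])

    def test_boundary_fold_change_excluded(self):
        res = self._results([2.0], [0.001], [0.001])
        assert select_markers(res).empty

    def test_strong_marker_included_with_direction(self):
        res = marker = self._results([4.2969], [0.001], [0.01])
        marker["direction"] = "up"
        sel = select_markers(res)
        assert list(sel.index) == ["f0"]
        assert sel["direction"].iloc[0] == "up"

    def test_fdr_rule_excludes(self):
        res = self._results([3.0], [0.04], [0.06])
        assert select_markers(res).empty

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        res = self._results(np.exp(rng.normal(0, 1.5, 50)),
                            rng.uniform(0, 0.2, 50), rng.uniform(0, 0.2, 50))
        tight = set(select_markers(res, fc_hi=2, fc_lo=0.5, p_max=0.05,
                                   q_max=0.05).index)
        loose = set(select_markers(res, fc_hi=1.5, fc_lo=0.6, p_max=0.1,
                                   q_max=0.1).index)
        assert tight <= loose


class TestEndToEndMarkers:
    def test_planted_markers_recovered_on_synthetic_study(self, small_cfg):
        study, truth = gen_mirna_study(small_cfg)
        filtered, thresholds = detection_filter(study.matrix)
        for t in thresholds:
            assert t.threshold == pytest.approx(
                5 * t.background_sd + t.negctrl_trimmed_mean)
        tissue = study.samples_where(specimen="tissue")
        ann = study.annotation[study.annotation["sample_id"].isin(tissue)]
        ts = ExpressionStudy(filtered.subset_samples(tissue), ann)
        table = marker_table(ts, SamConfig(n_perm=200, seed=small_cfg.seed))
        selected = select_markers(table)
        planted = set(truth.planted_de)
        assert planted <= set(selected.index)
        # planted directions recovered
        for f in planted:
            assert selected.loc[f, "direction"] == truth.planted_de[f]
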