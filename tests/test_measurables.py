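import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from replimap import measurables as meas
from replimap.resampling import PseudoPair

from conftest import make_statmap


class TestContrastPower:
    def test_orthonormal_unit_contrast(self):
        X, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(30, 3)))
        c = np.array([1.0, 0.0, 0.0])
        assert meas.contrast_power(X, c) == pytest.approx(1.0)

    def test_quadratic_scaling(self, rng):
        X = rng.normal(size=(40, 3))
        c = np.array([0.0, 1.0, -1.0])
        assert meas.contrast_power(2 * X, c) == pytest.approx(
            4 * meas.contrast_power(X, c)
        )

    def test_normal_equations_oracle(self):
        X = np.array([[1, 0], [1, 0], [1, 1], [1, 1], [1, 2], [1, 2]], dtype=float)
        c = np.array([0.0, 1.0])
        # independent solve: precision = c' (X'X)^-1 c via explicit inverse
        xtx = X.T @ X
        det = xtx[0, 0] * xtx[1, 1] - xtx[0, 1] * xtx[1, 0]
        inv = np.array([[xtx[1, 1], -xtx[0, 1]], [-xtx[1, 0], xtx[0, 0]]]) / det
        precision = c @ inv @ c
        assert meas.contrast_power(X, c) == pytest.approx(1.0 / precision, rel=1e-12)

    def test_rank_deficient_names_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="dependent columns"):
            meas.contrast_power(X, np.array([0.0, 1.0, 0.0]))


class TestHatOutliers:
    def test_intercept_only_no_outliers(self):
        X = np.ones((25, 1))
        assert meas.hat_outlier_count(X) == 0

    def test_extreme_leverage_row_detected(self, rng):
        X = np.column_stack([np.ones(21), np.r_[rng.normal(size=20), 50.0]])
        assert meas.hat_outlier_count(X) >= 1

    def test_column_rescaling_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        assert meas.hat_outlier_count(X) == meas.hat_outlier_count(
            X * np.array([2.0, 0.5, 10.0])
        )

    def test_explicit_leverage_oracle(self, rng):
        X = np.column_stack([np.ones(15), rng.normal(size=(15, 2))])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        expected = int(np.sum(np.diag(H) > 2 * 3 / 15))
        assert meas.hat_outlier_count(X) == expected


class TestSimilarityMeasures:
    def test_identical_runs_within_one(self, rng):
        m = make_statmap(rng.normal(size=(5, 5, 5)))
        assert meas.within_subject_similarity([m, m, m]) == pytest.approx(1.0)

    def test_single_run_is_nan(self, rng):
        m = make_statmap(rng.normal(size=(5, 5, 5)))
        assert np.isnan(meas.within_subject_similarity([m]))

    def test_mean_of_pairwise(self, rng):
        maps = [make_statmap(rng.normal(size=(6, 6, 6))) for _ in range(3)]
        mask = np.ones((6, 6, 6), bool)
        pairwise = [
            np.corrcoef(maps[i].data[mask], maps[j].data[mask])[0, 1]
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert meas.within_subject_similarity(maps) == pytest.approx(
            np.mean(pairwise), abs=1e-12
        )

    def test_between_duplicated_subjects_all_one(self, rng):
        m = make_statmap(rng.normal(size=(5, 5, 5)))
        mat = meas.between_subject_similarity([m, m, m])
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(mat[iu], 1.0)

    def test_between_pair_count(self, rng):
        maps = [make_statmap(rng.normal(size=(5, 5, 5))) for _ in range(6)]
        mat = meas.between_subject_similarity(maps)
        assert np.sum(~np.isnan(mat)) == 6 * 5  # off-diagonal entries

    def test_between_matches_direct_loop(self, rng):
        maps = [make_statmap(rng.normal(size=(5, 5, 5))) for _ in range(4)]
        mat = meas.between_subject_similarity(maps)
        mask = np.ones((5, 5, 5), bool)
        for i in range(4):
            for j in range(i + 1, 4):
                direct = np.corrcoef(maps[i].data[mask], maps[j].data[mask])[0, 1]
                assert mat[i, j] == pytest.approx(direct, abs=1e-12)


def _measurable_set(rng, n=12):
    between = rng.uniform(-0.2, 0.8, size=(n, n))
    between = (between + between.T) / 2
    np.fill_diagonal(between, np.nan)
    return meas.MeasurableSet(
        motion=rng.uniform(0.05, 0.3, size=n),
        contrast_power=rng.uniform(1.0, 3.0, size=n),
        hat_outliers=rng.integers(0, 4, size=n).astype(float),
        within=rng.uniform(0.1, 0.7, size=n),
        between=between,
    )


class TestExpandToPairLevel:
    def test_identical_groups_zero_absdiffs(self, rng):
        ms = _measurable_set(rng)
        pair = PseudoPair(0, 3, (0, 1, 2), (3, 4, 5))
        # force P and Q aggregates equal by copying values
        for name in ("motion", "contrast_power", "hat_outliers", "within"):
            vec = getattr(ms, name)
            vec[[3, 4, 5]] = vec[[0, 1, 2]]
        ms.between[np.ix_([3, 4, 5], [3, 4, 5])] = ms.between[
            np.ix_([0, 1, 2], [0, 1, 2])
        ]
        row = meas.expand_to_pair_level(ms, pair, outcome=0.5)
        for base in meas.BASE_VARIABLES:
            assert row[f"{base}__absdiff_of_means"] == pytest.approx(0.0)
            assert row[f"{base}__absdiff_of_sds"] == pytest.approx(0.0)

    def test_mean_and_absdiff_arithmetic(self, rng):
        ms = _measurable_set(rng, n=8)
        ms.motion[:] = [2, 2, 2, 2, 4, 4, 4, 4]
        pair = PseudoPair(0, 4, (0, 1, 2, 3), (4, 5, 6, 7))
        row = meas.expand_to_pair_level(ms, pair, outcome=0.0)
        assert row["motion__mean_of_means"] == pytest.approx(3.0)
        assert row["motion__absdiff_of_means"] == pytest.approx(2.0)

    def test_sd_uses_sample_denominator(self, rng):
        ms = _measurable_set(rng, n=8)
        pair = PseudoPair(0, 4, (0, 1, 2, 3), (4, 5, 6, 7))
        row = meas.expand_to_pair_level(ms, pair, outcome=0.0)
        # independent two-pass SD with n-1 denominator
        def sd(vals):
            m = sum(vals) / len(vals)
            return (sum((v - m) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5

        sp = sd(ms.motion[[0, 1, 2, 3]].tolist())
        sq = sd(ms.motion[[4, 5, 6, 7]].tolist())
        assert row["motion__mean_of_sds"] == pytest.approx((sp + sq) / 2, abs=1e-12)
        assert row["motion__absdiff_of_sds"] == pytest.approx(abs(sp - sq), abs=1e-12)

    def test_missing_values_flag_incomplete(self, rng):
        ms = _measurable_set(rng)
        ms.within[:] = np.nan
        pair = PseudoPair(0, 3, (0, 1, 2), (3, 4, 5))
        row = meas.expand_to_pair_level(ms, pair, outcome=0.1)
        assert row["incomplete"]


def _simulate_rows(rng, n_sorts=60, ks=(8, 16, 32), beta_k=0.004, noise=0.01,
                   extra=None):
    rows = []
    for sort in range(n_sorts):
        for k in ks:
            row = {"task": "sim", "sort_index": sort, "k": k,
                   "sample_size": float(k), "incomplete": False}
            for base in meas.BASE_VARIABLES:
                for ex in meas.EXPANSIONS:
                    row[f"{base}__{ex}"] = rng.normal()
            row["outcome"] = beta_k * k + noise * rng.normal()
            if extra is not None:
                row["outcome"] += extra(row)
            rows.append(row)
    return pd.DataFrame(rows)


class TestTaskRegression:
    def test_orthogonality_contract(self, rng):
        df = _simulate_rows(rng)
        res = meas.fit_task_regression(df, task="sim")
        cols = {n: res.design[:, i] for i, n in enumerate(res.columns)}
        anchors = [v for n, v in cols.items()
                   if n.split("__")[0] in ("motion", "contrast_power",
                                           "hat_outliers")]
        for n, v in cols.items():
            if n.startswith(("within__", "between__")):
                for a in anchors:
                    assert abs(v @ a) < 1e-8 * max(
                        1.0, np.linalg.norm(v) * np.linalg.norm(a)
                    )

    def test_planted_sample_size_effect_recovered(self, rng):
        df = _simulate_rows(rng, beta_k=0.01, noise=0.005)
        res = meas.fit_task_regression(df, task="sim")
        i = res.columns.index("sample_size")
        # demeaned regression on ks (8, 16): slope of outcome on k
        assert res.beta[i] == pytest.approx(0.01, abs=0.005)

    def test_null_simulation_small_effect_sizes(self, rng):
        ds = []
        for rep in range(10):
            df = _simulate_rows(rng, beta_k=0.0, noise=1.0, n_sorts=40)
            res = meas.fit_task_regression(df, task="sim")
            for base in meas.BASE_VARIABLES:
                d = meas.block_effect_size(res, base)
                if np.isfinite(d):
                    ds.append(abs(d))
        assert np.mean(ds) < 3.0

    def test_span_invariance_of_r2(self, rng):
        df = _simulate_rows(rng, extra=lambda r: 0.3 * r["within__mean_of_means"])
        res = meas.fit_task_regression(df, task="sim")
        # plain (un-orthogonalized) OLS on the same kept columns
        sub = df[df["k"] != max(df["k"])]
        y = sub["outcome"].to_numpy()
        y = y - y.mean()
        X = np.column_stack(
            [sub[n].to_numpy() - sub[n].to_numpy().mean() for n in res.columns]
        )
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r2_plain = 1 - ((y - X @ beta) ** 2).sum() / (y**2).sum()
        assert res.r2 == pytest.approx(r2_plain, abs=1e-8)

    def test_largest_k_removed(self, rng):
        df = _simulate_rows(rng, ks=(8, 16, 32))
        res = meas.fit_task_regression(df, task="sim")
        assert res.design.shape[0] == (df["k"] != 32).sum()

    def test_too_few_k_values_rejected(self, rng):
        df = _simulate_rows(rng, ks=(8, 16))
        with pytest.raises(ValueError, match="distinct k"):
            meas.fit_task_regression(df)

    def test_constant_regressor_dropped(self, rng):
        df = _simulate_rows(rng)
        df["hat_outliers__mean_of_means"] = 0.0
        res = meas.fit_task_regression(df, task="sim")
        assert "hat_outliers__mean_of_means" in res.dropped
        assert "hat_outliers__mean_of_means" not in res.columns


class TestEffectSizeAndDeltaR2:
    def _orthonormal_result(self):
        rng = np.random.default_rng(5)
        X, _ = np.linalg.qr(rng.normal(size=(50, 2)))
        beta = np.array([2.0, 0.3])
        return meas.TaskRegressionResult(
            task="t", columns=["sample_size", "motion__mean_of_means"],
            beta=beta, design=X, outcome=X @ beta, ssr=1.0, r2=0.9,
        )

    def test_orthonormal_unit_ssr(self):
        res = self._orthonormal_result()
        assert meas.block_effect_size(res, "sample_size") == pytest.approx(2.0)

    def test_residual_scaling_halves_d(self):
        res = self._orthonormal_result()
        d1 = meas.block_effect_size(res, "sample_size")
        res.ssr = 4.0
        assert meas.block_effect_size(res, "sample_size") == pytest.approx(d1 / 2)

    def test_formula_oracle_on_random_fit(self, rng):
        df = _simulate_rows(rng)
        res = meas.fit_task_regression(df, task="sim")
        xtx_inv = np.linalg.inv(res.design.T @ res.design)
        for base in ("motion", "sample_size"):
            d = meas.block_effect_size(res, base)
            idxs = [i for i, n in enumerate(res.columns)
                    if n == base or n.startswith(base + "__")]
            expected = max(
                (res.beta[i] / np.sqrt(res.ssr * xtx_inv[i, i]) for i in idxs),
                key=abs,
            )
            assert d == pytest.approx(expected, rel=1e-10)

    def test_outcome_built_from_one_expansion(self, rng):
        df = _simulate_rows(
            rng, beta_k=0.0, noise=0.001,
            extra=lambda r: 1.0 * r["motion__absdiff_of_means"],
        )
        res = meas.fit_task_regression(df, task="sim")
        assert meas.block_delta_r2(res, "motion") > 0.9

    def test_delta_r2_nonnegative_all_blocks(self, rng):
        df = _simulate_rows(rng)
        res = meas.fit_task_regression(df, task="sim")
        for base in ("sample_size",) + meas.BASE_VARIABLES:
            assert meas.block_delta_r2(res, base) >= 0.0


class TestMapAggregate:
    def test_all_zero_effects(self):
        assert meas.map_aggregate([0.0, 0.0, 0.0], "effect_size") == 0.0

    def test_huge_variance_shrinks_to_prior(self):
        vals = [1000.0, -998.0, 1002.0]
        assert abs(meas.map_aggregate(vals, "effect_size")) < 0.01

    def test_conjugate_normal_oracle(self):
        vals = [1.0, 1.2, 1.4]
        s2 = np.var(vals, ddof=1)
        n = 3
        expected = (n * np.mean(vals) / s2) / (n / s2 + 1.0)
        assert meas.map_aggregate(vals, "effect_size") == pytest.approx(
            expected, rel=1e-12
        )

    def test_delta_r2_logit_round_trip(self):
        vals = [0.3, 0.35, 0.4]
        x = logit(np.clip(vals, 1e-8, 1 - 1e-8))
        s2 = np.var(x, ddof=1)
        n = 3
        post = (n * np.mean(x) / s2 - 20.0 / 100.0) / (n / s2 + 1.0 / 100.0)
        assert meas.map_aggregate(vals, "delta_r2") == pytest.approx(
            expit(post), rel=1e-12
        )

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            meas.map_aggregate([0.5], "effect_size")
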