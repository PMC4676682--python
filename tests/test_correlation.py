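"""Spearman machinery, correlation profiles and group comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from t1bh.correlation import (
    auxiliary_correlations,
    build_profile,
    compare_group_t1,
    optimal_threshold,
    spearman,
)
from t1bh.thresholding import sweep_lesionwise


def average_ranks(x):
    """Explicit average-rank computation by sorting (independent of scipy)."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_by_hand(a, b):
    n = len(a)
    ma, mb = sum(a) / n, sum(b) / n
    cov = sum((ai - ma) * (bi - mb) for ai, bi in zip(a, b))
    va = sum((ai - ma) ** 2 for ai in a)
    vb = sum((bi - mb) ** 2 for bi in b)
    return cov / math.sqrt(va * vb)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman(x, x).r == pytest.approx(1.0)
        assert spearman(x, [-v for v in x]).r == pytest.approx(-1.0)
        assert spearman(x, x).p == 0.0

    def test_tied_example_matches_hand_rank_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 2, 4, 4, 5]
        expected = pearson_by_hand(average_ranks(x), average_ranks(y))
        assert expected == pytest.approx(0.9486832980505138)
        assert spearman(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_is_undefined(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert not res.defined
        assert math.isnan(res.p)

    def test_matches_scipy_on_random_tied_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            res = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert res.r == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_permutation_p(self):
        from itertools import permutations

        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [1.0, 2.0, 3.0, 4.0, 6.0, 5.0]
        res = spearman(x, y, method="exact")
        rx, robs = average_ranks(x), pearson_by_hand(
            average_ranks(x), average_ranks(y)
        )
        hits, total = 0, 0
        for perm in permutations(average_ranks(y)):
            total += 1
            hits += abs(pearson_by_hand(rx, list(perm))) >= abs(robs) - 1e-12
        assert res.p == pytest.approx(hits / total, abs=1e-12)
        with pytest.raises(ValueError):
            spearman(range(12), range(12), method="exact")

    @given(st.integers(1, 6))
    @settings(max_examples=6, deadline=None)
    def test_monotone_transform_invariance(self, k):
        rng = np.random.default_rng(k)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman(x, y).r
        assert spearman(np.exp(k * x), y).r == pytest.approx(base, abs=1e-12)
        assert spearman(x, y**3).r == pytest.approx(base, abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            spearman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            spearman([1.0, np.nan, 2.0], [1.0, 2.0, 3.0])


def profile_frame(thresholds, rs, sig):
    return pd.DataFrame(
        {
            "threshold_ms": thresholds,
            "mode": "lesion",
            "score": "edss",
            "spearman_r": rs,
            "p_value": [0.01 if s else 0.5 for s in sig],
            "n_included": 38,
            "estimable": True,
            "significant": sig,
        }
    )


class TestOptimalThreshold:
    def test_single_significant_point(self):
        prof = profile_frame([700, 1500], [0.2, 0.41], [False, True])
        assert optimal_threshold(prof) == 1500

    def test_no_significant_point_is_none(self):
        prof = profile_frame([700, 1500], [0.2, 0.3], [False, False])
        assert optimal_threshold(prof) is None

    def test_argmax_of_abs_r(self):
        prof = profile_frame(
            [700, 800, 1500, 1600],
            [0.40, 0.40, 0.44, 0.33],
            [True, True, True, True],
        )
        assert optimal_threshold(prof) == 1500

    def test_tie_resolves_to_lowest_threshold(self):
        prof = profile_frame([700, 1500], [-0.44, 0.44], [True, True])
        assert optimal_threshold(prof) == 700

    def test_empty_profile_raises(self):
        with pytest.raises(ValueError):
            optimal_threshold(profile_frame([], [], []))


class TestGroupComparison:
    def test_identical_groups(self, rng):
        vals = rng.normal(1400, 100, 30)
        lesions = pd.DataFrame(
            {
                "lesion_class": ["BH_vis"] * 30 + ["pure_FLAIR"] * 30,
                "mean_t1_ms": np.concatenate([vals, vals]),
            }
        )
        out = compare_group_t1(lesions)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_separated_groups(self, rng):
        lesions = pd.DataFrame(
            {
                "lesion_class": ["BH_vis"] * 50 + ["pure_FLAIR"] * 50,
                "mean_t1_ms": np.concatenate(
                    [rng.normal(0, 1, 50), rng.normal(10, 1, 50)]
                ),
            }
        )
        assert compare_group_t1(lesions).loc[0, "p_value"] < 1e-6

    def test_welch_matches_hand_formula(self, rng):
        a = rng.normal(1450, 210, 23)
        b = rng.normal(1330, 230, 31)
        lesions = pd.DataFrame(
            {
                "lesion_class": ["BH_vis"] * 23 + ["pure_FLAIR"] * 31,
                "mean_t1_ms": np.concatenate([a, b]),
            }
        )
        out = compare_group_t1(lesions).iloc[0]
        se = math.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        t_hand = (a.mean() - b.mean()) / se
        df_hand = se**4 / (
            (a.var(ddof=1) / len(a)) ** 2 / (len(a) - 1)
            + (b.var(ddof=1) / len(b)) ** 2 / (len(b) - 1)
        )
        assert out["t"] == pytest.approx(t_hand, rel=1e-12)
        assert out["p_value"] == pytest.approx(
            2 * stats.t.sf(abs(t_hand), df_hand), rel=1e-9
        )

    def test_cortex_included_as_group(self, rng):
        lesions = pd.DataFrame(
            {
                "lesion_class": ["BH_vis"] * 5,
                "mean_t1_ms": rng.normal(1450, 100, 5),
            }
        )
        cortex = pd.DataFrame({"mean_ms": rng.normal(1305, 30, 4)})
        out = compare_group_t1(lesions, cortex)
        assert set(out["group_a"]) | set(out["group_b"]) == {"BH_vis", "cortex"}

    def test_small_group_rejected(self):
        lesions = pd.DataFrame(
            {"lesion_class": ["BH_vis", "pure_FLAIR", "pure_FLAIR"],
             "mean_t1_ms": [1400.0, 1300.0, 1350.0]}
        )
        with pytest.raises(ValueError):
            compare_group_t1(lesions)


def make_records(rng, n_patients=12, n_per=6):
    rows = []
    for i in range(n_patients):
        for j in range(n_per):
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "lesion_id": j + 1,
                    "lesion_class": "BH_vis",
                    "voxel_count": 10,
                    "volume_mm3": float(rng.uniform(10, 200)),
                    "mean_t1_ms": float(rng.normal(1450, 200)),
                }
            )
    return pd.DataFrame(rows)


class TestBuildProfile:
    def test_reduces_to_unthresholded_correlation_below_all_lesions(self, rng):
        records = make_records(rng)
        clinical = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(12)],
                "edss": np.round(rng.uniform(0, 6.5, 12) * 2) / 2,
            }
        )
        sweep = sweep_lesionwise(records, (500.0, 1500.0))
        prof = build_profile(sweep, clinical, "edss", "lesion")
        totals = records.groupby("patient_id")["volume_mm3"].sum()
        direct = spearman(
            totals[clinical["patient_id"]].to_numpy(), clinical["edss"].to_numpy()
        )
        row = prof[prof["threshold_ms"] == 500.0].iloc[0]
        assert row["spearman_r"] == pytest.approx(direct.r, abs=1e-12)
        assert row["n_included"] == 12

    def test_too_few_included_marked_not_estimable(self, rng):
        records = make_records(rng, n_patients=5)
        records["mean_t1_ms"] = 1000.0
        records.loc[0, "mean_t1_ms"] = 1600.0  # one patient survives at 1500
        clinical = pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(5)], "edss": [1, 2, 3, 4, 5.0]}
        )
        sweep = sweep_lesionwise(records, (700.0, 1500.0))
        prof = build_profile(sweep, clinical, "edss", "lesion")
        row = prof[prof["threshold_ms"] == 1500.0].iloc[0]
        assert not row["estimable"] and not row["significant"]

    def test_missing_scores_drop_patients(self, rng):
        records = make_records(rng, n_patients=8)
        clinical = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(8)],
                "msfc": [0.1, 0.5, np.nan, 1.2, np.nan, -0.3, 0.8, 0.0],
            }
        )
        sweep = sweep_lesionwise(records, (500.0,))
        prof = build_profile(sweep, clinical, "msfc", "lesion")
        assert prof.iloc[0]["n_included"] == 6


def test_auxiliary_count_correlation_matches_volume_when_ranks_agree(rng):
    # one lesion of unit volume per count step: count ranks == volume ranks
    rows = []
    for i in range(10):
        for j in range(i + 1):
            rows.append(
                {
                    "patient_id": f"P{i}",
                    "lesion_id": j,
                    "lesion_class": "BH_vis",
                    "voxel_count": 1,
                    "volume_mm3": 1.0,
                    "mean_t1_ms": 1400.0,
                }
            )
    records = pd.DataFrame(rows)
    clinical = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(10)],
            "edss": np.round(rng.uniform(0, 6.5, 10) * 2) / 2,
            "duration_y": rng.uniform(0, 20, 10),
        }
    )
    sweep = sweep_lesionwise(records, (700.0,))
    aux = auxiliary_correlations(sweep, clinical, "edss")
    r_count = aux["count_vs_score"].iloc[0]["spearman_r"]
    prof = build_profile(sweep, clinical, "edss", "lesion")
    assert r_count == pytest.approx(prof.iloc[0]["spearman_r"], abs=1e-12)
    assert set(aux["duration"]["measure"]) == {"lesion_count", "cumulative_volume"}
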