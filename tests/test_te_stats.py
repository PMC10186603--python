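"""The TE-specific statistics: class tests, correlations, matching, overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from texpress import (
    FeatureAnnotation,
    TEStatsError,
    global_reference_log2fc,
    intersect_te_sets,
    match_groups,
    most_increased_tes,
    partial_correlation,
    pearson_correlation,
    te_type_test,
    total_te_counts,
)
from texpress.te_stats import (
    encode_covariates,
    mann_whitney_location,
    wilcoxon_vs_reference,
)
from conftest import make_matrix


def de_frame(ids, lfcs):
    n = len(ids)
    return pd.DataFrame(
        {
            "feature_id": list(ids),
            "base_mean": np.full(n, 100.0),
            "log2fc": np.asarray(lfcs, dtype=float),
            "se": np.ones(n),
            "wald_p": np.ones(n),
            "adj_p": np.ones(n),
        }
    )


def mixed_annotation(n_genes, n_per_class):
    records = [FeatureAnnotation(f"g{i}", "gene") for i in range(n_genes)]
    for cls, n in n_per_class.items():
        records += [
            FeatureAnnotation(f"{cls}{i}", "TE", f"{cls}{i}", "fam", cls)
            for i in range(n)
        ]
    return records


class TestGlobalReference:
    def test_all_zero(self):
        assert global_reference_log2fc(de_frame(["a", "b"], [0, 0])) == 0.0

    def test_hand_mean(self):
        val = global_reference_log2fc(de_frame(["a", "b", "c"], [1, -1, 2]))
        assert val == pytest.approx(2 / 3)

    def test_single_feature(self):
        assert global_reference_log2fc(de_frame(["a"], [0.7])) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(TEStatsError, match="empty"):
            global_reference_log2fc(de_frame([], []))


class TestTypeTest:
    def test_exact_u_statistic_and_p(self):
        # all 3 class values exceed all 3 reference values:
        # U = 9, one-sided p = 1/C(6,3), two-sided p = 0.1
        u, p, method = mann_whitney_location([1, 2, 3], [0, 0, 0])
        assert u == 9 and method == "exact"
        assert p == pytest.approx(0.1)

    def test_exact_example_through_te_type_test(self):
        ann = mixed_annotation(3, {"LINE": 3})
        de = de_frame(["g0", "g1", "g2", "LINE0", "LINE1", "LINE2"],
                      [0, 0, 0, 1, 2, 3])
        res = te_type_test(de, ann, "LINE", reference="genes_only")
        assert res.U_or_W == 9
        assert res.p_value == pytest.approx(0.1)
        assert res.reference_mean == 0.0

    def test_one_sample_degenerate_is_p_one(self):
        ann = mixed_annotation(2, {"LINE": 3})
        de = de_frame(["g0", "g1", "LINE0", "LINE1", "LINE2"],
                      [0.5, 0.5, 0.5, 0.5, 0.5])
        res = te_type_test(de, ann, "LINE", mode="one_sample")
        assert res.p_value == 1.0

    def test_one_sample_detects_shift(self):
        # class values all well above a gene-anchored reference mean
        rng = np.random.default_rng(0)
        lfc = rng.normal(0.8, 0.05, 12)
        res = te_type_test(
            de_frame([f"g{i}" for i in range(12)] + [f"LINE{i}" for i in range(12)],
                     np.concatenate([np.zeros(12), lfc])),
            mixed_annotation(12, {"LINE": 12}),
            "LINE", mode="one_sample", reference="genes_only",
        )
        assert res.p_value < 0.01

    def test_small_class_flagged_untestable(self):
        ann = mixed_annotation(5, {"LINE": 2})
        de = de_frame(["g0", "g1", "g2", "g3", "g4", "LINE0", "LINE1"],
                      [0, 0, 0, 0, 0, 1, 1])
        res = te_type_test(de, ann, "LINE")
        assert res.untestable and math.isnan(res.p_value)
        assert res.n_te == 2

    def test_location_equivariance(self):
        rng = np.random.default_rng(1)
        ann = mixed_annotation(300, {"LINE": 40})
        ids = [f"g{i}" for i in range(300)] + [f"LINE{i}" for i in range(40)]
        lfc = rng.normal(0, 0.3, 340)
        p0 = te_type_test(de_frame(ids, lfc), ann, "LINE").p_value
        for c in (0.5, -2.0, 10.0):
            pc = te_type_test(de_frame(ids, lfc + c), ann, "LINE").p_value
            assert abs(pc - p0) <= 1e-12

    def test_null_calibration_quick(self):
        rng = np.random.default_rng(2)
        ann = mixed_annotation(1000, {"LINE": 50})
        ids = [f"g{i}" for i in range(1000)] + [f"LINE{i}" for i in range(50)]
        rejections = 0
        reps = 200
        for _ in range(reps):
            de = de_frame(ids, rng.normal(0, 0.3, 1050))
            if te_type_test(de, ann, "LINE").p_value < 0.05:
                rejections += 1
        assert 0.01 <= rejections / reps <= 0.09

    def test_shapiro_reported_not_gating(self):
        rng = np.random.default_rng(3)
        ann = mixed_annotation(50, {"LINE": 30})
        ids = [f"g{i}" for i in range(50)] + [f"LINE{i}" for i in range(30)]
        # heavily non-normal class values: test still runs
        lfc = np.concatenate([rng.normal(0, 0.1, 50), rng.exponential(2.0, 30)])
        res = te_type_test(de_frame(ids, lfc), ann, "LINE")
        assert res.shapiro_p < 0.05
        assert 0 <= res.p_value <= 1


class TestCorrelations:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_hand_example(self):
        res = pearson_correlation([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.9820, abs=5e-5)

    def test_constant_vector_rejected(self):
        with pytest.raises(TEStatsError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_independent_vectors_mean_r_near_zero(self):
        rng = np.random.default_rng(4)
        rs = [
            pearson_correlation(rng.normal(size=200), rng.normal(size=200)).r
            for _ in range(300)
        ]
        assert abs(np.mean(rs)) <= 0.02

    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        a = pearson_correlation(x, y)
        b = partial_correlation(x, y)
        assert abs(a.r - b.r) <= 1e-12
        assert abs(a.p - b.p) <= 1e-12

    def test_confound_removed(self):
        rng = np.random.default_rng(6)
        n = 500
        raw_rs, partial_rs = [], []
        for _ in range(50):
            age = rng.uniform(25, 102, n)
            sex = (rng.normal((age - 63) / 25, 1.0) > 0).astype(float)
            y = 2.0 * sex + rng.normal(size=n)
            raw_rs.append(abs(pearson_correlation(age, y).r))
            partial_rs.append(abs(partial_correlation(age, y, sex[:, None]).r))
        assert np.mean(raw_rs) > 0.2
        assert np.mean(partial_rs) <= 0.05

    def test_partial_sign_matches_true_age_slope(self):
        rng = np.random.default_rng(7)
        n, hits = 200, 0
        reps = 500
        for _ in range(reps):
            age = rng.uniform(25, 102, n)
            sex = (rng.normal((age - 63) / 30, 1.0) > 0).astype(float)
            y = 0.02 * age + 1.0 * sex + rng.normal(size=n)
            if partial_correlation(age, y, sex[:, None]).r > 0:
                hits += 1
        assert hits / reps >= 0.95

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        cov = pd.DataFrame({"a": np.ones(20), "b": rng.normal(size=20)})
        with pytest.raises(TEStatsError, match="rank-deficient.*a"):
            partial_correlation(x, y, cov)

    def test_encode_covariates_expands_sex(self):
        md = pd.DataFrame(
            {"sample_id": ["a", "b"], "sex": ["F", "M"], "pmi": [3.0, 4.0]}
        )
        enc = encode_covariates(md, ["sex", "pmi"])
        assert list(enc.columns) == ["sex_M", "pmi"]
        assert enc["sex_M"].tolist() == [0.0, 1.0]


class TestTotalTECounts:
    def annotation(self):
        return mixed_annotation(1, {"LINE": 1, "SINE": 1})

    def test_no_tes_gives_zeros(self):
        cm = make_matrix([[1.0, 2.0]], normalized=True)
        ann = [FeatureAnnotation("f0", "gene")]
        assert total_te_counts(cm, ann).tolist() == [0.0, 0.0]

    def test_addition(self):
        cm = make_matrix([[3.0, 4.0], [1.0, 2.0]], normalized=True)
        ann = [
            FeatureAnnotation("f0", "TE", "a", "f", "LINE"),
            FeatureAnnotation("f1", "TE", "b", "f", "SINE"),
        ]
        assert total_te_counts(cm, ann).tolist() == [4.0, 6.0]

    def test_class_totals_partition_total(self, small_study):
        from texpress import CountMatrix

        counts, _, annotation, _ = small_study
        norm = CountMatrix(counts.values, counts.feature_ids, counts.sample_ids,
                           normalized=True)
        total = total_te_counts(norm, annotation)
        by_class = total_te_counts(norm, annotation, by_class=True)
        assert by_class.sum(axis=0).to_numpy() == pytest.approx(total.to_numpy())

    def test_raw_counts_rejected(self):
        cm = make_matrix([[1.0]])
        with pytest.raises(TEStatsError, match="normalized"):
            total_te_counts(cm, [FeatureAnnotation("f0", "gene")])


def metadata_from(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "age", "sex"])


class TestMatching:
    def test_exact_pairs_selected(self):
        md = metadata_from(
            [
                ("c1", "case", 70, "F"), ("c2", "case", 80, "M"),
                ("k1", "ctrl", 70, "F"), ("k2", "ctrl", 80, "M"),
                ("c3", "case", 99, "F"), ("k3", "ctrl", 40, "M"),
            ]
        )
        sel = match_groups(md, "group", 2)
        assert sel == {"case": ["c1", "c2"], "ctrl": ["k1", "k2"]}

    def test_greedy_matches_brute_force_total(self):
        ages_case = [61, 72, 55, 90, 44, 67]
        ages_ctrl = [60, 70, 57, 88, 46, 69]
        rows = [(f"c{i}", "case", a, "F") for i, a in enumerate(ages_case)]
        rows += [(f"k{i}", "ctrl", a, "F") for i, a in enumerate(ages_ctrl)]
        md = metadata_from(rows)
        n = 4
        sel = match_groups(md, "group", n)
        age = dict(zip(md["sample_id"], md["age"]))
        greedy_total = sum(
            abs(age[a] - age[b]) for a, b in zip(sel["case"], sel["ctrl"])
        )
        best = math.inf
        case_ids = [r[0] for r in rows[:6]]
        ctrl_ids = [r[0] for r in rows[6:]]
        for cases in itertools.combinations(case_ids, n):
            for ctrls in itertools.permutations(ctrl_ids, n):
                best = min(
                    best,
                    sum(abs(age[a] - age[b]) for a, b in zip(cases, ctrls)),
                )
        assert greedy_total == pytest.approx(best)

    def test_n_too_large_rejected(self):
        md = metadata_from([("c1", "case", 70, "F"), ("k1", "ctrl", 71, "F")])
        with pytest.raises(TEStatsError, match="candidates"):
            match_groups(md, "group", 2)

    def test_infeasible_sex_balance_reports_split(self):
        md = metadata_from(
            [
                ("c1", "case", 70, "F"), ("c2", "case", 75, "F"),
                ("k1", "ctrl", 70, "M"), ("k2", "ctrl", 75, "M"),
            ]
        )
        with pytest.raises(TEStatsError, match="infeasible sex balance"):
            match_groups(md, "group", 2)

    def test_extremes_maximize_age_gap_with_sex_balance(self):
        rng = np.random.default_rng(9)
        rows = [
            (f"s{i}", "all", float(a), ["F", "M"][i % 2])
            for i, a in enumerate(rng.uniform(25, 102, 30))
        ]
        md = metadata_from(rows)
        sel = match_groups(md, "group", 10, objective="extremes")
        ages = dict(zip(md["sample_id"], md["age"]))
        sexes = dict(zip(md["sample_id"], md["sex"]))
        young = sorted(ages[s] for s in sel["young"])
        old = sorted(ages[s] for s in sel["old"])
        assert max(young) < min(old)
        from collections import Counter
        assert Counter(sexes[s] for s in sel["young"]) == Counter(
            sexes[s] for s in sel["old"]
        )

    def test_extremes_deterministic(self):
        md = metadata_from(
            [(f"s{i}", "all", 30.0 + i, ["F", "M"][i % 2]) for i in range(12)]
        )
        a = match_groups(md, "group", 4, objective="extremes")
        b = match_groups(md.sample(frac=1, random_state=1), "group", 4,
                         objective="extremes")
        assert a == b


class TestSelection:
    def test_all_equal_gives_empty(self):
        de = de_frame(["t1", "t2"], [0.4, 0.4])
        assert most_increased_tes(de) == set()

    def test_strictly_above_mean(self):
        de = de_frame(["A", "B", "C"], [1.0, 0.0, 2.0])
        assert most_increased_tes(de) == {"C"}

    def test_single_te_empty(self):
        assert most_increased_tes(de_frame(["A"], [3.0])) == set()

    def test_empty_rejected(self):
        with pytest.raises(TEStatsError, match="no TE results"):
            most_increased_tes(de_frame([], []))

    def test_annotation_restricts_to_tes(self):
        ann = mixed_annotation(1, {"LINE": 2})
        de = de_frame(["g0", "LINE0", "LINE1"], [9.0, 0.0, 1.0])
        assert most_increased_tes(de, ann) == {"LINE1"}


class TestOverlap:
    def test_two_disjoint_sets(self):
        res = intersect_te_sets({"a": {"A"}, "b": {"B"}})
        assert res.region_counts == {"10": 1, "01": 1, "11": 0}

    def test_identical_sets_all_ones_region(self):
        res = intersect_te_sets({"a": {"x", "y"}, "b": {"x", "y"}})
        assert res.region_counts["11"] == 2
        assert res.region_counts["10"] == res.region_counts["01"] == 0

    def test_four_random_sets_match_brute_force(self):
        rng = np.random.default_rng(10)
        universe = [f"te{i}" for i in range(30)]
        sets = {
            name: {t for t in universe if rng.random() < 0.4}
            for name in ("w", "x", "y", "z")
        }
        res = intersect_te_sets(sets)
        names = list(sets)
        brute = {}
        for bits in itertools.product("01", repeat=4):
            if "1" not in bits:
                continue
            count = sum(
                1
                for t in universe
                if all((t in sets[n]) == (b == "1") for n, b in zip(names, bits))
            )
            brute["".join(bits)] = count
        assert res.region_counts == brute

    def test_too_many_sets_rejected(self):
        sets = {f"s{i}": {"A"} for i in range(7)}
        with pytest.raises(TEStatsError, match="between 2 and 6"):
            intersect_te_sets(sets)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 5))
    def test_region_counts_sum_to_union(self, seed, k):
        rng = np.random.default_rng(seed)
        universe = [f"te{i}" for i in range(20)]
        sets = {
            f"s{i}": {t for t in universe if rng.random() < 0.5} for i in range(k)
        }
        res = intersect_te_sets(sets)
        union = set().union(*sets.values())
        assert sum(res.region_counts.values()) == len(union)
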