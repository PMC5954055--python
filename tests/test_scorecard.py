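"""Lineage scorecard: QC, normalization, marker selection, moderated t, grading."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pscqc import scorecard as sc
from pscqc.errors import EmptyResultError, InputError, PanelError
from pscqc.synthetic import (
    PLANTED_MARKERS,
    SimulationConfig,
    default_lineage_effects,
    default_panel,
    gen_ct_timecourse,
)


def make_ct(ct_by_sample: dict, panel=None, days=None):
    """Tiny CtMatrix from {sample: {gene: ct}} plus optional metadata days."""
    rows = []
    for s, genes in ct_by_sample.items():
        for g, v in genes.items():
            rows.append({"gene": g, "sample": s, "ct": v})
    data = pd.DataFrame(rows)
    samples = pd.DataFrame(
        {
            "line": "L1",
            "condition": "neutral",
            "day": [days.get(s, 0) if days else 0 for s in ct_by_sample],
            "replicate": 1,
        },
        index=pd.Index(list(ct_by_sample), name="sample"),
    )
    return sc.CtMatrix(data=data, samples=samples, panel=panel or sorted({r["gene"] for r in rows}))


class TestQcFilter:
    def test_detection_boundaries(self):
        panel = [f"g{i}" for i in range(100)]
        ct = make_ct(
            {
                "s30": {g: 20.0 for g in panel[:30]},
                "s33": {g: 20.0 for g in panel[:33]},
                "s100": {g: 20.0 for g in panel},
            },
            panel=panel,
        )
        kept = sc.qc_filter(ct)
        # 30% detected removed, exactly 33% retained (strict less-than), 100% retained
        assert list(kept.samples.index) == ["s33", "s100"]

    def test_nondetects_do_not_count_as_detected(self):
        panel = [f"g{i}" for i in range(10)]
        vals = {g: 20.0 for g in panel[:2]}
        vals.update({g: np.nan for g in panel[2:]})
        ct = make_ct({"bad": vals, "good": {g: 20.0 for g in panel}}, panel=panel)
        kept = sc.qc_filter(ct)
        assert list(kept.samples.index) == ["good"]

    def test_all_removed_raises_with_threshold(self):
        panel = [f"g{i}" for i in range(10)]
        ct = make_ct({"s1": {panel[0]: 20.0}}, panel=panel)
        with pytest.raises(EmptyResultError, match="33"):
            sc.qc_filter(ct)


class TestNormalize:
    def test_cap_applied_to_high_and_missing_values(self):
        wide = pd.DataFrame({"s1": [37.2, 20.0, np.nan]}, index=["a", "b", "c"])
        capped = sc.cap_values(wide)
        assert capped["s1"].tolist() == [35.0, 20.0, 35.0]

    def test_delta_ct_identity_for_gene_at_control_mean(self):
        wide = pd.DataFrame(
            {"s1": [16.0, 18.0, 17.0], "s2": [20.0, 22.0, 21.0]},
            index=["ACTB", "GAPDH", "target"],
        )
        delta = sc.delta_ct_scale(wide)
        # target Ct equals the control mean in both samples -> delta-Ct of 0
        assert delta.loc["target"].tolist() == [0.0, 0.0]

    def test_quantile_normalization_matches_hand_oracle(self):
        wide = pd.DataFrame(
            {"s1": [2.0, 5.0, 3.0], "s2": [4.0, 1.0, 9.0], "s3": [8.0, 6.0, 7.0]},
            index=["g1", "g2", "g3"],
        )
        qn = sc.quantile_normalize(wide)
        # oracle: sort each column, average across columns, remap by rank
        target = np.sort(wide.to_numpy(), axis=0).mean(axis=1)
        expected = wide.copy()
        for col in wide:
            ranks = wide[col].rank(method="first").astype(int) - 1
            expected[col] = target[ranks.to_numpy()]
        pd.testing.assert_frame_equal(qn, expected)

    def test_quantile_normalization_equalizes_sample_distributions(self):
        rng = np.random.default_rng(0)
        wide = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        qn = sc.quantile_normalize(wide)
        sorted_cols = np.sort(qn.to_numpy(), axis=0)
        for j in range(1, 4):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_full_normalization_range_and_provenance(self):
        ct = gen_ct_timecourse(SimulationConfig(seed=1))
        norm = sc.normalize(ct)
        vals = norm.values.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 35.0
        assert "affine" in norm.provenance

    def test_missing_control_gene_names_sample(self):
        panel = ["ACTB", "GAPDH", "g1"]
        ct = make_ct(
            {"s1": {"ACTB": 16, "GAPDH": 16, "g1": 25}, "s2": {"ACTB": 16, "g1": 25}},
            panel=panel,
        )
        with pytest.raises(PanelError, match="s2"):
            sc.normalize(ct)


@pytest.fixture(scope="module")
def norm():
    ct = gen_ct_timecourse(SimulationConfig(seed=5))
    return sc.normalize(sc.qc_filter(ct))


class TestSelectMarkers:
    def test_recovers_planted_marker_sets_exactly(self, norm):
        markers = sc.select_markers(norm)
        for name, genes in markers.as_dict().items():
            assert sorted(genes) == sorted(PLANTED_MARKERS[name]), name

    def test_sets_have_fifteen_members_and_are_disjoint(self, norm):
        markers = sc.select_markers(norm)
        sets = markers.as_dict()
        assert all(len(v) == 15 for v in sets.values())
        union = sum(sets.values(), [])
        assert len(union) == len(set(union)) == 60

    def test_control_genes_never_selected(self, norm):
        markers = sc.select_markers(norm)
        union = sum(markers.as_dict().values(), [])
        assert "ACTB" not in union and "GAPDH" not in union

    def test_too_few_genes_raises(self, norm):
        small = sc.NormalizedExpressionMatrix(
            values=norm.values.iloc[:30], samples=norm.samples, provenance={}, cap=35.0
        )
        with pytest.raises(InputError):
            sc.select_markers(small)


class TestModeratedT:
    @staticmethod
    def fixture_matrix(n_genes=5, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            rng.normal(size=(n_genes, 6)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
        )
        return X, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)]

    def test_zero_prior_df_recovers_ordinary_t(self):
        X, A, B = self.fixture_matrix()
        res = sc.moderated_t(X, A, B, prior_df=0.0)
        from scipy import stats

        ordinary = stats.ttest_ind(X[A], X[B], axis=1).statistic
        assert np.allclose(res.t.to_numpy(), ordinary)

    def test_infinite_prior_df_full_shrinkage_limit(self):
        X, A, B = self.fixture_matrix()
        s0 = 0.7
        res = sc.moderated_t(X, A, B, prior_df=np.inf, prior_s2=s0**2)
        expected = (X[A].mean(axis=1) - X[B].mean(axis=1)) / (s0 * np.sqrt(1 / 3 + 1 / 3))
        assert np.allclose(res.t.to_numpy(), expected.to_numpy())

    def test_null_calibration_against_t_distribution(self):
        """On null data with inverse-chi-square gene variances, the moderated t
        spread matches the t distribution at the shrunk degrees of freedom."""
        rng = np.random.default_rng(42)
        n_genes, d0, s0sq = 5000, 8.0, 1.0
        gene_var = d0 * s0sq / rng.chisquare(d0, size=n_genes)
        X = pd.DataFrame(
            rng.normal(0, np.sqrt(gene_var)[:, None], size=(n_genes, 6)),
            columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
        )
        res = sc.moderated_t(X, [f"a{i}" for i in range(3)], [f"b{i}" for i in range(3)])
        assert 4.0 < res.prior_df < 16.0  # recovers the simulated prior scale
        df_total = res.total_df
        theoretical_sd = np.sqrt(df_total / (df_total - 2))
        assert abs(res.t.std() - theoretical_sd) / theoretical_sd < 0.15

    def test_small_groups_rejected(self):
        X, A, B = self.fixture_matrix()
        with pytest.raises(InputError):
            sc.moderated_t(X, A[:1], B)


class TestLineageScore:
    def test_markers_at_global_mean_score_zero(self):
        t = pd.Series(np.linspace(-2, 2, 41), index=[f"g{i}" for i in range(41)])
        markers = ["g0", "g40", "g20"]  # mean == global mean
        assert sc.lineage_score(t, markers) == pytest.approx(0.0, abs=1e-12)

    def test_one_sd_excess_with_sixteen_markers_scores_four(self):
        # 16 markers at +1 and 16 other genes at -1: global mean 0, global
        # (population) sd 1, marker mean one sd above -> score = 1 * sqrt(16)
        t = pd.Series(
            [1.0] * 16 + [-1.0] * 16,
            index=[f"m{i}" for i in range(16)] + [f"g{i}" for i in range(16)],
        )
        assert sc.lineage_score(t, [f"m{i}" for i in range(16)]) == pytest.approx(4.0)

    def test_random_marker_sets_on_null_scores_are_standard_normal(self):
        rng = np.random.default_rng(2)
        t = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        scores = []
        for _ in range(1000):
            markers = rng.choice(t.index, size=15, replace=False)
            scores.append(sc.lineage_score(t, list(markers)))
        assert 0.85 <= np.std(scores) <= 1.15
        assert abs(np.mean(scores)) < 0.1

    def test_empty_markers_rejected(self):
        t = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(InputError):
            sc.lineage_score(t, [])


class TestGrading:
    @pytest.mark.parametrize(
        "score, grade",
        [
            (3.4, "+++"), (3.01, "+++"),
            (3.0, "++"), (2.0, "++"), (2.5, "++"),
            (1.99, "+"), (1.0, "+"),
            (0.99, "+/-"), (0.2, "+/-"), (-5.0, "+/-"),
            (float("nan"), "nd"),
        ],
    )
    def test_bins(self, score, grade):
        assert sc.grade_for_score(score) == grade

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_grade_total_and_consistent(self, score):
        g = sc.grade_for_score(score)
        assert g in {"+++", "++", "+", "+/-"}
        if g == "+++":
            assert score > 3
        elif g == "++":
            assert 2 <= score <= 3
        elif g == "+":
            assert 1 <= score < 2
        else:
            assert score < 1


class TestBuildScorecard:
    def test_planted_effects_yield_high_grades_and_order(self):
        ct = gen_ct_timecourse(SimulationConfig(seed=6))
        norm = sc.normalize(sc.qc_filter(ct))
        markers = sc.select_markers(norm)
        card = sc.build_scorecard(norm, markers)
        t = card.table
        assert set(t["lineage"]) == {"ectoderm", "mesoderm", "endoderm"}
        # strong planted effects under every directed condition -> +++ potential
        assert (t["potential_grade"] == "+++").all()
        # neutral effects are planted weaker than directed ones
        assert (t["potential"] > t["propensity"]).all()

    def test_missing_condition_marked_not_analyzed(self):
        ct = gen_ct_timecourse(SimulationConfig(seed=7), lines=["L1"])
        # drop the endoderm day-16 samples for the line
        meta = ct.samples
        drop = meta.index[(meta["condition"] == "endoderm") & (meta["day"] == 16)]
        ct2 = sc.CtMatrix(
            data=ct.data[~ct.data["sample"].isin(drop)].reset_index(drop=True),
            samples=meta.drop(index=drop),
            panel=ct.panel,
        )
        norm = sc.normalize(ct2)
        markers = sc.MarkerSets(**PLANTED_MARKERS)
        card = sc.build_scorecard(norm, markers)
        row = card.table[(card.table["lineage"] == "endoderm")].iloc[0]
        assert row["potential_grade"] == "nd" and np.isnan(row["potential"])

    def test_potential_monotone_in_planted_effect_size(self):
        """Mean potential rises with the planted day-16 effect size."""
        from pscqc.scorecard import MarkerSets

        markers = MarkerSets(**PLANTED_MARKERS)
        mean_potential = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            scores = []
            for seed in (0, 1, 2):
                effects = default_lineage_effects(
                    default_panel(), effect_size=effect, neutral_effect=0.0, undiff_effect=0.0
                )
                ct = gen_ct_timecourse(
                    SimulationConfig(seed=30 + seed), lineage_effects=effects, lines=["L1", "L2"]
                )
                norm = sc.normalize(ct)
                card = sc.build_scorecard(norm, markers)
                scores.extend(card.table["potential"].dropna().tolist())
            mean_potential.append(np.mean(scores))
        assert mean_potential[0] < mean_potential[1] < mean_potential[2] < mean_potential[3]
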