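"""Group statistics: t/d closed forms, split-plot ANOVA, Bonferroni, reports."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from assrlab.stats_report import (
    aggregate_per_animal,
    bonferroni,
    cohens_d,
    make_report,
    mixed_rm_anova,
    unpaired_t,
)


class TestUnpairedT:
    def test_closed_form_toy(self):
        cmp = unpaired_t([1, 2, 3], [3, 4, 5])
        assert cmp.cohens_d == pytest.approx(-2.0)   # (mean_a - mean_b) / pooled SD
        assert abs(cmp.cohens_d) == pytest.approx(2.0)
        assert abs(cmp.statistic_t) == pytest.approx(np.sqrt(6), abs=1e-12)  # 2.449
        assert cmp.df == 4

    def test_identical_groups_null(self):
        cmp = unpaired_t([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert (cmp.statistic_t, cmp.cohens_d, cmp.p_value) == (0.0, 0.0, 1.0)

    def test_t_squared_equals_oneway_f(self, rng):
        a, b = rng.standard_normal(7) + 0.5, rng.standard_normal(6)
        cmp = unpaired_t(a, b)
        f, _ = sps.f_oneway(a, b)
        assert cmp.statistic_t ** 2 == pytest.approx(f, rel=1e-10)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 100.0))
    def test_cohens_d_scale_invariant(self, seed, c):
        r = np.random.default_rng(seed)
        a, b = r.standard_normal(5), r.standard_normal(6) + 1
        assert cohens_d(c * a, c * b) == pytest.approx(cohens_d(a, b), rel=1e-9)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            unpaired_t([1.0], [1.0, 2.0])

    def test_type_one_error_rate_at_nominal_alpha(self):
        """Null per-animal cohorts (7 vs 6): ~5% rejections at alpha=0.05."""
        r = np.random.default_rng(77)
        n_rep = 1000
        a = r.standard_normal((n_rep, 7))
        b = r.standard_normal((n_rep, 6))
        _, p = sps.ttest_ind(a, b, axis=1, equal_var=True)
        rate = (p < 0.05).mean()
        assert 0.03 <= rate <= 0.07


class TestAggregate:
    def test_channel_mean_within_animal(self):
        df = pd.DataFrame({"animal_id": ["a", "a"], "value": [1.0, 3.0]})
        assert aggregate_per_animal(df)["value"].tolist() == [2.0]

    def test_single_channel_identity(self):
        df = pd.DataFrame({"animal_id": list("abc"), "value": [1.0, 2.0, 3.0]})
        assert aggregate_per_animal(df)["value"].tolist() == [1.0, 2.0, 3.0]

    def test_study_cohort_shape(self, rng):
        """31 control channels over 7 animals, 26 mutant over 6: outputs 7 and 6."""
        ctrl_channels = [2, 6, 3, 6, 6, 3, 5]
        mut_channels = [5, 4, 6, 5, 3, 3]
        rows = []
        for g, counts in (("control", ctrl_channels), ("mutant", mut_channels)):
            for i, k in enumerate(counts):
                rows += [
                    {"animal_id": f"{g}{i}", "genotype": g, "value": rng.standard_normal()}
                    for _ in range(k)
                ]
        df = pd.DataFrame(rows)
        assert len(df) == 31 + 26
        out = aggregate_per_animal(df)
        assert (out["genotype"] == "control").sum() == 7
        assert (out["genotype"] == "mutant").sum() == 6

    def test_missing_animal_tag_rejected(self):
        with pytest.raises(ValueError, match="animal_id"):
            aggregate_per_animal(pd.DataFrame({"value": [1.0]}))


def toy_state_table(values, epochs=("Pre", "ISI1", "Post")):
    """Balanced table: subjects x epochs with explicit values per genotype."""
    rows = []
    for (animal, geno), vals in values.items():
        for e, v in zip(epochs, vals):
            rows.append(
                {"animal_id": animal, "channel_id": "c1", "genotype": geno,
                 "epoch": e, "band": "35-44", "mean_power": v}
            )
    return pd.DataFrame(rows)


def split_plot_oracle(wide, groups):
    """Hand-computed split-plot sums of squares (textbook formulas)."""
    a = len(set(groups))
    n = len(groups) // a
    b = wide.shape[1]
    grand = wide.mean()
    gm = {g: wide[[i for i, gg in enumerate(groups) if gg == g]].mean()
          for g in set(groups)}
    ss_a = sum(n * b * (gm[g] - grand) ** 2 for g in set(groups))
    subj_means = wide.mean(axis=1)
    ss_subj = b * sum((subj_means[i] - gm[groups[i]]) ** 2 for i in range(len(groups)))
    ep_means = wide.mean(axis=0)
    ss_b = a * n * ((ep_means - grand) ** 2).sum()
    ss_ab = 0.0
    for g in set(groups):
        sub = wide[[i for i, gg in enumerate(groups) if gg == g]]
        for j in range(b):
            ss_ab += n * (sub[:, j].mean() - gm[g] - ep_means[j] + grand) ** 2
    ss_tot = ((wide - grand) ** 2).sum()
    ss_err = ss_tot - ss_a - ss_subj - ss_b - ss_ab
    ms_a = ss_a / (a - 1)
    ms_subj = ss_subj / (a * (n - 1))
    ms_b = ss_b / (b - 1)
    ms_ab = ss_ab / ((a - 1) * (b - 1))
    ms_err = ss_err / (a * (n - 1) * (b - 1))
    return ms_a / ms_subj, ms_b / ms_err, ms_ab / ms_err


class TestMixedAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        """4 subjects x 3 epochs split-plot against the textbook SS oracle."""
        wide = np.array(
            [[3.0, 5.0, 4.0], [4.0, 6.0, 6.0], [7.0, 9.0, 10.0], [8.0, 11.0, 12.0]]
        )
        groups = ["control", "control", "mutant", "mutant"]
        f_a, f_b, f_ab = split_plot_oracle(wide, groups)
        table = toy_state_table(
            {
                ("s1", "control"): wide[0], ("s2", "control"): wide[1],
                ("s3", "mutant"): wide[2], ("s4", "mutant"): wide[3],
            }
        )
        res = mixed_rm_anova(table)
        assert res.F_between == pytest.approx(f_a, abs=1e-10)
        assert res.F_within == pytest.approx(f_b, abs=1e-10)
        assert res.F_interaction == pytest.approx(f_ab, abs=1e-10)
        assert res.df_between == (1, 2)

    def test_matches_pingouin_reference(self, rng):
        """Independent cross-check against pingouin's mixed ANOVA."""
        pg = pytest.importorskip("pingouin")
        values = {
            (f"s{i}", "control" if i < 4 else "mutant"): rng.standard_normal(3)
            for i in range(8)
        }
        table = toy_state_table(values)
        res = mixed_rm_anova(table)
        long = table.rename(columns={"mean_power": "y"})
        ref = pg.mixed_anova(
            data=long, dv="y", within="epoch", subject="animal_id", between="genotype"
        ).set_index("Source")
        assert res.F_between == pytest.approx(ref.loc["genotype", "F"], rel=1e-8)
        assert res.F_within == pytest.approx(ref.loc["epoch", "F"], rel=1e-8)
        assert res.F_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-8)

    def test_null_table_f_near_one_over_replicates(self):
        """Identical epoch profiles + noise: F_between averages ~1."""
        r = np.random.default_rng(5)
        fs = []
        for _ in range(300):
            values = {
                (f"s{i}", "control" if i < 3 else "mutant"): r.standard_normal(3)
                for i in range(6)
            }
            fs.append(mixed_rm_anova(toy_state_table(values)).F_between)
        # F(1, 4): mean = df2/(df2-2) = 2; median more stable ~ 0.5
        assert np.median(fs) == pytest.approx(sps.f.ppf(0.5, 1, 4), rel=0.3)

    def test_degenerate_identical_observations_flagged(self):
        values = {(f"s{i}", "control" if i < 2 else "mutant"): [1.0, 1.0, 1.0]
                  for i in range(4)}
        res = mixed_rm_anova(toy_state_table(values))
        assert res.degenerate
        assert np.isnan(res.F_between)

    def test_missing_cell_rejected(self):
        table = toy_state_table(
            {("s1", "control"): [1, 2, 3], ("s2", "control"): [2, 3, 4],
             ("s3", "mutant"): [1, 2, 3], ("s4", "mutant"): [2, 3, 4]}
        ).drop(index=[0])
        with pytest.raises(ValueError, match="missing cells"):
            mixed_rm_anova(table)

    def test_posthoc_family_is_epoch_pairs_within_genotype(self):
        r = np.random.default_rng(6)
        values = {
            (f"s{i}", "control" if i < 3 else "mutant"): r.standard_normal(5)
            for i in range(6)
        }
        table = toy_state_table(values, epochs=("Pre", "ISI1", "ISI25", "ISI50", "Post"))
        res = mixed_rm_anova(table)
        assert res.n_comparisons == 2 * 10  # 2 genotypes x C(5,2) pairs
        assert (res.posthoc["p_bonferroni"] >= res.posthoc["p_raw"] - 1e-15).all()
        assert (res.posthoc["p_bonferroni"] <= 1.0).all()


class TestBonferroni:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_monotone_never_below_raw_capped(self, ps):
        adj = bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestMakeReport:
    def test_tables_and_manifest_written(self, tmp_path):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        paths = make_report({"state_table": df, "manifest": {"seed": 3}}, tmp_path)
        names = {p.name for p in paths}
        assert names == {"state_table.tsv", "manifest.json"}
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["seed"] == 3
        assert manifest["tables"] == ["state_table.tsv"]

    def test_empty_results_manifest_only(self, tmp_path):
        paths = make_report({}, tmp_path)
        assert [p.name for p in paths] == ["manifest.json"]

    def test_repeat_runs_byte_identical(self, tmp_path, rng):
        df = pd.DataFrame({"x": rng.standard_normal(5)})
        make_report({"t": df}, tmp_path / "r1")
        make_report({"t": df}, tmp_path / "r2")
        assert (tmp_path / "r1/t.tsv").read_bytes() == (tmp_path / "r2/t.tsv").read_bytes()
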