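"""ANOVA/ANCOVA fold change, relative expression, repeated measures, CLD."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

import qpcrkit as qk


@pytest.fixture
def one_factor_noisy():
    spec = qk.SyntheticSpec(
        design={"factor1": ["L1", "L2", "L3"]},
        true_re={"L1": 1.0, "L2": 0.5, "L3": 0.2},
        n_rep=4, noise_sd=0.2, seed=21,
    )
    return qk.generate_dataset(spec)


@pytest.fixture
def two_factor_noisy():
    spec = qk.SyntheticSpec(
        design={"geno": ["S", "R"], "dose": ["0", "0.5"]},
        true_re={("S", "0.5"): 3.0, ("S", "0"): 0.8},
        n_rep=3, noise_sd=0.15, seed=22,
    )
    return qk.generate_dataset(spec)


def quiet(fn, *a, **k):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*a, **k)


class TestFitWdctModel:
    def test_anova_table_has_factor_and_residual_lines(self, one_factor_noisy):
        fit = quiet(qk.fit_wdct_model, one_factor_noisy)
        assert "factor1" in fit.anova.index
        assert fit.anova.loc["factor1", "p"] <= 1.0

    def test_anova_includes_interaction_ancova_does_not(self, two_factor_noisy):
        fa = quiet(qk.fit_wdct_model, two_factor_noisy, analysis_type="anova")
        fc = quiet(qk.fit_wdct_model, two_factor_noisy, main_factor="geno",
                   analysis_type="ancova")
        assert any(":" in t for t in fa.anova.index)
        assert not any(":" in t for t in fc.anova.index)

    def test_noiseless_distinct_means_give_infinite_f(self):
        spec = qk.SyntheticSpec(
            design={"f": ["A", "B", "C"]}, true_re={"B": 2.0, "C": 4.0},
            noise_sd=0.0, seed=23,
        )
        fit = quiet(qk.fit_wdct_model, qk.generate_dataset(spec))
        assert np.isinf(fit.anova.loc["f", "F"])
        assert fit.anova.loc["f", "p"] == 0.0

    def test_main_factor_must_have_two_levels(self):
        spec = qk.SyntheticSpec(design={"f": ["A"]}, n_rep=3, seed=1)
        with pytest.raises(ValueError, match="levels"):
            quiet(qk.fit_wdct_model, qk.generate_dataset(spec))

    def test_residuals_sum_to_zero(self, one_factor_noisy):
        fit = quiet(qk.fit_wdct_model, one_factor_noisy, random_effects=False)
        assert float(np.sum(fit.residuals)) == pytest.approx(0.0, abs=1e-8)


class TestAnovaFc:
    def test_calibrator_row_is_exactly_one(self, one_factor_noisy):
        _, rows = quiet(qk.anova_fc, one_factor_noisy, calibrator="L1")
        assert rows[0].label == "L1"
        assert rows[0].fc == 1.0
        assert rows[0].p_value == 1.0

    def test_noiseless_recovery_of_true_fc_map(self):
        spec = qk.SyntheticSpec(
            design={"f": ["L1", "L2", "L3"]},
            true_re={"L1": 1.0, "L2": 2.0, "L3": 8.0},
            noise_sd=0.0, seed=24,
        )
        _, rows = quiet(qk.anova_fc, qk.generate_dataset(spec), calibrator="L1")
        by = {r.label: r.fc for r in rows}
        assert by["L2 vs L1"] == pytest.approx(2.0, rel=1e-12)
        assert by["L3 vs L1"] == pytest.approx(8.0, rel=1e-12)

    def test_unknown_calibrator_rejected(self, one_factor_noisy):
        with pytest.raises(ValueError, match="calibrator"):
            quiet(qk.anova_fc, one_factor_noisy, calibrator="L9")

    def test_two_level_case_agrees_with_pooled_ttest(self):
        spec = qk.SyntheticSpec(
            design={"f": ["Co", "Tr"]}, true_re={"Tr": 3.0},
            n_rep=5, noise_sd=0.3, seed=25,
        )
        tab = qk.generate_dataset(spec)
        fit, rows = quiet(qk.anova_fc, tab, calibrator="Co", random_effects=False)
        af = tab.analysis_frame()
        co = af.loc[af["f"] == "Co", "wdct"]
        tr = af.loc[af["f"] == "Tr", "wdct"]
        ref = stats.ttest_ind(tr, co)
        r = rows[1]
        assert r.fc == pytest.approx(2 ** -(tr.mean() - co.mean()), rel=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        # F = t^2 on the model side
        assert fit.anova.loc["f", "F"] == pytest.approx(ref.statistic**2, rel=1e-9)

    def test_significant_interaction_triggers_warning(self):
        spec = qk.SyntheticSpec(
            design={"a": ["x", "y"], "b": ["u", "v"]},
            true_re={("x", "u"): 1.0, ("x", "v"): 8.0,
                     ("y", "u"): 8.0, ("y", "v"): 1.0},
            n_rep=4, noise_sd=0.1, seed=26,
        )
        with pytest.warns(UserWarning, match="interaction"):
            qk.anova_fc(qk.generate_dataset(spec), main_factor="a",
                        random_effects=False)

    def test_ancova_zero_effect_covariate_matches_anova(self):
        # covariate truly inert: ANCOVA FC estimates track the ANOVA ones
        spec = qk.SyntheticSpec(
            design={"a": ["L1", "L2"], "b": ["u", "v"]},
            true_re={("L2", "u"): 4.0, ("L2", "v"): 4.0},
            n_rep=4, noise_sd=0.2, seed=27,
        )
        tab = qk.generate_dataset(spec)
        _, r_an = quiet(qk.anova_fc, tab, main_factor="a", analysis_type="anova")
        _, r_ac = quiet(qk.anova_fc, tab, main_factor="a", analysis_type="ancova")
        assert r_ac[1].fc == pytest.approx(r_an[1].fc, rel=0.05)


class TestAnovaRe:
    def test_re_ratios_equal_fc_contrasts(self, one_factor_noisy):
        fit, re_rows = quiet(qk.anova_re, one_factor_noisy)
        _, fc_rows = quiet(qk.anova_fc, one_factor_noisy, calibrator="L1")
        re_by = {r.levels[0]: r.re for r in re_rows}
        fc_by = {r.label: r.fc for r in fc_rows}
        assert re_by["L2"] / re_by["L1"] == pytest.approx(
            fc_by["L2 vs L1"], rel=1e-9
        )
        assert re_by["L3"] / re_by["L1"] == pytest.approx(
            fc_by["L3 vs L1"], rel=1e-9
        )

    def test_rows_sorted_descending_by_re(self, two_factor_noisy):
        _, rows = quiet(qk.anova_re, two_factor_noisy)
        res = [r.re for r in rows]
        assert res == sorted(res, reverse=True)

    def test_cell_count_matches_design(self, two_factor_noisy):
        _, rows = quiet(qk.anova_re, two_factor_noisy)
        assert len(rows) == 4

    def test_identical_conditions_share_one_letter(self):
        spec = qk.SyntheticSpec(
            design={"f": ["A", "B", "C"]}, noise_sd=0.0, n_rep=3, seed=28
        )
        # add microscopic noise so the model is not perfectly degenerate
        tab = qk.generate_dataset(spec)
        tab.data["targetCt"] += np.random.default_rng(0).normal(0, 1e-6, 9)
        _, rows = quiet(qk.anova_re, tab)
        assert all(r.letter == rows[0].letter for r in rows)
        assert all(r.re == pytest.approx(1.0, abs=1e-4) for r in rows)

    def test_letters_respect_pairwise_significance(self, one_factor_noisy):
        fit, rows = quiet(qk.anova_re, one_factor_noisy, alpha=0.05)
        # L1 (RE 1) vs L3 (RE 0.2) are far apart under noise_sd 0.2, n 4
        by = {r.levels[0]: r.letter for r in rows}
        assert not set(by["L1"]) & set(by["L3"])


class TestRepeated:
    def test_noiseless_fc_recovery(self):
        t = qk.generate_repeated_dataset(
            n_id=3, times=("T1", "T2"), true_fc_vs_baseline={"T2": 4.0},
            noise_sd=0.0, seed=29,
        )
        _, rows = quiet(qk.repeated_fc, t)
        assert rows[1].fc == pytest.approx(4.0, rel=1e-12)

    def test_id_offsets_absorbed_by_random_intercept(self):
        t = qk.generate_repeated_dataset(
            n_id=4, times=("T1", "T2", "T3"),
            true_fc_vs_baseline={"T2": 2.0, "T3": 0.5},
            id_sd=0.8, noise_sd=0.0, seed=30,
        )
        _, rows = quiet(qk.repeated_fc, t)
        by = {r.label: r.fc for r in rows}
        assert by["T2 vs T1"] == pytest.approx(2.0, rel=1e-9)
        assert by["T3 vs T1"] == pytest.approx(0.5, rel=1e-9)

    def test_baseline_row_is_one(self):
        t = qk.generate_repeated_dataset(noise_sd=0.1, seed=31)
        _, rows = quiet(qk.repeated_fc, t, baseline="T1")
        assert rows[0].label == "T1"
        assert rows[0].fc == 1.0

    def test_treatment_crossed_design_fits(self):
        t = qk.generate_repeated_dataset(
            n_id=3, times=("T1", "T2"), treatments=("ctl", "drug"),
            true_fc_vs_baseline={"T2": 2.0}, noise_sd=0.1, seed=32,
        )
        fit, rows = quiet(qk.repeated_fc, t)
        assert {r.label for r in rows} == {"T1", "T2 vs T1"}
        assert any("treatment" in term for term in fit.anova.index)


class TestQpcrMeans:
    def test_main_effect_three_levels_three_contrasts(self, one_factor_noisy):
        fit = quiet(qk.fit_wdct_model, one_factor_noisy)
        out = quiet(qk.qpcr_means, fit, "factor1")
        assert len(out) == 3

    def test_slicing_two_by_two_design(self, two_factor_noisy):
        fit = quiet(qk.fit_wdct_model, two_factor_noisy)
        out = quiet(qk.qpcr_means, fit, "geno | dose")
        assert len(out) == 2  # one geno contrast per dose slice
        assert set(out["dose"]) == {"0", "0.5"}

    def test_interaction_cells_all_pairs(self, two_factor_noisy):
        fit = quiet(qk.fit_wdct_model, two_factor_noisy)
        out = quiet(qk.qpcr_means, fit, "geno:dose")
        assert len(out) == 6  # C(4, 2)

    def test_balanced_marginal_means_equal_cell_mean_averages(self, two_factor_noisy):
        fit = quiet(qk.fit_wdct_model, two_factor_noisy, random_effects=False)
        emm = qk.marginal_means(fit, "geno")
        af = two_factor_noisy.analysis_frame()
        cell = af.groupby(["geno", "dose"], observed=True)["wdct"].mean()
        for _, row in emm.iterrows():
            assert row["emmean"] == pytest.approx(
                cell.loc[row["geno"]].mean(), rel=1e-9
            )

    def test_absent_effect_rejected(self, one_factor_noisy):
        fit = quiet(qk.fit_wdct_model, one_factor_noisy)
        with pytest.raises(ValueError, match="not in the model"):
            qk.qpcr_means(fit, "ghost")


def brute_force_cliques(adj):
    """All maximal cliques of a small graph, by subset enumeration."""
    n = len(adj)
    cliques = []
    for size in range(n, 0, -1):
        for sub in itertools.combinations(range(n), size):
            if all(adj[i][j] for i, j in itertools.combinations(sub, 2)):
                s = set(sub)
                if not any(s < c for c in cliques):
                    cliques.append(s)
    return cliques


class TestCompactLetterDisplay:
    def test_all_nonsignificant_single_letter(self):
        out = qk.compact_letter_display(list("abc"), np.ones((3, 3)))
        assert out == ["a", "a", "a"]

    def test_all_significant_distinct_letters(self):
        p = np.zeros((4, 4))
        np.fill_diagonal(p, 1.0)
        out = qk.compact_letter_display(list("wxyz"), p)
        assert out == ["a", "b", "c", "d"]

    def test_three_group_chain(self):
        p = np.array([[1, 0.001, 0.001], [0.001, 1, 0.9], [0.001, 0.9, 1]])
        assert qk.compact_letter_display(list("abc"), p) == ["a", "b", "b"]

    def test_asymmetric_matrix_rejected(self):
        p = np.array([[1, 0.2], [0.3, 1]])
        with pytest.raises(ValueError, match="symmetric"):
            qk.compact_letter_display(["a", "b"], p)

    def test_share_letter_iff_nonsignificant_random_suite(self):
        rng = np.random.default_rng(77)
        alpha = 0.05
        for _ in range(200):
            n = rng.integers(2, 6)
            p = np.ones((n, n))
            iu = np.triu_indices(n, 1)
            vals = np.where(rng.random(len(iu[0])) < 0.5,
                            rng.uniform(0, alpha, len(iu[0])),
                            rng.uniform(alpha, 1, len(iu[0])))
            p[iu] = vals
            p = np.triu(p) + np.triu(p, 1).T
            letters = qk.compact_letter_display([str(i) for i in range(n)], p, alpha)
            adj = p >= alpha
            for i, j in itertools.combinations(range(n), 2):
                share = bool(set(letters[i]) & set(letters[j]))
                assert share == bool(adj[i, j]), (p, letters)
            # every letter group is contained in a maximal clique
            cliques = brute_force_cliques(adj)
            for letter in set("".join(letters)):
                group = {i for i in range(n) if letter in letters[i]}
                assert any(group <= c for c in cliques), (p, letters)


class TestAgainstRMixedModelOracle:
    def test_contrast_matches_lmer_emmeans(self, tmp_path):
        """Mixed-model contrast estimate/SE/df agree with lmerTest+emmeans."""
        spec = qk.SyntheticSpec(
            design={"f": ["Co", "Tr"]}, true_re={"Tr": 4.0},
            n_rep=6, noise_sd=0.25, rep_sd=0.3, seed=4242,
        )
        tab = qk.generate_dataset(spec)
        fit, rows = quiet(qk.anova_fc, tab, calibrator="Co")
        assert fit.is_mixed
        csv = tmp_path / "d.csv"
        tab.analysis_frame().to_csv(csv, index=False)
        script = (
            "suppressMessages({library(lmerTest); library(emmeans)});"
            f"d <- read.csv('{csv}');"
            "m <- lmer(wdct ~ f + (1|rep), data=d);"
            "s <- summary(contrast(emmeans(m, 'f'), 'revpairwise'));"
            "cat(s$estimate, s$SE, s$df, sep=',')"
        )
        import subprocess

        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        assert proc.returncode == 0, proc.stderr
        est_r, se_r, df_r = map(float, proc.stdout.strip().split(","))
        r = rows[1]
        assert np.log2(r.fc) == pytest.approx(-est_r, rel=1e-5)
        assert r.se_log2 == pytest.approx(se_r, rel=1e-4)
        assert fit.df_contrast == pytest.approx(df_r, abs=0.51)


class TestResidualDiagnostics:
    def test_normal_residuals_pass(self):
        spec = qk.SyntheticSpec(
            design={"f": ["A", "B"]}, n_rep=15, noise_sd=0.3, seed=33
        )
        fit = quiet(qk.fit_wdct_model, qk.generate_dataset(spec))
        rep = qk.residual_diagnostics(fit)
        assert rep.shapiro_p > 0.05
        assert "no evidence" in rep.advisory

    def test_heavy_tailed_residuals_flagged(self):
        spec = qk.SyntheticSpec(design={"f": ["A", "B"]}, n_rep=50,
                                noise_sd=0.0, seed=34)
        tab = qk.generate_dataset(spec)
        rng = np.random.default_rng(35)
        tab.data["targetCt"] += rng.standard_cauchy(100) * 0.2
        fit = quiet(qk.fit_wdct_model, tab, random_effects=False)
        rep = qk.residual_diagnostics(fit)
        assert rep.shapiro_p < 0.05
        assert "Kruskal-Wallis" in rep.advisory or "Mann-Whitney" in rep.advisory

    def test_constant_residuals_flagged_degenerate(self):
        spec = qk.SyntheticSpec(design={"f": ["A", "B"]}, noise_sd=0.0, seed=36)
        fit = quiet(qk.fit_wdct_model, qk.generate_dataset(spec),
                    random_effects=False)
        rep = qk.residual_diagnostics(fit)
        assert rep.degenerate
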