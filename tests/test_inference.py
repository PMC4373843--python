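import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comethnet import (
    BetaMatrix,
    CoMethNetError,
    SampleSheet,
    SimulationConfig,
    age_effect,
    effect_concordance,
    fit_acceleration,
    hypermethylation_count_test,
    module_eigenvector,
    paired_hiv_effect,
    reffree_adjust,
    rmt_dimension,
    simulate_cohort,
    storey_qvalues,
    unpaired_hiv_screen,
)
from comethnet.simulate import CellMixSpec

from .oracles import benjamini_hochberg, t_two_sided_p


def _paired_sheet(n_pairs, ages=None):
    rows = []
    for i in range(n_pairs):
        age = 30.0 if ages is None else ages[i]
        rows.append((f"p{i}_sp", age, 1, f"P{i}"))
        rows.append((f"p{i}_sn", age, 0, f"P{i}"))
    df = pd.DataFrame(
        rows, columns=["sample_id", "age", "hiv_status", "pair_id"]
    ).set_index("sample_id")
    return SampleSheet(df)


class TestPairedHivEffect:
    def test_zero_differences_reported_missing(self):
        sheet = _paired_sheet(6)
        values = np.tile(np.linspace(0.2, 0.7, 12), (3, 1))
        beta = BetaMatrix(pd.DataFrame(
            values, index=["a", "b", "c"], columns=sheet.sample_ids
        ))
        # each pair's SP and SN values are equal -> all differences zero
        eq = beta.values.copy()
        for sp, sn in sheet.pairs():
            eq[sp] = eq[sn]
        out = paired_hiv_effect(BetaMatrix(eq), sheet)
        assert out["t"].isna().all()

    def test_alternating_differences_cancel(self):
        sheet = _paired_sheet(24)
        sp = [p[0] for p in sheet.pairs()]
        sn = [p[1] for p in sheet.pairs()]
        values = pd.DataFrame(0.5, index=["probe"], columns=sheet.sample_ids)
        for j, s in enumerate(sp):
            values.at["probe", s] = 0.5 + (0.1 if j % 2 == 0 else -0.1)
        out = paired_hiv_effect(BetaMatrix(values), sheet)
        assert out.at["probe", "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.at["probe", "p"] == pytest.approx(1.0)
        assert out.at["probe", "signed_log_p"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_cdf_oracle_on_small_vector(self):
        diffs = np.array([0.02, -0.01, 0.03, 0.015, 0.005])
        sheet = _paired_sheet(5)
        sp = [p[0] for p in sheet.pairs()]
        sn = [p[1] for p in sheet.pairs()]
        values = pd.DataFrame(0.5, index=["probe"], columns=sheet.sample_ids)
        values.loc["probe", sp] = 0.5 + diffs
        values.loc["probe", sn] = 0.5
        out = paired_hiv_effect(BetaMatrix(values), sheet)
        t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert out.at["probe", "t"] == pytest.approx(t_expected)
        assert out.at["probe", "p"] == pytest.approx(
            t_two_sided_p(t_expected, 4), abs=1e-8
        )
        assert out.at["probe", "signed_log_p"] == pytest.approx(
            -np.log10(out.at["probe", "p"])
        )


class TestUnpairedScreen:
    def test_type_one_error_calibrated_on_null(self):
        cfg = SimulationConfig(seed=5, n_probes=1000, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        out = unpaired_hiv_screen(beta, sheet)
        frac = (out["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_t_matches_cdf_oracle(self):
        cfg = SimulationConfig(seed=5, n_probes=20, n_pairs=8, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        out = unpaired_hiv_screen(beta, sheet)
        df = 2 * 8 - 2
        for probe in beta.probe_ids[:5]:
            t = out.at[probe, "t"]
            assert out.at[probe, "p"] == pytest.approx(
                t_two_sided_p(t, df), abs=1e-8
            )

    def test_welch_option_changes_df(self):
        cfg = SimulationConfig(seed=5, n_probes=50, n_pairs=8, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        student = unpaired_hiv_screen(beta, sheet, equal_var=True)
        welch = unpaired_hiv_screen(beta, sheet, equal_var=False)
        assert not np.allclose(student["p"], welch["p"])


class TestStoreyQvalues:
    def test_all_ones_stay_ones(self):
        q = storey_qvalues(np.ones(50))
        np.testing.assert_allclose(q, 1.0)

    def test_reduces_to_bh_when_pi0_forced_to_one(self, rng):
        p = rng.random(500)
        q = storey_qvalues(p, pi0=1.0)
        np.testing.assert_allclose(q, benjamini_hochberg(p), atol=1e-12)

    def test_proportional_to_bh_by_pi0_factor(self, rng):
        for _ in range(3):
            p = rng.random(400) ** 2  # enriched near zero so pi0 < 1
            q = storey_qvalues(p)
            bh = benjamini_hochberg(p)
            assert (q <= 1.0 + 1e-12).all()
            assert (q <= bh + 1e-12).all()  # pi0 <= 1 can only shrink BH
            # away from the cap, Storey q / BH is the constant pi0 estimate
            free = (bh < 0.99) & (q < 0.99) & (bh > 0)
            ratio = q[free] / bh[free]
            np.testing.assert_allclose(ratio, ratio[0], atol=1e-8)

    def test_missing_pvalues_propagate(self):
        p = np.array([0.01, np.nan, 0.5])
        q = storey_qvalues(p)
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(CoMethNetError):
            storey_qvalues(np.array([0.5, 1.5]))


class TestAgeEffect:
    def test_linear_function_of_age_has_r_one(self):
        ages = np.linspace(22, 54, 8)
        sheet = _paired_sheet(8, ages=ages)
        full_ages = sheet.age.to_numpy()
        values = pd.DataFrame(
            {
                "up": 0.2 + 0.01 * full_ages,
                "down": 0.8 - 0.01 * full_ages,
            }
        ).T
        values.columns = sheet.sample_ids
        out = age_effect(BetaMatrix(values), sheet)
        assert out.at["up", "r"] == pytest.approx(1.0)
        assert out.at["down", "r"] == pytest.approx(-1.0)

    def test_planted_module_shows_age_signal(self, small_cohort):
        beta, sheet, _, truth = small_cohort
        out = age_effect(beta, sheet)
        members = truth.labels[truth.labels == 1].index
        background = truth.labels[truth.labels == 0].index
        assert out.loc[members, "r"].median() > out.loc[background, "r"].median()

    def test_subset_selector(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        sn_only = [s for s in sheet.sample_ids if sheet.hiv_status[s] == 0]
        out = age_effect(beta, sheet, subset=sn_only)
        assert out["r"].abs().max() <= 1.0


class TestEffectConcordance:
    def test_identity_gives_r_one(self, rng):
        x = pd.Series(rng.standard_normal(100), index=[f"p{i}" for i in range(100)])
        r, p = effect_concordance(x, x)
        assert r == pytest.approx(1.0)

    def test_independent_noise_is_weak(self):
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(10_000)]
        x = pd.Series(rng.standard_normal(10_000), index=idx)
        y = pd.Series(rng.standard_normal(10_000), index=idx)
        r, _ = effect_concordance(x, y)
        assert abs(r) < 0.03

    def test_symmetric_and_affine_invariant(self, rng):
        idx = [f"p{i}" for i in range(200)]
        x = pd.Series(rng.standard_normal(200), index=idx)
        y = pd.Series(x.to_numpy() + rng.standard_normal(200), index=idx)
        r_xy, _ = effect_concordance(x, y)
        r_yx, _ = effect_concordance(y, x)
        r_scaled, _ = effect_concordance(3.0 * x - 1.0, y)
        assert r_xy == pytest.approx(r_yx)
        assert r_xy == pytest.approx(r_scaled)

    def test_shared_planted_structure_concordant_across_cohorts(self):
        cfg_a = SimulationConfig(seed=11, probe_seed=50, n_pairs=12, n_probes=500)
        cfg_b = SimulationConfig(seed=12, probe_seed=50, n_pairs=12, n_probes=500)
        beta_a, sheet_a, _, _ = simulate_cohort(cfg_a)
        beta_b, sheet_b, _, _ = simulate_cohort(cfg_b)
        t_a = unpaired_hiv_screen(beta_a, sheet_a)["t"]
        t_b = unpaired_hiv_screen(beta_b, sheet_b)["t"]
        r_shared, _ = effect_concordance(t_a, t_b)
        # control: no planted HIV effect
        from comethnet import PlantedModule

        null_mod = [PlantedModule(size=300, gamma_hiv=0.0)]
        cfg_c = SimulationConfig(seed=11, probe_seed=50, n_pairs=12, n_probes=500,
                                 modules=null_mod)
        cfg_d = SimulationConfig(seed=12, probe_seed=50, n_pairs=12, n_probes=500,
                                 modules=null_mod)
        beta_c, sheet_c, _, _ = simulate_cohort(cfg_c)
        beta_d, sheet_d, _, _ = simulate_cohort(cfg_d)
        r_null, _ = effect_concordance(
            unpaired_hiv_screen(beta_c, sheet_c)["t"],
            unpaired_hiv_screen(beta_d, sheet_d)["t"],
        )
        assert r_shared > 0 and r_shared > r_null


class TestFitAcceleration:
    def test_reproduces_normal_equations(self, small_cohort):
        beta, sheet, _, truth = small_cohort
        ev = module_eigenvector(beta, truth.labels[truth.labels == 1].index, 1)
        fit = fit_acceleration(ev, sheet)
        X = np.column_stack([
            np.ones(len(sheet.sample_ids)),
            sheet.age.to_numpy(),
            sheet.hiv_status.to_numpy(dtype=float),
        ])
        y = ev.scores.loc[sheet.sample_ids].to_numpy()
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(
            [fit.intercept, fit.beta_age, fit.beta_hiv], coef, atol=1e-10
        )

    def test_null_hiv_effect_ci_covers_zero(self):
        from comethnet import PlantedModule

        covered = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, n_pairs=12, n_probes=300,
                modules=[PlantedModule(size=100, gamma_hiv=0.0)],
            )
            beta, sheet, _, truth = simulate_cohort(cfg)
            ev = module_eigenvector(beta, truth.labels[truth.labels == 1].index, 1)
            fit = fit_acceleration(ev, sheet)
            lo, hi = fit.acceleration_ci()
            covered += lo <= 0.0 <= hi
        assert covered >= 8

    def test_rank_deficient_design_rejected(self):
        # age constant within each serostatus group (and overall)
        sheet = _paired_sheet(6)
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.standard_normal(12), index=sheet.sample_ids)
        with pytest.raises(CoMethNetError):
            fit_acceleration(scores, sheet)

    def test_delta_method_se_positive(self, small_cohort):
        beta, sheet, _, truth = small_cohort
        ev = module_eigenvector(beta, truth.labels[truth.labels == 1].index, 1)
        fit = fit_acceleration(ev, sheet)
        assert fit.acceleration_se > 0
        lo, hi = fit.acceleration_ci()
        assert lo < fit.acceleration_years < hi


class TestRmtDimension:
    def test_iid_noise_has_dimension_zero(self):
        rng = np.random.default_rng(0)
        assert rmt_dimension(rng.standard_normal((48, 2000))) == 0

    def test_one_planted_factor(self):
        rng = np.random.default_rng(0)
        R = rng.standard_normal((48, 2000))
        R += np.outer(rng.standard_normal(48), rng.standard_normal(2000) * 0.5)
        assert rmt_dimension(R) == 1

    def test_second_factor_never_decreases_dimension(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((48, 2000))
        one = base + np.outer(
            rng.standard_normal(48), rng.standard_normal(2000) * 0.5
        )
        two = one + np.outer(
            rng.standard_normal(48), rng.standard_normal(2000) * 0.5
        )
        assert rmt_dimension(two) >= rmt_dimension(one)

    def test_too_few_samples_rejected(self):
        with pytest.raises(CoMethNetError):
            rmt_dimension(np.zeros((3, 100)))


class TestReffreeAdjust:
    def test_k_zero_is_identity(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        fit = reffree_adjust(beta, sheet, k=0)
        pd.testing.assert_frame_equal(fit.unadjusted, fit.adjusted)

    def test_clean_simulation_concordant(self):
        cfg = SimulationConfig(seed=3, n_probes=500, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        fit = reffree_adjust(beta, sheet)
        assert fit.concordance["hiv_status"] > 0.95
        assert fit.concordance["age"] > 0.95

    def test_confounded_mixture_shrinks_hiv_coefficients(self):
        spec = CellMixSpec(hiv_concentration=(12.0, 3.0, 1.5))
        conf = SimulationConfig(seed=3, n_probes=800, modules=[], cell_types=spec)
        beta, sheet, _, _ = simulate_cohort(conf)
        fit = reffree_adjust(beta, sheet)
        assert fit.k_latent >= 1
        assert (
            fit.adjusted["hiv_status"].abs().mean()
            < fit.unadjusted["hiv_status"].abs().mean()
        )


class TestHypermethylationCount:
    def _groups(self, sheet):
        sp = [s for s in sheet.sample_ids if sheet.hiv_status[s] == 1]
        sn = [s for s in sheet.sample_ids if sheet.hiv_status[s] == 0]
        return sp, sn

    def test_null_groups_balanced(self):
        cfg = SimulationConfig(seed=9, n_probes=300, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        sp, sn = self._groups(sheet)
        res = hypermethylation_count_test(
            beta, beta.probe_ids[:100], sheet, sp, sn
        )
        assert res.p > 0.05
        assert abs(res.n_positive / res.n_effective - 0.5) < 0.15

    def test_uniform_shift_detected(self):
        cfg = SimulationConfig(seed=9, n_probes=100, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        sp, sn = self._groups(sheet)
        shifted = beta.values.copy()
        members = beta.probe_ids[:30]
        shifted.loc[members, sp] = (shifted.loc[members, sp] + 0.05).clip(0, 1)
        res = hypermethylation_count_test(
            BetaMatrix(shifted), members, sheet, sp, sn
        )
        assert res.p < 0.01

    def test_single_probe_uninformative(self):
        cfg = SimulationConfig(seed=9, n_probes=50, modules=[])
        beta, sheet, _, _ = simulate_cohort(cfg)
        sp, sn = self._groups(sheet)
        res = hypermethylation_count_test(beta, beta.probe_ids[:1], sheet, sp, sn)
        assert res.p == pytest.approx(1.0)

    def test_empty_module_rejected(self, small_cohort):
        beta, sheet, _, _ = small_cohort
        sp, sn = self._groups(sheet)
        with pytest.raises(CoMethNetError):
            hypermethylation_count_test(beta, [], sheet, sp, sn)
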