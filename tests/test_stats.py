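"""Cohort statistics: prevalence, concordance, age, discordant pairs, smoking."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from xciskew.stats import (
    age_group_tests,
    age_regression,
    build_cohort_table,
    discordant_pair_test,
    longitudinal_concordance,
    lowess_inflection,
    prevalence_percent,
    prevalence_table,
    smoking_association,
    tissue_concordance,
)


def _calls(**cols):
    n = max(len(v) for v in cols.values() if hasattr(v, "__len__") and not isinstance(v, str))
    base = {
        "sample_id": [f"s{i}" for i in range(n)],
        "individual_id": [f"i{i}" for i in range(n)],
        "family_id": [f"f{i}" for i in range(n)],
        "zygosity": ["singleton"] * n,
        "age": [50.0] * n,
        "tissue": ["LCL"] * n,
        "smoking": ["never"] * n,
        "disease": ["none"] * n,
        "time_point": [1] * n,
        "n_snps": [3] * n,
        "xist_ase": [0.5] * n,
        "ds": [0.1] * n,
        "classification": ["random"] * n,
    }
    for k, v in cols.items():
        base[k] = list(v) if hasattr(v, "__len__") and not isinstance(v, str) else [v] * n
    return pd.DataFrame(base)


class TestPrevalence:
    def test_half_up_rounding(self):
        assert prevalence_percent(1, 8) == 13  # 12.5 rounds up
        assert prevalence_percent(0, 10) == 0
        assert prevalence_percent(10, 10) == 100

    def test_rows_sum_to_total_skewed(self):
        df = _calls(
            tissue=["LCL"] * 6 + ["fat"] * 4,
            classification=["skewed", "random", "skewed", "random", "random", "skewed",
                            "random", "skewed", "random", "random"],
        )
        rows = prevalence_table(df)
        assert sum(r.n_skewed for r in rows) == (df["classification"] == "skewed").sum()
        assert sum(r.n_informative for r in rows) == len(df)


class TestTissueConcordance:
    def _two_tissue(self, a_vals, b_vals):
        n = len(a_vals)
        df_a = _calls(xist_ase=a_vals)
        df_b = _calls(xist_ase=b_vals, tissue="fat")
        df_b["individual_id"] = df_a["individual_id"]
        df_b["sample_id"] = [f"t{i}" for i in range(n)]
        return pd.concat([df_a, df_b], ignore_index=True)

    def test_identical_and_antimonotone(self):
        vals = [0.1, 0.3, 0.5, 0.7, 0.9]
        df = self._two_tissue(vals, vals)
        assert tissue_concordance(df, "LCL", "fat").estimate == pytest.approx(1.0)
        df = self._two_tissue(vals, [1 - v for v in vals])
        assert tissue_concordance(df, "LCL", "fat").estimate == pytest.approx(-1.0)

    def test_insufficient_shared_individuals(self):
        df = self._two_tissue([0.1, 0.2], [0.3, 0.4])
        res = tissue_concordance(df, "LCL", "fat")
        assert not res.ok and res.n == 2

    @given(st.integers(0, 3))
    def test_rank_invariance_under_monotone_maps(self, which):
        """Spearman concordance is unchanged by strictly monotone transforms."""
        rng = np.random.default_rng(99)
        a = rng.uniform(0.01, 0.99, size=30)
        b = np.clip(a + rng.normal(0, 0.1, size=30), 0.001, 0.999)
        maps = [lambda x: x, lambda x: x ** 3, lambda x: np.exp(x) / 3,
                lambda x: 1 / (1 + np.exp(-5 * x))]
        base = tissue_concordance(self._two_tissue(a, b), "LCL", "fat").estimate
        mapped = tissue_concordance(self._two_tissue(maps[which](a), b), "LCL", "fat").estimate
        assert mapped == pytest.approx(base, abs=1e-12)

    def test_matches_generator_inter_tissue_correlation(self):
        """Latent concordance between tissues tracks the configured level."""
        from xciskew.config import SimulationConfig, TissueSpec
        from xciskew.simulate import simulate_latent_skew

        cfg = SimulationConfig(
            n_mz_pairs=0, n_dz_pairs=0, n_singletons=200,
            variance_components=(0.0, 0.0, 1.0), variance_components_older=None,
            age_drift=0.0,
            tissues=(TissueSpec("LCL", 1.0, False), TissueSpec("other", 0.8, False)),
        )
        latent = simulate_latent_skew(cfg)
        wide = latent.pivot(index="individual_id", columns="tissue", values="p")
        rho, _ = sps.spearmanr(wide["LCL"], wide["other"])
        assert abs(rho - 0.8) < 0.1


class TestAgeRegression:
    def test_noise_free_positive_slope(self):
        ages = np.linspace(40, 80, 50)
        df = _calls(age=ages, ds=0.002 * ages)
        res = age_regression(df)
        assert res.estimate > 0 and res.p_value < 1e-20

    def test_slope_recovered_within_3_se(self):
        rng = np.random.default_rng(21)
        ages = rng.uniform(38, 85, 500)
        ds = 0.001 * ages + rng.normal(0, 0.05, 500)
        res = age_regression(_calls(age=ages, ds=ds))
        se = 0.05 / (np.std(ages) * np.sqrt(500))
        assert abs(res.estimate - 0.001) < 3 * se

    def test_constant_age_is_degenerate(self):
        with pytest.raises(ValueError, match="constant"):
            age_regression(_calls(age=[50.0] * 10, ds=np.linspace(0, 0.5, 10)))


class TestLowessInflection:
    def test_flat_trend_has_no_inflection(self):
        ages = np.linspace(38, 85, 100)
        _, age0 = lowess_inflection(_calls(age=ages, ds=0.2))
        assert age0 is None

    def test_monotone_trend_inflects_at_minimum_age(self):
        ages = np.linspace(38, 85, 100)
        _, age0 = lowess_inflection(_calls(age=ages, ds=0.001 * ages))
        assert age0 == pytest.approx(38.0, abs=2.0)

    def test_span_validated(self):
        ages = np.linspace(38, 85, 30)
        with pytest.raises(ValueError, match="span"):
            lowess_inflection(_calls(age=ages), span=1.5)

    def test_hinge_recovered_near_its_true_age(self):
        """A piecewise-linear increase starting at 55 is located within [50, 60]."""
        rng = np.random.default_rng(31)
        ages = rng.uniform(38, 85, 2000)
        ds = 0.18 + 0.004 * np.maximum(0.0, ages - 55.0) + rng.normal(0, 0.05, 2000)
        _, age0 = lowess_inflection(_calls(age=ages, ds=np.clip(ds, 0, 0.5)))
        assert age0 is not None and 50.0 <= age0 <= 60.0


class TestAgeGroupTests:
    def test_age_55_lands_in_older_group(self):
        ages = [54.9] * 5 + [55.0] * 7
        df = _calls(age=ages, ds=[0.1] * 5 + [0.4] * 7)
        res = {r.statistic: r for r in age_group_tests(df, threshold=55.0)}
        assert res["t_test_ds"].extra["mean_older"] == pytest.approx(0.4)
        assert res["t_test_ds"].extra["mean_younger"] == pytest.approx(0.1)

    def test_complete_separation_chi2(self):
        n = 60
        df = _calls(
            age=[45.0] * n + [65.0] * n,
            classification=["random"] * n + ["skewed"] * n,
            ds=[0.1] * n + [0.4] * n,
        )
        res = {r.statistic: r for r in age_group_tests(df)}
        assert res["chi2_skew"].p_value < 1e-10
        assert res["t_test_ds"].p_value < 1e-10

    def test_decade_bins_reported(self):
        ages = [45, 55, 65, 75, 85]
        df = _calls(age=[float(a) for a in ages],
                    classification=["skewed", "random", "skewed", "random", "skewed"])
        res = {r.statistic: r for r in age_group_tests(df)}
        freqs = res["skew_freq_by_decade"].extra
        assert set(freqs) == {"40-50", "50-60", "60-70", ">70"}
        assert freqs["40-50"] == 1.0 and freqs[">70"] == 0.5


def _signed_rank_exact_p(diffs):
    """Oracle: exact two-sided signed-rank p by enumerating all sign flips."""
    diffs = np.asarray(diffs, dtype=float)
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.array(signs)).sum())
    ws = np.array(ws)
    mean_w = ws.mean()
    more_extreme = (np.abs(ws - mean_w) >= abs(w_obs - mean_w) - 1e-9).mean()
    return more_extreme


class TestDiscordantPairs:
    def _df(self, healthy_ds, affected_ds):
        n = len(healthy_ds)
        rows = []
        for i in range(n):
            for j, (dis, ds) in enumerate((("none", healthy_ds[i]), ("RA", affected_ds[i]))):
                rows.append({
                    "sample_id": f"s{i}_{j}", "individual_id": f"i{i}_{j}",
                    "family_id": f"f{i}", "zygosity": "MZ", "age": 60.0,
                    "tissue": "LCL", "smoking": "never", "disease": dis,
                    "time_point": 1, "n_snps": 3, "xist_ase": 0.5,
                    "ds": ds, "classification": "random",
                })
        return pd.DataFrame(rows)

    def test_constant_shift_matches_exact_enumeration(self):
        """Eight pairs all shifted by +0.14: p equals the minimum attainable
        two-sided exact signed-rank p for n = 8, i.e. 2/2^8."""
        healthy = [0.1, 0.15, 0.2, 0.25, 0.3, 0.12, 0.18, 0.22]
        affected = [h + 0.14 for h in healthy]
        res = discordant_pair_test(self._df(healthy, affected))
        assert res.p_value == pytest.approx(2 / 2**8)
        assert res.p_value == pytest.approx(_signed_rank_exact_p(np.full(8, 0.14)))
        assert res.extra["n_affected_more_skewed"] == 8

    def test_exact_p_agrees_with_enumeration_on_mixed_signs(self):
        rng = np.random.default_rng(17)
        healthy = rng.uniform(0.05, 0.4, 10)
        affected = np.clip(healthy + rng.normal(0.05, 0.08, 10), 0, 0.5)
        res = discordant_pair_test(self._df(healthy, affected))
        assert res.p_value == pytest.approx(_signed_rank_exact_p(affected - healthy))

    def test_all_zero_differences_degenerate(self):
        healthy = [0.1, 0.2, 0.3, 0.25]
        res = discordant_pair_test(self._df(healthy, healthy))
        assert not res.ok and res.p_value == 1.0 and "degenerate" in res.note

    def test_no_discordant_pairs(self):
        df = _calls(zygosity=["MZ"] * 6)
        res = discordant_pair_test(df)
        assert not res.ok


class TestSmokingAssociation:
    def test_effect_recovered_within_3_se(self):
        rng = np.random.default_rng(41)
        n = 300
        ages = rng.uniform(55, 85, n)
        smoker = rng.uniform(size=n) < 0.3
        ds = 0.2 + 0.05 * smoker + 0.001 * ages + rng.normal(0, 0.05, n)
        df = _calls(age=ages, smoking=np.where(smoker, "current", "never"), ds=ds)
        res = [r for r in smoking_association(df) if r.stratum == "older"][0]
        assert res.ok
        assert abs(res.estimate - 0.05) < 3 * 0.05 / np.sqrt(n * 0.3 * 0.7)

    def test_single_smoking_level_insufficient(self):
        df = _calls(age=[60.0] * 10, smoking="current")
        res = [r for r in smoking_association(df) if r.stratum == "older"][0]
        assert not res.ok

    def test_unknown_status_excluded(self):
        df = _calls(age=[60.0] * 12,
                    smoking=["unknown"] * 6 + ["never", "current"] * 3,
                    ds=np.linspace(0.1, 0.4, 12))
        res = [r for r in smoking_association(df) if r.stratum == "older"][0]
        assert res.n == 6


class TestLongitudinal:
    def _df(self, t1, t2):
        df1 = _calls(xist_ase=t1)
        df2 = _calls(xist_ase=t2, time_point=2)
        df2["individual_id"] = df1["individual_id"]
        df2["sample_id"] = [f"r{i}" for i in range(len(t2))]
        return pd.concat([df1, df2], ignore_index=True)

    def test_identical_and_independent(self):
        vals = list(np.linspace(0.1, 0.9, 20))
        assert longitudinal_concordance(self._df(vals, vals)).estimate == pytest.approx(1.0)
        rng = np.random.default_rng(3)
        res = longitudinal_concordance(self._df(vals, list(rng.uniform(size=20))))
        assert abs(res.estimate) < 0.5

    def test_stable_latent_skew_resimulated_reads(self):
        """Re-sampling reads from the same latent p at two time points keeps
        Spearman concordance above 0.9 (depth 500, 100 individuals)."""
        from xciskew.config import SimulationConfig, XIST_GRCH37
        from xciskew.io import PhasedGenotype
        from xciskew.quantify import quantify_sample
        from xciskew.simulate import simulate_allelic_counts

        rng = np.random.default_rng(55)
        cfg = SimulationConfig(depth_mean=500.0, depth_dispersion=0.0, overdispersion_rho=0.0)
        t1, t2 = [], []
        for i in range(100):
            p = float(rng.beta(2, 2))
            gts = [PhasedGenotype("X", XIST_GRCH37.start + j, "A", "G",
                                  "A" if rng.random() < 0.5 else "G", f"i{i}")
                   for j in range(3)]
            phases = {g.position: g for g in gts}
            for dest in (t1, t2):
                counts = simulate_allelic_counts(p, gts, cfg, rng, f"i{i}")
                call, _ = quantify_sample(counts, phases, f"i{i}")
                dest.append(call.xist_ase)
        res = longitudinal_concordance(self._df(t1, t2))
        assert res.estimate > 0.9


def test_build_cohort_table_deduplicates():
    skew = pd.DataFrame({
        "sample_id": ["a", "b"], "tissue": ["LCL", "LCL"], "n_snps": [3, 3],
        "xist_ase": [0.5, 0.6], "ds": [0.0, 0.1], "classification": ["random", "random"],
    })
    meta = pd.DataFrame({
        "sample_id": ["a", "b"], "individual_id": ["i1", "i1"],
        "family_id": ["f1", "f1"], "zygosity": ["MZ", "MZ"], "age": [50.0, 50.0],
        "tissue": ["LCL", "LCL"], "smoking": ["never", "never"],
        "disease": ["none", "none"], "time_point": [1, 1],
    })
    out = build_cohort_table(skew, meta)
    assert len(out) == 1 and out["sample_id"].iloc[0] == "a"
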