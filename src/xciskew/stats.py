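"""Cohort-level statistics on skew calls.

All functions take a *cohort table*: a DataFrame of per-sample skew calls
joined to sample metadata (columns sample_id, individual_id, family_id,
zygosity, age, tissue, smoking, disease, time_point, n_snps, xist_ase, ds,
classification).  Every test reports the number of observations used and a
p-value in [0, 1]; where the data are insufficient an AssociationResult with
``ok=False`` is returned rather than an exception, so batch runs degrade
gracefully.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "PrevalenceRow",
    "build_cohort_table",
    "prevalence_percent",
    "prevalence_table",
    "tissue_concordance",
    "age_regression",
    "lowess_inflection",
    "age_group_tests",
    "discordant_pair_test",
    "smoking_association",
    "longitudinal_concordance",
]


@dataclass
class AssociationResult:
    statistic: str
    estimate: float
    p_value: float
    n: int
    stratum: str = ""
    ok: bool = True
    note: str = ""
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "statistic": self.statistic,
            "stratum": self.stratum,
            "estimate": self.estimate,
            "p_value": self.p_value,
            "n": self.n,
            "ok": self.ok,
            "note": self.note,
        }


def _insufficient(statistic: str, n: int, stratum: str = "", note: str = "insufficient data") -> AssociationResult:
    return AssociationResult(statistic, float("nan"), float("nan"), n, stratum, ok=False, note=note)


@dataclass(frozen=True)
class PrevalenceRow:
    tissue: str
    n_informative: int
    n_skewed: int
    prevalence_percent: int


def build_cohort_table(skew: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join skew calls to metadata on sample_id.

    When an individual has multiple samples for a tissue/time point, the
    first by sample_id is kept (with a warning): downstream tests assume one
    call per (individual, tissue, time point).
    """
    merged = skew.merge(metadata, on=["sample_id", "tissue"], how="inner")
    key = ["individual_id", "tissue", "time_point"]
    dup = merged.duplicated(subset=key, keep=False)
    if dup.any():
        logger.warning(
            "%d samples share an (individual, tissue, time point); keeping first by sample_id",
            int(dup.sum()),
        )
        merged = merged.sort_values("sample_id").drop_duplicates(subset=key, keep="first")
    return merged.reset_index(drop=True)


def prevalence_percent(n_skewed: int, n_informative: int) -> int:
    """Integer percent with half-up rounding (145/422 -> 34)."""
    if not 0 <= n_skewed <= n_informative:
        raise ValueError("need 0 <= n_skewed <= n_informative")
    return int(math.floor(100.0 * n_skewed / n_informative + 0.5))


def prevalence_table(calls: pd.DataFrame) -> list[PrevalenceRow]:
    """Per-tissue count of informative and skewed samples, percent half-up."""
    rows = []
    for tissue, grp in calls.groupby("tissue", sort=True):
        n = len(grp)
        k = int((grp["classification"] == "skewed").sum())
        rows.append(PrevalenceRow(str(tissue), n, k, prevalence_percent(k, n)))
    return rows


def _per_individual(calls: pd.DataFrame, tissue: str, time_point: int = 1) -> pd.DataFrame:
    sub = calls[(calls["tissue"] == tissue) & (calls["time_point"] == time_point)]
    return sub.set_index("individual_id")


def tissue_concordance(
    calls: pd.DataFrame, tissue_a: str, tissue_b: str, time_point: int = 1
) -> AssociationResult:
    """Spearman correlation of XIST_ASE between two tissues of the same individuals."""
    a = _per_individual(calls, tissue_a, time_point)["xist_ase"]
    b = _per_individual(calls, tissue_b, time_point)["xist_ase"]
    shared = a.index.intersection(b.index)
    name = f"spearman[{tissue_a},{tissue_b}]"
    if len(shared) < 3:
        return _insufficient(name, len(shared))
    rho, p = sps.spearmanr(a.loc[shared], b.loc[shared])
    return AssociationResult(name, float(rho), float(p), len(shared))


def age_regression(calls: pd.DataFrame) -> AssociationResult:
    """OLS of DS on age for one tissue's calls: slope and two-sided p."""
    sub = calls.dropna(subset=["ds", "age"])
    if len(sub) < 3:
        return _insufficient("ols_ds_age", len(sub))
    age = sub["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant: degenerate regression design")
    X = sm.add_constant(age)
    fit = sm.OLS(sub["ds"].to_numpy(dtype=float), X).fit()
    return AssociationResult(
        "ols_ds_age", float(fit.params[1]), float(fit.pvalues[1]), len(sub),
        extra={"families": sorted(sub["family_id"].unique()) if "family_id" in sub else []},
    )


def lowess_inflection(
    calls: pd.DataFrame,
    span: float = 2.0 / 3.0,
    slope_threshold: Optional[float] = None,
) -> tuple[pd.DataFrame, Optional[float]]:
    """Lowess smooth of DS against age and the estimated onset of increase.

    Returns (curve, inflection_age).  The inflection is the first age at
    which the smoothed first derivative exceeds ``slope_threshold`` and stays
    positive through the end of the age range; with the default
    ``slope_threshold=None`` the threshold is half the maximum smoothed
    slope, which for a symmetric smoother locates the hinge of a
    piecewise-linear trend.  Returns None when the curve never satisfies the
    criterion (flat or decreasing trend).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    sub = calls.dropna(subset=["ds", "age"]).sort_values("age")
    if len(sub) < 20:
        raise ValueError("need at least 20 samples for a lowess trend")
    age = sub["age"].to_numpy(dtype=float)
    ds = sub["ds"].to_numpy(dtype=float)
    smooth = sm.nonparametric.lowess(ds, age, frac=span, delta=0.01 * np.ptp(age))
    xs, ys = smooth[:, 0], smooth[:, 1]
    xs, keep = np.unique(xs, return_index=True)
    ys = ys[keep]
    curve = pd.DataFrame({"age": xs, "ds_smooth": ys})
    if len(xs) < 3:
        return curve, None
    slope = np.gradient(ys, xs)
    thr = slope_threshold if slope_threshold is not None else 0.5 * float(slope.max())
    if thr <= 0:
        return curve, None
    above = slope > thr
    pos = slope > 0
    for i in range(len(xs)):
        if above[i] and pos[i:].all():
            return curve, float(xs[i])
    return curve, None


AGE_BINS = [(40.0, 50.0), (50.0, 60.0), (60.0, 70.0), (70.0, float("inf"))]


def age_group_tests(calls: pd.DataFrame, threshold: float = 55.0) -> list[AssociationResult]:
    """Compare DS between younger (< threshold) and older (>= threshold) samples.

    Returns a Welch t-test on mean DS, a chi-square test (no continuity
    correction) on skewed/random counts, and decade-bin skew frequencies.
    """
    sub = calls.dropna(subset=["ds", "age"])
    younger = sub[sub["age"] < threshold]
    older = sub[sub["age"] >= threshold]
    results: list[AssociationResult] = []

    if len(younger) < 2 or len(older) < 2:
        results.append(_insufficient("t_test_ds", len(sub)))
    else:
        t, p = sps.ttest_ind(older["ds"], younger["ds"], equal_var=False)
        results.append(
            AssociationResult(
                "t_test_ds", float(older["ds"].mean() - younger["ds"].mean()), float(p), len(sub),
                extra={"mean_younger": float(younger["ds"].mean()),
                       "mean_older": float(older["ds"].mean()),
                       "t": float(t)},
            )
        )

    tab = np.array([
        [(younger["classification"] == "skewed").sum(), (younger["classification"] == "random").sum()],
        [(older["classification"] == "skewed").sum(), (older["classification"] == "random").sum()],
    ])
    if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
        results.append(_insufficient("chi2_skew", len(sub)))
    else:
        chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
        results.append(
            AssociationResult(
                "chi2_skew", float(chi2), float(p), len(sub),
                extra={"freq_younger": float(tab[0, 0] / tab[0].sum()),
                       "freq_older": float(tab[1, 0] / tab[1].sum())},
            )
        )

    freqs = {}
    for lo, hi in AGE_BINS:
        grp = sub[(sub["age"] >= lo) & (sub["age"] < hi)]
        label = f"{int(lo)}-{int(hi)}" if np.isfinite(hi) else f">{int(lo)}"
        freqs[label] = float((grp["classification"] == "skewed").mean()) if len(grp) else float("nan")
    results.append(
        AssociationResult("skew_freq_by_decade", float("nan"), float("nan"), len(sub), extra=freqs)
    )
    return results


def discordant_pair_test(
    calls: pd.DataFrame, disease: str = "RA", tissue: Optional[str] = None
) -> AssociationResult:
    """Paired Wilcoxon signed-rank test of DS in MZ pairs discordant for a disease.

    Exact null distribution for <= 25 pairs, normal approximation above.
    Zero differences are dropped (standard signed-rank handling); if more
    than half the pairs are zeros the result is flagged degenerate and
    reported non-significant.
    """
    sub = calls[calls["zygosity"] == "MZ"]
    if tissue is not None:
        sub = sub[sub["tissue"] == tissue]
    sub = sub[sub["time_point"] == 1]
    affected, unaffected = [], []
    for fam, grp in sub.groupby("family_id"):
        if len(grp) != 2:
            continue
        status = set(grp["disease"])
        if status != {disease, "none"}:
            continue
        aff = grp[grp["disease"] == disease]["ds"].iloc[0]
        una = grp[grp["disease"] == "none"]["ds"].iloc[0]
        affected.append(float(aff))
        unaffected.append(float(una))
    n = len(affected)
    if n < 2:
        return _insufficient("wilcoxon_discordant", n)
    diffs = np.asarray(affected) - np.asarray(unaffected)
    n_zero = int((diffs == 0).sum())
    extra = {
        "mean_affected": float(np.mean(affected)),
        "mean_unaffected": float(np.mean(unaffected)),
        "n_affected_more_skewed": int((diffs > 0).sum()),
        "n_pairs": n,
    }
    if n_zero == n or n_zero > n / 2:
        return AssociationResult(
            "wilcoxon_discordant", 0.0, 1.0, n, ok=(n_zero < n),
            note="degenerate: majority of within-pair differences are zero", extra=extra,
        )
    method = "exact" if n <= 25 else "approx"
    stat, p = sps.wilcoxon(affected, unaffected, alternative="two-sided",
                           zero_method="wilcox", method=method)
    return AssociationResult(
        "wilcoxon_discordant", float(np.mean(diffs)), float(p), n, extra=extra,
    )


def smoking_association(calls: pd.DataFrame, threshold: float = 55.0) -> list[AssociationResult]:
    """OLS of DS on smoking status (never=0, current=1) with age as covariate.

    Fitted separately in the younger (< threshold) and older (>= threshold)
    strata; samples with unknown smoking status are excluded.  Also reports
    skewed-XCI frequency by smoking group per stratum.
    """
    sub = calls[calls["smoking"].isin(["never", "current"])].dropna(subset=["ds", "age"])
    out: list[AssociationResult] = []
    for label, grp in (
        ("younger", sub[sub["age"] < threshold]),
        ("older", sub[sub["age"] >= threshold]),
    ):
        smoker = (grp["smoking"] == "current").to_numpy(dtype=float)
        if len(grp) < 4 or len(np.unique(smoker)) < 2:
            out.append(_insufficient("ols_ds_smoking", len(grp), stratum=label,
                                     note="one smoking level only" if len(grp) else "no samples"))
            continue
        X = sm.add_constant(np.column_stack([smoker, grp["age"].to_numpy(dtype=float)]))
        fit = sm.OLS(grp["ds"].to_numpy(dtype=float), X).fit()
        freq = {
            s: float((grp.loc[grp["smoking"] == s, "classification"] == "skewed").mean())
            for s in ("never", "current")
        }
        out.append(
            AssociationResult(
                "ols_ds_smoking", float(fit.params[1]), float(fit.pvalues[1]), len(grp),
                stratum=label, extra={"skew_freq": freq},
            )
        )
    return out


def longitudinal_concordance(calls: pd.DataFrame, tissue: Optional[str] = None) -> AssociationResult:
    """Spearman correlation of XIST_ASE between time points 1 and 2."""
    sub = calls if tissue is None else calls[calls["tissue"] == tissue]
    t1 = sub[sub["time_point"] == 1].set_index(["individual_id", "tissue"])["xist_ase"]
    t2 = sub[sub["time_point"] == 2].set_index(["individual_id", "tissue"])["xist_ase"]
    shared = t1.index.intersection(t2.index)
    if len(shared) < 3:
        return _insufficient("spearman_longitudinal", len(shared))
    rho, p = sps.spearmanr(t1.loc[shared], t2.loc[shared])
    return AssociationResult("spearman_longitudinal", float(rho), float(p), len(shared))
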