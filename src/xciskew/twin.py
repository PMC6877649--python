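"""Classical twin variance decomposition (ACE) and intraclass correlations.

The ACE model attributes trait variance to additive genetics (A), shared
environment (C) and unique environment (E).  For a twin pair with trait
vector (x1, x2), the model is bivariate normal with common mean mu,
variance a2 + c2 + e2 on the diagonal and covariance a2 + c2 for MZ pairs
or 0.5*a2 + c2 for DZ pairs (DZ twins share on average half of segregating
additive effects).  The contrast between MZ and DZ resemblance identifies
a2.  Maximum likelihood is computed here directly on per-zygosity
sufficient statistics, so the fit cost is independent of the number of
pairs; the exchangeable covariance makes the likelihood invariant to the
order of twins within a pair.

The closed-form Falconer estimators (h2 = 2(rMZ - rDZ), c2 = 2 rDZ - rMZ,
e2 = 1 - rMZ) serve as an independent moment-based cross-check and as
optimizer starting values, never as the fit itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .stats import AssociationResult

logger = logging.getLogger(__name__)

__all__ = [
    "TwinPairSet",
    "ACEEstimate",
    "fit_ace",
    "falconer",
    "intraclass_spearman",
    "pairs_from_cohort",
    "stratified_heritability",
]

_DZ_ADDITIVE_CORR = 0.5  # no assortative-mating adjustment


@dataclass
class TwinPairSet:
    """Paired trait values by zygosity: arrays of shape (n_pairs, 2)."""

    mz: np.ndarray
    dz: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.atleast_2d(np.asarray(self.mz, dtype=float))
        self.dz = np.atleast_2d(np.asarray(self.dz, dtype=float))
        for name, arr in (("mz", self.mz), ("dz", self.dz)):
            if arr.size and arr.shape[1] != 2:
                raise ValueError(f"{name} pairs must have two trait values per row")
            if arr.size and not np.isfinite(arr).all():
                raise ValueError(f"non-finite trait values in {name} pairs")

    @property
    def n_mz(self) -> int:
        return 0 if self.mz.size == 0 else self.mz.shape[0]

    @property
    def n_dz(self) -> int:
        return 0 if self.dz.size == 0 else self.dz.shape[0]


@dataclass
class ACEEstimate:
    h2: float
    c2: float
    e2: float
    mean: float
    total_variance: float
    loglik: float
    loglik_ce: float
    p_value_A: float
    n_mz: int
    n_dz: int
    converged: bool = True
    note: str = ""

    def shares(self) -> tuple[float, float, float]:
        return (self.h2, self.c2, self.e2)


def _suffstats(pairs: np.ndarray) -> tuple[int, float, float, float]:
    if pairs.size == 0:
        return 0, 0.0, 0.0, 0.0
    x, y = pairs[:, 0], pairs[:, 1]
    return len(pairs), float((x + y).sum()), float((x * x + y * y).sum()), float((x * y).sum())


def _nll(params: np.ndarray, stats_mz, stats_dz) -> float:
    """Negative log-likelihood from sufficient statistics.

    params = (mu, va, vc, ve), raw (unstandardized) variance components.
    """
    mu, va, vc, ve = params
    sigma2 = va + vc + ve
    if sigma2 <= 0 or ve < 0 or va < 0 or vc < 0:
        return np.inf
    total = 0.0
    for cov, (n, s1, s2, s12) in (
        (va + vc, stats_mz),
        (_DZ_ADDITIVE_CORR * va + vc, stats_dz),
    ):
        if n == 0:
            continue
        det = sigma2 * sigma2 - cov * cov
        if det <= 0:
            return np.inf
        qsum = s2 - 2 * mu * s1 + 2 * n * mu * mu  # sum (x-mu)^2 + (y-mu)^2
        qcross = s12 - mu * s1 + n * mu * mu  # sum (x-mu)(y-mu)
        quad = (sigma2 * qsum - 2 * cov * qcross) / det
        total += 0.5 * (n * np.log(det) + quad) + n * np.log(2 * np.pi)
    return total


def _optimize(stats_mz, stats_dz, starts, fix_a: bool = False):
    best = None
    for start in starts:
        x0 = np.asarray(start, dtype=float)
        if fix_a:
            x0[1] = 0.0
        bounds = [
            (None, None),
            (0.0, 0.0) if fix_a else (0.0, None),
            (0.0, None),
            (1e-12, None),
        ]
        res = optimize.minimize(
            _nll, x0, args=(stats_mz, stats_dz), method="L-BFGS-B",
            bounds=bounds, options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_ace(pairs: TwinPairSet) -> ACEEstimate:
    """Maximum-likelihood ACE decomposition on MZ/DZ twin pairs.

    Boundary solutions (any component exactly zero) are permitted.  The
    p-value for the additive component is a likelihood-ratio test of ACE
    against CE referred to the 50:50 mixture of chi-square(0) and
    chi-square(1), the appropriate reference when the null pins a variance
    on its boundary; a likelihood ratio of ~0 (h2 estimated at the boundary)
    yields p = 1.
    """
    if pairs.n_mz < 2 or pairs.n_dz < 2:
        raise ValueError("need at least 2 MZ and 2 DZ pairs to fit the ACE model")
    stats_mz = _suffstats(pairs.mz)
    stats_dz = _suffstats(pairs.dz)
    allv = np.concatenate([pairs.mz.ravel(), pairs.dz.ravel()])
    mu0 = float(allv.mean())
    var0 = float(allv.var(ddof=1))
    if var0 <= 0:
        raise ValueError("trait variance is zero: nothing to decompose")

    r_mz = _double_entry_pearson(pairs.mz)
    r_dz = _double_entry_pearson(pairs.dz)
    h2f, c2f, e2f, _ = falconer(r_mz, r_dz)
    starts = [
        (mu0, h2f * var0, c2f * var0, max(e2f, 0.02) * var0),
        (mu0, var0 / 3, var0 / 3, var0 / 3),
        (mu0, 0.01 * var0, 0.01 * var0, 0.98 * var0),
    ]
    res_ce = _optimize(stats_mz, stats_dz, starts, fix_a=True)
    # include the CE optimum among ACE starts: guarantees ll_ace >= ll_ce
    res_ace = _optimize(stats_mz, stats_dz, starts + [res_ce.x], fix_a=False)

    mu, va, vc, ve = res_ace.x
    sigma2 = va + vc + ve
    h2, c2, e2 = va / sigma2, vc / sigma2, ve / sigma2
    ll_ace, ll_ce = -res_ace.fun, -res_ce.fun
    lr = max(0.0, 2.0 * (ll_ace - ll_ce))
    p_a = 1.0 if lr < 1e-8 else 0.5 * float(sps.chi2.sf(lr, df=1))
    converged = bool(res_ace.success and res_ce.success)
    if not converged:
        logger.warning("ACE optimizer did not report convergence: %s", res_ace.message)
    return ACEEstimate(
        h2=float(h2), c2=float(c2), e2=float(e2), mean=float(mu),
        total_variance=float(sigma2), loglik=float(ll_ace), loglik_ce=float(ll_ce),
        p_value_A=p_a, n_mz=pairs.n_mz, n_dz=pairs.n_dz, converged=converged,
        note="" if converged else str(res_ace.message),
    )


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float, bool]:
    """Closed-form moment estimators of the standardized ACE shares.

    Returns (h2, c2, e2, clipped): components clipped to [0, 1] and
    renormalized to sum 1; ``clipped`` flags whether clipping occurred.
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    raw = np.array([2 * (r_mz - r_dz), 2 * r_dz - r_mz, 1 - r_mz])
    clipped_arr = np.clip(raw, 0.0, 1.0)
    clipped = bool(np.any(clipped_arr != raw))
    total = clipped_arr.sum()
    if total == 0:
        return 0.0, 0.0, 1.0, True
    h2, c2, e2 = clipped_arr / total
    return float(h2), float(c2), float(e2), clipped


def _double_entry(pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return x, y


def _double_entry_pearson(pairs: np.ndarray) -> float:
    if len(pairs) < 2:
        return 0.0
    x, y = _double_entry(pairs)
    sx = x.std()
    if sx == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _ic_spearman(pairs: np.ndarray) -> float:
    """Double-entry intraclass Spearman: ranks on the doubled set (average ties)."""
    x, y = _double_entry(pairs)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx = rx.std()
    if sx == 0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def intraclass_spearman(
    pairs: np.ndarray,
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    zygosity: str = "",
) -> AssociationResult:
    """Intraclass Spearman correlation of a trait within twin pairs.

    Each pair enters in both orders (double entry), making the statistic
    exactly invariant to twin labelling.  The two-sided p-value comes from
    reshuffling the 2n individuals into pseudo-pairs (>= 10,000 permutations
    by default, seeded): p = (1 + #{|IC_perm| >= |IC_obs|}) / (B + 1).
    """
    pairs = np.atleast_2d(np.asarray(pairs, dtype=float))
    name = f"ic_spearman[{zygosity}]" if zygosity else "ic_spearman"
    if pairs.shape[0] < 3:
        return _ins(name, pairs.shape[0])
    if rng is None:
        rng = np.random.default_rng()
    n = pairs.shape[0]
    obs = _ic_spearman(pairs)

    flat = pairs.ravel()
    m = 2 * n
    # vectorized permutations: B shuffles -> (B, n, 2) pseudo-pairs
    perm_idx = np.argsort(rng.random((n_permutations, m)), axis=1)
    shuffled = flat[perm_idx].reshape(n_permutations, n, 2)
    x = np.concatenate([shuffled[:, :, 0], shuffled[:, :, 1]], axis=1)
    y = np.concatenate([shuffled[:, :, 1], shuffled[:, :, 0]], axis=1)
    rx = sps.rankdata(x, axis=1)
    ry = sps.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum(axis=1))
    ics = np.where(denom > 0, (rx * ry).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    p = (1.0 + float((np.abs(ics) >= abs(obs) - 1e-12).sum())) / (n_permutations + 1.0)
    return AssociationResult(name, float(obs), float(p), n)


def _ins(name: str, n: int) -> AssociationResult:
    return AssociationResult(name, float("nan"), float("nan"), n, ok=False, note="insufficient data")


def pairs_from_cohort(
    cohort: pd.DataFrame,
    tissue: str,
    trait: str = "ds",
    time_point: int = 1,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Complete twin pairs with trait values in one tissue, keyed by zygosity.

    Returns {"MZ": (pairs, ages), "DZ": (pairs, ages)} where pairs has shape
    (n, 2) and ages the shared pair age.  Pairs with only one informative
    co-twin are excluded; singletons never enter.
    """
    sub = cohort[(cohort["tissue"] == tissue) & (cohort["time_point"] == time_point)]
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for zyg in ("MZ", "DZ"):
        vals, ages = [], []
        for fam, grp in sub[sub["zygosity"] == zyg].groupby("family_id"):
            if len(grp) != 2 or grp[trait].isna().any():
                continue
            grp = grp.sort_values("individual_id")
            vals.append(grp[trait].to_numpy(dtype=float))
            a = grp["age"].to_numpy(dtype=float)
            if abs(a[0] - a[1]) > 1e-6:
                logger.warning("family %s co-twins have different ages; using the mean", fam)
            ages.append(float(a.mean()))
        out[zyg] = (
            np.asarray(vals, dtype=float).reshape(-1, 2),
            np.asarray(ages, dtype=float),
        )
    return out


def stratified_heritability(
    cohort: pd.DataFrame,
    tissue: str,
    age_threshold: float = 55.0,
    trait: str = "ds",
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
    residualize_age: bool = False,
) -> pd.DataFrame:
    """ACE fit and intraclass Spearman per age group for one tissue.

    Pairs are assigned to the younger (< threshold) or older (>= threshold)
    group by their shared pair age.  Strata without complete pairs are
    skipped (logged); strata lacking one zygosity report the intraclass
    correlations without an ACE fit.  ``residualize_age`` regresses the
    trait on age within stratum before fitting (optional preprocessing; off
    by default as in the published analysis scope).
    """
    if rng is None:
        rng = np.random.default_rng()
    by_zyg = pairs_from_cohort(cohort, tissue, trait=trait)
    rows = []
    for group, mask_fn in (
        ("younger", lambda a: a < age_threshold),
        ("older", lambda a: a >= age_threshold),
    ):
        mz, mz_age = by_zyg["MZ"]
        dz, dz_age = by_zyg["DZ"]
        mz_g = mz[mask_fn(mz_age)] if len(mz) else mz
        dz_g = dz[mask_fn(dz_age)] if len(dz) else dz
        if len(mz_g) == 0 and len(dz_g) == 0:
            logger.info("stratified_heritability: no complete pairs in %s/%s", tissue, group)
            continue
        if residualize_age:
            mz_g, dz_g = _residualize(mz_g, mz_age[mask_fn(mz_age)]), _residualize(dz_g, dz_age[mask_fn(dz_age)])
        row = {"tissue": tissue, "age_group": group,
               "n_mz_pairs": len(mz_g), "n_dz_pairs": len(dz_g)}
        if len(mz_g) >= 2 and len(dz_g) >= 2:
            est = fit_ace(TwinPairSet(mz_g, dz_g))
            row.update({"h2": est.h2, "c2": est.c2, "e2": est.e2,
                        "p_value_A": est.p_value_A, "ace_converged": est.converged})
        else:
            row.update({"h2": np.nan, "c2": np.nan, "e2": np.nan,
                        "p_value_A": np.nan, "ace_converged": False})
        for zyg, arr in (("MZ", mz_g), ("DZ", dz_g)):
            ic = intraclass_spearman(arr, n_permutations=n_permutations, rng=rng, zygosity=zyg)
            row[f"ic_{zyg.lower()}"] = ic.estimate
            row[f"ic_{zyg.lower()}_p"] = ic.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def _residualize(pairs: np.ndarray, ages: np.ndarray) -> np.ndarray:
    if len(pairs) < 3 or np.ptp(ages) == 0:
        return pairs
    flat = pairs.ravel()
    a = np.repeat(ages, 2)
    slope, intercept = np.polyfit(a, flat, 1)
    return (flat - (slope * a + intercept)).reshape(-1, 2)
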