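"""Synthetic twin-cohort generator with known ground truth.

The generator produces every input the pipeline consumes — phased
heterozygous X-linked SNVs (VCF), per-sample allelic read-count tables,
and sample metadata — plus a ground-truth table of the latent skew each
sample was generated from, so estimator and model recovery can be tested
without any restricted data.

Model
-----
Each individual i and tissue t carries a latent skew fraction
p_it in (0, 1): the fraction of cells inactivating haplotype 1.  On the
logit scale the trait is exactly multivariate normal with classical twin
(ACE) structure:

    z_it = latent_sd * ( sqrt(a2) A_i + sqrt(c2) C_f + sqrt(e2) E_it )

where A is a standard-normal additive-genetic score shared with correlation
1 within MZ pairs and 0.5 within DZ pairs, C is shared by all co-twins of a
family and E is unique, with tissue E-draws correlated to the reference
tissue at the configured per-tissue level.  In blood-like tissues the latent
magnitude |z| additionally drifts upward by ``age_drift`` per year of age
above ``age_threshold`` (acquired skew), and an optional second set of
variance shares applies at or above the threshold (age-gated genetics).

Reads at a heterozygous site are beta-binomial given the site's expected
haplotype-1 fraction: p for sites inside XIST (expressed from the inactive
X), ((1-p) + p*e) / (1 + e) for a non-PAR site with escape level e
(expressed from the active X, plus partial escape from the inactive one),
and 0.5 in the PARs.  ``overdispersion_rho = 0`` reduces exactly to
binomial sampling.  Reads never span two SNVs, so counts are independent
across sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .io import AllelicSite, PhasedGenotype, write_metadata, METADATA_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "LatentSkew",
    "CohortPaths",
    "build_cohort_frame",
    "simulate_latent_skew",
    "simulate_allelic_counts",
    "simulate_cohort",
    "sample_depth",
    "betabinomial",
]


@dataclass(frozen=True)
class LatentSkew:
    individual_id: str
    tissue: str
    z: float
    p: float


@dataclass(frozen=True)
class CohortPaths:
    vcf: Path
    counts_dir: Path
    metadata: Path
    truth: Path
    sites: Path


def build_cohort_frame(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Individuals with family structure, ages and covariates.

    Twins share family id, zygosity and age.  RA-discordant MZ pairs are the
    first ``n_ra_discordant_pairs`` MZ families (one affected co-twin each);
    smoking is assigned independently per individual.
    """
    rows = []
    fam = 0
    for kind, n_pairs in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        for _ in range(n_pairs):
            fam += 1
            age = rng.uniform(*config.age_range)
            for k in (1, 2):
                rows.append({
                    "individual_id": f"F{fam:04d}I{k}",
                    "family_id": f"F{fam:04d}",
                    "zygosity": kind,
                    "age": age,
                })
    for _ in range(config.n_singletons):
        fam += 1
        rows.append({
            "individual_id": f"F{fam:04d}I1",
            "family_id": f"F{fam:04d}",
            "zygosity": "singleton",
            "age": rng.uniform(*config.age_range),
        })
    df = pd.DataFrame(rows)

    u = rng.uniform(size=len(df))
    known = config.smoking_unknown_prob
    cur = config.smoking_current_prob
    df["smoking"] = np.where(u < known, "unknown",
                             np.where(u < known + (1 - known) * cur, "current", "never"))

    df["disease"] = "none"
    mz_fams = df.loc[df["zygosity"] == "MZ", "family_id"].unique()
    n_ra = min(config.n_ra_discordant_pairs, len(mz_fams))
    for f in mz_fams[:n_ra]:
        affected = df.index[(df["family_id"] == f)][int(rng.integers(2))]
        df.loc[affected, "disease"] = "RA"
    return df


def _component_shares(config: SimulationConfig, age: np.ndarray, blood_like: bool) -> tuple:
    """Per-individual (sqrt a2, sqrt c2, sqrt e2) arrays, honouring age gating."""
    base = np.sqrt(np.asarray(config.variance_components))
    wa = np.full(age.shape, base[0])
    wc = np.full(age.shape, base[1])
    we = np.full(age.shape, base[2])
    if blood_like and config.variance_components_older is not None:
        older = age >= config.age_threshold
        ob = np.sqrt(np.asarray(config.variance_components_older))
        wa[older], wc[older], we[older] = ob[0], ob[1], ob[2]
    return wa, wc, we


def simulate_latent_skew(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    cohort: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Latent skew per individual and tissue.

    Returns a DataFrame with columns individual_id, family_id, zygosity, age,
    smoking, disease, tissue, z, p (one row per individual x tissue).
    Deterministic given the configured seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if cohort is None:
        cohort = build_cohort_frame(config, rng)
    n = len(cohort)
    zyg = cohort["zygosity"].to_numpy()
    fam = cohort["family_id"].to_numpy()
    age = cohort["age"].to_numpy(dtype=float)

    # family-level shared scores
    fam_codes, fam_idx = np.unique(fam, return_inverse=True)
    A_fam = rng.standard_normal(len(fam_codes))
    C_fam = rng.standard_normal(len(fam_codes))
    A_own = rng.standard_normal(n)
    # MZ: co-twins share A exactly; DZ: corr 0.5; singletons: independent
    A = np.where(
        zyg == "MZ", A_fam[fam_idx],
        np.where(zyg == "DZ",
                 np.sqrt(0.5) * A_fam[fam_idx] + np.sqrt(0.5) * A_own,
                 A_own),
    )
    C = np.where(zyg == "singleton", rng.standard_normal(n), C_fam[fam_idx])

    E_ref = rng.standard_normal(n)
    frames = []
    for tissue in config.tissues:
        r = tissue.e_corr
        E = r * E_ref + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
        wa, wc, we = _component_shares(config, age, tissue.blood_like)
        z = config.latent_sd * tissue.latent_scale * (wa * A + wc * C + we * E)
        if tissue.blood_like:
            shift = np.zeros(n)
            shift += config.age_drift * np.maximum(0.0, age - config.age_threshold)
            shift += config.smoking_effect * (cohort["smoking"].to_numpy() == "current")
            shift += config.ra_effect * (cohort["disease"].to_numpy() == "RA")
            # push |p - 0.5| upward, keeping the parental direction of the skew
            z = z + np.where(z >= 0, shift, -shift)
        out = cohort.copy()
        out["tissue"] = tissue.name
        out["z"] = z
        out["p"] = 1.0 / (1.0 + np.exp(-z))
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def sample_depth(config: SimulationConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Per-site read depth: negative binomial (gamma-Poisson) or constant."""
    if config.depth_dispersion == 0:
        return np.full(size, int(round(config.depth_mean)))
    k = config.depth_dispersion
    prob = k / (k + config.depth_mean)
    return rng.negative_binomial(k, prob, size=size)


def betabinomial(
    rng: np.random.Generator, depth: int, fraction: float, rho: float
) -> int:
    """Beta-binomial draw with mean ``fraction`` and intraclass correlation ``rho``.

    rho = 0 is exactly binomial; fraction 0 or 1 is degenerate.
    """
    if depth == 0:
        return 0
    if fraction <= 0.0:
        return 0
    if fraction >= 1.0:
        return int(depth)
    if rho == 0.0:
        return int(rng.binomial(depth, fraction))
    scale = (1.0 - rho) / rho
    q = rng.beta(fraction * scale, (1.0 - fraction) * scale)
    return int(rng.binomial(depth, q))


def expected_hap1_fraction(p: float, in_xist: bool, in_par: bool, escape: float) -> float:
    """Expected haplotype-1 read fraction at a site given latent skew p.

    XIST is expressed from the inactive X, so its hap1 fraction is p itself.
    A non-PAR gene with escape level e is expressed from the active X plus a
    fraction e from the inactive one: ((1-p) + p e) / (1 + e).  PAR genes
    escape inactivation entirely (0.5).
    """
    if in_par:
        return 0.5
    if in_xist:
        return p
    return ((1.0 - p) + p * escape) / (1.0 + escape)


def simulate_allelic_counts(
    p: float,
    sites: Sequence[PhasedGenotype],
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str,
    escape_by_position: Optional[Mapping[int, float]] = None,
) -> list[AllelicSite]:
    """Beta-binomial read counts for one sample at its phased het sites."""
    escape_by_position = escape_by_position or {}
    depths = sample_depth(config, rng, len(sites))
    out = []
    for g, depth in zip(sites, depths):
        if g.contig.removeprefix("chr") != config.xist_interval.contig.removeprefix("chr"):
            raise ValueError(f"site {g.contig}:{g.position} is not on chromosome X")
        in_xist = config.xist_interval.contains(g.contig, g.position)
        in_par = any(iv.contains(g.contig, g.position) for iv in config.par_intervals)
        frac = expected_hap1_fraction(p, in_xist, in_par, escape_by_position.get(g.position, 0.0))
        k_hap1 = betabinomial(rng, int(depth), frac, config.overdispersion_rho)
        ref = k_hap1 if g.hap1_is_ref else int(depth) - k_hap1
        out.append(
            AllelicSite(
                contig=g.contig,
                position=g.position,
                ref_count=ref,
                alt_count=int(depth) - ref,
                sample_id=sample_id,
                in_xist=in_xist,
                in_par=in_par,
            )
        )
    return out


_BASES = np.array(list("ACGT"))


def _draw_site_pool(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Candidate SNV positions: a pool inside XIST and a pool elsewhere non-PAR.

    Pools are twice the per-sample site count so that individuals differ in
    which sites they are heterozygous at.  Each non-PAR site stands for one
    gene (reads never span sites) and carries an escape level drawn from a
    zero-inflated Beta.
    """
    iv = config.xist_interval
    n_x = max(2 * config.n_xist_snps, 1)
    xist_pos = np.sort(rng.choice(np.arange(iv.start, iv.end + 1), size=n_x, replace=False))
    par_ends = [p.end for p in config.par_intervals if p.start < iv.start]
    par_end = max(par_ends) if par_ends else 0
    n_np = max(2 * config.n_nonpar_snps, 1)
    lo, hi = par_end + 1, iv.start - 1
    nonpar_pos = np.sort(rng.choice(np.arange(lo, hi), size=n_np, replace=False))
    rows = []
    for pos in xist_pos:
        rows.append({"position": int(pos), "kind": "xist", "escape": 0.0})
    esc_zero = rng.uniform(size=n_np) < config.escape_zero_prob
    esc_val = rng.beta(*config.escape_beta, size=n_np)
    for pos, z0, e in zip(nonpar_pos, esc_zero, esc_val):
        rows.append({"position": int(pos), "kind": "nonpar", "escape": 0.0 if z0 else float(e)})
    df = pd.DataFrame(rows).sort_values("position").reset_index(drop=True)
    ref = rng.integers(0, 4, size=len(df))
    alt = (ref + rng.integers(1, 4, size=len(df))) % 4
    df["contig"] = config.xist_interval.contig
    df["ref"] = _BASES[ref]
    df["alt"] = _BASES[alt]
    return df


def _draw_genotypes(
    individuals: Sequence[str],
    pool: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[PhasedGenotype]]:
    """Per individual: which pool sites are heterozygous, and their phase."""
    xist_idx = pool.index[pool["kind"] == "xist"].to_numpy()
    nonpar_idx = pool.index[pool["kind"] == "nonpar"].to_numpy()
    out: dict[str, list[PhasedGenotype]] = {}
    for ind in individuals:
        chosen = np.concatenate([
            rng.choice(xist_idx, size=min(config.n_xist_snps, len(xist_idx)), replace=False)
            if config.n_xist_snps > 0 else np.empty(0, dtype=int),
            rng.choice(nonpar_idx, size=min(config.n_nonpar_snps, len(nonpar_idx)), replace=False)
            if config.n_nonpar_snps > 0 else np.empty(0, dtype=int),
        ]).astype(int)
        chosen.sort()
        hap1_is_ref = rng.uniform(size=len(chosen)) < 0.5
        gts = []
        for j, i_site in enumerate(chosen):
            row = pool.loc[i_site]
            gts.append(
                PhasedGenotype(
                    contig=str(row["contig"]),
                    position=int(row["position"]),
                    ref_allele=str(row["ref"]),
                    alt_allele=str(row["alt"]),
                    hap1_allele=str(row["ref"] if hap1_is_ref[j] else row["alt"]),
                    sample_id=ind,
                )
            )
        out[ind] = gts
    return out


def _write_vcf(
    path: Path,
    pool: pd.DataFrame,
    genotypes: Mapping[str, list[PhasedGenotype]],
    individuals: Sequence[str],
) -> None:
    """Plain-text multi-sample VCF 4.2: het individuals phased, others hom-ref."""
    by_ind = {
        ind: {g.position: g for g in gts} for ind, gts in genotypes.items()
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contig = pool["contig"].iloc[0] if len(pool) else "X"
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(individuals) + "\n")
        for _, row in pool.iterrows():
            gts = []
            for ind in individuals:
                g = by_ind.get(ind, {}).get(int(row["position"]))
                if g is None:
                    gts.append("0|0")
                else:
                    gts.append("0|1" if g.hap1_is_ref else "1|0")
            fh.write(
                f"{row['contig']}\t{int(row['position'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortPaths:
    """Emit all pipeline inputs plus the ground-truth table.

    Outputs under ``out_dir``: ``sites.vcf`` (phased genotypes of every
    individual), ``counts/<sample_id>.tsv`` (ASEReadCounter-style tables, one
    per individual x tissue x time point), ``metadata.tsv``, ``truth.tsv``
    (individual, tissue, true p and true DS) and ``sites.tsv`` (site pool
    with escape levels).  Byte-identical across runs for a fixed seed.
    """
    config.validate()
    if config.n_individuals == 0:
        raise ValueError("cohort must contain at least one individual")
    out_dir = Path(out_dir)
    counts_dir = out_dir / "counts"
    counts_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    latent = simulate_latent_skew(config, rng=rng)
    individuals = list(latent["individual_id"].unique())
    pool = _draw_site_pool(config, rng)
    genotypes = _draw_genotypes(individuals, pool, config, rng)
    escape = dict(zip(pool["position"].astype(int), pool["escape"].astype(float)))

    vcf_path = out_dir / "sites.vcf"
    _write_vcf(vcf_path, pool, genotypes, individuals)

    meta_rows = []
    for row in latent.itertuples(index=False):
        for tp in range(1, config.n_time_points + 1):
            sample_id = f"{row.individual_id}_{row.tissue}_t{tp}"
            sites = simulate_allelic_counts(
                float(row.p), genotypes[row.individual_id], config, rng,
                sample_id=sample_id, escape_by_position=escape,
            )
            pd.DataFrame(
                {
                    "contig": [s.contig for s in sites],
                    "position": [s.position for s in sites],
                    "variantID": ["." for _ in sites],
                    "refAllele": [g.ref_allele for g in genotypes[row.individual_id]],
                    "altAllele": [g.alt_allele for g in genotypes[row.individual_id]],
                    "refCount": [s.ref_count for s in sites],
                    "altCount": [s.alt_count for s in sites],
                    "totalCount": [s.total_count for s in sites],
                }
            ).to_csv(counts_dir / f"{sample_id}.tsv", sep="\t", index=False)
            meta_rows.append({
                "sample_id": sample_id,
                "individual_id": row.individual_id,
                "family_id": row.family_id,
                "zygosity": row.zygosity,
                "age": round(float(row.age), 6),
                "tissue": row.tissue,
                "smoking": row.smoking,
                "disease": row.disease,
                "time_point": tp,
            })

    metadata_path = out_dir / "metadata.tsv"
    write_metadata(pd.DataFrame(meta_rows, columns=METADATA_COLUMNS), metadata_path)

    truth_path = out_dir / "truth.tsv"
    truth = latent[["individual_id", "tissue", "p"]].copy()
    truth["ds_true"] = (0.5 - truth["p"]).abs()
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")

    sites_path = out_dir / "sites.tsv"
    pool[["contig", "position", "kind", "ref", "alt", "escape"]].to_csv(
        sites_path, sep="\t", index=False, float_format="%.10g"
    )
    logger.info(
        "simulate_cohort: %d individuals, %d tissues, %d sites -> %s",
        len(individuals), len(config.tissues), len(pool), out_dir,
    )
    return CohortPaths(vcf_path, counts_dir, metadata_path, truth_path, sites_path)
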