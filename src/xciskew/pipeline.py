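"""End-to-end orchestration: simulate -> quantify -> stats -> heritability.

Each stage reads and writes plain files so stages can be rerun in
isolation; a run manifest (seed, config echo, package versions) makes a
synthetic run reproducible from its output directory alone.  A single seed
fans out to per-stage substreams via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import GenomicInterval, QuantificationConfig, SimulationConfig
from .io import (
    read_allelic_counts,
    read_metadata,
    read_phased_vcf,
    read_skew_table,
    write_skew_table,
)
from .quantify import NonParResult, nonpar_ase, quantify_sample
from .simulate import simulate_cohort
from .stats import (
    age_group_tests,
    age_regression,
    build_cohort_table,
    discordant_pair_test,
    longitudinal_concordance,
    prevalence_table,
    smoking_association,
    tissue_concordance,
)
from .twin import stratified_heritability

logger = logging.getLogger(__name__)

__all__ = ["run_quantify", "run_stats", "run_heritability", "run_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_quantify(
    counts_dir: str | Path,
    vcf: str | Path,
    metadata_path: str | Path,
    out_path: str | Path,
    qc: Optional[QuantificationConfig] = None,
    escape_sites: Optional[Sequence[int]] = None,
    nonpar_out: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Skew-call every counts table in a directory.

    ``counts_dir`` holds one ``<sample_id>.tsv`` per sample; the VCF supplies
    phased genotypes per *individual* (metadata maps samples to individuals).
    Writes the skew table to ``out_path`` and, optionally, the alternative
    non-PAR estimates to ``nonpar_out``.
    """
    qc = qc or QuantificationConfig()
    counts_dir = Path(counts_dir)
    files = sorted(counts_dir.glob("*.tsv"))
    if not files:
        raise PipelineError(f"quantify: no counts tables (*.tsv) in {counts_dir}")
    meta = read_metadata(metadata_path)
    sample_info = meta.set_index("sample_id")
    phased = read_phased_vcf(vcf)
    phases_by_ind: dict[str, dict[int, object]] = {}
    for g in phased:
        phases_by_ind.setdefault(g.sample_id, {})[g.position] = g

    calls, nonpar_rows = [], []
    n_noninformative = 0
    for path in files:
        sample_id = path.stem
        if sample_id not in sample_info.index:
            logger.warning("quantify: %s not in metadata; skipped", sample_id)
            continue
        info = sample_info.loc[sample_id]
        sites = read_allelic_counts(
            path, sample_id=sample_id,
            xist_interval=qc.xist_interval, par_intervals=qc.par_intervals,
        )
        phases = phases_by_ind.get(str(info["individual_id"]), {})
        call, ases = quantify_sample(
            sites, phases, sample_id=sample_id, tissue=str(info["tissue"]),
            min_depth=qc.min_depth, skew_threshold=qc.skew_threshold,
            weight_by_depth=qc.weight_by_depth,
        )
        if call is None:
            n_noninformative += 1
        else:
            calls.append(call)
        np_res = nonpar_ase(ases, min_sites=qc.min_nonpar_sites, escape_positions=escape_sites)
        if np_res is not None:
            nonpar_rows.append({
                "sample_id": sample_id, "tissue": str(info["tissue"]),
                "n_sites": np_res.n_sites, "nonpar_value": np_res.value,
                "nonpar_deviation": np_res.deviation,
            })
    logger.info(
        "quantify: %d informative samples, %d non-informative (no XIST SNP passing filters)",
        len(calls), n_noninformative,
    )
    write_skew_table(calls, out_path)
    if nonpar_out is not None:
        pd.DataFrame(
            nonpar_rows,
            columns=["sample_id", "tissue", "n_sites", "nonpar_value", "nonpar_deviation"],
        ).to_csv(nonpar_out, sep="\t", index=False, float_format="%.12g")
    return read_skew_table(out_path)


_ALL_ANALYSES = ("prevalence", "concordance", "age", "discordant", "smoking", "longitudinal")


def run_stats(
    skew_table: str | Path,
    metadata_path: str | Path,
    out_dir: str | Path,
    analyses: Sequence[str] = _ALL_ANALYSES,
    age_threshold: float = 55.0,
    disease: str = "RA",
) -> dict[str, pd.DataFrame]:
    """Run the requested cohort analyses, one TSV per analysis."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    calls = build_cohort_table(read_skew_table(skew_table), read_metadata(metadata_path))
    if calls.empty:
        raise PipelineError("stats: no calls after joining skew table to metadata")
    tissues = sorted(calls["tissue"].unique())
    results: dict[str, pd.DataFrame] = {}

    if "prevalence" in analyses:
        rows = prevalence_table(calls[calls["time_point"] == 1])
        results["prevalence"] = pd.DataFrame([asdict(r) for r in rows])
    if "concordance" in analyses:
        rows = []
        for i, ta in enumerate(tissues):
            for tb in tissues[i + 1:]:
                res = tissue_concordance(calls, ta, tb)
                rows.append(res.as_row())
        results["concordance"] = pd.DataFrame(rows)
    if "age" in analyses:
        rows = []
        for t in tissues:
            sub = calls[(calls["tissue"] == t) & (calls["time_point"] == 1)]
            reg = age_regression(sub)
            reg.stratum = t
            rows.append(reg.as_row())
            for res in age_group_tests(sub, threshold=age_threshold):
                res.stratum = f"{t}:{res.stratum}" if res.stratum else t
                row = res.as_row()
                row.update({k: v for k, v in res.extra.items() if np.isscalar(v)})
                rows.append(row)
        results["age"] = pd.DataFrame(rows)
    if "discordant" in analyses:
        rows = []
        for t in tissues:
            res = discordant_pair_test(calls, disease=disease, tissue=t)
            res.stratum = t
            row = res.as_row()
            row.update(res.extra)
            rows.append(row)
        results["discordant"] = pd.DataFrame(rows)
    if "smoking" in analyses:
        rows = []
        for t in tissues:
            sub = calls[(calls["tissue"] == t) & (calls["time_point"] == 1)]
            for res in smoking_association(sub, threshold=age_threshold):
                res.stratum = f"{t}:{res.stratum}"
                rows.append(res.as_row())
        results["smoking"] = pd.DataFrame(rows)
    if "longitudinal" in analyses:
        rows = []
        for t in tissues:
            res = longitudinal_concordance(calls, tissue=t)
            res.stratum = t
            rows.append(res.as_row())
        results["longitudinal"] = pd.DataFrame(rows)

    for name, df in results.items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.12g")
    return results


def run_heritability(
    skew_table: str | Path,
    metadata_path: str | Path,
    out_path: str | Path,
    tissues: Optional[Sequence[str]] = None,
    age_threshold: float = 55.0,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Age-stratified ACE + intraclass-correlation table across tissues."""
    calls = build_cohort_table(read_skew_table(skew_table), read_metadata(metadata_path))
    if tissues is None:
        tissues = sorted(calls["tissue"].unique())
    rng = np.random.default_rng(seed)
    frames = []
    for t in tissues:
        df = stratified_heritability(
            calls, t, age_threshold=age_threshold,
            n_permutations=n_permutations, rng=rng,
        )
        if not df.empty:
            frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.to_csv(out_path, sep="\t", index=False, float_format="%.12g")
    return out


def run_all(
    config: SimulationConfig,
    out_dir: str | Path,
    analyses: Sequence[str] = _ALL_ANALYSES,
    n_permutations: int = 10_000,
) -> Path:
    """Synthetic end-to-end run: simulate, quantify, run statistics, fit models.

    Deterministic given ``config.seed``.  On stage failure a FAILED marker
    naming the stage is left in the output directory and the error re-raised.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_seed, herit_seed = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(config.seed).spawn(2)]
    stage = "simulate"
    try:
        sim_config = SimulationConfig.from_dict({**config.to_dict(), "seed": sim_seed})
        paths = simulate_cohort(sim_config, out_dir / "inputs")
        stage = "quantify"
        qc = QuantificationConfig(
            xist_interval=config.xist_interval, par_intervals=config.par_intervals,
        )
        sites = pd.read_csv(paths.sites, sep="\t")
        escape_sites = sites.loc[sites["escape"] > 0, "position"].astype(int).tolist()
        run_quantify(
            paths.counts_dir, paths.vcf, paths.metadata, out_dir / "skew_table.tsv",
            qc=qc, escape_sites=escape_sites, nonpar_out=out_dir / "nonpar_table.tsv",
        )
        stage = "stats"
        run_stats(
            out_dir / "skew_table.tsv", paths.metadata, out_dir / "stats",
            analyses=analyses, age_threshold=config.age_threshold,
        )
        stage = "heritability"
        run_heritability(
            out_dir / "skew_table.tsv", paths.metadata, out_dir / "heritability.tsv",
            age_threshold=config.age_threshold, n_permutations=n_permutations,
            seed=herit_seed,
        )
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    manifest = {
        "xciskew_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "analyses": list(analyses),
        "n_permutations": n_permutations,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir
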