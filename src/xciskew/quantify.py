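"""X-inactivation skew from XIST allele-specific expression.

In female bulk tissue, XIST is expressed only from the inactive X, so the
phased allelic ratio of reads over heterozygous SNVs inside XIST measures
the fraction of cells that inactivated a given parental haplotype.  The
sample-level statistic is

    XIST_ASE = mean over informative XIST SNVs of the haplotype-1 read fraction
    DS       = |0.5 - XIST_ASE|            (degree of skewing, in [0, 0.5])

A sample is called *skewed* when DS >= 0.3, i.e. at least an 80:20 cellular
mosaic (XIST_ASE <= 0.2 or >= 0.8), and *random* otherwise.  Sites must be
phased before averaging: averaging raw reference fractions across SNVs with
opposite phase would cancel the signal.

An alternative estimator aggregates the phased read fractions of all non-PAR
sites outside XIST (genes subject to inactivation are expressed from the
active X, so its expectation under full silencing is 1 - p rather than p).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .io import AllelicSite, PhasedGenotype

logger = logging.getLogger(__name__)

__all__ = [
    "SiteASE",
    "SkewCall",
    "NonParResult",
    "NonInformativeSample",
    "DEFAULT_MIN_DEPTH",
    "SKEW_THRESHOLD",
    "filter_sites",
    "site_ase",
    "xist_ase",
    "degree_of_skewing",
    "classify_skew",
    "nonpar_ase",
    "quantify_sample",
]

DEFAULT_MIN_DEPTH = 10
SKEW_THRESHOLD = 0.3


class NonInformativeSample(ValueError):
    """A sample with no informative XIST site: no skew call can be made."""


@dataclass(frozen=True)
class SiteASE:
    """Per-site allele-specific expression, both raw and phase-aligned."""

    site: AllelicSite
    ref_fraction: float
    hap1_fraction: float


@dataclass(frozen=True)
class SkewCall:
    sample_id: str
    tissue: str
    n_snps: int
    xist_ase: float
    ds: float
    classification: str


@dataclass(frozen=True)
class NonParResult:
    """Alternative skew estimate from non-PAR, non-XIST sites."""

    sample_id: str
    n_sites: int
    value: float  # mean phased hap1 fraction
    deviation: float  # |0.5 - value|, comparable to DS


def filter_sites(
    sites: Sequence[AllelicSite],
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_allele_count: int = 1,
) -> list[AllelicSite]:
    """Keep sites with depth >= ``min_depth`` and both alleles observed.

    The two published filters: total read depth of at least ten, and each
    allele seen at least once in the RNA (guarding against genotyping error
    at apparently-heterozygous sites).  Order is preserved; exclusion counts
    are logged.
    """
    kept: list[AllelicSite] = []
    n_depth = n_mono = 0
    for s in sites:
        if s.total_count < min_depth:
            n_depth += 1
        elif s.ref_count < min_allele_count or s.alt_count < min_allele_count:
            n_mono += 1
        else:
            kept.append(s)
    if n_depth or n_mono:
        logger.info(
            "filter_sites: kept %d / %d (excluded %d low depth, %d monoallelic)",
            len(kept), len(sites), n_depth, n_mono,
        )
    return kept


def site_ase(site: AllelicSite, phase: PhasedGenotype) -> SiteASE:
    """Reference-allele fraction at a site, re-oriented to haplotype 1.

    ``phase`` is the phased genotype of the individual the sample was drawn
    from (sample ids may differ between RNA sample and DNA genotype).
    """
    def _norm(c: str) -> str:
        return c[3:] if c.lower().startswith("chr") else c

    if phase.position != site.position or _norm(phase.contig) != _norm(site.contig):
        raise ValueError(
            f"phase record {phase.contig}:{phase.position} does not "
            f"match count row {site.contig}:{site.position}"
        )
    total = site.total_count
    if total == 0:
        raise ValueError("site has zero depth; filter before computing ASE")
    ref_fraction = site.ref_count / total
    hap1_fraction = ref_fraction if phase.hap1_is_ref else 1.0 - ref_fraction
    return SiteASE(site=site, ref_fraction=ref_fraction, hap1_fraction=hap1_fraction)


def xist_ase(sample_sites: Sequence[SiteASE], weight_by_depth: bool = False) -> float:
    """Sample-level XIST allelic expression: mean phased fraction over SNVs.

    The published statistic is the unweighted arithmetic mean; a
    depth-weighted variant is available behind a flag.
    """
    if not sample_sites:
        raise NonInformativeSample("no informative XIST site for this sample")
    if weight_by_depth:
        w = sum(s.site.total_count for s in sample_sites)
        return sum(s.hap1_fraction * s.site.total_count for s in sample_sites) / w
    return sum(s.hap1_fraction for s in sample_sites) / len(sample_sites)


def degree_of_skewing(xist_ase_value: float) -> float:
    """DS = |0.5 - XIST_ASE|: magnitude of skew, ignoring parental direction."""
    if not 0.0 <= xist_ase_value <= 1.0:
        raise ValueError(f"XIST_ASE must lie in [0, 1], got {xist_ase_value}")
    return abs(0.5 - xist_ase_value)


def classify_skew(ds: float, threshold: float = SKEW_THRESHOLD) -> str:
    """'skewed' iff DS >= threshold (boundary inclusive), else 'random'."""
    if not 0.0 <= ds <= 0.5 + 1e-12:
        raise ValueError(f"DS must lie in [0, 0.5], got {ds}")
    return "skewed" if ds >= threshold else "random"


def nonpar_ase(
    sample_sites: Sequence[SiteASE],
    min_sites: int = 5,
    escape_positions: Optional[Iterable[int]] = None,
) -> Optional[NonParResult]:
    """Alternative skew estimate from phased non-PAR, non-XIST site fractions.

    Sites listed in ``escape_positions`` (genes escaping inactivation, whose
    biallelic expression dilutes the signal) are excluded.  Returns None when
    fewer than ``min_sites`` informative sites remain.
    """
    escape = set(escape_positions) if escape_positions is not None else set()
    usable = [
        s for s in sample_sites
        if not s.site.in_xist and not s.site.in_par and s.site.position not in escape
    ]
    if len(usable) < min_sites:
        return None
    value = sum(s.hap1_fraction for s in usable) / len(usable)
    return NonParResult(
        sample_id=usable[0].site.sample_id,
        n_sites=len(usable),
        value=value,
        deviation=abs(0.5 - value),
    )


def quantify_sample(
    sites: Sequence[AllelicSite],
    phases: Mapping[int, PhasedGenotype],
    sample_id: str,
    tissue: str = "",
    min_depth: int = DEFAULT_MIN_DEPTH,
    skew_threshold: float = SKEW_THRESHOLD,
    weight_by_depth: bool = False,
) -> tuple[Optional[SkewCall], list[SiteASE]]:
    """Run the full per-sample pipeline: filter, phase-align, average, classify.

    ``phases`` maps position -> PhasedGenotype for this sample's individual.
    Returns (skew call or None if non-informative, all phased site ASE values
    that passed filters — XIST and non-XIST alike, for the alternative
    estimator).
    """
    kept = filter_sites(sites, min_depth=min_depth)
    ases: list[SiteASE] = []
    n_unphased = 0
    for s in kept:
        phase = phases.get(s.position)
        if phase is None:
            n_unphased += 1
            continue
        ases.append(site_ase(s, phase))
    if n_unphased:
        logger.info("%s: %d filtered sites had no phased genotype", sample_id, n_unphased)
    xist_sites = [a for a in ases if a.site.in_xist]
    if not xist_sites:
        return None, ases
    value = xist_ase(xist_sites, weight_by_depth=weight_by_depth)
    ds = degree_of_skewing(value)
    call = SkewCall(
        sample_id=sample_id,
        tissue=tissue,
        n_snps=len(xist_sites),
        xist_ase=value,
        ds=ds,
        classification=classify_skew(ds, threshold=skew_threshold),
    )
    return call, ases
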