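"""Configuration objects: genomic intervals, simulation parameters, pipeline settings.

Coordinates are 1-based inclusive (VCF convention) throughout; interval
membership is inclusive on both ends.  The XIST and pseudo-autosomal (PAR)
intervals are configuration values with GRCh37 defaults, not hard-coded
constants, so other builds or annotations can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

__all__ = [
    "GenomicInterval",
    "TissueSpec",
    "SimulationConfig",
    "QuantificationConfig",
    "XIST_GRCH37",
    "PAR1_GRCH37",
    "PAR2_GRCH37",
    "load_yaml_config",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, both-ends-inclusive interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    def contains(self, contig: str, position: int) -> bool:
        return _norm_contig(contig) == _norm_contig(self.contig) and self.start <= position <= self.end

    def __str__(self) -> str:  # CHR:START-END, as accepted by the CLI
        return f"{self.contig}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        contig, _, span = text.partition(":")
        start, _, end = span.partition("-")
        return cls(contig, int(start), int(end))


def _norm_contig(contig: str) -> str:
    return contig[3:] if contig.lower().startswith("chr") else contig


# GRCh37 annotations (GENCODE-era coordinates), used as defaults only.
XIST_GRCH37 = GenomicInterval("X", 73_040_486, 73_072_588)
PAR1_GRCH37 = GenomicInterval("X", 60_001, 2_699_520)
PAR2_GRCH37 = GenomicInterval("X", 154_931_044, 155_260_560)


@dataclass(frozen=True)
class TissueSpec:
    """One simulated tissue.

    ``e_corr`` is the correlation of this tissue's unique-environment draw
    with the reference (first) tissue's draw; the induced latent inter-tissue
    correlation is a2 + c2 + e_corr * e2.  ``blood_like`` tissues receive the
    age-related skew drift and any smoking / disease effects.
    ``latent_scale`` multiplies the global latent standard deviation, letting
    primary tissues carry less skew variance than blood-derived ones.
    """

    name: str
    e_corr: float = 1.0
    blood_like: bool = False
    latent_scale: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.e_corr <= 1.0:
            raise ValueError("e_corr must lie in [-1, 1]")


def _default_tissues() -> tuple[TissueSpec, ...]:
    # latent_scale values calibrated so that, at latent_sd = 1.3, the share of
    # samples beyond the 80:20 mosaic is ~28-34% in blood-derived tissues but
    # only ~12% in fat and ~16% in skin
    return (
        TissueSpec("LCL", 1.0, True, 1.0),
        TissueSpec("whole_blood", 0.8, True, 1.0),
        TissueSpec("fat", 0.42, False, 0.69),
        TissueSpec("skin", 0.3, False, 0.76),
    )


@dataclass
class SimulationConfig:
    """All parameters of the synthetic twin cohort generator.

    The defaults describe the emulated study population: ~420 female twins
    (61 MZ pairs, 63 DZ pairs, 174 singletons) aged 38-85, with ACE variance
    shares on the latent logit-skew scale of (0, 0.01, 0.99) below the age
    threshold and (0.34, 0, 0.66) at or above it in blood-like tissues, an
    age-related drift of the latent skew magnitude above 55 years, and
    read-level sampling at heterozygous sites inside and outside XIST.
    """

    n_mz_pairs: int = 61
    n_dz_pairs: int = 63
    n_singletons: int = 174
    tissues: tuple[TissueSpec, ...] = field(default_factory=_default_tissues)
    age_range: tuple[float, float] = (38.0, 85.0)

    # latent-scale trait model: z = latent_sd * (sqrt(a2) A + sqrt(c2) C + sqrt(e2) E)
    variance_components: tuple[float, float, float] = (0.0, 0.01, 0.99)
    variance_components_older: Optional[tuple[float, float, float]] = (0.34, 0.0, 0.66)
    latent_sd: float = 1.3
    age_threshold: float = 55.0
    age_drift: float = 0.025  # latent units per year above the threshold, blood-like tissues

    # site counts and read sampling
    n_xist_snps: int = 3
    n_nonpar_snps: int = 30
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0  # negative-binomial size; 0 -> constant depth
    overdispersion_rho: float = 0.01  # beta-binomial intraclass correlation

    # escape from inactivation at non-PAR sites: P(e = 0) and Beta params of e | e > 0
    escape_zero_prob: float = 0.75
    escape_beta: tuple[float, float] = (1.0, 4.0)

    # covariates and (by default null) effects on the latent skew magnitude
    smoking_current_prob: float = 0.14
    smoking_unknown_prob: float = 0.36
    smoking_effect: float = 0.0
    n_ra_discordant_pairs: int = 8
    ra_effect: float = 0.0

    n_time_points: int = 1
    xist_interval: GenomicInterval = XIST_GRCH37
    par_intervals: tuple[GenomicInterval, ...] = (PAR1_GRCH37, PAR2_GRCH37)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for triple in filter(None, [self.variance_components, self.variance_components_older]):
            if len(triple) != 3 or any(v < 0 for v in triple):
                raise ValueError("variance components must be three non-negative numbers")
            if abs(sum(triple) - 1.0) > 1e-8:
                raise ValueError(f"variance components must sum to 1, got {triple}")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must lie in [0, 1)")
        if self.n_mz_pairs + self.n_dz_pairs + self.n_singletons < 1:
            raise ValueError("cohort must contain at least one individual")
        if self.age_range[0] < 0 or self.age_range[1] < self.age_range[0]:
            raise ValueError("invalid age_range")
        if not self.tissues:
            raise ValueError("at least one tissue required")
        if self.n_ra_discordant_pairs < 0:
            raise ValueError("n_ra_discordant_pairs must be non-negative")

    @property
    def n_individuals(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_pairs) + self.n_singletons

    def blood_like_tissues(self) -> list[str]:
        return [t.name for t in self.tissues if t.blood_like]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["xist_interval"] = str(self.xist_interval)
        d["par_intervals"] = [str(iv) for iv in self.par_intervals]
        d["tissues"] = [asdict(t) for t in self.tissues]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "xist_interval" in d and isinstance(d["xist_interval"], str):
            d["xist_interval"] = GenomicInterval.parse(d["xist_interval"])
        if "par_intervals" in d:
            d["par_intervals"] = tuple(
                GenomicInterval.parse(iv) if isinstance(iv, str) else iv for iv in d["par_intervals"]
            )
        if "tissues" in d:
            d["tissues"] = tuple(
                TissueSpec(**t) if isinstance(t, dict) else t for t in d["tissues"]
            )
        for key in ("age_range", "variance_components", "variance_components_older",
                    "escape_beta"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class QuantificationConfig:
    """Thresholds of the skew-calling stage (defaults as published)."""

    min_depth: int = 10
    min_allele_count: int = 1
    skew_threshold: float = 0.3  # DS at/above which a sample is called skewed
    min_nonpar_sites: int = 5
    weight_by_depth: bool = False
    xist_interval: GenomicInterval = XIST_GRCH37
    par_intervals: tuple[GenomicInterval, ...] = (PAR1_GRCH37, PAR2_GRCH37)


def load_yaml_config(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping (missing keys -> defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)
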