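import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small but complete synthetic cohort on disk (all pipeline inputs)."""
    from xciskew.config import SimulationConfig
    from xciskew.simulate import simulate_cohort

    cfg = SimulationConfig(
        n_mz_pairs=8, n_dz_pairs=8, n_singletons=6,
        n_time_points=2, depth_mean=60.0, seed=20_240_101,
    )
    out = tmp_path_factory.mktemp("cohort")
    paths = simulate_cohort(cfg, out)
    return cfg, paths


def make_vcf(path, records, samples=("S1",)):
    """Write a minimal plain-text VCF.

    ``records`` is a list of (chrom, pos, ref, alt, [gt per sample]).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = {r[0] for r in records}
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")
    return path
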