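import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/reference.py oracles

from rohscan import (
    GenotypeMatrix,
    PlantedIsland,
    PopulationSpec,
    SampleTable,
    SimConfig,
    simulate_cohort,
)


@pytest.fixture
def sample_table() -> SampleTable:
    return SampleTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "population": ["APZ", "APZ", "BEZ"],
        "group": ["modern", "modern", "wild"],
    }))


def make_matrix(genotypes, positions, samples=None, chrom="1") -> GenotypeMatrix:
    """Build a small matrix from a (sites × samples) genotype array."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.ndim == 1:
        genotypes = genotypes[:, None]
    n_samples = genotypes.shape[1]
    if samples is None:
        samples = SampleTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n_samples)],
            "population": ["P1"] * n_samples,
            "group": ["modern"] * n_samples,
        }))
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "id": ".", "ref": "A", "alt": "G",
    })
    return GenotypeMatrix(sites=sites, samples=samples, genotypes=genotypes)


@pytest.fixture
def small_cohort():
    """10-Mb two-modern-plus-wild cohort with moderate autozygosity."""
    cfg = SimConfig(
        populations=(
            PopulationSpec("POP1", n_samples=8),
            PopulationSpec("POP2", n_samples=8),
            PopulationSpec("WILD", group="wild", n_samples=6),
        ),
        chrom_lengths={"1": 10_000_000},
        snv_density=400.0,
        target_autozygosity=0.2,
        tract_generations=25.0,
        seed=11,
    )
    return simulate_cohort(cfg)


# hand-written fixture VCF: 5 biallelic SNVs + 1 indel + 1 triallelic site
FIXTURE_VCF = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=100000>
##contig=<ID=2,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t1|0\t./.
1\t300\trs3\tG\tGA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
1\t400\trs4\tT\tA,C\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0
1\t500\trs5\tG\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1
2\t150\trs6\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1
2\t250\trs7\tC\tG\t.\tPASS\t.\tGT\t1|1\t0/0\t0/0
"""


@pytest.fixture
def fixture_vcf(tmp_path) -> Path:
    path = tmp_path / "fixture.vcf"
    path.write_text(FIXTURE_VCF)
    return path
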