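"""Synthetic multi-population genotype cohorts with planted ground truth.

Emulates the statistical structure a ROH analysis assumes in WGS data:
dense irregularly-spaced biallelic SNVs, per-population allele frequencies,
long autozygous (IBD) tracts whose lengths are exponential with mean 50/g Mb
for g generations to the common ancestor, population-fixed "selection island"
regions, hom→het genotyping error, and missing genotypes. The planted truth
(tracts, islands, realized autozygosity) is returned alongside the matrix so
downstream detection can be scored against it.

No linkage disequilibrium beyond the tracts themselves is simulated, and
there is no recombination-graph realism or phasing.

Sampling order is fixed given the seed: site positions per chromosome (in
config order), per-population allele frequencies, per-island allele draws,
then per sample (population order, then index) tracts and genotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
)

MB = 1_000_000


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, modern/wild group, cohort size."""

    name: str
    group: str = "modern"
    n_samples: int = 10


@dataclass(frozen=True)
class PlantedIsland:
    """Region fixed homozygous in every sample of the affected populations."""

    chrom: str
    start: int
    end: int
    populations: tuple[str, ...]


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults describe a desk-scale analogue of a livestock/wild WGS cohort:
    4 modern populations and one wild outgroup (10 diploid samples each) on a
    30-Mb single-chromosome genome at 1 SNV/kb, with a quarter of each genome
    autozygous in tracts from common ancestors g = 10 generations back
    (mean tract length 50/g = 5 Mb).

    ``snv_density`` is SNVs per Mb; ``allele_freq_beta`` parameterises the
    Beta(a, b) background alt-allele frequency drawn per site per population;
    ``het_error_rate`` is the probability a true homozygous genotype is
    mis-called heterozygous; rates are probabilities in [0, 1].
    """

    populations: tuple[PopulationSpec, ...] = (
        PopulationSpec("POP1"), PopulationSpec("POP2"),
        PopulationSpec("POP3"), PopulationSpec("POP4"),
        PopulationSpec("WILD", group="wild"),
    )
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 30 * MB})
    snv_density: float = 1000.0
    allele_freq_beta: tuple[float, float] = (0.8, 0.8)
    target_autozygosity: float = 0.25
    tract_generations: float = 10.0
    planted_islands: tuple[PlantedIsland, ...] = ()
    het_error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.target_autozygosity, self.het_error_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.tract_generations <= 0:
            raise ValueError("tract_generations must be positive")
        for isl in self.planted_islands:
            length = self.chrom_lengths.get(isl.chrom)
            if length is None or isl.start < 1 or isl.end > length or isl.start > isl.end:
                raise ValueError(
                    f"island {isl.chrom}:{isl.start}-{isl.end} outside chromosome"
                )

    @property
    def mean_tract_bp(self) -> float:
        """Expected autozygous tract length, 50/g Mb."""
        return 50.0 * MB / self.tract_generations

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "populations" in raw:
            raw["populations"] = tuple(PopulationSpec(**p) for p in raw["populations"])
        if "planted_islands" in raw:
            raw["planted_islands"] = tuple(
                PlantedIsland(populations=tuple(p.pop("populations")), **p)
                for p in (dict(d) for d in raw["planted_islands"])
            )
        if "allele_freq_beta" in raw:
            raw["allele_freq_beta"] = tuple(raw["allele_freq_beta"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort.

    ``true_tracts`` maps sample_id → list of (chrom, start, end) 1-based
    inclusive autozygous intervals (non-overlapping, merged);
    ``realized_autozygosity`` is the per-sample fraction of the genome those
    tracts cover.
    """

    true_tracts: dict[str, list[tuple[str, int, int]]]
    planted_islands: tuple[PlantedIsland, ...]
    realized_autozygosity: dict[str, float]
    het_error_rate: float
    missing_rate: float
    seed: int


def _sample_tracts(
    rng: np.random.Generator, chrom_len: int, target: float, mean_tract: float
) -> list[tuple[int, int]]:
    """Alternating renewal process of autozygous tracts on [1, chrom_len].

    Tract lengths ~ Exp(mean_tract); gap lengths ~ Exp(mean_tract·(1−t)/t) so
    the stationary covered fraction is the target t. The walk starts inside a
    tract with probability t (residual length is again exponential by
    memorylessness). Overlaps cannot arise; zero-length rounded tracts are
    dropped, adjacent ones merged.
    """
    if target <= 0.0:
        return []
    if target >= 1.0:
        return [(1, chrom_len)]
    mean_gap = mean_tract * (1.0 - target) / target
    tracts: list[tuple[int, int]] = []
    pos = 0.0
    if rng.random() < target:
        end = rng.exponential(mean_tract)
        tracts.append((1, min(int(end), chrom_len)))
        pos = end
    while pos < chrom_len:
        pos += rng.exponential(mean_gap)
        if pos >= chrom_len:
            break
        start = int(pos) + 1
        pos += rng.exponential(mean_tract)
        end = min(int(pos), chrom_len)
        if end >= start:
            tracts.append((start, end))
    # merge touching/overlapping intervals so the truth is well-defined
    merged: list[tuple[int, int]] = []
    for s, e in tracts:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return [(s, e) for s, e in merged if e >= s]


def _hw_genotypes(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Hardy–Weinberg genotype draw at per-site alt frequencies p."""
    u = rng.random(p.shape)
    hom_ref = (1.0 - p) ** 2
    gt = np.full(p.shape, 2, dtype=np.int8)
    gt[u < hom_ref + 2 * p * (1 - p)] = 1
    gt[u < hom_ref] = 0
    return gt


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Simulate a genotype matrix plus its planted ground truth.

    Inside autozygous tracts all genotypes are homozygous for a single
    haplotype drawn at the population allele frequencies; inside planted
    islands every sample of the affected populations is homozygous for the
    same per-site allele; elsewhere genotypes are Hardy–Weinberg draws.
    Hom→het errors and missingness are applied last, independently per
    genotype. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_lengths)
    genome_bp = sum(cfg.chrom_lengths.values())

    # 1) site positions: uniform per chromosome, sorted, deduplicated
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom in chroms:
        length = cfg.chrom_lengths[chrom]
        n = int(round(cfg.snv_density * length / MB))
        pos = np.unique(rng.integers(1, length + 1, size=n))
        pos_by_chrom[chrom] = pos

    # alleles: ref A, alt G at every site (genotype codes carry the signal)
    site_frames = [
        pd.DataFrame({
            "chrom": chrom,
            "pos": pos_by_chrom[chrom],
            "id": [f"{chrom}:{p}" for p in pos_by_chrom[chrom]],
            "ref": "A",
            "alt": "G",
        })
        for chrom in chroms
    ]
    sites = pd.concat(site_frames, ignore_index=True)

    # 2) per-population background allele frequencies
    a, b = cfg.allele_freq_beta
    freqs: dict[str, dict[str, np.ndarray]] = {
        pop.name: {c: rng.beta(a, b, size=len(pos_by_chrom[c])) for c in chroms}
        for pop in cfg.populations
    }

    # 3) per-island fixed allele per site (shared by all affected samples)
    island_alleles: list[dict[str, np.ndarray]] = []
    for isl in cfg.planted_islands:
        pos = pos_by_chrom[isl.chrom]
        in_isl = (pos >= isl.start) & (pos <= isl.end)
        allele = (rng.random(int(in_isl.sum())) < 0.5).astype(np.int8) * 2
        island_alleles.append({"mask": in_isl, "genotype": allele})

    roster = pd.DataFrame([
        {"sample_id": f"{pop.name}_{i:03d}", "population": pop.name, "group": pop.group}
        for pop in cfg.populations
        for i in range(pop.n_samples)
    ])
    samples = SampleTable(roster)

    n_sites = len(sites)
    genotypes = np.empty((n_sites, len(samples)), dtype=np.int8)
    true_tracts: dict[str, list[tuple[str, int, int]]] = {}
    realized: dict[str, float] = {}

    offsets = {}
    off = 0
    for chrom in chroms:
        offsets[chrom] = off
        off += len(pos_by_chrom[chrom])

    col = 0
    for pop in cfg.populations:
        for i in range(pop.n_samples):
            sid = f"{pop.name}_{i:03d}"
            gt = np.empty(n_sites, dtype=np.int8)
            tracts: list[tuple[str, int, int]] = []
            covered = 0
            for chrom in chroms:
                pos = pos_by_chrom[chrom]
                p = freqs[pop.name][chrom]
                g = _hw_genotypes(rng, p)
                for s, e in _sample_tracts(
                    rng, cfg.chrom_lengths[chrom],
                    cfg.target_autozygosity, cfg.mean_tract_bp,
                ):
                    tracts.append((chrom, s, e))
                    covered += e - s + 1
                    lo, hi = np.searchsorted(pos, [s, e + 1])
                    g[lo:hi] = (rng.random(hi - lo) < p[lo:hi]).astype(np.int8) * 2
                sl = slice(offsets[chrom], offsets[chrom] + len(pos))
                gt[sl] = g
            for isl, alleles in zip(cfg.planted_islands, island_alleles):
                if pop.name in isl.populations:
                    sl = slice(offsets[isl.chrom],
                               offsets[isl.chrom] + len(pos_by_chrom[isl.chrom]))
                    block = gt[sl]
                    block[alleles["mask"]] = alleles["genotype"]
            genotypes[:, col] = gt
            true_tracts[sid] = tracts
            realized[sid] = covered / genome_bp
            col += 1

    # 4) genotyping error then missingness, independent per genotype
    if cfg.het_error_rate > 0:
        hom = (genotypes == 0) | (genotypes == 2)
        flip = hom & (rng.random(genotypes.shape) < cfg.het_error_rate)
        genotypes[flip] = 1
    if cfg.missing_rate > 0:
        genotypes[rng.random(genotypes.shape) < cfg.missing_rate] = MISSING

    gm = GenotypeMatrix(sites=sites, samples=samples, genotypes=genotypes)
    truth = SyntheticTruth(
        true_tracts=true_tracts,
        planted_islands=cfg.planted_islands,
        realized_autozygosity=realized,
        het_error_rate=cfg.het_error_rate,
        missing_rate=cfg.missing_rate,
        seed=cfg.seed,
    )
    return gm, truth


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix as a plain-text GT-only VCF 4.2.

    Round-trips exactly through :func:`rohscan.genotype_io.read_vcf`
    (genotype codes, site order, coordinates).
    """
    sites = gm.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in gm.chroms:
            max_pos = int(sites.loc[sites["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={max_pos}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples.sample_ids) + "\n")
        gt_str = np.vectorize(_GT_STRING.__getitem__)
        for row, (_, site) in zip(gm.genotypes, sites.iterrows()):
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref}\t{site.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gt_str(row)) + "\n"
            )


def write_truth(truth: SyntheticTruth, prefix: str | Path) -> None:
    """Write truth tracts as pooled BED (sample in the name column) + JSON summary."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".tracts.bed"), "w") as fh:
        for sid, tracts in truth.true_tracts.items():
            for chrom, s, e in tracts:
                fh.write(f"{chrom}\t{s - 1}\t{e}\t{sid}\n")
    summary = {
        "seed": truth.seed,
        "het_error_rate": truth.het_error_rate,
        "missing_rate": truth.missing_rate,
        "realized_autozygosity": truth.realized_autozygosity,
        "planted_islands": [
            {"chrom": i.chrom, "start": i.start, "end": i.end,
             "populations": list(i.populations)}
            for i in truth.planted_islands
        ],
    }
    with open(prefix.with_suffix(".truth.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
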