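"""Genomic inbreeding (F_ROH), ROH summaries, time mapping and diversity.

F_ROH for an individual is Σ L_ROH / L_AUTO: the summed length of its ROH
segments over the autosomal genome length spanned by SNV positions. The total
is decomposed over segment-length classes (0.1–0.3, 0.3–0.5, 0.5–1.0,
1.0–5.0, >5 Mb) because segment length proxies the age of the inbreeding
event: an autozygous segment of L Mb points to a common ancestor roughly
g = 50/L generations back (expected IBD segment length 100/(2g) cM with
1 cM ≈ 1 Mb), so 1-Mb segments trace to ~50 generations and 100-kb segments
to ~500 generations. Years follow with a configurable generation interval
(default 3 years, typical of managed goat populations).

Nucleotide diversity π is the per-bp average pairwise difference within a
population, estimated as the unbiased per-site heterozygosity
2p̂(1−p̂)·n/(n−1) summed over variant sites and divided by the genome span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable
from .roh_detection import RohSet, l_auto_kb_from_sites

#: L_AUTO of the 29 goat autosomes spanned by the study-scale SNV map, kb
GOAT_L_AUTO_KB = 2_465_617.0


@dataclass(frozen=True)
class GenomeSpec:
    """Autosomal genome length spanned by SNV positions, in kb."""

    l_auto_kb: float

    def __post_init__(self) -> None:
        if self.l_auto_kb <= 0:
            raise ValueError("l_auto_kb must be positive")

    @classmethod
    def from_sites(cls, sites: pd.DataFrame) -> "GenomeSpec":
        return cls(l_auto_kb_from_sites(sites))


@dataclass(frozen=True)
class LengthClassSpec:
    """Segment-length class boundaries in Mb, left-closed right-open.

    The default classes are [0.1,0.3), [0.3,0.5), [0.5,1.0), [1.0,5.0),
    [5.0,∞); segments shorter than the first boundary fall into an extra
    leading class so that class contributions always sum to the total.
    """

    boundaries_mb: tuple[float, ...] = (0.1, 0.3, 0.5, 1.0, 5.0)

    def __post_init__(self) -> None:
        b = self.boundaries_mb
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        b = self.boundaries_mb
        labels = [f"<{b[0]}"]
        labels += [f"{b[i]}-{b[i + 1]}" for i in range(len(b) - 1)]
        labels.append(f">{b[-1]}")
        return labels

    def class_of(self, length_mb: float) -> str:
        idx = int(np.searchsorted(self.boundaries_mb, length_mb, side="right"))
        return self.labels[idx]


@dataclass(frozen=True)
class TimeMapping:
    """Generation interval used to convert generations to years."""

    generation_interval_years: float = 3.0

    def __post_init__(self) -> None:
        if self.generation_interval_years <= 0:
            raise ValueError("generation interval must be positive")


@dataclass
class FrohResult:
    """Per-individual genomic inbreeding with its length-class decomposition."""

    sample_id: str
    f_roh_total: float
    f_roh_by_class: dict[str, float]
    l_roh_kb: float
    l_auto_kb: float


def compute_froh(
    rs: RohSet,
    spec: GenomeSpec,
    classes: LengthClassSpec = LengthClassSpec(),
) -> list[FrohResult]:
    """F_ROH = Σ L_ROH / L_AUTO per individual, partitioned by length class.

    Each segment contributes wholly to the class of its own total length.
    Samples without segments get F_ROH = 0. A segment longer than the genome
    is rejected.
    """
    results = []
    for sid, segments in rs.by_sample().items():
        by_class = {label: 0.0 for label in classes.labels}
        total_kb = 0.0
        for seg in segments:
            if seg.length_kb > spec.l_auto_kb:
                raise ValueError(
                    f"segment {seg.chrom}:{seg.start_pos}-{seg.end_pos} longer "
                    f"than the genome ({spec.l_auto_kb} kb)"
                )
            by_class[classes.class_of(seg.length_mb)] += seg.length_kb
            total_kb += seg.length_kb
        results.append(FrohResult(
            sample_id=sid,
            f_roh_total=total_kb / spec.l_auto_kb,
            f_roh_by_class={k: v / spec.l_auto_kb for k, v in by_class.items()},
            l_roh_kb=total_kb,
            l_auto_kb=spec.l_auto_kb,
        ))
    return results


def froh_frame(results: list[FrohResult]) -> pd.DataFrame:
    """Per-sample F_ROH table with one column per length class."""
    rows = []
    for r in results:
        row = {"sample_id": r.sample_id, "f_roh": r.f_roh_total}
        row.update({f"f_roh_{k}": v for k, v in r.f_roh_by_class.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def breed_summary(rs: RohSet, samples: SampleTable) -> pd.DataFrame:
    """Per-population ROH summary plus a pooled "Total" row.

    Columns: number of animals, mean segment count per individual (animals
    without segments count as zero), mean segment length over all of the
    population's segments, and maximum segment length (kb). Rows are ordered
    by population label.
    """
    seg_frame = rs.to_frame()
    pop_of = dict(zip(samples.frame["sample_id"], samples.frame["population"]))
    rows = []

    def summarize(label: str, sample_ids: list[str]) -> dict:
        segs = seg_frame[seg_frame["sample_id"].isin(sample_ids)]
        n_roh_per_animal = [
            int((segs["sample_id"] == s).sum()) for s in sample_ids
        ]
        return {
            "population": label,
            "n_animals": len(sample_ids),
            "mean_n_roh": float(np.mean(n_roh_per_animal)) if sample_ids else 0.0,
            "mean_length_kb": float(segs["length_kb"].mean()) if len(segs) else 0.0,
            "max_length_kb": float(segs["length_kb"].max()) if len(segs) else 0.0,
        }

    for pop in samples.populations:
        ids = [s for s in rs.sample_ids if pop_of.get(s) == pop]
        rows.append(summarize(pop, ids))
    rows.append(summarize("Total", list(rs.sample_ids)))
    return pd.DataFrame(rows)


def generations_from_length(length_mb: float) -> float:
    """Generations to the common ancestor implied by a ROH of given length.

    g = 50 / L(Mb), from the expected IBD segment length 100/(2g) cM with
    1 cM ≈ 1 Mb: 1-Mb segments → 50 generations, 100-kb segments → 500.
    """
    if length_mb <= 0:
        raise ValueError("segment length must be positive")
    return 50.0 / length_mb


def years_from_length(length_mb: float, tm: TimeMapping = TimeMapping()) -> float:
    """Years to the common ancestor: generations × generation interval."""
    return generations_from_length(length_mb) * tm.generation_interval_years


def nucleotide_diversity(
    gm: GenotypeMatrix,
    population: str,
    spec: GenomeSpec,
    per_variant_site: bool = False,
) -> float:
    """Nucleotide diversity π per bp within one population.

    π = [Σ_sites 2 p̂(1−p̂) · n/(n−1)] / L, with p̂ the alt-allele frequency
    among called genotypes and n the called allele count at the site. The
    denominator L is the genome span in bp (WGS convention); with
    ``per_variant_site`` it is the number of contributing sites instead.
    """
    cols = [gm.sample_index(s) for s in gm.samples.samples_of(population)]
    if len(cols) < 2:
        raise ValueError(f"population {population!r} has fewer than 2 samples")
    gt = gm.genotypes[:, cols]
    called = gt != MISSING
    n_alleles = 2 * called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    ok = n_alleles >= 2
    p = np.zeros(len(gt))
    p[ok] = alt[ok] / n_alleles[ok]
    het = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore"):
        correction = np.where(ok, n_alleles / np.maximum(n_alleles - 1, 1), 0.0)
    total = float((het * correction)[ok].sum())
    denom = float(ok.sum()) if per_variant_site else spec.l_auto_kb * 1000.0
    return total / denom if denom else 0.0
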