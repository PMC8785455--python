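"""Candidate-variant genotype tabulation and wild/domestic divergence screen.

Given a list of candidate coding variants (positions plus metadata such as
the protein consequence — effects are input metadata, never computed here),
tabulate exact genotype counts per population, derive alt-allele frequencies
from called genotypes, and rank variants by the absolute frequency
difference between the pooled domestic and pooled wild groups. A variant is
flagged divergent when that difference reaches ``min_divergence``
(default 0.5; the cut-off is an explicit, configurable stand-in for what is
otherwise an eyeballed selection).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SampleTable

GENOTYPE_CLASSES = ["hom_ref", "het", "hom_alt", "missing"]


@dataclass(frozen=True)
class CandidateVariant:
    """One candidate site: coordinates, alleles and free-text metadata."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: str = "."
    consequence: str = "."

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos} {self.ref_allele}>{self.alt_allele} ({self.gene})"


def read_candidates(path: str | Path) -> list[CandidateVariant]:
    """Read a candidate TSV with columns chrom, pos, ref, alt, gene, consequence."""
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CandidateVariant(
            chrom=str(r.chrom), pos=int(r.pos),
            ref_allele=str(r.ref), alt_allele=str(r.alt),
            gene=str(getattr(r, "gene", ".")),
            consequence=str(getattr(r, "consequence", ".")),
        )
        for r in frame.itertuples()
    ]


@dataclass
class VariantResult:
    """Counts and frequencies for one candidate variant.

    ``counts``: population × (hom_ref, het, hom_alt, missing), exact genotype
    counts summing to population size. ``alt_freq``: per-population alt
    frequency over called alleles (NaN when no genotype is called). A variant
    absent from the matrix is reported with ``present=False``, never skipped.
    """

    variant: CandidateVariant
    present: bool
    counts: pd.DataFrame | None = None
    alt_freq: pd.Series | None = None


@dataclass
class ScreenResult:
    """Tabulated candidate variants for one cohort."""

    results: list[VariantResult]
    samples: SampleTable

    def __iter__(self):
        return iter(self.results)


def tabulate_genotypes(
    gm: GenotypeMatrix,
    variants: Sequence[CandidateVariant],
    samples: SampleTable | None = None,
) -> ScreenResult:
    """Exact per-population genotype counts at each candidate variant.

    A candidate whose chrom/pos is absent from the matrix is reported as
    absent; a candidate whose alleles disagree with the matrix site (e.g.
    ref/alt swapped) raises ``ValueError`` naming the variant.
    """
    samples = samples or gm.samples
    pops = samples.frame["population"].to_numpy()
    pop_labels = samples.populations
    key_to_row = {
        (c, p): i
        for i, (c, p) in enumerate(zip(gm.sites["chrom"], gm.sites["pos"]))
    }

    results = []
    for var in variants:
        row = key_to_row.get((var.chrom, var.pos))
        if row is None:
            results.append(VariantResult(variant=var, present=False))
            continue
        site = gm.sites.iloc[row]
        if (site["ref"], site["alt"]) != (var.ref_allele, var.alt_allele):
            raise ValueError(
                f"allele mismatch for {var.label}: matrix has "
                f"{site['ref']}>{site['alt']}"
            )
        gt = gm.genotypes[row]
        counts = pd.DataFrame(
            0, index=pop_labels, columns=GENOTYPE_CLASSES, dtype=int
        )
        for pop in pop_labels:
            sub = gt[pops == pop]
            counts.loc[pop] = [
                int((sub == 0).sum()), int((sub == 1).sum()),
                int((sub == 2).sum()), int((sub == MISSING).sum()),
            ]
        results.append(VariantResult(
            variant=var, present=True, counts=counts,
            alt_freq=allele_frequencies(counts),
        ))
    return ScreenResult(results=results, samples=samples)


def allele_frequencies(counts: pd.DataFrame) -> pd.Series:
    """Alt-allele frequency per population: (het + 2·hom_alt) / (2·called).

    Missing genotypes are excluded from the denominator; a population with no
    called genotype gets NaN.
    """
    called = counts[["hom_ref", "het", "hom_alt"]].sum(axis=1)
    alt = counts["het"] + 2 * counts["hom_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt / (2 * called)
    return freq.where(called > 0)


def _pooled_freq(counts: pd.DataFrame, populations: list[str]) -> float:
    sub = counts.loc[populations]
    called = int(sub[["hom_ref", "het", "hom_alt"]].to_numpy().sum())
    alt = int((sub["het"] + 2 * sub["hom_alt"]).sum())
    return alt / (2 * called) if called else float("nan")


def divergence_screen(
    sr: ScreenResult,
    min_divergence: float = 0.5,
) -> pd.DataFrame:
    """Wild vs domestic allele-frequency divergence, sorted descending.

    Frequencies are pooled over the genotype counts of each group's
    populations (so the pooled value is the count-weighted mean of population
    frequencies). Divergence is |domestic − wild|; ``divergent`` flags
    divergence ≥ ``min_divergence``.
    """
    frame = sr.samples.frame
    wild_pops = sorted(frame.loc[frame["group"] == "wild", "population"].unique())
    domestic_pops = sorted(frame.loc[frame["group"] == "modern", "population"].unique())
    if not wild_pops or not domestic_pops:
        raise ValueError("both wild and modern groups must be represented")

    rows = []
    for res in sr.results:
        if not res.present:
            rows.append({
                "variant": res.variant.label, "gene": res.variant.gene,
                "present": False, "wild_freq": np.nan, "domestic_freq": np.nan,
                "divergence": np.nan, "divergent": False,
            })
            continue
        wild = _pooled_freq(res.counts, wild_pops)
        dom = _pooled_freq(res.counts, domestic_pops)
        div = abs(dom - wild)
        rows.append({
            "variant": res.variant.label, "gene": res.variant.gene,
            "present": True, "wild_freq": wild, "domestic_freq": dom,
            "divergence": div, "divergent": bool(div >= min_divergence),
        })
    out = pd.DataFrame(rows)
    return out.sort_values("divergence", ascending=False, na_position="last").reset_index(drop=True)


def genotype_table(sr: ScreenResult, gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample genotype codes at the present candidate variants."""
    key_to_row = {
        (c, p): i
        for i, (c, p) in enumerate(zip(gm.sites["chrom"], gm.sites["pos"]))
    }
    data = {}
    for res in sr.results:
        if not res.present:
            continue
        row = key_to_row[(res.variant.chrom, res.variant.pos)]
        data[res.variant.label] = gm.genotypes[row]
    out = pd.DataFrame(data, index=gm.samples.sample_ids)
    out.insert(0, "population", gm.samples.frame["population"].to_numpy())
    return out
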