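"""ROH islands: shared-homozygosity regions and their classification.

For a group of individuals, each SNV gets the fraction of the group whose
ROH cover its position. A ROH island is a maximal run of consecutive SNVs on
one chromosome whose fraction is at or above a threshold (default 0.80 — at
least 80% of the group in a ROH), kept if it contains at least
``min_island_snvs`` SNVs. Islands detected in the pooled domestic cohort are
classified against the wild outgroup: an island whose mean wild fraction
falls below 55% is flagged as potentially domestication-related, since the
shared homozygosity arose after the wild/domestic split; islands homozygous
in both groups more likely reflect basic, selection-independent constraint.

Islands are also derived per population, their union annotated with genes,
and gene-level homozygosity profiles built: per gene × population, the mean
fraction over island SNVs inside the gene, flagged high above 0.75 and low
below 0.25 (strict inequalities).

Island bounds are the first/last qualifying SNV positions; no bp-distance
merging of adjacent islands is applied (``merge_gap_kb`` default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GeneRecord, GenotypeMatrix, SampleTable
from .roh_detection import RohSet

DEFAULT_ISLAND_THRESHOLD = 0.80
DEFAULT_WILD_THRESHOLD = 0.55
HIGH_GENE_FRACTION = 0.75
LOW_GENE_FRACTION = 0.25


@dataclass
class SnvRohFraction:
    """Per-SNV fraction of a group's individuals whose ROH cover the SNV."""

    group_label: str
    group_size: int
    fractions: np.ndarray  # aligned to the site table used to compute it

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) and (f.min() < 0.0 or f.max() > 1.0):
            raise ValueError("fractions outside [0, 1]")


@dataclass
class RohIsland:
    """Run of consecutive SNVs with group in-ROH fraction ≥ threshold."""

    chrom: str
    start_pos: int
    end_pos: int
    n_snv: int
    snv_indices: np.ndarray          # row indices into the site table
    snv_pos: np.ndarray              # member SNV positions
    mean_fraction: dict[str, float]  # group label → mean over member SNVs
    domestication_related: bool | None = None


def snv_roh_fraction(
    rs: RohSet,
    sites: pd.DataFrame,
    group: Sequence[str],
    group_label: str = "group",
) -> SnvRohFraction:
    """Fraction of ``group`` individuals with a ROH spanning each site."""
    group = list(group)
    if not group:
        raise ValueError("empty group")
    roster = set(rs.sample_ids)
    missing = [s for s in group if s not in roster]
    if missing:
        raise KeyError(f"samples not in RohSet: {missing}")

    pos_by_chrom = {
        chrom: block["pos"].to_numpy()
        for chrom, block in sites.groupby("chrom", sort=False)
    }
    offset_by_chrom = {
        chrom: int(block.index[0])
        for chrom, block in sites.groupby("chrom", sort=False)
    }
    counts = np.zeros(len(sites), dtype=np.int64)
    members = set(group)
    for seg in rs.segments:
        if seg.sample_id not in members or seg.chrom not in pos_by_chrom:
            continue
        pos = pos_by_chrom[seg.chrom]
        lo, hi = np.searchsorted(pos, [seg.start_pos, seg.end_pos + 1])
        off = offset_by_chrom[seg.chrom]
        counts[off + lo: off + hi] += 1
    return SnvRohFraction(group_label, len(group), counts / len(group))


def detect_islands(
    fr: SnvRohFraction,
    sites: pd.DataFrame,
    threshold: float = DEFAULT_ISLAND_THRESHOLD,
    min_island_snvs: int = 2,
) -> list[RohIsland]:
    """Maximal runs of consecutive same-chromosome SNVs with fraction ≥ threshold."""
    if len(fr.fractions) != len(sites):
        raise ValueError("fractions not aligned to sites")
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    above = fr.fractions >= threshold

    islands: list[RohIsland] = []
    i, n = 0, len(sites)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and chroms[j + 1] == chroms[j]:
            j += 1
        if j - i + 1 >= min_island_snvs:
            idx = np.arange(i, j + 1)
            islands.append(RohIsland(
                chrom=str(chroms[i]),
                start_pos=int(pos[i]),
                end_pos=int(pos[j]),
                n_snv=j - i + 1,
                snv_indices=idx,
                snv_pos=pos[idx].copy(),
                mean_fraction={fr.group_label: float(fr.fractions[idx].mean())},
            ))
        i = j + 1
    return islands


def classify_islands(
    islands: list[RohIsland],
    fr_wild: SnvRohFraction,
    wild_threshold: float = DEFAULT_WILD_THRESHOLD,
) -> list[RohIsland]:
    """Flag islands whose mean wild in-ROH fraction is below the threshold.

    Mutates and returns the islands: records the wild group's mean fraction
    over member SNVs and sets ``domestication_related`` to mean < threshold.
    """
    for isl in islands:
        mean_wild = float(fr_wild.fractions[isl.snv_indices].mean())
        isl.mean_fraction[fr_wild.group_label] = mean_wild
        isl.domestication_related = bool(mean_wild < wild_threshold)
    return islands


@dataclass
class IslandPipelineResult:
    """Pooled-cohort and per-population islands plus the union interval set."""

    pooled_islands: list[RohIsland]
    per_population_islands: dict[str, list[RohIsland]]
    fractions_by_population: dict[str, SnvRohFraction]
    pooled_fraction: SnvRohFraction
    wild_fraction: SnvRohFraction | None
    union_snv_indices: np.ndarray

    def union_intervals(self) -> list[tuple[str, int, int]]:
        """Merged (chrom, start, end) intervals over all per-population islands."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for islands in self.per_population_islands.values():
            for isl in islands:
                by_chrom.setdefault(isl.chrom, []).append((isl.start_pos, isl.end_pos))
        out: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            merged: list[list[int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            out.extend((chrom, s, e) for s, e in merged)
        return out


def run_island_pipeline(
    rs: RohSet,
    gm: GenotypeMatrix,
    samples: SampleTable | None = None,
    threshold: float = DEFAULT_ISLAND_THRESHOLD,
    min_island_snvs: int = 2,
    wild_threshold: float = DEFAULT_WILD_THRESHOLD,
) -> IslandPipelineResult:
    """Two-step island derivation with wild-outgroup classification.

    Step 1 pools all samples of the ``modern`` group, detects islands at the
    threshold, and classifies them against the wild group (when present).
    Step 2 detects islands separately within each population, wild included;
    their SNV union feeds gene profiling.
    """
    samples = samples or gm.samples
    sites = gm.sites

    modern = samples.group_samples("modern")
    wild = samples.group_samples("wild")
    pooled_group = modern if modern else samples.sample_ids
    pooled_fr = snv_roh_fraction(rs, sites, pooled_group, "modern")
    pooled_islands = detect_islands(pooled_fr, sites, threshold, min_island_snvs)

    wild_fr = None
    if wild:
        wild_fr = snv_roh_fraction(rs, sites, wild, "wild")
        classify_islands(pooled_islands, wild_fr, wild_threshold)

    fractions_by_pop: dict[str, SnvRohFraction] = {}
    per_pop: dict[str, list[RohIsland]] = {}
    union_mask = np.zeros(len(sites), dtype=bool)
    for pop in samples.populations:
        fr = snv_roh_fraction(rs, sites, samples.samples_of(pop), pop)
        fractions_by_pop[pop] = fr
        islands = detect_islands(fr, sites, threshold, min_island_snvs)
        per_pop[pop] = islands
        for isl in islands:
            union_mask[isl.snv_indices] = True

    return IslandPipelineResult(
        pooled_islands=pooled_islands,
        per_population_islands=per_pop,
        fractions_by_population=fractions_by_pop,
        pooled_fraction=pooled_fr,
        wild_fraction=wild_fr,
        union_snv_indices=np.flatnonzero(union_mask),
    )


# ---------------------------------------------------------------------------
# gene annotation and profiling
# ---------------------------------------------------------------------------

def annotate_genes(
    islands: Sequence[RohIsland], genes: Sequence[GeneRecord]
) -> list[list[GeneRecord]]:
    """Genes overlapping each island by ≥ 1 bp, ordered by start position."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    out = []
    for isl in islands:
        tree = trees.get(isl.chrom)
        hits = (
            [iv.data for iv in tree.overlap(isl.start_pos, isl.end_pos + 1)]
            if tree else []
        )
        out.append(sorted(hits, key=lambda g: (g.start, g.end, g.name)))
    return out


@dataclass
class GeneHomozygosityProfile:
    """Gene × population mean in-ROH fraction over island SNVs in the gene.

    ``fractions`` holds NaN for genes without island SNVs (reported, never
    silently dropped). ``high``/``low`` flag fractions strictly above 0.75 /
    strictly below 0.25.
    """

    fractions: pd.DataFrame
    n_island_snvs: pd.Series

    @property
    def high(self) -> pd.DataFrame:
        return self.fractions.gt(HIGH_GENE_FRACTION) & self.fractions.notna()

    @property
    def low(self) -> pd.DataFrame:
        return self.fractions.lt(LOW_GENE_FRACTION) & self.fractions.notna()


def gene_fraction_profile(
    genes: Sequence[GeneRecord],
    island_snv_indices: np.ndarray,
    sites: pd.DataFrame,
    fractions_by_population: Mapping[str, SnvRohFraction],
) -> GeneHomozygosityProfile:
    """Per gene × population mean fraction over island SNVs inside the gene."""
    chroms = sites["chrom"].to_numpy()[island_snv_indices]
    pos = sites["pos"].to_numpy()[island_snv_indices]

    rows = {}
    n_snvs = {}
    for g in genes:
        inside = island_snv_indices[
            (chroms == g.chrom) & (pos >= g.start) & (pos <= g.end)
        ]
        n_snvs[g.name] = len(inside)
        rows[g.name] = {
            pop: (float(fr.fractions[inside].mean()) if len(inside) else np.nan)
            for pop, fr in fractions_by_population.items()
        }
    return GeneHomozygosityProfile(
        fractions=pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1),
        n_island_snvs=pd.Series(n_snvs, dtype=int),
    )


def window_matrix(
    per_population_islands: Mapping[str, Sequence[RohIsland]],
    window_size: int = 1_000_000,
) -> pd.DataFrame:
    """Binary population × 1-Mb-window matrix of island occupancy.

    A cell is 1 iff the population has at least one island SNV inside the
    window. Columns are labelled ``chrom:window_end`` and ordered by
    chromosome then window. An island spanning a window boundary marks every
    window that contains one of its SNVs.
    """
    cells: dict[str, set[tuple[str, int]]] = {}
    all_windows: set[tuple[str, int]] = set()
    for pop, islands in per_population_islands.items():
        hit = set()
        for isl in islands:
            for w in np.unique((isl.snv_pos - 1) // window_size):
                hit.add((isl.chrom, int(w)))
        cells[pop] = hit
        all_windows |= hit
    windows = sorted(all_windows)
    frame = pd.DataFrame(
        [[int(w in cells[pop]) for w in windows] for pop in sorted(cells)],
        index=sorted(cells),
        columns=[f"{c}:{(w + 1) * window_size}" for c, w in windows],
    )
    return frame


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def islands_frame(islands: Sequence[RohIsland],
                  gene_lists: Sequence[Sequence[GeneRecord]] | None = None) -> pd.DataFrame:
    """Island table with per-group mean fractions and optional gene column."""
    rows = []
    for k, isl in enumerate(islands):
        row = {
            "chrom": isl.chrom, "start_pos": isl.start_pos,
            "end_pos": isl.end_pos, "n_snv": isl.n_snv,
        }
        row.update({f"mean_fraction_{g}": v for g, v in isl.mean_fraction.items()})
        if isl.domestication_related is not None:
            row["domestication_related"] = isl.domestication_related
        if gene_lists is not None:
            row["genes"] = ",".join(g.name for g in gene_lists[k]) or "."
        rows.append(row)
    return pd.DataFrame(rows)


def write_islands_bed(islands: Sequence[RohIsland], path: str | Path) -> None:
    """Islands as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for k, isl in enumerate(islands):
            fh.write(f"{isl.chrom}\t{isl.start_pos - 1}\t{isl.end_pos}\tisland_{k + 1}\n")


def write_manhattan_tsv(fr: SnvRohFraction, sites: pd.DataFrame, path: str | Path) -> None:
    """Per-SNV fractions as TSV (chrom, pos, fraction) for Manhattan plots."""
    pd.DataFrame({
        "chrom": sites["chrom"], "pos": sites["pos"], "fraction": fr.fractions,
    }).to_csv(path, sep="\t", index=False)
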