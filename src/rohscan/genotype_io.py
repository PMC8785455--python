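"""Genotype input/output and site-level quality control.

Reads multi-sample biallelic-SNV genotypes from VCF into an integer-coded
matrix, applies the cohort quality-control filters (autosomal, biallelic SNV,
polymorphic, overall and within-population call rate, optional per-genotype
depth masking), and parses gene annotation intervals from BED or GFF3.

Coordinates are 1-based inclusive everywhere inside the package (the VCF
convention); BED's 0-based half-open intervals are converted at the boundary.
Genotypes are coded 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype code for a missing call
MISSING: int = -1

GROUPS = ("modern", "wild")


# ---------------------------------------------------------------------------
# sample roster
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Sample → population → group (modern/wild) assignment.

    Wraps a DataFrame with columns ``sample_id``, ``population``, ``group``.
    Sample ids must be unique and each population must belong to exactly one
    group.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "population", "group"}
        missing_cols = required - set(self.frame.columns)
        if missing_cols:
            raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
        if self.frame["sample_id"].duplicated().any():
            dups = self.frame.loc[self.frame["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        bad_groups = set(self.frame["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown groups {sorted(bad_groups)}; expected {GROUPS}")
        n_groups = self.frame.groupby("population")["group"].nunique()
        split = n_groups[n_groups > 1]
        if not split.empty:
            raise ValueError(f"populations mapped to multiple groups: {list(split.index)}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleTable":
        """Read a TSV with header ``sample_id\\tpopulation\\tgroup``."""
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        """Population labels in sorted order."""
        return sorted(self.frame["population"].unique())

    def samples_of(self, population: str) -> list[str]:
        sel = self.frame["population"] == population
        if not sel.any():
            raise KeyError(f"population {population!r} not in sample table")
        return self.frame.loc[sel, "sample_id"].tolist()

    def group_samples(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise KeyError(f"unknown group {group!r}")
        return self.frame.loc[self.frame["group"] == group, "sample_id"].tolist()

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.frame[self.frame["sample_id"].isin(set(sample_ids))]
        return SampleTable(keep.copy())

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Sites × samples genotype codes with site coordinates and sample roster.

    ``sites`` is a DataFrame with columns chrom, pos, id, ref, alt sorted by
    (chrom block, pos); ``genotypes`` is an int8 array of shape
    (n_sites, n_samples) with codes {0, 1, 2, MISSING}; ``depths`` optionally
    carries per-genotype read depth (same shape, -1 where absent).
    """

    sites: pd.DataFrame
    samples: SampleTable
    genotypes: np.ndarray
    depths: np.ndarray | None = None

    def __post_init__(self) -> None:
        if list(self.sites.columns) != SITE_COLUMNS:
            self.sites = self.sites[SITE_COLUMNS]
        self.sites = self.sites.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} != "
                f"({len(self.sites)} sites, {len(self.samples)} samples)"
            )
        for chrom, block in self.sites.groupby("chrom", sort=False):
            pos = block["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"sites not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def chroms(self) -> list[str]:
        """Chromosomes in input order."""
        return list(dict.fromkeys(self.sites["chrom"]))

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def take_sites(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            samples=self.samples,
            genotypes=self.genotypes[idx],
            depths=None if self.depths is None else self.depths[idx],
        )

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Contiguous (chrom, row-slice) blocks in site order."""
        out: list[tuple[str, slice]] = []
        chroms = self.sites["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((chroms[start], slice(start, i)))
                start = i
        return out


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

_SNV_ALLELES = frozenset("ACGT")


def _is_biallelic_snv(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _SNV_ALLELES
        and alts[0].upper() in _SNV_ALLELES
        and ref.upper() != alts[0].upper()
    )


def read_vcf(
    path: str | Path,
    sample_table: SampleTable,
    region: tuple[str, int, int] | None = None,
) -> GenotypeMatrix:
    """Read a coordinate-sorted VCF into a GenotypeMatrix.

    Multi-allelic and non-SNV records are dropped (count logged). Phased and
    unphased genotypes are treated identically. ``region`` is an optional
    (chrom, start, end) 1-based inclusive filter.

    Raises ``KeyError`` if a roster sample is absent from the VCF header and
    ``ValueError`` if the input is not coordinate-sorted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    absent = [s for s in sample_table.sample_ids if s not in header_samples]
    if absent:
        raise KeyError(f"samples not in VCF header: {absent}")
    vcf.set_samples(sample_table.sample_ids)
    col_of = {s: i for i, s in enumerate(vcf.samples)}
    order = np.array([col_of[s] for s in sample_table.sample_ids])

    rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    site_records: list[tuple] = []
    n_dropped = 0
    has_depth = False
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()

    for v in vcf:
        if last is not None:
            if v.CHROM == last[0]:
                if v.POS < last[1]:
                    raise ValueError(
                        f"VCF not coordinate-sorted at {v.CHROM}:{v.POS}"
                    )
            elif v.CHROM in seen_chroms:
                raise ValueError(f"chromosome {v.CHROM} appears in two blocks")
        seen_chroms.add(v.CHROM)
        last = (v.CHROM, v.POS)

        if region is not None:
            chrom, start, end = region
            if v.CHROM != chrom or not (start <= v.POS <= end):
                continue
        if not _is_biallelic_snv(v.REF, v.ALT):
            n_dropped += 1
            continue

        gt = np.asarray(v.gt_types)[order].astype(np.int8)
        gt[gt == 3] = MISSING  # cyvcf2 gts012: 3 = unknown
        rows.append(gt)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            has_depth = True
            depth_rows.append(np.asarray(dp).reshape(-1)[order].astype(np.int32))
        else:
            depth_rows.append(np.full(len(order), -1, dtype=np.int32))
        site_records.append((v.CHROM, v.POS, v.ID or ".", v.REF, v.ALT[0]))

    if n_dropped:
        logger.info("read_vcf: dropped %d multi-allelic/non-SNV records", n_dropped)

    sites = pd.DataFrame(site_records, columns=SITE_COLUMNS) if site_records else (
        pd.DataFrame({c: pd.Series(dtype=("int64" if c == "pos" else "object"))
                      for c in SITE_COLUMNS})
    )
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(sample_table)), dtype=np.int8)
    )
    depths = np.vstack(depth_rows) if (depth_rows and has_depth) else None
    return GenotypeMatrix(sites=sites, samples=sample_table,
                          genotypes=genotypes, depths=depths)


# ---------------------------------------------------------------------------
# site filters
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Site-level quality-control thresholds.

    ``min_call_rate_overall`` / ``min_call_rate_per_population``: minimum
    fraction of called genotypes across the cohort and within every single
    population (both default 0.90). ``autosomes``: explicit set of chromosome
    names to keep (None keeps all — sex chromosomes and MT are excluded by
    listing autosomes, never by name heuristics). ``min_depth``: per-genotype
    read-depth floor, applied only when the matrix carries depths; genotypes
    below it are set missing before call rates are computed.
    """

    min_call_rate_overall: float = 0.90
    min_call_rate_per_population: float = 0.90
    autosomes: frozenset[str] | None = None
    require_biallelic_snv: bool = True
    min_depth: int = 8

    def __post_init__(self) -> None:
        for r in (self.min_call_rate_overall, self.min_call_rate_per_population):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"call rate {r} outside [0, 1]")
        if self.autosomes is not None:
            self.autosomes = frozenset(self.autosomes)


@dataclass
class FilterResult:
    """Filtered matrix plus the number of sites dropped per rule."""

    matrix: GenotypeMatrix
    dropped: Counter = field(default_factory=Counter)


def filter_sites(gm: GenotypeMatrix, cfg: FilterConfig) -> FilterResult:
    """Apply the site QC filters and report per-rule drop counts.

    Retains sites that are autosomal, biallelic SNVs, have overall call rate
    ≥ ``min_call_rate_overall`` AND call rate ≥
    ``min_call_rate_per_population`` within every population, and are
    polymorphic (both alleles observed among called genotypes). A site failing
    several rules is counted against the first one in that order. Idempotent.
    """
    gt = gm.genotypes.copy()
    if gm.depths is not None and cfg.min_depth > 0:
        gt[(gm.depths >= 0) & (gm.depths < cfg.min_depth)] = MISSING

    n_sites, n_samples = gt.shape
    called = gt != MISSING

    keep = np.ones(n_sites, dtype=bool)
    dropped: Counter = Counter()

    def apply_rule(name: str, ok: np.ndarray) -> None:
        newly = keep & ~ok
        dropped[name] += int(newly.sum())
        keep[newly] = False

    if cfg.autosomes is not None:
        apply_rule("non_autosomal",
                   gm.sites["chrom"].isin(cfg.autosomes).to_numpy())

    if cfg.require_biallelic_snv:
        ok = np.array([
            _is_biallelic_snv(r, [a])
            for r, a in zip(gm.sites["ref"], gm.sites["alt"])
        ]) if n_sites else np.ones(0, dtype=bool)
        apply_rule("non_biallelic_snv", ok)

    if n_samples:
        apply_rule("call_rate_overall",
                   called.sum(axis=1) / n_samples >= cfg.min_call_rate_overall)

        pop_ok = np.ones(n_sites, dtype=bool)
        pops = gm.samples.frame["population"].to_numpy()
        for pop in gm.samples.populations:
            cols = np.flatnonzero(pops == pop)
            rate = called[:, cols].sum(axis=1) / len(cols)
            pop_ok &= rate >= cfg.min_call_rate_per_population
        apply_rule("call_rate_population", pop_ok)

    has_alt = ((gt == 1) | (gt == 2)).any(axis=1)
    has_ref = ((gt == 0) | (gt == 1)).any(axis=1)
    apply_rule("monomorphic", has_alt & has_ref)

    out = GenotypeMatrix(
        sites=gm.sites.iloc[np.flatnonzero(keep)].reset_index(drop=True),
        samples=gm.samples,
        genotypes=gt[keep],
        depths=None,  # depth already applied; masking is idempotent
    )
    if out.n_sites == 0:
        logger.warning("filter_sites: no sites retained")
    return FilterResult(matrix=out, dropped=dropped)


# ---------------------------------------------------------------------------
# gene annotation intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """Gene interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")


def _parse_gff3_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for part in attrs.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes(path: str | Path, feature_types: Iterable[str] = ("gene",)) -> list[GeneRecord]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    The format is chosen by extension (.gff/.gff3 → GFF3, otherwise BED);
    both are converted to 1-based inclusive coordinates. For GFF3 only
    ``feature_types`` rows are kept and the name is taken from the Name, gene
    or ID attribute. Malformed lines raise ``ValueError`` with the line number.
    """
    path = Path(path)
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    wanted = set(feature_types)
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (not is_gff and line.startswith(("track", "browser"))):
                continue
            fields = line.split("\t")
            try:
                if is_gff:
                    if len(fields) < 9:
                        raise ValueError("GFF3 line has fewer than 9 fields")
                    if fields[2] not in wanted:
                        continue
                    attrs = _parse_gff3_attributes(fields[8])
                    name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID") or "."
                    genes.append(GeneRecord(fields[0], int(fields[3]), int(fields[4]), name))
                else:
                    if len(fields) < 3:
                        raise ValueError("BED line has fewer than 3 fields")
                    start0, end0 = int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else "."
                    genes.append(GeneRecord(fields[0], start0 + 1, end0, name))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from exc
    return genes


def write_genes_bed(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.name}\n")
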