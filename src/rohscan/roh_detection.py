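"""Sliding-window detection of runs of homozygosity (ROH).

Implements the scanning-window algorithm popularised by PLINK's --homozyg:
a window of ``window_snp`` consecutive SNVs slides along each chromosome and
is scored homozygous when it contains at most ``window_het`` heterozygous and
``window_missing`` missing calls — the heterozygote allowance exists because
erroneous het calls in WGS data would otherwise break long genuine ROH. Each
SNV receives the fraction of windows containing it that scored homozygous;
SNVs at or above ``window_threshold`` with a non-het call are eligible, and
maximal runs of eligible SNVs become segments subject to minimum SNV count,
minimum length, maximum inter-SNV gap and maximum kb-per-SNV density gates.

Edge rule: per-SNV denominators count only fully contained windows; a
chromosome with fewer SNVs than ``window_snp`` is treated as one truncated
window. All threshold comparisons are inclusive.

Parameter sets are validated by the maximal-genome-coverage criterion: the
fraction of the SNV-spanned genome a fully homozygous pseudo-individual could
have called as ROH under those parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class RohParams:
    """ROH scanning parameters (kb units where named so).

    Defaults follow the scanning tool's conventions with the window het
    allowance at 3 and the minimum segment length at 100 kb.
    """

    window_snp: int = 50
    window_het: int = 3
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 100.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if min(self.window_snp, self.min_snp) <= 0 or min(
            self.min_kb, self.max_gap_kb, self.max_density_kb_per_snp
        ) <= 0:
            raise ValueError("all ROH parameters must be positive")
        if self.window_het >= self.window_snp:
            raise ValueError("window_het must be smaller than window_snp")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RohParams":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run: first/last SNV positions (1-based), SNV counts."""

    sample_id: str
    chrom: str
    start_pos: int
    end_pos: int
    n_snv: int
    n_hom: int = 0

    @property
    def length_kb(self) -> float:
        return (self.end_pos - self.start_pos + 1) / 1000.0

    @property
    def length_mb(self) -> float:
        return self.length_kb / 1000.0


@dataclass
class RohSet:
    """All segments of a cohort plus the parameters that produced them."""

    segments: list[RohSegment]
    params: RohParams
    sample_ids: list[str]

    def __post_init__(self) -> None:
        roster = set(self.sample_ids)
        for seg in self.segments:
            if seg.sample_id not in roster:
                raise ValueError(f"segment sample {seg.sample_id!r} not in cohort")

    def by_sample(self) -> dict[str, list[RohSegment]]:
        out: dict[str, list[RohSegment]] = {s: [] for s in self.sample_ids}
        for seg in self.segments:
            out[seg.sample_id].append(seg)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s.sample_id, s.chrom, s.start_pos, s.end_pos, s.n_snv, s.n_hom,
                 s.length_kb)
                for s in self.segments
            ],
            columns=["sample_id", "chrom", "start_pos", "end_pos", "n_snv",
                     "n_hom", "length_kb"],
        )


# ---------------------------------------------------------------------------
# window statistic
# ---------------------------------------------------------------------------

def _window_hit_fraction_chrom(genotypes: np.ndarray, p: RohParams) -> np.ndarray:
    """Per-SNV fraction of homozygous windows containing it, one chromosome."""
    g = np.asarray(genotypes)
    n = len(g)
    if n == 0:
        raise ValueError("chromosome without SNVs")
    w = min(p.window_snp, n)  # truncated single window on short chromosomes
    het = np.cumsum(np.concatenate(([0], g == 1)))
    mis = np.cumsum(np.concatenate(([0], g == MISSING)))
    n_win = n - w + 1
    het_w = het[w:] - het[:n_win]
    mis_w = mis[w:] - mis[:n_win]
    hom_win = (het_w <= p.window_het) & (mis_w <= p.window_missing)
    hom_cum = np.cumsum(np.concatenate(([0], hom_win)))

    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    return (hom_cum[hi + 1] - hom_cum[lo]) / (hi - lo + 1)


def snv_window_hit_fraction(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    p: RohParams,
) -> np.ndarray:
    """Fraction of homozygous windows covering each SNV, computed per chromosome.

    ``genotypes`` is one sample's code vector aligned to ``sites`` (which may
    span several chromosomes; windows never cross a chromosome boundary).
    """
    g = np.asarray(genotypes)
    if len(g) != len(sites):
        raise ValueError("genotypes not aligned to sites")
    out = np.empty(len(g), dtype=float)
    chroms = sites["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out[start:i] = _window_hit_fraction_chrom(g[start:i], p)
            start = i
    return out


# ---------------------------------------------------------------------------
# segment calling
# ---------------------------------------------------------------------------

def _call_chrom(
    genotypes: np.ndarray, positions: np.ndarray, p: RohParams
) -> list[tuple[int, int]]:
    """Index ranges [i, j] (inclusive) of qualifying runs on one chromosome."""
    frac = _window_hit_fraction_chrom(genotypes, p)
    eligible = (frac >= p.window_threshold) & (genotypes != 1)
    gap_break = np.diff(positions) > p.max_gap_kb * 1000.0

    runs: list[tuple[int, int]] = []
    i = 0
    n = len(genotypes)
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and eligible[j + 1] and not gap_break[j]:
            j += 1
        runs.append((i, j))
        i = j + 1

    out = []
    for i, j in runs:
        n_snv = j - i + 1
        length_kb = (positions[j] - positions[i] + 1) / 1000.0
        if (
            n_snv >= p.min_snp
            and length_kb >= p.min_kb
            and length_kb / n_snv <= p.max_density_kb_per_snp
        ):
            out.append((i, j))
    return out


def call_roh_sample(
    genotypes: np.ndarray,
    sites: pd.DataFrame,
    p: RohParams,
    sample_id: str = "sample",
) -> list[RohSegment]:
    """Call ROH segments for one sample across all chromosomes in ``sites``."""
    g = np.asarray(genotypes)
    if len(g) != len(sites):
        raise ValueError("genotypes not aligned to sites")
    segments: list[RohSegment] = []
    chroms = sites["chrom"].to_numpy()
    pos_all = sites["pos"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            gc, pc = g[start:i], pos_all[start:i]
            for a, b in _call_chrom(gc, pc, p):
                hom = (gc[a:b + 1] == 0) | (gc[a:b + 1] == 2)
                segments.append(RohSegment(
                    sample_id=sample_id,
                    chrom=chroms[start],
                    start_pos=int(pc[a]),
                    end_pos=int(pc[b]),
                    n_snv=int(b - a + 1),
                    n_hom=int(hom.sum()),
                ))
            start = i
    return segments


def call_roh(gm: GenotypeMatrix, p: RohParams) -> RohSet:
    """Call ROH for every sample of the matrix; deterministic order."""
    segments: list[RohSegment] = []
    for col, sid in enumerate(gm.samples.sample_ids):
        segments.extend(call_roh_sample(gm.genotypes[:, col], gm.sites, p, sid))
    return RohSet(segments=segments, params=p, sample_ids=gm.samples.sample_ids)


# ---------------------------------------------------------------------------
# parameter validation
# ---------------------------------------------------------------------------

def l_auto_kb_from_sites(sites: pd.DataFrame) -> float:
    """Autosomal length spanned by SNV positions: Σ_chrom (max−min+1), in kb."""
    if len(sites) == 0:
        raise ValueError("no sites")
    span = sites.groupby("chrom")["pos"].agg(lambda s: s.max() - s.min() + 1)
    return float(span.sum()) / 1000.0


def max_genome_coverage(sites: pd.DataFrame, p: RohParams) -> float:
    """Maximal genome coverage achievable under ``p`` on this site map.

    Runs the caller on a pseudo-individual homozygous and called at every SNV
    and returns total called length over the SNV-spanned genome length. Used
    to validate a parameter set: values near 1 mean the gates themselves do
    not bound detectable autozygosity.
    """
    pseudo = np.zeros(len(sites), dtype=np.int8)
    segments = call_roh_sample(pseudo, sites, p, "pseudo_hom")
    total_kb = sum(s.length_kb for s in segments)
    return total_kb / l_auto_kb_from_sites(sites)


# ---------------------------------------------------------------------------
# .hom interchange
# ---------------------------------------------------------------------------

_HOM_COLUMNS = ["FID", "IID", "CHR", "SNP1", "SNP2", "POS1", "POS2",
                "KB", "NSNP", "DENSITY", "PHOM", "PHET"]


def write_hom(rs: RohSet, path: str | Path) -> None:
    """Write segments as a whitespace-delimited .hom-style table."""
    rows = []
    for s in rs.segments:
        rows.append([
            s.sample_id, s.sample_id, s.chrom,
            f"{s.chrom}:{s.start_pos}", f"{s.chrom}:{s.end_pos}",
            s.start_pos, s.end_pos,
            f"{s.length_kb:.3f}", s.n_snv,
            f"{s.length_kb / s.n_snv:.4f}",
            f"{s.n_hom / s.n_snv:.4f}", f"{0.0:.4f}",
        ])
    with open(path, "w") as fh:
        if not rows:
            fh.write(" ".join(_HOM_COLUMNS) + "\n")
        else:
            frame = pd.DataFrame(rows, columns=_HOM_COLUMNS)
            fh.write(frame.to_string(index=False) + "\n")


def read_hom(path: str | Path, params: RohParams | None = None) -> RohSet:
    """Read a .hom-style table back into a RohSet."""
    frame = pd.read_csv(path, sep=r"\s+")
    segments = [
        RohSegment(
            sample_id=str(r.IID), chrom=str(r.CHR),
            start_pos=int(r.POS1), end_pos=int(r.POS2),
            n_snv=int(r.NSNP), n_hom=int(round(float(r.PHOM) * int(r.NSNP))),
        )
        for r in frame.itertuples()
    ]
    sample_ids = list(dict.fromkeys(s.sample_id for s in segments))
    return RohSet(segments=segments, params=params or RohParams(),
                  sample_ids=sample_ids)


def write_segments_bed(rs: RohSet, path: str | Path) -> None:
    """Export segments as BED (0-based half-open), sample id in the name column."""
    with open(path, "w") as fh:
        for s in rs.segments:
            fh.write(f"{s.chrom}\t{s.start_pos - 1}\t{s.end_pos}\t{s.sample_id}\n")
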