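"""Naive reference implementations used as independent oracles.

Each function is written directly from the stated behaviour with explicit
loops and materialised windows, deliberately sharing no code with the
optimized implementations it checks.
"""

from __future__ import annotations

import numpy as np

MISSING = -1


def naive_window_hit_fraction(genotypes, window_snp, window_het, window_missing):
    """Materialise every window explicitly; per-SNV hit fraction."""
    g = list(genotypes)
    n = len(g)
    w = min(window_snp, n)
    windows = []
    for i in range(n - w + 1):
        block = g[i:i + w]
        n_het = sum(1 for x in block if x == 1)
        n_mis = sum(1 for x in block if x == MISSING)
        windows.append((i, i + w - 1, n_het <= window_het and n_mis <= window_missing))
    fractions = []
    for j in range(n):
        containing = [hom for (a, b, hom) in windows if a <= j <= b]
        fractions.append(sum(containing) / len(containing))
    return np.array(fractions)


def naive_call_roh(genotypes, positions, window_snp, window_het, window_missing,
                   window_threshold, min_snp, min_kb, max_gap_kb,
                   max_density_kb_per_snp):
    """Segment calling on one chromosome, straight from the rule statement.

    Returns (start_pos, end_pos, n_snv) tuples.
    """
    frac = naive_window_hit_fraction(genotypes, window_snp, window_het,
                                     window_missing)
    g = list(genotypes)
    n = len(g)
    eligible = [frac[j] >= window_threshold and g[j] != 1 for j in range(n)]

    runs = []
    current = []
    for j in range(n):
        if not eligible[j]:
            if current:
                runs.append(current)
                current = []
            continue
        if current and positions[j] - positions[current[-1]] > max_gap_kb * 1000:
            runs.append(current)
            current = []
        current.append(j)
    if current:
        runs.append(current)

    segments = []
    for run in runs:
        n_snv = len(run)
        length_kb = (positions[run[-1]] - positions[run[0]] + 1) / 1000
        if (n_snv >= min_snp and length_kb >= min_kb
                and length_kb / n_snv <= max_density_kb_per_snp):
            segments.append((int(positions[run[0]]), int(positions[run[-1]]), n_snv))
    return segments


def naive_site_coverage_fraction(segments_by_sample, sites, group):
    """Per-site fraction of group members covered, by direct interval scan."""
    from intervaltree import IntervalTree

    trees = {}
    for sid in group:
        tree_by_chrom = {}
        for chrom, start, end in segments_by_sample.get(sid, []):
            tree_by_chrom.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        trees[sid] = tree_by_chrom
    fractions = []
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        hit = sum(
            1 for sid in group
            if chrom in trees[sid] and trees[sid][chrom].overlaps_point(pos)
        )
        fractions.append(hit / len(group))
    return np.array(fractions)
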