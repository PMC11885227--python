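"""Open-chromatin candidate inference from coverage monotonicity across
fetal-fraction tiers.

Active fetal promoters sit in nucleosome-depleted regions, so the fetal
component contributes *less* cfDNA coverage there; as the fetal fraction
rises across merged tiers (5/10/15/20%), coverage at such positions falls
monotonically.  Candidate positions passing the strict-monotonicity filter
are tested for differential coverage between the extreme tiers (conditional
binomial given library totals, Benjamini-Hochberg corrected), extended by
12 bp flanks into overlapping 25 bp windows, chained into runs (kept at >= 5
windows), and mapped to downstream genes whose functional enrichment is
summarised with a hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic_io import GeneAnnotation, GenomicInterval
from .fetal_regions import GroupLibrary

__all__ = [
    "TierSet",
    "CandidateBlock",
    "WindowRun",
    "EnrichmentRow",
    "monotonic_filter",
    "differential_coverage",
    "window_runs",
    "map_downstream_genes",
    "enrich",
    "overlap_pct",
    "infer_list_size",
]

DOWN, UP = -1, 1  # direction codes: coverage falling / rising with ff


@dataclass
class TierSet:
    """Four merged libraries at increasing mean fetal fraction (5-20%)."""

    tiers: list[GroupLibrary]

    def __post_init__(self):
        if len(self.tiers) != 4:
            raise ValueError("a TierSet holds exactly 4 merged libraries")
        ffs = [t.mean_ff for t in self.tiers]
        if np.any(np.diff(ffs) <= 0):
            raise ValueError("tier fetal fractions must be strictly increasing")
        counts = {t.n_samples for t in self.tiers}
        if len(counts) != 1:
            raise ValueError("tiers must contain equal sample counts")


@dataclass
class CandidateBlock:
    """Monotone candidate positions of one chromosome."""

    chrom: str
    pos: np.ndarray        # sorted positions
    direction: np.ndarray  # DOWN / UP per position


@dataclass
class WindowRun:
    """A chain of overlapping/abutting 25 bp candidate windows."""

    interval: GenomicInterval
    n_windows: int
    direction: int

    def __post_init__(self):
        if self.n_windows < 1:
            raise ValueError("a run holds at least one window")


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    gene_count: int        # k: input genes annotated to the term
    list_size: int         # N: input genes mapped to any term
    background_count: int  # K: background genes annotated to the term
    background_size: int   # M
    overlap_pct: float     # 100 * k / N
    p_value: float
    adjusted_p: float


def monotonic_filter(tiers: TierSet) -> dict[str, CandidateBlock]:
    """Positions whose normalised depth is strictly monotone across all four
    tiers, with the direction of change; everything else is dropped."""
    libs = tiers.tiers
    factors = np.array([1e6 / t.total_reads for t in libs])
    out: dict[str, CandidateBlock] = {}
    for chrom in libs[0].track.data:
        norm = np.stack([t.track.data[chrom] * f for t, f in zip(libs, factors)])
        diffs = np.diff(norm, axis=0)
        down = np.all(diffs < 0, axis=0)
        up = np.all(diffs > 0, axis=0)
        pos = np.flatnonzero(down | up)
        direction = np.where(down[pos], DOWN, UP).astype(np.int8)
        out[chrom] = CandidateBlock(chrom, pos, direction)
    return out


def _binom_two_sided(x: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Two-sided binomial p-value, double-the-smaller-tail convention."""
    lower = stats.binom.cdf(x, n, p0)
    upper = stats.binom.sf(x - 1, n, p0)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def differential_coverage(
    low: GroupLibrary,
    high: GroupLibrary,
    positions: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-position count test between two merged libraries.

    At each position the high-library count is tested against a binomial
    conditional on the pooled count, with success probability given by the
    library totals -- the exact two-library analogue of an RNA-seq count
    test.  Fold change is the normalised high/low ratio.  Positions with zero
    counts in both libraries are dropped (their number is in
    ``df.attrs['n_dropped']``); p-values are Benjamini-Hochberg adjusted.
    """
    rows = []
    n_dropped = 0
    p0 = high.total_reads / (low.total_reads + high.total_reads)
    for chrom, arr_low in low.track.data.items():
        arr_high = high.track.data[chrom]
        pos = (positions.get(chrom) if positions is not None
               else np.arange(arr_low.size))
        if pos is None or len(pos) == 0:
            continue
        pos = np.asarray(pos)
        x1 = arr_low[pos].astype(np.int64)
        x2 = arr_high[pos].astype(np.int64)
        nz = (x1 + x2) > 0
        n_dropped += int((~nz).sum())
        pos, x1, x2 = pos[nz], x1[nz], x2[nz]
        if pos.size == 0:
            continue
        with np.errstate(divide="ignore"):
            fc = (x2 / high.total_reads) / np.where(x1 > 0, x1, np.nan) * low.total_reads
        pv = _binom_two_sided(x2, x1 + x2, p0)
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "count_low": x1, "count_high": x2,
            "fold_change": fc, "p_value": pv,
        }))
    if not rows:
        df = pd.DataFrame(columns=["chrom", "pos", "count_low", "count_high",
                                   "fold_change", "p_value", "adjusted_p"])
        df.attrs["n_dropped"] = n_dropped
        return df
    df = pd.concat(rows, ignore_index=True)
    df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df.attrs["n_dropped"] = n_dropped
    return df


def window_runs(
    candidates: Mapping[str, CandidateBlock],
    flank: int = 12,
    min_windows: int = 5,
    direction: int = DOWN,
    restrict_to: Sequence[GenomicInterval] | None = None,
) -> list[WindowRun]:
    """Chain candidate windows into runs and keep the long ones.

    Every candidate position p spawns the window [p-flank, p+flank+1); windows
    that overlap or abut chain into one run whose interval is their union and
    whose size is the number of member windows.  Runs shorter than
    ``min_windows`` are discarded.  ``restrict_to`` optionally intersects the
    candidate positions with a region set (e.g. previously called
    fetal-specific regions) before chaining.
    """
    width = 2 * flank + 1
    restrict: dict[str, list[GenomicInterval]] = {}
    if restrict_to is not None:
        for iv in restrict_to:
            restrict.setdefault(iv.chrom, []).append(iv)
    runs: list[WindowRun] = []
    for chrom in sorted(candidates):
        block = candidates[chrom]
        pos = block.pos[block.direction == direction]
        if restrict_to is not None:
            keep = np.zeros(pos.size, dtype=bool)
            for iv in restrict.get(chrom, ()):
                keep |= (pos >= iv.start) & (pos < iv.end)
            pos = pos[keep]
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > width) + 1
        for seg in np.split(pos, breaks):
            if seg.size < min_windows:
                continue
            start = max(int(seg[0]) - flank, 0)
            end = int(seg[-1]) + flank + 1
            runs.append(WindowRun(GenomicInterval(chrom, start, end),
                                  int(seg.size), direction))
    return runs


def map_downstream_genes(
    runs: Sequence[WindowRun],
    annotation: Sequence[GeneAnnotation],
    max_distance: int = 10_000,
) -> list[str]:
    """Genes whose TSS lies downstream of a run on the gene's own strand.

    A gene is collected when a run overlaps its TSS-upstream window of
    ``max_distance`` bp ([tss-d, tss) on +, (tss, tss+d] on -).  The
    de-duplicated gene-id list is returned in annotation order.
    """
    collected: list[str] = []
    seen = set()
    for g in annotation:
        tss = g.tss_pos
        if g.strand == "+":
            win_start, win_end = max(tss - max_distance, 0), tss
        else:
            win_start, win_end = tss + 1, tss + 1 + max_distance
        if win_start >= win_end:
            continue
        for run in runs:
            iv = run.interval
            if iv.chrom == g.body.chrom and iv.start < win_end and win_start < iv.end:
                if g.gene_id not in seen:
                    seen.add(g.gene_id)
                    collected.append(g.gene_id)
                break
    return collected


def enrich(
    genes: Sequence[str],
    annotation_sets: Mapping[str, Sequence[str] | set],
    background_size: int,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Hypergeometric upper-tail enrichment of a gene list against term sets.

    ``N`` (the Overlap% denominator) counts input genes mapped to at least one
    term, mirroring how list sizes behave in annotation-portal outputs; terms
    with an empty background set are skipped.  Rows come back sorted by
    p-value with Benjamini-Hochberg adjusted values attached.
    """
    gene_set = set(genes)
    mapped = set()
    sets = {t: set(g) for t, g in annotation_sets.items() if len(g) > 0}
    for members in sets.values():
        mapped |= gene_set & members
    N = len(mapped)
    rows = []
    for term, members in sets.items():
        k = len(gene_set & members)
        K = len(members)
        if N == 0 or k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, background_size, K, N))
        rows.append(EnrichmentRow(
            term_id=term,
            term_name=(term_names or {}).get(term, term),
            gene_count=k, list_size=N, background_count=K,
            background_size=background_size,
            overlap_pct=overlap_pct(k, N), p_value=p, adjusted_p=np.nan,
        ))
    rows.sort(key=lambda r: r.p_value)
    if rows:
        padj = multipletests([r.p_value for r in rows], method="fdr_bh")[1]
        for r, ap in zip(rows, padj):
            r.adjusted_p = float(ap)
    return rows


def overlap_pct(k: int, N: int) -> float:
    """The Overlap%% statistic: ``100 * k / N``, exactly."""
    if N <= 0:
        raise ValueError("list size N must be positive")
    return 100.0 * k / N


def infer_list_size(k: int, pct: float) -> int:
    """Invert ``overlap_pct``: recover the list-size denominator N from one
    printed (gene count, Overlap%%) pair."""
    if pct <= 0:
        raise ValueError("percentage must be positive")
    return int(round(100.0 * k / pct))
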