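"""Fetal-specific region discovery from fetal-fraction-stratified coverage.

Samples are sorted by fetal fraction and merged into equal-size strata; per
base, the normalised depth of the merged libraries is regressed on the group
mean fetal fraction.  A base is fetal-specific when it sits on the fitted
line within a relative-error tolerance (1.5% at clinical depth), its depth
rises with fetal fraction, and its raw merged depth never drops below a
minimum read support.  Qualifying bases are merged into maximal runs; the 50
bp upstream flanks of the called regions are summarised as a position weight
matrix whose consensus, on data with feto-placental loci, shows a CGGAA
tandem repeat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .genomic_io import (
    READ_LENGTH,
    ChromSizes,
    DepthTrack,
    GenomicInterval,
    SampleMeta,
    depth_from_starts,
)
from .synthetic_cohort import FragmentSet, ReferenceTable

__all__ = [
    "GroupLibrary",
    "PositionFit",
    "PositionFits",
    "FetalRegionSet",
    "PWM",
    "merge_groups",
    "fit_position",
    "fit_groups",
    "call_fetal_regions",
    "build_flank_pwm",
    "detect_tandem_repeat",
]

_BASE_ORDER = "ACGT"


@dataclass
class GroupLibrary:
    """A merged cohort stratum: pooled depth of all member samples."""

    group_label: str
    mean_ff: float
    n_samples: int
    track: DepthTrack          # raw (unnormalised) merged depth
    total_reads: int

    def __post_init__(self):
        if not (0.0 < self.mean_ff < 1.0):
            raise ValueError(f"group mean_ff={self.mean_ff} outside (0, 1)")


@dataclass
class PositionFit:
    """Per-base regression diagnostics of normalised depth on group ff."""

    chrom: str
    pos: int
    slope: float
    intercept: float
    rel_error: float
    evaluable: bool
    min_raw: float
    depths: np.ndarray | None = None


@dataclass
class PositionFits:
    """Vectorised :class:`PositionFit` over a contiguous chromosome span."""

    chrom: str
    start: int
    slope: np.ndarray
    intercept: np.ndarray
    rel_error: np.ndarray
    evaluable: np.ndarray
    min_raw: np.ndarray
    mode: Literal["coverage", "read_start"] = "coverage"
    read_length: int = READ_LENGTH

    def __len__(self) -> int:
        return self.slope.size

    def __getitem__(self, i: int) -> PositionFit:
        return PositionFit(self.chrom, self.start + i, float(self.slope[i]),
                           float(self.intercept[i]), float(self.rel_error[i]),
                           bool(self.evaluable[i]), float(self.min_raw[i]))


@dataclass
class FetalRegionSet:
    """Called fetal-specific intervals with per-region minimum raw depth."""

    regions: list[GenomicInterval]
    min_depth: list[float]
    source: Literal["chrY-anchor", "genome-wide"] = "genome-wide"

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class PWM:
    """Position weight matrix: rows A, C, G, T; columns normalised to 1."""

    matrix: np.ndarray  # shape (4, W)
    n_sequences: int

    def __post_init__(self):
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM needs 4 rows (A, C, G, T)")
        sums = self.matrix.sum(axis=0)
        if self.n_sequences > 0 and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.matrix.argmax(axis=0))


def _stratification_ff(meta: SampleMeta) -> float:
    if meta.ff_chrY is not None:
        return meta.ff_chrY
    if meta.true_ff is not None:
        return meta.true_ff
    raise ValueError(f"sample {meta.sample_id}: no fetal fraction for stratification")


def merge_groups(
    samples: Sequence[tuple[FragmentSet, SampleMeta]],
    chrom_sizes: ChromSizes,
    n_groups: int,
    mode: Literal["coverage", "read_start"] = "coverage",
) -> list[GroupLibrary]:
    """Sort samples by fetal fraction, split into ``n_groups`` equal-size
    strata, and pool each stratum's depth into one merged library."""
    if n_groups > len(samples):
        raise ValueError(f"n_groups={n_groups} exceeds n_samples={len(samples)}")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    ffs = np.array([_stratification_ff(m) for _, m in samples])
    order = np.argsort(ffs, kind="stable")
    groups = []
    for gi, idx in enumerate(np.array_split(order, n_groups)):
        members = [samples[i] for i in idx]
        starts = {
            c: np.sort(np.concatenate([f.starts.get(c, np.empty(0, dtype=np.int64))
                                       for f, _ in members]))
            for c in chrom_sizes
        }
        total = int(sum(m.total_reads for _, m in members))
        read_length = members[0][0].read_length
        track = depth_from_starts(starts, chrom_sizes, read_length, mode, total_reads=total)
        groups.append(GroupLibrary(
            group_label=f"G{gi + 1:02d}",
            mean_ff=float(ffs[idx].mean()),
            n_samples=len(members),
            track=track,
            total_reads=total,
        ))
    return groups


def fit_position(
    depths: Sequence[float],
    ffs: Sequence[float],
    chrom: str = "chr?",
    pos: int = 0,
    error_mode: Literal["max", "mean"] = "max",
    raw_depths: Sequence[float] | None = None,
) -> PositionFit:
    """Ordinary least squares of per-group depth on group mean fetal fraction.

    ``rel_error`` aggregates ``|observed - fitted| / fitted`` over groups
    (maximum by default, mean as the alternative functional); the fit is
    flagged non-evaluable when any fitted value is <= 0 or all depths vanish.
    """
    y = np.asarray(depths, dtype=float)
    x = np.asarray(ffs, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need >= 3 groups with matching depth values")
    if np.any(np.diff(x) <= 0):
        raise ValueError("group fetal fractions must be strictly increasing")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    raw = np.asarray(raw_depths, dtype=float) if raw_depths is not None else y
    if np.all(y == 0) or np.any(fitted <= 0):
        return PositionFit(chrom, pos, slope, intercept, np.inf, False,
                           float(raw.min()), y)
    rel = np.abs(y - fitted) / fitted
    rel_error = float(rel.max() if error_mode == "max" else rel.mean())
    return PositionFit(chrom, pos, slope, intercept, rel_error, True,
                       float(raw.min()), y)


def fit_groups(
    groups: Sequence[GroupLibrary],
    chroms: Iterable[str] | None = None,
    error_mode: Literal["max", "mean"] = "max",
    scale: float = 1e6,
    chunk: int = 250_000,
) -> dict[str, PositionFits]:
    """Vectorised per-base regression over every position of the requested
    chromosomes (all chromosomes of the merged tracks by default)."""
    if len(groups) < 3:
        raise ValueError("need >= 3 groups")
    ffs = np.array([g.mean_ff for g in groups])
    if np.any(np.diff(ffs) <= 0):
        raise ValueError("group mean fetal fractions must be strictly increasing")
    factors = np.array([scale / g.total_reads for g in groups])
    xc = ffs - ffs.mean()
    sxx = float(xc @ xc)
    mode = groups[0].track.mode
    read_length = READ_LENGTH
    chrom_list = list(chroms) if chroms is not None else list(groups[0].track.data)
    out: dict[str, PositionFits] = {}
    for chrom in chrom_list:
        n = groups[0].track.data[chrom].size
        slope = np.empty(n)
        intercept = np.empty(n)
        rel_error = np.empty(n)
        evaluable = np.empty(n, dtype=bool)
        min_raw = np.empty(n)
        for a in range(0, n, chunk):
            b = min(a + chunk, n)
            raw = np.stack([g.track.data[chrom][a:b] for g in groups]).astype(np.float64)
            norm = raw * factors[:, None]
            ybar = norm.mean(axis=0)
            sl = (xc @ norm) / sxx
            ic = ybar - sl * ffs.mean()
            fitted = ic[None, :] + sl[None, :] * ffs[:, None]
            ok = np.all(fitted > 0, axis=0) & np.any(raw > 0, axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.abs(norm - fitted) / fitted
            err = rel.max(axis=0) if error_mode == "max" else rel.mean(axis=0)
            err[~ok] = np.inf
            slope[a:b] = sl
            intercept[a:b] = ic
            rel_error[a:b] = err
            evaluable[a:b] = ok
            min_raw[a:b] = raw.min(axis=0)
        out[chrom] = PositionFits(chrom, 0, slope, intercept, rel_error,
                                  evaluable, min_raw, mode, read_length)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def call_fetal_regions(
    fits: Mapping[str, PositionFits] | Sequence[PositionFit],
    max_rel_error: float = 0.015,
    min_reads: float = 2.0,
    require_positive_slope: bool = True,
    source: Literal["chrY-anchor", "genome-wide"] = "genome-wide",
) -> FetalRegionSet:
    """Merge maximal runs of qualifying positions into fetal-specific regions.

    Qualifying: evaluable fit, ``rel_error < max_rel_error``, raw merged depth
    >= ``min_reads`` in every group, and (by default) a positive slope.  For
    coverage-mode depth each run's right edge is trimmed by ``read_length - 1``
    bases, inverting the coverage footprint of fixed-width reads so that
    called boundaries line up with read-start space.
    """
    if isinstance(fits, Mapping):
        per_chrom = list(fits.values())
    else:
        per_chrom = _pack_positionfits(list(fits))
    regions: list[GenomicInterval] = []
    min_depth: list[float] = []
    for pf in per_chrom:
        q = pf.evaluable & (pf.rel_error < max_rel_error) & (pf.min_raw >= min_reads)
        if require_positive_slope:
            q &= pf.slope > 0
        trim = pf.read_length - 1 if pf.mode == "coverage" else 0
        for s, e in _runs(q):
            e_trim = e - trim
            if e_trim <= s:
                continue
            regions.append(GenomicInterval(pf.chrom, pf.start + s, pf.start + e_trim))
            min_depth.append(float(pf.min_raw[s:e].min()))
    return FetalRegionSet(regions, min_depth, source)


def _pack_positionfits(fits: list[PositionFit]) -> list[PositionFits]:
    """Group a position-sorted stream of scalar fits into contiguous spans.

    Scalar fits carry no depth-mode information, so no coverage-footprint trim
    is applied (``mode='read_start'``)."""
    spans: list[PositionFits] = []
    i = 0
    while i < len(fits):
        j = i + 1
        while (j < len(fits) and fits[j].chrom == fits[i].chrom
               and fits[j].pos == fits[j - 1].pos + 1):
            j += 1
        block = fits[i:j]
        spans.append(PositionFits(
            block[0].chrom, block[0].pos,
            np.array([f.slope for f in block]),
            np.array([f.intercept for f in block]),
            np.array([f.rel_error for f in block]),
            np.array([f.evaluable for f in block]),
            np.array([f.min_raw for f in block]),
            mode="read_start",
        ))
        i = j
    return spans


def build_flank_pwm(
    regions: FetalRegionSet | Sequence[GenomicInterval],
    reference: ReferenceTable,
    flank: int = 50,
    side: Literal["upstream", "downstream"] = "upstream",
) -> PWM:
    """Base-frequency matrix over the ``flank`` bp flanks of the regions.

    Regions whose flank sequence is unavailable (outside the reference table
    or beyond chromosome bounds) are skipped with a warning."""
    ivs = regions.regions if isinstance(regions, FetalRegionSet) else list(regions)
    counts = np.zeros((4, flank))
    n_used = 0
    index = {b: i for i, b in enumerate(_BASE_ORDER)}
    for iv in ivs:
        if side == "upstream":
            a, b = iv.start - flank, iv.start
        else:
            a, b = iv.end, iv.end + flank
        seq = reference.get_seq(iv.chrom, a, b) if a >= 0 else None
        if seq is None or len(seq) != flank:
            warnings.warn(f"no reference sequence for flank of {iv.chrom}:{iv.start}-{iv.end};"
                          " region skipped")
            continue
        for col, base in enumerate(seq.upper()):
            if base in index:
                counts[index[base], col] += 1
        n_used += 1
    if n_used == 0:
        return PWM(np.zeros((4, flank)), 0)
    return PWM(counts / counts.sum(axis=0, keepdims=True), n_used)


def detect_tandem_repeat(consensus: str, unit_min: int = 3,
                         min_copies: int = 2) -> list[tuple[str, int, int]]:
    """Maximal exact tandem repeats ``(unit, copies, offset)`` in a string.

    A repeat is reported at its leftmost offset with its maximal number of
    complete copies; units shorter than ``unit_min`` are ignored.
    """
    if not consensus:
        raise ValueError("consensus must be non-empty")
    s = consensus
    n = len(s)
    found = []
    for u in range(unit_min, n // min_copies + 1):
        for i in range(0, n - u * min_copies + 1):
            unit = s[i:i + u]
            if i >= u and s[i - u:i] == unit:
                continue  # not leftmost
            copies = 1
            while s[i + copies * u:i + (copies + 1) * u] == unit:
                copies += 1
            if copies >= min_copies:
                found.append((unit, copies, i))
    return found
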