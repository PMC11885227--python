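"""Domain types and readers/writers for interval, depth, metadata and annotation data.

Every other stage of the pipeline consumes these containers.  Coordinates are
0-based half-open (BED convention) everywhere internally.

File dialects
-------------
* fragments / regions : BED3+ (tab-separated; extra columns preserved on read
  of regions, ignored for fragments)
* depth tracks        : bedGraph (run-length encoded)
* sample metadata     : TSV with header
  ``sample_id  total_reads  fetal_sex  ff_chrY  group_label  condition[  true_ff]``
* chromosome sizes    : two-column TSV ``chrom  length``
* gene annotation     : BED6 ``chrom  start  end  gene_id|gene_name  score  strand``
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "SampleMeta",
    "DepthTrack",
    "GeneAnnotation",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_fragments",
    "write_fragments",
    "read_fragments_sam",
    "accumulate_depth",
    "normalize_track",
    "read_regions",
    "write_regions",
    "read_track",
    "write_track",
    "read_sample_table",
    "write_sample_table",
    "read_annotation",
    "write_annotation",
]

READ_LENGTH = 40  #: default single-end read length (bp) assumed throughout

Strand = Literal["+", "-", "."]


class BedParseError(ValueError):
    """Raised for a malformed interval line; carries the offending line number."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        loc = f"{path}:{line_number}: " if line_number is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class ChromSizes(Mapping[str, int]):
    """Chromosome name -> length (bp).  Preserves insertion order."""

    def __init__(self, sizes: Mapping[str, int]):
        self._sizes = dict(sizes)
        for name, length in self._sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def total(self) -> int:
        return sum(self._sizes.values())

    def validate(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )


@dataclass
class SampleMeta:
    """Per-sample metadata.

    ``ff_chrY`` is the conventional chromosome-Y-dosage fetal fraction (missing
    for female fetuses); ``true_ff`` exists only for synthetic samples, where
    the generating fetal fraction is known.
    """

    sample_id: str
    total_reads: int
    fetal_sex: Literal["male", "female"]
    ff_chrY: float | None = None
    group_label: str = ""
    condition: Literal["control", "case", "unknown"] = "unknown"
    true_ff: float | None = None

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.fetal_sex not in ("male", "female"):
            raise ValueError(f"invalid fetal_sex {self.fetal_sex!r}")
        if self.condition not in ("control", "case", "unknown"):
            raise ValueError(f"invalid condition {self.condition!r}")
        for name in ("ff_chrY", "true_ff"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class DepthTrack:
    """Per-base counts per chromosome with a total-read normalising denominator.

    ``mode`` records whether a base counts covering reads (``coverage``) or
    read starts (``read_start``).  Raw tracks hold counts; normalised tracks
    hold ``raw / total_reads * scale`` with the scale recorded.
    """

    data: dict[str, np.ndarray]
    total_reads: int
    mode: Literal["coverage", "read_start"] = "coverage"
    normalized: bool = False
    scale: float | None = None

    def __post_init__(self):
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")

    def chrom_sum(self, chrom: str) -> float:
        return float(self.data[chrom].sum())

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))

    def copy(self) -> "DepthTrack":
        return DepthTrack(
            {c: a.copy() for c, a in self.data.items()},
            self.total_reads,
            self.mode,
            self.normalized,
            self.scale,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its transcription start site (TSS) and body.

    The TSS is a width-1 interval coinciding with the body start on the + strand
    and with ``body.end - 1`` on the - strand.
    """

    gene_id: str
    gene_name: str
    body: GenomicInterval
    strand: Literal["+", "-"]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> GenomicInterval:
        pos = self.body.start if self.strand == "+" else self.body.end - 1
        return GenomicInterval(self.body.chrom, pos, pos + 1, self.strand)

    @property
    def tss_pos(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return ChromSizes(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_chrom_sizes(sizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# fragments / regions (BED)


def _parse_bed(path, chrom_sizes: ChromSizes | None, min_fields: int = 3):
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedParseError(
                    f"expected >= {min_fields} tab-separated fields, got {len(fields)}",
                    path,
                    lineno,
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinate: {exc}", path, lineno) from None
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand)
                if chrom_sizes is not None:
                    chrom_sizes.validate(iv)
            except ValueError as exc:
                raise BedParseError(str(exc), path, lineno) from None
            intervals.append(iv)
    return intervals


def read_fragments(path, chrom_sizes: ChromSizes) -> list[GenomicInterval]:
    """Read aligned-fragment intervals from a BED3+ file, validated against
    ``chrom_sizes``.  Input order is preserved."""
    return _parse_bed(path, chrom_sizes, min_fields=3)


def write_fragments(fragments: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in fragments:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_regions(path, chrom_sizes: ChromSizes | None = None) -> list[GenomicInterval]:
    """Read a region set (BED3+, strand honoured when a valid 6th field exists)."""
    return _parse_bed(path, chrom_sizes, min_fields=3)


def write_regions(regions: Iterable[GenomicInterval], path, names: Sequence[str] | None = None,
                  scores: Sequence[float] | None = None) -> None:
    """Write regions as BED; BED6 when names/scores given, else BED3.

    An empty region set produces a file holding only a header comment."""
    regions = list(regions)
    with open(path, "w") as fh:
        fh.write("# cfnipt regions (0-based half-open)\n")
        for i, iv in enumerate(regions):
            if names is not None or scores is not None:
                name = names[i] if names is not None else "."
                score = scores[i] if scores is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fragments_sam(path, chrom_sizes: ChromSizes) -> list[GenomicInterval]:
    """Optional SAM/BAM adapter: aligned records with mapping quality > 0 and
    no duplicate flag become fragment intervals.  Requires :mod:`pysam`."""
    import pysam  # local import: optional dependency

    intervals = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_duplicate or rec.mapping_quality <= 0:
                continue
            iv = GenomicInterval(rec.reference_name, rec.reference_start, rec.reference_end)
            chrom_sizes.validate(iv)
            intervals.append(iv)
    return intervals


# ---------------------------------------------------------------------------
# depth


def accumulate_depth(
    fragments: Sequence[GenomicInterval],
    chrom_sizes: ChromSizes,
    mode: Literal["coverage", "read_start"] = "coverage",
) -> DepthTrack:
    """Accumulate per-base depth from fragment intervals.

    In ``coverage`` mode each fragment increments every base it covers, so the
    track total equals the summed fragment length; in ``read_start`` mode only
    the 5' start base is incremented and the total equals the fragment count.
    An empty fragment list yields an all-zero track (total_reads set to 1 so
    the track remains normalisable).
    """
    if mode not in ("coverage", "read_start"):
        raise ValueError(f"unknown depth mode {mode!r}")
    data = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    starts: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    ends: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for iv in fragments:
        chrom_sizes.validate(iv)
        starts[iv.chrom].append(iv.start)
        ends[iv.chrom].append(iv.end)
    for chrom, n in chrom_sizes.items():
        s = np.asarray(starts[chrom], dtype=np.int64)
        if s.size == 0:
            continue
        if mode == "read_start":
            data[chrom] = np.bincount(s, minlength=n).astype(np.int64)
        else:
            e = np.asarray(ends[chrom], dtype=np.int64)
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, s, 1)
            np.add.at(diff, e, -1)
            data[chrom] = np.cumsum(diff[:-1])
    return DepthTrack(data, total_reads=max(len(fragments), 1), mode=mode)


def depth_from_starts(
    starts_by_chrom: Mapping[str, np.ndarray],
    chrom_sizes: ChromSizes,
    read_length: int = READ_LENGTH,
    mode: Literal["coverage", "read_start"] = "coverage",
    total_reads: int | None = None,
) -> DepthTrack:
    """Fast path from per-chromosome read-start position arrays (fixed-width
    reads) to a :class:`DepthTrack`; used by the synthetic generator and the
    group-merging stage."""
    data = {}
    n_frag = 0
    for chrom, n in chrom_sizes.items():
        s = np.asarray(starts_by_chrom.get(chrom, ()), dtype=np.int64)
        n_frag += s.size
        if s.size == 0:
            data[chrom] = np.zeros(n, dtype=np.int32)
            continue
        counts = np.bincount(s, minlength=n).astype(np.int32)
        if mode == "read_start":
            data[chrom] = counts
        else:
            diff = np.zeros(n + 1, dtype=np.int32)
            diff[: n] += counts
            ends = np.minimum(s + read_length, n)
            np.subtract.at(diff, ends, 1)
            data[chrom] = np.cumsum(diff[:-1], dtype=np.int32)
    return DepthTrack(data, total_reads=total_reads or max(n_frag, 1), mode=mode)


def normalize_track(track: DepthTrack, scale: float = 1e6) -> DepthTrack:
    """Return a copy normalised by total read count: ``value / total_reads * scale``."""
    if track.normalized:
        raise ValueError("track is already normalized")
    if track.total_reads <= 0:
        raise ValueError("total_reads must be positive to normalize")
    if scale <= 0:
        raise ValueError("scale must be positive")
    factor = scale / track.total_reads
    data = {c: a.astype(np.float64) * factor for c, a in track.data.items()}
    return DepthTrack(data, track.total_reads, track.mode, normalized=True, scale=scale)


# ---------------------------------------------------------------------------
# bedGraph tracks


def write_track(track: DepthTrack, path) -> None:
    """Write a depth track as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        fh.write(f"# cfnipt bedGraph total_reads={track.total_reads} "
                 f"mode={track.mode} normalized={int(track.normalized)} "
                 f"scale={track.scale if track.scale is not None else 'NA'}\n")
        for chrom, arr in track.data.items():
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_track(path, chrom_sizes: ChromSizes) -> DepthTrack:
    total_reads, mode, normalized, scale = 1, "coverage", False, None
    data = {c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line.lstrip("# ").split():
                    if tok.startswith("total_reads="):
                        total_reads = int(tok.split("=", 1)[1])
                    elif tok.startswith("mode="):
                        mode = tok.split("=", 1)[1]
                    elif tok.startswith("normalized="):
                        normalized = bool(int(tok.split("=", 1)[1]))
                    elif tok.startswith("scale=") and tok.split("=", 1)[1] != "NA":
                        scale = float(tok.split("=", 1)[1])
                continue
            if not line or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError("bedGraph needs 4 fields", path, lineno)
            chrom, s, e, v = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if chrom not in data:
                raise BedParseError(f"unknown chromosome {chrom!r}", path, lineno)
            if e > chrom_sizes[chrom]:
                raise BedParseError("interval beyond chromosome end", path, lineno)
            data[chrom][s:e] = v
    if not normalized:
        data = {c: a.astype(np.int64) for c, a in data.items()}
    return DepthTrack(data, total_reads, mode, normalized, scale)


# ---------------------------------------------------------------------------
# sample metadata

_META_COLUMNS = ["sample_id", "total_reads", "fetal_sex", "ff_chrY",
                 "group_label", "condition", "true_ff"]


def write_sample_table(samples: Iterable[SampleMeta], path) -> None:
    rows = []
    for m in samples:
        rows.append({
            "sample_id": m.sample_id,
            "total_reads": m.total_reads,
            "fetal_sex": m.fetal_sex,
            "ff_chrY": "" if m.ff_chrY is None else f"{m.ff_chrY:.6f}",
            "group_label": m.group_label,
            "condition": m.condition,
            "true_ff": "" if m.true_ff is None else f"{m.true_ff:.6f}",
        })
    df = pd.DataFrame(rows, columns=_META_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group_label": str})
    samples = []
    for _, row in df.iterrows():
        def _opt(col):
            if col not in row or pd.isna(row[col]) or row[col] == "":
                return None
            return float(row[col])
        samples.append(SampleMeta(
            sample_id=str(row["sample_id"]),
            total_reads=int(row["total_reads"]),
            fetal_sex=str(row["fetal_sex"]),
            ff_chrY=_opt("ff_chrY"),
            group_label="" if pd.isna(row.get("group_label")) else str(row["group_label"]),
            condition=str(row.get("condition", "unknown")),
            true_ff=_opt("true_ff"),
        ))
    return samples


# ---------------------------------------------------------------------------
# gene annotation (BED6)


def write_annotation(genes: Iterable[GeneAnnotation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.body.chrom}\t{g.body.start}\t{g.body.end}\t"
                     f"{g.gene_id}|{g.gene_name}\t0\t{g.strand}\n")


def read_annotation(path, chrom_sizes: ChromSizes | None = None) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError("gene annotation needs BED6", path, lineno)
            try:
                body = GenomicInterval(fields[0], int(fields[1]), int(fields[2]), fields[5])
                if chrom_sizes is not None:
                    chrom_sizes.validate(body)
            except ValueError as exc:
                raise BedParseError(str(exc), path, lineno) from None
            gene_id, _, gene_name = fields[3].partition("|")
            genes.append(GeneAnnotation(gene_id, gene_name or gene_id, body, fields[5]))
    return genes
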