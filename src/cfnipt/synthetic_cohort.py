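"""Synthetic NIPT-like cfDNA cohort generator.

The clinical data the downstream analyses were designed for is access
restricted, so this module generates cohorts with the same statistical
structure: maternal background coverage mixed with a fetal component in
proportion to the fetal fraction; chrY mass present only for male fetuses;
autosomal fetal-specific loci whose coverage scales with fetal fraction and
whose upstream flanks carry a CGGAA-repeat motif; nucleosome-depleted-region
(NDR) coverage dips at the TSS of "fetal-expressed" genes that deepen
linearly with fetal fraction; trisomy / confined-placental-mosaicism dosage
shifts; and case-specific coverage perturbations at a panel of loci.

Reads are single-end, fixed width (40 bp by default).  Read-start positions
are drawn from the mixture ``(1-ff)*maternal + ff*fetal`` of two piecewise
constant per-base weight profiles; all randomness flows from one explicit
:class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import yaml

from .genomic_io import (
    READ_LENGTH,
    ChromSizes,
    DepthTrack,
    GeneAnnotation,
    GenomicInterval,
    SampleMeta,
    depth_from_starts,
    read_chrom_sizes,
    read_fragments,
    read_sample_table,
    write_annotation,
    write_chrom_sizes,
    write_fragments,
    write_sample_table,
)

__all__ = [
    "Karyotype",
    "EUPLOID",
    "FragmentSet",
    "ReferenceTable",
    "GenomeModel",
    "CohortSpec",
    "default_genome",
    "simulate_sample",
    "simulate_cohort",
    "expected_depth",
    "write_cohort",
    "load_cohort",
]

_BASES = np.array(list("ACGT"))

#: consensus planted in the 50 bp upstream flank of every fetal-specific
#: region, spanning flank offsets 6..19 (so "CGGAA" x2 starts at offset 8)
FLANK_MOTIF = "AGCGGAACGGAACG"
FLANK_MOTIF_OFFSET = 6


@dataclass(frozen=True)
class Karyotype:
    """``trisomy_chrom=None`` means euploid.  ``mosaic_fraction`` m is the
    fraction of aneuploid placental cells: m=1 full trisomy, 0<m<1 confined
    placental mosaicism.  The fetal sampling weight on the trisomic
    chromosome is multiplied by ``1 + m/2``."""

    trisomy_chrom: str | None = None
    mosaic_fraction: float = 0.0

    def __post_init__(self):
        if self.trisomy_chrom is not None and not (0.0 < self.mosaic_fraction <= 1.0):
            raise ValueError("mosaic_fraction must be in (0, 1] for a trisomy")


EUPLOID = Karyotype()


@dataclass
class FragmentSet:
    """Fixed-width fragments stored as sorted per-chromosome read-start arrays."""

    starts: dict[str, np.ndarray]
    read_length: int = READ_LENGTH

    @property
    def n_fragments(self) -> int:
        return int(sum(s.size for s in self.starts.values()))

    def chrom_count(self, chrom: str) -> int:
        return int(self.starts.get(chrom, np.empty(0)).size)

    def count_in(self, iv: GenomicInterval) -> int:
        """Number of fragments whose start lies inside ``iv``."""
        s = self.starts.get(iv.chrom)
        if s is None:
            return 0
        return int(np.searchsorted(s, iv.end) - np.searchsorted(s, iv.start))

    def to_intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in self.starts:
            for s in self.starts[chrom]:
                out.append(GenomicInterval(chrom, int(s), int(s) + self.read_length))
        return out

    def to_track(self, chrom_sizes: ChromSizes,
                 mode: Literal["coverage", "read_start"] = "coverage") -> DepthTrack:
        return depth_from_starts(self.starts, chrom_sizes, self.read_length, mode,
                                 total_reads=self.n_fragments)


class ReferenceTable:
    """Sparse reference sequence: blocks of sequence stored only where the
    genome model needs them (fetal-specific region flanks)."""

    def __init__(self):
        self._blocks: dict[str, list[tuple[int, str]]] = {}

    def add_block(self, chrom: str, start: int, seq: str) -> None:
        self._blocks.setdefault(chrom, []).append((start, seq))

    def get_seq(self, chrom: str, start: int, end: int) -> str | None:
        """Return the sequence of ``[start, end)`` if fully contained in one
        stored block, else ``None``."""
        for bstart, seq in self._blocks.get(chrom, ()):
            if bstart <= start and end <= bstart + len(seq):
                return seq[start - bstart:end - bstart]
        return None


@dataclass
class GenomeModel:
    """Toy genome: piecewise-constant maternal and fetal sampling profiles.

    Segment arrays describe, per genomic segment, the per-base sampling weight
    of the maternal and (male) fetal cfDNA components; each profile's total
    mass is 1.  ``seg_kind`` tags segments: ``bg`` (plain background),
    ``fetal_region`` (fetal-only locus), ``ndr`` (TSS-proximal dip),
    ``panel_up`` / ``panel_down`` (case-perturbed loci), ``chrY_bg``.
    """

    chrom_sizes: ChromSizes
    seg_chrom: np.ndarray
    seg_start: np.ndarray
    seg_end: np.ndarray
    seg_kind: np.ndarray
    maternal_rate: np.ndarray  # per-bp weight, sums(·len) to 1
    fetal_rate: np.ndarray     # per-bp weight for a male fetus, sums(·len) to 1
    planted_fetal_regions: list[GenomicInterval]
    genes: list[GeneAnnotation]
    fetal_expressed_genes: list[str]           # gene_ids carrying an NDR dip
    ndr_windows: list[GenomicInterval]
    panel_up: list[GenomicInterval]
    panel_down: list[GenomicInterval]
    panel_effect: float
    ndr_dip: float
    reference: ReferenceTable
    read_length: int = READ_LENGTH

    def __post_init__(self):
        L = self.seg_end - self.seg_start
        for name, rate in (("maternal", self.maternal_rate), ("fetal", self.fetal_rate)):
            if np.any(rate < 0):
                raise ValueError(f"{name} profile has negative weights")
            total = float(rate @ L)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} profile mass {total} != 1")
        regs = sorted(self.planted_fetal_regions)
        for a, b in zip(regs, regs[1:]):
            if a.overlaps(b):
                raise ValueError("planted fetal regions overlap")

    # -- calibration quantities measured from the model's own profiles -------

    def chry_calibration(self) -> tuple[float, float]:
        """(b_female, b_male): chrY read share at ff=0 and extrapolated ff=1."""
        L = (self.seg_end - self.seg_start).astype(float)
        on_y = np.array([c == "chrY" for c in self.seg_chrom])
        b_female = float((self.maternal_rate * L)[on_y].sum())
        b_male = float((self.fetal_rate * L)[on_y].sum())
        return b_female, b_male

    def dosage_background(self, target_chrom: str) -> list[GenomicInterval]:
        """Plain-background autosomal segments excluding the target chromosome:
        the denominator region set for aneuploidy dosage ratios."""
        out = []
        for c, s, e, k in zip(self.seg_chrom, self.seg_start, self.seg_end, self.seg_kind):
            if k == "bg" and c != target_chrom and c != "chrY":
                out.append(GenomicInterval(str(c), int(s), int(e)))
        return out

    def aneufc_calibration(self, target_chrom: str, ff_ref: float = 0.125
                           ) -> tuple[float, float]:
        """Return ``(f_exp, dosage_response)`` for the target chromosome.

        ``f_exp`` is the euploid expected ratio of target-chromosome reads to
        dosage-background reads; ``dosage_response`` is the expected relative
        dosage shift per unit of ``ff * m / 2``, slightly below 1 because part
        of the fetal profile's mass sits on chrY and the fetal-specific loci.
        """
        L = (self.seg_end - self.seg_start).astype(float)
        on_t = np.array([c == target_chrom for c in self.seg_chrom])
        bg = np.array([k == "bg" and c not in (target_chrom, "chrY")
                       for c, k in zip(self.seg_chrom, self.seg_kind)])
        mix = (1 - ff_ref) * self.maternal_rate + ff_ref * self.fetal_rate
        mass_t = float((mix * L)[on_t].sum())
        mass_bg = float((mix * L)[bg].sum())
        f_exp = mass_t / mass_bg
        fet_t = float((self.fetal_rate * L)[on_t].sum())
        # observed/expected dosage ratio is 1 + ff*(m/2)*fetal_mass_t/mixture_mass_t
        dosage_response = fet_t / mass_t
        return f_exp, float(dosage_response)

    # -- per-sample mixture -------------------------------------------------

    def segment_weights(self, ff: float, sex: str, karyotype: Karyotype = EUPLOID,
                        condition: str = "unknown") -> np.ndarray:
        """Per-bp sampling weight of every segment for one sample (unnormalised)."""
        if not (0.0 <= ff <= 1.0):
            raise ValueError(f"ff={ff} outside [0, 1]")
        fetal = self.fetal_rate.copy()
        L = (self.seg_end - self.seg_start).astype(float)
        if sex == "female":
            if karyotype.trisomy_chrom == "chrY":
                raise ValueError("female fetus cannot carry a chrY trisomy")
            on_y = np.array([c == "chrY" for c in self.seg_chrom])
            if ff > 0 and float((fetal * L)[on_y].sum()) > 0:
                fetal[on_y] = 0.0
                fetal /= float(fetal @ L)  # female fetal genome renormalised
        elif sex != "male":
            raise ValueError(f"invalid fetal sex {sex!r}")
        if karyotype.trisomy_chrom is not None:
            if karyotype.trisomy_chrom not in self.chrom_sizes:
                raise ValueError(f"unknown trisomy chromosome {karyotype.trisomy_chrom!r}")
            on_c = np.array([c == karyotype.trisomy_chrom for c in self.seg_chrom])
            fetal[on_c] *= 1.0 + karyotype.mosaic_fraction / 2.0
        w = (1.0 - ff) * self.maternal_rate + ff * fetal
        if condition == "case":
            up = self.seg_kind == "panel_up"
            dn = self.seg_kind == "panel_down"
            w = w.copy()
            w[up] *= 1.0 + self.panel_effect
            w[dn] *= 1.0 - self.panel_effect
        return w


@dataclass
class CohortSpec:
    """Cohort-level study conditions.

    Defaults follow the scaled-down desk conditions: 200,000 reads per sample
    (the clinical assay uses 4.2 million), fetal fraction uniform on
    [0.05, 0.20], all-male pregnancies (the discovery cohorts were restricted
    to karyotypically normal male fetuses)."""

    n_samples: int
    reads_per_sample: int = 200_000
    ff_low: float = 0.05
    ff_high: float = 0.20
    fraction_male: float = 1.0
    trisomy_chrom: str | None = None
    trisomy_fraction: float = 0.0      # fraction of samples carrying the trisomy
    mosaic_fraction: float = 1.0       # m for those samples
    case_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_samples < 0 or self.reads_per_sample <= 0:
            raise ValueError("n_samples must be >= 0 and reads_per_sample > 0")
        for name in ("fraction_male", "trisomy_fraction", "case_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.ff_low <= self.ff_high <= 1.0):
            raise ValueError("require 0 <= ff_low <= ff_high <= 1")


# ---------------------------------------------------------------------------
# default genome


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def default_genome(seed: int = 20_24, ndr_dip: float = 0.8,
                   panel_effect: float = 0.5) -> GenomeModel:
    """The packaged toy genome.

    Five autosome-like chromosomes (4, 2.5, 2, 1.5 and 1 Mb) plus a 0.5 Mb
    chrY.  chr1 carries no planted features and serves as the aneuploidy
    dosage target; its ~0.4 background share gives 2e5-read samples the same
    dosage-counting precision the clinical assay has on chr21 at 4.2e6 reads.
    Eight autosomal fetal-specific loci (150-300 bp, 4% of fetal mass) sit on
    chr2-chr4, two more on chrY; ten fetal-expressed genes carry a 150 bp NDR
    dip upstream of their TSS; twenty panel genes on chr5 carry 500 bp
    case-perturbed windows centred on their TSS.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = ChromSizes({
        "chr1": 4_000_000, "chr2": 2_500_000, "chr3": 2_000_000,
        "chr4": 1_500_000, "chr5": 1_000_000, "chrY": 500_000,
    })
    autosomes = ["chr1", "chr2", "chr3", "chr4", "chr5"]

    fetal_regions = [
        GenomicInterval("chr2", 300_000, 300_200),
        GenomicInterval("chr2", 800_000, 800_150),
        GenomicInterval("chr2", 1_300_000, 1_300_300),
        GenomicInterval("chr2", 1_900_000, 1_900_250),
        GenomicInterval("chr3", 400_000, 400_200),
        GenomicInterval("chr3", 1_200_000, 1_200_300),
        GenomicInterval("chr4", 500_000, 500_150),
        GenomicInterval("chr4", 1_100_000, 1_100_250),
    ]
    chry_regions = [
        GenomicInterval("chrY", 100_000, 100_200),
        GenomicInterval("chrY", 350_000, 350_200),
    ]

    def gene(gid, chrom, tss, strand, name=None):
        body = (GenomicInterval(chrom, tss, tss + 5_000, strand) if strand == "+"
                else GenomicInterval(chrom, tss - 4_999, tss + 1, strand))
        return GeneAnnotation(gid, name or gid, body, strand)

    ndr_tss = [("chr2", 500_000, "+"), ("chr2", 1_000_000, "-"), ("chr2", 1_600_000, "+"),
               ("chr3", 200_000, "+"), ("chr3", 800_000, "-"), ("chr3", 1_500_000, "+"),
               ("chr4", 200_000, "+"), ("chr4", 800_000, "-"),
               ("chr5", 920_000, "+"), ("chr5", 960_000, "+")]
    plain_tss = [("chr1", p, "+" if i % 2 == 0 else "-")
                 for i, p in enumerate(range(500_000, 3_500_001, 500_000))] + \
                [("chr2", 2_200_000, "+"), ("chr3", 1_800_000, "-"), ("chr4", 1_300_000, "+")]

    genes: list[GeneAnnotation] = []
    fetal_expressed: list[str] = []
    ndr_windows: list[GenomicInterval] = []
    for i, (chrom, tss, strand) in enumerate(ndr_tss):
        g = gene(f"NDRG{i + 1}", chrom, tss, strand)
        genes.append(g)
        fetal_expressed.append(g.gene_id)
        if strand == "+":
            ndr_windows.append(GenomicInterval(chrom, tss - 180, tss - 30, strand))
        else:
            ndr_windows.append(GenomicInterval(chrom, tss + 31, tss + 181, strand))
    panel_up, panel_down = [], []
    for i in range(20):
        tss = 100_000 + i * 40_000
        g = gene(f"PANG{i + 1}", "chr5", tss, "+")
        genes.append(g)
        win = GenomicInterval("chr5", tss - 250, tss + 250)
        (panel_up if i < 10 else panel_down).append(win)
    for i, (chrom, tss, strand) in enumerate(plain_tss):
        genes.append(gene(f"BGG{i + 1}", chrom, tss, strand))

    # ---- piecewise-constant profiles
    seg_chrom, seg_start, seg_end, seg_kind = [], [], [], []
    features: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chrom_sizes}
    for iv in fetal_regions:
        features[iv.chrom].append((iv.start, iv.end, "fetal_region"))
    for iv in chry_regions:
        features[iv.chrom].append((iv.start, iv.end, "fetal_region"))
    for iv in ndr_windows:
        features[iv.chrom].append((iv.start, iv.end, "ndr"))
    for iv in panel_up:
        features[iv.chrom].append((iv.start, iv.end, "panel_up"))
    for iv in panel_down:
        features[iv.chrom].append((iv.start, iv.end, "panel_down"))
    for chrom, n in chrom_sizes.items():
        pos = 0
        for s, e, kind in sorted(features[chrom]):
            if s > pos:
                seg_chrom.append(chrom); seg_start.append(pos); seg_end.append(s)
                seg_kind.append("chrY_bg" if chrom == "chrY" else "bg")
            seg_chrom.append(chrom); seg_start.append(s); seg_end.append(e)
            seg_kind.append(kind)
            pos = e
        if pos < n:
            seg_chrom.append(chrom); seg_start.append(pos); seg_end.append(n)
            seg_kind.append("chrY_bg" if chrom == "chrY" else "bg")

    seg_chrom = np.array(seg_chrom, dtype=object)
    seg_start = np.array(seg_start, dtype=np.int64)
    seg_end = np.array(seg_end, dtype=np.int64)
    seg_kind = np.array(seg_kind, dtype=object)
    L = (seg_end - seg_start).astype(float)
    on_y = np.array([c == "chrY" for c in seg_chrom])
    is_fsr = seg_kind == "fetal_region"
    is_ndr = seg_kind == "ndr"

    # maternal: uniform over autosomes, zero on chrY and on fetal-only loci
    maternal = np.zeros(len(seg_chrom))
    m_mask = ~on_y & ~is_fsr
    maternal[m_mask] = 1.0
    maternal /= float(maternal @ L)

    # fetal (male): 4% of mass on autosomal fetal-specific loci, 1% on the two
    # chrY loci, 4% uniform over the chrY background, remainder uniform over
    # autosomes with NDR windows attenuated by the dip depth
    fetal = np.zeros(len(seg_chrom))
    auto_fsr = is_fsr & ~on_y
    chry_fsr = is_fsr & on_y
    fetal[auto_fsr] = 0.04 / float(L[auto_fsr].sum())
    fetal[chry_fsr] = 0.01 / float(L[chry_fsr].sum())
    chry_bg = seg_kind == "chrY_bg"
    fetal[chry_bg] = 0.04 / float(L[chry_bg].sum())
    bg_like = ~on_y & ~is_fsr
    u = 0.91 / float(L[bg_like].sum())
    fetal[bg_like] = u
    fetal[is_ndr] = u * (1.0 - ndr_dip)
    fetal /= float(fetal @ L)

    reference = ReferenceTable()
    for iv in fetal_regions + chry_regions:
        block_start = iv.start - 60
        seq = list(_random_seq(rng, 80))  # covers [start-60, start+20)
        flank_start = 60 - 50              # flank [start-50, start) at offset 10
        off = flank_start + FLANK_MOTIF_OFFSET
        seq[off:off + len(FLANK_MOTIF)] = list(FLANK_MOTIF)
        reference.add_block(iv.chrom, block_start, "".join(seq))

    return GenomeModel(
        chrom_sizes=chrom_sizes,
        seg_chrom=seg_chrom, seg_start=seg_start, seg_end=seg_end, seg_kind=seg_kind,
        maternal_rate=maternal, fetal_rate=fetal,
        planted_fetal_regions=fetal_regions + chry_regions,
        genes=genes, fetal_expressed_genes=fetal_expressed, ndr_windows=ndr_windows,
        panel_up=panel_up, panel_down=panel_down, panel_effect=panel_effect,
        ndr_dip=ndr_dip, reference=reference,
    )


# ---------------------------------------------------------------------------
# simulation


def simulate_sample(
    genome: GenomeModel,
    ff: float,
    sex: Literal["male", "female"] = "male",
    karyotype: Karyotype = EUPLOID,
    condition: Literal["control", "case", "unknown"] = "control",
    n_reads: int = 200_000,
    rng: np.random.Generator | None = None,
    sample_id: str = "S0",
) -> tuple[FragmentSet, SampleMeta]:
    """Draw one sample's read starts from the maternal/fetal mixture profile."""
    rng = np.random.default_rng(0) if rng is None else rng
    w = genome.segment_weights(ff, sex, karyotype, condition)
    if sex == "female":
        on_y = np.array([c == "chrY" for c in genome.seg_chrom])
        if float((w * (genome.seg_end - genome.seg_start))[on_y].sum()) > 0:
            raise AssertionError("internal consistency: chrY mass for a female fetus")
    seg_len = genome.seg_end - genome.seg_start
    mass = w * seg_len
    counts = rng.multinomial(n_reads, mass / mass.sum())
    starts: dict[str, list[np.ndarray]] = {c: [] for c in genome.chrom_sizes}
    L = genome.read_length
    for i in np.flatnonzero(counts):
        chrom = str(genome.seg_chrom[i])
        high = min(int(genome.seg_end[i]), genome.chrom_sizes[chrom] - L + 1)
        low = min(int(genome.seg_start[i]), high - 1) if high > 0 else 0
        starts[chrom].append(rng.integers(low, max(high, low + 1), counts[i]))
    starts_sorted = {
        c: np.sort(np.concatenate(v)) if v else np.empty(0, dtype=np.int64)
        for c, v in starts.items()
    }
    frags = FragmentSet(starts_sorted, read_length=L)
    meta = SampleMeta(sample_id=sample_id, total_reads=n_reads, fetal_sex=sex,
                      condition=condition, true_ff=ff)
    return frags, meta


def simulate_cohort(
    spec: CohortSpec,
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
) -> list[tuple[FragmentSet, SampleMeta]]:
    """Simulate a cohort; deterministic given ``spec.rng_seed``.

    ``ff_chrY`` is filled in for male fetuses with the conventional chrY-dosage
    estimate computed from the sample's own reads."""
    from .ff_model import estimate_ff_chry  # deferred: avoids import cycle at module load

    rng = np.random.default_rng(spec.rng_seed) if rng is None else rng
    b_female, b_male = genome.chry_calibration()
    # plant exact feature counts (round(fraction * n)); which samples carry
    # them stays random
    n = spec.n_samples
    case_idx = set(rng.choice(n, int(round(spec.case_fraction * n)),
                              replace=False)) if n else set()
    tri_idx = set(rng.choice(n, int(round(spec.trisomy_fraction * n)),
                             replace=False)) if n and spec.trisomy_chrom else set()
    cohort = []
    for i in range(spec.n_samples):
        ff = float(rng.uniform(spec.ff_low, spec.ff_high))
        sex = "male" if rng.random() < spec.fraction_male else "female"
        kt = (Karyotype(spec.trisomy_chrom, spec.mosaic_fraction)
              if i in tri_idx else EUPLOID)
        condition = "case" if i in case_idx else "control"
        frags, meta = simulate_sample(genome, ff, sex, kt, condition,
                                      spec.reads_per_sample, rng, sample_id=f"S{i:05d}")
        if sex == "male":
            meta.ff_chrY = estimate_ff_chry(frags, meta, (b_female, b_male))
        cohort.append((frags, meta))
    return cohort


def simulate_merged_depth(
    genome: GenomeModel,
    ff: float,
    n_reads: int,
    rng: np.random.Generator,
    sex: Literal["male", "female"] = "male",
    karyotype: Karyotype = EUPLOID,
    condition: Literal["control", "case", "unknown"] = "control",
    mode: Literal["coverage", "read_start"] = "coverage",
    chunk: int = 20_000_000,
) -> DepthTrack:
    """Depth track of a merged library of iid samples sharing one fetal
    fraction, drawn as a single multinomial of ``n_reads`` read starts
    (distributionally identical to simulating the member samples one by one
    and pooling them, but without materialising per-sample fragment lists).
    """
    w = genome.segment_weights(ff, sex, karyotype, condition)
    seg_len = genome.seg_end - genome.seg_start
    mass = w * seg_len
    counts = rng.multinomial(n_reads, mass / mass.sum())
    L = genome.read_length
    data = {c: np.zeros(n, dtype=np.int32) for c, n in genome.chrom_sizes.items()}
    for i in np.flatnonzero(counts):
        chrom = str(genome.seg_chrom[i])
        n = genome.chrom_sizes[chrom]
        high = min(int(genome.seg_end[i]), n - L + 1)
        low = min(int(genome.seg_start[i]), high - 1) if high > 0 else 0
        remaining = int(counts[i])
        while remaining > 0:
            m = min(remaining, chunk)
            pos = rng.integers(low, max(high, low + 1), m)
            data[chrom] += np.bincount(pos, minlength=n).astype(np.int32)
            remaining -= m
    if mode == "coverage":
        for chrom, arr in data.items():
            cs = np.cumsum(arr, dtype=np.int64)
            cov = cs.copy()
            cov[L:] -= cs[:-L]
            data[chrom] = cov.astype(np.int32)
    return DepthTrack(data, total_reads=n_reads, mode=mode)


def expected_depth(
    genome: GenomeModel,
    ff: float,
    n_reads: float,
    sex: Literal["male", "female"] = "male",
    karyotype: Karyotype = EUPLOID,
    condition: Literal["control", "case", "unknown"] = "control",
    mode: Literal["coverage", "read_start"] = "coverage",
    chroms: Sequence[str] | None = None,
) -> DepthTrack:
    """Noiseless expected depth track (float32-valued) for one mixture setting.

    Expected read-start depth at a base is ``n_reads`` times its sampling
    probability; expected coverage sums the start probabilities of the
    ``read_length`` bases ending at it.  ``chroms`` restricts the output to a
    chromosome subset."""
    w = genome.segment_weights(ff, sex, karyotype, condition)
    seg_len = genome.seg_end - genome.seg_start
    total = float(w @ seg_len)
    data = {}
    L = genome.read_length
    for chrom, n in genome.chrom_sizes.items():
        if chroms is not None and chrom not in chroms:
            continue
        rate = np.zeros(n)
        for i in np.flatnonzero(np.array([c == chrom for c in genome.seg_chrom])):
            rate[genome.seg_start[i]:genome.seg_end[i]] = w[i] / total * n_reads
        rate[n - L + 1:] = 0.0  # starts are confined to [0, n - L]
        if mode == "read_start":
            data[chrom] = rate.astype(np.float32)
        else:
            cs = np.concatenate(([0.0], np.cumsum(rate)))
            b = np.arange(n)
            data[chrom] = (cs[b + 1] - cs[np.maximum(b - L + 1, 0)]).astype(np.float32)
    return DepthTrack(data, total_reads=max(int(n_reads), 1), mode=mode)


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(cohort: Sequence[tuple[FragmentSet, SampleMeta]],
                 genome: GenomeModel, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    write_annotation(genome.genes, out / "genes.bed")
    metas = []
    for frags, meta in cohort:
        write_fragments(frags.to_intervals(), out / f"{meta.sample_id}.bed")
        metas.append(meta)
    write_sample_table(metas, out / "metadata.tsv")


def load_cohort(in_dir, read_length: int = READ_LENGTH
                ) -> tuple[list[tuple[FragmentSet, SampleMeta]], ChromSizes]:
    src = Path(in_dir)
    chrom_sizes = read_chrom_sizes(src / "chrom.sizes")
    metas = read_sample_table(src / "metadata.tsv")
    cohort = []
    for meta in metas:
        ivs = read_fragments(src / f"{meta.sample_id}.bed", chrom_sizes)
        starts: dict[str, list[int]] = {c: [] for c in chrom_sizes}
        for iv in ivs:
            starts[iv.chrom].append(iv.start)
        frags = FragmentSet(
            {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in starts.items()},
            read_length=read_length,
        )
        cohort.append((frags, meta))
    return cohort, chrom_sizes
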