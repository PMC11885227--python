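"""Fetal-fraction estimators.

Two estimators live here: the conventional chromosome-Y dosage method
(fetal fraction read off a linear interpolation between the chrY read share
of a non-pregnant/female-fetus baseline and that of a fully fetal library),
and the fetal-specific-region model

    ff = beta_0 + beta_1 y_1 + ... + beta_n y_n

where ``y_i`` counts uniquely mapped reads starting in the i-th
fetal-specific region.  The region model is fitted by delete-d jackknife
resampling: in each of 1,000 iterations a random 5% of training samples is
excluded and an ordinary least squares fit is recorded; the final
coefficients are the elementwise medians over iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml
from scipy import stats

from .genomic_io import DepthTrack, GenomicInterval, SampleMeta
from .fetal_regions import FetalRegionSet
from .synthetic_cohort import FragmentSet

__all__ = [
    "FeatureVector",
    "FFModel",
    "ValidationReport",
    "estimate_ff_chry",
    "count_region_reads",
    "fit_ff_model",
    "predict_ff",
    "validate_model",
    "save_model",
    "load_model",
]


@dataclass
class FeatureVector:
    """Read counts of one sample over the model's fetal-specific regions."""

    sample_id: str
    y: np.ndarray           # integer counts, one per region
    total_reads: int

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if np.any(self.y < 0):
            raise ValueError("region counts must be non-negative")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")


@dataclass
class FFModel:
    """Region list plus jackknife-median coefficients ``beta_0..beta_n``."""

    regions: list[GenomicInterval]
    coef: np.ndarray                      # length n_regions + 1, beta_0 first
    holdout_fraction: float = 0.05
    iterations: int = 1000
    seed: int = 0
    normalize: Literal["cpm", "raw"] = "cpm"
    coef_archive: np.ndarray | None = None  # iterations x (n+1)
    n_flagged: int = 0                      # rank-deficient iterations
    train_sse: float = float("nan")

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if self.coef.size != len(self.regions) + 1:
            raise ValueError("coefficient count must equal n_regions + 1")


@dataclass
class ValidationReport:
    n: int
    pearson_r: float
    rmse: float
    bias: float


def _chry_share(source: FragmentSet | DepthTrack) -> float:
    if isinstance(source, FragmentSet):
        total = source.n_fragments
        if total == 0:
            raise ValueError("empty fragment set")
        return source.chrom_count("chrY") / total
    if source.mode != "read_start":
        raise ValueError("chrY dosage needs a read_start-mode track or fragments")
    total = source.total()
    if total == 0:
        raise ValueError("empty depth track")
    return source.chrom_sum("chrY") / total


def estimate_ff_chry(
    source: FragmentSet | DepthTrack,
    sample: SampleMeta,
    calib: tuple[float, float],
) -> float:
    """Conventional chrY-dosage fetal fraction for a male pregnancy.

    ``calib = (b_female, b_male)``: the chrY read share expected at fetal
    fraction 0 and (extrapolated) 1.  The estimate is clamped to [0, 1].
    """
    b_female, b_male = calib
    if b_male <= b_female:
        raise ValueError("degenerate calibration: b_male must exceed b_female")
    if sample.fetal_sex != "male":
        raise ValueError("chrY dosage requires a male fetus")
    f_y = _chry_share(source)
    return float(np.clip((f_y - b_female) / (b_male - b_female), 0.0, 1.0))


def count_region_reads(
    fragments: FragmentSet | Sequence[GenomicInterval],
    regions: FetalRegionSet | Sequence[GenomicInterval],
    sample_id: str = "S0",
    total_reads: int | None = None,
) -> FeatureVector:
    """Count fragments whose start position lies inside each region.

    The start-based rule gives every fragment at most one region, so adjacent
    regions never double-count; overlapping regions are rejected.
    """
    ivs = regions.regions if isinstance(regions, FetalRegionSet) else list(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom, group in by_chrom.items():
        group_sorted = sorted(group, key=lambda r: r.start)
        for a, b in zip(group_sorted, group_sorted[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping regions on {chrom}: "
                                 f"{a.start}-{a.end} and {b.start}-{b.end}")
    if isinstance(fragments, FragmentSet):
        y = np.array([fragments.count_in(iv) for iv in ivs], dtype=np.int64)
        total = total_reads or fragments.n_fragments
    else:
        frags = list(fragments)
        y = np.zeros(len(ivs), dtype=np.int64)
        for f in frags:
            for i, iv in enumerate(ivs):
                if f.chrom == iv.chrom and iv.start <= f.start < iv.end:
                    y[i] += 1
                    break
        total = total_reads or len(frags)
    return FeatureVector(sample_id, y, max(int(total), 1))


def _design(features: Sequence[FeatureVector], normalize: str) -> np.ndarray:
    rows = []
    for fv in features:
        y = fv.y.astype(float)
        if normalize == "cpm":
            y = y * 1e6 / fv.total_reads
        rows.append(np.concatenate(([1.0], y)))
    return np.asarray(rows)


def fit_ff_model(
    train: Sequence[tuple[FeatureVector, float]],
    holdout_fraction: float = 0.05,
    iterations: int = 1000,
    seed: int = 0,
    regions: Sequence[GenomicInterval] | None = None,
    normalize: Literal["cpm", "raw"] = "cpm",
) -> FFModel:
    """Delete-d jackknife fit of the region-count fetal-fraction model.

    Each iteration drops ``ceil(holdout_fraction * n)`` random samples and
    solves ordinary least squares on the rest (minimum-norm solution, flagged,
    when the retained design is rank deficient).  Final coefficients are the
    per-coefficient median over iterations; ``iterations=1`` with
    ``holdout_fraction=0`` reduces to plain OLS.
    """
    if not train:
        raise ValueError("empty training set")
    features = [fv for fv, _ in train]
    target = np.array([ff for _, ff in train], dtype=float)
    X = _design(features, normalize)
    n, p = X.shape
    n_drop = int(np.ceil(holdout_fraction * n)) if holdout_fraction > 0 else 0
    if n - n_drop < p + 1:
        raise ValueError(f"too few training samples ({n}) for {p - 1} regions "
                         f"after holdout of {n_drop}")
    rng = np.random.default_rng(seed)
    archive = np.empty((iterations, p))
    n_flagged = 0
    for it in range(iterations):
        if n_drop:
            keep = np.ones(n, dtype=bool)
            keep[rng.choice(n, size=n_drop, replace=False)] = False
        else:
            keep = slice(None)
        beta, _, rank, _ = np.linalg.lstsq(X[keep], target[keep], rcond=None)
        if rank < p:
            n_flagged += 1
        archive[it] = beta
    coef = np.median(archive, axis=0)
    sse = float(((X @ coef - target) ** 2).sum())
    region_list = (list(regions) if regions is not None
                   else [GenomicInterval("chrUn", i, i + 1) for i in range(p - 1)])
    return FFModel(region_list, coef, holdout_fraction, iterations, seed,
                   normalize, archive, n_flagged, sse)


def predict_ff(model: FFModel, x: FeatureVector, clamp: bool = True) -> float:
    """``beta_0 + sum_i beta_i y_i``; clamped to [0, 1] unless ``clamp=False``."""
    if x.y.size != len(model.regions):
        raise ValueError(f"feature length {x.y.size} != model regions {len(model.regions)}")
    raw = float(_design([x], model.normalize)[0] @ model.coef)
    return float(np.clip(raw, 0.0, 1.0)) if clamp else raw


def validate_model(
    model: FFModel,
    validation: Sequence[tuple[FeatureVector, float]],
) -> ValidationReport:
    """Pearson correlation (on unclamped predictions), RMSE and bias against
    known fetal fractions of an independent validation set."""
    if len(validation) < 3:
        raise ValueError("need >= 3 validation samples")
    pred = np.array([predict_ff(model, fv, clamp=False) for fv, _ in validation])
    truth = np.array([ff for _, ff in validation], dtype=float)
    r = float(stats.pearsonr(pred, truth).statistic)
    err = pred - truth
    return ValidationReport(n=len(validation), pearson_r=r,
                            rmse=float(np.sqrt((err ** 2).mean())),
                            bias=float(err.mean()))


# ---------------------------------------------------------------------------
# serialization


def save_model(model: FFModel, path) -> None:
    doc = {
        "regions": [[iv.chrom, iv.start, iv.end] for iv in model.regions],
        "coef": [float(c) for c in model.coef],
        "holdout_fraction": model.holdout_fraction,
        "iterations": model.iterations,
        "seed": model.seed,
        "normalize": model.normalize,
        "n_flagged": model.n_flagged,
        "train_sse": None if np.isnan(model.train_sse) else model.train_sse,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_model(path) -> FFModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return FFModel(
        regions=[GenomicInterval(c, s, e) for c, s, e in doc["regions"]],
        coef=np.array(doc["coef"], dtype=float),
        holdout_fraction=doc["holdout_fraction"],
        iterations=doc["iterations"],
        seed=doc["seed"],
        normalize=doc["normalize"],
        n_flagged=doc.get("n_flagged", 0),
        train_sse=doc["train_sse"] if doc.get("train_sse") is not None else float("nan"),
    )
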