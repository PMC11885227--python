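"""Case/control cfDNA coverage scanning and the signed-sum phenotype score.

A binary-contrast differential coverage scan over TSS-proximal windows yields
a panel of loci with higher (up) or lower (down) coverage in cases.  For a
test sample, reads mapping to up-loci are added and reads mapping to
down-loci subtracted (counts-per-million within sample) -- the signed sum S.
S is standardized against a reference model built blindly from the whole
cohort (or from labelled controls), shifted by +4 with negative values
clamped to zero, and samples above the cohort's empirical 99% quantile are
called.  Positive predictive value is evaluated among called samples with
known outcomes (lost-to-follow-up excluded from the denominator).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genomic_io import DepthTrack, GeneAnnotation, GenomicInterval, SampleMeta
from .fetal_regions import GroupLibrary
from .ff_model import FeatureVector, count_region_reads
from .open_chromatin import _binom_two_sided
from .synthetic_cohort import FragmentSet

__all__ = [
    "LociPanel",
    "PhenotypeScore",
    "PPVReport",
    "adjust_score",
    "profile_contrast",
    "build_panel",
    "tss_windows",
    "panel_features",
    "signed_sum",
    "score_cohort",
    "call_by_quantile",
    "evaluate_ppv",
]


@dataclass
class LociPanel:
    """Panel loci split by direction of the case/control coverage change."""

    up_regions: list[GenomicInterval]    # higher coverage in cases
    down_regions: list[GenomicInterval]  # lower coverage in cases
    stats: pd.DataFrame | None = None    # per-window construction statistics

    def __post_init__(self):
        ivs = sorted(self.up_regions + self.down_regions)
        for a, b in zip(ivs, ivs[1:]):
            if a.overlaps(b):
                raise ValueError("panel regions overlap")

    @property
    def regions(self) -> list[GenomicInterval]:
        return list(self.up_regions) + list(self.down_regions)


@dataclass
class PhenotypeScore:
    sample_id: str
    signed_sum: float
    z: float
    adjusted: float
    called: bool = False
    gestation_week: float | None = None


@dataclass
class PPVReport:
    n_called: int
    n_evaluable: int
    outcome_counts: dict[str, int]
    ppv: dict[str, float] | None   # None when no called sample is evaluable


def profile_contrast(
    case_track: DepthTrack,
    control_track: DepthTrack,
    viewport: GenomicInterval,
    smooth_window: int = 50,
) -> pd.DataFrame:
    """Paired smoothed profiles of two depth tracks within a viewing area.

    Each profile is rescaled to unit mean inside the viewport (removing the
    libraries' different numerical baselines) and smoothed with a centered
    running mean whose window is truncated at the viewport edges.
    """
    out = {"pos": np.arange(viewport.start, viewport.end)}
    h = smooth_window // 2
    for name, track in (("case", case_track), ("control", control_track)):
        arr = track.data[viewport.chrom][viewport.start:viewport.end].astype(float)
        mean = arr.mean()
        if mean <= 0:
            raise ValueError(f"{name} track has zero depth in the viewport")
        arr = arr / mean
        cs = np.concatenate(([0.0], np.cumsum(arr)))
        n = arr.size
        lo = np.maximum(np.arange(n) - h, 0)
        hi = np.minimum(np.arange(n) + h + 1, n)
        out[name] = (cs[hi] - cs[lo]) / (hi - lo)
    return pd.DataFrame(out)


def tss_windows(annotation: Sequence[GeneAnnotation], half_width: int = 250
                ) -> list[GenomicInterval]:
    """One window of ``2 * half_width`` bp centred on each TSS."""
    wins = []
    for g in annotation:
        tss = g.tss_pos
        start = max(tss - half_width, 0)
        wins.append(GenomicInterval(g.body.chrom, start, tss + half_width))
    return wins


def _window_counts(track: DepthTrack, windows: Sequence[GenomicInterval]) -> np.ndarray:
    counts = np.empty(len(windows), dtype=np.int64)
    for i, iv in enumerate(windows):
        counts[i] = int(track.data[iv.chrom][iv.start:iv.end].sum())
    return counts


def build_panel(
    case_group: GroupLibrary,
    control_group: GroupLibrary,
    windows: Sequence[GenomicInterval],
    alpha: float = 0.05,
) -> LociPanel:
    """Binary-contrast differential coverage over candidate windows.

    Each window's case count is tested against a binomial conditional on the
    pooled window count with success probability set by the library totals;
    Benjamini-Hochberg-significant windows at ``alpha`` join the panel, split
    by the sign of the normalised case/control fold change.
    """
    x_case = _window_counts(case_group.track, windows)
    x_ctrl = _window_counts(control_group.track, windows)
    p0 = case_group.total_reads / (case_group.total_reads + control_group.total_reads)
    nz = (x_case + x_ctrl) > 0
    pv = np.ones(len(windows))
    pv[nz] = _binom_two_sided(x_case[nz], (x_case + x_ctrl)[nz], p0)
    padj = np.ones(len(windows))
    if nz.any():
        padj[nz] = multipletests(pv[nz], method="fdr_bh")[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (x_case / case_group.total_reads) / (x_ctrl / control_group.total_reads)
    up, down = [], []
    for i, iv in enumerate(windows):
        if nz[i] and padj[i] < alpha:
            (up if fc[i] > 1 else down).append(iv)
    stats_df = pd.DataFrame({
        "chrom": [iv.chrom for iv in windows],
        "start": [iv.start for iv in windows],
        "end": [iv.end for iv in windows],
        "count_case": x_case, "count_control": x_ctrl,
        "fold_change": fc, "p_value": pv, "adjusted_p": padj,
    })
    return LociPanel(up, down, stats_df)


def panel_features(
    fragments: FragmentSet,
    panel: LociPanel,
    sample_id: str = "S0",
    total_reads: int | None = None,
) -> FeatureVector:
    """Per-sample read counts over the panel (up regions first, then down)."""
    return count_region_reads(fragments, panel.regions, sample_id, total_reads)


def signed_sum(x: FeatureVector, panel: LociPanel) -> float:
    """S = sum of up-locus counts minus sum of down-locus counts, in
    counts-per-million within the sample."""
    n_up = len(panel.up_regions)
    if x.y.size != n_up + len(panel.down_regions):
        raise ValueError("feature vector does not match the panel")
    cpm = x.y.astype(float) * 1e6 / x.total_reads
    return float(cpm[:n_up].sum() - cpm[n_up:].sum())


def adjust_score(z: float, shift: float = 4.0) -> float:
    """The reporting adjustment: add a constant shift (default 4) and clamp
    negative values to zero -- ``max(0, z + shift)`` exactly."""
    return max(0.0, z + shift)


def score_cohort(
    samples: Sequence[tuple[FeatureVector, SampleMeta]],
    panel: LociPanel,
    reference: Literal["blind_all", "labeled_controls"] = "blind_all",
    shift: float = 4.0,
) -> list[PhenotypeScore]:
    """Signed sums standardized against a reference model.

    ``blind_all`` builds the reference from the entire cohort without using
    labels (as a screening lab would, cases included); ``labeled_controls``
    uses condition == 'control' samples only.  Standardization is monotone,
    so the two references produce identical sample rankings.  The adjusted
    score is ``max(0, z + shift)``.
    """
    if len(samples) < 30:
        raise ValueError("need >= 30 samples for a stable reference")
    s_vals = np.array([signed_sum(fv, panel) for fv, _ in samples])
    if reference == "blind_all":
        ref = s_vals
    elif reference == "labeled_controls":
        ref = np.array([s for s, (_, m) in zip(s_vals, samples)
                        if m.condition == "control"])
        if ref.size < 2:
            raise ValueError("no labelled controls to build the reference from")
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    mu, sigma = float(ref.mean()), float(ref.std(ddof=1))
    if sigma == 0:
        raise ValueError("reference signed sums have zero spread")
    out = []
    for s, (fv, meta) in zip(s_vals, samples):
        z = (s - mu) / sigma
        out.append(PhenotypeScore(fv.sample_id, float(s), float(z),
                                  adjust_score(float(z), shift)))
    return out


def call_by_quantile(
    scores: Sequence[PhenotypeScore],
    q: float = 0.99,
) -> tuple[list[PhenotypeScore], float]:
    """Call samples whose adjusted score strictly exceeds the empirical
    ``q``-quantile (order-statistic quantile with linear interpolation)."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    adj = np.array([s.adjusted for s in scores])
    threshold = float(np.quantile(adj, q))
    for s in scores:
        s.called = s.adjusted > threshold
    return list(scores), threshold


def evaluate_ppv(
    calls: Sequence[PhenotypeScore],
    outcomes: Mapping[str, str | None],
) -> PPVReport:
    """Positive predictive value per confirmed outcome among called samples.

    ``outcomes[sample_id]`` is an outcome label, ``'none'`` for a confirmed
    negative, or ``None`` for lost-to-follow-up (excluded from the
    denominator).  With zero evaluable called samples the PPV is undefined
    and reported as ``None``.
    """
    called = [s for s in calls if s.called]
    evaluable = [s for s in called if outcomes.get(s.sample_id) is not None]
    counts = Counter(outcomes[s.sample_id] for s in evaluable)
    if not evaluable:
        return PPVReport(len(called), 0, dict(counts), None)
    ppv = {label: n / len(evaluable) for label, n in counts.items() if label != "none"}
    return PPVReport(len(called), len(evaluable), dict(counts), ppv)
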