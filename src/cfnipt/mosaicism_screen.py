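"""Fetal-fraction concordance screen for confined placental mosaicism (CPM).

An aneuploidy-positive NIPT call implies a fetal fraction: a full trisomy
shifts the target chromosome's dosage by half the fetal fraction, so the
observed dosage excess can be inverted into an "aneuploidy-implied" fetal
fraction (AneuFC).  Independent estimates come from chrY dosage (sexFC) and
the fetal-specific-region model (RegFC).  When only a fraction m of placental
cells is aneuploid, AneuFC is diluted to roughly m times the true fetal
fraction while sexFC/RegFC are not, so the standardized discrepancy between
the best independent estimate and AneuFC -- a combined Z-score against a
reference of concordant positives -- flags likely CPM.  Flags are advisory
annotations; they never demote a positive screening call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .genomic_io import DepthTrack, GenomicInterval
from .synthetic_cohort import FragmentSet

__all__ = ["FFTriple", "MosaicCall", "estimate_aneufc", "combined_zscore"]


@dataclass
class FFTriple:
    """Three fetal-fraction estimates for one aneuploidy-positive sample."""

    sample_id: str
    sexFC: float | None      # chrY dosage; undefined for female fetuses
    RegFC: float | None      # fetal-specific-region model
    AneuFC: float            # implied by the target chromosome's dosage excess
    target_chrom: str = ""

    def best_independent(self) -> float:
        if self.sexFC is not None:
            return self.sexFC
        if self.RegFC is not None:
            return self.RegFC
        raise ValueError(f"sample {self.sample_id}: no independent ff estimate")


@dataclass
class MosaicCall:
    sample_id: str
    discordance: float
    combined_z: float
    flagged: bool
    mu_ref: float
    sigma_ref: float
    cutoff: float


def _region_count(source: FragmentSet, regions: Sequence[GenomicInterval]) -> int:
    return int(sum(source.count_in(iv) for iv in regions))


def estimate_aneufc(
    source: FragmentSet,
    target_chrom: str,
    f_exp: float,
    background: Sequence[GenomicInterval] | None = None,
    dosage_response: float = 1.0,
) -> float:
    """Aneuploidy-implied fetal fraction from the target chromosome's dosage.

    ``f_obs`` is the target-chromosome read count over the read count in the
    euploid ``background`` region set (total non-target reads when no
    background is given); ``f_exp`` is the same ratio expected for a euploid
    sample.  A full trisomy at fetal fraction ff shifts the ratio by ff/2, so

        AneuFC = 2 * (f_obs / f_exp - 1) / dosage_response

    clamped to [0, 1].  ``dosage_response`` (default 1, the idealised case)
    calibrates how much relative dosage shift one unit of ff/2 produces.
    """
    if f_exp <= 0:
        raise ValueError("f_exp must be positive")
    if dosage_response <= 0:
        raise ValueError("dosage_response must be positive")
    n_target = source.chrom_count(target_chrom)
    if background is not None:
        n_denom = _region_count(source, background)
    else:
        n_denom = source.n_fragments - n_target
    if n_denom == 0:
        raise ValueError("no reads in the dosage background")
    f_obs = n_target / n_denom
    return float(np.clip(2.0 * (f_obs / f_exp - 1.0) / dosage_response, 0.0, 1.0))


def combined_zscore(
    triples: Sequence[FFTriple],
    reference: Sequence[FFTriple],
    cutoff: float = 3.0,
    mode: Literal["best", "joint"] = "best",
) -> list[MosaicCall]:
    """Standardize each sample's ff discordance against a reference of
    concordant positives.

    ``best`` mode (default): D = FF_best - AneuFC with FF_best = sexFC when
    defined, else RegFC; z = (D - mu_ref) / sigma_ref.  ``joint`` mode
    combines both pairwise discrepancies (sexFC-AneuFC and RegFC-AneuFC) into
    a root-mean-square of their separate standardizations.  A sample is
    flagged when z exceeds ``cutoff`` (an advisory annotation only).
    """
    if len(reference) < 20:
        raise ValueError(f"reference needs >= 20 samples, got {len(reference)}")

    def _d_best(t: FFTriple) -> float:
        return t.best_independent() - t.AneuFC

    if mode == "best":
        ref_d = np.array([_d_best(t) for t in reference])
        mu, sigma = float(ref_d.mean()), float(ref_d.std(ddof=1))
        if sigma == 0:
            raise ValueError("reference discordance has zero spread")
        out = []
        for t in triples:
            d = _d_best(t)
            z = (d - mu) / sigma
            out.append(MosaicCall(t.sample_id, d, z, z > cutoff, mu, sigma, cutoff))
        return out
    elif mode == "joint":
        pairs = []
        for attr in ("sexFC", "RegFC"):
            vals = [getattr(t, attr) - t.AneuFC for t in reference
                    if getattr(t, attr) is not None]
            if len(vals) >= 2:
                arr = np.array(vals)
                sd = float(arr.std(ddof=1))
                if sd == 0:
                    raise ValueError("reference discordance has zero spread")
                pairs.append((attr, float(arr.mean()), sd))
        if not pairs:
            raise ValueError("reference carries no usable ff estimates")
        out = []
        for t in triples:
            zs = [((getattr(t, attr) - t.AneuFC) - mu) / sd
                  for attr, mu, sd in pairs if getattr(t, attr) is not None]
            z = float(np.sqrt(np.mean(np.square(zs))) * np.sign(np.mean(zs)))
            d = _d_best(t)
            out.append(MosaicCall(t.sample_id, d, z, z > cutoff,
                                  float("nan"), float("nan"), cutoff))
        return out
    raise ValueError(f"unknown mode {mode!r}")
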