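"""End-to-end pipeline: simulate -> regions -> ff model -> mosaic screen ->
open chromatin -> phenotype score, with a provenance manifest.

The pipeline is deterministic: the serialized configuration plus its seed
fully determine every artifact, and the manifest records the configuration
hash so reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genomic_io import GenomicInterval, write_annotation, write_regions
from .synthetic_cohort import (
    CohortSpec, default_genome, simulate_cohort, simulate_sample, write_cohort,
)
from .fetal_regions import build_flank_pwm, call_fetal_regions, fit_groups, merge_groups
from .ff_model import (
    count_region_reads, fit_ff_model, predict_ff, save_model, validate_model,
)
from .mosaicism_screen import FFTriple, combined_zscore, estimate_aneufc
from .open_chromatin import DOWN, TierSet, map_downstream_genes, monotonic_filter, window_runs
from .phenotype_score import (
    build_panel, call_by_quantile, panel_features, score_cohort, tss_windows,
)

log = logging.getLogger("cfnipt")

_DEFAULTS = {
    "genome": {"seed": 2024, "ndr_dip": 0.8, "panel_effect": 0.5},
    "cohort": {"n_samples": 80, "reads_per_sample": 50_000, "ff_low": 0.05,
               "ff_high": 0.20, "fraction_male": 1.0, "case_fraction": 0.0},
    "regions": {"n_groups": 8, "max_rel_error": 0.2, "error_mode": "mean",
                "min_reads": 2, "flank": 50},
    "ff": {"holdout_fraction": 0.05, "iterations": 200,
           "validation_fraction": 0.25},
    "mosaic": {"enabled": False, "target_chrom": "chr1", "n_reference": 25,
               "n_test": 5, "mosaic_fraction": 0.4, "cutoff": 3.0},
    "chromatin": {"enabled": True, "samples_per_tier": 10,
                  "tier_ffs": [0.05, 0.10, 0.15, 0.20], "flank": 12,
                  "min_windows": 5, "max_distance": 10_000},
    "phenotype": {"enabled": True, "n_samples": 120, "case_fraction": 0.05,
                  "alpha": 0.05, "shift": 4.0, "quantile": 0.95,
                  "reference": "blind_all"},
}


@dataclass
class PipelineConfig:
    """Nested stage parameters; anything omitted falls back to the defaults."""

    seed: int = 1
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(seed=int(doc.get("seed", 1)),
                   stages={k: v for k, v in doc.items() if k != "seed"})

    def params(self, stage: str) -> dict:
        merged = dict(_DEFAULTS[stage])
        merged.update(self.stages.get(stage, {}))
        return merged

    def canonical(self) -> str:
        full = {"seed": self.seed}
        full.update({s: self.params(s) for s in _DEFAULTS})
        return yaml.safe_dump(full, sort_keys=True)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every enabled stage; return the provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "artifacts": [],
    }

    def emit(name):
        manifest["artifacts"].append(name)
        log.info("wrote %s", name)

    gp = config.params("genome")
    genome = default_genome(seed=gp["seed"], ndr_dip=gp["ndr_dip"],
                            panel_effect=gp["panel_effect"])
    rng = np.random.default_rng(config.seed)

    # --- simulate the discovery cohort
    cp = config.params("cohort")
    spec = CohortSpec(rng_seed=config.seed, **cp)
    cohort = simulate_cohort(spec, genome, rng)
    write_cohort(cohort, genome, out / "cohort")
    emit("cohort/")

    # --- fetal-specific regions + flank PWM
    rp = config.params("regions")
    if rp["n_groups"] > len(cohort):
        raise RuntimeError("stage 'regions': n_groups exceeds cohort size")
    groups = merge_groups(cohort, genome.chrom_sizes, rp["n_groups"])
    fits = fit_groups(groups, error_mode=rp["error_mode"])
    region_set = call_fetal_regions(fits, max_rel_error=rp["max_rel_error"],
                                    min_reads=rp["min_reads"])
    write_regions(region_set.regions, out / "regions.bed",
                  scores=region_set.min_depth)
    emit("regions.bed")
    pwm = build_flank_pwm(region_set, genome.reference, flank=rp["flank"])
    with open(out / "pwm.tsv", "w") as fh:
        for base, row in zip("ACGT", pwm.matrix):
            fh.write(base + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("consensus\t" + pwm.consensus + "\n")
    emit("pwm.tsv")

    # --- fetal-fraction model
    fp = config.params("ff")
    feats = [(count_region_reads(f, region_set, m.sample_id), m.true_ff)
             for f, m in cohort]
    n_val = max(3, int(fp["validation_fraction"] * len(feats)))
    train, val = feats[n_val:], feats[:n_val]
    model = fit_ff_model(train, holdout_fraction=fp["holdout_fraction"],
                         iterations=fp["iterations"], seed=config.seed,
                         regions=region_set.regions)
    save_model(model, out / "ff_model.yaml")
    emit("ff_model.yaml")
    report = validate_model(model, val)
    pd.DataFrame([asdict(report)]).to_csv(out / "ff_validation.tsv", sep="\t", index=False)
    emit("ff_validation.tsv")

    # --- mosaicism screen (optional)
    mp = config.params("mosaic")
    if mp["enabled"]:
        from .synthetic_cohort import Karyotype
        f_exp, kappa = genome.aneufc_calibration(mp["target_chrom"])
        bg = genome.dosage_background(mp["target_chrom"])
        b_calib = genome.chry_calibration()
        from .ff_model import estimate_ff_chry

        def triple(frags, meta, sid):
            aneu = estimate_aneufc(frags, mp["target_chrom"], f_exp, bg, kappa)
            sex = estimate_ff_chry(frags, meta, b_calib)
            return FFTriple(sid, sex, None, aneu, mp["target_chrom"])

        ref = []
        for i in range(mp["n_reference"]):
            ff = float(rng.uniform(0.05, 0.20))
            frags, meta = simulate_sample(genome, ff, "male",
                                          Karyotype(mp["target_chrom"], 1.0),
                                          "control", cp["reads_per_sample"], rng,
                                          sample_id=f"REF{i:03d}")
            ref.append(triple(frags, meta, meta.sample_id))
        tests = []
        for i in range(mp["n_test"]):
            ff = float(rng.uniform(0.10, 0.20))
            frags, meta = simulate_sample(
                genome, ff, "male",
                Karyotype(mp["target_chrom"], mp["mosaic_fraction"]),
                "control", cp["reads_per_sample"], rng, sample_id=f"CPM{i:03d}")
            tests.append(triple(frags, meta, meta.sample_id))
        calls = combined_zscore(tests, ref, cutoff=mp["cutoff"])
        pd.DataFrame([asdict(c) for c in calls]).to_csv(
            out / "mosaic.tsv", sep="\t", index=False)
        emit("mosaic.tsv")

    # --- open chromatin
    chp = config.params("chromatin")
    if chp["enabled"]:
        from .fetal_regions import GroupLibrary
        from .synthetic_cohort import simulate_merged_depth

        tiers = []
        for ti, ff in enumerate(chp["tier_ffs"]):
            n_reads = chp["samples_per_tier"] * cp["reads_per_sample"]
            track = simulate_merged_depth(genome, ff, n_reads, rng)
            tiers.append(GroupLibrary(f"tier{ti}", ff, chp["samples_per_tier"],
                                      track, n_reads))
        candidates = monotonic_filter(TierSet(tiers))
        runs = window_runs(candidates, flank=chp["flank"],
                           min_windows=chp["min_windows"], direction=DOWN)
        write_regions([r.interval for r in runs], out / "chromatin_runs.bed",
                      names=["down_with_ff"] * len(runs),
                      scores=[r.n_windows for r in runs])
        emit("chromatin_runs.bed")
        genes = map_downstream_genes(runs, genome.genes,
                                     max_distance=chp["max_distance"])
        (out / "downstream_genes.txt").write_text("\n".join(genes) + "\n")
        emit("downstream_genes.txt")

    # --- phenotype panel + scores
    pp = config.params("phenotype")
    if pp["enabled"]:
        spec_ph = CohortSpec(n_samples=pp["n_samples"],
                             reads_per_sample=cp["reads_per_sample"],
                             case_fraction=pp["case_fraction"],
                             fraction_male=0.5, rng_seed=config.seed + 1)
        ph_cohort = simulate_cohort(spec_ph, genome, rng)
        cases = [(f, m) for f, m in ph_cohort if m.condition == "case"]
        ctrls = [(f, m) for f, m in ph_cohort if m.condition == "control"]
        if not cases:
            raise RuntimeError("stage 'phenotype': no case samples in cohort")
        case_g = merge_groups(cases, genome.chrom_sizes, 1, mode="read_start")[0]
        ctrl_g = merge_groups(ctrls, genome.chrom_sizes, 1, mode="read_start")[0]
        wins = tss_windows(genome.genes)
        panel = build_panel(case_g, ctrl_g, wins, alpha=pp["alpha"])
        write_regions(panel.regions, out / "panel.bed",
                      names=["up"] * len(panel.up_regions) +
                            ["down"] * len(panel.down_regions))
        emit("panel.bed")
        if panel.regions:
            feats_ph = [(panel_features(f, panel, m.sample_id), m)
                        for f, m in ph_cohort]
            scores = score_cohort(feats_ph, panel, reference=pp["reference"],
                                  shift=pp["shift"])
            scores, threshold = call_by_quantile(scores, q=pp["quantile"])
            df = pd.DataFrame([asdict(s) for s in scores])
            df["condition"] = [m.condition for _, m in ph_cohort]
            df.to_csv(out / "scores.tsv", sep="\t", index=False)
            emit("scores.tsv")
            manifest["phenotype_threshold"] = threshold

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
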