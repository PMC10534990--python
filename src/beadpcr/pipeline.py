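"""End-to-end orchestration: synthesize -> segment -> quantify -> compare.

`run_demo_study` recreates the shape of the reference experiment — a
serial dilution series measured in replicate wells — entirely from the
synthetic generator, runs the full analysis, and compares the recovered
concentrations against a simulated reference method.  Every random
draw derives from the single configured seed, so a run is reproducible
(and byte-identical in its JSON output) from (config, seed).

Two entry points per replicate: full image rendering + segmentation, or
a direct per-bead intensity table (same statistical model, no imaging)
for fast statistical work.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import compare as compare_mod
from . import segmentation as seg_mod
from . import synthetic as syn_mod
from .quantify import (
    StudyDesign,
    WellIntensitySet,
    concentration_beads,
    poisson_lambda,
    quantify_well,
)

__all__ = ["RunConfig", "validate_config", "run_demo_study", "analyze_well_images"]


@dataclass
class RunConfig:
    """Configuration of a demo study run.

    ``level_concentrations`` are the true sample concentrations (cP/uL)
    of the dilution series; the generator converts them to per-bead
    Poisson means via the study design (lam = c * V_S / N_B).  The
    default series spans 4 decades in 10-fold steps like the reference
    dilution ladder.
    """

    design: StudyDesign = field(default_factory=StudyDesign)
    seg_params: seg_mod.SegmentationParams = field(
        default_factory=seg_mod.SegmentationParams
    )
    image_spec: syn_mod.ImageSpec = field(default_factory=syn_mod.ImageSpec)
    level_concentrations: tuple[float, ...] = (25000.0, 2500.0, 250.0, 25.0, 2.5)
    n_replicates: int = 12
    beads_per_replicate: int = 3300
    seed: int = 0
    use_images: bool = False
    pooled_lambda: bool = False
    reference_sd_log10: float = 0.02
    bead_diameter_cv: float = 0.07
    min_inrange_replicates: int = 8  # level is in measurement range if >= this many finite nonzero results

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_config(config: RunConfig | dict) -> RunConfig:
    """Normalize a config (dict or RunConfig); collect all violations."""
    if isinstance(config, dict):
        kwargs = dict(config)
        try:
            if "design" in kwargs and isinstance(kwargs["design"], dict):
                kwargs["design"] = StudyDesign(**kwargs["design"])
            if "seg_params" in kwargs and isinstance(kwargs["seg_params"], dict):
                kwargs["seg_params"] = seg_mod.SegmentationParams(**kwargs["seg_params"])
            if "image_spec" in kwargs and isinstance(kwargs["image_spec"], dict):
                kwargs["image_spec"] = syn_mod.ImageSpec(**kwargs["image_spec"])
            config = RunConfig(**kwargs)
        except (TypeError, ValueError) as e:
            raise ValueError(f"invalid configuration: {e}") from e
    errors = []
    if config.n_replicates < 1:
        errors.append("n_replicates: must be >= 1")
    if config.beads_per_replicate < 1:
        errors.append("beads_per_replicate: must be >= 1")
    if any(c < 0 for c in config.level_concentrations):
        errors.append("level_concentrations: must be >= 0")
    if config.reference_sd_log10 < 0:
        errors.append("reference_sd_log10: must be >= 0")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    return config


def analyze_well_images(
    marker_img: np.ndarray,
    detect_img: np.ndarray,
    params: seg_mod.SegmentationParams,
) -> WellIntensitySet:
    """Segment the marker channel, measure the detection channel."""
    dets = seg_mod.detect_beads(marker_img, params, channel="marker")
    seg_mod.measure_channel(dets, detect_img, "detect")
    vals = [d.intensities["detect"] for d in dets if d.valid]
    return WellIntensitySet(np.asarray(vals, dtype=float))


def _simulate_replicate_intensities(
    n_beads: int, lam: float, img: syn_mod.ImageSpec, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    targets = rng.poisson(lam, size=n_beads)
    pos = targets >= 1
    vals = np.where(
        pos,
        rng.normal(img.positive_intensity, img.positive_sd, n_beads),
        rng.normal(img.negative_intensity, img.negative_sd, n_beads),
    )
    return vals, int(pos.sum())


def run_demo_study(config: RunConfig | dict, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic dilution-series study.

    Returns a JSON-serializable bundle: per-replicate results, level
    summaries (mean concentration, log10 replicate SD, nonzero counts),
    and a method-comparison report against a simulated reference method
    on the levels within measurement range.
    """
    config = validate_config(config)
    design = config.design
    img = config.image_spec
    rng = np.random.default_rng(config.seed)
    control_intensity = 0.5 * (img.negative_intensity + img.positive_intensity)

    per_replicate = []
    level_concs: dict[str, list[float]] = {}
    warnings_acc: list[str] = []
    for li, true_conc in enumerate(config.level_concentrations):
        level = f"V{li + 1}"
        lam_true = true_conc * design.sample_volume_ul / design.n_beads_incubated
        level_concs[level] = []
        pooled_n = pooled_neg = 0
        for rep in range(config.n_replicates):
            rep_seed = int(rng.integers(0, 2**31))
            if config.use_images:
                pop = syn_mod.BeadPopulationSpec(
                    n_beads=config.beads_per_replicate,
                    diameter_cv=config.bead_diameter_cv,
                )
                marker, detect, _truth = syn_mod.render_well_image(
                    pop, img, lam_true, rep_seed
                )
                well = analyze_well_images(marker, detect, config.seg_params)
            else:
                vals, _ = _simulate_replicate_intensities(
                    config.beads_per_replicate,
                    lam_true,
                    img,
                    np.random.default_rng(rep_seed),
                )
                well = WellIntensitySet(vals)
            res = quantify_well(
                well, design, positive_control_intensity=control_intensity
            )
            rec = {
                "level": level,
                "replicate": rep,
                "seed": rep_seed,
                **res.to_dict(),
            }
            per_replicate.append(rec)
            if math.isfinite(res.concentration):
                level_concs[level].append(res.concentration)
                pooled_n += res.n
                pooled_neg += res.n_neg
            for flag in res.flags:
                if flag != "all_negative":
                    warnings_acc.append(f"{level} rep {rep}: {flag}")
        if config.pooled_lambda and pooled_n:
            lam_pooled = poisson_lambda(pooled_neg, pooled_n) if pooled_neg else math.inf
            level_concs[level] = (
                [concentration_beads(lam_pooled, design)]
                if math.isfinite(lam_pooled)
                else []
            )

    precision = compare_mod.replicate_precision(
        {k: np.asarray(v) for k, v in level_concs.items()}
    )
    level_summary = {}
    for li, true_conc in enumerate(config.level_concentrations):
        level = f"V{li + 1}"
        vals = np.asarray(level_concs[level], dtype=float)
        nonzero = vals[vals > 0]
        level_summary[level] = {
            "true_concentration": true_conc,
            "mean_concentration": float(nonzero.mean()) if nonzero.size else 0.0,
            **precision[level],
        }

    # reference method: truth perturbed with log10 noise, compared on
    # level means of the levels within measurement range
    inrange = [
        (level_summary[f"V{i+1}"], c)
        for i, c in enumerate(config.level_concentrations)
        if level_summary[f"V{i+1}"]["n_nonzero"] >= config.min_inrange_replicates
        and c > 0
    ]
    comparison = None
    if len(inrange) >= 3:
        truths = np.array([c for _, c in inrange])
        est = np.array([s["mean_concentration"] for s, _ in inrange])
        ref = syn_mod.simulate_paired_measurements(
            truths, 0.0, config.reference_sd_log10, 0.0,
            int(rng.integers(0, 2**31)),
        )["method_x"].to_numpy()
        report = compare_mod.compare_methods(
            compare_mod.PairedMeasurements(ref, est)
        )
        comparison = {
            "slope": report.slope,
            "intercept": report.intercept,
            "slope_ci": list(report.slope_ci),
            "intercept_ci": list(report.intercept_ci),
            "pearson_r": report.pearson_r,
            "pearson_p": report.pearson_p,
            "bland_altman_mean_difference": report.mean_difference,
            "limits_of_agreement": list(report.loa),
            "n_levels": report.n,
        }

    bundle = {
        "config": config.to_dict(),
        "seed": config.seed,
        "per_replicate": per_replicate,
        "levels": level_summary,
        "comparison": comparison,
        "warnings": warnings_acc,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "demo_study.json").write_text(
            json.dumps(bundle, indent=2, default=_json_default)
        )
    return bundle


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
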