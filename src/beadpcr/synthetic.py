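"""Synthetic data generator for the bead-dPCR pipeline.

Every input the analysis consumes can be produced here with known ground
truth: fluorescence images of bead monolayers (a bead-marker channel in
which every bead fluoresces and a detection channel in which only
PCR-positive beads are bright), per-bead target counts under Poisson
partitioning, Langmuir binding-assay tables, and paired two-method
concentration measurements with log-scale noise.

The default bead population matches the reference beads: mean diameter
94.8 um with a 7% coefficient of variation, i.e. a mean volume of
0.446 nL.  Bead diameters are drawn log-normal (mean/CV preserved, no
negative draws).  Monolayers are emulated as 2-D non-overlapping discs
in a circular well; at monolayer densities placement uses a jittered
hexagonal lattice (random sequential "dart throwing" jams near packing
fraction 0.55, below what a self-assembled monolayer reaches), with
dart throwing retained for sparse fields.

Rendering uses a projected-sphere fluorescence model: a bead of radius R
contributes intensity proportional to its chord length, i.e.
``I(r) = peak * sqrt(1 - (r/R)^2)`` for r < R, on top of a constant
background, plus optional Gaussian pixel noise.  Images are 16-bit;
values outside [0, 65535] are clipped with a warning.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding
from .quantify import sphere_volume

__all__ = [
    "BeadPopulationSpec",
    "ImageSpec",
    "GroundTruth",
    "draw_target_counts",
    "sample_diameters",
    "place_beads",
    "render_field",
    "render_well_image",
    "simulate_kinetics_assay",
    "simulate_isotherm_assay",
    "simulate_paired_measurements",
    "write_well",
]

_U16_MAX = 65535

#: input DNA concentration ladder (ng/uL) of the reference isotherm assay
DEFAULT_ISOTHERM_LADDER = (10.0, 63.0, 127.0, 199.0, 297.0, 401.0)

#: sampling schedule (s) for kinetics assays: dense early, where a
#: process with k_a ~ 0.2 1/s carries its information, then sparse out
#: to the 10-minute completeness check
DEFAULT_KINETICS_TIMES = (
    0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 30.0,
    45.0, 60.0, 90.0, 120.0, 180.0, 300.0, 600.0,
)


@dataclass(frozen=True)
class BeadPopulationSpec:
    """Bead count and size distribution of a synthetic population."""

    n_beads: int
    mean_diameter_um: float = 94.8
    diameter_cv: float = 0.07

    def __post_init__(self) -> None:
        if self.n_beads < 0:
            raise ValueError("n_beads must be >= 0")
        if self.mean_diameter_um <= 0:
            raise ValueError("mean_diameter_um must be positive")
        if self.diameter_cv < 0:
            raise ValueError("diameter_cv must be >= 0")

    @property
    def mean_volume_nl(self) -> float:
        return sphere_volume(self.mean_diameter_um)


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and intensity model of a rendered well image.

    ``negative_intensity`` / ``positive_intensity`` are the mean per-bead
    representative (peak) intensities in the detection channel; every
    bead carries ``marker_intensity`` in the bead-marker channel.  The
    default modes sit far apart relative to their spreads: endpoint PCR
    chemistry separates positives from negatives essentially completely,
    and the observed zero-positive wells at high dilution bound the
    per-bead misclassification rate well below 1e-3.
    """

    width: int = 512
    height: int = 512
    pixel_size_um: float = 8.0
    background_level: float = 500.0
    noise_sd: float = 25.0
    marker_intensity: float = 12000.0
    marker_cv: float = 0.05
    negative_intensity: float = 6000.0
    negative_sd: float = 600.0
    positive_intensity: float = 16000.0
    positive_sd: float = 900.0
    artifact_rate: float = 0.0
    artifact_intensity: float = 25000.0
    well_radius_px: float | None = None  # default: inscribed circle minus 2 px

    def __post_init__(self) -> None:
        if not self.positive_intensity > self.negative_intensity >= 0:
            raise ValueError("require positive_intensity > negative_intensity >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")

    @property
    def well_radius(self) -> float:
        if self.well_radius_px is not None:
            return self.well_radius_px
        return min(self.width, self.height) / 2.0 - 2.0


@dataclass
class GroundTruth:
    """Per-bead truth records and well totals for one rendered well."""

    beads: pd.DataFrame  # bead_id, x_px, y_px, radius_px, targets, positive, edge, ...
    lam: float
    n_artifacts: int = 0

    @property
    def n_beads(self) -> int:
        return int(len(self.beads))

    @property
    def n_positive(self) -> int:
        return int(self.beads["positive"].sum()) if len(self.beads) else 0

    @property
    def n_negative(self) -> int:
        return self.n_beads - self.n_positive


# ---------------------------------------------------------------------------
# population draws
# ---------------------------------------------------------------------------

def draw_target_counts(n_beads: int, lam: float, seed: int) -> np.ndarray:
    """Independent Poisson(lam) target counts for each bead."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if n_beads < 0:
        raise ValueError("n_beads must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(lam, size=n_beads)


def sample_diameters(pop: BeadPopulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Log-normal diameters with the spec's mean and CV."""
    if pop.diameter_cv == 0:
        return np.full(pop.n_beads, pop.mean_diameter_um)
    s2 = math.log1p(pop.diameter_cv**2)
    mu = math.log(pop.mean_diameter_um) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size=pop.n_beads)


# ---------------------------------------------------------------------------
# monolayer placement
# ---------------------------------------------------------------------------

def _hex_sites(well_radius: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice sites within a disc of the given radius."""
    dy = spacing * math.sqrt(3) / 2.0
    rows = int(well_radius / dy) + 1
    pts = []
    for j in range(-rows, rows + 1):
        y = j * dy
        xoff = 0.5 * spacing if j % 2 else 0.0
        half = int((well_radius + spacing) / spacing) + 1
        for i in range(-half, half + 1):
            x = i * spacing + xoff
            if x * x + y * y <= well_radius * well_radius:
                pts.append((x, y))
    return np.asarray(pts, dtype=float)


def _resolve_overlaps(
    centers: np.ndarray,
    jitter: np.ndarray,
    radii: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Apply jitter, then cancel it for any pair it pushed too close.

    If lattice positions themselves conflict (pathological radii), the
    placement is reported infeasible.
    """
    from scipy.spatial import cKDTree

    out = centers + jitter
    r_max = float(radii.max())
    for attempt in range(2):
        tree = cKDTree(out)
        pairs = tree.query_pairs(2.0 * r_max, output_type="ndarray")
        if len(pairs) == 0:
            return out
        i, j = pairs.T
        d = np.hypot(*(out[i] - out[j]).T)
        bad = d < (1.0 - tol) * (radii[i] + radii[j])
        if not bad.any():
            return out
        culprit = np.unique(np.concatenate([i[bad], j[bad]]))
        out[culprit] = centers[culprit]
    raise RuntimeError(
        f"packing infeasible: {bad.sum()} bead pairs overlap beyond "
        f"tolerance even at lattice positions"
    )


def place_beads(
    radii: np.ndarray,
    well_radius: float,
    rng: np.random.Generator,
    *,
    packing_tolerance: float = 0.05,
    strategy: str = "auto",
    max_attempts: int = 200,
) -> np.ndarray:
    """Non-overlapping 2-D centers for discs of the given radii in a well.

    Two circles may overlap by at most ``packing_tolerance``: centers
    must be at least ``(1 - tol) * (r_i + r_j)`` apart.  Strategy
    ``"dart"`` is random sequential placement; ``"hex"`` is a jittered
    hexagonal lattice (needed at monolayer densities, where sequential
    placement jams); ``"auto"`` picks by packing fraction.  Raises if
    the requested count cannot be placed, naming the achieved count.
    """
    radii = np.asarray(radii, dtype=float)
    n = radii.size
    if n == 0:
        return np.empty((0, 2))
    density = float((radii**2).sum()) / well_radius**2
    if strategy == "auto":
        strategy = "dart" if density <= 0.40 else "hex"

    if strategy == "hex":
        r_mean = float(radii.mean())
        r_max = float(radii.max())
        min_gap = (1.0 - packing_tolerance) * 2.0  # in units of mean radius pair
        r_eff = well_radius - r_mean
        # spacing from the site budget (5% headroom), shrinking if the
        # disc boundary eats too many sites
        s = math.sqrt(math.pi * r_eff**2 / (math.sqrt(3) / 2.0 * 1.05 * n))
        sites = _hex_sites(r_eff, s)
        for _ in range(6):
            if len(sites) >= n:
                break
            s *= 0.97 * math.sqrt(len(sites) / n) if len(sites) else 0.8
            sites = _hex_sites(r_eff, s)
        if len(sites) < n:
            raise RuntimeError(
                f"hex packing infeasible: requested {n} beads, lattice holds "
                f"only {len(sites)} sites at spacing {s:.1f}"
            )
        idx = rng.choice(len(sites), size=n, replace=False)
        centers = sites[idx]
        # jitter within the slack each bead has against a large neighbour
        slack = s - (1.0 - packing_tolerance) * (radii + np.quantile(radii, 0.99))
        jmax = 0.45 * np.clip(slack, 0.0, None)
        ang = rng.uniform(0, 2 * math.pi, n)
        rad = jmax * np.sqrt(rng.uniform(0, 1, n))
        jitter = np.c_[rad * np.cos(ang), rad * np.sin(ang)]
        centers = _resolve_overlaps(centers, jitter, radii, packing_tolerance)
        return centers

    if strategy != "dart":
        raise ValueError(f"unknown placement strategy {strategy!r}")
    centers = np.empty((n, 2))
    placed = 0
    for i in range(n):
        ok = False
        for _ in range(max_attempts):
            ang = rng.uniform(0, 2 * math.pi)
            rad = (well_radius - radii[i]) * math.sqrt(rng.uniform(0, 1))
            c = np.array([rad * math.cos(ang), rad * math.sin(ang)])
            if placed:
                d = np.hypot(*(centers[:placed] - c).T)
                if np.any(d < (1 - packing_tolerance) * (radii[:placed] + radii[i])):
                    continue
            centers[i] = c
            placed += 1
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"dart-throwing packing infeasible after {max_attempts} attempts "
                f"per bead: placed {placed} of {n}"
            )
    return centers


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_field(
    centers: np.ndarray,
    radii: np.ndarray,
    peaks: np.ndarray,
    *,
    width: int,
    height: int,
    background: float,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render projected-sphere beads onto a 16-bit background image.

    Pixel (row, col) centers sit at integer coordinates; x is the
    column.  Each bead adds ``peak * sqrt(1 - (d/R)^2)`` inside d < R.
    """
    img = np.full((height, width), float(background))
    centers = np.atleast_2d(np.asarray(centers, dtype=float)) if len(centers) else np.empty((0, 2))
    for (cx, cy), r, a in zip(centers, np.ravel(radii), np.ravel(peaks)):
        x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, width)
        y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, height)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = d2 < r * r
        img[y0:y1, x0:x1][mask] += a * np.sqrt(1.0 - d2[mask] / (r * r))
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        img += rng.normal(0.0, noise_sd, size=img.shape)
    clipped = (img < 0) | (img > _U16_MAX)
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} pixels clipped to the 16-bit range",
            stacklevel=2,
        )
        img = np.clip(img, 0, _U16_MAX)
    return np.round(img).astype(np.uint16)


def render_well_image(
    pop: BeadPopulationSpec,
    img: ImageSpec,
    lam: float,
    seed: int,
    *,
    packing_tolerance: float = 0.05,
    placement: str = "auto",
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """One synthetic well: (marker image, detection image, ground truth).

    Targets are Poisson(lam) per bead; a bead with >= 1 target is
    PCR-positive and bright in the detection channel.  A fraction
    ``img.artifact_rate`` of spurious small bright blobs is added to
    both channels and recorded in the truth as artifacts.
    """
    rng = np.random.default_rng(seed)
    n = pop.n_beads
    diam_um = sample_diameters(pop, rng)
    radii_px = diam_um / 2.0 / img.pixel_size_um
    centers = place_beads(
        radii_px,
        img.well_radius,
        rng,
        packing_tolerance=packing_tolerance,
        strategy=placement,
    )
    # shift well center into image coordinates
    centers = centers + np.array([img.width / 2.0, img.height / 2.0])

    targets = rng.poisson(lam, size=n) if lam > 0 else np.zeros(n, dtype=int)
    positive = targets >= 1
    marker_peaks = rng.normal(
        img.marker_intensity, img.marker_cv * img.marker_intensity, size=n
    )
    detect_peaks = np.where(
        positive,
        rng.normal(img.positive_intensity, img.positive_sd, size=n),
        rng.normal(img.negative_intensity, img.negative_sd, size=n),
    )
    detect_peaks = np.maximum(detect_peaks, 0.0)

    n_art = rng.poisson(img.artifact_rate * n) if img.artifact_rate > 0 else 0
    if n_art:
        ang = rng.uniform(0, 2 * math.pi, n_art)
        rad = img.well_radius * np.sqrt(rng.uniform(0, 1, n_art))
        art_centers = np.c_[rad * np.cos(ang), rad * np.sin(ang)] + np.array(
            [img.width / 2.0, img.height / 2.0]
        )
        art_radii = rng.uniform(0.6, 1.6, n_art)
        art_peaks = rng.normal(img.artifact_intensity, 0.1 * img.artifact_intensity, n_art)
        all_centers = np.vstack([centers, art_centers]) if n else art_centers
        all_radii = np.concatenate([radii_px, art_radii])
        all_marker = np.concatenate([marker_peaks, art_peaks])
        all_detect = np.concatenate([detect_peaks, art_peaks])
    else:
        all_centers, all_radii = centers, radii_px
        all_marker, all_detect = marker_peaks, detect_peaks

    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    marker_img = render_field(
        all_centers, all_radii, all_marker,
        width=img.width, height=img.height,
        background=img.background_level, noise_sd=img.noise_sd, rng=noise_rng,
    )
    detect_img = render_field(
        all_centers, all_radii, all_detect,
        width=img.width, height=img.height,
        background=img.background_level, noise_sd=img.noise_sd, rng=noise_rng,
    )

    if n:
        r = radii_px
        edge = (
            (centers[:, 0] - r < 0)
            | (centers[:, 1] - r < 0)
            | (centers[:, 0] + r > img.width - 1)
            | (centers[:, 1] + r > img.height - 1)
        )
    else:
        edge = np.zeros(0, dtype=bool)
    beads = pd.DataFrame(
        {
            "bead_id": np.arange(n),
            "x_px": centers[:, 0] if n else np.array([]),
            "y_px": centers[:, 1] if n else np.array([]),
            "radius_px": radii_px,
            "diameter_um": diam_um,
            "marker_peak": marker_peaks,
            "detect_peak": detect_peaks,
            "targets": targets,
            "positive": positive,
            "edge": edge,
        }
    )
    truth = GroundTruth(beads=beads, lam=lam, n_artifacts=int(n_art))
    return marker_img, detect_img, truth


# ---------------------------------------------------------------------------
# assay tables
# ---------------------------------------------------------------------------

def simulate_kinetics_assay(
    q_max: float,
    k_d: float,
    k_a: float,
    c0: float,
    n_beads: int,
    volume_ul: float,
    times_s: np.ndarray,
    noise_sd: float,
    seed: int,
    *,
    noise_rel: float = 0.0,
    n_replicates: int = 1,
    absorbance: bool = False,
) -> pd.DataFrame:
    """Supernatant time course of a bead-binding kinetics experiment.

    The bound-DNA trajectory follows the depleting Langmuir kinetics
    model with capacity ``b_max = n_beads * q_max / volume``; the
    supernatant concentration is ``C_0 - b_t`` by mass balance.  Noise
    on the measured supernatant is additive Gaussian (``noise_sd``,
    ng/uL) and/or proportional (``noise_rel``, photometric-style);
    ``n_replicates`` independent measurements are taken per time point.
    ``k_d`` is recorded in the table attributes for downstream
    equilibrium checks (the kinetic model itself neglects desorption,
    appropriate for K_D far below C_0).  Columns: t_s,
    supernatant_ng_ul, bound_ng_ul (true), and a260 if requested
    (1 absorbance unit = 50 ng/uL dsDNA).
    """
    times = np.asarray(times_s, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted ascending")
    if min(q_max, k_d, k_a, c0) < 0 or n_beads < 0 or volume_ul <= 0:
        raise ValueError("rates and concentrations must be >= 0")
    if noise_sd < 0 or noise_rel < 0:
        raise ValueError("noise levels must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    b_max = n_beads * q_max / volume_ul
    bound = np.asarray(binding.kinetics(times, k_a, b_max, c0), dtype=float)
    rng = np.random.default_rng(seed)
    t_rep = np.repeat(times, n_replicates)
    sup = np.repeat(c0 - bound, n_replicates)
    bound = np.repeat(bound, n_replicates)
    if noise_rel > 0:
        sup = sup * (1.0 + rng.normal(0.0, noise_rel, size=sup.size))
    if noise_sd > 0:
        sup = sup + rng.normal(0.0, noise_sd, size=sup.size)
    df = pd.DataFrame({"t_s": t_rep, "supernatant_ng_ul": sup, "bound_ng_ul": bound})
    if absorbance:
        df["a260"] = df["supernatant_ng_ul"] / binding.DSDNA_NG_PER_UL_PER_A260
    df.attrs.update(
        dict(q_max=q_max, k_d=k_d, k_a=k_a, c0=c0, n_beads=n_beads,
             volume_ul=volume_ul, b_max=b_max, noise_sd=noise_sd, seed=seed)
    )
    return df


def simulate_isotherm_assay(
    q_max: float,
    k_d: float,
    input_concs_ng_ul: np.ndarray,
    n_beads: int,
    volume_ul: float,
    noise_rel: float,
    seed: int,
    *,
    n_replicates: int = 1,
) -> binding.IsothermData:
    """Equilibrium isotherm table from an input-concentration ladder.

    For each input concentration the Langmuir equilibrium mass balance
    is solved exactly; each of ``n_replicates`` measured free
    concentrations gets multiplicative Gaussian noise of relative size
    ``noise_rel``, and bound amounts are derived per bead from the
    (noisy) free value by mass balance, as in a supernatant-depletion
    experiment.
    """
    inputs = np.asarray(input_concs_ng_ul, dtype=float)
    if np.any(inputs <= 0):
        raise ValueError("input concentrations must be positive")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    free = np.empty_like(inputs)
    for i, c in enumerate(inputs):
        frac = binding.capture_fraction(q_max, k_d, n_beads, c * volume_ul, volume_ul)
        free[i] = c * (1.0 - frac)
    inputs = np.repeat(inputs, n_replicates)
    free = np.repeat(free, n_replicates)
    if noise_rel > 0:
        free = free * (1.0 + rng.normal(0.0, noise_rel, size=free.size))
        free = np.clip(free, 0.0, inputs)
    bound_per_bead = (inputs - free) * volume_ul / n_beads
    return binding.IsothermData(
        free=free,
        bound=bound_per_bead,
        n_beads=n_beads,
        volume_ul=volume_ul,
        input_concentrations=inputs,
    )


def simulate_paired_measurements(
    true_concs: np.ndarray,
    bias_log10: float,
    sd_x: float,
    sd_y: float,
    seed: int,
    *,
    levels: list[str] | None = None,
) -> pd.DataFrame:
    """Paired two-method measurements as log-normal perturbations of truth.

    Method x measures ``10**(log10(c) + N(0, sd_x))``; method y adds a
    constant ``bias_log10`` offset on top of its own noise.  Columns:
    level, truth, method_x, method_y.
    """
    c = np.asarray(true_concs, dtype=float)
    if np.any(c <= 0):
        raise ValueError("true concentrations must be positive")
    if sd_x < 0 or sd_y < 0:
        raise ValueError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    lx = np.log10(c) + (rng.normal(0, sd_x, c.size) if sd_x > 0 else 0.0)
    ly = np.log10(c) + bias_log10 + (rng.normal(0, sd_y, c.size) if sd_y > 0 else 0.0)
    return pd.DataFrame(
        {
            "level": levels if levels is not None else [f"L{i+1}" for i in range(c.size)],
            "truth": c,
            "method_x": 10.0**lx,
            "method_y": 10.0**ly,
        }
    )


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_well(
    outdir: str | Path,
    well_id: str,
    marker_img: np.ndarray,
    detect_img: np.ndarray,
    truth: GroundTruth,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write TIFF channels, ground-truth CSV, and a JSON manifest."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "marker": outdir / f"{well_id}_marker.tif",
        "detect": outdir / f"{well_id}_detect.tif",
        "truth": outdir / f"{well_id}_truth.csv",
        "manifest": outdir / f"{well_id}_manifest.json",
    }
    tifffile.imwrite(paths["marker"], marker_img)
    tifffile.imwrite(paths["detect"], detect_img)
    truth.beads.to_csv(paths["truth"], index=False)
    meta = {
        "well_id": well_id,
        "lam": truth.lam,
        "n_beads": truth.n_beads,
        "n_positive": truth.n_positive,
        "n_artifacts": truth.n_artifacts,
    }
    if manifest:
        meta.update(manifest)
    paths["manifest"].write_text(json.dumps(meta, indent=2))
    return paths
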