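"""Poisson quantification for bead-partitioned digital PCR.

Turns per-bead endpoint fluorescence intensities into a target
concentration: decide whether the intensity distribution is unimodal or
bimodal (Gaussian mixtures compared by BIC), place a threshold at the
density minimum between the two modes, count PCR-negative beads, and
convert the negative fraction into the mean number of targets per bead
(lambda) and a sample concentration.

Two concentration calculators are provided.  The conventional droplet
formula needs the compartment volume ``V_C`` and dilution factor ``D``:

    C_s = (-ln(N_neg / N) / V_C) * D

The bead-count formula needs no volume at all — only the number of beads
``N_B`` incubated with the sample and the sample volume ``V_S``:

    c_S = lambda * N_B / V_S

because random partitioning is achieved by *binding* targets to a known
number of beads rather than by splitting a known volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

__all__ = [
    "StudyDesign",
    "WellIntensitySet",
    "ThresholdResult",
    "QuantResult",
    "select_modality",
    "find_threshold",
    "classify_intensities",
    "poisson_lambda",
    "lambda_confidence_interval",
    "concentration_beads",
    "concentration_volume",
    "detection_stats",
    "sphere_volume",
    "per_bead_loading",
    "quantify_well",
]

#: cubic micrometres per nanolitre
_UM3_PER_NL = 1.0e6


@dataclass(frozen=True)
class StudyDesign:
    """Constants of a bead-dPCR experiment.

    Defaults are the reference study conditions: 90,400 beads incubated
    with a 16 uL sample, ~3,300 beads analysed per replicate well, 12
    replicates per dilution level; droplet-mode constants are a 0.849 nL
    compartment (117.5 um droplet) and an overall dilution factor of 5.
    """

    n_beads_incubated: int = 90_400  # N_B
    sample_volume_ul: float = 16.0  # V_S
    beads_per_replicate: int = 3_300
    n_replicates: int = 12
    compartment_volume_nl: float = 0.849  # V_C (droplet mode)
    dilution_factor: float = 5.0  # D (droplet mode)
    bead_diameter_um: float = 94.8
    bead_diameter_cv: float = 0.07

    def __post_init__(self) -> None:
        for name in (
            "n_beads_incubated",
            "sample_volume_ul",
            "beads_per_replicate",
            "n_replicates",
            "compartment_volume_nl",
            "dilution_factor",
            "bead_diameter_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"StudyDesign.{name} must be positive")
        if self.bead_diameter_cv < 0:
            raise ValueError("StudyDesign.bead_diameter_cv must be >= 0")

    @property
    def bead_volume_nl(self) -> float:
        """Mean single-bead volume from the mean diameter."""
        return sphere_volume(self.bead_diameter_um)

    @property
    def analyzed_fraction(self) -> float:
        """Fraction of incubated beads that end up being analysed."""
        return self.beads_per_replicate * self.n_replicates / self.n_beads_incubated


@dataclass
class WellIntensitySet:
    """Valid-bead detection-channel intensities for one well."""

    intensities: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def n(self) -> int:
        return int(self.intensities.size)


@dataclass
class ThresholdResult:
    """Outcome of the modality decision and threshold search."""

    modality: int  # 1 or 2; 0 = indeterminate (too few beads)
    threshold: float | None
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    bic_1: float = math.nan
    bic_2: float = math.nan
    demoted: bool = False  # 2-component BIC win rejected as spurious
    threshold_fallback: bool = False  # no interior KDE minimum; midpoint used


@dataclass
class QuantResult:
    """Lambda and concentration for one well (or pooled set of wells)."""

    n: int
    n_neg: int
    lam: float
    concentration: float
    threshold: float | None = None
    flags: dict = field(default_factory=dict)
    lam_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lam_ci"] = list(self.lam_ci) if self.lam_ci is not None else None
        return d


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def select_modality(
    intensities: np.ndarray,
    *,
    min_n: int = 10,
    min_fraction: float | None = None,
    min_separation_sds: float = 2.0,
    n_init: int = 5,
    random_state: int = 0,
) -> ThresholdResult:
    """Decide between a unimodal and a bimodal intensity distribution.

    One- and two-component Gaussian mixtures are fitted by EM (k-means
    initialisation, ``n_init`` restarts) and compared by BIC; the lower
    BIC wins.  A two-component win is demoted to unimodal when either
    component weight falls below ``min_fraction`` (default ``5/n``) or the
    means are closer than ``min_separation_sds`` pooled standard
    deviations — both signal a spurious split of a single mode.
    """
    x = np.asarray(intensities, dtype=float).reshape(-1, 1)
    n = x.shape[0]
    if n < min_n:
        return ThresholdResult(
            modality=0, threshold=None, means=(), sds=(), weights=()
        )
    if np.ptp(x) == 0.0:
        # all identical: degenerate, trivially unimodal
        mu = float(x[0, 0])
        return ThresholdResult(1, None, (mu,), (0.0,), (1.0,))

    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            init_params="kmeans",
            random_state=random_state,
            reg_covar=1e-10 * float(np.var(x)) + 1e-12,
        )
        gm.fit(x)
        fits[k] = gm
    bic = {k: float(gm.bic(x)) for k, gm in fits.items()}

    modality = 2 if bic[2] < bic[1] else 1
    demoted = False
    if modality == 2:
        gm = fits[2]
        w = gm.weights_.ravel()
        mu = gm.means_.ravel()
        sd = np.sqrt(gm.covariances_.reshape(-1))
        min_frac = 5.0 / n if min_fraction is None else min_fraction
        pooled_sd = math.sqrt(float(w @ sd**2))
        if w.min() < min_frac or abs(mu[1] - mu[0]) < min_separation_sds * pooled_sd:
            modality = 1
            demoted = True

    gm = fits[modality]
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(s) for s in np.sqrt(gm.covariances_.reshape(-1))[order])
    weights = tuple(float(w) for w in gm.weights_.ravel()[order])
    res = ThresholdResult(
        modality=modality,
        threshold=None,
        means=means,
        sds=sds,
        weights=weights,
        bic_1=bic[1],
        bic_2=bic[2],
        demoted=demoted,
    )
    if modality == 2:
        find_threshold(intensities, res)
    return res


def find_threshold(
    intensities: np.ndarray,
    modality_result: ThresholdResult,
    *,
    grid_size: int = 512,
) -> float:
    """Place the positive/negative threshold between the two modes.

    A Gaussian kernel density estimate (Silverman bandwidth) is evaluated
    on a ``grid_size``-point grid restricted to the interval between the
    two component means; the threshold is the grid argmin of the density
    (ties broken toward lower intensity).  If the density has no interior
    minimum the midpoint of the means is used and flagged.
    """
    if modality_result.modality != 2:
        raise ValueError("threshold requires a bimodal intensity distribution")
    mu1, mu2 = modality_result.means
    if not mu1 < mu2:
        raise ValueError("degenerate component means")
    x = np.asarray(intensities, dtype=float).ravel()
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(mu1, mu2, grid_size)
    dens = kde(grid)
    i = int(np.argmin(dens))  # np.argmin returns the first (lowest) tie
    if i == 0 or i == grid_size - 1:
        modality_result.threshold = float(0.5 * (mu1 + mu2))
        modality_result.threshold_fallback = True
    else:
        modality_result.threshold = float(grid[i])
        modality_result.threshold_fallback = False
    return modality_result.threshold


def classify_intensities(intensities: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean positive/negative calls: intensity > threshold is positive."""
    return np.asarray(intensities, dtype=float) > threshold


# ---------------------------------------------------------------------------
# Poisson statistics
# ---------------------------------------------------------------------------

def poisson_lambda(n_neg: int, n: int) -> float:
    """Mean targets per bead from the negative fraction, ``-ln(N_neg/N)``.

    ``n_neg == 0`` (no negative bead) admits no finite estimate and
    returns ``inf``; callers flag the well as above-range.
    """
    if n < 1:
        raise ValueError("need at least one bead")
    if not 0 <= n_neg <= n:
        raise ValueError(f"n_neg={n_neg} outside [0, {n}]")
    if n_neg == 0:
        return math.inf
    return -math.log(n_neg / n)


def lambda_confidence_interval(
    n_neg: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson-interval CI on the negative fraction propagated through -ln.

    Auxiliary plumbing (off by default in pipeline output): the Wilson
    score interval for ``p = N_neg/N`` is mapped through ``-ln p``.
    """
    from scipy.stats import norm

    if not 0 <= n_neg <= n or n < 1:
        raise ValueError("invalid counts")
    z = norm.ppf(0.5 + confidence / 2.0)
    p = n_neg / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    lo_p, hi_p = max(center - half, 0.0), min(center + half, 1.0)
    lam_hi = math.inf if lo_p == 0.0 else -math.log(lo_p)
    lam_lo = 0.0 if hi_p >= 1.0 else -math.log(hi_p)
    return (lam_lo, lam_hi)


def concentration_beads(lam: float, design: StudyDesign) -> float:
    """Bead-count concentration ``c_S = lambda * N_B / V_S`` in cP/uL.

    No compartment-volume term: the count of beads incubated with the
    sample replaces the partition volume of droplet dPCR.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return lam * design.n_beads_incubated / design.sample_volume_ul


def concentration_volume(n_neg: int, n: int, design: StudyDesign) -> float:
    """Droplet-style concentration ``(-ln(N_neg/N) / V_C) * D`` in cP/uL."""
    lam = poisson_lambda(n_neg, n)
    v_c_ul = design.compartment_volume_nl * 1e-3
    if v_c_ul <= 0 or design.dilution_factor <= 0:
        raise ValueError("V_C and D must be positive")
    return lam / v_c_ul * design.dilution_factor


def detection_stats(
    concentration: float, design: StudyDesign, beads_analyzed: int
) -> tuple[float, float]:
    """Expected targets per replicate and the Poisson detection bound.

    With only ``beads_analyzed`` of the ``N_B`` incubated beads imaged,
    the expected target count per replicate is
    ``conc * V_S * beads_analyzed / N_B`` and the probability that a
    replicate holds at least one target — the best achievable detection
    rate — is ``1 - exp(-expected)``.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if beads_analyzed > design.n_beads_incubated:
        raise ValueError("cannot analyse more beads than were incubated")
    expected = (
        concentration
        * design.sample_volume_ul
        * beads_analyzed
        / design.n_beads_incubated
    )
    return expected, 1.0 - math.exp(-expected)


def sphere_volume(diameter_um: float) -> float:
    """Volume of a sphere of the given diameter, in nanolitres."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return math.pi / 6.0 * diameter_um**3 / _UM3_PER_NL


def per_bead_loading(input_ng: float, n_beads: int) -> float:
    """DNA mass offered per bead (ng/bead)."""
    if n_beads <= 0:
        raise ValueError("n_beads must be positive")
    if input_ng < 0:
        raise ValueError("input mass must be >= 0")
    return input_ng / n_beads


# ---------------------------------------------------------------------------
# per-well driver
# ---------------------------------------------------------------------------

def quantify_well(
    well: WellIntensitySet,
    design: StudyDesign,
    *,
    positive_control_intensity: float | None = None,
    with_ci: bool = False,
    random_state: int = 0,
) -> QuantResult:
    """Full per-well quantification: modality, threshold, lambda, c_S.

    A unimodal well is called all-negative if its mean lies below
    ``positive_control_intensity``, all-positive above it, and
    indeterminate when no control intensity is configured.  All-positive
    wells carry no finite estimate and are flagged above-range.
    """
    n = well.n
    flags: dict = {}
    tr = select_modality(well.intensities, random_state=random_state)
    if tr.modality == 0:
        flags["indeterminate"] = True
        return QuantResult(n, 0, math.nan, math.nan, None, flags)

    if tr.modality == 1:
        mean = tr.means[0]
        if positive_control_intensity is None:
            flags["indeterminate"] = True
            return QuantResult(n, 0, math.nan, math.nan, None, flags)
        if mean >= positive_control_intensity:
            flags["all_positive"] = True
            flags["above_range"] = True
            return QuantResult(n, 0, math.inf, math.inf, None, flags)
        flags["all_negative"] = True
        res = QuantResult(n, n, 0.0, 0.0, None, flags)
        if with_ci:
            res.lam_ci = lambda_confidence_interval(n, n)
        return res

    thr = tr.threshold
    if tr.threshold_fallback:
        flags["threshold_fallback"] = True
    positive = classify_intensities(well.intensities, thr)
    n_neg = int(n - positive.sum())
    if n_neg == 0:
        flags["all_positive"] = True
        flags["above_range"] = True
        return QuantResult(n, 0, math.inf, math.inf, thr, flags)
    lam = poisson_lambda(n_neg, n)
    if n_neg == n:
        flags["all_negative"] = True
    conc = concentration_beads(lam, design)
    res = QuantResult(n, n_neg, lam, conc, thr, flags)
    if with_ci:
        res.lam_ci = lambda_confidence_interval(n_neg, n)
    return res
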