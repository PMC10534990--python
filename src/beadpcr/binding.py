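"""Langmuir adsorption models for DNA-binding nanoreactor beads.

The beads present a saturable charge-mediated binding surface.  Two
models describe it:

*Equilibrium isotherm* — bound amount per bead as a function of the free
solution concentration,

    [DNA]_b = q_max * [DNA]_s / (K_D + [DNA]_s)

with capacity ``q_max`` (ng/bead) and dissociation constant ``K_D``
(ng/uL; divide by 1000 for ug/uL).

*Adsorption kinetics* — bound concentration over time for a closed
system that starts fully unbound.  Binding depletes both the free DNA
and the remaining surface sites, giving the bimolecular rate law

    db/dt = (k_a / b_max) * (C_0 - b) * (b_max - b),   b(0) = 0

whose closed form is implemented in :func:`kinetics`.  ``k_a`` (1/s) is
the pseudo-first-order adsorption rate in the dilute limit
``C_0 << b_max``; the trajectory rises monotonically to
``min(C_0, b_max)``, i.e. it never exceeds either the surface capacity
or the mass available.

Fitting is nonlinear least squares with multi-start initial guesses;
95% confidence intervals come from a seeded nonparametric bootstrap over
rows (default) or from the asymptotic Jacobian covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "IsothermData",
    "KineticsData",
    "LangmuirFit",
    "isotherm",
    "kinetics",
    "fit_isotherm",
    "fit_kinetics",
    "capture_fraction",
    "capacity_density",
    "absorbance_to_concentration",
]

#: ng/uL of dsDNA per unit of absorbance at 260 nm
DSDNA_NG_PER_UL_PER_A260 = 50.0


@dataclass
class IsothermData:
    """Equilibrium rows of (free concentration ng/uL, bound ng/bead)."""

    free: np.ndarray
    bound: np.ndarray
    n_beads: int | None = None
    volume_ul: float | None = None
    input_concentrations: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.free = np.asarray(self.free, dtype=float).ravel()
        self.bound = np.asarray(self.bound, dtype=float).ravel()
        if self.free.shape != self.bound.shape:
            raise ValueError("free and bound must have equal length")
        if np.any(self.free < 0) or np.any(self.bound < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class KineticsData:
    """Time-course rows of (t seconds, bound concentration ng/uL)."""

    t: np.ndarray
    bound: np.ndarray
    c0: float = math.nan
    n_beads: int | None = None
    volume_ul: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float).ravel()
        self.bound = np.asarray(self.bound, dtype=float).ravel()
        if self.t.shape != self.bound.shape:
            raise ValueError("t and bound must have equal length")
        if np.any(self.t < 0):
            raise ValueError("times must be >= 0")
        order = np.argsort(self.t, kind="stable")  # fits are order-invariant
        self.t, self.bound = self.t[order], self.bound[order]


@dataclass
class LangmuirFit:
    """Fit result: point estimates, 95% CIs, residuals, convergence."""

    params: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    residuals: np.ndarray
    rss: float
    converged: bool
    n_obs: int
    ci_method: str = "bootstrap"
    message: str = ""
    fixed: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = []
        for k, v in self.params.items():
            lo, hi = self.ci95.get(k, (math.nan, math.nan))
            lines.append(f"{k} = {v:.4g} (95% CI {lo:.4g}-{hi:.4g})")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def isotherm(free_conc, q_max: float, k_d: float):
    """Langmuir isotherm: bound per bead at the given free concentration.

    The degenerate point ``K_D = free = 0`` is defined as the saturation
    limit ``q_max``.
    """
    free = np.asarray(free_conc, dtype=float)
    if q_max < 0 or k_d < 0 or np.any(free < 0):
        raise ValueError("isotherm arguments must be >= 0")
    denom = k_d + free
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, q_max * free / np.where(denom > 0, denom, 1.0), q_max)
    return out if out.ndim else float(out)


def kinetics(t, k_a: float, b_max: float, c0: float):
    """Bound DNA concentration at time ``t`` under depleting Langmuir kinetics.

    Closed form of ``db/dt = (k_a/b_max)(C_0 - b)(b_max - b)``:

        b(t) = C_0 * b_max * (E - 1) / (b_max * E - C_0),
        E = exp(k_a * (1 - C_0/b_max) * t)

    with the continuous limit ``b = b_max * k_a t / (1 + k_a t)`` when
    ``C_0 = b_max``.  Starts at 0 and rises monotonically to
    ``min(C_0, b_max)``.
    """
    t = np.asarray(t, dtype=float)
    if k_a < 0 or b_max < 0 or c0 < 0:
        raise ValueError("kinetics parameters must be >= 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if b_max == 0 or c0 == 0:
        out = np.zeros_like(t)
        return out if out.ndim else float(out)
    rel = abs(c0 - b_max) / b_max
    if rel < 1e-9:
        out = b_max * k_a * t / (1.0 + k_a * t)
        return out if out.ndim else float(out)
    r = k_a * (1.0 - c0 / b_max)
    # numerically safe for either sign of r: factor exp to avoid overflow
    with np.errstate(over="ignore"):
        if r >= 0:
            em = np.exp(-r * t)  # <= 1
            out = c0 * b_max * (1.0 - em) / (b_max - c0 * em)
        else:
            ep = np.exp(r * t)  # E itself, <= 1 since r < 0
            out = c0 * b_max * (ep - 1.0) / (b_max * ep - c0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _nls(model, x, y, starts, bounds):
    """Multi-start trust-region least squares; best RSS wins."""
    best = None
    for p0 in starts:
        try:
            res = optimize.least_squares(
                lambda p: model(x, *p) - y,
                p0,
                bounds=bounds,
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    return best


def _ci_bootstrap(model, x, y, popt, starts, bounds, n_boot, rng):
    # resample fits start from the full-data optimum; the surface is
    # unimodal in the neighbourhood so multi-start is not repeated
    n = len(x)
    draws = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        res = _nls(model, x[idx], y[idx], [popt], bounds)
        if res is None:
            res = _nls(model, x[idx], y[idx], list(starts), bounds)
        if res is not None:
            draws.append(res.x)
    draws = np.asarray(draws)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    return lo, hi


def _ci_asymptotic(res, n_obs):
    """Jacobian-based 95% intervals from the linearised covariance."""
    from scipy.stats import t as tdist

    _, s, vt = np.linalg.svd(res.jac, full_matrices=False)
    s = s[s > np.finfo(float).eps * max(res.jac.shape) * s[0]]
    vt = vt[: s.size]
    cov = vt.T / s**2 @ vt
    dof = max(n_obs - len(res.x), 1)
    sigma2 = 2 * res.cost / dof
    se = np.sqrt(np.diag(cov) * sigma2)
    q = tdist.ppf(0.975, dof)
    return res.x - q * se, res.x + q * se


def fit_isotherm(
    data: IsothermData,
    *,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> LangmuirFit:
    """Least-squares Langmuir isotherm fit for ``q_max`` and ``K_D``.

    Initial guesses: ``q_max`` from the largest observed bound amount,
    ``K_D`` from the free concentration nearest half of it, plus coarse
    multi-start perturbations.  Requires at least three distinct free
    concentrations.
    """
    free, bound = data.free, data.bound
    if np.unique(free).size < 3:
        raise ValueError("need >= 3 distinct free concentrations")
    q0 = float(bound.max()) or 1.0
    half = 0.5 * q0
    k0 = float(free[np.argmin(np.abs(bound - half))]) or float(np.median(free[free > 0]) or 1.0)
    starts = [
        (q0, k0),
        (q0 * 1.5, k0 * 0.2),
        (q0 * 1.1, k0 * 5.0),
        (q0 * 3.0, k0),
    ]
    bounds = ([0.0, 0.0], [np.inf, np.inf])
    res = _nls(isotherm, free, bound, starts, bounds)
    if res is None:
        raise RuntimeError(
            f"isotherm fit failed to converge from {len(starts)} starts "
            f"(n={free.size}, q0={q0:.3g}, k0={k0:.3g})"
        )
    names = ("q_max", "K_D")
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        lo, hi = _ci_bootstrap(isotherm, free, bound, res.x, starts, bounds, n_boot, rng)
    else:
        lo, hi = _ci_asymptotic(res, free.size)
    return LangmuirFit(
        params=dict(zip(names, map(float, res.x))),
        ci95={n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)},
        residuals=res.fun,
        rss=float(2 * res.cost),
        converged=True,
        n_obs=int(free.size),
        ci_method=ci_method,
        message=res.message,
    )


def fit_kinetics(
    data: KineticsData,
    *,
    b_max: float | None = None,
    ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
) -> LangmuirFit:
    """Least-squares kinetics fit for ``k_a`` (and ``b_max`` unless fixed).

    Pass ``b_max`` to pin the capacity at the isotherm's ``q_max``
    (converted to a concentration); otherwise it is refit jointly.
    A flat all-zero trajectory yields ``k_a = 0`` rather than a spurious
    positive rate.
    """
    t, y = data.t, data.bound
    if t.size < 4:
        raise ValueError("need >= 4 time points")
    if math.isnan(data.c0):
        raise ValueError("KineticsData.c0 (initial free concentration) required")
    c0 = data.c0
    if np.all(y == 0):
        names = ("k_a",) if b_max is not None else ("k_a", "b_max")
        params = {n: 0.0 for n in names}
        return LangmuirFit(
            params=params,
            ci95={n: (0.0, 0.0) for n in names},
            residuals=np.zeros_like(y),
            rss=0.0,
            converged=True,
            n_obs=int(t.size),
            ci_method=ci_method,
            message="degenerate all-zero trajectory",
            fixed={"b_max": b_max} if b_max is not None else {},
        )
    # crude rate guess from the earliest sizeable rise
    asym = float(y.max())
    k_guess = 0.1
    rising = np.nonzero((y > 0.3 * asym) & (t > 0))[0]
    if rising.size:
        frac = min(y[rising[0]] / asym, 0.95)
        k_guess = max(-math.log(1 - frac) / t[rising[0]], 1e-4)

    if b_max is not None:
        model = lambda tt, ka: kinetics(tt, ka, b_max, c0)
        starts = [(k_guess,), (k_guess * 0.1,), (k_guess * 10,)]
        bounds = ([0.0], [np.inf])
        names = ("k_a",)
    else:
        bmax_guess = max(asym, 1e-6)
        if asym >= 0.98 * c0:
            bmax_guess = 2.0 * c0  # capacity not limiting; weakly identified
        model = lambda tt, ka, bm: kinetics(tt, ka, bm, c0)
        starts = [
            (k_guess, bmax_guess),
            (k_guess * 0.2, bmax_guess * 3),
            (k_guess * 5, bmax_guess),
            (k_guess, bmax_guess * 10),
        ]
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        names = ("k_a", "b_max")
    res = _nls(model, t, y, starts, bounds)
    if res is None:
        raise RuntimeError(
            f"kinetics fit failed to converge (n={t.size}, c0={c0:.3g})"
        )
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        lo, hi = _ci_bootstrap(model, t, y, res.x, starts, bounds, n_boot, rng)
    else:
        lo, hi = _ci_asymptotic(res, t.size)
    return LangmuirFit(
        params=dict(zip(names, map(float, res.x))),
        ci95={n: (float(l), float(h)) for n, l, h in zip(names, lo, hi)},
        residuals=res.fun,
        rss=float(2 * res.cost),
        converged=True,
        n_obs=int(t.size),
        ci_method=ci_method,
        message=res.message,
        fixed={"b_max": b_max} if b_max is not None else {},
    )


# ---------------------------------------------------------------------------
# equilibrium predictions
# ---------------------------------------------------------------------------

def capture_fraction(
    q_max: float,
    k_d: float,
    n_beads: int,
    input_mass_ng: float,
    volume_ul: float,
    *,
    rtol: float = 1e-10,
) -> float:
    """Predicted fraction of input DNA bound to beads at equilibrium.

    Solves the mass balance

        free * V + N * q_max * free / (K_D + free) = input

    for the free concentration by a bracketed root find on
    ``[0, input/V]`` and returns ``1 - free*V/input``.  ``q_max`` in
    ng/bead, ``K_D`` in ng/uL, volume in uL.
    """
    if n_beads == 0:
        return 0.0
    if min(q_max, k_d, input_mass_ng, volume_ul) <= 0 or n_beads < 0:
        raise ValueError("capture_fraction arguments must be positive")

    def balance(free: float) -> float:
        return free * volume_ul + n_beads * q_max * free / (k_d + free) - input_mass_ng

    hi = input_mass_ng / volume_ul
    free = optimize.brentq(balance, 0.0, hi, rtol=rtol, maxiter=200)
    return 1.0 - free * volume_ul / input_mass_ng


def capacity_density(q_max_ng: float, bead_volume_nl: float) -> float:
    """Binding-matrix capacity as a density, mg DNA per mL of bead.

    ng/bead over nL/bead; ng/nL equals mg/mL numerically.
    """
    if q_max_ng <= 0 or bead_volume_nl <= 0:
        raise ValueError("inputs must be positive")
    return q_max_ng / bead_volume_nl


def absorbance_to_concentration(a260) -> np.ndarray | float:
    """dsDNA concentration (ng/uL) from absorbance at 260 nm."""
    a = np.asarray(a260, dtype=float)
    out = a * DSDNA_NG_PER_UL_PER_A260
    return out if out.ndim else float(out)
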