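"""Angle extraction and axial circular statistics.

Orientation angles here are *axial*: the experimental geometry constrains
meaningful headings to half the circle, so angles are analysed modulo
180 deg by the standard doubling device (double to [0, 360), apply
ordinary circular statistics, halve back).

Two angles are extracted per trajectory:

* the **first straight angle** — the heading of the initial straight
  displacement out of the chamber, built by accreting successive 1-s
  segments while each deviates by no more than 10 deg from the previous
  segment;
* the **start-end angle** — the chord from the first point out of the
  chamber to the last point before the turn-back.

Both use the same two-branch arccosine formula (equivalent to atan2 in
the y-down frame; the branch at y_end == y_1 resolves to the first
branch, its continuous limit).

Orientation samples are screened with a Rayleigh uniformity test and fit
with the classical ten-model nested family of von Mises mixtures
(uniform / unimodal / axial-bimodal / general-bimodal variants), ranked
by AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import i0e, logsumexp
from scipy.stats import chi2

from .errors import (
    ContractError,
    DegenerateAngleError,
    InsufficientSampleError,
    UndefinedMeanError,
)
from .trajectory import Trajectory, _angdiff

TWO_PI = 2.0 * math.pi


def branch_angle(p_start: Sequence[float], p_end: Sequence[float]) -> float:
    """Heading from ``p_start`` to ``p_end`` in degrees [0, 360).

    Implements the two-branch arccosine construction: with
    r = ||p_end - p_start||,

    * y_end > y_1:  theta = arccos(-(x_1 - x_end) / r)
    * y_1 > y_end:  theta = 360 - arccos(-(x_1 - x_end) / r)
    * y_end == y_1: first branch (continuous limit).
    """
    x1, y1 = float(p_start[0]), float(p_start[1])
    xe, ye = float(p_end[0]), float(p_end[1])
    r = math.hypot(x1 - xe, y1 - ye)
    if r < 1e-12:
        raise DegenerateAngleError("coincident points have no defined heading")
    base = math.degrees(math.acos(max(-1.0, min(1.0, -(x1 - xe) / r))))
    if y1 > ye:
        return (360.0 - base) % 360.0
    return base % 360.0


def fold_axial(theta_deg: float | np.ndarray) -> float | np.ndarray:
    """Fold an angle to the axial domain [0, 180)."""
    return np.asarray(theta_deg) % 180.0 if np.ndim(theta_deg) else theta_deg % 180.0


@dataclass(frozen=True)
class AngleResult:
    """An extracted trajectory angle with its axial fold."""

    theta_deg: float
    axial_deg: float
    end_index: int  # sample index of the segment endpoint used


def first_straight_angle(traj: Trajectory, max_dev_deg: float = 10.0) -> AngleResult:
    """Heading of the first straight displacement out of the chamber.

    Segments are accreted from the first sample while each segment's
    heading deviates by at most ``max_dev_deg`` from the *previous*
    segment's heading; the angle is then taken from the first sample to
    the accreted endpoint.
    """
    xy = traj.xy
    if traj.n_samples < 2:
        raise DegenerateAngleError(f"trial {traj.trial_id}: need at least 2 samples")
    steps = np.diff(xy, axis=0)
    lengths = np.linalg.norm(steps, axis=1)
    if lengths[0] < 1e-12:
        raise DegenerateAngleError(
            f"trial {traj.trial_id}: zero displacement over the first segment"
        )
    headings = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    end = 1
    for j in range(1, steps.shape[0]):
        if lengths[j] < 1e-12 or _angdiff(headings[j], headings[j - 1]) > max_dev_deg:
            break
        end = j + 1
    theta = branch_angle(xy[0], xy[end])
    return AngleResult(theta, fold_axial(theta), end)


def angle_start_end(traj: Trajectory) -> AngleResult:
    """Chord angle from the first to the last sample of a cropped path."""
    theta = branch_angle(traj.xy[0], traj.xy[-1])
    return AngleResult(theta, fold_axial(theta), traj.n_samples - 1)


def circular_mean_axial(angles_deg: Sequence[float]) -> float:
    """Mean direction of an axial sample, in degrees [0, 180).

    Angles are doubled onto the full circle, vector-averaged, and halved
    back.  A perfectly balanced sample (zero resultant) has no defined
    mean.
    """
    a = np.radians(2.0 * np.asarray(angles_deg, float))
    if a.size == 0:
        raise ContractError("empty angular sample")
    C, S = np.mean(np.cos(a)), np.mean(np.sin(a))
    if math.hypot(C, S) < 1e-12:
        raise UndefinedMeanError("axial sample is perfectly balanced; mean undefined")
    return (math.degrees(math.atan2(S, C)) % 360.0) / 2.0


def resultant_length_axial(angles_deg: Sequence[float]) -> float:
    """Mean resultant length R-bar of the doubled sample, in [0, 1]."""
    a = np.radians(2.0 * np.asarray(angles_deg, float))
    return float(np.hypot(np.mean(np.cos(a)), np.mean(np.sin(a))))


@dataclass(frozen=True)
class RayleighResult:
    rbar: float
    z: float
    p: float
    n: int


def rayleigh_test_axial(angles_deg: Sequence[float]) -> RayleighResult:
    """Rayleigh uniformity test on doubled (axial) angles.

    Uses the standard series approximation to the null distribution of
    Z = n * R-bar^2 (accurate already for small n).
    """
    a = np.asarray(angles_deg, float)
    n = a.size
    if n < 3:
        raise InsufficientSampleError("Rayleigh test needs n >= 3")
    rbar = resultant_length_axial(a)
    z = n * rbar**2
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    return RayleighResult(float(rbar), float(z), float(min(max(p, 0.0), 1.0)), n)


# --------------------------------------------------------------------------
# Ten-model von Mises mixture family (axial data, fitted on doubled angles)
# --------------------------------------------------------------------------

#: model id -> free parameter names; expansion to (mu1, k1, mu2, k2, lam).
#: mu in radians on the doubled circle; lam is the weight of mode 1.
#: Identifiability constraints: mode 1 is the major component
#: (lam >= 0.5) and the minor mode is no sharper than the major one
#: (k2 = r2 * k1 with r2 in [0, 1]); without them tiny-weight,
#: high-concentration spike components let rich members absorb local
#: clumps of points and win the AIC ranking spuriously.
_FAMILY: dict[str, dict] = {
    "M1": {"free": (), "desc": "uniform"},
    "M2A": {"free": ("mu1", "k1"), "desc": "unimodal"},
    "M2B": {"free": ("mu1", "k1", "lam"), "desc": "unimodal + uniform"},
    "M2C": {"free": ("mu1", "k1", "r2", "lam"), "desc": "two concentrations, one direction"},
    "M3A": {"free": ("mu1", "k1"), "desc": "homogeneous axial bimodal"},
    "M3B": {"free": ("mu1", "k1", "lam"), "desc": "axial bimodal"},
    "M4A": {"free": ("mu1", "k1", "r2"), "desc": "homogeneous-weight axial, two concentrations"},
    "M4B": {"free": ("mu1", "k1", "r2", "lam"), "desc": "axial, two concentrations"},
    "M5A": {"free": ("mu1", "mu2", "k1"), "desc": "homogeneous bimodal"},
    "M5B": {"free": ("mu1", "mu2", "k1", "r2", "lam"), "desc": "bimodal"},
}

_BOUNDS = {
    "mu1": (0.0, TWO_PI),
    "mu2": (0.0, TWO_PI),
    "k1": (0.0, 200.0),
    "r2": (0.0, 1.0),
    "lam": (0.5, 1.0),
}


def _expand(model_id: str, theta: np.ndarray) -> tuple[float, float, float, float, float]:
    p = dict(zip(_FAMILY[model_id]["free"], theta))
    mu1 = p.get("mu1", 0.0)
    k1 = p.get("k1", 0.0)
    if model_id == "M1":
        return 0.0, 0.0, math.pi, 0.0, 0.5
    if model_id == "M2A":
        return mu1, k1, mu1, 0.0, 1.0
    if model_id == "M2B":
        return mu1, k1, mu1, 0.0, p["lam"]
    if model_id == "M2C":
        return mu1, k1, mu1, p["r2"] * k1, p["lam"]
    if model_id == "M3A":
        return mu1, k1, (mu1 + math.pi) % TWO_PI, k1, 0.5
    if model_id == "M3B":
        return mu1, k1, (mu1 + math.pi) % TWO_PI, k1, p["lam"]
    if model_id == "M4A":
        return mu1, k1, (mu1 + math.pi) % TWO_PI, p["r2"] * k1, 0.5
    if model_id == "M4B":
        return mu1, k1, (mu1 + math.pi) % TWO_PI, p["r2"] * k1, p["lam"]
    if model_id == "M5A":
        return mu1, k1, p["mu2"], k1, 0.5
    if model_id == "M5B":
        return mu1, k1, p["mu2"], p["r2"] * k1, p["lam"]
    raise ContractError(f"unknown model id {model_id}")


def _log_vm(x: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # log von Mises density via exponentially scaled Bessel for stability
    return kappa * np.cos(x - mu) - kappa - math.log(TWO_PI) - math.log(i0e(kappa))


def _loglik(model_id: str, theta: np.ndarray, x: np.ndarray) -> float:
    mu1, k1, mu2, k2, lam = _expand(model_id, theta)
    if model_id == "M1":
        return -x.size * math.log(TWO_PI)
    if lam >= 1.0 - 1e-12:
        return float(np.sum(_log_vm(x, mu1, k1)))
    terms = np.stack([math.log(lam) + _log_vm(x, mu1, k1), math.log1p(-lam) + _log_vm(x, mu2, k2)])
    return float(np.sum(logsumexp(terms, axis=0)))


@dataclass(frozen=True)
class CircularModelFit:
    """Maximum-likelihood fit of one family member on doubled angles.

    Mode directions are reported back on the axial scale (deg, [0, 180));
    concentrations refer to the doubled circle.
    """

    model_id: str
    description: str
    mode1_deg: float | None
    mode2_deg: float | None
    kappa1: float
    kappa2: float
    lam: float
    log_likelihood: float
    n_params: int
    aic: float
    delta_aic: float = math.nan
    converged: bool = True


@dataclass(frozen=True)
class CircularFamilyResult:
    """AIC-ranked family fits plus a likelihood-ratio check vs uniform."""

    fits: tuple[CircularModelFit, ...]  # ranked, best first
    excluded: tuple[CircularModelFit, ...]
    lr_stat: float
    lr_p: float

    @property
    def best(self) -> CircularModelFit:
        return self.fits[0]

    def to_frame(self):
        import pandas as pd

        rows = [
            {
                "model": f.model_id,
                "description": f.description,
                "mode1_deg": f.mode1_deg,
                "mode2_deg": f.mode2_deg,
                "kappa1": f.kappa1,
                "kappa2": f.kappa2,
                "lambda": f.lam,
                "log_likelihood": f.log_likelihood,
                "n_params": f.n_params,
                "AIC": f.aic,
                "delta_AIC": f.delta_aic,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)


#: warm starts: child model -> [(parent model, embedding of parent params)]
#: each embedding maps the parent's free-parameter vector into the child's,
#: so every fit starts at least as well as its nested parent's optimum.
_WARM: dict[str, list[tuple[str, callable]]] = {
    "M2B": [("M2A", lambda p: [p[0], p[1], 1.0])],
    "M2C": [("M2B", lambda p: [p[0], p[1], 0.0, p[2]])],
    "M3B": [("M3A", lambda p: [p[0], p[1], 0.5])],
    "M4A": [("M3A", lambda p: [p[0], p[1], 1.0])],
    "M4B": [
        ("M4A", lambda p: [p[0], p[1], p[2], 0.5]),
        ("M3B", lambda p: [p[0], p[1], 1.0, p[2]]),
        ("M2A", lambda p: [p[0], p[1], 0.0, 1.0]),
    ],
    "M5A": [("M3A", lambda p: [p[0], (p[0] + math.pi) % TWO_PI, p[1]])],
    "M5B": [
        ("M5A", lambda p: [p[0], p[1], p[2], 1.0, 0.5]),
        ("M4B", lambda p: [p[0], (p[0] + math.pi) % TWO_PI, p[1], p[2], p[3]]),
        ("M2A", lambda p: [p[0], (p[0] + math.pi) % TWO_PI, p[1], 0.0, 1.0]),
    ],
}


def _clip_to_bounds(theta: list, bounds: list[tuple[float, float]]) -> np.ndarray:
    return np.array([min(max(v, lo), hi) for v, (lo, hi) in zip(theta, bounds)])


def _fit_one(
    model_id: str,
    x: np.ndarray,
    n_restarts: int,
    rng: np.random.Generator,
    fitted: dict[str, np.ndarray] | None = None,
):
    free = _FAMILY[model_id]["free"]
    if not free:
        ll = _loglik(model_id, np.empty(0), x)
        return np.empty(0), ll, True
    bounds = [_BOUNDS[name] for name in free]
    # moment-based smart start: doubled-sample mean direction / concentration
    C, S = np.mean(np.cos(x)), np.mean(np.sin(x))
    mu_hat = math.atan2(S, C) % TWO_PI
    r = math.hypot(C, S)
    k_hat = min(max(r * (2.0 - r**2) / max(1.0 - r**2, 1e-6), 0.1), 50.0)
    starts = []
    smart = {"mu1": mu_hat, "mu2": (mu_hat + math.pi) % TWO_PI, "k1": k_hat, "r2": 1.0, "lam": 0.5}
    starts.append(np.array([smart[name] for name in free]))
    for parent, embed in _WARM.get(model_id, []):
        if fitted is not None and parent in fitted:
            starts.append(_clip_to_bounds(embed(list(fitted[parent])), bounds))
    for _ in range(max(n_restarts - 1, 0)):
        draw = {
            "mu1": rng.uniform(0, TWO_PI),
            "mu2": rng.uniform(0, TWO_PI),
            "k1": math.exp(rng.uniform(math.log(0.5), math.log(20.0))),
            "r2": rng.uniform(0.0, 1.0),
            "lam": rng.uniform(0.5, 0.95),
        }
        starts.append(np.array([draw[name] for name in free]))
    best_theta, best_ll, ok = None, -np.inf, False
    for s0 in starts:
        res = minimize(
            lambda th: -_loglik(model_id, th, x),
            s0,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_theta, best_ll, ok = res.x, -res.fun, ok or res.success
    if best_theta is None:
        return None, -np.inf, False
    return best_theta, best_ll, ok


def fit_circular_model_family(
    angles_deg: Sequence[float],
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = 0,
    models: Sequence[str] | None = None,
) -> CircularFamilyResult:
    """Fit and AIC-rank the ten-model orientation family on axial data.

    Angles are doubled internally onto the full circle.  Each non-uniform
    member is maximised from a moment-based start plus random restarts of
    a bounded quasi-Newton optimiser.  Models whose optimiser never
    converges are excluded from the ranking.  The likelihood-ratio
    statistic compares the best model against the uniform member.
    ``models`` restricts the fit to a subset of the family.
    """
    a = np.asarray(angles_deg, float)
    if a.size < 5:
        raise InsufficientSampleError("model family fit needs n >= 5")
    if models is not None:
        unknown = [m for m in models if m not in _FAMILY]
        if unknown:
            raise ContractError(f"unknown model ids {unknown}")
    x = np.radians(2.0 * a) % TWO_PI
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fits, excluded = [], []
    fitted_params: dict[str, np.ndarray] = {}
    for model_id, spec in _FAMILY.items():
        if models is not None and model_id not in models:
            continue
        theta, ll, ok = _fit_one(model_id, x, n_restarts, rng, fitted=fitted_params)
        if theta is not None:
            fitted_params[model_id] = np.asarray(theta)
        k = len(spec["free"])
        if theta is None:
            fit = CircularModelFit(
                model_id, spec["desc"], None, None, 0.0, 0.0, 0.5, -np.inf, k, np.inf, converged=False
            )
            excluded.append(fit)
            continue
        mu1, k1, mu2, k2, lam = _expand(model_id, theta)
        has_mode1 = model_id != "M1"
        has_mode2 = model_id not in ("M1", "M2A", "M2B")
        fit = CircularModelFit(
            model_id,
            spec["desc"],
            (math.degrees(mu1) % 360.0) / 2.0 if has_mode1 else None,
            (math.degrees(mu2) % 360.0) / 2.0 if has_mode2 else None,
            float(k1),
            float(k2),
            float(lam),
            float(ll),
            k,
            2.0 * k - 2.0 * ll,
            converged=ok,
        )
        (fits if ok else excluded).append(fit)
    if not fits:
        raise ContractError("no family member converged")
    fits.sort(key=lambda f: f.aic)
    best_aic = fits[0].aic
    ranked = tuple(
        CircularModelFit(**{**f.__dict__, "delta_aic": f.aic - best_aic}) for f in fits
    )
    m1 = next((f for f in ranked if f.model_id == "M1"), None)
    if m1 is not None and ranked[0].model_id != "M1":
        lr = 2.0 * (ranked[0].log_likelihood - m1.log_likelihood)
        lr_p = float(chi2.sf(lr, df=max(ranked[0].n_params, 1)))
    else:
        lr, lr_p = 0.0, 1.0
    return CircularFamilyResult(ranked, tuple(excluded), float(lr), lr_p)
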