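"""Group-level hypothesis tests and the strategy-choice covariate model.

Each strategy group's observed angles and path lengths are tested
against the model expectations.  The test chooser mirrors standard
practice: a Shapiro-Wilk normality screen gates between a one-sample
bootstrap t test (9999 replicates, +1-corrected p) and a signed-rank
Wilcoxon test.  Path lengths across the strategy groups are compared
with Kruskal-Wallis followed by pairwise rank-sum tests under Holm
adjustment.  Which strategy a fish adopts is modelled as a multinomial
logit of age, swimming speed, displacement type and trial number, with
cluster-robust standard errors by fish.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .arena import RANDOM_LABEL, STRATEGIES
from .errors import ContractError, InsufficientSampleError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, p, and a (bootstrap) mean with CI."""

    statistic_name: str  # one of {"t", "V", "W", "H"}
    statistic: float
    df: int | None
    p: float
    mean: float | None = None
    ci95: tuple[float, float] | None = None
    n_boot: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ContractError(f"p-value {self.p} outside [0, 1]")


def _boot_mean_ci(
    x: np.ndarray, reps: int, rng: np.random.Generator
) -> tuple[float, tuple[float, float]]:
    idx = rng.integers(0, x.size, size=(reps, x.size))
    means = x[idx].mean(axis=1)
    return float(means.mean()), (float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975)))


def bootstrap_t_test(
    sample: Sequence[float],
    mu0: float,
    reps: int = 9999,
    seed: int | np.random.Generator | None = 0,
) -> TestResult:
    """One-sample bootstrap t test of H0: mean == mu0.

    The null distribution of t is generated by resampling the
    mu0-centred sample with replacement; p = (1 + #{|t*| >= |t|}) /
    (reps + 1).  The reported mean and 95% CI are the bootstrap mean and
    percentile interval of the raw sample mean.
    """
    x = np.asarray(sample, float)
    n = x.size
    if n < 3:
        raise InsufficientSampleError("bootstrap t test needs n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m, s = float(x.mean()), float(x.std(ddof=1))
    if s == 0.0:
        # degenerate sample: decision is exact
        if m == mu0:
            return TestResult("t", 0.0, n - 1, 1.0, m, (m, m), reps, note="zero variance")
        return TestResult(
            "t",
            math.inf if m > mu0 else -math.inf,
            n - 1,
            1.0 / (reps + 1),
            m,
            (m, m),
            reps,
            note="zero variance",
        )
    t_obs = (m - mu0) / (s / math.sqrt(n))
    centred = x - m + mu0
    idx = rng.integers(0, n, size=(reps, n))
    b = centred[idx]
    bm = b.mean(axis=1)
    bs = b.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_star = (bm - mu0) / (bs / math.sqrt(n))
    # degenerate resamples (all elements identical): t* is 0 when the
    # resample sits at mu0, otherwise undefined and excluded from the count
    t_star = np.where(bs == 0.0, np.where(bm == mu0, 0.0, np.nan), t_star)
    with np.errstate(invalid="ignore"):
        exceed = np.abs(t_star) >= abs(t_obs)
    p = (1.0 + float(np.nansum(exceed))) / (reps + 1.0)
    mean_b, ci = _boot_mean_ci(x, reps, rng)
    return TestResult("t", float(t_obs), n - 1, float(p), mean_b, ci, reps)


def wilcoxon_signed_rank(
    sample: Sequence[float],
    mu0: float,
    boot_reps: int = 9999,
    seed: int | np.random.Generator | None = 0,
) -> TestResult:
    """Two-sided signed-rank Wilcoxon test against mu0.

    V is the sum of positive ranks; zero differences are dropped.  The p
    value is exact for n <= 25 without ties, else a continuity-corrected
    normal approximation.  A bootstrap mean/CI of the raw sample mean is
    attached for table reporting.
    """
    x = np.asarray(sample, float)
    if x.size < 3:
        raise InsufficientSampleError("Wilcoxon test needs n >= 3")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean_b, ci = _boot_mean_ci(x, boot_reps, rng)
    d = x - mu0
    d = d[d != 0.0]
    if d.size == 0:
        logger.warning("all differences zero in Wilcoxon test; p = 1")
        return TestResult("V", 0.0, None, 1.0, mean_b, ci, boot_reps, note="all ties at mu0")
    ranks = st.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = st.wilcoxon(d, alternative="two-sided", method=method, correction=True)
    return TestResult("V", v, None, float(res.pvalue), mean_b, ci, boot_reps)


def normality_check(sample: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality screen (W, p)."""
    x = np.asarray(sample, float)
    if not (3 <= x.size <= 5000):
        raise ContractError("Shapiro-Wilk requires 3 <= n <= 5000")
    if x.std() == 0.0:
        raise ContractError("Shapiro-Wilk undefined for a constant sample")
    w, p = st.shapiro(x)
    return TestResult("W", float(w), None, float(p))


def compare_to_expectation(
    sample: Sequence[float],
    mu0: float,
    alpha: float = 0.05,
    reps: int = 9999,
    seed: int | np.random.Generator | None = 0,
) -> tuple[TestResult, TestResult]:
    """Normality-gated one-sample test against an expectation.

    Shapiro p > alpha selects the bootstrap t test, otherwise the
    signed-rank Wilcoxon.  Returns (chosen test, Shapiro result).
    """
    shap = normality_check(sample)
    if shap.p > alpha:
        return bootstrap_t_test(sample, mu0, reps=reps, seed=seed), shap
    return wilcoxon_signed_rank(sample, mu0, boot_reps=reps, seed=seed), shap


def distance_across_groups(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis across groups plus Holm-adjusted pairwise rank-sums.

    Groups with fewer than 2 observations are dropped with a warning.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": list(groups)})
    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("dropping groups with <2 observations: %s", small)
        df = df[~df["group"].isin(small)]
    names = sorted(df["group"].unique())
    if len(names) < 2:
        raise ContractError("need at least 2 groups with >= 2 observations")
    samples = [df.loc[df["group"] == g, "value"].to_numpy() for g in names]
    if np.ptp(np.concatenate(samples)) == 0:
        h, p = 0.0, 1.0  # identical values everywhere
    else:
        h, p = st.kruskal(*samples)
    result = TestResult("H", float(h), len(names) - 1, float(p))
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u, pu = st.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            rows.append({"group1": names[i], "group2": names[j], "U": float(u), "p_raw": float(pu)})
    posthoc = pd.DataFrame(rows)
    if not posthoc.empty:
        posthoc["p_holm"] = multipletests(posthoc["p_raw"], method="holm")[1]
    return result, posthoc


@dataclass
class StrategyChoiceResult:
    """Tidy multinomial-logit coefficient table (each strategy vs RANDOM)."""

    table: pd.DataFrame
    converged: bool
    penalized: bool
    n_obs: int
    n_clusters: int

    def summary(self) -> str:
        head = (
            f"Multinomial logit of strategy choice vs {RANDOM_LABEL}"
            f" (n={self.n_obs}, fish clusters={self.n_clusters},"
            f" {'penalized' if self.penalized else 'cluster-robust SE'})\n"
        )
        return head + self.table.to_string(index=False, float_format=lambda v: f"{v: .4f}")


def strategy_choice_model(records: pd.DataFrame) -> StrategyChoiceResult:
    """Model which covariates predict the adopted navigation strategy.

    ``records`` needs columns label, fish_id, age_days, swim_speed_cm_s,
    displacement, trial_number (one row per trial).  Fits a multinomial
    logit with RANDOM as the reference outcome; repeated trials of the
    same fish are handled with cluster-robust standard errors.  Perfect
    separation triggers a penalized (L1) fallback without robust errors.

    Continuous covariates are standardised internally for optimiser
    conditioning; slopes and standard errors are reported back on the
    original scale.  The ``const`` row is the log-odds at covariate
    means (and zero indicators).
    """
    req = {"label", "fish_id", "age_days", "swim_speed_cm_s", "displacement", "trial_number"}
    missing = req - set(records.columns)
    if missing:
        raise ContractError(f"records missing columns: {sorted(missing)}")
    df = records.dropna(subset=sorted(req)).copy()
    present = [s for s in (RANDOM_LABEL,) + STRATEGIES if s in set(df["label"])]
    if len(present) < 2:
        raise ContractError("need at least 2 strategy labels present")
    for col in ("age_days", "swim_speed_cm_s"):
        if df[col].nunique() < 2:
            raise ContractError(f"covariate {col} is constant")
    y = pd.Categorical(df["label"], categories=present).codes
    X = pd.DataFrame(
        {
            "age_days": df["age_days"].astype(float),
            "swim_speed_cm_s": df["swim_speed_cm_s"].astype(float),
            "displacement_diagonal": (df["displacement"] == "diagonal").astype(float),
            "trial_second": (df["trial_number"].astype(int) == 2).astype(float),
        }
    )
    scales = pd.Series(1.0, index=X.columns)
    for col in ("age_days", "swim_speed_cm_s"):
        scales[col] = float(X[col].std(ddof=0)) or 1.0
        X[col] = (X[col] - X[col].mean()) / scales[col]
    X = sm.add_constant(X, has_constant="add")
    scales = pd.concat([pd.Series({"const": 1.0}), scales])
    groups = pd.Categorical(df["fish_id"]).codes
    model = sm.MNLogit(y, X.to_numpy())
    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(
                method="bfgs",
                maxiter=500,
                disp=0,
                cov_type="cluster",
                cov_kwds={"groups": groups},
            )
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged or not np.all(np.isfinite(res.bse)):
                raise np.linalg.LinAlgError("unstable fit")
        except Exception:
            logger.warning("multinomial fit unstable (possible separation); penalized fallback")
            res = model.fit_regularized(method="l1", alpha=1.0, disp=0, maxiter=500)
            penalized = True
            converged = True
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    rows = []
    terms = list(X.columns)
    for k, outcome in enumerate(present[1:]):  # column k compares outcome vs baseline
        for i, term in enumerate(terms):
            scale = float(scales[term])
            se = float(bse[i, k]) / scale if np.all(np.isfinite(bse)) else math.nan
            est = float(params[i, k]) / scale
            rows.append(
                {
                    "outcome": outcome,
                    "term": term,
                    "estimate": est,
                    "se": se,
                    "z": est / se if se and math.isfinite(se) and se > 0 else math.nan,
                    "p": float(pvals[i, k]) if np.all(np.isfinite(pvals)) else math.nan,
                }
            )
    return StrategyChoiceResult(
        table=pd.DataFrame(rows),
        converged=converged,
        penalized=penalized,
        n_obs=len(df),
        n_clusters=int(pd.Series(groups).nunique()),
    )


def visual_acuity_cpd(lens_diameter_mm: float) -> float:
    """Visual acuity (cycles/degree) from lens diameter via the published
    small-fish regression: acuity = 2.2957 + 1.225 * diameter.

    Calibrated only below 10 mm lens diameter.
    """
    if not (0.0 < lens_diameter_mm < 10.0):
        raise ContractError("lens-diameter regression calibrated for 0 < d < 10 mm")
    return 2.2957 + 1.225 * lens_diameter_mm
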