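"""Model-free behavioural read-outs and downstream analyses.

Covers choice proportions by status, per-subject logistic decision betas
(two-stage: per-subject GLM, then across-subject summaries), RT-window-wise
sliding betas, split-half cross-validation of a fitted variant, social value
orientation (SVO) scoring, and simple mediation with a percentile bootstrap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import ddm
from .ddm import ModelVariant, OptionPair, STATUSES
from .likelihood import DEConfig, LikelihoodConfig, fit_subject

logger = logging.getLogger(__name__)

__all__ = [
    "DecisionBetas",
    "SVOResult",
    "MediationResult",
    "choice_proportions",
    "decision_betas",
    "sliding_window_betas",
    "split_half_crossval",
    "svo_score",
    "classify_angle",
    "mediate",
    "SVO_CATEGORY_THRESHOLDS",
    "SVO_BINARY_BOUNDARY",
]

#: Category cut angles in degrees: altruist > 57.15 >= prosocial >= 22.45 >
#: individualist >= -12.04 > competitive.
SVO_CATEGORY_THRESHOLDS = (57.15, 22.45, -12.04)
SVO_BINARY_BOUNDARY = 22.45


@dataclass(frozen=True)
class DecisionBetas:
    subject_id: str
    status: str
    beta_dms: float
    beta_dmo: float
    intercept: float
    n_trials: int
    separated: bool = False

    @property
    def relative_beta(self) -> float:
        return self.beta_dms - self.beta_dmo


@dataclass(frozen=True)
class SVOResult:
    mean_self: float
    mean_other: float
    angle_deg: float
    category: str
    binary_group: str


@dataclass(frozen=True)
class MediationResult:
    path_a: float
    path_b: float
    direct_c_prime: float
    indirect_ab: float
    ci_low: float
    ci_high: float
    n_boot: int
    covariates_used: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return not (self.ci_low <= 0.0 <= self.ci_high)


# ---------------------------------------------------------------------------
# Choice proportions


def choice_proportions(data: pd.DataFrame) -> pd.DataFrame:
    """Per subject x status fractions choosing the larger-Ms / larger-Mo option.

    The two tallies are computed independently (a trial where one option has
    both the larger self- and other-payoff counts toward both); denominators
    are the full status trial counts.  Ties on the other-payoff contribute
    nothing to the larger-Mo numerator.
    """
    if data["choice"].isna().any():
        raise ValueError("choices must be present")
    rows = []
    for (sid, status), g in data.groupby(["subject_id", "status"]):
        dmo = (g["mo1"] - g["mo2"]).to_numpy()
        choice = g["choice"].to_numpy()
        n = len(g)
        if n == 0:
            continue
        frac_ms = float(np.mean(choice == 1))
        chose_larger_mo = ((dmo > 0) & (choice == 1)) | ((dmo < 0) & (choice == 0))
        frac_mo = float(np.mean(chose_larger_mo))
        rows.append(
            {
                "subject_id": sid,
                "status": status,
                "frac_larger_ms": frac_ms,
                "frac_larger_mo": frac_mo,
                "n_trials": n,
            }
        )
    out = pd.DataFrame(rows)
    missing = {
        (sid, s)
        for sid in data["subject_id"].unique()
        for s in STATUSES
        if s in set(data["status"])
    } - set(zip(out["subject_id"], out["status"]))
    for sid, s in sorted(missing):
        logger.warning("empty status cell (%s, %s): proportions undefined", sid, s)
    return out


# ---------------------------------------------------------------------------
# Logistic decision betas


def _fit_logistic(
    y: np.ndarray, X: np.ndarray, ridge: float = 1e-3
) -> tuple[np.ndarray, bool]:
    """Logistic fit; on (quasi-)separation fall back to an L2-penalised fit
    and flag it rather than dropping the cell."""
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(res.params)
        if np.all(np.isfinite(params)) and np.max(np.abs(params)) < 1e3:
            return params, False
    except Exception:
        pass
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
        alpha=ridge, L1_wt=0.0, maxiter=200
    )
    return np.asarray(res.params), True


def decision_betas(data: pd.DataFrame, ridge: float = 1e-3) -> pd.DataFrame:
    """Per-subject, per-status logistic regression of choice on the payoff
    differences (choice = 1 for the larger-self-payoff option)."""
    rows = []
    for (sid, status), g in data.groupby(["subject_id", "status"]):
        dms = (g["ms1"] - g["ms2"]).to_numpy(float)
        dmo = (g["mo1"] - g["mo2"]).to_numpy(float)
        y = g["choice"].to_numpy(float)
        X = np.column_stack([np.ones_like(dms), dms, dmo])
        params, separated = _fit_logistic(y, X, ridge)
        rows.append(
            {
                "subject_id": sid,
                "status": status,
                "intercept": params[0],
                "beta_dms": params[1],
                "beta_dmo": params[2],
                "relative_beta": params[1] - params[2],
                "n_trials": len(g),
                "separated": separated,
            }
        )
    return pd.DataFrame(rows)


def summarize_betas(betas: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean and SEM of the decision betas per status."""
    def sem(x):
        return x.std(ddof=1) / math.sqrt(len(x))

    return (
        betas.groupby("status")[["beta_dms", "beta_dmo", "relative_beta"]]
        .agg(["mean", sem])
        .rename(columns={"<lambda_0>": "sem"})
    )


# ---------------------------------------------------------------------------
# Sliding-window betas


def sliding_window_betas(
    sim_data: pd.DataFrame,
    window: float = 0.1,
    step: float = 0.01,
    min_trials: int = 20,
    by_status: bool = True,
    ridge: float = 1e-3,
) -> pd.DataFrame:
    """Logistic betas within moving RT windows.

    Windows [t, t + window) advance in ``step`` increments over the observed
    RT range; windows with fewer than ``min_trials`` trials are skipped
    (gaps, not errors).
    """
    if sim_data["rt"].isna().any():
        sim_data = sim_data.dropna(subset=["rt"])
    groups = sim_data.groupby("status") if by_status else [("all", sim_data)]
    rows = []
    for status, g in groups:
        rt = g["rt"].to_numpy(float)
        dms = (g["ms1"] - g["ms2"]).to_numpy(float)
        dmo = (g["mo1"] - g["mo2"]).to_numpy(float)
        y = g["choice"].to_numpy(float)
        t0, t1 = rt.min(), rt.max()
        starts = np.arange(t0, max(t1 - window, t0) + step / 2, step)
        for s in starts:
            sel = (rt >= s) & (rt < s + window)
            if sel.sum() < min_trials or len(np.unique(y[sel])) < 2:
                continue
            X = np.column_stack([np.ones(int(sel.sum())), dms[sel], dmo[sel]])
            params, separated = _fit_logistic(y[sel], X, ridge)
            rows.append(
                {
                    "status": status,
                    "window_start": float(s),
                    "window_mid": float(s + window / 2),
                    "beta_dms": params[1],
                    "beta_dmo": params[2],
                    "n_trials": int(sel.sum()),
                    "separated": separated,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Split-half cross-validation


def split_half_crossval(
    data: pd.DataFrame,
    variant: ModelVariant,
    like_cfg: LikelihoodConfig,
    de_cfg: DEConfig,
    rng: np.random.Generator,
    n_rep: int = 100,
    t_max: float = 10.0,
) -> pd.DataFrame:
    """Fit on a random status-stratified half, predict the held-out half.

    Held-out trials are simulated ``n_rep`` times; reports per-status
    predicted-choice accuracy (modal simulated choice vs actual) and the
    Pearson correlation of mean simulated RT with actual RT.
    """
    for s, g in data.groupby("status"):
        if len(g) < 20:
            raise ValueError(f"need >= 20 trials per status; {s} has {len(g)}")
    half_a_idx = []
    for _, g in data.groupby("status"):
        idx = g.index.to_numpy()
        rng.shuffle(idx)
        half_a_idx.extend(idx[: len(idx) // 2])
    half_a = data.loc[sorted(half_a_idx)]
    half_b = data.drop(index=half_a_idx)
    fit = fit_subject(half_a, variant, like_cfg, de_cfg)
    rows = []
    for status, g in half_b.groupby("status"):
        acc, mean_rts = [], []
        for _, row in g.iterrows():
            pair = OptionPair(int(row.ms1), int(row.mo1), int(row.ms2), int(row.mo2))
            batch = ddm.simulate_trial_distribution(
                fit.best_params, variant, status, pair, n_rep, rng, t_max=t_max
            )
            valid = batch.choices >= 0
            if not valid.any():
                continue
            p1 = float(np.mean(batch.choices[valid] == 1))
            acc.append(float((p1 >= 0.5) == bool(row.choice)))
            mean_rts.append((float(np.nanmean(batch.rts[valid])), float(row.rt)))
        sim_rt = np.array([a for a, _ in mean_rts])
        act_rt = np.array([b for _, b in mean_rts])
        rt_corr = (
            float(np.corrcoef(sim_rt, act_rt)[0, 1]) if len(sim_rt) > 2 else np.nan
        )
        rows.append(
            {
                "status": status,
                "accuracy": float(np.mean(acc)),
                "rt_correlation": rt_corr,
                "mean_sim_rt": float(np.mean(sim_rt)),
                "mean_actual_rt": float(np.mean(act_rt)),
                "n_heldout": len(g),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Social value orientation


def classify_angle(angle_deg: float) -> tuple[str, str]:
    """Map an SVO angle to (four-way category, binary group)."""
    hi, mid, lo = SVO_CATEGORY_THRESHOLDS
    if angle_deg > hi:
        cat = "altruist"
    elif angle_deg >= mid:
        cat = "prosocial"
    elif angle_deg >= lo:
        cat = "individualist"
    else:
        cat = "competitive"
    binary = "prosocial" if angle_deg >= SVO_BINARY_BOUNDARY else "individualistic"
    return cat, binary


def svo_score(item_allocations) -> SVOResult:
    """Score the six-item allocation instrument.

    The angle is ``atan((mean_other - 50) / (mean_self - 50))`` in degrees;
    the binary split is at 22.45 degrees.
    """
    items = np.asarray(item_allocations, dtype=float)
    if items.shape != (6, 2):
        raise ValueError("expected six (self, other) allocation pairs")
    mean_self = float(items[:, 0].mean())
    mean_other = float(items[:, 1].mean())
    num, den = mean_other - 50.0, mean_self - 50.0
    if den == 0 and num == 0:
        raise ValueError("both allocation means equal 50: angle undefined")
    if den == 0:
        angle = math.copysign(90.0, num)
    else:
        angle = math.degrees(math.atan(num / den))
    cat, binary = classify_angle(angle)
    return SVOResult(
        mean_self=mean_self,
        mean_other=mean_other,
        angle_deg=angle,
        category=cat,
        binary_group=binary,
    )


# ---------------------------------------------------------------------------
# Simple mediation


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient mediation design matrix (collinear columns)")
    return coef


def mediate(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> MediationResult:
    """Simple mediation via product of coefficients with percentile bootstrap.

    Path a: x -> m; path b: m -> y controlling x; c': x -> y controlling m.
    The indirect effect is a*b; its CI comes from ``n_boot`` case resamples.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    x, m, y = (np.asarray(v, dtype=float).ravel() for v in (x, m, y))
    n = len(x)
    if not (len(m) == len(y) == n):
        raise ValueError("x, m, y must be aligned")
    cov = (
        np.asarray(covariates, dtype=float).reshape(n, -1)
        if covariates is not None
        else np.empty((n, 0))
    )

    def paths(idx: np.ndarray) -> tuple[float, float, float]:
        xi, mi, yi, ci = x[idx], m[idx], y[idx], cov[idx]
        ones = np.ones((len(idx), 1))
        a = _ols(mi, np.hstack([ones, xi[:, None], ci]))[1]
        by = _ols(yi, np.hstack([ones, xi[:, None], mi[:, None], ci]))
        return a, by[2], by[1]  # a, b, c'

    all_idx = np.arange(n)
    a, b, c_prime = paths(all_idx)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            ab_a, ab_b, _ = paths(idx)
        except ValueError:
            boot[i] = np.nan
            continue
        boot[i] = ab_a * ab_b
    boot = boot[np.isfinite(boot)]
    lo_q = (1 - ci_level) / 2
    ci_low, ci_high = np.quantile(boot, [lo_q, 1 - lo_q])
    return MediationResult(
        path_a=float(a),
        path_b=float(b),
        direct_c_prime=float(c_prime),
        indirect_ab=float(a * b),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        covariates_used=covariate_names,
    )
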