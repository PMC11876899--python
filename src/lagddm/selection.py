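"""Random-effects Bayesian model selection and recovery harnesses.

Model evidence enters as -BIC/2 per subject x variant.  The group-level
posterior over model frequencies follows the standard variational Dirichlet
scheme: iterate per-subject soft assignments u_nm proportional to
exp(log_ev_nm + digamma(alpha_m) - digamma(sum alpha)) and the concentration
update alpha = alpha_0 + sum_n u_nm until alpha converges.  Exceedance
probabilities come from Monte-Carlo draws of the posterior Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp

from . import ddm, design, likelihood
from .ddm import DDMParams, ModelVariant, VARIANTS
from .likelihood import DEConfig, FitResult, LikelihoodConfig, fit_subject

__all__ = [
    "BMSResult",
    "random_effects_bms",
    "parameter_recovery",
    "model_recovery",
    "evidence_matrix",
]


@dataclass(frozen=True)
class BMSResult:
    alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    n_mc_samples: int
    n_iterations: int
    model_ids: tuple[int, ...] = ()


def random_effects_bms(
    log_evidence: np.ndarray,
    prior_alpha: float = 1.0,
    rng: np.random.Generator | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_mc_samples: int = 100_000,
    model_ids: Sequence[int] | None = None,
) -> BMSResult:
    """Group-level posterior over model frequencies (random-effects BMS)."""
    ev = np.asarray(log_evidence, dtype=float)
    if ev.ndim != 2 or ev.shape[0] < 2 or ev.shape[1] < 2:
        raise ValueError("log_evidence must be (n_subjects >= 2) x (n_models >= 2)")
    if not np.all(np.isfinite(ev)):
        raise ValueError("log_evidence must be finite")
    rng = rng if rng is not None else np.random.default_rng(0)
    n, m = ev.shape
    alpha = np.full(m, float(prior_alpha))
    for it in range(max_iter):
        log_u = ev + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        new_alpha = prior_alpha + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    else:
        raise RuntimeError(f"BMS did not converge in {max_iter} iterations; alpha={alpha}")
    draws = rng.dirichlet(alpha, size=n_mc_samples)
    winners = np.argmax(draws, axis=1)
    xp = np.bincount(winners, minlength=m) / n_mc_samples
    return BMSResult(
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        exceedance_prob=xp,
        n_mc_samples=n_mc_samples,
        n_iterations=it + 1,
        model_ids=tuple(model_ids) if model_ids is not None else tuple(range(1, m + 1)),
    )


def evidence_matrix(fits: Sequence[FitResult]) -> tuple[np.ndarray, list[str], list[int]]:
    """Stack per-subject fits into a (subjects x models) -BIC/2 matrix."""
    subjects = sorted({f.subject_id for f in fits})
    models = sorted({f.variant_id for f in fits})
    ev = np.full((len(subjects), len(models)), np.nan)
    for f in fits:
        ev[subjects.index(f.subject_id), models.index(f.variant_id)] = f.log_evidence
    if np.any(np.isnan(ev)):
        raise ValueError("every subject must be fitted with every model")
    return ev, subjects, models


# ---------------------------------------------------------------------------
# Recovery harnesses


def _simulate_subjects(
    truth_sets: Sequence[DDMParams],
    variant: ModelVariant,
    n_trials: int,
    seed: int,
    t_max: float = 10.0,
) -> list[pd.DataFrame]:
    root = np.random.SeedSequence(seed)
    frames = []
    for i, params in enumerate(truth_sets):
        ss = root.spawn(1)[0]
        design_rng, sim_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        options = design.generate_option_set(n_trials, design_rng)
        schedule = design._schedule_for_length(n_trials, design_rng)
        recs = design.generate_synthetic_subject(
            params, schedule, options, sim_rng, subject_id=f"r{i:02d}",
            variant=variant, t_max=t_max,
        )
        df = design.records_to_frame(recs)
        df = df[~df["censored"]].copy()
        frames.append(df)
    return frames


def parameter_recovery(
    truth_sets: Sequence[DDMParams],
    variant: ModelVariant,
    like_cfg: LikelihoodConfig,
    de_cfg: DEConfig,
    n_trials: int = 120,
    seed: int = 0,
) -> dict:
    """Simulate subjects from known parameters, refit, and tabulate recovery.

    Returns per-slot true/recovered arrays, Pearson correlations, mean bias,
    and the sign-agreement rate for onset-lag slots with |true| >= 0.3 s.
    """
    if len(truth_sets) < 5:
        raise ValueError("need >= 5 truth sets spanning the bounds")
    frames = _simulate_subjects(truth_sets, variant, n_trials, seed)
    slots = variant.slot_names
    true_mat = np.array(
        [[ddm.params_to_dict(p, variant)[k] for k in slots] for p in truth_sets]
    )
    rec_rows, failures = [], []
    for i, df in enumerate(frames):
        try:
            fit = fit_subject(df, variant, like_cfg, de_cfg, subject_id=f"r{i:02d}")
        except RuntimeError as e:  # recovery computed on completions
            failures.append(str(e))
            rec_rows.append(np.full(len(slots), np.nan))
            continue
        rec_rows.append(fit.best_vector)
    rec_mat = np.array(rec_rows)
    ok = ~np.isnan(rec_mat[:, 0])
    correlations, bias = {}, {}
    for j, name in enumerate(slots):
        t, r = true_mat[ok, j], rec_mat[ok, j]
        if np.std(t) == 0:
            correlations[name] = None  # degenerate truth spread
        else:
            correlations[name] = float(np.corrcoef(t, r)[0, 1])
        bias[name] = float(np.mean(r - t))
    # sign agreement for onset lags with clearly non-zero truth
    lag_cols = [j for j, n_ in enumerate(slots) if n_.startswith("rst")]
    agree, total = 0, 0
    for j in lag_cols:
        sel = ok & (np.abs(true_mat[:, j]) >= 0.3)
        agree += int(np.sum(np.sign(true_mat[sel, j]) == np.sign(rec_mat[sel, j])))
        total += int(np.sum(sel))
    return {
        "slots": list(slots),
        "true": true_mat,
        "recovered": rec_mat,
        "correlations": correlations,
        "bias": bias,
        "rst_sign_agreement": (agree / total) if total else None,
        "n_failures": len(failures),
        "failures": failures,
        "data": frames,
    }


def model_recovery(
    generating_params: dict[int, Sequence[DDMParams]],
    like_cfg: LikelihoodConfig,
    de_cfg: DEConfig,
    n_trials: int = 90,
    seed: int = 0,
    fit_variants: Sequence[int] = (1, 2, 3, 4),
) -> dict:
    """Simulate cohorts per generating variant, fit all variants, run BMS.

    Returns per-generator BMS results and a confusion matrix of winning
    variants (by exceedance probability).
    """
    results: dict[int, BMSResult] = {}
    confusion = np.zeros((len(generating_params), len(fit_variants)))
    for gi, (gen_id, truths) in enumerate(sorted(generating_params.items())):
        frames = _simulate_subjects(truths, VARIANTS[gen_id], n_trials, seed + gen_id)
        fits: list[FitResult] = []
        for i, df in enumerate(frames):
            for vid in fit_variants:
                fits.append(
                    fit_subject(df, VARIANTS[vid], like_cfg, de_cfg, subject_id=f"r{i:02d}")
                )
        ev, _, models = evidence_matrix(fits)
        bms = random_effects_bms(
            ev, rng=np.random.default_rng(seed + 1000 + gen_id), model_ids=models
        )
        results[gen_id] = bms
        confusion[gi, int(np.argmax(bms.exceedance_prob))] += 1
    return {
        "bms": results,
        "confusion": confusion,
        "generating_variants": sorted(generating_params),
        "fit_variants": list(fit_variants),
    }
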