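"""Dispersed ground-truth parameter sets for recovery harnesses.

Each slot is spread evenly over a plausible sub-range of the fitting bounds
and independently permuted, so true values are mutually near-orthogonal
across synthetic subjects (good conditioning for true-vs-recovered
correlations).  The onset-lag ranges keep the cohort means status-monotone
(better > equal > worse), mirroring the prosocial preset.
"""

from __future__ import annotations

import numpy as np

from .ddm import DDMParams

__all__ = ["recovery_truth_sets", "model_recovery_truths"]

# slot -> (low, high) truth ranges; well inside the default fitting bounds.
# Drift weights are chosen so typical per-second drift is of the same order
# as the diffusion coefficient, where the onset lags have real leverage on
# both choices and RT distributions.
# Onset-lag ranges are asymmetric: positive lags (other-payoff delayed) are
# only identifiable up to roughly the typical decision time, while negative
# lags (self-payoff delayed) bite much harder; the per-status ranges are wide
# but keep the cohort means ordered better > equal > worse.
_V2_RANGES = {
    "omega_s": (0.055, 0.160),
    "omega_o": (0.045, 0.140),
    "rst_b": (-0.70, 1.10),
    "rst_e": (-0.80, 0.60),
    "rst_w": (-1.00, -0.15),
    "threshold": (1.00, 1.40),
    "ndt": (0.20, 0.50),
    "bias_frac": (-0.25, 0.25),
}


def _spread(lo: float, hi: float, n: int, rng: np.random.Generator) -> np.ndarray:
    vals = np.linspace(lo, hi, n)
    rng.shuffle(vals)
    return vals


def recovery_truth_sets(n_subjects: int = 8, seed: int = 0) -> list[DDMParams]:
    """Variant-2 truths: shared weights, status-specific onset lags."""
    rng = np.random.default_rng([seed, 211])
    cols = {k: _spread(lo, hi, n_subjects, rng) for k, (lo, hi) in _V2_RANGES.items()}
    # keep the weakest-drift subject away from the largest threshold: that
    # corner produces decisions too noise-dominated to identify anything
    weakest = int(np.argmin(cols["omega_s"] + cols["omega_o"]))
    strongest = int(np.argmax(cols["omega_s"] + cols["omega_o"]))
    if cols["threshold"][weakest] > cols["threshold"][strongest]:
        t = cols["threshold"].copy()
        t[weakest], t[strongest] = t[strongest], t[weakest]
        cols["threshold"] = t
    out = []
    for i in range(n_subjects):
        thr = float(cols["threshold"][i])
        out.append(
            DDMParams(
                omega_s=float(cols["omega_s"][i]),
                omega_o=float(cols["omega_o"][i]),
                rst={
                    "better": float(cols["rst_b"][i]),
                    "equal": float(cols["rst_e"][i]),
                    "worse": float(cols["rst_w"][i]),
                },
                threshold=thr,
                ndt=float(cols["ndt"][i]),
                bias=float(cols["bias_frac"][i]) * thr,
            )
        )
    return out


def model_recovery_truths(
    n_subjects: int = 6, seed: int = 0
) -> dict[int, list[DDMParams]]:
    """Generating-parameter cohorts for model recovery.

    Variant-2 cohorts carry strong status-dependent onset lags with shared
    weights; variant-1 cohorts carry status-dependent weights with both
    attributes entering simultaneously.
    """
    rng = np.random.default_rng([seed, 613])
    v2 = recovery_truth_sets(n_subjects, seed)
    v1 = []
    # steep status-dependent weight patterns with roughly constant total
    # drift: an onset lag can only *suppress* an attribute early (and shifts
    # RTs doing so), so it cannot cheaply mimic these reversals
    for i in range(n_subjects):
        thr = float(rng.uniform(1.0, 1.2))
        ws = {
            "better": float(rng.uniform(0.110, 0.130)),
            "equal": float(rng.uniform(0.080, 0.095)),
            "worse": float(rng.uniform(0.050, 0.065)),
        }
        wo = {
            "better": float(rng.uniform(0.015, 0.030)),
            "equal": float(rng.uniform(0.055, 0.070)),
            "worse": float(rng.uniform(0.095, 0.115)),
        }
        v1.append(
            DDMParams(
                omega_s=ws,
                omega_o=wo,
                rst=0.0,
                threshold=thr,
                ndt=float(rng.uniform(0.25, 0.45)),
                bias=0.0,
            )
        )
    return {1: v1, 2: v2}
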