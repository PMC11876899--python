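"""Numba kernels for the Euler evidence walk.

All kernels consume pre-generated standard-normal increments so that the
calling layer owns every source of randomness (common random numbers for
the fitting objective fall out for free).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_paths", "observed_cell_counts"]


@njit(cache=True)
def run_paths(d_early, d_late, switch_step, bias, threshold, sigma, max_steps, noise):
    """Simulate one trial's paths to absorption.

    ``noise`` is (n_paths, max_steps) standard normals.  Returns per-path
    boundary signs (+1 upper, -1 lower, 0 censored) and step counts.
    """
    n = noise.shape[0]
    signs = np.zeros(n, dtype=np.int8)
    steps = np.empty(n, dtype=np.int64)
    for i in range(n):
        e = bias
        t = 0
        sign = np.int8(0)
        while t < max_steps:
            if t < switch_step:
                e += d_early
            else:
                e += d_late
            e += sigma * noise[i, t]
            t += 1
            if e >= threshold:
                sign = np.int8(1)
                break
            if e <= -threshold:
                sign = np.int8(-1)
                break
        signs[i] = sign
        steps[i] = t
    return signs, steps


@njit(cache=True)
def observed_cell_counts(
    d_early,
    d_late,
    switch_step,
    bias,
    threshold,
    sigma,
    ndt,
    dt,
    max_steps,
    noise,
    row0,
    n_sims,
    obs_choice,
    obs_bin,
    bin_width,
    n_bins,
    kernel_smooth,
):
    """Count, per trial, how many simulated paths land in the observed cell.

    ``d_early``/``d_late``/``switch_step`` are per-trial arrays.  ``noise``
    is a shared pool of standard-normal increment rows; trial ``j`` uses the
    ``n_sims`` rows starting at ``row0[j]`` (mod pool size), which keeps the
    common-random-number property while decorrelating the Monte-Carlo error
    across trials.  ``obs_choice`` is 1/0 (or -1 for a censored observation);
    ``obs_bin`` is the observed RT's histogram bin (clipped to
    [0, n_bins-1]).
    """
    n_trials = d_early.shape[0]
    n_pool = noise.shape[0]
    counts = np.zeros(n_trials, dtype=np.float64)
    for j in range(n_trials):
        de = d_early[j]
        dl = d_late[j]
        sw = switch_step[j]
        c = 0.0
        for i in range(n_sims):
            row = (row0[j] + i) % n_pool
            e = bias
            t = 0
            sign = 0
            while t < max_steps:
                if t < sw:
                    e += de
                else:
                    e += dl
                e += sigma * noise[row, t]
                t += 1
                if e >= threshold:
                    sign = 1
                    break
                if e <= -threshold:
                    sign = -1
                    break
            if sign == 0:
                if obs_choice[j] == -1:
                    c += 1.0
                continue
            choice = 1 if sign == 1 else 0
            if choice != obs_choice[j]:
                continue
            b = int((t * dt + ndt) / bin_width)
            if b >= n_bins:
                b = n_bins - 1
            ob = obs_bin[j]
            if not kernel_smooth:
                if b == ob:
                    c += 1.0
            elif b == ob:
                # triangular kernel [0.25, 0.5, 0.25] with reflected edges
                if b == 0 or b == n_bins - 1:
                    c += 0.75
                else:
                    c += 0.5
            elif b == ob - 1 or b == ob + 1:
                c += 0.25
        counts[j] = c
    return counts
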