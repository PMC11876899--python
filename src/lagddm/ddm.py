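"""Core simulator for the attribute-onset-lag drift diffusion model.

Two option attributes -- the chooser's own payoff difference (``dms``) and
the co-player's payoff difference (``dmo``) -- drive a noisy evidence
accumulator toward symmetric boundaries.  The relative start time (``rst``)
lets one attribute enter the accumulation later than the other: ``rst > 0``
means the self-payoff attribute enters first and the other-payoff attribute
is gated off for the first ``ceil(rst/dt)`` steps (and symmetrically for
``rst < 0``).

The accumulator is a literal Euler walk::

    E_0 = bias
    E_t = E_{t-1} + nu_t * dt + eps_t,   eps_t ~ Normal(0, sigma)

with ``sigma`` the *per-step* noise standard deviation (default 0.1 at
dt = 0.01 s, i.e. a continuum diffusion coefficient of sigma^2/dt = 1 per
second).  The walk stops at the first step where ``|E_t| >= threshold``;
response time is ``t*dt + ndt``.  Paths that never absorb within ``t_max``
are reported as censored, never resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from ._kernels import run_paths

__all__ = [
    "STATUSES",
    "DDMParams",
    "ModelVariant",
    "VARIANTS",
    "LatencySchedule",
    "OptionPair",
    "SimBatch",
    "SimOutcome",
    "EvidencePath",
    "effective_params",
    "drift_rate",
    "simulate_trial",
    "simulate_trial_distribution",
    "params_from_vector",
    "params_to_dict",
]

#: Relative-social-status condition labels, in canonical order.
STATUSES = ("better", "equal", "worse")

StatusScalar = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class OptionPair:
    """One binary dictator-game option pair.

    Option 1 is, by labelling convention, the option with the larger
    self-payoff, so ``delta_ms`` is always strictly positive.
    """

    ms1: int
    mo1: int
    ms2: int
    mo2: int

    def __post_init__(self) -> None:
        for v in (self.ms1, self.mo1, self.ms2, self.mo2):
            if not (1 <= v <= 20):
                raise ValueError(f"payoff {v} outside [1, 20]")
        if self.delta_ms <= 0:
            raise ValueError("options must be labelled so delta_ms > 0")

    @property
    def delta_ms(self) -> int:
        return self.ms1 - self.ms2

    @property
    def delta_mo(self) -> int:
        return self.mo1 - self.mo2


@dataclass(frozen=True)
class ModelVariant:
    """Which parameter slots a candidate model frees up.

    Variant 1 fixes the onset lag to zero but lets attribute weights vary
    with status; variant 2 shares the weights and frees the lag per status;
    variant 3 frees the weights with a single shared lag; variant 4 frees
    everything.
    """

    variant_id: int
    weights_by_status: bool
    rst_by_status: bool
    rst_fixed_zero: bool

    @property
    def slot_names(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.weights_by_status:
            names += [f"omega_s_{s[0]}" for s in STATUSES]
            names += [f"omega_o_{s[0]}" for s in STATUSES]
        else:
            names += ["omega_s", "omega_o"]
        if not self.rst_fixed_zero:
            if self.rst_by_status:
                names += [f"rst_{s[0]}" for s in STATUSES]
            else:
                names += ["rst"]
        names += ["threshold", "ndt", "bias_frac"]
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.slot_names)


VARIANTS: dict[int, ModelVariant] = {
    1: ModelVariant(1, weights_by_status=True, rst_by_status=False, rst_fixed_zero=True),
    2: ModelVariant(2, weights_by_status=False, rst_by_status=True, rst_fixed_zero=False),
    3: ModelVariant(3, weights_by_status=True, rst_by_status=False, rst_fixed_zero=False),
    4: ModelVariant(4, weights_by_status=True, rst_by_status=True, rst_fixed_zero=False),
}


@dataclass(frozen=True)
class DDMParams:
    """Full parameter vector for one model variant.

    ``omega_s``, ``omega_o`` and ``rst`` may each be a scalar (shared across
    status conditions) or a mapping ``{"better": ..., "equal": ...,
    "worse": ...}``.
    """

    omega_s: StatusScalar
    omega_o: StatusScalar
    rst: StatusScalar
    threshold: float
    ndt: float
    bias: float
    sigma: float = 0.1
    dt: float = 0.01

    def __post_init__(self) -> None:
        if not (self.threshold > 0):
            raise ValueError("threshold must be > 0")
        if self.ndt < 0:
            raise ValueError("ndt must be >= 0")
        if not abs(self.bias) < self.threshold:
            raise ValueError("|bias| must be < threshold")
        if not (self.dt > 0 and self.sigma > 0):
            raise ValueError("dt and sigma must be > 0")
        for v in self._all_values():
            if not math.isfinite(v):
                raise ValueError("non-finite parameter value")

    def _all_values(self):
        for x in (self.omega_s, self.omega_o, self.rst):
            if isinstance(x, Mapping):
                yield from (float(v) for v in x.values())
            else:
                yield float(x)
        yield from (self.threshold, self.ndt, self.bias, self.sigma, self.dt)


def _resolve(value: StatusScalar, status: str, slot: str) -> float:
    if isinstance(value, Mapping):
        try:
            return float(value[status])
        except KeyError:
            raise KeyError(f"parameter slot {slot!r} has no value for status {status!r}")
    return float(value)


def effective_params(
    params: DDMParams, variant: ModelVariant, status: str
) -> tuple[float, float, float]:
    """Resolve the status-specific ``(omega_s, omega_o, rst)`` triple."""
    if status not in STATUSES:
        raise ValueError(f"unknown status {status!r}")
    ws = _resolve(params.omega_s, status, "omega_s")
    wo = _resolve(params.omega_o, status, "omega_o")
    if variant.rst_fixed_zero:
        rst = 0.0
    else:
        rst = _resolve(params.rst, status, "rst")
    return ws, wo, rst


@dataclass(frozen=True)
class LatencySchedule:
    """Integer step indices at which each attribute starts contributing.

    The late attribute enters at step ``ceil(|rst| / dt)``; the early
    attribute enters at step 0, so ``min(entry_step_s, entry_step_o) == 0``.
    """

    entry_step_s: int
    entry_step_o: int

    @classmethod
    def from_rst(cls, rst: float, dt: float) -> "LatencySchedule":
        lag = int(math.ceil(abs(rst) / dt - 1e-12)) if rst != 0 else 0
        if rst >= 0:
            return cls(entry_step_s=0, entry_step_o=lag)
        return cls(entry_step_s=lag, entry_step_o=0)

    def gate_s(self, step: int) -> int:
        return 1 if step >= self.entry_step_s else 0

    def gate_o(self, step: int) -> int:
        return 1 if step >= self.entry_step_o else 0


def drift_rate(
    omega_s: float,
    omega_o: float,
    schedule: LatencySchedule,
    trial: OptionPair,
    step: int,
) -> float:
    """Per-second drift at integer ``step``, with onset gates applied."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return (
        schedule.gate_s(step) * omega_s * trial.delta_ms
        + schedule.gate_o(step) * omega_o * trial.delta_mo
    )


@dataclass(frozen=True)
class SimOutcome:
    """One simulated (choice, RT) pair.

    ``choice`` is 1 for the upper boundary (the larger-self-payoff option),
    0 for the lower, and None when the path was censored at ``t_max``.
    """

    choice: int | None
    rt: float | None
    censored: bool


@dataclass(frozen=True)
class EvidencePath:
    evidence: np.ndarray
    n_steps: int
    hit_boundary: str  # "upper" | "lower" | "censored"


@dataclass(frozen=True)
class SimBatch:
    """Empirical (choice, RT) distribution from many simulated paths.

    ``choices`` holds 1 (upper), 0 (lower) or -1 (censored); ``rts`` is NaN
    on censored paths.
    """

    choices: np.ndarray
    rts: np.ndarray

    @property
    def n(self) -> int:
        return len(self.choices)

    @property
    def censored_fraction(self) -> float:
        return float(np.mean(self.choices == -1))


def _phase_drifts(
    ws: float, wo: float, rst: float, trial: OptionPair, dt: float
) -> tuple[float, float, int]:
    """Per-step drift increments before/after the late attribute's entry."""
    if not all(math.isfinite(v) for v in (ws, wo, rst)):
        raise ValueError(f"non-finite effective parameters: ws={ws}, wo={wo}, rst={rst}")
    sched = LatencySchedule.from_rst(rst, dt)
    switch = max(sched.entry_step_s, sched.entry_step_o)
    d_late = (ws * trial.delta_ms + wo * trial.delta_mo) * dt
    d_early = (
        (ws * trial.delta_ms if sched.entry_step_s == 0 else 0.0)
        + (wo * trial.delta_mo if sched.entry_step_o == 0 else 0.0)
    ) * dt
    return d_early, d_late, switch


def _simulate_batch(
    params: DDMParams,
    variant: ModelVariant,
    status: str,
    trial: OptionPair,
    n_sims: int,
    rng: np.random.Generator,
    t_max: float,
    chunk: int = 5000,
) -> SimBatch:
    ws, wo, rst = effective_params(params, variant, status)
    d_early, d_late, switch = _phase_drifts(ws, wo, rst, trial, params.dt)
    max_steps = int(round(t_max / params.dt))
    if max_steps < 1:
        raise ValueError("t_max must be >= dt")
    choices = np.empty(n_sims, dtype=np.int8)
    rts = np.empty(n_sims, dtype=np.float64)
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        noise = rng.standard_normal((m, max_steps)).astype(np.float32)
        signs, steps = run_paths(
            d_early, d_late, switch, params.bias, params.threshold,
            params.sigma, max_steps, noise,
        )
        sl = slice(done, done + m)
        choices[sl] = np.where(signs == 0, -1, (signs + 1) // 2).astype(np.int8)
        rts[sl] = np.where(signs == 0, np.nan, steps * params.dt + params.ndt)
        done += m
    return SimBatch(choices=choices, rts=rts)


def simulate_trial(
    params: DDMParams,
    variant: ModelVariant,
    status: str,
    trial: OptionPair,
    rng: np.random.Generator,
    t_max: float = 10.0,
    return_path: bool = False,
):
    """Simulate a single evidence-accumulation path for one trial."""
    ws, wo, rst = effective_params(params, variant, status)
    d_early, d_late, switch = _phase_drifts(ws, wo, rst, trial, params.dt)
    max_steps = int(round(t_max / params.dt))
    if max_steps < 1:
        raise ValueError("t_max must be >= dt")
    noise = rng.standard_normal(max_steps)
    incr = np.full(max_steps, d_late)
    if switch > 0:
        incr[: min(switch, max_steps)] = d_early
    evidence = params.bias + np.cumsum(incr + params.sigma * noise)
    hits = np.flatnonzero(np.abs(evidence) >= params.threshold)
    if hits.size:
        t = int(hits[0]) + 1  # step count (1-based: first update is step 1)
        sign = 1 if evidence[hits[0]] >= params.threshold else -1
        out = SimOutcome(choice=(sign + 1) // 2, rt=t * params.dt + params.ndt, censored=False)
        boundary = "upper" if sign == 1 else "lower"
        path = evidence[:t]
    else:
        t = max_steps
        out = SimOutcome(choice=None, rt=None, censored=True)
        boundary = "censored"
        path = evidence
    if return_path:
        return out, EvidencePath(evidence=path, n_steps=t, hit_boundary=boundary)
    return out


def simulate_trial_distribution(
    params: DDMParams,
    variant: ModelVariant,
    status: str,
    trial: OptionPair,
    n_sims: int,
    rng: np.random.Generator,
    t_max: float = 10.0,
) -> SimBatch:
    """Simulate ``n_sims`` i.i.d. (choice, RT) outcomes for one trial."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    return _simulate_batch(params, variant, status, trial, n_sims, rng, t_max)


# ---------------------------------------------------------------------------
# Flat-vector parametrisation used by the fitting machinery.
# The starting bias is parametrised as a fraction of the threshold so box
# bounds stay independent (|bias| < threshold holds by construction).


def params_from_vector(
    vec: np.ndarray, variant: ModelVariant, sigma: float = 0.1, dt: float = 0.01
) -> DDMParams:
    """Build :class:`DDMParams` from a flat slot vector (see ``slot_names``)."""
    vec = np.asarray(vec, dtype=float)
    names = variant.slot_names
    if vec.shape != (len(names),):
        raise ValueError(f"expected {len(names)} slots for variant {variant.variant_id}")
    d = dict(zip(names, vec))
    if variant.weights_by_status:
        omega_s: StatusScalar = {s: d[f"omega_s_{s[0]}"] for s in STATUSES}
        omega_o: StatusScalar = {s: d[f"omega_o_{s[0]}"] for s in STATUSES}
    else:
        omega_s, omega_o = d["omega_s"], d["omega_o"]
    if variant.rst_fixed_zero:
        rst: StatusScalar = 0.0
    elif variant.rst_by_status:
        rst = {s: d[f"rst_{s[0]}"] for s in STATUSES}
    else:
        rst = d["rst"]
    threshold = d["threshold"]
    return DDMParams(
        omega_s=omega_s,
        omega_o=omega_o,
        rst=rst,
        threshold=threshold,
        ndt=d["ndt"],
        bias=d["bias_frac"] * threshold,
        sigma=sigma,
        dt=dt,
    )


def params_to_dict(params: DDMParams, variant: ModelVariant) -> dict[str, float]:
    """Flatten :class:`DDMParams` into named slots (inverse of the above)."""
    out: dict[str, float] = {}
    if variant.weights_by_status:
        for s in STATUSES:
            out[f"omega_s_{s[0]}"] = _resolve(params.omega_s, s, "omega_s")
            out[f"omega_o_{s[0]}"] = _resolve(params.omega_o, s, "omega_o")
    else:
        out["omega_s"] = _resolve(params.omega_s, "equal", "omega_s")
        out["omega_o"] = _resolve(params.omega_o, "equal", "omega_o")
    if not variant.rst_fixed_zero:
        if variant.rst_by_status:
            for s in STATUSES:
                out[f"rst_{s[0]}"] = _resolve(params.rst, s, "rst")
        else:
            out["rst"] = _resolve(params.rst, "equal", "rst")
    out["threshold"] = params.threshold
    out["ndt"] = params.ndt
    out["bias_frac"] = params.bias / params.threshold
    return out
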