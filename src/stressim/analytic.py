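"""Closed-form predictions for long-term SIM prevalence.

In the strong-selection, short-stress limit, sampling the SIM allele
frequency p_M once per cycle reduces the continuous dynamics to the
one-dimensional recursion

    p_M' = p_M * exp(-mu_M * tau) * (1 + lam) / (1 + p_M * lam),

where ``lam`` measures the hitchhiking gain per stress episode:
lam = ((1 - p_R) / p_R) * nu_R / (s/sigma + mu_M + nu_R), with p_R the
resistance frequency found at the onset of stress.  The composite
parameter

    Gamma = (s/sigma + mu_M + nu_R) / mu_R

controls the fixed point.  Stress strength ``s`` and SIM potency
``sigma`` enter every long-term quantity only through the ratio
``s / sigma``.

The non-recurrent regime (every stress novel; p_R at mutation balance)
has the fixed point  max{0, e^(-mu_M tau) - Gamma (1 - e^(-mu_M tau))},
which is positive exactly for cycle lengths below the critical value
tau_c = (1/mu_M) ln(1 + 1/Gamma).  The recurrent regime (the same stress
every cycle) keeps resistance high between episodes and multiplies the
Gamma term by a factor >= 1, so its prevalence never exceeds the
non-recurrent one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParameters

__all__ = [
    "AnalyticSummary",
    "gamma",
    "lambda_factor",
    "recursion_step",
    "recursion_fixed_point",
    "equilibrium_nr",
    "equilibrium_r",
    "critical_cycle_length",
    "resistance_relaxation",
    "heuristic_multistress_equilibrium",
    "summarize",
]


def gamma(params: ModelParameters) -> float:
    """Composite parameter Gamma = (s/sigma + mu_M + nu_R) / mu_R."""
    if params.mu_R == 0:
        raise ValueError("gamma is undefined for mu_R = 0")
    return (params.s / params.sigma + params.mu_M + params.nu_R) / params.mu_R


def lambda_factor(p_R_end: float, params: ModelParameters) -> float:
    """Hitchhiking gain factor for a stress met at resistance frequency ``p_R_end``.

    lam = ((1 - p_R_end) / p_R_end) * nu_R / (s/sigma + mu_M + nu_R).
    The smaller the standing resistance, the larger the sweep the SIM
    allele can ride.  Diverges as p_R_end -> 0.
    """
    if not 0.0 < p_R_end <= 1.0:
        raise ValueError(f"p_R_end must lie in (0, 1], got {p_R_end}")
    return ((1.0 - p_R_end) / p_R_end) * params.nu_R / (
        params.s / params.sigma + params.mu_M + params.nu_R
    )


def recursion_step(p_M: float, lambda_: float, mu_M: float, tau_decay: float) -> float:
    """One cycle of the sampled SIM-frequency map.

    ``tau_decay`` is the time over which the SIM allele decays by mutation
    within one cycle (the full cycle length in the equilibrium formulas).
    """
    if not 0.0 <= p_M <= 1.0:
        raise ValueError(f"p_M must lie in [0, 1], got {p_M}")
    if lambda_ < 0:
        raise ValueError(f"lambda must be >= 0, got {lambda_}")
    return p_M * math.exp(-mu_M * tau_decay) * (1.0 + lambda_) / (1.0 + p_M * lambda_)


def recursion_fixed_point(lambda_: float, mu_M: float, tau_decay: float) -> float:
    """Stable fixed point of :func:`recursion_step`, clamped to [0, 1].

    Solving p' = p gives p* = (e^(-mu_M tau)(1 + lam) - 1) / lam; the map
    is increasing and concave on [0, 1], so the interior fixed point (when
    it exists, i.e. when e^(-mu_M tau)(1 + lam) > 1) is unique and
    attracting; otherwise 0 attracts.
    """
    decay = math.exp(-mu_M * tau_decay)
    if lambda_ == 0.0:
        return 1.0 if decay == 1.0 else 0.0
    return min(1.0, max(0.0, (decay * (1.0 + lambda_) - 1.0) / lambda_))


def equilibrium_nr(params: ModelParameters, tau: float, *, clamp: bool = True) -> float:
    """Long-term SIM prevalence under non-recurrent stress at cycle length ``tau``.

    max{0, e^(-mu_M tau) - Gamma (1 - e^(-mu_M tau))}.  With ``clamp=False``
    the raw (possibly negative) value is returned, which is useful for
    root finding around the critical cycle length.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    decay = math.exp(-params.mu_M * tau)
    raw = decay - gamma(params) * (1.0 - decay)
    return max(0.0, raw) if clamp else raw


def equilibrium_r(params: ModelParameters, tau: float, *, clamp: bool = True) -> float:
    """Long-term SIM prevalence under recurrent stress at cycle length ``tau``.

    Identical to the non-recurrent formula except that the Gamma term is
    multiplied by 1 + ((mu_R + nu_R)/nu_R) / (e^((mu_R + nu_R) tau) - 1),
    the penalty for resistance carrying over between episodes.  The factor
    exceeds 1 for every finite tau, so recurrent <= non-recurrent always.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    decay = math.exp(-params.mu_M * tau)
    k = params.mu_R + params.nu_R
    carryover = 1.0 + (k / params.nu_R) / math.expm1(k * tau)
    raw = decay - gamma(params) * (1.0 - decay) * carryover
    return max(0.0, raw) if clamp else raw


def critical_cycle_length(params: ModelParameters) -> float:
    """Largest cycle length maintaining the SIM allele under non-recurrent stress.

    tau_c = (1/mu_M) ln(1 + 1/Gamma); ``equilibrium_nr`` is positive
    exactly on (0, tau_c).
    """
    return math.log1p(1.0 / gamma(params)) / params.mu_M


def resistance_relaxation(p_R0: float, t: float, params: ModelParameters) -> float:
    """Resistance frequency after ``t`` time units of mutation-only dynamics.

    Two-state linear relaxation toward mutation balance
    eps = nu_R/(mu_R + nu_R) at rate mu_R + nu_R:
    eps + (p_R0 - eps) e^(-(mu_R + nu_R) t).
    """
    if not 0.0 <= p_R0 <= 1.0:
        raise ValueError(f"p_R0 must lie in [0, 1], got {p_R0}")
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    eps = params.epsilon
    return eps + (p_R0 - eps) * math.exp(-(params.mu_R + params.nu_R) * t)


def heuristic_multistress_equilibrium(params: ModelParameters, tau: float, chi: int) -> float:
    """Approximate long-term SIM prevalence for ``chi`` cyclically applied stresses.

    With ``chi`` stresses each cognate stress recurs every ``chi * tau``
    time units, so the resistance met at its onset has relaxed from (near)
    fixation over all the intervening time, ``chi * tau - tau_S``.  The
    hitchhiking factor computed from that relaxed frequency is fed into
    the one-cycle recursion (SIM decay over the full cycle ``tau``), whose
    fixed point is returned.  At chi = 1 (and short stress pulses) this
    reduces to the recurrent-regime formula; as chi grows the relaxation
    completes and the value approaches the non-recurrent one.  Because
    linkage between resistance loci is ignored, the heuristic
    overestimates the simulated prevalence.
    """
    if chi < 1:
        raise ValueError(f"chi must be >= 1, got {chi}")
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    window = chi * tau - params.tau_S
    if window <= 0:
        raise ValueError("relaxation window chi*tau - tau_S must be positive")
    p_R_end = resistance_relaxation(1.0, window, params)
    lam = lambda_factor(p_R_end, params)
    return recursion_fixed_point(lam, params.mu_M, tau)


@dataclass(frozen=True)
class AnalyticSummary:
    """Closed-form quantities for one parameter set at one cycle length."""

    gamma: float
    lambda_: float
    tau_c: float
    p_hat_nr: float
    p_hat_r: float
    p_hat_nr_raw: float
    p_hat_r_raw: float

    def as_record(self) -> dict[str, float]:
        return {
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "tau_c": self.tau_c,
            "p_hat_nr": self.p_hat_nr,
            "p_hat_r": self.p_hat_r,
            "p_hat_nr_raw": self.p_hat_nr_raw,
            "p_hat_r_raw": self.p_hat_r_raw,
        }


def summarize(params: ModelParameters, tau: float | None = None) -> AnalyticSummary:
    """All closed-form quantities at cycle length ``tau`` (default tau_S + tau_NS)."""
    if tau is None:
        tau = params.tau
    g = gamma(params)
    return AnalyticSummary(
        gamma=g,
        lambda_=1.0 / g,  # non-recurrent value: p_R at mutation balance
        tau_c=critical_cycle_length(params),
        p_hat_nr=equilibrium_nr(params, tau),
        p_hat_r=equilibrium_r(params, tau),
        p_hat_nr_raw=equilibrium_nr(params, tau, clamp=False),
        p_hat_r_raw=equilibrium_r(params, tau, clamp=False),
    )
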