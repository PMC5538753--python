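"""Two-locus (four-genotype) SIM dynamics and stress-cycle iteration.

Genotype order throughout is ``(mr, Mr, mR, MR)``: the first letter is the
SIM locus (``M`` = mutator present), the second the resistance locus
(``R`` = resistant).

Two flows act on the frequency vector ``p``:

* **no stress** — pure mutation, a linear system ``dp/dt = M0 p`` whose
  matrix exponential gives the exact phase propagator;
* **stress** — resistant genotypes gain fitness ``1 + s`` (replicator
  term), and the susceptible mutator genotype ``Mr`` has all its outgoing
  mutation rates amplified by ``sigma``.

Long-term behaviour is probed by iterating cycles of stress (``tau_S``)
and no stress (``tau_NS``).  In the recurrent regime (``R``) the same
stress returns every cycle; in the non-recurrent regime (``NR``) each
stress is novel, modelled by resetting the resistance marginal to mutation
balance before every stress while preserving the SIM marginal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import ModelParameters

__all__ = [
    "GENOTYPES",
    "TwoLocusState",
    "EquilibriumResult",
    "InvalidStateError",
    "IntegrationError",
    "no_stress_derivative",
    "stress_derivative",
    "mutation_matrix",
    "integrate_phase",
    "nr_reset",
    "run_cycles",
]

GENOTYPES = ("mr", "Mr", "mR", "MR")

_SUM_TOL = 1e-9
_RENORM_TOL = 1e-12


class InvalidStateError(ValueError):
    """A genotype-frequency vector is non-finite, negative, or unnormalized."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the solver message as diagnostics."""


@dataclass(frozen=True)
class TwoLocusState:
    """Genotype frequencies ``(p_mr, p_Mr, p_mR, p_MR)`` at a time point."""

    p: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.shape != (4,):
            raise InvalidStateError(f"expected 4 genotype frequencies, got shape {self.p.shape}")

    # marginal frequencies
    @property
    def p_mr(self) -> float:
        return float(self.p[0])

    @property
    def p_Mr(self) -> float:
        return float(self.p[1])

    @property
    def p_mR(self) -> float:
        return float(self.p[2])

    @property
    def p_MR(self) -> float:
        return float(self.p[3])

    @property
    def p_M(self) -> float:
        """SIM-allele frequency p_Mr + p_MR."""
        return float(self.p[1] + self.p[3])

    @property
    def p_R(self) -> float:
        """Resistance-allele frequency p_mR + p_MR."""
        return float(self.p[2] + self.p[3])

    def validate(self) -> "TwoLocusState":
        if not np.all(np.isfinite(self.p)):
            raise InvalidStateError(f"non-finite frequencies {self.p}")
        if np.any(self.p < -_RENORM_TOL):
            raise InvalidStateError(f"negative frequencies {self.p}")
        if abs(self.p.sum() - 1.0) > _SUM_TOL:
            raise InvalidStateError(f"frequencies sum to {self.p.sum()}, not 1")
        return self

    @classmethod
    def from_marginals(cls, p_M: float, p_R: float, time: float = 0.0) -> "TwoLocusState":
        """Product state with independent loci at the given allele frequencies."""
        if not (0.0 <= p_M <= 1.0 and 0.0 <= p_R <= 1.0):
            raise InvalidStateError("marginal frequencies must lie in [0, 1]")
        p = np.array(
            [
                (1 - p_M) * (1 - p_R),
                p_M * (1 - p_R),
                (1 - p_M) * p_R,
                p_M * p_R,
            ]
        )
        return cls(p=p, time=time)

    def as_record(self) -> dict[str, float]:
        """JSON-serializable snapshot."""
        return {
            "time": self.time,
            "p_mr": self.p_mr,
            "p_Mr": self.p_Mr,
            "p_mR": self.p_mR,
            "p_MR": self.p_MR,
        }


@dataclass
class EquilibriumResult:
    """Outcome of iterating stress/no-stress cycles.

    ``p_hat_M`` is the long-term SIM prevalence; ``converged`` is one of
    ``"equilibrium"``, ``"extinct"``, or ``"iteration-cap"``.  ``history``
    holds per-cycle ``(p_M, p_R)`` samples taken at the end of each
    no-stress phase, i.e. immediately before the next stress.
    """

    p_hat_M: float
    converged: str
    n_cycles: int
    history: list[tuple[float, float]] = field(default_factory=list)
    final_state: TwoLocusState | None = None


def _as_vector(state: TwoLocusState | np.ndarray) -> np.ndarray:
    p = state.p if isinstance(state, TwoLocusState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidStateError(f"non-finite state components {p}")
    return p


def mutation_matrix(params: ModelParameters, stress: bool = False) -> np.ndarray:
    """Mutation-rate matrix ``M`` with ``dp/dt = M p`` (columns sum to 0).

    Under stress the susceptible mutator genotype ``Mr`` has all outgoing
    rates amplified by ``sigma``; without stress no amplification occurs.
    Gain of the SIM allele (m -> M) is neglected.
    """
    mu_M, mu_R, nu_R = params.mu_M, params.mu_R, params.nu_R
    a = params.sigma if stress else 1.0  # amplification of Mr outflow
    #          from:  mr          Mr              mR      MR
    return np.array(
        [
            [-nu_R,        a * mu_M,              mu_R,   0.0],            # mr
            [0.0,          -a * (mu_M + nu_R),    0.0,    mu_R],           # Mr
            [nu_R,         0.0,                   -mu_R,  mu_M],           # mR
            [0.0,          a * nu_R,              0.0,    -(mu_M + mu_R)], # MR
        ]
    )


def no_stress_derivative(state: TwoLocusState | np.ndarray, params: ModelParameters) -> np.ndarray:
    """Right-hand side of the no-stress (pure mutation) flow."""
    p = _as_vector(state)
    return mutation_matrix(params, stress=False) @ p


def stress_derivative(state: TwoLocusState | np.ndarray, params: ModelParameters) -> np.ndarray:
    """Right-hand side of the stress flow: selection on R plus amplified mutation."""
    p = _as_vector(state)
    p_R = p[2] + p[3]
    selection = params.s * np.array(
        [-p[0] * p_R, -p[1] * p_R, p[2] * (1 - p_R), p[3] * (1 - p_R)]
    )
    return selection + mutation_matrix(params, stress=True) @ p


def _renormalize(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if abs(total - 1.0) > _RENORM_TOL:
        p = p / total
    return p


def integrate_phase(
    state: TwoLocusState,
    params: ModelParameters,
    duration: float,
    environment: str,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    propagator: np.ndarray | None = None,
) -> TwoLocusState:
    """Advance ``state`` through one environmental phase.

    ``environment`` is ``"stress"`` or ``"no_stress"``.  The no-stress flow
    is linear, so it is propagated exactly with the matrix exponential of
    the mutation matrix (``propagator`` may supply a precomputed
    ``expm(M0 * duration)`` to amortize repeated cycles).  The stress flow
    is nonlinear (replicator term) and is integrated adaptively.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    p0 = _as_vector(state)
    if duration == 0:
        return state

    if environment == "no_stress":
        P = propagator if propagator is not None else expm(mutation_matrix(params) * duration)
        p1 = P @ p0
    elif environment == "stress":
        sol = solve_ivp(
            lambda _t, p: stress_derivative(p, params),
            (0.0, duration),
            p0,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise IntegrationError(f"stress-phase integration failed: {sol.message}")
        p1 = sol.y[:, -1]
    else:
        raise ValueError(f"environment must be 'stress' or 'no_stress', got {environment!r}")

    return TwoLocusState(p=_renormalize(p1), time=state.time + duration)


def nr_reset(state: TwoLocusState, params: ModelParameters) -> TwoLocusState:
    """Replace resistance by mutation balance ahead of a never-seen stress.

    The SIM marginal is preserved; the resistance marginal is set to
    ``epsilon = nu_R / (mu_R + nu_R)`` and the two loci become independent:
    ``((1-e)(p_mr+p_mR), (1-e)(p_Mr+p_MR), e(p_mr+p_mR), e(p_Mr+p_MR))``.
    """
    p = _as_vector(state)
    eps = params.epsilon
    p_m = p[0] + p[2]
    p_M = p[1] + p[3]
    return TwoLocusState(
        p=np.array([(1 - eps) * p_m, (1 - eps) * p_M, eps * p_m, eps * p_M]),
        time=state.time,
    )


def default_initial_state(params: ModelParameters) -> TwoLocusState:
    """SIM allele at 0.5, resistance at mutation balance, loci independent.

    The long-term prevalence is independent of the interior starting point,
    so any 0 < p_M(0) < 1 gives the same equilibrium.
    """
    return TwoLocusState.from_marginals(0.5, params.epsilon)


def run_cycles(
    initial: TwoLocusState | None,
    params: ModelParameters,
    regime: str,
    max_cycles: int = 10_000,
    convergence_tol: float = 1e-9,
    extinction_tol: float = 1e-10,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    consecutive: int = 3,
    decline_floor: float = 1e-6,
) -> EquilibriumResult:
    """Iterate stress/no-stress cycles until equilibrium, extinction, or the cap.

    Each cycle is: (``NR`` only: reset resistance to mutation balance) ->
    stress for ``tau_S`` -> no stress for ``tau_NS`` -> sample
    ``(p_M, p_R)``.  Equilibrium is declared when the sampled ``p_M``
    changes by less than ``convergence_tol`` for ``consecutive``
    consecutive cycles; extinction when ``p_M`` falls below
    ``extinction_tol`` while declining (the infinite-population frequency
    never reaches 0 exactly, so ``p_hat_M`` is then set to 0).

    A geometrically declining trajectory has per-cycle changes that shrink
    below ``convergence_tol`` long before the frequency itself reaches the
    extinction threshold; to avoid misreading such asymptotic loss as an
    interior equilibrium, convergence is not declared while the samples
    are still strictly declining below ``decline_floor``.
    """
    if regime not in ("R", "NR"):
        raise ValueError(f"regime must be 'R' or 'NR', got {regime!r}")
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")

    state = default_initial_state(params) if initial is None else initial.validate()

    if state.p_M <= 0.0:
        # no back-mutation into M: identically zero forever
        return EquilibriumResult(p_hat_M=0.0, converged="extinct", n_cycles=1,
                                 history=[(0.0, state.p_R)], final_state=state)

    propagator = expm(mutation_matrix(params) * params.tau_NS)

    history: list[tuple[float, float]] = []
    prev_p_M: float | None = None
    n_stable = 0
    for cycle in range(1, max_cycles + 1):
        if regime == "NR":
            state = nr_reset(state, params)
        state = integrate_phase(state, params, params.tau_S, "stress", rtol=rtol, atol=atol)
        state = integrate_phase(
            state, params, params.tau_NS, "no_stress", propagator=propagator
        )
        p_M, p_R = state.p_M, state.p_R
        history.append((p_M, p_R))

        if prev_p_M is not None:
            if p_M < extinction_tol and p_M < prev_p_M:
                return EquilibriumResult(
                    p_hat_M=0.0, converged="extinct", n_cycles=cycle,
                    history=history, final_state=state,
                )
            declining_to_zero = p_M < decline_floor and p_M < prev_p_M
            if abs(p_M - prev_p_M) < convergence_tol and not declining_to_zero:
                n_stable += 1
                if n_stable >= consecutive:
                    return EquilibriumResult(
                        p_hat_M=p_M, converged="equilibrium", n_cycles=cycle,
                        history=history, final_state=state,
                    )
            else:
                n_stable = 0
        prev_p_M = p_M

    return EquilibriumResult(
        p_hat_M=history[-1][0], converged="iteration-cap", n_cycles=max_cycles,
        history=history, final_state=state,
    )
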