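"""Multi-stress SIM dynamics on the 2^(chi+1)-genotype hypercube.

For ``chi`` distinct stresses the genome carries the SIM locus plus one
resistance locus per stress, all completely linked, giving ``2**(chi+1)``
genotypes encoded as bit masks: bit 0 is the SIM locus (1 = mutator allele
``M`` present), bits 1..chi the resistance loci (1 = resistant to stress
``i``).  Only single point mutations occur, so the mutation-rate matrix is
supported on single-bit neighbors of the genotype hypercube.

Fitness is additive over currently applied stresses (resistance to each
active stress contributes ``+s``; no cross-resistance, no epistasis), and
the SIM allele amplifies *all* outgoing mutation rates of a genotype by
``sigma`` whenever that genotype carries ``M`` and is susceptible to at
least one active stress.

Schedules are sequences of (active stress set, tau_S, tau_NS) phases,
either deterministically cyclic or drawn uniformly at random per phase
from the available stresses (seeded, hence reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .model_core import IntegrationError, InvalidStateError
from .params import ModelParameters

__all__ = [
    "GenotypeSpace",
    "MultiState",
    "StressSchedule",
    "MultistressResult",
    "build_space",
    "fitness_vector",
    "mutation_rate_matrix",
    "multistress_derivative",
    "initial_state",
    "simulate_schedule",
    "multiresistance_frequencies",
]

_MAX_CHI = 12  # 2^13 genotypes; dense linear algebra stays trivial below this
_SUM_TOL = 1e-9
_RENORM_TOL = 1e-12


@dataclass(frozen=True)
class GenotypeSpace:
    """Bit-encoded genotype space for 1 SIM locus + ``chi`` resistance loci."""

    chi: int

    @property
    def n_genotypes(self) -> int:
        return 2 ** (self.chi + 1)

    def has_sim(self, g: int) -> bool:
        return bool(g & 1)

    def is_resistant(self, g: int, stress: int) -> bool:
        """Whether genotype ``g`` is resistant to stress ``stress`` (1-based)."""
        if not 1 <= stress <= self.chi:
            raise ValueError(f"stress index must be in 1..{self.chi}, got {stress}")
        return bool(g >> stress & 1)

    def resistance_count(self, g: int) -> int:
        return bin(g >> 1).count("1")

    def label(self, g: int) -> str:
        sim = "M" if self.has_sim(g) else "m"
        res = "".join(
            "R" if g >> i & 1 else "r" for i in range(1, self.chi + 1)
        )
        return sim + res

    # boolean lookup tables, used to vectorize matrix construction
    def sim_mask(self) -> np.ndarray:
        return (np.arange(self.n_genotypes) & 1).astype(bool)

    def resistance_matrix(self) -> np.ndarray:
        """(n_genotypes, chi) boolean array: genotype g resistant to stress i+1."""
        g = np.arange(self.n_genotypes)[:, None]
        return (g >> np.arange(1, self.chi + 1)[None, :] & 1).astype(bool)


def build_space(chi: int) -> GenotypeSpace:
    """Genotype space for ``chi`` distinct stresses (2^(chi+1) genotypes)."""
    if chi < 1:
        raise ValueError(f"chi must be >= 1, got {chi}")
    if chi > _MAX_CHI:
        raise ValueError(f"chi = {chi} exceeds the dense-representation cap of {_MAX_CHI}")
    return GenotypeSpace(chi=chi)


@dataclass(frozen=True)
class MultiState:
    """Frequency vector over a genotype space at a time point."""

    frequencies: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )

    def validate(self, space: GenotypeSpace) -> "MultiState":
        p = self.frequencies
        if p.shape != (space.n_genotypes,):
            raise InvalidStateError(
                f"expected {space.n_genotypes} frequencies, got shape {p.shape}"
            )
        if not np.all(np.isfinite(p)):
            raise InvalidStateError("non-finite frequencies")
        if np.any(p < -_RENORM_TOL):
            raise InvalidStateError("negative frequencies")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise InvalidStateError(f"frequencies sum to {p.sum()}, not 1")
        return self

    def p_M(self, space: GenotypeSpace) -> float:
        return float(self.frequencies[space.sim_mask()].sum())

    def p_R(self, space: GenotypeSpace, stress: int) -> float:
        res = space.resistance_matrix()[:, stress - 1]
        return float(self.frequencies[res].sum())


def _validate_active(space: GenotypeSpace, active: frozenset[int] | set[int]) -> frozenset[int]:
    active = frozenset(active)
    if not all(1 <= i <= space.chi for i in active):
        raise ValueError(f"active stresses {sorted(active)} not within 1..{space.chi}")
    return active


def fitness_vector(space: GenotypeSpace, active: frozenset[int] | set[int], s: float) -> np.ndarray:
    """Marginal fitness w(g) = 1 + s * (number of active stresses g resists).

    Additive over simultaneous stresses; independent of the SIM bit.
    """
    active = _validate_active(space, active)
    w = np.ones(space.n_genotypes)
    if active:
        res = space.resistance_matrix()
        idx = [i - 1 for i in sorted(active)]
        w += s * res[:, idx].sum(axis=1)
    return w


def mutation_rate_matrix(
    space: GenotypeSpace, params: ModelParameters, active: frozenset[int] | set[int] = frozenset()
) -> np.ndarray:
    """Rate matrix Q with dp/dt = Q p (columns sum to zero).

    Single point mutations only: the SIM allele is lost at ``mu_M`` (never
    gained), each resistance allele is gained at ``nu_R`` and lost at
    ``mu_R`` independently.  All outgoing rates of a genotype are
    multiplied by ``sigma`` iff it carries ``M`` and is susceptible to at
    least one stress in ``active`` (stress does not activate SIM in fully
    resistant individuals).
    """
    active = _validate_active(space, active)
    n = space.n_genotypes
    Q = np.zeros((n, n))
    for g in range(n):
        amplify = (
            params.sigma
            if active
            and space.has_sim(g)
            and any(not space.is_resistant(g, i) for i in active)
            else 1.0
        )
        if space.has_sim(g):
            Q[g ^ 1, g] += amplify * params.mu_M
        for i in range(1, space.chi + 1):
            bit = 1 << i
            rate = params.mu_R if g & bit else params.nu_R
            Q[g ^ bit, g] += amplify * rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=0))
    return Q


def multistress_derivative(
    state: MultiState | np.ndarray,
    space: GenotypeSpace,
    params: ModelParameters,
    active: frozenset[int] | set[int],
    *,
    Q: np.ndarray | None = None,
    w: np.ndarray | None = None,
) -> np.ndarray:
    """Replicator-mutator right-hand side dp/dt = p (w - wbar) + Q p.

    ``Q`` and ``w`` may be precomputed for the active set to amortize
    repeated evaluation within one phase.
    """
    p = state.frequencies if isinstance(state, MultiState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(p)):
        raise InvalidStateError("non-finite state components")
    if Q is None:
        Q = mutation_rate_matrix(space, params, active)
    if w is None:
        w = fitness_vector(space, active, params.s)
    wbar = float(p @ w)
    return p * (w - wbar) + Q @ p


def initial_state(space: GenotypeSpace, params: ModelParameters, p_M0: float = 0.5) -> MultiState:
    """Product state: SIM at ``p_M0``, each resistance locus at mutation balance."""
    eps = params.epsilon
    sim = np.where(space.sim_mask(), p_M0, 1.0 - p_M0)
    res = space.resistance_matrix()
    p = sim * np.prod(np.where(res, eps, 1.0 - eps), axis=1)
    return MultiState(frequencies=p, time=0.0)


def multiresistance_frequencies(state: MultiState, space: GenotypeSpace) -> np.ndarray:
    """Total frequency of genotypes resistant to exactly k stresses, k = 0..chi."""
    counts = np.array([space.resistance_count(g) for g in range(space.n_genotypes)])
    return np.bincount(counts, weights=state.frequencies, minlength=space.chi + 1)


@dataclass(frozen=True)
class StressSchedule:
    """Ordered stress phases; each phase is (active set, tau_S, tau_NS).

    ``mode`` is ``"cyclic"`` (the phase list repeats until convergence) or
    ``"randomized"`` (the phase list is run exactly once, no repetition;
    its length is ``n_iterations`` and it is a deterministic function of
    ``seed``).
    """

    phases: tuple[tuple[frozenset[int], float, float], ...]
    mode: str = "cyclic"
    seed: int | None = None
    n_iterations: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cyclic", "randomized"):
            raise ValueError(f"mode must be 'cyclic' or 'randomized', got {self.mode!r}")
        if not self.phases:
            raise ValueError("schedule must contain at least one phase")
        for active, tau_S, tau_NS in self.phases:
            if not active:
                raise ValueError("each phase must apply at least one stress")
            if tau_S <= 0 or tau_NS <= 0:
                raise ValueError("phase durations must be > 0")

    @classmethod
    def cyclic(cls, chi: int, tau_S: float, tau_NS: float) -> "StressSchedule":
        """Stresses 1..chi applied one at a time in fixed rotation."""
        return cls(
            phases=tuple((frozenset({i}), tau_S, tau_NS) for i in range(1, chi + 1)),
            mode="cyclic",
        )

    @classmethod
    def randomized(
        cls, chi: int, tau_S: float, tau_NS: float, seed: int, n_iterations: int
    ) -> "StressSchedule":
        """Each phase's stress drawn uniformly (with replacement) from 1..chi."""
        rng = np.random.default_rng(seed)
        picks = rng.integers(1, chi + 1, size=n_iterations)
        return cls(
            phases=tuple((frozenset({int(i)}), tau_S, tau_NS) for i in picks),
            mode="randomized",
            seed=seed,
            n_iterations=n_iterations,
        )

    @classmethod
    def combined(cls, chi: int, tau_S: float, tau: float) -> "StressSchedule":
        """All chi stresses simultaneously, recurring every ``tau`` time units."""
        if tau <= tau_S:
            raise ValueError("cycle length tau must exceed tau_S")
        return cls(
            phases=((frozenset(range(1, chi + 1)), tau_S, tau - tau_S),),
            mode="cyclic",
        )

    @classmethod
    def paired(cls, chi: int, tau_S: float, tau: float) -> "StressSchedule":
        """Stresses grouped in consecutive pairs, pairs alternating every tau/(chi/2).

        One cycle through all pairs takes ``tau``, so each pair recurs
        every ``tau`` time units.
        """
        if chi % 2:
            raise ValueError("paired schedule requires an even number of stresses")
        n_pairs = chi // 2
        period = tau / n_pairs
        if period <= tau_S:
            raise ValueError("per-pair period tau/(chi/2) must exceed tau_S")
        return cls(
            phases=tuple(
                (frozenset({2 * k + 1, 2 * k + 2}), tau_S, period - tau_S)
                for k in range(n_pairs)
            ),
            mode="cyclic",
        )

    @classmethod
    def sequential(cls, chi: int, tau_S: float, tau: float) -> "StressSchedule":
        """Each stress alone, in rotation, one full cycle taking ``tau``."""
        period = tau / chi
        if period <= tau_S:
            raise ValueError("per-stress period tau/chi must exceed tau_S")
        return cls(
            phases=tuple(
                (frozenset({i}), tau_S, period - tau_S) for i in range(1, chi + 1)
            ),
            mode="cyclic",
        )

    def as_records(self) -> list[dict]:
        """JSON-serializable phase list."""
        return [
            {"active": sorted(a), "tau_S": ts, "tau_NS": tn} for a, ts, tn in self.phases
        ]


@dataclass
class MultistressResult:
    """Outcome of a multi-stress schedule simulation.

    ``history`` holds the p_M samples taken at the end of each no-stress
    phase (immediately before the next stress).  For randomized schedules
    ``mean``/``sd`` summarize the tail of the sample series; ``converged``
    is then always ``"iteration-cap"`` (the run has a fixed length).
    """

    p_hat_M: float
    converged: str
    n_cycles: int
    history: list[float] = field(default_factory=list)
    final_state: MultiState | None = None
    mean: float | None = None
    sd: float | None = None
    trajectory: list[dict] = field(default_factory=list)


def _renormalize(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, None)
    total = p.sum()
    if abs(total - 1.0) > _RENORM_TOL:
        p = p / total
    return p


class _PhaseIntegrator:
    """Caches per-active-set matrices and no-stress propagators for a run."""

    def __init__(self, space: GenotypeSpace, params: ModelParameters,
                 rtol: float, atol: float):
        self.space = space
        self.params = params
        self.rtol = rtol
        self.atol = atol
        self._stress: dict[frozenset[int], tuple[np.ndarray, np.ndarray]] = {}
        self._relax: dict[float, np.ndarray] = {}
        self._Q0 = mutation_rate_matrix(space, params, frozenset())

    def stress_phase(self, p: np.ndarray, active: frozenset[int], duration: float) -> np.ndarray:
        if active not in self._stress:
            self._stress[active] = (
                mutation_rate_matrix(self.space, self.params, active),
                fitness_vector(self.space, active, self.params.s),
            )
        Q, w = self._stress[active]

        def rhs(_t: float, p_: np.ndarray) -> np.ndarray:
            wbar = p_ @ w
            return p_ * (w - wbar) + Q @ p_

        sol = solve_ivp(rhs, (0.0, duration), p, method="LSODA",
                        rtol=self.rtol, atol=self.atol)
        if not sol.success:
            raise IntegrationError(f"stress-phase integration failed: {sol.message}")
        return _renormalize(sol.y[:, -1])

    def no_stress_phase(self, p: np.ndarray, duration: float) -> np.ndarray:
        P = self._relax.get(duration)
        if P is None:
            P = expm(self._Q0 * duration)
            self._relax[duration] = P
        return _renormalize(P @ p)


def simulate_schedule(
    space: GenotypeSpace,
    params: ModelParameters,
    schedule: StressSchedule,
    max_supercycles: int = 10_000,
    convergence_tol: float = 1e-9,
    extinction_tol: float = 1e-10,
    *,
    initial: MultiState | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    consecutive: int = 3,
    decline_floor: float = 1e-6,
    n_last: int = 1_000,
    record_trajectory: bool = False,
) -> MultistressResult:
    """Run a stress schedule to its long-term SIM prevalence.

    Cyclic schedules iterate the phase list as super-cycles; convergence
    is assessed on the vector of per-phase p_M samples of whole
    super-cycles (max change < ``convergence_tol`` for ``consecutive``
    super-cycles), extinction when every sample falls below
    ``extinction_tol`` while declining.  Convergence is not declared while
    the samples are still strictly declining below ``decline_floor``, so
    asymptotic loss is never misread as a tiny interior equilibrium.
    Randomized schedules run their
    phase list exactly once and report the mean and standard deviation of
    p_M over the last ``n_last`` samples.
    """
    state = initial_state(space, params) if initial is None else initial.validate(space)
    integ = _PhaseIntegrator(space, params, rtol, atol)

    p = state.frequencies.copy()
    t = state.time
    sim_mask = space.sim_mask()
    res_mat = space.resistance_matrix()
    history: list[float] = []
    trajectory: list[dict] = []

    def record(cycle: int, phase_index: int, active: frozenset[int]) -> float:
        p_M = float(p[sim_mask].sum())
        history.append(p_M)
        if record_trajectory:
            row = {
                "supercycle": cycle,
                "phase_index": phase_index,
                "active_stresses": "+".join(map(str, sorted(active))),
                "p_M": p_M,
            }
            for i in range(space.chi):
                row[f"p_R_{i + 1}"] = float(p[res_mat[:, i]].sum())
            multi = np.bincount(
                [space.resistance_count(g) for g in range(space.n_genotypes)],
                weights=p, minlength=space.chi + 1,
            )
            for k, freq in enumerate(multi):
                row[f"multiresistance_{k}"] = float(freq)
            trajectory.append(row)
        return p_M

    def finish(p_hat: float, status: str, n: int) -> MultistressResult:
        result = MultistressResult(
            p_hat_M=p_hat, converged=status, n_cycles=n, history=history,
            final_state=MultiState(frequencies=p, time=t), trajectory=trajectory,
        )
        if schedule.mode == "randomized":
            tail = np.array(history[-min(n_last, len(history)):])
            result.mean = float(tail.mean())
            result.sd = float(tail.std(ddof=0))
            result.p_hat_M = result.mean
        return result

    if schedule.mode == "randomized":
        for k, (active, tau_S, tau_NS) in enumerate(schedule.phases):
            p = integ.stress_phase(p, active, tau_S)
            p = integ.no_stress_phase(p, tau_NS)
            t += tau_S + tau_NS
            record(k, k, active)
        return finish(history[-1], "iteration-cap", len(schedule.phases))

    prev_samples: np.ndarray | None = None
    n_stable = 0
    for cycle in range(1, max_supercycles + 1):
        samples = np.empty(len(schedule.phases))
        for j, (active, tau_S, tau_NS) in enumerate(schedule.phases):
            p = integ.stress_phase(p, active, tau_S)
            p = integ.no_stress_phase(p, tau_NS)
            t += tau_S + tau_NS
            samples[j] = record(cycle, j, active)
        if prev_samples is not None:
            if samples.max() < extinction_tol and samples.max() < prev_samples.max():
                return finish(0.0, "extinct", cycle)
            declining_to_zero = (
                samples.max() < decline_floor and samples.max() < prev_samples.max()
            )
            if (
                np.max(np.abs(samples - prev_samples)) < convergence_tol
                and not declining_to_zero
            ):
                n_stable += 1
                if n_stable >= consecutive:
                    return finish(float(samples[-1]), "equilibrium", cycle)
            else:
                n_stable = 0
        prev_samples = samples
    return finish(history[-1], "iteration-cap", max_supercycles)
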