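"""Model parameters for the stress-induced mutagenesis (SIM) model.

The model tracks a haploid population with a stress-activated mutator locus
(alleles ``M``/``m``) completely linked to one or more resistance loci
(alleles ``R``/``r``).  Five rates govern the dynamics:

``s``
    selective advantage of a resistance allele while its cognate stress is
    applied (per unit time),
``sigma``
    factor (> 1) by which the SIM allele amplifies all outgoing mutation
    rates of a stressed, susceptible carrier,
``mu_M``
    loss rate of the SIM allele (per unit time; no back-mutation),
``mu_R`` / ``nu_R``
    loss / gain rate of a resistance allele (per unit time).

Stress arrives in cycles: a stress phase of length ``tau_S`` followed by a
no-stress phase of length ``tau_NS``; the cycle length is
``tau = tau_S + tau_NS``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace


class ParameterHierarchyWarning(UserWarning):
    """The parameters violate the assumed ordering s >> (mu_M, mu_R) >> nu_R.

    The closed-form equilibria are derived in a strong-selection /
    weak-gain-of-resistance limit; outside it they may be inaccurate, but
    the simulators remain valid, so a violation warns instead of raising.
    """


@dataclass(frozen=True)
class ModelParameters:
    """Rates and phase durations of the SIM model.

    All rates are per unit time and strictly positive; ``sigma`` must
    exceed 1 (a SIM allele that does not raise mutation rates is no
    mutator).  ``tau_S``/``tau_NS`` default to the single-stress cycling
    benchmark (short stress pulses, cycle length 100).
    """

    s: float
    sigma: float
    mu_M: float
    mu_R: float
    nu_R: float
    tau_S: float = 10.0
    tau_NS: float = 90.0

    def __post_init__(self) -> None:
        for name in ("s", "sigma", "mu_M", "mu_R", "nu_R", "tau_S", "tau_NS"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"{name} must be a finite number, got {value!r}")
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.sigma <= 1:
            raise ValueError(f"sigma must exceed 1, got {self.sigma!r}")

    @property
    def tau(self) -> float:
        """Full cycle length tau_S + tau_NS."""
        return self.tau_S + self.tau_NS

    @property
    def epsilon(self) -> float:
        """Mutation-balance frequency nu_R / (mu_R + nu_R) of a resistance allele."""
        return self.nu_R / (self.mu_R + self.nu_R)

    def hierarchy_satisfied(self, factor: float = 10.0) -> bool:
        """Whether s >> (mu_M, mu_R) >> nu_R holds, reading ">>" as ">= factor x"."""
        return (
            self.s >= factor * max(self.mu_M, self.mu_R)
            and min(self.mu_M, self.mu_R) >= factor * self.nu_R
        )

    def check_hierarchy(self, factor: float = 10.0) -> bool:
        """Warn (``ParameterHierarchyWarning``) if the rate hierarchy is violated.

        Returns True when the hierarchy holds.  Violations are legitimate
        inputs — the simulators do not rely on the hierarchy — but the
        closed-form predictions do, hence a warning rather than an error.
        """
        ok = self.hierarchy_satisfied(factor)
        if not ok:
            warnings.warn(
                "parameter hierarchy s >> (mu_M, mu_R) >> nu_R violated "
                f"(s={self.s}, mu_M={self.mu_M}, mu_R={self.mu_R}, "
                f"nu_R={self.nu_R}); analytic predictions may be inaccurate",
                ParameterHierarchyWarning,
                stacklevel=2,
            )
        return ok

    def with_durations(self, tau_S: float | None = None, tau_NS: float | None = None) -> "ModelParameters":
        """Copy with replaced phase durations."""
        kwargs = {}
        if tau_S is not None:
            kwargs["tau_S"] = tau_S
        if tau_NS is not None:
            kwargs["tau_NS"] = tau_NS
        return replace(self, **kwargs)


#: Benchmark set for single-stress cycling: strong selection (s = 1), potent
#: SIM allele (sigma = 100), resistance lost 100x faster than gained.
REFERENCE_PARAMS = ModelParameters(s=1.0, sigma=100.0, mu_M=1e-3, mu_R=1e-2, nu_R=1e-4)

#: Benchmark set for multi-drug treatment comparisons: weaker per-drug
#: selection (s = 0.5) and slower resistance loss (mu_R = 5e-3).
TREATMENT_PARAMS = ModelParameters(s=0.5, sigma=100.0, mu_M=1e-3, mu_R=5e-3, nu_R=1e-4)
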