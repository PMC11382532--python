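"""Closed-form planning of the Fill-it-up two-stage design.

The Fill-it-up design augments a two-arm superiority trial (experimental
treatment E versus control C, continuous endpoint, variance standardized
to 1) with ``n_H`` historical controls.  Stage 1 randomizes a fraction
``gamma`` of the maximum sample size.  An equivalence pre-test then compares
the randomized and historical control means: if equivalence within a margin
``Delta`` can be shown, the historical controls are pooled with the
randomized controls and superiority is tested immediately (test S1);
otherwise randomization is extended to the full sample size and superiority
is tested on randomized patients only (test S2).

This module provides the planning arithmetic: one-step sample sizes for a
z-test, the stage-1 fraction ``gamma`` that makes S1 and S2 equally powered,
admissible bounds for the equivalence margin, the variance-optimal pooling
weight, and the average sample size of the two-stage procedure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

from scipy.stats import norm

__all__ = [
    "DesignSpec",
    "StagePlan",
    "MarginBounds",
    "one_step_sample_size",
    "gamma_balanced",
    "gamma_general",
    "stage_plan",
    "margin_bounds",
    "optimal_weight",
    "average_sample_size",
]

# absolute slack used before applying a ceiling so that values that are an
# integer up to floating-point noise are not rounded one unit too far up
_CEIL_EPS = 1e-9


def _ceil(x: float) -> int:
    return int(math.ceil(x - _CEIL_EPS))


class InvalidParameterError(ValueError):
    """A design parameter violates its admissible range."""


class InfeasibleDesignError(ValueError):
    """No admissible design exists for the requested parameters."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise InvalidParameterError(f"{name} must lie in (0, 1), got {value!r}")


@dataclass(frozen=True)
class DesignSpec:
    """All planning-time parameters of the design.

    Parameters
    ----------
    delta
        Anticipated effect size ``mu_E - mu_C`` in standardized units
        (all response variances are fixed at 1).
    alpha_ept
        Nominal two-sided level of the equivalence pre-test.
    alpha_s1, alpha_s2
        One-sided levels of the pooled (S1) and the extended-randomization
        (S2) superiority tests.
    beta_s1, beta_s2
        Type-II error probabilities of S1 and S2 at effect ``delta``.
    n_h
        Number of available historical controls.
    margin
        Equivalence margin ``Delta`` (may be left unset during early
        planning; must be positive once set).
    """

    delta: float
    alpha_ept: float = 0.05
    alpha_s1: float = 0.05
    alpha_s2: float = 0.05
    beta_s1: float = 0.2
    beta_s2: float = 0.2
    n_h: int = 0
    margin: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise InvalidParameterError(f"delta must be positive, got {self.delta!r}")
        for name in ("alpha_ept", "alpha_s1", "alpha_s2", "beta_s1", "beta_s2"):
            _check_prob(name, getattr(self, name))
        if self.n_h < 0 or int(self.n_h) != self.n_h:
            raise InvalidParameterError(f"n_h must be a non-negative integer, got {self.n_h!r}")
        if self.margin is not None and self.margin <= 0:
            raise InvalidParameterError(f"margin must be positive, got {self.margin!r}")

    def with_margin(self, margin: float) -> "DesignSpec":
        return DesignSpec(**{**asdict(self), "margin": margin})


@dataclass(frozen=True)
class StagePlan:
    """Integer stage sizes of a planned Fill-it-up trial.

    ``n_e``/``n_c`` are the per-group stage-1 sizes, ``n_e2``/``n_c2`` the
    stage-2 additions, ``cap_n_e``/``cap_n_c`` the per-group totals,
    ``n_fiu`` the maximum total number of newly recruited patients and
    ``avn`` the average sample size accounting for the probability
    ``alpha_ept`` of stopping after stage 1.
    """

    n_e: int
    n_c: int
    n_e2: int
    n_c2: int
    gamma: float
    avn: int = 0

    @property
    def cap_n_e(self) -> int:
        return self.n_e + self.n_e2

    @property
    def cap_n_c(self) -> int:
        return self.n_c + self.n_c2

    @property
    def n_fiu(self) -> int:
        return self.cap_n_e + self.cap_n_c

    @property
    def stage1_total(self) -> int:
        return self.n_e + self.n_c

    def __post_init__(self) -> None:
        for name in ("n_e", "n_c", "n_e2", "n_c2"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise InvalidParameterError(f"{name} must be a non-negative integer, got {v!r}")

    def to_json(self) -> str:
        d = asdict(self)
        d.update(cap_n_e=self.cap_n_e, cap_n_c=self.cap_n_c, n_fiu=self.n_fiu,
                 stage1_total=self.stage1_total)
        return json.dumps(d, indent=2)


@dataclass(frozen=True)
class MarginBounds:
    """Admissible range for the equivalence margin ``Delta``.

    ``lower`` is the smallest margin for which the equivalence pre-test can
    reject at all; margins must stay strictly below ``upper`` (the effect
    size) so that the control groups may not differ by more than the
    treatment effect the trial is powered for.
    """

    lower: float
    upper: float

    @property
    def feasible(self) -> bool:
        return self.lower < self.upper


def one_step_sample_size(delta: float, alpha: float, beta: float) -> int:
    """Per-group sample size of a one-sided one-step z-test, balanced groups.

    Smallest integer ``n`` per group with
    ``n / 2 >= (z_{1-alpha} + z_{1-beta})**2 / delta**2``,
    i.e. the harmonic-mean sample-size identity
    ``N_E N_C / (N_E + N_C) = (z_{1-alpha} + z_{1-beta})**2 / delta**2``
    solved under ``N_E = N_C = n``.  The total is ``2 n``.
    """
    if delta <= 0:
        raise InvalidParameterError(f"delta must be positive, got {delta!r}")
    _check_prob("alpha", alpha)
    _check_prob("beta", beta)
    target = (norm.ppf(1 - alpha) + norm.ppf(1 - beta)) ** 2 / delta**2
    return _ceil(2 * target)


def gamma_balanced(n_per_group: int, n_h: int) -> float:
    """Stage-1 fraction for equal levels and balanced allocation.

    With per-group total ``N`` and ``n_H`` historical controls,

        gamma = (N - n_H + sqrt(N**2 + n_H**2)) / (2 N)

    which is the only positive root of the quadratic equating the effective
    sample sizes of the pooled and the extended superiority tests.  Always in
    ``[1/2, 1]``, equal to 1 when ``n_H = 0``, decreasing in ``n_H`` and
    tending to 1/2 as ``n_H`` grows.
    """
    if n_per_group < 1:
        raise InvalidParameterError("n_per_group must be >= 1")
    if n_h < 0:
        raise InvalidParameterError("n_h must be >= 0")
    n = float(n_per_group)
    return (n - n_h + math.hypot(n, n_h)) / (2 * n)


def gamma_general(spec: DesignSpec, cap_n_e: int, cap_n_c: int, n_h: int) -> float:
    """Stage-1 fraction for unequal levels or unbalanced totals.

    Solves the quadratic in ``gamma`` obtained by equating the effective
    sample size of the pooled test S1 (stage-1 patients plus historical
    controls) with that of the final test S2, scaled by the squared ratio of
    quantile sums

        q = ((z_{1-alpha_S1} + z_{1-beta_S1}) / (z_{1-alpha_S2} + z_{1-beta_S2}))**2.

    Only roots in ``(0, 1]`` are admissible; with two admissible roots the
    larger is returned.  Reduces to :func:`gamma_balanced` when the levels
    are equal and ``cap_n_e == cap_n_c``.
    """
    if cap_n_e < 1 or cap_n_c < 1:
        raise InvalidParameterError("per-group totals must be >= 1")
    q = (
        (norm.ppf(1 - spec.alpha_s1) + norm.ppf(1 - spec.beta_s1))
        / (norm.ppf(1 - spec.alpha_s2) + norm.ppf(1 - spec.beta_s2))
    ) ** 2
    h = n_h / cap_n_c
    disc = (h - q) ** 2 + 4 * n_h / (cap_n_e + cap_n_c) * q
    roots = [0.5 * (-h + q + s * math.sqrt(disc)) for s in (+1.0, -1.0)]
    admissible = [g for g in roots if 0.0 < g <= 1.0 + _CEIL_EPS]
    if not admissible:
        raise InfeasibleDesignError(
            f"no stage-1 fraction in (0, 1] exists (roots {roots!r})"
        )
    return min(max(admissible), 1.0)


def optimal_weight(n_h: int, n_c: int) -> float:
    """Variance-optimal weight of the historical mean in the pooled control.

    ``omega* = n_H / (n_H + n_C)`` minimizes
    ``omega**2 / n_H + (1 - omega)**2 / n_C``; at the optimum the pooled
    control mean has variance ``1 / (n_H + n_C)``, i.e. pooling simply
    concatenates the two control samples.
    """
    if n_h < 0 or n_c < 0 or n_h + n_c < 1:
        raise InvalidParameterError("need n_h + n_c >= 1 with non-negative counts")
    return n_h / (n_h + n_c)


def margin_bounds(
    n_c: int,
    n_h: int,
    alpha_ept: float,
    delta: float,
    *,
    two_sided: bool = False,
) -> MarginBounds:
    """Admissible range of the equivalence margin ``Delta``.

    The lower bound ``z_{1-alpha_Ept} * sqrt(1/n_H + 1/n_C)`` is the margin
    below which the pre-test can never reject its null hypothesis (the
    rejection region of the two one-sided tests is empty).  The upper bound
    is the effect size ``delta`` (exclusive).  With ``two_sided=True`` the
    quantile ``z_{1-alpha_Ept/2}`` is used instead, matching the critical
    value of the pre-test statistic itself rather than the conventional
    bound.
    """
    if n_c < 1 or n_h < 1:
        raise InvalidParameterError("margin bounds require n_c >= 1 and n_h >= 1")
    _check_prob("alpha_ept", alpha_ept)
    level = alpha_ept / 2 if two_sided else alpha_ept
    lower = norm.ppf(1 - level) * math.sqrt(1 / n_h + 1 / n_c)
    return MarginBounds(lower=lower, upper=delta)


def average_sample_size(plan: StagePlan, alpha_ept: float) -> int:
    """Average number of newly recruited patients of the two-stage design.

    The pre-test rejects (and the trial stops after stage 1) with
    probability ``alpha_ept`` under its null, so per group

        AVN_group = ceil(n_stage1 + (1 - alpha_ept) * n_stage2)

    and the reported AVN sums the per-group ceilings.
    """
    _check_prob("alpha_ept", alpha_ept)
    avn_e = _ceil(plan.n_e + (1 - alpha_ept) * plan.n_e2)
    avn_c = _ceil(plan.n_c + (1 - alpha_ept) * plan.n_c2)
    return avn_e + avn_c


def stage_plan(spec: DesignSpec) -> StagePlan:
    """Full planning chain: per-group total, stage-1 fraction, stage sizes.

    Computes the balanced per-group total for the final test S2 at
    ``(delta, alpha_s2, beta_s2)``, the stage-1 fraction from
    :func:`gamma_balanced` with ``n_H`` historical controls, per-group
    stage-1 sizes ``ceil(gamma * N)`` and the stage-2 remainders, and the
    average sample size at ``alpha_ept``.
    """
    n_per_group = one_step_sample_size(spec.delta, spec.alpha_s2, spec.beta_s2)
    gamma = gamma_balanced(n_per_group, spec.n_h)
    n1 = _ceil(gamma * n_per_group)
    n2 = n_per_group - n1
    plan = StagePlan(n_e=n1, n_c=n1, n_e2=n2, n_c2=n2, gamma=gamma)
    avn = average_sample_size(plan, spec.alpha_ept)
    return StagePlan(n_e=n1, n_c=n1, n_e2=n2, n_c2=n2, gamma=gamma, avn=avn)
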