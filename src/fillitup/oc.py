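"""Operating characteristics of the Fill-it-up design.

Family-wise error rate (FWER) and overall power are probabilities of events
in the joint distribution of the three test statistics
``(Z_Ept, Z_S1, Z_S2)``.  Because the two terminal tests partition the
sample space on the pre-test decision,

    FWER  = P(reject Ept and reject S1) + P(keep Ept and reject S2)
    power = 1 - [P(reject Ept and fail S1) + P(keep Ept and fail S2)]

Two analytic evaluation schemes are provided.

``normal-approx``
    treats the folded pre-test statistic ``Z_Ept`` as Gaussian with its
    stated mean ``(|mu_C - mu_H| - Delta)/se`` and unit variance, and uses
    the positive covariance ``Cov(Z_Ept, Z_S2)`` implied by the shared
    stage-1 controls.  This is the scheme in which the design's published
    operating characteristics are expressed and is the default.

``exact-folded``
    integrates the pre-test event exactly over both tails of the Gaussian
    difference ``ybar_C - ybar_H`` (the folded-normal treatment).  Near the
    equivalence boundary the two schemes differ: the normal approximation
    overstates the pre-test rejection probability there (at the boundary it
    gives ``alpha_Ept/2`` where the folded computation gives less).

``monte-carlo``
    delegates to :mod:`fillitup.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, multivariate_normal

from .design import DesignSpec, StagePlan, InvalidParameterError, optimal_weight

__all__ = [
    "ScenarioMeans",
    "JointMoments",
    "OCResult",
    "joint_moments",
    "fwer",
    "overall_power",
    "fwer_surface",
    "max_fwer",
]


@dataclass(frozen=True)
class ScenarioMeans:
    """True expected responses ``(mu_E, mu_C, mu_H)`` defining a scenario."""

    mu_e: float
    mu_c: float
    mu_h: float

    def __post_init__(self) -> None:
        for name in ("mu_e", "mu_c", "mu_h"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")


@dataclass(frozen=True)
class JointMoments:
    """First and second moments of ``(Z_Ept, Z_S1, Z_S2)``.

    ``Z_S1`` is normalized by the optimal-weight denominator
    ``sqrt(1/n_E + 1/(n_C + n_H))`` so that ``var_s1 = 1`` and
    ``cov_ept_s1 = 0`` exactly when ``omega = omega*``.  ``cov_ept_s2`` is
    reported for the orientation ``(ybar_C - ybar_H, ybar'_E - ybar'_C)``
    and is therefore negative; its magnitude is bounded by ``1/sqrt(2)``.
    """

    mu_ept: float
    mu_s1: float
    mu_s2: float
    var_s1: float
    cov_ept_s1: float
    cov_ept_s2: float


def joint_moments(
    scenario: ScenarioMeans,
    plan: StagePlan,
    n_h: int,
    margin: float,
    weight: Optional[float] = None,
) -> JointMoments:
    """Moments of the three test statistics under a truth configuration."""
    if margin <= 0:
        raise InvalidParameterError(f"margin must be positive, got {margin!r}")
    if weight is None:
        weight = optimal_weight(n_h, plan.n_c)
    se_ept = math.sqrt(1 / n_h + 1 / plan.n_c)
    se_s1 = math.sqrt(1 / plan.n_e + 1 / (plan.n_c + n_h))
    se_s2 = math.sqrt(1 / plan.cap_n_e + 1 / plan.cap_n_c)

    mu_ept = (abs(scenario.mu_c - scenario.mu_h) - margin) / se_ept
    pooled = weight * scenario.mu_h + (1 - weight) * scenario.mu_c
    mu_s1 = (scenario.mu_e - pooled) / se_s1
    mu_s2 = (scenario.mu_e - scenario.mu_c) / se_s2

    var_s1 = (1 / plan.n_e + weight**2 / n_h + (1 - weight) ** 2 / plan.n_c) / se_s1**2
    # covariances of the linearized pre-test statistic (ybar_C - ybar_H)/se
    cov_ept_s1 = (weight / n_h - (1 - weight) / plan.n_c) / (se_ept * se_s1)
    cov_ept_s2 = -(1 / plan.cap_n_c) / (se_ept * se_s2)
    return JointMoments(
        mu_ept=mu_ept, mu_s1=mu_s1, mu_s2=mu_s2,
        var_s1=var_s1, cov_ept_s1=cov_ept_s1, cov_ept_s2=cov_ept_s2,
    )


@dataclass(frozen=True)
class OCResult:
    """Operating-characteristic decomposition over the two branches.

    For ``kind='fwer'``, ``value = component_a + component_b`` with
    ``component_a = P(reject Ept, reject S1)`` and
    ``component_b = P(keep Ept, reject S2)``.  For ``kind='power'``,
    ``component_a``/``component_b`` are the two type-II error components and
    ``value = 1 - (component_a + component_b)``.
    """

    value: float
    component_a: float
    component_b: float
    kind: str
    method: str

    @property
    def total(self) -> float:
        return self.component_a + self.component_b


def _bvn_upper(mu_x: float, mu_y: float, rho: float, x0: float, y0: float) -> float:
    """P(X >= x0, Y >= y0) for a bivariate normal with unit variances."""
    if abs(rho) < 1e-12:
        return norm.sf(x0 - mu_x) * norm.sf(y0 - mu_y)
    mvn = multivariate_normal(mean=[mu_x, mu_y], cov=[[1.0, rho], [rho, 1.0]])
    # inclusion-exclusion on the lower-orthant CDF
    return 1.0 - norm.cdf(x0 - mu_x) - norm.cdf(y0 - mu_y) + float(mvn.cdf([x0, y0]))


def _branch_probs(
    scenario: ScenarioMeans,
    plan: StagePlan,
    spec: DesignSpec,
    method: str,
    weight: Optional[float],
) -> tuple[float, float, float]:
    """(P(reject Ept), P(rej Ept, rej S1), P(keep Ept, rej S2))."""
    margin = spec.margin
    if margin is None:
        raise InvalidParameterError("spec.margin must be set for operating characteristics")
    n_h = spec.n_h
    if weight is None:
        weight = optimal_weight(n_h, plan.n_c)
    m = joint_moments(scenario, plan, n_h, margin, weight)
    c_ept = -norm.ppf(1 - spec.alpha_ept / 2)
    z1 = norm.ppf(1 - spec.alpha_s1)
    z2 = norm.ppf(1 - spec.alpha_s2)
    sd_s1 = math.sqrt(m.var_s1)
    p_s1_reject = norm.sf((z1 - m.mu_s1) / sd_s1)

    if method == "normal-approx":
        p_rej = norm.cdf(c_ept - m.mu_ept)
        # pre-test and S1 are uncorrelated at omega*; keep the product form
        # otherwise via the linearized correlation
        rho1 = m.cov_ept_s1 / sd_s1
        if abs(rho1) < 1e-12:
            comp_a = p_rej * p_s1_reject
        else:
            # P(Z_Ept < c, Z_S1 > z1) = P(Z_S1 > z1) - P(Z_Ept >= c, Z_S1 > z1)
            e0 = c_ept - m.mu_ept
            s0 = (z1 - m.mu_s1) / sd_s1
            comp_a = norm.sf(s0) - _bvn_upper(0.0, 0.0, rho1, e0, s0)
        rho2 = abs(m.cov_ept_s2)  # positive covariance as stated for the design
        comp_b = _bvn_upper(m.mu_ept, m.mu_s2, rho2, c_ept, z2)
        return p_rej, comp_a, comp_b

    if method == "exact-folded":
        w_star = optimal_weight(n_h, plan.n_c)
        if abs(weight - w_star) > 1e-12:
            raise InvalidParameterError(
                "exact-folded evaluation requires the optimal weight omega*"
            )
        se = math.sqrt(1 / n_h + 1 / plan.n_c)
        m0 = scenario.mu_c - scenario.mu_h
        a = margin + c_ept * se  # reject iff |ybar_C - ybar_H| < a
        if a <= 0:
            p_rej = 0.0
            comp_a = 0.0
            comp_b = norm.sf(z2 - m.mu_s2)
            return p_rej, comp_a, comp_b
        x_hi = (a - m0) / se
        x_lo = (-a - m0) / se
        p_rej = norm.cdf(x_hi) - norm.cdf(x_lo)
        comp_a = p_rej * p_s1_reject  # S1 independent of the pre-test at omega*
        rho = m.cov_ept_s2  # corr of (ybar_C - ybar_H)/se with Z_S2
        mvn = multivariate_normal(mean=[0.0, m.mu_s2], cov=[[1.0, rho], [rho, 1.0]])

        def strip_and_s2(x: float) -> float:
            # P(X < x, Z_S2 > z2)
            return norm.cdf(x) - float(mvn.cdf([x, z2]))

        inner = strip_and_s2(x_hi) - strip_and_s2(x_lo)
        comp_b = norm.sf(z2 - m.mu_s2) - inner
        return p_rej, comp_a, comp_b

    raise ValueError(f"unknown method {method!r}")


def fwer(
    scenario: ScenarioMeans,
    plan: StagePlan,
    spec: DesignSpec,
    method: str = "normal-approx",
    *,
    weight: Optional[float] = None,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> OCResult:
    """Family-wise error rate of the procedure at a truth configuration.

    The caller is responsible for placing the scenario inside the composite
    null of interest (both superiority nulls true).  ``method`` is one of
    ``normal-approx``, ``exact-folded`` or ``monte-carlo``.
    """
    if method == "monte-carlo":
        from .simulate import SimulationConfig, monte_carlo_oc

        cfg = SimulationConfig(scenario=scenario, plan=plan, spec=spec,
                               n_replicates=n_replicates, seed=seed, weight=weight)
        res = monte_carlo_oc(cfg)
        return OCResult(value=res.reject_rate, component_a=res.reject_rate_s1,
                        component_b=res.reject_rate_s2, kind="fwer", method=method)
    _, comp_a, comp_b = _branch_probs(scenario, plan, spec, method, weight)
    return OCResult(value=comp_a + comp_b, component_a=comp_a, component_b=comp_b,
                    kind="fwer", method=method)


def overall_power(
    scenario: ScenarioMeans,
    plan: StagePlan,
    spec: DesignSpec,
    method: str = "normal-approx",
    *,
    weight: Optional[float] = None,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> OCResult:
    """Overall power ``1 - (beta_{Ept,S1} + beta_{Ept^c,S2})``.

    ``component_a`` is the probability of establishing equivalence but
    failing the pooled test S1; ``component_b`` of not establishing
    equivalence and failing the extended test S2.
    """
    if method == "monte-carlo":
        from .simulate import SimulationConfig, monte_carlo_oc

        cfg = SimulationConfig(scenario=scenario, plan=plan, spec=spec,
                               n_replicates=n_replicates, seed=seed, weight=weight)
        res = monte_carlo_oc(cfg)
        comp_a = res.borrow_rate - res.reject_rate_s1
        comp_b = (1 - res.borrow_rate) - res.reject_rate_s2
        return OCResult(value=res.reject_rate, component_a=comp_a, component_b=comp_b,
                        kind="power", method=method)
    p_rej, comp_a_rej, comp_b_rej = _branch_probs(scenario, plan, spec, method, weight)
    beta_a = p_rej - comp_a_rej
    beta_b = (1 - p_rej) - comp_b_rej
    return OCResult(value=1 - (beta_a + beta_b), component_a=beta_a, component_b=beta_b,
                    kind="power", method=method)


def fwer_surface(
    plan: StagePlan,
    spec: DesignSpec,
    diff_ept_grid: Optional[np.ndarray] = None,
    diff_s1_grid: Optional[np.ndarray] = None,
    method: str = "normal-approx",
    *,
    weight: Optional[float] = None,
    s2_at_boundary: bool = True,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """FWER over a grid of control-group and weighted treatment differences.

    ``diff_ept`` is ``mu_H - mu_C`` (with ``mu_C`` fixed at 0) and
    ``diff_s1`` the weighted treatment difference
    ``mu_E - (omega mu_H + (1 - omega) mu_C)``.  Defaults reproduce the
    design's evaluation scheme: ``mu_H`` varied over ``[-2.5, 0]`` in steps
    of 0.05 and weighted differences ``{-0.2, ..., 0}``.

    A grid point pins the pooled-test effect via ``diff_s1`` but leaves the
    plain treatment difference ``mu_E - mu_C`` of the S2 branch deep inside
    its null.  With ``s2_at_boundary=True`` (default) the S2 component is
    therefore evaluated at the least-favorable configuration of its own
    null, ``mu_E = mu_C`` with the same control-group difference, so that
    the surface reports the family-wise error against both composite nulls;
    with ``False`` both components use the literal grid scenario.  Returns a
    tidy frame with columns ``diff_ept, diff_s1, alpha_ept, fwer,
    component_a, component_b``.
    """
    if diff_ept_grid is None:
        diff_ept_grid = np.arange(-2.5, 0.0 + 1e-9, 0.05)
    if diff_s1_grid is None:
        diff_s1_grid = np.array([-0.2, -0.15, -0.1, -0.05, 0.0])
    if weight is None:
        weight = optimal_weight(spec.n_h, plan.n_c)
    kwargs = dict(weight=weight, n_replicates=n_replicates, seed=seed)
    rows = []
    for d_ept in np.atleast_1d(diff_ept_grid):
        mu_h = float(d_ept)
        comp_b_cache = None
        for d_s1 in np.atleast_1d(diff_s1_grid):
            mu_e = float(d_s1) + weight * mu_h  # mu_C = 0
            sc = ScenarioMeans(mu_e=mu_e, mu_c=0.0, mu_h=mu_h)
            res = fwer(sc, plan, spec, method, **kwargs)
            comp_a, comp_b = res.component_a, res.component_b
            if s2_at_boundary:
                if comp_b_cache is None:
                    sc_b = ScenarioMeans(mu_e=0.0, mu_c=0.0, mu_h=mu_h)
                    comp_b_cache = fwer(sc_b, plan, spec, method, **kwargs).component_b
                comp_b = comp_b_cache
            rows.append({"diff_ept": float(d_ept), "diff_s1": float(d_s1),
                         "alpha_ept": spec.alpha_ept, "fwer": comp_a + comp_b,
                         "component_a": comp_a, "component_b": comp_b})
    return pd.DataFrame(rows)


def max_fwer(
    plan: StagePlan,
    spec: DesignSpec,
    method: str = "normal-approx",
    *,
    weight: Optional[float] = None,
    refine: int = 2,
) -> float:
    """Supremum estimate of the FWER over the composite null region.

    Coarse grid over ``mu_H - mu_C`` in ``[-2.5, -Delta]`` and weighted
    differences in ``[-0.2, 0]`` (steps 0.05), followed by ``refine``
    rounds of ten-fold grid refinement around the running maximum.
    """
    margin = spec.margin
    if margin is None:
        raise InvalidParameterError("spec.margin must be set")
    lo_e, hi_e = -2.5, -margin
    lo_s, hi_s = -0.2, 0.0
    step_e, step_s = 0.05, 0.05
    best = (-np.inf, lo_e, hi_s)
    for _ in range(refine + 1):
        grid_e = np.arange(lo_e, hi_e + 1e-12, step_e)
        grid_s = np.arange(lo_s, hi_s + 1e-12, step_s)
        surf = fwer_surface(plan, spec, grid_e, grid_s, method, weight=weight)
        idx = surf["fwer"].idxmax()
        row = surf.loc[idx]
        if row["fwer"] > best[0]:
            best = (float(row["fwer"]), float(row["diff_ept"]), float(row["diff_s1"]))
        lo_e = max(-2.5, best[1] - step_e)
        hi_e = min(-margin, best[1] + step_e)
        lo_s = max(-0.2, best[2] - step_s)
        hi_s = min(0.0, best[2] + step_s)
        step_e /= 10
        step_s /= 10
    return best[0]
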