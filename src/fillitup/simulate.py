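"""Monte-Carlo engine for the two-stage Fill-it-up procedure.

Each replicate executes the full procedure: draw stage-1 experimental,
control and historical responses, run the equivalence pre-test, then either
pool with the historical controls and test S1, or draw the stage-2
responses and test S2 on all randomized patients.

Three sampling modes are available:

``patients``
    individual-level unit-variance normal responses; the same engine that
    feeds the patient-level dataset generator.
``means``
    draws the group sample means directly from their exact Gaussian
    sampling distribution; distributionally identical to ``patients`` and
    much faster at large replicate counts.
``statistics``
    draws ``(Z_Ept, Z_S1, Z_S2)`` from the joint normal approximation with
    the design's stated moments (the scheme in which the published
    operating characteristics are expressed); differs from the exact modes
    near the equivalence boundary, where the folded pre-test statistic is
    not Gaussian.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.stats import norm

from .design import DesignSpec, StagePlan, InvalidParameterError, optimal_weight, stage_plan
from .oc import ScenarioMeans, joint_moments

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "TABLE_MARGINS",
    "simulate_trial",
    "monte_carlo_oc",
    "scenario_preset",
]

# equivalence margins used in the design's simulation study presets, keyed by
# the two-sided level of the pre-test (small-effect study, delta = 0.275,
# n_H = 500); taken as given study constants
TABLE_MARGINS = {0.01: 0.27, 0.05: 0.22, 0.1: 0.19, 0.2: 0.15}


@dataclass(frozen=True)
class SimulationConfig:
    """A fully specified simulation run.

    ``spec.margin`` must be set.  ``weight=None`` uses the variance-optimal
    ``omega*`` at the stage-1 control count.  ``mode`` is one of
    ``means`` (default), ``patients`` or ``statistics``.
    """

    scenario: ScenarioMeans
    plan: StagePlan
    spec: DesignSpec
    n_replicates: int = 50_000
    seed: int = 0
    mode: str = "means"
    weight: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.spec.margin is None or self.spec.margin <= 0:
            raise InvalidParameterError("spec.margin must be set and positive")
        if self.mode not in ("patients", "means", "statistics"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SimulationResult:
    """Aggregated Monte-Carlo operating characteristics.

    ``reject_rate`` is the fraction of replicates with an overall rejection
    (``psi_FIU = 1``), ``borrow_rate`` the fraction in which the pre-test
    established equivalence (historical controls used), ``asn`` the mean
    number of newly recruited patients and ``mc_se`` the binomial standard
    error of ``reject_rate``.  ``reject_rate_s1``/``reject_rate_s2`` split
    the rejections by terminal test.
    """

    reject_rate: float
    borrow_rate: float
    asn: float
    mc_se: float
    reject_rate_s1: float
    reject_rate_s2: float
    n_replicates: int
    seed: int
    mode: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _draw_group_mean(rng: np.random.Generator, mu: float, n: int, size: int) -> np.ndarray:
    return rng.normal(mu, 1.0 / math.sqrt(n), size)


def simulate_trial(config: SimulationConfig, rng: np.random.Generator) -> dict:
    """One replicate at the individual patient level.

    Returns a record with the overall ``decision``, the terminal ``branch``
    (``"S1"`` or ``"S2"``) and the realized number of newly recruited
    patients ``n_randomized``.
    """
    from .stats import GroupSummary, z_ept, z_s1, z_s2, fill_it_up_decision

    sc, plan, spec = config.scenario, config.plan, config.spec
    y_e = rng.normal(sc.mu_e, 1.0, plan.n_e)
    y_c = rng.normal(sc.mu_c, 1.0, plan.n_c)
    y_h = rng.normal(sc.mu_h, 1.0, spec.n_h)
    summary = GroupSummary.from_samples(y_e, y_c, y_h)
    ept = z_ept(summary, spec.margin, spec.alpha_ept)
    if ept.reject:
        s1 = z_s1(summary, spec.alpha_s1, weight=config.weight)
        return {
            "decision": fill_it_up_decision(ept, s1=s1),
            "branch": "S1",
            "n_randomized": plan.stage1_total,
        }
    y_e2 = rng.normal(sc.mu_e, 1.0, plan.n_e2)
    y_c2 = rng.normal(sc.mu_c, 1.0, plan.n_c2)
    summary = GroupSummary.from_samples(y_e, y_c, y_h, y_e2, y_c2)
    s2 = z_s2(summary, spec.alpha_s2)
    return {
        "decision": fill_it_up_decision(ept, s2=s2),
        "branch": "S2",
        "n_randomized": plan.n_fiu,
    }


def _run_exact(config: SimulationConfig, rng: np.random.Generator):
    """Vectorized replicates on the exact sampling distribution of the means."""
    sc, plan, spec = config.scenario, config.plan, config.spec
    R = config.n_replicates
    mean_e = _draw_group_mean(rng, sc.mu_e, plan.n_e, R)
    mean_c = _draw_group_mean(rng, sc.mu_c, plan.n_c, R)
    mean_h = _draw_group_mean(rng, sc.mu_h, spec.n_h, R)

    se_ept = math.sqrt(1 / plan.n_c + 1 / spec.n_h)
    z_ept_stat = (np.abs(mean_c - mean_h) - spec.margin) / se_ept
    rej_ept = z_ept_stat < -norm.ppf(1 - spec.alpha_ept / 2)

    w = config.weight
    if w is None:
        w = optimal_weight(spec.n_h, plan.n_c)
    pooled = w * mean_h + (1 - w) * mean_c
    se_s1 = math.sqrt(1 / plan.n_e + w**2 / spec.n_h + (1 - w) ** 2 / plan.n_c)
    rej_s1 = (mean_e - pooled) / se_s1 > norm.ppf(1 - spec.alpha_s1)

    # stage-2 responses are drawn unconditionally; they only enter replicates
    # on the S2 branch
    if plan.n_e2 > 0:
        mean_e2 = _draw_group_mean(rng, sc.mu_e, plan.n_e2, R)
        mean_c2 = _draw_group_mean(rng, sc.mu_c, plan.n_c2, R)
        full_e = (plan.n_e * mean_e + plan.n_e2 * mean_e2) / plan.cap_n_e
        full_c = (plan.n_c * mean_c + plan.n_c2 * mean_c2) / plan.cap_n_c
    else:
        full_e, full_c = mean_e, mean_c
    se_s2 = math.sqrt(1 / plan.cap_n_e + 1 / plan.cap_n_c)
    rej_s2 = (full_e - full_c) / se_s2 > norm.ppf(1 - spec.alpha_s2)
    return rej_ept, rej_s1, rej_s2


def _run_statistics(config: SimulationConfig, rng: np.random.Generator):
    """Replicates drawn from the joint normal approximation of the statistics."""
    sc, plan, spec = config.scenario, config.plan, config.spec
    R = config.n_replicates
    m = joint_moments(sc, plan, spec.n_h, spec.margin, config.weight)
    sd_s1 = math.sqrt(m.var_s1)
    rho1 = m.cov_ept_s1 / sd_s1
    rho2 = abs(m.cov_ept_s2)  # positive covariance, as stated for the design

    x0 = rng.standard_normal(R)
    e1 = rng.standard_normal(R)
    e2 = rng.standard_normal(R)
    z_e = m.mu_ept + x0
    z_1 = m.mu_s1 + sd_s1 * (rho1 * x0 + math.sqrt(max(0.0, 1 - rho1**2)) * e1)
    z_2 = m.mu_s2 + rho2 * x0 + math.sqrt(max(0.0, 1 - rho2**2)) * e2

    rej_ept = z_e < -norm.ppf(1 - spec.alpha_ept / 2)
    rej_s1 = z_1 > norm.ppf(1 - spec.alpha_s1)
    rej_s2 = z_2 > norm.ppf(1 - spec.alpha_s2)
    return rej_ept, rej_s1, rej_s2


def monte_carlo_oc(config: SimulationConfig) -> SimulationResult:
    """Aggregate the full two-stage procedure over seeded replicates."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "statistics":
        rej_ept, rej_s1, rej_s2 = _run_statistics(config, rng)
    elif config.mode == "means":
        rej_ept, rej_s1, rej_s2 = _run_exact(config, rng)
    else:  # patients
        records = [simulate_trial(config, rng) for _ in range(config.n_replicates)]
        dec = np.array([r["decision"] for r in records], dtype=bool)
        s1_branch = np.array([r["branch"] == "S1" for r in records])
        rej_ept = s1_branch
        rej_s1 = dec & s1_branch
        rej_s2 = dec & ~s1_branch
        return _aggregate(config, rej_ept, rej_s1, rej_s2)
    rej_s1 = rej_s1 & rej_ept
    rej_s2 = rej_s2 & ~rej_ept
    return _aggregate(config, rej_ept, rej_s1, rej_s2)


def _aggregate(config, rej_ept, rej_s1, rej_s2) -> SimulationResult:
    plan = config.plan
    R = config.n_replicates
    psi = rej_s1 | rej_s2
    p = float(psi.mean())
    borrow = float(rej_ept.mean())
    asn = float(
        np.where(rej_ept, plan.stage1_total, plan.n_fiu).mean()
    )
    return SimulationResult(
        reject_rate=p,
        borrow_rate=borrow,
        asn=asn,
        mc_se=math.sqrt(p * (1 - p) / R),
        reject_rate_s1=float(rej_s1.mean()),
        reject_rate_s2=float(rej_s2.mean()),
        n_replicates=R,
        seed=config.seed,
        mode=config.mode,
    )


def scenario_preset(
    name: str,
    spec: DesignSpec,
    *,
    n_replicates: int = 50_000,
    seed: int = 0,
    mode: str = "means",
    weight_source: str = "stage1",
) -> SimulationConfig:
    """Null-scenario presets of the design's simulation study.

    ``scenario-I`` is the boundary (minimum-FWER) case: the control groups
    differ by exactly the margin (``mu_H = -Delta``) and the weighted
    treatment difference is zero (``mu_E = -omega Delta``).  ``scenario-II``
    is the maximum case: no treatment difference and control groups three
    margins apart (``mu_H = 3 Delta``).  If ``spec.margin`` is unset, the
    study's margin for ``spec.alpha_ept`` is looked up in
    :data:`TABLE_MARGINS`.  ``weight_source`` selects whether the
    scenario-I ``omega`` uses stage-1 (default) or full-data control counts.
    """
    plan = stage_plan(spec)
    margin = spec.margin
    if margin is None:
        try:
            margin = TABLE_MARGINS[spec.alpha_ept]
        except KeyError:
            raise InvalidParameterError(
                "spec.margin is unset and alpha_ept has no preset margin"
            ) from None
        spec = spec.with_margin(margin)
    n_c = plan.n_c if weight_source == "stage1" else plan.cap_n_c
    w = optimal_weight(spec.n_h, n_c)
    if name == "scenario-I":
        scenario = ScenarioMeans(mu_e=-w * margin, mu_c=0.0, mu_h=-margin)
    elif name == "scenario-II":
        scenario = ScenarioMeans(mu_e=0.0, mu_c=0.0, mu_h=3 * margin)
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    return SimulationConfig(scenario=scenario, plan=plan, spec=spec,
                            n_replicates=n_replicates, seed=seed, mode=mode)
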