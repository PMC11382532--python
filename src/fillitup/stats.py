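"""Test statistics and decision rules of the Fill-it-up procedure.

Three z-tests drive the design (all variances are standardized to 1):

* the equivalence pre-test ``Ept`` of ``H0: |mu_C - mu_H| >= Delta`` against
  ``H1: |mu_C - mu_H| < Delta`` on the stage-1 randomized controls versus
  the historical controls,
* the pooled superiority test ``S1`` of E against the omega-weighted
  combination of historical and randomized controls, used when the pre-test
  establishes comparability, and
* the extended-randomization superiority test ``S2`` of E against C on all
  randomized patients, used otherwise.

The overall decision ``psi_FIU`` rejects if the terminal test of the branch
actually taken rejects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from scipy.stats import norm

from .design import InvalidParameterError, optimal_weight

__all__ = [
    "GroupSummary",
    "TestResult",
    "ProtocolViolationError",
    "z_ept",
    "z_ept_tost",
    "z_s1",
    "z_s2",
    "weighted_effect",
    "fill_it_up_decision",
]


class ProtocolViolationError(RuntimeError):
    """A test was requested on a branch the pre-test decision does not allow."""


@dataclass(frozen=True)
class GroupSummary:
    """Sample means and counts entering the three tests.

    ``mean_e``/``mean_c``/``mean_h`` with ``n_e``/``n_c``/``n_h`` are the
    stage-1 and historical summaries.  ``mean_e_full``/``mean_c_full`` with
    ``n_e_full``/``n_c_full`` are the all-randomized summaries over
    ``N_E``/``N_C`` patients, required only for the final test S2.
    """

    mean_e: float
    mean_c: float
    mean_h: float
    n_e: int
    n_c: int
    n_h: int
    mean_e_full: Optional[float] = None
    mean_c_full: Optional[float] = None
    n_e_full: Optional[int] = None
    n_c_full: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_e_full is not None and self.n_e_full < self.n_e:
            raise InvalidParameterError("full-data count n_e_full below stage-1 count")
        if self.n_c_full is not None and self.n_c_full < self.n_c:
            raise InvalidParameterError("full-data count n_c_full below stage-1 count")

    @classmethod
    def from_samples(
        cls,
        y_e: np.ndarray,
        y_c: np.ndarray,
        y_h: np.ndarray,
        y_e2: Optional[np.ndarray] = None,
        y_c2: Optional[np.ndarray] = None,
    ) -> "GroupSummary":
        """Summarize raw response vectors (stage-2 vectors optional)."""
        y_e = np.asarray(y_e, dtype=float)
        y_c = np.asarray(y_c, dtype=float)
        y_h = np.asarray(y_h, dtype=float)
        kwargs = {}
        if y_e2 is not None and y_c2 is not None:
            full_e = np.concatenate([y_e, np.asarray(y_e2, dtype=float)])
            full_c = np.concatenate([y_c, np.asarray(y_c2, dtype=float)])
            kwargs = dict(
                mean_e_full=full_e.mean(),
                mean_c_full=full_c.mean(),
                n_e_full=full_e.size,
                n_c_full=full_c.size,
            )
        return cls(
            mean_e=y_e.mean(), mean_c=y_c.mean(), mean_h=y_h.mean(),
            n_e=y_e.size, n_c=y_c.size, n_h=y_h.size, **kwargs,
        )


@dataclass(frozen=True)
class TestResult:
    """Outcome of one z-test: statistic, critical value and binary decision."""

    statistic: float
    critical: float
    reject: bool
    test_id: str
    level: float
    weight: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def z_ept(summary: GroupSummary, margin: float, alpha_ept: float) -> TestResult:
    """Equivalence pre-test of randomized versus historical control means.

    ``Z_Ept = (|ybar_C - ybar_H| - Delta) / sqrt(1/n_C + 1/n_H)``, rejecting
    the non-equivalence null when ``Z_Ept < -z_{1-alpha_Ept/2}``.  The
    decision is identical to two one-sided shifted tests at level
    ``alpha_Ept/2`` each (see :func:`z_ept_tost`).
    """
    if margin <= 0:
        raise InvalidParameterError(f"margin must be positive, got {margin!r}")
    se = math.sqrt(1 / summary.n_c + 1 / summary.n_h)
    stat = float((abs(summary.mean_c - summary.mean_h) - margin) / se)
    crit = float(-norm.ppf(1 - alpha_ept / 2))
    return TestResult(statistic=stat, critical=crit, reject=bool(stat < crit),
                      test_id="Ept", level=alpha_ept)


def z_ept_tost(summary: GroupSummary, margin: float, alpha_ept: float) -> TestResult:
    """Equivalence pre-test in its two-one-sided-tests (TOST) form.

    Rejects when both shifted statistics
    ``(d - Delta)/se < -z`` and ``(d + Delta)/se > z`` hold, each one-sided
    test run at level ``alpha_Ept/2``.  Decision-identical to :func:`z_ept`;
    the reported statistic is the binding (least favorable) of the two.
    """
    if margin <= 0:
        raise InvalidParameterError(f"margin must be positive, got {margin!r}")
    se = math.sqrt(1 / summary.n_c + 1 / summary.n_h)
    d = summary.mean_c - summary.mean_h
    z = norm.ppf(1 - alpha_ept / 2)
    upper = (d - margin) / se   # must be < -z
    lower = (d + margin) / se   # must be > +z
    reject = bool((upper < -z) and (lower > z))
    stat = float(max(upper, -lower))   # shifted statistic closest to its bound
    return TestResult(statistic=stat, critical=float(-z), reject=reject,
                      test_id="Ept", level=alpha_ept)


def z_s1(
    summary: GroupSummary,
    alpha_s1: float,
    weight: Optional[float] = None,
) -> TestResult:
    """Pooled superiority test of E against the weighted hybrid control.

    ``Z_S1 = (ybar_E - (omega ybar_H + (1-omega) ybar_C))
    / sqrt(1/n_E + omega**2/n_H + (1-omega)**2/n_C)``, one-sided at
    ``alpha_S1``.  With the default variance-optimal
    ``omega* = n_H/(n_H + n_C)`` this is the ordinary two-sample z-test of E
    against the concatenated control sample, with denominator
    ``sqrt(1/n_E + 1/(n_H + n_C))``.  ``omega = 0`` discards the historical
    controls entirely.
    """
    if weight is None:
        weight = optimal_weight(summary.n_h, summary.n_c)
    if not 0.0 <= weight <= 1.0:
        raise InvalidParameterError(f"weight must lie in [0, 1], got {weight!r}")
    pooled = weight * summary.mean_h + (1 - weight) * summary.mean_c
    var = 1 / summary.n_e
    if weight > 0:
        var += weight**2 / summary.n_h
    if weight < 1:
        var += (1 - weight) ** 2 / summary.n_c
    stat = float((summary.mean_e - pooled) / math.sqrt(var))
    crit = float(norm.ppf(1 - alpha_s1))
    return TestResult(statistic=stat, critical=crit, reject=bool(stat > crit),
                      test_id="S1", level=alpha_s1, weight=float(weight))


def z_s2(summary: GroupSummary, alpha_s2: float) -> TestResult:
    """Superiority test of E against C on all randomized patients.

    ``Z_S2 = (ybar'_E - ybar'_C) / sqrt(1/N_E + 1/N_C)``, one-sided at
    ``alpha_S2``; historical controls are discarded.
    """
    if summary.mean_e_full is None or summary.mean_c_full is None:
        raise InvalidParameterError("S2 requires full-data means over N_E and N_C")
    se = math.sqrt(1 / summary.n_e_full + 1 / summary.n_c_full)
    stat = float((summary.mean_e_full - summary.mean_c_full) / se)
    crit = float(norm.ppf(1 - alpha_s2))
    return TestResult(statistic=stat, critical=crit, reject=bool(stat > crit),
                      test_id="S2", level=alpha_s2)


def weighted_effect(mu_e: float, mu_c: float, mu_h: float, weight: float) -> float:
    """Effect size actually tested by the pooled test S1.

    ``t = mu_E - (omega mu_H + (1-omega) mu_C) = delta + omega (mu_C - mu_H)``
    with ``delta = mu_E - mu_C``: a historical mean above the randomized
    control mean shrinks the tested effect, one below it inflates it.
    """
    return (mu_e - mu_c) + weight * (mu_c - mu_h)


def fill_it_up_decision(
    ept: TestResult,
    s1: Optional[TestResult] = None,
    s2: Optional[TestResult] = None,
) -> int:
    """Overall decision ``psi_FIU`` of the two-stage procedure.

    ``psi_FIU = max(phi_Ept * phi_S1, (1 - phi_Ept) * phi_S2)``: the branch
    selected by the pre-test must be the one supplied (S1 after rejection,
    S2 otherwise), and the overall null is rejected iff that terminal test
    rejects.
    """
    if (s1 is None) == (s2 is None):
        raise ProtocolViolationError("exactly one of s1/s2 must be supplied")
    if ept.reject and s1 is None:
        raise ProtocolViolationError("pre-test rejected: terminal test must be S1")
    if not ept.reject and s2 is None:
        raise ProtocolViolationError("pre-test did not reject: terminal test must be S2")
    terminal = s1 if ept.reject else s2
    return int(terminal.reject)
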