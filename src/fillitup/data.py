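"""Patient-level trial datasets: schema, CSV I/O, synthesis and analysis.

A Fill-it-up trial dataset is a flat table with one row per patient:

=============  =======================================================
column         values
=============  =======================================================
``PatID``      unique patient identifier
``Group``      ``H`` (historical), ``E`` (experimental), ``C`` (control)
``Recruitment``  ``historical``, ``initial`` (stage 1), ``further`` (stage 2)
``Response``   continuous endpoint value
=============  =======================================================

Historical patients are exactly those with ``Recruitment == historical``.
The analysis workflow mirrors the trial conduct: the equivalence pre-test
on historical versus initial controls, then either the pooled superiority
test S1 (no further recruitment) or, after stage-2 recruitment, the final
superiority test S2 on all randomized patients with the historical controls
discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import DesignSpec, StagePlan, InvalidParameterError, optimal_weight
from .oc import ScenarioMeans
from .stats import GroupSummary, TestResult, z_ept, z_s1, z_s2, fill_it_up_decision

__all__ = [
    "COLUMNS",
    "TrialDataset",
    "DatasetFormatError",
    "read_dataset",
    "write_dataset",
    "generate_synthetic_dataset",
    "analyze_step",
    "analyze_trial",
]

COLUMNS = ["PatID", "Group", "Recruitment", "Response"]
_GROUPS = {"H", "E", "C"}
_RECRUITMENTS = {"historical", "initial", "further"}


class DatasetFormatError(ValueError):
    """The dataset violates the patient-record schema."""


@dataclass(frozen=True)
class TrialDataset:
    """Validated collection of patient records (wraps a DataFrame)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        _validate(self.frame)

    def counts(self) -> pd.Series:
        """Patient counts per (Group, Recruitment) stratum."""
        return self.frame.groupby(["Group", "Recruitment"], observed=True).size()

    def _stratum(self, group: str, recruitment: Optional[str] = None) -> pd.Series:
        f = self.frame
        mask = f["Group"] == group
        if recruitment is not None:
            mask &= f["Recruitment"] == recruitment
        return f.loc[mask, "Response"]

    def summary(self, stage: int = 1) -> GroupSummary:
        """Group summaries for the analysis of the given stage.

        Stage 1 uses historical plus initial records; stage 2 additionally
        folds the further-recruited patients into the full-data means.
        """
        y_h = self._stratum("H")
        y_e = self._stratum("E", "initial")
        y_c = self._stratum("C", "initial")
        for name, y in (("H/historical", y_h), ("E/initial", y_e), ("C/initial", y_c)):
            if y.empty:
                raise DatasetFormatError(f"stratum {name} is missing")
        if stage == 1:
            return GroupSummary.from_samples(y_e.values, y_c.values, y_h.values)
        y_e2 = self._stratum("E", "further")
        y_c2 = self._stratum("C", "further")
        return GroupSummary.from_samples(y_e.values, y_c.values, y_h.values,
                                         y_e2.values, y_c2.values)


def _validate(frame: pd.DataFrame) -> None:
    if list(frame.columns) != COLUMNS:
        raise DatasetFormatError(
            f"columns must be exactly {COLUMNS}, got {list(frame.columns)}"
        )
    if len(frame) == 0:
        raise DatasetFormatError("dataset is empty")
    bad: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        if row.Group not in _GROUPS:
            bad.append(f"line {line}: unknown group {row.Group!r}")
        if row.Recruitment not in _RECRUITMENTS:
            bad.append(f"line {line}: unknown recruitment {row.Recruitment!r}")
        elif (row.Group == "H") != (row.Recruitment == "historical"):
            bad.append(f"line {line}: group H and recruitment 'historical' must coincide")
        if not np.isfinite(row.Response):
            bad.append(f"line {line}: non-finite response {row.Response!r}")
        if len(bad) >= 20:
            bad.append("... (further problems suppressed)")
            break
    if frame["PatID"].duplicated().any():
        dupes = frame.loc[frame["PatID"].duplicated(), "PatID"].unique()[:10]
        bad.append(f"duplicate PatID values: {list(dupes)}")
    if bad:
        raise DatasetFormatError("; ".join(bad))


def _canonicalize(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["Group"] = frame["Group"].astype(str).str.strip().str.upper()
    frame["Recruitment"] = frame["Recruitment"].astype(str).str.strip().str.lower()
    return frame


def read_dataset(path: Union[str, Path]) -> TrialDataset:
    """Read and validate a trial dataset from CSV.

    Group and recruitment codes are accepted case-insensitively and emitted
    in canonical case.  Malformed rows are reported with their line number.
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DatasetFormatError(f"{path}: empty dataset") from None
    if list(frame.columns) != COLUMNS:
        raise DatasetFormatError(
            f"{path}: header must be exactly {','.join(COLUMNS)}"
        )
    non_numeric = pd.to_numeric(frame["Response"], errors="coerce")
    bad_rows = frame.index[non_numeric.isna()]
    if len(bad_rows):
        lines = ", ".join(str(i + 2) for i in bad_rows[:10])
        raise DatasetFormatError(f"{path}: non-numeric response on line(s) {lines}")
    frame["Response"] = non_numeric.astype(float)
    return TrialDataset(_canonicalize(frame))


def write_dataset(dataset: TrialDataset, path: Union[str, Path]) -> None:
    """Write a trial dataset as CSV with the canonical header."""
    dataset.frame.to_csv(path, index=False)


def generate_synthetic_dataset(
    scenario: ScenarioMeans,
    plan: StagePlan,
    n_h: int,
    seed: int,
    stage: int = 1,
) -> TrialDataset:
    """Simulate a patient-level dataset at the scenario means.

    Responses are unit-variance normal draws.  Patient IDs enumerate the
    historical controls first, then the stage-1 (``initial``) and, for
    ``stage=2``, the stage-2 (``further``) randomized patients.
    Deterministic given ``seed``.
    """
    if stage not in (1, 2):
        raise InvalidParameterError("stage must be 1 or 2")
    rng = np.random.default_rng(seed)
    blocks = [("H", "historical", scenario.mu_h, n_h)]
    blocks += [("C", "initial", scenario.mu_c, plan.n_c),
               ("E", "initial", scenario.mu_e, plan.n_e)]
    if stage == 2:
        blocks += [("C", "further", scenario.mu_c, plan.n_c2),
                   ("E", "further", scenario.mu_e, plan.n_e2)]
    rows = []
    pat_id = 1
    for group, recruitment, mu, n in blocks:
        responses = rng.normal(mu, 1.0, n)
        for r in responses:
            rows.append((pat_id, group, recruitment, float(r)))
            pat_id += 1
    frame = pd.DataFrame(rows, columns=COLUMNS)
    return TrialDataset(frame)


def _info_fraction_report(n_h: int, n_c: int, step: str) -> str:
    if step == "s2":
        return "Control information: 100.0% randomized (historical controls discarded)."
    hist = 100.0 * n_h / (n_h + n_c)
    return (
        f"Control information: {hist:.1f}% historical ({n_h} patients), "
        f"{100 - hist:.1f}% randomized ({n_c} patients)."
    )


def analyze_step(
    dataset: TrialDataset,
    spec: DesignSpec,
    step: str,
    *,
    weight: Optional[float] = None,
) -> tuple[TestResult, str]:
    """Run one analysis step on a trial dataset.

    ``pretest`` compares historical and initial randomized controls at the
    margin ``spec.margin``; ``s1`` tests E (initial) against the pooled
    control sample with the variance-optimal weight; ``s2`` tests all
    randomized E against all randomized C, requiring stage-2 (``further``)
    records.  Returns the test result together with a human-readable report
    stating the decision and the split of control information between
    randomized and historical patients.
    """
    if step == "pretest":
        if spec.margin is None:
            raise InvalidParameterError("spec.margin must be set for the pre-test")
        summary = dataset.summary(stage=1)
        result = z_ept(summary, spec.margin, spec.alpha_ept)
        verdict = "equivalence established" if result.reject else "equivalence not established"
        report = (
            f"Equivalence pre-test: Z = {result.statistic:.4f}, "
            f"critical value {result.critical:.4f} -> {verdict}.\n"
            + _info_fraction_report(summary.n_h, summary.n_c, step)
        )
        return result, report
    if step == "s1":
        summary = dataset.summary(stage=1)
        pre = z_ept(summary, spec.margin, spec.alpha_ept) if spec.margin else None
        if pre is not None and not pre.reject:
            warnings.warn(
                "pooled test S1 requested although the pre-test did not reject",
                stacklevel=2,
            )
        result = z_s1(summary, spec.alpha_s1, weight=weight)
        verdict = "superiority shown" if result.reject else "superiority not shown"
        report = (
            f"Pooled superiority test S1 (omega = {result.weight:.4f}): "
            f"Z = {result.statistic:.4f}, critical value {result.critical:.4f} "
            f"-> {verdict}.\n" + _info_fraction_report(summary.n_h, summary.n_c, step)
        )
        return result, report
    if step == "s2":
        if "further" not in set(dataset.frame["Recruitment"]):
            raise DatasetFormatError(
                "step s2 requires stage-2 ('further') records"
            )
        summary = dataset.summary(stage=2)
        result = z_s2(summary, spec.alpha_s2)
        verdict = "superiority shown" if result.reject else "superiority not shown"
        report = (
            f"Superiority test S2 on {summary.n_e_full} vs {summary.n_c_full} "
            f"randomized patients: Z = {result.statistic:.4f}, critical value "
            f"{result.critical:.4f} -> {verdict}.\n"
            + _info_fraction_report(summary.n_h, summary.n_c, step)
        )
        return result, report
    raise ValueError(f"unknown analysis step {step!r}")


def analyze_trial(
    dataset: TrialDataset,
    spec: DesignSpec,
    *,
    weight: Optional[float] = None,
) -> dict:
    """Full two-stage analysis: pre-test, then the branch it selects.

    Returns a dict with the pre-test result, the terminal test result, the
    branch taken and the overall binary decision ``psi_FIU``.
    """
    ept, _ = analyze_step(dataset, spec, "pretest")
    if ept.reject:
        terminal, _ = analyze_step(dataset, spec, "s1", weight=weight)
        decision = fill_it_up_decision(ept, s1=terminal)
        branch = "S1"
    else:
        terminal, _ = analyze_step(dataset, spec, "s2")
        decision = fill_it_up_decision(ept, s2=terminal)
        branch = "S2"
    return {"pretest": ept, "terminal": terminal, "branch": branch, "decision": decision}
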