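"""Evidence-gated heuristic stepwise model improvement.

Initial pathway models are deliberate simplifications, so their fit is
usually poor.  The refiner repeatedly frees the fixed parameter with the
largest modification index, but only when external biological evidence
admits it: a candidate error covariance needs an interaction-database
(STRING-style) pair; a candidate path coefficient is also admissible when
a directed route between the two genes exists in the original pathway.
A freed parameter must survive a one-sided z-test (|z| >= 1.64) or it is
removed and blacklisted.  The loop stops as soon as the model reaches an
adequate fit (exact-fit P > alpha, close-fit P > alpha, or SRMR below the
adequate bound), when no admissible candidate remains, or at a step cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConvergenceError
from .graph import PathwayGraph, directed_path_exists
from .model import PathModel, check_block_recursive, check_bow_free
from .sem import FitConfig, FitResult, degrees_of_freedom, fit_ml, modification_indices

__all__ = [
    "EvidenceSet",
    "RefinementStep",
    "RefinementLog",
    "candidate_evidence",
    "stepwise_refine",
    "replay_refinement",
]

#: Variable names reserved for group indicators; never touched by refinement.
GROUP_INDICATOR_NAMES = frozenset({"group", "C"})


@dataclass
class EvidenceSet:
    """External evidence: interaction-database pairs plus the source pathway."""

    string_edges: set = field(default_factory=set)
    pathway: PathwayGraph | None = None

    def __post_init__(self):
        self.string_edges = {frozenset(map(str, pair)) for pair in self.string_edges}
        for pair in self.string_edges:
            if len(pair) != 2:
                raise ValueError(f"evidence pair {set(pair)} is not a 2-set")
        if self.pathway is not None:
            known = self.pathway.nodes
            strays = sorted({g for pair in self.string_edges for g in pair} - known)
            if strays:
                warnings.warn(
                    f"{len(strays)} evidence gene(s) not in the pathway: {strays[:10]}"
                )

    def has_pair(self, a: str, b: str) -> bool:
        return frozenset((str(a), str(b))) in self.string_edges


def candidate_evidence(candidate: tuple, ev: EvidenceSet) -> tuple[bool, str]:
    """Decide whether freeing ``candidate`` is biologically admissible.

    ``candidate`` is ``("beta", target, source)`` or ``("psi", a, b)``.
    Covariances are admissible only through a database pair; path
    coefficients also through a directed route in the original pathway.
    The returned source records which criterion fired (database preferred).
    """
    kind, a, b = candidate
    if a in GROUP_INDICATOR_NAMES or b in GROUP_INDICATOR_NAMES:
        raise ValueError("group-indicator parameters are never refined")
    if ev.has_pair(a, b):
        return True, "string"
    if kind == "beta" and ev.pathway is not None:
        target, source = a, b
        if (
            source in ev.pathway
            and target in ev.pathway
            and directed_path_exists(ev.pathway, source, target)
        ):
            return True, "directed_path"
    return False, "rejected_no_evidence"


@dataclass
class RefinementStep:
    """One decision of the stepwise loop."""

    step: int
    candidate: tuple
    mi: float
    evidence: str
    action: str  # accepted | rejected_z | rejected_no_evidence | rejected_identifiability | rejected_nonconvergent
    z: float = float("nan")
    chisq: float = float("nan")
    p_value: float = float("nan")
    rmsea_pclose: float = float("nan")
    srmr: float = float("nan")


@dataclass
class RefinementLog:
    steps: list = field(default_factory=list)
    stop_reason: str = ""

    def accepted(self) -> list:
        return [s for s in self.steps if s.action == "accepted"]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            kind, a, b = s.candidate
            rows.append(
                {
                    "step": s.step,
                    "kind": kind,
                    "target": a,
                    "source": b,
                    "mi": s.mi,
                    "evidence": s.evidence,
                    "action": s.action,
                    "z": s.z,
                    "chisq": s.chisq,
                    "p_value": s.p_value,
                    "rmsea_pclose": s.rmsea_pclose,
                    "srmr": s.srmr,
                }
            )
        return pd.DataFrame(rows)


def _adequate(fit: FitResult, config: FitConfig) -> str | None:
    if fit.df == 0 or fit.p_value > config.alpha:
        return "exact_fit"
    if np.isfinite(fit.rmsea_pclose) and fit.rmsea_pclose > config.alpha:
        return "close_fit"
    if fit.srmr < config.srmr_adequate:
        return "srmr_adequate"
    return None


def _identifiable_with(model: PathModel, candidate: tuple) -> bool:
    trial = model.copy()
    kind, a, b = candidate
    if kind == "beta":
        trial.add_beta(a, b)
    else:
        trial.add_psi(a, b)
    if check_bow_free(trial):
        return False
    ok, _ = check_block_recursive(trial)
    if not ok:
        return False
    try:
        degrees_of_freedom(trial)
    except ValueError:
        return False
    return True


def _free(model: PathModel, candidate: tuple, provenance: str) -> PathModel:
    out = model.copy()
    kind, a, b = candidate
    if kind == "beta":
        out.add_beta(a, b, provenance=provenance)
    else:
        out.add_psi(a, b, provenance=provenance)
    return out


def stepwise_refine(
    model: PathModel,
    data=None,
    *,
    S=None,
    n=None,
    evidence: EvidenceSet | None = None,
    config: FitConfig | None = None,
) -> tuple[PathModel, RefinementLog, FitResult]:
    """Run the heuristic stepwise search from an identified initial model.

    Returns the refined model, the replayable log and the final fit.
    Blacklisting is permanent, so the loop always terminates.
    """
    config = config or FitConfig()
    evidence = evidence or EvidenceSet()
    log = RefinementLog()
    current = model.copy()
    fit = fit_ml(current, data, S=S, n=n, config=config)
    blacklist: set = set()
    step = 0

    while True:
        reason = _adequate(fit, config)
        if reason is not None:
            log.stop_reason = reason
            break
        if len(log.accepted()) >= config.max_refine_steps:
            log.stop_reason = "step_cap"
            break
        mi_table = modification_indices(fit)
        progressed = False
        for row in mi_table.itertuples():
            kind = "beta" if row.kind == "beta" else "psi"
            candidate = (kind, row.target, row.source)
            if candidate in blacklist:
                continue
            admissible, source = candidate_evidence(candidate, evidence)
            if not admissible:
                blacklist.add(candidate)
                step += 1
                log.steps.append(
                    RefinementStep(step, candidate, row.mi, source, "rejected_no_evidence")
                )
                continue
            if not _identifiable_with(current, candidate):
                blacklist.add(candidate)
                step += 1
                log.steps.append(
                    RefinementStep(step, candidate, row.mi, source, "rejected_identifiability")
                )
                continue
            trial = _free(current, candidate, provenance=source)
            try:
                trial_fit = fit_ml(trial, data, S=S, n=n, config=config)
                label = (
                    f"{candidate[1]}~{candidate[2]}"
                    if kind == "beta"
                    else f"{candidate[1]}~~{candidate[2]}"
                )
                z = trial_fit.estimates()[label] / trial_fit.se[label]
            except Exception:
                blacklist.add(candidate)
                step += 1
                log.steps.append(
                    RefinementStep(step, candidate, row.mi, source, "rejected_nonconvergent")
                )
                continue
            step += 1
            if abs(z) < config.z_threshold:
                blacklist.add(candidate)
                log.steps.append(
                    RefinementStep(step, candidate, row.mi, source, "rejected_z", z=float(z))
                )
                continue
            current, fit = trial, trial_fit
            log.steps.append(
                RefinementStep(
                    step,
                    candidate,
                    row.mi,
                    source,
                    "accepted",
                    z=float(z),
                    chisq=fit.chisq,
                    p_value=fit.p_value,
                    rmsea_pclose=fit.rmsea_pclose,
                    srmr=fit.srmr,
                )
            )
            progressed = True
            break
        if not progressed:
            log.stop_reason = "no_admissible_candidates"
            break
    return current, log, fit


def replay_refinement(initial: PathModel, log: RefinementLog) -> PathModel:
    """Re-apply the accepted steps of a log to the initial model."""
    model = initial.copy()
    for s in log.accepted():
        kind, a, b = s.candidate
        if kind == "beta":
            model.add_beta(a, b, provenance=s.evidence)
        else:
            model.add_psi(a, b, provenance=s.evidence)
    return model
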