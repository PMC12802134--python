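"""Discretizing a fitted network into human-readable rules.

At the end of annealing, selectors and soft inclusions are near 0/1; a
cut (default 0.5) binarizes them: a rule is kept when its selector
exceeds the cut, a detector likewise, and a feature is a member of a
detector when its soft inclusion weight exceeds the cut.  Each surviving
rule reads as a conjunction of threshold clauses whose weight beta
contributes a multiplicative factor exp(beta) to the case odds when the
rule fires.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .model import ModelData, HyperParams, selector_value, soft_inclusion

if TYPE_CHECKING:  # pragma: no cover
    from .fit import FitResult

__all__ = [
    "Detector",
    "Rule",
    "RuleSet",
    "extract_rules",
    "render_rules",
    "export_rules",
    "import_rules",
    "evaluate_ruleset",
]


@dataclass
class Detector:
    modality: str  # "taxa" | "metabolite"
    member_ids: list[str]
    threshold: float  # taxa: relative-abundance sum; metab: standardized mean
    direction: str = "greater than"

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("detector must have at least one member")
        if self.modality == "taxa" and not 0 <= self.threshold <= 1:
            raise ValueError("taxa threshold must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "member_ids": list(self.member_ids),
            "threshold": self.threshold,
            "direction": self.direction,
        }


@dataclass
class Rule:
    detectors: list[Detector]
    beta: float

    def __post_init__(self) -> None:
        if not self.detectors:
            raise ValueError("rule must have at least one detector")

    @property
    def odds_factor(self) -> float:
        return math.exp(self.beta)

    def to_dict(self) -> dict:
        return {"beta": self.beta, "detectors": [d.to_dict() for d in self.detectors]}


@dataclass
class RuleSet:
    rules: list[Rule]
    intercept: float
    metab_standardization: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {"intercept": self.intercept, "rules": [r.to_dict() for r in self.rules]}


def extract_rules(
    fit: "FitResult",
    data: ModelData,
    hp: HyperParams = HyperParams(),
    cut: float = 0.5,
) -> RuleSet:
    """Binarize a fitted model at its final (annealed) temperatures.

    Rules/detectors/members survive when their selector or inclusion value
    exceeds ``cut``; detectors with no surviving member are dropped, and
    rules without surviving detectors are dropped.
    """
    params, temps = fit.params, fit.final_temps
    q = selector_value(params.rule_logits)
    z = selector_value(params.detector_logits)
    intercept = float(params.beta0)
    J, L = hp.J, hp.L
    rules: list[Rule] = []
    for k in range(hp.K):
        if q[k] <= cut:
            continue
        detectors: list[Detector] = []
        dead = False  # a selected detector that can never fire kills the rule
        for j in range(J):
            if z[k, j] <= cut:
                continue
            u = soft_inclusion(
                params.centers_M[k, j], params.radii_M[k, j], data.E_M, temps.tau_u
            )
            members = [data.metab_ids[i] for i in np.flatnonzero(u > cut)]
            thr = float(params.thresholds_M[k, j])
            if members:
                detectors.append(Detector("metabolite", members, thr))
            elif thr >= 0:
                # empty support aggregates to 0: 0 > thr is impossible
                dead = True
            # thr < 0 with no members: vacuously true, detector omitted
        for ell in range(L):
            if z[k, J + ell] <= cut:
                continue
            u = soft_inclusion(
                params.centers_T[k, ell], params.radii_T[k, ell], data.E_T, temps.tau_u
            )
            members = [data.taxa_ids[i] for i in np.flatnonzero(u > cut)]
            if members:
                detectors.append(
                    Detector("taxa", members, float(params.thresholds_T[k, ell]))
                )
            else:
                dead = True  # taxa thresholds are in [0, 1]
        if dead:
            continue
        if detectors:
            rules.append(Rule(detectors, float(params.beta[k])))
        else:
            # all selected detectors vacuous: a constant-true rule, i.e.
            # an intercept contribution
            intercept += float(params.beta[k])
    import warnings

    if not rules:
        warnings.warn("no rule survived selection; intercept-only model")
    return RuleSet(rules, intercept)


def _fmt_factor(x: float) -> str:
    return format(x, "#.3g").rstrip(".")


def render_rules(rs: RuleSet, case_label: str = "case") -> str:
    """English-language rendering, one paragraph per rule.

    Rules are ordered by |beta| descending; detector members are listed
    lexicographically.
    """
    if not rs.rules:
        return (
            "Intercept-only model: no rule survived selection. "
            f"Baseline odds of {case_label}: x{_fmt_factor(math.exp(rs.intercept))}."
        )
    lines = []
    for i, rule in enumerate(
        sorted(rs.rules, key=lambda r: (-abs(r.beta), r.beta)), start=1
    ):
        clauses = []
        for det in rule.detectors:
            members = ", ".join(sorted(det.member_ids))
            if det.modality == "taxa":
                agg = "sum of relative abundances"
            else:
                agg = "average standardized level"
            clauses.append(f"{agg} of {{{members}}} {det.direction} {det.threshold:.4g}")
        body = " AND ".join(clauses)
        factor = rule.odds_factor
        if rule.beta >= 0:
            change = f"increased by {_fmt_factor(factor)}-fold"
        else:
            change = f"decreased by {_fmt_factor(1.0 / factor)}-fold"
        lines.append(
            f"Rule {i}: IF {body} THEN odds of {case_label} "
            f"x{_fmt_factor(factor)} ({change})."
        )
    return "\n".join(lines)


def export_rules(rs: RuleSet, path: str) -> None:
    """Lossless JSON serialization of a rule set."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(rs.to_dict(), fh, indent=1, ensure_ascii=False)


def import_rules(path: str) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    rules = [
        Rule(
            [
                Detector(
                    d["modality"], list(d["member_ids"]), d["threshold"], d["direction"]
                )
                for d in r["detectors"]
            ],
            r["beta"],
        )
        for r in obj["rules"]
    ]
    return RuleSet(rules, obj["intercept"])


def evaluate_ruleset(
    rs: RuleSet, taxa_rel: pd.DataFrame, metab_std: pd.DataFrame
) -> np.ndarray:
    """Hard boolean evaluation of a rule set: predicted case labels.

    A detector fires when its aggregate strictly exceeds its threshold; a
    rule fires when all its detectors fire; the prediction is case when
    intercept + sum of firing rules' betas is positive.
    """
    n = len(taxa_rel)
    logit = np.full(n, rs.intercept)
    for rule in rs.rules:
        active = np.ones(n, dtype=bool)
        for det in rule.detectors:
            if det.modality == "taxa":
                agg = taxa_rel[det.member_ids].sum(axis=1).to_numpy()
            else:
                agg = metab_std[det.member_ids].mean(axis=1).to_numpy()
            active &= agg > det.threshold
        logit = logit + rule.beta * active
    return (logit > 0).astype(int)
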