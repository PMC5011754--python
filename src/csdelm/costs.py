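"""Cost-sensitive decisions and the rejection option.

Given vote probabilities P(j|tx) and a cost matrix C(i, j) — the cost of
assigning class i to a sample whose true class is j, zero on the diagonal
— the conditional risk of assigning class i is

    R(i|tx) = sum_j P(j|tx) * C(i, j)

and the cost-sensitive decision is the risk-minimising class.  With a
rejection option, the risk margin

    f(tx) = (second-smallest risk) - (smallest risk)

measures decision reliability: samples with f(tx) below a threshold
``delta`` are rejected instead of classified, incurring a per-class
rejection cost C(0, j) rather than a (typically larger) misclassification
cost.  An alternative "three-action" rule treats rejection as an extra
action with risk sum_j P(j|tx) * C(0, j) minimised jointly with the class
risks; the margin-threshold rule is the default.

All tie-breaks go to the lowest class index, so decisions are
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "REJECT",
    "CostSpec",
    "Decision",
    "uniform_costs",
    "conditional_risk",
    "decide",
    "rejection_margin",
    "decide_with_rejection",
    "incurred_cost",
    "decide_batch",
]


class _RejectType:
    """Singleton marker for the reject outcome."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "REJECT"

    def __reduce__(self):
        return (_RejectType, ())


REJECT = _RejectType()


@dataclass
class CostSpec:
    """Misclassification cost matrix, optional rejection costs and threshold.

    ``cost_matrix[i, j]`` is C(i, j): the cost of assigning class
    ``classes[i]`` to a sample of true class ``classes[j]``.  The diagonal
    must be zero and all costs nonnegative.  ``rejection_costs[j]`` is
    C(0, j); it and ``delta`` are present iff rejection is enabled.
    """

    classes: list
    cost_matrix: np.ndarray
    rejection_costs: np.ndarray | None = None
    delta: float | None = None

    def __post_init__(self):
        self.classes = list(self.classes)
        m = len(self.classes)
        if m < 2:
            raise ValueError("a cost spec needs at least 2 classes")
        C = np.asarray(self.cost_matrix, dtype=float)
        if C.shape != (m, m):
            raise ValueError(
                f"cost_matrix must be {m}x{m} for {m} classes, got {C.shape}"
            )
        if np.any(np.diag(C) != 0):
            raise ValueError("cost_matrix diagonal must be all zeros")
        if np.any(C < 0):
            raise ValueError("costs must be nonnegative")
        self.cost_matrix = C
        if self.rejection_costs is not None:
            r = np.asarray(self.rejection_costs, dtype=float)
            if r.shape != (m,):
                raise ValueError(
                    f"rejection_costs must have length {m}, got shape {r.shape}"
                )
            if np.any(r < 0):
                raise ValueError("rejection costs must be nonnegative")
            self.rejection_costs = r
        if self.delta is not None and self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def has_rejection(self) -> bool:
        return self.rejection_costs is not None and self.delta is not None

    def class_index(self, label) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise ValueError(
                f"label {label!r} not in class vocabulary {self.classes}"
            )

    def with_delta(self, delta: float) -> "CostSpec":
        return CostSpec(
            classes=self.classes,
            cost_matrix=self.cost_matrix.copy(),
            rejection_costs=None
            if self.rejection_costs is None
            else self.rejection_costs.copy(),
            delta=float(delta),
        )

    @classmethod
    def from_dict(cls, d: dict) -> "CostSpec":
        unknown = set(d) - {"classes", "cost_matrix", "rejection_costs", "delta"}
        if unknown:
            raise ValueError(f"unknown cost-spec keys: {sorted(unknown)}")
        for key in ("classes", "cost_matrix"):
            if key not in d:
                raise ValueError(f"cost spec is missing required key {key!r}")
        return cls(
            classes=d["classes"],
            cost_matrix=d["cost_matrix"],
            rejection_costs=d.get("rejection_costs"),
            delta=d.get("delta"),
        )

    @classmethod
    def from_json(cls, path) -> "CostSpec":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ValueError(f"invalid JSON in cost spec {path}: {exc}")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = {
            "classes": list(self.classes),
            "cost_matrix": self.cost_matrix.tolist(),
        }
        if self.rejection_costs is not None:
            d["rejection_costs"] = self.rejection_costs.tolist()
        if self.delta is not None:
            d["delta"] = self.delta
        return d

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def uniform_costs(classes: list) -> CostSpec:
    """0/1 cost matrix: every misclassification costs 1."""
    m = len(classes)
    C = np.ones((m, m)) - np.eye(m)
    return CostSpec(classes=classes, cost_matrix=C)


@dataclass
class Decision:
    """One classify-or-reject outcome with its risk diagnostics."""

    outcome: object  # class label or REJECT
    risk_vector: np.ndarray
    margin: float | None = None

    @property
    def rejected(self) -> bool:
        return self.outcome is REJECT


def _check_probs(P: np.ndarray, m: int) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (m,):
        raise ValueError(f"probability vector must have length {m}, got {P.shape}")
    if abs(P.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities must sum to 1, got {P.sum()!r}")
    return P


def conditional_risk(P: np.ndarray, C: np.ndarray) -> np.ndarray:
    """R(i) = sum_j P_j C(i, j) for every class i."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError(f"cost matrix must be square, got shape {C.shape}")
    P = _check_probs(P, C.shape[0])
    return C @ P


def decide(P: np.ndarray, C: np.ndarray, classes: list | None = None) -> Decision:
    """Risk-minimising class; ties go to the lowest class index.

    ``outcome`` is the class label when ``classes`` is given, else the
    class index.
    """
    risk = conditional_risk(P, C)
    s = int(np.argmin(risk))
    margin = None
    if len(risk) >= 2:
        _, margin = rejection_margin(risk)
    outcome = classes[s] if classes is not None else s
    return Decision(outcome=outcome, risk_vector=risk, margin=margin)


def rejection_margin(risk: np.ndarray) -> tuple[int, float]:
    """Risk-gap reliability margin.

    Returns ``(s, f)`` with ``s`` the risk-minimising class index
    (lowest-index tie-break) and ``f`` the gap between the runner-up risk
    and the minimum, ``f >= 0``.
    """
    risk = np.asarray(risk, dtype=float)
    if risk.ndim != 1 or len(risk) < 2:
        raise ValueError("need risks for at least 2 classes")
    s = int(np.argmin(risk))
    rest = np.delete(risk, s)
    return s, float(rest.min() - risk[s])


def decide_with_rejection(
    P: np.ndarray, spec: CostSpec, rule: str = "margin"
) -> Decision:
    """Classify-or-reject decision under a configured rejection option.

    ``rule="margin"`` (default): classify into the risk-minimising class
    when the risk margin f(tx) >= delta, otherwise reject.
    ``rule="three-action"``: rejection is an extra action with risk
    sum_j P_j C(0, j); the cheapest action wins, classes winning ties.
    """
    if spec.rejection_costs is None or spec.delta is None:
        raise ValueError(
            "rejection requires both rejection_costs and delta in the cost spec"
        )
    risk = conditional_risk(P, spec.cost_matrix)
    s, f = rejection_margin(risk)
    if rule == "margin":
        if f >= spec.delta:
            return Decision(outcome=spec.classes[s], risk_vector=risk, margin=f)
        return Decision(outcome=REJECT, risk_vector=risk, margin=f)
    if rule == "three-action":
        reject_risk = float(np.asarray(P) @ spec.rejection_costs)
        if reject_risk < risk[s]:
            return Decision(outcome=REJECT, risk_vector=risk, margin=f)
        return Decision(outcome=spec.classes[s], risk_vector=risk, margin=f)
    raise ValueError(f"unknown rejection rule {rule!r}")


def incurred_cost(decision: Decision, true_class, spec: CostSpec) -> float:
    """Realised cost of one decision against the true class.

    C(outcome, true) when classified (0 when correct); the rejection cost
    C(0, true) when rejected.
    """
    j = spec.class_index(true_class)
    if decision.rejected:
        if spec.rejection_costs is None:
            raise ValueError("decision was rejected but spec has no rejection costs")
        return float(spec.rejection_costs[j])
    i = spec.class_index(decision.outcome)
    return float(spec.cost_matrix[i, j])


def decide_batch(
    P: np.ndarray, spec: CostSpec, mode: str = "cs-delm", rule: str = "margin"
) -> list:
    """Apply one decision mode to every row of a probability matrix.

    ``mode="delm"``: plain majority vote (argmax probability), costs
    ignored at decision time.  ``mode="cs-delm"``: risk-minimising class.
    ``mode="cs-delm-reject"``: risk-minimising class with the configured
    rejection option.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    decisions = []
    for row in P:
        if mode == "delm":
            risk = conditional_risk(row, spec.cost_matrix)
            idx = int(np.argmax(row))
            decisions.append(Decision(outcome=spec.classes[idx], risk_vector=risk))
        elif mode == "cs-delm":
            decisions.append(decide(row, spec.cost_matrix, classes=spec.classes))
        elif mode == "cs-delm-reject":
            decisions.append(decide_with_rejection(row, spec, rule=rule))
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return decisions
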