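"""Evaluation metrics and experiment protocols for imbalanced data.

Metrics follow the imbalanced-classification convention: per-class
accuracies (PC on the positive class, NC on the negative class for binary
problems), their geometric mean (G-means), the average realised
misclassification/rejection cost, and the rejection fraction.  Rejected
samples count as incorrect in the per-class accuracies by default but
contribute only their rejection cost to the average cost.

Two protocols are provided: a rejection-threshold sweep over cached vote
probabilities, and a repeated random-split experiment comparing the plain
voting decision (D-ELM), the cost-sensitive decision (CS-D-ELM) and the
rejection-embedded cost-sensitive decision on identical probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .costs import CostSpec, decide_batch, incurred_cost
from .datasets import LabeledDataset, train_test_split
from .ensemble import fit_ensemble, predict_proba

__all__ = [
    "EvaluationReport",
    "evaluate",
    "SweepResult",
    "sweep_delta_from_probs",
    "sweep_delta",
    "RepeatedResult",
    "repeated_experiment",
    "MODES",
]

MODES = ("delm", "cs-delm", "cs-delm-reject")


@dataclass
class EvaluationReport:
    per_class_accuracy: np.ndarray
    nc: float | None
    pc: float | None
    g_means: float
    average_cost: float
    rejection_rate: float
    n_test: int

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": np.asarray(self.per_class_accuracy).tolist(),
            "nc": self.nc,
            "pc": self.pc,
            "g_means": self.g_means,
            "average_cost": self.average_cost,
            "rejection_rate": self.rejection_rate,
            "n_test": self.n_test,
        }


def evaluate(
    decisions: list,
    truth,
    spec: CostSpec,
    positive_class=None,
    rejects_in_denominator: bool = True,
) -> EvaluationReport:
    """Score a list of decisions against true labels.

    Per-class accuracy is (#correctly classified of class j) / (#class j);
    rejected samples are counted in the denominator (i.e. as errors)
    unless ``rejects_in_denominator`` is False, in which case they are
    excluded from the accuracy denominators entirely.  G-means is the
    geometric mean of the per-class accuracies over classes present in
    the truth.  ``positive_class`` (default: first class in the spec)
    fixes the PC/NC mapping for binary problems.
    """
    truth = np.asarray(truth, dtype=object)
    n = len(truth)
    if n < 1:
        raise ValueError("empty test set")
    if len(decisions) != n:
        raise ValueError(f"{len(decisions)} decisions but {n} truth labels")

    outcomes = np.asarray([d.outcome for d in decisions], dtype=object)
    rejected = np.asarray([d.rejected for d in decisions], dtype=bool)

    accs = np.full(len(spec.classes), np.nan)
    for idx, c in enumerate(spec.classes):
        in_class = truth == c
        denom = in_class if rejects_in_denominator else (in_class & ~rejected)
        if denom.sum() == 0:
            continue
        correct = in_class & ~rejected & (outcomes == c)
        accs[idx] = correct.sum() / denom.sum()

    present = ~np.isnan(accs)
    g_means = float(np.prod(accs[present]) ** (1.0 / present.sum()))

    nc = pc = None
    if len(spec.classes) == 2:
        pos = positive_class if positive_class is not None else spec.classes[0]
        p_idx = spec.class_index(pos)
        pc = float(accs[p_idx])
        nc = float(accs[1 - p_idx])

    total_cost = sum(incurred_cost(d, t, spec) for d, t in zip(decisions, truth))
    return EvaluationReport(
        per_class_accuracy=accs,
        nc=nc,
        pc=pc,
        g_means=g_means,
        average_cost=float(total_cost) / n,
        rejection_rate=float(rejected.sum()) / n,
        n_test=n,
    )


class SweepResult(NamedTuple):
    table: pd.DataFrame
    best_delta: float


def sweep_delta_from_probs(
    P: np.ndarray,
    truth,
    spec: CostSpec,
    deltas,
    rule: str = "margin",
    positive_class=None,
) -> SweepResult:
    """Evaluate the rejection decision at every threshold in ``deltas``.

    Vote probabilities are fixed (no retraining inside the sweep); only
    the classify-or-reject decision changes with delta.  The chosen delta
    minimises average cost, lowest delta winning ties.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("delta grid is empty")
    if np.any(deltas < 0):
        raise ValueError("delta grid must be nonnegative")
    if np.any(np.diff(deltas) < 0):
        raise ValueError("delta grid must be sorted ascending")
    rows = []
    for d in deltas:
        dec = decide_batch(P, spec.with_delta(d), mode="cs-delm-reject", rule=rule)
        rep = evaluate(dec, truth, spec, positive_class=positive_class)
        rows.append(
            {
                "delta": float(d),
                "average_cost": rep.average_cost,
                "rejection_rate": rep.rejection_rate,
                "g_means": rep.g_means,
                "nc": rep.nc,
                "pc": rep.pc,
            }
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["average_cost"].idxmin(), "delta"])
    return SweepResult(table=table, best_delta=best)


def sweep_delta(
    ensemble,
    test: LabeledDataset,
    spec: CostSpec,
    deltas,
    rule: str = "margin",
    positive_class=None,
) -> SweepResult:
    """Threshold sweep on a test set, from one cached probability pass."""
    P = predict_proba(ensemble, test.features)
    return sweep_delta_from_probs(
        P, test.labels, spec, deltas, rule=rule, positive_class=positive_class
    )


class RepeatedResult(NamedTuple):
    per_repeat: pd.DataFrame
    summary: pd.DataFrame


_METRICS = ["nc", "pc", "g_means", "average_cost", "rejection_rate"]


def repeated_experiment(
    data: LabeledDataset,
    spec: CostSpec,
    n_repeats: int = 30,
    train_size: int = 300,
    n_members: int = 50,
    hidden_size: int = 50,
    activation: str = "sigmoid",
    n_eliminate: int | None = None,
    base_seed: int = 0,
    delta_grid=None,
    tune_fraction: float = 0.25,
    rejection_rule: str = "margin",
    positive_class=None,
) -> RepeatedResult:
    """Repeated random-split comparison of the three decision modes.

    Per repeat: a seeded train/test split, one ensemble fit, then the
    D-ELM, CS-D-ELM and (when rejection is configured) rejection CS-D-ELM
    decisions are all taken from the same test-set vote probabilities.
    When ``delta_grid`` is given, delta is tuned per repeat by a sweep on
    a tuning split carved from the training portion (fraction
    ``tune_fraction``), never on the test set.  The summary holds
    per-mode means over repeats.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n = data.n_samples
    if train_size >= n:
        clamped = max(1, (2 * n) // 3)
        warnings.warn(
            f"train_size={train_size} >= n={n}; clamped to {clamped}",
            stacklevel=2,
        )
        train_size = clamped

    with_rejection = spec.rejection_costs is not None and (
        delta_grid is not None or spec.delta is not None
    )

    root = np.random.SeedSequence(base_seed)
    rows = []
    for r, repeat_seq in enumerate(root.spawn(n_repeats)):
        split_seq, tune_seq, ens_seq = repeat_seq.spawn(3)
        train, test = train_test_split(data, train_size, rng_seed=split_seq)

        delta = spec.delta
        if with_rejection and delta_grid is not None:
            tune_n = max(1, round(tune_fraction * train.n_samples))
            fit_part, tune_part = train_test_split(
                train, train.n_samples - tune_n, rng_seed=tune_seq
            )
        else:
            fit_part, tune_part = train, None

        ens = fit_ensemble(
            fit_part,
            n_members=n_members,
            hidden_size=hidden_size,
            activation=activation,
            n_eliminate=n_eliminate,
            rng_seed=ens_seq,
        )
        if tune_part is not None:
            delta = sweep_delta(
                ens, tune_part, spec, delta_grid, rule=rejection_rule
            ).best_delta

        P_test = predict_proba(ens, test.features)
        modes = ["delm", "cs-delm"] + (["cs-delm-reject"] if with_rejection else [])
        for mode in modes:
            mode_spec = spec.with_delta(delta) if mode == "cs-delm-reject" else spec
            dec = decide_batch(P_test, mode_spec, mode=mode, rule=rejection_rule)
            rep = evaluate(dec, test.labels, spec, positive_class=positive_class)
            rows.append(
                {
                    "repeat": r,
                    "mode": mode,
                    "delta": delta if mode == "cs-delm-reject" else None,
                    "k_survivors": ens.k,
                    "mean_member_accuracy": ens.mean_accuracy,
                    **{m: getattr(rep, m) for m in _METRICS},
                }
            )
    per_repeat = pd.DataFrame(rows)
    summary = (
        per_repeat.groupby("mode", sort=False)[_METRICS].mean().reset_index()
    )
    return RepeatedResult(per_repeat=per_repeat, summary=summary)
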