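"""Dissimilar ELM ensembles (D-ELM).

A voting ensemble of N independently seeded ELMs, pruned before voting by
a pairwise-disagreement ("dissimilarity") rule:

* ``Div[i, j]`` counts the reference samples on which members i and j
  predict different labels (symmetric, zero diagonal);
* ``eta_i = sum_j Div[i, j]`` is member i's total disagreement;
* with mean member accuracy ``p_bar <= 0.5`` the members with the
  *smallest* eta are eliminated (they agree with a mostly-wrong crowd);
  with ``0.5 < p_bar < 1`` the members with the *largest* eta are
  eliminated (they disagree with a mostly-right crowd).

The K survivors vote; per-class probabilities are vote counts over K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler

from .elm import ELMModel, init_elm, predict_labels, train_elm

__all__ = [
    "EnsembleModel",
    "VoteDistribution",
    "train_ensemble",
    "member_predictions",
    "dissimilarity_matrix",
    "eta_scores",
    "eliminate",
    "vote_probabilities",
    "fit_ensemble",
    "predict_proba",
    "majority_vote",
    "default_n_eliminate",
]


@dataclass
class VoteDistribution:
    """Vote tally of the K survivors on one sample: counts and counts/K."""

    counts: np.ndarray
    probabilities: np.ndarray
    classes: list


@dataclass
class EnsembleModel:
    members: list  # all N trained ELMModel, original order
    div_matrix: np.ndarray  # N x N disagreement counts
    eta: np.ndarray  # row sums of div_matrix
    mean_accuracy: float  # p_bar on the reference samples
    surviving: list  # ordered index subset, size K
    classes: list
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def k(self) -> int:
        return len(self.surviving)

    @property
    def survivors(self) -> list:
        return [self.members[i] for i in self.surviving]

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale


def default_n_eliminate(n_members: int) -> int:
    """Default pruning amount: ceil(N / 4)."""
    return -(-n_members // 4)


def train_ensemble(
    X: np.ndarray,
    y,
    classes: list,
    n_members: int,
    hidden_size: int,
    activation: str = "sigmoid",
    rng_seed: int | np.random.SeedSequence = 0,
) -> list:
    """Train ``n_members`` ELMs with independent seeded random streams.

    All members share ``hidden_size``, ``activation`` and the class
    vocabulary; their hidden layers come from child streams of one seed,
    so the ensemble is reproducible and members are mutually independent.
    """
    if n_members < 2:
        raise ValueError(f"n_members must be >= 2, got {n_members}")
    if len(set(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = np.asarray(X, dtype=float)
    seq = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    members = []
    for child in seq.spawn(n_members):
        model = init_elm(X.shape[1], hidden_size, activation, rng=child)
        members.append(train_elm(model, X, y, classes))
    return members


def member_predictions(members: list, X: np.ndarray) -> np.ndarray:
    """Label matrix of shape (n_samples, n_members): column i = member i."""
    cols = [predict_labels(m, X) for m in members]
    return np.stack(cols, axis=1)


def dissimilarity_matrix(predictions: np.ndarray) -> np.ndarray:
    """Pairwise disagreement counts over the M reference samples.

    ``predictions`` is M x N (rows = reference samples, columns =
    classifiers).  Entry (i, j) of the result counts samples where
    classifiers i and j predict different labels.
    """
    predictions = np.asarray(predictions)
    if predictions.ndim != 2:
        raise ValueError("predictions must be an M x N matrix of labels")
    n_samples, n_clf = predictions.shape
    if n_samples < 1 or n_clf < 2:
        raise ValueError(
            f"need M >= 1 samples and N >= 2 classifiers, got {predictions.shape}"
        )
    div = np.zeros((n_clf, n_clf), dtype=int)
    for i in range(n_clf):
        for j in range(i + 1, n_clf):
            d = int(np.sum(predictions[:, i] != predictions[:, j]))
            div[i, j] = d
            div[j, i] = d
    return div


def eta_scores(div: np.ndarray) -> np.ndarray:
    """Total disagreement of each member: row sums of the Div matrix."""
    return np.asarray(div).sum(axis=1)


def eliminate(eta: np.ndarray, mean_accuracy: float, n_eliminate: int) -> list:
    """Surviving member indices after dissimilarity-based pruning.

    With ``mean_accuracy <= 0.5`` the ``n_eliminate`` members with smallest
    eta are dropped; otherwise those with largest eta.  Ties in eta drop
    the higher original index first, so the result is deterministic.
    Survivors keep their original order.
    """
    eta = np.asarray(eta)
    n = len(eta)
    if not 0 <= n_eliminate <= n - 1:
        raise ValueError(
            f"n_eliminate must be in [0, {n - 1}], got {n_eliminate}"
        )
    if not 0.0 < mean_accuracy < 1.0:
        raise ValueError(
            f"mean_accuracy must lie strictly in (0, 1), got {mean_accuracy}"
        )
    if n_eliminate == 0:
        return list(range(n))
    idx = np.arange(n)
    if mean_accuracy <= 0.5:
        # mostly-wrong crowd: low disagreement means agreeing with errors
        order = np.lexsort((-idx, eta))
    else:
        order = np.lexsort((-idx, -eta))
    dropped = set(order[:n_eliminate].tolist())
    return [i for i in range(n) if i not in dropped]


def vote_probabilities(votes, classes: list) -> VoteDistribution:
    """Tally K survivor votes into per-class counts and probabilities."""
    votes = list(votes)
    if len(votes) == 0:
        raise RuntimeError("empty survivor set: no votes to tally")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros(len(classes), dtype=int)
    for v in votes:
        counts[index[v]] += 1
    return VoteDistribution(
        counts=counts, probabilities=counts / len(votes), classes=list(classes)
    )


def fit_ensemble(
    train,
    n_members: int = 20,
    hidden_size: int = 50,
    activation: str = "sigmoid",
    n_eliminate: int | None = None,
    rng_seed: int | np.random.SeedSequence = 0,
    standardize: bool = True,
    reference=None,
    retrain_survivors: bool = False,
) -> EnsembleModel:
    """Train and prune a D-ELM ensemble on a :class:`LabeledDataset`.

    Parameters
    ----------
    train : LabeledDataset
        Training data; also the reference sample set for the Div matrix
        and mean accuracy p_bar, unless ``reference`` is given.
    n_eliminate : int, optional
        Members to prune; defaults to ceil(N / 4).
    standardize : bool
        Standardize features (training-split statistics) before training;
        random-projection ELMs are scale-sensitive.
    reference : LabeledDataset, optional
        Held-out split on which to compute disagreements and p_bar.
    retrain_survivors : bool
        Redraw and refit the survivors after pruning.  Off by default:
        fresh random hidden layers would invalidate the dissimilarity
        selection, so survivors are normally reused as trained.
    """
    if n_eliminate is None:
        n_eliminate = default_n_eliminate(n_members)
    if not 0 <= n_eliminate <= n_members - 1:
        raise ValueError(
            f"n_eliminate must be in [0, {n_members - 1}], got {n_eliminate}"
        )
    seq = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    train_seq, retrain_seq = seq.spawn(2)

    X = np.asarray(train.features, dtype=float)
    mean = scale = None
    if standardize:
        scaler = StandardScaler().fit(X)
        mean = scaler.mean_
        scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
        X = (X - mean) / scale
    classes = list(train.classes)
    members = train_ensemble(
        X, train.labels, classes, n_members, hidden_size, activation, train_seq
    )

    if reference is None:
        ref_X, ref_y = X, np.asarray(train.labels, dtype=object)
    else:
        ref_X = np.asarray(reference.features, dtype=float)
        if mean is not None:
            ref_X = (ref_X - mean) / scale
        ref_y = np.asarray(reference.labels, dtype=object)

    preds = member_predictions(members, ref_X)
    div = dissimilarity_matrix(preds)
    eta = eta_scores(div)
    p_bar = float(np.mean(preds == ref_y[:, None]))

    if not 0.0 < p_bar < 1.0:
        warnings.warn(
            f"mean member accuracy p_bar={p_bar:.3f} is outside (0, 1); "
            "the elimination rule does not apply, keeping all members",
            stacklevel=2,
        )
        surviving = list(range(n_members))
    else:
        surviving = eliminate(eta, p_bar, n_eliminate)

    if retrain_survivors:
        for pos, i in zip(retrain_seq.spawn(len(surviving)), surviving):
            model = init_elm(X.shape[1], hidden_size, activation, rng=pos)
            members[i] = train_elm(model, X, train.labels, classes)

    return EnsembleModel(
        members=members,
        div_matrix=div,
        eta=eta,
        mean_accuracy=p_bar,
        surviving=surviving,
        classes=classes,
        feature_mean=mean,
        feature_scale=scale,
    )


def predict_proba(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Survivor vote probabilities P(j | tx) for each row of X (n x m)."""
    survivors = ensemble.survivors
    if len(survivors) == 0:
        raise RuntimeError("ensemble has no surviving members")
    Xs = ensemble._transform(X)
    preds = member_predictions(survivors, Xs)
    counts = np.zeros((preds.shape[0], len(ensemble.classes)), dtype=int)
    for c_idx, c in enumerate(ensemble.classes):
        counts[:, c_idx] = np.sum(preds == c, axis=1)
    return counts / len(survivors)


def majority_vote(ensemble: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Plurality label of the survivors; ties go to the lowest class index."""
    proba = predict_proba(ensemble, X)
    idx = np.argmax(proba, axis=1)
    return np.asarray([ensemble.classes[i] for i in idx], dtype=object)
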