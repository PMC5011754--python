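"""Labeled feature tables and a synthetic imbalanced-data generator.

The generator emulates reduced gene-expression classification sets:
small sample size, moderate-to-large feature count, imbalanced classes.
Features are class-conditional Gaussians — a small block of informative
features whose class means are shifted apart, the rest pure noise — which
reproduces the "high-dimensional, redundant, imbalanced" structure these
classifiers are built for without modelling platform-specific noise.
Class counts are exact (largest-remainder rounding of the proportions),
so imbalance is controlled, and everything is seeded.

Six presets mirror the shapes of commonly used benchmark sets (Diabetes,
Heart, Colon, Mushroom, Protein, Leukemia after feature selection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "SyntheticSpec",
    "generate",
    "train_test_split",
    "read_csv",
    "write_csv",
    "PRESETS",
    "preset",
]


@dataclass
class LabeledDataset:
    """Numeric feature matrix with per-sample class labels."""

    features: np.ndarray  # n x p float
    labels: np.ndarray  # length n, object dtype
    classes: list
    feature_names: list | None = None
    sample_ids: list | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        n, p = self.features.shape
        if n < 1 or p < 1:
            raise ValueError("need at least 1 sample and 1 feature")
        if len(self.labels) != n:
            raise ValueError(
                f"{n} samples but {len(self.labels)} labels"
            )
        if np.isnan(self.features).any():
            raise ValueError("features contain missing values")
        vocab = set(self.classes)
        for label in self.labels:
            if label not in vocab:
                raise ValueError(f"label {label!r} not in vocabulary {self.classes}")
        if self.feature_names is None:
            self.feature_names = [f"g{i + 1}" for i in range(p)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1}" for i in range(n)]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in self.classes}

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            classes=list(self.classes),
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic imbalanced dataset.

    ``effect_size`` is the separation of adjacent class means on each
    informative feature, in units of ``noise_sd``; 0 makes labels
    independent of features.
    """

    n_samples: int
    n_features: int
    class_proportions: tuple
    n_informative: int = 2
    effect_size: float = 1.5
    noise_sd: float = 1.0
    rng_seed: int = 0
    class_names: list | None = None

    def __post_init__(self):
        props = np.asarray(self.class_proportions, dtype=float)
        if len(props) < 2:
            raise ValueError("need at least 2 classes")
        if np.any(props <= 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must be positive and sum to 1, got {props}"
            )
        if not 1 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative must be in [1, {self.n_features}], "
                f"got {self.n_informative}"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.class_names is None:
            self.class_names = [f"c{i + 1}" for i in range(len(props))]
        if len(self.class_names) != len(props):
            raise ValueError("class_names length must match class_proportions")


def _exact_counts(n: int, proportions) -> np.ndarray:
    """Largest-remainder rounding of n * proportions to integers summing to n."""
    raw = np.asarray(proportions, dtype=float) * n
    base = np.floor(raw).astype(int)
    shortfall = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:shortfall]] += 1
    return base


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Draw a seeded class-conditional Gaussian dataset.

    Class c's mean on every informative feature is offset by
    ``(c - (m-1)/2) * effect_size * noise_sd``; all remaining features are
    N(0, noise_sd) noise shared across classes.  Sharing one shift across
    the informative block makes those features mutually redundant.
    """
    rng = np.random.default_rng(spec.rng_seed)
    m = len(spec.class_proportions)
    counts = _exact_counts(spec.n_samples, spec.class_proportions)
    offsets = (np.arange(m) - (m - 1) / 2) * spec.effect_size * spec.noise_sd

    X = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_features))
    labels = np.empty(spec.n_samples, dtype=object)
    start = 0
    for c_idx, count in enumerate(counts):
        block = slice(start, start + count)
        X[block, : spec.n_informative] += offsets[c_idx]
        labels[block] = spec.class_names[c_idx]
        start += count
    perm = rng.permutation(spec.n_samples)
    return LabeledDataset(
        features=X[perm], labels=labels[perm], classes=list(spec.class_names)
    )


def train_test_split(
    data: LabeledDataset,
    train_size: int,
    rng_seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded random partition into ``train_size`` training samples and the rest."""
    n = data.n_samples
    if not 1 <= train_size < n:
        raise ValueError(f"train_size must be in [1, {n - 1}], got {train_size}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(n)
    return data.subset(np.sort(perm[:train_size])), data.subset(
        np.sort(perm[train_size:])
    )


def write_csv(data: LabeledDataset, path, label_column: str = "label") -> None:
    """Write a header + one-row-per-sample CSV; features then the label column."""
    df = pd.DataFrame(data.features, columns=data.feature_names)
    df[label_column] = [str(v) for v in data.labels]
    df.to_csv(path, index=False)


def read_csv(path, label_column: str = "label", classes: list | None = None) -> LabeledDataset:
    """Read a labeled feature table written by :func:`write_csv`.

    Class order is first-appearance order unless ``classes`` is supplied.
    Raises informative errors naming the offending row/column on missing
    or non-numeric cells.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty")
    if label_column not in df.columns:
        raise ValueError(
            f"{path}: missing label column {label_column!r} "
            f"(columns: {list(df.columns)[:10]}...)"
        )
    labels = df[label_column].astype(str).to_numpy(dtype=object)
    feats = df.drop(columns=[label_column])
    for col in feats.columns:
        numeric = pd.to_numeric(feats[col], errors="coerce")
        bad = numeric.isna() & feats[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {feats[col][row]!r} "
                f"in column {col!r}, row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        feats[col] = numeric
    if classes is None:
        seen: dict = {}
        for v in labels:
            seen.setdefault(v, None)
        classes = list(seen)
    return LabeledDataset(
        features=feats.to_numpy(dtype=float),
        labels=labels,
        classes=classes,
        feature_names=list(feats.columns),
    )


# Shapes of six reduced expression benchmarks (post feature selection):
# (n, p, class names, per-class counts).
_PRESET_TABLE = {
    "diabetes-like": (97, 8, ["relapse", "nonrelapse"], [46, 51]),
    "heart-like": (270, 13, ["negative", "positive"], [150, 120]),
    "colon-like": (62, 52, ["negative", "positive"], [19, 43]),
    "mushroom-like": (263, 43, ["negative", "positive"], [111, 152]),
    "protein-like": (334, 73, ["negative", "positive"], [215, 119]),
    "leukemia-like": (72, 7129, ["ALL", "MLL", "AML"], [24, 20, 28]),
}

PRESETS = sorted(_PRESET_TABLE)


def preset(name: str, rng_seed: int = 0) -> SyntheticSpec:
    """SyntheticSpec for one of the named benchmark-shaped presets."""
    if name not in _PRESET_TABLE:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}"
        )
    n, p, names, counts = _PRESET_TABLE[name]
    return SyntheticSpec(
        n_samples=n,
        n_features=p,
        class_proportions=tuple(c / n for c in counts),
        n_informative=min(2, p),
        effect_size=1.5,
        noise_sd=1.0,
        rng_seed=rng_seed,
        class_names=list(names),
    )
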