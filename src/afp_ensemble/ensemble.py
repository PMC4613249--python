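"""The undersampling random-forest ensemble.

Class imbalance is handled by random undersampling: negatives in the
training set are sampled without replacement down to G times the number
of positives, partitioned into G disjoint groups of positive-set size,
and each group is joined with the full positive set to form one balanced
training subset.  One base classifier (a random forest by default) is
trained per subset and test instances are labeled by majority vote of the
G members.  G is odd by default ({1, 3, 5, 7, 9, 11, 13, 15}; 9 is the
ratio found optimal on the original AFP benchmark), so ties cannot occur;
if an even G is configured explicitly, a tie votes negative (the prior
majority class).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier

from .feature_assembly import FeatureMatrix

_ARCHIVE_FORMAT_VERSION = 1

#: Default admissible undersampling ratios (the degenerate 1 plus the sweep).
ALLOWED_G = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass(frozen=True)
class EnsembleConfig:
    """Configuration of the undersampling ensemble.

    ``G`` is both the negative:positive sampling ratio and the number of
    ensemble members.  ``n_trees`` and ``max_features`` parameterize the
    random-forest base learner (features-per-split defaults to sqrt(d));
    any classifier honoring the sklearn fit/predict contract may be
    plugged in via ``base_learner``.
    """

    G: int = 9
    n_trees: int = 100
    max_features: str | int | float = "sqrt"
    seed: int = 0
    sampling_seed: int | None = None  # defaults to seed
    base_learner: object | None = None
    allow_any_G: bool = False

    def __post_init__(self) -> None:
        if self.G < 1:
            raise ValueError("G must be >= 1")
        if not self.allow_any_G and self.G not in ALLOWED_G:
            raise ValueError(
                f"G={self.G} outside the validated set {ALLOWED_G}; "
                "pass allow_any_G=True to override"
            )

    @property
    def effective_sampling_seed(self) -> int:
        return self.seed if self.sampling_seed is None else self.sampling_seed

    def make_member(self, member_index: int):
        """A fresh, deterministically seeded base classifier."""
        member_seed = (self.seed * 1000003 + member_index) % (2**31 - 1)
        if self.base_learner is not None:
            est = clone(self.base_learner)
            if "random_state" in est.get_params():
                est.set_params(random_state=member_seed)
            return est
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=member_seed,
            n_jobs=1,
        )


@dataclass
class EnsembleModel:
    """G trained members plus the voting rule and training column order."""

    members: list
    config: EnsembleConfig
    feature_names: list[str]

    @property
    def G(self) -> int:
        return len(self.members)

    def save(self, path) -> None:
        joblib.dump(
            {
                "format_version": _ARCHIVE_FORMAT_VERSION,
                "members": self.members,
                "config": self.config,
                "feature_names": self.feature_names,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        payload = joblib.load(path)
        if payload.get("format_version") != _ARCHIVE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model archive version "
                f"{payload.get('format_version')!r}"
            )
        return cls(
            members=payload["members"],
            config=payload["config"],
            feature_names=payload["feature_names"],
        )


def build_subsets(
    train: FeatureMatrix, G: int, seed: int
) -> list[FeatureMatrix]:
    """Undersample and partition the training data into G balanced subsets.

    Exactly G*P negatives (P = number of positives) are drawn without
    replacement and split into G disjoint groups of P; subset k is the
    full positive set plus group k (2P rows each).
    """
    if train.labels is None:
        raise ValueError("build_subsets requires a labeled matrix")
    pos_idx = np.flatnonzero(train.labels == 1)
    neg_idx = np.flatnonzero(train.labels == 0)
    P = pos_idx.size
    if P < 1:
        raise ValueError("training data has no positive samples")
    if neg_idx.size < G * P:
        raise ValueError(
            f"need at least G*P = {G * P} negatives but found "
            f"{neg_idx.size}; use a smaller G"
        )
    rng = np.random.default_rng(seed)
    sampled = rng.choice(neg_idx, size=G * P, replace=False)
    subsets = []
    for k in range(G):
        group = sampled[k * P:(k + 1) * P]
        subsets.append(train.select_rows(np.concatenate([pos_idx, group])))
    return subsets


def train(train_matrix: FeatureMatrix,
          config: EnsembleConfig | None = None) -> EnsembleModel:
    """Fit the G-member undersampling ensemble on labeled training data."""
    config = config or EnsembleConfig()
    if train_matrix.labels is None:
        raise ValueError("training requires labels")
    if len(np.unique(train_matrix.labels)) < 2:
        raise ValueError("training data must contain both classes")
    subsets = build_subsets(
        train_matrix, config.G, config.effective_sampling_seed
    )
    members = []
    for k, subset in enumerate(subsets):
        est = config.make_member(k)
        est.fit(subset.values, subset.labels)
        members.append(est)
    return EnsembleModel(
        members=members,
        config=config,
        feature_names=list(train_matrix.feature_names),
    )


def predict(
    model: EnsembleModel, X: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote prediction: ``(labels, votes)`` with votes in [0, G].

    A sample is positive iff strictly more than G/2 members vote positive;
    with G odd a tie is impossible, with G even a tie (votes == G/2) is
    resolved to the negative class.
    """
    if list(X.feature_names) != list(model.feature_names):
        mismatch = next(
            (a for a, b in zip(X.feature_names, model.feature_names)
             if a != b),
            None,
        )
        raise ValueError(
            "feature columns do not match training columns "
            f"(first mismatch: {mismatch!r}, "
            f"{X.n_features} vs {len(model.feature_names)} columns)"
        )
    votes = np.zeros(X.n_samples, dtype=int)
    for member in model.members:
        votes += member.predict(X.values).astype(int)
    G = model.G
    if G % 2 == 1:
        assert not np.any(votes * 2 == G), "tie with odd G is impossible"
    labels = (votes * 2 > G).astype(int)
    return labels, votes
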