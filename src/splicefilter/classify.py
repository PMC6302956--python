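"""Self-trained random-forest filtering of candidate junctions.

Each dataset trains its own model: aggressive rule-based filtering labels
only the extreme cases (clearly genuine / clearly spurious), the labelled
sets are balanced by synthetic minority oversampling (SMOTE), a 100-tree
random forest is trained on the balanced feature matrices, and finally every
junction is scored with the forest's vote fraction.  Scores >= 0.5 (by
default) are called genuine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

from .model import (
    ContractError,
    IntronLocus,
    JunctionRecord,
    JunctionVerdict,
    N_FEATURES,
    PipelineConfig,
    TrainingError,
)


@dataclass
class TrainingSets:
    positive_keys: set[IntronLocus]
    negative_keys: set[IntronLocus]
    balanced_features: np.ndarray
    balanced_labels: np.ndarray
    seed: int


def label_junction(record: JunctionRecord, config: PipelineConfig) -> str | None:
    """Apply the rule sets to one junction: 'positive', 'negative' or None.

    The positive rules demand every strong-evidence signal at once; the
    negative rules fire on any single characteristic false-positive
    signature.  Most junctions match neither and stay unlabelled — the rules
    aim for precision, the forest generalises to the rest.
    """
    m = record.metrics
    if record.site_call is None or record.hamming is None:
        raise ContractError("site call and hamming scores required for labelling")
    min_hamming = record.hamming.min_score
    is_canonical_ish = record.site_call.category in ("canonical", "semi_canonical")

    positive = (
        is_canonical_ish
        and m.nb_reliable >= config.pos_min_reliable
        and m.entropy >= config.pos_min_entropy
        and m.maxmmes >= config.pos_min_maxmmes
        and m.mean_mismatches <= config.pos_max_mean_mismatches
        and min_hamming >= config.pos_min_hamming
    )
    if positive:
        return "positive"
    negative = (
        (record.site_call.category == "novel" and m.nb_raw <= config.neg_novel_max_raw)
        or (m.entropy == 0.0 and m.nb_raw <= config.neg_zero_entropy_max_raw)
        or (min_hamming <= config.neg_max_hamming)
        or (m.maxmmes <= config.neg_low_mmes_cutoff and m.nb_reliable == 0)
    )
    if negative:
        return "negative"
    return None


def build_training_keys(
    junctions: dict[IntronLocus, JunctionRecord], config: PipelineConfig
) -> tuple[set[IntronLocus], set[IntronLocus]]:
    """Rule-label all junctions into disjoint positive/negative key sets."""
    positive: set[IntronLocus] = set()
    negative: set[IntronLocus] = set()
    for locus, record in junctions.items():
        label = label_junction(record, config)
        if label == "positive":
            positive.add(locus)
        elif label == "negative":
            negative.add(locus)
    if len(positive) < config.min_training_set:
        raise TrainingError(
            f"positive training set too small ({len(positive)} < "
            f"{config.min_training_set}); consider relaxing the positive rules"
        )
    if len(negative) < config.min_training_set:
        raise TrainingError(
            f"negative training set too small ({len(negative)} < "
            f"{config.min_training_set}); consider relaxing the negative rules"
        )
    return positive, negative


def smote_balance(
    minority: np.ndarray,
    majority: np.ndarray,
    k: int = 5,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow the minority matrix to the majority size by SMOTE.

    Each synthetic sample sits on the segment between a minority sample and
    one of its k nearest minority neighbours (uniform interpolation factor).
    Degenerate cases: with a single minority sample the point is duplicated;
    k is capped at minority size - 1.  Deterministic under a fixed seed.
    """
    minority = np.asarray(minority, dtype=float)
    majority = np.asarray(majority, dtype=float)
    if minority.shape[0] == 0:
        raise ValueError("minority set is empty")
    deficit = majority.shape[0] - minority.shape[0]
    if deficit <= 0:
        return minority, majority
    rng = np.random.default_rng(seed)
    n = minority.shape[0]
    if n == 1:
        synthetic = np.repeat(minority, deficit, axis=0)
        return np.vstack([minority, synthetic]), majority
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(minority)
    _, neighbor_idx = nn.kneighbors(minority)  # column 0 is the point itself
    base = rng.integers(0, n, size=deficit)
    pick = rng.integers(1, k + 1, size=deficit)
    gap = rng.random(size=deficit)[:, None]
    partners = neighbor_idx[base, pick]
    synthetic = minority[base] + gap * (minority[partners] - minority[base])
    return np.vstack([minority, synthetic]), majority


def build_training_sets(
    junctions: dict[IntronLocus, JunctionRecord],
    config: PipelineConfig,
    features: dict[IntronLocus, np.ndarray],
) -> TrainingSets:
    """Rule-label, assemble feature matrices, and SMOTE-balance the classes."""
    positive, negative = build_training_keys(junctions, config)
    pos_mat = np.array([features[k] for k in sorted(positive)])
    neg_mat = np.array([features[k] for k in sorted(negative)])
    if pos_mat.shape[0] <= neg_mat.shape[0]:
        pos_mat, neg_mat = smote_balance(pos_mat, neg_mat, config.smote_k, config.seed)
    else:
        neg_mat, pos_mat = smote_balance(neg_mat, pos_mat, config.smote_k, config.seed)
    feats = np.vstack([pos_mat, neg_mat])
    labels = np.concatenate([np.ones(len(pos_mat)), np.zeros(len(neg_mat))])
    return TrainingSets(
        positive_keys=positive,
        negative_keys=negative,
        balanced_features=feats,
        balanced_labels=labels,
        seed=config.seed,
    )


def train_forest(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 100,
    seed: int = 1,
) -> RandomForestClassifier:
    """Train the random-forest ensemble on balanced labelled sets.

    Trees are grown to purity, so the predicted probability equals the
    fraction of trees voting genuine.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise TrainingError("training labels contain a single class")
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ContractError(
            f"expected ({features.shape[0]}, {N_FEATURES}) feature matrix, "
            f"got {features.shape}"
        )
    model = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )
    model.fit(features, labels)
    return model


def score_and_filter(
    model: RandomForestClassifier,
    junction_features: dict[IntronLocus, np.ndarray],
    threshold: float = 0.5,
) -> dict[IntronLocus, JunctionVerdict]:
    """Assign each junction a genuineness probability and a verdict.

    A junction is genuine iff probability >= threshold (0.5 by default;
    raise it to prioritise precision, lower it for recall).  Output keys are
    exactly the input keys — filtering never invents junctions.
    """
    if not junction_features:
        return {}
    keys = sorted(junction_features)
    mat = np.array([junction_features[k] for k in keys], dtype=float)
    if mat.shape[1] != N_FEATURES:
        raise ContractError(f"feature length {mat.shape[1]} != {N_FEATURES}")
    genuine_col = list(model.classes_).index(1)
    probs = model.predict_proba(mat)[:, genuine_col]
    return {
        k: JunctionVerdict(probability=float(p), genuine=bool(p >= threshold))
        for k, p in zip(keys, probs)
    }
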