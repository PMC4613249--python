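"""Intrinsic-disorder descriptors (28 features per protein).

From a per-residue disorder score vector (VSL2-style output in [0, 1]):
mean and population standard deviation of all scores (2), counts of
disordered / ordered segments (2), min/max segment lengths of each class
(4), and the mean disorder score of each of the 20 residue types (20).
A residue is called disordered when its score is >= the threshold
(default 0.5, the conventional decision boundary of disorder predictors);
a segment is a maximal run of same-class residues.
"""

from __future__ import annotations

import numpy as np

from .io_formats import AMINO_ACIDS, DisorderProfile, ProteinRecord

DISORDER_FEATURE_NAMES: tuple[str, ...] = (
    "dis_mean",
    "dis_std",
    "dis_n_disorder_segments",
    "dis_n_nondisorder_segments",
    "dis_min_disorder_len",
    "dis_max_disorder_len",
    "dis_min_nondisorder_len",
    "dis_max_nondisorder_len",
) + tuple(f"dis_avg_score_{aa}" for aa in AMINO_ACIDS)

DEFAULT_THRESHOLD: float = 0.5


def _segment_lengths(mask: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a boolean vector, in order."""
    lengths: list[int] = []
    run = 0
    for flag in mask:
        if flag:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


def disorder_features(
    record: ProteinRecord,
    profile: DisorderProfile,
    threshold: float = DEFAULT_THRESHOLD,
) -> np.ndarray:
    """The 28-dimensional disorder feature vector (see module docstring).

    When no segment of a class exists, its min and max lengths are 0.
    A residue type absent from the sequence gets average score 0 (a
    sentinel, recorded in the feature metadata).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly in (0, 1)")
    if profile.length != record.length:
        raise ValueError(
            f"{record.id}: disorder profile length {profile.length} "
            f"!= sequence length {record.length}"
        )
    scores = profile.scores
    disordered = scores >= threshold
    dis_lens = _segment_lengths(disordered)
    ord_lens = _segment_lengths(~disordered)

    per_residue = np.zeros(20)
    seq = np.frombuffer(record.sequence.encode(), dtype=np.uint8)
    for k, aa in enumerate(AMINO_ACIDS):
        sel = seq == ord(aa)
        if sel.any():
            per_residue[k] = scores[sel].mean()

    return np.concatenate([
        [
            scores.mean(),
            scores.std(),  # population form (divide by L)
            len(dis_lens),
            len(ord_lens),
            min(dis_lens) if dis_lens else 0,
            max(dis_lens) if dis_lens else 0,
            min(ord_lens) if ord_lens else 0,
            max(ord_lens) if ord_lens else 0,
        ],
        per_residue,
    ])
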