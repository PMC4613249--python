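"""Evolutionary-information descriptors from PSSM profiles.

Each L x 20 PSSM entry is first squashed into (0, 1) by the logistic
sigmoid f(x) = 1/(1 + e^(-x)); the scaled matrix is then reduced to a
10 x 10 functional-group-pair table: rows are grouped by the functional
group of the sequence residue at each position, columns by the group of
the target amino acid, the scaled scores summed within each pair and
divided by the sequence length L.  Flattened row-group-major this yields
100 features per protein.
"""

from __future__ import annotations

import numpy as np

from .descriptors_composition import DEFAULT_ALPHABET, FunctionalGroupAlphabet
from .io_formats import ProteinRecord, PSSMProfile


def sigmoid_scale(x):
    """Logistic sigmoid, elementwise: strictly increasing onto (0, 1),
    with f(x) + f(-x) = 1."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    expx = np.exp(x[~pos])  # stable for large negative x
    out[~pos] = expx / (1.0 + expx)
    if out.ndim == 0:
        return float(out)
    return out


def pssm_group_features(
    record: ProteinRecord,
    profile: PSSMProfile,
    alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
) -> np.ndarray:
    """100-dimensional group-pair PSSM encoding (see module docstring)."""
    if profile.length != record.length:
        raise ValueError(
            f"{record.id}: PSSM has {profile.length} rows but sequence "
            f"length is {record.length}"
        )
    lookup = {
        aa: k for k, (_, grp) in enumerate(alphabet.groups) for aa in grp
    }
    try:
        row_groups = np.array([lookup[aa] for aa in record.sequence])
    except KeyError as exc:
        raise ValueError(
            f"{record.id}: nonstandard residue {exc.args[0]!r}"
        ) from None
    col_groups = np.array([lookup[aa] for aa in profile.alphabet])

    scaled = sigmoid_scale(profile.scores)
    g = alphabet.size
    # Sum columns into groups, then rows into groups.
    col_sums = np.zeros((record.length, g))
    for j in range(g):
        col_sums[:, j] = scaled[:, col_groups == j].sum(axis=1)
    pair = np.zeros((g, g))
    for i in range(g):
        rows = row_groups == i
        if rows.any():
            pair[i] = col_sums[rows].sum(axis=0)
    return pair.ravel() / record.length


def pssm_feature_names(
    alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
) -> list[str]:
    return [
        f"pssm_{gi}_{gj}"
        for gi in alphabet.names
        for gj in alphabet.names
    ]
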