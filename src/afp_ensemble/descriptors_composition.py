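"""Reduced-alphabet sequence composition descriptors.

The 20 standard amino acids are partitioned into 10 functional groups by
side-chain chemistry (phenyl, carboxyl, imidazole, primary amine,
guanidino, thiol, sulfur, amido, hydroxyl, non-polar).  Group amino-acid
composition (AAC, 10 features) is the fraction of residues in each group,
f(g_i) = N(g_i)/L; group dipeptide composition (DPC, 100 features) is the
fraction of overlapping residue pairs in each ordered group pair,
f(g_i g_j) = N(g_i g_j)/(L-1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ProteinRecord


@dataclass(frozen=True)
class FunctionalGroupAlphabet:
    """An ordered partition of the 20 standard residues into named groups."""

    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        members = [aa for _, group in self.groups for aa in group]
        if sorted(members) != sorted("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError(
                "functional groups must partition the 20 standard residues"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.groups)

    @property
    def size(self) -> int:
        return len(self.groups)

    def index_of(self, residue: str) -> int:
        return _GROUP_INDEX[residue]


#: The default 10-group side-chain-chemistry alphabet, in fixed order.
DEFAULT_ALPHABET = FunctionalGroupAlphabet(groups=(
    ("phenyl", frozenset("FWY")),
    ("carboxyl", frozenset("DE")),
    ("imidazole", frozenset("H")),
    ("primary_amine", frozenset("K")),
    ("guanidino", frozenset("R")),
    ("thiol", frozenset("C")),
    ("sulfur", frozenset("M")),
    ("amido", frozenset("QN")),
    ("hydroxyl", frozenset("ST")),
    ("non_polar", frozenset("AGILVP")),
))

_GROUP_INDEX: dict[str, int] = {
    aa: k
    for k, (_, group) in enumerate(DEFAULT_ALPHABET.groups)
    for aa in group
}


def _group_indices(sequence: str,
                   alphabet: FunctionalGroupAlphabet) -> np.ndarray:
    if alphabet is DEFAULT_ALPHABET:
        lookup = _GROUP_INDEX
    else:
        lookup = {
            aa: k for k, (_, grp) in enumerate(alphabet.groups) for aa in grp
        }
    try:
        return np.array([lookup[aa] for aa in sequence], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(
            f"residue {exc.args[0]!r} is not a standard amino acid"
        ) from None


def group_aac(record: ProteinRecord,
              alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
              ) -> np.ndarray:
    """Functional-group amino-acid composition: length-10, sums to 1."""
    idx = _group_indices(record.sequence, alphabet)
    counts = np.bincount(idx, minlength=alphabet.size).astype(float)
    return counts / record.length


def group_dpc(record: ProteinRecord,
              alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
              ) -> np.ndarray:
    """Functional-group dipeptide composition: length-100, sums to 1.

    Dipeptides are the L-1 overlapping pairs; the output is row-major over
    (first group, second group) in alphabet order.
    """
    if record.length < 2:
        raise ValueError(
            f"{record.id}: dipeptide composition needs length >= 2"
        )
    idx = _group_indices(record.sequence, alphabet)
    g = alphabet.size
    pair_codes = idx[:-1] * g + idx[1:]
    counts = np.bincount(pair_codes, minlength=g * g).astype(float)
    return counts / (record.length - 1)


def aac_feature_names(
    alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
) -> list[str]:
    return [f"aac_{name}" for name in alphabet.names]


def dpc_feature_names(
    alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
) -> list[str]:
    return [
        f"dpc_{gi}_{gj}"
        for gi in alphabet.names
        for gj in alphabet.names
    ]
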