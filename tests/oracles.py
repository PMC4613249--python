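"""Independent brute-force oracles used to cross-check the descriptors.

These deliberately use naive loops and textbook formulas, sharing no code
with the package implementation.
"""

from __future__ import annotations

import numpy as np

GROUPS = {
    "phenyl": set("FWY"),
    "carboxyl": set("DE"),
    "imidazole": set("H"),
    "primary_amine": set("K"),
    "guanidino": set("R"),
    "thiol": set("C"),
    "sulfur": set("M"),
    "amido": set("QN"),
    "hydroxyl": set("ST"),
    "non_polar": set("AGILVP"),
}
GROUP_ORDER = list(GROUPS)
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


def group_of(residue: str) -> int:
    for k, name in enumerate(GROUP_ORDER):
        if residue in GROUPS[name]:
            return k
    raise ValueError(residue)


def naive_aac(sequence: str) -> np.ndarray:
    out = np.zeros(10)
    for aa in sequence:
        out[group_of(aa)] += 1
    return out / len(sequence)


def naive_dpc(sequence: str) -> np.ndarray:
    out = np.zeros((10, 10))
    for i in range(len(sequence) - 1):
        out[group_of(sequence[i]), group_of(sequence[i + 1])] += 1
    return out.ravel() / (len(sequence) - 1)


def naive_ac(sequence: str, prop_values: dict[str, float],
             lambda_max: int) -> np.ndarray:
    """Double-loop auto-covariance for one property scale."""
    vals = [prop_values[aa] for aa in sequence]
    L = len(vals)
    mean = sum(vals) / L
    out = []
    for lam in range(1, lambda_max + 1):
        total = 0.0
        for i in range(L - lam):
            total += (vals[i] - mean) * (vals[i + lam] - mean)
        out.append(total / (L - lam))
    return np.array(out)


def naive_pssm_group(sequence: str, scores: np.ndarray) -> np.ndarray:
    """Four-loop group-pair PSSM reduction with explicit sigmoid."""
    L = len(sequence)
    out = np.zeros((10, 10))
    for p in range(L):
        gi = group_of(sequence[p])
        for a in range(20):
            gj = group_of(AA_ORDER[a])
            out[gi, gj] += 1.0 / (1.0 + np.exp(-scores[p, a]))
    return out.ravel() / L


def naive_anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    """Textbook one-way ANOVA F for one feature and binary groups."""
    groups = [values[labels == g] for g in sorted(set(labels.tolist()))]
    N = len(values)
    k = len(groups)
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (N - k))
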