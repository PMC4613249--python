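"""Global physicochemical parameters and the auto-covariance (AC) encoder.

Two feature blocks:

* six ProtParam-style global parameters — theoretical isoelectric point,
  counts of negatively (D+E) and positively (R+K) charged residues,
  instability index, aliphatic index and GRAVY;
* 70 auto-covariance features, AC(j, lambda) for seven residue-level
  physicochemical scales and lags lambda = 1..10:

      AC(j, lam) = (1/(L-lam)) * sum_{i=1..L-lam}
                   (P_i^j - mean_j) * (P_{i+lam}^j - mean_j)

  with mean_j the sequence mean of property j.  Each property scale is,
  by default, standardized to zero mean / unit variance over the 20
  residues before encoding, so no scale dominates by units alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .io_formats import AMINO_ACIDS, ProteinRecord

#: Fixed property order of the default table.
PROPERTY_NAMES: tuple[str, ...] = (
    "hydrophobicity",
    "hydrophilicity",
    "net_charge",
    "van_der_waals",
    "free_energy_solution",
    "side_chain_interaction",
    "accessible_surface_area",
)

DEFAULT_LAMBDA_MAX: int = 10

GLOBAL_FEATURE_NAMES: tuple[str, ...] = (
    "phys_pI",
    "phys_n_negative",
    "phys_n_positive",
    "phys_instability_index",
    "phys_aliphatic_index",
    "phys_gravy",
)


@dataclass(frozen=True)
class PropertyTable:
    """Ordered residue-level property scales (each covers all 20 residues)."""

    names: tuple[str, ...]
    values: np.ndarray  # shape (n_properties, 20), columns in AMINO_ACIDS order

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.names), 20):
            raise ValueError(
                f"property table must be {len(self.names)} x 20, "
                f"got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    @classmethod
    def from_csv(cls, path) -> "PropertyTable":
        frame = pd.read_csv(path, comment="#", index_col="residue")
        missing = set(AMINO_ACIDS) - set(frame.index)
        if missing:
            raise ValueError(f"property table missing residues: {missing}")
        frame = frame.loc[list(AMINO_ACIDS)]
        return cls(names=tuple(frame.columns), values=frame.to_numpy().T)

    def standardized(self) -> "PropertyTable":
        """Zero-mean, unit-variance version of each scale over 20 residues."""
        mean = self.values.mean(axis=1, keepdims=True)
        std = self.values.std(axis=1, keepdims=True)
        if np.any(std == 0):
            raise ValueError("cannot standardize a constant property scale")
        return PropertyTable(self.names, (self.values - mean) / std)


def default_property_table() -> PropertyTable:
    """The packaged seven-scale table (see data/physchem_properties.csv)."""
    ref = resources.files("afp_ensemble").joinpath(
        "data/physchem_properties.csv"
    )
    with resources.as_file(ref) as path:
        table = PropertyTable.from_csv(path)
    if table.names != PROPERTY_NAMES:
        raise RuntimeError("packaged property table is out of sync")
    return table


@dataclass(frozen=True)
class GlobalPhyschem:
    """The six ProtParam-style global sequence parameters."""

    pI: float
    n_negative: int
    n_positive: int
    instability_index: float
    aliphatic_index: float
    gravy: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.pI, self.n_negative, self.n_positive,
            self.instability_index, self.aliphatic_index, self.gravy,
        ])


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu),
    with X the mole percent of each residue."""
    length = len(sequence)
    mole_pct = {
        aa: 100.0 * sequence.count(aa) / length for aa in "AVIL"
    }
    return (mole_pct["A"] + 2.9 * mole_pct["V"]
            + 3.9 * (mole_pct["I"] + mole_pct["L"]))


def global_physchem(record: ProteinRecord) -> GlobalPhyschem:
    """Compute the six global parameters for one sequence.

    pI uses the Bjellqvist pKa set via charge-curve bisection; the
    instability index is the dipeptide instability weight sum scaled by
    10/(L-1) (hence needs L >= 2); GRAVY is the mean Kyte-Doolittle
    hydropathy.
    """
    if record.length < 2:
        raise ValueError(
            f"{record.id}: instability index undefined for length < 2"
        )
    analysis = ProteinAnalysis(record.sequence)
    return GlobalPhyschem(
        pI=float(analysis.isoelectric_point()),
        n_negative=record.sequence.count("D") + record.sequence.count("E"),
        n_positive=record.sequence.count("R") + record.sequence.count("K"),
        instability_index=float(analysis.instability_index()),
        aliphatic_index=aliphatic_index(record.sequence),
        gravy=float(analysis.gravy()),
    )


def ac_encode(
    record: ProteinRecord,
    table: PropertyTable | None = None,
    lambda_max: int = DEFAULT_LAMBDA_MAX,
    standardize: bool = True,
) -> np.ndarray:
    """Auto-covariance encoding: length n_properties * lambda_max vector.

    Ordering is property-major, then lag 1..lambda_max.  Requires
    L > lambda_max (guaranteed after dataset filtering, where L >= 50).
    """
    if table is None:
        table = default_property_table()
    if standardize:
        table = table.standardized()
    L = record.length
    if L <= lambda_max:
        raise ValueError(
            f"{record.id}: length {L} too short for lag {lambda_max}"
        )
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    try:
        idx = np.array([aa_index[aa] for aa in record.sequence])
    except KeyError as exc:
        raise ValueError(
            f"{record.id}: nonstandard residue {exc.args[0]!r}"
        ) from None
    # profile[j, i] = property j value of residue at position i
    profile = table.values[:, idx]
    centered = profile - profile.mean(axis=1, keepdims=True)
    out = np.empty(len(table.names) * lambda_max)
    for j in range(len(table.names)):
        for lam in range(1, lambda_max + 1):
            prods = centered[j, :L - lam] * centered[j, lam:]
            out[j * lambda_max + (lam - 1)] = prods.sum() / (L - lam)
    return out


def ac_feature_names(
    table: PropertyTable | None = None,
    lambda_max: int = DEFAULT_LAMBDA_MAX,
) -> list[str]:
    names = table.names if table is not None else PROPERTY_NAMES
    return [
        f"ac_{prop}_{lam}"
        for prop in names
        for lam in range(1, lambda_max + 1)
    ]
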