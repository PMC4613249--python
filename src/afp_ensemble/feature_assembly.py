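"""Assembly of the hybrid feature space.

Concatenates the five descriptor families in fixed block order —
composition (110), global + auto-covariance physicochemistry (76),
disorder (28), functional domain (15), PSSM (100) — into a 329-dimensional
vector per protein, housed in a :class:`FeatureMatrix`.  Families can be
disabled individually; the column count is then the sum of enabled block
widths.  No scaling is applied at assembly time: random forests are
scale-invariant and ANOVA-F ranking is scale-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import (
    descriptors_composition as comp,
    descriptors_disorder as dis,
    descriptors_domain as dom,
    descriptors_physchem as phys,
    descriptors_pssm as pssm_mod,
)
from .io_formats import (
    DisorderProfile,
    DomainAnnotation,
    ProteinRecord,
    PSSMProfile,
)

LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """An n_samples x n_features table with named columns and optional labels.

    ``values`` is float64, row order follows ``protein_ids``, and the
    feature ordering is stable (names unique).  Labels, when present, are
    0/1 with 1 = antifreeze protein.
    """

    protein_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        n, d = self.values.shape
        if len(self.protein_ids) != n:
            raise ValueError("protein_ids length must match row count")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != d:
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length must match row count")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_rows(self, index) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            protein_ids=[self.protein_ids[i] for i in index],
            feature_names=list(self.feature_names),
            values=self.values[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def select_features(self, index) -> "FeatureMatrix":
        index = list(index)
        return FeatureMatrix(
            protein_ids=list(self.protein_ids),
            feature_names=[self.feature_names[i] for i in index],
            values=self.values[:, index],
            labels=self.labels,
        )

    def to_dataframe(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.values,
            index=pd.Index(self.protein_ids, name="protein_id"),
            columns=self.feature_names,
        )
        if self.labels is not None:
            frame[LABEL_COLUMN] = self.labels
        return frame

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        labels = None
        if LABEL_COLUMN in frame.columns:
            labels = frame[LABEL_COLUMN].to_numpy(dtype=int)
            frame = frame.drop(columns=[LABEL_COLUMN])
        return cls(
            protein_ids=[str(i) for i in frame.index],
            feature_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            labels=labels,
        )


@dataclass(frozen=True)
class AssemblyConfig:
    """Which descriptor families to compute and their parameters."""

    composition: bool = True
    physchem: bool = True
    disorder: bool = True
    domain: bool = True
    pssm: bool = True
    lambda_max: int = phys.DEFAULT_LAMBDA_MAX
    standardize_properties: bool = True
    disorder_threshold: float = dis.DEFAULT_THRESHOLD
    alphabet: comp.FunctionalGroupAlphabet = comp.DEFAULT_ALPHABET
    panel: dom.DomainPanel = dom.DEFAULT_PANEL
    property_table: phys.PropertyTable | None = None

    def disable(self, *families: str) -> "AssemblyConfig":
        return replace(self, **{fam: False for fam in families})


def feature_names(config: AssemblyConfig | None = None) -> list[str]:
    """The full column-name list implied by a config, in block order."""
    config = config or AssemblyConfig()
    names: list[str] = []
    if config.composition:
        names += comp.aac_feature_names(config.alphabet)
        names += comp.dpc_feature_names(config.alphabet)
    if config.physchem:
        names += list(phys.GLOBAL_FEATURE_NAMES)
        names += phys.ac_feature_names(
            config.property_table, config.lambda_max
        )
    if config.disorder:
        names += list(dis.DISORDER_FEATURE_NAMES)
    if config.domain:
        names += dom.domain_feature_names(config.panel)
    if config.pssm:
        names += pssm_mod.pssm_feature_names(config.alphabet)
    return names


def assemble(
    records: Sequence[ProteinRecord],
    pssms: Mapping[str, PSSMProfile] | None = None,
    disorder_profiles: Mapping[str, DisorderProfile] | None = None,
    domain_annotations: Mapping[str, DomainAnnotation] | None = None,
    config: AssemblyConfig | None = None,
) -> FeatureMatrix:
    """Build the hybrid feature matrix for a dataset.

    Every enabled family must have its annotation for every record (a
    missing domain annotation counts as an empty set, matching InterPro
    scans that return no hits); missing PSSM or disorder data raises with
    the offending protein ids — never silent imputation.
    """
    config = config or AssemblyConfig()
    if config.pssm:
        missing = [r.id for r in records
                   if pssms is None or r.id not in pssms]
        if missing:
            raise ValueError(f"missing PSSM profiles for: {missing[:10]}")
    if config.disorder:
        missing = [r.id for r in records
                   if disorder_profiles is None
                   or r.id not in disorder_profiles]
        if missing:
            raise ValueError(
                f"missing disorder profiles for: {missing[:10]}"
            )

    prop_table = config.property_table
    if config.physchem and prop_table is None:
        prop_table = phys.default_property_table()

    rows: list[np.ndarray] = []
    for rec in records:
        blocks: list[np.ndarray] = []
        if config.composition:
            blocks.append(comp.group_aac(rec, config.alphabet))
            blocks.append(comp.group_dpc(rec, config.alphabet))
        if config.physchem:
            blocks.append(phys.global_physchem(rec).as_array())
            blocks.append(phys.ac_encode(
                rec, prop_table, config.lambda_max,
                config.standardize_properties,
            ))
        if config.disorder:
            blocks.append(dis.disorder_features(
                rec, disorder_profiles[rec.id], config.disorder_threshold
            ))
        if config.domain:
            ann = None
            if domain_annotations is not None:
                ann = domain_annotations.get(rec.id)
            blocks.append(dom.domain_features(ann, config.panel))
        if config.pssm:
            blocks.append(pssm_mod.pssm_group_features(
                rec, pssms[rec.id], config.alphabet
            ))
        rows.append(np.concatenate(blocks))

    labels = None
    if records and all(r.label is not None for r in records):
        labels = np.array([r.label for r in records])
    names = feature_names(config)
    values = (np.vstack(rows) if rows
              else np.empty((0, len(names))))
    return FeatureMatrix(
        protein_ids=[r.id for r in records],
        feature_names=names,
        values=values,
        labels=labels,
    )
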