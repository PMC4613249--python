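"""Binary functional-domain indicator features.

A fixed panel of InterPro entries — by default the 15 entries observed in
at least 10 antifreeze proteins of the original training data — is turned
into a 0/1 presence vector per protein.  ``derive_panel`` rebuilds such a
panel from annotated, labeled data for retraining on new datasets.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import DomainAnnotation


@dataclass(frozen=True)
class DomainPanel:
    """An ordered list of InterPro entry ids used as indicator features."""

    entries: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("panel entries must be unique")

    @property
    def size(self) -> int:
        return len(self.entries)


#: The default 15-entry AFP panel, in rank order.
DEFAULT_PANEL = DomainPanel(entries=(
    "IPR001304", "IPR016186", "IPR016187", "IPR018378", "IPR013032",
    "IPR000742", "IPR000436", "IPR000538", "IPR007110", "IPR013783",
    "IPR000152", "IPR001881", "IPR003599", "IPR018097", "IPR013106",
))


def domain_features(
    annotation: DomainAnnotation | None,
    panel: DomainPanel = DEFAULT_PANEL,
) -> np.ndarray:
    """Binary presence vector over the panel (missing annotation = empty)."""
    entries = annotation.entries if annotation is not None else frozenset()
    return np.array(
        [1.0 if e in entries else 0.0 for e in panel.entries]
    )


def derive_panel(
    annotations: Sequence[DomainAnnotation],
    labels: Sequence[int],
    min_count: int = 10,
) -> DomainPanel:
    """Build a panel of entries present in >= min_count positive proteins.

    Entries are ordered by descending positive count, ties broken by
    lexicographic id.  An empty result warns and returns an empty panel.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if len(annotations) != len(labels):
        raise ValueError("annotations and labels must align")
    counts: Counter[str] = Counter()
    for ann, label in zip(annotations, labels):
        if label == 1:
            counts.update(ann.entries)
    qualifying = [(e, c) for e, c in counts.items() if c >= min_count]
    if not qualifying:
        warnings.warn(
            f"no InterPro entry reaches min_count={min_count} positives; "
            "panel is empty",
            stacklevel=2,
        )
        return DomainPanel(entries=())
    qualifying.sort(key=lambda item: (-item[1], item[0]))
    return DomainPanel(entries=tuple(e for e, _ in qualifying))


def domain_feature_names(panel: DomainPanel = DEFAULT_PANEL) -> list[str]:
    return [f"dom_{entry}" for entry in panel.entries]
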