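"""Synthetic labeled datasets emulating the AFP prediction inputs.

Real AFP benchmarks require a curated sequence collection plus PSI-BLAST
PSSMs, disorder-predictor scores and InterPro annotations.  This module
generates all four input kinds with a controllable class signal so the
full pipeline — and the imbalance / ensemble / dataset-size experiments —
runs with no external data.

Class signal is injected at the functional-group level: positive
sequences shift residue probability mass toward the hydroxyl, amido and
non-polar groups (ice-binding surfaces are enriched in such residues),
so the reduced-alphabet composition features are the natural detectors
and descriptor bugs surface as lost balanced accuracy.  ``signal = 0``
makes the class distributions identical; ``signal = 1`` draws positives
fully from the shifted profile.  Every generator is a pure function of
its parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ensemble as ens, evaluation as ev
from .descriptors_composition import DEFAULT_ALPHABET, FunctionalGroupAlphabet
from .descriptors_domain import DEFAULT_PANEL, DomainPanel
from .feature_assembly import AssemblyConfig, FeatureMatrix, assemble
from .io_formats import (
    DisorderProfile,
    DomainAnnotation,
    ProteinRecord,
    PSSMProfile,
)

#: Baseline functional-group frequencies: proportional to group sizes, so
#: the residue-level distribution is uniform over the 20 amino acids.
_BASE_GROUP_PROBS = np.array([3, 2, 1, 1, 1, 1, 1, 2, 2, 6]) / 20.0

#: Fully shifted positive-class profile: mass moved toward hydroxyl,
#: amido and non-polar groups (indices 8, 7, 9).
_SHIFTED_GROUP_PROBS = np.array(
    [0.075, 0.05, 0.025, 0.025, 0.025, 0.025, 0.025, 0.15, 0.20, 0.40]
)


def _class_profiles(signal: float) -> tuple[np.ndarray, np.ndarray]:
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must lie in [0, 1]")
    positive = (1.0 - signal) * _BASE_GROUP_PROBS + signal * _SHIFTED_GROUP_PROBS
    return positive, _BASE_GROUP_PROBS.copy()


def generate_sequences(
    n_pos: int,
    n_neg: int,
    length_range: tuple[int, int] = (50, 300),
    signal: float = 0.4,
    seed: int = 0,
    alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
) -> list[ProteinRecord]:
    """Labeled random sequences with class-specific group frequencies.

    Lengths are uniform over ``length_range`` (inclusive); residues are
    drawn per position by first picking a functional group from the
    class profile, then a member residue uniformly.  All output passes
    dataset filtering (standard alphabet, length >= 50 by default).
    """
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid length range {length_range}")
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sample counts must be non-negative")
    pos_profile, neg_profile = _class_profiles(signal)
    group_members = [sorted(grp) for _, grp in alphabet.groups]
    rng = np.random.default_rng(seed)
    records: list[ProteinRecord] = []
    for label, count, profile in (
        (1, n_pos, pos_profile),
        (0, n_neg, neg_profile),
    ):
        prefix = "afp" if label == 1 else "neg"
        for i in range(count):
            length = int(rng.integers(lo, hi + 1))
            groups = rng.choice(len(group_members), size=length, p=profile)
            seq = "".join(
                group_members[g][rng.integers(len(group_members[g]))]
                for g in groups
            )
            records.append(ProteinRecord(f"{prefix}{i + 1:04d}", seq, label))
    return records


def generate_pssm(
    record: ProteinRecord,
    class_signal: float = 0.5,
    seed: int = 0,
    alphabet: FunctionalGroupAlphabet = DEFAULT_ALPHABET,
) -> PSSMProfile:
    """Synthetic integer PSSM: uniform noise in [-5, 5] plus a conservation
    bias on the columns of each residue's own functional group; positives
    get an extra class-dependent bias of round(3 * class_signal)."""
    rng = np.random.default_rng(seed)
    lookup = {
        aa: k for k, (_, grp) in enumerate(alphabet.groups) for aa in grp
    }
    scores = rng.integers(-5, 6, size=(record.length, 20)).astype(float)
    col_groups = np.array([lookup[aa] for aa in "ARNDCQEGHILKMFPSTWYV"])
    bias = 2 + (round(3 * class_signal) if record.label == 1 else 0)
    for i, aa in enumerate(record.sequence):
        scores[i, col_groups == lookup[aa]] += bias
    return PSSMProfile(protein_id=record.id, scores=scores)


def generate_disorder(
    record: ProteinRecord, seed: int = 0, window: int = 5
) -> DisorderProfile:
    """Smoothed-noise disorder scores: moving average (window 5) of
    uniform(0, 1) draws, hence in [0, 1] with realistic run structure."""
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.0, 1.0, size=record.length)
    kernel = np.ones(window) / window
    smooth = np.convolve(raw, kernel, mode="same")
    return DisorderProfile(protein_id=record.id, scores=np.clip(smooth, 0, 1))


def generate_domains(
    records: list[ProteinRecord],
    panel: DomainPanel = DEFAULT_PANEL,
    enrichment: float = 0.4,
    negative_rate: float = 0.05,
    seed: int = 0,
) -> list[DomainAnnotation]:
    """Panel entries assigned to positives with probability ``enrichment``
    and to negatives with the lower ``negative_rate``."""
    if not 0.0 <= negative_rate <= enrichment <= 1.0:
        raise ValueError("need 0 <= negative_rate <= enrichment <= 1")
    rng = np.random.default_rng(seed)
    annotations = []
    for rec in records:
        p = enrichment if rec.label == 1 else negative_rate
        hits = frozenset(
            entry for entry in panel.entries if rng.random() < p
        )
        annotations.append(DomainAnnotation(rec.id, hits))
    return annotations


def generate_bundle(
    n_pos: int,
    n_neg: int,
    length_range: tuple[int, int] = (50, 300),
    signal: float = 0.4,
    seed: int = 0,
):
    """Sequences plus all three annotation kinds, keyed by protein id.

    Returns ``(records, pssms, disorder_profiles, domain_annotations)``,
    ready for :func:`afp_ensemble.feature_assembly.assemble`.
    """
    ss = np.random.SeedSequence(seed)
    seq_seed, pssm_seed, dis_seed, dom_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)
    )
    records = generate_sequences(
        n_pos, n_neg, length_range, signal, seq_seed
    )
    pssms = {
        rec.id: generate_pssm(rec, class_signal=signal,
                              seed=(pssm_seed + i) % (2**31 - 1))
        for i, rec in enumerate(records)
    }
    disorder = {
        rec.id: generate_disorder(rec, seed=(dis_seed + i) % (2**31 - 1))
        for i, rec in enumerate(records)
    }
    domains = {
        ann.protein_id: ann
        for ann in generate_domains(records, seed=dom_seed)
    }
    return records, pssms, disorder, domains


def generate_feature_dataset(
    n_pos: int,
    n_neg: int,
    n_informative: int = 5,
    n_noise: int = 45,
    shift: float = 2.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Gaussian tabular dataset: ``n_informative`` features carry a
    ``shift``-SD positive-class mean shift, the rest are pure N(0, 1)
    noise.  Used for feature-selection recovery studies."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    d = n_informative + n_noise
    values = rng.normal(size=(n, d))
    labels = np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)])
    values[labels == 1, :n_informative] += shift
    # Shuffle rows so class blocks are not contiguous.
    order = rng.permutation(n)
    return FeatureMatrix(
        protein_ids=[f"s{i + 1:04d}" for i in range(n)],
        feature_names=(
            [f"informative_{j + 1}" for j in range(n_informative)]
            + [f"noise_{j + 1}" for j in range(n_noise)]
        ),
        values=values[order],
        labels=labels[order],
    )


# ---------------------------------------------------------------------------
# Simulation experiments
# ---------------------------------------------------------------------------

EXPERIMENTS = ("g_sweep", "imbalance_sweep", "ensemble_vs_none", "size_sweep")

#: Study conditions for the synthetic experiments (chosen once; see the
#: methods note).  Composition-only features keep each replicate cheap.
_DEFAULTS = dict(
    n_pos=40,
    n_test=150,  # per class
    signal=0.4,
    length_range=(50, 150),
    replicates=10,
    n_trees=100,
)

_COMPOSITION_ONLY = AssemblyConfig(
    physchem=False, disorder=False, domain=False, pssm=False
)


def _extract(records: list[ProteinRecord]) -> FeatureMatrix:
    return assemble(records, config=_COMPOSITION_ONLY)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _make_train_test(
    n_pos: int, n_neg: int, n_test: int, signal: float,
    length_range: tuple[int, int], seed: int,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    s_train, s_test = _spawn_seeds(seed, 2)
    train = _extract(generate_sequences(
        n_pos, n_neg, length_range, signal, s_train
    ))
    test = _extract(generate_sequences(
        n_test, n_test, length_range, signal, s_test
    ))
    return train, test


def _single_forest_metrics(
    train: FeatureMatrix, test: FeatureMatrix, n_trees: int, seed: int
) -> ev.MetricsReport:
    """One random forest on the (possibly imbalanced) data, no sampling."""
    config = ens.EnsembleConfig(
        G=1, n_trees=n_trees, seed=seed, allow_any_G=True
    )
    est = config.make_member(0)
    est.fit(train.values, train.labels)
    return ev.compute_metrics(test.labels, est.predict(test.values))


def _ensemble_metrics(
    train: FeatureMatrix, test: FeatureMatrix, G: int, n_trees: int,
    seed: int,
) -> ev.MetricsReport:
    config = ens.EnsembleConfig(
        G=G, n_trees=n_trees, seed=seed, allow_any_G=True
    )
    model = ens.train(train, config)
    y_pred, _ = ens.predict(model, test)
    return ev.compute_metrics(test.labels, y_pred)


def run_experiment(
    name: str, params: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Run a named simulation; one row per (condition, replicate).

    Experiments (each replicate generates fresh training data and an
    independent balanced test set of ``n_test`` per class):

    * ``g_sweep`` — ensemble 10-fold-CV stand-in over G in
      {3, 5, 7, 9, 11, 13, 15}.
    * ``imbalance_sweep`` — a single forest trained on positive:negative
      ratios 1:1 .. 1:8 with no sampling or ensemble.
    * ``ensemble_vs_none`` — single forest on the full 1:9 data vs the
      G = 9 undersampling ensemble, paired per replicate.
    * ``size_sweep`` — G = 9 ensemble trained on 10% .. 80% of a fixed-
      size 1:9 pool.
    """
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; valid names: {EXPERIMENTS}"
        )
    p = dict(_DEFAULTS)
    p.update(params or {})
    replicates = int(p["replicates"])
    rows: list[dict] = []

    if name == "g_sweep":
        g_values = tuple(p.get("g_values", (3, 5, 7, 9, 11, 13, 15)))
        max_g = max(g_values)
        for rep, rep_seed in enumerate(_spawn_seeds(seed, replicates)):
            train, test = _make_train_test(
                p["n_pos"], max_g * p["n_pos"], p["n_test"],
                p["signal"], p["length_range"], rep_seed,
            )
            for G in g_values:
                report = _ensemble_metrics(
                    train, test, G, p["n_trees"], rep_seed
                )
                rows.append(_row(f"G={G}", rep, report, G=G))

    elif name == "imbalance_sweep":
        ratios = tuple(p.get("ratios", range(1, 9)))
        for rep, rep_seed in enumerate(_spawn_seeds(seed, replicates)):
            train_full, test = _make_train_test(
                p["n_pos"], max(ratios) * p["n_pos"], p["n_test"],
                p["signal"], p["length_range"], rep_seed,
            )
            neg_idx = np.flatnonzero(train_full.labels == 0)
            pos_idx = np.flatnonzero(train_full.labels == 1)
            for ratio in ratios:
                subset = train_full.select_rows(
                    np.concatenate([pos_idx,
                                    neg_idx[: ratio * p["n_pos"]]])
                )
                report = _single_forest_metrics(
                    subset, test, p["n_trees"], rep_seed
                )
                rows.append(_row(f"1:{ratio}", rep, report, ratio=ratio))

    elif name == "ensemble_vs_none":
        G = int(p.get("G", 9))
        for rep, rep_seed in enumerate(_spawn_seeds(seed, replicates)):
            train, test = _make_train_test(
                p["n_pos"], G * p["n_pos"], p["n_test"],
                p["signal"], p["length_range"], rep_seed,
            )
            without = _single_forest_metrics(
                train, test, p["n_trees"], rep_seed
            )
            with_ens = _ensemble_metrics(
                train, test, G, p["n_trees"], rep_seed
            )
            rows.append(_row("without_ensemble", rep, without))
            rows.append(_row("with_ensemble", rep, with_ens))

    elif name == "size_sweep":
        pool_pos = int(p.get("pool_pos", 80))
        G = int(p.get("G", 9))
        fractions = tuple(p.get("fractions",
                                (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)))
        for rep, rep_seed in enumerate(_spawn_seeds(seed, replicates)):
            train_full, test = _make_train_test(
                pool_pos, G * pool_pos, p["n_test"],
                p["signal"], p["length_range"], rep_seed,
            )
            pos_idx = np.flatnonzero(train_full.labels == 1)
            neg_idx = np.flatnonzero(train_full.labels == 0)
            for frac in fractions:
                n_pos_f = max(int(round(frac * pool_pos)), 2)
                n_neg_f = G * n_pos_f
                subset = train_full.select_rows(
                    np.concatenate([pos_idx[:n_pos_f], neg_idx[:n_neg_f]])
                )
                report = _ensemble_metrics(
                    subset, test, G, p["n_trees"], rep_seed
                )
                rows.append(_row(f"{int(frac * 100)}%", rep, report,
                                 fraction=frac))

    return pd.DataFrame(rows)


def _row(condition: str, replicate: int, report: ev.MetricsReport,
         **extra) -> dict:
    return {
        "condition": condition,
        "replicate": replicate,
        "Sn": report.Sn,
        "Sp": report.Sp,
        "Acc": report.Acc,
        "BAcc": report.BAcc,
        **extra,
    }


def summarize_experiment(results: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SD of each metric, preserving condition
    order of first appearance."""
    order = results["condition"].drop_duplicates().tolist()
    summary = (
        results.groupby("condition", sort=False)[["Sn", "Sp", "Acc", "BAcc"]]
        .agg(["mean", "std"])
    )
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return summary.loc[order].reset_index()
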