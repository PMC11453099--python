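"""End-to-end benchmarks on the synthetic corpus.

Two study designs:

* :func:`integration_benchmark` asks whether integrating the three classifier
  tracks through the boosted-tree meta-model beats (i) each single track and
  (ii) every two-track ablation, on pooled held-out test-fold residues --
  the qualitative claim behind a meta-classifier.  It uses the "realistic"
  track regime (single-track ROC-AUC ~0.6-0.75) with a quarter of antigens
  carrying a third, middle patch that only the weak global track sees.

* :func:`recovery_benchmark` runs the full calling pipeline (dynamic
  threshold -> top-N -> Ward clustering -> gap rule) on two-patch antigens
  with out-of-fold consensus scores and measures how often the planted
  epitope pair is recovered as k=2 and how well each cluster matches its
  best patch.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .calling import call_epitopes, cluster_residues
from .evaluation import cluster_level_f1, confusion, f1, pr_auc, roc_auc
from .fixtures import FixtureCase, FixtureSpec, make_benchmark_set
from .meta import (
    MetaModelConfig,
    ScoreTable,
    make_folds,
    normalize_scores,
    predict_meta,
    train_meta,
)
from .structure import SurfaceProfile


def _drop_track(table: ScoreTable, name: str) -> ScoreTable:
    return replace(table, scores=table.scores.drop(columns=[name]))


def _pooled(tables: list[ScoreTable], model) -> tuple[np.ndarray, np.ndarray]:
    scores = np.concatenate([predict_meta(model, t) for t in tables])
    labels = np.concatenate([t.labels for t in tables])
    return scores, labels


def integration_benchmark(
    seed: int = 0,
    n_antigens: int = 12,
    three_patch_fraction: float = 0.25,
    config: MetaModelConfig | None = None,
) -> dict:
    """Test-fold ROC/PR-AUC of the meta-model vs single tracks and ablations."""
    base = FixtureSpec(regime="realistic", noise_sd=0.15)
    cases = make_benchmark_set(n_antigens, seed=seed, base_spec=base,
                               three_patch_fraction=three_patch_fraction)
    tables = {c.antigen_id: normalize_scores(c.table) for c in cases}
    sizes = {c.antigen_id: len(c.structure) for c in cases}
    split = make_folds(sizes, n_folds=3, seed=seed)
    config = config or MetaModelConfig(seed=seed % 2**31)

    train_tables = [tables[a] for a in split.all_train]
    test_tables = [tables[a] for a in split.test]
    model = train_meta(train_tables, config)
    scores, labels = _pooled(test_tables, model)
    tracks = tables[split.test[0]].classifiers

    track_auc = {}
    track_pr = {}
    for name in tracks:
        ts = np.concatenate([t.scores[name].to_numpy() for t in test_tables])
        track_auc[name] = roc_auc(ts, labels)
        track_pr[name] = pr_auc(ts, labels)

    drop_one_auc = {}
    for name in tracks:
        sub_model = train_meta([_drop_track(t, name) for t in train_tables], config)
        sub_scores, _ = _pooled([_drop_track(t, name) for t in test_tables], sub_model)
        drop_one_auc[name] = roc_auc(sub_scores, labels)

    return {
        "meta_roc_auc": roc_auc(scores, labels),
        "meta_pr_auc": pr_auc(scores, labels),
        "track_roc_auc": track_auc,
        "track_pr_auc": track_pr,
        "drop_one_roc_auc": drop_one_auc,
        "n_test_residues": int(labels.size),
        "test_antigens": list(split.test),
    }


def _out_of_fold_scores(cases: list[FixtureCase], seed: int,
                        config: MetaModelConfig) -> dict[str, np.ndarray]:
    """Consensus scores for every antigen from a model that never saw it."""
    tables = {c.antigen_id: normalize_scores(c.table) for c in cases}
    sizes = {c.antigen_id: len(c.structure) for c in cases}
    split = make_folds(sizes, n_folds=3, seed=seed)
    groups = [split.test] + split.train_folds
    out: dict[str, np.ndarray] = {}
    for i, group in enumerate(groups):
        train_ids = [a for j, g in enumerate(groups) if j != i for a in g]
        model = train_meta([tables[a] for a in train_ids], config)
        for aid in group:
            out[aid] = predict_meta(model, tables[aid])
    return out


def recovery_benchmark(
    seed: int = 0,
    n_antigens: int = 10,
    k_max: int = 8,
) -> dict:
    """Run the calling pipeline end-to-end on two-patch antigens.

    Fixture residues are single pseudo-atoms on an open walk, so every
    residue is treated as surface-exposed (R = n) when setting the dynamic
    threshold.  Reports the fraction of antigens clustered into exactly two
    putative epitopes, per-cluster best-patch F1, and cluster sizes.
    """
    base = FixtureSpec(regime="strong", noise_sd=0.12)
    cases = make_benchmark_set(n_antigens, seed=seed, base_spec=base,
                               three_patch_fraction=0.0)
    config = MetaModelConfig(seed=seed % 2**31)
    consensus = _out_of_fold_scores(cases, seed, config)

    ks = []
    best_f1s = []
    cluster_sizes = []
    thresholds = []
    for case in cases:
        n = len(case.structure)
        profile = SurfaceProfile(rsa=np.ones(n), is_surface=np.ones(n, bool),
                                 rsa_threshold=0.05)
        pred, clusters, _ = call_epitopes(case.structure, profile,
                                          consensus[case.antigen_id], k_max=k_max)
        ks.append(clusters.k)
        thresholds.append(pred.N)
        cluster_sizes.extend(len(m) for m in clusters.members)
        universe = [r.key for r in case.structure.residues]
        for members in cluster_residues(case.structure, pred, clusters):
            cluster_keys = {r.key for r in members}
            best = max(
                f1(confusion(cluster_keys, {r.key for r in ann.residues}, universe))
                for ann in case.annotations
            )
            best_f1s.append(best)
    return {
        "k_values": ks,
        "fraction_k2": float(np.mean([k == 2 for k in ks])),
        "mean_best_cluster_f1": float(np.mean(best_f1s)),
        "cluster_sizes": cluster_sizes,
        "dynamic_thresholds": thresholds,
    }
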