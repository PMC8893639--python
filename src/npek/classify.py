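"""Per-cluster epitope classifiers and their cross-validated benchmarks.

Classifier kinds:

* ``rf`` — 100-tree random forest; the positive-class probability is the
  fraction of trees voting positive.
* ``knn`` — k-nearest neighbours, k = 5.
* ``nn`` — a single-hidden-layer (100 units) multilayer perceptron with
  adam-style defaults, up to 200 epochs.
* ``dummy_rf`` — the shuffled-label null: labels are reassigned by a uniform
  random permutation (preserving the positive fraction) once per CV repeat;
  a sound setup scores chance-level ROC-AUC (~0.5).
* ``similarity`` — the count-Tanimoto baseline: a molecule's score is its
  maximum similarity to the known epitopes of its cluster; under CV the
  references are the positives of the training folds only.

All benchmarks use repeated (3x) 5-fold stratified cross-validation and are
compared with ROC-AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .chem_io import Molecule, MoleculeSet
from .errors import (
    EmptySetError,
    InfeasibleCVError,
    ParameterError,
    UndefinedMetricError,
)
from .feature_stats import chi2_scores
from .fingerprints import (
    CLASSIFIER_PARAMS,
    FeatureMatrix,
    FingerprintParams,
    SparseCountFingerprint,
    build_feature_matrix,
    encode_count,
    encode_folded_bits,
    prune_correlated,
    remove_identical_fingerprints,
)

ML_KINDS = ("rf", "knn", "nn")


@dataclass(frozen=True)
class ModelSpec:
    """Classifier kind plus its (explicit) default hyperparameters."""

    kind: str  # rf | knn | nn | dummy_rf | similarity
    hyperparams: tuple = ()  # sorted (key, value) pairs; see defaults below
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ML_KINDS + ("dummy_rf", "similarity"):
            raise ParameterError(f"unknown model kind {self.kind!r}")

    @property
    def params(self) -> dict:
        return dict(self.hyperparams)

    @staticmethod
    def rf(n_trees: int = 100, seed: int = 0) -> "ModelSpec":
        return ModelSpec("rf", (("n_trees", n_trees),), seed)

    @staticmethod
    def knn(k: int = 5, seed: int = 0) -> "ModelSpec":
        return ModelSpec("knn", (("k", k),), seed)

    @staticmethod
    def nn(hidden: int = 100, max_epochs: int = 200, seed: int = 0) -> "ModelSpec":
        return ModelSpec("nn", (("hidden", hidden), ("max_epochs", max_epochs)), seed)

    @staticmethod
    def dummy_rf(n_trees: int = 100, seed: int = 0) -> "ModelSpec":
        return ModelSpec("dummy_rf", (("n_trees", n_trees),), seed)

    @staticmethod
    def similarity(seed: int = 0) -> "ModelSpec":
        return ModelSpec("similarity", (), seed)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified cross-validation settings (3 repeats of 5 folds)."""

    n_repeats: int = 3
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.stratified:
            raise ParameterError("only stratified CV is supported")
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ParameterError("need n_repeats >= 1 and n_folds >= 2")


@dataclass
class CVResult:
    per_fold_auc: list[float]  # n_repeats * n_folds values
    spec: ModelSpec
    cv: CVConfig
    n_features_used: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.per_fold_auc, ddof=1)) if len(self.per_fold_auc) > 1 else 0.0


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """ROC-AUC in the Mann-Whitney formulation (ties count one half).

    Raises UndefinedMetricError when only one class is present.
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise UndefinedMetricError("ROC-AUC undefined: labels contain a single class")
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def make_dummy_labels(labels: Sequence[bool], seed: int) -> np.ndarray:
    """Uniform random permutation of the label vector (positive count preserved)."""
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    return y[rng.permutation(len(y))]


def count_tanimoto(a: SparseCountFingerprint, b: SparseCountFingerprint) -> float:
    """Count Tanimoto similarity: sum_i min(a_i, b_i) / sum_i max(a_i, b_i).

    Two empty fingerprints have similarity 0 by convention.
    """
    if a.params != b.params:
        raise ParameterError("cannot compare fingerprints with different parameters")
    keys = a.counts.keys() | b.counts.keys()
    num = sum(min(a[k], b[k]) for k in keys)
    den = sum(max(a[k], b[k]) for k in keys)
    return num / den if den else 0.0


def similarity_scores(
    queries: Sequence[SparseCountFingerprint],
    reference_positives: Sequence[SparseCountFingerprint],
    exclude_self: bool = False,
) -> list[float]:
    """Per query: the maximum count-Tanimoto over the reference epitopes.

    With ``exclude_self`` (CV mode), a reference that is the query object
    itself is skipped, so a molecule never scores against itself.
    """
    if len(reference_positives) == 0:
        raise EmptySetError("similarity scoring requires a non-empty reference set")
    out = []
    for q in queries:
        refs = [r for r in reference_positives if not (exclude_self and r is q)]
        if not refs:
            raise EmptySetError("no reference left for a query after self-exclusion")
        out.append(max(count_tanimoto(q, r) for r in refs))
    return out


def _build_estimator(spec: ModelSpec, seed: int):
    p = spec.params
    if spec.kind in ("rf", "dummy_rf"):
        return RandomForestClassifier(n_estimators=p.get("n_trees", 100), random_state=seed)
    if spec.kind == "knn":
        return KNeighborsClassifier(n_neighbors=p.get("k", 5))
    if spec.kind == "nn":
        return MLPClassifier(
            hidden_layer_sizes=(p.get("hidden", 100),),
            max_iter=p.get("max_epochs", 200),
            random_state=seed,
        )
    raise ParameterError(f"no estimator for kind {spec.kind!r}")


def _derive_seeds(seed: int, n: int) -> list[int]:
    # per-component seeds kept below 2**31 so full runs replay identically
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def _chi2_top_k(counts: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Column indices of the k largest chi-squared statistics (ties: first column)."""
    stat, _ = chi2_scores(counts, labels)
    order = np.argsort(-stat, kind="stable")
    return np.sort(order[:k])


def select_top_features(fm: FeatureMatrix, labels: Sequence[bool], k: int) -> FeatureMatrix:
    """Restrict the matrix to the k features with largest chi-squared statistic.

    Ties are broken toward the lower feature id (columns are in ascending
    feature-id order, and the stable ranking keeps the earlier column).
    """
    if not 1 <= k <= fm.n_features:
        raise ParameterError(f"k={k} out of range [1, {fm.n_features}]")
    cols = _chi2_top_k(fm.counts, np.asarray(labels, dtype=bool), k)
    return fm.subset_features(fm.feature_ids[cols], {"select_top_k": k})


def _check_cv_feasible(y: np.ndarray, cv: CVConfig, context: str = "") -> None:
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos < cv.n_folds or n_neg < cv.n_folds:
        raise InfeasibleCVError(
            f"stratified {cv.n_folds}-fold CV infeasible{' for ' + context if context else ''}: "
            f"{n_pos} positives / {n_neg} negatives"
        )


def cross_validate(
    spec: ModelSpec,
    fm: FeatureMatrix,
    labels: Sequence[bool],
    cv: CVConfig = CVConfig(),
    fingerprints: Sequence[SparseCountFingerprint] | None = None,
    select_k: int | None = None,
    selection_per_fold: bool = True,
    context: str = "",
) -> CVResult:
    """Repeated stratified cross-validation of one model on one cluster x assay.

    ML kinds fit on the training folds and score the held-out fold by
    positive-class probability.  The similarity kind scores held-out molecules
    against the training-fold positives only (``fingerprints``, aligned with
    the matrix rows, default to the retained-feature count vectors).  The
    dummy kind shuffles the labels once per repeat before splitting.

    With ``select_k``, chi-squared feature selection is re-fit inside each
    training fold (leakage-safe); ``selection_per_fold=False`` instead ranks
    once on the whole data before splitting.
    """
    y = np.asarray(labels, dtype=bool)
    if len(y) != fm.n_molecules:
        raise ParameterError("labels length does not match the feature matrix")
    _check_cv_feasible(y, cv, context)
    if spec.kind == "similarity" and fingerprints is None:
        fingerprints = [
            SparseCountFingerprint(
                {int(f): int(c) for f, c in zip(fm.feature_ids, row) if c > 0}, fm.params
            )
            for row in fm.counts
        ]

    X = fm.counts.astype(np.float64)
    if select_k is not None and not selection_per_fold:
        cols = _chi2_top_k(fm.counts, y, select_k)
        X = X[:, cols]

    seeds = _derive_seeds(cv.seed, 2 * cv.n_repeats)
    aucs: list[float] = []
    n_features_used = X.shape[1] if select_k is None else min(select_k, fm.n_features)
    for rep in range(cv.n_repeats):
        split_seed, fit_seed = seeds[2 * rep], seeds[2 * rep + 1]
        y_rep = make_dummy_labels(y, fit_seed) if spec.kind == "dummy_rf" else y
        skf = StratifiedKFold(n_splits=cv.n_folds, shuffle=True, random_state=split_seed)
        for train_idx, test_idx in skf.split(X, y_rep):
            if spec.kind == "similarity":
                refs = [fingerprints[i] for i in train_idx if y_rep[i]]
                scores = similarity_scores([fingerprints[i] for i in test_idx], refs)
            else:
                X_tr, X_te = X[train_idx], X[test_idx]
                if select_k is not None and selection_per_fold:
                    cols = _chi2_top_k(
                        fm.counts[train_idx], y_rep[train_idx], min(select_k, fm.n_features)
                    )
                    X_tr, X_te = X_tr[:, cols], X_te[:, cols]
                est = _build_estimator(spec, fit_seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # MLP convergence at max_epochs
                    est.fit(X_tr, y_rep[train_idx])
                scores = est.predict_proba(X_te)[:, list(est.classes_).index(True)]
            aucs.append(roc_auc(scores, y_rep[test_idx]))
    return CVResult(aucs, spec, cv, n_features_used)


def feature_set_sweep(
    fm: FeatureMatrix,
    labels: Sequence[bool],
    cv: CVConfig,
    specs: Sequence[ModelSpec],
    k_grid: Sequence[int] | None = None,
    fingerprints: Sequence[SparseCountFingerprint] | None = None,
) -> pd.DataFrame:
    """Benchmark table over model kinds and feature-set sizes.

    ``k_grid`` defaults to powers of two capped at the feature count, plus the
    full feature count.  The similarity baseline always uses full fingerprints
    (k-independent; repeated per k for plotting parity).
    """
    if k_grid is None:
        k_grid = default_k_grid(fm.n_features)
    if list(k_grid) != sorted(k_grid):
        raise ParameterError("k_grid must be ascending")
    rows = []
    for spec in specs:
        for k in k_grid:
            if spec.kind == "similarity":
                res = cross_validate(spec, fm, labels, cv, fingerprints=fingerprints)
            else:
                res = cross_validate(spec, fm, labels, cv, select_k=min(k, fm.n_features))
            rows.append(
                {
                    "model": spec.kind,
                    "n_features": k,
                    "mean_auc": res.mean_auc,
                    "sd_auc": res.sd_auc,
                }
            )
    return pd.DataFrame(rows)


def default_k_grid(n_features: int) -> list[int]:
    """Powers of two up to n_features, plus n_features itself."""
    grid = []
    k = 1
    while k < n_features:
        grid.append(k)
        k *= 2
    grid.append(n_features)
    return grid


def build_cluster_matrix(
    mols: Sequence[Molecule],
    labels: Sequence[bool] | None = None,
    params: FingerprintParams = CLASSIFIER_PARAMS,
    min_occurrence: int = 10,
    pcc_threshold: float = 0.8,
    fingerprints: Sequence[SparseCountFingerprint] | None = None,
):
    """Standard per-cluster preprocessing chain.

    encode -> drop identical fingerprints -> trim to min_occurrence -> prune
    correlated features.  Returns (matrix, labels) when labels are given.
    """
    if fingerprints is None:
        fingerprints = [encode_count(m, params) for m in mols]
    fm = build_feature_matrix(mols, params, min_occurrence, fingerprints=fingerprints)
    if labels is not None:
        fm, labels = remove_identical_fingerprints(fm, labels)
    else:
        fm = remove_identical_fingerprints(fm)
    fm = prune_correlated(fm, pcc_threshold)
    if labels is not None:
        return fm, list(labels)
    return fm


def evaluate_holdout(
    pipeline,
    holdout: MoleculeSet,
    cluster_of=None,
) -> pd.DataFrame:
    """Score an independent holdout set with trained per-cluster models.

    Each holdout molecule is assigned a cluster via the pipeline's clustering
    encoding and scored by that cluster's per-assay model.  The table has one
    row per cluster per assay plus a pooled 'all' row; an AUC is reported as
    missing (NaN) when the holdout slice of a cluster lacks positives (or any
    negatives), or when the cluster has no trained model.  Holdout molecules
    overlapping the training set (by canonical SMILES) are excluded with a
    warning.
    """
    train_smiles = pipeline.training_smiles
    overlap = [m.smiles for m in holdout if m.smiles in train_smiles]
    if overlap:
        warnings.warn(
            f"{len(overlap)} holdout molecules overlap the training set and are excluded: "
            f"{overlap[:5]}{'...' if len(overlap) > 5 else ''}"
        )
    mols = [m for m in holdout if m.smiles not in train_smiles]
    if not mols:
        raise EmptySetError("holdout set empty after removing training overlap")

    assignments = [
        int(pipeline.cluster_model.assign(encode_folded_bits(m, pipeline.cluster_model.params).bits)[0])
        for m in mols
    ]
    rows = []
    pooled: dict[str, tuple[list[float], list[bool]]] = {"b": ([], []), "t": ([], [])}
    for cid in range(pipeline.cluster_model.k):
        members = [i for i, a in enumerate(assignments) if a == cid]
        for assay in ("b", "t"):
            labels = [getattr(mols[i], f"label_{assay}") for i in members]
            model = pipeline.assay_model(cid, assay)
            auc = np.nan
            if members and model is not None:
                scores = [pipeline.score(mols[i], cid, assay) for i in members]
                pooled[assay][0].extend(scores)
                pooled[assay][1].extend(labels)
                if any(labels) and not all(labels):
                    auc = roc_auc(scores, labels)
            rows.append(
                {
                    "cluster": cid,
                    "assay": assay,
                    "n": len(members),
                    "n_positive": int(sum(labels)),
                    "auc": auc,
                }
            )
    for assay in ("b", "t"):
        scores, labels = pooled[assay]
        auc = (
            roc_auc(scores, labels)
            if labels and any(labels) and not all(labels)
            else np.nan
        )
        rows.append(
            {"cluster": "all", "assay": assay, "n": len(labels), "n_positive": int(sum(labels)), "auc": auc}
        )
    return pd.DataFrame(rows)


def radius_chirality_benchmark(
    mols: Sequence[Molecule],
    labels: Sequence[bool],
    radii: Sequence[int],
    chiral_options: Sequence[bool] = (False, True),
    cv: CVConfig = CVConfig(),
    min_occurrence: int = 10,
    pcc_threshold: float = 0.8,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Mean RF AUC over the full pipeline per (radius, chirality) combination."""
    if len(radii) == 0:
        raise ParameterError("radii must be non-empty")
    spec = spec or ModelSpec.rf()
    rows = []
    for radius in radii:
        for chiral in chiral_options:
            p = FingerprintParams(radius=radius, chiral=chiral, variant="count_unfolded")
            fm, y = build_cluster_matrix(
                mols, labels, p, min_occurrence=min_occurrence, pcc_threshold=pcc_threshold
            )
            res = cross_validate(spec, fm, y, cv, context=f"radius={radius} chiral={chiral}")
            rows.append(
                {
                    "radius": radius,
                    "chiral": chiral,
                    "mean_auc": res.mean_auc,
                    "sd_auc": res.sd_auc,
                    "n_features": fm.n_features,
                }
            )
    return pd.DataFrame(rows)
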