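"""End-to-end two-step epitope prediction for query molecules.

Step 1 assigns the query to a structural class (k-means over the folded
non-chiral bit encoding).  Step 2 applies that cluster's B-cell and T-cell
models to the query's chiral unfolded count fingerprint restricted to the
cluster's retained-feature registry, and reports:

* per-assay epitope probabilities (ABSENT when the cluster holds no positives
  for an assay, so no model could be trained);
* the significant enriched substructures the query itself contains;
* the 5 most similar known epitopes, ranked by Euclidean distance over the
  cluster's retained feature counts, each annotated with the overall
  count-Tanimoto similarity on full unfolded fingerprints.  The two spaces are
  deliberately different: the distance ranks within the model's feature space,
  the Tanimoto describes whole-molecule similarity.
"""

from __future__ import annotations

import datetime
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np

from .chem_io import Molecule, MoleculeSet, parse_smiles
from .classify import ModelSpec, _build_estimator, count_tanimoto, select_top_features
from .clustering import ClusterModel, fit_kmeans
from .errors import EmptySetError, ParameterError, PipelineIOError
from .feature_stats import FeatureStats, feature_statistics
from .fingerprints import (
    CLASSIFIER_PARAMS,
    CLUSTERING_PARAMS,
    FeatureMatrix,
    FingerprintParams,
    SparseCountFingerprint,
    bit_matrix,
    build_feature_matrix,
    encode_count,
    encode_folded_bits,
    feature_substructure,
    prune_correlated,
    remove_identical_fingerprints,
)

FORMAT_VERSION = "npek-pipeline-1"

#: marker for a probability/model that cannot exist (no positives in cluster)
ABSENT = None


@dataclass
class EpitopeStore:
    """Known epitopes of one cluster: ids, structures and both encodings."""

    mol_ids: list[str]
    smiles: list[str]
    full_fps: list[SparseCountFingerprint]
    feature_vectors: np.ndarray  # n_epitopes x n_retained_features

    def __len__(self) -> int:
        return len(self.mol_ids)


@dataclass
class ClusterData:
    """Everything trained for one structural class.

    ``feature_ids`` is the full retained registry after trimming/pruning; a
    model trained on a chi-squared top-k subset carries its own registry in
    ``model_registry_*`` so scoring always matches the fitted input space.
    """

    feature_ids: np.ndarray
    model_b: object | None  # ABSENT when the cluster has no B positives
    model_t: object | None
    stats_b: list[FeatureStats] | None
    stats_t: list[FeatureStats] | None
    epitopes: EpitopeStore
    n_molecules: int = 0
    model_registry_b: np.ndarray | None = None  # defaults to feature_ids
    model_registry_t: np.ndarray | None = None

    def registry_for(self, assay: str) -> np.ndarray:
        r = self.model_registry_b if assay == "b" else self.model_registry_t
        return r if r is not None else self.feature_ids


@dataclass
class TrainedPipeline:
    cluster_model: ClusterModel
    clusters: dict[int, ClusterData]
    params: FingerprintParams  # classifier encoding
    training_smiles: set[str]
    seed: int
    version: str = FORMAT_VERSION
    created: str = ""
    metadata: dict = field(default_factory=dict)

    def assay_model(self, cluster_id: int, assay: str):
        cd = self.clusters.get(cluster_id)
        if cd is None:
            return ABSENT
        return cd.model_b if assay == "b" else cd.model_t

    def _query_vector(
        self, m: Molecule | str, cluster_id: int, registry: np.ndarray | None = None
    ) -> tuple[np.ndarray, int]:
        """Query counts restricted to the cluster registry, plus #dropped features."""
        q = encode_count(m, self.params)
        cd = self.clusters[cluster_id]
        reg = registry if registry is not None else cd.feature_ids
        known = set(int(f) for f in reg)
        x = np.array([q[int(f)] for f in reg], dtype=np.float64)
        dropped = sum(1 for f in q.counts if f not in known)
        return x, dropped

    def score(self, m: Molecule | str, cluster_id: int, assay: str) -> float:
        model = self.assay_model(cluster_id, assay)
        if model is ABSENT:
            raise ParameterError(f"cluster {cluster_id} has no {assay!r} model")
        cd = self.clusters[cluster_id]
        x, _ = self._query_vector(m, cluster_id, cd.registry_for(assay))
        return float(model.predict_proba(x[None, :])[0, list(model.classes_).index(True)])


@dataclass(frozen=True)
class Neighbor:
    mol_id: str
    smiles: str
    euclidean_distance: float
    tanimoto: float  # on full unfolded count fingerprints


@dataclass
class PredictionReport:
    query_smiles: str  # canonical
    cluster_id: int
    prob_b: float | None
    prob_t: float | None
    dropped_features: int
    significant_features_present: list[tuple[int, float, str]]  # (feature_id, corrected_p, fragment)
    neighbors: list[Neighbor]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "query_smiles": self.query_smiles,
            "cluster_id": self.cluster_id,
            "prob_b": self.prob_b,
            "prob_t": self.prob_t,
            "dropped_features": self.dropped_features,
            "significant_features_present": [
                {"feature_id": f, "corrected_p": p, "fragment": s}
                for f, p, s in self.significant_features_present
            ],
            "neighbors": [
                {
                    "mol_id": n.mol_id,
                    "smiles": n.smiles,
                    "euclidean_distance": n.euclidean_distance,
                    "tanimoto": n.tanimoto,
                }
                for n in self.neighbors
            ],
            "note": self.note,
        }


def train_pipeline(
    ms: MoleculeSet,
    k: int = 8,
    seed: int = 0,
    clustering_params: FingerprintParams = CLUSTERING_PARAMS,
    classifier_params: FingerprintParams = CLASSIFIER_PARAMS,
    min_occurrence: int = 10,
    pcc_threshold: float = 0.8,
    model_spec: ModelSpec | None = None,
    top_k_features: int | None = None,
) -> TrainedPipeline:
    """Cluster the collection and train per-cluster, per-assay classifiers.

    By default the production models use the full retained feature set;
    ``top_k_features`` selects a smaller chi-squared-ranked model instead for
    interpretability-first deployments.  A cluster with zero positives for an
    assay gets an ABSENT model for that assay.
    """
    model_spec = model_spec or ModelSpec.rf(seed=seed)
    bits = bit_matrix(ms.molecules, clustering_params)
    cmodel = fit_kmeans(bits, k=k, seed=seed, params=clustering_params)
    assignments = cmodel.assign(bits)

    clusters: dict[int, ClusterData] = {}
    for cid in range(k):
        member_idx = np.flatnonzero(assignments == cid)
        members = [ms.molecules[i] for i in member_idx]
        if not members:
            continue
        fps = [encode_count(m, classifier_params) for m in members]
        try:
            fm = build_feature_matrix(members, classifier_params, min_occurrence, fingerprints=fps)
        except EmptySetError:
            warnings.warn(f"cluster {cid}: no feature passed the min-occurrence trim; skipped")
            continue
        # identical-row removal keeps the same rows for both assays; only the
        # surviving labels differ (conflicts resolve positive per assay)
        fm_dedup, labels_b = remove_identical_fingerprints(fm, [m.label_b for m in members])
        _, labels_t = remove_identical_fingerprints(fm, [m.label_t for m in members])
        fm_pruned = prune_correlated(fm_dedup, pcc_threshold)

        kept_ids = set(fm_pruned.mol_ids)
        kept_members = [m for m in members if m.mol_id in kept_ids]
        kept_fps = [f for m, f in zip(members, fps) if m.mol_id in kept_ids]

        models: dict[str, object | None] = {}
        stats: dict[str, list[FeatureStats] | None] = {}
        registries: dict[str, np.ndarray | None] = {"b": None, "t": None}
        for assay, y in (("b", labels_b), ("t", labels_t)):
            if not any(y):
                models[assay], stats[assay] = ABSENT, None
                continue
            fm_fit = fm_pruned
            if top_k_features is not None and top_k_features < fm_pruned.n_features:
                fm_fit = select_top_features(fm_pruned, y, top_k_features)
                registries[assay] = fm_fit.feature_ids
            est = _build_estimator(model_spec, model_spec.seed)
            est.fit(fm_fit.counts.astype(np.float64), np.asarray(y, dtype=bool))
            models[assay] = est
            stats[assay] = feature_statistics(fm_pruned, y) if not all(y) else None

        epi_rows = [
            i for i, mid in enumerate(fm_pruned.mol_ids)
            if labels_b[i] or labels_t[i]
        ]
        by_id = {m.mol_id: (m, f) for m, f in zip(kept_members, kept_fps)}
        store = EpitopeStore(
            mol_ids=[fm_pruned.mol_ids[i] for i in epi_rows],
            smiles=[by_id[fm_pruned.mol_ids[i]][0].smiles for i in epi_rows],
            full_fps=[by_id[fm_pruned.mol_ids[i]][1] for i in epi_rows],
            feature_vectors=fm_pruned.counts[epi_rows].astype(np.float64),
        )
        clusters[cid] = ClusterData(
            feature_ids=fm_pruned.feature_ids,
            model_b=models["b"],
            model_t=models["t"],
            stats_b=stats["b"],
            stats_t=stats["t"],
            epitopes=store,
            n_molecules=fm_pruned.n_molecules,
            model_registry_b=registries["b"],
            model_registry_t=registries["t"],
        )

    return TrainedPipeline(
        cluster_model=cmodel,
        clusters=clusters,
        params=classifier_params,
        training_smiles={m.smiles for m in ms.molecules},
        seed=seed,
        created=datetime.date.today().isoformat(),
        metadata={"k": k, "min_occurrence": min_occurrence, "pcc_threshold": pcc_threshold},
    )


def nearest_epitopes(
    query_vector: np.ndarray,
    query_fp: SparseCountFingerprint,
    store: EpitopeStore,
    n: int = 5,
) -> list[Neighbor]:
    """Top-n stored epitopes by Euclidean distance over retained feature counts.

    Ties break toward the higher full-fingerprint Tanimoto, then the lower
    mol_id.  If n exceeds the store size the whole store is returned, ranked.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if len(store) == 0:
        raise EmptySetError("epitope store is empty")
    dists = np.sqrt(((store.feature_vectors - np.asarray(query_vector)) ** 2).sum(axis=1))
    rows = [
        Neighbor(
            mol_id=store.mol_ids[i],
            smiles=store.smiles[i],
            euclidean_distance=float(dists[i]),
            tanimoto=count_tanimoto(query_fp, store.full_fps[i]),
        )
        for i in range(len(store))
    ]
    rows.sort(key=lambda r: (r.euclidean_distance, -r.tanimoto, r.mol_id))
    return rows[:n]


def predict(
    smiles: str,
    tp: TrainedPipeline,
    n_neighbors: int = 5,
    significance: float = 0.05,
) -> PredictionReport:
    """Two-step analysis of one query molecule.

    Raises a parse error on invalid SMILES (no partial report).  A query
    routed to a cluster without trained models gets ABSENT probabilities and
    an explanatory note.
    """
    mol = parse_smiles(smiles)
    cid = int(tp.cluster_model.assign(encode_folded_bits(mol, tp.cluster_model.params).bits)[0])
    cd = tp.clusters.get(cid)
    if cd is None:
        return PredictionReport(
            query_smiles=mol.smiles, cluster_id=cid, prob_b=ABSENT, prob_t=ABSENT,
            dropped_features=0, significant_features_present=[], neighbors=[],
            note="no model was trained for this structural class",
        )

    x, dropped = tp._query_vector(mol, cid)
    q = encode_count(mol, tp.params)

    probs: dict[str, float | None] = {}
    for assay in ("b", "t"):
        model = cd.model_b if assay == "b" else cd.model_t
        probs[assay] = ABSENT if model is ABSENT else tp.score(mol, cid, assay)

    sig: dict[int, float] = {}
    for stats in (cd.stats_b, cd.stats_t):
        if stats is None:
            continue
        for st in stats:
            if st.corrected_p < significance and q[st.feature_id] >= 1:
                sig[st.feature_id] = min(sig.get(st.feature_id, 1.0), st.corrected_p)
    significant = [
        (fid, p, feature_substructure(mol, fid, tp.params).fragment_smiles)
        for fid, p in sorted(sig.items(), key=lambda kv: (kv[1], kv[0]))
    ]

    neighbors = (
        nearest_epitopes(x, q, cd.epitopes, n_neighbors) if len(cd.epitopes) else []
    )
    note = ""
    if probs["b"] is ABSENT and probs["t"] is ABSENT:
        note = "there are no known epitopes in this structural class; no model could be trained"
    return PredictionReport(
        query_smiles=mol.smiles,
        cluster_id=cid,
        prob_b=probs["b"],
        prob_t=probs["t"],
        dropped_features=dropped,
        significant_features_present=significant,
        neighbors=neighbors,
        note=note,
    )


def save_pipeline(tp: TrainedPipeline, directory) -> None:
    """Persist a trained pipeline (metadata JSON + joblib payload)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": tp.version,
        "seed": tp.seed,
        "created": tp.created,
        "k": tp.cluster_model.k,
        "metadata": tp.metadata,
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(tp, d / "pipeline.joblib")


def load_pipeline(directory) -> TrainedPipeline:
    """Load a pipeline saved by save_pipeline; round trips reproduce predictions."""
    d = Path(directory)
    meta_path = d / "meta.json"
    payload = d / "pipeline.joblib"
    if not meta_path.exists() or not payload.exists():
        raise FileNotFoundError(f"no saved pipeline found in {d}")
    meta = json.loads(meta_path.read_text())
    if meta.get("version") != FORMAT_VERSION:
        raise PipelineIOError(
            f"incompatible pipeline version {meta.get('version')!r}; expected {FORMAT_VERSION!r}"
        )
    tp = joblib.load(payload)
    if tp.version != FORMAT_VERSION:
        raise PipelineIOError("pipeline payload version mismatch")
    return tp
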