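"""Circular (Morgan/ECFP) fingerprint encoding and per-cluster feature matrices.

Two encodings are used at different stages:

* folded **bit** fingerprints (default 1024 bits, radius 3, non-chiral) feed the
  structural clustering;
* unfolded **count** fingerprints (radius 3, chiral) feed the epitope
  classifiers.  Count features keep the number of occurrences of each circular
  substructure and therefore distinguish repetitive motifs (long alkyl chains)
  that bit fingerprints conflate.

Feature identifiers are the toolkit's 32-bit unsigned atom-environment hashes;
hash collisions are accepted.  Folding maps a hash to ``hash mod n_bits``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import Molecule
from .errors import EmptySetError, FeatureLookupError, ParameterError

logger = logging.getLogger(__name__)

VARIANT_BIT_FOLDED = "bit_folded"
VARIANT_COUNT_UNFOLDED = "count_unfolded"


@dataclass(frozen=True)
class FingerprintParams:
    """Morgan fingerprint encoding parameters.

    radius 3 with 1024 folded bits (non-chiral) for clustering; radius 3
    chiral unfolded counts for classification.  ``n_bits`` is ignored for the
    count_unfolded variant.
    """

    radius: int = 3
    chiral: bool = False
    n_bits: int = 1024
    variant: str = VARIANT_BIT_FOLDED

    def __post_init__(self):
        if self.radius < 0:
            raise ParameterError("radius must be non-negative")
        if self.n_bits <= 0:
            raise ParameterError("n_bits must be positive")
        if self.variant not in (VARIANT_BIT_FOLDED, VARIANT_COUNT_UNFOLDED):
            raise ParameterError(f"unknown fingerprint variant {self.variant!r}")


#: encoding used for clustering throughout the pipeline
CLUSTERING_PARAMS = FingerprintParams(radius=3, chiral=False, n_bits=1024, variant=VARIANT_BIT_FOLDED)
#: encoding used for the classifiers
CLASSIFIER_PARAMS = FingerprintParams(radius=3, chiral=True, variant=VARIANT_COUNT_UNFOLDED)


def _generator(p: FingerprintParams):
    return rdFingerprintGenerator.GetMorganGenerator(
        radius=p.radius, fpSize=p.n_bits, includeChirality=p.chiral
    )


def _mol_from(m: Molecule | str | Chem.Mol) -> Chem.Mol:
    if isinstance(m, Chem.Mol):
        return m
    smiles = m.smiles if isinstance(m, Molecule) else m
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParameterError(f"invalid molecule {smiles!r}")
    return mol


@dataclass(frozen=True)
class SparseCountFingerprint:
    """Map from feature id (environment hash) to positive occurrence count."""

    counts: dict[int, int]
    params: FingerprintParams

    def __post_init__(self):
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("stored counts must be >= 1; absent key means 0")

    def __getitem__(self, feature_id: int) -> int:
        return self.counts.get(feature_id, 0)

    def support(self) -> frozenset[int]:
        return frozenset(self.counts)


@dataclass(frozen=True)
class FoldedBitFingerprint:
    """Fixed-length binary fingerprint (entries in {0, 1})."""

    bits: np.ndarray
    params: FingerprintParams

    def __post_init__(self):
        if len(self.bits) != self.params.n_bits:
            raise ValueError("bit vector length must equal params.n_bits")

    def popcount(self) -> int:
        return int(self.bits.sum())


def encode_count(m: Molecule | str, p: FingerprintParams = CLASSIFIER_PARAMS) -> SparseCountFingerprint:
    """Unfolded Morgan count fingerprint of one molecule.

    One entry per distinct atom environment up to ``p.radius``; the count is
    the number of atoms rooting that environment.
    """
    if p.variant != VARIANT_COUNT_UNFOLDED:
        raise ParameterError("encode_count requires the count_unfolded variant")
    fp = _generator(p).GetSparseCountFingerprint(_mol_from(m))
    return SparseCountFingerprint(
        {int(k): int(v) for k, v in fp.GetNonzeroElements().items()}, p
    )


def encode_folded_bits(m: Molecule | str, p: FingerprintParams = CLUSTERING_PARAMS) -> FoldedBitFingerprint:
    """Folded Morgan bit fingerprint: bit set at (feature hash mod n_bits)."""
    if p.variant != VARIANT_BIT_FOLDED:
        raise ParameterError("encode_folded_bits requires the bit_folded variant")
    fp = _generator(p).GetFingerprint(_mol_from(m))
    bits = np.zeros(p.n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return FoldedBitFingerprint(bits, p)


def bit_matrix(mols: Sequence[Molecule | str], p: FingerprintParams = CLUSTERING_PARAMS) -> np.ndarray:
    """n x n_bits binary matrix of folded fingerprints, rows in input order."""
    return np.vstack([encode_folded_bits(m, p).bits for m in mols])


@dataclass
class FeatureMatrix:
    """Molecules x retained-features count table for one cluster.

    ``feature_ids`` is the ordered registry of retained environment hashes;
    ``history`` records the filters applied (min_occurrence, pcc_threshold,
    identical-row removal).
    """

    mol_ids: list[str]
    feature_ids: np.ndarray  # ascending unless reordered by an explicit ranking
    counts: np.ndarray  # shape (n_molecules, n_features), non-negative ints
    params: FingerprintParams
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.feature_ids = np.asarray(self.feature_ids, dtype=np.int64)
        if self.counts.shape != (len(self.mol_ids), len(self.feature_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.mol_ids)} molecules x {len(self.feature_ids)} features"
            )

    @property
    def n_molecules(self) -> int:
        return len(self.mol_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def column(self, feature_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.feature_ids == feature_id)
        if idx.size == 0:
            raise FeatureLookupError(f"feature {feature_id} not in matrix registry")
        return self.counts[:, idx[0]]

    def subset_features(self, feature_ids: Sequence[int], history_entry: dict | None = None) -> "FeatureMatrix":
        """New matrix restricted to ``feature_ids`` in the given order."""
        pos = {int(f): i for i, f in enumerate(self.feature_ids)}
        try:
            cols = [pos[int(f)] for f in feature_ids]
        except KeyError as e:
            raise FeatureLookupError(f"feature {e.args[0]} not in matrix registry") from None
        hist = dict(self.history)
        if history_entry:
            hist.update(history_entry)
        return FeatureMatrix(
            list(self.mol_ids), np.asarray(feature_ids, dtype=np.int64),
            self.counts[:, cols], self.params, hist,
        )


def build_feature_matrix(
    mols: Sequence[Molecule | str],
    p: FingerprintParams = CLASSIFIER_PARAMS,
    min_occurrence: int = 10,
    fingerprints: Sequence[SparseCountFingerprint] | None = None,
) -> FeatureMatrix:
    """Count-fingerprint matrix trimmed to features occurring in >= min_occurrence molecules.

    Columns are in ascending feature-id order; rows follow the input order.
    Precomputed ``fingerprints`` may be passed to avoid re-encoding.
    Raises EmptySetError when no feature survives the trim.
    """
    if len(mols) == 0:
        raise EmptySetError("cannot build a feature matrix from zero molecules")
    if min_occurrence < 1:
        raise ParameterError("min_occurrence must be >= 1")
    if fingerprints is None:
        fingerprints = [encode_count(m, p) for m in mols]

    support_count: dict[int, int] = {}
    for fp in fingerprints:
        for fid in fp.counts:
            support_count[fid] = support_count.get(fid, 0) + 1
    retained = sorted(f for f, n in support_count.items() if n >= min_occurrence)
    if not retained:
        raise EmptySetError(
            f"no feature occurs in >= {min_occurrence} of the {len(mols)} molecules"
        )

    col = {f: j for j, f in enumerate(retained)}
    counts = np.zeros((len(mols), len(retained)), dtype=np.int64)
    for i, fp in enumerate(fingerprints):
        for fid, c in fp.counts.items():
            j = col.get(fid)
            if j is not None:
                counts[i, j] = c

    mol_ids = [m.mol_id if isinstance(m, Molecule) else f"mol_{i}" for i, m in enumerate(mols)]
    return FeatureMatrix(
        mol_ids, np.asarray(retained, dtype=np.int64), counts, p,
        history={"min_occurrence": min_occurrence},
    )


def prune_correlated(
    fm: FeatureMatrix,
    pcc_threshold: float = 0.8,
    ranking: Sequence[int] | None = None,
) -> FeatureMatrix:
    """Greedy removal of features correlating with an already-kept feature.

    Features are scanned in ``ranking`` order (default: ascending feature id);
    a feature is dropped iff its |Pearson correlation| with any kept feature is
    strictly above ``pcc_threshold``.  Correlations are computed on raw counts.
    Zero-variance columns have undefined PCC; they are treated as correlation 0
    (kept) and logged.
    """
    if not (0 < pcc_threshold < 1):
        raise ParameterError("pcc_threshold must be in (0, 1)")
    if ranking is None:
        order = np.argsort(fm.feature_ids, kind="stable")
    else:
        pos = {int(f): i for i, f in enumerate(fm.feature_ids)}
        order = np.asarray([pos[int(f)] for f in ranking])

    X = fm.counts.astype(np.float64)
    std = X.std(axis=0)
    constant = std == 0
    if constant.any():
        logger.warning(
            "prune_correlated: %d zero-variance columns kept (PCC undefined, treated as 0)",
            int(constant.sum()),
        )
    centered = X - X.mean(axis=0)
    norms = np.where(constant, 1.0, np.sqrt((centered**2).sum(axis=0)))

    kept: list[int] = []
    for j in order:
        j = int(j)
        drop = False
        if not constant[j]:
            for i in kept:
                if constant[i]:
                    continue
                pcc = float(centered[:, i] @ centered[:, j] / (norms[i] * norms[j]))
                if abs(pcc) > pcc_threshold:
                    drop = True
                    break
        if not drop:
            kept.append(j)

    kept_sorted = sorted(kept, key=lambda j: int(fm.feature_ids[j]))
    return FeatureMatrix(
        list(fm.mol_ids),
        fm.feature_ids[kept_sorted],
        fm.counts[:, kept_sorted],
        fm.params,
        history={**fm.history, "pcc_threshold": pcc_threshold},
    )


def remove_identical_fingerprints(
    fm: FeatureMatrix, labels: Sequence[bool] | None = None
):
    """Drop molecules whose retained-feature count vectors are identical.

    Among identical rows the first is kept.  When ``labels`` is given and the
    duplicates carry conflicting labels, the kept row becomes positive (and
    the conflict is logged); the call then returns ``(matrix, labels)``.
    """
    seen: dict[bytes, int] = {}
    keep_rows: list[int] = []
    out_labels: list[bool] = []
    conflicts = 0
    for i in range(fm.n_molecules):
        key = fm.counts[i].tobytes()
        if key in seen:
            if labels is not None:
                k = seen[key]
                if bool(labels[i]) != out_labels[k]:
                    conflicts += 1
                    out_labels[k] = True  # positive wins
            continue
        seen[key] = len(keep_rows)
        keep_rows.append(i)
        if labels is not None:
            out_labels.append(bool(labels[i]))
    if conflicts:
        logger.warning(
            "remove_identical_fingerprints: %d label conflicts resolved as positive", conflicts
        )
    out = FeatureMatrix(
        [fm.mol_ids[i] for i in keep_rows],
        fm.feature_ids,
        fm.counts[keep_rows],
        fm.params,
        history={**fm.history, "identical_rows_removed": fm.n_molecules - len(keep_rows)},
    )
    if labels is None:
        return out
    return out, out_labels


@dataclass(frozen=True)
class SubstructureDescription:
    """Serializable atom environment backing one fingerprint feature."""

    feature_id: int
    central_atom: int
    radius: int
    bond_indices: tuple[int, ...]
    fragment_smiles: str


def feature_substructure(m: Molecule | str, feature_id: int, p: FingerprintParams = CLASSIFIER_PARAMS) -> SubstructureDescription:
    """Atom environment (root atom + bonds within the feature's radius) for one feature.

    The molecule must actually contain the feature; otherwise FeatureLookupError.
    When several atoms root the same environment the lowest atom index is used.
    """
    mol = _mol_from(m)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    _generator(p).GetSparseCountFingerprint(mol, additionalOutput=ao)
    info = ao.GetBitInfoMap()
    if feature_id not in info:
        raise FeatureLookupError(
            f"feature {feature_id} does not occur in molecule "
            f"{(m.smiles if isinstance(m, Molecule) else m)!r}"
        )
    atom_idx, radius = min(info[feature_id])
    if radius == 0:
        frag = Chem.MolFragmentToSmiles(mol, atomsToUse=[atom_idx], bondsToUse=[])
        return SubstructureDescription(feature_id, atom_idx, 0, (), frag)
    env = list(Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom_idx))
    amap: dict[int, int] = {}
    submol = Chem.PathToSubmol(mol, env, atomMap=amap)
    frag = Chem.MolToSmiles(submol, rootedAtAtom=amap[atom_idx], canonical=True)
    return SubstructureDescription(feature_id, atom_idx, radius, tuple(env), frag)
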