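"""Seeded synthetic SMILES datasets with a planted, label-ruled signal.

Real non-peptidic epitope collections are dominated by repetitive structural
signals — glycolipid epitopes carry long fatty-acid chains attached to a
sugar or ring scaffold, and enriched substructures such as secondary amides
recur many times per molecule.  The generator emulates exactly that: a
background of diverse decorated scaffolds with short alkyl chains, and
positives whose chains are long and/or carry a planted motif fragment.  The
label rule (chain length >= threshold OR motif present) is satisfied exactly
by construction, so parameter-recovery tests know the ground truth.

Because chains are unbranched repeated CH2 units, chain length beyond the
fingerprint radius changes only the *counts* of interior environments, not
the environment set — the ``bit_blind`` preset exploits this to produce two
classes that bit fingerprints cannot separate but count fingerprints can.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem

from .chem_io import Molecule, MoleculeSet, SOURCE_BACKGROUND, SOURCE_EPITOPE, canonical_smiles
from .errors import GenerationError, ParameterError
from .fingerprints import FingerprintParams, encode_count, CLASSIFIER_PARAMS

DEFAULT_SCAFFOLDS = (
    "c1ccccc1",                 # benzene
    "OC1OC(CO)C(O)C(O)C1O",     # pyranose ring
    "C1CCNCC1",                 # piperidine
    "c1ccc2ccccc2c1",           # naphthalene
    "C1CCOC1",                  # tetrahydrofuran
    "OP(=O)(O)OC",              # phosphate linker
)

#: terminal decorations appended after the chain (class-independent variety)
_TERMINALS = ("", "O", "N", "F", "Cl", "C(C)C", "OC")


@dataclass(frozen=True)
class LabelRule:
    """Declarative positivity predicate over generated structure parameters."""

    chain_threshold: int | None = 10  # positive if chain length >= threshold
    motif_required: bool = False  # positive iff motif present (motif-only rule)

    def is_positive(self, chain_length: int, has_motif: bool) -> bool:
        if self.motif_required:
            return has_motif
        by_chain = self.chain_threshold is not None and chain_length >= self.chain_threshold
        return by_chain or has_motif


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; the defaults mirror the intended study shape:

    ~10% positives in a background of diverse decorated small molecules, with
    the positive signal carried by long carbon chains (12-20 CH2 units vs 1-6
    in the background) and a secondary-amide motif planted on most positives.
    """

    n_background: int = 300
    n_positive: int = 33
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    background_chain: tuple[int, int] = (1, 6)  # inclusive sampling range
    positive_chain: tuple[int, int] = (12, 20)
    planted_motif: str = "C(=O)NC"  # secondary amide fragment
    motif_prob: float = 0.8  # probability a positive carries the motif
    label_rule: LabelRule = field(default_factory=LabelRule)
    t_fraction: float = 0.4  # fraction of positives also positive in the T assay
    seed: int = 0

    @staticmethod
    def separable(n_background: int = 300, n_positive: int = 33, seed: int = 0) -> "SyntheticSpec":
        """Noise-free chain-length separation: positives >= 12, negatives <= 6."""
        return SyntheticSpec(n_background=n_background, n_positive=n_positive, seed=seed)

    @staticmethod
    def motif_only(n_background: int = 200, n_positive: int = 40, seed: int = 0) -> "SyntheticSpec":
        """Chains drawn identically in both classes; only the motif separates."""
        return SyntheticSpec(
            n_background=n_background,
            n_positive=n_positive,
            background_chain=(2, 8),
            positive_chain=(2, 8),
            motif_prob=1.0,
            label_rule=LabelRule(chain_threshold=None, motif_required=True),
            seed=seed,
        )

    @staticmethod
    def bit_blind(n_background: int = 120, n_positive: int = 60, seed: int = 0) -> "SyntheticSpec":
        """Classes differ only in chain length beyond the fingerprint radius.

        Both chain ranges exceed 2*radius+1 for radius 3, so the circular
        environment *set* of the chain is saturated and identical across
        classes; only occurrence counts differ.
        """
        return SyntheticSpec(
            n_background=n_background,
            n_positive=n_positive,
            background_chain=(9, 12),
            positive_chain=(18, 24),
            motif_prob=0.0,
            label_rule=LabelRule(chain_threshold=15, motif_required=False),
            seed=seed,
        )


def _assemble(scaffold: str, chain_length: int, terminal: str, motif: str | None,
              branch_at: int | None) -> str:
    """Concatenative SMILES assembly: scaffold + chain (+ branch) + motif/terminal."""
    chain = "C" * chain_length
    if branch_at is not None and 0 < branch_at < chain_length:
        chain = chain[:branch_at] + "(C)" + chain[branch_at:]
    tail = motif if motif is not None else terminal
    return scaffold + chain + tail


def generate(spec: SyntheticSpec) -> MoleculeSet:
    """Generate a seeded MoleculeSet with exact class sizes and unique SMILES.

    Every emitted SMILES is valid and canonical; positives and negatives
    satisfy the spec's label rule exactly.  The same seed reproduces the same
    set byte for byte.
    """
    if spec.n_background + spec.n_positive < 20:
        raise ParameterError("need at least 20 molecules in total")
    for s in spec.scaffolds:
        if Chem.MolFromSmiles(_assemble(s, 2, "", None, None)) is None:
            raise GenerationError(f"scaffold template {s!r} cannot yield valid SMILES")

    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()
    molecules: list[Molecule] = []

    def draw_class(n: int, positive: bool) -> None:
        lo, hi = spec.positive_chain if positive else spec.background_chain
        made = 0
        attempts = 0
        while made < n:
            attempts += 1
            if attempts > 200 * n:
                raise GenerationError(
                    f"could not generate {n} unique molecules from scaffolds {spec.scaffolds}"
                )
            scaffold = spec.scaffolds[int(rng.integers(len(spec.scaffolds)))]
            chain_length = int(rng.integers(lo, hi + 1))
            has_motif = positive and (rng.random() < spec.motif_prob)
            if spec.label_rule.is_positive(chain_length, has_motif) != positive:
                # e.g. motif-only rule: a positive that missed the motif draw
                if positive and spec.label_rule.motif_required:
                    has_motif = True
                else:
                    continue
            terminal = _TERMINALS[int(rng.integers(len(_TERMINALS)))]
            branch_at = int(rng.integers(1, chain_length)) if chain_length > 2 and rng.random() < 0.5 else None
            smi = _assemble(scaffold, chain_length, terminal,
                            spec.planted_motif if has_motif else None, branch_at)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            if positive:
                label_t = rng.random() < spec.t_fraction
                molecules.append(
                    Molecule(
                        mol_id=f"pos_{made}", smiles=canon, source=SOURCE_EPITOPE,
                        label_b=True, label_t=label_t,
                    )
                )
            else:
                molecules.append(
                    Molecule(mol_id=f"bg_{made}", smiles=canon, source=SOURCE_BACKGROUND)
                )
            made += 1

    draw_class(spec.n_background, positive=False)
    draw_class(spec.n_positive, positive=True)
    return MoleculeSet(molecules, provenance=f"synthetic(seed={spec.seed})")


def motif_feature_ids(
    spec: SyntheticSpec, params: FingerprintParams = CLASSIFIER_PARAMS
) -> frozenset[int]:
    """Fingerprint features introduced by the planted motif.

    Computed as the support difference between a reference scaffold+chain
    molecule with and without the motif appended — the ground truth that
    parameter-recovery tests compare feature rankings against.
    """
    scaffold = spec.scaffolds[0]
    length = max(4, spec.positive_chain[0])
    with_motif = encode_count(canonical_smiles(_assemble(scaffold, length, "", spec.planted_motif, None)), params)
    without = encode_count(canonical_smiles(_assemble(scaffold, length, "", None, None)), params)
    return frozenset(with_motif.support() - without.support())


def toy_fixture() -> MoleculeSet:
    """A fixed, hand-listed 24-molecule set for exact-value unit tests.

    Deliberately includes a canonical-duplicate pair ('CCO' / 'OCC'), a
    chiral/achiral trio around 2-aminopropan-1-ol, rings, chains and labeled
    positives; the raw list is NOT deduplicated.
    """
    records = [
        # (mol_id, smiles, label_b, label_t)
        ("tox_00", "CCO", False, False),
        ("tox_01", "OCC", False, False),          # canonical duplicate of tox_00
        ("tox_02", "C", False, False),
        ("tox_03", "C1CC1", False, False),
        ("tox_04", "c1ccccc1", False, False),
        ("tox_05", "Cc1ccccc1", False, False),
        ("tox_06", "CCCCCC", False, False),
        ("tox_07", "CCCCCCCCCCCCCC", True, False),   # long chain, B positive
        ("tox_08", "C[C@H](N)CO", False, False),
        ("tox_09", "C[C@@H](N)CO", False, False),  # enantiomer of tox_08
        ("tox_10", "CC(N)CO", False, False),       # achiral counterpart
        ("tox_11", "OC1OC(CO)C(O)C(O)C1O", False, False),
        ("tox_12", "OC1OC(CO)C(O)C(O)C1OCCCCCCCCCCCC", True, True),  # glycolipid-like
        ("tox_13", "OP(=O)(O)OCC", False, True),   # phosphate ester, T positive
        ("tox_14", "CC(=O)NC", False, False),
        ("tox_15", "CCCCCCCCCCCCC(=O)NC", True, False),
        ("tox_16", "c1ccc2ccccc2c1", False, False),
        ("tox_17", "C1CCNCC1", False, False),
        ("tox_18", "CC(C)CC(C)C", False, False),
        ("tox_19", "N", False, False),
        ("tox_20", "O=C(O)CCCCCCCCC", True, False),  # fatty acid, B positive
        ("tox_21", "C1CCOC1", False, False),
        ("tox_22", "CCN(CC)CC", False, False),
        ("tox_23", "CCO", True, False),            # duplicate of tox_00 with a positive label
    ]
    mols = []
    for mol_id, smi, lb, lt in records:
        src = SOURCE_EPITOPE if (lb or lt) else SOURCE_BACKGROUND
        mols.append(
            Molecule(mol_id=mol_id, smiles=canonical_smiles(smi), source=src, label_b=lb, label_t=lt)
        )
    return MoleculeSet(mols, provenance="toy_fixture")
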