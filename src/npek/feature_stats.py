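"""Chi-squared feature importance and substructure enrichment statistics.

For every retained fingerprint feature, the association between its per-class
count totals and epitope status is tested with a chi-squared statistic: the
null hypothesis is that the feature count of the epitopes was drawn from the
same population as the background, i.e. the expected class-wise count total is
the overall count total multiplied by the class's share of molecules.  With
two classes the statistic has one degree of freedom.  Bonferroni correction is
applied over the features tested in a cluster x assay.

Three interpretability statistics accompany each feature, mirroring the
columns of the per-cluster report tables:

* **epitope coverage** — fraction of positives containing the feature at
  least once;
* **fold-enrichment** — epitope coverage divided by background coverage
  (undefined when no background molecule contains the feature);
* **mean count difference** — mean count among feature-containing positives
  minus mean count among feature-containing background molecules (undefined
  when no background molecule contains the feature).

Undefined values are carried as an explicit MISSING marker and rendered "-"
in text reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .chem_io import Molecule, MoleculeSet
from .errors import ParameterError, UndefinedMetricError
from .fingerprints import FeatureMatrix, SubstructureDescription, feature_substructure

logger = logging.getLogger(__name__)

#: explicit marker for statistics that cannot be computed (rendered "-")
MISSING = None


@dataclass(frozen=True)
class FeatureStats:
    """Per-feature enrichment record — one row of a cluster x assay table."""

    feature_id: int
    raw_p: float
    corrected_p: float
    epitope_coverage: float
    fold_enrichment: float | None  # MISSING iff background coverage is 0
    mean_count_difference: float | None  # MISSING iff no background molecule has the feature


def chi2_scores(counts: np.ndarray, labels: Sequence[bool]) -> tuple[np.ndarray, np.ndarray]:
    """Chi-squared statistic and raw p per feature column.

    Observed values are the class-wise count sums; expected values are the
    total count of the feature times each class's share of molecules.  A
    feature with zero total count carries no evidence: statistic 0, p = 1.
    """
    counts = np.asarray(counts, dtype=np.float64)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise UndefinedMetricError("chi-squared feature test requires both classes")
    if (counts < 0).any():
        raise ParameterError("counts must be non-negative")

    n = len(y)
    obs_pos = counts[y].sum(axis=0)
    obs_neg = counts[~y].sum(axis=0)
    total = obs_pos + obs_neg
    share_pos = y.sum() / n
    exp_pos = total * share_pos
    exp_neg = total * (1 - share_pos)

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(
            total > 0,
            (obs_pos - exp_pos) ** 2 / np.where(exp_pos > 0, exp_pos, 1)
            + (obs_neg - exp_neg) ** 2 / np.where(exp_neg > 0, exp_neg, 1),
            0.0,
        )
    if (total == 0).any():
        logger.warning("chi2_scores: %d zero-count features set to p=1", int((total == 0).sum()))
    p = sps.chi2.sf(stat, df=1)
    p = np.where(total > 0, p, 1.0)
    return stat, p


def chi2_feature_test(fm: FeatureMatrix, labels: Sequence[bool]) -> np.ndarray:
    """Raw p-values per retained feature of the matrix."""
    _, p = chi2_scores(fm.counts, labels)
    return p


def bonferroni(raw_p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni correction: min(1, p * m) elementwise.

    ``m`` defaults to the number of p-values and must be at least that many
    (the number of features tested in the cluster x assay).
    """
    p = np.asarray(raw_p, dtype=np.float64)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ParameterError(f"m={m} smaller than the {len(p)} tests supplied")
    return np.minimum(1.0, p * m)


def feature_statistics(fm: FeatureMatrix, labels: Sequence[bool]) -> list[FeatureStats]:
    """Full per-feature statistics table, sorted by corrected p ascending.

    Ties in corrected p are broken toward the lower feature id so the table
    order is deterministic.
    """
    y = np.asarray(labels, dtype=bool)
    raw_p = chi2_feature_test(fm, y)
    corr_p = bonferroni(raw_p)

    pos = fm.counts[y]
    neg = fm.counts[~y]
    has_pos = pos >= 1
    has_neg = neg >= 1

    rows: list[FeatureStats] = []
    for j, fid in enumerate(fm.feature_ids):
        coverage = float(has_pos[:, j].mean()) if len(pos) else 0.0
        bg_coverage = float(has_neg[:, j].mean()) if len(neg) else 0.0
        if bg_coverage == 0:
            fold = MISSING
            mcd = MISSING
        else:
            fold = coverage / bg_coverage
            containing_pos = pos[has_pos[:, j], j]
            containing_neg = neg[has_neg[:, j], j]
            mean_pos = float(containing_pos.mean()) if containing_pos.size else 0.0
            mcd = mean_pos - float(containing_neg.mean())
        rows.append(
            FeatureStats(
                feature_id=int(fid),
                raw_p=float(raw_p[j]),
                corrected_p=float(corr_p[j]),
                epitope_coverage=coverage,
                fold_enrichment=fold,
                mean_count_difference=mcd,
            )
        )
    rows.sort(key=lambda r: (r.corrected_p, r.feature_id))
    return rows


@dataclass(frozen=True)
class FeatureReportRow:
    stats: FeatureStats
    example_mol_id: str
    substructure: SubstructureDescription


def top_features_report(
    stats: list[FeatureStats],
    max_features: int,
    mols: MoleculeSet | Sequence[Molecule],
    fm: FeatureMatrix,
    labels: Sequence[bool] | None = None,
) -> list[FeatureReportRow]:
    """Top ``max_features`` rows joined with a resolved substructure fragment.

    The example molecule for each feature is the feature-containing positive
    with the lowest mol_id (falling back to any containing molecule when no
    positive contains it).
    """
    molecules = list(mols)
    by_id = {m.mol_id: m for m in molecules}
    y = np.asarray(labels, dtype=bool) if labels is not None else np.zeros(fm.n_molecules, bool)

    rows: list[FeatureReportRow] = []
    for st in stats[:max_features]:
        col = fm.column(st.feature_id)
        containing = [(fm.mol_ids[i], bool(y[i])) for i in np.flatnonzero(col >= 1)]
        positives = sorted(mid for mid, is_pos in containing if is_pos)
        candidates = positives or sorted(mid for mid, _ in containing)
        example_id = candidates[0]
        sub = feature_substructure(by_id[example_id], st.feature_id, fm.params)
        rows.append(FeatureReportRow(st, example_id, sub))
    return rows


def render_value(v: float | None, fmt: str = "{:.2f}") -> str:
    """Render a statistic, using '-' for MISSING."""
    return "-" if v is MISSING else fmt.format(v)
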