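"""Tumor/normal cohort screening with tumor-purity calibration.

Bulk tumor expression is a mixture of tumor-intrinsic signal and
stromal/immune admixture.  Purity (the malignant-cell fraction) is either
supplied per sample or estimated from stromal/immune marker enrichment:
single-sample rank running-sum scores are combined and rank-calibrated to
a purity range across the cohort (higher admixture score means lower
purity).  Observed tumor profiles are then linearly de-mixed,

    adjusted = (observed - (1 - purity) * normal_reference) / purity,

before the per-miRNA tumor-vs-normal fold-regulation and unpaired t-test
screen is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .foldreg import from_ratio
from .io import ExpressionMatrix, geometric_mean

MIN_GENE_SET_OVERLAP = 10
PURITY_RANGE = (0.05, 1.0)


@dataclass(frozen=True)
class PuritySignatures:
    """Stromal and immune marker gene sets used for admixture scoring."""

    stromal_genes: frozenset[str]
    immune_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.stromal_genes or not self.immune_genes:
            raise ValueError("stromal and immune signatures must be non-empty")


def ssgsea_enrichment(sample_expression: pd.Series, gene_set: Iterable[str]) -> float:
    """Single-sample rank running-sum enrichment of a gene set.

    Genes are walked in decreasing expression order; the running sum steps
    up by 1/|hits| at set members and down by 1/|misses| elsewhere, and the
    score is the mean running-sum level (positive when the set concentrates
    at the top of the ranking).  Only ranks enter the statistic, so any
    monotone transform of the expression values leaves the score unchanged.
    """
    genes = set(gene_set)
    in_set = sample_expression.index.isin(genes)
    n_hit = int(in_set.sum())
    if n_hit < MIN_GENE_SET_OVERLAP:
        raise ValueError(
            f"gene set overlaps only {n_hit} of the sample's features "
            f"(need >= {MIN_GENE_SET_OVERLAP})"
        )
    n_miss = len(sample_expression) - n_hit
    if n_miss == 0:
        return 0.0
    # average ranks break ties deterministically
    order = np.argsort(-stats.rankdata(sample_expression.to_numpy()), kind="stable")
    steps = np.where(in_set[order], 1.0 / n_hit, -1.0 / n_miss)
    return float(np.cumsum(steps).mean())


def combined_admixture_score(
    sample_expression: pd.Series, signatures: PuritySignatures
) -> float:
    """Stromal + immune enrichment; higher means more non-tumor signal."""
    return ssgsea_enrichment(sample_expression, signatures.stromal_genes) + ssgsea_enrichment(
        sample_expression, signatures.immune_genes
    )


def estimate_purity(
    scores: Iterable[float], purity_range: tuple[float, float] = PURITY_RANGE
) -> np.ndarray:
    """Rank-calibrate combined admixture scores to per-sample purity.

    A monotone decreasing map: the sample with the lowest combined score is
    assigned the top of ``purity_range``, the highest the bottom, and ties
    share averaged ranks.  Absolute purity is only identified up to this
    cohort calibration; when ground-truth purity is available it should be
    supplied directly instead.
    """
    arr = np.asarray(list(scores), dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("combined admixture scores must be finite")
    lo, hi = purity_range
    if not (0 < lo < hi <= 1):
        raise ValueError("purity range must satisfy 0 < low < high <= 1")
    if arr.size == 1:
        return np.array([hi])
    frac = (stats.rankdata(arr) - 1) / (arr.size - 1)
    return hi - frac * (hi - lo)


def purity_adjust(
    observed_tumor: np.ndarray | pd.Series,
    purity: float,
    normal_reference: np.ndarray | pd.Series,
) -> np.ndarray | pd.Series:
    """Linearly de-mix an observed tumor profile at a known purity.

    Exact inverse of observed = purity * tumor + (1 - purity) * normal;
    the result is floored at 0 (intensities cannot be negative).
    """
    if not purity > 0:
        raise ValueError(f"purity must be positive, got {purity}")
    if purity > 1:
        raise ValueError(f"purity cannot exceed 1, got {purity}")
    adjusted = (observed_tumor - (1.0 - purity) * normal_reference) / purity
    return np.maximum(adjusted, 0)


def unpaired_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    variant: str = "welch",
    log2: bool = True,
    floor: float | None = None,
) -> float:
    """Two-sided unpaired t-test p-value on log2 expression.

    Welch's unequal-variance form is the default (cohorts are typically
    very unbalanced); the pooled-variance Student form is available via
    ``variant="student"``.  Degenerate inputs (zero variance in both
    groups) return p = 1 when the means agree and p = 0 otherwise.
    """
    if variant not in ("welch", "student"):
        raise ValueError(f"variant must be 'welch' or 'student', got {variant!r}")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("groups must contain finite values only")
    if log2:
        if floor is not None:
            a, b = np.maximum(a, floor), np.maximum(b, floor)
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log-scale test requires positive intensities")
        a, b = np.log2(a), np.log2(b)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.pvalue)


@dataclass
class CohortPanel:
    """Per-miRNA tumor/normal differential screen results."""

    table: pd.DataFrame  # tn_fr (signed), p, [q], selected, direction
    fr_threshold: float
    alpha: float
    calibrated: bool
    meta: dict = field(default_factory=dict)

    @property
    def selected(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])

    @property
    def overexpressed(self) -> set[str]:
        mask = self.table["selected"] & (self.table["direction"] == "over")
        return set(self.table.index[mask])

    @property
    def underexpressed(self) -> set[str]:
        mask = self.table["selected"] & (self.table["direction"] == "under")
        return set(self.table.index[mask])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="mirna")


def build_cohort_panel(
    m: ExpressionMatrix,
    fr_threshold: float = 1.2,
    alpha: float = 0.05,
    calibrate_purity: bool = True,
    purity: Mapping[str, float] | pd.Series | None = None,
    variant: str = "welch",
    bh: bool = False,
) -> CohortPanel:
    """Screen a tumor/normal cohort for differential miRNAs.

    Selection keeps miRNAs with average absolute fold-regulation at or
    above ``fr_threshold`` and raw p below ``alpha`` (no multiplicity
    correction by default; Benjamini-Hochberg q-values are reported
    alongside when ``bh`` is set).  When ``calibrate_purity`` is on, tumor
    profiles are de-mixed using per-sample purity taken from ``purity`` or
    the ``purity`` annotation column; with no purity available the screen
    runs uncalibrated.
    """
    tumors = m.samples_where(tissue="tumor")
    normals = m.samples_where(tissue="normal")
    for tissue, group in (("tumor", tumors), ("normal", normals)):
        if len(group) < 2:
            raise ValueError(f"need at least two {tissue} samples, found {len(group)}")

    vals = m.values.astype(float)
    floor = 1e-6 * np.median(vals.to_numpy()[vals.to_numpy() > 0])
    vals = vals.clip(lower=floor)
    normal_vals = vals[normals]
    normal_reference = pd.Series(
        geometric_mean(normal_vals.to_numpy(), axis=1), index=m.features
    )

    purities: pd.Series | None = None
    if calibrate_purity:
        if purity is not None:
            purities = pd.Series(dict(purity) if isinstance(purity, Mapping) else purity)
        elif "purity" in m.annotations:
            purities = m.annotations.loc[tumors, "purity"].dropna()
    calibrated = purities is not None

    tumor_vals = vals[tumors].copy()
    if calibrated:
        missing = [s for s in tumors if s not in purities.index]
        if missing:
            raise ValueError(f"tumor samples without purity: {missing}")
        for s in tumors:
            tumor_vals[s] = np.maximum(
                purity_adjust(tumor_vals[s], float(purities[s]), normal_reference),
                floor,
            )

    tumor_gm = geometric_mean(tumor_vals.to_numpy(), axis=1)
    ratio = tumor_gm / normal_reference.to_numpy()
    tn_fr = np.array([from_ratio(r, "signed").value for r in ratio])
    pvals = np.array(
        [
            unpaired_t(tumor_vals.iloc[i].to_numpy(), normal_vals.iloc[i].to_numpy(), variant)
            for i in range(len(m.features))
        ]
    )

    table = pd.DataFrame({"tn_fr": tn_fr, "p": pvals}, index=m.features)
    if bh:
        table["q"] = multipletests(pvals, method="fdr_bh")[1]
    table["selected"] = (np.abs(tn_fr) >= fr_threshold) & (pvals < alpha)
    table["direction"] = np.where(tn_fr > 0, "over", "under")
    table.loc[~table["selected"], "direction"] = "none"
    return CohortPanel(table, fr_threshold, alpha, calibrated)
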