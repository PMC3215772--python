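"""Correlation, family-binning and distribution statistics.

Reproduces the isochore-level analyses: Pearson correlations between GC,
gene density and expression; per-family average genic expression with
significance tests; and the family distributions of expressed and
non-detected genes.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q

from .expression import (
    STATUS_EXPRESSED,
    STATUS_NON_EXPRESSED,
)
from .genome import FAMILY_ORDER, Isochore

logger = logging.getLogger(__name__)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation after dropping NaN pairs.

    Returns NaN (with a warning) when fewer than 2 complete pairs remain or
    either series has zero variance; fewer than 3 pairs also warns, since a
    two-point correlation is degenerate (always +/-1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        logger.warning("pearson_correlation: fewer than 3 complete pairs")
        if x.size < 2:
            return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pearson_correlation: zero variance in a series")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_gc_expression(
    expr: pd.DataFrame, tissue: str, mode: str = "E_L"
) -> float:
    """Pearson r between isochore GC and expression level for one tissue.

    ``mode`` selects the length-normalized ("E_L") or density-normalized
    ("E_D") level; for E_D only isochores containing at least one CDS carry
    a defined value, so they alone enter the correlation.
    """
    if mode not in ("E_L", "E_D"):
        raise ValueError(f"mode must be 'E_L' or 'E_D', got {mode!r}")
    col = f"{mode}_{tissue}"
    if col not in expr.columns:
        raise ValueError(f"no expression column {col!r}; was {tissue!r} computed?")
    return pearson_correlation(expr["GC"], expr[col])


def correlate_density(
    expr: pd.DataFrame, against: str = "GC", tissue: str | None = None
) -> float:
    """Pearson r of gene density against GC, or against E_L of a tissue."""
    if against == "GC":
        return pearson_correlation(expr["GeneDensity"], expr["GC"])
    if against == "E_L":
        if tissue is None:
            raise ValueError("tissue required when correlating density with E_L")
        return pearson_correlation(expr["GeneDensity"], expr[f"E_L_{tissue}"])
    raise ValueError(f"against must be 'GC' or 'E_L', got {against!r}")


def family_mean_genic_expression(gene_expr: pd.DataFrame, tissue: str) -> pd.Series:
    """Mean defined E_CDS per isochore family for one tissue.

    Genes are binned by their host isochore's family; families with no gene
    carrying a defined expression value report NaN.
    """
    col = f"E_CDS_{tissue}"
    values = gene_expr[[col, "family"]].dropna()
    means = values.groupby("family")[col].mean()
    return means.reindex(FAMILY_ORDER)


def cochran_q_test(binary: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Cochran's Q on a subjects x groups binary (0/1) matrix.

    Tests whether the proportion of successes (here: expressed genes)
    differs between the matched groups.  Returns (Q, p); rows that are
    all-0 or all-1 carry no information and Q = 0, p = 1 when every column
    is identical.
    """
    arr = np.asarray(binary, dtype=int)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 groups")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("Cochran's Q requires a binary matrix")
    col_totals = arr.sum(axis=0)
    if np.ptp(col_totals) == 0 and (arr == arr[:, [0]]).all():
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = cochrans_q(arr, return_object=True)
    return float(res.statistic), float(res.pvalue)


def family_significance_test(
    gene_expr: pd.DataFrame,
    groups: Sequence[str],
    grouping: str = "families",
    tissue: str | None = None,
    family: str | None = None,
    method: str = "cochran",
    threshold_col: str | None = None,
) -> tuple[float, float]:
    """Test whether genic expression differs between families or tissues.

    ``grouping='families'`` compares the named isochore families within one
    tissue; ``grouping='tissues'`` compares the named tissues within one
    family.  The default method is Cochran's Q on the expressed/non-expressed
    binary indicator (genes x groups; for family comparisons the matched
    matrix is built by truncating families to their common gene count in
    family order).  ``method='mannwhitney'`` instead compares the defined
    E_CDS values of two groups with a Mann-Whitney U test.

    Returns (statistic, p).  Degenerate inputs (fewer than 2 groups, or
    all-constant data) return (NaN, NaN) with a warning.
    """
    if len(groups) < 2:
        logger.warning("family_significance_test: fewer than 2 groups")
        return float("nan"), float("nan")
    if grouping == "families":
        if tissue is None:
            raise ValueError("tissue required for a between-family comparison")
        sub = gene_expr[gene_expr["family"].isin(groups)]
        if method == "cochran":
            cols = []
            for fam in groups:
                ind = (
                    sub.loc[sub["family"] == fam, f"status_{tissue}"]
                    == STATUS_EXPRESSED
                ).astype(int)
                cols.append(ind.to_numpy())
            n = min(len(c) for c in cols)
            if n == 0:
                logger.warning("family_significance_test: empty family")
                return float("nan"), float("nan")
            matrix = np.column_stack([c[:n] for c in cols])
            return cochran_q_test(matrix)
        samples = [
            sub.loc[sub["family"] == fam, f"E_CDS_{tissue}"].dropna().to_numpy()
            for fam in groups
        ]
    elif grouping == "tissues":
        if family is None:
            raise ValueError("family required for a between-tissue comparison")
        sub = gene_expr[gene_expr["family"] == family]
        if method == "cochran":
            matrix = np.column_stack(
                [
                    (sub[f"status_{t}"] == STATUS_EXPRESSED).astype(int).to_numpy()
                    for t in groups
                ]
            )
            if matrix.shape[0] == 0:
                logger.warning("family_significance_test: empty family")
                return float("nan"), float("nan")
            return cochran_q_test(matrix)
        samples = [sub[f"E_CDS_{t}"].dropna().to_numpy() for t in groups]
    else:
        raise ValueError(f"grouping must be 'families' or 'tissues', got {grouping!r}")
    if method != "mannwhitney":
        raise ValueError(f"method must be 'cochran' or 'mannwhitney', got {method!r}")
    if len(samples) != 2:
        raise ValueError("Mann-Whitney mode compares exactly 2 groups")
    a, b = samples
    if a.size == 0 or b.size == 0 or (np.ptp(np.concatenate([a, b])) == 0):
        logger.warning("family_significance_test: degenerate samples")
        return float("nan"), float("nan")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def never_expressed_mask(gene_expr: pd.DataFrame, tissues: Sequence[str]) -> pd.Series:
    """Genes with zero aligned reads in every tissue."""
    mask = pd.Series(True, index=gene_expr.index)
    for t in tissues:
        mask &= gene_expr[f"status_{t}"] == STATUS_NON_EXPRESSED
    return mask


def non_detected_in_one_tissue_mask(
    gene_expr: pd.DataFrame, tissue: str, tissues: Sequence[str]
) -> pd.Series:
    """Genes non-expressed in exactly the given tissue and in no other."""
    mask = gene_expr[f"status_{tissue}"] == STATUS_NON_EXPRESSED
    for t in tissues:
        if t != tissue:
            mask &= gene_expr[f"status_{t}"] != STATUS_NON_EXPRESSED
    return mask


def expressed_mask(gene_expr: pd.DataFrame, tissue: str) -> pd.Series:
    """Genes expressed (count at or above threshold) in the given tissue."""
    return gene_expr[f"status_{tissue}"] == STATUS_EXPRESSED


def distribution_across_families(
    gene_subset: pd.DataFrame | pd.Series,
    families: Sequence[str] = FAMILY_ORDER,
) -> pd.Series:
    """Percentage of a gene subset falling in each isochore family.

    Accepts the subset rows of a gene expression table (uses its ``family``
    column) or a bare Series of family labels.  Sums to 100 over families;
    an empty subset yields all zeros with a warning.
    """
    labels = (
        gene_subset["family"] if isinstance(gene_subset, pd.DataFrame) else gene_subset
    )
    labels = labels.dropna()
    if labels.empty:
        logger.warning("distribution_across_families: empty subset")
        return pd.Series(0.0, index=list(families))
    counts = labels.value_counts().reindex(families, fill_value=0)
    return 100.0 * counts / counts.sum()


def fraction_isochores_without_cds(isochores: Sequence[Isochore]) -> pd.Series:
    """Per family, the percentage of isochores containing no CDS at all.

    Families with no isochores report NaN.
    """
    rows = pd.DataFrame(
        {
            "family": [iso.family for iso in isochores],
            "empty": [iso.gene_count == 0 for iso in isochores],
        }
    )
    grouped = rows.groupby("family")["empty"]
    pct = 100.0 * grouped.mean()
    return pct.reindex(FAMILY_ORDER)


def correlation_summary(expr: pd.DataFrame, tissues: Sequence[str]) -> pd.DataFrame:
    """All headline correlations in one table: GC vs E_L and E_D per tissue,
    density vs GC, and density vs E_L per tissue."""
    rows = []
    n_el = int(expr[[f"E_L_{t}" for t in tissues]].notna().any(axis=1).sum())
    n_ed = int((expr["CDS_count"] > 0).sum())
    for t in tissues:
        rows.append(("GC~E_L", t, correlate_gc_expression(expr, t, "E_L"), n_el))
        rows.append(("GC~E_D", t, correlate_gc_expression(expr, t, "E_D"), n_ed))
        rows.append(
            ("GeneDensity~E_L", t, correlate_density(expr, "E_L", t), n_el)
        )
    rows.append(("GeneDensity~GC", "-", correlate_density(expr, "GC"), len(expr)))
    return pd.DataFrame(rows, columns=["pair", "tissue", "r", "n"])
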