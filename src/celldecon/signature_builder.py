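"""Signature-matrix construction.

The signature matrix S holds, for t cell-type-discriminating genes and r
cell types, the mean expression of each gene over the replicates of each
type.  Genes are chosen in four stages:

1. black-list filtering — genes active in non-hematopoietic normal tissues
   (enrichment score > 0 in more than 5% of tissues) or in cancer cell lines
   (log2 expression > 7 in any line) are removed up front, before any
   ranking, so they can never enter the candidate lists;
2. pairwise differential expression — for every unordered pair of cell
   types, a two-sided unequal-variance (Welch) t-test per gene, with
   Benjamini–Hochberg q-values computed within that pair's family and a
   significance gate of q < 0.3;
3. top-G union lists — each pair contributes its G significant genes of
   largest absolute log2 fold change; the union over pairs (deduplicated,
   sorted by gene id) is the candidate list for that G;
4. condition-number selection — for G from 5 to 100 the candidate signature
   matrix is built and its 2-norm condition number kappa = sigma_max /
   sigma_min recorded; the G minimizing kappa (ties: smallest G) defines the
   final signature.  A low kappa means the linear system M = S F that the
   deconvolution solves is well conditioned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, PhenotypeAnnotation, SignatureMatrix
from .preprocess import quantile_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "BlackList",
    "PairwiseDEGTable",
    "GSelectionTrace",
    "normal_tissue_blacklist",
    "cancer_blacklist",
    "apply_blacklists",
    "welch_t_test",
    "qvalues",
    "pairwise_deg",
    "top_g_union",
    "build_signature",
    "class_means",
    "condition_number",
    "select_g",
    "construct_signature",
]

FC_PSEUDOCOUNT = 1.0  # added to linear-scale class means before the log2 ratio


@dataclass(frozen=True)
class BlackList:
    """Genes excluded from signature candidacy, tagged by provenance."""

    gene_ids: frozenset[str]
    source: str  # normal_tissue | cancer | user

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class PairwiseDEGTable:
    """Significant genes per class pair, ranked by |log2 fold change|.

    ``table`` columns: class_a, class_b, gene, t_statistic, p_value,
    q_value, log2_fold_change, rank (1 = largest |log2 fold change| within
    its pair).
    """

    table: pd.DataFrame
    q_cutoff: float = 0.3

    @property
    def pairs(self) -> list[tuple[str, str]]:
        seen = self.table[["class_a", "class_b"]].drop_duplicates()
        return list(map(tuple, seen.to_numpy()))

    def top_genes(self, class_a: str, class_b: str, g: int) -> list[str]:
        mask = (self.table["class_a"] == class_a) & (self.table["class_b"] == class_b)
        sub = self.table[mask]
        return sub.loc[sub["rank"] <= g, "gene"].tolist()


@dataclass
class GSelectionTrace:
    """Condition number versus union-list size G, plus the chosen G."""

    trace: pd.DataFrame  # columns: G, union_size, condition_number
    chosen_g: int
    chosen_condition_number: float
    chosen_genes: list[str] = field(default_factory=list)


def normal_tissue_blacklist(
    es_table: pd.DataFrame,
    es_threshold: float = 0.0,
    tissue_fraction: float = 0.05,
) -> BlackList:
    """Genes enriched (ES > ``es_threshold``) in strictly more than
    ``tissue_fraction`` of the observed tissues; the ES table (genes x
    tissues) is consumed as input, not computed here."""
    if es_table.shape[0] == 0 or es_table.shape[1] == 0:
        return BlackList(frozenset(), "normal_tissue")
    values = es_table.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("non-finite enrichment scores")
    frac = (values > es_threshold).mean(axis=1)
    genes = es_table.index[frac > tissue_fraction]
    return BlackList(frozenset(map(str, genes)), "normal_tissue")


def cancer_blacklist(ccle_table: pd.DataFrame, expr_threshold: float = 7.0) -> BlackList:
    """Genes whose log2 expression exceeds ``expr_threshold`` in at least
    one cancer cell line (strict inequality)."""
    if ccle_table.shape[0] == 0 or ccle_table.shape[1] == 0:
        return BlackList(frozenset(), "cancer")
    values = ccle_table.to_numpy()
    if not np.isfinite(values).all():
        raise ValueError("non-finite expression values")
    genes = ccle_table.index[(values > expr_threshold).any(axis=1)]
    return BlackList(frozenset(map(str, genes)), "cancer")


def apply_blacklists(matrix: ExpressionMatrix, *lists: BlackList) -> ExpressionMatrix:
    """Drop every black-listed gene row; counts logged per source."""
    banned: set[str] = set()
    for blacklist in lists:
        hit = blacklist.gene_ids & set(matrix.gene_ids)
        logger.info("black list %s removes %d genes", blacklist.source, len(hit))
        banned |= blacklist.gene_ids
    kept = [g for g in matrix.gene_ids if g not in banned]
    if not kept:
        raise ValueError("all genes black-listed; nothing left to build from")
    if len(kept) == len(matrix.gene_ids):
        return matrix
    return ExpressionMatrix(matrix.data.loc[kept].copy())


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Two-sided unequal-variance t-test.

    Returns (t, p) with Welch–Satterthwaite degrees of freedom.  Two
    constant groups with equal values give (0, 1); two constant groups with
    different values have an undefined statistic and raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both groups constant with different values: t undefined")
    result = stats.ttest_ind(a, b, equal_var=False)
    return float(result.statistic), float(result.pvalue)


def qvalues(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR-adjusted significance values.

    ``bh`` is the Benjamini–Hochberg step-up adjustment (default).
    ``storey`` additionally estimates the null proportion pi0 at
    lambda = 0.5 and scales the BH values by it; pi0 estimation is unstable
    for small families, hence not the default.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float((p > lam).mean()) / (1.0 - lam))
        if pi0 <= 0:
            pi0 = 1.0 / p.size  # all p small: degenerate family
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def _welch_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Welch t and p for two genes x replicates blocks.

    Rows where both groups are constant get t = 0, p = 1 for equal means
    and t = +/-inf, p = 0 otherwise (the mean difference is then exact).
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    degenerate = se2 == 0
    p = np.empty_like(t)
    ok = ~degenerate
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    if degenerate.any():
        equal = degenerate & (ma == mb)
        t[equal] = 0.0
        p[equal] = 1.0
        unequal = degenerate & (ma != mb)
        t[unequal] = np.sign(ma[unequal] - mb[unequal]) * np.inf
        p[unequal] = 0.0
    return t, p


def pairwise_deg(
    matrix: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    q_cutoff: float = 0.3,
    q_method: str = "bh",
    pseudocount: float = FC_PSEUDOCOUNT,
) -> PairwiseDEGTable:
    """Welch test per gene for every unordered class pair.

    q-values are computed within each pair's family of tests.  Genes with
    q < ``q_cutoff`` are retained and ranked within their pair by
    |log2 fold change| of the (pseudocounted) class means, descending; ties
    broken by gene id so ranks are deterministic.
    """
    annotation.validate_against(matrix)
    annotation.require_replicates(2)
    census = annotation.census()
    for label, n in census.items():
        if n == 2:
            logger.warning(
                "class %r has only 2 replicates; differential tests are low-powered",
                label,
            )
    genes = np.array(matrix.gene_ids)
    blocks = {
        label: matrix.data[annotation.samples_of(label)].to_numpy()
        for label in annotation.classes
    }
    records = []
    for class_a, class_b in combinations(annotation.classes, 2):
        a, b = blocks[class_a], blocks[class_b]
        t, p = _welch_vectorized(a, b)
        q = qvalues(p, method=q_method)
        log2_fc = np.log2(
            (a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount)
        )
        keep = q < q_cutoff
        if not keep.any():
            continue
        sub = pd.DataFrame(
            {
                "class_a": class_a,
                "class_b": class_b,
                "gene": genes[keep],
                "t_statistic": t[keep],
                "p_value": p[keep],
                "q_value": q[keep],
                "log2_fold_change": log2_fc[keep],
            }
        )
        sub = sub.sort_values(
            by=["log2_fold_change", "gene"],
            key=lambda col: -col.abs() if col.name == "log2_fold_change" else col,
            kind="mergesort",
        )
        sub["rank"] = np.arange(1, len(sub) + 1)
        records.append(sub)
    if not records:
        table = pd.DataFrame(
            columns=[
                "class_a", "class_b", "gene", "t_statistic", "p_value",
                "q_value", "log2_fold_change", "rank",
            ]
        )
    else:
        table = pd.concat(records, ignore_index=True)
    return PairwiseDEGTable(table, q_cutoff=q_cutoff)


def top_g_union(deg: PairwiseDEGTable, g: int) -> list[str]:
    """Union (deduplicated, sorted by gene id) of every pair's top-``g``
    genes; pairs with fewer than ``g`` significant genes contribute all."""
    if g < 1:
        raise ValueError("G must be >= 1")
    if deg.table.empty:
        raise ValueError("empty DEG table: no significant genes to select from")
    top = deg.table.loc[deg.table["rank"] <= g, "gene"]
    return sorted(set(top))


def class_means(
    matrix: ExpressionMatrix, annotation: PhenotypeAnnotation
) -> pd.DataFrame:
    """Genes x classes table of mean expression over each class's replicates."""
    annotation.validate_against(matrix)
    return pd.DataFrame(
        {
            label: matrix.data[annotation.samples_of(label)].mean(axis=1)
            for label in annotation.classes
        }
    )


def build_signature(
    matrix: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    gene_list: list[str],
    meta: dict | None = None,
) -> SignatureMatrix:
    """Signature matrix S: per-class mean expression of the listed genes."""
    missing = [g for g in gene_list if g not in matrix.data.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    means = class_means(matrix, annotation).loc[gene_list]
    return SignatureMatrix(means, meta or {})


def condition_number(signature: SignatureMatrix | pd.DataFrame | np.ndarray) -> float:
    """2-norm condition number sigma_max / sigma_min of the signature.

    Rank-deficient matrices return +inf (flagged with a warning): the
    deconvolution system would be singular.
    """
    if isinstance(signature, SignatureMatrix):
        values = signature.values
    elif isinstance(signature, pd.DataFrame):
        values = signature.to_numpy()
    else:
        values = np.asarray(signature, dtype=float)
    sigma = np.linalg.svd(values, compute_uv=False)
    r = min(values.shape)
    if sigma[r - 1] <= sigma[0] * np.finfo(float).eps * max(values.shape):
        warnings.warn("rank-deficient signature matrix: condition number infinite")
        return float("inf")
    return float(sigma[0] / sigma[r - 1])


def select_g(
    deg: PairwiseDEGTable,
    matrix: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    g_min: int = 5,
    g_max: int = 100,
) -> GSelectionTrace:
    """Scan G over [g_min, g_max], recording union-list size and condition
    number; choose the G with the smallest condition number (ties: smallest
    G).  G values whose union list is smaller than the number of classes are
    skipped (the system would be underdetermined)."""
    if deg.table.empty:
        raise ValueError("empty DEG table")
    means = class_means(matrix, annotation)
    r = means.shape[1]
    rows = []
    for g in range(g_min, g_max + 1):
        union = top_g_union(deg, g)
        if len(union) < r:
            logger.info("G=%d yields %d genes < %d classes; skipped", g, len(union), r)
            continue
        kappa = condition_number(means.loc[union])
        rows.append({"G": g, "union_size": len(union), "condition_number": kappa})
    if not rows:
        raise ValueError("no G in range produced enough genes for the class count")
    trace = pd.DataFrame(rows)
    best = int(trace["condition_number"].idxmin())  # idxmin takes the first = smallest G
    chosen_g = int(trace.loc[best, "G"])
    chosen_kappa = float(trace.loc[best, "condition_number"])
    return GSelectionTrace(
        trace=trace,
        chosen_g=chosen_g,
        chosen_condition_number=chosen_kappa,
        chosen_genes=top_g_union(deg, chosen_g),
    )


def construct_signature(
    references: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    blacklists: tuple[BlackList, ...] = (),
    q_cutoff: float = 0.3,
    q_method: str = "bh",
    g_min: int = 5,
    g_max: int = 100,
    normalize: bool = True,
) -> tuple[SignatureMatrix, GSelectionTrace, PairwiseDEGTable]:
    """End-to-end signature construction from replicated references.

    Quantile normalization -> black-list filtering -> pairwise differential
    expression -> condition-number-driven choice of G -> signature matrix of
    per-class means (raw linear-scale means of the normalized data;
    standardization happens later, at deconvolution time).
    """
    annotation.validate_against(references)
    working = quantile_normalize(references) if normalize else references
    working = apply_blacklists(working, *blacklists)
    deg = pairwise_deg(working, annotation, q_cutoff=q_cutoff, q_method=q_method)
    selection = select_g(deg, working, annotation, g_min=g_min, g_max=g_max)
    meta = {
        "chosen_G": selection.chosen_g,
        "condition_number": selection.chosen_condition_number,
        "n_signature_genes": len(selection.chosen_genes),
        "q_cutoff": q_cutoff,
        "q_method": q_method,
        "g_range": [g_min, g_max],
        "blacklists": {bl.source: len(bl) for bl in blacklists},
        "quantile_normalized": normalize,
        "scan": selection.trace.to_dict(orient="list"),
    }
    signature = build_signature(working, annotation, selection.chosen_genes, meta)
    return signature, selection, deg
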