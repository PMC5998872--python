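"""Reference-array quality control.

Reference arrays whose expression disagrees with their phenotype label bias
every downstream differential test, so before building a signature the
replicates are (1) clustered — complete linkage on Euclidean distance
between sample columns — to visualize phenotype/profile agreement, and
(2) screened with a correlation rule: an array is an outlier when strictly
more than ``pair_fraction`` (default 2/3) of its Pearson correlations to the
other arrays of its own class fall below ``r_threshold`` (default 0.85).

Flagged arrays and suggested class merges are reported, never applied
automatically: dropping and merging remain explicit calls so the QC stays
auditable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io_formats import ExpressionMatrix, PhenotypeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "Dendrogram",
    "QCReport",
    "cluster_samples",
    "detect_outliers",
    "drop_samples",
    "merge_classes",
]


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over samples.

    ``merges`` is the scipy linkage matrix: row i merges clusters
    ``merges[i,0]`` and ``merges[i,1]`` at height ``merges[i,2]``.
    """

    labels: list[str]
    merges: np.ndarray

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        """Serialize for external tree viewers; branch lengths are derived
        from merge heights (each child edge spans parent height minus child
        height)."""
        n = len(self.labels)

        def node(i: int) -> tuple[str, float]:
            if i < n:
                return self.labels[i], 0.0
            row = self.merges[i - n]
            height = row[2]
            parts = []
            for child in (int(row[0]), int(row[1])):
                text, child_height = node(child)
                parts.append(f"{text}:{max(height - child_height, 0.0):.6g}")
            return "(" + ",".join(parts) + ")", height

        text, _ = node(2 * n - 2)
        return text + ";"


@dataclass
class QCReport:
    """Outlier evidence per sample plus suggested class merges."""

    dendrogram: Dendrogram
    evidence: pd.DataFrame  # per sample: class, n_pairs, n_low, low_fraction, min_r, median_r, flagged
    outliers: list[str]
    merges_suggested: list[tuple[str, str]] = field(default_factory=list)
    r_threshold: float = 0.85
    pair_fraction: float = 2.0 / 3.0

    def to_dict(self) -> dict:
        return {
            "r_threshold": self.r_threshold,
            "pair_fraction": self.pair_fraction,
            "outliers": self.outliers,
            "merges_suggested": [list(pair) for pair in self.merges_suggested],
            "evidence": self.evidence.reset_index()
            .rename(columns={"index": "sample"})
            .to_dict(orient="records"),
        }


def cluster_samples(matrix: ExpressionMatrix) -> Dendrogram:
    """Agglomerative complete-linkage tree of the sample columns under
    Euclidean distance; deterministic for a given column order."""
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 samples")
    columns = matrix.values.T
    merges = linkage(pdist(columns, metric="euclidean"), method="complete")
    return Dendrogram(labels=matrix.sample_ids, merges=merges)


def detect_outliers(
    matrix: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    r_threshold: float = 0.85,
    pair_fraction: float = 2.0 / 3.0,
    correlation_scale: str = "log2",
) -> QCReport:
    """Correlation screen of every array against its own class.

    A sample is flagged when strictly more than ``pair_fraction`` of its
    within-class pairwise Pearson correlations are below ``r_threshold``.
    Classes of size 1 cannot be screened and are skipped with a warning.

    Correlations are computed on log2 intensities by default
    (``correlation_scale="linear"`` disables the transform): on linear
    scale a handful of very bright genes dominates the correlation, so the
    screen would measure agreement of the brightest genes only.
    """
    if correlation_scale not in ("log2", "linear"):
        raise ValueError(f"unknown correlation scale {correlation_scale!r}")
    annotation.validate_against(matrix)
    dendrogram = cluster_samples(matrix)
    frame = matrix.data
    if correlation_scale == "log2":
        frame = np.log2(frame.clip(lower=0) + 1.0)
    records: list[dict] = []
    outliers: list[str] = []
    for label in annotation.classes:
        members = annotation.samples_of(label)
        if len(members) < 2:
            warnings.warn(f"class {label!r} has a single sample; outlier screen skipped")
            continue
        sub = frame[members].to_numpy()
        corr = np.corrcoef(sub.T)
        for i, sample in enumerate(members):
            peers = np.delete(corr[i], i)
            n_low = int((peers < r_threshold).sum())
            low_fraction = n_low / len(peers)
            flagged = low_fraction > pair_fraction
            records.append(
                {
                    "sample": sample,
                    "class": label,
                    "n_pairs": len(peers),
                    "n_low": n_low,
                    "low_fraction": low_fraction,
                    "min_r": float(peers.min()),
                    "median_r": float(np.median(peers)),
                    "flagged": flagged,
                }
            )
            if flagged:
                outliers.append(sample)
    evidence = pd.DataFrame.from_records(records).set_index("sample") if records else (
        pd.DataFrame(
            columns=["class", "n_pairs", "n_low", "low_fraction", "min_r", "median_r", "flagged"]
        )
    )
    merges = _suggest_merges(dendrogram, annotation)
    return QCReport(
        dendrogram=dendrogram,
        evidence=evidence,
        outliers=outliers,
        merges_suggested=merges,
        r_threshold=r_threshold,
        pair_fraction=pair_fraction,
    )


def _suggest_merges(
    dendrogram: Dendrogram, annotation: PhenotypeAnnotation
) -> list[tuple[str, str]]:
    """Flag class pairs whose arrays interleave in the tree: the smallest
    subtree holding both classes contains nothing else, yet neither class
    forms a pure subtree of its own."""
    labels = dendrogram.labels
    n = len(labels)
    # leaf sets per internal node
    leaf_sets: list[set[int]] = [{i} for i in range(n)]
    for row in dendrogram.merges:
        leaf_sets.append(leaf_sets[int(row[0])] | leaf_sets[int(row[1])])
    class_of = {s: c for s, c in annotation.assignments.items()}
    classes = annotation.classes
    members = {
        c: {i for i, s in enumerate(labels) if class_of.get(s) == c} for c in classes
    }

    def smallest_containing(target: set[int]) -> set[int]:
        best = set(range(n))
        for leaves in leaf_sets:
            if target <= leaves and len(leaves) < len(best):
                best = leaves
        return best

    pure = {c: smallest_containing(members[c]) == members[c] for c in classes}
    suggestions: list[tuple[str, str]] = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            if pure[a] or pure[b] or not members[a] or not members[b]:
                continue
            combined = members[a] | members[b]
            if smallest_containing(combined) == combined:
                suggestions.append((a, b))
    return suggestions


def drop_samples(
    matrix: ExpressionMatrix,
    annotation: PhenotypeAnnotation,
    sample_ids: list[str],
) -> tuple[ExpressionMatrix, PhenotypeAnnotation]:
    """Remove the listed arrays from matrix and annotation; warns when a
    class is left with fewer than 2 replicates."""
    unknown = [s for s in sample_ids if s not in matrix.data.columns]
    if unknown:
        raise KeyError(f"unknown samples: {unknown}")
    if not sample_ids:
        return matrix, annotation
    kept = [s for s in matrix.sample_ids if s not in set(sample_ids)]
    new_matrix = ExpressionMatrix(matrix.data[kept].copy())
    new_assignments = {
        s: c for s, c in annotation.assignments.items() if s not in set(sample_ids)
    }
    new_annotation = PhenotypeAnnotation(new_assignments)
    for label, count in new_annotation.census().items():
        if count < 2:
            warnings.warn(f"class {label!r} left with {count} replicate(s) after drop")
    return new_matrix, new_annotation


def merge_classes(
    annotation: PhenotypeAnnotation,
    labels_to_merge: list[str],
    new_label: str,
) -> PhenotypeAnnotation:
    """Reassign all samples of the listed classes to ``new_label``."""
    known = set(annotation.classes)
    unknown = [l for l in labels_to_merge if l not in known]
    if unknown:
        raise KeyError(f"unknown classes: {unknown}")
    merge_set = set(labels_to_merge)
    return PhenotypeAnnotation(
        {
            s: (new_label if c in merge_set else c)
            for s, c in annotation.assignments.items()
        }
    )
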