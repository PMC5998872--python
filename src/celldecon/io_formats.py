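"""Readers, writers and in-memory containers for all on-disk artifacts.

Expression matrices are plain-text tables (TSV or CSV) with a header row of
sample identifiers and gene symbols in the first column.  Phenotype
annotations are two-column tables mapping sample -> cell-type class.
Signature matrices are genes x classes TSV files with a JSON sidecar that
records how they were built.  Proportion tables are CSV, one row per mixture
sample, with fit diagnostics in trailing columns.

All statistics downstream operate on linear-scale intensities.  Files stored
on log2 scale are anti-logged at load time via ``log2=True``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "PhenotypeAnnotation",
    "SignatureMatrix",
    "ProportionTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_list",
    "write_gene_list",
    "read_signature",
    "write_signature",
    "read_proportion_table",
    "write_proportion_table",
]

_DIAGNOSTIC_COLUMNS = ("chosen_nu", "reconstruction_rmse", "reconstruction_correlation")


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with labelled rows and columns.

    ``data`` is a :class:`pandas.DataFrame` whose index holds gene
    identifiers and whose columns hold sample labels.  Values are expression
    intensities on linear scale by convention.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample labels: {dups}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                "non-finite value at gene "
                f"{self.data.index[bad[0]]!r}, sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[gene_ids].copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[sample_ids].copy())


@dataclass
class PhenotypeAnnotation:
    """Mapping from reference sample label to its cell-type class."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("annotation is empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return list(seen)

    def census(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for label in self.assignments.values():
            counts[label] = counts.get(label, 0) + 1
        return counts

    def samples_of(self, label: str) -> list[str]:
        return [s for s, c in self.assignments.items() if c == label]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every annotated sample must exist in the companion matrix."""
        missing = [s for s in self.assignments if s not in matrix.data.columns]
        if missing:
            raise ValueError(f"annotated samples absent from matrix: {missing}")

    def require_replicates(self, minimum: int = 2) -> None:
        """Raise if any class has fewer than ``minimum`` replicates."""
        small = {c: n for c, n in self.census().items() if n < minimum}
        if small:
            raise ValueError(
                f"classes with fewer than {minimum} replicates: {small}"
            )


@dataclass
class SignatureMatrix:
    """Per-class representative expression of t signature genes (t x r).

    ``meta`` carries provenance: the chosen union-list size G, the condition
    number of the matrix, thresholds and black-list sources used.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] < self.data.shape[1]:
            raise ValueError(
                f"signature needs at least as many genes ({self.data.shape[0]}) "
                f"as classes ({self.data.shape[1]})"
            )
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in signature")
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValueError("non-finite value in signature matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def class_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class ProportionTable:
    """Estimated cell-type fractions per mixture sample, plus diagnostics.

    ``fractions`` is samples x classes, each row non-negative and summing to
    one.  ``diagnostics`` (optional) is indexed by the same samples with
    columns chosen_nu, reconstruction_rmse, reconstruction_correlation.
    """

    fractions: pd.DataFrame
    diagnostics: pd.DataFrame | None = None

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        values = self.fractions.to_numpy()
        if (values < 0).any():
            raise ValueError("proportion table contains negative fractions")
        sums = values.sum(axis=1)
        bad = np.abs(sums - 1.0) > self._SUM_TOL
        if bad.any():
            sample = self.fractions.index[int(np.argmax(bad))]
            raise ValueError(
                f"fractions for sample {sample!r} sum to {sums[np.argmax(bad)]!r}, not 1"
            )
        if self.diagnostics is not None and not self.diagnostics.index.equals(
            self.fractions.index
        ):
            raise ValueError("diagnostics index does not match fraction index")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def class_labels(self) -> list[str]:
        return list(self.fractions.columns)


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    log2: bool = False,
) -> ExpressionMatrix:
    """Load a genes x samples table, collapsing duplicate gene rows by mean.

    Parameters
    ----------
    path
        Text table; first row is the sample header, first column gene ids.
    delimiter
        Field separator; by default inferred from the extension
        (``.csv`` -> comma, anything else -> tab).
    log2
        If true the file stores log2 intensities, anti-logged on load so
        downstream statistics always see linear scale.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression matrix not found: {path}")
    sep = _detect_delimiter(path, delimiter)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dups = [label for label in header if label in seen or seen.add(label)]
    if dups:
        raise ValueError(f"duplicate sample labels in {path}: {sorted(set(dups))}")
    raw = pd.read_csv(path, sep=sep, index_col=0)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"empty expression matrix: {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.any().any() or numeric.isna().any().any():
        mask = numeric.isna().to_numpy()
        i, j = np.argwhere(mask)[0]
        raise ValueError(
            f"non-numeric cell in {path}: gene {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r} (value {raw.iat[i, j]!r})"
        )
    raw = numeric
    n_input = raw.shape[0]
    if raw.index.duplicated().any():
        raw = raw.groupby(level=0, sort=False).mean()
        n_collapsed = n_input - raw.shape[0]
        logger.info("collapsed %d duplicate gene rows by mean", n_collapsed)
    if log2:
        raw = np.exp2(raw)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    return ExpressionMatrix(raw)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    matrix.data.to_csv(path, sep=sep, lineterminator="\n", float_format="%.12g")


def read_annotation(path: str | Path, delimiter: str | None = None) -> PhenotypeAnnotation:
    """Load a two-column sample -> class table (no header required)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation not found: {path}")
    sep = _detect_delimiter(path, delimiter)
    table = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"annotation {path} needs two columns (sample, class)")
    # tolerate an optional header line
    if table.iloc[0, 0].lower() in {"sample", "sample_id"}:
        table = table.iloc[1:]
    assignments: dict[str, str] = {}
    for _, (sample, label) in table.iloc[:, :2].iterrows():
        if sample in assignments and assignments[sample] != label:
            raise ValueError(
                f"sample {sample!r} annotated with conflicting classes "
                f"{assignments[sample]!r} and {label!r}"
            )
        assignments[sample] = label
    return PhenotypeAnnotation(assignments)


def write_annotation(annotation: PhenotypeAnnotation, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sample, label in annotation.assignments.items():
            fh.write(f"{sample}\t{label}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and ``#`` comments ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene list not found: {path}")
    genes: list[str] = []
    seen: set[str] = set()
    for line in path.read_text(encoding="utf-8").splitlines():
        gene = line.strip()
        if not gene or gene.startswith("#"):
            continue
        if gene not in seen:
            genes.append(gene)
            seen.add(gene)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in genes:
            fh.write(f"{gene}\n")


def write_signature(signature: SignatureMatrix, path: str | Path) -> None:
    """Write the t x r matrix as TSV plus a ``.json`` provenance sidecar."""
    path = Path(path)
    signature.data.to_csv(path, sep="\t", lineterminator="\n", float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(signature.meta, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_signature(path: str | Path) -> SignatureMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signature matrix not found: {path}")
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
    return SignatureMatrix(data, meta)


def write_proportion_table(table: ProportionTable, path: str | Path) -> None:
    """CSV with class-label header, one row per sample, diagnostics trailing."""
    out = table.fractions.copy()
    if table.diagnostics is not None:
        for col in _DIAGNOSTIC_COLUMNS:
            if col in table.diagnostics.columns:
                out[col] = table.diagnostics[col]
    out.index.name = "sample"
    out.to_csv(Path(path), lineterminator="\n", float_format="%.12g")


def read_proportion_table(path: str | Path) -> ProportionTable:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"proportion table not found: {path}")
    raw = pd.read_csv(path, index_col=0)
    raw.index = raw.index.astype(str)
    diag_cols = [c for c in _DIAGNOSTIC_COLUMNS if c in raw.columns]
    diagnostics = raw[diag_cols] if diag_cols else None
    fractions = raw.drop(columns=diag_cols)
    return ProportionTable(fractions, diagnostics)


def class_map_from_table(path: str | Path) -> dict[str, str]:
    """Two-column fine-class -> benchmark-class mapping table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"class map not found: {path}")
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError("class map needs two columns (fine, benchmark)")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
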