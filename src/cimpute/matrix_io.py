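"""Reading and writing labeled matrices and imputation results.

A *labeled matrix* is a real-valued samples x attributes table in which every
sample carries a class label (the ``CL`` column of the CSV) and any data cell
may be missing.  Missing cells are represented internally as NaN; on disk they
are empty fields or a literal missing marker such as ``NA`` (case-insensitive).
The class label itself is never allowed to be missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, ValidationError

DEFAULT_MISSING_MARKERS = ("", "na")


@dataclass
class LabeledMatrix:
    """Samples x attributes matrix with per-sample class labels.

    Parameters
    ----------
    values
        ``(n, m)`` float array; NaN marks a missing cell.
    class_labels
        Length-``n`` array of class identifiers (any hashable scalar).
    attribute_names
        ``m`` column names, in original file order.
    class_name
        Name of the class-label column used when writing CSV.
    """

    values: np.ndarray
    class_labels: np.ndarray
    attribute_names: list[str] = field(default_factory=list)
    class_name: str = "CL"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValidationError("matrix must have at least one sample and one attribute")
        if len(self.class_labels) != n:
            raise ValidationError("class_labels length does not match number of samples")
        if any(label is None or (isinstance(label, float) and np.isnan(label))
               for label in self.class_labels):
            raise ValidationError("class label missing for at least one sample")
        if not self.attribute_names:
            self.attribute_names = [f"a{j}" for j in range(m)]
        if len(self.attribute_names) != m:
            raise ValidationError("attribute_names length does not match number of columns")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, m)`` array, True exactly where a cell is missing."""
        return np.isnan(self.values)

    @property
    def classes(self) -> list:
        """Distinct class labels in order of first appearance."""
        seen: dict = {}
        for label in self.class_labels:
            seen.setdefault(label, None)
        return list(seen)

    def copy(self) -> "LabeledMatrix":
        return LabeledMatrix(
            self.values.copy(),
            self.class_labels.copy(),
            list(self.attribute_names),
            self.class_name,
        )

    def to_frame(self) -> pd.DataFrame:
        """Class column first, then attribute columns in stored order."""
        df = pd.DataFrame(self.values, columns=self.attribute_names)
        df.insert(0, self.class_name, self.class_labels)
        return df


def _parse_cell(raw: str, markers: tuple[str, ...], row: int, col: str) -> float:
    text = raw.strip()
    if text.lower() in markers:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"non-numeric value {raw!r} at row {row}, column {col!r}"
        ) from None


def read_matrix(
    path: str | Path,
    class_column: str = "CL",
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> LabeledMatrix:
    """Read a labeled matrix from a headered CSV file.

    Empty cells and cells equal to one of ``missing_markers``
    (case-insensitive) become missing.  A missing entry in the class column is
    an error, since every sample must be labeled.
    """
    markers = tuple(m.lower() for m in missing_markers)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if class_column not in df.columns:
        raise ConfigurationError(
            f"class column {class_column!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    labels = []
    for i, raw in enumerate(df[class_column]):
        text = str(raw).strip()
        if text.lower() in markers:
            raise ValidationError(f"missing class label at row {i}")
        labels.append(text)
    attr_names = [c for c in df.columns if c != class_column]
    if not attr_names:
        raise ConfigurationError("matrix has no attribute columns besides the class column")
    values = np.empty((len(df), len(attr_names)), dtype=float)
    for j, col in enumerate(attr_names):
        for i, raw in enumerate(df[col]):
            values[i, j] = _parse_cell(str(raw), markers, i, col)
    return LabeledMatrix(values, np.asarray(labels, dtype=object), attr_names, class_column)


def write_matrix(matrix: LabeledMatrix, path: str | Path, missing_marker: str = "") -> None:
    """Write a labeled matrix as CSV, class column first."""
    df = matrix.to_frame()
    df.to_csv(path, index=False, na_rep=missing_marker)


def write_result(result, path: str | Path) -> None:
    """Write a completed matrix plus a sidecar provenance table.

    The completed matrix goes to ``path``; the per-cell provenance (winning
    itemset, score, estimated level, fallback flag) goes to
    ``path + '.provenance.tsv'``.
    """
    write_matrix(result.completed, path)
    rows = []
    for (i, j), prov in sorted(result.provenance.items()):
        rows.append(
            {
                "row": i,
                "attribute": result.completed.attribute_names[j],
                "index": prov.index,
                "score": prov.score,
                "support": prov.support,
                "confidence": prov.confidence,
                "lift": prov.lift,
                "level": prov.level,
                "value": prov.value_raw,
                "fallback": prov.fallback,
                "n_itemsets": prov.n_itemsets,
                "itemset": "" if prov.itemset is None else " ".join(map(str, prov.itemset)),
            }
        )
    prov_df = pd.DataFrame(
        rows,
        columns=[
            "row", "attribute", "index", "score", "support", "confidence",
            "lift", "level", "value", "fallback", "n_itemsets", "itemset",
        ],
    )
    prov_df.to_csv(str(path) + ".provenance.tsv", sep="\t", index=False)
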