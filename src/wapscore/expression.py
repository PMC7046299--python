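"""Two-group expression dataset container and TSV I/O.

The matrix is assumed already normalized and on a log-like scale; no
missing values are allowed (imputation/removal is upstream of this
package).  Samples carry exactly one label, ``disease`` or ``control``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["DISEASE", "CONTROL", "ExpressionDataset", "read_expression", "align"]

DISEASE = "disease"
CONTROL = "control"
_VALID_LABELS = frozenset({DISEASE, CONTROL})


class ExpressionDataset:
    """Gene-by-sample expression matrix with a disease/control label map.

    Parameters
    ----------
    expression
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  Values must be finite.
    labels
        Mapping or Series sample identifier -> ``"disease"`` | ``"control"``,
        covering exactly the matrix columns.
    metadata
        Optional free-form dictionary (e.g. planted ground truth from the
        synthetic generator); carried through gene/sample subsetting.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        labels: Mapping[str, str] | pd.Series,
        metadata: dict[str, Any] | None = None,
    ):
        labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
        if set(labels.index) != set(expression.columns):
            missing = set(expression.columns) ^ set(labels.index)
            raise ValueError(f"labels and matrix columns disagree on samples: {sorted(missing)[:5]}")
        bad = sorted(set(labels) - _VALID_LABELS)
        if bad:
            raise ValueError(f"labels must be 'disease' or 'control', got {bad}")
        values = expression.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        if expression.index.has_duplicates:
            raise ValueError("duplicate gene identifiers in expression matrix")
        self.expression = expression
        self.labels = labels.reindex(expression.columns)
        self.metadata = dict(metadata or {})
        self._disease = tuple(s for s in expression.columns if self.labels[s] == DISEASE)
        self._control = tuple(s for s in expression.columns if self.labels[s] == CONTROL)

    # -- accessors -------------------------------------------------------

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.expression.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.expression.columns)

    @property
    def n_genes(self) -> int:
        return len(self.expression.index)

    @property
    def n_samples(self) -> int:
        return len(self.expression.columns)

    @property
    def disease_samples(self) -> tuple[str, ...]:
        return self._disease

    @property
    def control_samples(self) -> tuple[str, ...]:
        return self._control

    @property
    def n_disease(self) -> int:
        return len(self._disease)

    @property
    def n_control(self) -> int:
        return len(self._control)

    def group_values(self, label: str) -> np.ndarray:
        """Genes x samples array for one group."""
        cols = self._disease if label == DISEASE else self._control
        return self.expression[list(cols)].to_numpy(dtype=float)

    def __repr__(self) -> str:
        return (
            f"ExpressionDataset(G={self.n_genes}, "
            f"disease={self.n_disease}, control={self.n_control})"
        )

    # -- subsetting ------------------------------------------------------

    def restrict_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        keep = [g for g in self.expression.index if g in set(genes)]
        if not keep:
            raise ValueError("gene restriction leaves no genes")
        return ExpressionDataset(self.expression.loc[keep], self.labels, self.metadata)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(
            self.expression[samples], self.labels[samples], self.metadata
        )

    def with_labels(self, labels: Mapping[str, str] | pd.Series) -> "ExpressionDataset":
        """Same matrix, new label map (used by permutation schemes)."""
        return ExpressionDataset(self.expression, labels, self.metadata)

    # -- I/O -------------------------------------------------------------

    def write_tsv(self, expression_path, labels_path) -> None:
        self.expression.rename_axis("gene").to_csv(expression_path, sep="\t")
        self.labels.rename_axis("sample").rename("group").to_csv(labels_path, sep="\t")


def read_expression(expression_path, labels_path) -> ExpressionDataset:
    """Read an expression TSV (first column gene ID) and a two-column label TSV."""
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    lab = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
    lab.index = lab.index.astype(str)
    return ExpressionDataset(expr, lab)


def align(dataset: ExpressionDataset, network) -> tuple[ExpressionDataset, "object"]:
    """Restrict dataset and network to their common gene universe.

    Returns the gene-restricted dataset and the induced subnetwork, whose
    vertex sets are then identical (the comparability requirement for
    scoring the same universe with both DEG and WAP statistics).
    """
    from .network import restrict_to_common_genes

    common = set(dataset.genes) & set(network.vertices)
    if not common:
        raise ValueError("expression data and network share no genes")
    return dataset.restrict_genes(common), restrict_to_common_genes(network, common)
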