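"""Expression matrices with tumor/normal group labels, and their TSV form.

Values are assumed to be on a log scale and normalised upstream; nothing
here models counts.  The on-disk form is a genes x samples TSV (first
column the gene symbol) plus a two-column sample -> group companion TSV.
Lines starting with ``#`` are provenance comments and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataset", "read_expression_tsv", "write_expression_tsv"]

GROUPS = ("tumor", "normal")


@dataclass
class ExpressionDataset:
    """A genes x samples log-expression matrix with a two-group design.

    Attributes
    ----------
    genes : list of str
        Row labels (unique, uppercase symbols).
    samples : list of str
        Column labels (unique sample ids).
    values : ndarray, shape (n_genes, n_samples)
    group : dict
        sample id -> ``"tumor"`` or ``"normal"``; both groups non-empty.
    """

    genes: list
    samples: list
    values: np.ndarray
    group: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.samples if s not in self.group]
        if missing:
            raise ValueError(f"samples without group label: {missing[:5]}")
        bad = {g for g in self.group.values() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        labels = [self.group[s] for s in self.samples]
        if "tumor" not in labels or "normal" not in labels:
            raise ValueError("both tumor and normal groups must be non-empty")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_mask(self, which: str = "tumor") -> np.ndarray:
        """Boolean mask over columns for one group."""
        if which not in GROUPS:
            raise ValueError(f"unknown group {which!r}")
        return np.array([self.group[s] == which for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


def write_expression_tsv(dataset: ExpressionDataset, matrix_path, groups_path, header_comment: str | None = None) -> None:
    """Write the matrix and the sample->group table as TSV."""
    with open(matrix_path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene\t" + "\t".join(dataset.samples) + "\n")
        for i, g in enumerate(dataset.genes):
            row = "\t".join(format(v, ".6g") for v in dataset.values[i])
            fh.write(f"{g}\t{row}\n")
    with open(groups_path, "wt", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sample\tgroup\n")
        for s in dataset.samples:
            fh.write(f"{s}\t{dataset.group[s]}\n")


def read_expression_tsv(matrix_path, groups_path) -> ExpressionDataset:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    grp = pd.read_csv(groups_path, sep="\t", comment="#")
    group: Mapping[str, str] = dict(zip(grp.iloc[:, 0].astype(str), grp.iloc[:, 1].astype(str)))
    return ExpressionDataset(
        genes=[str(g).upper() for g in mat.index],
        samples=[str(s) for s in mat.columns],
        values=mat.to_numpy(dtype=float),
        group=dict(group),
    )
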