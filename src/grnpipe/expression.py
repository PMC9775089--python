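"""Gene-by-sample expression container with a two-header-row TSV round trip.

The on-disk layout is plain TSV: the first header row names the samples,
the second header row (first cell ``group``) carries one case/control label
per sample, and every following row is one gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Log-scale expression values, genes as rows, with per-sample group labels."""

    genes: list
    samples: list
    values: np.ndarray
    groups: list
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.groups = [str(g) for g in self.groups]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"value matrix shape {self.values.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.groups) != len(self.samples):
            raise ValueError("exactly one group label per sample is required")
        if len(self.genes):
            finite = np.isfinite(self.values).sum(axis=1)
            if (finite < 3).any():
                bad = self.genes[int(np.argmin(finite))]
                raise ValueError(f"gene {bad!r} has fewer than 3 finite values")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.index_of(gene)]

    def to_tsv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("gene\t" + "\t".join(self.samples) + "\n")
            fh.write("group\t" + "\t".join(self.groups) + "\n")
            for gene, row in zip(self.genes, self.values):
                fh.write(gene + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) < 2:
                raise ValueError(f"{path}: expected a sample header row")
            samples = header[1:]
            second = fh.readline().rstrip("\n").split("\t")
            if second and second[0] == "group":
                groups = second[1:]
                first_gene_line = None
            else:
                # tolerate plain genes-by-samples TSV without a group row
                groups = ["na"] * len(samples)
                first_gene_line = second
            genes, rows = [], []
            lines = [first_gene_line] if first_gene_line else []
            lines += [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]
            for parts in lines:
                genes.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(genes, samples, np.asarray(rows, dtype=float), groups)
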