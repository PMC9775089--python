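"""Signed regulon inference for a set of transcription factors.

For each TF the Spearman statistic against every other gene is computed,
an empirical p-value is obtained by permuting the TF's sample labels, and
Benjamini-Hochberg correction is applied within the TF's own family of
tests.  Significant targets are split by the sign of the statistic, which
yields per-TF counts of positively and negatively associated targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .expression import ExpressionMatrix

__all__ = [
    "Regulon",
    "tf_target_association",
    "permutation_null",
    "build_regulons",
    "infer_regulons",
    "write_regulons",
    "write_regulon_summary",
    "load_regulons",
]


@dataclass
class Regulon:
    """One TF's significant targets split by association sign."""

    tf: str
    positive: set
    negative: set
    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    fdr: float = 0.05

    def __post_init__(self) -> None:
        self.positive = set(self.positive)
        self.negative = set(self.negative)
        if self.positive & self.negative:
            raise ValueError(f"regulon {self.tf}: a target cannot be both signs")
        if self.tf in self.positive or self.tf in self.negative:
            raise ValueError(f"regulon {self.tf}: TF cannot be its own target")

    @property
    def targets(self) -> frozenset:
        return frozenset(self.positive | self.negative)

    @property
    def size(self) -> int:
        return len(self.positive) + len(self.negative)


def _rank_z(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-scored average ranks; constant rows become all-zero."""
    r = stats.rankdata(values, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1)
    const = sd == 0
    sd = np.where(const, 1.0, sd)
    return r / sd[:, None], const


def tf_target_association(expr: ExpressionMatrix, tfs: Sequence[str]) -> pd.DataFrame:
    """Spearman statistic for every (tf, gene) pair, excluding tf-self.

    Returns a long table with columns tf, target, stat.
    """
    idx = [expr.index_of(tf) for tf in tfs]  # raises naming the missing TF
    z, const = _rank_z(expr.values)
    if const.any():
        bad = [g for g, c in zip(expr.genes, const) if c]
        warnings.warn("constant rows, association set to 0 for: " + ", ".join(bad), stacklevel=2)
    n = expr.n_samples
    stat = z[idx] @ z.T / n  # len(tfs) x n_genes
    np.clip(stat, -1.0, 1.0, out=stat)
    rows = []
    for k, tf in enumerate(tfs):
        for j, gene in enumerate(expr.genes):
            if j == idx[k]:
                continue
            rows.append((tf, gene, float(stat[k, j])))
    return pd.DataFrame(rows, columns=["tf", "target", "stat"])


def permutation_null(
    expr: ExpressionMatrix, tf: str, n_perm: int, seed: int = 0
) -> pd.Series:
    """Per-gene empirical p-values from permuting the TF's sample labels.

    p = (1 + #{permuted |stat| >= observed |stat|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ConfigError(f"n_perm must be >= 100, got {n_perm}")
    i = expr.index_of(tf)
    z, _ = _rank_z(expr.values)
    n = expr.n_samples
    obs = np.abs(z[i] @ z.T / n)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(z[i]) for _ in range(n_perm)])
    null = np.abs(perms @ z.T / n)  # n_perm x n_genes
    p = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    keep = [j for j in range(expr.n_genes) if j != i]
    return pd.Series(p[keep], index=[expr.genes[j] for j in keep], name=tf)


def build_regulons(
    assoc: pd.DataFrame,
    pvals: Mapping[str, pd.Series],
    fdr: float = 0.05,
) -> tuple[list[Regulon], pd.DataFrame]:
    """BH-correct within each TF and split significant targets by sign.

    Returns the regulons plus a summary table (tf, n_up, n_down, total).
    """
    if not 0.0 < fdr < 1.0:
        raise ConfigError(f"fdr must lie in (0, 1), got {fdr}")
    regulons = []
    summary_rows = []
    for tf, sub in assoc.groupby("tf", sort=False):
        targets = sub["target"].to_numpy()
        statv = sub["stat"].to_numpy()
        p = pvals[tf].reindex(targets).to_numpy()
        if np.isnan(p).any():
            missing = targets[np.isnan(p)][:3]
            raise ValueError(f"missing p-values for tf {tf}: {list(missing)}")
        reject, p_adj = multipletests(p, alpha=fdr, method="fdr_bh")[:2]
        table = pd.DataFrame(
            {
                "tf": tf,
                "target": targets,
                "stat": statv,
                "p": p,
                "p_adj": p_adj,
                "sign": np.sign(statv).astype(int),
                "member": reject.astype(int),
            }
        )
        pos = set(targets[reject & (statv > 0)])
        neg = set(targets[reject & (statv < 0)])
        regulons.append(Regulon(tf, pos, neg, table, fdr))
        summary_rows.append((tf, len(pos), len(neg), len(pos) + len(neg)))
    summary = pd.DataFrame(summary_rows, columns=["tf", "n_up", "n_down", "total"])
    return regulons, summary


def infer_regulons(
    expr: ExpressionMatrix,
    tfs: Sequence[str],
    n_perm: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> tuple[list[Regulon], pd.DataFrame]:
    """Association + permutation null + BH, end to end, deterministically seeded."""
    assoc = tf_target_association(expr, tfs)
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=len(tfs))
    pvals = {
        tf: permutation_null(expr, tf, n_perm=n_perm, seed=int(s))
        for tf, s in zip(tfs, seeds)
    }
    return build_regulons(assoc, pvals, fdr=fdr)


# ---------------------------------------------------------------------- I/O


def write_regulons(regulons: Iterable[Regulon], path) -> None:
    tables = [r.table for r in regulons if len(r.table)]
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["tf", "target", "stat", "p", "p_adj", "sign", "member"]
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regulon_summary(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, sep="\t", index=False)


def load_regulons(path, fdr: float = 0.05) -> list[Regulon]:
    df = pd.read_csv(path, sep="\t")
    regulons = []
    for tf, sub in df.groupby("tf", sort=False):
        member = sub["member"].astype(bool)
        pos = set(sub.loc[member & (sub["sign"] > 0), "target"])
        neg = set(sub.loc[member & (sub["sign"] < 0), "target"])
        regulons.append(Regulon(str(tf), pos, neg, sub.reset_index(drop=True), fdr))
    return regulons
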