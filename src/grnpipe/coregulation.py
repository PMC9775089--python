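"""TF-TF coregulator identification from shared-target overlap.

Two TFs are called coregulators when the overlap of their regulons is larger
than expected for independent draws from the gene universe, measured by the
hypergeometric upper tail and BH-corrected across all TF pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .regulons import Regulon

__all__ = [
    "CoregulationEdge",
    "shared_target_overlap",
    "coregulatory_network",
    "write_coregulation",
    "write_coregulator_lists",
    "write_coregulation_graphml",
]


@dataclass
class CoregulationEdge:
    tf_a: str
    tf_b: str
    shared: int
    expected: float
    p: float
    p_adj: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")


def _target_set(regulon) -> frozenset:
    if isinstance(regulon, Regulon):
        return regulon.targets
    return frozenset(regulon)


def shared_target_overlap(
    regulon_a, regulon_b, universe: Iterable[str], name_a: str = "a", name_b: str = "b"
) -> CoregulationEdge:
    """Hypergeometric upper-tail probability of the observed shared-target count.

    ``expected`` is |a| * |b| / |universe|.  Both regulons must be contained
    in the universe.
    """
    a = _target_set(regulon_a)
    b = _target_set(regulon_b)
    if isinstance(regulon_a, Regulon):
        name_a = regulon_a.tf
    if isinstance(regulon_b, Regulon):
        name_b = regulon_b.tf
    universe = frozenset(str(g) for g in universe)
    if not a <= universe:
        raise ValueError(f"regulon {name_a} is not contained in the universe")
    if not b <= universe:
        raise ValueError(f"regulon {name_b} is not contained in the universe")
    m = len(universe)
    shared = len(a & b)
    p = float(hypergeom.sf(shared - 1, m, len(a), len(b)))
    p = min(max(p, 5e-324), 1.0)
    expected = len(a) * len(b) / m if m else 0.0
    return CoregulationEdge(name_a, name_b, shared, expected, p)


def coregulatory_network(
    regulons: Sequence[Regulon],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Test every TF pair, BH-correct across pairs, keep edges with p_adj <= alpha.

    Returns the full tested-pair table (with a ``significant`` flag) and a
    per-TF dict of coregulator partners.
    """
    universe = frozenset(str(g) for g in universe)
    edges = [
        shared_target_overlap(ra, rb, universe)
        for ra, rb in combinations(regulons, 2)
    ]
    partners: dict = {r.tf: [] for r in regulons}
    if not edges:
        cols = ["tf_a", "tf_b", "shared", "expected", "p", "p_adj", "significant"]
        return pd.DataFrame(columns=cols), partners
    padj = multipletests([e.p for e in edges], alpha=alpha, method="fdr_bh")[1]
    for e, q in zip(edges, padj):
        e.p_adj = float(q)
    df = pd.DataFrame(
        {
            "tf_a": [e.tf_a for e in edges],
            "tf_b": [e.tf_b for e in edges],
            "shared": [e.shared for e in edges],
            "expected": [e.expected for e in edges],
            "p": [e.p for e in edges],
            "p_adj": [e.p_adj for e in edges],
        }
    )
    df["significant"] = (df["p_adj"] <= alpha).astype(int)
    df = df.sort_values(["p_adj", "p", "tf_a", "tf_b"]).reset_index(drop=True)
    for _, row in df[df["significant"] == 1].iterrows():
        partners[row["tf_a"]].append(row["tf_b"])
        partners[row["tf_b"]].append(row["tf_a"])
    partners = {tf: sorted(v) for tf, v in partners.items()}
    return df, partners


def write_coregulation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_coregulator_lists(partners: dict, path) -> None:
    rows = [(tf, ",".join(v)) for tf, v in sorted(partners.items())]
    pd.DataFrame(rows, columns=["tf", "coregulators"]).to_csv(path, sep="\t", index=False)


def write_coregulation_graphml(df: pd.DataFrame, path) -> None:
    g = nx.Graph()
    for _, row in df[df["significant"] == 1].iterrows():
        g.add_edge(row["tf_a"], row["tf_b"], shared=int(row["shared"]), p_adj=float(row["p_adj"]))
    nx.write_graphml(g, Path(path))
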