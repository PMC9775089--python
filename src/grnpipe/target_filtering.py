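"""Database-candidate / DEG filtering cascade for one transcription factor.

Candidates come from external target databases (user-supplied exported gene
lists).  "Functional" targets are candidates differentially expressed in
studies where the TF itself is up-regulated.  "Direct" targets are the
functional genes whose deregulation tracks the TF's presence: by default the
genes that are *not* DE in any study where the TF is not differentially
expressed (mode ``absent``); the alternative reading - keep only genes whose
direction flips without the TF - is available as mode ``flip``.

Gene symbols are case-folded to upper case throughout; no alias resolution
is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigError

__all__ = [
    "DEGTable",
    "TargetCascade",
    "merge_database_targets",
    "functional_targets",
    "direct_targets",
    "run_cascade",
    "load_deg_tables",
    "write_deg_tables",
    "load_gene_list",
    "write_cascade",
]

TF_STATUSES = ("up", "down", "not_de")


def _norm(genes: Iterable[str]) -> set:
    return {str(g).strip().upper() for g in genes if str(g).strip()}


@dataclass
class DEGTable:
    """One study's DEG call set with the study-level TF status."""

    study_id: str
    tf_status: str
    up: set
    down: set

    def __post_init__(self) -> None:
        if self.tf_status not in TF_STATUSES:
            raise ValueError(f"tf_status must be one of {TF_STATUSES}, got {self.tf_status!r}")
        self.up = _norm(self.up)
        self.down = _norm(self.down)
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"study {self.study_id}: genes both up and down: {sorted(overlap)}")

    @property
    def degs(self) -> set:
        return self.up | self.down

    def direction_of(self, gene: str) -> str | None:
        gene = gene.upper()
        if gene in self.up:
            return "up"
        if gene in self.down:
            return "down"
        return None


@dataclass
class TargetCascade:
    candidates: set
    functional: set
    direct: set
    candidate_sources: dict = field(default_factory=dict)
    functional_support: dict = field(default_factory=dict)
    direct_support: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.direct <= self.functional <= self.candidates:
            raise ValueError("cascade must satisfy direct <= functional <= candidates")


def merge_database_targets(lists: Mapping[str, Iterable[str]]) -> tuple[set, dict]:
    """Case-normalised union of named candidate lists with per-gene provenance."""
    if not lists:
        raise ConfigError("at least one candidate list is required")
    union: set = set()
    sources: dict = {}
    for name in sorted(lists):
        for gene in _norm(lists[name]):
            union.add(gene)
            sources.setdefault(gene, []).append(name)
    if not union:
        warnings.warn("candidate union is empty; the cascade will be empty", stacklevel=2)
    return union, sources


def functional_targets(
    candidates: Iterable[str],
    deg_tables: Iterable[DEGTable],
    policy: str = "any",
) -> tuple[set, dict]:
    """Candidates DE (either direction) in the TF-up studies.

    ``policy='any'`` requires support from at least one study, ``'all'`` from
    every study.  Returns the gene set and a per-gene list of supporting
    study ids.
    """
    if policy not in ("any", "all"):
        raise ValueError(f"policy must be 'any' or 'all', got {policy!r}")
    tables = list(deg_tables)
    if not tables:
        raise ConfigError("no TF-up studies supplied")
    for t in tables:
        if t.tf_status != "up":
            raise ConfigError(f"study {t.study_id} has tf_status {t.tf_status!r}, expected 'up'")
    cand = _norm(candidates)
    support = {
        g: sorted({t.study_id for t in tables if g in t.degs}) for g in cand
    }
    if policy == "any":
        hit = {g for g, s in support.items() if s}
    else:
        n_studies = len({t.study_id for t in tables})
        hit = {g for g, s in support.items() if len(s) == n_studies}
    return hit, {g: support[g] for g in hit}


def direct_targets(
    functional: Iterable[str],
    deg_tables: Iterable[DEGTable],
    mode: str = "absent",
    up_tables: Iterable[DEGTable] | None = None,
) -> tuple[set, dict]:
    """Validate functional targets against studies where the TF is not DE.

    mode ``absent`` (default): keep genes not DE in any validation study.
    mode ``flip``: keep genes DE in some validation study with the direction
    opposite to every direction observed for them in the TF-up studies
    (requires ``up_tables``).
    """
    if mode not in ("absent", "flip"):
        raise ValueError(f"mode must be 'absent' or 'flip', got {mode!r}")
    func = _norm(functional)
    tables = list(deg_tables)
    if not tables:
        warnings.warn(
            "no TF-not-DE validation studies supplied; returning functional set unchanged",
            stacklevel=2,
        )
        return set(func), {g: [] for g in func}
    for t in tables:
        if t.tf_status != "not_de":
            raise ConfigError(
                f"study {t.study_id} has tf_status {t.tf_status!r}, expected 'not_de'"
            )
    if mode == "absent":
        kept = {g for g in func if not any(g in t.degs for t in tables)}
        return kept, {g: [] for g in kept}
    if up_tables is None:
        raise ConfigError("mode='flip' requires the TF-up tables to establish directions")
    ups = list(up_tables)
    kept: set = set()
    support: dict = {}
    for g in func:
        up_dirs = {t.direction_of(g) for t in ups} - {None}
        flipped = [
            t.study_id
            for t in tables
            if t.direction_of(g) is not None and t.direction_of(g) not in up_dirs
        ]
        if flipped:
            kept.add(g)
            support[g] = sorted(flipped)
    return kept, support


def run_cascade(
    lists: Mapping[str, Iterable[str]],
    up_tables: Iterable[DEGTable],
    validation_tables: Iterable[DEGTable],
    policy: str = "any",
    mode: str = "absent",
) -> TargetCascade:
    up_tables = list(up_tables)
    candidates, sources = merge_database_targets(lists)
    functional, fsupport = functional_targets(candidates, up_tables, policy=policy)
    direct, dsupport = direct_targets(
        functional, validation_tables, mode=mode, up_tables=up_tables
    )
    return TargetCascade(candidates, functional, direct, sources, fsupport, dsupport)


# ---------------------------------------------------------------------- I/O


def load_gene_list(path) -> list:
    with Path(path).open() as fh:
        return [ln.strip().split("\t")[0] for ln in fh if ln.strip() and not ln.startswith("#")]


def load_deg_tables(path) -> list[DEGTable]:
    """Read a DEG TSV (columns gene, direction, study_id, tf_status) into tables."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "direction", "study_id", "tf_status"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: DEG table needs columns {sorted(required)}")
    tables = []
    for study_id, sub in df.groupby("study_id", sort=True):
        status = sub["tf_status"].iloc[0]
        up = set(sub.loc[sub["direction"] == "up", "gene"])
        down = set(sub.loc[sub["direction"] == "down", "gene"])
        tables.append(DEGTable(str(study_id), str(status), up, down))
    return tables


def write_deg_tables(tables: Iterable[DEGTable], path) -> None:
    rows = []
    for t in tables:
        for g in sorted(t.up):
            rows.append((g, "up", t.study_id, t.tf_status))
        for g in sorted(t.down):
            rows.append((g, "down", t.study_id, t.tf_status))
    pd.DataFrame(rows, columns=["gene", "direction", "study_id", "tf_status"]).to_csv(
        path, sep="\t", index=False
    )


def write_cascade(cascade: TargetCascade, path) -> None:
    rows = []
    for g in sorted(cascade.candidates):
        rows.append(
            {
                "gene": g,
                "is_functional": int(g in cascade.functional),
                "is_direct": int(g in cascade.direct),
                "sources": ",".join(cascade.candidate_sources.get(g, [])),
                "functional_support": ",".join(cascade.functional_support.get(g, [])),
                "direct_support": ",".join(cascade.direct_support.get(g, [])),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
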