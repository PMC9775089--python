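"""Synthetic inputs with recorded ground truth for every pipeline stage.

The expression generator is linear-Gaussian: TF profiles are independent
standard normals and each planted target is ``sign * effect * TF + noise``.
The similarity stage is rank-based, so any monotone link would behave the
same; linear is the simplest to verify.  Repression is encoded as a negative
coefficient so the sign-directed adjacency branch is exercised.  DEG study
tables and promoter sequences with planted motif sites are generated with
the same seeded-determinism contract: identical arguments (including the
seed) give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError
from .expression import ExpressionMatrix
from .motifs import ALPHABET, MotifModel, pwm_from_consensus, write_fasta, write_jaspar_pfm
from .target_filtering import DEGTable, write_deg_tables

__all__ = [
    "SimConfig",
    "GroundTruthNetwork",
    "simulate_expression",
    "simulate_deg_studies",
    "simulate_promoters",
    "effect_for_correlation",
    "write_simulation_bundle",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the planted-network expression simulation."""

    n_genes: int = 70
    n_tfs: int = 20
    targets_per_tf: int = 2
    n_samples_case: int = 50
    n_samples_control: int = 50
    effect_size: float = 2.0
    repression_fraction: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_tfs) < 1 or self.targets_per_tf < 0:
            raise ConfigError("n_genes and n_tfs must be >= 1, targets_per_tf >= 0")
        if self.n_tfs * self.targets_per_tf > self.n_genes - self.n_tfs:
            raise ConfigError(
                "n_tfs * targets_per_tf must be <= n_genes - n_tfs "
                f"({self.n_tfs} * {self.targets_per_tf} > {self.n_genes} - {self.n_tfs})"
            )
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.repression_fraction <= 1.0:
            raise ConfigError(
                f"repression_fraction must lie in [0, 1], got {self.repression_fraction}"
            )
        if self.n_samples_case + self.n_samples_control < 3:
            raise ConfigError("need at least 3 samples in total")

    @property
    def n_samples(self) -> int:
        return self.n_samples_case + self.n_samples_control


@dataclass
class GroundTruthNetwork:
    """Planted regulatory edges and (optionally) planted promoter motif sites."""

    edges: list = field(default_factory=list)  # (tf, target, sign)
    motif_sites: list = field(default_factory=list)  # (seq_id, offset, strand)

    def __post_init__(self) -> None:
        for tf, target, sign in self.edges:
            if sign not in (1, -1):
                raise ValueError(f"edge ({tf}, {target}): sign must be +1 or -1")

    @property
    def tfs(self) -> set:
        return {tf for tf, _, _ in self.edges}

    def undirected_pairs(self) -> set:
        return {frozenset((tf, t)) for tf, t, _ in self.edges}


def effect_for_correlation(rho: float, noise_sd: float = 1.0) -> float:
    """Linear coefficient giving TF-target Pearson correlation ``rho``."""
    if not 0.0 < rho < 1.0:
        raise ConfigError("rho must lie in (0, 1)")
    return rho * noise_sd / np.sqrt(1.0 - rho**2)


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruthNetwork]:
    """Planted linear-Gaussian expression matrix plus its ground-truth network."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_targets = config.n_tfs * config.targets_per_tf
    n_bg = config.n_genes - config.n_tfs - n_targets
    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    tg_names = [f"TG{i + 1:04d}" for i in range(n_targets)]
    bg_names = [f"BG{i + 1:04d}" for i in range(n_bg)]

    tf_vals = rng.standard_normal((config.n_tfs, n))
    signs = np.where(rng.random(n_targets) < config.repression_fraction, -1, 1)
    target_noise = rng.normal(0.0, config.noise_sd, size=(n_targets, n))
    bg_vals = rng.normal(0.0, config.noise_sd, size=(n_bg, n))

    edges = []
    tg_vals = np.empty((n_targets, n))
    for k in range(n_targets):
        tf_idx = k // config.targets_per_tf if config.targets_per_tf else 0
        tg_vals[k] = signs[k] * config.effect_size * tf_vals[tf_idx] + target_noise[k]
        edges.append((tf_names[tf_idx], tg_names[k], int(signs[k])))

    genes = tf_names + tg_names + bg_names
    values = np.vstack([tf_vals, tg_vals, bg_vals]) if genes else np.empty((0, n))
    samples = [f"S{j + 1:04d}" for j in range(n)]
    groups = ["case"] * config.n_samples_case + ["control"] * config.n_samples_control
    expr = ExpressionMatrix(genes, samples, values, groups)
    return expr, GroundTruthNetwork(edges=edges)


def simulate_deg_studies(
    tf: str,
    n_studies_tf_up: int,
    n_studies_tf_absent: int,
    candidate_targets: Iterable[str],
    seed: int = 0,
    direct_fraction: float = 0.3,
    confounded_fraction: float = 0.2,
) -> tuple[list[DEGTable], dict]:
    """Per-study DEG tables with planted functional and direct targets.

    Candidates are partitioned into three groups: "direct" genes are DE in
    every TF-up study and never DE when the TF is absent; "confounded" genes
    are DE in the TF-up studies but also DE (with flipped direction) in the
    TF-absent studies; the rest are never DE.  The TF itself is listed among
    the up-DEGs of every TF-up study.  Returns the tables plus the ground
    truth {'functional': ..., 'direct': ...}.
    """
    if n_studies_tf_up < 0 or n_studies_tf_absent < 0:
        raise ConfigError("study counts must be >= 0")
    if not 0.0 <= direct_fraction + confounded_fraction <= 1.0:
        raise ConfigError("direct_fraction + confounded_fraction must lie in [0, 1]")
    tf = str(tf).upper()
    candidates = sorted({str(g).upper() for g in candidate_targets} - {tf})
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(candidates))
    n_direct = round(direct_fraction * len(candidates))
    n_conf = round(confounded_fraction * len(candidates))
    direct = {candidates[i] for i in order[:n_direct]}
    confounded = {candidates[i] for i in order[n_direct : n_direct + n_conf]}
    direction = {
        g: ("up" if rng.random() < 0.5 else "down") for g in sorted(direct | confounded)
    }

    tables = []
    for k in range(n_studies_tf_up):
        up = {tf} | {g for g in direct | confounded if direction[g] == "up"}
        down = {g for g in direct | confounded if direction[g] == "down"}
        tables.append(DEGTable(f"TFUP{k + 1:02d}", "up", up, down))
    flipped = {"up": "down", "down": "up"}
    for k in range(n_studies_tf_absent):
        up = {g for g in confounded if flipped[direction[g]] == "up"}
        down = {g for g in confounded if flipped[direction[g]] == "down"}
        tables.append(DEGTable(f"NOTF{k + 1:02d}", "not_de", up, down))
    truth = {"functional": direct | confounded, "direct": set(direct)}
    return tables, truth


def simulate_promoters(
    pwm,
    n_seqs: int,
    seq_len: int,
    plant_fraction: float = 1.0,
    gc: float = 0.5,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, int, str]]]:
    """Order-0 background sequences with at most one planted motif site each.

    A fraction ``plant_fraction`` of the sequences receives exactly one site
    sampled from the PWM, at a uniform offset on a uniform strand; the truth
    list records every (sequence id, offset, strand).
    """
    pwm = pwm.pwm if isinstance(pwm, MotifModel) else np.asarray(pwm, dtype=float)
    w = pwm.shape[1]
    if w > seq_len:
        raise ValueError(f"motif width {w} exceeds sequence length {seq_len}")
    if not 0.0 <= plant_fraction <= 1.0:
        raise ConfigError(f"plant_fraction must lie in [0, 1], got {plant_fraction}")
    if not 0.0 < gc < 1.0:
        raise ConfigError(f"gc must lie in (0, 1), got {gc}")
    rng = np.random.default_rng(seed)
    bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base = np.array(list(ALPHABET))
    mat = rng.choice(4, size=(n_seqs, seq_len), p=bg)
    n_plant = round(plant_fraction * n_seqs)
    planted = np.sort(rng.choice(n_seqs, size=n_plant, replace=False))
    truth = []
    ids = [f"PROM{i + 1:04d}" for i in range(n_seqs)]
    for i in planted:
        offset = int(rng.integers(0, seq_len - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = np.array([rng.choice(4, p=pwm[:, k]) for k in range(w)])
        if strand == "-":
            site = (3 - site)[::-1]
        mat[i, offset : offset + w] = site
        truth.append((ids[i], offset, strand))
    records = [(ids[i], "".join(base[mat[i]])) for i in range(n_seqs)]
    return records, truth


def write_simulation_bundle(
    out_dir,
    config: SimConfig | None = None,
    motif_consensus: str = "TGTGGTCA",
    n_deg_up: int = 3,
    n_deg_absent: int = 3,
    n_promoters: int = 30,
    promoter_len: int = 500,
) -> dict:
    """Write a complete synthetic input set (expression, TF list, DEG tables,
    candidate lists, promoters, PWM database, truth JSON) for pipeline runs.

    Returns a dict of the written paths.
    """
    config = config or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, truth_net = simulate_expression(config)
    expr.to_tsv(out / "expression.tsv")
    tfs = sorted(truth_net.tfs) or expr.genes[: config.n_tfs]
    (out / "tf_list.txt").write_text("\n".join(tfs) + "\n")

    focal = tfs[0]
    candidates = sorted({t for _, t, _ in truth_net.edges})
    rng = np.random.default_rng(config.seed + 1)
    half = max(1, len(candidates) // 2)
    lists = {
        "db1": candidates[:half],
        "db2": candidates[half:],
        "db3": list(rng.choice(expr.genes, size=min(10, len(expr.genes)), replace=False)),
    }
    cand_dir = out / "candidates"
    cand_dir.mkdir(exist_ok=True)
    for name, genes in lists.items():
        (cand_dir / f"{name}.tsv").write_text("\n".join(sorted(set(genes))) + "\n")

    tables, deg_truth = simulate_deg_studies(
        focal, n_deg_up, n_deg_absent, candidates, seed=config.seed + 2
    )
    write_deg_tables(tables, out / "deg_tables.tsv")

    pwm = pwm_from_consensus(motif_consensus, strength=0.95)
    planted = MotifModel(name="PLANTED", pwm=pwm)
    records, site_truth = simulate_promoters(
        planted, n_promoters, promoter_len, plant_fraction=1.0, gc=0.5,
        seed=config.seed + 3,
    )
    write_fasta(records, out / "promoters.fa")
    write_jaspar_pfm([planted], out / "pwm_db.pfm")

    truth = {
        "edges": [list(e) for e in truth_net.edges],
        "focal_tf": focal,
        "deg_truth": {k: sorted(v) for k, v in deg_truth.items()},
        "motif_consensus": motif_consensus,
        "motif_sites": [list(s) for s in site_truth],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {
        "expression": str(out / "expression.tsv"),
        "tf_list": str(out / "tf_list.txt"),
        "candidates": str(cand_dir),
        "deg_tables": str(out / "deg_tables.tsv"),
        "promoters": str(out / "promoters.fa"),
        "pwm_db": str(out / "pwm_db.pfm"),
        "truth": str(out / "truth.json"),
        "focal_tf": focal,
    }
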