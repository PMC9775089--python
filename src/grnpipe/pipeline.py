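"""End-to-end orchestration: GRN -> hub TFs -> regulons -> coregulation ->
target cascade -> motifs, driven by one YAML config, with a JSON manifest.

Stages whose inputs are omitted from the config are skipped and recorded as
such.  All randomness flows from the explicit per-run seed, and no output
carries a timestamp, so identical configs reproduce byte-identical files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import coregulation, grn, motifs, regulons, target_filtering
from .errors import ConfigError
from .expression import ExpressionMatrix

__all__ = ["PipelineConfig", "run_pipeline", "select_hub_tfs"]


@dataclass
class PipelineConfig:
    """Paths and per-stage parameters for one pipeline run."""

    expression: str
    tf_list: str | None = None
    deg_tables: str | None = None
    candidates: str | None = None
    promoters: str | None = None
    pwm_db: str | None = None
    focal_tf: str | None = None
    method: str = "spearman"
    grid_size: int = 100
    n_hubs: int = 10
    n_perm: int = 200
    fdr: float = 0.05
    alpha: float = 0.05
    policy: str = "any"
    direct_mode: str = "absent"
    wmin: int = 6
    wmax: int = 20
    n_motifs: int = 2
    motif_null: int = 0
    compare_null: int = 200
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "expression" not in raw:
            raise ConfigError("config must provide 'expression'")
        base = Path(path).parent
        cfg = cls(**raw)
        for name in ("expression", "tf_list", "deg_tables", "candidates", "promoters", "pwm_db"):
            value = getattr(cfg, name)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, name, str((base / value).resolve()))
        return cfg

    def validate(self) -> None:
        for name in ("expression", "tf_list", "deg_tables", "candidates", "promoters", "pwm_db"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"configured {name} path does not exist: {value}")


def select_hub_tfs(degree_table: pd.DataFrame, tf_list: Sequence[str], k: int) -> list:
    """Top-k total-degree genes restricted to the supplied TF list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    tfset = {str(t) for t in tf_list}
    sub = degree_table[degree_table["gene"].isin(tfset)]
    if sub.empty:
        warnings.warn("no supplied TF appears in the network; hub list is empty", stacklevel=2)
        return []
    return list(sub["gene"].head(k))


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all configured stages, writing outputs and a JSON manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def record(stage, status, outputs=None, info=None):
        manifest["stages"][stage] = {
            "status": status,
            "outputs": outputs or {},
            "info": info or {},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    def fail(stage, exc):
        record(stage, "failed", info={"error": str(exc)})
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # ------------------------------------------------------------------ grn
    try:
        expr = ExpressionMatrix.from_tsv(config.expression)
        result = grn.reconstruct_grn(expr, method=config.method, grid_size=config.grid_size)
        paths = {
            "edges": str(out / "grn_edges.tsv"),
            "graphml": str(out / "grn.graphml"),
            "scan": str(out / "threshold_scan.tsv"),
            "degrees": str(out / "degree_table.tsv"),
        }
        grn.write_edge_list(result.adjacency, result.similarity, paths["edges"])
        grn.write_graphml(result.adjacency, result.similarity, paths["graphml"])
        grn.write_scan(result.scan, paths["scan"])
        grn.write_degree_table(result.degrees, paths["degrees"])
        record(
            "grn",
            "completed",
            paths,
            {
                "n_genes": expr.n_genes,
                "n_samples": expr.n_samples,
                "tau_star": result.scan.tau_star,
                "n_edges": result.adjacency.n_edges,
            },
        )
    except Exception as exc:  # noqa: BLE001 - abort with stage name and cause
        fail("grn", exc)

    # ----------------------------------------------------------------- hubs
    hubs: list = []
    if config.tf_list is None:
        record("hubs", "skipped", info={"reason": "no tf_list configured"})
    else:
        try:
            tfs = target_filtering.load_gene_list(config.tf_list)
            hubs = select_hub_tfs(result.degrees, tfs, config.n_hubs)
            path = str(out / "hub_tfs.tsv")
            pd.DataFrame({"tf": hubs}).to_csv(path, sep="\t", index=False)
            record("hubs", "completed", {"hubs": path}, {"n_hubs": len(hubs)})
        except Exception as exc:
            fail("hubs", exc)

    # ------------------------------------------------------------- regulons
    regulon_list: list = []
    if not hubs:
        record("regulons", "skipped", info={"reason": "no hub TFs available"})
    else:
        try:
            regulon_list, summary = regulons.infer_regulons(
                expr, hubs, n_perm=config.n_perm, fdr=config.fdr, seed=config.seed
            )
            paths = {
                "regulons": str(out / "regulons.tsv"),
                "summary": str(out / "regulon_summary.tsv"),
            }
            regulons.write_regulons(regulon_list, paths["regulons"])
            regulons.write_regulon_summary(summary, paths["summary"])
            record(
                "regulons",
                "completed",
                paths,
                {"n_tfs": len(regulon_list), "total_targets": int(summary["total"].sum())},
            )
        except Exception as exc:
            fail("regulons", exc)

    # --------------------------------------------------------- coregulation
    if len(regulon_list) < 2:
        record("coregulation", "skipped", info={"reason": "fewer than 2 regulons"})
    else:
        try:
            df, partners = coregulation.coregulatory_network(
                regulon_list, expr.genes, alpha=config.alpha
            )
            paths = {
                "edges": str(out / "coregulation.tsv"),
                "partners": str(out / "coregulators.tsv"),
                "graphml": str(out / "coregulation.graphml"),
            }
            coregulation.write_coregulation(df, paths["edges"])
            coregulation.write_coregulator_lists(partners, paths["partners"])
            coregulation.write_coregulation_graphml(df, paths["graphml"])
            record(
                "coregulation",
                "completed",
                paths,
                {"n_pairs_tested": len(df), "n_significant": int(df["significant"].sum())},
            )
        except Exception as exc:
            fail("coregulation", exc)

    # -------------------------------------------------------------- targets
    if config.deg_tables is None or config.candidates is None:
        record("targets", "skipped", info={"reason": "deg_tables or candidates not configured"})
    else:
        try:
            cand_dir = Path(config.candidates)
            files = sorted(cand_dir.glob("*.tsv")) + sorted(cand_dir.glob("*.txt"))
            lists = {f.stem: target_filtering.load_gene_list(f) for f in files}
            tables = target_filtering.load_deg_tables(config.deg_tables)
            up = [t for t in tables if t.tf_status == "up"]
            val = [t for t in tables if t.tf_status == "not_de"]
            cascade = target_filtering.run_cascade(
                lists, up, val, policy=config.policy, mode=config.direct_mode
            )
            path = str(out / "target_cascade.tsv")
            target_filtering.write_cascade(cascade, path)
            record(
                "targets",
                "completed",
                {"cascade": path},
                {
                    "n_candidates": len(cascade.candidates),
                    "n_functional": len(cascade.functional),
                    "n_direct": len(cascade.direct),
                },
            )
        except Exception as exc:
            fail("targets", exc)

    # --------------------------------------------------------------- motifs
    if config.promoters is None:
        record("motifs", "skipped", info={"reason": "no promoters configured"})
    else:
        try:
            seqs = motifs.read_fasta(config.promoters)
            found = motifs.discover_motifs(
                seqs,
                wmin=config.wmin,
                wmax=config.wmax,
                n_motifs=config.n_motifs,
                seed=config.seed,
                n_null=config.motif_null,
            )
            paths = {"motifs": str(out / "motifs.meme")}
            motifs.write_meme(found, paths["motifs"])
            info = {"n_motifs": len(found), "widths": [m.width for m in found]}
            if config.pwm_db is not None and found:
                db = motifs.read_jaspar_pfm(config.pwm_db)
                rows = []
                for model in found:
                    for match in motifs.compare_motifs(
                        model, db, n_null=config.compare_null, seed=config.seed
                    ):
                        rows.append(
                            (
                                match.query,
                                match.target,
                                match.offset,
                                match.orientation,
                                match.similarity,
                                match.p,
                                match.p_adj,
                            )
                        )
                paths["matches"] = str(out / "motif_matches.tsv")
                pd.DataFrame(
                    rows,
                    columns=[
                        "query", "target", "offset", "orientation",
                        "similarity", "p", "p_adj",
                    ],
                ).to_csv(paths["matches"], sep="\t", index=False, float_format="%.6g")
            record("motifs", "completed", paths, info)
        except Exception as exc:
            fail("motifs", exc)

    return manifest
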