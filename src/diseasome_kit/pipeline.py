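"""End-to-end orchestration: expression matrices in, disease-comorbidity
analytics out.

One validated config drives the full workflow: read and clean each
disease's matrix -> Z-score audit copy -> per-disease DEG calling ->
cross-disease overlap with the center disease (shared counts, Jaccard
scores, gene-disease networks) -> gene-set enrichment of the common DEGs ->
PPI hub and TF/miRNA regulator analytics.  Every stage materializes its
output to disk (TSV / SIF / GraphML / JSON) so any stage can be re-run or
inspected in isolation, and the final JSON report aggregates every count
and parameter.  Reports are byte-identical across re-runs on identical
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import diseasome, enrichment, netanalysis
from .deg import call_degs
from .io_formats import (
    read_edges_tsv,
    read_expression_tsv,
    read_gmt,
    read_group_spec,
    write_expression_tsv,
    write_network,
)
from .preprocess import zscore_normalize
from .types import DiseaseGeneSet

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised before any computation when the run config does not validate."""


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage and input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class RunConfig:
    center: str
    expression: dict[str, str]          # disease -> expression TSV path
    groups: dict[str, str]              # disease -> group-spec TSV path
    out_dir: str = "diseasome_out"
    fc_threshold: float = 1.0
    alpha: float = 0.01
    p_mode: str = "raw"
    ppi_min_score: int = netanalysis.DEFAULT_PPI_SCORE
    hub_min_degree: int = netanalysis.DEFAULT_HUB_DEGREE
    tf_min_degree: int = netanalysis.DEFAULT_TF_DEGREE
    mirna_min_degree: int = netanalysis.DEFAULT_MIRNA_DEGREE
    enrichment_alpha: float = 0.05
    exclusion_patterns: list[str] = field(default_factory=list)
    gmt_libraries: list[str] = field(default_factory=list)
    benchmark_libraries: list[str] = field(default_factory=list)
    ppi_edges: str | None = None
    tf_edges: str | None = None
    mirna_edges: str | None = None
    skip_enrichment: bool = False
    skip_networks: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def validate(self) -> None:
        if self.center not in self.expression:
            raise ConfigError(
                f"center disease '{self.center}' has no expression matrix"
            )
        if set(self.expression) != set(self.groups):
            raise ConfigError("expression and groups must name the same diseases")
        if len(self.expression) < 2:
            raise ConfigError("need the center plus at least one other disease")
        for t, v in [("fc_threshold", self.fc_threshold), ("alpha", self.alpha),
                     ("enrichment_alpha", self.enrichment_alpha),
                     ("ppi_min_score", self.ppi_min_score)]:
            if v <= 0:
                raise ConfigError(f"threshold {t} must be positive, got {v}")
        if self.p_mode not in ("raw", "adjusted"):
            raise ConfigError(f"unknown p_mode '{self.p_mode}'")
        paths = list(self.expression.values()) + list(self.groups.values())
        paths += self.gmt_libraries + self.benchmark_libraries
        paths += [p for p in (self.ppi_edges, self.tf_edges, self.mirna_edges)
                  if p is not None]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ConfigError(f"input paths do not exist: {missing}")

    def parameters(self) -> dict:
        return {
            "center": self.center,
            "fc_threshold": self.fc_threshold,
            "alpha": self.alpha,
            "p_mode": self.p_mode,
            "ppi_min_score": self.ppi_min_score,
            "hub_min_degree": self.hub_min_degree,
            "tf_min_degree": self.tf_min_degree,
            "mirna_min_degree": self.mirna_min_degree,
            "enrichment_alpha": self.enrichment_alpha,
            "exclusion_patterns": list(self.exclusion_patterns),
            "seed": self.seed,
        }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow; returns the report dict written to
    ``<out_dir>/report.json``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        str(p): _sha256(p)
        for p in sorted(
            set(
                list(config.expression.values())
                + list(config.groups.values())
                + config.gmt_libraries
                + config.benchmark_libraries
                + [q for q in (config.ppi_edges, config.tf_edges,
                               config.mirna_edges) if q]
            )
        )
    }

    report: dict = {
        "parameters": config.parameters(),
        "input_manifest": manifest,
        "stages": {},
    }

    # ---- per-disease DEG calling -----------------------------------------
    gene_sets: list[DiseaseGeneSet] = []
    deg_counts: dict[str, dict[str, int]] = {}
    background: set[str] = set()
    try:
        for disease in sorted(config.expression):
            spec = read_group_spec(config.groups[disease])
            study = read_expression_tsv(
                config.expression[disease], spec, disease_id=disease
            )
            background |= set(study.gene_ids)
            normalized = zscore_normalize(study)
            write_expression_tsv(
                normalized.study, out / f"{disease}_zscored.tsv"
            )
            table, gset = call_degs(
                study,
                fc_threshold=config.fc_threshold,
                alpha=config.alpha,
                p_mode=config.p_mode,
            )
            table.to_csv(out / f"{disease}_degs.tsv", sep="\t", index=False,
                         float_format="%.10g")
            gene_sets.append(gset)
            deg_counts[disease] = {
                "up": len(gset.up),
                "down": len(gset.down),
                "total": len(gset.up) + len(gset.down),
                "degenerate": int((table["call"] == "degenerate").sum()),
            }
            log.info("stage deg: %s -> %d up, %d down",
                     disease, len(gset.up), len(gset.down))
    except (ValueError, OSError) as exc:
        raise StageError("deg", str(exc)) from exc
    report["stages"]["deg"] = deg_counts

    # ---- diseasome --------------------------------------------------------
    try:
        pairs = diseasome.pairwise_table(gene_sets, center=config.center)
        pairs.to_csv(out / "diseasome_pairs.tsv", sep="\t", index=False,
                     float_format="%.10g")
        shared_counts: dict[str, dict[str, int]] = {}
        for _i, row in pairs.iterrows():
            shared_counts.setdefault(row["disease_j"], {})[row["direction"]] = int(
                row["n_shared"]
            )
        common_degs: set[str] = set()
        for direction in ("up", "down"):
            gdn = diseasome.build_gdn(config.center, gene_sets, direction)
            write_network(gdn, out / f"gdn_{direction}.sif", format="sif")
            write_network(gdn, out / f"gdn_{direction}.graphml", format="graphml")
            common_degs |= {
                n for n, d in gdn.nodes(data=True) if d["type"] == "gene"
            }
    except ValueError as exc:
        raise StageError("diseasome", str(exc)) from exc
    report["stages"]["diseasome"] = {
        "shared_per_pair": shared_counts,
        "n_common_degs": len(common_degs),
    }
    (out / "common_degs.txt").write_text(
        "\n".join(sorted(common_degs)) + ("\n" if common_degs else "")
    )

    # ---- enrichment -------------------------------------------------------
    if not config.skip_enrichment and common_degs:
        enr_summary: dict[str, dict] = {}
        try:
            for path, role in (
                [(p, "pathway") for p in config.gmt_libraries]
                + [(p, "benchmark") for p in config.benchmark_libraries]
            ):
                library = read_gmt(path)
                results = enrichment.hypergeom_enrich(
                    common_degs & background, library, background
                )
                curated = enrichment.curate(
                    results,
                    alpha=config.enrichment_alpha,
                    exclusion_patterns=config.exclusion_patterns,
                )
                frame = enrichment.results_to_frame(curated)
                frame.to_csv(
                    out / f"enrichment_{library.library_name}.tsv",
                    sep="\t", index=False, float_format="%.10g",
                )
                enr_summary[library.library_name] = {
                    "role": role,
                    "n_tested": len(results),
                    "n_significant": len(curated),
                    "top_term": curated[0].term_id if curated else None,
                }
        except ValueError as exc:
            raise StageError("enrichment", str(exc)) from exc
        report["stages"]["enrichment"] = enr_summary

    # ---- PPI / regulator networks ----------------------------------------
    if not config.skip_networks:
        net_summary: dict[str, dict] = {}
        try:
            if config.ppi_edges:
                table = read_edges_tsv(config.ppi_edges, "ppi")
                graph = netanalysis.induce_ppi(
                    common_degs, table, min_score=config.ppi_min_score
                )
                degrees = netanalysis.node_degrees(graph)
                hubs = netanalysis.select_hubs(
                    degrees, min_degree=config.hub_min_degree
                )
                degrees.to_csv(out / "ppi_degrees.tsv", sep="\t", index=False)
                hubs.to_csv(out / "ppi_hubs.tsv", sep="\t", index=False)
                write_network(graph, out / "ppi.graphml", format="graphml")
                write_network(graph, out / "ppi.sif", format="sif")
                net_summary["ppi"] = {
                    "n_nodes": graph.number_of_nodes(),
                    "n_edges": graph.number_of_edges(),
                    "n_hubs": len(hubs),
                    "hubs": hubs["node"].tolist(),
                }
            for kind, path, cut in (
                ("tf", config.tf_edges, config.tf_min_degree),
                ("mirna", config.mirna_edges, config.mirna_min_degree),
            ):
                if not path:
                    continue
                table = read_edges_tsv(path, kind)
                graph, rep = netanalysis.regulator_network(
                    common_degs, table, kind, min_degree=cut
                )
                rep.to_csv(out / f"{kind}_regulators.tsv", sep="\t", index=False)
                write_network(graph, out / f"{kind}_network.graphml",
                              format="graphml")
                selected = rep.loc[rep["selected"], "node"].tolist()
                net_summary[kind] = {
                    "n_regulators": len(rep),
                    "n_selected": len(selected),
                    "selected": selected,
                }
        except ValueError as exc:
            raise StageError("netanalysis", str(exc)) from exc
        report["stages"]["networks"] = net_summary

    _consistency_check(report, out)
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report


def _consistency_check(report: dict, out: Path) -> None:
    """Re-derive every aggregated count from the materialized stage outputs;
    any mismatch is a pipeline bug and aborts the run."""
    import pandas as pd

    for disease, counts in report["stages"]["deg"].items():
        table = pd.read_csv(out / f"{disease}_degs.tsv", sep="\t")
        for call in ("up", "down"):
            n = int((table["call"] == call).sum())
            if n != counts[call]:
                raise StageError(
                    "report",
                    f"{disease}: {call} count {counts[call]} != {n} in degs.tsv",
                )
    pairs = pd.read_csv(out / "diseasome_pairs.tsv", sep="\t")
    for _i, row in pairs.iterrows():
        want = report["stages"]["diseasome"]["shared_per_pair"][
            row["disease_j"]
        ][row["direction"]]
        if int(row["n_shared"]) != want:
            raise StageError("report", "pairwise table inconsistent with report")
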