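"""End-to-end orchestration with a declarative config and provenance capture.

A run executes, in order: scheme loading -> hallmark gene sets -> set
comparison reports -> prognostic subgroup reports -> (optional) co-expression
+ enrichment + module functional similarity -> (optional) ontology-version
diff.  Stages whose inputs are missing are skipped with a log entry, never
silently; a failure stops the run naming the stage.  Every run emits a
provenance record (tool version, config hash, input digests, ontology
version labels) because comparisons between mapping studies break down
exactly when this information is omitted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .coexpr import run_coexpression
from .evolution import diff_versions, write_diff_tsv
from .ontology import AnnotationTable, parse_obo
from .prognostic import (
    load_prognostic_tsv,
    pairwise_scheme_similarity,
    prognostic_hallmark_genes,
    subgroup_partition,
)
from .schemes import MappingScheme, build_hallmark_gene_sets, load_scheme
from .semsim import module_similarity_matrix
from .setcomp import (
    consensus_terms,
    exclusive_intersections,
    term_selection_frequency,
    unique_term_fraction,
    write_consensus_tsv,
    write_upset_tsv,
)

logger = logging.getLogger(__name__)

_PATH_KEYS = (
    "ontology", "ontology_new", "annotations", "annotations_new",
    "schemes", "prognostic", "expression", "correspondence",
)
_PARAM_DEFAULTS: dict[str, Any] = {
    "relations": ["is_a", "part_of"],
    "min_schemes": 3,
    "min_size": 5,
    "beta": None,  # None -> automatic soft-threshold pick
    "cut_height": 0.995,
    "min_module_size": 20,
    "alpha": 0.05,
    "weights": {"is_a": 0.8, "part_of": 0.6},
}


@dataclass
class RunConfig:
    """Declarative run description; every parameter is echoed into provenance."""

    paths: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    outdir: str = "hallmap_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known_top = {"paths", "params", "seed", "outdir"}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        paths = dict(raw.get("paths", {}))
        bad = set(paths) - set(_PATH_KEYS)
        if bad:
            raise ValueError(f"unknown path key(s): {sorted(bad)}")
        params = dict(_PARAM_DEFAULTS)
        for key, value in (raw.get("params") or {}).items():
            if key not in _PARAM_DEFAULTS:
                raise ValueError(f"unknown parameter key: {key!r}")
            params[key] = value
        cfg = cls(paths=paths, params=params,
                  seed=int(raw.get("seed", 0)), outdir=str(raw.get("outdir", "hallmap_run")))
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, p in self.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {key!r} does not exist: {p}")
        if not (0 < float(self.params["alpha"]) < 1):
            raise ValueError("alpha must be in (0, 1)")
        if int(self.params["min_size"]) < 1 or int(self.params["min_schemes"]) < 1:
            raise ValueError("min_size and min_schemes must be >= 1")
        for rel, w in dict(self.params["weights"]).items():
            if not (0 < float(w) < 1):
                raise ValueError(f"semantic weight for {rel!r} must be in (0, 1)")

    def digest(self) -> str:
        # outdir is excluded: the same inputs and parameters are the same run
        # wherever its outputs land.
        payload = dataclasses.asdict(self)
        payload.pop("outdir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


def _file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_provenance(config: RunConfig, version_labels: dict[str, str]) -> dict:
    return {
        "tool": "hallmap",
        "tool_version": __version__,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "input_digests": {k: _file_digest(p) for k, p in config.paths.items()},
        "ontology_versions": version_labels,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    relations = set(config.params["relations"])
    stage = "setup"
    try:
        stage = "load ontology"
        graph = parse_obo(config.paths["ontology"]) if "ontology" in config.paths else None
        annotations = None
        if graph is not None and "annotations" in config.paths:
            annotations = AnnotationTable.from_tsv(config.paths["annotations"], graph)

        stage = "load schemes"
        schemes: list[MappingScheme] = []
        if "schemes" in config.paths:
            df = pd.read_csv(config.paths["schemes"], sep="\t", dtype=str)
            for scheme_id, sub in df.groupby("scheme_id"):
                schemes.append(load_scheme(sub, scheme_id=str(scheme_id)))
        else:
            logger.warning("no scheme table configured; scheme stages skipped")

        provenance = build_provenance(
            config,
            {k: parse_obo(config.paths[k]).version_label
             for k in ("ontology", "ontology_new") if k in config.paths} or
            {"ontology": "none"},
        )
        provenance_id = provenance["config_hash"][:12]
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))

        gene_sets = []
        if schemes and graph is not None and annotations is not None:
            stage = "hallmark gene sets"
            for scheme in schemes:
                gs = build_hallmark_gene_sets(scheme, graph, annotations, relations)
                gene_sets.append(gs)
            with open(out / "hallmark_genes.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\nscheme_id\thallmark\tgene_id\n")
                for gs in gene_sets:
                    for hallmark in sorted(gs.per_hallmark):
                        for gene in sorted(gs.per_hallmark[hallmark]):
                            fh.write(f"{gs.scheme_id}\t{hallmark}\t{gene}\n")

        if len(schemes) >= 2:
            stage = "set comparison"
            freq = term_selection_frequency(schemes)
            with open(out / "term_frequency.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\nterm_id\tn_schemes\n")
                for term in sorted(freq.overall):
                    fh.write(f"{term}\t{freq.overall[term]}\n")
            with open(out / "unique_fractions.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\nscheme_id\tunique_pct\n")
                for scheme in schemes:
                    fh.write(f"{scheme.scheme_id}\t{unique_term_fraction(scheme, schemes)}\n")
            per_h, overall, _ = consensus_terms(schemes, int(config.params["min_schemes"]))
            with open(out / "consensus_terms.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\n")
                write_consensus_tsv(per_h, fh, schemes)
            if gene_sets:
                profile = exclusive_intersections({gs.scheme_id: gs.union for gs in gene_sets})
                with open(out / "upset_counts.tsv", "w") as fh:
                    fh.write(f"# provenance: {provenance_id}\n")
                    write_upset_tsv(profile, fh)

        if "prognostic" in config.paths and gene_sets:
            stage = "prognostic subgroups"
            prognostic = load_prognostic_tsv(config.paths["prognostic"])
            tables = []
            for gs in gene_sets:
                per_cancer = prognostic_hallmark_genes(gs.union, prognostic)
                tables.append(subgroup_partition(per_cancer, int(config.params["min_size"]),
                                                 scheme_id=gs.scheme_id))
            if len(tables) >= 2:
                sim = pairwise_scheme_similarity(tables)
                with open(out / "prognostic_jaccard.tsv", "w") as fh:
                    fh.write(f"# provenance: {provenance_id}\n")
                    sim.to_csv(fh, sep="\t", index=False)
        elif "prognostic" not in config.paths:
            logger.info("no prognostic table configured; prognostic stage skipped")

        if "expression" in config.paths and graph is not None and annotations is not None:
            stage = "co-expression"
            expr = pd.read_csv(config.paths["expression"], sep="\t", index_col=0)
            result = run_coexpression(
                expr, graph, annotations,
                beta=config.params["beta"],
                cut_height=float(config.params["cut_height"]),
                min_module_size=int(config.params["min_module_size"]),
                alpha=float(config.params["alpha"]),
                relations=relations,
            )
            with open(out / "modules.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\ngene_id\tmodule\n")
                result.module_labels.to_csv(fh, sep="\t", header=False)
            with open(out / "hubs.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\nmodule\tgene_id\n")
                for module, genes in result.hubs.items():
                    for g in genes:
                        fh.write(f"{module}\t{g}\n")
            with open(out / "enrichment.tsv", "w") as fh:
                fh.write(f"# provenance: {provenance_id}\n"
                         "module\tterm_id\tp_raw\tp_adjusted\tk\tK\tn\tN\n")
                for r in result.enrichment:
                    fh.write(f"{r.module_id}\t{r.term_id}\t{r.p_raw:.6g}\t"
                             f"{r.p_adjusted:.6g}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\n")
            stage = "module similarity"
            alpha = float(config.params["alpha"])
            modules = {}
            for r in result.enrichment:
                if r.p_raw < alpha:
                    modules.setdefault(f"M{r.module_id}", set()).add(r.term_id)
            if modules:
                try:
                    sim = module_similarity_matrix(modules, graph,
                                                   dict(config.params["weights"]))
                    with open(out / "module_similarity.tsv", "w") as fh:
                        fh.write(f"# provenance: {provenance_id}\n")
                        sim.to_csv(fh, sep="\t")
                except ValueError as exc:
                    logger.warning("module similarity skipped: %s", exc)
        elif "expression" not in config.paths:
            logger.info("no expression matrix configured; co-expression stage skipped")

        if "ontology_new" in config.paths and graph is not None and schemes:
            stage = "version diff"
            graph_new = parse_obo(config.paths["ontology_new"])
            if graph_new.version_label == graph.version_label:
                graph_new.version_label = graph.version_label + "+new"
            selected = set.union(*(s.all_terms for s in schemes))
            diff = diff_versions(graph, graph_new, selected, selected & graph_new.active_terms)
            with open(out / "version_diff_nodes.tsv", "w") as nfh, \
                    open(out / "version_diff_edges.tsv", "w") as efh:
                nfh.write(f"# provenance: {provenance_id}\n")
                efh.write(f"# provenance: {provenance_id}\n")
                write_diff_tsv(diff, nfh, efh)
        elif "ontology_new" not in config.paths:
            logger.info("no second ontology configured; version-diff stage skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
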