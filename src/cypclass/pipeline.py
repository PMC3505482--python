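"""Four-step classification pipeline with config, logging and provenance.

Stages: candidate filtering -> similarity graph -> Markov clustering ->
downstream layers (nomenclature, functional annotation, CYPome statistics).
Every output table carries a provenance header (tool version and the
parameters that produced it, no timestamps), so re-running with an identical
config reproduces byte-identical artifacts.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .candidate_filter import DEFAULT_P450_DOMAINS, select_candidates
from .cypome_stats import (
    build_profile,
    conserved_families,
    cypome_fraction,
    powerlaw_slope,
    size_histogram,
    write_histogram_tsv,
)
from .function_annot import (
    CuratedReference,
    annotate_proteins,
    propagate,
    read_category_table,
    write_annotation_tsv,
)
from .io_formats import (
    parse_domain_table,
    parse_hit_table,
    read_fasta,
    write_fasta,
)
from .mcl_core import MclParams, run_mcl
from .nomenclature import (
    assign_family,
    infer_clans,
    read_clan_map,
    read_reference_fasta,
    write_assignments_tsv,
    write_clans_tsv,
)
from .param_sweep import evaluate_clustering
from .simgraph import EdgeFilterParams, build_graph

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("cypclass")

STAGES = ("filter", "graph", "cluster", "annotate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Flat key-value configuration for the full pipeline.

    Required inputs: ``proteins`` (FASTA) and ``hits`` (12-column table).
    Optional inputs switch stages on: ``domains`` (+ ``accept_domains`` /
    ``promote``) enable candidate filtering; ``references`` and ``clan_map``
    enable nomenclature; ``curated_fasta`` + ``curated_categories`` (+
    ``function_hits``) enable functional transfer.
    """

    proteins: Path
    hits: Path
    out_dir: Path
    domains: Optional[Path] = None
    accept_domains: Optional[Path] = None
    promote: Optional[Path] = None
    references: Optional[Path] = None
    clan_map: Optional[Path] = None
    curated_fasta: Optional[Path] = None
    curated_categories: Optional[Path] = None
    function_hits: Optional[Path] = None
    e_max: float = 1e-50
    cov_min: float = 60.0
    inflation: float = 5.0
    prune_threshold: float = 1e-5
    tolerance: float = 1e-8
    max_iter: int = 200
    mega_threshold: int = 100
    function_e_cutoff: float = 1e-100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "proteins", "hits", "out_dir", "domains", "accept_domains", "promote",
            "references", "clan_map", "curated_fasta", "curated_categories",
            "function_hits",
        ):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, Path(v))
        # validate numeric parameters against their module invariants up front
        EdgeFilterParams(e_max=self.e_max, cov_min=self.cov_min)
        MclParams(
            inflation=self.inflation,
            prune_threshold=self.prune_threshold,
            tolerance=self.tolerance,
            max_iter=self.max_iter,
        )
        if self.mega_threshold < 1:
            raise ValueError("mega_threshold must be >= 1")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def provenance(self) -> list[str]:
        return [
            f"cypclass {__version__}",
            f"e_max={self.e_max:g} cov_min={self.cov_min:g} inflation={self.inflation:g}",
            f"prune={self.prune_threshold:g} tol={self.tolerance:g} "
            f"max_iter={self.max_iter} mega_threshold={self.mega_threshold}",
            f"seed={self.seed}",
        ]


def _require(path: Optional[Path], stage: str, what: str) -> Path:
    if path is None:
        raise PipelineError(f"stage {stage!r}: {what} not configured")
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: missing input path {path}")
    return path


def run_pipeline(config: PipelineConfig, resume_from: Optional[str] = None) -> Path:
    """Run the pipeline; returns the output directory.

    ``resume_from`` names a stage (filter/graph/cluster/annotate) to restart
    at, reusing earlier artifacts already present in ``out_dir``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    prov = config.provenance()
    if resume_from is not None and resume_from not in STAGES:
        raise PipelineError(f"unknown stage {resume_from!r}; choose from {STAGES}")
    start = STAGES.index(resume_from) if resume_from else 0

    proteins = read_fasta(_require(config.proteins, "filter", "proteins FASTA"))
    by_id = {p.id: p for p in proteins}

    # --- stage 1: candidate filter -------------------------------------
    candidates_fasta = out / "candidates.fasta"
    if start <= STAGES.index("filter") or not candidates_fasta.exists():
        log.info("stage filter: %d proteins", len(proteins))
        if config.domains is not None:
            domains = parse_domain_table(_require(config.domains, "filter", "domain table"))
            accept = DEFAULT_P450_DOMAINS
            if config.accept_domains is not None:
                accept = frozenset(
                    _read_id_list(_require(config.accept_domains, "filter", "accept list"))
                )
            promote: set[str] = set()
            if config.promote is not None:
                promote = set(_read_id_list(_require(config.promote, "filter", "promote list")))
            cand = select_candidates(proteins, domains, accept, promote)
            accepted = [by_id[i] for i in sorted(cand.accepted_ids)]
            with open(out / "flagged.tsv", "w") as fh:
                fh.write("protein_id\n")
                for pid in sorted(cand.flagged_ids):
                    fh.write(pid + "\n")
        else:
            accepted = proteins  # no domain table: every protein is a candidate
        write_fasta(accepted, candidates_fasta)
    accepted = read_fasta(candidates_fasta)
    lengths = {p.id: len(p) for p in accepted}

    # --- stage 2: similarity graph -------------------------------------
    graph_tsv = out / "graph.tsv"
    hits = parse_hit_table(_require(config.hits, "graph", "hit table"))
    hits = [h for h in hits if h.query_id in lengths and h.subject_id in lengths]
    params = EdgeFilterParams(e_max=config.e_max, cov_min=config.cov_min)
    graph = build_graph(hits, lengths, params)
    if start <= STAGES.index("graph") or not graph_tsv.exists():
        log.info(
            "stage graph: %d nodes, %d edges at E<=%g cov>=%g",
            graph.n_nodes, len(graph.edges), config.e_max, config.cov_min,
        )
        graph.write_edge_list(graph_tsv, header_lines=prov)

    # --- stage 3: Markov clustering ------------------------------------
    clusters_tsv = out / "clusters.tsv"
    mcl_params = MclParams(
        inflation=config.inflation,
        prune_threshold=config.prune_threshold,
        tolerance=config.tolerance,
        max_iter=config.max_iter,
    )
    clustering = run_mcl(graph, mcl_params)
    if start <= STAGES.index("cluster") or not clusters_tsv.exists():
        log.info(
            "stage cluster: %d clusters from %d nodes (inflation %g)",
            clustering.n_clusters, clustering.n_nodes, config.inflation,
        )
        clustering.write_tsv(clusters_tsv, header_lines=prov)

    # --- stage 4: nomenclature, function, stats ------------------------
    labels = clustering.labels()
    family_of: dict[str, str] = {}
    clan_of_family: dict[str, str] = {}
    if config.references is not None:
        refs = read_reference_fasta(_require(config.references, "annotate", "reference FASTA"))
        assignments = [assign_family(by_id[pid], refs) for pid in sorted(labels)]
        write_assignments_tsv(assignments, out / "families.tsv", header_lines=prov)
        family_of = {
            a.protein_id: a.family for a in assignments if a.family != "UNASSIGNED"
        }
        known = {}
        if config.clan_map is not None:
            known = read_clan_map(_require(config.clan_map, "annotate", "clan map"))
        clans = infer_clans(clustering, family_of, known)
        write_clans_tsv(clans, out / "clans.tsv", header_lines=prov)
        clan_of_family = {f: c.clan_name for c in clans for f in c.families}

    if config.curated_fasta is not None:
        curated_records = read_fasta(
            _require(config.curated_fasta, "annotate", "curated FASTA"), "plain"
        )
        categories = read_category_table(
            _require(config.curated_categories, "annotate", "curated categories")
        )
        curated = [
            CuratedReference(record=r, category=categories[r.id])
            for r in curated_records
            if r.id in categories
        ]
        if config.function_hits is not None:
            fn_hits = parse_hit_table(
                _require(config.function_hits, "annotate", "function hit table")
            )
        else:
            from .synth_fixtures import emulate_hits

            fn_hits = emulate_hits(list(accepted) + [c.record for c in curated])
        protein_ann = annotate_proteins(fn_hits, curated, config.function_e_cutoff)
        fam_ann, clan_ann = propagate(protein_ann, family_of, clan_of_family)
        write_annotation_tsv(fam_ann, out / "function_families.tsv", header_lines=prov)
        write_annotation_tsv(clan_ann, out / "function_clans.tsv", header_lines=prov)

    hist = size_histogram(clustering)
    write_histogram_tsv(hist, out / "histogram.tsv")
    summary: dict[str, Any] = {
        "n_proteins": len(proteins),
        "n_candidates": len(accepted),
        "n_clusters": clustering.n_clusters,
        "converged": clustering.converged,
        "cypome_fraction_pct": cypome_fraction(len(accepted), len(proteins)),
    }
    metrics = evaluate_clustering(clustering, mega_threshold=config.mega_threshold)
    summary.update(
        frac_singlet=metrics.frac_singlet,
        frac_mega=metrics.frac_mega,
        objective=metrics.objective,
    )
    if len({s for s in hist}) >= 3:
        slope, _ = powerlaw_slope(hist)
        summary["powerlaw_slope"] = slope
    if family_of:
        species_of = {p.id: p.species for p in accepted}
        taxon_of = {p.species: p.taxon_group for p in accepted}
        profile = build_profile(family_of, species_of, taxon_of)
        profile.counts.to_csv(out / "profile.tsv", sep="\t")
        universal = conserved_families(profile, profile.species)
        with open(out / "conserved.tsv", "w") as fh:
            fh.write("family\n")
            for fam in universal:
                fh.write(fam + "\n")
        summary["n_conserved_families"] = len(universal)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _read_id_list(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
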