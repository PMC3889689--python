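"""Configuration and orchestration of the full direct-target pipeline.

Data flow: scaffold filter -> differential expression -> peak selection and
gene assignment -> DE x bound intersection (direct targets) -> ortholog
collapse -> evidence subnetwork -> cohesive modules -> guilt-by-association.
Each stage is runnable standalone on the intermediate files of the previous
one (that is what the CLI subcommands do); ``run_pipeline`` chains them and
writes a machine- and human-readable report.  The pipeline is a pure
function of (inputs, config): reruns produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import annotation_io as aio
from . import diffexpr, integrate, netmod, peaks as peakmod, synthetic
from .models import CountMatrix, ScaffoldSet, TruthRecord

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "simulate", "run_pipeline",
           "stage_de", "stage_peaks", "stage_integrate", "stage_network"]


@dataclass
class PipelineConfig:
    """Flat key-value configuration; every threshold default matches the
    analysis conventions (twofold / FDR 5% DE, peak FDR 5% or fold 20,
    10 kb assignment window, 10 kb scaffold filter)."""

    # input files
    scaffolds_path: str = "scaffolds.tsv"
    gene_models_path: str = "genes.gff3"
    gene_models_format: str = "gff3"
    counts_path: str = "counts.tsv"
    control_samples: list[str] = field(default_factory=lambda: ["ctrl_1", "ctrl_2"])
    knockdown_samples: list[str] = field(default_factory=lambda: ["kd_1", "kd_2"])
    peaks_path: str = "peaks.narrowPeak"
    peaks_format: str = "narrowpeak"
    peak_fdr_dialect: str = "fraction"
    ortholog_map_path: str = "ortholog_map.tsv"
    network_path: str = "network.tsv"
    gene_sets_path: str = "gene_sets.gmt"
    function_sets_path: str = "function_sets.gmt"
    truth_path: Optional[str] = None

    # thresholds
    fold_threshold: float = 2.0
    de_fdr: float = 0.05
    peak_fdr: float = 0.05
    peak_fold: float = 20.0
    window: int = 10_000
    scaffold_min_length: int = 10_000
    dispersion: Optional[float] = None  # None: estimate from the data

    # network analysis
    evidence_mode: str = "bound_or_de"  # or "direct_targets"
    penalty: float = 2.0
    min_module_size: int = 3
    min_density: float = 0.3
    merge_overlap: float = 0.8
    module_growth_cap: int = 50
    min_known: int = 2

    # synthetic-data generation
    seed: int = 0
    n_scaffolds: int = 150
    n_genes: int = 10_000
    homeolog_fraction: float = 0.5
    de_fraction: float = 0.1
    fold_change_min: float = 4.0
    fold_change_max: float = 8.0
    nb_dispersion: float = 0.1
    min_baseline_mean: float = 0.0
    bound_de_fraction: float = 0.5
    n_noise_peaks: int = 500
    ciliary_fraction_of_targets: float = 0.2
    n_terms: int = 5
    n_planted_modules: int = 4

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "de_fdr", "peak_fdr", "peak_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.evidence_mode not in ("bound_or_de", "direct_targets"):
            raise ValueError("evidence_mode must be 'bound_or_de' or 'direct_targets'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def group_map(self) -> dict[str, str]:
        return {**{s: "control" for s in self.control_samples},
                **{s: "knockdown" for s in self.knockdown_samples}}


@dataclass
class PipelineReport:
    """Stage-by-stage counts, in pipeline order."""

    genes_annotated: int = 0
    genes_on_retained_scaffolds: int = 0
    genes_tested: int = 0
    de_genes: int = 0
    peaks_total: int = 0
    peaks_selected: int = 0
    peaks_assigned: int = 0
    assignments: int = 0
    bound_genes: int = 0
    direct_targets: int = 0
    overlap_p: float = 1.0
    reference_overlap_count: int = 0
    reference_overlap_percent: Optional[int] = None
    reference_overlap_p: float = 1.0
    significant_terms: int = 0
    subnetwork_nodes: int = 0
    subnetwork_edges: int = 0
    module_count: int = 0
    candidate_count: int = 0
    common_dispersion: float = 0.0
    replicate_correlation: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert self.peaks_selected <= self.peaks_total
        assert self.peaks_assigned <= self.peaks_selected
        assert self.de_genes <= self.genes_tested
        assert self.direct_targets <= min(self.de_genes, self.bound_genes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def to_text(self) -> str:
        lines = ["direct-target pipeline report", "-" * 30]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name:32s} {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# synthetic input bundle


def simulate(config: PipelineConfig, outdir) -> TruthRecord:
    """Emit a complete synthetic input bundle plus truth JSON into ``outdir``
    and rewrite the config's input paths to point at it."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    scaffolds, genes, orthologs = synthetic.generate_annotation(
        n_scaffolds=config.n_scaffolds,
        n_genes=config.n_genes,
        homeolog_fraction=config.homeolog_fraction,
        seed=seed,
    )
    counts, counts_truth = synthetic.generate_counts(
        genes,
        n_ctrl=len(config.control_samples),
        n_kd=len(config.knockdown_samples),
        de_fraction=config.de_fraction,
        fold_change_range=(config.fold_change_min, config.fold_change_max),
        dispersion=config.nb_dispersion,
        min_baseline_mean=config.min_baseline_mean,
        seed=seed,
    )
    true_de = counts_truth["true_de_genes"]

    # bound set: a fraction of the DE genes (the future direct targets)
    # plus an equal number of non-DE genes bound without a response
    rng = synthetic.stage_rng(seed, "bound")
    de_sorted = sorted(true_de)
    n_from_de = round(config.bound_de_fraction * len(de_sorted))
    from_de = {de_sorted[i] for i in rng.choice(len(de_sorted), size=n_from_de, replace=False)}
    non_de = sorted(set(g.gene_id for g in genes) - true_de)
    extra = {non_de[i] for i in rng.choice(len(non_de), size=min(n_from_de, len(non_de)), replace=False)}
    true_bound = from_de | extra

    peak_list = synthetic.generate_peaks(
        genes,
        true_bound,
        n_noise_peaks=config.n_noise_peaks,
        window=config.window,
        seed=seed,
        scaffolds=scaffolds,
    )

    true_targets = true_de & true_bound
    target_orthologs = sorted({g.human_ortholog for g in genes if g.gene_id in true_targets})
    modules = synthetic.plant_modules(
        target_orthologs, n_modules=config.n_planted_modules, seed=seed
    )
    network = synthetic.generate_network(
        orthologs.human_gene_ids, modules, seed=seed
    )
    gene_sets = synthetic.generate_gene_sets(
        orthologs.human_gene_ids,
        target_orthologs,
        ciliary_fraction_of_targets=config.ciliary_fraction_of_targets,
        n_terms=config.n_terms,
        seed=seed,
    )
    function_sets = synthetic.generate_function_sets(modules)

    config.scaffolds_path = str(outdir / "scaffolds.tsv")
    config.gene_models_path = str(outdir / "genes.gff3")
    config.gene_models_format = "gff3"
    config.counts_path = str(outdir / "counts.tsv")
    config.peaks_path = str(outdir / "peaks.narrowPeak")
    config.peaks_format = "narrowpeak"
    config.peak_fdr_dialect = "fraction"
    config.ortholog_map_path = str(outdir / "ortholog_map.tsv")
    config.network_path = str(outdir / "network.tsv")
    config.gene_sets_path = str(outdir / "gene_sets.gmt")
    config.function_sets_path = str(outdir / "function_sets.gmt")
    config.truth_path = str(outdir / "truth.json")

    aio.write_scaffolds(scaffolds, config.scaffolds_path)
    aio.write_gene_models(genes, config.gene_models_path, format="gff3")
    aio.write_counts(counts, config.counts_path)
    aio.write_peaks(peak_list, config.peaks_path, format="narrowpeak", fdr_dialect="fraction")
    aio.write_ortholog_map(orthologs, config.ortholog_map_path)
    aio.write_network(network, config.network_path)
    aio.write_gene_sets(gene_sets, config.gene_sets_path)
    aio.write_gene_sets(function_sets, config.function_sets_path)

    truth = TruthRecord(
        true_de_genes=true_de,
        true_bound_genes=true_bound,
        planted_fold_changes=counts_truth["planted_fold_changes"],
        nb_dispersion=counts_truth["nb_dispersion"],
        planted_modules=modules,
        seed=seed,
    )
    truth.to_json(config.truth_path)
    config.to_yaml(outdir / "config.yaml")
    return truth


# ---------------------------------------------------------------------------
# pipeline stages (each standalone on intermediate files)


def _load_annotation(config: PipelineConfig):
    scaffolds = aio.read_scaffolds(config.scaffolds_path)
    retained = aio.filter_scaffolds(scaffolds, config.scaffold_min_length)
    genes = aio.read_gene_models(config.gene_models_path, config.gene_models_format, scaffolds)
    kept = [g for g in genes if g.scaffold_id in retained]
    dropped = len(genes) - len(kept)
    if dropped:
        logger.info("annotation: %d gene(s) on removed scaffolds excluded", dropped)
    return scaffolds, retained, genes, kept


def _write_lines(items, path) -> None:
    with open(path, "w") as fh:
        for item in sorted(items):
            fh.write(f"{item}\n")


def _read_lines(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def stage_de(config: PipelineConfig, outdir) -> dict:
    """Differential expression on the tested universe: genes on retained
    scaffolds with a human ortholog (the cross-organism comparison set)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, _, genes, kept = _load_annotation(config)
    orthologs = aio.read_ortholog_map(config.ortholog_map_path)
    counts = aio.read_counts(config.counts_path, config.group_map())

    universe = [g.gene_id for g in kept if g.human_ortholog or g.gene_id in orthologs]
    universe = [g for g in universe if g in set(counts.gene_ids)]
    sub = CountMatrix(counts.counts.loc[sorted(universe)], counts.group)

    if config.dispersion is None:
        disp = diffexpr.estimate_common_dispersion(sub)
        common_dispersion = disp.common_dispersion
    else:
        common_dispersion = config.dispersion
    kept_by_id = {g.gene_id: g for g in kept}
    table = diffexpr.de_table(sub, [kept_by_id[g] for g in sub.gene_ids], dispersion=common_dispersion)
    de_set = diffexpr.call_de(table, config.fold_threshold, config.de_fdr)
    rpkm = diffexpr.compute_rpkm(sub, [kept_by_id[g] for g in sub.gene_ids])
    correlations = diffexpr.replicate_correlation(rpkm, sub.group)
    logger.info("de: %d genes tested, %d DE; replicate correlations %s",
                len(sub.gene_ids), len(de_set), correlations)

    table.sort_index().to_csv(outdir / "de_table.tsv", sep="\t")
    _write_lines(de_set, outdir / "de_genes.txt")
    _write_lines(universe, outdir / "universe.txt")
    with open(outdir / "de_qc.json", "w") as fh:
        json.dump({"common_dispersion": common_dispersion,
                   "replicate_correlation": correlations,
                   "genes_annotated": len(genes),
                   "genes_on_retained_scaffolds": len(kept)}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "genes_annotated": len(genes),
        "genes_on_retained_scaffolds": len(kept),
        "genes_tested": len(universe),
        "de_set": de_set,
        "universe": set(universe),
        "common_dispersion": common_dispersion,
        "replicate_correlation": correlations,
    }


def stage_peaks(config: PipelineConfig, outdir) -> dict:
    """Peak selection and assignment to genes on retained scaffolds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _, retained, _, kept = _load_annotation(config)
    all_peaks = aio.read_peaks(config.peaks_path, config.peaks_format, config.peak_fdr_dialect)
    on_retained = [p for p in all_peaks if p.scaffold_id in retained]
    selected = peakmod.select_peaks(on_retained, fdr_max=config.peak_fdr, fold_min=config.peak_fold)
    assignments = peakmod.assign_peaks_to_genes(selected, kept, window=config.window)
    bound = peakmod.bound_gene_set(assignments)
    logger.info("peaks: %d total, %d on retained scaffolds, %d selected, %d assigned, %d genes bound",
                len(all_peaks), len(on_retained), len(selected),
                len({a.peak_id for a in assignments}), len(bound))

    aio.write_peaks(selected, outdir / "selected_peaks.narrowPeak", format="narrowpeak",
                    fdr_dialect=config.peak_fdr_dialect)
    with open(outdir / "assignments.tsv", "w") as fh:
        fh.write("peak_id\tgene_id\tdistance\n")
        for a in assignments:
            fh.write(f"{a.peak_id}\t{a.gene_id}\t{a.distance}\n")
    _write_lines(bound, outdir / "bound_genes.txt")
    return {
        "peaks_total": len(all_peaks),
        "peaks_selected": len(selected),
        "peaks_assigned": len({a.peak_id for a in assignments}),
        "assignments": len(assignments),
        "bound_set": bound,
    }


def stage_integrate(config: PipelineConfig, outdir) -> dict:
    """Direct targets, overlap significance, and gene-set comparisons in
    ortholog space."""
    outdir = Path(outdir)
    universe = _read_lines(outdir / "universe.txt")
    de_set = _read_lines(outdir / "de_genes.txt")
    bound_set = _read_lines(outdir / "bound_genes.txt")
    orthologs = aio.read_ortholog_map(config.ortholog_map_path)
    gene_sets = aio.read_gene_sets(config.gene_sets_path)

    report = integrate.build_target_report(de_set, bound_set, universe)

    # gene-set comparisons live in ortholog (human) space
    universe_h = {orthologs.human_for(g) for g in universe} - {None}
    targets_h = {orthologs.human_for(g) for g in report.direct_targets} - {None}
    if "reference_proteome" in gene_sets:
        ref_count, ref_percent, ref_p = integrate.gene_set_overlap(
            targets_h, gene_sets["reference_proteome"], universe_h
        )
    else:
        ref_count, ref_percent, ref_p = 0, None, 1.0
    rows = integrate.term_enrichment(targets_h, gene_sets, universe_h)

    _write_lines(report.direct_targets, outdir / "direct_targets.txt")
    with open(outdir / "target_report.json", "w") as fh:
        json.dump({
            "universe": len(report.universe),
            "de_genes": len(report.de_set),
            "bound_genes": len(report.bound_set),
            "direct_targets": len(report.direct_targets),
            "overlap_p": report.overlap_p,
            "reference_overlap_count": ref_count,
            "reference_overlap_percent": ref_percent,
            "reference_overlap_p": ref_p,
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "enrichment.tsv", "w") as fh:
        fh.write("term_id\tk\tK\tn\tN\tp_value\tbh_fdr\tsignificant\n")
        for r in rows:
            fh.write(f"{r.term_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p_value!r}\t{r.bh_fdr!r}\t{r.significant}\n")
    return {
        "target_report": report,
        "reference_overlap": (ref_count, ref_percent, ref_p),
        "enrichment_rows": rows,
        "significant_terms": sum(r.significant for r in rows),
    }


def stage_network(config: PipelineConfig, outdir) -> dict:
    """Ortholog collapse, evidence subnetwork, modules, candidates."""
    outdir = Path(outdir)
    de_set = _read_lines(outdir / "de_genes.txt")
    bound_set = _read_lines(outdir / "bound_genes.txt")
    universe = _read_lines(outdir / "universe.txt")
    orthologs = aio.read_ortholog_map(config.ortholog_map_path)
    network = aio.read_network(config.network_path)
    function_sets = aio.read_gene_sets(config.function_sets_path)

    frog_evidence = {
        g: (g in bound_set, g in de_set)
        for g in universe | bound_set
        if g in bound_set or g in de_set
    }
    evidence = netmod.collapse_to_orthologs(frog_evidence, orthologs)
    if config.evidence_mode == "direct_targets":
        ids = set(evidence.index[evidence["direct_target"]])
    else:
        ids = set(evidence.index[evidence["bound"] | evidence["differential"]])
    sub = netmod.extract_subnetwork(network, ids)
    modules = netmod.detect_modules(
        sub,
        penalty=config.penalty,
        min_size=config.min_module_size,
        min_density=config.min_density,
        merge_overlap=config.merge_overlap,
        growth_cap=config.module_growth_cap,
    )
    candidates = netmod.guilt_by_association(modules, function_sets, min_known=config.min_known)

    evidence.to_csv(outdir / "evidence.tsv", sep="\t")
    aio.write_network(sub, outdir / "subnetwork.tsv")
    netmod.write_graphml(sub, outdir / "subnetwork.graphml")
    with open(outdir / "modules.tsv", "w") as fh:
        fh.write("module_id\tcohesiveness\tsize\tmembers\n")
        for i, m in enumerate(modules):
            members = ",".join(sorted(m.member_ids))
            fh.write(f"module_{i + 1:03d}\t{m.cohesiveness!r}\t{m.size}\t{members}\n")
    candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    return {
        "subnetwork_nodes": sub.n_nodes,
        "subnetwork_edges": sub.n_edges,
        "modules": modules,
        "candidates": candidates,
    }


_STAGES = ("de", "peaks", "integrate", "network")


def run_pipeline(config: PipelineConfig, outdir) -> PipelineReport:
    """Run every stage in order and write report.json / report.txt.

    A failing stage aborts with its name and cause; files it had already
    written are removed so no partial stage output survives.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    stage_fns = {
        "de": stage_de,
        "peaks": stage_peaks,
        "integrate": stage_integrate,
        "network": stage_network,
    }
    results: dict[str, dict] = {}
    for name in _STAGES:
        before = set(os.listdir(outdir))
        t0 = time.perf_counter()
        try:
            results[name] = stage_fns[name](config, outdir)
        except Exception as exc:
            for fname in set(os.listdir(outdir)) - before:
                try:
                    os.unlink(outdir / fname)
                except OSError:
                    pass
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    de, pk, it, nw = (results[s] for s in _STAGES)
    tr = it["target_report"]
    ref_count, ref_percent, ref_p = it["reference_overlap"]
    report.genes_annotated = de["genes_annotated"]
    report.genes_on_retained_scaffolds = de["genes_on_retained_scaffolds"]
    report.genes_tested = de["genes_tested"]
    report.de_genes = len(de["de_set"])
    report.peaks_total = pk["peaks_total"]
    report.peaks_selected = pk["peaks_selected"]
    report.peaks_assigned = pk["peaks_assigned"]
    report.assignments = pk["assignments"]
    report.bound_genes = len(pk["bound_set"])
    report.direct_targets = len(tr.direct_targets)
    report.overlap_p = tr.overlap_p
    report.reference_overlap_count = ref_count
    report.reference_overlap_percent = ref_percent
    report.reference_overlap_p = ref_p
    report.significant_terms = it["significant_terms"]
    report.subnetwork_nodes = nw["subnetwork_nodes"]
    report.subnetwork_edges = nw["subnetwork_edges"]
    report.module_count = len(nw["modules"])
    report.candidate_count = len(nw["candidates"])
    report.common_dispersion = de["common_dispersion"]
    report.replicate_correlation = de["replicate_correlation"]
    report.validate()
    report.to_json(outdir / "report.json")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(report.to_text())
    return report
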