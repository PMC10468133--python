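"""End-to-end workflow: profile → peaks → filter → networks → cliques → enrich.

Each stage reads only declared inputs and writes its artifacts into the run
directory; a manifest records input hashes, the config, and package version.
Reruns with identical inputs and config are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .cliques import intersect_networks, maximal_cliques, method_agreement, \
    summarize_cliques
from .config import PipelineConfig
from .enrichment import build_binary_matrix, cocluster, \
    detect_functional_clusters, enrich_terms, read_annotation
from .errors import CofracError, InputError, StageError
from .networks import collapse_local_networks, local_spearman_networks, \
    pcc_network, prince_scores, read_reference_complexes
from .peaks import quantify_peaks, select_component_count
from .proteome import average_lfq, filter_protein_groups, normalize_profiles, \
    read_protein_groups, read_reference_list, reference_overlap
from .traces import bin_to_fractions, normalize_to_peak, read_trace

log = logging.getLogger(__name__)

STAGES = ("profile", "peaks", "filter", "networks", "cliques", "enrich")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run all stages; returns the run directory containing a manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        name: Path(p) for name, p in {
            "trace_csv": config.trace_csv,
            "protein_groups_tsv": config.protein_groups_tsv,
            "reference_list": config.reference_list,
            "reference_complexes_tsv": config.reference_complexes_tsv,
            "annotation_tsv": config.annotation_tsv,
        }.items() if p is not None
    }
    for name, p in inputs.items():
        if not p.exists():
            raise InputError(f"input {name} not found: {p}")
    required = ("trace_csv", "protein_groups_tsv", "reference_complexes_tsv",
                "annotation_tsv")
    missing = [r for r in required if r not in inputs]
    if missing:
        raise InputError(f"pipeline requires inputs: {missing}")

    completed = []
    artifacts: list[Path] = []

    def stage(name):
        def wrap(fn):
            try:
                fn()
            except CofracError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            completed.append(name)
            log.info("stage %s complete", name)
        return wrap

    state: dict = {}

    @stage("profile")
    def _profile():
        trace = read_trace(inputs["trace_csv"])
        norm = normalize_to_peak(trace)
        lo, hi = config.fraction_range
        series = bin_to_fractions(trace, start_volume=float(trace.volume_ml[0]),
                                  fraction_volume=1.0, first_id=lo)
        norm_path = outdir / "trace_normalized.csv"
        norm.to_csv(norm_path)
        frac_path = outdir / "fractions.tsv"
        series.to_tsv(frac_path)
        artifacts.extend([norm_path, frac_path])
        state["trace"] = trace

    @stage("peaks")
    def _peaks():
        k, model = select_component_count(
            state["trace"], *config.k_range, seed=config.seed)
        path = outdir / "peak_model.json"
        model.to_json(path)
        frac = quantify_peaks(model)
        _write_json(outdir / "peak_area_fractions.json",
                    {"k": k, "area_fractions": [round(float(f), 12) for f in frac]})
        artifacts.extend([path, outdir / "peak_area_fractions.json"])

    @stage("filter")
    def _filter():
        table = read_protein_groups(inputs["protein_groups_tsv"])
        kept = filter_protein_groups(
            table, min_unique_peptides=config.min_unique_peptides,
            fraction_range=config.fraction_range)
        rep = kept.filter_report
        _write_json(outdir / "filter_report.json", {
            "n_input": rep.n_input, "n_fail_peptides": rep.n_fail_peptides,
            "n_fail_cooccurrence": rep.n_fail_cooccurrence,
            "n_decoy": rep.n_decoy, "n_contaminant": rep.n_contaminant,
            "n_output": rep.n_output})
        matrix = average_lfq(kept)
        matrix.to_tsv(outdir / "profiles_mean.tsv")
        normed = normalize_profiles(matrix)
        normed.to_tsv(outdir / "profiles_normalized.tsv")
        if "reference_list" in inputs:
            ref = read_reference_list(inputs["reference_list"])
            ov = reference_overlap(matrix, ref)
            _write_json(outdir / "reference_overlap.json", {
                "n_shared": ov.n_shared, "n_unique_study": ov.n_unique_study,
                "n_unique_reference": ov.n_unique_reference,
                "shared_abundance_pct": round(ov.shared_abundance_pct, 6),
                "unique_abundance_pct": round(ov.unique_abundance_pct, 6)})
            artifacts.append(outdir / "reference_overlap.json")
        artifacts.extend([outdir / "filter_report.json",
                          outdir / "profiles_mean.tsv",
                          outdir / "profiles_normalized.tsv"])
        state["matrix"] = matrix
        state["normalized"] = normed

    @stage("networks")
    def _networks():
        normed = state["normalized"]
        pcc = pcc_network(normed, threshold=config.pcc_threshold)
        locals_ = local_spearman_networks(
            normed, half_window=config.half_window,
            threshold=config.spearman_threshold)
        spearman = collapse_local_networks(locals_)
        reference = read_reference_complexes(inputs["reference_complexes_tsv"])
        prince = prince_scores(normed, reference,
                               threshold=config.prince_threshold,
                               seed=config.seed)
        for net, name in ((pcc, "pcc"), (spearman, "local_spearman"),
                          (prince, "prince")):
            path = outdir / f"network_{name}.tsv"
            net.to_tsv(path)
            artifacts.append(path)
        _write_json(outdir / "network_counts.json", {
            "n_pairs_evaluated": pcc.n_pairs_evaluated,
            "n_local_windows": len(locals_),
            "edges": {"pcc": pcc.n_edges, "local_spearman": spearman.n_edges,
                      "prince": prince.n_edges}})
        artifacts.append(outdir / "network_counts.json")
        state["networks"] = [pcc, spearman, prince]

    @stage("cliques")
    def _cliques():
        nets = state["networks"]
        consensus = intersect_networks(nets)
        consensus.to_tsv(outdir / "network_consensus.tsv")
        agreements = {}
        for i in range(len(nets)):
            for j in range(i + 1, len(nets)):
                res = method_agreement(nets[i], nets[j])
                agreements[f"{res.method_a}|{res.method_b}"] = {
                    "table": res.table.tolist(),
                    "odds_ratio": round(res.odds_ratio, 6),
                    "p_value": res.p_value,
                    "significant": res.significant}
        _write_json(outdir / "method_agreement.json", agreements)
        _write_json(outdir / "venn_counts.json", consensus.venn)
        cliques = maximal_cliques(consensus, min_size=config.min_clique_size)
        summary = summarize_cliques(cliques)
        summary.to_tsv(outdir / "cliques.tsv")
        _write_json(outdir / "clique_sizes.json",
                    {str(k): v for k, v in sorted(summary.size_histogram.items())})
        artifacts.extend([outdir / "network_consensus.tsv",
                          outdir / "method_agreement.json",
                          outdir / "venn_counts.json", outdir / "cliques.tsv",
                          outdir / "clique_sizes.json"])
        state["consensus"] = consensus

    @stage("enrich")
    def _enrich():
        annotation = read_annotation(inputs["annotation_tsv"])
        study = sorted(set(state["matrix"].proteins) & annotation.proteins)
        if not study:
            raise StageError("no study proteins covered by the annotation")
        results = enrich_terms(study, annotation,
                               alpha=config.enrichment_alpha)
        rows = ["term_id\tk\tK\tp_value\tp_bonferroni\tsignificant"]
        rows += [f"{r.term_id}\t{r.k}\t{r.K}\t{r.p_value:.6e}"
                 f"\t{r.p_bonferroni:.6e}\t{int(r.significant)}"
                 for r in results]
        (outdir / "enrichment.tsv").write_text("\n".join(rows) + "\n")
        significant = [r for r in results if r.significant]
        payload = {"n_tested": len(results), "n_significant": len(significant)}
        if significant:
            matrix = build_binary_matrix(significant, annotation, study)
            g = min(config.n_groups, *matrix.values.shape)
            clustered = cocluster(matrix, n_groups=g)
            clustered.to_tsv(outdir / "enrichment_matrix.tsv")
            calls = detect_functional_clusters(
                clustered, min_correspondence=config.min_correspondence)
            payload["n_groups"] = g
            payload["functional_clusters"] = [
                {"row_group": c.row_group, "col_group": c.col_group,
                 "correspondence": round(c.correspondence, 6),
                 "n_proteins": c.n_proteins, "n_terms": c.n_terms}
                for c in calls]
            artifacts.append(outdir / "enrichment_matrix.tsv")
        _write_json(outdir / "functional_clusters.json", payload)
        artifacts.extend([outdir / "enrichment.tsv",
                          outdir / "functional_clusters.json"])

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stages_completed": completed,
        "inputs": {name: _sha256(p) for name, p in sorted(inputs.items())},
        "artifacts": {p.name: _sha256(p) for p in sorted(set(artifacts))},
    }
    _write_json(outdir / "manifest.json", manifest)
    return outdir
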