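"""End-to-end orchestration of the remodeling-inference pipeline.

``run_pipeline`` drives the stages in order — simulate (or ingest),
ortholog mapping, restriction compilation, model fitting, relation
scoring, triggering analysis, biomarker search and enrichment summary —
writing each stage's tables into a run directory together with a
provenance manifest (config hash, master seed, per-stage row counts and
output checksums). Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .biomarkers import cap_candidates, search_combinations, LabeledSampleSet
from .cohorts import CORE_COHORTS
from .enrich import RankedList, enrichment_score, network_summary
from .expression import adjust_table, build_restrictions, drop_contradictions, restrictions_frame
from .model import fit_monte_carlo
from .orthologs import map_expression, reciprocal_best_hits
from .relate import score_proteins, select_related, RelationScore
from .synthetic import (
    generate_network,
    generate_truth_table,
    make_signature,
    plant_ground_truth,
    scores_for_pairs,
    simulate_cohorts,
    simulate_sample_matrix,
)
from .trigger import common_sources, triggering_report

_STAGES = (
    "simulate",
    "map",
    "compile",
    "fit",
    "relate",
    "trigger",
    "biomarkers",
    "enrich",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run on synthetic data."""

    outdir: str = "run"
    n_nodes: int = 200
    mean_degree: float = 3.0
    inhibitory_fraction: float = 0.3
    n_sources: int = 3
    noise_sd: float = 0.1
    effect_size: float = 1.0
    fdr: float = 0.01
    relation_threshold: float = 0.5
    combination_sizes: tuple[int, ...] = (2, 3)
    max_path_len: int = 3
    n_solutions: int = 6
    n_steps: int = 400
    n_rules: int = 8
    n_effectors: int = 12
    relate_cap: int = 40
    candidate_cap: int = 30
    n_samples_per_cohort: int = 5
    master_seed: int = 0

    def validate(self) -> None:
        if not 0 < self.fdr <= 1:
            raise ValueError("fdr must lie in (0, 1]")
        if not 0 <= self.relation_threshold < 1:
            raise ValueError("relation_threshold must lie in [0, 1)")
        if self.max_path_len < 1:
            raise ValueError("max_path_len must be >= 1")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if any(s < 1 for s in self.combination_sizes):
            raise ValueError("combination sizes must be positive")

    def stage_seed(self, stage: str) -> int:
        """Documented counter scheme: master * 1009 + stage index, mod 2^31."""
        return (self.master_seed * 1009 + _STAGES.index(stage)) % (2**31)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    header = f"# mi-remodel {__version__} config={cfg.config_hash()} seed={cfg.master_seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order; returns the provenance manifest."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items() if k != "outdir"},
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "stages": {},
    }

    def record(stage: str, rows: int, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "rows": rows,
            "outputs": {f.name: _sha256(f) for f in sorted(files)},
        }

    # -- simulate ---------------------------------------------------------
    seed = cfg.stage_seed("simulate")
    net = generate_network(
        cfg.n_nodes, cfg.mean_degree, cfg.inhibitory_fraction, seed=seed
    )
    truth = plant_ground_truth(
        net, n_sources=cfg.n_sources, depth=cfg.max_path_len, seed=seed
    )
    expression = simulate_cohorts(
        net, truth, noise_sd=cfg.noise_sd, effect_size=cfg.effect_size, seed=seed
    )
    scores = scores_for_pairs(truth.rbh_pairs, seed=seed)
    truth_table = generate_truth_table(net, n_rules=cfg.n_rules, seed=seed)
    signature = make_signature(
        truth, cohort="C6", n_effectors=cfg.n_effectors, seed=seed
    )
    samples = simulate_sample_matrix(
        net,
        truth,
        cohorts=CORE_COHORTS,
        n_per_cohort=cfg.n_samples_per_cohort,
        seed=seed,
    )
    net.write_sif(outdir / "network.sif")
    _write_tsv(expression, outdir / "expression.tsv", cfg)
    scores.write_tsv(outdir / "ortholog_scores.tsv")
    truth.to_json(outdir / "ground_truth.json")
    truth_table.to_json(outdir / "truth_table.json")
    _write_tsv(samples, outdir / "samples.tsv", cfg)
    (outdir / "signature.txt").write_text(
        "".join(f"{p}\t{s}\n" for p, s in sorted(signature.effectors.items()))
    )
    record(
        "simulate",
        len(expression),
        [
            outdir / "network.sif",
            outdir / "expression.tsv",
            outdir / "ortholog_scores.tsv",
            outdir / "ground_truth.json",
            outdir / "truth_table.json",
            outdir / "samples.tsv",
            outdir / "signature.txt",
        ],
    )

    # -- map --------------------------------------------------------------
    omap = reciprocal_best_hits(scores)
    mapped = map_expression(expression, omap)
    omap.write_tsv(outdir / "ortholog_map.tsv")
    _write_tsv(mapped, outdir / "expression_mapped.tsv", cfg)
    record("map", len(mapped), [outdir / "ortholog_map.tsv", outdir / "expression_mapped.tsv"])

    # -- compile ----------------------------------------------------------
    clean = drop_contradictions(mapped)
    adjusted = adjust_table(clean, fdr=cfg.fdr)
    restrictions = build_restrictions(mapped, fdr=cfg.fdr)
    _write_tsv(adjusted, outdir / "expression_adjusted.tsv", cfg)
    rframe = restrictions_frame(restrictions)
    _write_tsv(rframe, outdir / "restrictions.tsv", cfg)
    record(
        "compile",
        len(rframe),
        [outdir / "expression_adjusted.tsv", outdir / "restrictions.tsv"],
    )

    # -- fit --------------------------------------------------------------
    ensemble = fit_monte_carlo(
        net,
        truth_table,
        n_solutions=cfg.n_solutions,
        n_steps=cfg.n_steps,
        seed=cfg.stage_seed("fit"),
    )
    _write_tsv(ensemble.to_frame(), outdir / "ensemble_weights.tsv", cfg)
    _write_tsv(ensemble.accuracy_frame(), outdir / "ensemble_accuracy.tsv", cfg)
    record(
        "fit",
        ensemble.n_solutions,
        [outdir / "ensemble_weights.tsv", outdir / "ensemble_accuracy.tsv"],
    )

    # -- relate -----------------------------------------------------------
    core = rframe[rframe["cohort"] == "C6"].sort_values("protein")
    # cap the scored set for runtime; sources first, then lexicographic
    planted = truth.planted_sources["C6"]
    core = pd.concat(
        [core[core["protein"].isin(planted)], core[~core["protein"].isin(planted)]]
    ).head(cfg.relate_cap)
    directions = dict(zip(core["protein"], core["direction"]))
    relate_scores = score_proteins(ensemble, net, directions, signature)
    related = select_related(
        [RelationScore(p, v) for p, v in
         zip(relate_scores["protein"], relate_scores["predictive_value"])],
        threshold=cfg.relation_threshold,
    )
    relate_scores["included"] = relate_scores["protein"].isin(related)
    _write_tsv(relate_scores, outdir / "relation_scores.tsv", cfg)
    record("relate", len(relate_scores), [outdir / "relation_scores.tsv"])

    # -- trigger ----------------------------------------------------------
    reports = []
    per_cohort_sources: dict[str, list[str]] = {}
    for cohort in CORE_COHORTS:
        sub = [r for r in restrictions if r.cohort == cohort]
        report = triggering_report(net, sub, cohort, max_path_len=cfg.max_path_len)
        reports.append(report)
        per_cohort_sources[cohort] = report.sources
    frames = [r.to_frame().set_index("metric") for r in reports]
    trigger_table = pd.concat(frames, axis=1).reset_index()
    _write_tsv(trigger_table, outdir / "triggering_report.tsv", cfg)
    common = sorted(common_sources(per_cohort_sources))
    (outdir / "common_sources.json").write_text(
        json.dumps({"common_to_all": common,
                    "per_cohort": {c: sorted(v) for c, v in per_cohort_sources.items()}},
                   indent=1, sort_keys=True) + "\n"
    )
    record(
        "trigger",
        len(trigger_table),
        [outdir / "triggering_report.tsv", outdir / "common_sources.json"],
    )

    # -- biomarkers -------------------------------------------------------
    data = LabeledSampleSet.from_frame(samples)
    candidates = cap_candidates(relate_scores, cap=cfg.candidate_cap)
    sizes = tuple(s for s in cfg.combination_sizes if s <= len(candidates))
    ht_significant = set(rframe["protein"])
    report_df = search_combinations(
        data,
        candidates,
        sizes=sizes,
        strategy="models/HT",
        ht_significant=ht_significant,
        top_k=10,
    )
    _write_tsv(report_df, outdir / "biomarker_report.tsv", cfg)
    record("biomarkers", len(report_df), [outdir / "biomarker_report.tsv"])

    # -- enrich -----------------------------------------------------------
    summary: dict = {}
    for cohort in CORE_COHORTS:
        sub = mapped[mapped["cohort"] == cohort]
        ranked = RankedList.from_scores(
            dict(zip(sub["id"], sub["log2_ratio"].astype(float)))
        )
        up_set = {p for p, s in signature.effectors.items() if s > 0}
        if up_set & set(ranked.genes):
            summary[f"es_{cohort}"] = enrichment_score(ranked, up_set)
    avg_degree, avg_clust = network_summary(
        net.nodes, [(u, v) for u, v, _ in net.edges]
    )
    summary["network_avg_degree"] = avg_degree
    summary["network_avg_clustering"] = avg_clust
    summary["best_fit_accuracy"] = ensemble.best_accuracy
    summary["n_related"] = int(len(related))
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    record("enrich", len(summary), [outdir / "summary.json"])

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
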