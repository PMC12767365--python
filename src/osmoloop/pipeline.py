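"""End-to-end orchestration: simulate → differential loops → aggregates →
anchor overlaps → matched nulls → expression coupling.

Every stage is deterministic under the config's master seed; reports are
plain tab-separated tables plus a resolved-config copy and a log with
content hashes of each written file, so a rerun with the same seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anchors import anchor_feature_overlap, classify_de_novo
from .apa import apa, enrichment, timecourse_enrichment
from .io import ContactMatrix, CountTable, LoopSet, write_bedpe, write_counts
from .matching import MatchSpec, compute_covariates, stratified_match
from .nbdiff import (
    classify,
    design_matrix,
    filter_features,
    fit_nb_glm,
    lrt_test,
    anchor_gene_trajectories,
    wald_test,
    zscore_kmeans,
)
from .simulate import (
    DEFAULT_TIMEPOINTS,
    RNA_TIMEPOINTS,
    SimParams,
    SimulatedExperiment,
    loopspecs_to_loopset,
    make_differential_loopspecs,
    make_gene_truth,
    make_loopspecs,
    simulate_experiment,
    simulate_promoters,
    simulate_rna_counts,
)

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "extract_loop_counts",
    "pool_matrices",
    "run_pipeline",
    "write_report",
    "make_fixtures",
]

_ALLOWED_KEYS = {
    "seed", "resolution", "chrom_length", "apa_half_width",
    "n_gained", "n_lost", "n_static", "fold", "n_replicates",
    "loop_rule", "gene_rule", "gene_filter",
    "timecourse", "timecourse_replicates",
    "rna", "rna_replicates", "match_strata", "run_matching",
}


@dataclass
class PipelineConfig:
    """Flat configuration for a full simulated analysis run.

    Thresholds default to the analysis presets (loops padj < 0.1; genes
    padj < 0.05 and |log2FC| > 2; gene filter ≥ 50 counts in ≥ 4 samples).
    """

    seed: int
    resolution: int = 10_000
    chrom_length: int = 20_000_000
    apa_half_width: int = 10
    n_gained: int = 50
    n_lost: int = 100
    n_static: int = 50
    fold: float = 3.0
    n_replicates: int = 4
    loop_rule: str = "loop_default"
    gene_rule: str = "gene_timepoint"
    gene_filter: str = "gene_default"
    timecourse: bool = True
    timecourse_replicates: int = 1
    rna: bool = True
    rna_replicates: int = 2
    match_strata: int = 20
    run_matching: bool = True

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config missing required key: seed")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineReport:
    """Bundle of tables and scalar summaries produced by one run."""

    config: PipelineConfig
    loop_results: pd.DataFrame
    loop_confusion: pd.DataFrame
    apa_scores: pd.DataFrame
    de_novo: dict[str, float]
    promoter_overlap: dict[str, float]
    timecourse_curves: pd.DataFrame | None = None
    timecourse_correlation: float | None = None
    match_balance: pd.DataFrame | None = None
    gene_lrt: pd.DataFrame | None = None
    gene_clusters: pd.Series | None = None
    gene_trajectory_tests: pd.DataFrame | None = None
    gene_counts_per_timepoint: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)


def pool_matrices(
    mats: list[Mapping[str, ContactMatrix]]
) -> dict[str, ContactMatrix]:
    """Sum replicate contact maps chromosome-wise (raw counts add)."""
    out: dict[str, ContactMatrix] = {}
    chroms = mats[0].keys()
    for chrom in chroms:
        b1s, b2s, cs = [], [], []
        genome = mats[0][chrom].genome
        for m in mats:
            tri = m[chrom].triples()
            b1s.append(tri.bin1.to_numpy())
            b2s.append(tri.bin2.to_numpy())
            cs.append(tri["count"].to_numpy())
        out[chrom] = ContactMatrix(
            genome, chrom, np.concatenate(b1s), np.concatenate(b2s), np.concatenate(cs)
        )
    return out


def extract_loop_counts(
    experiment: SimulatedExperiment, loops: LoopSet
) -> CountTable:
    """Raw loop-pixel counts per sample, with a replicate/condition/time design."""
    res = experiment.params.resolution
    from .io import snap_to_grid

    gridded = snap_to_grid(loops, res)
    b1, b2 = gridded.anchor_bins(res)
    cols = {}
    design_rows = []
    for cond, t, rep in experiment.sample_keys():
        mat = experiment.matrices[(cond, t, rep)]
        name = f"{cond}_t{t:g}_rep{rep + 1}"
        cols[name] = [
            mat.get(int(i), int(j)) if c == mat.chrom else 0
            for c, i, j in zip(gridded.df.chrom1, b1, b2)
        ]
        design_rows.append(
            {"sample": name, "replicate": f"rep{rep + 1}", "condition": cond,
             "time": f"t{t:g}"}
        )
    index = (
        gridded.df["loop_id"] if "loop_id" in gridded.df.columns
        else pd.Index([f"loop{k:04d}" for k in range(len(gridded))], name="loop_id")
    )
    counts = pd.DataFrame(cols)
    counts.index = pd.Index(index, name="loop_id")
    design = pd.DataFrame(design_rows).set_index("sample")
    return CountTable(counts, design)


def differential_loops(
    experiment: SimulatedExperiment, loops: LoopSet, rule: str = "loop_default"
) -> pd.DataFrame:
    """Unscaled NB differential loop test (design: replicate + condition)."""
    table = extract_loop_counts(experiment, loops)
    X = design_matrix(table.design, ["replicate", "condition"])
    fit = fit_nb_glm(table.counts, X)
    coef = [c for c in fit.design_columns if c.startswith("condition[")][0]
    res = wald_test(fit, coef)
    res["klass"] = classify(res, rule)
    return res


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute every stage in dependency order on simulated data."""
    log: list[str] = []

    def stage(name: str, t0: float) -> None:
        log.append(f"stage={name} elapsed={_time.time() - t0:.2f}s seed={config.seed}")

    params = SimParams(
        chrom_length=config.chrom_length,
        resolution=config.resolution,
        n_replicates=config.n_replicates,
        seed=config.seed,
    )

    # -- differential loops ---------------------------------------------------
    t0 = _time.time()
    specs = make_differential_loopspecs(
        params, config.n_gained, config.n_lost, config.n_static, fold=config.fold
    )
    exp = simulate_experiment(params, specs, timepoints=[1.0])
    loops = loopspecs_to_loopset(specs, params)
    res = differential_loops(exp, loops, config.loop_rule)
    truth_klass = pd.Series(
        [s.klass for s in specs], index=res.index, name="truth"
    )
    confusion = pd.crosstab(truth_klass, res.klass)
    stage("differential_loops", t0)

    # -- APA ------------------------------------------------------------------
    t0 = _time.time()
    control = pool_matrices(
        [{params.chrom_name: exp.matrices[("control", 1.0, r)]}
         for r in range(params.n_replicates)]
    )
    treated = pool_matrices(
        [{params.chrom_name: exp.matrices[("treated", 1.0, r)]}
         for r in range(params.n_replicates)]
    )
    rows = []
    for klass in ("gained", "lost", "static"):
        sub = LoopSet(loops.df[loops.df.klass == klass])
        for cond, mats in (("control", control), ("treated", treated)):
            block = apa(mats, sub, half_width=config.apa_half_width)
            rows.append(
                {"klass": klass, "condition": cond,
                 "enrichment": enrichment(block).value, "n_used": block.n_used}
            )
    apa_scores = pd.DataFrame(rows)
    stage("apa", t0)

    # -- de novo / shared anchors --------------------------------------------
    t0 = _time.time()
    called_gained = LoopSet(loops.df[(res.klass == "gained").to_numpy()])
    reference = LoopSet(loops.df[loops.df.klass != "gained"])
    if len(called_gained) and len(reference):
        rep = classify_de_novo(called_gained, reference, slack_bp=config.resolution)
        de_novo = {
            "fraction_de_novo": rep.fraction_de_novo,
            "fraction_shared_anchor": rep.fraction_shared_anchor,
            "fraction_shared_anchor_anchors": rep.fraction_shared_anchor_anchors,
        }
    else:  # pragma: no cover - degenerate call set
        de_novo = {}
    stage("de_novo", t0)

    # -- promoter overlap by class -------------------------------------------
    t0 = _time.time()
    promoters = simulate_promoters(params, specs)
    _, flags = anchor_feature_overlap(loops, promoters, labels=loops.df.klass)
    promoter_overlap = flags.attrs.get("per_class", {})
    stage("promoter_overlap", t0)

    # -- matched null ---------------------------------------------------------
    match_balance = None
    if config.run_matching:
        t0 = _time.time()
        cov, n_missing = compute_covariates(
            loops, {"control": control, "treated": treated}
        )
        focal_mask = loops.df.klass == "gained"
        focal_cov = cov[cov.index.isin(loops.df.index[focal_mask])]
        pool_cov = cov[~cov.index.isin(loops.df.index[focal_mask])]
        mres = stratified_match(
            focal_cov, pool_cov, MatchSpec(n_strata=config.match_strata, seed=config.seed)
        )
        match_balance = pd.DataFrame(
            {"smd_pre": mres.smd_pre, "smd_post": mres.smd_post}
        )
        log.append(
            f"matching: missing_covariates={n_missing} "
            f"unmatched_focal={mres.n_unmatched_focal}"
        )
        stage("matched_null", t0)

    # -- time-course APA ------------------------------------------------------
    curves = None
    corr = None
    if config.timecourse:
        t0 = _time.time()
        tc_params = SimParams(
            chrom_length=config.chrom_length, resolution=config.resolution,
            n_replicates=config.timecourse_replicates, seed=config.seed + 1,
        )
        tc_specs = make_loopspecs(tc_params)
        tc_exp = simulate_experiment(
            tc_params, tc_specs, timepoints=list(DEFAULT_TIMEPOINTS),
            conditions=["treated"],
        )
        tc_loops = loopspecs_to_loopset(tc_specs, tc_params)
        by_time = {
            t: pool_matrices(
                [{tc_params.chrom_name: tc_exp.matrices[("treated", t, r)]}
                 for r in range(tc_params.n_replicates)]
            )
            for t in DEFAULT_TIMEPOINTS
        }
        by_class = {
            k: LoopSet(tc_loops.df[tc_loops.df.klass == k])
            for k in ("gained", "preexisting", "static")
        }
        curves, corr = timecourse_enrichment(by_time, by_class)
        stage("timecourse", t0)

    # -- RNA time course ------------------------------------------------------
    gene_lrt = None
    gene_clusters = None
    traj_tests = None
    counts_per_tp = None
    if config.rna:
        t0 = _time.time()
        truth_genes = make_gene_truth(seed=config.seed)
        rna = simulate_rna_counts(
            truth_genes, n_replicates=config.rna_replicates, seed=config.seed
        )
        filtered, n_removed = filter_features(rna, config.gene_filter)
        log.append(f"gene_filter: removed={n_removed} kept={len(filtered.counts)}")
        X_full = design_matrix(filtered.design, ["replicate", "time"])
        X_red = design_matrix(filtered.design, ["replicate"])
        fit_full = fit_nb_glm(filtered.counts, X_full)
        fit_red = fit_nb_glm(filtered.counts, X_red, dispersions=fit_full.dispersion)
        gene_lrt = lrt_test(fit_full, fit_red)
        # per-timepoint Wald classification and log2FC curves
        lfc_cols, n_up, n_down = {}, {}, {}
        for t in RNA_TIMEPOINTS[1:]:
            coef = f"time[t{t:g}]"
            if coef not in fit_full.design_columns:
                continue
            wt = wald_test(fit_full, coef)
            lab = classify(wt, config.gene_rule)
            lfc_cols[f"t{t:g}"] = wt.log2fc
            n_up[f"t{t:g}"] = int((lab == "up").sum())
            n_down[f"t{t:g}"] = int((lab == "down").sum())
        counts_per_tp = pd.DataFrame({"up": n_up, "down": n_down})
        lfc_by_time = pd.DataFrame(lfc_cols)
        sig = gene_lrt.index[gene_lrt.padj < 0.05]
        if len(sig) >= 3:
            sub = CountTable(filtered.counts.loc[sig], filtered.design)
            gene_clusters, _, _ = zscore_kmeans(sub, k=3, seed=config.seed)
        classes = truth_genes.set_index("gene_id").klass.reindex(lfc_by_time.index)
        classes = classes.str.replace("off_anchor_flat", "off_anchor").str.replace(
            "off_anchor_transient", "off_anchor"
        )
        _, traj_tests = anchor_gene_trajectories(lfc_by_time, classes)
        stage("rna", t0)

    return PipelineReport(
        config=config,
        loop_results=res,
        loop_confusion=confusion,
        apa_scores=apa_scores,
        de_novo=de_novo,
        promoter_overlap=promoter_overlap,
        timecourse_curves=curves,
        timecourse_correlation=corr,
        match_balance=match_balance,
        gene_lrt=gene_lrt,
        gene_clusters=gene_clusters,
        gene_trajectory_tests=traj_tests,
        gene_counts_per_timepoint=counts_per_tp,
        log=log,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(report: PipelineReport, outdir: str | Path) -> Path:
    """Write every table, the resolved config, and a hash-stamped log."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def table(df: pd.DataFrame | pd.Series | None, name: str) -> None:
        if df is None:
            return
        p = out / f"{name}.tsv"
        (df.to_frame() if isinstance(df, pd.Series) else df).to_csv(p, sep="\t")
        written.append(p)

    table(report.loop_results, "loop_results")
    table(report.loop_confusion, "loop_confusion")
    table(report.apa_scores, "apa_scores")
    table(report.timecourse_curves, "timecourse_curves")
    table(report.match_balance, "match_balance")
    table(report.gene_lrt, "gene_lrt")
    table(report.gene_clusters, "gene_clusters")
    table(report.gene_trajectory_tests, "gene_trajectory_tests")
    table(report.gene_counts_per_timepoint, "gene_counts_per_timepoint")
    scalars = {
        "de_novo": report.de_novo,
        "promoter_overlap": report.promoter_overlap,
        "timecourse_correlation": report.timecourse_correlation,
    }
    (out / "summary.json").write_text(json.dumps(scalars, indent=2, default=float))
    written.append(out / "summary.json")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(report.config), fh)
    lines = list(report.log) + [f"version={__version__}"]
    lines += [f"sha256 {p.name} {_sha256(p)}" for p in written]
    (out / "run.log").write_text("\n".join(lines) + "\n")
    return out


def make_fixtures(outdir: str | Path, seed: int = 0) -> Path:
    """Write a tiny deterministic dataset: 5 Mb, 12 loops, 2 reps, 3 timepoints."""
    from .io import write_bed, write_chromsizes, write_contacts

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = SimParams(chrom_length=5_000_000, n_replicates=2, seed=seed)
    specs = make_loopspecs(params, n_gained=4, n_preexisting=5, n_static=3,
                           gained_span_bins=(25, 45), preexisting_span_bins=(24, 40))
    times = [0.0, 1.0, 24.0]
    exp = simulate_experiment(params, specs, timepoints=times)
    write_chromsizes(params.genome, out / "chrom.sizes")
    for (cond, t, rep), mat in exp.matrices.items():
        write_contacts({params.chrom_name: mat},
                       out / f"contacts_{cond}_t{t:g}_rep{rep + 1}.tsv")
    loops = loopspecs_to_loopset(specs, params)
    write_bedpe(loops, out / "loops.bedpe")
    promoters = simulate_promoters(params, specs, n_background=20)
    write_bed(promoters, out / "promoters.bed")
    truth_genes = make_gene_truth(
        {"anchor_gained": 8, "anchor_static": 8, "anchor_lost": 8,
         "off_anchor_flat": 16, "off_anchor_transient": 8},
        seed=seed,
    )
    rna = simulate_rna_counts(truth_genes, seed=seed)
    write_counts(rna, out / "rna_counts.tsv", out / "rna_design.tsv")
    truth_genes.to_csv(out / "gene_truth.tsv", sep="\t", index=False)
    exp.truth.loops.to_csv(out / "loop_truth.tsv", sep="\t", index=False)
    return out
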