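"""Self-validation experiments run on the synthetic generator.

Each function simulates data under the generator's default study
conditions, runs the corresponding analysis stage, and returns the measured
quantities (recoveries, error rates, calibration statistics, balance
diagnostics). They back both the acceptance test suite and the
``scripts/acceptance.py`` reporting script; all randomness derives from the
``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .apa import apa, enrichment, timecourse_enrichment
from .io import LoopSet
from .matching import MatchSpec, stratified_match
from .nbdiff import (
    design_matrix,
    fit_nb_glm,
    lrt_test,
    wald_test,
    zscore_kmeans,
)
from .pipeline import differential_loops, pool_matrices
from .simulate import (
    DEFAULT_TIMEPOINTS,
    LoopSpec,
    SimParams,
    _place_loops,
    _stream,
    inject_loops,
    loopspecs_to_loopset,
    make_differential_loopspecs,
    make_gene_truth,
    make_loopspecs,
    simulate_background,
    simulate_experiment,
    simulate_rna_counts,
)

__all__ = [
    "apa_signal_recovery",
    "differential_loop_recovery",
    "wald_type1_error",
    "lrt_calibration_and_power",
    "kmeans_trajectory_recovery",
    "punctateness_curve",
    "timecourse_dynamics",
    "matching_balance",
]

#: sample-level extra-Poisson dispersion implied by the default depth factor
CONTACT_DISPERSION = float(np.expm1(SimParams().depth_log_sd ** 2))


def _gained_specs(params: SimParams, n: int, amplitude: float, sigma: float,
                  stream: int) -> list[LoopSpec]:
    pos = _place_loops(params, n, _stream(params.seed, stream), (30, 90), 12, [],
                       min_sep=25)
    return [
        LoopSpec(i, j, "gained", {1.0: amplitude}, control_amplitude=1.0,
                 sigma=sigma, domain_factor=1.0, stripe_factor=1.0)
        for i, j in pos
    ]


def apa_signal_recovery(seed: int, n_loops: int = 30, amplitude: float = 5.0,
                        sigma: float = 1.0) -> dict[str, float]:
    """APA enrichment over gained truth loops in treated vs control maps.

    Default conditions: one 20-Mb chromosome at 10-kb bins, 30 gained loops
    of amplitude 5 and kernel width 1 bin, absent in the control.
    """
    params = SimParams(seed=seed)
    specs = _gained_specs(params, n_loops, amplitude, sigma, stream=30)
    exp = simulate_experiment(params, specs, timepoints=[1.0])
    loops = loopspecs_to_loopset(specs, params)
    out = {}
    for cond in ("control", "treated"):
        mats = pool_matrices(
            [{params.chrom_name: exp.matrices[(cond, 1.0, r)]}
             for r in range(params.n_replicates)]
        )
        block = apa(mats, loops)
        out[f"{cond}_enrichment"] = enrichment(block).value
    out["n_loops"] = n_loops
    return out


def differential_loop_recovery(seed: int) -> dict[str, float]:
    """Sensitivity and empirical FDR of the unscaled NB loop test.

    200 truth loops (50 gained ×3, 100 lost ÷3, 50 static), 4 replicates
    per condition, classification at padj < 0.1.
    """
    params = SimParams(seed=seed)
    specs = make_differential_loopspecs(params)
    exp = simulate_experiment(params, specs, timepoints=[1.0])
    loops = loopspecs_to_loopset(specs, params)
    res = differential_loops(exp, loops)
    truth = pd.Series([s.klass for s in specs], index=res.index)
    out = {}
    for k in ("gained", "lost"):
        out[f"sensitivity_{k}"] = float(
            ((res.klass == k) & (truth == k)).sum() / (truth == k).sum()
        )
    called = res.klass != "static"
    wrong = ((res.klass == "gained") & (truth != "gained")) | (
        (res.klass == "lost") & (truth != "lost")
    )
    out["fdr"] = float(wrong.sum() / called.sum()) if called.any() else 0.0
    out["n_loops"] = len(specs)
    return out


def wald_type1_error(seed: int, n_features: int = 5000) -> dict[str, float]:
    """Rejection rate of the Wald test at α = 0.05 on null NB features.

    Feature means are log-uniform over the loop-pixel background range
    (20–150 counts); dispersion is the value implied by the generator's
    default per-sample depth variability. Paired 4 vs 4 design.
    """
    rng = _stream(seed, 40)
    mu = np.exp(rng.uniform(np.log(20), np.log(150), n_features))
    size = 1.0 / CONTACT_DISPERSION
    Y = rng.negative_binomial(size, size / (size + mu[:, None]), size=(n_features, 8))
    counts = pd.DataFrame(Y, columns=[f"s{i}" for i in range(8)])
    design = pd.DataFrame(
        {"replicate": ["r1", "r2", "r3", "r4"] * 2,
         "condition": ["control"] * 4 + ["treated"] * 4},
        index=counts.columns,
    )
    X = design_matrix(design, ["replicate", "condition"])
    fit = fit_nb_glm(counts, X)
    res = wald_test(fit, "condition[treated]")
    return {
        "rejection_rate": float((res.pvalue < 0.05).mean()),
        "n_features": n_features,
    }


def lrt_calibration_and_power(seed: int, n_null: int = 5000) -> dict[str, float]:
    """Null uniformity (KS) and late-induction power of the time-course LRT."""
    null_truth = make_gene_truth({"off_anchor_flat": n_null}, seed=seed)
    null_rna = simulate_rna_counts(null_truth, seed=seed)
    Xf = design_matrix(null_rna.design, ["replicate", "time"])
    Xr = design_matrix(null_rna.design, ["replicate"])
    ff = fit_nb_glm(null_rna.counts, Xf)
    fr = fit_nb_glm(null_rna.counts, Xr, dispersions=ff.dispersion)
    null_res = lrt_test(ff, fr)
    ks = stats.kstest(null_res.pvalue.dropna(), "uniform")
    # power: the default mixed population with late-induced gained-anchor genes
    truth = make_gene_truth(seed=seed + 1)
    rna = simulate_rna_counts(truth, seed=seed + 1)
    Xf = design_matrix(rna.design, ["replicate", "time"])
    Xr = design_matrix(rna.design, ["replicate"])
    ff = fit_nb_glm(rna.counts, Xf)
    fr = fit_nb_glm(rna.counts, Xr, dispersions=ff.dispersion)
    res = lrt_test(ff, fr)
    gained = (truth.klass == "anchor_gained").to_numpy()
    return {
        "ks_pvalue": float(ks.pvalue),
        "ks_statistic": float(ks.statistic),
        "null_rejection_rate": float((null_res.pvalue < 0.05).mean()),
        "sensitivity": float((res.padj[gained] < 0.05).mean()),
        "n_null": n_null,
    }


def kmeans_trajectory_recovery(seed: int, n_per_class: int = 60) -> dict[str, float]:
    """Adjusted Rand index of k-means on three separated trajectory archetypes."""
    truth = make_gene_truth(
        {"anchor_gained": n_per_class, "off_anchor_transient": n_per_class,
         "off_anchor_down": n_per_class},
        seed=seed,
    )
    rna = simulate_rna_counts(truth, seed=seed)
    labels, _, _ = zscore_kmeans(rna, k=3, seed=seed)
    return {
        "ari": float(adjusted_rand_score(truth.klass, labels)),
        "n_genes": 3 * n_per_class,
    }


def punctateness_curve(seed: int, sigmas=(0.5, 1.0, 2.0, 4.0),
                       amplitude: float = 5.0, n_loops: int = 30) -> dict:
    """enrichment(center, ring) as a function of the loop kernel width σ."""
    values = []
    for k, sigma in enumerate(sigmas):
        params = SimParams(seed=seed)
        specs = _gained_specs(params, n_loops, amplitude, sigma, stream=50)
        bg = simulate_background(params, rng=_stream(seed, 51, k))
        mat = inject_loops(bg, specs, "treated", 1.0, params, rng=_stream(seed, 52, k))
        loops = loopspecs_to_loopset(specs, params)
        block = apa({params.chrom_name: mat}, loops)
        values.append(enrichment(block, "center", "ring").value)
    return {
        "sigmas": list(sigmas),
        "enrichment": values,
        "strictly_decreasing": bool(all(a > b for a, b in zip(values, values[1:]))),
    }


def timecourse_dynamics(seed: int) -> dict:
    """Gained-class enrichment trajectory: peak time and gained-lost correlation."""
    params = SimParams(seed=seed, n_replicates=1)
    specs = make_loopspecs(params)
    exp = simulate_experiment(params, specs, timepoints=list(DEFAULT_TIMEPOINTS),
                              conditions=["treated"])
    loops = loopspecs_to_loopset(specs, params)
    by_time = {
        t: {params.chrom_name: exp.matrices[("treated", t, 0)]}
        for t in DEFAULT_TIMEPOINTS
    }
    by_class = {
        k: LoopSet(loops.df[loops.df.klass == k]) for k in ("gained", "preexisting")
    }
    curves, corr = timecourse_enrichment(by_time, by_class)
    gained = curves.loc["gained"]
    return {
        "peak_time_h": float(gained.idxmax()),
        "gained_lost_correlation": float(corr),
        "curves": curves,
    }


def matching_balance(seed: int, n_focal: int = 1000, pool_ratio: int = 8,
                     shift_sd: float = 1.0) -> dict:
    """Post-match SMDs when the pool is shifted by +1 sd on both covariates."""
    rng = _stream(seed, 60)
    n_pool = pool_ratio * n_focal
    focal = pd.DataFrame(
        {"log_size": rng.normal(0, 1, n_focal), "log_contact": rng.normal(0, 1, n_focal)}
    )
    pool = pd.DataFrame(
        {"log_size": rng.normal(shift_sd, 1, n_pool),
         "log_contact": rng.normal(shift_sd, 1, n_pool)},
        index=range(n_focal, n_focal + n_pool),
    )
    res = stratified_match(focal, pool, MatchSpec(seed=seed))
    return {
        "smd_pre": res.smd_pre.to_dict(),
        "smd_post": res.smd_post.to_dict(),
        "n_controls": int(len(res.control_indices)),
        "controls_unique": bool(
            len(set(res.control_indices)) == len(res.control_indices)
        ),
        "controls_disjoint": bool(not set(res.control_indices) & set(focal.index)),
        "n_unmatched": res.n_unmatched_focal,
    }
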