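"""Negative-binomial differential testing on deliberately unscaled counts.

This engine is shared by loop pixels, occupancy peaks and gene time courses.
Counts are modeled per feature as NB(mu, alpha) with a log link,

    log mu = X beta  (+ optional offsets, zero by default),

and **no size factors**: global signal changes between conditions are part
of the biology under study, so they must not be normalized away. Fitting is
iteratively reweighted least squares, batched across features sharing one
design matrix. Dispersion is estimated per feature by Cox–Reid-adjusted
profile maximum likelihood on a log-spaced grid, then stabilized by an
empirical-Bayes squeeze of log-dispersions toward their common value, with
per-feature shrinkage weights taken from the profile-likelihood curvature.
The squeeze borrows strength across features the way classic exact-test
count packages do; no mean-dispersion trend is fitted. Wald tests use the
normal reference, likelihood-ratio tests the chi-square reference with the
full model's dispersions in both fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .io import CountTable

__all__ = [
    "NBFit",
    "design_matrix",
    "fit_nb_glm",
    "estimate_dispersion",
    "wald_test",
    "lrt_test",
    "bh_adjust",
    "classify",
    "CLASS_RULES",
    "filter_features",
    "FILTER_RULES",
    "zscore_kmeans",
    "anchor_gene_trajectories",
]

DISPERSION_FLOOR = 1e-8


# -- design -------------------------------------------------------------------

def design_matrix(design: pd.DataFrame, factors: Sequence[str]) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for the named factors.

    Levels are sorted; the first level of each factor is the reference. The
    returned frame is samples × coefficients with readable column names like
    ``condition[treated]``.
    """
    cols = {"intercept": np.ones(len(design))}
    for f in factors:
        if f not in design.columns:
            raise ValueError(f"factor {f!r} not in design")
        levels = sorted(design[f].astype(str).unique())
        for lev in levels[1:]:
            cols[f"{f}[{lev}]"] = (design[f].astype(str) == lev).to_numpy(float)
    X = pd.DataFrame(cols, index=design.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns via QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[k] for k in range(X.shape[1]) if abs(r[k, k]) < 1e-10]
        raise ValueError(f"rank-deficient design; aliased columns: {bad}")
    return X


# -- batched IRLS -------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-feature NB log-likelihood; Poisson limit below the dispersion floor."""
    mu = np.maximum(mu, 1e-12)
    alpha = np.asarray(alpha, dtype=float)[:, None]
    poisson = y * np.log(mu) - mu - gammaln(y + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        inv = 1.0 / alpha
        nb = (
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    use_poisson = np.broadcast_to(alpha < 1e-7, nb.shape)
    return np.where(use_poisson, poisson, nb).sum(axis=1)


def _batched_irls(
    Y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray | float = 0.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs for all features at once (shared X, per-feature alpha).

    Returns (beta [f×p], cov [f×p×p], loglik [f], converged [f]).
    """
    f, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, float), (f,))
    off = np.broadcast_to(np.asarray(offset, float), (f, n))
    mu = np.maximum(Y.astype(float), 0.5)
    if beta0 is not None:
        eta = beta0 @ X.T + off
        mu = np.exp(np.clip(eta, -30, 30))
    beta = np.zeros((f, p)) if beta0 is None else beta0.copy()
    converged = np.zeros(f, dtype=bool)
    active = np.ones(f, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        m = mu[idx]
        a = alpha[idx][:, None]
        W = m / (1.0 + a * m)
        eta = np.log(m)
        z = eta - off[idx] + (Y[idx] - m) / m
        XtWX = np.einsum("sp,fs,sq->fpq", X, W, X)
        XtWz = np.einsum("sp,fs,fs->fp", X, W, z)
        try:
            new_beta = np.linalg.solve(XtWX + 1e-10 * np.eye(p), XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover
            break
        delta = np.abs(new_beta - beta[idx]).max(axis=1)
        beta[idx] = new_beta
        eta_new = np.clip(new_beta @ X.T + off[idx], -30, 30)
        mu[idx] = np.exp(eta_new)
        done = delta < tol
        converged[idx[done]] = True
        active[idx[done]] = False
    W = mu / (1.0 + alpha[:, None] * mu)
    XtWX = np.einsum("sp,fs,sq->fpq", X, W, X)
    cov = np.linalg.inv(XtWX + 1e-10 * np.eye(p))
    ll = _nb_loglik(Y, mu, alpha)
    return beta, cov, ll, converged


@dataclass
class NBFit:
    """Per-feature NB GLM fits sharing one design matrix."""

    coef: pd.DataFrame  # natural-log scale, features × coefficients
    se: pd.DataFrame
    dispersion: pd.Series
    loglik: pd.Series
    converged: pd.Series
    design_columns: list[str]
    base_mean: pd.Series
    all_zero: pd.Series

    @property
    def n_coef(self) -> int:
        return len(self.design_columns)


def estimate_dispersion(
    counts: pd.DataFrame,
    X: pd.DataFrame | np.ndarray,
    shrink: bool = True,
    grid_size: int = 44,
    grid_range: tuple[float, float] = (DISPERSION_FLOOR, 30.0),
) -> pd.Series:
    """Per-feature NB dispersion by Cox–Reid adjusted profile ML, EB-squeezed.

    For each feature the adjusted profile log-likelihood
    ``ll(alpha) − ½ log det(XᵀWX)`` is evaluated on a log-spaced alpha grid
    (GLM refit at every point, batched), maximized by quadratic
    interpolation around the grid argmax. With ``shrink=True`` log
    dispersions are then squeezed toward their precision-weighted common
    value, with each feature's sampling variance taken from the local
    curvature of its profile; features with flat profiles (little
    information) move furthest. Estimates are floored at 1e-8. This is not
    a mean-dispersion-trend estimator: the prior is a single common value.
    """
    Xa = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Y = counts.to_numpy(float)
    f = Y.shape[0]
    nonzero = Y.sum(axis=1) > 0
    lgrid = np.log(np.geomspace(grid_range[0], grid_range[1], grid_size))
    apl = np.full((f, grid_size), -np.inf)
    beta_ws: np.ndarray | None = None
    for k, la in enumerate(lgrid):
        alpha = np.full(f, np.exp(la))
        beta, cov, ll, _ = _batched_irls(Y, Xa, alpha, beta0=beta_ws)
        beta_ws = beta
        _, neg_logdet = np.linalg.slogdet(cov)  # cov = (XtWX)^-1
        apl[:, k] = ll + 0.5 * neg_logdet
    best = np.argmax(apl, axis=1)
    log_alpha = lgrid[best].copy()
    curv = np.full(f, 1.0)
    step = lgrid[1] - lgrid[0]
    interior = (best > 0) & (best < grid_size - 1)
    ii = np.flatnonzero(interior)
    y0 = apl[ii, best[ii] - 1]
    y1 = apl[ii, best[ii]]
    y2 = apl[ii, best[ii] + 1]
    denom = y0 - 2 * y1 + y2
    ok = denom < -1e-12
    shift = np.zeros(len(ii))
    shift[ok] = 0.5 * (y0 - y2)[ok] / denom[ok]
    log_alpha[ii] += np.clip(shift, -1, 1) * step
    curv[ii] = np.maximum(-denom / step**2, 1e-4)  # -d²apl/dlogα²
    curv[~interior] = 1e-4
    if shrink and nonzero.sum() >= 3:
        s2 = 1.0 / curv  # per-feature sampling variance of log alpha-hat
        s2 = np.clip(s2, 1e-3, 1e4)
        # common dispersion: argmax of the pooled adjusted profile likelihood
        # (summing across features avoids the selection bias of averaging
        # per-feature maxima, many of which sit on the grid floor)
        pooled = apl[nonzero].sum(axis=0)
        kbest = int(np.argmax(pooled))
        common = lgrid[kbest]
        if 0 < kbest < grid_size - 1:
            p0, p1, p2 = pooled[kbest - 1 : kbest + 2]
            den = p0 - 2 * p1 + p2
            if den < -1e-12:
                common += np.clip(0.5 * (p0 - p2) / den, -1, 1) * step
        # between-feature variance (DerSimonian-Laird) around the common value
        use = nonzero
        w = 1.0 / s2[use]
        q = np.sum(w * (log_alpha[use] - common) ** 2)
        df = use.sum()
        c = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
        post = (tau2 * log_alpha + s2 * common) / (tau2 + s2)
        log_alpha = np.where(nonzero, post, log_alpha)
    out = np.exp(log_alpha)
    out = np.clip(out, DISPERSION_FLOOR, None)
    out[~nonzero] = DISPERSION_FLOOR
    return pd.Series(out, index=counts.index, name="dispersion")


def fit_nb_glm(
    counts: pd.DataFrame | CountTable,
    X: pd.DataFrame,
    offsets: np.ndarray | float = 0.0,
    dispersions: pd.Series | np.ndarray | None = None,
) -> NBFit:
    """Fit per-feature NB GLMs with log link and fixed (zero) offsets.

    ``counts`` is features × samples; ``X`` samples × coefficients (see
    :func:`design_matrix`, which also rejects rank-deficient designs).
    Features with all-zero counts are flagged and excluded from testing but
    retained in the output. When ``dispersions`` is not given it is
    estimated by :func:`estimate_dispersion`.
    """
    if isinstance(counts, CountTable):
        counts = counts.counts
    if list(counts.columns) != list(X.index):
        raise ValueError("count columns and design rows must align")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    n, p = X.shape
    if n - p < 1:
        raise ValueError("need at least one residual degree of freedom")
    if isinstance(X, pd.DataFrame):
        design_matrix_check = np.linalg.matrix_rank(X.to_numpy())
        if design_matrix_check < p:
            raise ValueError("rank-deficient design matrix")
    if dispersions is None:
        dispersions = estimate_dispersion(counts, X)
    alpha = np.asarray(dispersions, dtype=float)
    Y = counts.to_numpy(float)
    Xa = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    beta, cov, ll, converged = _batched_irls(Y, Xa, alpha)
    se = np.sqrt(np.maximum(np.einsum("fpp->fp", cov.copy()), 0.0))
    all_zero = Y.sum(axis=1) == 0
    cols = list(X.columns) if isinstance(X, pd.DataFrame) else [f"b{k}" for k in range(p)]
    idx = counts.index
    return NBFit(
        coef=pd.DataFrame(beta, index=idx, columns=cols),
        se=pd.DataFrame(se, index=idx, columns=cols),
        dispersion=pd.Series(alpha, index=idx),
        loglik=pd.Series(ll, index=idx),
        converged=pd.Series(converged & ~all_zero, index=idx),
        design_columns=cols,
        base_mean=pd.Series(Y.mean(axis=1), index=idx, name="base_mean"),
        all_zero=pd.Series(all_zero, index=idx),
    )


def wald_test(fit: NBFit, coefficient: str) -> pd.DataFrame:
    """Two-sided normal Wald test of one coefficient.

    Returns base mean, log2 fold change (coefficient rescaled from natural
    log), SE, z statistic, p value and BH-adjusted p. All-zero features get
    NaN statistics.
    """
    if coefficient not in fit.design_columns:
        raise KeyError(f"coefficient {coefficient!r} not in fit")
    beta = fit.coef[coefficient].to_numpy()
    se = fit.se[coefficient].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    excluded = fit.all_zero.to_numpy()
    z = np.where(excluded, np.nan, z)
    p = np.where(excluded, np.nan, p)
    ln2 = np.log(2.0)
    out = pd.DataFrame(
        {
            "base_mean": fit.base_mean,
            "log2fc": beta / ln2,
            "lfc_se": se / ln2,
            "stat": z,
            "pvalue": p,
        },
        index=fit.coef.index,
    )
    out["padj"] = bh_adjust(out.pvalue)
    return out


def lrt_test(fit_full: NBFit, fit_reduced: NBFit) -> pd.DataFrame:
    """Likelihood-ratio test of nested designs, chi-square reference.

    The reduced fit must have been computed with the full model's
    dispersions (pass ``dispersions=fit_full.dispersion`` when fitting) so
    both log-likelihoods share one dispersion per feature.
    """
    df = fit_full.n_coef - fit_reduced.n_coef
    if df <= 0:
        raise ValueError("reduced design must be strictly nested in full")
    if not np.allclose(fit_full.dispersion, fit_reduced.dispersion):
        raise ValueError("LRT requires the same dispersion in both fits")
    stat = np.maximum(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = stats.chi2.sf(stat, df)
    excluded = fit_full.all_zero.to_numpy()
    stat = np.where(excluded, np.nan, stat)
    p = np.where(excluded, np.nan, p)
    out = pd.DataFrame(
        {"base_mean": fit_full.base_mean, "stat": stat, "df": df, "pvalue": p},
        index=fit_full.coef.index,
    )
    out["padj"] = bh_adjust(out.pvalue)
    return out


def bh_adjust(pvalues: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjustment; NaNs pass through."""
    arr = np.asarray(pvalues, dtype=float)
    out = np.full(arr.shape, np.nan)
    m = ~np.isnan(arr)
    if m.any():
        out[m] = multipletests(arr[m], method="fdr_bh")[1]
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="padj")
    return out


@dataclass(frozen=True)
class ClassRule:
    """Threshold rule mapping a differential table to gained/lost/static."""

    padj_max: float
    lfc_abs_min: float = 0.0
    up_label: str = "gained"
    down_label: str = "lost"


CLASS_RULES: dict[str, ClassRule] = {
    # loops: padj < 0.1, sign of LFC splits gained/lost
    "loop_default": ClassRule(0.1, 0.0),
    # genes per timepoint: padj < 0.05 and |log2FC| > 2
    "gene_timepoint": ClassRule(0.05, 2.0, "up", "down"),
    # occupancy peaks (CTCF/YAP1-style): padj < 0.05 and |log2FC| > 1
    "peak_default": ClassRule(0.05, 1.0, "increased", "decreased"),
    # relaxed significance for low signal-to-noise factors
    "peak_rad21": ClassRule(0.1, 1.0, "increased", "decreased"),
}


def classify(results: pd.DataFrame, rule: str | ClassRule = "loop_default") -> pd.Series:
    """Label each feature by the named threshold preset.

    Features failing either threshold (or with NaN padj) are ``static``;
    the three labels always partition the table.
    """
    r = CLASS_RULES[rule] if isinstance(rule, str) else rule
    padj = results["padj"].to_numpy()
    lfc = results["log2fc"].to_numpy()
    sig = (padj < r.padj_max) & (np.abs(lfc) > r.lfc_abs_min) & ~np.isnan(padj)
    labels = np.where(sig & (lfc > 0), r.up_label, np.where(sig, r.down_label, "static"))
    return pd.Series(labels, index=results.index, name="klass")


@dataclass(frozen=True)
class FilterRule:
    min_count: float | None = None
    min_samples: int | None = None
    min_mean: float | None = None


FILTER_RULES: dict[str, FilterRule] = {
    # genes: at least 50 raw counts in >= 4 samples (boundary inclusive)
    "gene_default": FilterRule(min_count=50, min_samples=4),
    # lenient variant: >= 10 counts in >= 4 samples
    "gene_lenient": FilterRule(min_count=10, min_samples=4),
    # peaks: mean count >= 15 across all samples (counts are unscaled)
    "peak_default": FilterRule(min_mean=15),
}


def filter_features(
    table: CountTable, rule: str | FilterRule = "gene_default"
) -> tuple[CountTable, int]:
    """Drop low-count features by a named preset; returns (filtered, n_removed)."""
    r = FILTER_RULES[rule] if isinstance(rule, str) else rule
    arr = table.counts.to_numpy()
    keep = np.ones(arr.shape[0], dtype=bool)
    if r.min_count is not None:
        keep &= (arr >= r.min_count).sum(axis=1) >= (r.min_samples or 1)
    if r.min_mean is not None:
        keep &= arr.mean(axis=1) >= r.min_mean
    filtered = CountTable(table.counts.loc[keep], table.design)
    return filtered, int((~keep).sum())


def zscore_kmeans(
    table: CountTable,
    k: int = 3,
    time_factor: str = "time",
    n_init: int = 20,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame, pd.DataFrame]:
    """Cluster replicate-averaged, z-scored log count profiles with k-means.

    Counts are log2(x+1)-transformed, averaged across replicates within each
    level of ``time_factor``, z-scored per feature (zero-variance features
    map to the zero vector), and clustered with ``k`` centers, ``n_init``
    restarts and a fixed seed. Returns (labels, centroids, z profiles).
    """
    log = np.log2(table.counts.to_numpy(float) + 1.0)
    times = table.design[time_factor].astype(str)
    levels = list(dict.fromkeys(times))  # keep design order
    prof = np.column_stack([log[:, (times == t).to_numpy()].mean(axis=1) for t in levels])
    mean = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (prof - mean) / sd, 0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
    labels = pd.Series(km.labels_, index=table.counts.index, name="cluster")
    centroids = pd.DataFrame(km.cluster_centers_, columns=levels)
    zdf = pd.DataFrame(z, index=table.counts.index, columns=levels)
    return labels, centroids, zdf


def anchor_gene_trajectories(
    lfc_by_time: pd.DataFrame,
    gene_classes: pd.Series,
    test_class: str = "anchor_gained",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class median log2FC curves plus one-sample t-tests for one class.

    ``lfc_by_time`` is genes × timepoints (log2 treated/control). For the
    tested class a one-sample t-test of mean log2FC ≠ 0 is run per
    timepoint and BH-adjusted across timepoints, with significance stars at
    0.05 / 0.01 / 0.001.
    """
    classes = gene_classes.reindex(lfc_by_time.index)
    medians = lfc_by_time.groupby(classes).median()
    medians.index.name = "klass"
    sub = lfc_by_time.loc[classes == test_class]
    rows = []
    for t in lfc_by_time.columns:
        vals = sub[t].dropna().to_numpy()
        if len(vals) >= 2 and np.std(vals) > 0:
            stat, p = stats.ttest_1samp(vals, 0.0)
        elif len(vals) >= 2 and np.allclose(vals, 0.0):
            stat, p = 0.0, 1.0  # identically zero effects carry no evidence
        else:
            stat, p = np.nan, np.nan
        rows.append({"time": t, "n": len(vals), "stat": stat, "pvalue": p})
    tests = pd.DataFrame(rows).set_index("time")
    tests["padj"] = bh_adjust(tests.pvalue.to_numpy())
    tests["stars"] = [
        "***" if q < 0.001 else "**" if q < 0.01 else "*" if q < 0.05 else ""
        for q in tests.padj.fillna(1.0)
    ]
    return medians, tests
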