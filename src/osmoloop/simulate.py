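"""Synthetic Hi-C, occupancy and expression data with known ground truth.

The generator emulates the statistical structure of a hyperosmotic-stress
time-course experiment:

* a distance-decay Poisson contact background, λ(d) = A·(1 + d/d0)^(−α);
* chromatin loops as multiplicative enrichments on that background — a
  Gaussian focal kernel at the loop pixel, a weak domain square between the
  anchors, and stripes along the square's borders;
* three loop classes with condition/time-dependent amplitude trajectories:
  *preexisting* loops collapse on treatment and partially recover late,
  *gained* loops appear de novo, peak at 1 h and decay by 24 h, *static*
  loops do not respond;
* occupancy peaks that lose signal globally on treatment but are
  preferentially retained at gained-loop anchors;
* negative-binomial gene counts with late induction at gained-anchor genes.

The focal kernel multiplies the background by ``1 + (a − 1)·g(r)/σ²`` with
``g`` a unit-peak Gaussian truncated at 3σ, so the center multiplier equals
the amplitude ``a`` at σ = 1 and the integrated added signal is independent
of σ: punctateness (σ) redistributes a fixed amount of loop signal between
the focal pixel and its surroundings, which is the phenomenology the
aggregate analyses are meant to detect.

All randomness flows from one master seed through named child streams, so
every output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ContactMatrix, CountTable, GenomeSpec, LoopSet

__all__ = [
    "SimParams",
    "LoopSpec",
    "TruthTable",
    "SimulatedExperiment",
    "simulate_background",
    "inject_loops",
    "simulate_experiment",
    "make_loopspecs",
    "make_differential_loopspecs",
    "loopspecs_to_loopset",
    "make_gene_truth",
    "simulate_rna_counts",
    "simulate_peaks",
    "simulate_promoters",
    "DEFAULT_TIMEPOINTS",
    "GAINED_TRAJECTORY",
    "PREEXISTING_TRAJECTORY",
]

#: Treatment time course in hours (0 h, 10 min, 30 min, 1 h, 3 h, 6 h, 12 h, 24 h).
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 1 / 6, 0.5, 1.0, 3.0, 6.0, 12.0, 24.0)

#: Gained loops: absent at 0 h, peak at 1 h, decay by 24 h but stay above baseline.
GAINED_TRAJECTORY: dict[float, float] = {
    0.0: 1.0, 1 / 6: 2.5, 0.5: 4.0, 1.0: 5.0, 3.0: 4.0, 6.0: 3.0, 12.0: 2.0, 24.0: 1.5,
}

#: Pre-existing loops: collapse by the first treated point, partial recovery from 3 h.
PREEXISTING_TRAJECTORY: dict[float, float] = {
    0.0: 5.0, 1 / 6: 1.5, 0.5: 1.4, 1.0: 1.3, 3.0: 2.0, 6.0: 2.5, 12.0: 3.0, 24.0: 3.5,
}

STATIC_AMPLITUDE = 4.0


@dataclass(frozen=True)
class SimParams:
    """Global simulation parameters.

    ``decay_amplitude`` (A, expected counts at distance 0), ``decay_scale``
    (d0, bins) and ``decay_exponent`` (α) set the contact background
    λ(d) = A·(1 + d/d0)^(−α). The defaults give loop-pixel background means
    of roughly 7–25 counts at 250 kb–1 Mb spans, comparable to a deeply
    sequenced 10-kb map. ``depth_log_sd`` is the SD of the per-sample
    log-normal depth factor that induces extra-Poisson replicate variance.
    """

    chrom_name: str = "chrS"
    chrom_length: int = 20_000_000
    resolution: int = 10_000
    decay_amplitude: float = 120.0
    decay_exponent: float = 1.0
    decay_scale: float = 5.0
    n_replicates: int = 4
    depth_log_sd: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decay_amplitude <= 0 or self.decay_exponent < 0 or self.decay_scale <= 0:
            raise ValueError("invalid decay parameters")

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec((self.chrom_name,), (self.chrom_length,), self.resolution)

    @property
    def n_bins(self) -> int:
        return self.genome.n_bins(self.chrom_name)

    def decay(self, d: np.ndarray | float) -> np.ndarray | float:
        return self.decay_amplitude * (1.0 + np.asarray(d, dtype=float) / self.decay_scale) ** (
            -self.decay_exponent
        )


@dataclass(frozen=True)
class LoopSpec:
    """One simulated loop: anchor bins, class, and its enrichment anatomy."""

    i: int
    j: int
    klass: str  # preexisting | gained | static
    amplitudes: Mapping[float, float]  # treated-condition center multiplier per time
    control_amplitude: float | None = None  # defaults to the earliest treated value
    sigma: float = 1.0
    domain_factor: float = 1.3
    stripe_factor: float = 1.15

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("loop requires i < j")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be non-negative")
        if self.domain_factor < 1 or self.stripe_factor < 1:
            raise ValueError("domain/stripe factors must be >= 1")

    def amplitude(self, condition: str, time: float) -> float:
        if condition == "control":
            if self.control_amplitude is not None:
                return self.control_amplitude
            return self.amplitudes[min(self.amplitudes)]
        try:
            return self.amplitudes[time]
        except KeyError:
            raise KeyError(f"no amplitude defined at time {time}")


@dataclass
class TruthTable:
    """Ground truth emitted alongside simulated data."""

    loops: pd.DataFrame
    genes: pd.DataFrame | None = None
    peaks: pd.DataFrame | None = None
    params: SimParams | None = None


@dataclass
class SimulatedExperiment:
    """Replicate contact maps per (condition, time) plus the truth table."""

    params: SimParams
    matrices: dict[tuple[str, float, int], ContactMatrix]
    truth: TruthTable
    depth_factors: dict[tuple[str, float, int], float]

    def conditions(self) -> list[str]:
        return sorted({k[0] for k in self.matrices})

    def times(self) -> list[float]:
        return sorted({k[1] for k in self.matrices})

    def sample_keys(self) -> list[tuple[str, float, int]]:
        return sorted(self.matrices, key=lambda k: (k[0], k[1], k[2]))


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named child RNG stream below 2^31 entropy words."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31)] + [int(k) for k in key]))


# -- contact maps -------------------------------------------------------------

def simulate_background(
    params: SimParams, rng: np.random.Generator | None = None, depth: float = 1.0
) -> ContactMatrix:
    """Draw a Poisson distance-decay background map, upper-triangular.

    Counts at bin distance d have mean ``depth · λ(d)``; the whole matrix is
    drawn diagonal-by-diagonal for speed.
    """
    if rng is None:
        rng = _stream(params.seed, 0)
    n = params.n_bins
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for d in range(n):
        lam = depth * float(params.decay(d))
        m = n - d
        if lam < 1e-12:
            continue
        draw = rng.poisson(lam, size=m)
        keep = draw > 0
        if keep.any():
            idx = np.arange(m)[keep]
            rows.append(idx)
            cols.append(idx + d)
            vals.append(draw[keep])
    if rows:
        b1 = np.concatenate(rows)
        b2 = np.concatenate(cols)
        c = np.concatenate(vals)
    else:  # pragma: no cover - degenerate parameters
        b1 = b2 = c = np.array([], dtype=int)
    return ContactMatrix(params.genome, params.chrom_name, b1, b2, c)


def _loop_multipliers(
    loopspecs: Sequence[LoopSpec], condition: str, time: float, n_bins: int
) -> dict[tuple[int, int], float]:
    """Sparse multiplicative enrichment field over upper-triangular pixels.

    Overlapping loop contributions compose multiplicatively.
    """
    field_: dict[tuple[int, int], float] = {}

    def mult(i: int, j: int, f: float) -> None:
        if 0 <= i <= j < n_bins and f != 1.0:
            key = (i, j)
            field_[key] = field_.get(key, 1.0) * f

    for spec in loopspecs:
        a = spec.amplitude(condition, time)
        # focal Gaussian kernel, truncated at 3 sigma, mass-conserving in sigma
        if a != 1.0:
            k = max(1, math.ceil(3 * spec.sigma))
            for di in range(-k, k + 1):
                for dj in range(-k, k + 1):
                    r2 = di * di + dj * dj
                    g = math.exp(-r2 / (2 * spec.sigma**2)) / spec.sigma**2
                    f = 1.0 + (a - 1.0) * g
                    if f > 0:
                        mult(spec.i + di, spec.j + dj, f)
        # domain square with stripe borders
        if spec.domain_factor != 1.0 or spec.stripe_factor != 1.0:
            i0, j0 = spec.i, spec.j
            for bi in range(i0, j0 + 1):
                for bj in range(max(bi, i0), j0 + 1):
                    f = spec.domain_factor
                    if bi in (i0, j0) or bj in (i0, j0):
                        f *= spec.stripe_factor
                    mult(bi, bj, f)
    return field_


def inject_loops(
    matrix: ContactMatrix,
    loopspecs: Sequence[LoopSpec],
    condition: str = "treated",
    time: float = 0.0,
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
    depth: float = 1.0,
) -> ContactMatrix:
    """Re-draw the pixels affected by the loop enrichment field.

    Each affected pixel's count is replaced by a fresh Poisson draw with mean
    ``depth · λ(d) · m(i, j)`` where m composes the focal kernel, domain and
    stripe multipliers of every loop covering the pixel. Unaffected pixels
    keep their original counts, so an all-neutral spec is an exact identity.
    """
    if params is None:
        raise ValueError("params required to recompute Poisson means")
    if rng is None:
        rng = _stream(params.seed, 1)
    field_ = _loop_multipliers(loopspecs, condition, time, matrix.n_bins)
    if not field_:
        return matrix
    n = matrix.n_bins
    keys = sorted(field_)
    ii = np.array([k[0] for k in keys], dtype=np.int64)
    jj = np.array([k[1] for k in keys], dtype=np.int64)
    lam = depth * np.asarray(params.decay(jj - ii), dtype=float) * np.array(
        [field_[k] for k in keys]
    )
    draws = rng.poisson(lam)
    tri = matrix.triples()
    old_key = tri.bin1.to_numpy() * n + tri.bin2.to_numpy()
    aff_key = ii * n + jj  # sorted because keys are sorted lexicographically
    keep = np.searchsorted(aff_key, old_key)
    keep = ~((keep < len(aff_key)) & (aff_key[np.minimum(keep, len(aff_key) - 1)] == old_key))
    nz = draws > 0
    b1 = np.concatenate([tri.bin1.to_numpy()[keep], ii[nz]])
    b2 = np.concatenate([tri.bin2.to_numpy()[keep], jj[nz]])
    c = np.concatenate([tri["count"].to_numpy()[keep], draws[nz]])
    return ContactMatrix(matrix.genome, matrix.chrom, b1, b2, c)


def simulate_experiment(
    params: SimParams,
    loopspecs: Sequence[LoopSpec],
    timepoints: Sequence[float] = (1.0,),
    conditions: Sequence[str] = ("control", "treated"),
) -> SimulatedExperiment:
    """Simulate replicate contact maps for every (condition, time) cell.

    Control maps use each loop's baseline amplitude at every time point;
    treated maps follow the loop's amplitude trajectory. Per-sample
    log-normal depth factors induce replicate-level variance. With zero
    timepoints only control replicates (at t = 0) are produced.
    """
    times = list(timepoints) if len(timepoints) else [0.0]
    conds = list(conditions) if len(timepoints) else ["control"]
    matrices: dict[tuple[str, float, int], ContactMatrix] = {}
    depths: dict[tuple[str, float, int], float] = {}
    for ci, cond in enumerate(conds):
        for ti, t in enumerate(times):
            for rep in range(params.n_replicates):
                rng = _stream(params.seed, 7, ci, ti, rep)
                depth = float(np.exp(rng.normal(0.0, params.depth_log_sd)))
                bg = simulate_background(params, rng=rng, depth=depth)
                mat = inject_loops(
                    bg, loopspecs, condition=cond, time=t, params=params, rng=rng,
                    depth=depth,
                )
                matrices[(cond, t, rep)] = mat
                depths[(cond, t, rep)] = depth
    truth = TruthTable(loops=_truth_frame(loopspecs, params), params=params)
    return SimulatedExperiment(params, matrices, truth, depths)


def _truth_frame(loopspecs: Sequence[LoopSpec], params: SimParams) -> pd.DataFrame:
    res = params.resolution
    rows = []
    for idx, s in enumerate(loopspecs):
        rows.append(
            {
                "loop_id": f"loop{idx:04d}",
                "chrom": params.chrom_name,
                "bin1": s.i,
                "bin2": s.j,
                "klass": s.klass,
                "sigma": s.sigma,
                "domain_factor": s.domain_factor,
                "stripe_factor": s.stripe_factor,
                "control_amplitude": s.amplitude("control", 0.0),
                **{f"amp_t{t:g}": a for t, a in sorted(s.amplitudes.items())},
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["span_bp"] = (df.bin2 - df.bin1) * res
    return df


def loopspecs_to_loopset(loopspecs: Sequence[LoopSpec], params: SimParams) -> LoopSet:
    """Gridded LoopSet (one-bin anchors) for a set of simulated loops."""
    res = params.resolution
    df = pd.DataFrame(
        {
            "chrom1": params.chrom_name,
            "start1": [s.i * res for s in loopspecs],
            "end1": [(s.i + 1) * res for s in loopspecs],
            "chrom2": params.chrom_name,
            "start2": [s.j * res for s in loopspecs],
            "end2": [(s.j + 1) * res for s in loopspecs],
            "klass": [s.klass for s in loopspecs],
        }
    )
    return LoopSet(df)


def _place_loops(
    params: SimParams,
    n: int,
    rng: np.random.Generator,
    span_range: tuple[int, int],
    margin: int,
    existing: list[tuple[int, int]],
    min_sep: int = 13,
) -> list[tuple[int, int]]:
    """Random loop pixels with pairwise Chebyshev separation >= min_sep bins."""
    n_bins = params.n_bins
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("could not place loops; genome too small for request")
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        i = int(rng.integers(margin, n_bins - span - margin))
        j = i + span
        ok = all(
            max(abs(i - pi), abs(j - pj)) >= min_sep for pi, pj in existing + placed
        )
        if ok:
            placed.append((i, j))
    return placed


def make_loopspecs(
    params: SimParams,
    n_gained: int = 30,
    n_preexisting: int = 30,
    n_static: int = 20,
    rng: np.random.Generator | None = None,
    sigma_gained: float = 1.0,
    sigma_preexisting: float = 2.0,
    gained_span_bins: tuple[int, int] = (30, 90),
    preexisting_span_bins: tuple[int, int] = (24, 60),
    domain_gained: float = 1.15,
    domain_preexisting: float = 1.4,
    stripe_gained: float = 1.1,
    stripe_preexisting: float = 1.25,
    shared_anchor_fraction: float = 0.5,
) -> list[LoopSpec]:
    """Default time-course loop population.

    Gained loops are longer-range, more punctate (smaller σ), and sit on
    weaker domains/stripes than pre-existing loops; about half of them are
    placed to share one anchor bin with a pre-existing loop (repurposed
    architectural nodes).
    """
    if rng is None:
        rng = _stream(params.seed, 2)
    margin = 12
    pre_pos = _place_loops(params, n_preexisting, rng, preexisting_span_bins, margin, [])
    static_pos = _place_loops(params, n_static, rng, preexisting_span_bins, margin, pre_pos)
    specs: list[LoopSpec] = []
    for i, j in pre_pos:
        specs.append(
            LoopSpec(i, j, "preexisting", dict(PREEXISTING_TRAJECTORY),
                     sigma=sigma_preexisting, domain_factor=domain_preexisting,
                     stripe_factor=stripe_preexisting)
        )
    for i, j in static_pos:
        specs.append(
            LoopSpec(i, j, "static", {t: STATIC_AMPLITUDE for t in DEFAULT_TIMEPOINTS},
                     sigma=sigma_preexisting, domain_factor=domain_preexisting,
                     stripe_factor=stripe_preexisting)
        )
    # gained loops: a fraction reuse one anchor of a pre-existing loop
    n_shared = int(round(shared_anchor_fraction * n_gained))
    occupied = pre_pos + static_pos
    gained_pos: list[tuple[int, int]] = []
    n_bins = params.n_bins
    attempts = 0
    while len(gained_pos) < n_shared:
        attempts += 1
        if attempts > 200 * n_gained + 1000:
            break
        pi, pj = pre_pos[int(rng.integers(len(pre_pos)))]
        anchor = pi if rng.random() < 0.5 else pj
        span = int(rng.integers(*gained_span_bins))
        i, j = (anchor, anchor + span) if rng.random() < 0.5 else (anchor - span, anchor)
        if not (margin <= i < j < n_bins - margin):
            continue
        # shared anchor: exempt the shared coordinate from the separation rule
        if all(
            (max(abs(i - qi), abs(j - qj)) >= 13) or (i, j) == (qi, qj)
            for qi, qj in gained_pos
        ) and all(max(abs(i - qi), abs(j - qj)) >= 5 for qi, qj in occupied + gained_pos):
            gained_pos.append((i, j))
    gained_pos += _place_loops(
        params, n_gained - len(gained_pos), rng, gained_span_bins, margin,
        occupied + gained_pos,
    )
    for i, j in gained_pos:
        specs.append(
            LoopSpec(i, j, "gained", dict(GAINED_TRAJECTORY), sigma=sigma_gained,
                     domain_factor=domain_gained, stripe_factor=stripe_gained)
        )
    return specs


def make_differential_loopspecs(
    params: SimParams,
    n_gained: int = 50,
    n_lost: int = 100,
    n_static: int = 50,
    fold: float = 3.0,
    rng: np.random.Generator | None = None,
    span_bins: tuple[int, int] = (24, 80),
    sigma: float = 1.0,
) -> list[LoopSpec]:
    """Two-condition loop population for differential testing.

    Gained loops triple their center enrichment under treatment, lost loops
    drop to a third, static loops are unchanged. Amplitudes are keyed at
    time 1.0 (the treated snapshot); control amplitude is the baseline.
    """
    if rng is None:
        rng = _stream(params.seed, 3)
    margin = 12
    pos = _place_loops(params, n_gained + n_lost + n_static, rng, span_bins, margin, [])
    specs = []
    for idx, (i, j) in enumerate(pos):
        if idx < n_gained:
            base = 2.0
            specs.append(LoopSpec(i, j, "gained", {1.0: base * fold},
                                  control_amplitude=base, sigma=sigma,
                                  domain_factor=1.0, stripe_factor=1.0))
        elif idx < n_gained + n_lost:
            base = 6.0
            specs.append(LoopSpec(i, j, "lost", {1.0: base / fold},
                                  control_amplitude=base, sigma=sigma,
                                  domain_factor=1.0, stripe_factor=1.0))
        else:
            specs.append(LoopSpec(i, j, "static", {1.0: STATIC_AMPLITUDE},
                                  control_amplitude=STATIC_AMPLITUDE, sigma=sigma,
                                  domain_factor=1.0, stripe_factor=1.0))
    return specs


# -- RNA counts ---------------------------------------------------------------

GENE_TRAJECTORIES: dict[str, dict[float, float]] = {
    # late induction at gained-anchor genes: >= 4-fold by the final timepoint
    "anchor_gained": {0.0: 1.0, 1.0: 1.0, 3.0: 1.3, 6.0: 2.0, 12.0: 3.2, 24.0: 4.5},
    "anchor_static": {0.0: 1.0, 1.0: 1.0, 3.0: 1.0, 6.0: 1.0, 12.0: 1.0, 24.0: 1.0},
    "anchor_lost": {0.0: 1.0, 1.0: 0.9, 3.0: 0.9, 6.0: 0.9, 12.0: 0.85, 24.0: 0.8},
    "off_anchor_flat": {0.0: 1.0, 1.0: 1.0, 3.0: 1.0, 6.0: 1.0, 12.0: 1.0, 24.0: 1.0},
    "off_anchor_transient": {0.0: 1.0, 1.0: 2.5, 3.0: 1.8, 6.0: 1.2, 12.0: 1.0, 24.0: 1.0},
    # sustained repression: the downregulated arm of the response
    "off_anchor_down": {0.0: 1.0, 1.0: 0.9, 3.0: 0.7, 6.0: 0.5, 12.0: 0.35, 24.0: 0.25},
}

RNA_TIMEPOINTS: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)


def make_gene_truth(
    n_per_class: Mapping[str, int] | None = None,
    rng: np.random.Generator | None = None,
    dispersion: float = 0.05,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth gene table: class, base mean, dispersion, f_g(t) trajectory."""
    if rng is None:
        rng = _stream(seed, 4)
    if n_per_class is None:
        n_per_class = {
            "anchor_gained": 60, "anchor_static": 60, "anchor_lost": 60,
            "off_anchor_flat": 240, "off_anchor_transient": 80, "off_anchor_down": 40,
        }
    rows = []
    gid = 0
    for klass, n in n_per_class.items():
        traj = GENE_TRAJECTORIES[klass]
        for _ in range(n):
            base = float(np.exp(rng.uniform(*np.log(base_mean_range))))
            rows.append(
                {"gene_id": f"gene{gid:05d}", "klass": klass, "base_mean": base,
                 "dispersion": dispersion,
                 **{f"f_t{t:g}": traj[t] for t in RNA_TIMEPOINTS}}
            )
            gid += 1
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, disp: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if disp < 1e-8:
        return rng.poisson(mu)
    size_ = 1.0 / disp
    p = size_ / (size_ + mu)
    return rng.negative_binomial(size_, p)


def simulate_rna_counts(
    truth_genes: pd.DataFrame,
    timepoints: Sequence[float] = RNA_TIMEPOINTS,
    n_replicates: int = 2,
    rep_log_sd: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> CountTable:
    """NB gene counts over the time course with a paired-replicate design.

    Mean of gene g in sample (rep r, time t) is
    ``base_g · f_g(t) · exp(b_r)`` with a per-replicate log-normal factor
    ``b_r`` constant across time (so the design's replicate term absorbs it).
    """
    if rng is None:
        rng = _stream(seed, 5)
    rep_factors = np.exp(rng.normal(0.0, rep_log_sd, size=n_replicates))
    cols = {}
    design_rows = []
    for r in range(n_replicates):
        for t in timepoints:
            f = truth_genes[f"f_t{t:g}"].to_numpy()
            mu = truth_genes.base_mean.to_numpy() * f * rep_factors[r]
            draws = np.empty(len(truth_genes), dtype=np.int64)
            for disp in np.unique(truth_genes.dispersion):
                m = truth_genes.dispersion.to_numpy() == disp
                draws[m] = _nb_draw(rng, mu[m], float(disp))
            name = f"rep{r + 1}_t{t:g}"
            cols[name] = draws
            design_rows.append({"sample": name, "replicate": f"rep{r + 1}", "time": f"t{t:g}"})
    counts = pd.DataFrame(cols, index=truth_genes.gene_id)
    design = pd.DataFrame(design_rows).set_index("sample")
    return CountTable(counts, design)


# -- occupancy peaks ----------------------------------------------------------

def simulate_peaks(
    params: SimParams,
    loopspecs: Sequence[LoopSpec],
    rng: np.random.Generator | None = None,
    n_replicates: int = 2,
    at_anchor_retention: float = 0.85,
    within_loop_retention: float = 0.35,
    base_mean_range: tuple[float, float] = (40.0, 400.0),
    dispersion: float = 0.05,
) -> tuple[CountTable, pd.DataFrame]:
    """Occupancy peak counts: global loss on treatment, retention at anchors.

    One peak per gained-loop anchor (class ``at_anchor``) and one in each
    gained loop's interior (``within_loop``); treated means are scaled by the
    class retention factor, so at-anchor peaks lose less signal than
    within-loop peaks.
    """
    if rng is None:
        rng = _stream(params.seed, 6)
    res = params.resolution
    rows = []
    pid = 0
    for s in loopspecs:
        if s.klass != "gained":
            continue
        for anchor_bin in (s.i, s.j):
            rows.append({"peak_id": f"peak{pid:05d}", "chrom": params.chrom_name,
                         "start": anchor_bin * res + res // 4,
                         "end": anchor_bin * res + res // 4 + 400,
                         "klass": "at_anchor"})
            pid += 1
        interior = int(rng.integers(s.i + 2, s.j - 1))
        rows.append({"peak_id": f"peak{pid:05d}", "chrom": params.chrom_name,
                     "start": interior * res + res // 3,
                     "end": interior * res + res // 3 + 400,
                     "klass": "within_loop"})
        pid += 1
    peaks = pd.DataFrame(rows)
    base = np.exp(rng.uniform(*np.log(base_mean_range), size=len(peaks)))
    retention = np.where(peaks.klass == "at_anchor", at_anchor_retention,
                         within_loop_retention)
    peaks["true_log2fc"] = np.log2(retention)
    cols = {}
    design_rows = []
    for cond, scale in (("control", np.ones(len(peaks))), ("treated", retention)):
        for r in range(n_replicates):
            name = f"{cond}_rep{r + 1}"
            cols[name] = _nb_draw(rng, base * scale, dispersion)
            design_rows.append({"sample": name, "replicate": f"rep{r + 1}",
                                "condition": cond})
    counts = pd.DataFrame(cols, index=peaks.peak_id)
    design = pd.DataFrame(design_rows).set_index("sample")
    return CountTable(counts, design), peaks


def simulate_promoters(
    params: SimParams,
    loopspecs: Sequence[LoopSpec],
    rng: np.random.Generator | None = None,
    p_overlap: Mapping[str, float] | None = None,
    n_background: int = 100,
    width: int = 2000,
) -> pd.DataFrame:
    """Promoter BED intervals with class-dependent anchor overlap probabilities.

    Defaults place promoters at gained-loop anchors far more often than at
    lost/static anchors, mirroring the promoter bias of stress-induced
    anchors; background promoters fall at random positions.
    """
    if rng is None:
        rng = _stream(params.seed, 8)
    if p_overlap is None:
        p_overlap = {"gained": 0.674, "preexisting": 0.231, "lost": 0.231, "static": 0.328}
    res = params.resolution
    rows = []
    for s in loopspecs:
        p = p_overlap.get(s.klass, 0.0)
        for anchor_bin in (s.i, s.j):
            if rng.random() < p:
                start = anchor_bin * res + int(rng.integers(0, res - width))
                rows.append({"chrom": params.chrom_name, "start": start,
                             "end": start + width, "name": f"prom_anchor_{len(rows)}"})
    for k in range(n_background):
        start = int(rng.integers(0, params.chrom_length - width))
        rows.append({"chrom": params.chrom_name, "start": start, "end": start + width,
                     "name": f"prom_bg_{k}"})
    return pd.DataFrame(rows)
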