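"""Data model and text I/O for binned contact matrices, loops, intervals and counts.

Conventions used throughout the package:

* all genomic intervals are 0-based, half-open (BED/BEDPE semantics);
* bin index = ``floor(position / resolution)``; a midpoint lying exactly on a
  bin boundary belongs to the higher (right-hand) bin;
* contact matrices are stored per chromosome as sparse upper-triangular
  integer counts; queries are symmetric, ``contact(i, j) == contact(j, i)``;
* inter-chromosomal entries are rejected at read time.

On-disk formats are plain text: two-column ``chrom.sizes``, tab-separated
contact triples with a ``#resolution=<bp>`` header, BEDPE, BED, and
feature-by-sample count tables with a matching sample-design table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GenomeSpec",
    "ContactMatrix",
    "LoopSet",
    "CountTable",
    "ContactParseError",
    "WindowOutOfBounds",
    "read_chromsizes",
    "write_chromsizes",
    "read_contacts",
    "write_contacts",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "snap_to_grid",
    "balance_matrix",
]

BEDPE_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


class ContactParseError(ValueError):
    """Malformed record in a contact/interval text file."""


class WindowOutOfBounds(ValueError):
    """A requested square window extends beyond the chromosome's bin grid."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names, lengths (bp) and the fixed bin size (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise ValueError(f"non-positive length for {name}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.resolution)  # ceil division


class ContactMatrix:
    """Sparse upper-triangular binned contact counts for one chromosome.

    ``entries`` are canonicalized to ``bin_i <= bin_j`` with duplicate keys
    summed; the matrix is interpreted symmetrically.
    """

    def __init__(
        self,
        genome: GenomeSpec,
        chrom: str,
        bin1: np.ndarray | Sequence[int],
        bin2: np.ndarray | Sequence[int],
        count: np.ndarray | Sequence[int],
        balance_weights: np.ndarray | None = None,
    ):
        n = genome.n_bins(chrom)
        bin1 = np.asarray(bin1, dtype=np.int64)
        bin2 = np.asarray(bin2, dtype=np.int64)
        count = np.asarray(count)
        if count.size and (np.any(count < 0) or not np.allclose(count, np.round(count))):
            bad = int(np.flatnonzero((count < 0) | (count != np.round(count)))[0])
            raise ContactParseError(
                f"invalid count {count[bad]} at record ({bin1[bad]}, {bin2[bad]})"
            )
        count = count.astype(np.int64)
        if bin1.size and (bin1.min() < 0 or bin2.min() < 0 or max(bin1.max(), bin2.max()) >= n):
            bad = int(
                np.flatnonzero((bin1 < 0) | (bin2 < 0) | (bin1 >= n) | (bin2 >= n))[0]
            )
            raise ContactParseError(
                f"bin out of range for {chrom} ({n} bins): record "
                f"({bin1[bad]}, {bin2[bad]}, {count[bad]})"
            )
        lo = np.minimum(bin1, bin2)
        hi = np.maximum(bin1, bin2)
        mat = sp.coo_matrix((count, (lo, hi)), shape=(n, n))
        mat.sum_duplicates()
        self.genome = genome
        self.chrom = chrom
        self._upper = mat.tocsr()
        self._sym: sp.csr_matrix | None = None
        self.balance_weights = balance_weights

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_dense(cls, genome: GenomeSpec, chrom: str, dense: np.ndarray) -> "ContactMatrix":
        iu = np.triu_indices_from(dense)
        vals = np.asarray(dense)[iu]
        keep = vals != 0
        return cls(genome, chrom, iu[0][keep], iu[1][keep], vals[keep])

    @property
    def n_bins(self) -> int:
        return self._upper.shape[0]

    @property
    def nnz(self) -> int:
        return self._upper.nnz

    def triples(self) -> pd.DataFrame:
        coo = self._upper.tocoo()
        df = pd.DataFrame({"bin1": coo.row, "bin2": coo.col, "count": coo.data})
        return df.sort_values(["bin1", "bin2"], ignore_index=True)

    def _symmetric(self) -> sp.csr_matrix:
        if self._sym is None:
            upper = self._upper
            self._sym = (upper + sp.triu(upper, k=1).T).tocsr()
        return self._sym

    def get(self, i: int, j: int) -> int:
        lo, hi = (i, j) if i <= j else (j, i)
        return int(self._upper[lo, hi])

    def window(self, center_i: int, center_j: int, half_width: int) -> np.ndarray:
        """Dense ``(2w+1)²`` block of raw counts centered on a pixel.

        Raises :class:`WindowOutOfBounds` when the block does not fit inside
        the bin grid; absent entries are zero.
        """
        w = int(half_width)
        n = self.n_bins
        if (
            center_i - w < 0
            or center_j - w < 0
            or center_i + w >= n
            or center_j + w >= n
        ):
            raise WindowOutOfBounds(
                f"window ±{w} at ({center_i}, {center_j}) exceeds [0, {n}) bins"
            )
        sym = self._symmetric()
        block = sym[center_i - w : center_i + w + 1, center_j - w : center_j + w + 1]
        return np.asarray(block.todense(), dtype=float)

    def row_sums(self) -> np.ndarray:
        return np.asarray(self._symmetric().sum(axis=1)).ravel()


@dataclass
class LoopSet:
    """Paired-anchor loops plus a metadata table aligned row-for-row.

    The anchor table always carries the six BEDPE columns; any further
    columns (per-sample counts, statistics, class labels) ride along as
    metadata and survive BEDPE round trips.
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=BEDPE_COLS))

    def __post_init__(self) -> None:
        missing = [c for c in BEDPE_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"LoopSet missing columns {missing}")
        df = self.df.reset_index(drop=True).copy()
        for c in ("start1", "end1", "start2", "end2"):
            df[c] = df[c].astype(np.int64)
        bad = (df.start1 >= df.end1) | (df.start2 >= df.end2)
        if bad.any():
            raise ValueError(f"degenerate anchor interval at row {int(np.flatnonzero(bad)[0])}")
        # canonical anchor order: anchor1 genomically <= anchor2
        flip = (df.chrom1 > df.chrom2) | ((df.chrom1 == df.chrom2) & (df.start1 > df.start2))
        if flip.any():
            a = df.loc[flip, ["chrom1", "start1", "end1"]].to_numpy()
            b = df.loc[flip, ["chrom2", "start2", "end2"]].to_numpy()
            df.loc[flip, ["chrom1", "start1", "end1"]] = b
            df.loc[flip, ["chrom2", "start2", "end2"]] = a
            for c in ("start1", "end1", "start2", "end2"):
                df[c] = df[c].astype(np.int64)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def spans(self) -> np.ndarray:
        """bp distance between anchor midpoints (intra-chromosomal loops)."""
        mid1 = (self.df.start1 + self.df.end1).to_numpy() // 2
        mid2 = (self.df.start2 + self.df.end2).to_numpy() // 2
        return np.abs(mid2 - mid1)

    def intra(self) -> np.ndarray:
        return (self.df.chrom1 == self.df.chrom2).to_numpy()

    def anchor_bins(self, resolution: int) -> tuple[np.ndarray, np.ndarray]:
        """Bin index of each anchor midpoint (boundary midpoints go right)."""
        mid1 = (self.df.start1 + self.df.end1).to_numpy() // 2
        mid2 = (self.df.start2 + self.df.end2).to_numpy() // 2
        return mid1 // resolution, mid2 // resolution

    def with_metadata(self, **cols) -> "LoopSet":
        df = self.df.copy()
        for k, v in cols.items():
            df[k] = np.asarray(v)
        return LoopSet(df)


@dataclass
class CountTable:
    """Integer feature-by-sample counts with a sample design table.

    ``design`` rows correspond one-to-one with the count columns and hold the
    per-sample factors (any subset of replicate / condition / time).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.design.index):
            raise ValueError("design rows must match count columns one-to-one")
        if self.design.shape[1] == 0:
            raise ValueError("design must carry at least one factor")

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


# -- chrom.sizes --------------------------------------------------------------

def read_chromsizes(path: str | Path, resolution: int) -> GenomeSpec:
    """Parse a two-column ``name<TAB>length`` file into a :class:`GenomeSpec`."""
    names: list[str] = []
    lengths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ContactParseError(f"{path}:{lineno}: expected two columns")
            try:
                length = int(parts[1])
            except ValueError:
                raise ContactParseError(f"{path}:{lineno}: non-integer length {parts[1]!r}")
            if length <= 0:
                raise ContactParseError(f"{path}:{lineno}: non-positive length")
            names.append(parts[0])
            lengths.append(length)
    if not names:
        raise ContactParseError(f"{path}: no chromosomes found")
    return GenomeSpec(tuple(names), tuple(lengths), resolution)


def write_chromsizes(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in zip(genome.chrom_names, genome.chrom_lengths):
            fh.write(f"{name}\t{length}\n")


# -- contact triples ----------------------------------------------------------

def read_contacts(path: str | Path, genome: GenomeSpec) -> dict[str, ContactMatrix]:
    """Read tab-separated ``chrom bin1 bin2 count`` triples, one matrix per chromosome.

    A ``#resolution=<bp>`` header, when present, is checked against the
    genome's resolution. Duplicate keys are summed, entries canonicalized to
    upper-triangular. Chromosomes absent from the file yield empty matrices.
    """
    per_chrom: dict[str, list[list[int]]] = {c: [[], [], []] for c in genome.chrom_names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#resolution="):
                    res = int(line.split("=", 1)[1])
                    if res != genome.resolution:
                        raise ContactParseError(
                            f"{path}: file resolution {res} != genome resolution "
                            f"{genome.resolution}"
                        )
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ContactParseError(f"{path}:{lineno}: expected 4 columns")
            chrom = parts[0]
            if chrom not in per_chrom:
                raise ContactParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                b1, b2, c = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError:
                raise ContactParseError(f"{path}:{lineno}: non-integer field")
            if c < 0:
                raise ContactParseError(f"{path}:{lineno}: negative count {c}")
            per_chrom[chrom][0].append(b1)
            per_chrom[chrom][1].append(b2)
            per_chrom[chrom][2].append(c)
    out = {}
    for chrom, (b1, b2, c) in per_chrom.items():
        out[chrom] = ContactMatrix(genome, chrom, b1, b2, c)
    return out


def write_contacts(matrices: Mapping[str, ContactMatrix], path: str | Path) -> None:
    mats = list(matrices.values())
    if not mats:
        raise ValueError("no matrices to write")
    resolution = mats[0].genome.resolution
    with open(path, "w") as fh:
        fh.write(f"#resolution={resolution}\n")
        for chrom in matrices:
            tri = matrices[chrom].triples()
            for b1, b2, c in tri.itertuples(index=False):
                fh.write(f"{chrom}\t{b1}\t{b2}\t{c}\n")


# -- BEDPE / BED --------------------------------------------------------------

def read_bedpe(path: str | Path) -> LoopSet:
    """Read BEDPE (0-based half-open); extra columns are kept as metadata."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 6:
        raise ContactParseError(f"{path}: BEDPE needs >= 6 columns")
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    names = list(BEDPE_COLS)
    header = first.startswith("#") and first.lstrip("#").split("\t")[:6] == BEDPE_COLS
    if header:
        names = first.lstrip("#").split("\t")
        df.columns = names
    else:
        extra = [f"col{i}" for i in range(7, df.shape[1] + 1)]
        df.columns = names + extra
    return LoopSet(df)


def write_bedpe(loops: LoopSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, loops.df.columns)) + "\n")
        loops.df.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 3:
        raise ContactParseError(f"{path}: BED needs >= 3 columns")
    cols = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, df.shape[1] + 1)]
    if df.shape[1] >= 4:
        cols[3] = "name"
    df.columns = cols
    if (df.start >= df.end).any():
        raise ContactParseError(f"{path}: interval with start >= end")
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# -- count tables -------------------------------------------------------------

def read_counts(counts_path: str | Path, design_path: str | Path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    design.index = design.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return CountTable(counts.astype(np.int64), design.loc[counts.columns])


def write_counts(table: CountTable, counts_path: str | Path, design_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.design.to_csv(design_path, sep="\t")


# -- grid operations ----------------------------------------------------------

def snap_to_grid(loops: LoopSet, resolution: int) -> LoopSet:
    """Replace each anchor by the single resolution-sized bin containing its midpoint.

    Midpoints on a bin boundary are assigned to the right-hand bin
    (``floor(mid / resolution)``). Idempotent on already-gridded loops.
    """
    b1, b2 = loops.anchor_bins(resolution)
    df = loops.df.copy()
    df["start1"] = b1 * resolution
    df["end1"] = (b1 + 1) * resolution
    df["start2"] = b2 * resolution
    df["end2"] = (b2 + 1) * resolution
    return LoopSet(df)


def balance_matrix(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative proportional fitting (ICE-style) balancing for display matrices.

    Multiplies rows/columns by weights until the maximum relative deviation
    of non-masked row sums from their mean is below ``tol``. Bins with zero
    coverage are masked (weight NaN) and contribute no balanced signal.
    Differential statistics elsewhere in the package always use raw counts;
    balancing exists for visualization-style pileups only.
    """
    if matrix.nnz == 0:
        raise ValueError("cannot balance an all-zero matrix")
    sym = matrix._symmetric().astype(float)
    n = sym.shape[0]
    mask = np.asarray(sym.sum(axis=1)).ravel() > 0
    b = np.ones(n)
    b[~mask] = 0.0
    for _ in range(max_iter):
        s = np.asarray((sym.multiply(b).T.multiply(b)).sum(axis=1)).ravel()
        s_active = s[mask]
        mean = s_active.mean()
        dev = np.abs(s_active / mean - 1.0).max()
        if dev < tol:
            break
        adj = np.ones(n)
        adj[mask] = np.sqrt(s[mask] / mean)
        b = b / adj
    weights = np.where(mask, b, np.nan)
    tri = matrix.triples()
    out = ContactMatrix(
        matrix.genome, matrix.chrom, tri.bin1.to_numpy(), tri.bin2.to_numpy(),
        tri["count"].to_numpy(), balance_weights=weights,
    )
    return out
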