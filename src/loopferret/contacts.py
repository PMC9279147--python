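"""Contact-matrix container, triplet-TSV I/O, balancing and normalisation.

A :class:`ContactMatrix` holds the binned, symmetric contact counts of a
single chromosome (or captured region) together with a per-bin exclusion
mask and, after balancing, per-bin correction weights.  Matrices are stored
densely in memory -- the package targets single-locus, desk-scale maps of a
few hundred to a few thousand bins -- and sparsely on disk as an
upper-triangle triplet TSV.

Balancing uses the symmetric Sinkhorn-Knopp fixed point, which at
convergence yields the same balanced matrix as Knight-Ruiz normalisation:
``w_i * C_ij * w_j`` has uniform row sums on unmasked bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "MatrixParseError",
    "BalanceError",
    "read_matrix",
    "write_matrix",
    "kr_balance",
    "expected_by_distance",
    "oe_transform",
    "equalize_coverage",
]


class MatrixParseError(ValueError):
    """Raised on malformed triplet-TSV input; message names the line."""


class BalanceError(RuntimeError):
    """Raised when matrix balancing fails to converge."""


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome/region.

    Parameters
    ----------
    chrom:
        Chromosome / region name.
    bin_size:
        Bin width in bp.
    counts:
        Dense symmetric nonnegative ``(n_bins, n_bins)`` array.
    mask:
        Per-bin boolean, ``True`` = excluded bin.
    weights:
        Per-bin balancing factors, NaN on masked bins; ``None`` before
        balancing.
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")
        if self.mask is None:
            self.mask = np.zeros(self.n_bins, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_bins,):
            raise ValueError("mask length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            chrom=self.chrom,
            bin_size=self.bin_size,
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            weights=None if self.weights is None else self.weights.copy(),
        )

    def total(self) -> float:
        """Total contact count, each pair (and the diagonal) counted once."""
        return float((self.counts.sum() + np.trace(self.counts)) / 2.0)

    def balanced(self) -> np.ndarray:
        """Balanced matrix ``w_i * C_ij * w_j`` with NaN on masked bins."""
        if self.weights is None:
            raise ValueError("matrix has no weights; run kr_balance first")
        b = self.counts * np.outer(self.weights, self.weights)
        b[self.mask, :] = np.nan
        b[:, self.mask] = np.nan
        return b


@dataclass
class ExpectedProfile:
    """Mean balanced signal per genomic separation (in bins)."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, d: int) -> float:
        return float(self.values[d])


# ---------------------------------------------------------------------------
# I/O: triplet TSV dialect
#   header:  "#bin_size=<bp> #n_bins=<n> #chrom=<name> [#kind=...]"
#   optional "#masked=<comma separated bin indices>"
#   body:    "bin_i<TAB>bin_j<TAB>count" (upper triangle, 0-based)
# ---------------------------------------------------------------------------

def write_matrix(matrix: ContactMatrix, path) -> None:
    """Write the upper triangle of ``matrix`` in the triplet TSV dialect."""
    n = matrix.n_bins
    with open(path, "w") as fh:
        fh.write(
            f"#bin_size={matrix.bin_size} #n_bins={n} #chrom={matrix.chrom}\n"
        )
        if matrix.mask.any():
            idx = ",".join(str(i) for i in np.flatnonzero(matrix.mask))
            fh.write(f"#masked={idx}\n")
        iu = np.triu_indices(n)
        vals = matrix.counts[iu]
        nz = vals != 0
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_matrix(path) -> ContactMatrix:
    """Read a triplet-TSV matrix, mirroring the stored triangle."""
    bin_size = n_bins = None
    chrom = None
    masked: list[int] = []
    counts = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.split():
                    tok = tok.lstrip("#")
                    if "=" not in tok:
                        continue
                    key, val = tok.split("=", 1)
                    if key == "bin_size":
                        bin_size = int(val)
                    elif key == "n_bins":
                        n_bins = int(val)
                    elif key == "chrom":
                        chrom = val
                    elif key == "masked" and val:
                        masked = [int(x) for x in val.split(",")]
                continue
            if n_bins is None or bin_size is None or chrom is None:
                raise MatrixParseError(
                    f"line {lineno}: data before complete header"
                )
            if counts is None:
                counts = np.zeros((n_bins, n_bins))
            parts = line.split("\t")
            if len(parts) != 3:
                raise MatrixParseError(f"line {lineno}: expected 3 columns")
            try:
                i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise MatrixParseError(f"line {lineno}: {exc}") from exc
            if not (0 <= i < n_bins and 0 <= j < n_bins):
                raise MatrixParseError(
                    f"line {lineno}: bin index out of range [0, {n_bins})"
                )
            if v < 0:
                raise MatrixParseError(f"line {lineno}: negative count")
            counts[i, j] = v
            counts[j, i] = v
    if n_bins is None or bin_size is None or chrom is None:
        raise MatrixParseError("missing or incomplete header line")
    if counts is None:
        counts = np.zeros((n_bins, n_bins))
    mask = np.zeros(n_bins, dtype=bool)
    mask[masked] = True
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts, mask=mask)


# ---------------------------------------------------------------------------
# Balancing and normalisation
# ---------------------------------------------------------------------------

def kr_balance(
    matrix: ContactMatrix, tol: float = 1e-8, max_iter: int = 1000
) -> tuple[ContactMatrix, int]:
    """Balance ``matrix`` so unmasked balanced row sums are uniform.

    Symmetric Sinkhorn iteration: ``w <- w * sqrt(T / rowsum(w C w))`` with
    target row sum ``T`` equal to the mean unmasked raw marginal.  Bins with
    zero marginal are masked before iterating.

    Returns a new matrix with ``weights`` filled, and the iteration count.
    Raises :class:`BalanceError` if the relative row-sum spread has not
    dropped below ``tol`` after ``max_iter`` iterations.
    """
    out = matrix.copy()
    marginal = out.counts.sum(axis=1)
    out.mask = out.mask | (marginal <= 0)
    keep = ~out.mask
    if keep.sum() < 2:
        raise BalanceError("fewer than 2 unmasked bins")
    sub = out.counts[np.ix_(keep, keep)]
    target = marginal[keep].mean()
    x = np.ones(keep.sum())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rows = x * (sub @ x)
        dev = np.abs(rows / target - 1.0).max()
        if dev <= tol:
            break
        x *= np.sqrt(target / rows)
    else:
        raise BalanceError(
            f"no convergence after {max_iter} iterations (spread {dev:.3g})"
        )
    weights = np.full(out.n_bins, np.nan)
    weights[keep] = x
    out.weights = weights
    return out, n_iter


def expected_by_distance(matrix: ContactMatrix) -> ExpectedProfile:
    """Mean balanced signal over unmasked pixel pairs at each separation."""
    b = matrix.balanced()
    n = matrix.n_bins
    e = np.full(n, np.nan)
    for d in range(n):
        diag = np.diagonal(b, offset=d)
        ok = ~np.isnan(diag)
        if ok.any():
            e[d] = diag[ok].mean()
    return ExpectedProfile(e)


def oe_transform(
    matrix: ContactMatrix, profile: ExpectedProfile | None = None
) -> np.ndarray:
    """Observed/expected matrix; NaN where masked or expected undefined."""
    if profile is None:
        profile = expected_by_distance(matrix)
    b = matrix.balanced()
    n = matrix.n_bins
    i, j = np.indices((n, n))
    e = profile.values[np.abs(i - j)]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = b / e
    oe[e == 0] = np.nan
    return oe


def equalize_coverage(
    a: ContactMatrix, b: ContactMatrix
) -> tuple[ContactMatrix, ContactMatrix]:
    """Divide each matrix by its own total count so both totals equal 1."""
    if a.n_bins != b.n_bins or a.bin_size != b.bin_size or a.chrom != b.chrom:
        raise ValueError("matrices must share shape, bin size and chrom")
    out = []
    for m in (a, b):
        t = m.total()
        if t <= 0:
            raise ValueError("cannot equalize a zero-total matrix")
        c = m.copy()
        c.counts = c.counts / t
        c.weights = None
        out.append(c)
    return out[0], out[1]
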