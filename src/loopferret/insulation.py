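"""Insulation scores, boundary calls and mappability-based filtering.

The insulation score of bin *i* is the mean balanced signal in the square
window ``[i-w, i-1] x [i+1, i+w]`` straddling the diagonal, expressed on a
log2 scale relative to the track mean.  TAD boundaries are strict local
minima of the track; the boundary score (BS) is the depth of the minimum
below the lower of its two flanking local maxima.  Bins near extremely
low-mappability regions -- identified by a two-component Gaussian mixture
on the raw matrix marginals -- are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .contacts import ContactMatrix

__all__ = [
    "InsulationTrack",
    "BoundaryCall",
    "MappabilityMask",
    "insulation_score",
    "call_boundaries",
    "fit_mappability_mask",
    "write_insulation_bedgraph",
    "write_boundaries_bed",
]


@dataclass
class InsulationTrack:
    window_bins: int
    values: np.ndarray  # log2 insulation, NaN where invalid
    valid: np.ndarray
    bin_size: int = 0
    chrom: str = ""

    def __post_init__(self) -> None:
        if self.window_bins < 1:
            raise ValueError("window_bins must be >= 1")


@dataclass
class BoundaryCall:
    bin: int
    boundary_score: float
    filtered: bool = False

    def __post_init__(self) -> None:
        if self.boundary_score < 0:
            raise ValueError("boundary_score must be >= 0")


@dataclass
class MappabilityMask:
    low_mappability: np.ndarray
    means: tuple[float, float] = (0.0, 0.0)
    variances: tuple[float, float] = (1.0, 1.0)
    mixing_weights: tuple[float, float] = (0.5, 0.5)
    exclusion_radius_bp: int = 125_000

    def __post_init__(self) -> None:
        if self.exclusion_radius_bp < 0:
            raise ValueError("exclusion_radius_bp must be >= 0")

    def exclusion_radius_bins(self, bin_size: int) -> int:
        return int(round(self.exclusion_radius_bp / bin_size))


def insulation_score(matrix: ContactMatrix, window_bp: int) -> InsulationTrack:
    """Per-bin insulation on log2 scale relative to the track mean.

    Bins within ``w`` of the matrix edge, or whose window square is more
    than half masked, are invalid.
    """
    if window_bp % matrix.bin_size != 0:
        raise ValueError("window_bp must be a multiple of bin_size")
    w = window_bp // matrix.bin_size
    n = matrix.n_bins
    if w >= n / 2:
        raise ValueError("window too large for matrix")
    b = matrix.balanced()
    raw = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(w, n - w):
        win = b[i - w : i, i + 1 : i + w + 1]
        defined = ~np.isnan(win)
        if defined.sum() <= win.size * 0.5:
            continue
        m = win[defined].mean()
        if m > 0:
            raw[i] = m
            valid[i] = True
    if not valid.any():
        return InsulationTrack(w, raw, valid, matrix.bin_size, matrix.chrom)
    norm = raw[valid].mean()
    values = np.full(n, np.nan)
    values[valid] = np.log2(raw[valid] / norm)
    return InsulationTrack(w, values, valid, matrix.bin_size, matrix.chrom)


def _valid_segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of valid bins as half-open (start, stop)."""
    segs = []
    i = 0
    n = len(valid)
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def _flank_max(
    vals: np.ndarray, pos: int, lo: int, hi: int, step: int, prominence: float
) -> float:
    """Walk from ``pos`` in direction ``step`` to the nearest flanking local
    maximum and return its value.  Dips smaller than ``prominence`` below the
    running maximum are walked through, so stochastic micro-wiggles on a
    valley floor do not truncate the flank; the walk stops at the first real
    intervening descent (or the segment edge)."""
    best = vals[pos]
    i = pos + step
    while lo <= i < hi:
        if vals[i] > best:
            best = vals[i]
        elif best - vals[i] > prominence:
            break
        i += step
    return best


def call_boundaries(
    track: InsulationTrack,
    mask: MappabilityMask | None = None,
    min_prominence: float = 0.5,
) -> list[BoundaryCall]:
    """Boundary at every strict local minimum of the valid track.

    Plateau minima are reported at their leftmost bin.  BS is the depth to
    the lower of the two nearest flanking local maxima, where maxima are
    located with a small prominence tolerance ``min_prominence`` (log2
    units) so that noise wiggles do not pass for flanking peaks.  Calls
    within the mappability exclusion radius of a low-mappability bin are
    flagged ``filtered`` (and normally dropped from summaries).
    """
    if not track.valid.any():
        raise ValueError("track has no valid bins")
    vals = track.values
    calls: list[BoundaryCall] = []
    for lo, hi in _valid_segments(track.valid):
        i = lo
        while i < hi:
            j = i
            while j + 1 < hi and vals[j + 1] == vals[i]:
                j += 1
            left_ok = i > lo and vals[i - 1] > vals[i]
            right_ok = j < hi - 1 and vals[j + 1] > vals[i]
            if left_ok and right_ok:
                lmax = _flank_max(vals, i, lo, hi, -1, min_prominence)
                rmax = _flank_max(vals, j, lo, hi, +1, min_prominence)
                bs = min(lmax, rmax) - vals[i]
                calls.append(BoundaryCall(bin=i, boundary_score=max(bs, 0.0)))
            i = j + 1
    if mask is not None and mask.low_mappability.any():
        if track.bin_size <= 0:
            raise ValueError("track needs bin_size for mappability filtering")
        r = mask.exclusion_radius_bins(track.bin_size)
        low = np.flatnonzero(mask.low_mappability)
        for c in calls:
            if np.any(np.abs(low - c.bin) <= r):
                c.filtered = True
    return calls


def fit_mappability_mask(
    matrix: ContactMatrix, exclusion_radius_bp: int = 125_000, random_state: int = 0
) -> MappabilityMask:
    """Two-component GMM on log1p raw marginals; flags the low component.

    If the fitted component means differ by less than one pooled standard
    deviation there is no separable low-mappability class and nothing is
    flagged.
    """
    n = matrix.n_bins
    if n < 10:
        raise ValueError("need at least 10 bins")
    marg = np.log1p(matrix.counts.sum(axis=1))
    gmm = GaussianMixture(
        n_components=2, n_init=5, random_state=random_state, covariance_type="full"
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gmm.fit(marg.reshape(-1, 1))
    means = gmm.means_.ravel()
    variances = gmm.covariances_.ravel()
    weights = gmm.weights_.ravel()
    lo = int(np.argmin(means))
    pooled_sd = float(np.sqrt(weights @ variances))
    flags = np.zeros(n, dtype=bool)
    if abs(means[0] - means[1]) >= pooled_sd and pooled_sd > 0:
        post = gmm.predict_proba(marg.reshape(-1, 1))
        flags = post[:, lo] > 0.5
    return MappabilityMask(
        low_mappability=flags,
        means=(float(means[0]), float(means[1])),
        variances=(float(variances[0]), float(variances[1])),
        mixing_weights=(float(weights[0]), float(weights[1])),
        exclusion_radius_bp=exclusion_radius_bp,
    )


def write_insulation_bedgraph(track: InsulationTrack, path) -> None:
    bs = track.bin_size or 1
    with open(path, "w") as fh:
        for i in np.flatnonzero(track.valid):
            fh.write(
                f"{track.chrom}\t{i * bs}\t{(i + 1) * bs}\t{track.values[i]:.6g}\n"
            )


def write_boundaries_bed(
    calls: list[BoundaryCall], track: InsulationTrack, path
) -> None:
    bs = track.bin_size or 1
    with open(path, "w") as fh:
        for k, c in enumerate(calls):
            if c.filtered:
                continue
            fh.write(
                f"{track.chrom}\t{c.bin * bs}\t{(c.bin + 1) * bs}\t"
                f"boundary_{k}\t{round(1000 * c.boundary_score)}\t.\n"
            )
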