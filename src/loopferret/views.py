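"""Locus-level comparison views: subtraction z-score maps and virtual 4C.

Subtraction maps compare two coverage-equalized contact matrices pixel by
pixel; each difference is converted to a z-score against the other pixels
of the same sub-diagonal, i.e. against interactions at the same genomic
distance.  Virtual 4C extracts the one-dimensional contact profile of a
viewpoint from a balanced matrix, normalises it to unit total signal and
quantifies the share falling inside a window of interest (for example an
enhancer region across a boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactMatrix, equalize_coverage

__all__ = ["SubtractionMap", "Virtual4CProfile", "subtraction_map", "virtual_4c",
           "write_zscore_tsv", "write_v4c_bedgraph"]


@dataclass
class SubtractionMap:
    z: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    degenerate_diagonals: np.ndarray  # True where sigma == 0 or < 3 pixels
    source_a: str = ""
    source_b: str = ""


@dataclass
class Virtual4CProfile:
    viewpoint: tuple[int, int]  # half-open bin range
    values: np.ndarray  # normalised, NaN where undefined
    exclusion_bins: int
    quant_window: tuple[int, int] | None = None
    quant_share: float | None = None


def subtraction_map(a: ContactMatrix, b: ContactMatrix) -> SubtractionMap:
    """Per-diagonal z-scores of the coverage-equalized difference a - b.

    Pixels where either input bin is masked are undefined.  Diagonals with
    zero spread or fewer than 3 defined pixels get z = 0 and are flagged.
    """
    a_eq, b_eq = equalize_coverage(a, b)
    n = a_eq.n_bins
    diff = a_eq.counts - b_eq.counts
    defined = ~(a_eq.mask | b_eq.mask)
    pair_ok = np.outer(defined, defined)
    z = np.zeros((n, n))
    mu = np.zeros(n)
    sigma = np.zeros(n)
    degenerate = np.zeros(n, dtype=bool)
    for d in range(n):
        idx = (np.arange(n - d), np.arange(d, n))
        ok = pair_ok[idx]
        vals = diff[idx][ok]
        if len(vals) < 3:
            degenerate[d] = True
            continue
        m = vals.mean()
        s = vals.std()  # population normalisation
        mu[d] = m
        sigma[d] = s
        if s == 0:
            degenerate[d] = True
            continue
        zd = np.zeros(n - d)
        zd[ok] = (diff[idx][ok] - m) / s
        z[idx] = zd
        z[idx[1], idx[0]] = zd
    z[~pair_ok] = 0.0
    return SubtractionMap(z=z, mu=mu, sigma=sigma, degenerate_diagonals=degenerate,
                          source_a=a.chrom, source_b=b.chrom)


def virtual_4c(
    matrix: ContactMatrix,
    viewpoint: tuple[int, int],
    exclusion_bins: int = 2,
    quant_window: tuple[int, int] | None = None,
) -> Virtual4CProfile:
    """Normalised contact profile of a viewpoint (half-open bin range).

    ``v(i)`` is the mean balanced signal between the viewpoint bins and bin
    *i*; bins within ``exclusion_bins`` of the viewpoint are undefined; the
    defined profile is normalised to sum 1.  ``quant_window`` (half-open bin
    range) yields the share of normalised signal inside the window.
    """
    lo, hi = viewpoint
    n = matrix.n_bins
    if not (0 <= lo < hi <= n):
        raise ValueError("viewpoint out of range")
    vp_bins = np.arange(lo, hi)
    if matrix.mask[vp_bins].all():
        raise ValueError("viewpoint fully masked")
    b = matrix.balanced()
    rows = b[vp_bins, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        v = np.nanmean(rows, axis=0)  # all-NaN columns stay NaN
    v[max(lo - exclusion_bins, 0) : min(hi + exclusion_bins, n)] = np.nan
    defined = ~np.isnan(v)
    total = v[defined].sum()
    if total <= 0:
        raise ValueError("profile has no signal outside the viewpoint")
    v = v / total
    share = None
    if quant_window is not None:
        qlo, qhi = quant_window
        if not (0 <= qlo < qhi <= n):
            raise ValueError("quant_window out of range")
        qv = v[qlo:qhi]
        share = float(np.nansum(qv))
    return Virtual4CProfile(
        viewpoint=viewpoint,
        values=v,
        exclusion_bins=exclusion_bins,
        quant_window=quant_window,
        quant_share=share,
    )


def write_zscore_tsv(zmap: SubtractionMap, bin_size: int, chrom: str, path) -> None:
    n = zmap.z.shape[0]
    with open(path, "w") as fh:
        fh.write(f"#bin_size={bin_size} #n_bins={n} #chrom={chrom} #kind=zscore\n")
        iu = np.triu_indices(n)
        vals = zmap.z[iu]
        nz = vals != 0
        for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:.6g}\n")


def write_v4c_bedgraph(profile: Virtual4CProfile, bin_size: int, chrom: str, path) -> None:
    with open(path, "w") as fh:
        for i, v in enumerate(profile.values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")
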