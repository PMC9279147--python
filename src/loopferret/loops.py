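"""Loop-anchor and loop-pair classification, strengths and statistics.

Anchors are classified by whether they carry a CBS oriented toward each of
their loops: *convergent-only* anchors have a properly oriented CBS for
every loop direction they engage, *nonconvergent* anchors loop in at least
one direction for which they lack a directional CBS, and *no-CTCF* anchors
carry no CBS at all.  Loops are convergent when anchor1 carries a forward
CBS and anchor2 a reverse CBS (motifs facing each other), and are further
split into five categories depending on what else their anchors do: a
convergent loop sharing an anchor with an opposite-direction nonconvergent
loop is *convergent-associated* (its partner is
*nonconvergent-associated*) -- the paired-loop signature produced by loop
interference, where a stalled cohesin stabilises a second complex on the
other side of the anchor.

Loop strength is the aggregate-peak-analysis log2 enrichment of the
observed/expected signal at the loop pixel over the corner background of
its window.  The statistical scheme is: chi-squared omnibus on the
category x bidirectional table with pairwise post-hoc chi-squared tests,
Kruskal-Wallis across loop categories with pairwise Mann-Whitney U
post-hocs, all post-hoc P values Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import CBSAnnotation

__all__ = [
    "Loop",
    "AnchorRecord",
    "LoopRecord",
    "classify_anchors",
    "classify_loops",
    "bidirectional_stats",
    "loop_strength",
    "aggregate_loops",
    "corner_association",
    "call_loops_simple",
    "read_loops_bedpe",
    "write_loops_bedpe",
    "CONVERGENT_ONLY",
    "NONCONVERGENT",
    "NO_CTCF",
    "LOOP_CATEGORIES",
]

CONVERGENT_ONLY = "convergent_only"
NONCONVERGENT = "nonconvergent"
NO_CTCF = "no_ctcf"

LOOP_CATEGORIES = (
    "single_sided_convergent",
    "double_sided_convergent",
    "convergent_associated",
    "nonconvergent",
    "nonconvergent_associated",
)


@dataclass
class Loop:
    """A pair of anchor intervals (bp, 0-based half-open, anchor1 lower)."""

    chrom: str
    anchor1_start: int
    anchor1_end: int
    anchor2_start: int
    anchor2_end: int
    resolution_bp: int
    loop_id: str = ""

    def __post_init__(self) -> None:
        if self.anchor1_start >= self.anchor2_start:
            raise ValueError("anchor1 must be the lower-coordinate anchor")
        if self.anchor1_end > self.anchor2_start:
            raise ValueError("anchors must not overlap")

    @property
    def distance_bp(self) -> int:
        return self.anchor2_start - self.anchor1_start

    def pixel(self) -> tuple[int, int]:
        """Loop pixel (bin_i, bin_j) at the loop's own resolution."""
        i = (self.anchor1_start + self.anchor1_end) // 2 // self.resolution_bp
        j = (self.anchor2_start + self.anchor2_end) // 2 // self.resolution_bp
        return i, j


@dataclass
class AnchorRecord:
    """A merged loop anchor with its attached loops and CBSs."""

    start: int
    end: int
    rightward_loops: list[str] = field(default_factory=list)
    leftward_loops: list[str] = field(default_factory=list)
    cbs: list[CBSAnnotation] = field(default_factory=list)
    category: str = NO_CTCF
    bidirectional: bool = False

    @property
    def has_forward(self) -> bool:
        return any(c.orientation == "forward" for c in self.cbs)

    @property
    def has_reverse(self) -> bool:
        return any(c.orientation == "reverse" for c in self.cbs)


@dataclass
class LoopRecord:
    loop_id: str
    convergent: bool
    category: str
    strength: float | None = None
    at_tad_corner: bool = False

    def __post_init__(self) -> None:
        conv_cats = {"single_sided_convergent", "double_sided_convergent",
                     "convergent_associated"}
        if self.category in conv_cats and not self.convergent:
            raise ValueError("convergent category on a nonconvergent loop")
        if self.category in {"nonconvergent", "nonconvergent_associated"} and self.convergent:
            raise ValueError("nonconvergent category on a convergent loop")


# ---------------------------------------------------------------------------
# Anchor classification
# ---------------------------------------------------------------------------

def _merge_intervals(
    intervals: list[tuple[int, int]], pad: int
) -> list[tuple[int, int]]:
    """Merge intervals that overlap once padded by ``pad`` on each side."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s - pad < merged[-1][1] + pad:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def classify_anchors(
    loops: list[Loop],
    cbs: list[CBSAnnotation],
    anchor_merge_bp: int | None = None,
) -> list[AnchorRecord]:
    """Merge loop anchors and classify them by CBS orientation.

    Anchors whose intervals overlap after padding by ``anchor_merge_bp``
    (default: one bin at the loops' resolution) become one record.  An
    anchor is *rightward* for a loop when it is anchor1.
    """
    if not loops:
        return []
    if anchor_merge_bp is None:
        anchor_merge_bp = max(l.resolution_bp for l in loops)
    if anchor_merge_bp < 0:
        raise ValueError("anchor_merge_bp must be >= 0")

    intervals = []
    for l in loops:
        intervals.append((l.anchor1_start, l.anchor1_end))
        intervals.append((l.anchor2_start, l.anchor2_end))
    merged = _merge_intervals(intervals, anchor_merge_bp)
    records = [AnchorRecord(start=s, end=e) for s, e in merged]
    starts = np.array([r.start for r in records])
    ends = np.array([r.end for r in records])

    def _find(s: int, e: int) -> AnchorRecord:
        k = int(np.searchsorted(starts, s, side="right") - 1)
        if k < 0 or e > ends[k]:
            raise ValueError(f"anchor [{s}, {e}) not covered by merged records")
        return records[k]

    for l in loops:
        _find(l.anchor1_start, l.anchor1_end).rightward_loops.append(l.loop_id)
        _find(l.anchor2_start, l.anchor2_end).leftward_loops.append(l.loop_id)

    for r in records:
        r.cbs = [c for c in cbs if c.start < r.end and c.end > r.start]
        r.bidirectional = bool(r.rightward_loops) and bool(r.leftward_loops)
        if not r.cbs:
            r.category = NO_CTCF
        elif (r.rightward_loops and not r.has_forward) or (
            r.leftward_loops and not r.has_reverse
        ):
            r.category = NONCONVERGENT
        else:
            r.category = CONVERGENT_ONLY
    return records


# ---------------------------------------------------------------------------
# Loop classification
# ---------------------------------------------------------------------------

def classify_loops(
    loops: list[Loop], anchors: list[AnchorRecord]
) -> list[LoopRecord]:
    """Assign each loop one of the five categories.

    Precedence for convergent loops satisfying several conditions:
    convergent_associated > double_sided_convergent > single_sided.
    """
    by_id = {l.loop_id: l for l in loops}
    anchor_of: dict[tuple[str, str], AnchorRecord] = {}
    for a in anchors:
        for lid in a.rightward_loops:
            anchor_of[(lid, "right")] = a
        for lid in a.leftward_loops:
            anchor_of[(lid, "left")] = a
    for l in loops:
        if (l.loop_id, "right") not in anchor_of or (l.loop_id, "left") not in anchor_of:
            raise ValueError(f"loop {l.loop_id} has unclassified anchors")

    convergent: dict[str, bool] = {}
    for l in loops:
        a1 = anchor_of[(l.loop_id, "right")]
        a2 = anchor_of[(l.loop_id, "left")]
        convergent[l.loop_id] = a1.has_forward and a2.has_reverse

    records = []
    for l in loops:
        a1 = anchor_of[(l.loop_id, "right")]
        a2 = anchor_of[(l.loop_id, "left")]
        # loops the two anchors engage in the direction opposite to this loop
        opposite = [
            by_id[lid] for lid in a1.leftward_loops
        ] + [by_id[lid] for lid in a2.rightward_loops]
        opp_conv = any(convergent[o.loop_id] for o in opposite)
        opp_nonconv = any(not convergent[o.loop_id] for o in opposite)
        if convergent[l.loop_id]:
            if opp_nonconv:
                cat = "convergent_associated"
            elif opp_conv:
                cat = "double_sided_convergent"
            else:
                cat = "single_sided_convergent"
        else:
            cat = "nonconvergent_associated" if opp_conv else "nonconvergent"
        records.append(LoopRecord(loop_id=l.loop_id, convergent=convergent[l.loop_id],
                                  category=cat))
    return records


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def chi2_test(table: np.ndarray) -> tuple[float, float, int]:
    """Pearson chi-squared without continuity correction: (stat, p, df)."""
    res = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted P values."""
    if not pvalues:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])


def bidirectional_stats(anchors: list[AnchorRecord]) -> dict:
    """Bidirectional-anchor fractions per category with the testing scheme.

    Omnibus chi-squared on the category x bidirectional table (2 df when
    all three categories are populated), then pairwise post-hoc chi-squared
    on the 2x2 subtables with BH correction.  Categories with no anchors
    are dropped with a warning.
    """
    cats = [CONVERGENT_ONLY, NONCONVERGENT, NO_CTCF]
    counts = {c: [0, 0] for c in cats}  # [bidirectional, unidirectional]
    for a in anchors:
        counts[a.category][0 if a.bidirectional else 1] += 1
    present = [c for c in cats if sum(counts[c]) > 0]
    for c in cats:
        if c not in present:
            warnings.warn(f"category {c} has no anchors; dropped from tests")
    if len(present) < 2:
        raise ValueError("omnibus test needs anchors in at least two categories")

    fractions = {c: counts[c][0] / sum(counts[c]) for c in present}
    table = np.array([counts[c] for c in present])
    if (table.sum(axis=0) == 0).any():
        omnibus = (0.0, 1.0, len(present) - 1)
    else:
        omnibus = chi2_test(table)

    pairs, raw_p, stats_ = [], [], []
    for i in range(len(present)):
        for j in range(i + 1, len(present)):
            sub = np.array([counts[present[i]], counts[present[j]]])
            if (sub.sum(axis=0) == 0).any():
                s, p = 0.0, 1.0
            else:
                s, p, _ = chi2_test(sub)
            pairs.append((present[i], present[j]))
            stats_.append(s)
            raw_p.append(p)
    adj = bh_adjust(raw_p)
    return {
        "fractions": fractions,
        "counts": {c: tuple(counts[c]) for c in present},
        "omnibus_chi2": omnibus[0],
        "omnibus_p": omnibus[1],
        "omnibus_df": omnibus[2],
        "posthoc": [
            {"pair": pair, "chi2": s, "p_raw": p, "p_adj": q}
            for pair, s, p, q in zip(pairs, stats_, raw_p, adj)
        ],
    }


# ---------------------------------------------------------------------------
# Loop strength / aggregation
# ---------------------------------------------------------------------------

def loop_strength(
    loop: Loop,
    oe: np.ndarray,
    window_bins: int = 10,
    center_bins: int = 3,
) -> float | None:
    """APA-style log2 enrichment of the loop pixel over corner background.

    Compares the mean obs/exp in a ``center_bins``-sided square around the
    loop pixel with the mean over the lower-left and upper-right corner
    squares of the ``(2 * window_bins + 1)``-sided window (the corners along
    the diagonal direction).  None when either region is fully undefined.
    """
    i, j = loop.pixel()
    n = oe.shape[0]
    w, c = window_bins, center_bins
    if i - w < 0 or j + w >= n or j - w < 0 or i + w >= n:
        raise ValueError("window exceeds matrix bounds")
    h = c // 2
    center = oe[i - h : i - h + c, j - h : j - h + c]
    ll = oe[i + w - c + 1 : i + w + 1, j - w : j - w + c]
    ur = oe[i - w : i - w + c, j + w - c + 1 : j + w + 1]
    corners = np.concatenate([ll.ravel(), ur.ravel()])
    if np.all(np.isnan(center)) or np.all(np.isnan(corners)):
        return None
    num = np.nanmean(center)
    den = np.nanmean(corners)
    if not np.isfinite(num) or not np.isfinite(den) or den <= 0 or num <= 0:
        return None
    return float(np.log2(num / den))


def aggregate_loops(
    loops: list[Loop], oe: np.ndarray, window_bins: int = 10
) -> tuple[np.ndarray, int]:
    """Elementwise mean obs/exp window over usable loops ("APA" matrix)."""
    n = oe.shape[0]
    w = window_bins
    windows = []
    for l in loops:
        i, j = l.pixel()
        if i - w < 0 or i + w >= n or j - w < 0 or j + w >= n:
            continue
        windows.append(oe[i - w : i + w + 1, j - w : j + w + 1])
    if not windows:
        raise ValueError("no usable loops for aggregation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        agg = np.nanmean(np.stack(windows), axis=0)
    return agg, len(windows)


def corner_association(
    loop_records: list[LoopRecord],
    loops: list[Loop],
    boundary_bins: list[int],
    bin_size: int,
    zone_radius_bins: int = 2,
) -> dict:
    """TAD-corner association and anchor-distance comparison per category.

    A loop sits at a TAD corner when both anchors fall within
    ``zone_radius_bins`` of a boundary bin.  Distances are compared with a
    Kruskal-Wallis omnibus across the populated categories followed by
    BH-corrected pairwise Mann-Whitney U tests (only when the omnibus is
    significant at 0.05).
    """
    by_id = {l.loop_id: l for l in loops}
    bounds = np.asarray(sorted(boundary_bins)) if boundary_bins else None
    for r in loop_records:
        l = by_id[r.loop_id]
        i, j = l.pixel()
        if bounds is None:
            r.at_tad_corner = False
        else:
            r.at_tad_corner = bool(
                np.min(np.abs(bounds - i)) <= zone_radius_bins
                and np.min(np.abs(bounds - j)) <= zone_radius_bins
            )

    fractions = {}
    distances: dict[str, list[int]] = {c: [] for c in LOOP_CATEGORIES}
    for c in LOOP_CATEGORIES:
        recs = [r for r in loop_records if r.category == c]
        if recs and bounds is not None:
            fractions[c] = sum(r.at_tad_corner for r in recs) / len(recs)
        distances[c] = [by_id[r.loop_id].distance_bp for r in recs]

    populated = [c for c in LOOP_CATEGORIES if len(distances[c]) > 0]
    result = {"corner_fractions": fractions, "distances": distances,
              "kruskal_p": None, "posthoc": []}
    groups = [distances[c] for c in populated if len(distances[c]) > 0]
    if len(groups) >= 2 and any(
        len(set(g1) | set(g2)) > 1 for g1 in groups for g2 in groups
    ):
        try:
            kw = stats.kruskal(*groups)
            result["kruskal_p"] = float(kw.pvalue)
        except ValueError:  # all values identical
            result["kruskal_p"] = 1.0
    if result["kruskal_p"] is not None and result["kruskal_p"] < 0.05:
        pairs, raw = [], []
        for i in range(len(populated)):
            for j in range(i + 1, len(populated)):
                u = stats.mannwhitneyu(
                    distances[populated[i]], distances[populated[j]],
                    alternative="two-sided",
                )
                pairs.append((populated[i], populated[j]))
                raw.append(float(u.pvalue))
        adj = bh_adjust(raw)
        result["posthoc"] = [
            {"pair": p, "p_raw": r, "p_adj": q} for p, r, q in zip(pairs, raw, adj)
        ]
    return result


# ---------------------------------------------------------------------------
# Simple loop caller (closes the synthetic pipeline; not an FDR caller)
# ---------------------------------------------------------------------------

def call_loops_simple(
    oe: np.ndarray,
    bin_size: int,
    threshold: float = 3.0,
    radius_bins: int = 2,
    min_offdiag_bins: int = 3,
    chrom: str = "sim",
) -> list[Loop]:
    """Local obs/exp maxima above threshold become single-bin loops.

    A pixel is called when it exceeds ``threshold``, lies more than 2 bins
    off the diagonal, and is the maximum of its Chebyshev neighbourhood of
    ``radius_bins`` (non-max suppression; ties and conflicts resolve in
    favour of the stronger, then lexicographically smaller pixel).
    """
    if threshold <= 1:
        raise ValueError("threshold must exceed 1")
    n = oe.shape[0]
    cand = []
    vals = np.nan_to_num(oe, nan=0.0)
    for i in range(n):
        for j in range(i + min_offdiag_bins, n):
            v = vals[i, j]
            if v > threshold:
                cand.append((v, i, j))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    kept: list[tuple[int, int]] = []
    for v, i, j in cand:
        if all(max(abs(i - ki), abs(j - kj)) > radius_bins for ki, kj in kept):
            kept.append((i, j))
    kept.sort()
    loops = []
    for k, (i, j) in enumerate(kept):
        loops.append(
            Loop(
                chrom=chrom,
                anchor1_start=i * bin_size,
                anchor1_end=(i + 1) * bin_size,
                anchor2_start=j * bin_size,
                anchor2_end=(j + 1) * bin_size,
                resolution_bp=bin_size,
                loop_id=f"loop_{k}",
            )
        )
    return loops


# ---------------------------------------------------------------------------
# BEDPE I/O
# ---------------------------------------------------------------------------

def read_loops_bedpe(path, resolution_bp: int) -> list[Loop]:
    out = []
    with open(path) as fh:
        for k, line in enumerate(fh):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                Loop(
                    chrom=f[0],
                    anchor1_start=int(f[1]),
                    anchor1_end=int(f[2]),
                    anchor2_start=int(f[4]),
                    anchor2_end=int(f[5]),
                    resolution_bp=resolution_bp,
                    loop_id=f[6] if len(f) > 6 else f"loop_{k}",
                )
            )
    return out


def write_loops_bedpe(
    loops: list[Loop], path, records: list[LoopRecord] | None = None
) -> None:
    by_id = {r.loop_id: r for r in records} if records else {}
    with open(path, "w") as fh:
        for l in loops:
            extra = ""
            r = by_id.get(l.loop_id)
            if r is not None:
                s = "" if r.strength is None else f"{r.strength:.6g}"
                extra = f"\t{r.category}\t{s}\t{int(r.at_tad_corner)}"
            fh.write(
                f"{l.chrom}\t{l.anchor1_start}\t{l.anchor1_end}\t"
                f"{l.chrom}\t{l.anchor2_start}\t{l.anchor2_end}\t{l.loop_id}{extra}\n"
            )
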