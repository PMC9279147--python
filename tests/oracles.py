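"""Independent straight-line oracles used by unit and acceptance tests.

Everything here re-derives results from first principles (exhaustive
enumeration, textbook formulas) without touching the package's own
implementation paths.
"""

import itertools
import math

import numpy as np

from loopferret.loops import Loop
from loopferret.motifs import CBSAnnotation


# ---------------------------------------------------------------------------
# Random toy loop sets on non-overlapping anchor slots
# ---------------------------------------------------------------------------

def random_toy_loop_set(rng, max_anchors=20, max_loops=50, resolution=10_000):
    """Random loops over spaced anchor slots with random CBS content.

    Slots are far enough apart that anchor merging is the identity, so the
    brute-force evaluator can reason per slot.
    """
    n_slots = rng.integers(2, max_anchors + 1)
    slot_gap = 5  # bins between slots; > merge padding
    slot_bins = np.arange(n_slots) * slot_gap
    cbs = []
    slot_cbs = []
    for k, b in enumerate(slot_bins):
        orientations = []
        for _ in range(rng.integers(0, 3)):
            o = "forward" if rng.random() < 0.5 else "reverse"
            orientations.append(o)
        slot_cbs.append(orientations)
        for i, o in enumerate(orientations):
            start = int(b) * resolution + 100 + 25 * i
            cbs.append(
                CBSAnnotation(chrom="t", start=start, end=start + 19,
                              orientation=o, source_peak=f"s{k}_{i}")
            )
    all_pairs = list(itertools.combinations(range(n_slots), 2))
    rng.shuffle(all_pairs)
    n_loops = int(rng.integers(1, min(max_loops, len(all_pairs)) + 1))
    loops = []
    for li, (i, j) in enumerate(all_pairs[:n_loops]):
        loops.append(
            Loop(
                chrom="t",
                anchor1_start=int(slot_bins[i]) * resolution,
                anchor1_end=(int(slot_bins[i]) + 1) * resolution,
                anchor2_start=int(slot_bins[j]) * resolution,
                anchor2_end=(int(slot_bins[j]) + 1) * resolution,
                resolution_bp=resolution,
                loop_id=f"L{li}",
            )
        )
    return loops, cbs, slot_bins, slot_cbs


def brute_force_classification(loops, slot_bins, slot_cbs, resolution=10_000):
    """Literal transcription of the anchor/loop category rules.

    Returns (anchor_info, loop_categories): per-slot dicts and a loop-id ->
    category mapping, derived with plain loops over the definitions.
    """
    slot_of_start = {int(b) * resolution: k for k, b in enumerate(slot_bins)}
    right_of = {k: [] for k in range(len(slot_bins))}  # slot is anchor1
    left_of = {k: [] for k in range(len(slot_bins))}   # slot is anchor2
    for l in loops:
        right_of[slot_of_start[l.anchor1_start]].append(l)
        left_of[slot_of_start[l.anchor2_start]].append(l)

    anchor_info = {}
    for k in range(len(slot_bins)):
        fwd = "forward" in slot_cbs[k]
        rev = "reverse" in slot_cbs[k]
        if not slot_cbs[k]:
            category = "no_ctcf"
        else:
            bad = (len(right_of[k]) > 0 and not fwd) or (
                len(left_of[k]) > 0 and not rev
            )
            category = "nonconvergent" if bad else "convergent_only"
        anchor_info[k] = {
            "category": category,
            "bidirectional": len(right_of[k]) > 0 and len(left_of[k]) > 0,
            "n_loops": len(right_of[k]) + len(left_of[k]),
        }

    def is_convergent(l):
        a1 = slot_of_start[l.anchor1_start]
        a2 = slot_of_start[l.anchor2_start]
        return "forward" in slot_cbs[a1] and "reverse" in slot_cbs[a2]

    loop_categories = {}
    for l in loops:
        a1 = slot_of_start[l.anchor1_start]
        a2 = slot_of_start[l.anchor2_start]
        opposite = left_of[a1] + right_of[a2]
        opp_conv = any(is_convergent(o) for o in opposite)
        opp_nonconv = any(not is_convergent(o) for o in opposite)
        if is_convergent(l):
            if opp_nonconv:
                cat = "convergent_associated"
            elif opp_conv:
                cat = "double_sided_convergent"
            else:
                cat = "single_sided_convergent"
        else:
            cat = "nonconvergent_associated" if opp_conv else "nonconvergent"
        loop_categories[l.loop_id] = cat
    return anchor_info, loop_categories


# ---------------------------------------------------------------------------
# Textbook statistics
# ---------------------------------------------------------------------------

def chi2_textbook(table):
    """Pearson chi-squared from expected counts, no continuity correction."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    stat = ((table - expected) ** 2 / expected).sum()
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df


def mann_whitney_exact(x, y):
    """U statistic and exact two-sided P by full enumeration (no ties)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    pooled = x + y
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        u = sum(1 for a in xs for b in ys if a > b)
        total += 1
        if min(u, n * m - u) <= min(u_obs, n * m - u_obs):
            count += 1
    return u_obs, count / total


def bh_textbook(pvalues):
    """Benjamini-Hochberg adjusted P values by the step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = math.inf
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = pvalues[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adjusted[i] = min(running_min, 1.0)
    return adjusted
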