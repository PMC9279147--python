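"""End-to-end orchestration of the synthetic experiments.

Two headline experiments drive the whole stack:

* the **boundary-composition panel** sweeps the number and orientation
  class of CTCF sites planted at a TAD junction and measures the resulting
  boundary scores (balance -> insulation -> boundary calls -> composition),
  recovering the monotone CBS-count/boundary-score relationship and the
  divergent-vs-nondivergent contrast;
* the **interference experiment** simulates a boundary carrying only
  forward-oriented sites with steric loop interference switched on or off,
  calls loops from the rendered maps, classifies anchors and loop pairs,
  and contrasts bidirectional-anchor fractions and paired loop strengths
  between the two arms.

All randomness flows from one root seed via per-stage substreams; reruns
with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import simgen
from .contacts import ContactMatrix, kr_balance, oe_transform
from .insulation import (
    call_boundaries,
    fit_mappability_mask,
    insulation_score,
)
from .loops import (
    Loop,
    bidirectional_stats,
    call_loops_simple,
    classify_anchors,
    classify_loops,
    loop_strength,
    NONCONVERGENT,
    CONVERGENT_ONLY,
)
from .motifs import CBSAnnotation
from .simgen import PlantedCBS, SimConfig, boundary_panel_cbs

__all__ = [
    "RunConfig",
    "planted_to_annotations",
    "analyze_scenario",
    "run_boundary_panel",
    "run_interference_experiment",
    "run_boundary_weakening",
]


@dataclass
class RunConfig:
    """Declarative configuration for a pipeline run."""

    scenario: str = "two_tads"
    seed: int = 0
    n_seeds: int = 20
    resolution_bp: int = 10_000
    window_bp: int = 250_000
    flank_bp: int = 100_000
    loop_threshold: float = 25.0
    loop_radius_bins: int = 2
    strength_window_bins: int = 10
    strength_center_bins: int = 3
    alpha: float = 0.05
    out_dir: str | None = None
    overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)



def _provenance_line(seed: int, **params) -> str:
    """One-line header recording the seed and a hash of the run config."""
    import hashlib

    blob = json.dumps(params, sort_keys=True, default=str)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    return f"# seed={seed} config_hash={digest}\n"


def _write_tsv(df: pd.DataFrame, path, seed: int, **params) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, **params))
        df.to_csv(fh, sep="\t", index=False)


def planted_to_annotations(
    cbs: list[PlantedCBS], config: SimConfig, chrom: str = "sim"
) -> list[CBSAnnotation]:
    """Lift lattice CBSs to genomic annotations (a 19-bp motif mid-bin)."""
    out = []
    for k, c in enumerate(sorted(cbs, key=lambda c: c.bin)):
        start = c.bin * config.bin_size_bp + config.bin_size_bp // 2
        out.append(
            CBSAnnotation(
                chrom=chrom,
                start=start,
                end=start + 19,
                orientation=c.orientation,
                log_odds_score=0.0,
                source_peak=f"planted_{k}",
            )
        )
    return out


def _boundary_score_at(matrix: ContactMatrix, junction: int, window_bp: int,
                       tolerance_bins: int = 10,
                       mappability_filter: bool = True) -> float:
    """BS of the boundary call nearest the planted junction (0 if none).

    ``mappability_filter=False`` skips the GMM-based exclusion; used for
    panels that plant no low-mappability bins, where coverage structure
    around site clusters would otherwise trip the mixture model.
    """
    balanced, _ = kr_balance(matrix)
    track = insulation_score(balanced, window_bp)
    mask = fit_mappability_mask(matrix) if mappability_filter else None
    calls = [c for c in call_boundaries(track, mask) if not c.filtered]
    near = [c for c in calls if abs(c.bin - junction) <= tolerance_bins]
    if not near:
        return 0.0
    return max(near, key=lambda c: c.boundary_score).boundary_score


def run_boundary_panel(
    n_cbs_values: range | list[int] = range(0, 11),
    classes: tuple[bool, ...] = (True, False),
    n_seeds: int = 6,
    seed: int = 0,
    window_bp: int = 250_000,
    capture_prob: float = 0.3,
    out_dir=None,
    **config_overrides,
) -> pd.DataFrame:
    """Sweep planted CBS count and divergence class; measure boundary score.

    Returns one row per (n_cbs, divergence class, seed) with the boundary
    score at the planted junction.  ``capture_prob`` is the per-site
    occupancy used for the panel sites; a moderate value keeps each added
    site informative (extruder crossing probability ~ (1-p)^k).

    Steric interference is disabled by default: one stalled leg blocks
    traffic in both directions and nucleates a roadblock queue, so with
    interference a single site already saturates insulation, hiding the
    compositional dose response the panel measures.
    """
    config_overrides.setdefault("interference_enabled", False)
    rows = []
    junction = 200
    for divergent in classes:
        for n_cbs in n_cbs_values:
            for s in range(n_seeds):
                run_seed = int(np.random.SeedSequence(
                    [seed, int(divergent), n_cbs, s]).generate_state(1)[0] % (2**31))
                cfg = SimConfig(seed=run_seed, **config_overrides)
                boundary = boundary_panel_cbs(
                    n_cbs, divergent=divergent, capture_prob=capture_prob,
                    junction=junction,
                )
                cbs = [PlantedCBS(simgen.FLANK_FWD_BIN, simgen.FORWARD), *boundary,
                       PlantedCBS(simgen.FLANK_REV_BIN, simgen.REVERSE)]
                snaps = simgen.simulate_extrusion(cfg, cbs)
                matrix, _ = simgen.render_contact_map(snaps, cfg, cbs=cbs)
                bs = _boundary_score_at(matrix, junction, window_bp,
                                        mappability_filter=False)
                rows.append({"n_cbs": n_cbs, "divergent": divergent,
                             "seed": s, "boundary_score": bs})
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(df, out / "boundary_panel.tsv", seed,
                   capture_prob=capture_prob, n_seeds=n_seeds,
                   window_bp=window_bp, **config_overrides)
        med = (df.groupby(["divergent", "n_cbs"])["boundary_score"]
                 .median().reset_index())
        _write_tsv(med, out / "boundary_panel_medians.tsv", seed,
                   capture_prob=capture_prob, n_seeds=n_seeds,
                   window_bp=window_bp, **config_overrides)
    return df


def analyze_scenario(
    scenario: str,
    seed: int,
    loop_threshold: float = 25.0,
    loop_radius_bins: int = 2,
    **overrides,
):
    """Simulate a scenario and run the loop-classification stack on it.

    Returns (anchors, loop_records, loops, oe, ground_truth, sim config).
    """
    matrix, gt, cfg = simgen.run_scenario(scenario, seed=seed, **overrides)
    balanced, _ = kr_balance(matrix)
    oe = oe_transform(balanced)
    loops = call_loops_simple(
        oe, bin_size=cfg.bin_size_bp, threshold=loop_threshold,
        radius_bins=loop_radius_bins, chrom=matrix.chrom,
    )
    annotations = planted_to_annotations(gt.cbs, cfg, chrom=matrix.chrom)
    anchors = classify_anchors(loops, annotations)
    records = classify_loops(loops, anchors) if loops else []
    return anchors, records, loops, oe, gt, cfg


def run_interference_experiment(
    n_seeds: int = 20,
    seed: int = 0,
    scenario: str = "forward_only_boundary",
    loop_threshold: float = 25.0,
    strength_window_bins: int = 10,
    strength_center_bins: int = 3,
    out_dir=None,
    **config_overrides,
) -> dict:
    """Interference on/off contrast on the forward-only boundary scenario.

    Pools anchors and loops across seeds per arm.  Reports per-category
    bidirectional fractions with the chi-squared scheme, and the strengths
    of convergent-associated vs nonconvergent-associated loop pairs.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds per arm")
    report: dict = {"arms": {}}
    for arm, interference in (("on", True), ("off", False)):
        pooled_anchors = []
        strengths = {"convergent_associated": [], "nonconvergent_associated": []}
        category_counts: dict[str, int] = {}
        for s in range(n_seeds):
            run_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0]
                           % (2**31))
            anchors, records, loops, oe, gt, cfg = analyze_scenario(
                scenario, seed=run_seed, loop_threshold=loop_threshold,
                interference_enabled=interference, **config_overrides,
            )
            pooled_anchors.extend(anchors)
            by_id = {l.loop_id: l for l in loops}
            for r in records:
                category_counts[r.category] = category_counts.get(r.category, 0) + 1
                if r.category in strengths:
                    i, j = by_id[r.loop_id].pixel()
                    w = strength_window_bins
                    if min(i, j) - w < 0 or max(i, j) + w >= oe.shape[0]:
                        continue  # too close to the matrix edge
                    st = loop_strength(
                        by_id[r.loop_id], oe, window_bins=w,
                        center_bins=strength_center_bins,
                    )
                    if st is not None:
                        strengths[r.category].append(st)
        arm_report: dict = {"category_counts": category_counts}
        try:
            arm_report["bidirectional"] = bidirectional_stats(pooled_anchors)
        except ValueError as exc:
            arm_report["bidirectional"] = {"error": str(exc)}
        frac = arm_report["bidirectional"].get("fractions", {})
        arm_report["nonconvergent_fraction"] = frac.get(NONCONVERGENT, 0.0)
        arm_report["convergent_only_fraction"] = frac.get(CONVERGENT_ONLY, 0.0)
        arm_report["strengths"] = strengths
        ca, na = strengths["convergent_associated"], strengths["nonconvergent_associated"]
        if len(ca) >= 2 and len(na) >= 2:
            mw = sps.mannwhitneyu(ca, na, alternative="greater")
            arm_report["strength_mw_p"] = float(mw.pvalue)
            arm_report["strength_median_delta"] = float(
                np.median(ca) - np.median(na))
        report["arms"][arm] = arm_report

    on = report["arms"]["on"]
    off = report["arms"]["off"]
    report["fraction_ratio_on_off"] = (
        float("inf")
        if off["nonconvergent_fraction"] == 0 and on["nonconvergent_fraction"] > 0
        else (on["nonconvergent_fraction"] / off["nonconvergent_fraction"]
              if off["nonconvergent_fraction"] else 0.0)
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "interference_report.json", "w") as fh:
            report["provenance"] = _provenance_line(
                seed, n_seeds=n_seeds, scenario=scenario,
                loop_threshold=loop_threshold, **config_overrides,
            ).strip("#\n ")
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def posthoc_nonconv_vs_conv_p(arm_report: dict) -> float:
    """BH-adjusted post-hoc P for nonconvergent vs convergent-only
    bidirectionality; 1.0 when the comparison is undefined (no
    nonconvergent anchors pooled)."""
    bid = arm_report.get("bidirectional", {})
    for entry in bid.get("posthoc", []):
        if set(entry["pair"]) == {NONCONVERGENT, CONVERGENT_ONLY}:
            return float(entry["p_adj"])
    return 1.0


def run_boundary_weakening(
    n_seeds: int = 20,
    seed: int = 0,
    capture_prob: float = 0.55,
    viewpoint: tuple[int, int] = (280, 284),
    quant_window: tuple[int, int] = (100, 160),
    window_bp: int = 250_000,
    out_dir=None,
    **config_overrides,
) -> pd.DataFrame:
    """Virtual-4C dose response of progressive boundary CBS removal.

    The six-site divergent boundary is weakened by deleting sites one at a
    time (in list order); for each deletion level the cross-boundary share
    of the virtual 4C profile from a viewpoint in the right-hand TAD is
    quantified inside a fixed window in the left-hand TAD.  All levels of
    one replicate share the simulator seed (common random numbers), so the
    within-replicate series isolates the effect of the deletions.

    Like the composition panel, the series runs without steric interference
    by default: a stalled leg otherwise blocks traffic in both directions,
    so a single remaining site saturates insulation and flattens the dose
    response the series is meant to expose.
    """
    from .views import virtual_4c

    config_overrides.setdefault("interference_enabled", False)

    orient = [simgen.REVERSE, simgen.REVERSE, simgen.FORWARD,
              simgen.REVERSE, simgen.FORWARD, simgen.REVERSE]
    bins = [192, 195, 198, 201, 204, 207]
    rows = []
    for s in range(n_seeds):
        run_seed = int(np.random.SeedSequence([seed, s]).generate_state(1)[0]
                       % (2**31))
        for n_removed in range(len(bins) + 1):
            boundary = [
                PlantedCBS(b, o, capture_prob)
                for b, o in list(zip(bins, orient))[n_removed:]
            ]
            cbs = [PlantedCBS(simgen.FLANK_FWD_BIN, simgen.FORWARD), *boundary,
                   PlantedCBS(simgen.FLANK_REV_BIN, simgen.REVERSE)]
            cfg = SimConfig(seed=run_seed, **config_overrides)
            snaps = simgen.simulate_extrusion(cfg, cbs)
            matrix, _ = simgen.render_contact_map(snaps, cfg, cbs=cbs)
            balanced, _ = kr_balance(matrix)
            prof = virtual_4c(balanced, viewpoint, quant_window=quant_window)
            rows.append({"seed": s, "n_removed": n_removed,
                         "cross_share": prof.quant_share})
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(df, out / "boundary_weakening.tsv", seed,
                   capture_prob=capture_prob, n_seeds=n_seeds,
                   viewpoint=viewpoint, quant_window=quant_window,
                   **config_overrides)
    return df


def monotone_fraction(df: pd.DataFrame, tolerance: float = 0.0) -> float:
    """Fraction of replicates whose cross-boundary share never decreases
    (beyond ``tolerance``) as sites are removed."""
    ok = 0
    seeds = df["seed"].unique()
    for s in seeds:
        series = df[df["seed"] == s].sort_values("n_removed")["cross_share"].to_numpy()
        if np.all(np.diff(series) >= -tolerance):
            ok += 1
    return ok / len(seeds)
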