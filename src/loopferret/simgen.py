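"""Synthetic-data generator: 1D cohesin loop-extrusion with CTCF stalling.

The simulator places ``n_extruders`` cohesin complexes on a lattice of
``n_bins`` bins.  Each complex has a left and a right leg; at every step a
non-stalled leg moves one bin outward.  Oriented CTCF binding sites (CBSs)
stall legs one-sidedly, reproducing the convergent-loop rule of the loop
extrusion model: a forward-oriented CBS captures left-moving legs (and thus
becomes the left anchor of rightward loops), a reverse-oriented CBS captures
right-moving legs.  With ``interference_enabled`` a moving leg can never
enter a bin currently occupied by another extruder's stalled leg: it stalls
in the adjacent bin and stays there while the blocker persists.  This steric
block is what lets a convergent loop indirectly stabilise a second, paired
loop in the nonconvergent direction.

Snapshots of extruder leg positions are rendered into a Hi-C-like contact
map: a power-law distance-decay background, one contact per extruder per
snapshot at its (left, right) loop base, and a handful of random intra-loop
contacts per extruder emulating the compacted loop interior.  Scenario
builders plant CBS clusters, TAD junctions and low-mappability bins and
record the matching ground truth for recovery tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .contacts import ContactMatrix, write_matrix

__all__ = [
    "SimConfig",
    "PlantedCBS",
    "SimulationState",
    "GroundTruth",
    "simulate_extrusion",
    "render_contact_map",
    "build_scenario",
    "generate_dataset",
    "SCENARIOS",
    "FORWARD",
    "REVERSE",
]

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one loop-extrusion run.

    Defaults are the package's standard preset: a 4-Mb region at 10-kb
    bins with 40 extruders, giving clearly resolvable loops in under a
    second of simulation.
    """

    n_bins: int = 400
    bin_size_bp: int = 10_000
    n_extruders: int = 40
    steps_per_snapshot: int = 10
    n_snapshots: int = 2000
    burn_in_steps: int = 500
    unload_prob: float = 0.002
    capture_prob_default: float = 0.9
    interference_enabled: bool = True
    intra_loop_samples: int = 2
    background_exponent: float = 1.0
    background_weight: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 20:
            raise ValueError("n_bins must be >= 20")
        for name in ("unload_prob", "capture_prob_default"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "n_extruders",
            "steps_per_snapshot",
            "n_snapshots",
            "burn_in_steps",
            "intra_loop_samples",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.background_exponent <= 0:
            raise ValueError("background_exponent must be > 0")


@dataclass(frozen=True)
class PlantedCBS:
    """An oriented CTCF site on the lattice; capture_prob is an occupancy
    proxy overriding the config default when not None."""

    bin: int
    orientation: str
    capture_prob: float | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be forward/reverse, got {self.orientation!r}")
        if self.capture_prob is not None and not 0.0 <= self.capture_prob <= 1.0:
            raise ValueError("capture_prob must be in [0, 1]")


@dataclass
class SimulationState:
    """One snapshot of all extruders (arrays indexed by extruder)."""

    left: np.ndarray
    right: np.ndarray
    left_stalled: np.ndarray
    right_stalled: np.ndarray
    step: int

    @property
    def n_extruders(self) -> int:
        return len(self.left)


@dataclass
class GroundTruth:
    """Planted annotations for recovery tests."""

    cbs: list[PlantedCBS] = field(default_factory=list)
    expected_convergent_pairs: list[tuple[int, int]] = field(default_factory=list)
    expected_nonconvergent_pairs: list[tuple[int, int]] = field(default_factory=list)
    boundaries: list[int] = field(default_factory=list)
    masked_bins: list[int] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "cbs": [
                {
                    "bin": c.bin,
                    "orientation": c.orientation,
                    "capture_prob": c.capture_prob,
                }
                for c in self.cbs
            ],
            "expected_convergent_pairs": [list(p) for p in self.expected_convergent_pairs],
            "expected_nonconvergent_pairs": [list(p) for p in self.expected_nonconvergent_pairs],
            "boundaries": list(self.boundaries),
            "masked_bins": list(self.masked_bins),
        }


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _capture_arrays(config: SimConfig, cbs: list[PlantedCBS]) -> tuple[np.ndarray, np.ndarray]:
    fwd = np.zeros(config.n_bins)
    rev = np.zeros(config.n_bins)
    seen: set[int] = set()
    for c in cbs:
        if not 0 <= c.bin < config.n_bins:
            raise ValueError(f"CBS bin {c.bin} out of range [0, {config.n_bins})")
        if c.bin in seen:
            raise ValueError(f"duplicate CBS bin {c.bin}")
        seen.add(c.bin)
        p = config.capture_prob_default if c.capture_prob is None else c.capture_prob
        if c.orientation == FORWARD:
            fwd[c.bin] = p
        else:
            rev[c.bin] = p
    return fwd, rev


def simulate_extrusion(
    config: SimConfig, cbs: list[PlantedCBS] | tuple[PlantedCBS, ...] = (),
    initial_positions: np.ndarray | None = None,
) -> list[SimulationState]:
    """Run the extrusion dynamics, returning snapshots of leg positions.

    ``initial_positions`` (one bin per extruder, both legs co-located)
    overrides the default uniform random loading; used by deterministic
    hand-stepped tests.
    """
    fwd_capture, rev_capture = _capture_arrays(config, list(cbs))
    rng = np.random.default_rng(config.seed)
    e = config.n_extruders
    n = config.n_bins

    if initial_positions is not None:
        pos = np.asarray(initial_positions, dtype=np.int64)
        if pos.shape != (e,):
            raise ValueError("initial_positions must have one bin per extruder")
    else:
        pos = rng.integers(0, n, size=e)
    left = pos.copy()
    right = pos.copy()
    l_cbs = np.zeros(e, dtype=bool)   # permanently stalled at a CBS
    r_cbs = np.zeros(e, dtype=bool)
    l_blk = np.zeros(e, dtype=bool)   # sterically blocked this step
    r_blk = np.zeros(e, dtype=bool)

    total_steps = config.burn_in_steps + config.n_snapshots * config.steps_per_snapshot
    snapshots: list[SimulationState] = []
    interference = config.interference_enabled

    for step in range(1, total_steps + 1):
        # fixed-size RNG draws keep the stream independent of the state
        u_unload = rng.random(e)
        reload_bins = rng.integers(0, n, size=e) if e else np.zeros(0, dtype=np.int64)
        u_capl = rng.random(e)
        u_capr = rng.random(e)

        unload = u_unload < config.unload_prob
        if config.unload_prob > 0:
            # an extruder whose leg runs off the lattice end slides off and
            # reloads; without this, edge bins act as artificial permanent
            # anchors.  With unloading disabled entirely (deterministic
            # miniature runs) the ends are reflecting instead.
            unload |= (left == 0) & ~l_cbs
            unload |= (right == n - 1) & ~r_cbs
        if unload.any():
            left[unload] = reload_bins[unload]
            right[unload] = reload_bins[unload]
            l_cbs[unload] = r_cbs[unload] = False
            l_blk[unload] = r_blk[unload] = False

        # occupancy of stalled legs (CBS-stalled or blocked), pre-move
        if interference and e:
            occ = np.zeros(n, dtype=bool)
            occ[left[l_cbs | l_blk]] = True
            occ[right[r_cbs | r_blk]] = True
        else:
            occ = None

        # left legs move toward lower indices
        tgt_l = np.maximum(left - 1, 0)
        movable_l = ~l_cbs & (left > 0)
        if occ is not None:
            blocked_l = movable_l & occ[tgt_l]
        else:
            blocked_l = np.zeros(e, dtype=bool)
        move_l = movable_l & ~blocked_l
        left[move_l] = tgt_l[move_l]
        l_blk = blocked_l
        newly = move_l & (u_capl < fwd_capture[left])
        l_cbs |= newly

        # right legs move toward higher indices
        tgt_r = np.minimum(right + 1, n - 1)
        movable_r = ~r_cbs & (right < n - 1)
        if occ is not None:
            blocked_r = movable_r & occ[tgt_r]
        else:
            blocked_r = np.zeros(e, dtype=bool)
        move_r = movable_r & ~blocked_r
        right[move_r] = tgt_r[move_r]
        r_blk = blocked_r
        newly = move_r & (u_capr < rev_capture[right])
        r_cbs |= newly

        if (
            step > config.burn_in_steps
            and (step - config.burn_in_steps) % config.steps_per_snapshot == 0
        ):
            snapshots.append(
                SimulationState(
                    left=left.copy(),
                    right=right.copy(),
                    left_stalled=(l_cbs | l_blk).copy(),
                    right_stalled=(r_cbs | r_blk).copy(),
                    step=step,
                )
            )
    return snapshots


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _default_convergent_pairs(cbs: list[PlantedCBS]) -> list[tuple[int, int]]:
    """Each forward CBS paired with the nearest reverse CBS to its right."""
    pairs = []
    rev_bins = sorted(c.bin for c in cbs if c.orientation == REVERSE)
    for c in cbs:
        if c.orientation != FORWARD:
            continue
        right = [b for b in rev_bins if b > c.bin]
        if right:
            pairs.append((c.bin, right[0]))
    return sorted(set(pairs))


def render_contact_map(
    snapshots: list[SimulationState],
    config: SimConfig,
    cbs: list[PlantedCBS] | tuple[PlantedCBS, ...] = (),
    masked_bins: list[int] | tuple[int, ...] = (),
    ground_truth: GroundTruth | None = None,
    chrom: str = "sim",
) -> tuple[ContactMatrix, GroundTruth]:
    """Turn extruder snapshots into a contact map plus ground truth.

    Background counts ``background_weight * (|i-j|+1)^-background_exponent``
    are added deterministically; each extruder contributes one count per
    snapshot at its loop base and ``intra_loop_samples`` random contacts
    inside the extruded interval.  Masked bins are zeroed.
    """
    if not snapshots:
        raise ValueError("need at least one snapshot")
    n = config.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    counts = config.background_weight * (d + 1.0) ** (-config.background_exponent)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lefts = np.concatenate([s.left for s in snapshots]) if snapshots[0].n_extruders else np.zeros(0, int)
    rights = np.concatenate([s.right for s in snapshots]) if snapshots[0].n_extruders else np.zeros(0, int)
    if len(lefts):
        np.add.at(counts, (lefts, rights), 1.0)
        np.add.at(counts, (rights, lefts), 1.0)
        k = config.intra_loop_samples
        if k > 0:
            ll = np.repeat(lefts, k)
            rr = np.repeat(rights, k)
            span = rr - ll + 1
            a = ll + (rng.random(len(ll)) * span).astype(np.int64)
            b = ll + (rng.random(len(ll)) * span).astype(np.int64)
            np.add.at(counts, (a, b), 1.0)
            np.add.at(counts, (b, a), 1.0)

    if ground_truth is None:
        cbs = list(cbs)
        ground_truth = GroundTruth(
            cbs=cbs,
            expected_convergent_pairs=_default_convergent_pairs(cbs),
            expected_nonconvergent_pairs=[],
            boundaries=sorted(
                c.bin
                for c in cbs
                if (config.capture_prob_default if c.capture_prob is None else c.capture_prob)
                >= 0.5
            ),
            masked_bins=sorted(masked_bins),
        )
    for b in ground_truth.masked_bins:
        counts[b, :] = 0.0
        counts[:, b] = 0.0
    mask = np.zeros(n, dtype=bool)
    mask[ground_truth.masked_bins] = True
    matrix = ContactMatrix(chrom=chrom, bin_size=config.bin_size_bp, counts=counts, mask=mask)
    return matrix, ground_truth


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

FLANK_FWD_BIN = 15
FLANK_REV_BIN = 385


def _flanked(boundary_cbs: list[PlantedCBS]) -> list[PlantedCBS]:
    """Add the TAD-framing anchor CBSs shared by all scenarios; the flanks
    sit one strength-window inside the lattice edge so aggregate windows
    around their loops stay within bounds."""
    return [PlantedCBS(FLANK_FWD_BIN, FORWARD), *boundary_cbs,
            PlantedCBS(FLANK_REV_BIN, REVERSE)]


def _scenario_two_tads(config: SimConfig) -> tuple[list[PlantedCBS], GroundTruth]:
    cbs = _flanked([PlantedCBS(199, REVERSE), PlantedCBS(201, FORWARD)])
    gt = GroundTruth(
        cbs=cbs,
        expected_convergent_pairs=[(15, 199), (201, 385)],
        expected_nonconvergent_pairs=[],
        boundaries=[200],
        masked_bins=[60, 61],
    )
    return cbs, gt


def _scenario_forward_only(config: SimConfig) -> tuple[list[PlantedCBS], GroundTruth]:
    # single forward CBS at the junction: left anchor of the convergent loop
    # toward the telomeric flank, and (with interference) right anchor of an
    # induced nonconvergent loop toward the centromeric flank
    cbs = _flanked([PlantedCBS(200, FORWARD)])
    gt = GroundTruth(
        cbs=cbs,
        expected_convergent_pairs=[(15, 385), (200, 385)],
        expected_nonconvergent_pairs=[(15, 199)] if config.interference_enabled else [],
        boundaries=[200],
        masked_bins=[],
    )
    return cbs, gt


def _scenario_ep_boundary(config: SimConfig) -> tuple[list[PlantedCBS], GroundTruth]:
    # six clustered sites ordered R,R,F,R,F,R with heterogeneous occupancy,
    # echoing a prototypical divergent boundary (4 reverse + 2 forward)
    occ = [0.9, 0.5, 0.9, 0.6, 0.9, 0.3]
    orient = [REVERSE, REVERSE, FORWARD, REVERSE, FORWARD, REVERSE]
    bins = [192, 195, 198, 201, 204, 207]
    boundary = [PlantedCBS(b, o, p) for b, o, p in zip(bins, orient, occ)]
    cbs = _flanked(boundary)
    # ground truth annotates the six-site cluster itself; the flanking
    # anchors emulate the neighbouring TADs' outer boundaries and stay
    # outside the annotated set
    gt = GroundTruth(
        cbs=boundary,
        expected_convergent_pairs=[(15, 192), (15, 195), (198, 385), (204, 385)],
        expected_nonconvergent_pairs=[],
        boundaries=[200],
        masked_bins=[],
    )
    return cbs, gt


def boundary_panel_cbs(
    n_cbs: int, divergent: bool, capture_prob: float = 0.3, junction: int = 200,
    spacing: int = 2,
) -> list[PlantedCBS]:
    """Boundary CBS layout for the composition panel.

    Divergent boundaries place reverse sites upstream and forward sites
    downstream of the junction (motifs pointing apart); nondivergent
    boundaries use forward sites only, spread across the junction.
    """
    if n_cbs < 0:
        raise ValueError("n_cbs must be >= 0")
    out: list[PlantedCBS] = []
    if divergent:
        n_rev = (n_cbs + 1) // 2
        n_fwd = n_cbs - n_rev
        for k in range(n_rev):
            out.append(PlantedCBS(junction - 1 - spacing * k, REVERSE, capture_prob))
        for k in range(n_fwd):
            out.append(PlantedCBS(junction + 1 + spacing * k, FORWARD, capture_prob))
    else:
        start = junction - spacing * ((n_cbs - 1) // 2) if n_cbs else junction
        for k in range(n_cbs):
            out.append(PlantedCBS(start + spacing * k, FORWARD, capture_prob))
    return sorted(out, key=lambda c: c.bin)


def _scenario_panel(config: SimConfig) -> tuple[list[PlantedCBS], GroundTruth]:
    cbs = _flanked(boundary_panel_cbs(6, divergent=True))
    gt = GroundTruth(
        cbs=cbs,
        expected_convergent_pairs=[(15, 385)],
        expected_nonconvergent_pairs=[],
        boundaries=[200],
        masked_bins=[],
    )
    return cbs, gt


SCENARIOS = {
    "two_tads": _scenario_two_tads,
    "ep_boundary_like": _scenario_ep_boundary,
    "forward_only_boundary": _scenario_forward_only,
    "divergent_vs_nondivergent_panel": _scenario_panel,
}


def build_scenario(
    name: str, seed: int = 0, **overrides
) -> tuple[SimConfig, list[PlantedCBS], GroundTruth]:
    """Resolve a named scenario into (config, planted CBSs, ground truth)."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    config = SimConfig(seed=seed, **overrides)
    cbs, gt = SCENARIOS[name](config)
    return config, cbs, gt


def run_scenario(
    name: str, seed: int = 0, **overrides
) -> tuple[ContactMatrix, GroundTruth, SimConfig]:
    """Simulate a named scenario end to end and render its contact map."""
    config, cbs, gt = build_scenario(name, seed=seed, **overrides)
    snaps = simulate_extrusion(config, cbs)
    matrix, gt = render_contact_map(snaps, config, cbs=cbs, ground_truth=gt)
    return matrix, gt, config


# ---------------------------------------------------------------------------
# Dataset files
# ---------------------------------------------------------------------------

def _write_cbs_bed(cbs: list[PlantedCBS], config: SimConfig, chrom: str, path: Path) -> None:
    with open(path, "w") as fh:
        for k, c in enumerate(sorted(cbs, key=lambda c: c.bin)):
            p = config.capture_prob_default if c.capture_prob is None else c.capture_prob
            start = c.bin * config.bin_size_bp + config.bin_size_bp // 2
            strand = "+" if c.orientation == FORWARD else "-"
            fh.write(
                f"{chrom}\t{start}\t{start + 19}\tcbs_{k}\t{round(1000 * p)}\t{strand}\n"
            )


def _write_loops_bedpe(
    pairs: list[tuple[int, int]], config: SimConfig, chrom: str, path: Path
) -> None:
    bs = config.bin_size_bp
    with open(path, "w") as fh:
        for k, (i, j) in enumerate(sorted(pairs)):
            fh.write(
                f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t"
                f"{chrom}\t{j * bs}\t{(j + 1) * bs}\tloop_{k}\n"
            )


def generate_dataset(name: str, seed: int, out_dir, **overrides) -> dict[str, Path]:
    """Simulate a named scenario and write matrix/CBS/loops/truth files.

    Rerunning with the same seed is byte-identical.  Returns the paths of
    the files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, gt, config = run_scenario(name, seed=seed, **overrides)
    paths = {
        "matrix": out / "matrix.tsv",
        "cbs": out / "cbs.bed",
        "loops": out / "loops.bedpe",
        "truth": out / "truth.json",
    }
    write_matrix(matrix, paths["matrix"])
    _write_cbs_bed(gt.cbs, config, matrix.chrom, paths["cbs"])
    _write_loops_bedpe(
        sorted(set(gt.expected_convergent_pairs) | set(gt.expected_nonconvergent_pairs)),
        config,
        matrix.chrom,
        paths["loops"],
    )
    with open(paths["truth"], "w") as fh:
        json.dump(gt.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
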