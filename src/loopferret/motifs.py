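"""CBS orientation from sequence and boundary CBS-composition statistics.

CTCF binding sites are oriented by scanning each peak sequence with a
position weight matrix on both strands and keeping the single best log-odds
hit (forward orientation = best hit on the + strand).  Boundary composition
then counts, for each insulation boundary plus a flanking region, the
overlapping CBSs and the ordered (reverse, forward) pairs that constitute a
divergent signature -- a reverse-oriented motif upstream of a
forward-oriented one, the two motifs pointing apart.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .insulation import BoundaryCall

__all__ = [
    "PWM",
    "CBSAnnotation",
    "BoundaryComposition",
    "scan_peak",
    "scan_peaks",
    "compose_boundaries",
    "composition_summary",
    "read_cbs_bed",
    "write_cbs_bed",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Per-position letter probabilities over ACGT with a 0-order background."""

    probs: np.ndarray  # (L, 4)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not math.isclose(self.background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.25,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        if background is None:
            return cls(probs)
        return cls(probs, np.asarray(background, dtype=float))

    @classmethod
    def from_jaspar(cls, source, pseudocount: float = 0.25) -> "PWM":
        """Load a raw-counts JASPAR matrix (file path, handle or text)."""
        if isinstance(source, (str,)) and "\n" in source:
            handle = io.StringIO(source)
        elif hasattr(source, "read"):
            handle = source
        else:
            handle = open(source)
        motif = bio_motifs.read(handle, "jaspar")
        counts = np.array([[motif.counts[b][i] for b in _ALPHABET]
                           for i in range(motif.length)])
        return cls.from_counts(counts, pseudocount=pseudocount)

    def consensus(self) -> str:
        return "".join(_ALPHABET[k] for k in self.probs.argmax(axis=1))

    def score(self, window: str) -> float:
        """Sum of log2(p/bg) over the window; N scores -inf."""
        total = 0.0
        for pos, letter in enumerate(window):
            k = _ALPHABET.find(letter)
            if k < 0:
                return float("-inf")
            total += math.log2(self.probs[pos, k] / self.background[k])
        return total


@dataclass
class CBSAnnotation:
    """Oriented CTCF site: interval in bp, strand-encoded orientation."""

    chrom: str
    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    log_odds_score: float = 0.0
    source_peak: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be forward/reverse")
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def strand(self) -> str:
        return "+" if self.orientation == "forward" else "-"


@dataclass
class BoundaryComposition:
    boundary_id: str
    n_cbs: int
    n_divergent_pairs: int
    divergent: bool
    boundary_score: float

    def __post_init__(self) -> None:
        if self.divergent and self.n_cbs < 2:
            raise ValueError("divergent composition requires >= 2 CBSs")


def scan_peak(sequence: str, pwm: PWM, threshold: float = 0.0,
              chrom: str = "", peak_start: int = 0, peak_id: str = "",
              ) -> CBSAnnotation | None:
    """Best single motif hit in a peak, or None below threshold.

    Both strands are scored at every offset (the - strand on the reverse
    complement).  Ties resolve to the highest score, then the leftmost
    offset, then the + strand.
    """
    seq = sequence.upper()
    L = len(pwm)
    if len(seq) < L:
        raise ValueError("sequence shorter than the motif")
    best: tuple[float, int, int] | None = None  # (score, offset, strand_rank)
    rc = seq.translate(_COMPLEMENT)[::-1]
    for offset in range(len(seq) - L + 1):
        s_fwd = pwm.score(seq[offset : offset + L])
        # a - strand hit covering seq[offset:offset+L] is the rc window
        # starting at the mirrored offset
        s_rev = pwm.score(rc[len(seq) - L - offset : len(seq) - offset])
        for strand_rank, s in ((0, s_fwd), (1, s_rev)):
            key = (-s, offset, strand_rank)
            if best is None or key < best:
                best = key
    score = -best[0]
    if not math.isfinite(score) or score < threshold:
        return None
    offset, strand_rank = best[1], best[2]
    return CBSAnnotation(
        chrom=chrom,
        start=peak_start + offset,
        end=peak_start + offset + L,
        orientation="forward" if strand_rank == 0 else "reverse",
        log_odds_score=score,
        source_peak=peak_id,
    )


def scan_peaks(fasta_path, peaks: list[tuple[str, int, int]], pwm: PWM,
               threshold: float = 0.0) -> list[CBSAnnotation]:
    """Scan BED-style peaks against a genome FASTA; one best hit per peak."""
    genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    for k, (chrom, start, end) in enumerate(peaks):
        seq = genome[chrom][start:end]
        if len(seq) < len(pwm):
            continue
        hit = scan_peak(seq, pwm, threshold=threshold, chrom=chrom,
                        peak_start=start, peak_id=f"peak_{k}")
        if hit is not None:
            out.append(hit)
    return out


def count_divergent_pairs(orientations: list[str]) -> int:
    """Ordered pairs (i < j) with reverse at i and forward at j."""
    n_rev = 0
    pairs = 0
    for o in orientations:
        if o == "reverse":
            n_rev += 1
        elif o == "forward":
            pairs += n_rev
    return pairs


def compose_boundaries(
    boundaries: list[BoundaryCall],
    cbs: list[CBSAnnotation],
    flank_bp: int = 100_000,
    bin_size: int = 10_000,
    chrom: str | None = None,
) -> list[BoundaryComposition]:
    """CBS composition of each boundary including a flanking region.

    A CBS counts when its interval overlaps
    ``[boundary_start - flank, boundary_end + flank)``; the divergent flag is
    set when at least one reverse CBS lies upstream of a forward CBS.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    sites = sorted(cbs, key=lambda c: (c.chrom, c.start))
    out = []
    for k, b in enumerate(boundaries):
        b_start = b.bin * bin_size
        b_end = (b.bin + 1) * bin_size
        lo, hi = b_start - flank_bp, b_end + flank_bp
        inside = [
            c for c in sites
            if (chrom is None or c.chrom == chrom) and c.start < hi and c.end > lo
        ]
        orientations = [c.orientation for c in inside]
        pairs = count_divergent_pairs(orientations)
        out.append(
            BoundaryComposition(
                boundary_id=f"boundary_{k}",
                n_cbs=len(inside),
                n_divergent_pairs=pairs,
                divergent=pairs >= 1,
                boundary_score=b.boundary_score,
            )
        )
    return out


def composition_summary(compositions: list[BoundaryComposition]) -> pd.DataFrame:
    """Boundary-score distribution stratified by CBS count and divergence.

    Per stratum: count, median, quartiles (linear interpolation) and
    whiskers at the last observation within 1.5 IQR of the quartiles.
    """
    if not compositions:
        raise ValueError("need at least one composition")
    df = pd.DataFrame(
        {
            "n_cbs": [c.n_cbs for c in compositions],
            "divergent": [c.divergent for c in compositions],
            "bs": [c.boundary_score for c in compositions],
        }
    )
    rows = []
    for (n_cbs, divergent), grp in df.groupby(["n_cbs", "divergent"]):
        v = grp["bs"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
        iqr = q3 - q1
        in_lo = v[v >= q1 - 1.5 * iqr]
        in_hi = v[v <= q3 + 1.5 * iqr]
        rows.append(
            {
                "n_cbs": int(n_cbs),
                "divergent": bool(divergent),
                "count": len(v),
                "median_bs": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": in_lo.min() if len(in_lo) else np.nan,
                "whisker_high": in_hi.max() if len(in_hi) else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(["n_cbs", "divergent"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED6 I/O (strand encodes orientation, score = round(1000 * occupancy proxy))
# ---------------------------------------------------------------------------

def read_cbs_bed(path) -> list[CBSAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                CBSAnnotation(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    orientation="forward" if f[5] == "+" else "reverse",
                    log_odds_score=float(f[4]) if len(f) > 4 else 0.0,
                    source_peak=f[3] if len(f) > 3 else "",
                )
            )
    return out


def write_cbs_bed(cbs: list[CBSAnnotation], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(cbs, key=lambda c: (c.chrom, c.start)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.source_peak or '.'}\t"
                f"{c.log_odds_score:.6g}\t{c.strand}\n"
            )
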