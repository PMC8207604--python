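"""Presence–absence variation (PAV) detection from windowed read depth.

Large FNB deletions — up to hundreds of kilobases — are invisible to an
indel caller but leave an unmistakable footprint in coverage: the mutant
shows extremely low or no reads over the deleted segment while a control
sequenced in parallel shows normal depth.  This module compares
median-normalized windowed depth between a mutant and a control sample and
merges runs of depleted windows into PAV calls.

A region depleted in *both* samples (repeat, assembly gap, shared natural
deletion) is deliberately not callable: the control must itself be well
covered for a window to count as evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DepthTrack",
    "PavParams",
    "PavCall",
    "depth_track_from_alignment",
    "detect_pav",
    "read_depth_bed",
    "write_depth_bed",
    "write_pav_bed",
]


@dataclass
class DepthTrack:
    """Windowed mean depth for one sample.

    Windows tile each chromosome without overlap; ``normalizer`` is the
    genome-wide median of per-window mean depth over non-empty windows, so
    normalized depth is ~1.0 in single-copy regions regardless of the
    sample's sequencing effort.
    """

    sample_id: str
    window_size: int
    windows: dict[str, np.ndarray] = field(default_factory=dict)  # chrom -> (n,3): start,end,depth
    _normalizer: float | None = None

    @property
    def normalizer(self) -> float:
        if self._normalizer is None:
            depths = np.concatenate([w[:, 2] for w in self.windows.values()]) if self.windows else np.array([])
            positive = depths[depths > 0]
            if positive.size == 0:
                raise ValueError(f"track {self.sample_id}: all windows empty, cannot normalize")
            self._normalizer = float(np.median(positive))
        return self._normalizer

    def normalized(self, chrom: str) -> np.ndarray:
        return self.windows[chrom][:, 2] / self.normalizer

    def same_grid(self, other: "DepthTrack") -> bool:
        if set(self.windows) != set(other.windows):
            return False
        return all(
            np.array_equal(self.windows[c][:, :2], other.windows[c][:, :2])
            for c in self.windows
        )

    def scaled(self, c: float) -> "DepthTrack":
        """Copy with all raw depths multiplied by ``c`` (testing aid)."""
        return DepthTrack(
            self.sample_id,
            self.window_size,
            {k: np.column_stack([w[:, :2], w[:, 2] * c]) for k, w in self.windows.items()},
        )


@dataclass(frozen=True)
class PavParams:
    """Tunables of the window-ratio PAV caller.

    ``max_mutant_ratio`` is deliberately above zero (default 0.1): a handful
    of mismapped reads inside a true deletion must not rescue it.
    ``min_control_norm_depth`` (default 0.5) demands that the control
    actually covers the window, excluding regions depleted in both samples.
    Calls need at least ``min_windows`` depleted windows, and runs separated
    by at most ``merge_gap_windows`` non-depleted windows are merged.
    """

    window_size: int = 500
    max_mutant_ratio: float = 0.1
    min_control_norm_depth: float = 0.5
    min_windows: int = 2
    merge_gap_windows: int = 1

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.min_windows <= 0 or self.merge_gap_windows < 0:
            raise ValueError("window parameters must be positive")
        if not (0 < self.max_mutant_ratio < 1):
            raise ValueError("max_mutant_ratio must be in (0, 1)")
        if self.min_control_norm_depth <= 0:
            raise ValueError("min_control_norm_depth must be positive")


@dataclass
class PavCall:
    chrom: str
    start: int  # half-open 0-based
    end: int
    n_windows: int
    mean_mutant_norm_depth: float
    mean_control_norm_depth: float
    zygosity_hint: str  # HOMOZYGOUS_LOSS | PARTIAL_LOSS

    @property
    def length(self) -> int:
        return self.end - self.start


def depth_track_from_alignment(
    path: str | Path, window_size: int, sample_id: str | None = None
) -> DepthTrack:
    """Windowed mean depth from a coordinate-sorted, indexed BAM.

    Mean depth per window is the per-base coverage sum divided by window
    length (``count_coverage`` over all four nucleotides).
    """
    import pysam

    path = Path(path)
    with pysam.AlignmentFile(str(path)) as bam:
        if not bam.has_index():
            raise ValueError(f"{path} has no index; sort and index it first")
        windows: dict[str, np.ndarray] = {}
        for chrom, length in zip(bam.references, bam.lengths):
            starts = np.arange(0, length, window_size)
            rows = []
            for s in starts:
                e = min(s + window_size, length)
                cov = np.sum(bam.count_coverage(chrom, int(s), int(e)))
                rows.append((s, e, cov / (e - s)))
            windows[chrom] = np.array(rows, dtype=float)
    return DepthTrack(sample_id or path.stem, window_size, windows)


def read_depth_bed(path: str | Path, sample_id: str | None = None) -> DepthTrack:
    """Read a 4-column BED-like depth file: chrom, start, end, mean_depth."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "depth"],
        comment="#", dtype={"chrom": str},
    )
    windows: dict[str, np.ndarray] = {}
    sizes = []
    for chrom, sub in df.groupby("chrom", sort=False):
        arr = sub[["start", "end", "depth"]].to_numpy(dtype=float)
        arr = arr[np.argsort(arr[:, 0])]
        windows[chrom] = arr
        if len(arr):
            sizes.append(int(np.max(arr[:, 1] - arr[:, 0])))
    wsize = max(sizes) if sizes else 0
    return DepthTrack(sample_id or Path(path).stem, wsize, windows)


def write_depth_bed(track: DepthTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.windows:
            for s, e, d in track.windows[chrom]:
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{d:.4f}\n")


def _runs_with_gaps(flags: np.ndarray, min_windows: int, max_gap: int) -> list[tuple[int, int]]:
    """Merge runs of True flags, bridging gaps of at most ``max_gap`` False
    windows; keep runs containing >= ``min_windows`` flagged windows.
    Returned bounds index flagged windows (inclusive start, exclusive end)."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    count = 1
    for i in idx[1:]:
        if i - prev - 1 <= max_gap:
            prev = i
            count += 1
        else:
            if count >= min_windows:
                runs.append((start, prev + 1))
            start = prev = i
            count = 1
    if count >= min_windows:
        runs.append((start, prev + 1))
    return runs


def detect_pav(mutant: DepthTrack, control: DepthTrack, p: PavParams | None = None) -> list[PavCall]:
    """Call PAVs where mutant coverage collapses but control coverage holds.

    A window is depleted when (mutant normalized depth) / (control
    normalized depth) <= ``max_mutant_ratio`` *and* the control's normalized
    depth is at least ``min_control_norm_depth``.  Runs of depleted windows
    (gap-tolerant) of at least ``min_windows`` become calls; the zygosity
    hint is HOMOZYGOUS_LOSS when mean mutant normalized depth <= 0.1, else
    PARTIAL_LOSS (a heterozygous large deletion sits near 0.5).

    Normalization makes the decision invariant to scaling either track's
    raw depths by any positive constant.
    """
    p = p or PavParams()
    if not mutant.same_grid(control):
        raise ValueError("mutant and control depth tracks are on different window grids")
    calls: list[PavCall] = []
    for chrom in mutant.windows:
        m = mutant.normalized(chrom)
        c = control.normalized(chrom)
        ctrl_ok = c >= p.min_control_norm_depth
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(c > 0, m / np.where(c > 0, c, 1.0), np.inf)
        flags = ctrl_ok & (ratio <= p.max_mutant_ratio)
        coords = mutant.windows[chrom]
        for i0, i1 in _runs_with_gaps(flags, p.min_windows, p.merge_gap_windows):
            sel = slice(i0, i1)
            mean_m = float(np.mean(m[sel]))
            mean_c = float(np.mean(c[sel]))
            calls.append(
                PavCall(
                    chrom=chrom,
                    start=int(coords[i0, 0]),
                    end=int(coords[i1 - 1, 1]),
                    n_windows=i1 - i0,
                    mean_mutant_norm_depth=mean_m,
                    mean_control_norm_depth=mean_c,
                    zygosity_hint="HOMOZYGOUS_LOSS" if mean_m <= 0.1 else "PARTIAL_LOSS",
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def write_pav_bed(calls: Sequence[PavCall], path: str | Path) -> None:
    """BED of PAV calls; name column carries the zygosity hint, score the
    mutant/control normalized-depth ratio scaled to 0-1000."""
    with open(path, "w") as fh:
        for c in calls:
            ratio = c.mean_mutant_norm_depth / max(c.mean_control_norm_depth, 1e-12)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.zygosity_hint}\t{min(1000, int(ratio * 1000))}\t.\n"
            )
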