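"""Read-depth copy-number estimation and per-sample CNV segmentation.

Sequencing coverage in a window scales linearly with the local copy count,
so a sample's windowed depth track can be rescaled to diploid copy numbers
by anchoring the genome-wide median at CN = 2.  Each window is then
classified as loss (CN < 1.5), normal (1.5 <= CN <= 2.5) or gain
(CN > 2.5), and runs of consistently non-normal windows are merged into
per-sample CNV segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

#: Copy number below which a window is called a loss.
LOSS_THRESHOLD = 1.5
#: Copy number above which a window is called a gain.
GAIN_THRESHOLD = 2.5

SEGMENT_COLS = ["sample_id", "chrom", "start", "end", "state", "cn", "n_windows"]


class CnState(str, Enum):
    """Diploid-relative copy-number state of a window or segment."""

    LOSS = "loss"
    NORMAL = "normal"
    GAIN = "gain"


@dataclass
class DepthTrack:
    """Windowed raw read depth for one sample.

    ``windows`` has columns chrom, start, end, depth; intervals are
    0-based half-open, sorted, non-overlapping, constant width within a
    chromosome.
    """

    sample_id: str
    breed: str
    windows: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.windows["depth"] < 0).any():
            raise ValueError("raw depth must be non-negative")


@dataclass
class CopyNumberMatrix:
    """Diploid-scaled copy numbers, windows (rows) x samples (columns).

    ``windows`` carries the interval coordinates row-aligned with ``cn``;
    ``breeds`` maps each sample column to its breed label.
    """

    windows: pd.DataFrame
    cn: pd.DataFrame
    breeds: dict[str, str]

    @property
    def samples(self) -> list[str]:
        return list(self.cn.columns)

    def genome_size(self) -> int:
        return int(self.windows.groupby("chrom", sort=False)["end"].max().sum())

    def to_tsv(self, path) -> None:
        out = pd.concat([self.windows.reset_index(drop=True),
                         self.cn.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)


def normalize_depth(track: DepthTrack, min_windows: int = 100) -> np.ndarray:
    """Rescale a raw depth track to diploid copy numbers.

    CN_w = 2 * depth_w / median(depth), so the autosomal median maps to
    CN = 2.  The median (not the mean) is used so the normalization is
    robust to the CNVs themselves.

    Raises
    ------
    ValueError
        If the track has fewer than ``min_windows`` windows or its median
        depth is zero (an uninterpretable sample).
    """
    depth = track.windows["depth"].to_numpy(dtype=float)
    if depth.size < min_windows:
        raise ValueError(
            f"need at least {min_windows} windows to normalize, got {depth.size}"
        )
    med = float(np.median(depth))
    if med <= 0:
        raise ValueError(f"median depth is {med}; sample {track.sample_id} "
                         "cannot be normalized")
    return 2.0 * depth / med


def classify_window(cn):
    """Classify copy number(s) into loss / normal / gain.

    Boundary values 1.5 and 2.5 are classified as normal.  Accepts a scalar
    (returns :class:`CnState`) or an array (returns an object array of
    states).  Negative copy numbers are rejected.
    """
    arr = np.asarray(cn, dtype=float)
    if arr.ndim == 0:
        v = float(arr)
        if v < 0:
            raise ValueError("copy number must be non-negative")
        if v < LOSS_THRESHOLD:
            return CnState.LOSS
        if v > GAIN_THRESHOLD:
            return CnState.GAIN
        return CnState.NORMAL
    if (arr < 0).any():
        raise ValueError("copy number must be non-negative")
    states = np.full(arr.shape, CnState.NORMAL, dtype=object)
    states[arr < LOSS_THRESHOLD] = CnState.LOSS
    states[arr > GAIN_THRESHOLD] = CnState.GAIN
    return states


def build_cn_matrix(tracks: list[DepthTrack]) -> CopyNumberMatrix:
    """Normalize every track onto a shared window grid."""
    if not tracks:
        raise ValueError("no tracks given")
    windows = tracks[0].windows[["chrom", "start", "end"]].reset_index(drop=True)
    cn = {}
    for t in tracks:
        if len(t.windows) != len(windows):
            raise ValueError("tracks are on different window grids")
        cn[t.sample_id] = normalize_depth(t)
    breeds = {t.sample_id: t.breed for t in tracks}
    return CopyNumberMatrix(windows=windows, cn=pd.DataFrame(cn), breeds=breeds)


def segment_sample(
    windows: pd.DataFrame,
    cn: np.ndarray,
    sample_id: str = "",
    *,
    gap_windows: int = 1,
    min_windows: int = 2,
) -> pd.DataFrame:
    """Merge classified windows into per-sample CNV segments.

    A segment is a maximal run of same-state non-normal windows on one
    chromosome, tolerating up to ``gap_windows`` interior normal windows
    between consecutive non-normal windows.  A window of the opposite
    state always ends the run.  Segments with fewer than ``min_windows``
    non-normal windows are discarded.  The segment copy number is the mean
    CN over all windows in its span (bridged normal windows included).

    Returns a DataFrame with columns sample_id, chrom, start, end, state,
    cn, n_windows (n_windows counts the non-normal members).
    """
    states = classify_window(cn)
    chroms = windows["chrom"].to_numpy()
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()

    segs: list[tuple] = []

    def close(first: int, last: int, state: CnState, n_members: int) -> None:
        if n_members < min_windows:
            return
        seg_cn = float(np.mean(cn[first : last + 1]))
        segs.append(
            (sample_id, chroms[first], int(starts[first]), int(ends[last]),
             state.value, seg_cn, n_members)
        )

    nn = np.flatnonzero(states != CnState.NORMAL)
    if nn.size:
        first = last = int(nn[0])
        run_state = states[first]
        n_members = 1
        for i in nn[1:]:
            i = int(i)
            same_run = (
                states[i] == run_state
                and chroms[i] == chroms[last]
                and i - last - 1 <= gap_windows
            )
            if same_run:
                last = i
                n_members += 1
            else:
                close(first, last, run_state, n_members)
                first = last = i
                run_state = states[i]
                n_members = 1
        close(first, last, run_state, n_members)

    return pd.DataFrame(segs, columns=SEGMENT_COLS)


def segment_all(
    matrix: CopyNumberMatrix, *, gap_windows: int = 1, min_windows: int = 2
) -> pd.DataFrame:
    """Segment every sample of a copy-number matrix; concatenated result."""
    parts = [
        segment_sample(
            matrix.windows,
            matrix.cn[s].to_numpy(),
            s,
            gap_windows=gap_windows,
            min_windows=min_windows,
        )
        for s in matrix.samples
    ]
    if not parts:
        return pd.DataFrame(columns=SEGMENT_COLS)
    return pd.concat(parts, ignore_index=True)


def segments_to_bed6(segments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample segments as BED6: name = state, score = round(100 * CN)."""
    return pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"],
            "end": segments["end"],
            "name": segments["state"],
            "score": (100 * segments["cn"]).round().astype(int),
            "strand": ".",
        }
    )
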