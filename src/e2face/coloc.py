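"""Weighted colocalization coefficient between two fluorescence channels.

The statistic quantifies, within a per-cell region of interest, how much of
one channel's supra-threshold signal (channel A, e.g. a tagged enzyme) lies
on pixels where a second channel (channel B, e.g. a mitochondrial marker) is
also above threshold:

    M = sum(A over pixels in ROI with A > thr_A and B > thr_B)
        / sum(A over pixels in ROI with A > thr_A)

It is intensity-weighted (brighter A pixels count more), bounded in [0, 1],
and defined as 0 (flagged) when no ROI pixel exceeds thr_A.  Thresholds are
explicit per-ROI inputs; an optional Otsu automatic mode is provided for
convenience and is clearly labelled as such in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd


@dataclass
class TwoChannelImage:
    channel_a: np.ndarray
    channel_b: np.ndarray
    bit_depth: int | None = None

    def __post_init__(self):
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.channel_a.shape != self.channel_b.shape:
            raise ValueError(
                f"channel shapes differ: {self.channel_a.shape} vs {self.channel_b.shape}"
            )
        if self.channel_a.ndim != 2:
            raise ValueError("channels must be 2-D")
        for name, ch in (("a", self.channel_a), ("b", self.channel_b)):
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name} intensities must be finite and >= 0")


@dataclass
class ROI:
    mask: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} has no pixels")


@dataclass
class ColocResult:
    coefficient: float
    thr_a: float
    thr_b: float
    n_pixels_a: int
    n_overlap: int
    empty_denominator: bool = False

    def __post_init__(self):
        if not 0.0 <= self.coefficient <= 1.0:
            raise ValueError("coefficient outside [0, 1]")
        if self.n_overlap > self.n_pixels_a:
            raise ValueError("overlap pixel count exceeds supra-threshold count")


Denominator = Literal["supra", "all"]


def weighted_coloc(
    image: TwoChannelImage,
    roi: ROI,
    thr_a: float,
    thr_b: float,
    denominator: Denominator = "supra",
) -> ColocResult:
    """Weighted colocalization coefficient for one ROI.

    Strict inequality on both thresholds.  The default denominator restricts
    to supra-threshold channel-A pixels; ``denominator="all"`` uses the total
    channel-A intensity over the whole ROI instead.
    """
    if roi.mask.shape != image.channel_a.shape:
        raise ValueError("ROI mask shape differs from image shape")
    a = image.channel_a
    b = image.channel_b
    in_roi = roi.mask
    above_a = in_roi & (a > thr_a)
    overlap = above_a & (b > thr_b)
    num = float(a[overlap].sum())
    if denominator == "supra":
        den = float(a[above_a].sum())
    elif denominator == "all":
        den = float(a[in_roi].sum())
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if den == 0.0:
        return ColocResult(
            coefficient=0.0,
            thr_a=thr_a,
            thr_b=thr_b,
            n_pixels_a=int(above_a.sum()),
            n_overlap=int(overlap.sum()),
            empty_denominator=True,
        )
    return ColocResult(
        coefficient=num / den,
        thr_a=thr_a,
        thr_b=thr_b,
        n_pixels_a=int(above_a.sum()),
        n_overlap=int(overlap.sum()),
    )


def otsu_threshold(channel: np.ndarray, roi: ROI) -> float:
    """Automatic Otsu threshold over ROI pixels (not part of the published
    procedure, which set thresholds interactively per cell)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(channel, dtype=float)[roi.mask]))


# ---------------------------------------------------------------------------
# Batch processing
# ---------------------------------------------------------------------------

def _read_gray(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # drop any color axis
        arr = arr[..., 0]
    return arr


def batch_coloc(
    manifest: str | Path | pd.DataFrame,
    denominator: Denominator = "supra",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell coefficients plus per-condition mean and SD (ddof=1).

    The manifest is a TSV (or DataFrame) with columns: cell_id, path_a,
    path_b, path_mask, thr_a, thr_b, condition.  A single-cell condition
    reports SD as NaN (undefined).
    """
    if isinstance(manifest, pd.DataFrame):
        df = manifest.copy()
        base = Path(".")
    else:
        df = pd.read_csv(manifest, sep="\t")
        base = Path(manifest).parent
    required = {"cell_id", "path_a", "path_b", "path_mask", "thr_a", "thr_b", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for idx, row in df.iterrows():
        try:
            a = _read_gray(base / str(row["path_a"]))
            b = _read_gray(base / str(row["path_b"]))
            mask = _read_gray(base / str(row["path_mask"])) > 0
        except (FileNotFoundError, OSError) as exc:
            raise ValueError(
                f"manifest row {idx} (cell {row['cell_id']!r}): cannot read input: {exc}"
            ) from exc
        image = TwoChannelImage(channel_a=a, channel_b=b)
        roi = ROI(mask=mask, label=str(row["cell_id"]))
        res = weighted_coloc(
            image, roi, float(row["thr_a"]), float(row["thr_b"]), denominator
        )
        rows.append(
            {
                "cell_id": row["cell_id"],
                "condition": row["condition"],
                "coefficient": res.coefficient,
                "thr_a": res.thr_a,
                "thr_b": res.thr_b,
                "n_pixels_a": res.n_pixels_a,
                "n_overlap": res.n_overlap,
                "empty_denominator": res.empty_denominator,
            }
        )
    per_cell = pd.DataFrame(rows)
    summary = (
        per_cell.groupby("condition", sort=True)["coefficient"]
        .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return per_cell, summary
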