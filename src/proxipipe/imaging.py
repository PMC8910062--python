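"""Ratiometric surface:total quantification of reporter micrographs.

Input fields are projected 16-bit images with a "surface" channel (an
extracellular epitope stained without permeabilization, so only reporter at
the plasma membrane is labelled) and a "total" channel (a fluorescent moiety
reporting all reporter protein in the cell).  Per field:

1. the background of each channel is the centre of the most populated
   histogram bin of a cell-free region (or of the whole image when no
   region is demarcated — valid when cells cover a minority of pixels);
2. each channel is thresholded stringently: a pixel is kept when its
   background-subtracted value strictly exceeds k times the background
   (defaults: k = 7 for surface, k = 20 for total), and kept pixels carry
   their background-subtracted values;
3. the mean retained intensity of each channel is taken, and the field's
   trafficking readout is the ratio mean_surface / mean_total.

Fields are aggregated pixels -> field -> experiment -> condition: per
experiment the field ratios are averaged, per condition the experiment
means are averaged and normalized to the control condition, with the SEM
and a two-sided Student t-test against control computed over experiment
means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from .errors import ValidationError

MIN_BACKGROUND_PIXELS = 100
K_SURFACE = 7.0
K_TOTAL = 20.0


@dataclass
class FieldImage:
    """One projected multi-channel field."""

    surface: np.ndarray
    total: np.ndarray
    nuclear: np.ndarray | None = None
    background_mask: np.ndarray | None = None  # True on cell-free pixels

    def __post_init__(self):
        self.surface = np.asarray(self.surface)
        self.total = np.asarray(self.total)
        if self.surface.shape != self.total.shape:
            raise ValidationError("surface and total channels differ in shape")
        for name in ("nuclear", "background_mask"):
            arr = getattr(self, name)
            if arr is not None and np.asarray(arr).shape != self.surface.shape:
                raise ValidationError(f"{name} shape differs from channels")
        for chan in (self.surface, self.total):
            if chan.min() < 0 or chan.max() > 65535:
                raise ValidationError("intensities must lie in the 16-bit range")


@dataclass(frozen=True)
class FieldQuant:
    """Per-field quantification; ``valid`` is False when a channel retained
    no pixels after thresholding."""

    background_surface: float
    background_total: float
    mean_surface: float
    mean_total: float
    ratio: float
    n_pixels_surface: int
    n_pixels_total: int
    valid: bool


def estimate_background(
    image: np.ndarray, region_mask: np.ndarray | None = None, bin_width: int = 1
) -> float:
    """Most populated histogram bin of the (masked) pixel values.

    Values are binned as ``floor(v / bin_width)``; the returned background
    is the centre of the winning bin, which for ``bin_width == 1`` on
    integer data is simply the modal pixel value.  Ties go to the lowest
    bin.
    """
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    pixels = np.asarray(image)
    if region_mask is not None:
        pixels = pixels[np.asarray(region_mask, dtype=bool)]
    pixels = pixels.ravel()
    if pixels.size < MIN_BACKGROUND_PIXELS:
        raise ValidationError(
            f"background region too small ({pixels.size} < {MIN_BACKGROUND_PIXELS} pixels)"
        )
    bins = np.floor_divide(pixels.astype(np.int64), bin_width)
    counts = np.bincount(bins)
    k = int(np.argmax(counts))
    return float(k * bin_width + (bin_width - 1) / 2.0)


def threshold_channel(
    image: np.ndarray, background: float, k: float
) -> tuple[np.ndarray, int]:
    """Retain background-subtracted pixels strictly above k x background.

    Returns the 1-D array of retained (background-subtracted) values and
    their count.  A zero background retains every positive pixel and emits
    a warning, since the multiplicative cutoff is then vacuous.
    """
    if k <= 0:
        raise ValidationError("threshold multiplier k must be positive")
    if background < 0:
        raise ValidationError("background must be non-negative")
    if background == 0:
        warnings.warn("background is 0; every positive pixel retained")
    sub = np.asarray(image, dtype=float) - background
    retained = sub[sub > k * background]
    return retained, int(retained.size)


def quantify_field(
    field: FieldImage,
    k_surface: float = K_SURFACE,
    k_total: float = K_TOTAL,
    bin_width: int = 1,
) -> FieldQuant:
    """Background-estimate, threshold and ratio one field."""
    bg_s = estimate_background(field.surface, field.background_mask, bin_width)
    bg_t = estimate_background(field.total, field.background_mask, bin_width)
    ret_s, n_s = threshold_channel(field.surface, bg_s, k_surface)
    ret_t, n_t = threshold_channel(field.total, bg_t, k_total)
    valid = n_s > 0 and n_t > 0
    if not valid:
        warnings.warn("field retained no pixels in a channel; marked invalid")
        return FieldQuant(bg_s, bg_t, 0.0, 0.0, float("nan"), n_s, n_t, False)
    mean_s = float(ret_s.mean())
    mean_t = float(ret_t.mean())
    return FieldQuant(bg_s, bg_t, mean_s, mean_t, mean_s / mean_t, n_s, n_t, True)


def quants_to_frame(
    records: Iterable[tuple[str, str, FieldQuant]]
) -> pd.DataFrame:
    """Flatten (condition, experiment, FieldQuant) records to a DataFrame."""
    rows = [
        (
            cond,
            exp,
            q.mean_surface,
            q.mean_total,
            q.ratio,
            q.valid,
        )
        for cond, exp, q in records
    ]
    return pd.DataFrame(
        rows,
        columns=["condition", "experiment", "mean_surface", "mean_total", "ratio", "valid"],
    )


_MEASURES = {"surface": "mean_surface", "total": "mean_total", "ratio": "ratio"}


def aggregate_experiment(
    quants: pd.DataFrame, control_condition: str
) -> pd.DataFrame:
    """Condition-level summary normalized to the control condition.

    *quants* is the frame produced by :func:`quants_to_frame`.  Invalid
    fields are dropped.  For each of surface, total and ratio: experiment
    means are averaged per condition and divided by the control condition's
    mean; the SEM is taken over the normalized experiment means; the
    p-value is a two-sided Student t-test of the condition's experiment
    means against the control's.
    """
    df = quants[quants["valid"]].copy()
    if control_condition not in set(df["condition"]):
        raise ValidationError(f"control condition {control_condition!r} missing")
    exp_means = df.groupby(["condition", "experiment"])[
        ["mean_surface", "mean_total", "ratio"]
    ].mean()
    n_ctrl_exps = exp_means.loc[control_condition].shape[0]
    if n_ctrl_exps < 2:
        raise ValidationError(">= 2 experiments required for significance testing")
    rows = []
    for cond in sorted(exp_means.index.get_level_values(0).unique()):
        row: dict[str, object] = {"condition": cond}
        for name, col in _MEASURES.items():
            vals = exp_means.loc[cond][col].to_numpy()
            ctrl = exp_means.loc[control_condition][col].to_numpy()
            norm = vals / ctrl.mean()
            row[f"mean_{name}_norm"] = float(norm.mean())
            row[f"sem_{name}"] = (
                float(norm.std(ddof=1) / np.sqrt(len(norm))) if len(norm) > 1 else float("nan")
            )
            if cond == control_condition:
                row[f"p_{name}"] = 1.0
            else:
                p = stats.ttest_ind(vals, ctrl, equal_var=True).pvalue
                row[f"p_{name}"] = 1.0 if np.isnan(p) else float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("condition")


# -- TIFF IO ---------------------------------------------------------------


def read_field_tiff(
    path, channel_order: Sequence[str] = ("surface", "total", "nuclear"), mask_path=None
) -> FieldImage:
    """Read a multi-page/multi-channel 16-bit TIFF into a FieldImage.

    ``channel_order`` names the pages/leading axis entries; ``surface`` and
    ``total`` are required.  An optional companion mask TIFF (non-zero =
    cell-free background) can be supplied.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValidationError("field TIFF must contain >= 2 channels")
    channels = {name: arr[i] for i, name in enumerate(channel_order) if i < arr.shape[0]}
    if "surface" not in channels or "total" not in channels:
        raise ValidationError("channel_order must provide 'surface' and 'total'")
    mask = None
    if mask_path is not None:
        mask = tifffile.imread(mask_path) > 0
    return FieldImage(
        surface=channels["surface"],
        total=channels["total"],
        nuclear=channels.get("nuclear"),
        background_mask=mask,
    )


def write_field_tiff(field: FieldImage, path, mask_path=None) -> None:
    """Write a FieldImage as a multi-page 16-bit TIFF (surface, total[, nuclear])."""
    pages = [field.surface, field.total]
    if field.nuclear is not None:
        pages.append(field.nuclear)
    tifffile.imwrite(path, np.stack([p.astype(np.uint16) for p in pages]))
    if mask_path is not None and field.background_mask is not None:
        tifffile.imwrite(mask_path, field.background_mask.astype(np.uint8))
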