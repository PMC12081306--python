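"""From multichannel pulse/chase images to fraction-pulse and lifetime maps.

The pipeline mirrors a standard fluorescence quantification workflow:

1. percentile normalization (segmentation only -- quantification always uses
   raw intensities plus calibration),
2. optional block-mean downsampling,
3. object segmentation (nuclei from a nuclear stain, or puncta from the
   pulse+chase sum) -- a classical smoothing/threshold/size-filter stand-in
   for externally trained classifiers, whose label maps are accepted as-is,
4. local background estimation in an annulus around each object,
5. conversion of background-subtracted intensity to micromolar dye via a
   linear per-channel calibration,
6. fraction pulse and lifetime per object or per pixel,
7. aggregation over a region label map (atlas stand-in) with exclusion of
   configured region ids and of regions failing a negative-control intensity
   threshold (mean + 2 SD of tag-free control animals, per channel).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology

from . import estimation
from .errors import DomainError, SegmentationError

__all__ = [
    "QuantImage", "ChannelCalibration", "CalibrationCurve", "Background",
    "normalize_channels", "downsample", "segment_objects", "local_background",
    "to_micromolar", "quantify", "quantify_pixels", "median_filter_lifetime",
    "aggregate_regions", "negative_control_filter",
    "triple_label_observations",
]

CHANNEL_ROLES = ("nuclear_stain", "pulse", "chase", "chase2", "immunolabel")

#: percentile anchors of the segmentation normalization
NORM_PERCENTILES = (0.3, 99.7)

#: default region-label exclusion reason for atlas root / fibers / ventricles
ATLAS_EXCLUSION_REASON = "atlas_root_or_fiber_or_ventricle"


@dataclass
class QuantImage:
    """Named 2-D channels with fixed roles and a common shape.

    ``channels`` maps a role from ``CHANNEL_ROLES`` to a non-negative float
    array; ``pulse`` and ``chase`` must be present. ``pixel_size_um`` is the
    side of a pixel in micrometers.
    """

    channels: dict
    pixel_size_um: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "pulse" not in self.channels or "chase" not in self.channels:
            raise DomainError("pulse and chase channels are required")
        shapes = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise DomainError(f"unknown channel role {role!r}")
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise DomainError(f"channel {role!r} has negative intensities")
            self.channels[role] = arr
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise DomainError("all channels must share one shape")
        if self.pixel_size_um <= 0:
            raise DomainError("pixel_size_um must be > 0")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role: str) -> np.ndarray:
        return self.channels[role]

    @property
    def has_chase2(self) -> bool:
        return "chase2" in self.channels


class ChannelCalibration(NamedTuple):
    """Linear fluorescence-to-concentration calibration for one channel."""

    slope: float  # intensity units per uM
    intercept: float  # intensity at 0 uM
    valid_range: tuple = (0.0, math.inf)  # uM


class CalibrationCurve(dict):
    """Mapping of channel role -> :class:`ChannelCalibration`."""

    def __init__(self, mapping):
        super().__init__()
        for role, cal in dict(mapping).items():
            cal = ChannelCalibration(*cal)
            if cal.slope <= 0:
                raise DomainError(f"calibration slope for {role!r} must be > 0")
            self[role] = cal

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CalibrationCurve":
        """Build from a table with channel / slope / intercept columns."""
        mapping = {}
        for _, row in frame.iterrows():
            rng = (float(row.get("range_low", 0.0)),
                   float(row.get("range_high", math.inf)))
            mapping[row["channel"]] = ChannelCalibration(
                float(row["slope"]), float(row["intercept"]), rng)
        return cls(mapping)


def normalize_channels(image: QuantImage) -> QuantImage:
    """Rescale every channel so the 0.3/99.7 intensity percentiles map to 0/1.

    The output is clipped to [0, 1] and intended for segmentation only;
    quantification always works on raw intensities with the calibration.
    """
    out = {}
    for role, arr in image.channels.items():
        lo, hi = np.percentile(arr, NORM_PERCENTILES)
        if hi <= lo:
            raise DomainError(
                f"channel {role!r} is (nearly) constant; normalization is "
                "degenerate")
        out[role] = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    return QuantImage(channels=out, pixel_size_um=image.pixel_size_um,
                      metadata=dict(image.metadata))


def _block_mean(arr: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean pooling; trailing partial blocks average actual pixels."""
    sums = measure.block_reduce(arr, (factor, factor), np.sum, cval=0.0)
    counts = measure.block_reduce(np.ones_like(arr), (factor, factor),
                                  np.sum, cval=0.0)
    return sums / counts


def downsample(image: QuantImage, factor: int) -> QuantImage:
    """Block-mean downsample all channels; pixel size scales by ``factor``."""
    if int(factor) != factor or factor < 1:
        raise DomainError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return image
    out = {role: _block_mean(arr, factor)
           for role, arr in image.channels.items()}
    return QuantImage(channels=out,
                      pixel_size_um=image.pixel_size_um * factor,
                      metadata=dict(image.metadata))


_SEGMENT_DEFAULTS = {
    "nuclei": {"sigma": 2.0, "min_area": 40, "max_area": 10000},
    "puncta": {"sigma": 1.0, "min_area": 3, "max_area": 500},
}


def segment_objects(image: QuantImage, mode: str = "nuclei",
                    threshold: float | None = None,
                    sigma: float | None = None,
                    min_area: int | None = None,
                    max_area: int | None = None) -> np.ndarray:
    """Classical segmentation stand-in: smooth, threshold, size-filter, label.

    ``nuclei`` mode segments the nuclear-stain channel; ``puncta`` mode the
    pulse+chase sum. ``threshold`` is absolute (on the smoothed image); when
    None, Otsu's threshold is used. Returns an integer label map (0 =
    background). Externally produced label maps can be used everywhere a
    label map is accepted, bypassing this function.
    """
    if mode not in _SEGMENT_DEFAULTS:
        raise DomainError("mode must be 'nuclei' or 'puncta'")
    defaults = _SEGMENT_DEFAULTS[mode]
    sigma = defaults["sigma"] if sigma is None else sigma
    min_area = defaults["min_area"] if min_area is None else min_area
    max_area = defaults["max_area"] if max_area is None else max_area

    if mode == "nuclei":
        if "nuclear_stain" not in image.channels:
            raise DomainError("nuclei mode requires a nuclear_stain channel")
        data = image["nuclear_stain"]
    else:
        data = image["pulse"] + image["chase"]
    smoothed = filters.gaussian(data, sigma=sigma, preserve_range=True)
    thr = filters.threshold_otsu(smoothed) if threshold is None else threshold
    mask = smoothed > thr
    labels = measure.label(mask)
    # size filter
    for region in measure.regionprops(labels):
        if not (min_area <= region.area <= max_area):
            labels[labels == region.label] = 0
    labels = measure.label(labels > 0)
    if labels.max() == 0:
        warnings.warn("segmentation found zero objects")
    return labels


class Background(NamedTuple):
    """A local background estimate; ``global_fallback`` marks the fallback."""

    value: float
    global_fallback: bool = False


def local_background(channel: np.ndarray, label_map: np.ndarray,
                     object_id: int, *, inner_margin: int = 1,
                     width: int = 5,
                     artifact_mask: np.ndarray | None = None) -> Background:
    """Median intensity of an annulus around one object.

    The annulus starts ``inner_margin`` pixels outside the object mask and is
    ``width`` pixels wide; pixels of any object and of the optional artifact
    mask are excluded. If nothing remains, the median of all non-object,
    non-artifact pixels in the image is returned with
    ``global_fallback=True``.
    """
    mask = label_map == object_id
    if not mask.any():
        raise DomainError(f"object {object_id} not present in label map")
    pad = inner_margin + width + 1
    rows, cols = np.nonzero(mask)
    r0 = max(rows.min() - pad, 0)
    r1 = min(rows.max() + pad + 1, label_map.shape[0])
    c0 = max(cols.min() - pad, 0)
    c1 = min(cols.max() + pad + 1, label_map.shape[1])
    sub_mask = mask[r0:r1, c0:c1]
    sub_labels = label_map[r0:r1, c0:c1]
    sub_channel = channel[r0:r1, c0:c1]

    inner = ndimage.binary_dilation(sub_mask,
                                    morphology.disk(inner_margin))
    outer = ndimage.binary_dilation(sub_mask,
                                    morphology.disk(inner_margin + width))
    annulus = outer & ~inner & (sub_labels == 0)
    if artifact_mask is not None:
        annulus &= ~artifact_mask[r0:r1, c0:c1].astype(bool)
    if annulus.any():
        return Background(float(np.median(sub_channel[annulus])), False)
    free = label_map == 0
    if artifact_mask is not None:
        free &= ~artifact_mask.astype(bool)
    if not free.any():
        raise SegmentationError("no background pixels available at all")
    return Background(float(np.median(channel[free])), True)


def to_micromolar(intensity, background, calibration: ChannelCalibration,
                  *, return_flags: bool = False):
    """Convert background-subtracted intensity to micromolar concentration.

    ``uM = max(intensity - background, 0) / slope``. The estimated background
    (annulus median or per-pixel map) already contains the calibration
    intercept, so only the slope enters. Negative differences clamp to 0
    (``clamped`` flag); values outside the calibration's valid range set the
    ``extrapolated`` flag. Works elementwise on arrays.
    """
    intensity = np.asarray(intensity, dtype=float)
    diff = intensity - background
    clamped = diff < 0
    um = np.where(clamped, 0.0, diff) / calibration.slope
    lo, hi = calibration.valid_range
    extrapolated = (um < lo) | (um > hi)
    if um.ndim == 0:
        um = float(um)
        clamped = bool(clamped)
        extrapolated = bool(extrapolated)
    if return_flags:
        return um, {"clamped": clamped, "extrapolated": extrapolated}
    return um


def triple_label_observations(um_pulse: float, um_chase1: float,
                              um_chase2: float, t_pulse: float,
                              t_chase1: float, t_chase2: float) -> list:
    """The three survival ratios of a one-pulse/two-chase design.

    Each ratio is paired with the time window over which it is treated as an
    exponential survival: pulse/(pulse+chase1) with the pulse-to-chase1
    interval, (pulse+chase1)/total with the pulse-to-chase2 interval, and
    chase1/(chase1+chase2) with the chase1-to-chase2 interval. Returns
    ``[(fraction, interval_days), ...]`` suitable for
    :func:`pulsechase.estimation.multi_interval_fit`.
    """
    if not t_pulse < t_chase1 < t_chase2:
        raise DomainError("need t_pulse < t_chase1 < t_chase2")
    obs = []
    if um_pulse + um_chase1 > 0:
        obs.append((um_pulse / (um_pulse + um_chase1), t_chase1 - t_pulse))
    total = um_pulse + um_chase1 + um_chase2
    if total > 0:
        obs.append(((um_pulse + um_chase1) / total, t_chase2 - t_pulse))
    if um_chase1 + um_chase2 > 0:
        obs.append((um_chase1 / (um_chase1 + um_chase2), t_chase2 - t_chase1))
    return obs


def _object_lifetime(fp: float | None, delta_t: float):
    """(lifetime, flag) for one object's fraction pulse."""
    if fp is None:
        return np.nan, "undefined_fraction"
    if fp >= 1.0:
        return np.nan, "infinite_lifetime"
    if fp <= 0.0:
        return np.nan, "zero_fraction"
    return estimation.lifetime_from_fraction(fp, delta_t), ""


def quantify(image: QuantImage, label_map: np.ndarray,
             calibration: CalibrationCurve, delta_t: float, *,
             inner_margin: int = 1, annulus_width: int = 5,
             artifact_mask: np.ndarray | None = None,
             region_map: np.ndarray | None = None) -> pd.DataFrame:
    """Per-object intensities, micromolar amounts, fraction pulse, lifetime.

    For every labeled object the per-channel mean intensity and local
    background are measured, converted to micromolar via the calibration, and
    combined into a fraction pulse and a lifetime over ``delta_t`` days. With
    a ``chase2`` channel the three triple-label survival ratios are reported
    and the headline fraction pulse is (pulse+chase)/(pulse+chase+chase2).
    Undefined or infinite lifetimes are flagged, not dropped.
    """
    if delta_t <= 0:
        raise DomainError("delta_t must be > 0")
    label_map = np.asarray(label_map)
    if label_map.shape != image.shape:
        raise DomainError("label map shape mismatch")
    roles = ["pulse", "chase"] + (["chase2"] if image.has_chase2 else [])
    for role in roles:
        if role not in calibration:
            raise DomainError(f"calibration missing channel {role!r}")

    rows = []
    for region in measure.regionprops(label_map):
        row = {"label": region.label, "n_pixels": int(region.area),
               "centroid_row": region.centroid[0],
               "centroid_col": region.centroid[1]}
        um = {}
        for role in image.channels:
            mask = label_map == region.label
            mean_int = float(image[role][mask].mean())
            row[f"mean_{role}"] = mean_int
            if role in calibration:
                bg = local_background(image[role], label_map, region.label,
                                      inner_margin=inner_margin,
                                      width=annulus_width,
                                      artifact_mask=artifact_mask)
                row[f"background_{role}"] = bg.value
                row[f"background_global_{role}"] = bg.global_fallback
                um[role] = to_micromolar(mean_int, bg.value, calibration[role])
                row[f"um_{role}"] = um[role]
        if image.has_chase2:
            total = um["pulse"] + um["chase"] + um["chase2"]
            fp = (um["pulse"] + um["chase"]) / total if total > 0 else None
        else:
            total = um["pulse"] + um["chase"]
            fp = um["pulse"] / total if total > 0 else None
        row["total_protein_um"] = total
        row["fraction_pulse"] = np.nan if fp is None else fp
        lifetime, flag = _object_lifetime(fp, delta_t)
        row["lifetime_days"] = lifetime
        row["flag"] = flag
        if region_map is not None:
            vals, counts = np.unique(
                region_map[label_map == region.label], return_counts=True)
            row["region_id"] = int(vals[np.argmax(counts)])
        rows.append(row)
    return pd.DataFrame(rows)


def quantify_pixels(image: QuantImage, calibration: CalibrationCurve,
                    delta_t: float, *,
                    background: dict | None = None,
                    protein_floor_um: float = 0.0,
                    downsample_factor: int = 1) -> dict:
    """Per-pixel micromolar, fraction-pulse and lifetime maps.

    ``background`` maps a channel role to a scalar or array subtracted before
    calibration (default: the channel's calibration intercept). Pixels whose
    total protein (pulse+chase uM) does not exceed ``protein_floor_um`` are
    masked invalid before the lifetime conversion, so noise-dominated ratios
    never produce lifetimes. Returns a dict of maps plus the validity mask.
    """
    if delta_t <= 0:
        raise DomainError("delta_t must be > 0")
    if downsample_factor > 1:
        image = downsample(image, downsample_factor)
    background = background or {}
    um = {}
    for role in ("pulse", "chase"):
        bg = background.get(role, calibration[role].intercept)
        um[role] = to_micromolar(image[role], bg, calibration[role])
    total = um["pulse"] + um["chase"]
    valid = total > protein_floor_um
    with np.errstate(invalid="ignore", divide="ignore"):
        fp = np.where(valid, um["pulse"] / np.where(valid, total, 1.0), np.nan)
        defined = valid & (fp > 0) & (fp < 1)
        lifetime = np.where(defined, delta_t / np.log(1.0 / np.clip(
            fp, 1e-300, estimation.FRACTION_CLIP)), np.nan)
    return {"um_pulse": um["pulse"], "um_chase": um["chase"],
            "total_protein_um": total, "fraction_pulse": fp,
            "lifetime_days": lifetime, "valid": defined,
            "pixel_size_um": image.pixel_size_um}


def median_filter_lifetime(lifetime_map: np.ndarray,
                           size: int = 3) -> np.ndarray:
    """NaN-tolerant median filter applied before per-condition capping."""
    arr = np.asarray(lifetime_map, dtype=float)
    return ndimage.generic_filter(arr, np.nanmedian, size=size,
                                  mode="nearest")


def aggregate_regions(data, region_map: np.ndarray, *,
                      exclude_ids: tuple = (0,),
                      animal_id=None) -> pd.DataFrame:
    """Aggregate a lifetime map or object table over a region label map.

    ``data`` is either the dict returned by :func:`quantify_pixels` or an
    object table with a ``region_id`` column. Per region the mean and median
    lifetime, total protein and pixel/object count are reported. Pixels whose
    region id is in ``exclude_ids`` (atlas root, fiber tracts, ventricles)
    are dropped and reported as excluded rows.
    """
    rows = []
    if isinstance(data, dict):
        region_map = np.asarray(region_map)
        if region_map.shape != data["lifetime_days"].shape:
            raise DomainError("region map shape mismatch")
        valid = data["valid"]
        for rid in np.unique(region_map):
            sel = (region_map == rid) & valid
            if int(rid) in exclude_ids:
                rows.append({"animal_id": animal_id, "region_id": int(rid),
                             "n_pixels": int(sel.sum()), "excluded": True,
                             "reason": ATLAS_EXCLUSION_REASON})
                continue
            if not sel.any():
                continue
            lt = data["lifetime_days"][sel]
            rows.append({
                "animal_id": animal_id, "region_id": int(rid),
                "mean_lifetime_days": float(np.mean(lt)),
                "median_lifetime_days": float(np.median(lt)),
                "total_protein_um": float(np.sum(data["total_protein_um"][sel])),
                "mean_pulse": float(np.mean(data["um_pulse"][sel])),
                "mean_chase": float(np.mean(data["um_chase"][sel])),
                "n_pixels": int(sel.sum()), "excluded": False, "reason": ""})
    else:
        table = data
        if "region_id" not in table.columns:
            raise DomainError("object table needs a region_id column")
        for rid, grp in table.groupby("region_id"):
            if int(rid) in exclude_ids:
                rows.append({"animal_id": animal_id, "region_id": int(rid),
                             "n_pixels": int(grp["n_pixels"].sum()),
                             "excluded": True,
                             "reason": ATLAS_EXCLUSION_REASON})
                continue
            lt = grp["lifetime_days"].dropna()
            rows.append({
                "animal_id": animal_id, "region_id": int(rid),
                "mean_lifetime_days": float(lt.mean()),
                "median_lifetime_days": float(lt.median()),
                "total_protein_um": float(grp["total_protein_um"].sum()),
                "mean_pulse": float(grp["um_pulse"].mean()),
                "mean_chase": float(grp["um_chase"].mean()),
                "n_pixels": int(grp["n_pixels"].sum()),
                "excluded": False, "reason": ""})
    return pd.DataFrame(rows)


def negative_control_filter(control_tables, signal_table: pd.DataFrame,
                            n_sd: float = 2.0,
                            channels: tuple = ("mean_pulse", "mean_chase")
                            ) -> pd.DataFrame:
    """Exclude regions not clearly above tag-free control autofluorescence.

    ``control_tables`` is a list of per-animal region tables from control
    animals lacking the protein tag, each with ``region_id`` and the
    ``channels`` columns. Per region and channel the threshold is the control
    mean + ``n_sd`` standard deviations (across control animals; at least two
    controls required, otherwise the region is excluded with reason
    ``no_control``). A signal region failing the threshold in *either*
    channel is marked excluded with reason ``negative_control_threshold``.
    """
    controls = pd.concat(
        [t.assign(_animal=i) for i, t in enumerate(control_tables)],
        ignore_index=True)
    stats_tbl = controls.groupby("region_id")[list(channels)].agg(
        ["mean", "std", "count"])

    out = signal_table.copy()
    out["excluded"] = out.get("excluded", False)
    out["reason"] = out.get("reason", "")
    for idx, row in out.iterrows():
        if row["excluded"]:
            continue
        rid = row["region_id"]
        if rid not in stats_tbl.index:
            out.loc[idx, ["excluded", "reason"]] = True, "no_control"
            continue
        ok = True
        for ch in channels:
            n = stats_tbl.loc[rid, (ch, "count")]
            if n < 2 or not np.isfinite(stats_tbl.loc[rid, (ch, "std")]):
                out.loc[idx, ["excluded", "reason"]] = True, "no_control"
                ok = False
                break
            thr = (stats_tbl.loc[rid, (ch, "mean")]
                   + n_sd * stats_tbl.loc[rid, (ch, "std")])
            if row[ch] <= thr:
                ok = False
                out.loc[idx, ["excluded", "reason"]] = (
                    True, "negative_control_threshold")
                break
        if ok:
            out.loc[idx, "excluded"] = False
    return out
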