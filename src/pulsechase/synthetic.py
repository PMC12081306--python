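"""Synthetic fixtures with known ground truth for every other module.

The generators emulate the statistical structure the analyses assume:
single-exponential turnover (per-object fraction pulse ``exp(-dt/tau)``
exactly by construction), linear fluorescence calibration with an instrument
offset, smooth neuropil background, Poisson shot noise plus additive Gaussian
read noise (the standard fluorescence camera model), bi-exponential clearance
traces on an uneven sampling grid, and per-animal x per-region lifetime
tables with group effects and animal-level random offsets.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clearance import ClearanceTrace
from .errors import DomainError, SegmentationError
from .imagequant import CalibrationCurve, QuantImage

__all__ = ["GroundTruth", "make_image", "make_region_dataset",
           "make_clearance_trace", "DEFAULT_CALIBRATION"]

#: slope (intensity per uM) and intercept used by default in forward models
DEFAULT_CALIBRATION = CalibrationCurve({
    "pulse": (40.0, 100.0),
    "chase": (40.0, 100.0),
    "chase2": (40.0, 100.0),
    "nuclear_stain": (40.0, 100.0),
})


@dataclass
class GroundTruth:
    """Per-object truth plus everything needed for an exact round trip."""

    objects: pd.DataFrame  # label, row, col, radius, tau_days, um_pulse, ...
    label_map: np.ndarray  # perfect masks (0 = background)
    delta_t: float
    seed: int | None
    calibration: CalibrationCurve
    background_intensity: float
    noise: dict = field(default_factory=dict)


def _place_objects(rng, shape, n_objects, radius, min_separation,
                   max_tries=20000):
    """Rejection-sample non-overlapping centers; error when space runs out."""
    centers = []
    margin = radius + 2
    for _ in range(max_tries):
        if len(centers) == n_objects:
            break
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_separation ** 2
               for rr, cc in centers):
            centers.append((r, c))
    if len(centers) < n_objects:
        raise SegmentationError(
            f"placed only {len(centers)}/{n_objects} objects without overlap")
    return centers


def make_image(n_objects: int = 100, mode: str = "nuclei",
               tau_days=10.0, delta_t: float = 7.0, snr: float = 20.0,
               *, shape: tuple = (512, 512), total_um: float = 5.0,
               background_intensity: float = 60.0,
               background_gradient: float = 0.0,
               calibration: CalibrationCurve = DEFAULT_CALIBRATION,
               seed: int | None = 0) -> tuple[QuantImage, GroundTruth]:
    """Render a pulse/chase image with known per-object lifetimes.

    ``tau_days`` is a scalar, a length-``n_objects`` sequence, or a callable
    of the (row, col) center. Per object the fraction pulse is exactly
    ``exp(-delta_t/tau)``; pulse/chase micromolar amounts split ``total_um``
    accordingly and are pushed through the linear calibration onto a smooth
    background (optionally with a vertical gradient of
    ``background_gradient`` intensity units per pixel). ``snr`` is the ratio
    of the mean object pulse-signal amplitude to the total noise standard
    deviation at that intensity; ``snr=inf`` disables noise entirely. Nuclei
    are uniform disks (radius ~10 px) with a matching nuclear-stain channel;
    puncta are Gaussian spots (sigma ~2 px).
    """
    if n_objects < 1:
        raise DomainError("n_objects must be >= 1")
    if delta_t <= 0 or total_um <= 0 or snr <= 0:
        raise DomainError("delta_t, total_um and snr must be > 0")
    rng = np.random.default_rng(seed)

    if mode == "nuclei":
        radius, min_sep = 10.0, 24.0
    elif mode == "puncta":
        radius, min_sep = 2.0, 9.0
    else:
        raise DomainError("mode must be 'nuclei' or 'puncta'")

    centers = _place_objects(rng, shape, n_objects, radius, min_sep)
    if callable(tau_days):
        taus = np.array([float(tau_days(r, c)) for r, c in centers])
    else:
        taus = np.broadcast_to(np.asarray(tau_days, dtype=float),
                               (n_objects,)).copy()
    if np.any(taus <= 0):
        raise DomainError("all lifetimes must be > 0")

    fp = np.exp(-delta_t / taus)
    um_pulse = fp * total_um
    um_chase = (1.0 - fp) * total_um

    um_maps = {"pulse": np.zeros(shape), "chase": np.zeros(shape)}
    stain = np.zeros(shape)
    label_map = np.zeros(shape, dtype=np.int32)
    rr_idx, cc_idx = np.mgrid[0:shape[0], 0:shape[1]]
    records = []
    for i, (r, c) in enumerate(centers):
        dist2 = (rr_idx - r) ** 2 + (cc_idx - c) ** 2
        if mode == "nuclei":
            mask = dist2 <= radius ** 2
            profile = mask.astype(float)
        else:
            profile = np.exp(-dist2 / (2.0 * radius ** 2))
            profile[dist2 > (4 * radius) ** 2] = 0.0
            mask = profile > 0.05
        um_maps["pulse"] += um_pulse[i] * profile
        um_maps["chase"] += um_chase[i] * profile
        stain += 3.0 * total_um * profile
        label_map[mask] = i + 1
        records.append({"label": i + 1, "row": r, "col": c,
                        "radius": radius, "tau_days": taus[i],
                        "fraction_pulse": fp[i], "um_pulse": um_pulse[i],
                        "um_chase": um_chase[i],
                        "total_um": total_um})

    grad = background_gradient * rr_idx
    channels = {}
    signal_amp = calibration["pulse"].slope * float(np.mean(um_pulse))
    noise_sd = 0.0 if math.isinf(snr) else signal_amp / snr
    noise_meta = {"snr": snr, "noise_sd": noise_sd}
    sources = {"pulse": um_maps["pulse"], "chase": um_maps["chase"]}
    if mode == "nuclei":
        sources["nuclear_stain"] = stain
    for role, um_map in sources.items():
        cal = calibration[role]
        clean = cal.intercept + cal.slope * um_map + background_intensity + grad
        if noise_sd == 0.0:
            channels[role] = clean
        else:
            # Poisson shot noise (80% of the budget) + Gaussian read noise
            shot_sd = 0.8 * noise_sd
            read_sd = noise_sd * math.sqrt(1.0 - 0.8 ** 2)
            peak = cal.intercept + cal.slope * total_um + background_intensity
            gain = peak / shot_sd ** 2  # counts per intensity unit
            noisy = rng.poisson(np.clip(clean, 0, None) * gain) / gain
            noisy = noisy + rng.normal(0.0, read_sd, size=shape)
            channels[role] = np.clip(noisy, 0.0, None)

    image = QuantImage(channels=channels,
                       metadata={"mode": mode, "seed": seed})
    truth = GroundTruth(objects=pd.DataFrame(records), label_map=label_map,
                        delta_t=delta_t, seed=seed, calibration=calibration,
                        background_intensity=background_intensity,
                        noise=noise_meta)
    return image, truth


def make_region_dataset(n_animals_per_group: int = 4,
                        regions: dict | int = 12,
                        group_effects: dict | None = None,
                        animal_sd: float = 0.5,
                        residual_sd: float = 1.4,
                        n_pixels: int = 1000,
                        seed: int | None = 0) -> pd.DataFrame:
    """Per-pixel long lifetime table with group and animal effects.

    ``lifetime = region_mean + group_effect + animal_offset + noise`` per
    pixel. ``regions`` is either a count (region means spread over 11-17
    days, the range typical of synaptic scaffold proteins) or a dict
    ``region_id -> mean lifetime``. ``group_effects`` maps group name to an
    additive effect in days (default: control 0, enriched -2.4, i.e. a ~17%
    lifetime reduction on a 14.2-day baseline). Animal offsets are normal
    with SD ``animal_sd``; pixel noise with SD ``residual_sd``. At most
    ``n_pixels`` rows are emitted per animal x region, matching the capped
    tables downstream mixed models consume.
    """
    if group_effects is None:
        group_effects = {"control": 0.0, "enriched": -2.4}
    rng = np.random.default_rng(seed)
    if isinstance(regions, int):
        means = np.linspace(11.0, 17.0, regions)
        regions = {i + 1: float(m) for i, m in enumerate(means)}
    rows = []
    animal_counter = 0
    for group, effect in group_effects.items():
        for _ in range(n_animals_per_group):
            animal_counter += 1
            offset = rng.normal(0.0, animal_sd)
            for rid, mean in regions.items():
                base = mean + effect + offset
                noise = rng.normal(0.0, residual_sd, size=n_pixels)
                rows.append(pd.DataFrame({
                    "animal_id": animal_counter, "group": group,
                    "region_id": rid,
                    "lifetime_days": base + noise}))
    return pd.concat(rows, ignore_index=True)


def make_clearance_trace(a: float = 100.0, tau1: float = 20.0,
                         b: float = 30.0, tau2: float = 400.0,
                         c: float = 5.0, *, noise_sd: float = 0.0,
                         seed: int | None = 0,
                         times_min: np.ndarray | None = None
                         ) -> ClearanceTrace:
    """Bi-exponential decay sampled on an uneven in vivo-like grid.

    Default sampling covers the first 4 h at 2-10 min spacing (densest right
    after the bolus) and then 4-12 h intervals out to ~24 h, mirroring awake
    imaging sessions. Gaussian noise of ``noise_sd`` a.u. is added when
    requested; the trace is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if times_min is None:
        early = np.cumsum(np.linspace(2.0, 10.0, 40))  # 0-4 h, widening
        late = []
        t = early[-1]
        while t < 1440.0:  # re-imaging out to ~24 h
            t += rng.uniform(240.0, 720.0)
            late.append(t)
        times_min = np.concatenate([[0.0], early, late])
    times_min = np.asarray(times_min, dtype=float)
    clean = (a * np.exp(-times_min / tau1) + b * np.exp(-times_min / tau2) + c)
    noisy = clean + rng.normal(0.0, noise_sd, size=times_min.shape) \
        if noise_sd > 0 else clean
    return ClearanceTrace(times=times_min, intensities=noisy)
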