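"""Synthetic segmented cardiac-like phantoms with demographics and a
rule-based reference classifier.

A phantom emulates a short-axis cardiac view: a circular left-ventricular
(LV) blood pool (code 1), a muscular myocardium ring around it (code 2)
whose thickness is the class-discriminating feature, and a right-ventricular
(RV) blood pool disk beside it (code 3), on a noisy background.  Intensity
bands are non-overlapping (background 0.1, blood pools 0.5, myocardium 0.9
on [0, 1]) so a simple threshold segmenter is well-posed.

The reference classifier reads *only pixels* (never masks): it counts
myocardium-band pixels inside a fixed window around the LV center and calls
the phantom "hypertensive" (label 1) when the count exceeds the annulus area
of the midpoint thickness between the two classes — hypertensive remodelling
thickens the LV wall, so wall thickness is the honest analog of the signal a
trained model would exploit.  Because the window geometrically excludes the
RV and the blood-pool intensity band, the classifier provably ignores both
cavities, which pins down the ground-truth attribution the counterfactual
engine should recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import SegmentMap, SegmentedInstance

__all__ = [
    "LV_CAVITY",
    "LV_MYOCARDIUM",
    "RV_CAVITY",
    "default_segmap",
    "PhantomParams",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
    "ReferenceClassifier",
    "reference_classifier",
    "threshold_segmenter",
]

LV_CAVITY = 1
LV_MYOCARDIUM = 2
RV_CAVITY = 3


def default_segmap() -> SegmentMap:
    return SegmentMap(
        (
            (LV_CAVITY, "LV cavity"),
            (LV_MYOCARDIUM, "LV myocardium"),
            (RV_CAVITY, "RV cavity"),
        )
    )


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, intensity and noise parameters of one phantom.

    Radii and thicknesses in pixels; intensities on [0, 1].  The myocardium
    annulus spans radii ``(lv_cavity_radius, lv_cavity_radius + myocardium_thickness]``
    around ``lv_center`` so the ring always encloses the cavity; the RV disk
    sits at ``lv_center + rv_offset`` with the LV structures carved out.
    """

    height: int = 128
    width: int = 128
    frames: int = 1
    lv_center: Tuple[float, float] = (64.0, 64.0)
    lv_cavity_radius: float = 20.0
    myocardium_thickness: float = 5.0
    rv_offset: Tuple[float, float] = (0.0, -44.0)
    rv_radius: float = 12.0
    intensity_background: float = 0.1
    intensity_cavity: float = 0.5
    intensity_myocardium: float = 0.9
    intensity_rv: float = 0.5
    noise_sd: float = 0.03
    center_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lv_cavity_radius <= 0 or self.rv_radius <= 0:
            raise ValueError("radii must be positive")
        if self.myocardium_thickness <= 0:
            raise ValueError("myocardium thickness must be positive")
        outer = self.lv_cavity_radius + self.myocardium_thickness
        r0, c0 = self.lv_center
        rv_r = r0 + self.rv_offset[0]
        rv_c = c0 + self.rv_offset[1]
        margin = self.center_jitter
        for rr, cc, rad in ((r0, c0, outer), (rv_r, rv_c, self.rv_radius)):
            if (
                rr - rad - margin < 0
                or rr + rad + margin >= self.height
                or cc - rad - margin < 0
                or cc + rad + margin >= self.width
            ):
                raise ValueError("phantom structure extends out of frame bounds")


@dataclass(frozen=True)
class CohortSpec:
    """Two-class phantom cohort: wall thickness separates the classes.

    Per-class thickness draws are Gaussian (truncated positive); the default
    thin N(3, 0.5) vs thick N(7, 0.5) px separation makes the reference
    classifier near-perfect by construction.  Demographics (age, sex, BMI)
    are generated alongside for cohort-filter exercises.
    """

    n_per_class: int = 10
    thickness_mean_thin: float = 3.0
    thickness_mean_thick: float = 7.0
    thickness_sd: float = 0.5
    frames: int = 1
    noise_sd: float = 0.03
    center_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.thickness_sd <= 0:
            raise ValueError("thickness_sd must be positive")
        if abs(self.thickness_mean_thick - self.thickness_mean_thin) < 4 * self.thickness_sd:
            raise ValueError(
                "class thickness distributions overlap too much for a "
                "well-posed reference task"
            )


def _disk(h: int, w: int, center: Tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_phantom(params: PhantomParams) -> SegmentedInstance:
    """Rasterize one phantom; deterministic for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    frames_px = np.empty((params.frames, h, w), dtype=float)
    frames_mask = np.empty((params.frames, h, w), dtype=np.int64)

    center = np.asarray(params.lv_center, dtype=float)
    if params.center_jitter > 0:
        center = center + rng.uniform(-params.center_jitter, params.center_jitter, size=2)
    rv_center = (center[0] + params.rv_offset[0], center[1] + params.rv_offset[1])

    cavity = _disk(h, w, tuple(center), params.lv_cavity_radius)
    outer = _disk(h, w, tuple(center), params.lv_cavity_radius + params.myocardium_thickness)
    annulus = outer & ~cavity
    rv = _disk(h, w, rv_center, params.rv_radius) & ~outer

    mask = np.zeros((h, w), dtype=np.int64)
    mask[cavity] = LV_CAVITY
    mask[annulus] = LV_MYOCARDIUM
    mask[rv] = RV_CAVITY

    clean = np.full((h, w), params.intensity_background, dtype=float)
    clean[cavity] = params.intensity_cavity
    clean[annulus] = params.intensity_myocardium
    clean[rv] = params.intensity_rv

    for f in range(params.frames):
        noise = rng.normal(0.0, params.noise_sd, size=(h, w)) if params.noise_sd > 0 else 0.0
        frames_px[f] = np.clip(clean + noise, 0.0, 1.0)
        frames_mask[f] = mask

    return SegmentedInstance(id=f"phantom_{params.seed}", pixels=frames_px, mask=frames_mask)


def generate_cohort(
    spec: CohortSpec,
) -> Tuple[List[SegmentedInstance], "pd.DataFrame", Dict[str, int]]:
    """Generate a two-class cohort with demographics and true labels.

    Returns ``(instances, demographics, true_labels)`` where labels are 1 for
    the thick-walled class. Ids are disjoint and reproducible per seed.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    instances: List[SegmentedInstance] = []
    rows = []
    labels: Dict[str, int] = {}
    for label, mean in ((0, spec.thickness_mean_thin), (1, spec.thickness_mean_thick)):
        for i in range(spec.n_per_class):
            t = rng.normal(mean, spec.thickness_sd)
            while t <= 0.5:  # truncate away degenerate walls
                t = rng.normal(mean, spec.thickness_sd)
            params = PhantomParams(
                frames=spec.frames,
                myocardium_thickness=float(t),
                noise_sd=spec.noise_sd,
                center_jitter=spec.center_jitter,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            inst = generate_phantom(params)
            pid = f"{'thick' if label else 'thin'}_{i:03d}"
            age = float(np.clip(rng.normal(62 if label else 55, 8), 30, 90))
            bmi = float(np.clip(rng.normal(29 if label else 25, 4), 15, 50))
            sex = str(rng.choice(["F", "M"]))
            demo = {"age": round(age, 1), "sex": sex, "bmi": round(bmi, 1)}
            inst = SegmentedInstance(id=pid, pixels=inst.pixels, mask=inst.mask, demographics=demo)
            instances.append(inst)
            labels[pid] = label
            rows.append({"id": pid, **demo, "wall_thickness": round(float(t), 2)})
    return instances, pd.DataFrame(rows), labels


@dataclass(frozen=True)
class ReferenceClassifier:
    """Deterministic wall-thickness classifier reading only pixel intensities.

    Counts pixels with intensity >= ``band_threshold`` (the myocardium band)
    inside a square window of half-width ``window_halfwidth`` around
    ``lv_center``, averaged over frames, and predicts 1 when the count
    exceeds ``count_threshold``.  The default threshold is the annulus area
    at the midpoint thickness between the two cohort classes,
    π((r + t_mid)² − r²), computed analytically — nothing is fit to data.
    """

    lv_center: Tuple[float, float] = (64.0, 64.0)
    window_halfwidth: int = 30
    band_threshold: float = 0.7
    lv_cavity_radius: float = 20.0
    midpoint_thickness: float = 5.0

    @property
    def count_threshold(self) -> float:
        r, t = self.lv_cavity_radius, self.midpoint_thickness
        return float(np.pi * ((r + t) ** 2 - r**2))

    def band_count(self, pixels: np.ndarray) -> float:
        """Mean per-frame myocardium-band pixel count inside the window."""
        pixels = np.asarray(pixels, dtype=float)
        if pixels.ndim == 2:
            pixels = pixels[np.newaxis]
        r0, c0 = int(round(self.lv_center[0])), int(round(self.lv_center[1]))
        hw = self.window_halfwidth
        win = pixels[
            :,
            max(r0 - hw, 0) : r0 + hw + 1,
            max(c0 - hw, 0) : c0 + hw + 1,
        ]
        return float((win >= self.band_threshold).sum() / win.shape[0])

    def predict_score(self, batch: np.ndarray) -> np.ndarray:
        """Monotone score in [0, 1], crossing 0.5 exactly at the threshold."""
        batch = np.asarray(batch, dtype=float)
        if batch.ndim == 3:
            batch = batch[np.newaxis]
        counts = np.array([self.band_count(item) for item in batch])
        return 1.0 / (1.0 + np.exp(-(counts - self.count_threshold) / 50.0))

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return (self.predict_score(batch) >= 0.5).astype(int)


def reference_classifier(batch: np.ndarray, **kwargs) -> np.ndarray:
    """Functional form of :class:`ReferenceClassifier` with default geometry."""
    return ReferenceClassifier(**kwargs).predict(batch)


def threshold_segmenter(
    pixels: np.ndarray,
    band_edges: Tuple[float, float] = (0.3, 0.7),
    min_size: int = 8,
) -> np.ndarray:
    """Intensity-band segmentation into codes {0, 1, 2, 3}.

    Pixels below ``band_edges[0]`` are background, between the edges blood
    pool, above them myocardium.  Small connected components are removed,
    then blood-pool components are assigned: the one nearest the myocardium
    ring's centroid becomes the LV cavity (it sits inside the ring), every
    other becomes RV.  A flat image yields all background.
    """
    pixels = np.asarray(pixels, dtype=float)
    squeeze = pixels.ndim == 2
    if squeeze:
        pixels = pixels[np.newaxis]
    out = np.zeros(pixels.shape, dtype=np.int64)
    lo, hi = band_edges
    for f in range(pixels.shape[0]):
        frame = pixels[f]
        cavity_band = (frame >= lo) & (frame < hi)
        myo_band = frame >= hi
        for band in (cavity_band, myo_band):
            lab, n = ndimage.label(band)
            if n:
                sizes = np.bincount(lab.ravel())
                small = np.isin(lab, np.nonzero(sizes < min_size)[0])
                band &= ~small
        mask = np.zeros(frame.shape, dtype=np.int64)
        mask[myo_band] = LV_MYOCARDIUM
        lab, n = ndimage.label(cavity_band)
        if n:
            if myo_band.any():
                myo_centroid = np.array(ndimage.center_of_mass(myo_band))
                centroids = ndimage.center_of_mass(cavity_band, lab, range(1, n + 1))
                d = [np.hypot(*(np.array(c) - myo_centroid)) for c in centroids]
                lv_label = int(np.argmin(d)) + 1
            else:
                lv_label = 0  # no ring found: call every pool RV
            for k in range(1, n + 1):
                mask[lab == k] = LV_CAVITY if k == lv_label else RV_CAVITY
        out[f] = mask
    return out[0] if squeeze else out
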