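"""Nucleus and nucleolus segmentation and per-region measurement.

Nuclei are found on a nuclear-filling channel (DNA counterstain or a
protein like NPM1 that fills the nucleoplasm) by Gaussian smoothing,
Otsu thresholding, hole filling and a watershed split of touching
objects; border-touching and under-sized nuclei are discarded.  Nucleoli
are then found by per-nucleus Otsu thresholding of the condensate
channel, so that the threshold adapts to each nucleus's own dilute-phase
level.

Measurements follow the partition-coefficient convention: the dense-phase
intensity of a nucleolus is the MEAN inside its mask, while the
dilute-phase intensity of a nucleus is the MEDIAN over the nucleoplasm
(nucleus minus all nucleoli) after eroding a safety margin from both the
nucleus boundary and every nucleolus boundary, to keep partial-volume
pixels out of the dilute estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage import morphology, segmentation as skseg
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu

from nucleoquant.io import ImageStack


@dataclass
class RegionLabelMap:
    """A labelled segmentation at one level of the hierarchy.

    ``labels`` is an integer image (0 = background); ``level`` is
    ``"nucleus"`` or ``"nucleolus"``; for nucleoli, ``parent`` maps each
    nucleolus label to the label of the nucleus containing it.
    """

    labels: np.ndarray
    level: str
    parent: dict = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.level not in ("nucleus", "nucleolus"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.parent is None:
            self.parent = {}

    @property
    def ids(self):
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def is_empty(self) -> bool:
        return not (self.labels > 0).any()


@dataclass
class NucleolusRecord:
    """Per-nucleolus dense-phase measurement."""

    nucleolus_id: int
    nucleus_id: int
    I_dense: float  # mean intensity inside the nucleolus, AU
    area: float  # um^2
    eccentricity: float
    centroid: tuple  # (row, col), pixels


@dataclass
class NucleusRecord:
    """Per-nucleus dilute-phase measurement."""

    nucleus_id: int
    I_dilute: float  # median nucleoplasm intensity, AU; NaN if unmeasurable
    area: float  # um^2


def segment_nuclei(
    stack: ImageStack,
    channel,
    min_area: float = 50.0,
    sigma: float = 2.0,
    frame: int = 0,
) -> RegionLabelMap:
    """Segment nuclei on a nuclear-filling channel.

    Gaussian smoothing + Otsu threshold + hole filling, then a
    distance-transform watershed to split touching nuclei.  Regions
    smaller than ``min_area`` (um^2) and regions touching the image
    border are removed.  A blank or near-constant image yields an empty
    map with a warning rather than an error.
    """
    plane = stack.plane(frame, channel).astype(float)
    min_px = int(np.ceil(min_area / stack.pixel_size**2))
    smoothed = gaussian(plane, sigma=sigma, preserve_range=True)
    if np.ptp(smoothed) < 1e-12:
        warnings.warn("blank image: no nuclei found", stacklevel=2)
        return RegionLabelMap(np.zeros(plane.shape, np.int32), "nucleus")
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr
    if not mask.any() or mask.all():
        warnings.warn("no region above threshold: empty nucleus map", stacklevel=2)
        return RegionLabelMap(np.zeros(plane.shape, np.int32), "nucleus")
    mask = ndi.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    labels = _watershed_split(mask, min_px)
    labels = skseg.clear_border(labels)
    labels = morphology.remove_small_objects(labels, max_size=min_px - 1)
    labels, _, _ = skseg.relabel_sequential(labels)
    if labels.max() == 0:
        warnings.warn("no nucleus surviving size/border filters", stacklevel=2)
    return RegionLabelMap(labels.astype(np.int32), "nucleus")


def _watershed_split(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Split touching convex objects with a distance-transform watershed."""
    if not mask.any():
        return np.zeros(mask.shape, np.int32)
    distance = ndi.distance_transform_edt(mask)
    # peaks at least a typical nuclear radius apart
    min_dist = max(5, int(np.sqrt(min_px / np.pi)))
    coords = peak_local_max(distance, min_distance=min_dist, labels=mask)
    markers = np.zeros(mask.shape, np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return skmeasure.label(mask).astype(np.int32)
    return skseg.watershed(-distance, markers, mask=mask).astype(np.int32)


def segment_nucleoli(
    stack: ImageStack,
    channel,
    nuclei: RegionLabelMap,
    min_area: float = 0.2,
    min_contrast: float = 0.2,
    border_erosion_px: int = 3,
    frame: int = 0,
) -> RegionLabelMap:
    """Segment nucleoli inside each nucleus on the condensate channel.

    Each nucleus is thresholded independently (Otsu over its own pixels)
    so the split adapts to that nucleus's dilute level; the nucleus mask
    is first eroded by ``border_erosion_px`` so that dim background
    pixels swept in at the nucleus boundary cannot masquerade as the
    dilute phase.  A nucleus whose putative dense phase exceeds its
    dilute phase by less than ``min_contrast`` (relative) contributes
    nothing — there is no detectable condensed phase (the
    partition-coefficient-1 limit).  Each nucleolus is assigned to the
    nucleus containing its centroid.
    """
    plane = stack.plane(frame, channel).astype(float)
    min_px = max(1, int(np.ceil(min_area / stack.pixel_size**2)))
    out = np.zeros(plane.shape, np.int32)
    parent: dict[int, int] = {}
    next_id = 1
    footprint = morphology.disk(border_erosion_px) if border_erosion_px else None
    for nuc_id in nuclei.ids:
        region = nuclei.labels == nuc_id
        if footprint is not None:
            region = morphology.erosion(region, footprint)
        vals = plane[region]
        if vals.size < 4 or np.ptp(vals) < 1e-12:
            continue
        thr = threshold_otsu(vals)
        fg = vals > thr
        if not fg.any() or fg.all():
            continue
        dense, dilute = vals[fg].mean(), np.median(vals[~fg])
        if dilute <= 0 or (dense - dilute) / dilute < min_contrast:
            continue  # no detectable condensed phase in this nucleus
        mask = region & (plane > thr)
        mask = ndi.binary_fill_holes(mask)
        mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
        for obj in skmeasure.regionprops(skmeasure.label(mask)):
            rr, cc = obj.coords[:, 0], obj.coords[:, 1]
            # assignment by centroid: robust if a blob grazes a neighbour
            crow, ccol = (int(round(x)) for x in obj.centroid)
            owner = nuclei.labels[crow, ccol]
            if owner == 0:
                owner = nuc_id
            out[rr, cc] = next_id
            parent[next_id] = int(owner)
            next_id += 1
    return RegionLabelMap(out, "nucleolus", parent=parent)


def measure_regions(
    stack: ImageStack,
    channel,
    nuclei: RegionLabelMap,
    nucleoli: RegionLabelMap,
    erosion_px: int = 2,
    background: float = 0.0,
    frame: int = 0,
) -> tuple[list[NucleolusRecord], list[NucleusRecord]]:
    """Measure dense- and dilute-phase intensities, area and shape.

    Per nucleolus: mean intensity (I_dense), area in um^2, eccentricity of
    the moment-equivalent ellipse, centroid.  Per nucleus: median
    nucleoplasm intensity (I_dilute) measured over the nucleus eroded by
    ``erosion_px`` with every nucleolus dilated by the same margin, and
    nucleus area.  ``background`` (default 0) is subtracted from both
    intensities.  A nucleus left with no nucleoplasm pixels is flagged
    with ``I_dilute = NaN``.
    """
    plane = stack.plane(frame, channel).astype(float)
    if nuclei.labels.shape != plane.shape or nucleoli.labels.shape != plane.shape:
        raise ValueError("label maps must match the image plane shape")
    px_area = stack.pixel_size**2

    footprint = morphology.disk(erosion_px)
    nucleolus_any = nucleoli.labels > 0
    dilated_nucleoli = morphology.dilation(nucleolus_any, footprint) if erosion_px else nucleolus_any

    nucleolus_records = []
    for obj in skmeasure.regionprops(nucleoli.labels, intensity_image=plane):
        nucleolus_records.append(
            NucleolusRecord(
                nucleolus_id=int(obj.label),
                nucleus_id=int(nucleoli.parent.get(obj.label, 0)),
                I_dense=float(obj.intensity_mean) - background,
                area=float(obj.area) * px_area,
                eccentricity=float(obj.eccentricity) if obj.area > 1 else 0.0,
                centroid=tuple(obj.centroid),
            )
        )

    nucleus_records = []
    for nuc_id in nuclei.ids:
        region = nuclei.labels == nuc_id
        eroded = morphology.erosion(region, footprint) if erosion_px else region
        nucleoplasm = eroded & ~dilated_nucleoli
        if nucleoplasm.any():
            i_dilute = float(np.median(plane[nucleoplasm])) - background
        else:
            warnings.warn(f"nucleus {nuc_id}: no nucleoplasm after erosion", stacklevel=2)
            i_dilute = float("nan")
        nucleus_records.append(
            NucleusRecord(
                nucleus_id=int(nuc_id),
                I_dilute=i_dilute,
                area=float(region.sum()) * px_area,
            )
        )
    return nucleolus_records, nucleus_records


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap of two boolean masks (1.0 = identical)."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
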