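"""Fluorescence trace extraction from time-lapse image stacks.

Mirrors the standard colony-imaging analysis: threshold a reference frame to
select all fluorescent objects, average the pixel intensity of each object
per frame (background-subtracted), form the population mean trace, and
normalize it to the point of complete on-switching.  Per-object maxima give
the average-brightness metric used for cross-construct comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .experiment import SwitchingExperiment, SwitchingProtocol

__all__ = ["ObjectMap", "segment_objects", "extract_traces", "object_brightness"]


@dataclass
class ObjectMap:
    """Labeled object image: integer labels contiguous from 1, 0 = background."""

    labels: np.ndarray
    areas: np.ndarray
    centroids: np.ndarray  # (n, 2) row, col

    @property
    def n_objects(self) -> int:
        return len(self.areas)


def segment_objects(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    min_area: int = 5,
) -> ObjectMap:
    """Threshold a grayscale image and label connected components.

    ``method="otsu"`` picks the global Otsu threshold; ``method="fixed"``
    uses the supplied ``threshold``.  8-connected components smaller than
    ``min_area`` pixels are discarded and labels relabeled contiguously.  An
    image with no above-threshold pixels yields an empty map with a warning,
    not an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segmentation expects a single 2-D grayscale image")
    if method == "otsu":
        if image.min() == image.max():
            mask = np.zeros(image.shape, dtype=bool)
        else:
            mask = image > threshold_otsu(image)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed-threshold segmentation requires a threshold value")
        mask = image > threshold
    else:
        raise ValueError("method must be 'otsu' or 'fixed'")

    labels = sk_label(mask, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_area]
    out = np.zeros_like(labels)
    areas, centroids = [], []
    for new_label, p in enumerate(props, start=1):
        out[labels == p.label] = new_label
        areas.append(p.area)
        centroids.append(p.centroid)
    if not areas:
        warnings.warn("no objects above threshold: returning an empty object map")
        return ObjectMap(labels=out, areas=np.array([], dtype=int), centroids=np.empty((0, 2)))
    return ObjectMap(labels=out, areas=np.asarray(areas, dtype=int), centroids=np.asarray(centroids))


def extract_traces(
    stack: np.ndarray,
    objects: ObjectMap,
    protocol: SwitchingProtocol,
    subtract_background: bool = True,
) -> SwitchingExperiment:
    """Per-object mean-intensity traces from an image stack.

    Each object's trace is the mean pixel intensity inside its label per
    frame, minus the per-frame median of unlabeled (background) pixels when
    ``subtract_background``.  The stack's frame count must match the
    protocol.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, height, width)")
    if stack.shape[0] != protocol.n_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames but the protocol defines {protocol.n_frames}"
        )
    if stack.shape[1:] != objects.labels.shape:
        raise ValueError("stack frame geometry does not match the object map")
    if objects.n_objects == 0:
        raise ValueError("object map is empty: nothing to extract")

    labels = objects.labels
    ids = np.arange(1, objects.n_objects + 1)
    bg_mask = labels == 0
    traces = np.empty((objects.n_objects, stack.shape[0]))
    for f in range(stack.shape[0]):
        frame = stack[f]
        means = ndimage.mean(frame, labels=labels, index=ids)
        if subtract_background and bg_mask.any():
            means = means - np.median(frame[bg_mask])
        traces[:, f] = means
    return SwitchingExperiment(
        protocol=protocol,
        traces=traces,
        object_ids=[int(i) for i in ids],
        metadata={"n_objects": int(objects.n_objects), "background_subtracted": bool(subtract_background)},
    )


def object_brightness(experiment: SwitchingExperiment) -> tuple[float, np.ndarray]:
    """Average of per-object maximum brightness.

    Maxima are taken over the raw (non-normalized) traces, since this metric
    feeds cross-construct brightness comparison.  Returns ``(mean, per-object
    maxima)``.
    """
    if experiment.n_objects < 1:
        raise ValueError("experiment contains no objects")
    maxima = experiment.traces.max(axis=1)
    return float(maxima.mean()), maxima
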