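"""Channel combination: neuron identification, soma detection and subtraction.

A nucleus overlapping the neurite-channel mask marks a neuron (for
dopaminergic cultures this is the automated analogue of a TH+ cell).
Neurite-channel components containing no neuron nucleus are staining
artifacts or debris and are removed.  Somata are the thick cores of the
neurite-channel mask (distance-transform threshold, recovered by geodesic
dilation); skeleton branches overlapping the soma are discarded so that
measured neurite length reflects projections only, and soma subtraction
likewise yields the neurite-only area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .calibration import Calibration, area_um2
from .nuclei import LabeledRegions
from .preprocess import BinaryMask
from .skeleton import Skeleton

DEFAULT_SOMA_RADIUS_PX = 8

_STRUCT8 = np.ones((3, 3), dtype=int)


@dataclass
class NeuronAssignment:
    """Nuclei identified as neurons by overlap with the neurite mask."""

    neuron_nucleus_labels: np.ndarray
    soma_mask: BinaryMask
    neuron_count: int


def identify_neurons(nuclei_regions: LabeledRegions, neurite_mask: BinaryMask) -> NeuronAssignment:
    """A nucleus is a neuron iff at least one of its pixels overlaps the
    neurite-channel foreground."""
    labels = nuclei_regions.label_raster
    overlap = np.unique(labels[(labels > 0) & neurite_mask.raster])
    empty_soma = BinaryMask(
        np.zeros(neurite_mask.raster.shape, dtype=bool),
        neurite_mask.calibration,
        neurite_mask.scale_factor,
    )
    return NeuronAssignment(
        neuron_nucleus_labels=overlap.astype(int),
        soma_mask=empty_soma,
        neuron_count=int(len(overlap)),
    )


def detect_somata(
    neurite_mask: BinaryMask,
    nuclei_regions: LabeledRegions,
    soma_radius_px: int = DEFAULT_SOMA_RADIUS_PX,
) -> BinaryMask:
    """Soma mask from a distance-transform threshold on the neurite mask.

    Pixels at Euclidean distance >= ``soma_radius_px`` from the background
    seed the somata; geodesic dilation by the same radius within the neurite
    mask recovers the full cell body (equivalently, a morphological opening),
    so structures thinner than twice the radius - the neurites - contribute
    nothing.  Only soma components overlapping at least one nucleus are kept.
    """
    raster = neurite_mask.raster
    dist = ndimage.distance_transform_edt(raster)
    core = dist >= soma_radius_px
    if not core.any():
        return BinaryMask(np.zeros_like(raster), neurite_mask.calibration, neurite_mask.scale_factor)
    from skimage.morphology import disk

    soma = ndimage.binary_dilation(core, structure=disk(soma_radius_px)) & raster

    # keep only soma bodies that contain a nucleus
    soma_labels, n = ndimage.label(soma, structure=_STRUCT8)
    if n:
        nucleus_fg = nuclei_regions.label_raster > 0
        keep_ids = np.unique(soma_labels[(soma_labels > 0) & nucleus_fg])
        keep_lut = np.zeros(n + 1, dtype=bool)
        keep_lut[keep_ids] = True
        soma = keep_lut[soma_labels]
    return BinaryMask(soma, neurite_mask.calibration, neurite_mask.scale_factor)


def remove_orphan_components(
    neurite_mask: BinaryMask,
    assignment: NeuronAssignment,
    nuclei_regions: LabeledRegions,
) -> BinaryMask:
    """Remove neurite-channel components containing no neuron nucleus pixel.

    This is the false-positive / staining-artifact feedback step: anything
    not attached to an identified neuron is discarded.
    """
    labels, n = ndimage.label(neurite_mask.raster, structure=_STRUCT8)
    if n == 0:
        return neurite_mask.copy()
    neuron_lut = np.isin(nuclei_regions.label_raster, assignment.neuron_nucleus_labels)
    keep_ids = np.unique(labels[(labels > 0) & neuron_lut])
    keep_lut = np.zeros(n + 1, dtype=bool)
    keep_lut[keep_ids] = True
    return BinaryMask(keep_lut[labels], neurite_mask.calibration, neurite_mask.scale_factor)


def prune_soma_overlap(skeleton: Skeleton, soma_mask: BinaryMask) -> Skeleton:
    """Delete skeleton vertices lying inside the soma mask.

    The soma mask (source scale) is upsampled to the skeleton's scale;
    branches crossing a soma are clipped at its boundary and branches fully
    inside are removed.  Idempotent, and never increases total length.
    """
    if skeleton.is_empty:
        return skeleton
    factor = skeleton.scale_factor // soma_mask.scale_factor
    if factor < 1:
        raise ValueError("soma mask is at a finer scale than the skeleton")
    soma = soma_mask.raster
    if factor > 1:
        soma = np.repeat(np.repeat(soma, factor, axis=0), factor, axis=1)
    rc = np.round(skeleton.coords).astype(int)
    rc[:, 0] = np.clip(rc[:, 0], 0, soma.shape[0] - 1)
    rc[:, 1] = np.clip(rc[:, 1], 0, soma.shape[1] - 1)
    inside = soma[rc[:, 0], rc[:, 1]]
    if not inside.any():
        return skeleton
    return skeleton.remove_points(inside)


def neurite_area_um2(
    neurite_mask: BinaryMask,
    soma_mask: BinaryMask,
    calibration: Calibration | None = None,
) -> float:
    """Area of the neurite mask with the soma mask subtracted, in um^2."""
    if neurite_mask.raster.shape != soma_mask.raster.shape:
        raise ValueError(
            f"mask shape mismatch: {neurite_mask.raster.shape} vs {soma_mask.raster.shape}"
        )
    cal = calibration or neurite_mask.calibration
    pixels = int(np.sum(neurite_mask.raster & ~soma_mask.raster))
    return area_um2(pixels, cal, neurite_mask.scale_factor)
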