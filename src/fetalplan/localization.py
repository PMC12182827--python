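"""Fetal body localization: pluggable segmentation backends + thorax box.

The deep-learning body/landmark segmentation networks used clinically are
deliberately behind a seam here: a :class:`SegmentationBackend` is any
callable taking an :class:`ImageVolume` and returning a :class:`LabelMap`
on the same grid.  Three implementations are provided:

* :class:`OracleBackend` — returns stored ground-truth labels (e.g. from the
  phantom), resampled by nearest neighbour onto whatever grid it is called
  with, optionally dilated/eroded/translation-jittered to emulate network
  error;
* :class:`ThresholdBackend` — intensity threshold (Otsu by default) plus
  largest connected component; a crude classical fallback;
* :class:`ExternalCommandBackend` — shells out to a user-supplied executable
  (e.g. a trained network's inference script).  The command receives two
  arguments: the path of the input NIfTI and the path where it must write
  the output label NIfTI.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path
from typing import Mapping, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, LocalizationError
from .imaging_core import (
    BODY_CODES,
    BoundingBox,
    ImageVolume,
    LabelMap,
    load_labels,
    patient_to_voxel,
    require_same_grid,
    save_volume,
    voxel_to_patient,
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@runtime_checkable
class SegmentationBackend(Protocol):
    """Anything that maps a volume to a label map on the same grid."""

    def __call__(self, volume: ImageVolume) -> LabelMap: ...


class OracleBackend:
    """Backend that answers from a stored ground-truth label map.

    The stored map may live on a different grid (e.g. the full phantom grid
    while the pipeline queries a thorax crop): each queried voxel center is
    mapped through the stored map's affine and sampled nearest-neighbour.

    Parameters
    ----------
    labels : LabelMap
        Ground-truth labels in the patient frame.
    dilate_vox, erode_vox : int
        Binary dilation/erosion iterations applied per label (26-connected),
        emulating over/under-segmentation.
    jitter_mm : float
        Magnitude of a random rigid translation applied to the answer,
        emulating localization error.  Direction drawn once at construction.
    seed : int
        Seed for the jitter direction.
    """

    def __init__(
        self,
        labels: LabelMap,
        *,
        dilate_vox: int = 0,
        erode_vox: int = 0,
        jitter_mm: float = 0.0,
        seed: int = 0,
    ):
        self.labels = labels
        self.dilate_vox = int(dilate_vox)
        self.erode_vox = int(erode_vox)
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        self.jitter = jitter_mm * direction

    def __call__(self, volume: ImageVolume) -> LabelMap:
        idx = np.ascontiguousarray(
            np.indices(volume.shape, dtype=np.float32).reshape(3, -1).T
        )
        pts = voxel_to_patient(idx, volume) - self.jitter
        src = np.rint(patient_to_voxel(pts, self.labels)).astype(np.int64)
        inside = np.all((src >= 0) & (src < np.asarray(self.labels.shape)), axis=1)
        out = np.zeros(len(src), dtype=np.uint16)
        s = src[inside]
        out[inside] = self.labels.labels[s[:, 0], s[:, 1], s[:, 2]]
        arr = out.reshape(volume.shape)
        if self.dilate_vox or self.erode_vox:
            arr = self._morph(arr)
        return LabelMap(arr, volume.affine, self.labels.label_codes)

    def _morph(self, arr: np.ndarray) -> np.ndarray:
        out = np.zeros_like(arr)
        for code in sorted(set(int(v) for v in self.labels.label_codes.values())):
            m = arr == code
            if not m.any():
                continue
            if self.erode_vox:
                m = ndimage.binary_erosion(m, _CONN26, iterations=self.erode_vox)
            if self.dilate_vox:
                m = ndimage.binary_dilation(m, _CONN26, iterations=self.dilate_vox)
            out[m & (out == 0)] = code
        return out


class ThresholdBackend:
    """Foreground = intensity above a threshold (Otsu when not given)."""

    def __init__(self, threshold: float | None = None,
                 label_codes: Mapping[str, int] = BODY_CODES):
        self.threshold = threshold
        self.label_codes = dict(label_codes)

    def __call__(self, volume: ImageVolume) -> LabelMap:
        thr = self.threshold
        if thr is None:
            from skimage.filters import threshold_otsu

            thr = float(threshold_otsu(volume.data))
        mask = volume.data > thr
        code = next(iter(self.label_codes.values()))
        return LabelMap(mask.astype(np.uint16) * code, volume.affine,
                        self.label_codes)


class ExternalCommandBackend:
    """Run a user-supplied executable: ``cmd <input.nii.gz> <output.nii.gz>``.

    The executable must write a NIfTI label map on the input grid to the
    output path.  ``label_codes`` names its integer labels.
    """

    def __init__(self, command: list[str], label_codes: Mapping[str, int]):
        self.command = list(command)
        self.label_codes = dict(label_codes)

    def __call__(self, volume: ImageVolume) -> LabelMap:
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "input.nii.gz"
            out = Path(tmp) / "output.nii.gz"
            save_volume(volume, inp)
            subprocess.run([*self.command, str(inp), str(out)], check=True)
            labels = load_labels(out, self.label_codes)
        require_same_grid(labels, volume)
        return labels


# ---------------------------------------------------------------------------


def extract_body_mask(volume: ImageVolume, backend: SegmentationBackend) -> LabelMap:
    """Binary fetal body mask: backend output, largest 26-connected
    component, internal holes filled.

    Raises :class:`LocalizationError` when the backend returns an empty
    segmentation (the prospective-failure mode of the pipeline).
    """
    raw = backend(volume)
    require_same_grid(raw, volume)
    fg = raw.labels > 0
    if not fg.any():
        raise LocalizationError("backend produced an empty body segmentation")
    comp, n = ndimage.label(fg, structure=_CONN26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
        fg = comp == (int(np.argmax(sizes)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    return LabelMap(fg.astype(np.uint16), volume.affine, BODY_CODES)


def thorax_bounding_box(
    body: LabelMap,
    margin_mm: float = 10.0,
    thorax_fraction: tuple[float, float] = (0.25, 0.75),
) -> BoundingBox:
    """Voxel-axis-aligned box focusing on the thorax.

    The body mask's voxel patient-coordinates are projected on the mask's
    first principal axis (the fetal longitudinal axis); voxels whose
    projection falls in the fractional band ``thorax_fraction`` of the
    projection extent are kept; their tight voxel box is expanded by
    ``margin_mm`` (converted per axis) and clipped to the grid.
    """
    lo_f, hi_f = thorax_fraction
    if not (0.0 <= lo_f < hi_f <= 1.0):
        raise InvalidInputError(f"bad thorax fraction {thorax_fraction}")
    vox = np.argwhere(body.labels > 0)
    if vox.size == 0:
        raise LocalizationError("empty body mask")
    pts = voxel_to_patient(vox.astype(float), body)
    centered = pts - pts.mean(axis=0)
    # principal axis of the mask point cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    pmin, pmax = proj.min(), proj.max()
    extent = pmax - pmin
    band = (proj >= pmin + lo_f * extent) & (proj <= pmin + hi_f * extent)
    sel = vox[band]
    lower = sel.min(axis=0)
    upper = sel.max(axis=0) + 1
    grow = np.ceil(margin_mm / body.spacing - 1e-9).astype(int)
    lower = np.maximum(lower - grow, 0)
    upper = np.minimum(upper + grow, np.asarray(body.shape))
    return BoundingBox(tuple(lower), tuple(upper))
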