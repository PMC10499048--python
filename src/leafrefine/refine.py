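"""Local refinement: apply a filter only inside annotated instance regions.

The refinement mechanism takes each annotated leaf instance, filters a
padded crop around its mask, and composites the filtered values back *only
at mask pixels*.  Every pixel outside the mask is bit-identical to the
input — refinement is strictly local.  The mechanism can be deployed in
three dataset-construction scenarios:

* ``TRAIN_REPLACE`` — every training image is replaced by its refined
  version (annotations unchanged; filtering never moves geometry).
* ``TRAIN_COMBINE`` — the refined copies are *added* to the originals,
  exactly doubling image and annotation counts, acting as a form of
  data augmentation with partially corrupted instances.
* ``TEST_REFINE`` — the refinement is applied to test images as a
  preprocessing/postprocessing probe of model robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .dataset_io import DatasetBundle, InstanceAnnotation, rasterize
from .filters import FilterSpec, FilterType, apply_filter_spec

__all__ = ["Scenario", "ScenarioSpec", "refine_instance", "refine_image", "build_scenario"]


class Scenario(str, Enum):
    TRAIN_REPLACE = "train-replace"
    TRAIN_COMBINE = "train-combine"
    TEST_REFINE = "test"


# scenarios allowed per split
_ALLOWED = {
    Scenario.TRAIN_REPLACE: {"train"},
    Scenario.TRAIN_COMBINE: {"train"},
    Scenario.TEST_REFINE: {"test", "val"},
}


@dataclass(frozen=True)
class ScenarioSpec:
    scenario: Scenario
    filter: FilterSpec
    target_split: str = "train"

    def __post_init__(self) -> None:
        if self.target_split not in _ALLOWED[self.scenario]:
            raise ValueError(
                f"scenario {self.scenario.value} not valid on split "
                f"{self.target_split!r} (allowed: {sorted(_ALLOWED[self.scenario])})"
            )


def _single_pass_spec(spec: FilterSpec) -> list[FilterSpec]:
    """Decompose a stacked filter into its sequential stages."""
    if spec.filter_type is FilterType.GLPF_THEN_HBF:
        return [
            FilterSpec(FilterType.GLPF, spec.kernel_size, spec.sigma),
            FilterSpec(
                FilterType.HBF, spec.second_kernel_size, spec.sigma, spec.amplification
            ),
        ]
    return [spec]


def refine_instance(img: np.ndarray, mask: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Filter one instance region; all other pixels are bit-identical.

    The mask's bounding box is padded by the kernel radius (clamped to the
    image bounds), the filter runs on the padded crop, and filtered values
    are composited back at mask pixels only.  A stacked GLPF→HBF spec runs
    as two consecutive local passes on the same region, so the HBF stage
    sees the already-blurred composite.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    out = img.astype(np.uint8, copy=True)
    if not mask.any() or spec.filter_type is FilterType.IDENTITY:
        return out
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    for stage in _single_pass_spec(spec):
        pad = stage.pad_radius
        y0 = max(int(rows[0]) - pad, 0)
        y1 = min(int(rows[-1]) + 1 + pad, mask.shape[0])
        x0 = max(int(cols[0]) - pad, 0)
        x1 = min(int(cols[-1]) + 1 + pad, mask.shape[1])
        crop = out[y0:y1, x0:x1]
        filtered = apply_filter_spec(crop, stage)
        sub = mask[y0:y1, x0:x1]
        crop[sub] = filtered[sub]
    return out


def refine_image(
    img: np.ndarray, annotations: list[InstanceAnnotation], spec: FilterSpec
) -> np.ndarray:
    """Refine every annotated instance, in ascending annotation-id order.

    Later instances see earlier results, so overlapping pixels are
    filtered more than once; disjoint instances commute.
    """
    out = np.asarray(img).astype(np.uint8, copy=True)
    h, w = out.shape[:2]
    for ann in sorted(annotations, key=lambda a: a.id):
        out = refine_instance(out, rasterize(ann, h, w), spec)
    return out


def build_scenario(bundle: DatasetBundle, spec: ScenarioSpec) -> DatasetBundle:
    """Construct the refined dataset for one deployment scenario.

    ``TRAIN_REPLACE`` / ``TEST_REFINE`` replace every image with its
    refined version (annotations untouched).  ``TRAIN_COMBINE`` keeps all
    originals and appends the refined copies under fresh unique ids, so
    image and annotation counts exactly double.
    """
    bundle.validate()
    out = bundle.copy()
    refined: dict[int, np.ndarray] = {}
    for rec in bundle.images:
        if rec.id not in bundle.pixels:
            raise ValueError(f"image {rec.id} has no pixel data loaded")
        refined[rec.id] = refine_image(
            bundle.pixels[rec.id], bundle.annotations_for(rec.id), spec.filter
        )
    if spec.scenario in (Scenario.TRAIN_REPLACE, Scenario.TEST_REFINE):
        out.pixels.update(refined)
        return out
    # TRAIN_COMBINE: append refined copies with fresh ids
    next_img = max((r.id for r in bundle.images), default=0) + 1
    next_ann = max((a.id for a in bundle.annotations), default=0) + 1
    id_map: dict[int, int] = {}
    for rec in bundle.images:
        new_id = next_img
        next_img += 1
        id_map[rec.id] = new_id
        stem, dot, ext = rec.file_name.rpartition(".")
        new_name = f"{stem}_refined.{ext}" if dot else f"{rec.file_name}_refined"
        out.images.append(
            replace(rec, id=new_id, file_name=new_name)
        )
        out.pixels[new_id] = refined[rec.id]
    for ann in bundle.annotations:
        out.annotations.append(
            replace(ann, id=next_ann, image_id=id_map[ann.image_id])
        )
        next_ann += 1
    out.validate()
    return out
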