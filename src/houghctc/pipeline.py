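"""End-to-end counting of one field: segmentation -> routing -> Hough -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .components import Component, Fate, build_stage_masks, measure_and_route
from .config import PipelineConfig
from .field import MultichannelField, to_grayscale
from .hough import (
    CellEvent,
    CircleDetection,
    ClusterEvent,
    assign_circles,
    classify_events,
    find_circles,
    intensity_weight,
    radius_range_from_physical,
)
from .reporting import SampleResult, summarize_sample
from .segmentation import (
    ExclusionRegion,
    ThresholdReport,
    combine_masks,
    remove_artifacts,
    threshold_field_channel,
)

log = logging.getLogger(__name__)


@dataclass
class FieldCount:
    """Everything the pipeline produced for one field."""

    sample_result: SampleResult
    cell_events: list[CellEvent]
    cluster_events: list[ClusterEvent]
    rejected_components: list[Component]
    components: list[Component]
    masks: dict[str, np.ndarray]
    thresholds: dict[str, ThresholdReport]

    @property
    def detected_centers(self) -> list[tuple[float, float]]:
        return [e.center for e in self.cell_events]

    def events_dataframe(self, field_id: str = "") -> pd.DataFrame:
        rows = [
            dict(
                field_id=field_id,
                component_label=e.component_label,
                kind=e.kind,
                center_row=e.center[0],
                center_col=e.center[1],
                radius_px=e.radius_px,
                diameter_um=e.diameter_um,
                score=e.score,
            )
            for e in self.cell_events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "field_id", "component_label", "kind", "center_row",
                "center_col", "radius_px", "diameter_um", "score",
            ],
        )

    def clusters_dataframe(self, field_id: str = "") -> pd.DataFrame:
        rows = [
            dict(
                field_id=field_id,
                component_label=c.component_label,
                n_cells=c.n_cells,
                area_px=c.area_px,
                area_um2=c.area_um2,
            )
            for c in self.cluster_events
        ]
        return pd.DataFrame(
            rows, columns=["field_id", "component_label", "n_cells", "area_px", "area_um2"]
        )


def _component_red_veto(combined: np.ndarray, red_mask: np.ndarray) -> np.ndarray:
    """Remove whole blue*green components that touch any CD45 foreground.

    Optional stricter alternative to the default pixel-level red
    exclusion (see configuration flag ``component_red_veto``).
    """
    lab = skmeasure.label(combined > 0, connectivity=2)
    bad = np.unique(lab[(lab > 0) & (red_mask > 0)])
    out = combined.copy()
    if bad.size:
        out[np.isin(lab, bad)] = 0
    return out


def count_field(
    field: MultichannelField,
    config: PipelineConfig | None = None,
    exclusions: list[ExclusionRegion] | None = None,
    sensitivity: float | None = None,
) -> FieldCount:
    """Run the full enumeration pipeline on one field."""
    cfg = config or PipelineConfig()
    sens = cfg.sensitivity if sensitivity is None else sensitivity

    # 1. grayscale tracks and per-channel binarization (Otsu + optional override)
    masks: dict[str, np.ndarray] = {}
    reports: dict[str, ThresholdReport] = {}
    for role in ("blue", "green", "red"):
        plane = to_grayscale(field.plane(role))
        mask, report = threshold_field_channel(
            plane, manual=cfg.manual_thresholds.get(role)
        )
        masks[role] = mask
        reports[role] = report

    # 2. CK+/Hoechst+/CD45- logic
    if cfg.component_red_veto:
        bg = ((masks["blue"] > 0) & (masks["green"] > 0)).astype(np.uint8)
        combined = _component_red_veto(bg, masks["red"])
    else:
        combined = combine_masks(masks["blue"], masks["green"], masks["red"])
    combined = remove_artifacts(combined, exclusions)
    masks["combined"] = combined

    # 3. morphology and routing
    components = measure_and_route(
        combined, cfg.min_area_px, cfg.max_area_px, cfg.min_circularity
    )
    cell_mask, cluster_mask = build_stage_masks(components, field.shape)
    masks["cell"] = cell_mask
    masks["cluster"] = cluster_mask

    # 4. CK-intensity weighting and Hough counting on both stage masks
    green = to_grayscale(field.green)
    r_min, r_max = radius_range_from_physical(*cfg.cell_diameter_um, field.resolution)
    circles: list[CircleDetection] = []
    # The stage mask is softened (Gaussian window, zeroed below 5%) before
    # weighting: a hard mask would clip every cell at the Otsu iso-contour
    # and that cut itself reads as a circular edge, duplicating detections.
    # The soft window keeps the sub-threshold outer rim visible without
    # introducing any sharp boundary of its own.
    taper_fp = np.ones((7, 7), bool)
    for mask in (cell_mask, cluster_mask):
        if mask.any():
            support = ndimage.binary_dilation(mask > 0, structure=taper_fp)
            window = ndimage.gaussian_filter(support.astype(float), 1.5)
            window[window < 0.05] = 0.0
            weighted = window * to_grayscale(green).astype(float)
            circles.extend(
                find_circles(
                    weighted,
                    r_min,
                    r_max,
                    sensitivity=sens,
                    min_center_distance=cfg.min_center_distance,
                    upsample=cfg.upsample,
                )
            )
    # the two dilated supports can overlap: drop near-duplicate circles
    circles.sort(key=lambda c: (-c.score, c.center[0], c.center[1]))
    unique: list[CircleDetection] = []
    for c in circles:
        if all(
            np.hypot(c.center[0] - u.center[0], c.center[1] - u.center[1])
            > cfg.min_center_distance
            for u in unique
        ):
            unique.append(c)
    circles = unique

    # 5. attribution and classification
    routed = [c for c in components if c.fate in (Fate.CELL_MASK, Fate.CLUSTER_MASK)]
    assigned = assign_circles(circles, routed, field.shape)
    cells, clusters, rejected = classify_events(routed, assigned, field.resolution)

    result = summarize_sample(
        cells,
        clusters,
        blood_volume_ml=cfg.blood_volume_ml,
        sample_id=field.field_id,
        rejected_components=len(rejected),
    )
    log.info(
        "%s: %d free + %d clustered in %d clusters (%d rejected components)",
        field.field_id, result.free_ctcs, result.clustered_ctcs,
        result.clusters, len(rejected),
    )
    return FieldCount(
        sample_result=result,
        cell_events=cells,
        cluster_events=clusters,
        rejected_components=rejected,
        components=components,
        masks=masks,
        thresholds=reports,
    )
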