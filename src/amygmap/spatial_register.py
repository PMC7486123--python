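"""Rigid landmark registration onto section templates and subregion assignment.

Each imaged section is traced with six ordered landmark points; a rigid
(rotation + translation, no scaling, no reflection) Procrustes fit maps
those landmarks onto the template's canonical six, the same transform is
applied to every segmented cell, and coordinates are re-expressed relative
to the template's dorsal-most point. Cells are then assigned to the lateral
(LA) or basal (BA) amygdala polygon by point-in-polygon tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

N_LANDMARKS = 6


def validate_landmarks(points: np.ndarray) -> np.ndarray:
    """Validate a 6-point 2-D landmark set; returns a float array (6, 2)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise ValueError(f"landmark set must be {N_LANDMARKS} 2-D points, got shape {pts.shape}")
    centered = pts - pts.mean(axis=0)
    # collinear (or coincident) sets have rank < 2 and no unique rotation
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("landmarks are collinear or coincident; rotation is not identifiable")
    return pts


@dataclass
class RigidTransform:
    """Proper rigid map x -> R x + t (det(R) = +1, no scaling).

    ``residual_rms`` is the root-mean-square landmark mismatch of the fit
    that produced the transform (0 for hand-built transforms).
    """

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (2, 2):
            raise ValueError("rotation must be 2x2")
        if not np.allclose(R.T @ R, np.eye(2), atol=1e-8):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("reflection (det=-1) is not a valid rigid transform here")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    @property
    def angle_rad(self) -> float:
        return float(np.arctan2(self.rotation[1, 0], self.rotation[0, 0]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)


def fit_procrustes(
    source: np.ndarray,
    target: np.ndarray,
    residual_warn_um: float = 100.0,
) -> RigidTransform:
    """Least-squares rigid fit of ``source`` landmarks onto ``target``.

    Correspondence is by order (point i of source maps to point i of
    target). The rotation is constrained to det=+1: a mirrored landmark set
    yields the best proper rotation with a large residual, which is logged
    when the RMS exceeds ``residual_warn_um``.
    """
    src = validate_landmarks(source)
    tgt = validate_landmarks(target)
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    mapped = src @ R.T + t
    rms = float(np.sqrt(((mapped - tgt) ** 2).sum(axis=1).mean()))
    if rms >= residual_warn_um:
        logger.warning(
            "procrustes residual RMS %.1f um exceeds %.1f um; landmarks may be "
            "mirrored or mis-ordered",
            rms,
            residual_warn_um,
        )
    return RigidTransform(R, t, residual_rms=rms)


def apply_transform(
    t: RigidTransform,
    cells: pd.DataFrame,
    origin: np.ndarray | tuple[float, float] = (0.0, 0.0),
    manual_shift_um: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Map cell coordinates and re-express them relative to ``origin``.

    ``cells`` must carry ``x_um``/``y_um`` columns; all other columns pass
    through. ``manual_shift_um`` records the optional user-supplied
    post-registration nudge (applied after the rigid map, provenance noted
    in the returned frame's attrs); it is never estimated automatically.
    """
    out = cells.copy()
    xy = out[["x_um", "y_um"]].to_numpy(dtype=float)
    mapped = t.apply(xy) + np.asarray(manual_shift_um, float) - np.asarray(origin, float)
    out["x_um"] = mapped[:, 0]
    out["y_um"] = mapped[:, 1]
    out.attrs["manual_shift_um"] = tuple(float(v) for v in manual_shift_um)
    return out


@dataclass
class RegionTemplate:
    """Section template: BLA outline, LA/BA split, canonical landmarks.

    Coordinates are in micrometres with the origin at the dorsal-most point
    of the outline and y increasing ventrally. ``subregions`` optionally
    refines the parcellation; assignment priority follows insertion order.
    """

    section: str
    outline: Polygon
    la: Polygon
    ba: Polygon
    landmarks: np.ndarray
    subregions: dict[str, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.landmarks = validate_landmarks(self.landmarks)
        if self.outline.area <= 0:
            raise ValueError("degenerate (zero-area) template outline")
        inter = self.la.intersection(self.ba).area
        if inter > 1e-6 * min(self.la.area, self.ba.area):
            raise ValueError("LA and BA interiors overlap")
        union = self.la.union(self.ba)
        if union.difference(self.outline.buffer(1e-6)).area > 1e-6 * union.area:
            raise ValueError("LA union BA extends outside the outline")

    @property
    def origin(self) -> np.ndarray:
        """Dorsal-most outline vertex (minimum y; ties broken by x)."""
        xy = np.asarray(self.outline.exterior.coords)
        order = np.lexsort((xy[:, 0], xy[:, 1]))
        return xy[order[0]]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return shapely.contains_xy(self.outline, x, y)


def assign_region(
    cells: pd.DataFrame,
    template: RegionTemplate,
    with_subregions: bool = False,
) -> pd.DataFrame:
    """Assign each cell to LA / BA / outside by point-in-polygon.

    Boundary points follow a half-open rule: a point on any LA edge
    (including the shared LA-BA border) is assigned LA, i.e. the polygon
    listed first wins. Cells outside the outline — and in any sliver of the
    outline covered by neither nucleus — are labelled ``outside``.
    """
    if template.la is None or template.ba is None:
        raise ValueError("template is missing LA/BA polygons")
    out = cells.copy()
    pts = shapely.points(out["x_um"].to_numpy(float), out["y_um"].to_numpy(float))
    in_la = shapely.covers(template.la, pts)
    in_ba = shapely.covers(template.ba, pts) & ~in_la
    region = np.where(in_la, "LA", np.where(in_ba, "BA", "outside"))
    n_edge = int((in_la & shapely.covers(template.ba, pts)).sum())
    if n_edge:
        logger.info("assign_region: %d on-border points assigned to LA by the half-open rule", n_edge)
    out["region"] = region
    if with_subregions and template.subregions:
        sub = np.full(len(out), "", dtype=object)
        for name, poly in template.subregions.items():
            hit = shapely.covers(poly, pts) & (sub == "")
            sub[hit] = name
        out["subregion"] = sub
    return out
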