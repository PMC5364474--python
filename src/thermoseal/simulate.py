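"""Seeded synthetic thermal colony scenes with ground truth.

Generates single-band temperature rasters that emulate the statistical
structure the detector assumes: a cold ambient background with Gaussian
spatial noise, optional warm landscape patches (confounders below the
detection threshold by default), individual seals as warm rasterized
ellipses with class-specific planar area and body temperature, and
multi-seal aggregations whose footprints merge above the detection
threshold while each member keeps a distinct warm core separated by cooler
contact seams.

Every scene is reproducible: identical (config, seed) gives a bit-identical
raster and truth. A single global random stream is consumed in a documented
order — background noise, landscape patches, isolated seals, aggregations —
so outputs are stable under the same config but not under config edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import GridTransform, ThermalRaster
from .assess import GroundTruthPoint
from .vector import write_points

__all__ = [
    "AggregationSpec",
    "SceneConfig",
    "SealRecord",
    "SyntheticTruth",
    "generate_scene",
    "write_truth",
]


@dataclass(frozen=True)
class AggregationSpec:
    """One aggregation: n touching same-class seals with distinct warm cores.

    ``core_excess_c`` is the peak temperature of a member's core above its
    body surface; ``seam_depression_c`` cools the contact line between
    touching bodies; ``core_spacing_px`` is a lower bound on the distance
    between adjacent member centers (the actual spacing is driven by the
    sampled body sizes so that neighboring bodies overlap).
    """

    n_members: int
    member_class: str = "adult"
    core_excess_c: float = 3.0
    seam_depression_c: float = 0.0
    core_spacing_px: float = 7.0

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("an aggregation needs at least 2 members")
        if self.member_class not in ("adult", "yoy"):
            raise ValueError(f"member_class must be 'adult' or 'yoy', got {self.member_class!r}")


@dataclass(frozen=True)
class SceneConfig:
    """Scene layout and thermal statistics.

    Defaults emulate a winter breeding-colony survey: 8 cm GSD, ambient
    near 0 °C with 0.8 °C spatial noise (well below a 9 °C detection
    threshold), YOY bodies 12–14 °C with 0.25–0.60 m² planar area, adult
    bodies 13–16 °C with 1.2–3.0 m², and a few warm landscape patches
    peaking below the threshold.
    """

    gsd_m: float = 0.08
    extent_m: tuple[float, float] = (40.0, 40.0)
    origin: tuple[float, float] = (500000.0, 5000000.0)
    crs: int = 32620  # UTM zone 20N
    nodata: float = -9999.0
    ambient_mean_c: float = 0.0
    ambient_sd_c: float = 0.8
    n_warm_patches: int = 3
    patch_radius_m: tuple[float, float] = (0.3, 1.0)
    patch_excess_c: tuple[float, float] = (3.0, 5.0)
    n_yoy: int = 0
    yoy_temp_c: tuple[float, float] = (12.0, 14.0)
    yoy_area_m2: tuple[float, float] = (0.25, 0.60)
    yoy_aspect: tuple[float, float] = (1.4, 2.2)
    n_adult: int = 0
    adult_temp_c: tuple[float, float] = (13.0, 16.0)
    adult_area_m2: tuple[float, float] = (1.2, 3.0)
    adult_aspect: tuple[float, float] = (2.0, 3.0)
    aggregations: tuple[AggregationSpec, ...] = ()
    min_gap_px: int = 2
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.yoy_area_m2[1] > 0.85:
            raise ValueError("YOY planar area range must stay <= 0.85 m2")
        if not (0.85 < self.adult_area_m2[0] and self.adult_area_m2[1] <= 3.5):
            raise ValueError("adult planar area range must lie within (0.85, 3.5] m2")
        for n in (self.n_yoy, self.n_adult, self.n_warm_patches):
            if n < 0:
                raise ValueError("object counts must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.extent_m[1] / self.gsd_m)),
                int(round(self.extent_m[0] / self.gsd_m)))


@dataclass(frozen=True)
class SealRecord:
    """Per-seal truth: class, true footprint area, body temperature, group."""

    id: int
    label: str
    area_m2: float
    body_temp_c: float
    aggregation_id: int | None = None


@dataclass
class SyntheticTruth:
    """Ground truth for a generated scene: one point per seal, at its centroid."""

    points: list[GroundTruthPoint] = field(default_factory=list)
    records: list[SealRecord] = field(default_factory=list)


class PlacementError(RuntimeError):
    pass


def _ellipse_cells(shape, center_rc, a_px, b_px, theta):
    """Grid cells whose centers fall inside an ellipse (index space)."""
    r0, c0 = center_rc
    pad = int(np.ceil(max(a_px, b_px))) + 1
    rlo, rhi = int(np.floor(r0)) - pad, int(np.ceil(r0)) + pad + 1
    clo, chi = int(np.floor(c0)) - pad, int(np.ceil(c0)) + pad + 1
    rlo, clo = max(rlo, 0), max(clo, 0)
    rhi, chi = min(rhi, shape[0]), min(chi, shape[1])
    if rlo >= rhi or clo >= chi:
        return np.empty(0, np.intp), np.empty(0, np.intp)
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    dr = rr - r0
    dc = cc - c0
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return rr[inside].ravel(), cc[inside].ravel()


def _footprint_free(occupied, rows, cols, gap_px, shape):
    """True if all cells plus a gap_px margin are inside the grid and free."""
    if rows.size == 0:
        return False
    if (rows.min() < gap_px or cols.min() < gap_px
            or rows.max() >= shape[0] - gap_px or cols.max() >= shape[1] - gap_px):
        return False
    r0, r1 = rows.min() - gap_px, rows.max() + gap_px + 1
    c0, c1 = cols.min() - gap_px, cols.max() + gap_px + 1
    window = occupied[r0:r1, c0:c1]
    if not window.any():
        return True
    # exact check: dilate the new footprint by gap_px (Chebyshev) and
    # require no overlap with already-occupied cells
    new = np.zeros(window.shape, dtype=bool)
    new[rows - r0, cols - c0] = True
    if gap_px > 0:
        new = ndimage.binary_dilation(new, structure=np.ones((3, 3), bool),
                                      iterations=gap_px)
    return not (new & window).any()


def _sample_ellipse(rng, cfg: SceneConfig, cls: str):
    if cls == "yoy":
        area = rng.uniform(*cfg.yoy_area_m2)
        aspect = rng.uniform(*cfg.yoy_aspect)
        temp = rng.uniform(*cfg.yoy_temp_c)
    else:
        area = rng.uniform(*cfg.adult_area_m2)
        aspect = rng.uniform(*cfg.adult_aspect)
        temp = rng.uniform(*cfg.adult_temp_c)
    area_px = area / cfg.gsd_m ** 2
    a = np.sqrt(area_px * aspect / np.pi)  # semi-major, px
    b = a / aspect
    theta = rng.uniform(0, np.pi)
    return area, temp, a, b, theta


def _place_isolated(rng, cfg, cls, values, occupied, truth, seal_id):
    shape = values.shape
    for _ in range(cfg.max_retries):
        area, temp, a, b, theta = _sample_ellipse(rng, cfg, cls)
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        rows, cols = _ellipse_cells(shape, (r0, c0), a, b, theta)
        if not _footprint_free(occupied, rows, cols, cfg.min_gap_px, shape):
            continue
        values[rows, cols] = temp
        occupied[rows, cols] = True
        x, y = _transform_of(cfg).xy(r0 - 0.5, c0 - 0.5)  # center in world coords
        truth.points.append(GroundTruthPoint(id=seal_id, x=float(x), y=float(y), label=cls))
        truth.records.append(SealRecord(
            id=seal_id, label=cls,
            area_m2=rows.size * cfg.gsd_m ** 2,
            body_temp_c=temp,
        ))
        return
    density = occupied.mean()
    raise PlacementError(
        f"could not place a {cls} after {cfg.max_retries} tries "
        f"(occupied fraction {density:.2f}); reduce counts or grow the extent"
    )


def _place_aggregation(rng, cfg, spec: AggregationSpec, agg_idx, values, occupied,
                       truth, next_id):
    """Place one aggregation: members along a zigzag path of touching ellipses.

    Member bodies are elongated ellipses aligned with the local path heading;
    the path turns sharply (alternating ~±100°) so the merged footprint is
    irregular (low solidity), as merged seal groups are in real imagery.
    Member temperature = body base + Gaussian core − seam depression where
    two bodies meet.
    """
    shape = values.shape
    for _ in range(cfg.max_retries):
        # sample member bodies from the class size/temperature ranges
        geoms = [_sample_ellipse(rng, cfg, spec.member_class)
                 for _ in range(spec.n_members)]  # (area, temp, a, b, theta)

        # chain centers along a sharply zigzagging path; the step between
        # adjacent centers is short enough that their bodies overlap
        centers = []
        r = rng.uniform(0, shape[0])
        c = rng.uniform(0, shape[1])
        heading = rng.uniform(0, 2 * np.pi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        centers.append((r, c, heading))
        for k in range(1, spec.n_members):
            a_prev = geoms[k - 1][2]
            b_next = geoms[k][3]
            step = max(spec.core_spacing_px, 0.85 * a_prev + 0.6 * b_next)
            r = r + step * np.sin(heading)
            c = c + step * np.cos(heading)
            heading = heading + sign * np.deg2rad(rng.uniform(85, 115))
            sign = -sign
            centers.append((r, c, heading))

        # one shared surface temperature per huddle: touching bodies are
        # thermally coupled, and a base-temperature step between members
        # would itself read as an edge to the high-pass filter
        if spec.member_class == "yoy":
            base_temp = rng.uniform(*cfg.yoy_temp_c)
        else:
            base_temp = rng.uniform(*cfg.adult_temp_c)

        sigmas = []
        member_cells = []
        all_rows, all_cols = [], []
        ok = True
        for (rm, cm, hd), (_area, _temp, a, b, _th) in zip(centers, geoms):
            rows, cols = _ellipse_cells(shape, (rm, cm), a, b, hd)
            if rows.size == 0:
                ok = False
                break
            sigmas.append(max(0.45 * b, 1.0))  # core radius ~ half body width
            member_cells.append((rows, cols))
            all_rows.append(rows)
            all_cols.append(cols)
        if not ok:
            continue
        rows = np.concatenate(all_rows)
        cols = np.concatenate(all_cols)
        if not _footprint_free(occupied, rows, cols, cfg.min_gap_px, shape):
            continue

        # temperature field: shared base + the strongest member core bump
        # (a continuous max: crease lines between cores are valleys, so the
        # high-pass response along them stays non-positive), optionally
        # cooled along the narrow band where two members are equidistant
        uniq = np.stack([rows, cols], axis=1)
        uniq = np.unique(uniq, axis=0)
        urows, ucols = uniq[:, 0], uniq[:, 1]
        d2 = np.stack([
            (urows - rm) ** 2 + (ucols - cm) ** 2 for (rm, cm, _h) in centers
        ], axis=0)  # (k, ncells)
        # truncated, rescaled Gaussian bumps: exactly zero beyond 2 sigma,
        # so the field equals the shared base near the footprint rim and the
        # filter sees no body-edge structure, only the internal cores
        sig = np.asarray(sigmas)[:, None]
        trunc = np.exp(-2.0)  # value at the 2-sigma cutoff
        bumps = (np.exp(-d2 / (2 * sig ** 2)) - trunc) / (1.0 - trunc)
        np.clip(bumps, 0.0, None, out=bumps)
        core = spec.core_excess_c * bumps.max(axis=0)
        if len(centers) > 1 and spec.seam_depression_c:
            d = np.sqrt(np.sort(d2, axis=0))
            seam_cool = spec.seam_depression_c * np.exp(-((d[1] - d[0]) ** 2) / 2.0)
        else:
            seam_cool = 0.0
        values[urows, ucols] = base_temp + core - seam_cool
        occupied[urows, ucols] = True

        t = _transform_of(cfg)
        for (rm, cm, _h), (mr, mc) in zip(centers, member_cells):
            x, y = t.xy(rm - 0.5, cm - 0.5)
            truth.points.append(GroundTruthPoint(
                id=next_id, x=float(x), y=float(y), label=spec.member_class))
            truth.records.append(SealRecord(
                id=next_id, label=spec.member_class,
                area_m2=mr.size * cfg.gsd_m ** 2,
                body_temp_c=base_temp, aggregation_id=agg_idx))
            next_id += 1
        return next_id
    density = occupied.mean()
    raise PlacementError(
        f"could not place aggregation #{agg_idx} ({spec.n_members} members) "
        f"after {cfg.max_retries} tries (occupied fraction {density:.2f})"
    )


def _transform_of(cfg: SceneConfig) -> GridTransform:
    return GridTransform(origin_x=cfg.origin[0], origin_y=cfg.origin[1], gsd_m=cfg.gsd_m)


def generate_scene(cfg: SceneConfig) -> tuple[ThermalRaster, SyntheticTruth]:
    """Generate a synthetic thermal scene and its ground truth.

    Consumes the seeded random stream in the order: background noise, warm
    landscape patches, isolated YOY, isolated adults, aggregations. Raises
    :class:`PlacementError` when objects cannot be placed without violating
    the minimum-gap rule after bounded retries.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = cfg.shape
    values = cfg.ambient_mean_c + rng.normal(0.0, cfg.ambient_sd_c, size=shape)

    # warm landscape patches: smooth disks of excess temperature
    for _ in range(cfg.n_warm_patches):
        radius_px = rng.uniform(*cfg.patch_radius_m) / cfg.gsd_m
        excess = rng.uniform(*cfg.patch_excess_c)
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        rows, cols = _ellipse_cells(shape, (r0, c0), radius_px, radius_px, 0.0)
        if rows.size:
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            values[rows, cols] += excess * np.exp(-d2 / (2 * (radius_px / 2) ** 2))

    occupied = np.zeros(shape, dtype=bool)
    truth = SyntheticTruth()
    seal_id = 0
    for _ in range(cfg.n_yoy):
        _place_isolated(rng, cfg, "yoy", values, occupied, truth, seal_id)
        seal_id += 1
    for _ in range(cfg.n_adult):
        _place_isolated(rng, cfg, "adult", values, occupied, truth, seal_id)
        seal_id += 1
    for agg_idx, spec in enumerate(cfg.aggregations):
        seal_id = _place_aggregation(rng, cfg, spec, agg_idx, values, occupied,
                                     truth, seal_id)

    raster = ThermalRaster(values=values, transform=_transform_of(cfg),
                           crs=cfg.crs, nodata=cfg.nodata)
    return raster, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialize truth points in the assessment module's point format."""
    write_points(truth.points, path)
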