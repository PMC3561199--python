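"""Synthetic pancreas-section generator with pixel-level ground truth.

Emulates the statistical structure of immunofluorescence sections of human
pancreas that the downstream quantification assumes:

* endocrine objects spanning scattered single cells and small clusters up to
  large islets, with a lognormal islet cell-count distribution (many small
  objects, few large ones);
* size-dependent cellular composition — small islets have a beta-cell core
  with an alpha/delta mantle, large islets intermingle non-beta cells;
* an optional PP-cell-rich zone containing elongated, irregularly shaped
  clusters composed solely of PP-cells, and islets carrying PP in their
  periphery; outside the zone PP appears only as sparse singlets or
  occasional intra-islet cells;
* per-region area-fraction targets (percent of tissue area per endocrine
  type) hit by iterative object addition with a stated tolerance.

Cells are filled discs (radius ~ N(cell_radius_mean, cell_radius_sd),
truncated below) packed on a jittered grid inside a star-convex islet
polygon; pure-PP clusters use an anisotropically scaled, concavity-perturbed
polygon, which yields the lower circularity and larger Feret diameter that
distinguish them from round islets.

Everything is driven by one :class:`numpy.random.Generator` seeded from the
config, so identical configs give bit-identical images and ground truth.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation as grey_dilation, disk as disk_selem

from .vslice import ChannelStack, Tile, TileGrid, CHANNELS, HORMONE_TO_TYPE, CELL_TYPES

TYPE_CODES = {t: i + 1 for i, t in enumerate(CELL_TYPES)}  # 0 = background
CODE_TO_TYPE = {v: k for k, v in TYPE_CODES.items()}

#: Area-fraction targets (percent of tissue area) for a PP-cell-poor region:
#: the low, pancreas-wide PP baseline with beta > alpha > delta.
POOR_TARGETS = {"beta": 0.7, "alpha": 0.5, "delta": 0.1, "pp": 0.01}

#: Targets for the PP-cell-rich region: PP dominates while beta- and
#: alpha-cell area fractions are markedly reduced.
RICH_TARGETS = {"beta": 0.3, "alpha": 0.08, "delta": 0.1, "pp": 1.2}


class UnsatisfiableTargetError(ValueError):
    """Raised when area-fraction targets cannot be realized by placement."""


@dataclass
class NoiseModel:
    """Intensity model for rendered channels (arbitrary units in [0, 1])."""

    background: float = 0.05
    background_sd: float = 0.02
    foreground: float = 0.8
    foreground_sd: float = 0.05
    blur_sigma: float = 1.0  # px


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic section.

    Lengths are micrometres; ``pixel_size`` converts to pixels. Composition
    dictionaries give per-type fractions for the smallest and largest islets;
    intermediate islets interpolate linearly in log10(area).
    """

    image_size: tuple[int, int] = (512, 512)  # (h, w) px
    pixel_size: float = 1.0  # um / px
    cell_radius_mean: float = 5.0  # um
    cell_radius_sd: float = 1.0  # um
    cell_radius_min: float = 2.0  # um
    islet_count_density: float = 30.0  # islets per mm^2 of tissue
    islet_size_log_mean: float = 3.0  # ln cell count
    islet_size_log_sd: float = 1.0
    singlet_fraction: float = 0.6  # P(single cell) when topping up deficits
    composition_small: dict[str, float] = field(
        default_factory=lambda: {"beta": 0.80, "alpha": 0.12, "delta": 0.06, "pp": 0.02}
    )
    composition_large: dict[str, float] = field(
        default_factory=lambda: {"beta": 0.55, "alpha": 0.28, "delta": 0.10, "pp": 0.07}
    )
    #: None -> whole section PP-poor; "all" -> whole section PP-rich;
    #: else a polygon [(row, col), ...] in pixel coordinates enclosing the
    #: PP-rich zone.
    pp_rich_zone: None | str | list[tuple[float, float]] = None
    pp_cluster_elongation: tuple[float, float] = (3.0, 0.8)  # aspect mean, sd
    pp_cluster_fraction: float = 0.8  # share of rich-zone PP area from pure clusters
    target_area_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"pp_poor": dict(POOR_TARGETS), "pp_rich": dict(RICH_TARGETS)}
    )
    target_rel_tol: float = 0.10  # relative tolerance on realized fractions
    min_object_gap: float = 25.0  # um clearance between placed objects
    mantle_max_diameter: float = 60.0  # um; smaller islets get core/mantle architecture
    nuclei_spacing: float = 12.0  # um between nuclei centers
    nuclei_radius: float = 3.0  # um
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ValueError(f"image_size must be at least 64x64, got {self.image_size}")
        for name in (
            "pixel_size",
            "cell_radius_mean",
            "cell_radius_sd",
            "cell_radius_min",
            "nuclei_spacing",
            "nuclei_radius",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for comp_name in ("composition_small", "composition_large"):
            comp = getattr(self, comp_name)
            if set(comp) != set(CELL_TYPES):
                raise ValueError(f"{comp_name} must define exactly {CELL_TYPES}")
            for t, v in comp.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{comp_name}[{t!r}] = {v} outside [0, 1]")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{comp_name} fractions must sum to 1 within 1e-9")
        if not 0.0 <= self.singlet_fraction <= 1.0:
            raise ValueError("singlet_fraction must lie in [0, 1]")
        if self.islet_count_density < 0:
            raise ValueError("islet_count_density must be non-negative")

    def to_json(self, path: str | pathlib.Path) -> None:
        d = asdict(self)
        d["image_size"] = list(self.image_size)
        pathlib.Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def pp_rich_config(**overrides) -> GeneratorConfig:
    """Preset: a section entirely inside the PP-cell-rich zone."""
    cfg = GeneratorConfig(pp_rich_zone="all", seed=1, **overrides)
    return cfg


def pp_poor_config(**overrides) -> GeneratorConfig:
    """Preset: a section entirely outside the PP-cell-rich zone."""
    return GeneratorConfig(pp_rich_zone=None, seed=1, **overrides)


@dataclass
class GroundTruth:
    """Pixel-level truth for one synthetic section.

    ``label_map`` assigns each pixel its object id (0 = background);
    ``type_map`` assigns the endocrine type code of the cell painted there
    (see :data:`TYPE_CODES`); ``object_table`` has one row per object;
    ``true_area_fractions[region][type]`` is the realized percent of region
    tissue area, computed from the maps themselves (self-consistent by
    construction).
    """

    label_map: np.ndarray  # int32
    type_map: np.ndarray  # uint8
    region_mask: np.ndarray  # bool, True inside the PP-rich zone
    object_table: pd.DataFrame
    true_area_fractions: dict[str, dict[str, float]]
    config: GeneratorConfig

    def recompute_area_fractions(self) -> dict[str, dict[str, float]]:
        """Recount per-type pixels from the maps (consistency oracle)."""
        return _area_fractions_from_maps(self.type_map, self.region_mask)

    def write(self, out_dir: str | pathlib.Path, section_id: str = "section") -> None:
        out_dir = pathlib.Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(out_dir / f"{section_id}_labels.tif", self.label_map.astype(np.int32))
        self.object_table.to_csv(out_dir / f"{section_id}_objects.csv", index=False)
        rows = [
            {"region": region, "cell_type": t, "percent": pct}
            for region, fracs in self.true_area_fractions.items()
            for t, pct in fracs.items()
        ]
        pd.DataFrame(rows).to_csv(out_dir / f"{section_id}_area_fractions.csv", index=False)
        self.config.to_json(out_dir / f"{section_id}_config.json")


def _area_fractions_from_maps(
    type_map: np.ndarray, region_mask: np.ndarray
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for region, mask in (("pp_rich", region_mask), ("pp_poor", ~region_mask)):
        denom = int(mask.sum())
        if denom == 0:
            continue
        out[region] = {
            t: 100.0 * int(((type_map == TYPE_CODES[t]) & mask).sum()) / denom
            for t in CELL_TYPES
        }
    return out


def _smooth_radial_noise(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Periodic smooth perturbation of polygon radii in [1-a, 1+a]."""
    raw = rng.normal(0.0, 1.0, n)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    smooth = np.convolve(np.tile(raw, 3), kernel, mode="same")[n : 2 * n]
    peak = np.max(np.abs(smooth)) or 1.0
    return 1.0 + amplitude * smooth / peak


def _star_polygon(
    rng: np.random.Generator,
    radius_px: float,
    amplitude: float,
    aspect: float = 1.0,
    n_vertices: int = 24,
) -> np.ndarray:
    """Vertices (row, col) of a star-convex polygon centered at the origin."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = radius_px * _smooth_radial_noise(rng, n_vertices, amplitude)
    rr = radii * np.sin(theta)
    cc = radii * np.cos(theta) * aspect
    phi = rng.uniform(0.0, np.pi)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    return np.column_stack([rr, cc]) @ rot.T


@dataclass
class _PaintedObject:
    """Local raster of one endocrine object before placement."""

    footprint: np.ndarray  # bool
    types: np.ndarray  # uint8, 0 outside footprint
    cell_count: int
    pure_pp: bool
    kind: str  # "islet" | "pp_cluster" | "singlet" | "small_cluster"


def _interp_composition(cfg: GeneratorConfig, cell_count: int) -> dict[str, float]:
    """Linear interpolation in log10(expected area) between the small- and
    large-islet composition anchors."""
    cell_area = np.pi * cfg.cell_radius_mean**2
    log_a = np.log10(max(cell_count * cell_area, cell_area))
    lo, hi = np.log10(2 * cell_area), np.log10(3000 * cell_area)
    w = float(np.clip((log_a - lo) / (hi - lo), 0.0, 1.0))
    comp = {
        t: (1 - w) * cfg.composition_small[t] + w * cfg.composition_large[t]
        for t in CELL_TYPES
    }
    total = sum(comp.values())
    return {t: v / total for t, v in comp.items()}


def _largest_remainder_counts(comp: dict[str, float], n: int) -> dict[str, int]:
    exact = {t: comp[t] * n for t in CELL_TYPES}
    counts = {t: int(np.floor(v)) for t, v in exact.items()}
    short = n - sum(counts.values())
    for t in sorted(CELL_TYPES, key=lambda t: exact[t] - counts[t], reverse=True)[:short]:
        counts[t] += 1
    return counts


def _sample_cell_radius(rng: np.random.Generator, cfg: GeneratorConfig, n: int = 1) -> np.ndarray:
    r = rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd, n)
    return np.maximum(r, cfg.cell_radius_min)


def _paint_cluster(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    cell_count: int,
    composition: dict[str, float],
    pure_pp: bool,
    in_rich_zone: bool,
) -> _PaintedObject:
    """Pack cell discs on a jittered grid inside a polygon boundary."""
    px = cfg.pixel_size
    cell_r_px = cfg.cell_radius_mean / px
    cell_area_px = np.pi * cell_r_px**2
    packing = 0.62
    radius_px = float(np.sqrt(cell_count * cell_area_px / packing / np.pi))

    if pure_pp:
        aspect = max(1.5, rng.normal(*cfg.pp_cluster_elongation))
        verts = _star_polygon(rng, radius_px / np.sqrt(aspect), 0.45, aspect=aspect)
    else:
        verts = _star_polygon(rng, radius_px, 0.22)

    margin = int(np.ceil(cell_r_px + cfg.cell_radius_sd / px)) + 2
    r_min, c_min = verts.min(axis=0)
    verts_local = verts - [r_min, c_min] + margin
    h = int(np.ceil(verts_local[:, 0].max())) + margin
    w = int(np.ceil(verts_local[:, 1].max())) + margin
    poly_mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(verts_local[:, 0], verts_local[:, 1], shape=(h, w))
    poly_mask[rr, cc] = True

    # jittered square grid of candidate cell centers inside the polygon;
    # spacing < 2 cell radii keeps neighboring discs overlapping so the
    # object footprint stays connected
    spacing = 1.45 * cell_r_px
    rows = np.arange(spacing / 2, h, spacing)
    cols = np.arange(spacing / 2, w, spacing)
    centers = np.array([(r, c) for r in rows for c in cols])
    centers = centers + rng.uniform(-1.0, 1.0, centers.shape)
    inside = [
        (r, c)
        for r, c in centers
        if 0 <= int(r) < h and 0 <= int(c) < w and poly_mask[int(r), int(c)]
    ]
    if not inside:
        inside = [(h / 2.0, w / 2.0)]
    centers = np.array(inside)
    n_cells = len(centers)

    if pure_pp:
        type_per_cell = np.full(n_cells, TYPE_CODES["pp"], dtype=np.uint8)
    else:
        counts = _largest_remainder_counts(composition, n_cells)
        centroid = centers.mean(axis=0)
        dist = np.hypot(*(centers - centroid).T)
        eff_diam_um = 2.0 * np.sqrt(n_cells * cell_area_px / packing / np.pi) * px
        type_per_cell = np.zeros(n_cells, dtype=np.uint8)
        if eff_diam_um < cfg.mantle_max_diameter:
            # small islet: beta core, non-beta mantle (PP outermost in the
            # rich zone, emulating PP at the islet periphery)
            order = np.argsort(dist)
            mantle_order = (
                ("alpha", "delta", "pp") if not in_rich_zone else ("alpha", "delta",)
            )
            seq: list[str] = ["beta"] * counts["beta"]
            non_beta: list[str] = []
            for t in mantle_order:
                non_beta.extend([t] * counts[t])
            if in_rich_zone:
                non_beta.extend(["pp"] * counts["pp"])  # outermost ring
            seq.extend(non_beta)
            for rank, t in zip(order, seq):
                type_per_cell[rank] = TYPE_CODES[t]
        else:
            # large islet: intermingled types
            seq = []
            for t in CELL_TYPES:
                seq.extend([t] * counts[t])
            perm = rng.permutation(n_cells)
            for idx, t in zip(perm, seq):
                type_per_cell[idx] = TYPE_CODES[t]

    footprint = np.zeros((h, w), dtype=bool)
    types = np.zeros((h, w), dtype=np.uint8)
    radii = _sample_cell_radius(rng, cfg, n_cells) / px
    for (r, c), rad, code in zip(centers, radii, type_per_cell):
        rr, cc = draw_disk((r, c), rad, shape=(h, w))
        footprint[rr, cc] = True
        types[rr, cc] = code

    # trim to tight bbox
    rows_any = np.flatnonzero(footprint.any(axis=1))
    cols_any = np.flatnonzero(footprint.any(axis=0))
    sl = (slice(rows_any[0], rows_any[-1] + 1), slice(cols_any[0], cols_any[-1] + 1))
    kind = "pp_cluster" if pure_pp else "islet"
    return _PaintedObject(footprint[sl], types[sl], n_cells, pure_pp, kind)


def _paint_singlet(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    cell_type: str,
    radius_px: float | None = None,
) -> _PaintedObject:
    px = cfg.pixel_size
    rad = radius_px if radius_px is not None else float(_sample_cell_radius(rng, cfg)[0] / px)
    size = int(np.ceil(2 * rad)) + 3
    footprint = np.zeros((size, size), dtype=bool)
    rr, cc = draw_disk((size / 2.0, size / 2.0), rad, shape=(size, size))
    footprint[rr, cc] = True
    types = np.where(footprint, TYPE_CODES[cell_type], 0).astype(np.uint8)
    return _PaintedObject(footprint, types, 1, cell_type == "pp", "singlet")


def _paint_small_cluster(
    rng: np.random.Generator, cfg: GeneratorConfig, cell_type: str, n_cells: int
) -> _PaintedObject:
    comp = {t: (1.0 if t == cell_type else 0.0) for t in CELL_TYPES}
    obj = _paint_cluster(rng, cfg, n_cells, comp, pure_pp=False, in_rich_zone=False)
    obj.types[obj.footprint] = TYPE_CODES[cell_type]
    obj.pure_pp = False
    obj.kind = "small_cluster"
    return obj


class _Canvas:
    """Mutable section state during generation."""

    def __init__(self, cfg: GeneratorConfig):
        h, w = cfg.image_size
        self.cfg = cfg
        self.label_map = np.zeros((h, w), dtype=np.int32)
        self.type_map = np.zeros((h, w), dtype=np.uint8)
        self.blocked = np.zeros((h, w), dtype=bool)  # occupancy + clearance
        self.records: list[dict] = []
        self.next_id = 1
        self.gap_px = max(1, int(round(cfg.min_object_gap / cfg.pixel_size)))
        self._gap_selem = disk_selem(self.gap_px)

    def try_place(
        self,
        rng: np.random.Generator,
        obj: _PaintedObject,
        allowed: np.ndarray,
        region: str,
        max_tries: int = 60,
    ) -> bool:
        """Place the object uniformly at random within ``allowed``; the
        object plus a clearance ring must avoid previously placed objects and
        stay entirely inside the allowed region."""
        h, w = self.label_map.shape
        oh, ow = obj.footprint.shape
        if oh > h or ow > w:
            return False
        pad = self.gap_px
        dilated = grey_dilation(np.pad(obj.footprint, pad), self._gap_selem)
        dh, dw = dilated.shape
        for _ in range(max_tries):
            r0 = int(rng.integers(0, h - oh + 1))
            c0 = int(rng.integers(0, w - ow + 1))
            rd0, cd0 = r0 - pad, c0 - pad
            # clearance window clipped at image edge (border contact allowed)
            rs, cs = max(rd0, 0), max(cd0, 0)
            re, ce = min(rd0 + dh, h), min(cd0 + dw, w)
            dil_view = dilated[rs - rd0 : re - rd0, cs - cd0 : ce - cd0]
            if np.any(self.blocked[rs:re, cs:ce] & dil_view):
                continue
            if not np.all(allowed[r0 : r0 + oh, c0 : c0 + ow][obj.footprint]):
                continue
            oid = self.next_id
            self.next_id += 1
            win_lab = self.label_map[r0 : r0 + oh, c0 : c0 + ow]
            win_typ = self.type_map[r0 : r0 + oh, c0 : c0 + ow]
            win_lab[obj.footprint] = oid
            win_typ[obj.footprint] = obj.types[obj.footprint]
            self.blocked[rs:re, cs:ce] |= dil_view
            area_px = int(obj.footprint.sum())
            per_type = {
                t: int((obj.types == TYPE_CODES[t]).sum()) for t in CELL_TYPES
            }
            rows_idx, cols_idx = np.nonzero(obj.footprint)
            rec = {
                "object_id": oid,
                "kind": obj.kind,
                "cell_count": obj.cell_count,
                "pure_pp_cluster": obj.pure_pp,
                "region": region,
                "centroid_row": r0 + float(rows_idx.mean()),
                "centroid_col": c0 + float(cols_idx.mean()),
                "area_px": area_px,
            }
            for t in CELL_TYPES:
                rec[f"{t}_px"] = per_type[t]
                rec[f"comp_{t}"] = per_type[t] / area_px
            self.records.append(rec)
            return True
        return False


def _fill_region(
    rng: np.random.Generator,
    canvas: _Canvas,
    region: str,
    region_mask: np.ndarray,
    targets: dict[str, float],
) -> None:
    cfg = canvas.cfg
    px = cfg.pixel_size
    region_px = int(region_mask.sum())
    if region_px == 0:
        return
    cell_area_px = np.pi * (cfg.cell_radius_mean / px) ** 2
    budget = {t: targets.get(t, 0.0) / 100.0 * region_px for t in CELL_TYPES}
    # discrete cells cannot realize arbitrarily small targets exactly: the
    # tolerance floor is one mean cell's area
    tol = {t: max(cfg.target_rel_tol * budget[t], cell_area_px) for t in CELL_TYPES}

    def painted(t: str) -> int:
        return int(
            ((canvas.type_map == TYPE_CODES[t]) & region_mask).sum()
        )

    # --- stage 1: mixed islets, count set by islet_count_density -------------
    region_mm2 = region_px * (px / 1000.0) ** 2
    n_islets = int(round(cfg.islet_count_density * region_mm2))
    rich = region == "pp_rich"
    placed_islets = 0
    attempts = 0
    while placed_islets < n_islets and attempts < 8 * max(n_islets, 1):
        attempts += 1
        cell_count = int(
            np.clip(rng.lognormal(cfg.islet_size_log_mean, cfg.islet_size_log_sd), 3, 2500)
        )
        comp = _interp_composition(cfg, cell_count)
        # painted area ~ the cluster polygon area: cell discs overlap at the
        # packing spacing, so area ~ n * cell_area / packing
        est = {t: comp[t] * cell_count * cell_area_px / 0.62 for t in CELL_TYPES}
        if any(painted(t) + est[t] > budget[t] + tol[t] for t in CELL_TYPES):
            continue  # rejected: would overshoot a per-type budget
        obj = _paint_cluster(rng, cfg, cell_count, comp, pure_pp=False, in_rich_zone=rich)
        if any(
            painted(t) + int((obj.types == TYPE_CODES[t]).sum()) > budget[t] + tol[t]
            for t in CELL_TYPES
        ):
            continue
        if canvas.try_place(rng, obj, region_mask, region):
            placed_islets += 1

    # --- stage 2: pure-PP clusters fill most of the rich-zone PP budget ------
    if rich and budget["pp"] > 0:
        cluster_goal = cfg.pp_cluster_fraction * budget["pp"]
        failures = 0
        while painted("pp") < min(cluster_goal, budget["pp"] - tol["pp"]) and failures < 40:
            cell_count = int(
                np.clip(rng.lognormal(cfg.islet_size_log_mean, cfg.islet_size_log_sd), 5, 1500)
            )
            deficit = budget["pp"] - painted("pp")
            cell_count = int(min(cell_count, max(5, 0.62 * deficit / cell_area_px)))
            obj = _paint_cluster(rng, cfg, cell_count, {}, pure_pp=True, in_rich_zone=True)
            if painted("pp") + int(obj.footprint.sum()) > budget["pp"] + tol["pp"]:
                failures += 1
                continue
            if not canvas.try_place(rng, obj, region_mask, region):
                failures += 1

    # --- stage 3: top up each type with singlets / small clusters -----------
    for t in CELL_TYPES:
        failures = 0
        while painted(t) < budget[t] - tol[t]:
            if failures > 200:
                raise UnsatisfiableTargetError(
                    f"cannot reach {t} target {targets.get(t, 0.0)}% in region "
                    f"{region!r}: placement failed after {failures} tries "
                    f"(min_object_gap={cfg.min_object_gap} um, "
                    f"image_size={cfg.image_size})"
                )
            deficit = budget[t] - painted(t)
            if rng.uniform() < cfg.singlet_fraction or deficit < 4 * cell_area_px:
                rad = None
                if deficit < cell_area_px * 1.2:
                    rad = max(
                        cfg.cell_radius_min / px, float(np.sqrt(deficit / np.pi))
                    )
                obj = _paint_singlet(rng, cfg, t, radius_px=rad)
            else:
                n_cells = int(rng.integers(2, 9))
                n_cells = min(n_cells, max(2, int(deficit / cell_area_px)))
                obj = _paint_small_cluster(rng, cfg, t, n_cells)
            if painted(t) + int(obj.footprint.sum()) > budget[t] + tol[t]:
                failures += 1
                continue
            if not canvas.try_place(rng, obj, region_mask, region):
                failures += 1


def _render_channels(
    rng: np.random.Generator, cfg: GeneratorConfig, type_map: np.ndarray
) -> dict[str, np.ndarray]:
    h, w = type_map.shape
    nm = cfg.noise
    px = cfg.pixel_size

    # nuclear counterstain: nuclei on a jittered grid across the whole
    # tissue (the section background is uniform exocrine parenchyma)
    nuclei_mask = np.zeros((h, w), dtype=bool)
    spacing = cfg.nuclei_spacing / px
    # grid runs edge to edge so the derived tissue mask reaches the borders
    rows = np.r_[np.arange(0.0, h - 1, spacing), h - 1.0]
    cols = np.r_[np.arange(0.0, w - 1, spacing), w - 1.0]
    jitter_r = rng.uniform(-2.0, 2.0, (len(rows), len(cols)))
    jitter_c = rng.uniform(-2.0, 2.0, (len(rows), len(cols)))
    rad = cfg.nuclei_radius / px
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            rr, cc = draw_disk((r + jitter_r[i, j], c + jitter_c[i, j]), rad, shape=(h, w))
            nuclei_mask[rr, cc] = True

    channels: dict[str, np.ndarray] = {}
    masks = {
        hormone: type_map == TYPE_CODES[ct] for hormone, ct in HORMONE_TO_TYPE.items()
    }
    masks["nuclei"] = nuclei_mask
    for name in CHANNELS:
        img = nm.background + rng.normal(0.0, nm.background_sd, (h, w))
        fg = masks[name]
        img[fg] = nm.foreground + rng.normal(0.0, nm.foreground_sd, int(fg.sum()))
        if nm.blur_sigma > 0:
            img = ndi.gaussian_filter(img, nm.blur_sigma)
        channels[name] = np.clip(img, 0.0, 1.0)
    return channels


def _region_mask(cfg: GeneratorConfig) -> np.ndarray:
    h, w = cfg.image_size
    if cfg.pp_rich_zone is None:
        return np.zeros((h, w), dtype=bool)
    if cfg.pp_rich_zone == "all":
        return np.ones((h, w), dtype=bool)
    verts = np.asarray(cfg.pp_rich_zone, dtype=float)
    mask = np.zeros((h, w), dtype=bool)
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=(h, w))
    mask[rr, cc] = True
    return mask


def generate_section(
    config: GeneratorConfig, section_id: str = "section", block_index: int | None = None
) -> tuple[ChannelStack, GroundTruth]:
    """Generate one synthetic multichannel section plus its ground truth.

    Objects are placed without overlap and with a clearance ring of
    ``min_object_gap`` so that morphological merging downstream does not fuse
    distinct objects. Realized per-type area fractions land within
    ``target_rel_tol`` (relative) of ``target_area_fractions`` per region,
    with an absolute floor of one mean cell's area fraction.

    Raises
    ------
    UnsatisfiableTargetError
        If a target cannot be reached by object placement, naming the
        conflicting parameters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    canvas = _Canvas(config)
    rich_mask = _region_mask(config)

    for region, mask in (("pp_rich", rich_mask), ("pp_poor", ~rich_mask)):
        if not mask.any():
            continue
        targets = config.target_area_fractions.get(region, {})
        _fill_region(rng, canvas, region, mask, targets)

    object_table = pd.DataFrame(
        canvas.records,
        columns=[
            "object_id", "kind", "cell_count", "pure_pp_cluster", "region",
            "centroid_row", "centroid_col", "area_px",
            *[f"{t}_px" for t in CELL_TYPES],
            *[f"comp_{t}" for t in CELL_TYPES],
        ],
    )
    truth = GroundTruth(
        label_map=canvas.label_map,
        type_map=canvas.type_map,
        region_mask=rich_mask,
        object_table=object_table,
        true_area_fractions=_area_fractions_from_maps(canvas.type_map, rich_mask),
        config=config,
    )
    channels = _render_channels(rng, config, canvas.type_map)
    stack = ChannelStack(
        channels=channels,
        pixel_size=config.pixel_size,
        section_id=section_id,
        block_index=block_index,
    )
    return stack, truth


def series_configs(
    n_blocks: int,
    boundary_block: int,
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
    **overrides,
) -> list[GeneratorConfig]:
    """Configs for a head-to-tail block series: blocks before
    ``boundary_block`` are PP-rich, the rest PP-poor."""
    configs = []
    for i in range(n_blocks):
        zone = "all" if i < boundary_block else None
        configs.append(
            GeneratorConfig(
                pp_rich_zone=zone,
                image_size=image_size,
                seed=(seed * 1_000_003 + 7919 * i) % (2**31),
                **overrides,
            )
        )
    return configs


def generate_block_series(
    configs: list[GeneratorConfig],
) -> list[tuple[ChannelStack, GroundTruth]]:
    """Generate an ordered series of sections, one per tissue block."""
    if not configs:
        raise ValueError("generate_block_series requires at least one config")
    if len(configs) < 2:
        raise ValueError("a block series needs at least 2 blocks")
    return [
        generate_section(cfg, section_id=f"block{i:02d}", block_index=i)
        for i, cfg in enumerate(configs)
    ]


def render_tiles(stack: ChannelStack, tile_size: int, overlap: int = 0) -> TileGrid:
    """Cut a section into a rectangular grid of overlapping tiles.

    The inverse of stitching: overlapping strips are pixelwise identical
    copies of the source, so ``stitch(render_tiles(stack)) == stack``. A tile
    size larger than the image yields a single tile.
    """
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    if tile_size <= overlap:
        raise ValueError(f"tile_size ({tile_size}) must exceed overlap ({overlap})")
    h, w = stack.shape

    def origins(extent: int) -> list[int]:
        if tile_size >= extent:
            return [0]
        step = tile_size - overlap
        pos = list(range(0, extent - tile_size + 1, step))
        if pos[-1] + tile_size < extent:
            pos.append(extent - tile_size)
        return pos

    row_origins = origins(h)
    col_origins = origins(w)
    tiles = []
    for i, r0 in enumerate(row_origins):
        for j, c0 in enumerate(col_origins):
            th = min(tile_size, h)
            tw = min(tile_size, w)
            tiles.append(
                Tile(
                    channels={
                        name: arr[r0 : r0 + th, c0 : c0 + tw].copy()
                        for name, arr in stack.channels.items()
                    },
                    grid_pos=(i, j),
                    origin=(r0, c0),
                )
            )
    return TileGrid(
        tiles=tiles,
        n_rows=len(row_origins),
        n_cols=len(col_origins),
        overlap=overlap,
        pixel_size=stack.pixel_size,
        section_id=stack.section_id,
        block_index=stack.block_index,
    )
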