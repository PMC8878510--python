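"""Seeded synthetic CAM-xenograft scenes with ground truth.

The generator emulates the tissue structure seen in DAPI-stained sections of
human xenografts grown on the chicken chorioallantoic membrane: large, round
human tumour nuclei inside the section, a dense rim of small elongated
chicken nuclei at the border (the CAM itself), sparse infiltrating chicken
nuclei inside the human tissue, and cytoplasmic or fibrous marker signal over
a chosen subset of cells. Nuclei are rendered as filled ellipses (so any
target area/eccentricity is realized exactly up to rasterization), images are
quantized to 8 bits after optional additive Gaussian noise, and every scene
carries a full ground-truth table, which makes segmentation, classification
and quantification testable without real tissue images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import draw

from .classification import (
    CLASS_CHICKEN_INFILTRATING,
    CLASS_CHICKEN_PERIPHERAL,
    CLASS_HUMAN,
    eccentricity_from_coords,
    k3_density,
)
from .segmentation import DAPI, ImageScene

MORPH_CYTOPLASMIC = "cytoplasmic_ring"
MORPH_FIBRE = "elongated_fibre"

# fibre footprint: 2 x 30 px, aspect ratio 15 — passes the elongation filter
# (boundary-step perimeter 64 over area 60) by construction
FIBRE_SHAPE = (2, 30)

# minimum per-ellipse area for a touching pair, so the union exceeds the
# 200-px splitting threshold even after overlap
_PAIR_MIN_AREA = 115.0
_PAIR_CENTER_FACTOR = 0.85  # centre distance as a fraction of summed radii


class SceneGenerationError(RuntimeError):
    """Raised when requested nucleus counts cannot be placed without overlap."""


@dataclass(frozen=True)
class MarkerSpec:
    """One marker channel: who is positive and how the signal looks.

    morphology ``cytoplasmic_ring`` paints the whole cell territory (nucleus
    plus the surrounding ring out to ``SceneParams.marker_radius``) at the
    given intensity, so both nuclear and cytoplasmic mean intensities of a
    positive cell equal ``intensity`` exactly in a noise-free scene.
    ``elongated_fibre`` paints a thin 2x30 rectangle through the cell, the
    footprint of fibrous stellate-cell markers such as ACTA-2.
    """

    name: str
    target_class: str = CLASS_HUMAN
    positive_fraction: float = 0.5
    morphology: str = MORPH_CYTOPLASMIC
    intensity: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 <= self.positive_fraction <= 1.0):
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.morphology not in (MORPH_CYTOPLASMIC, MORPH_FIBRE):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        if not (0.0 <= self.intensity <= 1.0):
            raise ValueError("intensity must lie in [0, 1]")


@dataclass(frozen=True)
class SceneParams:
    """Study conditions for one synthetic scene.

    Defaults emulate a 10x field of xenograft tissue: ~8% nuclear coverage,
    human nuclei of 80-180 px² and low eccentricity inside the section,
    small highly eccentric chicken nuclei packed into a 40-px CAM rim, a few
    infiltrating chicken nuclei, mild sensor noise (sd 0.02 of full scale)
    over a faint background. The chicken/human area and eccentricity ranges
    are disjoint on purpose ("separable" geometry): classifier tests rely on
    it.
    """

    image_height: int = 512
    image_width: int = 512
    n_human: int = 150
    n_chicken_rim: int = 150
    n_chicken_infiltrating: int = 30
    human_area_range: tuple[float, float] = (80.0, 180.0)
    human_ecc_range: tuple[float, float] = (0.1, 0.5)
    chicken_area_range: tuple[float, float] = (20.0, 60.0)
    chicken_ecc_range: tuple[float, float] = (0.75, 0.95)
    rim_width: int = 40
    touching_pair_fraction: float = 0.0
    marker_specs: tuple[MarkerSpec, ...] = ()
    noise_sd: float = 0.02
    background_level: float = 0.05
    seed: int = 0
    dapi_intensity: float = 0.8
    marker_radius: int = 10  # cytoplasmic territory radius for marker rendering

    def __post_init__(self) -> None:
        for name in ("n_human", "n_chicken_rim", "n_chicken_infiltrating"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("human_area_range", "human_ecc_range",
                     "chicken_area_range", "chicken_ecc_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be a non-degenerate (low, high) interval")
        for name in ("human_ecc_range", "chicken_ecc_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo and hi < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.touching_pair_fraction <= 1.0:
            raise ValueError("touching_pair_fraction must lie in [0, 1]")
        if self.rim_width >= min(self.image_height, self.image_width) / 2:
            raise ValueError("rim_width must be < min(image dims)/2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must lie in [0, 1]")
        names = [m.name for m in self.marker_specs]
        if len(names) != len(set(names)):
            raise ValueError("marker names must be unique")


@dataclass
class GroundTruth:
    """What the generator actually drew.

    ``nuclei``: one row per nucleus (id, row, col, class, area_px,
    eccentricity) with realized (rasterized) area and eccentricity.
    ``positives``: marker name -> set of positive nucleus ids.
    ``intensities``: marker name -> {nucleus id: rendered intensity}.
    """

    nuclei: pd.DataFrame
    positives: dict[str, frozenset[int]] = field(default_factory=dict)
    intensities: dict[str, dict[int, float]] = field(default_factory=dict)


def _ellipse_axes(area: float, ecc: float) -> tuple[float, float]:
    """Semi-major/minor axes of an ellipse with the given area and eccentricity."""
    a = np.sqrt(area / (np.pi * np.sqrt(1.0 - ecc**2)))
    return a, area / (np.pi * a)


def quantize_u8(raster: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and quantize to uint8, rounding half up."""
    clipped = np.clip(raster, 0.0, 1.0)
    return np.floor(clipped * 255.0 + 0.5).astype(np.uint8)


class _Placer:
    """Rejection-sampling placement of non-overlapping ellipses."""

    def __init__(self, params: SceneParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.centers: list[tuple[float, float]] = []
        self.radii: list[float] = []      # semi-major axes
        self.big_gap: list[bool] = []     # needs marker-territory clearance
        target_classes = {m.target_class for m in params.marker_specs}
        self._marker_gap = 2.0 * params.marker_radius + 2.0
        self._target_classes = target_classes

    def _gap(self, cls: str, other_big: bool) -> float:
        big = cls in self._target_classes
        return self._marker_gap if (big or other_big) else 3.0

    def _fits(self, row: float, col: float, a: float, cls: str) -> bool:
        for (r0, c0), a0, big0 in zip(self.centers, self.radii, self.big_gap):
            gap = self._gap(cls, big0)
            if (row - r0) ** 2 + (col - c0) ** 2 < (a + a0 + gap) ** 2:
                return False
        return True

    def add(self, row: float, col: float, a: float, cls: str) -> None:
        self.centers.append((row, col))
        self.radii.append(a)
        self.big_gap.append(cls in self._target_classes)

    def sample_interior(self, a: float) -> tuple[float, float]:
        p = self.p
        margin = p.rim_width + a + 1
        if p.image_height - 2 * margin <= 1 or p.image_width - 2 * margin <= 1:
            raise SceneGenerationError("interior region too small for requested nuclei")
        row = self.rng.uniform(margin, p.image_height - 1 - margin)
        col = self.rng.uniform(margin, p.image_width - 1 - margin)
        return row, col

    def sample_rim(self, a: float) -> tuple[float, float]:
        p = self.p
        for _ in range(200):
            row = self.rng.uniform(a + 1, p.image_height - 2 - a)
            col = self.rng.uniform(a + 1, p.image_width - 2 - a)
            border_dist = min(row, p.image_height - 1 - row, col, p.image_width - 1 - col)
            if border_dist < p.rim_width:
                return row, col
        raise SceneGenerationError("could not sample a rim position")


def _render_nucleus(
    canvas: np.ndarray, row: float, col: float, area: float, ecc: float,
    theta: float, value: float,
) -> tuple[np.ndarray, np.ndarray]:
    a, b = _ellipse_axes(area, ecc)
    rr, cc = draw.ellipse(row, col, a, b, shape=canvas.shape, rotation=theta)
    canvas[rr, cc] = value
    return rr, cc


def generate_scene(params: SceneParams) -> tuple[ImageScene, GroundTruth]:
    """Render one synthetic scene and its ground truth.

    Placement is rejection sampling with a clearance rule: nuclei never touch
    (so the ground-truth count is exact), and when markers are present,
    marker-target cells keep a full territory's clearance so rendered marker
    signal never bleeds into a neighbouring cell's territory. A requested
    configuration that cannot be placed raises SceneGenerationError naming
    the offending count. Identical params (including seed) give bit-identical
    output.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    placer = _Placer(p, rng)
    shape = (p.image_height, p.image_width)
    dapi = np.full(shape, float(p.background_level))

    records: list[dict] = []
    coords: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    next_id = 1
    max_tries = 2000

    def place_one(cls: str, area_range, ecc_range, sampler) -> None:
        nonlocal next_id
        area = rng.uniform(*area_range)
        ecc = rng.uniform(*ecc_range)
        theta = rng.uniform(0.0, np.pi)
        a, _ = _ellipse_axes(area, ecc)
        for _ in range(max_tries):
            row, col = sampler(a)
            if placer._fits(row, col, a, cls):
                placer.add(row, col, a, cls)
                rr, cc = _render_nucleus(dapi, row, col, area, ecc, theta, p.dapi_intensity)
                records.append(
                    {"id": next_id, "row": row, "col": col, "class": cls,
                     "area_px": len(rr),
                     "eccentricity": eccentricity_from_coords(rr, cc)}
                )
                coords[next_id] = (rr, cc)
                next_id += 1
                return
        raise SceneGenerationError(
            f"placement failed for class {cls!r}: could not fit requested count"
        )

    # --- touching pairs (exercise the watershed splitter) -----------------
    n_pairs = int(round(p.touching_pair_fraction * p.n_human / 2.0))
    n_single_human = p.n_human - 2 * n_pairs
    if n_pairs and p.human_area_range[1] <= _PAIR_MIN_AREA:
        raise SceneGenerationError(
            "touching pairs need human_area_range to reach above "
            f"{_PAIR_MIN_AREA} px so the pair union exceeds the split threshold"
        )
    for _ in range(n_pairs):
        lo = max(p.human_area_range[0], _PAIR_MIN_AREA)
        area1, area2 = rng.uniform(lo, p.human_area_range[1], size=2)
        ecc_hi = min(p.human_ecc_range[1], 0.3)
        ecc1, ecc2 = rng.uniform(p.human_ecc_range[0], max(p.human_ecc_range[0] + 1e-6, ecc_hi), size=2)
        r1, r2 = np.sqrt(area1 / np.pi), np.sqrt(area2 / np.pi)
        d = _PAIR_CENTER_FACTOR * (r1 + r2)
        a_pair = max(r1, r2) + d  # bounding radius of the pair
        placed = False
        for _ in range(max_tries):
            row, col = placer.sample_interior(a_pair)
            phi = rng.uniform(0.0, 2 * np.pi)
            row2, col2 = row + d * np.sin(phi), col + d * np.cos(phi)
            if placer._fits(row, col, a_pair, CLASS_HUMAN):
                placer.add(row, col, a_pair, CLASS_HUMAN)
                for (rw, cl, ar, ec) in ((row, col, area1, ecc1), (row2, col2, area2, ecc2)):
                    theta = rng.uniform(0.0, np.pi)
                    rr, cc = _render_nucleus(dapi, rw, cl, ar, ec, theta, p.dapi_intensity)
                    records.append(
                        {"id": next_id, "row": rw, "col": cl, "class": CLASS_HUMAN,
                         "area_px": len(rr),
                         "eccentricity": eccentricity_from_coords(rr, cc)}
                    )
                    coords[next_id] = (rr, cc)
                    next_id += 1
                placed = True
                break
        if not placed:
            raise SceneGenerationError(
                f"placement failed for touching pairs: n_human={p.n_human}"
            )

    for _ in range(n_single_human):
        place_one(CLASS_HUMAN, p.human_area_range, p.human_ecc_range,
                  placer.sample_interior)
    for _ in range(p.n_chicken_rim):
        place_one(CLASS_CHICKEN_PERIPHERAL, p.chicken_area_range,
                  p.chicken_ecc_range, placer.sample_rim)
    for _ in range(p.n_chicken_infiltrating):
        place_one(CLASS_CHICKEN_INFILTRATING, p.chicken_area_range,
                  p.chicken_ecc_range, placer.sample_interior)

    nuclei = pd.DataFrame(
        records, columns=["id", "row", "col", "class", "area_px", "eccentricity"]
    )

    # --- marker channels ---------------------------------------------------
    channels: dict[str, np.ndarray] = {}
    positives: dict[str, frozenset[int]] = {}
    intensities: dict[str, dict[int, float]] = {}
    for spec in p.marker_specs:
        channel = np.zeros(shape)
        eligible = nuclei.loc[nuclei["class"] == spec.target_class, "id"].to_numpy()
        k = int(round(spec.positive_fraction * len(eligible)))
        chosen = np.sort(rng.choice(eligible, size=k, replace=False)) if k else np.array([], int)
        for cid in chosen:
            rr, cc = coords[int(cid)]
            if spec.morphology == MORPH_CYTOPLASMIC:
                _paint_territory(channel, rr, cc, p.marker_radius, spec.intensity)
            else:
                _paint_fibre(channel, nuclei, int(cid), rng, spec.intensity)
        positives[spec.name] = frozenset(int(c) for c in chosen)
        intensities[spec.name] = {int(c): spec.intensity for c in chosen}
        channels[spec.name] = channel

    # --- noise and quantization -------------------------------------------
    out_channels: dict[str, np.ndarray] = {}
    for name, raster in [(DAPI, dapi)] + [(m.name, channels[m.name]) for m in p.marker_specs]:
        if p.noise_sd > 0:
            raster = raster + rng.normal(0.0, p.noise_sd, size=shape)
        out_channels[name] = quantize_u8(raster)

    scene = ImageScene(channels=out_channels)
    truth = GroundTruth(nuclei=nuclei, positives=positives, intensities=intensities)
    return scene, truth


def _paint_territory(
    channel: np.ndarray, rr: np.ndarray, cc: np.ndarray, radius: int, value: float
) -> None:
    """Paint the cell territory: all pixels within ``radius`` of the nucleus."""
    pad = radius + 1
    r0 = max(int(rr.min()) - pad, 0)
    c0 = max(int(cc.min()) - pad, 0)
    r1 = min(int(rr.max()) + pad + 1, channel.shape[0])
    c1 = min(int(cc.max()) + pad + 1, channel.shape[1])
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rr - r0, cc - c0] = True
    dist = ndi.distance_transform_edt(~local)
    channel[r0:r1, c0:c1][dist <= radius] = value


def _paint_fibre(
    channel: np.ndarray, nuclei: pd.DataFrame, cid: int,
    rng: np.random.Generator, value: float,
) -> None:
    """Paint a thin fibre rectangle (random horizontal/vertical) through the cell."""
    rec = nuclei.loc[nuclei["id"] == cid].iloc[0]
    row, col = int(round(rec["row"])), int(round(rec["col"]))
    h, w = FIBRE_SHAPE if rng.integers(2) == 0 else FIBRE_SHAPE[::-1]
    r0 = np.clip(row - h // 2, 0, channel.shape[0])
    c0 = np.clip(col - w // 2, 0, channel.shape[1])
    channel[r0:min(r0 + h, channel.shape[0]), c0:min(c0 + w, channel.shape[1])] = value


def training_features_from_truth(truth: GroundTruth) -> pd.DataFrame:
    """Labeled feature table straight from ground truth (for classifier training)."""
    df = truth.nuclei
    out = pd.DataFrame(
        {
            "label": df["id"].to_numpy(),
            "area_px": df["area_px"].astype(float).to_numpy(),
            "eccentricity": df["eccentricity"].to_numpy(),
            "k3_density_px": k3_density(df[["row", "col"]].to_numpy()),
            "class": df["class"].to_numpy(),
        }
    )
    return out


# --- file I/O ---------------------------------------------------------------

NUCLEI_SIDE_CAR = "{stem}.nuclei.csv"
MARKER_SIDE_CAR = "{stem}.markers.csv"


def scene_to_files(scene: ImageScene, truth: GroundTruth, path: str | Path) -> list[Path]:
    """Write a scene as a multipage 8-bit TIFF plus ground-truth CSV sidecars.

    Channel order in the file matches the scene's declared order (DAPI
    first); channel names go into the TIFF description as JSON. Returns the
    written paths. Reading back reproduces pixel values exactly.
    """
    path = Path(path)
    names = list(scene.channels)
    stack = np.stack([scene.channels[n] for n in names])
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        description=json.dumps({"channels": names}),
        metadata=None,
    )
    written = [path]
    nuc_path = path.with_name(NUCLEI_SIDE_CAR.format(stem=path.stem))
    truth.nuclei.to_csv(nuc_path, index=False)
    written.append(nuc_path)
    rows = [
        {"marker": m, "cell_id": cid, "intensity": truth.intensities[m][cid]}
        for m in truth.positives
        for cid in sorted(truth.positives[m])
    ]
    marker_path = path.with_name(MARKER_SIDE_CAR.format(stem=path.stem))
    pd.DataFrame(rows, columns=["marker", "cell_id", "intensity"]).to_csv(
        marker_path, index=False
    )
    written.append(marker_path)
    return written


def read_scene(path: str | Path) -> tuple[ImageScene, GroundTruth | None]:
    """Read a scene TIFF (and ground-truth sidecars, when present)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    if stack.ndim == 2:
        stack = stack[None]
    try:
        names = json.loads(desc)["channels"]
    except (json.JSONDecodeError, KeyError, TypeError):
        names = [DAPI] + [f"channel_{i}" for i in range(1, len(stack))]
    scene = ImageScene(channels=dict(zip(names, stack)))

    nuc_path = path.with_name(NUCLEI_SIDE_CAR.format(stem=path.stem))
    if not nuc_path.exists():
        return scene, None
    nuclei = pd.read_csv(nuc_path)
    positives: dict[str, frozenset[int]] = {}
    intensities: dict[str, dict[int, float]] = {}
    marker_path = path.with_name(MARKER_SIDE_CAR.format(stem=path.stem))
    if marker_path.exists():
        mdf = pd.read_csv(marker_path)
        for marker, grp in mdf.groupby("marker"):
            positives[str(marker)] = frozenset(grp["cell_id"].astype(int))
            intensities[str(marker)] = dict(
                zip(grp["cell_id"].astype(int), grp["intensity"].astype(float))
            )
    return scene, GroundTruth(nuclei=nuclei, positives=positives, intensities=intensities)


def separable_scene_params(**overrides) -> SceneParams:
    """SceneParams preset with chicken and human feature ranges fully disjoint."""
    base = SceneParams()
    return replace(base, **overrides) if overrides else base
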