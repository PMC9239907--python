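"""Interpretable histopathological features from tissue label maps.

The inputs are a per-pixel tissue-type map (tumor / stroma / necrosis /
fat / background), as produced by an upstream tile classifier, and a table
of detected nuclei with per-nucleus morphology and stain statistics.  The
outputs are human-readable features:

* tissue-type features — per-class area and area fraction, region
  properties (moment-ellipse axis lengths, eccentricity, solidity,
  perimeter) of both the largest connected component and the union of all
  components, pairwise area ratios, and the entropy of tumor and stroma;
* cell-type features — aggregative statistics (mean, variance, deciles) of
  nuclear area, diameter, circularity and stain intensity, stratified by
  parent tissue type and by lymphocyte vs other cells;
* relative specimen size — the foreground fraction of the grid.

The entropy of a class is defined as the mean Shannon entropy (bits) of the
tissue-class composition of fixed square patches (default 64 px, the tile
scale of the upstream classifier), restricted to patches intersecting that
class.  All areas are in µm² and lengths in µm via the map's pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage import measure

TISSUE_CLASSES = ("background", "tumor", "stroma", "necrosis", "fat")
FOREGROUND_CLASSES = ("tumor", "stroma", "necrosis", "fat")
ENTROPY_CLASSES = ("tumor", "stroma")
AGGREGATE_PARENTS = ("tumor", "stroma", "necrosis")
CELL_TYPES = ("all", "lymphocyte", "other")
NUCLEUS_MEASUREMENTS = ("area", "diameter", "circularity", "eosin_mean", "hematoxylin_mean")
PERCENTILES = tuple(range(10, 100, 10))
REGION_PROPS = (
    "area",
    "area_fraction",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "solidity",
    "perimeter",
)
DEFAULT_PATCH_PX = 64
FEATURE_REGISTRY_VERSION = "1"


@dataclass
class TissueMap:
    """A 2-D grid of tissue-class indices with a palette and pixel size."""

    labels: np.ndarray  # 2-D int array
    palette: dict[int, str]  # index -> class name
    microns_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("label grid must be a nonempty 2-D array")
        if self.microns_per_pixel <= 0:
            raise ValueError("pixel size must be positive")
        present = set(np.unique(self.labels).tolist())
        if not present <= set(self.palette):
            raise ValueError(f"grid indices {present - set(self.palette)} missing from palette")
        unknown = set(self.palette.values()) - set(TISSUE_CLASSES)
        if unknown:
            raise ValueError(f"unknown tissue classes in palette: {unknown}")

    def mask(self, cls: str) -> np.ndarray:
        idx = [i for i, name in self.palette.items() if name == cls]
        return np.isin(self.labels, idx)

    def class_at(self, x: float, y: float) -> str:
        """Tissue class of the pixel containing point (x, y) in pixel coords."""
        col, row = int(np.floor(x)), int(np.floor(y))
        h, w = self.labels.shape
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"point ({x}, {y}) outside the {w}x{h} grid")
        return self.palette[int(self.labels[row, col])]


def default_palette() -> dict[int, str]:
    return {i: name for i, name in enumerate(TISSUE_CLASSES)}


_CLASS_COLORS = {
    "background": (255, 255, 255),
    "tumor": (228, 26, 28),
    "stroma": (55, 126, 184),
    "necrosis": (77, 175, 74),
    "fat": (255, 255, 51),
}


def save_tissue_map(tm: TissueMap, png_path) -> None:
    """Write an indexed PNG plus a JSON palette sidecar."""
    png_path = Path(png_path)
    img = Image.fromarray(tm.labels.astype(np.uint8), mode="P")
    # an explicit color palette keeps PIL from remapping the indices
    pal = [0] * 768
    for idx, name in tm.palette.items():
        r, g, b = _CLASS_COLORS[name]
        pal[3 * idx : 3 * idx + 3] = [r, g, b]
    img.putpalette(pal)
    img.save(png_path)
    sidecar = {
        "palette": {str(k): v for k, v in tm.palette.items()},
        "microns_per_pixel": tm.microns_per_pixel,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_tissue_map(png_path) -> TissueMap:
    png_path = Path(png_path)
    labels = np.array(Image.open(png_path))
    sidecar = json.loads(png_path.with_suffix(".json").read_text())
    palette = {int(k): v for k, v in sidecar["palette"].items()}
    return TissueMap(labels, palette, float(sidecar["microns_per_pixel"]))


# -- tissue-type features --------------------------------------------------

def _mask_props(mask: np.ndarray, mpp: float, total_px: int) -> dict[str, float]:
    props = measure.regionprops(mask.astype(np.uint8))[0]
    return {
        "area": float(props.area) * mpp**2,
        "area_fraction": float(props.area) / total_px,
        "major_axis_length": float(props.axis_major_length) * mpp,
        "minor_axis_length": float(props.axis_minor_length) * mpp,
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "perimeter": float(props.perimeter) * mpp,
    }


def region_features(tm: TissueMap, cls: str, connectivity: int = 2) -> dict[str, float]:
    """Region properties of one tissue class.

    Returns ``{cls}_whole_*`` for the union of all components and
    ``{cls}_lcc_*`` for the largest (8-connected by default) component,
    plus an ``{cls}_absent`` flag; an absent class yields all zeros with
    the flag set.
    """
    if cls not in TISSUE_CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    mask = tm.mask(cls)
    total_px = tm.labels.size
    out: dict[str, float] = {}
    if not mask.any():
        for scope in ("whole", "lcc"):
            for prop in REGION_PROPS:
                out[f"{cls}_{scope}_{prop}"] = 0.0
        out[f"{cls}_absent"] = 1.0
        return out
    mpp = tm.microns_per_pixel
    whole = _mask_props(mask, mpp, total_px)
    labeled = measure.label(mask, connectivity=connectivity)
    components = measure.regionprops(labeled)
    largest = max(components, key=lambda p: p.area)
    lcc = _mask_props(labeled == largest.label, mpp, total_px)
    for prop in REGION_PROPS:
        out[f"{cls}_whole_{prop}"] = whole[prop]
        out[f"{cls}_lcc_{prop}"] = lcc[prop]
    out[f"{cls}_absent"] = 0.0
    return out


def _patch_entropy(tm: TissueMap, cls: str, patch_px: int) -> float:
    """Mean Shannon entropy (bits) of patch class composition, over patches
    intersecting ``cls``; NaN when the class is absent."""
    mask_cls = tm.mask(cls)
    if not mask_cls.any():
        return float("nan")
    h, w = tm.labels.shape
    names = sorted(set(tm.palette.values()))
    index_of = {}
    for idx, name in tm.palette.items():
        index_of.setdefault(name, []).append(idx)
    entropies = []
    for i0 in range(0, h, patch_px):
        for j0 in range(0, w, patch_px):
            patch = tm.labels[i0 : i0 + patch_px, j0 : j0 + patch_px]
            if not mask_cls[i0 : i0 + patch_px, j0 : j0 + patch_px].any():
                continue
            counts = np.array(
                [np.isin(patch, index_of.get(name, [])).sum() for name in names],
                dtype=float,
            )
            p = counts / counts.sum()
            p = p[p > 0]
            entropies.append(float(-(p * np.log2(p)).sum()))
    return float(np.mean(entropies))


def composition_features(tm: TissueMap, patch_px: int = DEFAULT_PATCH_PX) -> dict[str, float]:
    """Pairwise class area ratios and the entropy of tumor and stroma.

    A ratio with a zero-area denominator is missing (NaN), never infinite.
    """
    areas = {cls: float(tm.mask(cls).sum()) for cls in FOREGROUND_CLASSES}
    out: dict[str, float] = {}
    for a in FOREGROUND_CLASSES:
        for b in FOREGROUND_CLASSES:
            if a == b:
                continue
            out[f"ratio_{a}_to_{b}"] = areas[a] / areas[b] if areas[b] > 0 else float("nan")
    for cls in ENTROPY_CLASSES:
        out[f"{cls}_entropy"] = _patch_entropy(tm, cls, patch_px)
    return out


# -- nuclei ----------------------------------------------------------------

NUCLEUS_COLUMNS = (
    "id", "x", "y", "area", "diameter", "circularity",
    "eosin_mean", "hematoxylin_mean", "cell_type",
)


def validate_nuclei(nuclei: pd.DataFrame) -> None:
    missing = set(NUCLEUS_COLUMNS) - set(nuclei.columns)
    if missing:
        raise ValueError(f"nucleus table lacks columns: {sorted(missing)}")
    if len(nuclei) and (
        (nuclei["area"] <= 0).any() or (nuclei["diameter"] <= 0).any()
    ):
        raise ValueError("nuclear areas and diameters must be positive")


def assign_parents(nuclei: pd.DataFrame, tm: TissueMap) -> pd.DataFrame:
    """Assign each nucleus the tissue class at its centroid pixel.

    The class is read directly from the pixel containing the centroid (no
    interpolation; a boundary centroid gets that pixel's class).  Nuclei on
    background are flagged ``excluded`` and ignored by the aggregates.
    Out-of-bounds centroids raise.
    """
    validate_nuclei(nuclei)
    out = nuclei.copy()
    parents = [tm.class_at(x, y) for x, y in zip(out["x"], out["y"])]
    out["parent"] = parents
    out["excluded"] = out["parent"] == "background"
    return out


def nuclear_aggregates(nuclei: pd.DataFrame) -> dict[str, float]:
    """Aggregative statistics of nuclear morphology by parent and cell type.

    For each parent tissue in {tumor, stroma, necrosis} × cell type in
    {all, lymphocyte, other} × measurement: mean, variance (population) and
    deciles 10–90 (linear-interpolation quantiles); plus the lymphocyte
    fraction per parent.  Empty strata are missing (NaN); a parent with
    nuclei but no lymphocytes has lymphocyte fraction 0.
    """
    if "parent" not in nuclei.columns:
        raise ValueError("call assign_parents first")
    usable = nuclei[~nuclei["excluded"]]
    out: dict[str, float] = {}
    for parent in AGGREGATE_PARENTS:
        sub = usable[usable["parent"] == parent]
        out[f"{parent}_lymphocyte_fraction"] = (
            float((sub["cell_type"] == "lymphocyte").mean()) if len(sub) else float("nan")
        )
        for ct in CELL_TYPES:
            if ct == "all":
                grp = sub
            elif ct == "lymphocyte":
                grp = sub[sub["cell_type"] == "lymphocyte"]
            else:
                grp = sub[sub["cell_type"] != "lymphocyte"]
            for meas in NUCLEUS_MEASUREMENTS:
                prefix = f"{parent}_{ct}_{meas}"
                if len(grp) == 0:
                    out[f"{prefix}_mean"] = float("nan")
                    out[f"{prefix}_var"] = float("nan")
                    for pct in PERCENTILES:
                        out[f"{prefix}_p{pct}"] = float("nan")
                    continue
                vals = grp[meas].to_numpy(dtype=float)
                out[f"{prefix}_mean"] = float(vals.mean())
                out[f"{prefix}_var"] = float(vals.var(ddof=0))
                for pct in PERCENTILES:
                    out[f"{prefix}_p{pct}"] = float(np.percentile(vals, pct))
    return out


# -- the full embedding ----------------------------------------------------

def feature_registry() -> list[str]:
    """Ordered, versioned names of every feature in the embedding."""
    names: list[str] = []
    for cls in FOREGROUND_CLASSES:
        for scope in ("whole", "lcc"):
            for prop in REGION_PROPS:
                names.append(f"{cls}_{scope}_{prop}")
        names.append(f"{cls}_absent")
    for a in FOREGROUND_CLASSES:
        for b in FOREGROUND_CLASSES:
            if a != b:
                names.append(f"ratio_{a}_to_{b}")
    for cls in ENTROPY_CLASSES:
        names.append(f"{cls}_entropy")
    for parent in AGGREGATE_PARENTS:
        names.append(f"{parent}_lymphocyte_fraction")
        for ct in CELL_TYPES:
            for meas in NUCLEUS_MEASUREMENTS:
                names.append(f"{parent}_{ct}_{meas}_mean")
                names.append(f"{parent}_{ct}_{meas}_var")
                for pct in PERCENTILES:
                    names.append(f"{parent}_{ct}_{meas}_p{pct}")
    names.append("relative_specimen_size")
    return names


def embed_specimen(
    tm: TissueMap, nuclei: pd.DataFrame, patch_px: int = DEFAULT_PATCH_PX
) -> pd.Series:
    """Concatenate tissue-type, composition and nuclear features.

    Returns a Series indexed by the versioned feature registry; every
    registered feature is present (value or NaN).  ``relative_specimen_size``
    is the foreground (non-background) fraction of the grid.
    """
    feats: dict[str, float] = {}
    for cls in FOREGROUND_CLASSES:
        feats.update(region_features(tm, cls))
    feats.update(composition_features(tm, patch_px=patch_px))
    labeled = assign_parents(nuclei, tm) if "parent" not in nuclei.columns else nuclei
    feats.update(nuclear_aggregates(labeled))
    feats["relative_specimen_size"] = float(tm.mask("background").size - tm.mask("background").sum()) / tm.labels.size
    registry = feature_registry()
    return pd.Series([feats[name] for name in registry], index=registry, dtype=float)
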