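"""Render correlation maps as 3-D surface images and assemble the image set.

Each correlation map (synchronous / asynchronous / integrated) becomes one
square surface image: intensity plotted over the wavenumber x wavenumber
plane, colored by a perceptually uniform palette, no axes or ticks, fixed
view angles. Per-map intensity autoscaling is the default so images are
invariant to the map's absolute amplitude (which is quadratic/quartic in
absorbance and would otherwise leak overall scale rather than shape).

:func:`build_image_dataset` renders the three categories for every sample
and draws one seed-controlled, class-stratified train/test/external-
validation role assignment shared by all categories (default counts
84/36/52 on 172 samples, 516 images total).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.colors import Normalize
from matplotlib.figure import Figure
from PIL import Image

from .cos import CorrelationMaps

__all__ = [
    "RenderConfig",
    "ImageRecord",
    "ImageDataset",
    "RenderError",
    "render_surface",
    "assign_roles",
    "build_image_dataset",
    "read_manifest",
]

CATEGORIES = ("synchronous", "asynchronous", "integrated")
ROLES = ("train", "test", "ev")


class RenderError(ValueError):
    """Non-finite map or invalid render configuration."""


@dataclass(frozen=True)
class RenderConfig:
    image_size: int = 224
    colormap: str = "viridis"
    view: tuple[float, float] = (30.0, -60.0)  # (elevation, azimuth) degrees
    format: str = "PNG"  # PNG | JPEG
    quality: int = 95
    decorations: bool = False

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise RenderError("image_size must be >= 32")
        elev, azim = self.view
        if not (0 <= elev <= 90) or not (-180 <= azim <= 180):
            raise RenderError("view must be elevation in [0,90], azimuth in [-180,180]")
        if self.format.upper() not in {"PNG", "JPEG"}:
            raise RenderError(f"unsupported format {self.format!r}")


def render_surface_array(
    matrix: np.ndarray,
    wavenumbers: np.ndarray | None = None,
    config: RenderConfig = RenderConfig(),
    intensity_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render one map to an RGB uint8 array (deterministic for fixed input).

    ``intensity_range`` overrides the per-map autoscaling with a shared
    (vmin, vmax), for ablations where absolute amplitude should be kept.
    """
    Z = np.asarray(matrix, dtype=float)
    if not np.isfinite(Z).all():
        raise RenderError("map contains NaN/Inf")
    n1, n2 = Z.shape
    w = (
        np.asarray(wavenumbers, dtype=float)
        if wavenumbers is not None
        else np.arange(n2, dtype=float)
    )
    if intensity_range is None:
        vmin, vmax = float(Z.min()), float(Z.max())
    else:
        vmin, vmax = intensity_range
    if vmax - vmin < 1e-300:  # flat surface: center the palette
        mid = vmin
        vmin, vmax = mid - 1.0, mid + 1.0

    s = config.image_size
    dpi = 100.0
    fig = Figure(figsize=(s / dpi, s / dpi), dpi=dpi)
    canvas = FigureCanvasAgg(fig)
    if config.decorations:
        ax = fig.add_subplot(projection="3d")
    else:
        ax = fig.add_axes((0.0, 0.0, 1.0, 1.0), projection="3d")
        ax.set_axis_off()
    X, Y = np.meshgrid(w[:n2], w[:n1])
    # quads finer than the output pixel grid are invisible but costly
    stride_cap = max(32, s)
    ax.plot_surface(
        X,
        Y,
        Z,
        cmap=config.colormap,
        norm=Normalize(vmin=vmin, vmax=vmax),
        rcount=min(n1, stride_cap),
        ccount=min(n2, stride_cap),
        antialiased=False,
        linewidth=0,
    )
    ax.set_zlim(vmin, vmax)
    ax.view_init(elev=config.view[0], azim=config.view[1])
    canvas.draw()
    buf = np.asarray(canvas.buffer_rgba())[:, :, :3].copy()
    return buf


def render_surface(
    map_matrix: np.ndarray,
    path: str | Path,
    wavenumbers: np.ndarray | None = None,
    config: RenderConfig = RenderConfig(),
    intensity_range: tuple[float, float] | None = None,
) -> Path:
    """Render one map component to an image file (PNG or JPEG)."""
    rgb = render_surface_array(map_matrix, wavenumbers, config, intensity_range)
    path = Path(path)
    img = Image.fromarray(rgb)
    if config.format.upper() == "JPEG":
        img.save(path, format="JPEG", quality=config.quality)
    else:
        img.save(path, format="PNG")
    return path


# ---------------------------------------------------------------------- #
# Dataset assembly


@dataclass(frozen=True)
class ImageRecord:
    path: Path
    label: str
    sample_id: str
    role: str


@dataclass
class ImageDataset:
    """Per-category image lists sharing one role assignment."""

    records: dict[str, list[ImageRecord]]  # category -> records
    split_counts: tuple[int, int, int]
    seed: int

    def by_role(self, category: str, role: str) -> list[ImageRecord]:
        return [r for r in self.records[category] if r.role == role]


def assign_roles(
    sample_ids: list[str],
    labels: dict[str, str],
    counts: tuple[int, int, int],
    seed: int,
) -> dict[str, str]:
    """Class-stratified random train/test/ev role assignment.

    Role totals reproduce ``counts`` exactly; within each role the class
    mix follows the global class proportions (largest-remainder rounding,
    last role takes the per-class remainder). Deterministic per seed.
    """
    n = len(sample_ids)
    if sum(counts) != n:
        raise RenderError(f"counts {counts} do not sum to the sample count {n}")
    if any(c <= 0 for c in counts):
        raise RenderError("every role needs at least one sample")
    rng = np.random.default_rng(seed)
    classes = sorted(set(labels[s] for s in sample_ids))
    pools = {
        c: [s for s in sorted(sample_ids) if labels[s] == c] for c in classes
    }
    for c in classes:
        pools[c] = list(rng.permutation(pools[c]))

    # controlled rounding of the class x role quota matrix: floors first,
    # then leftover units to the cells with the largest fractional parts,
    # always respecting both the class sizes and the role totals — every
    # cell ends within one sample of its exact proportional share.
    quota = {(c, r): t * len(pools[c]) / n for c in classes for r, t in zip(ROLES, counts)}
    take = {cell: int(np.floor(q)) for cell, q in quota.items()}
    class_deficit = {c: len(pools[c]) - sum(take[c, r] for r in ROLES) for c in classes}
    role_deficit = {
        r: t - sum(take[c, r] for c in classes) for r, t in zip(ROLES, counts)
    }
    while any(d > 0 for d in role_deficit.values()):
        cands = [
            (quota[c, r] - take[c, r], c, r)
            for c in classes
            for r in ROLES
            if class_deficit[c] > 0 and role_deficit[r] > 0
        ]
        _, c, r = max(cands, key=lambda t: (t[0], t[1], t[2]))
        take[c, r] += 1
        class_deficit[c] -= 1
        role_deficit[r] -= 1

    assignment: dict[str, str] = {}
    for c in classes:
        for r in ROLES:
            for _ in range(take[c, r]):
                assignment[pools[c].pop()] = r
    return assignment


def build_image_dataset(
    maps: dict[str, CorrelationMaps],
    labels: dict[str, str],
    out_dir: str | Path,
    counts: tuple[int, int, int] = (84, 36, 52),
    seed: int = 0,
    config: RenderConfig = RenderConfig(),
    categories: tuple[str, ...] = CATEGORIES,
) -> ImageDataset:
    """Render every sample's maps and write the role manifest.

    One image per (sample, category), files under
    ``out_dir/<category>/<sample_id>.<ext>``; manifest CSV columns
    ``sample_id,class,category,role,path``.
    """
    out_dir = Path(out_dir)
    sids = list(maps)
    roles = assign_roles(sids, labels, counts, seed)
    ext = "jpg" if config.format.upper() == "JPEG" else "png"
    records: dict[str, list[ImageRecord]] = {c: [] for c in categories}
    rows = []
    for category in categories:
        cat_dir = out_dir / category
        cat_dir.mkdir(parents=True, exist_ok=True)
        for sid in sids:
            cm = maps[sid]
            mat = {
                "synchronous": cm.sync,
                "asynchronous": cm.asyn,
                "integrated": cm.integrated,
            }[category]
            path = cat_dir / f"{sid}.{ext}"
            render_surface(mat, path, cm.wavenumbers, config)
            rec = ImageRecord(path, labels[sid], sid, roles[sid])
            records[category].append(rec)
            rows.append((sid, labels[sid], category, roles[sid], str(path)))
    pd.DataFrame(
        rows, columns=["sample_id", "class", "category", "role", "path"]
    ).to_csv(out_dir / "manifest.csv", index=False)
    return ImageDataset(records, counts, seed)


def read_manifest(path: str | Path) -> ImageDataset:
    df = pd.read_csv(path, dtype=str)
    records: dict[str, list[ImageRecord]] = {}
    for _, row in df.iterrows():
        records.setdefault(row["category"], []).append(
            ImageRecord(Path(row["path"]), row["class"], row["sample_id"], row["role"])
        )
    any_cat = next(iter(records.values()))
    counts = tuple(sum(1 for r in any_cat if r.role == role) for role in ROLES)
    return ImageDataset(records, counts, seed=-1)
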