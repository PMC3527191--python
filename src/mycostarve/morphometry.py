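"""Skeleton-based hyphal diameter morphometry.

Measures hyphal diameters from bright-field micrographs of dispersed stained
mycelium through a six-stage chain: (1) binarize (Gaussian smoothing + global
Otsu threshold, dark objects as foreground); (2) outline all objects;
(3) skeletonize to a 1-px medial representation; (4) remove skeleton
intersections so only simple paths remain; (5/6) fragment each path and cast
two orthogonal rays from each fragment center to the first background
crossing — the sum of the two ray lengths, scaled by the pixel size, is the
local hyphal diameter.  Pooled diameter samples are summarized as a Gaussian
kernel density together with thin/thick population fractions at a split
threshold (default 2 µm, between the ≈1 µm secondary-growth and ≈3 µm
primary-growth populations).

Conventions: 8-connectivity throughout; coordinates are (row, col) with
origin at the top-left, 0-based.  Empty hyphal ghosts (unstained cell-wall
outlines) are excluded by the stain polarity itself: their 1-px walls do not
survive smoothing + Otsu, so they never enter the foreground mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, signal, stats
from skimage import filters, morphology

__all__ = [
    "Micrograph",
    "SkeletonFragment",
    "DiameterSample",
    "DiameterDistribution",
    "MorphometryConfig",
    "read_micrograph",
    "binarize",
    "outline",
    "skeletonize",
    "prune_intersections",
    "fragment_skeleton",
    "measure_diameters",
    "measure_micrograph",
    "diameter_density",
    "density_modes",
    "process_micrograph_batch",
    "samples_to_frame",
    "write_samples",
    "read_samples",
]

logger = logging.getLogger(__name__)

# 8-neighbourhood offsets, used for neighbour counting and path tracing
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=np.uint8)


@dataclass
class Micrograph:
    """A grayscale micrograph with its µm-per-pixel calibration."""

    pixels: np.ndarray  # float intensities in [0, 1]
    pixel_size: float  # µm per px
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 3:
            raise ValueError("micrograph must be a 2-D image of at least 3x3 px")


@dataclass
class SkeletonFragment:
    """A consecutive run of skeleton pixels with a defined local orientation."""

    pixels: np.ndarray  # (n, 2) int array of (row, col)
    fragment_id: int

    @property
    def center(self) -> tuple[int, int]:
        r, c = self.pixels[len(self.pixels) // 2]
        return int(r), int(c)

    @property
    def orientation(self) -> np.ndarray:
        """Unit vector from first to last pixel of the fragment."""
        vec = self.pixels[-1].astype(float) - self.pixels[0].astype(float)
        norm = np.hypot(*vec)
        if norm == 0:
            raise ValueError("degenerate fragment with identical endpoints")
        return vec / norm


@dataclass
class DiameterSample:
    diameter_um: float
    center: tuple[int, int]  # (row, col)
    fragment_id: int
    source_id: str = ""


@dataclass
class DiameterDistribution:
    """Kernel density of pooled diameters plus population split fractions."""

    grid: np.ndarray  # µm
    density: np.ndarray  # integrates to 1 over grid
    bandwidth: float  # µm
    n_samples: int
    thin_fraction: float
    thick_fraction: float
    split_threshold: float  # µm


@dataclass
class MorphometryConfig:
    """All tunable stage parameters (lengths in px unless suffixed _um)."""

    pixel_size_um: float = 0.2
    smoothing_sigma: float = 1.0
    min_object_px: int = 64
    fragment_len: int = 7
    max_diameter_um: float = 10.0
    split_threshold_um: float = 2.0
    kde_bandwidth_um: float | None = None  # None = Silverman's rule
    grid_max_um: float = 6.0

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Image input
# ---------------------------------------------------------------------------

def read_micrograph(path: str | Path, pixel_size: float) -> Micrograph:
    """Read a TIFF/PNG micrograph; RGB is converted by luminance."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 3:  # RGB(A) -> luminance
        data = data[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if data.max() > 1.0:
        data = data / 255.0
    return Micrograph(data, pixel_size, source_id=path.name)


# ---------------------------------------------------------------------------
# Steps 1-4: binary mask, outline, skeleton, junction removal
# ---------------------------------------------------------------------------

def binarize(
    m: Micrograph, smoothing_sigma: float = 1.0, min_object_px: int = 64
) -> np.ndarray:
    """Smooth, Otsu-threshold (dark = foreground) and drop small components.

    Holes are deliberately *not* filled: the unstained lumina of empty hyphal
    ghosts must stay out of the stained-foreground fraction.  A constant
    image yields an empty mask with a warning.
    """
    if min_object_px < 0:
        raise ValueError("min_object_px must be >= 0")
    img = m.pixels
    if smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, smoothing_sigma)
    if np.ptp(img) == 0:
        warnings.warn("constant-intensity image: returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    threshold = filters.threshold_otsu(img)
    mask = img < threshold  # stained objects are dark
    if min_object_px > 0:
        # max_size semantics: components of <= max_size px are removed
        mask = morphology.remove_small_objects(
            mask, max_size=min_object_px - 1, connectivity=2
        )
    return mask


def outline(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 8-adjacent to background (image border counts as background)."""
    eroded = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3), dtype=bool), border_value=0
    )
    return mask & ~eroded


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """1-px-wide 8-connected medial skeleton preserving component topology."""
    return morphology.skeletonize(mask)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    return ndimage.convolve(
        skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant", cval=0
    )


def prune_intersections(skel: np.ndarray) -> np.ndarray:
    """Delete junction pixels (>= 3 skeleton neighbours) until only simple
    paths remain; isolated pixels are dropped as well."""
    out = skel.copy()
    while True:
        counts = _neighbor_counts(out)
        junctions = out & (counts >= 3)
        if not junctions.any():
            break
        out &= ~junctions
    out &= _neighbor_counts(out) >= 1  # drop isolated pixels
    return out


# ---------------------------------------------------------------------------
# Steps 5-6: fragmentation and orthogonal measurement
# ---------------------------------------------------------------------------

def _trace_paths(skel: np.ndarray) -> list[np.ndarray]:
    """Order the pixels of each connected component (simple path or cycle)."""
    pixels = {tuple(p) for p in np.argwhere(skel)}
    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for p in pixels:
        adjacency[p] = [
            (p[0] + dr, p[1] + dc)
            for dr, dc in _OFFSETS
            if (p[0] + dr, p[1] + dc) in pixels
        ]
    visited: set[tuple[int, int]] = set()
    paths: list[np.ndarray] = []
    # endpoints first so open paths are traced end-to-end; leftovers are cycles
    order = sorted(pixels, key=lambda p: (len(adjacency[p]) != 1, p))
    for start in order:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        current = start
        while True:
            nxt = [q for q in adjacency[current] if q not in visited]
            if not nxt:
                break
            current = nxt[0]
            path.append(current)
            visited.add(current)
        paths.append(np.array(path, dtype=int))
    return paths


def fragment_skeleton(skel: np.ndarray, fragment_len: int = 7) -> list[SkeletonFragment]:
    """Cut each simple path into consecutive fragments of ``fragment_len`` px.

    A terminal remainder of >= 3 px becomes its own fragment, a shorter one
    is merged into the previous fragment; paths shorter than 3 px yield no
    fragment.  Call after :func:`prune_intersections`.
    """
    if fragment_len < 3:
        raise ValueError("fragment_len must be >= 3")
    fragments: list[SkeletonFragment] = []
    fid = 0
    for path in _trace_paths(skel):
        L = len(path)
        if L < 3:
            continue
        n_full, rem = divmod(L, fragment_len)
        bounds = [i * fragment_len for i in range(n_full)]
        if n_full == 0:
            chunks = [path]
        else:
            chunks = [path[b : b + fragment_len] for b in bounds]
            if rem >= 3:
                chunks.append(path[n_full * fragment_len :])
            elif rem > 0:
                chunks[-1] = path[(n_full - 1) * fragment_len :]
        for chunk in chunks:
            if (chunk[0] == chunk[-1]).all():  # closed loop sub-path; skip
                continue
            fragments.append(SkeletonFragment(chunk, fid))
            fid += 1
    return fragments


def _ray_length(
    mask: np.ndarray,
    center: tuple[int, int],
    direction: np.ndarray,
    max_steps: int,
    step: float = 0.25,
) -> float | None:
    """Distance from center to the first background crossing along direction.

    Returns None when the ray leaves the image before reaching background or
    exceeds ``max_steps`` sub-pixel steps.
    """
    h, w = mask.shape
    r0, c0 = center
    for i in range(1, max_steps + 1):
        t = i * step
        r = int(round(r0 + t * direction[0]))
        c = int(round(c0 + t * direction[1]))
        if not (0 <= r < h and 0 <= c < w):
            return None
        if not mask[r, c]:
            return t
    return None


def measure_diameters(
    fragments: Iterable[SkeletonFragment],
    mask: np.ndarray,
    pixel_size: float,
    max_diameter: float = 10.0,
    source_id: str = "",
) -> list[DiameterSample]:
    """Orthogonal two-sided ray-cast diameters at each fragment center.

    From each center, rays are cast along ±(normal to the fragment
    orientation) in 0.25-px steps until the first background crossing;
    diameter = (d₊ + d₋)·pixel_size.  Samples are discarded when the center
    is off-foreground, a ray exits the image, or the diameter exceeds
    ``max_diameter`` (crossing/blob artifacts).
    """
    samples: list[DiameterSample] = []
    max_steps = int(np.ceil(max_diameter / pixel_size / 0.25)) + 4
    n_discarded = 0
    for frag in fragments:
        center = frag.center
        if not mask[center]:
            n_discarded += 1
            continue
        o = frag.orientation
        normal = np.array([-o[1], o[0]])
        d_plus = _ray_length(mask, center, normal, max_steps)
        d_minus = _ray_length(mask, center, -normal, max_steps)
        if d_plus is None or d_minus is None:
            n_discarded += 1
            continue
        diameter = (d_plus + d_minus) * pixel_size
        if diameter > max_diameter:
            n_discarded += 1
            continue
        samples.append(DiameterSample(diameter, center, frag.fragment_id, source_id))
    if n_discarded:
        logger.debug("measure_diameters: discarded %d fragments", n_discarded)
    return samples


def measure_micrograph(
    m: Micrograph, config: MorphometryConfig | None = None
) -> list[DiameterSample]:
    """Run the full per-image chain: binarize → skeletonize → prune →
    fragment → measure."""
    cfg = config or MorphometryConfig(pixel_size_um=m.pixel_size)
    mask = binarize(m, cfg.smoothing_sigma, cfg.min_object_px)
    skel = prune_intersections(skeletonize(mask))
    fragments = fragment_skeleton(skel, cfg.fragment_len)
    return measure_diameters(
        fragments, mask, m.pixel_size, cfg.max_diameter_um, source_id=m.source_id
    )


# ---------------------------------------------------------------------------
# Density summarization
# ---------------------------------------------------------------------------

def diameter_density(
    samples: Sequence[DiameterSample] | np.ndarray,
    bandwidth: float | None = None,
    grid_max: float = 6.0,
    split_threshold: float = 2.0,
    grid_points: int = 512,
) -> DiameterDistribution:
    """Gaussian kernel density of diameters on [0, grid_max] µm.

    ``bandwidth`` is in µm; None selects Silverman's rule.  The density is
    renormalized to integrate to 1 over the grid.  ``thin_fraction`` is the
    proportion of raw samples below ``split_threshold``.
    """
    if len(samples) and isinstance(samples[0], DiameterSample):
        d = np.array([s.diameter_um for s in samples])
    else:
        d = np.asarray(samples, dtype=float)
    if d.size < 2:
        raise ValueError(
            "need at least 2 diameter samples for a density estimate; "
            "pool more micrographs"
        )
    grid = np.linspace(0.0, grid_max, grid_points)
    sd = d.std(ddof=1)
    if sd == 0:  # degenerate: all samples identical; place one narrow kernel
        bw = bandwidth if bandwidth else max(1e-3, 0.01 * float(d.mean()))
        density = stats.norm.pdf(grid, loc=float(d[0]), scale=bw)
    else:
        if bandwidth is None:
            kde = stats.gaussian_kde(d, bw_method="silverman")
        else:
            if bandwidth <= 0:
                raise ValueError("bandwidth must be positive")
            kde = stats.gaussian_kde(d, bw_method=bandwidth / sd)
        bw = kde.factor * sd
        density = kde(grid)
    area = np.trapezoid(density, grid)
    if area <= 0:
        raise ValueError("density mass fell outside the grid; raise grid_max")
    density = density / area
    thin = float((d < split_threshold).mean())
    return DiameterDistribution(
        grid=grid,
        density=density,
        bandwidth=float(bw),
        n_samples=int(d.size),
        thin_fraction=thin,
        thick_fraction=1.0 - thin,
        split_threshold=split_threshold,
    )


def density_modes(dist: DiameterDistribution, min_height_frac: float = 0.05) -> np.ndarray:
    """Diameters (µm) of the local density maxima above a height floor."""
    peaks, _ = signal.find_peaks(
        dist.density, height=min_height_frac * dist.density.max()
    )
    return dist.grid[peaks]


# ---------------------------------------------------------------------------
# Batch processing and I/O
# ---------------------------------------------------------------------------

def process_micrograph_batch(
    paths: Sequence[str | Path] | Sequence[Micrograph],
    config: MorphometryConfig | None = None,
) -> tuple[list[DiameterSample], dict[str, int]]:
    """Measure a set of micrographs sharing one calibration and pool samples.

    Unreadable files are skipped with a logged error; if every file fails a
    ``RuntimeError`` is raised.  Returns (pooled samples, per-image counts).
    """
    cfg = config or MorphometryConfig()
    pooled: list[DiameterSample] = []
    counts: dict[str, int] = {}
    n_failed = 0
    for item in paths:
        try:
            m = (
                item
                if isinstance(item, Micrograph)
                else read_micrograph(item, cfg.pixel_size_um)
            )
            samples = measure_micrograph(m, cfg)
        except (OSError, ValueError) as exc:
            logger.error("skipping %s: %s", item, exc)
            n_failed += 1
            continue
        counts[m.source_id or str(item)] = len(samples)
        pooled.extend(samples)
        logger.info("%s: %d diameter samples", m.source_id, len(samples))
    if paths and n_failed == len(paths):
        raise RuntimeError("all micrographs failed to process")
    return pooled, counts


def samples_to_frame(samples: Sequence[DiameterSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (s.source_id, s.fragment_id, s.center[1], s.center[0], s.diameter_um)
            for s in samples
        ],
        columns=["source_id", "fragment_id", "x", "y", "diameter_um"],
    )


def write_samples(samples: Sequence[DiameterSample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> list[DiameterSample]:
    frame = pd.read_csv(path, sep="\t")
    return [
        DiameterSample(
            row.diameter_um, (int(row.y), int(row.x)), int(row.fragment_id),
            str(row.source_id),
        )
        for row in frame.itertuples()
    ]
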