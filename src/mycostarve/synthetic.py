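"""Ground-truthed synthetic inputs for every pipeline stage.

Three generator families emulate the structures of a submerged carbon-
starvation study without requiring any microscopy or array data:

* **Micrographs** — bright-field-like images of dispersed mycelium: dark
  ribbons of constant width along smoothly meandering random paths on a
  bright background (Lactophenol-blue-style dark-on-bright polarity), with
  true diameters drawn from one- or two-component normal mixtures (the thick
  ≈3 µm primary-growth and thin ≈1 µm secondary-growth populations).  A
  configurable fraction of tubes is rendered as empty "ghosts": two parallel
  1-px dark walls with an unstained lumen, contributing nothing to the truth
  mask — mimicking the cell-wall exoskeletons left behind by dying
  compartments.
* **Ontology DAGs and annotations** — single-rooted random ``is_a`` DAGs plus
  direct gene→term annotations with planted enriched terms at controlled
  study/background rates.
* **Expression matrices** — log-normal genes × samples matrices over the four
  cultivation phases (triplicate ``exp``, duplicate ``day1``/``day3``/``day6``)
  with planted fold changes and per-gene/group ground truth.

Every generator is a pure function of its arguments including ``seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

from .godag import AnnotationMap, GoDag
from .transcriptome import ExpressionMatrix, GROUPS

__all__ = [
    "TubeSpec",
    "SyntheticImageBundle",
    "SyntheticDagBundle",
    "SyntheticExpressionBundle",
    "generate_mycelium_image",
    "generate_go_dag",
    "generate_annotations",
    "generate_expression",
    "write_image",
    "write_truth_table",
]

#: rendering intensities before noise: bright background, dark stained objects
BACKGROUND_INTENSITY = 0.9
FOREGROUND_INTENSITY = 0.2


@dataclass
class TubeSpec:
    """Ground truth for one rendered hypha."""

    path: np.ndarray  # (n, 2) float array of (row, col) pixel coordinates
    true_diameter: float  # µm
    population_id: int
    ghost: bool = False

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.true_diameter <= 0:
            raise ValueError("true_diameter must be positive")
        if len(self.path) < 2:
            raise ValueError("tube path needs at least 2 points")


@dataclass
class SyntheticImageBundle:
    """A rendered micrograph with its per-tube ground truth."""

    image: np.ndarray  # float intensities in [0, 1]
    pixel_size: float  # µm per px
    tubes: list[TubeSpec]
    truth_mask: np.ndarray  # bool, stained foreground only (ghosts excluded)

    def __post_init__(self) -> None:
        if self.image.shape != self.truth_mask.shape:
            raise ValueError("image and truth_mask must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def stained_diameters(self) -> np.ndarray:
        return np.array([t.true_diameter for t in self.tubes if not t.ghost])


@dataclass
class SyntheticDagBundle:
    dag: GoDag
    annotations: AnnotationMap  # direct, unpropagated
    study_set: set[str]
    planted_terms: dict[str, tuple[float, float]]  # term -> (study, background) rate


@dataclass
class SyntheticExpressionBundle:
    matrix: ExpressionMatrix  # linear scale
    truth: pd.DataFrame  # genes × starvation groups, true linear fold change vs exp
    de_genes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Micrograph generation
# ---------------------------------------------------------------------------

def _random_path(
    rng: np.random.Generator,
    shape: tuple[int, int],
    margin: float,
    length_px: float,
    step_px: float = 1.0,
    angle_jitter: float = 0.03,
) -> np.ndarray:
    """Meandering path with bounded curvature, reflected off image borders."""
    h, w = shape
    r = rng.uniform(margin, h - margin)
    c = rng.uniform(margin, w - margin)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    n_steps = max(2, int(round(length_px / step_px)))
    pts = np.empty((n_steps, 2))
    pts[0] = (r, c)
    for i in range(1, n_steps):
        heading += rng.normal(0.0, angle_jitter)
        dr = step_px * math.sin(heading)
        dc = step_px * math.cos(heading)
        nr, nc = r + dr, c + dc
        if nr < margin or nr > h - margin:  # bounce off horizontal borders
            dr = -dr
            heading = math.atan2(dr, dc)
            nr = r + dr
        if nc < margin or nc > w - margin:
            dc = -dc
            heading = math.atan2(dr, dc)
            nc = c + dc
        r, c = nr, nc
        pts[i] = (r, c)
    return pts


def _tube_mask(path: np.ndarray, radius_px: float, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose center lies within radius_px of the continuous midline.

    The path is densified to < 0.25 px spacing and exact point distances are
    taken via a KD-tree, so the rendered ribbon has geometric width
    2·radius_px without rasterization widening.
    """
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    dense = [path[:1]]
    for i, L in enumerate(seg_len):
        n = max(1, int(math.ceil(L / 0.25)))
        steps = np.arange(1, n + 1)[:, None] / n
        dense.append(path[i] + seg[i] * steps)
    dense_arr = np.concatenate(dense)

    pad = int(math.ceil(radius_px)) + 2
    r0 = max(0, int(np.floor(dense_arr[:, 0].min())) - pad)
    r1 = min(shape[0], int(np.ceil(dense_arr[:, 0].max())) + pad + 1)
    c0 = max(0, int(np.floor(dense_arr[:, 1].min())) - pad)
    c1 = min(shape[1], int(np.ceil(dense_arr[:, 1].max())) + pad + 1)
    rows, cols = np.mgrid[r0:r1, c0:c1]
    centers = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    dist, _ = cKDTree(dense_arr).query(centers, k=1)
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = (dist <= radius_px).reshape(rows.shape)
    return mask


def generate_mycelium_image(
    n_tubes: int,
    populations: Sequence[tuple[float, float, float]] = ((3.0, 0.3, 0.5), (1.0, 0.15, 0.5)),
    empty_ghost_fraction: float = 0.0,
    pixel_size: float = 0.2,
    noise_sd: float = 0.05,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    tube_length_px: tuple[float, float] = (150.0, 300.0),
    angle_jitter: float = 0.03,
) -> SyntheticImageBundle:
    """Render a synthetic micrograph of dispersed stained mycelium.

    Tube diameters are drawn from the normal mixture given by
    ``populations`` (mean µm, sd µm, weight); a fraction
    ``empty_ghost_fraction`` of tubes is rendered outline-only (ghosts).
    Overlapping tubes union their masks, deliberately producing skeleton
    crossings downstream.  Gaussian noise of ``noise_sd`` is added and the
    image clipped to [0, 1].  Identical arguments (incl. seed) yield a
    bit-identical bundle.
    """
    weights = np.array([w for _, _, w in populations], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("population weights must sum to 1")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    for mean, sd, _ in populations:
        if mean <= 0 or sd <= 0:
            raise ValueError("population means and sds must be positive")
    if not 0.0 <= empty_ghost_fraction <= 1.0:
        raise ValueError("empty_ghost_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    max_radius_px = max(
        (mean + 4 * sd) / (2 * pixel_size) for mean, sd, _ in populations
    )
    margin = max_radius_px + 3
    if 2 * margin >= min(shape):
        raise ValueError("image too small to hold the widest tube")

    stained = np.zeros(shape, dtype=bool)
    walls = np.zeros(shape, dtype=bool)
    tubes: list[TubeSpec] = []
    for _ in range(n_tubes):
        pop = int(rng.choice(len(populations), p=weights))
        mean, sd, _ = populations[pop]
        diameter = float(rng.normal(mean, sd))
        while diameter <= 0:  # resample pathological tail draws
            diameter = float(rng.normal(mean, sd))
        ghost = bool(rng.random() < empty_ghost_fraction)
        length = float(rng.uniform(*tube_length_px))
        path = _random_path(rng, shape, margin, length, angle_jitter=angle_jitter)
        mask = _tube_mask(path, diameter / (2 * pixel_size), shape)
        if ghost:
            walls |= mask & ~ndimage.binary_erosion(mask, border_value=0)
        else:
            stained |= mask
        tubes.append(TubeSpec(path, diameter, pop, ghost))

    image = np.full(shape, BACKGROUND_INTENSITY)
    image[stained | walls] = FOREGROUND_INTENSITY
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)
    image = np.clip(image, 0.0, 1.0)
    return SyntheticImageBundle(image, pixel_size, tubes, stained)


def write_image(bundle: SyntheticImageBundle, path: str | Path) -> None:
    """Write the rendered image as 8-bit grayscale TIFF or PNG."""
    data = np.round(bundle.image * 255).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_truth_table(bundle: SyntheticImageBundle, path: str | Path) -> None:
    """Per-tube ground truth TSV (tube_id, population_id, true_diameter_um, ghost)."""
    rows = [
        (i, t.population_id, t.true_diameter, int(t.ghost))
        for i, t in enumerate(bundle.tubes)
    ]
    pd.DataFrame(
        rows, columns=["tube_id", "population_id", "true_diameter_um", "ghost"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ontology / annotation generation
# ---------------------------------------------------------------------------

def generate_go_dag(n_terms: int, max_parents: int = 3, seed: int = 0) -> GoDag:
    """Random single-rooted DAG: term i draws 1..max_parents parents among 0..i-1."""
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"T:{i:07d}" for i in range(n_terms)]
    terms = {tid: f"synthetic term {i}" for i, tid in enumerate(ids)}
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, max_parents + 1))
        chosen = rng.choice(i, size=min(k, i), replace=False)
        parents[ids[i]] = {ids[int(j)] for j in chosen}
    return GoDag(terms, parents)


def generate_annotations(
    dag: GoDag,
    n_genes: int,
    planted: Sequence[tuple[str, float, float]] = (),
    seed: int = 0,
    study_size: int | None = None,
    background_terms_per_gene: int = 3,
) -> tuple[AnnotationMap, set[str]]:
    """Direct (unpropagated) gene→term annotations with planted enrichment.

    ``planted`` lists (term, study_fraction, background_fraction): each study
    gene receives the term with probability study_fraction, each background
    gene with background_fraction.  Remaining annotations are uniform draws
    of ``background_terms_per_gene`` terms per gene.  Returns the map and the
    study gene set (default size: 10 % of genes).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    for term, sf, bf in planted:
        if term not in dag:
            raise KeyError(f"planted term {term!r} not in DAG")
        if not (0.0 <= sf <= 1.0 and 0.0 <= bf <= 1.0):
            raise ValueError("planted fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:06d}" for i in range(n_genes)]
    if study_size is None:
        study_size = max(1, n_genes // 10)
    study = set(rng.choice(genes, size=study_size, replace=False).tolist())
    all_terms = sorted(dag.terms)
    gene_to_terms: dict[str, set[str]] = {}
    for gene in genes:
        picks = rng.choice(len(all_terms), size=min(background_terms_per_gene, len(all_terms)), replace=False)
        terms = {all_terms[int(i)] for i in picks}
        for term, sf, bf in planted:
            rate = sf if gene in study else bf
            if rng.random() < rate:
                terms.add(term)
            else:
                terms.discard(term)
        gene_to_terms[gene] = terms
    return AnnotationMap(gene_to_terms, propagated=False), study


# ---------------------------------------------------------------------------
# Expression generation
# ---------------------------------------------------------------------------

def generate_expression(
    n_genes: int,
    replicates: Sequence[int] = (3, 2, 2, 2),
    de_fraction: float = 0.1,
    fc_range: tuple[float, float] = (2.0, 8.0),
    noise_sd: float = 0.3,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
) -> SyntheticExpressionBundle:
    """Log-normal expression with planted fold changes across the four phases.

    log2 expression = per-gene baseline + per-group effect + N(0, noise_sd²).
    A fraction ``de_fraction`` of genes is differentially expressed: in each
    starvation group they receive a log2 effect of ±log2(FC), FC drawn
    uniformly from ``fc_range`` and the sign drawn per gene and group.  The
    truth table records the linear fold change versus ``exp`` for every gene
    and starvation group (1.0 for non-DE genes).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if fc_range[0] < 1.0 or fc_range[1] < fc_range[0]:
        raise ValueError("fc_range must satisfy 1 <= min <= max")
    if len(replicates) != len(GROUPS):
        raise ValueError(f"replicates must give counts for {GROUPS}")
    if any(r < 2 for r in replicates):
        raise ValueError("need >= 2 replicates per group")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:06d}" for i in range(n_genes)]
    samples: list[str] = []
    group_of: dict[str, str] = {}
    for g, r in zip(GROUPS, replicates):
        for j in range(r):
            name = f"{g}_{j + 1}"
            samples.append(name)
            group_of[name] = g

    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    de_genes = {genes[int(i)] for i in de_idx}

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    effects = np.zeros((n_genes, len(GROUPS)))
    starvation_cols = [GROUPS.index(g) for g in GROUPS if g != "exp"]
    for i in de_idx:
        for col in starvation_cols:
            fc = rng.uniform(*fc_range)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effects[int(i), col] = sign * math.log2(fc)

    log2_values = np.empty((n_genes, len(samples)))
    for s_idx, s in enumerate(samples):
        col = GROUPS.index(group_of[s])
        log2_values[:, s_idx] = (
            baseline + effects[:, col] + rng.normal(0.0, noise_sd, size=n_genes)
        )
    values = pd.DataFrame(2.0 ** log2_values, index=genes, columns=samples)
    groups = pd.Series(group_of)
    truth = pd.DataFrame(
        2.0 ** effects[:, starvation_cols],
        index=genes,
        columns=[GROUPS[c] for c in starvation_cols],
    )
    matrix = ExpressionMatrix(values, groups, log2=False)
    return SyntheticExpressionBundle(matrix, truth, de_genes)
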