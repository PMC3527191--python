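"""End-to-end orchestration of the morphometry and transcriptome studies.

Two entry points mirror the study's analysis flows:

* :func:`run_morphometry_study` batch-measures one image set per cultivation
  time point and emits per-time-point diameter densities plus a long-format
  table suitable for overlaid density plotting.
* :func:`run_transcriptome_study` calls differential expression per
  starvation day, derives up/down gene lists, runs annotation enrichment per
  list and summarizes the three up (and three down) enriched-term sets into
  common most-specific terms.

Both return a :class:`RunReport` echoing the configuration and per-stage
summaries, and write their outputs as TSV/JSON into the configured directory.
"""

from __future__ import annotations

import configparser
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import godag, morphometry, transcriptome

__all__ = [
    "MorphometryStudyConfig",
    "TranscriptomeStudyConfig",
    "RunReport",
    "run_morphometry_study",
    "run_transcriptome_study",
    "read_config",
]

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Serializable per-run record: config echo, stage summaries, timings."""

    version: str
    config: dict
    stages: list[dict] = field(default_factory=list)
    error: str | None = None

    def add_stage(self, name: str, seconds: float, **summary) -> None:
        self.stages.append({"name": name, "seconds": round(seconds, 3), **summary})

    def payload(self) -> dict:
        """Report content without wall-clock timings (stable across reruns)."""
        return {
            "version": self.version,
            "config": self.config,
            "stages": [
                {k: v for k, v in s.items() if k != "seconds"} for s in self.stages
            ],
            "error": self.error,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


@dataclass
class MorphometryStudyConfig:
    """One image set per time point, shared stage parameters, output dir."""

    time_points: dict[str, list[str]]
    morphometry: morphometry.MorphometryConfig = field(
        default_factory=morphometry.MorphometryConfig
    )
    out_dir: str = "morphometry_out"

    def validate(self) -> None:
        if not self.time_points:
            raise ValueError("config lists no image sets")
        for name, paths in self.time_points.items():
            if not paths:
                raise ValueError(f"time point {name!r} lists no images")


@dataclass
class TranscriptomeStudyConfig:
    matrix_path: str
    groups_path: str
    annotations_path: str
    obo_path: str | None = None  # None = flat annotations, no propagation
    matrix_log2: bool = False
    baseline: str = "exp"
    q_de: float = 0.005
    q_enrich: float = 0.05
    propagate: bool = True
    include_self: bool = True
    out_dir: str = "transcriptome_out"

    def validate(self) -> None:
        for p in (self.matrix_path, self.groups_path, self.annotations_path):
            if not p:
                raise ValueError("matrix, groups and annotations paths are required")


def run_morphometry_study(config: MorphometryStudyConfig) -> RunReport:
    """Measure diameters per time point and write density/population outputs."""
    config.validate()
    report = RunReport(__version__, {"time_points": config.time_points,
                                     "morphometry": config.morphometry.to_dict(),
                                     "out_dir": config.out_dir})
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long_rows = []
    summary: dict[str, dict] = {}
    for name, paths in config.time_points.items():
        t0 = time.perf_counter()
        samples, counts = morphometry.process_micrograph_batch(
            paths, config.morphometry
        )
        dist = morphometry.diameter_density(
            samples,
            bandwidth=config.morphometry.kde_bandwidth_um,
            grid_max=config.morphometry.grid_max_um,
            split_threshold=config.morphometry.split_threshold_um,
        )
        morphometry.write_samples(samples, out_dir / f"samples_{name}.tsv")
        for g, dens in zip(dist.grid, dist.density):
            long_rows.append((name, g, dens))
        summary[name] = {
            "n_samples": dist.n_samples,
            "mean_um": float(pd.Series([s.diameter_um for s in samples]).mean()),
            "thin_fraction": dist.thin_fraction,
            "thick_fraction": dist.thick_fraction,
            "per_image_counts": counts,
        }
        report.add_stage(f"measure[{name}]", time.perf_counter() - t0, **summary[name])
    pd.DataFrame(long_rows, columns=["time_point", "diameter_um", "density"]).to_csv(
        out_dir / "density.tsv", sep="\t", index=False
    )
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    report.save(out_dir / "run_report.json")
    return report


def run_transcriptome_study(config: TranscriptomeStudyConfig) -> RunReport:
    """DE per day → gene lists → enrichment → common most-specific terms."""
    config.validate()
    report = RunReport(__version__, asdict(config))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    matrix = transcriptome.read_expression(
        config.matrix_path, config.groups_path, log2=config.matrix_log2
    )
    annotations = godag.read_annotations(config.annotations_path)
    dag = None
    if config.obo_path:
        dag = godag.parse_obo(config.obo_path)
        if config.propagate:
            annotations = godag.propagate_annotations(dag, annotations)
    report.add_stage(
        "load", time.perf_counter() - t0,
        n_genes=len(matrix.values), n_samples=matrix.values.shape[1],
        n_annotated=len(annotations.gene_to_terms),
    )

    population = set(matrix.values.index)
    days = [g for g in transcriptome.STARVATION_GROUPS
            if (matrix.groups == g).any()]
    calls: dict[str, pd.Series] = {}
    gene_lists: dict[tuple[str, str], set[str]] = {}
    for day in days:
        t0 = time.perf_counter()
        result = transcriptome.de_contrast(
            matrix, day, baseline=config.baseline, q_crit=config.q_de
        )
        result.to_csv(out_dir / f"de_{day}.tsv", sep="\t")
        calls[day] = result["call"]
        for direction in ("up", "down"):
            gene_lists[(day, direction)] = set(result.index[result["call"] == direction])
        report.add_stage(
            f"de[{day}]", time.perf_counter() - t0,
            n_up=len(gene_lists[(day, "up")]), n_down=len(gene_lists[(day, "down")]),
        )

    if len(days) == 3:
        venn = transcriptome.venn_counts(*(calls[d] for d in days))
        with open(out_dir / "venn.json", "w") as fh:
            json.dump(venn.to_dict(), fh, indent=2)
        report.add_stage("venn", 0.0, **{
            "conjoint_up": venn.conjoint_up, "conjoint_down": venn.conjoint_down,
            "n_de_any": venn.n_de_any, "frac_de_any": venn.frac_de_any,
        })

    enriched_sets: dict[str, list[set[str]]] = {"up": [], "down": []}
    for (day, direction), genes in gene_lists.items():
        t0 = time.perf_counter()
        result = godag.enrich(genes, population, annotations, q_crit=config.q_enrich)
        if dag is not None and len(result):
            result.insert(1, "name", result["term"].map(dag.terms))
        result.to_csv(out_dir / f"enrichment_{direction}_{day}.tsv", sep="\t",
                      index=False)
        terms = set(result.loc[result["enriched"], "term"])
        enriched_sets[direction].append(terms)
        report.add_stage(f"enrich[{direction}_{day}]", time.perf_counter() - t0,
                         n_genes=len(genes), n_enriched_terms=len(terms))

    common_summary = {}
    if dag is not None:
        for direction, sets in enriched_sets.items():
            if len(sets) != 3:
                continue
            t0 = time.perf_counter()
            if all(not s for s in sets):
                result = godag.CommonSpecificResult(set(), set(), {})
            else:
                result = godag.common_most_specific(
                    dag, sets, include_self=config.include_self
                )
            rows = [
                (t, dag.terms[t], "common",
                 ";".join(f"{c}@{d}" for c, d in sorted(result.provenance.get(t, []))))
                for t in sorted(result.common)
            ] + [(t, dag.terms[t], "non_common", "") for t in sorted(result.non_common)]
            pd.DataFrame(
                rows, columns=["term", "name", "status", "provenance"]
            ).to_csv(out_dir / f"common_terms_{direction}.tsv", sep="\t", index=False)
            common_summary[direction] = {
                "common": sorted(result.common),
                "non_common": sorted(result.non_common),
            }
            report.add_stage(f"common[{direction}]", time.perf_counter() - t0,
                             n_common=len(result.common),
                             n_non_common=len(result.non_common))
    with open(out_dir / "common_summary.json", "w") as fh:
        json.dump(common_summary, fh, indent=2)
    report.save(out_dir / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# Configuration files
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"morphometry", "transcriptome", "image", "dag", "annotations",
                   "expression", "run"}


def read_config(path: str | Path) -> dict[str, dict[str, str]]:
    """Flat INI-style config: one [stage] section per module, key = value."""
    parser = configparser.ConfigParser()
    read = parser.read(path)
    if not read:
        raise FileNotFoundError(path)
    out: dict[str, dict[str, str]] = {}
    for section in parser.sections():
        if section not in _KNOWN_SECTIONS:
            raise ValueError(f"unknown config section [{section}]")
        out[section] = dict(parser.items(section))
    return out
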