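"""Differential-expression calling for the four-phase starvation design.

Expression matrices (genes × samples) carry sample→group labels over the four
cultivation phases ``exp`` (exponential growth), ``day1``, ``day3`` and
``day6`` (16, 60 and 140 h post carbon depletion).  Each starvation group is
contrasted independently against ``exp`` with an empirical-Bayes moderated
t-test: per-gene pooled two-sample variances are shrunk toward a prior
variance s0² with d0 prior degrees of freedom, both estimated by closed-form
moment matching on the log residual variances, and the moderated statistic is
referred to a t distribution with d0 + d_g degrees of freedom.  Calls are
made at a Benjamini–Hochberg FDR threshold with no minimal fold-change
criterion; fold changes are reported separately as ratios of arithmetic
linear-scale group means, and conjoint (all-three-time-point) behaviour is
summarized as three-set Venn region counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .godag import bh_adjust

__all__ = [
    "GROUPS",
    "STARVATION_GROUPS",
    "ExpressionMatrix",
    "ModeratedFit",
    "VennCounts",
    "filter_rows",
    "collapse_multiprobe",
    "scale_to_reference",
    "fold_changes",
    "moderated_t_fit",
    "call_de",
    "de_contrast",
    "venn_counts",
    "read_expression",
    "write_expression",
]

logger = logging.getLogger(__name__)

GROUPS = ("exp", "day1", "day3", "day6")
STARVATION_GROUPS = ("day1", "day3", "day6")


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values plus sample→group labels.

    ``log2`` flags the scale of ``values``; linear-scale values must be
    strictly positive so the two scales are interconvertible.
    """

    values: pd.DataFrame
    groups: pd.Series
    log2: bool = False

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        unlabeled = set(self.values.columns) - set(self.groups.index)
        if unlabeled:
            raise ValueError(f"samples without group label: {sorted(unlabeled)}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if not self.log2 and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale expression values must be positive")

    def to_log2(self) -> "ExpressionMatrix":
        if self.log2:
            return self
        return ExpressionMatrix(np.log2(self.values), self.groups, log2=True)

    def to_linear(self) -> "ExpressionMatrix":
        if not self.log2:
            return self
        return ExpressionMatrix(2.0 ** self.values, self.groups, log2=False)

    def samples_in(self, group: str) -> list[str]:
        hits = [s for s in self.values.columns if self.groups[s] == group]
        if not hits:
            raise ValueError(f"no samples labeled {group!r}")
        return hits


# ---------------------------------------------------------------------------
# Matrix preparation
# ---------------------------------------------------------------------------

def filter_rows(matrix: ExpressionMatrix, exclude_ids: Iterable[str]) -> ExpressionMatrix:
    """Drop listed row ids (control probes, genetic elements); warn on absent ids."""
    exclude = set(exclude_ids)
    present = exclude & set(matrix.values.index)
    absent = exclude - present
    if absent:
        logger.warning("%d exclude ids not present in matrix", len(absent))
    logger.info("filter_rows: removing %d of %d rows", len(present), len(matrix.values))
    return ExpressionMatrix(
        matrix.values.drop(index=list(present)), matrix.groups, matrix.log2
    )


def collapse_multiprobe(
    matrix: ExpressionMatrix, probe_to_transcript: Mapping[str, str]
) -> ExpressionMatrix:
    """Average multi-probe transcripts (arithmetic mean on the current scale)."""
    missing = [p for p in matrix.values.index if p not in probe_to_transcript]
    if missing:
        raise KeyError(f"probes absent from the probe→transcript map: {missing[:5]}")
    transcript = pd.Index([probe_to_transcript[p] for p in matrix.values.index])
    collapsed = matrix.values.groupby(transcript, sort=False).mean()
    return ExpressionMatrix(collapsed, matrix.groups, matrix.log2)


def scale_to_reference(
    matrix: ExpressionMatrix, reference_gene: str, reference_group: str = "exp"
) -> ExpressionMatrix:
    """Express linear values as percent of a reference gene's group mean.

    All values are multiplied by ``100 / mean(reference_gene over
    reference_group samples)``, so the reference gene's mean in the reference
    group becomes exactly 100 — the convention used to report expression
    relative to the actin level during exponential growth.
    """
    linear = matrix.to_linear()
    if reference_gene not in linear.values.index:
        raise KeyError(f"reference gene {reference_gene!r} not in matrix")
    ref_mean = linear.values.loc[reference_gene, linear.samples_in(reference_group)].mean()
    if ref_mean == 0:
        raise ValueError("reference gene mean is zero in the reference group")
    return ExpressionMatrix(linear.values * (100.0 / ref_mean), linear.groups, log2=False)


def fold_changes(
    matrix: ExpressionMatrix,
    baseline_group: str = "exp",
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene fold change of each group's linear mean over the baseline mean."""
    linear = matrix.to_linear()
    baseline = linear.values[linear.samples_in(baseline_group)].mean(axis=1)
    if (baseline == 0).any():
        raise ValueError("zero baseline mean encountered")
    if groups is None:
        groups = [g for g in pd.unique(linear.groups) if g != baseline_group]
    out = {}
    for g in groups:
        out[g] = linear.values[linear.samples_in(g)].mean(axis=1) / baseline
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Moderated t-test (empirical Bayes shrinkage of variances)
# ---------------------------------------------------------------------------

@dataclass
class ModeratedFit:
    """Variance-shrinkage hyperparameters and per-gene posterior variances.

    s̃_g² = (d0·s0² + d_g·s_g²) / (d0 + d_g); with d0 = inf all posterior
    variances equal s0², with d0 = 0 no shrinkage occurs.
    """

    s2: np.ndarray
    df: float
    prior_df: float
    prior_var: float
    post_var: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if math.isinf(self.prior_df):
            self.post_var = np.full_like(self.s2, self.prior_var)
        elif self.prior_df == 0:
            self.post_var = self.s2.copy()
        else:
            self.post_var = (self.prior_df * self.prior_var + self.df * self.s2) / (
                self.prior_df + self.df
            )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of (prior_df d0, prior_var s0²).

    Matches mean and variance of log s_g² against the scaled-F model: with
    z_g = log s_g² and e_g = z_g − ψ(d_g/2) + log(d_g/2),
    ψ'(d0/2) = var(e) − ψ'(d_g/2) and s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)).
    If the moment equation has no positive solution the variances are
    effectively equal and d0 = inf (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(np.sum((e - e_mean) ** 2) / (e.size - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0 = math.exp(e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        # variances indistinguishable: complete shrinkage toward the plain mean
        d0 = math.inf
        s0 = float(s2[ok].mean())
    return d0, s0


def moderated_t_fit(
    matrix: ExpressionMatrix,
    group: str,
    baseline: str = "exp",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test of *group* versus *baseline* (log2 scale).

    Per gene: pooled variance s_g² with d_g = n1 + n0 − 2 df; hyperparameters
    (d0, s0²) estimated by :func:`fit_variance_prior` unless ``prior_df``
    forces d0 (0 recovers the ordinary pooled t, ``inf`` full shrinkage);
    t̃_g = Δmean / sqrt(s̃_g²·(1/n1 + 1/n0)); two-sided p from t with
    d0 + d_g df (normal when d0 = inf).

    Returns a DataFrame (index = genes) with columns ``mean_log2_diff``,
    ``t`` and ``p``; the :class:`ModeratedFit` is attached as
    ``result.attrs["fit"]``.  q-values are added downstream by
    :func:`call_de` via the shared BH adjustment.
    """
    log2m = matrix.to_log2()
    s1 = log2m.samples_in(group)
    s0 = log2m.samples_in(baseline)
    n1, n0 = len(s1), len(s0)
    if n1 < 2 or n0 < 2:
        raise ValueError("need >= 2 samples in each contrasted group")
    x1 = log2m.values[s1].to_numpy(float)
    x0 = log2m.values[s0].to_numpy(float)
    if not (np.isfinite(x1).all() and np.isfinite(x0).all()):
        raise ValueError("expression values must be finite")
    diff = x1.mean(axis=1) - x0.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x0 - x0.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df_resid = float(n1 + n0 - 2)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    s2 = ss / df_resid

    if prior_df is None:
        d0, s0_var = fit_variance_prior(s2, df_resid)
    elif prior_df == 0:
        d0, s0_var = 0.0, float("nan")
    else:
        d0 = float(prior_df)
        _, s0_var = fit_variance_prior(s2, df_resid)
    fit = ModeratedFit(s2=s2, df=df_resid, prior_df=d0, prior_var=s0_var)

    se = np.sqrt(fit.post_var * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # cap the moderated df at the summed residual df over all genes: even
    # complete shrinkage cannot gain more information than the data contain
    df_total = min(d0 + df_resid, s2.size * df_resid)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    result = pd.DataFrame(
        {"mean_log2_diff": diff, "t": t, "p": p}, index=log2m.values.index
    )
    result.attrs["fit"] = fit
    result.attrs["contrast"] = (group, baseline)
    return result


def call_de(result: pd.DataFrame, q_crit: float = 0.005) -> pd.DataFrame:
    """Add BH q-values and up/down/ns calls (strict q < q_crit, no FC filter)."""
    out = result.copy()
    out["q"] = bh_adjust(out["p"].to_numpy())
    call = np.where(
        (out["q"] < q_crit) & (out["mean_log2_diff"] > 0),
        "up",
        np.where((out["q"] < q_crit) & (out["mean_log2_diff"] < 0), "down", "ns"),
    )
    out["call"] = call
    out.attrs = dict(result.attrs)
    out.attrs["q_crit"] = q_crit
    return out


def de_contrast(
    matrix: ExpressionMatrix,
    group: str,
    baseline: str = "exp",
    q_crit: float = 0.005,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Full per-gene contrast table: moderated t, q, call and linear fold change."""
    result = call_de(moderated_t_fit(matrix, group, baseline, prior_df), q_crit)
    fc = fold_changes(matrix, baseline_group=baseline, groups=[group])[group]
    result.insert(1, "fold_change", fc)
    return result


# ---------------------------------------------------------------------------
# Venn logic
# ---------------------------------------------------------------------------

_REGIONS = ("100", "010", "001", "110", "101", "011", "111")


@dataclass
class VennCounts:
    """Three-set Venn region counts of day1/day3/day6 DE calls.

    Region keys are membership masks over (day1, day3, day6); e.g. ``"101"``
    counts genes called in day1 and day6 but not day3.  ``conjoint_up`` /
    ``conjoint_down`` are the triple intersections; ``n_de_any`` counts genes
    differentially expressed (either direction) at >= 1 time point and
    ``frac_de_any`` is its share of the gene universe.
    """

    up: dict[str, int]
    down: dict[str, int]
    conjoint_up: int
    conjoint_down: int
    n_de_any: int
    n_genes: int
    frac_de_any: float

    def to_dict(self) -> dict:
        return {
            "up": self.up,
            "down": self.down,
            "conjoint_up": self.conjoint_up,
            "conjoint_down": self.conjoint_down,
            "n_de_any": self.n_de_any,
            "n_genes": self.n_genes,
            "frac_de_any": self.frac_de_any,
        }


def _region_counts(sets: Sequence[set[str]]) -> dict[str, int]:
    a, b, c = sets
    universe = a | b | c
    counts = {r: 0 for r in _REGIONS}
    for gene in universe:
        key = f"{int(gene in a)}{int(gene in b)}{int(gene in c)}"
        counts[key] += 1
    return counts


def venn_counts(
    calls_day1: pd.Series, calls_day3: pd.Series, calls_day6: pd.Series
) -> VennCounts:
    """Region counts of the three per-day call vectors (values up/down/ns)."""
    idx = calls_day1.index
    if not (idx.equals(calls_day3.index) and idx.equals(calls_day6.index)):
        raise ValueError("call vectors must share one gene universe")
    calls = (calls_day1, calls_day3, calls_day6)
    up_sets = [set(c.index[c == "up"]) for c in calls]
    down_sets = [set(c.index[c == "down"]) for c in calls]
    up = _region_counts(up_sets)
    down = _region_counts(down_sets)
    de_any = set().union(*up_sets, *down_sets)
    return VennCounts(
        up=up,
        down=down,
        conjoint_up=up["111"],
        conjoint_down=down["111"],
        n_de_any=len(de_any),
        n_genes=len(idx),
        frac_de_any=len(de_any) / len(idx) if len(idx) else float("nan"),
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_expression(
    matrix_path: str | Path, groups_path: str | Path, log2: bool = False
) -> ExpressionMatrix:
    """Read a genes×samples TSV plus a two-column sample<TAB>group sidecar."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    groups = pd.read_csv(
        groups_path, sep="\t", index_col=0, header=None, names=["sample", "group"]
    )["group"]
    return ExpressionMatrix(values, groups, log2=log2)


def write_expression(
    matrix: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path
) -> None:
    matrix.values.to_csv(matrix_path, sep="\t")
    matrix.groups.to_csv(groups_path, sep="\t", header=False)
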