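"""Translation-table comparison via loess residuals and Kruskal-Wallis tests.

Genomes reassigning TGA to tryptophan (NCBI table 4) are compared with
standard-code (table 11) genomes on off-frame stop codon density.  Because
table 4 genomes are strongly AT-rich, raw densities are confounded by GC
content: a single loess curve of density against genome GC is fitted on the
pooled cohort (both groups), and the groups are compared on their residuals
with a tie-corrected Kruskal-Wallis rank test.

The loess here is the classic locally weighted regression: for each point,
a tricube-weighted polynomial of local degree 2 is fitted over the span
fraction of nearest neighbours (span 0.75 by default, no robustness
iterations).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequence import GenomeRecord, osc_density


def fit_loess(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Loess fit evaluated at every observation; returns (fitted, residuals).

    Tricube kernel over the ``span`` fraction of nearest neighbours, local
    polynomial of ``degree``.  Raises when the span gives too few local
    points for the polynomial.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"span {span} gives only {k} local points for a degree-{degree} fit "
            f"on n={n} genomes; increase the span or pool more genomes"
        )
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        neighbours = np.argpartition(d, k - 1)[:k]
        dmax = d[neighbours].max()
        if dmax == 0:  # all local x identical: weighted mean
            fitted[i] = y[neighbours].mean()
            continue
        w = (1 - (d[neighbours] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        # centred Vandermonde keeps the intercept as the fitted value
        dx = x[neighbours] - x[i]
        design = np.vander(dx, degree + 1, increasing=True)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[neighbours] * sw, rcond=None)
        fitted[i] = coef[0]
    return fitted, y - fitted


@dataclass
class GroupTestResult:
    statistic: float
    p: float
    group_means: dict[str, float]


def residual_group_test(
    residuals: Sequence[float], labels: Sequence[str]
) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis on residual ranks, with group means."""
    residuals = np.asarray(residuals, dtype=np.float64)
    labels = np.asarray(labels)
    groups = {}
    for g in np.unique(labels):
        vals = residuals[labels == g]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 genomes")
        groups[str(g)] = vals
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*groups.values())
    return GroupTestResult(
        statistic=float(stat),
        p=float(p),
        group_means={g: float(v.mean()) for g, v in groups.items()},
    )


@dataclass
class ResidualComparison:
    """Pooled loess fit plus group test for one codon set and frame."""

    codon_set: str
    frame: str
    per_genome: pd.DataFrame  # genome_id, group, gc, density, fitted, residual
    kw_statistic: float
    p: float
    group_mean_residuals: dict[str, float]


def compare_density_groups(
    gc: Sequence[float],
    density: Sequence[float],
    labels: Sequence[str],
    genome_ids: Sequence[str] | None = None,
    codon_set_label: str = "stops",
    frame_label: str = "both",
    span: float = 0.75,
) -> ResidualComparison:
    """Loess-detrend pooled densities by GC, then Kruskal-Wallis on residuals.

    The pooled fit includes every genome from both groups; labels enter only
    at the test stage.
    """
    gc = np.asarray(gc, dtype=np.float64)
    density = np.asarray(density, dtype=np.float64)
    labels = list(labels)
    if genome_ids is None:
        genome_ids = [f"g{i}" for i in range(len(gc))]
    if len(gc) < 10:
        raise ValueError("need at least 10 genomes pooled across groups")
    fitted, resid = fit_loess(gc, density, span=span)
    test = residual_group_test(resid, labels)
    per_genome = pd.DataFrame(
        {
            "genome_id": list(genome_ids),
            "group": labels,
            "gc": gc,
            "density": density,
            "fitted": fitted,
            "residual": resid,
        }
    )
    return ResidualComparison(
        codon_set=codon_set_label,
        frame=frame_label,
        per_genome=per_genome,
        kw_statistic=test.statistic,
        p=test.p,
        group_mean_residuals=test.group_means,
    )


def compare_codes(
    cohort_11: Sequence[GenomeRecord],
    cohort_4: Sequence[GenomeRecord],
    codon_set: Iterable[str],
    frames: Iterable = ("+1", "+2"),
    span: float = 0.75,
    codon_set_label: str | None = None,
) -> ResidualComparison:
    """Compare table-11 and table-4 genome cohorts on one codon set / frame.

    Densities are computed identically for both cohorts; the GC covariate is
    whole-CDS GC content.
    """
    frames = tuple(frames)
    codon_set = frozenset(codon_set)
    genomes = list(cohort_11) + list(cohort_4)
    labels = ["table11"] * len(cohort_11) + ["table4"] * len(cohort_4)
    gc = [g.gc for g in genomes]
    dens = [osc_density(g, codon_set, frames) for g in genomes]
    label = codon_set_label or "+".join(sorted(codon_set))
    frame_label = "both" if set(frames) >= {"+1", "+2"} or set(frames) >= {1, 2} else str(frames[0])
    return compare_density_groups(
        gc,
        dens,
        labels,
        genome_ids=[g.genome_id for g in genomes],
        codon_set_label=label,
        frame_label=frame_label,
        span=span,
    )
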