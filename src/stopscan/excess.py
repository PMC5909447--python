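"""Z-score excess statistics, BH-FDR, cohort summaries and GC correlations.

A genome's excess of a codon set in a frame is the standard Z score of its
real off-frame density against the replicate null distribution:
``z = (real - mean(sims)) / sd(sims)`` (n-1 denominator).  Two-tailed p
values come from the normal approximation; significance of a positive
excess additionally requires z > 0, after Benjamini-Hochberg correction
across genomes within one (codon set, frame, model) family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .null_models import SimulationEnsemble


@dataclass
class ExcessResult:
    """Per (genome, codon set, frame, null model) excess statistics."""

    genome_id: str
    model: str
    codon_set: str
    frame: str
    real_density: float
    sim_mean: float
    sim_sd: float
    z: float  # NaN when the replicate sd is zero (undefined flag)
    p: float
    q: float = np.nan

    @property
    def z_defined(self) -> bool:
        return np.isfinite(self.z)


def z_score(real: float, sims: Sequence[float]) -> float:
    """Standard Z of ``real`` against the simulated distribution.

    Returns NaN (the undefined flag) when the simulated sd is zero rather
    than an infinite score.
    """
    sims = np.asarray(sims, dtype=np.float64)
    if sims.size < 2:
        raise ValueError("z_score needs at least 2 simulated values")
    sd = sims.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((real - sims.mean()) / sd)


def p_from_z(z: float) -> float:
    """Two-tailed standard-normal p value, ``2 * Phi(-|z|)``."""
    if not np.isfinite(z):
        return float("nan")
    return float(2.0 * stats.norm.sf(abs(z)))


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, in input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return np.array([])
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ensembles_to_results(ensembles: Iterable[SimulationEnsemble]) -> list[ExcessResult]:
    """Compute Z and p for every tracked (codon set, frame) of each ensemble."""
    out = []
    for ens in ensembles:
        for label, frame in ens.keys():
            sims = ens.sims[(label, frame)]
            real = ens.real[(label, frame)]
            z = z_score(real, sims)
            out.append(
                ExcessResult(
                    genome_id=ens.genome_id,
                    model=ens.model,
                    codon_set=label,
                    frame=frame,
                    real_density=real,
                    sim_mean=float(sims.mean()),
                    sim_sd=float(sims.std(ddof=1)),
                    z=z,
                    p=p_from_z(z),
                )
            )
    return out


def apply_fdr(results: Sequence[ExcessResult]) -> list[ExcessResult]:
    """Fill ``q`` by BH correction across genomes within each
    (codon set, frame, model) family; undefined-z rows keep q = NaN."""
    by_family: dict[tuple, list[ExcessResult]] = {}
    for r in results:
        by_family.setdefault((r.codon_set, r.frame, r.model), []).append(r)
    for fam in by_family.values():
        defined = [r for r in fam if np.isfinite(r.p)]
        if defined:
            qs = bh_fdr([r.p for r in defined])
            for r, q in zip(defined, qs):
                r.q = float(q)
    return list(results)


def summarize_excess(
    results: Sequence[ExcessResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Count genomes with significant positive (z > 0, q < alpha) and
    negative (z < 0, q < alpha) excesses per (codon set, frame, model)."""
    results = apply_fdr(list(results))
    rows = []
    by_family: dict[tuple, list[ExcessResult]] = {}
    for r in results:
        by_family.setdefault((r.codon_set, r.frame, r.model), []).append(r)
    for (codon_set, frame, model), fam in sorted(by_family.items()):
        n = len(fam)
        pos = sum(1 for r in fam if r.z_defined and r.z > 0 and r.q < alpha)
        neg = sum(1 for r in fam if r.z_defined and r.z < 0 and r.q < alpha)
        rows.append(
            {
                "codon_set": codon_set,
                "frame": frame,
                "model": model,
                "n_genomes": n,
                "n_excess": pos,
                "pct_excess": 100.0 * pos / n,
                "n_negative_excess": neg,
                "pct_negative_excess": 100.0 * neg / n,
            }
        )
    return pd.DataFrame(rows)


def excess_gc_correlation(
    results: Sequence[ExcessResult], gc_by_genome: Mapping[str, float]
) -> tuple[float, float]:
    """Tie-aware Spearman correlation of genome Z scores against GC content.

    All results must belong to one (codon set, frame, model) family.
    Returns (rho, p); (NaN, NaN) for a constant input vector.
    """
    keys = {(r.codon_set, r.frame, r.model) for r in results}
    if len(keys) > 1:
        raise ValueError("results span multiple families; correlate one at a time")
    pairs = [
        (r.z, gc_by_genome[r.genome_id]) for r in results if np.isfinite(r.z)
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 genomes with finite z")
    z, gc = zip(*pairs)
    if len(set(z)) == 1 or len(set(gc)) == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(gc, z)
    return float(rho), float(p)


def rank_restrict(
    results: Sequence[ExcessResult], top_n: int
) -> list[ExcessResult]:
    """The ``top_n`` genomes by descending Z (ties broken by genome_id).

    All results must share one (codon set, frame, model) key; if ``top_n``
    exceeds the available genomes, all are returned with a warning.
    """
    keys = {(r.codon_set, r.frame, r.model) for r in results}
    if len(keys) > 1:
        raise ValueError("results span multiple (codon_set, frame, model) keys")
    if top_n > len(results):
        warnings.warn(
            f"top_n={top_n} exceeds the {len(results)} available genomes",
            stacklevel=2,
        )
    ranked = sorted(results, key=lambda r: (-r.z if np.isfinite(r.z) else np.inf, r.genome_id))
    return ranked[: min(top_n, len(ranked))]


def results_to_frame(results: Sequence[ExcessResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in results],
            "model": [r.model for r in results],
            "codon_set": [r.codon_set for r in results],
            "frame": [r.frame for r in results],
            "real_density": [r.real_density for r in results],
            "sim_mean": [r.sim_mean for r in results],
            "sim_sd": [r.sim_sd for r in results],
            "z": [r.z for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )
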