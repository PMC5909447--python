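"""Codon Adaptation Index as an expression proxy, with a half-split protocol.

CAI (Sharp & Li) is the geometric mean of per-codon relative adaptiveness
``w`` against a highly expressed reference set — here ribosomal-protein
genes (rplA-rplF, rplI-rplU, rpsB-rpsU).  Within each amino acid,
``w(codon) = reference frequency / max synonymous reference frequency``;
single-synonym amino acids and stops are excluded from the mean.

To keep the expression proxy independent of the density measurement, each
CDS is split: the first 30 nt are removed (5' ends are biased for ribosome
binding), CAI is computed on the first half of the remainder, and off-frame
densities on the untouched second half of the full CDS.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genetics import CODON_INDEX, TranslationTable
from .sequence import CodingSequence, GenomeRecord, codon_set_indices
from typing import Iterable

#: ribosomal-protein reference gene patterns: rplA-F, rplI-U, rpsB-U
_REFERENCE_RE = re.compile(r"^(rpl[a-fi-u]|rps[b-u])$", re.IGNORECASE)

W_FLOOR = 0.01  # relative adaptiveness floor for reference-absent codons


def select_reference_set(genome: GenomeRecord) -> list[CodingSequence]:
    """CDSs whose gene name matches the ribosomal-protein reference ranges."""
    hits = [
        cds
        for cds in genome.cds_list
        if cds.gene is not None and _REFERENCE_RE.match(cds.gene.strip())
    ]
    if not hits:
        raise ValueError(
            f"{genome.genome_id}: no ribosomal-protein reference genes found; "
            "supply an explicit reference CDS list"
        )
    if len(hits) < 20:
        warnings.warn(
            f"{genome.genome_id}: only {len(hits)} reference genes found "
            "(20 expected)",
            stacklevel=2,
        )
    return hits


@dataclass
class SplitHalves:
    """The two disjoint measurement regions of one CDS."""

    cds_id: str
    cai_half: str  # first half of (CDS minus first 30 nt), whole codons
    density_half: str  # second half of the full CDS, codon aligned


def trim_and_split(cds: CodingSequence) -> SplitHalves | None:
    """Split a CDS into its disjoint CAI half and density half.

    The CAI half is the first half of the CDS minus the first 30 nt
    (codons 11 to floor(n/2)); the density half is the second half of the
    full CDS (codons floor(n/2)+1 to n).  The halves never overlap, so the
    expression proxy and the density never resample the same sequence.
    CDSs of fewer than 22 codons leave no CAI codons and are excluded
    (returns None).
    """
    n = cds.n_codons
    half = n // 2
    if half <= 10:
        return None
    half_start = 3 * half
    return SplitHalves(
        cds.cds_id, cds.sequence[30:half_start], cds.sequence[half_start:]
    )


@dataclass
class RelativeAdaptiveness:
    """Per-codon relative adaptiveness ``w`` in (0, 1] for one genome."""

    table: TranslationTable
    w: dict[str, float]  # sense codon -> w
    reference_ids: tuple[str, ...] = ()


def compute_w(
    reference_halves: Iterable[str],
    table: TranslationTable,
    reference_ids: Iterable[str] = (),
) -> RelativeAdaptiveness:
    """Relative adaptiveness from codon counts over the reference CAI halves.

    Within each amino acid w = count / max synonymous count, floored at
    0.01 for reference-absent codons; amino acids entirely absent from the
    reference are uninformative and get w = 1 for every synonym.
    """
    counts = np.zeros(64, dtype=np.int64)
    n_seqs = 0
    for half in reference_halves:
        seq = CodingSequence("ref", half)
        counts += np.bincount(seq.codon_idx, minlength=64)
        n_seqs += 1
    if n_seqs == 0:
        raise ValueError("reference set is empty")
    w: dict[str, float] = {}
    for aa, codons in table.synonyms.items():
        c = np.array([counts[CODON_INDEX[x]] for x in codons], dtype=np.float64)
        if c.max() == 0:
            for codon in codons:
                w[codon] = 1.0
            continue
        rel = c / c.max()
        for codon, val in zip(codons, rel):
            w[codon] = float(max(val, W_FLOOR))
    return RelativeAdaptiveness(table, w, tuple(reference_ids))


def cai(sequence_half: str, adaptiveness: RelativeAdaptiveness) -> float:
    """Geometric mean of w over the codons of a CAI half.

    Stops and single-synonym amino acids (Met; Trp under table 11) are
    excluded from the mean, per the standard CAI definition.
    """
    table = adaptiveness.table
    single = table.single_synonym_aas()
    seq = CodingSequence("cai", sequence_half)
    logs = []
    for codon in seq.codons:
        aa = table.codon_to_aa[codon]
        if aa == "*" or aa in single:
            continue
        logs.append(np.log(adaptiveness.w[codon]))
    if not logs:
        raise ValueError("no informative codons in the CAI half")
    return float(np.exp(np.mean(logs)))


def half_density(
    density_half: str, codon_set: Iterable[str], frames: Iterable = ("+1", "+2")
) -> float:
    """Off-frame density of ``codon_set`` within the density half, per 100
    codons of the half (same scan contract as whole CDSs)."""
    from .sequence import scan_offframe_codons, _normalize_frames

    seq = CodingSequence("half", density_half)
    counts = scan_offframe_codons(seq)
    idx = codon_set_indices(codon_set)
    numer = 0
    for f in _normalize_frames(frames):
        numer += int(counts.frame(f)[idx].sum())
    return 100.0 * numer / seq.n_codons


def genome_cai_table(
    genome: GenomeRecord,
    codon_set: Iterable[str] = ("TAA", "TAG", "TGA"),
    frames: Iterable = ("+1", "+2"),
    reference: list[CodingSequence] | None = None,
):
    """Per-CDS CAI (first-half) and off-frame density (second-half) table."""
    import pandas as pd

    if reference is None:
        reference = select_reference_set(genome)
    ref_halves = []
    ref_ids = []
    for cds in reference:
        split = trim_and_split(cds)
        if split is not None:
            ref_halves.append(split.cai_half)
            ref_ids.append(cds.cds_id)
    adapt = compute_w(ref_halves, genome.table, ref_ids)
    rows = []
    codon_set = frozenset(codon_set)
    for cds in genome.cds_list:
        split = trim_and_split(cds)
        if split is None:
            continue
        rows.append(
            {
                "genome_id": genome.genome_id,
                "cds_id": cds.cds_id,
                "cai": cai(split.cai_half, adapt),
                "second_half_density": half_density(split.density_half, codon_set, frames),
            }
        )
    return pd.DataFrame(rows)


def cai_density_association(
    genome: GenomeRecord,
    codon_set: Iterable[str] = ("TAA", "TAG", "TGA"),
    frames: Iterable = ("+1", "+2"),
    reference: list[CodingSequence] | None = None,
) -> tuple[float, float]:
    """Tie-aware Spearman of per-CDS CAI against second-half density.

    Returns (rho, p); (NaN, NaN) when either vector is constant.
    """
    tab = genome_cai_table(genome, codon_set, frames, reference)
    if len(tab) < 10:
        raise ValueError("need at least 10 CDSs with both measurements")
    if tab["cai"].nunique() == 1 or tab["second_half_density"].nunique() == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(tab["cai"], tab["second_half_density"])
    return float(rho), float(p)
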