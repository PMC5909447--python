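"""Amino-acid-repeat codon-usage test for off-frame stop selection.

In a repeat of two identical amino acids followed by a codon starting with
a pyrimidine (Y = C or T), only the first codon's synonymous (third) site
can complete an off-frame stop: isoleucine repeats (ATH|ATH|YNN) can encode
+1 TAA through an A at site 3, valine repeats (GTN|GTN|YNN) +1 TAG, while
the identical second codon strictly cannot (its site-6 A faces a Y).  If
off-frame stops are selected for, A use should be higher at site 3 than at
site 6.  The A/T-ending restriction limits both repeat codons to A/T-ending
synonyms, controlling the GC3 difference between the compared sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .genetics import CODONS, NT_INDEX, TranslationTable
from .sequence import CodingSequence, GenomeRecord


@dataclass(frozen=True)
class DicodonConfig:
    """One repeat-context test: which amino acid, which target stop, and
    whether codons are restricted to A/T-ending synonyms."""

    amino_acid: str  # one-letter code of the repeated amino acid
    target: str  # descriptive label, e.g. "+1 TAA"
    restricted: bool = False
    follower_first: frozenset = frozenset({"C", "T"})
    site_nucleotide: str = "A"

    def allowed_codon_ids(self, table: TranslationTable) -> np.ndarray:
        codons = table.synonyms.get(self.amino_acid)
        if not codons:
            raise ValueError(f"{self.amino_acid!r} has no codons under table {table.table_id}")
        if self.restricted:
            codons = tuple(c for c in codons if c[2] in "AT")
        return np.array([CODONS.index(c) for c in codons], dtype=np.int64)

    @property
    def label(self) -> str:
        suffix = " (A/T-ending)" if self.restricted else ""
        return f"{self.amino_acid}-repeat {self.target}{suffix}"


def ile_taa(restricted: bool = False) -> DicodonConfig:
    """Isoleucine repeats probing +1 TAA (ATH|ATH|YNN)."""
    return DicodonConfig("I", "+1 TAA", restricted=restricted)


def val_tag(restricted: bool = False) -> DicodonConfig:
    """Valine repeats probing +1 TAG (GTN|GTN|YNN)."""
    return DicodonConfig("V", "+1 TAG", restricted=restricted)


@dataclass
class DicodonContextResult:
    """Per-genome pooled site-3 / site-6 nucleotide usage."""

    genome_id: str
    config_label: str
    n_contexts: int
    a3: float  # proportion of contexts with the target nucleotide at site 3
    a6: float
    log_ratio: float  # NaN when either proportion is zero (undefined flag)
    gc3: float


def find_contexts(
    cds: CodingSequence, config: DicodonConfig, table: TranslationTable
) -> list[tuple[str, str]]:
    """Emit (site-3, site-6) nucleotides of every qualifying codon triple.

    Codons i and i+1 must both encode the configured amino acid (restricted
    to A/T-ending synonyms when the flag is set) and codon i+2 must start
    with a follower-class nucleotide.  Overlapping repeats all qualify.
    """
    cod = cds.codon_idx
    if len(cod) < 3:
        return []
    allowed = np.zeros(64, dtype=bool)
    allowed[config.allowed_codon_ids(table)] = True
    member = allowed[cod]
    follower = np.zeros(4, dtype=bool)
    for c in config.follower_first:
        follower[NT_INDEX[c]] = True
    follower_ok = follower[cod >> 4]
    hits = np.where(member[:-2] & member[1:-1] & follower_ok[2:])[0]
    third = "ACGT"
    return [(third[cod[i] & 3], third[cod[i + 1] & 3]) for i in hits]


def genome_site_usage(
    genome: GenomeRecord, config: DicodonConfig
) -> DicodonContextResult:
    """Pool qualifying contexts over all CDSs of one genome.

    A genome with zero contexts is flagged (n_contexts = 0, proportions NaN)
    and excluded listwise from the paired tests.
    """
    n = 0
    hit3 = 0
    hit6 = 0
    target = config.site_nucleotide
    for cds in genome.cds_list:
        for s3, s6 in find_contexts(cds, config, genome.table):
            n += 1
            hit3 += s3 == target
            hit6 += s6 == target
    if n == 0:
        return DicodonContextResult(
            genome.genome_id, config.label, 0, float("nan"), float("nan"),
            float("nan"), genome.gc3,
        )
    a3 = hit3 / n
    a6 = hit6 / n
    log_ratio = math.log(a3 / a6) if a3 > 0 and a6 > 0 else float("nan")
    return DicodonContextResult(genome.genome_id, config.label, n, a3, a6, log_ratio, genome.gc3)


@dataclass
class PairedTestResult:
    statistic: float
    p: float
    mean_a3: float
    mean_a6: float
    n_a3_greater: int
    n_genomes: int


def paired_context_test(cohort: Sequence[DicodonContextResult]) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test of A3 - A6 across genomes.

    Zero differences are dropped (Wilcoxon convention); genomes without
    contexts are excluded listwise.
    """
    usable = [r for r in cohort if r.n_contexts > 0]
    if len(usable) < 6:
        raise ValueError("paired test needs at least 6 genomes with contexts")
    a3 = np.array([r.a3 for r in usable])
    a6 = np.array([r.a6 for r in usable])
    diffs = a3 - a6
    nz = diffs[diffs != 0]
    if nz.size == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(nz, alternative="two-sided")
    return PairedTestResult(
        statistic=float(stat),
        p=float(p),
        mean_a3=float(a3.mean()),
        mean_a6=float(a6.mean()),
        n_a3_greater=int((a3 > a6).sum()),
        n_genomes=len(usable),
    )


def usage_gc3_correlation(
    cohort: Sequence[DicodonContextResult],
) -> tuple[float, float]:
    """Tie-aware Spearman of log(A3/A6) against genome GC3.

    Genomes with an undefined log-ratio are dropped; returns (NaN, NaN) for
    constant inputs.
    """
    pairs = [(r.log_ratio, r.gc3) for r in cohort if np.isfinite(r.log_ratio)]
    if len(pairs) < 3:
        raise ValueError("need at least 3 genomes with a defined log-ratio")
    lr, gc3 = zip(*pairs)
    if len(set(lr)) == 1 or len(set(gc3)) == 1:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(gc3, lr)
    return float(rho), float(p)
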