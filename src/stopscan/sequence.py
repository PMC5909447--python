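"""CDS data model, filtering, off-frame codon scanning and OSC densities.

An out-of-frame stop codon (OSC) is a stop trinucleotide read in the +1 or
+2 frame of a CDS, spanning two in-frame codons.  Frames follow the
convention that +1 codons start at 1-based nucleotide positions 2, 5, 8, ...
and +2 codons at positions 3, 6, 9, ...; a CDS of n codons yields exactly
n - 1 complete off-frame codons in each frame.  Densities are reported per
100 in-frame codons, with the start and terminal stop codon included both in
the scan and in the denominator (applied identically to real and simulated
sequences, so excess statistics are unaffected by the convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .genetics import CODON_INDEX, CODONS, TranslationTable, str_to_nt_idx

# rejection reason codes, in the order the rules are checked
REASON_LENGTH = "length"
REASON_ALPHABET = "alphabet"
REASON_INTERNAL_STOP = "internal_stop"
REASON_INVALID_STOP = "invalid_stop"

_FRAME_ALIASES = {"+1": 1, "+2": 2, 1: 1, 2: 2}


def _normalize_frames(frames: Iterable) -> tuple[int, ...]:
    out = []
    for f in frames:
        if f not in _FRAME_ALIASES:
            raise ValueError(f"unknown frame {f!r}; use '+1' or '+2'")
        out.append(_FRAME_ALIASES[f])
    if not out:
        raise ValueError("at least one frame required")
    return tuple(dict.fromkeys(out))


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the four-rule CDS filter; rejection is a value, not an error."""

    accepted: bool
    reason: str | None = None


def filter_cds(raw_sequence: str, table: TranslationTable) -> FilterDecision:
    """Apply the four CDS integrity rules and report the first failure.

    Rules, in order: length is a multiple of three; alphabet is exactly
    {A, C, G, T}; no internal codon is a stop under ``table``; the terminal
    codon is in ``table``'s stop set.
    """
    if not raw_sequence:
        raise ValueError("raw_sequence must be nonempty")
    if len(raw_sequence) % 3 != 0:
        return FilterDecision(False, REASON_LENGTH)
    nt = str_to_nt_idx(raw_sequence)
    if (nt == 255).any():
        return FilterDecision(False, REASON_ALPHABET)
    cod = _codon_idx_from_nt(nt)
    stops = table.stop_mask[cod]
    if stops[:-1].any():
        return FilterDecision(False, REASON_INTERNAL_STOP)
    if not stops[-1]:
        return FilterDecision(False, REASON_INVALID_STOP)
    return FilterDecision(True, None)


def _codon_idx_from_nt(nt: np.ndarray) -> np.ndarray:
    c = nt.astype(np.int16).reshape(-1, 3)
    return c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]


class CodingSequence:
    """One CDS: nucleotide string plus derived codon arrays.

    Construction validates length and alphabet only; stop-codon conformance
    is the filter's concern (see :func:`filter_cds`).
    """

    __slots__ = ("cds_id", "sequence", "gene", "nt_idx", "codon_idx")

    def __init__(self, cds_id: str, sequence: str, gene: str | None = None):
        if len(sequence) == 0 or len(sequence) % 3 != 0:
            raise ValueError(f"{cds_id}: length must be a nonzero multiple of 3")
        nt = str_to_nt_idx(sequence)
        if (nt == 255).any():
            raise ValueError(f"{cds_id}: sequence contains non-ACGT characters")
        self.cds_id = cds_id
        self.sequence = sequence
        self.gene = gene
        self.nt_idx = nt.astype(np.int8)
        self.codon_idx = _codon_idx_from_nt(nt)

    @property
    def n_codons(self) -> int:
        return len(self.codon_idx)

    @property
    def codons(self) -> list[str]:
        """Ordered in-frame codons; concatenating them reproduces ``sequence``."""
        return [CODONS[i] for i in self.codon_idx]

    def __len__(self) -> int:
        return len(self.sequence)

    def __repr__(self) -> str:  # pragma: no cover
        return f"CodingSequence({self.cds_id!r}, {self.n_codons} codons)"


@dataclass
class FrameCodonCounts:
    """Counts of complete off-frame codons for one CDS, per frame."""

    plus1: np.ndarray  # (64,) counts
    plus2: np.ndarray  # (64,) counts
    total_inframe_codons: int

    def frame(self, frame) -> np.ndarray:
        return self.plus1 if _FRAME_ALIASES[frame] == 1 else self.plus2

    def count(self, frame, codon: str) -> int:
        return int(self.frame(frame)[CODON_INDEX[codon]])


def scan_offframe_codons(cds: CodingSequence) -> FrameCodonCounts:
    """Count every complete +1 and +2 frame codon inside the CDS.

    The scan covers the whole CDS including the start and terminal stop
    codons; each frame of an n-codon CDS yields exactly n - 1 codons.
    """
    if cds.n_codons < 2:
        raise ValueError("CDS must have at least 2 codons to scan off-frames")
    nt = cds.nt_idx.astype(np.int16)
    codes = nt[:-2] * 16 + nt[1:-1] * 4 + nt[2:]
    plus1 = np.bincount(codes[1::3], minlength=64)
    plus2 = np.bincount(codes[2::3], minlength=64)
    return FrameCodonCounts(plus1, plus2, cds.n_codons)


class GenomeRecord:
    """A genome's filtered CDS set plus composition metadata."""

    def __init__(
        self,
        genome_id: str,
        table: TranslationTable,
        cds_list: Sequence[CodingSequence],
        genus: str | None = None,
        genome_size_bp: int | None = None,
    ):
        if not cds_list:
            raise ValueError(f"{genome_id}: cds_list must be nonempty")
        self.genome_id = genome_id
        self.table = table
        self.cds_list = list(cds_list)
        self.genus = genus
        self.genome_size_bp = genome_size_bp
        self._cache: dict = {}

    @property
    def n_cds(self) -> int:
        return len(self.cds_list)

    @property
    def total_codons(self) -> int:
        return sum(c.n_codons for c in self.cds_list)

    @property
    def gc(self) -> float:
        return gc_metrics(self)[0]

    @property
    def gc3(self) -> float:
        return gc_metrics(self)[1]

    def frame_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Genome-wide (64,) off-frame codon counts for frames +1 and +2."""
        if "frame_counts" not in self._cache:
            c1 = np.zeros(64, dtype=np.int64)
            c2 = np.zeros(64, dtype=np.int64)
            for cds in self.cds_list:
                fc = scan_offframe_codons(cds)
                c1 += fc.plus1
                c2 += fc.plus2
            self._cache["frame_counts"] = (c1, c2)
        return self._cache["frame_counts"]

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenomeRecord({self.genome_id!r}, {self.n_cds} CDSs)"


def gc_metrics(genome: GenomeRecord) -> tuple[float, float]:
    """Return (GC, GC3) fractions over the genome's filtered CDSs."""
    if "gc_metrics" not in genome._cache:
        gc_count = 0
        gc3_count = 0
        total = 0
        codons = 0
        for cds in genome.cds_list:
            nt = cds.nt_idx
            gc_count += int(((nt == 1) | (nt == 2)).sum())
            third = nt[2::3]
            gc3_count += int(((third == 1) | (third == 2)).sum())
            total += len(nt)
            codons += cds.n_codons
        genome._cache["gc_metrics"] = (gc_count / total, gc3_count / codons)
    return genome._cache["gc_metrics"]


def codon_set_indices(codon_set: Iterable[str]) -> np.ndarray:
    idx = np.array(sorted(CODON_INDEX[c] for c in codon_set), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("codon_set must be nonempty")
    return idx


def osc_density(
    genome: GenomeRecord,
    codon_set: Iterable[str],
    frames: Iterable = ("+1", "+2"),
) -> float:
    """Off-frame density of ``codon_set`` per 100 in-frame codons.

    Both-frame density is the sum of the +1 and +2 numerators over the same
    denominator (total codons including start and stop).
    """
    idx = codon_set_indices(codon_set)
    which = _normalize_frames(frames)
    c1, c2 = genome.frame_counts()
    numer = 0
    if 1 in which:
        numer += int(c1[idx].sum())
    if 2 in which:
        numer += int(c2[idx].sum())
    return 100.0 * numer / genome.total_codons


def assemble_genome(
    genome_id: str,
    raw_records: Iterable[tuple[str, str] | tuple[str, str, str | None]],
    table: TranslationTable,
    genus: str | None = None,
    genome_size_bp: int | None = None,
) -> tuple[GenomeRecord | None, Counter]:
    """Filter raw CDS records and assemble a :class:`GenomeRecord`.

    ``raw_records`` yields ``(cds_id, sequence)`` or ``(cds_id, sequence,
    gene)``.  Returns the genome (``None`` if every CDS was rejected) and a
    Counter of rejection reasons plus the ``"accepted"`` count.
    """
    kept: list[CodingSequence] = []
    tally: Counter = Counter()
    for rec in raw_records:
        cds_id, seq = rec[0], rec[1]
        gene = rec[2] if len(rec) > 2 else None
        decision = filter_cds(seq, table)
        if decision.accepted:
            kept.append(CodingSequence(cds_id, seq, gene=gene))
            tally["accepted"] += 1
        else:
            tally[decision.reason] += 1
    if not kept:
        return None, tally
    return GenomeRecord(genome_id, table, kept, genus=genus, genome_size_bp=genome_size_bp), tally


def per_codon_score(
    genome: GenomeRecord,
    prob_by_codon: Mapping[str, float] | Callable[[str], float],
    aggregate: str = "median",
) -> float:
    """Aggregate a user-supplied per-codon score over a genome.

    Hook for external per-codon models (e.g. tRNA-informed frameshift
    probabilities): each CDS is scored by the mean of ``prob_by_codon``
    over its codons, and the per-CDS scores are combined by ``aggregate``
    ("median" or "mean").  The scoring model itself is supplied by the
    caller; this package does not implement one.
    """
    if callable(prob_by_codon):
        table = np.array([prob_by_codon(c) for c in CODONS], dtype=np.float64)
    else:
        table = np.array([prob_by_codon[c] for c in CODONS], dtype=np.float64)
    per_cds = [float(table[cds.codon_idx].mean()) for cds in genome.cds_list]
    if aggregate == "median":
        return float(np.median(per_cds))
    if aggregate == "mean":
        return float(np.mean(per_cds))
    raise ValueError("aggregate must be 'median' or 'mean'")


def dedupe_by_genus(genomes: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Keep the first genome per genus (genomes without genus always kept)."""
    seen: set[str] = set()
    out = []
    for g in genomes:
        if g.genus is None or g.genus not in seen:
            out.append(g)
            if g.genus is not None:
                seen.add(g.genus)
    return out


def apply_size_filter(
    genomes: Sequence[GenomeRecord], min_bp: int = 500_000
) -> list[GenomeRecord]:
    """Drop genomes smaller than ``min_bp`` where size metadata is present."""
    return [
        g for g in genomes if g.genome_size_bp is None or g.genome_size_bp >= min_bp
    ]
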