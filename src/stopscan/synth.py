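"""Synthetic bacterial genome cohorts for exercising the pipeline.

Genomes are built codon-by-codon: an amino-acid sequence is drawn i.i.d.
from a fixed bacterial-like composition, and each amino acid is encoded by
a synonym drawn i.i.d. from a genome-specific codon-usage table whose
third-site G+C matches a requested GC3 target.  Because internal codons are
exchangeable by construction, the unbiased generator is null-calibrated for
the shuffle and synonymous-resampling models.  Optional enrichment rewrites
synonymous choices to plant an off-frame stop signal of tunable strength,
giving the alternative hypothesis the excess statistics must recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genetics import CODON_INDEX, CODONS, NT_INDEX, TranslationTable, codons_to_str, get_table
from .null_models import CodonUsageTable
from .sequence import CodingSequence, GenomeRecord
from .dicodon import DicodonConfig

#: average bacterial protein composition (fractions, normalized at import)
AA_PROFILE: dict[str, float] = {
    "A": 0.089, "R": 0.055, "N": 0.041, "D": 0.054, "C": 0.011,
    "Q": 0.039, "E": 0.061, "G": 0.074, "H": 0.021, "I": 0.060,
    "L": 0.100, "K": 0.053, "M": 0.024, "F": 0.040, "P": 0.043,
    "S": 0.060, "T": 0.054, "W": 0.012, "Y": 0.029, "V": 0.070,
}
_total = sum(AA_PROFILE.values())
AA_PROFILE = {a: v / _total for a, v in AA_PROFILE.items()}

#: 20 ribosomal-protein gene names inside the CAI reference ranges
REFERENCE_GENE_NAMES = (
    "rplA", "rplB", "rplC", "rplD", "rplE", "rplF",
    "rplI", "rplJ", "rplK", "rplL", "rplM", "rplN",
    "rpsB", "rpsC", "rpsD", "rpsE", "rpsF", "rpsG", "rpsH", "rpsI",
)


def sample_codon_usage(
    gc3_target: float,
    concentration: float,
    rng: np.random.Generator,
    table: TranslationTable | None = None,
    aa_profile: dict[str, float] | None = None,
) -> CodonUsageTable:
    """Draw a per-amino-acid codon-usage table hitting a GC3 target.

    Per amino acid, synonym weights are drawn from a symmetric Dirichlet
    (``concentration`` per synonym: large = near uniform, small = spiky) and
    then exponentially tilted toward or away from G/C third sites so that
    the expected third-site G+C of a codon stream drawn under ``aa_profile``
    equals ``gc3_target``.  Infeasible targets (the code fixes some third
    sites, e.g. Met ATG) are clamped with a warning.
    """
    if not 0.0 < gc3_target < 1.0:
        raise ValueError("gc3_target must be in (0, 1)")
    table = table or get_table(11)
    profile = aa_profile or AA_PROFILE
    base: dict[str, np.ndarray] = {}
    gc3_ind: dict[str, np.ndarray] = {}
    for aa in table.aa_keys:
        syns = table.synonyms[aa]
        k = len(syns)
        base[aa] = rng.dirichlet(np.full(k, concentration)) if k > 1 else np.ones(1)
        gc3_ind[aa] = np.array([c[2] in "GC" for c in syns], dtype=np.float64)

    weights = {aa: profile.get(aa, 0.0) for aa in table.aa_keys}
    wsum = sum(weights.values())

    def tilted(eta: float) -> dict[str, np.ndarray]:
        out = {}
        for aa in table.aa_keys:
            v = base[aa] * np.exp(eta * gc3_ind[aa])
            out[aa] = v / v.sum()
        return out

    def expected(eta: float) -> float:
        probs = tilted(eta)
        return sum(
            weights[aa] / wsum * float(probs[aa] @ gc3_ind[aa])
            for aa in table.aa_keys
        )

    lo, hi = -60.0, 60.0
    e_lo, e_hi = expected(lo), expected(hi)
    if gc3_target <= e_lo:
        warnings.warn(
            f"gc3_target {gc3_target:.3f} below feasible minimum {e_lo:.3f}; clamped",
            stacklevel=2,
        )
        eta = lo
    elif gc3_target >= e_hi:
        warnings.warn(
            f"gc3_target {gc3_target:.3f} above feasible maximum {e_hi:.3f}; clamped",
            stacklevel=2,
        )
        eta = hi
    else:
        eta = brentq(lambda e: expected(e) - gc3_target, lo, hi, xtol=1e-10)
    return CodonUsageTable(table, tilted(eta))


def generate_genome(
    genome_id: str,
    rng: np.random.Generator,
    n_cds: int = 150,
    cds_length: tuple[int, int] = (60, 400),
    gc3_target: float = 0.5,
    concentration: float = 50.0,
    table: TranslationTable | None = None,
    aa_profile: dict[str, float] | None = None,
    genus: str | None = None,
    label_reference_genes: bool = False,
) -> GenomeRecord:
    """Generate one genome of filtered-CDS-conformant sequences.

    Every CDS is ATG + i.i.d. internal codons (drawn from a usage table
    conditional on a drawn amino-acid sequence, so in-frame stops cannot
    occur) + a terminal stop from the table's stop set; the output passes
    all four CDS filter rules by construction.
    """
    table = table or get_table(11)
    profile = aa_profile or AA_PROFILE
    usage = sample_codon_usage(gc3_target, concentration, rng, table, profile)

    lo, hi = cds_length
    lengths = rng.integers(lo, hi + 1, size=n_cds)
    n_internal = lengths - 2
    total = int(n_internal.sum())

    aa_keys = table.aa_keys
    aa_probs = np.array([profile.get(a, 0.0) for a in aa_keys], dtype=np.float64)
    aa_probs = aa_probs / aa_probs.sum()
    aa_cum = np.cumsum(aa_probs)
    aa_ids = np.searchsorted(aa_cum, rng.random(total), side="right")
    codons = usage._bank.sample(aa_ids, rng.random(total))

    stop_ids = np.array([CODON_INDEX[c] for c in sorted(table.stop_codons)])
    stops = stop_ids[rng.integers(0, len(stop_ids), size=n_cds)]
    start = CODON_INDEX["ATG"]

    cds_list = []
    offsets = np.concatenate(([0], np.cumsum(n_internal)))
    for i in range(n_cds):
        body = codons[offsets[i] : offsets[i + 1]]
        arr = np.concatenate(([start], body, [stops[i]]))
        gene = None
        if label_reference_genes and i < len(REFERENCE_GENE_NAMES):
            gene = REFERENCE_GENE_NAMES[i]
        cds_list.append(
            CodingSequence(f"{genome_id}_cds{i:05d}", codons_to_str(arr), gene=gene)
        )
    size = int(3 * (lengths.sum()))
    return GenomeRecord(genome_id, table, cds_list, genus=genus, genome_size_bp=size)


# ---------------------------------------------------------------------------
# planted signals


def _osc_replacement_table(
    table: TranslationTable, stop: str, frame: int
) -> np.ndarray:
    """Per-codon synonymous replacement that completes ``stop`` in ``frame``
    with a fixed downstream neighbour; -1 where no synonym can."""
    repl = np.full(64, -1, dtype=np.int64)
    for c in CODONS:
        aa = table.codon_to_aa[c]
        if aa == "*":
            continue
        syns = table.synonyms[aa]
        if frame == 1:  # window = codon nts 2,3 + next nt 1
            cands = [s for s in syns if s[1] == stop[0] and s[2] == stop[1]]
        else:  # frame 2: window = codon nt 3 + next nts 1,2
            cands = [s for s in syns if s[2] == stop[0]]
        if not cands:
            continue
        same_block = [s for s in cands if s[:2] == c[:2]]
        same_first = [s for s in cands if s[0] == c[0]]
        pick = (same_block or same_first or cands)[0]
        repl[CODON_INDEX[c]] = CODON_INDEX[pick]
    return repl


def inject_osc_bias(
    genome: GenomeRecord,
    stop: str = "TAA",
    frame=1,
    delta: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GenomeRecord:
    """Plant an off-frame stop enrichment of strength ``delta`` in [0, 1].

    One left-to-right pass: at every internal codon whose downstream
    neighbour (taken from the original sequence) completes the target stop
    and whose amino acid has an OSC-forming synonym, that synonym is adopted
    with probability ``delta``.  The amino-acid sequence is unchanged;
    delta = 0 is the identity in distribution, delta = 1 saturates every
    eligible site.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    frame = 1 if frame in (1, "+1") else 2
    table = genome.table
    repl = _osc_replacement_table(table, stop, frame)
    s = [NT_INDEX[c] for c in stop]

    new_cds = []
    for cds in genome.cds_list:
        orig = cds.codon_idx
        n = len(orig)
        if n < 3:
            new_cds.append(CodingSequence(cds.cds_id, cds.sequence, gene=cds.gene))
            continue
        cand = repl[orig]
        nxt = orig[1:]
        if frame == 1:
            next_ok = (nxt >> 4) == s[2]
        else:
            next_ok = ((nxt >> 4) == s[1]) & (((nxt >> 2) & 3) == s[2])
        elig = np.zeros(n, dtype=bool)
        elig[:-1] = next_ok & (cand[:-1] >= 0)
        elig[0] = False
        elig[-1] = False
        apply = elig & (rng.random(n) < delta)
        cod = orig.copy()
        cod[apply] = cand[apply]
        new_cds.append(CodingSequence(cds.cds_id, codons_to_str(cod), gene=cds.gene))
    return GenomeRecord(
        genome.genome_id, table, new_cds, genus=genome.genus,
        genome_size_bp=genome.genome_size_bp,
    )


def inject_dicodon_bias(
    genome: GenomeRecord,
    config: DicodonConfig,
    delta: float,
    rng: np.random.Generator | None = None,
) -> GenomeRecord:
    """Bias the third site of the first codon of qualifying repeats.

    At each qualifying context, the site-3 nucleotide is replaced by the
    config's target nucleotide with probability ``delta`` (a mixture of the
    base third-site distribution with a point mass), provided the swap is
    synonymous.  Site 6 is untouched.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    table = genome.table
    target_nt = NT_INDEX[config.site_nucleotide]

    allowed = np.zeros(64, dtype=bool)
    allowed[config.allowed_codon_ids(table)] = True
    follower = np.zeros(4, dtype=bool)
    for c in config.follower_first:
        follower[NT_INDEX[c]] = True

    new_cds = []
    for cds in genome.cds_list:
        cod = cds.codon_idx.copy()
        if len(cod) >= 3:
            member = allowed[cod]
            follower_ok = follower[cod >> 4]
            hits = np.where(member[:-2] & member[1:-1] & follower_ok[2:])[0]
            for i in hits:
                swapped = (cod[i] & ~np.int64(3)) | target_nt
                if table.aa_by_index[swapped] != table.aa_by_index[cod[i]]:
                    continue  # swap would not be synonymous
                if rng.random() < delta:
                    cod[i] = swapped
        new_cds.append(CodingSequence(cds.cds_id, codons_to_str(cod), gene=cds.gene))
    return GenomeRecord(
        genome.genome_id, table, new_cds, genus=genome.genus,
        genome_size_bp=genome.genome_size_bp,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class EnrichmentSpec:
    """Planted off-frame stop signal applied to every genome of a cohort."""

    stop: str = "TAA"
    frame: str = "+1"
    delta: float = 0.0


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    GC3 targets are evenly spaced across ``gc3`` so realized per-genome GC3
    is monotone in the request; ``table_id`` may be a scalar or one id per
    genome; ``delta = 0`` reduces exactly to the unbiased generator.
    """

    n_genomes: int = 50
    n_cds: tuple[int, int] = (100, 200)
    cds_length: tuple[int, int] = (60, 400)
    gc3: tuple[float, float] = (0.25, 0.75)
    table_id: int | Sequence[int] = 11
    concentration: float = 50.0
    enrichment: EnrichmentSpec | None = None
    label_reference_genes: bool = False
    seed: int | None = None

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for name, (lo, hi) in (("n_cds", self.n_cds), ("cds_length", self.cds_length)):
            if lo > hi or lo < 1:
                raise ValueError(f"{name} range {lo}..{hi} is empty or invalid")
        if not (0 < self.gc3[0] <= self.gc3[1] < 1):
            raise ValueError("gc3 range must lie inside (0, 1)")


def generate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Generate a cohort plus its truth table, reproducibly from the seed."""
    master = seed if seed is not None else spec.seed
    children = np.random.SeedSequence(master).spawn(spec.n_genomes)
    if spec.n_genomes == 1:
        gc3_targets = [0.5 * (spec.gc3[0] + spec.gc3[1])]
    else:
        gc3_targets = np.linspace(spec.gc3[0], spec.gc3[1], spec.n_genomes)
    if isinstance(spec.table_id, int):
        table_ids = [spec.table_id] * spec.n_genomes
    else:
        table_ids = list(spec.table_id)
        if len(table_ids) != spec.n_genomes:
            raise ValueError("table_id sequence length must equal n_genomes")

    genomes = []
    rows = []
    delta = spec.enrichment.delta if spec.enrichment else 0.0
    for i in range(spec.n_genomes):
        rng = np.random.default_rng(children[i])
        n_cds = int(rng.integers(spec.n_cds[0], spec.n_cds[1] + 1))
        g = generate_genome(
            f"synth{i:04d}",
            rng,
            n_cds=n_cds,
            cds_length=spec.cds_length,
            gc3_target=float(gc3_targets[i]),
            concentration=spec.concentration,
            table=get_table(table_ids[i]),
            genus=f"Genus{i:04d}",
            label_reference_genes=spec.label_reference_genes,
        )
        if spec.enrichment is not None and delta > 0:
            g = inject_osc_bias(
                g, spec.enrichment.stop, spec.enrichment.frame, delta, rng
            )
        genomes.append(g)
        rows.append(
            {
                "genome_id": g.genome_id,
                "table_id": table_ids[i],
                "gc3_target": float(gc3_targets[i]),
                "gc3_realized": g.gc3,
                "delta": delta,
                "n_cds": g.n_cds,
                "n_codons": g.total_codons,
            }
        )
    return genomes, pd.DataFrame(rows)
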