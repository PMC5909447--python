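"""Null-sequence simulators and the per-genome simulation ensemble driver.

Four null models generate sequences that preserve different features of the
real CDSs, each asking a different question of the observed off-frame stop
codon (OSC) densities:

``markov2`` / ``markov5``
    Codon-position-aware Markov chains trained on the genome's internal CDS
    nucleotides (start and stop codons discounted).  Preserve local
    nucleotide context statistics but not amino-acid or codon identity.
``shuffle``
    Internal codons of each CDS uniformly permuted; start and stop fixed.
    Preserves GC content and the exact codon multiset; destroys codon order.
``synsite``
    Each codon resampled within its coding block (same amino acid, same
    first two nucleotides) using genome-wide third-site frequencies.
    Preserves the amino-acid sequence and block membership per position.
``syncodon``
    Each codon resampled from the full synonym set of its amino acid with
    coding blocks pooled.  Preserves the amino-acid sequence only.

Every simulated genome is scored with the same density contract as the real
genome (per 100 codons, start/stop included); an ensemble of ``n_reps``
replicates (200 by default) supplies the null mean and standard deviation
behind the Z-score excess statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .genetics import (
    CODON_INDEX,
    CODONS,
    NT_OF_CODON,
    NTS,
    TranslationTable,
    codons_to_str,
)
from .sequence import CodingSequence, GenomeRecord, codon_set_indices

MODEL_KINDS = ("markov2", "markov5", "shuffle", "synsite", "syncodon")

#: the eight TAN/TGN codons analysed individually, plus the pooled stop set
TRACKED_CODONS = ("TAA", "TAG", "TGA", "TAC", "TAT", "TGC", "TGG", "TGT")

FRAMES = ("+1", "+2", "both")


def default_tracked_sets(table: TranslationTable) -> dict[str, frozenset[str]]:
    """Tracked codon sets: each TAN/TGN codon alone plus the table's stop set."""
    sets = {c: frozenset([c]) for c in TRACKED_CODONS}
    sets["stops"] = frozenset(table.stop_codons)
    return sets


# ---------------------------------------------------------------------------
# categorical sampling bank (shared by synsite / syncodon / generators)


class CategoricalBank:
    """Vectorized per-category categorical sampler over candidate codons."""

    def __init__(self, candidates: list[np.ndarray], probs: list[np.ndarray]):
        if len(candidates) != len(probs):
            raise ValueError("candidates and probs must align")
        kmax = max((len(c) for c in candidates), default=1)
        n = len(candidates)
        self.cand = np.zeros((n, kmax), dtype=np.int16)
        self.cum = np.ones((n, kmax), dtype=np.float64)
        for i, (c, p) in enumerate(zip(candidates, probs)):
            if len(c) == 0:
                raise ValueError(f"category {i} has no candidates")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"category {i} probabilities do not sum to 1")
            self.cand[i, : len(c)] = c
            self.cand[i, len(c) :] = c[-1]
            self.cum[i, : len(c)] = np.cumsum(p)
            self.cum[i, len(c) - 1 :] = 1.0

    def sample(self, cats: np.ndarray, u: np.ndarray) -> np.ndarray:
        idx = (u[:, None] > self.cum[cats]).sum(axis=1)
        return self.cand[cats, idx].astype(np.int64)


# ---------------------------------------------------------------------------
# synonymous-site and synonymous-codon usage tables


@dataclass
class SynonymousSiteTable:
    """Per coding-block third-site codon frequencies of one genome.

    6-fold amino acids are split into their 2-fold and 4-fold blocks and
    tabulated separately; 1-fold blocks have a single deterministic entry.
    """

    table: TranslationTable
    probs: dict[tuple[str, str], np.ndarray]  # block key -> probs over block codons
    _bank: CategoricalBank = field(init=False, repr=False)

    def __post_init__(self):
        cands, ps = [], []
        for key in self.table.block_keys:
            codons = self.table.blocks[key]
            p = self.probs[key]
            cands.append(np.array([CODON_INDEX[c] for c in codons], dtype=np.int64))
            ps.append(np.asarray(p, dtype=np.float64))
        self._bank = CategoricalBank(cands, ps)

    def sample_codons(self, codon_idx: np.ndarray, u: np.ndarray) -> np.ndarray:
        cats = self.table.block_index[codon_idx]
        if (cats < 0).any():
            raise ValueError("cannot resample a stop codon within a coding block")
        return self._bank.sample(cats, u)


@dataclass
class CodonUsageTable:
    """Per amino-acid synonym frequencies of one genome (blocks pooled)."""

    table: TranslationTable
    probs: dict[str, np.ndarray]  # amino acid -> probs over table.synonyms[aa]
    _bank: CategoricalBank = field(init=False, repr=False)

    def __post_init__(self):
        cands, ps = [], []
        for aa in self.table.aa_keys:
            codons = self.table.synonyms[aa]
            p = self.probs[aa]
            cands.append(np.array([CODON_INDEX[c] for c in codons], dtype=np.int64))
            ps.append(np.asarray(p, dtype=np.float64))
        self._bank = CategoricalBank(cands, ps)

    def sample_codons(self, codon_idx: np.ndarray, u: np.ndarray) -> np.ndarray:
        cats = self.table.aa_index[codon_idx]
        if (cats < 0).any():
            raise ValueError("cannot resample a stop codon as an amino acid")
        return self._bank.sample(cats, u)

    def expected_gc3(self, aa_weights: Mapping[str, float]) -> float:
        """Expected third-site G+C fraction of a codon stream drawn from this
        table with amino-acid frequencies ``aa_weights``."""
        total = sum(aa_weights.values())
        e = 0.0
        for aa, w in aa_weights.items():
            p = self.probs[aa]
            gc3 = np.array([c[2] in "GC" for c in self.table.synonyms[aa]], float)
            e += (w / total) * float(p @ gc3)
        return e


def _internal_codon_counts(genome: GenomeRecord) -> np.ndarray:
    counts = np.zeros(64, dtype=np.int64)
    for cds in genome.cds_list:
        counts += np.bincount(cds.codon_idx[1:-1], minlength=64)
    return counts


def build_synsite_table(genome: GenomeRecord) -> SynonymousSiteTable:
    """Third-site frequencies per coding block, from internal codons."""
    counts = _internal_codon_counts(genome)
    table = genome.table
    probs = {}
    for key, codons in table.blocks.items():
        c = np.array([counts[CODON_INDEX[x]] for x in codons], dtype=np.float64)
        if c.sum() == 0:
            c = np.ones_like(c)  # block absent from genome: uniform fallback
        probs[key] = c / c.sum()
    return SynonymousSiteTable(table, probs)


def build_codon_usage(genome: GenomeRecord) -> CodonUsageTable:
    """Synonym frequencies per amino acid (blocks pooled), from internal codons."""
    counts = _internal_codon_counts(genome)
    table = genome.table
    probs = {}
    for aa, codons in table.synonyms.items():
        c = np.array([counts[CODON_INDEX[x]] for x in codons], dtype=np.float64)
        if c.sum() == 0:
            c = np.ones_like(c)
        probs[aa] = c / c.sum()
    return CodonUsageTable(table, probs)


# ---------------------------------------------------------------------------
# single-CDS simulators


def shuffle_codons(cds: CodingSequence, rng: np.random.Generator) -> str:
    """Uniformly permute the internal codons; start and stop re-attached."""
    if cds.n_codons <= 3:
        return cds.sequence
    internal = cds.codon_idx[1:-1]
    perm = rng.permutation(len(internal))
    out = np.concatenate(([cds.codon_idx[0]], internal[perm], [cds.codon_idx[-1]]))
    return codons_to_str(out)


def simulate_cds_synsite(
    cds: CodingSequence, table: SynonymousSiteTable, rng: np.random.Generator
) -> str:
    """Resample each internal codon's synonymous site within its coding block."""
    return _resample_internal(cds, table, rng)


def simulate_cds_syncodon(
    cds: CodingSequence, usage: CodonUsageTable, rng: np.random.Generator
) -> str:
    """Resample each internal codon from its amino acid's full synonym set."""
    return _resample_internal(cds, usage, rng)


def _resample_internal(cds, sampler, rng) -> str:
    if cds.n_codons <= 2:
        return cds.sequence
    internal = cds.codon_idx[1:-1]
    u = rng.random(len(internal))
    new = sampler.sample_codons(internal, u)
    out = np.concatenate(([cds.codon_idx[0]], new, [cds.codon_idx[-1]]))
    return codons_to_str(out)


# ---------------------------------------------------------------------------
# Markov models


@dataclass
class MarkovModel:
    """Codon-position-aware Markov chain over internal CDS nucleotides.

    ``transitions[k][(context, pos)]`` is the probability vector over ACGT
    given the preceding ``k`` nucleotides ``context`` whose first nucleotide
    sits at codon position ``pos`` (0-based within its codon).  All orders
    1..order are tabulated so unseen full contexts back off to shorter ones,
    terminating at the codon-position-specific mononucleotide distribution.
    """

    order: int
    genome_id: str
    transitions: dict[int, dict[tuple[str, int], np.ndarray]]
    pos_mono: np.ndarray  # (3, 4) per-codon-position nucleotide distribution

    def lookup(self, context: str, pos_first: int) -> np.ndarray:
        """Distribution of the nucleotide following ``context``; with backoff."""
        n = len(context)
        for k in range(min(self.order, n), 0, -1):
            sub = context[n - k :]
            p = (pos_first + (n - k)) % 3
            probs = self.transitions[k].get((sub, p))
            if probs is not None:
                return probs
        return self.pos_mono[(pos_first + n) % 3]


def build_markov_model(genome: GenomeRecord, order: int) -> MarkovModel:
    """Train an ``order``-2 or -5 Markov model on internal CDS regions.

    Start and stop codons of each CDS are discounted; the window slides one
    nucleotide at a time; probabilities are count-normalized (maximum
    likelihood) and keyed by context string and codon position.
    """
    if order not in (2, 5):
        raise ValueError("order must be 2 or 5")
    counts: dict[int, dict[tuple[str, int], np.ndarray]] = {
        k: {} for k in range(1, order + 1)
    }
    mono = np.zeros((3, 4), dtype=np.float64)
    trained = False
    for cds in genome.cds_list:
        internal = cds.sequence[3:-3]
        if len(internal) <= order:
            continue
        trained = True
        nt_codes = [NTS.index(c) for c in internal]
        for j, code in enumerate(nt_codes):
            mono[j % 3, code] += 1
            for k in range(1, order + 1):
                if j >= k:
                    key = (internal[j - k : j], (j - k) % 3)
                    vec = counts[k].get(key)
                    if vec is None:
                        vec = np.zeros(4, dtype=np.float64)
                        counts[k][key] = vec
                    vec[code] += 1
    if not trained:
        raise ValueError(
            f"{genome.genome_id}: no internal CDS region longer than order {order}"
        )
    transitions = {
        k: {key: vec / vec.sum() for key, vec in d.items()} for k, d in counts.items()
    }
    row_sums = mono.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    return MarkovModel(order, genome.genome_id, transitions, mono / row_sums)


def simulate_cds_markov(
    cds: CodingSequence, model: MarkovModel, rng: np.random.Generator
) -> str:
    """Simulate one CDS: real start codon + ``order`` seed nucleotides, then
    nucleotide-by-nucleotide sampling until the real length minus the stop,
    which is appended verbatim.  Codon positions follow the simulated
    sequence's own frame."""
    internal_len = len(cds.sequence) - 6
    if internal_len <= model.order:
        return cds.sequence
    internal = cds.sequence[3:-3]
    out = list(internal[: model.order])
    us = rng.random(internal_len - model.order)
    for step in range(internal_len - model.order):
        j = model.order + step
        context = "".join(out[-model.order :])
        probs = model.lookup(context, (j - model.order) % 3)
        idx = int(np.searchsorted(np.cumsum(probs), us[step], side="right"))
        out.append(NTS[min(idx, 3)])
    return cds.sequence[:3] + "".join(out) + cds.sequence[-3:]


# ---------------------------------------------------------------------------
# genome-level replicate machinery


class _SimWorkspace:
    """Precomputed index arrays for fast whole-genome replicate scoring.

    CDS lengths are identical between the real genome and every simulated
    replicate, so window positions are computed once and only the nucleotide
    content changes per replicate.
    """

    def __init__(self, genome: GenomeRecord, codon_sets: Mapping[str, frozenset]):
        n_per = np.array([c.n_codons for c in genome.cds_list], dtype=np.int64)
        offsets = np.concatenate(([0], np.cumsum(n_per)))
        self.total_codons = int(offsets[-1])
        self.codon_concat = np.concatenate([c.codon_idx for c in genome.cds_list])

        internal = np.ones(self.total_codons, dtype=bool)
        internal[offsets[:-1]] = False
        internal[offsets[1:] - 1] = False
        self.internal_mask = internal
        self.internal_idx = np.where(internal)[0]
        self.seg_id = np.repeat(
            np.arange(len(n_per)), np.maximum(n_per - 2, 0)
        ).astype(np.float64)

        nonlast = np.ones(self.total_codons, dtype=bool)
        nonlast[offsets[1:] - 1] = False
        w = 3 * np.where(nonlast)[0]
        self.f1_idx = w + 1
        self.f2_idx = w + 2

        self.set_labels = list(codon_sets)
        self.set_indices = [codon_set_indices(codon_sets[s]) for s in self.set_labels]

    def nt_concat(self, codon_concat: np.ndarray) -> np.ndarray:
        return NT_OF_CODON[codon_concat].reshape(-1).astype(np.int16)

    def count_sets(self, codon_concat: np.ndarray) -> np.ndarray:
        """(n_sets, 2) counts of each tracked set in frames +1 and +2."""
        nt = self.nt_concat(codon_concat)
        out = np.empty((len(self.set_indices), 2), dtype=np.int64)
        for col, idx in enumerate((self.f1_idx, self.f2_idx)):
            codes = nt[idx] * 16 + nt[idx + 1] * 4 + nt[idx + 2]
            bc = np.bincount(codes, minlength=64)
            for row, s in enumerate(self.set_indices):
                out[row, col] = bc[s].sum()
        return out

    def counts_to_densities(self, counts: np.ndarray) -> np.ndarray:
        """(n_sets, 3) densities per 100 codons for +1, +2 and both frames."""
        dens = np.empty(counts.shape[:-1] + (3,), dtype=np.float64)
        dens[..., :2] = 100.0 * counts / self.total_codons
        dens[..., 2] = dens[..., 0] + dens[..., 1]
        return dens


@dataclass
class SimulationEnsemble:
    """Real and replicate densities for one (genome, model) pair."""

    genome_id: str
    model: str
    n_reps: int
    seed: int | None
    codon_sets: dict[str, frozenset]
    real: dict[tuple[str, str], float]  # (set label, frame) -> density
    sims: dict[tuple[str, str], np.ndarray]  # (set label, frame) -> (n_reps,)

    def sim_mean(self, label: str, frame: str) -> float:
        return float(self.sims[(label, frame)].mean())

    def sim_sd(self, label: str, frame: str) -> float:
        return float(self.sims[(label, frame)].std(ddof=1))

    def keys(self) -> list[tuple[str, str]]:
        return list(self.real)


def _replicate_codons(genome, ws, model_kind, sampler, rng) -> np.ndarray:
    """One simulated genome as a concatenated codon array."""
    if model_kind == "shuffle":
        new = ws.codon_concat.copy()
        if len(ws.internal_idx):
            keys = ws.seg_id + rng.random(len(ws.internal_idx))
            order = np.argsort(keys, kind="stable")
            new[ws.internal_idx] = ws.codon_concat[ws.internal_idx][order]
        return new
    if model_kind in ("synsite", "syncodon"):
        new = ws.codon_concat.copy()
        if len(ws.internal_idx):
            u = rng.random(len(ws.internal_idx))
            new[ws.internal_idx] = sampler.sample_codons(
                ws.codon_concat[ws.internal_idx], u
            )
        return new
    # markov2 / markov5: per-CDS sequential synthesis
    parts = [simulate_cds_markov(cds, sampler, rng) for cds in genome.cds_list]
    from .genetics import str_to_nt_idx

    nt = str_to_nt_idx("".join(parts)).astype(np.int16)
    cod = nt.reshape(-1, 3)
    return (cod[:, 0] * 16 + cod[:, 1] * 4 + cod[:, 2]).astype(np.int64)


def run_ensemble(
    genome: GenomeRecord,
    model_kind: str,
    n_reps: int = 200,
    seed: int | None = None,
    codon_sets: Mapping[str, frozenset] | None = None,
) -> SimulationEnsemble:
    """Simulate ``n_reps`` replicate genomes and record tracked densities.

    Every CDS is re-simulated independently in each replicate; one random
    stream per genome is split per replicate so results are reproducible
    from ``seed`` regardless of evaluation order.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    sets = dict(codon_sets) if codon_sets is not None else default_tracked_sets(genome.table)
    ws = _SimWorkspace(genome, sets)

    sampler = None
    if model_kind == "synsite":
        sampler = build_synsite_table(genome)
    elif model_kind == "syncodon":
        sampler = build_codon_usage(genome)
    elif model_kind in ("markov2", "markov5"):
        sampler = build_markov_model(genome, 2 if model_kind == "markov2" else 5)

    children = np.random.SeedSequence(seed).spawn(n_reps)
    counts = np.empty((n_reps, len(ws.set_labels), 2), dtype=np.int64)
    for r in range(n_reps):
        rng = np.random.default_rng(children[r])
        try:
            sim = _replicate_codons(genome, ws, model_kind, sampler, rng)
        except Exception as exc:  # annotate with replicate index per contract
            raise RuntimeError(f"replicate {r} failed for {genome.genome_id}") from exc
        counts[r] = ws.count_sets(sim)

    sim_dens = ws.counts_to_densities(counts)  # (n_reps, n_sets, 3)
    real_dens = ws.counts_to_densities(ws.count_sets(ws.codon_concat))

    real = {}
    sims = {}
    for i, label in enumerate(ws.set_labels):
        for j, frame in enumerate(FRAMES):
            real[(label, frame)] = float(real_dens[i, j])
            sims[(label, frame)] = sim_dens[:, i, j].copy()
    return SimulationEnsemble(
        genome_id=genome.genome_id,
        model=model_kind,
        n_reps=n_reps,
        seed=seed,
        codon_sets=sets,
        real=real,
        sims=sims,
    )
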