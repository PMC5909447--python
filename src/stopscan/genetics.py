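"""Genetic-code primitives: codon encodings and NCBI translation tables.

Codons are indexed 0..63 with A=0, C=1, G=2, T=3 and the first nucleotide
most significant (``index = 16*a + 4*b + c``).  A *coding block* is the set
of synonymous codons of one amino acid sharing their first two nucleotides;
the three 6-fold amino acids (Leu, Ser, Arg) therefore split into a 2-fold
and a 4-fold block, and under translation table 4 tryptophan forms a 2-fold
TG block {TGA, TGG}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

NTS = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NTS)}

#: all 64 codons in index order
CODONS = [a + b + c for a in NTS for b in NTS for c in NTS]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: (64, 3) array mapping codon index -> nucleotide indices
NT_OF_CODON = np.array(
    [[NT_INDEX[c[0]], NT_INDEX[c[1]], NT_INDEX[c[2]]] for c in CODONS],
    dtype=np.int8,
)

#: (64, 3) array of ASCII bytes, for fast codon-array -> string conversion
NT_BYTES_OF_CODON = np.array(
    [[ord(c[0]), ord(c[1]), ord(c[2])] for c in CODONS], dtype=np.uint8
)

#: 256-entry lookup from ASCII byte to nucleotide index (255 = invalid)
ASCII_TO_NT = np.full(256, 255, dtype=np.uint8)
for _c, _i in NT_INDEX.items():
    ASCII_TO_NT[ord(_c)] = _i
    ASCII_TO_NT[ord(_c.lower())] = _i

STOP = "*"


def codons_to_str(codon_idx: np.ndarray) -> str:
    """Convert an array of codon indices to a nucleotide string."""
    return NT_BYTES_OF_CODON[codon_idx].tobytes().decode("ascii")


def str_to_nt_idx(sequence: str) -> np.ndarray:
    """Map a nucleotide string to an int8 index array (255 where invalid)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return ASCII_TO_NT[raw]


@dataclass(frozen=True)
class TranslationTable:
    """A genetic-code variant: codon -> amino acid map plus stop codon set.

    Instances are built from Biopython's NCBI tables via :meth:`from_ncbi_id`.
    Stops are encoded as ``"*"`` in ``codon_to_aa``.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    start_codons: frozenset[str]
    _derived: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_ncbi_id(cls, table_id: int) -> "TranslationTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: STOP for c in bio.stop_codons}
        mapping.update(bio.forward_table)
        if set(mapping) != set(CODONS):
            raise ValueError(f"table {table_id} does not cover all 64 codons")
        return cls(
            table_id=table_id,
            codon_to_aa=mapping,
            stop_codons=frozenset(bio.stop_codons),
            start_codons=frozenset(bio.start_codons),
        )

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    # -- derived, lazily computed views -------------------------------------

    @property
    def aa_by_index(self) -> np.ndarray:
        """(64,) array of single-letter amino acids ('*' for stop)."""
        if "aa_by_index" not in self._derived:
            self._derived["aa_by_index"] = np.array(
                [self.codon_to_aa[c] for c in CODONS], dtype="<U1"
            )
        return self._derived["aa_by_index"]

    @property
    def stop_mask(self) -> np.ndarray:
        """(64,) boolean mask over codon indices."""
        if "stop_mask" not in self._derived:
            m = np.zeros(64, dtype=bool)
            for c in self.stop_codons:
                m[CODON_INDEX[c]] = True
            self._derived["stop_mask"] = m
        return self._derived["stop_mask"]

    @property
    def synonyms(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> tuple of its codons (sense amino acids only)."""
        if "synonyms" not in self._derived:
            syn: dict[str, list[str]] = {}
            for c in CODONS:
                aa = self.codon_to_aa[c]
                if aa != STOP:
                    syn.setdefault(aa, []).append(c)
            self._derived["synonyms"] = {a: tuple(v) for a, v in syn.items()}
        return self._derived["synonyms"]

    @property
    def blocks(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """(amino acid, first-two-nt prefix) -> codons of that coding block."""
        if "blocks" not in self._derived:
            blk: dict[tuple[str, str], list[str]] = {}
            for c in CODONS:
                aa = self.codon_to_aa[c]
                if aa != STOP:
                    blk.setdefault((aa, c[:2]), []).append(c)
            self._derived["blocks"] = {k: tuple(v) for k, v in blk.items()}
        return self._derived["blocks"]

    @property
    def block_index(self) -> np.ndarray:
        """(64,) array of coding-block ids (-1 for stop codons)."""
        if "block_index" not in self._derived:
            keys = sorted(self.blocks)
            key_id = {k: i for i, k in enumerate(keys)}
            arr = np.full(64, -1, dtype=np.int64)
            for i, c in enumerate(CODONS):
                aa = self.codon_to_aa[c]
                if aa != STOP:
                    arr[i] = key_id[(aa, c[:2])]
            self._derived["block_keys"] = keys
            self._derived["block_index"] = arr
        return self._derived["block_index"]

    @property
    def block_keys(self) -> list[tuple[str, str]]:
        self.block_index  # populate
        return self._derived["block_keys"]

    @property
    def aa_index(self) -> np.ndarray:
        """(64,) array of amino-acid ids (-1 for stop codons)."""
        if "aa_index" not in self._derived:
            aas = sorted(self.synonyms)
            aa_id = {a: i for i, a in enumerate(aas)}
            arr = np.full(64, -1, dtype=np.int64)
            for i, c in enumerate(CODONS):
                aa = self.codon_to_aa[c]
                if aa != STOP:
                    arr[i] = aa_id[aa]
            self._derived["aa_keys"] = aas
            self._derived["aa_index"] = arr
        return self._derived["aa_index"]

    @property
    def aa_keys(self) -> list[str]:
        self.aa_index  # populate
        return self._derived["aa_keys"]

    def single_synonym_aas(self) -> frozenset[str]:
        """Amino acids with exactly one codon (Met and, under table 11, Trp)."""
        return frozenset(a for a, s in self.synonyms.items() if len(s) == 1)


@lru_cache(maxsize=None)
def get_table(table_id: int) -> TranslationTable:
    """Cached access to the NCBI translation table with this id."""
    return TranslationTable.from_ncbi_id(table_id)


TABLE_11 = get_table(11)
TABLE_4 = get_table(4)
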