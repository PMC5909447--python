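"""Readers and writers: CDS FASTA cohorts, GenBank flat files, result TSVs.

A cohort on disk is a directory of per-genome multi-FASTA files (one record
per CDS) plus a ``metadata.tsv`` sidecar with columns ``genome_id``,
``table_id``, ``genus``, ``genome_size_bp`` and ``fasta`` (file name).
Gene names may be carried in the FASTA description as ``gene=<name>``.
"""

from __future__ import annotations

import re
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genetics import get_table
from .null_models import SimulationEnsemble
from .sequence import GenomeRecord, assemble_genome, osc_density

_GENE_RE = re.compile(r"gene=(\S+)")

METADATA_COLUMNS = ["genome_id", "table_id", "genus", "genome_size_bp", "fasta"]


def write_genome_fasta(genome: GenomeRecord, path: str | Path) -> None:
    """One FASTA record per CDS; gene names kept in the description."""
    with open(path, "w") as fh:
        for cds in genome.cds_list:
            desc = f" gene={cds.gene}" if cds.gene else ""
            fh.write(f">{cds.cds_id}{desc}\n")
            for i in range(0, len(cds.sequence), 70):
                fh.write(cds.sequence[i : i + 70] + "\n")


def write_cohort(
    genomes: Sequence[GenomeRecord],
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> Path:
    """Write per-genome FASTAs plus the metadata sidecar (and truth table)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in genomes:
        fname = f"{g.genome_id}.fasta"
        write_genome_fasta(g, out / fname)
        rows.append(
            {
                "genome_id": g.genome_id,
                "table_id": g.table.table_id,
                "genus": g.genus or "",
                "genome_size_bp": g.genome_size_bp or 0,
                "fasta": fname,
            }
        )
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        out / "metadata.tsv", sep="\t", index=False
    )
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def read_cds_fasta(
    path: str | Path,
) -> list[tuple[str, str, str | None]]:
    """Yield (cds_id, sequence, gene) triples from a CDS multi-FASTA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _GENE_RE.search(rec.description)
        out.append((rec.id, str(rec.seq).upper(), m.group(1) if m else None))
    return out


def read_cohort(
    cohort_dir: str | Path,
) -> tuple[list[GenomeRecord], dict[str, Counter]]:
    """Read a cohort directory; returns genomes plus per-genome filter tallies."""
    cohort_dir = Path(cohort_dir)
    meta = pd.read_csv(cohort_dir / "metadata.tsv", sep="\t")
    genomes = []
    tallies: dict[str, Counter] = {}
    for row in meta.itertuples():
        table = get_table(int(row.table_id))
        raw = read_cds_fasta(cohort_dir / row.fasta)
        genus = str(row.genus) if str(row.genus) not in ("", "nan") else None
        size = int(row.genome_size_bp) if row.genome_size_bp else None
        genome, tally = assemble_genome(
            str(row.genome_id), raw, table, genus=genus, genome_size_bp=size
        )
        tallies[str(row.genome_id)] = tally
        if genome is not None:
            genomes.append(genome)
    return genomes, tallies


def read_genbank(path: str | Path, genome_id: str | None = None):
    """Extract CDS features (either strand, reverse-complemented to coding
    orientation) from a GenBank flat file and assemble a filtered genome.

    The translation table is taken from the first CDS ``transl_table``
    qualifier (default 11).
    """
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    table_id = 11
    raw: list[tuple[str, str, str | None]] = []
    size = 0
    for rec in records:
        size += len(rec.seq)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if "transl_table" in feat.qualifiers:
                table_id = int(feat.qualifiers["transl_table"][0])
            gene = feat.qualifiers.get("gene", [None])[0]
            locus = feat.qualifiers.get("locus_tag", [f"cds{len(raw)}"])[0]
            seq = str(feat.extract(rec.seq)).upper()
            raw.append((locus, seq, gene))
    gid = genome_id or records[0].id
    genome, tally = assemble_genome(gid, raw, get_table(table_id), genome_size_bp=size)
    return genome, tally


# ---------------------------------------------------------------------------
# result writers


def write_density_table(
    genomes: Sequence[GenomeRecord],
    codons: Iterable[str],
    path: str | Path,
) -> pd.DataFrame:
    """Per-genome density TSV: genome_id, codon, frame, density."""
    rows = []
    for g in genomes:
        for codon in codons:
            for frame in ("+1", "+2", "both"):
                frames = ("+1", "+2") if frame == "both" else (frame,)
                rows.append(
                    {
                        "genome_id": g.genome_id,
                        "codon": codon,
                        "frame": frame,
                        "density": osc_density(g, [codon], frames),
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_ensembles(
    ensembles: Sequence[SimulationEnsemble], path: str | Path
) -> pd.DataFrame:
    """Ensemble summary TSV: one row per (genome, model, codon set, frame)."""
    rows = []
    for ens in ensembles:
        for label, frame in ens.keys():
            rows.append(
                {
                    "genome_id": ens.genome_id,
                    "model": ens.model,
                    "codon": label,
                    "frame": frame,
                    "real_density": ens.real[(label, frame)],
                    "sim_mean": ens.sim_mean(label, frame),
                    "sim_sd": ens.sim_sd(label, frame),
                    "n_reps": ens.n_reps,
                    "seed": ens.seed,
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
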