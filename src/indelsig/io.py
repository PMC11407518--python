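"""Readers and writers for the standard formats the pipeline touches.

FASTA (proteomes and alignments), 12-column tabular BLAST, relaxed PHYLIP and
FASTA super-matrix export with a TSV partition table, and TSV clade maps.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO

from .model import GAP, VALID_RESIDUES, BlastHit, Msa, ProteinSeq

if TYPE_CHECKING:  # pragma: no cover
    from .msa import SuperMatrix

logger = logging.getLogger(__name__)


def read_fasta(path, genome_id: str | None = None) -> list[ProteinSeq]:
    """Read one protein FASTA file into :class:`ProteinSeq` records.

    The header token before the first whitespace becomes ``seq_id``; lowercase
    residues are uppercased and a single terminal ``'*'`` is stripped silently.
    ``genome_id`` defaults to the file stem (one proteome per genome file).
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    seqs: list[ProteinSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in seen:
            raise ValueError(f"duplicate seq_id {sid!r} in {path}")
        seen.add(sid)
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        bad = set(residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"invalid residue(s) {sorted(bad)} in record {sid!r} of {path}"
            )
        seqs.append(ProteinSeq(seq_id=sid, genome_id=gid, residues=residues))
    return seqs


def write_fasta(seqs, path, width: int = 70) -> None:
    """Write records (ProteinSeq, or (id, string) pairs) as FASTA."""
    with open(path, "w") as fh:
        for item in seqs:
            if isinstance(item, ProteinSeq):
                sid, s = item.seq_id, item.residues
            else:
                sid, s = item
            fh.write(f">{sid}\n")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_alignment_fasta(path, family_id: str | None = None) -> Msa:
    """Read an aligned FASTA file (rows may contain '-' or '.')."""
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate seq_id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    fid = family_id if family_id is not None else path.stem
    return Msa(fid, rows)


def write_alignment_fasta(msa: Msa, path, width: int = 70) -> None:
    write_fasta(msa.rows.items(), path, width=width)


def read_blast_tab(path, max_evalue: float = 1e-20) -> list[BlastHit]:
    """Parse outfmt-6 tabular BLAST, keeping hits with evalue <= ``max_evalue``.

    Column order is fixed (qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore); extra columns are ignored with a logged
    warning, fewer than 12 is a parse error naming the line.
    """
    hits: list[BlastHit] = []
    warned_extra = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if len(fields) > 12 and not warned_extra:
                logger.warning(
                    "%s:%d: %d columns; ignoring columns beyond 12",
                    path, lineno, len(fields),
                )
                warned_extra = True
            evalue = float(fields[10])
            if evalue > max_evalue:
                continue
            hits.append(
                BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    evalue=evalue,
                    bitscore=float(fields[11]),
                )
            )
    return hits


def read_clade_map(path) -> dict[str, str]:
    """Read a two-column TSV of genome_id -> clade label."""
    clades: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            genome, clade = line.split("\t")[:2]
            clades[genome] = clade
    return clades


def write_clade_map(clade_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for genome, clade in clade_map.items():
            fh.write(f"{genome}\t{clade}\n")


def write_partitions(partitions, path) -> None:
    """TSV partition table: family_id, start, end (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("family_id\tstart\tend\n")
        for family_id, start, end in partitions:
            fh.write(f"{family_id}\t{start}\t{end}\n")


def write_supermatrix(
    sm: "SuperMatrix",
    path,
    fmt: str = "fasta",
    partitions_path=None,
) -> None:
    """Write the concatenated super-matrix for external tree inference.

    ``fmt`` is ``fasta`` or ``phylip-relaxed`` (header ``n_taxa n_cols``,
    names terminated by two spaces). The partition table is written alongside
    as TSV (default: ``<path>.partitions.tsv``). Output is byte-deterministic
    for a fixed matrix.
    """
    if not sm.rows:
        raise ValueError("empty super-matrix")
    path = Path(path)
    if fmt == "fasta":
        write_fasta(((g, sm.rows[g]) for g in sm.genome_order), path)
    elif fmt == "phylip-relaxed":
        with open(path, "w") as fh:
            fh.write(f"{len(sm.genome_order)} {sm.ncols}\n")
            for g in sm.genome_order:
                fh.write(f"{g}  {sm.rows[g]}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if partitions_path is None:
        partitions_path = path.with_suffix(path.suffix + ".partitions.tsv")
    write_partitions(sm.partitions, partitions_path)


def read_supermatrix_fasta(path) -> dict[str, str]:
    """Read back a FASTA super-matrix as genome -> row (for round trips)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_proteome_dir(directory, clade_map_file=None):
    """Load a directory of per-genome FASTA files into a ProteomeSet.

    Every ``*.fasta``/``*.faa`` file is one proteome named by its stem; the
    clade map defaults to ``clade_map.tsv`` inside the directory.
    """
    from .model import ProteomeSet

    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix in (".fasta", ".faa", ".fa")
    )
    if not files:
        raise ValueError(f"no FASTA proteomes found in {directory}")
    genomes: dict[str, str] = {}
    sequences: list[ProteinSeq] = []
    for p in files:
        genomes[p.stem] = p.stem
        sequences.extend(read_fasta(p))
    if clade_map_file is None:
        clade_map_file = directory / "clade_map.tsv"
    clade_map = read_clade_map(clade_map_file)
    return ProteomeSet(genomes, sequences, clade_map)
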