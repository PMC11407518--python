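"""Shared domain types for the CSI / core-genome pipeline.

Conventions used throughout the package:

* the gap character is ``'-'`` (``'.'`` in inputs is normalised on read);
* all reported coordinates — alignment columns and residue positions alike —
  are 1-based and inclusive, matching the conventional presentation of
  signature-indel tables ("2 aa Ins, 282–322");
* ``'X'`` denotes an unknown residue and never counts as a match, neither for
  percent identity nor for flank conservation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
GAP = "-"
VALID_RESIDUES = frozenset(AMINO_ACIDS + UNKNOWN)


@dataclass(frozen=True)
class ProteinSeq:
    """An ungapped protein sequence belonging to one genome."""

    seq_id: str
    genome_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"invalid residue(s) {sorted(bad)} in sequence {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class ProteomeSet:
    """The input universe: genomes, their proteins, and the clade map.

    Parameters
    ----------
    genomes
        Mapping of genome id to display name.
    sequences
        The proteins; every ``genome_id`` must be a listed genome and every
        ``seq_id`` must be unique.
    clade_map
        Mapping of genome id to clade label; must cover every genome.
    """

    def __init__(
        self,
        genomes: Mapping[str, str],
        sequences: Iterable[ProteinSeq],
        clade_map: Mapping[str, str],
    ) -> None:
        self.genomes: dict[str, str] = dict(genomes)
        self.sequences: dict[str, ProteinSeq] = {}
        for seq in sequences:
            if seq.seq_id in self.sequences:
                raise ValueError(f"duplicate seq_id {seq.seq_id!r}")
            if seq.genome_id not in self.genomes:
                raise ValueError(
                    f"sequence {seq.seq_id!r} references unknown genome "
                    f"{seq.genome_id!r}"
                )
            self.sequences[seq.seq_id] = seq
        missing = set(self.genomes) - set(clade_map)
        if missing:
            raise ValueError(f"genomes without clade label: {sorted(missing)}")
        self.clade_map: dict[str, str] = {g: clade_map[g] for g in self.genomes}

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)

    @property
    def clades(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.clade_map.values():
            seen.setdefault(label)
        return list(seen)

    def clade_members(self, clade: str) -> list[str]:
        return [g for g, c in self.clade_map.items() if c == clade]

    def genome_of(self, seq_id: str) -> str:
        return self.sequences[seq_id].genome_id

    def sequences_of(self, genome_id: str) -> list[ProteinSeq]:
        return [s for s in self.sequences.values() if s.genome_id == genome_id]

    def __len__(self) -> int:
        return len(self.genomes)


class Msa:
    """A multiple sequence alignment of one protein family.

    Rows are an ordered map of ``seq_id`` to aligned string over the residue
    alphabet plus ``'-'``; all rows share the same length. De-gapping a row
    must reproduce the source protein exactly (checked by callers that hold
    the source, not here).
    """

    def __init__(self, family_id: str, rows: Mapping[str, str]) -> None:
        if not rows:
            raise ValueError(f"alignment {family_id!r} has no rows")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths in alignment {family_id!r}")
        self.family_id = family_id
        self.rows: dict[str, str] = {
            sid: row.replace(".", GAP) for sid, row in rows.items()
        }
        self.ncols: int = lengths.pop()

    def __len__(self) -> int:
        return len(self.rows)

    def ungapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def column(self, col: int) -> str:
        """1-based column as a string over rows in order."""
        return "".join(row[col - 1] for row in self.rows.values())


@dataclass(frozen=True)
class ScanParams:
    """Tunables of the signature-indel scan.

    Defaults mirror the classical criteria: an indel of fixed length flanked
    on both sides by at least four conserved residues within the neighbouring
    40 alignment columns, with no tolerated exceptions.
    """

    flank_window: int = 40
    min_conserved_flank: int = 4
    conserved_fraction: float = 1.0
    max_indel_len: int = 10
    min_indel_len: int = 1
    max_exceptions: int = 0
    allow_missing: bool = True

    def __post_init__(self) -> None:
        if self.min_indel_len < 1:
            raise ValueError("min_indel_len must be >= 1")
        if self.max_indel_len < self.min_indel_len:
            raise ValueError("max_indel_len < min_indel_len")
        if self.flank_window < self.min_conserved_flank:
            raise ValueError("flank_window must be >= min_conserved_flank")
        if not (0.0 < self.conserved_fraction <= 1.0):
            raise ValueError("conserved_fraction must be in (0, 1]")
        if self.max_exceptions < 0:
            raise ValueError("max_exceptions must be >= 0")

    @classmethod
    def from_json(cls, path) -> "ScanParams":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


INSERTION = "insertion"
DELETION = "deletion"


@dataclass
class CsiRecord:
    """A detected (or planted) clade-specific conserved signature indel.

    ``indel_type`` is the state of the target clade relative to the outgroup:
    ``insertion`` if clade members carry residues where others are gapped,
    ``deletion`` if clade members are gapped. ``block_cols`` is the alignment
    column interval of the indel, ``ref_region`` the 1-based residue interval
    in the reference sequence spanning the block plus its flank windows.
    """

    family_id: str
    reference_seq_id: str
    indel_type: str
    indel_length: int
    block_cols: tuple[int, int]
    ref_region: tuple[int, int]
    clade: str
    exceptions: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)
    flank_conserved: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.indel_type not in (INSERTION, DELETION):
            raise ValueError(f"bad indel_type {self.indel_type!r}")
        start, end = self.block_cols
        if self.indel_length != end - start + 1:
            raise ValueError(
                f"indel_length {self.indel_length} != block width {end - start + 1}"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["block_cols"] = list(self.block_cols)
        d["ref_region"] = list(self.ref_region)
        d["flank_conserved"] = list(self.flank_conserved)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CsiRecord":
        d = dict(d)
        d["block_cols"] = tuple(d["block_cols"])
        d["ref_region"] = tuple(d["ref_region"])
        d["flank_conserved"] = tuple(d["flank_conserved"])
        return cls(**d)


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular BLAST output (outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("negative e-value")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity outside [0, 100]")
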