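"""Detection of clade-specific conserved signature indels (CSIs).

A CSI is a fixed-length insertion or deletion in a protein alignment that is
shared by all members of a target clade (optionally tolerating a small number
of *isolated exceptions* outside the clade) and is embedded in a conserved
region: both flanks must contain a minimum number of invariant columns within
a neighbouring window. The scan proceeds in three stages:

1. :func:`find_indel_blocks` — maximal alignment intervals in which every row
   is either all-gap or all-residue (candidate fixed-length indels);
2. :func:`classify_block` — the clade-specificity verdict;
3. :func:`flank_conservation` — the conserved-flank requirement.

:func:`scan_clade_csis` chains the three and emits :class:`CsiRecord` objects;
:func:`validate_csi` re-checks a claimed record against the same rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .model import (
    DELETION,
    GAP,
    INSERTION,
    UNKNOWN,
    CsiRecord,
    Msa,
    ScanParams,
)


@dataclass(frozen=True)
class IndelBlock:
    """A maximal block-consistent alignment interval with mixed gap state.

    Every row is all-gap or all-residue across ``cols`` (1-based inclusive),
    both sets are non-empty, and extending the interval by one column in
    either direction breaks this consistency.
    """

    family_id: str
    cols: tuple[int, int]
    gapped_rows: frozenset[str]
    residue_rows: frozenset[str]

    @property
    def length(self) -> int:
        return self.cols[1] - self.cols[0] + 1


@dataclass
class Verdict:
    """Outcome of the clade-specificity check for one block."""

    passed: bool
    reason: str
    indel_type: str | None = None
    exceptions: list[str] = field(default_factory=list)
    missing: list[str] = field(default_factory=list)


def _gap_mask(msa: Msa) -> tuple[list[str], np.ndarray]:
    ids = list(msa.rows)
    arr = np.frombuffer(
        "".join(msa.rows[i] for i in ids).encode("ascii"), dtype=np.uint8
    ).reshape(len(ids), msa.ncols)
    return ids, arr == ord(GAP)


def find_indel_blocks(msa: Msa, min_len: int = 1, max_len: int = 10) -> list[IndelBlock]:
    """All maximal block-consistent intervals with length in [min_len, max_len].

    Because block consistency forces every row's gap state to be constant
    across the interval, maximal blocks are exactly the maximal runs of
    columns sharing an identical gap pattern; runs where all rows agree
    (no gaps, or all gaps) are not indels and are skipped, as are runs whose
    maximal length falls outside the requested range.
    """
    ids, gaps = _gap_mask(msa)
    ncols = msa.ncols
    if ncols == 0:
        return []
    # boundaries between runs of identical gap-pattern columns
    if ncols > 1:
        change = np.any(gaps[:, 1:] != gaps[:, :-1], axis=0)
        starts = np.concatenate(([0], np.flatnonzero(change) + 1))
        ends = np.concatenate((starts[1:] - 1, [ncols - 1]))
    else:
        starts, ends = np.array([0]), np.array([0])
    blocks: list[IndelBlock] = []
    for s, e in zip(starts, ends):
        col = gaps[:, s]
        ngap = int(col.sum())
        if ngap == 0 or ngap == len(ids):
            continue
        length = e - s + 1
        if not (min_len <= length <= max_len):
            continue
        gapped = frozenset(ids[i] for i in np.flatnonzero(col))
        blocks.append(
            IndelBlock(
                family_id=msa.family_id,
                cols=(int(s) + 1, int(e) + 1),
                gapped_rows=gapped,
                residue_rows=frozenset(ids) - gapped,
            )
        )
    blocks.sort(key=lambda b: b.cols[0])
    return blocks


def classify_block(
    block: IndelBlock,
    clade_map: Mapping[str, str],
    target_clade: str,
    params: ScanParams,
    genome_map: Mapping[str, str],
) -> Verdict:
    """Clade-specificity verdict for one indel block.

    The target clade must be unanimous in its gap/residue state (no exception
    allowance *inside* the clade); genomes outside the clade sharing the clade
    state are counted as exceptions, tolerated up to ``params.max_exceptions``
    and reported. At least one outside genome must hold the opposite state,
    otherwise the block carries no phylogenetic contrast. Clade genomes with
    no homologue in the family are tolerated (``allow_missing``) provided at
    least two clade rows remain.
    """
    if target_clade not in set(clade_map.values()):
        raise ValueError(f"clade {target_clade!r} absent from clade map")
    row_ids = block.gapped_rows | block.residue_rows
    row_genomes = {sid: genome_map[sid] for sid in row_ids}
    clade_genomes = {g for g, c in clade_map.items() if c == target_clade}
    present = {g for g in row_genomes.values() if g in clade_genomes}
    missing = sorted(clade_genomes - present)
    if missing and not params.allow_missing:
        return Verdict(False, "homologue missing and allow_missing is off",
                       missing=missing)
    if len(present) < 2:
        return Verdict(False, "fewer than two clade rows present",
                       missing=missing)
    clade_rows = {s for s in row_ids if row_genomes[s] in clade_genomes}
    clade_gapped = clade_rows & block.gapped_rows
    if clade_gapped and clade_rows - clade_gapped:
        return Verdict(False, "clade not unanimous", missing=missing)
    state_gap = bool(clade_gapped)
    sharing = block.gapped_rows if state_gap else block.residue_rows
    opposite = block.residue_rows if state_gap else block.gapped_rows
    exceptions = sorted(
        {row_genomes[s] for s in sharing - clade_rows}
    )
    if not any(row_genomes[s] not in clade_genomes for s in opposite):
        return Verdict(False, "no outside genome with opposite state",
                       missing=missing)
    indel_type = DELETION if state_gap else INSERTION
    if len(exceptions) > params.max_exceptions:
        return Verdict(
            False,
            f"{len(exceptions)} exception(s) exceed max_exceptions="
            f"{params.max_exceptions}",
            indel_type=indel_type, exceptions=exceptions, missing=missing,
        )
    return Verdict(True, "ok", indel_type=indel_type,
                   exceptions=exceptions, missing=missing)


def _conserved_columns(msa: Msa, lo: int, hi: int, params: ScanParams) -> int:
    """Count conserved columns in 1-based inclusive [lo, hi].

    A column is conserved iff it is gap-free among the rows present and a
    single residue (never ``'X'``) reaches frequency >= conserved_fraction.
    """
    if lo > hi:
        return 0
    count = 0
    nrows = len(msa.rows)
    for c in range(lo, hi + 1):
        col = msa.column(c)
        if GAP in col:
            continue
        best = max(
            (col.count(ch) for ch in set(col) if ch != UNKNOWN), default=0
        )
        if best / nrows >= params.conserved_fraction:
            count += 1
    return count


def flank_conservation(
    msa: Msa, block: IndelBlock, params: ScanParams
) -> tuple[int, int, bool]:
    """Conserved-column counts in the windows flanking a block.

    Examines up to ``flank_window`` columns immediately left and right of the
    block, clamped at the alignment edges; passes iff both counts reach
    ``min_conserved_flank``.
    """
    s, e = block.cols
    w = params.flank_window
    left = _conserved_columns(msa, max(1, s - w), s - 1, params)
    right = _conserved_columns(msa, e + 1, min(msa.ncols, e + w), params)
    ok = left >= params.min_conserved_flank and right >= params.min_conserved_flank
    return left, right, ok


def _ref_region(msa: Msa, ref_id: str, block: IndelBlock, params: ScanParams
                ) -> tuple[int, int]:
    """Residue interval in the reference spanning block plus flank windows."""
    s, e = block.cols
    lo = max(1, s - params.flank_window)
    hi = min(msa.ncols, e + params.flank_window)
    row = msa.rows[ref_id]
    before = sum(1 for ch in row[: lo - 1] if ch != GAP)
    inside = sum(1 for ch in row[lo - 1 : hi] if ch != GAP)
    if inside == 0:
        raise ValueError(
            f"reference {ref_id!r} has no residues in flanked span of "
            f"{block.family_id}"
        )
    return before + 1, before + inside


def scan_clade_csis(
    msas: Iterable[Msa],
    clade_map: Mapping[str, str],
    target_clade: str,
    params: ScanParams,
    genome_map: Mapping[str, str],
) -> list[CsiRecord]:
    """Scan family alignments for CSIs specific to ``target_clade``.

    The reference sequence of each record is the clade member with the
    lexicographically smallest genome id having a row in the family; records
    are sorted by (family_id, start column).
    """
    clades = set(clade_map.values())
    if len(clades) < 2:
        raise ValueError("at least two clades are required for a CSI scan")
    records: list[CsiRecord] = []
    for msa in msas:
        for sid in msa.rows:
            if sid not in genome_map:
                raise ValueError(
                    f"row {sid!r} of {msa.family_id!r} maps to no genome"
                )
        for block in find_indel_blocks(
            msa, params.min_indel_len, params.max_indel_len
        ):
            verdict = classify_block(
                block, clade_map, target_clade, params, genome_map
            )
            if not verdict.passed:
                continue
            left, right, ok = flank_conservation(msa, block, params)
            if not ok:
                continue
            clade_rows = sorted(
                (genome_map[s], s)
                for s in (block.gapped_rows | block.residue_rows)
                if clade_map.get(genome_map[s]) == target_clade
            )
            ref_id = clade_rows[0][1]
            records.append(
                CsiRecord(
                    family_id=msa.family_id,
                    reference_seq_id=ref_id,
                    indel_type=verdict.indel_type,
                    indel_length=block.length,
                    block_cols=block.cols,
                    ref_region=_ref_region(msa, ref_id, block, params),
                    clade=target_clade,
                    exceptions=verdict.exceptions,
                    missing=verdict.missing,
                    flank_conserved=(left, right),
                )
            )
    records.sort(key=lambda r: (r.family_id, r.block_cols[0]))
    return records


def scan_all_clades(
    msas: Iterable[Msa],
    clade_map: Mapping[str, str],
    params: ScanParams,
    genome_map: Mapping[str, str],
) -> list[CsiRecord]:
    """Run :func:`scan_clade_csis` for every clade label in turn."""
    msas = list(msas)
    out: list[CsiRecord] = []
    seen: dict[str, None] = {}
    for label in clade_map.values():
        seen.setdefault(label)
    for clade in seen:
        out.extend(scan_clade_csis(msas, clade_map, clade, params, genome_map))
    out.sort(key=lambda r: (r.family_id, r.block_cols[0], r.clade))
    return out


def validate_csi(
    msa: Msa,
    record: CsiRecord,
    params: ScanParams,
    clade_map: Mapping[str, str],
    genome_map: Mapping[str, str],
) -> tuple[bool, list[str]]:
    """Re-check a claimed CSI record; True iff the scan would emit it exactly."""
    if record.reference_seq_id not in msa.rows:
        raise ValueError(
            f"reference {record.reference_seq_id!r} not in alignment "
            f"{msa.family_id!r}"
        )
    s, e = record.block_cols
    if not (1 <= s <= e <= msa.ncols):
        raise ValueError(f"block columns {record.block_cols} out of range")
    emitted = scan_clade_csis(
        [msa], clade_map, record.clade, params, genome_map
    )
    match = next((r for r in emitted if r.block_cols == record.block_cols), None)
    if match is None:
        return False, ["no passing block at these columns"]
    reasons = []
    for name in ("reference_seq_id", "indel_type", "indel_length",
                 "ref_region", "exceptions", "missing", "flank_conserved"):
        got, want = getattr(match, name), getattr(record, name)
        if got != want:
            reasons.append(f"{name} mismatch: scan={got!r} record={want!r}")
    return not reasons, reasons
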