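"""Family alignment, gap-fraction trimming, and super-matrix concatenation.

The aligner is a classical progressive method: a UPGMA guide tree over 3-mer
cosine distances, then profile–profile global alignment with BLOSUM62 column
scores and affine gaps (open 10, extend 1, first gap character charged the
open penalty). It is deterministic and its de-gapped rows reproduce the
input sequences exactly; externally produced aligned FASTA can be imported
in its place (see :func:`indelsig.io.read_alignment_fasta`).

Trimming is a pure gap-fraction rule: any column whose gap fraction exceeds
the threshold (default 0.2) is removed. This replaces heuristic trimmers
with a fully specified, idempotent criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .model import AMINO_ACIDS, GAP, UNKNOWN, Msa, ProteinSeq

_ALPHABET = AMINO_ACIDS + UNKNOWN  # 21 symbols; gaps carry zero weight
_CODE = {ch: i for i, ch in enumerate(_ALPHABET)}

GAP_OPEN = -10.0
GAP_EXTEND = -1.0


def _blosum21() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21))
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            out[i, j] = m[a][b]
    return out


_S21 = _blosum21()


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column residue frequencies (L x 21); gaps contribute zero weight."""
    n, L = len(rows), len(rows[0])
    F = np.zeros((L, 21))
    for row in rows:
        for i, ch in enumerate(row):
            if ch != GAP:
                F[i, _CODE[ch]] += 1.0
    return F / n


@njit(cache=True)
def _gotoh(M, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    n, m = M.shape
    NEG = -1e30
    D = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    pD = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + gap_extend * (i - 1)
        pX[i, 0] = 1
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + gap_extend * (j - 1)
        pY[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # align column i of A with column j of B
            best, arg = D[i - 1, j - 1], 0
            if Ix[i - 1, j - 1] > best:
                best, arg = Ix[i - 1, j - 1], 1
            if Iy[i - 1, j - 1] > best:
                best, arg = Iy[i - 1, j - 1], 2
            D[i, j] = best + M[i - 1, j - 1]
            pD[i, j] = arg
            # gap in B (consume A column i)
            best, arg = D[i - 1, j] + gap_open, 0
            if Ix[i - 1, j] + gap_extend > best:
                best, arg = Ix[i - 1, j] + gap_extend, 1
            if Iy[i - 1, j] + gap_open > best:
                best, arg = Iy[i - 1, j] + gap_open, 2
            Ix[i, j] = best
            pX[i, j] = arg
            # gap in A (consume B column j)
            best, arg = D[i, j - 1] + gap_open, 0
            if Iy[i, j - 1] + gap_extend > best:
                best, arg = Iy[i, j - 1] + gap_extend, 1
            if Ix[i, j - 1] + gap_open > best:
                best, arg = Ix[i, j - 1] + gap_open, 2
            Iy[i, j] = best
            pY[i, j] = arg
    # traceback: ops 0=align, 1=gap in B, 2=gap in A
    state = 0
    best = D[n, m]
    if Ix[n, m] > best:
        best, state = Ix[n, m], 1
    if Iy[n, m] > best:
        best, state = Iy[n, m], 2
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            ops[k] = 0
            prev = pD[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            ops[k] = 1
            prev = pX[i, j]
            i -= 1
        else:
            ops[k] = 2
            prev = pY[i, j]
            j -= 1
        state = prev
    return ops[k:]


def _merge(rows_a: dict[str, str], rows_b: dict[str, str]) -> dict[str, str]:
    """Profile–profile global alignment of two sub-alignments."""
    Fa = _profile(list(rows_a.values()))
    Fb = _profile(list(rows_b.values()))
    M = (Fa @ _S21) @ Fb.T
    ops = _gotoh(M, GAP_OPEN, GAP_EXTEND)
    out: dict[str, str] = {}
    for sid, row in rows_a.items():
        chunks = []
        i = 0
        for op in ops:
            if op == 2:
                chunks.append(GAP)
            else:
                chunks.append(row[i])
                i += 1
        out[sid] = "".join(chunks)
    for sid, row in rows_b.items():
        chunks = []
        j = 0
        for op in ops:
            if op == 1:
                chunks.append(GAP)
            else:
                chunks.append(row[j])
                j += 1
        out[sid] = "".join(chunks)
    return out


def _kmer_vectors(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    vocab: dict[str, int] = {}
    counts = []
    for s in seqs:
        c: dict[int, int] = {}
        for i in range(max(0, len(s) - k + 1)):
            w = s[i : i + k]
            idx = vocab.setdefault(w, len(vocab))
            c[idx] = c.get(idx, 0) + 1
        counts.append(c)
    X = np.zeros((len(seqs), max(1, len(vocab))))
    for r, c in enumerate(counts):
        for idx, n in c.items():
            X[r, idx] = n
    return X


def align_family(members: Sequence[ProteinSeq], family_id: str | None = None
                 ) -> Msa:
    """Progressive multiple alignment of one family.

    Guide tree: UPGMA (average linkage) on cosine distances between 3-mer
    count vectors; merges follow the tree bottom-up. Raises on fewer than two
    members (a single-sequence alignment is undefined here).
    """
    if len(members) < 2:
        raise ValueError("align_family requires >= 2 sequences")
    fid = family_id if family_id is not None else members[0].seq_id.split("|")[-1]
    seqs = [m.residues for m in members]
    X = _kmer_vectors(seqs)
    if len(members) == 2:
        merged = _merge({members[0].seq_id: seqs[0]}, {members[1].seq_id: seqs[1]})
    else:
        dist = pdist(X, metric="cosine")
        dist = np.nan_to_num(dist, nan=1.0)
        Z = linkage(dist, method="average")
        clusters: dict[int, dict[str, str]] = {
            i: {m.seq_id: m.residues} for i, m in enumerate(members)
        }
        nxt = len(members)
        for a, b, _, _ in Z:
            clusters[nxt] = _merge(clusters.pop(int(a)), clusters.pop(int(b)))
            nxt += 1
        merged = clusters[nxt - 1]
    ordered = {m.seq_id: merged[m.seq_id] for m in members}
    return Msa(fid, ordered)


def trim_alignment(msa: Msa, max_gap_fraction: float = 0.2
                   ) -> tuple[Msa, dict[int, int]]:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the trimmed alignment and a 1-based column map old -> new for the
    surviving columns. A gap-free column is never removed; if nothing
    survives, raises with advice to relax the threshold.
    """
    nrows = len(msa.rows)
    rows = list(msa.rows.values())
    keep: list[int] = []
    for c in range(msa.ncols):
        gaps = sum(1 for r in rows if r[c] == GAP)
        if gaps / nrows <= max_gap_fraction:
            keep.append(c)
    if not keep:
        raise ValueError(
            f"all {msa.ncols} columns of {msa.family_id!r} exceed gap "
            f"fraction {max_gap_fraction}; raise max_gap_fraction"
        )
    colmap = {c + 1: i + 1 for i, c in enumerate(keep)}
    new_rows = {
        sid: "".join(row[c] for c in keep) for sid, row in msa.rows.items()
    }
    return Msa(msa.family_id, new_rows), colmap


@dataclass
class SuperMatrix:
    """Concatenated trimmed family alignments with partition records."""

    genome_order: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("unequal super-matrix row lengths")
        expect = 1
        for _, start, end in self.partitions:
            if start != expect or end < start:
                raise ValueError("partitions do not tile the matrix")
            expect = end + 1
        if self.rows and expect != self.ncols + 1:
            raise ValueError("partitions do not cover the matrix")

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def concatenate(
    msas: Iterable[Msa],
    genome_order: Sequence[str],
    genome_map: Mapping[str, str],
) -> SuperMatrix:
    """Concatenate family alignments in lexicographic family order.

    ``genome_map`` maps each row's seq_id to its genome. A genome missing
    from a family is filled with gaps across that partition; two rows from
    one genome in the same family is an error (run core selection first).
    """
    ordered = sorted(msas, key=lambda m: m.family_id)
    if not ordered:
        raise ValueError("no alignments to concatenate")
    parts: dict[str, list[str]] = {g: [] for g in genome_order}
    partitions: list[tuple[str, int, int]] = []
    start = 1
    for msa in ordered:
        by_genome: dict[str, str] = {}
        for sid, row in msa.rows.items():
            g = genome_map[sid]
            if g in by_genome:
                raise ValueError(
                    f"genome {g!r} has two rows in family {msa.family_id!r}"
                )
            by_genome[g] = row
        for g in genome_order:
            parts[g].append(by_genome.get(g, GAP * msa.ncols))
        partitions.append((msa.family_id, start, start + msa.ncols - 1))
        start += msa.ncols
    rows = {g: "".join(parts[g]) for g in genome_order}
    return SuperMatrix(list(genome_order), rows, partitions)
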