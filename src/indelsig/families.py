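"""Protein family construction and core-family selection.

Families are built CD-HIT-style: sequences are sorted by decreasing length
and greedily attached to the first existing family whose representative they
match at both thresholds (default 50% identity and 50% coverage of the
shorter sequence), else they found a new family. The *core* set keeps the
families present in at least a stated fraction (default 80%) of the genomes,
with one best-hit representative per genome so that downstream alignments
have at most one row per genome.

Identity and coverage come from a global alignment (BLOSUM62, affine gap
open 10 / extend 1): identity is matching columns over columns where both
rows hold a residue, coverage is those columns over the shorter sequence's
length. An edit-distance prefilter (edlib) skips pairs that provably cannot
reach both thresholds: any alignment of a pair with unit-cost distance d has
at most (|a|+|b|-d)/2 matches, while passing both thresholds requires at
least 0.25*min(|a|,|b|) matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

from .model import UNKNOWN, BlastHit, ProteinSeq

_aligner: PairwiseAligner | None = None


def _get_aligner() -> PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -1.0
        a.mode = "global"
        _aligner = a
    return _aligner


def pairwise_identity_global(a: ProteinSeq | str, b: ProteinSeq | str
                             ) -> tuple[float, float]:
    """Global-alignment identity and coverage of a sequence pair.

    Returns ``(identity, coverage)`` where identity is matching columns over
    both-residue columns (``'X'`` never matches) and coverage is both-residue
    columns over the shorter sequence's length.
    """
    sa = a.residues if isinstance(a, ProteinSeq) else a
    sb = b.residues if isinstance(b, ProteinSeq) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    aln = _get_aligner().align(sa, sb)[0]
    matches = 0
    both = 0
    for (qs, qe), (ss, _) in zip(*aln.aligned):
        both += qe - qs
        for i in range(qe - qs):
            ca = sa[qs + i]
            if ca == sb[ss + i] and ca != UNKNOWN:
                matches += 1
    identity = matches / both if both else 0.0
    coverage = both / min(len(sa), len(sb))
    return identity, coverage


def _may_pass(sa: str, sb: str) -> bool:
    """Edit-distance upper bound: can this pair reach 50/50 thresholds?"""
    d = edlib.align(sa, sb, task="distance")["editDistance"]
    max_matches = (len(sa) + len(sb) - d) / 2
    return max_matches >= 0.25 * min(len(sa), len(sb))


@dataclass
class Family:
    """One protein family with its representative and per-genome best hits."""

    family_id: str
    members: list[str]
    representative: str
    # identity/coverage of each member vs the representative (cached)
    scores: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_genome: dict[str, str] = field(default_factory=dict)
    prevalence: float = 0.0


class FamilySet:
    """A partition of sequences into families."""

    def __init__(self, families: list[Family], seqs: Mapping[str, ProteinSeq],
                 n_genomes: int) -> None:
        self.families: dict[str, Family] = {f.family_id: f for f in families}
        self.seqs = dict(seqs)
        self.n_genomes = n_genomes
        self.family_of: dict[str, str] = {}
        for f in families:
            for m in f.members:
                if m in self.family_of:
                    raise ValueError(f"sequence {m!r} in two families")
                self.family_of[m] = f.family_id

    def __len__(self) -> int:
        return len(self.families)

    def to_table(self):
        """Long-format DataFrame: family_id, genome_id, seq_id, is_representative."""
        import pandas as pd

        rows = []
        for fid in sorted(self.families):
            fam = self.families[fid]
            for m in sorted(fam.members):
                rows.append(
                    {
                        "family_id": fid,
                        "genome_id": self.seqs[m].genome_id,
                        "seq_id": m,
                        "is_representative": m == fam.representative,
                    }
                )
        return pd.DataFrame(rows,
                            columns=["family_id", "genome_id", "seq_id",
                                     "is_representative"])


def _sorted_seqs(seqs: Iterable[ProteinSeq]) -> list[ProteinSeq]:
    return sorted(seqs, key=lambda s: (-len(s.residues), s.seq_id))


def cluster_greedy(
    seqs: Iterable[ProteinSeq],
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    n_genomes: int | None = None,
) -> FamilySet:
    """Greedy incremental clustering in length order (CD-HIT convention).

    Each sequence joins the first existing family (in founding order) whose
    representative it matches at both thresholds, else founds a new family.
    Deterministic: ties in length break lexicographically by seq_id.
    """
    ordered = _sorted_seqs(seqs)
    if not ordered:
        raise ValueError("no sequences to cluster")
    families: list[Family] = []
    width = max(5, len(str(len(ordered))))
    for seq in ordered:
        placed = False
        for fam in families:
            rep = fam.representative_seq  # type: ignore[attr-defined]
            if not _may_pass(seq.residues, rep.residues):
                continue
            ident, cov = pairwise_identity_global(seq, rep)
            if ident >= min_identity and cov >= min_coverage:
                fam.members.append(seq.seq_id)
                fam.scores[seq.seq_id] = (ident, cov)
                placed = True
                break
        if not placed:
            fam = Family(
                family_id=f"fam{len(families):0{width}d}",
                members=[seq.seq_id],
                representative=seq.seq_id,
                scores={seq.seq_id: (1.0, 1.0)},
            )
            fam.representative_seq = seq  # type: ignore[attr-defined]
            families.append(fam)
    seq_map = {s.seq_id: s for s in ordered}
    genomes = {s.genome_id for s in ordered}
    total = n_genomes if n_genomes is not None else len(genomes)
    for fam in families:
        fam.prevalence = len({seq_map[m].genome_id for m in fam.members}) / total
        del fam.representative_seq  # type: ignore[attr-defined]
    return FamilySet(families, seq_map, total)


def select_core(fams: FamilySet, prevalence: float = 0.8) -> FamilySet:
    """Keep families present in >= ``prevalence`` of the genomes.

    Within each kept family the per-genome representative is the member with
    the highest identity to the family representative (ties: longest member,
    then lexicographically smallest seq_id).
    """
    kept: list[Family] = []
    for fid in sorted(fams.families):
        fam = fams.families[fid]
        genomes = {fams.seqs[m].genome_id for m in fam.members}
        frac = len(genomes) / fams.n_genomes
        if frac < prevalence:
            continue
        rep = fams.seqs[fam.representative]
        per_genome: dict[str, str] = {}
        for g in sorted(genomes):
            candidates = [m for m in fam.members if fams.seqs[m].genome_id == g]
            def rank(m: str):
                if m not in fam.scores:
                    fam.scores[m] = pairwise_identity_global(fams.seqs[m], rep)
                ident = fam.scores[m][0]
                return (-ident, -len(fams.seqs[m].residues), m)
            per_genome[g] = min(candidates, key=rank)
        kept.append(
            Family(
                family_id=fam.family_id,
                members=list(fam.members),
                representative=fam.representative,
                scores=dict(fam.scores),
                per_genome=per_genome,
                prevalence=frac,
            )
        )
    return FamilySet(kept, fams.seqs, fams.n_genomes)


class _DSU:
    def __init__(self):
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def families_from_blast(
    hits: Iterable[BlastHit],
    seqs: Mapping[str, ProteinSeq],
    max_evalue: float = 1e-20,
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    n_genomes: int | None = None,
) -> FamilySet:
    """Single-linkage families from pre-computed BLAST hits.

    Hits must pass the e-value threshold *and* the identity/coverage
    thresholds (identity from the hit's percent identity, coverage from its
    alignment length over the shorter sequence). Connected components of the
    surviving hit graph become families under the same representative rules
    as greedy clustering; sequences without qualifying hits stay singletons.
    """
    hits = list(hits)
    unresolved = sorted(
        ({h.query_id for h in hits} | {h.subject_id for h in hits}) - set(seqs)
    )
    if unresolved:
        raise ValueError(f"hit ids not in proteome set: {unresolved}")
    dsu = _DSU()
    for sid in seqs:
        dsu.find(sid)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue > max_evalue:
            continue
        if h.percent_identity / 100.0 < min_identity:
            continue
        shorter = min(len(seqs[h.query_id]), len(seqs[h.subject_id]))
        if h.align_len / shorter < min_coverage:
            continue
        dsu.union(h.query_id, h.subject_id)
    comps: dict[str, list[str]] = {}
    for sid in seqs:
        comps.setdefault(dsu.find(sid), []).append(sid)
    def rep_of(members: list[str]) -> str:
        return min(members, key=lambda m: (-len(seqs[m].residues), m))
    ordered = sorted(comps.values(), key=lambda ms: rep_of(ms))
    width = max(5, len(str(len(ordered))))
    genomes = {s.genome_id for s in seqs.values()}
    total = n_genomes if n_genomes is not None else len(genomes)
    families = []
    for i, members in enumerate(ordered):
        rep = rep_of(members)
        fam = Family(
            family_id=f"fam{i:0{width}d}",
            members=sorted(members),
            representative=rep,
            scores={rep: (1.0, 1.0)},
        )
        fam.prevalence = len({seqs[m].genome_id for m in members}) / total
        families.append(fam)
    return FamilySet(families, seqs, total)
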