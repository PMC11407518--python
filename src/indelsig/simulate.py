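"""Synthetic proteome cohorts with planted signature indels.

The generator emulates the study design behind CSI surveys: a set of genomes
related by a clade-structured tree, protein families shared across (most of)
the cohort, substitution divergence producing realistic within- and
between-clade amino-acid identity, and fixed-length clade-specific indels
embedded in conserved regions. Because every planted indel is recorded in a
:class:`TruthManifest`, every downstream stage (clustering, trimming,
concatenation, AAI, scanning, rendering) can be tested against exact ground
truth without downloading genomes.

The substitution model is deliberately minimal: each site mutates
independently on each branch with a per-branch probability (the *rate*), and
a mutation replaces the residue by one of the 19 alternatives uniformly.
Under this model the expected identity between two genomes separated from a
common ancestor by one branch of rate *p* each has the closed form
``(1-p)**2 + p**2/19``, which the tests use as an analytic oracle. The tree
is clade-first and balanced: one root, one ancestor per clade (branch rate
``between_rate``), one branch per genome (rate ``within_rate``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .csiscan import classify_block, find_indel_blocks, flank_conservation
from .model import (
    AMINO_ACIDS,
    DELETION,
    GAP,
    INSERTION,
    CsiRecord,
    Msa,
    ProteinSeq,
    ProteomeSet,
    ScanParams,
)

_AA_BYTES = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class CladeSpec:
    """Cohort design: clade labels with sizes and the two branch rates."""

    clades: tuple[tuple[str, int], ...]
    within_rate: float = 0.03
    between_rate: float = 0.12

    def __post_init__(self) -> None:
        if sum(n for _, n in self.clades) < 4:
            raise ValueError("total genomes must be >= 4")
        for r in (self.within_rate, self.between_rate):
            if not (0.0 <= r <= 0.95):
                raise ValueError("branch rates must lie in [0, 0.95]")
        labels = [c for c, _ in self.clades]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate clade labels")

    @classmethod
    def parse(cls, text: str, within_rate: float = 0.03,
              between_rate: float = 0.12) -> "CladeSpec":
        """Parse 'Astrict:6,A:4,B:2' style clade descriptions."""
        clades = []
        for part in text.split(","):
            label, n = part.split(":")
            clades.append((label.strip(), int(n)))
        return cls(tuple(clades), within_rate, between_rate)

    def genome_ids(self) -> dict[str, str]:
        """Genome id -> clade label, in deterministic order."""
        out: dict[str, str] = {}
        for label, n in self.clades:
            for i in range(n):
                out[f"{label}_{i + 1:02d}"] = label
        return out


@dataclass
class SimulationResult:
    """A simulated cohort: proteomes, true per-family alignments, roots."""

    proteomes: ProteomeSet
    alignments: dict[str, Msa]
    roots: dict[str, str]
    spec: CladeSpec

    @property
    def genome_map(self) -> dict[str, str]:
        """seq_id -> genome_id over all alignment rows."""
        return {
            sid: _genome(sid)
            for m in self.alignments.values()
            for sid in m.rows
        }


@dataclass
class TruthManifest:
    """Ground truth of a planting run, usable as a test oracle."""

    seed: int
    records: list[CsiRecord] = field(default_factory=list)
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)
    exception_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "records": [r.to_dict() for r in self.records],
                    "missing_pairs": [list(p) for p in self.missing_pairs],
                    "exception_pairs": [list(p) for p in self.exception_pairs],
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            records=[CsiRecord.from_dict(r) for r in d["records"]],
            missing_pairs=[tuple(p) for p in d["missing_pairs"]],
            exception_pairs=[tuple(p) for p in d["exception_pairs"]],
        )


def _mutate(residues: np.ndarray, rate: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Per-site Bernoulli substitution to a uniformly chosen other residue."""
    out = residues.copy()
    if rate <= 0.0:
        return out
    hit = np.flatnonzero(rng.random(residues.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 20, hit.size)) % 20
    return out


def _to_str(codes: np.ndarray) -> str:
    return _AA_BYTES[codes].tobytes().decode("ascii")


def simulate_proteomes(
    spec: CladeSpec,
    n_families: int,
    length_range: tuple[int, int],
    seed: int,
    background_indel_rate: float = 0.0,
) -> SimulationResult:
    """Simulate a clade-structured cohort of proteomes.

    Each family draws a root sequence i.i.d. uniform over the 20 residues with
    a length uniform in ``length_range``; clade ancestors derive from the root
    at ``between_rate`` and genomes from their clade ancestor at
    ``within_rate``. With ``background_indel_rate > 0``, a genome's family
    member additionally suffers a short (1–3 aa) deletion with that
    probability, which appears as gaps in the true alignment. Deterministic
    for a fixed seed.
    """
    lo, hi = length_range
    if lo < 120:
        raise ValueError("length_range minimum must be >= 120")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    genome_clades = spec.genome_ids()
    genomes = {g: g for g in genome_clades}
    alignments: dict[str, Msa] = {}
    roots: dict[str, str] = {}
    sequences: list[ProteinSeq] = []
    width = max(4, len(str(n_families)))
    for f in range(n_families):
        fid = f"F{f:0{width}d}"
        L = int(rng.integers(lo, hi + 1))
        root = rng.integers(0, 20, L)
        roots[fid] = _to_str(root)
        rows: dict[str, str] = {}
        for label, n in spec.clades:
            anc = _mutate(root, spec.between_rate, rng)
            for i in range(n):
                gid = f"{label}_{i + 1:02d}"
                leaf = _mutate(anc, spec.within_rate, rng)
                row = _to_str(leaf)
                if background_indel_rate > 0.0 and rng.random() < background_indel_rate:
                    dlen = int(rng.integers(1, 4))
                    dpos = int(rng.integers(0, L - dlen + 1))
                    row = row[:dpos] + GAP * dlen + row[dpos + dlen:]
                sid = f"{gid}|{fid}"
                rows[sid] = row
                sequences.append(
                    ProteinSeq(sid, gid, row.replace(GAP, ""))
                )
        alignments[fid] = Msa(fid, rows)
    proteomes = ProteomeSet(genomes, sequences, genome_clades)
    return SimulationResult(proteomes, alignments, roots, spec)


@dataclass(frozen=True)
class PlantSpec:
    """One indel to plant: where, for whom, and optional complications."""

    family_id: str
    clade: str
    indel_type: str
    length: int
    position: int
    exception_genome: str | None = None
    missing_genomes: tuple[str, ...] = ()


def plant_csis(
    sim: SimulationResult,
    plan: Sequence[PlantSpec],
    params: ScanParams,
    seed: int,
) -> tuple[SimulationResult, TruthManifest]:
    """Plant clade-specific indels into a simulated cohort.

    For an *insertion*, one random motif of the stated length is inserted at
    the stated root position in every clade member (and in the optional
    exception genome); outsiders receive an all-gap block. For a *deletion*,
    the stated root run is gapped out of every clade member. To guarantee the
    flank-conservation criterion holds by construction, the
    ``min_conserved_flank`` columns immediately adjacent to the block on each
    side are reverted to the root residue in every row. Optional
    missing-homologue entries remove the family member of the named genomes.

    Returns a new :class:`SimulationResult` (input untouched) plus the
    :class:`TruthManifest`; every manifest record is produced by running the
    scanner's own classification and flank measurements on the mutated
    alignment, so the manifest is correct by construction.
    """
    rng = np.random.default_rng(seed)
    seen_families: set[str] = set()
    alignments = {fid: Msa(fid, dict(m.rows)) for fid, m in sim.alignments.items()}
    manifest = TruthManifest(seed=seed)
    clade_map = sim.proteomes.clade_map
    for p in plan:
        if p.family_id in seen_families:
            raise ValueError(f"two plants in family {p.family_id!r}")
        seen_families.add(p.family_id)
        if p.clade not in set(clade_map.values()):
            raise ValueError(f"clade {p.clade!r} absent from cohort")
        if p.indel_type not in (INSERTION, DELETION):
            raise ValueError(f"bad indel_type {p.indel_type!r}")
        msa = alignments[p.family_id]
        root = sim.roots[p.family_id]
        L = len(root)
        w = params.flank_window
        span = p.length if p.indel_type == DELETION else 0
        if L < 2 * w + span:
            raise ValueError(
                f"family {p.family_id!r} too short ({L} aa) for flank window "
                f"{w} and indel length {p.length}"
            )
        if p.position < w + 1 or p.position + span + w - 1 > L:
            raise ValueError(
                f"plant position {p.position} leaves < {w} residues on a side"
            )
        members = set(sim.proteomes.clade_members(p.clade))
        in_state = set(members)
        if p.exception_genome is not None:
            if p.exception_genome in members:
                raise ValueError("exception genome must lie outside the clade")
            in_state.add(p.exception_genome)
        pos = p.position
        if p.indel_type == INSERTION:
            motif = _to_str(rng.integers(0, 20, p.length))
            new_rows = {}
            for sid, row in msa.rows.items():
                fill = motif if _genome(sid) in in_state else GAP * p.length
                new_rows[sid] = row[: pos - 1] + fill + row[pos - 1:]
            block_cols = (pos, pos + p.length - 1)
            flank_src = {  # alignment column -> root position, per side
                "left": range(pos - params.min_conserved_flank, pos),
                "right": range(pos + p.length, pos + p.length
                               + params.min_conserved_flank),
            }
            root_of_col = lambda c: c - p.length if c >= pos else c  # noqa: E731
        else:
            new_rows = {}
            for sid, row in msa.rows.items():
                if _genome(sid) in in_state:
                    new_rows[sid] = row[: pos - 1] + GAP * p.length + row[pos + p.length - 1:]
                else:
                    new_rows[sid] = row
            block_cols = (pos, pos + p.length - 1)
            flank_src = {
                "left": range(pos - params.min_conserved_flank, pos),
                "right": range(pos + p.length, pos + p.length
                               + params.min_conserved_flank),
            }
            root_of_col = lambda c: c  # noqa: E731
        # revert flank columns to the root residue across all taxa
        for side in ("left", "right"):
            for col in flank_src[side]:
                r = root[root_of_col(col) - 1]
                for sid in new_rows:
                    row = new_rows[sid]
                    if row[col - 1] != GAP:
                        new_rows[sid] = row[: col - 1] + r + row[col:]
        for g in p.missing_genomes:
            sid = f"{g}|{p.family_id}"
            if sid not in new_rows:
                raise ValueError(f"no row {sid!r} to remove")
            del new_rows[sid]
            manifest.missing_pairs.append((p.family_id, g))
        if p.exception_genome is not None:
            manifest.exception_pairs.append((p.family_id, p.exception_genome))
        alignments[p.family_id] = Msa(p.family_id, new_rows)
        manifest.records.append(
            _manifest_record(alignments[p.family_id], block_cols, p, params,
                             clade_map)
        )
    # rebuild the proteome set from the mutated alignments
    sequences = [
        ProteinSeq(sid, _genome(sid), msa.ungapped(sid))
        for msa in alignments.values()
        for sid in msa.rows
    ]
    proteomes = ProteomeSet(sim.proteomes.genomes, sequences, clade_map)
    mutated = SimulationResult(proteomes, alignments, sim.roots, sim.spec)
    manifest.records.sort(key=lambda r: (r.family_id, r.block_cols[0]))
    return mutated, manifest


def _genome(seq_id: str) -> str:
    return seq_id.split("|", 1)[0]


def _manifest_record(
    msa: Msa,
    block_cols: tuple[int, int],
    p: PlantSpec,
    params: ScanParams,
    clade_map,
) -> CsiRecord:
    from .csiscan import _ref_region  # shared coordinate logic

    genome_map = {sid: _genome(sid) for sid in msa.rows}
    blocks = [
        b for b in find_indel_blocks(msa, params.min_indel_len, params.max_indel_len)
        if b.cols == block_cols
    ]
    if len(blocks) != 1:
        raise RuntimeError(
            f"planted block {block_cols} in {p.family_id!r} is not a clean "
            "maximal indel block"
        )
    block = blocks[0]
    lenient = ScanParams(
        flank_window=params.flank_window,
        min_conserved_flank=params.min_conserved_flank,
        conserved_fraction=params.conserved_fraction,
        max_indel_len=params.max_indel_len,
        min_indel_len=params.min_indel_len,
        max_exceptions=1 if p.exception_genome else params.max_exceptions,
        allow_missing=params.allow_missing,
    )
    verdict = classify_block(block, clade_map, p.clade, lenient, genome_map)
    if not verdict.passed or verdict.indel_type != p.indel_type:
        raise RuntimeError(
            f"planted CSI in {p.family_id!r} fails its own criteria: "
            f"{verdict.reason}"
        )
    left, right, ok = flank_conservation(msa, block, params)
    if not ok:
        raise RuntimeError(
            f"planted CSI in {p.family_id!r} lacks conserved flanks "
            f"({left}, {right})"
        )
    clade_rows = sorted(
        g for g in clade_map if clade_map[g] == p.clade
        and f"{g}|{p.family_id}" in msa.rows
    )
    ref_id = f"{clade_rows[0]}|{p.family_id}"
    return CsiRecord(
        family_id=p.family_id,
        reference_seq_id=ref_id,
        indel_type=p.indel_type,
        indel_length=p.length,
        block_cols=block_cols,
        ref_region=_ref_region(msa, ref_id, block, params),
        clade=p.clade,
        exceptions=verdict.exceptions,
        missing=verdict.missing,
        flank_conserved=(left, right),
    )


def make_plan(
    sim: SimulationResult,
    n_csis: int,
    seed: int,
    params: ScanParams | None = None,
    lengths: tuple[int, int] = (1, 4),
    n_missing: int = 3,
    n_exceptions: int = 0,
) -> list[PlantSpec]:
    """Draw a random planting plan covering all clades.

    ``n_missing`` of the planted CSIs (in clades with >= 3 members) each drop
    one clade member's homologue; ``n_exceptions`` of them additionally mark
    one genome outside the clade with the clade state.
    """
    params = params or ScanParams()
    rng = np.random.default_rng(seed)
    fids = sorted(sim.alignments)
    if n_csis > len(fids):
        raise ValueError("more CSIs requested than families available")
    chosen = [fids[i] for i in rng.choice(len(fids), n_csis, replace=False)]
    clades = [c for c, _ in sim.spec.clades]
    sizes = dict(sim.spec.clades)
    genome_clades = sim.proteomes.clade_map
    plan: list[PlantSpec] = []
    n_missing_left, n_exc_left = n_missing, n_exceptions
    for k, fid in enumerate(chosen):
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        indel_type = INSERTION if rng.random() < 0.5 else DELETION
        clade = clades[k % len(clades)]
        if n_missing_left > 0 and sizes[clade] < 3:
            big = [c for c in clades if sizes[c] >= 3]
            clade = big[k % len(big)]
        L = len(sim.roots[fid])
        w = params.flank_window
        span = length if indel_type == DELETION else 0
        pos = int(rng.integers(w + 1, L - span - w + 2))
        missing: tuple[str, ...] = ()
        if n_missing_left > 0 and sizes[clade] >= 3:
            members = sorted(g for g, c in genome_clades.items() if c == clade)
            missing = (members[int(rng.integers(0, len(members)))],)
            n_missing_left -= 1
        exception = None
        if n_exc_left > 0:
            outside = sorted(g for g, c in genome_clades.items() if c != clade)
            exception = outside[int(rng.integers(0, len(outside)))]
            n_exc_left -= 1
        plan.append(
            PlantSpec(fid, clade, indel_type, length, pos,
                      exception_genome=exception, missing_genomes=missing)
        )
    return plan
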