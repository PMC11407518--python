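"""Average amino-acid identity (AAI) from the trimmed core alignment.

AAI between two genomes is the percentage of matching residues over the
super-matrix columns where both genomes hold a residue other than ``'X'``.
Computed this way it equals the length-weighted mean of per-family percent
identities, and — because it uses core families only — it is the
core-protein AAI variant, which tracks whole-genome AAI closely while being
less sensitive to horizontal transfer.

A diagnostic neighbor-joining tree on ``d = 1 - AAI/100`` is provided for
clade-recovery checks; proper ML inference on the exported super-matrix is
left to external tools.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .model import GAP, UNKNOWN
from .msa import SuperMatrix

logger = logging.getLogger(__name__)

_GAP_B = ord(GAP)
_X_B = ord(UNKNOWN)


@dataclass
class AaiMatrix:
    """Symmetric percent-identity matrix over genomes.

    ``values`` holds percentages in [0, 100] with 100 on the diagonal and NaN
    where no qualifying columns overlap; ``overlap`` counts the both-present
    columns behind each entry.
    """

    genomes: list[str]
    values: np.ndarray
    overlap: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genomes, columns=self.genomes)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="genome")

    def value(self, g1: str, g2: str) -> float:
        i, j = self.genomes.index(g1), self.genomes.index(g2)
        return float(self.values[i, j])


def _encode(sm: SuperMatrix) -> np.ndarray:
    return np.frombuffer(
        "".join(sm.rows[g] for g in sm.genome_order).encode("ascii"),
        dtype=np.uint8,
    ).reshape(len(sm.genome_order), sm.ncols)


def aai_pair(sm: SuperMatrix, g1: str, g2: str) -> float:
    """AAI percentage for one genome pair (NaN if no qualifying columns)."""
    a = np.frombuffer(sm.rows[g1].encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(sm.rows[g2].encode("ascii"), dtype=np.uint8)
    ok = (a != _GAP_B) & (b != _GAP_B) & (a != _X_B) & (b != _X_B)
    n = int(ok.sum())
    if n == 0:
        logger.warning("no qualifying columns between %s and %s", g1, g2)
        return float("nan")
    return 100.0 * float((a[ok] == b[ok]).sum()) / n


def aai_matrix(sm: SuperMatrix) -> AaiMatrix:
    """All-pairs AAI over the super-matrix."""
    if len(sm.genome_order) < 2:
        raise ValueError("need >= 2 genomes")
    X = _encode(sm)
    present = (X != _GAP_B) & (X != _X_B)
    n = len(sm.genome_order)
    values = np.full((n, n), 100.0)
    overlap = np.zeros((n, n), dtype=np.int64)
    overlap[np.diag_indices(n)] = present.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            ok = present[i] & present[j]
            m = int(ok.sum())
            overlap[i, j] = overlap[j, i] = m
            if m == 0:
                logger.warning(
                    "no qualifying columns between %s and %s",
                    sm.genome_order[i], sm.genome_order[j],
                )
                values[i, j] = values[j, i] = float("nan")
            else:
                v = 100.0 * float((X[i, ok] == X[j, ok]).sum()) / m
                values[i, j] = values[j, i] = v
    return AaiMatrix(list(sm.genome_order), values, overlap)


def clade_aai_summary(m: AaiMatrix, clade_map: Mapping[str, str]) -> pd.DataFrame:
    """Intra- and inter-clade AAI ranges (min, max, mean, pair counts).

    Intra rows use unordered member pairs excluding self and are omitted
    (with a log message) for singleton clades; inter rows use all cross
    pairs between two clades.
    """
    idx = {g: i for i, g in enumerate(m.genomes)}
    clades: dict[str, list[str]] = {}
    for g in m.genomes:
        clades.setdefault(clade_map[g], []).append(g)
    labels = list(clades)
    rows = []
    for a_i, ca in enumerate(labels):
        for cb in labels[a_i:]:
            if ca == cb:
                members = clades[ca]
                if len(members) < 2:
                    logger.info("singleton clade %r: intra row omitted", ca)
                    continue
                vals = [
                    m.values[idx[g1], idx[g2]]
                    for k, g1 in enumerate(members)
                    for g2 in members[k + 1:]
                ]
            else:
                vals = [
                    m.values[idx[g1], idx[g2]]
                    for g1 in clades[ca]
                    for g2 in clades[cb]
                ]
            arr = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "clade_i": ca,
                    "clade_j": cb,
                    "n_pairs": len(vals),
                    "min": float(np.nanmin(arr)),
                    "max": float(np.nanmax(arr)),
                    "mean": float(np.nanmean(arr)),
                }
            )
    return pd.DataFrame(rows,
                        columns=["clade_i", "clade_j", "n_pairs",
                                 "min", "max", "mean"])


def nj_tree(m: AaiMatrix) -> str:
    """Neighbor-joining newick on distances ``d = 1 - AAI/100``.

    Negative branch lengths are clamped to zero; ties break by genome order
    (the distance-matrix row order). Raises if any AAI value is missing.
    """
    if np.isnan(m.values).any():
        raise ValueError(
            "AAI matrix has missing values; raise family prevalence so every "
            "genome pair shares columns"
        )
    d = 1.0 - m.values / 100.0
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(d, ids=m.genomes)
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()


def is_monophyletic(newick: str, tips: set[str], all_tips: set[str]) -> bool:
    """Does the unrooted tree contain the bipartition {tips | rest}?"""
    tree = TreeNode.read(_io.StringIO(newick))
    tips = set(tips)
    if not tips <= all_tips:
        raise ValueError("tips not in tree")
    if len(tips) in (1, len(all_tips)):
        return True
    rest = all_tips - tips
    for node in tree.non_tips(include_self=True):
        sub = {t.name for t in node.tips()}
        if sub == tips or sub == rest:
            return True
    return False
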