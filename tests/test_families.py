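import numpy as np
import pytest

from indelsig.families import (
    Family,
    FamilySet,
    cluster_greedy,
    families_from_blast,
    pairwise_identity_global,
    select_core,
)
from indelsig.model import BlastHit, ProteinSeq

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_seq(rng, n=200):
    return "".join(AAS[i] for i in rng.integers(0, 20, n))


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity_global("MKVLT", "MKVLT") == (1.0, 1.0)

    def test_single_substitution(self):
        ident, cov = pairwise_identity_global("MKVL", "MKIL")
        assert ident == pytest.approx(0.75)
        assert cov == pytest.approx(1.0)

    def test_coverage_is_relative_to_shorter(self):
        ident, cov = pairwise_identity_global("MKVL", "MK")
        assert cov == pytest.approx(1.0)
        assert ident == pytest.approx(1.0)

    def test_unknown_residue_never_matches(self):
        ident, _ = pairwise_identity_global("MXVL", "MXVL")
        assert ident == pytest.approx(3 / 4)


class TestGreedyClustering:
    def test_identical_copies_form_one_family(self):
        seqs = [ProteinSeq("a1", "g1", "MKVLT" * 30),
                ProteinSeq("b1", "g2", "MKVLT" * 30)]
        fs = cluster_greedy(seqs)
        assert len(fs) == 1
        fam = next(iter(fs.families.values()))
        assert sorted(fam.members) == ["a1", "b1"]

    def test_unrelated_random_sequences_stay_apart(self):
        rng = np.random.default_rng(7)
        a, b = _random_seq(rng), _random_seq(rng)
        ident, _ = pairwise_identity_global(a, b)
        assert ident < 0.5
        fs = cluster_greedy([ProteinSeq("a", "g1", a), ProteinSeq("b", "g2", b)])
        assert len(fs) == 2

    def test_membership_survives_brute_force_recheck(self, small_cohort):
        """Every member meets both thresholds against its representative
        (re-verified with the pairwise oracle, not the cached scores)."""
        seqs = [small_cohort.proteomes.sequences[sid]
                for fid in sorted(small_cohort.alignments)[:3]
                for sid in small_cohort.alignments[fid].rows]
        assert len(seqs) <= 30
        fs = cluster_greedy(seqs)
        for fam in fs.families.values():
            rep = fs.seqs[fam.representative]
            for m in fam.members:
                ident, cov = pairwise_identity_global(fs.seqs[m], rep)
                assert ident >= 0.5 and cov >= 0.5

    def test_every_sequence_in_exactly_one_family(self, small_cohort):
        seqs = [small_cohort.proteomes.sequences[sid]
                for fid in sorted(small_cohort.alignments)[:5]
                for sid in small_cohort.alignments[fid].rows]
        fs = cluster_greedy(seqs)
        members = [m for f in fs.families.values() for m in f.members]
        assert sorted(members) == sorted(s.seq_id for s in seqs)

    def test_representative_is_longest_member(self, small_cohort):
        seqs = [small_cohort.proteomes.sequences[sid]
                for fid in sorted(small_cohort.alignments)[:4]
                for sid in small_cohort.alignments[fid].rows]
        fs = cluster_greedy(seqs)
        for fam in fs.families.values():
            best = min(fam.members,
                       key=lambda m: (-len(fs.seqs[m].residues), m))
            assert fam.representative == best


def _family_set_over(n_genomes, present_genomes, paralogs=()):
    """A one-family FamilySet over an n-genome universe for select_core tests."""
    base = "MKVLTAGHQWERTYIPASDF" * 10
    seqs = {}
    members = []
    for i, g in enumerate(present_genomes):
        sid = f"{g}.p1"
        seqs[sid] = ProteinSeq(sid, g, base)
        members.append(sid)
    for g, residues in paralogs:
        sid = f"{g}.p2"
        seqs[sid] = ProteinSeq(sid, g, residues)
        members.append(sid)
    rep = members[0]
    fam = Family("fam00000", members, rep, scores={rep: (1.0, 1.0)})
    return FamilySet([fam], seqs, n_genomes)


class TestCoreSelection:
    def test_38_genome_prevalence_threshold(self):
        """31/38 genomes (0.816) is core at 80%; 30/38 (0.789) is not."""
        kept = select_core(
            _family_set_over(38, [f"g{i:02d}" for i in range(31)]), 0.8)
        assert len(kept) == 1
        dropped = select_core(
            _family_set_over(38, [f"g{i:02d}" for i in range(30)]), 0.8)
        assert len(dropped) == 0

    def test_paralog_with_higher_identity_wins(self):
        base = "MKVLTAGHQWERTYIPASDF" * 10
        # ~92% identical paralog vs ~71% identical paralog in genome g01
        strong = base[:184] + "W" * 16
        weak = base[:142] + "W" * 58
        fs = _family_set_over(
            10, [f"g{i:02d}" for i in range(10)],
            paralogs=[("g01", strong)])
        fs.families["fam00000"].members.append("g01.p3")
        fs.seqs["g01.p3"] = ProteinSeq("g01.p3", "g01", weak)
        fs.family_of["g01.p3"] = "fam00000"
        core = select_core(fs, 0.8)
        fam = core.families["fam00000"]
        assert fam.per_genome["g01"] == "g01.p1"  # exact copy beats both
        # remove the exact copy: the stronger paralog must win
        fam2 = _family_set_over(10, [f"g{i:02d}" for i in range(10)])
        fam2.families["fam00000"].members += ["g01.p2", "g01.p3"]
        fam2.seqs["g01.p2"] = ProteinSeq("g01.p2", "g01", strong)
        fam2.seqs["g01.p3"] = ProteinSeq("g01.p3", "g01", weak)
        fam2.families["fam00000"].members.remove("g01.p1")
        del fam2.seqs["g01.p1"]
        core2 = select_core(fam2, 0.8)
        assert core2.families["fam00000"].per_genome["g01"] == "g01.p2"


def _hit(q, s, ev=1e-30, pid=90.0, alen=200):
    return BlastHit(q, s, pid, alen, ev, 300.0)


class TestBlastFamilies:
    @pytest.fixture()
    def seqs(self):
        rng = np.random.default_rng(3)
        return {x: ProteinSeq(x, f"g_{x}", _random_seq(rng))
                for x in "ABCDE"}

    def test_transitive_closure(self, seqs):
        fs = families_from_blast([_hit("A", "B"), _hit("B", "C")], seqs)
        fams = {frozenset(f.members) for f in fs.families.values()}
        assert frozenset("ABC") in fams
        assert frozenset("D") in fams and frozenset("E") in fams

    def test_weak_evalue_hit_is_ignored(self, seqs):
        fs = families_from_blast([_hit("A", "B", ev=1e-10)], seqs,
                                 max_evalue=1e-20)
        assert all(len(f.members) == 1 for f in fs.families.values())

    def test_unresolvable_id_is_reported(self, seqs):
        with pytest.raises(ValueError, match="ZZ"):
            families_from_blast([_hit("A", "ZZ")], seqs)

    def test_components_match_networkx_on_random_graphs(self, seqs):
        import networkx as nx

        rng = np.random.default_rng(11)
        ids = list(seqs)
        for _ in range(50):
            edges = [
                (ids[int(rng.integers(0, 5))], ids[int(rng.integers(0, 5))])
                for _ in range(int(rng.integers(0, 6)))
            ]
            fs = families_from_blast([_hit(a, b) for a, b in edges], seqs)
            got = {frozenset(f.members) for f in fs.families.values()}
            g = nx.Graph()
            g.add_nodes_from(ids)
            g.add_edges_from((a, b) for a, b in edges if a != b)
            want = {frozenset(c) for c in nx.connected_components(g)}
            assert got == want
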