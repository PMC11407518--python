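import numpy as np
import pytest

from indelsig.csiscan import (
    classify_block,
    find_indel_blocks,
    flank_conservation,
    scan_all_clades,
    scan_clade_csis,
    validate_csi,
)
from indelsig.model import CsiRecord, Msa, ScanParams

from oracles import brute_force_scan, random_alignment, records_as_tuples

AAS = "ACDEFGHIKLMNPQRSTVWY"


class TestFindIndelBlocks:
    def test_gap_free_alignment_has_no_blocks(self):
        msa = Msa("f", {"a": "MKVLT", "b": "MKILT", "c": "MKILW"})
        assert find_indel_blocks(msa) == []

    def test_single_gapped_run_is_one_block(self):
        msa = Msa("f", {"a": "MKVLTAGH", "b": "MKVL--GH", "c": "MKVLTAGH"})
        blocks = find_indel_blocks(msa)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.cols == (5, 6)
        assert b.gapped_rows == {"b"} and b.residue_rows == {"a", "c"}

    def test_overlong_block_excluded_not_truncated(self):
        msa = Msa("f", {"a": "M" + "K" * 12 + "T", "b": "M" + "-" * 12 + "T"})
        assert find_indel_blocks(msa, min_len=1, max_len=10) == []
        assert len(find_indel_blocks(msa, min_len=1, max_len=12)) == 1

    def test_adjacent_runs_with_different_patterns_split(self):
        msa = Msa("f", {"a": "MK--TAGH", "b": "MK---AGH", "c": "MKVLTAGH"})
        blocks = find_indel_blocks(msa)
        assert [b.cols for b in blocks] == [(3, 4), (5, 5)]


def _clade_msa():
    """4 clade rows with a 2-col insert, 9 outsiders gapped there."""
    left = "MKVLTAGHQW" * 4
    right = "ACDEFGHIKL" * 4
    rows = {}
    for i in range(4):
        rows[f"in{i}"] = left + "WW" + right
    for i in range(9):
        rows[f"out{i}"] = left + "--" + right
    return Msa("f", rows)


class TestClassify:
    def setup_method(self):
        self.msa = _clade_msa()
        self.gm = {sid: sid for sid in self.msa.rows}
        self.clade_map = {
            sid: ("target" if sid.startswith("in") else "rest")
            for sid in self.msa.rows
        }
        [self.block] = find_indel_blocks(self.msa)

    def test_exclusive_insert_passes(self):
        v = classify_block(self.block, self.clade_map, "target", ScanParams(),
                           self.gm)
        assert v.passed and v.indel_type == "insertion" and v.exceptions == []

    def test_isolated_exception_needs_allowance(self):
        clade_map = dict(self.clade_map)
        rows = dict(self.msa.rows)
        rows["out0"] = rows["in0"]  # a distant genome shares the insert
        msa = Msa("f", rows)
        [block] = find_indel_blocks(msa)
        v0 = classify_block(block, clade_map, "target", ScanParams(), self.gm)
        assert not v0.passed
        v1 = classify_block(block, clade_map, "target",
                            ScanParams(max_exceptions=1), self.gm)
        assert v1.passed and v1.exceptions == ["out0"]

    def test_split_clade_always_fails(self):
        rows = dict(self.msa.rows)
        rows["in0"] = rows["out0"]  # clade member lacks the insert
        msa = Msa("f", rows)
        [block] = find_indel_blocks(msa)
        v = classify_block(block, self.clade_map, "target",
                           ScanParams(max_exceptions=5), self.gm)
        assert not v.passed and "unanimous" in v.reason

    def test_complementary_clade_sees_the_deletion(self):
        # in a two-clade universe an insert in one clade is, equivalently, a
        # deletion specific to the other; both readings are clean verdicts
        v = classify_block(self.block, self.clade_map, "rest", ScanParams(),
                           self.gm)
        assert v.passed and v.indel_type == "deletion" and v.exceptions == []

    def test_third_clade_blocks_specificity(self):
        clade_map = dict(self.clade_map)
        for sid in ("out7", "out8"):
            clade_map[sid] = "third"
        # scanning "rest": the two "third" genomes share the gap state, so
        # they surface as exceptions and break exclusivity
        v = classify_block(self.block, clade_map, "rest", ScanParams(),
                           self.gm)
        assert not v.passed and v.exceptions == ["out7", "out8"]


class TestFlankConservation:
    def test_fully_conserved_windows_count_forty(self):
        msa = _clade_msa()
        [block] = find_indel_blocks(msa)
        left, right, ok = flank_conservation(msa, block, ScanParams())
        assert (left, right, ok) == (40, 40, True)

    def test_exactly_three_conserved_fails_four_passes(self):
        for n_conserved, expect in ((3, False), (4, True)):
            msa = _noisy_left_flank(n_conserved)
            [block] = find_indel_blocks(msa)
            left, right, ok = flank_conservation(msa, block, ScanParams())
            assert left == n_conserved
            assert ok is expect

    def test_counts_match_brute_force_census(self):
        rng = np.random.default_rng(19)
        params = ScanParams()
        from oracles import _census

        for _ in range(40):
            rows = random_alignment(rng, max_rows=8, max_cols=100)
            msa = Msa("f", rows)
            for block in find_indel_blocks(msa):
                left, right, _ = flank_conservation(msa, block, params)
                s, e = block.cols
                rlist = list(rows.values())
                assert left == _census(
                    rlist, max(1, s - 40), s - 1, params)
                assert right == _census(
                    rlist, e + 1, min(msa.ncols, e + 40), params)


def _noisy_left_flank(n_conserved):
    """Left window with exactly n conserved columns; right fully conserved."""
    rng = np.random.default_rng(99)
    ncols_left = 40
    rows = {f"r{i}": [] for i in range(6)}
    for c in range(ncols_left):
        if c < n_conserved:
            ch = AAS[rng.integers(0, 20)]
            for r in rows.values():
                r.append(ch)
        else:
            # de-conserve: one row differs
            ch = "A"
            for i, r in enumerate(rows.values()):
                r.append("W" if i == 0 else ch)
    left = {k: "".join(v) for k, v in rows.items()}
    right = "MKVLTAGHQW" * 4
    out = {}
    for i, (k, v) in enumerate(left.items()):
        mid = "CC" if i < 3 else "--"
        out[k] = v + mid + right
    return Msa("f", out)


class TestScan:
    def test_recovers_planted_indels_exactly(self, planted_cohort,
                                             default_params):
        mut, manifest = planted_cohort
        gm = mut.genome_map
        records = scan_all_clades(
            mut.alignments.values(), mut.proteomes.clade_map,
            default_params, gm,
        )
        key = lambda r: (r.family_id, r.clade, r.block_cols, r.indel_type)
        assert sorted(map(key, records)) == sorted(map(key, manifest.records))

    def test_planted_family_is_silent_for_other_clades(self, planted_cohort,
                                                       default_params):
        mut, manifest = planted_cohort
        gm = mut.genome_map
        rec = manifest.records[0]
        other = [c for c in mut.proteomes.clades if c != rec.clade]
        for clade in other:
            assert scan_clade_csis(
                [mut.alignments[rec.family_id]], mut.proteomes.clade_map,
                clade, default_params, gm,
            ) == []

    def test_one_aa_deletion_recovered_as_deletion(self, small_cohort,
                                                   default_params):
        from indelsig.simulate import PlantSpec, plant_csis

        fid = sorted(small_cohort.alignments)[0]
        mut, manifest = plant_csis(
            small_cohort, [PlantSpec(fid, "B", "deletion", 1, 80)],
            default_params, seed=41,
        )
        records = scan_clade_csis(
            [mut.alignments[fid]], mut.proteomes.clade_map, "B",
            default_params, mut.genome_map,
        )
        assert len(records) == 1
        assert records[0].indel_type == "deletion"
        assert records[0].indel_length == 1

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        params = ScanParams()
        for trial in range(150):
            rows = random_alignment(rng)
            msa = Msa(f"t{trial}", rows)
            gm = {sid: sid for sid in rows}
            labels = [f"c{int(rng.integers(0, 3))}" for _ in rows]
            if len(set(labels)) < 2:
                labels[0] = "c_extra"
            clade_map = dict(zip(rows, labels))
            for clade in set(labels):
                got = records_as_tuples(
                    scan_clade_csis([msa], clade_map, clade, params, gm))
                assert got == brute_force_scan(msa, clade_map, clade, params,
                                               gm)

    def test_stricter_parameters_never_add_records(self):
        rng = np.random.default_rng(23)
        base = ScanParams(max_exceptions=2, min_conserved_flank=2)
        stricter = [
            ScanParams(max_exceptions=1, min_conserved_flank=2),
            ScanParams(max_exceptions=2, min_conserved_flank=4),
            ScanParams(max_exceptions=0, min_conserved_flank=6),
        ]
        for trial in range(60):
            rows = random_alignment(rng, max_rows=8, max_cols=80)
            msa = Msa(f"t{trial}", rows)
            gm = {sid: sid for sid in rows}
            clade_map = {
                sid: ("p" if i % 2 else "q") for i, sid in enumerate(rows)
            }
            loose = records_as_tuples(
                scan_all_clades([msa], clade_map, base, gm))
            for params in stricter:
                tight = records_as_tuples(
                    scan_all_clades([msa], clade_map, params, gm))
                assert {t[0] for t in tight} <= {t[0] for t in loose}


class TestValidate:
    def test_scan_emission_round_trips(self, planted_cohort, default_params):
        mut, manifest = planted_cohort
        gm = mut.genome_map
        records = scan_all_clades(
            mut.alignments.values(), mut.proteomes.clade_map,
            default_params, gm,
        )
        for rec in records:
            ok, reasons = validate_csi(
                mut.alignments[rec.family_id], rec, default_params,
                mut.proteomes.clade_map, gm,
            )
            assert ok, reasons

    def test_tampered_record_is_rejected_with_reason(self, planted_cohort,
                                                     default_params):
        mut, manifest = planted_cohort
        rec = manifest.records[0]
        gm = mut.genome_map
        shifted = CsiRecord(
            family_id=rec.family_id,
            reference_seq_id=rec.reference_seq_id,
            indel_type=rec.indel_type,
            indel_length=rec.indel_length + 1,
            block_cols=(rec.block_cols[0], rec.block_cols[1] + 1),
            ref_region=rec.ref_region,
            clade=rec.clade,
        )
        ok, reasons = validate_csi(
            mut.alignments[rec.family_id], shifted, default_params,
            mut.proteomes.clade_map, gm,
        )
        assert not ok and reasons
        wrong_region = CsiRecord(**{**rec.__dict__,
                                    "ref_region": (1, rec.ref_region[1])})
        ok2, reasons2 = validate_csi(
            mut.alignments[rec.family_id], wrong_region, default_params,
            mut.proteomes.clade_map, gm,
        )
        assert not ok2
        assert any("ref_region" in r for r in reasons2)

    def test_dangling_reference_is_error(self, planted_cohort, default_params):
        mut, manifest = planted_cohort
        rec = manifest.records[0]
        bad = CsiRecord(**{**rec.__dict__, "reference_seq_id": "ghost|x"})
        with pytest.raises(ValueError, match="ghost"):
            validate_csi(
                mut.alignments[rec.family_id], bad, default_params,
                mut.proteomes.clade_map, mut.genome_map,
            )
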