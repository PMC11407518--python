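"""Independent brute-force oracles used by the test suite.

These re-derive the scanner's output directly from the definitions —
exhaustive interval enumeration, per-column censuses, per-member threshold
re-checks — without touching the implementation's internals, so agreement is
meaningful evidence of correctness.
"""

from __future__ import annotations

GAP = "-"
UNKNOWN = "X"


def brute_force_scan(msa, clade_map, target_clade, params, genome_map):
    """All CSIs for one clade by exhaustive enumeration + definitional filter.

    Returns a set of tuples
    (block_cols, indel_type, exceptions, missing, flank_counts).
    """
    ids = list(msa.rows)
    rows = [msa.rows[i] for i in ids]
    n = msa.ncols
    found = set()
    for s in range(1, n + 1):
        for e in range(s, n + 1):
            if not (params.min_indel_len <= e - s + 1 <= params.max_indel_len):
                continue
            states = []
            consistent = True
            for row in rows:
                seg = row[s - 1 : e]
                if seg == GAP * len(seg):
                    states.append("gap")
                elif GAP not in seg:
                    states.append("res")
                else:
                    consistent = False
                    break
            if not consistent:
                continue
            if "gap" not in states or "res" not in states:
                continue
            # maximality: one more column on either side must break consistency
            if _extensible(rows, s, e, n):
                continue
            verdict = _classify(ids, states, clade_map, target_clade, params,
                                genome_map)
            if verdict is None:
                continue
            indel_type, exceptions, missing = verdict
            left = _census(rows, max(1, s - params.flank_window), s - 1, params)
            right = _census(rows, e + 1, min(n, e + params.flank_window), params)
            if left < params.min_conserved_flank or right < params.min_conserved_flank:
                continue
            found.add(((s, e), indel_type, exceptions, missing, (left, right)))
    return found


def _extensible(rows, s, e, n):
    for ns, ne in ((s - 1, e), (s, e + 1)):
        if ns < 1 or ne > n:
            continue
        ok = True
        for row in rows:
            seg = row[ns - 1 : ne]
            if GAP in seg and seg != GAP * len(seg):
                ok = False
                break
        if ok:
            return True
    return False


def _classify(ids, states, clade_map, target_clade, params, genome_map):
    genome_state = {}
    for sid, st in zip(ids, states):
        genome_state[genome_map[sid]] = st
    clade_genomes = [g for g, c in clade_map.items() if c == target_clade]
    present = [g for g in clade_genomes if g in genome_state]
    missing = tuple(sorted(g for g in clade_genomes if g not in genome_state))
    if missing and not params.allow_missing:
        return None
    if len(present) < 2:
        return None
    clade_states = {genome_state[g] for g in present}
    if len(clade_states) != 1:
        return None
    S = clade_states.pop()
    outside = [g for g in genome_state if g not in clade_genomes]
    exceptions = tuple(sorted(g for g in outside if genome_state[g] == S))
    if not any(genome_state[g] != S for g in outside):
        return None
    if len(exceptions) > params.max_exceptions:
        return None
    indel_type = "deletion" if S == "gap" else "insertion"
    return indel_type, exceptions, missing


def _census(rows, lo, hi, params):
    count = 0
    for c in range(lo, hi + 1):
        col = [row[c - 1] for row in rows]
        if GAP in col:
            continue
        freqs = {}
        for ch in col:
            if ch != UNKNOWN:
                freqs[ch] = freqs.get(ch, 0) + 1
        if freqs and max(freqs.values()) / len(col) >= params.conserved_fraction:
            count += 1
    return count


def records_as_tuples(records):
    """Scanner records in the oracle's comparison form."""
    return {
        (r.block_cols, r.indel_type, tuple(r.exceptions), tuple(r.missing),
         r.flank_conserved)
        for r in records
    }


def random_alignment(rng, max_rows=12, max_cols=120):
    """A random alignment with conserved columns and block/ragged gap runs."""
    n_rows = int(rng.integers(3, max_rows + 1))
    n_cols = int(rng.integers(20, max_cols + 1))
    aas = "ACDEFGHIKLMNPQRSTVWY"
    cols = []
    for _ in range(n_cols):
        if rng.random() < 0.6:  # conserved column
            cols.append([aas[rng.integers(0, 20)]] * n_rows)
        else:
            cols.append([aas[rng.integers(0, 20)] for _ in range(n_rows)])
    rows = ["".join(c[r] for c in cols) for r in range(n_rows)]
    for _ in range(int(rng.integers(0, 5))):
        length = int(rng.integers(1, 9))
        start = int(rng.integers(0, n_cols - length + 1))
        k = int(rng.integers(1, n_rows))
        which = rng.choice(n_rows, size=k, replace=False)
        for r in which:
            row = rows[r]
            if rng.random() < 0.8:  # clean block
                rows[r] = row[:start] + GAP * length + row[start + length:]
            else:  # ragged: jitter the run per row
                js = max(0, start + int(rng.integers(-2, 3)))
                je = min(n_cols, js + length)
                rows[r] = row[:js] + GAP * (je - js) + row[je:]
    return {f"r{i:02d}": rows[i] for i in range(n_rows)}
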