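#!/usr/bin/env python
"""Render figure-style excerpts for the first insertion and first deletion.

The excerpt convention follows signature-indel publications: top line is the
reference sequence over the flanked region, dashes mean identity with the
top line, blanks mean a gap, and the indel columns are starred. Writes
results/csi_examples.txt.
"""

from pathlib import Path

from indelsig.io import read_alignment_fasta, read_clade_map
from indelsig.model import ScanParams
from indelsig.render import render_csi_text
from indelsig.simulate import TruthManifest

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"


def main() -> None:
    clade_map = read_clade_map(COHORT / "clade_map.tsv")
    manifest = TruthManifest.from_json(COHORT / "truth_manifest.json")
    picks = {}
    for rec in manifest.records:
        picks.setdefault(rec.indel_type, rec)
    blocks = []
    for rec in picks.values():
        msa = read_alignment_fasta(COHORT / "alignments" / f"{rec.family_id}.afa")
        labels = {sid: f"{sid.split('|')[0]} ({clade_map[sid.split('|')[0]]})"
                  for sid in msa.rows}
        blocks.append(render_csi_text(msa, rec, labels=labels,
                                      params=ScanParams()))
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "csi_examples.txt"
    out.write_text("\n".join(blocks))
    for rec in picks.values():
        print(f"{rec.indel_type}: {rec.indel_length} aa in {rec.family_id} "
              f"(clade {rec.clade}, region {rec.ref_region[0]}–{rec.ref_region[1]})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
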