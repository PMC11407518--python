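"""Publication-style CSI alignment excerpts and summary tables.

The excerpt format follows the signature-indel literature: the top line is
the reference sequence over the flanked region; in every other row a dash
means identity with the residue on the top line, a letter a difference, and
a blank a gap. The indel columns are marked by ``*`` in a marker line. The
text form is deterministic and losslessly parseable (used as a test oracle);
an HTML variant highlights the indel block.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .model import GAP, CsiRecord, Msa, ScanParams

IDENT = "-"
GAP_GLYPH = " "
MARKER = "*"


def _span(msa: Msa, record: CsiRecord, params: ScanParams) -> tuple[int, int]:
    s, e = record.block_cols
    return max(1, s - params.flank_window), min(msa.ncols, e + params.flank_window)


def render_csi_text(
    msa: Msa,
    record: CsiRecord,
    labels: Mapping[str, str] | None = None,
    params: ScanParams | None = None,
    width: int = 60,
) -> str:
    """Render one CSI as a fixed-width text block.

    ``labels`` maps seq_id to a display name (species + accession); the
    reference row is printed first and verbatim, other rows use the
    dash-identity convention. Raises if the record does not refer to rows
    and columns of this alignment.
    """
    params = params or ScanParams()
    if record.reference_seq_id not in msa.rows:
        raise ValueError(
            f"reference {record.reference_seq_id!r} not in alignment"
        )
    s, e = record.block_cols
    if not (1 <= s <= e <= msa.ncols):
        raise ValueError(f"block columns {record.block_cols} out of range")
    labels = labels or {}
    lo, hi = _span(msa, record, params)
    ref_id = record.reference_seq_id
    ref = msa.rows[ref_id][lo - 1 : hi]
    order = [ref_id] + [sid for sid in msa.rows if sid != ref_id]
    name = {sid: labels.get(sid, sid) for sid in order}
    lw = max(len(n) for n in name.values())
    size = f"{record.indel_length} aa {'Ins' if record.indel_type == 'insertion' else 'Del'}"
    lines = [
        f"# {msa.family_id} | {record.clade} | {size} | "
        f"region {record.ref_region[0]}–{record.ref_region[1]} | "
        f"columns {lo}–{hi}"
    ]
    marker_full = "".join(
        MARKER if s <= c <= e else " " for c in range(lo, hi + 1)
    )
    for off in range(0, hi - lo + 1, width):
        chunk = slice(off, off + width)
        lines.append("")
        lines.append(" " * lw + "  " + marker_full[chunk])
        top = ref[chunk]
        lines.append(name[ref_id].ljust(lw) + "  "
                     + top.replace(GAP, GAP_GLYPH))
        for sid in order[1:]:
            row = msa.rows[sid][lo - 1 : hi][chunk]
            shown = []
            for rch, tch in zip(row, top):
                if rch == GAP:
                    shown.append(GAP_GLYPH)
                elif rch == tch:
                    shown.append(IDENT)
                else:
                    shown.append(rch)
            lines.append(name[sid].ljust(lw) + "  " + "".join(shown))
    return "\n".join(lines) + "\n"


def parse_csi_text(text: str) -> dict[str, str]:
    """Invert :func:`render_csi_text`: recover each row's aligned span.

    Returns display label -> aligned string (with ``'-'`` gaps), proving the
    rendering is lossless for residues and gap placement.
    """
    data = [
        line for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    # the label field has a fixed width: the longest label is unpadded, so its
    # first double space sits exactly at the field boundary
    lw = max(
        _label_width(line) for line in data if line[:1].strip()
    )
    chunks: dict[str, list[str]] = {}
    top_label: str | None = None
    order: list[str] = []
    for line in data:
        label = line[:lw].rstrip()
        body = line[lw + 2 :]
        if not label:
            continue  # marker line
        if top_label is None:
            top_label = label
        if label not in chunks:
            chunks[label] = []
            order.append(label)
        chunks[label].append(body)
    rows: dict[str, str] = {}
    top = "".join(chunks[top_label])
    rows[top_label] = top.replace(GAP_GLYPH, GAP)
    for label in order[1:]:
        body = "".join(chunks[label])
        body = body.ljust(len(top))
        out = []
        for rch, tch in zip(body, top):
            if rch == GAP_GLYPH:
                out.append(GAP)
            elif rch == IDENT:
                out.append(tch if tch != GAP_GLYPH else GAP)
            else:
                out.append(rch)
        rows[label] = "".join(out)
    return rows


def _label_width(line: str) -> int:
    # label field ends at the first run of two spaces
    return line.index("  ")


def render_csi_html(
    msa: Msa,
    record: CsiRecord,
    labels: Mapping[str, str] | None = None,
    params: ScanParams | None = None,
    width: int = 60,
) -> str:
    """HTML variant: the text block in <pre> with the indel columns spanned."""
    text = render_csi_text(msa, record, labels=labels, params=params, width=width)
    body = text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    return (
        "<html><body><pre style=\"font-family:monospace\">"
        f"{body}"
        "</pre></body></html>\n"
    )


_TABLE_COLUMNS = [
    "csi_id", "protein", "accession", "indel_size", "indel_position",
    "specificity", "footnotes", "family_id", "clade", "indel_type",
    "indel_length", "block_start", "block_end", "ref_start", "ref_end",
    "reference_seq_id", "exceptions", "missing",
    "flank_conserved_left", "flank_conserved_right",
]


def export_csi_table(
    records: Iterable[CsiRecord],
    protein_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate CSIs in the conventional summary-table style.

    Size renders as ``"<n> aa Ins|Del"``, position as ``"<a>–<b>"`` (the
    flanked reference region); footnote flags: ``*`` isolated exception(s)
    outside the clade, ``†`` homologue not detected in some species. Extra
    machine-readable columns allow records to be reconstructed.
    """
    protein_names = protein_names or {}
    rows = []
    ordered = sorted(records, key=lambda r: (r.clade, r.family_id, r.block_cols))
    for i, r in enumerate(ordered, start=1):
        flags = ("*" if r.exceptions else "") + ("†" if r.missing else "")
        rows.append(
            {
                "csi_id": f"CSI_{i:04d}",
                "protein": protein_names.get(r.family_id, r.family_id),
                "accession": r.reference_seq_id,
                "indel_size": f"{r.indel_length} aa "
                              f"{'Ins' if r.indel_type == 'insertion' else 'Del'}",
                "indel_position": f"{r.ref_region[0]}–{r.ref_region[1]}",
                "specificity": r.clade,
                "footnotes": flags,
                "family_id": r.family_id,
                "clade": r.clade,
                "indel_type": r.indel_type,
                "indel_length": r.indel_length,
                "block_start": r.block_cols[0],
                "block_end": r.block_cols[1],
                "ref_start": r.ref_region[0],
                "ref_end": r.ref_region[1],
                "reference_seq_id": r.reference_seq_id,
                "exceptions": ";".join(r.exceptions),
                "missing": ";".join(r.missing),
                "flank_conserved_left": r.flank_conserved[0],
                "flank_conserved_right": r.flank_conserved[1],
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def records_from_table(df: pd.DataFrame) -> list[CsiRecord]:
    """Rebuild :class:`CsiRecord` objects from an exported table."""
    out = []
    for _, row in df.iterrows():
        out.append(
            CsiRecord(
                family_id=row["family_id"],
                reference_seq_id=row["reference_seq_id"],
                indel_type=row["indel_type"],
                indel_length=int(row["indel_length"]),
                block_cols=(int(row["block_start"]), int(row["block_end"])),
                ref_region=(int(row["ref_start"]), int(row["ref_end"])),
                clade=row["clade"],
                exceptions=[x for x in str(row["exceptions"] or "").split(";") if x],
                missing=[x for x in str(row["missing"] or "").split(";") if x],
                flank_conserved=(int(row["flank_conserved_left"]),
                                 int(row["flank_conserved_right"])),
            )
        )
    return out
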