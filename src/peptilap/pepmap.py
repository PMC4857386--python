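"""Layered peptide-coverage maps over aligned precursor groups.

For each pro-hormone precursor family this builds the "visualization
database" view: the member precursors as (optionally pre-aligned) sequence
rows, with three layers mapped onto the alignment — the identified
peptides, the assembled LPVs, and the known reference peptides from the
annotation effort.  In-vivo modifications (pyro-Glu, amidation, acetylation,
phosphorylation) are rendered inline as a parenthesised tag after the
modified residue.  Export goes to JSON/TSV for programmatic use and to a
spreadsheet with one sheet per group and hyperlinked accessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .assembly import LPV, PlacedPeptide
from .model import ModKind, PeptideFeature, PrecursorProtein
from .ortho import OrthoGroup

GAP = "-"

_TAGS = {
    ModKind.PYRO_GLU.value: "pyro-Glu",
    ModKind.AMIDE_CTERM.value: "amide",
    ModKind.ACETYL_NTERM.value: "acetyl",
    ModKind.PHOSPHO.value: "phospho",
}

_UNIPROT_URL = "https://www.uniprot.org/uniprotkb/{accession}"


class AlignmentError(ValueError):
    """An alignment row does not ungap to its member sequence."""


@dataclass
class MapRow:
    label: str
    kind: str  # "sequence" | "peptide" | "lpv" | "reference"
    accession: str
    text: str


@dataclass
class AlignedGroupMap:
    group_id: str
    rows: list[MapRow] = field(default_factory=list)


def ungap(row: str) -> str:
    return row.replace(GAP, "")


def map_span_to_alignment(start: int, end: int, gapped_row: str) -> tuple[int, int]:
    """Map an ungapped 1-based inclusive span to 1-based alignment columns.

    The returned column range covers exactly the residues of the span;
    leading/trailing gap columns are excluded.
    """
    residue_cols = [i + 1 for i, ch in enumerate(gapped_row) if ch != GAP]
    if start < 1 or end > len(residue_cols):
        raise ValueError(f"span {start}..{end} outside sequence of length {len(residue_cols)}")
    return residue_cols[start - 1], residue_cols[end - 1]


def _render_layer_row(
    gapped_row: str,
    start: int,
    end: int,
    mods: Sequence[tuple[str, int, bool]] = (),
) -> str:
    """Render one peptide as an alignment-width string: residues inside the
    span (gaps preserved), spaces outside, in-vivo modification tags in
    parentheses after the modified residue."""
    tags: dict[int, list[str]] = {}
    for kind, pos, _localized in sorted(mods):
        tag = _TAGS.get(kind)
        if tag is not None and start <= pos <= end:
            tags.setdefault(pos, []).append(tag)
    col_start, col_end = map_span_to_alignment(start, end, gapped_row)
    out = []
    residue_index = 0
    for col, ch in enumerate(gapped_row, start=1):
        if ch != GAP:
            residue_index += 1
        if col < col_start or col > col_end:
            out.append(" ")
        elif ch == GAP:
            out.append(GAP)
        else:
            out.append(ch)
            for tag in tags.get(residue_index, ()):
                out.append(f"({tag})")
    return "".join(out).rstrip()


def build_group_map(
    group: OrthoGroup,
    proteins: Mapping[str, PrecursorProtein],
    peptides: Sequence[PlacedPeptide] = (),
    lpvs: Sequence[LPV] = (),
    references: Optional[Sequence[PeptideFeature]] = None,
    alignment: Optional[Mapping[str, str]] = None,
) -> AlignedGroupMap:
    """Assemble the layered map for one group.

    ``alignment`` maps accession -> gapped row; it is mandatory for
    multi-member groups (alignment computation is external) and defaults to
    the bare sequence for single-member groups.  Layer order is: member
    sequences, identified peptides, LPVs, reference peptides.
    """
    members = sorted(set(group.members) & set(proteins))
    if alignment is None:
        if len(members) > 1:
            raise AlignmentError(
                f"group {group.group_id} has {len(members)} members; an alignment is required"
            )
        alignment = {acc: proteins[acc].sequence for acc in members}
    for acc in members:
        if acc not in alignment:
            raise AlignmentError(f"no alignment row for member {acc}")
        if ungap(alignment[acc]) != proteins[acc].sequence:
            raise AlignmentError(f"alignment row for {acc} does not match its sequence")

    gmap = AlignedGroupMap(group_id=group.group_id)
    for acc in members:
        gmap.rows.append(MapRow(label=acc, kind="sequence", accession=acc, text=alignment[acc]))
    for pep in sorted(peptides, key=lambda p: p.anchor):
        gmap.rows.append(
            MapRow(
                label=f"peptide {pep.start}-{pep.end}",
                kind="peptide",
                accession=pep.accession,
                text=_render_layer_row(alignment[pep.accession], pep.start, pep.end,
                                       sorted(pep.modifications)),
            )
        )
    for lpv in sorted(lpvs, key=lambda l: l.anchor):
        gmap.rows.append(
            MapRow(
                label=f"LPV {lpv.start}-{lpv.end}",
                kind="lpv",
                accession=lpv.accession,
                text=_render_layer_row(alignment[lpv.accession], lpv.start, lpv.end,
                                       sorted(lpv.modifications)),
            )
        )
    refs = group.reference_peptides if references is None else references
    for ref in sorted(refs, key=lambda r: (r.accession, r.start, r.end)):
        if ref.accession not in alignment:
            continue
        gmap.rows.append(
            MapRow(
                label=f"reference {ref.name or ''} {ref.start}-{ref.end}".strip(),
                kind="reference",
                accession=ref.accession,
                text=_render_layer_row(alignment[ref.accession], ref.start, ref.end),
            )
        )
    return gmap


def strip_layer_row(text: str) -> str:
    """Inverse of the layer renderer: remove spaces, gaps and modification
    tags, recovering the plain peptide sequence."""
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            i = text.index(")", i) + 1
            continue
        if ch not in (" ", GAP):
            out.append(ch)
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def maps_to_json(maps: Sequence[AlignedGroupMap], path: str | Path) -> None:
    payload = [
        {
            "group_id": m.group_id,
            "rows": [
                {"label": r.label, "kind": r.kind, "accession": r.accession, "text": r.text}
                for r in m.rows
            ],
        }
        for m in sorted(maps, key=lambda m: m.group_id)
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def maps_to_xlsx(maps: Sequence[AlignedGroupMap], path: str | Path) -> None:
    """One sheet per group; accession cells hyperlink to their database
    entry.  Workbook metadata is pinned so identical inputs give identical
    files."""
    import datetime

    from openpyxl import Workbook

    wb = Workbook()
    wb.remove(wb.active)
    wb.properties.created = datetime.datetime(2000, 1, 1)
    wb.properties.modified = datetime.datetime(2000, 1, 1)
    for m in sorted(maps, key=lambda m: m.group_id):
        ws = wb.create_sheet(title=str(m.group_id)[:31])
        for i, row in enumerate(m.rows, start=1):
            label_cell = ws.cell(row=i, column=1, value=row.label)
            if row.kind == "sequence":
                label_cell.hyperlink = _UNIPROT_URL.format(accession=row.accession)
            ws.cell(row=i, column=2, value=row.kind)
            ws.cell(row=i, column=3, value=row.text)
    wb.save(str(path))
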