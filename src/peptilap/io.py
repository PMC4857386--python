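"""Readers and writers for evidence tables, FASTA files and result tables.

Two evidence dialects are supported:

``generic_tsv``
    Columns ``sequence``, ``modifications``, ``accessions``, ``sample``,
    ``msms_count`` and optional ``intensity``.  Modifications use the
    canonical grammar ``kind@position`` joined by ``;`` with 1-based
    positions within the peptide, e.g. ``phospho@3;amide_cterm@13``.
    An unlocalized phosphosite carries a trailing ``?`` (``phospho@3?``).

``maxquant_evidence``
    A MaxQuant evidence/peptides-style table.  Positions are recovered from
    the ``Modified sequence`` column, where modifications appear as
    parenthesised tokens after the residue, e.g. ``_(ac)SYS(ph)MEHFRW_``.

Rows violating the domain invariants (too short, bad symbols, inconsistent
modification positions) are collected and reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    DEFAULT_MIN_LENGTH,
    InvariantError,
    ModKind,
    ModificationEvent,
    PeptideObservation,
    PrecursorProtein,
)

logger = logging.getLogger(__name__)


class EvidenceFormatError(ValueError):
    """The evidence file lacks a mandatory column or is otherwise malformed."""


class ModificationParseError(ValueError):
    """A modification string could not be interpreted."""


@dataclass
class RejectedRow:
    """An input row that failed a domain invariant, kept for reporting."""

    row_number: int
    sequence: str
    reason: str


# ---------------------------------------------------------------------------
# canonical modification grammar
# ---------------------------------------------------------------------------

def parse_modifications(text: str) -> list[ModificationEvent]:
    """Parse the canonical ``kind@pos`` grammar into ModificationEvents."""
    text = (text or "").strip()
    if not text:
        return []
    events = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if "@" not in token:
            raise ModificationParseError(f"malformed modification token {token!r}")
        kind_str, _, pos_str = token.partition("@")
        localized = True
        if pos_str.endswith("?"):
            localized = False
            pos_str = pos_str[:-1]
        try:
            kind = ModKind(kind_str.strip())
        except ValueError as exc:
            raise ModificationParseError(f"unknown modification kind {kind_str!r}") from exc
        try:
            position = int(pos_str)
        except ValueError as exc:
            raise ModificationParseError(f"bad position in token {token!r}") from exc
        events.append(ModificationEvent(kind=kind, position=position, localized=localized))
    return events


def format_modifications(mods: Iterable[ModificationEvent]) -> str:
    """Inverse of :func:`parse_modifications` (canonical, sorted order)."""
    parts = []
    for m in sorted(mods, key=lambda m: (m.position, m.kind.value)):
        suffix = "" if m.localized else "?"
        parts.append(f"{m.kind.value}@{m.position}{suffix}")
    return ";".join(parts)


# MaxQuant-style parenthesised tokens inside a modified sequence string.
_MAXQUANT_TOKENS = {
    "ac": ModKind.ACETYL_NTERM,
    "gl": ModKind.PYRO_GLU,
    "pyr": ModKind.PYRO_GLU,
    "am": ModKind.AMIDE_CTERM,
    "ph": ModKind.PHOSPHO,
    "ox": ModKind.OXIDATION,
}


def parse_modified_sequence(modseq: str) -> tuple[str, list[ModificationEvent]]:
    """Parse a MaxQuant ``Modified sequence`` string such as
    ``_(ac)SYS(ph)MEHFRW(am)_`` into (stripped sequence, events)."""
    s = modseq.strip().strip("_")
    sequence_chars: list[str] = []
    events: list[ModificationEvent] = []
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "(":
            j = s.find(")", i)
            if j < 0:
                raise ModificationParseError(f"unbalanced parenthesis in {modseq!r}")
            token = s[i + 1 : j].lower()
            kind = _MAXQUANT_TOKENS.get(token)
            if kind is None:
                raise ModificationParseError(f"unknown modification token {token!r} in {modseq!r}")
            if kind is ModKind.ACETYL_NTERM or (kind is ModKind.PYRO_GLU and not sequence_chars):
                position = 1  # N-terminal token precedes the first residue
            else:
                position = len(sequence_chars)
            events.append(ModificationEvent(kind=kind, position=max(position, 1)))
            i = j + 1
        else:
            sequence_chars.append(ch.upper())
            i += 1
    seq = "".join(sequence_chars)
    # amide tokens written after the last residue end up at the final position
    fixed = []
    for ev in events:
        if ev.kind is ModKind.AMIDE_CTERM:
            fixed.append(ModificationEvent(ModKind.AMIDE_CTERM, len(seq)))
        else:
            fixed.append(ev)
    return seq, fixed


# ---------------------------------------------------------------------------
# evidence tables
# ---------------------------------------------------------------------------

_GENERIC_COLUMNS = ("sequence", "modifications", "accessions", "sample", "msms_count")
_MAXQUANT_COLUMNS = ("Sequence", "Modified sequence", "Proteins", "Experiment", "MS/MS Count")


def read_evidence(
    path: str | Path,
    dialect: str = "generic_tsv",
    min_length: int = DEFAULT_MIN_LENGTH,
    rejects: Optional[list[RejectedRow]] = None,
) -> list[PeptideObservation]:
    """Read a peptide evidence table into PeptideObservations.

    One row is one modification-specific peptide variant in one sample; the
    same peptide observed in several samples yields several observations.
    Rows failing invariants (notably the minimum-length filter) are appended
    to *rejects* and logged.

    Raises
    ------
    EvidenceFormatError
        if a mandatory column is missing.
    ModificationParseError
        if a modification token cannot be parsed (reported with row number).
    """
    path = Path(path)
    if dialect not in ("generic_tsv", "maxquant_evidence"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = _GENERIC_COLUMNS if dialect == "generic_tsv" else _MAXQUANT_COLUMNS
    for col in required[:4]:
        if col not in df.columns:
            raise EvidenceFormatError(f"evidence file {path} is missing column {col!r}")

    observations: list[PeptideObservation] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        record = dict(zip(df.columns, row))
        try:
            if dialect == "generic_tsv":
                sequence = record["sequence"].strip().upper()
                mods = parse_modifications(record["modifications"])
                accessions = [a for a in record["accessions"].replace(",", ";").split(";") if a]
                sample_id = record["sample"].strip()
                count = int(record["msms_count"]) if record.get("msms_count", "").strip() else 1
                intensity = (
                    float(record["intensity"]) if record.get("intensity", "").strip() else None
                )
            else:
                sequence, mods = parse_modified_sequence(record["Modified sequence"])
                plain = record.get("Sequence", "").strip().upper()
                if plain and plain != sequence:
                    raise ModificationParseError(
                        f"Sequence/Modified sequence mismatch: {plain!r} vs {sequence!r}"
                    )
                accessions = [a for a in record["Proteins"].replace(",", ";").split(";") if a]
                sample_id = record.get("Experiment", "").strip() or record.get("Raw file", "").strip()
                count_str = record.get("MS/MS Count", "").strip()
                count = int(count_str) if count_str else 1
                intensity_str = record.get("Intensity", "").strip()
                intensity = float(intensity_str) if intensity_str else None
        except ModificationParseError as exc:
            raise ModificationParseError(f"row {idx}: {exc}") from exc

        obs = PeptideObservation(
            sequence=sequence,
            modifications=mods,
            accessions=accessions,
            sample_id=sample_id,
            spectral_count=count,
            intensity=intensity,
        )
        try:
            obs.validate(min_length=min_length)
        except InvariantError as exc:
            reject = RejectedRow(row_number=idx, sequence=sequence, reason=str(exc))
            if rejects is not None:
                rejects.append(reject)
            logger.info("rejected evidence row %d (%s): %s", idx, sequence, exc)
            continue
        observations.append(obs)
    return observations


def write_evidence(observations: Sequence[PeptideObservation], path: str | Path) -> None:
    """Write observations as a generic TSV evidence table (round-trip safe)."""
    rows = [
        {
            "sequence": o.sequence,
            "modifications": format_modifications(o.modifications),
            "accessions": ";".join(o.accessions),
            "sample": o.sample_id,
            "msms_count": o.spectral_count,
            "intensity": "" if o.intensity is None else o.intensity,
        }
        for o in observations
    ]
    pd.DataFrame(rows, columns=["sequence", "modifications", "accessions", "sample",
                                "msms_count", "intensity"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[PrecursorProtein]:
    """Read precursor proteins from FASTA.

    The first whitespace-separated header token is the accession; a ``GN=``
    token, if present, is taken as the gene name.  Sequences are uppercased
    and ``*`` stop symbols stripped.  Duplicate accessions are an error.
    """
    proteins: list[PrecursorProtein] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        accession = rec.id
        seen[accession] = seen.get(accession, 0) + 1
        gene = None
        species = ""
        for token in rec.description.split():
            if token.startswith("GN="):
                gene = token[3:]
            elif token.startswith("OS="):
                species = token[3:]
        proteins.append(
            PrecursorProtein(
                accession=accession,
                sequence=str(rec.seq).upper().replace("*", ""),
                species=species,
                gene=gene,
                description=rec.description,
            )
        )
    duplicates = sorted(acc for acc, n in seen.items() if n > 1)
    if duplicates:
        raise ValueError(f"duplicate accessions in {path}: {duplicates}")
    return proteins


def write_fasta(proteins: Sequence[PrecursorProtein], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            header = p.accession
            if p.gene:
                header += f" GN={p.gene}"
            if p.species:
                header += f" OS={p.species}"
            fh.write(f">{header}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# result tables (LPVs, candidates, occupancies) — TSV and XLSX
# ---------------------------------------------------------------------------

def lpv_table(lpvs) -> pd.DataFrame:
    """Serialize assembled LPVs to a flat table (round-trip safe via
    :func:`lpvs_from_table`)."""
    rows = []
    for l in lpvs:
        mods = ";".join(
            f"{kind}@{pos}" + ("" if localized else "?")
            for kind, pos, localized in sorted(l.modifications)
        )
        rows.append(
            {
                "group_id": l.group_id,
                "accession": l.accession,
                "start": l.start,
                "end": l.end,
                "sequence": l.sequence,
                "n_term_blocked": l.n_term_blocked,
                "c_term_blocked": l.c_term_blocked,
                "modifications": mods,
                "support": ";".join(str(i) for i in sorted(l.support)),
                "n_support": len(l.support),
            }
        )
    cols = ["group_id", "accession", "start", "end", "sequence", "n_term_blocked",
            "c_term_blocked", "modifications", "support", "n_support"]
    return pd.DataFrame(rows, columns=cols)


def lpvs_from_table(df: pd.DataFrame) -> list:
    """Rebuild LPV records from a table written by :func:`lpv_table`."""
    from .assembly import LPV  # local import to keep io importable standalone

    out = []
    for rec in df.to_dict("records"):
        mods = set()
        for token in str(rec.get("modifications", "") or "").split(";"):
            token = token.strip()
            if not token:
                continue
            kind, _, pos = token.partition("@")
            localized = not pos.endswith("?")
            mods.add((kind, int(pos.rstrip("?")), localized))
        support = frozenset(
            int(x) for x in str(rec.get("support", "") or "").split(";") if x.strip()
        )
        out.append(
            LPV(
                sequence=str(rec["sequence"]),
                accession=str(rec["accession"]),
                start=int(rec["start"]),
                end=int(rec["end"]),
                n_term_blocked=_as_bool(rec["n_term_blocked"]),
                c_term_blocked=_as_bool(rec["c_term_blocked"]),
                support=support,
                modifications=frozenset(mods),
                group_id=str(rec["group_id"]),
            )
        )
    return out


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value)



def read_annotation_tables(
    features_path: Optional[str | Path] = None,
    genes_path: Optional[str | Path] = None,
    known_peptides_path: Optional[str | Path] = None,
):
    """Read the flat annotation sources into an AnnotationSet.

    ``features`` needs columns accession/start/end[/name]; ``genes`` a
    single ``gene`` column; ``known_peptides`` columns accession/sequence.
    """
    from .model import AnnotationSet, PeptideFeature

    features = []
    if features_path:
        df = pd.read_csv(features_path, sep="\t", keep_default_na=False)
        features = [
            PeptideFeature(str(r["accession"]), int(r["start"]), int(r["end"]),
                           str(r.get("name", "")))
            for r in df.to_dict("records")
        ]
    genes: list[str] = []
    if genes_path:
        df = pd.read_csv(genes_path, sep="\t", keep_default_na=False)
        genes = [str(g) for g in df["gene"]]
    known: list[tuple[str, str]] = []
    if known_peptides_path:
        df = pd.read_csv(known_peptides_path, sep="\t", keep_default_na=False)
        known = [(str(r["accession"]), str(r["sequence"])) for r in df.to_dict("records")]
    return AnnotationSet(
        uniprot_peptide_features=features,
        neuropeptide_genes=genes,
        known_peptides=known,
    )


def write_table(df: pd.DataFrame, path: str | Path, fmt: Optional[str] = None) -> None:
    """Write a result table as TSV or XLSX, inferred from the suffix."""
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix == ".xlsx" else "tsv")
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown output format {fmt!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".xlsx":
        return pd.read_excel(path)
    return pd.read_csv(path, sep="\t", keep_default_na=False)
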