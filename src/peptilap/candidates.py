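"""Bioactive-neuropeptide candidate filtering.

An assembled LPV is promoted to the candidate hotlist when its precursor
context matches canonical prohormone-convertase processing:

* N-terminal: K or R at position -1 immediately preceding the peptide;
* C-terminal: K/R at both +1 and +2 (dibasic site trailing the peptide),
  OR the peptide is C-terminally amidated with G at +1 (the glycine removed
  by peptidyl-glycine alpha-amidating monooxygenase).

The filter is a pure function of the flanking context and the amidation
state; abundance plays no role.  Candidate rows carry the display string
``UP.SEQUENCE.DOWN`` with ``*`` marking an amidated C-terminus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .assembly import LPV
from .model import PrecursorProtein
from .motifs import FlankContext, extract_flanks
from .ortho import GroupIndex

BASIC = frozenset("KR")


class CTermMode(str, enum.Enum):
    DIBASIC = "dibasic"
    AMIDE_G = "amide_G"
    NONE = "none"


@dataclass
class CandidateRecord:
    lpv: LPV
    flank: FlankContext
    n_term_pass: bool
    c_term_pass: bool
    c_term_mode: CTermMode

    @property
    def is_candidate(self) -> bool:
        return self.n_term_pass and self.c_term_pass

    @property
    def display(self) -> str:
        """Table-style display string: up-flank, sequence (with trailing *
        for an amidated C-terminus), down-flank."""
        star = "*" if self.flank.amidated else ""
        return f"{self.flank.up}.{self.lpv.sequence}{star}.{self.flank.down}"


def evaluate_candidate(lpv: LPV, flank: FlankContext) -> CandidateRecord:
    """Apply the convertase-context filter to one LPV.

    Padding '-' at a flank position (protein boundary) simply fails the
    test for that position; no signal-peptide logic is applied.
    """
    n_pass = flank.n_minus_1 in BASIC
    amidated = flank.amidated or lpv.is_amidated
    if amidated and flank.down_at(1) == "G":
        c_pass, mode = True, CTermMode.AMIDE_G
    elif flank.down_at(1) in BASIC and flank.down_at(2) in BASIC:
        c_pass, mode = True, CTermMode.DIBASIC
    else:
        c_pass, mode = False, CTermMode.NONE
    return CandidateRecord(
        lpv=lpv, flank=flank, n_term_pass=n_pass, c_term_pass=c_pass, c_term_mode=mode
    )


def evaluate_display_row(up: str, sequence: str, down: str, amidated: bool) -> CandidateRecord:
    """Evaluate a candidate given only its printed flanks and amidation
    state (e.g. a transcribed published table row)."""
    lpv = LPV(
        sequence=sequence, accession="", start=1, end=len(sequence),
        n_term_blocked=False, c_term_blocked=amidated,
        support=frozenset(), modifications=frozenset(),
    )
    flank = FlankContext(up=up, down=down, amidated=amidated)
    return evaluate_candidate(lpv, flank)


def load_reference_candidates() -> pd.DataFrame:
    """Load the bundled reference list of published rat-hypothalamus
    candidate neuropeptides (family, 3-residue flanks, sequence, amidation
    state).  Every row satisfies the convertase-context filter and the set
    exercises both C-terminal pass modes (dibasic and amide+G)."""
    from importlib import resources

    path = resources.files("peptilap") / "data" / "reference_candidates.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    df["amidated"] = df["amidated"].astype(str).str.lower() == "true"
    return df


def build_hotlist(
    lpvs: Sequence[LPV],
    proteins: Mapping[str, PrecursorProtein],
    group_index: Optional[GroupIndex] = None,
    restrict_prohormone: bool = True,
    flank_width: int = 3,
) -> list[CandidateRecord]:
    """Evaluate all LPVs and return the passing candidates, sorted by
    (group, anchor).  With *restrict_prohormone*, only LPVs from flagged
    pro-hormone precursor groups are considered (never adds candidates)."""
    records = []
    for lpv in sorted(lpvs, key=lambda l: (l.group_id, l.anchor)):
        if restrict_prohormone and group_index is not None:
            group = group_index.groups.get(lpv.group_id)
            if group is None or not group.is_prohormone:
                continue
        flank = extract_flanks(lpv, proteins[lpv.accession], k=flank_width)
        record = evaluate_candidate(lpv, flank)
        if record.is_candidate:
            records.append(record)
    return records


def hotlist_frame(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Tabular export of the hotlist (one row per candidate)."""
    return pd.DataFrame(
        [
            {
                "group_id": r.lpv.group_id,
                "accession": r.lpv.accession,
                "start": r.lpv.start,
                "end": r.lpv.end,
                "display": r.display,
                "c_term_mode": r.c_term_mode.value,
                "amidated": r.flank.amidated,
                "n_support": len(r.lpv.support),
            }
            for r in records
        ],
        columns=["group_id", "accession", "start", "end", "display",
                 "c_term_mode", "amidated", "n_support"],
    )
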