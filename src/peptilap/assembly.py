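"""Longest Peptide Variant (LPV) assembly.

Endogenous-peptide datasets are dominated by exopeptidase "ladders": series
of peptides differing by single terminal residues.  The assembly collapses
these by iteratively merging the pair of anchored peptides with the largest
sequence overlap until no allowed pair remains.  The surviving maximal
sequences — the LPVs — are the minimum set of peptides that explains every
identified peptide, and their termini reflect specific (convertase-like)
rather than unspecific protease activity.

Rules:

* overlap is the number of shared residues between two peptides anchored on
  the same precursor, with no gaps; a minimum overlap of two residues is
  required (containment counts as overlap);
* in-vivo terminal modifications block merging past the modified residue —
  no extension upstream of an acetylated/pyro-Glu N-terminus, and no
  extension downstream of an amidated C-terminus;
* every merged sequence is verified to be a substring of a member precursor;
* internal modifications (phosphorylation, oxidation) never block merging
  and are carried along in precursor coordinates.

Ties on the maximal overlap are broken by the lexicographically smallest
merged anchor (accession, start, end), making the output independent of
input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    ModKind,
    PeptideObservation,
    PrecursorProtein,
    TERMINAL_BLOCKERS_C,
    TERMINAL_BLOCKERS_N,
)
from .ortho import OrthoGroup

logger = logging.getLogger(__name__)

#: Minimum number of shared residues for two peptides to be mergeable.
MIN_OVERLAP = 2

# A precursor-coordinate modification: (kind value, 1-based position, localized)
SiteMod = tuple[str, int, bool]


@dataclass(frozen=True)
class PlacedPeptide:
    """A peptide anchored to a span of one precursor protein (1-based,
    inclusive coordinates)."""

    sequence: str
    accession: str
    start: int
    end: int
    n_term_blocked: bool = False
    c_term_blocked: bool = False
    support: frozenset = frozenset()
    modifications: frozenset = frozenset()  # of SiteMod

    @property
    def anchor(self) -> tuple[str, int, int]:
        return (self.accession, self.start, self.end)

    @property
    def key(self) -> tuple:
        """Unique, orderable identity used for deterministic tie-breaking."""
        return (self.accession, self.start, self.end, self.n_term_blocked, self.c_term_blocked)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class LPV:
    """A longest peptide variant: the maximal merged peptide of one
    precursor region, with its supporting evidence."""

    sequence: str
    accession: str
    start: int
    end: int
    n_term_blocked: bool
    c_term_blocked: bool
    support: frozenset
    modifications: frozenset
    group_id: str = ""

    @property
    def anchor(self) -> tuple[str, int, int]:
        return (self.accession, self.start, self.end)

    @property
    def is_amidated(self) -> bool:
        # amidation is the only C-terminal blocker ingested
        return self.c_term_blocked

    @property
    def is_phospho(self) -> bool:
        return any(kind == ModKind.PHOSPHO.value for kind, _, _ in self.modifications)


class AssemblyError(RuntimeError):
    """Internal consistency failure during merging."""


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_peptide(
    observation: PeptideObservation,
    group: OrthoGroup,
    proteins: Mapping[str, PrecursorProtein],
    obs_id: int = 0,
) -> Optional[PlacedPeptide]:
    """Anchor a peptide to the leftmost occurrence in the first member
    precursor (members ordered by accession) that contains its sequence.

    Returns None when no member contains the sequence; such peptides are
    reported and excluded from assembly.
    """
    seq = observation.sequence
    for accession in sorted(group.members):
        protein = proteins.get(accession)
        if protein is None:
            continue
        pos = protein.sequence.find(seq)
        if pos < 0:
            continue
        if protein.sequence.find(seq, pos + 1) >= 0:
            logger.info(
                "peptide %s occurs more than once in %s; leftmost occurrence used",
                seq, accession,
            )
        start = pos + 1
        mods = frozenset(
            (m.kind.value, start + m.position - 1, m.localized) for m in observation.modifications
        )
        return PlacedPeptide(
            sequence=seq,
            accession=accession,
            start=start,
            end=pos + len(seq),
            n_term_blocked=observation.n_term_blocked,
            c_term_blocked=observation.c_term_blocked,
            support=frozenset([obs_id]),
            modifications=mods,
        )
    return None


def place_observations(
    observations: Sequence[PeptideObservation],
    observation_ids: Sequence[int],
    group: OrthoGroup,
    proteins: Mapping[str, PrecursorProtein],
) -> tuple[list[PlacedPeptide], list[int]]:
    """Place and deduplicate a group's observations into the unique peptide
    set used for assembly.

    Deduplication is by (sequence, terminal-block state): modification-
    specific variants that differ only in internal modifications collapse
    into one placed peptide whose support and site modifications are the
    union.  Returns (unique placed peptides, ids of unplaceable
    observations).
    """
    unique: dict[tuple, PlacedPeptide] = {}
    unplaced: list[int] = []
    for obs, obs_id in zip(observations, observation_ids):
        placed = place_peptide(obs, group, proteins, obs_id=obs_id)
        if placed is None:
            unplaced.append(obs_id)
            logger.info("peptide %s not found in any member of %s", obs.sequence, group.group_id)
            continue
        key = placed.key
        if key in unique:
            prev = unique[key]
            unique[key] = replace(
                prev,
                support=prev.support | placed.support,
                modifications=prev.modifications | placed.modifications,
            )
        else:
            unique[key] = placed
    return [unique[k] for k in sorted(unique)], unplaced


# ---------------------------------------------------------------------------
# pairwise overlap and merging
# ---------------------------------------------------------------------------

def overlap_length(a: PlacedPeptide, b: PlacedPeptide) -> Optional[int]:
    """Number of shared residues between two anchored peptides, or None when
    merging is disallowed.

    Disallowed when the peptides sit on different precursors, share fewer
    than MIN_OVERLAP residues, or when merging would extend past a blocked
    terminus (amidated C-terminus, acetylated/pyro-Glu N-terminus).
    """
    if a.accession != b.accession:
        return None
    shared = min(a.end, b.end) - max(a.start, b.start) + 1
    if shared < MIN_OVERLAP:
        return None
    # terminal blockers: no extension past a blocked terminus
    if a.n_term_blocked and b.start < a.start:
        return None
    if b.n_term_blocked and a.start < b.start:
        return None
    if a.c_term_blocked and b.end > a.end:
        return None
    if b.c_term_blocked and a.end > b.end:
        return None
    return shared


def merge_pair(
    a: PlacedPeptide,
    b: PlacedPeptide,
    proteins: Mapping[str, PrecursorProtein],
) -> PlacedPeptide:
    """Merge two allowed-overlapping peptides into the shortest sequence
    containing both (the union of their anchor intervals)."""
    shared = overlap_length(a, b)
    if shared is None:
        raise AssemblyError(f"merge of non-overlapping peptides {a.anchor} and {b.anchor}")
    start = min(a.start, b.start)
    end = max(a.end, b.end)
    precursor = proteins[a.accession].sequence
    sequence = precursor[start - 1 : end]
    # terminal state comes from whichever peptide(s) provide each terminus
    n_block = (a.n_term_blocked and a.start == start) or (b.n_term_blocked and b.start == start)
    c_block = (a.c_term_blocked and a.end == end) or (b.c_term_blocked and b.end == end)
    merged = PlacedPeptide(
        sequence=sequence,
        accession=a.accession,
        start=start,
        end=end,
        n_term_blocked=n_block,
        c_term_blocked=c_block,
        support=a.support | b.support,
        modifications=a.modifications | b.modifications,
    )
    if precursor[start - 1 : end] != sequence or len(sequence) != end - start + 1:
        raise AssemblyError(f"merged sequence not a precursor substring at {merged.anchor}")
    return merged


# ---------------------------------------------------------------------------
# greedy assembly
# ---------------------------------------------------------------------------

def _pair_priority(a: PlacedPeptide, b: PlacedPeptide, shared: int) -> tuple:
    """Sort key: larger overlap first, then smallest merged anchor, then the
    smallest peptide identity pair (for full determinism)."""
    merged_anchor = (a.accession, min(a.start, b.start), max(a.end, b.end))
    lo, hi = sorted((a.key, b.key))
    return (-shared, merged_anchor, lo, hi)


def assemble_lpvs(
    placed: Iterable[PlacedPeptide],
    proteins: Mapping[str, PrecursorProtein],
    group_id: str = "",
) -> list[LPV]:
    """Iteratively merge the pair with the largest allowed overlap until no
    pair with overlap >= MIN_OVERLAP remains; the fixpoint set are the LPVs.

    Candidate pairs are maintained incrementally: after each merge only the
    pairs involving the new peptide are recomputed.  Output order is by
    anchor; the result is invariant to input order.
    """
    active: dict[tuple, PlacedPeptide] = {p.key: p for p in placed}
    # allowed pairs as {frozen pair of keys: priority}
    pairs: dict[tuple, tuple] = {}

    def add_pairs_for(p: PlacedPeptide) -> None:
        for q in active.values():
            if q.key == p.key:
                continue
            shared = overlap_length(p, q)
            if shared is not None:
                k = tuple(sorted((p.key, q.key)))
                pairs[k] = _pair_priority(p, q, shared)

    items = list(active.values())
    for i, p in enumerate(items):
        for q in items[i + 1 :]:
            shared = overlap_length(p, q)
            if shared is not None:
                k = tuple(sorted((p.key, q.key)))
                pairs[k] = _pair_priority(p, q, shared)

    while pairs:
        best_key = min(pairs, key=lambda k: pairs[k])
        ka, kb = best_key
        a, b = active.pop(ka), active.pop(kb)
        pairs = {k: v for k, v in pairs.items() if ka not in k and kb not in k}
        merged = merge_pair(a, b, proteins)
        # a merge can land on an existing peptide's identity; absorb support
        if merged.key in active:
            prev = active.pop(merged.key)
            pairs = {k: v for k, v in pairs.items() if merged.key not in k}
            merged = replace(
                merged,
                support=merged.support | prev.support,
                modifications=merged.modifications | prev.modifications,
            )
        active[merged.key] = merged
        add_pairs_for(merged)

    lpvs = [
        LPV(
            sequence=p.sequence,
            accession=p.accession,
            start=p.start,
            end=p.end,
            n_term_blocked=p.n_term_blocked,
            c_term_blocked=p.c_term_blocked,
            support=p.support,
            modifications=p.modifications,
            group_id=group_id,
        )
        for p in active.values()
    ]
    lpvs.sort(key=lambda l: (l.anchor, l.n_term_blocked, l.c_term_blocked))
    return lpvs


def assert_fixpoint(lpvs: Sequence[LPV]) -> None:
    """Raise AssemblyError if any pair of output LPVs still has an allowed
    overlap (the defining fixpoint property of the assembly)."""
    as_placed = [
        PlacedPeptide(
            sequence=l.sequence, accession=l.accession, start=l.start, end=l.end,
            n_term_blocked=l.n_term_blocked, c_term_blocked=l.c_term_blocked,
        )
        for l in lpvs
    ]
    for i, a in enumerate(as_placed):
        for b in as_placed[i + 1 :]:
            if overlap_length(a, b) is not None:
                raise AssemblyError(f"output not a fixpoint: {a.anchor} and {b.anchor} overlap")
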