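"""Orthologous protein groups and pro-hormone precursor annotation.

Identified peptides are organised by membership to cross-species orthologous
protein families (one group = one family).  A group is flagged as a
pro-hormone precursor family when any member carries evidence of encoding
processed bioactive peptides, aggregated from three sources: Uniprot-style
"Peptide" sequence features, a neuropeptide gene list, and known mature
peptide sequences.  Observations are then assigned to a single group when one
group explains all their proteins, or to a merged multi-group set otherwise,
with the pro-hormone flag propagated across the merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import AnnotationSet, PeptideFeature, PeptideObservation, PrecursorProtein

logger = logging.getLogger(__name__)


@dataclass
class OrthoGroup:
    """A family of orthologous precursor proteins."""

    group_id: str
    members: list[str]
    is_prohormone: bool = False
    reference_peptides: list[PeptideFeature] = field(default_factory=list)


@dataclass
class GroupIndex:
    """Accession -> group lookup plus the bin of unmapped accessions."""

    groups: dict[str, OrthoGroup]
    by_accession: dict[str, str]
    proteins: dict[str, PrecursorProtein]
    unmapped_accessions: list[str] = field(default_factory=list)

    def group_of(self, accession: str) -> Optional[OrthoGroup]:
        gid = self.by_accession.get(accession)
        return self.groups[gid] if gid is not None else None

    @property
    def n_prohormone(self) -> int:
        return sum(g.is_prohormone for g in self.groups.values())


@dataclass
class GroupAssignment:
    """Observations sharing one evidence protein group, assigned to one
    orthologous group or to a merged set of groups."""

    assigned_group_ids: tuple[str, ...]
    observation_ids: list[int]
    is_prohormone: bool


@dataclass
class AssignmentResult:
    assignments: list[GroupAssignment]
    unmapped_observation_ids: list[int]

    def assignment_of(self, obs_id: int) -> Optional[GroupAssignment]:
        for a in self.assignments:
            if obs_id in a.observation_ids:
                return a
        return None


# ---------------------------------------------------------------------------

def read_mapping_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (accession, group_id) TSV mapping table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns or "group_id" not in df.columns:
        raise ValueError(f"mapping table {path} needs columns 'accession' and 'group_id'")
    return list(zip(df["accession"], df["group_id"]))


def build_group_index(
    mapping: Iterable[tuple[str, str]],
    proteins: Sequence[PrecursorProtein],
) -> GroupIndex:
    """Build the accession -> orthologous-group framework.

    Each accession must map to exactly one group; a contradiction is an
    error.  Proteins absent from the mapping are held in a reported
    "unmapped" bin rather than dropped.
    """
    by_accession: dict[str, str] = {}
    groups: dict[str, OrthoGroup] = {}
    for accession, group_id in mapping:
        prev = by_accession.get(accession)
        if prev is not None and prev != group_id:
            raise ValueError(
                f"accession {accession} mapped to two groups: {prev} and {group_id}"
            )
        by_accession[accession] = group_id
        grp = groups.setdefault(group_id, OrthoGroup(group_id=group_id, members=[]))
        if accession not in grp.members:
            grp.members.append(accession)
    protein_index = {p.accession: p for p in proteins}
    unmapped = sorted(acc for acc in protein_index if acc not in by_accession)
    if unmapped:
        logger.info("%d proteins not covered by the group mapping", len(unmapped))
    return GroupIndex(
        groups=groups,
        by_accession=by_accession,
        proteins=protein_index,
        unmapped_accessions=unmapped,
    )


def flag_prohormone_groups(index: GroupIndex, annotations: AnnotationSet) -> GroupIndex:
    """Flag groups as pro-hormone precursor families (in place, returned).

    A group is flagged iff at least one member has a Peptide feature, OR a
    member's gene name appears in the neuropeptide gene list
    (case-insensitive exact match), OR a known mature peptide sequence is an
    exact substring of a member sequence.  Reference peptide spans from all
    sources are stored on the group, deduplicated, so re-flagging is
    idempotent and adding sources is monotone.
    """
    gene_set = {g.lower() for g in annotations.neuropeptide_genes}

    def add_reference(group: OrthoGroup, feat: PeptideFeature) -> None:
        if feat not in group.reference_peptides:
            group.reference_peptides.append(feat)
        group.is_prohormone = True

    for feat in annotations.uniprot_peptide_features:
        group = index.group_of(feat.accession)
        if group is None:
            logger.warning("Peptide feature for unknown accession %s skipped", feat.accession)
            continue
        protein = index.proteins.get(feat.accession)
        if protein is not None:
            feat.validate(len(protein.sequence))
        add_reference(group, feat)

    if gene_set:
        for group in index.groups.values():
            for acc in group.members:
                protein = index.proteins.get(acc)
                if protein and protein.gene and protein.gene.lower() in gene_set:
                    group.is_prohormone = True

    for accession, peptide in annotations.known_peptides:
        group = index.group_of(accession)
        if group is None:
            logger.warning("known peptide for unknown accession %s skipped", accession)
            continue
        for acc in group.members:
            protein = index.proteins.get(acc)
            if protein is None:
                continue
            start = protein.sequence.find(peptide)
            if start >= 0:
                add_reference(
                    group,
                    PeptideFeature(acc, start + 1, start + len(peptide), name="known peptide"),
                )
                break
    return index


def assign_observations(
    observations: Sequence[PeptideObservation],
    index: GroupIndex,
) -> AssignmentResult:
    """Assign observations to orthologous groups.

    Observations are keyed by their evidence protein group (the accession
    set reported for the row).  If a single orthologous group explains all
    those accessions it is assigned; if several are needed, a merged
    multi-group set is formed and the pro-hormone flag of any constituent
    propagates to the whole set.  Observations whose accessions are all
    unmapped go to the unmapped bin.  Every observation lands in exactly one
    assignment or the bin.
    """
    buckets: dict[tuple[str, ...], list[int]] = {}
    unmapped: list[int] = []
    for obs_id, obs in enumerate(observations):
        gids = sorted({index.by_accession[a] for a in obs.accessions if a in index.by_accession})
        if not gids:
            unmapped.append(obs_id)
            continue
        buckets.setdefault(tuple(gids), []).append(obs_id)

    assignments = [
        GroupAssignment(
            assigned_group_ids=gids,
            observation_ids=obs_ids,
            is_prohormone=any(index.groups[g].is_prohormone for g in gids),
        )
        for gids, obs_ids in sorted(buckets.items())
    ]
    return AssignmentResult(assignments=assignments, unmapped_observation_ids=unmapped)
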