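"""Shared domain types for endogenous-peptide (peptidomics) analysis.

The objects here describe modification-specific peptide observations from a
label-free LC-MS/MS peptidomics experiment, the precursor proteins they derive
from, and the annotation sources used to recognise pro-hormone precursors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_ACCEPTORS = frozenset("STY")

#: Minimum peptide length accepted by default; short sequences cannot be
#: identified confidently by MS/MS and are rejected at ingest.
DEFAULT_MIN_LENGTH = 6


class ModKind(str, enum.Enum):
    """Site-specific modifications of possible in-vivo origin (plus Met
    oxidation, which is tracked but never treated as biologically blocking)."""

    ACETYL_NTERM = "acetyl_nterm"
    PYRO_GLU = "pyro_glu"
    AMIDE_CTERM = "amide_cterm"
    PHOSPHO = "phospho"
    OXIDATION = "oxidation"


#: Modifications that block merging of overlapping peptides past the modified
#: terminus: an acetylated or pyro-Glu N-terminus cannot be extended upstream,
#: an amidated C-terminus cannot be extended downstream.
TERMINAL_BLOCKERS_N = frozenset({ModKind.ACETYL_NTERM, ModKind.PYRO_GLU})
TERMINAL_BLOCKERS_C = frozenset({ModKind.AMIDE_CTERM})


class InvariantError(ValueError):
    """A domain object violates one of its structural invariants."""


@dataclass(frozen=True, order=True)
class ModificationEvent:
    """One modification on one residue of a peptide.

    Parameters
    ----------
    kind:
        The modification class.
    position:
        1-based residue index within the *peptide* (not the precursor).
    localized:
        For phosphorylation only: whether the site passed the localization
        probability threshold.  Unlocalized phospho is retained because
        occupancy quantification deliberately separates site localization
        from spectral counting.
    """

    kind: ModKind
    position: int
    localized: bool = True

    def validate(self, sequence: str) -> None:
        n = len(sequence)
        if not 1 <= self.position <= n:
            raise InvariantError(
                f"modification position {self.position} outside peptide of length {n}"
            )
        if self.kind in (ModKind.ACETYL_NTERM, ModKind.PYRO_GLU) and self.position != 1:
            raise InvariantError(f"{self.kind.value} must sit on residue 1")
        if self.kind is ModKind.AMIDE_CTERM and self.position != n:
            raise InvariantError("amide_cterm must sit on the last residue")
        if self.kind is ModKind.PHOSPHO and sequence[self.position - 1] not in PHOSPHO_ACCEPTORS:
            raise InvariantError(
                f"phospho on non-S/T/Y residue {sequence[self.position - 1]!r} "
                f"at position {self.position}"
            )


@dataclass
class PeptideObservation:
    """One modification-specific peptide variant observed in one sample."""

    sequence: str
    modifications: list[ModificationEvent] = field(default_factory=list)
    accessions: list[str] = field(default_factory=list)
    sample_id: str = ""
    spectral_count: int = 1
    intensity: Optional[float] = None

    def validate(self, min_length: int = DEFAULT_MIN_LENGTH) -> None:
        if not self.sequence:
            raise InvariantError("empty peptide sequence")
        if not set(self.sequence) <= set(AMINO_ACIDS):
            bad = sorted(set(self.sequence) - set(AMINO_ACIDS))
            raise InvariantError(f"non-amino-acid symbols {bad} in sequence")
        if len(self.sequence) < min_length:
            raise InvariantError(
                f"sequence shorter than minimum length {min_length}: {self.sequence!r}"
            )
        if self.spectral_count < 0:
            raise InvariantError("negative spectral count")
        for mod in self.modifications:
            mod.validate(self.sequence)

    # -- modification helpers -------------------------------------------------

    @property
    def mod_key(self) -> tuple:
        """Canonical, order-independent key of the modification multiset."""
        return tuple(sorted((m.kind.value, m.position, m.localized) for m in self.modifications))

    @property
    def is_phospho(self) -> bool:
        return any(m.kind is ModKind.PHOSPHO for m in self.modifications)

    @property
    def is_amidated(self) -> bool:
        return any(m.kind is ModKind.AMIDE_CTERM for m in self.modifications)

    @property
    def n_term_blocked(self) -> bool:
        return any(m.kind in TERMINAL_BLOCKERS_N for m in self.modifications)

    @property
    def c_term_blocked(self) -> bool:
        return any(m.kind in TERMINAL_BLOCKERS_C for m in self.modifications)

    def localized_phospho_positions(self) -> list[int]:
        return [m.position for m in self.modifications if m.kind is ModKind.PHOSPHO and m.localized]


@dataclass(frozen=True)
class PrecursorProtein:
    """A precursor (pro-hormone or background) protein sequence."""

    accession: str
    sequence: str
    species: str = ""
    gene: Optional[str] = None
    description: str = ""

    def validate(self) -> None:
        if not self.sequence:
            raise InvariantError(f"empty sequence for {self.accession}")
        if not self.sequence.isupper():
            raise InvariantError(f"sequence for {self.accession} must be uppercase")


@dataclass(frozen=True)
class PeptideFeature:
    """A Uniprot-style 'Peptide' feature: an annotated mature peptide span
    (1-based, inclusive) within a precursor protein."""

    accession: str
    start: int
    end: int
    name: str = ""

    def validate(self, protein_length: Optional[int] = None) -> None:
        if self.start < 1 or self.end < self.start:
            raise InvariantError(f"bad feature span {self.start}..{self.end}")
        if protein_length is not None and self.end > protein_length:
            raise InvariantError(
                f"feature {self.name!r} span {self.start}..{self.end} exceeds "
                f"protein length {protein_length}"
            )


@dataclass
class AnnotationSet:
    """The three annotation sources used to flag pro-hormone precursor groups:
    Uniprot Peptide features, a neuropeptide gene list, and a list of known
    mature peptide sequences tied to precursor accessions."""

    uniprot_peptide_features: list[PeptideFeature] = field(default_factory=list)
    neuropeptide_genes: list[str] = field(default_factory=list)
    known_peptides: list[tuple[str, str]] = field(default_factory=list)


def count_unique(observations: Iterable[PeptideObservation]) -> tuple[int, int]:
    """Count distinct modification-specific peptide variants and distinct
    stripped sequences.

    A modification-specific variant is a (sequence, modification multiset)
    pair; several variants can share one stripped sequence, so the first
    count is always >= the second.
    """
    variants = set()
    sequences = set()
    for obs in observations:
        variants.add((obs.sequence, obs.mod_key))
        sequences.add(obs.sequence)
    return len(variants), len(sequences)
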