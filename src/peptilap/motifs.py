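"""Flanking-residue extraction and position-specific motif matrices.

Prohormone convertases cleave precursors at mono-/dibasic (K/R) sites, so
the residues immediately flanking genuine neuropeptide termini are strongly
biased toward K/R; secretory-pathway kinase substrates show an S-x-E
phosphorylation motif.  This module extracts fixed-width flanking contexts
(3 residues by default, ``-`` padded at protein boundaries) and summarises
them as per-position residue frequency, enrichment over a background
proteome, and a binomial z-score — the numeric matrices behind sequence-logo
plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .assembly import LPV, PlacedPeptide
from .model import AMINO_ACIDS, ModKind, PrecursorProtein

PAD = "-"

#: Approximate amino-acid frequencies of the mouse proteome (fractions),
#: used as the default logo background; override via any mapping that sums
#: to 1 over the 20 residues.
MOUSE_BACKGROUND: dict[str, float] = {
    "A": 0.0691, "R": 0.0561, "N": 0.0361, "D": 0.0481, "C": 0.0230,
    "Q": 0.0481, "E": 0.0701, "G": 0.0631, "H": 0.0260, "I": 0.0441,
    "L": 0.1002, "K": 0.0571, "M": 0.0220, "F": 0.0371, "P": 0.0611,
    "S": 0.0852, "T": 0.0531, "W": 0.0120, "Y": 0.0270, "V": 0.0611,
}


@dataclass(frozen=True)
class FlankContext:
    """The k residues up- and downstream of a peptide in its precursor,
    boundary-padded with '-'."""

    up: str
    down: str
    amidated: bool = False

    @property
    def n_minus_1(self) -> str:
        return self.up[-1] if self.up else PAD

    def down_at(self, offset: int) -> str:
        """Residue at +offset (1-based) after the C-terminus, '-' if padded."""
        return self.down[offset - 1] if 0 < offset <= len(self.down) else PAD


@dataclass
class MotifMatrix:
    """Position x residue matrices: observed frequency, enrichment over
    background (difference of fractions), and binomial z-score.

    Rows are window positions (e.g. -3..-1 or +1..+3), columns the 20
    residues.  Padding symbols are excluded from the per-position counts, so
    observed frequencies sum to 1 over counted symbols at every position.
    """

    observed: pd.DataFrame
    enrichment: pd.DataFrame
    z: pd.DataFrame
    counts: pd.DataFrame
    n_per_position: pd.Series
    background: pd.Series

    def modal_residue(self, position) -> str:
        return self.observed.loc[position].idxmax()


def extract_flanks(
    placed: PlacedPeptide | LPV,
    precursor: PrecursorProtein,
    k: int = 3,
) -> FlankContext:
    """Read the k residues on each side of an anchored peptide, left/right
    padded with '-' at the protein boundaries."""
    seq = precursor.sequence
    start0 = placed.start - 1  # 0-based index of first residue
    up = seq[max(0, start0 - k) : start0]
    up = PAD * (k - len(up)) + up
    down = seq[placed.end : placed.end + k]
    down = down + PAD * (k - len(down))
    amidated = getattr(placed, "c_term_blocked", False)
    return FlankContext(up=up, down=down, amidated=amidated)


def build_motif_matrix(
    windows: Sequence[str],
    positions: Optional[Sequence] = None,
    background: Optional[Mapping[str, float]] = None,
) -> MotifMatrix:
    """Build the per-position frequency/enrichment/z matrices from
    equal-length aligned windows.

    Parameters
    ----------
    windows:
        Aligned strings of equal length; '-' marks padding and is excluded
        from the counts at its position.
    positions:
        Row labels (e.g. ``[-3, -2, -1]``); defaults to 0-based offsets.
    background:
        Residue -> fraction mapping; defaults to the mouse proteome table.
        The z-score at position p for residue r is
        ``(f_obs - f_bg) / sqrt(f_bg (1 - f_bg) / n_p)`` with n_p the number
        of counted (non-padding) symbols at p.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no contexts provided")
    width = len(windows[0])
    if any(len(w) != width for w in windows):
        raise ValueError("windows must all have the same length")
    if positions is None:
        positions = list(range(width))
    bg = pd.Series(background or MOUSE_BACKGROUND, dtype=float)
    bg = bg / bg.sum()

    residues = list(AMINO_ACIDS)
    counts = pd.DataFrame(0, index=list(positions), columns=residues, dtype=int)
    for w in windows:
        for pos, ch in zip(positions, w):
            if ch != PAD:
                counts.loc[pos, ch] += 1
    n = counts.sum(axis=1)
    observed = counts.div(n.where(n > 0, 1), axis=0)
    enrichment = observed.sub(bg[residues], axis=1)
    se = pd.DataFrame(
        {
            r: [math.sqrt(bg[r] * (1 - bg[r]) / ni) if ni > 0 else math.nan for ni in n]
            for r in residues
        },
        index=list(positions),
    )
    z = enrichment / se
    return MotifMatrix(
        observed=observed, enrichment=enrichment, z=z,
        counts=counts, n_per_position=n, background=bg[residues],
    )


def terminal_motif_matrices(
    flanks: Iterable[FlankContext],
    background: Optional[Mapping[str, float]] = None,
    k: int = 3,
) -> tuple[MotifMatrix, MotifMatrix]:
    """Matrices for the N-terminal (-k..-1) and C-terminal (+1..+k) flanking
    regions of a set of peptides."""
    flanks = list(flanks)
    n_mat = build_motif_matrix(
        [f.up for f in flanks], positions=list(range(-k, 0)), background=background
    )
    c_mat = build_motif_matrix(
        [f.down for f in flanks], positions=list(range(1, k + 1)), background=background
    )
    return n_mat, c_mat


def phospho_site_contexts(
    placed_observations: Sequence[tuple],
    proteins: Mapping[str, PrecursorProtein],
    window: int = 5,
) -> list[str]:
    """Fixed-width windows (2*window+1) centered on each localized
    phosphosite, using precursor context when the peptide is anchored.

    Parameters
    ----------
    placed_observations:
        (observation, PlacedPeptide-or-None) pairs.  Anchored peptides use
        the precursor sequence for context; unanchored ones use the peptide
        itself, '-'-padded.
    """
    contexts: list[str] = []
    for obs, placed in placed_observations:
        for pep_pos in sorted(
            m.position for m in obs.modifications
            if m.kind is ModKind.PHOSPHO and m.localized
        ):
            if placed is not None:
                seq = proteins[placed.accession].sequence
                center0 = placed.start - 1 + pep_pos - 1
            else:
                seq = obs.sequence
                center0 = pep_pos - 1
            left = seq[max(0, center0 - window) : center0]
            right = seq[center0 + 1 : center0 + 1 + window]
            contexts.append(
                PAD * (window - len(left)) + left + seq[center0] + right
                + PAD * (window - len(right))
            )
    return contexts


def phospho_motif_matrix(
    contexts: Sequence[str],
    window: int = 5,
    background: Optional[Mapping[str, float]] = None,
) -> MotifMatrix:
    return build_motif_matrix(
        contexts, positions=list(range(-window, window + 1)), background=background
    )


def matrix_to_frame(matrix: MotifMatrix) -> pd.DataFrame:
    """Long-format export (position, residue, observed, enrichment, z) for
    logo-rendering tools."""
    rows = []
    for pos in matrix.observed.index:
        for r in matrix.observed.columns:
            rows.append(
                {
                    "position": pos,
                    "residue": r,
                    "count": int(matrix.counts.loc[pos, r]),
                    "observed": matrix.observed.loc[pos, r],
                    "background": matrix.background[r],
                    "enrichment": matrix.enrichment.loc[pos, r],
                    "z": matrix.z.loc[pos, r],
                }
            )
    return pd.DataFrame(rows)
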