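"""Residue-level phosphorylation-site occupancy by spectral counting.

Occupancy (fractional stoichiometry) of a phosphosite is estimated under
the assumption that phosphorylation does not materially change ionization
efficiency: a moving-window spectral count is kept per precursor residue —
how many MS/MS spectra cover that residue in any peptide, and how many of
those spectra belong to phosphorylated peptides.  Site localization is kept
separate from quantification: a phosphopeptide's spectra are attributed to
EVERY S/T/Y residue it covers, so an unlocalized phosphopeptide still
contributes counts.  Occupancy is then the phospho count over the total
count at that residue, reported for S/T/Y residues whose phospho evidence
was observed at least ``min_obs`` times, with per-sample values retained
for replicate variation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .model import PHOSPHO_ACCEPTORS, PeptideObservation, PrecursorProtein


@dataclass
class AnchoredObservation:
    """An observation tied to a span (1-based, inclusive) of one precursor."""

    observation: PeptideObservation
    accession: str
    start: int
    end: int


def anchor_observations(
    observations: Sequence[PeptideObservation],
    precursor: PrecursorProtein,
) -> tuple[list[AnchoredObservation], list[PeptideObservation]]:
    """Anchor observations to a precursor at the leftmost occurrence of
    their sequence; unanchorable observations are returned separately."""
    anchored, skipped = [], []
    for obs in observations:
        pos = precursor.sequence.find(obs.sequence)
        if pos < 0:
            skipped.append(obs)
            continue
        anchored.append(
            AnchoredObservation(obs, precursor.accession, pos + 1, pos + len(obs.sequence))
        )
    return anchored, skipped


@dataclass
class ResidueCoverage:
    """Per-residue pooled and per-sample spectral counts for one precursor."""

    accession: str
    total: dict[int, int] = field(default_factory=dict)
    phospho: dict[int, int] = field(default_factory=dict)
    per_sample_total: dict[str, dict[int, int]] = field(default_factory=dict)
    per_sample_phospho: dict[str, dict[int, int]] = field(default_factory=dict)
    phospho_events: dict[int, int] = field(default_factory=dict)  # distinct observations
    localized_positions: set[int] = field(default_factory=set)


def residue_coverage(
    anchored: Sequence[AnchoredObservation],
    precursor: PrecursorProtein,
) -> ResidueCoverage:
    """Accumulate per-residue spectral counts.

    ``total`` sums spectral counts of all peptides covering a residue;
    ``phospho`` sums counts of phosphorylated peptides, attributed to every
    S/T/Y residue the peptide covers regardless of localization.
    """
    cov = ResidueCoverage(accession=precursor.accession)
    seq = precursor.sequence
    for a in anchored:
        obs = a.observation
        count = obs.spectral_count
        sample = obs.sample_id
        st = cov.per_sample_total.setdefault(sample, {})
        sp = cov.per_sample_phospho.setdefault(sample, {})
        sty_positions = [
            pos for pos in range(a.start, a.end + 1) if seq[pos - 1] in PHOSPHO_ACCEPTORS
        ]
        for pos in range(a.start, a.end + 1):
            cov.total[pos] = cov.total.get(pos, 0) + count
            st[pos] = st.get(pos, 0) + count
        if obs.is_phospho:
            for pos in sty_positions:
                cov.phospho[pos] = cov.phospho.get(pos, 0) + count
                sp[pos] = sp.get(pos, 0) + count
                cov.phospho_events[pos] = cov.phospho_events.get(pos, 0) + 1
            for pep_pos in obs.localized_phospho_positions():
                cov.localized_positions.add(a.start + pep_pos - 1)
    return cov


@dataclass
class SiteOccupancy:
    """Occupancy estimate for one S/T/Y residue of one precursor."""

    accession: str
    position: int
    residue: str
    phospho_count: int
    total_count: int
    occupancy: float
    n_observations: int
    localized: bool
    per_sample: dict[str, float] = field(default_factory=dict)


def compute_occupancy(
    coverage: ResidueCoverage,
    precursor: PrecursorProtein,
    min_obs: int = 3,
    min_obs_unit: str = "spectra",
) -> list[SiteOccupancy]:
    """Turn residue coverage into reported site occupancies.

    Only S/T/Y residues whose pooled phospho evidence reaches ``min_obs``
    are reported.  ``min_obs_unit`` selects the threshold interpretation:
    ``"spectra"`` counts pooled phospho spectra (default) and
    ``"observations"`` counts distinct phosphopeptide observations.
    ``localized`` marks sites supported by at least one localized
    identification at exactly that position.
    """
    if min_obs < 1:
        raise ValueError("min_obs must be >= 1")
    if min_obs_unit not in ("spectra", "observations"):
        raise ValueError(f"unknown min_obs_unit {min_obs_unit!r}")
    sites = []
    for pos in sorted(coverage.phospho):
        residue = precursor.sequence[pos - 1]
        if residue not in PHOSPHO_ACCEPTORS:
            continue
        evidence = (
            coverage.phospho[pos] if min_obs_unit == "spectra"
            else coverage.phospho_events.get(pos, 0)
        )
        if evidence < min_obs:
            continue
        total = coverage.total[pos]
        per_sample = {}
        for sample, totals in coverage.per_sample_total.items():
            t = totals.get(pos, 0)
            if t > 0:
                p = coverage.per_sample_phospho.get(sample, {}).get(pos, 0)
                per_sample[sample] = p / t
        sites.append(
            SiteOccupancy(
                accession=coverage.accession,
                position=pos,
                residue=residue,
                phospho_count=coverage.phospho[pos],
                total_count=total,
                occupancy=coverage.phospho[pos] / total,
                n_observations=coverage.phospho_events.get(pos, 0),
                localized=pos in coverage.localized_positions,
                per_sample=per_sample,
            )
        )
    return sites


def occupancy_frame(sites: Sequence[SiteOccupancy], gene_names: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Tabular export: one row per site, one column per sample occupancy."""
    samples = sorted({s for site in sites for s in site.per_sample})
    rows = []
    for site in sites:
        row = {
            "accession": site.accession,
            "gene": (gene_names or {}).get(site.accession, ""),
            "position": site.position,
            "residue": site.residue,
            "phospho_count": site.phospho_count,
            "total_count": site.total_count,
            "occupancy": site.occupancy,
            "n_observations": site.n_observations,
            "localized": site.localized,
        }
        for s in samples:
            row[f"occupancy_{s}"] = site.per_sample.get(s, float("nan"))
        rows.append(row)
    cols = ["accession", "gene", "position", "residue", "phospho_count", "total_count",
            "occupancy", "n_observations", "localized"] + [f"occupancy_{s}" for s in samples]
    return pd.DataFrame(rows, columns=cols)
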