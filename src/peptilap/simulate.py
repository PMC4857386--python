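"""Synthetic pro-hormone peptidomics datasets with a ground-truth ledger.

The generator emulates the statistical structure a tissue peptidomics
experiment assumes:

* pro-hormone precursors containing mature peptides separated by sampled
  basic convertase sites (dibasic KR/KK/RR or monobasic R before a peptide;
  dibasic after it);
* C-terminal amidation of a configurable fraction of mature peptides: the
  precursor carries a Gly after the peptide, the observed peptide loses the
  Gly and gains a C-terminal amide;
* secretory-pathway (S-x-E) phosphosites planted in mature peptides at a
  drawn per-site occupancy, and S/T-P sites in background proteins;
* exopeptidase ladder degradation: each mature peptide is observed
  full-length plus geometric single-residue trimmed fragments that never
  cross a mature-peptide boundary;
* overdispersed (negative binomial) spectral counts over replicate samples,
  with phospho/non-phospho spectra split binomially at the planted
  occupancy.

Every emitted observation traces back to a ledger entry, so downstream
stages (assembly, motif analysis, candidate filtering, occupancy) can be
validated against planted truth.  All randomness flows from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    AMINO_ACIDS,
    AnnotationSet,
    ModKind,
    ModificationEvent,
    PeptideFeature,
    PeptideObservation,
    PrecursorProtein,
)

#: residues drawn for unconstrained positions; uniform over the 20 residues
_ALPHABET = np.array(list(AMINO_ACIDS))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment (defaults emulate a
    hypothalamus-style study: 32 replicate samples, mono/dibasic processing
    weighted toward KR and R, about half of mature peptides amidated)."""

    n_prohormones: int = 12
    n_background_proteins: int = 40
    matures_per_precursor: tuple[int, int] = (2, 5)
    mature_length: tuple[int, int] = (8, 28)
    #: probabilities of the convertase site preceding a mature peptide
    cleavage_weights: dict = field(
        default_factory=lambda: {"KR": 0.55, "KK": 0.10, "RR": 0.10, "R": 0.25}
    )
    amidation_prob: float = 0.5
    phospho_site_prob: float = 0.4
    occupancy_range: tuple[float, float] = (0.2, 0.9)
    #: expected number of ladder fragments per mature peptide per sample;
    #: 0 disables degradation entirely
    ladder_rate: float = 3.0
    #: geometric parameter for trim depth (P(depth k) ~ (1-p)^(k-1) p, k>=1)
    trim_p: float = 0.5
    mean_spectral_count: float = 6.0
    nb_dispersion: float = 2.0
    background_fragment_rate: float = 1.0
    n_samples: int = 32
    min_peptide_length: int = 6
    guarantee_full_length: bool = True
    seed: int = 0


@dataclass
class MatureRecord:
    """Ground truth for one planted mature peptide."""

    accession: str
    start: int  # 1-based span of the observed peptide within the precursor
    end: int
    sequence: str
    amidated: bool
    site_label: str  # convertase site preceding the peptide (KR/KK/RR/R)
    up_flank: str
    down_flank: str
    phospho_position: Optional[int] = None  # precursor coordinate
    occupancy: Optional[float] = None


@dataclass
class BackgroundSite:
    accession: str
    position: int
    residue: str
    occupancy: float


@dataclass
class TruthLedger:
    matures: list[MatureRecord] = field(default_factory=list)
    background_sites: list[BackgroundSite] = field(default_factory=list)

    def matures_of(self, accession: str) -> list[MatureRecord]:
        return [m for m in self.matures if m.accession == accession]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "matures": [asdict(m) for m in self.matures],
            "background_sites": [asdict(b) for b in self.background_sites],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# precursor simulation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _has_repeated_kmer(sequence: str, k: int) -> bool:
    seen = set()
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if kmer in seen:
            return True
        seen.add(kmer)
    return False


def _draw_site(rng: np.random.Generator, weights: dict, dibasic_only: bool = False) -> str:
    sites = [s for s in weights if not dibasic_only or len(s) == 2]
    p = np.array([weights[s] for s in sites], dtype=float)
    p /= p.sum()
    return sites[rng.choice(len(sites), p=p)]


def _build_prohormone(
    rng: np.random.Generator, config: SimulationConfig, accession: str
) -> tuple[str, list[MatureRecord]]:
    parts: list[str] = [_random_seq(rng, int(rng.integers(15, 31)))]
    length = len(parts[0])
    records: list[MatureRecord] = []
    n_matures = int(rng.integers(config.matures_per_precursor[0],
                                 config.matures_per_precursor[1] + 1))
    for _ in range(n_matures):
        left = _draw_site(rng, config.cleavage_weights)
        core_len = int(rng.integers(config.mature_length[0], config.mature_length[1] + 1))
        core = list(_random_seq(rng, core_len))
        phospho_off = None
        occupancy = None
        if rng.random() < config.phospho_site_prob:
            # plant an S-x-E secretory-kinase motif away from the termini
            phospho_off = int(rng.integers(1, core_len - 3))
            core[phospho_off] = "S"
            core[phospho_off + 2] = "E"
            occupancy = float(rng.uniform(*config.occupancy_range))
        amidated = bool(rng.random() < config.amidation_prob)
        if amidated and core[-1] == "G":  # the observed peptide must not end in the removed Gly
            core[-1] = "A"
        mature = "".join(core)
        right = _draw_site(rng, config.cleavage_weights, dibasic_only=True)
        insert = left + mature + ("G" if amidated else "") + right
        start = length + len(left) + 1
        end = start + len(mature) - 1
        spacer = _random_seq(rng, int(rng.integers(6, 16)))
        parts.append(insert + spacer)
        length += len(insert) + len(spacer)
        records.append(
            MatureRecord(
                accession=accession,
                start=start,
                end=end,
                sequence=mature,
                amidated=amidated,
                site_label=left,
                up_flank="",  # filled in below from the final sequence
                down_flank="",
                phospho_position=(start + phospho_off) if phospho_off is not None else None,
                occupancy=occupancy,
            )
        )
    sequence = "".join(parts)
    for rec in records:
        rec.up_flank = sequence[rec.start - 4 : rec.start - 1]
        rec.down_flank = sequence[rec.end : rec.end + 3]
    return sequence, records


def simulate_precursors(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PrecursorProtein], TruthLedger]:
    """Generate pro-hormone precursors and background proteins with a
    ground-truth ledger.  Precursors are regenerated until they contain no
    repeated k-mer at the minimum peptide length, so every ladder fragment
    anchors uniquely."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    proteins: list[PrecursorProtein] = []
    ledger = TruthLedger()
    k = config.min_peptide_length
    for i in range(config.n_prohormones):
        accession = f"PRH{i:03d}"
        for _attempt in range(50):
            seq, records = _build_prohormone(rng, config, accession)
            if not _has_repeated_kmer(seq, k):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"could not generate repeat-free precursor {accession}")
        proteins.append(
            PrecursorProtein(accession=accession, sequence=seq, species="synthetic",
                             gene=f"Prh{i}")
        )
        ledger.matures.extend(records)
    for i in range(config.n_background_proteins):
        accession = f"BKG{i:03d}"
        for _attempt in range(50):
            length = int(rng.integers(80, 201))
            seq = list(_random_seq(rng, length))
            pos = int(rng.integers(10, length - 10))
            seq[pos] = "S" if rng.random() < 0.5 else "T"
            seq[pos + 1] = "P"  # proline-directed background phosphosite
            seq_str = "".join(seq)
            if not _has_repeated_kmer(seq_str, k):
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not generate repeat-free background protein {accession}")
        proteins.append(
            PrecursorProtein(accession=accession, sequence=seq_str, species="synthetic",
                             gene=f"Bkg{i}")
        )
        ledger.background_sites.append(
            BackgroundSite(
                accession=accession, position=pos + 1, residue=seq_str[pos],
                occupancy=float(rng.uniform(*config.occupancy_range)),
            )
        )
    return proteins, ledger


# ---------------------------------------------------------------------------
# evidence simulation
# ---------------------------------------------------------------------------

def _nb_count(rng: np.random.Generator, config: SimulationConfig, at_least_one: bool) -> int:
    r = config.nb_dispersion
    p = r / (r + config.mean_spectral_count)
    count = int(rng.negative_binomial(r, p))
    if at_least_one:
        count = max(count, 1)
    return count


def _emit(
    out: list[PeptideObservation],
    parents: list[int],
    parent_id: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    sequence: str,
    accession: str,
    sample: str,
    count: int,
    amidated: bool,
    phospho_pep_pos: Optional[int],
    occupancy: Optional[float],
) -> None:
    """Emit one peptide species, splitting its spectra into phospho and
    unmodified observations at the planted occupancy."""
    if count <= 0:
        return
    base_mods = []
    if amidated:
        base_mods.append(ModificationEvent(ModKind.AMIDE_CTERM, len(sequence)))
    k_phos = 0
    if phospho_pep_pos is not None and occupancy is not None:
        k_phos = int(rng.binomial(count, occupancy))
    if k_phos > 0:
        mods = base_mods + [ModificationEvent(ModKind.PHOSPHO, phospho_pep_pos, localized=True)]
        out.append(PeptideObservation(sequence=sequence, modifications=mods,
                                      accessions=[accession], sample_id=sample,
                                      spectral_count=k_phos))
        parents.append(parent_id)
    if count - k_phos > 0:
        out.append(PeptideObservation(sequence=sequence, modifications=list(base_mods),
                                      accessions=[accession], sample_id=sample,
                                      spectral_count=count - k_phos))
        parents.append(parent_id)


def simulate_evidence(
    precursors: Sequence[PrecursorProtein],
    ledger: TruthLedger,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[PeptideObservation], list[int]]:
    """Emit the evidence table: full-length mature peptides, ladder
    fragments, background-protein fragments, with spectral counts and
    phospho splitting.

    Returns (observations, parent ids) where the parent id indexes
    ``ledger.matures`` for pro-hormone observations and is ``-1 - j`` for
    fragments of background protein site j (and ``-10**6`` for plain
    background fragments), so every row traces to its ledger entry.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    by_acc = {p.accession: p for p in precursors}
    observations: list[PeptideObservation] = []
    parents: list[int] = []

    for mat_id, mat in enumerate(ledger.matures):
        L = len(mat.sequence)
        phospho_off = (
            mat.phospho_position - mat.start if mat.phospho_position is not None else None
        )
        for s in range(config.n_samples):
            sample = f"s{s:02d}"
            count = _nb_count(rng, config, at_least_one=config.guarantee_full_length)
            _emit(observations, parents, mat_id, rng, config, mat.sequence, mat.accession,
                  sample, count, mat.amidated,
                  None if phospho_off is None else phospho_off + 1, mat.occupancy)
            n_frag = int(rng.poisson(config.ladder_rate))
            for _ in range(n_frag):
                t_n = int(rng.geometric(config.trim_p) - 1)
                t_c = int(rng.geometric(config.trim_p) - 1)
                if t_n == 0 and t_c == 0:
                    t_n = 1  # a fragment differs from the full-length form
                if t_n + t_c >= L:
                    continue
                frag = mat.sequence[t_n : L - t_c]
                frag_phospho = None
                if phospho_off is not None and t_n <= phospho_off < L - t_c:
                    frag_phospho = phospho_off - t_n + 1
                _emit(observations, parents, mat_id, rng, config, frag, mat.accession,
                      sample, _nb_count(rng, config, at_least_one=False),
                      mat.amidated and t_c == 0, frag_phospho, mat.occupancy)

    site_by_acc = {b.accession: (j, b) for j, b in enumerate(ledger.background_sites)}
    for p in precursors:
        if not p.accession.startswith("BKG"):
            continue
        seq = p.sequence
        j, site = site_by_acc[p.accession]
        for s in range(config.n_samples):
            sample = f"s{s:02d}"
            n_frag = int(rng.poisson(config.background_fragment_rate))
            for _ in range(n_frag):
                flen = int(rng.integers(7, 21))
                start0 = int(rng.integers(0, len(seq) - flen + 1))
                frag = seq[start0 : start0 + flen]
                covers = start0 < site.position <= start0 + flen
                _emit(observations, parents, -1 - j if covers else -(10 ** 6), rng, config,
                      frag, p.accession, sample,
                      _nb_count(rng, config, at_least_one=False), False,
                      site.position - start0 if covers else None,
                      site.occupancy if covers else None)
    return observations, parents


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

def make_annotation_fixtures(
    ledger: TruthLedger,
    precursors: Sequence[PrecursorProtein],
    feature_fraction: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[AnnotationSet, list[tuple[str, str]]]:
    """Build annotation inputs from the ledger: Uniprot-style Peptide
    features for a subset of planted matures, and a mapping table assigning
    each precursor its own orthologous group (``G_<accession>``)."""
    rng = np.random.default_rng(0) if rng is None else rng
    features = []
    for i, mat in enumerate(ledger.matures):
        if feature_fraction >= 1.0 or rng.random() < feature_fraction:
            features.append(
                PeptideFeature(mat.accession, mat.start, mat.end, name=f"mature_{i}")
            )
    if feature_fraction <= 0.0:
        features = []
    mapping = [(p.accession, f"G_{p.accession}") for p in precursors]
    annotations = AnnotationSet(uniprot_peptide_features=features)
    return annotations, mapping


# ---------------------------------------------------------------------------
# one-call dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    proteins: list[PrecursorProtein]
    ledger: TruthLedger
    observations: list[PeptideObservation]
    parents: list[int]
    annotations: AnnotationSet
    mapping: list[tuple[str, str]]


def simulate_dataset(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
    feature_fraction: float = 1.0,
) -> SyntheticDataset:
    """Generate a complete synthetic dataset (precursors, evidence,
    annotations, mapping) from one seed."""
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**asdict(config), "seed": seed})
        config.cleavage_weights = dict(config.cleavage_weights)
    rng = np.random.default_rng(config.seed)
    proteins, ledger = simulate_precursors(config, rng)
    observations, parents = simulate_evidence(proteins, ledger, config, rng)
    annotations, mapping = make_annotation_fixtures(
        ledger, proteins, feature_fraction=feature_fraction, rng=rng
    )
    return SyntheticDataset(
        config=config, proteins=proteins, ledger=ledger,
        observations=observations, parents=parents,
        annotations=annotations, mapping=mapping,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text inputs for the pipeline: evidence
    TSV, precursor FASTA, mapping TSV, Peptide-feature TSV, truth JSON."""
    import pandas as pd

    from .io import write_evidence, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "evidence": out / "evidence.tsv",
        "fasta": out / "precursors.fasta",
        "mapping": out / "mapping.tsv",
        "features": out / "peptide_features.tsv",
        "truth": out / "truth.json",
    }
    write_evidence(dataset.observations, paths["evidence"])
    write_fasta(dataset.proteins, paths["fasta"])
    pd.DataFrame(dataset.mapping, columns=["accession", "group_id"]).to_csv(
        paths["mapping"], sep="\t", index=False
    )
    pd.DataFrame(
        [
            {"accession": f.accession, "start": f.start, "end": f.end, "name": f.name}
            for f in dataset.annotations.uniprot_peptide_features
        ],
        columns=["accession", "start", "end", "name"],
    ).to_csv(paths["features"], sep="\t", index=False)
    dataset.ledger.to_json(paths["truth"])
    return paths
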