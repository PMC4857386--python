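# peptilap

Analysis toolkit for **tissue peptidomics**: large-scale LC-MS/MS
identification of endogenous peptides (neuropeptides and other pro-hormone
products) extracted from tissue such as hypothalamus.

Peptidomics datasets are dominated by two confounds. First, unspecific
exopeptidase activity turns every genuine peptide into a *ladder* of
single-residue truncations, inflating the peptide list by an order of
magnitude. Second, most identified peptides derive from abundant
intracellular proteins (tissue damage), not from secreted pro-hormone
precursors. `peptilap` addresses both:

* **Longest Peptide Variant (LPV) assembly** — anchored, overlapping
  peptides from one precursor are merged iteratively, always combining the
  pair with the largest overlap (minimum 2 shared residues, no gaps), until
  a fixpoint is reached. In-vivo terminal modifications (N-terminal
  acetylation, pyro-Glu, C-terminal amidation) *block* merging past the
  modified residue, so biologically distinct termini survive the collapse.
  The resulting LPVs are the minimum peptide set explaining every
  observation.
* **Orthologous-group annotation** — peptides are organised into
  cross-species protein families via a provided accession→group mapping;
  families are flagged as *pro-hormone precursors* from Uniprot-style
  "Peptide" features, a neuropeptide gene list, or known mature peptide
  sequences.
* **Cleavage-motif matrices** — per-position residue frequencies,
  background enrichment and binomial z-scores for the 3-residue contexts
  flanking peptide/LPV termini (and ±5 windows around phosphosites): the
  numbers behind sequence-logo plots of prohormone-convertase specificity
  (K/R at −1, dibasic +1/+2, Gly at +1 for amidated peptides; S-x-E for
  secretory-kinase phosphosites).
* **Candidate hotlist** — an LPV is a bioactive-neuropeptide candidate iff
  K/R precedes its N-terminus at −1 **and** either K/R occupies both +1 and
  +2 after its C-terminus or the peptide is amidated with the donor glycine
  at +1.
* **Phosphosite occupancy** — fractional stoichiometry per precursor
  residue by spectral counting: occupancy = (spectra of phosphorylated
  peptides covering the residue) / (all spectra covering it), with
  localization kept separate from quantification and sites reported when
  their phospho evidence is observed ≥ 3 times.
* **Peptide coverage maps** — layered, alignment-aware views of each
  pro-hormone family (precursor sequences, identified peptides, LPVs,
  reference peptides, inline modification tags), exported as JSON/XLSX.
* **Synthetic data simulator** — seeded generator of pro-hormone precursors,
  ladder degradation, amidation, planted phosphosite stoichiometries and
  negative-binomial spectral counts, with a ground-truth ledger that makes
  every stage testable offline.

## Worked example

```python
from peptilap import PeptideObservation, PrecursorProtein, assemble_lpvs, place_observations
from peptilap.ortho import OrthoGroup

precursor = PrecursorProtein(
    accession="GCG",
    sequence="MKSIYFVAGLFVMLVQGDKRHSQGTFTSDYSKYLDSRRAQDFVQWLMNT",
)
group = OrthoGroup(group_id="g_gcg", members=["GCG"])
full = "HSQGTFTSDYSKYLDS"
ladder = [full] + [full[k:] for k in range(1, 6)] + [full[:-k] for k in range(1, 5)]
observations = [PeptideObservation(seq, accessions=["GCG"]) for seq in ladder]

placed, _ = place_observations(observations, list(range(len(observations))),
                               group, {"GCG": precursor})
lpvs = assemble_lpvs(placed, {"GCG": precursor}, group.group_id)
print(len(lpvs), lpvs[0].sequence, lpvs[0].start, lpvs[0].end, len(lpvs[0].support))
```

prints

```
1 HSQGTFTSDYSKYLDS 21 36 10
```

— ten ladder observations collapse into one LPV anchored at precursor
residues 21–36, supported by all ten. Its flanking context is `DKR.…​.RRA`:
K/R at −1 and a dibasic +1/+2 site, so it passes the candidate filter in
`dibasic` mode. The `examples/` directory contains one short script per
capability (simulation, assembly, motifs, hotlist, occupancy, full
pipeline), each printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```bash
peptilap simulate --seed 1 --out simdata/
peptilap run --evidence simdata/evidence.tsv --fasta simdata/precursors.fasta \
             --mapping simdata/mapping.tsv --features simdata/peptide_features.tsv \
             --out run/
```

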