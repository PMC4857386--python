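# Methods

## Problem setting

Endogenous-peptide (peptidomics) experiments identify peptides without
enzymatic digestion, so each identification reflects in-vivo processing plus
whatever degradation occurred between dissection and denaturation.  Two
structural features follow.  Unspecific exo-peptidase activity produces
ladder series — peptides differing by single terminal residues — so the raw
peptide list overstates the number of distinct processing products roughly
five-fold.  And because tissue lysis releases abundant intracellular
proteins, only a minority of identifications derive from secreted
pro-hormone precursors, the biologically interesting class.  The framework
separates these signals: family-level annotation isolates pro-hormone
precursors, ladder collapse recovers the underlying processing products,
and the terminal/modification analyses read out convertase and
secretory-kinase specificity.

## Evidence model

An observation is one modification-specific peptide variant in one sample:
a stripped sequence, a list of site-specific modifications, the precursor
accessions that can explain it, a sample identifier, and an MS/MS spectral
count used as the abundance proxy.  Only modifications of plausible in-vivo
origin are modelled — N-terminal acetylation, pyro-Glu, C-terminal
amidation, phosphorylation (S/T/Y) — plus Met oxidation, which is tracked
but never treated as biologically informative.  The default minimum peptide
length is 6 residues, the shortest length confidently identifiable by
MS/MS; shorter rows are rejected at ingest and reported.  Rows lacking a
spectral count default to 1 so plain sequence lists remain usable.
Phosphosites below the localization threshold of the upstream search are
ingested with `localized=False` rather than dropped, because occupancy
quantification (below) deliberately does not depend on localization.
Leucine/isoleucine are never merged; sequences are compared literally.

## Orthologous groups and pro-hormone flagging

Family membership comes from a pre-computed accession→group mapping table
(any provenance works; building one via sequence search is out of scope).
A family is flagged *pro-hormone precursor* if any member carries a
Uniprot-style "Peptide" feature (an annotated processed bioactive peptide),
its gene name appears in a neuropeptide gene list (case-insensitive exact
match), or a known mature peptide sequence occurs verbatim in a member.
Flagging is monotone and idempotent: sources only ever add evidence, and
reference peptides are deduplicated.  Observations whose accessions span
several families are assigned to the merged family set, and the flag
propagates across the merge — the conservative choice for an
indistinguishable protein group.

## LPV assembly

Peptides are first anchored: each unique peptide (deduplicated by sequence
and terminal-block state; internal modifications and supports are unioned)
is placed at the leftmost occurrence in the alphabetically first member
precursor containing it.  Peptides found in no member are excluded and
reported.  Overlap between two anchored peptides is the size of the
intersection of their residue intervals — positional, not string, overlap,
so identical k-mers at different loci never merge — and merging requires at
least 2 shared residues with no gaps.  Terminal modifications block
extension past the modified residue: nothing extends upstream of an
acetylated/pyro-Glu N-terminus or downstream of an amidated C-terminus;
peptides sharing the blocked terminus itself may still merge.  Assembly
greedily merges the allowed pair with the largest overlap and repeats until
no allowed pair remains; the surviving maximal peptides are the LPVs, the
minimum set explaining every input peptide.

Choices the definition leaves open, fixed here for determinism: ties on the
maximal overlap are broken by the lexicographically smallest merged anchor
(accession, start, end), then by the smaller peptide-identity pair; merging
is restricted to peptides anchored on the same member protein (cross-member
comparison is the coverage map's job, since "no gaps" cannot hold across an
alignment); multi-occurrence placements take the leftmost span and are
logged.  These make the output invariant to input order, which is verified
by tests, along with equivalence to a naive re-scan oracle on random
instances and the fixpoint/support-conservation invariants.  The
implementation maintains the candidate-pair set incrementally (only pairs
involving the newly merged peptide are recomputed), which is what makes the
oracle comparison a genuine dual-route check.

## Terminal motifs

For each peptide or LPV the 3 residues up- and downstream in the precursor
are read, `-`-padded at protein boundaries.  A motif matrix reports, per
window position and residue: observed frequency (padding excluded from the
denominator), enrichment as the difference to a background frequency, and a
binomial z-score `(f_obs − f_bg)/sqrt(f_bg(1−f_bg)/n)`.  The shipped
default background is a mouse-proteome amino-acid frequency table
(overridable); the z formulation reproduces the scaling semantics of
logo-plot tools but is declared as such, not claimed identical to any
specific renderer.  Phosphosite windows (±5) are centred on localized sites
and use the precursor sequence when the peptide is anchored, else the
peptide itself with padding.

## Candidate filter

An LPV is a candidate bioactive neuropeptide iff K/R occupies −1 before its
N-terminus AND either (a) K/R occupies both +1 and +2 after its C-terminus
(dibasic convertase site) or (b) the LPV is C-terminally amidated and +1 is
the donor glycine removed by peptidyl-glycine α-amidating monooxygenase.
The filter is a pure function of context and amidation state; abundance
plays no role, and restricting to pro-hormone families can only remove
candidates.  Padded boundary positions simply fail their test — no
signal-peptide model is applied, a deliberately conservative choice.
Candidates are rendered as `UP.SEQUENCE.DOWN` with `*` marking amidation.
A bundled reference table of 54 published rat-hypothalamus candidates in
this format serves as the worked-example validation set.

## Phosphosite occupancy

A moving-window spectral count is kept per precursor residue: the total
count of spectra from peptides covering the residue, and the count from
phosphorylated peptides.  Site specificity is kept separate from
quantification: a phosphopeptide's spectra are attributed to *every* S/T/Y
residue it covers, so unlocalized evidence still counts and no spectra are
discarded.  Occupancy is the phospho count over the total count.  Sites are
reported when their pooled phospho spectral count reaches `min_obs`
(default 3); an alternative interpretation — at least 3 distinct
phosphopeptide observations — is exposed via `min_obs_unit`.  Per-sample
occupancies are retained for replicate-variation analysis.  The estimator
assumes phosphorylation does not materially change ionization efficiency;
this is a stated caveat, not modelled.  Multiply-phosphorylated peptides
contribute their spectral count once per covered S/T/Y residue.

## Coverage maps

Per pro-hormone family the map stacks: member precursor rows (pre-aligned
externally for multi-member families; the package performs no alignment and
refuses multi-member groups without one), identified peptides, LPVs, and
reference peptides, in that order, all mapped through gap-aware column
arithmetic.  In-vivo modifications appear as `(tag)` after the modified
residue.  Stripping gaps, spaces and tags from any layer row reproduces the
original sequence exactly, and regeneration from the same inputs is
byte-identical (spreadsheet metadata timestamps are pinned).

## Synthetic data generator

The simulator emulates the data structure the framework assumes, with a
complete ground-truth ledger.  Defaults describe a study-style experiment;
each is a one-time choice, not a tuning knob:

| parameter | default | rationale |
|---|---|---|
| replicate samples | 32 | a large replicated tissue study |
| pro-hormones / background proteins | 12 / 40 | pro-hormone families are a small minority of identified families |
| matures per precursor | 2–5 | typical polyprotein organisation |
| cleavage-site weights | KR .55, KK .10, RR .10, R .25 | processing dominated by dibasic KR and monobasic R |
| amidation probability | 0.5 | amidation is common among bioactive peptides |
| S-x-E site probability / occupancy | 0.4, U(0.2, 0.9) | secretory-kinase motif; mostly mid-to-high stoichiometry |
| ladder rate / trim depth | Poisson(3) fragments, geometric p=0.5 | heavy single-residue exopeptidase laddering |
| spectral counts | NB(mean 6, dispersion 2) | overdispersed counts stress the occupancy estimator |

Precursors are built as leader + (site, mature, optional amidation Gly,
dibasic site, spacer)\* and regenerated until no 6-mer repeats within a
precursor, so every ladder fragment anchors uniquely.  C-side sites are
drawn dibasic-only while N-side sites include monobasic R: a monobasic
trailing context would (correctly) fail the candidate filter, and the
generator's contract is that every planted mature is recoverable by it.
Evidence emission guarantees one full-length observation per mature per
sample (configurable), trims ladder fragments geometrically without
crossing mature boundaries, keeps the amide only on fragments retaining the
mature C-terminus, emits sub-length fragments for the reader to filter, and
splits each species' spectra binomially into phospho/unmodified at the
planted occupancy.  Background proteins carry planted S/T-P sites and
random fragments.  All randomness flows from one integer seed through a
single PCG64 generator.

What the simulator does **not** emulate: missed/false identifications (no
FDR model), intensity profiles, chimeric or cross-precursor peptides,
shared peptides between paralogs (each precursor is its own family),
signal peptides, or realistic amino-acid composition (residues are uniform
outside planted structure).  Passing the recovery tests therefore shows the
algorithms are correct under the stated degradation model, not that real
data meet that model.

## Problem sizes and verification

The test suite and acceptance script run entirely on synthetic data at
sizes chosen for exhaustiveness per unit time: oracle equivalence on 1,000
random ≤12-peptide instances; exact LPV/hotlist recovery over 100 seeds at
4 precursors × 2 samples; occupancy recovery at three spectral depths
(mean count 2/6/12 across 4/16/48 samples) within 3 binomial standard
errors; the full end-to-end run in the acceptance script at the default
12-precursor, 32-sample configuration.  Dataset-scale counts for a deposited
rat-hypothalamus peptidome can be reproduced by dropping locally converted
copies of its peptide tables under `data/external/` (see
`tests/test_acceptance.py`); the repository ships no copy of deposited
data.

## Known limitations

* Merging never crosses member proteins within a family; if true processing
  products were only observable by combining evidence across orthologs, the
  LPV count would overestimate.
* The candidate filter implements the stated −1 / +1,+2 / amide+G rule
  only; it does not require a full dibasic pair at −2/−1.
* The occupancy threshold interpretation ("observed at least three times")
  defaults to pooled phospho spectra ≥ 3; both interpretations are exposed
  because spectra and observations differ in overdispersed data.
* Group mapping construction (sequence-similarity search against an
  orthology database) is consumed as input, never computed.
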