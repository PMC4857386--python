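"""Generate a synthetic pro-hormone peptidomics dataset.

The simulator plants mature peptides between basic convertase sites inside
precursor proteins, degrades them into exopeptidase ladders, adds amidation
and S-x-E phosphosites, and emits a MaxQuant-style evidence table with a
ground-truth ledger.
"""

from peptilap import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_prohormones=6, n_background_proteins=10,
                                       n_samples=4, seed=1))

n_amidated = sum(m.amidated for m in ds.ledger.matures)
n_phospho = sum(m.phospho_position is not None for m in ds.ledger.matures)
print(f"proteins:            {len(ds.proteins)} "
      f"({sum(p.accession.startswith('PRH') for p in ds.proteins)} pro-hormones)")
print(f"planted matures:     {len(ds.ledger.matures)} "
      f"({n_amidated} amidated, {n_phospho} with an S-x-E phosphosite)")
print(f"evidence rows:       {len(ds.observations)} across {ds.config.n_samples} samples")
print(f"example mature:      {ds.ledger.matures[0].up_flank}."
      f"{ds.ledger.matures[0].sequence}.{ds.ledger.matures[0].down_flank}")
# The up/down flanks show the convertase context: K/R before the peptide,
# a dibasic site (or the amidation Gly) after it.
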