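"""Run the complete pipeline on simulator output and inspect the manifest.

Equivalent to `peptilap simulate ... && peptilap run ...` from the shell.
"""

import json
import tempfile
from pathlib import Path

from peptilap import RunConfig, SimulationConfig, run_pipeline, simulate_dataset
from peptilap.simulate import write_dataset

with tempfile.TemporaryDirectory() as tmp:
    ds = simulate_dataset(SimulationConfig(n_prohormones=6, n_background_proteins=10,
                                           n_samples=4, seed=4))
    paths = write_dataset(ds, Path(tmp) / "inputs")
    config = RunConfig(evidence=str(paths["evidence"]), fasta=str(paths["fasta"]),
                       mapping=str(paths["mapping"]), features=str(paths["features"]),
                       out_dir=str(Path(tmp) / "out"))
    manifest = run_pipeline(config)
    print(json.dumps(manifest["stages"], indent=1, sort_keys=True))
    print(f"\nplanted matures: {len(ds.ledger.matures)}")
# 'collapse.n_prohormone_lpvs' and 'hotlist.n_candidates' both equal the
# number of planted mature peptides: ladder redundancy was fully collapsed
# and every specifically processed peptide passed the convertase filter.
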