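"""Collapse an exopeptidase ladder into its Longest Peptide Variant.

Ten truncated observations of one glucagon-like peptide merge back into a
single maximal sequence; the LPV support records every contributing
observation.
"""

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

placed, unplaced = place_observations(observations, list(range(len(observations))),
                                      group, {"GCG": precursor})
lpvs = assemble_lpvs(placed, {"GCG": precursor}, group.group_id)

print(f"input peptides: {len(observations)} (ladder of single-residue truncations)")
(lpv,) = lpvs
print(f"assembled LPVs: {len(lpvs)}")
print(f"LPV sequence:   {lpv.sequence} at {lpv.accession}:{lpv.start}-{lpv.end}")
print(f"supported by:   {len(lpv.support)} observations")
# One LPV explaining all ten observations means the ladder was pure
# exopeptidase redundancy around a single specifically processed peptide.
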