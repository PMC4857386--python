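"""Bioactive-neuropeptide candidate filter on published worked examples.

Evaluates three hallmark precursor contexts — glucagon (dibasic C-terminal
site), corticotropin-releasing hormone and kisspeptin (amidated, Gly at +1)
— plus the full bundled reference list.
"""

from peptilap.candidates import evaluate_display_row, load_reference_candidates

for name, up, seq, down, amidated in [
    ("glucagon 1-16", "DKR", "HSQGTFTSDYSKYLDS", "RRA", False),
    ("CRH fragment", "AER", "GAEDALGGHQ", "GAL", True),
    ("kisspeptin", "VQR", "EKDMSAYNWNSFGLRY", "GRR", True),
]:
    rec = evaluate_display_row(up, seq, down, amidated)
    print(f"{name:15s} {rec.display:45s} candidate={rec.is_candidate} "
          f"mode={rec.c_term_mode.value}")

rows = load_reference_candidates().to_dict("records")
n_pass = sum(
    evaluate_display_row(r["up"], r["sequence"], r["down"], r["amidated"]).is_candidate
    for r in rows
)
print(f"\nreference list: {n_pass}/{len(rows)} rows pass the convertase-context filter")
# 'dibasic' = K/R at +1 and +2 after the peptide; 'amide_G' = C-terminal
# amide with the donor glycine at +1. Both require K/R at -1.
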