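"""Contact-aware encoders RRC and RRPC on a hand-built contact map.

A predicted contact map is thresholded at 0.80 (strictly greater passes);
contacts with at least one endpoint inside the site's window qualify. RRC
appends the outside endpoints' residues to the window before computing a
20-dim composition; RRPC turns each qualifying contact into one of 400
ordered residue-pair types (lower sequence index first).
"""

import numpy as np

from kcrsite import (
    ContactMap,
    ContactRecord,
    ProteinRecord,
    encode_aac,
    encode_rrc,
    encode_rrpc,
    expand_segment,
    extract_segment,
    filter_contacts,
    select_window_contacts,
)

sequence = "A" * 9 + "K" + "A" * 25 + "W" + "A" * 4 + "C" + "A" * 10
protein = ProteinRecord("demo", sequence)
segment = extract_segment(protein, 10, n=5)  # window covers positions 5..15

cmap = ContactMap.from_records("demo", [
    ContactRecord(8, 36, 0.92),   # window residue 8 <-> distant W at 36
    ContactRecord(12, 41, 0.88),  # window residue 12 <-> distant C at 41
    ContactRecord(9, 30, 0.60),   # below threshold: discarded
    ContactRecord(20, 45, 0.99),  # both endpoints outside the window
])
kept = filter_contacts(cmap, 0.80)
contacts = select_window_contacts(kept, segment)
print(f"{len(cmap)} predicted contacts -> {len(kept)} above 0.80 "
      f"-> {len(contacts)} qualifying for the window")

expanded = expand_segment(segment, contacts, protein)
print(f"appended residues (position, type): {expanded.appended_residues}")

rrc, aac = encode_rrc(expanded), encode_aac(segment)
print("\nRRC vs AAC (the appended W and C shift the composition):")
for name, r, a in zip(rrc.names, rrc.values, aac.values):
    if r > 0 or a > 0:
        print(f"  {name[-1]}: rrc={r:.4f}  aac={a:.4f}")

rrpc = encode_rrpc(segment, contacts, protein)
print("\nRRPC pair types present (each qualifying contact contributes one):")
for name, value in zip(rrpc.names, rrpc.values):
    if value > 0:
        print(f"  {name}: {value:.2f}")

# with no contact above threshold, RRC reduces exactly to AAC
empty = filter_contacts(cmap, 1.0)
reduced = encode_rrc(expand_segment(segment, select_window_contacts(empty, segment), protein))
print("\nRRC == AAC when the thresholded map is empty:",
      bool(np.array_equal(reduced.values, aac.values)))
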