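"""Window extraction and classic sequence encoders on a toy protein.

Extracts the 2n+1 window around a lysine, then prints the nonzero amino-acid
composition (AAC) and a few k-spaced pair (CKSAAP) dimensions. Composition
values are frequencies over the real (non-pad) residues of the window, so
each printed block sums to 1.
"""

from kcrsite import ProteinRecord, encode_aac, encode_cksaap, extract_segment

protein = ProteinRecord("demo", "MSTKALWKEDGHKCVILKNPQR")
print(f"protein {protein.id}: {protein.sequence} (length {protein.length})")

segment = extract_segment(protein, 8, n=5)  # lysine at position 8
print(f"window around K{8} (n=5): {segment.residues}")

aac = encode_aac(segment)
print("\nAAC dimensions with nonzero frequency:")
for name, value in zip(aac.names, aac.values):
    if value > 0:
        print(f"  {name}: {value:.4f}")
print(f"  (sum = {aac.values.sum():.1f} -- a proper composition)")

cksaap = encode_cksaap(segment, gaps=(1,))
nonzero = [(n, v) for n, v in zip(cksaap.names, cksaap.values) if v > 0]
print(f"\nCKSAAP gap-1 pairs present ({len(nonzero)} of 400 dimensions):")
for name, value in nonzero:
    print(f"  {name}: {value:.4f}")
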