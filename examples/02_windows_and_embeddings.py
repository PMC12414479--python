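"""Cut a 31-residue site window and attach mock embedding rows.

Shows the '*'-padding at a terminal site, the binary mask, and the fact
that the window's embedding rows are sliced out of the full-sequence
embedding (so they keep the long-range context a real protein language
model would give them).
"""

import numpy as np

from phosfx import MockBackend, ProteinRecord, embed_sequence, extract_window, window_embedding

protein = ProteinRecord("demo", "STYAAAAKLRRSDEAAAGGHQWERTYAAAMNP")
backend = MockBackend(dim=16, seed=0)
emb = embed_sequence(backend, protein)
print(f"embedding shape: {emb.values.shape}  (L x D, one row per residue)")

for pos in (2, 12):
    window = window_embedding(extract_window(protein, pos), emb)
    pads = int((window.mask == 0).sum())
    print(f"\nsite {protein.id}:{pos} ({protein.residue(pos)})")
    print(f"  window: {window.window_seq}")
    print(f"  pads:   {pads} (mask covers {int(window.mask.sum())} real residues)")
    centre_matches = np.array_equal(window.window_emb[15], emb.values[pos - 1])
    print(f"  centre row equals embedding row {pos - 1}: {centre_matches}")
    print(f"  pad rows are all-zero: {bool((window.window_emb[window.mask == 0] == 0).all())}")
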