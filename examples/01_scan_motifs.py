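"""Score and scan a promoter sequence with a position weight matrix.

Builds a CCAAT-box-like PWM, scores a few windows on the normalized
log-odds scale (consensus = 1.0, worst window = 0.0), and scans a short
sequence on both strands.
"""

import numpy as np

import promgram as pg

# a sharp CCAAT-box PWM: 85% on the consensus base at each position
matrix = np.full((5, 4), 0.05)
for i, base in enumerate("CCAAT"):
    matrix[i, "ACGT".index(base)] = 0.85
caat = pg.PWM("CAAT", matrix, threshold=0.8, is_anchor=True)

print(f"consensus {caat.consensus}: score "
      f"{pg.score_window(caat, caat.consensus):.3f}")
print(f"one mismatch CCAGT:        score "
      f"{pg.score_window(caat, 'CCAGT'):.3f}")

seq = "TTGGACCAATCGGATTGGTTATTGG"   # forward CCAAT at 6, ATTGG = its RC
hits = pg.scan_sequence(caat, seq, both_strands=True)
print(f"\n{len(hits)} hits at threshold {caat.threshold} in {seq}:")
for h in hits:
    print(f"  [{h.start:2d},{h.end:2d}) strand {h.strand} "
          f"score {h.score:.3f}")
print("\nEach hit is a window whose normalized log-odds score clears the"
      "\nPWM cutoff; minus-strand hits are scored on the reverse"
      "\ncomplement and reported in forward coordinates.")
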