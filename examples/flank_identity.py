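"""Score flank conservation with Levenshtein ratio vs global alignment.

The verification stage can use either the Levenshtein distance ratio
(fast, no traceback) or Needleman-Wunsch identity (explicit scoring).
This compares the two on a pair of 100-bp flanks differing by 4
substitutions and 1 deletion.
"""

import numpy as np

from ssrmine import ScoringScheme, ld_identity, levenshtein, nw_align, nw_identity

rng = np.random.default_rng(3)
bases = "ACGT"
a = "".join(bases[i] for i in rng.integers(0, 4, size=100))

chars = list(a)
for pos in (10, 35, 60, 85):                     # 4 substitutions
    chars[pos] = "T" if chars[pos] != "T" else "G"
del chars[50]                                    # 1 deletion
b = "".join(chars)

print(f"LD(a, b) = {levenshtein(a, b)} edits")
print(f"LD identity      = {ld_identity(a, b):.3f}")
scheme = ScoringScheme(match=1, mismatch=-1, gap=-2)
score, matches, length = nw_align(a, b, scheme)
print(f"NW score {score}, {matches} matches over {length} columns")
print(f"NW identity      = {nw_identity(a, b, scheme):.3f}")
print(f"conserved at 5%? LD: {levenshtein(a, b) / 100 <= 0.05}")
# Five edits on a 100-bp flank sit exactly at the default 5% conservation
# threshold: the pair would be kept. The NW identity counts matches per
# alignment column, so one deletion costs one gapped column.
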