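"""Scan synthetic transcripts for miRNA target sites.

Scores antisense complementarity (match 0, G:U wobble 0.5, mismatch 1,
gap 2; doubled in the position 2-13 seed) and reports windows with
expectation <= 3.0.
"""

import numpy as np

from stressmir.simulate import revcomp_rna
from stressmir.targets import scan_transcripts

mirna = "UGUGUUCCCAGCUCGACCCCG"
rng = np.random.default_rng(5)

transcripts = {}
flank = "".join(rng.choice(list("ACGU"), 120))
transcripts["perfect_site"] = flank[:50] + revcomp_rna(mirna) + flank[50:]
wobbled = list(revcomp_rna(mirna))
wobbled[len(mirna) - 15] = "U"  # G:U wobble opposite miRNA position 15
transcripts["wobble_site"] = flank[:30] + "".join(wobbled) + flank[30:]
transcripts["no_site"] = "".join(rng.choice(list("ACGU"), 150))

for tid in transcripts:
    hits = scan_transcripts(mirna, {tid: transcripts[tid]}, cutoff=3.0)
    if not hits:
        print(f"{tid}: no site at expectation <= 3.0")
        continue
    h = hits[0]
    print(f"{tid}: expectation {h.expectation:.1f} at {h.t_start + 1}-{h.t_end} "
          f"({h.inhibition})")
    print("  miRNA 5'->3'  " + h.alignment.splitlines()[0])
    print("                " + h.alignment.splitlines()[1])
    print("  site  3'->5'  " + h.alignment.splitlines()[2])

# Expectation 0 is a perfect antisense duplex; the wobble adds 0.5 (1.0 if it
# fell inside the seed); random sequence has no window under the cutoff.
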