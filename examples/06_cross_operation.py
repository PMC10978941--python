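"""Cross-operation decoding: reusing the arithmetic classifier for hand use.

Classifiers trained on addition/subtraction labels are applied, without
refitting, to right/left-hand labels through the addition<->right-hand
mapping. When an early arithmetic code is re-expressed late as a
matched-sign hand code, transfer works prospectively (train early, test
late) but not retrospectively -- the signature of motor-code reuse.
"""

import numpy as np

from pmdarith import decoding, synth

ds = synth.make_fixture_dataset("snarc_reuse", seed=7)
pp = decoding.build_pseudopopulation(ds.pop, seed=7)
xop = decoding.cross_operation_decode(pp, "arithmetic", "hand", seed=7)
xop = decoding.permutation_significance(pp, xop, n_perm=200, seed=7)
summary = decoding.prospective_retrospective_summary(xop)

for region, res in summary.as_dict().items():
    print(f"{region:13s}: {res['significant']:3d}/{res['total']} windows "
          f"significant ({100 * res['fraction']:.1f}%), "
          f"binomial p = {res['p']:.3g}")
print("\nprospective >> chance while retrospective ~ chance: the arithmetic")
print("classifier predicts FUTURE hand use, i.e. the hand code reuses the")
print("arithmetic population pattern (addition->right, subtraction->left)")
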