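"""Encode one sequence window under all six feature schemes.

The window is the 11-mer context of a candidate S/T site; each scheme
turns it into the numeric vector an SVM consumes.
"""

import numpy as np

from glycmotif.encoders import (
    PSSMProfile,
    build_pwm,
    encode_aac,
    encode_aapc,
    encode_asa,
    encode_binary,
    encode_pssm400,
    encode_pwm,
)
from glycmotif.seqdata import ProteinRecord, SequenceFragment

frag = SequenceFragment("PKVAASTGHIK", 5, "DEMO", 6, "positive")
print(f"window: {frag.window} (center residue {frag.window[5]} at offset 0)\n")

binary = encode_binary(frag)
print(f"binary  : {binary.shape[0]}-dim one-hot, {int(binary.sum())} ones "
      "(one per non-pad position)")

aac = encode_aac(frag)
print(f"aac     : 20-dim composition, A fraction = {aac[1]:.3f} "
      "(2 alanines / 11 residues)")

aapc = encode_aapc(frag)
print(f"aapc    : 400-dim pair composition, {int(round(1/aapc[aapc>0].min()))} "
      "adjacent pairs counted")

pwm = build_pwm([frag, SequenceFragment("PKVAATTGHIK", 5, "DEMO", 7, "positive")])
vec = encode_pwm(frag, pwm)
print(f"pwm     : 11-dim frequency lookup, center value = {vec[5]:.2f} "
      "(S and T each seen once at offset 0 -> 0.50)")

protein = ProteinRecord("DEMO", "PKVAASTGHIK")
profile = PSSMProfile("DEMO", protein.sequence, np.zeros((11, 20)))
pssm = encode_pssm400(profile, protein, 6)
print(f"pssm    : 400-dim transform, all {pssm[0]:.2f} for a zero profile "
      "(sigmoid of 0)")

asa_table = {("DEMO", i): 10.0 * i for i in range(1, 12)}
asa = encode_asa(asa_table, protein, 6)
print(f"asa     : 11-dim exposure vector, min {asa.min():.2f} max {asa.max():.2f} "
      "(min-max normalized)")
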