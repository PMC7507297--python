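"""Document array two ways: start-table lookup vs rank bitvector.

The lightweight route stores one bit per text position (1 at
separators) plus a small rank directory, and reads the owning string
of each suffix as rank1(SA[i]) + 1 with rank exclusive of its
argument.  Both routes must agree everywhere.
"""

import numpy as np

import textindex as ti

coll = ti.generate_collection(
    ti.FixtureSpec(d=5, length=(4, 12), alphabet="protein", seed=3)
)
ct = ti.encode_collection(coll)
sa = ti.gsaca_k(ct)

direct = ti.document_array(ct, sa, mode="direct")
light = ti.document_array(ct, sa, mode="light")
print("N =", ct.N, " d =", ct.d)
print("direct DA head:", direct[:10].tolist())
print("light  DA head:", light[:10].tolist())
print("identical everywhere:", bool(np.array_equal(direct, light)))

bv = ti.build_separator_bitvector(ct)
print("\nrank1 is exclusive: rank1(N-1) =", bv.rank1(ct.N - 1),
      "separators precede the end-marker, so DA[0] =",
      bv.rank1(int(sa[0])) + 1, "= d + 1")
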