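"""Build every index structure for a tiny FASTA collection.

Writes the two-record collection {AB, CA} to a temporary FASTA file,
builds SA, LCP, DA, GSA and BWT through the pipeline, and prints each
array next to the suffix it describes.
"""

import tempfile
from pathlib import Path

import textindex as ti

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "two.fa"
    fasta.write_text(">s1\nAB\n>s2\nCA\n")

    coll = ti.read_collection(fasta, format="fasta")
    ct = ti.encode_collection(coll)
    print(f"collection: d={ct.d} strings, concatenated length N={ct.N}, "
          f"alphabet size sigma={ct.sigma}")

    sa = ti.gsaca_k(ct)
    lcp = ti.lcp_from_sa(ct, sa)
    da = ti.document_array(ct, sa)
    gsa = ti.gsa_from_sa_da(ct, sa, da)
    bwt = ti.bwt_from_sa(ct, sa)

    print("\n i  SA  DA  LCP  BWT  GSA      suffix")
    rendered = ti.render_bwt(bwt).decode()
    for i in range(ct.N):
        suffix = ti.render_bwt(ct.codes[sa[i]:]).decode()
        print(f"{i:2d}  {sa[i]:2d}  {da[i]:2d}  {lcp[i]:3d}   {rendered[i]}   "
              f"({gsa.docs[i]},{gsa.offs[i]})   {suffix}")

    print("\nRow i lists the i-th smallest suffix of T = AB$CA$#.")
    print("SA is its start position; DA the string owning it (3 = the")
    print("end-marker pseudo-string); LCP the prefix length it shares")
    print("with the row above, never crossing a separator; BWT the")
    print("symbol preceding it in T; GSA the same suffix as a")
    print("(string, offset) pair.")
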