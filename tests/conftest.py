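import math

import numpy as np
import pytest

import textindex as ti


@pytest.fixture(scope="session")
def w1():
    """The two-string worked example ["AB", "CA"]."""
    return ti.encode_collection(ti.StringCollection.from_strings(["AB", "CA"]))


@pytest.fixture(scope="session")
def w2():
    """The single-string worked example ["A"]."""
    return ti.encode_collection(ti.StringCollection.from_strings(["A"]))


@pytest.fixture(scope="session")
def corpus():
    """The canonical 500-instance random corpus, encoded."""
    out = []
    for spec, coll in ti.oracle_corpus():
        out.append((spec, coll, ti.encode_collection(coll)))
    return out


@pytest.fixture(scope="session")
def corpus_results(corpus):
    """Suffix arrays from all three construction routes per instance."""
    rows = []
    for spec, coll, ct in corpus:
        sa, stats = ti.gsaca_k(ct, return_stats=True)
        rows.append(
            {
                "spec": spec,
                "coll": coll,
                "ct": ct,
                "sa": sa,
                "depth": stats["max_depth"],
                "brute": ti.brute_force_sa(ct),
                "ref": ti.sa_via_distinct_separators(ct),
            }
        )
    return rows


def log2_bound(n: int) -> float:
    return max(1.0, math.log2(n))
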