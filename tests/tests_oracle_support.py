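"""Independent oracles shared between test modules.

Each function re-derives an expectation by a different route from the
implementation it checks (exact rational arithmetic, plain-loop predicate
scans), so agreement is informative.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd

from gbsim.tables import (GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING,
                          GenotypeTable)


def oracle_call(n_ref: int, n_alt: int, e: Fraction, prior):
    """Exact-arithmetic posterior genotype over {hom_ref, het, hom_alt}."""
    like = [
        (1 - e) ** n_ref * e ** n_alt,
        Fraction(1, 2) ** (n_ref + n_alt),
        e ** n_ref * (1 - e) ** n_alt,
    ]
    post = [p * l for p, l in zip(prior, like)]
    total = sum(post)
    post = [p / total for p in post]
    best = max(range(3), key=lambda i: post[i])
    p_err = float(1 - post[best])
    gq = 99 if p_err < 1e-10 else min(99, round(-10 * math.log10(p_err)))
    return (GT_HOM_REF, GT_HET, GT_HOM_ALT)[best], gq


def brute_force_keep(row, crit) -> bool:
    """Plain-loop re-implementation of the three site-retention predicates."""
    n = len(row)
    present = [g for g in row if g != GT_MISSING]
    if (n - len(present)) / n > crit.max_missing_frac:
        return False
    if not present:
        return False
    alt = sum(1.0 for g in present if g == GT_HOM_ALT) + \
        0.5 * sum(1 for g in present if g == GT_HET)
    freq = alt / len(present)
    if min(freq, 1 - freq) < crit.min_maf:
        return False
    max_het = getattr(crit, "max_het_frac", None)
    if max_het is not None:
        if sum(1 for g in present if g == GT_HET) / len(present) >= max_het:
            return False
    return True


def random_table(rng: np.random.Generator, n_sites: int, n_samples: int):
    gt = rng.choice([GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING],
                    size=(n_sites, n_samples),
                    p=[0.4, 0.1, 0.4, 0.1]).astype(np.int8)
    sites = pd.DataFrame({"contig": ["c"] * n_sites, "pos": range(n_sites),
                          "ref": ["A"] * n_sites, "alt": ["G"] * n_sites})
    table = GenotypeTable(sites, [f"s{i}" for i in range(n_samples)], gt,
                          np.full(gt.shape, 10, dtype=np.int32),
                          np.full(gt.shape, 50, dtype=np.int16))
    return table, gt
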