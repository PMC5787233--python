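"""Independent reference implementations used to check the package.

These deliberately avoid the code paths under test: pairwise diversity by
explicit haplotype-pair enumeration, and Tajima's D coded directly from the
defining formulas with constants obtained by direct summation.
"""

import itertools
import math

import numpy as np


def pi_sum_all_pairs(haplotype_matrix: np.ndarray) -> float:
    """Average Hamming distance over all haplotype pairs, summed over sites.

    haplotype_matrix: (sites x haplotypes) allele codes, no missing data.
    """
    n = haplotype_matrix.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    total = sum(int(np.sum(haplotype_matrix[:, i] != haplotype_matrix[:, j]))
                for i, j in pairs)
    return total / len(pairs) * 1.0 if pairs else 0.0


def tajimas_d_reference(derived_counts, n: int) -> float:
    """Tajima's D from a list of per-site derived counts, from first principles."""
    S = sum(1 for k in derived_counts if 0 < k < n)
    if S == 0:
        return math.nan
    pi = sum(2.0 * k * (n - k) / (n * (n - 1)) for k in derived_counts)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1.0))
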