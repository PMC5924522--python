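"""Independent oracles used by unit and acceptance tests.

Each oracle computes its quantity by a route deliberately different from
the package implementation: integer enumeration for Fisher's exact test,
ordered-pair enumeration for expected offspring, and direct distribution
arithmetic for the large-sample isolation value of a trial simulator.
"""

import itertools
from math import comb

import numpy as np
from scipy import stats


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer enumeration of fixed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    nums = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    obs = nums[a - lo]
    return sum(x for x in nums if x <= obs) / comb(n, c1)


def expected_offspring_oracle(windows):
    """(hybrids, pure) expectations by enumerating ordered parent pairs.

    ``windows`` is a sequence of (n_Z, n_E) pairs.  For a window with n
    matings, the chance a random ordered pairing is inter-strain is the
    mixed fraction of the n x n pair grid; expectations scale by n.
    """
    hyb = pure = 0.0
    for n_z, n_e in windows:
        n = n_z + n_e
        if n == 0:
            continue
        strains = ["Z"] * n_z + ["E"] * n_e
        mixed = sum(a != b for a, b in itertools.product(strains, repeat=2))
        hyb += n * mixed / n**2
        pure += n * (n**2 - mixed) / n**2
    return hyb, pure


def truncnorm_hour_masses(loc: float, scale: float, span: float = 7.0) -> np.ndarray:
    """Hourly masses of a normal law truncated to (0, span)."""
    a, b = (0.0 - loc) / scale, (span - loc) / scale
    dist = stats.truncnorm(a, b, loc=loc, scale=scale)
    edges = np.arange(0.0, span + 0.5, 1.0)
    return np.diff(dist.cdf(edges))


def analytic_ri(mass_e: np.ndarray, mass_z: np.ndarray) -> float:
    """Large-sample isolation value for equal strain mating totals."""
    n = mass_e + mass_z
    occ = n > 0
    hyb = (2.0 * mass_e[occ] * mass_z[occ] / n[occ]).sum()
    pure = ((mass_e[occ] ** 2 + mass_z[occ] ** 2) / n[occ]).sum()
    return 1.0 - hyb / pure
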