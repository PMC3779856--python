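"""Nearest-integer comparator: round replicate means, test Mendelian consistency.

The baseline estimates each individual's copy number as the integer
nearest to the average of its replicate measurements and flags a family
as containing a de novo mutation when no decomposition of the parental
totals into haplotype pairs can jointly reproduce every offspring total
via Mendelian transmission.  It yields family-level flags only: with
totals alone there is no attribution of which member mutated or whether
the event was a gain or a loss.

Ties at .5 are rounded half-to-even (numpy convention); under the
Gaussian noise model ties have probability zero, so the choice is
documented rather than consequential.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import numpy as np

__all__ = [
    "nearest_integer_cn",
    "mendelian_consistent",
    "flag_family_nearest_integer",
]


def nearest_integer_cn(replicates: np.ndarray) -> int:
    """Integer nearest to the replicate mean, floored at 0 (half-to-even)."""
    x = np.asarray(replicates, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one replicate")
    return int(max(np.round(x.mean()), 0))


def _decompositions(total: int) -> list[tuple[int, int]]:
    return [(a, total - a) for a in range(total // 2 + 1)]


def mendelian_consistent(
    father_cn: int | None,
    mother_cn: int | None,
    offspring_cns: list[int],
) -> bool:
    """Can some joint parental decomposition explain all offspring totals?

    True iff there exist non-negative integer haplotype decompositions
    father = a_f1 + a_f2 and mother = a_m1 + a_m2 such that every
    offspring total equals one paternal plus one maternal haplotype
    (offspring choose transmissions independently, but under the same
    decomposition).  A missing parent (None) is unconstrained: it may
    hold any non-negative pair, so any offspring total can be matched and
    the test is conservative (it never flags such families).
    """
    kids = tuple(sorted(int(k) for k in offspring_cns))
    if any(k < 0 for k in kids):
        raise ValueError("offspring copy numbers must be non-negative")
    if father_cn is None or mother_cn is None:
        # an unconstrained parent can contribute 0..inf, e.g. pair (0, t):
        # every non-negative offspring total is reachable.
        return True
    if father_cn < 0 or mother_cn < 0:
        raise ValueError("parental copy numbers must be non-negative")
    return _consistent_cached(int(father_cn), int(mother_cn), kids)


@lru_cache(maxsize=100_000)
def _consistent_cached(f: int, m: int, kids: tuple[int, ...]) -> bool:
    if not kids:
        return True
    for fd in _decompositions(f):
        for md in _decompositions(m):
            sums = {a + b for a, b in product(fd, md)}
            if all(k in sums for k in kids):
                return True
    return False


def flag_family_nearest_integer(
    father_reps: np.ndarray | None,
    mother_reps: np.ndarray | None,
    offspring_reps: list[np.ndarray],
) -> bool:
    """Family-level mutation flag: True iff rounded CNs are Mendelian-inconsistent."""

    def cn(reps: np.ndarray | None) -> int | None:
        if reps is None or np.asarray(reps).size == 0:
            return None
        return nearest_integer_cn(reps)

    kids = [nearest_integer_cn(r) for r in offspring_reps]
    return not mendelian_consistent(cn(father_reps), cn(mother_reps), kids)
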