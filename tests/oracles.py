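"""Independent oracles used by the test suite.

These deliberately avoid the package's code paths: exact rational
arithmetic for hypergeometric tails, and plain breadth-first reachability
for ontology closures.
"""

from fractions import Fraction
from math import comb


def hypergeom_tail(case_carriers: int, n_cases: int,
                   control_carriers: int, n_controls: int) -> Fraction:
    """Exact one-sided Fisher p: P(X >= a) by direct factorial arithmetic.

    X is the number of carriers among the cases when a + c carriers are
    distributed over n_cases + n_controls patients.
    """
    a, c = case_carriers, control_carriers
    total_patients = n_cases + n_controls
    carriers = a + c
    denom = comb(total_patients, carriers)
    acc = Fraction(0)
    for x in range(a, min(carriers, n_cases) + 1):
        acc += Fraction(comb(n_cases, x) * comb(n_controls, carriers - x), denom)
    return acc


def reachable_from(edges, start):
    """All nodes reachable from ``start`` following parent->child edges
    (reflexive), by naive fixed-point iteration."""
    seen = {start}
    changed = True
    while changed:
        changed = False
        for parent, child in edges:
            if parent in seen and child not in seen:
                seen.add(child)
                changed = True
    return seen
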