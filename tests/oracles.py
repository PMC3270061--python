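"""Brute-force oracles, independent of the package's recursion.

Everything here enumerates count vectors with itertools and recomputes
masses, weights and bin indices from first principles, so the tests
compare two genuinely different routes to the same numbers.
"""

from fractions import Fraction
from itertools import permutations, product
from math import floor


def all_compositions(N, L):
    """All count vectors with sum <= L, in ascending N-digit order."""
    for counts in product(range(L + 1), repeat=N):
        if sum(counts) <= L:
            yield counts


def count_sequences_brute(counts):
    """Distinct orderings of the multiset, by materializing permutations."""
    word = []
    for i, n in enumerate(counts):
        word.extend([i] * n)
    return len(set(permutations(word)))


def bin_of(mass, bin_width):
    """Round-half-up bin index recomputed with rational arithmetic."""
    return floor(Fraction(mass, bin_width) + Fraction(1, 2))


def histogram_brute(masses, L, bin_width=1000, adduct=0, mass_max=None,
                    caps=None, sequences=False):
    """Reference histogram built by filtering the full enumeration."""
    bins = {}
    for counts in all_compositions(len(masses), L):
        if caps is not None and any(n > c for n, c in zip(counts, caps)):
            continue
        mass = sum(n * m for n, m in zip(counts, masses)) + adduct
        if mass_max is not None and mass > mass_max:
            continue
        w = count_sequences_brute(counts) if sequences else 1
        b = bin_of(mass, bin_width)
        bins[b] = bins.get(b, 0) + w
    return bins


def count_mass_bounded_brute(masses, L, mass_max, adduct=0, quantum=1):
    """Mass-limited count over quantized masses, by full enumeration."""
    weights = [(2 * m + quantum) // (2 * quantum) for m in masses]
    budget = (2 * (mass_max - adduct) + quantum) // (2 * quantum)
    if mass_max - adduct < 0:
        return 0
    n = 0
    for counts in all_compositions(len(masses), L):
        if sum(c * w for c, w in zip(counts, weights)) <= budget:
            n += 1
    return n
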