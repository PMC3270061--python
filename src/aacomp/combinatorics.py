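"""Closed-form and dynamic-programming counts of compositions and sequences.

A composition over an alphabet of N letters is a count vector
(n₁, …, n_N); its length is L = Σ nᵢ.  The number of compositions of
exact length L is the stars-and-bars binomial C(N+L−1, L); summed over
all lengths 0..L it telescopes to C(N+L, N).  Each composition of length
L corresponds to L!/(n₁!…n_N!) distinct sequences, and the number of
non-empty sequences of length ≤ L is the geometric sum N(N^L−1)/(N−1).

All counts are exact arbitrary-precision integers: the sequence counts
exceed 2⁶³ already for modest L.  The complexity-ratio helpers return
exact rationals used to reason about job splitting, and
:func:`count_mass_bounded` counts mass-limited compositions without
enumerating them (a bounded-knapsack dynamic program over quantized
masses).
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np

from .alphabet import Alphabet, MassConfig


def sequences_for_composition(counts: Sequence[int]) -> int:
    """Multinomial coefficient L!/(n₁!…n_N!) — sequences realizing a composition."""
    if any(n < 0 for n in counts):
        raise ValueError("counts must be non-negative")
    out = 1
    remaining = sum(counts)
    for n in counts:
        out *= math.comb(remaining, n)
        remaining -= n
    return out


def compositions_exact_length(N: int, L: int) -> int:
    """Number of compositions of exact length L: C(N+L−1, L)."""
    _check_nl(N, L)
    return math.comb(N + L - 1, L)


def compositions_up_to_length(N: int, L: int, include_empty: bool = True) -> int:
    """Number of compositions of length ≤ L: C(N+L, N), optionally minus the empty one.

    The closed form includes the single length-0 composition; published
    count tables conventionally exclude it (``include_empty=False``).
    """
    _check_nl(N, L)
    total = math.comb(N + L, N)
    return total if include_empty else total - 1


def sequences_up_to_length(N: int, L: int) -> int:
    """Number of non-empty sequences of length ≤ L: N(N^L − 1)/(N − 1), exact.

    For N=1 the formula degenerates (division by zero); the limit is L.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if L < 0:
        raise ValueError("L must be >= 0")
    if N == 1:
        return L
    return N * (N**L - 1) // (N - 1)


def sequences_to_compositions_ratio(N: int, L: int) -> int:
    """Rounded ratio of non-empty sequence to composition counts (half-up)."""
    a = compositions_up_to_length(N, L, include_empty=False)
    if a == 0:
        raise ValueError("no non-empty compositions at L=0")
    ratio = Fraction(sequences_up_to_length(N, L), a)
    return math.floor(ratio + Fraction(1, 2))


def complexity_ratio_over_start(N: int, L: int, start: int) -> Fraction:
    """Exact work ratio C(L, start)/C(L, start+1) = 1 + L/(N − start + 1).

    C(L, s) is the number of compositions a job (L, start=s) enumerates;
    the ratio quantifies the speed-up from splitting one job at level
    ``start`` into L+1 jobs at level ``start+1``.
    """
    if not 1 <= start <= N - 1:
        raise ValueError("start must be in 1..N-1")
    if L < 0:
        raise ValueError("L must be >= 0")
    return 1 + Fraction(L, N - start + 1)


def complexity_ratio_over_length(N: int, L: int, start: int) -> Fraction:
    """Exact work ratio C(L, start)/C(L−1, start) = 1 + (N − start + 1)/L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 1 <= start <= N:
        raise ValueError("start must be in 1..N")
    return 1 + Fraction(N - start + 1, L)


def job_composition_count(N: int, L: int, start: int) -> int:
    """Compositions enumerated by a job (L, start): C(N−start+1+L, N−start+1).

    ``start`` may be N+1 (fully determined prefix, one composition).
    """
    free = N - start + 1
    if free < 0:
        raise ValueError("start must be <= N+1")
    if free == 0:
        return 1
    return compositions_up_to_length(free, L)


def count_mass_bounded(
    alphabet: Alphabet,
    length_max: int,
    cfg: MassConfig,
    quantum: int = 10_000,
) -> int:
    """Count compositions with length ≤ length_max and mass ≤ cfg.mass_max
    without enumerating them.

    Masses are quantized to ``quantum`` µDa (default 0.01 Da) by
    round-half-up, and counts per (length, mass-bin) cell are accumulated
    residue by residue with the bounded-knapsack recurrence

        f_new(l, b) = f_old(l, b) + f_new(l−1, b − wᵢ)

    The count includes the empty composition whenever the adduct alone is
    under the ceiling.  Memory is O(length_max × mass_max/quantum) machine
    words; lower the quantum for tighter thresholds at more memory.
    """
    if cfg.mass_max is None:
        raise ValueError("count_mass_bounded requires cfg.mass_max")
    if quantum < 1:
        raise ValueError("quantum must be >= 1 µDa")
    if length_max < 0:
        raise ValueError("length_max must be >= 0")
    budget = cfg.mass_max - cfg.adduct
    if budget < 0:
        return 0
    nbins = (2 * budget + quantum) // (2 * quantum)  # round-half-up(budget/q)
    weights = [(2 * m + quantum) // (2 * quantum) for m in alphabet.masses]

    # int64 is safe iff the unbounded total already fits comfortably.
    unbounded = compositions_up_to_length(alphabet.size, length_max)
    dtype = object if unbounded >= 2**62 else np.int64

    f = np.zeros((length_max + 1, nbins + 1), dtype=dtype)
    f[0, 0] = 1
    for w in weights:
        for l in range(1, length_max + 1):
            if w == 0:
                f[l, :] += f[l - 1, :]
            elif w <= nbins:
                f[l, w:] += f[l - 1, :-w]
    return int(f.sum())


def _check_nl(N: int, L: int) -> None:
    if N < 1:
        raise ValueError("N must be >= 1")
    if L < 0:
        raise ValueError("L must be >= 0")
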