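"""Recursive enumeration of compositions and exact mass histograms.

The enumeration visits count vectors (n₁, …, n_N) with Σ nᵢ ≤ L like
N-digit numbers in ascending order (digit 1 most significant): for N=3,
L=2 the order is (0,0,0), (0,0,1), (0,0,2), (0,1,0), (0,1,1), (0,2,0),
(1,0,0), (1,0,1), (1,1,0), (2,0,0).  The histogram-accumulating variant
carries the running prefix mass into each recursive call (no mass is
ever recomputed), adds each composition's mass to a 0.001 Da bin by
default, and — when a mass ceiling is set — abandons a branch as soon as
the running mass exceeds it.  The pruning is sound because alphabets are
mass-ascending: every residue at or after the current index is at least
as heavy as the current one.

Weighting: each composition contributes weight 1 (``compositions``) or
its multinomial sequence count (``sequences``), the latter built
incrementally by multiplying C(length-so-far + nᵢ, nᵢ) as each count is
fixed.
"""

from __future__ import annotations

import math
import sys
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

from .alphabet import Alphabet, ConfigurationError, MassConfig, composition_mass
from .combinatorics import sequences_for_composition

WEIGHTINGS = ("compositions", "sequences")


@dataclass(frozen=True)
class Composition:
    """A count vector over an alphabet; many sequences share one composition."""

    counts: Tuple[int, ...]

    @property
    def length(self) -> int:
        return sum(self.counts)

    def mass(self, alphabet: Alphabet, cfg: Optional[MassConfig] = None) -> int:
        return composition_mass(self.counts, alphabet, cfg)


class MassHistogram:
    """Sparse histogram of composition masses with exact integer counts.

    A mass m (µDa) falls into bin round-half-up(m / bin_width), computed
    on exact integers as (2m + bin_width) div (2·bin_width).  Bin counts
    are arbitrary-precision; merging histograms is per-bin addition and
    therefore commutative and associative — partial histograms from
    parallel workers combine to a bit-identical result in any order.
    """

    __slots__ = ("bin_width", "_bins")

    def __init__(self, bin_width: int = 1000, bins: Optional[Dict[int, int]] = None):
        if bin_width < 1:
            raise ConfigurationError("bin_width must be >= 1 µDa")
        self.bin_width = bin_width
        self._bins: Dict[int, int] = defaultdict(int)
        if bins:
            for b, c in bins.items():
                if c > 0:
                    self._bins[b] += c

    def bin_index(self, mass: int) -> int:
        return (2 * mass + self.bin_width) // (2 * self.bin_width)

    def add(self, mass: int, weight: int = 1) -> None:
        if weight <= 0:
            raise ValueError("weight must be positive")
        self._bins[self.bin_index(mass)] += weight

    @property
    def bins(self) -> Dict[int, int]:
        """Bin index → count (a copy; empty bins are never stored)."""
        return dict(self._bins)

    @property
    def total_weight(self) -> int:
        return sum(self._bins.values())

    def merge_in(self, other: "MassHistogram") -> None:
        if other.bin_width != self.bin_width:
            raise ConfigurationError(
                f"cannot merge histograms with bin widths "
                f"{self.bin_width} and {other.bin_width}"
            )
        for b, c in other._bins.items():
            self._bins[b] += c

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MassHistogram)
            and self.bin_width == other.bin_width
            and dict(self._bins) == dict(other._bins)
        )

    def __repr__(self) -> str:
        return (
            f"MassHistogram(bin_width={self.bin_width}, "
            f"n_bins={len(self._bins)}, total_weight={self.total_weight})"
        )


def histogram_merge(h1: MassHistogram, h2: MassHistogram) -> MassHistogram:
    """Per-bin sum of two histograms (identical bin widths required)."""
    out = MassHistogram(h1.bin_width, h1._bins)
    out.merge_in(h2)
    return out


@dataclass(frozen=True)
class EnumerationConfig:
    """Length limit, mass bookkeeping, weighting mode and per-residue caps."""

    length_max: int
    mass_config: MassConfig = field(default_factory=MassConfig)
    weighting: str = "compositions"
    occurrence_caps: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.length_max < 0:
            raise ConfigurationError("length_max must be >= 0")
        if self.weighting not in WEIGHTINGS:
            raise ConfigurationError(
                f"weighting must be one of {WEIGHTINGS}, got {self.weighting!r}"
            )
        if self.occurrence_caps is not None and any(
            c < 0 for c in self.occurrence_caps
        ):
            raise ConfigurationError("occurrence caps must be >= 0")


def _ensure_recursion_room(depth: int) -> None:
    needed = depth + 200
    if sys.getrecursionlimit() < needed:
        sys.setrecursionlimit(needed)


def enumerate_compositions(
    L: int,
    alphabet: Alphabet,
    visitor: Optional[Callable[[Composition], None]] = None,
) -> int:
    """Visit every composition of length ≤ L in ascending N-digit order.

    Returns the number of visits, C(N+L, N) (the empty composition is
    visited first, (L, 0, …, 0) last).  With ``visitor=None`` the
    recursion still walks every composition and only counts.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    N = alphabet.size
    _ensure_recursion_room(N)
    counts = [0] * N
    visits = 0

    def rec(i: int, budget: int) -> None:
        nonlocal visits
        if i == N:
            visits += 1
            if visitor is not None:
                visitor(Composition(tuple(counts)))
            return
        for n in range(budget + 1):
            counts[i] = n
            rec(i + 1, budget - n)
        counts[i] = 0

    rec(0, L)
    return visits


def accumulate_histogram(
    job,
    alphabet: Alphabet,
    cfg: EnumerationConfig,
    hist: Optional[MassHistogram] = None,
    emit: Optional[Callable[[Tuple[int, ...]], None]] = None,
) -> MassHistogram:
    """Accumulate the mass histogram of one enumeration job.

    The job fixes counts for alphabet indices below ``job.start`` (1-based)
    with prefix mass ``job.m0``; the recursion assigns counts to indices
    start..N with total ≤ job.L, carrying the running mass.  Each visited
    composition adds ``weight × job.multiplicity`` to the bin of
    (m0 + Σ nᵢmᵢ + adduct).  With a mass ceiling the recursion returns as
    soon as the running mass exceeds it, which is equivalent to post-hoc
    filtering.  ``emit``, if given, receives the full count vector of each
    in-limit composition (requires a consistent ``prefix_counts``).
    """
    N = alphabet.size
    if not 1 <= job.start <= N + 1:
        raise ValueError(f"job.start must be in 1..{N + 1}, got {job.start}")
    if job.L < 0 or job.m0 < 0:
        raise ValueError("job must have L >= 0 and m0 >= 0")
    mc = cfg.mass_config
    if hist is None:
        hist = MassHistogram(mc.bin_width)
    elif hist.bin_width != mc.bin_width:
        raise ConfigurationError("histogram bin width differs from config")
    caps = cfg.occurrence_caps
    if caps is not None and len(caps) != N:
        raise ConfigurationError("occurrence_caps must have one entry per residue")

    masses = alphabet.masses
    bins = hist._bins
    bw = hist.bin_width
    k = job.multiplicity
    mmax = mc.mass_max
    limited = mmax is not None
    base = job.m0 + mc.adduct
    s0 = job.start - 1  # first free 0-based index
    _ensure_recursion_room(N - s0)

    fast = cfg.weighting == "compositions" and caps is None and emit is None
    if fast:

        def rec(i: int, budget: int, m: int) -> None:
            mi = masses[i]
            if i == N - 1:  # last index: one complete composition per count
                for _ in range(budget + 1):
                    if limited and m > mmax:
                        return
                    bins[(2 * m + bw) // (2 * bw)] += k
                    m += mi
                return
            for n in range(budget + 1):
                if limited and m > mmax:
                    return
                rec(i + 1, budget - n, m)
                m += mi

        if s0 >= N:  # fully determined prefix: a single composition
            if not (limited and base > mmax):
                bins[(2 * base + bw) // (2 * bw)] += k
        else:
            rec(s0, job.L, base)
        return hist

    # general path: sequence weighting, occurrence caps and/or emission
    prefix = tuple(job.prefix_counts)
    if len(prefix) != s0:
        raise ConfigurationError(
            "sequence weighting / caps / emission require prefix_counts "
            "matching the start index"
        )
    if caps is not None and any(p > c for p, c in zip(prefix, caps)):
        return hist  # the fixed prefix itself violates a cap
    sequences = cfg.weighting == "sequences"
    w0 = sequences_for_composition(prefix) if sequences else 1
    full = list(prefix) + [0] * (N - s0)
    comb = math.comb

    def gen(i: int, budget: int, m: int, length: int, w: int) -> None:
        if i == N:
            if limited and m > mmax:
                return
            bins[(2 * m + bw) // (2 * bw)] += w * k
            if emit is not None:
                emit(tuple(full))
            return
        mi = masses[i]
        top = budget if caps is None else min(budget, caps[i])
        for n in range(top + 1):
            if limited and m > mmax:
                break
            full[i] = n
            if sequences:
                gen(i + 1, budget - n, m, length + n, w * comb(length + n, n))
            else:
                gen(i + 1, budget - n, m, length + n, w)
            m += mi
        full[i] = 0

    gen(s0, job.L, base, sum(prefix), w0)
    return hist
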