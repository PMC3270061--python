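# Methods

## Model

A composition over an alphabet of N residues is a count vector
(n₁, …, n_N); its length is L = Σ nᵢ and its monoisotopic mass
m = Σ nᵢmᵢ + adduct, where the adduct is 0 (bare residue sum), water
(intact peptide) or water + proton ([M+H]⁺). Compositions, not
sequences, carry the mass information: every one of the
L!/(n₁!…n_N!) orderings of a composition has the same mass, so the
theoretical peptide mass distribution is a histogram over compositions,
optionally weighted by that multinomial when sequence counts are wanted.

Counting identities used throughout (all exact, arbitrary precision):
exact-length compositions C(N+L−1, L); up-to-length compositions
C(N+L, N) including the single empty composition (count tables
conventionally subtract it; both conventions are exposed); up-to-length
non-empty sequences N(N^L−1)/(N−1), with the N=1 degenerate case
defined as L.

## Exact mass arithmetic

All masses are integers in micro-Daltons (1 µDa = 10⁻⁶ Da). The default
residue masses are computed from elemental formulas and exact-decimal
monoisotopic atomic masses (H 1.00782503207, C 12, N 14.0030740048,
O 15.9949146196, S 31.9720711744 Da), rounded half-up to 1 µDa — e.g.
Gly = C₂H₃NO = 57.021464 Da. Integer arithmetic matters in three
places: histogram binning is reproducible across platforms; isomeric
prefixes (2×Gly+1×Val vs 3×Ala, both exactly 213 111 342 µDa) collide
bit-exactly for duplicate-job detection; and parallel histogram merging
is associative and commutative, so results are independent of worker
count and completion order. Alphabet TSV masses are decimal Daltons with
at most six decimals, scaled to µDa exactly (never through binary
floats). Leucine/isoleucine are isobaric; the ordering tie is broken
alphabetically.

## Enumeration

Compositions are visited like N-digit numbers in ascending order (digit
1 most significant) with digit sum ≤ L; recursion depth is at most the
number of free indices. The histogram-accumulating variant passes the
running prefix mass down the recursion (no mass is recomputed), adds
each composition to bin round-half-up(m / bin width), and — when a mass
ceiling is set — returns from a branch as soon as the running mass
exceeds it. Pruning is exact (identical to post-hoc filtering on the
true mass) because alphabets are mass-ascending, so every deeper or
larger assignment only adds mass. Rounding ties round up: the reference
"round to integer" is otherwise unspecified, and half-up on exact
integers is the reproducible common reading. The empty composition is
counted (weight 1 in the adduct's bin), matching the closed form;
reporting layers subtract it where non-empty totals are conventional.

Sequence weighting multiplies the running multinomial incrementally
(×C(length-so-far + nᵢ, nᵢ) as each count is fixed). Per-residue
occurrence caps simply truncate each loop. The innermost alphabet index
is unrolled into a flat loop in the compositions-weighting fast path;
this changes no output, only constant factors.

## Job splitting and parallel execution

One call (L, start=1, m₀=0) equals the L+1 calls (L−n, start=2, n·m₁)
for n = 0..L. A job table is built by expanding the root to level 2 and
then, level by level (s = 2..max_start−1), replacing in place every
level-s job whose remaining length exceeds a threshold L_max,s by its
split; thresholds must be non-decreasing in s (a deeper level should
not split more aggressively than a shallower one; the reference working
set is L_max = 20, 24, 28, 34, 40 up to start ≤ 7). After every build
the conservation invariant is verified: the multiplicities-weighted sum
of C(N−start+1+L, N−start+1) over jobs must equal C(N+L_total, N).
Zero-length jobs are kept and executed (each contributes one
composition); this keeps conservation exact at the cost of a slightly
larger job count than other bookkeeping conventions would report.

Duplicate jobs — identical (L, start, m₀) triplets from isomeric
prefixes — are merged into one job with multiplicity k, valid only
under compositions weighting (the merged members' prefixes differ, so
per-composition emission and sequence multinomials are undefined; the
executor rejects the combination). Both "fraction of jobs that are
members of a duplicate group" and "fraction a merge removes" are
reported, since "percent duplicates" is ambiguous.

Execution follows a master/worker contract: jobs are dispatched FIFO in
table order to a local process pool (workers=1 degenerates to a serial
in-process loop); each worker returns a sparse partial histogram, merged
into the master's accumulator as it arrives. A worker failure aborts the
run with the failing job's triplet; no partial results are emitted. The
multi-prefix-mass variant (one recursion serving several m₀ values at
once) is not implemented; duplicate merging covers the
compositions-weighting case.

## Mass-bounded counting without enumeration

`count_mass_bounded` counts compositions with length ≤ L and mass ≤
ceiling by a dynamic program over (length, mass-bin) cells, adding one
residue type at a time with the bounded-knapsack recurrence
f_new(l, b) = f_old(l, b) + f_new(l−1, b−wᵢ). Masses are quantized to a
`quantum` (default 10 000 µDa = 0.01 Da) by round-half-up; memory is
O(L × ceiling/quantum) words. At a 3 kDa ceiling the quantization error
is a few hundredths of a Dalton against residue masses of ~57–186 Da,
far below one percentage point on aggregate fractions; callers needing
exact thresholds set `quantum=1` (exact, more memory). The DP switches
to Python-object arithmetic automatically when the unbounded total
could approach int64 overflow.

## Tryptic compositions

A tryptic composition with c missed cleavages contains exactly c+1
residues from {K, R}; positional constraints (C-terminal placement) are
invisible to composition counting and are ignored. Each of the c+2 K/R
multisets becomes a variant: a mass/length offset plus an arbitrary
multiset over the 18-residue reduced alphabet. Enumeration runs each
variant's job table with the offset added to every prefix mass and
merges the histograms. With the default masses, the longest tryptic
composition with peptide mass (residue sum + water) ≤ 3 kDa has 51
residues (one K plus fifty glycines), and ~87% of tryptic compositions
of length ≤ 30 exceed 3 kDa — the fraction a mass-limited enumeration
skips, computed here by the DP counter rather than by enumerating.

## Determinism and problem sizes

Nothing in the method is stochastic: no seeds exist, and every run —
serial or parallel, merged or not — produces bit-identical histograms
(the output files omit wall time and worker count for this reason). The
test suite exercises full enumerations up to N=20, L=8 (3.1 million
compositions, a few seconds), brute-force cross-checks on alphabets of
≤ 4 letters, and the tryptic DP at its full published scale (length 30,
3 kDa); these sizes keep the whole suite under a minute while covering
every code path at the largest scale the closed forms can confirm
independently.

## Known limitations

- Emitting every composition is an explicit opt-in for small serial
  runs; large-L emission is out of scope by design.
- Sequence weighting cannot be combined with tryptic mode or merged
  duplicates (see above); compositions weighting supports both.
- Isotope patterns, average masses, and m/z charge conversion are out
  of scope; the histogram is monoisotopic mass only.
- Scheduling is FIFO by default (`--dispatch largest-first` reorders
  the table for load balance; results are unchanged); there is no
  checkpointing or fault-tolerant re-dispatch — a failed job fails the
  run.
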