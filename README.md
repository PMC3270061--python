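# aacomp

Exact enumeration and counting of amino-acid compositions and their
monoisotopic mass distribution.

Peptide masses are not spread uniformly: because peptides are built from
twenty residues with specific masses, the theoretical peptide mass
distribution consists of ~1 Da-spaced peaks separated by sparse "quiet
zones" and empty "forbidden zones". Knowing this distribution — for
plain peptides, tryptic peptides, modified alphabets — supports mass
defect filtering, peptide mass fingerprinting and de novo sequencing.
Obtaining it requires enumerating *every* theoretically possible
composition up to a length and/or mass limit, a task whose size grows
combinatorially. `aacomp` does this exactly, and fast enough to be
rerun "to order" whenever the alphabet, enzyme or mass limits change.

## What it computes

A composition over an alphabet of *N* residues is a count vector
(n₁, …, n_N) with length L = Σ nᵢ and monoisotopic mass
m = Σ nᵢmᵢ (+ optionally water, or water + proton). The package provides:

- **Closed-form counts** — compositions of exact length L:
  C(N+L−1, L); of all lengths ≤ L: C(N+L, N); sequences per composition:
  the multinomial L!/(n₁!…n_N!); sequences of length ≤ L:
  N(N^L−1)/(N−1). All exact big integers.
- **Recursive enumeration** — visits every composition in ascending
  N-digit order and accumulates an exact mass histogram (0.001 Da bins
  by default), carrying the running mass into the recursion and
  abandoning any branch whose mass already exceeds an optional ceiling.
- **Job splitting & parallel execution** — one task (L, start=1, m₀=0)
  is equivalent to the L+1 jobs (L−n, start=2, n·m₁); applying this
  level by level under per-level length thresholds yields a table of
  independent jobs dispatched to worker processes, whose partial
  histograms merge bit-identically in any order. Jobs with identical
  (L, start, m₀) — isomeric prefixes such as GGV vs AAA, both
  213.111 Da — are executed once with a multiplicity.
- **Mass-bounded DP counting** — the number of compositions under a
  mass ceiling, without enumeration, by a knapsack-style dynamic
  program over quantized masses.
- **Tryptic mode** — compositions with exactly (missed cleavages + 1)
  residues from {K, R}, handled as mass/length offsets over the
  18-letter reduced alphabet.

All mass arithmetic uses integer micro-Daltons (1 µDa = 10⁻⁶ Da), so
histogram bins, duplicate detection and parallel merges are exact.

## Worked example

```
$ aacomp count -N 20 -L 10
compositions_exact_length: 20,030,010
compositions_up_to_length: 30,045,014
sequences_up_to_length: 10,778,947,368,420
ratio_sequences_to_compositions: 358,760
```

30,045,014 is the number of non-empty compositions of length ≤ 10 over
the 20 standard residues (C(30, 20) − 1); on average each mass-distinct
composition stands in for ~358,760 sequences — which is why the mass
distribution is built over compositions, not sequences.

```
$ aacomp enumerate -N 20 -L 3 --workers 2 --out hist.tsv
$ head -4 hist.tsv ; grep -c $'\t' hist.tsv
# aacomp 0.1.0
# alphabet_sha256: 62bdaaf7d07ed3...
# alphabet_size: 20
# length_max: 3
```

The histogram TSV lists `bin_index  mass_da  count` rows (one per
occupied 0.001 Da bin) under a manifest header that reproduces the run
exactly; its total weight 1,771 is C(23, 20): the 1,770 non-empty
compositions of length ≤ 3 plus the empty one.

```
$ aacomp jobs -N 20 -L 40 --lmax 20,24,28,34,40 --merge-duplicates --out jobs.tsv
```

writes the job table (with the conservation total C(60, 20) and
duplicate-group statistics in the header) that a long parallel run would
dispatch.

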