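"""Job splitting, duplicate merging and master/worker execution.

A single enumeration task (L, start=1, m0=0) is equivalent to the L+1
jobs (L, 2, 0), (L−1, 2, m₁), …, (0, 2, L·m₁), obtained by fixing the
count of the first (lightest) residue.  Applying the same expansion
level by level — splitting every level-s job whose remaining length
exceeds a threshold L_max,s — yields a table of independent jobs whose
weighted composition counts conserve the total C(N+L, N) exactly.

Isomeric prefixes (e.g. Gly-Gly-Val vs Ala-Ala-Ala, both 213.111 Da)
produce jobs with identical (L, start, m0); under compositions weighting
such duplicates may be executed once with a multiplicity.

Execution follows a master/worker contract: jobs are dispatched FIFO in
table order to a pool of stateless workers, each returning a partial
histogram; per-bin integer merging makes the final histogram
bit-identical for any worker count or completion order.
"""

from __future__ import annotations

import logging
import multiprocessing
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .alphabet import Alphabet, ConfigurationError
from .combinatorics import compositions_up_to_length, job_composition_count
from .enumeration import EnumerationConfig, MassHistogram, accumulate_histogram

logger = logging.getLogger(__name__)


class JobExecutionError(ConfigurationError):
    """A worker failed while executing a job; the run aborts."""


@dataclass(frozen=True)
class JobSpec:
    """One independent unit of enumeration work.

    ``start`` is the 1-based first free alphabet index; counts for indices
    below it are fixed by ``prefix_counts`` with total mass ``m0``.  A
    ``multiplicity`` k > 1 marks a merged duplicate: its histogram is
    counted k times.
    """

    L: int
    start: int
    m0: int
    prefix_counts: Tuple[int, ...] = ()
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("job length budget must be >= 0")
        if self.start < 1:
            raise ValueError("start is 1-based and must be >= 1")
        if self.m0 < 0:
            raise ValueError("prefix mass must be >= 0")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    @property
    def triplet(self) -> Tuple[int, int, int]:
        return (self.L, self.start, self.m0)


def split_job(job: JobSpec, alphabet: Alphabet) -> List[JobSpec]:
    """Replace a job by the L+1 equivalent jobs that fix the next index.

    The n-th child (n = 0..L) sets the count at index ``start`` to n:
    (L−n, start+1, m0 + n·m_start).  Merging the children's histograms
    reproduces the parent's exactly.
    """
    if job.start > alphabet.size:
        raise ConfigurationError(
            f"cannot split job with start={job.start}: no free index "
            f"in an alphabet of size {alphabet.size}"
        )
    m = alphabet.masses[job.start - 1]
    return [
        JobSpec(
            L=job.L - n,
            start=job.start + 1,
            m0=job.m0 + n * m,
            prefix_counts=job.prefix_counts + (n,),
            multiplicity=job.multiplicity,
        )
        for n in range(job.L + 1)
    ]


@dataclass(frozen=True)
class JobTableParams:
    """Splitting depth and per-level length thresholds.

    Every level-s job with remaining length > ``lmax[s]`` is split into
    level s+1 jobs, for s = 2..max_start−1.  Thresholds must be present
    for exactly those levels and be non-decreasing in s.
    """

    max_start: int = 2
    lmax: Dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.max_start < 2:
            raise ConfigurationError("max_start must be >= 2")
        needed = list(range(2, self.max_start))
        missing = [s for s in needed if s not in self.lmax]
        if missing:
            raise ConfigurationError(
                f"lmax thresholds missing for level(s) {missing}"
            )
        values = [self.lmax[s] for s in needed]
        if any(b < a for a, b in zip(values, values[1:])):
            raise ConfigurationError("lmax thresholds must be non-decreasing")


@dataclass(frozen=True)
class JobTable:
    """An ordered job list; insertion order is the dispatch order.

    ``total_length`` is the root task's L when the table covers a single
    full enumeration (None for concatenated tables, e.g. tryptic
    variants, where the conservation identity does not apply as is).
    """

    jobs: Tuple[JobSpec, ...]
    total_length: Optional[int] = None

    def __len__(self) -> int:
        return len(self.jobs)

    def __iter__(self):
        return iter(self.jobs)

    def conservation_total(self, alphabet: Alphabet) -> int:
        """Σ over jobs of k · C(N−start+1+L, N−start+1)."""
        N = alphabet.size
        return sum(
            j.multiplicity * job_composition_count(N, j.L, j.start)
            for j in self.jobs
        )

    def validate(self, alphabet: Alphabet) -> None:
        """Check the conservation invariant against the closed form."""
        if self.total_length is None:
            return
        expected = compositions_up_to_length(alphabet.size, self.total_length)
        actual = self.conservation_total(alphabet)
        if actual != expected:
            raise ConfigurationError(
                f"job table violates conservation: covers {actual} "
                f"compositions, expected {expected}"
            )


def build_job_table(
    L: int, alphabet: Alphabet, params: Optional[JobTableParams] = None
) -> JobTable:
    """Split the root task (L, 1, 0) into a job table.

    The root is always expanded to level 2; then for each level
    s = 2..max_start−1, every job with remaining length > lmax[s] is
    replaced in place by its split (children keep the parent's position,
    so the table stays in generation order).  The conservation invariant
    is verified before returning.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    if params is None:
        params = JobTableParams()
    jobs = split_job(JobSpec(L, 1, 0), alphabet)
    for s in range(2, params.max_start):
        if s > alphabet.size:
            break  # nothing at this level can be split further
        threshold = params.lmax[s]
        nxt: List[JobSpec] = []
        for job in jobs:
            if job.start == s and job.L > threshold:
                nxt.extend(split_job(job, alphabet))
            else:
                nxt.append(job)
        jobs = nxt
    table = JobTable(tuple(jobs), total_length=L)
    table.validate(alphabet)
    return table


def merge_duplicate_jobs(table: JobTable) -> JobTable:
    """Merge jobs with identical (L, start, m0) into one with a multiplicity.

    Exact integer µDa equality — isomeric prefixes collide bit-exactly.
    Valid only for compositions weighting (merged jobs have different
    prefixes, so per-composition emission and sequence weighting are
    undefined); :func:`execute` enforces this.  The first member's prefix
    and table position are retained; conservation is preserved.
    """
    groups: Dict[Tuple[int, int, int], int] = {}
    order: List[JobSpec] = []
    for job in table.jobs:
        key = job.triplet
        if key in groups:
            groups[key] += job.multiplicity
        else:
            groups[key] = job.multiplicity
            order.append(job)
    merged = tuple(replace(j, multiplicity=groups[j.triplet]) for j in order)
    return JobTable(merged, total_length=table.total_length)


@dataclass(frozen=True)
class DuplicateStats:
    """How many jobs in a table collide on (L, start, m0).

    Two fractions are reported because "percent duplicates" is ambiguous:
    ``fraction_members`` counts every member of a colliding group,
    ``fraction_redundant`` only the members beyond the first (the jobs a
    merge actually removes).
    """

    n_jobs: int
    n_groups: int
    n_duplicate_members: int
    n_redundant: int

    @property
    def fraction_members(self) -> float:
        return self.n_duplicate_members / self.n_jobs if self.n_jobs else 0.0

    @property
    def fraction_redundant(self) -> float:
        return self.n_redundant / self.n_jobs if self.n_jobs else 0.0


def duplicate_stats(table: JobTable) -> DuplicateStats:
    sizes: Dict[Tuple[int, int, int], int] = {}
    for job in table.jobs:
        sizes[job.triplet] = sizes.get(job.triplet, 0) + 1
    n_jobs = len(table.jobs)
    n_groups = len(sizes)
    dup_members = sum(c for c in sizes.values() if c > 1)
    return DuplicateStats(
        n_jobs=n_jobs,
        n_groups=n_groups,
        n_duplicate_members=dup_members,
        n_redundant=n_jobs - n_groups,
    )


def _run_job(payload) -> Dict[int, int]:
    job, alphabet, cfg = payload
    try:
        hist = accumulate_histogram(job, alphabet, cfg)
        return dict(hist._bins)
    except Exception as exc:  # surfaced to the master with the job identity
        raise JobExecutionError(
            f"job (L={job.L}, start={job.start}, m0={job.m0}) failed: {exc}"
        ) from None


def execute(
    table: JobTable,
    alphabet: Alphabet,
    cfg: EnumerationConfig,
    workers: int = 1,
) -> MassHistogram:
    """Execute every job exactly once and merge the partial histograms.

    ``workers=1`` runs serially in-process; otherwise a local process
    pool plays the worker role, the current process the master.  Results
    are bit-identical regardless of worker count or completion order.
    A worker failure aborts the whole run (no partial histogram).
    """
    if workers < 1:
        raise ConfigurationError("workers must be >= 1")
    if cfg.weighting != "compositions" and any(
        j.multiplicity != 1 for j in table.jobs
    ):
        raise ConfigurationError(
            "merged duplicate jobs are only valid with compositions weighting"
        )
    hist = MassHistogram(cfg.mass_config.bin_width)
    if workers == 1 or len(table.jobs) <= 1:
        for i, job in enumerate(table.jobs):
            accumulate_histogram(job, alphabet, cfg, hist)
            logger.debug(
                "job %d/%d done (L=%d, start=%d, m0=%d)",
                i + 1, len(table.jobs), job.L, job.start, job.m0,
            )
        return hist

    payloads = [(job, alphabet, cfg) for job in table.jobs]
    ctx = multiprocessing.get_context()
    done = 0
    with ctx.Pool(processes=workers) as pool:
        for bins in pool.imap_unordered(_run_job, payloads):
            for b, c in bins.items():
                hist._bins[b] += c
            done += 1
            logger.debug("merged %d/%d partial histograms", done, len(payloads))
    return hist
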