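import random

import pytest

from aacomp import (
    Alphabet,
    ConfigurationError,
    EnumerationConfig,
    JobSpec,
    JobTable,
    JobTableParams,
    MassConfig,
    Residue,
    accumulate_histogram,
    build_job_table,
    compositions_up_to_length,
    duplicate_stats,
    execute,
    histogram_merge,
    merge_duplicate_jobs,
    split_job,
)


def _random_alphabet(rng, n):
    masses = rng.sample(range(1_000_000, 60_000_000), n)
    return Alphabet(
        Residue(chr(ord("a") + i), m) for i, m in enumerate(masses)
    )


def _histogram_of(jobs, alphabet, cfg):
    out = None
    for job in jobs:
        h = accumulate_histogram(job, alphabet, cfg)
        out = h if out is None else histogram_merge(out, h)
    return out


class TestSplitJob:
    def test_worked_example_three_letters(self, abc_alphabet):
        m1 = abc_alphabet.masses[0]
        children = split_job(JobSpec(2, 1, 0), abc_alphabet)
        assert [(j.L, j.start, j.m0) for j in children] == [
            (2, 2, 0), (1, 2, m1), (0, 2, 2 * m1)
        ]
        assert [j.prefix_counts for j in children] == [(0,), (1,), (2,)]

    def test_zero_budget_job_splits_into_one(self, abc_alphabet):
        children = split_job(JobSpec(0, 2, 123, prefix_counts=(0,)),
                             abc_alphabet)
        assert len(children) == 1
        assert children[0] == JobSpec(0, 3, 123, prefix_counts=(0, 0))

    def test_split_beyond_last_index_rejected(self, gv_alphabet):
        with pytest.raises(ConfigurationError):
            split_job(JobSpec(2, 3, 0, prefix_counts=(0, 0)), gv_alphabet)

    def test_split_children_reproduce_parent_histogram(self):
        rng = random.Random(23)
        for _ in range(8):
            n = rng.randint(1, 4)
            a = _random_alphabet(rng, n)
            L = rng.randint(0, 6)
            start = rng.randint(1, n)
            prefix = tuple(rng.randint(0, 1) for _ in range(start - 1))
            m0 = sum(c * m for c, m in zip(prefix, a.masses))
            parent = JobSpec(L, start, m0, prefix_counts=prefix)
            cfg = EnumerationConfig(length_max=L + sum(prefix))
            expected = accumulate_histogram(parent, a, cfg)
            got = _histogram_of(split_job(parent, a), a, cfg)
            assert got == expected


class TestJobTable:
    def test_plain_split_has_l_plus_one_jobs(self, default_alpha):
        table = build_job_table(30, default_alpha, JobTableParams(max_start=2))
        assert len(table) == 31
        assert all(j.start == 2 for j in table)

    def test_large_threshold_is_no_op(self, default_alpha):
        params = JobTableParams(max_start=3, lmax={2: 100})
        assert build_job_table(12, default_alpha, params).jobs == \
            build_job_table(12, default_alpha, JobTableParams()).jobs

    def test_conservation_for_deep_table(self, default_alpha):
        params = JobTableParams(max_start=5, lmax={2: 20, 3: 24, 4: 28})
        table = build_job_table(30, default_alpha, params)
        assert table.conservation_total(default_alpha) == \
            compositions_up_to_length(20, 30)

    def test_conservation_for_random_params(self):
        rng = random.Random(5)
        for _ in range(10):
            n = rng.randint(2, 6)
            a = _random_alphabet(rng, n)
            L = rng.randint(0, 8)
            max_start = rng.randint(2, n + 1)
            lmax, last = {}, 0
            for s in range(2, max_start):
                last = last + rng.randint(0, 3)
                lmax[s] = last
            table = build_job_table(L, a, JobTableParams(max_start, lmax))
            assert table.conservation_total(a) == \
                compositions_up_to_length(n, L)

    def test_table_histogram_equals_root_job(self):
        rng = random.Random(17)
        for _ in range(6):
            n = rng.randint(2, 5)
            a = _random_alphabet(rng, n)
            L = rng.randint(0, 7)
            max_start = rng.randint(2, n + 1)
            lmax = {s: rng.randint(0, L) for s in range(2, max_start)}
            lmax = dict(zip(sorted(lmax), sorted(lmax.values())))
            cfg = EnumerationConfig(length_max=L)
            root = accumulate_histogram(JobSpec(L, 1, 0), a, cfg)
            table = build_job_table(L, a, JobTableParams(max_start, lmax))
            assert execute(table, a, cfg) == root

    def test_missing_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            JobTableParams(max_start=4, lmax={2: 10})

    def test_decreasing_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            JobTableParams(max_start=4, lmax={2: 10, 3: 5})


class TestDuplicateJobs:
    def test_table_without_duplicates_unchanged(self, abc_alphabet):
        table = build_job_table(3, abc_alphabet, JobTableParams())
        assert merge_duplicate_jobs(table).jobs == table.jobs

    def test_isomeric_prefixes_merge_with_multiplicity(self, default_alpha):
        a = default_alpha
        ggv = JobSpec(37, 6, 2 * a.mass_of("G") + a.mass_of("V"),
                      prefix_counts=(2, 0, 0, 0, 1))
        aaa = JobSpec(37, 6, 3 * a.mass_of("A"),
                      prefix_counts=(0, 3, 0, 0, 0))
        assert ggv.m0 == aaa.m0 == 213_111_342
        merged = merge_duplicate_jobs(JobTable((ggv, aaa)))
        assert len(merged) == 1
        assert merged.jobs[0].multiplicity == 2
        assert merged.jobs[0].prefix_counts == (2, 0, 0, 0, 1)

    def test_deep_table_contains_isomeric_duplicates(self, default_alpha):
        params = JobTableParams(
            max_start=7, lmax={2: 20, 3: 24, 4: 28, 5: 34, 6: 40}
        )
        table = build_job_table(40, default_alpha, params)
        stats = duplicate_stats(table)
        assert stats.n_redundant > 0
        merged = merge_duplicate_jobs(table)
        assert len(merged) == stats.n_groups
        merged.validate(default_alpha)  # conservation preserved

    def test_merging_preserves_histogram(self):
        rng = random.Random(3)
        # isomer-rich alphabet: b+c == 2a guarantees duplicate prefixes
        a = Alphabet([Residue("a", 4_000_000), Residue("b", 3_000_000),
                      Residue("c", 5_000_000), Residue("d", 9_000_000)])
        cfg = EnumerationConfig(length_max=6)
        params = JobTableParams(max_start=4, lmax={2: 2, 3: 3})
        table = build_job_table(6, a, params)
        merged = merge_duplicate_jobs(table)
        assert len(merged) < len(table)
        assert execute(merged, a, cfg) == execute(table, a, cfg)


class TestExecute:
    def test_parallel_equals_serial(self, default_alpha):
        cfg = EnumerationConfig(length_max=5)
        table = build_job_table(5, default_alpha, JobTableParams())
        serial = execute(table, default_alpha, cfg, workers=1)
        for workers in (2, 4):
            assert execute(table, default_alpha, cfg, workers=workers) == serial
        assert serial.total_weight == 53_130

    def test_empty_table_gives_empty_histogram(self, gv_alphabet):
        hist = execute(JobTable(()), gv_alphabet,
                       EnumerationConfig(length_max=3))
        assert hist.bins == {}
        assert hist.total_weight == 0

    def test_mass_limited_parallel_run(self, default_alpha):
        cfg = EnumerationConfig(
            length_max=6, mass_config=MassConfig(mass_max=400_000_000)
        )
        table = build_job_table(6, default_alpha, JobTableParams())
        assert execute(table, default_alpha, cfg, workers=2) == \
            execute(table, default_alpha, cfg, workers=1)

    def test_merged_jobs_with_sequence_weighting_rejected(self, gv_alphabet):
        table = JobTable((JobSpec(2, 2, 0, prefix_counts=(0,),
                                  multiplicity=2),))
        cfg = EnumerationConfig(length_max=2, weighting="sequences")
        with pytest.raises(ConfigurationError):
            execute(table, gv_alphabet, cfg)
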