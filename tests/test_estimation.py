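"""Haplotype-frequency estimation: segregation counting, EM, and the merge."""

import itertools

import numpy as np
import pytest

from hlapop import (
    Cohort,
    EMSettings,
    GenotypeRecord,
    SyntheticConfig,
    combine_estimates,
    count_phase_known,
    em_frequencies,
    parse_allele,
    parse_haplotype,
    simulate_cohort,
)
from hlapop.tables import HaplotypeTable

from conftest import two_locus_pool

LOCI = ("A", "B")


def _rec(sid, a1, a2, b1, b2, family=None, role="unrelated"):
    return GenotypeRecord(
        subject_id=sid,
        genotypes={
            "A": (parse_allele(a1), parse_allele(a2)),
            "B": (parse_allele(b1), parse_allele(b2)),
        },
        family_id=family,
        role=role,
    )


# --- family segregation ---------------------------------------------------


def test_trio_with_homozygous_child_fully_resolves():
    cohort = Cohort(
        LOCI,
        [
            _rec("m", "A*01:01", "A*02:01", "B*07:02", "B*08:01", "f1", "parent"),
            _rec("p", "A*01:01", "A*03:01", "B*07:02", "B*44:02", "f1", "parent"),
            _rec("c", "A*01:01", "A*01:01", "B*07:02", "B*07:02", "f1", "child"),
        ],
    )
    table, inconsistencies = count_phase_known(cohort)
    assert not inconsistencies
    assert sum(table.counts.values()) == 4
    assert table.counts[parse_haplotype("A*01:01~B*07:02", LOCI)] == 2
    assert table.counts[parse_haplotype("A*02:01~B*08:01", LOCI)] == 1
    assert table.counts[parse_haplotype("A*03:01~B*44:02", LOCI)] == 1


def test_trio_with_four_distinct_alleles_resolves_by_transmission():
    cohort = Cohort(
        LOCI,
        [
            _rec("m", "A*01:01", "A*02:01", "B*07:02", "B*08:01", "f1", "parent"),
            _rec("p", "A*03:01", "A*24:02", "B*44:02", "B*51:01", "f1", "parent"),
            _rec("c", "A*01:01", "A*03:01", "B*07:02", "B*44:02", "f1", "child"),
        ],
    )
    table, inconsistencies = count_phase_known(cohort)
    assert not inconsistencies
    assert table.counts == {
        parse_haplotype("A*01:01~B*07:02", LOCI): 1,
        parse_haplotype("A*02:01~B*08:01", LOCI): 1,
        parse_haplotype("A*03:01~B*44:02", LOCI): 1,
        parse_haplotype("A*24:02~B*51:01", LOCI): 1,
    }


def test_mendelian_inconsistency_reported_not_counted():
    cohort = Cohort(
        LOCI,
        [
            _rec("m", "A*01:01", "A*01:01", "B*07:02", "B*07:02", "f1", "parent"),
            _rec("p", "A*02:01", "A*02:01", "B*08:01", "B*08:01", "f1", "parent"),
            _rec("c", "A*03:01", "A*01:01", "B*07:02", "B*08:01", "f1", "child"),
        ],
    )
    table, inconsistencies = count_phase_known(cohort)
    assert len(inconsistencies) == 1
    assert inconsistencies[0].locus == "A"
    assert sum((table.counts or {}).values()) == 0


def test_ambiguous_trio_left_to_em():
    # everyone shares the same heterozygous genotype: transmission ambiguous
    cohort = Cohort(
        LOCI,
        [
            _rec("m", "A*01:01", "A*02:01", "B*07:02", "B*08:01", "f1", "parent"),
            _rec("p", "A*01:01", "A*02:01", "B*07:02", "B*08:01", "f1", "parent"),
            _rec("c", "A*01:01", "A*02:01", "B*07:02", "B*08:01", "f1", "child"),
        ],
    )
    table, inconsistencies = count_phase_known(cohort)
    assert not inconsistencies
    assert sum((table.counts or {}).values()) == 0


# --- EM ---------------------------------------------------------------------


def test_em_equals_direct_counts_on_homozygous_cohort():
    records = [
        _rec("s1", "A*01:01", "A*01:01", "B*07:02", "B*07:02"),
        _rec("s2", "A*01:01", "A*01:01", "B*07:02", "B*07:02"),
        _rec("s3", "A*02:01", "A*02:01", "B*08:01", "B*08:01"),
    ]
    table = em_frequencies(Cohort(LOCI, records), LOCI, EMSettings(seed=0))
    assert table.frequencies[parse_haplotype("A*01:01~B*07:02", LOCI)] == pytest.approx(4 / 6)
    assert table.frequencies[parse_haplotype("A*02:01~B*08:01", LOCI)] == pytest.approx(2 / 6)


def test_em_symmetric_fixed_point_for_lone_double_heterozygote():
    records = [_rec("s1", "A*01:01", "A*02:01", "B*07:02", "B*08:01")]
    table = em_frequencies(
        Cohort(LOCI, records), LOCI, EMSettings(seed=0, restarts=1)
    )
    # the uniform start is a fixed point: all four haplotypes at 0.25
    assert sorted(table.frequencies.values()) == pytest.approx([0.25] * 4)


def _grid_optimum(cohort, pool_haps, step=0.02):
    """Brute-force likelihood maximization over the 3-simplex (oracle)."""
    from hlapop.estimation import _compatible_pairs

    index = {h: i for i, h in enumerate(pool_haps)}
    subj = []
    for r in cohort.records:
        pairs = [
            (index[h1], index[h2])
            for h1, h2 in _compatible_pairs(r, LOCI, 2)
            if h1 in index and h2 in index
        ]
        subj.append(pairs)
    k = int(round(1 / step))
    best, best_f = -np.inf, None
    for c in itertools.product(range(k + 1), repeat=3):
        if sum(c) > k:
            continue
        f = np.array([c[0], c[1], c[2], k - sum(c)]) / k
        ll = 0.0
        for pairs in subj:
            like = sum(
                f[i] * f[j] * (1 if i == j else 2) for i, j in pairs
            )
            if like <= 0:
                ll = -np.inf
                break
            ll += np.log(like)
        if ll > best:
            best, best_f = ll, f
    return best_f


def test_em_matches_bruteforce_grid_on_hidden_phase():
    pool = two_locus_pool()
    cfg = SyntheticConfig(
        pool=pool, n_subjects=50, n_trios=0, inbreeding_f=0.0,
        scramble_rate=0.0, seed=21,
    )
    cohort, _ = simulate_cohort(cfg)
    est = em_frequencies(cohort, LOCI, EMSettings(seed=0))
    grid_f = _grid_optimum(cohort, [e.haplotype for e in pool])
    est_f = np.array([est.frequencies.get(e.haplotype, 0.0) for e in pool])
    assert np.abs(est_f - grid_f).max() < 0.03


def test_em_equals_gene_counting_on_phase_known_data():
    # phase known <=> at most one heterozygous locus per subject
    records = [
        _rec("s1", "A*01:01", "A*02:01", "B*07:02", "B*07:02"),
        _rec("s2", "A*01:01", "A*01:01", "B*07:02", "B*08:01"),
        _rec("s3", "A*02:01", "A*02:01", "B*08:01", "B*08:01"),
    ]
    table = em_frequencies(Cohort(LOCI, records), LOCI, EMSettings(seed=1))
    # direct gene counting: each subject has at most one heterozygous locus,
    # so both chromosomes are observable
    assert table.frequencies[parse_haplotype("A*01:01~B*07:02", LOCI)] == pytest.approx(2 / 6)
    assert table.frequencies[parse_haplotype("A*02:01~B*07:02", LOCI)] == pytest.approx(1 / 6)
    assert table.frequencies[parse_haplotype("A*01:01~B*08:01", LOCI)] == pytest.approx(1 / 6)
    assert table.frequencies[parse_haplotype("A*02:01~B*08:01", LOCI)] == pytest.approx(2 / 6)


def test_em_recovery_error_decreases_with_cohort_size():
    pool = two_locus_pool()
    true = np.array([e.frequency for e in pool])
    maes = []
    for n in (50, 200, 800):
        cfg = SyntheticConfig(
            pool=pool, n_subjects=n, n_trios=0, inbreeding_f=0.0,
            scramble_rate=0.0, seed=31,
        )
        cohort, _ = simulate_cohort(cfg)
        est = em_frequencies(cohort, LOCI, EMSettings(seed=0))
        est_f = np.array([est.frequencies.get(e.haplotype, 0.0) for e in pool])
        maes.append(np.abs(est_f - true).mean())
    assert maes[2] < maes[0]


# --- merge -------------------------------------------------------------------


def test_combine_identity_cases():
    counted = HaplotypeTable.from_counts(
        LOCI, {parse_haplotype("A*01:01~B*07:02", LOCI): 4}
    )
    empty_em = HaplotypeTable(LOCI, {}, None, 0)
    merged = combine_estimates(counted, empty_em)
    assert merged.frequencies == {parse_haplotype("A*01:01~B*07:02", LOCI): 1.0}

    em = HaplotypeTable(
        LOCI,
        {
            parse_haplotype("A*01:01~B*07:02", LOCI): 0.75,
            parse_haplotype("A*02:01~B*08:01", LOCI): 0.25,
        },
        None,
        8,
    )
    empty_counted = HaplotypeTable.from_counts(LOCI, {})
    assert combine_estimates(empty_counted, em).frequencies == em.frequencies


def test_combine_weighted_merge_arithmetic():
    h1 = parse_haplotype("A*01:01~B*07:02", LOCI)
    h2 = parse_haplotype("A*02:01~B*08:01", LOCI)
    counted = HaplotypeTable.from_counts(LOCI, {h1: 60, h2: 10})  # 70 chromosomes
    em = HaplotypeTable(LOCI, {h1: 0.5, h2: 0.5}, None, 388)
    merged = combine_estimates(counted, em)
    assert merged.total_chromosomes == 458
    assert merged.frequencies[h1] == pytest.approx((60 + 0.5 * 388) / 458)
    assert merged.frequencies[h2] == pytest.approx((10 + 0.5 * 388) / 458)
    assert merged.total_frequency() == pytest.approx(1.0)


def test_combine_rejects_locus_mismatch():
    counted = HaplotypeTable.from_counts(LOCI, {})
    em = HaplotypeTable(("A", "C"), {}, None, 0)
    with pytest.raises(ValueError):
        combine_estimates(counted, em)
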