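"""Query path: FP correction, level selection, interpolated median."""

import numpy as np
import pytest

from qqfilter import (
    MinimizerParams,
    QuerySketch,
    ThresholdScheme,
    build_index,
    corrected_count,
    count_minimizers,
    estimate_file,
    estimate_sketch,
    interpolate_median,
    min_hits_to_estimate,
    minimizer_values,
    normalize,
    query_level_counts,
    select_levels,
    sketch_transcript,
)
from qqfilter.estimate import LevelCounts
from qqfilter.synthetic import write_fasta

from conftest import random_dna


# --- false-positive correction ---------------------------------------------


def test_corrected_count_zero_fpr_is_identity():
    assert corrected_count(17, 100, 0.0) == 17.0


def test_corrected_count_pure_noise_is_zero():
    m, fpr = 200, 0.03
    assert corrected_count(m * fpr, m, fpr) == 0.0


def test_corrected_count_arithmetic():
    assert corrected_count(24, 100, 0.05) == pytest.approx((24 - 5) / 0.95)
    assert corrected_count(24, 100, 0.05) == pytest.approx(20.0)


def test_corrected_count_clamped_to_observed():
    assert corrected_count(3, 100, 0.5) <= 3.0
    assert corrected_count(0, 100, 0.1) == 0.0


# --- estimation trigger -----------------------------------------------------


def test_half_of_14_minimizers_triggers_at_7():
    assert min_hits_to_estimate(14) == 7


@pytest.mark.parametrize("m,expected", [(1, 1), (2, 1), (13, 7), (100, 50)])
def test_trigger_is_smallest_count_reaching_half(m, expected):
    assert min_hits_to_estimate(m) == expected
    assert 2 * expected >= m
    assert 2 * (expected - 1) < m


# --- level selection vs exhaustive evaluation ------------------------------


def _oracle_select(corrected: np.ndarray, m: int, e: int):
    """Evaluate the two half-coverage inequalities at every candidate level."""
    q = corrected.shape[0]
    solutions = []
    for x in range(1, q + 1):
        a = float(corrected[x - 1, e])
        b = float(corrected[x:, e].sum())
        if 2 * (a + b) >= m and 2 * b < m:
            solutions.append((x, a, b))
    return solutions


def _level_counts(corrected: np.ndarray) -> LevelCounts:
    return LevelCounts(raw=np.ceil(corrected).astype(np.int64), corrected=corrected)


def test_select_levels_matches_exhaustive_oracle():
    rng = np.random.default_rng(0)
    q, m = 5, 14
    for _ in range(300):
        corrected = rng.uniform(0, m / 2, size=(q, 1)) * (rng.random((q, 1)) < 0.6)
        got = select_levels(_level_counts(corrected), m, 0)
        expect = _oracle_select(corrected, m, 0)
        assert len(expect) <= 1  # the crossing level is unique
        if expect:
            x, a, b = expect[0]
            assert got is not None
            assert got[0] == x
            assert got[2] == pytest.approx(a)
            assert got[3] == pytest.approx(b)
        else:
            assert got is None


def test_select_levels_all_found_at_top_level():
    corrected = np.zeros((3, 1))
    corrected[2, 0] = 14.0
    sel = select_levels(_level_counts(corrected), 14, 0)
    assert sel is not None and sel[0] == 3 and sel[1] == 3


def test_select_levels_zero_counts_not_expressed():
    assert select_levels(_level_counts(np.zeros((4, 1))), 10, 0) is None


def test_select_levels_split_between_levels_1_and_3():
    """Half the minimizers at level 1 and half at level 3: level 3 already
    reaches the half on its own (with nothing above it), so the top-down
    scan stops there -- exactly what the exhaustive evaluation decides."""
    corrected = np.zeros((3, 1))
    corrected[0, 0] = 7.0
    corrected[2, 0] = 7.0
    got = select_levels(_level_counts(corrected), 14, 0)
    expect = _oracle_select(corrected, 14, 0)
    assert [got[0]] == [x for x, _, _ in expect] == [3]


# --- interpolation ----------------------------------------------------------


def _scheme(thresholds, mode="user"):
    return ThresholdScheme(mode=mode, thresholds=thresholds, cutoff=thresholds[0])


def test_top_level_estimate_is_its_threshold():
    scheme = _scheme((1, 4, 8))
    assert interpolate_median((3, 3, 10.0, 0.0), 14, scheme) == 8.0


def test_not_expressed_estimate_is_zero():
    assert interpolate_median(None, 14, _scheme((1, 4, 8))) == 0.0


def test_interpolation_boundary_hits_lower_threshold():
    """When level x exactly reaches the half (b = m/2 - a), mu = T_x."""
    m, a = 14, 4.0
    b = m / 2 - a
    scheme = _scheme((1, 4, 8))
    assert interpolate_median((1, 2, a, b), m, scheme) == pytest.approx(1.0)


def test_interpolation_other_boundary_hits_upper_threshold():
    """When the levels above already held almost half, mu -> T_y."""
    m = 14
    scheme = _scheme((1, 4, 8))
    mu = interpolate_median((1, 2, 5.0, m / 2 - 1e-9), m, scheme)
    assert mu == pytest.approx(4.0, abs=1e-6)


def test_interpolation_clamped_into_bucket():
    scheme = _scheme((2, 6, 9))
    mu = interpolate_median((1, 2, 0.5, 0.0), 14, scheme)  # would overshoot below
    assert 2.0 <= mu <= 6.0


# --- normalization ----------------------------------------------------------


def test_normalize_at_t2_is_one_and_scales():
    scheme = _scheme((1, 4, 8), mode="auto")
    assert normalize(4.0, scheme) == 1.0
    assert normalize(6.0, scheme) == 1.5


def test_normalize_requires_auto_thresholds():
    with pytest.raises(ValueError, match="automatic thresholds"):
        normalize(4.0, _scheme((1, 4, 8), mode="user"))


# --- whole-query behavior on exact-count toy indexes ------------------------


def _toy_index(tmp_path, reads_per_experiment, k=15, w=19, q=40):
    """User thresholds t_i = i and a vanishing FPR: counts map 1:1 to
    levels, so the interpolated median can be checked against true counts."""
    experiments = []
    for name, reads in reads_per_experiment.items():
        path = tmp_path / f"{name}.fa"
        write_fasta(reads, path)
        experiments.append((name, [path]))
    params = MinimizerParams(k=k, w=w)
    return build_index(
        experiments, params, q,
        mode="user", user_thresholds=list(range(1, q + 1)), target_fpr=1e-6,
    ), params


def test_estimate_matches_brute_force_median(tmp_path, tiny_fixture):
    """With unit-width buckets and negligible FPR the interpolated median
    lands within one bucket of the true median of minimizer counts for at
    least 90% of transcripts."""
    params = MinimizerParams(k=19, w=19)
    index = build_index(
        tiny_fixture["experiments"], params, 40,
        mode="user", user_thresholds=list(range(1, 41)), target_fpr=1e-6,
    )
    exact = [count_minimizers(files, params).counts
             for _, files in tiny_fixture["experiments"]]
    table = estimate_file(index, tiny_fixture["transcripts_fasta"])
    from Bio import SeqIO

    n_ok = n_total = 0
    for record in SeqIO.parse(tiny_fixture["transcripts_fasta"], "fasta"):
        values = minimizer_values(str(record.seq), params)
        row = table[table.transcript == record.id].iloc[0]
        for e, (name, _) in enumerate(tiny_fixture["experiments"]):
            true_counts = np.array([exact[e].get(v, 0) for v in values])
            true_median = float(np.median(true_counts))
            n_total += 1
            if abs(row[name] - true_median) <= 1.0:
                n_ok += 1
    assert n_ok / n_total >= 0.9


def test_estimate_monotone_in_coverage(tmp_path):
    """Doubling an experiment's depth of a transcript never lowers the
    unnormalized estimate on an exact-count toy index."""
    rng = np.random.default_rng(1)
    tx = random_dna(rng, 300)
    index, params = _toy_index(tmp_path, {
        "lo": [(f"r{i}", tx) for i in range(3)],
        "hi": [(f"r{i}", tx) for i in range(6)],
    })
    est = estimate_sketch(index, sketch_transcript("tx", tx, params))
    lo, hi = est.estimates
    assert lo == pytest.approx(3.0, abs=1.0)
    assert hi == pytest.approx(6.0, abs=1.0)
    assert hi >= lo


def test_median_robust_to_contaminated_minimizers(tmp_path):
    """Raising a quarter of a transcript's minimizers to 10x their count
    moves the estimate by less than one bucket width."""
    rng = np.random.default_rng(2)
    tx = random_dna(rng, 400)
    quarter = tx[:100]
    clean = [(f"c{i}", tx) for i in range(5)]
    contaminated = clean + [(f"x{i}", quarter) for i in range(45)]
    index, params = _toy_index(
        tmp_path, {"clean": clean, "dirty": contaminated}, q=60
    )
    est = estimate_sketch(index, sketch_transcript("tx", tx, params))
    assert abs(est.estimates[1] - est.estimates[0]) <= 1.0


def test_query_costs_exactly_q_bulk_passes(tiny_index):
    tiny_index.query_passes = 0
    sketch = QuerySketch("probe", list(range(50)))
    query_level_counts(tiny_index, sketch)
    assert tiny_index.query_passes == tiny_index.q


def test_param_mismatch_rejected(tiny_index):
    other = MinimizerParams(k=21, w=25)
    sketch = QuerySketch("probe", [1, 2, 3], params=other)
    with pytest.raises(ValueError, match="mismatch"):
        query_level_counts(tiny_index, sketch)


def test_absent_transcript_estimates_zero(tmp_path):
    rng = np.random.default_rng(3)
    present = random_dna(rng, 300)
    absent = random_dna(rng, 300)
    index, params = _toy_index(tmp_path, {"e": [(f"r{i}", present) for i in range(4)]})
    est = estimate_sketch(index, sketch_transcript("absent", absent, params))
    assert est.estimates[0] == 0.0


def test_estimate_file_edge_cases(tmp_path, tiny_index):
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    table = estimate_file(tiny_index, empty)
    assert list(table.columns) == ["transcript", *tiny_index.experiments]
    assert len(table) == 0
    short = tmp_path / "short.fa"
    short.write_text(">stub\nACGT\n")
    table = estimate_file(tiny_index, short)
    assert (table.iloc[0, 1:] == 0).all()
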