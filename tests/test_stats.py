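import numpy as np
import pandas as pd
import pytest

from txslip import (
    CoverageTable,
    Gene,
    GenomeAnnotation,
    IndelRecord,
    SimulationConfig,
    SlippageSimParams,
    bh_correct,
    bin_by_coverage,
    complementarity_chisq,
    complementarity_histogram,
    composition_bias_test,
    dinucleotide_bias,
    events_to_catalog,
    generate_genome,
    homopolymer_rate_curve,
    indel_rate,
    periodicity_test,
    positional_bias,
    simulate_expected_deletions,
    simulate_slippage_events,
)
from txslip.stats import coverage_bin_edges

from conftest import random_seq


def make_records(n, kind="deletion", rng=None, replicate="1", event_len=2):
    rng = rng or np.random.default_rng(0)
    return [
        IndelRecord("x", replicate, int(rng.integers(1, 1000)), kind,
                    random_seq(rng, 15), random_seq(rng, event_len),
                    random_seq(rng, 15))
        for _ in range(n)
    ]


# --- BH ----------------------------------------------------------------------


def test_bh_step_up_hand_example():
    # step-up on (0.01, 0.02, 0.03, 0.04): q_i = min over j>=i of p_j*m/j
    # = (0.04, 0.04, 0.04, 0.04)
    assert bh_correct([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_correct([0.5]) == pytest.approx([0.5])
    assert bh_correct([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)
    assert len(bh_correct([])) == 0


def test_bh_permutation_invariant_and_dominates_p():
    rng = np.random.default_rng(8)
    p = rng.random(25)
    q = bh_correct(p)
    assert np.all(q >= p - 1e-12)
    perm = rng.permutation(25)
    assert bh_correct(p[perm]) == pytest.approx(q[perm])


# --- rates -------------------------------------------------------------------


def simple_coverage(depth=10.0, length=100_000):
    ann = GenomeAnnotation(sequences={"c": "A" * (length + 20)},
                           genes=[Gene("g", "c", 10, 10 + length, "+")])
    return ann, CoverageTable({"g": depth})


def test_rate_arithmetic_and_depth_scaling():
    ann, cov = simple_coverage(depth=10.0, length=100_000)  # 1e6 transcribed nt
    recs = make_records(5)
    rt = indel_rate(recs, cov, ann)
    assert rt.mean_rate("deletion") == pytest.approx(5e-6)
    cov2 = CoverageTable({"g": 20.0})
    assert indel_rate(recs, cov2, ann).mean_rate("deletion") == pytest.approx(2.5e-6)


def test_rate_recovers_planted_generator_rate(small_genome):
    params, ann, cov = small_genome
    total = cov.total_transcribed_nt(ann)
    rho = 2e-5
    rng = np.random.default_rng(55)
    n = int(rng.poisson(rho * total))
    events = simulate_slippage_events(ann, cov, params, 0, n, rng)
    est = indel_rate(events_to_catalog(events), cov, ann).mean_rate("deletion")
    assert abs(est - rho) <= 3 * np.sqrt(rho / total)


def test_zero_denominator_rejected():
    ann, _ = simple_coverage()
    with pytest.raises(ValueError):
        indel_rate(make_records(2), CoverageTable({"g": 0.0}), ann)


# --- homopolymer curve -------------------------------------------------------


def test_exponent_recovery_from_generator(small_genome):
    params, ann, cov = small_genome
    rng = np.random.default_rng(21)
    events = simulate_slippage_events(ann, cov, params, 6000, 0, rng)
    _, fit = homopolymer_rate_curve(events_to_catalog(events), ann, cov)
    assert fit is not None
    b = params.insertion_run_exponent
    assert abs(fit["b"] - b) <= 0.25 * b


def test_flat_frequencies_give_zero_slope():
    # hand-built table path: equal frequencies across three classes
    ann = GenomeAnnotation(
        sequences={"c": "G" + "AAAA" + "G" + "AAAAA" + "G" + "AAAAAA" + "G"},
        genes=[Gene("g", "c", 0, 19, "+")],
    )
    cov = CoverageTable({"g": 1.0})
    recs = []
    # one event per run nucleotide -> frequency 1/depth for every length class
    for start, length in [(1, 4), (6, 5), (12, 6)]:
        for _ in range(length):
            recs.append(IndelRecord("x", "1", start + 1, "insertion",
                                    ("CCCCG" + "A" * length)[-9:], "A",
                                    "GCCCCCCCC"))
    _, fit = homopolymer_rate_curve(recs, ann, cov)
    assert fit is not None
    assert abs(fit["b"]) < 1e-9
    assert fit["r2"] == pytest.approx(0.0)


def test_single_class_fit_omitted():
    ann = GenomeAnnotation(sequences={"c": "GGAAAAGG"},
                           genes=[Gene("g", "c", 0, 8, "+")])
    cov = CoverageTable({"g": 1.0})
    recs = [IndelRecord("x", "1", 3, "insertion", "CCCCGAAAA", "A", "GGCCCCCCC")]
    with pytest.warns(UserWarning, match="fit omitted"):
        _, fit = homopolymer_rate_curve(recs, ann, cov)
    assert fit is None


# --- composition -------------------------------------------------------------


def test_extreme_composition_bias_detected(small_genome):
    _, ann, cov = small_genome
    rng = np.random.default_rng(3)
    recs = [
        IndelRecord("x", str(rep), 10, "deletion", random_seq(rng, 9), "AA",
                    random_seq(rng, 9))
        for rep in range(1, 9)
        for _ in range(30)
    ]
    df, summary = composition_bias_test(recs, ann, cov)
    row = df[df["label"] == "A"].iloc[0]
    assert row["direction"] == "enriched" and row["q"] < 0.05
    for b in "GC":
        assert df[df["label"] == b].iloc[0]["direction"] == "depleted"
    assert summary["deleted_gc_mean"] == 0.0


def test_single_replicate_falls_back_to_binomial(small_genome):
    _, ann, cov = small_genome
    recs = make_records(40)
    with pytest.warns(UserWarning, match="binomial"):
        df, _ = composition_bias_test(recs, ann, cov)
    assert set(df["label"]) == set("ACGT")


# --- positional / dinucleotide -----------------------------------------------


def test_planted_minus_one_base_flagged():
    rng = np.random.default_rng(6)
    obs = [r.with_(upstream=r.upstream[:-1] + "A") for r in make_records(300, rng=rng)]
    exp = make_records(3000, rng=rng)
    df = positional_bias(obs, exp)
    cell = df[(df["position"] == -1) & (df["label"] == "A")].iloc[0]
    assert cell["direction"] == "enriched" and cell["q"] < 0.01


def test_positional_window_one():
    rng = np.random.default_rng(7)
    df = positional_bias(make_records(50, rng=rng), make_records(500, rng=rng),
                         window=1)
    assert set(df["position"]) == {-1, 1}
    assert len(df) == 8


def test_planted_dinucleotide_flagged_and_null_no_signal():
    rng = np.random.default_rng(10)
    obs = [r.with_(upstream=r.upstream[:-2] + "CA") for r in make_records(200, rng=rng)]
    exp = make_records(3200, rng=rng)
    df = dinucleotide_bias(obs, exp)
    ca = df[df["label"] == "CA"].iloc[0]
    assert ca["direction"] == "enriched" and ca["q"] < 0.001
    # observed == expected exactly -> all q == 1
    same = make_records(160, rng=rng)
    df2 = dinucleotide_bias(same, same)
    assert np.allclose(df2["q"], 1.0)


# --- periodicity -------------------------------------------------------------


def test_periodicity_direction_and_null():
    obs = [IndelRecord("x", "1", 10, "deletion", "ACGTACGTA", "A" * L, "CCGTACGTA")
           for L in (3, 3, 3, 6)]
    exp = [IndelRecord("x", "1", 10, "deletion", "ACGTACGTA", "A" * L, "CCGTACGTA")
           for L in (1, 2, 3, 4, 5, 6)]
    res = periodicity_test(obs, exp)
    o3, orest = res["table"][0]
    assert (o3, orest) == (4, 0)
    assert res["p_one_sided"] < 1
    res2 = periodicity_test(exp, exp)
    assert res2["p_one_sided"] > 0.5
    res3 = periodicity_test([], exp)
    assert np.isnan(res3["p_one_sided"])


# --- complementarity chi-square ----------------------------------------------


def test_chisq_identical_histograms():
    h = np.array([5, 10, 20, 30, 20, 10, 5, 3, 2, 1])
    res = complementarity_chisq(h, h)
    assert res["statistic"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0)


def test_chisq_extreme_shift_significant():
    obs = np.zeros(10, dtype=int)
    obs[9] = 100
    exp = np.array([10, 25, 30, 20, 10, 3, 1, 0.5, 0.3, 0.2])
    res = complementarity_chisq(obs, exp)
    assert res["p"] < 1e-4


def test_chisq_pools_sparse_tail_cells():
    obs = np.array([50, 30, 10, 5, 3, 1, 1, 0, 0, 0])
    exp = np.array([45, 35, 12, 4, 2, 1, 0.5, 0.3, 0.1, 0.2])
    res = complementarity_chisq(obs, exp)
    pooled = res["pooled_cells"]
    assert any(len(cell) > 1 for cell in pooled)  # high tail merged
    assert res["df"] == len(pooled) - 1


def test_chisq_all_zero_expected_rejected():
    with pytest.raises(ValueError):
        complementarity_chisq(np.ones(10), np.zeros(10))


# --- coverage bins -----------------------------------------------------------


def test_bin_edges_enumeration():
    edges = coverage_bin_edges()
    assert len(edges) - 1 == 26  # 10 + 9 + 4 + 3 bins
    assert edges[:11] == [float(x) for x in range(11)]
    assert edges[11:20] == [float(x) for x in range(20, 101, 10)]
    assert edges[20:24] == [200.0, 300.0, 400.0, 500.0]
    assert edges[24:] == [1000.0, 2000.0, float("inf")]


def test_gene_binning_and_rates():
    seq = "A" * 500
    ann = GenomeAnnotation(
        sequences={"c": seq},
        genes=[Gene("mid", "c", 0, 100, "+"), Gene("high", "c", 200, 300, "+")],
    )
    cov = CoverageTable({"mid": 7.2, "high": 2500.0})
    recs = [IndelRecord("x", "1", 50, "deletion", "A" * 9, "AA", "A" * 9)]
    df = bin_by_coverage(ann, cov, recs)
    row = df[(df["bin_low"] == 7.0)].iloc[0]
    assert row["events"] == 1 and row["coverage"] == pytest.approx(720.0)
    top = df.iloc[-1]
    assert top["bin_low"] == 2000.0 and top["coverage"] == pytest.approx(250_000.0)
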