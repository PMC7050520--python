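"""Tail statistics: regressions, tests, coupling, saturation, metagene."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fulltx.polya_stats import (
    compare_distributions,
    full_length_pairing,
    load_polya_table,
    metagene_coverage,
    pas_usage_chi2,
    saturation_curve,
    splice_utr_coupling,
    tail_vs_expression,
    tail_vs_utr_length,
)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "tail_length", "gene", "isoform_id", "utr_id",
                 "pas_type", "utr_length", "intron_retained"],
    )


def _expr_records(counts_medians):
    rows = []
    i = 0
    for iso, (count, median) in counts_medians.items():
        for _ in range(count):
            rows.append((f"r{i}", median, "g", iso, None, None, None, False))
            i += 1
    return _records(rows)


def test_tail_vs_expression_two_point_slope():
    rec = _expr_records({"a": (10, 60.0), "b": (1000, 40.0)})
    res = tail_vs_expression(rec)
    assert res.n == 2
    assert res.slope == pytest.approx(-10.0)


def test_tail_vs_expression_excludes_below_threshold():
    rec = _expr_records({"a": (9, 60.0), "b": (10, 50.0), "c": (100, 45.0)})
    res = tail_vs_expression(rec)
    assert res.n == 2  # the 9-read isoform is excluded
    with pytest.raises(ValueError):
        tail_vs_expression(_expr_records({"a": (9, 60.0), "b": (100, 40.0)}))


def test_tail_vs_utr_length_two_point_slope():
    rows = []
    for utr, (n, median, ulen) in {
        "u1": (10, 40.0, 100), "u2": (20, 50.0, 1000)
    }.items():
        for i in range(n):
            rows.append((f"{utr}.{i}", median, "g", "iso", utr, None, ulen,
                         False))
    res = tail_vs_utr_length(_records(rows))
    assert res.slope == pytest.approx(10.0)
    assert res.r_squared == pytest.approx(1.0)


@pytest.mark.parametrize("slope", [-10.0, -5.0, 0.0, 5.0])
def test_regression_recovers_planted_slope(slope):
    rng = np.random.default_rng(int(abs(slope) * 10 + 3))
    rows = []
    for i in range(200):
        count = int(10 ** rng.uniform(1, 2.5))
        median = 55.0 + slope * math.log10(count) + rng.normal(0, 5)
        rows += [(f"r{i}.{j}", median, "g", f"iso{i}", None, None, None,
                  False) for j in range(count)]
    res = tail_vs_expression(_records(rows))
    assert abs(res.slope - slope) < 2 * res.slope_se


def test_identical_samples_ks_zero():
    a = list(range(10))
    out = compare_distributions(a, a)
    assert out["ks_stat"] == 0.0
    assert out["ks_p"] == 1.0


def test_mwu_exact_matches_enumeration():
    # complete separation at n1 = n2 = 5: the two-sided exact p-value is
    # 2 / C(10, 5) by direct enumeration of equally likely rank splits
    a, b = [1, 2, 3, 4, 5], [11, 12, 13, 14, 15]
    out = compare_distributions(a, b)
    assert out["mwu_p"] == pytest.approx(2 / math.comb(10, 5))
    # independent enumeration of every split for a non-degenerate case
    pooled = [1, 4, 6, 7, 9, 12, 15, 20]
    a2 = [1, 6, 9, 20]
    from itertools import combinations

    def u_stat(sample_a, sample_b):
        return sum(
            (x > y) + 0.5 * (x == y) for x in sample_a for y in sample_b
        )

    u_obs = u_stat(a2, [x for x in pooled if x not in a2])
    n_extreme = 0
    splits = list(combinations(range(8), 4))
    mu = 4 * 4 / 2
    for idx in splits:
        sa = [pooled[i] for i in idx]
        sb = [pooled[i] for i in range(8) if i not in idx]
        if abs(u_stat(sa, sb) - mu) >= abs(u_obs - mu) - 1e-9:
            n_extreme += 1
    expected_p = n_extreme / len(splits)
    got = compare_distributions(a2, [x for x in pooled if x not in a2])
    assert got["mwu_p"] == pytest.approx(expected_p)


def test_planted_median_shift_detected():
    rng = np.random.default_rng(42)
    a = rng.normal(50, 18, size=5000)
    b = rng.normal(56, 18, size=5000)  # +6 nt shift
    out = compare_distributions(a, b)
    assert out["ks_p"] < 0.01 and out["mwu_p"] < 0.01
    assert out["median_b"] > out["median_a"]


def test_chi2_identical_rows_and_hand_value():
    out = pas_usage_chi2([[10, 10], [10, 10]])
    assert out["chi2"] == pytest.approx(0.0)
    assert out["p"] == pytest.approx(1.0)
    # [[20,0],[0,20]]: every expected count is 10, Pearson chi2 = 4*10 = 40
    out2 = pas_usage_chi2([[20, 0], [0, 20]])
    assert out2["chi2"] == pytest.approx(40.0)
    assert pas_usage_chi2([[5, 6, 7], [7, 6, 5]])["dof"] == 2


def test_chi2_drops_zero_margins():
    with pytest.warns(UserWarning):
        out = pas_usage_chi2([[10, 0, 5], [20, 0, 10]])
    assert out["dof"] == 1


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    def pmf(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / denom
    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def test_coupling_fisher_examples():
    rec = _records(
        [(f"r{i}", 50.0, "g", iso, u, None, None, False)
         for i, (iso, u) in enumerate(
            [("i1", "u1")] * 5 + [("i1", "u2")] * 5
            + [("i2", "u1")] * 5 + [("i2", "u2")] * 5)]
    )
    out = splice_utr_coupling(rec)
    assert len(out) == 1
    assert out["p"].iloc[0] == pytest.approx(1.0)
    # perfect coupling [[10,0],[0,10]]
    rec2 = _records(
        [(f"s{i}", 50.0, "g", iso, u, None, None, False)
         for i, (iso, u) in enumerate(
            [("i1", "u1")] * 10 + [("i2", "u2")] * 10)]
    )
    out2 = splice_utr_coupling(rec2)
    assert out2["p"].iloc[0] == pytest.approx(2 / math.comb(20, 10))
    assert out2["p"].iloc[0] == pytest.approx(_fisher_oracle(10, 0, 0, 10))


def test_coupling_q_values_monotone_and_geq_p():
    rng = np.random.default_rng(8)
    rows = []
    for gi in range(12):
        n1 = int(rng.integers(5, 15))
        for i in range(20):
            iso = "i1" if i % 2 else "i2"
            u = "u1" if (i < n1) else "u2"
            rows.append((f"g{gi}.{i}", 50.0, f"g{gi}", iso, u, None, None,
                         False))
    out = splice_utr_coupling(_records(rows)).sort_values("p")
    assert (out["q"].values >= out["p"].values - 1e-12).all()
    assert (np.diff(out["q"].values) >= -1e-12).all()


def test_saturation_full_fraction_is_exact_and_matches_closed_form():
    rng = np.random.default_rng(3)
    # 10 isoforms with 3 reads each plus one with 30 reads
    read_to_iso = {}
    k = 0
    sizes = {f"i{j}": 3 for j in range(10)}
    sizes["big"] = 30
    for iso, m in sizes.items():
        for _ in range(m):
            read_to_iso[f"r{k}"] = iso
            k += 1
    n = len(read_to_iso)
    df = saturation_curve(read_to_iso, [0.2, 0.5, 1.0], n_reps=200, seed=9)
    assert df[df["fraction"] == 1.0]["mean_isoforms"].iloc[0] == len(sizes)
    for _, row in df.iterrows():
        kk = int(row["n_reads"])
        expect = sum(
            1 - math.comb(n - m, kk) / math.comb(n, kk) if n - m >= kk else 1.0
            for m in sizes.values()
        )
        # detection indicators are within [0,1]; 4 sigma Monte-Carlo band
        se = math.sqrt(len(sizes) * 0.25 / 200)
        assert abs(row["mean_isoforms"] - expect) < 4 * se + 1e-9


def test_saturation_rejects_bad_fraction():
    with pytest.raises(ValueError):
        saturation_curve({"r": "i"}, [0.0], 1, 0)


def test_pairing_splits_and_utr_less_entries():
    class ISO:
        def __init__(self, iso_id, reads):
            self.isoform_id = iso_id
            self.gene_id = "g"
            self.read_ids = set(reads)

    class UTR:
        def __init__(self, utr_id, reads):
            self.utr_id = utr_id
            self.read_ids = set(reads)

    isoA = ISO("isoA", {"r1", "r2", "r3"})
    isoB = ISO("isoB", {"r4"})
    u1, u2 = UTR("u1", {"r1"}), UTR("u2", {"r2", "r3"})
    df = full_length_pairing([isoA, isoB], [u1, u2])
    # isoA splits over two UTRs; isoB has no assigned reads -> UTR-less
    a_rows = df[df["isoform_id"] == "isoA"]
    assert len(a_rows) == 2 and set(a_rows["utr_id"]) == {"u1", "u2"}
    b_rows = df[df["isoform_id"] == "isoB"]
    assert len(b_rows) == 1 and b_rows["utr_id"].isna().all()
    # pigeonhole: with every isoform paired, rows >= isoforms
    assert len(df) >= 2


def test_polya_table_duplicate_ids_error(tmp_path):
    p = tmp_path / "polya.tsv"
    p.write_text(
        "readname\tpolya_length\tqc_tag\nr1\t50\tPASS\nr1\t60\tPASS\n"
    )
    with pytest.raises(ValueError, match="duplicate"):
        load_polya_table(p)


def test_polya_table_headerless_nanopolish_dialect(tmp_path):
    p = tmp_path / "polya.tsv"
    p.write_text(
        "r1\tchrI\t100\t0\t10\t20\t80\t100\t51.5\tPASS\n"
        "r2\tchrI\t200\t0\t10\t20\t80\t100\t60.0\tNOREGION\n"
    )
    df = load_polya_table(p)
    assert list(df["readname"]) == ["r1", "r2"]
    assert df["polya_length"].iloc[0] == pytest.approx(51.5)


def test_metagene_profile_normalized(sim_clean_small):
    res, result = sim_clean_small
    reads = [o.read for o in result.outcomes if o.passed]
    prof = metagene_coverage(reads, result.ann)
    assert prof.sum() == pytest.approx(1.0)
    assert (prof >= 0).all()
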