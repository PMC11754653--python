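import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from retrolib.quantify import (
    CountTable,
    QuantifyError,
    axis_statistics,
    classify_amplicon_reads,
    editing_rate,
    extract_barcodes,
    inverse_normal_transform,
    match_msd_reads,
    msdna_production,
    relative_abundance,
    summarize_axis,
    within_group_normalize,
    working_fraction,
)
from tests.conftest import make_count_table


# -- brute-force oracles (independent of the implementation) -----------------


def oracle_msdna(counts: dict, wt_id: str) -> dict:
    """Scalar recomputation of msDNA % of wild type from raw counts."""
    tot = {role: sum(col.values()) for role, col in counts.items()}
    ra = {role: {v: c / tot[role] for v, c in col.items()} for role, col in counts.items()}
    prod = {}
    for v in counts["msdna"]:
        plasmid = (ra["plasmid_pre"][v] + ra["plasmid_post"][v]) / 2
        prod[v] = ra["msdna"][v] / plasmid if plasmid > 0 else math.nan
    return {v: 100.0 * p / prod[wt_id] for v, p in prod.items()}


def oracle_editing(counts: dict, min_plasmid: int) -> dict:
    psum = {
        v: counts["plasmid_t0"][v] + counts["plasmid_t24"][v] + counts["plasmid_t48"][v]
        for v in counts["plasmid_t0"]
    }
    ptot = sum(psum.values())
    gtot = sum(counts["genome_t48"].values())
    out = {}
    for v, s in psum.items():
        g = counts["genome_t48"][v]
        if s > min_plasmid and g > 0:
            out[v] = (g / gtot) / (s / ptot)
    return out


def table_to_dicts(table: CountTable) -> dict:
    return {
        table.samples.loc[c, "role"]: table.counts[c].to_dict()
        for c in table.counts.columns
    }


# -- relative abundance ------------------------------------------------------


def test_relative_abundance():
    ra = relative_abundance({"A": 3, "B": 1})
    assert ra["A"] == 0.75 and ra["B"] == 0.25
    assert relative_abundance({"A": 7}).iloc[0] == 1.0
    with pytest.raises(QuantifyError):
        relative_abundance({"A": 0, "B": 0})


# -- msDNA production --------------------------------------------------------


def make_msdna_table(pre, post, ms):
    ids = list(pre)
    counts = pd.DataFrame(
        {"s_pre": pre, "s_post": post, "s_ms": ms},
        index=pd.Index(ids, name="variant_id"),
    )
    samples = pd.DataFrame(
        {
            "s_pre": {"role": "plasmid_pre", "replicate": "r1", "site": "e"},
            "s_post": {"role": "plasmid_post", "replicate": "r1", "site": "e"},
            "s_ms": {"role": "msdna", "replicate": "r1", "site": "e"},
        }
    ).T.rename_axis("sample")
    return CountTable(counts=counts, samples=samples)


def test_msdna_production_hand_case():
    # v: RA_msdna=0.05, mean plasmid RA=0.10; wt ratio 1.0 -> 50%
    table = make_msdna_table(
        pre={"wt": 46, "v": 8, "x": 46},
        post={"wt": 44, "v": 12, "x": 44},
        ms={"wt": 45, "v": 5, "x": 50},
    )
    act = msdna_production(table, "wt")
    vals = act.set_index("variant_id")["value"]
    assert vals["v"] == pytest.approx(50.0)
    assert vals["wt"] == 100.0


def test_msdna_variant_identical_to_wt_is_100():
    table = make_msdna_table(
        pre={"wt": 50, "v": 50}, post={"wt": 30, "v": 30}, ms={"wt": 80, "v": 80}
    )
    vals = msdna_production(table, "wt").set_index("variant_id")["value"]
    assert vals["v"] == 100.0


def test_msdna_zero_plasmid_is_missing_not_infinite():
    table = make_msdna_table(
        pre={"wt": 50, "v": 0}, post={"wt": 30, "v": 0}, ms={"wt": 80, "v": 5}
    )
    vals = msdna_production(table, "wt").set_index("variant_id")["value"]
    assert np.isnan(vals["v"])


def test_msdna_missing_wt_rejected():
    table = make_msdna_table(pre={"v": 5}, post={"v": 5}, ms={"v": 5})
    with pytest.raises(QuantifyError):
        msdna_production(table, "wt")


def test_msdna_matches_bruteforce_oracle_exactly():
    rng = np.random.default_rng(7)
    for _ in range(20):
        table = make_count_table(rng, int(rng.integers(5, 50)), "msdna")
        wt = table.counts.index[0]
        got = msdna_production(table, wt).set_index("variant_id")["value"]
        want = oracle_msdna(table_to_dicts(table), wt)
        for v, w in want.items():
            if math.isnan(w):
                assert np.isnan(got[v])
            else:
                assert got[v] == w  # bit-for-bit


# -- editing rate ------------------------------------------------------------


def make_editing_table(t0, t24, t48, genome):
    ids = list(t0)
    counts = pd.DataFrame(
        {"s0": t0, "s24": t24, "s48": t48, "sg": genome},
        index=pd.Index(ids, name="variant_id"),
    )
    samples = pd.DataFrame(
        {
            "s0": {"role": "plasmid_t0", "replicate": "r1", "site": "s1"},
            "s24": {"role": "plasmid_t24", "replicate": "r1", "site": "s1"},
            "s48": {"role": "plasmid_t48", "replicate": "r1", "site": "s1"},
            "sg": {"role": "genome_t48", "replicate": "r1", "site": "s1"},
        }
    ).T.rename_axis("sample")
    return CountTable(counts=counts, samples=samples)


def test_editing_rate_filter_rule():
    # plasmid sums {12, 10, 0}, genome {5, 5, 5}: only the sum-12 barcode
    # survives "counts > 10 in plasmid and seen in genome"
    table = make_editing_table(
        t0={"a": 5, "b": 4, "c": 0},
        t24={"a": 4, "b": 3, "c": 0},
        t48={"a": 3, "b": 3, "c": 0},
        genome={"a": 5, "b": 5, "c": 5},
    )
    act = editing_rate(table, min_plasmid=10)
    assert act["variant_id"].tolist() == ["a"]


def test_editing_rate_nonworking_flag():
    # covered in plasmid (sum 12 > 10) but never seen in the genome
    table = make_editing_table(
        t0={"a": 5, "b": 5}, t24={"a": 4, "b": 4}, t48={"a": 3, "b": 3},
        genome={"a": 0, "b": 9},
    )
    act = editing_rate(table, min_plasmid=10, drop_nonworking=False)
    flags = act.set_index("variant_id")["working"]
    assert not flags["a"] and flags["b"]
    assert np.isnan(act.set_index("variant_id").loc["a", "value"])
    wf = working_fraction(table, min_plasmid=10)
    assert wf["working_fraction"].iloc[0] == 0.5


def test_editing_rate_equal_plasmid_ratio():
    table = make_editing_table(
        t0={"a": 10, "b": 10}, t24={"a": 10, "b": 10}, t48={"a": 10, "b": 10},
        genome={"a": 30, "b": 10},
    )
    vals = editing_rate(table).set_index("variant_id")["value"]
    assert vals["a"] / vals["b"] == pytest.approx(3.0)


def test_editing_rate_matches_bruteforce_oracle_exactly():
    rng = np.random.default_rng(13)
    for _ in range(20):
        table = make_count_table(rng, int(rng.integers(5, 50)), "editing")
        got = editing_rate(table, min_plasmid=10).set_index("variant_id")["value"]
        want = oracle_editing(table_to_dicts(table), 10)
        assert set(got.index) == set(want)
        for v, w in want.items():
            assert got[v] == w


def test_filter_monotonicity():
    rng = np.random.default_rng(3)
    table = make_count_table(rng, 40, "editing")
    sizes = [len(editing_rate(table, min_plasmid=m)) for m in (0, 5, 10, 50, 200)]
    assert sizes == sorted(sizes, reverse=True)


def test_scale_invariance():
    rng = np.random.default_rng(5)
    table = make_count_table(rng, 30, "editing")
    scaled = CountTable(counts=table.counts * 7, samples=table.samples)
    a = editing_rate(table, min_plasmid=0).set_index("variant_id")["value"]
    b = editing_rate(scaled, min_plasmid=0).set_index("variant_id")["value"]
    common = a.index.intersection(b.index)
    assert np.allclose(a[common], b[common])


def test_missing_role_rejected():
    table = make_editing_table(
        t0={"a": 5}, t24={"a": 5}, t48={"a": 5}, genome={"a": 5}
    )
    table.samples.loc["sg", "role"] = "amplicon"
    with pytest.raises(QuantifyError, match="genome_t48"):
        editing_rate(table)


# -- within-group normalization / summaries ----------------------------------


def make_activity(values: dict[str, float]) -> pd.DataFrame:
    rows = []
    for (strand, grp), v in values.items():
        rows.append(
            {"variant_id": f"{strand}_{grp}", "strand": strand, "grp": grp,
             "replicate": "r1", "site": "s1", "value": v}
        )
    return pd.DataFrame(rows)


def test_within_group_normalize_basic():
    act = make_activity({("target", 1): 2.0, ("non_target", 1): 4.0})
    norm = within_group_normalize(act, "strand", "non_target", ["strand", "grp"])
    vals = norm.set_index("strand")["value"]
    assert vals["target"] == 0.5 and vals["non_target"] == 1.0


def test_within_group_normalize_drops_groups_missing_reference():
    act = make_activity(
        {("target", 1): 2.0, ("non_target", 1): 4.0, ("target", 2): 3.0}
    )
    norm = within_group_normalize(act, "strand", "non_target", ["strand", "grp"])
    assert norm.attrs["n_groups_dropped"] == 1
    assert set(norm["grp"]) == {1}


def test_summarize_axis():
    rows = []
    for rep, med_vals in (("r1", [0.3, 0.4, 0.5]), ("r2", [0.5, 0.6, 0.7])):
        for i, v in enumerate(med_vals):
            rows.append({"strand": "target", "replicate": rep, "site": "s1",
                         "value": v, "variant_id": f"v{i}"})
        rows.append({"strand": "non_target", "replicate": rep, "site": "s1",
                     "value": 1.0, "variant_id": "ref"})
    summ = summarize_axis(pd.DataFrame(rows), "strand")
    s = summ.summary.set_index("strand")
    assert s.loc["target", "grand_mean"] == pytest.approx((0.4 + 0.6) / 2)
    assert s.loc["non_target", "grand_mean"] == 1.0
    with pytest.raises(QuantifyError):
        summarize_axis(pd.DataFrame(rows).iloc[0:0], "strand")


# -- statistics --------------------------------------------------------------


def closed_form_t(values, null):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    t = (mean - null) / (sd / math.sqrt(n))
    return t


def test_one_sample_t_all_equal_null():
    act = make_activity({("target", i): 1.0 for i in range(4)})
    res = axis_statistics(act, "strand", test="one_sample_t", null=1.0)
    assert res["statistic"].iloc[0] == 0.0
    assert res["p_raw"].iloc[0] == 1.0


def test_one_sample_t_closed_form_and_bonferroni():
    values = [0.5, 0.6, 0.7]
    act = make_activity({("target", i): v for i, v in enumerate(values)})
    res = axis_statistics(act, "strand", null=1.0, correction="bonferroni")
    t = closed_form_t(values, 1.0)
    # df=2 Student t has closed-form two-sided p = 1 - |t|/sqrt(2 + t^2)
    p = 1 - abs(t) / math.sqrt(2 + t * t)
    assert res["statistic"].iloc[0] == pytest.approx(t, abs=1e-9)
    assert res["p_raw"].iloc[0] == pytest.approx(p, abs=1e-9)
    assert res["p_adj"].iloc[0] == pytest.approx(min(1.0, p), abs=1e-9)


def test_bonferroni_scales_p_by_m():
    rng = np.random.default_rng(0)
    act = pd.DataFrame(
        {
            "lvl": np.repeat(list("abcde"), 6),
            "value": rng.normal(1.0, 0.1, 30),
        }
    )
    res = axis_statistics(act, "lvl", correction="bonferroni")
    assert np.allclose(res["p_adj"], np.minimum(1.0, res["p_raw"] * 5))


def test_planted_shift_detected():
    rng = np.random.default_rng(1)
    act = pd.DataFrame({"lvl": ["shift"] * 9, "value": rng.normal(0.5, 0.01, 9)})
    res = axis_statistics(act, "lvl", null=1.0)
    assert res["p_adj"].iloc[0] < 1e-3


def test_paired_t():
    act = pd.DataFrame(
        {
            "lvl": ["a"] * 4 + ["b"] * 4,
            "pair": list(range(4)) * 2,
            "value": [1.0, 1.1, 0.9, 1.2, 0.5, 0.55, 0.45, 0.6],
        }
    )
    res = axis_statistics(act, "lvl", test="paired_t", pair_col="pair")
    diffs = [1.0 - 0.5, 1.1 - 0.55, 0.9 - 0.45, 1.2 - 0.6]
    assert res["statistic"].iloc[0] == pytest.approx(closed_form_t(diffs, 0.0))


def test_anova_dunnett_matches_scipy_reference():
    rng = np.random.default_rng(2)
    groups = {
        "ref": rng.normal(1.0, 0.05, 8),
        "same": rng.normal(1.0, 0.05, 8),
        "down": rng.normal(0.6, 0.05, 8),
    }
    act = pd.DataFrame(
        {
            "lvl": np.repeat(list(groups), 8),
            "value": np.concatenate(list(groups.values())),
        }
    )
    res = axis_statistics(act, "lvl", test="anova_dunnett", reference="ref")
    res = res.set_index("level")
    ref = stats.dunnett(groups["down"], groups["same"], control=groups["ref"])
    assert res.loc["down", "p_adj"] == pytest.approx(ref.pvalue[0], abs=1e-3)
    assert res.loc["down", "p_adj"] < 0.001 < res.loc["same", "p_adj"]


def test_degenerate_groups_rejected():
    act = pd.DataFrame({"lvl": ["a"], "value": [1.0]})
    with pytest.raises(QuantifyError):
        axis_statistics(act, "lvl")


# -- read classification -----------------------------------------------------


def test_classify_amplicon_reads():
    wt = "ACGTACGTAAGGCCTTACGT"
    ed = "ACGTACGTATGGCCTTACGT"  # single substitution in the middle
    reads = ["TTT" + ed + "GGG"] * 3 + ["CC" + wt + "AA"] * 7
    res = classify_amplicon_reads(reads, wt, ed)
    assert (res.n_edit, res.n_wt) == (3, 7)
    assert res.ratio_edit_wt == pytest.approx(3 / 7)
    assert res.percent_edit == pytest.approx(30.0)
    # a 1-nt deletion spanning the window is an indel
    indel_read = "TTT" + wt[:9] + wt[10:] + "GGG"
    res2 = classify_amplicon_reads([indel_read], wt, ed)
    assert res2.n_indel == 1
    # no WT reads: literal ratio undefined, percentage still defined
    res3 = classify_amplicon_reads(["TTT" + ed + "GGG"], wt, ed)
    assert res3.ratio_edit_wt is None
    assert res3.percent_edit == 100.0
    # reverse-complement orientation is classified
    from retrolib.annotation import revcomp

    res4 = classify_amplicon_reads([revcomp("TT" + wt + "AA")], wt, ed)
    assert res4.n_wt == 1


# -- inverse normal transform -------------------------------------------------


def test_inverse_normal_transform_blom():
    z = inverse_normal_transform([3.0, 1.0, 2.0])
    # Blom: (r - 3/8) / (n + 1/4) for n=3 -> 0.1923..., 0.5, 0.8077...
    expect = stats.norm.ppf([(3 - 0.375) / 3.25, (1 - 0.375) / 3.25, (2 - 0.375) / 3.25])
    assert np.allclose(z, expect)
    assert z[2] == pytest.approx(0.0)  # median maps to zero
    # monotone in ranks
    vals = np.array([5.0, -1.0, 2.5, 7.0, 0.0])
    zz = inverse_normal_transform(vals)
    assert (np.argsort(zz) == np.argsort(vals)).all()
    with pytest.raises(QuantifyError):
        inverse_normal_transform([1.0, 1.0, 1.0])
    with pytest.raises(QuantifyError):
        inverse_normal_transform([1.0])


# -- barcode extraction ------------------------------------------------------


F5, F3 = "TCGATCGGTACA", "AGGTCCATGCTT"


def test_extract_barcodes_exact_and_mismatch():
    wl = ["AAAAAAAAAA", "CCCCCCCCCC"]
    reads = [
        F5 + "AAAAAAAAAA" + F3,  # exact
        F5 + "AAAAAAAAAT" + F3,  # 1 mismatch from wl[0]
    ]
    counts = extract_barcodes(reads, (F5, F3), wl, max_mismatch=1)
    assert counts["AAAAAAAAAA"] == 2
    counts0 = extract_barcodes(reads, (F5, F3), wl, max_mismatch=0)
    assert counts0["AAAAAAAAAA"] == 1
    assert counts0.attrs["n_unassigned"] == 1


def test_extract_barcodes_tie_unassigned():
    wl = ["AAAAAAAAAA", "AAAAAAAATT"]  # Hamming 2 apart
    read = F5 + "AAAAAAAAAT" + F3  # equidistant (1 from each)
    # whitelist itself is ambiguous at max_mismatch=1 (2 <= 2*1)
    with pytest.raises(QuantifyError, match="ambiguous"):
        extract_barcodes([read], (F5, F3), wl, max_mismatch=1)
    counts = extract_barcodes([read], (F5, F3), wl, max_mismatch=0)
    assert counts.sum() == 0


def test_extract_barcodes_reverse_orientation():
    from retrolib.annotation import revcomp

    wl = ["ACGTACGTAC"]
    read = revcomp(F5 + "ACGTACGTAC" + F3)
    counts = extract_barcodes([read], (F5, F3), wl)
    assert counts["ACGTACGTAC"] == 1


# -- msd read matching -------------------------------------------------------


def test_match_msd_reads():
    catalog = {"v1": "ACGTACGTACGTACGT", "v2": "TTTTACGTACGTACGT"}
    reads = [
        "ACGTACGTACGTACGTAAAA",          # exact prefix match -> v1
        "GGGGGG" + "TTTTACGTACGTACGT",   # homopolymer trim -> v2
        "CACACACACACACACA",              # matches nothing
    ]
    counts = match_msd_reads(reads, catalog)
    assert counts["v1"] == 1 and counts["v2"] == 1
    assert counts.attrs["n_unassigned"] == 1
    with pytest.raises(QuantifyError, match="ambiguous"):
        match_msd_reads(reads, {"a": "ACGT", "b": "ACGTAC"})
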