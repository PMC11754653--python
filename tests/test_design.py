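import itertools

import numpy as np
import pytest

from retrolib.annotation import revcomp
from retrolib.design import (
    CUT_OFFSETS,
    DONOR_CENTERS,
    DONOR_LENGTHS,
    DesignError,
    Variant,
    attach_barcode,
    build_donor,
    editron_matrix,
    motif_permutations,
    p4_gc_series,
    pseudo_wt_control,
    random_barcodes,
    scan_pams,
    scanning_deletions,
    scanning_insertions,
    single_substitutions,
    stem_bubble_variants,
)
from retrolib.edits import Edit


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


# -- substitutions -----------------------------------------------------------


def test_single_substitutions_enumerate_all_hamming1_neighbors(ann):
    variants = single_substitutions(ann)
    assert len(variants) == 3 * len(ann)
    # brute-force oracle: every Hamming-1 neighbor, exactly once
    wt = ann.ncrna_seq
    oracle = {
        wt[: i] + b + wt[i + 1 :]
        for i in range(len(wt))
        for b in "ACGT"
        if b != wt[i]
    }
    assert {v.sequence for v in variants} == oracle
    assert all(hamming(v.sequence, wt) == 1 for v in variants)
    # ordered by (position, alt base)
    keys = [(v.params["position"], v.params["alt"]) for v in variants]
    assert keys == sorted(keys)


# -- deletions / insertions --------------------------------------------------


def test_scanning_deletions_counts_and_content(ann):
    variants = scanning_deletions(ann, lengths={1, 2, 3, 4, 5})
    L = len(ann)
    assert len(variants) == sum(L - k + 1 for k in range(1, 6))
    wt = ann.ncrna_seq
    oracle = {
        (start, k): wt[: start - 1] + wt[start - 1 + k :]
        for k in range(1, 6)
        for start in range(1, L - k + 2)
    }
    for v in variants:
        assert v.sequence == oracle[(v.params["start"], v.params["length"])]
    # last emitted variant for lengths {5} starts at L-4
    only5 = scanning_deletions(ann, lengths={5})
    assert only5[-1].params["start"] == L - 4


def test_deletion_longer_than_sequence_rejected(ann):
    with pytest.raises(DesignError):
        scanning_deletions(ann, lengths={len(ann) + 1})


def test_scanning_insertions_count_and_determinism(ann):
    a = scanning_insertions(ann, lengths={1, 3, 5}, seed=11)
    b = scanning_insertions(ann, lengths={1, 3, 5}, seed=11)
    assert len(a) == (len(ann) + 1) * 3
    assert [v.sequence for v in a] == [v.sequence for v in b]
    c = scanning_insertions(ann, lengths={1}, fill_policy="AAA")
    first = next(v for v in c if v.params["gap"] == 0)
    assert first.sequence == "A" + ann.ncrna_seq


# -- stem bubbles ------------------------------------------------------------


@pytest.mark.parametrize("stem,bubble", [("P2", 4), ("P3", 4), ("P4", 5)])
def test_stem_bubble_break_and_restore(ann, stem, bubble):
    arm_len = ann.stem_arm_length(stem)
    for d in (1, arm_len - bubble + 1):
        broken, restored = stem_bubble_variants(ann, stem, d)
        # broken: zero complementary pairs in the window
        s5, _ = ann.region(f"{stem}_5arm")
        _, e3 = ann.region(f"{stem}_3arm")
        w5 = broken.sequence[s5 + d - 2 : s5 + d - 2 + bubble]
        partners = ann.ncrna_seq[e3 - d - bubble + 1 : e3 - d + 1][::-1]
        assert all(x != {"A": "T", "T": "A", "C": "G", "G": "C"}[p] for x, p in zip(w5, partners))
        # restored: pairing pattern recovered with non-wild-type sequence
        r5 = restored.sequence[s5 + d - 2 : s5 + d - 2 + bubble]
        r3 = restored.sequence[e3 - d - bubble + 1 : e3 - d + 1]
        assert revcomp(r5) == r3
        assert restored.sequence != ann.ncrna_seq
    with pytest.raises(DesignError):
        stem_bubble_variants(ann, stem, arm_len - bubble + 2)


def test_stem_bubble_valid_distance_count(ann):
    arm_len = ann.stem_arm_length("P4")
    pairs = [stem_bubble_variants(ann, "P4", d) for d in range(1, arm_len - 5 + 2)]
    assert len(pairs) == arm_len - 5 + 1


# -- motif permutations ------------------------------------------------------


def test_motif_permutations(ann):
    variants = motif_permutations(ann)
    assert len(variants) == 64
    motifs = {v.params["motif"] for v in variants}
    assert motifs == {"".join(c) for c in itertools.product("ACGT", repeat=3)}
    wt_motif = next(v for v in variants if v.params["motif"] == "TTT")
    assert wt_motif.sequence == ann.ncrna_seq
    assert any(v.params["motif"] == "GTT" for v in variants)


# -- GC series ---------------------------------------------------------------


def test_p4_gc_series_bins_and_pairing(ann):
    bins = [(10 * i, 10 * (i + 1)) for i in range(10)]
    variants = p4_gc_series(ann, n_per_bin=5, bins=bins, seed=3)
    assert len(variants) == 50
    s5, e5 = ann.region("P4_5arm")
    s3, e3 = ann.region("P4_3arm")
    for v in variants:
        lo, hi = v.params["gc_bin"]
        arm = v.sequence[s5 - 1 : e5]
        gc = 100 * sum(b in "GC" for b in arm) / len(arm)
        assert v.params["gc_percent"] == gc
        assert lo <= gc <= hi
        assert revcomp(arm) == v.sequence[s3 - 1 : e3]


def test_gc_bin_infeasible_for_short_arm(ann):
    with pytest.raises(DesignError, match="infeasible"):
        p4_gc_series(ann, n_per_bin=1, bins=[(3, 4)])  # 10-nt arm: no GC% in [3,4)


# -- barcodes ----------------------------------------------------------------


def test_attach_barcode_and_pseudo_wt(ann):
    wt = Variant("wt", "control_pseudo_wt", ann.ncrna_seq)
    used = set()
    bc = attach_barcode(wt, "ACGTACGTAC", ann, used=used)
    assert len(bc.sequence) == len(ann) + 10
    with pytest.raises(DesignError, match="collision"):
        attach_barcode(wt, "ACGTACGTAC", ann, used=used)
    with pytest.raises(DesignError):
        attach_barcode(wt, "ACGT", ann)
    # pseudo-WT differs from wild type only inside the P4 loop
    pwt = pseudo_wt_control(ann, "TTTTTAAAAA")
    ls, le = ann.region("P4_loop")
    assert pwt.sequence[: ls - 1] == ann.ncrna_seq[: ls - 1]
    assert pwt.sequence[le + 10 :] == ann.ncrna_seq[le:]


def test_random_barcodes_min_distance():
    bcs = random_barcodes(100, seed=5, min_dist=3)
    assert len(set(bcs)) == 100
    arr = np.array([[ord(c) for c in b] for b in bcs])
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    np.fill_diagonal(d, 99)
    assert d.min() >= 3


# -- edit round-trip property ------------------------------------------------


def test_every_variant_reconstructs_from_wild_type(ann):
    variants = (
        single_substitutions(ann)
        + scanning_deletions(ann)
        + scanning_insertions(ann, seed=2)
        + motif_permutations(ann)
        + p4_gc_series(ann, n_per_bin=3, seed=2)
    )
    for v in variants:
        assert v.reconstruct(ann.ncrna_seq) == v.sequence


def test_interval_mapping_consistent_with_new_length(ann):
    # mapping every region through each designed edit keeps intervals in
    # bounds of the edited sequence
    variants = scanning_deletions(ann, lengths={3}) + scanning_insertions(
        ann, lengths={5}, seed=4
    )
    for v in variants:
        for name, interval in ann.regions.items():
            mapped = interval
            for e in v.edits:
                mapped = e.map_interval(mapped)
                if mapped is None:
                    break
            if mapped is not None:
                s, e_ = mapped
                assert 1 <= s <= e_ + 1 and e_ <= len(v.sequence)


# -- editron factorial -------------------------------------------------------


def test_editron_factorial_counts(site, chassis):
    designs = editron_matrix(site, chassis, seed=0)
    assert len(designs) == 5 * 5 * 2 * 5 * 25
    donors = {(d.donor_length, d.donor_center_offset, d.donor_strand) for d in designs}
    pairs = {(d.donor_length, d.donor_center_offset, d.donor_strand, d.cut_offset) for d in designs}
    assert len(donors) == 50
    assert len(pairs) == 250
    assert len({d.design_id for d in designs}) == len(designs)
    assert len({d.barcode for d in designs}) == len(designs)


def test_editron_restriction(site, chassis):
    full = editron_matrix(site, chassis, seed=0)
    restricted = editron_matrix(
        site, chassis, seed=0, restrict=lambda c: c["cut"] != -8
    )
    assert len(restricted) == len(full) * 4 // 5


def test_build_donor_geometry(site):
    bc = "ACGTACGTAC"
    pam = site.pam_for_offset(0)
    nt = build_donor(site, bc, pam, 94, 0, "non_target")
    t = build_donor(site, bc, pam, 94, 0, "target")
    assert len(nt) == 94
    assert t == revcomp(nt)
    assert bc in nt
    # homology arms around the insert differ by <= 1 nt
    left = nt.index(bc)
    right = len(nt) - left - len(bc)
    assert abs(left - right) <= 1


def test_build_donor_recodes_pam(site):
    bc = "ACGTACGTAC"
    pam = site.pam_for_offset(0)  # plus-strand NGG downstream of the insert
    donor = build_donor(site, bc, pam, 112, 0, "non_target")
    # the genomic GG (PAM) must be AT in the donor
    pos_in_locus = pam.pam_start  # 0-based index of first G
    edited_pos = pos_in_locus + len(bc)  # shifted by the insert
    start = site.insertion_point + 5 + 1 - 112 // 2  # donor window start, 1-based
    within = edited_pos - (start - 1)
    assert donor[within : within + 2] == "AT"


def test_donor_window_out_of_bounds(site):
    pam = site.pam_for_offset(0)
    with pytest.raises(DesignError):
        build_donor(site, "ACGTACGTAC", pam, 10 * len(site.locus_seq), 0, "non_target")


def test_planted_pams_found_by_scan_oracle(site):
    cuts = {(strand, cut) for strand, _, cut in scan_pams(site.locus_seq)}
    for pam in site.pams:
        want = site.insertion_point + pam.cut_offset
        assert any(cut == want for _, cut in cuts)
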