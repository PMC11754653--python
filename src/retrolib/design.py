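"""Deterministic enumeration of retron ncRNA variant libraries and editron factorials.

Variant classes mirror the classic saturation-mutagenesis sweeps used to map
a retron ncRNA's sequence/structure requirements: all single-nucleotide
substitutions, scanning deletions (1–5 nt) and insertions (1/3/5 nt),
stem-bubble break/restore pairs for the P2/P3/P4 stem-loops, all 64
permutations of the 3-nt RT recognition motif, and a P4-stem GC-content
series. Editron designs enumerate the HDR-donor factorial: donor length ×
donor center × donor strand × gRNA cut offset × ncRNA chassis, each design
carrying a unique 10-nt barcode that the donor writes into the genome.

All enumerators are deterministic given (annotation, parameters, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from retrolib.annotation import ChassisCatalog, RetronAnnotation, revcomp
from retrolib.edits import Edit, apply_edits

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: bubble window sizes per stem (nt of pairing removed)
BUBBLE_LENGTH = {"P2": 4, "P3": 4, "P4": 5}

BARCODE_LENGTH = 10

#: editron factorial defaults
DONOR_LENGTHS = (54, 64, 78, 94, 112)
DONOR_CENTERS = (-20, -10, 0, 10, 20)
DONOR_STRANDS = ("non_target", "target")
CUT_OFFSETS = (-16, -8, 0, 8, 16)


class DesignError(ValueError):
    pass


@dataclass
class Variant:
    """A designed ncRNA variant: sequence plus the edit that produced it."""

    variant_id: str
    var_class: str
    sequence: str
    params: dict = field(default_factory=dict)
    barcode: str | None = None
    edits: list[Edit] = field(default_factory=list)

    def reconstruct(self, wild_type: str) -> str:
        """Re-apply the recorded edits to the wild type (round-trip check)."""
        return apply_edits(wild_type, self.edits)


# ---------------------------------------------------------------------------
# ncRNA variant enumerators
# ---------------------------------------------------------------------------


def single_substitutions(ann: RetronAnnotation) -> list[Variant]:
    """All 3·L single-nucleotide substitutions, ordered by (position, alt base)."""
    wt = ann.ncrna_seq
    out = []
    for pos in range(1, len(wt) + 1):
        ref = wt[pos - 1]
        for alt in BASES:
            if alt == ref:
                continue
            edit = Edit("substitution", pos, bases=alt)
            out.append(
                Variant(
                    variant_id=f"sub_{pos}{ref}>{alt}",
                    var_class="substitution",
                    sequence=edit.apply(wt),
                    params={"position": pos, "ref": ref, "alt": alt},
                    edits=[edit],
                )
            )
    return out


def scanning_deletions(ann: RetronAnnotation, lengths: Iterable[int] = (1, 2, 3, 4, 5)) -> list[Variant]:
    """One deletion variant per (start, k): k consecutive bases removed."""
    wt = ann.ncrna_seq
    L = len(wt)
    lengths = sorted(set(lengths))
    if not lengths:
        raise DesignError("lengths must be nonempty")
    out = []
    for k in lengths:
        if k > L:
            raise DesignError(f"deletion length {k} exceeds sequence length {L}")
        for start in range(1, L - k + 2):
            edit = Edit("deletion", start, length=k)
            out.append(
                Variant(
                    variant_id=f"del_{start}_{k}",
                    var_class="deletion",
                    sequence=edit.apply(wt),
                    params={"start": start, "length": k},
                    edits=[edit],
                )
            )
    return out


def scanning_insertions(
    ann: RetronAnnotation,
    lengths: Iterable[int] = (1, 3, 5),
    fill_policy: str | None = None,
    seed: int = 0,
) -> list[Variant]:
    """One insertion variant per (gap position 0..L, k).

    fill_policy: a fixed fill string (cycled/truncated to k) or None for
    seeded random fills.
    """
    wt = ann.ncrna_seq
    L = len(wt)
    lengths = sorted(set(lengths))
    rng = np.random.default_rng(seed)
    out = []
    for k in lengths:
        if k < 1:
            raise DesignError("insertion length must be >= 1")
        for gap in range(0, L + 1):
            if fill_policy is None:
                fill = "".join(rng.choice(list(BASES), size=k))
            else:
                if not set(fill_policy) <= set(BASES):
                    raise DesignError("fill_policy must be over ACGT")
                fill = (fill_policy * k)[:k]
            edit = Edit("insertion", gap, bases=fill)
            out.append(
                Variant(
                    variant_id=f"ins_{gap}_{k}",
                    var_class="insertion",
                    sequence=edit.apply(wt),
                    params={"gap": gap, "length": k, "fill": fill},
                    edits=[edit],
                )
            )
    return out


def _stem_window(ann: RetronAnnotation, stem: str, distance_from_base: int, bubble: int):
    """1-based coordinate windows for a bubble at the given pair distance.

    Pair 1 is the stem base: the 5' arm's first base paired with the 3'
    arm's last base.
    """
    s5, e5 = ann.region(f"{stem}_5arm")
    s3, e3 = ann.region(f"{stem}_3arm")
    arm_len = e5 - s5 + 1
    if not (1 <= distance_from_base <= arm_len - bubble + 1):
        raise DesignError(
            f"bubble of {bubble} at distance {distance_from_base} exceeds {stem} arm ({arm_len} pairs)"
        )
    w5 = (s5 + distance_from_base - 1, s5 + distance_from_base + bubble - 2)
    w3 = (e3 - (distance_from_base + bubble - 2), e3 - (distance_from_base - 1))
    return w5, w3


def stem_bubble_variants(
    ann: RetronAnnotation, stem: str, distance_from_base: int
) -> tuple[Variant, Variant]:
    """A (broken, restored) pair of stem variants.

    broken: the 5'-arm window is replaced so that no position in the window
    can pair with its partner (each base b becomes the first of A>C>G>T that
    is neither b nor the complement of its wild-type partner). restored: the
    mirrored 3'-arm window is additionally replaced with the reverse
    complement of the new 5' window, recovering the pairing pattern with a
    non-wild-type sequence.
    """
    if stem not in BUBBLE_LENGTH:
        raise DesignError(f"unknown stem {stem!r}")
    bubble = BUBBLE_LENGTH[stem]
    wt = ann.ncrna_seq
    (w5s, w5e), (w3s, w3e) = _stem_window(ann, stem, distance_from_base, bubble)
    old5 = wt[w5s - 1 : w5e]
    # partner of 5'-window offset j is the mirrored 3' base, read 3'→5'
    partners = wt[w3s - 1 : w3e][::-1]
    new5 = []
    for b, partner in zip(old5, partners):
        for cand in BASES:
            if cand != b and cand != COMPLEMENT[partner]:
                new5.append(cand)
                break
    new5 = "".join(new5)
    e_break = Edit("substitution", w5s, bases=new5)
    broken = Variant(
        variant_id=f"{stem}_break_d{distance_from_base}",
        var_class="stem_break",
        sequence=e_break.apply(wt),
        params={"stem": stem, "distance_from_base": distance_from_base, "bubble": bubble},
        edits=[e_break],
    )
    e_restore = Edit("substitution", w3s, bases=revcomp(new5))
    restored = Variant(
        variant_id=f"{stem}_restore_d{distance_from_base}",
        var_class="stem_restore",
        sequence=e_restore.apply(e_break.apply(wt)),
        params={"stem": stem, "distance_from_base": distance_from_base, "bubble": bubble},
        edits=[e_break, e_restore],
    )
    return broken, restored


def stem_bubble_scan(ann: RetronAnnotation, stem: str) -> list[Variant]:
    """All (broken, restored) pairs along the stem, interleaved."""
    bubble = BUBBLE_LENGTH[stem]
    arm_len = ann.stem_arm_length(stem)
    out: list[Variant] = []
    for d in range(1, arm_len - bubble + 2):
        out.extend(stem_bubble_variants(ann, stem, d))
    return out


def motif_permutations(ann: RetronAnnotation) -> list[Variant]:
    """All 64 3-nt RT recognition motif replacements (wild-type TTT included
    as a control)."""
    wt = ann.ncrna_seq
    ms, _ = ann.rt_motif_interval
    out = []
    for combo in itertools.product(BASES, repeat=3):
        motif = "".join(combo)
        edit = Edit("substitution", ms, bases=motif)
        out.append(
            Variant(
                variant_id=f"motif_{motif}",
                var_class="motif_permutation",
                sequence=edit.apply(wt),
                params={"motif": motif, "is_wt_motif": motif == "TTT"},
                edits=[edit],
            )
        )
    return out


def p4_gc_series(
    ann: RetronAnnotation,
    n_per_bin: int = 25,
    bins: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[Variant]:
    """Re-randomized P4 stems at controlled GC content.

    For each GC%-range bin, draws ``n_per_bin`` stems whose 5' arm has a GC
    fraction inside the bin; the 3' arm is kept reverse-complementary. Bins
    are half-open [lo, hi) except the last, which is closed.
    """
    if bins is None:
        bins = [(10 * i, 10 * (i + 1)) for i in range(10)]
    rng = np.random.default_rng(seed)
    wt = ann.ncrna_seq
    s5, e5 = ann.region("P4_5arm")
    s3, e3 = ann.region("P4_3arm")
    arm_len = e5 - s5 + 1
    out = []
    for bin_idx, (lo, hi) in enumerate(bins):
        last = bin_idx == len(bins) - 1
        feasible_g = [
            g
            for g in range(arm_len + 1)
            if (lo <= 100 * g / arm_len < hi) or (last and 100 * g / arm_len == hi)
        ]
        if not feasible_g:
            raise DesignError(
                f"GC bin [{lo}, {hi}) infeasible for P4 arm length {arm_len}"
            )
        for i in range(n_per_bin):
            while True:
                g = int(rng.choice(feasible_g))
                arm = ["G" if rng.random() < 0.5 else "C" for _ in range(g)]
                arm += ["A" if rng.random() < 0.5 else "T" for _ in range(arm_len - g)]
                rng.shuffle(arm)
                arm5 = "".join(arm)
                if arm5 != wt[s5 - 1 : e5]:
                    break
            e_5 = Edit("substitution", s5, bases=arm5)
            e_3 = Edit("substitution", s3, bases=revcomp(arm5))
            seq = apply_edits(wt, [e_5, e_3])
            out.append(
                Variant(
                    variant_id=f"gc_{lo:g}_{hi:g}_{i}",
                    var_class="gc_series",
                    sequence=seq,
                    params={
                        "gc_bin": (lo, hi),
                        "gc_percent": 100 * g / arm_len,
                    },
                    edits=[e_5, e_3],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------


def random_barcodes(n: int, seed: int = 0, min_dist: int = 3, length: int = BARCODE_LENGTH) -> list[str]:
    """Seeded random barcodes with minimum pairwise Hamming distance."""
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, length), dtype=np.int8)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n + 1000:
            raise DesignError("barcode pool exhausted (min_dist too strict for n)")
        cand = rng.integers(0, 4, size=length).astype(np.int8)
        if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_dist:
            continue
        accepted = np.vstack([accepted, cand])
        out.append("".join(BASES[b] for b in cand))
    return out


def attach_barcode(
    variant: Variant,
    barcode: str,
    ann: RetronAnnotation,
    used: set[str] | None = None,
) -> Variant:
    """Insert a 10-nt barcode at a fixed offset inside the P4 loop.

    The insertion point is the midpoint of the wild-type P4 loop, mapped
    through the variant's recorded edits so that barcodes land in the loop
    even for length-changing upstream variants. Applying this to the plain
    wild type yields the pseudo-wild-type normalization control.
    """
    if len(barcode) != BARCODE_LENGTH or not set(barcode) <= set(BASES):
        raise DesignError(f"barcode must be {BARCODE_LENGTH} nt over ACGT: {barcode!r}")
    if used is not None:
        if barcode in used:
            raise DesignError(f"barcode collision within library: {barcode}")
        used.add(barcode)
    ls, le = ann.region("P4_loop")
    anchor = ls + (le - ls) // 2  # insert after this wild-type base
    pos: int | None = anchor
    for e in variant.edits:
        pos = e.map_position(pos)
        if pos is None:
            raise DesignError(
                f"P4 loop anchor deleted by variant {variant.variant_id}; cannot barcode"
            )
    edit = Edit("insertion", pos, bases=barcode)
    return Variant(
        variant_id=variant.variant_id,
        var_class=variant.var_class,
        sequence=edit.apply(variant.sequence),
        params={**variant.params, "barcode": barcode},
        barcode=barcode,
        edits=[*variant.edits, edit],
    )


def pseudo_wt_control(ann: RetronAnnotation, barcode: str, used: set[str] | None = None) -> Variant:
    """Wild-type ncRNA carrying only a P4-loop barcode: the 100% normalizer
    that controls for the cost of adding 10 nucleotides."""
    wt = Variant(
        variant_id="pseudo_wt",
        var_class="control_pseudo_wt",
        sequence=ann.ncrna_seq,
        params={},
        edits=[],
    )
    return attach_barcode(wt, barcode, ann, used=used)


# ---------------------------------------------------------------------------
# Editron designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PamSite:
    """A planted SpCas9 PAM enabling one cut offset at an editing site."""

    cut_offset: int
    strand: str  # '+': NGG on the given locus strand; '-': CCN on it
    pam_start: int  # 1-based position of the PAM's first base in plus coords


@dataclass
class EditingSite:
    """A genomic locus with an insertion point and PAMs for each cut offset.

    ``insertion_point`` is a 1-based inter-base position: the barcode is
    inserted between base ip and base ip+1. A PAM's blunt cut (between
    protospacer positions 17/18, 3 bp from the PAM) must land at
    insertion_point + cut_offset.
    """

    site_id: str
    locus_seq: str
    insertion_point: int
    pams: list[PamSite]

    def __post_init__(self) -> None:
        for pam in self.pams:
            if cut_position(pam, self.locus_seq) != self.insertion_point + pam.cut_offset:
                raise DesignError(
                    f"PAM for offset {pam.cut_offset} cuts at "
                    f"{cut_position(pam, self.locus_seq)}, expected "
                    f"{self.insertion_point + pam.cut_offset}"
                )
            s = self.locus_seq
            if pam.strand == "+":
                if s[pam.pam_start : pam.pam_start + 2] != "GG":
                    raise DesignError(f"no NGG at +{pam.pam_start}")
            else:
                if s[pam.pam_start - 1 : pam.pam_start + 1] != "CC":
                    raise DesignError(f"no CCN at -{pam.pam_start}")

    def pam_for_offset(self, cut_offset: int) -> PamSite:
        for pam in self.pams:
            if pam.cut_offset == cut_offset:
                return pam
        raise DesignError(f"site {self.site_id} has no PAM for cut offset {cut_offset}")


def cut_position(pam: PamSite, locus_seq: str) -> int:
    """1-based inter-base blunt-cut position for a PAM (cut after this base)."""
    if pam.strand == "+":
        return pam.pam_start - 4
    return pam.pam_start + 5


def spacer_for_pam(pam: PamSite, locus_seq: str) -> str:
    """20-nt gRNA spacer (protospacer sequence, 5'→3' on the PAM strand)."""
    q = pam.pam_start
    if pam.strand == "+":
        if q - 21 < 0:
            raise DesignError("protospacer runs off the locus 5' end")
        return locus_seq[q - 21 : q - 1]
    if q + 22 > len(locus_seq):
        raise DesignError("protospacer runs off the locus 3' end")
    return revcomp(locus_seq[q + 2 : q + 22])


def scan_pams(locus_seq: str) -> list[tuple[str, int, int]]:
    """All NGG PAMs on either strand: (strand, pam_start, cut_position)."""
    out = []
    for i in range(1, len(locus_seq) - 1):
        if locus_seq[i] == "G" and locus_seq[i + 1] == "G":
            pam = PamSite(0, "+", i)  # pam_start 1-based = i (N at i, GG at i+1,i+2)
            out.append(("+", i, cut_position(pam, locus_seq)))
        if locus_seq[i - 1] == "C" and locus_seq[i] == "C":
            pam = PamSite(0, "-", i)
            out.append(("-", i, cut_position(pam, locus_seq)))
    return out


def _recode_pam(seq: str, pam: PamSite, shift: int) -> str:
    """NGG→NAT recode of a PAM in (possibly insertion-shifted) coordinates.

    In plus-strand coordinates both orientations recode the GG/CC
    dinucleotide to AT.
    """
    if pam.strand == "+":
        lo = pam.pam_start + shift  # 0-based index of first G
    else:
        lo = pam.pam_start - 1 + shift  # 0-based index of first C
    if lo < 0 or lo + 2 > len(seq):
        return seq
    return seq[:lo] + "AT" + seq[lo + 2 :]


@dataclass
class EditronDesign:
    design_id: str
    site_id: str
    donor_length: int
    donor_center_offset: int
    donor_strand: str
    cut_offset: int
    grna_spacer: str
    chassis_id: str
    donor_seq: str
    barcode: str
    pam_strand: str

    def axis_labels(self) -> dict:
        return {
            "site": self.site_id,
            "length": self.donor_length,
            "center": self.donor_center_offset,
            "strand": self.donor_strand,
            "cut": self.cut_offset,
            "chassis": self.chassis_id,
        }


def build_donor(
    site: EditingSite,
    barcode: str,
    pam: PamSite,
    length: int,
    center_offset: int = 0,
    strand: str = "non_target",
) -> str:
    """Construct an HDR donor for inserting ``barcode`` at the site.

    The donor is the edited-allele sequence: barcode inserted at the
    insertion point and the paired gRNA's PAM recoded NGG→NAT (to prevent
    re-cutting), windowed to ``length`` nt. ``center_offset`` 0 centers the
    window on the middle of the 10-nt insert; the window shifts by
    ``center_offset`` nt toward the locus 3' end when positive.
    ``strand='non_target'`` emits the PAM-containing strand's sequence,
    ``'target'`` its reverse complement (the strand the gRNA pairs with).
    """
    ip = site.insertion_point
    edited = site.locus_seq[:ip] + barcode + site.locus_seq[ip:]
    # PAM coordinates shift by the insert length when downstream of ip
    pam_plus_lo = pam.pam_start if pam.strand == "+" else pam.pam_start - 1
    shift = len(barcode) if pam_plus_lo > ip else 0
    edited = _recode_pam(edited, pam, shift)
    c = ip + len(barcode) // 2 + center_offset  # edited coords
    start = c - length // 2 + 1  # 1-based
    end = start + length - 1
    if start < 1 or end > len(edited):
        raise DesignError(
            f"donor window [{start}, {end}] out of locus bounds (length {len(edited)})"
        )
    window = edited[start - 1 : end]
    if barcode not in window:
        raise DesignError("donor window does not contain the barcode insert")
    pam_on_plus = pam.strand == "+"
    non_target_seq = window if pam_on_plus else revcomp(window)
    if strand == "non_target":
        return non_target_seq
    if strand == "target":
        return revcomp(non_target_seq)
    raise DesignError(f"unknown strand {strand!r}")


def editron_matrix(
    site: EditingSite,
    chassis: ChassisCatalog,
    lengths: Sequence[int] = DONOR_LENGTHS,
    centers: Sequence[int] = DONOR_CENTERS,
    strands: Sequence[str] = DONOR_STRANDS,
    cut_offsets: Sequence[int] = CUT_OFFSETS,
    seed: int = 0,
    restrict: Callable[[dict], bool] | None = None,
) -> list[EditronDesign]:
    """Full donor × gRNA × chassis factorial for one editing site.

    Each design receives a unique seeded barcode (pairwise Hamming distance
    ≥ 3). ``restrict`` optionally drops axis combinations (called with the
    axis-label dict; return False to exclude).
    """
    combos = [
        {
            "length": ln,
            "center": ct,
            "strand": st,
            "cut": co,
            "chassis": ch.chassis_id,
            "site": site.site_id,
        }
        for ln, ct, st, co, ch in itertools.product(
            lengths, centers, strands, cut_offsets, chassis
        )
    ]
    if restrict is not None:
        combos = [c for c in combos if restrict(c)]
    barcodes = random_barcodes(len(combos), seed=seed)
    designs = []
    for i, (combo, bc) in enumerate(zip(combos, barcodes)):
        pam = site.pam_for_offset(combo["cut"])
        donor = build_donor(
            site, bc, pam, combo["length"], combo["center"], combo["strand"]
        )
        designs.append(
            EditronDesign(
                design_id=f"{site.site_id}_d{i:05d}",
                site_id=site.site_id,
                donor_length=combo["length"],
                donor_center_offset=combo["center"],
                donor_strand=combo["strand"],
                cut_offset=combo["cut"],
                grna_spacer=spacer_for_pam(pam, site.locus_seq),
                chassis_id=combo["chassis"],
                donor_seq=donor,
                barcode=bc,
                pam_strand=pam.strand,
            )
        )
    return designs
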