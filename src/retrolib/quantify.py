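"""From raw reads/counts to normalized activity measures.

The two activity statistics of a pooled retron experiment:

* msDNA production — a variant's msDNA relative abundance over its plasmid
  relative abundance (pre/post-expression average), scaled so the wild type
  (or barcoded pseudo-wild-type control) sits at 100%.
* editing rate ("barcode representation") — a design's barcode relative
  abundance among genome-edited reads divided by its relative abundance in
  the time-integrated (t0+t24+t48) plasmid pool, with low-coverage and
  non-working barcodes filtered, then normalized within groups that differ
  only along the axis of interest.

Zero plasmid abundance propagates as missing, never as infinity; the
pipeline filters rather than smooths (no pseudocounts).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from retrolib.annotation import revcomp
from retrolib.io import read_fastq

logger = logging.getLogger("retrolib.quantify")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.addHandler(_h)

MSDNA_ROLES = {"plasmid_pre", "plasmid_post", "msdna"}
EDITING_ROLES = {"plasmid_t0", "plasmid_t24", "plasmid_t48", "genome_t48"}
KNOWN_ROLES = MSDNA_ROLES | EDITING_ROLES | {"amplicon"}

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


class QuantifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """variant/barcode × sample read counts with sample metadata.

    ``counts``: DataFrame, index = variant_id, columns = sample names,
    non-negative integers. ``samples``: DataFrame indexed by sample name
    with columns ``role``, ``replicate``, ``site``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise QuantifyError("negative counts")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise QuantifyError(f"samples missing metadata: {sorted(missing)}")
        bad = set(self.samples["role"]) - KNOWN_ROLES
        if bad:
            raise QuantifyError(f"unknown sample roles: {sorted(bad)}")

    def columns_for(self, role: str, replicate=None, site=None) -> list[str]:
        sel = self.samples["role"] == role
        if replicate is not None:
            sel &= self.samples["replicate"] == replicate
        if site is not None:
            sel &= self.samples["site"] == site
        return [c for c in self.counts.columns if c in self.samples.index[sel]]

    def groups(self) -> list[tuple]:
        """Distinct (replicate, site) pairs, sorted."""
        return sorted(
            set(zip(self.samples["replicate"], self.samples["site"])),
            key=lambda t: (str(t[0]), str(t[1])),
        )

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.rename_axis("variant_id").to_csv(counts_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="variant_id")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts=counts, samples=samples)


# ---------------------------------------------------------------------------
# Read counting
# ---------------------------------------------------------------------------


def _reads_iter(reads: Iterable[str] | str | Path) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        return read_fastq(reads)
    return reads


def _whitelist_matrix(whitelist: Sequence[str]) -> np.ndarray:
    k = len(whitelist[0])
    mat = np.empty((len(whitelist), k), dtype=np.int8)
    for i, bc in enumerate(whitelist):
        if len(bc) != k or not set(bc) <= set("ACGT"):
            raise QuantifyError(f"bad whitelist barcode {bc!r}")
        mat[i] = [_BASE_INDEX[b] for b in bc]
    return mat


def extract_barcodes(
    reads: Iterable[str] | str | Path,
    anchors: tuple[str, str],
    whitelist: Sequence[str],
    max_mismatch: int = 0,
) -> pd.Series:
    """Count whitelist barcodes in anchored amplicon reads.

    A read is assigned by locating the 5' flank (exact, both orientations
    tried), extracting the insert between the flanks, and matching it to the
    whitelist within ``max_mismatch`` (unique best match only; ties go
    unassigned). The whitelist must be unambiguous: minimum pairwise Hamming
    distance > 2*max_mismatch.
    """
    flank5, flank3 = anchors
    if not flank5 or not flank3:
        raise QuantifyError("anchors must be nonempty")
    if not whitelist:
        raise QuantifyError("whitelist must be nonempty")
    wl = list(whitelist)
    k = len(wl[0])
    mat = _whitelist_matrix(wl)
    if len(wl) > 1:
        # pairwise ambiguity check
        d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, k + 1)
        if int(d.min()) <= 2 * max_mismatch:
            raise QuantifyError(
                f"ambiguous whitelist: two barcodes within Hamming {int(d.min())} "
                f"<= 2*max_mismatch ({2 * max_mismatch})"
            )
    exact = {bc: i for i, bc in enumerate(wl)}
    counts = np.zeros(len(wl), dtype=np.int64)
    n_total = n_unassigned = 0
    for read in _reads_iter(reads):
        n_total += 1
        bc = None
        for r in (read, revcomp(read)):
            i = r.find(flank5)
            if i < 0:
                continue
            lo = i + len(flank5)
            if r[lo + k : lo + k + len(flank3)] != flank3:
                continue
            bc = r[lo : lo + k]
            break
        idx = None
        if bc is not None and len(bc) == k and set(bc) <= set("ACGT"):
            idx = exact.get(bc)
            if idx is None and max_mismatch > 0:
                vec = np.array([_BASE_INDEX[b] for b in bc], dtype=np.int8)
                dists = (mat != vec).sum(axis=1)
                best = int(dists.min())
                if best <= max_mismatch and int((dists == best).sum()) == 1:
                    idx = int(dists.argmin())
        if idx is None:
            n_unassigned += 1
        else:
            counts[idx] += 1
    logger.info(
        "extract_barcodes: %d reads, %d assigned, %d unassigned",
        n_total,
        n_total - n_unassigned,
        n_unassigned,
    )
    out = pd.Series(counts, index=pd.Index(wl, name="barcode"))
    out.attrs["n_total"] = n_total
    out.attrs["n_unassigned"] = n_unassigned
    return out


def trim_homopolymer(read: str, min_run: int = 3, bases: str = "GC") -> str:
    """Trim the leading G/C homopolymer tail left by poly-dC/TdT library prep."""
    if not read:
        return read
    b = read[0]
    if b not in bases:
        return read
    run = len(read) - len(read.lstrip(b))
    return read[run:] if run >= min_run else read


def match_msd_reads(
    reads: Iterable[str] | str | Path,
    catalog: Mapping[str, str],
) -> pd.Series:
    """Count catalog variants by exact windowed match (no barcode).

    Reads are trimmed of a leading G/C homopolymer run, then matched if a
    catalog sequence is a prefix of the trimmed read in either orientation.
    """
    seqs = list(catalog.values())
    if len(set(seqs)) != len(seqs):
        raise QuantifyError("ambiguous catalog: duplicate sequences")
    ordered = sorted(seqs, key=len)
    for i, s in enumerate(ordered):
        for t in ordered[i + 1 :]:
            if t.startswith(s):
                raise QuantifyError(
                    "ambiguous catalog: one sequence is a prefix of another"
                )
    by_seq = {seq: vid for vid, seq in catalog.items()}
    lengths = sorted({len(s) for s in seqs})
    counts = {vid: 0 for vid in catalog}
    n_total = n_unassigned = 0
    for read in _reads_iter(reads):
        n_total += 1
        hit = None
        for r in (trim_homopolymer(read), trim_homopolymer(revcomp(read))):
            for ln in lengths:
                vid = by_seq.get(r[:ln])
                if vid is not None:
                    hit = vid
                    break
            if hit:
                break
        if hit is None:
            n_unassigned += 1
        else:
            counts[hit] += 1
    logger.info(
        "match_msd_reads: %d reads, %d assigned, %d unassigned",
        n_total,
        n_total - n_unassigned,
        n_unassigned,
    )
    out = pd.Series(counts, name="count")
    out.attrs["n_total"] = n_total
    out.attrs["n_unassigned"] = n_unassigned
    return out


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def relative_abundance(counts) -> pd.Series:
    """Raw count over the total raw counts (proportions summing to 1)."""
    s = pd.Series(counts, dtype=float)
    total = s.sum()
    if total <= 0:
        raise QuantifyError("all-zero count column")
    return s / total


def msdna_production(table: CountTable, wt_id: str) -> pd.DataFrame:
    """msDNA production per variant, as % of wild type, per replicate.

    prod(v) = RA_msdna(v) / mean(RA_pre(v), RA_post(v)); the output is
    100 × prod(v)/prod(wt). Variants with zero plasmid abundance are emitted
    as missing.
    """
    if wt_id not in table.counts.index:
        raise QuantifyError(f"normalizer {wt_id!r} absent from count table")
    rows = []
    for replicate, site in table.groups():
        cols = {
            role: table.columns_for(role, replicate=replicate, site=site)
            for role in ("plasmid_pre", "plasmid_post", "msdna")
        }
        for role, cs in cols.items():
            if len(cs) != 1:
                raise QuantifyError(
                    f"replicate {replicate!r}/site {site!r}: need exactly one "
                    f"{role} sample, found {len(cs)}"
                )
        ra_pre = relative_abundance(table.counts[cols["plasmid_pre"][0]])
        ra_post = relative_abundance(table.counts[cols["plasmid_post"][0]])
        ra_ms = relative_abundance(table.counts[cols["msdna"][0]])
        plasmid = (ra_pre + ra_post) / 2
        with np.errstate(divide="ignore", invalid="ignore"):
            prod = ra_ms / plasmid
        prod[plasmid == 0] = np.nan
        wt_prod = prod.loc[wt_id]
        if not np.isfinite(wt_prod) or wt_prod == 0:
            raise QuantifyError(
                f"wild-type {wt_id!r} has zero/undefined production in "
                f"replicate {replicate!r}"
            )
        pct = 100.0 * prod / wt_prod
        n_missing = int(pct.isna().sum())
        if n_missing:
            logger.info(
                "msdna_production: replicate %s/site %s: %d variants with zero "
                "plasmid abundance emitted as missing",
                replicate,
                site,
                n_missing,
            )
        for vid, val in pct.items():
            rows.append(
                {
                    "variant_id": vid,
                    "replicate": replicate,
                    "site": site,
                    "measure": "msdna_pct_wt",
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def editing_rate(
    table: CountTable,
    min_plasmid: int = 10,
    drop_nonworking: bool = True,
) -> pd.DataFrame:
    """Barcode representation per design, per replicate × site.

    The plasmid pool is the per-barcode sum over t0+t24+t48 (integrating
    plasmid abundance over the editing window). representation =
    RA_genome / RA_plasmid_pool. Barcodes with plasmid sum <= ``min_plasmid``
    (strictly: kept only when > min_plasmid) are removed; barcodes never seen
    in the genome are flagged non-working and removed unless
    ``drop_nonworking=False``.
    """
    rows = []
    for replicate, site in table.groups():
        cols = {
            role: table.columns_for(role, replicate=replicate, site=site)
            for role in ("plasmid_t0", "plasmid_t24", "plasmid_t48", "genome_t48")
        }
        for role, cs in cols.items():
            if len(cs) != 1:
                raise QuantifyError(
                    f"replicate {replicate!r}/site {site!r}: need exactly one "
                    f"{role} sample, found {len(cs)}"
                )
        plasmid_sum = (
            table.counts[cols["plasmid_t0"][0]]
            + table.counts[cols["plasmid_t24"][0]]
            + table.counts[cols["plasmid_t48"][0]]
        )
        genome = table.counts[cols["genome_t48"][0]]
        ra_plasmid = relative_abundance(plasmid_sum)
        ra_genome = relative_abundance(genome)
        keep_plasmid = plasmid_sum > min_plasmid
        n_low = int((~keep_plasmid).sum())
        working = genome > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            rep = ra_genome / ra_plasmid
        rep[ra_plasmid == 0] = np.nan
        kept = keep_plasmid & (working if drop_nonworking else True)
        logger.info(
            "editing_rate: replicate %s/site %s: %d barcodes below plasmid "
            "threshold, %d non-working of %d covered",
            replicate,
            site,
            n_low,
            int((keep_plasmid & ~working).sum()),
            int(keep_plasmid.sum()),
        )
        for vid in table.counts.index[kept]:
            rows.append(
                {
                    "variant_id": vid,
                    "replicate": replicate,
                    "site": site,
                    "measure": "barcode_representation",
                    "value": rep.loc[vid] if working.loc[vid] else np.nan,
                    "plasmid_sum": int(plasmid_sum.loc[vid]),
                    "genome_count": int(genome.loc[vid]),
                    "working": bool(working.loc[vid]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "replicate",
            "site",
            "measure",
            "value",
            "plasmid_sum",
            "genome_count",
            "working",
        ],
    )


def working_fraction(table: CountTable, min_plasmid: int = 10) -> pd.DataFrame:
    """Fraction of plasmid-covered barcodes with at least one genome read."""
    act = editing_rate(table, min_plasmid=min_plasmid, drop_nonworking=False)
    return (
        act.groupby(["replicate", "site"])["working"]
        .mean()
        .rename("working_fraction")
        .reset_index()
    )


def within_group_normalize(
    act: pd.DataFrame,
    axis: str,
    reference_level,
    axis_cols: Sequence[str],
    value_col: str = "value",
) -> pd.DataFrame:
    """Normalize an activity table to a reference level along one axis.

    Groups are variants sharing every label in ``axis_cols`` except ``axis``,
    within replicate × site. Each value is divided by its group's
    reference-level value; groups lacking a usable reference are dropped
    (tallied in ``.attrs['n_groups_dropped']``).
    """
    if axis not in act.columns:
        raise QuantifyError(f"axis column {axis!r} absent from activity table")
    group_cols = [c for c in axis_cols if c != axis] + ["replicate", "site"]
    group_cols = [c for c in group_cols if c in act.columns]
    out_frames = []
    n_dropped = 0
    for _, grp in act.groupby(group_cols, dropna=False, sort=True):
        ref_rows = grp[grp[axis] == reference_level]
        ref_vals = ref_rows[value_col].dropna()
        if len(ref_vals) != 1 or ref_vals.iloc[0] == 0:
            n_dropped += 1
            continue
        norm = grp.copy()
        norm[value_col] = grp[value_col] / ref_vals.iloc[0]
        norm["measure"] = "normalized_representation"
        out_frames.append(norm)
    if n_dropped:
        logger.info(
            "within_group_normalize(%s): %d groups dropped (missing/filtered reference)",
            axis,
            n_dropped,
        )
    out = (
        pd.concat(out_frames, ignore_index=True)
        if out_frames
        else act.iloc[0:0].copy()
    )
    out.attrs["n_groups_dropped"] = n_dropped
    return out


@dataclass
class AxisSummary:
    """Per-(replicate, site) medians plus the grand mean per axis level."""

    medians: pd.DataFrame
    summary: pd.DataFrame


def summarize_axis(
    norm: pd.DataFrame,
    axis: str,
    value_col: str = "value",
) -> AxisSummary:
    """Median over variants within (replicate, site), then mean ± sd of those
    medians across replicates and sites, per axis level."""
    if norm.empty:
        raise QuantifyError("empty activity table")
    medians = (
        norm.dropna(subset=[value_col])
        .groupby([axis, "replicate", "site"], sort=True)[value_col]
        .median()
        .rename("median")
        .reset_index()
    )
    summary = (
        medians.groupby(axis)["median"]
        .agg(grand_mean="mean", sd="std", n_medians="count")
        .reset_index()
    )
    return AxisSummary(medians=medians, summary=summary)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def _one_sample_t(values: np.ndarray, null: float) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise QuantifyError("one-sample t needs >= 2 observations")
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0:
        if mean == null:
            return 0.0, 1.0
        return float(np.inf) if mean > null else float(-np.inf), 0.0
    t = (mean - null) / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def axis_statistics(
    act: pd.DataFrame,
    axis: str,
    value_col: str = "value",
    test: str = "one_sample_t",
    null: float = 1.0,
    reference=None,
    correction: str | None = "bonferroni",
    pair_col: str | None = None,
) -> pd.DataFrame:
    """Group-comparison statistics along an axis.

    test:
        ``one_sample_t`` — each non-reference level vs ``null`` (use after
        within-group normalization, where the reference sits at 1.0);
        ``paired_t`` — two levels paired by ``pair_col``;
        ``anova_dunnett`` — one-way ANOVA with Dunnett contrasts vs
        ``reference``.
    correction: ``bonferroni`` or None (Dunnett adjusts internally).
    Returns one row per comparison: level, statistic, p_raw, p_adj.
    """
    data = act.dropna(subset=[value_col])
    levels = sorted(data[axis].unique(), key=str)
    rows = []
    if test == "one_sample_t":
        for level in levels:
            if reference is not None and level == reference:
                continue
            vals = data.loc[data[axis] == level, value_col].to_numpy()
            t, p = _one_sample_t(vals, null)
            rows.append({"level": level, "statistic": t, "p_raw": p, "n": len(vals)})
    elif test == "paired_t":
        if pair_col is None:
            raise QuantifyError("paired_t requires pair_col")
        if len(levels) != 2:
            raise QuantifyError(f"paired_t needs exactly 2 levels, got {levels}")
        wide = data.pivot_table(index=pair_col, columns=axis, values=value_col).dropna()
        if len(wide) < 2:
            raise QuantifyError("paired_t needs >= 2 complete pairs")
        diff = wide[levels[0]].to_numpy() - wide[levels[1]].to_numpy()
        t, p = _one_sample_t(diff, 0.0)
        rows.append(
            {"level": f"{levels[0]} vs {levels[1]}", "statistic": t, "p_raw": p, "n": len(wide)}
        )
    elif test == "anova_dunnett":
        if reference is None:
            raise QuantifyError("anova_dunnett requires a reference level")
        control = data.loc[data[axis] == reference, value_col].to_numpy()
        others = [lv for lv in levels if lv != reference]
        groups = [data.loc[data[axis] == lv, value_col].to_numpy() for lv in others]
        for g, lv in zip(groups + [control], others + [reference]):
            if g.size < 2:
                raise QuantifyError(f"group {lv!r} has < 2 observations")
        f_stat, f_p = stats.f_oneway(control, *groups)
        res = stats.dunnett(*groups, control=control)
        for lv, t, p in zip(others, res.statistic, res.pvalue):
            rows.append(
                {
                    "level": lv,
                    "statistic": float(t),
                    "p_raw": float(p),  # Dunnett p is already family-adjusted
                    "n": int(data.loc[data[axis] == lv, value_col].size),
                    "anova_F": float(f_stat),
                    "anova_p": float(f_p),
                }
            )
        out = pd.DataFrame(rows)
        out["p_adj"] = out["p_raw"]
        return out
    else:
        raise QuantifyError(f"unknown test {test!r}")
    out = pd.DataFrame(rows)
    if correction == "bonferroni" and len(out) > 0:
        out["p_adj"] = multipletests(out["p_raw"], method="bonferroni")[1]
    elif correction is None:
        out["p_adj"] = out["p_raw"]
    else:
        raise QuantifyError(f"unknown correction {correction!r}")
    return out


# ---------------------------------------------------------------------------
# Amplicon classification and transforms
# ---------------------------------------------------------------------------


@dataclass
class AmpliconCounts:
    n_wt: int
    n_edit: int
    n_indel: int
    n_unclassified: int

    @property
    def ratio_edit_wt(self) -> float | None:
        """The literal precise-edit / wild-type read ratio (None if no WT)."""
        return None if self.n_wt == 0 else self.n_edit / self.n_wt

    @property
    def percent_edit(self) -> float | None:
        total = self.n_wt + self.n_edit + self.n_indel
        return None if total == 0 else 100.0 * self.n_edit / total

    @property
    def percent_indel(self) -> float | None:
        total = self.n_wt + self.n_edit + self.n_indel
        return None if total == 0 else 100.0 * self.n_indel / total


def classify_amplicon_reads(
    reads: Iterable[str] | str | Path,
    wt_window: str,
    edited_window: str,
    anchors: tuple[str, str] | None = None,
) -> AmpliconCounts:
    """Exact-match classification of genome amplicon reads.

    A read is a precise edit if it contains ``edited_window``, wild type if
    it contains ``wt_window`` (reverse complement tried for both). Reads
    containing both ``anchors`` (default: the outer 8-mers of the wild-type
    window) but neither window are indel/other; anything else is
    unclassified. Both the literal edit/WT ratio and the edit percentage of
    classified reads are reported.
    """
    if len(wt_window) != len(edited_window):
        raise QuantifyError("windows must have equal length")
    if anchors is None:
        k = min(8, len(wt_window) // 2)
        anchors = (wt_window[:k], wt_window[-k:])
    left, right = anchors
    n_wt = n_edit = n_indel = n_un = 0
    for read in _reads_iter(reads):
        orientations = (read, revcomp(read))
        if any(edited_window in r for r in orientations):
            cls = "edit"
        elif any(wt_window in r for r in orientations):
            cls = "wt"
        elif any(left in r and right in r for r in orientations):
            cls = "indel"
        else:
            cls = "unclassified"
        if cls == "wt":
            n_wt += 1
        elif cls == "edit":
            n_edit += 1
        elif cls == "indel":
            n_indel += 1
        else:
            n_un += 1
    return AmpliconCounts(n_wt=n_wt, n_edit=n_edit, n_indel=n_indel, n_unclassified=n_un)


def inverse_normal_transform(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform, z_i = Φ⁻¹((r_i − c)/(n + 1 − 2c)).

    The default offset c = 3/8 is the Blom variant; ties receive average
    ranks. NaNs pass through as NaN.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    vals = arr[finite]
    if vals.size < 2:
        raise QuantifyError("inverse normal transform needs >= 2 finite values")
    if np.all(vals == vals[0]):
        raise QuantifyError("all values identical; transform undefined")
    ranks = stats.rankdata(vals, method="average")
    z = stats.norm.ppf((ranks - offset) / (vals.size + 1 - 2 * offset))
    out = np.full(arr.shape, np.nan)
    out[finite] = z
    return out
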