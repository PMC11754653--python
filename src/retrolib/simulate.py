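"""Synthetic pooled-library experiments with planted ground truth.

Everything the quantification and modelling stages consume can be generated
here with known truth: a self-consistent synthetic ncRNA annotation, a
per-position msDNA tolerance landscape, multiplicative editron axis effects,
multinomial sequencing counts with lognormal replicate jitter, and FASTQ
reads with anchored barcodes. Parameter recovery against these planted
values is how the pipeline is tested end to end; no external data needed.

Defaults mirror the directions seen in pooled retron experiments (target
strand donors ≈50% of non-target, short 54-nt donors ≈10% of 94-nt ones,
PAM-proximal −8 cuts ≈130% of centered cuts, intolerant positions around
the priming guanosine and the P3 loop) — they are planted truths for
recovery tests, not asserted facts about any particular dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from retrolib.annotation import RetronAnnotation, revcomp
from retrolib.design import (
    BASES,
    EditingSite,
    EditronDesign,
    PamSite,
    Variant,
    attach_barcode,
    cut_position,
    p4_gc_series,
    pseudo_wt_control,
    random_barcodes,
    single_substitutions,
)
from retrolib.edits import Edit
from retrolib.quantify import CountTable


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Synthetic annotation
# ---------------------------------------------------------------------------


def synthetic_annotation(seed: int = 0) -> RetronAnnotation:
    """A self-consistent synthetic retron ncRNA annotation.

    Layout (5'→3'): a1 — priming G — P2 stem-loop — P3 stem-loop (loop
    carries the TTT RT motif) — spacer — P4 stem-loop — a2 (reverse
    complement of a1). msr spans the priming G through P3; msd spans P4.
    All stem arms are perfectly paired; every structural invariant of a real
    annotation holds, so the fixture exercises the same validation paths.
    """
    rng = np.random.default_rng(seed)

    def rand(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n))

    a1 = rand(8)
    p2_5 = rand(8)
    p2_loop = rand(4)
    p3_5 = rand(6)
    p3_loop_flanks = (rand(2), rand(2))  # TTT motif sits between them
    p4_5 = rand(10)
    p4_loop = rand(8)
    spacer1, spacer2, spacer3 = rand(2), rand(2), rand(2)

    parts: list[tuple[str | None, str]] = [
        ("a1", a1),
        (None, "G"),  # priming guanosine, immediately after a1
        ("P2_5arm", p2_5),
        (None, p2_loop),
        ("P2_3arm", revcomp(p2_5)),
        (None, spacer1),
        ("P3_5arm", p3_5),
        ("P3_loop", p3_loop_flanks[0] + "TTT" + p3_loop_flanks[1]),
        ("P3_3arm", revcomp(p3_5)),
        (None, spacer2),
        ("P4_5arm", p4_5),
        ("P4_loop", p4_loop),
        ("P4_3arm", revcomp(p4_5)),
        (None, spacer3),
        ("a2", revcomp(a1)),
    ]
    seq = ""
    regions: dict[str, tuple[int, int]] = {}
    for name, chunk in parts:
        start = len(seq) + 1
        seq += chunk
        if name is not None:
            regions[name] = (start, len(seq))
    priming_g = regions["a1"][1] + 1
    regions["msr"] = (priming_g, regions["P3_3arm"][1])
    regions["msd"] = (regions["P4_5arm"][0] - len(spacer2), regions["a2"][1])
    motif_start = regions["P3_loop"][0] + len(p3_loop_flanks[0])
    return RetronAnnotation(
        ncrna_seq=seq,
        regions=regions,
        priming_g_pos=priming_g,
        rt_motif_interval=(motif_start, motif_start + 2),
    )


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthModel:
    """Planted truths for simulation: an msDNA tolerance landscape and
    multiplicative editron axis effects.

    position_weights: per-ncRNA-position msDNA tolerance (1 = fully
    tolerated, ~0 = intolerant); a variant's production multiplies the
    weights of the positions its edits touch, times a per-class multiplier,
    times a GC term ``exp(gc_coeff · (GC% − wt GC%))`` for re-randomized P4
    stems. Editron effects are per-axis-level multiplicative factors on the
    genome-editing probability. noise_sigma: lognormal replicate jitter on
    true proportions. nonworking_fraction: share of designs planted dead
    (factor 0). baseline_edit_rate: overall fraction of genome reads that
    carry any barcode (1.0 = all).
    """

    position_weights: np.ndarray
    class_multipliers: dict = field(
        default_factory=lambda: {"deletion": 0.6, "insertion": 0.75}
    )
    gc_coeff: float = -0.015
    wt_gc_percent: float = 50.0
    strand_effects: dict = field(
        default_factory=lambda: {"non_target": 1.0, "target": 0.5}
    )
    length_effects: dict = field(
        default_factory=lambda: {54: 0.1, 64: 0.4, 78: 0.7, 94: 1.0, 112: 1.3}
    )
    cut_effects: dict = field(
        default_factory=lambda: {-16: 0.40, -8: 1.30, 0: 1.0, 8: 0.65, 16: 0.45}
    )
    center_effects: dict = field(
        default_factory=lambda: {-20: 0.6, -10: 0.9, 0: 1.0, 10: 0.9, 20: 0.6}
    )
    chassis_effects: dict = field(default_factory=dict)
    noise_sigma: float = 0.1
    nonworking_fraction: float = 0.2
    baseline_edit_rate: float = 1.0

    def production(self, variant: Variant, ann: RetronAnnotation) -> float:
        """Planted msDNA production of a variant (wild type = 1.0)."""
        w = self.position_weights
        wt = ann.ncrna_seq
        value = float(self.class_multipliers.get(variant.var_class, 1.0))
        # positions are tracked in wild-type coordinates via the edit list,
        # which is applied left to right on the evolving sequence; for the
        # enumerators used here each edit addresses near-wild-type coords.
        for e in variant.edits:
            if e.kind == "substitution":
                for j, base in enumerate(e.bases):
                    pos = e.pos + j
                    if pos <= len(wt) and wt[pos - 1] != base:
                        value *= float(w[pos - 1])
            elif e.kind == "deletion":
                for pos in range(e.pos, e.pos + e.length):
                    if pos <= len(wt):
                        value *= float(w[pos - 1])
            elif e.kind == "insertion":
                pos = min(max(e.pos, 1), len(wt))
                ls, le = ann.region("P4_loop")
                if not (ls <= pos <= le):  # P4-loop barcodes are cost-free
                    value *= float(w[pos - 1])
        gc = variant.params.get("gc_percent")
        if gc is not None:
            value *= float(np.exp(self.gc_coeff * (gc - self.wt_gc_percent)))
        return value

    def editron_effect(self, design: EditronDesign) -> float:
        return (
            float(self.strand_effects.get(design.donor_strand, 1.0))
            * float(self.length_effects.get(design.donor_length, 1.0))
            * float(self.cut_effects.get(design.cut_offset, 1.0))
            * float(self.center_effects.get(design.donor_center_offset, 1.0))
            * float(self.chassis_effects.get(design.chassis_id, 1.0))
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["position_weights"] = [float(x) for x in self.position_weights]
        return d


def default_ground_truth(ann: RetronAnnotation, **overrides) -> GroundTruthModel:
    """Tolerance landscape shaped like a retron ncRNA's: tolerant stems P2/P4
    and loops, intolerant priming guanosine, P3 loop/RT motif and a2 flank."""
    L = len(ann.ncrna_seq)
    w = np.ones(L)

    def set_region(name: str, value: float) -> None:
        s, e = ann.region(name)
        w[s - 1 : e] = value

    set_region("a1", 0.4)
    set_region("P2_5arm", 0.7)
    set_region("P2_3arm", 0.7)
    set_region("P3_5arm", 0.3)
    set_region("P3_3arm", 0.3)
    set_region("P3_loop", 0.1)
    ms, me = ann.rt_motif_interval
    w[ms - 1 : me] = 0.02
    g = ann.priming_g_pos
    w[max(0, g - 3) : min(L, g + 2)] = 0.05
    # msd bases flanking a2 are poorly tolerated
    a2s, _ = ann.region("a2")
    w[max(0, a2s - 6) : a2s - 1] = 0.2
    s5, e5 = ann.region("P4_5arm")
    arm = ann.ncrna_seq[s5 - 1 : e5]
    wt_gc = 100.0 * sum(b in "GC" for b in arm) / len(arm)
    return GroundTruthModel(position_weights=w, wt_gc_percent=wt_gc, **overrides)


# ---------------------------------------------------------------------------
# Experiment container
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    manifest: pd.DataFrame
    table: CountTable
    ground_truth: dict
    seed: int

    def dump_ground_truth(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=float)


def _jitter(props: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma <= 0:
        return props
    jit = props * rng.lognormal(0.0, sigma, size=props.size)
    return jit / jit.sum()


# ---------------------------------------------------------------------------
# msDNA production counts
# ---------------------------------------------------------------------------


def simulate_msdna_counts(
    library: Sequence[Variant],
    model: GroundTruthModel,
    ann: RetronAnnotation,
    depth: int = 10**6,
    n_replicates: int = 3,
    seed: int = 0,
) -> SimulatedExperiment:
    """Multinomial plasmid_pre/plasmid_post/msdna counts for an ncRNA library.

    Each replicate gets its own lognormal-jittered plasmid composition; the
    msDNA sample draws with probabilities ∝ plasmid proportion × planted
    production. The library should include the wild-type (or barcoded
    pseudo-wild-type) normalizer, whose planted production is 1.0.
    """
    if not library:
        raise SimulationError("library is empty")
    if depth < 1:
        raise SimulationError("depth must be positive")
    rng = np.random.default_rng(seed)
    ids = [v.variant_id for v in library]
    if len(set(ids)) != len(ids):
        raise SimulationError("duplicate variant_ids in library")
    production = np.array([model.production(v, ann) for v in library])
    base = np.full(len(library), 1.0 / len(library))
    counts = {}
    samples = {}
    for r in range(1, n_replicates + 1):
        props = _jitter(base, model.noise_sigma, rng)
        ms = props * production
        if ms.sum() == 0:
            raise SimulationError("all planted productions are zero")
        ms = ms / ms.sum()
        for role, p in (
            ("plasmid_pre", props),
            ("plasmid_post", props),
            ("msdna", ms),
        ):
            name = f"rep{r}_{role}"
            counts[name] = rng.multinomial(depth, p)
            samples[name] = {"role": role, "replicate": f"rep{r}", "site": "ecoli"}
    table = CountTable(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="variant_id")),
        samples=pd.DataFrame(samples).T.rename_axis("sample"),
    )
    manifest = pd.DataFrame(
        {
            "variant_id": ids,
            "var_class": [v.var_class for v in library],
            "barcode": [v.barcode for v in library],
            "sequence": [v.sequence for v in library],
            "true_production": production,
        }
    )
    gt = {
        "kind": "msdna",
        "seed": seed,
        "depth": depth,
        "true_production": dict(zip(ids, map(float, production))),
        "model": model.to_dict(),
    }
    return SimulatedExperiment(manifest=manifest, table=table, ground_truth=gt, seed=seed)


# ---------------------------------------------------------------------------
# Editing counts
# ---------------------------------------------------------------------------


def simulate_editing_counts(
    designs: Sequence[EditronDesign],
    model: GroundTruthModel,
    depth: int = 10**6,
    n_replicates: int = 3,
    seed: int = 0,
) -> SimulatedExperiment:
    """Multinomial plasmid t0/t24/t48 and genome_t48 counts for editron designs.

    Plasmid composition is stable over the time course (each time point is
    an independent multinomial around the same jittered proportions); the
    genome sample draws with probabilities ∝ plasmid proportion × the
    product of planted axis factors. A seeded ``nonworking_fraction`` of
    designs is planted dead (factor 0) per site.
    """
    if not designs:
        raise SimulationError("no designs")
    if depth < 1:
        raise SimulationError("depth must be positive")
    rng = np.random.default_rng(seed)
    sites = sorted({d.site_id for d in designs})
    counts = {}
    samples = {}
    effects = {}
    working = {}
    index = [d.barcode for d in designs]
    if len(set(index)) != len(index):
        raise SimulationError("duplicate barcodes across designs")
    for d in designs:
        eff = model.editron_effect(d)
        alive = rng.random() >= model.nonworking_fraction
        working[d.barcode] = bool(alive) and eff > 0
        effects[d.barcode] = eff if working[d.barcode] else 0.0
    for site in sites:
        site_designs = [d for d in designs if d.site_id == site]
        bcs = [d.barcode for d in site_designs]
        eff = np.array([effects[b] for b in bcs])
        base = np.full(len(bcs), 1.0 / len(bcs))
        for r in range(1, n_replicates + 1):
            props = _jitter(base, model.noise_sigma, rng)
            genome_p = props * eff * model.baseline_edit_rate
            if genome_p.sum() == 0:
                raise SimulationError("no working designs at site " + site)
            unedited = max(0.0, 1.0 - model.baseline_edit_rate)
            genome_p = genome_p / genome_p.sum() * (1.0 - unedited)
            full = np.append(genome_p, unedited)
            draws = {
                "plasmid_t0": rng.multinomial(depth, props),
                "plasmid_t24": rng.multinomial(depth, props),
                "plasmid_t48": rng.multinomial(depth, props),
                "genome_t48": rng.multinomial(depth, full / full.sum())[:-1],
            }
            for role, vec in draws.items():
                name = f"{site}_rep{r}_{role}"
                col = pd.Series(0, index=index, dtype=np.int64)
                col.loc[bcs] = vec
                counts[name] = col
                samples[name] = {"role": role, "replicate": f"rep{r}", "site": site}
    table = CountTable(
        counts=pd.DataFrame(counts, index=pd.Index(index, name="variant_id")),
        samples=pd.DataFrame(samples).T.rename_axis("sample"),
    )
    manifest = pd.DataFrame(
        [
            {
                "variant_id": d.barcode,
                "design_id": d.design_id,
                "barcode": d.barcode,
                **d.axis_labels(),
                "true_effect": effects[d.barcode],
                "working": working[d.barcode],
            }
            for d in designs
        ]
    )
    gt = {
        "kind": "editing",
        "seed": seed,
        "depth": depth,
        "true_effects": {k: float(v) for k, v in effects.items()},
        "model": model.to_dict(),
    }
    return SimulatedExperiment(manifest=manifest, table=table, ground_truth=gt, seed=seed)


# ---------------------------------------------------------------------------
# Editing sites
# ---------------------------------------------------------------------------


def make_editing_site(
    seed: int = 0,
    cut_offsets: Sequence[int] = (-16, -8, 0, 8, 16),
    length: int = 300,
    site_id: str = "site1",
) -> EditingSite:
    """A random locus with PAMs planted so every cut offset is achievable.

    Negative offsets get their PAM on the minus strand and non-negative on
    the plus strand, giving roughly symmetric PAMs around the insertion
    point (which is placed at the locus midpoint).
    """
    rng = np.random.default_rng(seed)
    ip = length // 2
    plan: dict[int, str] = {}  # 0-based index -> base

    def plant(idx0: int, base: str) -> None:
        if idx0 < 0 or idx0 >= length:
            raise SimulationError(
                f"cut offset requires PAM beyond locus bounds (index {idx0})"
            )
        if plan.get(idx0, base) != base:
            raise SimulationError("conflicting PAM plants; offsets unplantable together")
        plan[idx0] = base

    pams = []
    for off in cut_offsets:
        if off < 0:
            t = ip + off - 5  # CCN PAM start, 1-based
            plant(t - 1, "C")
            plant(t, "C")
            if t + 22 > length:
                raise SimulationError("protospacer beyond locus 3' end")
            pams.append(PamSite(cut_offset=off, strand="-", pam_start=t))
        else:
            q = ip + off + 4  # NGG PAM start, 1-based
            plant(q, "G")
            plant(q + 1, "G")
            if q - 21 < 0:
                raise SimulationError("protospacer beyond locus 5' end")
            pams.append(PamSite(cut_offset=off, strand="+", pam_start=q))
    locus = rng.choice(list(BASES), size=length)
    for idx0, base in plan.items():
        locus[idx0] = base
    return EditingSite(
        site_id=site_id,
        locus_seq="".join(locus),
        insertion_point=ip,
        pams=pams,
    )


# ---------------------------------------------------------------------------
# Chassis
# ---------------------------------------------------------------------------


def default_chassis_catalog(
    ann: RetronAnnotation, n: int = 25, seed: int = 0
) -> "ChassisCatalog":
    """A chassis panel shaped like a pooled editing study's: the wild type,
    a1/a2 duplex extensions (23/27 bp), P4 stem-length variants (+2/−2
    pairs), a single-base deletion and two point substitutions at tolerated
    positions, padded with random 'ML-proposed' P4-loop re-randomizations.

    Structural variants are emitted as sequences with documented overrides
    (coordinates are not remapped for non-wild-type entries).
    """
    from retrolib.annotation import ChassisCatalog, ChassisEntry

    rng = np.random.default_rng(seed)
    wt = ann.ncrna_seq

    def rand(k: int) -> str:
        return "".join(rng.choice(list(BASES), size=k))

    entries = [
        ChassisEntry("wild_type", wt, "unmodified ncRNA", annotation=ann),
    ]
    for k in (23, 27):
        ext = rand(k)
        entries.append(
            ChassisEntry(
                f"a1a2_ext{k}",
                ext + wt + revcomp(ext),
                f"a1/a2 duplex extended by {k} bp",
                overrides=("coordinates shifted by extension",),
            )
        )
    s5, e5 = ann.region("P4_5arm")
    s3, e3 = ann.region("P4_3arm")
    add = rand(2)
    longer = wt[: s5 - 1] + add + wt[s5 - 1 : e3] + revcomp(add) + wt[e3:]
    shorter = wt[: s5 - 1] + wt[s5 + 1 : e3 - 2] + wt[e3:]
    entries.append(
        ChassisEntry("p4_plus2", longer, "P4 stem lengthened by 2 bp", overrides=("P4 resized",))
    )
    entries.append(
        ChassisEntry("p4_minus2", shorter, "P4 stem shortened by 2 bp", overrides=("P4 resized",))
    )
    # single-base deletion and two substitutions at tolerated positions
    # (the spacer 3' of P4)
    sp = e3 + 1
    if sp <= len(wt):
        entries.append(
            ChassisEntry(
                f"del{sp}", wt[: sp - 1] + wt[sp:], f"deletion at position {sp}",
                overrides=("length change",),
            )
        )
    ls, le = ann.region("P4_loop")
    for pos in (ls, ls + 1):
        ref = wt[pos - 1]
        alt = next(b for b in BASES if b != ref)
        entries.append(
            ChassisEntry(
                f"{ref}{pos}{alt}",
                wt[: pos - 1] + alt + wt[pos:],
                f"{ref}{pos}{alt} substitution",
            )
        )
    i = 0
    while len(entries) < n:
        i += 1
        loop = rand(le - ls + 1)
        seq = wt[: ls - 1] + loop + wt[le:]
        if seq != wt:
            entries.append(
                ChassisEntry(f"ml_{i}", seq, "model-proposed P4 loop re-randomization")
            )
    return ChassisCatalog(entries=entries[:n])


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadLayout:
    """Anchored amplicon layout: flank5 + 10-nt barcode + flank3."""

    flank5: str = "TCGATCGGTACA"
    flank3: str = "AGGTCCATGCTT"


def emit_reads(
    experiment: SimulatedExperiment,
    layout: ReadLayout = ReadLayout(),
    error_rate: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write per-sample FASTQ files reproducing the experiment's counts.

    Each read is flank5 + barcode + flank3; uniform substitution errors at
    ``error_rate`` are applied to the variable insert (the flanks are
    primer-derived and emitted as synthesized). With error_rate 0,
    re-counting the FASTQ with ``extract_barcodes`` reproduces the source
    count table exactly.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    barcode_of = dict(
        zip(experiment.manifest["variant_id"], experiment.manifest["barcode"])
    )
    paths = {}
    base_arr = np.frombuffer(b"ACGT", dtype="S1")
    for sample in experiment.table.counts.columns:
        col = experiment.table.counts[sample]
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        inserts = []
        for vid, count in col.items():
            if count <= 0:
                continue
            bc = barcode_of.get(vid)
            if not isinstance(bc, str):
                raise SimulationError(f"variant {vid!r} has no barcode in the manifest")
            inserts.extend([bc] * int(count))
        if inserts:
            mat = np.frombuffer("".join(inserts).encode(), dtype="S1").reshape(
                len(inserts), -1
            )
            if error_rate > 0:
                mat = mat.copy()
                idx = {b: i for i, b in enumerate(base_arr)}
                codes = np.vectorize(idx.get)(mat)
                hit = rng.random(mat.shape) < error_rate
                shift = rng.integers(1, 4, size=mat.shape)
                codes = np.where(hit, (codes + shift) % 4, codes)
                mat = base_arr[codes]
            bodies = [b"".join(row).decode() for row in mat]
        else:
            bodies = []
        opener = __import__("gzip").open if gzip_output else open
        with opener(path, "wt") as fh:
            for i, body in enumerate(bodies):
                seq = layout.flank5 + body + layout.flank3
                fh.write(f"@{sample}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths


# ---------------------------------------------------------------------------
# Activity datasets for the regressor
# ---------------------------------------------------------------------------


def simulate_activity_dataset(
    ann: RetronAnnotation,
    n_variants: int = 3000,
    model: GroundTruthModel | None = None,
    noise_sigma: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Designed variants with planted activities for model training.

    The mixture is length-preserving (random multi-substitutions, all single
    substitutions, re-randomized P4 GC stems) so the sequence→activity map
    stays positionally stable. activity = planted production × lognormal
    noise; the planted production is retained for recovery scoring.
    """
    if n_variants < 50:
        raise SimulationError("n_variants must be >= 50")
    if model is None:
        model = default_ground_truth(ann)
    rng = np.random.default_rng(seed)
    wt = ann.ncrna_seq
    L = len(wt)

    variants: list[Variant] = list(single_substitutions(ann))
    n_gc = max(10, int(0.2 * n_variants))
    variants.extend(
        p4_gc_series(ann, n_per_bin=max(1, n_gc // 10), seed=int(rng.integers(2**31)))
    )
    while len(variants) < n_variants:
        k = int(rng.integers(1, 5))
        positions = sorted(rng.choice(L, size=k, replace=False) + 1)
        edits = []
        for pos in positions:
            ref = wt[pos - 1]
            alt = rng.choice([b for b in BASES if b != ref])
            edits.append(Edit("substitution", int(pos), bases=str(alt)))
        seq = wt
        for e in edits:
            seq = e.apply(seq)
        variants.append(
            Variant(
                variant_id=f"rand_{len(variants)}",
                var_class="substitution",
                sequence=seq,
                params={"positions": [int(p) for p in positions]},
                edits=edits,
            )
        )
    variants = variants[:n_variants]
    production = np.array([model.production(v, ann) for v in variants])
    noise = rng.lognormal(0.0, noise_sigma, size=len(variants)) if noise_sigma > 0 else 1.0
    activity = production * noise
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "var_class": [v.var_class for v in variants],
            "sequence": [v.sequence for v in variants],
            "gc_percent": [v.params.get("gc_percent", np.nan) for v in variants],
            "true_production": production,
            "activity": 100.0 * activity,
        }
    )
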