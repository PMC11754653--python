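"""Retron ncRNA sequence + structural annotation.

The retron ncRNA is the coordinate system for everything else in the package:
variant enumeration, barcode placement and the simulator's tolerance
landscape all address positions on it. Coordinates are 1-based closed
intervals on the ncRNA read 5'→3', matching how positions are named in the
retron literature ("deletion at position 139", "C144T"). Sequences are
stored in the DNA alphabet; RNA input is converted transparently (U→T),
since all downstream counting operates on DNA sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml
from Bio.Seq import Seq

#: region names every annotation must declare
REQUIRED_REGIONS = (
    "msr",
    "msd",
    "a1",
    "a2",
    "P2_5arm",
    "P2_3arm",
    "P3_5arm",
    "P3_3arm",
    "P3_loop",
    "P4_5arm",
    "P4_3arm",
    "P4_loop",
)

#: the stems whose two arms must be reverse-complementary in the wild type
STEMS = ("P2", "P3", "P4")

WT_RT_MOTIF = "TTT"  # UUU on the RNA; the Eco1 RT recognition motif in the P3 loop

DNA = set("ACGT")


class AnnotationError(ValueError):
    """Raised when an annotation violates a structural invariant."""


def as_dna(seq: str) -> str:
    """Uppercase and convert RNA (U) to the stored DNA alphabet (T)."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - DNA
    if bad:
        raise AnnotationError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class RetronAnnotation:
    """An ncRNA sequence with named structural regions.

    Parameters
    ----------
    ncrna_seq:
        The ncRNA, DNA-encoded, 5'→3'.
    regions:
        name → (start, end), 1-based closed intervals.
    priming_g_pos:
        1-based position of the conserved priming guanosine (the branching
        point of the 2'–5' msDNA linkage), immediately after the a1 region.
    rt_motif_interval:
        3-nt closed interval inside the P3 loop holding the RT recognition
        motif (UUU in the wild type).
    """

    ncrna_seq: str
    regions: dict[str, tuple[int, int]]
    priming_g_pos: int
    rt_motif_interval: tuple[int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ncrna_seq", as_dna(self.ncrna_seq))
        self.validate()

    # -- accessors ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.ncrna_seq)

    def region(self, name: str) -> tuple[int, int]:
        try:
            return self.regions[name]
        except KeyError:
            raise AnnotationError(f"unknown region {name!r}") from None

    def region_sequence(self, name: str) -> str:
        start, end = self.region(name)
        return self.ncrna_seq[start - 1 : end]

    def stem_arm_length(self, stem: str) -> int:
        s, e = self.region(f"{stem}_5arm")
        return e - s + 1

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        L = len(self.ncrna_seq)
        if L == 0:
            raise AnnotationError("empty ncRNA sequence")
        for name in REQUIRED_REGIONS:
            if name not in self.regions:
                raise AnnotationError(f"missing required region {name!r}")
        for name, (start, end) in self.regions.items():
            if not (1 <= start <= end <= L):
                raise AnnotationError(
                    f"region {name!r} interval [{start}, {end}] out of bounds for length {L}"
                )
        mr, md = self.regions["msr"], self.regions["msd"]
        if not (mr[1] < md[0] or md[1] < mr[0]):
            raise AnnotationError("msr and msd overlap")
        for stem in STEMS:
            five = self.region_sequence(f"{stem}_5arm")
            three = self.region_sequence(f"{stem}_3arm")
            if len(five) != len(three):
                raise AnnotationError(
                    f"{stem} arms differ in length ({len(five)} vs {len(three)})"
                )
            if revcomp(five) != three:
                raise AnnotationError(f"{stem} arms are not reverse-complementary")
        if not (1 <= self.priming_g_pos <= L):
            raise AnnotationError("priming position out of bounds")
        if self.ncrna_seq[self.priming_g_pos - 1] != "G":
            raise AnnotationError(
                f"priming base not G (found {self.ncrna_seq[self.priming_g_pos - 1]!r} "
                f"at position {self.priming_g_pos})"
            )
        ms, me = self.rt_motif_interval
        ls, le = self.region("P3_loop")
        if me - ms != 2:
            raise AnnotationError("rt_motif_interval must span exactly 3 nt")
        if not (ls <= ms and me <= le):
            raise AnnotationError("rt_motif_interval not inside P3_loop")
        motif = self.ncrna_seq[ms - 1 : me]
        if motif != WT_RT_MOTIF:
            raise AnnotationError(
                f"wild-type RT motif must be {WT_RT_MOTIF} (UUU), found {motif}"
            )

    def with_sequence(self, seq: str) -> "RetronAnnotation":
        """Same coordinates on a different (same-length) sequence; revalidates."""
        return replace(self, ncrna_seq=seq)


def region_sequence(ann: RetronAnnotation, name: str) -> str:
    """Substring of the ncRNA for the named region (1-based closed interval)."""
    return ann.region_sequence(name)


def load_annotation(config_path: str | Path) -> RetronAnnotation:
    """Load and validate an annotation from a YAML config.

    Expected keys: ``seq`` (string), ``regions`` (name → [start, end]),
    ``priming_g_pos`` (int), ``rt_motif_start`` (int).
    """
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    for key in ("seq", "regions", "priming_g_pos", "rt_motif_start"):
        if key not in cfg:
            raise AnnotationError(f"annotation config missing key {key!r}")
    regions = {str(k): (int(v[0]), int(v[1])) for k, v in cfg["regions"].items()}
    start = int(cfg["rt_motif_start"])
    return RetronAnnotation(
        ncrna_seq=str(cfg["seq"]),
        regions=regions,
        priming_g_pos=int(cfg["priming_g_pos"]),
        rt_motif_interval=(start, start + 2),
    )


def dump_annotation(ann: RetronAnnotation, path: str | Path) -> None:
    cfg = {
        "seq": ann.ncrna_seq,
        "regions": {k: [int(v[0]), int(v[1])] for k, v in ann.regions.items()},
        "priming_g_pos": int(ann.priming_g_pos),
        "rt_motif_start": int(ann.rt_motif_interval[0]),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


@dataclass
class ChassisEntry:
    chassis_id: str
    ncrna_seq: str
    description: str = ""
    #: annotation for this chassis, or None when coordinates are not remapped
    annotation: RetronAnnotation | None = None
    #: names of invariants this entry is documented to deviate from
    overrides: tuple[str, ...] = ()


@dataclass
class ChassisCatalog:
    """Named ncRNA scaffold variants used as carriers for editron cargo."""

    entries: list[ChassisEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.chassis_id for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AnnotationError(f"duplicate chassis ids: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ChassisEntry]:
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [e.chassis_id for e in self.entries]

    def get(self, chassis_id: str) -> ChassisEntry:
        for e in self.entries:
            if e.chassis_id == chassis_id:
                return e
        raise KeyError(chassis_id)
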