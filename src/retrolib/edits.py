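"""Primitive sequence edits with coordinate mapping.

Every designed variant records the edit that produces it from the wild-type
sequence, so libraries can be re-validated by an independent apply step and
annotation intervals can be mapped through length-changing edits.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Edit:
    """A single edit on a 1-based sequence.

    kind:
        ``substitution`` — replace ``length`` bases starting at ``pos`` with
        ``bases`` (same length); ``deletion`` — remove ``length`` bases
        starting at ``pos``; ``insertion`` — insert ``bases`` after position
        ``pos`` (``pos`` = 0 prepends).
    """

    kind: str
    pos: int
    length: int = 0
    bases: str = ""

    def apply(self, seq: str) -> str:
        if self.kind == "substitution":
            if not (1 <= self.pos and self.pos + len(self.bases) - 1 <= len(seq)):
                raise ValueError("substitution window out of bounds")
            return seq[: self.pos - 1] + self.bases + seq[self.pos - 1 + len(self.bases) :]
        if self.kind == "deletion":
            if not (1 <= self.pos and self.pos + self.length - 1 <= len(seq)):
                raise ValueError("deletion window out of bounds")
            return seq[: self.pos - 1] + seq[self.pos - 1 + self.length :]
        if self.kind == "insertion":
            if not (0 <= self.pos <= len(seq)):
                raise ValueError("insertion point out of bounds")
            return seq[: self.pos] + self.bases + seq[self.pos :]
        raise ValueError(f"unknown edit kind {self.kind!r}")

    def map_position(self, p: int) -> int | None:
        """Map a 1-based position through the edit; None if deleted."""
        if self.kind == "substitution":
            return p
        if self.kind == "deletion":
            if p < self.pos:
                return p
            if p < self.pos + self.length:
                return None
            return p - self.length
        if self.kind == "insertion":
            return p if p <= self.pos else p + len(self.bases)
        raise ValueError(self.kind)

    def map_interval(self, interval: tuple[int, int]) -> tuple[int, int] | None:
        """Map a closed interval; None if it is entirely deleted."""
        start, end = interval
        if self.kind == "deletion":
            cut_lo, cut_hi = self.pos, self.pos + self.length - 1
            if start < cut_lo:
                ms = start
            elif start <= cut_hi:
                ms = cut_lo  # clamp to first base after the deleted window
            else:
                ms = start - self.length
            if end < cut_lo:
                me = end
            elif end <= cut_hi:
                me = cut_lo - 1  # clamp to last base before the deleted window
            else:
                me = end - self.length
            return None if ms > me else (ms, me)
        ms = self.map_position(start)
        me = self.map_position(end)
        assert ms is not None and me is not None
        return (ms, me)


def apply_edits(seq: str, edits: list[Edit]) -> str:
    """Apply edits left to right; each edit's coordinates refer to the
    sequence as modified by the previous ones."""
    for e in edits:
        seq = e.apply(seq)
    return seq
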