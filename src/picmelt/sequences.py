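"""Promoter sequences with TSS-relative numbering.

Promoter positions are numbered relative to the transcription start site
(TSS) with no position 0: …, −2, −1, +1, +2, ….  All intervals expressed
in TSS-relative coordinates are half-open ``[start, stop)`` in that
numbering (so the 15-base window −9…+7 is written ``(-9, 7)`` and skips
the nonexistent 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
VALID_BASES = frozenset(COMPLEMENT)


def complement(seq: str) -> str:
    """Watson–Crick complement (same orientation, not reversed)."""
    try:
        return "".join(COMPLEMENT[b] for b in seq)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    return complement(seq)[::-1]


def is_wc_pair(a: str, b: str) -> bool:
    return COMPLEMENT.get(a) == b


@dataclass
class PromoterSequence:
    """A promoter duplex with TSS-relative numbering.

    ``template_strand`` and ``non_template_strand`` are both stored 5'→3'.
    Position ``i`` (0-based array index) of the template strand pairs with
    position ``L-1-i`` of the non-template strand.  ``tss_index`` is the
    0-based array index on the *template* strand corresponding to the +1
    site.  ``mismatch_region`` and ``annotations`` are half-open intervals
    in TSS-relative coordinates.
    """

    template_strand: str
    non_template_strand: str
    tss_index: int = 0
    mismatch_region: Optional[Tuple[int, int]] = None
    annotations: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        t, n = self.template_strand.upper(), self.non_template_strand.upper()
        if len(t) != len(n):
            raise ValueError("strands must have equal length")
        bad = set(t + n) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases: {sorted(bad)}")
        self.template_strand, self.non_template_strand = t, n
        mm = set(self.mismatch_positions())
        for i in range(len(t)):
            if i in mm:
                continue
            if not is_wc_pair(t[i], n[len(t) - 1 - i]):
                raise ValueError(
                    f"non-complementary pair at template index {i} "
                    "outside the mismatch region")

    def __len__(self) -> int:
        return len(self.template_strand)

    # --- TSS-relative coordinate helpers -------------------------------
    def tss_to_index(self, pos: int) -> int:
        """Template-strand array index for a TSS-relative position."""
        if pos == 0:
            raise ValueError("TSS-relative numbering has no position 0")
        idx = self.tss_index + pos - (1 if pos > 0 else 0)
        if not 0 <= idx < len(self):
            raise IndexError(f"position {pos:+d} outside the promoter")
        return idx

    def index_to_tss(self, idx: int) -> int:
        off = idx - self.tss_index
        return off + 1 if off >= 0 else off

    def interval_indices(self, start: int, stop: int) -> list:
        """Template indices covered by the half-open TSS interval
        [start, stop), skipping position 0."""
        return [self.tss_to_index(p)
                for p in range(start, stop) if p != 0]

    def mismatch_positions(self) -> list:
        if self.mismatch_region is None:
            return []
        return self.interval_indices(*self.mismatch_region)

    # --- construction ---------------------------------------------------
    @classmethod
    def from_template(cls, template: str, tss_index: int = 0,
                      **kw) -> "PromoterSequence":
        """Build a fully complementary duplex from the template strand."""
        return cls(template, reverse_complement(template),
                   tss_index=tss_index, **kw)

    @classmethod
    def random(cls, length: int, seed: int, tss_index: Optional[int] = None,
               **kw) -> "PromoterSequence":
        import numpy as np
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("ACGT"), size=length))
        if tss_index is None:
            tss_index = length // 2
        return cls.from_template(template, tss_index=tss_index, **kw)

    # --- plain-text IO (two lines: template, non-template) --------------
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.template_strand + "\n")
            fh.write(self.non_template_strand + "\n")

    @classmethod
    def from_file(cls, path, tss_index: int = 0, **kw) -> "PromoterSequence":
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        if len(lines) < 2:
            raise ValueError("sequence file needs two lines "
                             "(template, non-template)")
        return cls(lines[0], lines[1], tss_index=tss_index, **kw)
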