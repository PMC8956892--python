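"""STR allele designations.

A Y-STR allele is named by its repeat count, with micro-variant alleles
carrying a fractional suffix counting extra bases beyond complete repeat
units ("24.1" = 24 repeats plus one base).  The suffix digit is the number
of extra bases, so ".15" is not a valid designation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["AlleleCall", "MalformedAlleleError"]

_ALLELE_RE = re.compile(r"^(\d{1,2})(?:\.(\d))?$")


class MalformedAlleleError(ValueError):
    """Raised for allele text that is not a valid STR designation."""


@dataclass(frozen=True, order=True)
class AlleleCall:
    """One STR allele: complete repeat units plus optional extra bases.

    Ordering is lexicographic on (repeats, variant), so 22 < 22.1 < 23.
    """

    repeats: int
    variant: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.repeats <= 99):
            raise MalformedAlleleError(f"repeat count out of range: {self.repeats}")
        if not (0 <= self.variant <= 9):
            raise MalformedAlleleError(f"micro-variant digit out of range: {self.variant}")

    @property
    def value(self) -> float:
        """Numeric value used for repeat-length distances: repeats + variant/10."""
        return self.repeats + self.variant / 10.0

    def __str__(self) -> str:
        if self.variant:
            return f"{self.repeats}.{self.variant}"
        return str(self.repeats)

    @classmethod
    def parse(cls, text: str) -> "AlleleCall":
        """Parse an allele designation like ``"24"`` or ``"24.1"``.

        Raises :class:`MalformedAlleleError` on anything else (``"x"``,
        ``"24.15"``, ``"24.0"`` is accepted and normalises to ``"24"``).
        """
        m = _ALLELE_RE.match(text.strip())
        if m is None:
            raise MalformedAlleleError(f"malformed allele designation: {text!r}")
        return cls(int(m.group(1)), int(m.group(2) or 0))
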