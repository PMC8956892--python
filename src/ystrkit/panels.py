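"""Built-in Y-STR locus panels.

Panels are nested marker systems: the 9-locus minimal haplotype, the
12-locus PowerPlex Y set, the 17-locus Yfiler set and the 23-locus
PowerPlex Y23 set.  DYS385a/b is a duplicated locus: one locus name
("DYS385") carrying two allele calls per sample, counted as two locus
slots when sizing a panel.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "LocusPanel",
    "MINIMAL",
    "POWERPLEX_Y12",
    "YFILER17",
    "PPY23",
    "PANELS",
    "get_panel",
    "normalize_locus",
    "UnknownLocusError",
]


class UnknownLocusError(ValueError):
    """Raised when a locus name cannot be resolved against a panel."""


# Canonical names keyed by a squashed (uppercase, alphanumeric-only) form.
_ALIASES = {
    "YGATAH4": "Y-GATA-H4",
    "GATAH4": "Y-GATA-H4",
    "H4": "Y-GATA-H4",
    "DYS385AB": "DYS385",
    "DYS385": "DYS385",
    "DYS3891": "DYS389I",
    "DYS38911": "DYS389II",
}


def normalize_locus(name: str) -> str:
    """Resolve common spelling variants to canonical locus names.

    ``"Y-GATA-H4"``, ``"YGATAH4"`` and ``"y_gata_h4"`` are the same locus;
    ``DYS385a``/``DYS385b`` normalise to the shared ``DYS385`` name.
    """
    squashed = re.sub(r"[^0-9A-Z]", "", name.upper())
    if squashed in _ALIASES:
        return _ALIASES[squashed]
    m = re.match(r"^(DYS\d+)(I{1,2}|[AB])?$", squashed)
    if m:
        base, suffix = m.groups()
        if suffix in ("A", "B"):
            return base
        return base + (suffix or "")
    return name.strip()


@dataclass(frozen=True)
class LocusPanel:
    """An ordered set of Y-STR loci with multi-copy bookkeeping.

    ``loci`` names each locus once; loci in ``multi_copy`` carry two calls
    per sample and count as two slots in :attr:`n_slots`.
    """

    name: str
    loci: tuple[str, ...]
    multi_copy: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError(f"panel {self.name}: duplicate loci")
        if not self.multi_copy <= set(self.loci):
            raise ValueError(f"panel {self.name}: multi_copy loci not in panel")

    @property
    def n_slots(self) -> int:
        """Number of typed locus slots (multi-copy loci count twice)."""
        return len(self.loci) + len(self.multi_copy)

    def __contains__(self, locus: str) -> bool:
        return locus in self.loci

    def is_subpanel_of(self, other: "LocusPanel") -> bool:
        return set(self.loci) <= set(other.loci)


_MINIMAL_LOCI = (
    "DYS19",
    "DYS385",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
)

_PPY12_EXTRA = ("DYS437", "DYS438", "DYS439")
_YFILER_EXTRA = ("DYS448", "DYS456", "DYS458", "DYS635", "Y-GATA-H4")
_PPY23_EXTRA = ("DYS481", "DYS533", "DYS549", "DYS570", "DYS576", "DYS643")

_MULTI = frozenset({"DYS385"})

MINIMAL = LocusPanel("Minimal", _MINIMAL_LOCI, _MULTI)
POWERPLEX_Y12 = LocusPanel("PowerPlexY12", _MINIMAL_LOCI + _PPY12_EXTRA, _MULTI)
YFILER17 = LocusPanel("Yfiler17", _MINIMAL_LOCI + _PPY12_EXTRA + _YFILER_EXTRA, _MULTI)
PPY23 = LocusPanel(
    "PPY23", _MINIMAL_LOCI + _PPY12_EXTRA + _YFILER_EXTRA + _PPY23_EXTRA, _MULTI
)

PANELS: dict[str, LocusPanel] = {
    p.name: p for p in (MINIMAL, POWERPLEX_Y12, YFILER17, PPY23)
}


def get_panel(name: str) -> LocusPanel:
    try:
        return PANELS[name]
    except KeyError:
        raise UnknownLocusError(
            f"unknown panel {name!r}; available: {sorted(PANELS)}"
        ) from None
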