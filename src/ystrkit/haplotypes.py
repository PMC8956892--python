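"""Haplotypes and population datasets.

A haplotype is one male's multi-locus Y-STR profile.  The duplicated
DYS385a/b locus carries an unordered pair of allele calls; haplotype
identity is order-insensitive there.  Amelogenin-Y deletion status is
carried as metadata only and never enters any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Union

from .alleles import AlleleCall
from .panels import LocusPanel

__all__ = [
    "Haplotype",
    "PopulationDataset",
    "filter_complete",
    "subset_panel",
    "DatasetError",
]

Call = Union[AlleleCall, tuple[AlleleCall, AlleleCall]]


class DatasetError(ValueError):
    """Raised for structurally invalid datasets (duplicate IDs, stray loci)."""


def _norm_call(locus: str, call: Call, panel: LocusPanel) -> Call:
    multi = locus in panel.multi_copy
    if multi:
        if not (isinstance(call, tuple) and len(call) == 2):
            raise DatasetError(f"{locus} requires a pair of allele calls")
        a, b = call
        return (a, b) if a <= b else (b, a)
    if isinstance(call, tuple):
        raise DatasetError(f"{locus} is single-copy but got a pair")
    return call


@dataclass(frozen=True)
class Haplotype:
    """One sample's profile: locus → allele call (pair for DYS385)."""

    sample_id: str
    calls: Mapping[str, Call]
    amelogenin_y_deleted: bool = False
    missing_loci: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        overlap = self.missing_loci & set(self.calls)
        if overlap:
            raise DatasetError(
                f"sample {self.sample_id}: loci both called and missing: {sorted(overlap)}"
            )

    @property
    def complete(self) -> bool:
        return not self.missing_loci

    def key(self, panel: LocusPanel) -> tuple:
        """Hashable identity over the panel's loci; DYS385 pair sorted."""
        out = []
        for locus in panel.loci:
            call = self.calls.get(locus)
            if call is None:
                out.append(None)
            elif isinstance(call, tuple):
                out.append(tuple(sorted(call)))
            else:
                out.append(call)
        return tuple(out)

    def restricted_to(self, panel: LocusPanel) -> "Haplotype":
        calls = {l: c for l, c in self.calls.items() if l in panel.loci}
        missing = frozenset(l for l in self.missing_loci if l in panel.loci)
        return replace(self, calls=calls, missing_loci=missing)


@dataclass(frozen=True)
class PopulationDataset:
    """A named collection of haplotypes on a declared locus panel."""

    name: str
    panel: LocusPanel
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))
        ids = [h.sample_id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"dataset {self.name}: duplicate sample IDs {dupes}")
        panel_loci = set(self.panel.loci)
        normed = []
        for h in self.haplotypes:
            stray = (set(h.calls) | h.missing_loci) - panel_loci
            if stray:
                raise DatasetError(
                    f"sample {h.sample_id}: loci outside panel "
                    f"{self.panel.name}: {sorted(stray)}"
                )
            calls = {l: _norm_call(l, c, self.panel) for l, c in h.calls.items()}
            normed.append(replace(h, calls=calls))
        object.__setattr__(self, "haplotypes", tuple(normed))

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def n(self) -> int:
        return len(self.haplotypes)


def filter_complete(
    ds: PopulationDataset,
) -> tuple[PopulationDataset, PopulationDataset]:
    """Partition a dataset into complete profiles and partial profiles.

    A profile is complete when every panel locus has a call.  Returns
    ``(complete, excluded)``; together they hold every input haplotype
    exactly once.
    """
    panel_loci = set(ds.panel.loci)
    comp, part = [], []
    for h in ds.haplotypes:
        called = set(h.calls)
        (comp if panel_loci <= called else part).append(h)
    return (
        PopulationDataset(ds.name, ds.panel, tuple(comp)),
        PopulationDataset(f"{ds.name}_excluded", ds.panel, tuple(part)),
    )


def subset_panel(ds: PopulationDataset, target: LocusPanel) -> PopulationDataset:
    """Restrict a dataset to a sub-panel's loci.

    Each haplotype keeps only the target loci, so a profile complete on the
    larger panel is complete on the sub-panel.
    """
    if not target.is_subpanel_of(ds.panel):
        extra = sorted(set(target.loci) - set(ds.panel.loci))
        raise DatasetError(
            f"target panel {target.name} has loci absent from {ds.panel.name}: {extra}"
        )
    return PopulationDataset(
        ds.name, target, tuple(h.restricted_to(target) for h in ds.haplotypes)
    )


def concat(name: str, datasets: Iterable[PopulationDataset]) -> PopulationDataset:
    """Concatenate datasets sharing a panel, prefixing IDs to keep them unique."""
    datasets = list(datasets)
    panel = datasets[0].panel
    haps = []
    for ds in datasets:
        if ds.panel.loci != panel.loci:
            raise DatasetError("cannot concatenate datasets on different panels")
        for h in ds.haplotypes:
            haps.append(replace(h, sample_id=f"{ds.name}:{h.sample_id}"))
    return PopulationDataset(name, panel, tuple(haps))
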