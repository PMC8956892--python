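"""Forensic diversity parameters for Y-STR populations.

Per-locus parameters
--------------------
Gene diversity (Nei's unbiased estimator)::

    GD = n/(n-1) * (1 - sum_i p_i^2)

with p_i the allele frequencies and n the number of allele observations
at the locus (2N for the duplicated DYS385a/b, N otherwise).

Polymorphic information content (Botstein's form for a haploid marker)::

    PIC = 1 - sum p_i^2 - (sum p_i^2)^2 + sum p_i^4

Match probability PM = sum p_i^2 and power of discrimination PD = 1 - PM.

Haplotype-level parameters
--------------------------
Haplotype diversity HD = n(1 - sum p_i^2)/(n-1) over haplotype
frequencies — identically the fraction of unordered sample pairs that
carry different haplotypes — and discrimination capacity DC = h/n with h
the number of distinct haplotypes.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .alleles import AlleleCall
from .haplotypes import PopulationDataset

__all__ = [
    "LocusSummary",
    "ForensicReport",
    "allele_frequencies",
    "gene_diversity",
    "pic",
    "match_probability",
    "haplotype_counts",
    "haplotype_diversity",
    "discrimination_capacity",
    "summarize",
]


@dataclass(frozen=True)
class LocusSummary:
    locus: str
    freqs: dict[AlleleCall, float]
    n_obs: int
    n_alleles_distinct: int
    gene_diversity: float
    pic: float
    match_probability: float
    power_of_discrimination: float


@dataclass(frozen=True)
class ForensicReport:
    """All per-locus and haplotype-level forensic parameters of a dataset."""

    population: str
    per_locus: tuple[LocusSummary, ...]
    n: int
    h: int
    singletons: int
    haplotype_diversity: float
    discrimination_capacity: float
    haplotype_match_probability: float
    mean_gd: float
    se_gd: float | None
    total_distinct_alleles: int
    mean_alleles_per_locus: float

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        d["per_locus"] = [
            {
                **{f: getattr(ls, f) for f in ls.__dataclass_fields__},
                "freqs": {str(a): f for a, f in ls.freqs.items()},
            }
            for ls in self.per_locus
        ]
        return d

    def summary(self) -> str:
        """Human-readable report table (values truncated at 4 decimals)."""
        from .io import display_round as dr

        lines = [
            f"Population: {self.population}",
            f"n = {self.n}   distinct haplotypes h = {self.h}   "
            f"singletons = {self.singletons}",
            f"HD = {dr(self.haplotype_diversity)}   DC = {dr(self.discrimination_capacity)}   "
            f"haplotype PM = {dr(self.haplotype_match_probability)}",
            f"mean GD = {dr(self.mean_gd)}"
            + (f" +/- {dr(self.se_gd)} (SE)" if self.se_gd is not None else ""),
            f"distinct alleles = {self.total_distinct_alleles} "
            f"({dr(self.mean_alleles_per_locus, 3)} per locus)",
            "",
            f"{'locus':<12}{'k':>4}{'GD':>9}{'PIC':>9}{'PM':>9}{'PD':>9}",
        ]
        for ls in self.per_locus:
            lines.append(
                f"{ls.locus:<12}{ls.n_alleles_distinct:>4}"
                f"{dr(ls.gene_diversity):>9}{dr(ls.pic):>9}"
                f"{dr(ls.match_probability):>9}{dr(ls.power_of_discrimination):>9}"
            )
        return "\n".join(lines)


def allele_frequencies(
    ds: PopulationDataset,
) -> dict[str, dict[AlleleCall, float]]:
    """Per-locus allele relative frequencies.

    Single-copy loci have denominator n; the duplicated DYS385a/b pools
    both copies with denominator 2n.
    """
    if ds.n == 0:
        raise ValueError("empty dataset")
    out: dict[str, dict[AlleleCall, float]] = {}
    for locus in ds.panel.loci:
        counts: Counter[AlleleCall] = Counter()
        for h in ds.haplotypes:
            call = h.calls.get(locus)
            if call is None:
                continue
            if isinstance(call, tuple):
                counts.update(call)
            else:
                counts[call] += 1
        total = sum(counts.values())
        out[locus] = (
            {a: c / total for a, c in sorted(counts.items())} if total else {}
        )
    return out


def gene_diversity(freqs: dict[AlleleCall, float] | list[float], n: int) -> float:
    """Nei's unbiased gene diversity, clipped to [0, 1]."""
    if n < 2:
        raise ValueError("gene diversity requires n >= 2 observations")
    p = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    gd = n / (n - 1) * (1.0 - sum(x * x for x in p))
    return min(1.0, max(0.0, gd))


def pic(freqs: dict[AlleleCall, float] | list[float]) -> float:
    """Botstein's polymorphic information content."""
    p = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    s2 = sum(x * x for x in p)
    s4 = sum(x**4 for x in p)
    return 1.0 - s2 - s2 * s2 + s4


def _locus_pm(freqs: dict[AlleleCall, float] | list[float]) -> float:
    p = list(freqs.values()) if isinstance(freqs, dict) else list(freqs)
    return sum(x * x for x in p)


def haplotype_counts(ds: PopulationDataset) -> tuple[int, int, Counter]:
    """(h, singletons, frequency spectrum) of distinct full-panel haplotypes."""
    counts = Counter(h.key(ds.panel) for h in ds.haplotypes)
    spectrum = Counter(counts.values())
    h = len(counts)
    singletons = spectrum.get(1, 0)
    return h, singletons, spectrum


def haplotype_diversity(ds: PopulationDataset) -> float:
    """HD = n(1 - sum p_i^2)/(n - 1) over haplotype frequencies."""
    n = ds.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    counts = Counter(h.key(ds.panel) for h in ds.haplotypes)
    s2 = sum((c / n) ** 2 for c in counts.values())
    return n * (1.0 - s2) / (n - 1)


def discrimination_capacity(ds: PopulationDataset) -> float:
    """DC = h/n: distinct haplotypes per sampled individual."""
    if ds.n < 1:
        raise ValueError("empty dataset")
    h, _, _ = haplotype_counts(ds)
    return h / ds.n


def match_probability(ds: PopulationDataset, level: str = "haplotype") -> float:
    """Random-match probability PM = sum p_i^2.

    ``level="haplotype"`` uses haplotype frequencies; ``level="locus"``
    returns the mean per-locus PM.
    """
    if level == "haplotype":
        n = ds.n
        counts = Counter(h.key(ds.panel) for h in ds.haplotypes)
        return sum((c / n) ** 2 for c in counts.values())
    if level == "locus":
        freqs = allele_frequencies(ds)
        pms = [_locus_pm(f) for f in freqs.values() if f]
        return sum(pms) / len(pms)
    raise ValueError(f"unknown level {level!r}")


def summarize(ds: PopulationDataset) -> ForensicReport:
    """Assemble the full forensic report for a complete dataset."""
    n = ds.n
    if n < 2:
        raise ValueError("forensic summary requires n >= 2")
    freqs = allele_frequencies(ds)
    per_locus = []
    for locus in ds.panel.loci:
        f = freqs[locus]
        if not f:
            continue
        n_obs = 2 * n if locus in ds.panel.multi_copy else n
        pm = _locus_pm(f)
        per_locus.append(
            LocusSummary(
                locus=locus,
                freqs=f,
                n_obs=n_obs,
                n_alleles_distinct=len(f),
                gene_diversity=gene_diversity(f, n_obs),
                pic=pic(f),
                match_probability=pm,
                power_of_discrimination=1.0 - pm,
            )
        )
    h, singles, _ = haplotype_counts(ds)
    gds = [ls.gene_diversity for ls in per_locus]
    mean_gd = sum(gds) / len(gds)
    if len(gds) > 1:
        var = sum((g - mean_gd) ** 2 for g in gds) / (len(gds) - 1)
        se_gd = math.sqrt(var / len(gds))
    else:
        se_gd = None
    total_alleles = sum(ls.n_alleles_distinct for ls in per_locus)
    return ForensicReport(
        population=ds.name,
        per_locus=tuple(per_locus),
        n=n,
        h=h,
        singletons=singles,
        haplotype_diversity=haplotype_diversity(ds),
        discrimination_capacity=h / n,
        haplotype_match_probability=match_probability(ds, "haplotype"),
        mean_gd=mean_gd,
        se_gd=se_gd,
        total_distinct_alleles=total_alleles,
        mean_alleles_per_locus=total_alleles / ds.panel.n_slots,
    )
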