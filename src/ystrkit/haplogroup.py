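"""Bayesian Y-haplogroup assignment from STR allele frequencies.

Each candidate haplogroup g has per-locus allele frequency distributions
f_g(allele | locus).  A haplotype's posterior is

    P(g | haplotype)  ∝  prior(g) · Π_locus f_g(allele at locus)

with unseen alleles floored at a small smoothing frequency ε so that a
single never-observed allele penalises rather than vetoes a haplogroup.
The duplicated DYS385a/b contributes both observations, scored against
the one per-locus distribution.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alleles import AlleleCall
from .haplotypes import Haplotype, PopulationDataset
from .panels import normalize_locus

__all__ = [
    "HaplogroupFrequencyTable",
    "HaplogroupCall",
    "UNCLASSIFIABLE",
    "load_frequency_table",
    "save_frequency_table",
    "assign_haplogroup",
    "population_haplogroup_spectrum",
]

log = logging.getLogger(__name__)

UNCLASSIFIABLE = "unclassifiable"

_NORM_TOL = 1e-9


class FrequencyTableError(ValueError):
    """Raised for malformed or non-normalised frequency tables."""


@dataclass(frozen=True)
class HaplogroupFrequencyTable:
    """Per-haplogroup, per-locus allele frequency distributions."""

    haplogroups: tuple[str, ...]
    freq: dict[str, dict[str, dict[AlleleCall, float]]]
    priors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.priors:
            u = 1.0 / len(self.haplogroups)
            object.__setattr__(self, "priors", {g: u for g in self.haplogroups})
        if abs(sum(self.priors.values()) - 1.0) > _NORM_TOL:
            raise FrequencyTableError("priors must sum to 1")
        for g in self.haplogroups:
            for locus, dist in self.freq[g].items():
                s = sum(dist.values())
                if abs(s - 1.0) > _NORM_TOL:
                    raise FrequencyTableError(
                        f"frequencies for ({g}, {locus}) sum to {s:.6g}, not 1"
                    )

    @property
    def loci(self) -> tuple[str, ...]:
        first = self.freq[self.haplogroups[0]]
        return tuple(first)


@dataclass(frozen=True)
class HaplogroupCall:
    haplogroup: str
    posterior: float
    score: float  # log-likelihood of the winning haplogroup
    runner_up: str | None
    runner_up_posterior: float
    posteriors: dict[str, float]


def load_frequency_table(path: str | Path) -> HaplogroupFrequencyTable:
    """Load a (haplogroup, locus, allele, frequency) delimited table.

    Per-(haplogroup, locus) frequencies must sum to 1 within 1e-9.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"haplogroup", "locus", "allele", "frequency"}
    cols = {c.strip().lower(): c for c in df.columns}
    if not required <= set(cols):
        raise FrequencyTableError(
            f"frequency table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    freq: dict[str, dict[str, dict[AlleleCall, float]]] = {}
    for _, row in df.iterrows():
        g = str(row[cols["haplogroup"]]).strip()
        locus = normalize_locus(str(row[cols["locus"]]))
        allele = AlleleCall.parse(str(row[cols["allele"]]))
        f = float(row[cols["frequency"]])
        freq.setdefault(g, {}).setdefault(locus, {})[allele] = f
    return HaplogroupFrequencyTable(haplogroups=tuple(sorted(freq)), freq=freq)


def save_frequency_table(table: HaplogroupFrequencyTable, path: str | Path) -> None:
    rows = [
        {"haplogroup": g, "locus": locus, "allele": str(a), "frequency": repr(f)}
        for g in table.haplogroups
        for locus, dist in table.freq[g].items()
        for a, f in sorted(dist.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _locus_loglik(
    dist: dict[AlleleCall, float], call, epsilon: float
) -> float | None:
    """Log-likelihood of the observed call(s); None means hard zero."""
    obs = call if isinstance(call, tuple) else (call,)
    total = 0.0
    for a in obs:
        f = dist.get(a, 0.0)
        if f <= 0.0:
            if epsilon <= 0.0:
                return None
            f = epsilon
        total += math.log(f)
    return total


def assign_haplogroup(
    h: Haplotype,
    table: HaplogroupFrequencyTable,
    epsilon: float = 1e-3,
) -> HaplogroupCall:
    """Maximum-posterior haplogroup for one haplotype.

    Loci absent from the table are skipped with a warning.  If every
    haplogroup has zero likelihood and smoothing is disabled
    (``epsilon=0``), the call is :data:`UNCLASSIFIABLE` rather than an
    error.
    """
    table_loci = set(table.loci)
    scored_loci = [l for l in h.calls if l in table_loci]
    skipped = set(h.calls) - table_loci
    if skipped:
        log.warning(
            "sample %s: loci absent from frequency table skipped: %s",
            h.sample_id,
            sorted(skipped),
        )
    logpost: dict[str, float] = {}
    for g in table.haplogroups:
        ll = math.log(table.priors[g]) if table.priors[g] > 0 else -math.inf
        for locus in scored_loci:
            dist = table.freq[g].get(locus)
            if dist is None:
                continue
            part = _locus_loglik(dist, h.calls[locus], epsilon)
            if part is None:
                ll = -math.inf
                break
            ll += part
        logpost[g] = ll
    best = max(logpost.values())
    if best == -math.inf:
        return HaplogroupCall(
            haplogroup=UNCLASSIFIABLE,
            posterior=0.0,
            score=-math.inf,
            runner_up=None,
            runner_up_posterior=0.0,
            posteriors={g: 0.0 for g in table.haplogroups},
        )
    weights = {g: math.exp(v - best) for g, v in logpost.items()}
    z = sum(weights.values())
    post = {g: w / z for g, w in weights.items()}
    ranked = sorted(post.items(), key=lambda kv: kv[1], reverse=True)
    winner, p1 = ranked[0]
    runner, p2 = ranked[1] if len(ranked) > 1 else (None, 0.0)
    return HaplogroupCall(
        haplogroup=winner,
        posterior=p1,
        score=logpost[winner],
        runner_up=runner,
        runner_up_posterior=p2,
        posteriors=post,
    )


def population_haplogroup_spectrum(
    ds: PopulationDataset,
    table: HaplogroupFrequencyTable,
    epsilon: float = 1e-3,
) -> tuple[dict[str, float], int]:
    """Percentage frequency of assigned haplogroups in a population.

    Returns ``(spectrum, n_unclassifiable)``; percentages are over
    classified samples and sum to 100.
    """
    counts: Counter[str] = Counter()
    for h in ds.haplotypes:
        counts[assign_haplogroup(h, table, epsilon).haplogroup] += 1
    n_unclass = counts.pop(UNCLASSIFIABLE, 0)
    total = sum(counts.values())
    spectrum = {g: 100.0 * c / total for g, c in sorted(counts.items())} if total else {}
    return spectrum, n_unclass
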