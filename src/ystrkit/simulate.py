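"""Synthetic Y-STR population generator.

Populations are simulated under a star genealogy: every sampled male
descends independently from the modal (founder) haplotype of his
haplogroup, accumulating per-locus stepwise mutations over a configured
number of generations.  The mutation count per locus is
Poisson(mutation_rate x depth_generations) and each mutation moves the
allele by +/-1 repeat with equal probability; repeat counts reflect at
the 5 and 45 sanity bounds.  Micro-variant alleles arise as a separate,
locus-restricted event at DYS481, DYS576 and DYS390 — the loci where
incomplete-repeat alleles are actually seen on this panel.  A configured
number of samples are degraded to partial profiles by blanking random
loci.

At a typical Y-STR mutation rate of about 2e-3 per locus per generation
and a few hundred generations of depth, a sample of ~100 men yields the
singleton-dominated haplotype spectrum characteristic of real forensic
Y-STR datasets (nearly every profile unique).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alleles import AlleleCall
from .haplotypes import Haplotype, PopulationDataset
from .panels import PPY23, LocusPanel

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_population",
    "simulate_divergent_pair",
    "make_haplogroup_fixture",
    "DEFAULT_HAPLOGROUP_MIX",
]

REPEAT_MIN = 5
REPEAT_MAX = 45

# Loci where micro-variant (incomplete-repeat) alleles are injected, with
# the extra-base digit each produces.
MICROVARIANT_LOCI = {"DYS481": 1, "DYS576": 1, "DYS390": 3}

# Haplogroup mixture emulating a North-Indian endogamous caste population:
# R1a-dominated with substantial H and L.
DEFAULT_HAPLOGROUP_MIX = {
    "R1a": 0.57,
    "H": 0.15,
    "L": 0.13,
    "J2b": 0.04,
    "R1b": 0.03,
    "Q": 0.02,
    "E1b1b": 0.02,
    "G2a": 0.02,
    "I2a": 0.01,
    "J1": 0.01,
}

# Modal repeat counts typical for PowerPlex Y23 loci; founders start here.
_MODAL_ALLELES = {
    "DYS19": 15,
    "DYS385": (13, 17),
    "DYS389I": 13,
    "DYS389II": 30,
    "DYS390": 24,
    "DYS391": 10,
    "DYS392": 11,
    "DYS393": 12,
    "DYS437": 14,
    "DYS438": 10,
    "DYS439": 11,
    "DYS448": 19,
    "DYS456": 15,
    "DYS458": 16,
    "DYS635": 23,
    "Y-GATA-H4": 12,
    "DYS481": 24,
    "DYS533": 11,
    "DYS549": 12,
    "DYS570": 18,
    "DYS576": 18,
    "DYS643": 10,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: ~100 males on the 23-locus panel, a handful
    of partial profiles, and a haplogroup mix dominated by R1a/H/L."""

    n_samples: int = 100
    panel: LocusPanel = PPY23
    haplogroup_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAPLOGROUP_MIX)
    )
    founder_haplotypes: dict[str, Haplotype] | None = None
    mutation_rate: float = 0.002
    depth_generations: int = 600
    microvariant_rate: float = 0.02
    partial_profile_count: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.haplogroup_mix.values()) - 1.0) > 1e-9:
            raise ValueError("haplogroup mixture proportions must sum to 1")
        for name in ("mutation_rate", "microvariant_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.partial_profile_count > self.n_samples:
            raise ValueError("more partial profiles requested than samples")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["panel"] = self.panel.name
        d.pop("founder_haplotypes")
        return d


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded alongside a simulated dataset."""

    config: dict
    seed: int
    haplogroup: dict[str, str]  # sample_id -> generating haplogroup
    n_mutations: dict[str, int]  # sample_id -> total mutation count

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _reflect(value: int) -> int:
    """Reflect a repeat count back into the [REPEAT_MIN, REPEAT_MAX] band."""
    lo, hi = REPEAT_MIN, REPEAT_MAX
    while not (lo <= value <= hi):
        value = 2 * lo - value if value < lo else 2 * hi - value
    return value


def _default_founders(
    cfg: SimulationConfig, rng: np.random.Generator
) -> dict[str, Haplotype]:
    """Modal haplotypes per haplogroup: panel modes plus a small
    haplogroup-specific random offset so founders are distinct."""
    founders = {}
    for g in sorted(cfg.haplogroup_mix):
        calls: dict = {}
        for locus in cfg.panel.loci:
            modal = _MODAL_ALLELES.get(locus, 14)
            if locus in cfg.panel.multi_copy:
                a, b = modal if isinstance(modal, tuple) else (modal, modal + 3)
                offs = rng.integers(-2, 3, size=2)
                calls[locus] = (
                    AlleleCall(_reflect(int(a + offs[0]))),
                    AlleleCall(_reflect(int(b + offs[1]))),
                )
            else:
                off = int(rng.integers(-2, 3))
                calls[locus] = AlleleCall(_reflect(int(modal) + off))
        founders[g] = Haplotype(sample_id=f"founder_{g}", calls=calls)
    return founders


def _mutate_call(
    call: AlleleCall, n_steps: int, rng: np.random.Generator
) -> AlleleCall:
    if n_steps == 0:
        return call
    steps = rng.choice((-1, 1), size=n_steps).sum()
    return AlleleCall(_reflect(call.repeats + int(steps)), call.variant)


def _evolve(
    h: Haplotype,
    panel: LocusPanel,
    mu_t: float,
    rng: np.random.Generator,
) -> tuple[dict, int]:
    """One lineage: per-locus Poisson(mu_t) stepwise mutations."""
    calls: dict = {}
    total = 0
    for locus in panel.loci:
        call = h.calls[locus]
        if locus in panel.multi_copy:
            k1, k2 = rng.poisson(mu_t, size=2)
            total += int(k1 + k2)
            calls[locus] = (
                _mutate_call(call[0], int(k1), rng),
                _mutate_call(call[1], int(k2), rng),
            )
        else:
            k = int(rng.poisson(mu_t))
            total += k
            calls[locus] = _mutate_call(call, k, rng)
    return calls, total


def _apply_microvariants(
    calls: dict, panel: LocusPanel, rate: float, rng: np.random.Generator
) -> dict:
    for locus, digit in MICROVARIANT_LOCI.items():
        if locus in panel.loci and rng.random() < rate:
            c = calls[locus]
            calls[locus] = AlleleCall(c.repeats, digit)
    return calls


def _sample_population(
    cfg: SimulationConfig,
    founders: dict[str, Haplotype],
    rng: np.random.Generator,
    name: str,
    id_prefix: str,
) -> tuple[PopulationDataset, dict[str, str], dict[str, int]]:
    groups = sorted(cfg.haplogroup_mix)
    probs = np.array([cfg.haplogroup_mix[g] for g in groups])
    hg_of: dict[str, str] = {}
    muts: dict[str, int] = {}
    haps = []
    assignments = rng.choice(len(groups), size=cfg.n_samples, p=probs)
    partial_idx = set(
        rng.choice(cfg.n_samples, size=cfg.partial_profile_count, replace=False).tolist()
        if cfg.partial_profile_count
        else []
    )
    for i in range(cfg.n_samples):
        g = groups[assignments[i]]
        sid = f"{id_prefix}{i + 1:03d}"
        calls, total = _evolve(
            founders[g], cfg.panel, cfg.mutation_rate * cfg.depth_generations, rng
        )
        calls = _apply_microvariants(calls, cfg.panel, cfg.microvariant_rate, rng)
        missing: frozenset[str] = frozenset()
        if i in partial_idx:
            n_blank = int(rng.integers(1, 4))
            blanked = rng.choice(len(cfg.panel.loci), size=n_blank, replace=False)
            blank_loci = {cfg.panel.loci[j] for j in blanked}
            calls = {l: c for l, c in calls.items() if l not in blank_loci}
            missing = frozenset(blank_loci)
        haps.append(
            Haplotype(sample_id=sid, calls=calls, missing_loci=missing)
        )
        hg_of[sid] = g
        muts[sid] = total
    return PopulationDataset(name, cfg.panel, tuple(haps)), hg_of, muts


def simulate_population(
    cfg: SimulationConfig, name: str = "synthetic"
) -> tuple[PopulationDataset, SimulationTruth]:
    """Simulate one population; fully deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    founders = cfg.founder_haplotypes or _default_founders(cfg, rng)
    ds, hg_of, muts = _sample_population(cfg, founders, rng, name, "S")
    truth = SimulationTruth(
        config=cfg.to_dict(), seed=cfg.seed, haplogroup=hg_of, n_mutations=muts
    )
    return ds, truth


def simulate_divergent_pair(
    cfg: SimulationConfig, divergence_t: int
) -> tuple[
    tuple[PopulationDataset, SimulationTruth],
    tuple[PopulationDataset, SimulationTruth],
]:
    """Two populations descended from shared founders.

    Each population's founder set first evolves ``divergence_t``
    generations independently from the common ancestors, then samples
    drift ``cfg.depth_generations`` further as usual, so among-population
    divergence grows with ``divergence_t`` while within-population
    structure stays fixed.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestors = cfg.founder_haplotypes or _default_founders(cfg, rng)
    out = []
    for pop_i, prefix in ((1, "A"), (2, "B")):
        founders = {}
        for g, anc in ancestors.items():
            calls, _ = _evolve(
                anc, cfg.panel, cfg.mutation_rate * divergence_t, rng
            )
            founders[g] = Haplotype(sample_id=f"founder_{g}_p{pop_i}", calls=calls)
        ds, hg_of, muts = _sample_population(
            cfg, founders, rng, f"pop{pop_i}", prefix
        )
        truth = SimulationTruth(
            config={**cfg.to_dict(), "divergence_t": divergence_t, "population": pop_i},
            seed=cfg.seed,
            haplogroup=hg_of,
            n_mutations=muts,
        )
        out.append((ds, truth))
    return out[0], out[1]


def make_haplogroup_fixture(
    n_haplogroups: int = 10,
    n_loci: int = 15,
    separation: int = 4,
    seed: int = 0,
    spread: float = 0.15,
):
    """Synthetic frequency table with controllably separated haplogroups.

    Per haplogroup and locus, alleles follow a discretised unimodal
    distribution (weights proportional to spread^|offset| over offsets
    -2..2) whose centre sits ``separation`` repeats from the neighbouring
    haplogroup's centre.  Returns ``(table, sampler)`` where
    ``sampler(n, seed)`` draws haplotypes with known truth labels.
    With separation 0 all haplogroups coincide (classification at
    chance); with separation >= 4 and a tight spread the supports are
    nearly disjoint and classification approaches 100%.
    """
    from .haplogroup import HaplogroupFrequencyTable

    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    groups = tuple(f"HG{i + 1:02d}" for i in range(n_haplogroups))
    loci = tuple(f"STR{j + 1:02d}" for j in range(n_loci))
    offsets = np.arange(-2, 3)
    weights = spread ** np.abs(offsets)
    weights = weights / weights.sum()
    base = rng.integers(10, 16, size=n_loci)
    freq: dict[str, dict[str, dict[AlleleCall, float]]] = {}
    for gi, g in enumerate(groups):
        freq[g] = {}
        for j, locus in enumerate(loci):
            centre = int(base[j]) + gi * separation
            dist = {}
            for off, w in zip(offsets, weights):
                rep = _reflect(centre + int(off))
                a = AlleleCall(rep)
                dist[a] = dist.get(a, 0.0) + float(w)
            total = sum(dist.values())
            freq[g][locus] = {a: f / total for a, f in dist.items()}
    table = HaplogroupFrequencyTable(haplogroups=groups, freq=freq)

    def sampler(n: int, sample_seed: int = 0):
        srng = np.random.default_rng(sample_seed)
        haps, labels = [], []
        picks = srng.integers(0, n_haplogroups, size=n)
        for i in range(n):
            g = groups[picks[i]]
            calls = {}
            for locus in loci:
                alleles = list(freq[g][locus])
                probs = np.array([freq[g][locus][a] for a in alleles])
                calls[locus] = alleles[srng.choice(len(alleles), p=probs)]
            haps.append(Haplotype(sample_id=f"F{i + 1:04d}", calls=calls))
            labels.append(g)
        return haps, labels

    return table, sampler
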