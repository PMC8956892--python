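import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")

from ystrkit import (
    AlleleCall,
    Haplotype,
    LocusPanel,
    PopulationDataset,
    SimulationConfig,
    simulate_population,
)


def toy_panel(n_loci: int = 1, multi: bool = False) -> LocusPanel:
    loci = tuple(f"L{i + 1}" for i in range(n_loci))
    mc = frozenset({loci[-1]}) if multi else frozenset()
    return LocusPanel(f"toy{n_loci}", loci, mc)


def ds_from_alleles(rows, name="toy", panel=None) -> PopulationDataset:
    """Dataset from per-sample allele tuples: each row is a tuple of ints
    (single-copy) or int pairs (multi-copy) in panel locus order."""
    rows = [r if isinstance(r, tuple) else (r,) for r in rows]
    if panel is None:
        panel = toy_panel(len(rows[0]))
    haps = []
    for i, row in enumerate(rows):
        calls = {}
        for locus, v in zip(panel.loci, row):
            if isinstance(v, tuple):
                calls[locus] = tuple(AlleleCall(x) for x in v)
            else:
                calls[locus] = AlleleCall(v)
        haps.append(Haplotype(sample_id=f"s{i + 1}", calls=calls))
    return PopulationDataset(name, panel, tuple(haps))


@pytest.fixture(scope="session")
def study_population():
    """Default-conditions simulated population (~100 males, PPY23)."""
    return simulate_population(SimulationConfig(seed=20220316 % 2**31))


@pytest.fixture(scope="session")
def small_population():
    """Small complete population for fast per-test statistics."""
    cfg = SimulationConfig(n_samples=30, partial_profile_count=0, seed=42)
    ds, truth = simulate_population(cfg)
    return ds, truth
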