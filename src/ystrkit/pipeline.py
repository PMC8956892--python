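"""End-to-end analysis pipeline.

Stage order is fixed: completeness filter → forensic summary per
population → (given ≥2 populations) pairwise Rst / AMOVA / classical MDS
→ (given a frequency table) haplogroup spectrum.  Every run writes a
machine-readable manifest recording seeds, versions and the
input/excluded/complete sample counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance import amova, classical_mds, pairwise_rst
from .forensic import summarize
from .haplogroup import (
    load_frequency_table,
    population_haplogroup_spectrum,
)
from .haplotypes import PopulationDataset, filter_complete
from .io import read_haplotype_table, write_report
from .panels import get_panel

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError", "ValidationError"]

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Configuration or input-file problem detected before any stage runs."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    input_tables: list[str]
    output_dir: str
    panel: str = "PPY23"
    frequency_table: str | None = None
    n_perm: int = 1000
    seed: int = 0
    smoothing_epsilon: float = 1e-3
    include_dys385: bool = False
    dys389_subtract: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValidationError(f"bad pipeline config: {exc}") from None

    def validate(self) -> None:
        if not self.input_tables:
            raise ValidationError("no input tables given")
        for p in self.input_tables:
            if not Path(p).exists():
                raise ValidationError(f"input table not found: {p}")
        if self.frequency_table and not Path(self.frequency_table).exists():
            raise ValidationError(
                f"frequency table not found: {self.frequency_table}"
            )
        if self.panel not in ("Minimal", "PowerPlexY12", "Yfiler17", "PPY23"):
            raise ValidationError(f"unknown panel {self.panel!r}")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full workflow; returns the manifest dict.

    On stage failure a :class:`PipelineError` is raised; outputs written
    so far are retained next to a ``FAILED`` marker naming the stage.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = get_panel(cfg.panel)
    manifest: dict = {
        "ystrkit_version": __version__,
        "config": dataclasses.asdict(cfg),
        "populations": [],
    }
    try:
        complete_sets: list[PopulationDataset] = []
        for path in cfg.input_tables:
            ds = _stage("load")(read_haplotype_table, path, panel)
            comp, excl = _stage("filter_complete")(filter_complete, ds)
            log.info(
                "population %s: %d input, %d complete, %d excluded",
                ds.name, ds.n, comp.n, excl.n,
            )
            manifest["populations"].append(
                {
                    "name": ds.name,
                    "n_input": ds.n,
                    "n_complete": comp.n,
                    "n_excluded": excl.n,
                    "excluded_samples": [h.sample_id for h in excl],
                }
            )
            report = _stage("forensic_summary")(summarize, comp)
            write_report(report, outdir / f"forensic_{ds.name}.json", "json")
            write_report(report, outdir / f"forensic_{ds.name}.csv", "csv")
            complete_sets.append(comp)

        if len(complete_sets) >= 2:
            dm = _stage("pairwise_rst")(
                pairwise_rst,
                complete_sets,
                n_perm=cfg.n_perm,
                seed=cfg.seed,
                include_dys385=cfg.include_dys385,
                dys389_subtract=cfg.dys389_subtract,
            )
            pd.DataFrame(dm.rst, index=dm.labels, columns=dm.labels).to_csv(
                outdir / "rst_matrix.csv"
            )
            pd.DataFrame(dm.p_values, index=dm.labels, columns=dm.labels).to_csv(
                outdir / "rst_pvalues.csv"
            )
            res = _stage("amova")(
                amova,
                complete_sets,
                n_perm=cfg.n_perm,
                seed=cfg.seed,
                include_dys385=cfg.include_dys385,
                dys389_subtract=cfg.dys389_subtract,
            )
            (outdir / "amova.json").write_text(
                json.dumps(dataclasses.asdict(res), indent=2)
            )
            mds = _stage("mds")(classical_mds, dm, 2)
            coords = pd.DataFrame(
                mds.coordinates,
                index=mds.labels,
                columns=[f"dim{i + 1}" for i in range(mds.coordinates.shape[1])],
            )
            coords.to_csv(outdir / "mds_coordinates.csv")
            manifest["amova"] = {
                "phi_st": res.phi_st,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "seed": res.seed,
            }
            manifest["mds_eigenvalues"] = [float(v) for v in mds.eigenvalues]

        if cfg.frequency_table:
            table = _stage("haplogroup_load")(
                load_frequency_table, cfg.frequency_table
            )
            from .haplogroup import assign_haplogroup

            spectra = {}
            rows = []
            for comp in complete_sets:
                spec, n_unclass = _stage("haplogroup_spectrum")(
                    population_haplogroup_spectrum,
                    comp, table, cfg.smoothing_epsilon,
                )
                spectra[comp.name] = {
                    "spectrum_percent": spec,
                    "n_unclassifiable": n_unclass,
                }
                for h in comp:
                    call = assign_haplogroup(h, table, cfg.smoothing_epsilon)
                    rows.append(
                        {
                            "population": comp.name,
                            "sample_id": h.sample_id,
                            "haplogroup": call.haplogroup,
                            "posterior": call.posterior,
                            "runner_up": call.runner_up,
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / "haplogroup_calls.csv", index=False)
            (outdir / "haplogroup_spectrum.json").write_text(
                json.dumps(spectra, indent=2)
            )
            manifest["haplogroup_spectra"] = spectra
    except PipelineError as exc:
        (outdir / "FAILED").write_text(f"stage: {exc.stage}\n{exc}\n")
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
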