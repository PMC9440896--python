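"""End-to-end orchestration: simulate/load -> ratios -> significance A ->
differential calling -> over-representation -> reports.

A run is a pure function of its configuration (including the seed): two
runs with identical config byte-match every tabular output.  Each run
writes one results directory containing the tables, a JSON manifest with
stage counts, and a log recording every protein exclusion and gate
decision exactly once.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .enrichment import overrepresentation
from .io_tables import (GeneSetCollection, QuantTable, RunConfig,
                        read_gmt, read_quant_table, write_gmt,
                        write_quant_table, write_results)
from .outlier_stats import (call_differential, compute_log_ratios,
                            robust_spread, score_table)
from .simulate import SimulationConfig, simulate_gene_sets, simulate_quant_experiment

__all__ = ["RunManifest", "run_de_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure; names the stage and the cause."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    timestamp: str
    n_input_proteins: int = 0
    n_retained: int = 0
    n_excluded: int = 0
    n_de_up: int = 0
    n_de_down: int = 0
    n_categories_tested: int = 0
    outputs: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_retained + self.n_excluded != self.n_input_proteins:
            raise PipelineError("manifest", "retained + excluded != input proteins")
        if self.n_de_up + self.n_de_down > self.n_retained:
            raise PipelineError("manifest", "DE counts exceed retained proteins")

    def to_dict(self) -> dict:
        return {
            "config": self.config, "seed": self.seed, "version": self.version,
            "timestamp": self.timestamp,
            "counts": {
                "input_proteins": self.n_input_proteins,
                "retained": self.n_retained,
                "excluded": self.n_excluded,
                "de_up": self.n_de_up,
                "de_down": self.n_de_down,
                "categories_tested": self.n_categories_tested,
            },
            "outputs": self.outputs,
        }


# defaults for the simulated gene-set collection accompanying a simulated run
_SIM_N_CATEGORIES = 20
_SIM_CATEGORY_SIZE = 50


def _load_or_simulate(config: RunConfig, outdir: Path):
    if config.quant_table is not None:
        path = Path(config.quant_table)
        if not path.exists():
            raise PipelineError("load", f"input file not found: {path}")
        return read_quant_table(path), None
    sim_kwargs = dict(config.simulation or {})
    sim_kwargs.setdefault("seed", config.seed)
    if "baseline_range" in sim_kwargs:
        sim_kwargs["baseline_range"] = tuple(sim_kwargs["baseline_range"])
    sim = SimulationConfig(**sim_kwargs)
    table, truth = simulate_quant_experiment(sim)
    write_quant_table(table, outdir / "quant_table.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    logger.info("simulated %d proteins (%d truly differential)",
                len(table), int(truth["is_de"].sum()))
    return table, truth


def _gene_sets(config: RunConfig, table: QuantTable,
               truth: pd.DataFrame | None, outdir: Path) -> GeneSetCollection:
    if config.gene_sets is not None:
        path = Path(config.gene_sets)
        if not path.exists():
            raise PipelineError("enrichment", f"gene-set file not found: {path}")
        return read_gmt(path)
    if truth is None or not truth["is_de"].any():
        planted = table.protein_ids[:_SIM_CATEGORY_SIZE]
    else:
        planted = list(truth.loc[truth["is_de"], "protein_id"])
    sets = simulate_gene_sets(
        n_categories=_SIM_N_CATEGORIES,
        category_size=min(_SIM_CATEGORY_SIZE, len(table)),
        universe=table.protein_ids,
        planted_category_members=planted,
        seed=config.seed + 1,
    )
    write_gmt(sets, outdir / "gene_sets.gmt")
    return sets


def run_de_pipeline(config: RunConfig) -> RunManifest:
    """Run the full replicate-free differential-abundance analysis.

    Stages: load or simulate the quantification table; form log2 ratios
    (excluding proteins not quantified in both conditions); estimate the
    asymmetric robust spread; score every protein with significance A;
    call differential proteins at the fold-change and p gates; test
    category over-representation against the detected-protein background;
    write tables and a manifest.
    """
    outdir = Path(config.outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise PipelineError("setup", f"cannot create output directory: {exc}")

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    root = logging.getLogger("ratiosig")
    root.addHandler(handler)
    previous_level = root.level
    root.setLevel(logging.INFO)
    try:
        manifest = RunManifest(config=config.to_dict(), seed=config.seed,
                               version=__version__,
                               timestamp=datetime.now(timezone.utc).isoformat())

        table, truth = _load_or_simulate(config, outdir)
        manifest.n_input_proteins = len(table)

        try:
            ratio_set = compute_log_ratios(table, config.treated, config.control)
        except KeyError as exc:
            raise PipelineError("ratios", str(exc))
        manifest.n_retained = ratio_set.n_retained
        manifest.n_excluded = ratio_set.n_excluded

        try:
            spread = robust_spread(ratio_set)
        except ValueError as exc:
            raise PipelineError("spread", str(exc))
        logger.info("robust spread: r-1=%.4g r0=%.4g r1=%.4g "
                    "(sd_left=%.4g sd_right=%.4g)", spread.r_minus1,
                    spread.r0, spread.r1, spread.sd_left, spread.sd_right)

        scores = score_table(ratio_set, spread)
        up, down, annotated = call_differential(
            scores, fc_threshold=config.fc_threshold,
            p_threshold=config.p_threshold)
        manifest.n_de_up = len(up)
        manifest.n_de_down = len(down)
        logger.info("differential calling: %d up, %d down of %d retained "
                    "(FC > %g, p < %g)", len(up), len(down),
                    ratio_set.n_retained, config.fc_threshold, config.p_threshold)

        sets = _gene_sets(config, table, truth, outdir)
        background = list(ratio_set.ratios.index)
        try:
            enr = overrepresentation(up | down, background, sets,
                                     min_category_size=config.min_category_size)
        except ValueError as exc:
            raise PipelineError("enrichment", str(exc))
        manifest.n_categories_tested = len(enr)

        files = write_results(annotated, enr, outdir)
        manifest.outputs = {name: str(outdir / name) for name in files}
        for extra in ("quant_table.tsv", "truth.tsv", "gene_sets.gmt"):
            if (outdir / extra).exists():
                manifest.outputs[extra] = str(outdir / extra)

        manifest.validate()
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2)
        manifest.outputs["manifest.json"] = str(outdir / "manifest.json")
        return manifest
    finally:
        root.removeHandler(handler)
        root.setLevel(previous_level)
        handler.close()
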