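"""End-to-end orchestration: read -> call -> partition -> test -> sweep -> enrich.

:func:`analyze_contrasts` is the in-memory engine; :func:`run_coreset_analysis`
wraps it with file I/O driven by a :class:`RunConfig` (loadable from YAML) and
writes every result table plus a JSON run summary. All stage failures are
re-raised as :class:`~coredeg.errors.PipelineError` carrying the stage name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__, coreset, enrichment, io, overlap, simulate
from .errors import CoredegError, PipelineError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one core-set analysis run."""

    table1: str
    table2: str
    dialect1: str = "generic"
    dialect2: str = "generic"
    tuber_side1: str | None = None
    tuber_side2: str | None = None
    contrast_id1: str | None = None
    contrast_id2: str | None = None
    annotation: str | None = None
    annotation_format: str = "two_column_tsv"
    hierarchy: str | None = None
    alpha: float = 0.05
    universe_mode: str = "tested_in_both"
    sweep: bool = False
    sweep_grid: tuple[float, ...] = coreset.DEFAULT_ALPHA_GRID
    reference_size: int = enrichment.DEFAULT_REFERENCE_SIZE
    reference_seed: int = 0
    sidedness: str = "two_sided"
    fdr_threshold: float = 0.05
    outdir: str = "results/coreset"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        if "sweep_grid" in raw:
            raw["sweep_grid"] = tuple(float(a) for a in raw["sweep_grid"])
        return cls(**raw)


def analyze_contrasts(
    table1: io.ContrastTable,
    table2: io.ContrastTable,
    alpha: float = 0.05,
    universe_mode: str = "tested_in_both",
    sweep_grid: tuple[float, ...] | None = None,
) -> dict[str, Any]:
    """Core-set analysis of two in-memory contrast tables.

    Returns a dict with the universe size, the Venn partition (object and
    counts), the core set with directions, both overlap-test results, and
    the alpha sweep when requested.
    """

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except CoredegError as exc:
            raise PipelineError(name, str(exc)) from exc

    universe = stage("build_universe", coreset.build_universe,
                     table1, table2, universe_mode)
    calls1 = stage("call_directions", coreset.call_directions, table1, alpha)
    calls2 = stage("call_directions", coreset.call_directions, table2, alpha)
    partition = stage("venn_partition", coreset.venn_partition,
                      calls1, calls2, universe)
    core = coreset.extract_core_set(partition)
    c = partition.counts()
    logger.info(
        "universe N=%d; k1=%d, k2=%d, core r=%d (up %d, down %d)",
        c["N"], c["k1"], c["k2"], c["r"],
        c["concordant_up"], c["concordant_down"],
    )
    directional = stage(
        "overlap_test", overlap.directional_overlap_test,
        partition.r, partition.k1, partition.k2, partition.N,
    )
    nondirectional = stage(
        "overlap_test", overlap.nondirectional_overlap_test,
        partition.r, partition.k1, partition.k2, partition.N,
    )
    out: dict[str, Any] = {
        "version": __version__,
        "alpha": alpha,
        "universe_mode": universe_mode,
        "contrast_1": table1.contrast_id,
        "contrast_2": table2.contrast_id,
        "venn": c,
        "N": c["N"], "k1": c["k1"], "k2": c["k2"], "r": c["r"],
        "directional": directional.to_dict(),
        "nondirectional": nondirectional.to_dict(),
        "partition": partition,
        "core_set": core,
        "calls": (calls1, calls2),
    }
    if sweep_grid:
        out["alpha_sweep"] = stage(
            "alpha_sweep", coreset.alpha_sweep,
            table1, table2, tuple(sweep_grid), universe_mode,
        )
    return out


def run_coreset_analysis(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis from files and write all outputs.

    Writes under ``config.outdir``: ``venn_partition.tsv``, ``core_set.tsv``,
    ``overlap_tests.tsv``, optional ``alpha_sweep.tsv`` and
    ``enrichment.tsv``, and ``summary.json``. Returns the summary dict.
    """

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except CoredegError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with the stage
            raise PipelineError(name, str(exc)) from exc

    t1 = stage("read_table1", io.read_de_table, config.table1,
               dialect=config.dialect1, tuber_side=config.tuber_side1,
               contrast_id=config.contrast_id1)
    t2 = stage("read_table2", io.read_de_table, config.table2,
               dialect=config.dialect2, tuber_side=config.tuber_side2,
               contrast_id=config.contrast_id2)
    result = analyze_contrasts(
        t1, t2, alpha=config.alpha, universe_mode=config.universe_mode,
        sweep_grid=config.sweep_grid if config.sweep else None,
    )

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    partition: coreset.VennPartition = result["partition"]
    calls1, calls2 = result["calls"]
    q1 = dict(zip(calls1["locus_id"], calls1["q_value"]))
    q2 = dict(zip(calls2["locus_id"], calls2["q_value"]))
    venn_tbl = partition.to_frame()
    venn_tbl["q1"] = venn_tbl["locus_id"].map(q1)
    venn_tbl["q2"] = venn_tbl["locus_id"].map(q2)
    io.write_results(venn_tbl, outdir / "venn_partition.tsv")
    core_tbl = venn_tbl[venn_tbl["region"].isin(
        ["concordant_up", "concordant_down"])]
    io.write_results(core_tbl, outdir / "core_set.tsv")
    io.write_results(
        pd.DataFrame([result["directional"], result["nondirectional"]]),
        outdir / "overlap_tests.tsv",
    )
    if "alpha_sweep" in result:
        io.write_results(result["alpha_sweep"], outdir / "alpha_sweep.tsv")

    summary = {
        k: result[k]
        for k in ("version", "alpha", "universe_mode", "contrast_1",
                  "contrast_2", "venn", "N", "k1", "k2", "r",
                  "directional", "nondirectional")
    }
    summary["reference_seed"] = config.reference_seed

    if config.annotation:
        annot = stage("read_annotation", io.read_annotation,
                      config.annotation, config.annotation_format)
        hier = (stage("read_hierarchy", io.read_term_hierarchy, config.hierarchy)
                if config.hierarchy else None)
        universe = coreset.Universe(partition.universe)
        ref = stage("sample_reference", enrichment.sample_reference,
                    universe, config.reference_size, config.reference_seed)
        enr = stage("term_enrichment", enrichment.term_enrichment,
                    frozenset(result["core_set"]), ref, annot, hier,
                    config.sidedness, config.fdr_threshold)
        io.write_results(enr, outdir / "enrichment.tsv")
        summary["enrichment"] = {
            "n_terms_tested": int(len(enr)),
            "n_significant": int(enr["significant"].sum()) if len(enr) else 0,
            "fdr_threshold": config.fdr_threshold,
            "sidedness": config.sidedness,
        }

    io.write_results(summary, outdir / "summary.json", format="json")
    return summary


def run_simulation_study(
    params: simulate.SimParams,
    n_reps: int = 100,
    mode: str = "power",
    alpha_test: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated simulation study; one row per replicate.

    ``calibration`` mode records (N, k1, k2, r, p_value, reject) per null
    replicate; ``power`` mode additionally runs core-set recovery against
    the truth labels and records precision and recall. Deterministic for a
    fixed ``seed``.
    """
    if mode not in ("calibration", "power"):
        raise PipelineError("simulation_study", f"unknown mode {mode!r}")
    seeds = simulate.replicate_seeds(seed, n_reps)
    rows = []
    for i, s in enumerate(seeds):
        t1, t2, truth = simulate.simulate_dual_contrast(
            replace(params, seed=int(s)))
        N, k1, k2, r = coreset.overlap_counts(t1, t2, params.alpha)
        res = overlap.directional_overlap_test(r, k1, k2, N)
        row = dict(rep=i, seed=int(s), N=N, k1=k1, k2=k2, r=r,
                   p_value=res.p_value, log10_p=res.log10_p,
                   reject=res.p_value <= alpha_test)
        if mode == "power":
            universe = coreset.build_universe(t1, t2)
            part = coreset.venn_partition(
                coreset.call_directions(t1, params.alpha),
                coreset.call_directions(t2, params.alpha),
                universe,
            )
            core = coreset.extract_core_set(part)
            m = simulate.evaluate_recovery(core, truth)
            row.update(precision=m.precision, recall=m.recall,
                       true_core=m.true_core)
        rows.append(row)
    return pd.DataFrame(rows)
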