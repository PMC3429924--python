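"""End-to-end pipeline: simulate cohorts, score clones, summarise.

Every intermediate artifact is materialised as TSV so each stage can be
re-run and inspected independently; a JSON manifest records the full
configuration, seed and file digests so a run is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import call_wings
from .config import PipelineConfig
from .io import write_clone_table, write_wing_table
from .model import CloneFrequencyModel
from .simulate import simulate_cohort

__all__ = ["run_pipeline"]

log = logging.getLogger("wingmosaic.pipeline")


def _atomic_write_text(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> call -> stats for every group; return the manifest.

    Outputs under ``config.output_dir``: ``wings.tsv``, ``clones.tsv``,
    ``summary.tsv`` (one published-style row per group),
    ``poisson_<group>.tsv`` and ``halve_by_half_<group>.tsv`` diagnostics,
    and ``manifest.json``. Identical config + seed give byte-identical
    tables.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # -- simulate ------------------------------------------------------
    stage = "simulate"
    try:
        # each group is driven by its own simulation seed so a stage-by-stage
        # CLI run with the same flags reproduces the pipeline byte for byte
        wings = []
        for gspec in config.groups:
            wings.extend(
                simulate_cohort(gspec.simulation, gspec.n_wings, group=gspec.label)
            )
        wings_path = out / "wings.tsv"
        tmp = wings_path.with_suffix(".tsv.tmp")
        write_wing_table(wings, tmp)
        os.replace(tmp, wings_path)
        log.info("simulate: %d wings in %.1fs", len(wings), time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- call ----------------------------------------------------------
    stage = "call"
    t1 = time.perf_counter()
    try:
        calls = call_wings(
            wings,
            max_gap=config.calling.max_gap,
            hinge_mask=config.calling.hinge_x,
            min_trichomes_solo=config.calling.min_trichomes_solo,
        )
        clones_path = out / "clones.tsv"
        tmp = clones_path.with_suffix(".tsv.tmp")
        write_clone_table(calls, tmp)
        os.replace(tmp, clones_path)
        log.info("call: %d clones in %.1fs", len(calls), time.perf_counter() - t1)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # -- stats ---------------------------------------------------------
    stage = "stats"
    t2 = time.perf_counter()
    try:
        sim_by_group = {g.label: g.simulation for g in config.groups}
        model = CloneFrequencyModel.from_wing_records(
            wings,
            max_gap=config.calling.max_gap,
            hinge_mask=config.calling.hinge_x,
            min_trichomes_solo=config.calling.min_trichomes_solo,
            screened_cells=config.stats.screened_cells,
            size_classes=config.stats.classes,
            m_override=config.stats.m_override,
            simulation_config=(
                next(iter(sim_by_group.values())) if len(sim_by_group) == 1 else None
            ),
        )
        results = model.fit(
            n_bootstrap=config.stats.n_bootstrap, seed=config.seed
        )
        summary_path = out / "summary.tsv"
        _atomic_write_text(
            summary_path, results.summary_frame().to_csv(sep="\t", index=False)
        )
        table_paths = [wings_path, clones_path, summary_path]
        for group, s in results.summaries.items():
            if s.n > 0:
                pois = results.poisson_fit(group, pool_below=config.stats.pool_below)
                pframe = pd.DataFrame(
                    {
                        "i": list(range(pois.i_max + 1)),
                        "observed": list(pois.observed),
                        "expected": [round(e, 4) for e in pois.expected],
                    }
                )
                pframe.attrs = {}
                ppath = out / f"poisson_{group}.tsv"
                header = (
                    f"# nu={pois.nu:.6g} chi2={pois.statistic:.4g} "
                    f"df={pois.df} p={pois.pvalue:.4g}\n"
                )
                _atomic_write_text(ppath, header + pframe.to_csv(sep="\t", index=False))
                table_paths.append(ppath)

                exp, (stat, df, p) = results.halve_by_half(
                    group, pool_below=config.stats.pool_below
                )
                hframe = pd.DataFrame(
                    {
                        "size_class": list(range(1, exp.K + 1)),
                        "observed": list(s.class_counts[: exp.K]),
                        "expected": [round(e, 4) for e in exp.expected],
                    }
                )
                hpath = out / f"halve_by_half_{group}.tsv"
                header = f"# chi2={stat:.4g} df={df} p={p:.4g}\n"
                _atomic_write_text(hpath, header + hframe.to_csv(sep="\t", index=False))
                table_paths.append(hpath)
        log.info("stats: %d groups in %.1fs", len(results.summaries), time.perf_counter() - t2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config_dict = _config_dict(config)
    manifest = {
        "wingmosaic_version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in table_paths},
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    _atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    return manifest
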