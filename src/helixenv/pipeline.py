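"""Pipeline driver: datamart -> align -> scan -> census -> manova.

Stage order follows the analysis recipe: class filter, redundancy
removal, consensus grouping, grouping by length, positional alignment,
then the statistics.  Every run writes a manifest with a config hash and
per-file checksums so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from helixenv import alignment, datamarts, io, multivariate, univariate
from helixenv.types import ChainRecord

log = logging.getLogger("helixenv")


@dataclass
class RunConfig:
    consensus_mode: str = "pdb-dssp-stride"
    redundancy_level: float | None = None
    class_label: str | None = None
    flank: int = alignment.DEFAULT_FLANK
    descriptors: list[str] | None = None
    test: str = "t"
    lengths: list[int] | None = None    # None: every length with enough data
    min_instances: int = 3
    normality_alpha: float = 0.05
    correlation_cutoff: float = 0.9
    assess_threshold: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValueError("flank must be >= 0")
        for name in ("normality_alpha", "assess_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


def run_pipeline(config: RunConfig, records: Sequence[ChainRecord],
                 table: pd.DataFrame, outdir: str | Path) -> dict:
    """Execute all stages and write the report bundle under ``outdir``.

    Returns a summary dict; an empty consensus set is not an error (a
    'no ensembles' report is written and the summary says so).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    t0 = time.perf_counter()

    log.info("stage datamart: %d chains in", len(records))
    marts = datamarts.build_datamarts(
        records, class_label=config.class_label,
        consensus_mode=config.consensus_mode,
        redundancy_level=config.redundancy_level)
    summary_table = datamarts.datamart_summary(marts)
    path = outdir / "datamart.tsv"
    summary_table.to_csv(path, sep="\t", index=False)
    written.append(path)
    membership = {
        name: [dataclasses.asdict(h) for h in mart.members]
        for name, mart in marts.items()}
    path = outdir / "membership.json"
    path.write_text(json.dumps(membership, indent=2))
    written.append(path)
    log.info("stage datamart: %d helices out", marts["DM"].total)

    records_by_id = {r.chain_id: r for r in records}
    lengths = config.lengths or [
        L for L, n in sorted(marts["DM"].counts.items())
        if n >= config.min_instances]
    per_length: dict[int, dict] = {}
    for length in lengths:
        instances = marts["DM"].instances_of_length(length)
        if len(instances) < config.min_instances:
            log.warning("length %d: only %d instances, skipped",
                        length, len(instances))
            continue
        per_length[length] = _analyse_length(
            config, length, instances, records_by_id, table, outdir, written)

    if not per_length:
        log.warning("no ensembles: consensus produced no analysable lengths")
        path = outdir / "no_ensembles.txt"
        path.write_text("no consensus helix ensembles at the requested "
                        "lengths/instance threshold\n")
        written.append(path)

    config_dict = dataclasses.asdict(config)
    io.write_manifest(outdir, config_dict, written)
    elapsed = time.perf_counter() - t0
    log.info("pipeline done in %.2fs, %d files", elapsed, len(written))
    return {
        "n_chains": len(records),
        "datamart_total": marts["DM"].total,
        "lengths_analysed": sorted(per_length),
        "outputs": [str(p) for p in written],
        "elapsed_s": elapsed,
    }


def _analyse_length(config: RunConfig, length: int, instances,
                    records_by_id: Mapping[str, ChainRecord],
                    table: pd.DataFrame, outdir: Path,
                    written: list[Path]) -> dict:
    t0 = time.perf_counter()
    ensemble = alignment.align_ensemble(
        instances, records_by_id, table,
        descriptors=config.descriptors, flank=config.flank)
    descriptors = list(ensemble.values)

    profiles = []
    for d in descriptors:
        profile = alignment.position_profile(ensemble, d)
        profile.insert(0, "descriptor", d)
        profiles.append(profile)
    path = outdir / f"profiles_L{length}.tsv"
    pd.concat(profiles, ignore_index=True).to_csv(path, sep="\t", index=False)
    written.append(path)

    scan_rows = []
    for d in descriptors:
        profile = alignment.position_profile(ensemble, d)["mean"].to_numpy()
        scan = univariate.sliding_window_scan(
            profile, window=length, test=config.test)
        for s, p in enumerate(scan.p_values):
            scan_rows.append({"descriptor": d, "window": length,
                              "placement": s, "p_value": p})
    path = outdir / f"scan_L{length}.tsv"
    pd.DataFrame(scan_rows).to_csv(path, sep="\t", index=False)
    written.append(path)

    census_table, census_summary = univariate.signal_census(ensemble)
    path = outdir / f"census_L{length}.tsv"
    census_table.to_csv(path, sep="\t", index=False)
    written.append(path)

    manova_report = _manova_for_ensemble(config, ensemble)
    path = outdir / f"manova_L{length}.json"
    path.write_text(json.dumps(manova_report, indent=2, default=str))
    written.append(path)

    log.info("length %d: %d instances analysed in %.2fs",
             length, ensemble.n_instances, time.perf_counter() - t0)
    return {"ensemble": ensemble, "census": census_summary,
            "manova": manova_report}


def _manova_for_ensemble(config: RunConfig,
                         ensemble: alignment.AlignedEnsemble) -> dict:
    """Residue-level inside/outside MANOVA after the two filters."""
    frames, labels = [], []
    for d, mat in ensemble.values.items():
        frames.append(mat[~ensemble.gap_mask])
    data = pd.DataFrame(np.column_stack(frames), columns=list(ensemble.values))
    span = np.zeros(ensemble.n_positions, dtype=bool)
    span[ensemble.helix_columns] = True
    labels = np.broadcast_to(span, ensemble.gap_mask.shape)[
        ~ensemble.gap_mask]
    try:
        report = multivariate.apply_filters(
            data, labels, alpha=config.normality_alpha,
            cutoff=config.correlation_cutoff)
        if not report.retained:
            return {"status": "no descriptors retained",
                    "removed": report.removed}
        manova = multivariate.manova_inside_outside(
            data, labels, report.retained)
    except Exception as exc:   # degenerate data is reported, not fatal
        return {"status": f"failed: {exc}"}
    return {
        "status": "ok",
        "retained": report.retained,
        "n_inside": manova.n_inside,
        "n_outside": manova.n_outside,
        "statistics": json.loads(
            manova.statistics.to_json(orient="index")),
        "min_p": manova.min_p,
    }
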