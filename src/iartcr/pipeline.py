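"""Umbrella pipeline: simulate -> repertoire / phenotype / expression -> outcome.

Each stage writes its outputs under the configured directory with
provenance headers, and a run manifest records checksums of every file so
deterministic stages can be verified to reproduce byte-identical results.
Stage failures abort the run naming the failing stage; files from the
failed stage keep a ``.partial`` suffix.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, expression, outcome, phenotyping, repertoire, simulate
from .io_utils import PipelineConfig, config_hash, read_table, write_table

__all__ = ["run_pipeline", "RunManifest", "PipelineError"]

log = logging.getLogger("iartcr")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _StageWriter:
    """Writes stage outputs to .partial files, renamed only on stage success."""

    def __init__(self, out_dir: Path, meta: dict):
        self.out_dir = out_dir
        self.meta = meta
        self.pending: list[tuple[Path, Path]] = []

    def write(self, df: pd.DataFrame, name: str, sep: str = ",") -> None:
        final = self.out_dir / name
        partial = self.out_dir / (name + ".partial")
        write_table(df, partial, meta=self.meta, sep=sep)
        self.pending.append((partial, final))

    def commit(self) -> list[Path]:
        done = []
        for partial, final in self.pending:
            os.replace(partial, final)
            done.append(final)
        self.pending.clear()
        return done


def run_pipeline(config: PipelineConfig) -> RunManifest:
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashed = config.to_dict()
    hashed.pop("out_dir", None)  # output location does not alter results
    chash = config_hash(hashed)
    meta = {"tool": f"iartcr {__version__}", "seed": config.seed, "config": chash}
    manifest = RunManifest(
        version=__version__,
        config_hash=chash,
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    written: list[Path] = []

    def run_stage(name, fn):
        writer = _StageWriter(out_dir, meta)
        log.info("stage %s: start", name)
        try:
            result = fn(writer)
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise PipelineError(name, exc) from exc
        written.extend(writer.commit())
        manifest.stages.append(name)
        log.info("stage %s: done", name)
        return result

    state: dict = {}

    # --- simulate ------------------------------------------------------
    if config.simulate:
        def _simulate(writer: _StageWriter):
            ds = simulate.simulate_dataset(config.sim_config())
            writer.write(ds.cohort, "cohort.csv")
            writer.write(ds.chains, "airr.tsv", sep="\t")
            writer.write(ds.truth.cells, "cells.csv")
            writer.write(ds.counts.reset_index(), "counts.csv")
            writer.write(ds.flow, "flow.csv")
            writer.write(ds.cpeptide, "cpeptide.csv")
            writer.write(ds.truth.participants, "truth_participants.csv")
            log.info(
                "simulated %d participants, %d cells, %d chains",
                len(ds.cohort),
                len(ds.truth.cells),
                len(ds.chains),
            )
            return ds
        state["dataset"] = run_stage("simulate", _simulate)
        ds = state["dataset"]
        state["chains"] = ds.chains
        state["cells"] = ds.truth.cells
        state["counts"] = ds.counts
        state["flow"] = ds.flow
        state["cpeptide"] = ds.cpeptide
        state["arms"] = ds.cohort.set_index("participant_id")["arm"]
    else:
        if config.airr_path:
            # parsed inside the repertoire stage so a corrupt file aborts there
            state["chains_loader"] = lambda: repertoire.read_airr(config.airr_path)
        if config.cells_path:
            state["cells"] = read_table(config.cells_path)
        if config.counts_path:
            from .io_utils import read_counts

            state["counts"] = read_counts(config.counts_path)
        if config.flow_path:
            state["flow"] = read_table(config.flow_path)
        if config.cpeptide_path:
            state["cpeptide"] = read_table(config.cpeptide_path)
        if config.arms_path:
            arms = read_table(config.arms_path)
            state["arms"] = arms.set_index("participant_id")["arm"]

    cells = state.get("cells")
    cluster_map = (
        cells.set_index("cell_id")["cluster"] if cells is not None else None
    )

    # --- repertoire ----------------------------------------------------
    if config.run_repertoire and ("chains" in state or "chains_loader" in state):
        def _repertoire(writer: _StageWriter):
            chains = state["chains"] if "chains" in state else state["chains_loader"]()
            groups = repertoire.find_shared_chains(chains, strict_vj=config.strict_vj)
            expanded, summary = repertoire.detect_expanded(groups)
            groups, privacy = repertoire.classify_privacy(groups)
            log.info(
                "repertoire: %d productive chains -> %d expanded chains, %d expanded cells "
                "(%d private / %d public chains)",
                int(chains["productive"].sum()),
                summary.n_expanded_chains,
                summary.n_expanded_cells,
                privacy.n_private_chains,
                privacy.n_public_chains,
            )
            flat = groups.copy()
            flat["cell_ids"] = flat["cell_ids"].map(";".join)
            flat["participant_ids"] = flat["participant_ids"].map(";".join)
            writer.write(flat, "chain_groups.csv")
            if cluster_map is not None:
                _, edges = repertoire.build_sharing_graph(
                    cluster_map,
                    groups,
                    cell_participants=cells.set_index("cell_id")["participant_id"],
                )
                writer.write(edges, "sharing_edges.csv")
                fracs = repertoire.cluster_expansion_fractions(
                    cluster_map, summary.expanded_cells
                )
                writer.write(fracs, "cluster_expansion.csv")
                if summary.n_expanded_cells >= 2:
                    ks = repertoire.compare_expansion_distribution(
                        cluster_map[list(summary.expanded_cells)].to_numpy(),
                        cluster_map.to_numpy(),
                        n_permutations=config.n_permutations,
                        seed=config.seed,
                    )
                    writer.write(
                        pd.DataFrame(
                            [
                                {
                                    "d": ks.d,
                                    "p_permutation": ks.p_permutation,
                                    "p_asymptotic": ks.p_asymptotic,
                                    "n_permutations": ks.n_permutations,
                                }
                            ]
                        ),
                        "expansion_ks.csv",
                    )
            if config.db_path:
                db = pd.read_csv(config.db_path, sep="\t", comment="#")
                matches, db_summary = repertoire.match_database(chains, db)
                writer.write(matches, "db_matches.csv")
                log.info("db lookup: %s", db_summary)
            return summary
        state["repertoire_summary"] = run_stage("repertoire", _repertoire)

    # --- phenotyping ---------------------------------------------------
    if config.run_phenotyping and "flow" in state:
        def _phenotype(writer: _StageWriter):
            flow = state["flow"]
            thresholds = simulate.default_thresholds()
            mat = phenotyping.classify_maturation(flow, thresholds)
            c3 = phenotyping.gate_cluster3_like(flow, thresholds)
            labels = pd.DataFrame(
                {"event_id": flow.get("event_id", flow.index), "maturation": mat, "cluster3_like": c3}
            )
            writer.write(labels, "flow_labels.csv")
            freqs = phenotyping.population_frequencies(flow, thresholds, "maturation")
            writer.write(freqs, "population_frequencies.csv")
            return labels
        run_stage("phenotype", _phenotype)

    # --- expression ----------------------------------------------------
    if config.run_expression and "counts" in state:
        def _express(writer: _StageWriter):
            counts = state["counts"]
            norm = expression.normalize(counts)
            assign = expression.cluster_cells(norm, seed=config.seed)
            writer.write(
                assign.labels.rename_axis("cell_id").reset_index(), "leiden_clusters.csv"
            )
            markers = expression.top_markers(counts, assign.labels)
            writer.write(markers[markers["rank"] <= 25], "top_markers.csv")
            de_target = None
            if cluster_map is not None:
                de_target = 3 if config.use_truth_clusters else None
                de_labels = cluster_map.reindex(counts.index)
            if de_target is None:
                annotations = expression.annotate_clusters(markers)
                tcm = [c for c, v in annotations.items() if v == "Tcm"]
                de_target = tcm[0] if tcm else int(assign.labels.value_counts().index[0])
                de_labels = assign.labels
            de = expression.differential_expression(
                counts, de_labels, de_target, alpha=config.de_alpha
            )
            writer.write(de, "differential_expression.csv")
            n_up = int((de["significant"] & (de["direction"] == "up")).sum())
            n_dn = int((de["significant"] & (de["direction"] == "down")).sum())
            log.info("expression: %d clusters; DE cluster %s: %d up / %d down", assign.k, de_target, n_up, n_dn)
            return de
        state["de"] = run_stage("expression", _express)

    # --- outcome -------------------------------------------------------
    if config.run_outcome and "cpeptide" in state and cells is not None and "arms" in state:
        def _outcome(writer: _StageWriter):
            flow = state.get("flow") if config.run_phenotyping else None
            screen = outcome.biomarker_screen(
                cells,
                state["cpeptide"],
                state["arms"],
                flow_table=flow if flow is not None and "participant_id" in getattr(flow, "columns", []) else None,
                thresholds=simulate.default_thresholds() if flow is not None else None,
                shrink=config.shrink_decay,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            writer.write(screen.decay, "decay_rates.csv")
            writer.write(screen.features.rename_axis("participant_id").reset_index(), "features.csv")
            writer.write(screen.correlations, "correlations.csv")
            writer.write(screen.flags, "biomarker_flags.csv")
            return screen
        state["screen"] = run_stage("outcome", _outcome)

    for path in written:
        manifest.checksums[path.name] = _sha256(path)
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
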