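"""End-to-end orchestration: simulate -> classify -> DE -> stats -> qPCR.

One configuration file (the simulation profile, plus thresholds) drives a
reproducible run that writes every table the analysis produces, a
machine-readable ``report.json`` of the headline numbers, and a
``manifest.json`` with per-output checksums for reproducibility audits.
``report.json`` is byte-deterministic for a fixed config and seed; wall-clock
timestamps live only in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import expression_core as ec
from . import genome_context as gc
from . import integrative_stats as ist
from . import qpcr_validation as qv
from . import synthetic_data as sd

logger = logging.getLogger("lnccompartment")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamps: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "outputs": self.outputs,
            "timestamps": self.timestamps,
        }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        if math.isnan(f):
            return None
        return f
    return obj


def run_full_analysis(
    config: str | os.PathLike | dict | sd.SimulationConfig,
    outdir: str | os.PathLike,
    seed: int | None = None,
    up: float = 2.0,
    down: float = 0.5,
    window: int | None = None,
) -> tuple[RunManifest, dict]:
    """Run the whole analysis on a simulated study and write all outputs.

    Returns (manifest, report).  Any stage failure raises
    :class:`PipelineError` naming the stage; files the failing stage already
    wrote are renamed with a ``.partial`` suffix.
    """
    if isinstance(config, sd.SimulationConfig):
        cfg = config
        cfg_text = yaml.safe_dump(cfg.__dict__, sort_keys=True)
    elif isinstance(config, dict):
        cfg = sd.SimulationConfig.from_dict(config)
        cfg_text = yaml.safe_dump(config, sort_keys=True)
    else:
        with open(config) as fh:
            raw = yaml.safe_load(fh)
        cfg = sd.SimulationConfig.from_dict(raw)
        cfg_text = yaml.safe_dump(raw, sort_keys=True)
    seed = cfg.master_seed if seed is None else int(seed)
    window = cfg.bidirectional_window_bp if window is None else int(window)
    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    from . import __version__

    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_text.encode()).hexdigest(),
        seed=seed,
        version=__version__,
    )
    report: dict = {"seed": seed, "thresholds": {"up": up, "down": down, "window": window}}
    stage_files: list[str] = []

    def run_stage(name, fn):
        stage_files.clear()
        t0 = time.time()
        logger.info("stage %s ...", name)
        try:
            result = fn()
        except Exception as exc:
            for path in stage_files:
                if os.path.exists(path):
                    os.replace(path, path + ".partial")
            raise PipelineError(name, exc) from exc
        manifest.timestamps[name] = time.time() - t0
        for path in stage_files:
            manifest.outputs[os.path.relpath(path, outdir)] = _sha256(path)
        logger.info("stage %s done (%.1fs)", name, manifest.timestamps[name])
        return result

    def out(*parts: str) -> str:
        path = os.path.join(outdir, *parts)
        os.makedirs(os.path.dirname(path), exist_ok=True)
        stage_files.append(path)
        return path

    # --- simulate ---------------------------------------------------------
    def _simulate():
        study = sd.generate_dataset(cfg, seed)
        sim_paths = sd.write_simulation(study, os.path.join(outdir, "sim"))
        stage_files.extend(sim_paths.values())
        return study

    study = run_stage("simulate", _simulate)

    # --- classify ---------------------------------------------------------
    def _classify():
        table, fractions = gc.classify_all(study.lncs, study.genes, window=window)
        gc.write_classification_tsv(table, out("classes.tsv"))
        report["class_fractions"] = {k: float(v) for k, v in fractions.items()}
        return table

    classes = run_stage("classify", _classify)

    # --- normalize + DE ---------------------------------------------------
    def _de():
        lnc_expr = study.lnc_expr
        mrna_expr = study.mrna_expr
        if not cfg.already_normalized:
            lnc_expr = ec.quantile_normalize(lnc_expr)
            mrna_expr = ec.quantile_normalize(mrna_expr)
        de_lnc, de_mrna = {}, {}
        counts = {}
        for comp in ec.COMPARTMENTS:
            de_lnc[comp] = ec.call_de(lnc_expr, lnc_expr.pair(comp), up=up, down=down)
            de_mrna[comp] = ec.call_de(mrna_expr, mrna_expr.pair(comp), up=up, down=down)
            ec.write_de_table(de_lnc[comp], comp, out("de", f"lnc_{comp}.tsv"))
            ec.write_de_table(de_mrna[comp], comp, out("de", f"mrna_{comp}.tsv"))
            n_up, n_down = ec.de_counts(de_lnc[comp])
            counts[comp] = {"up": n_up, "down": n_down}
        report["de_counts"] = counts
        return lnc_expr, de_lnc, de_mrna

    lnc_expr, de_lnc, de_mrna = run_stage("de", _de)

    # --- integrative stats ------------------------------------------------
    def _stats():
        lengths = study.truth.set_index("lnc_id")["length"]
        grid = ist.length_expression_grid(lnc_expr, lengths, classes)
        grid.write_tsv(out("stats", "length_expression_grid.tsv"))
        report["grid_total_rho"] = {
            s: _jsonable(grid.rho.loc["Total", s]) for s in grid.rho.columns
        }

        corr, table, fisher = ist.fold_change_concordance(de_lnc["heart"], de_lnc["plasma"])
        report["heart_plasma_concordance"] = {
            "rho": corr.rho,
            "p": corr.p,
            "n": corr.n,
            "table": [table.a, table.b, table.c, table.d],
            "odds_ratio": fisher.odds_ratio,
            "fisher_p": fisher.p_two_sided,
        }

        overlap = ist.intersect_de(
            de_lnc["heart"], de_lnc["plasma"], de_lnc["whole_blood"], classes,
            probe_transcript=lnc_expr.probe_transcript,
        )
        overlap.to_csv(out("stats", "triple_overlap.tsv"), sep="\t", index=False)
        report["n_triple_overlap"] = int(len(overlap))

        pairs_report = {}
        for comp in ec.COMPARTMENTS:
            res = ist.pair_concordance(
                de_lnc[comp], de_mrna[comp], classes,
                lnc_transcript=lnc_expr.probe_transcript,
                mrna_transcript=study.mrna_expr.probe_transcript,
            )
            pairs_report[comp] = {
                c4: None
                if r is None
                else {
                    "odds_ratio": r.fisher.odds_ratio,
                    "p": r.fisher.p_two_sided,
                    "n_pairs": r.n_pairs,
                }
                for c4, r in res.items()
            }
        report["pair_concordance"] = pairs_report
        pd.DataFrame(
            [
                (comp, c4, d["odds_ratio"] if d else None, d["p"] if d else None, d["n_pairs"] if d else 0)
                for comp, per in pairs_report.items()
                for c4, d in per.items()
            ],
            columns=["compartment", "class4", "odds_ratio", "p", "n_pairs"],
        ).to_csv(out("stats", "pair_concordance.tsv"), sep="\t", index=False)

        # MDS on DE-probe fold changes and on full expression profiles
        fold = pd.DataFrame(
            {c: de_lnc[c]["log2fc"] for c in ec.COMPARTMENTS}
        )
        de_any = pd.concat(
            [de_lnc[c]["direction"].isin(("up", "down")) for c in ec.COMPARTMENTS], axis=1
        ).any(axis=1)
        mds_fold = ist.classical_mds(ist.correlation_distance_matrix(fold[de_any.values]))
        mds_fold.coords.to_csv(out("stats", "mds_fold.tsv"), sep="\t")
        expr_log = np.log(lnc_expr.intensity)
        mds_expr = ist.classical_mds(ist.correlation_distance_matrix(expr_log))
        mds_expr.coords.to_csv(out("stats", "mds_expr.tsv"), sep="\t")

        bic = ist.bicluster_grid(grid)
        with open(out("stats", "grid_row_tree.nwk"), "w") as fh:
            fh.write(bic.row_newick + "\n")
        with open(out("stats", "grid_col_tree.nwk"), "w") as fh:
            fh.write(bic.col_newick + "\n")
        report["grid_col_order"] = bic.col_order
        return grid

    run_stage("stats", _stats)

    # --- qPCR -------------------------------------------------------------
    def _qpcr():
        table = qv.validate_targets(study.qpcr, reference=cfg.qpcr.get("reference", "GAPDH"))
        qv.write_qpcr_tsv(table, out("qpcr.tsv"))
        report["qpcr"] = {
            row["gene"]: {"fold_change": row["fold_change"], "p": row["p"]}
            for _, row in table.iterrows()
        }

    run_stage("qpcr", _qpcr)

    # --- report + manifest ------------------------------------------------
    def _report():
        with open(out("report.json"), "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
            fh.write("\n")

    run_stage("report", _report)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest, report
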