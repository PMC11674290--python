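"""One-shot pipeline: (optional) screening -> stability -> consensus -> validation.

Driven by a YAML/dict config; writes plain-text TSV result tables plus one
JSON metadata file (parameters, seed, stage row counts, versions) so a run
is fully reproducible and diffable.  Any stage failure aborts with the
failing stage named.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import io as rio
from .consensus import reffinder_geomean, topk_intersection
from .model import CtMatrix
from .quantify import ddct_fold_change, reference_shift
from .screening import ScreeningCriteria, screen_candidates
from .stability import METHODS, run_all_methods

__all__ = ["run_pipeline", "tidy_stability"]

log = logging.getLogger("refstab")

RESULT_FILES = ("stability.tsv", "consensus.tsv", "quant.tsv", "venn.tsv", "run.json")


class PipelineError(RuntimeError):
    """Raised with the failing stage named."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def tidy_stability(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-method tables into one tidy frame: gene, method, value, rank, aux."""
    frames = []
    for method, table in tables.items():
        t = table.reset_index()
        t.insert(1, "method", method)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError("config must be a mapping or a YAML file containing one")
    return dict(config)


def _validate_config(cfg: dict) -> None:
    if "ct" not in cfg:
        raise ValueError("config is missing the 'ct' table path")
    if "groups" not in cfg:
        raise ValueError("config is missing the 'groups' assignment")
    methods = cfg.get("methods", list(METHODS))
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown stability methods in config: {sorted(unknown)}")


def _default_quantify(ct: CtMatrix, consensus: pd.DataFrame, optimal_n) -> dict:
    """Pick a default validation setup: worst-consensus gene as target,
    the top consensus genes (optimal_n if known, else 2) as references,
    first group as calibrator, second as treatment."""
    ordered = list(consensus.index)
    n_refs = int(optimal_n) if optimal_n else 2
    refs = ordered[:n_refs]
    target = ordered[-1]
    groups = ct.group_names
    return {"target": target, "refs": refs, "calibrator": groups[0], "treatment": groups[1]}


def run_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Run the configured analysis end to end; returns the in-memory results.

    Config keys: ``ct`` (path), ``groups`` (path or mapping), optional
    ``expression`` (path, triggers screening), ``screening`` (criteria
    mapping), ``methods``, ``efficiency``, ``topk``, ``quantify``
    (target/refs/calibrator/treatment), ``seed``, ``out_dir``.
    """
    cfg = _load_config(config)
    _validate_config(cfg)
    out_dir = Path(out_dir or cfg.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    results: dict = {}

    try:
        ct = rio.read_ct_table(cfg["ct"], cfg["groups"])
        counts["ct_genes"], counts["ct_samples"] = ct.data.shape
        log.info("loaded Ct table: %d genes x %d samples", *ct.data.shape)
    except Exception as e:
        raise PipelineError("load", e) from e

    if cfg.get("expression"):
        try:
            mat = rio.read_expression_table(cfg["expression"])
            crit = ScreeningCriteria(**cfg.get("screening", {}))
            screening = screen_candidates(mat, crit)
            results["screening"] = screening
            counts["screen_survivors"] = len(screening.survivors)
            screening.table.to_csv(out_dir / "screening.tsv", sep="\t")
            log.info("screening: %s", screening.stage_counts)
        except Exception as e:
            raise PipelineError("screen", e) from e

    try:
        methods = list(cfg.get("methods", METHODS))
        tables = run_all_methods(ct, efficiency=cfg.get("efficiency", 2.0), methods=methods)
        tidy = tidy_stability(tables)
        tidy.to_csv(out_dir / "stability.tsv", sep="\t", index=False, float_format="%.9g")
        results["stability"] = tables
        counts["stability_rows"] = len(tidy)
        log.info("stability: %d methods, %d rows", len(tables), len(tidy))
    except Exception as e:
        raise PipelineError("stability", e) from e

    try:
        ranks = pd.DataFrame({m: tables[m]["rank"] for m in methods})
        consensus = reffinder_geomean(ranks)
        consensus.to_csv(out_dir / "consensus.tsv", sep="\t", float_format="%.9g")
        results["consensus"] = consensus
        counts["consensus_rows"] = len(consensus)

        k = int(cfg.get("topk", 5))
        rank_series = {m: tables[m]["rank"] for m in methods}
        core = topk_intersection(rank_series, k=k)
        per_method_top = {m: topk_intersection([s], k=k) for m, s in rank_series.items()}
        venn = pd.DataFrame(
            {m: {g: g in top for g in ct.gene_ids} for m, top in per_method_top.items()}
        )
        venn["in_all"] = [g in core for g in venn.index]
        venn.index.name = "gene"
        venn.to_csv(out_dir / "venn.tsv", sep="\t")
        results["topk_core"] = core
        counts["topk_core"] = len(core)
        log.info("consensus core (top %d of every method): %s", k, sorted(core))
    except Exception as e:
        raise PipelineError("consensus", e) from e

    try:
        qcfg = cfg.get("quantify")
        if qcfg is None:
            gres = tables["genorm"].attrs.get("result") if "genorm" in tables else None
            qcfg = _default_quantify(ct, consensus, gres.optimal_n if gres else None)
        quant = ddct_fold_change(
            ct,
            target=qcfg["target"],
            refs=qcfg["refs"],
            calibrator_group=qcfg["calibrator"],
            treatment_group=qcfg["treatment"],
            efficiency=cfg.get("efficiency", 2.0),
        )
        shifts = {
            r: reference_shift(ct, r, qcfg["calibrator"], qcfg["treatment"])
            for r in quant.refs
        }
        qtable = pd.DataFrame(
            [
                {
                    "target": quant.target,
                    "refs": ",".join(quant.refs),
                    "calibrator": quant.calibrator_group,
                    "treatment": quant.treatment_group,
                    "ddct": quant.ddct,
                    "fold_change": quant.fold_change,
                    "p_value": quant.p_value,
                    "tier": quant.tier,
                    "ref_shifts": ";".join(f"{r}={s:.4f}" for r, s in shifts.items()),
                }
            ]
        )
        qtable.to_csv(out_dir / "quant.tsv", sep="\t", index=False, float_format="%.9g")
        results["quantification"] = quant
        results["reference_shifts"] = shifts
        counts["quant_rows"] = len(qtable)
        log.info("quantified %s vs refs %s: fold %.3g", quant.target, quant.refs, quant.fold_change)
    except Exception as e:
        raise PipelineError("quantify", e) from e

    rio.write_run_metadata(
        out_dir / "run.json",
        parameters={**cfg, "stage_counts": counts},
        seed=cfg.get("seed"),
    )
    results["stage_counts"] = counts
    results["out_dir"] = out_dir
    return results
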