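"""End-to-end pipeline orchestration.

``run_pipeline`` executes the enabled stages in dependency order —
simulate -> encode -> train -> score -> cluster -> classify -> evaluate ->
tmb -> rrg — against one flat, schema-validated configuration with a single
global seed.  Each stage writes its artifact(s) plus a JSON manifest holding
the stage parameters, the derived stage seed and the SHA-256 of every input
file, so a rerun with identical config and inputs reproduces byte-identical
artifacts and manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import model as pmodel
from . import pairs as ppairs
from . import simulate as psim
from . import subtypes as psub
from . import surveval as pse
from .characterize import compute_tmb, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

STAGES = ("simulate", "encode", "train", "score", "cluster", "classify", "evaluate", "tmb")

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "expression", "clinical", "mutations",
    "signature_genes", "simulate", "encode", "train", "score", "cluster",
    "evaluate", "tmb",
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Stage seed from (global seed, stage name) by stable hashing, < 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _manifest(out_dir: Path, stage: str, params: dict, seed: int | None,
              inputs: list[Path], outputs: list[Path]) -> None:
    payload = {
        "stage": stage,
        "params": params,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def validate_config(config: dict) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("config requires a global 'seed'")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    for key in ("expression", "clinical", "mutations"):
        if key in config and not Path(config[key]).exists():
            raise ValueError(f"input path for {key!r} does not exist: {config[key]}")
    return config


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the enabled stages; returns a report dict with per-stage results."""
    config = validate_config(dict(config))
    out = Path(out_dir or config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stages = config.get("stages", list(STAGES))
    report: dict = {"stages_run": []}

    expr_path = Path(config["expression"]) if "expression" in config else out / "expression.tsv"
    clin_path = Path(config["clinical"]) if "clinical" in config else out / "clinical.tsv"

    if "simulate" in stages:
        params = dict(config.get("simulate", {}))
        sseed = derive_seed(seed, "simulate")
        cohort = psim.simulate_cohort(psim.SimulationConfig(seed=sseed, **params))
        pio.write_expression(cohort.expression, expr_path)
        pio.write_clinical(cohort.survival, clin_path)
        subtype_path = out / "true_subtypes.tsv"
        cohort.true_subtype.to_csv(subtype_path, sep="\t")
        _manifest(out, "simulate", params, sseed, [], [expr_path, clin_path, subtype_path])
        report["stages_run"].append("simulate")
        report["simulate"] = {"n_samples": cohort.expression.shape[1],
                              "n_genes": cohort.expression.shape[0]}

    expr = pio.read_expression(expr_path) if expr_path.exists() else None
    clinical = pio.read_clinical(clin_path) if clin_path.exists() else None
    signature = config.get("signature_genes")
    if signature is None and expr is not None:
        signature = list(expr.index)

    pfm = None
    if "encode" in stages:
        params = {"low": 0.2, "high": 0.8, **config.get("encode", {})}
        gene_list = [g for g in signature if g in expr.index]
        all_pairs = ppairs.enumerate_pairs(gene_list)
        pfm = ppairs.encode_pairs(expr, all_pairs)
        enc_path = out / "pair_indicators.tsv"
        pfm.indicators.to_csv(enc_path, sep="\t")
        _manifest(out, "encode", params, None, [expr_path], [enc_path])
        report["stages_run"].append("encode")
        report["encode"] = {"pairs_enumerated": len(all_pairs)}

    model = None
    funnel = None
    if "train" in stages:
        params = {"alpha": 0.05, "folds": 10, "low": 0.2, "high": 0.8, "keep_alpha": 0.05,
                  **config.get("train", {})}
        tseed = derive_seed(seed, "train")
        model, funnel = pmodel.train_funnel(
            pfm, clinical, alpha=params["alpha"], n_folds=params["folds"], seed=tseed,
            low=params["low"], high=params["high"], keep_alpha=params["keep_alpha"],
        )
        model_path = out / "model.json"
        pio.write_model(model, model_path)
        _manifest(out, "train", params, tseed, [expr_path, clin_path], [model_path])
        report["stages_run"].append("train")
        report["train"] = funnel.as_dict()
        if not model.terms:
            report["train"]["note"] = "no prognostic pairs"

    scores = None
    if "score" in stages:
        params = dict(config.get("score", {}))
        if params.get("published"):
            model = pmodel.published_model()
        if model is None:
            model = pio.read_model(out / "model.json")
        if model.terms:
            scores = pmodel.score_expression(model, expr)
            score_path = out / "scores.tsv"
            scores.to_csv(score_path, sep="\t")
            _manifest(out, "score", params, None, [expr_path], [score_path])
            report["score"] = {
                "n_high": int((scores["risk_group"] == "high").sum()),
                "n_low": int((scores["risk_group"] == "low").sum()),
                "cutoff": model.cutoff,
            }
        else:
            report["score"] = {"note": "no prognostic pairs; scoring skipped"}
        report["stages_run"].append("score")

    if "cluster" in stages:
        params = {"k_range": [2, 3, 4, 5, 6], "reps": 1000, "subsample": 0.8,
                  **config.get("cluster", {})}
        cseed = derive_seed(seed, "cluster")
        sig_expr = expr.loc[[g for g in signature if g in expr.index]]
        cons = psub.consensus_cluster(
            sig_expr, k_range=tuple(params["k_range"]), reps=params["reps"],
            subsample=params["subsample"], seed=cseed,
        )
        lab_path = out / "subtypes.tsv"
        cons.labels[cons.chosen_k].to_csv(lab_path, sep="\t")
        _manifest(out, "cluster", params, cseed, [expr_path], [lab_path])
        report["stages_run"].append("cluster")
        report["cluster"] = {"chosen_k": cons.chosen_k,
                             "cdf_area": {k: round(v, 6) for k, v in cons.cdf_area.items()}}

    if "evaluate" in stages and scores is not None:
        params = {"horizons": [1, 3, 5], "time_unit": "days", **config.get("evaluate", {})}
        auc = pse.td_auc(scores["mkpc_score"], clinical,
                         horizons=tuple(params["horizons"]), time_unit=params["time_unit"])
        groups = {
            g: clinical.loc[scores.index[scores["risk_group"] == g].intersection(clinical.index)]
            for g in ("high", "low")
        }
        if all(len(v) for v in groups.values()):
            chi2, p = pse.logrank_test(groups)
        else:
            chi2, p = float("nan"), float("nan")
        eval_path = out / "evaluation.json"
        payload = {"auc": {k: (None if np.isnan(v) else v) for k, v in auc.items()},
                   "logrank_chi_square": chi2, "logrank_p": p}
        eval_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        _manifest(out, "evaluate", params, None, [expr_path, clin_path], [eval_path])
        report["stages_run"].append("evaluate")
        report["evaluate"] = payload

    if "tmb" in stages and "mutations" in config:
        params = {"exome_mb": 38.0, **config.get("tmb", {})}
        mut = pio.read_maf_lite(config["mutations"])
        roster = list(expr.columns) if expr is not None else None
        tmb = compute_tmb(mut, exome_size_mb=params["exome_mb"], sample_roster=roster)
        tmb_path = out / "tmb.tsv"
        tmb.to_csv(tmb_path, sep="\t")
        report["tmb"] = {"n_samples": len(tmb)}
        if scores is not None:
            common = tmb.index.intersection(scores.index)
            if len(common) and scores.loc[common, "risk_group"].nunique() == 2:
                res = wilcoxon_rank_sum(tmb.loc[common, "tmb"], scores.loc[common, "risk_group"])
                report["tmb"]["wilcoxon_p"] = res["p"]
        _manifest(out, "tmb", params, None, [Path(config["mutations"])], [tmb_path])
        report["stages_run"].append("tmb")

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
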