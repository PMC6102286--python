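"""End-to-end orchestration: simulate/load -> correct -> discover -> validate.

``run_pipeline`` executes the whole analysis — delta computation, quantile
normalization, batch regression, the progressive PC-correction sweep,
cross-ancestry panel evaluation per correction level, panel-size
refinement at the best correction, permutation p-values for the final
panel, and the cholesterol-ester association scan — and writes every
table plus a JSON summary to the output directory.  All randomness flows
from the config seed, so a fixed config reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, io, preprocess, signature
from .association import panel_phenotype_scan
from .preprocess import DeltaExpression
from .simulate import StudyData, simulate_study

__all__ = ["PipelineResult", "run_pipeline", "prepare_delta"]

log = logging.getLogger("statinsig")


@dataclass
class PipelineResult:
    config: io.RunConfig
    phenotypes: pd.DataFrame
    pc_evals: list
    best_k: int
    gene_evals: list
    best_n: int
    signature: signature.SignatureTable
    panel: list[str]
    association: pd.DataFrame
    summary: dict


def _load_inputs(config: io.RunConfig):
    if config.simulation is not None:
        sim = config.simulation
        if sim.seed != config.seed:
            sim = sim.replace(seed=config.seed)
        study = simulate_study(sim)
        return (study.expression.statin, study.expression.control,
                study.phenotypes, study)
    statin = io.load_expression(config.statin_path)
    control = io.load_expression(config.control_path)
    phenotypes = io.load_phenotypes(config.phenotype_path)
    return statin, control, phenotypes, None


def prepare_delta(statin: pd.DataFrame, control: pd.DataFrame,
                  phenotypes: pd.DataFrame) -> DeltaExpression:
    """Delta -> quantile normalization -> batch regression."""
    delta = preprocess.compute_delta(statin, control)
    delta = preprocess.quantile_normalize(delta)
    batch = phenotypes.set_index("sample_id")["batch"]
    return preprocess.regress_out_batch(delta, batch)


def _labels(phenotypes: pd.DataFrame, ancestry: str) -> pd.Series:
    pheno = phenotypes.set_index("sample_id")
    lab = pheno["responder_class"].where(pheno["ancestry"] == ancestry, "none")
    return lab


def run_pipeline(config: io.RunConfig, output_dir=None) -> PipelineResult:
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_file_log(outdir / "run.log")
    written: list[str] = []

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        df.to_csv(outdir / name, sep="\t", float_format="%.10g", **kw)
        written.append(name)

    logged = {k: v for k, v in io._config_to_dict(config).items()
              if not k.endswith(("_dir", "_path"))}  # keep the log path-free
    log.info("config: %s", json.dumps(logged, sort_keys=True))

    stage = "inputs"
    try:
        statin, control, phenotypes, study = _load_inputs(config)
        if config.simulation is not None:
            io.write_expression(statin, outdir / "statin.tsv")
            io.write_expression(control, outdir / "control.tsv")
            io.write_phenotypes(phenotypes, outdir / "phenotypes.tsv")
            (outdir / "planted_genes.txt").write_text(
                "\n".join(study.expression.planted_genes) + "\n")
            written += ["statin.tsv", "control.tsv", "phenotypes.tsv",
                        "planted_genes.txt"]

        stage = "preprocess"
        delta = prepare_delta(statin, control, phenotypes)
        pca = preprocess.pca_samples(delta)
        k_max = min(config.k_max, pca.scores.shape[1])
        datasets = preprocess.pc_correction_sweep(
            delta, k_max, pca, recompute_pca_per_k=config.recompute_pca_per_k)
        diag = preprocess.pc_covariate_diagnostics(pca, phenotypes)
        save(diag, "pc_covariate_diagnostics.tsv", index=False)

        stage = "pc_sweep"
        ea = _labels(phenotypes, "EA")
        aa = _labels(phenotypes, "AA")
        pc_evals = classify.pc_sweep_eval(
            datasets, ea, aa, n_top_genes=config.n_top_genes,
            n_repeats=config.n_repeats, seed=config.seed,
            s0_method=config.s0_method,
            train_on_discovery=config.train_on_discovery)
        aucs = np.array([e.auc for e in pc_evals])
        best_k = int(np.lexsort((np.arange(1, k_max + 1), -aucs))[0]) + 1
        save(pd.DataFrame({"n_pcs": range(1, k_max + 1), "auc": aucs,
                           "n_repeats": config.n_repeats,
                           "seed": config.seed}),
             "pc_sweep.tsv", index=False)
        log.info("pc sweep: best k = %d (AUC %.3f)", best_k, aucs[best_k - 1])

        stage = "gene_count_sweep"
        best_ds = datasets[best_k - 1]
        grid = [n for n in range(config.n_grid_start, config.n_grid_stop + 1)
                if n <= len(best_ds.gene_ids)]
        gene_evals, best_n = classify.gene_count_sweep(
            best_ds, ea, aa, grid, n_repeats=config.n_repeats,
            seed=config.seed, s0_method=config.s0_method)
        save(pd.DataFrame({"n_genes": grid,
                           "auc": [e.auc for e in gene_evals],
                           "n_repeats": config.n_repeats,
                           "seed": config.seed}),
             "gene_count_sweep.tsv", index=False)
        best_eval = gene_evals[grid.index(best_n)]
        save(pd.DataFrame(best_eval.roc_points, columns=["fpr", "tpr"]),
             "roc_points.tsv", index=False)
        log.info("gene sweep: best n = %d (AUC %.3f)", best_n, best_eval.auc)

        stage = "signature"
        sig = signature.compute_signature(
            best_ds, ea, s0_method=config.s0_method, B=config.B,
            seed=config.seed)
        panel = signature.top_k_genes(sig, best_n)
        out_table = sig.table.sort_values("rank")
        save(out_table, "signature_table.tsv", index=True)
        (outdir / "signature_meta.json").write_text(json.dumps({
            "s0": sig.s0, "s0_method": sig.s0_method,
            "n_permutations": sig.n_permutations, "seed": config.seed,
            "p_floor": sig.floor}, indent=2, sort_keys=True))
        written.append("signature_meta.json")
        (outdir / "panel_genes.txt").write_text("\n".join(panel) + "\n")
        written.append("panel_genes.txt")

        stage = "association"
        assoc = None
        if "ce_delta" in phenotypes.columns and \
                phenotypes["ce_delta"].notna().sum() >= 3:
            ce = phenotypes.set_index("sample_id")["ce_delta"]
            assoc = panel_phenotype_scan(best_ds, panel, ce)
            save(assoc, "ce_association.tsv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    n_floor = int(sig.table["floor_flag"].sum())
    best_auc = float(best_eval.auc)
    null_band = (0.35, 0.65)
    summary = {
        "best_n_pcs": best_k,
        "best_n_genes": best_n,
        "auc_by_n_pcs": {str(k + 1): float(a) for k, a in enumerate(aucs)},
        "best_auc": best_auc,
        "auc_within_null_band": bool(null_band[0] <= best_auc <= null_band[1]),
        "s0": sig.s0,
        "n_permutations": config.B,
        "p_value_floor": sig.floor,
        "n_genes_at_p_floor": n_floor,
        "seed": config.seed,
        "n_repeats": config.n_repeats,
        "outputs": sorted(written + ["summary.json"]),
    }
    if assoc is not None:
        top = assoc.iloc[0]
        summary["top_association"] = {
            "gene_id": top["gene_id"], "rho": float(top["rho"]),
            "p_raw": float(top["p_raw"]),
            "p_adjusted": float(top["p_adjusted"]),
            "significant_after_bonferroni": bool(top["p_adjusted"] < 0.05),
        }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True))
    log.info("wrote summary.json")

    return PipelineResult(
        config=config, phenotypes=phenotypes, pc_evals=pc_evals,
        best_k=best_k, gene_evals=gene_evals, best_n=best_n, signature=sig,
        panel=panel, association=assoc, summary=summary)


def _setup_file_log(path: Path) -> None:
    # timestamp-free format keeps repeated runs byte-identical
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
            h.close()
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
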