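"""End-to-end orchestration with plain-file handoffs between stages.

Stages: simulate -> combat -> profile -> cluster -> score -> survival ->
gsea -> mutation. Every stage reads its inputs from files and writes its
outputs back to the run directory, so any stage can be re-run in isolation;
a run manifest records config hash, per-stage seeds, file checksums and
timings. A stage failure aborts downstream stages; partial outputs are kept.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, batch_correction, enrichment, io_core
from . import mutation_landscape as ml
from . import pattern_discovery as pdisc
from . import signature_score as sigsc
from . import survival_analysis as surv
from . import synthetic_cohort as synth
from . import tme_profiling as tme

ALL_STAGES = [
    "simulate",
    "combat",
    "profile",
    "cluster",
    "score",
    "survival",
    "gsea",
    "mutation",
]

DEFAULT_CONFIG: dict = {
    "stages": ALL_STAGES,
    "inputs": {},  # expression/clinical/maf/gmt/signature_matrix paths when not simulating
    "simulate": {"n_samples": 300, "n_genes": 2000},
    "combat": {"batch_col": "cohort"},
    "profile": {"nu_grid": [0.25, 0.5, 0.75], "n_perm": 100, "ssgsea_alpha": 0.25},
    "cluster": {"k_min": 2, "k_max": 6, "reps": 200, "p_item": 0.8, "elbow": 0.1,
                "filter_fractions": True},
    "score": {"deg_alpha": 0.05, "deg_fc": 1.5, "boruta_alpha": 0.01,
              "boruta_max_iter": 100, "n_trees": 500},
    "survival": {"horizons_years": [3, 5, 10], "cut_bounds": [0.1, 0.9]},
    "gsea": {"n_perm": 100, "weight": 1.0},
    "mutation": {"exome_mb": 38.0, "top_n": 20},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict | None, out_dir, seed: int = 0) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    config = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in config["stages"]]

    inputs = config["inputs"]
    if "simulate" not in stages:
        if "expression" not in inputs:
            raise ValueError("stage 'combat': no expression input and simulate disabled")
        if "mutation" in stages and "maf" not in inputs:
            raise ValueError("stage 'mutation': enabled but config provides no MAF input")

    ss = np.random.SeedSequence(seed)
    stage_seeds = {
        s: int(v) % (2**31 - 1) for s, v in zip(ALL_STAGES, ss.generate_state(len(ALL_STAGES)))
    }
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stage_seeds": {s: stage_seeds[s] for s in stages},
        "version": __version__,
        "stages": {},
    }

    paths = {
        "expression": out / "expression.tsv",
        "clinical": out / "clinical.tsv",
        "maf": out / "mutations.maf",
        "gmt": out / "marker_sets.gmt",
        "signature_matrix": out / "signature_matrix.tsv",
        "expression_adjusted": out / "expression_adjusted_log2.tsv",
        "fractions": out / "cell_fractions.tsv",
        "fraction_stats": out / "cell_fraction_stats.tsv",
        "ssgsea": out / "ssgsea_scores.tsv",
        "estimate": out / "estimate_scores.tsv",
        "assignments": out / "cluster_assignments.tsv",
        "k_selection": out / "k_selection.json",
        "deg": out / "deg_table.tsv",
        "signatures": out / "ici_signatures.gmt",
        "scores": out / "ici_scores.tsv",
        "survival": out / "survival_summary.json",
        "calibration": out / "calibration.tsv",
        "gsea": out / "gsea_results.tsv",
        "tmb": out / "tmb.tsv",
        "mutation_freq": out / "mutation_frequencies.tsv",
        "mutation_assoc": out / "mutation_summary.json",
    }
    for key, p in inputs.items():
        if key in paths:
            paths[key] = Path(p)

    def _record(stage: str, status: str, t0: float, outputs: list, error: str | None = None):
        manifest["stages"][stage] = {
            "status": status,
            "seconds": round(time.time() - t0, 3),
            "outputs": {
                str(p.name): _sha256(p) for p in outputs if Path(p).exists()
            },
            **({"error": error} if error else {}),
        }

    failed = False
    for stage in stages:
        t0 = time.time()
        if failed:
            manifest["stages"][stage] = {"status": "skipped (upstream failure)"}
            continue
        try:
            outputs = _run_stage(stage, config, paths, stage_seeds[stage])
            _record(stage, "complete", t0, outputs)
        except Exception as exc:  # noqa: BLE001 - manifest must record any failure
            _record(stage, "failed", t0, [], error=f"{type(exc).__name__}: {exc}")
            failed = True

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _run_stage(stage: str, config: dict, paths: dict, seed: int) -> list:
    if stage == "simulate":
        sim_cfg = {k: v for k, v in config["simulate"].items()}
        sim_cfg["seed"] = seed
        cohort = synth.simulate_cohort(synth.CohortConfig(**sim_cfg))
        written = synth.write_cohort(cohort, paths["expression"].parent)
        return [Path(p) for p in written.values()]

    if stage == "combat":
        expr = io_core.read_expression(paths["expression"]).to_log2()
        clinical = io_core.read_clinical(paths["clinical"])
        batch = clinical.loc[expr.sample_ids, config["combat"]["batch_col"]]
        adjusted, _ = batch_correction.combat_adjust(expr, batch)
        io_core.write_expression(adjusted, paths["expression_adjusted"])
        return [paths["expression_adjusted"]]

    if stage == "profile":
        cfg = config["profile"]
        expr = io_core.read_expression(paths["expression_adjusted"], log2_scale=True)
        sets = io_core.read_gmt(paths["gmt"])
        scores = tme.ssgsea_scores(expr, sets, alpha=cfg["ssgsea_alpha"])
        io_core.write_table(scores.scores, paths["ssgsea"])
        stromal = sets["stromal_signature"] if "stromal_signature" in sets.sets else sets[list(sets)[0]]
        immune = sets["immune_signature"] if "immune_signature" in sets.sets else sets[list(sets)[-1]]
        est = tme.estimate_scores(expr, stromal, immune, alpha=cfg["ssgsea_alpha"])
        io_core.write_table(est, paths["estimate"])
        sig = pd.read_csv(paths["signature_matrix"], sep="\t", index_col=0)
        marker_names = [n for n in sets.sets if n.endswith("_markers")]
        if marker_names:
            # Deconvolution runs on the discriminative marker genes, the way
            # leukocyte signature matrices are built.
            markers = sorted(set().union(*(sets[n] for n in marker_names)))
            sig = sig.loc[[g for g in markers if g in sig.index]]
        lin = expr.to_linear()
        frac = tme.deconvolve_fractions(
            lin, sig, nu_grid=tuple(cfg["nu_grid"]), n_perm=cfg["n_perm"], seed=seed
        )
        io_core.write_table(frac.fractions, paths["fractions"])
        diag = pd.DataFrame(
            {
                "p_value": frac.p_value,
                "correlation": frac.correlation,
                "rmse": frac.rmse,
                "nu": frac.nu,
                "invalid": frac.invalid,
            }
        )
        io_core.write_table(diag, paths["fraction_stats"])
        return [paths["ssgsea"], paths["estimate"], paths["fractions"], paths["fraction_stats"]]

    if stage == "cluster":
        cfg = config["cluster"]
        fractions = pd.read_csv(paths["fractions"], sep="\t", index_col=0)
        if cfg["filter_fractions"]:
            diag = pd.read_csv(paths["fraction_stats"], sep="\t", index_col=0)
            keep = diag.index[(diag["p_value"] < 0.05) & (~diag["invalid"].astype(bool))]
            if len(keep) >= max(10, cfg["k_max"] + 1):
                fractions = fractions.loc[keep]
        results = pdisc.consensus_sweep(
            fractions,
            range(cfg["k_min"], cfg["k_max"] + 1),
            reps=cfg["reps"],
            p_item=cfg["p_item"],
            seed=seed,
        )
        sel = pdisc.select_k(results, elbow=cfg["elbow"])
        chosen = results[sel.chosen_k]
        io_core.write_table(chosen.assignments.to_frame(), paths["assignments"])
        for k, res in results.items():
            io_core.write_table(
                res.consensus_matrix, paths["assignments"].parent / f"consensus_k{k}.tsv"
            )
        with open(paths["k_selection"], "w") as fh:
            json.dump(
                {
                    "k_range": sel.k_range,
                    "delta_area": {str(k): v for k, v in sel.delta_area.items()},
                    "chosen_k": sel.chosen_k,
                },
                fh,
                indent=2,
            )
        return [paths["assignments"], paths["k_selection"]]

    if stage == "score":
        cfg = config["score"]
        expr = io_core.read_expression(paths["expression_adjusted"], log2_scale=True)
        assignments = pd.read_csv(paths["assignments"], sep="\t", index_col=0)["cluster"]
        est = pd.read_csv(paths["estimate"], sep="\t", index_col=0)
        common = [s for s in expr.sample_ids if s in assignments.index]
        sub = io_core.ExpressionMatrix(expr.data[common], log2_scale=True)
        deg, degs, gclust, partition, scores = sigsc.derive_ici_signature(
            sub,
            assignments.loc[common],
            immune_score=est["immune_score"],
            alpha=cfg["deg_alpha"],
            fc=cfg["deg_fc"],
            boruta_alpha=cfg["boruta_alpha"],
            boruta_max_iter=cfg["boruta_max_iter"],
            n_trees=cfg["n_trees"],
            seed=seed,
        )
        io_core.write_table(deg.table, paths["deg"])
        sig_sets = io_core.GeneSetCollection(
            {
                "signature_A": set(partition.signature_A),
                "signature_B": set(partition.signature_B),
                "signature_A_selected": set(partition.selected_A),
                "signature_B_selected": set(partition.selected_B),
            }
        )
        io_core.write_gmt(sig_sets, paths["signatures"])
        scores["gene_cluster"] = gclust
        clinical = io_core.read_clinical(paths["clinical"])
        merged = scores.join(clinical[["os_time", "os_event"]], how="inner").dropna()
        cut, _ = surv.optimal_cutpoint(
            merged["ici_score"], merged["os_time"], merged["os_event"],
            bounds=tuple(config["survival"]["cut_bounds"]),
        )
        scores = sigsc.dichotomize_scores(scores, cut)
        io_core.write_table(scores, paths["scores"])
        return [paths["deg"], paths["signatures"], paths["scores"]]

    if stage == "survival":
        cfg = config["survival"]
        scores = pd.read_csv(paths["scores"], sep="\t", index_col=0)
        clinical = io_core.read_clinical(paths["clinical"])
        df = scores.join(clinical[["os_time", "os_event", "age"]], how="inner").dropna(
            subset=["os_time", "os_event"]
        )
        chi2, dof, p = surv.logrank_test(df["os_time"], df["os_event"], df["group"])
        model = surv.cox_fit(
            df[["ici_score", "age"]], df["os_time"], df["os_event"], stepwise=True
        )
        nomo = surv.build_nomogram(
            model, df, horizons_years=tuple(cfg["horizons_years"])
        )
        cal_frames = []
        for h in nomo.horizons_months:
            if np.isnan(nomo.baseline_at_horizons[h]):
                continue
            cal = surv.calibration_curve(
                model, df, df["os_time"], df["os_event"], horizon=h
            )
            cal["horizon_months"] = h
            cal_frames.append(cal)
        if cal_frames:
            io_core.write_table(pd.concat(cal_frames), paths["calibration"], index=False)
        summary = {
            "logrank": {"chi2": chi2, "df": dof, "p": p,
                        "note": "groups from a maximally selected cutpoint; p uncorrected"},
            "cox": {
                "coefficients": model.coefficients.to_dict(),
                "standard_errors": model.standard_errors.to_dict(),
                "aic": model.aic,
                "covariates": model.covariates,
            },
            "nomogram": {
                "reference": nomo.reference.to_dict(),
                "scale": nomo.scale,
                "baseline_at_horizons_months": {
                    str(k): (None if np.isnan(v) else v)
                    for k, v in nomo.baseline_at_horizons.items()
                },
            },
        }
        with open(paths["survival"], "w") as fh:
            json.dump(summary, fh, indent=2)
        return [paths["survival"], paths["calibration"]]

    if stage == "gsea":
        cfg = config["gsea"]
        expr = io_core.read_expression(paths["expression_adjusted"], log2_scale=True)
        scores = pd.read_csv(paths["scores"], sep="\t", index_col=0)
        sets = io_core.read_gmt(paths["gmt"])
        ranked = enrichment.rank_genes(expr, scores["group"])
        res = enrichment.gsea(
            ranked, sets, weight=cfg["weight"], n_perm=cfg["n_perm"], seed=seed
        )
        table = res.table.copy()
        table["leading_edge"] = table["leading_edge"].map(lambda g: ",".join(g))
        io_core.write_table(table, paths["gsea"])
        return [paths["gsea"]]

    if stage == "mutation":
        cfg = config["mutation"]
        maf = io_core.read_maf(paths["maf"])
        scores = pd.read_csv(paths["scores"], sep="\t", index_col=0)
        samples = scores.index.tolist()
        tmb = ml.compute_tmb(maf, exome_mb=cfg["exome_mb"], samples=samples)
        io_core.write_table(tmb.table, paths["tmb"])
        freq = ml.mutation_frequencies(maf, samples, scores["group"], top_n=cfg["top_n"])
        io_core.write_table(freq.table, paths["mutation_freq"])
        rates = ml.compare_mutation_rates(freq.oncoprint, scores["group"])
        rho, p_rho = ml.spearman_assoc(
            scores.loc[samples, "ici_score"], tmb.table.loc[samples, "tmb"]
        )
        groups = scores["group"]
        stat, p_grp, test = surv.compare_groups(
            tmb.table.loc[samples, "tmb"], groups.loc[samples]
        )
        summary = {
            "tmb_spearman": {"rho": rho, "p": p_rho},
            "tmb_group_test": {"stat": stat, "p": p_grp, "test": test},
            "per_gene_rates": rates.reset_index().to_dict(orient="records"),
        }
        with open(paths["mutation_assoc"], "w") as fh:
            json.dump(summary, fh, indent=2)
        return [paths["tmb"], paths["mutation_freq"], paths["mutation_assoc"]]

    raise ValueError(f"unknown stage {stage!r}")
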