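"""End-to-end experiment: simulate -> normalize -> score -> resample ->
Cox -> genome-wide scan -> enrichment -> benchmark.

The orchestration mirrors the benchmarking study design: train published
style signatures (a 10-gene rank-linear model and a 31-gene PCR model) on a
cell-line panel; apply them to pooled clinical cohorts with cohort-stratified
Cox models; compare them against size- and form-matched resampled control
signatures; quantify normalization-induced disagreement of signature scores
with Bland-Altman limits; scan every gene for univariate prognostic signal;
and run ORA/GSEA against a synthetic gene-set collection.
"""

from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import genescan, io, normalize, resample, signatures, survival, synthdata
from .config import RunConfig, child_seed

log = logging.getLogger("radbench")


def _sim_config(cfg: RunConfig, seed: int) -> synthdata.SimulationConfig:
    sim = {k: v for k, v in cfg["simulation"].items() if k != "cohort_spec"}
    if sim.get("biology_seed") is None:
        sim["biology_seed"] = child_seed(cfg.seed, "biology")
    return synthdata.SimulationConfig(**sim, seed=seed)


def _stage(name):
    t0 = _time.perf_counter()
    log.info("stage %s started", name)
    return lambda: log.info("stage %s done in %.1fs", name,
                            _time.perf_counter() - t0)


def run_experiment(cfg: RunConfig, outdir=None) -> dict:
    """Run the full benchmarking experiment; returns the report dict.

    Writes per-stage TSV/JSON outputs plus a resolved-config snapshot under
    ``outdir`` (config ``outdir`` by default).
    """
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.snapshot(outdir / "resolved_config.json")
    chash = cfg.hash()
    seed = cfg.seed
    report: dict = {"seed": seed, "config_hash": chash}

    # ---- synthetic inputs -------------------------------------------------
    done = _stage("simulate")
    sig_rng = np.random.default_rng(child_seed(seed, "signature_genes"))
    sim_panel = _sim_config(cfg, child_seed(seed, "panel"))
    genes = synthdata.gene_ids(sim_panel.n_genes)
    scfg = cfg["signatures"]
    k10 = scfg["n_rank_linear_genes"]
    k31 = scfg["n_pcr_genes"]
    kim_genes = list(sig_rng.choice(genes, size=k31, replace=False))
    # redraw the generating gene set if a gene ends up with a constant
    # within-line rank (collinear design), mirroring the resampling stage
    for attempt in range(100):
        rsi_genes = list(sig_rng.choice(genes, size=k10, replace=False))
        rsi_coefs = sig_rng.normal(0.0, scfg["coef_sd"], size=k10)
        rsi_coefs -= rsi_coefs.mean()  # sum-zero gauge of the rank model
        panel = synthdata.simulate_cell_line_panel(
            sim_panel, rsi_genes, rsi_coefs,
            intercept=scfg["sf2_intercept"], sf2_link=scfg["sf2_link"])
        try:
            signatures.train_rank_linear(panel, rsi_genes)
            break
        except ValueError:
            log.info("redrawing generating signature (attempt %d)", attempt + 1)
    else:
        raise RuntimeError("could not draw a trainable generating signature")
    sim_clin = _sim_config(cfg, child_seed(seed, "cohorts"))
    cohort_spec = cfg["simulation"]["cohort_spec"]
    if cohort_spec is not None:
        cohort_spec = [tuple(entry) for entry in cohort_spec]
    else:
        cohort_spec = synthdata.DEFAULT_COHORT_SPEC
    cohorts = synthdata.simulate_clinical_cohorts(sim_clin, cohort_spec)
    io.write_clinical(cohorts, outdir / "clinical.csv", chash)
    report["n_patients_total"] = len(cohorts.clinical)
    done()

    # ---- signature training ----------------------------------------------
    done = _stage("train")
    rsi_like = signatures.train_rank_linear(
        panel, rsi_genes, rank_scope=scfg["rank_scope"],
        signature_id="rank_linear_10")
    kim_like = signatures.train_pcr(
        panel, kim_genes, variance_threshold=scfg["variance_threshold"],
        max_components=scfg["max_components"], signature_id="pcr_31")
    published = {rsi_like.signature_id: rsi_like,
                 kim_like.signature_id: kim_like}
    signatures.write_signature(rsi_like, outdir / "signature_rank_linear_10.tsv")
    done()

    # ---- grouping + published Cox fits ------------------------------------
    done = _stage("survival")
    groups = survival.group_patients(cohorts)
    wanted = cfg["groups"]
    if wanted:
        missing = set(wanted) - {g.label for g in groups}
        if missing:
            raise ValueError(f"requested group(s) with no cohort: {sorted(missing)}")
        groups = [g for g in groups if g.label in wanted]

    cov_cfg = cfg["covariate"]
    adjusted_groups = {}
    if cov_cfg["enabled"]:
        cov_cohorts = cov_cfg["cohorts"]
        cov_gene = cov_cfg["gene"] or genes[0]
        for g in groups:
            if not g.label.startswith("OS"):
                continue
            applicable = (cov_cohorts if cov_cohorts is not None
                          else [g.patients["cohort_id"].iloc[0]])
            applicable = [c for c in applicable
                          if (g.patients["cohort_id"] == c).any()]
            if not applicable:
                continue
            vals = cohorts.expr.loc[cov_gene]
            adjusted_groups[g.label] = survival.attach_cohort_covariate(
                g, cov_cfg["name"], vals, applicable)

    published_fits: dict[str, dict[str, survival.CoxResult]] = {}
    rows = []
    for g in groups:
        published_fits[g.label] = {}
        for sid, sig in published.items():
            sv = signatures.score(sig, cohorts.expr)
            fit = survival.fit_cox(g, sv)
            published_fits[g.label][sid] = fit
            rows.append({"signature_id": sid, "group": g.label,
                         "adjusted": False, "n": fit.n, "events": fit.n_events,
                         "hr_per_sd": fit.hr_per_sd, "ci_lower": fit.ci_lower,
                         "ci_upper": fit.ci_upper, "p": fit.p,
                         "converged": fit.converged})
            if g.label in adjusted_groups:
                afit = survival.fit_cox(adjusted_groups[g.label], sv)
                rows.append({"signature_id": sid, "group": g.label,
                             "adjusted": True, "n": afit.n,
                             "events": afit.n_events,
                             "hr_per_sd": afit.hr_per_sd,
                             "ci_lower": afit.ci_lower,
                             "ci_upper": afit.ci_upper, "p": afit.p,
                             "converged": afit.converged})
    cox_table = pd.DataFrame(rows)
    cox_table.to_csv(outdir / "published_cox.tsv", sep="\t", index=False)
    done()

    # ---- resampled controls + benchmark -----------------------------------
    done = _stage("resample")
    rcfg = cfg["resample"]
    bench_rows = []
    prop_by_k: dict[str, dict[int, float]] = {g.label: {} for g in groups}
    for k in rcfg["sizes"]:
        # rank-linear needs n_lines >= k+2; larger sizes use PCR, which
        # remains well-posed when k exceeds the number of cell lines
        form = ("rank_linear" if (k <= len(panel.line_ids) - 2
                                  and k != cfg["signatures"]["n_pcr_genes"])
                else "pcr")
        rset = resample.generate_resampled(
            panel, k=k, n_signatures=rcfg["n_signatures"], model_form=form,
            seed=child_seed(seed, f"resample_k{k}"))
        score_mat = np.column_stack(
            [signatures.score(s, cohorts.expr).values.to_numpy()
             for s in rset.signatures])
        for g in groups:
            fits = _batch_cox(g, score_mat, cohorts)
            prop_by_k[g.label][k] = float(
                np.mean([f.p < rcfg["alpha"] for f in fits]))
            pub_id = (rsi_like.signature_id if form == "rank_linear"
                      and k == k10 else
                      kim_like.signature_id if k == k31 else None)
            if pub_id is not None:
                rep = resample.benchmark(published_fits[g.label][pub_id],
                                         fits, alpha=rcfg["alpha"])
                bench_rows.append({
                    "group": g.label, "k": k, "model_form": form,
                    "published_id": pub_id,
                    "published_hr": rep.published_hr,
                    "published_ci_lower": rep.published_ci[0],
                    "published_ci_upper": rep.published_ci[1],
                    "resampled_hr_mean": rep.resampled_hr_mean,
                    "resampled_hr_sd": rep.resampled_hr_sd,
                    "published_within_resampled": rep.published_within_resampled,
                    "percentile_of_published": rep.percentile_of_published,
                    "prop_resampled_significant": rep.prop_resampled_significant,
                })
    bench_table = pd.DataFrame(bench_rows)
    bench_table.to_csv(outdir / "benchmark.tsv", sep="\t", index=False)
    report["prop_resampled_significant_by_group_k"] = {
        lbl: {str(k): v for k, v in d.items()} for lbl, d in prop_by_k.items()}
    report["benchmark"] = bench_rows
    done()

    # ---- normalization agreement ------------------------------------------
    done = _stage("normalize")
    ncfg = cfg["normalization"]
    n_arr = min(ncfg["n_agreement_arrays"], len(cohorts.clinical))
    truth = cohorts.expr.iloc[:, :n_arr]
    sim_probe = _sim_config(cfg, child_seed(seed, "probes"))
    arrays = synthdata.expression_to_probes(truth, sim_probe)
    normed = {
        "mas5": normalize.normalize_mas5_style(
            arrays, trim_frac=ncfg["trim_frac"], target=ncfg["target"]),
        "rma": normalize.normalize_rma_style(arrays),
        "iron": normalize.normalize_iron_style(
            arrays, invariant_frac=ncfg["invariant_frac"],
            n_prune_iters=ncfg["n_prune_iters"]),
    }
    method_scores = {name: signatures.score(rsi_like, nx.expr).values
                     for name, nx in normed.items()}
    agree_rows = []
    for a, b in (("mas5", "rma"), ("mas5", "iron"), ("iron", "rma")):
        res = normalize.bland_altman(method_scores[a], method_scores[b])
        agree_rows.append({"pair": f"{a}_vs_{b}", "mean_diff": res.mean_diff,
                           "sd_diff": res.sd_diff, "loa_lower": res.loa_lower,
                           "loa_upper": res.loa_upper, "width": res.width,
                           "n": res.n})
    agree_table = pd.DataFrame(agree_rows)
    agree_table.to_csv(outdir / "agreement.tsv", sep="\t", index=False)
    report["agreement"] = agree_rows
    done()

    # ---- genome-wide scans ------------------------------------------------
    done = _stage("scan")
    scans: dict[str, genescan.GeneScanResult] = {}
    scan_summary = {}
    for g in groups:
        res = genescan.univariate_scan(g, cohorts.expr)
        scans[g.label] = res
        pv = res.converged_pvals()
        D, ks_p = genescan.pvalue_uniformity(pv)
        scan_summary[g.label] = {
            "prop_p_lt_0.05": genescan.proportion_significant(pv),
            "ks_D": D, "ks_p": ks_p,
            "n_genes_tested": res.n_genes_tested, "n_failed": res.n_failed}
        res.table.to_csv(outdir / f"scan_{g.label}.tsv", sep="\t")
    report["gene_scan"] = scan_summary
    done()

    # ---- enrichment -------------------------------------------------------
    done = _stage("enrichment")
    ecfg = cfg["enrichment"]
    special = {}
    if cohorts.truth is not None:
        prog = cohorts.truth.prognostic_genes
        if len(prog) >= ecfg["min_set"]:
            special["planted_prognostic"] = prog
        rt_genes = list(cohorts.truth.beta_rt.index[cohorts.truth.beta_rt != 0])
        if len(rt_genes) >= ecfg["min_set"]:
            special["planted_rt_specific"] = rt_genes
    collection = synthdata.simulate_gene_sets(
        genes, n_sets=ecfg["n_sets"], min_size=ecfg["min_size"],
        max_size=ecfg["max_size"], seed=child_seed(seed, "gene_sets"),
        special_sets=special)
    io.write_gmt(collection, outdir / "gene_sets.gmt")

    enr_summary = {}
    for sid, sig in published.items():
        res = enr.ora(sig.genes, collection, min_overlap=ecfg["min_overlap"])
        res.table.to_csv(outdir / f"ora_{sid}.tsv", sep="\t", index=False)
        clusters = enr.reduce_terms(res, collection,
                                    ecfg["similarity_threshold"], ecfg["alpha"])
        enr_summary[f"ora_{sid}"] = {
            "n_tested": len(res.table),
            "n_significant": int((res.table["p_adj"] < ecfg["alpha"]).sum())
            if len(res.table) else 0,
            "n_clusters": len(clusters.clusters)}

    def _ranked(tbl: pd.DataFrame):
        ok = tbl[tbl["converged"]]
        order = np.argsort(-ok["log_hr"].to_numpy(), kind="stable")
        return list(ok.index[order]), ok["log_hr"].to_numpy()[order]

    for lbl, scan in scans.items():
        rg, metric = _ranked(scan.table)
        res = enr.gsea_preranked(
            rg, metric, collection, weight_p=ecfg["weight_p"],
            n_perm=ecfg["n_perm"], seed=child_seed(seed, f"gsea_{lbl}"),
            min_set=ecfg["min_set"], max_set=ecfg["max_set"])
        res.table.to_csv(outdir / f"gsea_{lbl}.tsv", sep="\t", index=False)
        clusters = enr.reduce_terms(res, collection,
                                    ecfg["similarity_threshold"], ecfg["alpha"])
        enr_summary[f"gsea_{lbl}"] = {
            "n_tested": len(res.table),
            "n_significant": int((res.table["p_adj"] < ecfg["alpha"]).sum())
            if len(res.table) else 0,
            "n_clusters": len(clusters.clusters)}

    for outcome in ("FR", "OS"):
        rt_lbl, nort_lbl = f"{outcome}_RT", f"{outcome}_noRT"
        if rt_lbl in scans and nort_lbl in scans:
            rg, metric = enr.hr_difference_ranking(scans[rt_lbl],
                                                   scans[nort_lbl])
            res = enr.gsea_preranked(
                rg, metric, collection, weight_p=ecfg["weight_p"],
                n_perm=ecfg["n_perm"],
                seed=child_seed(seed, f"gsea_diff_{outcome}"),
                min_set=ecfg["min_set"], max_set=ecfg["max_set"])
            res.table.to_csv(outdir / f"gsea_hrdiff_{outcome}.tsv",
                             sep="\t", index=False)
            enr_summary[f"gsea_hrdiff_{outcome}"] = {
                "n_tested": len(res.table),
                "n_significant": int((res.table["p_adj"] < ecfg["alpha"]).sum())
                if len(res.table) else 0}
    report["enrichment"] = enr_summary
    done()

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
    return report


def _batch_cox(group: survival.AnalysisGroup, score_mat: np.ndarray,
               cohorts) -> list[survival.CoxResult]:
    """Fit one Cox model per score column using the vectorized scan path."""
    pats = group.patients
    pos = [cohorts.clinical.index.get_loc(s) for s in pats.index]
    Z = score_mat[pos]
    sd = Z.std(axis=0, ddof=1)
    Z = (Z - Z.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    beta, se, p, conv = survival.cox_scan(
        pats["time"].to_numpy(), pats["event"].to_numpy(), Z,
        pats["cohort_id"].to_numpy())
    out = []
    for j in range(Z.shape[1]):
        out.append(survival.CoxResult(
            beta=float(beta[j]), se=float(se[j]),
            hr_per_sd=float(np.exp(beta[j])),
            ci_lower=float(np.exp(beta[j] - 1.96 * se[j])),
            ci_upper=float(np.exp(beta[j] + 1.96 * se[j])),
            p=float(p[j]), n=group.n, n_events=group.n_events,
            converged=bool(conv[j])))
    return out


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
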