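"""End-to-end pipeline driver: chain all analysis stages and emit a report.

Stages run in order — rates, light-response fits (growth and qO2), Q per
regime, PAM statistics, clustering + eigengene-phenotype correlation,
enrichment, volumes — each guarded so a failure or a missing input localizes
to its own report section while the rest of the run completes.  The report
is a single JSON document; per-stage tables are written as TSVs next to it.

Hidden ground-truth columns (``truth_*``) present in synthetic inputs are
stripped before any estimator sees the data.
"""

from __future__ import annotations

import json
import math
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, expression_clustering, fluorometry, morphometrics
from . import photoresponse, reactor_kinetics
from .enrichment import AnnotationMap, enrichment_table
from .io import (PipelineConfig, load_gas_params, read_expression_matrix,
                 read_table, write_table)
from .synthetic_data import TRUTH_COLUMNS


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else ("Infinity" if math.isinf(f) else f)
    return obj


def _strip_truth(df: pd.DataFrame) -> pd.DataFrame:
    """Drop hidden ground-truth columns so estimators never read them."""
    return df.drop(columns=[c for c in df.columns
                            if c in TRUTH_COLUMNS or c.startswith("truth_")])


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage for which inputs are configured.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Stage failures are caught and recorded; missing inputs mark a stage
    ``skipped``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "software": f"photoacclim {__version__}",
            "seed": config.seed,
            "config": _jsonify(config.__dict__),
        },
        "stages": {},
    }
    stages = report["stages"]

    def guard(name, fn):
        try:
            out = fn()
            if out is None:
                stages[name] = {"status": "skipped",
                                "reason": "input not configured"}
            else:
                stages[name] = {"status": "ok", **_jsonify(out)}
        except Exception as exc:  # localized stage failure
            stages[name] = {"status": "failed", "error": str(exc),
                            "traceback": traceback.format_exc(limit=3)}

    state: dict = {}

    def stage_rates():
        if config.steady_state_table is None:
            return None
        gas = load_gas_params(config.gas_params)
        df = _strip_truth(read_table(config.steady_state_table,
                                     schema="steady_state"))
        records = [reactor_kinetics.SteadyStateRecord(
            Ii=r.Ii, D=r.D, mu=r.mu, OD730=r.OD730, x=r.x, O2=r.O2_uM,
            pH=r.pH, organism=str(r.organism))
            for r in df.itertuples()]
        rates = reactor_kinetics.rates_table(records, gas)
        write_table(rates, outdir / "rates.tsv",
                    units={"Ii": "umol_photons_m-2_s-1", "mu": "h-1",
                           "qO2": "mmol_h-1_g-1", "qX": "Cmmol_h-1_g-1"})
        state["rates"] = rates
        return {"n_records": len(rates),
                "qO2_max": float(rates["qO2"].max()),
                "mu_max_observed": float(rates["mu"].max())}

    def stage_fit(column, name):
        def fn():
            rates = state.get("rates")
            if rates is None:
                return None
            fit = photoresponse.fit_light_response(
                rates["Ii"].values, rates[column].values,
                model=config.fit_model)
            state[f"fit_{name}"] = fit
            curve = pd.DataFrame({
                "Ii": np.linspace(1.0, rates["Ii"].max() * 1.2, 200)})
            curve[column] = fit.predict(curve["Ii"].values)
            write_table(curve, outdir / f"curve_{name}.tsv", units={})
            return {"model": fit.model, "Rmax": fit.Rmax, "Ik": fit.Ik,
                    "beta": fit.beta, "alpha": fit.alpha,
                    "peak_Ii": fit.peak_Ii, "se": fit.se,
                    "f_pvalue": fit.f_pvalue}
        return fn

    def stage_quotient():
        rates = state.get("rates")
        fit = state.get("fit_growth")
        if rates is None or fit is None:
            return None
        labels = photoresponse.classify_regimes(rates["Ii"].values, fit,
                                                delta=config.regime_delta)
        qfits = reactor_kinetics.photosynthetic_quotient(
            rates["qO2"].values, rates["qX"].values, labels)
        return {regime: {"Q": f.Q, "stderr": f.stderr, "n": f.n,
                         "ok": f.ok, "message": f.message}
                for regime, f in qfits.items()}

    def stage_pam():
        if config.trace_table is None and config.rlc_table is None:
            return None
        trace = rlc = None
        if config.trace_table is not None:
            tdf = read_table(config.trace_table, schema="trace")
            trace = fluorometry.FluorescenceTrace(
                tdf["time_s"].values, tdf["F"].values, tdf["phase"].values)
        if config.rlc_table is not None:
            rdf = read_table(config.rlc_table, schema="rlc")
            rlc = fluorometry.RapidLightCurve(
                rdf["PAR"].values, rdf["F"].values, rdf["Fm_prime"].values)
        pam = fluorometry.summarize(trace=trace, rlc=rlc,
                                    rcef_window_s=config.rcef_window_s)
        return {"rETRmax": pam.rETRmax, "alpha_r": pam.alpha_r,
                "rETRmax_observed": pam.rETRmax_observed,
                "rCEF": pam.rCEF, "FvFm": pam.FvFm, "flags": pam.flags}

    def stage_clustering():
        if config.expression_table is None:
            return None
        rpkm = read_expression_matrix(config.expression_table)
        result, rep = expression_clustering.cluster_pipeline(
            rpkm, k=config.cluster_k, quantile=config.filter_quantile,
            policy=config.filter_policy, pseudocount=config.pseudocount,
            n_major=config.n_major)
        state["clusters"] = result
        write_table(result.labels.rename("cluster").reset_index(),
                    outdir / "cluster_labels.tsv", units={})
        sizes = result.sizes()
        return {"k": result.k,
                "sizes": sizes.to_dict(),
                "pct": {cid: 100.0 * n / int(sizes.sum())
                        for cid, n in sizes.to_dict().items()},
                "n_genes_clustered": int(sizes.sum()),
                "n_removed_low_expression": len(
                    rep["removed_low_expression"]),
                "variance_explained": result.variance_explained,
                "eigengenes": {cid: v for cid, v in
                               result.eigengenes.items()}}

    def stage_correlation():
        result = state.get("clusters")
        rates = state.get("rates")
        if result is None or rates is None:
            return None
        if len(result.conditions) != len(rates):
            return {"note": "condition count does not match steady states; "
                            "correlation skipped"}
        mu = rates["mu"].values
        return {str(cid): expression_clustering.correlate_eigengene(eig, mu)
                for cid, eig in result.eigengenes.items()}

    def stage_enrichment():
        result = state.get("clusters")
        if result is None or config.annotation_table is None:
            return None
        ann = AnnotationMap.from_frame(
            read_table(config.annotation_table, schema="annotation"))
        universe = (None if config.enrichment_universe == "expressed"
                    else list(ann._map))
        table = enrichment_table(result.labels, ann, universe,
                                 alpha=config.enrichment_alpha)
        write_table(table, outdir / "enrichment.tsv", units={})
        sig = table[table["significant"]]
        return {"n_tests": len(table), "n_significant": len(sig),
                "significant": sig[["cluster", "level", "category",
                                    "pct_genes", "ratio", "p_value"]]
                .to_dict("records")}

    def stage_volumes():
        if config.cell_table is None:
            return None
        cells = read_table(config.cell_table, schema="cells")
        summary, fold = morphometrics.summarize_volumes(cells)
        write_table(summary, outdir / "volume_summary.tsv",
                    units={"mean": "um3", "sd": "um3"})
        return {"summary": summary.to_dict("records"),
                "fold_changes": fold.to_dict("records")}

    guard("rates", stage_rates)
    guard("light_fit_growth", stage_fit("mu", "growth"))
    guard("light_fit_qO2", stage_fit("qO2", "qO2"))
    guard("photosynthetic_quotient", stage_quotient)
    guard("pam", stage_pam)
    guard("clustering", stage_clustering)
    guard("eigengene_correlation", stage_correlation)
    guard("enrichment", stage_enrichment)
    guard("volumes", stage_volumes)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def summarize_report(report: dict) -> str:
    """Human-readable one-screen summary of a pipeline report."""
    lines = [f"photoacclim run ({report['provenance']['software']}, "
             f"seed {report['provenance']['seed']})"]
    for name, stage in report["stages"].items():
        status = stage.get("status", "?")
        extra = ""
        if name == "light_fit_growth" and status == "ok":
            extra = (f": Rmax={stage['Rmax']:.4g} h-1, "
                     f"Ik={stage['Ik']:.4g}, model={stage['model']}")
        elif name == "rates" and status == "ok":
            extra = f": qO2_max={stage['qO2_max']:.3g} mmol h-1 g-1"
        elif name == "clustering" and status == "ok":
            extra = f": k={stage['k']}, sizes={stage['sizes']}"
        lines.append(f"  {name:26s} {status}{extra}")
    return "\n".join(lines)
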