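"""End-to-end analysis driver: simulate/load -> validate -> person-time ->
SMRs -> risk sets -> rate-ratio models -> NCO adjustment -> bias adjustment.

Every stage logs worker counts, outputs apply the disclosure-suppression
rule, and a manifest records the configuration and seed so a result bundle
can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .bias import BiasParameters, confounding_risk_ratio, mc_sensitivity
from .io import (PipelineConfig, ValidationReport, apply_plant_filter,
                 read_cohort_csv, validate_and_recode, write_cohort_csv)
from .nco import adjust, adjust_double
from .persontime import tabulate
from .rates import ReferenceRateTable
from .risksets import build_risk_sets, risk_sets_to_frame
from .rrmodels import fit_conditional, rr_trend_test
from .smr import smr_report
from .synthetic import SimConfig, generate_cohort, generate_reference_rates

log = logging.getLogger("occohort")


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns a summary dict (also written out)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_manifest(), "version": __version__}

    # ---- load or simulate -------------------------------------------------
    stage = "load"
    try:
        if config.cohort_path:
            cohort, parse_errors = read_cohort_csv(config.cohort_path, config.exposures_path)
            rate_tables = {label: ReferenceRateTable.from_csv(path, label=label)
                           for label, path in config.rates_paths.items()}
        else:
            sim = SimConfig(n_workers=config.n_workers, seed=config.seed,
                            asbestos_plant_index=3, smoker_exposed_prob=0.75)
            cohort = generate_cohort(sim)
            rate_tables = {"reference": generate_reference_rates(sim)}
            parse_errors = []
            write_cohort_csv(cohort, out / "workers.csv", out / "exposures.csv")
            rate_tables["reference"].to_csv(out / "rates_reference.csv")
        log.info("load: %d workers, %d rate tables", len(cohort), len(rate_tables))
    except Exception as exc:
        raise StageError(stage, exc)

    try:
        stage = "validate"
        cohort, report = validate_and_recode(cohort, config, parse_errors)
        summary["validation"] = report.to_dict()
        cohort = apply_plant_filter(cohort, config.exclude_plants)

        stage = "person-time"
        pt = tabulate(cohort, config.cumulative_spec, config.follow_up)
        pt.to_tsv(out / "persontime.tsv")
        summary["person_years"] = pt.total_person_years()
        log.info("person-time: %.0f person-years", summary["person_years"])

        stage = "smr"
        for label, table in rate_tables.items():
            rep = smr_report(pt, table, list(config.causes),
                             suppression_threshold=config.suppression_threshold)
            rep.to_csv(out / f"smr_{label}.tsv", sep="\t", index=False)

        stage = "risk-sets"
        sets = {}
        for cause in ("lung", "copd"):
            sets[cause] = build_risk_sets(cohort, cause, config.cumulative_spec,
                                          follow_up=config.follow_up)
            log.info("risk-sets[%s]: %d sets (%d empty)", cause, len(sets[cause]),
                     sum(rs.excluded for rs in sets[cause]))
        risk_sets_to_frame(sets["lung"]).to_csv(out / "risksets_lung.tsv",
                                                sep="\t", index=False)

        stage = "rr-models"
        fits = {cause: fit_conditional(s, exposure="exposed") for cause, s in sets.items()}
        model_report = {cause: fit.to_report() for cause, fit in fits.items()}
        for cause, s in sets.items():
            try:
                model_report[cause]["trend_p"] = rr_trend_test(s)
            except ValueError:
                model_report[cause]["trend_p"] = None
        (out / "rr_models.json").write_text(json.dumps(model_report, indent=1))

        stage = "nco-adjust"
        lung = fits["lung"]["exposed"]
        copd = fits["copd"]["exposed"]
        adj = adjust(lung, copd)
        nco_rows = [{"outcome": "lung", "nco": "copd",
                     "rr_unadjusted": round(lung.rr, 2),
                     "rr_nco": round(copd.rr, 2),
                     "rr_adjusted": round(adj.rr_adj, 2),
                     "ci_low": round(adj.ci_low, 2), "ci_high": round(adj.ci_high, 2)}]
        try:
            meso_sets = build_risk_sets(cohort, "mesothelioma", config.cumulative_spec,
                                        follow_up=config.follow_up)
            meso = fit_conditional(meso_sets, exposure="exposed")["exposed"]
            if meso.identifiable and not meso.separated:
                dbl = adjust_double(lung, copd, meso)
                nco_rows.append({"outcome": "lung", "nco": "copd+mesothelioma",
                                 "rr_unadjusted": round(lung.rr, 2),
                                 "rr_nco": round(copd.rr * meso.rr, 2),
                                 "rr_adjusted": round(dbl.rr_adj, 2),
                                 "ci_low": round(dbl.ci_low, 2),
                                 "ci_high": round(dbl.ci_high, 2)})
        except ValueError:
            log.info("nco-adjust: too few mesothelioma deaths for dual adjustment")
        pd.DataFrame(nco_rows).to_csv(out / "nco_report.tsv", sep="\t", index=False)
        summary["nco"] = nco_rows

        stage = "bias-adjust"
        p1 = sum(w.ever_smoker for w in cohort) / max(len(cohort), 1)
        params = BiasParameters(p_cohort=p1, p_reference=0.271, rr_confounder=19.1,
                                seed=config.seed)
        crr = confounding_risk_ratio(p1, 0.271, 19.1)
        res = mc_sensitivity(params, smr=1.0)
        bias_rows = [{"label": "lung-smoking", "p_cohort": round(p1, 3),
                      "p_reference": 0.271, "rr": 19.1, "crr": round(crr, 2),
                      "smr_adjusted_per_unit_smr": round(res.smr_adjusted, 2)}]
        pd.DataFrame(bias_rows).to_csv(out / "bias_report.tsv", sep="\t", index=False)
        summary["bias"] = bias_rows
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc)

    manifest = {"config": config.to_manifest(), "version": __version__, "seed": config.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
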