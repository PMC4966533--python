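"""End-to-end analysis pipeline: the full study replica.

``run_full_analysis`` executes the three analysis components in order on a
simulated (or loaded) cohort:

1. dosimetry-only modeling — EQD2 conversion, LKB maximum-likelihood fit
   (plus fixed published parameter sets, e.g. the QUANTEC late rectal
   model), and a univariate logistic sweep over dosimetric indices ranked
   by AUC;
2. multivariate modeling — LASSO covariate selection at the best index,
   then unpenalized refits (full selected set, reduced set, univariate)
   with profile CIs and AUCs;
3. cross-validation / cohort statistics — partial LKB models with one
   covariate at a time, the exposure contingency table, the two-sample
   covariate comparison, and NTCP-vs-index prediction curves stratified
   by the strongest covariates.

Every stage is seeded from a single global seed via a counter-based
spawn, logged, and serialized, so the whole report is recomputable from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import stats as cohort_stats
from .dvh import ConfigurationError, DoseIndexSpec, FractionationScheme, eqd2_convert
from .lkb import QUANTEC_LATE_RECTAL, LKBParams, apply_fixed_lkb, fit_lkb, fit_lkb_partial, geud
from .logistic import (
    LogisticNTCPModel,
    compute_index_values,
    fit_logistic,
    lasso_select,
    sweep_univariate,
)
from .roc import auc, auc_ci
from .synthetic_cohort import CohortSpec, SyntheticCohort, generate_cohort, load_cohort

log = logging.getLogger("ntcp_rectox")

__all__ = ["AnalysisConfig", "AnalysisReport", "StageError", "run_full_analysis", "fig2_curves"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Configuration of a full analysis run.

    Either ``cohort_dir`` (covariates.csv + doses.csv) or ``cohort_spec``
    (simulate) must be provided.  All settings are serialized into the
    report for reproducibility.
    """

    cohort_dir: str | None = None
    cohort_spec: CohortSpec | None = None
    scheme: FractionationScheme = field(default_factory=FractionationScheme)
    eqd2: bool = True
    x_grid: tuple = tuple(range(10, 100, 5))
    d_grid: tuple = tuple(range(10, 75, 5))
    lasso_candidates: tuple = (
        "age", "diabetes", "statins", "metformin", "alpha_blockers",
        "hormonal", "psa", "gleason", "prostate_volume", "boost_volume",
        "rectal_volume",
    )
    cv_folds: int = 5
    n_boot: int = 2000
    seed: int = 0
    out_dir: str | None = None
    lkb_bin_width: float = 0.25
    partial_covariates: tuple = ("statins", "psa")
    contingency_exposure: str = "statins"
    two_sample_variable: str = "psa"
    outcome: str = "tox_acute_ge2"

    def validate(self) -> None:
        if self.cohort_dir is None and self.cohort_spec is None:
            raise ConfigurationError("cohort_dir/cohort_spec: one input source is required")
        if self.cv_folds < 3:
            raise ConfigurationError("cv_folds: must be >= 3")
        if self.n_boot < 200:
            raise ConfigurationError("n_boot: must be >= 200")
        FractionationScheme(self.scheme.n_fractions, self.scheme.alpha_beta)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scheme" in raw:
            raw["scheme"] = FractionationScheme(**raw["scheme"])
        if "cohort_spec" in raw and raw["cohort_spec"] is not None:
            raw["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
        for key in ("x_grid", "d_grid", "lasso_candidates", "partial_covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class AnalysisReport:
    config: dict
    stage_seeds: dict
    lkb_table: pd.DataFrame
    sweep_table: pd.DataFrame
    best_d_index: str | None
    best_v_index: str | None
    mv_tables: dict            # index name -> coefficient DataFrame
    partial_lkb: pd.DataFrame
    contingency: cohort_stats.ContingencyResult
    two_sample: cohort_stats.TwoSampleResult
    fig2: pd.DataFrame
    n_patients: int

    def to_json_dict(self) -> dict:
        return {
            "config": self.config,
            "stage_seeds": self.stage_seeds,
            "n_patients": self.n_patients,
            "lkb": self.lkb_table.to_dict(orient="records"),
            "sweep": self.sweep_table.to_dict(orient="records"),
            "best_d_index": self.best_d_index,
            "best_v_index": self.best_v_index,
            "multivariate": {k: v.to_dict(orient="records") for k, v in self.mv_tables.items()},
            "partial_lkb": self.partial_lkb.to_dict(orient="records"),
            "contingency": dataclasses.asdict(self.contingency),
            "two_sample": dataclasses.asdict(self.two_sample),
        }


def _stage_seeds(seed: int, names) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: int(child.generate_state(1)[0] % (2**31)) for name, child in
            zip(names, children)}


def _coef_table(model: LogisticNTCPModel) -> pd.DataFrame:
    rows = []
    for name in model.coefs:
        lo, hi = model.ci95[name]
        rows.append({"term": name, "estimate": model.coefs[name],
                     "ci_lo": lo, "ci_hi": hi, "p": model.pvalues[name]})
    return pd.DataFrame(rows)


def fig2_curves(
    model: LogisticNTCPModel,
    index_range,
    strata: dict,
    univariate_model: LogisticNTCPModel | None = None,
    baseline: dict | None = None,
) -> pd.DataFrame:
    """Tabulated NTCP-vs-index curves per stratum of one covariate.

    ``strata`` maps a stratifying variable name to the values at which to
    hold it (e.g. ``{"statins": [0, 1]}`` or PSA quantiles); the other
    model covariates are held at ``baseline`` (default 0).  The univariate
    reference model, when given, contributes a ``"univariate"`` stratum.
    """
    (var, levels), = strata.items()
    if var not in model.covariate_names:
        raise ConfigurationError(f"{var}: not a covariate of the model")
    grid = np.asarray(index_range, float)
    base = dict(baseline or {})
    rows = []
    for level in levels:
        patient = {name: base.get(name, 0.0) for name in model.covariate_names}
        patient[var] = level
        for d in grid:
            rows.append({"stratum": f"{var}={level:g}", "index_value": d,
                         "ntcp": model.predict(patient, d)})
    if univariate_model is not None:
        for d in grid:
            rows.append({"stratum": "univariate", "index_value": d,
                         "ntcp": univariate_model.predict({}, d)})
    return pd.DataFrame(rows)


def _run_stage(name: str, fn):
    t0 = time.perf_counter()
    log.info("stage %s: start", name)
    try:
        out = fn()
    except Exception as exc:
        log.error("stage %s: failed (%s)", name, exc)
        raise StageError(name, exc) from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
    return out


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the three-component analysis and write the structured report."""
    config.validate()
    seeds = _stage_seeds(config.seed, ["simulate", "sweep", "lasso", "bootstrap"])
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- input ----------------------------------------------------------
    def load():
        if config.cohort_dir is not None:
            return load_cohort(config.cohort_dir)
        spec = dataclasses.replace(config.cohort_spec, seed=seeds["simulate"]
                                   if config.cohort_spec.seed == 0 else config.cohort_spec.seed)
        return generate_cohort(spec)

    cohort: SyntheticCohort = _run_stage("load_cohort", load)
    y = cohort.outcomes
    n_in = len(cohort.patients)

    # --- component 1: dosimetry-only ------------------------------------
    def dosimetry_stage():
        if y.sum() == 0 or y.sum() == y.size:
            from .lkb import DegenerateDataError

            raise DegenerateDataError("cohort has no events (or no non-events)")
        eff = [eqd2_convert(s, config.scheme) if config.eqd2 else s for s in cohort.doses]
        fit = fit_lkb(eff, y, bin_width=config.lkb_bin_width)
        g = np.array([geud(s, fit.params.n) for s in eff])
        from .lkb import lkb_ntcp

        own_scores = lkb_ntcp(g, fit.params)
        own_auc = auc(own_scores, y)
        own_ci = auc_ci(own_scores, y, n_boot=config.n_boot, seed=seeds["bootstrap"])
        q_scores, q_mean = apply_fixed_lkb(eff, QUANTEC_LATE_RECTAL)
        q_auc = auc(q_scores, y)
        q_ci = auc_ci(q_scores, y, n_boot=config.n_boot, seed=seeds["bootstrap"])
        rows = []
        ci = fit.ci95 or {}
        rows.append({
            "model": "study_fit", "td50": fit.params.td50, "m": fit.params.m,
            "n": fit.params.n,
            "td50_lo": ci.get("td50", (None, None))[0], "td50_hi": ci.get("td50", (None, None))[1],
            "m_lo": ci.get("m", (None, None))[0], "m_hi": ci.get("m", (None, None))[1],
            "n_lo": ci.get("n", (None, None))[0], "n_hi": ci.get("n", (None, None))[1],
            "loglik": fit.loglik, "converged": fit.converged,
            "auc": own_auc, "auc_lo": own_ci[0], "auc_hi": own_ci[1],
            "mean_predicted_incidence": float(own_scores.mean()),
        })
        rows.append({
            "model": "quantec_late", "td50": QUANTEC_LATE_RECTAL.td50,
            "m": QUANTEC_LATE_RECTAL.m, "n": QUANTEC_LATE_RECTAL.n,
            "loglik": None, "converged": True,
            "auc": q_auc, "auc_lo": q_ci[0], "auc_hi": q_ci[1],
            "mean_predicted_incidence": q_mean,
        })
        lkb_table = pd.DataFrame(rows)
        sweep = sweep_univariate(
            cohort.doses, y, cohort.patients, config.x_grid, config.d_grid,
            config.scheme, config.eqd2, n_boot=0,
        )
        return eff, fit, lkb_table, sweep

    eff_doses, lkb_fit, lkb_table, sweep = _run_stage("dosimetry_modeling", dosimetry_stage)

    sweep_table = sweep.table()
    d_cells = [c for c in sweep.cells if c.spec.kind == "D_at_volume" and c.auc is not None]
    v_cells = [c for c in sweep.cells if c.spec.kind == "V_at_dose" and c.auc is not None]
    best_d = max(d_cells, key=lambda c: c.auc).spec if d_cells else None
    best_v = max(v_cells, key=lambda c: c.auc).spec if v_cells else None

    # --- component 2: multivariate --------------------------------------
    def multivariate_stage():
        tables = {}
        models = {}
        for spec in filter(None, [best_d, best_v]):
            values = compute_index_values(cohort.doses, spec, config.scheme, config.eqd2)
            usable = [c for c in config.lasso_candidates
                      if c in cohort.patients.columns
                      and cohort.patients[c].std(ddof=0) > 0]
            sel = lasso_select(
                cohort.patients, y, spec, values, usable,
                cv_folds=config.cv_folds, seed=seeds["lasso"],
            )
            # two-stage reporting: unpenalized refit on exactly the selected set
            full = fit_logistic(cohort.patients, y, spec, values, sel.selected)
            # reduced set: selected terms significant at 0.05 in the full refit
            reduced_names = tuple(nm for nm in sel.selected if full.pvalues[nm] < 0.05)
            reduced = (fit_logistic(cohort.patients, y, spec, values, reduced_names)
                       if reduced_names != sel.selected
                       else full)
            uni = fit_logistic(cohort.patients, y, spec, values, ())
            rows = []
            for label, model in (("full_lasso_set", full), ("reduced", reduced),
                                 ("univariate", uni)):
                t = _coef_table(model)
                t.insert(0, "fit", label)
                scores = np.array([
                    model.predict(cohort.patients.iloc[i], values[i])
                    for i in range(len(values))
                ])
                a = auc(scores, y)
                lo, hi = auc_ci(scores, y, n_boot=config.n_boot, seed=seeds["bootstrap"])
                t["auc"] = a
                t["auc_lo"] = lo
                t["auc_hi"] = hi
                rows.append(t)
            tables[spec.name] = pd.concat(rows, ignore_index=True)
            models[spec.name] = {"full": full, "reduced": reduced, "uni": uni,
                                 "values": values, "selected": sel.selected}
        return tables, models

    mv_tables, mv_models = _run_stage("multivariate_modeling", multivariate_stage)

    # --- component 3: cross-validation & cohort statistics ---------------
    def crossval_stage():
        rows = []
        for name in config.partial_covariates:
            if name not in cohort.patients.columns:
                continue
            res = fit_lkb_partial(
                eff_doses, y, cohort.patients[name].to_numpy(float), name,
                bin_width=config.lkb_bin_width,
            )
            rows.append({
                "covariate": name, "td50": res.params.td50, "m": res.params.m,
                "n": res.params.n, "delta": res.delta,
                "delta_lo": None if res.delta_ci is None else res.delta_ci[0],
                "delta_hi": None if res.delta_ci is None else res.delta_ci[1],
                "loglik": res.loglik, "converged": res.converged,
                "degenerate": res.degenerate_covariate,
            })
        partial = pd.DataFrame(rows)
        cont = cohort_stats.contingency_2x2(
            cohort.patients, config.contingency_exposure, config.outcome
        )
        two = cohort_stats.two_sample_compare(
            cohort.patients[config.two_sample_variable].to_numpy(float), y
        )
        return partial, cont, two

    partial_lkb, contingency, two_sample = _run_stage("cross_validation", crossval_stage)

    # Fig-2-style prediction curves at the best D index
    def curves_stage():
        if best_d is None or best_d.name not in mv_models:
            return pd.DataFrame(columns=["stratum", "index_value", "ntcp"])
        entry = mv_models[best_d.name]
        model = entry["reduced"]
        grid = np.linspace(np.min(entry["values"]), np.max(entry["values"]), 50)
        frames = []
        baseline = {name: float(cohort.patients[name].median())
                    for name in model.covariate_names}
        for var in model.covariate_names:
            col = cohort.patients[var]
            levels = ([0, 1] if set(pd.unique(col)) <= {0, 1}
                      else [float(col.quantile(q)) for q in (0.25, 0.75)])
            frames.append(
                fig2_curves(model, grid, {var: levels}, entry["uni"], baseline)
            )
        if not frames:
            frames.append(fig2_curves_univariate(entry["uni"], grid))
        return pd.concat(frames, ignore_index=True).drop_duplicates()

    fig2 = _run_stage("prediction_curves", curves_stage)

    report = AnalysisReport(
        config=_config_dict(config),
        stage_seeds=seeds,
        lkb_table=lkb_table,
        sweep_table=sweep_table,
        best_d_index=None if best_d is None else best_d.name,
        best_v_index=None if best_v is None else best_v.name,
        mv_tables=mv_tables,
        partial_lkb=partial_lkb,
        contingency=contingency,
        two_sample=two_sample,
        fig2=fig2,
        n_patients=n_in,
    )
    assert report.n_patients == len(cohort.patients), "patients dropped in pipeline"
    if out_dir:
        _write_report(report, out_dir)
    return report


def fig2_curves_univariate(model: LogisticNTCPModel, grid) -> pd.DataFrame:
    rows = [{"stratum": "univariate", "index_value": float(d),
             "ntcp": model.predict({}, d)} for d in grid]
    return pd.DataFrame(rows)


def _config_dict(config: AnalysisConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("cohort_spec") is not None:
        spec = d["cohort_spec"]
        tox = spec.get("toxicity_model")
        if tox is not None and "index" in tox and not isinstance(tox["index"], str):
            tox["index"] = config.cohort_spec.toxicity_model.index.name
    return json.loads(json.dumps(d, default=str))


def _write_report(report: AnalysisReport, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=str, sort_keys=True)
    report.lkb_table.to_csv(out_dir / "table1_lkb.csv", index=False)
    report.sweep_table.to_csv(out_dir / "sweep.csv", index=False)
    report.sweep_table.to_csv(out_dir / "fig1_auc.csv", index=False)
    names = list(report.mv_tables)
    if len(names) > 0:
        report.mv_tables[names[0]].to_csv(out_dir / "table2_mv.csv", index=False)
    if len(names) > 1:
        report.mv_tables[names[1]].to_csv(out_dir / "table3_mv.csv", index=False)
    report.fig2.to_csv(out_dir / "fig2_curves.csv", index=False)
    with open(out_dir / "cohort_stats.json", "w") as fh:
        json.dump(
            {
                "contingency": dataclasses.asdict(report.contingency),
                "two_sample": dataclasses.asdict(report.two_sample),
            },
            fh,
            indent=2,
            default=str,
        )
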