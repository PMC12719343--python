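"""End-to-end analysis orchestration.

The default plan mirrors a joint polygenic-score/twin analysis of a
depression diagnosis and suicidal thoughts and behaviors: threshold
homogeneity tests per binary phenotype, FIML phenotypic and twin-pair
correlations, one trivariate Cholesky ladder (PRS, diagnosis, item) per
PRS x item combination, a four-variate diagnosis + items ladder, and an
optional non-parametric bootstrap of the bivariate diagnosis/attempt AE
model.  All randomness flows from one master seed split per stage; rerun
with identical seeds gives byte-identical report tables.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cohort import TwinDataset, read_cohort, standardize_prs
from .descriptives import fiml_correlation_matrix, twin_pair_correlation
from .inference import (FitOptions, bootstrap_ci, profile_ci, select_model,
                        test_threshold_homogeneity)
from .model import CholeskyModel, VariableSpec, build_ace_model
from .simulate import SimulationConfig, simulate_ace_cohort


class PlanError(ValueError):
    pass


@dataclass
class AnalysisPlan:
    """Declarative description of a full analysis run."""

    dataset: object                     # path, TwinDataset or SimulationConfig
    variable_spec: object = None        # spec source when dataset is a path
    prs_variables: tuple = ("prs_md", "prs_sb")
    diagnosis: str = "mdd"
    stb_variables: tuple = ("si", "sp", "sa")
    covariate_effects: dict = field(default_factory=lambda: {
        "mdd": ("sex",), "sp": ("age",), "sa": ("age",)})
    ladder: tuple = ("ACE", "AE", "CE", "E")
    seed: int = 0
    restarts: int = 10
    maxiter: int = 300
    fast: bool = False
    ci_method: str = "none"             # 'profile' or 'none'
    bootstrap_B: int = 0
    bootstrap_pair: tuple = ("mdd", "sa")
    run_multivariate: bool = True
    outdir: str | None = None

    def validate(self, ds: TwinDataset):
        names = {v.name for v in ds.variables}
        roles = list(self.prs_variables) + [self.diagnosis] \
            + list(self.stb_variables)
        for r in roles:
            if r not in names:
                raise PlanError(f"role variable {r!r} not in dataset")
        if not isinstance(self.diagnosis, str):
            raise PlanError("exactly one diagnosis variable required")


@dataclass
class ReportBundle:
    tables: dict
    fits: dict
    log: dict

    def write(self, outdir):
        os.makedirs(outdir, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t",
                         index=False, float_format="%.6g")
        with open(os.path.join(outdir, "run_log.json"), "w") as fh:
            json.dump(self.log, fh, indent=2, sort_keys=True, default=str)


# --------------------------------------------------------------------- #
# model ladders


def _analysis_specs(ds, names, plan):
    specs = []
    for n in names:
        base = ds.variable(n)
        covs = tuple(plan.covariate_effects.get(n, ()))
        specs.append(VariableSpec(n, base.scale,
                                  components_allowed=base.components_allowed,
                                  covariates=covs))
    return tuple(specs)


def build_ladder(specs, labels=("ACE", "AE", "CE", "E")):
    """Nested Cholesky ladder; genetic submodels always retain the own
    loading of pure-A (polygenic-score) variables."""
    full = build_ace_model(specs, active_components=("A", "C", "E"))
    a_keep = {(i + 1, i + 1) for i, v in enumerate(specs)
              if v.components_allowed == ("A",)}
    a_droppable = [(int(i) + 1, int(j) + 1)
                   for i, j in np.argwhere(full.free["A"])
                   if (int(i) + 1, int(j) + 1) not in a_keep]
    out = []
    for label in labels:
        m = full
        if "C" not in label:
            m = m.drop_paths("C")
        if "A" not in label and a_droppable:
            m = m.drop_paths("A", entries=a_droppable)
        out.append((label, m))
    return out


# --------------------------------------------------------------------- #
# stages


def _center_age(ds: TwinDataset) -> TwinDataset:
    """Center the age covariate at its observed mean so thresholds refer
    to the average assessment age."""
    if "age" not in ds.covariates:
        return ds
    vals = [m.covariates.get("age", np.nan)
            for f in ds.families for m in f.members]
    vals = np.asarray(vals, dtype=float)
    center = float(np.nanmean(vals)) if np.isfinite(vals).any() else 0.0
    for fam in ds.families:
        for m in fam.members:
            if np.isfinite(m.covariates.get("age", np.nan)):
                m.covariates["age"] = m.covariates["age"] - center
    ds.provenance["age_center"] = f"{center:.4f}"
    return ds


def load_plan_dataset(plan: AnalysisPlan):
    if isinstance(plan.dataset, TwinDataset):
        return plan.dataset
    if isinstance(plan.dataset, SimulationConfig):
        ds, _ = simulate_ace_cohort(plan.dataset)
        return ds
    return read_cohort(plan.dataset, plan.variable_spec)


def run_pipeline(plan: AnalysisPlan) -> ReportBundle:
    ds = load_plan_dataset(plan)
    plan.validate(ds)
    ds = _center_age(ds)
    for prs in plan.prs_variables:
        ds = standardize_prs(ds, prs)
    master = np.random.SeedSequence(plan.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ("fit", "bootstrap"), master.spawn(2))}
    options = FitOptions(restarts=plan.restarts, maxiter=plan.maxiter,
                         seed=stage_seeds["fit"], fast=plan.fast)
    tables = {}
    fits = {}
    log = {"seed": plan.seed, "stage_seeds": stage_seeds,
           "version": __version__, "errors": {},
           "options": {"restarts": plan.restarts, "maxiter": plan.maxiter,
                       "fast": plan.fast, "ci_method": plan.ci_method},
           "adjustment": "covariate effects modelled as liability-mean "
                         "shifts with thresholds held fixed (definition-"
                         "variable adjustment); no residualization",
           "provenance": dict(ds.provenance)}
    binary_roles = [plan.diagnosis] + list(plan.stb_variables)

    # 1. threshold homogeneity
    rows = []
    for var in binary_roles:
        try:
            r = test_threshold_homogeneity(ds, var)
            rows.append({"variable": var, "minus2ll_saturated": r.m2ll_full,
                         "minus2ll_homogeneous": r.m2ll_reduced,
                         "delta_m2ll": r.delta_m2ll, "delta_df": r.delta_df,
                         "p": r.p})
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            log["errors"][f"homogeneity:{var}"] = str(exc)
    tables["threshold_homogeneity"] = pd.DataFrame(rows)

    # 2. twin-pair correlations
    from .descriptives import DescriptivesError
    rows = []
    for var in binary_roles + list(plan.prs_variables):
        row = {"variable": var}
        for zyg in ("MZ", "DZ"):
            try:
                est = twin_pair_correlation(ds, var, zyg)
                row[f"r_{zyg}"] = est.value
                row[f"r_{zyg}_lo"] = est.ci[0]
                row[f"r_{zyg}_hi"] = est.ci[1]
                row[f"n_{zyg}"] = est.n_effective
                if est.flag:
                    row[f"flag_{zyg}"] = est.flag
            except DescriptivesError as exc:
                # too few informative pairs: undefined estimate, not a
                # stage failure
                row[f"r_{zyg}"] = np.nan
                row[f"flag_{zyg}"] = str(exc)
            except Exception as exc:  # noqa: BLE001
                log["errors"][f"twin_corr:{var}:{zyg}"] = str(exc)
        rows.append(row)
    tables["twin_correlations"] = pd.DataFrame(rows)

    # 3. phenotypic correlation matrix
    matrix_vars = (list(plan.stb_variables) + [plan.diagnosis]
                   + list(plan.prs_variables) + ["sex", "age"])
    try:
        mat = fiml_correlation_matrix(ds, matrix_vars)
        rows = []
        for a in matrix_vars:
            row = {"variable": a}
            for b in matrix_vars:
                row[b] = mat[a][b].value
            rows.append(row)
        tables["phenotypic_correlations"] = pd.DataFrame(rows)
    except Exception as exc:  # noqa: BLE001
        log["errors"]["phenotypic_correlations"] = str(exc)

    # 4. trivariate ladders per PRS x item
    comp_rows = []
    est_rows = []
    for prs in plan.prs_variables:
        for stb in plan.stb_variables:
            key = f"{prs}+{plan.diagnosis}+{stb}"
            try:
                specs = _analysis_specs(ds, (prs, plan.diagnosis, stb), plan)
                ladder = build_ladder(specs, plan.ladder)
                sel, rows_lrt, all_fits = select_model(ladder, ds, options)
                fits[key] = sel
                for r in rows_lrt:
                    comp_rows.append({
                        "analysis": key, "model": r.label_reduced,
                        "vs": r.label_full, "minus2ll": r.m2ll_reduced,
                        "delta_m2ll": r.delta_m2ll, "delta_df": r.delta_df,
                        "p": r.p, "delta_aic": r.delta_aic,
                        "selected": r.label_reduced == sel.label})
                comp_rows.append({
                    "analysis": key, "model": all_fits[0].label, "vs": "-",
                    "minus2ll": all_fits[0].m2ll, "delta_m2ll": 0.0,
                    "delta_df": 0, "p": 1.0, "delta_aic": 0.0,
                    "selected": all_fits[0].label == sel.label})
                est_rows.extend(_estimate_rows(key, sel, ds, plan, options,
                                               (plan.diagnosis, stb)))
            except Exception as exc:  # noqa: BLE001
                log["errors"][f"ladder:{key}"] = str(exc)
    tables["model_comparisons"] = pd.DataFrame(comp_rows)
    tables["standardized_estimates"] = pd.DataFrame(est_rows)

    # 5. multivariate diagnosis + items ladder
    if plan.run_multivariate:
        try:
            names = (plan.diagnosis,) + tuple(plan.stb_variables)
            specs = _analysis_specs(ds, names, plan)
            ladder = build_ladder(specs, plan.ladder)
            sel, rows_lrt, all_fits = select_model(ladder, ds, options)
            fits["multivariate"] = sel
            mrows = [{
                "analysis": "multivariate", "model": r.label_reduced,
                "vs": r.label_full, "minus2ll": r.m2ll_reduced,
                "delta_m2ll": r.delta_m2ll, "delta_df": r.delta_df,
                "p": r.p, "delta_aic": r.delta_aic,
                "selected": r.label_reduced == sel.label} for r in rows_lrt]
            tables["model_comparisons_multivariate"] = pd.DataFrame(mrows)
            summary = sel.summary
            rows = []
            for i, a in enumerate(names):
                row = {"variable": a}
                for j, b in enumerate(names):
                    if i == j:
                        row[b] = 1.0
                    elif i > j:
                        row[b] = summary.correlation("A", a, b)
                    else:
                        row[b] = summary.correlation("E", a, b)
                rows.append(row)
            tables["component_correlations"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            log["errors"]["multivariate"] = str(exc)

    # 6. bootstrap of the bivariate diagnosis/attempt AE model
    if plan.bootstrap_B >= 2:
        try:
            specs = _analysis_specs(ds, plan.bootstrap_pair, plan)
            ae = build_ladder(specs, ("AE",))[0][1]
            boot = bootstrap_ci(
                ae, ds, plan.bootstrap_B, stage_seeds["bootstrap"],
                quantities=[("std", "A", v) for v in plan.bootstrap_pair],
                options=FitOptions(restarts=1, maxiter=plan.maxiter,
                                   seed=stage_seeds["bootstrap"],
                                   fast=plan.fast))
            rows = [{"quantity": f"A({v})",
                     "lower": boot["intervals"][("std", "A", v)][0],
                     "upper": boot["intervals"][("std", "A", v)][1],
                     "B": boot["B"], "n_failed": boot["n_failed"]}
                    for v in plan.bootstrap_pair]
            tables["bootstrap"] = pd.DataFrame(rows)
            if boot["warning"]:
                log["errors"]["bootstrap"] = boot["warning"]
        except Exception as exc:  # noqa: BLE001
            log["errors"]["bootstrap"] = str(exc)

    bundle = ReportBundle(tables=tables, fits=fits, log=log)
    if plan.outdir:
        bundle.write(plan.outdir)
    return bundle


def _estimate_rows(key, fit, ds, plan, options, report_vars):
    summary = fit.summary
    rows = []
    for var in report_vars:
        row = {"analysis": key, "model": fit.label, "variable": var}
        for comp in ("A", "C", "E"):
            row[comp] = summary.proportion(comp, var)
        if plan.ci_method == "profile":
            for comp in ("A", "E"):
                lo, hi, flag = profile_ci(fit, ds, ("std", comp, var),
                                          options=options)
                row[f"{comp}_lo"], row[f"{comp}_hi"] = lo, hi
                if flag:
                    row[f"{comp}_flag"] = flag
        rows.append(row)
    return rows


_TABLE_IDS = (
    "threshold_homogeneity", "twin_correlations",
    "phenotypic_correlations", "model_comparisons",
    "model_comparisons_multivariate", "standardized_estimates",
    "component_correlations", "bootstrap",
)


def reproduce_tables(bundle: ReportBundle, which: str) -> pd.DataFrame:
    """Fetch one report table by id; unknown ids list the valid ones."""
    if which not in bundle.tables:
        raise PlanError(
            f"unknown table id {which!r}; valid ids: "
            + ", ".join(sorted(set(_TABLE_IDS) & set(bundle.tables))))
    return bundle.tables[which]
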