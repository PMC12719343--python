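"""Synthetic twin cohorts with classical-twin-design structure.

Two generating routes are provided:

* **latent mode** -- per-family standard-normal A/C/E factor scores with the
  textbook sharing structure (A correlates 1.0 across MZ co-twins and 0.5
  across DZ co-twins via a common/unique mixture with sqrt(0.5) weights;
  C is duplicated; E is independent), combined through a generating
  :class:`~twinpath.model.CholeskyModel`;
* **locus mode** -- meiosis-based polygenic scores: parents are simulated at
  independent biallelic loci and DZ members are produced as full siblings
  by independent gamete draws, so the expected sibling score correlation of
  0.5 emerges mechanistically rather than by construction.

The default study-like configuration emulates a young-adult twin cohort in
which suicidal-behavior items are asked only of members endorsing a
depression screen: ~1250 twin pairs, depression diagnosis prevalence ~0.18,
screen prevalence ~0.35, conditional endorsement of ideation/plan/attempt
among diagnosed members near 38%/14%/6.5%, ages 19-39, 67% female, and
mixed missingness (singleton members, missing polygenic scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .cohort import CohortError, FamilyRecord, Member, TwinDataset
from .fiml import mvn_rectangle_probability
from .model import CholeskyModel, VariableSpec, model_from_components


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generating conditions for a synthetic twin cohort."""

    n_mz_pairs: int
    n_dz_pairs: int
    model: CholeskyModel
    seed: int
    gating_screen: str | None = None
    gating_dependents: tuple = ()
    singleton_fraction: float = 0.0
    missing_fraction: dict = field(default_factory=dict)  # var -> prob
    drop_variables: tuple = ()   # generated but not written (e.g. a screen)
    age_range: tuple = (19.0, 39.0)
    p_female: float = 0.67
    covariate_centers: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_mz_pairs < 0 or self.n_dz_pairs < 0:
            raise SimulationError("pair counts must be >= 0")
        if not 0.0 <= self.singleton_fraction <= 1.0:
            raise SimulationError("singleton_fraction must be in [0,1]")
        if self.seed is None:
            raise SimulationError("seed is mandatory")


@dataclass
class TruthRecord:
    """Latent component scores saved alongside a simulated cohort.

    ``factors[zyg][comp]`` has shape (n_pairs, 2, p): per-pair, per-member
    factor scores.  ``component_values`` are the Cholesky-weighted sums, the
    per-variable component contributions to liability (same shape).
    """

    variables: tuple
    factors: dict
    component_values: dict
    model: CholeskyModel

    def cross_twin_correlation(self, component, variable, zygosity):
        i = self.variables.index(variable)
        vals = self.component_values[zygosity][component][:, :, i]
        return float(np.corrcoef(vals[:, 0], vals[:, 1])[0, 1])


def _factor_scores(rng, n, p, zygosity, component):
    """(n, 2, p) standard-normal factor scores with CTD sharing."""
    if component == "A":
        if zygosity == "MZ":
            g = rng.standard_normal((n, p))
            return np.stack([g, g], axis=1)
        common = rng.standard_normal((n, p))
        unique = rng.standard_normal((n, 2, p))
        return (math.sqrt(0.5) * common[:, None, :]
                + math.sqrt(0.5) * unique)
    if component == "C":
        c = rng.standard_normal((n, p))
        return np.stack([c, c], axis=1)
    if component == "E":
        return rng.standard_normal((n, 2, p))
    raise SimulationError(f"unknown component {component!r}")


def simulate_ace_cohort(config: SimulationConfig):
    """Generate a cohort and its latent truth record.

    Binary variables must have model-implied unit liability variance (the
    generating model enforces this through its scale constraint); a violated
    constraint raises an error because the threshold scale would then be
    unidentified.
    """
    model = config.model
    try:
        model.validate()
    except Exception as exc:
        raise SimulationError(str(exc)) from exc
    if model.constraint_penalty > 0:
        raise SimulationError(
            "generating model violates the unit-variance constraint for an "
            "ordinal variable (unidentified scale)"
        )
    rng = np.random.default_rng(config.seed)
    p = model.p
    var_names = [v.name for v in model.variables]
    cov_names = sorted({c for v in model.variables for c in v.covariates})
    centers = dict(config.covariate_centers)
    centers.setdefault("sex", config.p_female)
    centers.setdefault("age", sum(config.age_range) / 2.0)

    factors = {}
    component_values = {}
    families = []
    fam_counter = 0
    for zyg, n in (("MZ", config.n_mz_pairs), ("DZ", config.n_dz_pairs)):
        fz = {c: _factor_scores(rng, n, p, zyg, c) for c in ("A", "C", "E")}
        comp_vals = {
            c: np.einsum("ij,nmj->nmi", model.paths[c], fz[c])
            for c in ("A", "C", "E")
        }
        liab = sum(comp_vals.values())  # (n, 2, p)
        factors[zyg] = fz
        component_values[zyg] = comp_vals

        # covariates: twins share age; MZ share sex, DZ sexes independent
        age = rng.uniform(*config.age_range, size=n)
        if zyg == "MZ":
            sex = np.repeat(
                (rng.random(n) < config.p_female).astype(float)[:, None],
                2, axis=1)
        else:
            sex = (rng.random((n, 2)) < config.p_female).astype(float)
        covs = {"age": np.repeat(age[:, None], 2, axis=1), "sex": sex}

        shift = np.zeros((n, 2, p))
        for i, v in enumerate(model.variables):
            for cname in v.covariates:
                x = covs.get(cname)
                if x is None:
                    continue
                beta = model.betas[(v.name, cname)]
                shift[:, :, i] += beta * (x - centers.get(cname, 0.0))
        liab_obs = liab + shift

        values = liab_obs.copy()
        for i, v in enumerate(model.variables):
            if v.is_binary:
                tau = model.thresholds[v.name]
                values[:, :, i] = (liab_obs[:, :, i] > tau).astype(float)
            else:
                values[:, :, i] += model.means.get(v.name, 0.0)

        # assemble family records
        singleton = rng.random(n) < config.singleton_fraction
        drop_member = rng.integers(0, 2, size=n)
        miss = {
            name: rng.random((n, 2)) < frac
            for name, frac in config.missing_fraction.items()
        }
        for f in range(n):
            members = []
            for m in range(2):
                phen = {}
                for i, name in enumerate(var_names):
                    if name in config.drop_variables:
                        continue
                    val = values[f, m, i]
                    if singleton[f] and m == drop_member[f]:
                        val = np.nan
                    if name in miss and miss[name][f, m]:
                        val = np.nan
                    phen[name] = val
                mc = {c: float(covs[c][f, m]) for c in covs if c in cov_names
                      or c in ("age", "sex")}
                members.append(Member(phen, mc))
            fam_counter += 1
            families.append(FamilyRecord(f"F{fam_counter:05d}", zyg, members))

    ds = TwinDataset(tuple(model.variables), families,
                     covariates=("sex", "age"),
                     provenance={"source": "twinpath.simulate",
                                 "seed": str(config.seed)})
    if config.gating_screen is not None:
        ds = apply_gating(ds, config.gating_screen, config.gating_dependents)
    if config.drop_variables:
        out_vars = tuple(v for v in model.variables
                         if v.name not in config.drop_variables)
        fams = []
        for fam in ds.families:
            members = [
                Member({k: v for k, v in m.phenotypes.items()
                        if k not in config.drop_variables},
                       dict(m.covariates))
                for m in fam.members
            ]
            fams.append(FamilyRecord(fam.family_id, fam.zygosity, members))
        ds = TwinDataset(out_vars, fams, ds.covariates, dict(ds.provenance))
    truth = TruthRecord(tuple(var_names), factors, component_values, model)
    ds.validate()
    return ds, truth


def apply_gating(ds: TwinDataset, screen: str, dependents,
                 screen_values=None) -> TwinDataset:
    """Set dependent phenotypes missing whenever the screen is 0 or missing.

    The screen may be a variable of the dataset, or an external per-member
    value map ``{(family_id, member_index): 0/1}`` via ``screen_values`` for
    screens that are administered but not analyzed.
    """
    dependents = tuple(dependents)
    if screen in dependents:
        raise CohortError("screen variable cannot be its own dependent")
    new_fams = []
    for fam in ds.families:
        members = []
        for m, member in enumerate(fam.members):
            phen = dict(member.phenotypes)
            if screen_values is not None:
                s = screen_values.get((fam.family_id, m), np.nan)
            else:
                s = phen.get(screen, np.nan)
            endorsed = np.isfinite(s) and s == 1.0
            if not endorsed:
                for dep in dependents:
                    if dep in phen:
                        phen[dep] = np.nan
            members.append(Member(phen, dict(member.covariates)))
        new_fams.append(FamilyRecord(fam.family_id, fam.zygosity, members))
    return TwinDataset(ds.variables, new_fams, ds.covariates,
                       dict(ds.provenance))


# --------------------------------------------------------------------- #
# meiosis-based polygenic scores


def simulate_polygenic_pairs(n_pairs, zygosity, n_loci, seed,
                             freq_range=(0.1, 0.9)):
    """Per-member polygenic scores from simulated biallelic genotypes.

    Parents are drawn in Hardy-Weinberg proportions at ``n_loci``
    independent loci with allele frequencies uniform on ``freq_range``;
    children receive one allele per parent per locus.  MZ members share one
    meiosis; DZ members are independent full siblings.  Scores are
    effect-weighted allele-count sums, standardized over all members.

    Returns ``(genetic_values, prs)``; both have shape (n_pairs, 2), the
    former being the raw weighted allele sums before standardization.
    """
    if zygosity not in ("MZ", "DZ"):
        raise SimulationError(f"zygosity must be MZ or DZ, got {zygosity!r}")
    if n_loci < 1:
        raise SimulationError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*freq_range, size=n_loci)
    weights = rng.standard_normal(n_loci)
    mother = rng.binomial(2, freqs, size=(n_pairs, n_loci))
    father = rng.binomial(2, freqs, size=(n_pairs, n_loci))

    def meiosis(parent):
        # transmit 1 allele: genotype 0 -> 0, 2 -> 1, 1 -> Bernoulli(1/2)
        coin = rng.integers(0, 2, size=parent.shape)
        return np.where(parent == 1, coin, parent // 2)

    child1 = meiosis(mother) + meiosis(father)
    if zygosity == "MZ":
        child2 = child1.copy()
    else:
        child2 = meiosis(mother) + meiosis(father)
    g = np.stack([child1 @ weights, child2 @ weights], axis=1)
    prs = (g - g.mean()) / g.std(ddof=1)
    return g, prs


# --------------------------------------------------------------------- #
# study-like default configuration


STUDY_VARIABLES = (
    VariableSpec("prs_md", "continuous", components_allowed=("A",)),
    VariableSpec("prs_sb", "continuous", components_allowed=("A",)),
    VariableSpec("screen", "binary_liability"),
    VariableSpec("mdd", "binary_liability", covariates=("sex",)),
    VariableSpec("si", "binary_liability"),
    VariableSpec("sp", "binary_liability", covariates=("age",)),
    VariableSpec("sa", "binary_liability", covariates=("age",)),
)

# generating truth: AE structure echoing the study's best-fitting models.
# Heritabilities from the standardized estimates (diagnosis ~0.40, ideation
# ~0.52, plan ~0.60, attempt ~0.80); genetic correlations from the reported
# rA matrices; environmental correlations weak between diagnosis and items,
# strong among items.
_H2 = {"prs_md": 1.0, "prs_sb": 1.0, "screen": 0.40, "mdd": 0.40,
       "si": 0.52, "sp": 0.60, "sa": 0.80}
_RA = np.array([
    #  prs_md prs_sb screen mdd   si    sp    sa
    [1.00, 0.10, 0.22, 0.25, 0.18, 0.22, 0.14],
    [0.10, 1.00, 0.12, 0.12, 0.20, 0.16, 0.14],
    [0.22, 0.12, 1.00, 0.90, 0.60, 0.45, 0.48],
    [0.25, 0.12, 0.90, 1.00, 0.65, 0.48, 0.52],
    [0.18, 0.20, 0.60, 0.65, 1.00, 0.91, 0.85],
    [0.22, 0.16, 0.45, 0.48, 0.91, 1.00, 0.97],
    [0.14, 0.14, 0.48, 0.52, 0.85, 0.97, 1.00],
])
_RE = np.array([
    [1.00, 0.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 1.00, 0.00, 0.00, 0.00, 0.00, 0.00],
    [0.00, 0.00, 1.00, 0.70, 0.10, 0.12, -0.20],
    [0.00, 0.00, 0.70, 1.00, 0.06, 0.12, -0.25],
    [0.00, 0.00, 0.10, 0.06, 1.00, 0.75, 0.60],
    [0.00, 0.00, 0.12, 0.12, 0.75, 1.00, 0.64],
    [0.00, 0.00, -0.20, -0.25, 0.60, 0.64, 1.00],
])

#: marginal prevalences; diagnosis 0.18 (study range 16.7-19.7%), screen
#: 0.35 (so that roughly one member in three is asked the items); item
#: prevalences are solved below so conditional endorsement among diagnosed
#: members hits ideation 0.38, plan 0.14, attempt 0.065 (mid study ranges).
_PREV = {"screen": 0.35, "mdd": 0.18}
_CONDITIONAL = {"si": 0.38, "sp": 0.14, "sa": 0.065}

#: probit covariate effects: female excess in diagnosis liability; plan and
#: attempt decline with age (~ -0.035 per year on the liability scale)
_BETAS = {("mdd", "sex"): 0.35, ("sp", "age"): -0.035, ("sa", "age"): -0.035}


def _phenotypic_corr(model, v1, v2):
    S = model.within_covariance()
    i, j = model.var_index(v1), model.var_index(v2)
    return S[i, j] / math.sqrt(S[i, i] * S[j, j])


def _solve_item_threshold(corr3, tau_screen, tau_mdd, target):
    """tau such that P(item | screen = 1, diagnosis = 1) = target.

    Items are only observed for screen endorsers, so the observable
    conditional endorsement among diagnosed members conditions on both.
    ``corr3`` is the 3x3 liability correlation matrix (item, screen, mdd).
    """
    base = mvn_rectangle_probability(
        [0.0, 0.0], corr3[1:, 1:], [tau_screen, tau_mdd],
        [np.inf, np.inf])

    def f(tau):
        joint = mvn_rectangle_probability(
            [0.0, 0.0, 0.0], corr3, [tau, tau_screen, tau_mdd],
            [np.inf, np.inf, np.inf])
        return joint / base - target

    return brentq(f, -3.0, 4.0, xtol=1e-10)


def study_model() -> CholeskyModel:
    """The default generating model for study-like cohorts."""
    props = {name: {"A": _H2[name], "E": 1.0 - _H2[name]}
             for name in _H2}
    model = model_from_components(
        STUDY_VARIABLES, props, {"A": _RA, "E": _RE}, betas=_BETAS)
    taus = {name: float(ndtri(1.0 - prev)) for name, prev in _PREV.items()}
    for item, target in _CONDITIONAL.items():
        corr3 = np.eye(3)
        corr3[0, 1] = corr3[1, 0] = _phenotypic_corr(model, item, "screen")
        corr3[0, 2] = corr3[2, 0] = _phenotypic_corr(model, item, "mdd")
        corr3[1, 2] = corr3[2, 1] = _phenotypic_corr(model, "screen", "mdd")
        taus[item] = _solve_item_threshold(
            corr3, taus["screen"], taus["mdd"], target)
    model.thresholds.update(taus)
    return model


def study_config(seed, n_mz_pairs=530, n_dz_pairs=720,
                 singleton_fraction=0.28, with_covariates=True,
                 prs_missing=0.13) -> SimulationConfig:
    """Study-scale defaults: ~900 complete diagnosis pairs plus ~350
    singleton members, item responses gated on the depression screen."""
    model = study_model()
    if not with_covariates:
        model = model.copy()
        for key in model.betas:
            model.betas[key] = 0.0
    return SimulationConfig(
        n_mz_pairs=n_mz_pairs,
        n_dz_pairs=n_dz_pairs,
        model=model,
        seed=seed,
        gating_screen="screen",
        gating_dependents=("si", "sp", "sa"),
        singleton_fraction=singleton_fraction,
        missing_fraction={"prs_md": prs_missing, "prs_sb": prs_missing},
        drop_variables=(),
    )
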