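"""Multivariate Cholesky ACE liability models for twin data.

A :class:`CholeskyModel` holds lower-triangular path matrices for the
additive-genetic (A), shared-environment (C) and non-shared-environment (E)
sources of variance, liability thresholds for binary variables, free means
for continuous variables, and covariate ("definition variable") coefficients
that shift liability means per individual.

Classical-twin-design sharing constants are fixed: additive-genetic factor
scores correlate 1.0 across monozygotic (MZ) co-twins and 0.5 across
dizygotic (DZ) co-twins; shared-environment scores correlate 1.0 in both
zygosity groups; non-shared environment scores are uncorrelated.

Scale identification for binary (liability-threshold) variables is handled
by reparameterization: the diagonal path of one "carrier" component (E when
present, otherwise C, otherwise A) is not a free parameter but is computed
as sqrt(1 - sum of the variable's other squared paths), so the model-implied
total liability variance is exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

COMPONENTS = ("A", "C", "E")

#: cross-twin correlations of the latent factor scores, by component
RA_MZ = 1.0
RA_DZ = 0.5
RC = 1.0
RE = 0.0

# radicand floor for the derived carrier diagonal of binary variables
_RADICAND_FLOOR = 1e-6


class ModelError(ValueError):
    """Raised for invalid model specifications."""


@dataclass(frozen=True)
class VariableSpec:
    """Declares one analysis variable.

    Parameters
    ----------
    name : str
        Variable identifier; must match a dataset column stem.
    scale : {'continuous', 'binary_liability'}
        Continuous variables contribute a normal density to the likelihood;
        binary variables are threshold indicators of a unit-variance
        latent liability.
    components_allowed : subset of {'A', 'C', 'E'}
        Variance sources the variable may load on.  A polygenic score is
        declared ``('A',)`` only: by construction its variance is entirely
        additive-genetic.
    covariates : tuple of str
        Names of covariates whose effects shift this variable's liability
        mean (equivalently, its threshold).
    """

    name: str
    scale: str
    components_allowed: tuple = ("A", "C", "E")
    covariates: tuple = ()

    def __post_init__(self):
        if self.scale not in ("continuous", "binary_liability"):
            raise ModelError(f"unknown scale {self.scale!r} for {self.name!r}")
        comps = tuple(self.components_allowed)
        if not comps or any(c not in COMPONENTS for c in comps):
            raise ModelError(
                f"components_allowed for {self.name!r} must be a nonempty "
                f"subset of {COMPONENTS}, got {comps!r}"
            )
        object.__setattr__(self, "components_allowed", comps)
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def is_binary(self) -> bool:
        return self.scale == "binary_liability"

    @property
    def threshold_count(self) -> int:
        return 1 if self.is_binary else 0


@dataclass
class ExpectedMoments:
    """Model-implied mean vector (length 2p) and covariance (2p x 2p).

    Coordinates are ordered member 1's p variables, then member 2's.
    """

    mean: np.ndarray
    cov: np.ndarray
    variables: tuple


@dataclass
class ComponentSummary:
    """Standardized variance proportions and component correlation matrices.

    ``proportions`` maps component -> length-p array of standardized
    variance shares (A_i + C_i + E_i = 1 per variable).  ``correlations``
    maps component -> p x p correlation matrix; entries involving a
    variable with no variance in that component are NaN (undefined, never
    silently zero).
    """

    variables: tuple
    proportions: dict
    correlations: dict

    def proportion(self, component: str, variable: str) -> float:
        i = self.variables.index(variable)
        return float(self.proportions[component][i])

    def correlation(self, component: str, var1: str, var2: str) -> float:
        i = self.variables.index(var1)
        j = self.variables.index(var2)
        return float(self.correlations[component][i, j])


class CholeskyModel:
    """Trivariate-style Cholesky ACE model over an ordered variable list.

    Parameters are stored as dense p x p lower-triangular matrices per
    component together with boolean "free" masks; entries that are neither
    free nor derived are fixed at their stored value (normally 0).
    """

    def __init__(self, variables, active_components=("A", "C", "E")):
        self.variables = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ModelError("duplicate variable names")
        self.active_components = tuple(
            c for c in COMPONENTS if c in active_components
        )
        if not self.active_components:
            raise ModelError("at least one active component required")
        p = len(self.variables)
        self.p = p
        self.paths = {c: np.zeros((p, p)) for c in COMPONENTS}
        self.free = {c: np.zeros((p, p), dtype=bool) for c in COMPONENTS}
        for comp in self.active_components:
            for i, vi in enumerate(self.variables):
                for j in range(i + 1):
                    vj = self.variables[j]
                    if (comp in vi.components_allowed
                            and comp in vj.components_allowed):
                        self.free[comp][i, j] = True
        # carrier diagonals of binary variables are derived, not free
        self._carrier = {}
        for i, v in enumerate(self.variables):
            if v.is_binary:
                carrier = None
                for comp in ("E", "C", "A"):
                    if (comp in self.active_components
                            and comp in v.components_allowed):
                        carrier = comp
                        break
                if carrier is None:
                    raise ModelError(
                        f"binary variable {v.name!r} has no active component "
                        "to carry its unit-variance constraint"
                    )
                self._carrier[i] = carrier
                self.free[carrier][i, i] = False
        self.thresholds = {v.name: 0.0 for v in self.variables if v.is_binary}
        self.means = {
            v.name: 0.0 for v in self.variables if not v.is_binary
        }
        self.betas = {
            (v.name, c): 0.0 for v in self.variables for c in v.covariates
        }
        self._penalty = 0.0
        self._apply_scale_constraint()
        self._init_defaults()

    # ------------------------------------------------------------------ #
    # construction helpers

    def _init_defaults(self):
        """Reasonable interior starting values."""
        for i, v in enumerate(self.variables):
            comps = [c for c in self.active_components
                     if c in v.components_allowed]
            share = 1.0 / len(comps)
            for comp in comps:
                if self.free[comp][i, i]:
                    self.paths[comp][i, i] = math.sqrt(share)
        self._apply_scale_constraint()

    def copy(self) -> "CholeskyModel":
        new = CholeskyModel.__new__(CholeskyModel)
        new.variables = self.variables
        new.active_components = self.active_components
        new.p = self.p
        new.paths = {c: m.copy() for c, m in self.paths.items()}
        new.free = {c: m.copy() for c, m in self.free.items()}
        new._carrier = dict(self._carrier)
        new.thresholds = dict(self.thresholds)
        new.means = dict(self.means)
        new.betas = dict(self.betas)
        new._penalty = self._penalty
        return new

    def drop_paths(self, component: str, entries=None) -> "CholeskyModel":
        """Return a copy with the given path entries fixed at zero.

        ``entries`` is a list of (row, col) 1-based variable-index pairs;
        ``None`` drops every free entry of the component.  Derived carrier
        diagonals are reassigned if a binary variable loses its carrier.
        """
        new = self.copy()
        mask = new.free[component]
        if entries is None:
            sel = np.argwhere(mask)
        else:
            sel = np.asarray([(i - 1, j - 1) for i, j in entries])
            for i, j in sel:
                if not mask[i, j]:
                    raise ModelError(
                        f"path {component}[{i + 1},{j + 1}] is not free"
                    )
        for i, j in sel:
            new.free[component][i, j] = False
            new.paths[component][i, j] = 0.0
        # if the component is now entirely absent, deactivate it
        if not new.free[component].any() and not np.any(
                new.paths[component][np.tril_indices(new.p)]):
            still_derived = any(c == component for c in new._carrier.values())
            if not still_derived:
                new.active_components = tuple(
                    c for c in new.active_components if c != component
                )
        new._apply_scale_constraint()
        return new

    # ------------------------------------------------------------------ #
    # parameter vector interface

    def _free_path_entries(self):
        for comp in COMPONENTS:
            idx = np.argwhere(self.free[comp])
            for i, j in idx:
                yield comp, int(i), int(j)

    def parameter_labels(self):
        labels = [f"{c.lower()}{i + 1}{j + 1}"
                  for c, i, j in self._free_path_entries()]
        labels += [f"tau_{n}" for n in sorted(self.thresholds)]
        labels += [f"mu_{n}" for n in sorted(self.means)]
        labels += [f"beta_{v}_{c}" for v, c in sorted(self.betas)]
        return labels

    @property
    def n_free_params(self) -> int:
        return len(self.pack())

    def pack(self) -> np.ndarray:
        vals = [self.paths[c][i, j] for c, i, j in self._free_path_entries()]
        vals += [self.thresholds[n] for n in sorted(self.thresholds)]
        vals += [self.means[n] for n in sorted(self.means)]
        vals += [self.betas[k] for k in sorted(self.betas)]
        return np.asarray(vals, dtype=float)

    def unpack(self, theta) -> "CholeskyModel":
        """Return a copy with free parameters set from ``theta``."""
        theta = np.asarray(theta, dtype=float)
        new = self.copy()
        k = 0
        for comp, i, j in self._free_path_entries():
            new.paths[comp][i, j] = theta[k]
            k += 1
        for n in sorted(new.thresholds):
            new.thresholds[n] = theta[k]
            k += 1
        for n in sorted(new.means):
            new.means[n] = theta[k]
            k += 1
        for key in sorted(new.betas):
            new.betas[key] = theta[k]
            k += 1
        if k != len(theta):
            raise ModelError(
                f"parameter vector length {len(theta)}, expected {k}"
            )
        new._apply_scale_constraint()
        return new

    def parameter_bounds(self):
        bounds = []
        for comp, i, j in self._free_path_entries():
            if self.variables[i].is_binary:
                bounds.append((-0.999, 0.999))
            elif i == j:
                bounds.append((1e-4, 10.0))
            else:
                bounds.append((-10.0, 10.0))
        bounds += [(-5.0, 5.0)] * len(self.thresholds)
        bounds += [(-10.0, 10.0)] * len(self.means)
        bounds += [(-5.0, 5.0)] * len(self.betas)
        return bounds

    def _apply_scale_constraint(self):
        """Recompute derived carrier diagonals; accumulate boundary penalty."""
        penalty = 0.0
        for i, carrier in self._carrier.items():
            other = 0.0
            for comp in COMPONENTS:
                row = self.paths[comp][i, : i + 1]
                if comp == carrier:
                    other += float(np.sum(row[:-1] ** 2))
                else:
                    other += float(np.sum(row ** 2))
            rad = 1.0 - other
            if rad < _RADICAND_FLOOR:
                penalty += (
                    _RADICAND_FLOOR - rad) ** 2
                rad = _RADICAND_FLOOR
            self.paths[carrier][i, i] = math.sqrt(rad)
        self._penalty = penalty

    @property
    def constraint_penalty(self) -> float:
        """Quadratic penalty accrued when a binary row's non-carrier paths
        exceed the unit-variance budget (used by the optimizer)."""
        return self._penalty

    # ------------------------------------------------------------------ #
    # model-implied structure

    def validate(self):
        for comp in COMPONENTS:
            if np.any(np.triu(self.paths[comp], k=1) != 0.0):
                raise ModelError(f"{comp} paths not lower-triangular")
        for i, v in enumerate(self.variables):
            if v.is_binary:
                tot = sum(
                    float(np.sum(self.paths[c][i] ** 2)) for c in COMPONENTS
                )
                if abs(tot - 1.0) > 1e-6 and self._penalty == 0.0:
                    raise ModelError(
                        f"binary variable {v.name!r} has implied variance "
                        f"{tot:.6f} != 1"
                    )

    def component_covariance(self, component: str) -> np.ndarray:
        L = self.paths[component]
        return L @ L.T

    def within_covariance(self) -> np.ndarray:
        return sum(self.component_covariance(c) for c in COMPONENTS)

    def cross_covariance(self, zygosity: str) -> np.ndarray:
        if zygosity == "MZ":
            ra = RA_MZ
        elif zygosity == "DZ":
            ra = RA_DZ
        else:
            raise ModelError(f"unknown zygosity {zygosity!r}")
        return (ra * self.component_covariance("A")
                + RC * self.component_covariance("C")
                + RE * self.component_covariance("E"))

    def expected_moments(self, zygosity: str, covariates=None) -> ExpectedMoments:
        """Expected 2p mean and 2p x 2p covariance for a twin pair.

        ``covariates`` is ``{covariate_name: (x_member1, x_member2)}``;
        unreferenced covariates may be omitted (treated as 0).
        """
        covariates = covariates or {}
        S = self.within_covariance()
        C = self.cross_covariance(zygosity)
        p = self.p
        cov = np.empty((2 * p, 2 * p))
        cov[:p, :p] = S
        cov[p:, p:] = S
        cov[:p, p:] = C
        cov[p:, :p] = C.T
        mean = np.zeros(2 * p)
        for i, v in enumerate(self.variables):
            base = self.means.get(v.name, 0.0)
            for m in range(2):
                shift = base
                for c in v.covariates:
                    x = covariates.get(c, (0.0, 0.0))[m]
                    shift += self.betas[(v.name, c)] * x
                mean[m * p + i] = shift
        return ExpectedMoments(mean=mean, cov=cov,
                               variables=tuple(v.name for v in self.variables))

    def standardized_components(self) -> ComponentSummary:
        covs = {c: self.component_covariance(c) for c in COMPONENTS}
        total = sum(covs.values())
        v = np.diag(total)
        if np.any(v <= 0):
            raise ModelError("zero total variance for some variable")
        proportions = {c: np.diag(covs[c]) / v for c in COMPONENTS}
        correlations = {}
        for c in COMPONENTS:
            d = np.sqrt(np.diag(covs[c]))
            with np.errstate(divide="ignore", invalid="ignore"):
                R = covs[c] / np.outer(d, d)
            R[~np.isfinite(R)] = np.nan
            np.fill_diagonal(R, np.where(d > 0, 1.0, np.nan))
            correlations[c] = R
        return ComponentSummary(
            variables=tuple(v_.name for v_ in self.variables),
            proportions=proportions,
            correlations=correlations,
        )

    def component_correlations(self) -> ComponentSummary:
        return self.standardized_components()

    def var_index(self, name: str) -> int:
        for i, v in enumerate(self.variables):
            if v.name == name:
                return i
        raise ModelError(f"unknown variable {name!r}")

    def __repr__(self):
        comps = "".join(self.active_components)
        names = ", ".join(v.name for v in self.variables)
        return f"CholeskyModel({comps}; {names}; k={self.n_free_params})"


def build_ace_model(variables, active_components=("A", "C", "E")):
    """Construct a full Cholesky model with free lower-triangular paths."""
    return CholeskyModel(variables, active_components=active_components)


def model_from_components(variables, proportions, correlations,
                          thresholds=None, means=None, betas=None):
    """Build a CholeskyModel from target standardized structure.

    Intended for specifying simulation truths: ``proportions`` maps variable
    name -> {component: standardized share}; ``correlations`` maps component
    -> p x p correlation matrix between the components of the variables that
    have them (full p x p, entries for absent components ignored).  Shares
    must sum to 1 for every variable (continuous variables here are taken to
    have unit total variance, as a standardized polygenic score does).

    Component covariances are assembled as D^{1/2} R D^{1/2}, repaired to the
    nearest positive-semidefinite matrix if slightly indefinite, and factored
    back into lower-triangular paths.
    """
    variables = tuple(variables)
    p = len(variables)
    model = CholeskyModel(variables)
    for comp in COMPONENTS:
        d = np.array([proportions[v.name].get(comp, 0.0) for v in variables])
        if not np.any(d > 0):
            model.paths[comp][:] = 0.0
            continue
        R = np.asarray(correlations.get(comp, np.eye(p)), dtype=float).copy()
        np.fill_diagonal(R, 1.0)
        cov = np.outer(np.sqrt(d), np.sqrt(d)) * R
        cov = _nearest_psd(cov)
        model.paths[comp][:] = _lower_factor(cov)
    # overwrite carrier diagonals through the constraint so binary rows are
    # exactly unit variance even after PSD repair
    model._apply_scale_constraint()
    model.validate()
    if thresholds:
        model.thresholds.update(thresholds)
    if means:
        model.means.update(means)
    if betas:
        for key, val in betas.items():
            if key not in model.betas:
                raise ModelError(f"no covariate slot {key!r}")
            model.betas[key] = val
    return model


def _nearest_psd(mat, eps=1e-10):
    mat = (mat + mat.T) / 2.0
    w, V = np.linalg.eigh(mat)
    if w.min() >= 0:
        return mat
    w = np.clip(w, eps, None)
    return (V * w) @ V.T


def _lower_factor(cov):
    """Cholesky factor tolerant of semidefinite input."""
    p = cov.shape[0]
    try:
        return np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        w = np.clip(w, 0.0, None)
        root = (V * np.sqrt(w)) @ V.T
        # re-triangularize via QR of the transpose
        q, r = np.linalg.qr(root.T)
        L = r.T
        # fix signs so diagonal >= 0
        s = np.sign(np.diag(L))
        s[s == 0] = 1.0
        return L * s
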