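"""Descriptive statistics: FIML correlations and contingency tests.

Correlations are estimated on the liability/observed scale by maximum
likelihood: Pearson for two continuous variables, polyserial for a
continuous-binary pair, tetrachoric for two binary variables.  Latent
thresholds are estimated from the margins and the correlation by the
conditional likelihood of the joint observations (two-step FIML).  Twin-pair
correlations impose threshold homogeneity (one threshold shared by both
members and, when requested, across zygosity) as twin models assume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri
from scipy.stats import chi2, pearsonr

from .fiml import mvn_rectangle_probability

_RHO_LIM = 0.999
_CHI2_95 = float(chi2.ppf(0.95, 1))


class DescriptivesError(ValueError):
    pass


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DescriptivesError("negative cell count")
        if self.n < 1:
            raise DescriptivesError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_arrays(cls, group, outcome):
        group = np.asarray(group, dtype=float)
        outcome = np.asarray(outcome, dtype=float)
        ok = np.isfinite(group) & np.isfinite(outcome)
        g, o = group[ok], outcome[ok]
        return cls(
            a=int(np.sum((g == 0) & (o == 0))),
            b=int(np.sum((g == 0) & (o == 1))),
            c=int(np.sum((g == 1) & (o == 0))),
            d=int(np.sum((g == 1) & (o == 1))),
        )


@dataclass
class CorrelationEstimate:
    value: float
    ci: tuple
    method: str
    n_effective: int
    flag: str = ""

    def __str__(self):
        lo, hi = self.ci
        return f"{self.value:.2f} ({lo:.2f}, {hi:.2f})"


def yates_chi_square(t: ContingencyTable2x2):
    """Pearson chi-squared with Yates' continuity correction, df = 1.

    The corrected deviation |ad - bc| - n/2 is floored at zero (the
    conservative clamp), so perfectly homogeneous tables give statistic 0.
    """
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise DescriptivesError("zero marginal total: test undefined")
    num = max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2
    stat = n * num / math.prod(margins)
    p = float(chi2.sf(stat, 1))
    return stat, 1, p


_V_LABELS = ((0.5, "large"), (0.3, "medium"), (0.1, "small"))


def cramers_v(statistic, n, shape=(2, 2)):
    """Cramer's V effect size with the conventional magnitude label.

    Labels use half-open bins: < 0.1 negligible, [0.1, 0.3) small,
    [0.3, 0.5) medium, >= 0.5 large.
    """
    if statistic < 0 or n < 1:
        raise DescriptivesError("invalid inputs")
    r, c = shape
    v = math.sqrt(statistic / (n * min(r - 1, c - 1)))
    v = min(v, 1.0)
    label = "negligible"
    for cut, name in _V_LABELS:
        if v >= cut:
            label = name
            break
    return v, label


# --------------------------------------------------------------------- #
# latent-scale pairwise correlations (individual level)


def _profile_ci_scalar(nll, rho_hat, lo_bound, hi_bound, level=0.95):
    """Likelihood-based CI by bisection on a one-parameter profile."""
    crit = float(chi2.ppf(level, 1))
    base = nll(rho_hat)

    def bound(direction):
        lim = hi_bound if direction > 0 else lo_bound
        x0, x1 = rho_hat, lim
        if 2.0 * (nll(lim) - base) < crit:
            return lim, "boundary"
        for _ in range(60):
            mid = (x0 + x1) / 2.0
            if 2.0 * (nll(mid) - base) < crit:
                x0 = mid
            else:
                x1 = mid
            if abs(x1 - x0) < 1e-4:
                break
        return (x0 + x1) / 2.0, ""

    lo, f_lo = bound(-1)
    hi, f_hi = bound(+1)
    flag = ";".join(x for x in (f_lo and "lower-" + f_lo,
                                f_hi and "upper-" + f_hi) if x)
    return (lo, hi), flag


def _pattern_counts(y1, y2):
    counts = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            counts[i, j] = np.sum((y1 == i) & (y2 == j))
    return counts


def tetrachoric(y1, y2, shared_threshold=False):
    """Tetrachoric correlation by two-step ML (thresholds from margins)."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    ok = np.isfinite(y1) & np.isfinite(y2)
    y1, y2 = y1[ok], y2[ok]
    n = y1.size
    if n < 10:
        raise DescriptivesError("fewer than 10 joint observations")
    if shared_threshold:
        pbar = np.concatenate([y1, y2]).mean()
        t1 = t2 = _safe_ndtri(1.0 - pbar)
    else:
        t1 = _safe_ndtri(1.0 - y1.mean())
        t2 = _safe_ndtri(1.0 - y2.mean())
    counts = _pattern_counts(y1, y2)
    if counts[0, 0] + counts[1, 1] == n or counts[0, 1] + counts[1, 0] == n:
        # perfect (anti-)concordance: boundary estimate
        val = 1.0 if counts[0, 0] + counts[1, 1] == n else -1.0
        return val, (t1, t2), "boundary"

    def nll(rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        ll = 0.0
        for i in (0, 1):
            for j in (0, 1):
                if counts[i, j] == 0:
                    continue
                lo = [t1 if i else -np.inf, t2 if j else -np.inf]
                hi = [np.inf if i else t1, np.inf if j else t2]
                pr = mvn_rectangle_probability([0, 0], cov, lo, hi)
                ll += counts[i, j] * math.log(max(pr, 1e-300))
        return -ll

    res = minimize_scalar(nll, bounds=(-_RHO_LIM, _RHO_LIM),
                          method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x), (t1, t2), ""


def _safe_ndtri(q):
    return float(ndtri(np.clip(q, 1e-6, 1 - 1e-6)))


def polyserial(x, y):
    """Polyserial correlation: continuous x, binary y, two-step ML."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10:
        raise DescriptivesError("fewer than 10 joint observations")
    z = (x - x.mean()) / x.std(ddof=1)
    tau = _safe_ndtri(1.0 - y.mean())

    def nll(rho):
        s = math.sqrt(max(1.0 - rho * rho, 1e-10))
        q = (rho * z - tau) / s
        p1 = np.clip(ndtr(q), 1e-12, 1 - 1e-12)
        return -float(np.sum(np.where(y == 1, np.log(p1), np.log(1 - p1))))

    res = minimize_scalar(nll, bounds=(-_RHO_LIM, _RHO_LIM),
                          method="bounded", options={"xatol": 1e-6})
    return float(res.x), tau, nll


def _corr_pair(x, y, scale_x, scale_y):
    """(estimate, ci, method, n, flag) for one variable pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 10:
        return CorrelationEstimate(np.nan, (np.nan, np.nan), "none", n,
                                   flag="low-n")
    if scale_x == "continuous" and scale_y == "continuous":
        r = float(pearsonr(x[ok], y[ok]).statistic)
        zcrit = 1.959963984540054
        zr = np.arctanh(np.clip(r, -_RHO_LIM, _RHO_LIM))
        se = 1.0 / math.sqrt(max(n - 3, 1))
        ci = (math.tanh(zr - zcrit * se), math.tanh(zr + zcrit * se))
        return CorrelationEstimate(r, ci, "pearson", n)
    if scale_x != "continuous" and scale_y != "continuous":
        rho, (t1, t2), flag = tetrachoric(x, y)
        if flag == "boundary":
            return CorrelationEstimate(rho, (rho, rho), "tetrachoric", n,
                                       flag=flag)

        def nll(r):
            cov = np.array([[1.0, r], [r, 1.0]])
            counts = _pattern_counts(x[ok], y[ok])
            ll = 0.0
            for i in (0, 1):
                for j in (0, 1):
                    if counts[i, j] == 0:
                        continue
                    lo = [t1 if i else -np.inf, t2 if j else -np.inf]
                    hi = [np.inf if i else t1, np.inf if j else t2]
                    pr = mvn_rectangle_probability([0, 0], cov, lo, hi)
                    ll += counts[i, j] * math.log(max(pr, 1e-300))
            return -ll

        ci, flag = _profile_ci_scalar(nll, rho, -_RHO_LIM, _RHO_LIM)
        return CorrelationEstimate(rho, ci, "tetrachoric", n, flag=flag)
    # mixed
    if scale_x == "continuous":
        cont, binv = x, y
    else:
        cont, binv = y, x
    rho, tau, nll = polyserial(cont, binv)
    ci, flag = _profile_ci_scalar(nll, rho, -_RHO_LIM, _RHO_LIM)
    return CorrelationEstimate(rho, ci, "polyserial", n, flag=flag)


def fiml_correlation_matrix(ds, variables):
    """Pairwise latent-scale correlation matrix over individuals.

    ``variables`` may name phenotypes or covariates (sex is treated as
    binary, other covariates as continuous).  Returns a dict of dicts of
    :class:`CorrelationEstimate`; the diagonal is exactly 1.
    """
    if len(variables) < 2:
        raise DescriptivesError("need at least 2 variables")
    cols = {}
    scales = {}
    phen_names = {v.name for v in ds.variables}
    for name in variables:
        if name in phen_names:
            cols[name] = ds.values(name)
            scales[name] = ds.variable(name).scale
        elif name in ds.covariates:
            vals = []
            for fam in ds.families:
                for member in fam.members:
                    vals.append(member.covariates.get(name, np.nan))
            cols[name] = np.asarray(vals, dtype=float)
            scales[name] = "binary_liability" if name == "sex" \
                else "continuous"
        else:
            raise DescriptivesError(f"unknown variable {name!r}")
    out = {a: {} for a in variables}
    for i, a in enumerate(variables):
        for j, b in enumerate(variables):
            if j < i:
                out[a][b] = out[b][a]
            elif i == j:
                n = int(np.isfinite(cols[a]).sum())
                out[a][b] = CorrelationEstimate(1.0, (1.0, 1.0), "self", n)
            else:
                out[a][b] = _corr_pair(cols[a], cols[b],
                                       scales[a], scales[b])
    return out


# --------------------------------------------------------------------- #
# twin-pair correlations


def twin_pair_correlation(ds, variable, zygosity) -> CorrelationEstimate:
    """Within-pair correlation by FIML under threshold homogeneity.

    Binary variables: tetrachoric correlation with one threshold shared by
    both members, estimated from complete pairs plus singletons.
    Continuous variables: bivariate-normal ML with common mean/variance.
    Profile-likelihood 95% CI.
    """
    spec = ds.variable(variable)
    pairs = ds.pair_values(variable, zygosity)
    both = pairs[np.isfinite(pairs).all(axis=1)]
    single = pairs[np.isfinite(pairs).sum(axis=1) == 1]
    singles = single[np.isfinite(single)]
    n_pairs = both.shape[0]
    if n_pairs < 10:
        raise DescriptivesError(
            f"{variable} {zygosity}: fewer than 10 informative pairs "
            f"({n_pairs})")
    if spec.is_binary:
        for col in (0, 1):
            if len(set(both[:, col])) < 2 and singles.size == 0:
                return CorrelationEstimate(
                    np.nan, (np.nan, np.nan), "tetrachoric", n_pairs,
                    flag="no-variation")
        prev = np.concatenate([both.ravel(), singles]).mean()
        tau = _safe_ndtri(1.0 - prev)
        counts = _pattern_counts(both[:, 0], both[:, 1])
        n1 = float(np.sum(singles == 1))
        n0 = float(np.sum(singles == 0))

        def nll(rho):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            ll = 0.0
            for i in (0, 1):
                for j in (0, 1):
                    if counts[i, j] == 0:
                        continue
                    lo = [tau if i else -np.inf, tau if j else -np.inf]
                    hi = [np.inf if i else tau, np.inf if j else tau]
                    pr = mvn_rectangle_probability([0, 0], cov, lo, hi)
                    ll += counts[i, j] * math.log(max(pr, 1e-300))
            p1 = max(1.0 - ndtr(tau), 1e-300)
            ll += n1 * math.log(p1) + n0 * math.log(max(1 - p1, 1e-300))
            return -ll

        concord = counts[0, 0] + counts[1, 1]
        if concord == n_pairs or counts[0, 1] + counts[1, 0] == n_pairs:
            val = 1.0 if concord == n_pairs else -1.0
            ci, flag = _profile_ci_scalar(nll, val * _RHO_LIM,
                                          -_RHO_LIM, _RHO_LIM)
            return CorrelationEstimate(val, ci, "tetrachoric", n_pairs,
                                       flag="boundary")
        res = minimize_scalar(nll, bounds=(-_RHO_LIM, _RHO_LIM),
                              method="bounded", options={"xatol": 1e-6})
        rho = float(res.x)
        ci, flag = _profile_ci_scalar(nll, rho, -_RHO_LIM, _RHO_LIM)
        return CorrelationEstimate(rho, ci, "tetrachoric", n_pairs,
                                   flag=flag)
    # continuous: common mean/variance bivariate normal, singletons included
    allv = np.concatenate([both.ravel(), singles])
    mu, sd = float(allv.mean()), float(allv.std(ddof=1))
    z = (both - mu) / sd
    zs = (singles - mu) / sd
    s11 = float(np.mean(z[:, 0] ** 2 + z[:, 1] ** 2) / 2.0)
    s12 = float(np.mean(z[:, 0] * z[:, 1]))

    def nll(rho):
        det = max(1.0 - rho * rho, 1e-12)
        n = z.shape[0]
        quad = n * (s11 * 2.0 - 2.0 * rho * s12) / det
        ll = -0.5 * quad - 0.5 * n * math.log(det)
        ll += -0.5 * float(np.sum(zs ** 2))
        return -ll

    res = minimize_scalar(nll, bounds=(-_RHO_LIM, _RHO_LIM),
                          method="bounded", options={"xatol": 1e-7})
    rho = float(res.x)
    ci, flag = _profile_ci_scalar(nll, rho, -_RHO_LIM, _RHO_LIM)
    return CorrelationEstimate(rho, ci, "pearson", n_pairs, flag=flag)
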