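"""Six-group ACE likelihood machinery for a binary sleep-duration moderator.

The phenotype (insomnia symptoms, residualized for age and sex and
z-standardized) is modelled for twin pairs classified into six groups:
MZ/DZ pairs concordant for short sleep, concordant for normal/long sleep,
and discordant for sleep duration.  Within each sleep-duration group the
phenotypic variance decomposes into additive-genetic (A), shared-
environmental (C) and non-shared-environmental (E) path coefficients, in
the style of a sex-limitation model where the moderating stratum is sleep
duration rather than sex (and, unlike sex, MZ pairs can be discordant for
it).

Three heterogeneity variants are supported:

``full``
    Group-specific paths and means plus qualitative-difference
    correlations ``rA_mz``, ``rA_dz``, ``rC`` that attenuate the
    cross-twin covariance of discordant pairs (11 free parameters for
    ACE).
``quantitative``
    Group-specific paths and means; the qualitative correlations are
    fixed at 1 (8 free parameters).
``homogeneity``
    One set of paths and one mean shared by both groups (4 free
    parameters).

The objective is full-information maximum likelihood (FIML): complete
pairs contribute a bivariate Gaussian density at the model-implied
moments; pairs with a single phenotyped twin contribute the univariate
marginal for that twin's own sleep group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scales import NORMAL_LONG, SHORT, classify_sleep_duration, residualize_standardize

__all__ = [
    "PairGroup",
    "ACEPathParams",
    "ModelSpec",
    "build_model",
    "GroupedPairData",
    "implied_moments",
    "neg2ll",
    "standardized_components",
    "aic",
    "lrt",
    "lrt_pvalue",
    "ACEHeterogeneityModel",
    "ACEHeterogeneityResults",
]

LOG_2PI = float(np.log(2.0 * np.pi))


class PairGroup(str, Enum):
    """The six likelihood groups of the moderated twin design."""

    MZ_CONC_SHORT = "MZ_CS"
    MZ_CONC_NORMAL = "MZ_CN"
    MZ_DISCORDANT = "MZ_D"
    DZ_CONC_SHORT = "DZ_CS"
    DZ_CONC_NORMAL = "DZ_CN"
    DZ_DISCORDANT = "DZ_D"

    @property
    def is_mz(self) -> bool:
        return self.value.startswith("MZ")

    @property
    def is_discordant(self) -> bool:
        return self.value.endswith("_D")


@dataclass(frozen=True)
class ACEPathParams:
    """Path coefficients, group means and qualitative correlations.

    ``a_s, c_s, e_s`` are the short-sleep group's paths (phenotype SD
    units), ``a_n, c_n, e_n`` the normal/long group's; ``mu_s, mu_n`` the
    group means.  ``rA_mz``, ``rA_dz``, ``rC`` correlate the two groups'
    genetic and shared-environmental factors and act only on the
    cross-twin covariance of discordant pairs (1 = the same factors
    operate in both groups; cross-twin E covariance is always 0).
    """

    a_s: float
    c_s: float
    e_s: float
    a_n: float
    c_n: float
    e_n: float
    mu_s: float = 0.0
    mu_n: float = 0.0
    rA_mz: float = 1.0
    rA_dz: float = 1.0
    rC: float = 1.0

    def variance(self, sleep_group: str) -> float:
        a, c, e = self.paths(sleep_group)
        return a * a + c * c + e * e

    def mean(self, sleep_group: str) -> float:
        return self.mu_s if sleep_group == SHORT else self.mu_n

    def paths(self, sleep_group: str) -> tuple[float, float, float]:
        if sleep_group == SHORT:
            return self.a_s, self.c_s, self.e_s
        return self.a_n, self.c_n, self.e_n


PARAM_NAMES = ("a_s", "c_s", "e_s", "a_n", "c_n", "e_n",
               "mu_s", "mu_n", "rA_mz", "rA_dz", "rC")
_PATHS = {"A": ("a_s", "a_n"), "C": ("c_s", "c_n"), "E": ("e_s", "e_n")}


@dataclass(frozen=True)
class ModelSpec:
    """Which parameters are free, fixed, or equated across sleep groups.

    ``param_map`` maps every parameter name to ``"free"``, ``("fixed",
    value)`` or ``("equated", partner_name)``.  ``free_names`` lists the
    independently estimated parameters in optimization order.
    """

    kind: str
    components: str
    free_names: tuple[str, ...]
    param_map: dict[str, object] = field(hash=False)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def to_params(self, theta) -> ACEPathParams:
        theta = np.asarray(theta, dtype=float)
        vals = dict(zip(self.free_names, theta))
        out = {}
        for name in PARAM_NAMES:
            rule = self.param_map[name]
            if rule == "free":
                out[name] = vals[name]
            elif isinstance(rule, tuple) and rule[0] == "fixed":
                out[name] = rule[1]
            else:  # equated to a free partner
                out[name] = vals[rule[1]]
        return ACEPathParams(**out)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        return [(-1.0, 1.0) if n.startswith("r") else (None, None)
                for n in self.free_names]


def build_model(kind: str, components: str = "ACE") -> ModelSpec:
    """Construct the parameter map for one heterogeneity variant.

    ``kind`` is ``full``, ``quantitative`` or ``homogeneity``;
    ``components`` is ``ACE``, ``AE``, ``CE`` or ``E``.  Dropping
    components is supported for the quantitative and homogeneity kinds
    only (the full model is always fitted as ACE).
    """
    if kind not in ("full", "quantitative", "homogeneity"):
        raise ValueError(f"unknown model kind: {kind!r}")
    if components not in ("ACE", "AE", "CE", "E"):
        raise ValueError(f"unknown component set: {components!r}")
    if kind == "full" and components != "ACE":
        raise ValueError("dropped-component variants are defined for the "
                         "quantitative and homogeneity kinds only")

    pmap: dict[str, object] = {}
    free: list[str] = []
    dropped = {"A": "A" not in components, "C": "C" not in components,
               "E": False}

    for comp, (name_s, name_n) in _PATHS.items():
        if dropped[comp]:
            pmap[name_s] = ("fixed", 0.0)
            pmap[name_n] = ("fixed", 0.0)
        elif kind == "homogeneity":
            pmap[name_s] = "free"
            free.append(name_s)
            pmap[name_n] = ("equated", name_s)
        else:
            pmap[name_s] = "free"
            pmap[name_n] = "free"
            free.extend([name_s, name_n])

    if kind == "homogeneity":
        pmap["mu_s"] = "free"
        free.append("mu_s")
        pmap["mu_n"] = ("equated", "mu_s")
    else:
        pmap["mu_s"] = "free"
        pmap["mu_n"] = "free"
        free.extend(["mu_s", "mu_n"])

    for r in ("rA_mz", "rA_dz", "rC"):
        if kind == "full":
            pmap[r] = "free"
            free.append(r)
        else:
            pmap[r] = ("fixed", 1.0)

    return ModelSpec(kind=kind, components=components,
                     free_names=tuple(free), param_map=pmap)


def implied_moments(params: ACEPathParams, group: PairGroup,
                    model_kind: str = "full"):
    """Model-implied mean vector (length 2) and 2x2 covariance for a group.

    Twin 1 of a discordant pair is, by convention, the short sleeper.
    Under the quantitative and homogeneity kinds the qualitative
    correlations are treated as 1 regardless of their values in
    ``params``.
    """
    rA_mz, rA_dz, rC = ((params.rA_mz, params.rA_dz, params.rC)
                        if model_kind == "full" else (1.0, 1.0, 1.0))
    v_s, v_n = params.variance(SHORT), params.variance(NORMAL_LONG)

    if group is PairGroup.MZ_CONC_SHORT or group is PairGroup.DZ_CONC_SHORT:
        mu = np.array([params.mu_s, params.mu_s])
        var = np.array([v_s, v_s])
        alpha = 1.0 if group.is_mz else 0.5
        cov = alpha * params.a_s ** 2 + params.c_s ** 2
    elif group is PairGroup.MZ_CONC_NORMAL or group is PairGroup.DZ_CONC_NORMAL:
        mu = np.array([params.mu_n, params.mu_n])
        var = np.array([v_n, v_n])
        alpha = 1.0 if group.is_mz else 0.5
        cov = alpha * params.a_n ** 2 + params.c_n ** 2
    else:  # discordant, twin 1 short
        mu = np.array([params.mu_s, params.mu_n])
        var = np.array([v_s, v_n])
        if group.is_mz:
            cov = rA_mz * params.a_s * params.a_n + rC * params.c_s * params.c_n
        else:
            cov = 0.5 * rA_dz * params.a_s * params.a_n + rC * params.c_s * params.c_n
    sigma = np.array([[var[0], cov], [cov, var[1]]])
    return mu, sigma


@dataclass
class GroupedPairData:
    """Sufficient statistics of a cohort for the six-group FIML objective.

    ``pair_stats[group]`` holds ``(n, s1, s2)`` for complete pairs: the
    pair count, the 2-vector of column sums and the 2x2 matrix of raw
    cross-products.  ``single_stats[sleep_group]`` holds ``(n, sx, sxx)``
    for individuals whose co-twin has no phenotype.  Because every pair
    in a group shares the same implied moments, these statistics make the
    likelihood evaluation O(#groups) irrespective of cohort size.
    """

    pair_stats: dict[PairGroup, tuple[int, np.ndarray, np.ndarray]]
    single_stats: dict[str, tuple[int, float, float]]
    n_obs: int
    n_pairs_complete: int
    n_excluded_pairs: int
    pair_values: dict[PairGroup, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, zyg, label1, label2, y1, y2, keep_values: bool = False):
        zyg = np.asarray(zyg, dtype=object)
        label1 = np.asarray(label1, dtype=object)
        label2 = np.asarray(label2, dtype=object)
        y1 = np.asarray(y1, dtype=float).copy()
        y2 = np.asarray(y2, dtype=float).copy()

        valid1 = np.isin(label1, (SHORT, NORMAL_LONG))
        valid2 = np.isin(label2, (SHORT, NORMAL_LONG))
        ok1 = np.isfinite(y1) & valid1
        ok2 = np.isfinite(y2) & valid2
        both = ok1 & ok2

        short1 = label1 == SHORT
        short2 = label2 == SHORT
        # order discordant pairs so twin 1 is the short sleeper
        swap = both & (short1 != short2) & ~short1
        y1[swap], y2[swap] = y2[swap], y1[swap].copy()
        short1s = np.where(swap, short2, short1)
        short2s = np.where(swap, short1, short2)

        is_mz = zyg == "MZ"
        masks = {
            PairGroup.MZ_CONC_SHORT: both & is_mz & short1s & short2s,
            PairGroup.MZ_CONC_NORMAL: both & is_mz & ~short1s & ~short2s,
            PairGroup.MZ_DISCORDANT: both & is_mz & (short1s != short2s),
            PairGroup.DZ_CONC_SHORT: both & ~is_mz & short1s & short2s,
            PairGroup.DZ_CONC_NORMAL: both & ~is_mz & ~short1s & ~short2s,
            PairGroup.DZ_DISCORDANT: both & ~is_mz & (short1s != short2s),
        }

        pair_stats: dict[PairGroup, tuple[int, np.ndarray, np.ndarray]] = {}
        pair_values: dict[PairGroup, np.ndarray] = {}
        n_obs = 0
        n_pairs_complete = 0
        for grp, mask in masks.items():
            vals = np.column_stack([y1[mask], y2[mask]])
            n = vals.shape[0]
            pair_stats[grp] = (n, vals.sum(axis=0), vals.T @ vals)
            pair_values[grp] = vals
            n_obs += 2 * n
            n_pairs_complete += n

        single_stats = {}
        for lab in (SHORT, NORMAL_LONG):
            v = np.concatenate([
                y1[ok1 & ~both & (label1 == lab)],
                y2[ok2 & ~both & (label2 == lab)],
            ])
            single_stats[lab] = (v.size, float(v.sum()), float(v @ v))
            n_obs += v.size

        n_excluded = int((~ok1 & ~ok2).sum())
        out = cls(pair_stats=pair_stats, single_stats=single_stats,
                  n_obs=n_obs, n_pairs_complete=n_pairs_complete,
                  n_excluded_pairs=n_excluded)
        if keep_values:
            out.pair_values = pair_values
        return out

    def sample_moments(self) -> dict[str, tuple[float, float]]:
        """Pooled per-sleep-group (mean, variance), used for start values."""
        sums = {SHORT: [0.0, 0.0, 0.0], NORMAL_LONG: [0.0, 0.0, 0.0]}

        def _acc(lab, n, sx, sxx):
            sums[lab][0] += n
            sums[lab][1] += sx
            sums[lab][2] += sxx

        for grp, (n, s1, s2) in self.pair_stats.items():
            if grp.is_discordant:
                _acc(SHORT, n, s1[0], s2[0, 0])
                _acc(NORMAL_LONG, n, s1[1], s2[1, 1])
            else:
                lab = SHORT if grp.value.endswith("CS") else NORMAL_LONG
                _acc(lab, 2 * n, s1.sum(), s2[0, 0] + s2[1, 1])
        for lab, (n, sx, sxx) in self.single_stats.items():
            _acc(lab, n, sx, sxx)

        out = {}
        for lab, (n, sx, sxx) in sums.items():
            if n > 1:
                m = sx / n
                out[lab] = (m, max(sxx / n - m * m, 1e-6))
            else:
                out[lab] = (0.0, 1.0)
        return out


def neg2ll(params: ACEPathParams, data: GroupedPairData,
           model_kind: str = "full") -> float:
    """FIML -2 log-likelihood of the cohort under the six-group model.

    Returns ``+inf`` when any implied pair covariance matrix is not
    positive definite (a rejected point for the optimizer).
    """
    total = 0.0
    for grp, (n, s1, s2) in data.pair_stats.items():
        if n == 0:
            continue
        mu, sigma = implied_moments(params, grp, model_kind)
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
        if det <= 0 or sigma[0, 0] <= 0 or sigma[1, 1] <= 0:
            return float("inf")
        # centred scatter from raw sufficient statistics
        m = s2 - np.outer(s1, mu) - np.outer(mu, s1) + n * np.outer(mu, mu)
        inv00 = sigma[1, 1] / det
        inv11 = sigma[0, 0] / det
        inv01 = -sigma[0, 1] / det
        quad = inv00 * m[0, 0] + inv11 * m[1, 1] + 2.0 * inv01 * m[0, 1]
        total += n * (2.0 * LOG_2PI + np.log(det)) + quad

    for lab, (n, sx, sxx) in data.single_stats.items():
        if n == 0:
            continue
        mu = params.mean(lab)
        var = params.variance(lab)
        if var <= 0:
            return float("inf")
        quad = (sxx - 2.0 * mu * sx + n * mu * mu) / var
        total += n * (LOG_2PI + np.log(var)) + quad
    return float(total)


def standardized_components(params: ACEPathParams,
                            sleep_group: str) -> tuple[float, float, float]:
    """Proportions of variance (A, C, E) for one sleep-duration group."""
    a, c, e = params.paths(sleep_group)
    total = a * a + c * c + e * e
    if total <= 0:
        raise ValueError("total variance is zero")
    return (a * a / total, c * c / total, e * e / total)


def aic(minus2ll: float, n_free: int) -> float:
    """Akaike information criterion: -2LL + 2 * (free parameters)."""
    if n_free < 0:
        raise ValueError("n_free must be non-negative")
    return float(minus2ll) + 2.0 * n_free


def lrt_pvalue(diff_minus2ll: float, diff_df: int) -> float:
    """Upper-tail chi-square probability of a -2LL difference."""
    if diff_minus2ll < 0:
        raise ValueError("-2LL difference must be non-negative")
    if diff_df < 1:
        raise ValueError("diff_df must be >= 1")
    return float(stats.chi2.sf(diff_minus2ll, diff_df))


def lrt(nested, reference, tol: float = 1e-6):
    """Likelihood-ratio chi-square test of a nested against a fuller model.

    Returns ``(diff_minus2ll, diff_df, p)``.  A difference more negative
    than ``-tol`` signals an optimizer failure and raises.
    """
    if nested.n_free >= reference.n_free:
        raise ValueError("nested model must have fewer free parameters")
    diff = nested.minus2ll - reference.minus2ll
    if diff < -tol:
        raise ValueError(
            f"nested model fits better than reference by {-diff:.3g}; "
            "optimizer failure")
    diff = max(diff, 0.0)
    diff_df = reference.n_free - nested.n_free
    return diff, diff_df, lrt_pvalue(diff, diff_df)


# ---------------------------------------------------------------------------
# Model / Results


class ACEHeterogeneityModel:
    """Six-group moderated ACE model bound to a twin cohort.

    Parameters
    ----------
    data : GroupedPairData
        Sufficient statistics of the (already residualized and
        standardized) phenotype.
    kind : {"full", "quantitative", "homogeneity"}
    components : {"ACE", "AE", "CE", "E"}

    Use :meth:`from_cohort` to build directly from a pair-per-row cohort
    frame; it residualizes the phenotype on age and sex and z-standardizes
    it before grouping, so covariate effects never enter the likelihood.
    """

    def __init__(self, data: GroupedPairData, kind: str = "quantitative",
                 components: str = "ACE"):
        self.data = data
        self.spec = build_model(kind, components)

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, kind: str = "quantitative",
                    components: str = "ACE", phenotype: str = "isi",
                    adjust_covariates: bool = True) -> "ACEHeterogeneityModel":
        data = grouped_data_from_cohort(cohort, phenotype=phenotype,
                                        adjust_covariates=adjust_covariates)
        return cls(data, kind=kind, components=components)

    def neg2ll(self, params: ACEPathParams) -> float:
        return neg2ll(params, self.data, self.spec.kind)

    def _objective(self, theta) -> float:
        # finite rejection value: keeps quasi-Newton finite differences sane
        val = neg2ll(self.spec.to_params(theta), self.data, self.spec.kind)
        return min(val, 1e12)

    def _start_values(self, rng: np.random.Generator, n_starts: int):
        moments = self.data.sample_moments()
        (m_s, v_s), (m_n, v_n) = moments[SHORT], moments[NORMAL_LONG]
        starts = []
        shares0 = np.array([0.3, 0.2, 0.5])
        for k in range(n_starts):
            shares = shares0 if k == 0 else rng.dirichlet([1.0, 1.0, 1.0])
            r0 = 0.9 if k == 0 else float(rng.uniform(0.3, 1.0))
            vals = {
                "a_s": np.sqrt(shares[0] * v_s), "c_s": np.sqrt(shares[1] * v_s),
                "e_s": np.sqrt(max(shares[2], 0.05) * v_s),
                "a_n": np.sqrt(shares[0] * v_n), "c_n": np.sqrt(shares[1] * v_n),
                "e_n": np.sqrt(max(shares[2], 0.05) * v_n),
                "mu_s": m_s, "mu_n": m_n,
                "rA_mz": r0, "rA_dz": r0, "rC": r0,
            }
            if self.spec.kind == "homogeneity":
                vv = 0.5 * (v_s + v_n)
                vals["a_s"] = np.sqrt(shares[0] * vv)
                vals["c_s"] = np.sqrt(shares[1] * vv)
                vals["e_s"] = np.sqrt(max(shares[2], 0.05) * vv)
                vals["mu_s"] = 0.5 * (m_s + m_n)
            starts.append(np.array([vals[n] for n in self.spec.free_names]))
        return starts

    def fit(self, seed: int = 0, n_starts: int = 5,
            agree_tol: float = 1e-4) -> "ACEHeterogeneityResults":
        """Minimize the FIML objective from several dispersed starts.

        The reported fit is the best of ``n_starts`` quasi-Newton
        (L-BFGS-B) runs started from Dirichlet-drawn standardized-
        component configurations.  ``converged`` requires the best run to
        have terminated successfully and the best two runs to agree in
        -2LL within ``agree_tol``.
        """
        rng = np.random.default_rng(seed)
        bounds = self.spec.bounds()
        runs = []
        for x0 in self._start_values(rng, max(n_starts, 2)):
            res = optimize.minimize(self._objective, x0, method="L-BFGS-B",
                                    bounds=bounds,
                                    options={"maxiter": 1000, "ftol": 1e-13,
                                             "gtol": 1e-8})
            runs.append(res)
        runs.sort(key=lambda r: (r.fun, float(np.linalg.norm(r.x))))
        best = runs[0]
        if not np.isfinite(best.fun):
            raise RuntimeError("no start converged to a finite -2LL; "
                               "check the data grouping")
        n_agree = sum(1 for r in runs if r.fun - best.fun <= agree_tol)
        converged = bool(best.success) and (len(runs) < 2 or n_agree >= 2)
        return ACEHeterogeneityResults(
            model=self, theta=np.asarray(best.x, dtype=float),
            minus2ll=float(best.fun), converged=converged,
            n_starts_agreeing=n_agree)


@dataclass
class ACEHeterogeneityResults:
    """Fit results: estimates, fit indices and profile confidence intervals.

    ``df`` is the total number of non-missing phenotype observations
    minus the number of free parameters, so ``df + n_free`` is constant
    across models fitted to the same data.
    """

    model: ACEHeterogeneityModel
    theta: np.ndarray
    minus2ll: float
    converged: bool
    n_starts_agreeing: int
    _ci_cache: dict = field(default_factory=dict, repr=False)

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def params(self) -> ACEPathParams:
        return self.spec.to_params(self.theta)

    @property
    def n_free(self) -> int:
        return self.spec.n_free

    @property
    def df(self) -> int:
        return self.model.data.n_obs - self.n_free

    @property
    def aic(self) -> float:
        return aic(self.minus2ll, self.n_free)

    def standardized(self, sleep_group: str) -> tuple[float, float, float]:
        return standardized_components(self.params, sleep_group)

    # -- profile confidence intervals on the standardized scale ----------

    def _profile_objective_factory(self, component: str, sleep_group: str):
        """Reduced objective with one standardized component held fixed.

        The component's path for the target group is reconstructed from
        the remaining two paths so that its variance share equals ``t``:
        ``p_fixed = sqrt(t/(1-t) * (p1^2 + p2^2))``.
        """
        comp_idx = {"A": 0, "C": 1, "E": 2}[component]
        names = ["a", "c", "e"]
        suffix = "_s" if (sleep_group == SHORT
                          or self.spec.kind == "homogeneity") else "_n"
        fixed_name = names[comp_idx] + suffix
        other_names = [names[i] + suffix for i in range(3) if i != comp_idx]
        if fixed_name not in self.spec.free_names:
            raise ValueError(
                f"component {component} is not free in this model")
        free = list(self.spec.free_names)
        j = free.index(fixed_name)
        other_idx = [free.index(n) for n in other_names]
        reduced_names = [n for n in free if n != fixed_name]
        red_bounds = [b for n, b in zip(free, self.spec.bounds())
                      if n != fixed_name]

        def expand(theta_red, t):
            full = np.empty(len(free))
            red = dict(zip(reduced_names, theta_red))
            for i, n in enumerate(free):
                if n != fixed_name:
                    full[i] = red[n]
            ssq = sum(full[i] ** 2 for i in other_idx)
            full[j] = np.sqrt(t / max(1.0 - t, 1e-12) * ssq)
            return full

        def profiled(t, starts):
            def obj(theta_red):
                return self.model._objective(expand(theta_red, t))
            best = None
            for x0 in starts:
                res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                        bounds=red_bounds,
                                        options={"maxiter": 500,
                                                 "ftol": 1e-12})
                if best is None or res.fun < best.fun:
                    best = res
            return float(best.fun), np.asarray(best.x)

        x_hat = np.array([self.theta[free.index(n)] for n in reduced_names])
        return profiled, x_hat

    def standardized_ci(self, component: str, sleep_group: str,
                        level: float = 0.95, tol: float = 1e-4):
        """Profile-likelihood CI for one standardized variance component.

        Bounds are the values of the component's variance share at which
        the profiled -2LL exceeds the minimum by the chi-square(1)
        critical value; they are clamped to [0, 1] when the profile never
        crosses the threshold on that side.
        """
        key = (component, sleep_group, level)
        if key in self._ci_cache:
            return self._ci_cache[key]
        # dropped components have a degenerate CI at 0
        names = {"A": "a", "C": "c", "E": "e"}[component]
        suffix = "_s" if (sleep_group == SHORT
                          or self.spec.kind == "homogeneity") else "_n"
        if names + suffix not in self.spec.free_names:
            self._ci_cache[key] = (0.0, 0.0)
            return (0.0, 0.0)

        crit = float(stats.chi2.ppf(level, 1))
        threshold = self.minus2ll + crit
        comp_map = dict(zip("ACE", self.standardized(sleep_group)))
        t_hat = comp_map[component]
        profiled, x_hat = self._profile_objective_factory(component, sleep_group)

        state = {"x": x_hat.copy()}

        def g(t):
            # two inner starts: the MLE configuration and the previous
            # profile solution — either alone can stall far from the optimum
            val, x = profiled(min(max(t, 0.0), 1.0 - 1e-9),
                              [x_hat, state["x"]])
            state["x"] = x
            return val - threshold

        def bisect(lo, hi, g_lo_neg):
            # g changes sign in [lo, hi]; g(side near t_hat) < 0
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                if hi - lo < tol:
                    break
                if g(mid) <= 0:
                    if g_lo_neg == "lo":
                        lo = mid
                    else:
                        hi = mid
                else:
                    if g_lo_neg == "lo":
                        hi = mid
                    else:
                        lo = mid
            return 0.5 * (lo + hi)

        # lower bound
        state["x"] = x_hat.copy()
        if g(0.0) <= 0:
            lower = 0.0
        else:
            state["x"] = x_hat.copy()
            lower = bisect(0.0, t_hat, g_lo_neg="hi")
        # upper bound
        t_cap = 1.0 - 1e-6
        state["x"] = x_hat.copy()
        if g(t_cap) <= 0:
            upper = 1.0
        else:
            state["x"] = x_hat.copy()
            upper = bisect(t_hat, t_cap, g_lo_neg="lo")
        lower, upper = max(0.0, min(lower, t_hat)), min(1.0, max(upper, t_hat))
        self._ci_cache[key] = (lower, upper)
        return (lower, upper)

    def compare_lrt(self, reference: "ACEHeterogeneityResults"):
        """LRT of this (nested) fit against a fuller reference fit."""
        return lrt(self, reference)

    def summary(self, ci: bool = True) -> str:
        spec = self.spec
        lines = [
            f"ACE heterogeneity model ({spec.kind}, {spec.components})",
            f"  free parameters: {self.n_free}   df: {self.df}",
            f"  -2LL: {self.minus2ll:.2f}   AIC: {self.aic:.2f}",
            f"  converged: {self.converged} "
            f"({self.n_starts_agreeing} starts agreeing)",
            "  standardized variance components:",
        ]
        for lab, tag in ((SHORT, "short sleep"), (NORMAL_LONG, "normal/long sleep")):
            comps = dict(zip("ACE", self.standardized(lab)))
            row = f"    {tag:>18}: "
            for comp in "ACE":
                cell = f"{comp}={comps[comp]:.2f}"
                if ci:
                    lo, hi = self.standardized_ci(comp, lab)
                    cell += f" ({lo:.2f}, {hi:.2f})"
                row += cell + "  "
            lines.append(row)
        return "\n".join(lines)


def grouped_data_from_cohort(cohort: pd.DataFrame, phenotype: str = "isi",
                             adjust_covariates: bool = True,
                             keep_values: bool = False) -> GroupedPairData:
    """Residualize, standardize and group a pair-per-row cohort frame.

    The phenotype columns ``<phenotype>1``/``<phenotype>2`` are stacked
    across twins, regressed on age and sex (coded female = 1) and
    z-standardized, then grouped by zygosity and the per-twin sleep
    labels derived from ``hours1``/``hours2``.
    """
    n = len(cohort)
    y = np.concatenate([cohort[f"{phenotype}1"].to_numpy(dtype=float),
                        cohort[f"{phenotype}2"].to_numpy(dtype=float)])
    if adjust_covariates:
        age = np.concatenate([cohort["age"].to_numpy(dtype=float)] * 2)
        sex = np.concatenate([
            (cohort["sex1"].astype(str) == "F").to_numpy(dtype=float),
            (cohort["sex2"].astype(str) == "F").to_numpy(dtype=float),
        ])
        y = residualize_standardize(y, np.column_stack([age, sex]))
    else:
        ok = np.isfinite(y)
        y = (y - np.nanmean(y[ok])) / np.nanstd(y[ok], ddof=1)

    def labels(hours):
        return [classify_sleep_duration(h) if np.isfinite(h) else None
                for h in hours]

    return GroupedPairData.from_arrays(
        zyg=cohort["zyg"].to_numpy(dtype=object),
        label1=labels(cohort["hours1"].to_numpy(dtype=float)),
        label2=labels(cohort["hours2"].to_numpy(dtype=float)),
        y1=y[:n], y2=y[n:], keep_values=keep_values)
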