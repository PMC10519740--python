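"""Twin-pair correlations and cross-trait correlation models.

Two analyses live here.  First, the six-group twin-pair correlations of
the insomnia phenotype (MZ/DZ x concordant-short / concordant-normal /
discordant), with Fisher-z confidence intervals and double-entry
symmetrization for the MZ concordant buckets.  Second, cross-trait
correlation models: the within-person correlation between insomnia
symptoms and a co-trait is estimated per sleep-duration pair group
(concordant-short, concordant-normal, discordant) from the 4-variate
pair vector (X1, Y1, X2, Y2) by maximum likelihood, with the cross-twin
correlations free per zygosity as nuisance parameters so the relatedness
of the sample is controlled for.  Equality of the three group
correlations is tested by a 2-df likelihood-ratio test; the family of
five co-traits uses a Bonferroni-corrected threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ace_engine import PairGroup, grouped_data_from_cohort
from .scales import NORMAL_LONG, SHORT, classify_sleep_duration, residualize_standardize

__all__ = [
    "CorrelationEstimate",
    "EqualityTestResult",
    "group_pairs",
    "twin_correlation",
    "twin_correlation_table",
    "PairCorrelationModel",
    "PairCorrelationResults",
    "cross_trait_correlation",
    "equality_lrt",
    "bonferroni",
    "cross_trait_table",
]

SLEEP_PAIR_GROUPS = ("concordant_short", "concordant_normal", "discordant")


@dataclass(frozen=True)
class CorrelationEstimate:
    """A correlation with its 95% CI, sample size and provenance."""

    r: float
    ci: tuple[float, float]
    n_pairs: int
    group: str
    double_entry: bool = False


@dataclass(frozen=True)
class EqualityTestResult:
    """LRT of equal within-person correlations across the three groups."""

    free_minus2ll: float
    constrained_minus2ll: float
    diff_df: int
    p: float
    r_constrained: float
    bonferroni_threshold: float | None = None


def bonferroni(alpha: float, m: int) -> float:
    """Family-wise threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# Twin-pair correlations (six groups)


def group_pairs(cohort: pd.DataFrame, phenotype: str = "isi",
                adjust_covariates: bool = True):
    """Partition complete pairs into the six likelihood groups.

    Returns ``(buckets, n_excluded)`` where ``buckets`` maps each
    :class:`PairGroup` to an ``(n, 2)`` array of phenotype values
    (discordant pairs ordered so twin 1 is the short sleeper) and
    ``n_excluded`` counts pairs without two usable observations.
    """
    data = grouped_data_from_cohort(cohort, phenotype=phenotype,
                                    adjust_covariates=adjust_covariates,
                                    keep_values=True)
    buckets = data.pair_values
    n_excluded = len(cohort) - data.n_pairs_complete
    return buckets, n_excluded


def twin_correlation(values: np.ndarray, group: str | PairGroup | None = None,
                     double_entry: bool | None = None) -> CorrelationEstimate:
    """Pearson twin-pair correlation with a Fisher-z 95% CI.

    ``double_entry=None`` applies double-entry symmetrization to the MZ
    concordant buckets (where twin ordering is arbitrary), matching the
    convention used for the printed correlation table; the CI always uses
    the number of pairs, not the doubled row count.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 2)
    n = values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if double_entry is None:
        double_entry = group in (PairGroup.MZ_CONC_SHORT,
                                 PairGroup.MZ_CONC_NORMAL,
                                 PairGroup.MZ_CONC_SHORT.value,
                                 PairGroup.MZ_CONC_NORMAL.value)
    x, y = values[:, 0], values[:, 1]
    if double_entry:
        x, y = np.concatenate([x, y]), np.concatenate([y, x])
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        ci = (r, r)
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    label = group.value if isinstance(group, PairGroup) else (group or "")
    return CorrelationEstimate(r=r, ci=ci, n_pairs=n, group=label,
                               double_entry=bool(double_entry))


def twin_correlation_table(cohort: pd.DataFrame, phenotype: str = "isi",
                           adjust_covariates: bool = True) -> pd.DataFrame:
    """Six-group twin correlations plus pooled MZ/DZ rows."""
    buckets, _ = group_pairs(cohort, phenotype, adjust_covariates)
    rows = []
    for grp in PairGroup:
        est = twin_correlation(buckets[grp], group=grp)
        rows.append({"group": grp.value, "n_pairs": est.n_pairs, "r": est.r,
                     "ci_lo": est.ci[0], "ci_hi": est.ci[1],
                     "double_entry": est.double_entry})
    for zyg in ("MZ", "DZ"):
        vals = np.vstack([buckets[g] for g in PairGroup
                          if g.value.startswith(zyg) and len(buckets[g])])
        est = twin_correlation(vals, group=f"{zyg}_all",
                               double_entry=(zyg == "MZ"))
        rows.append({"group": f"{zyg}_all", "n_pairs": est.n_pairs, "r": est.r,
                     "ci_lo": est.ci[0], "ci_hi": est.ci[1],
                     "double_entry": est.double_entry})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-trait pair-likelihood model


def _pair_sleep_group(l1, l2):
    if l1 == l2 == SHORT:
        return "concordant_short"
    if l1 == l2 == NORMAL_LONG:
        return "concordant_normal"
    if {l1, l2} == {SHORT, NORMAL_LONG}:
        return "discordant"
    return None


def _prepare_buckets(cohort: pd.DataFrame, trait_y: str, trait_x: str = "isi",
                     adjust_covariates: bool = True):
    """Residualized (X1, Y1, X2, Y2, zyg) arrays per sleep pair group."""
    n = len(cohort)

    def residualized(prefix):
        v = np.concatenate([cohort[f"{prefix}1"].to_numpy(dtype=float),
                            cohort[f"{prefix}2"].to_numpy(dtype=float)])
        if not adjust_covariates:
            return v
        age = np.concatenate([cohort["age"].to_numpy(dtype=float)] * 2)
        sex = np.concatenate([
            (cohort["sex1"].astype(str) == "F").to_numpy(dtype=float),
            (cohort["sex2"].astype(str) == "F").to_numpy(dtype=float)])
        return residualize_standardize(v, np.column_stack([age, sex]))

    x = residualized(trait_x)
    y = residualized(trait_y)
    x1, x2, y1, y2 = x[:n], x[n:], y[:n], y[n:]

    def labels(col):
        return np.array([classify_sleep_duration(h) if np.isfinite(h) else None
                         for h in cohort[col].to_numpy(dtype=float)],
                        dtype=object)

    l1, l2 = labels("hours1"), labels("hours2")
    zyg = cohort["zyg"].to_numpy(dtype=object)

    buckets = {g: [] for g in SLEEP_PAIR_GROUPS + ("total",)}
    for i in range(n):
        row = (x1[i], y1[i], x2[i], y2[i])
        if not np.any(np.isfinite(row)):
            continue
        buckets["total"].append((*row, zyg[i]))
        g = _pair_sleep_group(l1[i], l2[i])
        if g is None:
            continue
        if g == "discordant" and l1[i] != SHORT:
            row = (x2[i], y2[i], x1[i], y1[i])
        buckets[g].append((*row, zyg[i]))

    out = {}
    for g, rows in buckets.items():
        if rows:
            arr = np.array([r[:4] for r in rows], dtype=float)
            z = np.array([r[4] for r in rows], dtype=object)
        else:
            arr = np.empty((0, 4))
            z = np.empty(0, dtype=object)
        out[g] = (arr, z)
    return out


_PARAM_NAMES = ("mu_x", "mu_y", "sd_x", "sd_y", "r_wp",
                "r_xx_MZ", "r_yy_MZ", "r_xy_MZ",
                "r_xx_DZ", "r_yy_DZ", "r_xy_DZ")
_RWP_INDEX = 4


class PairCorrelationModel:
    """ML model of a within-person X-Y correlation in clustered twin data.

    The pair vector (X1, Y1, X2, Y2) is modelled as 4-variate Gaussian.
    The within-person correlation ``r_wp`` is equated across twins and
    zygosities (it is the estimand); the cross-twin same-trait and
    cross-twin cross-trait correlations are free per zygosity so the
    non-independence of twins is absorbed rather than ignored.  Pairs
    with any subset of the four entries observed contribute their
    marginal Gaussian density (FIML).
    """

    def __init__(self, values: np.ndarray, zygosity: np.ndarray,
                 group: str = ""):
        values = np.asarray(values, dtype=float).reshape(-1, 4)
        self.group = group
        self.n_pairs = values.shape[0]
        if self.n_pairs < 3:
            raise ValueError("need >= 3 pairs with data")
        self.n_obs = int(np.isfinite(values).sum())
        # sufficient statistics per (zygosity, missingness pattern)
        self._stats = []
        zygosity = np.asarray(zygosity, dtype=object)
        for zi, z in enumerate(("MZ", "DZ")):
            vals = values[zygosity == z]
            if not len(vals):
                continue
            finite = np.isfinite(vals)
            patterns = {}
            for row, mask in zip(vals, finite):
                if not mask.any():
                    continue
                patterns.setdefault(tuple(np.flatnonzero(mask)), []).append(
                    row[mask])
            for idx, rows in patterns.items():
                m = np.asarray(rows, dtype=float)
                self._stats.append((zi, np.array(idx), m.shape[0],
                                    m.sum(axis=0), m.T @ m))
        self._values = values
        self._zygosity = zygosity

    # -- likelihood ------------------------------------------------------

    @staticmethod
    def _sigma(theta, zyg_index):
        mu_x, mu_y, sd_x, sd_y, r_wp = theta[:5]
        off = 5 + 3 * zyg_index
        r_xx, r_yy, r_xy = theta[off:off + 3]
        corr = np.array([
            [1.0, r_wp, r_xx, r_xy],
            [r_wp, 1.0, r_xy, r_yy],
            [r_xx, r_xy, 1.0, r_wp],
            [r_xy, r_yy, r_wp, 1.0]])
        d = np.array([sd_x, sd_y, sd_x, sd_y])
        mu = np.array([mu_x, mu_y, mu_x, mu_y])
        return mu, corr * np.outer(d, d)

    def neg2ll(self, theta) -> float:
        total = 0.0
        sig = {}
        for zi in (0, 1):
            mu, sigma = self._sigma(theta, zi)
            lam = np.linalg.eigvalsh(sigma)[0]
            if lam <= 1e-10:
                return 1e10 * (1.0 + max(0.0, -lam))
            sig[zi] = (mu, sigma)
        log2pi = np.log(2.0 * np.pi)
        for zi, idx, n, s1, s2 in self._stats:
            mu, sigma = sig[zi]
            mu_k = mu[idx]
            sig_k = sigma[np.ix_(idx, idx)]
            sign, logdet = np.linalg.slogdet(sig_k)
            if sign <= 0:
                return 1e10
            m = s2 - np.outer(s1, mu_k) - np.outer(mu_k, s1) \
                + n * np.outer(mu_k, mu_k)
            quad = float(np.trace(np.linalg.solve(sig_k, m)))
            total += n * (idx.size * log2pi + logdet) + quad
        return float(total)

    def _starts(self):
        v = self._values
        mu_x = np.nanmean(np.concatenate([v[:, 0], v[:, 2]]))
        mu_y = np.nanmean(np.concatenate([v[:, 1], v[:, 3]]))
        sd_x = max(np.nanstd(np.concatenate([v[:, 0], v[:, 2]]), ddof=1), 1e-2)
        sd_y = max(np.nanstd(np.concatenate([v[:, 1], v[:, 3]]), ddof=1), 1e-2)
        xy = np.column_stack([np.concatenate([v[:, 0], v[:, 2]]),
                              np.concatenate([v[:, 1], v[:, 3]])])
        ok = np.isfinite(xy).all(axis=1)
        r0 = 0.0
        if ok.sum() > 3:
            r0 = float(np.clip(np.corrcoef(xy[ok, 0], xy[ok, 1])[0, 1],
                               -0.9, 0.9))
        base = [mu_x, mu_y, sd_x, sd_y, r0]
        starts = [np.array(base + [0.3, 0.3, 0.15, 0.15, 0.15, 0.1]),
                  np.array(base + [0.0] * 6)]
        return starts

    @staticmethod
    def _bounds():
        return [(None, None), (None, None), (1e-3, None), (1e-3, None)] \
            + [(-0.999, 0.999)] * 7

    def fit(self, extra_starts=()) -> "PairCorrelationResults":
        best = None
        runs = []
        for x0 in [*self._starts(), *extra_starts]:
            res = optimize.minimize(self.neg2ll, x0, method="L-BFGS-B",
                                    bounds=self._bounds(),
                                    options={"maxiter": 500, "ftol": 1e-12})
            runs.append(res)
            if best is None or res.fun < best.fun:
                best = res
        converged = bool(best.success) and np.isfinite(best.fun)
        if not converged and best.fun >= 1e9:
            raise RuntimeError(f"pair correlation fit failed in group "
                               f"{self.group!r}")
        return PairCorrelationResults(model=self,
                                      theta=np.asarray(best.x, float),
                                      minus2ll=float(best.fun),
                                      converged=converged)


@dataclass
class PairCorrelationResults:
    model: PairCorrelationModel
    theta: np.ndarray
    minus2ll: float
    converged: bool

    n_free: int = 11

    @property
    def params(self) -> dict:
        return dict(zip(_PARAM_NAMES, self.theta))

    @property
    def r(self) -> float:
        return float(self.theta[_RWP_INDEX])

    def profile_ci(self, level: float = 0.95, tol: float = 1e-4):
        """Likelihood-based CI for the within-person correlation."""
        crit = float(stats.chi2.ppf(level, 1))
        threshold = self.minus2ll + crit
        reduced0 = np.delete(self.theta, _RWP_INDEX)
        bounds = [b for i, b in enumerate(self.model._bounds())
                  if i != _RWP_INDEX]
        state = {"x": reduced0.copy()}

        def profiled(r):
            def obj(red):
                theta = np.insert(red, _RWP_INDEX, r)
                return self.model.neg2ll(theta)
            best = None
            for x0 in (reduced0, state["x"]):
                res = optimize.minimize(obj, x0, method="L-BFGS-B",
                                        bounds=bounds,
                                        options={"maxiter": 300,
                                                 "ftol": 1e-11})
                if best is None or res.fun < best.fun:
                    best = res
            state["x"] = best.x
            return float(best.fun)

        def bound(lo, hi, increasing):
            # profiled(-2LL) - threshold changes sign in [lo, hi]
            for _ in range(60):
                if hi - lo < tol:
                    break
                mid = 0.5 * (lo + hi)
                above = profiled(mid) > threshold
                if increasing:  # searching above r_hat
                    hi, lo = (mid, lo) if above else (hi, mid)
                else:
                    hi, lo = (hi, mid) if above else (mid, lo)
            return 0.5 * (lo + hi)

        r_hat = self.r
        state["x"] = reduced0.copy()
        lo = -0.999 if profiled(-0.999) <= threshold else bound(
            -0.999, r_hat, increasing=False)
        state["x"] = reduced0.copy()
        hi = 0.999 if profiled(0.999) <= threshold else bound(
            r_hat, 0.999, increasing=True)
        return (min(lo, r_hat), max(hi, r_hat))

    def estimate(self, ci_method: str = "fisher") -> CorrelationEstimate:
        if ci_method == "profile":
            ci = self.profile_ci()
        else:
            n = self.model.n_pairs
            z = np.arctanh(np.clip(self.r, -0.999999, 0.999999))
            half = stats.norm.ppf(0.975) / np.sqrt(max(n - 3, 1))
            ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
        return CorrelationEstimate(r=self.r, ci=ci, n_pairs=self.model.n_pairs,
                                   group=self.model.group)


def cross_trait_correlation(cohort: pd.DataFrame, trait_y: str,
                            trait_x: str = "isi",
                            adjust_covariates: bool = True,
                            include_total: bool = True
                            ) -> dict[str, PairCorrelationResults]:
    """Per-sleep-group ML estimates of the X-Y within-person correlation.

    Returns fits for the three sleep pair groups plus ``"total"`` (all
    pairs pooled), each controlling for twin relatedness via
    zygosity-specific nuisance correlations.
    """
    buckets = _prepare_buckets(cohort, trait_y, trait_x, adjust_covariates)
    if not include_total:
        buckets.pop("total", None)
    out = {}
    for g, (vals, zyg) in buckets.items():
        n_usable = int(np.isfinite(vals).all(axis=1).sum())
        if n_usable < 3:
            raise ValueError(f"fewer than 3 complete pairs in group {g!r}")
        out[g] = PairCorrelationModel(vals, zyg, group=g).fit()
    return out


def equality_lrt(fits: dict[str, PairCorrelationResults],
                 bonferroni_m: int | None = None,
                 alpha: float = 0.05) -> EqualityTestResult:
    """2-df LRT of one common within-person correlation across three groups.

    ``fits`` holds the free per-group results (keys = the three sleep
    pair groups).  The constrained model re-optimizes all three groups
    jointly with a single shared ``r_wp``.
    """
    groups = [g for g in SLEEP_PAIR_GROUPS if g in fits]
    if len(groups) != 3:
        raise ValueError("need fits for all three sleep pair groups")
    free_m2ll = sum(fits[g].minus2ll for g in groups)
    models = [fits[g].model for g in groups]
    thetas = [fits[g].theta for g in groups]

    def unpack(x):
        r = x[0]
        out = []
        for i in range(3):
            red = x[1 + 10 * i:1 + 10 * (i + 1)]
            out.append(np.insert(red, _RWP_INDEX, r))
        return out

    def obj(x):
        return sum(m.neg2ll(t) for m, t in zip(models, unpack(x)))

    r0 = float(np.mean([fits[g].r for g in groups]))
    x0 = np.concatenate([[r0]] + [np.delete(t, _RWP_INDEX) for t in thetas])
    bounds = [(-0.999, 0.999)]
    for m in models:
        bounds.extend(b for i, b in enumerate(m._bounds())
                      if i != _RWP_INDEX)
    res = optimize.minimize(obj, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 1000, "ftol": 1e-12})
    constrained = float(res.fun)
    diff = max(constrained - free_m2ll, 0.0)
    p = float(stats.chi2.sf(diff, 2))
    thr = bonferroni(alpha, bonferroni_m) if bonferroni_m else None
    return EqualityTestResult(free_minus2ll=free_m2ll,
                              constrained_minus2ll=constrained,
                              diff_df=2, p=p, r_constrained=float(res.x[0]),
                              bonferroni_threshold=thr)


def cross_trait_table(cohort: pd.DataFrame,
                      traits: tuple[str, ...] = ("anx", "anxsens", "dep",
                                                 "gcse", "psyc"),
                      trait_x: str = "isi", alpha: float = 0.05,
                      ci_method: str = "fisher") -> pd.DataFrame:
    """Correlation table: total and per-group r with CIs and equality p.

    One row per co-trait; the Bonferroni threshold divides ``alpha`` by
    the number of traits tested.
    """
    thr = bonferroni(alpha, len(traits))
    rows = []
    for trait in traits:
        fits = cross_trait_correlation(cohort, trait, trait_x)
        test = equality_lrt({g: fits[g] for g in SLEEP_PAIR_GROUPS},
                            bonferroni_m=len(traits), alpha=alpha)
        row = {"trait": trait}
        for g in ("total",) + SLEEP_PAIR_GROUPS:
            est = fits[g].estimate(ci_method=ci_method)
            row[f"r_{g}"] = est.r
            row[f"r_{g}_lo"], row[f"r_{g}_hi"] = est.ci
        row["p_equality"] = test.p
        row["bonferroni_threshold"] = thr
        row["significant_corrected"] = test.p < thr
        rows.append(row)
    return pd.DataFrame(rows)
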