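"""Synthetic twin-cohort generator with the structure the analyses assume.

The real cohort (4000 adolescent twin pairs with insomnia symptoms,
sleep duration, co-traits and polygenic scores) is access-restricted, so
every downstream stage is exercised on cohorts simulated here.  The
generator reproduces the statistical skeleton of that design:

* MZ/DZ pair structure (35.4% MZ) and sex composition (46.0% male);
* a binary short-sleep moderator arising from an ACE-structured liability
  thresholded at a target prevalence, which yields concordant and
  discordant pairs in both zygosities;
* an insomnia phenotype with moderator-dependent ACE paths (twin
  correlations 1 / 0.5 for the MZ / DZ genetic factor);
* co-traits with target within-person correlations per sleep group;
* a deliberately weak polygenic-score proxy for twin 1 only
  (R-squared with the phenotype below 1%).

Scores are mapped linearly onto the questionnaire scales and clipped to
their theoretical ranges; clipping mass is kept negligible by the default
locations/scales so the Gaussian covariance structure survives intact.
Everything is deterministic given the master seed: each generation stage
draws from its own fixed substream, so adding a co-trait does not perturb
the phenotype draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ace_engine import ACEPathParams, PairGroup, implied_moments
from .scales import NORMAL_LONG, SHORT

__all__ = [
    "TraitSpec",
    "SimConfig",
    "simulate_cohort",
    "simulate_grouped",
    "implied_summary",
    "write_cohort",
    "read_cohort",
    "CohortFormatError",
]

# fixed substream indices for the master seed (order is part of the contract:
# appending new stages must not renumber existing ones)
_SUB_STRUCTURE = 0
_SUB_SLEEP = 1
_SUB_PHENO = 2
_SUB_PGS = 3
_SUB_MISSING = 4
_SUB_COTRAIT_BASE = 10

PGS_COLUMNS = ("pgs_p1", "pgs_p03", "pgs_p001")


class CohortFormatError(ValueError):
    """Raised when a cohort file cannot be parsed."""


@dataclass(frozen=True)
class TraitSpec:
    """One co-trait: target within-person correlations and scale mapping.

    ``r_short`` / ``r_normal`` are the correlations between the co-trait
    and the (standardized) insomnia phenotype for individuals in the
    short and normal/long sleep groups.  The raw score is
    ``location + scale * t`` clipped to ``[lo, hi]``.
    """

    name: str
    r_short: float
    r_normal: float
    location: float
    scale: float
    lo: float
    hi: float

    def __post_init__(self):
        for r in (self.r_short, self.r_normal):
            if abs(r) > 1.0:
                raise ValueError(
                    f"{self.name}: target correlation {r} infeasible; "
                    f"the feasible bound is |r| <= 1")


def _default_phenotype() -> ACEPathParams:
    # standardized shares: short A=.13 C=.19 E=.68 (total variance 1.2),
    # normal/long A=.35 C=0 E=.65 (total variance 1.0)
    return ACEPathParams(
        a_s=np.sqrt(0.13 * 1.2), c_s=np.sqrt(0.19 * 1.2), e_s=np.sqrt(0.68 * 1.2),
        a_n=np.sqrt(0.35), c_n=0.0, e_n=np.sqrt(0.65),
        mu_s=0.30, mu_n=0.0)


def _default_cotraits() -> tuple[TraitSpec, ...]:
    return (
        TraitSpec("anx", 0.46, 0.38, location=5.0, scale=1.4, lo=0, hi=10),
        TraitSpec("anxsens", 0.42, 0.34, location=18.0, scale=5.0, lo=0, hi=36),
        TraitSpec("dep", 0.47, 0.44, location=13.0, scale=3.7, lo=0, hi=26),
        TraitSpec("gcse", -0.03, -0.02, location=7.5, scale=1.0, lo=4, hi=11),
        TraitSpec("psyc", 0.26, 0.25, location=25.0, scale=7.0, lo=0, hi=91),
    )


@dataclass
class SimConfig:
    """Generating values and sizes for one synthetic cohort.

    The sleep-liability paths (``aL``, ``cL``, ``eL``; squares sum to 1)
    and the 0.215 short-sleep prevalence are calibrated so the expected
    six-group pair counts at 4000 pairs approximate the reference
    design's (roughly 137/944/335 MZ and 202/1675/708 DZ pairs).  The
    phenotype defaults are the quantitative-heterogeneity generating
    values (standardized shares 0.13/0.19/0.68 short, 0.35/0/0.65
    normal/long, with a larger total variance in the short group).
    """

    n_pairs: int = 4000
    prop_mz: float = 0.354
    prop_male: float = 0.460
    aL: float = float(np.sqrt(0.33))
    cL: float = float(np.sqrt(0.17))
    eL: float = float(np.sqrt(0.50))
    short_sleep_prevalence: float = 0.215
    phenotype: ACEPathParams = field(default_factory=_default_phenotype)
    cotraits: tuple[TraitSpec, ...] = field(default_factory=_default_cotraits)
    pgs_r2: float = 0.005
    missing_rate: float = 0.02
    #: correlation between the sleep-liability and phenotype latent factors
    #: (0 = the moderator is aetiologically independent of the phenotype)
    moderator_phenotype_corr: float = 0.0
    isi_location: float = 10.0
    isi_scale: float = 3.0
    beta_age: float = 0.3
    beta_sex: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("prop_mz", "prop_male", "short_sleep_prevalence",
                     "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        ssq = self.aL ** 2 + self.cL ** 2 + self.eL ** 2
        if abs(ssq - 1.0) > 1e-8:
            raise ValueError(f"sleep-liability paths must satisfy "
                             f"aL^2+cL^2+eL^2 = 1, got {ssq:.6f}")
        if not (0.0 <= self.pgs_r2 < 1.0):
            raise ValueError("pgs_r2 must be in [0, 1)")
        if abs(self.moderator_phenotype_corr) > 1.0:
            raise ValueError("moderator_phenotype_corr must be in [-1, 1]")
        p = self.phenotype
        for lab in (SHORT, NORMAL_LONG):
            v = p.variance(lab)
            if v <= 0:
                raise ValueError(f"phenotype variance for {lab} must be > 0")
            a, _, _ = p.paths(lab)
            share = a * a / v
            if self.pgs_r2 > 0 and self.pgs_r2 >= share:
                raise ValueError(
                    f"pgs_r2 ({self.pgs_r2}) must be below the A variance "
                    f"share of the {lab} group ({share:.4f})")

    # -- flat JSON round trip -------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phenotype"] = dataclasses.asdict(self.phenotype)
        d["cotraits"] = [dataclasses.asdict(t) for t in self.cotraits]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "phenotype" in d:
            d["phenotype"] = ACEPathParams(**d["phenotype"])
        if "cotraits" in d:
            d["cotraits"] = tuple(TraitSpec(**t) for t in d["cotraits"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(key,)))


def _twin_factors(rng: np.random.Generator, is_mz: np.ndarray):
    """Latent A (twin corr 1 MZ / 0.5 DZ), shared C and independent E."""
    n = is_mz.size
    a1 = rng.standard_normal(n)
    a_extra = rng.standard_normal(n)
    a2 = np.where(is_mz, a1, 0.5 * a1 + np.sqrt(0.75) * a_extra)
    c = rng.standard_normal(n)
    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    return a1, a2, c, e1, e2


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw one cohort, one row per twin pair, deterministic given the seed."""
    n = config.n_pairs
    p = config.phenotype

    rng = _substream(config.seed, _SUB_STRUCTURE)
    is_mz = rng.random(n) < config.prop_mz
    zyg = np.where(is_mz, "MZ", "DZ")
    sex1 = np.where(rng.random(n) < config.prop_male, "M", "F")
    sex2 = np.where(is_mz, sex1,
                    np.where(rng.random(n) < config.prop_male, "M", "F"))
    age = 16.0 + rng.uniform(-0.5, 0.5, n)

    # sleep-duration liability, thresholded at the target prevalence
    rng = _substream(config.seed, _SUB_SLEEP)
    sa1, sa2, sc, se1, se2 = _twin_factors(rng, is_mz)
    tau = stats.norm.ppf(config.short_sleep_prevalence)
    liab1 = config.aL * sa1 + config.cL * sc + config.eL * se1
    liab2 = config.aL * sa2 + config.cL * sc + config.eL * se2
    short1, short2 = liab1 < tau, liab2 < tau
    rng_hours = rng  # continue the sleep substream for the decorative hours
    hours1 = np.where(short1, rng_hours.uniform(4.0, 6.9, n),
                      rng_hours.uniform(7.0, 10.0, n))
    hours2 = np.where(short2, rng_hours.uniform(4.0, 6.9, n),
                      rng_hours.uniform(7.0, 10.0, n))

    # phenotype with moderator-dependent paths
    rng = _substream(config.seed, _SUB_PHENO)
    pa1, pa2, pc, pe1, pe2 = _twin_factors(rng, is_mz)
    rho = config.moderator_phenotype_corr
    if rho != 0.0:
        mix = np.sqrt(1.0 - rho * rho)
        pa1 = rho * sa1 + mix * pa1
        pa2 = rho * sa2 + mix * pa2
        pc = rho * sc + mix * pc
        pe1 = rho * se1 + mix * pe1
        pe2 = rho * se2 + mix * pe2

    def pheno(short, a_f, c_f, e_f):
        a, c, e = np.where(short, p.a_s, p.a_n), np.where(short, p.c_s, p.c_n), \
            np.where(short, p.e_s, p.e_n)
        mu = np.where(short, p.mu_s, p.mu_n)
        return mu + a * a_f + c * c_f + e * e_f

    val1 = pheno(short1, pa1, pc, pe1)
    val2 = pheno(short2, pa2, pc, pe2)
    female1 = (sex1 == "F").astype(float)
    female2 = (sex2 == "F").astype(float)
    isi1 = np.clip(config.isi_location + config.isi_scale * val1
                   + config.beta_age * (age - 16.0) + config.beta_sex * female1,
                   0.0, 28.0)
    isi2 = np.clip(config.isi_location + config.isi_scale * val2
                   + config.beta_age * (age - 16.0) + config.beta_sex * female2,
                   0.0, 28.0)

    df = pd.DataFrame({
        "pair_id": np.arange(1, n + 1), "zyg": zyg,
        "sex1": sex1, "sex2": sex2, "age": age,
        "hours1": hours1, "hours2": hours2,
        "isi1": isi1, "isi2": isi2,
    })

    # co-traits: loading r on the standardized phenotype plus unique noise
    def z_of(val, short):
        sd = np.where(short, np.sqrt(p.variance(SHORT)),
                      np.sqrt(p.variance(NORMAL_LONG)))
        mu = np.where(short, p.mu_s, p.mu_n)
        return (val - mu) / sd

    z1, z2 = z_of(val1, short1), z_of(val2, short2)
    for i, trait in enumerate(config.cotraits):
        rng = _substream(config.seed, _SUB_COTRAIT_BASE + i)
        for twin, (z, short) in enumerate(((z1, short1), (z2, short2)), start=1):
            r = np.where(short, trait.r_short, trait.r_normal)
            t = r * z + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
            df[f"{trait.name}{twin}"] = np.clip(
                trait.location + trait.scale * t, trait.lo, trait.hi)

    # polygenic-score proxy, twin 1 only, three thresholds sharing the
    # genetic signal but with independent unique noise
    rng = _substream(config.seed, _SUB_PGS)
    a1_paths = np.where(short1, p.a_s, p.a_n)
    v1 = np.where(short1, p.variance(SHORT), p.variance(NORMAL_LONG))
    share1 = a1_paths ** 2 / v1
    beta = np.sqrt(config.pgs_r2 / share1) if config.pgs_r2 > 0 else np.zeros(n)
    for col in PGS_COLUMNS:
        raw = beta * pa1 + np.sqrt(1.0 - beta ** 2) * rng.standard_normal(n)
        df[col] = (raw - raw.mean()) / raw.std(ddof=1)

    # singleton pairs: twin 2 contributes no data at all
    rng = _substream(config.seed, _SUB_MISSING)
    singleton = rng.random(n) < config.missing_rate
    twin2_cols = ["hours2", "isi2"] + [f"{t.name}2" for t in config.cotraits]
    df.loc[singleton, twin2_cols] = np.nan
    return df


def simulate_grouped(group_sizes: dict, params: ACEPathParams, seed: int = 0,
                     isi_location: float = 10.0, isi_scale: float = 3.0
                     ) -> pd.DataFrame:
    """Cohort with exact six-group pair counts (no liability thresholding).

    Because the moderator and the phenotype use independent latent
    factors, conditioning on group membership only fixes the labels; the
    phenotype draw is unchanged.  Used for parameter-recovery studies at
    prescribed group sizes.  Sleep hours are filled with representative
    values (6 h short, 8 h normal/long).
    """
    rows = []
    rng = np.random.default_rng(seed)
    pair_id = 1
    for grp, n in group_sizes.items():
        grp = PairGroup(grp)
        if n == 0:
            continue
        is_mz = np.full(n, grp.is_mz)
        a1, a2, c, e1, e2 = _twin_factors(rng, is_mz)
        if grp.is_discordant:
            short1, short2 = np.ones(n, bool), np.zeros(n, bool)
        elif grp.value.endswith("CS"):
            short1 = short2 = np.ones(n, bool)
        else:
            short1 = short2 = np.zeros(n, bool)

        def pheno(short, af, cf, ef):
            a = np.where(short, params.a_s, params.a_n)
            cc = np.where(short, params.c_s, params.c_n)
            e = np.where(short, params.e_s, params.e_n)
            mu = np.where(short, params.mu_s, params.mu_n)
            return mu + a * af + cc * cf + e * ef

        sub = pd.DataFrame({
            "pair_id": np.arange(pair_id, pair_id + n),
            "zyg": "MZ" if grp.is_mz else "DZ",
            "sex1": "F", "sex2": "F", "age": 16.0,
            "hours1": np.where(short1, 6.0, 8.0),
            "hours2": np.where(short2, 6.0, 8.0),
            "isi1": np.clip(isi_location + isi_scale * pheno(short1, a1, c, e1),
                            0.0, 28.0),
            "isi2": np.clip(isi_location + isi_scale * pheno(short2, a2, c, e2),
                            0.0, 28.0),
        })
        pair_id += n
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def implied_summary(config: SimConfig) -> dict:
    """Closed-form moments and group probabilities implied by a config.

    Returns, per six-group label: the expected pair count, the implied
    mean vector, per-twin variances and the cross-twin correlation of the
    raw phenotype, plus the orthant probabilities of the liability model.
    """
    p = config.phenotype
    tau = stats.norm.ppf(config.short_sleep_prevalence)
    prev = config.short_sleep_prevalence

    def orthant(r):
        if r >= 1.0 - 1e-12:
            return prev
        return float(stats.multivariate_normal.cdf(
            [tau, tau], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]]))

    r_mz = config.aL ** 2 + config.cL ** 2
    r_dz = 0.5 * config.aL ** 2 + config.cL ** 2
    out = {}
    for grp in PairGroup:
        r_liab = r_mz if grp.is_mz else r_dz
        p_ss = orthant(r_liab)
        p_nn = 1.0 - 2.0 * prev + p_ss
        if grp.value.endswith("CS"):
            prob = p_ss
        elif grp.value.endswith("CN"):
            prob = p_nn
        else:
            prob = 1.0 - p_ss - p_nn
        zyg_prob = config.prop_mz if grp.is_mz else 1.0 - config.prop_mz
        mu, sigma = implied_moments(p, grp, model_kind="full")
        denom = np.sqrt(sigma[0, 0] * sigma[1, 1])
        out[grp.value] = {
            "probability": prob,
            "expected_pairs": config.n_pairs * zyg_prob * prob
                              * (1.0 - config.missing_rate),
            "mean": mu.tolist(),
            "variances": [sigma[0, 0], sigma[1, 1]],
            "cross_twin_correlation": float(sigma[0, 1] / denom),
        }
    return out


def write_cohort(path, cohort: pd.DataFrame) -> None:
    """Write a cohort CSV (full float precision; exact round trip)."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises :class:`CohortFormatError` naming the first malformed line.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CohortFormatError(str(exc)) from exc
    required = {"pair_id", "zyg"}
    missing = required - set(df.columns)
    if missing:
        raise CohortFormatError(f"missing required columns: {sorted(missing)}")
    bad = ~df["zyg"].isin(["MZ", "DZ"])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise CohortFormatError(f"line {line}: zygosity must be MZ or DZ")
    return df
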