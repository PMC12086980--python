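"""Mapping reported outcomes (BMI, BMI percentile, prevalence) onto zBMI.

Trials report obesity outcomes on several scales. The analysis needs all of
them as age- and sex-standardised BMI z-scores (zBMI). Three mappings are
implemented:

* **BMI -> zBMI** by Monte-Carlo sampling: draw a synthetic cohort (BMI
  lognormal moment-matched to the reported mean/SD, age normal truncated to
  the growth-reference range, sex Bernoulli), transform each individual
  through the LMS growth reference, and average.
* **percentile -> zBMI** analytically: assuming zBMI ~ Normal(mu, sigma^2),
  the mean and variance of the BMI percentile 100*Phi(Z) have closed forms
  (the variance via a bivariate-normal orthant probability); invert them.
* **prevalence -> zBMI**: proportions above known z-score thresholds pin
  down (mu, sigma) under normality (sigma fixed at the reference value 1
  when only one category is reported).

The LMS growth reference (Box-Cox power L, median M, coefficient of
variation S, tabulated by sex and age) is pluggable; a smooth synthetic
reference is bundled for self-contained testing, and CDC/WHO-style tables
load from CSV with columns ``sex, age_years, L, M, S``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

#: Default z-score thresholds for prevalence outcomes: the 85th percentile
#: (overweight-or-obese) and 95th percentile (obese) of the reference
#: population.
DEFAULT_PREVALENCE_THRESHOLDS = (1.036433, 1.644854)


class MappingError(ValueError):
    """A summary cannot be mapped (out of range, no solution, degenerate)."""


# ---------------------------------------------------------------------------
# LMS reference


@dataclass
class LMSReference:
    """Growth reference in LMS form: per sex, (age, L, M, S) with linear
    interpolation in age. ``sex`` is coded 1 = male, 0 = female."""

    table: pd.DataFrame  # columns: sex, age_years, L, M, S

    def __post_init__(self) -> None:
        t = self.table
        required = {"sex", "age_years", "L", "M", "S"}
        if not required.issubset(t.columns):
            raise ValueError(f"LMS table needs columns {sorted(required)}")
        if (t["M"] <= 0).any() or (t["S"] <= 0).any():
            raise ValueError("M and S must be positive")
        self._by_sex = {}
        for sex, grp in t.groupby("sex"):
            grp = grp.sort_values("age_years")
            ages = grp["age_years"].to_numpy(float)
            if np.any(np.diff(ages) <= 0):
                raise ValueError(f"ages not strictly increasing for sex={sex}")
            self._by_sex[int(sex)] = (
                ages,
                grp["L"].to_numpy(float),
                grp["M"].to_numpy(float),
                grp["S"].to_numpy(float),
            )

    @property
    def age_range(self) -> tuple[float, float]:
        lo = max(v[0][0] for v in self._by_sex.values())
        hi = min(v[0][-1] for v in self._by_sex.values())
        return lo, hi

    def lms(self, age: np.ndarray, sex: np.ndarray):
        """Interpolated (L, M, S) at given ages/sexes (broadcastable arrays)."""
        age = np.asarray(age, float)
        sex = np.asarray(sex)
        lo, hi = self.age_range
        if np.any(age < lo - 1e-12) or np.any(age > hi + 1e-12):
            raise MappingError(
                f"age outside reference range [{lo:g}, {hi:g}]"
            )
        L = np.empty_like(age)
        M = np.empty_like(age)
        S = np.empty_like(age)
        for s, (ages, Ls, Ms, Ss) in self._by_sex.items():
            m = sex == s
            if np.any(m):
                L[m] = np.interp(age[m], ages, Ls)
                M[m] = np.interp(age[m], ages, Ms)
                S[m] = np.interp(age[m], ages, Ss)
        return L, M, S

    @classmethod
    def from_csv(cls, path) -> "LMSReference":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def synthetic_reference(
    age_lo: float = 5.0, age_hi: float = 19.0, step: float = 0.5
) -> LMSReference:
    """Smooth synthetic LMS reference for self-contained tests and examples.

    Emulates the qualitative shape of childhood BMI references: median BMI
    rising from ~15.5 to ~21.5 kg/m^2 over ages 5-19, slight sex offset,
    constant coefficient of variation, Box-Cox power away from 0 and 1. It
    is *not* a population growth chart.
    """
    ages = np.arange(age_lo, age_hi + step / 2, step)
    rows = []
    for sex in (0, 1):
        M = 15.5 + 0.35 * (ages - age_lo) + 0.01 * (ages - age_lo) ** 2
        M = M + (0.2 if sex == 1 else 0.0)
        rows.append(
            pd.DataFrame(
                {"sex": sex, "age_years": ages, "L": -0.6, "M": M, "S": 0.12}
            )
        )
    return LMSReference(pd.concat(rows, ignore_index=True))


def zbmi_of_individual(bmi, age, sex, ref: LMSReference):
    """LMS z-score: z = ((BMI/M)^L - 1) / (L*S), with the log-form limit
    z = ln(BMI/M)/S as L -> 0. Vectorised over inputs."""
    bmi = np.asarray(bmi, float)
    if np.any(bmi <= 0):
        raise MappingError("bmi must be positive")
    scalar = bmi.ndim == 0
    bmi = np.atleast_1d(bmi)
    age = np.broadcast_to(np.asarray(age, float), bmi.shape)
    sex = np.broadcast_to(np.asarray(sex), bmi.shape)
    L, M, S = ref.lms(age, sex)
    ratio = bmi / M
    with np.errstate(invalid="ignore"):
        z = np.where(
            np.abs(L) < 1e-7,
            np.log(ratio) / S,
            (np.power(ratio, L) - 1.0) / (L * S),
        )
    return float(z[0]) if scalar else z


def bmi_from_zbmi(z, age, sex, ref: LMSReference):
    """Inverse LMS transform: BMI = M * (1 + L*S*z)^(1/L) (exp(S*z) as L->0)."""
    z = np.atleast_1d(np.asarray(z, float))
    age = np.broadcast_to(np.asarray(age, float), z.shape)
    sex = np.broadcast_to(np.asarray(sex), z.shape)
    L, M, S = ref.lms(age, sex)
    inner = 1.0 + L * S * z
    if np.any(inner <= 0):
        raise MappingError("z-score outside the invertible LMS range")
    bmi = np.where(
        np.abs(L) < 1e-7, M * np.exp(S * z), M * np.power(inner, 1.0 / L)
    )
    return bmi


# ---------------------------------------------------------------------------
# Arm summaries and mapping results


@dataclass
class ArmSummary:
    """Reported summary of one arm at one time point, on its original scale."""

    scale: str  # bmi | percentile | prevalence
    mean: float | None = None
    sd: float | None = None
    n: int | None = None
    age_mean: float | None = None
    age_sd: float | None = None
    prop_male: float = 0.5
    #: for prevalence scale: {z_threshold: proportion above threshold}
    proportions: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not 0.0 <= self.prop_male <= 1.0:
            raise ValueError("prop_male must be in [0, 1]")
        if self.proportions:
            items = sorted(self.proportions.items())
            props = [p for _, p in items]
            if any(not 0.0 <= p <= 1.0 for p in props):
                raise ValueError("proportions must be in [0, 1]")
            # tail probabilities must decrease as the threshold rises
            if any(p2 > p1 + 1e-12 for (_, p1), (_, p2) in zip(items, items[1:])):
                raise MappingError("proportions inconsistent with threshold order")


@dataclass
class MappingResult:
    mean_zbmi: float
    sd_zbmi: float | None
    mc_se: float | None
    method: str  # sampling | analytic | prevalence
    notes: str = ""


# ---------------------------------------------------------------------------
# BMI -> zBMI (sampling)


def bmi_to_zbmi_sampling(
    summary: ArmSummary,
    ref: LMSReference,
    n_samples: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> MappingResult:
    """Map a reported BMI mean/SD to mean zBMI by simulating a cohort.

    BMI is drawn lognormal with moments matched to the reported mean and SD
    (sigma_log^2 = ln(1 + SD^2/mean^2), mu_log = ln(mean) - sigma_log^2/2),
    age normal truncated to the reference age range, sex Bernoulli(prop_male).
    The Monte-Carlo standard error of the mean is reported alongside.
    """
    if summary.scale != "bmi":
        raise MappingError(f"expected scale 'bmi', got {summary.scale!r}")
    if summary.mean is None or summary.sd is None or summary.sd <= 0:
        raise MappingError("bmi mapping needs a positive mean and SD")
    if summary.age_mean is None:
        raise MappingError("bmi mapping needs the arm's mean age")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    m, s = summary.mean, summary.sd
    sigma2_log = math.log1p((s / m) ** 2)
    mu_log = math.log(m) - sigma2_log / 2.0
    bmi = rng.lognormal(mu_log, math.sqrt(sigma2_log), size=n_samples)

    lo, hi = ref.age_range
    age_sd = summary.age_sd if summary.age_sd else 0.0
    notes = ""
    if age_sd > 0:
        a, b = (lo - summary.age_mean) / age_sd, (hi - summary.age_mean) / age_sd
        if a >= b:
            raise MappingError("reference range cannot cover the age distribution")
        trunc_mass = stats.norm.cdf(a) + stats.norm.sf(b)
        if trunc_mass > 1e-12:
            notes = f"age truncated to [{lo:g}, {hi:g}] ({trunc_mass:.3%} of mass)"
        age = stats.truncnorm.rvs(
            a, b, loc=summary.age_mean, scale=age_sd, size=n_samples,
            random_state=rng,
        )
    else:
        if not lo <= summary.age_mean <= hi:
            raise MappingError("mean age outside the reference range")
        age = np.full(n_samples, summary.age_mean)
    sex = (rng.random(n_samples) < summary.prop_male).astype(int)

    z = zbmi_of_individual(bmi, age, sex, ref)
    sd_z = float(np.std(z, ddof=1))
    return MappingResult(
        mean_zbmi=float(np.mean(z)),
        sd_zbmi=sd_z,
        mc_se=sd_z / math.sqrt(n_samples),
        method="sampling",
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Percentile -> zBMI (analytic)


def _phi2_equal(a: float, rho: float) -> float:
    """P(X <= a, Y <= a) for standard bivariate normal with correlation rho,
    via Owen's T (machine precision)."""
    if rho >= 1.0:
        return float(stats.norm.cdf(a))
    if abs(a) < 1e-14:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    t = math.sqrt((1.0 - rho) / (1.0 + rho))
    return float(stats.norm.cdf(a) - 2.0 * special.owens_t(a, t))


def percentile_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of the BMI percentile 100*Phi(Z) when Z ~ N(mu, sigma^2).

    E = 100*Phi(a) with a = mu/sqrt(1+sigma^2); the second moment is the
    orthant probability 100^2 * Phi2(a, a; rho) with rho = sigma^2/(1+sigma^2).
    """
    a = mu / math.sqrt(1.0 + sigma**2)
    rho = sigma**2 / (1.0 + sigma**2)
    mean = 100.0 * stats.norm.cdf(a)
    second = 1e4 * _phi2_equal(a, rho)
    var = max(second - mean**2, 0.0)
    return float(mean), math.sqrt(var)


def percentile_to_zbmi_analytic(
    summary: ArmSummary, sigma_max: float = 10.0, tol: float = 1e-8
) -> MappingResult:
    """Invert the percentile moment equations for (mu, sigma) of zBMI.

    From the reported percentile mean the standardised threshold
    a = Phi^-1(mean/100) is exact; the reported SD then determines
    rho = sigma^2/(1+sigma^2) by a monotone one-dimensional root find, and
    (mu, sigma) follow. With SD -> 0 the mapping degenerates to
    mu = Phi^-1(mean/100), sigma = 0.
    """
    if summary.scale != "percentile":
        raise MappingError(f"expected scale 'percentile', got {summary.scale!r}")
    m, s = summary.mean, summary.sd
    if m is None or s is None or not 0.0 < m < 100.0:
        raise MappingError("percentile mean must be in (0, 100) with an SD")
    a = float(stats.norm.ppf(m / 100.0))
    if s <= tol:
        return MappingResult(a, 0.0, None, "analytic", notes="degenerate SD=0")

    target_var = s**2

    def gap(rho: float) -> float:
        second = 1e4 * _phi2_equal(a, rho)
        return second - (100.0 * stats.norm.cdf(a)) ** 2 - target_var

    rho_max = sigma_max**2 / (1.0 + sigma_max**2)
    if gap(rho_max) < 0:
        raise MappingError(
            f"no zBMI normal with sigma <= {sigma_max:g} matches percentile "
            f"SD {s:g}"
        )
    rho = optimize.brentq(gap, 0.0, rho_max, xtol=tol * 1e-4, rtol=1e-14)
    sigma = math.sqrt(rho / (1.0 - rho))
    mu = a * math.sqrt(1.0 + sigma**2)
    return MappingResult(float(mu), float(sigma), None, "analytic")


# ---------------------------------------------------------------------------
# Prevalence -> zBMI


def prevalence_to_zbmi(
    summary: ArmSummary,
    thresholds: tuple[float, ...] | None = None,
) -> MappingResult:
    """Estimate mean zBMI from proportions above z-score thresholds.

    With two categories the two tail equations
    P(Z > z_k) = Phi((mu - z_k)/sigma) determine (mu, sigma) exactly (a 2x2
    linear system in (mu/sigma, 1/sigma) probit space). With one category,
    sigma is fixed at the reference-population value 1 and mu solved directly;
    the result is flagged.
    """
    if summary.scale != "prevalence":
        raise MappingError(f"expected scale 'prevalence', got {summary.scale!r}")
    props = dict(summary.proportions)
    if thresholds is not None and not props:
        raise MappingError("no proportions supplied")
    if not props:
        raise MappingError("prevalence mapping needs >= 1 proportion")
    for z, p in props.items():
        if not 0.0 < p < 1.0:
            raise MappingError(
                f"proportion {p:g} at threshold {z:g} is on the boundary"
            )
    items = sorted(props.items())
    if len(items) == 1:
        (z1, p1), = items
        sigma = 1.0
        mu = z1 + sigma * stats.norm.ppf(p1)  # P(Z > z1) = p1
        return MappingResult(
            float(mu), sigma, None, "prevalence",
            notes="sigma fixed at reference value 1 (single category)",
        )
    if len(items) > 2:
        raise MappingError("at most two prevalence categories supported")
    (z1, p1), (z2, p2) = items
    # (z_k - mu)/sigma = Phi^-1(1 - p_k): two linear equations in (mu, sigma)
    q1, q2 = stats.norm.ppf(1.0 - p1), stats.norm.ppf(1.0 - p2)
    if q2 <= q1:
        raise MappingError("proportions inconsistent with threshold ordering")
    sigma = (z2 - z1) / (q2 - q1)
    if sigma <= 0:
        raise MappingError("implied sigma is non-positive")
    mu = z1 - sigma * q1
    return MappingResult(float(mu), float(sigma), None, "prevalence")


def map_summary(
    summary: ArmSummary,
    ref: LMSReference | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
    thresholds: tuple[float, ...] = DEFAULT_PREVALENCE_THRESHOLDS,
) -> MappingResult:
    """Dispatch an arm summary to the mapper for its scale."""
    if summary.scale == "bmi":
        if ref is None:
            raise MappingError("bmi mapping needs an LMS reference")
        return bmi_to_zbmi_sampling(summary, ref, n_samples=n_samples, seed=seed)
    if summary.scale == "percentile":
        return percentile_to_zbmi_analytic(summary)
    if summary.scale == "prevalence":
        return prevalence_to_zbmi(summary, thresholds)
    raise MappingError(f"scale {summary.scale!r} needs no mapping or is unknown")
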