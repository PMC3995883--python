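"""Synthetic cohort generation with the statistical structure the
validation analysis assumes.

Each diagnostic group is described by the marginal moments of its age,
education, MMSE and story-recall distributions.  Recall scores live on
the bounded 0-56 scale, so group targets are realised by truncated
normals whose latent parameters are solved so the *truncated* moments
match (:func:`solve_truncnorm`).  Severely impaired groups can print a
score SD larger than the mean right next to the floor — moments no
truncated normal (a log-concave family) can attain — and for those the
generator uses a zero-inflated floor mixture (a point mass at 0 plus a
moment-matched truncated normal) that reproduces the target mean and SD
exactly.

The control group's delayed-recall score can instead be generated from a
linear demographic model (intercept + education and age effects plus
Gaussian noise), so that regression-based norming has a known truth to
recover.  MMSE, immediate recall and the retest score are tied to the
delayed score through a Gaussian copula; the MMSE loading is calibrated
so the pooled MMSE-DSR correlation across groups hits a configurable
target.

One root seed drives the whole cohort; each group gets its own child
stream, so adding a group leaves the others' draws untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from scipy import optimize, stats

from .cohort import MAX_RECALL, CohortTable, SubjectRecord
from .errors import FeasibilityError, ValidationError

SCORE_LO, SCORE_HI = 0.0, float(MAX_RECALL)

#: HIS ceiling for non-vascular groups (the vascular gate is HIS <= 4).
HIS_CAP = 4


# ---------------------------------------------------------------------------
# specs

@dataclass
class GroupSpec:
    """Marginal targets for one diagnostic group."""

    label: str
    n: int
    age_mean: float
    age_sd: float
    edu_mean: float
    edu_sd: float
    isr_mean: float
    isr_sd: float
    dsr_mean: float
    dsr_sd: float
    mmse_mean: float
    mmse_sd: float
    hamd_mean: float = 3.5
    hamd_sd: float = 3.0
    male_frac: float = 0.6

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"group {self.label}: n must be >= 1")
        for name in ("age_sd", "edu_sd", "isr_sd", "dsr_sd", "mmse_sd", "hamd_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"group {self.label}: {name} < 0")
        for name in ("isr_mean", "dsr_mean"):
            v = getattr(self, name)
            if not (SCORE_LO <= v <= SCORE_HI):
                raise ValidationError(
                    f"group {self.label}: {name}={v} outside [0, {MAX_RECALL}]")


@dataclass
class RegressionSpec:
    """Generating demographic model for the control group's DSR."""

    intercept: float
    beta_edu: float
    beta_age: float
    residual_sd: float


@dataclass
class RetestSpec:
    """Which group is re-tested, what fraction, at what test-retest r."""

    group: str = "MCI"
    fraction: float = 56 / 134
    r: float = 0.887


@dataclass
class CohortSpec:
    """Full cohort description; ``seed`` fixes the entire output stream."""

    groups: list
    nc_regression: Optional[RegressionSpec] = None
    mmse_dsr_partial_r: float = 0.575
    isr_dsr_rho: float = 0.9
    retest: Optional[RetestSpec] = None
    seed: int = 0

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(labels) != len(set(labels)):
            raise ValidationError("group labels must be unique")


# ---------------------------------------------------------------------------
# truncated-normal moment matching

def _truncnorm(mu: float, sigma: float, lo: float = SCORE_LO,
               hi: float = SCORE_HI):
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm(a, b, loc=mu, scale=sigma)


def solve_truncnorm(target_mean: float, target_sd: float,
                    lower: float = SCORE_LO, upper: float = SCORE_HI):
    """Latent (mu, sigma) whose truncation to [lower, upper] has the
    requested mean and SD (each within 1e-6).

    Raises :class:`FeasibilityError` when no truncated normal can attain
    the targets.  Two infeasible regimes exist: an SD beyond the hard
    bound (upper-lower)/2 that no bounded distribution can reach, and —
    because truncated normals are log-concave — an SD exceeding the
    distance from the mean to the nearer bound (the truncated-exponential
    frontier).  Results are memoized: the same targets recur across
    replicate cohorts.
    """
    return _solve_truncnorm_cached(float(target_mean), float(target_sd),
                                   float(lower), float(upper))


@lru_cache(maxsize=512)
def _solve_truncnorm_cached(target_mean: float, target_sd: float,
                            lower: float, upper: float):
    if not (lower < target_mean < upper):
        raise FeasibilityError(
            f"target mean {target_mean} outside ({lower}, {upper})")
    if target_sd <= 0:
        raise FeasibilityError("target SD must be > 0")
    half_range = (upper - lower) / 2
    if target_sd >= half_range:
        raise FeasibilityError(
            f"target SD {target_sd} infeasible: no distribution on "
            f"[{lower}, {upper}] has SD >= {half_range}")

    def residuals(p):
        mu, log_sigma = p
        d = _truncnorm(mu, math.exp(log_sigma), lower, upper)
        return [d.mean() - target_mean, d.std() - target_sd]

    sol = optimize.least_squares(
        residuals, x0=[target_mean, math.log(target_sd)],
        xtol=3e-16, ftol=3e-16, gtol=3e-16, max_nfev=500)
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    err = np.abs(residuals([mu, math.log(sigma)]))
    if err.max() > 1e-6:
        raise FeasibilityError(
            f"no truncated normal on [{lower}, {upper}] attains mean "
            f"{target_mean}, SD {target_sd} (log-concavity limits SD near "
            f"a bound; best residual {err.max():.3g})")
    return mu, sigma


class TruncNormMarginal:
    """Inverse-CDF sampler for a moment-matched truncated normal."""

    def __init__(self, mean: float, sd: float,
                 lower: float = SCORE_LO, upper: float = SCORE_HI):
        self.mean, self.sd = mean, sd
        self.mu, self.sigma = solve_truncnorm(mean, sd, lower, upper)
        self._dist = _truncnorm(self.mu, self.sigma, lower, upper)

    def ppf(self, u):
        return self._dist.ppf(u)


class ZeroInflatedMarginal:
    """Point mass at the floor plus a truncated-normal component.

    Used when the target SD exceeds what any truncated normal can attain
    near the floor (severe floor effects).  With mixing weight p on the
    component and component moments (m1, m1/2), choosing
    m1 = (sd^2 + mean^2) / (1.25 * mean) and p = mean / m1 matches the
    target mean and SD exactly.
    """

    def __init__(self, mean: float, sd: float,
                 lower: float = SCORE_LO, upper: float = SCORE_HI):
        self.mean, self.sd = mean, sd
        self.lower = lower
        m = mean - lower
        if m <= 0:
            raise FeasibilityError("zero-inflated target mean must exceed floor")
        m1 = (sd ** 2 + m ** 2) / (1.25 * m)
        p = m / m1
        if not (0 < p <= 1) or lower + m1 >= upper:
            raise FeasibilityError(
                f"cannot build floor mixture for mean {mean}, SD {sd}")
        self.p = p
        self._component = TruncNormMarginal(lower + m1, m1 / 2, lower, upper)

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        out = np.full(u.shape, self.lower)
        hit = u > 1 - self.p
        if hit.any():
            out[hit] = self._component.ppf((u[hit] - (1 - self.p)) / self.p)
        return out


@lru_cache(maxsize=512)
def score_marginal(mean: float, sd: float, lower: float = SCORE_LO,
                   upper: float = SCORE_HI):
    """Moment-matched marginal for a bounded score: truncated normal when
    feasible, zero-inflated floor mixture otherwise.  Marginals are
    immutable and memoized."""
    try:
        return TruncNormMarginal(mean, sd, lower, upper)
    except FeasibilityError:
        return ZeroInflatedMarginal(mean, sd, lower, upper)


# ---------------------------------------------------------------------------
# coupling calibration

def _nc_model_moments(g: GroupSpec, reg: RegressionSpec):
    mean = reg.intercept + reg.beta_edu * g.edu_mean + reg.beta_age * g.age_mean
    var = ((reg.beta_edu * g.edu_sd) ** 2 + (reg.beta_age * g.age_sd) ** 2
           + reg.residual_sd ** 2)
    return mean, math.sqrt(var)


def _dsr_moments(spec: CohortSpec, g: GroupSpec):
    if g.label == "NC" and spec.nc_regression is not None:
        return _nc_model_moments(g, spec.nc_regression)
    return g.dsr_mean, g.dsr_sd


_QUAD_Z = np.linspace(-8.0, 8.0, 4001)


def _transform_moments(transform) -> tuple:
    """(linear_coeff, sd) of g(Z) for standard normal Z: the first
    Hermite coefficient E[Z g(Z)] and the actual SD of the transformed
    variable, by quadrature.  For jointly latent-normal pairs the
    first-order covariance between two transforms with latent
    correlation rho is rho * linear_coeff_1 * linear_coeff_2."""
    pdf = stats.norm.pdf(_QUAD_Z)
    gz = transform(stats.norm.cdf(_QUAD_Z))
    m0 = float(np.trapezoid(gz * pdf, _QUAD_Z))
    m1 = float(np.trapezoid(_QUAD_Z * gz * pdf, _QUAD_Z))
    m2 = float(np.trapezoid(gz * gz * pdf, _QUAD_Z))
    var = max(m2 - m0 ** 2, 0.0)
    return m1, math.sqrt(var)


def _group_factors(spec: CohortSpec, g: GroupSpec):
    """Per-group marginal geometry for the coupling calibration:
    (linear coeff, actual SD) of the DSR marginal and of the clipped
    MMSE transform."""
    reg = spec.nc_regression if (g.label == "NC" and spec.nc_regression) else None
    if reg is not None:
        _, sd_model = _nc_model_moments(g, reg)
        gd = (sd_model, sd_model)  # linear construction
    else:
        marg = score_marginal(g.dsr_mean, g.dsr_sd)
        gd = _transform_moments(lambda u: marg.ppf(u))
    gm = _transform_moments(
        lambda u: np.clip(g.mmse_mean + g.mmse_sd * stats.norm.ppf(u), 0, 30))
    return gd, gm


def _implied_pooled_cov(spec: CohortSpec, c: float,
                        factors=None) -> np.ndarray:
    """Model-implied pooled covariance of (age, edu, DSR, MMSE).

    Within each group, age and education are independent; DSR depends on
    them only through the control group's generating regression; MMSE
    loads on the standardized DSR deviation with loading ``c``.  Pooling
    adds the between-group dispersion of the group means.
    """
    ns_ = np.array([g.n for g in spec.groups], dtype=float)
    w = ns_ / ns_.sum()
    if factors is None:
        factors = [_group_factors(spec, g) for g in spec.groups]
    mus, sigmas = [], []
    for g, ((g1_d, sd_d), (g1_m, sd_m)) in zip(spec.groups, factors):
        dm, _ = _dsr_moments(spec, g)
        mus.append([g.age_mean, g.edu_mean, dm, g.mmse_mean])
        cov = np.zeros((4, 4))
        cov[0, 0] = g.age_sd ** 2
        cov[1, 1] = g.edu_sd ** 2
        cov[2, 2] = sd_d ** 2
        cov[3, 3] = sd_m ** 2
        reg = spec.nc_regression if (g.label == "NC"
                                     and spec.nc_regression) else None
        if reg is not None:
            cov[2, 0] = cov[0, 2] = reg.beta_age * g.age_sd ** 2
            cov[2, 1] = cov[1, 2] = reg.beta_edu * g.edu_sd ** 2
        cov[3, 2] = cov[2, 3] = c * g1_d * g1_m
        # MMSE inherits DSR's demographic covariance through the loading
        if g1_d > 0:
            cov[3, 0] = cov[0, 3] = c * g1_m * cov[2, 0] / g1_d
            cov[3, 1] = cov[1, 3] = c * g1_m * cov[2, 1] / g1_d
        sigmas.append(cov)
    mus = np.array(mus)
    mbar = w @ mus
    pooled = np.zeros((4, 4))
    for wi, mu, cov in zip(w, mus, sigmas):
        d = mu - mbar
        pooled += wi * (cov + np.outer(d, d))
    return pooled


def _implied_partial_r(spec: CohortSpec, c: float, factors=None) -> float:
    """MMSE-DSR partial correlation given age and education implied by
    the generating model with MMSE loading ``c``."""
    s = _implied_pooled_cov(spec, c, factors)
    xx = s[:2, :2]
    yy = s[2:, 2:]
    yx = s[2:, :2]
    resid = yy - yx @ np.linalg.pinv(xx) @ yx.T
    denom = math.sqrt(max(resid[0, 0], 0.0) * max(resid[1, 1], 0.0))
    if denom <= 0:
        return 0.0
    return float(resid[0, 1] / denom)


#: Groups over which the MMSE-DSR partial correlation target is defined
#: (the core diagnostic sample; peripheral groups do not enter the
#: calibration).
CORE_GROUPS = ("NC", "MCI", "AD")


def mmse_coupling(spec: CohortSpec) -> float:
    """Within-group MMSE loading c on the standardized DSR signal such
    that the model-implied pooled MMSE-DSR partial correlation (given
    age and education) over the core diagnostic groups equals the
    spec's target.

    The implied partial correlation is monotone in c, so the loading is
    found by scalar root finding; for a single-group spec with no
    demographic structure in either variable it reduces to the target
    itself.  The result is cached on the spec, which is treated as
    immutable after construction.
    """
    cached = getattr(spec, "_coupling", None)
    if cached is not None:
        return cached
    core = [g for g in spec.groups if g.label in CORE_GROUPS]
    cal_spec = spec
    if core and len(core) < len(spec.groups):
        cal_spec = replace(spec, groups=core)
    r = spec.mmse_dsr_partial_r
    factors = [_group_factors(cal_spec, g) for g in cal_spec.groups]
    lo, hi = -0.99, 0.99
    f_lo = _implied_partial_r(cal_spec, lo, factors) - r
    f_hi = _implied_partial_r(cal_spec, hi, factors) - r
    if f_lo >= 0:
        c = lo
    elif f_hi <= 0:
        c = hi
    else:
        c = float(optimize.brentq(
            lambda cc: _implied_partial_r(cal_spec, cc, factors) - r, lo, hi,
            xtol=1e-10))
    spec._coupling = c
    return c


# ---------------------------------------------------------------------------
# generation

def _education_level(years: float) -> str:
    if years <= 0:
        return "illiterate"
    if years <= 6:
        return "primary"
    if years <= 12:
        return "middle"
    return "higher"


_DEMENTIA_LABELS = {"AD", "VaD", "other_dementia"}


def _round_int(x):
    return np.rint(np.asarray(x)).astype(int)


def _generate_group(g: GroupSpec, spec: CohortSpec, rng: np.random.Generator,
                    coupling: Optional[float] = None):
    n = g.n
    age = np.clip(np.rint(rng.normal(g.age_mean, g.age_sd, n)), 50, 85)
    edu = np.clip(np.rint(rng.normal(g.edu_mean, g.edu_sd, n)), 0, 25)

    z_dsr = rng.standard_normal(n)
    reg = spec.nc_regression if (g.label == "NC" and spec.nc_regression) else None
    if reg is not None:
        dsr_cont = (reg.intercept + reg.beta_edu * edu + reg.beta_age * age
                    + reg.residual_sd * z_dsr)
        mu_model, sd_model = _nc_model_moments(g, reg)
        if sd_model > 0:
            z_total = (dsr_cont - mu_model) / sd_model
        else:
            z_total = np.zeros(n)  # fully degenerate spec: no DSR signal
        dsr_marginal = None
    else:
        dsr_marginal = score_marginal(g.dsr_mean, g.dsr_sd)
        dsr_cont = dsr_marginal.ppf(stats.norm.cdf(z_dsr))
        z_total = z_dsr
    dsr = _round_int(np.clip(dsr_cont, SCORE_LO, SCORE_HI))

    rho = spec.isr_dsr_rho
    z_isr = rho * z_total + math.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n)
    isr_marginal = score_marginal(g.isr_mean, g.isr_sd)
    isr = _round_int(np.clip(isr_marginal.ppf(stats.norm.cdf(z_isr)),
                             SCORE_LO, SCORE_HI))

    c = mmse_coupling(spec) if coupling is None else coupling
    z_mmse = c * z_total + math.sqrt(max(0.0, 1 - c ** 2)) * rng.standard_normal(n)
    mmse = _round_int(np.clip(g.mmse_mean + g.mmse_sd * z_mmse, 0, 30))

    if g.label == "depression":
        hamd = _round_int(np.clip(rng.normal(18.0, 4.0, n), 13, 52))
    else:
        hamd = _round_int(np.clip(rng.normal(g.hamd_mean, g.hamd_sd, n), 0, 12))
    if g.label == "VaD":
        his = np.clip(7 + rng.poisson(1.5, n), 7, 18)
    else:
        his = np.clip(rng.poisson(1.0, n), 0, HIS_CAP)
    if g.label in _DEMENTIA_LABELS:
        adl = np.clip(16 + rng.poisson(6.0, n), 16, 56)
        cdr = rng.choice([1.0, 2.0], size=n, p=[0.7, 0.3])
        cdr_mem = cdr.copy()
    else:
        adl = 14 + np.minimum(rng.poisson(0.5, n), 1)
        if g.label in {"MCI", "VCI"}:
            cdr = np.full(n, 0.5)
        else:
            cdr = np.zeros(n)
        cdr_mem = cdr.copy()
    sex = np.where(rng.random(n) < g.male_frac, "male", "female")

    retest = np.full(n, None, dtype=object)
    rt = spec.retest
    if rt is not None and g.label == rt.group:
        k = int(round(rt.fraction * n))
        idx = np.sort(rng.choice(n, size=k, replace=False))
        # observed-scale blend: corr(baseline, retest) = r up to the
        # (small) attenuation from clipping and integer rounding
        dsr_mu, dsr_sigma = _dsr_moments(spec, g)
        rt_cont = (dsr_mu + rt.r * (dsr_cont - dsr_mu)
                   + dsr_sigma * math.sqrt(max(0.0, 1 - rt.r ** 2))
                   * rng.standard_normal(n))
        rt_scores = _round_int(np.clip(rt_cont, SCORE_LO, SCORE_HI))
        for i in idx:
            retest[i] = int(rt_scores[i])

    records = []
    for i in range(n):
        records.append(SubjectRecord(
            id=f"{g.label}-{i + 1:04d}",
            age=float(age[i]),
            education_years=float(edu[i]),
            education_level=_education_level(edu[i]),
            sex=str(sex[i]),
            group=g.label,
            mmse=int(mmse[i]),
            adl=int(adl[i]),
            cdr_global=float(cdr[i]),
            cdr_memory=float(cdr_mem[i]),
            his=int(his[i]),
            hamd17=int(hamd[i]),
            isr=int(isr[i]),
            dsr=int(dsr[i]),
            dsr_retest=retest[i],
        ))
    return records


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> CohortTable:
    """Generate one cohort according to ``spec``.

    ``seed`` overrides ``spec.seed``.  The same seed yields an identical
    table; each group consumes an independent child stream of the root
    seed, so groups are reproducible in isolation.
    """
    root_seed = spec.seed if seed is None else seed
    children = np.random.SeedSequence(root_seed).spawn(len(spec.groups))
    coupling = mmse_coupling(spec)
    records = []
    for g, child in zip(spec.groups, children):
        records.extend(_generate_group(g, spec, np.random.default_rng(child),
                                       coupling))
    return CohortTable(records, provenance=f"simulated(seed={root_seed})")


# ---------------------------------------------------------------------------
# config IO

def _spec_from_dict(d: dict) -> CohortSpec:
    groups = [GroupSpec(**g) for g in d["groups"]]
    reg = d.get("nc_regression")
    retest = d.get("retest")
    return CohortSpec(
        groups=groups,
        nc_regression=RegressionSpec(**reg) if reg else None,
        mmse_dsr_partial_r=d.get("mmse_dsr_partial_r", 0.575),
        isr_dsr_rho=d.get("isr_dsr_rho", 0.9),
        retest=RetestSpec(**retest) if retest else None,
        seed=d.get("seed", 0),
    )


def load_cohort_spec(path) -> CohortSpec:
    """Load a cohort spec from a YAML (or JSON-as-YAML) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return _spec_from_dict(yaml.safe_load(fh))


def table1_spec() -> CohortSpec:
    """The packaged default cohort config: the published group-level
    moments of the validation study's screened sample (control, MCI, AD,
    vascular and other dementias), the control-group norming regression,
    and the MCI retest subset."""
    ref = resources.files("normscreen").joinpath("data/table1.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return _spec_from_dict(yaml.safe_load(fh))
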