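"""Three-level Bayesian meta-regression on zBMI mean differences.

Model
-----
Each observation is a mean difference (MD) in change-from-baseline zBMI
between an intervention arm ``a`` and a reference arm ``b`` of trial ``i`` at
follow-up time ``t``. For a control-referenced observation the mean is

    alpha + beta' x_a + gamma' w_i + delta' v_t + eta' (interaction products)

and for an active-referenced observation the mean is the difference of the
two arms' predictors, which cancels the intercept, the trial-level and the
time-point-level terms — such comparisons inform only differences of
intervention-level characteristics.

Between-trial variation is captured by random effects u indexed by
(arm, follow-up category) within each trial, with Var(u) = tau^2 and
Cov(u, u') = tau^2/2 for any two distinct effects in the same trial — the
usual exchangeable network-meta-analysis structure, applied to follow-up
times exactly as to arms. Residuals are multivariate normal within a trial:
variance se^2 on the diagonal, correlation rho_time between the same
comparison at different times, and rho_arm between different comparisons
sharing a reference arm. Marginalising the random effects gives, per trial,

    y ~ N(X theta, R + tau^2 C),   C = Z (I + J) Z' / 2,

with Z the signed incidence of observations onto (arm, category) effects.

Inference
---------
Priors are Normal(0, prior_coef_sd^2) on every coefficient and
Uniform(0, tau_upper) on tau. Sampling is by a blocked Gibbs scheme: the
residual and random-effect blocks are simultaneously diagonalised once
(R = LL', C~ = L^-1 C L^-T = Q Lam Q'), after which the whitened model is an
independent-observation weighted regression with weights 1/(1 + tau^2
lambda_k); the full coefficient vector is then drawn exactly from its
conjugate multivariate-normal conditional, and tau from its bounded
univariate conditional by shrinkage slice sampling. Spike-and-slab priors
for stochastic search variable selection plug into the same scheme via
per-coefficient prior SDs and conjugate Bernoulli updates of the inclusion
indicators.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .config import ModelConfig
from .data import AnalysisDataset, ComparisonObservation
from .indicators import (
    ALL_INDICATORS,
    INTERVENTION_INDICATORS,
    TIME_INDICATORS,
    TRIAL_INDICATORS,
    level_of,
)

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.05
ESS_THRESHOLD = 400.0
_RIDGE = 1e-10


# ---------------------------------------------------------------------------
# Design construction


def interaction_name(a: str, b: str) -> str:
    """Canonical label for an interaction pair (ordered by indicator list)."""
    order = {k: i for i, k in enumerate(ALL_INDICATORS)}
    a, b = sorted((a, b), key=order.__getitem__)
    return f"{a}:{b}"


@dataclass
class Design:
    X: np.ndarray                 # n_obs x p, centred if requested
    columns: list[str]
    centering: np.ndarray         # per-column means subtracted (0 for intercept)
    is_active_ref: np.ndarray     # bool per row
    interactions: list[tuple[str, str]]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def decenter_intercept(self, theta: np.ndarray) -> float:
        """Intercept on the uncentred scale: alpha_c - sum(coef * mean)."""
        return float(theta[0] - theta[1:] @ self.centering[1:])


def _phi(
    dataset: AnalysisDataset,
    obs: ComparisonObservation,
    arm_id: str,
    interactions: list[tuple[str, str]],
) -> np.ndarray:
    """Arm-level covariate vector [1, x, w, v, products] for one observation."""
    arm = dataset.arms[arm_id]
    trial = dataset.trials[obs.trial_id]
    x = arm.indicator_vector()
    w = np.array([getattr(trial, k) for k in TRIAL_INDICATORS], float)
    v = obs.time_vector()
    vals = {}
    vals.update(zip(INTERVENTION_INDICATORS, x))
    vals.update(zip(TRIAL_INDICATORS, w))
    vals.update(zip(TIME_INDICATORS, v))
    prods = [vals[a] * vals[b] for a, b in interactions]
    return np.concatenate(([1.0], x, w, v, prods))


def build_design(
    dataset: AnalysisDataset,
    interactions: list[tuple[str, str]] | None = None,
    center: bool = True,
) -> Design:
    """Build the design matrix with interactions and mean-centring.

    Interaction products are computed per arm (using the arm's trial- and
    time-level values where a pair crosses levels) and differenced for
    active-referenced rows, so purely trial/time products cancel there just
    as the main trial/time terms do. Centring subtracts each covariate's
    mean over observation rows; active-referenced rows are raw differences
    and are invariant to centring, so only control-referenced rows are
    shifted. Centring means are stored for de-centring the intercept.
    """
    interactions = list(interactions or [])
    for a, b in interactions:
        level_of(a), level_of(b)  # raises on unknown/dropped indicator
        if a == b:
            raise ValueError(f"self-interaction {a!r}")
    columns = (
        ["intercept"]
        + list(INTERVENTION_INDICATORS)
        + list(TRIAL_INDICATORS)
        + list(TIME_INDICATORS)
        + [interaction_name(a, b) for a, b in interactions]
    )
    n = dataset.n_observations
    p = len(columns)
    phi_a = np.zeros((n, p))
    X = np.zeros((n, p))
    is_active = np.zeros(n, bool)
    for i, obs in enumerate(dataset.observations):
        pa = _phi(dataset, obs, obs.arm_id, interactions)
        phi_a[i] = pa
        if dataset.arms[obs.reference_arm_id].is_control:
            X[i] = pa
        else:
            is_active[i] = True
            X[i] = pa - _phi(dataset, obs, obs.reference_arm_id, interactions)

    centering = np.zeros(p)
    if center:
        centering = phi_a.mean(axis=0)
        centering[0] = 0.0
        X[~is_active] -= centering[None, :]
        X[~is_active, 0] = 1.0
    return Design(
        X=X,
        columns=columns,
        centering=centering,
        is_active_ref=is_active,
        interactions=interactions,
    )


# ---------------------------------------------------------------------------
# Covariance structure


def within_trial_covariance(
    observations: list[ComparisonObservation],
    rho_time: float,
    rho_arm: float = 0.5,
) -> np.ndarray:
    """Residual covariance block for one trial's observations.

    Diagonal se_i^2; off-diagonal rho_time*se_i*se_j for the same comparison
    at different follow-up times, rho_arm*se_i*se_j for different comparisons
    sharing a reference arm, 0 otherwise. Near-singular blocks get a ridge of
    1e-10 * max(diag) (logged); a block still not positive definite is an
    error.
    """
    m = len(observations)
    ses = np.array([o.se for o in observations])
    R = np.diag(ses**2)
    for i in range(m):
        for j in range(i + 1, m):
            oi, oj = observations[i], observations[j]
            same_comparison = (
                oi.arm_id == oj.arm_id
                and oi.reference_arm_id == oj.reference_arm_id
            )
            if same_comparison:
                rho = rho_time
            elif oi.reference_arm_id == oj.reference_arm_id:
                rho = rho_arm
            else:
                rho = 0.0
            R[i, j] = R[j, i] = rho * ses[i] * ses[j]
    if m > 1:
        w = np.linalg.eigvalsh(R)
        if w[0] <= 0:
            ridge = _RIDGE * float(R.diagonal().max())
            logger.warning(
                "within-trial covariance not PD (min eig %.3e); adding ridge %.3e",
                w[0], ridge,
            )
            R = R + ridge * np.eye(m)
            if np.linalg.eigvalsh(R)[0] <= 0:
                raise np.linalg.LinAlgError(
                    "within-trial covariance block not positive definite"
                )
    return R


def random_effect_structure(
    observations: list[ComparisonObservation],
    control_arms: set[str],
) -> np.ndarray:
    """Unit-tau^2 random-effect covariance C = Z (I + J) Z' / 2.

    Effects are indexed by (active arm, follow-up category); an observation
    loads +1 on its intervention arm's effect and -1 on its reference arm's
    effect when the reference is active. Multiply by tau^2 for the RE
    contribution to the marginal covariance.
    """
    keys: list[tuple[str, str]] = []
    index: dict[tuple[str, str], int] = {}

    def key_of(arm_id: str, cat: str) -> int:
        k = (arm_id, cat)
        if k not in index:
            index[k] = len(keys)
            keys.append(k)
        return index[k]

    m = len(observations)
    rows = []
    for o in observations:
        rows.append(
            (
                key_of(o.arm_id, o.followup_category),
                key_of(o.reference_arm_id, o.followup_category)
                if o.reference_arm_id not in control_arms
                else None,
            )
        )
    Z = np.zeros((m, len(keys)))
    for i, (ka, kb) in enumerate(rows):
        Z[i, ka] += 1.0
        if kb is not None:
            Z[i, kb] -= 1.0
    q = len(keys)
    return 0.5 * Z @ (np.eye(q) + np.ones((q, q))) @ Z.T


@dataclass
class TrialBlock:
    trial_id: str
    rows: np.ndarray  # indices into the observation order
    R: np.ndarray
    C: np.ndarray


def trial_blocks(dataset: AnalysisDataset, config: ModelConfig) -> list[TrialBlock]:
    order: dict[str, list[int]] = {}
    for i, obs in enumerate(dataset.observations):
        order.setdefault(obs.trial_id, []).append(i)
    controls = {a.arm_id for a in dataset.arms.values() if a.is_control}
    blocks = []
    for tid, idx in order.items():
        obs = [dataset.observations[i] for i in idx]
        blocks.append(
            TrialBlock(
                trial_id=tid,
                rows=np.array(idx),
                R=within_trial_covariance(obs, config.rho_time, config.rho_arm),
                C=random_effect_structure(obs, controls),
            )
        )
    return blocks


def log_likelihood(
    y: np.ndarray,
    X: np.ndarray,
    theta: np.ndarray,
    tau: float,
    blocks: list[TrialBlock],
) -> float:
    """Marginal log likelihood: sum over trials of the N(X theta, R + tau^2 C)
    log density (random effects integrated out analytically)."""
    total = 0.0
    for b in blocks:
        V = b.R + tau**2 * b.C
        r = y[b.rows] - X[b.rows] @ theta
        cf = linalg.cho_factor(V, lower=True)
        quad = r @ linalg.cho_solve(cf, r)
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        total += -0.5 * (len(r) * math.log(2.0 * math.pi) + logdet + quad)
    return float(total)


# ---------------------------------------------------------------------------
# Whitening: simultaneous diagonalisation of (R, C)


@dataclass
class _Whitened:
    X: np.ndarray    # stacked transformed design
    y: np.ndarray
    lam: np.ndarray  # per transformed row: eigenvalue of L^-1 C L^-T


def _whiten(y, X, blocks) -> _Whitened:
    Xt, yt, lams = [], [], []
    for b in blocks:
        L = np.linalg.cholesky(b.R)
        Ct = linalg.solve_triangular(L, b.C, lower=True)
        Ct = linalg.solve_triangular(L, Ct.T, lower=True).T
        lam, Q = np.linalg.eigh(0.5 * (Ct + Ct.T))
        lam = np.clip(lam, 0.0, None)
        W = Q.T @ linalg.solve_triangular(L, np.eye(len(b.rows)), lower=True)
        Xt.append(W @ X[b.rows])
        yt.append(W @ y[b.rows])
        lams.append(lam)
    return _Whitened(np.vstack(Xt), np.concatenate(yt), np.concatenate(lams))


def whitened_loglik(w: _Whitened, theta: np.ndarray, tau: float) -> float:
    """Log likelihood in the whitened parameterisation (equal to
    :func:`log_likelihood` up to the fixed Jacobian of the whitening)."""
    d = 1.0 + tau**2 * w.lam
    r = w.y - w.X @ theta
    return float(-0.5 * (np.sum(np.log(d)) + np.sum(r**2 / d)))


# ---------------------------------------------------------------------------
# Gibbs sampler


def _slice_tau(logp, tau0: float, upper: float, rng) -> float:
    """One shrinkage slice-sampling update of tau on [0, upper]."""
    logy = logp(tau0) - rng.exponential()
    lo, hi = 0.0, upper
    for _ in range(200):
        cand = rng.uniform(lo, hi)
        if logp(cand) > logy:
            return cand
        if cand < tau0:
            lo = cand
        else:
            hi = cand
    return tau0


@dataclass
class SsvsSpec:
    """Spike-and-slab prior spec for a subset of design columns."""

    indices: np.ndarray      # columns under selection
    spike_sd: float = 0.01
    slab_sd: float = 1.0
    p_incl: float = 0.5


@dataclass
class FitResult:
    columns: list[str]
    theta: np.ndarray          # (chains, draws, p)
    tau: np.ndarray | None     # (chains, draws) or None in FE mode
    inclusion: np.ndarray | None  # (chains, draws, k) 0/1 for SSVS columns
    design: Design
    config: ModelConfig
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def parameter_names(self) -> list[str]:
        names = list(self.columns)
        if self.tau is not None:
            names.append("tau")
        return names

    def samples(self, name: str) -> np.ndarray:
        if name == "tau":
            if self.tau is None:
                raise KeyError("fixed-effects fit has no tau samples")
            return self.tau
        return self.theta[:, :, self.columns.index(name)]

    def posterior_mean(self) -> pd.Series:
        return pd.Series(
            self.theta.mean(axis=(0, 1)), index=self.columns, name="mean"
        )

    def summary(self) -> pd.DataFrame:
        arrays = {c: self.theta[:, :, j] for j, c in enumerate(self.columns)}
        if self.tau is not None:
            arrays["tau"] = self.tau
        out = summarize(arrays)
        if not self.diagnostics.empty:
            out = out.join(self.diagnostics)
        return out

    @property
    def converged(self) -> bool:
        if self.diagnostics.empty:
            return True
        return bool((self.diagnostics["rhat"].dropna() < RHAT_THRESHOLD).all())

    def decentered_intercept(self) -> float:
        return self.design.decenter_intercept(
            self.posterior_mean().to_numpy()
        )


def summarize(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Posterior mean, central 95% credible interval and tail probabilities.

    P(<0) and P(>0) are the fractions of samples strictly below/above zero;
    samples exactly at zero (a measure-zero event) count to neither, so the
    two need not sum to one when such samples occur.
    """
    rows = []
    for name, arr in samples.items():
        flat = np.asarray(arr).ravel()
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "p_lt0": float(np.mean(flat < 0)),
                "p_gt0": float(np.mean(flat > 0)),
            }
        )
    return pd.DataFrame(rows, index=list(samples))


def _diagnostics(arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        rows = {}
        for name, arr in arrays.items():
            if arr.shape[0] >= 2 and arr.shape[1] >= 4:
                rows[name] = {
                    "rhat": float(az.rhat(arr)),
                    "ess": float(az.ess(arr)),
                }
            else:
                rows[name] = {"rhat": np.nan, "ess": np.nan}
    return pd.DataFrame(rows).T


def fit(
    dataset: AnalysisDataset,
    config: ModelConfig,
    interactions: list[tuple[str, str]] | None = None,
    ssvs: SsvsSpec | None = None,
    design: Design | None = None,
) -> FitResult:
    """Fit the meta-regression by blocked Gibbs sampling.

    Random-effects mode samples (theta, tau) jointly; fixed-effects mode pins
    tau = 0. With an :class:`SsvsSpec`, the listed columns get the
    spike-and-slab mixture prior and latent inclusion indicators are sampled
    alongside. Deterministic given ``config.seed``. A fit whose split-R-hat
    exceeds 1.05 on any parameter is flagged (``converged`` False and a
    warning logged), never silently accepted.
    """
    if design is None:
        design = build_design(dataset, interactions, center=config.center)
    y = np.array([o.md for o in dataset.observations])
    blocks = trial_blocks(dataset, config)
    w = _whiten(y, design.X, blocks)

    p = design.p
    tau_fixed = config.tau_fixed
    prior_sd_base = np.full(p, config.prior_coef_sd)
    if ssvs is not None:
        if not 0.0 < ssvs.p_incl < 1.0:
            raise ValueError("p_incl must be in (0, 1)")
        if ssvs.spike_sd >= ssvs.slab_sd:
            logger.warning(
                "spike SD %.3g not below slab SD %.3g: selection is "
                "unidentified and inclusion frequencies collapse to the prior",
                ssvs.spike_sd, ssvs.slab_sd,
            )

    n_iter = config.warmup + config.draws
    theta_out = np.empty((config.chains, config.draws, p))
    tau_out = (
        np.empty((config.chains, config.draws)) if tau_fixed is None else None
    )
    incl_out = (
        np.empty((config.chains, config.draws, len(ssvs.indices)))
        if ssvs is not None
        else None
    )

    XtX_cache = w.X  # alias for readability below
    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        theta = np.zeros(p)
        tau = tau_fixed if tau_fixed is not None else min(0.1, config.tau_upper / 2)
        incl = np.ones(len(ssvs.indices), bool) if ssvs is not None else None
        prior_sd = prior_sd_base.copy()
        for it in range(n_iter):
            if ssvs is not None:
                prior_sd[ssvs.indices] = np.where(
                    incl, ssvs.slab_sd, ssvs.spike_sd
                )
            d = 1.0 + tau**2 * w.lam
            wt = 1.0 / d
            Xw = XtX_cache * wt[:, None]
            A = XtX_cache.T @ Xw + np.diag(1.0 / prior_sd**2)
            b = Xw.T @ w.y
            L = np.linalg.cholesky(A)
            mu = linalg.cho_solve((L, True), b)
            z = rng.standard_normal(p)
            theta = mu + linalg.solve_triangular(L, z, lower=True, trans=1)

            if ssvs is not None:
                tj = theta[ssvs.indices]
                log_odds = (
                    math.log(ssvs.p_incl / (1.0 - ssvs.p_incl))
                    + (-0.5 * (tj / ssvs.slab_sd) ** 2 - math.log(ssvs.slab_sd))
                    - (-0.5 * (tj / ssvs.spike_sd) ** 2 - math.log(ssvs.spike_sd))
                )
                incl = rng.random(len(tj)) < 1.0 / (1.0 + np.exp(-log_odds))

            if tau_fixed is None:
                r = w.y - XtX_cache @ theta

                def logp_tau(t: float) -> float:
                    dd = 1.0 + t**2 * w.lam
                    return -0.5 * float(np.sum(np.log(dd)) + np.sum(r**2 / dd))

                tau = _slice_tau(logp_tau, tau, config.tau_upper, rng)

            if it >= config.warmup:
                k = it - config.warmup
                theta_out[chain, k] = theta
                if tau_out is not None:
                    tau_out[chain, k] = tau
                if incl_out is not None:
                    incl_out[chain, k] = incl

    arrays = {c: theta_out[:, :, j] for j, c in enumerate(design.columns)}
    if tau_out is not None:
        arrays["tau"] = tau_out
    diag = _diagnostics(arrays)
    result = FitResult(
        columns=design.columns,
        theta=theta_out,
        tau=tau_out,
        inclusion=incl_out,
        design=design,
        config=config,
        diagnostics=diag,
    )
    if not result.converged:
        bad = diag.index[diag["rhat"] >= RHAT_THRESHOLD].tolist()
        logger.warning("fit did not converge (R-hat >= %.2f) for %s",
                       RHAT_THRESHOLD, bad)
    return result
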