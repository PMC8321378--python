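"""Hierarchical Gaussian generative classifier over CDR profiles (SpaGen).

The model for the CDR value of eye *i* in direction *d* (d = 1..24) is

    Y_{i,d} = beta0 + betaG0 * I_G + betaCDAR * CDAR_i
              + sum_k [ group-specific sine/cosine terms at frequencies
                        2*pi*k*d/24, k = 1..n_harmonics ]
              + z_i + e_{i,d}

with a per-eye random effect z_i ~ N(0, sigma_z^2) shared by all
directions, and independent within-eye noise e_{i,d} ~ N(0, sigma_G^2)
for glaucomatous eyes and N(0, sigma_H^2) for healthy eyes.  Marginally
each eye's profile is multivariate normal with compound-symmetric
covariance V = sigma_z^2 * J + sigma_g^2 * I, whose two eigenvalues
(sigma_g^2 with multiplicity n-1, sigma_g^2 + n*sigma_z^2 with
multiplicity 1) give closed-form determinants and quadratic forms.

Classification of a new profile is by the Bayes posterior

    p_G * f_G(y) / (p_G * f_G(y) + p_H * f_H(y)),

and the Rim Deformation Score (RDS) is half the difference of squared
Mahalanobis distances from the healthy and glaucomatous group
distributions; under a shared covariance the two decision rules are
equivalent through a log-odds identity.

Fitting is by maximum likelihood: the fixed effects are profiled out by
generalized least squares given the variance components, and the
variance components are optimized numerically on the log scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .errors import FittingError
from .geometry import CDRProfile, GLAUCOMA, HEALTHY

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# configuration and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Structural choices of the generative model.

    use_cdar
        Include the cup-to-disc area ratio as a shared covariate.
    n_variances
        1 for a shared within-eye noise variance, 2 for group-specific
        variances (glaucoma vs healthy).
    n_dirs
        Number of profile directions (24 at 15-degree spacing).
    n_harmonics
        Fourier harmonics per group in the mean (2 by default:
        sin/cos at 2*pi*d/24 and 4*pi*d/24).
    """

    use_cdar: bool = True
    n_variances: int = 2
    n_dirs: int = 24
    n_harmonics: int = 2

    def __post_init__(self) -> None:
        if self.n_dirs < 4:
            raise ValueError("n_dirs must be >= 4")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics must be >= 1")
        if self.n_variances not in (1, 2):
            raise ValueError("n_variances must be 1 or 2")

    @property
    def table_name(self) -> str:
        """Human-readable configuration name (ablation-style)."""
        parts = [f"CDR profile of {self.n_dirs} values",
                 f"{self.n_variances} variance parameter"
                 + ("s" if self.n_variances > 1 else "")]
        if self.use_cdar:
            parts.append("CDAR")
        return " and ".join(parts)


def count_parameters(config: ModelConfig) -> int:
    """Number of free parameters: prior + fixed effects + variances.

    The full default configuration (CDAR covariate, two group noise
    variances) has 15 = 1 prior + 11 fixed effects (beta0, betaG0,
    betaCDAR, 8 Fourier coefficients) + 3 variance components.
    """
    fixed = 2 + (1 if config.use_cdar else 0) + 4 * config.n_harmonics
    variances = 1 + config.n_variances  # sigma_z^2 plus noise variance(s)
    return 1 + fixed + variances


@dataclass
class SpaGenParams:
    """Model parameters; ``fourier_g``/``fourier_h`` are ordered
    (sin 2*pi*d/n, cos 2*pi*d/n, sin 4*pi*d/n, cos 4*pi*d/n, ...)."""

    beta0: float
    beta_g0: float
    fourier_g: np.ndarray
    fourier_h: np.ndarray
    sigma_z2: float
    sigma_g2: float
    sigma_h2: float
    prior_g: float
    beta_cdar: float | None = None
    n_dirs: int = 24

    def __post_init__(self) -> None:
        self.fourier_g = np.asarray(self.fourier_g, dtype=float)
        self.fourier_h = np.asarray(self.fourier_h, dtype=float)
        if self.fourier_g.shape != self.fourier_h.shape:
            raise ValueError("fourier_g and fourier_h must have equal length")
        if self.sigma_z2 < 0:
            raise ValueError("sigma_z2 must be >= 0")
        # zero noise variance is permitted for degenerate (noiseless)
        # forward simulation; density evaluation requires > 0
        if self.sigma_g2 < 0 or self.sigma_h2 < 0:
            raise ValueError("noise variances must be >= 0")
        if not 0.0 < self.prior_g < 1.0:
            raise ValueError("prior_g must lie in (0, 1)")

    @property
    def n_harmonics(self) -> int:
        return self.fourier_g.size // 2


@dataclass
class GroupMoments:
    """Mean vector and compound-symmetric covariance of one group."""

    mean: np.ndarray
    cov: np.ndarray
    sigma2: float | None = None    # noise variance (structured form)
    sigma_z2: float | None = None  # random-effect variance (structured form)

    @property
    def structured(self) -> bool:
        return self.sigma2 is not None and self.sigma_z2 is not None


@dataclass
class SpaGenFit:
    """A fitted model: parameters, attained log-likelihood, bookkeeping."""

    config: ModelConfig
    params: SpaGenParams
    loglik: float
    converged: bool
    n_params: int
    se: dict[str, float] = field(default_factory=dict)

    def moments(self, group: str, cdar: float | None = None) -> GroupMoments:
        mean = mean_vector(self.params, group, cdar, config=self.config)
        cov = covariance_matrix(self.params, group)
        s2 = self.params.sigma_g2 if group == GLAUCOMA else self.params.sigma_h2
        return GroupMoments(mean=mean, cov=cov, sigma2=s2,
                            sigma_z2=self.params.sigma_z2)


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def fourier_basis(n_dirs: int, n_harmonics: int) -> np.ndarray:
    """Design columns sin/cos(2*pi*k*d/n) for d = 1..n, k = 1..H."""
    d = np.arange(1, n_dirs + 1)
    cols = []
    for k in range(1, n_harmonics + 1):
        w = 2.0 * math.pi * k * d / n_dirs
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def mean_vector(params: SpaGenParams, group: str, cdar: float | None = None,
                config: ModelConfig | None = None) -> np.ndarray:
    """Group mean profile given CDAR."""
    if group not in (GLAUCOMA, HEALTHY):
        raise ValueError(f"unknown group {group!r}")
    n_dirs = config.n_dirs if config is not None else params.n_dirs
    basis = fourier_basis(n_dirs, params.n_harmonics)
    mu = np.full(n_dirs, params.beta0, dtype=float)
    if params.beta_cdar is not None:
        if cdar is None or not np.isfinite(cdar):
            raise ValueError("cdar is required when the model includes betaCDAR")
        mu += params.beta_cdar * cdar
    if group == GLAUCOMA:
        mu += params.beta_g0
        mu += basis @ params.fourier_g
    else:
        mu += basis @ params.fourier_h
    return mu


def covariance_matrix(params: SpaGenParams, group: str,
                      config: ModelConfig | None = None) -> np.ndarray:
    """Marginal covariance sigma_z^2 * J + sigma_g^2 * I of one group."""
    if group not in (GLAUCOMA, HEALTHY):
        raise ValueError(f"unknown group {group!r}")
    n_dirs = config.n_dirs if config is not None else params.n_dirs
    s2 = params.sigma_g2 if group == GLAUCOMA else params.sigma_h2
    return params.sigma_z2 * np.ones((n_dirs, n_dirs)) + s2 * np.eye(n_dirs)


def _cs_quad(r: np.ndarray, sigma2: float, sigma_z2: float) -> float:
    """r' V^-1 r for V = sigma_z2*J + sigma2*I via the eigen closed form."""
    n = r.size
    rbar = float(r.mean())
    ss = float(r @ r)
    return (ss - n * rbar * rbar) / sigma2 + n * rbar * rbar / (sigma2 + n * sigma_z2)


def _cs_logdet(n: int, sigma2: float, sigma_z2: float) -> float:
    return (n - 1) * math.log(sigma2) + math.log(sigma2 + n * sigma_z2)


def log_density(y: np.ndarray, moments: GroupMoments) -> float:
    """Multivariate-normal log-density of a profile under group moments.

    Uses the two-eigenvalue closed form when the compound-symmetry
    structure is available, otherwise a dense Cholesky solve.
    """
    y = np.asarray(y, dtype=float)
    r = y - moments.mean
    n = r.size
    if moments.structured:
        if moments.sigma2 <= 0:
            raise np.linalg.LinAlgError("covariance is not positive definite")
        quad = _cs_quad(r, moments.sigma2, moments.sigma_z2)
        logdet = _cs_logdet(n, moments.sigma2, moments.sigma_z2)
    else:
        sign, logdet = np.linalg.slogdet(moments.cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("covariance is not positive definite")
        quad = float(r @ np.linalg.solve(moments.cov, r))
    return -0.5 * (n * _LOG2PI + logdet + quad)


def mahalanobis_sq(y: np.ndarray, moments: GroupMoments) -> float:
    """Squared Mahalanobis distance of a profile from a group."""
    r = np.asarray(y, dtype=float) - moments.mean
    if moments.structured:
        return _cs_quad(r, moments.sigma2, moments.sigma_z2)
    return float(r @ np.linalg.solve(moments.cov, r))


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _design(is_glaucoma: bool, cdar: float | None, config: ModelConfig,
            basis: np.ndarray) -> np.ndarray:
    n = config.n_dirs
    cols = [np.ones(n), np.full(n, 1.0 if is_glaucoma else 0.0)]
    if config.use_cdar:
        cols.append(np.full(n, float(cdar)))
    z = np.zeros_like(basis)
    cols.append(basis if is_glaucoma else z)    # glaucoma Fourier block
    cols.append(z if is_glaucoma else basis)    # healthy Fourier block
    return np.column_stack(cols)


def _param_names(config: ModelConfig) -> list[str]:
    names = ["beta0", "beta_g0"]
    if config.use_cdar:
        names.append("beta_cdar")
    for grp in ("g", "h"):
        for k in range(1, config.n_harmonics + 1):
            names += [f"beta_{grp}_sin{k}", f"beta_{grp}_cos{k}"]
    return names


def _gls(X_list, Y, groups_g, s2g, s2h, sz2):
    """Profiled GLS fixed effects and per-eye quadratic pieces.

    Returns (beta, A) where A = sum_i X_i' V_i^-1 X_i.  Uses the
    Sherman-Morrison form V^-1 = (I - c*J) / s2 with c = sz2/(s2+n*sz2).
    """
    p = X_list[0].shape[1]
    n = X_list[0].shape[0]
    A = np.zeros((p, p))
    b = np.zeros(p)
    for X, y, is_g in zip(X_list, Y, groups_g):
        s2 = s2g if is_g else s2h
        c = sz2 / (s2 + n * sz2)
        Xs = X.sum(axis=0)
        ys = y.sum()
        A += (X.T @ X - c * np.outer(Xs, Xs)) / s2
        b += (X.T @ y - c * Xs * ys) / s2
    beta = np.linalg.solve(A, b)
    return beta, A


def _profiled_negloglik(logv, X_list, Y, groups_g, config):
    sz2 = math.exp(logv[0])
    s2g = math.exp(logv[1])
    s2h = math.exp(logv[2]) if config.n_variances == 2 else s2g
    n = config.n_dirs
    try:
        beta, _ = _gls(X_list, Y, groups_g, s2g, s2h, sz2)
    except np.linalg.LinAlgError:
        return 1e12
    ll = 0.0
    for X, y, is_g in zip(X_list, Y, groups_g):
        s2 = s2g if is_g else s2h
        r = y - X @ beta
        ll += -0.5 * (n * _LOG2PI + _cs_logdet(n, s2, sz2) + _cs_quad(r, s2, sz2))
    return -ll


def fit_ml(profiles, config: ModelConfig | None = None,
           prior_g: float | None = None) -> SpaGenFit:
    """Maximum-likelihood fit of the generative model to labeled profiles.

    Fixed effects are profiled out by GLS; the variance components are
    optimized by L-BFGS-B on the log scale (the likelihood has a single
    maximum under the normal error model, so one start suffices).  The
    prior glaucoma probability defaults to the training prevalence.
    """
    config = config or ModelConfig()
    profiles = list(profiles)
    if any(p.label is None for p in profiles):
        raise FittingError("all training profiles must carry a diagnosis label")
    groups_g = [p.label == GLAUCOMA for p in profiles]
    n_g = sum(groups_g)
    n_h = len(profiles) - n_g
    if n_g < 2 or n_h < 2:
        raise FittingError(
            f"need at least 2 eyes per group, got {n_g} glaucoma / {n_h} healthy")
    if any(p.n_dirs != config.n_dirs for p in profiles):
        raise FittingError("profile length does not match config.n_dirs")

    basis = fourier_basis(config.n_dirs, config.n_harmonics)
    X_list = [_design(g, p.cdar if config.use_cdar else None, config, basis)
              for p, g in zip(profiles, groups_g)]
    Y = [np.asarray(p.values, dtype=float) for p in profiles]

    # moment-based start: OLS residuals split into between/within-eye variance
    Xall = np.vstack(X_list)
    yall = np.concatenate(Y)
    beta0, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
    resid = [y - X @ beta0 for X, y in zip(X_list, Y)]
    within = float(np.mean([r.var(ddof=1) for r in resid]))
    between = float(np.var([r.mean() for r in resid], ddof=1))
    sz2_0 = max(between - within / config.n_dirs, 1e-6)
    s2_0 = max(within, 1e-6)
    x0 = [math.log(sz2_0)] + [math.log(s2_0)] * config.n_variances

    res = optimize.minimize(
        _profiled_negloglik, x0=np.array(x0),
        args=(X_list, Y, groups_g, config),
        method="L-BFGS-B", bounds=[(-30.0, 5.0)] * len(x0),
    )
    sz2 = math.exp(res.x[0])
    s2g = math.exp(res.x[1])
    s2h = math.exp(res.x[2]) if config.n_variances == 2 else s2g
    beta, A = _gls(X_list, Y, groups_g, s2g, s2h, sz2)
    se = np.sqrt(np.diag(np.linalg.inv(A)))
    names = _param_names(config)

    H = config.n_harmonics
    off = 3 if config.use_cdar else 2
    params = SpaGenParams(
        beta0=float(beta[0]),
        beta_g0=float(beta[1]),
        beta_cdar=float(beta[2]) if config.use_cdar else None,
        fourier_g=beta[off:off + 2 * H],
        fourier_h=beta[off + 2 * H:off + 4 * H],
        sigma_z2=sz2, sigma_g2=s2g, sigma_h2=s2h,
        prior_g=prior_g if prior_g is not None else n_g / len(profiles),
        n_dirs=config.n_dirs,
    )
    return SpaGenFit(config=config, params=params, loglik=float(-res.fun),
                     converged=bool(res.success), n_params=count_parameters(config),
                     se=dict(zip(names, se.tolist())))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationOutput:
    posterior_g: float
    rds: float
    decision: str
    threshold: float
    kind: str = "posterior"


def posterior_glaucoma(y: np.ndarray, cdar: float | None, fit: SpaGenFit) -> float:
    """Bayes posterior probability that a profile is glaucomatous."""
    y = np.asarray(y, dtype=float)
    if y.size != fit.config.n_dirs:
        raise ValueError(f"profile length {y.size} != model n_dirs {fit.config.n_dirs}")
    lg = log_density(y, fit.moments(GLAUCOMA, cdar)) + math.log(fit.params.prior_g)
    lh = log_density(y, fit.moments(HEALTHY, cdar)) + math.log(1.0 - fit.params.prior_g)
    return float(math.exp(lg - logsumexp([lg, lh])))


def rds(y: np.ndarray, cdar: float | None, fit: SpaGenFit) -> float:
    """Rim Deformation Score: half the difference of squared Mahalanobis
    distances from the healthy and glaucomatous group distributions."""
    y = np.asarray(y, dtype=float)
    if y.size != fit.config.n_dirs:
        raise ValueError(f"profile length {y.size} != model n_dirs {fit.config.n_dirs}")
    d2h = mahalanobis_sq(y, fit.moments(HEALTHY, cdar))
    d2g = mahalanobis_sq(y, fit.moments(GLAUCOMA, cdar))
    return 0.5 * (d2h - d2g)


def rds_threshold_from_posterior(p_th: float, prior_g: float) -> float:
    """RDS threshold equivalent to a posterior threshold under equal
    group covariances: log[p_th/(1-p_th) * (1-p_G)/p_G]."""
    return math.log(p_th / (1.0 - p_th) * (1.0 - prior_g) / prior_g)


def classify(score: float, threshold: float, kind: str = "posterior") -> str:
    """Decision rule: glaucoma iff score >= threshold."""
    if kind not in ("posterior", "rds"):
        raise ValueError(f"unknown score kind {kind!r}")
    return GLAUCOMA if score >= threshold else HEALTHY


def classify_profiles(profiles, fit: SpaGenFit, threshold: float = 0.5,
                      kind: str = "posterior") -> list[ClassificationOutput]:
    """Score and classify a collection of profiles."""
    out = []
    for p in profiles:
        post = posterior_glaucoma(p.values, p.cdar, fit)
        score_rds = rds(p.values, p.cdar, fit)
        score = post if kind == "posterior" else score_rds
        out.append(ClassificationOutput(
            posterior_g=post, rds=score_rds,
            decision=classify(score, threshold, kind),
            threshold=threshold, kind=kind))
    return out


# ---------------------------------------------------------------------------
# CDAR-only baseline
# ---------------------------------------------------------------------------

@dataclass
class CdarBaseline:
    """Two-parameter linear discriminant on CDAR (intercept + slope),
    scored on the logit scale and thresholded by the same ROC machinery
    as the full model."""

    intercept: float
    slope: float

    def score(self, cdar) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(cdar, dtype=float)


def fit_cdar_baseline(profiles) -> CdarBaseline:
    """Logistic fit of diagnosis on CDAR alone."""
    import statsmodels.api as sm

    profiles = list(profiles)
    if any(p.label is None for p in profiles):
        raise FittingError("all training profiles must carry a diagnosis label")
    y = np.array([1.0 if p.label == GLAUCOMA else 0.0 for p in profiles])
    if y.min() == y.max():
        raise FittingError("both diagnostic groups are required")
    x = sm.add_constant(np.array([p.cdar for p in profiles]))
    res = sm.Logit(y, x).fit(disp=0)
    return CdarBaseline(intercept=float(res.params[0]), slope=float(res.params[1]))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def fit_to_json(fit: SpaGenFit, path=None) -> str:
    """Serialize a fit as flat JSON (config + named parameters + loglik)."""
    p = fit.params
    doc = {
        "config": asdict(fit.config),
        "params": {
            "beta0": p.beta0, "beta_g0": p.beta_g0, "beta_cdar": p.beta_cdar,
            "fourier_g": p.fourier_g.tolist(), "fourier_h": p.fourier_h.tolist(),
            "sigma_z2": p.sigma_z2, "sigma_g2": p.sigma_g2, "sigma_h2": p.sigma_h2,
            "prior_g": p.prior_g, "n_dirs": p.n_dirs,
        },
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_params": fit.n_params,
        "se": fit.se,
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def fit_from_json(source) -> SpaGenFit:
    """Load a fit written by :func:`fit_to_json` (path or JSON string)."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    config = ModelConfig(**doc["config"])
    pd_ = dict(doc["params"])
    params = SpaGenParams(
        beta0=pd_["beta0"], beta_g0=pd_["beta_g0"], beta_cdar=pd_["beta_cdar"],
        fourier_g=np.array(pd_["fourier_g"]), fourier_h=np.array(pd_["fourier_h"]),
        sigma_z2=pd_["sigma_z2"], sigma_g2=pd_["sigma_g2"], sigma_h2=pd_["sigma_h2"],
        prior_g=pd_["prior_g"], n_dirs=pd_.get("n_dirs", config.n_dirs),
    )
    return SpaGenFit(config=config, params=params, loglik=doc["loglik"],
                     converged=doc["converged"], n_params=doc["n_params"],
                     se=doc.get("se", {}))
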