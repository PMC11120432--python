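"""Ordinal reader-study statistics.

Implements the statistical machinery of a multi-reader ordinal image
scoring study:

* a normal-approximation paired sample-size estimate;
* simulation of 5-point Likert scores from a cumulative-logit latent
  model with crossed Gaussian random intercepts (specimen, reader,
  structure);
* maximum-likelihood fitting of the cumulative link mixed model (CLMM,
  proportional odds with logit link) via the Laplace approximation —
  inner Newton maximization over the stacked random-effect vector,
  outer quasi-Newton over thresholds, fixed effects, and log random-SDs;
* latent-scale estimated marginal means (EMMs) with Tukey-adjusted
  pairwise contrasts (equicoordinate multivariate-normal adjustment);
* one-way repeated-measures ANOVA with Tukey-Kramer post hoc tests for
  continuous ROI metrics.

The latent model: a response in category s (of K ordered categories)
occurs with P(score <= s) = logistic(theta_s - eta), where
eta = x'beta + u_structure + u_reader + u_specimen and each u is a
zero-mean Gaussian random intercept.  EMMs are identified only up to
threshold location; we center by the mean threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.tools.numdiff import approx_hess2

__all__ = [
    "LikertDataset",
    "ClmmFit",
    "EmmTable",
    "min_sample_size",
    "simulate_likert",
    "fit_clmm",
    "emm_and_tukey",
    "rm_anova_tukey",
    "RmAnovaResult",
]

RANDOM_TERMS = ("structure", "reader", "specimen")


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------

def min_sample_size(delta: float, sd: float, power: float, alpha: float) -> int:
    """Minimum n for a paired comparison, two-sided normal approximation.

    n = ceil( ((z_{1-alpha/2} + z_{power}) * sd / |delta|)^2 )

    With delta 0.5, sd 0.4, power 0.8, alpha 0.01 this yields n = 8.
    """
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if delta == 0:
        raise ValueError("delta must be nonzero")
    if sd <= 0:
        raise ValueError("sd must be positive")
    z_a = stats.norm.ppf(1 - alpha / 2)
    z_b = stats.norm.ppf(power)
    return int(math.ceil(((z_a + z_b) * sd / abs(delta)) ** 2))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class LikertDataset:
    """Long-format ordinal scores with crossed grouping factors."""

    data: pd.DataFrame  # columns: specimen, reader, structure, sequence, score
    weighting: str = ""
    sequence_levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"specimen", "reader", "structure", "sequence", "score"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"dataset needs columns {sorted(required)}")
        scores = self.data["score"].to_numpy()
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.allclose(scores, np.round(scores)):
                raise ValueError("scores must be integers")
        if scores.min() < 1 or scores.max() > 5:
            raise ValueError("scores must lie in 1..5")
        if not self.sequence_levels:
            self.sequence_levels = tuple(pd.unique(self.data["sequence"]))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, weighting: str = "") -> "LikertDataset":
        return cls(pd.read_csv(path), weighting=weighting)


@dataclass
class ClmmFit:
    thresholds: np.ndarray          # K-1 ordered cutpoints
    beta: np.ndarray                # fixed effects (non-reference levels)
    beta_names: tuple[str, ...]
    re_sd: dict[str, float]         # random-intercept SDs by term
    loglik: float
    vcov_fixed: np.ndarray          # covariance of [thresholds, beta]
    converged: bool
    reference_level: str = ""
    n_obs: int = 0
    random_effects: dict = field(default_factory=dict)

    @property
    def beta_se(self) -> np.ndarray:
        k = len(self.thresholds)
        return np.sqrt(np.diag(self.vcov_fixed)[k:])


@dataclass
class EmmTable:
    levels: tuple[str, ...]
    emm: np.ndarray
    se: np.ndarray
    contrasts: pd.DataFrame  # columns: contrast, estimate, se, z, p_raw, p_tukey


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_likert(
    design: dict[str, Sequence],
    beta_truth: dict[str, float],
    thresholds: Sequence[float],
    re_sd_truth: dict[str, float],
    seed: int = 0,
    weighting: str = "",
) -> LikertDataset:
    """Draw a full-factorial Likert dataset from the latent cumulative model.

    ``design`` maps 'specimen'/'reader'/'structure' to level label lists
    and 'sequence' to the sequence levels; ``beta_truth`` gives the latent
    effect of each sequence level (the reference should be 0).  Scores are
    sampled with P(score <= s) = logistic(theta_s - eta).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    for key in ("specimen", "reader", "structure", "sequence"):
        if key not in design or len(design[key]) == 0:
            raise ValueError(f"design must provide non-empty {key!r} levels")
    rng = np.random.default_rng(seed)
    intercepts = {
        term: {
            lvl: rng.normal(0.0, re_sd_truth.get(term, 0.0))
            for lvl in design[term]
        }
        for term in RANDOM_TERMS
    }
    rows = []
    seq_levels = list(design["sequence"])
    for sp in design["specimen"]:
        for rd in design["reader"]:
            for st in design["structure"]:
                base = (
                    intercepts["specimen"][sp]
                    + intercepts["reader"][rd]
                    + intercepts["structure"][st]
                )
                for sq in seq_levels:
                    eta = beta_truth.get(sq, 0.0) + base
                    cum = expit(thresholds - eta)
                    probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
                    score = int(rng.choice(len(probs), p=probs)) + 1
                    rows.append((sp, rd, st, sq, score))
    df = pd.DataFrame(
        rows, columns=["specimen", "reader", "structure", "sequence", "score"]
    )
    return LikertDataset(df, weighting=weighting, sequence_levels=tuple(seq_levels))


# ---------------------------------------------------------------------------
# cumulative link (mixed) model
# ---------------------------------------------------------------------------

def _cumlogit_terms(eta: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """Log-probability and its first/second derivatives w.r.t. eta.

    lo/hi are the per-observation lower/upper cutpoints (+-inf at the
    ends); P = F(hi - eta) - F(lo - eta) with logistic F.  The cumulative
    logit pmf is log-concave in eta, so -d2 >= 0.
    """
    a = hi - eta
    b = lo - eta
    Fa, Fb = expit(a), expit(b)
    p = np.clip(Fa - Fb, 1e-300, None)
    fa = Fa * (1 - Fa)
    fb = Fb * (1 - Fb)
    logp = np.log(p)
    d1 = -(fa - fb) / p
    # f'(x) = f(x) (1 - 2 F(x))
    dfa = fa * (1 - 2 * Fa)
    dfb = fb * (1 - 2 * Fb)
    d2 = (dfa - dfb) / p - d1**2
    return logp, d1, d2


class _ClmmProblem:
    """Design matrices and Laplace objective for one dataset."""

    def __init__(self, ds: LikertDataset, random_terms: Sequence[str]):
        df = ds.data
        self.n = len(df)
        scores = df["score"].to_numpy().astype(int)
        cats = np.sort(np.unique(scores))
        if cats.size < 2:
            raise ValueError("all scores fall in a single category")
        self.n_cat = cats.size
        self.score_idx = np.searchsorted(cats, scores)
        levels = list(ds.sequence_levels)
        if len(levels) < 2:
            raise ValueError("need at least 2 sequence levels")
        self.reference = levels[0]
        self.beta_names = tuple(levels[1:])
        seq = df["sequence"].to_numpy()
        self.X = np.column_stack(
            [(seq == lvl).astype(float) for lvl in self.beta_names]
        )
        self.random_terms = tuple(t for t in RANDOM_TERMS if t in random_terms)
        self.group_idx = []
        self.group_levels = []
        for term in self.random_terms:
            vals = df[term].to_numpy()
            lv, idx = np.unique(vals, return_inverse=True)
            self.group_levels.append(lv)
            self.group_idx.append(idx)
        self.q_per_term = [len(lv) for lv in self.group_levels]
        self.q = int(sum(self.q_per_term))
        self.offsets = np.cumsum([0] + self.q_per_term)
        # dense Z (n x q): fine at desk scale
        self.Z = np.zeros((self.n, self.q))
        for t, idx in enumerate(self.group_idx):
            self.Z[np.arange(self.n), self.offsets[t] + idx] = 1.0
        self._u_warm = np.zeros(self.q)

    # parameter vector: [theta_1, log diffs (n_cat-2), beta, log sd per term]
    def unpack(self, params: np.ndarray):
        k = self.n_cat - 1
        th = np.empty(k)
        th[0] = params[0]
        if k > 1:
            th[1:] = params[0] + np.cumsum(np.exp(params[1: k]))
        nb = len(self.beta_names)
        beta = params[k: k + nb]
        log_sd = params[k + nb:]
        return th, beta, log_sd

    def cutpoints(self, th: np.ndarray):
        ext = np.concatenate(([-np.inf], th, [np.inf]))
        lo = ext[self.score_idx]
        hi = ext[self.score_idx + 1]
        return lo, hi

    def _inner_newton(self, eta_fix, lo, hi, d_inv, u0, tol=1e-8, max_iter=50):
        """Maximize joint log density over u; returns (u*, H, logp at u*)."""
        u = u0.copy()
        Z = self.Z
        for _ in range(max_iter):
            eta = eta_fix + Z @ u
            logp, d1, d2 = _cumlogit_terms(eta, lo, hi)
            g = Z.T @ d1 - d_inv * u
            W = np.maximum(-d2, 1e-12)
            H = (Z * W[:, None]).T @ Z
            H[np.diag_indices_from(H)] += d_inv
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            # damped Newton: halve until the joint density does not decrease
            obj0 = logp.sum() - 0.5 * np.sum(d_inv * u**2)
            alpha = 1.0
            for _ls in range(20):
                u_new = u + alpha * step
                eta_new = eta_fix + Z @ u_new
                logp_new, _, _ = _cumlogit_terms(eta_new, lo, hi)
                obj_new = logp_new.sum() - 0.5 * np.sum(d_inv * u_new**2)
                if obj_new >= obj0 - 1e-12:
                    break
                alpha *= 0.5
            delta = np.max(np.abs(u_new - u))
            u = u_new
            if delta < tol:
                break
        eta = eta_fix + Z @ u
        logp, d1, d2 = _cumlogit_terms(eta, lo, hi)
        W = np.maximum(-d2, 1e-12)
        H = (self.Z * W[:, None]).T @ self.Z
        H[np.diag_indices_from(H)] += d_inv
        return u, H, logp.sum()

    def neg_loglik_grad_fixed(self, params: np.ndarray) -> np.ndarray:
        """Analytic gradient of the fixed-effects (q == 0) negative loglik."""
        th, beta, _ = self.unpack(params)
        lo, hi = self.cutpoints(th)
        eta = self.X @ beta
        a, b = hi - eta, lo - eta
        Fa, Fb = expit(a), expit(b)
        p = np.clip(Fa - Fb, 1e-300, None)
        fa, fb = Fa * (1 - Fa), Fb * (1 - Fb)
        d1 = -(fa - fb) / p
        k = self.n_cat - 1
        g_theta = np.zeros(k)
        upper = self.score_idx  # hi_i = theta[score_idx] when score_idx < k
        lower = self.score_idx - 1
        np.add.at(g_theta, upper[upper < k], (fa / p)[upper < k])
        np.subtract.at(g_theta, lower[lower >= 0], (fb / p)[lower >= 0])
        g_beta = self.X.T @ d1
        # chain rule to (theta1, log-diff) parametrization
        g = np.empty(len(params))
        g[0] = g_theta.sum()
        for m in range(1, k):
            g[m] = np.exp(params[m]) * g_theta[m:].sum()
        g[k: k + len(beta)] = g_beta
        return -g

    def neg_marginal_loglik(self, params: np.ndarray) -> float:
        th, beta, log_sd = self.unpack(params)
        lo, hi = self.cutpoints(th)
        eta_fix = self.X @ beta
        if self.q == 0:
            logp, _, _ = _cumlogit_terms(eta_fix, lo, hi)
            return -logp.sum()
        sd = np.exp(log_sd)
        d_inv = np.empty(self.q)
        for t in range(len(self.random_terms)):
            d_inv[self.offsets[t]: self.offsets[t + 1]] = 1.0 / sd[t] ** 2
        u, H, logp_sum = self._inner_newton(eta_fix, lo, hi, d_inv, self._u_warm)
        self._u_warm = u
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        prior = -0.5 * np.sum(d_inv * u**2) - np.sum(
            [self.q_per_term[t] * log_sd[t] for t in range(len(sd))]
        )
        laplace = logp_sum + prior - 0.5 * logdet
        return -laplace

    def start_params(self) -> np.ndarray:
        # empirical cumulative logits as threshold starts
        counts = np.bincount(self.score_idx, minlength=self.n_cat)
        cum = np.cumsum(counts)[:-1] / self.n
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        th = np.log(cum / (1 - cum))
        th = np.maximum.accumulate(th)
        k = self.n_cat - 1
        p = [th[0]]
        if k > 1:
            diffs = np.maximum(np.diff(th), 1e-2)
            p.extend(np.log(diffs))
        p.extend([0.0] * len(self.beta_names))
        p.extend([np.log(0.5)] * len(self.random_terms))
        return np.asarray(p)


def fit_clmm(
    data: LikertDataset,
    random_terms: Sequence[str] = RANDOM_TERMS,
    tol: float = 1e-6,
) -> ClmmFit:
    """Fit the cumulative link mixed model by Laplace-approximated ML.

    With ``random_terms`` empty this reduces to exact ML of the
    fixed-effects proportional-odds model.  Non-convergence is flagged on
    the returned fit, never silent.
    """
    prob = _ClmmProblem(data, random_terms)
    x0 = prob.start_params()
    n_re = len(prob.random_terms)
    bounds = [(None, None)] * (len(x0) - n_re) + [(-6.0, 3.0)] * n_re
    if prob.q == 0:
        res = optimize.minimize(
            prob.neg_marginal_loglik,
            x0,
            jac=prob.neg_loglik_grad_fixed,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
        )
    else:
        res = optimize.minimize(
            prob.neg_marginal_loglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": tol * 1e-2, "gtol": 1e-6},
        )
    th, beta, log_sd = prob.unpack(res.x)
    # covariance of the natural fixed parameters [thresholds, beta] by the
    # delta method through the (theta1, log-diff) parametrization
    k = prob.n_cat - 1
    nb = len(prob.beta_names)

    hess = approx_hess2(res.x, prob.neg_marginal_loglik)
    try:
        vcov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov_all = np.linalg.pinv(hess)
    J = np.zeros((k + nb, len(res.x)))
    J[0, 0] = 1.0
    for j in range(1, k):
        J[j, 0] = 1.0
        for m in range(1, j + 1):
            J[j, m] = np.exp(res.x[m])
    for b in range(nb):
        J[k + b, k + b] = 1.0
    vcov_fixed = J @ vcov_all @ J.T
    # refresh the conditional modes at the optimum (the Hessian sweep above
    # leaves the warm start at a perturbed point)
    prob.neg_marginal_loglik(res.x)

    re_sd = {
        term: float(np.exp(log_sd[t])) for t, term in enumerate(prob.random_terms)
    }
    return ClmmFit(
        thresholds=th,
        beta=beta,
        beta_names=prob.beta_names,
        re_sd=re_sd,
        loglik=float(-res.fun),
        vcov_fixed=vcov_fixed,
        converged=bool(res.success),
        reference_level=prob.reference,
        n_obs=prob.n,
        random_effects={
            term: dict(zip(prob.group_levels[t], prob._u_warm[prob.offsets[t]: prob.offsets[t + 1]]))
            for t, term in enumerate(prob.random_terms)
        },
    )


# ---------------------------------------------------------------------------
# EMMs and Tukey-adjusted contrasts
# ---------------------------------------------------------------------------

def _tukey_mvn_pvalue(z_obs: float, corr: np.ndarray, seed: int, n_draws: int) -> float:
    """P(max_c |Z_c| >= z_obs) for Z ~ MVN(0, corr), seeded Monte Carlo."""
    rng = np.random.default_rng(seed)
    # eigen square root handles the singular contrast covariance
    w, V = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    A = V * np.sqrt(w)
    draws = rng.standard_normal((n_draws, corr.shape[0])) @ A.T
    return float(np.mean(np.max(np.abs(draws), axis=1) >= abs(z_obs)))


def emm_and_tukey(fit: ClmmFit, seed: int = 12345, n_draws: int = 200_000) -> EmmTable:
    """Latent-scale EMMs and Tukey-adjusted pairwise sequence contrasts.

    EMM(level) = beta_level - mean(thresholds) with random effects at
    zero (beta of the reference level is 0).  Contrast inference uses
    Wald z statistics from the fixed-effect covariance; the Tukey
    adjustment is the equicoordinate multivariate-normal probability
    over the full contrast set, evaluated by seeded Monte Carlo.
    """
    if not fit.converged:
        raise ValueError("cannot compute EMMs from a non-converged fit")
    k_th = len(fit.thresholds)
    levels = (fit.reference_level,) + fit.beta_names
    n_lvl = len(levels)
    # linear map from [thresholds, beta] to EMMs
    L = np.zeros((n_lvl, k_th + len(fit.beta)))
    L[:, :k_th] = -1.0 / k_th
    for i in range(1, n_lvl):
        L[i, k_th + i - 1] = 1.0
    est = L @ np.concatenate((fit.thresholds, fit.beta))
    cov = L @ fit.vcov_fixed @ L.T
    se = np.sqrt(np.diag(cov))

    pairs = [(i, j) for i in range(n_lvl) for j in range(i + 1, n_lvl)]
    C = np.zeros((len(pairs), n_lvl))
    for c, (i, j) in enumerate(pairs):
        C[c, i], C[c, j] = 1.0, -1.0
    c_est = C @ est
    c_cov = C @ cov @ C.T
    c_se = np.sqrt(np.diag(c_cov))
    z = c_est / c_se
    corr = c_cov / np.outer(c_se, c_se)
    p_raw = 2 * stats.norm.sf(np.abs(z))
    p_tukey = np.array(
        [
            max(_tukey_mvn_pvalue(zc, corr, seed + c, n_draws), p_raw[c])
            for c, zc in enumerate(z)
        ]
    )
    contrasts = pd.DataFrame(
        {
            "contrast": [f"{levels[i]} - {levels[j]}" for i, j in pairs],
            "estimate": c_est,
            "se": c_se,
            "z": z,
            "p_raw": p_raw,
            "p_tukey": np.clip(p_tukey, 0.0, 1.0),
        }
    )
    return EmmTable(levels=tuple(levels), emm=est, se=se, contrasts=contrasts)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA + Tukey-Kramer
# ---------------------------------------------------------------------------

@dataclass
class RmAnovaResult:
    f_stat: float
    p_value: float
    df_effect: int
    df_error: int
    ms_error: float
    grand_mean: float
    seq_means: pd.Series
    tukey: pd.DataFrame  # columns: contrast, diff, q, p_tukey


def rm_anova_tukey(table: pd.DataFrame) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Tukey-Kramer post hoc tests.

    ``table`` is wide-format: rows = specimens (subjects), columns =
    sequences, cells = the metric value.  The decomposition removes the
    specimen block effect; sequence means are compared with the
    studentized-range distribution on the residual mean square.
    """
    arr = table.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("table has missing cells")
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 specimens and >= 2 sequences")
    grand = arr.mean()
    seq_means = arr.mean(axis=0)
    subj_means = arr.mean(axis=1)
    ss_total = np.sum((arr - grand) ** 2)
    ss_seq = n * np.sum((seq_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_err = ss_total - ss_seq - ss_subj
    df_seq = k - 1
    df_err = (k - 1) * (n - 1)
    ms_seq = ss_seq / df_seq
    ms_err = ss_err / df_err
    if ms_err <= 0:
        f_stat = 0.0 if ms_seq == 0 else np.inf
        p = 1.0 if ms_seq == 0 else 0.0
    else:
        f_stat = ms_seq / ms_err
        p = float(stats.f.sf(f_stat, df_seq, df_err))

    cols = list(table.columns)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = seq_means[i] - seq_means[j]
            if ms_err <= 0:
                q_obs = 0.0 if diff == 0 else np.inf
            else:
                # Tukey-Kramer standard error; balanced here (n per mean)
                q_obs = abs(diff) / np.sqrt(ms_err * (1.0 / n + 1.0 / n) / 2.0)
            p_t = 1.0 if q_obs == 0 else float(stats.studentized_range.sf(q_obs, k, df_err))
            rows.append(
                {
                    "contrast": f"{cols[i]} - {cols[j]}",
                    "diff": diff,
                    "q": q_obs,
                    "p_tukey": min(1.0, p_t),
                }
            )
    return RmAnovaResult(
        f_stat=float(f_stat),
        p_value=p,
        df_effect=df_seq,
        df_error=df_err,
        ms_error=float(ms_err),
        grand_mean=float(grand),
        seq_means=pd.Series(seq_means, index=cols),
        tukey=pd.DataFrame(rows),
    )
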