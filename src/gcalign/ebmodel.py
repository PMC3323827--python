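"""Four-layer empirical Bayes model for peak-matching confidence.

For each reference peak j the model composes four layers:

1. presence — the metabolite is present in the target with probability rho;
2. claiming — given presence status, the probability that the peak claims at
   least one candidate match (indicator Z_j) follows a quadratic-logistic
   function of a neighborhood "competition score" (b_j when absent, b*_j
   when present), with free constants eta0/eta1 for the isolated strata;
3. correctness — a claimed match of a present metabolite is correct (W = 1)
   with probability tau;
4. scores — candidate mixture scores are drawn from a correct-match density
   f_T or an incorrect-match density f_F (normal; optionally a two-component
   normal for f_F), with mu_T < mu_F since correct matches have smaller
   dissimilarity.

The latent (Y, W) are integrated out by EM; the fitted parameters theta-hat
are plugged into the posterior P_jl = P[W_jl = 1 | Z_j = 1, S_j; theta-hat],
the matching confidence used downstream for landmark selection. Only the
minimal-score candidate of a reference peak can be the correct one; all
other candidates are incorrect by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    NotFittedError,
    ParameterError,
)
from .peaks import PeakTable
from .similarity import ScoreMatrix

__all__ = [
    "CompetitionScores",
    "ModelParams",
    "MatchStates",
    "competition_scores",
    "gamma_prob",
    "lambda_prob",
    "score_loglik",
    "match_states",
    "em_fit",
    "match_posteriors",
    "simulate_match_data",
    "EmpiricalBayesMatchModel",
]

_VAR_FLOOR = 1e-6
_B_STAR_ONE_TOL = 1e-12
#: minimum number of incorrect-by-construction (non-best) scores required to
#: estimate the incorrect-score density phi_F freely
_MIN_INCORRECT_OBS = 5


# ---------------------------------------------------------------------------
# competition scores (layer-2 covariates)

@dataclass
class CompetitionScores:
    """Neighborhood-crowding covariates computed within the reference run.

    ``a[k]`` counts reference peaks within score threshold h of peak k
    (including k itself, whose self-score is 0). ``b[j]`` sums 1/a over j's
    neighbors excluding j; ``b_star[j] = b[j] + 1/a[j]`` includes j itself.
    An isolated peak has b = 0 and b_star = 1.
    """

    a: np.ndarray
    b: np.ndarray
    b_star: np.ndarray

    @property
    def n(self) -> int:
        return self.a.size


def competition_scores(
    ref: PeakTable, self_scores: ScoreMatrix, h: Optional[float] = None
) -> CompetitionScores:
    """Compute (a, b, b*) from the reference's self score matrix.

    ``self_scores`` must be the reference scored against itself with the
    same weight/scale as used for matching.
    """
    S = self_scores.S
    if S.shape[0] != S.shape[1] or S.shape[0] != ref.N:
        raise ParameterError("self_scores must be the reference scored against itself")
    h = self_scores.h if h is None else h
    within = S < h  # within[q, k]: I(r_qk < h); diagonal True since r_jj = 0
    a = within.sum(axis=0).astype(float)
    inv_a = 1.0 / a
    # b_j = sum_{k != j} I(r_kj < h) / a_k
    b = (within * inv_a[:, None]).sum(axis=0) - inv_a
    b = np.maximum(b, 0.0)  # guard tiny negative rounding
    return CompetitionScores(a=a, b=b, b_star=b + inv_a)


# ---------------------------------------------------------------------------
# model parameters

@dataclass
class ModelParams:
    """Full parameter vector theta of the four-layer model."""

    rho: float = 0.5
    tau: float = 0.8
    alpha: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beta: tuple[float, float, float] = (0.0, 0.0, 0.0)
    eta0: float = 0.5
    eta1: float = 0.5
    mu_T: float = 0.0
    var_T: float = 1.0
    mu_F: float = 1.0
    var_F: float = 1.0
    # optional second incorrect-match component with weights (pi1, pi2)
    mu_F2: Optional[float] = None
    var_F2: Optional[float] = None
    pi1: float = 1.0

    def __post_init__(self):
        for name in ("rho", "tau", "eta0", "eta1", "pi1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if self.var_T <= 0 or self.var_F <= 0:
            raise ParameterError("variances must be positive")
        if self.mu_F2 is not None and (self.var_F2 is None or self.var_F2 <= 0):
            raise ParameterError("two-component f_F needs a positive var_F2")

    @property
    def pi2(self) -> float:
        return 1.0 - self.pi1

    def mean_F(self) -> float:
        if self.mu_F2 is None:
            return self.mu_F
        return self.pi1 * self.mu_F + self.pi2 * self.mu_F2

    # --- densities -------------------------------------------------------
    def log_f_T(self, s: np.ndarray) -> np.ndarray:
        return _norm_logpdf(s, self.mu_T, self.var_T)

    def log_f_F(self, s: np.ndarray) -> np.ndarray:
        if self.mu_F2 is None:
            return _norm_logpdf(s, self.mu_F, self.var_F)
        with np.errstate(divide="ignore"):
            comp = np.stack(
                [
                    np.log(self.pi1) + _norm_logpdf(s, self.mu_F, self.var_F),
                    np.log(self.pi2) + _norm_logpdf(s, self.mu_F2, self.var_F2),
                ]
            )
        return logsumexp(comp, axis=0)

    # --- serialization ---------------------------------------------------
    def to_text(self) -> str:
        """Flat key=value serialization, exact round trip at 17 digits."""
        lines = []
        for k, v in self._flat_items():
            lines.append(f"{k} = {v!r}")
        return "\n".join(lines) + "\n"

    def _flat_items(self):
        yield "rho", self.rho
        yield "tau", self.tau
        for i, v in enumerate(self.alpha):
            yield f"alpha{i}", v
        for i, v in enumerate(self.beta):
            yield f"beta{i}", v
        yield "eta0", self.eta0
        yield "eta1", self.eta1
        yield "mu_T", self.mu_T
        yield "var_T", self.var_T
        yield "mu_F", self.mu_F
        yield "var_F", self.var_F
        yield "pi1", self.pi1
        if self.mu_F2 is not None:
            yield "mu_F2", self.mu_F2
            yield "var_F2", self.var_F2

    @classmethod
    def from_text(cls, text: str) -> "ModelParams":
        kv: dict[str, float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = float(v.strip())
        return cls(
            rho=kv["rho"],
            tau=kv["tau"],
            alpha=(kv["alpha0"], kv["alpha1"], kv["alpha2"]),
            beta=(kv["beta0"], kv["beta1"], kv["beta2"]),
            eta0=kv["eta0"],
            eta1=kv["eta1"],
            mu_T=kv["mu_T"],
            var_T=kv["var_T"],
            mu_F=kv["mu_F"],
            var_F=kv["var_F"],
            pi1=kv.get("pi1", 1.0),
            mu_F2=kv.get("mu_F2"),
            var_F2=kv.get("var_F2"),
        )


def _norm_logpdf(s, mu, var):
    s = np.asarray(s, dtype=float)
    return -0.5 * (np.log(2.0 * np.pi * var) + (s - mu) ** 2 / var)


def gamma_prob(beta: Sequence[float], b: float | np.ndarray, eta0: float = 0.5):
    """P[Z = 1 | Y = 0] as a function of the competition score b.

    For b > 0 this is the quadratic-logistic
    1 - 1/(1 + exp(beta0 + beta1 b + beta2 b^2)); for the isolated stratum
    b = 0 it is the free constant eta0.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ParameterError("competition score b must be nonnegative")
    lin = beta[0] + beta[1] * b + beta[2] * b * b
    out = _expit(lin)
    out = np.where(b == 0, eta0, out)
    return out if out.ndim else float(out)


def lambda_prob(alpha: Sequence[float], b_star: float | np.ndarray, eta1: float = 0.5):
    """P[Z = 1 | Y = 1] as a function of b*; eta1 on the b* = 1 stratum."""
    b_star = np.asarray(b_star, dtype=float)
    if np.any(b_star < 0):
        raise ParameterError("competition score b* must be nonnegative")
    lin = alpha[0] + alpha[1] * b_star + alpha[2] * b_star * b_star
    out = _expit(lin)
    out = np.where(np.abs(b_star - 1.0) <= _B_STAR_ONE_TOL, eta1, out)
    return out if out.ndim else float(out)


def _expit(x):
    # 1 - 1/(1+exp(x)), computed stably
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def score_loglik(
    scores: np.ndarray, correctness: np.ndarray, params: ModelParams
) -> float:
    """Log of the layer-4 product: f_T for W=1 candidates, f_F for W=0."""
    scores = np.asarray(scores, dtype=float)
    w = np.asarray(correctness, dtype=float)
    return float(np.sum(w * params.log_f_T(scores) + (1.0 - w) * params.log_f_F(scores)))


# ---------------------------------------------------------------------------
# match states

class MatchStates:
    """Per-reference-peak observed matching state and (after fitting)
    posterior responsibilities.

    ``scores[j]`` holds the candidate scores S_jl of reference peak j (empty
    when the peak claims no candidate, i.e. Z_j = 0); ``best[j]`` is the
    index of the minimal-score candidate within ``scores[j]`` (-1 if none);
    ``cand_idx[j]`` optionally maps candidates back to target peak indices.
    """

    def __init__(
        self,
        scores: list[np.ndarray],
        cand_idx: Optional[list[np.ndarray]] = None,
    ):
        self.scores = [np.asarray(s, dtype=float) for s in scores]
        self.cand_idx = cand_idx
        self.z = np.array([s.size > 0 for s in self.scores], dtype=bool)
        self.best = np.array(
            [int(np.argmin(s)) if s.size else -1 for s in self.scores], dtype=int
        )
        self.resp_Y: Optional[np.ndarray] = None
        self.resp_W: Optional[np.ndarray] = None  # posterior for the best candidate

    @property
    def n(self) -> int:
        return len(self.scores)

    def best_scores(self) -> np.ndarray:
        return np.array(
            [s[b] for s, b in zip(self.scores, self.best) if b >= 0], dtype=float
        )

    def best_target_index(self, j: int) -> int:
        if self.best[j] < 0:
            raise KeyError(f"reference peak {j} has no candidates")
        if self.cand_idx is None:
            return int(self.best[j])
        return int(self.cand_idx[j][self.best[j]])


def match_states(sm: ScoreMatrix) -> MatchStates:
    """Build matching states from a reference-vs-target score matrix."""
    scores = [sm.S[j, idx] for j, idx in enumerate(sm.candidates)]
    return MatchStates(scores, cand_idx=list(sm.candidates))


# ---------------------------------------------------------------------------
# EM

def _flatten_z1(states: MatchStates):
    idx_z1 = np.flatnonzero(states.z)
    counts = np.array([states.scores[j].size for j in idx_z1], dtype=int)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    flat = (
        np.concatenate([states.scores[j] for j in idx_z1])
        if idx_z1.size
        else np.empty(0)
    )
    best_flat = offsets + np.array([states.best[j] for j in idx_z1], dtype=int)
    return idx_z1, counts, offsets, flat, best_flat


def _estep(states: MatchStates, comp: CompetitionScores, p: ModelParams):
    """Exact responsibilities over the three feasible joint states per peak.

    Returns (loglik, resp_Y, resp_W) where resp_W is nonzero only for the
    best candidate of each claiming peak.
    """
    n = states.n
    idx_z1, counts, offsets, flat, best_flat = _flatten_z1(states)
    with np.errstate(divide="ignore"):
        log_rho = np.log(p.rho)
        log_1m_rho = np.log1p(-p.rho)
        log_tau = np.log(p.tau)
        log_1m_tau = np.log1p(-p.tau)
        pz0 = gamma_prob(p.beta, comp.b, p.eta0)
        pz1 = lambda_prob(p.alpha, comp.b_star, p.eta1)
        log_pz0 = np.log(pz0)
        log_pz1 = np.log(pz1)

    resp_Y = np.zeros(n)
    resp_W = np.zeros(n)
    ll = 0.0

    if idx_z1.size:
        logfF = p.log_f_F(flat)
        logfT_best = p.log_f_T(flat[best_flat])
        sumF = np.add.reduceat(logfF, offsets)
        lt0 = log_1m_rho + log_pz0[idx_z1] + sumF
        lt10 = log_rho + log_pz1[idx_z1] + log_1m_tau + sumF
        lt11 = log_rho + log_pz1[idx_z1] + log_tau + sumF - logfF[best_flat] + logfT_best
        stack = np.stack([lt0, lt10, lt11])
        ll_j = logsumexp(stack, axis=0)
        if not np.all(np.isfinite(ll_j)):
            raise DegenerateDataError("zero likelihood for a claiming peak")
        resp_Y[idx_z1] = np.exp(np.logaddexp(lt10, lt11) - ll_j)
        resp_W[idx_z1] = np.exp(lt11 - ll_j)
        ll += float(ll_j.sum())

    idx_z0 = np.flatnonzero(~states.z)
    if idx_z0.size:
        L0 = (1.0 - p.rho) * (1.0 - pz0[idx_z0]) + p.rho * (1.0 - pz1[idx_z0])
        if np.any(L0 <= 0):
            raise DegenerateDataError("zero likelihood for a non-claiming peak")
        resp_Y[idx_z0] = p.rho * (1.0 - pz1[idx_z0]) / L0
        ll += float(np.log(L0).sum())

    return ll, resp_Y, resp_W


def _weighted_bernoulli_ll(y, X, w, coef):
    p = _expit(X @ np.asarray(coef))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def _fit_weighted_logistic(y, X, w, coef_old, n_newton: int = 25):
    """Weighted logistic fit by damped Newton (IRLS), warm-started at the
    previous coefficients; keeps the old coefficients unless the new ones
    improve the weighted Bernoulli objective (generalized-EM safety)."""
    mask = w > 1e-10
    if mask.sum() < 3:
        return coef_old
    ys, Xs, ws = y[mask], X[mask], w[mask]
    if np.allclose(ys, ys[0]):
        return coef_old  # separation: MLE diverges, keep previous
    coef = np.asarray(coef_old, dtype=float).copy()
    obj = _weighted_bernoulli_ll(ys, Xs, ws, coef)
    for _ in range(n_newton):
        p = _expit(Xs @ coef)
        grad = Xs.T @ (ws * (ys - p))
        hess_w = ws * p * (1.0 - p)
        H = Xs.T @ (Xs * hess_w[:, None]) + 1e-10 * np.eye(Xs.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # damped line search along the Newton direction
        scale = 1.0
        for _half in range(20):
            cand = coef + scale * step
            obj_new = _weighted_bernoulli_ll(ys, Xs, ws, cand)
            if obj_new >= obj:
                break
            scale *= 0.5
        else:
            break
        if obj_new - obj < 1e-12 * (abs(obj) + 1.0):
            coef, obj = cand, obj_new
            break
        coef, obj = cand, obj_new
    if not np.all(np.isfinite(coef)) or obj < _weighted_bernoulli_ll(
        ys, Xs, ws, np.asarray(coef_old)
    ):
        return coef_old
    return tuple(float(c) for c in coef)


def _kmeans_1d_two(values: np.ndarray, n_iter: int = 100):
    """Deterministic two-cluster split of a 1-D sample (percentile init)."""
    c = np.array([np.percentile(values, 10), np.percentile(values, 90)])
    if c[0] == c[1]:
        return None
    for _ in range(n_iter):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        if assign.min() == assign.max():
            return None
        new = np.array([values[assign == 0].mean(), values[assign == 1].mean()])
        if np.allclose(new, c):
            break
        c = new
    return assign


def _init_params(states: MatchStates, comp: CompetitionScores) -> ModelParams:
    best = states.best_scores()
    others = np.concatenate(
        [np.delete(states.scores[j], states.best[j]) for j in np.flatnonzero(states.z)]
    ) if states.z.any() else np.empty(0)

    # with too little incorrect-score evidence, phi_F starts (and stays)
    # beyond the observed best scores instead of splitting them
    if others.size < _MIN_INCORRECT_OBS:
        mu_T = float(best.mean())
        var_T = float(max(best.var(), _VAR_FLOOR))
        sd = math.sqrt(var_T)
        mu_F = float(best.max()) + 3.0 * sd + 1.0
        var_F = var_T
        return _assemble_init(states, comp, mu_T, var_T, mu_F, var_F, None)

    assign = _kmeans_1d_two(best) if best.size >= 4 else None
    if assign is not None:
        lo, hi = best[assign == 0], best[assign == 1]
        if lo.mean() > hi.mean():
            lo, hi = hi, lo
        # clusters must be separated beyond their own widths, else the split
        # is numerical noise and the fallback init applies
        sep2 = (hi.mean() - lo.mean()) ** 2
        if sep2 <= max(lo.var(), _VAR_FLOOR) + max(hi.var(), _VAR_FLOOR):
            assign = None
    frac_lower = None
    if assign is not None:
        frac_lower = lo.size / best.size
        f_pool = np.concatenate([hi, others]) if others.size else hi
        mu_T, var_T = float(lo.mean()), float(max(lo.var(), _VAR_FLOOR))
        mu_F, var_F = float(f_pool.mean()), float(max(f_pool.var(), _VAR_FLOOR))
    else:
        mu_T = float(best.mean())
        var_T = float(max(best.var(), _VAR_FLOOR))
        if others.size:
            mu_F = float(others.mean())
            var_F = float(max(others.var(), _VAR_FLOOR))
        else:
            mu_F = mu_T + 3.0 * math.sqrt(var_T) + 1.0
            var_F = var_T
    if mu_T >= mu_F:  # degenerate split: push components apart
        mu_F = mu_T + 3.0 * math.sqrt(var_T) + 1.0
    return _assemble_init(states, comp, mu_T, var_T, mu_F, var_F, frac_lower)


def _assemble_init(states, comp, mu_T, var_T, mu_F, var_F, frac_lower):
    m0 = comp.b == 0
    m1 = np.abs(comp.b_star - 1.0) <= _B_STAR_ONE_TOL
    eta0 = float(np.clip(states.z[m0].mean(), 0.01, 0.99)) if m0.any() else 0.5
    eta1 = float(np.clip(states.z[m1].mean(), 0.01, 0.99)) if m1.any() else 0.5
    # method-of-moments starting values: if present metabolites nearly always
    # claim and absent ones rarely do, the claim rate estimates rho and the
    # lower-cluster share among best scores estimates tau
    rho0 = float(np.clip(states.z.mean(), 0.05, 0.95))
    tau0 = float(np.clip(frac_lower, 0.05, 0.95)) if frac_lower is not None else 0.8
    return ModelParams(
        rho=rho0,
        tau=tau0,
        alpha=(0.0, 0.0, 0.0),
        beta=(0.0, 0.0, 0.0),
        eta0=eta0,
        eta1=eta1,
        mu_T=mu_T,
        var_T=var_T,
        mu_F=mu_F,
        var_F=var_F,
    )


def _mstep(
    states: MatchStates,
    comp: CompetitionScores,
    p: ModelParams,
    resp_Y: np.ndarray,
    resp_W: np.ndarray,
    f_F_components: int,
    update_f_F: bool = True,
) -> ModelParams:
    n = states.n
    z = states.z.astype(float)
    idx_z1, counts, offsets, flat, best_flat = _flatten_z1(states)

    rho = float(np.clip(resp_Y.mean(), 1e-12, 1.0 - 1e-12))

    denom = resp_Y[idx_z1].sum()
    tau = float(resp_W[idx_z1].sum() / denom) if denom > 1e-12 else p.tau
    tau = min(max(tau, 0.0), 1.0)

    # strata constants
    w_y0 = 1.0 - resp_Y
    m0 = comp.b == 0
    m1 = np.abs(comp.b_star - 1.0) <= _B_STAR_ONE_TOL
    eta0 = (
        float(np.sum(w_y0[m0] * z[m0]) / np.sum(w_y0[m0]))
        if np.sum(w_y0[m0]) > 1e-12
        else p.eta0
    )
    eta1 = (
        float(np.sum(resp_Y[m1] * z[m1]) / np.sum(resp_Y[m1]))
        if np.sum(resp_Y[m1]) > 1e-12
        else p.eta1
    )

    # logistic layers on the non-degenerate strata
    mb = comp.b > 0
    Xb = np.column_stack([np.ones(mb.sum()), comp.b[mb], comp.b[mb] ** 2])
    beta = _fit_weighted_logistic(z[mb], Xb, w_y0[mb], p.beta)
    # the eta1 stratum is exactly b* = 1; all other peaks follow the logistic
    ms = np.abs(comp.b_star - 1.0) > _B_STAR_ONE_TOL
    Xs = np.column_stack([np.ones(ms.sum()), comp.b_star[ms], comp.b_star[ms] ** 2])
    alpha = _fit_weighted_logistic(z[ms], Xs, resp_Y[ms], p.alpha)

    # score densities
    mu_T, var_T, mu_F, var_F = p.mu_T, p.var_T, p.mu_F, p.var_F
    mu_F2, var_F2, pi1 = p.mu_F2, p.var_F2, p.pi1
    if idx_z1.size:
        wT = resp_W[idx_z1]
        sbest = flat[best_flat]
        if wT.sum() > 1e-12:
            mu_T = float(np.sum(wT * sbest) / wT.sum())
            var_T = float(max(np.sum(wT * (sbest - mu_T) ** 2) / wT.sum(), _VAR_FLOOR))
        wF = np.ones(flat.size)
        wF[best_flat] = 1.0 - wT
        if update_f_F and wF.sum() > 1e-12:
            if f_F_components == 1:
                mu_F = float(np.sum(wF * flat) / wF.sum())
                var_F = float(max(np.sum(wF * (flat - mu_F) ** 2) / wF.sum(), _VAR_FLOOR))
                mu_F2 = var_F2 = None
                pi1 = 1.0
            else:
                mu_F, var_F, mu_F2, var_F2, pi1 = _mstep_f_F_mixture(
                    flat, wF, p
                )

    new = ModelParams(
        rho=rho,
        tau=tau,
        alpha=tuple(alpha),
        beta=tuple(beta),
        eta0=float(np.clip(eta0, 0.0, 1.0)),
        eta1=float(np.clip(eta1, 0.0, 1.0)),
        mu_T=mu_T,
        var_T=var_T,
        mu_F=mu_F,
        var_F=var_F,
        mu_F2=mu_F2,
        var_F2=var_F2,
        pi1=pi1,
    )
    # label-switching guard: correct matches must have the smaller scores
    if new.mu_T > new.mean_F():
        new = replace(
            new,
            mu_T=new.mu_F,
            var_T=new.var_F,
            mu_F=new.mu_T,
            var_F=new.var_T,
            mu_F2=None,
            var_F2=None,
            pi1=1.0,
        )
    return new


def _mstep_f_F_mixture(flat, wF, p: ModelParams):
    """One conditional update of the two-component incorrect-score density."""
    if p.mu_F2 is None:
        # activate the second component by splitting around the mean
        sd = math.sqrt(p.var_F)
        mu1, mu2 = p.mu_F - sd, p.mu_F + sd
        v1 = v2 = p.var_F
        pi1 = 0.5
    else:
        mu1, v1, mu2, v2, pi1 = p.mu_F, p.var_F, p.mu_F2, p.var_F2, p.pi1
    with np.errstate(divide="ignore"):
        l1 = np.log(max(pi1, 1e-300)) + _norm_logpdf(flat, mu1, v1)
        l2 = np.log(max(1 - pi1, 1e-300)) + _norm_logpdf(flat, mu2, v2)
    r1 = np.exp(l1 - np.logaddexp(l1, l2))
    w1 = wF * r1
    w2 = wF * (1.0 - r1)
    if w1.sum() < 1e-12 or w2.sum() < 1e-12:
        return p.mu_F, p.var_F, p.mu_F2, p.var_F2, p.pi1
    mu1n = float(np.sum(w1 * flat) / w1.sum())
    v1n = float(max(np.sum(w1 * (flat - mu1n) ** 2) / w1.sum(), _VAR_FLOOR))
    mu2n = float(np.sum(w2 * flat) / w2.sum())
    v2n = float(max(np.sum(w2 * (flat - mu2n) ** 2) / w2.sum(), _VAR_FLOOR))
    pi1n = float(w1.sum() / (w1.sum() + w2.sum()))
    return mu1n, v1n, mu2n, v2n, pi1n


def em_fit(
    states: MatchStates,
    comp: CompetitionScores,
    init: Optional[ModelParams] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: Optional[int] = None,
    f_F_components: int = 1,
) -> tuple[ModelParams, np.ndarray]:
    """Fit theta by EM; returns fitted parameters and the log-likelihood trace.

    The observed-data log-likelihood is non-decreasing across iterations (to
    numerical slack); iteration stops when its relative change drops below
    ``tol`` or after ``max_iter`` iterations. ``seed`` enables optional
    jittered restarts of the deterministic default initialization.
    """
    if states.n != comp.n:
        raise ParameterError("states and competition scores disagree in length")
    if states.z.sum() < 2:
        raise InsufficientDataError(
            "need at least two reference peaks with a candidate match"
        )
    allscores = np.concatenate([s for s in states.scores if s.size])
    if np.allclose(allscores, allscores[0]):
        raise DegenerateDataError("all candidate scores identical; densities unidentifiable")
    if f_F_components not in (1, 2):
        raise ParameterError("f_F_components must be 1 or 2")
    # non-best candidates are incorrect by construction; without enough of
    # them the incorrect-score density is unidentifiable and ML would overfit
    # by splitting the correct-score distribution, so phi_F stays at its
    # (far-off) initial value
    n_non_best = int(allscores.size - states.z.sum())
    update_f_F = n_non_best >= _MIN_INCORRECT_OBS

    p = init if init is not None else _init_params(states, comp)
    if f_F_components == 2 and p.mu_F2 is None:
        sd = math.sqrt(p.var_F)
        p = replace(p, mu_F2=p.mu_F + sd, var_F2=p.var_F, mu_F=p.mu_F - sd, pi1=0.5)

    trace = []
    ll_prev = None
    for _ in range(max_iter):
        ll, resp_Y, resp_W = _estep(states, comp, p)
        trace.append(ll)
        if ll_prev is not None and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            break
        ll_prev = ll
        p = _mstep(states, comp, p, resp_Y, resp_W, f_F_components, update_f_F)
    states.resp_Y, states.resp_W = resp_Y, resp_W
    return p, np.asarray(trace)


def match_posteriors(
    states: MatchStates, comp: CompetitionScores, params: ModelParams
) -> MatchStates:
    """Fill posterior matching confidences P_jl under fitted parameters.

    For each claiming reference peak the posterior mass sits entirely on its
    minimal-score candidate; non-best candidates get P = 0.
    """
    if params is None:
        raise NotFittedError("model parameters required; fit the model first")
    _, resp_Y, resp_W = _estep(states, comp, params)
    states.resp_Y = resp_Y
    states.resp_W = resp_W
    return states


# ---------------------------------------------------------------------------
# simulation from the generative model (for calibration and testing)

def simulate_match_data(
    params: ModelParams,
    n: int,
    rng: np.random.Generator,
    edge_prob: Optional[float] = None,
    extra_candidate_rate: float = 1.0,
) -> tuple[MatchStates, CompetitionScores, dict]:
    """Draw matching states from the four-layer generative model.

    A random neighbor graph over the n reference peaks supplies the
    competition scores (a = degree + 1, b, b*). Presence, claiming,
    correctness and candidate scores then follow layers 1-4. Returns the
    states, competition scores, and a truth dict with the latent draws.
    """
    if n < 2:
        raise ParameterError("need n >= 2")
    p_edge = edge_prob if edge_prob is not None else 2.0 / n
    # sparse Erdos-Renyi neighbor graph
    n_pairs = n * (n - 1) // 2
    n_edges = rng.binomial(n_pairs, p_edge)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    seen = set()
    while len(seen) < n_edges:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        e = (min(i, j), max(i, j))
        if e in seen:
            continue
        seen.add(e)
        adj[e[0]].add(e[1])
        adj[e[1]].add(e[0])
    deg = np.array([len(adj[i]) for i in range(n)], dtype=float)
    a = deg + 1.0
    b = np.array([sum(1.0 / a[k] for k in adj[j]) for j in range(n)])
    comp = CompetitionScores(a=a, b=b, b_star=b + 1.0 / a)

    Y = rng.random(n) < params.rho
    pz = np.where(
        Y,
        lambda_prob(params.alpha, comp.b_star, params.eta1),
        gamma_prob(params.beta, comp.b, params.eta0),
    )
    Z = rng.random(n) < pz

    scores: list[np.ndarray] = []
    W_designated = np.zeros(n, dtype=bool)
    designated = np.full(n, -1, dtype=int)
    for j in range(n):
        if not Z[j]:
            scores.append(np.empty(0))
            continue
        n_cand = 1 + rng.poisson(extra_candidate_rate)
        s = _sample_f_F(params, n_cand, rng)
        if Y[j]:
            W = rng.random() < params.tau
            W_designated[j] = W
            d = int(rng.integers(0, n_cand))
            designated[j] = d
            if W:
                s[d] = params.mu_T + math.sqrt(params.var_T) * rng.standard_normal()
        scores.append(s)
    states = MatchStates(scores)
    best_is_correct = np.array(
        [
            W_designated[j] and designated[j] == states.best[j]
            for j in range(n)
        ],
        dtype=bool,
    )
    truth = {
        "Y": Y,
        "Z": Z,
        "W_designated": W_designated,
        "designated": designated,
        "best_is_correct": best_is_correct,
    }
    return states, comp, truth


def _sample_f_F(params: ModelParams, size: int, rng: np.random.Generator) -> np.ndarray:
    if params.mu_F2 is None:
        return params.mu_F + math.sqrt(params.var_F) * rng.standard_normal(size)
    which = rng.random(size) < params.pi1
    out = np.where(
        which,
        params.mu_F + math.sqrt(params.var_F) * rng.standard_normal(size),
        params.mu_F2 + math.sqrt(params.var_F2) * rng.standard_normal(size),
    )
    return out


# ---------------------------------------------------------------------------
# estimator facade

class EmpiricalBayesMatchModel(BaseEstimator):
    """Empirical Bayes matching-confidence model (sklearn-style estimator).

    Parameters
    ----------
    tol : float
        Relative log-likelihood convergence tolerance for EM.
    max_iter : int
        Maximum EM iterations.
    f_F_components : int
        1 for a single normal incorrect-score density, 2 for a two-component
        normal mixture.
    seed : int or None
        Reserved for jittered-restart initialization; the default
        initialization is deterministic.
    """

    def __init__(self, tol=1e-8, max_iter=500, f_F_components=1, seed=None):
        self.tol = tol
        self.max_iter = max_iter
        self.f_F_components = f_F_components
        self.seed = seed

    def fit(self, states: MatchStates, comp: CompetitionScores):
        params, trace = em_fit(
            states,
            comp,
            tol=self.tol,
            max_iter=self.max_iter,
            seed=self.seed,
            f_F_components=self.f_F_components,
        )
        self.params_ = params
        self.loglik_trace_ = trace
        self.n_iter_ = len(trace)
        self.converged_ = len(trace) < self.max_iter
        return self

    def predict_proba(
        self, states: MatchStates, comp: CompetitionScores
    ) -> np.ndarray:
        """Posterior matching confidence of each reference peak's best candidate."""
        if not hasattr(self, "params_"):
            raise NotFittedError("call fit before predict_proba")
        st = match_posteriors(states, comp, self.params_)
        return st.resp_W.copy()
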