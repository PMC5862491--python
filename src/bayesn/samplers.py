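"""Gibbs full-conditional updates for the whole-genome regression family.

Reference NumPy implementations of every update, operating on a
:class:`ChainState`, plus an exact-enumeration posterior oracle for tiny
instances. The production engine (``bayesn.engine``) drives numba-compiled
sweep kernels with identical mathematics; these functions are the readable
contract and power the ``backend="python"`` chain.

Conventions
-----------
* Indicator draws integrate out the corresponding effects: single-site
  for delta_j, the whole window's included set for Delta_i. Excluded
  effects are refreshed from their priors so variance updates always
  condition on a full-length alpha vector (all conditionals stay
  conjugate and the dimension is fixed).
* ``ycorr`` is y minus all current fitted terms, maintained incrementally.
* All Bernoulli odds are computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .genome import WindowPartition
from .priors import ModelSpec

__all__ = [
    "ChainState",
    "OracleSpec",
    "init_state",
    "sample_mean",
    "sample_locus_bayesb",
    "sample_locus_variance",
    "sample_window_bayesn",
    "sample_window_variance",
    "sample_ante_locus",
    "sample_t_coefficients",
    "sample_ante_scales",
    "sample_residual_variance",
    "sample_inclusion_probability",
    "enumerate_posterior",
]

_LOGIT_CAP = 35.0


def _bernoulli_logit(logit: float, rng: np.random.Generator) -> int:
    if logit > _LOGIT_CAP:
        return 1
    if logit < -_LOGIT_CAP:
        return 0
    p1 = 1.0 / (1.0 + math.exp(-logit))
    return int(rng.random() < p1)


def _prior_logodds(pi: float) -> float:
    """log[(1-pi)/pi] with saturation at the caps."""
    if pi <= 0.0:
        return _LOGIT_CAP + 1.0
    if pi >= 1.0:
        return -_LOGIT_CAP - 1.0
    return math.log((1.0 - pi) / pi)


@dataclass
class ChainState:
    """All current MCMC values plus the data the updates need."""

    y: np.ndarray
    Z: np.ndarray  # centered, n x m
    zz: np.ndarray  # per-column squared norms
    spec: ModelSpec
    windows: WindowPartition | None

    mu: float = 0.0
    alpha: np.ndarray = None
    delta: np.ndarray = None
    Delta: np.ndarray = None
    sigma2_locus: np.ndarray = None
    sigma2_window: np.ndarray = None
    sigma2_alpha: float = 0.0
    sigma2_e: float = 1.0
    t_coef: np.ndarray = None
    gamma: np.ndarray = None
    lambda_t: np.ndarray = None
    lambda_gamma: np.ndarray = None
    pi_current: float = 1.0
    Pi_current: float = 1.0
    ycorr: np.ndarray = None
    first_of_chrom: np.ndarray = None  # bool per SNP (anteBayesB chains)
    win_offsets: np.ndarray = None  # CSR offsets into SNP order

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    @property
    def nested(self) -> bool:
        return self.spec.method in ("bayesn", "bayesnc")

    @property
    def common_variance(self) -> bool:
        return self.spec.method in ("bayesc", "bayescpi", "bayesnc")

    def locus_slab_var(self, j: int) -> float:
        if self.spec.method in ("bayesc", "bayescpi"):
            return self.sigma2_alpha
        if self.spec.method == "bayesnc":
            return self.sigma2_alpha
        if self.spec.method == "bayesn":
            return self.sigma2_window[self.windows.window_of_snp[j]]
        return self.sigma2_locus[j]

    def window_slab_var(self, i: int) -> float:
        return self.sigma2_alpha if self.common_variance else self.sigma2_window[i]

    def fitted_coefficients(self) -> np.ndarray:
        """u_j = alpha*delta (times the window indicator when nested)."""
        u = self.alpha * self.delta
        if self.nested:
            u = u * self.Delta[self.windows.window_of_snp]
        return u

    def recompute_ycorr(self) -> np.ndarray:
        return self.y - self.mu - self.Z @ self.fitted_coefficients()

    def ycorr_drift(self) -> float:
        return float(np.max(np.abs(self.ycorr - self.recompute_ycorr())))

    def recompute_gamma(self) -> None:
        """gamma_j = alpha_j - t_j alpha_{j-1} (alpha_j on chromosome starts)."""
        g = self.alpha.copy()
        inner = ~self.first_of_chrom
        idx = np.flatnonzero(inner)
        g[idx] = self.alpha[idx] - self.t_coef[idx] * self.alpha[idx - 1]
        self.gamma = g


def init_state(
    y: np.ndarray,
    Z: np.ndarray,
    spec: ModelSpec,
    windows: WindowPartition | None = None,
    marker_map=None,
    start: str = "null",
    rng: np.random.Generator | None = None,
) -> ChainState:
    """Build a consistent starting state (all effects out of the model)."""
    y = np.asarray(y, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    if Z.shape[0] != len(y):
        raise ValueError(
            f"y has {len(y)} records but Z has {Z.shape[0]} rows"
        )
    rng = rng or np.random.default_rng(spec.seed)
    n, m = Z.shape
    st = ChainState(y=y, Z=Z, zz=(Z * Z).sum(axis=0), spec=spec, windows=windows)
    prior_var_alpha = spec.nu_alpha * spec.S_alpha2 / (spec.nu_alpha - 2.0)
    st.alpha = np.zeros(m)
    st.delta = np.zeros(m, dtype=np.int8)
    st.sigma2_locus = np.full(m, prior_var_alpha)
    st.sigma2_alpha = prior_var_alpha
    st.sigma2_e = spec.nu_e * spec.S_e2 / (spec.nu_e - 2.0)
    st.mu = float(np.mean(y)) if spec.fit_intercept else 0.0
    st.pi_current = spec.pi if spec.pi is not None else 1.0
    if windows is not None:
        st.Delta = np.zeros(windows.w, dtype=np.int8)
        st.sigma2_window = np.full(windows.w, prior_var_alpha)
        st.win_offsets = windows.snp_ranges()
        st.Pi_current = spec.Pi if spec.Pi is not None else 1.0
    if spec.method == "antebayesb":
        if marker_map is None:
            st.first_of_chrom = np.zeros(m, dtype=bool)
            st.first_of_chrom[0] = True
        else:
            st.first_of_chrom = np.zeros(m, dtype=bool)
            for _, sl in marker_map.chrom_slices():
                st.first_of_chrom[sl.start] = True
        st.t_coef = np.zeros(m)
        st.lambda_gamma = np.full(
            m, spec.nu_gamma * spec.S_gamma2 / (spec.nu_gamma - 2.0)
        )
        st.lambda_t = np.full(m, spec.nu_t * spec.S_t2 / (spec.nu_t - 2.0))
        st.gamma = np.zeros(m)
    if start == "prior":
        st.alpha = rng.normal(0.0, math.sqrt(prior_var_alpha), size=m)
    st.ycorr = st.recompute_ycorr()
    return st


def sample_mean(state: ChainState, y: np.ndarray, rng: np.random.Generator) -> None:
    """Population mean under a flat prior: N(mean(ycorr)+mu, sigma_e^2/n)."""
    n = state.n
    mu_new = (
        float(np.mean(state.ycorr)) + state.mu
        + rng.normal(0.0, math.sqrt(state.sigma2_e / n))
    )
    state.ycorr += state.mu - mu_new
    state.mu = mu_new


def _locus_update(
    state: ChainState,
    j: int,
    pi: float,
    slab_var: float,
    rng: np.random.Generator,
) -> None:
    """Joint (delta_j, alpha_j) draw with alpha_j integrated out of the odds."""
    z = state.Z[:, j]
    zz = state.zz[j]
    u_old = state.alpha[j] * state.delta[j]
    if zz <= 0.0:  # monomorphic column carries no information
        state.delta[j] = 0
        state.alpha[j] = rng.normal(0.0, math.sqrt(slab_var))
        if u_old != 0.0:
            state.ycorr += z * u_old
        return
    rhs = float(z @ state.ycorr) + zz * u_old
    v = zz * slab_var + state.sigma2_e
    log_bf = 0.5 * (
        math.log(state.sigma2_e / v)
        + rhs * rhs * slab_var / (state.sigma2_e * v)
    )
    d = _bernoulli_logit(_prior_logodds(pi) + log_bf, rng)
    if d:
        mean = rhs * slab_var / v
        alpha_new = mean + rng.normal(0.0, math.sqrt(state.sigma2_e * slab_var / v))
        u_new = alpha_new
    else:
        alpha_new = rng.normal(0.0, math.sqrt(slab_var))
        u_new = 0.0
    if u_new != u_old:
        state.ycorr += z * (u_old - u_new)
    state.alpha[j] = alpha_new
    state.delta[j] = d


def sample_locus_bayesb(
    state: ChainState, j: int, spec: ModelSpec, rng: np.random.Generator
) -> None:
    _locus_update(state, j, state.pi_current, state.locus_slab_var(j), rng)


def sample_locus_variance(
    state: ChainState, j: int, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """sigma_j^2 ~ scaled-inv-chi2(nu+1, (nu S^2 + alpha_j^2)/(nu+1))."""
    scale_sum = spec.nu_alpha * spec.S_alpha2 + state.alpha[j] ** 2
    state.sigma2_locus[j] = scale_sum / rng.chisquare(spec.nu_alpha + 1.0)


def sample_window_bayesn(
    state: ChainState, i: int, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Partially-collapsed window update.

    (a) Delta_i from Bernoulli odds with the currently-included effects
    integrated out (multivariate normal marginal, closed form);
    (b) included effects redrawn jointly from their Gaussian conditional,
    excluded ones from the prior; when Delta_i = 1 every (delta, alpha)
    pair in the window then gets a single-site update with pi_i and the
    window slab variance; when Delta_i = 0 indicators are prior draws.
    """
    o0, o1 = state.win_offsets[i], state.win_offsets[i + 1]
    if o1 <= o0:
        return
    idx = np.arange(o0, o1)
    sig_i = state.window_slab_var(i)
    S = idx[state.delta[idx] == 1]
    if state.Delta[i] == 1 and len(S) > 0:
        r = state.ycorr + state.Z[:, S] @ state.alpha[S]
    else:
        r = state.ycorr.copy()
    if len(S) > 0:
        ZS = state.Z[:, S]
        G = ZS.T @ ZS
        rhs = ZS.T @ r
        A = G + (state.sigma2_e / sig_i) * np.eye(len(S))
        x = np.linalg.solve(A, rhs)
        _, logdet = np.linalg.slogdet(A)
        log_bf = (
            -0.5 * (len(S) * math.log(sig_i / state.sigma2_e) + logdet)
            + 0.5 * float(rhs @ x) / state.sigma2_e
        )
    else:
        log_bf = 0.0
    Pi = state.Pi_current
    d_new = _bernoulli_logit(_prior_logodds(Pi) + log_bf, rng)
    state.Delta[i] = d_new
    if d_new:
        if len(S) > 0:
            L = np.linalg.cholesky(A)
            noise = np.linalg.solve(L.T, rng.standard_normal(len(S)))
            alpha_S = x + math.sqrt(state.sigma2_e) * noise
            state.alpha[S] = alpha_S
            state.ycorr = r - ZS @ alpha_S
        else:
            state.ycorr = r
        out = idx[state.delta[idx] == 0]
        state.alpha[out] = rng.normal(0.0, math.sqrt(sig_i), size=len(out))
        pi_i = float(state.spec.pi_i[i])
        for j in idx:
            _locus_update(state, int(j), pi_i, sig_i, rng)
    else:
        state.ycorr = r
        pi_i = float(state.spec.pi_i[i])
        state.alpha[idx] = rng.normal(0.0, math.sqrt(sig_i), size=len(idx))
        state.delta[idx] = (rng.random(len(idx)) < (1.0 - pi_i)).astype(np.int8)


def sample_window_variance(
    state: ChainState, i: int, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """sigma_i^2 ~ scaled-inv-chi2(nu+m_i, (nu S^2 + sum alpha^2)/(nu+m_i))."""
    o0, o1 = state.win_offsets[i], state.win_offsets[i + 1]
    ss = float(np.sum(state.alpha[o0:o1] ** 2))
    scale_sum = spec.nu_alpha * spec.S_alpha2 + ss
    state.sigma2_window[i] = scale_sum / rng.chisquare(spec.nu_alpha + (o1 - o0))


def sample_ante_locus(
    state: ChainState, j: int, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Joint (delta_j, alpha_j) under first-order antedependence.

    alpha_j = t_j alpha_{j-1} + gamma_j (alpha_1 = gamma_1 per chromosome);
    the odds integrate gamma_j out and include the propagation of alpha_j
    into the successor's conditional prior mean.
    """
    z = state.Z[:, j]
    zz = state.zz[j]
    lam_j = state.lambda_gamma[j]
    prior_mean = (
        0.0 if state.first_of_chrom[j] else state.t_coef[j] * state.alpha[j - 1]
    )
    P0 = 1.0 / lam_j
    b0 = prior_mean / lam_j
    has_next = j + 1 < state.m and not state.first_of_chrom[j + 1]
    if has_next:
        tn = state.t_coef[j + 1]
        ln = state.lambda_gamma[j + 1]
        P0 += tn * tn / ln
        b0 += tn * state.alpha[j + 1] / ln
    u_old = state.alpha[j] * state.delta[j]
    if zz > 0.0:
        rhs = float(z @ state.ycorr) + zz * u_old
        P1 = P0 + zz / state.sigma2_e
        b1 = b0 + rhs / state.sigma2_e
    else:
        P1, b1 = P0, b0
    logit = (
        _prior_logodds(state.pi_current)
        + 0.5 * (b1 * b1 / P1 - b0 * b0 / P0)
        - 0.5 * math.log(P1 / P0)
    )
    d = _bernoulli_logit(logit, rng)
    P, b = (P1, b1) if d else (P0, b0)
    alpha_new = b / P + rng.normal(0.0, math.sqrt(1.0 / P))
    u_new = alpha_new * d
    if u_new != u_old:
        state.ycorr += z * (u_old - u_new)
    state.alpha[j] = alpha_new
    state.delta[j] = d
    state.gamma[j] = alpha_new - prior_mean


def sample_t_coefficients(
    state: ChainState, j: int, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Conjugate normal draw of t_j from alpha_j ~ N(t_j alpha_{j-1}, lam_gj)."""
    if state.first_of_chrom[j]:
        return
    if spec.fix_t_at_zero:
        state.t_coef[j] = 0.0
        return
    a_prev = state.alpha[j - 1]
    P = a_prev * a_prev / state.lambda_gamma[j] + 1.0 / state.lambda_t[j]
    b = a_prev * state.alpha[j] / state.lambda_gamma[j]
    state.t_coef[j] = b / P + rng.normal(0.0, math.sqrt(1.0 / P))


def sample_ante_scales(
    state: ChainState, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """Scale-mixture variances: lambda_gamma and lambda_t conjugate updates."""
    state.recompute_gamma()
    m = state.m
    state.lambda_gamma = (
        spec.nu_gamma * spec.S_gamma2 + state.gamma**2
    ) / rng.chisquare(spec.nu_gamma + 1.0, size=m)
    inner = ~state.first_of_chrom
    lam_t = state.lambda_t.copy()
    lam_t[inner] = (spec.nu_t * spec.S_t2 + state.t_coef[inner] ** 2) / rng.chisquare(
        spec.nu_t + 1.0, size=int(inner.sum())
    )
    state.lambda_t = lam_t


def sample_residual_variance(
    state: ChainState, spec: ModelSpec, rng: np.random.Generator
) -> None:
    """sigma_e^2 ~ scaled-inv-chi2(nu_e+n, (nu_e S_e^2 + ycorr'ycorr)/(nu_e+n))."""
    scale_sum = spec.nu_e * spec.S_e2 + float(state.ycorr @ state.ycorr)
    state.sigma2_e = scale_sum / rng.chisquare(spec.nu_e + state.n)


def sample_inclusion_probability(
    state: ChainState, counts: tuple[int, int], rng: np.random.Generator
) -> float:
    """Beta draw under the uniform prior: Beta(n_zero+1, n_total-n_zero+1)."""
    n_zero, n_total = counts
    if not 0 <= n_zero <= n_total:
        raise ValueError("need 0 <= n_zero <= n_total")
    return float(rng.beta(n_zero + 1.0, n_total - n_zero + 1.0))


# ---------------------------------------------------------------------------
# exact-enumeration oracle


@dataclass
class OracleSpec:
    """Fixed-variance normal-prior configuration for exhaustive enumeration."""

    sigma2: float  # slab variance (common to all effects)
    sigma2_e: float
    pi: float | None = None  # per-SNP exclusion (non-nested)
    pi_i: np.ndarray | None = None  # per-window per-SNP exclusion (nested)
    Pi: float | None = None  # per-window exclusion (nested)
    windows: WindowPartition | None = None
    max_indicators: int = 12


def _log_marginal(y, Z_S, sigma2, sigma2_e):
    """log N(y; 0, sigma2 Z_S Z_S' + sigma2_e I) minus the null's constant."""
    if Z_S.shape[1] == 0:
        return 0.0
    G = Z_S.T @ Z_S
    rhs = Z_S.T @ y
    A = G + (sigma2_e / sigma2) * np.eye(Z_S.shape[1])
    _, logdet = np.linalg.slogdet(A)
    quad = float(rhs @ np.linalg.solve(A, rhs))
    return (
        -0.5 * (Z_S.shape[1] * math.log(sigma2 / sigma2_e) + logdet)
        + 0.5 * quad / sigma2_e
    )


def enumerate_posterior(oracle: OracleSpec, y: np.ndarray, Z: np.ndarray) -> dict:
    """Exact posterior over indicator configurations (tiny instances).

    Every configuration of (Delta, delta) gets its Gaussian marginal
    likelihood (all included effects integrated out) times its prior mass;
    probabilities are normalized. Returns the configuration table plus
    per-SNP and per-window inclusion probabilities.
    """
    y = np.asarray(y, dtype=np.float64)
    Z = np.asarray(Z, dtype=np.float64)
    m = Z.shape[1]
    nested = oracle.windows is not None
    n_ind = m + (oracle.windows.w if nested else 0)
    if n_ind > oracle.max_indicators:
        raise ValueError(
            f"{n_ind} indicators exceed the enumeration limit "
            f"{oracle.max_indicators}"
        )
    def log_bern(p_zero: float, d: int) -> float:
        """log prior of indicator d when P(indicator=0) = p_zero."""
        pr = (1.0 - p_zero) if d else p_zero
        return math.log(pr) if pr > 0.0 else -math.inf

    configs, logws = [], []
    if nested:
        w = oracle.windows.w
        win_of = oracle.windows.window_of_snp
        Pi = oracle.Pi
        pi_i = np.asarray(oracle.pi_i, dtype=np.float64)
        for Delta in product((0, 1), repeat=w):
            lp_D = sum(log_bern(Pi, d) for d in Delta)
            if lp_D == -math.inf:
                continue
            for delta in product((0, 1), repeat=m):
                lp = lp_D + sum(
                    log_bern(pi_i[win_of[j]], dj) for j, dj in enumerate(delta)
                )
                if lp == -math.inf:
                    continue
                S = [
                    j for j in range(m) if delta[j] == 1 and Delta[win_of[j]] == 1
                ]
                lp += _log_marginal(y, Z[:, S], oracle.sigma2, oracle.sigma2_e)
                configs.append((tuple(Delta), tuple(delta)))
                logws.append(lp)
    else:
        pi = oracle.pi
        for delta in product((0, 1), repeat=m):
            lp = sum(log_bern(pi, dj) for dj in delta)
            if lp == -math.inf:
                continue
            S = [j for j in range(m) if delta[j] == 1]
            lp += _log_marginal(y, Z[:, S], oracle.sigma2, oracle.sigma2_e)
            configs.append(((), tuple(delta)))
            logws.append(lp)
    logws = np.asarray(logws)
    logws -= logws.max()
    probs = np.exp(logws)
    probs /= probs.sum()
    incl_snp = np.zeros(m)
    incl_win = np.zeros(oracle.windows.w) if nested else None
    for (Delta, delta), p in zip(configs, probs):
        for j in range(m):
            included = delta[j] == 1 and (
                not nested or Delta[oracle.windows.window_of_snp[j]] == 1
            )
            if included:
                incl_snp[j] += p
        if nested:
            for i, d in enumerate(Delta):
                if d:
                    incl_win[i] += p
    return {
        "configs": configs,
        "prob": probs,
        "incl_prob_snp": incl_snp,
        "incl_prob_window": incl_win,
    }
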