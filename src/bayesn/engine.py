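"""Chain orchestration, posterior summaries, GEBV prediction and metrics.

`run_chain` runs a seeded systematic-scan Gibbs sampler (default backend:
numba-compiled sweep kernels; ``backend="python"`` drives the reference
updates in :mod:`bayesn.samplers`) and accumulates streaming posterior
means — no full trace is retained. Evaluation follows the standard
genomic-prediction conventions: accuracy is the Pearson correlation of
GEBV with true breeding values in the validation set, bias is the OLS
regression slope of TBV on GEBV (1 = unbiased), and window counts track
how many windows/SNPs carry nonzero effects per iteration.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genome import GenotypeMatrix, WindowPartition, center_genotypes
from .priors import ModelSpec
from . import samplers as S

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorSummary",
    "EvalResult",
    "run_chain",
    "predict_gebv",
    "accuracy",
    "bias_slope",
    "window_counts",
    "paired_t_test",
]


@dataclass
class PosteriorSummary:
    """Post-burn-in means, inclusion probabilities and window counts."""

    mean_effect: np.ndarray
    incl_prob_snp: np.ndarray
    incl_prob_window: np.ndarray | None
    mean_n_snps_in: float
    mean_n_windows_in: float | None
    pi_posterior_mean: float | None
    Pi_posterior_mean: float | None
    Pi_posterior_sd: float | None
    mu_mean: float
    sigma2_e_mean: float
    n_samples: int
    spec: ModelSpec = None
    column_means: np.ndarray | None = None
    snp_id: np.ndarray | None = None
    windows: WindowPartition | None = None
    config_counts: Counter | None = None


@dataclass
class EvalResult:
    """Per-replicate accuracies/biases plus cross-replicate aggregates."""

    accuracy: np.ndarray
    bias: np.ndarray
    mean_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)
    mean_bias: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=np.float64)
        self.bias = np.asarray(self.bias, dtype=np.float64)
        self.mean_accuracy = float(np.mean(self.accuracy))
        self.sd_accuracy = float(np.std(self.accuracy, ddof=1)) if len(
            self.accuracy
        ) > 1 else 0.0
        self.mean_bias = float(np.mean(self.bias))


def _prepare(y, Z, spec, windows):
    """Center if needed and fill in derived hyperparameters."""
    y = np.asarray(y, dtype=np.float64)
    column_means = None
    snp_id = None
    if isinstance(Z, GenotypeMatrix):
        if not Z.centered and Z.column_means is None:
            logger.info("genotype matrix not centered; centering now")
            Z = center_genotypes(Z)
        column_means = Z.column_means
        snp_id = Z.map.snp_id if Z.map is not None else None
        scores = Z.scores
    else:
        scores = np.asarray(Z, dtype=np.float64)
        mu_col = scores.mean(axis=0)
        if np.any(np.abs(mu_col) > 1e-8 * max(len(y), 1)):
            logger.info("genotype array not centered; centering now")
            scores = scores - mu_col
            column_means = mu_col
    if scores.shape[0] != len(y):
        raise ValueError(
            f"y has {len(y)} records but Z has {scores.shape[0]} rows"
        )
    needs_derive = (
        spec.S_alpha2 is None
        or spec.S_e2 is None
        or (spec.method in ("bayesn", "bayesnc") and (spec.Pi is None or spec.pi_i is None))
        or (spec.method not in ("bayesn", "bayesnc") and spec.pi is None)
    )
    if needs_derive:
        if column_means is not None:
            p = column_means / 2.0
            poly = (p > 0) & (p < 1)
            pq_bar = float((p * (1 - p))[poly].mean())
        else:
            raise ValueError(
                "cannot calibrate scales: supply a raw/centered GenotypeMatrix "
                "with column means, or a fully-specified ModelSpec"
            )
        m_i = windows.m_i if windows is not None else None
        spec = spec.derived(y, scores.shape[1], m_i, pq_bar)
    return y, np.asfortranarray(scores), spec, column_means, snp_id


def run_chain(
    y,
    Z,
    spec: ModelSpec,
    windows: WindowPartition | None = None,
    marker_map=None,
    seed: int | None = None,
    backend: str = "numba",
    start: str = "null",
    track_configs: bool = False,
    check_every: int = 1000,
    trace_path=None,
    trace_thin: int = 100,
) -> PosteriorSummary:
    """Run the Gibbs chain for the selected method and summarize it.

    A window counts as "in" on an iteration when Delta_i = 1 (BayesN/NC)
    or when any of its SNPs has a nonzero effect (BayesB/anteBayesB).
    ``trace_path`` optionally writes a thinned TSV trace (iteration, mu,
    sigma2_e, pi or Pi, #delta=1, #Delta=1) for diagnostics.
    """
    y, Zf, spec, column_means, snp_id = _prepare(y, Z, spec, windows)
    nested = spec.method in ("bayesn", "bayesnc")
    if nested and windows is None:
        raise ValueError(f"method {spec.method!r} requires a window partition")
    if isinstance(Z, GenotypeMatrix):
        marker_map = marker_map or Z.map
    chain_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(chain_seed)
    py_seed, kern_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
    rng = np.random.default_rng(py_seed)
    use_numba = backend == "numba"
    if use_numba:
        from . import _kernels as K

        K.seed_kernel_rng(kern_seed)

    state = S.init_state(
        y, Zf, spec, windows=windows, marker_map=marker_map, start=start, rng=rng
    )
    n, m = state.n, state.m
    w = windows.w if windows is not None else None
    win_of = windows.window_of_snp if windows is not None else None
    offsets = windows.snp_ranges() if windows is not None else None
    rbuf = np.empty(n)

    sum_u = np.zeros(m)
    sum_incl = np.zeros(m)
    sum_incl_win = np.zeros(w) if windows is not None else None
    sum_wins_in = 0.0
    sum_snps_in = 0.0
    sum_pi = 0.0
    sum_Pi = 0.0
    sum_Pi2 = 0.0
    sum_mu = 0.0
    sum_sige = 0.0
    kept = 0
    configs = Counter() if track_configs else None

    ante = spec.method == "antebayesb"
    common_var = spec.method in ("bayesc", "bayescpi", "bayesnc")

    trace_fh = None
    if trace_path is not None:
        trace_fh = open(trace_path, "w")
        trace_fh.write("iteration\tmu\tsigma2_e\tpi_or_Pi\tn_delta\tn_Delta\n")

    for it in range(spec.chain_length):
        if spec.fit_intercept:
            S.sample_mean(state, y, rng)
        if nested:
            slab_win = (
                np.full(w, state.sigma2_alpha) if common_var else state.sigma2_window
            )
            if use_numba:
                K.bayesn_sweep(
                    Zf,
                    state.zz,
                    state.ycorr,
                    state.alpha,
                    state.delta,
                    state.Delta,
                    offsets,
                    np.asarray(spec.pi_i, dtype=np.float64),
                    state.Pi_current,
                    slab_win,
                    state.sigma2_e,
                    rbuf,
                )
            else:
                if common_var:
                    state.sigma2_window = slab_win
                for i in range(w):
                    S.sample_window_bayesn(state, i, spec, rng)
        elif ante:
            if use_numba:
                K.ante_sweep(
                    Zf,
                    state.zz,
                    state.ycorr,
                    state.alpha,
                    state.delta,
                    state.t_coef,
                    state.lambda_t,
                    state.lambda_gamma,
                    state.first_of_chrom,
                    state.pi_current,
                    state.sigma2_e,
                    not spec.fix_t_at_zero,
                )
            else:
                for j in range(m):
                    S.sample_ante_locus(state, j, spec, rng)
                for j in range(m):
                    S.sample_t_coefficients(state, j, spec, rng)
        else:
            slab = (
                np.full(m, state.sigma2_alpha)
                if common_var
                else state.sigma2_locus
            )
            if use_numba:
                K.bayesb_sweep(
                    Zf,
                    state.zz,
                    state.ycorr,
                    state.alpha,
                    state.delta,
                    slab,
                    state.pi_current,
                    state.sigma2_e,
                )
            else:
                if common_var:
                    state.sigma2_locus = slab
                for j in range(m):
                    S.sample_locus_bayesb(state, j, spec, rng)

        if spec.update_variances:
            if ante:
                S.sample_ante_scales(state, spec, rng)
            elif common_var:
                # common slab variance learns from the included effects only
                # (excluded effects feed no other update in these methods)
                if nested:
                    nz = (state.delta == 1) & (state.Delta[win_of] == 1)
                else:
                    nz = state.delta == 1
                ssq = float(np.sum(state.alpha[nz] ** 2))
                state.sigma2_alpha = (
                    spec.nu_alpha * spec.S_alpha2 + ssq
                ) / rng.chisquare(spec.nu_alpha + int(nz.sum()))
            elif nested:
                ssq = np.add.reduceat(state.alpha**2, offsets[:-1])
                state.sigma2_window = (
                    spec.nu_alpha * spec.S_alpha2 + ssq
                ) / rng.chisquare(spec.nu_alpha + windows.m_i.astype(np.float64))
            else:
                state.sigma2_locus = (
                    spec.nu_alpha * spec.S_alpha2 + state.alpha**2
                ) / rng.chisquare(spec.nu_alpha + 1.0, size=m)
        if spec.update_sigma_e:
            S.sample_residual_variance(state, spec, rng)
        if spec.method == "bayescpi" or (spec.pi_unknown and not nested):
            n_zero = int(m - state.delta.sum())
            state.pi_current = S.sample_inclusion_probability(state, (n_zero, m), rng)
        if nested and spec.Pi_unknown:
            w_zero = int(w - state.Delta.sum())
            state.Pi_current = S.sample_inclusion_probability(state, (w_zero, w), rng)

        if trace_fh is not None and (it + 1) % trace_thin == 0:
            trace_fh.write(
                f"{it + 1}\t{state.mu:.6g}\t{state.sigma2_e:.6g}\t"
                f"{state.Pi_current if nested else state.pi_current:.6g}\t"
                f"{int(state.delta.sum())}\t"
                f"{int(state.Delta.sum()) if nested else ''}\n"
            )

        if (it + 1) % check_every == 0:
            drift = state.ycorr_drift()
            if not np.isfinite(drift):
                raise FloatingPointError(
                    f"NaN in chain state at iteration {it + 1}: "
                    f"sigma_e^2={state.sigma2_e}, mu={state.mu}"
                )
            if drift > 1e-6 * max(1.0, float(np.abs(y).max())):
                logger.warning(
                    "ycorr drift %.3g at iteration %d; recomputing", drift, it + 1
                )
                state.ycorr = state.recompute_ycorr()
            logger.info(
                "iter %d: sigma2_e=%.4f, #delta=%d, #Delta=%s",
                it + 1,
                state.sigma2_e,
                int(state.delta.sum()),
                int(state.Delta.sum()) if nested else "-",
            )

        if it >= spec.burn_in:
            u = state.fitted_coefficients()
            nz = u != 0.0
            sum_u += u
            sum_incl += nz
            sum_snps_in += int(nz.sum())
            if windows is not None:
                if nested:
                    win_in = state.Delta.astype(bool)
                else:
                    win_in = np.zeros(w, dtype=bool)
                    win_in[win_of[nz]] = True
                sum_incl_win += win_in
                sum_wins_in += int(win_in.sum())
            sum_pi += state.pi_current
            sum_Pi += state.Pi_current
            sum_Pi2 += state.Pi_current**2
            sum_mu += state.mu
            sum_sige += state.sigma2_e
            kept += 1
            if track_configs:
                key = (
                    tuple(int(d) for d in (state.Delta if nested else ())),
                    tuple(int(d) for d in state.delta),
                )
                configs[key] += 1

    if trace_fh is not None:
        trace_fh.close()
    Pi_mean = sum_Pi / kept if nested else None
    Pi_sd = (
        math.sqrt(max(0.0, sum_Pi2 / kept - (sum_Pi / kept) ** 2)) if nested else None
    )
    return PosteriorSummary(
        mean_effect=sum_u / kept,
        incl_prob_snp=sum_incl / kept,
        incl_prob_window=(sum_incl_win / kept) if windows is not None else None,
        mean_n_snps_in=sum_snps_in / kept,
        mean_n_windows_in=(sum_wins_in / kept) if windows is not None else None,
        pi_posterior_mean=(
            sum_pi / kept if (spec.method == "bayescpi" or spec.pi_unknown) else None
        ),
        Pi_posterior_mean=Pi_mean,
        Pi_posterior_sd=Pi_sd,
        mu_mean=sum_mu / kept,
        sigma2_e_mean=sum_sige / kept,
        n_samples=kept,
        spec=spec,
        column_means=column_means,
        snp_id=snp_id,
        windows=windows,
        config_counts=configs,
    )


def predict_gebv(summary: PosteriorSummary, Z_new) -> np.ndarray:
    """GEBV = Z_new @ posterior-mean effects.

    Z_new must be centered with the TRAINING column means; a raw
    GenotypeMatrix is centered here using the means stored in the summary.
    """
    if isinstance(Z_new, GenotypeMatrix):
        scores = Z_new.scores
        if not Z_new.centered and Z_new.column_means is None:
            if summary.column_means is None:
                raise ValueError("no training column means available for centering")
            scores = scores - summary.column_means
    else:
        scores = np.asarray(Z_new, dtype=np.float64)
    if scores.shape[1] != len(summary.mean_effect):
        raise ValueError(
            f"SNP set mismatch: model has {len(summary.mean_effect)} SNPs, "
            f"genotypes have {scores.shape[1]}"
        )
    return scores @ summary.mean_effect


def accuracy(gebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation between GEBV and TBV."""
    gebv = np.asarray(gebv, dtype=np.float64)
    tbv = np.asarray(tbv, dtype=np.float64)
    if len(gebv) != len(tbv) or len(gebv) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(gebv) == 0.0 or np.std(tbv) == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.corrcoef(gebv, tbv)[0, 1])


def bias_slope(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """OLS slope of TBV on GEBV; 1 = unbiased, >1 = GEBV biased downward."""
    tbv = np.asarray(tbv, dtype=np.float64)
    gebv = np.asarray(gebv, dtype=np.float64)
    vg = np.var(gebv)
    if vg == 0.0:
        raise ValueError("zero-variance GEBV: slope undefined")
    return float(np.cov(tbv, gebv, ddof=0)[0, 1] / vg)


def window_counts(summary: PosteriorSummary) -> dict:
    """Posterior-mean numbers of windows and SNPs with nonzero effects."""
    return {
        "mean_windows_in": summary.mean_n_windows_in,
        "mean_snps_in": summary.mean_n_snps_in,
    }


def paired_t_test(acc_a, acc_b) -> dict:
    """Two-sided paired t-test on per-replicate accuracy differences."""
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = a - b
    mean_diff = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if math.isclose(mean_diff, 0.0, abs_tol=1e-300):
            return {"t": 0.0, "p": 1.0, "mean_diff": 0.0, "degenerate": True}
        return {
            "t": math.copysign(math.inf, mean_diff),
            "p": 0.0,
            "mean_diff": mean_diff,
            "degenerate": True,
        }
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "mean_diff": mean_diff, "degenerate": False}
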