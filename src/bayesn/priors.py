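"""Hyperparameter calibration for the whole-genome regression mixture models.

Priors of the family: SNP effects are spike-and-slab, point mass at zero
with probability pi (per SNP), pi_i (per SNP within window i) or Pi (per
window), and a t-distributed slab realised as a normal with a scaled
inverse chi-square variance. The calibrators here map interpretable
quantities — assumed QTL count s, SNPs fitted per QTL k, additive variance
V_A, mean allele-frequency product pq_bar — onto the prior constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelSpec",
    "METHODS",
    "compute_pi",
    "compute_window_pi",
    "compute_Pi",
    "compute_snp_scale",
    "expected_t_variance",
    "effective_nonzero_fraction",
    "compute_residual_scale",
]

METHODS = ("bayesb", "bayesc", "bayescpi", "bayesn", "bayesnc", "antebayesb")


def compute_pi(m: int, s: int, k: int) -> float:
    """Prior exclusion probability pi = (m - s*k)/m for s QTL, k SNPs each."""
    if m <= 0:
        raise ValueError("m must be positive")
    if s * k > m:
        raise ValueError(f"s*k = {s * k} exceeds the SNP count m = {m}")
    return (m - s * k) / m


def compute_window_pi(m_i: int, k: int) -> float:
    """Window-specific exclusion probability (m_i - k)/m_i, clamped at 0.

    When a window holds fewer SNPs than k, all of them are eligible
    (a window cannot fit more SNPs than it contains).
    """
    if m_i < 1:
        raise ValueError("m_i must be >= 1")
    return max(0.0, (m_i - k) / m_i)


def compute_Pi(w: int, s: int) -> float:
    """Proportion of windows containing no QTL, (w - s)/w."""
    if s > w:
        raise ValueError(
            f"s = {s} QTL exceed w = {w} windows (at most one QTL per window)"
        )
    return (w - s) / w


def compute_snp_scale(
    V_A: float, pq_bar: float, pi: float, m: int, nu_alpha: float = 4.0
) -> float:
    """Slab scale S_alpha^2 = [V_A / (2 pq_bar (1-pi) m)] (nu-2)/nu.

    Spreads the additive variance V_A over the expected (1-pi)m nonzero
    effects, each contributing 2 p q Var(effect).
    """
    if V_A <= 0 or pq_bar <= 0 or m <= 0:
        raise ValueError("V_A, pq_bar and m must be positive")
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must lie in [0, 1)")
    if nu_alpha <= 2:
        raise ValueError("nu_alpha must exceed 2 for a finite slab variance")
    return V_A / (2.0 * pq_bar * (1.0 - pi) * m) * (nu_alpha - 2.0) / nu_alpha


def expected_t_variance(nu_t: float, S_t2: float) -> float:
    """Prior expectation of a scaled-inv-chi-square variance: nu S^2/(nu-2)."""
    if nu_t <= 2:
        raise ValueError("nu_t must exceed 2 for a finite expected variance")
    if S_t2 < 0:
        raise ValueError("S_t2 must be non-negative")
    return nu_t * S_t2 / (nu_t - 2.0)


def effective_nonzero_fraction(Pi: float, pi_i: float) -> float:
    """(1-Pi)(1-pi_i): prior fraction of SNPs with nonzero effect.

    With pi_i = (m_i-k)/m_i and Pi = (w-s)/w this equals s*k/m whenever
    m_i is constant across windows, matching the single-level pi of the
    non-nested models.
    """
    for p in (Pi, pi_i):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    return (1.0 - Pi) * (1.0 - pi_i)


def compute_residual_scale(V_E: float, nu_e: float = 4.0) -> float:
    """Residual scale S_e^2 = V_E (nu_e-2)/nu_e, so E[sigma_e^2] = V_E."""
    if V_E <= 0:
        raise ValueError("V_E must be positive")
    if nu_e <= 2:
        raise ValueError("nu_e must exceed 2")
    return V_E * (nu_e - 2.0) / nu_e


@dataclass
class ModelSpec:
    """Method selector plus every hyperparameter and chain control.

    Probabilities left as None are derived from (s, k) and the data's
    window structure at fit time; scales left as None are calibrated from
    the phenotypic variance assuming h2 ~ 0.5 unless supplied.
    """

    method: str = "bayesn"
    k: int = 2
    s: int = 300
    pi: float | None = None
    pi_i: np.ndarray | None = None
    Pi: float | None = None
    nu_alpha: float = 4.0
    S_alpha2: float | None = None
    nu_e: float = 4.0
    S_e2: float | None = None
    nu_gamma: float = 4.0
    S_gamma2: float | None = None
    nu_t: float = 4.0
    S_t2: float = 0.1
    pi_unknown: bool = False
    Pi_unknown: bool = False
    chain_length: int = 21_000
    burn_in: int = 1_000
    seed: int = 0
    # numerical/engine controls
    fit_intercept: bool = True
    update_variances: bool = True
    update_sigma_e: bool = True
    fix_t_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; choose from {METHODS}")
        for name in ("nu_alpha", "nu_e", "nu_gamma", "nu_t"):
            if getattr(self, name) <= 2:
                raise ValueError(f"{name} must exceed 2 (finite prior variance)")
        for name in ("pi", "Pi"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("S_alpha2", "S_e2", "S_gamma2", "S_t2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")

    def derived(self, y: np.ndarray, m: int, m_i: np.ndarray | None, pq_bar: float):
        """Fill in pi/pi_i/Pi and the scales from data summaries.

        Returns a new fully-specified ModelSpec; the input is unchanged.
        Starting values of pi/Pi are used for the scale calibration even
        when they are treated as unknown in the chain.
        """
        import copy

        spec = copy.copy(self)
        var_y = float(np.var(y))
        nested = spec.method in ("bayesn", "bayesnc")
        if nested:
            if m_i is None:
                raise ValueError(f"method {spec.method!r} requires a window partition")
            w = len(m_i)
            if spec.Pi is None:
                spec.Pi = compute_Pi(w, spec.s)
            if spec.pi_i is None:
                spec.pi_i = np.array(
                    [compute_window_pi(int(mi), spec.k) for mi in m_i]
                )
            # per-SNP nonzero fraction implied by the nested prior
            frac = (1.0 - spec.Pi) * float(
                np.sum((1.0 - spec.pi_i) * m_i) / np.sum(m_i)
            )
            pi_equiv = min(1.0 - 1e-12, 1.0 - frac)
        else:
            if spec.pi is None:
                spec.pi = compute_pi(m, spec.s, spec.k)
            pi_equiv = spec.pi
        if spec.S_alpha2 is None:
            V_A = var_y / 2.0
            spec.S_alpha2 = compute_snp_scale(
                V_A, pq_bar, min(pi_equiv, 1.0 - 1e-12), m, spec.nu_alpha
            )
        if spec.S_gamma2 is None:
            spec.S_gamma2 = spec.S_alpha2
        if spec.S_e2 is None:
            V_E = var_y / 2.0
            spec.S_e2 = compute_residual_scale(V_E, spec.nu_e)
        return spec
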