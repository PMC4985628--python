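"""Ewens sampling formula: likelihood and MLE of θ (no dispersal limitation).

Under neutral dynamics without dispersal limitation (immigration probability
m = 1), the probability of observing the abundance configuration
``{n_1..n_S}`` in a sample of ``J`` individuals is the Ewens sampling
formula::

    P(D | θ) = J! / (Π_i n_i · Π_a φ_a!) · θ^S / (θ)_J

where ``(θ)_J = θ(θ+1)...(θ+J−1)`` is the rising factorial, ``θ`` the
fundamental biodiversity number, and ``φ_a`` the number of species with
abundance ``a``. The MLE of θ solves the classical score equation
``S = Σ_{k=0}^{J−1} θ/(θ+k)``, whose left side is strictly increasing in θ,
so a bracketing root find is exact and safe.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .community import CommunitySample

__all__ = ["EwensFit", "ewens_log_likelihood", "ewens_mle", "expected_species"]

#: θ search bracket; hitting either end is reported as a boundary (non-converged) fit.
THETA_MIN = 1e-8
THETA_MAX = 1e8


@dataclasses.dataclass(frozen=True)
class EwensFit:
    """Maximum-likelihood Ewens fit.

    ``converged`` is False for boundary cases (S == 1 or S == J), where the
    likelihood is maximized at θ → 0 or θ → ∞ and ``theta_hat`` is capped.
    """

    theta_hat: float
    log_likelihood: float
    converged: bool
    iterations: int
    status: str = "ok"


def log_sad_multiplicity(sad: CommunitySample) -> float:
    """log of the combinatorial prefactor J! / (Π n_i · Π φ_a!).

    Common to the Ewens and Etienne formulas; it counts the orderings of
    individuals consistent with the abundance configuration.
    """
    log_nfac = gammaln(sad.J + 1)
    log_prod_n = float(np.sum(np.log(sad.as_array())))
    log_prod_phi = float(sum(gammaln(c + 1) for c in sad.phi.values()))
    return log_nfac - log_prod_n - log_prod_phi


def ewens_log_likelihood(sad: CommunitySample, theta: float) -> float:
    """Log of the Ewens sampling formula probability of ``sad`` at ``theta``.

    All arithmetic is in log space; the rising factorial is an exact O(J)
    sum of logs.
    """
    if theta <= 0:
        raise ValueError(f"theta must be > 0, got {theta}")
    log_poch = float(np.sum(np.log(theta + np.arange(sad.J))))
    out = log_sad_multiplicity(sad) + sad.S * np.log(theta) - log_poch
    return float(min(out, 0.0))


def _score(theta: float, J: int, S: int) -> float:
    """S − Σ_{k=0}^{J−1} θ/(θ+k); root in θ is the Ewens MLE."""
    k = np.arange(J)
    return S - float(np.sum(theta / (theta + k)))


def expected_species(theta: float, J: int) -> float:
    """Expected species count E[S] = Σ_{k=0}^{J−1} θ/(θ+k) under Ewens."""
    return float(np.sum(theta / (theta + np.arange(J))))


def ewens_mle(sad: CommunitySample, rtol: float = 1e-10) -> EwensFit:
    """Maximum-likelihood estimate of θ for one SAD.

    Solves ``S = Σ_{k=0}^{J−1} θ/(θ+k)`` by safeguarded bracketing on
    ``[THETA_MIN, THETA_MAX]``. ``S == 1`` (likelihood increasing as θ → 0)
    and ``S == J`` (increasing as θ → ∞) are boundary cases: the estimate is
    capped and flagged ``converged=False``.
    """
    J, S = sad.J, sad.S
    if S == 1:
        theta = THETA_MIN
        return EwensFit(theta, ewens_log_likelihood(sad, theta), False, 0, "boundary: S == 1")
    if S == J:
        theta = THETA_MAX
        return EwensFit(theta, ewens_log_likelihood(sad, theta), False, 0, "boundary: S == J")
    # score is positive at tiny theta (sum -> ~1 < S) and negative at huge
    # theta (sum -> J > S), so the bracket is valid whenever 1 < S < J
    iterations = 0

    def score(theta: float) -> float:
        nonlocal iterations
        iterations += 1
        return _score(theta, J, S)

    theta_hat = brentq(score, THETA_MIN, THETA_MAX, rtol=rtol, maxiter=200)
    return EwensFit(
        theta_hat=float(theta_hat),
        log_likelihood=ewens_log_likelihood(sad, float(theta_hat)),
        converged=True,
        iterations=iterations,
    )
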