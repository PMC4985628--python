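"""Sequential-construction sampler for neutral local communities.

The sampler draws one local community of ``J`` individuals under the neutral
model with biodiversity number ``θ`` and immigration parameter ``I`` using
the two-level urn of the sequential construction:

* individual ``j`` (1-based) founds a new immigrant lineage with probability
  ``I/(I + j − 1)`` (taken as 1 for ``j = 1``), otherwise it copies the
  species of a uniformly chosen earlier individual;
* the ``k``-th immigrant lineage takes a brand-new metacommunity species with
  probability ``θ/(θ + k − 1)`` (1 for ``k = 1``), otherwise the species of
  a uniformly chosen earlier lineage.

This yields exact draws from the Etienne sampling distribution (verified
against its closed forms for small J in the test suite), so ensembles of
such draws are the reference distribution of the exact neutrality test.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .community import CommunitySample
from .etienne import (
    LogKSeries,
    NeutralFit,
    etienne_log_likelihood,
    log_k_series,
    m_to_i,
    stirling_log_rows,
)
from .ewens import ewens_log_likelihood

__all__ = [
    "SimulationConfig",
    "Ensemble",
    "simulate_neutral_sample",
    "simulate_ensemble",
]


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a neutral-community simulation run.

    ``n_sim`` defaults to 100, the ensemble size of the exact neutrality
    test. Identical configs (including seed) produce identical output.
    """

    theta: float
    m: float
    J: int
    n_sim: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not 0 < self.m < 1:
            raise ValueError("m must be in (0, 1)")
        if self.J < 1 or self.n_sim < 1:
            raise ValueError("J and n_sim must be >= 1")


def simulate_neutral_sample(
    theta: float,
    I: float,
    J: int,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> CommunitySample:
    """Draw one neutral community SAD of ``J`` individuals at (θ, I).

    ``I`` may be ``math.inf`` (no dispersal limitation: every individual is
    an immigrant, reducing to the Ewens process at θ). O(J) time and memory.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if I < 0:
        raise ValueError("I must be >= 0")
    if J < 1:
        raise ValueError("J must be >= 1")
    u_imm = rng.random(J)
    u_copy = rng.random(J)
    unlimited = math.isinf(I)
    species_of_individual = np.empty(J, dtype=np.int64)
    lineage_species: list[int] = []
    n_species = 0
    u_lin = iter(())
    u_lin_copy = iter(())

    for j in range(J):
        if j == 0 or unlimited or u_imm[j] * (I + j) < I:
            k = len(lineage_species)
            if k == 0:
                new_species = True
            else:
                try:
                    u = next(u_lin)
                except StopIteration:
                    # lineage-level uniforms drawn lazily in blocks of J
                    u_lin = iter(rng.random(J))
                    u_lin_copy = iter(rng.random(J))
                    u = next(u_lin)
                new_species = u * (theta + k) < theta
            if new_species:
                sp = n_species
                n_species += 1
            else:
                sp = lineage_species[int(next(u_lin_copy) * k)]
            lineage_species.append(sp)
        else:
            sp = int(species_of_individual[int(u_copy[j] * j)])
        species_of_individual[j] = sp
    counts = np.bincount(species_of_individual, minlength=n_species)
    return CommunitySample.from_counts(counts, sample_id=sample_id)


@dataclasses.dataclass(frozen=True)
class Ensemble:
    """Artificial datasets simulated at a fitted neutral model, each scored
    with the log-likelihood at the SAME fitted parameters (no refit)."""

    fit: NeutralFit
    samples: tuple[CommunitySample, ...]
    log_likelihoods: np.ndarray
    seed: int

    def __len__(self) -> int:
        return len(self.samples)


def _score_sample(
    sam: CommunitySample, fit: NeutralFit, rows: dict[int, np.ndarray]
) -> float:
    if fit.formula == "ewens":
        return ewens_log_likelihood(sam, fit.theta)
    ks: LogKSeries = log_k_series(sam, rows)
    return etienne_log_likelihood(sam, fit.theta, fit.m, ks)


def simulate_ensemble(
    fit: NeutralFit,
    J: int,
    n_sim: int = 100,
    seed: int = 0,
    refit: bool = False,
) -> Ensemble:
    """Simulate ``n_sim`` neutral communities at a fitted model and score them.

    One root seed is split into per-replicate substreams by replicate index,
    so the ensemble is reproducible and independent of evaluation order.
    Likelihoods are evaluated at the fitted (θ, m) without refitting unless
    ``refit=True``, in which case each artificial dataset is scored at its
    own MLE. Stirling rows are computed in one sweep shared by the whole
    ensemble.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    I = math.inf if fit.formula == "ewens" else fit.I
    streams = np.random.SeedSequence(seed).spawn(n_sim)
    samples = tuple(
        simulate_neutral_sample(
            fit.theta, I, J, np.random.default_rng(streams[r]), sample_id=f"sim_{r:03d}"
        )
        for r in range(n_sim)
    )
    if refit:
        from .etienne import etienne_mle  # local import to avoid cycle at module load

        logls = np.array([etienne_mle(s).log_likelihood for s in samples])
    else:
        needed = {n for s in samples for n in s.phi if n > 1}
        rows = stirling_log_rows(needed)
        logls = np.array([_score_sample(s, fit, rows) for s in samples])
    return Ensemble(fit=fit, samples=samples, log_likelihoods=logls, seed=seed)
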