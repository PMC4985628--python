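"""Batch neutrality survey over an OTU table, and reporting helpers.

:func:`run_survey` runs the full per-sample pipeline — SAD extraction,
Ewens MLE, Etienne MLE, Ewens-vs-Etienne likelihood-ratio test, exact
neutrality test — over every sample of an OTU table, and aggregates
per-site summaries (community counts, NSD counts and percentages, neutral
counts). Per-sample failures (e.g. an all-zero row) are recorded as a row
status and never abort the batch, so large unattended surveys complete.

The per-sample output columns mirror the field's standard reporting: J (the
total number of reads in the sample), S (the number of species in the
sample), θ, m, Log(L0), Log(L1), q-value and p-value.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .community import CommunitySample, OTUTable, sample_to_sad
from .etienne import LARGE_J_GUARD, etienne_mle, log_k_series
from .ewens import ewens_mle
from .neutrality import (
    DEFAULT_ALPHA,
    DEFAULT_N_SIM,
    exact_neutrality_test,
    lrt_from_fits,
)
from .simulate import Ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "SurveyConfig",
    "SurveyResults",
    "run_survey",
    "summarize_counts",
    "export_rank_abundance",
    "rarefy",
]

PER_SAMPLE_COLUMNS = [
    "sample_id",
    "subject_id",
    "body_site",
    "body_location",
    "region",
    "J",
    "S",
    "theta",
    "m",
    "logL0",
    "logL1",
    "lrt_deviance",
    "lrt_p",
    "nsd",
    "q",
    "p",
    "p_empirical",
    "neutral",
    "seed",
    "status",
]


@dataclasses.dataclass(frozen=True)
class SurveyConfig:
    """Survey-wide parameters.

    ``seed`` is the root seed; each sample's exact test gets an independent
    substream, so results do not depend on sample order. ``max_J`` guards
    against accidentally fitting enormous samples (the K-series costs
    O(J·Σn_i)); set ``allow_large=True`` or rarefy to proceed.
    """

    alpha: float = DEFAULT_ALPHA
    n_sim: int = DEFAULT_N_SIM
    seed: int = 0
    variant: str = "chisq"
    max_J: int = LARGE_J_GUARD
    allow_large: bool = False
    rarefy_to: int | None = None


@dataclasses.dataclass(frozen=True)
class SurveyResults:
    """Per-sample rows, per-site summary, and the full run configuration."""

    per_sample: pd.DataFrame
    site_summary: pd.DataFrame
    run_config: dict


def rarefy(sad: CommunitySample, depth: int, rng: np.random.Generator) -> CommunitySample:
    """Subsample a SAD to ``depth`` reads without replacement."""
    if depth >= sad.J:
        return sad
    reads = np.repeat(np.arange(sad.S), sad.as_array())
    keep = rng.choice(reads, size=depth, replace=False)
    counts = np.bincount(keep, minlength=sad.S)
    return CommunitySample.from_counts(counts, sample_id=sad.sample_id)


def run_survey(table: OTUTable, config: SurveyConfig = SurveyConfig()) -> SurveyResults:
    """Fit and test every sample of ``table``; aggregate per-site summaries.

    Deterministic given ``(table, config)``: sample ``i`` uses the ``i``-th
    substream of the root seed for rarefaction and its exact test.
    """
    streams = np.random.SeedSequence(config.seed).spawn(table.n_samples)
    rows = []
    for i, sample_id in enumerate(table.sample_ids):
        md = table.metadata.loc[sample_id]
        row = {
            "sample_id": sample_id,
            "subject_id": md.get("subject_id", "unknown"),
            "body_site": md.get("body_site", "unknown"),
            "body_location": md.get("body_location", "other"),
            "region": md.get("region", "unknown"),
            "seed": int(streams[i].generate_state(1, np.uint32)[0] % 2**31),
            "status": "ok",
        }
        try:
            sad = sample_to_sad(table, sample_id)
            if config.rarefy_to is not None:
                sad = rarefy(
                    sad, config.rarefy_to, np.random.default_rng(streams[i].spawn(1)[0])
                )
            if sad.J > config.max_J and not config.allow_large:
                raise ValueError(
                    f"J={sad.J} exceeds the size guard ({config.max_J}); "
                    "rarefy or set allow_large"
                )
            row.update(_analyze_sample(sad, config, seed=row["seed"]))
        except Exception as exc:  # row-level failure, never aborts the batch
            logger.warning("sample %s failed: %s", sample_id, exc)
            row["status"] = f"failed: {exc}"
        rows.append(row)
        logger.info("sample %s done (%d/%d)", sample_id, i + 1, table.n_samples)
    per_sample = pd.DataFrame(rows).reindex(columns=PER_SAMPLE_COLUMNS)
    summary = summarize_counts(per_sample)
    return SurveyResults(
        per_sample=per_sample,
        site_summary=summary,
        run_config=dataclasses.asdict(config),
    )


def _analyze_sample(sad: CommunitySample, config: SurveyConfig, seed: int) -> dict:
    kseries = log_k_series(sad)
    ew = ewens_mle(sad)
    et = etienne_mle(sad, kseries=kseries)
    lrt = lrt_from_fits(ew, et, alpha=config.alpha, sample_id=sad.sample_id)
    exact = exact_neutrality_test(
        sad,
        n_sim=config.n_sim,
        seed=seed,
        variant=config.variant,
        alpha=config.alpha,
        fit=et,
    )
    return {
        "J": sad.J,
        "S": sad.S,
        "theta": et.theta,
        "m": et.m,
        "logL0": exact.logL_obs,
        "logL1": exact.logL_sim_mean,
        "lrt_deviance": lrt.deviance,
        "lrt_p": lrt.p_value,
        "nsd": lrt.nsd,
        "q": exact.q,
        "p": exact.p_chisq,
        "p_empirical": exact.p_empirical,
        "neutral": exact.neutral,
    }


def summarize_counts(
    per_sample: pd.DataFrame,
    group_keys: tuple[str, ...] = ("body_location", "body_site"),
) -> pd.DataFrame:
    """Group per-sample rows into per-site counts and NSD percentages.

    Percentages are printed with one decimal (round-half-even). Failed rows
    count toward ``n_communities`` but not toward NSD/neutral counts.
    """
    if per_sample.empty:
        raise ValueError("per_sample is empty")
    missing = [k for k in group_keys if k not in per_sample.columns]
    if missing:
        raise KeyError(f"unknown group key(s) {missing}")
    grouped = per_sample.groupby(list(group_keys), sort=True, dropna=False)
    out = grouped.agg(
        n_communities=("sample_id", "count"),
        n_nsd=("nsd", lambda s: int(s.eq(True).sum())),
        n_neutral=("neutral", lambda s: int(s.eq(True).sum())),
    ).reset_index()
    out["pct_nsd"] = np.round(100.0 * out["n_nsd"] / out["n_communities"], 1)
    return out


def export_rank_abundance(
    sad: CommunitySample, ensemble: Ensemble | None = None
) -> pd.DataFrame:
    """Rank-abundance curves: observed sample plus any simulated ensemble.

    One row per (curve, rank): ``curve`` is ``"observed"`` or ``sim_###``,
    ``rank`` runs 1..S in descending abundance, and ``ln_abundance`` is the
    natural log of the abundance at that rank (the conventional axes of a
    rank-abundance plot).
    """
    frames = [_curve_frame("observed", sad)]
    if ensemble is not None:
        frames.extend(
            _curve_frame(sim.sample_id, sim) for sim in ensemble.samples
        )
    return pd.concat(frames, ignore_index=True)


def _curve_frame(label: str, sad: CommunitySample) -> pd.DataFrame:
    ab = sad.as_array()
    return pd.DataFrame(
        {
            "curve": label,
            "rank": np.arange(1, sad.S + 1),
            "abundance": ab,
            "ln_abundance": np.log(ab),
        }
    )
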