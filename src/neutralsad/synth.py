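"""Synthetic OTU tables with known ground truth.

Stands in for real 16S survey tables in tests and examples: per-sample
abundance vectors with read depths J ~ 10²–10⁴ and species counts S ~
10–500, generated either from the neutral model at known (θ, m) — via the
sequential-construction sampler — or from two classical niche SAD models:

* **geometric series** (niche pre-emption): species ``i`` receives expected
  share ``k(1−k)^(i−1)`` (renormalized over the S species), a strongly
  dominance-structured, non-neutral SAD;
* **lognormal**: expected shares proportional to draws from a lognormal in
  log-abundance.

Counts are drawn by a single multinomial of size J per sample, and
zero-count species are dropped, so every generated table satisfies the
OTU-table invariants. Ground-truth parameters are emitted alongside the
table as a truth record. Default parameters are the calibration conditions
used throughout the test suite: neutral (θ=40, m=0.9, J=1000), geometric
(k=0.5, S=11, J=2000), lognormal (σ=1.5, S=100, J=2000).

OTU identity is NOT matched across samples (each sample's species are
arbitrary labels): every statistic implemented here is a per-sample SAD
function, so cross-sample identity would be cosmetic. No sequencing-error,
chimera, or compositional artifacts are emulated.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .community import OTUTable, write_metadata, write_otu_table
from .simulate import simulate_neutral_sample
from .etienne import m_to_i

__all__ = [
    "SyntheticSpec",
    "generate_neutral_table",
    "generate_niche_table",
    "generate_table",
    "write_fixture",
]

_DEFAULT_SITES = ("Stool",)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic OTU table.

    ``generator`` selects the SAD model; only the parameters of that model
    are read. ``body_sites`` are assigned cyclically across samples;
    ``region`` tags every sample.
    """

    n_samples: int = 20
    generator: str = "neutral"
    seed: int = 0
    # neutral parameters
    theta: float = 40.0
    m: float = 0.9
    J: int = 1000
    # geometric niche parameters (dominance k), shares k(1-k)^(i-1) over S species
    k: float = 0.5
    S: int = 11
    # lognormal niche parameters (mean/sd of log abundance)
    lognormal_mean: float = 0.0
    lognormal_sd: float = 1.5
    # metadata template
    body_sites: tuple[str, ...] = _DEFAULT_SITES
    region: str = "V1-V3"
    subject_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.generator not in ("neutral", "geometric", "lognormal"):
            raise ValueError(f"unknown generator {self.generator!r}")
        if self.generator == "neutral":
            if self.theta <= 0 or not 0 < self.m < 1 or self.J < 1:
                raise ValueError("neutral generator needs theta > 0, 0 < m < 1, J >= 1")
        else:
            if self.S < 1 or self.J < 1:
                raise ValueError("niche generators need S >= 1 and J >= 1")
            if self.generator == "geometric" and not 0 < self.k < 1:
                raise ValueError("geometric dominance k must be in (0, 1)")
            if self.generator == "lognormal" and self.lognormal_sd < 0:
                raise ValueError("lognormal sd must be >= 0")


def _expected_shares(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.generator == "geometric":
        shares = spec.k * (1 - spec.k) ** np.arange(spec.S)
    else:  # lognormal
        shares = np.exp(
            rng.normal(spec.lognormal_mean, spec.lognormal_sd, size=spec.S)
        )
    return shares / shares.sum()


def _assemble_table(
    spec: SyntheticSpec, per_sample_counts: list[np.ndarray]
) -> OTUTable:
    """Union per-sample SADs into one wide table; absent OTUs get zeros."""
    sample_ids = [f"{spec.generator}_{i:04d}" for i in range(spec.n_samples)]
    rows = {}
    for sid, counts in zip(sample_ids, per_sample_counts):
        rows[sid] = {f"OTU_{sid}_{j:04d}": int(c) for j, c in enumerate(counts)}
    counts_df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(np.int64)
    counts_df = counts_df[sorted(counts_df.columns)]
    metadata = pd.DataFrame(
        {
            "subject_id": [
                f"{spec.subject_prefix}{i % max(1, spec.n_samples):04d}"
                for i in range(spec.n_samples)
            ],
            "body_site": [
                spec.body_sites[i % len(spec.body_sites)]
                for i in range(spec.n_samples)
            ],
            "region": spec.region,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return OTUTable(counts_df, metadata)


def _truth_record(spec: SyntheticSpec, realized: pd.DataFrame) -> pd.DataFrame:
    base = {"generator": spec.generator, "seed": spec.seed, "J": spec.J}
    if spec.generator == "neutral":
        base.update(theta=spec.theta, m=spec.m, I=m_to_i(spec.m, spec.J))
    elif spec.generator == "geometric":
        base.update(k=spec.k, S=spec.S)
    else:
        base.update(
            lognormal_mean=spec.lognormal_mean,
            lognormal_sd=spec.lognormal_sd,
            S=spec.S,
        )
    truth = realized.copy()
    for key, val in base.items():
        truth[key] = val
    return truth


def generate_neutral_table(spec: SyntheticSpec) -> tuple[OTUTable, pd.DataFrame]:
    """n_samples independent neutral-community draws at (θ, m, J)."""
    if spec.generator != "neutral":
        raise ValueError("spec.generator must be 'neutral'")
    I = m_to_i(spec.m, spec.J)
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_samples)
    counts = []
    realized_S = []
    for i in range(spec.n_samples):
        sad = simulate_neutral_sample(
            spec.theta, I, spec.J, np.random.default_rng(streams[i])
        )
        counts.append(sad.as_array())
        realized_S.append(sad.S)
    table = _assemble_table(spec, counts)
    realized = pd.DataFrame(
        {"sample_id": table.sample_ids, "realized_S": realized_S}
    ).set_index("sample_id")
    return table, _truth_record(spec, realized)


def generate_niche_table(spec: SyntheticSpec) -> tuple[OTUTable, pd.DataFrame]:
    """n_samples draws from a geometric or lognormal niche SAD model."""
    if spec.generator not in ("geometric", "lognormal"):
        raise ValueError("spec.generator must be 'geometric' or 'lognormal'")
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_samples)
    counts = []
    realized_S = []
    for i in range(spec.n_samples):
        rng = np.random.default_rng(streams[i])
        shares = _expected_shares(spec, rng)
        draw = rng.multinomial(spec.J, shares)
        draw = draw[draw > 0]  # zero-count species dropped per sample
        counts.append(np.sort(draw)[::-1])
        realized_S.append(int(draw.size))
    table = _assemble_table(spec, counts)
    realized = pd.DataFrame(
        {"sample_id": table.sample_ids, "realized_S": realized_S}
    ).set_index("sample_id")
    return table, _truth_record(spec, realized)


def generate_table(spec: SyntheticSpec) -> tuple[OTUTable, pd.DataFrame]:
    """Dispatch on ``spec.generator``."""
    if spec.generator == "neutral":
        return generate_neutral_table(spec)
    return generate_niche_table(spec)


def write_fixture(
    table: OTUTable,
    out_dir: str | Path,
    dialect: str = "wide",
    truth: pd.DataFrame | None = None,
    stem: str = "otu_table",
) -> dict[str, Path]:
    """Write an OTU table plus its metadata (and optional truth record) as
    TSVs under ``out_dir``; ``read_otu_table`` inverts the table exactly."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": out_dir / f"{stem}.{dialect}.tsv",
        "metadata": out_dir / f"{stem}.metadata.tsv",
    }
    write_otu_table(table, paths["table"], dialect=dialect)
    write_metadata(table, paths["metadata"])
    if truth is not None:
        paths["truth"] = out_dir / f"{stem}.truth.tsv"
        truth.to_csv(paths["truth"], sep="\t")
    return paths
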