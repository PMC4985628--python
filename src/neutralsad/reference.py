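"""Reference results from a published neutrality survey of the HMP 16S data.

Two kinds of reference tables ship with the package, one pair per 16S
variable region (V1-V3 and V3-V5):

* per-site counts of communities for which the Ewens and Etienne formulas
  made no significant difference (NSD) under the likelihood-ratio test;
* the per-sample parameter tables (J, S, θ, m, log-likelihoods, q, p) of
  the 26 (V1-V3) and 23 (V3-V5) communities — out of 7437 surveyed — that
  passed the exact neutrality test.

These serve as fixed inputs for validating the χ²(1)/likelihood-ratio
machinery and the reporting aggregations against published values; they are
not used by any fitting code.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_nsd_counts", "load_neutral_communities", "REGIONS"]

REGIONS = ("V1-V3", "V3-V5")

_REGION_KEY = {"V1-V3": "v13", "V3-V5": "v35"}


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("neutralsad.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _region_key(region: str) -> str:
    try:
        return _REGION_KEY[region]
    except KeyError:
        raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")


def load_nsd_counts(region: str) -> pd.DataFrame:
    """Per-site community counts and NSD counts for one 16S region."""
    return _load(f"hmp_{_region_key(region)}_nsd_counts.tsv")


def load_neutral_communities(region: str) -> pd.DataFrame:
    """Per-sample parameters of the communities that passed the exact
    neutrality test in one 16S region."""
    df = _load(f"hmp_{_region_key(region)}_neutral_communities.tsv")
    return df.astype(
        {
            "sample_id": str,
            "J": int,
            "S": int,
            "theta": float,
            "m": float,
            "logL0": float,
            "logL1": float,
            "q": float,
            "p": float,
        }
    )
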