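import numpy as np
import pandas as pd
import pytest

from neutralsad import (
    CommunitySample,
    SurveyConfig,
    SyntheticSpec,
    etienne_mle,
    export_rank_abundance,
    generate_table,
    run_survey,
    simulate_ensemble,
    summarize_counts,
)
from neutralsad.reference import load_neutral_communities, load_nsd_counts
from neutralsad.sites import location_for_site


@pytest.fixture(scope="module")
def small_survey():
    spec = SyntheticSpec(
        n_samples=8, generator="neutral", theta=15, m=0.8, J=200, seed=11,
        body_sites=("Stool", "Throat"),
    )
    table, _ = generate_table(spec)
    config = SurveyConfig(n_sim=20, seed=99)
    return table, config, run_survey(table, config)


def test_survey_covers_every_sample_once(small_survey):
    table, _, results = small_survey
    assert list(results.per_sample["sample_id"]) == table.sample_ids
    assert (results.per_sample["status"] == "ok").all()
    assert results.per_sample["J"].eq(200).all()


def test_survey_is_deterministic(small_survey):
    table, config, results = small_survey
    again = run_survey(table, config)
    pd.testing.assert_frame_equal(results.per_sample, again.per_sample)


def test_survey_site_summary_consistency(small_survey):
    _, _, results = small_survey
    s = results.site_summary
    assert s["n_communities"].sum() == len(results.per_sample)
    assert (s["n_nsd"] <= s["n_communities"]).all()
    for _, row in s.iterrows():
        expect = round(100.0 * row["n_nsd"] / row["n_communities"], 1)
        assert row["pct_nsd"] == expect


def test_survey_records_failures_as_row_status():
    counts = pd.DataFrame(
        [[5, 3], [0, 0]], index=["good", "empty"], columns=["o1", "o2"]
    )
    from neutralsad import OTUTable

    results = run_survey(OTUTable(counts), SurveyConfig(n_sim=5, seed=1))
    by_id = results.per_sample.set_index("sample_id")
    assert by_id.loc["good", "status"] == "ok"
    assert by_id.loc["empty", "status"].startswith("failed")


def test_size_guard_fails_row_not_batch():
    counts = pd.DataFrame([[40_000], [5]], index=["big", "ok"], columns=["o1"])
    from neutralsad import OTUTable

    results = run_survey(OTUTable(counts), SurveyConfig(n_sim=5, seed=1))
    by_id = results.per_sample.set_index("sample_id")
    assert "size guard" in by_id.loc["big", "status"]
    assert by_id.loc["ok", "status"] == "ok"


def test_survey_judges_neutral_table_mostly_neutral():
    """A table of genuinely neutral communities is reported mostly neutral
    by the empirical-variant exact test at survey level."""
    spec = SyntheticSpec(
        n_samples=12, generator="neutral", theta=20, m=0.8, J=300, seed=5
    )
    table, _ = generate_table(spec)
    res = run_survey(table, SurveyConfig(n_sim=50, seed=3, variant="empirical"))
    assert (res.per_sample["status"] == "ok").all()
    assert res.per_sample["neutral"].sum() >= 9
    assert res.site_summary["n_neutral"].sum() == res.per_sample["neutral"].sum()


def test_summarize_counts_single_row():
    df = pd.DataFrame(
        [{"sample_id": "x", "body_location": "gut", "body_site": "Stool",
          "nsd": True, "neutral": False}]
    )
    out = summarize_counts(df)
    assert out.loc[0, "n_communities"] == 1
    assert out.loc[0, "pct_nsd"] == 100.0


def test_summarize_counts_unknown_key():
    df = pd.DataFrame([{"sample_id": "x", "body_site": "Stool", "nsd": True,
                        "neutral": True, "body_location": "gut"}])
    with pytest.raises(KeyError):
        summarize_counts(df, group_keys=("habitat",))


def test_published_anterior_nares_nsd_percentage():
    """158 communities with 156 NSD must print as 98.7%."""
    ref = load_nsd_counts("V1-V3").set_index("body_site")
    row = ref.loc["Anterior nares"]
    per_sample = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(row["n_communities"])],
            "body_site": "Anterior nares",
            "body_location": "airways",
            "nsd": [i < row["n_nsd"] for i in range(row["n_communities"])],
            "neutral": False,
        }
    )
    out = summarize_counts(per_sample)
    assert out.loc[0, "pct_nsd"] == 98.7


def test_published_neutral_communities_group_by_location():
    """The passing communities of the published survey aggregate to 21
    urogenital (V1-V3) and 14 skin (V3-V5)."""
    v13 = load_neutral_communities("V1-V3")
    locs13 = v13["body_site"].map(location_for_site).value_counts()
    assert len(v13) == 26 and locs13["urogenital"] == 21
    v35 = load_neutral_communities("V3-V5")
    locs35 = v35["body_site"].map(location_for_site).value_counts()
    assert len(v35) == 23 and locs35["skin"] == 14


def test_rank_abundance_export_values():
    sad = CommunitySample.from_counts([8, 4, 2, 1])
    out = export_rank_abundance(sad)
    assert list(out["rank"]) == [1, 2, 3, 4]
    np.testing.assert_allclose(out["ln_abundance"], np.log([8, 4, 2, 1]))
    assert set(out["curve"]) == {"observed"}


def test_rank_abundance_export_with_ensemble(rng):
    from neutralsad import simulate_neutral_sample

    sad = simulate_neutral_sample(10.0, 20.0, 150, rng)
    fit = etienne_mle(sad)
    ens = simulate_ensemble(fit, sad.J, n_sim=5, seed=2)
    out = export_rank_abundance(sad, ens)
    assert set(out["curve"]) == {"observed"} | {s.sample_id for s in ens.samples}
    for sim in ens.samples:
        curve = out[out["curve"] == sim.sample_id]
        assert len(curve) == sim.S
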