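import numpy as np
import pandas as pd
import pytest

import frailtykit as fk


@pytest.fixture(scope="session")
def catalog():
    return fk.load_default_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Small mixed-kind catalog (permissive size) with a medication map."""
    deficits = (
        fk.DeficitDefinition(id="htn", label="Hypertension", system="cardiovascular",
                             kind="binary", variant_class="physical", source="medication"),
        fk.DeficitDefinition(id="diabetes", label="Diabetes", system="metabolic",
                             kind="binary", variant_class="physical", source="medication"),
        fk.DeficitDefinition(id="anaemia", label="Anaemia", system="laboratory",
                             kind="threshold", threshold=12.0, direction="below",
                             variant_class="physical"),
        fk.DeficitDefinition(id="adl", label="ADL impairment", system="function",
                             kind="ordinal", n_levels=5, variant_class="physical"),
        fk.DeficitDefinition(id="tremor", label="Tremor", system="neurological",
                             kind="binary", variant_class="physical"),
        fk.DeficitDefinition(id="polypharmacy", label="Polypharmacy",
                             system="clinical-measurement", kind="binary",
                             variant_class="physical", source="polypharmacy"),
        fk.DeficitDefinition(id="memory", label="Memory impairment", system="cognition",
                             kind="ordinal", n_levels=3, variant_class="cognitive"),
    )
    med_map = fk.MedicationConditionMap(
        rules={"antihypertensive": "htn", "statin": "htn", "metformin": "diabetes"}
    )
    return fk.DeficitCatalog(
        name="toy", version="1", deficits=deficits, medication_map=med_map
    )


@pytest.fixture(scope="session")
def dementia_trial():
    cfg = fk.preset("dementia", n=1500, seed=101)
    baseline, outcomes, truth = fk.generate_trial(cfg)
    return cfg, baseline, outcomes, truth


@pytest.fixture(scope="session")
def dementia_fi(dementia_trial):
    cfg, baseline, _, _ = dementia_trial
    table = fk.build_fi_table(baseline, cfg.catalog, "physical")
    return table.loc[~table["excluded"], "fi"].to_numpy()


@pytest.fixture(scope="session")
def dementia_model_data(dementia_trial):
    """Merged FI + prepared outcomes + demographics for regression tests."""
    cfg, baseline, outcomes, _ = dementia_trial
    fi_table = fk.build_fi_table(baseline, cfg.catalog, "physical")
    prepared = fk.prepare_outcomes(outcomes, follow_up=cfg.follow_up_days)
    return (
        fi_table.loc[~fi_table["excluded"]]
        .merge(prepared, on="participant_id")
        .merge(baseline[["participant_id", "age_years", "sex"]], on="participant_id")
    )


def two_group_poisson_data(rate_ratio_groups):
    """Saturated two-group person-time dataset: list of (fi, n, events, time)."""
    rows = []
    for fi_val, n, events, t in rate_ratio_groups:
        for i in range(n):
            rows.append({"fi": fi_val, "sae_event": int(i < events),
                         "observation_time": t, "attrition": 0})
    return pd.DataFrame(rows)


def two_group_logistic_data(groups):
    """Two-group binary dataset: list of (fi, n, successes)."""
    rows = []
    for fi_val, n, k in groups:
        for i in range(n):
            rows.append({"fi": fi_val, "attrition": int(i < k), "sae_event": 0,
                         "observation_time": 1.0})
    return pd.DataFrame(rows)
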