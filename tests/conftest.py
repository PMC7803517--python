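import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from keloidcerna.containers import ExpressionMatrix, validate_sample_sheet
from keloidcerna.simulate import (
    SimulationConfig,
    emit_target_table,
    simulate_counts,
    simulate_mirna_array,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_sheet(n_keloid=8, n_control=6):
    """Paired day0/day42 sample sheet for the two-group design."""
    rows = []
    for prefix, group, n in (("K", "keloid", n_keloid), ("N", "control", n_control)):
        for i in range(1, n + 1):
            for tp in ("day0", "day42"):
                rows.append(
                    {"sample_id": f"{prefix}{i}_{tp}", "individual_id": f"{prefix}{i}",
                     "group": group, "timepoint": tp}
                )
    return validate_sample_sheet(pd.DataFrame(rows))


def make_matrix(values, feature_ids, sheet, unit):
    frame = pd.DataFrame(values, index=feature_ids, columns=list(sheet.index))
    return ExpressionMatrix(frame, sheet, unit)


def two_condition_matrix(values, unit="counts", group="keloid"):
    """Features × (n day0 + n day42) matrix within one group, one sample per individual."""
    values = np.asarray(values)
    n = values.shape[1] // 2
    rows = []
    for i in range(values.shape[1]):
        tp = "day0" if i < n else "day42"
        rows.append(
            {"sample_id": f"S{i}", "individual_id": f"I{i % n}",
             "group": group, "timepoint": tp}
        )
    sheet = validate_sample_sheet(pd.DataFrame(rows))
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                         columns=list(sheet.index))
    return ExpressionMatrix(frame, sheet, unit)


@pytest.fixture(scope="session")
def small_config():
    """Reduced feature budget so session-scoped simulations stay fast."""
    return SimulationConfig(n_mrna=600, n_lncrna=120, n_mirna=120, seed=7)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    counts, sheet, biotypes, lengths, truth = simulate_counts(small_config)
    mirna = simulate_mirna_array(small_config, truth)
    targets = emit_target_table(
        truth, seed=small_config.seed,
        mirna_ids=mirna.feature_ids, gene_ids=counts.feature_ids,
    )
    return {
        "config": small_config, "counts": counts, "sheet": sheet,
        "biotypes": biotypes, "lengths": lengths, "truth": truth,
        "mirna": mirna, "targets": targets,
    }
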