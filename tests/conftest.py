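import numpy as np
import pandas as pd
import pytest

from repstrat import RepertoireSet, SimConfig, generate_repertoires


def make_reps(rows, labels):
    """Build a RepertoireSet from (subject, v_call, j_call, cdr3, isotype) tuples."""
    df = pd.DataFrame(rows, columns=["subject_id", "v_call", "j_call", "cdr3_aa", "isotype"])
    df.insert(0, "sequence_id", [f"s{i}" for i in range(len(df))])
    df["chain"] = "heavy"
    return RepertoireSet(df, labels)


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-cohort repertoire with recoverable planted clusters."""
    cfg = SimConfig(
        n_case=10,
        n_control=10,
        seqs_per_subject=300,
        n_planted_clusters=6,
        planted_cluster_size=60,
        planted_purity=0.9,
        seed=11,
    )
    return generate_repertoires(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
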