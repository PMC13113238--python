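import numpy as np
import pandas as pd
import pytest

from mutacc import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def small_config(**overrides):
    """Desk-scale simulation settings shared by the integration tests."""
    defaults = dict(
        n_scaffolds=2,
        scaffold_length=50_000,
        genes_per_scaffold=10,
        n_sublines=12,
        generations=61.75,
        n_sites=1.0e8,
        background_sites=2000,
        cnv_rate=0.01,
        cnv_length_max=10_000,
        seed=7,
    )
    defaults.update(overrides)
    return sim.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    """One small end-to-end simulation reused across tests (read-only)."""
    cfg = sim.SimulationConfig(
        n_scaffolds=2,
        scaffold_length=50_000,
        genes_per_scaffold=10,
        n_sublines=12,
        generations=61.75,
        n_sites=1.0e8,
        background_sites=2000,
        cnv_rate=0.01,
        cnv_length_max=10_000,
        seed=7,
    )
    return sim.run_simulation(cfg)


def make_evidence_row(
    subline="S01",
    scaffold="scaffold_1",
    pos=100,
    counts=None,
    multimap=0,
):
    """One evidence row from a dict like {'A': (6, 6), 'G': (6, 6)}."""
    counts = counts or {}
    row = {"subline_id": subline, "scaffold": scaffold, "pos": pos}
    total = 0
    for base in "ACGT":
        fwd, rev = counts.get(base, (0, 0))
        row[f"count{base}_fwd"] = fwd
        row[f"count{base}_rev"] = rev
        total += fwd + rev
    row["depth"] = total + multimap
    row["multimap_reads"] = multimap
    return row


def evidence_frame(rows):
    from mutacc.simulate import EVIDENCE_COLUMNS

    return pd.DataFrame(rows)[EVIDENCE_COLUMNS]
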