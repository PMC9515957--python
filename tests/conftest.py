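import numpy as np
import pandas as pd
import pytest

from tilseq.repertoire import Repertoire
from tilseq.simulate import SynthConfig, generate_cells, generate_repertoire_set


def make_repertoire(freq_by_aa, sample_id="S1", patient_id="P1", tissue="TUMOR",
                    timepoint=None, total_reads=10_000):
    """Build a productive repertoire from an {aa: frequency} mapping."""
    rows = []
    for i, (aa, f) in enumerate(sorted(freq_by_aa.items())):
        rows.append({"cdr3_nt": f"NT{i:04d}", "cdr3_aa": aa, "v_gene": "V",
                     "j_gene": "J", "read_count": max(int(round(f * total_reads)), 1),
                     "productive": True})
    df = pd.DataFrame(rows)
    df["frequency"] = df["read_count"] / df["read_count"].sum()
    return Repertoire(sample_id, patient_id, tissue, df, timepoint)


@pytest.fixture(scope="session")
def default_truth():
    """One default-condition synthetic study (repertoires + clone truth)."""
    cfg = SynthConfig(seed=11)
    reps, truth = generate_repertoire_set(cfg)
    return cfg, reps, truth


@pytest.fixture(scope="session")
def default_cells(default_truth):
    """Default-condition single-cell data (contigs + expression + truth)."""
    cfg, reps, truth = default_truth
    contigs, adata, truth = generate_cells(cfg, truth)
    return cfg, contigs, adata, truth
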