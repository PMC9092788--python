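import numpy as np
import pandas as pd
import pytest

from metaclone.core import Repertoire, SampleMeta
from metaclone.simulate import SimConfig


def make_repertoire(
    sample_id: str,
    templates,
    cdr3_aa=None,
    rearrangement_nt=None,
    productive=None,
    total_nucleated_cells: int = 1000,
) -> Repertoire:
    """Small hand-built repertoire for unit tests."""
    n = len(templates)
    rows = pd.DataFrame({
        "rearrangement_nt": rearrangement_nt or [f"nt{i}" for i in range(n)],
        "cdr3_aa": cdr3_aa or [f"CASS{i}F" for i in range(n)],
        "templates": templates,
        "productive": productive if productive is not None else [True] * n,
    })
    return Repertoire(
        sample_id=sample_id, rows=rows, total_nucleated_cells=total_nucleated_cells
    )


@pytest.fixture
def small_sim_config():
    """Reduced cohort for fast end-to-end tests."""
    return SimConfig(
        n_tumors=6,
        n_truncal=10,
        private_clone_range=(60, 150),
        n_shared_clones=30,
        n_excluded_clones=3,
        total_nucleated_cells=20000,
        n_background_probes=40,
    )


@pytest.fixture
def four_samples():
    return [
        SampleMeta("P", "primary", is_primary=True, is_thoracic=True,
                   is_left_thoracic=True),
        SampleMeta("M01", "thorax", is_thoracic=True),
        SampleMeta("M02", "left thorax", is_thoracic=True, is_left_thoracic=True),
        SampleMeta("M03", "distant"),
    ]


def random_call_frame(rng: np.random.Generator, samples, mutation_ids):
    """Random caller-call table hitting the filter boundaries on purpose."""
    rows = []
    for s in samples:
        for mid in mutation_ids:
            chrom, pos, ref, alt = mid.split("_")
            for caller in ("mutect", "varscan", "strelka"):
                if rng.random() < 0.65:
                    depth = int(rng.choice([15, 19, 20, 40, 120]))
                    alt_reads = int(rng.choice([2, 3, 4, 10, 30]))
                    alt_reads = min(alt_reads, depth)
                    rows.append({
                        "sample_id": s, "caller": caller, "chrom": chrom,
                        "pos": int(pos), "ref": ref, "alt": alt,
                        "tumor_depth": depth,
                        "normal_depth": int(rng.choice([5, 9, 10, 60])),
                        "tumor_vaf": alt_reads / depth,
                        "normal_vaf": float(rng.choice([0.0, 0.009, 0.01, 0.05])),
                        "alt_reads": alt_reads,
                        "pop_freq_max": float(rng.choice([0.0, 0.009, 0.01, 0.1])),
                        "lod": float(rng.choice([5.0, 9.99, 10.0, 40.0]))
                        if caller == "mutect" else np.nan,
                        "quality": float(rng.choice([20.0, 34.9, 35.0, 60.0]))
                        if caller == "strelka" else np.nan,
                        "effect": "nonsynonymous", "mutation_id": mid,
                    })
    return pd.DataFrame(rows)
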