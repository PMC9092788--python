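"""Mutant-peptide enumeration, MHC binder classification, neoantigen overlap.

Binding affinities are consumed from an external predictor's table (mutation
id, peptide, HLA allele, IC50 in nM).  Classification uses the conventional
thresholds: IC50 < 500 nM is a binder, < 50 nM a strong (high-affinity)
binder; both inequalities strict.  A tumor's neoantigen set is keyed by
mutation id — a mutation codes a predicted neoantigen in a tumor when it is
in that tumor's final consensus set and carries at least one binder peptide.
"""

from __future__ import annotations

import pandas as pd

from .core import classify_ic50
from ._sets import jaccard_matrix

AFFINITY_COLUMNS = ["mutation_id", "peptide", "hla_allele", "ic50_nm"]


def enumerate_mutant_peptides(
    protein_context: str,
    mutant_position: int,
    lengths: tuple[int, ...] = (9, 10),
) -> list[str]:
    """All k-mer windows of the protein context overlapping the mutant residue.

    ``mutant_position`` is 1-based within the context.  A residue far from
    both protein ends yields 9 nine-mers and 10 ten-mers; windows are
    truncated at the context boundaries.
    """
    n = len(protein_context)
    if not 1 <= mutant_position <= n:
        raise ValueError(
            f"mutant position {mutant_position} outside context of length {n}"
        )
    i = mutant_position - 1
    peptides = []
    for k in lengths:
        lo = max(0, i - k + 1)
        hi = min(i, n - k)
        for start in range(lo, hi + 1):
            peptides.append(protein_context[start:start + k])
    return peptides


def classify_binders(
    table: pd.DataFrame, strong_nm: float = 50.0, binder_nm: float = 500.0
) -> pd.DataFrame:
    """Attach ``binder_class`` (strong_binder / binder / non_binder) to an
    affinity table with an ``ic50_nm`` column."""
    if (table["ic50_nm"] <= 0).any():
        raise ValueError("ic50 values must be positive")
    dup = table.duplicated(subset=["mutation_id", "peptide", "hla_allele"])
    if dup.any():
        raise ValueError("duplicate (mutation_id, peptide, hla_allele) rows")
    out = table.copy()
    out["binder_class"] = [
        classify_ic50(v, strong_nm, binder_nm) for v in out["ic50_nm"]
    ]
    return out


def neoantigen_sets(
    classified: pd.DataFrame, final: dict[str, set[str]]
) -> tuple[dict[str, set[str]], dict[str, set[str]], pd.DataFrame]:
    """Per-tumor predicted-neoantigen mutation sets at both thresholds.

    Returns (binder sets, strong-binder sets, counts table).  The counts
    table reports both mutation-level and peptide-level counts per tumor;
    strong counts are always bounded by the 500 nM counts.
    """
    binder_rows = classified[classified["binder_class"] != "non_binder"]
    strong_rows = classified[classified["binder_class"] == "strong_binder"]
    binder_mutations = set(binder_rows["mutation_id"])
    strong_mutations = set(strong_rows["mutation_id"])

    binder_sets, strong_sets, rows = {}, {}, []
    for tumor, muts in final.items():
        binder_sets[tumor] = muts & binder_mutations
        strong_sets[tumor] = muts & strong_mutations
        rows.append({
            "sample_id": tumor,
            "n_neoantigen_mutations": len(binder_sets[tumor]),
            "n_strong_neoantigen_mutations": len(strong_sets[tumor]),
            "n_binder_peptides": int(
                binder_rows["mutation_id"].isin(muts).sum()
            ),
            "n_strong_peptides": int(
                strong_rows["mutation_id"].isin(muts).sum()
            ),
        })
    counts = pd.DataFrame(rows).set_index("sample_id")
    return binder_sets, strong_sets, counts


def neoantigen_jaccard(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise Jaccard matrix of per-tumor neoantigen mutation sets."""
    return jaccard_matrix(sets)
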