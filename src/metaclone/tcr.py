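"""TCR-beta repertoire metrics and cross-tumor overlap analyses.

Three per-sample summaries drive the heterogeneity analysis:

* **density** — productive template count normalized to the total
  nucleated-cell genome equivalents of the sample, an estimate of the
  fraction of cells that are T cells;
* **richness** — number of unique (nucleotide-level) rearrangements, a
  diversity measure;
* **clonality** — one minus Pielou's evenness of the productive clone
  frequency distribution, ``1 + sum_i p_i log2(p_i) / log2(N)``: 0 for a
  perfectly even (polyclonal) repertoire, approaching 1 when a few expanded
  clones dominate (monoclonal).

Overlap analyses (Jaccard index, clonotypes shared across all tumors,
primary-vs-metastasis sharing, spatial exclusion of prevalent clonotypes)
work on nucleotide rearrangements by default and amino-acid CDR3 sequences
where the displayed clonotypes are amino-acid level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Repertoire, SampleMeta
from ._sets import jaccard, jaccard_matrix


@dataclass(frozen=True)
class RepertoireMetrics:
    sample_id: str
    density: float
    richness: int
    clonality: float
    n_productive_templates: int


def density(rep: Repertoire, productive_only: bool = True) -> float:
    """Productive template count / total nucleated-cell equivalents, capped at 1."""
    if rep.total_nucleated_cells <= 0:
        raise ValueError("total_nucleated_cells must be positive")
    rows = rep.productive if productive_only else rep.rows
    d = float(rows["templates"].sum()) / rep.total_nucleated_cells
    if d > 1:
        warnings.warn(
            f"sample {rep.sample_id}: template count exceeds nucleated-cell "
            "denominator; density capped at 1",
            stacklevel=2,
        )
        return 1.0
    return d


def richness(rep: Repertoire, productive_only: bool = True) -> int:
    """Number of distinct nucleotide rearrangements among qualifying rows."""
    rows = rep.productive if productive_only else rep.rows
    return int(rows["rearrangement_nt"].nunique())


def clonality_from_frequencies(p) -> float:
    """``1 + sum_i p_i log2(p_i) / log2(N)`` for a clone-frequency vector.

    The vector must be positive and sum to 1; N is its length.  A single
    clone returns 1 by convention (maximally monoclonal; the evenness
    denominator log2(1) vanishes there).
    """
    p = np.asarray(p, float)
    n = len(p)
    if n == 0:
        raise ValueError("clonality undefined for an empty frequency vector")
    if (p <= 0).any():
        raise ValueError("clone frequencies must be positive")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("clone frequencies must sum to 1")
    if n == 1:
        return 1.0
    entropy = -(p * np.log2(p)).sum()
    return float(1.0 - entropy / np.log2(n))


def clonality(rep: Repertoire) -> float:
    """1 - Pielou's evenness of the productive clone-frequency distribution:
    0 for a perfectly even repertoire, near 1 when a few expanded clones
    dominate.  Computed on productive rearrangements only."""
    p = rep.productive["frequency"].to_numpy(float)
    if len(p) == 0:
        raise ValueError(
            f"clonality undefined for sample {rep.sample_id}: no productive rows"
        )
    return clonality_from_frequencies(p)


def metrics(rep: Repertoire) -> RepertoireMetrics:
    return RepertoireMetrics(
        sample_id=rep.sample_id,
        density=density(rep),
        richness=richness(rep),
        clonality=clonality(rep),
        n_productive_templates=rep.n_productive_templates,
    )


def metrics_table(reps: dict[str, Repertoire]) -> pd.DataFrame:
    rows = [metrics(r) for r in reps.values()]
    return pd.DataFrame(
        [
            {
                "sample_id": m.sample_id, "density": m.density,
                "richness": m.richness, "clonality": m.clonality,
                "n_productive_templates": m.n_productive_templates,
            }
            for m in rows
        ]
    ).set_index("sample_id")


def _clonotype_set(rep: Repertoire, key: str) -> set[str]:
    col = {"nt": "rearrangement_nt", "aa": "cdr3_aa"}.get(key)
    if col is None:
        raise ValueError(f"unknown clonotype key {key!r}; use 'nt' or 'aa'")
    return set(rep.productive[col])


def repertoire_jaccard(a: Repertoire, b: Repertoire, key: str = "nt") -> float:
    """Jaccard index of two repertoires' productive clonotype sets."""
    return jaccard(_clonotype_set(a, key), _clonotype_set(b, key))


def repertoire_jaccard_matrix(reps: dict[str, Repertoire], key: str = "nt") -> pd.DataFrame:
    return jaccard_matrix({s: _clonotype_set(r, key) for s, r in reps.items()})


def top_clonotypes(rep: Repertoire, k: int) -> pd.DataFrame:
    """Top-k amino-acid clonotypes by aggregated productive frequency.

    Nucleotide rearrangements sharing one CDR3 amino-acid sequence are summed
    before ranking; ties rank lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    agg = (
        rep.productive.groupby("cdr3_aa")["frequency"].sum()
        .rename("frequency").reset_index()
        .sort_values(["frequency", "cdr3_aa"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return agg.head(k)


def prevalent_clonotypes(reps: dict[str, Repertoire], k: int = 10) -> set[str]:
    """Union of every sample's top-k amino-acid clonotypes — the candidate
    set for the spatial-exclusion analysis."""
    out: set[str] = set()
    for rep in reps.values():
        out |= set(top_clonotypes(rep, k)["cdr3_aa"])
    return out


def exclusion_report(
    reps: dict[str, Repertoire],
    clonotypes: set[str],
    samples: list[SampleMeta],
    group_flag: str = "is_left_thoracic",
) -> pd.DataFrame:
    """Per-clonotype presence/absence by anatomical group.

    A clonotype is flagged ``excluded`` when it is undetected in one group
    while detected in at least half of the other group's samples — the
    pattern of prevalent clonotypes entirely absent from the left-thoracic
    tumors.  Clonotypes absent from every sample are not reported.
    """
    in_group = {s.sample_id: bool(getattr(s, group_flag)) for s in samples}
    missing = set(reps) - set(in_group)
    if missing:
        raise ValueError(f"samples without metadata/group flag: {sorted(missing)}")
    g1 = [s for s in reps if in_group[s]]
    g0 = [s for s in reps if not in_group[s]]
    presence = {
        s: _clonotype_set(reps[s], "aa") for s in reps
    }
    rows = []
    for ct in sorted(clonotypes):
        det1 = [s for s in g1 if ct in presence[s]]
        det0 = [s for s in g0 if ct in presence[s]]
        if not det1 and not det0:
            continue
        excluded = (
            (len(det1) == 0 and len(det0) >= max(1, len(g0) / 2))
            or (len(det0) == 0 and len(det1) >= max(1, len(g1) / 2))
        )
        rows.append({
            "cdr3_aa": ct,
            "n_detected_group": len(det1),
            "n_detected_other": len(det0),
            "detected_group": ",".join(det1),
            "detected_other": ",".join(det0),
            "excluded": excluded,
            "absent_from": (
                group_flag if not det1 else ("other" if not det0 else "")
            ),
        })
    return pd.DataFrame(
        rows,
        columns=[
            "cdr3_aa", "n_detected_group", "n_detected_other",
            "detected_group", "detected_other", "excluded", "absent_from",
        ],
    )


def shared_across_all(
    reps: dict[str, Repertoire], key: str = "nt"
) -> tuple[set[str], pd.Series, pd.Series]:
    """Clonotypes detected in every sample, with per-sample shared
    proportion (|shared| / richness) and summed productive frequency."""
    if len(reps) < 2:
        raise ValueError("shared_across_all requires at least 2 samples")
    sets = {s: _clonotype_set(r, key) for s, r in reps.items()}
    shared = set.intersection(*sets.values())
    col = {"nt": "rearrangement_nt", "aa": "cdr3_aa"}[key]
    props, freqs = {}, {}
    for s, rep in reps.items():
        rich = len(sets[s])
        props[s] = len(shared) / rich if rich else 0.0
        prod = rep.productive
        freqs[s] = float(prod.loc[prod[col].isin(shared), "frequency"].sum())
    return shared, pd.Series(props, name="proportion"), pd.Series(freqs, name="frequency")


@dataclass(frozen=True)
class PrimaryOverlap:
    n_primary_only: int
    n_met_only: int
    n_shared: int
    shared_proportion_in_met: float
    shared_frequency_in_met: float


def primary_overlap(primary: Repertoire, met: Repertoire, key: str = "nt") -> PrimaryOverlap:
    """Partition of clonotypes into primary-only / metastasis-only / shared,
    with the shared proportion and frequency measured within the metastasis."""
    a = _clonotype_set(primary, key)
    b = _clonotype_set(met, key)
    shared = a & b
    col = {"nt": "rearrangement_nt", "aa": "cdr3_aa"}[key]
    prod = met.productive
    freq = float(prod.loc[prod[col].isin(shared), "frequency"].sum())
    return PrimaryOverlap(
        n_primary_only=len(a - b),
        n_met_only=len(b - a),
        n_shared=len(shared),
        shared_proportion_in_met=(len(shared) / len(b)) if b else 0.0,
        shared_frequency_in_met=freq,
    )
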