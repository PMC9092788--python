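"""Methylation calls and the methylated-neoantigen ratio.

Array beta values strictly above 0.3 are called methylated.  Because the
array does not annotate mutations, probes are assigned to a mutation when
they lie on the same chromosome within a promoter-scale window (default
2,000 bp) of the mutated position; a mutation counts as methylated in a
sample when any assigned probe is methylated (a mean-beta combiner is
available as an alternative).  The per-tumor statistic is the fraction of
probe-covered neoantigen-coding mutations that are methylated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import METHYLATION_BETA_THRESHOLD

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "beta"]


def call_methylated(
    probes: pd.DataFrame, threshold: float = METHYLATION_BETA_THRESHOLD
) -> pd.DataFrame:
    """Attach the ``methylated`` flag: beta strictly above the threshold."""
    if len(probes) and ((probes["beta"] < 0) | (probes["beta"] > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    out = probes.copy()
    out["methylated"] = probes["beta"] > threshold if len(probes) else pd.Series(dtype=bool)
    return out


def map_probes_to_mutations(
    probes: pd.DataFrame,
    mutation_positions: pd.DataFrame,
    window_bp: int = 2000,
) -> dict[str, list[str]]:
    """Assign probes to mutations: same chromosome, |probe - mutation| <= window.

    ``mutation_positions`` needs columns ``mutation_id``, ``chrom``, ``pos``.
    Returns mutation_id -> list of probe ids (empty list = no coverage).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom = {c: g for c, g in probes.groupby("chrom")} if len(probes) else {}
    out: dict[str, list[str]] = {}
    for row in mutation_positions.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            out[row.mutation_id] = []
            continue
        near = g[(g["pos"] - row.pos).abs() <= window_bp]
        out[row.mutation_id] = list(near["probe_id"])
    return out


def mutation_methylation_state(
    probes_called: pd.DataFrame,
    probe_map: dict[str, list[str]],
    combiner: str = "any",
    threshold: float = METHYLATION_BETA_THRESHOLD,
) -> dict[str, bool | None]:
    """Per-mutation methylation state; None when no probe covers the mutation.

    ``any`` calls a mutation methylated when any assigned probe is; ``mean``
    thresholds the mean beta of assigned probes instead.
    """
    by_id = probes_called.set_index("probe_id")
    out: dict[str, bool | None] = {}
    for mut, probe_ids in probe_map.items():
        if not probe_ids:
            out[mut] = None
        elif combiner == "any":
            out[mut] = bool(by_id.loc[probe_ids, "methylated"].any())
        elif combiner == "mean":
            out[mut] = bool(by_id.loc[probe_ids, "beta"].mean() > threshold)
        else:
            raise ValueError(f"unknown combiner {combiner!r}")
    return out


@dataclass(frozen=True)
class MethylatedNeoantigenRatio:
    sample_id: str
    ratio: float | None
    n_covered: int
    n_methylated: int
    flagged: bool = False


def methylated_neoantigen_ratio(
    sample_id: str,
    probes: pd.DataFrame,
    neo_mutations: set[str],
    mutation_positions: pd.DataFrame,
    window_bp: int = 2000,
    combiner: str = "any",
) -> MethylatedNeoantigenRatio:
    """Fraction of a tumor's probe-covered neoantigen-coding mutations that
    are methylated.  Mutations without probe coverage are excluded from both
    numerator and denominator; a zero denominator yields ratio None with the
    sample flagged."""
    pos = mutation_positions[mutation_positions["mutation_id"].isin(neo_mutations)]
    called = call_methylated(probes)
    states = mutation_methylation_state(
        called, map_probes_to_mutations(called, pos, window_bp), combiner
    )
    covered = {m: s for m, s in states.items() if s is not None}
    if not covered:
        return MethylatedNeoantigenRatio(sample_id, None, 0, 0, flagged=True)
    n_meth = sum(covered.values())
    return MethylatedNeoantigenRatio(
        sample_id, n_meth / len(covered), len(covered), n_meth
    )


def ratio_table(
    probes_by_sample: dict[str, pd.DataFrame],
    neo_sets: dict[str, set[str]],
    mutation_positions: pd.DataFrame,
    window_bp: int = 2000,
    combiner: str = "any",
) -> pd.DataFrame:
    rows = []
    for s, probes in probes_by_sample.items():
        r = methylated_neoantigen_ratio(
            s, probes, neo_sets.get(s, set()), mutation_positions, window_bp, combiner
        )
        rows.append({
            "sample_id": r.sample_id, "methylated_neoantigen_ratio": r.ratio,
            "n_covered": r.n_covered, "n_methylated": r.n_methylated,
            "flagged": r.flagged,
        })
    return pd.DataFrame(rows).set_index("sample_id")
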