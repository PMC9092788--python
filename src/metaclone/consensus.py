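"""Multi-caller somatic-mutation consensus with cross-tumor rescue.

The calling strategy mirrors standard FFPE multi-region practice: each tumor
is called by MuTect, VarScan2 and Strelka2 independently; per-call evidence
filters remove weakly supported or likely-germline variants; a mutation is
accepted in a tumor when at least two callers report it after filtering; and
a mutation rejected by the two-caller rule in one tumor is rescued there when
the same mutation is observed (accepted or rejected) in at least two tumors,
since recurrence across independent tumors is itself strong evidence.

Boundary semantics are literal: ">=" thresholds are inclusive, "<"/"below"
thresholds exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CALLERS, GERMLINE_LABEL, MutationMatrix


@dataclass(frozen=True)
class FilterConfig:
    """Evidence thresholds for the per-call filters and consensus rules.

    Defaults are the study's printed criteria: tumor depth >= 20x, germline
    depth >= 10x, tumor VAF >= 0.02, germline VAF < 0.01, >= 4 supporting
    reads, population frequency < 0.01, MuTect LOD >= 10, Strelka quality
    >= 35, two-caller consensus, rescue when shared by >= 2 tumors.
    """

    min_tumor_depth: int = 20
    min_normal_depth: int = 10
    min_tumor_vaf: float = 0.02
    max_normal_vaf: float = 0.01
    min_alt_reads: int = 4
    max_pop_freq: float = 0.01
    min_lod: float = 10.0
    min_quality: float = 35.0
    min_callers: int = 2
    rescue_min_tumors: int = 2

    def __post_init__(self):
        numeric = {k: v for k, v in asdict(self).items()}
        bad = [k for k, v in numeric.items() if v <= 0]
        if bad:
            raise ValueError(f"FilterConfig thresholds must be positive: {bad}")
        if self.min_callers > len(CALLERS):
            raise ValueError("min_callers cannot exceed the number of callers")


# reason codes attached to failing calls
_BASE_CRITERIA = (
    ("low_tumor_depth", lambda df, c: df["tumor_depth"] >= c.min_tumor_depth),
    ("low_normal_depth", lambda df, c: df["normal_depth"] >= c.min_normal_depth),
    ("low_tumor_vaf", lambda df, c: df["tumor_vaf"] >= c.min_tumor_vaf),
    ("high_normal_vaf", lambda df, c: df["normal_vaf"] < c.max_normal_vaf),
    ("few_alt_reads", lambda df, c: df["alt_reads"] >= c.min_alt_reads),
    ("common_in_population", lambda df, c: df["pop_freq_max"] < c.max_pop_freq),
)


def apply_base_filters(
    calls: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition calls into (pass, fail); failing rows carry every violated
    criterion in a ``fail_reasons`` column (semicolon-joined)."""
    cfg = cfg or FilterConfig()
    if calls.empty:
        empty = calls.copy()
        fail = calls.copy()
        fail["fail_reasons"] = pd.Series(dtype=str)
        return empty, fail
    ok = np.ones(len(calls), dtype=bool)
    reasons = [[] for _ in range(len(calls))]
    for code, pred in _BASE_CRITERIA:
        passed = pred(calls, cfg).to_numpy()
        ok &= passed
        for i in np.flatnonzero(~passed):
            reasons[i].append(code)
    passed_df = calls[ok].copy()
    failed_df = calls[~ok].copy()
    failed_df["fail_reasons"] = [";".join(r) for r, k in zip(reasons, ok) if not k]
    return passed_df, failed_df


def apply_caller_filters(
    calls: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply caller-specific score filters.

    MuTect calls with LOD < ``min_lod`` and Strelka calls with quality below
    ``min_quality`` fail; VarScan calls pass unchanged.  A MuTect call with a
    missing LOD (or Strelka call with missing quality) is an input error.
    """
    cfg = cfg or FilterConfig()
    if calls.empty:
        fail = calls.copy()
        fail["fail_reasons"] = pd.Series(dtype=str)
        return calls.copy(), fail
    is_mutect = (calls["caller"] == "mutect").to_numpy()
    is_strelka = (calls["caller"] == "strelka").to_numpy()
    lod = calls["lod"].to_numpy(float)
    qual = calls["quality"].to_numpy(float)
    if np.isnan(lod[is_mutect]).any():
        raise ValueError("mutect call missing required lod score")
    if np.isnan(qual[is_strelka]).any():
        raise ValueError("strelka call missing required quality score")
    ok = np.ones(len(calls), dtype=bool)
    reasons = np.array([""] * len(calls), dtype=object)
    low_lod = is_mutect & (lod < cfg.min_lod)
    low_q = is_strelka & (qual < cfg.min_quality)
    ok &= ~(low_lod | low_q)
    reasons[low_lod] = "low_lod"
    reasons[low_q] = "low_quality"
    passed_df = calls[ok].copy()
    failed_df = calls[~ok].copy()
    failed_df["fail_reasons"] = reasons[~ok]
    return passed_df, failed_df


def consensus_per_tumor(
    caller_sets: dict[str, set[str]], cfg: FilterConfig | None = None
) -> tuple[set[str], set[str]]:
    """Two-caller rule for a single tumor.

    ``caller_sets`` maps caller name to its post-filter mutation_id set.
    Returns (accepted, rejected): accepted ids appear in >= ``min_callers``
    caller sets, rejected ids appear in at least one but fewer.
    """
    cfg = cfg or FilterConfig()
    counts: dict[str, int] = {}
    for ids in caller_sets.values():
        for m in ids:
            counts[m] = counts.get(m, 0) + 1
    accepted = {m for m, n in counts.items() if n >= cfg.min_callers}
    rejected = set(counts) - accepted
    return accepted, rejected


def rescue_shared(
    accepted_by_tumor: dict[str, set[str]],
    rejected_by_tumor: dict[str, set[str]],
    cfg: FilterConfig | None = None,
) -> dict[str, set[str]]:
    """Cross-tumor rescue: a rejected mutation re-enters a tumor's final set
    when it occurs (accepted or rejected) in >= ``rescue_min_tumors`` distinct
    tumors.  Single pass; occurrence counts include the rejecting tumor.
    """
    cfg = cfg or FilterConfig()
    if set(accepted_by_tumor) != set(rejected_by_tumor):
        raise ValueError("accepted and rejected maps must share sample keys")
    occurrence: dict[str, int] = {}
    for t in accepted_by_tumor:
        for m in accepted_by_tumor[t] | rejected_by_tumor[t]:
            occurrence[m] = occurrence.get(m, 0) + 1
    final = {}
    for t in accepted_by_tumor:
        rescued = {
            m for m in rejected_by_tumor[t]
            if occurrence[m] >= cfg.rescue_min_tumors
        }
        final[t] = set(accepted_by_tumor[t]) | rescued
    return final


@dataclass
class ConsensusResult:
    """Outputs of the staged consensus pipeline with per-stage audit counts."""

    final: dict[str, set[str]]
    accepted: dict[str, set[str]]
    rejected: dict[str, set[str]]
    stage_counts: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_consensus(
    calls: pd.DataFrame, cfg: FilterConfig | None = None
) -> ConsensusResult:
    """Full staged pipeline: base filters -> caller filters -> per-tumor
    two-caller consensus -> cross-tumor rescue."""
    cfg = cfg or FilterConfig()
    base_pass, base_fail = apply_base_filters(calls, cfg)
    caller_pass, caller_fail = apply_caller_filters(base_pass, cfg)

    samples = sorted(calls["sample_id"].unique()) if len(calls) else []
    accepted: dict[str, set[str]] = {}
    rejected: dict[str, set[str]] = {}
    for t in samples:
        sub = caller_pass[caller_pass["sample_id"] == t]
        caller_sets = {
            c: set(sub.loc[sub["caller"] == c, "mutation_id"]) for c in CALLERS
        }
        accepted[t], rejected[t] = consensus_per_tumor(caller_sets, cfg)
    final = rescue_shared(accepted, rejected, cfg) if samples else {}

    counts = pd.DataFrame({
        "stage": ["input", "base_filter", "caller_filter", "consensus", "final"],
        "n_calls_or_mutations": [
            len(calls), len(base_pass), len(caller_pass),
            sum(len(s) for s in accepted.values()),
            sum(len(s) for s in final.values()),
        ],
    })
    return ConsensusResult(final=final, accepted=accepted, rejected=rejected,
                           stage_counts=counts)


def build_mutation_matrix(
    final: dict[str, set[str]], include_germline: bool = False
) -> MutationMatrix:
    """Binary presence/absence matrix from per-tumor final mutation sets.

    Columns are lexicographic by mutation_id; when requested a trailing
    all-zero ``germline`` row models the mutation-free ancestor.
    """
    if not final:
        raise ValueError("final mutation map is empty")
    mutations = sorted(set().union(*final.values()))
    rows = {t: [1 if m in s else 0 for m in mutations] for t, s in final.items()}
    presence = pd.DataFrame.from_dict(rows, orient="index", columns=mutations)
    presence = presence.loc[list(final.keys())]
    if include_germline:
        presence.loc[GERMLINE_LABEL] = 0
    return MutationMatrix(presence=presence, includes_germline_row=include_germline)


@dataclass(frozen=True)
class SharingSummary:
    total: int
    shared_all: int
    shared_ge2: int
    unique: int
    per_sample_counts: pd.Series
    pct_shared_ge2: int
    pct_unique: int


def sharing_percentages(shared_ge2: int, unique: int, total: int) -> tuple[int, int]:
    """Percent shared-by->=2 and percent unique, rounded to nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    return (round(100 * shared_ge2 / total), round(100 * unique / total))


def sharing_summary(matrix: MutationMatrix) -> SharingSummary:
    """Cross-tumor sharing statistics of the (germline-free) mutation matrix."""
    presence = matrix.drop_germline()
    n_tumors = presence.shape[0]
    col_counts = presence.sum(axis=0)
    total = int(presence.shape[1])
    shared_all = int((col_counts == n_tumors).sum())
    shared_ge2 = int((col_counts >= 2).sum())
    unique = int((col_counts == 1).sum())
    pct_shared, pct_unique = sharing_percentages(shared_ge2, unique, total)
    return SharingSummary(
        total=total, shared_all=shared_all, shared_ge2=shared_ge2, unique=unique,
        per_sample_counts=presence.sum(axis=1),
        pct_shared_ge2=pct_shared, pct_unique=pct_unique,
    )
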