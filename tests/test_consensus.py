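"""Filter, consensus and rescue rules, checked against a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from metaclone.consensus import (
    FilterConfig,
    apply_base_filters,
    apply_caller_filters,
    build_mutation_matrix,
    consensus_per_tumor,
    rescue_shared,
    run_consensus,
    sharing_percentages,
    sharing_summary,
)
from metaclone.core import CALLERS
from metaclone import io as mio
from conftest import random_call_frame

CFG = FilterConfig()


def _call(**kw):
    base = dict(
        sample_id="T1", caller="varscan", chrom="1", pos=100, ref="A", alt="T",
        tumor_depth=100, normal_depth=50, tumor_vaf=0.3, normal_vaf=0.0,
        alt_reads=30, pop_freq_max=0.0, lod=np.nan, quality=np.nan,
        effect="nonsynonymous", mutation_id="1_100_A_T",
    )
    base.update(kw)
    return base


class TestBaseFilters:
    def test_boundary_call_passes_all_inclusive_thresholds(self):
        calls = pd.DataFrame([_call(tumor_depth=20, normal_depth=10,
                                    tumor_vaf=0.02, normal_vaf=0.0,
                                    alt_reads=4, pop_freq_max=0.0)])
        passed, failed = apply_base_filters(calls, CFG)
        assert len(passed) == 1 and len(failed) == 0

    @pytest.mark.parametrize("field,value,reason", [
        ("tumor_depth", 19, "low_tumor_depth"),
        ("normal_depth", 9, "low_normal_depth"),
        ("tumor_vaf", 0.019, "low_tumor_vaf"),
        ("normal_vaf", 0.01, "high_normal_vaf"),      # < 0.01 is exclusive
        ("alt_reads", 3, "few_alt_reads"),
        ("pop_freq_max", 0.01, "common_in_population"),  # < 0.01 exclusive
    ])
    def test_each_criterion_fails_with_reason(self, field, value, reason):
        calls = pd.DataFrame([_call(**{field: value})])
        passed, failed = apply_base_filters(calls, CFG)
        assert len(passed) == 0
        assert reason in failed["fail_reasons"].iloc[0]

    def test_multiple_violations_all_reported(self):
        calls = pd.DataFrame([_call(tumor_depth=5, alt_reads=1)])
        _, failed = apply_base_filters(calls, CFG)
        reasons = failed["fail_reasons"].iloc[0]
        assert "low_tumor_depth" in reasons and "few_alt_reads" in reasons

    def test_empty_input_gives_empty_partition(self):
        empty = pd.DataFrame(columns=list(_call().keys()))
        passed, failed = apply_base_filters(empty, CFG)
        assert passed.empty and failed.empty

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        calls = random_call_frame(rng, ["T1", "T2"], ["1_100_A_T", "2_200_C_G"])
        passed, failed = apply_base_filters(calls, CFG)
        assert len(passed) + len(failed) == len(calls)
        assert set(passed.index).isdisjoint(failed.index)


class TestCallerFilters:
    @pytest.mark.parametrize("caller,field,value,ok", [
        ("mutect", "lod", 10.0, True),
        ("mutect", "lod", 9.99, False),
        ("strelka", "quality", 35.0, True),
        ("strelka", "quality", 34.9, False),
    ])
    def test_score_boundaries(self, caller, field, value, ok):
        kw = {"caller": caller, field: value}
        if caller == "mutect":
            kw["quality"] = np.nan
        else:
            kw["lod"] = np.nan
        passed, failed = apply_caller_filters(pd.DataFrame([_call(**kw)]), CFG)
        assert (len(passed) == 1) is ok

    def test_varscan_passes_without_scores(self):
        passed, failed = apply_caller_filters(pd.DataFrame([_call()]), CFG)
        assert len(passed) == 1

    def test_missing_required_score_raises(self):
        calls = pd.DataFrame([_call(caller="mutect", lod=np.nan)])
        with pytest.raises(ValueError, match="lod"):
            apply_caller_filters(calls, CFG)


class TestConsensusAndRescue:
    def test_two_callers_accepted_one_rejected(self):
        acc, rej = consensus_per_tumor(
            {"mutect": {"a", "b"}, "strelka": {"a"}, "varscan": set()}, CFG
        )
        assert acc == {"a"} and rej == {"b"}

    def test_accepted_invariant_to_caller_permutation(self):
        sets = {"mutect": {"a"}, "strelka": {"a", "b"}, "varscan": {"b"}}
        acc1, _ = consensus_per_tumor(sets, CFG)
        perm = {"varscan": sets["mutect"], "mutect": sets["strelka"],
                "strelka": sets["varscan"]}
        acc2, _ = consensus_per_tumor(perm, CFG)
        assert acc1 == acc2 == {"a", "b"}

    def test_rescue_of_id_accepted_elsewhere(self):
        final = rescue_shared(
            accepted_by_tumor={"T1": set(), "T2": {"x"}, "T3": {"x"}},
            rejected_by_tumor={"T1": {"x"}, "T2": set(), "T3": set()},
            cfg=CFG,
        )
        assert final["T1"] == {"x"}

    def test_unshared_reject_not_rescued(self):
        final = rescue_shared(
            accepted_by_tumor={"T1": set(), "T2": set()},
            rejected_by_tumor={"T1": {"x"}, "T2": set()},
            cfg=CFG,
        )
        assert final["T1"] == set()

    def test_two_rejecting_tumors_rescue_each_other(self):
        # occurrence counting includes the rejecting tumor itself
        final = rescue_shared(
            accepted_by_tumor={"T1": set(), "T2": set()},
            rejected_by_tumor={"T1": {"x"}, "T2": {"x"}},
            cfg=CFG,
        )
        assert final["T1"] == {"x"} and final["T2"] == {"x"}
        # under the exclude-self reading the same input would rescue nothing:
        # each tumor sees the id in only one *other* tumor
        occurrence_other = 1
        assert occurrence_other < CFG.rescue_min_tumors

    def test_rescue_is_single_pass_fixed_point(self):
        accepted = {"T1": {"a"}, "T2": set(), "T3": {"b"}}
        rejected = {"T1": {"b"}, "T2": {"a", "c"}, "T3": set()}
        final = rescue_shared(accepted, rejected, CFG)
        # re-running with the rescued sets as accepted adds nothing
        again = rescue_shared(final, {t: set() for t in final}, CFG)
        assert again == final
        for t in final:
            assert final[t] >= accepted[t]


class TestMatrixAndSharing:
    def test_small_matrix_layout(self):
        m = build_mutation_matrix({"T1": {"a", "b"}, "T2": {"a"}})
        assert list(m.presence.columns) == ["a", "b"]
        assert m.presence.loc["T1"].tolist() == [1, 1]
        assert m.presence.loc["T2"].tolist() == [1, 0]

    def test_germline_row_appended_all_zero(self):
        m = build_mutation_matrix({"T1": {"a"}, "T2": {"a"}}, include_germline=True)
        assert m.includes_germline_row
        assert m.presence.loc["germline"].sum() == 0

    def test_matrix_round_trips_through_writer(self, tmp_path):
        m = build_mutation_matrix({"T1": {"a", "b"}, "T2": {"b"}},
                                  include_germline=True)
        path = tmp_path / "matrix.tsv"
        mio.write_matrix(m.presence, path)
        back = mio.read_matrix(path).rename_axis(None)
        pd.testing.assert_frame_equal(back, m.presence, check_dtype=False)

    def test_sharing_counts_direct(self):
        final = {
            f"T{i}": set() for i in range(1, 21)
        }
        # columns present in 3, 1, 2 and 20 of 20 tumors
        for i in (1, 2, 3):
            final[f"T{i}"].add("m3")
        final["T1"].add("m1")
        for i in (4, 5):
            final[f"T{i}"].add("m2")
        for i in range(1, 21):
            final[f"T{i}"].add("mall")
        for i in range(1, 21):
            final[f"T{i}"].add(f"priv{i}")  # keep every tumor nonempty
        s = sharing_summary(build_mutation_matrix(final))
        assert s.shared_all == 1
        assert s.shared_ge2 == 3
        assert s.unique == s.total - 3

    def test_all_private_matrix(self):
        s = sharing_summary(build_mutation_matrix({"T1": {"a"}, "T2": {"b"}}))
        assert s.shared_ge2 == 0 and s.unique == s.total == 2

    def test_reported_sharing_fractions_at_printed_rounding(self):
        assert sharing_percentages(170, 58, 228) == (75, 25)


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_pipeline(calls: pd.DataFrame, cfg: FilterConfig,
                         rescue_includes_self: bool = True):
    """Direct evaluation of every (call, rule) pair, used as an independent
    oracle for the staged implementation."""
    def call_passes(r):
        ok = (
            r.tumor_depth >= cfg.min_tumor_depth
            and r.normal_depth >= cfg.min_normal_depth
            and r.tumor_vaf >= cfg.min_tumor_vaf
            and r.normal_vaf < cfg.max_normal_vaf
            and r.alt_reads >= cfg.min_alt_reads
            and r.pop_freq_max < cfg.max_pop_freq
        )
        if r.caller == "mutect":
            ok = ok and r.lod >= cfg.min_lod
        if r.caller == "strelka":
            ok = ok and r.quality >= cfg.min_quality
        return ok

    tumors = sorted(calls["sample_id"].unique())
    accepted, rejected = {}, {}
    for t in tumors:
        support = {}
        for r in calls[calls["sample_id"] == t].itertuples(index=False):
            if call_passes(r):
                support.setdefault(r.mutation_id, set()).add(r.caller)
        accepted[t] = {m for m, cs in support.items() if len(cs) >= cfg.min_callers}
        rejected[t] = {m for m, cs in support.items() if 0 < len(cs) < cfg.min_callers}
    final = {}
    for t in tumors:
        final[t] = set(accepted[t])
        for m in rejected[t]:
            others = [u for u in tumors
                      if m in accepted[u] or m in rejected[u]]
            count = len(others) if rescue_includes_self else len(
                [u for u in others if u != t]
            )
            if count >= cfg.rescue_min_tumors:
                final[t].add(m)
    return final


@pytest.mark.parametrize("seed", range(25))
def test_staged_pipeline_equals_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n_tumors = int(rng.integers(2, 5))
    n_mut = int(rng.integers(2, 13))
    samples = [f"T{i}" for i in range(n_tumors)]
    muts = [f"{i + 1}_{100 * (i + 1)}_A_T" for i in range(n_mut)]
    calls = random_call_frame(rng, samples, muts)
    staged = run_consensus(calls, CFG).final
    assert staged == brute_force_pipeline(calls, CFG, rescue_includes_self=True)


def test_oracle_readings_diverge_on_borderline_sharing():
    """The include-self and exclude-self readings of the rescue rule diverge
    exactly when a rejected mutation occurs in rescue_min_tumors tumors, one
    of which is the rejecting tumor: single-caller support in T1 and T2 and
    no support in T3 rescues under include-self only.  The implementation
    follows the include-self reading."""
    rows = [
        _call(sample_id="T1", caller="varscan"),
        _call(sample_id="T2", caller="varscan"),
        # anchor mutation so every tumor has calls
        _call(sample_id="T3", caller="varscan", mutation_id="2_200_C_G",
              chrom="2", pos=200, ref="C", alt="G"),
        _call(sample_id="T3", caller="mutect", mutation_id="2_200_C_G",
              chrom="2", pos=200, ref="C", alt="G", lod=40.0),
    ]
    calls = pd.DataFrame(rows)
    inc = brute_force_pipeline(calls, CFG, rescue_includes_self=True)
    exc = brute_force_pipeline(calls, CFG, rescue_includes_self=False)
    assert inc["T1"] == inc["T2"] == {"1_100_A_T"}
    assert exc["T1"] == exc["T2"] == set()
    staged = run_consensus(calls, CFG).final
    assert staged == inc  # default documented reading: include self
    # random cohorts: include-self is always a superset of exclude-self
    for seed in range(10):
        rng = np.random.default_rng(seed)
        rand = random_call_frame(
            rng, ["T1", "T2", "T3"], ["1_100_A_T", "2_200_C_G", "3_300_G_A"]
        )
        inc_r = brute_force_pipeline(rand, CFG, rescue_includes_self=True)
        exc_r = brute_force_pipeline(rand, CFG, rescue_includes_self=False)
        for t in inc_r:
            assert inc_r[t] >= exc_r[t]
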