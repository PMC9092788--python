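"""Readers and writers for the cohort's tidy TSV dialects.

A cohort directory holds::

    metadata.tsv            sample_id, site_label, is_primary, is_thoracic,
                            is_left_thoracic, is_lymph_node (0/1 flags)
    calls.tsv               tidy caller-call table (one row per call per caller)
    repertoires/<s>.tsv     rearrangement_nt, cdr3_aa, templates, productive
    tcr_denominators.tsv    sample_id, total_nucleated_cells
    probes/<s>.tsv          probe_id, chrom, pos, beta
    affinities.tsv          mutation_id, peptide, hla_allele, ic50_nm
    cell_fractions.tsv      sample_id, cd8_t, treg, others
    truth.json              (simulated cohorts only) ground truth for recovery

The generator writes exactly what the readers consume; any component other
than metadata may be absent.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .core import (
    CALL_COLUMNS,
    Cohort,
    Repertoire,
    SampleMeta,
    validate_cohort,
)
from .simulate import SimulatedCohort, SimTruth

META_COLUMNS = [
    "sample_id", "site_label", "is_primary", "is_thoracic",
    "is_left_thoracic", "is_lymph_node",
]


def write_metadata(samples: list[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": s.sample_id, "site_label": s.site_label,
            "is_primary": int(s.is_primary), "is_thoracic": int(s.is_thoracic),
            "is_left_thoracic": int(s.is_left_thoracic),
            "is_lymph_node": int(s.is_lymph_node),
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return [
        SampleMeta(
            sample_id=r.sample_id, site_label=str(r.site_label),
            is_primary=bool(r.is_primary), is_thoracic=bool(r.is_thoracic),
            is_left_thoracic=bool(r.is_left_thoracic),
            is_lymph_node=bool(r.is_lymph_node),
        )
        for r in df.itertuples(index=False)
    ]


def write_calls(calls: pd.DataFrame, path) -> None:
    calls[CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_calls(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t",
        dtype={"sample_id": str, "chrom": str, "ref": str, "alt": str},
    )[CALL_COLUMNS]


def write_repertoires(reps: dict[str, Repertoire], cohort_dir) -> None:
    rep_dir = Path(cohort_dir) / "repertoires"
    rep_dir.mkdir(parents=True, exist_ok=True)
    denom = []
    for s, rep in reps.items():
        out = rep.rows[["rearrangement_nt", "cdr3_aa", "templates", "productive"]].copy()
        out["productive"] = out["productive"].astype(int)
        out.to_csv(rep_dir / f"{s}.tsv", sep="\t", index=False)
        denom.append({"sample_id": s, "total_nucleated_cells": rep.total_nucleated_cells})
    pd.DataFrame(denom).to_csv(
        Path(cohort_dir) / "tcr_denominators.tsv", sep="\t", index=False
    )


def read_repertoires(cohort_dir) -> dict[str, Repertoire]:
    cohort_dir = Path(cohort_dir)
    denom_path = cohort_dir / "tcr_denominators.tsv"
    if not denom_path.exists():
        return {}
    denom = pd.read_csv(denom_path, sep="\t", dtype={"sample_id": str})
    reps = {}
    for r in denom.itertuples(index=False):
        rows = pd.read_csv(
            cohort_dir / "repertoires" / f"{r.sample_id}.tsv", sep="\t",
            dtype={"rearrangement_nt": str, "cdr3_aa": str},
        )
        rows["productive"] = rows["productive"].astype(bool)
        reps[r.sample_id] = Repertoire(
            sample_id=r.sample_id, rows=rows,
            total_nucleated_cells=int(r.total_nucleated_cells),
        )
    return reps


def write_probes(probes: dict[str, pd.DataFrame], cohort_dir) -> None:
    probe_dir = Path(cohort_dir) / "probes"
    probe_dir.mkdir(parents=True, exist_ok=True)
    for s, df in probes.items():
        df[["probe_id", "chrom", "pos", "beta"]].to_csv(
            probe_dir / f"{s}.tsv", sep="\t", index=False
        )


def read_probes(cohort_dir) -> dict[str, pd.DataFrame]:
    probe_dir = Path(cohort_dir) / "probes"
    if not probe_dir.exists():
        return {}
    out = {}
    for path in sorted(probe_dir.glob("*.tsv")):
        out[path.stem] = pd.read_csv(
            path, sep="\t", dtype={"probe_id": str, "chrom": str}
        )
    return out


def write_matrix(matrix_df: pd.DataFrame, path) -> None:
    matrix_df.to_csv(path, sep="\t", index_label="sample_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def _truth_to_json(truth: SimTruth) -> dict:
    return {
        "sets_by_tumor": {t: sorted(s) for t, s in truth.sets_by_tumor.items()},
        "truncal_ids": truth.truncal_ids,
        "designated_truncal": truth.designated_truncal,
        "positions": truth.positions.to_dict(orient="list"),
        "excluded_clonotypes_aa": truth.excluded_clonotypes_aa,
        "shared_clones_nt": truth.shared_clones_nt,
        "latent_u": truth.latent_u,
        "latent_v": truth.latent_v,
        "target_ratios": truth.target_ratios,
    }


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SimTruth(
        sets_by_tumor={t: set(s) for t, s in d["sets_by_tumor"].items()},
        truncal_ids=d["truncal_ids"],
        designated_truncal=d["designated_truncal"],
        positions=pd.DataFrame(d["positions"]),
        excluded_clonotypes_aa=d["excluded_clonotypes_aa"],
        shared_clones_nt=d["shared_clones_nt"],
        latent_u=d["latent_u"],
        latent_v=d["latent_v"],
        target_ratios=d["target_ratios"],
    )


def write_cohort(sim: SimulatedCohort | Cohort, cohort_dir) -> None:
    """Write a cohort (optionally with simulation truth) as a cohort directory."""
    cohort_dir = Path(cohort_dir)
    cohort_dir.mkdir(parents=True, exist_ok=True)
    cohort = sim.cohort if isinstance(sim, SimulatedCohort) else sim
    write_metadata(cohort.samples, cohort_dir / "metadata.tsv")
    if cohort.calls is not None:
        write_calls(cohort.calls, cohort_dir / "calls.tsv")
    if cohort.repertoires:
        write_repertoires(cohort.repertoires, cohort_dir)
    if cohort.probes:
        write_probes(cohort.probes, cohort_dir)
    if cohort.affinities is not None:
        cohort.affinities.to_csv(cohort_dir / "affinities.tsv", sep="\t", index=False)
    if cohort.cell_fractions is not None:
        cohort.cell_fractions.to_csv(
            cohort_dir / "cell_fractions.tsv", sep="\t", index=False
        )
    if isinstance(sim, SimulatedCohort):
        with open(cohort_dir / "truth.json", "w") as fh:
            json.dump(_truth_to_json(sim.truth), fh, indent=1, sort_keys=True)


def read_cohort(cohort_dir) -> Cohort:
    """Read and validate a cohort directory; missing components stay None."""
    cohort_dir = Path(cohort_dir)
    samples = read_metadata(cohort_dir / "metadata.tsv")
    calls = None
    if (cohort_dir / "calls.tsv").exists():
        calls = read_calls(cohort_dir / "calls.tsv")
    affinities = None
    if (cohort_dir / "affinities.tsv").exists():
        affinities = pd.read_csv(
            cohort_dir / "affinities.tsv", sep="\t",
            dtype={"mutation_id": str, "peptide": str, "hla_allele": str},
        )
    cell_fractions = None
    if (cohort_dir / "cell_fractions.tsv").exists():
        cell_fractions = pd.read_csv(
            cohort_dir / "cell_fractions.tsv", sep="\t", dtype={"sample_id": str}
        )
    cohort = Cohort(
        samples=samples, calls=calls,
        repertoires=read_repertoires(cohort_dir),
        probes=read_probes(cohort_dir),
        affinities=affinities, cell_fractions=cell_fractions,
    )
    return validate_cohort(cohort)
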