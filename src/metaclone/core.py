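"""Shared domain model and cohort validation.

The pipeline operates on one patient's multi-tumor cohort: a primary tumor and
its synchronous metastases, each profiled by whole-exome sequencing (three
somatic callers), TCR-beta repertoire sequencing, a methylation array, and an
MHC class I binding-affinity table for mutant peptides.  The types here are
thin validated containers around pandas structures; every downstream module
consumes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALLERS = ("mutect", "varscan", "strelka")
EFFECTS = ("nonsynonymous", "silent", "stopgain", "other")

GERMLINE_LABEL = "germline"

#: columns of the tidy caller-call table
CALL_COLUMNS = [
    "sample_id", "caller", "chrom", "pos", "ref", "alt",
    "tumor_depth", "normal_depth", "tumor_vaf", "normal_vaf", "alt_reads",
    "pop_freq_max", "lod", "quality", "effect", "mutation_id",
]


class CohortValidationError(ValueError):
    """Raised with a per-violation report when cohort inputs are inconsistent."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            "cohort validation failed:\n" + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass(frozen=True)
class SampleMeta:
    """Anatomical metadata for one tumor sample."""

    sample_id: str
    site_label: str = ""
    is_primary: bool = False
    is_thoracic: bool = False
    is_left_thoracic: bool = False
    is_lymph_node: bool = False

    def __post_init__(self):
        if self.is_left_thoracic and not self.is_thoracic:
            raise CohortValidationError(
                [f"sample {self.sample_id!r}: is_left_thoracic requires is_thoracic"]
            )


def mutation_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical join key for a mutation: ``chrom_pos_ref_alt``."""
    return f"{chrom}_{pos}_{ref}_{alt}"


@dataclass(frozen=True)
class CallerCall:
    """One variant observation by one caller in one tumor.

    ``lod`` is present only for MuTect calls and ``quality`` only for Strelka
    calls; the other callers carry NaN in the tabular representation.
    """

    sample_id: str
    caller: str
    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_depth: int
    normal_depth: int
    tumor_vaf: float
    normal_vaf: float
    alt_reads: int
    pop_freq_max: float = 0.0
    lod: float | None = None
    quality: float | None = None
    effect: str = "nonsynonymous"

    def __post_init__(self):
        errs = []
        if self.caller not in CALLERS:
            errs.append(f"unknown caller {self.caller!r}")
        if self.pos < 1:
            errs.append(f"pos must be >= 1, got {self.pos}")
        if self.caller == "mutect" and self.lod is None:
            errs.append("mutect call missing lod")
        if self.caller != "mutect" and self.lod is not None:
            errs.append(f"{self.caller} call carries lod")
        if self.caller == "strelka" and self.quality is None:
            errs.append("strelka call missing quality")
        if self.caller != "strelka" and self.quality is not None:
            errs.append(f"{self.caller} call carries quality")
        if not 0 <= self.tumor_vaf <= 1 or not 0 <= self.normal_vaf <= 1:
            errs.append("VAF outside [0, 1]")
        # alt reads should agree with vaf * depth up to rounding
        if self.tumor_depth > 0 and abs(
            self.alt_reads - self.tumor_vaf * self.tumor_depth
        ) > 1.0:
            errs.append(
                f"alt_reads {self.alt_reads} inconsistent with "
                f"tumor_vaf*tumor_depth = {self.tumor_vaf * self.tumor_depth:.2f}"
            )
        if errs:
            raise CohortValidationError([f"call {self.chrom}:{self.pos}: {e}" for e in errs])

    @property
    def mutation_id(self) -> str:
        return mutation_id(self.chrom, self.pos, self.ref, self.alt)


def calls_to_frame(calls) -> pd.DataFrame:
    """Convert an iterable of :class:`CallerCall` into the tidy call table."""
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id, "caller": c.caller, "chrom": c.chrom,
            "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "tumor_depth": c.tumor_depth, "normal_depth": c.normal_depth,
            "tumor_vaf": c.tumor_vaf, "normal_vaf": c.normal_vaf,
            "alt_reads": c.alt_reads, "pop_freq_max": c.pop_freq_max,
            "lod": np.nan if c.lod is None else c.lod,
            "quality": np.nan if c.quality is None else c.quality,
            "effect": c.effect, "mutation_id": c.mutation_id,
        })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


@dataclass
class Repertoire:
    """A TCR-beta repertoire for one sample.

    ``rows`` must provide columns ``rearrangement_nt``, ``cdr3_aa``,
    ``templates`` and ``productive``.  The productive-template frequency
    column is always recomputed from templates at construction so that the
    frequencies of productive rows sum to one.
    """

    sample_id: str
    rows: pd.DataFrame
    total_nucleated_cells: int

    def __post_init__(self):
        req = {"rearrangement_nt", "cdr3_aa", "templates", "productive"}
        missing = req - set(self.rows.columns)
        if missing:
            raise CohortValidationError(
                [f"repertoire {self.sample_id}: missing columns {sorted(missing)}"]
            )
        if self.total_nucleated_cells <= 0:
            raise CohortValidationError(
                [f"repertoire {self.sample_id}: total_nucleated_cells must be positive"]
            )
        rows = self.rows.reset_index(drop=True).copy()
        if (rows["templates"] < 1).any():
            raise CohortValidationError(
                [f"repertoire {self.sample_id}: stored rows require templates >= 1"]
            )
        if rows["rearrangement_nt"].duplicated().any():
            dup = rows.loc[rows["rearrangement_nt"].duplicated(), "rearrangement_nt"].iloc[0]
            raise CohortValidationError(
                [f"repertoire {self.sample_id}: duplicate rearrangement {dup!r}"]
            )
        prod = rows["productive"].astype(bool)
        total_prod = int(rows.loc[prod, "templates"].sum())
        freq = np.zeros(len(rows))
        if total_prod > 0:
            freq[prod.to_numpy()] = rows.loc[prod, "templates"].to_numpy(float) / total_prod
        rows["frequency"] = freq
        rows["productive"] = prod
        self.rows = rows

    @property
    def productive(self) -> pd.DataFrame:
        return self.rows[self.rows["productive"]]

    @property
    def n_productive_templates(self) -> int:
        return int(self.productive["templates"].sum())


@dataclass
class MutationMatrix:
    """Binary tumors x mutations presence/absence matrix.

    When ``includes_germline_row`` is set the matrix carries an extra all-zero
    row labelled ``germline`` modelling the mutation-free ancestor used to
    root the phylogeny.
    """

    presence: pd.DataFrame
    includes_germline_row: bool = False

    def __post_init__(self):
        vals = self.presence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise CohortValidationError(["mutation matrix entries must be 0/1"])
        self.presence = self.presence.astype(np.int8)
        if self.includes_germline_row:
            if GERMLINE_LABEL not in self.presence.index:
                raise CohortValidationError(["germline row requested but absent"])
            if self.presence.loc[GERMLINE_LABEL].any():
                raise CohortValidationError(["germline row must be all zeros"])
        somatic = self.drop_germline()
        if somatic.shape[1] and (somatic.sum(axis=0) == 0).any():
            raise CohortValidationError(["mutation matrix has an all-zero column"])

    def drop_germline(self) -> pd.DataFrame:
        if self.includes_germline_row:
            return self.presence.drop(index=GERMLINE_LABEL)
        return self.presence

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.presence.columns)


@dataclass(frozen=True)
class NeoantigenRecord:
    """A mutant peptide with its MHC class I binding affinity."""

    mutation_id: str
    peptide: str
    hla_allele: str
    ic50: float
    binder_class: str = "non_binder"

    def __post_init__(self):
        if len(self.peptide) not in (9, 10):
            raise CohortValidationError(
                [f"peptide {self.peptide!r} must be a 9- or 10-mer"]
            )
        if self.ic50 <= 0:
            raise CohortValidationError([f"ic50 must be positive, got {self.ic50}"])
        expected = classify_ic50(self.ic50)
        if self.binder_class != expected:
            raise CohortValidationError(
                [f"binder_class {self.binder_class!r} inconsistent with ic50 {self.ic50}"]
            )


def classify_ic50(ic50: float, strong_nm: float = 50.0, binder_nm: float = 500.0) -> str:
    """Classify an IC50 (nM): < 50 strong binder, < 500 binder, else non-binder."""
    if ic50 < strong_nm:
        return "strong_binder"
    if ic50 < binder_nm:
        return "binder"
    return "non_binder"


METHYLATION_BETA_THRESHOLD = 0.3


@dataclass(frozen=True)
class ProbeBeta:
    """A CpG probe beta value; beta strictly above 0.3 is called methylated."""

    probe_id: str
    chrom: str
    pos: int
    beta: float

    def __post_init__(self):
        if not 0 <= self.beta <= 1:
            raise CohortValidationError([f"probe {self.probe_id}: beta outside [0,1]"])
        if self.pos < 1:
            raise CohortValidationError([f"probe {self.probe_id}: pos must be >= 1"])

    @property
    def methylated(self) -> bool:
        return self.beta > METHYLATION_BETA_THRESHOLD


@dataclass(frozen=True)
class CellFractions:
    """Deconvolved immune cell fractions for one sample (consumed, not computed)."""

    sample_id: str
    cd8_t: float
    treg: float
    others: float = 0.0

    def __post_init__(self):
        fracs = (self.cd8_t, self.treg, self.others)
        if any(f < 0 for f in fracs):
            raise CohortValidationError([f"sample {self.sample_id}: negative cell fraction"])
        if sum(fracs) > 1 + 1e-9:
            raise CohortValidationError(
                [f"sample {self.sample_id}: cell fractions sum above 1"]
            )


@dataclass
class Cohort:
    """A validated bundle of per-sample inputs for one patient.

    Any component may be absent (None); the pipeline degrades gracefully,
    skipping stages whose inputs are missing.
    """

    samples: list[SampleMeta]
    calls: pd.DataFrame | None = None
    repertoires: dict[str, Repertoire] = field(default_factory=dict)
    probes: dict[str, pd.DataFrame] = field(default_factory=dict)
    affinities: pd.DataFrame | None = None
    cell_fractions: pd.DataFrame | None = None
    validated: bool = False

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id, "site_label": s.site_label,
                    "is_primary": int(s.is_primary), "is_thoracic": int(s.is_thoracic),
                    "is_left_thoracic": int(s.is_left_thoracic),
                    "is_lymph_node": int(s.is_lymph_node),
                }
                for s in self.samples
            ]
        )

    @property
    def primary_id(self) -> str | None:
        ids = [s.sample_id for s in self.samples if s.is_primary]
        return ids[0] if ids else None


def validate_cohort(cohort: Cohort) -> Cohort:
    """Validate cross-table consistency; raises with a per-violation report.

    Idempotent: validating an already validated cohort changes nothing.
    """
    violations: list[str] = []
    ids = cohort.sample_ids
    if len(ids) < 2:
        violations.append("cohort requires at least 2 samples")
    seen = set()
    for sid in ids:
        if sid in seen:
            violations.append(f"duplicate sample_id {sid!r}")
        seen.add(sid)
    n_primary = sum(s.is_primary for s in cohort.samples)
    if n_primary > 1:
        violations.append(f"{n_primary} samples flagged primary; at most one allowed")
    for s in cohort.samples:
        if s.is_left_thoracic and not s.is_thoracic:
            violations.append(
                f"sample {s.sample_id!r}: is_left_thoracic without is_thoracic"
            )

    known = set(ids)

    def check_ids(found, table_name):
        for sid in sorted(set(found) - known):
            violations.append(f"{table_name}: unknown sample_id {sid!r}")

    if cohort.calls is not None and len(cohort.calls):
        check_ids(cohort.calls["sample_id"].unique(), "calls")
    check_ids(cohort.repertoires, "repertoires")
    check_ids(cohort.probes, "probes")
    if cohort.cell_fractions is not None and len(cohort.cell_fractions):
        check_ids(cohort.cell_fractions["sample_id"].unique(), "cell_fractions")

    if violations:
        raise CohortValidationError(violations)
    cohort.validated = True
    return cohort
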