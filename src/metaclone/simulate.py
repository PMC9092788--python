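"""Seeded synthetic-cohort generator.

The study's data are request-only, so the pipeline is exercised on a
synthetic patient emulating its structure: ~20 tumors (one primary, the rest
synchronous metastases) whose somatic mutations are placed on a clonal
phylogeny (a truncal set present in every tumor — including one designated
truncal stop-gain — clade-shared branch mutations, and private mutations),
observed through three noisy caller views; power-law TCR repertoires with a
clone pool shared by all tumors and a prevalent clonotype set planted absent
from the left-thoracic group; log-uniform mutant-peptide binding affinities;
and methylation beta values coupled to the repertoire latent through a
Gaussian copula so that a negative methylation-immunity association of known
strength is planted for recovery testing.

Everything is driven by one integer seed through named, ordered child
streams, so a cohort is bit-reproducible and the generator's outputs
round-trip through the package's own readers and writers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    CALLERS,
    CALL_COLUMNS,
    Cohort,
    Repertoire,
    SampleMeta,
    mutation_id as make_mutation_id,
    validate_cohort,
)

_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_HLA = ["HLA-A*02:01", "HLA-A*11:01", "HLA-B*15:01", "HLA-B*40:01", "HLA-C*07:02"]

#: the designated truncal stop-gain present in every tumor
TRUNCAL_STOPGAIN = ("17", 7578382, "G", "C")


@dataclass(frozen=True)
class SimConfig:
    """Study-conditions of the synthetic cohort.

    Mutation-side defaults reproduce the reported cohort summaries: 20
    tumors, exactly 10 truncal mutations, per-tumor non-silent counts drawn
    in the reported 57-98 window, caller sensitivity 0.9 with per-caller
    false-call rate 0.02.  Repertoire-side defaults plant a 100-clone pool
    shared by all tumors, 5 prevalent clonotypes absent from the
    left-thoracic group, power-law clone sizes (exponent 2), and per-sample
    T-cell density in the reported 3-38% range.  ``rho_plant`` is the
    Spearman coupling between the methylated-neoantigen ratio and the
    repertoire latent (default -0.7, the planted immunosuppression signal).
    """

    n_tumors: int = 20
    n_truncal: int = 10
    clade_mutation_mean: float = 6.0
    count_range: tuple[int, int] = (57, 98)
    caller_sensitivity: float = 0.9
    caller_false_rate: float = 0.02
    tumor_depth_mean: float = 120.0
    normal_depth_mean: float = 60.0
    vaf_range: tuple[float, float] = (0.15, 0.6)
    contamination_rate: float = 0.015
    lod_mean: float = 40.0
    lod_sd: float = 12.0
    quality_mean: float = 60.0
    quality_sd: float = 10.0

    n_shared_clones: int = 100
    n_excluded_clones: int = 5
    private_clone_range: tuple[int, int] = (250, 600)
    power_law_exponent: float = 2.0
    total_nucleated_cells: int = 50000
    density_range: tuple[float, float] = (0.03, 0.38)

    peptides_per_mutation: int = 2
    ic50_bounds_nm: tuple[float, float] = (1.0, 50000.0)

    probes_per_mutation: int = 2
    probe_offset_max: int = 1500
    n_background_probes: int = 200
    ratio_range: tuple[float, float] = (0.15, 0.85)
    rho_plant: float = -0.7

    def __post_init__(self):
        for p in (self.caller_sensitivity, self.caller_false_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not -1 <= self.rho_plant <= 1:
            raise ValueError("rho_plant must lie in [-1, 1]")
        if self.n_tumors < 2:
            raise ValueError("need at least 2 tumors")


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort, kept for recovery diagnostics."""

    sets_by_tumor: dict[str, set[str]]
    truncal_ids: list[str]
    designated_truncal: str
    positions: pd.DataFrame
    excluded_clonotypes_aa: list[str]
    shared_clones_nt: list[str]
    latent_u: dict[str, float]
    latent_v: dict[str, float]
    target_ratios: dict[str, float]
    tree_nested: object = None


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: SimTruth
    config: SimConfig = field(default_factory=SimConfig)
    seed: int = 0


# ---------------------------------------------------------------------------
# metadata


def default_metadata(n_tumors: int) -> list[SampleMeta]:
    """One primary ``P`` plus metastases ``M01..``; the left-thoracic group
    is the primary and the three nearest metastases, the first half of the
    cohort is thoracic, and a few thoracic nodes are lymph nodes."""
    ids = ["P"] + [f"M{i:02d}" for i in range(1, n_tumors)]
    n_thoracic = max(2, n_tumors // 2)
    metas = []
    for i, sid in enumerate(ids):
        thoracic = i < n_thoracic
        left = sid in {"P", "M02", "M03", "M04"} and thoracic
        lymph = thoracic and sid in {"M05", "M06"}
        metas.append(SampleMeta(
            sample_id=sid,
            site_label=(
                "primary" if sid == "P"
                else ("left thorax" if left else ("thorax" if thoracic else "distant"))
            ),
            is_primary=sid == "P",
            is_thoracic=thoracic,
            is_left_thoracic=left,
            is_lymph_node=lymph,
        ))
    return metas


# ---------------------------------------------------------------------------
# truth phylogeny and mutation sets


def _balanced_tree(leaves: list[str], rng) -> object:
    """Random balanced nested-tuple tree over the given leaves."""
    leaves = list(leaves)
    rng.shuffle(leaves)

    def build(sub):
        if len(sub) == 1:
            return sub[0]
        half = len(sub) // 2
        return (build(sub[:half]), build(sub[half:]))

    return build(leaves)


def _leaves_of(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return _leaves_of(node[0]) + _leaves_of(node[1])


def _internal_nodes(node):
    if isinstance(node, str):
        return
    yield node
    yield from _internal_nodes(node[0])
    yield from _internal_nodes(node[1])


def _new_mutation_ids(n: int, rng, used: set[str]) -> list[str]:
    out = []
    while len(out) < n:
        chrom = str(rng.integers(1, 23))
        pos = int(rng.integers(1_000_000, 200_000_000))
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        mid = make_mutation_id(chrom, pos, ref, alt)
        if mid not in used:
            used.add(mid)
            out.append(mid)
    return out


def simulate_truth(cfg: SimConfig, seed) -> tuple[list[SampleMeta], SimTruth]:
    """True per-tumor mutation sets on a group-aware clonal phylogeny.

    Anatomical groups form clades so that mutation overlap is higher within
    than between groups; every tumor carries the truncal set (including the
    designated stop-gain), clade mutations of its ancestors, and enough
    private mutations to land in the configured per-tumor count window.
    """
    rng = np.random.default_rng(seed)
    metas = default_metadata(cfg.n_tumors)
    groups: list[list[str]] = [[], [], []]
    for m in metas:
        if m.is_left_thoracic:
            groups[0].append(m.sample_id)
        elif m.is_thoracic:
            groups[1].append(m.sample_id)
        else:
            groups[2].append(m.sample_id)
    subtrees = [_balanced_tree(g, rng) for g in groups if g]
    tree = subtrees[0]
    for sub in subtrees[1:]:
        tree = (tree, sub)

    used: set[str] = set()
    chrom, pos, ref, alt = TRUNCAL_STOPGAIN
    designated = make_mutation_id(chrom, pos, ref, alt)
    used.add(designated)
    truncal = [designated] + _new_mutation_ids(cfg.n_truncal - 1, rng, used)

    sets = {m.sample_id: set(truncal) for m in metas}
    positions_rows = [
        {"mutation_id": mid, "chrom": mid.split("_")[0],
         "pos": int(mid.split("_")[1]),
         "effect": "stopgain" if mid == designated else "nonsynonymous"}
        for mid in truncal
    ]

    for node in _internal_nodes(tree):
        clade = _leaves_of(node)
        if len(clade) in (1, cfg.n_tumors):
            continue
        n_mut = int(rng.poisson(cfg.clade_mutation_mean))
        for mid in _new_mutation_ids(n_mut, rng, used):
            for s in clade:
                sets[s].add(mid)
            positions_rows.append({
                "mutation_id": mid, "chrom": mid.split("_")[0],
                "pos": int(mid.split("_")[1]), "effect": "nonsynonymous",
            })

    lo, hi = cfg.count_range
    for m in metas:
        s = m.sample_id
        target = int(rng.integers(lo, hi + 1))
        n_private = max(target - len(sets[s]), 0)
        for mid in _new_mutation_ids(n_private, rng, used):
            sets[s].add(mid)
            positions_rows.append({
                "mutation_id": mid, "chrom": mid.split("_")[0],
                "pos": int(mid.split("_")[1]), "effect": "nonsynonymous",
            })

    truth = SimTruth(
        sets_by_tumor=sets,
        truncal_ids=truncal,
        designated_truncal=designated,
        positions=pd.DataFrame(positions_rows),
        excluded_clonotypes_aa=[],
        shared_clones_nt=[],
        latent_u={},
        latent_v={},
        target_ratios={},
        tree_nested=tree,
    )
    return metas, truth


# ---------------------------------------------------------------------------
# caller views


def simulate_caller_calls(truth: SimTruth, cfg: SimConfig, seed) -> pd.DataFrame:
    """Noisy per-tumor per-caller call tables.

    Each true mutation is seen by each caller with probability
    ``caller_sensitivity``; evidence fields are drawn so that the large
    majority of true calls clear the printed filters (occasional germline
    contamination, low LOD or low quality produce realistic filter losses).
    False calls are injected per caller at ``caller_false_rate`` and land
    overwhelmingly in a single caller, so the two-caller rule removes them.
    """
    rng = np.random.default_rng(seed)
    used = set(truth.positions["mutation_id"])
    effect_by_id = dict(zip(truth.positions["mutation_id"], truth.positions["effect"]))
    rows = []

    def evidence(caller, vaf):
        depth = max(int(rng.poisson(cfg.tumor_depth_mean)), 1)
        alt = int(rng.binomial(depth, vaf))
        ndepth = max(int(rng.poisson(cfg.normal_depth_mean)), 1)
        if rng.random() < cfg.contamination_rate:  # germline contamination
            nvaf = float(rng.uniform(0.01, 0.05))
        else:
            nvaf = float(rng.uniform(0.0, 0.009))
        return {
            "tumor_depth": depth, "normal_depth": ndepth,
            "tumor_vaf": alt / depth, "normal_vaf": nvaf, "alt_reads": alt,
            "lod": float(rng.normal(cfg.lod_mean, cfg.lod_sd))
            if caller == "mutect" else np.nan,
            "quality": float(rng.normal(cfg.quality_mean, cfg.quality_sd))
            if caller == "strelka" else np.nan,
        }

    for tumor, muts in truth.sets_by_tumor.items():
        muts = sorted(muts)
        vafs = rng.uniform(*cfg.vaf_range, size=len(muts))
        pop = rng.uniform(0.0, 0.005, size=len(muts))
        for mid, vaf, pf in zip(muts, vafs, pop):
            chrom, pos, ref, alt_base = mid.split("_")
            for caller in CALLERS:
                if rng.random() >= cfg.caller_sensitivity:
                    continue
                ev = evidence(caller, vaf)
                rows.append({
                    "sample_id": tumor, "caller": caller, "chrom": chrom,
                    "pos": int(pos), "ref": ref, "alt": alt_base,
                    **ev, "pop_freq_max": float(pf),
                    "effect": effect_by_id[mid], "mutation_id": mid,
                })
        # false positives, biased to single-caller support
        for caller in CALLERS:
            n_false = int(rng.poisson(cfg.caller_false_rate * len(muts)))
            for mid in _new_mutation_ids(n_false, rng, used):
                chrom, pos, ref, alt_base = mid.split("_")
                ev = evidence(caller, float(rng.uniform(*cfg.vaf_range)))
                pf = float(rng.uniform(0.02, 0.2)) if rng.random() < 0.3 else 0.0
                rows.append({
                    "sample_id": tumor, "caller": caller, "chrom": chrom,
                    "pos": int(pos), "ref": ref, "alt": alt_base,
                    **ev, "pop_freq_max": pf,
                    "effect": "nonsynonymous", "mutation_id": mid,
                })
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


# ---------------------------------------------------------------------------
# repertoires


def _random_cdr3(rng, n: int) -> list[str]:
    out = set()
    while len(out) < n:
        mid_len = int(rng.integers(6, 11))
        seq = "CASS" + "".join(rng.choice(_AA, size=mid_len)) + "F"
        out.add(seq)
    return sorted(out)


def _random_nt(rng, n: int, length: int = 39) -> list[str]:
    out = set()
    while len(out) < n:
        out.add("".join(rng.choice(_BASES, size=length)))
    return sorted(out)


def _lerp(bounds: tuple[float, float], q) -> float:
    return bounds[0] + (bounds[1] - bounds[0]) * q


def sample_latents(cfg: SimConfig, sample_ids: list[str], seed):
    """Bivariate standard-normal latents (u drives the repertoire, v the
    methylated-neoantigen ratio) with Gaussian-copula correlation chosen so
    the planted Spearman coupling equals ``rho_plant``."""
    rng = np.random.default_rng(seed)
    r = 2 * math.sin(math.pi * cfg.rho_plant / 6)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=len(sample_ids))
    u = {s: float(z[i, 0]) for i, s in enumerate(sample_ids)}
    v = {s: float(z[i, 1]) for i, s in enumerate(sample_ids)}
    return u, v


def simulate_repertoires(
    cfg: SimConfig,
    metas: list[SampleMeta],
    latent_u: dict[str, float],
    seed,
) -> tuple[dict[str, Repertoire], list[str], list[str]]:
    """Per-tumor repertoires with planted structure.

    Clone sizes follow a truncated power law; a clone pool is present in
    every sample; the excluded clonotypes are highly prevalent in every
    non-left-thoracic sample and receive zero templates in left-thoracic
    samples.  Density, richness and clonality all increase with the shared
    latent ``u`` so the three metrics are positively inter-correlated.
    """
    rng = np.random.default_rng(seed)
    shared_aa = _random_cdr3(rng, cfg.n_shared_clones)
    shared_nt = _random_nt(rng, cfg.n_shared_clones)
    excl_aa = _random_cdr3(rng, cfg.n_excluded_clones)
    excl_nt = _random_nt(rng, cfg.n_excluded_clones)
    excl_aa = [a for a in excl_aa if a not in set(shared_aa)]

    reps: dict[str, Repertoire] = {}
    for m in metas:
        s = m.sample_id
        dens = _lerp(cfg.density_range, float(norm.cdf(latent_u[s] + rng.normal(0, 0.1))))
        n_private = int(round(_lerp(cfg.private_clone_range,
                                    float(norm.cdf(latent_u[s] + rng.normal(0, 0.1))))))
        # Zipf exponent of the clone-size law increases with the latent, so
        # higher-infiltration samples are also more clonally expanded
        zipf_s = 0.6 + 0.5 * float(norm.cdf(latent_u[s] + rng.normal(0, 0.1)))

        priv_aa = _random_cdr3(rng, n_private)
        priv_nt = [f"{s}:{nt}" for nt in _random_nt(rng, n_private)]
        include_excl = not m.is_left_thoracic

        aa = list(shared_aa) + list(priv_aa)
        nt = list(shared_nt) + list(priv_nt)
        if include_excl:
            aa += list(excl_aa)
            nt += list(excl_nt)
        n_clones = len(aa)
        # rank-based power-law weights; the planted excluded clonotypes take
        # the top ranks in non-left-thoracic samples so they are among each
        # sample's most prevalent clonotypes
        ranks = np.empty(n_clones)
        body = rng.permutation(np.arange(len(excl_aa) if include_excl else 0,
                                         n_clones) + 1.0)
        if include_excl and len(excl_aa):
            ranks[:-len(excl_aa)] = body
            ranks[-len(excl_aa):] = np.arange(1, len(excl_aa) + 1)
        else:
            ranks[:] = body
        p = ranks ** (-zipf_s)
        p /= p.sum()
        total_templates = int(round(dens * cfg.total_nucleated_cells))
        counts = rng.multinomial(total_templates, p)
        # every generated clone stays detectable: richness is planted as the
        # clone count itself, so it tracks the latent rather than the
        # sampling depth; planted excluded clones stay clearly prevalent
        counts = np.maximum(counts, 1)
        if include_excl and len(excl_aa):
            counts[-len(excl_aa):] = np.maximum(counts[-len(excl_aa):], 5)

        rows = pd.DataFrame({
            "rearrangement_nt": np.array(nt, dtype=object),
            "cdr3_aa": np.array(aa, dtype=object),
            "templates": counts,
            "productive": True,
        })
        # a small unproductive fraction, excluded from all metrics
        n_unprod = max(1, int(0.1 * len(rows)))
        unprod = pd.DataFrame({
            "rearrangement_nt": [f"{s}:np:{x}" for x in _random_nt(rng, n_unprod, 30)],
            "cdr3_aa": _random_cdr3(rng, n_unprod),
            "templates": 1 + rng.poisson(1.0, n_unprod),
            "productive": False,
        })
        reps[s] = Repertoire(
            sample_id=s,
            rows=pd.concat([rows, unprod], ignore_index=True),
            total_nucleated_cells=cfg.total_nucleated_cells,
        )
    return reps, excl_aa, shared_nt


# ---------------------------------------------------------------------------
# affinities


def simulate_affinities(truth: SimTruth, cfg: SimConfig, seed) -> pd.DataFrame:
    """Log-uniform IC50 affinities over the configured nM bounds.

    Affinity is mutation-intrinsic: each mutation draws a log-scale center
    shared by its peptides, so binder status travels with the mutation
    across tumors (the property the neoantigen-overlap analysis relies on).
    """
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(cfg.ic50_bounds_nm[0]), np.log10(cfg.ic50_bounds_nm[1])
    rows = []
    nonsil = truth.positions[truth.positions["effect"] != "silent"]
    for mid in nonsil["mutation_id"]:
        center = rng.uniform(lo, hi)
        for k in range(cfg.peptides_per_mutation):
            length = 9 if k % 2 == 0 else 10
            pep = "".join(rng.choice(_AA, size=length))
            log_ic50 = float(np.clip(center + rng.normal(0, 0.15), lo, hi))
            rows.append({
                "mutation_id": mid, "peptide": pep,
                "hla_allele": _HLA[int(rng.integers(len(_HLA)))],
                "ic50_nm": float(10 ** log_ic50),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylation and cell fractions


def simulate_methylation(
    cfg: SimConfig,
    truth: SimTruth,
    neo_mutations: set[str],
    latent_u: dict[str, float],
    latent_v: dict[str, float],
    seed,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, float]]:
    """Per-sample probe tables plus deconvolved cell fractions.

    Probe positions are array-like (shared across samples) and placed within
    the mapping window of every neoantigen-coding mutation.  Per sample, a
    target methylated fraction ``r_s`` is the copula transform of latent
    ``v``; a fraction ``r_s`` of covered mutations draws probes from a
    high-beta component (Beta(40,3)) and the rest from a low one
    (Beta(2,40)), so the realized methylated-neoantigen ratio tracks
    ``r_s``.  CD8 fractions increase with the repertoire latent.
    """
    rng = np.random.default_rng(seed)
    pos_df = truth.positions[truth.positions["mutation_id"].isin(neo_mutations)]
    probe_rows = []
    probe_counter = 0
    mut_probe_ids: dict[str, list[int]] = {}
    for row in pos_df.itertuples(index=False):
        ids = []
        for _ in range(cfg.probes_per_mutation):
            offset = int(rng.integers(-cfg.probe_offset_max, cfg.probe_offset_max + 1))
            probe_rows.append({
                "probe_id": f"cg{probe_counter:07d}", "chrom": row.chrom,
                "pos": max(1, row.pos + offset),
            })
            ids.append(probe_counter)
            probe_counter += 1
        mut_probe_ids[row.mutation_id] = ids
    for _ in range(cfg.n_background_probes):
        probe_rows.append({
            "probe_id": f"cg{probe_counter:07d}",
            "chrom": str(rng.integers(1, 23)),
            "pos": int(rng.integers(400_000_000, 500_000_000)),
        })
        probe_counter += 1
    layout = pd.DataFrame(probe_rows)

    probes_by_sample: dict[str, pd.DataFrame] = {}
    target_ratios: dict[str, float] = {}
    cf_rows = []
    for s in latent_v:
        r_s = _lerp(cfg.ratio_range, float(norm.cdf(latent_v[s])))
        target_ratios[s] = r_s
        beta = rng.beta(1.5, 15, size=len(layout))
        sample_muts = sorted(truth.sets_by_tumor.get(s, set()) & neo_mutations)
        # plant the methylated fraction: a random subset of exactly
        # round(r_s * n) covered mutations draws high-beta probes
        n_meth = int(round(r_s * len(sample_muts)))
        meth_ids = set(
            rng.choice(len(sample_muts), size=n_meth, replace=False).tolist()
        ) if sample_muts else set()
        for i, mid in enumerate(sample_muts):
            a, b = (40, 3) if i in meth_ids else (2, 40)
            for pi in mut_probe_ids[mid]:
                beta[pi] = rng.beta(a, b)
        df = layout.copy()
        df["beta"] = np.clip(beta, 0.0, 1.0)
        probes_by_sample[s] = df

        cd8 = 0.05 + 0.25 * float(norm.cdf(latent_u[s] + rng.normal(0, 0.3)))
        treg = 0.02 + 0.04 * float(rng.random())
        cf_rows.append({
            "sample_id": s, "cd8_t": cd8, "treg": treg,
            "others": max(0.0, 1 - cd8 - treg - float(rng.uniform(0.2, 0.5))),
        })
    return probes_by_sample, pd.DataFrame(cf_rows), target_ratios


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(cfg: SimConfig | None = None, seed: int = 0) -> SimulatedCohort:
    """Generate a full validated cohort plus its ground truth.

    Randomness flows from ``seed`` through ordered child streams (truth,
    latents, calls, repertoires, affinities, methylation), so cohorts are
    reproducible and stages can be regenerated independently.
    """
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(seed)
    s_truth, s_lat, s_calls, s_rep, s_aff, s_meth = ss.spawn(6)

    metas, truth = simulate_truth(cfg, s_truth)
    sample_ids = [m.sample_id for m in metas]
    latent_u, latent_v = sample_latents(cfg, sample_ids, s_lat)
    truth.latent_u, truth.latent_v = latent_u, latent_v

    calls = simulate_caller_calls(truth, cfg, s_calls)
    reps, excl_aa, shared_nt = simulate_repertoires(cfg, metas, latent_u, s_rep)
    truth.excluded_clonotypes_aa = excl_aa
    truth.shared_clones_nt = shared_nt

    affinities = simulate_affinities(truth, cfg, s_aff)
    binder_mutations = set(
        affinities.loc[affinities["ic50_nm"] < 500, "mutation_id"]
    )
    probes, cell_fractions, target_ratios = simulate_methylation(
        cfg, truth, binder_mutations, latent_u, latent_v, s_meth
    )
    truth.target_ratios = target_ratios

    cohort = Cohort(
        samples=metas, calls=calls, repertoires=reps, probes=probes,
        affinities=affinities, cell_fractions=cell_fractions,
    )
    validate_cohort(cohort)
    return SimulatedCohort(cohort=cohort, truth=truth, config=cfg, seed=seed)
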