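"""Correlation and group-comparison layer.

Continuous-vs-continuous associations use Spearman's rank correlation with
mid-ranks for ties and the two-sided t-approximation for p-values; two-group
contrasts use the rank-sum (Mann-Whitney) test and contrasts over three or
more levels the Kruskal-Wallis test with tie correction.  Pairwise-matrix
associations (TCR Jaccard vs neoantigen Jaccard) correlate the strict
upper-triangle vectors of both matrices; the observations are tumor pairs
and hence not independent, so a Mantel permutation p-value is available as
an alternative to the plain correlation reported by default.

No multiple-testing correction is applied by default (p < 0.05 taken as
significant); Benjamini-Hochberg adjustment is available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._sets import upper_triangle_pairs


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int
    flagged: bool = False


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation on complete pairs (n >= 3).

    A constant input vector leaves the correlation undefined; the result is
    flagged with NaN statistics rather than raising.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"spearman requires >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined", stacklevel=2)
        return CorrelationResult(np.nan, np.nan, n, flagged=True)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), n)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over >= 2 groups.

    Degenerate all-identical data returns H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis requires >= 2 nonempty groups")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def rank_sum(a, b) -> tuple[float, float]:
    """Two-sided rank-sum (Mann-Whitney U) test for a two-group contrast."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return float(len(a) * len(b) / 2), 1.0
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)


def mantel_p(
    mat_x: pd.DataFrame, mat_y: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> float:
    """Permutation p-value for the upper-triangle Spearman correlation of two
    labelled symmetric matrices, permuting sample labels jointly."""
    labels = list(mat_x.index)
    x = upper_triangle_pairs(mat_x).to_numpy()
    obs = spearman(x, upper_triangle_pairs(mat_y.loc[labels, labels]).to_numpy()).rho
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        y_perm = mat_y.loc[perm, perm]
        y_perm.index = labels
        y_perm.columns = labels
        r = spearman(x, upper_triangle_pairs(y_perm).to_numpy()).rho
        if abs(r) >= abs(obs):
            count += 1
    return (count + 1) / (n_perm + 1)


@dataclass
class AssociationInputs:
    """Bundle of upstream outputs consumed by :func:`metric_associations`.

    Any component may be None; the corresponding associations are reported
    as unavailable while the rest are still computed.
    """

    metrics: pd.DataFrame | None = None          # density/richness/clonality per sample
    tcr_ji: pd.DataFrame | None = None
    neo_ji: pd.DataFrame | None = None
    mutation_ji: pd.DataFrame | None = None
    cell_fractions: pd.DataFrame | None = None   # sample_id index, cd8_t / treg columns
    methylated_ratio: pd.Series | None = None
    metadata: pd.DataFrame | None = None         # sample_id index, 0/1 group flags


def _corr_row(name, x, y, n_required=3):
    try:
        res = spearman(x, y)
        direction = "positive" if res.rho > 0 else ("negative" if res.rho < 0 else "none")
        return {"association": name, "kind": "spearman", "n": res.n,
                "statistic": res.rho, "p": res.p, "direction": direction,
                "note": "flagged" if res.flagged else ""}
    except ValueError as e:
        return {"association": name, "kind": "spearman", "n": 0,
                "statistic": np.nan, "p": np.nan, "direction": "",
                "note": str(e)}


def _contrast_row(name, a, b):
    try:
        u, p = rank_sum(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        direction = (
            "higher_in_group" if med_a > med_b
            else ("lower_in_group" if med_a < med_b else "none")
        )
        return {"association": name, "kind": "rank_sum", "n": len(a) + len(b),
                "statistic": u, "p": p, "direction": direction, "note": ""}
    except ValueError as e:
        return {"association": name, "kind": "rank_sum", "n": 0,
                "statistic": np.nan, "p": np.nan, "direction": "", "note": str(e)}


def metric_associations(inputs: AssociationInputs, adjust: bool = False) -> pd.DataFrame:
    """Tidy table of every cohort-level association and group contrast.

    One row per association: variables, n, statistic, p, direction.
    Associations whose inputs are missing appear with a note; the rest are
    computed.  With ``adjust`` the p-values gain a Benjamini-Hochberg column.
    """
    rows = []
    m = inputs.metrics

    def missing(name, what):
        rows.append({"association": name, "kind": "", "n": 0,
                     "statistic": np.nan, "p": np.nan, "direction": "",
                     "note": f"missing input: {what}"})

    # metric inter-correlations
    metric_pairs = [
        ("density_vs_richness", "density", "richness"),
        ("density_vs_clonality", "density", "clonality"),
        ("richness_vs_clonality", "richness", "clonality"),
    ]
    for name, a, b in metric_pairs:
        if m is None:
            missing(name, "repertoire metrics")
        else:
            rows.append(_corr_row(name, m[a], m[b]))

    # pairwise-JI correlations (upper-triangle vectors, aligned label order)
    if inputs.tcr_ji is None or inputs.neo_ji is None:
        missing("tcr_ji_vs_neoantigen_ji", "TCR or neoantigen JI matrix")
    else:
        labels = list(inputs.tcr_ji.index)
        x = upper_triangle_pairs(inputs.tcr_ji)
        y = upper_triangle_pairs(inputs.neo_ji.loc[labels, labels])
        rows.append(_corr_row("tcr_ji_vs_neoantigen_ji", x.to_numpy(), y.to_numpy()))

    # cell-fraction correlations
    cf = inputs.cell_fractions
    if cf is None or m is None:
        missing("cd8_vs_richness", "cell fractions or metrics")
        missing("cd8_vs_clonality", "cell fractions or metrics")
        missing("cd8_treg_ratio_vs_richness", "cell fractions or metrics")
        missing("cd8_treg_ratio_vs_clonality", "cell fractions or metrics")
    else:
        joined = m.join(cf, how="inner")
        ratio = joined["cd8_t"] / joined["treg"].replace(0, np.nan)
        rows.append(_corr_row("cd8_vs_richness", joined["cd8_t"], joined["richness"]))
        rows.append(_corr_row("cd8_vs_clonality", joined["cd8_t"], joined["clonality"]))
        rows.append(_corr_row("cd8_treg_ratio_vs_richness", ratio, joined["richness"]))
        rows.append(_corr_row("cd8_treg_ratio_vs_clonality", ratio, joined["clonality"]))

    # methylated-neoantigen ratio correlations
    mr = inputs.methylated_ratio
    targets = [("density", m), ("richness", m), ("clonality", m)]
    if mr is None:
        for t, _ in targets:
            missing(f"methylated_ratio_vs_{t}", "methylated-neoantigen ratio")
        missing("methylated_ratio_vs_cd8", "methylated-neoantigen ratio")
    else:
        for t, src in targets:
            if src is None:
                missing(f"methylated_ratio_vs_{t}", "repertoire metrics")
            else:
                joined = pd.concat([mr.rename("ratio"), src[t]], axis=1).dropna()
                rows.append(_corr_row(f"methylated_ratio_vs_{t}",
                                      joined["ratio"], joined[t]))
        if cf is None:
            missing("methylated_ratio_vs_cd8", "cell fractions")
        else:
            joined = pd.concat([mr.rename("ratio"), cf["cd8_t"]], axis=1).dropna()
            rows.append(_corr_row("methylated_ratio_vs_cd8",
                                  joined["ratio"], joined["cd8_t"]))

    # anatomical group contrasts on the repertoire metrics
    meta = inputs.metadata
    contrasts = [
        ("thoracic", "is_thoracic"),
        ("lymph_node", "is_lymph_node"),
        ("left_thoracic", "is_left_thoracic"),
    ]
    if meta is None or m is None:
        for gname, _ in contrasts:
            for metric in ("density", "richness", "clonality"):
                missing(f"{gname}_contrast_{metric}", "metadata or metrics")
    else:
        joined = m.join(meta, how="inner")
        for gname, flag in contrasts:
            grp = joined[flag].astype(bool)
            for metric in ("density", "richness", "clonality"):
                name = f"{gname}_contrast_{metric}"
                if grp.all() or (~grp).all():
                    missing(name, f"both levels of {flag}")
                else:
                    rows.append(_contrast_row(
                        name, joined.loc[grp, metric], joined.loc[~grp, metric]
                    ))

    table = pd.DataFrame(rows)
    if adjust:
        from statsmodels.stats.multitest import multipletests

        ok = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                table.loc[ok, "p"], method="fdr_bh"
            )[1]
        table["p_adjusted"] = adj
    return table
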