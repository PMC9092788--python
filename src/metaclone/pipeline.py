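"""End-to-end orchestration: consensus -> phylogeny -> TCR -> neoantigen ->
methylation -> associations, with a reproducible output bundle.

Every stage is a pure function of (inputs, config, seed); the run manifest
records the configuration, seed and a SHA-256 checksum of every written
file, so two runs on the same cohort are byte-identical.  Missing inputs
degrade gracefully: stages whose inputs are absent are skipped and the
report marks their sections unavailable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import consensus as cons
from . import io as mio
from . import methylation as meth
from . import neoantigen as neo
from . import phylo
from . import stats as assoc
from . import tcr
from .consensus import FilterConfig
from .core import Cohort, validate_cohort


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    cohort: Cohort | str | Path,
    out_dir: str | Path,
    filter_config: FilterConfig | None = None,
    tree_mode: str = "nni",
    methylation_window_bp: int = 2000,
    seed: int = 0,
    top_k_clonotypes: int = 10,
) -> dict:
    """Run every available stage on a cohort (object or cohort directory).

    Returns the manifest dict; all tables, the germline-rooted newick, the
    Jaccard matrices, the associations table and a markdown report are
    written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not isinstance(cohort, Cohort):
        cohort = mio.read_cohort(cohort)
    validate_cohort(cohort)
    cfg = filter_config or FilterConfig()

    written: list[Path] = []
    report: list[str] = ["# metaclone run report", ""]
    inputs = assoc.AssociationInputs(metadata=cohort.meta_frame().set_index("sample_id"))
    final = None
    neo_sets = None
    positions = None

    def emit(df: pd.DataFrame, name: str, **kwargs):
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    # --- consensus ---------------------------------------------------------
    if cohort.calls is not None and len(cohort.calls):
        try:
            result = cons.run_consensus(cohort.calls, cfg)
            final = result.final
            matrix = cons.build_mutation_matrix(final, include_germline=True)
            summary = cons.sharing_summary(matrix)
            emit(result.stage_counts, "consensus_stage_counts.tsv", index=False)
            final_rows = pd.DataFrame(
                [
                    {"sample_id": t, "mutation_id": m}
                    for t in sorted(final) for m in sorted(final[t])
                ]
            )
            emit(final_rows, "final_calls.tsv", index=False)
            emit(matrix.presence, "mutation_matrix.tsv", index_label="sample_id")
            positions = (
                cohort.calls[["mutation_id", "chrom", "pos"]]
                .drop_duplicates("mutation_id")
            )
            report += [
                "## Mutation consensus",
                f"- {summary.total} mutations; {summary.shared_ge2} "
                f"({summary.pct_shared_ge2}%) shared by >= 2 tumors, "
                f"{summary.unique} ({summary.pct_unique}%) unique, "
                f"{summary.shared_all} truncal (all tumors).", "",
            ]
        except Exception as e:  # pragma: no cover - stage guard
            raise StageError("consensus", e)

        # --- phylogeny -----------------------------------------------------
        try:
            mut_ji = phylo.mutation_jaccard(matrix)
            inputs.mutation_ji = mut_ji
            emit(mut_ji, "mutation_jaccard.tsv", index_label="sample_id")
            tree = phylo.search_tree(matrix.presence, mode=tree_mode, seed=seed)
            (out / "tree.nwk").write_text(tree.newick + "\n")
            written.append(out / "tree.nwk")
            report += [
                "## Phylogeny",
                f"- germline-rooted maximum-parsimony tree, Fitch score "
                f"{tree.parsimony_score} ({tree_mode} search).", "",
            ]
        except Exception as e:
            raise StageError("phylo", e)
    else:
        report += ["## Mutation consensus", "- unavailable: no caller calls.", ""]

    # --- TCR repertoire ----------------------------------------------------
    if cohort.repertoires:
        try:
            metrics = tcr.metrics_table(cohort.repertoires)
            inputs.metrics = metrics
            emit(metrics, "tcr_metrics.tsv")
            tcr_ji = tcr.repertoire_jaccard_matrix(cohort.repertoires)
            inputs.tcr_ji = tcr_ji
            emit(tcr_ji, "tcr_jaccard.tsv", index_label="sample_id")
            shared, props, freqs = tcr.shared_across_all(cohort.repertoires)
            shared_df = pd.concat([props, freqs], axis=1)
            emit(shared_df, "tcr_shared_across_all.tsv", index_label="sample_id")
            candidates = tcr.prevalent_clonotypes(cohort.repertoires, top_k_clonotypes)
            excl = tcr.exclusion_report(
                cohort.repertoires, candidates, cohort.samples
            )
            emit(excl, "tcr_exclusion_report.tsv", index=False)
            primary = cohort.primary_id
            if primary and primary in cohort.repertoires:
                rows = []
                for s, rep in cohort.repertoires.items():
                    if s == primary:
                        continue
                    ov = tcr.primary_overlap(cohort.repertoires[primary], rep)
                    rows.append({"sample_id": s, **asdict(ov)})
                emit(pd.DataFrame(rows), "tcr_primary_overlap.tsv", index=False)
            n_excl = int(excl["excluded"].sum()) if len(excl) else 0
            report += [
                "## TCR repertoire",
                f"- density {metrics['density'].min():.3f}-{metrics['density'].max():.3f}, "
                f"richness {metrics['richness'].min()}-{metrics['richness'].max()}, "
                f"clonality {metrics['clonality'].min():.3f}-{metrics['clonality'].max():.3f}.",
                f"- {len(shared)} clonotypes shared across all tumors; "
                f"{n_excl} prevalent clonotypes spatially excluded.", "",
            ]
        except Exception as e:
            raise StageError("tcr", e)
    else:
        report += ["## TCR repertoire", "- unavailable: no repertoires.", ""]

    # --- neoantigens -------------------------------------------------------
    if cohort.affinities is not None and final is not None:
        try:
            classified = neo.classify_binders(cohort.affinities)
            neo_sets, strong_sets, counts = neo.neoantigen_sets(classified, final)
            emit(counts, "neoantigen_counts.tsv")
            neo_ji = neo.neoantigen_jaccard(neo_sets)
            inputs.neo_ji = neo_ji
            emit(neo_ji, "neoantigen_jaccard.tsv", index_label="sample_id")
            report += [
                "## Neoantigens",
                f"- mean {counts['n_neoantigen_mutations'].mean():.1f} "
                "neoantigen-coding mutations per tumor (IC50 < 500 nM), "
                f"{counts['n_strong_neoantigen_mutations'].mean():.1f} strong "
                "(IC50 < 50 nM).", "",
            ]
        except Exception as e:
            raise StageError("neoantigen", e)
    else:
        report += ["## Neoantigens", "- unavailable: no affinities or consensus.", ""]

    # --- methylation -------------------------------------------------------
    if cohort.probes and neo_sets is not None and positions is not None:
        try:
            ratios = meth.ratio_table(
                cohort.probes, neo_sets, positions, methylation_window_bp
            )
            inputs.methylated_ratio = ratios["methylated_neoantigen_ratio"]
            emit(ratios, "methylated_neoantigen_ratio.tsv")
            report += [
                "## Methylation",
                f"- methylated-neoantigen ratio "
                f"{ratios['methylated_neoantigen_ratio'].min():.2f}-"
                f"{ratios['methylated_neoantigen_ratio'].max():.2f}.", "",
            ]
        except Exception as e:
            raise StageError("methylation", e)
    else:
        report += ["## Methylation", "- unavailable: no probes or neoantigen sets.", ""]

    # --- associations ------------------------------------------------------
    if cohort.cell_fractions is not None:
        inputs.cell_fractions = cohort.cell_fractions.set_index("sample_id")
    try:
        table = assoc.metric_associations(inputs)
        emit(table, "associations.tsv", index=False)
        sig = table[(table["p"] < 0.05)]
        report += [
            "## Associations",
            f"- {len(sig)} of {int(table['p'].notna().sum())} computed "
            "associations significant at p < 0.05.", "",
        ]
    except Exception as e:
        raise StageError("associations", e)

    report_path = out / "report.md"
    report_path.write_text("\n".join(report))
    written.append(report_path)

    manifest = {
        "seed": seed,
        "tree_mode": tree_mode,
        "methylation_window_bp": methylation_window_bp,
        "filter_config": asdict(cfg),
        "checksums": {p.name: _sha256(p) for p in sorted(written)},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
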