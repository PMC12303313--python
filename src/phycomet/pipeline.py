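"""End-to-end orchestration of the co-culture metabolomics analysis.

Stage order mirrors the analysis graph: preprocessing (log transform,
presence cutoff) -> chemodiversity and ordination (including the
combined-monoculture comparison) -> PLS-VIP selection per (species,
compartment) contrast -> inclusion-list/annotation linking -> MSI tally ->
suspect screen -> exchange inference -> growth statistics.  Every stage's
parameters are echoed into a machine-readable JSON report so each documented
default (log base, quantile type, majority fraction, ppm tolerance) is
auditable per run; optional inputs degrade to explicit ``skipped`` stage
status.  Re-running on identical inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation_linking as al
from . import diversity as dv
from . import exchange as ex
from . import growth_stats as gs
from . import preprocess as pp
from . import pls_select as ps
from . import synthetic as syn
from .errors import PhycometError
from .tables_io import (
    FeatureTable,
    GrowthSeries,
    PhenoData,
    SuspectEntry,
    check_samples_covered,
)

SCHEMA_VERSION = "1.0"
REPORT_STAGES = (
    "preprocess", "diversity", "ordination", "selection",
    "linking", "msi_tally", "suspects", "exchange", "growth",
)


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run (echoed verbatim into the report)."""

    cutoff_q: float = 0.05
    log_base: float = 2.0
    pls_components: int = 5
    pls_tune_length: int = 10
    pls_quantile: float = 0.95
    pls_folds: int = 5
    min_fraction: float = 0.5
    ppm_tolerance: float = 5.0
    anova_alpha: float = 0.05
    diversity_pooling: str = "union"
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineInputs:
    table: FeatureTable
    pheno: PhenoData
    growth: list[GrowthSeries] | None = None
    inclusion: list[al.InclusionEntry] | None = None
    annotations: list[al.AnnotationRecord] | None = None
    suspects: list[SuspectEntry] | None = None
    truth: syn.SyntheticTruth | None = None


def synthetic_inputs(
    gen_config: syn.GeneratorConfig | None = None,
    seed: int = 0,
    fragmented_fraction: float = 0.3,
) -> PipelineInputs:
    """Build a full synthetic input bundle (feature table, phenodata,
    inclusion list, annotations, suspect list, growth curves)."""
    cfg = gen_config or syn.GeneratorConfig(design_seed=seed, noise_seed=seed + 1)
    table, pheno, truth = syn.generate_feature_dataset(cfg)
    inclusion, annotations = syn.generate_inclusion_and_annotations(
        table, truth, fraction=fragmented_fraction, seed=seed + 2, polarity=cfg.polarity
    )
    # diatom suppressed throughout; haptophyte unaffected except a modest
    # day-8 increase (~2.5 x the replicate noise sd, so the overall condition
    # effect stays below the per-day one)
    growth = syn.generate_growth_curves(
        suppression=0.7, species="SM", seed=seed + 3
    ) + syn.generate_growth_curves(
        suppression=1.0, late_factor=1.1, late_from_day=8, species="PP", seed=seed + 4
    )
    truth.growth_effect = {"SM": 0.7, "PP": 1.0}
    suspects = syn.synthetic_suspect_list(seed=seed + 5)
    return PipelineInputs(table=table, pheno=pheno, growth=growth,
                          inclusion=inclusion, annotations=annotations,
                          suspects=suspects, truth=truth)


def run_pipeline(
    inputs: PipelineInputs,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Execute all stages; return the report dict and optionally write the
    report bundle (JSON + per-stage TSVs) to ``out_dir``."""
    config = config or PipelineConfig()
    check_samples_covered(inputs.table, inputs.pheno)
    report: dict = {"schema_version": SCHEMA_VERSION, "parameters": config.to_dict()}
    tables: dict[str, pd.DataFrame] = {}

    # -- preprocess: one cutoff per compartment dataset ---------------------
    transformed = pp.log_transform(inputs.table, base=config.log_base)
    ph = inputs.pheno.table
    cutoffs: dict[str, float] = {}
    presence_blocks = []
    for comp in sorted(ph["compartment"].unique()):
        cols = [s for s in transformed.sample_ids if ph.loc[s, "compartment"] == comp]
        sub = transformed.subset_samples(cols)
        cutoff = pp.estimate_presence_cutoff(sub.intensities, q=config.cutoff_q)
        cutoffs[comp] = cutoff
        presence_blocks.append(pp.to_presence_matrix(sub, cutoff, q=config.cutoff_q).matrix)
    presence = pp.PresenceMatrix(
        pd.concat(presence_blocks, axis=1)[list(inputs.table.sample_ids)],
        cutoff=float(np.mean(list(cutoffs.values()))),
        cutoff_method="normal lower-tail, fitted per compartment dataset",
        q=config.cutoff_q,
    )
    report["preprocess"] = {
        "status": "ok", "cutoffs": cutoffs, "q": config.cutoff_q,
        "log_base": config.log_base,
        "n_features": int(len(inputs.table.feature_ids)),
        "n_samples": int(len(inputs.table.sample_ids)),
    }

    # -- diversity ----------------------------------------------------------
    div = dv.group_diversity(presence, inputs.pheno, pooling=config.diversity_pooling)
    div_df = dv.diversity_frame(div)
    tables["diversity"] = div_df
    report["diversity"] = {"status": "ok",
                           "records": div_df.to_dict(orient="records")}

    # -- ordination: all-sample PCA and combined-mono comparison ------------
    exo_samples = [s for s in transformed.sample_ids if ph.loc[s, "compartment"] == "exo"]
    pca_all = dv.pca(transformed.intensities[exo_samples].T, n_components=2)
    polarity = ph["polarity"].iloc[0]
    comb_blocks, comb_labels = [], []
    for sp in ("SM", "PP"):
        pseudo, _ = pp.combine_monoculture_pairs(inputs.table, inputs.pheno,
                                                 sp, "exo", polarity)
        pseudo_t = pp.log_transform(pseudo, base=config.log_base)
        comb_blocks.append(pseudo_t.intensities)
        comb_labels += ["combined-mono"] * pseudo_t.intensities.shape[1]
        co_cols = inputs.pheno.samples_for(species=sp, compartment="exo", culture="co")
        comb_blocks.append(transformed.intensities[co_cols])
        comb_labels += [f"{sp}-co"] * len(co_cols)
    comb_matrix = pd.concat(comb_blocks, axis=1)
    pca_comb = dv.pca(comb_matrix.T, n_components=2)
    report["ordination"] = {
        "status": "ok",
        "all_exo_explained": [float(v) for v in pca_all.explained_fraction],
        "combined_mono_explained": [float(v) for v in pca_comb.explained_fraction],
        "combined_mono_labels": comb_labels,
    }
    scores = pca_comb.scores.copy()
    scores.insert(0, "group", comb_labels)
    scores.insert(0, "sample_id", scores.index)
    tables["pca_combined_mono_scores"] = scores.reset_index(drop=True)

    # -- PLS selection per (species, compartment) ---------------------------
    selections: dict[tuple[str, str], ps.SelectionResult] = {}
    sel_summary = {}
    for sp in ("SM", "PP"):
        for comp in ("endo", "exo"):
            cols = inputs.pheno.samples_for(species=sp, compartment=comp)
            X = transformed.intensities[cols].T
            labels = ph.loc[cols, "culture"]
            sel = ps.select_features(
                X, labels,
                components=config.pls_components,
                tune_length=config.pls_tune_length,
                quantile=config.pls_quantile,
                folds=config.pls_folds,
                seed=config.seed,
            )
            selections[(sp, comp)] = sel
            key = f"{sp}_{comp}"
            sel_summary[key] = {
                "n_selected": len(sel.selected),
                "n_co_enriched": int((sel.direction == "co-enriched").sum()),
                "threshold": sel.threshold,
                "n_components": sel.n_components,
            }
            tables[f"selection_{key}"] = pd.DataFrame({
                "feature_id": sel.selected,
                "VIP": sel.vip.loc[sel.selected].to_numpy(),
                "threshold": sel.threshold,
                "direction": sel.direction.to_numpy(),
                "condition": key,
            })
    report["selection"] = {"status": "ok", "contrasts": sel_summary}

    # -- linking / tally / suspects ----------------------------------------
    if inputs.inclusion is None:
        report["linking"] = {"status": "skipped", "reason": "no inclusion list"}
        report["msi_tally"] = {"status": "skipped", "reason": "no inclusion list"}
        linked = None
    else:
        link_map = al.link_inclusion_to_features(inputs.inclusion, inputs.table)
        status_counts = pd.Series([r.match_status for r in link_map]).value_counts()
        report["linking"] = {"status": "ok",
                             "n_inclusion": len(link_map),
                             "match_status_counts": status_counts.to_dict()}
        if inputs.annotations is None:
            report["msi_tally"] = {"status": "skipped", "reason": "no annotations"}
            linked = None
        else:
            linked = al.link_annotations_to_features(
                inputs.annotations, link_map, ppm_tolerance=config.ppm_tolerance
            )
            species_sets = {
                sp: set().union(*(selections[(sp, c)].selected for c in ("endo", "exo")))
                for sp in ("SM", "PP")
            }
            tally = al.tally_msi_levels(linked, selections=species_sets)
            tables["msi_tally"] = tally.reset_index()
            report["msi_tally"] = {"status": "ok",
                                   "table": tally.reset_index().to_dict(orient="records")}
            tables["linked_annotations"] = pd.DataFrame([
                {"precursor_mz": la.record.precursor_mz, "rt": la.record.rt,
                 "name": la.record.name, "msi_level": la.record.msi_level,
                 "feature_id": la.feature_id or "", "match_status": la.match_status,
                 "comment": la.comment}
                for la in linked
            ])
    if linked is None or inputs.suspects is None:
        report["suspects"] = {"status": "skipped", "reason": "no annotations or suspect list"}
    else:
        matches = al.screen_suspects(linked, inputs.suspects)
        report["suspects"] = {
            "status": "ok",
            "n_matches": len(matches),
            "by_level": pd.Series([m.level for m in matches]).value_counts().to_dict(),
            "by_source": pd.Series([m.source_species for m in matches]).value_counts().to_dict(),
        }

    # -- exchange inference -------------------------------------------------
    cond_presence = ex.condition_presence(presence, inputs.pheno,
                                          min_fraction=config.min_fraction)
    cross_tab = {}
    for sp in ("SM", "PP"):
        sel = selections[(sp, "endo")]
        diff_co = [f for f in sel.selected if sel.direction.loc[f] == "co-enriched"]
        results = ex.classify_exchange(diff_co, cond_presence, focal=sp)
        summary = ex.summarize_exchange(results)
        cross_tab[sp] = summary["count"].to_dict()
        tables[f"exchange_{sp}"] = ex.exchange_frame(results)
    report["exchange"] = {"status": "ok", "cross_tab": cross_tab}

    # -- growth statistics --------------------------------------------------
    if inputs.growth is None:
        report["growth"] = {"status": "skipped", "reason": "no growth series"}
    else:
        stats_tables = gs.growth_statistics(inputs.growth, alpha=config.anova_alpha)
        growth_section: dict = {"status": "ok"}
        for name, tab in stats_tables.items():
            tables[name] = tab.reset_index()
            if name.startswith("anova"):
                growth_section[f"{name}_condition_p"] = float(tab.loc["sample", "p"])
            else:
                growth_section[f"{name}_p_by_day"] = {
                    str(day): float(p) for day, p in tab["p"].items()
                }
        report["growth"] = growth_section

    if out_dir is not None:
        write_report(report, tables, out_dir)
    return report


def write_report(report: dict, tables: dict[str, pd.DataFrame],
                 out_dir: str | Path) -> None:
    """Write report.json plus one TSV per stage table; deterministic bytes."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # pragma: no cover
        raise PhycometError(f"cannot create output directory {out}: {e}") from e
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    for name in sorted(tables):
        tables[name].to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def validate_report(report: dict) -> None:
    """Check the report against the shipped stage schema."""
    if report.get("schema_version") != SCHEMA_VERSION:
        raise PhycometError(f"schema_version mismatch: {report.get('schema_version')}")
    missing = [s for s in REPORT_STAGES if s not in report]
    if missing:
        raise PhycometError(f"report missing stage section(s): {missing}")
    for s in REPORT_STAGES:
        if "status" not in report[s]:
            raise PhycometError(f"stage {s} lacks a status field")
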