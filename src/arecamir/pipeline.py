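"""End-to-end orchestration of the screening pipeline.

Stages: exposure panel -> cohort panel -> concordance integration and
signature selection -> target consensus voting -> pathway enrichment with
phenotype-module rollup.  Every published cutoff is a ``RunConfig``
default, never hard-coded downstream, and the resolved configuration is
written into each output bundle for provenance.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import ane, cohort, enrich, integrate, targets
from .io import ExpressionMatrix, load_panel_table, write_gmt
from .simulate import SimConfig, simulate_ane_experiment, simulate_cohort, simulate_gmt, simulate_target_sources

log = logging.getLogger("arecamir")


@dataclass(frozen=True)
class RunConfig:
    """Published cutoffs and run flags."""

    ane_fr: float = 1.2
    cohort_fr: float = 1.2
    alpha: float = 0.05
    signature: float = 2.0
    strict: bool = True
    min_votes: int = 4
    calibrate_purity: bool = True
    ease: bool = False
    bh: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ane_fr", "cohort_fr", "alpha", "signature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _write_config(config: RunConfig, out_dir: Path) -> None:
    with open(out_dir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def run_pipeline(
    out_dir: str | Path,
    ane_matrix: ExpressionMatrix,
    cohort_matrix: ExpressionMatrix,
    source_tables: list[pd.DataFrame],
    gmt: dict[str, list[str]],
    config: RunConfig = RunConfig(),
) -> dict:
    """Run every stage on in-memory inputs and write a report bundle.

    Returns a summary dict with the per-stage record counts and the key
    derived sets (OncomiRs, TSmiRs, signatures, consensus targets,
    enriched pathways with module rollup).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_config(config, out_dir)

    ane_panel = ane.build_ane_panel(ane_matrix, threshold=config.ane_fr)
    ane_panel.write(out_dir / "ane_panel.tsv")
    log.info("exposure panel: %d miRNAs, %d up, %d down, %d discordant",
             len(ane_panel.table), len(ane_panel.up_any), len(ane_panel.down_any),
             len(ane_panel.discordant))

    cohort_panel = cohort.build_cohort_panel(
        cohort_matrix,
        fr_threshold=config.cohort_fr,
        alpha=config.alpha,
        calibrate_purity=config.calibrate_purity,
        bh=config.bh,
    )
    cohort_panel.write(out_dir / "cohort_panel.tsv")
    log.info("cohort panel: %d selected (%d over, %d under)",
             len(cohort_panel.selected), len(cohort_panel.overexpressed),
             len(cohort_panel.underexpressed))

    oncomirs, tsmirs = integrate.intersect_panels(
        ane_panel.up_any,
        ane_panel.down_any,
        cohort_panel.overexpressed,
        cohort_panel.underexpressed,
        ane_table=ane_panel.table,
        cohort_table=cohort_panel.table,
    )
    onco_frame = integrate.records_to_panel_frame(oncomirs)
    ts_frame = integrate.records_to_panel_frame(tsmirs)
    for name, frame in (("oncomir_panel.tsv", onco_frame), ("tsmir_panel.tsv", ts_frame)):
        if len(frame):
            integrate.render_panel_table(frame).to_csv(out_dir / name, sep="\t", index=False)
        else:
            (out_dir / name).write_text("mirna\ttn_fr\tp\tavg_fc\n")

    signatures = {
        "oncomir": integrate.select_signatures(oncomirs, config.signature, config.strict),
        "tsmir": integrate.select_signatures(tsmirs, config.signature, config.strict),
    }
    pd.DataFrame(
        [{"mirna": m, "cls": cls} for cls, ms in signatures.items() for m in ms]
    ).to_csv(out_dir / "signatures.tsv", sep="\t", index=False)
    log.info("integration: %d OncomiRs (%d signature), %d TSmiRs (%d signature)",
             len(oncomirs), len(signatures["oncomir"]), len(tsmirs), len(signatures["tsmir"]))

    hub_mirnas = signatures["tsmir"] or [r.mirna for r in tsmirs]
    assertions = targets.load_sources(source_tables)
    edges = (
        targets.consensus_vote(assertions, hub_mirnas, config.min_votes)
        if hub_mirnas
        else []
    )
    targets.export_network(edges, out_dir / "consensus_network.tsv")
    gene_counts = targets.union_targets(edges)
    gene_counts.to_csv(out_dir / "target_genes.tsv", sep="\t", index_label="gene")
    log.info("targets: %d consensus edges over %d genes", len(edges), len(gene_counts))

    statistic = "ease" if config.ease else "hypergeometric"
    records = (
        enrich.run_ora(list(gene_counts.index), gmt, statistic=statistic)
        if len(gene_counts)
        else []
    )
    enrich.records_frame(records).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
    rollup = enrich.module_rollup(records)

    summary = {
        "n_mirnas": int(len(ane_panel.table)),
        "ane_up_any": len(ane_panel.up_any),
        "ane_down_any": len(ane_panel.down_any),
        "ane_common_up": len(ane_panel.common_up),
        "ane_common_down": len(ane_panel.common_down),
        "ane_discordant": len(ane_panel.discordant),
        "cohort_selected": len(cohort_panel.selected),
        "cohort_over": len(cohort_panel.overexpressed),
        "cohort_under": len(cohort_panel.underexpressed),
        "n_oncomirs": len(oncomirs),
        "n_tsmirs": len(tsmirs),
        "oncomir_signatures": signatures["oncomir"],
        "tsmir_signatures": signatures["tsmir"],
        "n_consensus_edges": len(edges),
        "n_target_genes": int(len(gene_counts)),
        "n_enriched_pathways": len(records),
        "module_rollup": rollup,
    }
    with open(out_dir / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary


def run_synthetic_pipeline(
    out_dir: str | Path,
    sim: SimConfig = SimConfig(),
    config: RunConfig = RunConfig(),
) -> tuple[dict, dict]:
    """Generate all inputs synthetically and run the full pipeline.

    The exposure and cohort experiments share planted miRNA names for the
    first planted features, so concordant OncomiRs/TSmiRs exist by
    construction.  Returns (summary, truth maps per stage).
    """
    ane_m, ane_truth = simulate_ane_experiment(sim)
    coh_m, coh_truth = simulate_cohort(sim)

    # align cohort feature names with the exposure experiment so that the
    # planted common-up/down miRNAs are concordant across both screens
    renames = {}
    ane_names = list(ane_m.features)
    coh_names = list(coh_m.features)
    n_shared_up = min(sim.n_common_up, sim.cohort_n_up)
    n_shared_down = min(sim.n_common_down, sim.cohort_n_down)
    for i in range(n_shared_up):
        renames[coh_names[i]] = ane_names[i]
    for i in range(n_shared_down):
        renames[coh_names[sim.cohort_n_up + i]] = ane_names[sim.n_common_up + i]
    coh_m.values.rename(index=renames, inplace=True)
    coh_truth.cohort_de = {renames.get(k, k): v for k, v in coh_truth.cohort_de.items()}

    planted_onco = {renames.get(n, n) for n in coh_names[:n_shared_up]}
    planted_ts = {
        renames[coh_names[sim.cohort_n_up + i]] for i in range(n_shared_down)
    }

    source_tables, target_truth = simulate_target_sources(
        sim, mirnas=sorted(planted_ts) or None
    )
    query_genes = sorted({g for _, g in target_truth.consensus_edges})
    gmt, gmt_truth = simulate_gmt(sim, query_genes=query_genes)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gmt(gmt, out_dir / "pathways.gmt")

    summary = run_pipeline(out_dir, ane_m, coh_m, source_tables, gmt, config)
    truths = {
        "ane": ane_truth,
        "cohort": coh_truth,
        "targets": target_truth,
        "gmt": gmt_truth,
        "planted_oncomirs": planted_onco,
        "planted_tsmirs": planted_ts,
    }
    return summary, truths


def integrate_published_tables(
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Integrate the packaged published panel tables.

    Recomputes the ratio-scale average fold-regulation per row and applies
    two-axis signature selection; returns the integrated frame and the
    signature lists per class.
    """
    combined = integrate.integrate_panel_tables(
        load_panel_table("oncomir"), load_panel_table("tsmir")
    )
    signatures = {
        cls: integrate.select_signatures(
            combined[combined["cls"] == cls], config.signature, config.strict
        )
        for cls in ("OncomiR", "TSmiR")
    }
    return combined, signatures
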