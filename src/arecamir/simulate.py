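"""Synthetic-data generators with stored ground truth.

Every input the screening pipeline consumes can be emulated at desk
scale: paired isogenic cell-line experiments with planted multiplicative
exposure effects, tumor/normal cohorts where the observed tumor signal is
a purity-weighted mixture of tumor-intrinsic and normal profiles,
multi-source target-assertion tables with a planted consensus core, and
GMT collections with one planted enriched pathway.  Each generator is
deterministic given its seed and returns the planted truth alongside the
data, so recovery can be scored exactly.

Microarray-style intensities are modelled as log-normal: a per-miRNA
baseline times a multiplicative planted effect times exp(N(0, sigma))
noise, with optional per-chip scale factors emulating batch effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

VALIDATED_SOURCES = ("miRecords", "miRTarBase", "TarBase")
PREDICTED_SOURCES = (
    "DIANA-microT-CDS",
    "ElMMo",
    "MicroCosm",
    "miRanda",
    "miRDB",
    "PicTar",
    "PITA",
    "TargetScan",
)
ALL_SOURCES = VALIDATED_SOURCES + PREDICTED_SOURCES


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for all generators.

    Paired-line defaults mirror a two-line screening array (hundreds of
    probes, effects around 2-fold, log-scale noise sigma 0.1, a handful
    of replicates); cohort defaults keep the ~10:1 tumor:normal imbalance
    of public head-and-neck cohorts at desk scale (40 vs 10) with purity
    drawn from Beta(8, 2); target sources mirror an 11-database snapshot
    with a 4-vote consensus core.
    """

    seed: int = 0
    # paired cell-line experiment
    n_mirnas: int = 500
    lines: tuple[str, ...] = ("OECM1", "SAS")
    replicates: int = 3
    noise_sigma: float = 0.1
    effect: float = 2.0
    n_common_up: int = 40
    n_common_down: int = 40
    n_discordant: int = 10
    chip_scale_sigma: float = 0.3
    # tumor/normal cohort
    cohort_n_mirnas: int = 300
    n_tumors: int = 40
    n_normals: int = 10
    cohort_n_up: int = 30
    cohort_n_down: int = 30
    cohort_effect: float = 2.0
    purity_alpha: float = 8.0
    purity_beta: float = 2.0
    # target sources
    n_sources: int = 11
    core_size: int = 50
    noise_edges: int = 150
    min_votes: int = 4
    # gene sets
    n_pathways: int = 20
    pathway_size: int = 40
    universe_size: int = 1000
    enrichment_odds: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.chip_scale_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.effect < 1 or self.cohort_effect < 1:
            raise ValueError("planted effects are ratios >= 1; direction is separate")
        if self.n_sources < self.min_votes:
            raise ValueError("need at least min_votes sources")
        planted = self.n_common_up + self.n_common_down + self.n_discordant
        if planted > self.n_mirnas:
            raise ValueError("more planted miRNAs than features")
        if self.cohort_n_up + self.cohort_n_down > self.cohort_n_mirnas:
            raise ValueError("more planted cohort effects than features")


@dataclass
class SimulationTruth:
    """Planted ground truth for a generator call."""

    planted_up: set[str] = field(default_factory=set)
    planted_down: set[str] = field(default_factory=set)
    planted_discordant: set[str] = field(default_factory=set)
    effect_sizes: dict = field(default_factory=dict)
    cohort_de: dict = field(default_factory=dict)  # mirna -> signed effect
    purity: dict = field(default_factory=dict)  # sample -> (0, 1]
    scale_factors: dict = field(default_factory=dict)  # sample -> chip scale
    consensus_edges: set = field(default_factory=set)  # (mirna, gene)
    enriched_pathway: str | None = None


def _mirna_names(n: int, prefix: str = "miR-sim") -> list[str]:
    return [f"{prefix}-{i:04d}" for i in range(n)]


def simulate_ane_experiment(
    cfg: SimConfig = SimConfig(), seed: int | None = None
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Paired parental/exposed experiment with planted exposure effects.

    The first planted miRNAs are common-up (shared effect in every line),
    the next common-down, then discordant (up in the first line, down in
    the second).  Per-chip scale factors are planted and stored so
    normalization recovery can be checked.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = _mirna_names(cfg.n_mirnas)
    truth = SimulationTruth()
    n_up, n_dn, n_disc = cfg.n_common_up, cfg.n_common_down, cfg.n_discordant
    truth.planted_up = set(names[:n_up])
    truth.planted_down = set(names[n_up : n_up + n_dn])
    truth.planted_discordant = set(names[n_up + n_dn : n_up + n_dn + n_disc])

    # per-(miRNA, line) multiplier applied to the exposed condition
    multiplier = pd.DataFrame(1.0, index=names, columns=list(cfg.lines))
    for name in truth.planted_up:
        multiplier.loc[name, :] = cfg.effect
        truth.effect_sizes[name] = cfg.effect
    for name in truth.planted_down:
        multiplier.loc[name, :] = 1.0 / cfg.effect
        truth.effect_sizes[name] = cfg.effect
    for name in truth.planted_discordant:
        multiplier.loc[name, cfg.lines[0]] = cfg.effect
        multiplier.loc[name, cfg.lines[1]] = 1.0 / cfg.effect
        truth.effect_sizes[name] = cfg.effect

    baseline = np.exp(rng.normal(np.log(500.0), 1.0, size=cfg.n_mirnas))
    columns, data, ann_rows = [], [], []
    for line in cfg.lines:
        for condition in ("parental", "exposed"):
            for rep in range(cfg.replicates):
                sample = f"{line}_{condition}_{rep}"
                eff = multiplier[line].to_numpy() if condition == "exposed" else 1.0
                scale = float(np.exp(rng.normal(0.0, cfg.chip_scale_sigma)))
                noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=cfg.n_mirnas))
                data.append(baseline * eff * noise * scale)
                columns.append(sample)
                ann_rows.append({"sample": sample, "cell_line": line, "condition": condition})
                truth.scale_factors[sample] = scale
    values = pd.DataFrame(np.column_stack(data), index=names, columns=columns)
    ann = pd.DataFrame(ann_rows).set_index("sample")
    return ExpressionMatrix(values, ann), truth


def simulate_cohort(
    cfg: SimConfig = SimConfig(), seed: int | None = None
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Tumor/normal cohort with purity-diluted planted effects.

    Observed tumor signal is purity * tumor-intrinsic + (1 - purity) *
    normal profile, with multiplicative log-normal noise on top; purity is
    Beta-distributed per tumor and stored both in the truth and as a
    sample annotation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = _mirna_names(cfg.cohort_n_mirnas, "miR-coh")
    truth = SimulationTruth()
    effect = np.ones(cfg.cohort_n_mirnas)
    for i in range(cfg.cohort_n_up):
        effect[i] = cfg.cohort_effect
        truth.cohort_de[names[i]] = cfg.cohort_effect
    for i in range(cfg.cohort_n_up, cfg.cohort_n_up + cfg.cohort_n_down):
        effect[i] = 1.0 / cfg.cohort_effect
        truth.cohort_de[names[i]] = -cfg.cohort_effect

    normal_profile = np.exp(rng.normal(np.log(500.0), 1.0, size=cfg.cohort_n_mirnas))
    tumor_profile = normal_profile * effect

    columns, data, ann_rows = [], [], []
    purities = np.clip(
        rng.beta(cfg.purity_alpha, cfg.purity_beta, size=cfg.n_tumors), 0.05, 1.0
    )
    for j in range(cfg.n_tumors):
        sample = f"tumor_{j:03d}"
        p = float(purities[j])
        mean = p * tumor_profile + (1.0 - p) * normal_profile
        noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=cfg.cohort_n_mirnas))
        data.append(mean * noise)
        columns.append(sample)
        ann_rows.append({"sample": sample, "tissue": "tumor", "purity": p})
        truth.purity[sample] = p
    for j in range(cfg.n_normals):
        sample = f"normal_{j:03d}"
        noise = np.exp(rng.normal(0.0, cfg.noise_sigma, size=cfg.cohort_n_mirnas))
        data.append(normal_profile * noise)
        columns.append(sample)
        ann_rows.append({"sample": sample, "tissue": "normal", "purity": np.nan})
    values = pd.DataFrame(np.column_stack(data), index=names, columns=columns)
    ann = pd.DataFrame(ann_rows).set_index("sample")
    return ExpressionMatrix(values, ann), truth


def simulate_target_sources(
    cfg: SimConfig = SimConfig(),
    mirnas: list[str] | None = None,
    seed: int | None = None,
) -> tuple[list[pd.DataFrame], SimulationTruth]:
    """Multi-source target-assertion tables with a planted consensus core.

    Core edges appear in at least ``cfg.min_votes`` randomly chosen
    sources; noise edges appear in at most ``cfg.min_votes - 1``, so a
    vote at the consensus threshold separates the two exactly.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sources = list(ALL_SOURCES[: cfg.n_sources])
    if len(sources) < cfg.n_sources:
        sources += [f"predicted_extra_{i}" for i in range(cfg.n_sources - len(sources))]
    if mirnas is None:
        mirnas = [f"miR-net-{i:03d}" for i in range(8)]
    genes = [f"GENE{i:04d}" for i in range(cfg.universe_size)]

    n_pairs = cfg.core_size + cfg.noise_edges
    gene_pick = rng.choice(cfg.universe_size, size=n_pairs, replace=False)
    mirna_pick = rng.integers(0, len(mirnas), size=n_pairs)
    pairs = [(mirnas[m], genes[g]) for m, g in zip(mirna_pick, gene_pick)]
    core, noise = pairs[: cfg.core_size], pairs[cfg.core_size :]

    truth = SimulationTruth(consensus_edges=set(core))
    rows: dict[str, list] = {s: [] for s in sources}
    for mirna, gene in core:
        votes = int(rng.integers(cfg.min_votes, cfg.n_sources + 1))
        for s_idx in rng.choice(len(sources), size=votes, replace=False):
            rows[sources[s_idx]].append((mirna, gene))
    for mirna, gene in noise:
        votes = int(rng.integers(1, cfg.min_votes))
        for s_idx in rng.choice(len(sources), size=votes, replace=False):
            rows[sources[s_idx]].append((mirna, gene))

    tables = []
    for s in sources:
        evidence = "validated" if s in VALIDATED_SOURCES else "predicted"
        tables.append(
            pd.DataFrame(
                [
                    {"source": s, "mirna": m, "gene": g, "evidence": evidence}
                    for m, g in sorted(rows[s])
                ],
                columns=["source", "mirna", "gene", "evidence"],
            )
        )
    return tables, truth


def simulate_gmt(
    cfg: SimConfig = SimConfig(),
    query_genes: list[str] | None = None,
    seed: int | None = None,
) -> tuple[dict[str, list[str]], SimulationTruth]:
    """GMT collection with one pathway enriched for the query genes.

    The enriched pathway samples genes with weight ``enrichment_odds`` on
    query genes versus 1 elsewhere (odds 1 reduces to a decoy); decoys
    are uniform draws from the universe.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    universe = [f"GENE{i:04d}" for i in range(cfg.universe_size)]
    if query_genes is None:
        query_genes = list(rng.choice(universe, size=80, replace=False))
    query = set(query_genes) & set(universe)

    weights = np.array([cfg.enrichment_odds if g in query else 1.0 for g in universe])
    weights = weights / weights.sum()
    enriched = sorted(
        rng.choice(universe, size=cfg.pathway_size, replace=False, p=weights)
    )
    gmt = {"planted_pathway": enriched}
    for i in range(cfg.n_pathways - 1):
        gmt[f"decoy_{i:02d}"] = sorted(
            rng.choice(universe, size=cfg.pathway_size, replace=False)
        )
    truth = SimulationTruth(enriched_pathway="planted_pathway")
    return gmt, truth


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
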