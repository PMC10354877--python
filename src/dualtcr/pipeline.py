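"""End-to-end orchestration: ingest -> classify -> clonotype -> diversity -> stats.

``run_analysis`` takes one :class:`RunConfig` and writes a reproducible
report bundle of plain TSV tables: class proportions, clone proportions,
unique-clone-by-tissue matrix, clone-size statistics with Welch ANOVA and
Games-Howell post hoc per stratum family, the per-cluster dual-vs-single
screen, V-gene usage tables, and the secondary-chain-drop diversity
comparison. Outputs are pure functions of (config, inputs): re-running the
same config on the same files yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classify import (
    FilterConfig,
    build_cell_profiles,
    classify_profiles,
    summarize_classes,
)
from .clonotype import clone_counts_by_stratum, clone_size_samples, tabulate_clones
from .contig_io import attach_metadata, read_10x_contigs, read_airr_rearrangements
from .diversity import dual_drop_comparison
from .stats import GroupSummary, cluster_screen, games_howell, gene_usage_table, welch_anova

logger = logging.getLogger(__name__)

BUNDLE_FILES = [
    "class_proportions.tsv",
    "clone_proportions.tsv",
    "unique_clones_by_tissue.tsv",
    "clone_size_stats.tsv",
    "welch_games_howell.tsv",
    "cluster_screen.tsv",
    "usage_TRA.tsv",
    "usage_TRB.tsv",
    "dual_drop_diversity.tsv",
]


@dataclass
class RunConfig:
    """One analysis run: inputs, filter thresholds, and report options."""

    contigs: str
    dialect: str = "10x"  # or "airr"
    metadata: str | None = None
    tissue_map: dict[str, str] = field(default_factory=dict)
    filter: FilterConfig = field(default_factory=FilterConfig)
    key_mode: str = "vjcdr3nt"
    alpha: float = 0.05
    fold_threshold: float = 2.0
    outdir: str = "dualtcr_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.dialect not in ("10x", "airr"):
            raise ValueError(f"dialect must be '10x' or 'airr', got {self.dialect!r}")
        if not Path(self.contigs).exists():
            raise FileNotFoundError(self.contigs)
        if self.metadata is not None and not Path(self.metadata).exists():
            raise FileNotFoundError(self.metadata)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stats_family(samples, family_label: str) -> list[dict]:
    """Welch ANOVA + Games-Howell over one family of clone-size samples."""
    rows: list[dict] = []
    groups = [
        GroupSummary.from_sample(s) for s in samples if s.testable and s.variance > 0
    ]
    if len(groups) < 2:
        rows.append({"family": family_label, "test": "untestable", "detail": "", "statistic": float("nan"), "df": float("nan"), "p": float("nan"), "stars": ""})
        return rows
    w = welch_anova(groups)
    rows.append(
        {
            "family": family_label,
            "test": "welch_anova",
            "detail": ";".join(g.label for g in groups),
            "statistic": w.F,
            "df": w.df2,
            "p": w.p,
            "stars": "",
        }
    )
    for r in games_howell(groups):
        rows.append(
            {
                "family": family_label,
                "test": "games_howell",
                "detail": f"{r.pair[0]} vs {r.pair[1]}",
                "statistic": r.t,
                "df": r.df,
                "p": r.p_adj,
                "stars": r.significance_stars,
            }
        )
    return rows


def run_analysis(config: RunConfig) -> Path:
    """Run the full pipeline and write the report bundle; returns the outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dualtcr")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))

    try:
        reader = read_10x_contigs if config.dialect == "10x" else read_airr_rearrangements
        table = reader(config.contigs)
        if config.metadata:
            table = attach_metadata(table, config.metadata, tissue_map=config.tissue_map or None)
        logger.info("ingested %d contigs over %d barcodes", table.n_records, len(table.barcodes))

        profiles = build_cell_profiles(table, config.filter)
        per_cell = classify_profiles(profiles, config.filter)
        per_cell.to_csv(outdir / "cell_classification.tsv", sep="\t", index=False)

        overall = summarize_classes(profiles, config.filter)
        by_tissue = summarize_classes(profiles, config.filter, by="tissue")
        pd.concat([overall, by_tissue]).to_csv(
            outdir / "class_proportions.tsv", sep="\t", index=False
        )

        clones = tabulate_clones(profiles, config.filter, key_mode=config.key_mode)
        cp = clones.class_proportions().rename("fraction_of_unique_clones").reset_index()
        cp.columns = ["allele_class", "fraction_of_unique_clones"]
        cp["n_unique_clones"] = cp["allele_class"].map(
            clones.df["allele_class"].value_counts()
        )
        cp.to_csv(outdir / "clone_proportions.tsv", sep="\t", index=False)

        clone_out = clones.df.copy()
        clone_out["patients"] = clone_out["patients"].map(lambda s: ";".join(sorted(s)))
        clone_out.to_csv(outdir / "clone_table.tsv", sep="\t", index=False)

        table1 = clone_counts_by_stratum(clones)
        table1.to_csv(outdir / "unique_clones_by_tissue.tsv", sep="\t")

        # stratum families: per-tissue (blood vs tissues), blood by subset,
        # merged tissue by subset
        tissue_strata = [("tissue", "P"), ("tissue", "N"), ("tissue", "T")]
        subset_strata = [
            ("tissue_subset", ("P", "CD4")),
            ("tissue_subset", ("P", "CD8")),
            ("tissue_subset", (("N", "T"), "CD4")),
            ("tissue_subset", (("N", "T"), "CD8")),
        ]
        all_samples = clone_size_samples(clones, tissue_strata + subset_strata)
        size_rows = [
            {
                "stratum": s.label,
                "allele_class": s.allele_class,
                "n_clones": s.n,
                "mean_clone_size": s.mean,
                "variance": s.variance,
                "testable": s.testable,
            }
            for s in all_samples
        ]
        pd.DataFrame(size_rows).to_csv(outdir / "clone_size_stats.tsv", sep="\t", index=False)

        stat_rows: list[dict] = []
        for stratum in tissue_strata + subset_strata:
            fam = [s for s in all_samples if s.label == f"{stratum[0]}:{stratum[1]}"]
            stat_rows.extend(_stats_family(fam, fam[0].label))
        pd.DataFrame(stat_rows).to_csv(outdir / "welch_games_howell.tsv", sep="\t", index=False)

        # per-cluster screen in merged tissue
        clusters = sorted(
            {c for d in clones.cluster_counts.values() for c in d},
        )
        cluster_strata = [("tissue_cluster", (("N", "T"), c)) for c in clusters]
        cluster_samples = clone_size_samples(clones, cluster_strata)
        screen = cluster_screen(cluster_samples, alpha=config.alpha, fold_threshold=config.fold_threshold)
        pd.DataFrame([dataclasses.asdict(r) for r in screen]).to_csv(
            outdir / "cluster_screen.tsv", sep="\t", index=False
        )

        for locus in ("TRA", "TRB"):
            usage = gene_usage_table(clones, locus)
            usage.to_csv(outdir / f"usage_{locus}.tsv", sep="\t")

        comp = dual_drop_comparison(profiles, config.filter, key_mode=config.key_mode)
        rows = []
        for name, res in (("full", comp.full), ("dropped", comp.dropped)):
            rows.append(
                {
                    "keying": name,
                    "richness": res.richness,
                    "shannon": res.shannon,
                    "simpson": res.simpson,
                    "clonality": res.clonality,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "dual_drop_diversity.tsv", sep="\t", index=False)

        with open(outdir / "run_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        logger.info("bundle written to %s", outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
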