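"""Dual-chain-aware clonotype identity, clone tables, and clone-size samples.

A clonotype is the exact multiset of a cell's retained chains — every chain,
not just the top one per locus — so a cell with two alpha chains never shares
a clone with a single-alpha cell even if their top chains coincide. Identity
is nucleotide-level ``locus|v_gene|j_gene|cdr3_nt`` by default, the strictest
standard convention; looser variants (drop J, amino-acid junction) are
available via ``key_mode``.

Clone sizes are counted within-stratum: a clone observed in both blood and
tumor contributes its blood cells to the blood sample and its tumor cells to
the tumor sample, matching per-compartment presentation of expansion.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    ANALYSIS_CLASSES,
    AlleleClass,
    CellChainProfile,
    ChainDescriptor,
    FilterConfig,
    classify_cell,
)
from .contig_io import VALID_TISSUES

logger = logging.getLogger(__name__)

KEY_MODES = ("vjcdr3nt", "vcdr3nt", "vjcdr3aa")


def _chain_token(chain: ChainDescriptor, key_mode: str) -> str:
    if key_mode == "vjcdr3nt":
        return f"{chain.locus}|{chain.v_gene}|{chain.j_gene}|{chain.cdr3_nt}"
    if key_mode == "vcdr3nt":
        return f"{chain.locus}|{chain.v_gene}|{chain.cdr3_nt}"
    if key_mode == "vjcdr3aa":
        return f"{chain.locus}|{chain.v_gene}|{chain.j_gene}|{chain.cdr3_aa}"
    raise ValueError(f"unknown key_mode {key_mode!r}; expected one of {KEY_MODES}")


def clone_key(
    profile: CellChainProfile,
    key_mode: str = "vjcdr3nt",
    allow_excluded: bool = False,
    drop_secondary: bool = False,
) -> str:
    """Canonical clonotype key for one cell: order-independent over chains.

    Parameters
    ----------
    drop_secondary
        When True, only the top chain per locus (highest UMIs, lexicographic
        CDR3nt tie-break) enters the key — emulating workflows that discard
        secondary TCR alleles.
    allow_excluded
        MULTI_BOTH_EXCLUDED cells are outside the analysis; keying one is an
        error unless explicitly allowed.
    """
    cls = classify_cell(profile)
    if cls is AlleleClass.MULTI_BOTH_EXCLUDED and not allow_excluded:
        raise ValueError(f"barcode {profile.barcode}: excluded multi-both cell has no clone key")
    if cls is AlleleClass.INCOMPLETE:
        raise ValueError(f"barcode {profile.barcode}: incomplete cell has no clone key")
    alpha, beta = profile.alpha_chains, profile.beta_chains
    if drop_secondary:
        alpha, beta = alpha[:1], beta[:1]
    tokens = sorted(_chain_token(c, key_mode) for c in alpha + beta)
    return ";".join(tokens)


@dataclass
class CloneTable:
    """Per-clone cell counts, overall and per stratum.

    ``df`` has one row per (clone_key, allele_class) with columns:
    clone_key, allele_class, n_cells, n_P/n_N/n_T (per tissue),
    per-subset and per-cluster counts in ``subset_counts``/``cluster_counts``
    (nested dicts keyed by clone), and the set of contributing patients.
    """

    df: pd.DataFrame
    subset_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    cluster_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    tissue_subset_counts: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    tissue_cluster_counts: dict[str, dict[tuple[str, str], int]] = field(default_factory=dict)
    key_mode: str = "vjcdr3nt"

    @property
    def n_clones(self) -> int:
        return len(self.df)

    @property
    def n_cells(self) -> int:
        return int(self.df["n_cells"].sum())

    def class_proportions(self) -> pd.Series:
        """Fraction of unique clones per allele class."""
        return self.df["allele_class"].value_counts(normalize=True).sort_index()


def _dropped_key_map(
    profiles: Sequence[CellChainProfile],
    config: FilterConfig | None,
    key_mode: str,
) -> dict[str, str]:
    """Map each full clone key to its top-chain-only (secondary-dropped) key.

    The representative chain per locus is chosen per clone, not per cell:
    highest total UMIs across the clone's cells, lexicographic CDR3nt
    tie-break. A per-cell choice would let UMI sampling noise nominate
    different top chains in different cells of one clone, splitting clones
    and breaking the many-to-one merge property of the drop.
    """
    agg: dict[str, dict[tuple, list]] = {}
    for p in profiles:
        cls = classify_cell(p, config)
        if cls not in ANALYSIS_CLASSES:
            continue
        key = clone_key(p, key_mode=key_mode)
        chains = agg.setdefault(key, {})
        for c in p.alpha_chains + p.beta_chains:
            entry = chains.setdefault(c.identity, [0, c])
            entry[0] += c.umis
    mapping: dict[str, str] = {}
    for key, chains in agg.items():
        tops: dict[str, tuple] = {}
        for (locus, _v, _j, cdr3), (umis, chain) in chains.items():
            rank = (-umis, cdr3)
            if locus not in tops or rank < tops[locus][0]:
                tops[locus] = (rank, chain)
        tokens = sorted(_chain_token(t[1], key_mode) for t in tops.values())
        mapping[key] = ";".join(tokens)
    return mapping


def tabulate_clones(
    profiles: Sequence[CellChainProfile],
    config: FilterConfig | None = None,
    key_mode: str = "vjcdr3nt",
    drop_secondary: bool = False,
) -> CloneTable:
    """Group classified cells into clones and tally per-stratum cell counts.

    MULTI_BOTH_EXCLUDED and INCOMPLETE cells are left out. One row per
    (clone key, class); tissue counts sum to the total count per row.
    With ``drop_secondary`` each cell is keyed by its clone's top chain per
    locus only, merging clones that differ solely in secondary alleles.
    """
    profiles = list(profiles)
    drop_map = _dropped_key_map(profiles, config, key_mode) if drop_secondary else None
    rows: dict[str, dict] = {}
    subset_counts: dict[str, dict[str, int]] = {}
    cluster_counts: dict[str, dict[str, int]] = {}
    ts_counts: dict[str, dict[tuple[str, str], int]] = {}
    tc_counts: dict[str, dict[tuple[str, str], int]] = {}

    for p in profiles:
        cls = classify_cell(p, config)
        if cls not in ANALYSIS_CLASSES:
            continue
        key = clone_key(p, key_mode=key_mode)
        if drop_map is not None:
            key = drop_map[key]
        tissue = p.metadata.get("tissue", "") or ""
        subset = p.metadata.get("subset", "") or ""
        cluster = p.metadata.get("cluster", "") or ""
        patient = p.metadata.get("patient_id", "") or ""
        row = rows.setdefault(
            key,
            {
                "clone_key": key,
                "allele_class": cls.value,
                "n_cells": 0,
                **{f"n_{t}": 0 for t in VALID_TISSUES},
                "patients": set(),
            },
        )
        if row["allele_class"] != cls.value and drop_map is None:
            # identical chain multisets imply identical chain counts, so the
            # class is a function of the key; a clash means a key_mode that
            # collapses distinct chains (possible under vjcdr3aa)
            logger.warning("clone %s seen with classes %s and %s", key, row["allele_class"], cls.value)
        row["n_cells"] += 1
        if tissue in VALID_TISSUES:
            row[f"n_{tissue}"] += 1
        if patient:
            row["patients"].add(patient)
        if subset:
            sc = subset_counts.setdefault(key, {})
            sc[subset] = sc.get(subset, 0) + 1
            tsc = ts_counts.setdefault(key, {})
            tsc[(tissue, subset)] = tsc.get((tissue, subset), 0) + 1
        if cluster:
            cc = cluster_counts.setdefault(key, {})
            cc[cluster] = cc.get(cluster, 0) + 1
            tcc = tc_counts.setdefault(key, {})
            tcc[(tissue, cluster)] = tcc.get((tissue, cluster), 0) + 1

    if rows:
        df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["clone_key"]))
    else:
        df = pd.DataFrame(
            columns=["clone_key", "allele_class", "n_cells", "n_P", "n_N", "n_T", "patients"]
        )
    return CloneTable(
        df,
        subset_counts=subset_counts,
        cluster_counts=cluster_counts,
        tissue_subset_counts=ts_counts,
        tissue_cluster_counts=tc_counts,
        key_mode=key_mode,
    )


def clone_counts_by_stratum(table: CloneTable) -> pd.DataFrame:
    """Unique-clone counts, allele classes x tissues.

    Entry (class, tissue) counts distinct clones with at least one cell of
    that class in that tissue; a clone spanning tissues contributes to each
    column, so rows need not sum to the all-tissue unique total.
    """
    classes = [c.value for c in ANALYSIS_CLASSES]
    out = pd.DataFrame(0, index=classes, columns=list(VALID_TISSUES))
    for tissue in VALID_TISSUES:
        present = table.df[table.df[f"n_{tissue}"] > 0]
        counts = present["allele_class"].value_counts()
        for cls in classes:
            out.loc[cls, tissue] = int(counts.get(cls, 0))
    out.index.name = "allele_class"
    return out


@dataclass
class CloneSizeSample:
    """Per-clone cell counts within one stratum."""

    label: str
    allele_class: str
    sizes: np.ndarray

    @property
    def n(self) -> int:
        return len(self.sizes)

    @property
    def testable(self) -> bool:
        """At least two clones; fewer cannot enter any comparison."""
        return self.n >= 2

    @property
    def mean(self) -> float:
        return float(np.mean(self.sizes)) if self.n else float("nan")

    @property
    def variance(self) -> float:
        return float(np.var(self.sizes, ddof=1)) if self.n > 1 else float("nan")


def _stratum_size(row: dict, table: CloneTable, stratum: tuple) -> int:
    """Cell count of one clone inside a (tissue?, subset?, cluster?) stratum."""
    kind, value = stratum
    key = row["clone_key"]
    if kind == "all":
        return int(row["n_cells"])
    if kind == "tissue":
        tissues = value if isinstance(value, tuple) else (value,)
        return int(sum(row[f"n_{t}"] for t in tissues))
    if kind == "subset":
        return int(table.subset_counts.get(key, {}).get(value, 0))
    if kind == "cluster":
        return int(table.cluster_counts.get(key, {}).get(value, 0))
    if kind == "tissue_subset":
        tissues, subset = value
        tissues = tissues if isinstance(tissues, tuple) else (tissues,)
        tsc = table.tissue_subset_counts.get(key, {})
        return int(sum(tsc.get((t, subset), 0) for t in tissues))
    if kind == "tissue_cluster":
        tissues, cluster = value
        tissues = tissues if isinstance(tissues, tuple) else (tissues,)
        tcc = table.tissue_cluster_counts.get(key, {})
        return int(sum(tcc.get((t, cluster), 0) for t in tissues))
    raise ValueError(f"unknown stratum kind {kind!r}")


def clone_size_samples(
    table: CloneTable,
    strata: Sequence[tuple],
    classes: Sequence[AlleleClass] = ANALYSIS_CLASSES,
) -> list[CloneSizeSample]:
    """Extract per-clone within-stratum cell counts for each (stratum, class).

    ``strata`` entries are ``(kind, value)`` pairs, e.g. ``("tissue", "P")``,
    ``("tissue", ("N", "T"))`` for merged tissue, ``("tissue_subset",
    ("P", "CD8"))``, ``("tissue_cluster", (("N", "T"), "terminal Tex"))``.
    Strata with fewer than two clones are emitted but flagged untestable.
    """
    samples: list[CloneSizeSample] = []
    for stratum in strata:
        kind, value = stratum
        label = f"{kind}:{value}"
        for cls in classes:
            sub = table.df[table.df["allele_class"] == cls.value]
            sizes = np.array(
                [s for row in sub.to_dict("records") if (s := _stratum_size(row, table, stratum)) > 0],
                dtype=float,
            )
            samples.append(CloneSizeSample(label=label, allele_class=cls.value, sizes=sizes))
    return samples
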