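"""Per-cell chain profiles and allele-count classification.

Every barcode is reduced to its accepted alpha- and beta-chain sets and then
assigned one of five classes by chain counts:

* ``SINGLE`` — one alpha and one beta chain (1a, 1b)
* ``DUAL_ALPHA`` — two alpha chains, one beta (2a, 1b): alpha allelic inclusion
* ``DUAL_BETA`` — one alpha, two beta chains (1b, 2b): beta allelic inclusion
* ``MULTI_BOTH_EXCLUDED`` — at least two of each: indistinguishable from a
  cell-capture doublet, hence excluded from all biology
* ``INCOMPLETE`` — missing a chain of either locus; never part of any
  denominator (an alpha-beta TCR needs both chains)

Which contigs count as chains is controlled by :class:`FilterConfig`. The
default accepts any productive contig with at least one UMI — appropriate for
deposits that are already quality-filtered — with thresholds exposed for
sensitivity analysis.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .contig_io import ContigTable, METADATA_COLUMNS

logger = logging.getLogger(__name__)


class AlleleClass(str, Enum):
    """Cell classification by number of expressed TCR alleles per locus."""

    SINGLE = "SINGLE"
    DUAL_ALPHA = "DUAL_ALPHA"
    DUAL_BETA = "DUAL_BETA"
    MULTI_BOTH_EXCLUDED = "MULTI_BOTH_EXCLUDED"
    INCOMPLETE = "INCOMPLETE"


#: Classes that enter the class-fraction denominator (cells with >=1a and >=1b).
DENOMINATOR_CLASSES = (
    AlleleClass.SINGLE,
    AlleleClass.DUAL_ALPHA,
    AlleleClass.DUAL_BETA,
    AlleleClass.MULTI_BOTH_EXCLUDED,
)

#: Classes carried into clonotype/diversity/statistics analyses.
ANALYSIS_CLASSES = (AlleleClass.SINGLE, AlleleClass.DUAL_ALPHA, AlleleClass.DUAL_BETA)


@dataclass(frozen=True, order=True)
class ChainDescriptor:
    """One accepted chain: an expressed rearranged allele of TRA or TRB."""

    locus: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    umis: int = 0
    productive: bool = True
    cdr3_aa: str = ""

    @property
    def identity(self) -> tuple[str, str, str, str]:
        """Chain identity used for deduplication and clone keys."""
        return (self.locus, self.v_gene, self.j_gene, self.cdr3_nt)


@dataclass
class FilterConfig:
    """Contig acceptance rules applied before classification.

    Parameters
    ----------
    frame_policy
        ``"productive_only"`` (default) keeps only in-frame/productive
        contigs; ``"include_nonproductive"`` keeps everything, which admits
        transcribed pseudogene rearrangements (e.g. TRBV21-1) as alleles.
    min_umis
        Minimum UMI count for a chain to be accepted.
    min_umi_fraction_of_top
        A chain must carry at least this fraction of the top chain's UMIs at
        the same locus — a knob for suppressing low-evidence secondary chains.
    max_chains_per_locus_policy
        ``"cap_at_two_by_umis"`` (default) keeps the top two chains by UMIs
        at a locus with >2 chains; ``"exclude_cell"`` sends such cells to
        MULTI_BOTH_EXCLUDED.
    """

    frame_policy: str = "productive_only"
    min_umis: int = 1
    min_umi_fraction_of_top: float = 0.0
    max_chains_per_locus_policy: str = "cap_at_two_by_umis"

    def __post_init__(self) -> None:
        if self.frame_policy not in ("productive_only", "include_nonproductive"):
            raise ValueError(f"unknown frame_policy {self.frame_policy!r}")
        if self.max_chains_per_locus_policy not in ("cap_at_two_by_umis", "exclude_cell"):
            raise ValueError(
                f"unknown max_chains_per_locus_policy {self.max_chains_per_locus_policy!r}"
            )
        if self.min_umis < 0:
            raise ValueError("min_umis must be >= 0")
        if not 0.0 <= self.min_umi_fraction_of_top <= 1.0:
            raise ValueError("min_umi_fraction_of_top must be in [0, 1]")


def _chain_sort_key(chain: ChainDescriptor) -> tuple[int, str]:
    # descending UMIs, ties broken lexicographically on CDR3nt
    return (-chain.umis, chain.cdr3_nt)


@dataclass
class CellChainProfile:
    """Accepted chains of one barcode, deterministically ordered."""

    barcode: str
    alpha_chains: tuple[ChainDescriptor, ...]
    beta_chains: tuple[ChainDescriptor, ...]
    metadata: dict = field(default_factory=dict)
    exceeded_locus_cap: bool = False

    @property
    def n_alpha(self) -> int:
        return len(self.alpha_chains)

    @property
    def n_beta(self) -> int:
        return len(self.beta_chains)

    @property
    def chains(self) -> tuple[ChainDescriptor, ...]:
        return self.alpha_chains + self.beta_chains


def _accept_chains(
    chains: list[ChainDescriptor], config: FilterConfig
) -> tuple[tuple[ChainDescriptor, ...], bool]:
    """Filter, deduplicate, order, and cap one locus' chains.

    Returns the retained chains and whether the pre-cap count exceeded two.
    """
    if config.frame_policy == "productive_only":
        chains = [c for c in chains if c.productive]
    # collapse identical (locus, v, j, cdr3nt) observations, summing UMIs
    merged: dict[tuple, ChainDescriptor] = {}
    for c in chains:
        prev = merged.get(c.identity)
        if prev is None:
            merged[c.identity] = c
        else:
            merged[c.identity] = ChainDescriptor(
                c.locus, c.v_gene, c.j_gene, c.cdr3_nt,
                prev.umis + c.umis, prev.productive or c.productive, c.cdr3_aa,
            )
    kept = [c for c in merged.values() if c.umis >= config.min_umis]
    kept.sort(key=_chain_sort_key)
    if kept and config.min_umi_fraction_of_top > 0:
        floor = config.min_umi_fraction_of_top * kept[0].umis
        kept = [c for c in kept if c.umis >= floor]
    exceeded = len(kept) > 2
    if exceeded and config.max_chains_per_locus_policy == "cap_at_two_by_umis":
        kept = kept[:2]
    return tuple(kept), exceeded


def build_cell_profiles(
    table: ContigTable, config: FilterConfig | None = None
) -> list[CellChainProfile]:
    """Build one :class:`CellChainProfile` per barcode from a contig table.

    Chains failing the filter are removed; identical chains collapse with
    summed UMIs; ordering is descending UMIs with lexicographic CDR3nt
    tie-break, so the result is invariant to input row order.
    """
    config = config or FilterConfig()
    df = table.contigs
    meta_by_barcode: dict[str, dict] = {}
    if len(table.cells):
        meta_by_barcode = (
            table.cells.drop_duplicates("barcode").set_index("barcode").to_dict("index")
        )

    by_barcode: dict[str, tuple[list[ChainDescriptor], list[ChainDescriptor]]] = {}
    for row in df.itertuples(index=False):
        chain = ChainDescriptor(
            row.locus, row.v_gene, row.j_gene, row.cdr3_nt,
            int(row.umis), bool(row.productive), str(row.cdr3_aa),
        )
        alpha, beta = by_barcode.setdefault(str(row.barcode), ([], []))
        (alpha if row.locus == "TRA" else beta).append(chain)

    profiles: list[CellChainProfile] = []
    for barcode in sorted(by_barcode):
        alpha, beta = by_barcode[barcode]
        a_kept, a_over = _accept_chains(alpha, config)
        b_kept, b_over = _accept_chains(beta, config)
        md = meta_by_barcode.get(barcode, {})
        profiles.append(
            CellChainProfile(
                barcode=str(barcode),
                alpha_chains=a_kept,
                beta_chains=b_kept,
                metadata=md,
                exceeded_locus_cap=a_over or b_over,
            )
        )
    return profiles


def classify_cell(profile: CellChainProfile, config: FilterConfig | None = None) -> AlleleClass:
    """Assign one allele class from the per-locus chain counts.

    (1a,1b) -> SINGLE; (2a,1b) -> DUAL_ALPHA; (1a,2b) -> DUAL_BETA;
    (>=2a,>=2b) -> MULTI_BOTH_EXCLUDED (doublet-indistinguishable); a missing
    locus -> INCOMPLETE. Under the ``exclude_cell`` cap policy, a locus that
    exceeded two chains forces MULTI_BOTH_EXCLUDED.
    """
    config = config or FilterConfig()
    if (
        config.max_chains_per_locus_policy == "exclude_cell"
        and profile.exceeded_locus_cap
    ):
        return AlleleClass.MULTI_BOTH_EXCLUDED
    na, nb = profile.n_alpha, profile.n_beta
    if na == 0 or nb == 0:
        return AlleleClass.INCOMPLETE
    if na >= 2 and nb >= 2:
        return AlleleClass.MULTI_BOTH_EXCLUDED
    if na >= 2:
        return AlleleClass.DUAL_ALPHA
    if nb >= 2:
        return AlleleClass.DUAL_BETA
    return AlleleClass.SINGLE


def classify_profiles(
    profiles: Iterable[CellChainProfile], config: FilterConfig | None = None
) -> pd.DataFrame:
    """Classify every profile; returns a per-cell table.

    Columns: barcode, allele_class, n_alpha, n_beta, top alpha/beta chain
    descriptors, and the metadata columns.
    """
    rows = []
    for p in profiles:
        cls = classify_cell(p, config)
        top_a = p.alpha_chains[0] if p.alpha_chains else None
        top_b = p.beta_chains[0] if p.beta_chains else None
        rows.append(
            {
                "barcode": p.barcode,
                "allele_class": cls.value,
                "n_alpha": p.n_alpha,
                "n_beta": p.n_beta,
                "alpha1_v": top_a.v_gene if top_a else "",
                "alpha1_cdr3_nt": top_a.cdr3_nt if top_a else "",
                "beta1_v": top_b.v_gene if top_b else "",
                "beta1_cdr3_nt": top_b.cdr3_nt if top_b else "",
                **{c: p.metadata.get(c, "") for c in METADATA_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def summarize_classes(
    profiles: Sequence[CellChainProfile],
    config: FilterConfig | None = None,
    by: str | None = None,
) -> pd.DataFrame:
    """Count and fraction cells per allele class, overall or per stratum.

    Fractions are over cells carrying at least one chain of each locus:
    INCOMPLETE cells are excluded from the denominator, while doublet-like
    MULTI_BOTH_EXCLUDED cells are included in it (they are real barcodes
    with paired-chain data, just uninterpretable).

    Parameters
    ----------
    by
        Optional metadata column (``tissue``, ``subset``, ``cluster``,
        ``patient_id``) to stratify by; None gives a single overall stratum.
    """
    if not profiles:
        warnings.warn("summarize_classes called with no profiles", stacklevel=2)
        return pd.DataFrame(columns=["stratum", "allele_class", "n_cells", "fraction"])

    records = []
    for p in profiles:
        cls = classify_cell(p, config)
        stratum = p.metadata.get(by, "") if by else "all"
        records.append((stratum, cls.value))
    df = pd.DataFrame(records, columns=["stratum", "allele_class"])

    out = []
    for stratum, grp in df.groupby("stratum", sort=True):
        counts = grp["allele_class"].value_counts()
        denom = int(sum(counts.get(c.value, 0) for c in DENOMINATOR_CLASSES))
        if denom == 0:
            warnings.warn(f"stratum {stratum!r}: no cells with both chains", stacklevel=2)
        for cls in AlleleClass:
            n = int(counts.get(cls.value, 0))
            frac = (
                np.nan
                if cls is AlleleClass.INCOMPLETE
                else (n / denom if denom else 0.0)
            )
            out.append(
                {"stratum": stratum, "allele_class": cls.value, "n_cells": n, "fraction": frac}
            )
    return pd.DataFrame(out)
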