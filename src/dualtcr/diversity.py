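"""Repertoire diversity indices and the secondary-chain-drop comparison.

Routine single-cell workflows keep only the top chain per locus, which merges
clonotypes that differ only in a secondary allele. Because the merge is
many-to-one, the dropped-chain richness can never exceed the dual-aware
richness; this module quantifies how large that underestimation is for
richness, Shannon entropy, Simpson diversity, and clonality.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .classify import CellChainProfile, FilterConfig
from .clonotype import tabulate_clones


@dataclass(frozen=True)
class DiversityResult:
    """Standard repertoire diversity indices over a clone-size vector.

    shannon is in nats; clonality = 1 - shannon/ln(richness), 0 when
    richness <= 1 (a fully even repertoire has clonality 0, a monoclonal
    one has clonality approaching 1).
    """

    richness: int
    shannon: float
    simpson: float
    clonality: float


def diversity(counts: Sequence[float] | np.ndarray) -> DiversityResult:
    """Compute richness, Shannon (nats), Simpson (1 - sum p_i^2), clonality.

    ``counts`` are per-clone cell counts, all >= 1.
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty clone-size vector")
    if (c < 1).any():
        raise ValueError("clone sizes must be >= 1")
    p = c / c.sum()
    shannon = float(-(p * np.log(p)).sum())
    simpson = float(1.0 - (p**2).sum())
    richness = int(c.size)
    clonality = 0.0 if richness <= 1 else float(1.0 - shannon / np.log(richness))
    return DiversityResult(richness=richness, shannon=shannon, simpson=simpson, clonality=clonality)


@dataclass(frozen=True)
class DualDropComparison:
    """Diversity with full dual-aware keys vs top-chain-only keys.

    ``dropped`` rebuilds clonotypes after retaining only each cell's top-UMI
    chain per locus; deltas are full - dropped per metric.
    """

    full: DiversityResult
    dropped: DiversityResult

    @property
    def richness_delta(self) -> int:
        return self.full.richness - self.dropped.richness

    @property
    def richness_ratio(self) -> float:
        return self.dropped.richness / self.full.richness

    @property
    def shannon_delta(self) -> float:
        return self.full.shannon - self.dropped.shannon

    @property
    def simpson_delta(self) -> float:
        return self.full.simpson - self.dropped.simpson


def dual_drop_comparison(
    profiles: Sequence[CellChainProfile],
    config: FilterConfig | None = None,
    key_mode: str = "vjcdr3nt",
) -> DualDropComparison:
    """Compare diversity with and without secondary TCR chains.

    Both keyings run on the same cells (MULTI_BOTH_EXCLUDED and INCOMPLETE
    are outside both). Dropping secondary chains maps clone keys many-to-one,
    so dropped richness <= full richness always.
    """
    full_tab = tabulate_clones(profiles, config=config, key_mode=key_mode)
    drop_tab = tabulate_clones(profiles, config=config, key_mode=key_mode, drop_secondary=True)
    full = diversity(full_tab.df["n_cells"].to_numpy())
    dropped = diversity(drop_tab.df["n_cells"].to_numpy())
    return DualDropComparison(full=full, dropped=dropped)
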