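"""Heteroscedastic inference for clone-size comparisons.

Clone-size samples have very unequal variances and sizes across groups
(single vs dual-TCR clones, blood vs tissue), so classical one-way ANOVA and
Tukey HSD are inappropriate. This module implements, from first principles:

* Welch's heteroscedastic one-way ANOVA (Welch 1951),
* the studentized-range survival function by numerical integration of the
  classical double integral, and
* the Games-Howell pairwise post hoc test, which combines Welch-Satterthwaite
  degrees of freedom with studentized-range critical values.

On top of these sit two screens: a per-cluster comparison of dual vs single
clone sizes flagged at ``p < alpha`` and fold change above a threshold, and a
V-gene usage table over unique clones with pseudogene annotation.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
from scipy import integrate, special, stats as sps

from .clonotype import CloneSizeSample, CloneTable

__all__ = [
    "GroupSummary",
    "WelchResult",
    "GamesHowellResult",
    "ClusterScreenRow",
    "welch_anova",
    "welch_t_test",
    "studentized_range_sf",
    "games_howell",
    "cluster_screen",
    "gene_usage_table",
    "PSEUDOGENES",
]

#: IMGT-annotated human TRAV/TRBV pseudogenes relevant to usage screens.
#: TRBV21-1 matters most: it is transcribed in dual-beta cells despite being
#: untranslatable. Editable via the ``pseudogenes`` argument of
#: :func:`gene_usage_table`.
PSEUDOGENES = frozenset(
    {
        "TRBV21-1",
        "TRBV22-1",
        "TRBV23-1",
        "TRBV1",
        "TRBV12-1",
        "TRBV12-2",
        "TRBV26",
        "TRAV8-5",
        "TRAV11",
        "TRAV15",
        "TRAV28",
        "TRAV31",
        "TRAV32",
        "TRAV33",
        "TRAV37",
    }
)


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group: size, mean, unbiased variance."""

    label: str
    n: int
    mean: float
    variance: float

    @classmethod
    def from_values(cls, label: str, values: Sequence[float]) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label=label, n=int(v.size), mean=float(v.mean()), variance=float(v.var(ddof=1)))

    @classmethod
    def from_sample(cls, sample: CloneSizeSample) -> "GroupSummary":
        return cls(
            label=f"{sample.label}/{sample.allele_class}",
            n=sample.n,
            mean=sample.mean,
            variance=sample.variance,
        )


@dataclass(frozen=True)
class WelchResult:
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class GamesHowellResult:
    pair: tuple[str, str]
    mean_diff: float
    se: float
    t: float
    df: float
    p_adj: float

    @property
    def significance_stars(self) -> str:
        if self.p_adj < 0.001:
            return "***"
        if self.p_adj < 0.01:
            return "**"
        if self.p_adj < 0.05:
            return "*"
        return "ns"


def _validate_groups(groups: Sequence[GroupSummary]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.n < 2:
            raise ValueError(f"group {g.label!r} has n={g.n} < 2")
        if not g.variance > 0:
            raise ValueError(
                f"group {g.label!r} has zero variance; exact ties make the "
                "heteroscedastic statistics degenerate"
            )


def welch_anova(groups: Sequence[GroupSummary]) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA from group summaries.

    Weights w_i = n_i / s_i^2; the F statistic compares the weighted
    between-group sum of squares to a correction term built from the
    normalized weights, with df1 = k - 1 and the Welch denominator degrees
    of freedom df2 = (k^2 - 1) / (3 * lambda) where
    lambda = sum (1 - w_i/W)^2 / (n_i - 1).
    """
    _validate_groups(groups)
    k = len(groups)
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s2 = np.array([g.variance for g in groups], dtype=float)

    w = n / s2
    W = w.sum()
    grand = (w * m).sum() / W
    lam = (((1.0 - w / W) ** 2) / (n - 1.0)).sum()
    numer = (w * (m - grand) ** 2).sum() / (k - 1)
    denom = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * lam
    F = float(numer / denom)
    df1 = float(k - 1)
    df2 = float((k**2 - 1.0) / (3.0 * lam))
    p = float(sps.f.sf(F, df1, df2))
    return WelchResult(F=F, df1=df1, df2=df2, p=p)


def welch_t_test(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Two-sided Welch t test from summaries: returns (t, df, p)."""
    va, vb = a.variance / a.n, b.variance / b.n
    se = math.sqrt(va + vb)
    t = (a.mean - b.mean) / se
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


# --- studentized range distribution -------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(160)


def _range_cdf_normal(w: float, k: int) -> float:
    """P(range of k iid standard normals <= w) via Gauss-Legendre quadrature.

    Integrates k * phi(z) * [Phi(z) - Phi(z - w)]^(k-1) over z; the
    integrand is negligible outside z in [-9, w + 9].
    """
    if w <= 0:
        return 0.0
    lo, hi = -9.0, w + 9.0
    z = 0.5 * (hi - lo) * _GL_NODES + 0.5 * (hi + lo)
    inner = special.ndtr(z) - special.ndtr(z - w)
    np.clip(inner, 0.0, 1.0, out=inner)
    dens = k * np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi) * inner ** (k - 1)
    val = 0.5 * (hi - lo) * float(np.dot(_GL_WEIGHTS, dens))
    return min(max(val, 0.0), 1.0)


def _chi_scale_logdensity(s: np.ndarray, df: float) -> np.ndarray:
    """Log density of S = sqrt(chi2_df / df), the pooled-SD scale factor."""
    half = 0.5 * df
    return (
        half * math.log(df)
        - special.gammaln(half)
        - (half - 1.0) * math.log(2.0)
        + (df - 1.0) * np.log(s)
        - half * s * s
    )


def studentized_range_sf(q: float, k: int, df: float) -> float:
    """Upper-tail probability P(Q >= q) of the studentized range.

    Q = range of k iid standard-normal means divided by an independent
    chi-based scale with ``df`` degrees of freedom. Computed by numerical
    integration of the classical double integral: the normal-range
    probability at scaled width q*s, averaged over the scale density.
    Absolute accuracy ~1e-5 for q in [0, 10], k <= 20, df >= 2.
    """
    if not (np.isfinite(q) and np.isfinite(k) and np.isfinite(df)):
        raise ValueError("q, k, df must be finite")
    if q < 0:
        raise ValueError("q must be >= 0")
    if k < 2 or int(k) != k:
        raise ValueError("k must be an integer >= 2")
    if df <= 0:
        raise ValueError("df must be > 0")
    k = int(k)
    if q == 0.0:
        return 1.0
    if df > 1e5:  # scale concentrates at 1
        return 1.0 - _range_cdf_normal(q, k)

    def integrand(s: float) -> float:
        return math.exp(_chi_scale_logdensity(np.array([s]), df)[0]) * _range_cdf_normal(
            q * s, k
        )

    # the scale density has mean ~1 and sd ~1/sqrt(2 df); split the domain
    # around the mode for quad stability at large df
    sd = 1.0 / math.sqrt(2.0 * df)
    hi = 1.0 + 12.0 * sd
    cdf, _ = integrate.quad(integrand, 0.0, hi, epsabs=1e-10, epsrel=1e-9, limit=200)
    tail, _ = integrate.quad(integrand, hi, np.inf, epsabs=1e-12, limit=100)
    cdf += tail
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def games_howell(groups: Sequence[GroupSummary]) -> list[GamesHowellResult]:
    """Games-Howell pairwise post hoc comparisons.

    For each pair: se = sqrt(s_i^2/n_i + s_j^2/n_j), t = |diff|/se,
    Welch-Satterthwaite df, and p_adj from the studentized-range upper tail
    at q = t * sqrt(2) with k = total number of groups.
    """
    _validate_groups(groups)
    k = len(groups)
    results = []
    for a, b in itertools.combinations(groups, 2):
        va, vb = a.variance / a.n, b.variance / b.n
        se = math.sqrt(va + vb)
        diff = a.mean - b.mean
        t = abs(diff) / se
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        p = studentized_range_sf(t * math.sqrt(2.0), k, df)
        results.append(
            GamesHowellResult(pair=(a.label, b.label), mean_diff=diff, se=se, t=t, df=df, p_adj=p)
        )
    return results


# --- screens --------------------------------------------------------------


@dataclass(frozen=True)
class ClusterScreenRow:
    """One phenotype cluster's dual-vs-single clone-size comparison."""

    cluster: str
    dual_class: str
    mean_dual: float
    mean_single: float
    n_dual: int
    n_single: int
    fold: float
    p_adj: float
    flagged: bool
    testable: bool = True


def cluster_screen(
    samples: Iterable[CloneSizeSample],
    alpha: float = 0.05,
    fold_threshold: float = 2.0,
) -> list[ClusterScreenRow]:
    """Flag clusters where dual clones are significantly larger than single.

    ``samples`` carry per-cluster clone sizes for SINGLE plus one or more
    dual classes (labels are shared within a cluster). Per cluster, all
    testable groups enter one Games-Howell family (Welch t when only two);
    a (cluster, dual class) row is flagged iff its adjusted p < ``alpha``
    AND mean_dual/mean_single > ``fold_threshold``. Under-sized groups are
    reported untestable rather than silently dropped.
    """
    by_cluster: dict[str, dict[str, CloneSizeSample]] = {}
    for s in samples:
        by_cluster.setdefault(s.label, {})[s.allele_class] = s

    rows: list[ClusterScreenRow] = []
    for cluster in sorted(by_cluster):
        group = by_cluster[cluster]
        single = group.get("SINGLE")
        dual_classes = [c for c in ("DUAL_ALPHA", "DUAL_BETA") if c in group]
        for dc in dual_classes:
            dual = group[dc]
            degenerate = (
                single is not None
                and single.testable
                and dual.testable
                and (not single.variance > 0 or not dual.variance > 0)
            )
            if single is None or not single.testable or not dual.testable or degenerate:
                rows.append(
                    ClusterScreenRow(
                        cluster=cluster,
                        dual_class=dc,
                        mean_dual=dual.mean,
                        mean_single=single.mean if single else float("nan"),
                        n_dual=dual.n,
                        n_single=single.n if single else 0,
                        fold=float("nan"),
                        p_adj=float("nan"),
                        flagged=False,
                        testable=False,
                    )
                )
                continue
            testable = [
                GroupSummary.from_sample(s)
                for s in group.values()
                if s.testable and s.variance > 0
            ]
            g_dual = GroupSummary.from_sample(dual)
            g_single = GroupSummary.from_sample(single)
            if len(testable) > 2:
                gh = games_howell(testable)
                want = {g_dual.label, g_single.label}
                p = next(r.p_adj for r in gh if set(r.pair) == want)
            else:
                _, _, p = welch_t_test(g_dual, g_single)
            fold = dual.mean / single.mean
            rows.append(
                ClusterScreenRow(
                    cluster=cluster,
                    dual_class=dc,
                    mean_dual=dual.mean,
                    mean_single=single.mean,
                    n_dual=dual.n,
                    n_single=single.n,
                    fold=fold,
                    p_adj=p,
                    flagged=bool(p < alpha and fold > fold_threshold),
                )
            )
    return rows


def gene_usage_table(
    table: CloneTable,
    locus: str,
    pseudogenes: frozenset[str] | set[str] = PSEUDOGENES,
):
    """V-gene usage frequencies per allele class over unique clones.

    Each clone contributes every V gene it carries at ``locus`` — a
    dual-alpha clone adds both of its TRAV genes. Frequencies are normalized
    per class column. The enrichment column is the dual/single frequency
    ratio for the locus' own dual class (DUAL_ALPHA for TRA, DUAL_BETA for
    TRB), the readout for pseudogene skew among secondary rearrangements.
    """
    import pandas as pd

    if locus not in ("TRA", "TRB"):
        raise ValueError("locus must be TRA or TRB")
    counts: dict[str, dict[str, float]] = {}
    for row in table.df.itertuples(index=False):
        for token in row.clone_key.split(";"):
            parts = token.split("|")
            if parts[0] != locus:
                continue
            v = parts[1]
            col = counts.setdefault(row.allele_class, {})
            col[v] = col.get(v, 0) + 1
    freq = pd.DataFrame(counts).fillna(0.0).sort_index()
    freq = freq / freq.sum(axis=0)
    freq["pseudogene"] = [g in pseudogenes for g in freq.index]
    dual_col = "DUAL_ALPHA" if locus == "TRA" else "DUAL_BETA"
    if dual_col in freq.columns and "SINGLE" in freq.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            freq["enrichment_dual_over_single"] = freq[dual_col] / freq["SINGLE"]
    freq.index.name = "gene"
    return freq
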