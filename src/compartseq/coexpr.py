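"""Coexpression grouping from 4-point compartment profiles.

A gene's profile is its (housekeeping-corrected) mean NE over the ordered
compartments.  Pairwise similarity is the coefficient of determination
R² = r² of the Pearson correlation over those points.  With n points the
correlation is significant at level alpha when

    R² > t²/(t² + n - 2),   t = two-tailed Student-t critical value, df = n-2.

For n = 4 and alpha = 0.05 this threshold is exactly (1 - alpha)² = 0.9025
(for df = 2 the t CDF is F(t) = 1/2 + t/(2*sqrt(2 + t²)), so the critical
R² collapses to a closed form).

Coordinately expressed groups are maximal cliques in the graph whose edges
join positively correlated pairs with R² at or above a grouping threshold
(default 0.93, stricter than the significance bound).  Significance here is
sign-aware: an anticorrelated pair can have R² = 1 yet is not coordinate
expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import COMPARTMENTS
from .quant import NETable

logger = logging.getLogger(__name__)

#: default within-group R² floor used for clique formation
GROUPING_THRESHOLD = 0.93


def critical_r2(n: int, alpha: float = 0.05) -> float:
    """Smallest R² significant at two-tailed ``alpha`` for ``n`` observations.

    Computed as t²/(t² + df) with df = n - 2 and t the two-tailed Student-t
    critical value.  Requires n >= 3 (df > 0).
    """
    if n < 3:
        raise ValueError("need at least 3 observations (df = n - 2 > 0)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n - 2
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t * t / (t * t + df))


@dataclass
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float
    r2: float
    constant: bool = False
    significant: bool = False


def profile_r2(
    a, b, alpha: float = 0.05, gene_a: str = "a", gene_b: str = "b"
) -> CorrelationResult:
    """Pearson r and R² of two compartment profiles (sign-aware significance).

    A constant profile has no defined correlation; it is reported as R² = 0
    with ``constant=True`` rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("profiles must be equal-length 1-d vectors of >= 3 values")
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(gene_a, gene_b, 0.0, 0.0, constant=True)
    r = float(np.corrcoef(a, b)[0, 1])
    r2 = r * r
    sig = bool(r > 0 and r2 > critical_r2(len(a), alpha))
    return CorrelationResult(gene_a, gene_b, r, r2, significant=sig)


def pairwise_correlations(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(r, R²) gene x gene matrices; constant profiles correlate at 0."""
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r[~np.isfinite(r)] = 0.0
    const = sd == 0
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    r = pd.DataFrame(r, index=profiles.index, columns=profiles.index)
    return r, r**2


@dataclass
class CoexpressionGroup:
    group_id: str
    members: tuple[str, ...]
    min_within_r2: float
    max_between_r2: dict[str, float] = field(default_factory=dict)


@dataclass
class GroupingResult:
    groups: list[CoexpressionGroup]
    assignments: pd.Series            # gene -> group id or "none"
    r: pd.DataFrame
    r2: pd.DataFrame
    threshold: float
    separation_threshold: float
    ambiguities: list[tuple[str, str, str]] = field(default_factory=list)
    loose_associates: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def members(self, group_id: str) -> tuple[str, ...]:
        for g in self.groups:
            if g.group_id == group_id:
                return g.members
        raise KeyError(group_id)


def form_groups(
    profiles: pd.DataFrame,
    threshold: float = GROUPING_THRESHOLD,
    alpha: float = 0.05,
    require_separation: bool = True,
    min_size: int = 1,
) -> GroupingResult:
    """Maximal-clique coexpression groups over the candidate genes.

    Edges join gene pairs with r > 0 and R² >= ``threshold``.  Cliques are
    reported largest first (ties by lexicographic member order).  A gene
    belonging to several maximal cliques stays with the first-reported
    (larger) one and the ambiguity is logged.  With ``require_separation``,
    a clique is reported only if no positively correlated cross pair against
    an already-reported group reaches the significance bound
    ``critical_r2(n, alpha)``.
    """
    import networkx as nx

    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n_obs = profiles.shape[1]
    sep = critical_r2(n_obs, alpha)
    r, r2 = pairwise_correlations(profiles)

    G = nx.Graph()
    G.add_nodes_from(profiles.index)
    genes = list(profiles.index)
    for i, gi in enumerate(genes):
        for gj in genes[i + 1 :]:
            if r.at[gi, gj] > 0 and r2.at[gi, gj] >= threshold:
                G.add_edge(gi, gj)

    cliques = sorted(
        (sorted(c) for c in nx.find_cliques(G)), key=lambda c: (-len(c), c)
    )
    assigned: dict[str, str] = {}
    groups: list[CoexpressionGroup] = []
    ambiguities: list[tuple[str, str, str]] = []
    for clique in cliques:
        free = [g for g in clique if g not in assigned]
        if len(free) < max(min_size, 1):
            continue
        if require_separation and _violates_separation(free, groups, r, r2, sep):
            continue
        gid = f"group{len(groups) + 1}"
        for g in clique:
            if g in assigned:
                ambiguities.append((g, assigned[g], gid))
                logger.warning(
                    "gene %s belongs to maximal cliques of %s and %s; kept with %s",
                    g, assigned[g], gid, assigned[g],
                )
        for g in free:
            assigned[g] = gid
        sub = r2.loc[free, free].to_numpy()
        min_within = 1.0 if len(free) == 1 else float(sub[~np.eye(len(free), dtype=bool)].min())
        assert min_within >= threshold or len(free) == 1
        groups.append(CoexpressionGroup(gid, tuple(free), min_within))

    for g in groups:
        for h in groups:
            if h.group_id == g.group_id:
                continue
            cross = r2.loc[list(g.members), list(h.members)].to_numpy()
            g.max_between_r2[h.group_id] = float(cross.max()) if cross.size else 0.0

    assignments = pd.Series("none", index=profiles.index, name="group")
    for gene, gid in assigned.items():
        assignments.loc[gene] = gid

    loose: dict[str, tuple[str, ...]] = {}
    for grp in groups:
        cand = []
        for gene in profiles.index:
            if assignments.loc[gene] != "none":
                continue
            rs = r.loc[gene, list(grp.members)]
            r2s = r2.loc[gene, list(grp.members)]
            if (rs > 0).all() and (r2s > sep).all():
                cand.append(gene)
        if cand:
            loose[grp.group_id] = tuple(cand)

    return GroupingResult(
        groups=groups,
        assignments=assignments,
        r=r,
        r2=r2,
        threshold=threshold,
        separation_threshold=sep,
        ambiguities=ambiguities,
        loose_associates=loose,
    )


def _violates_separation(members, groups, r, r2, sep) -> bool:
    for grp in groups:
        for m in members:
            for o in grp.members:
                if r.at[m, o] > 0 and r2.at[m, o] >= sep:
                    return True
    return False


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    coordinates: pd.DataFrame          # samples x PCs
    explained_variance_ratio: np.ndarray
    replicate_distances: pd.Series     # compartment -> distance between replicates
    flagged: tuple[str, ...]
    degenerate: bool = False


def replicate_qc(ne: NETable, n_components: int = 2, flag_ratio: float = 1.0) -> QCReport:
    """Sample-level PCA of log NE; flags replicate pairs that fail to co-locate.

    A compartment is flagged when the distance between its replicates in PC
    space exceeds ``flag_ratio`` times the median distance between samples of
    different compartments.  An all-constant matrix yields a degenerate report.
    """
    from sklearn.decomposition import PCA

    X = np.log10(ne.gene_ne.to_numpy(dtype=float).T + 1.0)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.allclose(X.std(axis=0), 0):
        empty = pd.DataFrame(
            np.zeros((X.shape[0], 1)), index=ne.gene_ne.columns, columns=["PC1"]
        )
        return QCReport(empty, np.array([0.0]), pd.Series(dtype=float), (), degenerate=True)
    k = min(n_components, X.shape[0] - 1)
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X - X.mean(axis=0))
    coords = pd.DataFrame(
        coords, index=ne.gene_ne.columns, columns=[f"PC{i+1}" for i in range(k)]
    )

    comp = ne.samples["compartment"]
    dists = {}
    for c in comp.unique():
        reps = comp.index[comp == c]
        if len(reps) >= 2:
            pts = coords.loc[reps].to_numpy()
            dists[c] = float(np.linalg.norm(pts[0] - pts[1]))
    rep_d = pd.Series(dists)
    cross = [
        float(np.linalg.norm(coords.loc[a].to_numpy() - coords.loc[b].to_numpy()))
        for i, a in enumerate(coords.index)
        for b in coords.index[i + 1 :]
        if comp[a] != comp[b]
    ]
    med = float(np.median(cross)) if cross else np.inf
    flagged = tuple(rep_d.index[rep_d > flag_ratio * med])
    return QCReport(coords, pca.explained_variance_ratio_, rep_d, flagged)
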