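"""Transcription-factor candidate ranking for coexpression groups.

For each group, candidate factors are those predicted to bind a matrix
present in the promoters of *all* group members.  Two evidence channels are
combined:

* motif evidence — the one-sided hypergeometric probability of seeing at
  least the observed number of group promoters carrying the matrix, given
  the matrix's carrier count in a background gene universe;
* expression evidence — the mean sign-aware R² between the factor's own
  4-point compartment profile and each group member's profile.

The combined score is ``-log10(P) * mean R²``: zero when the profiles are
uninformative, monotone increasing in both channels.  Factors whose matrix
is unique to the group (common to it and to no other group) are flagged as
particularly strong candidates, as are factors passing the classic
P < 0.05 and R² > 0.9 filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr import profile_r2
from .motifs import MatrixPartition, MotifPresenceMatrix

_P_FLOOR = 1e-300


def motif_enrichment_p(
    matrix_id: str,
    members,
    presence: MotifPresenceMatrix | pd.DataFrame,
    universe=None,
    k: int | None = None,
) -> float:
    """One-sided hypergeometric P of >= k carriers of the matrix in the group.

    ``k`` defaults to the observed carrier count among the members (equal to
    the group size when the matrix is common to all members).  The universe
    defaults to every gene in the presence matrix and must contain the group.
    """
    pres = presence.presence if isinstance(presence, MotifPresenceMatrix) else presence
    members = list(members)
    universe = list(universe) if universe is not None else list(pres.index)
    if not set(members) <= set(universe):
        raise ValueError("background universe must contain the group")
    if len(universe) < len(members):
        raise ValueError("background universe smaller than group")
    col = pres.loc[universe, matrix_id]
    n_carriers = int(col.sum())
    observed = int(pres.loc[members, matrix_id].sum())
    if k is None:
        k = observed
    if k <= 0:
        return 1.0
    M, n, N = len(universe), n_carriers, len(members)
    return float(stats.hypergeom.sf(k - 1, M, n, N))


def combined_score(enrichment_p: float, mean_r2: float) -> float:
    """-log10(P) x mean R²; monotone in both evidence channels."""
    if not 0.0 <= mean_r2 <= 1.0:
        raise ValueError("mean R² must lie in [0, 1]")
    if enrichment_p < 0 or enrichment_p > 1:
        raise ValueError("P must lie in [0, 1]")
    if enrichment_p == 0:
        warnings.warn("enrichment P of 0 clamped to 1e-300")
        enrichment_p = _P_FLOOR
    return float(-np.log10(enrichment_p) * mean_r2)


def tf_expression_correlation(
    factors, members, profiles: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-factor sign-aware R² against each group member, plus the mean.

    An anticorrelated (r <= 0) or constant pairing contributes R² = 0.
    Factors absent from the profile table are returned with
    ``quantified = False`` and NaN correlations.
    """
    members = list(members)
    rows = []
    for f in sorted(set(factors)):
        if f not in profiles.index:
            rows.append({"factor": f, "quantified": False, "mean_r2": np.nan,
                         **{m: np.nan for m in members}})
            continue
        vals = {}
        for m in members:
            res = profile_r2(profiles.loc[f], profiles.loc[m], alpha=alpha)
            vals[m] = res.r2 if (res.r > 0 and not res.constant) else 0.0
        rows.append({"factor": f, "quantified": True,
                     "mean_r2": float(np.mean(list(vals.values()))), **vals})
    return pd.DataFrame(rows).set_index("factor")


@dataclass
class TFRanking:
    """Per-group candidate tables with the two ranking views."""

    tables: dict[str, pd.DataFrame]
    universe_size: int
    alpha: float
    r2_cutoff: float
    params: dict = field(default_factory=dict)

    def by_score(self, group_id: str) -> pd.DataFrame:
        """All quantified candidates, best combined score first."""
        t = self.tables[group_id]
        t = t[t["quantified"]]
        return t.sort_values(
            ["combined_score", "enrichment_p", "factor"],
            ascending=[False, True, True],
        ).reset_index(drop=True)

    def filtered(self, group_id: str) -> pd.DataFrame:
        """Candidates passing P < alpha and mean R² > cutoff, best R² first."""
        t = self.tables[group_id]
        t = t[t["passes_filter"]]
        return t.sort_values(
            ["mean_r2", "enrichment_p", "factor"], ascending=[False, True, True]
        ).reset_index(drop=True)


def rank_candidates(
    groups,
    presence: MotifPresenceMatrix | pd.DataFrame,
    partition: MatrixPartition,
    profiles: pd.DataFrame,
    tf_map: pd.DataFrame,
    universe=None,
    alpha: float = 0.05,
    r2_cutoff: float = 0.9,
) -> TFRanking:
    """Build the per-group TF candidate tables.

    ``tf_map`` is a many-to-many table with columns ``matrix`` and
    ``factor``.  A factor enters a group's table when at least one of its
    matrices is common to all group members; its enrichment P is the best
    (smallest) P over those matrices, and it is flagged unique when any of
    them is unique to the group.
    """
    pres = presence.presence if isinstance(presence, MotifPresenceMatrix) else presence
    if hasattr(groups, "groups"):
        groups = groups.groups
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(g.group_id, list(g.members)) for g in groups]
    universe = list(universe) if universe is not None else list(pres.index)

    tables: dict[str, pd.DataFrame] = {}
    for gid, members in items:
        members = list(members)
        common = sorted(partition.common[gid])
        p_of_matrix = {
            m: motif_enrichment_p(m, members, pres, universe=universe) for m in common
        }
        sub = tf_map[tf_map["matrix"].isin(common)]
        factor_matrices = sub.groupby("factor")["matrix"].agg(sorted)
        corr = tf_expression_correlation(factor_matrices.index, members, profiles, alpha)
        rows = []
        for factor, mats in factor_matrices.items():
            p = min(p_of_matrix[m] for m in mats)
            quantified = bool(corr.loc[factor, "quantified"])
            mean_r2 = float(corr.loc[factor, "mean_r2"]) if quantified else np.nan
            uniq = any(m in partition.unique[gid] for m in mats)
            passes = bool(quantified and p < alpha and mean_r2 > r2_cutoff)
            rows.append(
                {
                    "factor": factor,
                    "matrices": ";".join(mats),
                    "unique_to_group": uniq,
                    "enrichment_p": p,
                    "mean_r2": mean_r2,
                    "combined_score": combined_score(p, mean_r2) if quantified else np.nan,
                    "quantified": quantified,
                    "passes_filter": passes,
                }
            )
        table = pd.DataFrame(
            rows,
            columns=["factor", "matrices", "unique_to_group", "enrichment_p",
                     "mean_r2", "combined_score", "quantified", "passes_filter"],
        )
        # every factor here binds a common matrix, and no other factor does
        assert set(table["factor"]) == set(sub["factor"].unique())
        tables[gid] = table

    return TFRanking(
        tables=tables,
        universe_size=len(universe),
        alpha=alpha,
        r2_cutoff=r2_cutoff,
        params={"r2_cutoff": r2_cutoff},
    )
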