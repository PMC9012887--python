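"""Exact count-based differential expression between compartments.

The Audic–Claverie construction compares one feature's read counts x and y
in two libraries of sizes N1 and N2 under Poisson sampling.  Given x, the
second count follows the conditional distribution

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

a negative binomial with x+1 "successes" and success probability
N1/(N1+N2); :func:`conditional_count_pmf` evaluates it in log space.

For the reported two-sided P value we use the exact minimum-likelihood test
*conditional on the pair total* t = x+y, under which y ~ Binomial(t, q)
with q = N2/(N1+N2): the P value is the total probability of all outcomes
no more likely than the observed one.  Conditioning on the total makes the
test exactly symmetric under (x, N1) <-> (y, N2), which the flat-prior
conditional p(y|x) is not; both formulations agree on which outcomes are
extreme and coincide asymptotically.

Transcript-level P values are aggregated to genes (Šidák-corrected minimum),
adjusted per comparison (Benjamini–Hochberg by default), and the three
developmentally adjacent comparisons are combined into a 7-category Venn
partition of the significant genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .constants import ADJACENT_PAIRS, COMPARTMENTS, pair_name
from .quant import CountMatrix, compute_ne

#: relative tolerance for probability ties in the minimum-likelihood rule
_TIE_RTOL = 1e-7


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def conditional_count_log_pmf(y, x, n1, n2):
    """log p(y | x) of the Audic–Claverie conditional distribution."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or x < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    r = n2 / n1
    return (
        special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        + y * math.log(r)
        - (x + y + 1) * math.log1p(r)
    )


def conditional_count_pmf(y, x, n1, n2):
    """p(y | x): probability of count y in library 2 given x in library 1."""
    return np.exp(conditional_count_log_pmf(y, x, n1, n2))


def _binom_logpmf(k, t, q):
    return (
        special.gammaln(t + 1)
        - special.gammaln(k + 1)
        - special.gammaln(t - k + 1)
        + k * math.log(q)
        + (t - k) * math.log1p(-q)
    )


def _search_monotone(lo, hi, pred):
    """Smallest k in [lo, hi] with pred(k) True; pred monotone (F..FT..T)."""
    while lo < hi:
        mid = (lo + hi) // 2
        if pred(mid):
            hi = mid
        else:
            lo = mid + 1
    return lo


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided exact P for counts (x, y) in libraries of sizes (n1, n2).

    Minimum-likelihood rule on the distribution of y conditional on the
    total t = x + y (Binomial(t, n2/(n1+n2))): sums the probability of every
    outcome whose likelihood does not exceed the observed one.  Symmetric
    under (x, n1) <-> (y, n2); equals 1 when the observed split is the mode.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    t = x + y
    if t == 0:
        return 1.0
    q = n2 / (n1 + n2)
    lp = lambda k: _binom_logpmf(k, t, q)
    lp_obs = lp(y)
    tie = math.log1p(_TIE_RTOL)
    mode = min(t, int(math.floor((t + 1) * q)))
    if lp(mode) <= lp_obs + tie:
        return 1.0
    # binom cdf/sf via the regularized incomplete beta function
    cdf = lambda k: special.bdtr(k, t, q) if k >= 0 else 0.0
    sf = lambda k: special.bdtrc(k, t, q) if k >= 0 else 1.0  # P(Y > k)
    if y > mode:
        right = sf(y - 1)
        # pmf is non-decreasing on [0, mode]: find largest a with lp(a) <= lp_obs
        if lp(0) > lp_obs + tie:
            left = 0.0
        else:
            a = _search_monotone(0, mode, lambda k: lp(k) > lp_obs + tie) - 1
            left = cdf(a)
    else:
        left = cdf(y)
        # pmf is non-increasing on [mode, t]: find smallest b with lp(b) <= lp_obs
        if lp(t) > lp_obs + tie:
            right = 0.0
        else:
            b = _search_monotone(mode, t, lambda k: lp(k) <= lp_obs + tie)
            right = sf(b - 1)
    return float(min(1.0, left + right))


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _adjust(pvals: np.ndarray, method: str) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return pvals
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(pvals, method=key)[1]


def _sidak_min(pvals: np.ndarray) -> float:
    """Gene-level P from its transcripts: Šidák-corrected minimum."""
    k = len(pvals)
    pmin = float(np.min(pvals))
    if k == 1:
        return pmin
    return float(-np.expm1(k * np.log1p(-min(pmin, 1.0))))


def pairwise_de(
    counts: CountMatrix,
    pairs=None,
    alpha: float = 0.05,
    adjust: str = "bh",
    replicate_mode: str = "pooled",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Exact DE test for every compartment pair, aggregated to gene level.

    Replicates are summed per compartment before testing (``"pooled"``,
    the default: the exact test models unreplicated library counts), or each
    replicate pair is tested and the larger P kept (``"each"``, conservative).
    Returns a tidy frame with one row per gene and pair, BH- (or Bonferroni-)
    adjusted within each pair, and the log2 fold change of compartment mean
    NE with a pseudocount.
    """
    if adjust not in ("bh", "bonferroni"):
        raise ValueError("adjust must be 'bh' or 'bonferroni'")
    if replicate_mode not in ("pooled", "each"):
        raise ValueError("replicate_mode must be 'pooled' or 'each'")
    comps = counts.compartments
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(comps) for b in comps[i + 1 :]]
    for c1, c2 in pairs:
        if c1 not in comps or c2 not in comps:
            raise ValueError(f"unknown compartment in pair ({c1}, {c2})")

    ne = compute_ne(counts)
    lib = counts.library_sizes()
    gene_of = counts.gene_map
    frames = []
    for c1, c2 in pairs:
        s1, s2 = counts.samples_of(c1), counts.samples_of(c2)
        if replicate_mode == "pooled":
            x = counts.counts[s1].sum(axis=1)
            y = counts.counts[s2].sum(axis=1)
            N1, N2 = float(lib[s1].sum()), float(lib[s2].sum())
            p_tx = np.array(
                [audic_claverie_p(int(xi), int(yi), N1, N2) for xi, yi in zip(x, y)]
            )
        else:
            reps = min(len(s1), len(s2))
            pcols = []
            for r in range(reps):
                N1, N2 = float(lib[s1[r]]), float(lib[s2[r]])
                pcols.append(
                    np.array(
                        [
                            audic_claverie_p(int(xi), int(yi), N1, N2)
                            for xi, yi in zip(counts.counts[s1[r]], counts.counts[s2[r]])
                        ]
                    )
                )
            p_tx = np.max(np.column_stack(pcols), axis=1)
            x = counts.counts[s1].sum(axis=1)
            y = counts.counts[s2].sum(axis=1)
            N1, N2 = float(lib[s1].sum()), float(lib[s2].sum())

        tx = pd.DataFrame({"gene": gene_of.values, "p": p_tx, "x": x.values, "y": y.values},
                          index=counts.counts.index)
        gene = tx.groupby("gene").agg(
            p_raw=("p", lambda v: _sidak_min(v.to_numpy())),
            x=("x", "sum"),
            y=("y", "sum"),
        )
        gene["p_adj"] = _adjust(gene["p_raw"].to_numpy(), adjust)
        mean1 = ne.compartment_ne.loc[gene.index, c1]
        mean2 = ne.compartment_ne.loc[gene.index, c2]
        gene["log2fc"] = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
        gene["n1"], gene["n2"] = N1, N2
        gene["pair"] = pair_name(c1, c2)
        gene["significant"] = gene["p_adj"] < alpha
        frames.append(gene.reset_index())
    out = pd.concat(frames, ignore_index=True)
    out.attrs["alpha"] = alpha
    out.attrs["adjust"] = adjust
    return out


@dataclass
class VennPartition:
    """Per-gene label over the adjacent comparisons and the 7-category counts."""

    labels: pd.Series
    counts: dict[str, int]
    n_significant: int
    categories: tuple[str, ...]

    def __post_init__(self):
        total = sum(self.counts.values())
        assert total == self.n_significant, "Venn categories must partition the significant genes"


def venn_categories(adjacent=ADJACENT_PAIRS) -> tuple[str, ...]:
    names = [pair_name(*p) for p in adjacent]
    cats = []
    for size in (1, 2, 3):
        for picks in _subsets(names, size):
            cats.append("&".join(picks))
    return tuple(cats)


def _subsets(names, size):
    from itertools import combinations

    return combinations(names, size)


def venn_partition(results: pd.DataFrame, adjacent=ADJACENT_PAIRS) -> VennPartition:
    """Label each gene by the subset of adjacent comparisons where it is DE."""
    names = [pair_name(*p) for p in adjacent]
    have = set(results["pair"])
    missing = [n for n in names if n not in have]
    if missing:
        raise ValueError(f"missing adjacent comparisons: {missing}")
    sig = results[results["pair"].isin(names) & results["significant"]]
    member = sig.groupby("gene")["pair"].agg(
        lambda v: "&".join([n for n in names if n in set(v)])
    )
    all_genes = results["gene"].unique()
    labels = pd.Series("none", index=pd.Index(all_genes, name="gene"))
    labels.loc[member.index] = member
    cats = venn_categories(adjacent)
    counts = {c: int((labels == c).sum()) for c in cats}
    return VennPartition(
        labels=labels, counts=counts, n_significant=int(len(member)), categories=cats
    )
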