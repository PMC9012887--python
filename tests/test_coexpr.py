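"""Critical R², profile correlation, clique grouping, and replicate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compartseq.constants import COMPARTMENTS
from compartseq.coexpr import (
    critical_r2,
    form_groups,
    pairwise_correlations,
    profile_r2,
    replicate_qc,
)


def quadrature_critical_r2(n: int, alpha: float) -> float:
    """Oracle: invert the t tail integral numerically, no ppf involved."""
    from scipy.integrate import quad
    from scipy.optimize import brentq

    df = n - 2

    def density(x):
        from scipy.special import gammaln

        c = np.exp(gammaln((df + 1) / 2) - gammaln(df / 2)) / np.sqrt(df * np.pi)
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    def tail_minus_target(t):
        return quad(density, t, np.inf)[0] - alpha / 2

    t = brentq(tail_minus_target, 1e-9, 1e6)
    return t * t / (t * t + df)


def test_critical_r2_closed_form_for_four_points():
    """At df = 2 the critical R² collapses to (1 - alpha)² exactly."""
    assert critical_r2(4, 0.05) == pytest.approx((1 - 0.05) ** 2, abs=1e-12)
    assert critical_r2(4, 0.10) == pytest.approx((1 - 0.10) ** 2, abs=1e-12)


@pytest.mark.parametrize("n,alpha", [(4, 0.5), (4, 0.05), (6, 0.01), (10, 0.2)])
def test_critical_r2_matches_quadrature_oracle(n, alpha):
    assert critical_r2(n, alpha) == pytest.approx(quadrature_critical_r2(n, alpha), abs=1e-9)


def test_critical_r2_vanishes_as_alpha_approaches_one():
    assert critical_r2(4, 0.999) < 1e-5


def test_critical_r2_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        critical_r2(2, 0.05)
    with pytest.raises(ValueError):
        critical_r2(4, 0.0)


# ---------------------------------------------------------------------------
# profile correlation
# ---------------------------------------------------------------------------

@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    vals=st.lists(st.floats(0.01, 1000), min_size=4, max_size=4, unique=True),
    scale=st.floats(0.01, 100),
    offset=st.floats(0, 100),
)
def test_positive_affine_transform_gives_perfect_r2(vals, scale, offset):
    a = np.array(vals)
    res = profile_r2(a, scale * a + offset)
    assert res.r2 == pytest.approx(1.0, abs=1e-9)
    assert res.r > 0 and res.significant


def test_reflected_profile_has_r2_one_but_is_not_significant():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = profile_r2(a, -a)
    assert res.r2 == pytest.approx(1.0, abs=1e-12)
    assert res.r < 0 and not res.significant


def test_hand_computed_r2():
    """(1,2,3,4) vs (1,2,3,5): R² = 6.5² / (5 x 8.75) from the raw sums."""
    res = profile_r2([1, 2, 3, 4], [1, 2, 3, 5])
    assert res.r2 == pytest.approx(42.25 / 43.75, abs=1e-12)
    assert res.significant  # 0.9657 > 0.9025


def test_constant_profile_flagged_not_nan():
    res = profile_r2([2, 2, 2, 2], [1, 2, 3, 4])
    assert res.constant and res.r2 == 0.0 and not res.significant


def test_wrong_length_rejected():
    with pytest.raises(ValueError):
        profile_r2([1, 2], [3, 4])


def test_pairwise_matrix_is_symmetric_with_unit_diagonal(corrected_ne):
    r, r2 = pairwise_correlations(corrected_ne.profiles().head(15))
    assert np.allclose(r, r.T)
    assert np.allclose(np.diag(r2), 1.0)
    assert ((r2.to_numpy() >= -1e-12) & (r2.to_numpy() <= 1 + 1e-12)).all()


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def test_low_noise_recovery_is_exact(dataset, corrected_ne):
    """Planted 3-group structure is recovered perfectly at the default noise."""
    from sklearn.metrics import adjusted_rand_score

    _, truth = dataset
    cand = [g for gid in ("group1", "group2", "group3") for g in truth.group_members(gid)]
    res = form_groups(corrected_ne.profiles(cand))
    assert adjusted_rand_score(truth.membership[cand], res.assignments[cand]) == 1.0
    recovered = {frozenset(g.members) for g in res.groups}
    planted = {frozenset(truth.group_members(gid)) for gid in ("group1", "group2", "group3")}
    assert recovered == planted
    for g in res.groups:
        assert g.min_within_r2 >= res.threshold
        assert all(v < res.separation_threshold for v in g.max_between_r2.values())


def test_regulator_gene_joins_its_groups_clique(dataset, corrected_ne):
    _, truth = dataset
    members = list(truth.group_members("group2")) + [truth.regulator_ids["group2"]]
    res = form_groups(corrected_ne.profiles(members))
    assert len(res.groups) == 1
    assert set(res.groups[0].members) == set(members)


def test_threshold_one_gives_only_singletons():
    rng = np.random.default_rng(0)
    profiles = pd.DataFrame(rng.lognormal(0, 1, (6, 4)), columns=list(COMPARTMENTS),
                            index=[f"g{i}" for i in range(6)])
    res = form_groups(profiles, threshold=1.0, require_separation=False)
    assert all(len(g.members) == 1 for g in res.groups)


def _shared_gene_profiles(d=0.228):
    base = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1.0, -1.0, -1.0, 1.0]) * d
    return pd.DataFrame(
        {"A": base + e, "X": base, "C": base - e}, index=list(COMPARTMENTS)
    ).T


def test_shared_gene_stays_with_first_clique_and_ambiguity_is_logged():
    """X belongs to maximal cliques {A, X} and {C, X}; ties break
    lexicographically, X stays with A, and the overlap is recorded."""
    profiles = _shared_gene_profiles()
    r, r2 = pairwise_correlations(profiles)
    assert r2.at["A", "X"] > 0.93 > r2.at["A", "C"]
    res = form_groups(profiles, require_separation=False)
    assert res.assignments["A"] == res.assignments["X"] == "group1"
    assert ("X", "group1", "group2") in res.ambiguities
    assert res.assignments["C"] == "group2"  # remaining singleton clique


def test_separation_rule_suppresses_correlated_leftovers():
    profiles = _shared_gene_profiles()
    res = form_groups(profiles, require_separation=True)
    assert res.assignments["C"] == "none"  # C correlates with X above the bound


def test_loose_associates_sit_between_significance_and_grouping_threshold():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1.0, -1.0, -1.0, 1.0])
    profiles = pd.DataFrame(
        {"m1": base, "m2": base * 2.0, "loose": base + 0.35 * e},
        index=list(COMPARTMENTS),
    ).T
    res = form_groups(profiles)
    r2 = res.r2.at["loose", "m1"]
    assert res.separation_threshold < r2 < res.threshold
    assert res.assignments["loose"] == "none"
    assert res.loose_associates.get("group1") == ("loose",)


def test_invalid_threshold_rejected(corrected_ne):
    with pytest.raises(ValueError):
        form_groups(corrected_ne.profiles().head(4), threshold=0.0)


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def test_duplicate_replicates_sit_at_distance_zero(corrected_ne):
    from dataclasses import replace

    gene = corrected_ne.gene_ne.copy()
    for c in COMPARTMENTS:
        gene[f"{c}_2"] = gene[f"{c}_1"]
    ne = replace(corrected_ne, gene_ne=gene)
    qc = replicate_qc(ne)
    assert np.allclose(qc.replicate_distances, 0.0, atol=1e-9)
    assert qc.flagged == ()


def test_pc1_separates_epithelia_from_fibers(dataset):
    from compartseq.quant import compute_ne

    counts, _ = dataset
    qc = replicate_qc(compute_ne(counts))
    pc1 = qc.coordinates["PC1"]
    epi = pc1[[s for s in pc1.index if s.startswith(("EC", "EQ"))]]
    fib = pc1[[s for s in pc1.index if s.startswith(("FP", "FC"))]]
    assert epi.min() > fib.max() or epi.max() < fib.min()
    assert qc.explained_variance_ratio[0] > 0.5


def test_constant_matrix_is_degenerate(corrected_ne):
    from dataclasses import replace

    gene = pd.DataFrame(1.0, index=corrected_ne.gene_ne.index,
                        columns=corrected_ne.gene_ne.columns)
    qc = replicate_qc(replace(corrected_ne, gene_ne=gene))
    assert qc.degenerate
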