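"""Promoter extraction, PWM scanning/thresholds, and matrix set algebra."""

import itertools

import numpy as np
import pandas as pd
import pytest

from compartseq.motifs import (
    PWM,
    extract_promoters,
    partition_matrices,
    read_jaspar,
    read_meme,
    reverse_complement,
    scan_promoters,
    score_threshold_fpr,
    sequence_background,
    write_jaspar,
    write_meme,
)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 8000))
    return {"chr1": seq}


def test_plus_strand_window_coordinates():
    genome = _toy_genome()
    tss = pd.DataFrame([("g", "chr1", 5000, "+")], columns=["gene", "chrom", "pos", "strand"])
    seqs, errors = extract_promoters(tss, genome, window=1000)
    assert not errors
    assert seqs["g"] == genome["chr1"][4000:5000]


def test_minus_strand_window_is_reverse_complement_downstream():
    genome = _toy_genome()
    tss = pd.DataFrame([("g", "chr1", 5000, "-")], columns=["gene", "chrom", "pos", "strand"])
    seqs, _ = extract_promoters(tss, genome, window=1000)
    assert seqs["g"] == reverse_complement(genome["chr1"][5001:6001])


def test_window_truncated_at_contig_edge_and_off_contig_is_error():
    genome = _toy_genome()
    tss = pd.DataFrame(
        [("near", "chr1", 10, "+"), ("off", "chr1", 9999, "+"), ("badchrom", "chr2", 5, "+")],
        columns=["gene", "chrom", "pos", "strand"],
    )
    seqs, errors = extract_promoters(tss, genome, window=1000)
    assert len(seqs["near"]) == 10
    assert {e[0] for e in errors} == {"off", "badchrom"}


def test_synthetic_promoters_round_trip_through_embedded_genome(promoter_data):
    from compartseq.synthetic import embed_promoters

    promoters = promoter_data[0]
    genome, tss = embed_promoters(promoters.sequences)
    seqs, errors = extract_promoters(tss, genome, window=1000)
    assert not errors
    assert seqs == promoters.sequences


def test_promoter_extraction_via_fasta_file(tmp_path, promoter_data):
    from compartseq.motifs import write_fasta
    from compartseq.synthetic import embed_promoters

    promoters = promoter_data[0]
    genome, tss = embed_promoters(promoters.sequences)
    path = tmp_path / "genome.fa"
    write_fasta(genome, path)
    seqs, _ = extract_promoters(tss, path, window=1000)
    assert seqs == promoters.sequences


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def test_fpr_threshold_matches_exhaustive_enumeration():
    """For a small PWM, enumerate all 4^w windows under the background and
    check the exact-convolution threshold."""
    pwm = PWM.from_consensus("toy", "TGACGT"[:6], fidelity=0.8)
    bg = np.array([0.3, 0.2, 0.2, 0.3])
    lo = pwm.log_odds(bg)
    scores, weights = [], []
    for word in itertools.product(range(4), repeat=pwm.width):
        scores.append(sum(lo[i, b] for i, b in enumerate(word)))
        weights.append(np.prod([bg[b] for b in word]))
    scores, weights = np.array(scores), np.array(weights)
    uniq = np.unique(scores)
    for fpr in (1e-2, 1e-3, 1e-4):
        thr = score_threshold_fpr(pwm, bg, fpr)
        # the guaranteed bound: exact tail at the threshold never exceeds fpr
        assert weights[scores >= thr - 1e-9].sum() <= fpr + 1e-12
        # tightness: within width x resolution of the exact smallest threshold
        ok = [v for v in uniq if weights[scores >= v - 1e-12].sum() <= fpr + 1e-15]
        exact_thr = min(ok) if ok else np.inf
        # not needlessly conservative: at most width x resolution above the
        # smallest achieving score value (it may legitimately fall below it,
        # inside a gap of the discrete score distribution)
        assert thr <= exact_thr + pwm.width * 1e-3 + 1e-9


def test_planted_motifs_are_detected_in_every_member(dataset, promoter_data):
    counts, truth = dataset
    _, presence, groups, _ = promoter_data
    for i, (gid, members) in enumerate(sorted(groups.items())):
        assert presence.presence.loc[members, f"M_G{i + 1}"].all()


def test_false_positive_rate_on_unplanted_pairs_is_low(promoter_data):
    """Presence without a planted site only arises from chance hits; with a
    1e-4 per-position FPR over ~2 kb of scanned positions that is < ~0.2."""
    promoters, presence, _, _ = promoter_data
    planted = {(g, m) for g, m in zip(promoters.sites["gene"], promoters.sites["matrix"])}
    unplanted = [
        presence.presence.at[g, p.matrix_id]
        for g in presence.presence.index
        for p in promoters.pwms
        if (g, p.matrix_id) not in planted
    ]
    assert np.mean(unplanted) < 0.3


def test_all_n_sequence_has_no_hits(promoter_data):
    promoters = promoter_data[0]
    res = scan_promoters({"blank": "N" * 1000}, promoters.pwms,
                         background=np.full(4, 0.25))
    assert res.hits.empty
    assert not res.presence.to_numpy().any()


def test_palindromic_pwm_hits_both_strands_at_same_positions():
    pwm = PWM.from_consensus("pal", "TGATATCA", fidelity=0.9)
    assert reverse_complement(pwm.consensus) == pwm.consensus
    rng = np.random.default_rng(1)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
    seq = seq[:500] + "TGATATCA" + seq[508:]
    res = scan_promoters({"s": seq}, [pwm], background=np.full(4, 0.25))
    fwd = set(map(tuple, res.hits.loc[res.hits["strand"] == "+", ["start", "end"]].values))
    rev = set(map(tuple, res.hits.loc[res.hits["strand"] == "-", ["start", "end"]].values))
    assert fwd == rev and (500, 508) in fwd


def test_max_frac_threshold_rule(promoter_data):
    promoters = promoter_data[0]
    res = scan_promoters(promoters.sequences, promoters.pwms,
                         threshold=("max_frac", 0.99))
    # consensus sites score maximally, so every planted member pair is still found
    planted = promoters.sites[promoters.sites["in_member"]]
    for g, m in zip(planted["gene"], planted["matrix"]):
        assert res.presence.at[g, m]


def test_empty_pwm_set_rejected(promoter_data):
    with pytest.raises(ValueError, match="empty PWM"):
        scan_promoters(promoter_data[0].sequences, [])


def test_scan_invariant_under_gene_reordering(promoter_data):
    promoters = promoter_data[0]
    sub = {g: promoters.sequences[g] for g in list(promoters.sequences)[:10]}
    rev = dict(reversed(list(sub.items())))
    bg = sequence_background(sub.values())
    a = scan_promoters(sub, promoters.pwms, background=bg)
    b = scan_promoters(rev, promoters.pwms, background=bg)
    assert a.presence.sort_index().equals(b.presence.sort_index())


# ---------------------------------------------------------------------------
# PWM IO
# ---------------------------------------------------------------------------

def test_jaspar_and_meme_round_trips(tmp_path, promoter_data):
    pwms = promoter_data[0].pwms
    write_jaspar(pwms, tmp_path / "p.jaspar")
    write_meme(pwms, tmp_path / "p.meme")
    for back in (read_jaspar(tmp_path / "p.jaspar"), read_meme(tmp_path / "p.meme")):
        assert [p.matrix_id for p in back] == [p.matrix_id for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.probs, b.probs, atol=1e-3)


# ---------------------------------------------------------------------------
# common / unique partition
# ---------------------------------------------------------------------------

def _brute_force_partition(presence: pd.DataFrame, groups: dict):
    common = {
        g: {m for m in presence.columns if presence.loc[members, m].all()}
        for g, members in groups.items()
    }
    unique = {
        g: {m for m in common[g] if all(m not in common[h] for h in groups if h != g)}
        for g in groups
    }
    return common, unique


def test_partition_matches_brute_force_on_random_presence():
    rng = np.random.default_rng(5)
    genes = [f"g{i}" for i in range(12)]
    mats = [f"m{i}" for i in range(30)]
    presence = pd.DataFrame(rng.random((12, 30)) < 0.6, index=genes, columns=mats)
    groups = {"A": genes[:4], "B": genes[4:9], "C": genes[9:12]}
    part = partition_matrices(presence, groups)
    common, unique = _brute_force_partition(presence, groups)
    assert {g: set(v) for g, v in part.common.items()} == common
    assert {g: set(v) for g, v in part.unique.items()} == unique
    for g in groups:
        total = len(part.all_groups) + len(part.unique[g]) + sum(
            len(part.shared_only(g, h)) for h in groups if h != g
        )
        assert total == len(part.common[g])


def _engineered_presence(class_counts: dict, sizes=(4, 5, 2), extra_absent=10):
    """Presence matrix whose common/unique accounting hits exact class counts.

    A matrix of class S is present in every member of the groups in S and in
    all but one member of every other group (present-in-some must not count)."""
    gids = ("group1", "group2", "group3")
    genes = {g: [f"{g}_m{i}" for i in range(s)] for g, s in zip(gids, sizes)}
    all_genes = [x for v in genes.values() for x in v]
    cols, data = [], []
    k = 0
    for cls, count in class_counts.items():
        for _ in range(count):
            col = pd.Series(False, index=all_genes)
            for g in gids:
                if g in cls:
                    col[genes[g]] = True
                else:
                    col[genes[g][:-1]] = True  # one member misses it
            cols.append(f"mat{k}")
            data.append(col)
            k += 1
    for _ in range(extra_absent):
        cols.append(f"mat{k}")
        data.append(pd.Series(False, index=all_genes))
        k += 1
    presence = pd.concat(data, axis=1)
    presence.columns = cols
    return presence, genes


def test_engineered_partition_reproduces_published_accounting():
    """51 = 20 + 2 + 17 + 12 (group 1), 37 = 20 + 2 + 9 + 6 (group 2), and
    87 - 20 - 17 - 9 = 41 (group 3)."""
    class_counts = {
        ("group1", "group2", "group3"): 20,
        ("group1", "group2"): 2,
        ("group1", "group3"): 17,
        ("group2", "group3"): 9,
        ("group1",): 12,
        ("group2",): 6,
        ("group3",): 41,
    }
    presence, genes = _engineered_presence(class_counts)
    part = partition_matrices(presence, genes)
    assert len(part.common["group1"]) == 51
    assert len(part.common["group2"]) == 37
    assert len(part.common["group3"]) == 87
    assert len(part.all_groups) == 20
    assert len(part.unique["group1"]) == 12
    assert len(part.unique["group2"]) == 6
    assert len(part.unique["group3"]) == 41
    assert len(part.shared_only("group1", "group2")) == 2
    assert len(part.shared_only("group1", "group3")) == 17
    assert len(part.shared_only("group2", "group3")) == 9
    assert len(part.common["group3"]) - len(part.all_groups) \
        - len(part.shared_only("group3", "group1")) \
        - len(part.shared_only("group3", "group2")) == 41


def test_single_group_unique_equals_common():
    presence = pd.DataFrame(True, index=["a", "b"], columns=["m1", "m2"])
    part = partition_matrices(presence, {"only": ["a", "b"]})
    assert part.unique["only"] == part.common["only"] == frozenset({"m1", "m2"})


def test_empty_group_rejected(promoter_data):
    _, presence, _, _ = promoter_data
    with pytest.raises(ValueError, match="no members"):
        partition_matrices(presence, {"empty": []})


def test_planted_motif_is_unique_to_its_group(promoter_data):
    _, _, _, partition = promoter_data
    for i, gid in enumerate(("group1", "group2", "group3")):
        assert f"M_G{i + 1}" in partition.common[gid]
        assert f"M_G{i + 1}" in partition.unique[gid]
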