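# compartseq

Coordinate gene-expression analysis over ordered tissue compartments, at
desk scale.

## The problem

During lens fiber-cell differentiation, cells move through an ordered
series of anatomical compartments — central epithelium (EC), equatorial
epithelium (EQ), cortical fibers (FP), central fibers (FC) — while a small
set of crystallin genes comes to dominate the transcriptome.  Bulk RNA-seq
of microdissected compartments (two pooled replicates each) poses three
linked statistical problems that this package solves as a tested, reusable
pipeline:

1. **Compositional skew.**  Expression is measured relative to the mRNA
   pool.  When one transcript (δ1-crystallin/ASL1) grows from ~2.5% to ~16%
   of the pool, every other gene *appears* to fall.  Normalized expression
   (NE, an RPKM-style unit: reads / length-kb / depth-millions) is corrected
   by a housekeeping panel: factor(c) = mean over panel genes *g* of
   NE(g,c)/NE(g,EC), and corrected NE = NE/factor, so a corrected value of 1
   is the average control-gene level in that compartment.
2. **Differential expression without replicates of the count model.**
   Counts x, y in libraries N1, N2 are compared with the exact
   Audic–Claverie construction: conditional on x, y follows
   p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)).  The reported
   two-sided P is the exact minimum-likelihood tail conditional on the pair
   total (symmetric under swapping the libraries).  Transcript P values are
   aggregated to genes (Šidák minimum), BH-adjusted per comparison, and the
   three adjacent comparisons are combined into a 7-category Venn partition.
3. **Coordinate expression from 4-point profiles.**  Gene pairs are
   compared by the coefficient of determination R² = r² of their profiles
   over the four compartments.  With n = 4 points, R² is significant at
   two-tailed α when R² > t²/(t²+2) with t the Student-t critical value at
   df = 2 — exactly (1−α)² = **0.9025** for α = 0.05.  Coordinately
   expressed groups are maximal cliques of positively correlated pairs with
   R² ≥ 0.93.  Candidate regulators are then ranked per group by combining
   a promoter-motif hypergeometric enrichment P (over 1-kb upstream windows
   scanned with PWMs at an exact per-position FPR threshold) with the mean
   profile R² of the factor against the group: score = −log10(P) × mean R².

A first-class synthetic generator (`compartseq.synthetic`) reproduces the
study design — planted profile-shape groups, the dominant-transcript skew,
constant housekeeping genes, negative-binomial noise over 2 replicates, and
promoters carrying planted group motifs — so every stage has a
ground-truth recovery test.

## Worked example

```python
from compartseq import (
    SyntheticConfig, generate_counts, generate_promoters,
    compute_ne, housekeeping_correct, HousekeepingPanel,
    pairwise_de, venn_partition, form_groups, critical_r2,
    scan_promoters, partition_matrices, rank_candidates,
)

config = SyntheticConfig(seed=1)
counts, truth = generate_counts(config)

ne = housekeeping_correct(compute_ne(counts),
                          HousekeepingPanel(genes=truth.housekeeping_ids))
print("correction factors:", ne.correction_factors.round(3).to_dict())

de = pairwise_de(counts, pairs=[("EC", "EQ"), ("EQ", "FP"), ("FP", "FC")])
venn = venn_partition(de)
print("DE genes in >=1 adjacent comparison:", venn.n_significant)

candidates = [g for gid in ("group1", "group2", "group3")
              for g in truth.group_members(gid)]
grouping = form_groups(ne.profiles(candidates))
print("critical R2 (n=4, alpha=0.05):", critical_r2(4, 0.05))
for g in grouping.groups:
    print(f"{g.group_id}: {', '.join(g.members)} "
          f"(min within-group R2 = {g.min_within_r2:.3f})")

promoters = generate_promoters(config, truth)
presence = scan_promoters(promoters.sequences, promoters.pwms)
groups = {g.group_id: list(g.members) for g in grouping.groups}
partition = partition_matrices(presence, groups)
ranking = rank_candidates(groups, presence, partition, ne.profiles(),
                          promoters.tf_map)
for gid in groups:
    top = ranking.by_score(gid).iloc[0]
    print(f"{gid}: unique matrices {sorted(partition.unique[gid])}, "
          f"top factor {top['factor']} (P = {top['enrichment_p']:.2e}, "
          f"mean R2 = {top['mean_r2']:.3f}, score = {top['combined_score']:.2f})")
```

prints

```
correction factors: {'EC': 1.0, 'EQ': 0.279, 'FP': 0.241, 'FC': 0.209}
DE genes in >=1 adjacent comparison: 120
critical R2 (n=4, alpha=0.05): 0.9025
group1: g2_01, g2_02, g2_03, g2_04, g2_05 (min within-group R2 = 0.990)
group2: g1_01, g1_02, g1_03, g1_04 (min within-group R2 = 0.933)
group3: g3_01, g3_02 (min within-group R2 = 0.999)
group1: unique matrices ['M_G2'], top factor tf_g2 (P = 6.10e-05, mean R2 = 0.998, score = 4.21)
group2: unique matrices ['M_G1'], top factor tf_g1 (P = 7.29e-04, mean R2 = 0.972, score = 3.05)
group3: unique matrices ['M_G3'], top factor tf_g3 (P = 3.87e-02, mean R2 = 0.999, score = 1.41)
```

Reading the output: the correction factors fall to ~0.21 toward the fibers
— the planted crystallin-like groups plus the dominant transcript crowd out
everything else, and dividing by the factors undoes that.  All three
planted groups are recovered exactly (largest clique reported first; labels
are arbitrary), every within-group pair clears the 0.93 floor, each group's
planted motif is the unique matrix for that group, and the planted
regulator ranks first in each group's score view.  Note that *all* 120
genes are differentially expressed in relative units — with deep libraries
the compositional shift alone moves every gene, which is precisely why the
housekeeping correction exists.  Each planted group is also detected where
its shape changes (e.g. fiber-up-regulated genes in EQ–FP).

The same stages are available from the shell:

```bash
compartseq synth --out data/ --seed 1
compartseq quant --counts data/counts.tsv --panel panel.txt --out ne.tsv
compartseq diffexp --counts data/counts.tsv --pairs EC:EQ,EQ:FP,FP:FC \
    --out de.tsv --venn venn.json
compartseq groups --ne ne.tsv --genes g1_01,g1_02,... --out groups.tsv
compartseq scan --promoters data/promoters.fa --pwms data/pwms.jaspar --out scan/
compartseq rank-tfs --ne ne.tsv --groups groups.tsv \
    --presence scan/presence.tsv --tf-map data/tf_map.tsv --out rank/
```

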