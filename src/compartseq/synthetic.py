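"""Synthetic 4-compartment dataset with known ground truth.

Emulates the statistical structure of a pooled-replicate bulk RNA-seq study
of the ordered lens compartments EC -> EQ -> FP -> FC:

* three planted coordinately expressed gene groups with distinct 4-point
  profile shapes (epithelial rise-then-plateau; dramatic fiber up-regulation;
  a transient equatorial peak), pairwise separable in expectation;
* one dominant transcript whose share of the read pool rises from 2.5% of
  the pool in EC to 16% in FC (the delta1-crystallin/ASL1 skew), the central
  compositional confounder the housekeeping correction must undo;
* a panel of housekeeping genes with constant true abundance;
* negative-binomial (or exact multinomial) count noise over 2 independent
  replicates per compartment;
* promoter sequences carrying planted group-specific motifs, one planted
  regulator gene per group whose expression follows the group shape, and
  decoy PWMs/factors;
* optionally a constant 4:1 abundance pair for ratio-invariance tests.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COMPARTMENTS
from .coexpr import critical_r2, profile_r2
from .motifs import PWM, reverse_complement
from .quant import CountMatrix, samples_frame

#: default planted-profile shapes (relative means over EC, EQ, FP, FC)
DEFAULT_SHAPES: tuple[tuple[float, ...], ...] = (
    (0.3, 5.0, 5.0, 4.5),    # rises into the equatorial epithelium, then level
    (0.2, 0.6, 6.0, 10.0),   # increases dramatically into the fibers
    (0.3, 4.0, 1.2, 0.4),    # transient equatorial peak
)

#: planted group motif consensi and decoys
PLANTED_CONSENSUS = ("TGACGCAAT", "GGATTACCG", "CACGTTAGC")
DECOY_CONSENSUS = ("ATCGCTAGA", "TTGACCTTG", "CCGAAGGCT")


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic generator."""

    n_genes: int = 120
    group_sizes: tuple[int, ...] = (4, 5, 2)
    profile_shapes: tuple[tuple[float, ...], ...] = DEFAULT_SHAPES
    dominant_gene_fractions: tuple[float, ...] = (0.025, 0.05, 0.12, 0.16)
    housekeeping_count: int = 14
    dispersion: float = 0.01
    library_sizes: tuple[int, ...] = (1_000_000,) * 8
    promoter_length: int = 1000
    planted_motifs: dict[str, str] | None = None   # group id -> matrix id
    background_motif_prob: float = 0.02
    gc_content: float = 0.42
    seed: int = 0
    counting: str = "nb"                 # "nb" | "multinomial"
    include_dominant: bool = True
    include_ratio_pair: bool = False
    ratio: float = 4.0
    plant_regulators: bool = True
    n_decoy_pwms: int = 3
    transcripts_per_gene: int = 1
    group_expression_scale: float = 200.0
    site_fidelity: float = 1.0           # 1.0 plants the consensus site

    def __post_init__(self):
        if len(self.group_sizes) != len(self.profile_shapes):
            raise ValueError("one profile shape per group is required")
        if sum(self.group_sizes) > self.n_genes:
            raise ValueError("group_sizes exceed n_genes")
        if len(self.dominant_gene_fractions) != len(COMPARTMENTS):
            raise ValueError("need one dominant fraction per compartment")
        if any(not 0 <= f < 1 for f in self.dominant_gene_fractions):
            raise ValueError("dominant fractions must lie in [0, 1)")
        if len(self.library_sizes) != 2 * len(COMPARTMENTS):
            raise ValueError("need 4 compartments x 2 replicates library sizes")
        if any(l <= 0 for l in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.counting not in ("nb", "multinomial"):
            raise ValueError("counting must be 'nb' or 'multinomial'")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        sep = critical_r2(len(COMPARTMENTS), 0.05)
        for i, a in enumerate(self.profile_shapes):
            for b in self.profile_shapes[i + 1 :]:
                res = profile_r2(a, b)
                if res.r > 0 and res.r2 >= sep:
                    raise ValueError(
                        "profile shapes are not separable: a pair has "
                        f"R² = {res.r2:.3f} >= {sep:.4f} with positive correlation"
                    )

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(f"group{i + 1}" for i in range(len(self.group_sizes)))

    def motif_of(self, group_id: str) -> str:
        if self.planted_motifs:
            return self.planted_motifs[group_id]
        i = self.group_ids.index(group_id)
        return f"M_G{i + 1}"


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery tests."""

    membership: pd.Series                      # gene -> group id / "background"
    true_abundance: pd.DataFrame               # genes x compartments, molar units
    housekeeping_ids: tuple[str, ...]
    dominant_id: str | None
    regulator_ids: dict[str, str]              # group id -> regulator gene
    ratio_pair: tuple[str, str] | None
    planted_sites: pd.DataFrame | None = None  # filled by generate_promoters

    def group_members(self, group_id: str) -> tuple[str, ...]:
        return tuple(self.membership.index[self.membership == group_id])


@dataclass
class PromoterSet:
    """Promoter sequences, the PWM set, planted-site records, factor map."""

    sequences: dict[str, str]
    pwms: list[PWM]
    sites: pd.DataFrame     # gene, matrix, start, end, strand, in_member
    tf_map: pd.DataFrame    # matrix, factor

    def write_fasta(self, path) -> None:
        from .motifs import write_fasta

        write_fasta(self.sequences, path)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.sites.itertuples(index=False):
                fh.write(f"{s.gene}\t{s.start}\t{s.end}\t{s.matrix}\t0\t{s.strand}\n")


def read_sites_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene", "start", "end", "matrix", "score", "strand"],
    )
    return df.drop(columns="score")


# ---------------------------------------------------------------------------
# construction of expectations
# ---------------------------------------------------------------------------

def _gene_names(config: SyntheticConfig):
    names, membership = [], []
    for gi, size in enumerate(config.group_sizes):
        for j in range(size):
            names.append(f"g{gi + 1}_{j + 1:02d}")
            membership.append(f"group{gi + 1}")
    hk = [f"hk{j + 1:02d}" for j in range(config.housekeeping_count)]
    names += hk
    membership += ["background"] * len(hk)
    regulators = {}
    if config.plant_regulators:
        for gi in range(len(config.group_sizes)):
            name = f"tf_g{gi + 1}"
            regulators[f"group{gi + 1}"] = name
            names.append(name)
            membership.append("background")
    ratio_pair = None
    if config.include_ratio_pair:
        ratio_pair = ("rpA", "rpB")
        names += list(ratio_pair)
        membership += ["background", "background"]
    dominant = "dom1" if config.include_dominant else None
    if dominant:
        names.append(dominant)
        membership.append("background")
    n_bg = config.n_genes - len(names)
    if n_bg < 0:
        raise ValueError("n_genes too small for the configured special genes")
    bg = [f"bg{j + 1:03d}" for j in range(n_bg)]
    names += bg
    membership += ["background"] * n_bg
    return names, membership, tuple(hk), regulators, ratio_pair, dominant, bg


def _build_truth(config: SyntheticConfig, rng: np.random.Generator):
    names, membership, hk, regulators, ratio_pair, dominant, bg = _gene_names(config)
    membership = pd.Series(membership, index=pd.Index(names, name="gene"))
    shapes = {f"group{i + 1}": np.asarray(s, dtype=float)
              for i, s in enumerate(config.profile_shapes)}

    ab = pd.DataFrame(0.0, index=membership.index, columns=list(COMPARTMENTS))
    for gid, shape in shapes.items():
        for gene in membership.index[membership == gid]:
            scale = config.group_expression_scale * rng.lognormal(0.0, 0.3)
            ab.loc[gene] = shape / shape.mean() * scale
    for gid, gene in regulators.items():
        scale = config.group_expression_scale / 4.0 * rng.lognormal(0.0, 0.3)
        ab.loc[gene] = shapes[gid] / shapes[gid].mean() * scale
    for gene in hk:
        ab.loc[gene] = rng.lognormal(np.log(20.0), 1.0)
    if ratio_pair:
        shape = shapes["group1"] / shapes["group1"].mean()
        scale = config.group_expression_scale * rng.lognormal(0.0, 0.3)
        ab.loc[ratio_pair[0]] = shape * scale
        ab.loc[ratio_pair[1]] = shape * scale / config.ratio
    for gene in bg:
        base = rng.lognormal(np.log(5.0), 1.0)
        ab.loc[gene] = base * rng.lognormal(0.0, 0.3, size=len(COMPARTMENTS))

    # transcripts and lengths
    tx_rows = []
    k = max(1, config.transcripts_per_gene)
    for gene in membership.index:
        for t in range(k):
            length = int(np.clip(rng.lognormal(np.log(2000.0), 0.5), 300, 10000))
            tx_rows.append((f"{gene}.t{t + 1}", gene, length))
    tx = pd.DataFrame(tx_rows, columns=["transcript_id", "gene_id", "length"]).set_index(
        "transcript_id"
    )

    # read-space weights: abundance x length (kb), gene abundance split evenly
    w = (
        ab.loc[tx["gene_id"]].to_numpy()
        * (tx["length"].to_numpy() / 1e3)[:, None]
        / k
    )
    w = pd.DataFrame(w, index=tx.index, columns=list(COMPARTMENTS))

    if dominant:
        dom_tx = w.index[tx["gene_id"] == dominant]
        f = np.asarray(config.dominant_gene_fractions, dtype=float)
        others = w.drop(index=dom_tx).sum(axis=0).to_numpy()
        w_dom = f / (1.0 - f) * others
        w.loc[dom_tx] = w_dom / len(dom_tx)
        dom_len = tx.loc[dom_tx, "length"].to_numpy()
        ab.loc[dominant] = (w.loc[dom_tx].to_numpy() * 1e3 / dom_len[:, None]).sum(axis=0)

    truth = GroundTruth(
        membership=membership,
        true_abundance=ab,
        housekeeping_ids=hk,
        dominant_id=dominant,
        regulator_ids=regulators,
        ratio_pair=ratio_pair,
    )
    return truth, tx, w


def expected_counts(config: SyntheticConfig):
    """Expected count matrix (transcripts x samples) and the ground truth.

    Expectations are library_size x weight / column-weight-sum with weight =
    abundance x length; the noise-free limit of both sampling modes.
    """
    rng = np.random.default_rng(config.seed)
    truth, tx, w = _build_truth(config, rng)
    sample_names = [f"{c}_{r}" for c in COMPARTMENTS for r in (1, 2)]
    p = w / w.sum(axis=0)
    mu = pd.DataFrame(index=w.index, columns=sample_names, dtype=float)
    for i, s in enumerate(sample_names):
        comp = s.split("_")[0]
        mu[s] = p[comp] * config.library_sizes[i]
    return mu, truth, tx


def generate_counts(config: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw the transcript x 8-sample count matrix and its ground truth.

    ``counting="nb"`` draws independent negative binomial counts with
    variance mu + dispersion * mu² per replicate (Poisson at dispersion 0);
    ``counting="multinomial"`` distributes each library exactly, so column
    sums equal the configured library sizes.
    """
    rng = np.random.default_rng(config.seed)
    truth, tx, w = _build_truth(config, rng)
    sample_names = [f"{c}_{r}" for c in COMPARTMENTS for r in (1, 2)]
    p = (w / w.sum(axis=0)).to_numpy()
    comp_index = {c: i for i, c in enumerate(COMPARTMENTS)}
    counts = np.zeros((len(w), len(sample_names)), dtype=np.int64)
    for j, s in enumerate(sample_names):
        lib = config.library_sizes[j]
        pj = p[:, comp_index[s.split("_")[0]]]
        if config.counting == "multinomial":
            counts[:, j] = rng.multinomial(lib, pj / pj.sum())
        else:
            mu = lib * pj
            if config.dispersion == 0:
                counts[:, j] = rng.poisson(mu)
            else:
                n = 1.0 / config.dispersion
                prob = n / (n + mu)
                counts[:, j] = rng.negative_binomial(n, prob)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=w.index, columns=sample_names),
        gene_map=tx["gene_id"],
        lengths=tx["length"].astype(float),
        samples=samples_frame(sample_names),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# promoters, PWMs, planted sites
# ---------------------------------------------------------------------------

def default_pwms(config: SyntheticConfig) -> list[PWM]:
    pwms = []
    for i in range(len(config.group_sizes)):
        pwms.append(
            PWM.from_consensus(f"M_G{i + 1}", PLANTED_CONSENSUS[i % len(PLANTED_CONSENSUS)])
        )
    for i in range(config.n_decoy_pwms):
        pwms.append(
            PWM.from_consensus(f"M_X{i + 1}", DECOY_CONSENSUS[i % len(DECOY_CONSENSUS)])
        )
    return pwms


def _random_seq(rng, length, gc) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=probs)


def _sample_site(rng, pwm: PWM, fidelity: float) -> str:
    if fidelity >= 1.0:
        return pwm.consensus
    site = []
    for row in pwm.probs:
        if rng.random() < fidelity:
            site.append("ACGT"[int(np.argmax(row))])
        else:
            site.append("ACGT"[rng.choice(4, p=row)])
    return "".join(site)


def _place(rng, occupied: list[tuple[int, int]], length: int, width: int):
    for _ in range(50):
        start = int(rng.integers(0, length - width + 1))
        if all(start + width <= a or start >= b for a, b in occupied):
            occupied.append((start, start + width))
            return start
    return None


def generate_promoters(config: SyntheticConfig, truth: GroundTruth) -> PromoterSet:
    """Promoter FASTA with planted group motifs, PWM set, site BED, factor map.

    Every group member's promoter carries >= 1 planted instance of the
    group's motif (the consensus by default, hence at maximal score);
    background promoters carry each planted motif independently with
    probability ``background_motif_prob``.  Also assembles the many-to-many
    matrix -> factor table: each planted matrix is bound by its group's
    planted regulator plus decoy factors drawn from background genes.
    """
    pwms = default_pwms(config)
    by_id = {p.matrix_id: p for p in pwms}
    for gid in config.group_ids:
        mid = config.motif_of(gid)
        if mid not in by_id:
            raise ValueError(f"planted motif {mid!r} not in the PWM set")
        if by_id[mid].width > config.promoter_length:
            raise ValueError("motif longer than promoter")

    rng = np.random.default_rng((config.seed, 7))
    group_of = truth.membership
    planted_ids = [config.motif_of(g) for g in config.group_ids]

    seqs: dict[str, str] = {}
    rows = []
    for gene in truth.membership.index:
        arr = _random_seq(rng, config.promoter_length, config.gc_content)
        seq = "".join("ACGT"[i] for i in arr)
        occupied: list[tuple[int, int]] = []
        to_plant: list[tuple[str, bool]] = []
        gid = group_of[gene]
        if gid != "background":
            to_plant.append((config.motif_of(gid), True))
        for mid in planted_ids:
            if (gid == "background" or mid != config.motif_of(gid)) and (
                rng.random() < config.background_motif_prob
            ):
                to_plant.append((mid, False))
        for mid, in_member in to_plant:
            pwm = by_id[mid]
            start = _place(rng, occupied, config.promoter_length, pwm.width)
            if start is None:
                continue
            site = _sample_site(rng, pwm, config.site_fidelity)
            strand = "+" if rng.random() < 0.5 else "-"
            ins = site if strand == "+" else reverse_complement(site)
            seq = seq[:start] + ins + seq[start + pwm.width :]
            rows.append((gene, mid, start, start + pwm.width, strand, in_member))
        seqs[gene] = seq

    sites = pd.DataFrame(
        rows, columns=["gene", "matrix", "start", "end", "strand", "in_member"]
    )
    truth.planted_sites = sites

    # matrix -> factor map: planted regulator + decoy co-binders per matrix
    special = set(truth.regulator_ids.values()) | set(truth.housekeeping_ids) | {truth.dominant_id}
    if truth.ratio_pair:
        special |= set(truth.ratio_pair)
    bg_pool = [g for g in truth.membership.index
               if truth.membership[g] == "background" and g not in special]
    tf_rows = []
    cursor = 0
    for gi, gid in enumerate(config.group_ids):
        mid = config.motif_of(gid)
        if gid in truth.regulator_ids:
            tf_rows.append((mid, truth.regulator_ids[gid]))
        for _ in range(2):
            tf_rows.append((mid, bg_pool[cursor % len(bg_pool)]))
            cursor += 1
    for p in pwms:
        if p.matrix_id not in planted_ids:
            for _ in range(2):
                tf_rows.append((p.matrix_id, bg_pool[cursor % len(bg_pool)]))
                cursor += 1
    tf_map = pd.DataFrame(tf_rows, columns=["matrix", "factor"]).drop_duplicates()

    for p in pwms:
        p.factors = tuple(tf_map.loc[tf_map["matrix"] == p.matrix_id, "factor"])

    return PromoterSet(sequences=seqs, pwms=pwms, sites=sites, tf_map=tf_map)


def embed_promoters(sequences: dict[str, str], spacer: int = 50):
    """Embed promoters in a single synthetic contig for extraction round-trips.

    Every third gene is placed on the minus strand.  Returns
    ``(genome, tss_table)`` such that
    :func:`compartseq.motifs.extract_promoters` with the right window
    reproduces ``sequences`` exactly.
    """
    parts: list[str] = []
    cursor = 0
    rows = []
    for i, (gene, seq) in enumerate(sequences.items()):
        parts.append("N" * spacer)
        cursor += spacer
        if i % 3 == 2:
            tss = cursor
            parts.append("A" + reverse_complement(seq))
            cursor += 1 + len(seq)
            rows.append((gene, "chrS", tss, "-"))
        else:
            parts.append(seq)
            tss = cursor + len(seq)
            parts.append("A")
            cursor += len(seq) + 1
            rows.append((gene, "chrS", tss, "+"))
    genome = {"chrS": "".join(parts)}
    tss = pd.DataFrame(rows, columns=["gene", "chrom", "pos", "strand"])
    return genome, tss


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_gtf(counts: CountMatrix, path) -> None:
    """GTF-lite: sequential transcript + single-exon records on one contig."""
    cursor = 1
    with open(path, "w") as fh:
        for t in counts.counts.index:
            gene = counts.gene_map[t]
            length = int(counts.lengths[t])
            start, end = cursor, cursor + length - 1
            attrs = f'gene_id "{gene}"; transcript_id "{t}";'
            fh.write(f"chrS\tsynth\ttranscript\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
            fh.write(f"chrS\tsynth\texon\t{start}\t{end}\t.\t+\t.\t{attrs}\n")
            cursor = end + 101


def write_dataset(outdir, counts: CountMatrix, truth: GroundTruth,
                  promoters: PromoterSet | None = None) -> None:
    """Write the whole dataset as plain-text files under ``outdir``."""
    import os

    from .motifs import write_jaspar, write_meme

    os.makedirs(outdir, exist_ok=True)
    counts.to_tsv(os.path.join(outdir, "counts.tsv"))
    counts.to_mtx(os.path.join(outdir, "mtx"))
    write_gtf(counts, os.path.join(outdir, "annotation.gtf"))
    truth.membership.rename("group").to_csv(os.path.join(outdir, "truth_membership.tsv"), sep="\t")
    truth.true_abundance.to_csv(os.path.join(outdir, "true_abundance.tsv"), sep="\t")
    if promoters is not None:
        promoters.write_fasta(os.path.join(outdir, "promoters.fa"))
        promoters.write_bed(os.path.join(outdir, "planted_sites.bed"))
        write_jaspar(promoters.pwms, os.path.join(outdir, "pwms.jaspar"))
        write_meme(promoters.pwms, os.path.join(outdir, "pwms.meme"))
        promoters.tf_map.to_csv(os.path.join(outdir, "tf_map.tsv"), sep="\t", index=False)
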