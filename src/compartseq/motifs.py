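"""Promoter extraction, PWM scanning, and the common/unique matrix partition.

Promoters are the 1-kb windows immediately upstream of each transcription
start site, strand-aware and 0-based half-open.  Each position weight
matrix (one matrix, possibly many binding factors) is scanned on both
strands with log2 odds against a 0-order background; a promoter "contains"
a matrix when at least one window scores above a threshold, by default the
score whose per-position false positive rate under the background is 1e-4
(computed by exact convolution of the discretized score distribution, the
classic PATSER construction).

Group set algebra: a matrix is *common* to a group when present in every
member's promoter, and *unique* to the group when it is common to that
group but not common to any other group (presence in some, but not all,
promoters of another group does not disqualify it).  The partition of each
group's common set into all-group / pairwise-shared / unique classes is
exact and additive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# PWM
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """Position weight matrix over A, C, G, T with bound-factor annotation."""

    matrix_id: str
    probs: np.ndarray                      # (width, 4), rows sum to 1
    factors: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (width, 4)")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        rows = self.probs.sum(axis=1)
        if np.any(rows <= 0):
            raise ValueError("every position needs positive mass")
        self.probs = self.probs / rows[:, None]

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(cls, matrix_id, counts, pseudocount: float = 0.5, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(matrix_id, counts / counts.sum(axis=1, keepdims=True), **kw)

    @classmethod
    def from_consensus(
        cls, matrix_id, consensus: str, fidelity: float = 0.85, **kw
    ) -> "PWM":
        """Near-consensus PWM: ``fidelity`` mass on the consensus base."""
        off = (1.0 - fidelity) / 3.0
        probs = np.full((len(consensus), 4), off)
        for i, b in enumerate(consensus.upper()):
            probs[i, _BASE_INDEX[b]] = fidelity
        return cls(matrix_id, probs, **kw)

    def log_odds(self, background: np.ndarray, pseudo: float = 1e-6) -> np.ndarray:
        """(width, 4) log2 odds of the motif model vs the background."""
        bg = np.asarray(background, dtype=float)
        bg = bg / bg.sum()
        return np.log2((self.probs + pseudo) / (bg + pseudo)[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.matrix_id, self.probs[::-1, ::-1].copy(), self.factors, self.name
        )

    def max_score(self, background: np.ndarray) -> float:
        return float(self.log_odds(background).max(axis=1).sum())


# ----- PWM file IO (JASPAR and minimal MEME, via Bio.motifs) ---------------

def write_jaspar(pwms, path, scale: int = 100) -> None:
    from Bio import motifs as bmotifs

    records = []
    for p in pwms:
        counts = {b: list(np.round(p.probs[:, i] * scale, 4)) for i, b in enumerate(_BASES)}
        m = bmotifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = p.matrix_id
        m.name = p.name or ",".join(p.factors) or p.matrix_id
        records.append(m)
    with open(path, "w") as fh:
        fh.write(bmotifs.write(records, "jaspar"))


def read_jaspar(path) -> list[PWM]:
    from Bio import motifs as bmotifs

    out = []
    with open(path) as fh:
        for m in bmotifs.parse(fh, "jaspar"):
            counts = np.column_stack([m.counts[b] for b in _BASES])
            out.append(PWM.from_counts(m.matrix_id, counts, pseudocount=0.0, name=m.name or ""))
    return out


def write_meme(pwms, path, background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """Minimal MEME motif format."""
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.5f}" for b, f in zip(_BASES, bg))
            + "\n\n"
        )
        for p in pwms:
            fh.write(f"MOTIF {p.matrix_id} {p.name or p.matrix_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {p.width} "
                f"nsites= 100 E= 0\n"
            )
            for row in p.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    from Bio import motifs as bmotifs

    out = []
    with open(path) as fh:
        for m in bmotifs.parse(fh, "minimal"):
            mid = getattr(m, "matrix_id", None) or m.name
            counts = np.column_stack([m.counts[b] for b in _BASES])
            out.append(PWM.from_counts(mid, counts, pseudocount=0.0, name=m.name or ""))
    return out


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

def extract_promoters(tss: pd.DataFrame, genome, window: int = 1000):
    """Strand-aware upstream windows ``[TSS - window, TSS)`` (0-based half-open).

    ``tss`` needs columns gene, chrom, pos (0-based position of the first
    transcribed base) and strand.  Minus-strand windows are
    ``[TSS + 1, TSS + 1 + window)`` on the reference, reverse-complemented.
    Windows are truncated at contig edges with a warning; a TSS lying off
    its contig produces a per-gene error record instead of a sequence.

    Returns ``(sequences, errors)`` where sequences maps gene -> str.
    """
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        from pyfaidx import Fasta

        fa = Fasta(str(genome))
        contigs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        contigs = {k: str(v) for k, v in dict(genome).items()}

    seqs: dict[str, str] = {}
    errors: list[tuple[str, str]] = []
    for row in tss.itertuples(index=False):
        gene, chrom, pos, strand = row.gene, row.chrom, int(row.pos), row.strand
        if chrom not in contigs:
            errors.append((gene, f"unknown contig {chrom}"))
            continue
        ref = contigs[chrom]
        if pos < 0 or pos >= len(ref):
            errors.append((gene, f"TSS {pos} outside contig {chrom} (len {len(ref)})"))
            continue
        if strand == "+":
            start, end = max(0, pos - window), pos
            seq = ref[start:end]
        elif strand == "-":
            start, end = pos + 1, min(len(ref), pos + 1 + window)
            seq = reverse_complement(ref[start:end])
        else:
            errors.append((gene, f"bad strand {strand!r}"))
            continue
        if len(seq) < window:
            logger.warning("promoter of %s truncated at contig edge (%d bp)", gene, len(seq))
        seqs[gene] = seq.upper()
    return seqs, errors


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict, path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def sequence_background(seqs) -> np.ndarray:
    """0-order base composition of a sequence set (with a small floor)."""
    counts = np.ones(4)  # pseudocount keeps log odds finite on skewed sets
    for s in seqs:
        for b, i in _BASE_INDEX.items():
            counts[i] += s.count(b)
    return counts / counts.sum()


def score_threshold_fpr(
    pwm: PWM, background: np.ndarray, fpr: float = 1e-4, resolution: float = 1e-3
) -> float:
    """Smallest score with per-position tail probability <= ``fpr``.

    Exact distribution of the log2-odds score of a background-generated
    window, by convolution over positions on a discretized score grid.
    Per-position scores are rounded *up* to the grid, so the returned
    threshold is conservative: the true tail probability at the threshold
    never exceeds ``fpr`` (the threshold itself is at most
    width x resolution above the exact one).
    """
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    lo = pwm.log_odds(bg)
    grid = np.ceil(lo / resolution - 1e-12).astype(np.int64)
    dist = np.array([1.0])
    offset = 0  # value of index 0 in grid units
    for i in range(pwm.width):
        vals = grid[i]
        lo_v, hi_v = int(vals.min()), int(vals.max())
        new = np.zeros(len(dist) + (hi_v - lo_v))
        for b in range(4):
            shift = int(vals[b]) - lo_v
            new[shift : shift + len(dist)] += bg[b] * dist
        dist = new
        offset += lo_v
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(-tail, -fpr)  # first index with tail <= fpr
    if idx >= len(dist):
        idx = len(dist) - 1
    return (idx + offset) * resolution


@dataclass
class MotifPresenceMatrix:
    """Gene x matrix presence with per-hit records and the scan parameters."""

    presence: pd.DataFrame      # bool, genes x matrix ids
    hits: pd.DataFrame          # gene, matrix, start, end, strand, score
    params: dict = field(default_factory=dict)
    background: np.ndarray | None = None

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for h in self.hits.itertuples(index=False):
                fh.write(
                    f"{h.gene}\t{h.start}\t{h.end}\t{h.matrix}\t"
                    f"{h.score:.3f}\t{h.strand}\n"
                )


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    w = lo.shape[0]
    n = len(idx) - w + 1
    if n <= 0:
        return np.empty(0)
    # N (index 4) scores as background: log-odds contribution 0
    padded = np.hstack([lo, np.zeros((w, 1))])
    scores = np.zeros(n)
    for j in range(w):
        scores += padded[j, idx[j : j + n]]
    return scores


def scan_promoters(
    promoters,
    pwms,
    threshold: tuple[str, float] = ("fpr", 1e-4),
    background: np.ndarray | None = None,
) -> MotifPresenceMatrix:
    """Scan every promoter with every PWM on both strands.

    ``threshold`` is ``("fpr", p)`` for an exact per-position false positive
    rate under the background, or ``("max_frac", f)`` for a fraction of the
    maximum attainable score.  Positions outside {A,C,G,T} contribute a
    background (zero) log-odds term.
    """
    if isinstance(promoters, (str, bytes)) or hasattr(promoters, "__fspath__"):
        promoters = read_fasta(promoters)
    pwms = list(pwms)
    if not pwms:
        raise ValueError("empty PWM set")
    if background is None:
        background = sequence_background(promoters.values())
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    kind, value = threshold
    thresholds = {}
    for p in pwms:
        if kind == "fpr":
            thresholds[p.matrix_id] = score_threshold_fpr(p, background, value)
        elif kind == "max_frac":
            thresholds[p.matrix_id] = value * p.max_score(background)
        else:
            raise ValueError("threshold kind must be 'fpr' or 'max_frac'")

    genes = list(promoters)
    encoded = {g: _encode(promoters[g]) for g in genes}
    rows = []
    presence = pd.DataFrame(False, index=pd.Index(genes, name="gene"),
                            columns=[p.matrix_id for p in pwms])
    for p in pwms:
        lo_f = p.log_odds(background)
        lo_r = p.reverse_complement().log_odds(background)
        thr = thresholds[p.matrix_id] - 1e-9
        for g in genes:
            idx = encoded[g]
            for strand, lo in (("+", lo_f), ("-", lo_r)):
                scores = _window_scores(idx, lo)
                for pos in np.nonzero(scores >= thr)[0]:
                    rows.append((g, p.matrix_id, int(pos), int(pos) + p.width,
                                 strand, float(scores[pos])))
                    presence.at[g, p.matrix_id] = True
    hits = pd.DataFrame(
        rows, columns=["gene", "matrix", "start", "end", "strand", "score"]
    )
    return MotifPresenceMatrix(
        presence=presence,
        hits=hits,
        params={"threshold": threshold, "window": max(map(len, promoters.values()), default=0)},
        background=background,
    )


# ---------------------------------------------------------------------------
# common / unique partition
# ---------------------------------------------------------------------------

@dataclass
class MatrixPartition:
    """Classification of each group's common matrices by which groups share them."""

    group_ids: tuple[str, ...]
    common: dict[str, frozenset]                   # group -> matrices in all members
    by_class: dict[frozenset, frozenset]           # set-of-groups -> matrices
    unique: dict[str, frozenset]
    all_groups: frozenset

    def shared_only(self, g: str, h: str) -> frozenset:
        return self.by_class.get(frozenset({g, h}), frozenset())

    def counts(self) -> pd.DataFrame:
        rows = []
        for g in self.group_ids:
            rows.append(
                {
                    "group": g,
                    "common": len(self.common[g]),
                    "all_groups": len(self.all_groups),
                    **{
                        f"shared_{h}_only": len(self.shared_only(g, h))
                        for h in self.group_ids
                        if h != g
                    },
                    "unique": len(self.unique[g]),
                }
            )
        return pd.DataFrame(rows).set_index("group")


def partition_matrices(presence: MotifPresenceMatrix | pd.DataFrame, groups) -> MatrixPartition:
    """Common/unique matrix accounting over coexpression groups.

    ``groups`` maps group id -> member genes (or is a list of objects with
    ``group_id`` and ``members``).  For every group the additive identity
    |common(g)| = |all groups| + sum of pairwise-shared-only + ... + |unique(g)|
    holds exactly because classes partition common(g).
    """
    pres = presence.presence if isinstance(presence, MotifPresenceMatrix) else presence
    if hasattr(groups, "groups"):
        groups = groups.groups
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(g.group_id, list(g.members)) for g in groups]
    common: dict[str, frozenset] = {}
    for gid, members in items:
        members = list(members)
        if not members:
            raise ValueError(f"group {gid} has no members")
        missing = [m for m in members if m not in pres.index]
        if missing:
            raise ValueError(f"group {gid} members absent from presence matrix: {missing}")
        mask = pres.loc[members].all(axis=0)
        common[gid] = frozenset(pres.columns[mask])

    gids = tuple(g for g, _ in items)
    by_class: dict[frozenset, set] = {}
    for m in frozenset().union(*common.values()) if common else frozenset():
        cls = frozenset(g for g in gids if m in common[g])
        by_class.setdefault(cls, set()).add(m)
    by_class = {k: frozenset(v) for k, v in by_class.items()}
    unique = {g: by_class.get(frozenset({g}), frozenset()) for g in gids}
    all_groups = by_class.get(frozenset(gids), frozenset()) if len(gids) > 1 else frozenset()

    # additive identity: the classes containing g partition common(g)
    for g in gids:
        total = sum(len(ms) for cls, ms in by_class.items() if g in cls)
        assert total == len(common[g])

    return MatrixPartition(
        group_ids=gids,
        common=common,
        by_class=by_class,
        unique=unique,
        all_groups=all_groups,
    )
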