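"""Normalized expression (NE) and housekeeping-panel compositional correction.

NE is an RPKM-style statistic: the reads falling in a transcript's exons,
divided by the transcript length in kilobases and the sample's sequencing
depth in millions of mapped reads.  Gene-level NE is the sum of the gene's
transcript NE values (the gene's total mRNA output); compartment-level NE is
the mean over replicate samples.

Relative expression units are distorted when a single transcript comes to
dominate the mRNA pool.  In the embryonic chicken lens the
delta1-crystallin (ASL1) message rises from roughly 2.5% of all mRNA in the
central epithelium to 16% in the central fibers, which makes every other
gene's *apparent* level fall even when its true synthesis is constant.
:func:`housekeeping_correct` counters this compositional skew by rescaling
each compartment with the average behaviour of a panel of control genes,
each first normalized to its own level in a reference compartment.  After
correction, a value of 1 equals the average control-gene level in that
compartment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import COMPARTMENTS

logger = logging.getLogger(__name__)

#: Control genes commonly used as qRT-PCR / RNA-seq references.
DEFAULT_HOUSEKEEPING_GENES: tuple[str, ...] = (
    "GAPDH", "ACTB", "HMBS", "H6PD", "RPL4", "RPLP0", "RPLP1",
    "TFRC", "ALB", "B2M", "SDHA", "TBP", "TUBB", "YWHAZ",
)


def samples_frame(sample_names) -> pd.DataFrame:
    """Build the sample sheet from names of the form ``<compartment>_<replicate>``."""
    rows = []
    for s in sample_names:
        comp, _, rep = s.partition("_")
        if comp not in COMPARTMENTS or not rep:
            raise ValueError(f"cannot parse sample name {s!r}; expected e.g. 'EC_1'")
        rows.append((s, comp, int(rep)))
    return pd.DataFrame(rows, columns=["sample", "compartment", "replicate"]).set_index("sample")


@dataclass
class CountMatrix:
    """Transcript-level read counts over compartment/replicate samples.

    Parameters
    ----------
    counts
        Integer counts, transcripts x samples.
    gene_map
        transcript id -> gene id (each transcript maps to exactly one gene).
    lengths
        transcript id -> transcript length in bases.
    samples
        Sample sheet indexed by sample name with ``compartment`` and
        ``replicate`` columns; built from column names when omitted.
    """

    counts: pd.DataFrame
    gene_map: pd.Series
    lengths: pd.Series
    samples: pd.DataFrame = None

    def __post_init__(self):
        if self.samples is None:
            self.samples = samples_frame(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_map = self.gene_map.reindex(self.counts.index)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.gene_map.isna().any():
            missing = self.gene_map.index[self.gene_map.isna()].tolist()
            raise ValueError(f"transcripts without a gene assignment: {missing[:5]}")
        bad = self.lengths.notna() & (self.lengths <= 0)
        if bad.any():
            raise ValueError("transcript lengths must be positive")
        unknown = set(self.samples["compartment"]) - set(COMPARTMENTS)
        if unknown:
            raise ValueError(f"unknown compartments: {sorted(unknown)}")

    @property
    def compartments(self) -> list[str]:
        present = set(self.samples["compartment"])
        return [c for c in COMPARTMENTS if c in present]

    def samples_of(self, compartment: str) -> list[str]:
        sel = self.samples.index[self.samples["compartment"] == compartment]
        return list(sel)

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    # ----- IO ---------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"gene_id": self.gene_map, "length": self.lengths}
        ).join(self.counts)
        df.index.name = "transcript_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="transcript_id")
        gene_map = df.pop("gene_id")
        lengths = df.pop("length").astype(float)
        return cls(df.astype(int), gene_map, lengths)

    def to_mtx(self, outdir) -> None:
        """Write a MatrixMarket triple (matrix.mtx, transcripts.tsv, samples.tsv)."""
        import os

        from scipy import io as sio
        from scipy import sparse

        os.makedirs(outdir, exist_ok=True)
        sio.mmwrite(
            os.path.join(outdir, "matrix.mtx"),
            sparse.csr_matrix(self.counts.to_numpy()),
        )
        pd.DataFrame({"gene_id": self.gene_map, "length": self.lengths}).rename_axis(
            "transcript_id"
        ).to_csv(os.path.join(outdir, "transcripts.tsv"), sep="\t")
        self.samples.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t")

    @classmethod
    def from_mtx(cls, outdir) -> "CountMatrix":
        import os

        from scipy import io as sio

        mat = sio.mmread(os.path.join(outdir, "matrix.mtx")).toarray().astype(int)
        tx = pd.read_csv(os.path.join(outdir, "transcripts.tsv"), sep="\t", index_col=0)
        samples = pd.read_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index_col=0)
        counts = pd.DataFrame(mat, index=tx.index, columns=samples.index)
        return cls(counts, tx["gene_id"], tx["length"].astype(float), samples)


def read_transcript_annotation(gtf_path) -> pd.DataFrame:
    """Transcript -> (gene id, exonic length) from a GTF.

    Length is the summed exon span per transcript; transcripts without exon
    records fall back to the transcript feature span.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for t in db.features_of_type("transcript"):
        exons = list(db.children(t, featuretype="exon"))
        length = sum(e.end - e.start + 1 for e in exons) if exons else t.end - t.start + 1
        rows.append((t.attributes["transcript_id"][0], t.attributes["gene_id"][0], length))
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "length"]).set_index(
        "transcript_id"
    )


@dataclass
class HousekeepingPanel:
    """Reference genes assumed stably expressed, anchored to one compartment."""

    genes: tuple[str, ...] = DEFAULT_HOUSEKEEPING_GENES
    reference: str = "EC"
    pseudocount: float = 0.0

    def __post_init__(self):
        if self.reference not in COMPARTMENTS:
            raise ValueError(f"reference compartment must be one of {COMPARTMENTS}")

    @classmethod
    def from_file(cls, path, reference: str = "EC") -> "HousekeepingPanel":
        with open(path) as fh:
            genes = tuple(line.strip() for line in fh if line.strip() and not line.startswith("#"))
        return cls(genes=genes, reference=reference)


@dataclass
class NETable:
    """Normalized expression at transcript, gene, and compartment level."""

    transcript_ne: pd.DataFrame
    gene_ne: pd.DataFrame
    compartment_ne: pd.DataFrame
    samples: pd.DataFrame
    library_sizes: pd.Series
    corrected: bool = False
    correction_factors: pd.Series | None = None
    excluded_transcripts: tuple[str, ...] = field(default_factory=tuple)

    def profiles(self, genes=None) -> pd.DataFrame:
        """Gene x compartment matrix of (mean) NE, in compartment order."""
        df = self.compartment_ne
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes absent from NE table: {missing[:5]}")
            df = df.loc[list(genes)]
        return df

    def to_tsv(self, path) -> None:
        out = self.gene_ne.join(self.compartment_ne.add_prefix("mean_"))
        out["corrected"] = self.corrected
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def compute_ne(
    counts: CountMatrix,
    density: str = "per_sample",
    library_sizes: pd.Series | None = None,
) -> NETable:
    """Compute NE = count / (length_kb x depth_millions) for every transcript.

    ``density`` selects the depth normalizer: ``"per_sample"`` uses each
    sample's own mapped-read total, ``"pooled"`` applies the mean depth of
    the whole dataset to every sample (both leave compartment profiles of a
    gene unchanged up to per-sample scalars).
    """
    if density not in ("per_sample", "pooled"):
        raise ValueError("density must be 'per_sample' or 'pooled'")
    lib = counts.library_sizes() if library_sizes is None else library_sizes.reindex(counts.counts.columns)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    if density == "pooled":
        lib = pd.Series(float(lib.mean()), index=lib.index)

    mat = counts.counts
    lengths = counts.lengths
    excluded = tuple(lengths.index[lengths.isna()])
    if excluded:
        logger.warning("excluding %d transcripts with missing length", len(excluded))
        mat = mat.drop(index=list(excluded))
        lengths = lengths.drop(index=list(excluded))

    transcript_ne = mat.div(lengths / 1e3, axis=0).div(lib / 1e6, axis=1)
    gene_ne = transcript_ne.groupby(counts.gene_map.loc[transcript_ne.index]).sum()
    comp_cols = {c: counts.samples_of(c) for c in counts.compartments}
    compartment_ne = pd.DataFrame(
        {c: gene_ne[cols].mean(axis=1) for c, cols in comp_cols.items()}
    )
    return NETable(
        transcript_ne=transcript_ne,
        gene_ne=gene_ne,
        compartment_ne=compartment_ne,
        samples=counts.samples,
        library_sizes=lib,
        excluded_transcripts=excluded,
    )


def housekeeping_correct(ne: NETable, panel: HousekeepingPanel | None = None) -> NETable:
    """Divide each compartment by the panel-average relative control level.

    factor(c) = mean over panel genes g of NE(g, c) / NE(g, reference);
    corrected NE(g, c) = NE(g, c) / factor(c).  Panel genes absent from the
    table, or with zero reference expression (unless a pseudocount is set),
    are dropped with a warning.
    """
    panel = panel or HousekeepingPanel()
    if panel.reference not in ne.compartment_ne.columns:
        raise ValueError(f"reference compartment {panel.reference!r} not in NE table")
    present = [g for g in panel.genes if g in ne.compartment_ne.index]
    missing = set(panel.genes) - set(present)
    if missing:
        warnings.warn(f"panel genes absent from NE table, dropped: {sorted(missing)}")
    sub = ne.compartment_ne.loc[present] + panel.pseudocount
    ref = sub[panel.reference]
    usable = ref > 0
    if not usable.all():
        warnings.warn(
            "panel genes with zero reference-compartment NE, dropped: "
            f"{sorted(ref.index[~usable])}"
        )
        sub = sub.loc[usable]
    if sub.empty:
        raise ValueError("no usable housekeeping panel genes")
    factors = sub.div(sub[panel.reference], axis=0).mean(axis=0)

    sample_factor = ne.samples["compartment"].map(factors)
    return replace(
        ne,
        transcript_ne=ne.transcript_ne.div(sample_factor, axis=1),
        gene_ne=ne.gene_ne.div(sample_factor, axis=1),
        compartment_ne=ne.compartment_ne.div(factors, axis=1),
        corrected=True,
        correction_factors=factors,
    )
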