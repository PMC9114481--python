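"""Gene models, strand-aware promoters, and sequence/conservation features.

Genes are stored with 0-based half-open coordinates. GTF input (1-based
inclusive) is converted on ingest. The promoter of a gene is the 4-kb window
centered on its strand-aware transcription start site (TSS): the annotated
start for ``+`` genes and the annotated end for ``-`` genes, clipped at the
chromosome boundary.

Sequence features follow the classic CpG observed/expected convention:
GC content is (G+C)/(non-N bases), the observed CpG fraction counts CG
dinucleotides over overlapping windows (denominator L-1), and the expected
CpG fraction is (GC/2)^2.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROMOTER_FLANK = 2000  # bases on each side of the TSS -> 4-kb promoter

Biotype = Literal["lncRNA", "protein_coding"]


@dataclass
class GeneModel:
    """A gene with optional sequence and per-base conservation track.

    ``conservation`` is aligned to ``[start, end)``; missing bases are NaN.
    """

    gene_id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exon_count: int = 1
    sequence: str | None = None
    conservation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"gene length {self.end - self.start}"
            )

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class PromoterInterval:
    """4-kb (at most) half-open window centered on a gene's TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    tss: int


def promoter_of(
    gene: GeneModel,
    flank: int = PROMOTER_FLANK,
    chrom_length: int | None = None,
) -> PromoterInterval:
    """Return the promoter window ``[tss - flank, tss + flank)``.

    The interval is clipped to ``[0, chrom_length)``; no error is raised at
    chromosome edges.
    """
    tss = gene.tss
    start = max(0, tss - flank)
    end = tss + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return PromoterInterval(gene.gene_id, gene.chrom, start, end, tss)


def promoters_of(
    genes: Iterable[GeneModel],
    flank: int = PROMOTER_FLANK,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PromoterInterval]:
    lengths = chrom_lengths or {}
    return [promoter_of(g, flank, lengths.get(g.chrom)) for g in genes]


# ---------------------------------------------------------------------------
# Sequence features
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """GC fraction over non-N bases; NaN when every base is N."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    n_valid = len(seq) - seq.count("N")
    if n_valid == 0:
        return math.nan
    return (seq.count("G") + seq.count("C")) / n_valid


def normalized_cpg(seq: str) -> float:
    """CpG observed/expected ratio.

    Observed = #CG dinucleotides (overlapping scan) / (L - 1);
    expected = (GC content / 2)^2. NaN when the expected fraction is zero.
    """
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    seq = seq.upper()
    observed = _count_cpg(seq) / (len(seq) - 1)
    gc = gc_content(seq)
    expected = (gc / 2.0) ** 2
    if not expected or math.isnan(expected):
        return math.nan
    return observed / expected


def _count_cpg(seq: str) -> int:
    return sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")


def cpg_count(seq: str) -> int:
    """Number of CG dinucleotides (overlapping scan)."""
    return _count_cpg(seq.upper())


def mean_conservation(gene: GeneModel, promoter: PromoterInterval) -> float:
    """Mean per-base conservation within the promoter, ignoring missing bases.

    The gene's conservation track covers ``[gene.start, gene.end)``; only the
    overlap with the promoter contributes. NaN when no scored base overlaps.
    """
    if gene.conservation is None:
        raise ValueError(f"{gene.gene_id}: no conservation track")
    track = np.asarray(gene.conservation, dtype=float)
    lo = max(promoter.start, gene.start) - gene.start
    hi = min(promoter.end, gene.end) - gene.start
    if hi <= lo:
        return math.nan
    window = track[lo:hi]
    if np.all(np.isnan(window)):
        return math.nan
    return float(np.nanmean(window))


# ---------------------------------------------------------------------------
# Feature comparison across methylation categories
# ---------------------------------------------------------------------------


def compare_feature_by_category(
    values: Mapping[str, float] | pd.Series,
    categories: Mapping[str, str] | pd.Series,
    test: Literal["ks", "wilcoxon"] = "ks",
) -> pd.DataFrame:
    """Pairwise two-sample tests of a per-gene feature between categories.

    Kolmogorov-Smirnov for distribution-shaped features (GC content,
    normalized CpG); Wilcoxon rank-sum for count-like or score features
    (conservation, CpG counts, exon counts). The rank-sum test uses exact
    enumeration when both groups have n <= 20, otherwise the normal
    approximation with continuity correction.

    Returns one row per category pair with columns
    ``category_a, category_b, n_a, n_b, statistic, p``; for the rank-sum
    test ``statistic`` is the rank sum W of group a.
    """
    values = pd.Series(values, dtype=float)
    categories = pd.Series(categories)
    common = values.index.intersection(categories.index)
    values, categories = values.loc[common], categories.loc[common]
    keep = values.notna()
    values, categories = values[keep], categories[keep]

    groups = {c: values[categories == c].to_numpy() for c in sorted(categories.unique())}
    usable = {}
    for name, arr in groups.items():
        if arr.size < 2:
            warnings.warn(f"category {name!r} has < 2 members; skipped")
            continue
        usable[name] = arr
    if len(usable) < 2:
        raise ValueError("need >= 2 categories with >= 2 members each")

    rows = []
    for a, b in combinations(sorted(usable), 2):
        xa, xb = usable[a], usable[b]
        if test == "ks":
            res = stats.ks_2samp(xa, xb)
            stat, p = float(res.statistic), float(res.pvalue)
        elif test == "wilcoxon":
            method = "exact" if (len(xa) <= 20 and len(xb) <= 20) else "asymptotic"
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            # report the classical rank-sum statistic of group a
            stat = float(res.statistic + len(xa) * (len(xa) + 1) / 2)
            p = float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {"category_a": a, "category_b": b, "n_a": len(xa), "n_b": len(xb),
             "statistic": stat, "p": p}
        )
    return pd.DataFrame(rows)


def gene_feature_table(genes: Sequence[GeneModel], flank: int = PROMOTER_FLANK) -> pd.DataFrame:
    """Per-gene scalar features: GC, normalized CpG, CpG count, exons, conservation."""
    rows = []
    for g in genes:
        seq = g.sequence
        row: dict[str, object] = {
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "exon_count": g.exon_count,
            "length": g.end - g.start,
        }
        if seq:
            row["gc_content"] = gc_content(seq)
            row["normalized_cpg"] = normalized_cpg(seq) if len(seq) >= 2 else math.nan
            row["cpg_count"] = cpg_count(seq)
        if g.conservation is not None:
            row["mean_conservation"] = mean_conservation(g, promoter_of(g, flank))
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

GENE_TSV_COLUMNS = ["gene_id", "biotype", "chrom", "strand", "start", "end", "exon_count"]


def read_gene_table(path) -> list[GeneModel]:
    """Read a BED-like gene TSV (0-based half-open) into GeneModel objects."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(GENE_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return [
        GeneModel(
            gene_id=str(r.gene_id), biotype=str(r.biotype), chrom=str(r.chrom),
            strand=str(r.strand), start=int(r.start), end=int(r.end),
            exon_count=int(r.exon_count),
        )
        for r in df.itertuples()
    ]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "biotype": g.biotype, "chrom": g.chrom,
             "strand": g.strand, "start": g.start, "end": g.end,
             "exon_count": g.exon_count}
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gtf(path, biotypes: set[str] | None = None) -> list[GeneModel]:
    """Read gene/exon records from a GTF (1-based inclusive -> half-open).

    ``exon_count`` is the number of exon records per gene; genes without exon
    records get 1.
    """
    names = ["chrom", "source", "feature", "start", "end", "score", "strand",
             "frame", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=names,
                     dtype={"chrom": str})
    attr = df["attributes"].str.extract(
        r'gene_id "(?P<gene_id>[^"]+)"(?:.*?gene_(?:bio)?type "(?P<biotype>[^"]+)")?'
    )
    df = pd.concat([df, attr], axis=1)
    genes = []
    exon_counts = (
        df[df["feature"] == "exon"].groupby("gene_id").size().to_dict()
    )
    for r in df[df["feature"] == "gene"].itertuples():
        bt = r.biotype if isinstance(r.biotype, str) else "lncRNA"
        if biotypes and bt not in biotypes:
            continue
        genes.append(
            GeneModel(
                gene_id=str(r.gene_id), biotype=bt, chrom=str(r.chrom),
                strand=str(r.strand), start=int(r.start) - 1, end=int(r.end),
                exon_count=int(exon_counts.get(r.gene_id, 1)),
            )
        )
    return genes


def read_fasta_sequences(path) -> dict[str, str]:
    """Read gene sequences keyed by record id from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_conservation_track(path) -> pd.DataFrame:
    """Read a wiggle-like TSV with columns chrom, pos (0-based), score."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    need = {"chrom", "pos", "score"}
    if not need <= set(df.columns):
        raise ValueError(f"conservation track needs columns {sorted(need)}")
    return df


def attach_conservation(genes: Sequence[GeneModel], track: pd.DataFrame) -> None:
    """Attach per-base conservation arrays to genes from a (chrom,pos,score) table."""
    by_chrom = {c: g.set_index("pos")["score"] for c, g in track.groupby("chrom")}
    for gene in genes:
        scores = by_chrom.get(gene.chrom)
        if scores is None:
            continue
        arr = np.full(gene.end - gene.start, np.nan)
        within = scores.loc[(scores.index >= gene.start) & (scores.index < gene.end)]
        arr[within.index.to_numpy() - gene.start] = within.to_numpy()
        gene.conservation = arr
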