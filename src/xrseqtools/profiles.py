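"""Descriptive repair analytics over damage-filtered reads.

Implements the figure-level summaries of an XR-seq study: strand-resolved
unit-gene metaprofiles in RPKM, TS/NTS repair ratios, CEAS-style
genomic-location distributions, read-length histograms and positional
dinucleotide composition.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CODE_NAMES, gene_index_maps, location_maps
from .models import FilteredRead, GeneModel, GenomeBundle, LOCATION_CATEGORIES

logger = logging.getLogger(__name__)

ALL_DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@dataclass
class UnitGeneProfile:
    """Binned TS/NTS repair signal over a length-normalised 'unit gene'.

    Signals are per-bin RPKM (reads per kilobase per million mapped reads),
    averaged across the selected genes; bin 0 is the TSS end, the last bin
    the TES end, in the gene's 5'->3' orientation.
    """

    n_bins: int
    ts_signal: np.ndarray
    nts_signal: np.ndarray
    n_genes_used: int
    normalization_total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin": np.arange(self.n_bins),
            "ts_rpkm": self.ts_signal,
            "nts_rpkm": self.nts_signal,
        })


@dataclass
class GenomeDistribution:
    """Fraction of filtered reads per genomic-location category."""

    fractions: dict[str, float]
    n_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self.fractions), "fraction": list(self.fractions.values())}
        )


@dataclass
class CompositionProfile:
    """Read-length histogram plus positional dinucleotide frequencies for
    one length stratum (position x 16 dinucleotides; rows sum to 1)."""

    length_histogram: pd.Series
    dinucleotide_matrix: pd.DataFrame
    stratum_length: int

    @property
    def median_length(self) -> float:
        lengths = np.repeat(
            self.length_histogram.index.to_numpy(), self.length_histogram.to_numpy()
        )
        return float(np.median(lengths)) if lengths.size else float("nan")


@dataclass
class TsNtsRatio:
    """Overall and per-gene TS/NTS read-count ratio over selected genes."""

    ts_count: int
    nts_count: int
    ratio: float
    infinite: bool
    per_gene: pd.DataFrame


def select_unit_genes(
    genes: list[GeneModel], min_length: int = 5000, min_gap: int = 5000
) -> list[GeneModel]:
    """Genes longer than ``min_length`` with both neighbour gaps >= ``min_gap``
    (chromosome ends count as open space)."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    keep = []
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        for i, g in enumerate(chrom_genes):
            if g.length <= min_length:
                continue
            left_ok = i == 0 or g.start - chrom_genes[i - 1].end >= min_gap
            right_ok = (
                i == len(chrom_genes) - 1
                or chrom_genes[i + 1].start - g.end >= min_gap
            )
            if left_ok and right_ok:
                keep.append(g)
    keep.sort(key=lambda g: (g.chrom, g.start))
    return keep


def _assign_reads_to_genes(
    reads: list[FilteredRead], genes: list[GeneModel], bundle: GenomeBundle
) -> list[tuple[FilteredRead, int]]:
    """(read, gene index) pairs for reads whose midpoint falls in a gene body.

    Only reads mapped to the bundle's species are considered.
    """
    sub = GenomeBundle(bundle.species_id, bundle.chromosomes, list(genes))
    gmaps = gene_index_maps(sub)
    pairs = []
    for fr in reads:
        a = fr.read
        if a.species_id != bundle.species_id or a.chrom not in gmaps:
            continue
        gi = int(gmaps[a.chrom][a.midpoint])
        if gi >= 0:
            pairs.append((fr, gi))
    return pairs


def compute_metaprofile(
    reads: list[FilteredRead],
    genes: list[GeneModel],
    bundle: GenomeBundle,
    n_bins: int = 100,
    total_mapped: int | None = None,
) -> UnitGeneProfile:
    """Average TS and NTS repair along the unit gene.

    Each read is assigned to the gene containing its midpoint; its strand
    class is TS when the read strand differs from the gene (mRNA) strand.
    Per-gene per-bin counts are converted to RPKM with the gene's own bin
    length, then averaged over all selected genes (genes without reads
    contribute zeros). ``total_mapped`` defaults to the number of filtered
    reads passed in.
    """
    if not genes:
        raise ValueError("empty unit-gene set")
    total = total_mapped if total_mapped is not None else len(reads)
    ts = np.zeros((len(genes), n_bins))
    nts = np.zeros((len(genes), n_bins))
    for fr, gi in _assign_reads_to_genes(reads, genes, bundle):
        gene = genes[gi]
        a = fr.read
        if gene.strand == "+":
            d = a.midpoint - gene.start
        else:
            d = gene.end - 1 - a.midpoint
        b = min(n_bins * d // gene.length, n_bins - 1)
        if a.strand != gene.strand:
            ts[gi, b] += 1
        else:
            nts[gi, b] += 1
    bin_kb = np.array([g.length / n_bins / 1000.0 for g in genes])[:, None]
    scale = bin_kb * (max(total, 1) / 1e6)
    ts_rpkm = (ts / scale).mean(axis=0)
    nts_rpkm = (nts / scale).mean(axis=0)
    return UnitGeneProfile(n_bins, ts_rpkm, nts_rpkm, len(genes), total)


def ts_nts_ratio(
    reads: list[FilteredRead], genes: list[GeneModel], bundle: GenomeBundle
) -> TsNtsRatio:
    """TS/NTS read-count ratio over the selected genes, plus a per-gene table."""
    pairs = _assign_reads_to_genes(reads, genes, bundle)
    if not pairs:
        raise ValueError("no reads assigned to the selected genes")
    per = np.zeros((len(genes), 2), dtype=np.int64)  # columns: TS, NTS
    for fr, gi in pairs:
        cls = 0 if fr.read.strand != genes[gi].strand else 1
        per[gi, cls] += 1
    ts_count, nts_count = int(per[:, 0].sum()), int(per[:, 1].sum())
    infinite = nts_count == 0 and ts_count > 0
    ratio = float("inf") if infinite else ts_count / nts_count
    with np.errstate(divide="ignore", invalid="ignore"):
        gene_ratio = per[:, 0] / per[:, 1]
    table = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "ts_count": per[:, 0],
        "nts_count": per[:, 1],
        "ts_nts_ratio": gene_ratio,
    })
    return TsNtsRatio(ts_count, nts_count, ratio, infinite, table)


def classify_genomic_location(
    reads: list[FilteredRead],
    bundle: GenomeBundle,
    promoter_span: int = 1000,
    downstream_span: int = 1000,
) -> GenomeDistribution:
    """CEAS-style location distribution of read midpoints.

    Priority at overlaps: promoter > 5'UTR > 3'UTR > exon > intron >
    downstream > intergenic. If no gene carries a feature substructure only
    ``genic``/``intergenic`` are reported. Fractions are over the bundle's
    reads and sum to 1.
    """
    have_features = any(g.features for g in bundle.genes)
    lmaps = location_maps(bundle, promoter_span, downstream_span)
    counts: dict[str, int] = (
        {c: 0 for c in LOCATION_CATEGORIES} if have_features
        else {"genic": 0, "intergenic": 0}
    )
    n = 0
    for fr in reads:
        a = fr.read
        if a.species_id != bundle.species_id:
            continue
        n += 1
        code = int(lmaps[a.chrom][a.midpoint])
        if have_features:
            counts[CODE_NAMES[code]] += 1
        else:
            counts["intergenic" if code == 0 else "genic"] += 1
    if n == 0:
        raise ValueError("no reads from this species to classify")
    fractions = {c: v / n for c, v in counts.items()}
    return GenomeDistribution(fractions, n)


def composition_profile(
    reads: list[FilteredRead],
    stratum_length: int = 26,
    length_range: tuple[int, int] = (15, 40),
) -> CompositionProfile:
    """Length histogram and positional dinucleotide frequencies.

    The histogram covers ``length_range`` (extended if longer/shorter reads
    are observed). The matrix gives, for reads of ``stratum_length`` nt, the
    frequency of each dinucleotide at each 1-based start position; an empty
    stratum yields an empty matrix with a warning.
    """
    lengths = [fr.length for fr in reads]
    lo = min(length_range[0], min(lengths, default=length_range[0]))
    hi = max(length_range[1], max(lengths, default=length_range[1]))
    idx = np.arange(lo, hi + 1)
    binned = np.bincount(np.array(lengths, dtype=np.int64) - lo, minlength=idx.size) \
        if lengths else np.zeros(idx.size, dtype=np.int64)
    hist = pd.Series(binned, index=idx, name="count")
    stratum = [fr.read.sequence for fr in reads if fr.length == stratum_length]
    if not stratum:
        warnings.warn(f"no reads of length {stratum_length}; empty composition matrix")
        mat = pd.DataFrame(columns=ALL_DINUCLEOTIDES)
    else:
        counts = np.zeros((stratum_length - 1, 16), dtype=np.int64)
        col = {d: j for j, d in enumerate(ALL_DINUCLEOTIDES)}
        for seq in stratum:
            for i in range(stratum_length - 1):
                counts[i, col[seq[i:i + 2]]] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        mat = pd.DataFrame(
            freq, index=pd.Index(np.arange(1, stratum_length), name="position"),
            columns=ALL_DINUCLEOTIDES,
        )
    return CompositionProfile(hist, mat, stratum_length)


def dipyrimidine_positional_frequency(profile: CompositionProfile) -> pd.Series:
    """Summed TT+TC+CT+CC frequency per position (the damage-register
    enrichment curve)."""
    if profile.dinucleotide_matrix.empty:
        return pd.Series(dtype=float)
    return profile.dinucleotide_matrix[["TT", "TC", "CT", "CC"]].sum(axis=1)
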