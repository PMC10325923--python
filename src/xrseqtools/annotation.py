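"""Per-base annotation maps used by the simulator and the classifiers.

Genomic-location categories follow the usual CEAS-style priority
(promoter > 5'UTR > 3'UTR > exon > intron > downstream > intergenic):
each map is painted in *increasing* priority order so the highest-priority
category wins at any overlap. Promoters span ``[TSS - promoter_span, TSS)``
on the gene strand; downstream regions are the mirror image at the TES.
"""

from __future__ import annotations

import numpy as np

from .models import GeneModel, GenomeBundle

CATEGORY_CODES: dict[str, int] = {
    "intergenic": 0,
    "downstream": 1,
    "intron": 2,
    "exon": 3,
    "3'UTR": 4,
    "5'UTR": 5,
    "promoter": 6,
}
CODE_NAMES: dict[int, str] = {v: k for k, v in CATEGORY_CODES.items()}


def _promoter_interval(gene: GeneModel, span: int, chrom_len: int) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.start - span), gene.start
    return gene.end, min(chrom_len, gene.end + span)


def _downstream_interval(gene: GeneModel, span: int, chrom_len: int) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.end, min(chrom_len, gene.end + span)
    return max(0, gene.start - span), gene.start


def location_maps(
    bundle: GenomeBundle,
    promoter_span: int = 1000,
    downstream_span: int = 1000,
) -> dict[str, np.ndarray]:
    """Per-chromosome int8 arrays of location codes (see CATEGORY_CODES).

    Genes without a feature substructure contribute their whole body as exon.
    """
    maps = {
        name: np.zeros(len(seq), dtype=np.int8) for name, seq in bundle.chromosomes.items()
    }
    chrom_lens = {name: len(seq) for name, seq in bundle.chromosomes.items()}
    # low -> high priority
    for code_name in ("downstream", "intron", "exon", "3'UTR", "5'UTR", "promoter"):
        code = CATEGORY_CODES[code_name]
        for gene in bundle.genes:
            arr = maps[gene.chrom]
            if code_name == "downstream":
                a, b = _downstream_interval(gene, downstream_span, chrom_lens[gene.chrom])
                arr[a:b] = code
            elif code_name == "promoter":
                a, b = _promoter_interval(gene, promoter_span, chrom_lens[gene.chrom])
                arr[a:b] = code
            elif gene.features:
                for cat, (a, b) in gene.features:
                    if cat == code_name:
                        arr[a:b] = code
            elif code_name == "exon":  # featureless gene: whole body is exonic
                arr[gene.start:gene.end] = code
    return maps


def gene_index_maps(bundle: GenomeBundle) -> dict[str, np.ndarray]:
    """Per-chromosome int32 arrays mapping position -> gene index (-1 outside).

    Assumes non-overlapping gene bodies (the toy-genome invariant); with
    overlaps the later gene in the list wins.
    """
    maps = {
        name: np.full(len(seq), -1, dtype=np.int32)
        for name, seq in bundle.chromosomes.items()
    }
    for i, gene in enumerate(bundle.genes):
        maps[gene.chrom][gene.start:gene.end] = i
    return maps


def dipyrimidine_sites(bundle: GenomeBundle) -> list[tuple[str, str, np.ndarray]]:
    """Enumerate dipyrimidine sites on both strands of every chromosome.

    Returns ``(chrom, strand, positions)`` triples where ``positions`` are
    the reference coordinates of the left edge of each damaged dinucleotide
    (a minus-strand dipyrimidine is a purine pair on the reference).
    """
    out: list[tuple[str, str, np.ndarray]] = []
    for chrom, seq in bundle.chromosomes.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        pyr = (arr == ord("C")) | (arr == ord("T"))
        pur = ~pyr
        plus = np.flatnonzero(pyr[:-1] & pyr[1:])
        minus = np.flatnonzero(pur[:-1] & pur[1:])
        out.append((chrom, "+", plus))
        out.append((chrom, "-", minus))
    return out
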