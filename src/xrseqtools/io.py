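"""File interchange: FASTA/FASTQ libraries, BED6 intervals, TSV manifests.

Chromosome names in filtered-read BED6 output carry a ``species:`` prefix so
species attribution survives a round trip through plain interval files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignedRead, FilteredRead, GeneModel, GenomeBundle, ReadRecord
from .readproc import damage_registers

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_genome_fasta(bundle: GenomeBundle, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in bundle.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path, species_id: str,
                      genes: list[GeneModel] | None = None) -> GenomeBundle:
    chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return GenomeBundle(species_id, chroms, list(genes or []))


def write_reads(reads: list[ReadRecord], path: str | Path, fmt: str = "fasta") -> None:
    """FASTA by default; FASTQ writes a constant 'I' quality when reads
    carry none."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if fmt == "fastq":
            quals = r.qualities or "I" * len(r.sequence)
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_reads(path: str | Path, fmt: str | None = None) -> list[ReadRecord]:
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = None
        if fmt == "fastq":
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), quals))
    return out


def write_genes_bed(genes: list[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes],
        columns=BED6_COLUMNS,
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    return [
        GeneModel(str(r.name_), r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


FEATURE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand",
                   "category", "f_start", "f_end"]


def write_genes_with_features(genes: list[GeneModel], path: str | Path) -> None:
    """TSV preserving the UTR/exon/intron substructure BED6 cannot carry."""
    rows = []
    for g in genes:
        feats = g.features or (("exon", (g.start, g.end)),)
        for cat, (a, b) in feats:
            rows.append((g.gene_id, g.chrom, g.start, g.end, g.strand, cat, a, b))
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_genes_with_features(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        first = sub.iloc[0]
        feats = tuple(
            (r.category, (int(r.f_start), int(r.f_end))) for r in sub.itertuples()
        )
        genes.append(GeneModel(str(gid), first["chrom"], int(first["start"]),
                               int(first["end"]), first["strand"], feats))
    return genes


def write_filtered_bed(reads: list[FilteredRead], path: str | Path) -> None:
    """BED6 of filtered reads: name=read_id, score=registers fired,
    chrom=``species:chrom``."""
    rows = [
        (f"{fr.read.species_id}:{fr.read.chrom}", fr.read.start, fr.read.end,
         fr.read.read_id, len(fr.damage_registers), fr.read.strand)
        for fr in reads
    ]
    pd.DataFrame(rows, columns=BED6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def aligned_from_bed(path: str | Path, bundles: dict[str, GenomeBundle],
                     default_species: str | None = None) -> list[AlignedRead]:
    """Ingest externally produced alignments.

    The 6th-column strand is taken as the excised oligomer's strand of
    origin; sequences are re-fetched from the genome so the damage filter
    can be applied. Chromosomes may carry a ``species:`` prefix; otherwise
    ``default_species`` must name the bundle to use.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
    out = []
    for r in df.itertuples():
        chrom = str(r.chrom)
        if ":" in chrom:
            species, chrom = chrom.split(":", 1)
        elif default_species is not None:
            species = default_species
        else:
            raise ValueError("chrom lacks species prefix and no default_species given")
        bundle = bundles[species]
        seq = bundle.fetch(chrom, int(r.start), int(r.end), r.strand)
        out.append(AlignedRead(str(r.name), species, chrom, int(r.start),
                               int(r.end), r.strand, seq))
    return out


def filtered_from_bed(path: str | Path, bundles: dict[str, GenomeBundle],
                      default_species: str | None = None) -> list[FilteredRead]:
    """Read a filtered-read BED6 back, recomputing registers from sequence."""
    out = []
    for a in aligned_from_bed(path, bundles, default_species):
        regs = damage_registers(a.sequence)
        out.append(FilteredRead(a, regs))
    return out


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_sheet(samples: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(samples, indent=2) + "\n")


def read_sample_sheet(path: str | Path) -> list[dict]:
    return json.loads(Path(path).read_text())
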