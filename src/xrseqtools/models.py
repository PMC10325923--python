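"""Core domain types shared across the toolkit.

Coordinates are 0-based, half-open (BED convention) throughout; strands are
``"+"`` / ``"-"``. A lesion's ``pos`` is always the *reference* (leftmost)
coordinate of the damaged dinucleotide interval ``[pos, pos + 2)``; for a
minus-strand lesion the stored dinucleotide is therefore the reverse
complement of the reference slice, read 5'->3' on the damaged strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PYRIMIDINE_PAIRS = ("TT", "TC", "CT", "CC")
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: genomic-location categories in classification priority order (high -> low)
LOCATION_CATEGORIES = (
    "promoter",
    "5'UTR",
    "3'UTR",
    "exon",
    "intron",
    "downstream",
    "intergenic",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A strand-aware gene with an optional UTR/exon/intron substructure.

    ``features`` is a list of ``(category, (start, end))`` tuples with
    category one of ``5'UTR``, ``exon``, ``intron``, ``3'UTR``; when present
    they tile ``[start, end)`` without overlap.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    features: tuple[tuple[str, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.features:
            spans = sorted(iv for _, iv in self.features)
            if spans[0][0] != self.start or spans[-1][1] != self.end:
                raise ValueError(f"{self.gene_id}: features do not tile the gene body")
            for (_, a_end), (b_start, _) in zip(spans, spans[1:]):
                if a_end != b_start:
                    raise ValueError(f"{self.gene_id}: features overlap or leave gaps")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start site (reference coordinate of the 5' gene end)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def template_strand(self) -> str:
        """The transcribed strand (template for RNAPII) of this gene."""
        return "-" if self.strand == "+" else "+"


@dataclass(slots=True)
class GenomeBundle:
    """One species' simulation/alignment universe: sequences plus genes."""

    species_id: str
    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                raise ValueError(f"{self.species_id}/{name}: sequence has non-ACGT characters")
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"{g.gene_id}: extends past chromosome end")

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)`` 5'->3' on ``strand``."""
        s = self.chromosomes[chrom][start:end]
        return s if strand == "+" else revcomp(s)


@dataclass(frozen=True, slots=True)
class DamageEvent:
    """A UV photoproduct at a dipyrimidine site.

    ``pos`` is the reference coordinate of the dinucleotide's left edge;
    ``dinucleotide`` is read 5'->3' on the damaged strand.
    """

    chrom: str
    strand: str
    pos: int
    dinucleotide: str
    damage_type: str = "CPD"

    def __post_init__(self) -> None:
        if self.dinucleotide not in PYRIMIDINE_PAIRS:
            raise ValueError(f"not a dipyrimidine: {self.dinucleotide}")
        if self.damage_type not in ("CPD", "64PP"):
            raise ValueError(f"unknown damage type {self.damage_type}")


@dataclass(frozen=True, slots=True)
class GenotypeSpec:
    """Repair phenotype of a simulated cell line.

    global_efficiency
        Probability that a lesion outside transcribed-strand context is
        excised during the experiment window (XPC-dependent global repair).
    tcr_efficiency
        Probability that a lesion on the transcribed strand of an active gene
        is excised (transcription-coupled repair).
    active_gene_fraction
        Fraction of genes flagged transcribed; TCR applies only to their TS.
    spurious_transcription_rate
        Probability that a lesion *outside* TS context is nevertheless treated
        as transcription-coupled (models pervasive / spurious transcription).
    """

    name: str
    global_efficiency: float
    tcr_efficiency: float
    active_gene_fraction: float = 1.0
    spurious_transcription_rate: float = 0.0

    def __post_init__(self) -> None:
        for label in ("global_efficiency", "tcr_efficiency", "active_gene_fraction",
                      "spurious_transcription_rate"):
            v = getattr(self, label)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {v}")


@dataclass(frozen=True, slots=True)
class ExcisionEvent:
    """The dual-incision excision product released from one lesion.

    ``offset5`` is the distance (nt) from the fragment 5' end to the damage
    dinucleotide; ``offset3`` the distance from the dinucleotide 3' edge to
    the original 3' incision; ``nibble3`` the nucleotides lost from the 3'
    end after excision. ``fragment`` is the genomic substring on the damaged
    strand, 5'->3'.
    """

    damage: DamageEvent
    offset5: int
    offset3: int
    nibble3: int
    fragment: str

    def __post_init__(self) -> None:
        if len(self.fragment) != self.offset5 + 2 + self.offset3 - self.nibble3:
            raise ValueError("fragment length inconsistent with incision offsets")

    @property
    def length(self) -> int:
        return len(self.fragment)


@dataclass(frozen=True, slots=True)
class ReadRecord:
    """A raw sequencing read (sequence plus optional qualities)."""

    read_id: str
    sequence: str
    qualities: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"{self.read_id}: alphabet must be A/C/G/T/N")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """A uniquely mapped excision read.

    ``sequence`` is the excised oligomer 5'->3' on the damaged strand, i.e.
    the read sequence itself; for ``strand == "-"`` it equals the reverse
    complement of the reference slice ``[start, end)``.
    """

    read_id: str
    species_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"{self.read_id}: interval/sequence length mismatch")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class FilteredRead:
    """An aligned read that passed the damage-site filter.

    ``damage_registers`` is the nonempty subset of ``{"A", "B"}`` whose
    dinucleotide is a pyrimidine pair, with register A at 1-based read
    positions (L-7, L-6) and register B at (L-6, L-5) — i.e. the damage
    dinucleotide sits 6 or 5 nt from the 3' end respectively.
    """

    read: AlignedRead
    damage_registers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.damage_registers:
            raise ValueError("at least one damage register must have fired")
        if set(self.damage_registers) - {"A", "B"}:
            raise ValueError("registers must be a subset of {A, B}")

    @property
    def length(self) -> int:
        return self.read.length


@dataclass(slots=True)
class SpikeInMeasurement:
    """Species-resolved read counts for one qXR-seq sample."""

    sample_id: str
    genotype: str
    cells_equivalent: float
    n_target: int
    n_spike: int

    def __post_init__(self) -> None:
        if self.n_spike <= 0:
            raise ValueError(
                f"{self.sample_id}: no spike-in reads; target/spike ratio undefined"
            )
        if self.n_target < 0:
            raise ValueError(f"{self.sample_id}: negative target count")
        if self.cells_equivalent <= 0:
            raise ValueError(f"{self.sample_id}: cells_equivalent must be positive")

    @property
    def ratio(self) -> float:
        return self.n_target / self.n_spike
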