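"""Raw libraries -> damage-filtered aligned reads.

Stages mirror a standard excision-repair sequencing preprocess: 3' adapter
trimming, exact deduplication, unique exact-match alignment against the
combined two-species universe, and the damage-site filter that keeps only
24-29 nt reads carrying a pyrimidine pair where the photoproduct is
expected (5-6 nt from the 3' end).

The aligner is a toy-scale exact-substring search (seed-and-verify over a
k-mer index) suitable for the simulated genomes this package ships;
externally produced alignments can be ingested from BED6 instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import AlignedRead, FilteredRead, GenomeBundle, ReadRecord, revcomp

logger = logging.getLogger(__name__)

PYRIMIDINE_PAIRS = {"TT", "TC", "CT", "CC"}

MIN_FILTER_LENGTH = 24
MAX_FILTER_LENGTH = 29


@dataclass
class StageCounts:
    """Read counts surviving each preprocessing stage."""

    n_input: int = 0
    n_trimmed: int = 0
    n_deduplicated: int = 0
    n_with_n_dropped: int = 0
    n_aligned_unique: int = 0
    n_multi_hit: int = 0
    n_no_hit: int = 0
    n_filtered: int = 0

    def log(self) -> None:
        logger.info(
            "stages: input=%d trimmed=%d dedup=%d N-dropped=%d unique=%d "
            "multi=%d unmapped=%d filtered=%d",
            self.n_input, self.n_trimmed, self.n_deduplicated,
            self.n_with_n_dropped, self.n_aligned_unique, self.n_multi_hit,
            self.n_no_hit, self.n_filtered,
        )


def trim_adapters(
    reads: list[ReadRecord], adapter: str, min_overlap: int = 3
) -> list[ReadRecord]:
    """Remove the 3' adapter by exact match.

    If the full adapter occurs in the read, everything from its first
    occurrence on is removed; otherwise the longest read suffix equal to an
    adapter prefix of at least ``min_overlap`` nt is removed. Reads with no
    match are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be nonempty")
    out = []
    for r in reads:
        seq = r.sequence
        cut = seq.find(adapter)
        if cut < 0:
            cut = len(seq)
            max_ov = min(len(seq), len(adapter) - 1)
            for ov in range(max_ov, min_overlap - 1, -1):
                if seq.endswith(adapter[:ov]):
                    cut = len(seq) - ov
                    break
        if cut == len(seq):
            out.append(r)
        elif cut == 0:
            continue  # adapter dimer: nothing left of the insert
        else:
            q = r.qualities[:cut] if r.qualities is not None else None
            out.append(ReadRecord(r.read_id, seq[:cut], q))
    return out


def deduplicate(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Keep the first occurrence of each distinct sequence (idempotent)."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.sequence not in seen:
            seen.add(r.sequence)
            out.append(r)
    return out


class GenomeIndex:
    """Exact-substring index over both strands of a set of genomes.

    Seeds on the first ``k`` nt of the query, verifies the full sequence by
    string comparison; reverse-strand hits are found by querying the
    reverse complement against the forward index.
    """

    def __init__(self, bundles: list[GenomeBundle], k: int = 12):
        self.k = k
        self.sequences: dict[tuple[str, str], str] = {}
        codes_parts, loc_parts = [], []
        self._loci: list[tuple[str, str]] = []
        for b in bundles:
            for chrom, seq in b.chromosomes.items():
                li = len(self._loci)
                self._loci.append((b.species_id, chrom))
                self.sequences[(b.species_id, chrom)] = seq
                codes = _kmer_codes_u64(seq, k)
                codes_parts.append(codes)
                loc = np.empty((codes.size, 2), dtype=np.int64)
                loc[:, 0] = li
                loc[:, 1] = np.arange(codes.size)
                loc_parts.append(loc)
        allc = np.concatenate(codes_parts)
        allloc = np.concatenate(loc_parts)
        order = np.argsort(allc, kind="stable")
        self._sorted_codes = allc[order]
        self._sorted_loc = allloc[order]

    def find_all(self, sequence: str) -> list[tuple[str, str, int, int, str]]:
        """All exact occurrences as (species, chrom, start, end, strand)."""
        hits: list[tuple[str, str, int, int, str]] = []
        L = len(sequence)
        if L < self.k:
            return hits
        for strand, query in (("+", sequence), ("-", revcomp(sequence))):
            seed = _kmer_codes_u64(query[: self.k], self.k)
            lo = np.searchsorted(self._sorted_codes, seed[0], side="left")
            hi = np.searchsorted(self._sorted_codes, seed[0], side="right")
            for li, pos in self._sorted_loc[lo:hi].tolist():
                species, chrom = self._loci[li]
                seq = self.sequences[(species, chrom)]
                if seq[pos:pos + L] == query:
                    hits.append((species, chrom, pos, pos + L, strand))
        return hits


def _kmer_codes_u64(seq: str, k: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint64)
    lut[ord("C")], lut[ord("G")], lut[ord("T")] = 1, 2, 3
    v = lut[arr]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | v[j:j + n]
    return out


def align_reads(
    reads: list[ReadRecord],
    bundles: list[GenomeBundle] | GenomeIndex,
    counts: StageCounts | None = None,
) -> list[AlignedRead]:
    """Unique exact-match alignment against the combined universe.

    Reads containing N are dropped before search. Reads with zero or more
    than one hit across both strands of all species are discarded (species
    attribution must be unambiguous) and tallied in ``counts``.
    """
    index = bundles if isinstance(bundles, GenomeIndex) else GenomeIndex(bundles)
    out: list[AlignedRead] = []
    n_multi = n_none = n_ambig_base = 0
    for r in reads:
        if "N" in r.sequence:
            n_ambig_base += 1
            continue
        hits = index.find_all(r.sequence)
        if len(hits) == 1:
            species, chrom, start, end, strand = hits[0]
            out.append(AlignedRead(r.read_id, species, chrom, start, end, strand,
                                   r.sequence))
        elif len(hits) > 1:
            n_multi += 1
        else:
            n_none += 1
    if counts is not None:
        counts.n_with_n_dropped = n_ambig_base
        counts.n_aligned_unique = len(out)
        counts.n_multi_hit = n_multi
        counts.n_no_hit = n_none
    return out


def damage_registers(sequence: str) -> tuple[str, ...]:
    """Registers among {A, B} holding a pyrimidine pair.

    Register A is 1-based read positions (L-7, L-6) — damage dinucleotide 6
    nt from the 3' end; register B is (L-6, L-5) — 5 nt from the 3' end.
    """
    L = len(sequence)
    fired = []
    if L >= 8 and sequence[L - 8:L - 6] in PYRIMIDINE_PAIRS:
        fired.append("A")
    if L >= 7 and sequence[L - 7:L - 5] in PYRIMIDINE_PAIRS:
        fired.append("B")
    return tuple(fired)


def filter_damage_reads(
    aligned: list[AlignedRead],
    min_length: int = MIN_FILTER_LENGTH,
    max_length: int = MAX_FILTER_LENGTH,
) -> list[FilteredRead]:
    """Keep 24-29 nt reads with TT/TC/CT/CC at the expected damage site
    (either register), recording which registers fired."""
    out = []
    for a in aligned:
        if not min_length <= a.length <= max_length:
            continue
        regs = damage_registers(a.sequence)
        if regs:
            out.append(FilteredRead(a, regs))
    return out


def process_library(
    reads: list[ReadRecord],
    bundles: list[GenomeBundle] | GenomeIndex,
    adapter: str,
    *,
    min_overlap: int = 3,
    min_length: int = MIN_FILTER_LENGTH,
    max_length: int = MAX_FILTER_LENGTH,
) -> tuple[list[FilteredRead], StageCounts]:
    """Full preprocess: trim -> dedup -> align -> damage filter."""
    counts = StageCounts(n_input=len(reads))
    trimmed = trim_adapters(reads, adapter, min_overlap)
    counts.n_trimmed = len(trimmed)
    deduped = deduplicate(trimmed)
    counts.n_deduplicated = len(deduped)
    aligned = align_reads(deduped, bundles, counts)
    filtered = filter_damage_reads(aligned, min_length, max_length)
    counts.n_filtered = len(filtered)
    counts.log()
    return filtered, counts
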