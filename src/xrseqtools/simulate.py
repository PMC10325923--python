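"""Synthetic two-species XR-seq libraries with ground truth.

The generator emulates the statistical structure of an excision-repair
sequencing experiment: UV photoproducts placed at dipyrimidine sites, a
genotype-dependent mixture of global and transcription-coupled repair, the
dual-incision excision geometry (incisions 19-21 nt 5' and 5-6 nt 3' of the
lesion, with optional 3' nibbling of the released oligomer), and a
constant-quantity spike-in species mixed into every library. Every emitted
read is recorded in a truth manifest so downstream estimators can be scored
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import (
    CODE_NAMES,
    dipyrimidine_sites,
    gene_index_maps,
    location_maps,
)
from .models import (
    DamageEvent,
    ExcisionEvent,
    GeneModel,
    GenomeBundle,
    GenotypeSpec,
    revcomp,
)

logger = logging.getLogger(__name__)

#: Illumina-style 3' adapter appended to every emitted fragment
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

BASES = np.frombuffer(b"ACGT", dtype="S1")


class SizingError(ValueError):
    """Requested genes cannot be packed into the chromosome with the gaps asked for."""


@dataclass(frozen=True)
class ExcisionGeometry:
    """Dual-incision geometry of the released oligomer.

    ``offset5_probs`` / ``offset3_probs`` give the distribution of the 5'
    (19-21 nt) and 3' (5-6 nt) incision distances from the photoproduct;
    ``nibble3_probs`` the distribution of nucleotides lost from the 3' end
    after excision. Fragments shorter than ``min_length`` are resampled.

    The defaults put the mode and median of the fragment-length
    distribution at 26 nt with support [24, 29], matching the observed
    excision-product size range; the sub-26 weights are deliberate knobs
    since degradation of the released oligomer is not precisely
    characterised.
    """

    offset5_probs: dict[int, float] = field(
        default_factory=lambda: {19: 0.70, 20: 0.20, 21: 0.10}
    )
    offset3_probs: dict[int, float] = field(
        default_factory=lambda: {5: 0.80, 6: 0.20}
    )
    nibble3_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.85, 1: 0.10, 2: 0.05}
    )
    min_length: int = 24

    def __post_init__(self) -> None:
        for name in ("offset5_probs", "offset3_probs", "nibble3_probs"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} has negative probabilities")


DEFAULT_GEOMETRY = ExcisionGeometry()

#: Nominal repair phenotypes of the five simulated cell-line classes.
#: WT has strong global repair with a mild TS excess; XPC_KO loses global
#: repair but keeps TCR; CSB_KO keeps only global repair; the double
#: knockout retains residual TCR-dominated repair around 0.3% of WT and the
#: triple knockout a uniform residuum around 0.05% of WT (use
#: ``calibrate_knockout`` to pin these levels exactly on a given genome).
GENOTYPE_PRESETS: dict[str, GenotypeSpec] = {
    "WT": GenotypeSpec("WT", global_efficiency=0.5, tcr_efficiency=0.7),
    "XPC_KO": GenotypeSpec("XPC_KO", global_efficiency=0.005, tcr_efficiency=0.5),
    "CSB_KO": GenotypeSpec("CSB_KO", global_efficiency=0.4, tcr_efficiency=0.4),
    "XPC_CSB_KO": GenotypeSpec(
        "XPC_CSB_KO", global_efficiency=8.6e-4, tcr_efficiency=5.0e-3
    ),
    "XPC_CSB_CSA_KO": GenotypeSpec(
        "XPC_CSB_CSA_KO", global_efficiency=2.7e-4, tcr_efficiency=2.7e-4
    ),
}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# toy genomes


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _gene_features(
    rng: np.random.Generator, gene: GeneModel, utr5: int, utr3: int
) -> tuple[tuple[str, tuple[int, int]], ...]:
    """UTR/exon/intron tiling of a gene body, laid out 5'->3' then mapped
    to reference coordinates (mirror-imaged for minus-strand genes)."""
    L = gene.length
    if L < utr5 + utr3 + 600:
        segments = [("exon", 0, L)]
    else:
        n_introns = int(rng.integers(1, 4))
        body0, body1 = utr5, L - utr3
        n_cuts = 2 * n_introns
        inner = body1 - body0
        if inner < (n_cuts + 1) * 150:
            segments = [("5'UTR", 0, utr5), ("exon", body0, body1), ("3'UTR", body1, L)]
        else:
            cuts = np.sort(rng.choice(np.arange(1, inner), size=n_cuts, replace=False))
            bounds = [body0, *(body0 + cuts).tolist(), body1]
            segments = [("5'UTR", 0, utr5)]
            for i in range(len(bounds) - 1):
                cat = "exon" if i % 2 == 0 else "intron"
                segments.append((cat, bounds[i], bounds[i + 1]))
            segments.append(("3'UTR", body1, L))
    feats = []
    for cat, a, b in segments:
        if a == b:
            continue
        if gene.strand == "+":
            feats.append((cat, (gene.start + a, gene.start + b)))
        else:
            feats.append((cat, (gene.end - b, gene.end - a)))
    return tuple(feats)


def make_toy_genome(
    seed,
    species_id: str = "target",
    n_chroms: int = 2,
    chrom_len: int = 300_000,
    n_genes: int = 24,
    gene_len_range: tuple[int, int] = (5_500, 9_000),
    min_gap: int = 5_200,
    *,
    gc: float = 0.5,
    edge_margin: int = 2_000,
    with_features: bool = True,
    utr5: int = 300,
    utr3: int = 500,
) -> GenomeBundle:
    """Random genome with non-overlapping, gap-constrained genes.

    Genes are distributed as evenly as possible across chromosomes; within a
    chromosome the slack left after honouring ``min_gap`` is split into
    random inter-gene gaps. Deterministic for a fixed seed.
    """
    rng = _rng(seed)
    lo, hi = gene_len_range
    if lo > hi or lo <= 0:
        raise ValueError("invalid gene_len_range")
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0)
                 for i in range(n_chroms)]
    chromosomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    for ci in range(n_chroms):
        chrom = f"chr{ci + 1}"
        chromosomes[chrom] = _random_sequence(rng, chrom_len, gc)
        k = per_chrom[ci]
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        required = int(lengths.sum()) + (k - 1) * min_gap + 2 * edge_margin
        if required > chrom_len:
            raise SizingError(
                f"{species_id}/{chrom}: {k} genes of {lo}-{hi} bp with gaps >= "
                f"{min_gap} bp need {required} bp but chromosome is {chrom_len} bp"
            )
        extra = chrom_len - required
        slack = rng.multinomial(extra, np.full(k + 1, 1.0 / (k + 1)))
        cursor = edge_margin + int(slack[0])
        for gi in range(k):
            start = cursor
            end = start + int(lengths[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            gene = GeneModel(f"{species_id}_g{len(genes) + 1:03d}", chrom, start, end, strand)
            if with_features:
                gene = replace(gene, features=_gene_features(rng, gene, utr5, utr3))
            genes.append(gene)
            cursor = end + min_gap + int(slack[gi + 1])
    return GenomeBundle(species_id, chromosomes, genes)


def _kmer_codes(seq: str, k: int) -> np.ndarray:
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


def kmer_collisions(bundles: list[GenomeBundle], k: int = 24) -> int:
    """Number of k-mers (strand-collapsed) occurring more than once in the
    combined universe — zero guarantees unambiguous exact alignment of any
    read of length >= k."""
    parts = []
    for b in bundles:
        for seq in b.chromosomes.values():
            parts.append(_kmer_codes(seq, k))
            parts.append(_kmer_codes(revcomp(seq), k))
    allc = np.concatenate(parts)
    _, counts = np.unique(allc, return_counts=True)
    return int((counts > 1).sum())


def make_species_pair(
    seed,
    *,
    target_kwargs: dict | None = None,
    spike_kwargs: dict | None = None,
    max_attempts: int = 20,
) -> tuple[GenomeBundle, GenomeBundle]:
    """Target + spike genomes whose combined 24-mer universe is collision-free.

    Regenerates on collision (vanishingly rare at the default sizes) so the
    toy aligner's species attribution is exact by construction.
    """
    tkw = dict(species_id="target")
    tkw.update(target_kwargs or {})
    skw = dict(species_id="spike", n_chroms=1, chrom_len=140_000, n_genes=10,
               gene_len_range=(5_500, 8_000), min_gap=5_200)
    skw.update(spike_kwargs or {})
    ss = np.random.SeedSequence(seed)
    for attempt in range(max_attempts):
        s1, s2 = ss.spawn(2)
        target = make_toy_genome(np.random.default_rng(s1), **tkw)
        spike = make_toy_genome(np.random.default_rng(s2), **skw)
        if kmer_collisions([target, spike]) == 0:
            return target, spike
        logger.warning("24-mer collision in toy universe; regenerating (attempt %d)", attempt + 1)
        ss = ss.spawn(1)[0]
    raise RuntimeError("could not generate a collision-free two-species universe")


# ---------------------------------------------------------------------------
# damage and excision


def induce_damage(
    genome: GenomeBundle,
    per_site_rate: float,
    damage_type: str = "CPD",
    seed=None,
) -> list[DamageEvent]:
    """Bernoulli photoproduct placement at every dipyrimidine site.

    Both strands are scanned independently; the expected count is
    ``per_site_rate`` times the number of dipyrimidine sites.
    """
    if not 0.0 <= per_site_rate <= 1.0:
        raise ValueError("per_site_rate must be in [0, 1]")
    rng = _rng(seed)
    events: list[DamageEvent] = []
    if per_site_rate == 0.0:
        return events
    for chrom, strand, positions in dipyrimidine_sites(genome):
        if per_site_rate >= 1.0:
            hit = positions
        else:
            hit = positions[rng.random(positions.size) < per_site_rate]
        seq = genome.chromosomes[chrom]
        for pos in hit.tolist():
            dinuc = seq[pos:pos + 2]
            if strand == "-":
                dinuc = revcomp(dinuc)
            events.append(DamageEvent(chrom, strand, pos, dinuc, damage_type))
    return events


def _excision_probabilities(
    genome: GenomeBundle,
    damages: list[DamageEvent],
    genotype: GenotypeSpec,
    active_gene_ids: set[str],
) -> np.ndarray:
    """Marginal excision probability per lesion under the genotype.

    TS context (lesion on the template strand of an active gene) is excised
    with ``tcr_efficiency``; anything else with ``global_efficiency``, plus
    a spurious-transcription admixture toward the TCR rate.
    """
    gmaps = gene_index_maps(genome)
    genes = genome.genes
    p = np.empty(len(damages))
    g, t, s = (genotype.global_efficiency, genotype.tcr_efficiency,
               genotype.spurious_transcription_rate)
    p_other = g + s * (t - g)
    for i, d in enumerate(damages):
        gi = int(gmaps[d.chrom][d.pos])
        is_ts = (
            gi >= 0
            and genes[gi].gene_id in active_gene_ids
            and d.strand == genes[gi].template_strand
        )
        p[i] = t if is_ts else p_other
    return p


def _active_gene_ids(genome: GenomeBundle, genotype: GenotypeSpec,
                     rng: np.random.Generator) -> set[str]:
    n = len(genome.genes)
    k = int(round(genotype.active_gene_fraction * n))
    idx = rng.permutation(n)[:k]
    return {genome.genes[i].gene_id for i in idx}


def _sample_geometry(rng: np.random.Generator, geometry: ExcisionGeometry, n: int):
    def draw(probs: dict[int, float]) -> np.ndarray:
        vals = np.fromiter(probs.keys(), dtype=np.int64)
        return rng.choice(vals, size=n, p=np.fromiter(probs.values(), dtype=float))

    o5 = draw(geometry.offset5_probs)
    o3 = draw(geometry.offset3_probs)
    nb = draw(geometry.nibble3_probs)
    for _ in range(100):
        short = (o5 + 2 + o3 - nb) < geometry.min_length
        if not short.any():
            break
        k = int(short.sum())
        sub = _sample_geometry(rng, geometry, k)
        o5[short], o3[short], nb[short] = sub
    return o5, o3, nb


def sample_excision_events(
    genome: GenomeBundle,
    damages: list[DamageEvent],
    genotype: GenotypeSpec,
    seed=None,
    *,
    geometry: ExcisionGeometry = DEFAULT_GEOMETRY,
    cells_equivalent: float = 1.0,
) -> list[ExcisionEvent]:
    """Genotype-dependent excision of lesions with dual-incision geometry.

    At ``cells_equivalent == 1`` each lesion is excised at most once, with
    probability set by its repair-pathway context; other values scale the
    expected number of released fragments linearly (fractional cells thin
    the library, >1 cell-equivalents allow repeated excision of the same
    lesion site across genome copies).
    """
    rng = _rng(seed)
    if not damages:
        return []
    active = _active_gene_ids(genome, genotype, rng)
    p = _excision_probabilities(genome, damages, genotype, active)
    c = float(cells_equivalent)
    if c <= 0:
        raise ValueError("cells_equivalent must be positive")
    m, frac = int(np.floor(c)), c - int(np.floor(c))
    copies = np.zeros(len(damages), dtype=np.int64)
    if m > 0:
        copies += rng.binomial(m, p)
    if frac > 0:
        copies += rng.binomial(1, np.clip(frac * p, 0.0, 1.0))
    idx = np.repeat(np.arange(len(damages)), copies)
    if idx.size == 0:
        return []
    o5, o3, nb = _sample_geometry(rng, geometry, idx.size)
    events: list[ExcisionEvent] = []
    for j, di in enumerate(idx.tolist()):
        d = damages[di]
        seq = genome.chromosomes[d.chrom]
        if d.strand == "+":
            a = d.pos - int(o5[j])
            b = d.pos + 2 + int(o3[j]) - int(nb[j])
            if a < 0 or b > len(seq):
                continue
            frag = seq[a:b]
        else:
            a = d.pos - int(o3[j]) + int(nb[j])
            b = d.pos + 2 + int(o5[j])
            if a < 0 or b > len(seq):
                continue
            frag = revcomp(seq[a:b])
        events.append(ExcisionEvent(d, int(o5[j]), int(o3[j]), int(nb[j]), frag))
    return events


# ---------------------------------------------------------------------------
# library assembly

MANIFEST_COLUMNS = [
    "read_id", "species", "chrom", "strand", "damage_pos", "damage_type",
    "dinucleotide", "offset5", "offset3", "nibble3", "length",
    "frag_start", "frag_end", "region", "ts_label",
]


def mix_spikein(
    target_events: list[ExcisionEvent],
    spike_events: list[ExcisionEvent],
    spike_quantity: int,
    seed=None,
    *,
    target_species: str = "target",
    spike_species: str = "spike",
    adapter: str = DEFAULT_ADAPTER,
) -> tuple[list, pd.DataFrame]:
    """Interleave target excision products with a fixed quantity of spike
    products, appending the sequencing adapter; returns the read list and a
    per-read truth manifest (region / TS labels filled by the caller).

    ``spike_quantity`` must be identical for every sample in a series — it
    is the constant external standard the quantification divides by.
    """
    from .models import ReadRecord  # local import to keep module load cheap

    rng = _rng(seed)
    if spike_quantity <= 0 or not spike_events:
        raise ValueError("spike-in is empty: target/spike ratio would be undefined")
    if spike_quantity < len(spike_events):
        pick = rng.choice(len(spike_events), size=spike_quantity, replace=False)
        spike_sel = [spike_events[i] for i in np.sort(pick).tolist()]
    else:
        spike_sel = list(spike_events)
        if spike_quantity > len(spike_events):
            logger.warning(
                "spike pool (%d) smaller than requested quantity (%d); using all",
                len(spike_events), spike_quantity,
            )
    tagged = [(target_species, e) for e in target_events] + [
        (spike_species, e) for e in spike_sel
    ]
    order = rng.permutation(len(tagged))
    reads = []
    rows = []
    for out_i, i in enumerate(order.tolist()):
        species, ev = tagged[i]
        rid = f"r{out_i + 1:07d}"
        reads.append(ReadRecord(rid, ev.fragment + adapter))
        d = ev.damage
        if d.strand == "+":
            frag_start = d.pos - ev.offset5
        else:
            frag_start = d.pos - ev.offset3 + ev.nibble3
        rows.append((
            rid, species, d.chrom, d.strand, d.pos, d.damage_type, d.dinucleotide,
            ev.offset5, ev.offset3, ev.nibble3, ev.length,
            frag_start, frag_start + ev.length, "", "",
        ))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    return reads, manifest


def annotate_manifest(
    manifest: pd.DataFrame,
    bundles: dict[str, GenomeBundle],
    promoter_span: int = 1000,
    downstream_span: int = 1000,
) -> pd.DataFrame:
    """Fill the ``region`` and ``ts_label`` truth columns from the annotation.

    Region uses the same category priority as the genomic-location
    classifier, evaluated at the damage site; TS/NTS is relative to the gene
    containing the lesion (``NA`` outside gene bodies).
    """
    lmaps = {sp: location_maps(b, promoter_span, downstream_span) for sp, b in bundles.items()}
    gmaps = {sp: gene_index_maps(b) for sp, b in bundles.items()}
    regions, ts = [], []
    for sp, chrom, strand, pos in zip(
        manifest["species"], manifest["chrom"], manifest["strand"], manifest["damage_pos"]
    ):
        code = int(lmaps[sp][chrom][pos])
        regions.append(CODE_NAMES[code])
        gi = int(gmaps[sp][chrom][pos])
        if gi < 0:
            ts.append("NA")
        else:
            gene = bundles[sp].genes[gi]
            ts.append("TS" if strand == gene.template_strand else "NTS")
    out = manifest.copy()
    out["region"] = regions
    out["ts_label"] = ts
    return out


@dataclass
class SimulatedSample:
    """One synthetic qXR-seq library with its ground truth."""

    sample_id: str
    genotype: GenotypeSpec
    reads: list
    manifest: pd.DataFrame
    meta: dict


def expected_excision_rate(
    genome: GenomeBundle, genotype: GenotypeSpec, damage_rate: float
) -> float:
    """Expected excised fragments per cell-equivalent (the sample-level truth
    the spike-in estimator should recover ratios of)."""
    gmaps = gene_index_maps(genome)
    genes = genome.genes
    total = 0.0
    for chrom, strand, positions in dipyrimidine_sites(genome):
        if positions.size == 0:
            continue
        gi = gmaps[chrom][positions]
        ts = np.zeros(positions.size, dtype=bool)
        inside = gi >= 0
        if inside.any():
            tmpl = np.array([g.template_strand for g in genes]) if genes else np.empty(0)
            ts[inside] = tmpl[gi[inside]] == strand
        g, t, s = (genotype.global_efficiency, genotype.tcr_efficiency,
                   genotype.spurious_transcription_rate)
        p_other = g + s * (t - g)
        total += damage_rate * (ts.sum() * t + (~ts).sum() * p_other)
    return total


def simulate_sample(
    target: GenomeBundle,
    spike: GenomeBundle,
    genotype: GenotypeSpec,
    *,
    seed,
    damage_rate: float = 0.2,
    spike_damage_rate: float = 0.08,
    spike_global_efficiency: float = 0.5,
    spike_quantity: int = 2000,
    cells_equivalent: float = 1.0,
    damage_type: str = "CPD",
    geometry: ExcisionGeometry = DEFAULT_GEOMETRY,
    adapter: str = DEFAULT_ADAPTER,
    sample_id: str | None = None,
    promoter_span: int = 1000,
    downstream_span: int = 1000,
) -> SimulatedSample:
    """End-to-end simulation of one library: damage, excision, spike mixing,
    truth annotation. The spike species is repaired with global repair only —
    it is a fixed external standard, independent of the target genotype."""
    ss = np.random.SeedSequence(seed)
    r_dmg, r_exc, r_spk_dmg, r_spk_exc, r_mix = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    damages = induce_damage(target, damage_rate, damage_type, r_dmg)
    events = sample_excision_events(
        target, damages, genotype, r_exc, geometry=geometry,
        cells_equivalent=cells_equivalent,
    )
    spike_damages = induce_damage(spike, spike_damage_rate, damage_type, r_spk_dmg)
    spike_geno = GenotypeSpec("spike_standard", spike_global_efficiency,
                              spike_global_efficiency)
    spike_events = sample_excision_events(
        spike, spike_damages, spike_geno, r_spk_exc, geometry=geometry
    )
    reads, manifest = mix_spikein(
        events, spike_events, spike_quantity, r_mix,
        target_species=target.species_id, spike_species=spike.species_id,
        adapter=adapter,
    )
    manifest = annotate_manifest(
        manifest, {target.species_id: target, spike.species_id: spike},
        promoter_span, downstream_span,
    )
    sid = sample_id or f"{genotype.name}_s{seed}"
    meta = {
        "sample_id": sid,
        "genotype": genotype.name,
        "cells_equivalent": cells_equivalent,
        "spike_quantity": spike_quantity,
        "seed": int(seed),
        "damage_rate": damage_rate,
        "n_lesions": len(damages),
        "n_target_reads": int((manifest["species"] == target.species_id).sum()),
        "n_spike_reads": int((manifest["species"] == spike.species_id).sum()),
        "excision_rate_per_cell": expected_excision_rate(target, genotype, damage_rate),
    }
    return SimulatedSample(sid, genotype, reads, manifest, meta)


# ---------------------------------------------------------------------------
# calibration


def calibrate_knockout(
    genome: GenomeBundle,
    wildtype: GenotypeSpec,
    relative_level: float,
    *,
    name: str,
    intergenic_share: float | None = None,
    tcr_to_global: float | None = None,
    promoter_span: int = 1000,
    downstream_span: int = 1000,
) -> GenotypeSpec:
    """Knockout efficiencies whose expected per-cell excision rate is
    ``relative_level`` times the wild type's on this genome.

    Exactly one of ``intergenic_share`` (expected fraction of excision
    events the location classifier calls intergenic) or ``tcr_to_global``
    (TCR/global efficiency ratio) pins the second degree of freedom.
    """
    if (intergenic_share is None) == (tcr_to_global is None):
        raise ValueError("give exactly one of intergenic_share or tcr_to_global")
    lmap = location_maps(genome, promoter_span, downstream_span)
    gmap = gene_index_maps(genome)
    tmpl = np.array([g.template_strand for g in genome.genes])
    n_total = n_ts = n_int = 0
    for chrom, strand, positions in dipyrimidine_sites(genome):
        if positions.size == 0:
            continue
        n_total += positions.size
        gi = gmap[chrom][positions]
        inside = gi >= 0
        n_ts += int((tmpl[gi[inside]] == strand).sum()) if inside.any() else 0
        n_int += int((lmap[chrom][positions] == 0).sum())
    p_wt = (wildtype.tcr_efficiency * n_ts
            + wildtype.global_efficiency * (n_total - n_ts)) / n_total
    e = relative_level * p_wt * n_total  # expected excisions per cell (rate 1)
    if intergenic_share is not None:
        tau = intergenic_share
        g = tau * e / n_int
        t = (e - g * (n_total - n_ts)) / n_ts
    else:
        rho = tcr_to_global
        g = e / (rho * n_ts + (n_total - n_ts))
        t = rho * g
    if not (0.0 <= g <= 1.0 and 0.0 <= t <= 1.0):
        raise ValueError(
            f"calibration infeasible: global={g:.3g}, tcr={t:.3g} outside [0, 1]"
        )
    return GenotypeSpec(name, global_efficiency=float(g), tcr_efficiency=float(t))
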