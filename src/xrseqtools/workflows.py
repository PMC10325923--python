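"""End-to-end experiment recipes on synthetic data.

These functions wire the generator, the read processor and the estimators
into the standard in-silico experiments: a wild-type library for geometry
and composition checks, paired knockout/wild-type libraries for spike-in
quantification, a genomic-location recovery run, and a serial-dilution
series. Problem sizes default to desk scale (a few hundred kilobases, a
few times 10^4 reads) so each recipe runs in seconds to a couple of
minutes on one CPU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import FilteredRead, GenomeBundle, GenotypeSpec
from .profiles import (
    CompositionProfile,
    classify_genomic_location,
    composition_profile,
)
from .quant import RelativeRepair, measurement_from_reads, relative_repair
from .readproc import GenomeIndex, StageCounts, process_library
from .simulate import (
    DEFAULT_ADAPTER,
    DEFAULT_GEOMETRY,
    GENOTYPE_PRESETS,
    ExcisionGeometry,
    SimulatedSample,
    calibrate_knockout,
    make_species_pair,
    simulate_sample,
)

logger = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass
class ProcessedSample:
    """A simulated sample run through the full preprocess."""

    sample: SimulatedSample
    filtered: list[FilteredRead]
    counts: StageCounts
    target: GenomeBundle
    spike: GenomeBundle


def build_universe(seed: int, **kwargs) -> tuple[GenomeBundle, GenomeBundle, GenomeIndex]:
    """Two-species toy universe plus its alignment index."""
    target, spike = make_species_pair(seed, **kwargs)
    return target, spike, GenomeIndex([target, spike])


def simulate_and_process(
    target: GenomeBundle,
    spike: GenomeBundle,
    index: GenomeIndex,
    genotype: GenotypeSpec,
    *,
    seed: int,
    damage_rate: float = 0.2,
    spike_quantity: int = 2000,
    cells_equivalent: float = 1.0,
    geometry: ExcisionGeometry = DEFAULT_GEOMETRY,
    adapter: str = DEFAULT_ADAPTER,
) -> ProcessedSample:
    sample = simulate_sample(
        target, spike, genotype, seed=seed, damage_rate=damage_rate,
        spike_quantity=spike_quantity, cells_equivalent=cells_equivalent,
        geometry=geometry, adapter=adapter,
    )
    filtered, counts = process_library(sample.reads, index, adapter)
    return ProcessedSample(sample, filtered, counts, target, spike)


# ---------------------------------------------------------------------------
# geometry / composition experiment


@dataclass
class GeometryResult:
    processed: ProcessedSample
    composition: CompositionProfile
    median_length: float
    length_support: tuple[int, int]
    n_filtered: int


def run_wt_geometry(
    seed: int,
    *,
    damage_rate: float = 0.1,
    genome_kwargs: dict | None = None,
) -> GeometryResult:
    """A wild-type library big enough (>=10^4 filtered reads at defaults)
    to read off the excision-length distribution and damage registers."""
    s_genome, s_lib = _child_seeds(seed, 2)
    target, spike, index = build_universe(s_genome, target_kwargs=genome_kwargs)
    proc = simulate_and_process(
        target, spike, index, GENOTYPE_PRESETS["WT"], seed=s_lib,
        damage_rate=damage_rate,
    )
    comp = composition_profile(proc.filtered)
    lengths = [fr.length for fr in proc.filtered]
    return GeometryResult(
        proc, comp, comp.median_length,
        (min(lengths), max(lengths)), len(proc.filtered),
    )


# ---------------------------------------------------------------------------
# qXR-seq quantification experiment


@dataclass
class QuantRecovery:
    """Planted vs recovered relative repair across replicate simulations."""

    planted_percent: float
    rr_per_seed: list[float]
    mean_rr: float
    ci_low: float
    ci_high: float
    per_seed_results: list[RelativeRepair] = field(repr=False, default_factory=list)


def run_qxr_recovery(
    seed: int,
    relative_levels: dict[str, float],
    *,
    n_seeds: int = 20,
    damage_rate: float = 0.16,
    spike_quantity: int = 2000,
    intergenic_shares: dict[str, float] | None = None,
    n_boot: int = 500,
) -> dict[str, QuantRecovery]:
    """Recover planted knockout-to-wild-type repair levels with the
    spike-in estimator.

    ``relative_levels`` maps genotype name -> planted per-cell excision rate
    relative to WT (e.g. ``{"XPC_CSB_KO": 0.003}``); all knockouts share
    each seed's wild-type reference library. The summary CI on the mean is
    a seed-level percentile bootstrap.
    """
    s_genome, *lib_seeds = _child_seeds(seed, 1 + n_seeds)
    target, spike, index = build_universe(s_genome)
    wt = GENOTYPE_PRESETS["WT"]
    shares = intergenic_shares or {}
    genotypes = {}
    for name, level in relative_levels.items():
        if name in shares:
            genotypes[name] = calibrate_knockout(
                target, wt, level, name=name, intergenic_share=shares[name]
            )
        else:
            genotypes[name] = calibrate_knockout(
                target, wt, level, name=name, tcr_to_global=1.0
            )
    rrs: dict[str, list[RelativeRepair]] = {name: [] for name in relative_levels}
    for i, lib_seed in enumerate(lib_seeds):
        seeds = _child_seeds(lib_seed, 1 + len(genotypes))
        ref_proc = simulate_and_process(
            target, spike, index, wt, seed=seeds[0], damage_rate=damage_rate,
            spike_quantity=spike_quantity,
        )
        ref_m = measurement_from_reads(
            ref_proc.filtered, f"WT_{i}", "WT", target.species_id, spike.species_id
        )
        for j, (name, geno) in enumerate(genotypes.items()):
            ko_proc = simulate_and_process(
                target, spike, index, geno, seed=seeds[1 + j],
                damage_rate=damage_rate, spike_quantity=spike_quantity,
            )
            ko_m = measurement_from_reads(
                ko_proc.filtered, f"{name}_{i}", name,
                target.species_id, spike.species_id,
            )
            rrs[name].append(
                relative_repair(ko_m, ref_m, n_boot=n_boot, seed=seeds[1 + j])
            )
    out = {}
    rng = np.random.default_rng(_child_seeds(seed + 7, 1)[0])
    for name, results in rrs.items():
        vals = np.array([r.rr_percent for r in results])
        boot_means = np.array([
            vals[rng.integers(0, vals.size, vals.size)].mean() for _ in range(2000)
        ])
        lo, hi = np.quantile(boot_means, [0.025, 0.975])
        out[name] = QuantRecovery(
            100.0 * relative_levels[name], vals.tolist(), float(vals.mean()),
            float(lo), float(hi), results,
        )
    return out


# ---------------------------------------------------------------------------
# genomic-location recovery


@dataclass
class LocationRecovery:
    planted_intergenic: float
    observed_intergenic: float
    manifest_intergenic: float
    n_reads: int
    fractions: dict[str, float]


def run_intergenic_recovery(
    seed: int,
    *,
    intergenic_share: float = 0.27,
    relative_level: float = 0.374,
    damage_rate: float = 0.2,
) -> LocationRecovery:
    """Plant a knockout-profile intergenic repair share and recover it with
    the location classifier.

    ``relative_level`` scales the double-knockout-profile genotype up from
    its native level so the library reaches >=10^4 filtered reads at desk
    scale; the intergenic share — the quantity under test — is unchanged by
    that scaling.
    """
    s_genome, s_lib = _child_seeds(seed, 2)
    target, spike, index = build_universe(s_genome)
    geno = calibrate_knockout(
        target, GENOTYPE_PRESETS["WT"], relative_level,
        name="XPC_CSB_KO_scaled", intergenic_share=intergenic_share,
    )
    proc = simulate_and_process(
        target, spike, index, geno, seed=s_lib, damage_rate=damage_rate
    )
    dist = classify_genomic_location(proc.filtered, target)
    man = proc.sample.manifest
    man_target = man[man["species"] == target.species_id]
    man_frac = float((man_target["region"] == "intergenic").mean())
    return LocationRecovery(
        intergenic_share, dist.fractions["intergenic"], man_frac,
        dist.n_reads, dist.fractions,
    )


# ---------------------------------------------------------------------------
# serial dilution


def run_dilution_series(
    seed: int,
    cells: tuple[float, ...] = (1.0, 0.5, 0.25, 0.125, 0.0625),
    *,
    damage_rate: float = 0.1,
    spike_quantity: int = 2000,
):
    """Simulated qXR-seq dilution series of the wild type; returns the
    measurements and the through-origin linearity fit."""
    from .quant import dilution_linearity

    s_genome, *lib_seeds = _child_seeds(seed, 1 + len(cells))
    target, spike, index = build_universe(s_genome)
    measurements = []
    for c, s in zip(cells, lib_seeds):
        proc = simulate_and_process(
            target, spike, index, GENOTYPE_PRESETS["WT"], seed=s,
            damage_rate=damage_rate, spike_quantity=spike_quantity,
            cells_equivalent=c,
        )
        measurements.append(
            measurement_from_reads(
                proc.filtered, f"WT_c{c}", "WT",
                target.species_id, spike.species_id, cells_equivalent=c,
            )
        )
    return measurements, dilution_linearity(measurements)
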