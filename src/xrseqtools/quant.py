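"""Spike-in-normalised quantification (qXR-seq).

Every sample receives the same quantity of spike-in material, so the ratio
of target-species to spike-species filtered reads is proportional to the
absolute amount of excised oligomer per cell. Relative repair between two
samples is the ratio of those ratios, corrected for cell input:

    RR% = 100 * (ratio_sample / ratio_reference) * (cells_ref / cells_sample)

Uncertainty comes from a binomial bootstrap over read species labels — the
only sampling noise the counting model itself introduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import FilteredRead, SpikeInMeasurement


@dataclass
class LinearityFit:
    """Through-origin least-squares fit of ratio on cell input."""

    slope: float
    r_squared: float
    residuals: np.ndarray
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared outside [0, 1]")


@dataclass
class RelativeRepair:
    """RR% point estimate with a percentile bootstrap confidence interval."""

    rr_percent: float
    ci_low: float
    ci_high: float
    n_boot: int
    ci_level: float


def species_counts(
    reads: list[FilteredRead], target_species: str, spike_species: str
) -> tuple[int, int]:
    """Exact filtered-read counts by species; spike must be nonzero."""
    n_target = sum(1 for fr in reads if fr.read.species_id == target_species)
    n_spike = sum(1 for fr in reads if fr.read.species_id == spike_species)
    if n_spike == 0:
        raise ValueError("no spike-species reads: measurement invalid")
    return n_target, n_spike


def measurement_from_reads(
    reads: list[FilteredRead],
    sample_id: str,
    genotype: str,
    target_species: str,
    spike_species: str,
    cells_equivalent: float = 1.0,
) -> SpikeInMeasurement:
    n_t, n_s = species_counts(reads, target_species, spike_species)
    return SpikeInMeasurement(sample_id, genotype, cells_equivalent, n_t, n_s)


def dilution_linearity(
    measurements: list[SpikeInMeasurement], through_origin: bool = True
) -> LinearityFit:
    """Fit target/spike ratio against cell input over a dilution series.

    Through-origin by default (zero cells implies zero excision products);
    R^2 is computed about the model's own mean structure (uncentred for the
    through-origin fit), so noiseless proportional data gives exactly 1.
    """
    if len(measurements) < 3:
        raise ValueError("need at least 3 dilution points")
    x = np.array([m.cells_equivalent for m in measurements], dtype=float)
    y = np.array([m.ratio for m in measurements], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("dilution points must span distinct cell inputs")
    if through_origin:
        slope = float(x @ y / (x @ x))
        fitted = slope * x
        ss_tot = float(y @ y)
        intercept = 0.0
    else:
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_tot = float(((y - y.mean()) ** 2).sum())
    resid = y - fitted
    ss_res = float(resid @ resid)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearityFit(float(slope), float(np.clip(r2, 0.0, 1.0)), resid,
                        float(intercept))


def _bootstrap_ratios(
    m: SpikeInMeasurement, rng: np.random.Generator, n_boot: int
) -> np.ndarray:
    """Resample the species label of each of the sample's reads."""
    n = m.n_target + m.n_spike
    bt = rng.binomial(n, m.n_target / n, size=n_boot)
    bs = n - bt
    bs = np.maximum(bs, 1)  # guard: a zero-spike resample has no defined ratio
    return bt / bs


def relative_repair(
    sample: SpikeInMeasurement,
    reference: SpikeInMeasurement,
    n_boot: int = 1000,
    seed=None,
    ci_level: float = 0.95,
) -> RelativeRepair:
    """Repair of ``sample`` as a percentage of ``reference``.

    Assumes the same spike quantity went into both libraries; unequal cell
    inputs are corrected through ``cells_equivalent``.
    """
    if reference.n_target == 0:
        raise ValueError("reference ratio is zero; relative repair undefined")
    rng = np.random.default_rng(seed)
    cells = reference.cells_equivalent / sample.cells_equivalent
    rr = 100.0 * (sample.ratio / reference.ratio) * cells
    bs = _bootstrap_ratios(sample, rng, n_boot)
    br = _bootstrap_ratios(reference, rng, n_boot)
    br = np.where(br == 0, np.nan, br)
    boot = 100.0 * (bs / br) * cells
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.nanquantile(boot, [alpha, 1.0 - alpha])
    return RelativeRepair(float(rr), float(lo), float(hi), n_boot, ci_level)


def detection_limit(
    null_measurements: list[SpikeInMeasurement],
    reference: SpikeInMeasurement,
    n_boot: int = 1000,
    seed=None,
    ci_level: float = 0.95,
    rel_tol: float = 0.02,
) -> float:
    """Smallest RR% whose bootstrap CI excludes the repair-null background.

    The background is the largest RR% observed among replicate measurements
    of a repair-null genotype (spurious species assignments / nonspecific
    capture). A hypothetical sample at candidate RR% is given the
    reference's spike depth and cell input; bisection finds the point where
    its lower CI bound first clears the background.
    """
    if len(null_measurements) < 2:
        raise ValueError("need at least 2 repair-null replicates")
    cells = 1.0  # candidate constructed at the reference's cell input
    bg = max(
        100.0 * (m.ratio / reference.ratio)
        * (reference.cells_equivalent / m.cells_equivalent)
        for m in null_measurements
    )
    if bg == 0.0:
        return 0.0

    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2**31)

    def lower_bound(rr: float) -> float:
        n_t = max(1, round(rr / 100.0 * reference.ratio * reference.n_spike))
        m = SpikeInMeasurement("candidate", "candidate",
                               reference.cells_equivalent, n_t, reference.n_spike)
        res = relative_repair(m, reference, n_boot=n_boot, seed=child,
                              ci_level=ci_level)
        return res.ci_low

    lo, hi = bg, bg * 2.0
    for _ in range(40):
        if lower_bound(hi) > bg:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the detection limit")
    while (hi - lo) / hi > rel_tol:
        mid = 0.5 * (lo + hi)
        if lower_bound(mid) > bg:
            hi = mid
        else:
            lo = mid
    return float(hi) * cells
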