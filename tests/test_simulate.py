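"""Generator correctness: genome packing, damage placement, excision
geometry, genotype phenotypes and spike-in mixing."""

from __future__ import annotations

import numpy as np
import pytest

from xrseqtools import io as xio
from xrseqtools.models import PYRIMIDINE_PAIRS, GenotypeSpec, revcomp
from xrseqtools.simulate import (
    GENOTYPE_PRESETS,
    SizingError,
    calibrate_knockout,
    expected_excision_rate,
    induce_damage,
    kmer_collisions,
    make_toy_genome,
    mix_spikein,
    sample_excision_events,
    simulate_sample,
)

ALL_EXCISED = GenotypeSpec("all", 1.0, 1.0)


def brute_force_dipyrimidines(bundle):
    """Independent scan for dipyrimidine sites on both strands."""
    sites = set()
    for chrom, seq in bundle.chromosomes.items():
        for i in range(len(seq) - 1):
            pair = seq[i:i + 2]
            if pair in PYRIMIDINE_PAIRS:
                sites.add((chrom, "+", i, pair))
            rc = revcomp(pair)
            if rc in PYRIMIDINE_PAIRS:
                sites.add((chrom, "-", i, rc))
    return sites


class TestToyGenome:
    def test_packing_constraints(self):
        g = make_toy_genome(1, n_chroms=1, chrom_len=200_000, n_genes=10,
                            gene_len_range=(6_000, 8_000), min_gap=6_000)
        assert len(g.genes) == 10
        genes = sorted(g.genes, key=lambda x: x.start)
        for a, b in zip(genes, genes[1:]):
            assert b.start - a.end >= 6_000
        for gene in genes:
            assert 6_000 <= gene.length <= 8_000
            assert 0 <= gene.start < gene.end <= 200_000
            spans = sorted(iv for _, iv in gene.features)
            assert spans[0][0] == gene.start and spans[-1][1] == gene.end

    def test_seed_determinism_bytes(self, tmp_path):
        pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
        for p in (pa, pb):
            g = make_toy_genome(7, n_chroms=1, chrom_len=50_000, n_genes=3)
            xio.write_genome_fasta(g, p)
            xio.write_genes_bed(g.genes, p.with_suffix(".bed"))
        assert pa.read_bytes() == pb.read_bytes()
        assert pa.with_suffix(".bed").read_bytes() == pb.with_suffix(".bed").read_bytes()

    def test_different_seeds_differ(self):
        g1 = make_toy_genome(1, n_chroms=1, chrom_len=50_000, n_genes=3)
        g2 = make_toy_genome(2, n_chroms=1, chrom_len=50_000, n_genes=3)
        assert [(g.start, g.end) for g in g1.genes] != [(g.start, g.end) for g in g2.genes]

    def test_infeasible_packing_raises(self):
        with pytest.raises(SizingError):
            make_toy_genome(1, n_chroms=1, chrom_len=30_000, n_genes=5,
                            gene_len_range=(6_000, 8_000), min_gap=6_000)

    def test_two_species_kmer_uniqueness(self, small_pair):
        assert kmer_collisions(list(small_pair)) == 0


class TestInduceDamage:
    def test_rate_zero_empty(self, small_pair):
        assert induce_damage(small_pair[0], 0.0, seed=1) == []

    def test_rate_one_equals_brute_force(self, small_pair):
        target, _ = small_pair
        events = induce_damage(target, 1.0, seed=1)
        got = {(e.chrom, e.strand, e.pos, e.dinucleotide) for e in events}
        assert got == brute_force_dipyrimidines(target)

    def test_events_sit_on_dipyrimidines(self, small_pair):
        target, _ = small_pair
        for e in induce_damage(target, 0.02, seed=3):
            ref = target.chromosomes[e.chrom][e.pos:e.pos + 2]
            assert (ref if e.strand == "+" else revcomp(ref)) == e.dinucleotide
            assert e.dinucleotide in PYRIMIDINE_PAIRS

    def test_binomial_moments(self):
        genome = make_toy_genome(3, n_chroms=1, chrom_len=200_000, n_genes=2)
        n_sites = sum(
            1 for _ in brute_force_dipyrimidines(genome)
        )
        assert n_sites > 9e4
        rate = 0.01
        counts = [len(induce_damage(genome, rate, seed=s)) for s in range(20)]
        expected = n_sites * rate
        sd_mean = np.sqrt(expected * (1 - rate) / 20)
        assert abs(np.mean(counts) - expected) < 3 * sd_mean


class TestExcision:
    def test_zero_efficiencies_empty(self, small_pair):
        target, _ = small_pair
        damages = induce_damage(target, 0.1, seed=1)
        geno = GenotypeSpec("null", 0.0, 0.0)
        assert sample_excision_events(target, damages, geno, seed=1) == []

    def test_tcr_only_restricted_to_ts_of_genes(self, small_pair):
        target, _ = small_pair
        damages = induce_damage(target, 0.2, seed=1)
        geno = GenotypeSpec("tcr_only", 0.0, 1.0)
        events = sample_excision_events(target, damages, geno, seed=1)
        assert events
        by_chrom = {}
        for g in target.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for ev in events:
            d = ev.damage
            gene = next(g for g in by_chrom[d.chrom] if g.start <= d.pos < g.end)
            assert d.strand == gene.template_strand

    def test_geometry_support_and_median(self):
        genome = make_toy_genome(5, n_chroms=1, chrom_len=150_000, n_genes=8)
        damages = induce_damage(genome, 0.2, seed=2)
        events = sample_excision_events(genome, damages, ALL_EXCISED, seed=2)
        lengths = np.array([e.length for e in events])
        assert lengths.size >= 10_000
        assert lengths.min() == 24 and lengths.max() == 29
        assert np.median(lengths) == 26

    def test_fragment_matches_genome(self, small_pair):
        target, _ = small_pair
        damages = induce_damage(target, 0.05, seed=4)
        for ev in sample_excision_events(target, damages, ALL_EXCISED, seed=4):
            d = ev.damage
            if d.strand == "+":
                a = d.pos - ev.offset5
                frag = target.chromosomes[d.chrom][a:a + ev.length]
            else:
                a = d.pos - ev.offset3 + ev.nibble3
                frag = revcomp(target.chromosomes[d.chrom][a:a + ev.length])
            assert frag == ev.fragment
            # the lesion dinucleotide sits offset5 nt from the fragment 5' end
            assert ev.fragment[ev.offset5:ev.offset5 + 2] == d.dinucleotide


@pytest.fixture(scope="module")
def manifests(small_pair):
    target, spike = small_pair
    out = {}
    for name, geno in GENOTYPE_PRESETS.items():
        s = simulate_sample(target, spike, geno, seed=99, damage_rate=0.9,
                            spike_quantity=200)
        out[name] = s.manifest[s.manifest["species"] == "target"]
    return out


class TestGenotypePresets:
    @staticmethod
    def ts_nts(man):
        ts = int((man["ts_label"] == "TS").sum())
        nts = int((man["ts_label"] == "NTS").sum())
        return ts, nts

    def test_wt_asymmetry_small(self, manifests):
        ts, nts = self.ts_nts(manifests["WT"])
        assert 1.0 < ts / nts < 2.0

    def test_xpc_knockouts_show_strong_ts_excess(self, manifests):
        for name in ("XPC_KO", "XPC_CSB_KO"):
            ts, nts = self.ts_nts(manifests[name])
            assert ts / max(nts, 1) > 2.0, name

    def test_csb_knockout_no_ts_excess(self, manifests):
        ts, nts = self.ts_nts(manifests["CSB_KO"])
        assert 0.8 < ts / nts < 1.25

    def test_triple_knockout_lowest_and_symmetric(self, manifests):
        totals = {n: len(m) for n, m in manifests.items()}
        assert totals["XPC_CSB_CSA_KO"] == min(totals.values())
        # counts are tiny at this repair level; assert only the absence of
        # the strong TS excess the XPC knockouts show
        ts, nts = self.ts_nts(manifests["XPC_CSB_CSA_KO"])
        assert (ts + 1) / (nts + 1) < 10.0

    def test_efficiency_span_three_orders(self, small_pair):
        target, _ = small_pair
        rates = {
            n: expected_excision_rate(target, g, 1.0)
            for n, g in GENOTYPE_PRESETS.items()
        }
        assert rates["WT"] / rates["XPC_CSB_CSA_KO"] > 1_000


@pytest.fixture(scope="module")
def pools(small_pair):
    target, spike = small_pair
    t_events = sample_excision_events(
        target, induce_damage(target, 0.05, seed=1), ALL_EXCISED, seed=1
    )
    s_events = sample_excision_events(
        spike, induce_damage(spike, 0.15, seed=2), ALL_EXCISED, seed=2
    )
    return t_events, s_events


class TestMixSpikein:
    def test_counts_and_manifest(self, pools):
        t, s = pools
        reads, manifest = mix_spikein(t[:1000], s, 1000, seed=1)
        assert len(reads) == 2000, (len(t), len(s))
        assert (manifest["species"] == "target").sum() == 1000
        assert (manifest["species"] == "spike").sum() == 1000

    def test_doubling_target_doubles_ratio(self, pools):
        t, s = pools
        _, m1 = mix_spikein(t[:500], s, 800, seed=1)
        _, m2 = mix_spikein(t[:1000], s, 800, seed=1)
        r1 = (m1["species"] == "target").sum() / (m1["species"] == "spike").sum()
        r2 = (m2["species"] == "target").sum() / (m2["species"] == "spike").sum()
        assert r2 == pytest.approx(2 * r1)

    def test_zero_spike_is_error(self, pools):
        t, _ = pools
        with pytest.raises(ValueError):
            mix_spikein(t, [], 100, seed=1)

    def test_empty_target_valid(self, pools):
        _, s = pools
        reads, manifest = mix_spikein([], s, 500, seed=1)
        assert len(reads) == 500
        assert (manifest["species"] == "target").sum() == 0


class TestSimulateSample:
    def test_manifest_damage_invariant(self, small_pair):
        """Every emitted read has the recorded dipyrimidine at its damage
        position and its fragment equals the genomic substring."""
        target, spike = small_pair
        bundles = {"target": target, "spike": spike}
        s = simulate_sample(target, spike, GENOTYPE_PRESETS["WT"], seed=21,
                            damage_rate=0.05, spike_quantity=300)
        seqs = {r.read_id: r.sequence for r in s.reads}
        for row in s.manifest.itertuples():
            b = bundles[row.species]
            dinuc = b.fetch(row.chrom, row.damage_pos, row.damage_pos + 2, row.strand)
            assert dinuc == row.dinucleotide and dinuc in PYRIMIDINE_PAIRS
            frag = b.fetch(row.chrom, row.frag_start, row.frag_end, row.strand)
            assert seqs[row.read_id].startswith(frag)

    def test_seed_fixes_every_byte(self, small_pair, tmp_path):
        target, spike = small_pair
        files = []
        for tag in ("x", "y"):
            s = simulate_sample(target, spike, GENOTYPE_PRESETS["WT"], seed=8,
                                damage_rate=0.02, spike_quantity=200)
            fa = tmp_path / f"{tag}.fasta"
            xio.write_reads(s.reads, fa)
            xio.write_manifest(s.manifest, tmp_path / f"{tag}.tsv")
            files.append(fa)
        assert files[0].read_bytes() == files[1].read_bytes()
        assert (tmp_path / "x.tsv").read_bytes() == (tmp_path / "y.tsv").read_bytes()


class TestCalibration:
    def test_relative_level_is_planted_exactly(self, small_pair):
        target, _ = small_pair
        wt = GENOTYPE_PRESETS["WT"]
        ko = calibrate_knockout(target, wt, 0.003, name="dko", intergenic_share=0.27)
        r = expected_excision_rate(target, ko, 1.0) / expected_excision_rate(target, wt, 1.0)
        assert r == pytest.approx(0.003, rel=1e-9)

    def test_infeasible_calibration_raises(self, small_pair):
        target, _ = small_pair
        wt = GENOTYPE_PRESETS["WT"]
        with pytest.raises(ValueError):
            calibrate_knockout(target, wt, 5.0, name="bad", tcr_to_global=1.0)
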