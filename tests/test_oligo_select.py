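import numpy as np
import pytest

from oligobar import (
    Genome,
    GenomicInterval,
    SimulationSpec,
    Specificity,
    SpecificityPolicy,
    density,
    screen_specificity,
    simulate_genome,
    thin_to_target,
    tile_candidates,
)
from oligobar.oligo_select import policy_for, single_copy_oligos

from oracles import brute_best_max_gap, oracle_specificity_labels, revcomp


def _single_copy_genome(seq: str, name: str = "chr1.1") -> Genome:
    return Genome(copies={name: seq}, homolog_groups={name.rsplit(".", 1)[0]: [name]})


class TestTiling:
    @pytest.mark.parametrize(
        "region_len,l,step,expected",
        [
            (100, 45, 5, 12),  # offsets 0,5,...,55
            (45, 45, 5, 1),
            (44, 45, 5, 0),  # region shorter than the oligo: empty, not an error
            (104, 45, 5, 12),
            (105, 45, 5, 13),
        ],
    )
    def test_window_count(self, region_len, l, step, expected):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        g = _single_copy_genome(seq)
        cands = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 0, region_len), l, step)
        assert len(cands) == expected
        assert all(c.locus.length == l for c in cands)

    def test_window_with_n_flagged_not_dropped(self):
        seq = "ACGT" * 20 + "N" + "ACGT" * 20
        g = _single_copy_genome(seq)
        cands = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 0, len(seq)), 45, 5)
        with_n = [c for c in cands if "N" in c.sequence]
        assert with_n and all(not c.passes_composition for c in with_n)
        assert all(c.passes_composition for c in cands if "N" not in c.sequence)

    def test_composition_filters(self):
        # homopolymer run of 8 and GC out of bounds both fail
        seq = "ACGT" * 10 + "A" * 50 + "GCGC" * 30
        g = _single_copy_genome(seq)
        cands = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 0, len(seq)), 45, 1)
        runs = [c for c in cands if "A" * 8 in c.sequence]
        assert runs and all(not c.passes_composition for c in runs)
        hot = [c for c in cands if c.gc_fraction > 0.70]
        assert hot and all(not c.passes_composition for c in hot)

    def test_region_must_be_on_design_copy(self):
        g = Genome(
            copies={"chr1.1": "A" * 100, "chr1.2": "A" * 200},
            homolog_groups={"chr1": ["chr1.1", "chr1.2"]},
        )
        with pytest.raises(ValueError, match="design copy"):
            tile_candidates(g, "chr1", GenomicInterval("chr1.1", 0, 100), 45, 5)


class TestDensity:
    @pytest.mark.parametrize(
        "n,length,expected",
        [(4800, 4_440_780, 1.08), (4800, 3_837_500, 1.25), (0, 1000, 0.00)],
    )
    def test_values(self, n, length, expected):
        assert round(density(n, length), 2) == expected

    def test_nonpositive_length_fatal(self):
        with pytest.raises(ValueError):
            density(10, 0)


class TestThinning:
    def _oligos(self, starts, l=45):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, max(starts) + l + 1))
        g = _single_copy_genome(seq)
        out = []
        for s in starts:
            c = tile_candidates(g, "chr1", GenomicInterval("chr1.1", s, s + l), l, l)
            out.append(c[0])
        return out

    def test_identity_when_under_target(self):
        oligos = self._oligos(list(range(0, 500, 50)))
        assert thin_to_target(oligos, 10) == oligos
        assert thin_to_target(oligos, 50) == oligos

    def test_uniform_input_gives_regular_subsample(self):
        oligos = self._oligos(list(range(0, 2000, 100)))  # 20 evenly spaced
        picked = thin_to_target(oligos, 10)
        starts = [o.locus.start for o in picked]
        assert starts == list(range(100, 2000, 200))  # every 2nd oligo
        gaps = {b - a for a, b in zip(starts, starts[1:])}
        assert gaps == {200}

    def test_nonpositive_target_fatal(self):
        with pytest.raises(ValueError):
            thin_to_target(self._oligos([0, 50]), 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_clustered_input_near_optimal_uniformity(self, seed):
        """Greedy picks keep the max gap within 2x the ideal spacing whenever
        the brute-force optimum over all subsets achieves that too."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 15))
        starts = sorted(rng.choice(np.arange(0, 1500, 50), size=n, replace=False).tolist())
        oligos = self._oligos(starts, l=45)
        k = 5
        picked = thin_to_target(oligos, k)
        assert len(picked) == k
        ps = [o.locus.start for o in picked]
        assert ps == sorted(ps)
        span = starts[-1] - starts[0]
        ideal = span * n / (n - 1) / k
        greedy_gap = max(b - a for a, b in zip(ps, ps[1:]))
        best = brute_best_max_gap(starts, k, 45)
        assert best is not None
        assert greedy_gap <= max(2 * ideal, best)


class TestSpecificity:
    def test_own_homologs_never_disqualify(self, tetraploid_genome):
        genome, _ = tetraploid_genome
        region = GenomicInterval(genome.design_copy["chr1"], 0, 2000)
        cands = tile_candidates(genome, "chr1", region, 45, 100)
        screen_specificity(cands, genome, policy_for(genome, "chr1"))
        assert all(c.specificity is Specificity.SINGLE_COPY for c in cands)

    def test_verbatim_copy_on_other_chromosome_cross_hybridizes(self):
        rng = np.random.default_rng(3)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        b = b[:1000] + a[100:145] + b[1045:]  # plant the oligo verbatim on chr2
        g = Genome(
            copies={"chr1.1": a, "chr2.1": b},
            homolog_groups={"chr1": ["chr1.1"], "chr2": ["chr2.1"]},
        )
        cands = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 0, 3000), 45, 5)
        screen_specificity(cands, g, policy_for(g, "chr1"))
        planted = next(c for c in cands if c.locus.start == 100)
        assert planted.specificity is Specificity.CROSS_HYBRIDIZING

    def test_reverse_complement_hit_counts(self):
        rng = np.random.default_rng(4)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        payload = a[500:545]
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        b = b[:800] + revcomp(payload) + b[845:]
        g = Genome(
            copies={"chr1.1": a, "chr2.1": b},
            homolog_groups={"chr1": ["chr1.1"], "chr2": ["chr2.1"]},
        )
        cands = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 500, 545), 45, 5)
        screen_specificity(cands, g, policy_for(g, "chr1"))
        assert cands[0].specificity is Specificity.CROSS_HYBRIDIZING

    def test_eighty_pct_identity_duplicate_detected(self):
        """A 45-mer duplicated across chromosomes at 80% identity (9 mismatches)
        is above the 75% homology cutoff and must disqualify."""
        rng = np.random.default_rng(5)
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        payload = list(a[1000:1045])
        for pos in range(0, 45, 5):  # 9 substitutions -> 36/45 = 80%
            payload[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[payload[pos]]
        b = "".join("ACGT"[i] for i in rng.integers(0, 4, 4000))
        b = b[:2000] + "".join(payload) + b[2045:]
        g = Genome(
            copies={"chr1.1": a, "chr2.1": b},
            homolog_groups={"chr1": ["chr1.1"], "chr2": ["chr2.1"]},
        )
        cands = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 1000, 1045), 45, 5)
        screen_specificity(cands, g, policy_for(g, "chr1"))
        assert cands[0].specificity is Specificity.CROSS_HYBRIDIZING
        # at homology 85% the same duplicate no longer disqualifies
        cands2 = tile_candidates(g, "chr1", GenomicInterval("chr1.1", 1000, 1045), 45, 5)
        screen_specificity(cands2, g, policy_for(g, "chr1", homology_pct=85.0))
        assert cands2[0].specificity is Specificity.SINGLE_COPY

    def test_repeat_family_flagged_repetitive(self):
        from oligobar.synthetic_genome import RepeatFamily

        spec = SimulationSpec(
            n_chromosomes=2,
            chromosome_lengths=(10_000, 10_000),
            ploidy=2,
            repeat_families=(RepeatFamily("TE1", 800, 8),),
            rng_seed=9,
        )
        genome, ledger = simulate_genome(spec)
        reps = ledger[ledger.kind.str.startswith("REPEAT")]
        row = reps[reps.chromosome_id == "chr1"].iloc[0]
        design = genome.design_copy["chr1"]
        region = GenomicInterval(design, int(row.ref_start), int(row.ref_stop))
        cands = tile_candidates(genome, "chr1", region, 45, 50)
        screen_specificity(cands, genome, policy_for(genome, "chr1"))
        assert all(c.specificity is Specificity.REPETITIVE for c in cands)

    def test_matches_exhaustive_oracle(self):
        spec = SimulationSpec(
            n_chromosomes=2,
            chromosome_lengths=(6_000, 6_000),
            ploidy=2,
            snp_rate=2e-3,
            rng_seed=21,
        )
        genome, _ = simulate_genome(spec)
        region = GenomicInterval(genome.design_copy["chr1"], 0, 6_000)
        cands = tile_candidates(genome, "chr1", region, 45, 80)
        policy = policy_for(genome, "chr1")
        screen_specificity(cands, genome, policy)
        expected = oracle_specificity_labels(genome, cands, policy)
        assert [c.specificity.value for c in cands] == expected

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_single_copy_set_monotone_in_policy(self, seed):
        """Raising the homology threshold or the repeat cutoff can only grow
        the SINGLE_COPY set, never shrink it."""
        from oligobar.synthetic_genome import RepeatFamily

        spec = SimulationSpec(
            n_chromosomes=2,
            chromosome_lengths=(8_000, 8_000),
            ploidy=2,
            snp_rate=5e-3,
            repeat_families=(RepeatFamily("r", 300, 4),),
            rng_seed=seed,
        )
        genome, _ = simulate_genome(spec)
        region = GenomicInterval(genome.design_copy["chr1"], 0, 8_000)

        def sc_set(**kw):
            cands = tile_candidates(genome, "chr1", region, 45, 120)
            screen_specificity(cands, genome, policy_for(genome, "chr1", **kw))
            return {
                c.locus.start for c in cands if c.specificity is Specificity.SINGLE_COPY
            }

        assert sc_set(homology_pct=70.0) <= sc_set(homology_pct=90.0)
        assert sc_set(max_kmer_genome_count=2) <= sc_set(max_kmer_genome_count=20)

    def test_single_copy_oligos_relocate_to_their_locus(self, tetraploid_genome):
        genome, _ = tetraploid_genome
        design = genome.design_copy["chr1"]
        region = GenomicInterval(design, 0, 3000)
        cands = tile_candidates(genome, "chr1", region, 45, 60)
        screen_specificity(cands, genome, policy_for(genome, "chr1"))
        seq = genome.copies[design]
        for c in single_copy_oligos(cands):
            assert seq.find(c.sequence) == c.locus.start
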