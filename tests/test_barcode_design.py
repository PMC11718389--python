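import numpy as np
import pytest

from oligobar import (
    Genome,
    SimulationSpec,
    simulate_genome,
)
from oligobar.barcode_design import (
    BarcodePlan,
    Color,
    DesignError,
    DesignParams,
    InfeasibleColoringError,
    PositionClass,
    assign_colors,
    assign_mark_counts,
    design_barcode,
    load_published_design,
    min_start_separation,
    plan_from_table,
    plan_regions,
    plan_table,
    signature,
    signatures_equal,
    single_copy_starts,
    solve_colors,
    write_plan,
)
from oligobar.oligo_select import CompositionPolicy

from oracles import enumerate_valid_colorings

TL, I, TR = (
    PositionClass.TERMINAL_LEFT,
    PositionClass.INTERSTITIAL,
    PositionClass.TERMINAL_RIGHT,
)
G, R = Color.GREEN, Color.RED

# scaled-down parameters for desk-size synthetic chromosomes
SMALL = DesignParams(
    oligo_len=45,
    step=25,
    min_region_bp=3_000,
    max_region_bp=5_000,
    n_target=60,
    separation_bp=30_000,
    grow_step=500,
    placement_grid=2_000,
)


def _flat_genome(n_chrom: int, length: int, seed: int = 0) -> Genome:
    rng = np.random.default_rng(seed)
    copies = {}
    groups = {}
    for i in range(n_chrom):
        cid = f"chr{i + 1}.1"
        copies[cid] = "".join("ACGT"[b] for b in rng.integers(0, 4, length))
        groups[f"chr{i + 1}"] = [cid]
    return Genome(copies=copies, homolog_groups=groups)


class TestMarkCounts:
    def test_eight_chromosomes_default_split(self):
        lengths = [88, 77, 100, 94, 84, 90, 95, 87]  # chr2, chr5, chr8 shortest
        g = Genome(
            copies={f"chr{i+1}.1": "A" * (l * 10) for i, l in enumerate(lengths)},
            homolog_groups={f"chr{i+1}": [f"chr{i+1}.1"] for i in range(8)},
        )
        marks = assign_mark_counts(g)
        assert sum(1 for v in marks.values() if v == 2) == 3
        assert {c for c, v in marks.items() if v == 2} == {"chr2", "chr5", "chr8"}

    def test_explicit_map_overrides(self):
        g = _flat_genome(2, 1000)
        assert assign_mark_counts(g, explicit={"chr1": 2, "chr2": 2}) == {
            "chr1": 2,
            "chr2": 2,
        }

    def test_explicit_map_must_cover_all(self):
        g = _flat_genome(2, 1000)
        with pytest.raises(DesignError, match="chr2"):
            assign_mark_counts(g, explicit={"chr1": 2})

    def test_single_chromosome_gets_majority_class(self):
        g = _flat_genome(1, 1000)
        assert assign_mark_counts(g) == {"chr1": 3}


class TestPlanRegions:
    def test_three_mark_layout_constraints(self):
        g = _flat_genome(1, 120_000, seed=2)
        regions = plan_regions(g, "chr1", 3, SMALL)
        assert [r.position_class for r in regions] == [TL, I, TR]
        ivs = [r.interval for r in regions]
        assert ivs[0].start == 0
        assert ivs[2].stop == 120_000
        # disjoint and ordered
        assert ivs[0].stop <= ivs[1].start and ivs[1].stop <= ivs[2].start
        # start-to-start separation floor respected
        assert ivs[1].start - ivs[0].start >= SMALL.separation_bp
        assert ivs[2].start - ivs[1].start >= SMALL.separation_bp
        # regions sized within bounds and filled to target
        for r in regions:
            assert SMALL.min_region_bp <= r.interval.length <= SMALL.max_region_bp
            assert r.n_oligos == SMALL.n_target
            assert all(r.interval.contains(o.locus) for o in r.oligos)

    def test_two_mark_layout_anchored_at_ends(self):
        g = _flat_genome(1, 80_000, seed=3)
        regions = plan_regions(g, "chr1", 2, SMALL)
        assert [r.position_class for r in regions] == [TL, TR]
        assert regions[0].interval.start == 0
        assert regions[1].interval.stop == 80_000

    def test_too_short_chromosome_names_constraint(self):
        g = _flat_genome(1, 50_000, seed=4)
        with pytest.raises(DesignError, match="separation"):
            plan_regions(g, "chr1", 3, SMALL)

    def test_interstitial_placement_is_exhaustive_argmax(self):
        """The chosen interstitial window matches a brute-force scan of every
        feasible grid placement, with the documented tie-breaking."""
        g = _flat_genome(1, 120_000, seed=5)
        eligible = single_copy_starts(g, "chr1", SMALL)
        regions = plan_regions(g, "chr1", 3, SMALL, eligible=eligible)
        left, inter, right = (r.interval for r in regions)
        starts = sorted(o.locus.start for o in eligible)

        def count(a, b):
            return sum(1 for s in starts if a <= s and s + SMALL.oligo_len <= b)

        s_lo = max(SMALL.separation_bp, left.stop)
        s_hi = min(right.start - SMALL.separation_bp, right.start - SMALL.min_region_bp)
        grid = list(range(s_lo, s_hi + 1, SMALL.placement_grid))
        if grid[-1] != s_hi:
            grid.append(s_hi)
        scored = sorted(
            grid,
            key=lambda s: (
                -count(s, s + SMALL.min_region_bp),
                abs(s + SMALL.min_region_bp / 2 - 60_000),
                s,
            ),
        )
        # the realized region grew from the brute-force winner
        assert inter.start <= scored[0] <= inter.stop


class TestSeparationAndSignatures:
    def test_published_layout_separation(self):
        plan = plan_from_table(load_published_design())
        assert min_start_separation(plan) == 35_831_680

    def test_single_region_chromosomes_report_na(self):
        df = load_published_design()
        one = plan_from_table(df[df.probe == "Ms1.1"].assign(chromosome="chr1"))
        assert min_start_separation(one) is None

    def test_two_adjacent_starts(self):
        df = load_published_design().head(2).copy()
        df.loc[df.index[1], "start_bp"] = 1
        df.loc[df.index[1], "stop_bp"] = 4_440_781
        assert min_start_separation(plan_from_table(df)) == 1

    @pytest.mark.parametrize(
        "a,b,equal",
        [
            ([(TL, G), (TR, R)], [(TL, R), (TR, G)], True),
            ([(TL, G), (I, G), (TR, R)], [(TL, R), (I, G), (TR, G)], True),
            ([(TL, G), (I, R), (TR, G)], [(TL, G), (I, G), (TR, G)], False),
            ([(TL, G), (TR, G)], [(TL, R), (TR, R)], False),
        ],
    )
    def test_reversal_equivalence(self, a, b, equal):
        assert signatures_equal(tuple(a), tuple(b)) is equal


class TestColoring:
    def test_two_chromosomes_two_marks_feasible(self):
        colors = solve_colors({"c1": (TL, TR), "c2": (TL, TR)})
        assert colors["c1"] != colors["c2"]

    def test_three_two_mark_chromosomes_exactly_feasible(self):
        colors = solve_colors({f"c{i}": (TL, TR) for i in range(3)})
        canon = {min(c, c[::-1], key=lambda x: [y.value for y in x]) for c in colors.values()}
        assert len(canon) == 3  # GG, RR and the GR~RG class all used

    def test_four_two_mark_chromosomes_infeasible_with_certificate(self):
        with pytest.raises(InfeasibleColoringError) as exc:
            solve_colors({f"c{i}": (TL, TR) for i in range(4)})
        cert = exc.value.certificate
        assert cert["n_classes"] == 3 and len(cert["chromosomes"]) == 4
        # brute-force enumeration agrees: no valid assignment exists
        assert enumerate_valid_colorings({f"c{i}": 2 for i in range(4)}) == []

    def test_published_mark_split_has_valid_coloring(self):
        profiles = {f"s{i}": (TL, TR) for i in range(3)}
        profiles.update({f"l{i}": (TL, I, TR) for i in range(5)})
        colors = solve_colors(profiles)
        sigs = {
            c: tuple(zip(profiles[c], colors[c])) for c in profiles
        }
        chroms = sorted(sigs)
        for i, a in enumerate(chroms):
            for b in chroms[i + 1 :]:
                assert not signatures_equal(sigs[a], sigs[b])
        # cross-check feasibility by exhaustive enumeration
        marks = {c: len(p) for c, p in profiles.items()}
        assert enumerate_valid_colorings(marks)

    def test_solver_result_is_among_enumerated_valid_colorings(self):
        profiles = {"a": (TL, TR), "b": (TL, TR), "c": (TL, I, TR)}
        colors = solve_colors(profiles)
        idx = {G: 0, R: 1}
        ours = {c: tuple(idx[x] for x in colors[c]) for c in profiles}
        valid = enumerate_valid_colorings({c: len(p) for c, p in profiles.items()})
        assert ours in valid


class TestFullDesign:
    @pytest.fixture(scope="class")
    @staticmethod
    def designed():
        g = _flat_genome(2, 120_000, seed=8)
        plan = design_barcode(g, SMALL, explicit_marks={"chr1": 2, "chr2": 3})
        return g, plan

    def test_signature_uniqueness_and_totals(self, designed):
        _, plan = designed
        sigs = plan.signatures()
        chroms = sorted(sigs)
        for i, a in enumerate(chroms):
            for b in chroms[i + 1 :]:
                assert not signatures_equal(sigs[a], sigs[b])
        assert plan.total_oligos == sum(r.n_oligos for r in plan.regions)
        assert plan.total_oligos == 5 * SMALL.n_target  # 2 + 3 regions

    def test_determinism_byte_identical_outputs(self, designed, tmp_path):
        g, plan = designed
        plan2 = design_barcode(g, SMALL, explicit_marks={"chr1": 2, "chr2": 3})
        assert plan_table(plan).equals(plan_table(plan2))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_plan(plan, d1)
        write_plan(plan2, d2)
        for name in ("barcode_plan.tsv", "barcode_plan.bed", "barcode_probes.fasta"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_published_arithmetic_from_table(self):
        """The published 21-region layout: 21 x 4800 = 100 800 oligos."""
        plan = plan_from_table(load_published_design())
        assert len(plan.regions) == 21
        assert plan.total_oligos == 100_800
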