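"""Event accounting, summary table, density, gaps, spectra, audit, GC."""

import numpy as np
import pytest
from scipy.stats import chi2

import rilmap as rm
from rilmap.genotypes import encode_calls
from rilmap.map_stats import (
    add_totals,
    allele_class_spectrum,
    count_recombination_events,
    expected_pattern_count,
    find_gaps,
    format_summary,
    gc_near_breakpoints,
    genotype_error_audit,
    load_published_summary,
    snp_density,
    summarize_map,
)
from rilmap.template_map import LinkageGroup, TemplateMap, event_ledger, genetic_positions


def _template(rows_per_group):
    groups = [LinkageGroup(patterns=encode_calls(rows)) for rows in rows_per_group]
    t = TemplateMap(groups, [f"L{i}" for i in range(len(rows_per_group[0][0]))])
    genetic_positions(t)
    return t


class TestCountRecombinationEvents:
    @pytest.mark.parametrize(
        "column,expected",
        [("AAB", (1, 1, 0)), ("AHB", (2, 0, 2)), ("AAA", (0, 0, 0)),
         ("A-B", (1, 1, 0)), ("AH-B", (2, 0, 2)), ("ABA", (2, 2, 0))],
    )
    def test_single_line_transitions(self, column, expected):
        t = _template([[c for c in column]])  # one line scanned down the map
        assert count_recombination_events(t) == expected

    def test_agrees_with_template_ledger(self, clean_build):
        *_, result = clean_build
        total, hom_hom, hom_het = count_recombination_events(result.template)
        assert total == event_ledger(result.template).total
        assert total == hom_hom + hom_het

    def test_expected_patterns_bound_observed(self, clean_build):
        *_, result = clean_build
        total, _, _ = count_recombination_events(result.template)
        expected = expected_pattern_count(total, result.template.n_groups)
        observed = sum(g.n_positions for g in result.template.groups)
        assert observed <= expected


class TestExpectedPatternCount:
    @pytest.mark.parametrize(
        "events,groups,expected", [(2082, 12, 2094), (0, 12, 12), (1, 1, 2)]
    )
    def test_one_baseline_per_group_plus_one_per_event(self, events, groups, expected):
        assert expected_pattern_count(events, groups) == expected

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            expected_pattern_count(-1, 12)


class TestSummarizeMap:
    def test_published_per_group_rows_reproduce_printed_totals(self):
        df = add_totals(load_published_summary())
        totals = df[df["linkage_group"] == "Total"].iloc[0]
        assert totals["snps"] == 2_008_196
        assert totals["patterns"] == 1177
        assert totals["scaffolds"] == 57_388

    def test_totals_equal_column_sums_on_built_map(self, clean_build):
        *_, result = clean_build
        df = summarize_map(result.template, result.scaffold_placements)
        per_group = df[df["linkage_group"] != "Total"]
        totals = df[df["linkage_group"] == "Total"].iloc[0]
        for col in ("snps", "patterns", "scaffolds"):
            assert totals[col] == per_group[col].sum()
        assert totals["length_cm"] == pytest.approx(per_group["length_cm"].sum())
        assert totals["scaffolds"] == len(result.scaffold_placements)

    def test_empty_map_is_all_zeros(self):
        t = TemplateMap([], [])
        df = summarize_map(t)
        assert df["snps"].sum() == 0 and df["scaffolds"].sum() == 0

    def test_plain_text_rendering_rounds_cm_to_one_decimal(self):
        txt = format_summary(add_totals(load_published_summary()))
        assert "2,008,196" in txt and "959.5" in txt


class TestSnpDensity:
    def test_published_density(self):
        assert snp_density(192_589_591, 2_008_196) == 95.9

    @pytest.mark.parametrize("bp,snps,expected", [(100, 100, 1.0), (0, 5, 0.0)])
    def test_degenerate_quotients(self, bp, snps, expected):
        assert snp_density(bp, snps) == expected

    def test_zero_snps_invalid(self):
        with pytest.raises(ValueError):
            snp_density(100, 0)


class TestFindGaps:
    def _template_with_spans(self, spans):
        # each step toggles the first r lines, so adjacent recombinant
        # counts (and hence half_R spans) are exact by construction
        n_rec = [int(round(s * 96 / 50)) for s in spans]
        row = ["A"] * 96
        rows = ["".join(row)]
        for r in n_rec:
            for i in range(r):
                row[i] = "B" if row[i] == "A" else "A"
            rows.append("".join(row))
        g = LinkageGroup(patterns=encode_calls(rows))
        t = TemplateMap([g], [f"L{i}" for i in range(96)])
        genetic_positions(t)
        return t

    def test_threshold_and_ordering(self):
        t = self._template_with_spans([6.0, 3.0, 5.0])  # realised: 6.25/3.125/5.21
        gaps = find_gaps(t, min_cm=5.0)
        assert len(gaps) == 2
        assert gaps["span_cm"].tolist() == sorted(
            gaps["span_cm"].tolist(), reverse=True
        )
        assert gaps["span_cm"].iloc[0] >= gaps["span_cm"].iloc[1] >= 5.0

    def test_no_gaps_when_threshold_exceeds_all(self):
        t = self._template_with_spans([4.0, 3.0])
        assert len(find_gaps(t, min_cm=5.0)) == 0

    def test_boundary_inclusive(self):
        t = _template([["A" * 96, "B" * 14 + "A" * 82]])  # one 7.29 cM interval
        gaps = find_gaps(t, min_cm=50 * 14 / 96)
        assert len(gaps) == 1
        assert gaps["recombinants"].iloc[0] == 14


class TestAlleleClassSpectrum:
    def test_single_class(self):
        assert allele_class_spectrum(["G"] * 5, ["A"] * 5)["C/T"] == 1.0

    def test_four_way_toy(self):
        spec = allele_class_spectrum(list("GCTA"), list("AGGT"))
        assert spec == {"C/T": 0.25, "C/G": 0.25, "C/A": 0.25, "A/T": 0.25}

    def test_uniform_random_pairs_match_enumeration(self):
        # of the 12 ordered distinct pairs: 4 are C/T, 2 C/G, 4 C/A, 2 A/T
        rng = np.random.default_rng(0)
        pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
        picks = rng.integers(0, 12, size=6000)
        ref = [pairs[i][0] for i in picks]
        alt = [pairs[i][1] for i in picks]
        spec = allele_class_spectrum(ref, alt)
        assert spec["C/T"] == pytest.approx(4 / 12, abs=0.025)
        assert spec["C/A"] == pytest.approx(4 / 12, abs=0.025)
        assert spec["C/G"] == pytest.approx(2 / 12, abs=0.025)
        assert spec["A/T"] == pytest.approx(2 / 12, abs=0.025)

    def test_simulated_catalog_is_uniform_over_pairs(self, clean_build):
        truth = clean_build[0]
        spec = allele_class_spectrum(truth.snps["ref"], truth.snps["alt"])
        assert spec["C/T"] == pytest.approx(4 / 12, abs=0.03)


class TestGenotypeErrorAudit:
    def test_het_consensus_with_one_hom_call(self):
        calls = encode_calls(["AH", "HH", "HA", "HH"])  # 4 snps x 2 lines
        audit = genotype_error_audit(calls, ["s1"] * 4)
        # consensus is H for both lines; 2 of 8 called cells are hom
        assert audit.het_as_hom_rate == pytest.approx(2 / 8)
        assert audit.hom_as_het_rate == 0.0

    def test_perfect_calls_have_zero_error(self):
        calls = encode_calls(["AB", "AB", "AB"])
        audit = genotype_error_audit(calls, ["s1"] * 3)
        assert audit.het_as_hom_rate == 0
        assert audit.hom_as_het_rate == 0
        assert audit.hom_as_other_hom_rate == 0
        assert audit.missing_rate == 0

    def test_low_coverage_hides_heterozygotes_most(self, clean_build):
        _, _, _, filtered, _, _ = clean_build
        audit = genotype_error_audit(
            filtered.calls, filtered.sites["scaffold"].to_numpy()
        )
        assert audit.het_as_hom_rate > 0.3
        assert audit.het_as_hom_rate > 20 * audit.hom_as_other_hom_rate


class TestGcNearBreakpoints:
    def test_null_case_identical_composition(self):
        gc, gc_asm, p = gc_near_breakpoints(["ACGT" * 50], {"s": "ACGT" * 500})
        assert gc == gc_asm == 0.5
        assert p == pytest.approx(1.0)

    def test_two_proportion_chi_square_against_hand_computation(self):
        # contexts: 360 GC of 1000; assembly: 3730 GC of 10000
        contexts = ["G" * 360 + "A" * 640]
        gc, gc_asm, p = gc_near_breakpoints(contexts, (3730, 10000))
        assert gc == pytest.approx(0.360)
        assert gc_asm == pytest.approx(0.373)
        # independent oracle: Pearson chi-square on the 2x2 table
        table = np.array([[360, 640], [3730, 6270]], dtype=float)
        row = table.sum(1, keepdims=True)
        col = table.sum(0, keepdims=True)
        expected = row * col / table.sum()
        stat = ((table - expected) ** 2 / expected).sum()
        assert p == pytest.approx(chi2.sf(stat, 1))

    def test_single_base_context(self):
        gc, _, _ = gc_near_breakpoints(["G"], (50, 100))
        assert gc == 1.0

    def test_empty_contexts_rejected(self):
        with pytest.raises(ValueError):
            gc_near_breakpoints([], (1, 2))
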