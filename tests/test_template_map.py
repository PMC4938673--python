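"""Pattern arithmetic, ordering optimality, clustering, placement, cM."""

import itertools

import numpy as np
import pytest

import rilmap as rm
from rilmap.genotypes import GT_MISS, encode_calls
from rilmap.template_map import (
    LinkageGroup,
    MapBuildConfig,
    TemplateMap,
    _opposite_matrix,
    _path_cost,
    build_template_map,
    cluster_linkage_groups,
    collapse_patterns,
    event_ledger,
    genetic_positions,
    order_patterns,
    pattern_distance,
    place_patterns,
    place_snp_on_template,
)


class TestPatternDistance:
    @pytest.mark.parametrize(
        "p,q,expected",
        [("AAB", "AAB", 0), ("AAB", "ABB", 1), ("AHB", "ABB", 0),
         ("A-B", "B-B", 1), ("HHH", "ABA", 0), ("AB", "BA", 2)],
    )
    def test_heterozygote_matching_rule(self, p, q, expected):
        assert pattern_distance(p, q) == expected

    def test_symmetric(self):
        assert pattern_distance("AABH", "BBA-") == pattern_distance("BBA-", "AABH")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pattern_distance("AAB", "AB")


class TestOrderPatterns:
    def test_recovers_known_chain(self):
        # p1-p2-p3-p4 with adjacent distances 1, all others >= 2
        chain = ["AAAABBBB", "AAABBBBB", "AABBBBBB", "ABBBBBBB"]
        pats = encode_calls([chain[i] for i in (2, 0, 3, 1)])
        order = order_patterns(pats)
        decoded = ["".join("AHB-"[c] if c >= 0 else "-" for c in pats[i]) for i in order]
        assert decoded == chain or decoded == chain[::-1]
        D = _opposite_matrix(pats, pats)
        assert _path_cost(D, order) == 3

    def test_single_pattern(self):
        assert order_patterns(encode_calls(["AAB"])).tolist() == [0]

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(2, 9))
            pats = rng.choice(
                [0, 1, 2, -1], size=(n, 20), p=[0.45, 0.05, 0.45, 0.05]
            ).astype(np.int8)
            D = _opposite_matrix(pats, pats)
            best = min(
                _path_cost(D, np.array(p)) for p in itertools.permutations(range(n))
            )
            assert _path_cost(D, order_patterns(pats)) == best

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        pats = rng.choice([0, 2], size=(12, 30)).astype(np.int8)
        assert np.array_equal(order_patterns(pats), order_patterns(pats))


class TestClusterLinkageGroups:
    def test_singleton(self):
        groups = cluster_linkage_groups(encode_calls(["AAB"]))
        assert len(groups) == 1 and groups[0].tolist() == [0]

    def test_true_chromosomes_recovered(self, clean_build):
        truth = clean_build[0]
        # ten true genotype patterns per chromosome at ~8 cM spacing: the
        # adjacent RIL recombination fraction (~0.14) stays below threshold
        pats, labels = [], []
        for c in range(12):
            sub = truth.snps[truth.snps["chrom"] == c].sort_values("cM")
            cm = sub["cM"].to_numpy()
            picks = [int(np.argmin(np.abs(cm - t))) for t in np.linspace(4, 76, 10)]
            rows = sub.iloc[picks]["snp_id"].to_numpy()
            pats.append(truth.true_genotypes[rows])
            labels += [c] * 10
        groups = cluster_linkage_groups(np.concatenate(pats))
        assert len(groups) == 12
        labels = np.array(labels)
        for g in groups:
            assert len(set(labels[g])) == 1

    def test_one_chromosome_is_one_group(self, clean_build):
        truth = clean_build[0]
        sub = truth.snps[truth.snps["chrom"] == 0]
        rows = sub.iloc[:: max(len(sub) // 20, 1)]["snp_id"].to_numpy()
        groups = cluster_linkage_groups(truth.true_genotypes[rows])
        assert len(groups) == 1


def _toy_template():
    rows = ["AAAABBBB", "AAABBBBB", "AABBBBBB", "BBBBBBBB"]
    g = LinkageGroup(patterns=encode_calls(rows))
    return TemplateMap([g], [f"L{i}" for i in range(8)])


class TestPlacement:
    def test_exact_match_places_with_zero_mismatch(self):
        p = place_snp_on_template("AABBBBBB", _toy_template())
        assert (p.group, p.pos_lo, p.pos_hi, p.mismatches, p.rejected) == (
            0, 2, 2, 0, False
        )

    def test_far_pattern_rejected_as_anomalous(self):
        p = place_snp_on_template("BBBAAAAA", _toy_template(), max_mismatch=2)
        assert p.rejected and p.mismatches > 2

    def test_missing_data_tie_reported_as_window(self):
        # missing at the line distinguishing rows 0 and 1 -> both tie at 0
        p = place_snp_on_template("AAA-BBBB", _toy_template())
        assert not p.rejected
        assert (p.pos_lo, p.pos_hi) == (0, 1)

    def test_empty_template_invalid(self):
        with pytest.raises(ValueError):
            place_patterns(encode_calls(["AAB"]), TemplateMap([], []))


class TestGeneticPositions:
    def test_identical_adjacent_patterns_are_zero_cm_apart(self):
        g = LinkageGroup(patterns=encode_calls(["AABB", "AABB"]))
        t = TemplateMap([g], list("abcd"))
        (cm,) = genetic_positions(t)
        assert cm.tolist() == [0.0, 0.0]

    def test_half_r_convention_on_14_of_96(self):
        rows = ["A" * 96, "B" * 14 + "A" * 82]
        t = TemplateMap([LinkageGroup(patterns=encode_calls(rows))], [str(i) for i in range(96)])
        (cm,) = genetic_positions(t, "half_R")
        assert cm[-1] == pytest.approx(50 * 14 / 96)  # ~7.29 cM

    def test_haldane_waller_at_half_recombinants(self):
        rows = ["AAAA", "BBAA"]
        t = TemplateMap([LinkageGroup(patterns=encode_calls(rows))], list("abcd"))
        (cm,) = genetic_positions(t, "haldane_waller")
        assert cm[-1] == pytest.approx(50.0)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            genetic_positions(_toy_template(), "kosambi")


class TestCollapsePatterns:
    def test_missing_acts_as_wildcard(self):
        reps, members = collapse_patterns(encode_calls(["AABB", "AA-B", "BBAA"]))
        assert len(reps) == 2
        assert sorted(len(m) for m in members) == [1, 2]

    def test_no_shared_information_means_no_merge(self):
        reps, _ = collapse_patterns(encode_calls(["AA--", "--BB"]))
        assert len(reps) == 2


class TestBuildTemplateMap:
    def test_recovers_twelve_linkage_groups(self, clean_build):
        *_, result = clean_build
        assert result.template.n_groups == 12

    def test_scaffolds_placed_on_true_chromosomes(self, clean_build):
        from helpers import group_to_chromosome, misplaced_scaffolds

        truth, *_, result = clean_build
        assert group_to_chromosome(truth, result.scaffold_placements).nunique() == 12
        assert misplaced_scaffolds(truth, result.scaffold_placements) == 0

    def test_scaffold_order_matches_truth(self, clean_build):
        from scipy.stats import kendalltau

        truth, *_, result = clean_build
        truemap = truth.scaffold_placements.groupby("scaffold").first()
        for _, sub in result.scaffold_placements.groupby("group"):
            if len(sub) < 40:
                continue
            tau, _ = kendalltau(
                truemap.loc[sub["scaffold"], "chrom_start"], sub["pos_lo"]
            )
            assert abs(tau) >= 0.95  # reflections resolved by taking |tau|

    def test_repeat_snps_enriched_in_anomalous_set(self, artifact_build):
        truth, _, _, filtered, report, result = artifact_build
        # map rejection (filter cascade or anomaly) back to the simulated SNPs
        rejected = ~report.keep_mask
        rejected[np.nonzero(report.keep_mask)[0]] = result.rejected_snps
        is_repeat = truth.snps["is_repeat"].to_numpy()
        rate_repeat = rejected[is_repeat].mean()
        rate_true = rejected[~is_repeat].mean()
        assert rate_repeat > max(rate_true, 1e-9) * 10

    def test_total_events_invariant_under_group_reversal(self, clean_build):
        *_, result = clean_build
        before = event_ledger(result.template).total
        flipped = TemplateMap(
            [LinkageGroup(patterns=g.patterns[::-1]) for g in result.template.groups],
            result.template.line_ids,
        )
        assert event_ledger(flipped).total == before

    def test_map_length_non_increasing_at_fixed_threshold(self, clean_build):
        _, _, _, filtered, _, _ = clean_build
        cfg = MapBuildConfig(init_min_snps=10, final_min_snps=10, max_iterations=8)
        result = build_template_map(filtered, cfg)
        lengths = [h["total_cm"] for h in result.history]
        assert all(b <= a + 1e-9 for a, b in zip(lengths, lengths[1:]))

    def test_rebuild_on_converged_output_is_a_fixed_point(self, clean_build):
        _, _, _, filtered, _, result = clean_build
        surviving = filtered.subset(~result.rejected_snps)
        again = build_template_map(surviving)
        assert again.template.n_groups == result.template.n_groups
        a = sorted(g.patterns.tobytes() for g in again.template.groups)
        b = sorted(g.patterns.tobytes() for g in result.template.groups)
        assert a == b

    def test_refuses_when_no_scaffold_is_rich_enough(self, clean_build):
        _, _, _, filtered, _, _ = clean_build
        with pytest.raises(ValueError, match="lower"):
            build_template_map(filtered, MapBuildConfig(init_min_snps=10**6))
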