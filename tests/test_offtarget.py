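"""Cross-tab arithmetic, correlation, homology search, levels, enrichment."""

import math
from itertools import combinations

import numpy as np
import pytest

from ota_sentinel.expression import DEGRecord
from ota_sentinel.matchscan import GeneMatchClass
from ota_sentinel.offtarget import (AlignmentParams, correlate_match_foldchange,
                                    crosstab_matches, enrich_hypergeometric,
                                    evalue, find_homologs, level_table,
                                    pairwise_identity, pathway_levels,
                                    round_pct, tabulate_counts)
from ota_sentinel.sequences import gen_dsrna, reverse_complement

from conftest import random_dna


def rec(gene, lfc=0.0, status="ns"):
    fdr = 0.01 if status != "ns" else 0.5
    return DEGRecord(gene, lfc, fdr / 2, fdr, status)


def cls(gene, length):
    return GeneMatchClass(gene, length, None)


# -- cross-tab ---------------------------------------------------------------

# the study transcriptome's per-length table: (length, total, up, down)
STUDY_LADDER = [("7", 5462, 3, 3), ("8", 3722, 2, 1), ("9", 1272, 0, 1),
                ("10", 325, 0, 0), ("11", 103, 0, 0), ("12", 21, 0, 0),
                ("13", 9, 0, 0), ("14", 3, 0, 0), ("15", 1, 0, 0)]


def test_tabulate_reproduces_printed_percentages():
    rows = {r.label: r for r in tabulate_counts(STUDY_LADDER)}
    assert (rows["8"].pct_up, rows["8"].pct_down, rows["8"].pct_ns) == (0.05, 0.03, 99.92)
    assert (rows["9"].pct_down, rows["9"].pct_ns) == (0.08, 99.92)
    assert rows["15"].pct_ns == 100.0
    total = rows["Total"]
    assert (total.n_total, total.n_up, total.n_down, total.n_ns) == (10918, 5, 5, 10908)


def test_total_row_is_the_column_sum():
    rows = tabulate_counts(STUDY_LADDER)
    body, total = rows[:-1], rows[-1]
    for col in ("n_total", "n_up", "n_down", "n_ns"):
        assert getattr(total, col) == sum(getattr(r, col) for r in body)


def test_round_pct_is_half_up():
    assert round_pct(1, 8) == 12.5
    assert round_pct(1, 16) == 6.25
    assert round_pct(1, 3200) == 0.03   # 0.03125 -> 0.03 (below the half)
    assert round_pct(5, 8000) == 0.06   # 0.0625  -> 0.06 (below the half)
    assert round_pct(1, 800) == 0.13    # 0.125   -> 0.13 (exactly half rounds up)


def test_crosstab_joins_and_percentages():
    classes = [cls("a", 8), cls("b", 8), cls("c", 8), cls("d", 9)]
    degs = [rec("a", 2.5, "up"), rec("b"), rec("d", -1.7, "down")]
    with pytest.warns(UserWarning, match="missing"):
        rows = {r.label: r for r in crosstab_matches(classes, degs)}
    assert (rows["8"].n_total, rows["8"].n_up, rows["8"].n_ns) == (3, 1, 2)
    assert rows["9"].n_down == 1
    assert rows["Total"].n_total == 4


def test_crosstab_all_ns_without_degs():
    classes = [cls("a", 7), cls("b", 12)]
    degs = [rec("a"), rec("b")]
    rows = crosstab_matches(classes, degs)
    assert all(r.pct_ns == 100.0 for r in rows)


def test_crosstab_duplicate_deg_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        crosstab_matches([cls("a", 8)], [rec("a"), rec("a")])


# -- correlation -------------------------------------------------------------

def test_perfectly_antimonotone_series():
    classes = [cls(g, l) for g, l in zip("abcd", (7, 8, 9, 10))]
    degs = [rec(g, f, "up") for g, f in zip("abcd", (4.0, 3.0, 2.0, 1.0))]
    res = correlate_match_foldchange(classes, degs)
    assert res.coefficient == pytest.approx(-1.0)


def test_constant_fold_changes_flagged_degenerate():
    classes = [cls(g, l) for g, l in zip("abc", (7, 8, 9))]
    degs = [rec(g, 1.0) for g in "abc"]
    res = correlate_match_foldchange(classes, degs)
    assert res.degenerate and res.coefficient == 0.0


def test_too_few_pairs_rejected():
    with pytest.raises(ValueError, match=">= 3"):
        correlate_match_foldchange([cls("a", 7)], [rec("a")])


def test_null_correlation_is_small_on_independent_data():
    rng = np.random.default_rng(31)
    rhos = []
    for _ in range(50):
        lengths = rng.integers(7, 16, size=200)
        lfcs = rng.normal(0, 1, size=200)
        classes = [cls(f"g{i}", int(l)) for i, l in enumerate(lengths)]
        degs = [rec(f"g{i}", float(f)) for i, f in enumerate(lfcs)]
        rhos.append(correlate_match_foldchange(classes, degs).coefficient)
    assert abs(np.mean(rhos)) < 0.03
    assert np.percentile(np.abs(rhos), 95) < 0.2


def test_signed_flag_changes_the_response_variable():
    classes = [cls(g, l) for g, l in zip("abcd", (7, 8, 9, 10))]
    degs = [rec(g, f) for g, f in zip("abcd", (-4.0, -3.0, -2.0, -1.0))]
    assert correlate_match_foldchange(classes, degs, signed=True).coefficient > 0
    assert correlate_match_foldchange(classes, degs, signed=False).coefficient < 0


# -- homology search ---------------------------------------------------------

def test_evalue_formula_toy_numbers():
    params = AlignmentParams(lambda_=1.33, k=0.621)
    assert evalue(30, 1000, 1000, params) == pytest.approx(2.9157e-12, rel=1e-3)


def test_self_hit_has_full_identity():
    rng = np.random.default_rng(41)
    query = random_dna(rng, 500)
    subjects = [("self", query)] + [(f"r{i}", random_dna(rng, 500)) for i in range(5)]
    hits = find_homologs(query, subjects, evalue_threshold=1e-10)
    assert hits[0].subject_id == "self"
    assert hits[0].identity == pytest.approx(100.0)
    assert hits[0].score == 500


def test_reverse_complement_subject_found_on_antisense_strand():
    rng = np.random.default_rng(42)
    query = random_dna(rng, 300)
    hits = find_homologs(query, [("rc", reverse_complement(query))],
                         evalue_threshold=1e-10)
    assert len(hits) == 1 and hits[0].strand == "antisense"


def test_random_database_yields_no_hits_at_strict_threshold():
    rng = np.random.default_rng(43)
    query = random_dna(rng, 432)
    misses = 0
    for _ in range(5):
        subjects = [(f"s{i}", random_dna(rng, 1000)) for i in range(50)]
        misses += len(find_homologs(query, subjects, evalue_threshold=1e-10)) == 0
    assert misses == 5  # expected chance hits ~ 5e4 * 1e-10 per search


def test_diverged_homolog_recovered_with_gaps():
    rng = np.random.default_rng(44)
    query = random_dna(rng, 400)
    # 5% substitutions plus two short indels
    subject = list(query)
    for i in rng.choice(400, 20, replace=False):
        subject[i] = "ACGT"[(("ACGT".index(subject[i])) + 1) % 4]
    subject = "".join(subject)
    subject = subject[:100] + subject[103:250] + "AC" + subject[250:]
    hits = find_homologs(query, [("hom", subject)], evalue_threshold=1e-10)
    assert len(hits) == 1
    assert hits[0].identity > 90.0
    assert hits[0].query_end - hits[0].query_start > 350


def test_query_shorter_than_word_rejected():
    with pytest.raises(ValueError, match="word size"):
        find_homologs("ACGTACGT", [("s", "ACGT" * 100)])


def test_empty_transcriptome_is_not_an_error():
    assert find_homologs("ACGT" * 20, []) == []


def test_evalue_null_calibration():
    """Observed chance-hit counts track the summed E-value expectation."""
    rng = np.random.default_rng(45)
    params = AlignmentParams(word_size=5)
    threshold = 2.0
    observed = 0
    n_seeds = 20
    for _ in range(n_seeds):
        query = random_dna(rng, 200)
        subjects = [(f"s{i}", random_dna(rng, 500)) for i in range(10)]
        observed += len(find_homologs(query, subjects, params,
                                      evalue_threshold=threshold))
    expected = n_seeds * threshold
    assert abs(observed - expected) <= 3 * math.sqrt(expected)


# -- pairwise identity -------------------------------------------------------

def test_identical_sequences_full_identity():
    assert pairwise_identity("ACGTACGT", "ACGTACGT") == pytest.approx(100.0)


def test_hand_computed_global_alignment_identity():
    # match 1, mismatch -1, linear gap -2: the gapless alignment (score -4)
    # beats any gapped one, and no column matches
    params = AlignmentParams(match=1, mismatch=-1, gap_open=0, gap_extend=2)
    assert pairwise_identity("ACGT", "TGCA", params) == pytest.approx(0.0)


def test_half_identity():
    assert pairwise_identity("AAAA", "AATT") == pytest.approx(50.0)


# -- pathway levels ----------------------------------------------------------

TOY = {"P1": {"g1", "g2"}, "P2": {"g2", "g3"}, "P3": {"g3", "g4"}}


def test_toy_chain_levels():
    assert pathway_levels(TOY, {"g1"}) == {"g1": 1, "g2": 1, "g3": 2, "g4": 3}


def test_isolated_seed_pathway():
    annotation = {"P1": {"g1", "g2"}, "P2": {"g3", "g4"}}
    assert pathway_levels(annotation, {"g1"}) == {"g1": 1, "g2": 1}


def test_seed_absent_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="no seed gene"):
        assert pathway_levels(TOY, {"zz"}) == {}


def test_genes_take_minimal_level():
    annotation = {"P1": {"s", "a"}, "P2": {"a", "b"}, "P3": {"b", "a"}}
    levels = pathway_levels(annotation, {"s"})
    assert levels["a"] == 1 and levels["b"] == 2


def test_level_map_invariant_under_input_order():
    fwd = pathway_levels(dict(sorted(TOY.items())), {"g1"})
    rev = pathway_levels(dict(sorted(TOY.items(), reverse=True)), {"g1"})
    assert fwd == rev


def test_max_level_truncates():
    assert pathway_levels(TOY, {"g1"}, max_level=2) == {"g1": 1, "g2": 1, "g3": 2}


def test_level_table_reproduces_study_total_row():
    """Adult ring counts: level 2 (2698; 190 up; 6 down), level 3 (25545; 1261; 39)."""
    rows = {r.label: r for r in tabulate_counts(
        [("Level 2", 2698, 190, 6), ("Level 3", 25545, 1261, 39)]
    )}
    total = rows["Total"]
    assert (total.n_total, total.n_up, total.n_down, total.n_ns) == (28243, 1451, 45, 26747)
    assert (total.pct_up, total.pct_down, total.pct_ns) == (5.14, 0.16, 94.70)
    assert (rows["Level 2"].pct_up, rows["Level 2"].pct_down, rows["Level 2"].pct_ns) \
        == (7.04, 0.22, 92.74)


def test_level_table_counts_from_levels_and_degs():
    levels = {"g1": 1, "g2": 2, "g3": 2, "g4": 3}
    degs = [rec("g2", 2.0, "up"), rec("g3"), rec("g4", -2.0, "down")]
    rows = {r.label: r for r in level_table(levels, degs)}
    assert (rows["Level 2"].n_total, rows["Level 2"].n_up) == (2, 1)
    assert (rows["Level 3"].n_total, rows["Level 3"].n_down) == (1, 1)
    assert rows["Total"].n_total == 3  # level-1 genes excluded


# -- enrichment --------------------------------------------------------------

def brute_force_upper_tail(universe_n, term_n, draw_n, overlap):
    """P(X >= overlap) by enumeration over all subsets of the universe."""
    universe = list(range(universe_n))
    term = set(universe[:term_n])
    hits = total = 0
    for subset in combinations(universe, draw_n):
        total += 1
        hits += len(term & set(subset)) >= overlap
    return hits / total


def test_enrichment_exact_small_case():
    universe = [f"g{i}" for i in range(10)]
    term = {"t": set(universe[:5])}
    res = enrich_hypergeometric(set(universe[:3]), term, universe)
    assert res.loc[0, "pvalue"] == pytest.approx(10 / 120)


def test_enrichment_matches_brute_force_enumeration():
    rng = np.random.default_rng(51)
    for _ in range(20):
        n_u = int(rng.integers(4, 12))
        n_t = int(rng.integers(1, n_u + 1))
        n_d = int(rng.integers(1, n_u + 1))
        universe = [f"g{i}" for i in range(n_u)]
        term = set(universe[:n_t])
        degs = set(rng.choice(universe, size=n_d, replace=False))
        res = enrich_hypergeometric(degs, {"t": term}, universe)
        expected = brute_force_upper_tail(n_u, n_t, n_d, len(term & degs))
        assert res.loc[0, "pvalue"] == pytest.approx(expected)


def test_zero_overlap_and_full_term_are_certain_events():
    universe = [f"g{i}" for i in range(8)]
    res = enrich_hypergeometric({"g7"}, {"none": set(universe[:3]) - {"g7"},
                                         "all": set(universe)}, universe)
    assert (res["pvalue"] == 1.0).all()


def test_empty_universe_rejected():
    with pytest.raises(ValueError, match="universe"):
        enrich_hypergeometric(set(), {"t": {"a"}}, set())
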