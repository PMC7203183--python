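"""Parsers, canonical masking, loop nomenclature, featurization, folding."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minirings.structure_features import (
    CANONICAL_PAIRS,
    FeatureVector,
    SecondaryStructure,
    apply_canonical_mask,
    classify_loops,
    extract_features,
    fold,
    parse_ct,
    parse_dot_bracket,
    parse_structure,
    to_dot_bracket,
    write_ct,
)

rna = st.text(alphabet="ACGU", min_size=1, max_size=40)


# -- parsing ----------------------------------------------------------------


def test_parse_dot_bracket_canonical_hairpin():
    s = parse_dot_bracket("GGGAAACCC", "(((...)))")
    assert s.pairs == frozenset({(0, 8), (1, 7), (2, 6)})


@pytest.mark.parametrize("db", ["((.)", "(()", ".)(", "(((...))"])
def test_unbalanced_dot_bracket_raises(db):
    with pytest.raises(ValueError, match="unbalanced"):
        parse_dot_bracket("A" * len(db), db)


def test_ct_round_trip_equals_dot_bracket_parse():
    db = parse_dot_bracket("GGGGAAAACCCC", "((((....))))")
    again = parse_ct(write_ct(db, title="hairpin"))
    assert again.pairs == db.pairs and again.sequence == db.sequence
    # parse_structure dispatches on format
    assert parse_structure(write_ct(db)).pairs == db.pairs
    assert parse_structure("((((....))))", "GGGGAAAACCCC").pairs == db.pairs


def test_ct_partner_asymmetry_raises_with_line():
    text = "3 bad\n1 G 0 2 3 1\n2 A 1 3 0 2\n3 C 2 0 2 3\n"
    with pytest.raises(ValueError, match="asymmetric"):
        parse_ct(text)


def test_pseudoknot_and_double_pairing_rejected():
    with pytest.raises(ValueError, match="crossing"):
        SecondaryStructure("GGGGAAAACCCC", frozenset({(0, 6), (3, 9)}))
    with pytest.raises(ValueError, match="more than one pair"):
        SecondaryStructure("GGGGAAAACCCC", frozenset({(0, 6), (0, 9)}))


@settings(deadline=None, derandomize=True)
@given(rna)
def test_fold_write_parse_round_trip(seq):
    s = fold(seq)
    assert parse_ct(write_ct(s)).pairs == s.pairs
    assert parse_dot_bracket(seq, to_dot_bracket(s)).pairs == s.pairs


# -- canonical mask ---------------------------------------------------------


def test_canonical_mask_drops_noncanonical_pairs():
    # nested drawn pairs: G-U (kept), C-G (kept), C-A (dropped)
    s = SecondaryStructure("GCCAAAAAGU", frozenset({(0, 9), (1, 8), (2, 7)}))
    masked = apply_canonical_mask(s)
    kept = {(s.sequence[i], s.sequence[j]) for i, j in masked.pairs}
    assert kept <= CANONICAL_PAIRS
    assert (0, 9) in masked.pairs      # G-U wobble included
    assert (1, 8) in masked.pairs      # Watson-Crick
    assert (2, 7) not in masked.pairs  # C-A excluded, both positions unpaired


def test_canonical_mask_is_identity_on_canonical_structures():
    s = fold("GGGGAAAACCCC")
    assert apply_canonical_mask(s).pairs == s.pairs


# -- loop classification ----------------------------------------------------


def test_hairpin_loop_positions_are_eloop():
    s = parse_dot_bracket("GGGAAACCC", "(((...)))")
    labels = classify_loops(s)
    assert labels.count("eloop") == 3 and labels.count("other_unpaired") == 0


def test_fully_unpaired_sequence_has_no_eloop():
    s = SecondaryStructure("ACGUACGU", frozenset())
    labels = classify_loops(s)
    assert labels.count("eloop") == 0 and labels.count("other_unpaired") == 8


def test_bulges_and_dangles_are_other_unpaired():
    #  5' dangle, bulge inside stem, hairpin loop, 3' dangle
    seq = "AGGCGAAAGCCA"
    db = ".((.(...)))."
    labels = classify_loops(parse_dot_bracket(seq, db))
    assert labels[0] == "other_unpaired" and labels[-1] == "other_unpaired"
    assert labels[3] == "other_unpaired"          # bulge between stacked pairs
    assert labels[5:8] == ["eloop"] * 3           # the hairpin loop proper


# -- features ---------------------------------------------------------------


def test_feature_arithmetic_from_worked_counts():
    fv = FeatureVector.from_counts(n_total=101, n_paired=60, n_eloop=4, n_gc_stem=52, n_gc_loop=22)
    assert [round(v, 1) for v in fv.values] == [59.4, 9.8, 86.7, 53.7]
    assert fv.counts["n_unpaired"] == 41 and not fv.is_degenerate


def test_features_of_perfect_hairpin():
    fv = extract_features(fold("GGGGAAAACCCC"))
    assert [round(v, 1) for v in fv.values] == [66.7, 100.0, 100.0, 0.0]


def test_zero_denominator_sentinels():
    fv = extract_features(SecondaryStructure("AAAAAAA", frozenset()))
    assert fv.pct_stem == 0.0 and fv.degenerate_stem and not fv.degenerate_loop
    full = FeatureVector.from_counts(n_total=8, n_paired=8, n_eloop=0, n_gc_stem=8, n_gc_loop=0)
    assert full.degenerate_loop and full.pct_eloop == 0.0


def test_features_invariant_to_pair_listing_order():
    seq = "GGCGAAAGCC"
    pairs = [(0, 9), (1, 8), (2, 7)]
    a = extract_features(SecondaryStructure(seq, frozenset(pairs)))
    b = extract_features(SecondaryStructure(seq, frozenset(reversed(pairs))))
    assert a.values == b.values


@settings(deadline=None, derandomize=True)
@given(rna)
def test_stem_percentage_complement_identity(seq):
    fv = extract_features(fold(seq))
    n = fv.counts
    assert fv.pct_stem + 100.0 * n["n_unpaired"] / n["n_total"] == pytest.approx(100.0)


# -- folding ----------------------------------------------------------------


def _brute_force_max_pairs(seq, i=None, j=None):
    """Exhaustive recursion over all nested canonical structures (oracle)."""
    if i is None:
        i, j = 0, len(seq) - 1
    if i >= j:
        return 0
    best = _brute_force_max_pairs(seq, i + 1, j)
    for k in range(i + 4, j + 1):
        if (seq[i], seq[k]) in CANONICAL_PAIRS:
            inner = _brute_force_max_pairs(seq, i + 1, k - 1)
            outer = _brute_force_max_pairs(seq, k + 1, j) if k + 1 <= j else 0
            best = max(best, 1 + inner + outer)
    return best


def test_builtin_fold_worked_examples():
    assert len(fold("GGGGAAAACCCC").pairs) == 4
    assert len(fold("AAAAAAA").pairs) == 0


def test_builtin_fold_matches_brute_force_small():
    rng = random.Random(7)
    for _ in range(100):
        n = rng.randint(1, 12)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        assert len(fold(seq).pairs) == _brute_force_max_pairs(seq)


@settings(deadline=None, derandomize=True)
@given(rna)
def test_builtin_fold_structural_invariants(seq):
    s = fold(seq)
    partner = s.partner()
    for i, j in s.pairs:
        assert (seq[i], seq[j]) in CANONICAL_PAIRS
        assert j - i - 1 >= 3  # minimum hairpin
    assert sum(p is not None for p in partner) == 2 * len(s.pairs)


def test_fold_determinism_and_5prime_preference():
    a, b = fold("GCGCAAAAGCGC"), fold("GCGCAAAAGCGC")
    assert a.pairs == b.pairs
    # 5'-most traceback: position 0 pairs with the smallest admissible partner
    s = fold("GAAAACAAAAUC")
    if s.pairs:
        i0 = min(i for i, _ in s.pairs)
        assert i0 == min(i for p in s.pairs for i in p)


def test_external_backend_runs_and_is_nested():
    s = fold("GGGGAAAACCCC", backend="external_mfe")
    assert s.provenance.startswith("external_mfe")
    assert len(s.pairs) >= 3  # a stable hairpin by any thermodynamic model


def test_fold_rejects_bad_input():
    with pytest.raises(ValueError, match="position 2"):
        fold("AXGU")
    with pytest.raises(ValueError, match="empty"):
        fold("")
    with pytest.raises(ValueError, match="backend"):
        fold("ACGU", backend="centroid")
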