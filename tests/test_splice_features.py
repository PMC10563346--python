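import math

import numpy as np
import pytest

import pdivas as P
from pdivas.splice_features import (
    DEFAULT_MES_CAP, MotifModel, PWMSiteScorer, SpliceGainFeatures,
    assemble_features, constraint_lookup, default_motif_model,
    map_alt_to_ref, masked_gain_features, mes_score, mes_variant_feature,
)
from pdivas.variant_io import ConstraintTrack, Variant


def make_stub(stub_scorer_factory, ref_seq, alt_seq, ref_acc, ref_don,
              alt_acc, alt_don):
    return stub_scorer_factory({ref_seq: (ref_acc, ref_don),
                                alt_seq: (alt_acc, alt_don)})


def test_noop_variant_gives_zero_deltas(stub_scorer_factory):
    seq = "ACGTACGTACGT"
    acc = np.linspace(0, 0.6, len(seq))
    don = np.linspace(0.5, 0, len(seq))
    scorer = stub_scorer_factory({seq: (acc, don)})
    g = masked_gain_features(scorer, seq, seq, var_offset=6, d=300)
    assert g.acc_delta_gain == 0.0 and g.don_delta_gain == 0.0
    assert g.acc_raw_gain == pytest.approx(acc.max())
    assert g.don_raw_gain == pytest.approx(don.max())


def test_delta_subtraction_and_mask(stub_scorer_factory):
    ref = "AAAAACAAAA"
    alt = "AAAAATAAAA"
    zeros = np.zeros(10)
    ref_don = zeros.copy()
    ref_don[7] = 0.1
    alt_don = zeros.copy()
    alt_don[7] = 0.9
    scorer = make_stub(stub_scorer_factory, ref, alt, zeros, ref_don,
                       zeros, alt_don)
    g = masked_gain_features(scorer, ref, alt, var_offset=5, d=300)
    assert g.don_delta_gain == pytest.approx(0.8)
    assert g.don_raw_gain == pytest.approx(0.9)
    # same scores, but position 7 is an annotated donor: delta masked to 0
    g2 = masked_gain_features(scorer, ref, alt, var_offset=5,
                              annotated_sites=[(7, "donor")], d=300)
    assert g2.don_delta_gain == 0.0
    assert g2.don_raw_gain == pytest.approx(0.9)  # raw invariant to the mask
    # mask matches by kind: an annotated acceptor there does not mask donor
    g3 = masked_gain_features(scorer, ref, alt, var_offset=5,
                              annotated_sites=[(7, "acceptor")], d=300)
    assert g3.don_delta_gain == pytest.approx(0.8)


def test_aggregate_definitions():
    g = SpliceGainFeatures(acc_delta_gain=0.3, don_delta_gain=0.7,
                           acc_raw_gain=0.4, don_raw_gain=0.8)
    assert g.delta_gain_max == pytest.approx(0.7)
    assert g.delta_gain_mean == pytest.approx(0.5)
    assert g.raw_gain_mean == pytest.approx(0.6)
    assert g.raw_gain_max == pytest.approx(0.8)


def test_masking_monotonicity_property(stub_scorer_factory):
    """Adding annotated sites never increases delta_gain_max or mean."""
    rng = np.random.default_rng(42)
    n = 60
    seq_r = "A" * n
    seq_a = "C" + "A" * (n - 1)
    for _ in range(25):
        scorer = make_stub(stub_scorer_factory, seq_r, seq_a,
                           rng.random(n), rng.random(n),
                           rng.random(n), rng.random(n))
        sites = [(int(p), k) for p, k in zip(
            rng.integers(0, n, 8),
            rng.choice(["donor", "acceptor"], 8))]
        prev_max = prev_mean = np.inf
        for m in range(0, 9, 2):
            g = masked_gain_features(scorer, seq_r, seq_a, var_offset=n // 2,
                                     annotated_sites=sites[:m], d=300)
            assert g.delta_gain_max <= prev_max + 1e-12
            assert g.delta_gain_mean <= prev_mean + 1e-12
            prev_max, prev_mean = g.delta_gain_max, g.delta_gain_mean


def test_insertion_frame_shift_against_mapping_oracle(stub_scorer_factory):
    """Deltas left of an insertion match the unshifted subtraction; positions
    right of it match the shifted one (brute-force alignment oracle)."""
    rng = np.random.default_rng(7)
    n, ins = 40, 3
    var_off = 20
    seq_r = "A" * n
    seq_a = "A" * var_off + "C" * (1 + ins) + "A" * (n - var_off - 1)
    ref_don = rng.random(n)
    alt_don = rng.random(n + ins)
    zeros_r, zeros_a = np.zeros(n), np.zeros(n + ins)
    scorer = make_stub(stub_scorer_factory, seq_r, seq_a,
                       zeros_r, ref_don, zeros_a, alt_don)
    # brute-force oracle: explicit alignment map of alt positions to ref
    expected = []
    for p in range(n + ins):
        if p <= var_off:
            ref_score = ref_don[p]
        elif p <= var_off + ins:
            ref_score = 0.0  # inserted base, no ref counterpart
        else:
            ref_score = ref_don[p - ins]
        expected.append(alt_don[p] - ref_score)
    expected_gain = max(0.0, max(expected))
    g = masked_gain_features(scorer, seq_r, seq_a, var_offset=var_off,
                             ref_len=1, alt_len=1 + ins, d=300)
    assert g.don_delta_gain == pytest.approx(expected_gain, abs=1e-12)


def test_map_alt_to_ref_deletion():
    # deletion ref_len=3, alt_len=1 anchored at 10
    assert map_alt_to_ref(9, 10, 3, 1) == 9
    assert map_alt_to_ref(10, 10, 3, 1) == 10
    assert map_alt_to_ref(11, 10, 3, 1) == 13  # first base after the deletion


def test_window_shorter_than_variant_errors(stub_scorer_factory):
    scorer = make_stub(stub_scorer_factory, "ACG", "ACG",
                       np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))
    with pytest.raises(ValueError):
        masked_gain_features(scorer, "ACG", "ACG", var_offset=2, ref_len=5)


# ---------------------------------------------------------------------------
# Motif scoring


def test_mes_score_background_model_is_zero():
    bg = np.full(4, 0.25)
    model = MotifModel(donor=np.full((9, 4), 0.25),
                       acceptor=np.full((23, 4), 0.25), background=bg)
    assert mes_score("CAGGTAAGT", model, "donor") == pytest.approx(0.0)
    assert mes_score("A" * 23, model, "acceptor") == pytest.approx(0.0)


def test_mes_score_consensus_equals_hand_sum():
    model = default_motif_model()
    window = "CAGGTAAGT"
    by_hand = 0.0
    for i, base in enumerate(window):
        p = model.donor[i, "ACGT".index(base)]
        by_hand += math.log2(p / 0.25)
    assert mes_score(window, model, "donor") == pytest.approx(by_hand)


def test_mes_score_input_validation():
    model = default_motif_model()
    with pytest.raises(ValueError):
        mes_score("CAGGTAAG", model, "donor")  # length 8
    with pytest.raises(ValueError):
        mes_score("CAGGTAAGN", model, "donor")


def _mes_oracle(ref_seq, alt_seq, var_offset, ref_len, alt_len, model):
    """Exhaustive window enumeration with plain loops."""
    def window_scores(seq, span_lo, span_hi, kind, w):
        best = -np.inf
        for start in range(len(seq) - w + 1):
            if start + w <= span_lo or start >= span_hi:
                continue  # window does not overlap the variant
            window = seq[start:start + w]
            bits = 0.0
            for i, base in enumerate(window):
                bits += math.log2(model.matrix(kind)[i, "ACGT".index(base)]
                                  / model.background["ACGT".index(base)])
            best = max(best, bits)
        return best

    feature = 0.0
    for kind, w in (("donor", 9), ("acceptor", 23)):
        r = window_scores(ref_seq, var_offset, var_offset + ref_len, kind, w)
        a = window_scores(alt_seq, var_offset, var_offset + alt_len, kind, w)
        if a > r + 1e-9 and a > 1e-9:  # same tie tolerance as the contract
            feature = max(feature, min(a, model.cap) / model.cap)
    return feature


def test_mes_variant_feature_identity_and_cap():
    model = default_motif_model()
    seq = "ACGT" * 15
    assert mes_variant_feature(seq, seq, 30, model=model) == 0.0


def test_mes_variant_feature_created_donor_matches_oracle():
    """An SNV creating the only strong donor in a toy intron scores equal to
    the exhaustive enumeration over all 9 overlapping windows."""
    model = default_motif_model()
    rng = np.random.default_rng(11)
    hits = 0
    for _ in range(300):
        n = int(rng.integers(30, 61))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        off = int(rng.integers(12, n - 12))
        base = seq[off]
        alt_base = "ACGT"[(("ACGT".index(base)) + 1) % 4]
        alt = seq[:off] + alt_base + seq[off + 1:]
        got = mes_variant_feature(seq, alt, off, model=model)
        want = _mes_oracle(seq, alt, off, 1, 1, model)
        assert got == pytest.approx(want, abs=1e-12)
        hits += got > 0
    assert hits > 0  # some random substitutions do create motif gains


def test_mes_variant_feature_planted_consensus():
    model = default_motif_model()
    flank = "ATATATATATAT"
    broken = flank + "CAGGCAAGT" + flank  # +2 GT broken
    fixed = flank + "CAGGTAAGT" + flank
    off = len(flank) + 4
    feat = mes_variant_feature(broken, fixed, off, model=model)
    a = mes_score("CAGGTAAGT", model, "donor")
    assert feat == pytest.approx(min(a, model.cap) / model.cap)
    assert feat > 0.9


# ---------------------------------------------------------------------------
# Constraint and assembly


def test_constraint_lookup_boundaries():
    track = ConstraintTrack([("chr1", 100, 200, 0.9)])
    inside = Variant("chr1", 150, "A", "G")
    assert constraint_lookup(inside, track) == 0.9
    # 1-based 201 is 0-based 200 == half-open end -> missing
    boundary = Variant("chr1", 201, "A", "G")
    assert constraint_lookup(boundary, track) is None
    uncovered = Variant("chr1", 500, "A", "G")
    assert constraint_lookup(uncovered, track) is None


def test_assemble_features_completeness():
    g = SpliceGainFeatures(0.3, 0.7, 0.4, 0.8)
    v = Variant("chr1", 150, "A", "G")
    fv = assemble_features(v, g, mes=0.5, constraint=0.9)
    assert fv.is_complete
    assert fv.spliceai_del_gain_mean == pytest.approx(0.5)
    assert fv.spliceai_del_gain_max == pytest.approx(0.7)
    assert fv.spliceai_raw_gain_mean == pytest.approx(0.6)
    incomplete = assemble_features(v, g, mes=0.5, constraint=None)
    assert not incomplete.is_complete
    assert np.isnan(incomplete.to_array()[3])
    zeroed = assemble_features(v, SpliceGainFeatures(0, 0, 0, 0), 0.0, 0.0)
    assert zeroed.is_complete
    maxed = assemble_features(v, g, 0.5, 0.9, raw_gain_agg="max")
    assert maxed.spliceai_raw_gain_mean == pytest.approx(0.8)


def test_all_features_in_unit_interval(pipeline, labeled_features):
    _, X, _ = labeled_features
    arr = X.to_numpy()
    assert np.nanmin(arr) >= 0.0 and np.nanmax(arr) <= 1.0


def test_pwm_scorer_marks_planted_junctions(reference, pipeline):
    """The PWM scorer gives its highest donor scores at annotated junctions."""
    t = next(tr for tr in reference.transcripts if tr.strand == "+")
    seq = reference.genome[t.chrom]
    scorer = PWMSiteScorer()
    lo, hi = t.span
    acc, don = scorer.score(seq[lo - 1:hi])
    for pos, kind in t.splice_sites():
        off = pos - lo
        if kind == "donor":
            assert don[off] > 0.8
        else:
            assert acc[off] > 0.6
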