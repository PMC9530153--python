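import numpy as np
import pytest

from scramblekit.contact import (ContactMatrix, ROISpec,
                                 default_roi, events_to_bin_pairs,
                                 moving_average_correlation,
                                 read_contact_tsv, roi_bait_profile,
                                 roi_event_profile, synth_contact_matrix,
                                 write_contact_tsv)
from scramblekit.refmodel import random_reference
from scramblekit.scramble import RearrangementEvent, SimConfig, \
    simulate_strain


def test_matrix_is_symmetric_and_validated():
    cm = synth_contact_matrix(20, "linear", -1.0, noise_sd=0.4, seed=1)
    assert np.allclose(cm.matrix, cm.matrix.T)
    with pytest.raises(ValueError):
        ContactMatrix(np.arange(9.0).reshape(3, 3))


def test_noise_free_matrix_follows_exact_decay():
    cm = synth_contact_matrix(15, "linear", -1.0, noise_sd=0.0, seed=0)
    m = cm.matrix
    # off-diagonal entries proportional to 1/distance
    assert m[0, 2] / m[0, 4] == pytest.approx(2.0)
    assert m[3, 9] / m[3, 6] == pytest.approx(0.5)


def test_circular_end_bins_touch_more_than_linear():
    lin = synth_contact_matrix(30, "linear", -1.0, 0.0, seed=2)
    cir = synth_contact_matrix(30, "circular", -1.0, 0.0, seed=2)
    assert cir.matrix[0, 29] > lin.matrix[0, 29]
    roi = default_roi(30)
    w1 = list(range(*roi.window1))
    w2 = list(range(*roi.window2))
    assert (cir.matrix[np.ix_(w1, w2)] > lin.matrix[np.ix_(w1, w2)]).all()


def test_noise_free_circular_matrix_is_circulant():
    cm = synth_contact_matrix(24, "circular", -1.2, 0.0, seed=3)
    rolled = np.roll(np.roll(cm.matrix, 5, axis=0), 5, axis=1)
    assert np.allclose(rolled, cm.matrix)


def test_matrix_tsv_round_trip(tmp_path):
    cm = synth_contact_matrix(12, "circular", -1.0, 0.3, seed=4)
    dense, coo = tmp_path / "m.tsv", tmp_path / "m.coo.tsv"
    write_contact_tsv(cm, dense, dense=True)
    write_contact_tsv(cm, coo, dense=False)
    back_d = read_contact_tsv(dense, topology="circular")
    back_c = read_contact_tsv(coo, topology="circular")
    assert np.allclose(back_d.matrix, cm.matrix)
    assert np.allclose(back_c.matrix, cm.matrix)


def test_window_count_arithmetic():
    cm = synth_contact_matrix(10, "linear", -1.0, 0.0, seed=5)
    pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
    counts = {p: 1 for p in pairs[:25]}
    res = moving_average_correlation(counts, cm, window=10, shift=3)
    assert res.n_windows == (25 - 10) // 3 + 1


def test_perfectly_proportional_events_give_r_one():
    cm = synth_contact_matrix(12, "linear", -1.0, 0.2, seed=6)
    counts = {(i, j): cm.matrix[i, j] * 10
              for i in range(12) for j in range(i + 1, 12)}
    res = moving_average_correlation(counts, cm)
    assert res.r == pytest.approx(1.0, abs=1e-9)
    assert res.p < 1e-6


def test_result_is_input_order_invariant():
    cm = synth_contact_matrix(14, "linear", -1.0, 0.3, seed=7)
    rng = np.random.default_rng(8)
    items = [((i, j), int(rng.integers(0, 5)))
             for i in range(14) for j in range(i + 1, 14)]
    res_a = moving_average_correlation(dict(items), cm)
    res_b = moving_average_correlation(dict(reversed(items)), cm)
    assert res_a.r == res_b.r and res_a.p == res_b.p


def test_too_few_usable_pairs_is_an_error():
    cm = synth_contact_matrix(10, "linear", -1.0, 0.0, seed=9)
    with pytest.raises(ValueError, match="window"):
        moving_average_correlation({(0, 1): 3}, cm, window=10)


def test_roi_validation():
    with pytest.raises(ValueError):
        ROISpec((0, 3), (2, 6)).validate(10)       # overlap
    with pytest.raises(ValueError):
        ROISpec((0, 3), (8, 12)).validate(10)      # outside


def test_roi_profiles():
    ref = random_reference(n_segments=30, mean_segment_len=3400,
                           topology="circular", seed=13)
    n_bins = (len(ref.sequence) + 9999) // 10000
    left_bait = ROISpec((0, 1), (1, 2))      # one subtelomeric bait region
    lin = synth_contact_matrix(n_bins, "linear", -1.0, 0.0, seed=10)
    cir = synth_contact_matrix(n_bins, "circular", -1.0, 0.0, seed=10)
    p_lin = roi_bait_profile(lin, left_bait)
    p_cir = roi_bait_profile(cir, left_bait)
    # the distal arm regains contact with the bait on the ring, with the
    # gap growing toward the far chromosome end
    gap = (p_cir["contact"] / p_lin["contact"]).to_numpy()
    third = len(gap) // 3
    assert (gap[-third:] > 1.0).all()
    assert gap[-1] > gap[-third]
    roi = default_roi(n_bins, roi_bp=10_000)
    prof = roi_event_profile([], ref, roi, n_bins=n_bins)
    assert (prof["events"] == 0).all()
    ev = RearrangementEvent("inversion", (2,), (1, 2))
    prof2 = roi_event_profile([ev], ref, roi, n_bins=n_bins)
    assert prof2["events"].sum() >= 0     # loci may or may not touch ROI


def test_contact_biased_sampling_prefers_strong_bin_pairs():
    """With a contact matrix dominated by one off-diagonal bin pair, most
    sampled locus pairs fall into that pair."""
    ref = random_reference(n_segments=20, mean_segment_len=2500, seed=12)
    n_bins = (len(ref.sequence) + 9999) // 10000
    m = np.ones((n_bins, n_bins))
    m[1, 3] = m[3, 1] = 4000.0
    cm = ContactMatrix(m, 10_000, "linear")
    events = []
    for seed in range(300):
        t = simulate_strain(ref, SimConfig(
            n_events=1, poisson=False, type_probs=(0, 1, 0),
            ploidy="diploid", contact_bias=cm, seed=seed))
        events.extend(t.events)
    counts = events_to_bin_pairs(events, ref, 10_000, n_bins)
    assert counts.get((1, 3), 0) / len(events) > 0.5
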