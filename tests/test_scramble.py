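import numpy as np
import pytest

from scramblekit.refmodel import random_reference
from scramblekit.scramble import (SignedStructure, SimConfig,
                                  apply_event, diploid_genome,
                                  simulate_strain, viability_check)


@pytest.mark.parametrize("order,loci,etype,expected", [
    ((1, 2, 3, 4), (1, 2), "deletion", (1, 3, 4)),
    ((1, 2, 3, 4), (1, 3), "inversion", (1, -3, -2, 4)),
    ((1, 2, 3), (1, 2), "duplication", (1, 2, 2, 3)),
    ((1, -2, 3, 4), (1, 3), "inversion", (1, -3, 2, 4)),
])
def test_apply_event_linear(order, loci, etype, expected):
    st = SignedStructure(order, "linear")
    assert apply_event(st, *loci, etype).order == expected


def test_apply_event_circular_wraparound_arc():
    st = SignedStructure((1, 2, 3, 4), "circular")
    # arc from locus 3 wrapping through the origin to locus 1 = (4,)
    assert apply_event(st, 3, 0, "deletion").order == (1, 2, 3)
    assert apply_event(st, 3, 1, "deletion").order == (2, 3)


@pytest.mark.parametrize("loci", [(2, 2), (0, 5)])
def test_apply_event_bad_loci(loci):
    st = SignedStructure((1, 2, 3, 4), "linear")
    with pytest.raises(ValueError):
        apply_event(st, *loci, "deletion")


def test_cannot_delete_whole_ring():
    st = SignedStructure((1,), "circular")
    with pytest.raises(ValueError):
        apply_event(st, 0, 0, "deletion")


def test_viability_rules(small_ref):
    ref = small_ref
    full = SignedStructure.reference(ref)
    assert viability_check(full, ref, "haploid")
    ess = ref.essential_ids()[0]
    removed = SignedStructure(
        tuple(s for s in full.order if s != ess), "linear")
    assert not viability_check(removed, ref, "haploid")
    assert viability_check(removed, ref, "diploid")
    cen = ref.centromere_id()
    no_cen = SignedStructure(
        tuple(s for s in full.order if s != cen), "linear")
    assert not viability_check(no_cen, ref, "diploid")
    two_cen = SignedStructure(full.order + (cen,), "linear")
    assert not viability_check(two_cen, ref, "haploid")


def test_zero_events_returns_reference(small_ref):
    truth = simulate_strain(small_ref,
                            SimConfig(n_events=0, poisson=False, seed=1))
    assert truth.structure.order == SignedStructure.reference(
        small_ref).order
    assert truth.events == []


def test_simulation_is_seed_deterministic(small_ref):
    cfg = SimConfig(n_events=5.0, poisson=True, seed=42)
    t1 = simulate_strain(small_ref, cfg)
    t2 = simulate_strain(small_ref, cfg)
    assert t1.structure.order == t2.structure.order
    assert t1.events == t2.events
    assert np.array_equal(t1.copy_numbers, t2.copy_numbers)


@pytest.mark.parametrize("seed", range(8))
def test_event_replay_reproduces_structure(small_ref, seed):
    """Replaying the logged (type, structure-locus) history on the
    reference structure must land on the recorded final structure and copy
    numbers."""
    truth = simulate_strain(small_ref, SimConfig(n_events=5, poisson=False,
                                                 seed=100 + seed))
    st = SignedStructure.reference(small_ref)
    for ev in truth.events:
        st = apply_event(st, *ev.structure_loci, ev.type)
    assert st.order == truth.structure.order
    assert np.array_equal(st.copy_numbers(small_ref.n_segments),
                          truth.copy_numbers)


def test_haploid_essentials_never_deleted():
    """With every interior segment essential except one, no surviving
    haploid strain ever loses an essential segment, yet the free segment is
    deletable."""
    ref = random_reference(n_segments=9, mean_segment_len=400, seed=5,
                           essential_segments=(2, 3, 5, 6, 8),
                           centromere_segment=4)
    free_deleted = 0
    for seed in range(200):
        truth = simulate_strain(
            ref, SimConfig(n_events=2, poisson=False, seed=seed))
        cn = truth.copy_numbers
        for e in ref.essential_ids():
            assert cn[e - 1] >= 1
        assert cn[ref.centromere_id() - 1] == 1
        free_deleted += cn[6] == 0          # the only deletable segment
    assert free_deleted > 0


def test_circular_equivalence_and_normalization():
    a = SignedStructure((1, -3, 4), "circular")
    rotated = SignedStructure((-3, 4, 1), "circular")
    reflected = SignedStructure((3, -1, -4), "circular")
    assert a.equivalent(rotated)
    assert a.equivalent(reflected)
    assert not a.equivalent(SignedStructure((1, 3, 4), "circular"))
    norm = reflected.orientation_normalized()
    assert sum(s < 0 for s in norm.order) == 1


def test_diploid_genome_properties(small_ref):
    truth = simulate_strain(small_ref, SimConfig(n_events=3, poisson=False,
                                                 seed=9))
    syn, native, snps = diploid_genome(small_ref, truth.structure,
                                       snp_density=0.01, seed=3)
    assert small_ref.site_seq not in native
    assert syn == truth.structure.sequence(small_ref)
    # substitution count ~ Binomial(n_eligible, density) within 3 sigma
    n = len(native)
    mean, sd = n * 0.01, np.sqrt(n * 0.01 * 0.99)
    assert abs(len(snps) - mean) < 3 * sd + 80   # flank-exclusion slack
    with pytest.raises(ValueError):
        diploid_genome(small_ref, truth.structure, snp_density=0.0)
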