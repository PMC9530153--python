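import numpy as np
import pandas as pd
import pytest

from scramblekit.reads import GenomeSource, ReadSimConfig, emit_reads
from scramblekit.reconstruct import (ReconstructionError,
                                     build_segment_graph, classify_events,
                                     estimate_copy_number,
                                     reconstruct_structure, reconstructed_bp,
                                     retention_rate, segment_depth)
from scramblekit.scramble import (SignedStructure, SimConfig,
                                  diploid_genome, simulate_strain)


def _junc_df(ref, juncs, labels=None):
    rows = []
    for k, ((sa, ea), (sb, eb)) in enumerate(juncs):
        rows.append({"chrom": ref.chrom_id, "segA": sa, "endA": ea,
                     "segB": sb, "endB": eb, "support": 20,
                     "label": labels[k] if labels else "novel"})
    df = pd.DataFrame(rows)
    parental = ref.parental_junctions()
    df["label"] = [
        "parental" if tuple(sorted([(int(r.segA), r.endA),
                                    (int(r.segB), r.endB)])) in parental
        else "novel" for r in df.itertuples()]
    return df


# ---------------------------------------------------------------------------
# depth & copy number
# ---------------------------------------------------------------------------

def test_uniform_depth_recovered(small_ref):
    pairs = emit_reads([GenomeSource("wt", small_ref.sequence)],
                       ReadSimConfig(mean_depth=100, error_rate=0.0,
                                     seed=1))
    depths = segment_depth(pairs, small_ref)
    assert np.all(np.abs(depths - 100) / 100 < 0.10)


def test_deleted_segment_depth_near_zero(small_ref):
    st = SignedStructure(tuple(s for s in range(1, 13) if s != 5),
                         "linear")
    pairs = emit_reads([GenomeSource("mut", st.sequence(small_ref))],
                       ReadSimConfig(mean_depth=80, error_rate=0.0, seed=2))
    depths = segment_depth(pairs, small_ref)
    assert depths[4] < 5
    assert depths[3] > 50


def test_diploid_homolog_resolved_depth_is_half_total(small_ref):
    st = SignedStructure.reference(small_ref)
    syn, native, _ = diploid_genome(small_ref, st, snp_density=0.01, seed=3)
    pairs = emit_reads([GenomeSource("syn", syn),
                        GenomeSource("nat", native)],
                       ReadSimConfig(mean_depth=60, error_rate=0.0, seed=4))
    depths = segment_depth(pairs, small_ref, native_seq=native)
    # each homolog sequenced at ~60x; synthetic share is ~half of the
    # 120x total at the locus
    assert np.all(np.abs(depths - 60) / 60 < 0.15)


@pytest.mark.parametrize("depths,expected", [
    ([100, 3, 101, 99], [1, 0, 1, 1]),
    ([100, 195, 101, 99], [1, 2, 1, 1]),
    ([100, 310, 99, 101], [1, 3, 1, 1]),
])
def test_copy_number_rounding(depths, expected):
    prof = estimate_copy_number(np.array(depths, float), anchor_index=0)
    assert prof.copies.tolist() == expected


def test_copy_number_needs_nonzero_baseline():
    with pytest.raises(ReconstructionError):
        estimate_copy_number(np.zeros(4), anchor_index=0)


def test_mosaic_depth_is_flagged():
    prof = estimate_copy_number(np.array([100.0, 148.0, 101.0, 99.0]),
                                anchor_index=0)
    assert prof.mosaic[1]
    assert not prof.mosaic[0]


# ---------------------------------------------------------------------------
# graph + reconstruction
# ---------------------------------------------------------------------------

def _mini_ref():
    from scramblekit.refmodel import random_reference
    return random_reference(n_segments=4, mean_segment_len=400, seed=8)


def test_reference_graph_is_simple_path():
    ref = _mini_ref()
    df = _junc_df(ref, [((1, "R"), (2, "L")), ((2, "R"), (3, "L")),
                        ((3, "R"), (4, "L"))])
    g = build_segment_graph(df, np.ones(4, int))
    assert g.number_of_nodes() == 8
    assert sum(1 for *_e, d in g.edges(data=True)
               if d["kind"] == "segment") == 4
    assert sum(1 for *_e, d in g.edges(data=True)
               if d["kind"] == "junction") == 3


def test_deletion_reconstructs_uniquely():
    ref = _mini_ref()
    df = _junc_df(ref, [((1, "R"), (3, "L")), ((3, "R"), (4, "L"))])
    structures, status, _ = reconstruct_structure(
        df, np.array([1, 0, 1, 1]), ref)
    assert status == "unique"
    assert structures[0].order == (1, 3, 4)


def test_inversion_reconstructs_uniquely():
    ref = _mini_ref()
    df = _junc_df(ref, [((1, "R"), (2, "R")), ((2, "L"), (3, "L")),
                        ((3, "R"), (4, "L"))])
    structures, status, _ = reconstruct_structure(
        df, np.ones(4, int), ref)
    assert status == "unique"
    assert structures[0].order == (1, -2, 3, 4)


def test_tandem_duplication_reconstructs_uniquely():
    ref = _mini_ref()
    df = _junc_df(ref, [((1, "R"), (2, "L")), ((2, "R"), (2, "L")),
                        ((2, "R"), (3, "L")), ((3, "R"), (4, "L"))])
    structures, status, _ = reconstruct_structure(
        df, np.array([1, 2, 1, 1]), ref)
    assert status == "unique"
    assert structures[0].order == (1, 2, 2, 3, 4)


def test_interleaved_repeats_are_reported_ambiguous():
    """Two loops hanging off the same duplicated segment can be traversed
    in either order: both walks must be enumerated and flagged."""
    from scramblekit.refmodel import random_reference
    ref = random_reference(n_segments=5, mean_segment_len=400, seed=9)
    df = _junc_df(ref, [((1, "R"), (2, "L")), ((2, "R"), (3, "L")),
                        ((3, "R"), (2, "L")), ((2, "R"), (4, "L")),
                        ((4, "R"), (2, "L")), ((2, "R"), (5, "L"))])
    structures, status, _ = reconstruct_structure(
        df, np.array([1, 3, 1, 1, 1]), ref)
    assert status == "ambiguous"
    orders = {s.order for s in structures}
    assert (1, 2, 3, 2, 4, 2, 5) in orders
    assert (1, 2, 4, 2, 3, 2, 5) in orders


def test_missing_junction_marks_inconsistent():
    ref = _mini_ref()
    df = _junc_df(ref, [((1, "R"), (2, "L")), ((3, "R"), (4, "L"))])
    structures, status, diag = reconstruct_structure(
        df, np.ones(4, int), ref)
    assert status == "inconsistent"
    assert structures == []
    assert diag["unconnected_ends"]


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def test_classify_deletion_run(small_ref):
    st = SignedStructure(tuple(s for s in range(1, 13)
                               if s not in (2, 3)), "linear")
    events = classify_events(small_ref, structure=st)
    assert len(events) == 1
    ev = events[0]
    assert ev.type == "deletion" and ev.segments == (2, 3)
    assert ev.loci == (1, 3)


def test_classify_inversion_needs_two_novel_junctions(small_ref):
    st = SignedStructure((1, -2, *range(3, 13)), "linear")
    events = classify_events(small_ref, structure=st)
    assert [e.type for e in events] == ["inversion"]
    assert events[0].segments == (2,) and events[0].loci == (1, 2)


def test_classify_tandem_duplication(small_ref):
    st = SignedStructure((1, 2, 2, *range(3, 13)), "linear")
    events = classify_events(small_ref, structure=st)
    assert [e.type for e in events] == ["duplication"]
    assert events[0].segments == (2,)


def test_classify_from_junctions_and_copies(small_ref):
    df = _junc_df(small_ref, [((1, "R"), (2, "R")), ((2, "L"), (3, "L"))])
    events = classify_events(small_ref, junction_df=df,
                             copies=np.ones(12, int))
    assert [e.type for e in events] == ["inversion"]
    assert events[0].segments == (2,)


def test_mixed_orientation_block_flagged_complex(small_ref):
    st = SignedStructure((1, 2, -2, *range(3, 13)), "linear")
    events = classify_events(small_ref, structure=st)
    assert any(e.type == "complex" for e in events)
    assert not any(e.type == "inversion" for e in events)


# ---------------------------------------------------------------------------
# retention + conservation
# ---------------------------------------------------------------------------

def test_retention_rate_exact(uniform_ref):
    assert retention_rate(np.array([1, 1, 1, 1]), uniform_ref) == 100.00
    assert retention_rate(np.array([1, 0, 0, 1]), uniform_ref) == 50.00
    assert retention_rate(np.array([1, 2, 0, 1]), uniform_ref) == 75.00


@pytest.mark.parametrize("seed", range(6))
def test_reconstructed_bp_conservation(small_ref, seed):
    truth = simulate_strain(small_ref, SimConfig(n_events=4, poisson=False,
                                                 seed=500 + seed))
    total = sum(
        small_ref.segment(abs(s)).length_bp for s in truth.structure.order)
    assert reconstructed_bp(truth.copy_numbers, small_ref) == total
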