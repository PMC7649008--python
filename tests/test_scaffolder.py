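"""Junction-resolution engine: ordering, shared labels, cut arithmetic,
gap estimation, rescue branches, containment, and whole-pipeline
invariants on simulated bundles."""

import random
from collections import Counter

import pytest

from mapfuse import fixtures, scaffolder as sc
from mapfuse._util import revcomp
from mapfuse.io_formats import LabelMap, MapAlignment
from tests.conftest import run_pipeline


def mk_align(entry=1, qry=1, anchor=1, qs=1.0, qe=100.0, as_=1.0, ae=100.0,
             orient="forward", conf=10.0, channel=1, pairs=((1, 1),)):
    return MapAlignment(entry, qry, anchor, qs, qe, as_, ae, orient, conf,
                        channel, list(pairs))


# ---------------------------------------------------------------------------
# ordering and shared labels
# ---------------------------------------------------------------------------

def test_order_alignments_by_anchor_start():
    aligns = [mk_align(qry=1, as_=300.0), mk_align(qry=2, as_=100.0),
              mk_align(qry=3, as_=200.0)]
    ordered = sc.order_alignments(aligns, 1)
    assert [a.anchor_start_bp for a in ordered] == [100.0, 200.0, 300.0]


def test_order_alignments_confidence_tiebreak():
    aligns = [mk_align(qry=1, as_=100.0, conf=9.0),
              mk_align(qry=2, as_=100.0, conf=12.0)]
    ordered = sc.order_alignments(aligns, 1)
    assert [a.confidence for a in ordered] == [12.0, 9.0]
    assert sc.order_alignments([aligns[0]], 1) == [aligns[0]]
    assert sc.order_alignments([], 1) == []


def test_shared_labels_intersection_and_order():
    k = mk_align(qry=1, pairs=[(5, 1), (6, 2), (7, 3)])
    n = mk_align(qry=2, pairs=[(7, 1), (8, 2)])
    assert sc.shared_labels(k, n).anchor_site_ids == [7]
    disjoint = mk_align(qry=2, pairs=[(9, 1)])
    assert not sc.shared_labels(k, disjoint)
    same = mk_align(qry=2, pairs=[(5, 4), (6, 5), (7, 6), (8, 7)])
    k4 = mk_align(qry=1, pairs=[(5, 1), (6, 2), (7, 3), (8, 4)])
    assert sc.shared_labels(k4, same).anchor_site_ids == [5, 6, 7, 8]


def test_shared_labels_channel_mismatch_rejected():
    with pytest.raises(ValueError):
        sc.shared_labels(mk_align(channel=1), mk_align(channel=2))


# ---------------------------------------------------------------------------
# Case 1 cut arithmetic
# ---------------------------------------------------------------------------

def _case1_setup(len_k=10_000, len_n=9_000, p_k=8000.0, p_n=1500.0,
                 orient_n="forward"):
    rng = random.Random(0)
    rec_k = sc.ContigRecord(1, "ck", "ck", 1, len_k,
                            "".join(rng.choice("ACGT") for _ in range(len_k)))
    rec_n = sc.ContigRecord(2, "cn", "cn", 1, len_n,
                            "".join(rng.choice("ACGT") for _ in range(len_n)))
    rec_n.orientation = orient_n
    cmap_k = LabelMap(1, float(len_k), {1: [(1, p_k)]})
    cmap_n = LabelMap(2, float(len_n), {1: [(1, p_n)]})
    align_k = mk_align(qry=1, pairs=[(40, 1)])
    align_n = mk_align(qry=2, pairs=[(40, 1)],
                       orient=orient_n)
    shared = sc.SharedLabelSet(1, 2, 1, [40])
    return rec_k, rec_n, shared, align_k, align_n, cmap_k, cmap_n


def test_merge_at_shared_label_forward_lengths():
    """Left keeps 8000, right keeps 9000-1500: fused length 15500."""
    args = _case1_setup()
    dec = sc.merge_at_shared_label(*args)
    assert dec.kind == "fuse_at_label"
    assert dec.cuts == (8000, 1500)
    rec_k, rec_n = args[0], args[1]
    fused = (rec_k.length - dec.removed_left) + (rec_n.length - dec.removed_right)
    assert fused == 15_500


def test_merge_at_shared_label_reverse_right():
    """A reverse-aligned right contig is cut at the mirrored label."""
    args = _case1_setup(orient_n="reverse")
    dec = sc.merge_at_shared_label(*args)
    p_n = dec.cuts[1]
    assert p_n == 9000 - 1500 + 1  # mirror keeps the labelled base
    rec_n = args[1]
    kept = rec_n.length - dec.removed_right
    assert kept == 1500 - 1
    assert rec_n.oriented_seq == revcomp(rec_n.seq)


def test_merge_missing_site_is_data_error():
    args = list(_case1_setup())
    args[5] = LabelMap(1, 10_000.0, {1: []})  # contig map without the site
    with pytest.raises(sc.DataError, match="site"):
        sc.merge_at_shared_label(*args)


# ---------------------------------------------------------------------------
# Case 2: gap estimation and rescue
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sa_n,ea_k,size_k,em_k,sm_n,expected",
    [
        (1_012_000, 1_000_000, 100_000, 95_000, 2_000, 5_000),
        (4_000, 1_000, 100_000, 98_500, 1_400, 100),
        (2_000, 1_000, 100_000, 98_000, 500, -1_500),
    ],
)
def test_estimate_gap_size_substitution(sa_n, ea_k, size_k, em_k, sm_n, expected):
    align_k = mk_align(qry=1, qs=1.0, qe=float(em_k), ae=float(ea_k))
    align_n = mk_align(qry=2, qs=float(sm_n), qe=float(size_k), as_=float(sa_n))
    assert sc.estimate_gap_size(align_k, align_n, size_k) == expected


def test_estimate_gap_size_reverse_mirroring():
    """Mirrored coordinates reproduce the forward-case estimate."""
    # forward: size 10000, last aligned label at 9500 -> d_k = 500
    fwd_k = mk_align(qry=1, qs=100.0, qe=9500.0, ae=50_000.0)
    # same contig stored reverse: native span [501, 9900]
    rev_k = mk_align(qry=1, qs=501.0, qe=9900.0, ae=50_000.0, orient="reverse")
    align_n = mk_align(qry=2, qs=300.0, qe=9_000.0, as_=52_000.0)
    g_fwd = sc.estimate_gap_size(fwd_k, align_n, 10_000)
    g_rev = sc.estimate_gap_size(rev_k, align_n, 10_000)
    assert g_fwd == g_rev == 2_000 - 500 - 300


def test_rescue_above_threshold_emits_gap():
    rec_k = sc.ContigRecord(1, "a", "a", 1, 4, "ACGT")
    rec_n = sc.ContigRecord(2, "b", "b", 1, 4, "ACGT")
    dec = sc.resolve_unlabelled_junction(rec_k, rec_n, 5_000.0, "ACGT", "ACGT",
                                         sc.ScaffoldParams(), 1)
    assert dec.kind == "sized_gap" and dec.emitted_gap == 5_000


def test_rescue_planted_overlap_fuses_without_duplication():
    rng = random.Random(2)
    a = "".join(rng.choice("ACGT") for _ in range(30_000))
    b = a[-6_000:] + "".join(rng.choice("ACGT") for _ in range(24_000))
    rec_k = sc.ContigRecord(1, "a", "a", 1, len(a), a)
    rec_n = sc.ContigRecord(2, "b", "b", 1, len(b), b)
    dec = sc.resolve_unlabelled_junction(rec_k, rec_n, 100.0, a, b,
                                         sc.ScaffoldParams(), 1)
    assert dec.kind == "fuse_by_alignment"
    assert dec.score == 6_000
    assert dec.removed_left + dec.removed_right == 6_000


def test_rescue_unrelated_windows_gets_sentinel_gap():
    rng = random.Random(3)
    a = "".join(rng.choice("ACGT") for _ in range(30_000))
    b = "".join(rng.choice("ACGT") for _ in range(30_000))
    rec_k = sc.ContigRecord(1, "a", "a", 1, len(a), a)
    rec_n = sc.ContigRecord(2, "b", "b", 1, len(b), b)
    dec = sc.resolve_unlabelled_junction(rec_k, rec_n, -200.0, a, b,
                                         sc.ScaffoldParams(), 1)
    assert dec.kind == "sized_gap" and dec.emitted_gap == 13


# ---------------------------------------------------------------------------
# pipeline-level properties
# ---------------------------------------------------------------------------

def test_no_alignments_all_singletons(clean_bundle):
    plans, singles, decisions = sc.build_scaffolds(
        clean_bundle.contigs, clean_bundle.key, clean_bundle.contig_maps,
        clean_bundle.anchor_maps, [])
    assert plans == [] and decisions == []
    assert singles == [e.component_name for e in clean_bundle.key]


def test_unknown_map_id_is_hard_error(clean_bundle):
    rogue = mk_align(qry=99_999)
    with pytest.raises(sc.DataError, match="99999"):
        sc.build_scaffolds(clean_bundle.contigs, clean_bundle.key,
                           clean_bundle.contig_maps, clean_bundle.anchor_maps,
                           [rogue])


def test_decision_census_matches_truth(clean_bundle, clean_result):
    """Every junction class resolves the way the fixture planted it."""
    _, singles, decisions, _, _ = clean_result
    truth = clean_bundle.truth
    by_pair = {(d.left, d.right): d for d in decisions}
    for j in truth.junctions:
        d = by_pair[(j.left, j.right)]
        if j.kind == "gap":
            assert d.kind == "sized_gap"
            assert d.emitted_gap == j.size  # zero noise: exact recovery
        elif j.overlap_class == "labelled":
            assert d.kind == "fuse_at_label"
        elif j.overlap_class == "alignable":
            assert d.kind == "fuse_by_alignment" and d.score > 5000
        else:  # tiny
            assert d.kind == "sized_gap" and d.emitted_gap == 13
    for ct in truth.contained:
        d = by_pair[(ct.host, ct.name)]
        if ct.expect_insert:
            assert d.kind == "containment_insert"
            assert ct.name not in singles
        else:
            assert d.kind == "containment_singleton"
            assert ct.name in singles


def test_noiseless_scaffold_chunks_are_genome_substrings(clean_bundle, clean_result):
    """Byte-exact reconstruction at every fused junction (zero noise)."""
    plans, _, _, _, records = clean_result
    genome = clean_bundle.truth.genome
    for plan in plans:
        seq = records[plan.name]
        for chunk in seq.split("N"):
            if chunk:
                assert chunk in genome


def test_base_conservation_ledger(noisy_bundle, noisy_result):
    """Output length == input length - removed bases + emitted gap bases,
    computed independently from the decision list."""
    _, _, decisions, _, records = noisy_result
    input_total = sum(e.component_length for e in noisy_bundle.key)
    removed = sum(d.removed_left + d.removed_right for d in decisions)
    gaps = sum(d.emitted_gap or 0 for d in decisions)
    out_total = sum(len(s) for s in records.values())
    assert out_total == input_total - removed + gaps


def test_every_contig_reachable_from_output(clean_bundle, clean_result):
    """Safety: no junction resolution ever discards a contig."""
    _, _, _, all_plans, _ = clean_result
    sources = set()
    for plan in all_plans:
        for part in plan.parts:
            if not part.is_gap:
                sources.add(part.component)
    expected = {e.component_name for e in clean_bundle.key}
    assert sources == expected


def test_pipeline_outputs_deterministic(noisy_bundle, noisy_result):
    _, _, _, _, records = noisy_result
    rerun = run_pipeline(noisy_bundle)
    assert rerun[4] == records


def test_true_gaps_never_closed(noisy_bundle, noisy_result):
    """Junctions with a real gap >= 3.4 kb always stay gaps, even with
    sizing noise."""
    _, _, decisions, _, _ = noisy_result
    gap_pairs = {(j.left, j.right) for j in noisy_bundle.truth.junctions
                 if j.kind == "gap" and j.size >= 3_400}
    for d in decisions:
        if (d.left, d.right) in gap_pairs:
            assert d.kind == "sized_gap"


def test_junction_kind_mix(clean_result):
    _, _, decisions, _, _ = clean_result
    kinds = Counter(d.kind for d in decisions)
    assert kinds["fuse_at_label"] >= 1
    assert kinds["fuse_by_alignment"] >= 1
    assert kinds["containment_insert"] >= 1
    assert kinds["containment_singleton"] >= 1
    assert kinds["sized_gap"] >= 1
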