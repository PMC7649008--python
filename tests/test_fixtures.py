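"""Synthetic-data generator: determinism, digestion oracle, layout
conservation, and bundle self-consistency."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mapfuse import fixtures, io_formats as iof
from mapfuse._util import revcomp


def test_genome_deterministic_by_seed():
    assert fixtures.generate_genome(100, 1) == fixtures.generate_genome(100, 1)
    assert fixtures.generate_genome(100, 1) != fixtures.generate_genome(100, 2)


def test_genome_zero_length_rejected():
    with pytest.raises(ValueError):
        fixtures.generate_genome(0, 1)


def test_genome_base_composition_uniform():
    g = fixtures.generate_genome(1_000_000, 42)
    for base in "ACGT":
        assert abs(g.count(base) / len(g) - 0.25) < 0.01


def test_digest_palindromic_motif():
    assert fixtures.digest("AACTTAAGTT", "CTTAAG") == [3]


def test_digest_absent_motif():
    assert fixtures.digest("AAAAAA", "CTTAAG") == []


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_digest_equals_sliding_window_scan(seed):
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 10_000).tobytes().decode()
    for motif in ("CTTAAG", "GCTCTTC"):
        probes = {motif, revcomp(motif)}
        expected = sorted({i + 1 for i in range(len(seq) - len(motif) + 1)
                           if seq[i:i + len(motif)] in probes})
        assert fixtures.digest(seq, motif) == expected


def test_fragment_two_exact_gaps():
    spec = fixtures.FixtureSpec(
        genome_length=200_000, seed=5, n_gap_junctions=2,
        gap_size_range=(1000, 1000), n_overlap_junctions=0, n_contained=0,
        reverse_fraction=0.0)
    genome = fixtures.generate_genome(spec.genome_length, spec.seed)
    contigs, truth = fixtures.fragment(genome, spec)
    assert len(truth.contigs) == 3
    holes = []
    for a, b in zip(truth.contigs, truth.contigs[1:]):
        holes.append(b.genome_start - a.genome_end - 1)
    assert holes == [1000, 1000]
    for c in truth.contigs:
        assert contigs[c.name] == truth.genome[c.genome_start - 1 : c.genome_end]


def test_fragment_scaled_design_counts_match_spec():
    """A 1/10-scale version of the published simulation design: the truth
    manifest carries exactly the requested junction and containment counts."""
    spec = fixtures.FixtureSpec(
        genome_length=23_100_000, seed=9, n_gap_junctions=50,
        gap_size_range=(3400, 99_600), n_overlap_junctions=50,
        overlap_size_range=(278, 98_600), n_contained=5)
    genome = fixtures.generate_genome(spec.genome_length, spec.seed)
    _, truth = fixtures.fragment(genome, spec)
    kinds = [j.kind for j in truth.junctions]
    assert kinds.count("gap") == 50
    assert kinds.count("overlap") == 50
    assert len(truth.contained) == 5
    assert len(truth.contigs) == 101


def test_fragment_conservation_identity(clean_bundle):
    """sum(contigs) - sum(overlaps) + sum(gaps) == genome length (ignoring
    containment, which duplicates sequence)."""
    truth = clean_bundle.truth
    linear_total = sum(c.genome_end - c.genome_start + 1 for c in truth.contigs)
    ov = sum(j.size for j in truth.junctions if j.kind == "overlap")
    gaps = sum(j.size for j in truth.junctions if j.kind == "gap")
    covered = truth.contigs[-1].genome_end - truth.contigs[0].genome_start + 1
    assert linear_total - ov + gaps == covered


def test_fragment_infeasible_spec_rejected():
    spec = fixtures.FixtureSpec(genome_length=50_000, n_gap_junctions=8,
                                n_overlap_junctions=8, n_contained=0)
    with pytest.raises(ValueError, match="infeasible"):
        fixtures.fragment(fixtures.generate_genome(50_000, 1), spec)


def test_zero_noise_pair_positions_are_exact(clean_bundle):
    """Without sizing noise, every aligned pair's anchor position equals the
    label's genome position, and the contig-side position maps back to the
    same genome coordinate through the contig's true interval and strand."""
    truth = {c.name: c for c in clean_bundle.truth.contigs}
    truth.update({c.name: c for c in clean_bundle.truth.contained})
    by_id = {e.component_id: e.component_name for e in clean_bundle.key}
    for a in clean_bundle.alignments[:20]:
        name = by_id[a.query_map_id]
        t = truth[name]
        amap = clean_bundle.anchor_maps[a.channel][a.anchor_id]
        cmap = clean_bundle.contig_maps[a.channel][a.query_map_id]
        apos = amap.positions(a.channel)
        qpos = cmap.positions(a.channel)
        for anchor_site, query_site in a.pairs:
            g = apos[anchor_site]
            p = qpos[query_site]
            start = t.genome_start if hasattr(t, "genome_start") else t.host_start
            if t.strand == "+":
                assert g == pytest.approx(t.genome_start + p - 1)
            else:
                assert g == pytest.approx(t.genome_end - p + 1)


def test_all_labels_dropped_means_no_alignments():
    spec = fixtures.FixtureSpec(seed=4, label_fn_rate=1.0, n_contained=0)
    bundle = fixtures.simulate(spec)
    assert bundle.alignments == []
    assert all(not c.aligned for c in bundle.truth.contigs)


def test_bundle_round_trips_through_parsers(clean_bundle, tmp_path):
    paths = fixtures.write_bundle(clean_bundle, tmp_path)
    key = iof.parse_key(paths["key"])
    assert key == clean_bundle.key
    for ch in clean_bundle.contig_maps:
        cmaps = {m.map_id: m for m in iof.parse_cmap(paths[f"contig_cmap_{ch}"])}
        assert set(cmaps) == set(clean_bundle.contig_maps[ch])
        for lm in cmaps.values():
            for channel, sites in lm.sites.items():
                ids = [s for s, _ in sites]
                assert ids == sorted(ids)
                assert all(p <= lm.length_bp for _, p in sites)
        aligns = iof.parse_xmap(paths[f"xmap_{ch}"])
        want = [a for a in clean_bundle.alignments if a.channel == ch]
        assert [a.pairs for a in aligns] == [a.pairs for a in want]
        for a in aligns:
            assert a.query_start_bp <= a.query_end_bp
            assert a.anchor_start_bp <= a.anchor_end_bp
            site_ids = {s for s, _ in cmaps[a.query_map_id].sites[ch]}
            assert {q for _, q in a.pairs} <= site_ids


def test_simulation_fully_deterministic(tmp_path):
    spec = fixtures.FixtureSpec(seed=21, genome_length=1_000_000,
                                n_gap_junctions=2, n_overlap_junctions=2,
                                n_contained=0)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    fixtures.write_bundle(fixtures.simulate(spec), d1)
    fixtures.write_bundle(fixtures.simulate(spec), d2)
    for f1 in sorted(d1.iterdir()):
        assert f1.read_bytes() == (d2 / f1.name).read_bytes()
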