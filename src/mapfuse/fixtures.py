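"""Synthetic optical-map scaffolding datasets with known ground truth.

The generator emulates what a hybrid-scaffolding run leaves behind: a random
genome is fragmented into contigs separated by either real gaps or
artificial overlaps (the duplicated junctions the scaffolder is meant to
repair), a few contigs are made exact subsequences of larger ones to
simulate containment, every sequence is labelled in silico at enzyme motif
occurrences, and an anchor map plus per-contig maps and alignments are
emitted in the same CMAP/XMAP/key/FASTA dialects the parsers read.

Overlap junctions come in three sub-populations so each resolution path can
be exercised independently:

* ``labelled`` — the overlap contains at least one channel-1 label, so the
  junction resolves by shared-label fusion;
* ``alignable`` — the overlap is label-free but long enough (6-28 kb) for
  the alignment rescue to clear the score threshold;
* ``tiny`` — label-free and at most 200 bp: unresolvable, the junction
  keeps a sentinel gap.

Label-position noise is multiplicative on the *intervals* between adjacent
anchor labels (optical sizing error grows with distance), applied to the
anchor only; contig maps come from the sequence itself and are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np

from ._util import revcomp
from .io_formats import (KeyEntry, LabelMap, MapAlignment, write_cmap,
                         write_fasta, write_key, write_xmap)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Spec / truth containers
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Parameters of one simulated dataset (defaults: desk-scale run)."""

    genome_length: int = 5_000_000
    seed: int = 0
    n_gap_junctions: int = 8
    gap_size_range: tuple[int, int] = (3_000, 100_000)
    n_overlap_junctions: int = 8
    overlap_size_range: tuple[int, int] = (300, 100_000)
    n_contained: int = 2
    contained_size_range: tuple[int, int] = (20_000, 60_000)
    motifs: tuple[str, ...] = ("CTTAAG", "GCTCTTC")
    label_noise_sd: float = 0.003
    label_fn_rate: float = 0.0
    label_fp_rate: float = 0.0
    # fraction of overlap junctions forced to contain >= 1 channel-1 label
    shared_label_control: float = 0.5
    # fraction resolvable only by alignment (label-free, 6-28 kb)
    frac_overlap_alignable: float = 0.25
    # fraction of contained contigs whose host lacks interior labels,
    # making re-insertion the expected outcome
    frac_contained_insertable: float = 0.5
    reverse_fraction: float = 0.25
    alignable_size_range: tuple[int, int] = (6_000, 28_000)
    tiny_size_range: tuple[int, int] = (50, 200)

    def validate(self) -> None:
        for lo, hi in (self.gap_size_range, self.overlap_size_range,
                       self.contained_size_range):
            if lo <= 0 or hi < lo:
                raise ValueError("size ranges must be positive and ordered")
        for rate in (self.label_fn_rate, self.label_fp_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("label error rates must lie in [0, 1]")
        if min(self.n_gap_junctions, self.n_overlap_junctions, self.n_contained) < 0:
            raise ValueError("junction counts must be >= 0")


@dataclass
class ContigTruth:
    name: str
    genome_start: int  # 1-based inclusive
    genome_end: int
    strand: str  # "+" | "-"
    aligned: bool = True


@dataclass
class JunctionTruth:
    left: str
    right: str
    kind: str          # "gap" | "overlap"
    size: int          # true gap size, or true overlap size
    overlap_class: str | None = None  # labelled | alignable | tiny
    has_label: bool = False           # >= 1 channel-1 label inside the overlap


@dataclass
class ContainedTruth:
    name: str
    host: str
    host_start: int    # 1-based on the host's native sequence
    host_end: int
    genome_start: int
    genome_end: int
    strand: str
    expect_insert: bool


@dataclass
class FixtureTruth:
    genome: str
    contigs: list[ContigTruth] = field(default_factory=list)
    junctions: list[JunctionTruth] = field(default_factory=list)
    contained: list[ContainedTruth] = field(default_factory=list)

    @property
    def genome_length(self) -> int:
        return len(self.genome)


@dataclass
class Bundle:
    """In-memory equivalent of the file set a scaffolding run produces."""

    key: list[KeyEntry]
    contig_maps: dict[int, dict[int, LabelMap]]
    anchor_maps: dict[int, dict[int, LabelMap]]
    alignments: list[MapAlignment]
    contigs: dict[str, str]
    truth: FixtureTruth
    spec: FixtureSpec


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def generate_genome(length: int, seed: int) -> str:
    """Uniform random ACGT sequence, reproducible by seed."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def digest(sequence: str, motif: str) -> list[int]:
    """1-based start positions of motif occurrences on either strand.

    Forward-strand occurrences of the motif and of its reverse complement
    are merged, sorted and deduplicated — the in-silico analogue of
    enzymatic labelling, which marks both strands.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    hits: set[int] = set()
    for probe in {motif.upper(), revcomp(motif.upper())}:
        start = sequence.find(probe)
        while start != -1:
            hits.add(start + 1)
            start = sequence.find(probe, start + 1)
    return sorted(hits)


def _scrub_motifs(genome: bytearray, lo: int, hi: int, motifs: Iterable[str],
                  rng: np.random.Generator) -> None:
    """Mutate bases so no motif occurrence starts within [lo, hi] (1-based)."""
    probes = set()
    for m in motifs:
        probes.add(m.upper())
        probes.add(revcomp(m.upper()))
    max_len = max(len(p) for p in probes)
    window_lo = max(0, lo - 1 - max_len)
    for _ in range(200):  # always converges in a handful of rounds
        window = genome[window_lo : hi + max_len].decode("ascii")
        dirty = False
        for probe in probes:
            start = window.find(probe)
            while start != -1:
                g0 = window_lo + start  # 0-based genome start of occurrence
                if lo - max_len <= g0 + 1 <= hi:
                    pos = g0 + len(probe) // 2
                    old = genome[pos]
                    choices = [b for b in b"ACGT" if b != old]
                    genome[pos] = int(rng.choice(choices))
                    dirty = True
                start = window.find(probe, start + 1)
        if not dirty:
            return
    raise RuntimeError("failed to scrub motifs from window")


def _plant_motif(genome: bytearray, pos: int, motif: str) -> None:
    """Overwrite genome bases so a motif occurrence starts at pos (1-based)."""
    genome[pos - 1 : pos - 1 + len(motif)] = motif.encode("ascii")


# ---------------------------------------------------------------------------
# Fragmentation
# ---------------------------------------------------------------------------

def fragment(genome: str, spec: FixtureSpec) -> tuple[dict[str, str], FixtureTruth]:
    """Fragment a genome into contigs per spec; returns (contigs, truth).

    The returned truth carries the (possibly locally edited) genome: windows
    destined for label-free overlaps are scrubbed of motif occurrences and
    labelled overlaps get a planted motif when none occurred naturally, so
    the junction classes are guaranteed, not merely likely.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    n_ov = spec.n_overlap_junctions
    n_lab = round(spec.shared_label_control * n_ov)
    n_aln = min(round(spec.frac_overlap_alignable * n_ov), n_ov - n_lab)
    n_tiny = n_ov - n_lab - n_aln

    junction_kinds = (["gap"] * spec.n_gap_junctions
                      + ["labelled"] * n_lab + ["alignable"] * n_aln
                      + ["tiny"] * n_tiny)
    rng.shuffle(junction_kinds)

    def draw(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    sizes = []
    for kind in junction_kinds:
        if kind == "gap":
            sizes.append(draw(*spec.gap_size_range))
        elif kind == "labelled":
            sizes.append(draw(*spec.overlap_size_range))
        elif kind == "alignable":
            sizes.append(draw(*spec.alignable_size_range))
        else:
            sizes.append(draw(*spec.tiny_size_range))

    n_contigs = len(junction_kinds) + 1
    gap_total = sum(s for s, k in zip(sizes, junction_kinds) if k == "gap")
    overlap_total = sum(s for s, k in zip(sizes, junction_kinds) if k != "gap")
    span_for_contigs = len(genome) - gap_total + overlap_total
    mean_len = span_for_contigs // n_contigs
    min_needed = max([s for s, k in zip(sizes, junction_kinds) if k != "gap"],
                     default=0) + 4000
    if mean_len < min_needed:
        raise ValueError(
            f"spec infeasible for genome length {len(genome)}: needs at least "
            f"{min_needed * n_contigs + gap_total - overlap_total} bp"
        )
    weights = rng.uniform(0.7, 1.3, size=n_contigs)
    lengths = np.maximum((weights / weights.sum() * span_for_contigs).astype(int),
                         min_needed)

    gbuf = bytearray(genome, "ascii")
    contigs: dict[str, str] = {}
    truth = FixtureTruth(genome="")
    start = 1
    prev_name = None
    for i in range(n_contigs):
        end = min(start + int(lengths[i]) - 1, len(genome))
        name = f"contig_{i + 1:03d}"
        strand = "-" if rng.random() < spec.reverse_fraction else "+"
        truth.contigs.append(ContigTruth(name, start, end, strand))
        if prev_name is not None:
            kind, size = junction_kinds[i - 1], sizes[i - 1]
            if kind == "gap":
                truth.junctions.append(JunctionTruth(prev_name, name, "gap", size))
            else:
                truth.junctions.append(JunctionTruth(
                    prev_name, name, "overlap", size, overlap_class=kind,
                    has_label=(kind == "labelled")))
        prev_name = name
        if i < n_contigs - 1:
            kind, size = junction_kinds[i], sizes[i]
            if kind == "gap":
                start = end + size + 1
            else:
                ov_lo, ov_hi = end - size + 1, end  # genome span of the overlap
                if kind == "labelled":
                    motif = spec.motifs[0]
                    window_hits = digest(gbuf[ov_lo - 1 : ov_hi].decode("ascii"), motif)
                    if not any(p + ov_lo - 1 <= ov_hi - len(motif) + 1
                               for p in window_hits):
                        _plant_motif(gbuf, (ov_lo + ov_hi) // 2, motif)
                else:
                    _scrub_motifs(gbuf, ov_lo, ov_hi, spec.motifs, rng)
                start = ov_lo
        if end >= len(genome):
            break

    # contained contigs: exact subsequences of sufficiently large hosts
    hosts = [c for c in truth.contigs
             if c.genome_end - c.genome_start + 1 >= 3 * spec.contained_size_range[1]]
    rng.shuffle(hosts)
    for j in range(spec.n_contained):
        if not hosts:
            raise ValueError("spec infeasible: no contig large enough to host "
                             "a contained contig")
        host = hosts.pop()
        size = draw(*spec.contained_size_range)
        host_len = host.genome_end - host.genome_start + 1
        margin = max(2000, host_len // 10)
        x = draw(host.genome_start + margin, host.genome_end - margin - size)
        y = x + size - 1
        name = f"contained_{j + 1:03d}"
        strand = "-" if rng.random() < spec.reverse_fraction else "+"
        expect = j < round(spec.frac_contained_insertable * spec.n_contained)
        # guarantee enough interior labels for the count comparison
        motif = spec.motifs[0]
        inner = digest(gbuf[x - 1 : y].decode("ascii"), motif)
        if len(inner) < 5:
            for frac in (0.15, 0.35, 0.5, 0.65, 0.85):
                _plant_motif(gbuf, x + int(size * frac), motif)
        # host-native coordinates of the contained interval
        if host.strand == "+":
            hs, he = x - host.genome_start + 1, y - host.genome_start + 1
        else:
            hs, he = host.genome_end - y + 1, host.genome_end - x + 1
        truth.contained.append(ContainedTruth(
            name, host.name, hs, he, x, y, strand, expect))

    truth.genome = gbuf.decode("ascii")
    for c in truth.contigs:
        seq = truth.genome[c.genome_start - 1 : c.genome_end]
        contigs[c.name] = revcomp(seq) if c.strand == "-" else seq
    for ct in truth.contained:
        seq = truth.genome[ct.genome_start - 1 : ct.genome_end]
        contigs[ct.name] = revcomp(seq) if ct.strand == "-" else seq
    return contigs, truth


# ---------------------------------------------------------------------------
# Anchor / alignment bundle
# ---------------------------------------------------------------------------

def _noisy_positions(positions: np.ndarray, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Multiplicative interval noise: each inter-label distance is scaled."""
    if sd <= 0 or len(positions) == 0:
        return positions.astype(float)
    diffs = np.diff(np.concatenate(([0.0], positions.astype(float))))
    noisy = diffs * (1.0 + rng.normal(0.0, sd, size=len(diffs)))
    return np.cumsum(np.maximum(noisy, 0.1))


def build_anchor_bundle(truth: FixtureTruth, contigs: dict[str, str],
                        spec: FixtureSpec) -> Bundle:
    """Simulate the anchor CMAP, contig CMAPs, XMAPs and key for a fixture."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    genome = truth.genome
    all_records = ([(c.name, c.genome_start, c.genome_end, c.strand, None)
                    for c in truth.contigs]
                   + [(ct.name, ct.genome_start, ct.genome_end, ct.strand, ct)
                      for ct in truth.contained])
    key = [KeyEntry(i + 1, name, end - start + 1)
           for i, (name, start, end, _, _) in enumerate(all_records)]
    degraded = {}  # host name -> (x, y) genome interval losing interior pairs
    for ct in truth.contained:
        if ct.expect_insert:
            degraded.setdefault(ct.host, []).append((ct.genome_start, ct.genome_end))

    contig_maps: dict[int, dict[int, LabelMap]] = {}
    anchor_maps: dict[int, dict[int, LabelMap]] = {}
    alignments: list[MapAlignment] = []
    entry_id = 1
    aligned_names: set[str] = set()

    for ch, motif in enumerate(spec.motifs, start=1):
        gpos = np.array(digest(genome, motif), dtype=float)
        noisy = _noisy_positions(gpos, spec.label_noise_sd, rng)
        survives = rng.random(len(gpos)) >= spec.label_fn_rate
        anchor_sites: list[tuple[int, float]] = []
        site_of_label: dict[int, int] = {}  # genome label index -> anchor site id
        pos_entries = [(noisy[i], i) for i in range(len(gpos)) if survives[i]]
        n_fp = int(rng.binomial(max(len(gpos), 1), spec.label_fp_rate))
        for _ in range(n_fp):
            pos_entries.append((float(rng.uniform(1, len(genome))), -1))
        pos_entries.sort()
        for sid, (pos, label_idx) in enumerate(pos_entries, start=1):
            anchor_sites.append((sid, float(pos)))
            if label_idx >= 0:
                site_of_label[label_idx] = sid
        anchor_len = max(float(len(genome)),
                         (pos_entries[-1][0] + 100.0) if pos_entries else 0.0)
        anchor_maps[ch] = {1: LabelMap(1, anchor_len, {ch: anchor_sites})}
        contig_maps[ch] = {}

        label_index = {int(g): i for i, g in enumerate(gpos)}
        for map_id, (name, g_start, g_end, strand, _ct) in enumerate(all_records, start=1):
            length = g_end - g_start + 1
            inside = [int(g) for g in gpos if g_start <= g <= g_end]
            if strand == "+":
                native = [(g - g_start + 1, g) for g in inside]
            else:
                native = [(g_end - g + 1, g) for g in inside]
            native.sort()
            sites = [(i + 1, float(p)) for i, (p, _) in enumerate(native)]
            contig_maps[ch][map_id] = LabelMap(map_id, float(length), {ch: sites})
            qsite_of_g = {g: i + 1 for i, (_, g) in enumerate(native)}
            drop = set()
            for (dx, dy) in degraded.get(name, []):
                region = [g for g in inside if dx <= g <= dy]
                drop.update(region[1:-1])  # keep the outermost two
            pairs = []
            for g in inside:
                if g in drop or label_index[g] not in site_of_label:
                    continue
                pairs.append((noisy[label_index[g]], site_of_label[label_index[g]],
                              qsite_of_g[g], g))
            if len(pairs) < 2:
                continue
            pairs.sort()
            pair_list = [(sid, qid) for _, sid, qid, _ in pairs]
            anchor_span = (pairs[0][0], pairs[-1][0])
            native_of_g = {g: p for p, g in native}
            natives = sorted(float(native_of_g[g]) for *_, g in pairs)
            alignments.append(MapAlignment(
                entry_id=entry_id, query_map_id=map_id, anchor_id=1,
                query_start_bp=natives[0], query_end_bp=natives[-1],
                anchor_start_bp=float(anchor_span[0]),
                anchor_end_bp=float(anchor_span[1]),
                orientation="forward" if strand == "+" else "reverse",
                confidence=float(len(pair_list)), channel=ch,
                pairs=pair_list, query_len_bp=float(length),
                anchor_len_bp=anchor_len,
            ))
            entry_id += 1
            aligned_names.add(name)

    for c in truth.contigs:
        c.aligned = c.name in aligned_names
    return Bundle(key=key, contig_maps=contig_maps, anchor_maps=anchor_maps,
                  alignments=alignments, contigs=contigs, truth=truth, spec=spec)


def simulate(spec: FixtureSpec) -> Bundle:
    """Generate a full fixture: genome -> contigs -> anchor bundle."""
    genome = generate_genome(spec.genome_length, spec.seed)
    contigs, truth = fragment(genome, spec)
    return build_anchor_bundle(truth, contigs, spec)


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: Bundle, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture as the file set the scaffold command consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["fasta"] = out / "contigs.fasta"
    write_fasta(bundle.contigs, paths["fasta"])
    paths["key"] = out / "assembly.key"
    write_key(bundle.key, paths["key"])
    for ch in sorted(bundle.contig_maps):
        p = out / f"contigs_ch{ch}.cmap"
        write_cmap(bundle.contig_maps[ch].values(), p)
        paths[f"contig_cmap_{ch}"] = p
        p = out / f"anchor_ch{ch}.cmap"
        write_cmap(bundle.anchor_maps[ch].values(), p)
        paths[f"anchor_cmap_{ch}"] = p
        p = out / f"alignments_ch{ch}.xmap"
        write_xmap([a for a in bundle.alignments if a.channel == ch], p)
        paths[f"xmap_{ch}"] = p
    paths["truth"] = out / "truth.tsv"
    _write_truth_tsv(bundle.truth, paths["truth"])
    paths["spec"] = out / "fixture_spec.json"
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(bundle.spec), fh, indent=1, default=list)
    return paths


def _write_truth_tsv(truth: FixtureTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#section\tfields...\n")
        for c in truth.contigs:
            fh.write(f"contig\t{c.name}\t{c.genome_start}\t{c.genome_end}\t"
                     f"{c.strand}\t{int(c.aligned)}\n")
        for j in truth.junctions:
            fh.write(f"junction\t{j.left}\t{j.right}\t{j.kind}\t{j.size}\t"
                     f"{j.overlap_class or '.'}\t{int(j.has_label)}\n")
        for ct in truth.contained:
            fh.write(f"contained\t{ct.name}\t{ct.host}\t{ct.host_start}\t"
                     f"{ct.host_end}\t{ct.genome_start}\t{ct.genome_end}\t"
                     f"{ct.strand}\t{int(ct.expect_insert)}\n")
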