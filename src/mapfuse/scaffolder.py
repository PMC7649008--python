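"""Junction resolution: turn optical-map alignments into merged scaffolds.

A hybrid-scaffolding run leaves adjacent contigs separated by a sentinel
gap even when the optical map shows they overlap, duplicating the shared
region.  This module re-examines every adjacent contig pair on each anchor
and resolves the junction one of three ways:

* **shared-label fusion** — the contig maps share at least one anchor label;
  both contigs are cut at that label's position on their own label maps and
  fused without a gap;
* **gap sizing with alignment rescue** — no shared label; the gap size ``g``
  is estimated from the alignment coordinates (distance between the
  flanking aligned labels on the anchor minus the unaligned contig tails).
  Small or negative ``g`` triggers a local alignment of the facing contig
  ends; a sufficiently strong hit fuses the contigs at the alignment start,
  otherwise ``g`` Ns (with a 13-N floor) are emitted;
* **containment** — a contig whose anchor span lies strictly inside
  another's is either re-inserted between the outermost shared labels (when
  it has more labels mapped there than its host) or emitted as a singleton.

All cut arithmetic happens in *anchor-oriented* coordinates: a
reverse-aligned contig is reverse-complemented first and a label at native
position ``p`` moves to ``length - p + 1``.  Fractional label positions are
rounded half-up exactly once, at cut time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from . import aligner
from ._util import revcomp, round_half_up
from .io_formats import KeyEntry, LabelMap, MapAlignment, parse_subseq_name

log = logging.getLogger(__name__)


class DataError(ValueError):
    """Input files are mutually inconsistent."""


# ---------------------------------------------------------------------------
# Plan types (rendering targets for the writers)
# ---------------------------------------------------------------------------

@dataclass
class SlicePart:
    """A 1-based inclusive slice of an input contig, possibly minus strand."""

    component: str
    start: int
    end: int
    strand: str = "+"
    is_gap: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GapPart:
    length: int
    estimated_size: float | None = None
    is_gap: bool = True

    def __post_init__(self) -> None:
        self.is_gap = True


@dataclass
class ScaffoldPlan:
    name: str
    parts: list

    @property
    def length(self) -> int:
        return sum(p.length for p in self.parts)

    def validate(self) -> None:
        prev_gap = False
        for p in self.parts:
            if p.length < 1:
                raise ValueError(f"{self.name}: zero-length part")
            if p.is_gap and prev_gap:
                raise ValueError(f"{self.name}: consecutive gap parts")
            prev_gap = p.is_gap


# ---------------------------------------------------------------------------
# Decisions
# ---------------------------------------------------------------------------

@dataclass
class JunctionDecision:
    """Resolution of one junction (or one containment relation)."""

    kind: str  # fuse_at_label | fuse_by_alignment | sized_gap |
    #            containment_insert | containment_singleton
    anchor_id: int
    left: str
    right: str
    channel: int | None = None
    label_id: int | None = None
    g: float | None = None
    emitted_gap: int | None = None
    score: int | None = None
    removed_left: int = 0
    removed_right: int = 0
    cuts: tuple[int, ...] | None = None  # label/insert cut positions, oriented bp
    note: str = ""


@dataclass
class SharedLabelSet:
    """Anchor labels aligned in both members of a contig pair."""

    map_id_k: int
    map_id_n: int
    channel: int
    anchor_site_ids: list[int]

    def __bool__(self) -> bool:
        return bool(self.anchor_site_ids)

    @property
    def last(self) -> int:
        return self.anchor_site_ids[-1]


@dataclass(frozen=True)
class ScaffoldParams:
    gap_merge_threshold: float = 1000.0
    min_align_score: int = 5000
    window_bp: int = 30_000
    min_gap: int = 13
    backend: str = "builtin"  # "builtin" | "blat"
    blat_path: str = "blat"
    align: aligner.AlignParams = field(default_factory=aligner.AlignParams)


# ---------------------------------------------------------------------------
# Contig registry
# ---------------------------------------------------------------------------

@dataclass
class ContigRecord:
    """One key-file component resolved against the input assembly."""

    map_id: int
    name: str
    source_name: str
    source_start: int  # 1-based inclusive slice of the input contig
    source_end: int
    seq: str           # native orientation, as stored in the input FASTA
    orientation: str = "forward"  # set from the kept alignment

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def oriented_seq(self) -> str:
        if self.orientation == "reverse":
            if self._rc is None:
                self._rc = revcomp(self.seq)
            return self._rc
        return self.seq

    def __post_init__(self) -> None:
        self._rc: str | None = None

    def orient_pos(self, p: float) -> int:
        """Native label position (bp, possibly fractional) -> oriented index."""
        rp = round_half_up(p)
        if self.orientation == "reverse":
            return self.length - rp + 1
        return rp


def resolve_contigs(key: Sequence[KeyEntry], assembly: Mapping[str, str]) -> dict[int, ContigRecord]:
    """Map every key component to its sequence, honoring _subseq_ names."""
    out: dict[int, ContigRecord] = {}
    for entry in key:
        sub = parse_subseq_name(entry.component_name)
        if sub is not None and sub[0] in assembly:
            base, start, end = sub
            seq = assembly[base][start - 1 : end]
        else:
            base, start = entry.component_name, 1
            if base not in assembly:
                raise DataError(f"key component {base!r} not found in assembly FASTA")
            seq = assembly[base]
            end = len(seq)
        if len(seq) != entry.component_length:
            log.warning(
                "component %s: key length %d != sequence length %d",
                entry.component_name, entry.component_length, len(seq),
            )
        out[entry.component_id] = ContigRecord(
            map_id=entry.component_id, name=entry.component_name,
            source_name=base, source_start=start, source_end=end, seq=seq,
        )
    return out


# ---------------------------------------------------------------------------
# Elements: mutable part lists while junctions are being resolved
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    map_id: int
    o_lo: int  # 1-based inclusive, oriented coordinates of that contig
    o_hi: int

    @property
    def length(self) -> int:
        return self.o_hi - self.o_lo + 1


def _drop_right(segs: list[Segment], n: int) -> int:
    """Remove n oriented bases from the right end; returns bases removed."""
    removed = 0
    while n > 0 and segs:
        last = segs[-1]
        if last.length <= n:
            n -= last.length
            removed += last.length
            segs.pop()
        else:
            last.o_hi -= n
            removed += n
            n = 0
    return removed


def _drop_left(segs: list[Segment], n: int) -> int:
    removed = 0
    while n > 0 and segs:
        first = segs[0]
        if first.length <= n:
            n -= first.length
            removed += first.length
            segs.pop(0)
        else:
            first.o_lo += n
            removed += n
            n = 0
    return removed


def _cut_right_at(segs: list[Segment], map_id: int, pos: int) -> int:
    """Keep oriented positions <= pos of contig map_id at the right end."""
    removed = 0
    while segs:
        last = segs[-1]
        if last.map_id != map_id:
            break  # never discard another contig's sequence
        if last.o_lo > pos:
            removed += last.length
            segs.pop()
            continue
        if last.o_hi > pos:
            removed += last.o_hi - pos
            last.o_hi = pos
        break
    return removed


def _cut_left_at(segs: list[Segment], map_id: int, pos: int) -> int:
    """Keep oriented positions > pos of contig map_id at the left end."""
    removed = 0
    while segs:
        first = segs[0]
        if first.map_id != map_id:
            break
        if first.o_hi <= pos:
            removed += first.length
            segs.pop(0)
            continue
        if first.o_lo <= pos:
            removed += pos - first.o_lo + 1
            first.o_lo = pos + 1
        break
    return removed


def _segs_tail(segs: list[Segment], registry: Mapping[int, ContigRecord], n: int) -> str:
    parts: list[str] = []
    need = n
    for seg in reversed(segs):
        if need <= 0:
            break
        rec = registry[seg.map_id]
        take = min(need, seg.length)
        hi = seg.o_hi
        parts.append(rec.oriented_seq[hi - take : hi])
        need -= take
    return "".join(reversed(parts))


def _segs_head(segs: list[Segment], registry: Mapping[int, ContigRecord], n: int) -> str:
    parts: list[str] = []
    need = n
    for seg in segs:
        if need <= 0:
            break
        rec = registry[seg.map_id]
        take = min(need, seg.length)
        lo = seg.o_lo
        parts.append(rec.oriented_seq[lo - 1 : lo - 1 + take])
        need -= take
    return "".join(parts)


def _segment_to_slice(seg: Segment, registry: Mapping[int, ContigRecord]) -> SlicePart:
    rec = registry[seg.map_id]
    if rec.orientation == "reverse":
        n_lo = rec.length - seg.o_hi + 1
        n_hi = rec.length - seg.o_lo + 1
        strand = "-"
    else:
        n_lo, n_hi = seg.o_lo, seg.o_hi
        strand = "+"
    off = rec.source_start - 1
    return SlicePart(rec.source_name, off + n_lo, off + n_hi, strand)


def render_plan_sequence(plan: ScaffoldPlan, assembly: Mapping[str, str]) -> str:
    """Materialize a plan into its scaffold sequence."""
    chunks: list[str] = []
    for part in plan.parts:
        if part.is_gap:
            chunks.append("N" * part.length)
        else:
            seq = assembly[part.component][part.start - 1 : part.end]
            chunks.append(revcomp(seq) if part.strand == "-" else seq)
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Spec operations
# ---------------------------------------------------------------------------

def order_alignments(alignments: Iterable[MapAlignment], anchor_id: int) -> list[MapAlignment]:
    """Alignments on one anchor, sorted by anchor start.

    Ties break by descending confidence, then ascending query map id.
    """
    subset = [a for a in alignments if a.anchor_id == anchor_id]
    return sorted(subset, key=lambda a: (a.anchor_start_bp, -a.confidence, a.query_map_id))


def shared_labels(align_k: MapAlignment, align_n: MapAlignment,
                  anchor_positions: Mapping[int, float] | None = None) -> SharedLabelSet:
    """Anchor site ids aligned in both pair lists, anchor-position ordered."""
    if align_k.channel != align_n.channel:
        raise ValueError("shared_labels requires alignments from the same channel")
    in_n = {r for r, _ in align_n.pairs}
    shared = [r for r, _ in align_k.pairs if r in in_n]
    seen: set[int] = set()
    shared = [r for r in shared if not (r in seen or seen.add(r))]
    if anchor_positions is not None:
        shared.sort(key=lambda r: anchor_positions.get(r, float("inf")))
    return SharedLabelSet(align_k.query_map_id, align_n.query_map_id,
                          align_k.channel, shared)


def _query_site_position(align: MapAlignment, cmap: LabelMap, anchor_site: int) -> float:
    """Native position of the query site paired with an anchor site."""
    for r, q in align.pairs:
        if r == anchor_site:
            pos = cmap.positions(align.channel).get(q)
            if pos is None:
                raise DataError(
                    f"map {align.query_map_id}: site {q} (channel {align.channel}) "
                    "missing from its label map"
                )
            return pos
    raise DataError(
        f"map {align.query_map_id}: anchor site {anchor_site} not in alignment pairs"
    )


def merge_at_shared_label(
    rec_k: ContigRecord, rec_n: ContigRecord, shared: SharedLabelSet,
    align_k: MapAlignment, align_n: MapAlignment,
    cmap_k: LabelMap, cmap_n: LabelMap,
) -> JunctionDecision:
    """Case-1 decision: cut both contigs at the last shared anchor label.

    The cut position on each contig is that contig's own label position for
    the shared site (oriented); the left contig keeps [1..P], the right one
    keeps (P..length].
    """
    if not shared:
        raise ValueError("merge_at_shared_label requires a non-empty shared set")
    label = shared.last
    p_k = rec_k.orient_pos(_query_site_position(align_k, cmap_k, label))
    p_n = rec_n.orient_pos(_query_site_position(align_n, cmap_n, label))
    return JunctionDecision(
        kind="fuse_at_label", anchor_id=align_k.anchor_id,
        left=rec_k.name, right=rec_n.name, channel=shared.channel,
        label_id=label, removed_left=rec_k.length - p_k, removed_right=p_n,
        cuts=(p_k, p_n), note=f"cut left@{p_k} right@{p_n}",
    )


def estimate_gap_size(align_k: MapAlignment, align_n: MapAlignment,
                      size_k: float, size_n: float | None = None) -> float:
    """Optical-map gap estimate between two adjacent contig alignments.

    With ``n`` the anchor distance between the facing aligned labels,
    ``d_k`` the unaligned tail of the left contig and ``d_n`` the unaligned
    head of the right contig, the gap is ``g = n - d_k - d_n``; ``g`` may be
    negative (predicted overlap).  For reverse-aligned contigs the contig
    spans are mirrored into anchor orientation first (which needs that
    contig's size).
    """
    if align_k.is_reverse:
        em_k = size_k - align_k.query_start_bp + 1
    else:
        em_k = align_k.query_end_bp
    if align_n.is_reverse:
        if size_n is None:
            raise ValueError("size_n is required when the right contig is reverse-aligned")
        sm_n = size_n - align_n.query_end_bp + 1
    else:
        sm_n = align_n.query_start_bp
    n = align_n.anchor_start_bp - align_k.anchor_end_bp
    d_k = size_k - em_k
    d_n = sm_n
    return n - d_k - d_n


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class _Element:
    """A growing run of fused contigs during junction resolution."""

    segs: list[Segment]
    left_map: int   # contig map at the current left end
    right_map: int  # contig map at the current right end


def _pick_shared_channel(
    aligns_k: Mapping[int, MapAlignment], aligns_n: Mapping[int, MapAlignment],
    anchor_maps: Mapping[int, Mapping[int, LabelMap]], anchor_id: int,
) -> SharedLabelSet | None:
    """Shared labels for a pair, arbitrated across label channels.

    Prefer the channel whose last shared label sits furthest along the
    anchor (the cut closest to the junction); on a tie, the channel with
    more shared labels.
    """
    best: tuple[float, int, SharedLabelSet] | None = None
    for channel in sorted(set(aligns_k) & set(aligns_n)):
        anchor_pos = {}
        amap = anchor_maps.get(channel, {}).get(anchor_id)
        if amap is not None:
            anchor_pos = amap.positions(channel)
        shared = shared_labels(aligns_k[channel], aligns_n[channel],
                               anchor_pos if anchor_pos else None)
        if not shared:
            continue
        last_pos = anchor_pos.get(shared.last, 0.0) if anchor_pos else 0.0
        key = (last_pos, len(shared.anchor_site_ids))
        if best is None or key > (best[0], best[1]):
            best = (key[0], key[1], shared)
    return best[2] if best else None


def resolve_containment(
    rec_k: ContigRecord, rec_n: ContigRecord,
    aligns_k: Mapping[int, MapAlignment], aligns_n: Mapping[int, MapAlignment],
    contig_maps: Mapping[int, Mapping[int, LabelMap]],
    anchor_maps: Mapping[int, Mapping[int, LabelMap]], anchor_id: int,
) -> JunctionDecision:
    """Case-3 decision for a contig whose anchor span lies inside another's.

    The contained contig is re-inserted between the outermost shared labels
    when it has more of its labels mapped in that region than its host;
    otherwise (including ties and no shared labels) it stays a singleton.
    """
    shared = _pick_shared_channel(aligns_k, aligns_n, anchor_maps, anchor_id)
    base = JunctionDecision(kind="containment_singleton", anchor_id=anchor_id,
                            left=rec_k.name, right=rec_n.name)
    if shared is None or len(shared.anchor_site_ids) < 2:
        base.note = "no shared labels; cannot place insert"
        return base
    channel = shared.channel
    l_l, l_r = shared.anchor_site_ids[0], shared.anchor_site_ids[-1]
    amap = anchor_maps.get(channel, {}).get(anchor_id)
    if amap is None:
        base.note = "anchor label map unavailable"
        return base
    anchor_pos = amap.positions(channel)
    lo, hi = anchor_pos[l_l], anchor_pos[l_r]

    def labels_in_region(align: MapAlignment) -> int:
        return sum(1 for r, _ in align.pairs if lo <= anchor_pos.get(r, -1.0) <= hi)

    count_k = labels_in_region(aligns_k[channel])
    count_n = labels_in_region(aligns_n[channel])
    if count_n <= count_k:  # ties conservatively keep the host
        base.note = f"labels host={count_k} insert={count_n}"
        return base
    align_k, align_n = aligns_k[channel], aligns_n[channel]
    cmap_k = contig_maps[channel][rec_k.map_id]
    cmap_n = contig_maps[channel][rec_n.map_id]
    p_ll_k = rec_k.orient_pos(_query_site_position(align_k, cmap_k, l_l))
    p_lr_k = rec_k.orient_pos(_query_site_position(align_k, cmap_k, l_r))
    p_ll_n = rec_n.orient_pos(_query_site_position(align_n, cmap_n, l_l))
    p_lr_n = rec_n.orient_pos(_query_site_position(align_n, cmap_n, l_r))
    if not (p_ll_k < p_lr_k and p_ll_n < p_lr_n):
        base.note = "degenerate label geometry; kept as singleton"
        return base
    return JunctionDecision(
        kind="containment_insert", anchor_id=anchor_id,
        left=rec_k.name, right=rec_n.name, channel=channel, label_id=l_r,
        removed_left=p_lr_k - p_ll_k,
        removed_right=rec_n.length - (p_lr_n - p_ll_n),
        cuts=(p_ll_k, p_lr_k, p_ll_n, p_lr_n),
        note=f"labels host={count_k} insert={count_n}",
    )


def _apply_insert(segs: list[Segment], host: int, h_lo: int, h_hi: int,
                  ins: Segment) -> bool:
    """Replace host oriented range (h_lo, h_hi] with an insert segment."""
    idx = next((i for i, s in enumerate(segs)
                if s.map_id == host and s.o_lo <= h_lo and h_hi <= s.o_hi), None)
    if idx is None:
        return False
    seg = segs[idx]
    new = []
    if h_lo >= seg.o_lo:
        new.append(Segment(host, seg.o_lo, h_lo))
    new.append(ins)
    if h_hi + 1 <= seg.o_hi:
        new.append(Segment(host, h_hi + 1, seg.o_hi))
    segs[idx : idx + 1] = new
    return True


def resolve_unlabelled_junction(
    rec_k: ContigRecord, rec_n: ContigRecord, g: float,
    window_k: str, window_n: str, params: ScaffoldParams, anchor_id: int,
) -> JunctionDecision:
    """Case-2 decision: alignment rescue for small gaps, sized gap otherwise."""
    base = JunctionDecision(kind="sized_gap", anchor_id=anchor_id,
                            left=rec_k.name, right=rec_n.name, g=g)
    if g > params.gap_merge_threshold:
        base.emitted_gap = max(round_half_up(g), 1)
        return base
    hit: aligner.LocalAlignment | None = None
    try:
        if params.backend == "blat":
            hit = aligner.external_blat_adapter(window_k, window_n, params.blat_path)
        else:
            hit = aligner.local_align(window_k, window_n, params.align)
    except Exception as exc:  # junction preserved, never dropped
        log.warning("aligner failed at %s|%s (%s); emitting sized gap",
                    rec_k.name, rec_n.name, exc)
        hit = None
    if hit is not None and hit.score > params.min_align_score:
        drop_k = len(window_k) - (hit.a_start - 1)
        drop_n = hit.b_start - 1
        return JunctionDecision(
            kind="fuse_by_alignment", anchor_id=anchor_id,
            left=rec_k.name, right=rec_n.name, g=g, score=hit.score,
            removed_left=drop_k, removed_right=drop_n,
            note=f"alignment a[{hit.a_start}..{hit.a_end}] b[{hit.b_start}..{hit.b_end}]",
        )
    base.emitted_gap = max(round_half_up(g), params.min_gap)
    base.score = hit.score if hit is not None else None
    return base


def build_scaffolds(
    assembly: Mapping[str, str],
    key: Sequence[KeyEntry],
    contig_maps: Mapping[int, Mapping[int, LabelMap]],
    anchor_maps: Mapping[int, Mapping[int, LabelMap]],
    alignments: Sequence[MapAlignment],
    params: ScaffoldParams = ScaffoldParams(),
) -> tuple[list[ScaffoldPlan], list[str], list[JunctionDecision]]:
    """Resolve every junction and return (plans, singleton names, decisions).

    ``contig_maps`` and ``anchor_maps`` map channel -> map_id -> LabelMap.
    One plan is produced per anchor (ascending anchor id); contigs absent
    from every alignment are returned as singletons in key order.
    """
    registry = resolve_contigs(key, assembly)
    missing = sorted({a.query_map_id for a in alignments} - set(registry))
    if missing:
        raise DataError(f"aligned map ids missing from key file: {missing}")

    # one anchor per contig map: keep the highest-confidence anchor
    by_map: dict[int, list[MapAlignment]] = {}
    for a in alignments:
        by_map.setdefault(a.query_map_id, []).append(a)
    kept: list[MapAlignment] = []
    for map_id, group in by_map.items():
        anchors: dict[int, float] = {}
        for a in group:
            anchors[a.anchor_id] = anchors.get(a.anchor_id, 0.0) + a.confidence
        best_anchor = max(anchors, key=lambda k: (anchors[k], -k))
        for a in group:
            if a.anchor_id == best_anchor:
                kept.append(a)
            else:
                log.info("map %d: discarding alignment to anchor %d "
                         "(kept anchor %d)", map_id, a.anchor_id, best_anchor)
        primary = max((a for a in group if a.anchor_id == best_anchor),
                      key=lambda a: (a.confidence, -a.channel))
        registry[map_id].orientation = primary.orientation

    # per anchor: map_id -> channel -> alignment
    per_anchor: dict[int, dict[int, dict[int, MapAlignment]]] = {}
    for a in kept:
        per_anchor.setdefault(a.anchor_id, {}).setdefault(
            a.query_map_id, {})[a.channel] = a

    plans: list[ScaffoldPlan] = []
    decisions: list[JunctionDecision] = []
    in_scaffold: set[int] = set()  # map ids rendered inside some plan

    for anchor_id in sorted(per_anchor):
        amap_aligns = per_anchor[anchor_id]
        spans: dict[int, tuple[float, float, float]] = {}
        for map_id, by_ch in amap_aligns.items():
            starts = [al.anchor_start_bp for al in by_ch.values()]
            ends = [al.anchor_end_bp for al in by_ch.values()]
            conf = max(al.confidence for al in by_ch.values())
            spans[map_id] = (min(starts), max(ends), conf)
        order = sorted(spans, key=lambda m: (spans[m][0], -spans[m][2], m))

        # --- containment pass (innermost first) -------------------------
        contained_of: dict[int, int] = {}
        for m_id in order:
            s, e, _ = spans[m_id]
            hosts = [h for h in order
                     if h != m_id and spans[h][0] < s and e < spans[h][1]]
            if hosts:
                contained_of[m_id] = min(hosts, key=lambda h: spans[h][1] - spans[h][0])
        elements: dict[int, _Element] = {
            m: _Element([Segment(m, 1, registry[m].length)], m, m) for m in order
        }
        for m_id in sorted(contained_of, key=lambda m: spans[m][1] - spans[m][0]):
            host = contained_of[m_id]
            while host not in elements and host in contained_of:
                host = contained_of[host]
            dec = resolve_containment(
                registry[host], registry[m_id],
                amap_aligns[host], amap_aligns[m_id],
                contig_maps, anchor_maps, anchor_id,
            )
            if dec.kind == "containment_insert":
                h_lo, h_hi, i_lo, i_hi = dec.cuts  # type: ignore[misc]
                ok = _apply_insert(elements[host].segs, host, h_lo, h_hi,
                                   Segment(m_id, i_lo + 1, i_hi))
                if ok:
                    in_scaffold.add(m_id)
                else:  # insert region no longer intact in the host
                    dec = replace(dec, kind="containment_singleton",
                                  removed_left=0, removed_right=0, cuts=None,
                                  note=dec.note + "; insert region unavailable")
            decisions.append(dec)
            del elements[m_id]
        linear = [m for m in order if m in elements]

        # --- pairwise pass ----------------------------------------------
        parts: list = []
        pending: _Element | None = None
        for m_id in linear:
            in_scaffold.add(m_id)
            el = elements[m_id]
            if pending is None:
                pending = el
                continue
            k_id, n_id = pending.right_map, m_id
            rec_k, rec_n = registry[k_id], registry[n_id]
            shared = _pick_shared_channel(
                amap_aligns[k_id], amap_aligns[n_id], anchor_maps, anchor_id)
            if shared is not None:
                ch = shared.channel
                dec = merge_at_shared_label(
                    rec_k, rec_n, shared,
                    amap_aligns[k_id][ch], amap_aligns[n_id][ch],
                    contig_maps[ch][k_id], contig_maps[ch][n_id],
                )
                p_k, p_n = dec.cuts  # type: ignore[misc]
                dec.removed_left = _cut_right_at(pending.segs, k_id, p_k)
                dec.removed_right = _cut_left_at(el.segs, n_id, p_n)
                pending.segs.extend(el.segs)
                pending.right_map = el.right_map
            else:
                def primary(by_ch: Mapping[int, MapAlignment]) -> MapAlignment:
                    return max(by_ch.values(), key=lambda a: (a.confidence, -a.channel))

                al_k = primary(amap_aligns[k_id])
                al_n = primary(amap_aligns[n_id])
                g = estimate_gap_size(al_k, al_n, rec_k.length, rec_n.length)
                win_k = _segs_tail(pending.segs, registry, params.window_bp)
                win_n = _segs_head(el.segs, registry, params.window_bp)
                dec = resolve_unlabelled_junction(
                    rec_k, rec_n, g, win_k, win_n, params, anchor_id)
                if dec.kind == "fuse_by_alignment":
                    dec.removed_left = _drop_right(pending.segs, dec.removed_left)
                    dec.removed_right = _drop_left(el.segs, dec.removed_right)
                    pending.segs.extend(el.segs)
                    pending.right_map = el.right_map
                else:
                    parts.extend(_segment_to_slice(s, registry) for s in pending.segs)
                    parts.append(GapPart(dec.emitted_gap, estimated_size=g))
                    pending = el
            decisions.append(dec)
        if pending is not None:
            parts.extend(_segment_to_slice(s, registry) for s in pending.segs)
        if parts:
            plan = ScaffoldPlan(f"scaffold_{anchor_id}", parts)
            plan.validate()
            plans.append(plan)

    singleton_names = [registry[e.component_id].name for e in key
                       if e.component_id not in in_scaffold]
    return plans, singleton_names, decisions


def singleton_plans(names: Sequence[str], key: Sequence[KeyEntry],
                    assembly: Mapping[str, str]) -> list[ScaffoldPlan]:
    """One-part plans for singleton components, for the FASTA/AGP writers."""
    registry = resolve_contigs(key, assembly)
    by_name = {rec.name: rec for rec in registry.values()}
    plans = []
    for name in names:
        rec = by_name[name]
        plans.append(ScaffoldPlan(
            rec.name,
            [SlicePart(rec.source_name, rec.source_start, rec.source_end, "+")],
        ))
    return plans


def total_plan_length(plans: Iterable[ScaffoldPlan]) -> int:
    return sum(p.length for p in plans)


__all__ = [
    "ScaffoldPlan", "SlicePart", "GapPart", "JunctionDecision",
    "SharedLabelSet", "ScaffoldParams", "ContigRecord", "DataError",
    "order_alignments", "shared_labels", "merge_at_shared_label",
    "estimate_gap_size", "resolve_unlabelled_junction", "resolve_containment",
    "build_scaffolds", "singleton_plans", "render_plan_sequence",
    "resolve_contigs",
]
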