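"""Readers and writers for the file formats a Bionano hybrid-scaffold run
produces and this tool consumes or emits.

Formats handled:

* **key** — tab-separated table mapping numeric map identifiers to contig
  names and lengths.
* **CMAP** — tab-separated label-site table: for each map, the bp position of
  every enzymatic labelling site, plus a channel-0 terminal row marking the
  map end.
* **XMAP** — tab-separated alignment table between a query (contig) map and a
  reference (anchor) map, including the explicit ``(refSite,qrySite)`` pair
  string.
* **FASTA** — input contigs and output scaffolds.
* **AGP v2.1** — the component layout of each output scaffold.

Coordinates are kept exactly as printed (1-based bp, possibly fractional for
CMAP/XMAP positions); rounding to sequence indices happens only at slice
time, never here.  Reverse-orientation XMAP rows (query start > query end in
the raw file) are normalized at parse time to an ascending span plus an
explicit orientation flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from Bio import SeqIO

from ._util import PathOrStream, iter_data_lines, open_text, revcomp


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyEntry:
    """One row of a key file: map identifier -> contig name and length."""

    component_id: int
    component_name: str
    component_length: int


@dataclass
class LabelMap:
    """One optical map: ordered label sites per channel.

    ``sites`` maps a label channel to an ordered list of
    ``(site_id, position_bp)`` tuples; positions may be fractional, as
    printed in the CMAP.  The channel-0 terminal row of the CMAP sets
    ``length_bp`` and is not stored as a site.
    """

    map_id: int
    length_bp: float
    sites: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def positions(self, channel: int) -> dict[int, float]:
        """Site id -> position for one channel."""
        return dict(self.sites.get(channel, []))

    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())


@dataclass
class MapAlignment:
    """One XMAP record: a contig map aligned to an anchor.

    ``query_start_bp <= query_end_bp`` always holds; a raw reverse row is
    normalized and its direction recorded in ``orientation``.  ``pairs`` is
    the ordered list of ``(anchor_site_id, query_site_id)`` from the
    Alignment column.
    """

    entry_id: int
    query_map_id: int
    anchor_id: int
    query_start_bp: float
    query_end_bp: float
    anchor_start_bp: float
    anchor_end_bp: float
    orientation: str  # "forward" | "reverse"
    confidence: float
    channel: int
    pairs: list[tuple[int, int]]
    query_len_bp: float = 0.0
    anchor_len_bp: float = 0.0

    @property
    def is_reverse(self) -> bool:
        return self.orientation == "reverse"


@dataclass(frozen=True)
class AgpRow:
    object_name: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # "W" | "N"
    component_name: str = ""
    component_start: int = 0
    component_end: int = 0
    strand: str = "+"
    gap_length: int = 0
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"


_SUBSEQ_RE = re.compile(r"^(?P<base>.+)_subseq_(?P<start>\d+):(?P<end>\d+)$")


def parse_subseq_name(name: str) -> tuple[str, int, int] | None:
    """Decode the split-contig naming convention ``NAME_subseq_START:END``.

    Returns ``(base_name, start, end)`` (1-based inclusive slice of the
    input contig) or None when the name is not of that form.
    """
    m = _SUBSEQ_RE.match(name)
    if m is None:
        return None
    return m.group("base"), int(m.group("start")), int(m.group("end"))


# ---------------------------------------------------------------------------
# key file
# ---------------------------------------------------------------------------

def parse_key(source: PathOrStream) -> list[KeyEntry]:
    """Parse a key file into KeyEntry rows, preserving order.

    Lines starting with '#' are comments; a literal column-title row
    (first field "CompntId") is tolerated and skipped.
    """
    stream = open_text(source)
    entries: list[KeyEntry] = []
    seen: set[int] = set()
    for lineno, line in iter_data_lines(stream):
        fields = line.split("\t")
        if fields[0] == "CompntId":  # bare header row in real key files
            continue
        if len(fields) < 3:
            raise FormatError(f"key line {lineno}: expected 3 columns, got {len(fields)}")
        try:
            cid = int(fields[0])
            clen = int(fields[2])
        except ValueError as exc:
            raise FormatError(f"key line {lineno}: non-integer id or length: {exc}") from exc
        if cid in seen:
            raise FormatError(f"duplicate component id {cid} in key file")
        seen.add(cid)
        entries.append(KeyEntry(cid, fields[1], clen))
    return entries


def write_key(entries: Iterable[KeyEntry], dest: PathOrStream) -> None:
    stream = open_text(dest, "w")
    stream.write("# CompntId\tCompntName\tCompntLength\n")
    for e in entries:
        stream.write(f"{e.component_id}\t{e.component_name}\t{e.component_length}\n")


# ---------------------------------------------------------------------------
# CMAP
# ---------------------------------------------------------------------------

_CMAP_COLUMNS = ("CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel", "Position")


def _header_index(line: str) -> dict[str, int]:
    names = line.lstrip("#h").strip().split("\t")
    return {name.strip(): i for i, name in enumerate(names)}


def parse_cmap(source: PathOrStream) -> list[LabelMap]:
    """Parse a CMAP stream into LabelMaps.

    Rows are grouped by map id; the channel-0 terminal row sets the map
    length and is not kept as a site.  Columns are located by name from the
    '#h' header line; extra columns are ignored.
    """
    stream = open_text(source)
    cols: dict[str, int] | None = None
    maps: dict[int, LabelMap] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#h"):
                cols = _header_index(line)
            continue
        if cols is None:
            raise FormatError("CMAP has no '#h' column header line")
        for required in _CMAP_COLUMNS:
            if required not in cols:
                raise FormatError(f"CMAP missing required column {required!r}")
        fields = line.split("\t")
        try:
            map_id = int(fields[cols["CMapId"]])
            length = float(fields[cols["ContigLength"]])
            site_id = int(fields[cols["SiteID"]])
            channel = int(fields[cols["LabelChannel"]])
            position = float(fields[cols["Position"]])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"CMAP line {lineno}: {exc}") from exc
        lm = maps.get(map_id)
        if lm is None:
            lm = maps[map_id] = LabelMap(map_id=map_id, length_bp=length)
        if position > length + 1e-6:
            raise FormatError(
                f"CMAP line {lineno}: position {position} exceeds map length {length}"
            )
        if channel == 0:  # terminal row: marks map end
            lm.length_bp = length
            continue
        lm.sites.setdefault(channel, []).append((site_id, position))
    for lm in maps.values():
        for channel, sites in lm.sites.items():
            sites.sort(key=lambda sp: sp[0])
            ids = [s for s, _ in sites]
            if len(ids) != len(set(ids)):
                raise FormatError(f"map {lm.map_id}: duplicate site ids in channel {channel}")
    return list(maps.values())


def write_cmap(maps: Iterable[LabelMap], dest: PathOrStream) -> None:
    stream = open_text(dest, "w")
    stream.write("# CMAP File Version:\t0.2\n")
    stream.write("#h CMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\n")
    stream.write("#f int\tfloat\tint\tint\tint\tfloat\n")
    for lm in maps:
        n = lm.n_sites()
        rows: list[tuple[int, int, float]] = []
        for channel, sites in sorted(lm.sites.items()):
            rows.extend((site_id, channel, pos) for site_id, pos in sites)
        rows.sort(key=lambda r: (r[1], r[0]))
        for site_id, channel, pos in rows:
            stream.write(
                f"{lm.map_id}\t{lm.length_bp:.1f}\t{n}\t{site_id}\t{channel}\t{pos:.1f}\n"
            )
        stream.write(f"{lm.map_id}\t{lm.length_bp:.1f}\t{n}\t{n + 1}\t0\t{lm.length_bp:.1f}\n")


# ---------------------------------------------------------------------------
# XMAP
# ---------------------------------------------------------------------------

_XMAP_COLUMNS = (
    "XmapEntryID", "QryContigID", "RefContigID", "QryStartPos", "QryEndPos",
    "RefStartPos", "RefEndPos", "Orientation", "Confidence", "Alignment",
)
_PAIR_RE = re.compile(r"\((\d+),(\d+)\)")


def _parse_pair_string(text: str, lineno: int) -> list[tuple[int, int]]:
    pairs = []
    pos = 0
    for m in _PAIR_RE.finditer(text):
        if m.start() != pos:
            raise FormatError(
                f"XMAP line {lineno}: malformed pair token {text[pos:m.start()]!r}"
            )
        pairs.append((int(m.group(1)), int(m.group(2))))
        pos = m.end()
    if pos != len(text):
        raise FormatError(f"XMAP line {lineno}: malformed pair token {text[pos:]!r}")
    return pairs


def parse_xmap(source: PathOrStream, channel: int | None = None) -> list[MapAlignment]:
    """Parse an XMAP stream into MapAlignments.

    ``channel`` overrides the file's LabelChannel column; when neither is
    available the channel defaults to 1.  Reverse rows are normalized so
    ``query_start_bp <= query_end_bp``.
    """
    stream = open_text(source)
    cols: dict[str, int] | None = None
    out: list[MapAlignment] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#h"):
                cols = _header_index(line)
            continue
        if cols is None:
            raise FormatError("XMAP has no '#h' column header line")
        for required in _XMAP_COLUMNS:
            if required not in cols:
                raise FormatError(f"XMAP missing required column {required!r}")
        fields = line.split("\t")
        try:
            qry_start = float(fields[cols["QryStartPos"]])
            qry_end = float(fields[cols["QryEndPos"]])
            rec = MapAlignment(
                entry_id=int(fields[cols["XmapEntryID"]]),
                query_map_id=int(fields[cols["QryContigID"]]),
                anchor_id=int(fields[cols["RefContigID"]]),
                query_start_bp=min(qry_start, qry_end),
                query_end_bp=max(qry_start, qry_end),
                anchor_start_bp=float(fields[cols["RefStartPos"]]),
                anchor_end_bp=float(fields[cols["RefEndPos"]]),
                orientation="",
                confidence=float(fields[cols["Confidence"]]),
                channel=1,
                pairs=_parse_pair_string(fields[cols["Alignment"]], lineno),
                query_len_bp=float(fields[cols["QryLen"]]) if "QryLen" in cols else 0.0,
                anchor_len_bp=float(fields[cols["RefLen"]]) if "RefLen" in cols else 0.0,
            )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"XMAP line {lineno}: {exc}") from exc
        sym = fields[cols["Orientation"]].strip()
        if sym == "+":
            rec.orientation = "forward"
        elif sym == "-":
            rec.orientation = "reverse"
        else:
            raise FormatError(f"XMAP line {lineno}: unknown orientation symbol {sym!r}")
        if not rec.pairs:
            raise FormatError(f"XMAP line {lineno}: empty alignment pair list")
        if "LabelChannel" in cols:
            rec.channel = int(fields[cols["LabelChannel"]])
        if channel is not None:
            rec.channel = channel
        out.append(rec)
    return out


def write_xmap(alignments: Iterable[MapAlignment], dest: PathOrStream) -> None:
    stream = open_text(dest, "w")
    stream.write("# XMAP File Version:\t0.2\n")
    stream.write(
        "#h XmapEntryID\tQryContigID\tRefContigID\tQryStartPos\tQryEndPos\t"
        "RefStartPos\tRefEndPos\tOrientation\tConfidence\tHitEnum\tQryLen\t"
        "RefLen\tLabelChannel\tAlignment\n"
    )
    for a in alignments:
        if a.is_reverse:  # raw dialect stores a descending query span
            qs, qe = a.query_end_bp, a.query_start_bp
            sym = "-"
        else:
            qs, qe = a.query_start_bp, a.query_end_bp
            sym = "+"
        pair_str = "".join(f"({r},{q})" for r, q in a.pairs)
        stream.write(
            f"{a.entry_id}\t{a.query_map_id}\t{a.anchor_id}\t{qs:.1f}\t{qe:.1f}\t"
            f"{a.anchor_start_bp:.1f}\t{a.anchor_end_bp:.1f}\t{sym}\t"
            f"{a.confidence:.2f}\t{len(a.pairs)}M\t{a.query_len_bp:.1f}\t"
            f"{a.anchor_len_bp:.1f}\t{a.channel}\t{pair_str}\n"
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: PathOrStream) -> dict[str, str]:
    """Read FASTA into an ordered name->sequence mapping.

    Names are truncated at the first whitespace; duplicate names and empty
    sequences are errors.
    """
    stream = open_text(source)
    records: dict[str, str] = {}
    for rec in SeqIO.parse(stream, "fasta"):
        name = rec.id
        if name in records:
            raise FormatError(f"duplicate sequence name {name!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {name!r}")
        records[name] = seq
    return records


def write_fasta(
    records: Mapping[str, str] | Iterable[tuple[str, str]],
    dest: PathOrStream,
    line_width: int = 80,
) -> None:
    stream = open_text(dest, "w")
    items = records.items() if isinstance(records, Mapping) else records
    for name, seq in items:
        stream.write(f">{name}\n")
        for i in range(0, len(seq), line_width):
            stream.write(seq[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------

def plans_to_agp_rows(plans: Sequence) -> list[AgpRow]:
    """Flatten ScaffoldPlans into AGP rows with tiling object coordinates."""
    rows: list[AgpRow] = []
    for plan in plans:
        cursor = 1
        for part_number, part in enumerate(plan.parts, start=1):
            if part.is_gap:
                if part.length < 1:
                    raise ValueError(f"{plan.name}: gap length {part.length} < 1")
                rows.append(AgpRow(
                    object_name=plan.name,
                    object_start=cursor,
                    object_end=cursor + part.length - 1,
                    part_number=part_number,
                    component_type="N",
                    gap_length=part.length,
                ))
            else:
                if part.length < 1:
                    raise ValueError(
                        f"{plan.name}: zero-length slice of {part.component}"
                    )
                rows.append(AgpRow(
                    object_name=plan.name,
                    object_start=cursor,
                    object_end=cursor + part.length - 1,
                    part_number=part_number,
                    component_type="W",
                    component_name=part.component,
                    component_start=part.start,
                    component_end=part.end,
                    strand=part.strand,
                ))
            cursor += part.length
    return rows


def write_agp(plans: Sequence, dest: PathOrStream) -> None:
    """Write ScaffoldPlans as AGP v2.1."""
    stream = open_text(dest, "w")
    stream.write("##agp-version\t2.1\n")
    for r in plans_to_agp_rows(plans):
        if r.component_type == "W":
            tail = (f"{r.component_name}\t{r.component_start}\t{r.component_end}\t"
                    f"{r.strand}")
        else:
            tail = f"{r.gap_length}\t{r.gap_type}\t{r.linkage}\t{r.evidence}"
        stream.write(
            f"{r.object_name}\t{r.object_start}\t{r.object_end}\t{r.part_number}\t"
            f"{r.component_type}\t{tail}\n"
        )


def read_agp(source: PathOrStream) -> list[AgpRow]:
    stream = open_text(source)
    rows: list[AgpRow] = []
    for lineno, line in iter_data_lines(stream):
        f = line.split("\t")
        if len(f) < 9:
            raise FormatError(f"AGP line {lineno}: expected 9 columns")
        base = dict(
            object_name=f[0], object_start=int(f[1]), object_end=int(f[2]),
            part_number=int(f[3]), component_type=f[4],
        )
        if f[4] == "W":
            rows.append(AgpRow(**base, component_name=f[5],
                               component_start=int(f[6]), component_end=int(f[7]),
                               strand=f[8]))
        elif f[4] == "N":
            rows.append(AgpRow(**base, gap_length=int(f[5]), gap_type=f[6],
                               linkage=f[7], evidence=f[8]))
        else:
            raise FormatError(f"AGP line {lineno}: unsupported component type {f[4]!r}")
    return rows


def agp_to_sequences(rows: Sequence[AgpRow], contigs: Mapping[str, str]) -> dict[str, str]:
    """Rebuild scaffold sequences from AGP rows + input contigs.

    Independent of the FASTA writer; used to cross-check that the emitted
    FASTA and AGP describe the same assembly.
    """
    out: dict[str, list[str]] = {}
    cursors: dict[str, int] = {}
    for r in rows:
        parts = out.setdefault(r.object_name, [])
        expect = cursors.get(r.object_name, 1)
        if r.object_start != expect:
            raise FormatError(
                f"{r.object_name}: object coordinates do not tile at part {r.part_number}"
            )
        if r.component_type == "N":
            if r.object_end - r.object_start + 1 != r.gap_length:
                raise FormatError(f"{r.object_name}: gap length mismatch")
            parts.append("N" * r.gap_length)
        else:
            seq = contigs[r.component_name][r.component_start - 1 : r.component_end]
            if len(seq) != r.object_end - r.object_start + 1:
                raise FormatError(
                    f"{r.object_name}: component span does not match object span"
                )
            parts.append(revcomp(seq) if r.strand == "-" else seq)
        cursors[r.object_name] = r.object_end + 1
    return {name: "".join(parts) for name, parts in out.items()}
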