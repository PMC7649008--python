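"""Small shared helpers: rounding, reverse complement, stream opening."""

from __future__ import annotations

import gzip
import io
import math
from pathlib import Path
from typing import IO, Iterator, Union

PathOrStream = Union[str, Path, IO[str]]

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from lower (0.5 -> 1).

    Fractional bp coordinates from optical maps are converted to sequence
    indices at exactly one point (slice time); this is that conversion.
    """
    return int(math.floor(x + 0.5))


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def open_text(source: PathOrStream, mode: str = "r") -> IO[str]:
    """Open a path (plain or .gz) as a text stream; pass streams through."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, mode + "b"))  # type: ignore[arg-type]
    return open(path, mode)


def iter_data_lines(stream: IO[str]) -> Iterator[tuple[int, str]]:
    """Yield (1-based line number, line) for non-comment, non-blank lines."""
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line
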