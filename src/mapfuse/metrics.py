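"""Assembly contiguity statistics and the junction-decision census.

NX here is defined on the assembly's own total length (the length of the
sequence at which the cumulative sorted-descending length first reaches X%
of the total), not against an external reference; auN is the
area-under-the-Nx-curve statistic sum(L_i^2) / sum(L_i).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scaffolder import JunctionDecision


@dataclass(frozen=True)
class AssemblyStats:
    """Core contiguity numbers, recomputable from the length multiset."""

    total_bp: int
    n_sequences: int
    n50: int
    l50: int
    n90: int
    l90: int
    aun: float
    n_bases: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def _nx(sorted_desc: Sequence[int], total: int, x: int) -> tuple[int, int]:
    threshold = total * x / 100.0
    cum = 0
    for rank, length in enumerate(sorted_desc, start=1):
        cum += length
        if cum >= threshold:
            return length, rank
    return sorted_desc[-1], len(sorted_desc)


def length_stats(lengths: Iterable[int], n_bases: int = 0) -> AssemblyStats:
    """N50/L50, N90/L90 and auN from a multiset of sequence lengths."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        raise ValueError("length_stats requires a non-empty length list")
    if ls[-1] <= 0:
        raise ValueError("lengths must be positive")
    total = sum(ls)
    n50, l50 = _nx(ls, total, 50)
    n90, l90 = _nx(ls, total, 90)
    aun = sum(x * x for x in ls) / total
    return AssemblyStats(total_bp=total, n_sequences=len(ls), n50=n50, l50=l50,
                 n90=n90, l90=l90, aun=aun, n_bases=n_bases)


def assembly_stats(records: Mapping[str, str]) -> AssemblyStats:
    """Scaffold-level stats for a name->sequence mapping, counting Ns."""
    lengths = [len(s) for s in records.values()]
    n_bases = sum(s.count("N") for s in records.values())
    return length_stats(lengths, n_bases=n_bases)


def scaffolds_to_contigs(records: Mapping[str, str] | Iterable[str]) -> list[int]:
    """Contig lengths after splitting every scaffold at each run of Ns."""
    seqs = records.values() if isinstance(records, Mapping) else records
    lengths: list[int] = []
    for seq in seqs:
        for run in seq.split("N"):
            if run:
                lengths.append(len(run))
    return lengths


def decisions_to_frame(decisions: Sequence[JunctionDecision]) -> pd.DataFrame:
    """The per-junction decision report as a tidy table."""
    cols = ["anchor_id", "left", "right", "kind", "channel", "label_id", "g",
            "emitted_gap", "score", "removed_left", "removed_right", "note"]
    rows = [{c: getattr(d, c) for c in cols} for d in decisions]
    return pd.DataFrame(rows, columns=cols)


def junction_census(decisions: Sequence[JunctionDecision] | pd.DataFrame) -> dict:
    """Counts by decision kind plus overlap-size and gap bookkeeping.

    ``duplicated_bases_removed`` totals the bases trimmed at fusion
    junctions (one copy of each duplicated region); ``overlap_sizes`` lists
    the removed-duplication size per fused junction.
    """
    if isinstance(decisions, pd.DataFrame):
        frame = decisions
    else:
        frame = decisions_to_frame(decisions)
    counts = frame["kind"].value_counts().to_dict() if len(frame) else {}
    fused = frame[frame["kind"].isin(["fuse_at_label", "fuse_by_alignment"])] \
        if len(frame) else frame
    overlap_sizes = ((fused["removed_left"].fillna(0) +
                      fused["removed_right"].fillna(0)).astype(int).tolist()
                     if len(frame) else [])
    gaps = frame[frame["kind"] == "sized_gap"] if len(frame) else frame
    total_gap = int(gaps["emitted_gap"].fillna(0).sum()) if len(frame) else 0
    removed = int(frame["removed_left"].fillna(0).sum()
                  + frame["removed_right"].fillna(0).sum()) if len(frame) else 0
    return {
        "counts": {k: int(v) for k, v in counts.items()},
        "overlap_sizes": overlap_sizes,
        "duplicated_bases_removed": int(sum(overlap_sizes)),
        "total_removed_bases": removed,
        "total_emitted_gap_bases": total_gap,
    }
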