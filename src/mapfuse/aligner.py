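"""Local sequence alignment with a BLAT-comparable score.

The junction-rescue step needs the best local alignment of two ~30 kb
windows under the scoring scheme match +1, mismatch -1, gap-open -1,
gap-extend 0 (a gap run of any length costs 1), so that the published
score threshold for merging transfers directly.

Two execution paths:

* small problems (product of lengths under ``full_dp_max_cells``) are solved
  exactly — full Smith-Waterman/Gotoh over the whole matrix;
* large problems use seed-and-extend in the BLAT style: exact k-mer seeds
  (default k=11) are merged per diagonal, extended to maximal gapless
  segments with an X-drop rule, and colinear segments are chained with one
  gap-open penalty per join.

Restricting large-window alignments to seed-derived gapless segments is what
keeps unrelated windows at low scores: under free gap extension an
unrestricted optimal path through two random 30 kb windows would chain
thousands of short spurious match runs and exceed any fixed threshold,
which is not how a seed-based aligner behaves.

The free-extension scheme makes the exact-DP row recurrence a running
maximum, so each DP row is a handful of vectorized numpy operations.  ``N``
never matches anything, including another ``N``.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i


class ConfigurationError(RuntimeError):
    """An external backend is requested but not usable."""


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of two windows; spans are 1-based inclusive."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    matches: int
    mismatches: int
    gap_opens: int


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -1  # gap extension is free
    seed_k: int = 11
    xdrop: int = 20
    full_dp_max_cells: int = 4_000_000
    max_window_bp: int = 300_000  # hard cap: 10x the default rescue window


DEFAULT_PARAMS = AlignParams()

_NEG = -(2**30)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _dp(a: np.ndarray, b: np.ndarray, jlo: np.ndarray, jhi: np.ndarray,
        p: AlignParams) -> LocalAlignment | None:
    """Gotoh local alignment over per-row contiguous column windows.

    ``jlo[i]``/``jhi[i]`` (1-based, inclusive) bound the columns explored in
    row ``i`` (index 1..m).  With the full window on every row this is exact
    Smith-Waterman under the free-extension scheme; with a band it is the
    extension stage of seed-and-extend.

    Free gap extension collapses the gap states to running maxima: within a
    row, E(i,j) = max_{j'<j} H(i,j') - 1, and the running maximum of H
    equals the running maximum of the gap-free cell value, so one
    ``np.maximum.accumulate`` per row suffices.  Column-wise the same holds
    via a per-column best-so-far array.
    """
    m, n = len(a), len(b)
    colbest = np.full(n + 2, _NEG, dtype=np.int32)  # max H(i',j) over i'<i
    colarg = np.zeros(n + 2, dtype=np.int32)
    prev_H = np.zeros(0, dtype=np.int32)
    prev_lo = 1
    rows_ptr: dict[int, np.ndarray] = {}
    rows_earg: dict[int, np.ndarray] = {}
    rows_farg: dict[int, np.ndarray] = {}
    rows_lo: dict[int, int] = {}
    rows_s: dict[int, np.ndarray] = {}
    best = (0, 0, 0)  # score, i, j

    for i in range(1, m + 1):
        lo, hi = int(jlo[i]), int(jhi[i])
        if lo > hi:
            prev_H = np.zeros(0, dtype=np.int32)
            prev_lo = 1
            continue
        w = hi - lo + 1
        js = np.arange(lo, hi + 1)
        s = np.where((b[lo - 1 : hi] == a[i - 1]) & (a[i - 1] < 4),
                     p.match, p.mismatch).astype(np.int32)
        # H(i-1, j-1) for j in window; 0 outside the previous row's window
        diag_src = np.zeros(w, dtype=np.int32)
        if prev_H.size:
            src_j = js - 1  # absolute column of the diagonal predecessor
            valid = (src_j >= prev_lo) & (src_j <= prev_lo + prev_H.size - 1)
            diag_src[valid] = prev_H[src_j[valid] - prev_lo]
        diag = diag_src + s
        F = colbest[lo : hi + 1] + p.gap_open
        farg = colarg[lo : hi + 1].copy()
        base = np.maximum(0, np.maximum(diag, F))
        ptr = np.zeros(w, dtype=np.int8)          # 0 stop, 1 diag, 2 F, 3 E
        ptr[F == base] = 2
        ptr[diag == base] = 1                      # prefer diagonal on ties
        ptr[base == 0] = 0
        run = np.maximum.accumulate(base)
        cand = np.where(base == run, np.arange(w, dtype=np.int32), -1)
        rarg = np.maximum.accumulate(cand)
        E = np.empty(w, dtype=np.int32)
        E[0] = _NEG
        E[1:] = run[:-1] + p.gap_open
        earg = np.empty(w, dtype=np.int32)
        earg[0] = 0
        earg[1:] = rarg[:-1]
        H = np.maximum(base, E)
        use_e = E > base
        ptr[use_e] = 3
        rows_ptr[i] = ptr
        rows_earg[i] = earg
        rows_farg[i] = farg
        rows_s[i] = s
        rows_lo[i] = lo
        rmax = int(H.max(initial=0))
        if rmax > best[0]:
            j_at = int(np.argmax(H))
            best = (rmax, i, lo + j_at)
        upd = H > colbest[lo : hi + 1]
        colarg[lo : hi + 1][upd] = i
        np.maximum(colbest[lo : hi + 1], H, out=colbest[lo : hi + 1])
        prev_H, prev_lo = H, lo

    score, bi, bj = best
    if score <= 0:
        return None
    # traceback
    i, j = bi, bj
    a_end, b_end = bi, bj
    matches = mismatches = gap_opens = 0
    a_start, b_start = bi, bj
    while True:
        lo = rows_lo[i]
        code = int(rows_ptr[i][j - lo])
        if code == 0:
            a_start, b_start = i + 1, j + 1
            break
        if code == 1:
            if int(rows_s[i][j - lo]) == p.match:
                matches += 1
            else:
                mismatches += 1
            a_start, b_start = i, j
            ni, nj = i - 1, j - 1
            if ni == 0 or ni not in rows_lo or not (
                rows_lo[ni] <= nj <= rows_lo[ni] + len(rows_ptr[ni]) - 1
            ):
                break
            i, j = ni, nj
        elif code == 2:
            gap_opens += 1
            i = int(rows_farg[i][j - lo])
        else:
            gap_opens += 1
            j = lo + int(rows_earg[i][j - lo])
    return LocalAlignment(score=score, a_start=a_start, a_end=a_end,
                          b_start=b_start, b_end=b_end, matches=matches,
                          mismatches=mismatches, gap_opens=gap_opens)


def _seed_hits(a: np.ndarray, b: np.ndarray, k: int) -> dict[int, list[tuple[int, int]]]:
    """Merged exact k-mer seed runs per diagonal.

    Returns diagonal (d = i - j, 0-based) -> list of merged seed intervals
    ``(i_start, i_end)`` on sequence a (0-based, end exclusive).
    """
    if len(a) < k or len(b) < k:
        return {}
    index: dict[bytes, list[int]] = {}
    bb = b.tobytes()
    for j in range(len(b) - k + 1):
        kmer = bb[j : j + k]
        if 4 in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    raw: dict[int, list[int]] = {}
    ab = a.tobytes()
    for i in range(len(a) - k + 1):
        hits = index.get(ab[i : i + k])
        if not hits:
            continue
        for j in hits:
            raw.setdefault(i - j, []).append(i)
    merged: dict[int, list[tuple[int, int]]] = {}
    for d, starts in raw.items():
        starts.sort()
        runs: list[tuple[int, int]] = []
        run_lo, run_hi = starts[0], starts[0] + k
        for i in starts[1:]:
            if i <= run_hi:  # overlapping/adjacent seeds on the diagonal
                run_hi = max(run_hi, i + k)
            else:
                runs.append((run_lo, run_hi))
                run_lo, run_hi = i, i + k
        runs.append((run_lo, run_hi))
        merged[d] = runs
    return merged


@dataclass(frozen=True)
class _Hsp:
    a_lo: int  # 0-based inclusive
    a_hi: int  # 0-based exclusive
    d: int     # diagonal: b index = a index - d
    score: int
    matches: int
    mismatches: int


def _extend_gapless(a: np.ndarray, b: np.ndarray, d: int, lo: int, hi: int,
                    p: AlignParams) -> _Hsp:
    """X-drop gapless extension of a seed run [lo, hi) on diagonal d."""
    eq = lambda i: a[i] == b[i - d] and a[i] < 4  # noqa: E731
    # right extension
    best_hi, best_sc, sc = hi, 0, 0
    i = hi
    limit = min(len(a), len(b) + d)
    while i < limit and sc > best_sc - p.xdrop:
        sc += p.match if eq(i) else p.mismatch
        i += 1
        if sc > best_sc:
            best_sc, best_hi = sc, i
    # left extension
    best_lo, best_sc, sc = lo, 0, 0
    i = lo - 1
    floor = max(0, d)
    while i >= floor and sc > best_sc - p.xdrop:
        sc += p.match if eq(i) else p.mismatch
        i -= 1
        if sc > best_sc:
            best_sc, best_lo = sc, i + 1
    seg_a = a[best_lo:best_hi]
    seg_b = b[best_lo - d : best_hi - d]
    matches = int(np.count_nonzero((seg_a == seg_b) & (seg_a < 4)))
    mismatches = (best_hi - best_lo) - matches
    score = matches * p.match + mismatches * p.mismatch
    return _Hsp(best_lo, best_hi, d, score, matches, mismatches)


def _chain_hsps(hsps: list[_Hsp], p: AlignParams) -> LocalAlignment | None:
    """Best colinear chain of gapless segments; each join costs one gap open."""
    if not hsps:
        return None
    hsps = sorted(hsps, key=lambda h: (h.a_lo, h.a_lo - h.d))
    n = len(hsps)
    best_chain = [h.score for h in hsps]
    prev = [-1] * n
    for i, h in enumerate(hsps):
        for j in range(i):
            g = hsps[j]
            if g.a_hi <= h.a_lo and g.a_hi - g.d <= h.a_lo - h.d:
                # a join crosses unaligned sequence on at least one side and
                # costs one gap open, unless the segments abut exactly
                abutting = g.a_hi == h.a_lo and g.d == h.d
                cand = best_chain[j] + h.score + (0 if abutting else p.gap_open)
                if cand > best_chain[i]:
                    best_chain[i] = cand
                    prev[i] = j
    end = max(range(n), key=lambda i: best_chain[i])
    if best_chain[end] <= 0:
        return None
    chain = []
    i = end
    while i != -1:
        chain.append(hsps[i])
        i = prev[i]
    chain.reverse()
    matches = sum(h.matches for h in chain)
    mismatches = sum(h.mismatches for h in chain)
    gap_opens = 0
    for g, h in zip(chain, chain[1:]):
        if not (g.a_hi == h.a_lo and g.d == h.d):
            gap_opens += 1
    first, last = chain[0], chain[-1]
    return LocalAlignment(
        score=matches * p.match + mismatches * p.mismatch + gap_opens * p.gap_open,
        a_start=first.a_lo + 1, a_end=last.a_hi,
        b_start=first.a_lo - first.d + 1, b_end=last.a_hi - last.d,
        matches=matches, mismatches=mismatches, gap_opens=gap_opens,
    )


def local_align(window_a: str, window_b: str,
                params: AlignParams = DEFAULT_PARAMS) -> LocalAlignment | None:
    """Best local alignment of two windows, or None when nothing positive.

    Exact DP for small inputs; seed-and-extend with banded extension for
    large ones.  Raises ValueError when a window exceeds the hard cap.
    """
    if not window_a or not window_b:
        raise ValueError("alignment windows must be non-empty")
    if len(window_a) > params.max_window_bp or len(window_b) > params.max_window_bp:
        raise ValueError(
            f"window exceeds hard cap of {params.max_window_bp} bp"
        )
    a, b = _encode(window_a), _encode(window_b)
    m, n = len(a), len(b)
    if (m + 1) * (n + 1) <= params.full_dp_max_cells:
        jlo = np.ones(m + 1, dtype=np.int64)
        jhi = np.full(m + 1, n, dtype=np.int64)
        return _dp(a, b, jlo, jhi, params)
    seed_runs = _seed_hits(a, b, params.seed_k)
    if not seed_runs:
        return None
    hsps: list[_Hsp] = []
    for d in sorted(seed_runs):
        extended: list[_Hsp] = []
        for lo, hi in seed_runs[d]:
            if extended and lo < extended[-1].a_hi:
                continue  # swallowed by the previous extension
            extended.append(_extend_gapless(a, b, d, lo, hi, params))
        hsps.extend(h for h in extended if h.score > 0)
    best = _chain_hsps(hsps, params)
    return best if best is not None and best.score > 0 else None


# ---------------------------------------------------------------------------
# External BLAT backend
# ---------------------------------------------------------------------------

def _parse_psl(text: str) -> LocalAlignment | None:
    """Best hit from (headerless) PSL; score = matches - mismatches - gap opens."""
    best: LocalAlignment | None = None
    for line in text.splitlines():
        f = line.split("\t")
        if len(f) < 17 or not f[0].isdigit():
            continue
        matches, mismatches = int(f[0]), int(f[1])
        rep = int(f[2])
        q_gap, t_gap = int(f[4]), int(f[6])
        score = matches + rep - mismatches - q_gap - t_gap
        hit = LocalAlignment(
            score=score,
            a_start=int(f[11]) + 1, a_end=int(f[12]),
            b_start=int(f[15]) + 1, b_end=int(f[16]),
            matches=matches + rep, mismatches=mismatches,
            gap_opens=q_gap + t_gap,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def external_blat_adapter(window_a: str, window_b: str,
                          blat_path: str = "blat") -> LocalAlignment | None:
    """Run an external ``blat`` binary on the two windows and parse its PSL.

    Provided for users who want bit-for-bit fidelity with the published
    workflow; the builtin backend is the default and needs no external
    executable.
    """
    exe = shutil.which(blat_path)
    if exe is None:
        raise ConfigurationError(
            f"BLAT executable {blat_path!r} not found; use the builtin aligner "
            "backend instead (aligner.local_align)"
        )
    with tempfile.TemporaryDirectory() as tmp:
        tmpd = Path(tmp)
        qry, ref, out = tmpd / "a.fa", tmpd / "b.fa", tmpd / "out.psl"
        qry.write_text(f">a\n{window_a}\n")
        ref.write_text(f">b\n{window_b}\n")
        subprocess.run(
            [exe, str(ref), str(qry), str(out), "-out=psl", "-noHead"],
            check=True, capture_output=True,
        )
        return _parse_psl(out.read_text())
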