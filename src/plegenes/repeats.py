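"""Detection of long inverted (reverse-complement) repeat pairs in promoters.

A repeat pair is two equal-length, non-overlapping segments where the first
is the reverse complement of the second up to a mismatch density of
``max_mismatch_rate``. Such pairs can base-pair into a stem-loop; the
*stem* is the copy length and the *loop* is the separation
``start(copy2) - end(copy1)`` on the signed promoter scale (+1 = A of the
start codon, no position 0).

Geometry: a pair in lock-step extension lives on one anti-diagonal
``a = start(copy1) + end(copy2)`` of the sequence-vs-complement comparison,
so pairs are runs along anti-diagonals. A reported pair is a *maximal
scoring subsequence* (Ruzzo-Tompa) of the match profile with mismatches
penalized at the budget-neutral rate, which keeps planted repeats at their
exact length instead of absorbing chance matches in the flanks. The fast
finder visits only anti-diagonals hit by an exact k-mer seed (guaranteed to
exist for the default budget); the brute-force oracle enumerates every
anti-diagonal of small sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import complement, revcomp


@dataclass(frozen=True)
class RepeatPair:
    """One inverted-repeat pair, coordinates on the signed promoter scale."""

    copy1: tuple  # (start, end), start <= end <= -1
    copy2: tuple
    length: int
    mismatches: int

    @property
    def separation(self) -> int:
        """Signed-coordinate loop length: start(copy2) - end(copy1)."""
        return self.copy2[0] - self.copy1[1]


def _budget(rate: float, length: int) -> int:
    return int(rate * length + 1e-9)


def _ruzzo_tompa(scores):
    """All maximal scoring subsequences (Ruzzo & Tompa); (start, end) 0-based."""
    segs: list = []  # [start, end, Lcum, Rcum]
    cum = 0.0
    for i, x in enumerate(scores):
        left = cum
        cum += x
        if x <= 0:
            continue
        cur = [i, i, left, cum]
        while True:
            j = len(segs) - 1
            while j >= 0 and segs[j][2] >= cur[2]:
                j -= 1
            if j < 0 or segs[j][3] >= cur[3]:
                segs.append(cur)
                break
            cur = [segs[j][0], cur[1], segs[j][2], cur[3]]
            del segs[j:]
    return [(s, e) for s, e, _, _ in segs]


def _maximal_runs(match: np.ndarray, min_len: int, rate: float):
    """Maximal high-identity runs in a boolean match vector.

    Runs are the maximal scoring subsequences of the +1 (match) /
    -(1-rate)/rate (mismatch) score profile, so a run tolerates interior
    mismatches up to a density of ``rate`` but never extends through
    lower-identity flanks; at rate 0 runs are the clean match blocks.
    Returns (start, end, mismatches) tuples, 0-based inclusive, for runs of
    length >= min_len.

    Speed: by pigeonhole every qualifying run contains an uninterrupted
    match stretch of the guaranteed seed length, so vectors without such a
    stretch are rejected without scanning.
    """
    n = int(match.size)
    if n == 0:
        return []
    match_pos = np.flatnonzero(match)
    if match_pos.size < min_len * (1.0 - rate) - 1:
        return []

    # quick reject: need one clean stretch of at least k_req somewhere
    k_req = _guaranteed_seed_k(min_len, rate)
    breaks = np.flatnonzero(np.diff(match_pos) > 1)
    seg_start = np.concatenate([[0], breaks + 1])
    seg_end = np.concatenate([breaks, [match_pos.size - 1]])
    block_lens = match_pos[seg_end] - match_pos[seg_start] + 1
    if not np.any(block_lens >= k_req):
        return []

    if rate <= 0:
        runs = [
            (int(match_pos[s]), int(match_pos[e]))
            for s, e, ln in zip(seg_start, seg_end, block_lens)
            if ln >= min_len
        ]
        return [(s, e, 0) for s, e in runs]

    penalty = (1.0 - rate) / rate
    scores = np.where(match, 1.0, -penalty)
    out = []
    for s, e in _ruzzo_tompa(scores.tolist()):
        if e - s + 1 >= min_len:
            cnt = int(np.count_nonzero(~match[s : e + 1]))
            out.append((s, e, cnt))
    return out


def _scan_diagonals(seq: str, diagonals, min_len: int, rate: float, offset: int):
    """Enumerate maximal pairs on the given anti-diagonals."""
    n = len(seq)
    sb = np.frombuffer(seq.encode(), dtype=np.uint8)
    cb = np.frombuffer(complement(seq).encode(), dtype=np.uint8)
    pairs = []
    seen = set()
    for a in diagonals:
        p_lo = max(0, a - n + 1)
        p_hi = (a - 1) // 2
        if p_hi - p_lo + 1 < min_len:
            continue
        # match[p] = seq[p] == complement(seq[a - p]) for p in [p_lo, p_hi]
        window = cb[a - p_hi : a - p_lo + 1][::-1]
        match = sb[p_lo : p_hi + 1] == window
        for s, e, cnt in _maximal_runs(match, min_len, rate):
            p1, p2 = s + p_lo, e + p_lo
            key = (a, p1, p2)
            if key in seen:
                continue
            seen.add(key)
            c1 = (offset + p1, offset + p2)
            c2 = (offset + a - p2, offset + a - p1)
            pairs.append(
                RepeatPair(copy1=c1, copy2=c2, length=p2 - p1 + 1, mismatches=cnt)
            )
    pairs.sort(key=lambda r: (-r.length, r.copy1[0]))
    return pairs


def _guaranteed_seed_k(min_len: int, rate: float) -> int:
    """Largest k such that every feasible run >= min_len holds an exact k-mer."""
    t0 = _budget(rate, min_len)
    k = (min_len - t0) // (t0 + 1)
    if rate > 0:
        k = min(k, max(1, int((1.0 - rate) / rate) - 1))
    return max(1, k)


def find_inverted_repeats(
    promoter: str,
    min_len: int = 100,
    max_mismatch_rate: float = 0.02,
    offset: int | None = None,
) -> list[RepeatPair]:
    """All maximal inverted-repeat pairs of length >= ``min_len``.

    ``offset`` is the signed promoter coordinate of base 1 (default: the
    sequence ends at -1, so offset = -len(promoter)). Pairs are sorted by
    length descending. Overlapping (hairpin-contiguous) copies are excluded.
    """
    seq = promoter.upper()
    n = len(seq)
    if offset is None:
        offset = -n
    if n < 2 * min_len or min_len < 1:
        return []
    k = min(20, _guaranteed_seed_k(min_len, max_mismatch_rate))
    if k < 8:
        # budget too loose for seeding guarantees: scan every anti-diagonal
        diagonals = range(1, 2 * n - 2)
    else:
        index: dict = {}
        for i in range(n - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        cands = set()
        for kmer, positions in index.items():
            partners = index.get(revcomp(kmer))
            if not partners:
                continue
            for i in positions:
                for j in partners:
                    cands.add(i + j + k - 1)
        diagonals = sorted(cands)
    return _scan_diagonals(seq, diagonals, min_len, max_mismatch_rate, offset)


def brute_force_inverted_repeats(
    seq: str,
    min_len: int,
    max_mismatch_rate: float = 0.02,
    offset: int | None = None,
) -> list[RepeatPair]:
    """Exhaustive all-anti-diagonal enumeration; test oracle for small inputs."""
    if len(seq) > 2000:
        raise ValueError("brute-force oracle refuses sequences > 2000 nt")
    n = len(seq)
    if offset is None:
        offset = -n
    if n < 2 * min_len or min_len < 1:
        return []
    return _scan_diagonals(seq.upper(), range(1, 2 * n - 2), min_len, max_mismatch_rate, offset)


def loop_report(pairs: list[RepeatPair], fmt: str = "tsv") -> str:
    """Stem/loop summary of repeat pairs as TSV (default) or JSON."""
    import json

    rows = [
        {
            "copy1_start": p.copy1[0],
            "copy1_end": p.copy1[1],
            "copy2_start": p.copy2[0],
            "copy2_end": p.copy2[1],
            "stem_len": p.length,
            "loop_len": p.separation,
            "mismatches": p.mismatches,
        }
        for p in pairs
    ]
    if fmt == "json":
        return json.dumps(rows, indent=2)
    header = "copy1_start\tcopy1_end\tcopy2_start\tcopy2_end\tstem_len\tloop_len\tmismatches"
    lines = [header] + [
        "\t".join(str(r[k]) for k in header.split("\t")) for r in rows
    ]
    return "\n".join(lines) + "\n"
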