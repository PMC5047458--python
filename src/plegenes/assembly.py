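"""BAC clone processing: vector trimming, end-overlap detection, ordering.

Overlapping clone ends are how the gene cluster's layout is deduced: if the
3' end of clone A matches the 5' end of clone B at high identity, B extends
A to the right, and chaining such overlaps across a set of clones
linearizes them (and the genes they carry) onto one coordinate frame.

Vector location and overlap verification use edlib (banded bit-vector edit
alignment); candidate overlaps are proposed by shared k-mers so that only
plausible clone pairs are aligned.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import edlib

from ._util import revcomp
from .errors import AmbiguousOrderError


@dataclass(frozen=True)
class TrimResult:
    insert: str
    vector_interval: tuple | None  # (start, end) 1-based on the clone, or None
    vector_found: bool
    identity: float


@dataclass(frozen=True)
class Overlap:
    clone_a: str
    clone_b: str
    end_a: str  # "3'" or "5'": which end of A carries the overlap
    end_b: str
    length: int
    identity: float
    gaps: int
    orientation: str  # "+" if B overlaps A as-is, "-" if B had to be reverse-complemented


@dataclass(frozen=True)
class CloneCluster:
    """Ordered clones on a shared frame, plus the genes they imply in order."""

    clones: tuple  # (name, offset, orientation) sorted by offset
    gene_order: tuple
    span: int


def _cigar_stats(cigar: str):
    """(columns, identities, gaps) from an edlib extended cigar."""
    columns = identities = gaps = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        k = int(num)
        num = ""
        columns += k
        if ch == "=":
            identities += k
        elif ch in "ID":
            gaps += k
    return columns, identities, gaps


def trim_vector(clone_seq: str, vector_seq: str, min_identity: float = 95.0) -> TrimResult:
    """Locate and excise the single best vector occurrence from a clone.

    Both orientations of the vector are tried (infix alignment). When no hit
    reaches ``min_identity`` the input is returned unchanged and flagged.
    """
    if not vector_seq:
        raise ValueError("vector sequence must be non-empty")
    clone = clone_seq.upper()
    best = None
    for vec in (vector_seq.upper(), revcomp(vector_seq.upper())):
        res = edlib.align(vec, clone, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        ident = 100.0 * (len(vec) - res["editDistance"]) / len(vec)
        if best is None or ident > best[0]:
            best = (ident, res["locations"][0])
    if best is None or best[0] < min_identity:
        return TrimResult(insert=clone_seq, vector_interval=None, vector_found=False,
                          identity=best[0] if best else 0.0)
    ident, (s, e) = best
    return TrimResult(
        insert=clone[:s] + clone[e + 1 :],
        vector_interval=(s + 1, e + 1),
        vector_found=True,
        identity=round(ident, 1),
    )


def _index_kmers(seq: str, k: int, stride: int = 1) -> dict:
    index: dict = defaultdict(list)
    for i in range(0, len(seq) - k + 1, stride):
        index[seq[i : i + k]].append(i)
    return index


def _candidate_offset(index_a: dict, seq_b: str, k: int, min_hits: int = 3):
    """Most-supported alignment diagonal (posA - posB) from shared k-mers."""
    votes: Counter = Counter()
    for j in range(0, len(seq_b) - k + 1):
        for i in index_a.get(seq_b[j : j + k], ()):
            votes[i - j] += 1
    if not votes:
        return None
    offset, hits = votes.most_common(1)[0]
    return offset if hits >= min_hits else None


def _verify_overlap(seq_a: str, seq_b: str, offset: int):
    """Align the implied suffix/prefix segments; (length, identity, gaps)."""
    if offset >= 0:
        seg_a = seq_a[offset:]
        seg_b = seq_b[: len(seg_a)]
    else:
        seg_b = seq_b[-offset:]
        seg_a = seq_a[: len(seg_b)]
    length = min(len(seg_a), len(seg_b))
    if length == 0:
        return None
    seg_a, seg_b = seg_a[:length], seg_b[:length]
    res = edlib.align(seg_a, seg_b, mode="NW", task="path")
    columns, identities, gaps = _cigar_stats(res["cigar"])
    return length, round(100.0 * identities / columns, 1), gaps


def pairwise_overlaps(
    inserts: dict,
    min_overlap: int = 2000,
    min_identity: float = 99.0,
    k: int = 31,
) -> list[Overlap]:
    """All suffix-prefix overlaps between clone inserts meeting the thresholds.

    Both relative orientations are tested; each unordered clone pair is
    reported at most once (the better orientation wins). ``inserts`` maps
    clone name to sequence.
    """
    names = sorted(inserts)
    out = []
    for ai in range(len(names)):
        na = names[ai]
        sa = inserts[na].upper()
        index_a = _index_kmers(sa, k)
        for bi in range(ai + 1, len(names)):
            nb = names[bi]
            best = None
            for orient, sb in (("+", inserts[nb].upper()), ("-", revcomp(inserts[nb].upper()))):
                offset = _candidate_offset(index_a, sb, k=k)
                if offset is None:
                    continue
                ver = _verify_overlap(sa, sb, offset)
                if ver is None:
                    continue
                length, ident, gaps = ver
                if length < min_overlap or ident < min_identity:
                    continue
                if offset >= 0:
                    end_a, end_b = "3'", "5'"
                else:
                    end_a, end_b = "5'", "3'"
                cand = Overlap(na, nb, end_a, end_b, length, ident, gaps, orient)
                if best is None or (cand.length, cand.identity) > (best.length, best.identity):
                    best = cand
            if best is not None:
                out.append(best)
    return out


def order_clones(
    overlaps: list[Overlap],
    clone_genes: dict,
    clone_lengths: dict | None = None,
    dedupe_tolerance: int = 5000,
) -> list[CloneCluster]:
    """Linearize clones into clusters along the overlap graph.

    ``clone_genes`` maps clone name -> [(gene_id, position_on_clone), ...];
    it also defines the clone universe (clones without overlaps become
    singleton clusters). Branching or cyclic overlap components raise
    :class:`AmbiguousOrderError` rather than guessing a genome order.

    The same gene seen near the same frame position in two overlapping
    clones is reported once (merged within ``dedupe_tolerance``).
    """
    clone_lengths = clone_lengths or {}
    nodes = set(clone_genes) | {o.clone_a for o in overlaps} | {o.clone_b for o in overlaps}
    adj: dict = defaultdict(list)
    for o in overlaps:
        adj[o.clone_a].append(o)
        adj[o.clone_b].append(o)

    # connected components
    seen: set = set()
    clusters = []
    for start in sorted(nodes):
        if start in seen:
            continue
        comp = [start]
        seen.add(start)
        queue = [start]
        while queue:
            u = queue.pop()
            for o in adj[u]:
                v = o.clone_b if o.clone_a == u else o.clone_a
                if v not in seen:
                    seen.add(v)
                    comp.append(v)
                    queue.append(v)
        comp_edges = {id(o) for u in comp for o in adj[u]}
        if len(comp_edges) != len(comp) - 1 or any(len(adj[u]) > 2 for u in comp):
            raise AmbiguousOrderError(comp)

        clusters.append(_linearize(comp, adj, clone_genes, clone_lengths, dedupe_tolerance))
    clusters.sort(key=lambda c: c.clones[0][0])
    return clusters


def _clone_len(name, clone_genes, clone_lengths):
    if name in clone_lengths:
        return clone_lengths[name]
    genes = clone_genes.get(name, [])
    return max((pos for _, pos in genes), default=0) + 1


def _linearize(comp, adj, clone_genes, clone_lengths, tol) -> CloneCluster:
    # assign orientations and offsets by walking the path from one end
    placed = {}  # name -> (offset, orientation)
    start = sorted(u for u in comp if len(adj[u]) <= 1)[0] if len(comp) > 1 else comp[0]
    placed[start] = (0, "+")
    queue = [start]
    while queue:
        u = queue.pop()
        off_u, ori_u = placed[u]
        len_u = _clone_len(u, clone_genes, clone_lengths)
        for o in adj[u]:
            v = o.clone_b if o.clone_a == u else o.clone_a
            if v in placed:
                continue
            len_v = _clone_len(v, clone_genes, clone_lengths)
            # orientation of v relative to the frame
            ori_v = ori_u if o.orientation == "+" else ("-" if ori_u == "+" else "+")
            # which end of u does the overlap sit on, in frame coordinates?
            end_u = o.end_a if o.clone_a == u else o.end_b
            if ori_u == "-":
                end_u = "3'" if end_u == "5'" else "5'"
            if end_u == "3'":
                off_v = off_u + len_u - o.length
            else:
                off_v = off_u - (len_v - o.length)
            placed[v] = (off_v, ori_v)
            queue.append(v)

    # canonical direction: majority of clones unflipped; flip the frame if not
    n_minus = sum(1 for _, (_, ori) in placed.items() if ori == "-")
    if n_minus * 2 > len(placed):
        span_hi = max(off + _clone_len(nm, clone_genes, clone_lengths) for nm, (off, _) in placed.items())
        placed = {
            nm: (span_hi - (off + _clone_len(nm, clone_genes, clone_lengths)),
                 "+" if ori == "-" else "-")
            for nm, (off, ori) in placed.items()
        }
    lo = min(off for off, _ in placed.values())
    placed = {nm: (off - lo, ori) for nm, (off, ori) in placed.items()}
    span = max(
        off + _clone_len(nm, clone_genes, clone_lengths) for nm, (off, ori) in placed.items()
    )

    # genes on the shared frame, deduplicated across overlapping clones
    gene_positions = []
    for nm, (off, ori) in placed.items():
        ln = _clone_len(nm, clone_genes, clone_lengths)
        for gid, pos in clone_genes.get(nm, []):
            frame_pos = off + (pos if ori == "+" else ln - pos)
            gene_positions.append((frame_pos, gid))
    gene_positions.sort()
    order = []
    for pos, gid in gene_positions:
        if order and order[-1][1] == gid and abs(pos - order[-1][0]) <= tol:
            continue
        order.append((pos, gid))

    clones = tuple(sorted(((nm, off, ori) for nm, (off, ori) in placed.items()),
                          key=lambda t: (t[1], t[0])))
    return CloneCluster(clones=clones, gene_order=tuple(g for _, g in order), span=span)
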