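"""cDNA-guided spliced alignment under the GT-AG rule.

A reference coding sequence is mapped onto genomic DNA with a two-state
dynamic program: an *exon* state with match/mismatch/gap moves, and an
*intron* state that can only be entered where the genomic dinucleotide is
``GT`` and left where it is ``AG``, for a flat, length-independent penalty,
with intron length bounded between ``min_intron`` and ``max_intron``. The
alignment is global in the cDNA and local ("fit") in the genomic sequence.

Two modes share this scoring model:

* ``full_dp`` — the exact O(n*m) dynamic program over the whole genomic
  sequence. It is the optimum by construction and serves as the oracle for
  the fast mode; practical only for small instances.
* ``anchored`` (default) — exact k-mer seeding, collinear chaining, and
  exact bounded DP (the same two-state recursion) in the windows between
  chained anchors, so boundaries and score reproduce the full DP wherever
  the optimal path passes through the anchor chain.

Ties are broken toward fewer introns (the intron count is carried as a
secondary, lexicographic score component) and then toward leftmost donor
sites.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._util import revcomp
from .errors import InvalidSpecError
from .models import GeneModel

_SCALE = 4096  # scaled score = raw * _SCALE - (number of introns)
_NEG = -(1 << 60)


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -3
    gap: int = -4
    intron_penalty: int = -10
    min_intron: int = 40
    max_intron: int = 20000
    anchor_k: int = 15
    mode: str = "anchored"

    def __post_init__(self):
        if not (self.match > 0 > self.mismatch):
            raise InvalidSpecError("need match > 0 > mismatch")
        if self.min_intron < 4:
            raise InvalidSpecError("min_intron must be >= 4")
        if self.max_intron < self.min_intron:
            raise InvalidSpecError("max_intron must be >= min_intron")
        if self.mode not in ("anchored", "full_dp"):
            raise InvalidSpecError("mode must be 'anchored' or 'full_dp'")


class _Aln(NamedTuple):
    scaled: int
    exons: tuple  # 1-based inclusive intervals on the (possibly revcomp'd) sequence
    introns: tuple
    mismatches: int
    gaps: int


# ---------------------------------------------------------------------------
# exact two-state DP
# ---------------------------------------------------------------------------


def _dp(g: str, c: str, p: AlignParams, free_start: bool = True, free_end: bool = True):
    """Exact spliced alignment of the full cDNA ``c`` against genomic ``g``.

    ``free_start``/``free_end`` control whether unaligned genomic sequence
    before/after the gene is free (fit alignment) or forbidden (fixed ends,
    used for inter-anchor refinement). Returns an ``_Aln`` or ``None`` when
    no path exists.
    """
    n, m = len(g), len(c)
    matchS = p.match * _SCALE
    mismS = p.mismatch * _SCALE
    gapS = p.gap * _SCALE
    intronS = p.intron_penalty * _SCALE - 1
    min_i, max_i = p.min_intron, p.max_intron

    tb = np.zeros((n + 1, m + 1), dtype=np.int8)
    donors: dict = {}
    ring_size = min_i + 2
    ring = [[_NEG] * (m + 1) for _ in range(ring_size)]
    row0 = ring[0]
    row0[0] = 0
    for j in range(1, m + 1):
        row0[j] = gapS * j
        tb[0, j] = 3

    gt = np.zeros(n + 1, dtype=bool)  # donor may start at position d (1-based)
    ag = np.zeros(n + 1, dtype=bool)  # acceptor may end at position i
    for d in range(1, n):
        if g[d - 1] == "G" and g[d] == "T":
            gt[d] = True
    for i in range(2, n + 1):
        if g[i - 2] == "A" and g[i - 1] == "G":
            ag[i] = True

    dqs = [deque() for _ in range(m + 1)]
    best_end = (row0[m], 0)
    prev = row0
    neg_half = _NEG // 2

    for i in range(1, n + 1):
        cur = ring[i % ring_size]
        dnew = i - min_i + 1
        if dnew >= 1 and gt[dnew]:
            src = ring[(dnew - 1) % ring_size]
            for j in range(m + 1):
                v = src[j]
                if v > neg_half:
                    dq = dqs[j]
                    while dq and dq[-1][0] < v:
                        dq.pop()
                    dq.append((v, dnew))
        lim = i - max_i + 1
        close_ok = ag[i]
        gi = g[i - 1]

        if free_start:
            cur[0] = 0
            tb[i, 0] = 5
        else:
            best = prev[0] + gapS
            mv = 2
            if close_ok:
                dq = dqs[0]
                while dq and dq[0][1] < lim:
                    dq.popleft()
                if dq and dq[0][0] + intronS > best:
                    best = dq[0][0] + intronS
                    mv = 4
                    donors[(i, 0)] = dq[0][1]
            cur[0] = best
            tb[i, 0] = mv

        for j in range(1, m + 1):
            if gi == c[j - 1] and gi != "N":
                best = prev[j - 1] + matchS
            else:
                best = prev[j - 1] + mismS
            mv = 1
            v = prev[j] + gapS
            if v > best:
                best = v
                mv = 2
            v = cur[j - 1] + gapS
            if v > best:
                best = v
                mv = 3
            if close_ok:
                dq = dqs[j]
                while dq and dq[0][1] < lim:
                    dq.popleft()
                if dq and dq[0][0] + intronS > best:
                    best = dq[0][0] + intronS
                    mv = 4
                    donors[(i, j)] = dq[0][1]
            cur[j] = best
            tb[i, j] = mv
        if free_end and cur[m] > best_end[0]:
            best_end = (cur[m], i)
        prev = cur

    if free_end:
        score, end_i = best_end
    else:
        score = ring[n % ring_size][m] if n else row0[m]
        end_i = n
    if score <= neg_half:
        return None
    return _Aln(score, *_traceback(g, c, tb, donors, end_i, m, free_start))


def _traceback(g, c, tb, donors, end_i, m, free_start):
    i, j = end_i, m
    runs = []
    run_lo = run_hi = None
    introns = []
    mismatches = gaps = 0

    def consume(pos):
        nonlocal run_lo, run_hi
        if run_lo is None:
            run_lo = run_hi = pos
        elif pos == run_lo - 1:
            run_lo = pos
        else:
            runs.append((run_lo, run_hi))
            run_lo = run_hi = pos

    while True:
        mv = tb[i, j]
        if mv == 1:
            consume(i)
            if g[i - 1] != c[j - 1] or g[i - 1] == "N":
                mismatches += 1
            i -= 1
            j -= 1
        elif mv == 2:
            consume(i)
            gaps += 1
            i -= 1
        elif mv == 3:
            gaps += 1
            j -= 1
        elif mv == 4:
            d = donors[(i, j)]
            introns.append((d, i))
            i = d - 1
        else:  # 0 (origin) or 5 (free genomic start)
            break
        if i == 0 and j == 0:
            break
        if free_start and j == 0 and tb[i, j] == 5:
            break
    if run_lo is not None:
        runs.append((run_lo, run_hi))
    runs.reverse()
    introns.reverse()
    return tuple(runs), tuple(introns), mismatches, gaps


# ---------------------------------------------------------------------------
# anchored mode
# ---------------------------------------------------------------------------


def _find_anchors(g: str, c: str, k: int):
    """Maximal exact co-diagonal k-mer runs (gs, cs, length), 0-based."""
    index: dict = {}
    for j in range(len(c) - k + 1):
        kmer = c[j : j + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(j)
    diags: dict = {}
    for i in range(len(g) - k + 1):
        hits = index.get(g[i : i + k])
        if hits:
            for j in hits:
                diags.setdefault(i - j, []).append(i)
    anchors = []
    for d, gl in diags.items():
        gl.sort()
        start = prev = gl[0]
        for x in gl[1:]:
            if x == prev + 1:
                prev = x
            else:
                anchors.append((start, start - d, prev - start + k))
                start = prev = x
        anchors.append((start, start - d, prev - start + k))
    return anchors


def _chain_anchors(anchors, p: AlignParams):
    """Collinear chaining; returns the best-scoring anchor chain, in order."""
    if len(anchors) > 4000:
        anchors = sorted(anchors, key=lambda a: -a[2])[:4000]
    anchors = sorted(anchors, key=lambda a: (a[1], a[0]))
    A = len(anchors)
    best = [a[2] * p.match for a in anchors]
    pred = [-1] * A
    for i in range(A):
        gs_i, cs_i, ln_i = anchors[i]
        for j in range(i):
            gs_j, cs_j, ln_j = anchors[j]
            if cs_i <= cs_j or gs_i <= gs_j:
                continue
            cgap = cs_i - (cs_j + ln_j)
            ggap = gs_i - (gs_j + ln_j)
            if cgap < -min(ln_i, ln_j) + 1 or ggap < -min(ln_i, ln_j) + 1:
                continue
            if cgap > 400 or ggap > p.max_intron + 200 or ggap < cgap - 60:
                continue
            eff_c, eff_g = max(cgap, 0), max(ggap, 0)
            if eff_g > eff_c + p.min_intron // 2:
                cost = -p.intron_penalty + 2 * eff_c
            else:
                cost = abs(eff_g - eff_c) * (-p.gap) + 2 * min(eff_c, eff_g)
            cand = best[j] + ln_i * p.match - cost
            if cand > best[i]:
                best[i] = cand
                pred[i] = j
    end = max(range(A), key=lambda i: (best[i], -anchors[i][1], -anchors[i][0]))
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = pred[end]
    chain.reverse()
    return chain


def _anchored(g: str, c: str, p: AlignParams):
    n, m = len(g), len(c)
    if m < p.anchor_k:
        return _dp(g, c, p, True, True)
    anchors = _find_anchors(g, c, p.anchor_k)
    if not anchors:
        return None
    chain = _chain_anchors(anchors, p)

    # trim to strictly increasing, non-overlapping anchors (both coordinates)
    trimmed = []
    for gs, cs, ln in chain:
        if trimmed:
            pgs, pcs, pln = trimmed[-1]
            delta = max(pcs + pln - cs, pgs + pln - gs, 0)
            gs += delta
            cs += delta
            ln -= delta
            if ln < 4:
                continue
        trimmed.append([gs, cs, ln])
    if not trimmed:
        return None

    pads = [max(1, min(8, (ln - 1) // 2)) for _, _, ln in trimmed]

    scaled = 0
    exons: list = []
    introns: list = []
    mismatches = gaps = 0

    def add(res: _Aln, offset: int):
        nonlocal scaled, mismatches, gaps
        scaled += res.scaled
        exons.extend((s + offset, e + offset) for s, e in res.exons)
        introns.extend((s + offset, e + offset) for s, e in res.introns)
        mismatches += res.mismatches
        gaps += res.gaps

    # head (free genomic start)
    gs0, cs0, _ = trimmed[0]
    head_c = cs0 + pads[0]
    if head_c > 0:
        extra = p.max_intron if head_c >= p.anchor_k else 0
        wlo = max(0, gs0 + pads[0] - (2 * head_c + 50 + extra))
        res = _dp(g[wlo : gs0 + pads[0]], c[:head_c], p, True, False)
        if res is None:
            return None
        add(res, wlo)

    # anchor interiors and inter-anchor windows
    for idx, (gs, cs, ln) in enumerate(trimmed):
        pad = pads[idx]
        lo_g, hi_g = gs + pad, gs + ln - 1 - pad
        if hi_g >= lo_g:
            scaled += (hi_g - lo_g + 1) * p.match * _SCALE
            exons.append((lo_g + 1, hi_g + 1))
        if idx + 1 < len(trimmed):
            ngs, ncs, _ = trimmed[idx + 1]
            npad = pads[idx + 1]
            ga, gb = gs + ln - pad, ngs + npad
            ca, cb = cs + ln - pad, ncs + npad
            res = _dp(g[ga:gb], c[ca:cb], p, False, False)
            if res is None:
                return None
            add(res, ga)

    # tail (free genomic end)
    gsl, csl, lnl = trimmed[-1]
    padl = pads[-1]
    tail_c = m - (csl + lnl - padl)
    if tail_c > 0:
        extra = p.max_intron if tail_c >= p.anchor_k else 0
        ga = gsl + lnl - padl
        gb = min(n, ga + 2 * tail_c + 50 + extra)
        res = _dp(g[ga:gb], c[csl + lnl - padl :], p, False, True)
        if res is None:
            return None
        add(res, ga)

    # merge touching exon fragments
    exons.sort()
    merged = []
    for s, e in exons:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    introns.sort()
    return _Aln(scaled, tuple(merged), tuple(introns), mismatches, gaps)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _align_one_strand(g: str, c: str, p: AlignParams):
    if p.mode == "full_dp":
        return _dp(g, c, p, True, True)
    return _anchored(g, c, p)


def spliced_align(
    genomic: str,
    cdna: str,
    params: AlignParams | None = None,
    *,
    contig_id: str = "contig",
    cdna_id: str = "cdna",
) -> GeneModel:
    """Best spliced alignment of ``cdna`` over both strands of ``genomic``.

    Returns an empty :class:`GeneModel` (no exons, score 0) when no
    alignment scores above zero.
    """
    if not genomic or not cdna:
        raise ValueError("genomic and cdna must be non-empty")
    p = params or AlignParams()
    genomic = genomic.upper()
    cdna = cdna.upper()

    results = []
    for strand, seq in (("+", genomic), ("-", revcomp(genomic))):
        res = _align_one_strand(seq, cdna, p)
        if res is not None:
            results.append((res.scaled, strand == "+", strand, res, seq))
    if not results:
        return GeneModel(contig_id=contig_id, cdna_id=cdna_id)
    results.sort(key=lambda t: (t[0], t[1]), reverse=True)
    scaled, _, strand, res, seq = results[0]
    raw = -((-scaled) // _SCALE)
    if raw <= 0 or not res.exons:
        return GeneModel(contig_id=contig_id, cdna_id=cdna_id)

    n = len(genomic)
    if strand == "+":
        exons = res.exons
    else:
        exons = tuple(sorted((n - e + 1, n - s + 1) for s, e in res.exons))
    pieces = [genomic[s - 1 : e] for s, e in exons]
    cds = "".join(pieces)
    if strand == "-":
        cds = revcomp(cds)
    return GeneModel(
        contig_id=contig_id,
        strand=strand,
        exons=exons,
        cdna_id=cdna_id,
        alignment_score=raw,
        mismatch_count=res.mismatches,
        cds_sequence=cds,
    )


def annotate_contig(
    contig: str,
    cdna: str,
    params: AlignParams | None = None,
    *,
    contig_id: str = "contig",
    cdna_id: str = "cdna",
    stop_fraction: float = 0.5,
    max_genes: int = 50,
) -> list[GeneModel]:
    """Iteratively align, mask, and realign to find every gene on a contig.

    Stops when the best remaining alignment scores below ``stop_fraction``
    of the first gene's score (the genes of one family score alike; anything
    far weaker is a spurious partial hit). Models are returned sorted by
    position and named ``gene1``, ``gene2``, ...
    """
    p = params or AlignParams()
    masked = list(contig.upper())
    models: list[GeneModel] = []
    first_score = None
    while len(models) < max_genes:
        model = spliced_align(
            "".join(masked), cdna, p, contig_id=contig_id, cdna_id=cdna_id
        )
        if model.is_empty or model.alignment_score <= 0:
            break
        if first_score is None:
            first_score = model.alignment_score
        elif model.alignment_score < stop_fraction * first_score:
            break
        models.append(model)
        for i in range(model.start - 1, model.end):
            masked[i] = "N"
    models.sort(key=lambda m: m.start)
    for i, m in enumerate(models):
        m.name = f"gene{i + 1}"
    return models


# ---------------------------------------------------------------------------
# region extraction and identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UpstreamRegion:
    seq: str
    start_coord: int  # promoter coordinate of base 1 (negative; -1 is last base)
    truncated: bool


@dataclass(frozen=True)
class GeneRegions:
    upstream: UpstreamRegion
    cds: str
    introns: tuple  # transcript order, gene strand


def extract_regions(model: GeneModel, contig: str, upstream_len: int = 6000) -> GeneRegions:
    """Upstream/CDS/intron sequences of a gene model, on the gene strand.

    The upstream record runs 5' of exon 1 up to promoter position -1 (the
    base immediately before the start codon); it is truncated and flagged
    when it would run off the contig.
    """
    if model.is_empty:
        raise ValueError("cannot extract regions from an empty model")
    n = len(contig)
    if model.strand == "+":
        lo = model.start - upstream_len
        truncated = lo < 1
        up = contig[max(lo, 1) - 1 : model.start - 1]
    else:
        hi = model.end + upstream_len
        truncated = hi > n
        up = revcomp(contig[model.end : min(hi, n)])
    upstream = UpstreamRegion(seq=up, start_coord=-len(up), truncated=truncated)

    pieces = [contig[s - 1 : e] for s, e in model.exons]
    cds = "".join(pieces)
    intron_seqs = [contig[s - 1 : e] for s, e in model.introns]
    if model.strand == "-":
        cds = revcomp(cds)
        intron_seqs = [revcomp(s) for s in reversed(intron_seqs)]
    return GeneRegions(upstream=upstream, cds=cds, introns=tuple(intron_seqs))


class PercentIdentity(NamedTuple):
    percent: float
    gaps: int


def pairwise_identity(seq_a: str, seq_b: str, alphabet: str = "nt") -> PercentIdentity:
    """Global-alignment percent identity (matches / alignment columns * 100).

    Reported to 0.1%. ``alphabet`` selects nucleotide scoring or BLOSUM62
    for proteins; the identity definition is the same for both.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        seq_a = seq_a.rstrip("*")
        seq_b = seq_b.rstrip("*")
    else:
        aligner.match_score = 2
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    pct = round(100.0 * counts.identities / columns, 1)
    return PercentIdentity(percent=pct, gaps=counts.gaps)


def summary_table(models: list[GeneModel]) -> "pd.DataFrame":
    """Per-gene summary: strand plus exon and intron sizes in transcript order."""
    import pandas as pd

    rows = []
    for m in models:
        rows.append(
            {
                "gene": m.name or m.cdna_id,
                "contig": m.contig_id,
                "strand": m.strand,
                "score": m.alignment_score,
                "mismatches": m.mismatch_count,
                "exon_sizes": ",".join(map(str, m.exon_sizes())),
                "intron_sizes": ",".join(map(str, m.intron_sizes())),
            }
        )
    return pd.DataFrame(rows)
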