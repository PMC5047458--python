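"""In-silico PCR and the three-step pooled screen of a 384-well BAC library.

A primer pair amplifies a template wherever the forward primer matches one
strand and the reverse primer matches the other, facing each other within a
product-size limit. Matching is exact by default; an optional mismatch
tolerance never applies to the 3'-terminal bases, since polymerase
extension requires a matched 3' end. Thermodynamics (annealing temperature)
is carried as metadata only.

The screen mirrors the bench protocol: step 1 pools each whole plate, step
2 splits every positive plate into 24 pools of 16 clones (one pool per
column), step 3 tests the 16 wells of each positive pool singly. A well is
called positive when any panel pair yields a product within +/-5% of one of
its expected sizes (gel-based size calling is not base-exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import revcomp
from .synthetic import Library
from .tables import PrimerPair, screening_panel

SIZE_TOLERANCE = 0.05  # +/-5% product-size acceptance window


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    start: int  # 1-based inclusive; product includes both primers
    end: int
    length: int
    strand: str  # strand carrying the forward-primer hit

    def __post_init__(self):
        if self.length != self.end - self.start + 1:
            raise ValueError("amplicon length must equal end - start + 1")


@dataclass
class ScreenResult:
    step1_positive_plates: list
    step2_positive_pools: list  # (plate, column)
    step3_positive_wells: list  # (plate, row, column)
    pcr_count: int  # pooled/single templates assayed across all steps


def _exact_hits(template: str, primer: str) -> list[int]:
    hits, start = [], template.find(primer)
    while start != -1:
        hits.append(start)
        start = template.find(primer, start + 1)
    return hits


def _mismatch_hits(template: str, primer: str, max_mismatch: int, three_prime_exact: int):
    """Sliding-window primer sites with <= max_mismatch, 3' end exact."""
    n, k = len(template), len(primer)
    if n < k:
        return []
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(t, k)
    mism = (windows != p).sum(axis=1)
    tail = min(three_prime_exact, k)
    tail_ok = (windows[:, k - tail :] == p[k - tail :]).all(axis=1)
    return np.flatnonzero((mism <= max_mismatch) & tail_ok).tolist()


def _primer_sites(template, primer, max_mismatch, three_prime_exact):
    if max_mismatch <= 0:
        return _exact_hits(template, primer)
    return _mismatch_hits(template, primer, max_mismatch, three_prime_exact)


def insilico_pcr(
    template: str,
    pair: PrimerPair,
    max_product: int = 10000,
    max_mismatch: int = 0,
    three_prime_exact: int = 5,
    template_id: str = "template",
) -> list[Amplicon]:
    """All products of a primer pair on both strands of a template."""
    template = template.upper()
    amps = {}
    configs = (
        ("+", pair.forward, pair.reverse),
        ("-", pair.reverse, pair.forward),
    )
    for strand, left, right in configs:
        left_hits = _primer_sites(template, left, max_mismatch, three_prime_exact)
        if not left_hits:
            continue
        right_rc = revcomp(right)
        right_hits = _primer_sites(template, right_rc, max_mismatch, three_prime_exact)
        for i in left_hits:
            for j in right_hits:
                if j < i + len(left):
                    continue
                length = j + len(right_rc) - i
                if length > max_product:
                    continue
                amps[(i + 1, i + length)] = Amplicon(
                    template_id=template_id,
                    start=i + 1,
                    end=i + length,
                    length=length,
                    strand=strand,
                )
    return [amps[k] for k in sorted(amps)]


def _sizes_match(length: int, expected: tuple, tolerance: float = SIZE_TOLERANCE) -> bool:
    return any(abs(length - exp) <= tolerance * exp for exp in expected)


def template_is_positive(template: str, panel, **pcr_kwargs) -> bool:
    """True if any panel pair yields a product near one of its expected sizes."""
    for pair in panel:
        for amp in insilico_pcr(template, pair, **pcr_kwargs):
            if _sizes_match(amp.length, pair.expected_products):
                return True
    return False


def pool(sequences) -> tuple:
    """A pooled template set; positive iff any member amplifies."""
    return tuple(sequences)


def pool_is_positive(sequences, panel, **pcr_kwargs) -> bool:
    return any(template_is_positive(s, panel, **pcr_kwargs) for s in sequences)


def run_three_step_screen(library: Library, panel=None, **pcr_kwargs) -> ScreenResult:
    """Hierarchical pooled PCR screen: plate pools, column pools of 16, singles.

    ``pcr_count`` counts the templates assayed (one per pooled or single
    reaction set), the quantity the pooling strategy is designed to keep far
    below one reaction per well.
    """
    panel = tuple(panel) if panel is not None else screening_panel()
    layout = library.layout
    pcr_count = 0

    positive_plates = []
    for plate in range(1, layout.n_plates + 1):
        members = (library.wells[w] for w in library.plate_wells(plate))
        pcr_count += 1
        if pool_is_positive(members, panel, **pcr_kwargs):
            positive_plates.append(plate)

    positive_pools = []
    for plate in positive_plates:
        for col in range(1, layout.cols + 1):
            members = (
                library.wells[(plate, row, col)] for row in range(1, layout.rows + 1)
            )
            pcr_count += 1
            if pool_is_positive(members, panel, **pcr_kwargs):
                positive_pools.append((plate, col))

    positive_wells = []
    for plate, col in positive_pools:
        for row in range(1, layout.rows + 1):
            pcr_count += 1
            if template_is_positive(library.wells[(plate, row, col)], panel, **pcr_kwargs):
                positive_wells.append((plate, row, col))

    return ScreenResult(
        step1_positive_plates=positive_plates,
        step2_positive_pools=positive_pools,
        step3_positive_wells=positive_wells,
        pcr_count=pcr_count,
    )


@dataclass(frozen=True)
class PanelVerdict:
    pair_id: int
    product_sizes_on_positives: tuple
    products_on_decoys: tuple
    status: str  # "usable" | "rejected_no_product" | "rejected_off_size" | "rejected_nonspecific"


def verify_primer_panel(panel, positive_templates, decoys=(), **pcr_kwargs) -> list[PanelVerdict]:
    """Per-pair usability report over known-positive and decoy templates.

    A pair is usable when it yields at least one near-expected-size product
    on the positives and nothing on the decoys; pairs with no product, only
    off-size products, or decoy products are rejected.
    """
    out = []
    for pair in panel:
        pos_sizes = []
        for tpl in positive_templates:
            pos_sizes += [a.length for a in insilico_pcr(tpl, pair, **pcr_kwargs)]
        decoy_sizes = []
        for tpl in decoys:
            decoy_sizes += [a.length for a in insilico_pcr(tpl, pair, **pcr_kwargs)]
        if decoy_sizes:
            status = "rejected_nonspecific"
        elif not pos_sizes:
            status = "rejected_no_product"
        elif not any(_sizes_match(s, pair.expected_products) for s in pos_sizes):
            status = "rejected_off_size"
        else:
            status = "usable"
        out.append(
            PanelVerdict(
                pair_id=pair.id,
                product_sizes_on_positives=tuple(sorted(set(pos_sizes))),
                products_on_decoys=tuple(sorted(set(decoy_sizes))),
                status=status,
            )
        )
    return out
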