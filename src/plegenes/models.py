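"""Core result containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GeneModel:
    """One annotated gene: exon intervals on a contig plus alignment metadata.

    Coordinates are 1-based inclusive contig positions, exons sorted by start
    regardless of strand. Introns are the gaps between consecutive exons. On
    the minus strand the first exon of the transcript is the *rightmost*
    interval; interval order in ``exons`` stays genomic.
    """

    contig_id: str = ""
    strand: str = "+"
    exons: tuple = ()
    cdna_id: str = ""
    alignment_score: int = 0
    mismatch_count: int = 0
    cds_sequence: str | None = field(default=None, compare=False)
    name: str = field(default="", compare=False)

    @property
    def introns(self) -> tuple:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def is_empty(self) -> bool:
        return not self.exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_sizes(self) -> tuple:
        """Exon lengths in transcript order (5' to 3' on the gene strand)."""
        sizes = tuple(e - s + 1 for s, e in self.exons)
        return sizes if self.strand == "+" else sizes[::-1]

    def intron_sizes(self) -> tuple:
        sizes = tuple(e - s + 1 for s, e in self.introns)
        return sizes if self.strand == "+" else sizes[::-1]

    def validate(self, contig: str | None = None, min_intron: int = 4) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        from ._util import revcomp

        prev_end = 0
        for s, e in self.exons:
            if not (1 <= s <= e):
                raise ValueError(f"bad exon interval ({s}, {e})")
            if s <= prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e
        for s, e in self.introns:
            if e - s + 1 < min_intron:
                raise ValueError(f"intron ({s}, {e}) shorter than {min_intron}")
            if contig is not None:
                seq = contig[s - 1 : e]
                if self.strand == "-":
                    seq = revcomp(seq)
                if not (seq.startswith("GT") and seq.endswith("AG")):
                    raise ValueError(f"intron ({s}, {e}) violates the GT-AG rule")
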