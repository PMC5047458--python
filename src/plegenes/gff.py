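"""GFF3 serialization of gene models (gene/mRNA/exon/CDS, 1-based inclusive).

Writing is plain text in standard nine-column GFF3; reading goes through
gffutils (in-memory database) after a light syntactic pre-check that
reports the first malformed line by number. Alignment metadata (reference
cDNA id, score, mismatch count) rides on the mRNA feature's attributes so
a written file reconstructs the same :class:`GeneModel` list.
"""

from __future__ import annotations

import pathlib

import gffutils

from .errors import GFF3ParseError
from .models import GeneModel

_SOURCE = "plegenes"


def _feature_line(seqid, ftype, start, end, score, strand, phase, attrs) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
    return "\t".join(
        [seqid, _SOURCE, ftype, str(start), str(end), score, strand, phase, attr_str]
    )


def write_gff3(models: list[GeneModel], path) -> None:
    """Write models as gene -> mRNA -> exon/CDS feature trees."""
    lines = ["##gff-version 3"]
    for i, m in enumerate(models):
        if m.is_empty:
            continue
        gid = m.name or f"gene{i + 1}"
        lines.append(
            _feature_line(m.contig_id, "gene", m.start, m.end, ".", m.strand, ".",
                          {"ID": gid})
        )
        tid = f"{gid}.t1"
        lines.append(
            _feature_line(
                m.contig_id, "mRNA", m.start, m.end, str(m.alignment_score), m.strand, ".",
                {"ID": tid, "Parent": gid, "cdna_id": m.cdna_id,
                 "mismatches": m.mismatch_count},
            )
        )
        exons = m.exons if m.strand == "+" else m.exons[::-1]  # transcript order
        cum = 0
        for k, (s, e) in enumerate(exons):
            lines.append(
                _feature_line(m.contig_id, "exon", s, e, ".", m.strand, ".",
                              {"ID": f"{tid}.exon{k + 1}", "Parent": tid})
            )
            phase = (3 - cum % 3) % 3
            lines.append(
                _feature_line(m.contig_id, "CDS", s, e, ".", m.strand, str(phase),
                              {"ID": f"{tid}.cds{k + 1}", "Parent": tid})
            )
            cum += e - s + 1
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def _precheck(path) -> None:
    for lineno, line in enumerate(pathlib.Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GFF3ParseError(f"expected 9 tab-separated columns, got {len(cols)}", lineno)
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            raise GFF3ParseError("start/end are not integers", lineno) from None
        if start < 1 or end < start:
            raise GFF3ParseError(f"bad coordinates {start}..{end}", lineno)
        if cols[6] not in "+-.":
            raise GFF3ParseError(f"bad strand {cols[6]!r}", lineno)


def read_gff3(path) -> list[GeneModel]:
    """Parse a GFF3 file written by :func:`write_gff3` back into models."""
    _precheck(path)
    if not any(
        line and not line.startswith("#")
        for line in pathlib.Path(path).read_text().splitlines()
    ):
        return []  # header-only file: no features
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted types on bad input
        raise GFF3ParseError(f"gffutils could not parse file: {exc}") from exc

    models = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            continue
        mrna = mrnas[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        score = int(float(mrna.score)) if mrna.score not in (".", None) else 0
        models.append(
            GeneModel(
                contig_id=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cdna_id=mrna.attributes.get("cdna_id", [""])[0],
                alignment_score=score,
                mismatch_count=int(mrna.attributes.get("mismatches", ["0"])[0]),
                name=gene.id,
            )
        )
    models.sort(key=lambda m: m.start)
    return models
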