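"""Reading and writing annotated plastomes.

GenBank flat files are the primary interchange format; FASTA + GFF3 is the
alternative.  GenBank 1-based inclusive coordinates are converted to the
package's 0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import os
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import GeneAnnotation, PlastomeRecord, ValidationError

__all__ = ["read_plastome", "write_genbank", "write_fasta", "write_gff3"]

_FEATURE_CATEGORY = {"CDS": "protein", "tRNA": "tRNA", "rRNA": "rRNA"}


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def _category_from_name(name: str) -> str:
    if name.startswith("trn"):
        return "tRNA"
    if name.startswith("rrn"):
        return "rRNA"
    return "protein"


def read_plastome(path: str | os.PathLike, format: str | None = None) -> PlastomeRecord:
    """Read an annotated plastome from GenBank or FASTA(+GFF3).

    ``format`` is ``"genbank"`` or ``"fasta+gff3"``; when omitted it is
    guessed from the extension.  For FASTA input, a GFF3 file with the same
    stem (``.gff3`` or ``.gff``) is read when present.  Joined/multi-interval
    features become multi-exon annotations; a ``pseudo`` qualifier or
    attribute sets ``is_pseudo``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".genbank", ".gbff"):
            format = "genbank"
        elif suffix in (".fa", ".fasta", ".fna"):
            format = "fasta+gff3"
        else:
            raise ParseError(f"cannot guess format of {path}")
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+gff3":
        return _read_fasta_gff3(path)
    raise ValueError(f"unknown format {format!r}")


def _read_genbank(path: Path) -> PlastomeRecord:
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    n = len(seqrec.seq)
    is_circular = seqrec.annotations.get("topology", "circular") == "circular"

    # One annotation per gene copy: typed features (CDS/tRNA/rRNA) carry the
    # category and exon structure; bare `gene` features are used only when no
    # typed feature shares their name and span.
    typed: dict[tuple[str, tuple[int, int]], GeneAnnotation] = {}
    bare: dict[tuple[str, tuple[int, int]], GeneAnnotation] = {}
    for feat in seqrec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA"):
            continue
        name = _feature_name(feat)
        if not name:
            continue
        exons = sorted((int(p.start), int(p.end)) for p in feat.location.parts)
        for s, e in exons:
            if not (0 <= s < e <= n):
                raise ValidationError(
                    f"{path}: feature {name} coordinates {(s, e)} outside sequence"
                )
        note = feat.qualifiers.get("note", [""])[0]
        ann = GeneAnnotation(
            name=name,
            category=_FEATURE_CATEGORY.get(feat.type) or _category_from_name(name),
            strand="-" if feat.location.strand == -1 else "+",
            exons=exons,
            is_pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
            copy_tag=note if note in ("IR_A", "IR_B") else "single",
            trans_spliced="trans_splicing" in feat.qualifiers,
        )
        key = (name, _span(tuple(exons)))
        (typed if feat.type != "gene" else bare).setdefault(key, ann)
    merged = dict(bare)
    merged.update(typed)
    annotations = sorted(merged.values(), key=lambda a: (a.start, a.name))
    record = PlastomeRecord(
        id=seqrec.id,
        sequence=str(seqrec.seq).upper(),
        is_circular=is_circular,
        annotations=annotations,
        source=str(path),
    )
    record.validate()
    return record


def _span(exons: tuple) -> tuple[int, int]:
    return (min(s for s, _ in exons), max(e for _, e in exons))


def _feature_name(feat) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def _read_fasta_gff3(path: Path) -> PlastomeRecord:
    try:
        seqrec = SeqIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    annotations: list[GeneAnnotation] = []
    gff = None
    for ext in (".gff3", ".gff"):
        cand = path.with_suffix(ext)
        if cand.exists():
            gff = cand
            break
    if gff is not None:
        annotations = _parse_gff3(gff, len(seqrec.seq))
    record = PlastomeRecord(
        id=seqrec.id,
        sequence=str(seqrec.seq).upper(),
        is_circular=True,
        annotations=annotations,
        source=str(path),
    )
    record.validate()
    return record


def _parse_gff3(path: Path, genome_length: int) -> list[GeneAnnotation]:
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except EmptyInputError:
        return []
    annotations = []
    for gene in db.features_of_type("gene"):
        name = gene.attributes.get("Name", gene.attributes.get("ID", ["?"]))[0]
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        category = gene.attributes.get("gene_biotype", [None])[0] or (
            _category_from_name(name)
        )
        if category not in ("protein", "tRNA", "rRNA"):
            category = _category_from_name(name)
        is_pseudo = (
            "pseudo" in gene.attributes or gene.attributes.get("pseudo", ["false"])[0] == "true"
        )
        copy_tag = gene.attributes.get("copy_tag", ["single"])[0]
        ann = GeneAnnotation(
            name=name,
            category=category,
            strand=gene.strand if gene.strand in "+-" else "+",
            exons=exons,
            is_pseudo=is_pseudo,
            copy_tag=copy_tag if copy_tag in ("single", "IR_A", "IR_B") else "single",
            trans_spliced=gene.attributes.get("trans_spliced", ["false"])[0] == "true",
        )
        ann.validate(genome_length)
        annotations.append(ann)
    return annotations


def _location(ann: GeneAnnotation) -> SimpleLocation | CompoundLocation:
    strand = -1 if ann.strand == "-" else 1
    parts = [SimpleLocation(s, e, strand) for s, e in ann.exons]
    if len(parts) == 1:
        return parts[0]
    if strand == -1:
        parts = parts[::-1]
    return CompoundLocation(parts)


def write_genbank(record: PlastomeRecord, path: str | os.PathLike) -> None:
    """Emit a GenBank flat file (1-based inclusive coordinates)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id[:16],
        description="plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.is_circular else "linear",
        },
    )
    for ann in record.annotations:
        qualifiers: dict = {"gene": [ann.name]}
        if ann.is_pseudo:
            qualifiers["pseudo"] = [""]
        if ann.copy_tag != "single":
            qualifiers["note"] = [ann.copy_tag]
        if ann.trans_spliced:
            qualifiers["trans_splicing"] = [""]
        ftype = {"protein": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}[ann.category]
        seqrec.features.append(
            SeqFeature(_location(ann), type="gene", qualifiers=dict(qualifiers))
        )
        seqrec.features.append(
            SeqFeature(_location(ann), type=ftype, qualifiers=qualifiers)
        )
    SeqIO.write([seqrec], str(path), "genbank")


def write_fasta(record: PlastomeRecord, path: str | os.PathLike) -> None:
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, description="")
    SeqIO.write([seqrec], str(path), "fasta")


def write_gff3(record: PlastomeRecord, path: str | os.PathLike) -> None:
    """Emit gene + exon features as GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3", f"##sequence-region {record.id} 1 {len(record)}"]
    for i, ann in enumerate(record.annotations):
        attrs = [f"ID=gene{i}", f"Name={ann.name}"]
        if ann.is_pseudo:
            attrs.append("pseudo=true")
        if ann.copy_tag != "single":
            attrs.append(f"copy_tag={ann.copy_tag}")
        if ann.trans_spliced:
            attrs.append("trans_spliced=true")
        attrs.append(f"gene_biotype={ann.category}")
        s, e = ann.span
        lines.append(
            "\t".join(
                [
                    record.id,
                    "plastomekit",
                    "gene",
                    str(s + 1),
                    str(e),
                    ".",
                    ann.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
        for j, (xs, xe) in enumerate(ann.exons):
            lines.append(
                "\t".join(
                    [
                        record.id,
                        "plastomekit",
                        "exon",
                        str(xs + 1),
                        str(xe),
                        ".",
                        ann.strand,
                        ".",
                        f"ID=gene{i}.exon{j};Parent=gene{i}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
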