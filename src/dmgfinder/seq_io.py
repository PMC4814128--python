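"""FASTA/GFF input-output and the ORF header convention.

A comparison run takes, per strain, one genome FASTA (chromosome plus
plasmid contigs) and one ORF FASTA (all annotated coding sequences, DNA).
The two files of a strain are paired by identical base filename; the strain
name is the base filename without extension.

ORF FASTA headers come in two dialects:

* ``badge`` — ``>ORF_ID contig=<id> start=<int> stop=<int> strand=<+|->
  annotation=<free text>`` (coordinates 1-based inclusive, coding-strand
  sequence);
* ``bare`` — anything else; the first whitespace token is the ORF id and
  location fields are left unset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from urllib.parse import unquote

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")
_AMBIG_RE = re.compile(r"[^ACGTN]")

DEFAULT_ANNOTATION = "hypothetical protein"


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_seq(seq: str, context: str) -> str:
    """Uppercase and map IUPAC ambiguity codes other than N to N."""
    seq = seq.upper()
    if _AMBIG_RE.search(seq):
        n_amb = len(_AMBIG_RE.findall(seq))
        logger.warning(
            "%s: %d ambiguous base(s) outside {A,C,G,T,N} mapped to N",
            context, n_amb,
        )
        seq = _AMBIG_RE.sub("N", seq)
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA (or protein) sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """One annotated coding sequence (DNA, coding strand).

    ``start``/``stop`` are 1-based inclusive coordinates on ``contig``
    with start <= stop; minus-strand ORFs store the reverse complement of
    the contig slice so that ``seq`` always reads in coding orientation.
    """

    orf_id: str
    seq: str
    strain: str = ""
    contig: str = ""
    start: int = 0
    stop: int = 0
    strand: str = "+"
    annotation: str = DEFAULT_ANNOTATION

    def __post_init__(self) -> None:
        if not self.orf_id:
            raise ValueError("orf_id must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.orf_id}: strand must be + or -")
        if self.start and self.stop and self.start > self.stop:
            raise ValueError(
                f"ORF {self.orf_id}: start {self.start} > stop {self.stop}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def header(self) -> str:
        """Badge-dialect FASTA header text (without the leading '>')."""
        return (
            f"{self.orf_id} contig={self.contig} start={self.start} "
            f"stop={self.stop} strand={self.strand} annotation={self.annotation}"
        )


@dataclass
class GroupData:
    """One strain group: paired genome contigs and ORF sets per strain."""

    name: str
    genomes: dict[str, list[SequenceRecord]] = field(default_factory=dict)
    orfs: dict[str, list[OrfRecord]] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return sorted(self.genomes)

    def all_orfs(self) -> list[OrfRecord]:
        out: list[OrfRecord] = []
        for strain in self.strains:
            out.extend(self.orfs[strain])
        return out

    def all_contigs(self) -> list[SequenceRecord]:
        out: list[SequenceRecord] = []
        for strain in self.strains:
            for rec in self.genomes[strain]:
                out.append(replace(rec, id=f"{strain}|{rec.id}"))
        return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Order is preserved, multi-line sequences are joined and lowercase is
    mapped to uppercase. Empty files yield an empty list. Empty-id headers,
    duplicate ids and non-FASTA content raise ``ValueError``.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise ValueError(f"{path}: not FASTA content (no leading '>')")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">") and not line[1:].strip():
            raise ValueError(f"{path}: empty-id FASTA header at line {lineno}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        desc = " ".join(desc.split())
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=_clean_seq(str(rec.seq), f"{path}:{rec.id}"),
                description=desc,
            )
        )
    return records


def write_fasta(
    records: list[SequenceRecord] | list[OrfRecord],
    path: str | Path,
    width: int = 70,
) -> None:
    """Write records to FASTA, wrapping sequence lines at ``width``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            if isinstance(rec, OrfRecord):
                header = rec.header()
            else:
                header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_BADGE_KEYS = ("contig", "start", "stop", "strand")


def looks_like_badge_header(header: str) -> bool:
    return all(f"{k}=" in header for k in _BADGE_KEYS)


def parse_orf_header(header: str, dialect: str = "badge", strain: str = "") -> OrfRecord:
    """Parse the text after '>' of an ORF FASTA header.

    Returns an :class:`OrfRecord` with an empty placeholder sequence "N";
    callers replace ``seq`` with the record body. ``badge`` dialect parses
    the key=value convention; ``bare`` takes the first whitespace token as
    the ORF id and fills defaults.
    """
    header = header.strip()
    if not header:
        raise ValueError("empty ORF header")
    if dialect == "bare":
        return OrfRecord(orf_id=header.split()[0], seq="N", strain=strain)
    if dialect != "badge":
        raise ValueError(f"unknown header dialect {dialect!r}")
    tokens = header.split()
    orf_id = tokens[0]
    if "=" in orf_id:
        raise ValueError(f"badge header missing orf_id: {header!r}")
    fields: dict[str, str] = {}
    # annotation= consumes the rest of the line, so find it first
    m = re.search(r"\bannotation=(.*)$", header)
    annotation = m.group(1).strip() if m else DEFAULT_ANNOTATION
    head = header[: m.start()] if m else header
    for tok in head.split()[1:]:
        if "=" not in tok:
            continue
        key, _, val = tok.partition("=")
        fields[key] = val
    for key in _BADGE_KEYS:
        if key not in fields:
            raise ValueError(f"badge header for {orf_id!r} lacks field {key!r}")
    try:
        start = int(fields["start"])
        stop = int(fields["stop"])
    except ValueError as exc:
        raise ValueError(
            f"badge header for {orf_id!r}: unparsable coordinates "
            f"start={fields['start']!r} stop={fields['stop']!r}"
        ) from exc
    return OrfRecord(
        orf_id=orf_id,
        seq="N",
        strain=strain,
        contig=fields["contig"],
        start=start,
        stop=stop,
        strand=fields["strand"],
        annotation=annotation or DEFAULT_ANNOTATION,
    )


def read_orf_fasta(path: str | Path, dialect: str = "auto", strain: str = "") -> list[OrfRecord]:
    """Read an ORF FASTA, parsing headers in the given dialect.

    ``auto`` uses the badge dialect when every key=value field is present
    on the first header, else bare.
    """
    path = Path(path)
    raw = read_fasta(path)
    if not raw:
        return []
    if dialect == "auto":
        first_header = None
        with path.open() as fh:
            for line in fh:
                if line.startswith(">"):
                    first_header = line[1:].strip()
                    break
        dialect = "badge" if first_header and looks_like_badge_header(first_header) else "bare"
    # re-read headers: read_fasta splits id/description; reconstruct
    out: list[OrfRecord] = []
    seen: set[str] = set()
    for rec in raw:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        meta = parse_orf_header(header, dialect=dialect, strain=strain)
        if meta.orf_id in seen:
            raise ValueError(f"{path}: duplicate ORF id {meta.orf_id!r}")
        seen.add(meta.orf_id)
        out.append(replace(meta, seq=rec.seq))
    return out


def _parse_gff_attributes(attr_text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition("=")
        attrs[key.strip()] = unquote(val.strip())
    return attrs


def rast2badge(genome: list[SequenceRecord], gff: str | Path) -> list[OrfRecord]:
    """Convert annotation output (genome FASTA + GFF3 CDS features) into
    badge-dialect ORF records.

    One ORF per CDS line: the sequence is cut from the contig at the
    1-based inclusive coordinates, reverse-complemented for minus-strand
    features; the annotation is the ``product`` attribute when present.
    """
    gff = Path(gff)
    contigs = {rec.id: rec for rec in genome}
    out: list[OrfRecord] = []
    counter = 0
    with gff.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                break  # trailing ##FASTA section
            cols = line.split("\t")
            if len(cols) < 8:
                raise ValueError(f"{gff}:{lineno}: not a GFF3 feature line")
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame = cols[:8]
            if ftype != "CDS":
                continue
            if seqid not in contigs:
                raise ValueError(f"{gff}:{lineno}: unknown seqid {seqid!r}")
            start, end = int(start_s), int(end_s)
            contig = contigs[seqid]
            if start < 1 or end > contig.length or start > end:
                raise ValueError(
                    f"{gff}:{lineno}: CDS {start}..{end} outside contig "
                    f"{seqid!r} bounds (1..{contig.length})"
                )
            attrs = _parse_gff_attributes(cols[8]) if len(cols) > 8 else {}
            counter += 1
            orf_id = (
                attrs.get("locus_tag")
                or attrs.get("ID")
                or f"{seqid}_cds{counter}"
            )
            subseq = contig.seq[start - 1 : end]
            if strand == "-":
                subseq = revcomp(subseq)
            out.append(
                OrfRecord(
                    orf_id=orf_id,
                    seq=subseq,
                    contig=seqid,
                    start=start,
                    stop=end,
                    strand=strand if strand in "+-" else "+",
                    annotation=attrs.get("product", DEFAULT_ANNOTATION),
                )
            )
    return out


def load_group(
    genomes_dir: str | Path,
    orfs_dir: str | Path,
    name: str,
    dialect: str = "auto",
) -> GroupData:
    """Load one strain group from paired genome/ORF FASTA directories.

    Files are paired by base filename; the strain name is the base filename
    without extension. Strains are sorted lexicographically so downstream
    order never depends on filesystem listing order.
    """
    genomes_dir, orfs_dir = Path(genomes_dir), Path(orfs_dir)
    for d in (genomes_dir, orfs_dir):
        if not d.is_dir():
            raise FileNotFoundError(f"group directory {d} does not exist")
    fasta_exts = {".fasta", ".fa", ".fna", ".ffn"}
    genome_files = {
        p.stem: p for p in sorted(genomes_dir.iterdir()) if p.suffix.lower() in fasta_exts
    }
    orf_files = {
        p.stem: p for p in sorted(orfs_dir.iterdir()) if p.suffix.lower() in fasta_exts
    }
    orphans = sorted(set(genome_files) ^ set(orf_files))
    if orphans:
        raise ValueError(
            f"group {name!r}: unpaired genome/ORF files for strain(s): "
            + ", ".join(orphans)
        )
    group = GroupData(name=name)
    for strain in sorted(genome_files):
        contigs = read_fasta(genome_files[strain])
        orfs = read_orf_fasta(orf_files[strain], dialect=dialect, strain=strain)
        contig_ids = {c.id for c in contigs}
        for orf in orfs:
            if orf.contig and orf.contig not in contig_ids:
                raise ValueError(
                    f"group {name!r}, strain {strain!r}: ORF {orf.orf_id!r} "
                    f"references unknown contig {orf.contig!r}"
                )
            if not orf.contig:
                logger.warning(
                    "group %r, strain %r: ORF %r carries no contig location "
                    "(bare header dialect)",
                    name, strain, orf.orf_id,
                )
        group.genomes[strain] = contigs
        group.orfs[strain] = orfs
    return group
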