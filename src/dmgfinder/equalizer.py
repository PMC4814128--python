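"""Annotation equalizer: repair inconsistent gene calling within a group.

Automated annotation pipelines disagree: a gene properly annotated in one
genome of a group may be missing from the gene calls of another genome even
though the sequence sits in its contigs (frameshifted by a sequencing
error, or simply not called). Marker prediction with a 100% occurrence
requirement then silently loses the gene. The equalizer compares every
genome's ORF set against the annotations of the other genomes of the same
group and, wherever a gene is present in the genome sequence but absent
from the gene calls, extracts the aligned genomic region and appends it to
the ORF set as an extra, flagged ORF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align_engine import AlignParams, find_hits
from .config import BadgeConfig
from .seq_io import GroupData, OrfRecord, SequenceRecord, revcomp

logger = logging.getLogger(__name__)

EQUALIZED_TOKEN = "equalized"
_RECIPROCAL_OVERLAP = 0.5


@dataclass
class AddedOrf:
    strain: str
    orf: OrfRecord
    source_strain: str
    source_orf_id: str
    identity: float


@dataclass
class EqualizationReport:
    """What the equalizer inspected and added, per strain."""

    added: dict[str, list[AddedOrf]] = field(default_factory=dict)
    n_inspected: int = 0

    @property
    def n_added(self) -> int:
        return sum(len(v) for v in self.added.values())


def _overlap_frac(a: OrfRecord, b: OrfRecord) -> float:
    """Smaller of the two reciprocal overlap fractions (same contig/strand)."""
    if a.contig != b.contig or a.strand != b.strand:
        return 0.0
    inter = min(a.stop, b.stop) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a.stop - a.start + 1), inter / (b.stop - b.start + 1))


def equalize_group(
    group: GroupData, cfg: BadgeConfig | None = None
) -> tuple[GroupData, EqualizationReport]:
    """Supplement each strain's ORF set with missing gene calls found in the
    other genomes of the group.

    For each strain S and each ORF o annotated in another strain: if o has
    no passing hit in S's ORF set but does have one in S's genome, the
    aligned genomic region (strand-resolved) is appended to S's ORFs.
    Overlapping additions (> 50% reciprocal overlap on the same strand)
    collapse to the best-identity one. Uses the primary step-1 cutoffs.
    Idempotent: a second run adds nothing.
    """
    cfg = cfg or BadgeConfig()
    params = AlignParams(
        task="dc_like" if cfg.mode == "dc" else "megablast_like",
        perc_identity_cut=cfg.megablast_perc_identity_cut,
        query_cov_cut=cfg.query_cov_cut,
    )
    # ORF-vs-ORF screening uses subject coverage too (both sides are genes)
    orf_params = AlignParams(
        task=params.task,
        perc_identity_cut=cfg.megablast_perc_identity_cut,
        query_cov_cut=cfg.query_cov_cut,
        subject_cov_cut=cfg.subject_cov_cut,
    )

    report = EqualizationReport()
    new_group = GroupData(name=group.name)
    for strain in group.strains:
        new_group.genomes[strain] = list(group.genomes[strain])
        new_group.orfs[strain] = list(group.orfs[strain])

    for strain in group.strains:
        own_orfs = group.orfs[strain]
        own_records = [
            SequenceRecord(id=f"{strain}|{o.orf_id}", seq=o.seq) for o in own_orfs
        ]
        contigs = group.genomes[strain]

        # dedupe foreign ORFs by sequence; keep the first by (strain, orf_id)
        foreign: list[tuple[str, OrfRecord]] = []
        seen_seqs: set[str] = set()
        for other in group.strains:
            if other == strain:
                continue
            for o in sorted(group.orfs[other], key=lambda x: x.orf_id):
                if o.seq in seen_seqs:
                    continue
                seen_seqs.add(o.seq)
                foreign.append((other, o))
        report.n_inspected += len(foreign)
        if not foreign:
            continue

        queries = [
            SequenceRecord(id=f"{src}|{o.orf_id}", seq=o.seq) for src, o in foreign
        ]
        annotated = {
            h.query_id for h in find_hits(queries, own_records, orf_params,
                                          backend=cfg.backend)
        }
        missing = [
            (src, o) for src, o in foreign if f"{src}|{o.orf_id}" not in annotated
        ]
        if not missing:
            continue
        miss_queries = [
            SequenceRecord(id=f"{src}|{o.orf_id}", seq=o.seq) for src, o in missing
        ]
        genome_hits = find_hits(
            miss_queries, contigs,
            AlignParams(task=params.task,
                        perc_identity_cut=cfg.megablast_perc_identity_cut,
                        query_cov_cut=cfg.query_cov_cut),
            backend=cfg.backend,
        )
        best_hit: dict[str, object] = {}
        for h in genome_hits:
            prev = best_hit.get(h.query_id)
            if prev is None or h.score > prev.score:  # type: ignore[attr-defined]
                best_hit[h.query_id] = h

        candidates: list[AddedOrf] = []
        contig_by_id = {c.id: c for c in contigs}
        for src, o in missing:
            qid = f"{src}|{o.orf_id}"
            h = best_hit.get(qid)
            if h is None:
                continue
            lo, hi = min(h.s_start, h.s_end), max(h.s_start, h.s_end)
            contig = contig_by_id[h.subject_id]
            region = contig.seq[lo - 1 : hi]
            strand = h.strand
            if strand == "-":
                region = revcomp(region)
            new_orf = OrfRecord(
                orf_id=f"EQ_{src}_{o.orf_id}",
                seq=region,
                strain=strain,
                contig=contig.id,
                start=lo,
                stop=hi,
                strand=strand,
                annotation=f"{EQUALIZED_TOKEN} from {src}:{o.orf_id} | {o.annotation}",
            )
            candidates.append(
                AddedOrf(strain=strain, orf=new_orf, source_strain=src,
                         source_orf_id=o.orf_id, identity=h.perc_identity)
            )

        # collapse overlapping additions to the best-identity one
        candidates.sort(key=lambda a: (-a.identity, a.orf.orf_id))
        kept: list[AddedOrf] = []
        for cand in candidates:
            if any(
                _overlap_frac(cand.orf, k.orf) > _RECIPROCAL_OVERLAP for k in kept
            ):
                continue
            kept.append(cand)
        kept.sort(key=lambda a: (a.orf.contig, a.orf.start, a.orf.orf_id))
        if kept:
            existing_ids = {o.orf_id for o in new_group.orfs[strain]}
            for cand in kept:
                if cand.orf.orf_id in existing_ids:
                    continue
                new_group.orfs[strain].append(cand.orf)
                report.added.setdefault(strain, []).append(cand)
            logger.info(
                "equalizer: strain %s gained %d ORF(s)", strain, len(kept)
            )
    return new_group, report


def report_rows(report: EqualizationReport) -> list[dict]:
    """Flatten an EqualizationReport for TSV output."""
    rows = []
    for strain in sorted(report.added):
        for a in report.added[strain]:
            rows.append({
                "strain": strain,
                "added_orf_id": a.orf.orf_id,
                "source": f"{a.source_strain}:{a.source_orf_id}",
                "contig": a.orf.contig,
                "start": a.orf.start,
                "stop": a.orf.stop,
                "identity": round(a.identity, 2),
            })
    return rows
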