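"""The six-step diagnostic marker gene (DMG) prediction pipeline.

Given a target group A and a background group B (each a set of strains with
genome contigs and annotated ORFs), a DMG is a gene present in (nearly) all
A genomes and absent from all B genomes:

1. discard every A-ORF with a high-quality hit in the B ORF sets;
2. discard survivors with a high-quality hit in the B *genome* sequences
   (catches genes present in B but unannotated or frameshifted there);
3. group the survivors into gene families across A genomes and apply the
   occurrence filter;
4. (optional) discard families with long low-identity hits in B genomes
   (sensitive dc-level screen); sub-threshold hits are annotated;
5. (optional) discard families with short high-identity hits in B genomes;
   the longest sub-threshold hit length is annotated per family;
6. assemble outputs: per-family FASTAs, a representative FASTA, the tabular
   report, presence/copy-number matrices, settings echo and per-step counts.

Mode switches: ``dc`` substitutes the sensitive dc-level search for the
primary one in steps 1-3; ``protein`` compares translated sequences at
steps 1 and 3 (steps 2, 4, 5 stay nucleotide); ``mut_dna``/``mut_protein``
report genes identical within A whose best B counterpart is similar but not
identical (candidate point-mutation markers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .align_engine import (
    AlignmentHit,
    AlignParams,
    find_hits,
    hit_passes,
    translate_orf,
)
from .config import BadgeConfig
from .seq_io import GroupData, OrfRecord, SequenceRecord, revcomp, write_fasta

logger = logging.getLogger(__name__)

# noise floors for *annotating* residual sub-threshold background hits
# (family removal is governed solely by the configured cutoffs)
_DC_RESIDUAL_MIN_SCORE = 20.0
_BLASTN_RESIDUAL_MIN_LEN = 30


@dataclass
class DmgFamily:
    """One predicted marker gene family across the target group."""

    dmg_id: str
    members: list[OrfRecord]
    percent_occurrence: float
    per_genome_frequency: dict[str, int]
    representative: OrfRecord
    dc_blast_hit: str = "no"
    max_blastn: int = 0

    @property
    def n_strains(self) -> int:
        return len(self.per_genome_frequency)


@dataclass
class RunOutputs:
    """Everything a prediction run produces."""

    families: list[DmgFamily]
    step_counts: list[tuple[str, int]]
    distribution: pd.DataFrame
    frequency: pd.DataFrame
    residual_hits: list[AlignmentHit] = field(default_factory=list)
    config: BadgeConfig | None = None


def _qualified_id(orf: OrfRecord) -> str:
    return f"{orf.strain}|{orf.orf_id}"


def _orf_records(
    orfs: list[OrfRecord], protein: bool = False
) -> list[SequenceRecord]:
    """SequenceRecords keyed by strain-qualified id, optionally translated."""
    out = []
    for orf in orfs:
        seq = translate_orf(orf.seq) if protein else orf.seq
        out.append(SequenceRecord(id=_qualified_id(orf), seq=seq))
    return out


def _base_task(cfg: BadgeConfig) -> str:
    if cfg.mode == "dc":
        return "dc_like"
    if cfg.mode in ("protein", "mut_protein"):
        return "blastp_like"
    return "megablast_like"


def _primary_params(cfg: BadgeConfig, task: str | None = None) -> AlignParams:
    return AlignParams(
        task=task or _base_task(cfg),
        perc_identity_cut=cfg.megablast_perc_identity_cut,
        query_cov_cut=cfg.query_cov_cut,
        subject_cov_cut=cfg.subject_cov_cut,
    )


def step1_orf_filter(
    a_orfs: list[OrfRecord],
    b_orfs: list[OrfRecord],
    cfg: BadgeConfig,
) -> list[OrfRecord]:
    """Step 1: keep A-ORFs with no passing hit in the B ORF sets."""
    if not a_orfs:
        raise ValueError("nothing to compare: target-group ORF set is empty")
    protein = cfg.mode in ("protein", "mut_protein")
    params = _primary_params(cfg)
    queries = _orf_records(a_orfs, protein=protein)
    subjects = _orf_records(b_orfs, protein=protein)
    hits = find_hits(queries, subjects, params, backend=cfg.backend)
    hit_queries = {h.query_id for h in hits}
    return [o for o in a_orfs if _qualified_id(o) not in hit_queries]


def step2_genome_filter(
    candidates: list[OrfRecord],
    b_genomes: list[SequenceRecord],
    cfg: BadgeConfig,
) -> list[OrfRecord]:
    """Step 2: keep candidates with no passing hit in the B genome contigs.

    Always nucleotide; subject coverage is not applied (subjects are whole
    contigs).
    """
    if not candidates:
        logger.warning("step 2: empty candidate set")
        return []
    task = "dc_like" if cfg.mode == "dc" else "megablast_like"
    params = AlignParams(
        task=task,
        perc_identity_cut=cfg.megablast_perc_identity_cut,
        query_cov_cut=cfg.query_cov_cut,
        subject_cov_cut=None,
    )
    queries = _orf_records(candidates)
    hits = find_hits(queries, b_genomes, params, backend=cfg.backend)
    hit_queries = {h.query_id for h in hits}
    return [o for o in candidates if _qualified_id(o) not in hit_queries]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def group_into_families(
    candidates: list[OrfRecord],
    cfg: BadgeConfig,
    a_strains: list[str],
) -> list[DmgFamily]:
    """Step 3a: single-linkage clustering of candidates into families.

    Two candidates are linked iff a hit between them passes the primary
    cutoffs in either direction; each connected component is one family.
    Family ids are assigned in ascending (representative strain, contig,
    start) order; the representative is the longest member (ties to the
    lexicographically smallest ORF id).
    """
    if not candidates:
        return []
    protein = cfg.mode in ("protein", "mut_protein")
    params = _primary_params(cfg)
    records = _orf_records(candidates, protein=protein)
    by_id = {_qualified_id(o): o for o in candidates}
    uf = _UnionFind(sorted(by_id))
    hits = find_hits(records, records, params, backend=cfg.backend)
    for h in hits:
        if h.query_id != h.subject_id:
            uf.union(h.query_id, h.subject_id)
    components: dict[str, list[OrfRecord]] = {}
    for qid in sorted(by_id):
        components.setdefault(uf.find(qid), []).append(by_id[qid])

    n_a = len(a_strains)
    families: list[DmgFamily] = []
    for comp in components.values():
        members = sorted(comp, key=lambda o: (o.strain, o.contig, o.start, o.orf_id))
        rep = sorted(members, key=lambda o: (-o.length, o.orf_id))[0]
        freq: dict[str, int] = {}
        for o in members:
            freq[o.strain] = freq.get(o.strain, 0) + 1
        families.append(
            DmgFamily(
                dmg_id="",
                members=members,
                percent_occurrence=100.0 * len(freq) / n_a,
                per_genome_frequency=freq,
                representative=rep,
            )
        )
    families.sort(
        key=lambda f: (
            f.representative.strain,
            f.representative.contig,
            f.representative.start,
            f.representative.orf_id,
        )
    )
    for i, fam in enumerate(families, start=1):
        fam.dmg_id = f"DMG_{i}"
    return families


def occurrence_filter(
    families: list[DmgFamily], min_occurrence: float
) -> list[DmgFamily]:
    """Step 3b: keep families present in >= ``min_occurrence`` of A genomes."""
    if not 0 < min_occurrence <= 1:
        raise ValueError("min_occurrence must lie in (0, 1]")
    thresh = 100.0 * min_occurrence - 1e-9
    return [f for f in families if f.percent_occurrence >= thresh]


def _family_background_hits(
    families: list[DmgFamily],
    b_genomes: list[SequenceRecord],
    params: AlignParams,
    backend: str,
) -> dict[str, list[AlignmentHit]]:
    """All (unfiltered) background-genome hits per family id."""
    queries: list[SequenceRecord] = []
    owner: dict[str, str] = {}
    for fam in families:
        for o in fam.members:
            qid = _qualified_id(o)
            queries.append(SequenceRecord(id=qid, seq=o.seq))
            owner[qid] = fam.dmg_id
    hits = find_hits(queries, b_genomes, params, backend=backend)
    out: dict[str, list[AlignmentHit]] = {f.dmg_id: [] for f in families}
    for h in hits:
        out[owner[h.query_id]].append(h)
    return out


def dc_filter(
    families: list[DmgFamily],
    b_genomes: list[SequenceRecord],
    cfg: BadgeConfig,
) -> tuple[list[DmgFamily], list[AlignmentHit]]:
    """Step 4: discard families with long low-identity background hits.

    A family is removed iff any member has a dc-level hit in the B genomes
    with identity >= ``dc_perc_identity_cut`` and query coverage >=
    ``dc_query_cov_cut``. Surviving families with weaker residual dc hits
    are annotated ``dc_blast_hit = yes``. Returns (survivors, residual
    hits retained for reporting).
    """
    if not cfg.enable_dc_filter or not families:
        return list(families), []
    probe = AlignParams(task="dc_like")  # permissive: classify afterwards
    removal = AlignParams(
        task="dc_like",
        perc_identity_cut=cfg.dc_perc_identity_cut,
        query_cov_cut=cfg.dc_query_cov_cut,
    )
    per_family = _family_background_hits(families, b_genomes, probe, cfg.backend)
    survivors: list[DmgFamily] = []
    residual: list[AlignmentHit] = []
    for fam in families:
        fam_hits = per_family[fam.dmg_id]
        if any(hit_passes(h, removal) for h in fam_hits):
            logger.info("step 4: %s removed (dc-level background hit)", fam.dmg_id)
            continue
        keep = [h for h in fam_hits if h.score >= _DC_RESIDUAL_MIN_SCORE]
        fam.dc_blast_hit = "yes" if keep else "no"
        residual.extend(keep)
        survivors.append(fam)
    return survivors, residual


def short_hit_filter(
    families: list[DmgFamily],
    b_genomes: list[SequenceRecord],
    cfg: BadgeConfig,
) -> tuple[list[DmgFamily], list[AlignmentHit]]:
    """Step 5: discard families with short high-identity background hits.

    Uses a small-word nucleotide search with no coverage floor; a family is
    removed iff any member produces a hit at identity >=
    ``megablast_perc_identity_cut`` longer than ``max_blastn_len_cut`` bp.
    Survivors record ``max_blastn`` = the longest such sub-threshold hit
    (0 if none).
    """
    if not cfg.enable_short_hit_filter or not families:
        return list(families), []
    probe = AlignParams(
        task="blastn_like",
        perc_identity_cut=cfg.megablast_perc_identity_cut,
        query_cov_cut=0.0,
    )
    per_family = _family_background_hits(families, b_genomes, probe, cfg.backend)
    survivors: list[DmgFamily] = []
    residual: list[AlignmentHit] = []
    for fam in families:
        fam_hits = [
            h for h in per_family[fam.dmg_id]
            if h.align_length >= _BLASTN_RESIDUAL_MIN_LEN
        ]
        if any(h.align_length > cfg.max_blastn_len_cut for h in fam_hits):
            logger.info("step 5: %s removed (short high-identity background hit)", fam.dmg_id)
            continue
        fam.max_blastn = max((h.align_length for h in fam_hits), default=0)
        residual.extend(fam_hits)
        survivors.append(fam)
    return survivors, residual


def _matrices(
    families: list[DmgFamily], a_strains: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    strains = sorted(a_strains)
    ids = [f.dmg_id for f in families]
    freq = pd.DataFrame(0, index=ids, columns=strains, dtype=int)
    for fam in families:
        for strain, n in fam.per_genome_frequency.items():
            freq.loc[fam.dmg_id, strain] = n
    dist = (freq > 0).astype(int)
    freq.index.name = dist.index.name = "DMG_ID"
    return dist, freq


def mut_level_filter(
    a_orfs: list[OrfRecord],
    b_orfs: list[OrfRecord],
    b_genomes: list[SequenceRecord],
    cfg: BadgeConfig,
    a_strains: list[str],
) -> list[DmgFamily]:
    """Mutation-level mode: genes identical across all A genomes whose best
    B counterpart passes the cutoffs but is not string-identical.

    Comparison is at the DNA level (``mut_dna``) or on translations
    (``mut_protein``); hits below the cutoffs (truly B-absent genes) are the
    business of the ordinary pipeline, not this mode.
    """
    if cfg.mode not in ("mut_dna", "mut_protein"):
        raise ValueError("mut_level_filter requires mode mut_dna or mut_protein")
    protein = cfg.mode == "mut_protein"
    level = (lambda s: translate_orf(s)) if protein else (lambda s: s)

    groups: dict[str, list[OrfRecord]] = {}
    for orf in a_orfs:
        groups.setdefault(level(orf.seq), []).append(orf)
    n_a = len(a_strains)
    b_keys = {level(o.seq) for o in b_orfs}
    b_contig_seqs = [c.seq for c in b_genomes]

    params = _primary_params(cfg, task="blastp_like" if protein else "megablast_like")
    candidates: list[tuple[str, list[OrfRecord]]] = []
    for key, members in sorted(groups.items()):
        strains = {o.strain for o in members}
        if len(strains) < n_a:
            continue  # not identical across all of group A
        if key in b_keys:
            continue  # identical copy annotated in B
        if not protein and any(
            members[0].seq in s or revcomp(members[0].seq) in s for s in b_contig_seqs
        ):
            continue  # identical copy present in a B genome
        candidates.append((key, members))

    if not candidates:
        return []
    queries = [
        SequenceRecord(id=f"cand_{i}", seq=key) for i, (key, _) in enumerate(candidates)
    ]
    subjects = _orf_records(b_orfs, protein=protein)
    hits = find_hits(queries, subjects, params, backend=cfg.backend)
    with_counterpart = {h.query_id for h in hits}

    families: list[DmgFamily] = []
    for i, (_key, members) in enumerate(candidates):
        if f"cand_{i}" not in with_counterpart:
            continue
        members = sorted(members, key=lambda o: (o.strain, o.contig, o.start, o.orf_id))
        rep = sorted(members, key=lambda o: (-o.length, o.orf_id))[0]
        freq: dict[str, int] = {}
        for o in members:
            freq[o.strain] = freq.get(o.strain, 0) + 1
        families.append(
            DmgFamily(
                dmg_id="",
                members=members,
                percent_occurrence=100.0,
                per_genome_frequency=freq,
                representative=rep,
            )
        )
    families.sort(
        key=lambda f: (
            f.representative.strain,
            f.representative.contig,
            f.representative.start,
            f.representative.orf_id,
        )
    )
    for i, fam in enumerate(families, start=1):
        fam.dmg_id = f"DMG_{i}"
    return families


def run_pipeline(
    group_a: GroupData, group_b: GroupData, cfg: BadgeConfig
) -> RunOutputs:
    """Execute the full prediction cascade and assemble outputs."""
    a_orfs = group_a.all_orfs()
    b_orfs = group_b.all_orfs()
    b_genomes = group_b.all_contigs()
    a_strains = group_a.strains
    step_counts: list[tuple[str, int]] = []

    def log_step(name: str, count: int) -> None:
        step_counts.append((name, count))
        logger.info("%s: %d candidate(s) remain", name, count)

    if cfg.mode in ("mut_dna", "mut_protein"):
        families = mut_level_filter(a_orfs, b_orfs, b_genomes, cfg, a_strains)
        log_step("mut_level_filter", len(families))
        dist, freq = _matrices(families, a_strains)
        return RunOutputs(
            families=families, step_counts=step_counts,
            distribution=dist, frequency=freq, config=cfg,
        )

    survivors1 = step1_orf_filter(a_orfs, b_orfs, cfg)
    log_step("step1_orf_filter", len(survivors1))

    survivors2 = step2_genome_filter(survivors1, b_genomes, cfg) if survivors1 else []
    log_step("step2_genome_filter", len(survivors2))

    families = group_into_families(survivors2, cfg, a_strains) if survivors2 else []
    families = occurrence_filter(families, cfg.min_occurrence)
    # renumber after the occurrence filter so ids stay dense
    for i, fam in enumerate(families, start=1):
        fam.dmg_id = f"DMG_{i}"
    log_step("step3_occurrence_filter", len(families))

    residual: list[AlignmentHit] = []
    families, dc_residual = dc_filter(families, b_genomes, cfg)
    residual.extend(dc_residual)
    log_step("step4_dc_filter", len(families))

    families, bn_residual = short_hit_filter(families, b_genomes, cfg)
    residual.extend(bn_residual)
    log_step("step5_short_hit_filter", len(families))

    for i, fam in enumerate(families, start=1):
        fam.dmg_id = f"DMG_{i}"
    dist, freq = _matrices(families, a_strains)
    return RunOutputs(
        families=families, step_counts=step_counts,
        distribution=dist, frequency=freq,
        residual_hits=residual, config=cfg,
    )


def distribution_mode(
    all_genomes: GroupData,
    dummy: SequenceRecord | None = None,
    cfg: BadgeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, RunOutputs]:
    """Presence/copy-number matrices for *all* genomes.

    Runs the ordinary pipeline with every genome as the target group, a
    single-sequence dummy background and a minimum occurrence equivalent to
    one genome, so nothing is discarded and the distribution matrices cover
    the whole gene pool.
    """
    n = len(all_genomes.strains)
    if n == 0:
        raise ValueError("distribution mode requires at least one genome")
    if dummy is None:
        dummy = SequenceRecord(id="dummy", seq="ATGCCC")
    cfg = cfg or BadgeConfig()
    cfg = replace(cfg, min_occurrence=1.0 / n, enable_dc_filter=False,
                  enable_short_hit_filter=False)
    group_b = GroupData(name="dummy_group")
    group_b.genomes["dummy"] = [dummy]
    group_b.orfs["dummy"] = [
        OrfRecord(orf_id="dummy_orf", seq=dummy.seq, strain="dummy",
                  contig=dummy.id, start=1, stop=dummy.length, strand="+")
    ]
    n_input = len(all_genomes.all_orfs())
    outputs = run_pipeline(all_genomes, group_b, cfg)
    n_after = dict(outputs.step_counts).get("step2_genome_filter", 0)
    if n_after < n_input:
        logger.warning(
            "distribution mode: dummy sequence produced %d passing hit(s); "
            "choose a shorter or more dissimilar dummy",
            n_input - n_after,
        )
    return outputs.distribution, outputs.frequency, outputs


# --- output files ----------------------------------------------------------


def _render_alignment(hit: AlignmentHit, qseq: str, sseq: str, width: int = 60) -> str:
    """Plain-text pairwise rendering of one residual hit."""
    import edlib

    qs = qseq[hit.q_start - 1 : hit.q_end]
    if hit.strand == "-":
        s_lo, s_hi = hit.s_end, hit.s_start
        ss = revcomp(sseq[s_lo - 1 : s_hi])
    else:
        ss = sseq[hit.s_start - 1 : hit.s_end]
    res = edlib.align(qs, ss, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, qs, ss)
    lines = [
        f"# {hit.query_id} vs {hit.subject_id} "
        f"identity={hit.perc_identity:.1f}% length={hit.align_length} "
        f"q={hit.q_start}..{hit.q_end} s={hit.s_start}..{hit.s_end} "
        f"score={hit.score:.0f}"
    ]
    for i in range(0, len(nice["query_aligned"]), width):
        lines.append("Q " + nice["query_aligned"][i : i + width])
        lines.append("  " + nice["matched_aligned"][i : i + width])
        lines.append("S " + nice["target_aligned"][i : i + width])
        lines.append("")
    return "\n".join(lines)


def write_outputs(
    outputs: RunOutputs,
    outdir: str | Path,
    cfg: BadgeConfig,
    group_b: GroupData | None = None,
    intermediates: dict[str, list[OrfRecord]] | None = None,
) -> None:
    """Write every output file of a run into ``outdir``.

    Deterministic: rerunning with identical inputs and config reproduces
    byte-identical files.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    families = outputs.families

    reps = [
        SequenceRecord(id=f.dmg_id, seq=f.representative.seq,
                       description=f.representative.header())
        for f in families
    ]
    write_fasta(reps, outdir / "DMG_representatives.fasta")

    fam_dir = outdir / "DMG_fastas"
    fam_dir.mkdir(exist_ok=True)
    for fam in families:
        write_fasta(fam.members, fam_dir / f"{fam.dmg_id}.fasta")

    rows = []
    for fam in families:
        for orf in fam.members:
            rows.append({
                "DMG_ID": fam.dmg_id,
                "percent_occurrence": round(fam.percent_occurrence, 2),
                "dc_blast_hit": fam.dc_blast_hit,
                "max_blastn": fam.max_blastn,
                "ORF_ID": _qualified_id(orf),
                "ORF_length": orf.length,
                "annotation": orf.annotation,
                "contig": orf.contig,
                "start": orf.start,
                "stop": orf.stop,
            })
    pd.DataFrame(
        rows,
        columns=["DMG_ID", "percent_occurrence", "dc_blast_hit", "max_blastn",
                 "ORF_ID", "ORF_length", "annotation", "contig", "start", "stop"],
    ).to_csv(outdir / "DMG_table.tsv", sep="\t", index=False)

    outputs.distribution.to_csv(outdir / "DMG_distribution.tsv", sep="\t")
    outputs.frequency.to_csv(outdir / "DMG_frequency.tsv", sep="\t")
    cfg.to_file(outdir / "settings.txt")

    with (outdir / "step_counts.log").open("w") as fh:
        for name, count in outputs.step_counts:
            fh.write(f"{name}\t{count}\n")

    member_seqs: dict[str, str] = {}
    for fam in families:
        for orf in fam.members:
            member_seqs[_qualified_id(orf)] = orf.seq
    contig_seqs: dict[str, str] = {}
    if group_b is not None:
        for rec in group_b.all_contigs():
            contig_seqs[rec.id] = rec.seq
    with (outdir / "residual_hits.txt").open("w") as fh:
        for hit in sorted(
            outputs.residual_hits,
            key=lambda h: (h.query_id, h.subject_id, h.s_start),
        ):
            if hit.query_id in member_seqs and hit.subject_id in contig_seqs:
                fh.write(
                    _render_alignment(
                        hit, member_seqs[hit.query_id], contig_seqs[hit.subject_id]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    f"# {hit.query_id} vs {hit.subject_id} "
                    f"identity={hit.perc_identity:.1f}% "
                    f"length={hit.align_length}\n"
                )

    if not cfg.clean_up and intermediates:
        verbose_dir = outdir / "intermediate"
        verbose_dir.mkdir(exist_ok=True)
        for name, orfs in intermediates.items():
            write_fasta(orfs, verbose_dir / f"{name}.fasta")
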