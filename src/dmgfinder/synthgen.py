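"""Deterministic synthetic comparative-genomics fixtures with ground truth.

The generator plants gene content into random bacterial-like genomes so
that every filter of the prediction cascade has a known, constructed
target:

* ``core`` genes shared by every genome of both groups (killed at step 1);
* ``true_dmg`` genes exclusive to the target group (the planted truth);
* ``partial`` target genes present in only a fraction of target genomes
  (killed by the occurrence filter at 100% occurrence);
* ``decoy_unannotated`` / ``decoy_frameshift`` genes annotated in the
  target group but also embedded (unannotated, the latter with a 1 bp
  indel) in a background contig (killed at step 2);
* ``diverged_homolog`` target genes with a background homolog at a chosen
  identity (killed at the sensitive dc screen, step 4);
* ``shortseg`` target genes containing an exact background segment of
  stated length (killed at the short-hit screen, step 5);
* ``multicopy`` target-exclusive genes duplicated within one genome
  (reported with copy number 2);
* ``unequal_annot`` target genes present in every target contig but
  annotated in only k genomes (recovered only via the annotation
  equalizer).

Background composition is i.i.d. nucleotides at the requested GC; planted
genes start with ATG and avoid in-frame stops so protein mode works on the
same fixtures. Same spec + seed => byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align_engine import AlignParams, dp_align_oracle
from .seq_io import GroupData, OrfRecord, SequenceRecord, revcomp, write_fasta

logger = logging.getLogger(__name__)

ROLES = (
    "core", "true_dmg", "partial", "decoy_unannotated", "decoy_frameshift",
    "diverged_homolog", "shortseg", "multicopy", "unequal_annot",
)

# expected fate of each role under default thresholds / min_occurrence 1.0
ROLE_FATE = {
    "core": "step1",
    "true_dmg": "kept",
    "partial": "occurrence_filter",
    "decoy_unannotated": "step2",
    "decoy_frameshift": "step2",
    "diverged_homolog": "step4",
    "shortseg": "step5",
    "multicopy": "kept",
    "unequal_annot": "equalizer_dependent",
}


@dataclass
class SynthSpec:
    """Generator parameters. The defaults are the reference fixture: a
    2-vs-3 strain comparison with every decoy class planted once."""

    n_a: int = 2
    n_b: int = 3
    genome_len: int = 200_000
    n_plasmids: int = 1
    plasmid_len: int = 20_000
    n_core: int = 40
    n_dmg: int = 3
    n_partial: int = 1
    partial_fraction: float = 0.5
    n_unannotated_decoys: int = 1
    n_frameshift_decoys: int = 1
    n_diverged: int = 1
    diverged_identity: float = 0.85
    n_shortseg: int = 1
    shortseg_len: int = 150
    n_multicopy: int = 1
    n_unequal_annot: int = 0
    unequal_annot_k: int = 1
    gene_len: tuple[int, int] = (600, 1200)
    gc: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_a, self.n_b, self.n_core, self.n_dmg, self.n_partial,
            self.n_unannotated_decoys, self.n_frameshift_decoys,
            self.n_diverged, self.n_shortseg, self.n_multicopy,
            self.n_unequal_annot,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("need at least one genome per group")
        if not 0 < self.diverged_identity <= 1:
            raise ValueError("diverged_identity must lie in (0, 1]")
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")
        if self.gene_len[0] < 60 or self.gene_len[0] > self.gene_len[1]:
            raise ValueError("gene_len range invalid")


@dataclass(frozen=True)
class PlantedGene:
    gene_id: str
    role: str
    seq: str
    expected_fate: str


@dataclass
class GroundTruth:
    """Planted genes with role tags and expected pipeline fate."""

    genes: list[PlantedGene] = field(default_factory=list)

    def by_role(self, *roles: str) -> list[PlantedGene]:
        return [g for g in self.genes if g.role in roles]

    def expected_family_genes(self, min_occurrence: float = 1.0,
                              partial_fraction: float | None = None) -> set[str]:
        """Gene ids expected to survive the default cascade."""
        out = {g.gene_id for g in self.by_role("true_dmg", "multicopy")}
        for g in self.by_role("partial"):
            if partial_fraction is not None and partial_fraction >= min_occurrence - 1e-9:
                out.add(g.gene_id)
        return out

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"gene_id": g.gene_id, "role": g.role,
                 "expected_fate": g.expected_fate, "length": len(g.seq)}
                for g in self.genes
            ]
        ).to_csv(path, sep="\t", index=False)


_BASES = np.array(list("ACGT"))


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_gene(rng: np.random.Generator, length: int, gc: float) -> str:
    """ATG + stop-free random codons + TAA, total length rounded to codons."""
    n_codons = max(length // 3, 20)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_dna(rng, 3, gc)
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def mutate_sequence(
    seq: str,
    target_identity: float,
    indel_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    max_retries: int = 30,
) -> str:
    """Mutate ``seq`` so the optimal local-alignment identity to the input
    lands within one percentage point of ``target_identity``.

    Substitutions at uniformly random positions; the stated fraction of
    edits are 1 bp indels. The achieved identity is verified against the
    exact Smith-Waterman oracle, resampling with an adjusted edit count on
    a miss (bounded retries).
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must lie in (0, 1]")
    if target_identity == 1.0:
        return seq
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(seq)
    target_pct = 100.0 * target_identity
    n_edits = max(1, round(n * (1 - target_identity)))
    params = AlignParams(task="megablast_like")
    for _attempt in range(max_retries):
        if n_edits >= n:
            break
        chars = list(seq)
        positions = rng.choice(n, size=n_edits, replace=False)
        n_indels = int(round(indel_fraction * n_edits))
        for k, pos in enumerate(sorted(positions.tolist(), reverse=True)):
            if k < n_indels:
                if k % 2 == 0:
                    del chars[pos]
                else:
                    chars.insert(pos, str(_BASES[rng.integers(4)]))
            else:
                old = chars[pos]
                choices = [b for b in "ACGT" if b != old]
                chars[pos] = choices[int(rng.integers(3))]
        mutated = "".join(chars)
        hit = dp_align_oracle(mutated, seq, params, both_strands=False)
        if hit is None:
            n_edits = max(1, n_edits - max(1, n // 100))
            continue
        achieved = hit.perc_identity
        if abs(achieved - target_pct) <= 1.0 and achieved < 100.0:
            return mutated
        # adjust: one substitution moves identity by ~100/n points
        delta = int(round((achieved - target_pct) * n / 100.0))
        n_edits = max(1, n_edits + (delta if delta else (1 if achieved > target_pct else -1)))
    raise ValueError(
        f"could not reach target identity {target_identity} on a "
        f"{n} bp sequence within {max_retries} attempts"
    )


def _assemble_contig(
    rng: np.random.Generator,
    contig_id: str,
    strain: str,
    placements: list[tuple[str, str, bool]],  # (orf_id, seq, annotate)
    total_len: int,
    gc: float,
    annotations: dict[str, str],
    min_spacer: int = 50,
) -> tuple[SequenceRecord, list[OrfRecord]]:
    """Concatenate random spacers and genes into one contig; genes land on a
    random strand, non-overlapping, separated by >= ``min_spacer`` bp."""
    gene_total = sum(len(seq) for _, seq, _ in placements)
    n_spacers = len(placements) + 1
    needed = gene_total + n_spacers * min_spacer
    if needed > total_len:
        raise ValueError(
            f"contig {contig_id}: planted genes need at least {needed} bp "
            f"but contig length is {total_len}"
        )
    extra = total_len - needed
    if extra > 0 and n_spacers > 0:
        split = rng.multinomial(extra, np.full(n_spacers, 1.0 / n_spacers))
    else:
        split = np.zeros(n_spacers, dtype=int)
    parts: list[str] = []
    orfs: list[OrfRecord] = []
    pos = 0
    for i, (orf_id, gene_seq, annotate) in enumerate(placements):
        spacer = _random_dna(rng, min_spacer + int(split[i]), gc)
        parts.append(spacer)
        pos += len(spacer)
        strand = "+" if rng.random() < 0.5 else "-"
        start = pos + 1
        stop = pos + len(gene_seq)
        parts.append(gene_seq if strand == "+" else revcomp(gene_seq))
        pos = stop
        if annotate:
            orfs.append(
                OrfRecord(
                    orf_id=orf_id, seq=gene_seq, strain=strain,
                    contig=contig_id, start=start, stop=stop, strand=strand,
                    annotation=annotations.get(orf_id, "hypothetical protein"),
                )
            )
    parts.append(_random_dna(rng, min_spacer + int(split[-1]), gc))
    contig = SequenceRecord(id=contig_id, seq="".join(parts))
    return contig, orfs


def generate_dataset(
    spec: SynthSpec, out_dir: str | Path | None = None
) -> tuple[GroupData, GroupData, GroundTruth]:
    """Generate group A (target) and group B (background) with ground truth.

    When ``out_dir`` is given, writes ``group_{a,b}/{genomes,orfs}/<strain>
    .fasta`` plus ``manifest.tsv`` in the layout :func:`seq_io.load_group`
    expects.
    """
    rng = np.random.default_rng(spec.seed)
    glen = lambda: int(rng.integers(spec.gene_len[0], spec.gene_len[1] + 1))  # noqa: E731

    truth = GroundTruth()
    annotations: dict[str, str] = {}

    def plant(role: str, count: int, prefix: str) -> list[PlantedGene]:
        genes = []
        for i in range(count):
            gid = f"{prefix}_{i + 1:03d}"
            gene = PlantedGene(
                gene_id=gid, role=role, seq=_random_gene(rng, glen(), spec.gc),
                expected_fate=ROLE_FATE[role],
            )
            genes.append(gene)
            truth.genes.append(gene)
            annotations[gid] = f"{role} protein {i + 1}"
        return genes

    core = plant("core", spec.n_core, "core")
    dmg = plant("true_dmg", spec.n_dmg, "dmg")
    partial = plant("partial", spec.n_partial, "part")
    dec_un = plant("decoy_unannotated", spec.n_unannotated_decoys, "dun")
    dec_fs = plant("decoy_frameshift", spec.n_frameshift_decoys, "dfs")
    diverged = plant("diverged_homolog", spec.n_diverged, "div")
    shortseg = plant("shortseg", spec.n_shortseg, "sseg")
    multicopy = plant("multicopy", spec.n_multicopy, "mcp")
    unequal = plant("unequal_annot", spec.n_unequal_annot, "uneq")

    # background homolog / embedded copies
    diverged_b = {
        g.gene_id: mutate_sequence(
            g.seq, spec.diverged_identity, indel_fraction=0.1, seed=rng
        )
        for g in diverged
    }
    frameshift_b = {}
    for g in dec_fs:
        cut = int(0.3 * len(g.seq))
        frameshift_b[g.gene_id] = g.seq[:cut] + g.seq[cut + 1:]
    # the planted exact background segment sits mid-gene
    shortseg_b = {}
    for g in shortseg:
        mid = (len(g.seq) - spec.shortseg_len) // 2
        shortseg_b[g.gene_id] = g.seq[mid : mid + spec.shortseg_len]

    n_partial_strains = max(1, int(round(spec.partial_fraction * spec.n_a)))
    a_strains = [f"A{i + 1}" for i in range(spec.n_a)]
    b_strains = [f"B{i + 1}" for i in range(spec.n_b)]

    group_a = GroupData(name="group_a")
    group_b = GroupData(name="group_b")

    for ai, strain in enumerate(a_strains):
        chrom_genes = [(g.gene_id, g.seq, True) for g in core]
        plasmid_genes: list[tuple[str, str, bool]] = []
        bucket = plasmid_genes if spec.n_plasmids else chrom_genes
        for g in dmg + dec_un + dec_fs + diverged + shortseg:
            bucket.append((g.gene_id, g.seq, True))
        for g in partial:
            if ai < n_partial_strains:
                bucket.append((g.gene_id, g.seq, True))
        for g in multicopy:
            bucket.append((f"{g.gene_id}_c1", g.seq, True))
            if ai == 0:
                bucket.append((f"{g.gene_id}_c2", g.seq, True))
                annotations[f"{g.gene_id}_c2"] = annotations.get(
                    g.gene_id, "hypothetical protein"
                )
            annotations[f"{g.gene_id}_c1"] = annotations.get(
                g.gene_id, "hypothetical protein"
            )
        for g in unequal:
            bucket.append((g.gene_id, g.seq, ai < spec.unequal_annot_k))

        contig, orfs = _assemble_contig(
            rng, "chromosome", strain, chrom_genes, spec.genome_len, spec.gc,
            annotations,
        )
        contigs, all_orfs = [contig], list(orfs)
        for p in range(spec.n_plasmids):
            placements = plasmid_genes if p == 0 else []
            pc, porfs = _assemble_contig(
                rng, f"plasmid_{p + 1}", strain, placements, spec.plasmid_len,
                spec.gc, annotations,
            )
            contigs.append(pc)
            all_orfs.extend(porfs)
        group_a.genomes[strain] = contigs
        group_a.orfs[strain] = sorted(
            all_orfs, key=lambda o: (o.contig, o.start)
        )

    for bi, strain in enumerate(b_strains):
        chrom_genes = [(g.gene_id, g.seq, True) for g in core]
        if bi == 0:
            for g in dec_un:
                chrom_genes.append((f"{g.gene_id}_bcopy", g.seq, False))
            for g in dec_fs:
                chrom_genes.append((f"{g.gene_id}_bcopy", frameshift_b[g.gene_id], False))
            for g in shortseg:
                chrom_genes.append((f"{g.gene_id}_bseg", shortseg_b[g.gene_id], False))
        for g in diverged:
            chrom_genes.append((f"{g.gene_id}_hom", diverged_b[g.gene_id], True))
            annotations[f"{g.gene_id}_hom"] = annotations.get(
                g.gene_id, "hypothetical protein"
            )
        contig, orfs = _assemble_contig(
            rng, "chromosome", strain, chrom_genes, spec.genome_len, spec.gc,
            annotations,
        )
        contigs, all_orfs = [contig], list(orfs)
        for p in range(spec.n_plasmids):
            pc, porfs = _assemble_contig(
                rng, f"plasmid_{p + 1}", strain, [], spec.plasmid_len,
                spec.gc, annotations,
            )
            contigs.append(pc)
            all_orfs.extend(porfs)
        group_b.genomes[strain] = contigs
        group_b.orfs[strain] = sorted(
            all_orfs, key=lambda o: (o.contig, o.start)
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        for group, label in ((group_a, "group_a"), (group_b, "group_b")):
            gdir = out_dir / label / "genomes"
            odir = out_dir / label / "orfs"
            gdir.mkdir(parents=True, exist_ok=True)
            odir.mkdir(parents=True, exist_ok=True)
            for strain in group.strains:
                write_fasta(group.genomes[strain], gdir / f"{strain}.fasta")
                write_fasta(group.orfs[strain], odir / f"{strain}.fasta")
        truth.to_tsv(out_dir / "manifest.tsv")
    return group_a, group_b, truth


def read_spec_file(path: str | Path) -> SynthSpec:
    """Read a flat ``key = value`` generator spec file."""
    kwargs: dict = {}
    import dataclasses

    valid = {f.name for f in dataclasses.fields(SynthSpec)}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown spec key {key!r}")
        if key == "gene_len":
            lo, hi = val.replace(",", " ").split()
            kwargs[key] = (int(lo), int(hi))
        elif key in ("partial_fraction", "diverged_identity", "gc"):
            kwargs[key] = float(val)
        else:
            kwargs[key] = int(val)
    return SynthSpec(**kwargs)
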