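"""Local-alignment search between sequence sets.

The pipeline expresses every decision in percent identity and query/subject
coverage, so the engine contract is small: given queries, subjects and
cutoffs, return the best local alignment per query-subject pair that clears
the cutoffs. Two backends satisfy it:

* ``builtin`` (default) — exact k-mer seeding on both strands, diagonal-band
  seed clustering, then gapped extension of the query inside a subject
  window (edit-distance path via edlib, rescored under the engine's affine
  scoring, with the best-scoring contiguous sub-path kept as the local hit).
  Word sizes mirror the BLAST family: 28 for ``megablast_like``, 11 for
  ``blastn_like`` and ``dc_like``, 3 for ``blastp_like``. ``dc_like`` is the
  higher-sensitivity nucleotide screen (small word, gap-tolerant seeding)
  emulating discontiguous megablast's role without its exact seed templates.
* ``external`` — shells out to NCBI blastn/blastp tabular output, then
  applies the same cutoffs. Falls back to builtin when the binary is absent.

:func:`dp_align_oracle` is an exact Smith-Waterman reference (full-matrix
optimal local alignment under the same scoring, via biotite) used by the
test suite as an independent check on the seeded engine; it is never on the
production path.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from .seq_io import SequenceRecord, revcomp, write_fasta

logger = logging.getLogger(__name__)

NUC_TASKS = ("megablast_like", "dc_like", "blastn_like")
PROT_TASKS = ("blastp_like",)
DEFAULT_WORD_SIZE = {
    "megablast_like": 28,
    "dc_like": 11,
    "blastn_like": 11,
    "blastp_like": 3,
}

_NUC_ALPHABET = set("ACGTN")
_PROT_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*U")


@dataclass
class AlignParams:
    """Search task plus the identity/coverage cutoffs applied to hits."""

    task: str = "megablast_like"
    word_size: int | None = None
    perc_identity_cut: float = 0.0
    query_cov_cut: float = 0.0
    subject_cov_cut: float | None = None
    max_target_hits: int = 500
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    protein_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.task not in NUC_TASKS + PROT_TASKS:
            raise ValueError(f"unknown alignment task {self.task!r}")
        if self.word_size is None:
            self.word_size = DEFAULT_WORD_SIZE[self.task]
        floor = 2 if self.task in PROT_TASKS else 4
        if self.word_size < floor:
            raise ValueError(
                f"word_size {self.word_size} below minimum {floor} for {self.task}"
            )
        for cut in (self.perc_identity_cut, self.query_cov_cut):
            if not 0 <= cut <= 100:
                raise ValueError("identity/coverage cutoffs must lie in [0, 100]")
        if self.subject_cov_cut is not None and not 0 <= self.subject_cov_cut <= 100:
            raise ValueError("subject_cov_cut must lie in [0, 100]")

    @property
    def is_protein(self) -> bool:
        return self.task in PROT_TASKS


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject.

    Coordinates are 1-based inclusive; ``s_start > s_end`` marks a
    minus-strand hit. ``perc_identity`` is matches over alignment columns
    (gaps included); coverage percentages are span over full length.
    """

    query_id: str
    subject_id: str
    perc_identity: float
    align_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    query_cov: float
    subject_cov: float
    score: float

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"


def hit_passes(hit: AlignmentHit, params: AlignParams) -> bool:
    """True iff the hit clears every cutoff set in ``params`` (inclusive >=)."""
    if hit.perc_identity < params.perc_identity_cut:
        return False
    if hit.query_cov < params.query_cov_cut:
        return False
    if params.subject_cov_cut is not None and hit.subject_cov < params.subject_cov_cut:
        return False
    return True


# --- translation -----------------------------------------------------------

_TABLE11 = None


def _codon_table():
    global _TABLE11
    if _TABLE11 is None:
        from Bio.Data import CodonTable

        _TABLE11 = CodonTable.unambiguous_dna_by_id[11]
    return _TABLE11


def translate_orf(seq: str) -> str:
    """Translate a coding-strand DNA sequence with the bacterial code
    (translation table 11).

    The first codon becomes M when it is a recognised start (ATG/GTG/TTG);
    internal stops are kept as ``*`` with a warning, a trailing partial
    codon is dropped with a warning.
    """
    if len(seq) < 3:
        raise ValueError(f"cannot translate sequence of length {len(seq)} (< 3)")
    table = _codon_table()
    if len(seq) % 3:
        logger.warning("dropping trailing partial codon (%d nt)", len(seq) % 3)
    aas: list[str] = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if codon in table.stop_codons:
            aas.append("*")
            if i + 3 < len(seq) - 2:
                logger.warning("internal stop codon at nt %d kept as '*'", i + 1)
        else:
            aas.append(table.forward_table.get(codon, "X"))
    if seq[:3] in ("ATG", "GTG", "TTG"):
        aas[0] = "M"
    return "".join(aas)


# --- scoring helpers -------------------------------------------------------

_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _pair_score(a: str, b: str, params: AlignParams) -> tuple[float, bool]:
    """(score, is_match) for one aligned column; N never counts as a match."""
    if params.is_protein:
        mat = _blosum62()
        try:
            sc = float(mat[a, b])
        except (KeyError, IndexError):
            sc = float(params.mismatch)
        return sc, a == b and a not in ("X", "*")
    if a == b and a != "N":
        return float(params.match), True
    return float(params.mismatch), False


# --- the exact DP oracle ---------------------------------------------------

_ORACLE_MAX_COMBINED = 20_000


def dp_align_oracle(
    q: SequenceRecord | str,
    s: SequenceRecord | str,
    params: AlignParams | None = None,
    both_strands: bool = True,
) -> AlignmentHit | None:
    """Optimal-score Smith-Waterman local alignment under the engine scoring.

    Full-matrix dynamic programming (quadratic); guarded to a combined
    length of 20 kb. Returns ``None`` when no positive-scoring local
    alignment exists. Test oracle only.
    """
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    params = params or AlignParams()
    qid = q.id if isinstance(q, SequenceRecord) else "query"
    sid = s.id if isinstance(s, SequenceRecord) else "subject"
    qseq = q.seq if isinstance(q, SequenceRecord) else q
    sseq = s.seq if isinstance(s, SequenceRecord) else s
    if len(qseq) + len(sseq) > _ORACLE_MAX_COMBINED:
        raise ValueError(
            f"oracle size guard: combined length {len(qseq) + len(sseq)} "
            f"exceeds {_ORACLE_MAX_COMBINED}"
        )

    if params.is_protein:
        matrix = balign.SubstitutionMatrix.std_protein_matrix()
        alph = matrix.get_alphabet1()
        mk = lambda t: bseq.GeneralSequence(alph, list(t))  # noqa: E731
        strands = [("+", qseq)]
    else:
        alph = bseq.Alphabet(["A", "C", "G", "T", "N"])
        m = np.full((5, 5), params.mismatch, dtype=np.int32)
        for i in range(4):
            m[i, i] = params.match
        matrix = balign.SubstitutionMatrix(alph, alph, m)
        mk = lambda t: bseq.GeneralSequence(alph, list(t))  # noqa: E731
        strands = [("+", qseq)]
        if both_strands:
            strands.append(("-", revcomp(qseq)))

    best: AlignmentHit | None = None
    for strand, qs in strands:
        alns = balign.align_optimal(
            mk(qs), mk(sseq), matrix,
            gap_penalty=(params.gap_open, params.gap_extend),
            local=True, max_number=1,
        )
        if not alns:
            continue
        aln = alns[0]
        if aln.score <= 0 or len(aln.trace) == 0:
            continue
        matches = 0
        ncols = len(aln.trace)
        for qi, si in aln.trace:
            if qi != -1 and si != -1:
                _, is_m = _pair_score(qs[qi], sseq[si], params)
                matches += int(is_m)
        qlo = int(min(t[0] for t in aln.trace if t[0] != -1))
        qhi = int(max(t[0] for t in aln.trace if t[0] != -1))
        slo = int(min(t[1] for t in aln.trace if t[1] != -1))
        shi = int(max(t[1] for t in aln.trace if t[1] != -1))
        if strand == "-":
            q_start, q_end = len(qseq) - qhi, len(qseq) - qlo
            s_start, s_end = shi + 1, slo + 1
        else:
            q_start, q_end = qlo + 1, qhi + 1
            s_start, s_end = slo + 1, shi + 1
        hit = AlignmentHit(
            query_id=qid,
            subject_id=sid,
            perc_identity=100.0 * matches / ncols,
            align_length=ncols,
            q_start=q_start,
            q_end=q_end,
            s_start=s_start,
            s_end=s_end,
            query_cov=100.0 * (q_end - q_start + 1) / len(qseq),
            subject_cov=100.0 * (abs(s_end - s_start) + 1) / len(sseq),
            score=float(aln.score),
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


# --- builtin seed-and-extend engine ---------------------------------------

_BAND_PAD = 48  # subject-window padding beyond the seed diagonal span
_MAX_WINDOWS_PER_PAIR = 4
_DIAG_CLUSTER_GAP = 40  # seeds within this diagonal distance share a window


def _kmer_index(
    queries: list[tuple[int, str, str]], word: int
) -> dict[str, list[tuple[int, str, int]]]:
    """kmer -> [(query_index, strand, query_position)] over all query strands."""
    index: dict[str, list[tuple[int, str, int]]] = {}
    for qi, strand, seq in queries:
        for pos in range(0, len(seq) - word + 1):
            kmer = seq[pos : pos + word]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((qi, strand, pos))
    return index


def _rescore_path(
    qseq: str, window: str, cigar: str, q0: int, s0: int, params: AlignParams
) -> tuple[float, int, int, int, int, int, int] | None:
    """Walk an edlib CIGAR, rescore columns under the affine scoring, and
    return the best-scoring contiguous sub-path (Kadane over columns).

    Returns (score, matches, ncols, q_lo, q_hi, s_lo, s_hi) in 0-based
    half-open-ish coordinates on qseq/window, or None if nothing positive.
    """
    # expand cigar into per-column (op) steps
    cols: list[tuple[float, bool, int, int]] = []  # score, match, qpos, spos
    qi, si = q0, s0
    num = ""
    gap_open, gap_ext = params.gap_open, params.gap_extend
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        run = int(num)
        num = ""
        if ch in "=X":
            for _ in range(run):
                sc, ism = _pair_score(qseq[qi], window[si], params)
                cols.append((sc, ism, qi, si))
                qi += 1
                si += 1
        elif ch == "I":  # insertion to target = gap in subject (query consumed)
            for k in range(run):
                sc = gap_open + gap_ext if k == 0 else gap_ext
                cols.append((float(sc), False, qi, -1))
                qi += 1
        elif ch == "D":  # deletion = gap in query (subject consumed)
            for k in range(run):
                sc = gap_open + gap_ext if k == 0 else gap_ext
                cols.append((float(sc), False, -1, si))
                si += 1
        else:
            raise ValueError(f"unexpected CIGAR op {ch!r}")
    if not cols:
        return None
    # Kadane: best contiguous column run
    best_sum = 0.0
    best_span: tuple[int, int] | None = None
    cur_sum = 0.0
    cur_start = 0
    for i, (sc, _ism, _qp, _sp) in enumerate(cols):
        if cur_sum <= 0:
            cur_sum = sc
            cur_start = i
        else:
            cur_sum += sc
        if cur_sum > best_sum:
            best_sum = cur_sum
            best_span = (cur_start, i)
    if best_span is None or best_sum <= 0:
        return None
    lo, hi = best_span
    # trim boundary gap columns (a local alignment never starts/ends in a gap)
    while lo <= hi and (cols[lo][2] == -1 or cols[lo][3] == -1):
        lo += 1
    while hi >= lo and (cols[hi][2] == -1 or cols[hi][3] == -1):
        hi -= 1
    if hi < lo:
        return None
    seg = cols[lo : hi + 1]
    score = sum(c[0] for c in seg)
    matches = sum(1 for c in seg if c[1])
    qps = [c[2] for c in seg if c[2] != -1]
    sps = [c[3] for c in seg if c[3] != -1]
    return (score, matches, len(seg), min(qps), max(qps), min(sps), max(sps))


def _extend_in_window(
    qseq_oriented: str,
    subject: str,
    win_lo: int,
    win_hi: int,
    params: AlignParams,
) -> tuple[float, int, int, int, int, int, int] | None:
    """Glocal edlib alignment of the oriented query inside subject[win_lo:win_hi],
    rescored to the best local sub-path. Subject coordinates returned are
    0-based on the full subject."""
    window = subject[win_lo:win_hi]
    if not window:
        return None
    res = edlib.align(qseq_oriented, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    s_off = res["locations"][0][0]
    if s_off is None:
        s_off = 0
    out = _rescore_path(qseq_oriented, window, res["cigar"], 0, s_off, params)
    if out is None:
        return None
    score, matches, ncols, qlo, qhi, slo, shi = out
    return (score, matches, ncols, qlo, qhi, slo + win_lo, shi + win_lo)


def _make_hit(
    qid: str,
    sid: str,
    qlen: int,
    slen: int,
    strand: str,
    ext: tuple[float, int, int, int, int, int, int],
) -> AlignmentHit:
    score, matches, ncols, qlo, qhi, slo, shi = ext
    if strand == "-":
        # qlo/qhi are on the reverse-complemented query
        q_start, q_end = qlen - qhi, qlen - qlo
        s_start, s_end = shi + 1, slo + 1
    else:
        q_start, q_end = qlo + 1, qhi + 1
        s_start, s_end = slo + 1, shi + 1
    return AlignmentHit(
        query_id=qid,
        subject_id=sid,
        perc_identity=100.0 * matches / ncols,
        align_length=ncols,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        query_cov=100.0 * (q_end - q_start + 1) / qlen,
        subject_cov=100.0 * (abs(s_end - s_start) + 1) / slen,
        score=score,
    )


def _validate_alphabet(records: list[SequenceRecord], params: AlignParams, what: str) -> None:
    alpha = _PROT_ALPHABET if params.is_protein else _NUC_ALPHABET
    for rec in records:
        head = set(rec.seq[:200])
        if not head <= alpha:
            bad = "".join(sorted(head - alpha))
            kind = "protein" if params.is_protein else "nucleotide"
            raise ValueError(
                f"{what} {rec.id!r} is not a {kind} sequence for task "
                f"{params.task} (unexpected characters {bad!r})"
            )
        if not params.is_protein and set(rec.seq) & set("EFILPQZ*"):
            raise ValueError(
                f"{what} {rec.id!r} contains protein characters but task "
                f"{params.task} is nucleotide"
            )


def find_hits_builtin(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    params: AlignParams,
) -> list[AlignmentHit]:
    """Seed-and-extend search; best hit per query-subject pair, filtered by
    the cutoffs in ``params``, sorted by (query_id, descending score)."""
    _validate_alphabet(queries, params, "query")
    _validate_alphabet(subjects, params, "subject")
    word = int(params.word_size)
    # two-hit seeding for small words keeps random 200 kb backgrounds quiet
    min_seeds = 2 if word < 16 else 1

    oriented: list[tuple[int, str, str]] = []
    for qi, q in enumerate(queries):
        oriented.append((qi, "+", q.seq))
        if not params.is_protein:
            oriented.append((qi, "-", revcomp(q.seq)))
    index = _kmer_index(oriented, word)
    oriented_seq = {(qi, st): seq for qi, st, seq in oriented}

    hits: list[AlignmentHit] = []
    for subj in subjects:
        sseq = subj.seq
        best_per_query: dict[int, AlignmentHit] = {}
        # exact-containment fast path
        handled_exact: set[tuple[int, str]] = set()
        for qi, strand, qs in oriented:
            pos = sseq.find(qs)
            if pos < 0:
                continue
            handled_exact.add((qi, strand))
            q = queries[qi]
            score = float(len(qs) * params.match) if not params.is_protein else float(
                sum(_pair_score(c, c, params)[0] for c in qs)
            )
            ident = 100.0 * sum(
                1 for c in qs if c != "N"
            ) / len(qs) if not params.is_protein else 100.0
            if strand == "-":
                s_start, s_end = pos + len(qs), pos + 1
            else:
                s_start, s_end = pos + 1, pos + len(qs)
            hit = AlignmentHit(
                query_id=q.id,
                subject_id=subj.id,
                perc_identity=ident,
                align_length=len(qs),
                q_start=1,
                q_end=len(qs),
                s_start=s_start,
                s_end=s_end,
                query_cov=100.0,
                subject_cov=100.0 * len(qs) / len(sseq),
                score=score,
            )
            prev = best_per_query.get(qi)
            if prev is None or hit.score > prev.score:
                best_per_query[qi] = hit

        # seed scan
        seeds: dict[tuple[int, str], dict[int, list[int]]] = {}
        if index:
            for spos in range(0, len(sseq) - word + 1):
                kmer = sseq[spos : spos + word]
                entry = index.get(kmer)
                if not entry:
                    continue
                for qi, strand, qpos in entry:
                    if (qi, strand) in handled_exact:
                        continue
                    diag = spos - qpos
                    seeds.setdefault((qi, strand), {}).setdefault(diag, []).append(spos)

        for (qi, strand), diags in sorted(seeds.items()):
            qs = oriented_seq[(qi, strand)]
            q = queries[qi]
            # cluster diagonals within _DIAG_CLUSTER_GAP
            clusters: list[list[int]] = []
            for d in sorted(diags):
                if clusters and d - clusters[-1][-1] <= _DIAG_CLUSTER_GAP:
                    clusters[-1].append(d)
                else:
                    clusters.append([d])
            scored_clusters = []
            for cluster in clusters:
                n_seeds = sum(len(diags[d]) for d in cluster)
                if n_seeds < min_seeds:
                    continue
                positions = [p for d in cluster for p in diags[d]]
                scored_clusters.append((n_seeds, min(cluster), cluster, positions))
            scored_clusters.sort(key=lambda t: (-t[0], t[1]))
            for _n, _d0, cluster, positions in scored_clusters[:_MAX_WINDOWS_PER_PAIR]:
                dlo, dhi = min(cluster), max(cluster)
                win_lo = max(0, dlo - _BAND_PAD)
                win_hi = min(len(sseq), dhi + len(qs) + _BAND_PAD)
                # ensure the window covers seed span generously
                win_lo = min(win_lo, max(0, min(positions) - len(qs)))
                win_hi = max(win_hi, min(len(sseq), max(positions) + word + len(qs)))
                ext = _extend_in_window(qs, sseq, win_lo, win_hi, params)
                if ext is None:
                    continue
                hit = _make_hit(q.id, subj.id, len(qs), len(sseq), strand, ext)
                prev = best_per_query.get(qi)
                if prev is None or hit.score > prev.score:
                    best_per_query[qi] = hit

        for qi in sorted(best_per_query):
            hit = best_per_query[qi]
            if hit_passes(hit, params):
                hits.append(hit)

    hits.sort(key=lambda h: (h.query_id, -h.score, h.subject_id, h.s_start))
    # cap hits per query
    capped: list[AlignmentHit] = []
    count: dict[str, int] = {}
    for hit in hits:
        c = count.get(hit.query_id, 0)
        if c < params.max_target_hits:
            capped.append(hit)
            count[hit.query_id] = c + 1
    return capped


# --- external BLAST+ backend ----------------------------------------------

_BLAST_FIELDS = "qseqid sseqid pident length qstart qend sstart send bitscore qlen slen"


def _blast_binary(params: AlignParams) -> str | None:
    name = "blastp" if params.is_protein else "blastn"
    return shutil.which(name)


def find_hits_external(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    params: AlignParams,
) -> list[AlignmentHit]:
    """Search via NCBI BLAST+ tabular output, filtered with the same cutoffs.

    Maps ``megablast_like``/``dc_like``/``blastn_like`` to blastn -task
    megablast/dc-megablast/blastn and ``blastp_like`` to blastp. Falls back
    to the builtin engine when the binary is not on PATH.
    """
    binary = _blast_binary(params)
    if binary is None:
        logger.warning("BLAST+ binary not found; falling back to builtin engine")
        return find_hits_builtin(queries, subjects, params)
    _validate_alphabet(queries, params, "query")
    _validate_alphabet(subjects, params, "subject")
    task_map = {
        "megablast_like": "megablast",
        "dc_like": "dc-megablast",
        "blastn_like": "blastn",
    }
    with tempfile.TemporaryDirectory(prefix="dmgfinder_blast_") as tmp:
        qpath = Path(tmp) / "q.fasta"
        spath = Path(tmp) / "s.fasta"
        write_fasta(queries, qpath)
        write_fasta(subjects, spath)
        cmd = [
            binary, "-query", str(qpath), "-subject", str(spath),
            "-outfmt", f"6 {_BLAST_FIELDS}", "-evalue", "1000",
            "-max_target_seqs", str(max(params.max_target_hits, 500)),
        ]
        if not params.is_protein:
            cmd += ["-task", task_map[params.task], "-dust", "no"]
            if params.task != "dc_like":
                cmd += ["-word_size", str(params.word_size)]
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
    best: dict[tuple[str, str], AlignmentHit] = {}
    for line in proc.stdout.splitlines():
        f = line.split("\t")
        qid, sid = f[0], f[1]
        qlen, slen = int(f[9]), int(f[10])
        q_start, q_end = int(f[4]), int(f[5])
        s_start, s_end = int(f[6]), int(f[7])
        hit = AlignmentHit(
            query_id=qid,
            subject_id=sid,
            perc_identity=float(f[2]),
            align_length=int(f[3]),
            q_start=q_start,
            q_end=q_end,
            s_start=s_start,
            s_end=s_end,
            query_cov=100.0 * (abs(q_end - q_start) + 1) / qlen,
            subject_cov=100.0 * (abs(s_end - s_start) + 1) / slen,
            score=float(f[8]),
        )
        key = (qid, sid)
        prev = best.get(key)
        if prev is None or hit.score > prev.score:
            best[key] = hit
    hits = [h for h in best.values() if hit_passes(h, params)]
    hits.sort(key=lambda h: (h.query_id, -h.score, h.subject_id, h.s_start))
    return hits


def find_hits(
    queries: list[SequenceRecord],
    subjects: list[SequenceRecord],
    params: AlignParams,
    backend: str = "builtin",
) -> list[AlignmentHit]:
    """Dispatch to the selected backend (``builtin`` or ``external``)."""
    if not queries or not subjects:
        return []
    if backend == "external":
        return find_hits_external(queries, subjects, params)
    if backend != "builtin":
        raise ValueError(f"unknown backend {backend!r}")
    return find_hits_builtin(queries, subjects, params)
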