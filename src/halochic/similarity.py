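"""Pairwise local alignment and the coverage/identity quantities used downstream.

Hits are either ingested from 12-column BLAST tabular output (``-outfmt 6``) or
produced by a built-in Smith-Waterman aligner suitable for desk-scale corpora.
Coordinates follow the BLAST convention: 1-based, inclusive, on the unaligned
sequences.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: columns of the ``-outfmt 6`` dialect, in order
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class HitParseError(ValueError):
    """Raised when a tabular hit line cannot be interpreted."""


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local alignment in BLAST tabular terms.

    ``aln_length`` counts alignment columns (matches + mismatches + gap
    columns), so it can exceed either aligned span.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatch: int
    gapopen: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ValueError(
                f"inverted coordinates in hit {self.query_id}/{self.subject_id}"
            )
        if self.aln_length < 1:
            raise ValueError("alignment length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("percent identity must lie in [0, 100]")
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start + 1

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start + 1

    def swapped(self) -> "AlignmentHit":
        """The same alignment reported with query and subject exchanged."""
        return AlignmentHit(
            query_id=self.subject_id,
            subject_id=self.query_id,
            pct_identity=self.pct_identity,
            aln_length=self.aln_length,
            mismatch=self.mismatch,
            gapopen=self.gapopen,
            q_start=self.s_start,
            q_end=self.s_end,
            s_start=self.q_start,
            s_end=self.q_end,
            evalue=self.evalue,
            bitscore=self.bitscore,
        )


@dataclass
class ScoringScheme:
    """Scoring for the built-in local aligner.

    E-values are a deterministic Karlin-Altschul-style transform of the raw
    score and the search-space size.  They provide a monotone ranking
    compatible with the printed thresholds but are not calibrated against any
    BLAST release.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267  # gapped BLOSUM62 (11,1) analogue
    karlin_k: float = 0.041
    db_residues: int = 1_000_000

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        self._aligner = Align.PairwiseAligner(mode="local")
        self._aligner.substitution_matrix = substitution_matrices.load(
            self.matrix_name
        )
        # a gap of length L costs gap_open + L * gap_extend
        self._aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        self._aligner.extend_gap_score = -self.gap_extend

    def bitscore(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def evalue(self, raw_score: float, query_len: int) -> float:
        return query_len * self.db_residues * 2.0 ** (-self.bitscore(raw_score))

    def min_raw_score(self, evalue_max: float, query_len: int) -> float:
        """Smallest raw score whose E-value is below ``evalue_max``."""
        bits = math.log2(query_len * self.db_residues / evalue_max)
        return (bits * math.log(2) + math.log(self.karlin_k)) / self.karlin_lambda


def soft_mask(sequence: str) -> str:
    """Low-complexity masking hook; intentionally a no-op.

    BLAST-style SEG masking is not reproduced here; synthetic corpora carry no
    low-complexity tracts.  The hook exists so a masking stage has a seam.
    """
    return sequence


# ---------------------------------------------------------------------------
# tabular IO


def parse_hits(stream: TextIO | str | Iterable[str]) -> list[AlignmentHit]:
    """Parse BLAST tabular (``-outfmt 6``) rows into :class:`AlignmentHit`.

    Malformed rows raise :class:`HitParseError` naming the 1-based line.
    Comment lines (``#``) and blank lines are skipped.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    hits: list[AlignmentHit] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 12:
            raise HitParseError(
                f"line {lineno}: expected 12 columns, got {len(fields)}"
            )
        try:
            hits.append(
                AlignmentHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise HitParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_hits(hits: Iterable[AlignmentHit], stream: TextIO) -> None:
    """Write hits as 12-column BLAST tabular rows."""
    for h in hits:
        stream.write(
            f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_length}\t"
            f"{h.mismatch}\t{h.gapopen}\t{h.q_start}\t{h.q_end}\t{h.s_start}\t"
            f"{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
        )


def read_fasta(path_or_stream) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    The id is the first whitespace-delimited header token.
    """
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(path_or_stream, "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path_or_stream) -> None:
    records = [
        SeqRecord(Seq(seq), id=pid, description="") for pid, seq in sequences.items()
    ]
    SeqIO.write(records, path_or_stream, "fasta")


# ---------------------------------------------------------------------------
# alignment


def _alignment_stats(alignment, seq_a: str, seq_b: str):
    """Identities, mismatches, gap openings and column count of an alignment."""
    blocks_a, blocks_b = alignment.aligned
    identities = 0
    mismatches = 0
    gapopen = 0
    columns = 0
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            jump_a = a0 - prev_a_end
            jump_b = b0 - prev_b_end
            columns += jump_a + jump_b
            gapopen += (jump_a > 0) + (jump_b > 0)
        for ca, cb in zip(seq_a[a0:a1], seq_b[b0:b1]):
            if ca == cb:
                identities += 1
            else:
                mismatches += 1
        columns += a1 - a0
        prev_a_end, prev_b_end = a1, b1
    return identities, mismatches, gapopen, columns


def local_align(
    seq_a: str,
    seq_b: str,
    scheme: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """Optimal Smith-Waterman local alignment with affine gaps.

    Returns a single best-scoring hit (or an empty list when no
    positive-scoring window exists).  Coordinates are 1-based inclusive;
    percent identity is identities over alignment columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    scheme = scheme or ScoringScheme()
    alignments = scheme._aligner.align(soft_mask(seq_a), soft_mask(seq_b))
    if len(alignments) == 0 or alignments.score <= 0:
        return []
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return []
    identities, mismatches, gapopen, columns = _alignment_stats(aln, seq_a, seq_b)
    raw = aln.score
    return [
        AlignmentHit(
            query_id=query_id,
            subject_id=subject_id,
            pct_identity=100.0 * identities / columns,
            aln_length=columns,
            mismatch=mismatches,
            gapopen=gapopen,
            q_start=int(blocks_a[0][0]) + 1,
            q_end=int(blocks_a[-1][1]),
            s_start=int(blocks_b[0][0]) + 1,
            s_end=int(blocks_b[-1][1]),
            evalue=scheme.evalue(raw, len(seq_a)),
            bitscore=scheme.bitscore(raw),
        )
    ]


def all_vs_all(
    queries: Mapping[str, str],
    subjects: Mapping[str, str] | None = None,
    scheme: ScoringScheme | None = None,
    evalue_max: float | None = None,
    emit_both_directions: bool = True,
) -> list[AlignmentHit]:
    """Align every query against every subject (or all unordered pairs).

    A cheap raw-score prescreen (``aligner.score``) skips pairs that cannot
    reach ``evalue_max`` before the full traceback is computed.  With
    ``subjects=None`` the comparison is all-vs-all over ``queries`` excluding
    self-hits; each passing pair is reported in both orientations so the hit
    table behaves like a symmetric BLAST run.
    """
    scheme = scheme or ScoringScheme()
    symmetric = subjects is None
    subjects = queries if symmetric else subjects
    q_ids = sorted(queries)
    s_ids = sorted(subjects)
    hits: list[AlignmentHit] = []
    aligner = scheme._aligner
    for i, qid in enumerate(q_ids):
        qseq = queries[qid]
        if evalue_max is not None:
            min_raw = scheme.min_raw_score(evalue_max * 100.0, len(qseq))
        else:
            min_raw = 0.0
        start = i + 1 if symmetric else 0
        for sid in s_ids[start:]:
            if symmetric and sid == qid:
                continue
            sseq = subjects[sid]
            if aligner.score(qseq, sseq) < min_raw:
                continue
            for hit in local_align(qseq, sseq, scheme, qid, sid):
                hits.append(hit)
                if emit_both_directions:
                    hits.append(hit.swapped())
    return hits


def mutual_coverage(
    hit: AlignmentHit, len_q: int, len_s: int
) -> tuple[float, float]:
    """Aligned fraction of the query and of the subject.

    Both coverages must independently clear a threshold for the "mutual
    coverage" criteria used by the family and screening filters.
    """
    if len_q <= 0 or len_s <= 0:
        raise ValueError("sequence lengths must be positive")
    if hit.q_end > len_q or hit.s_end > len_s:
        raise ValueError(
            f"hit {hit.query_id}/{hit.subject_id} extends beyond sequence length"
        )
    return (hit.q_span / len_q, hit.s_span / len_s)
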