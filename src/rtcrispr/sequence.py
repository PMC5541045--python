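"""Core sequence operations: identity, dereplication, consensus, local search.

This module is the engine behind the pipeline's filtering and annotation
steps: a CD-HIT-style greedy dereplication of protein sets at an identity
ceiling, a progressive (center-star) consensus builder used to derive one
representative sequence per protein clade, and an exact Smith-Waterman
local search whose scores are converted to bit scores and e-values with
gapped Karlin-Altschul statistics, mirroring how BLAST reports hits.

Alignments are computed with Biopython's ``PairwiseAligner`` (exact dynamic
programming, affine gaps); no heuristic seeding is used, which is fine at
the scale this package operates on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

# Published gapped Karlin-Altschul parameters for BLOSUM62 with
# gap open 11 / extend 1 (the BLASTP defaults).
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041


@dataclass
class DomainHit:
    """A located domain annotation on a protein (1-based inclusive aa coords)."""

    family: str
    start: int
    end: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"domain start {self.start} > end {self.end}")
        if self.evalue <= 0:
            raise ValueError("e-value must be positive")


@dataclass
class ProteinRecord:
    """A protein sequence with optional organism/phylum metadata and domains."""

    id: str
    sequence: str
    organism: str = ""
    phylum: str = ""
    domains: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(f"record {self.id!r}: invalid residues {sorted(bad)}")
        for d in self.domains:
            if d.end > len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: domain {d.family} exceeds sequence length"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SearchParams:
    """Scoring and extreme-value statistics for local similarity search.

    ``lambda_`` and ``K`` are the gapped Karlin-Altschul parameters matching
    the substitution matrix and gap costs; defaults are the published
    BLOSUM62 11/1 values.  ``search_space_policy`` controls the m*n term of
    the e-value: ``product-of-lengths`` uses the raw query x target lengths,
    ``effective-length`` subtracts the expected HSP length from each.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = BLOSUM62_GAPPED_LAMBDA
    K: float = BLOSUM62_GAPPED_K
    search_space_policy: str = "product-of-lengths"

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.search_space_policy not in ("product-of-lengths", "effective-length"):
            raise ValueError(f"unknown search space policy {self.search_space_policy!r}")

    def matrix(self):
        return substitution_matrices.load(self.substitution_matrix)


@dataclass
class Hit:
    """One local-search hit, with 1-based inclusive query coordinates."""

    target_id: str
    score: float
    bitscore: float
    evalue: float
    query_start: int = 0
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0


DEFAULT_PARAMS = SearchParams()


def _global_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = params.matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    # terminal gaps are free: overhangs are not penalised
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    aligner.mode = "global"
    return aligner


def _local_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = params.matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "local"
    return aligner


def pairwise_identity(a: str, b: str, params: SearchParams | None = None) -> float:
    """Percent identity between two sequences in [0, 100].

    Computed on the optimal global alignment with free terminal gaps
    (so a shorter sequence is not penalised for overhangs), with the number
    of identical aligned positions divided by the length of the shorter
    sequence — the CD-HIT denominator convention.  Arguments are
    canonically ordered before aligning so the result is symmetric even
    when co-optimal alignments exist.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    if (b, a) < (a, b):
        a, b = b, a
    params = params or DEFAULT_PARAMS
    aligner = _global_aligner(params)
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return 100.0 * identities / min(len(a), len(b))


def dereplicate(
    records: Sequence[ProteinRecord],
    max_identity: float = 85.0,
    min_len: int = 200,
    params: SearchParams | None = None,
) -> list[ProteinRecord]:
    """Greedy longest-first dereplication at an identity ceiling.

    Records shorter than ``min_len`` are dropped.  The remainder are
    processed longest-first (ties broken by input order); a record is kept
    iff its identity to every already-kept representative is at most
    ``max_identity`` percent.  The returned list preserves the input order
    of the keepers.
    """
    survivors = [r for r in records if len(r) >= min_len]
    order = sorted(range(len(survivors)), key=lambda i: (-len(survivors[i]), i))
    kept_idx: list[int] = []
    for i in order:
        rec = survivors[i]
        if all(
            pairwise_identity(rec.sequence, survivors[j].sequence, params) <= max_identity
            for j in kept_idx
        ):
            kept_idx.append(i)
    kept_idx.sort()
    return [survivors[i] for i in kept_idx]


def _merge_alignment(rows: list[str], new_seq: str, params: SearchParams) -> list[str]:
    """Align ``new_seq`` against the current profile consensus and propagate
    gaps into all rows ('once a gap, always a gap')."""
    profile = _column_consensus(rows, majority=0.0, drop_gap_majority=False)
    aligner = _global_aligner(params)
    alignment = aligner.align(profile, new_seq)[0]
    a_gapped, b_gapped = alignment[0], alignment[1]
    out_rows = []
    for row in rows:
        merged = []
        k = 0
        for col in a_gapped:
            if col == "-":
                merged.append("-")
            else:
                merged.append(row[k])
                k += 1
        out_rows.append("".join(merged))
    out_rows.append(b_gapped)
    return out_rows


def _column_consensus(
    rows: list[str], majority: float, drop_gap_majority: bool = True
) -> str:
    n = len(rows)
    out = []
    for col in zip(*rows):
        gaps = col.count("-")
        if drop_gap_majority and gaps > n / 2:
            continue
        counts: dict[str, int] = {}
        for c in col:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            continue
        best = max(sorted(counts), key=counts.get)  # lexicographic tie-break
        if counts[best] > majority * n:
            out.append(best)
        else:
            out.append("X")
    return "".join(out)


def progressive_align(
    sequences: Sequence[str], params: SearchParams | None = None
) -> list[str]:
    """Center-star progressive multiple alignment.

    The center is the sequence with the highest summed identity to all
    others; the rest join in decreasing order of identity to the center,
    each via a global pairwise alignment against the running consensus.
    Rows are returned in the input order of the sequences.
    """
    params = params or DEFAULT_PARAMS
    if not sequences:
        raise ValueError("progressive_align requires at least one sequence")
    if len(sequences) == 1:
        return [sequences[0]]
    n = len(sequences)
    ident = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            pid = pairwise_identity(sequences[i], sequences[j], params)
            ident[i][j] = ident[j][i] = pid
    center = max(range(n), key=lambda i: (sum(ident[i]), -i))
    order = [center] + sorted(
        (i for i in range(n) if i != center), key=lambda i: (-ident[center][i], i)
    )
    rows = [sequences[center]]
    for i in order[1:]:
        rows = _merge_alignment(rows, sequences[i], params)
    # restore input order
    permuted = {orig: row for orig, row in zip(order, rows)}
    return [permuted[i] for i in range(n)]


def build_consensus(
    records: Sequence[ProteinRecord],
    majority: float = 0.5,
    params: SearchParams | None = None,
) -> str:
    """Majority consensus of a progressively aligned record set.

    Columns where gaps dominate are dropped; in the remaining columns the
    modal residue is emitted iff it exceeds the ``majority`` fraction of
    rows, else ``X``.
    """
    if not records:
        raise ValueError("build_consensus requires at least one record")
    if len(records) == 1:
        return records[0].sequence
    rows = progressive_align([r.sequence for r in records], params)
    return _column_consensus(rows, majority=majority)


def bit_score(raw_score: float, params: SearchParams) -> float:
    return (params.lambda_ * raw_score - math.log(params.K)) / math.log(2.0)


def _search_space(qlen: int, tlen: int, params: SearchParams) -> float:
    if params.search_space_policy == "product-of-lengths":
        return float(qlen) * float(tlen)
    # effective-length policy: subtract the expected HSP length
    ell = math.log(params.K * qlen * tlen) / (params.lambda_ * 2.0)
    return max(qlen - ell, 1.0) * max(tlen - ell, 1.0)


def evalue_from_score(
    raw_score: float, qlen: int, tlen: int, params: SearchParams
) -> tuple[float, float]:
    """Return (bitscore, e-value) for a raw local alignment score."""
    bits = bit_score(raw_score, params)
    ev = _search_space(qlen, tlen, params) * math.pow(2.0, -bits)
    return bits, ev


def local_search(
    query: str,
    targets: Iterable[tuple[str, str]],
    params: SearchParams | None = None,
) -> list[Hit]:
    """Exact Smith-Waterman search of ``query`` against named targets.

    Returns hits sorted by ascending e-value (ties broken by target id).
    E-values use the Karlin-Altschul formula ``m*n*2^-bitscore`` with the
    search space given by the params policy.
    """
    if not query:
        raise ValueError("local_search requires a non-empty query")
    params = params or DEFAULT_PARAMS
    aligner = _local_aligner(params)
    hits: list[Hit] = []
    for tid, tseq in targets:
        if not tseq:
            continue
        result = aligner.align(query, tseq)
        score = result.score
        bits, ev = evalue_from_score(score, len(query), len(tseq), params)
        qs = qe = ts = te = 0
        if score > 0:
            best = result[0]
            qblocks, tblocks = best.aligned
            if len(qblocks):
                qs, qe = int(qblocks[0][0]) + 1, int(qblocks[-1][1])
                ts, te = int(tblocks[0][0]) + 1, int(tblocks[-1][1])
        hits.append(Hit(tid, float(score), bits, ev, qs, qe, ts, te))
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def find_domains(
    sequence: str,
    profiles: Iterable[tuple[str, str]],
    params: SearchParams | None = None,
    max_evalue: float = 0.01,
) -> list[DomainHit]:
    """Locate domain families on a protein by profile-consensus search.

    Every profile with an e-value at or below ``max_evalue`` yields one
    DomainHit at its best local-alignment footprint, reported in
    N-to-C order along the protein.
    """
    hits = local_search(sequence, profiles, params)
    domains = [
        DomainHit(h.target_id, h.query_start, h.query_end, h.bitscore, h.evalue)
        for h in hits
        if h.evalue <= max_evalue and h.query_start > 0
    ]
    domains.sort(key=lambda d: (d.start, d.end, d.family))
    return domains
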