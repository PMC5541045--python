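"""CRISPR repeat-spacer array detection and orientation.

Detection is de novo: exact 8-mer seeds occurring at array-like periods are
chained and extended column-wise into full repeat units, then validated
against repeat/spacer length windows and a repeat-to-consensus identity
floor.  Orientation follows a three-criterion cascade:

(i)   an intrinsic signal score — the leader flank of an array is AT-richer
      than the trailer flank, and the trailer-proximal terminal repeat is
      the most degenerate copy; confident (H/M band) scores decide
      orientation outright, but only when both 200-nt flanks are available;
(ii)  otherwise, an exact match of the repeat consensus (either strand)
      against a database of direct repeats with known transcriptional
      orientation;
(iii) otherwise, similarity (>=90% identity on either strand) to the repeat
      of another, already-oriented array of the same group.

Arrays exhausting the cascade stay ``undetermined``.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio.Seq import Seq

from .sequence import SearchParams, pairwise_identity

# identity between DNA repeats is scored with the EDNAFULL-style matrix;
# the extreme-value parameters are never used for identity
DNA_PARAMS = SearchParams(
    substitution_matrix="NUC.4.4", gap_open=10, gap_extend=1, lambda_=0.28, K=0.03
)

REPEAT_LEN_RANGE = (19, 48)
SPACER_LEN_RANGE = (17, 72)
FLANK_NT = 200


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class CrisprArray:
    """A detected repeat-spacer array (1-based inclusive coordinates)."""

    contig: str
    start: int
    end: int
    repeats: list[tuple[tuple[int, int], str]]
    spacers: list[tuple[tuple[int, int], str]]
    repeat_consensus: str
    orientation: str = "undetermined"
    band: str = "NA"
    criterion: str = "none"
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.repeats) < 3:
            raise ValueError("an array needs at least 3 repeats")
        coords = [c for c, _ in self.repeats]
        if coords != sorted(coords):
            raise ValueError("repeats must be coordinate-sorted")
        if len(self.spacers) != len(self.repeats) - 1:
            raise ValueError("repeats and spacers must strictly alternate")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class RepeatDB:
    """Direct repeats with known transcriptional orientation.

    Each entry stores the repeat written in its canonical (transcribed)
    orientation, so an array whose consensus matches an entry as-is lies
    forward on the contig, and one matching the reverse complement lies
    in reverse.
    """

    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for seq, orientation, _fam in self.entries:
            if seq != seq.upper() or set(seq) - set("ACGT"):
                raise ValueError(f"repeat {seq!r} is not uppercase DNA")
            key = (seq, orientation)
            if key in seen:
                raise ValueError(f"duplicate repeat entry {key}")
            seen.add(key)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RepeatDB":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {name: i for i, name in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                entries.append(
                    (parts[idx["repeat"]], parts[idx["orientation"]], parts[idx["family"]])
                )
        return cls(entries)

    def sequences(self) -> set[str]:
        return {seq for seq, _o, _f in self.entries}


def _modal_count(bases: list[str]) -> int:
    counts: dict[str, int] = {}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    return max(counts.values())


def _consensus_of(units: list[str]) -> str:
    out = []
    for col in zip(*units):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        out.append(max(sorted(counts), key=counts.get))
    return "".join(out)


def _unit_identity(unit: str, consensus: str) -> float:
    if not consensus:
        return 0.0
    matches = sum(1 for a, b in zip(unit, consensus) if a == b)
    return 100.0 * matches / len(consensus)


def detect_arrays(
    contig: str,
    contig_id: str = "contig",
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = REPEAT_LEN_RANGE,
    spacer_len: tuple[int, int] = SPACER_LEN_RANGE,
    repeat_id_min: float = 85.0,
    k: int = 8,
) -> list[CrisprArray]:
    """De novo detection of repeat-spacer arrays on one contig.

    Exact k-mer seeds recurring at periods compatible with the repeat and
    spacer length windows are chained; each chain is extended column-wise
    in both directions while at most ``max(1, 15% )`` of the units deviate
    from the modal base, then validated.  Overlapping candidates are
    resolved by keeping the one with more repeats, then longer span, then
    leftmost.  Coordinates are 1-based inclusive.
    """
    seq = contig.upper()
    n = len(seq)
    min_period = repeat_len[0] + spacer_len[0]
    max_period = repeat_len[1] + spacer_len[1]
    if n < min_repeats * repeat_len[0] + (min_repeats - 1) * spacer_len[0]:
        return []

    index: dict[str, list[int]] = defaultdict(list)
    valid = set("ACGT")
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= valid:
            index[kmer].append(i)

    chains: list[list[int]] = []
    for kmer in sorted(index):
        pos = index[kmer]
        if len(pos) < min_repeats:
            continue
        chain = [pos[0]]
        for p in pos[1:]:
            d = p - chain[-1]
            if d < min_period:
                continue  # same-unit or overlapping occurrence
            if d <= max_period:
                chain.append(p)
            else:
                if len(chain) >= min_repeats:
                    chains.append(chain)
                chain = [p]
        if len(chain) >= min_repeats:
            chains.append(chain)

    candidates = []
    for chain in chains:
        arr = _extend_chain(seq, chain, k, repeat_len, spacer_len, repeat_id_min, min_repeats)
        if arr is not None:
            candidates.append(arr)

    return [
        _build_array(contig_id, seq, starts, length)
        for starts, length in _resolve_overlaps(candidates)
    ]


def _extend_chain(seq, chain, k, repeat_len, spacer_len, repeat_id_min, min_repeats):
    n = len(seq)
    anchors = list(chain)
    m = len(anchors)
    allowed_dev = max(1, int(0.15 * m))
    left = right = 0

    def column_ok(offset: int) -> bool:
        bases = []
        for a in anchors:
            p = a + offset
            if p < 0 or p >= n:
                return False
            bases.append(seq[p])
        return (m - _modal_count(bases)) <= allowed_dev

    def min_gap(l: int, r: int) -> int:
        return min(
            anchors[i + 1] - anchors[i] - k - l - r for i in range(m - 1)
        )

    progressed = True
    while progressed:
        progressed = False
        for side in ("L", "R"):
            l, r = (left + 1, right) if side == "L" else (left, right + 1)
            if k + l + r > repeat_len[1]:
                continue
            if min_gap(l, r) < spacer_len[0]:
                continue
            offset = -l if side == "L" else k + r - 1
            if column_ok(offset):
                left, right = l, r
                progressed = True

    length = k + left + right
    if length < repeat_len[0]:
        return None
    units = [seq[a - left : a - left + length] for a in anchors]
    cons = _consensus_of(units)

    # trim terminal units that diverge beyond the identity floor
    while len(units) >= min_repeats and _unit_identity(units[0], cons) < repeat_id_min:
        units = units[1:]
        anchors = anchors[1:]
        cons = _consensus_of(units)
    while len(units) >= min_repeats and _unit_identity(units[-1], cons) < repeat_id_min:
        units = units[:-1]
        anchors = anchors[:-1]
        cons = _consensus_of(units)
    if len(units) < min_repeats:
        return None
    if any(_unit_identity(u, cons) < repeat_id_min for u in units):
        return None
    gaps = [anchors[i + 1] - anchors[i] - length for i in range(len(anchors) - 1)]
    if any(g < spacer_len[0] or g > spacer_len[1] for g in gaps):
        return None
    return (tuple(a - left for a in anchors), length)


def _resolve_overlaps(candidates):
    # candidates: (unit_starts, unit_length); span from first start to last end
    def span(c):
        starts, length = c
        return starts[0], starts[-1] + length - 1

    uniq = {c: c for c in candidates}
    items = sorted(uniq.values(), key=lambda c: span(c))
    groups: list[list] = []
    cur_end = -1
    for c in items:
        s, e = span(c)
        if groups and s <= cur_end:
            groups[-1].append(c)
            cur_end = max(cur_end, e)
        else:
            groups.append([c])
            cur_end = e
    winners = []
    for group in groups:
        group.sort(key=lambda c: (-len(c[0]), -(span(c)[1] - span(c)[0]), span(c)[0]))
        winners.append(group[0])
    winners.sort(key=lambda c: span(c)[0])
    return winners


def _build_array(contig_id, seq, unit_starts, length):
    repeats = []
    spacers = []
    units = [seq[s : s + length] for s in unit_starts]
    cons = _consensus_of(units)
    for i, s in enumerate(unit_starts):
        repeats.append(((s + 1, s + length), units[i]))
        if i + 1 < len(unit_starts):
            sp_start = s + length
            sp_end = unit_starts[i + 1] - 1
            spacers.append(((sp_start + 1, sp_end + 1), seq[sp_start : sp_end + 1]))
    return CrisprArray(
        contig=contig_id,
        start=unit_starts[0] + 1,
        end=unit_starts[-1] + length,
        repeats=repeats,
        spacers=spacers,
        repeat_consensus=cons,
    )


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("A") + seq.count("T")) / len(seq)


def score_orientation(
    array: CrisprArray,
    contig: str,
    flank: int = FLANK_NT,
    band_h: float = 0.15,
    band_m: float = 0.06,
) -> tuple[str, str, float]:
    """Intrinsic orientation signal of an array.

    The signed score combines the AT-richness excess of the left flank over
    the right flank (the leader is AT-richer) with the degeneracy excess of
    the last repeat over the first (the trailer-proximal repeat is the most
    diverged from consensus).  A positive score means the leader is on the
    left, i.e. forward orientation.  |score| maps to confidence bands H/M/L;
    if either flank is shorter than ``flank`` nucleotides the band is NA
    regardless of the score.  Returns (orientation, band, score).
    """
    if array.start < 1 or array.end > len(contig):
        raise ValueError("array coordinates outside contig")
    left = contig[max(0, array.start - 1 - flank) : array.start - 1]
    right = contig[array.end : array.end + flank]
    cons = array.repeat_consensus
    deg_first = 100.0 - _unit_identity(array.repeats[0][1], cons)
    deg_last = 100.0 - _unit_identity(array.repeats[-1][1], cons)
    score = 0.0
    if left and right:
        score += _at_fraction(left) - _at_fraction(right)
    score += (deg_last - deg_first) / 100.0
    orientation = "forward" if score >= 0 else "reverse"
    if len(left) < flank or len(right) < flank:
        band = "NA"
    else:
        band = "H" if abs(score) >= band_h else "M" if abs(score) >= band_m else "L"
    return orientation, band, score


def resolve_orientation(
    array: CrisprArray,
    contig: str,
    db: RepeatDB | None = None,
    group_arrays: list[CrisprArray] | None = None,
    group_id_min: float = 90.0,
) -> CrisprArray:
    """Apply the orientation cascade and return the finalised array.

    Criterion i accepts the intrinsic score when its band is H or M;
    criterion ii matches the repeat consensus (either strand) exactly
    against the oriented repeat database; criterion iii inherits the
    orientation of a group member whose repeat is >=``group_id_min``%
    identical on either strand.  A confident criterion-i call is never
    downgraded.
    """
    if array.criterion == "i" and array.band in ("H", "M"):
        return array
    orientation, band, score = score_orientation(array, contig)
    if band in ("H", "M"):
        return replace(array, orientation=orientation, band=band, criterion="i", score=score)

    cons = array.repeat_consensus
    if db is not None:
        seqs = db.sequences()
        fwd = cons in seqs
        rev = revcomp(cons) in seqs
        if fwd != rev:  # unambiguous db hit
            return replace(
                array,
                orientation="forward" if fwd else "reverse",
                band=band,
                criterion="ii",
                score=score,
            )

    best = None
    for member in group_arrays or []:
        if member.orientation == "undetermined" or member.criterion not in ("i", "ii"):
            continue
        same = pairwise_identity(cons, member.repeat_consensus, DNA_PARAMS)
        flip = pairwise_identity(cons, revcomp(member.repeat_consensus), DNA_PARAMS)
        if max(same, flip) >= group_id_min:
            inherited = (
                member.orientation
                if same >= flip
                else ("reverse" if member.orientation == "forward" else "forward")
            )
            if best is None or max(same, flip) > best[0]:
                best = (max(same, flip), inherited)
    if best is not None:
        return replace(
            array, orientation=best[1], band=band, criterion="iii", score=score
        )
    return replace(
        array, orientation="undetermined", band=band, criterion="none", score=score
    )
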