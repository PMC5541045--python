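"""Cas-gene annotation, fusion calling, locus extraction and reporting.

Operations here turn raw gene features into classified CRISPR-cas loci:
profile-based Cas family annotation at an e-value of 0.01 (1e-6 for
subtype-defining signatures), RT fusion-architecture calling from located
domains, greedy neighborhood chaining around the RT gene with a strict
"<5 kb intervening sequence" trimming rule, effector subtype calling from
Csm/Cmr signatures, and the clade-by-architecture distribution table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .arrays import CrisprArray
from .profiles import CMR_SIGNATURES, CSM_SIGNATURES, SUBTYPE_SIGNATURES
from .sequence import DomainHit, SearchParams, local_search

WINDOW_BP = 50_000
GAP_MAX_BP = 5_000
ARRAY_LINK_BP = 1_000
EVALUE_ANNOT = 0.01
EVALUE_SUBTYPE = 1e-6

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"
MIN_ORF_BP = 300


@dataclass
class GeneFeature:
    """A protein-coding gene on a contig (1-based inclusive, stop included)."""

    contig: str
    start: int
    end: int
    strand: str
    locus_tag: str
    translation: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.locus_tag}: end < start")
        if self.strand not in "+-":
            raise ValueError(f"{self.locus_tag}: bad strand {self.strand!r}")
        expected = (self.end - self.start + 1) // 3 - 1
        if abs(len(self.translation) - expected) > 1:
            raise ValueError(
                f"{self.locus_tag}: translation length {len(self.translation)} "
                f"inconsistent with span (expected ~{expected})"
            )


@dataclass
class CasHit:
    """A gene annotated as a Cas family member."""

    feature: GeneFeature
    family: str
    evalue: float
    subtype_specific: bool = False

    def __post_init__(self) -> None:
        if self.evalue > EVALUE_ANNOT:
            raise ValueError("CasHit above the 0.01 annotation threshold")
        if self.subtype_specific and self.evalue > EVALUE_SUBTYPE:
            raise ValueError("subtype-specific hits require e-value <= 1e-6")


@dataclass
class Locus:
    """A trimmed CRISPR-cas locus centred on an RT gene."""

    contig: str
    start: int
    end: int
    features: list[CasHit]
    arrays: list[CrisprArray]
    rt_feature: GeneFeature
    fusion_class: str = "RT"
    subtype: str = "unknown"
    clade: str = "unassigned"
    rt_linked_array: bool = False

    @property
    def architecture(self) -> str:
        """Ordered family labels along the locus, arrays included."""
        items = [(h.feature.start, h.family) for h in self.features]
        items += [(a.start, "Array") for a in self.arrays]
        return "-".join(label for _pos, label in sorted(items))


def call_orfs(contig: str, contig_id: str = "contig", min_len: int = MIN_ORF_BP) -> list[GeneFeature]:
    """Call ORFs of at least ``min_len`` bp on both strands.

    One ORF per stop codon: the reading frame's first ATG after the
    previous in-frame stop.  Coordinates are on the forward strand,
    1-based inclusive, stop codon included.  Deterministic order by
    (start, strand).
    """
    seq = contig.upper()
    features: list[GeneFeature] = []

    def scan(s: str, strand: str) -> None:
        n = len(s)
        for frame in range(3):
            start_candidate = None
            for i in range(frame, n - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if start_candidate is not None:
                        orf_len = i + 3 - start_candidate
                        if orf_len >= min_len:
                            _emit(s, start_candidate, i + 3, strand)
                    start_candidate = None
                elif codon == START_CODON and start_candidate is None:
                    start_candidate = i

    def _emit(s: str, a: int, b: int, strand: str) -> None:
        aa = str(Seq(s[a : b - 3]).translate(table=11))
        if strand == "+":
            start, end = a + 1, b
        else:
            start, end = len(seq) - b + 1, len(seq) - a
        features.append(
            GeneFeature(contig_id, start, end, strand, f"orf_{start}_{strand}", aa)
        )

    scan(seq, "+")
    scan(str(Seq(seq).reverse_complement()), "-")
    features.sort(key=lambda f: (f.start, f.strand))
    return features


def annotate_cas(
    features: list[GeneFeature],
    profiles: list[tuple[str, str]],
    params: SearchParams | None = None,
) -> list[CasHit]:
    """Annotate gene features against the consensus-profile library.

    Each feature keeps its single best family iff that hit reaches the
    0.01 e-value threshold; the subtype-specific flag additionally
    requires e-value <= 1e-6 and a Csm/Cmr signature family.  Features
    with no qualifying hit are excluded.
    """
    if not profiles:
        raise ValueError("annotate_cas requires a non-empty profile set")
    out = []
    for feat in features:
        hits = local_search(feat.translation, profiles, params)
        if not hits or hits[0].evalue > EVALUE_ANNOT:
            continue
        best = hits[0]
        out.append(
            CasHit(
                feature=feat,
                family=best.target_id,
                evalue=best.evalue,
                subtype_specific=(
                    best.evalue <= EVALUE_SUBTYPE and best.target_id in SUBTYPE_SIGNATURES
                ),
            )
        )
    return out


def detect_fusion(feature: GeneFeature, domains: list[DomainHit]) -> str:
    """Fusion architecture of an RT-bearing gene.

    ``RT-Cas1`` iff a Cas1 domain lies C-terminal to the RT domain on the
    same translation; ``Cas6-RT-Cas1`` additionally requires a Cas6 domain
    N-terminal to the RT; otherwise ``RT``.
    """
    rt = next((d for d in domains if d.family == "RT"), None)
    if rt is None:
        raise ValueError(f"{feature.locus_tag}: no RT domain present")
    cas1_cterm = any(d.family == "cas1" and d.start > rt.end for d in domains)
    cas6_nterm = any(d.family == "cas6" and d.end < rt.start for d in domains)
    if cas1_cterm and cas6_nterm:
        return "Cas6-RT-Cas1"
    if cas1_cterm:
        return "RT-Cas1"
    return "RT"


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Intervening bases between two spans (0 if they touch or overlap)."""
    if b_start > a_end:
        return b_start - a_end - 1
    if a_start > b_end:
        return a_start - b_end - 1
    return 0


def extract_locus(
    contig_id: str,
    contig_len: int,
    rt_feature: GeneFeature,
    cas_hits: list[CasHit],
    arrays: list[CrisprArray],
    window: int = WINDOW_BP,
    gap_max: int = GAP_MAX_BP,
    array_link: int = ARRAY_LINK_BP,
) -> Locus:
    """Extract and trim the CRISPR-cas locus around an RT gene.

    Candidate elements are cas gene hits and arrays within ``window`` bp of
    the RT gene.  Starting from the RT, elements are chained greedily left
    and right while the intervening gap to the previous retained element is
    strictly below ``gap_max``; the locus is trimmed to the outermost
    retained cas gene or array.  Idempotent: re-extracting an already
    trimmed locus returns the same region.
    """
    if rt_feature.start < 1 or rt_feature.end > contig_len:
        raise ValueError("rt_feature outside contig")

    rt_span = (rt_feature.start, rt_feature.end)
    items: list[tuple[int, int, str, object]] = []
    rt_hit = None
    for hit in cas_hits:
        f = hit.feature
        if f.contig != contig_id:
            continue
        if (f.start, f.end, f.strand) == (rt_feature.start, rt_feature.end, rt_feature.strand):
            rt_hit = hit
            continue
        if _gap(*rt_span, f.start, f.end) <= window:
            items.append((f.start, f.end, "cas", hit))
    for arr in arrays:
        if arr.contig != contig_id:
            continue
        if _gap(*rt_span, arr.start, arr.end) <= window:
            items.append((arr.start, arr.end, "array", arr))
    anchor_kind = "cas" if rt_hit is not None else "rt"
    anchor_payload = rt_hit if rt_hit is not None else rt_feature
    items.append((rt_feature.start, rt_feature.end, anchor_kind, anchor_payload))
    items.sort(key=lambda e: (e[0], e[1]))
    anchor_idx = next(i for i, e in enumerate(items) if e[3] is anchor_payload)

    retained = {anchor_idx}
    for direction in (+1, -1):
        span = rt_span
        i = anchor_idx + direction
        while 0 <= i < len(items):
            e = items[i]
            if _gap(span[0], span[1], e[0], e[1]) >= gap_max:
                break
            retained.add(i)
            span = (min(span[0], e[0]), max(span[1], e[1]))
            i += direction

    kept = sorted(retained)
    kept_cas = [items[i][3] for i in kept if items[i][2] == "cas"]
    kept_arrays = [items[i][3] for i in kept if items[i][2] == "array"]

    bounds = [(e.feature.start, e.feature.end) for e in kept_cas]
    bounds += [(a.start, a.end) for a in kept_arrays]
    bounds.append(rt_span)  # the RT gene is always part of its own locus
    start = min(b[0] for b in bounds)
    end = max(b[1] for b in bounds)

    linked = any(
        _gap(rt_feature.start, rt_feature.end, a.start, a.end) < array_link
        for a in kept_arrays
    )
    kept_cas.sort(key=lambda h: h.feature.start)
    return Locus(
        contig=contig_id,
        start=start,
        end=end,
        features=kept_cas,
        arrays=sorted(kept_arrays, key=lambda a: a.start),
        rt_feature=rt_feature,
        rt_linked_array=linked,
    )


def classify_subtype(locus: Locus) -> str:
    """Effector subtype of a locus from its signature gene content.

    Subtype-specific Csm hits give III-A/D, Cmr hits give III-B/C; both
    present is reported as ``ambiguous``; cas genes without signatures are
    ``partial``; no cas genes at all is ``unknown``.  The RT gene itself
    does not count as a cas gene.
    """
    families = {h.family for h in locus.features if h.subtype_specific}
    has_csm = bool(families & CSM_SIGNATURES)
    has_cmr = bool(families & CMR_SIGNATURES)
    if has_csm and has_cmr:
        return "ambiguous"
    if has_csm:
        return "III-A/D"
    if has_cmr:
        return "III-B/C"
    if any(h.family != "RT" for h in locus.features):
        return "partial"
    return "unknown"


EFFECTOR_COLUMNS = ["Cmr(B-C)", "Csm(A-D)", "partial/unknown"]
FUSION_COLUMNS = ["RT", "RT-Cas1", "Cas6-RT-Cas1"]

_SUBTYPE_TO_EFFECTOR = {
    "III-B/C": "Cmr(B-C)",
    "III-A/D": "Csm(A-D)",
}


def tabulate_distribution(loci: list[Locus]) -> pd.DataFrame:
    """Clade x (effector complex, fusion class) count table.

    Rows are clade labels, columns a MultiIndex of effector complex and RT
    fusion class; marginals sum to the number of loci.  Pure counting —
    permutation-invariant in the locus order.
    """
    columns = pd.MultiIndex.from_product([EFFECTOR_COLUMNS, FUSION_COLUMNS])
    clades = sorted({loc.clade for loc in loci})
    table = pd.DataFrame(0, index=pd.Index(clades, name="clade"), columns=columns)
    for loc in loci:
        effector = _SUBTYPE_TO_EFFECTOR.get(loc.subtype, "partial/unknown")
        table.loc[loc.clade, (effector, loc.fusion_class)] += 1
    return table
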