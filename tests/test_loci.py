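"""Unit tests for ORF calling, cas annotation, fusion, loci and reporting."""

import numpy as np
import pytest

from rtcrispr.arrays import detect_arrays, revcomp
from rtcrispr.loci import (
    CasHit,
    GeneFeature,
    Locus,
    annotate_cas,
    call_orfs,
    classify_subtype,
    detect_fusion,
    extract_locus,
    tabulate_distribution,
)
from rtcrispr.sequence import DomainHit, local_search
from rtcrispr.synth import (
    ArraySpec,
    GenomeSpec,
    generate_genome,
    mutate_protein,
    standard_template,
)

REPEAT = "GTTTCAGACGAACCCTTGTAGGGTTGAAGC"


def gf(tag, start, end, strand="+", contig="c"):
    return GeneFeature(contig, start, end, strand, tag, "A" * ((end - start + 1) // 3 - 1))


def cas_hit(tag, start, end, family, evalue=1e-10, specific=False):
    return CasHit(gf(tag, start, end), family, evalue, specific)


@pytest.fixture(scope="module")
def one_locus_genome():
    template = standard_template("III-A/D", "RT-Cas1", decoys=1)
    return generate_genome(GenomeSpec(length_bp=25_000, loci=[template], seed=42))


# --- call_orfs ---------------------------------------------------------------


def test_call_orfs_empty_on_featureless_sequence():
    assert call_orfs("N" * 2_000) == []


def test_call_orfs_recovers_planted_genes_exactly(one_locus_genome):
    genome, truth = one_locus_genome
    called = {(g.start, g.end, g.strand) for g in call_orfs(genome.sequence)}
    for gene in truth.planted_genes:
        assert (gene["start"], gene["end"], gene["strand"]) in called


def test_call_orfs_mirror_on_reverse_complement(one_locus_genome):
    genome, _truth = one_locus_genome
    n = len(genome.sequence)
    fwd = call_orfs(genome.sequence)
    rev = call_orfs(revcomp(genome.sequence))
    flip = {"+": "-", "-": "+"}
    mirrored = sorted((n - g.end + 1, n - g.start + 1, flip[g.strand]) for g in rev)
    assert sorted((g.start, g.end, g.strand) for g in fwd) == mirrored


# --- annotate_cas ------------------------------------------------------------


def test_annotate_cas_recovers_planted_families(one_locus_genome, profiles):
    genome, truth = one_locus_genome
    hits = annotate_cas(genome.genes, profiles)
    by_tag = {h.feature.locus_tag: h for h in hits}
    for gene in truth.planted_genes:
        fam = gene["family"]
        if fam == "decoy":
            assert gene["tag"] not in by_tag
        elif fam in ("RT", "RT-Cas1", "Cas6-RT-Cas1"):
            assert gene["tag"] in by_tag  # fused genes hit an RT-module family
        else:
            assert by_tag[gene["tag"]].family == fam
            assert by_tag[gene["tag"]].evalue <= 1e-6 or not by_tag[
                gene["tag"]
            ].subtype_specific


def test_annotate_cas_weak_hit_is_never_subtype_specific(profiles, profile_map):
    # degrade a signature family until its best e-value sits between the
    # subtype (1e-6) and annotation (0.01) thresholds
    rng = np.random.default_rng(7)
    cons = profile_map["csm3"]
    weak = None
    for k in range(0, len(cons), 2):
        cand = "M" + mutate_protein(rng, cons, k)
        best = local_search(cand, profiles)[0]
        if 1e-6 < best.evalue <= 0.01 and best.target_id == "csm3":
            weak = cand
            break
    assert weak is not None, "could not build a window-region homolog"
    feat = GeneFeature("c", 1, 3 * (len(weak) + 1), "+", "weak", weak)
    hits = annotate_cas([feat], profiles)
    assert len(hits) == 1
    assert hits[0].family == "csm3"
    assert not hits[0].subtype_specific


def test_cas_hit_threshold_invariants():
    with pytest.raises(ValueError):
        cas_hit("x", 1, 300, "cas10", evalue=0.5)
    with pytest.raises(ValueError):
        cas_hit("x", 1, 300, "csm3", evalue=1e-4, specific=True)


# --- detect_fusion -----------------------------------------------------------


def test_detect_fusion_classes():
    feat = gf("rt", 1, 2703)
    rt = DomainHit("RT", 1, 400, 100.0, 1e-50)
    cas1 = DomainHit("cas1", 420, 700, 80.0, 1e-40)
    cas6 = DomainHit("cas6", 1, 180, 70.0, 1e-30)
    rt_mid = DomainHit("RT", 200, 600, 100.0, 1e-50)
    cas1_late = DomainHit("cas1", 620, 900, 80.0, 1e-40)
    assert detect_fusion(feat, [rt]) == "RT"
    assert detect_fusion(feat, [rt, cas1]) == "RT-Cas1"
    assert detect_fusion(feat, [cas6, rt_mid, cas1_late]) == "Cas6-RT-Cas1"
    # Cas1 N-terminal to RT does not make a C-terminal fusion
    assert detect_fusion(feat, [DomainHit("cas1", 1, 180, 80.0, 1e-40), rt_mid]) == "RT"
    with pytest.raises(ValueError):
        detect_fusion(feat, [cas1])


# --- extract_locus -----------------------------------------------------------


def test_gap_boundary_4999_retained_5000_excluded():
    rt = gf("rt", 1000, 2000)
    for gap in (4_999, 5_000):
        neighbour = cas_hit("n", 2000 + gap + 1, 2000 + gap + 900, "cas10")
        locus = extract_locus("c", 60_000, rt, [neighbour], [])
        if gap < 5_000:
            assert locus.features == [neighbour]
            assert (locus.start, locus.end) == (1000, neighbour.feature.end)
        else:
            assert locus.features == []
            assert (locus.start, locus.end) == (1000, 2000)


def test_extract_locus_chains_through_small_gaps_and_stops_at_big_one():
    rt = gf("rt", 20_000, 21_000)
    near = cas_hit("near", 21_500, 22_400, "cas10")
    far = cas_hit("far", 22_500, 23_400, "csm3")  # chained via `near`
    beyond = cas_hit("beyond", 29_000, 29_900, "csm4")  # 5.6 kb after `far`
    locus = extract_locus("c", 60_000, rt, [near, far, beyond], [])
    assert [h.feature.locus_tag for h in locus.features] == ["near", "far"]
    assert locus.end == 23_400


def test_extract_locus_window_excludes_distant_elements():
    rt = gf("rt", 1_000, 2_000)
    distant = cas_hit("d", 55_000, 55_900, "cas10")
    locus = extract_locus("c", 100_000, rt, [distant], [])
    assert locus.features == []


def test_extract_locus_is_idempotent():
    rt = gf("rt", 10_000, 11_200)
    hits = [
        cas_hit("a", 7_500, 8_400, "cas10"),
        cas_hit("b", 12_000, 12_900, "csm3"),
    ]
    spec = ArraySpec(repeat_seq=REPEAT, n_repeats=4)
    from .conftest import planted_array_contig

    contig, s, e = planted_array_contig(spec, seed=3)
    arr = detect_arrays(contig, "c")[0]
    # shift the array next to the RT gene
    from dataclasses import replace

    shift = 11_300 - arr.start
    arr = replace(
        arr,
        start=arr.start + shift,
        end=arr.end + shift,
        repeats=[((a + shift, b + shift), u) for (a, b), u in arr.repeats],
        spacers=[((a + shift, b + shift), u) for (a, b), u in arr.spacers],
    )
    first = extract_locus("c", 60_000, rt, hits, [arr])
    second = extract_locus("c", 60_000, rt, first.features, first.arrays)
    assert (second.start, second.end) == (first.start, first.end)
    assert second.features == first.features
    assert first.rt_linked_array  # array sits within 1 kb of the RT gene


def test_extract_locus_rejects_rt_outside_contig():
    with pytest.raises(ValueError):
        extract_locus("c", 500, gf("rt", 1_000, 2_000), [], [])


# --- classify_subtype --------------------------------------------------------


def _locus(features):
    return Locus("c", 1, 10_000, features, [], gf("rt", 1, 1_200))


def test_classify_subtype_signatures():
    csm = cas_hit("a", 2_000, 2_600, "csm3", evalue=1e-40, specific=True)
    cmr = cas_hit("b", 3_000, 3_600, "cmr4", evalue=1e-40, specific=True)
    adapt = cas_hit("d", 4_000, 4_600, "cas1", evalue=1e-40)
    assert classify_subtype(_locus([csm, adapt])) == "III-A/D"
    assert classify_subtype(_locus([cmr, adapt])) == "III-B/C"
    assert classify_subtype(_locus([csm, cmr])) == "ambiguous"
    assert classify_subtype(_locus([adapt])) == "partial"
    assert classify_subtype(_locus([])) == "unknown"


def test_weak_signature_hit_gives_partial_not_subtype():
    weak_csm = cas_hit("a", 2_000, 2_600, "csm3", evalue=1e-4, specific=False)
    assert classify_subtype(_locus([weak_csm])) == "partial"


# --- tabulate_distribution ---------------------------------------------------


def _classified_locus(clade, subtype, fusion):
    loc = _locus([])
    loc.clade, loc.subtype, loc.fusion_class = clade, subtype, fusion
    return loc


def test_distribution_empty_is_all_zero():
    table = tabulate_distribution([])
    assert int(table.to_numpy().sum()) == 0


def test_distribution_counts_and_permutation_invariance():
    loci = [
        _classified_locus("1", "III-A/D", "RT"),
        _classified_locus("1", "III-B/C", "RT-Cas1"),
        _classified_locus("2", "partial", "Cas6-RT-Cas1"),
        _classified_locus("2", "III-B/C", "RT-Cas1"),
    ]
    table = tabulate_distribution(loci)
    assert int(table.to_numpy().sum()) == len(loci)
    assert table.loc["1", ("Csm(A-D)", "RT")] == 1
    assert table.loc["2", ("partial/unknown", "Cas6-RT-Cas1")] == 1
    assert table.loc["2", ("Cmr(B-C)", "RT-Cas1")] == 1
    assert tabulate_distribution(loci[::-1]).equals(table)
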