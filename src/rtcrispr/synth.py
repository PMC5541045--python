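"""Synthetic genomes, protein families and clade trees with planted truth.

Every downstream stage of the pipeline is testable without downloads: this
module emits bacterial-style genome sequences containing type III CRISPR-cas
operons (Csm and Cmr architectures), repeat-spacer arrays carrying a
leader-orientation signal (AT-rich leader flank, degenerate trailer-proximal
terminal repeat), RT genes in the three fusion architectures (RT, RT-Cas1,
Cas6-RT-Cas1), decoy genes with no Cas similarity, protein families with a
controlled identity ladder, and support-annotated trees with planted clades.
All generators are pure functions of (spec, seed), and the emitted truth
ledger records the exact coordinates and classes of everything planted.

Planted cas genes are mutated copies of the shipped consensus profiles, so
profile annotation behaves like a consensus BLAST with essentially zero
e-values for true genes; decoy genes are codon-shuffled ORFs audited at
generation time to have no profile hit at e <= 0.01.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .loci import EFFECTOR_COLUMNS, FUSION_COLUMNS, GeneFeature
from .phylo import CladeInfo, CladePartition, SupportTree
from .profiles import profile_dict
from .sequence import ProteinRecord, local_search, pairwise_identity

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, NCBI table 11, stops excluded
_CODONS: dict[str, list[str]] = {}
_BASES = "TCAG"
_TABLE11 = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _aa in enumerate(_TABLE11):
    if _aa != "*":
        _codon = _BASES[_i // 16] + _BASES[(_i // 4) % 4] + _BASES[_i % 4]
        _CODONS.setdefault(_aa, []).append(_codon)

# a 12-bp block containing a stop codon in all six reading frames (it is its
# own reverse complement); placed around every planted gene so ORF calling
# recovers planted coordinates exactly
INSULATOR = "TTAATTAATTAA"

GENE_DIVERGENCE = 0.05  # substitutions per site applied to profile consensi
LINKER = "GGSGG"

CSM_OPERON = ["cas10", "csm2", "csm3", "csm4", "csm5"]
CMR_OPERON = ["cas10", "cmr1", "cmr3", "cmr4", "cmr5", "cmr6"]
RT_BEARING = {"RT", "RT-Cas1", "Cas6-RT-Cas1"}


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n > 0 else ""


def at_rich_dna(rng: np.random.Generator, n: int, gc: float, enrichment: float) -> str:
    return random_dna(rng, n, max(0.02, gc - enrichment))


def mutate_protein(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs <= 0:
        return seq
    n_subs = min(n_subs, len(seq))
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in AA20 if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def mutate_dna(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs <= 0:
        return seq
    n_subs = min(n_subs, len(seq))
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    )


# ---------------------------------------------------------------------------
# specs


@dataclass
class ArraySpec:
    """A planted repeat-spacer array and its orientation signal strength.

    ``leader_at_enrichment`` is the AT-fraction excess of the 200-nt leader
    flank over the genomic background; ``terminal_repeat_mutations`` is the
    number of substitutions carried by the trailer-proximal terminal repeat.
    Both default to a strong, H-band signal; setting them near zero yields
    L/NA-band arrays for exercising the orientation fallbacks.
    """

    repeat_seq: str
    n_repeats: int = 6
    spacer_len_range: tuple[int, int] = (25, 45)
    leader_at_enrichment: float = 0.25
    terminal_repeat_mutations: int = 3
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if not (19 <= len(self.repeat_seq) <= 48):
            raise ValueError("repeat length must be in 19..48 bp")
        if self.n_repeats < 3:
            raise ValueError("an array needs at least 3 repeats")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.leader_at_enrichment < 0:
            raise ValueError("leader AT enrichment must be >= 0")
        if self.terminal_repeat_mutations < 0:
            raise ValueError("terminal repeat mutations must be >= 0")


@dataclass
class LocusTemplate:
    """One CRISPR-cas locus to plant: operon architecture plus array.

    ``gene_order`` holds Cas family labels (plus optional ``decoy``
    entries) and exactly one RT-bearing label; fused classes collapse the
    RT/Cas1/Cas6 domains into a single gene.  The array is placed directly
    downstream of the RT-bearing gene, within 1 kb by default.
    """

    subtype: str
    gene_order: list[str]
    fusion_class: str
    array_spec: ArraySpec
    intergenic_gaps_bp: list[int] | None = None
    clade_label: str = "unassigned"
    rt_protein: str | None = None
    cas1_protein: str | None = None
    array_gap_bp: int | None = None

    def __post_init__(self) -> None:
        if self.subtype not in ("III-A/D", "III-B/C"):
            raise ValueError(f"bad subtype {self.subtype!r}")
        rt_genes = [g for g in self.gene_order if g in RT_BEARING]
        if len(rt_genes) != 1:
            raise ValueError("gene_order must contain exactly one RT-bearing gene")
        if self.fusion_class not in ("RT", "RT-Cas1", "Cas6-RT-Cas1"):
            raise ValueError(f"bad fusion class {self.fusion_class!r}")
        if rt_genes[0] != self.fusion_class:
            raise ValueError(
                f"fusion_class {self.fusion_class!r} inconsistent with "
                f"RT-bearing gene {rt_genes[0]!r}"
            )
        if self.intergenic_gaps_bp is not None and len(self.intergenic_gaps_bp) != len(
            self.gene_order
        ) - 1:
            raise ValueError("need one intergenic gap per adjacent gene pair")


@dataclass
class GenomeSpec:
    length_bp: int
    loci: list[LocusTemplate] = field(default_factory=list)
    gc_content: float = 0.5
    decoy_gene_count: int = 0
    seed: int = 0
    contig_id: str = "synthetic_contig"

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("genome length must be positive")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        if self.decoy_gene_count < 0:
            raise ValueError("decoy_gene_count must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger of everything the generator planted."""

    planted_arrays: list[dict] = field(default_factory=list)
    planted_loci: list[dict] = field(default_factory=list)
    planted_genes: list[dict] = field(default_factory=list)
    cluster_assignments: dict[str, int] = field(default_factory=dict)
    clade_partition: dict[str, str] = field(default_factory=dict)

    def distribution_table(self) -> pd.DataFrame:
        columns = pd.MultiIndex.from_product([EFFECTOR_COLUMNS, FUSION_COLUMNS])
        clades = sorted({loc["clade_label"] for loc in self.planted_loci})
        table = pd.DataFrame(0, index=pd.Index(clades, name="clade"), columns=columns)
        effector_of = {"III-B/C": "Cmr(B-C)", "III-A/D": "Csm(A-D)"}
        for loc in self.planted_loci:
            eff = effector_of.get(loc["subtype"], "partial/unknown")
            table.loc[loc["clade_label"], (eff, loc["fusion_class"])] += 1
        return table

    def to_json(self) -> str:
        payload = {
            "planted_arrays": self.planted_arrays,
            "planted_loci": self.planted_loci,
            "planted_genes": self.planted_genes,
            "cluster_assignments": self.cluster_assignments,
            "clade_partition": self.clade_partition,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SyntheticGenome:
    id: str
    sequence: str
    genes: list[GeneFeature]


# ---------------------------------------------------------------------------
# genome generation


def _gene_protein(
    rng: np.random.Generator,
    family: str,
    profiles: Mapping[str, str],
    rt_protein: str | None = None,
    cas1_protein: str | None = None,
) -> str:
    """Planted protein for a (possibly fused) gene, leading Met included."""

    def dom(fam: str) -> str:
        cons = profiles[fam]
        return mutate_protein(rng, cons, round(GENE_DIVERGENCE * len(cons)))

    if family == "RT":
        body = rt_protein or dom("RT")
    elif family == "RT-Cas1":
        body = (rt_protein or dom("RT")) + LINKER + (cas1_protein or dom("cas1"))
    elif family == "Cas6-RT-Cas1":
        body = (
            dom("cas6") + LINKER + (rt_protein or dom("RT")) + LINKER
            + (cas1_protein or dom("cas1"))
        )
    elif family == "cas1":
        body = cas1_protein or dom("cas1")
    else:
        body = dom(family)
    return "M" + body


def _decoy_protein(
    rng: np.random.Generator, profiles: Mapping[str, str], max_tries: int = 25
) -> str:
    """Codon-shuffle-equivalent decoy: a length-matched random-permutation
    protein audited to have no profile hit at e <= 0.01."""
    fams = sorted(profiles)
    for _ in range(max_tries):
        fam = fams[rng.integers(len(fams))]
        residues = list(profiles[fam])
        rng.shuffle(residues)
        candidate = "M" + "".join(residues)
        hits = local_search(candidate, sorted(profiles.items()))
        if not hits or hits[0].evalue > 0.01:
            return candidate
    raise RuntimeError("could not generate a clean decoy protein")


def realize_array(
    spec: ArraySpec, rng: np.random.Generator, gc: float = 0.5, flank: int = 200
) -> tuple[str, int, int]:
    """Emit the array with its 200-nt AT-enriched leader flank.

    Returns (block, array_start, array_end) with 0-based array coordinates
    relative to the block.  For ``forward`` orientation the leader flank
    precedes the array; for ``reverse`` the whole leader+array block is
    reverse-complemented so the leader ends up on the right.
    """
    lo, hi = spec.spacer_len_range
    spacers: list[str] = []
    seen = set()
    while len(spacers) < spec.n_repeats - 1:
        s = random_dna(rng, int(rng.integers(lo, hi + 1)), gc)
        if s not in seen:
            seen.add(s)
            spacers.append(s)
    units = [spec.repeat_seq] * spec.n_repeats
    units[-1] = mutate_dna(rng, units[-1], spec.terminal_repeat_mutations)
    parts = []
    for i, u in enumerate(units):
        parts.append(u)
        if i < len(spacers):
            parts.append(spacers[i])
    array = "".join(parts)
    leader = at_rich_dna(rng, flank, gc, spec.leader_at_enrichment)
    block = leader + array
    if spec.orientation == "reverse":
        comp = str.maketrans("ACGT", "TGCA")
        block = block.translate(comp)[::-1]
        return block, 0, len(array) - 1
    return block, len(leader), len(block) - 1


def generate_genome(spec: GenomeSpec) -> tuple[SyntheticGenome, SyntheticTruth]:
    """Realize a genome spec into sequence + features + truth ledger.

    Loci are laid out left to right with their stated intergenic gaps; each
    array sits downstream of its RT-bearing gene, within 1 kb unless the
    template overrides the gap.  Identical specs (including seed) give
    byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    profiles = profile_dict()
    segments: list[str] = []
    cursor = 0  # 0-based length so far
    genes: list[GeneFeature] = []
    truth = SyntheticTruth()

    def emit(seq: str) -> int:
        nonlocal cursor
        segments.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    def emit_gene(family: str, protein: str, tag: str) -> GeneFeature:
        dna = INSULATOR + reverse_translate(rng, protein) + "TAA" + INSULATOR
        start0 = emit(dna)
        g_start = start0 + len(INSULATOR) + 1  # 1-based
        g_end = start0 + len(dna) - len(INSULATOR)
        feat = GeneFeature(spec.contig_id, g_start, g_end, "+", tag, protein)
        genes.append(feat)
        truth.planted_genes.append(
            {"start": g_start, "end": g_end, "strand": "+", "family": family, "tag": tag}
        )
        return feat

    emit(random_dna(rng, int(rng.integers(300, 800)), spec.gc_content))

    for t_idx, template in enumerate(spec.loci):
        gaps = template.intergenic_gaps_bp or [
            int(rng.integers(50, 301)) for _ in range(len(template.gene_order) - 1)
        ]
        locus_bounds: list[tuple[int, int]] = []
        rt_done = False
        for g_idx, family in enumerate(template.gene_order):
            tag = f"locus{t_idx}_gene{g_idx}_{family}"
            if family == "decoy":
                protein = _decoy_protein(rng, profiles)
                feat = emit_gene(family, protein, tag)
            else:
                protein = _gene_protein(
                    rng, family, profiles, template.rt_protein, template.cas1_protein
                )
                feat = emit_gene(family, protein, tag)
                locus_bounds.append((feat.start, feat.end))
            if family in RT_BEARING and not rt_done:
                rt_done = True
                gap = template.array_gap_bp
                if gap is None:
                    gap = int(rng.integers(350, 800))
                pad = max(0, gap - 200 - len(INSULATOR))
                emit(random_dna(rng, pad, spec.gc_content))
                block, a0, a1 = realize_array(template.array_spec, rng, spec.gc_content)
                b_start = emit(block)
                arr_start, arr_end = b_start + a0 + 1, b_start + a1 + 1
                truth.planted_arrays.append(
                    {
                        "start": arr_start,
                        "end": arr_end,
                        "orientation": template.array_spec.orientation,
                        "n_repeats": template.array_spec.n_repeats,
                        "repeat_len": len(template.array_spec.repeat_seq),
                    }
                )
                locus_bounds.append((arr_start, arr_end))
                if template.array_spec.orientation == "forward":
                    # trailer flank: plain background so the AT signal is one-sided
                    emit(random_dna(rng, 200, spec.gc_content))
            if g_idx < len(template.gene_order) - 1:
                emit(random_dna(rng, gaps[g_idx], spec.gc_content))
        truth.planted_loci.append(
            {
                "start": min(b[0] for b in locus_bounds),
                "end": max(b[1] for b in locus_bounds),
                "subtype": template.subtype,
                "fusion_class": template.fusion_class,
                "clade_label": template.clade_label,
            }
        )
        if cursor > spec.length_bp:
            raise ValueError(
                f"locus template {t_idx} exceeds genome length "
                f"({cursor} > {spec.length_bp} bp)"
            )
        emit(random_dna(rng, int(rng.integers(800, 2000)), spec.gc_content))

    for d in range(spec.decoy_gene_count):
        protein = _decoy_protein(rng, profiles)
        emit_gene("decoy", protein, f"decoy{d}")
        emit(random_dna(rng, int(rng.integers(200, 800)), spec.gc_content))

    if cursor > spec.length_bp:
        raise ValueError(
            f"planted content exceeds genome length ({cursor} > {spec.length_bp} bp)"
        )
    emit(random_dna(rng, spec.length_bp - cursor, spec.gc_content))
    sequence = "".join(segments)
    return SyntheticGenome(spec.contig_id, sequence, genes), truth


DEFAULT_REPEAT = "GTTTCAGACGAACCCTTGTAGGGTTGAAGC"


def standard_template(
    subtype: str,
    fusion_class: str,
    clade_label: str = "unassigned",
    array_spec: ArraySpec | None = None,
    decoys: int = 0,
    rt_protein: str | None = None,
    cas1_protein: str | None = None,
) -> LocusTemplate:
    """A canonical type III operon template for a subtype and fusion class.

    Effector genes (Csm or Cmr set with cas10) come first, then the
    RT-bearing gene with its array, then the adaptation module; separate
    cas1 appears only in the unfused class.  ``decoys`` interleaves that
    many codon-shuffled genes into the operon.
    """
    effector = list(CSM_OPERON if subtype == "III-A/D" else CMR_OPERON)
    tail = [fusion_class] + (["cas1"] if fusion_class == "RT" else []) + ["cas2"]
    gene_order = effector + tail
    for d in range(decoys):
        gene_order.insert(1 + 2 * d, "decoy")
    return LocusTemplate(
        subtype=subtype,
        gene_order=gene_order,
        fusion_class=fusion_class,
        array_spec=array_spec or ArraySpec(repeat_seq=DEFAULT_REPEAT),
        clade_label=clade_label,
        rt_protein=rt_protein,
        cas1_protein=cas1_protein,
    )


def generate_cohort(
    n_genomes: int = 20,
    n_clades: int = 4,
    seed: int = 0,
    genome_len: int = 30_000,
    clade_divergence: float = 0.25,
    member_divergence: float = 0.10,
    decoys_per_genome: int = 1,
) -> list[tuple[SyntheticGenome, SyntheticTruth]]:
    """A cohort of single-locus genomes with clade-structured RT proteins.

    Clades are founded by RT (and Cas1) variants ``clade_divergence``
    substitutions-per-site away from the consensus; members diverge a
    further ``member_divergence`` from their founder, which keeps
    within-clade RT identities safely below the 85% dereplication ceiling
    while leaving clades clearly separated on a tree.  Architectures and
    fusion classes rotate through the canonical template set; the clade
    label of genome i is ``str(i % n_clades + 1)``.
    """
    rng = np.random.default_rng(seed)
    profiles = profile_dict()
    rt_cons, cas1_cons = profiles["RT"], profiles["cas1"]
    rt_founders = [
        mutate_protein(rng, rt_cons, round(clade_divergence * len(rt_cons)))
        for _ in range(n_clades)
    ]
    cas1_founders = [
        mutate_protein(rng, cas1_cons, round(clade_divergence * len(cas1_cons)))
        for _ in range(n_clades)
    ]
    subtypes = ["III-A/D", "III-B/C"]
    fusions = ["RT", "RT-Cas1", "Cas6-RT-Cas1"]
    out = []
    for i in range(n_genomes):
        c = i % n_clades
        rt = mutate_protein(rng, rt_founders[c], round(member_divergence * len(rt_cons)))
        cas1 = mutate_protein(
            rng, cas1_founders[c], round(member_divergence * len(cas1_cons))
        )
        template = standard_template(
            subtype=subtypes[i % 2],
            fusion_class=fusions[i % 3],
            clade_label=str(c + 1),
            rt_protein=rt,
            cas1_protein=cas1,
            decoys=decoys_per_genome,
        )
        spec = GenomeSpec(
            length_bp=genome_len,
            loci=[template],
            seed=int(rng.integers(2**31)),
            contig_id=f"genome{i:03d}",
        )
        out.append(generate_genome(spec))
    return out


# ---------------------------------------------------------------------------
# protein families


def generate_protein_family(
    n: int = 1,
    identity_ladder: Sequence[float] = (1.0,),
    seed: int = 0,
    founder_len: int = 300,
    tolerance_pp: float = 2.0,
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Protein clusters with a controlled pairwise-identity ladder.

    Per cluster, a random founder is mutated to hit each target identity in
    the ladder within ``tolerance_pp`` percentage points (verified against
    the pairwise identity operation itself); founders are resampled until
    all cross-cluster identities sit below ``min(ladder) - 10`` points.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for v in identity_ladder:
        if not (0.0 < v <= 1.0):
            raise ValueError(f"identity target {v} outside (0, 1]")
    rng = np.random.default_rng(seed)
    floor = min(identity_ladder) * 100.0 - 10.0
    founders: list[str] = []
    while len(founders) < n:
        cand = "".join(rng.choice(list(AA20), size=founder_len))
        if all(pairwise_identity(cand, f) < floor for f in founders):
            founders.append(cand)
    records: list[ProteinRecord] = []
    clusters: dict[str, int] = {}
    for c, founder in enumerate(founders):
        for j, target in enumerate(identity_ladder):
            k = round((1.0 - target) * founder_len)
            member = mutate_protein(rng, founder, k)
            for _ in range(30):
                pid = pairwise_identity(founder, member)
                err = pid - target * 100.0
                if abs(err) <= tolerance_pp:
                    break
                step = max(1, round(abs(err) / 100.0 * founder_len))
                k = k + step if err > 0 else max(0, k - step)
                member = mutate_protein(rng, founder, k)
            rid = f"fam{c}_{j}"
            records.append(ProteinRecord(rid, member))
            clusters[rid] = c
    return records, clusters


# ---------------------------------------------------------------------------
# clade trees and alignments


def _random_binary(
    rng: np.random.Generator, leaves: list[TreeNode], support: float | None
) -> TreeNode:
    nodes = list(leaves)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        parent = TreeNode(children=[a, b])
        parent.length = 0.1
        parent.support = support
        nodes.append(parent)
    return nodes[0]


def generate_clade_tree(
    n_leaves: int,
    planted_clades: Mapping[str, int | Iterable[str]],
    support_high: float = 0.95,
    support_low: float = 0.5,
    seed: int = 0,
    phyla: Mapping[str, str] | None = None,
) -> tuple[SupportTree, CladePartition]:
    """A support-annotated tree with planted monophyletic clades.

    Each planted clade is a monophyletic subtree whose root support is
    ``support_high`` (>= 0.92); every other internal node gets
    ``support_low``.  Leaves inside clades are flagged CRISPR-associated;
    the rest are background.  ``planted_clades`` maps labels to leaf-id
    iterables or to member counts (ids are then auto-generated).
    """
    if not (support_high >= 0.92 > support_low):
        raise ValueError("need support_high >= 0.92 > support_low")
    rng = np.random.default_rng(seed)
    clade_leaves: dict[str, list[str]] = {}
    auto = 0
    for label in planted_clades:
        members = planted_clades[label]
        if isinstance(members, int):
            ids = [f"L{auto + i:03d}" for i in range(members)]
            auto += members
        else:
            ids = list(members)
        clade_leaves[label] = ids
    used: set[str] = set()
    for label, ids in clade_leaves.items():
        overlap = used & set(ids)
        if overlap:
            raise ValueError(f"clade {label!r} overlaps another clade: {sorted(overlap)}")
        used |= set(ids)
    n_background = n_leaves - len(used)
    if n_background < 0:
        raise ValueError("planted clades exceed n_leaves")
    background = [f"B{auto + i:03d}" for i in range(n_background)]

    def tip(name: str) -> TreeNode:
        t = TreeNode(name=name)
        t.length = 0.1
        return t

    items: list[TreeNode] = []
    clade_roots: dict[str, TreeNode] = {}
    for label in sorted(clade_leaves):
        sub = _random_binary(rng, [tip(x) for x in clade_leaves[label]], support_low)
        sub.support = support_high
        sub.length = 0.1
        clade_roots[label] = sub
        items.append(sub)
    items.extend(tip(b) for b in background)
    root = _random_binary(rng, items, support_low) if len(items) > 1 else items[0]
    root.support = getattr(root, "support", None)
    if root in clade_roots.values():
        # whole tree is a single clade; keep its high support at the root
        pass
    else:
        root.support = None
    root.length = None

    metadata: dict[str, dict] = {}
    for label, ids in clade_leaves.items():
        ph = (phyla or {}).get(label, f"Phylum_{label}")
        for leaf in ids:
            metadata[leaf] = {"phylum": ph, "crispr_associated": True}
    for leaf in background:
        metadata[leaf] = {"phylum": "Other", "crispr_associated": False}

    stree = SupportTree(root, metadata)
    labels = {leaf: "unassigned" for leaf in stree.leaf_names()}
    clades: dict[str, CladeInfo] = {}
    for label, ids in clade_leaves.items():
        phyla_counts: dict[str, int] = {}
        for leaf in ids:
            labels[leaf] = label
            ph = metadata[leaf]["phylum"]
            phyla_counts[ph] = phyla_counts.get(ph, 0) + 1
        clades[label] = CladeInfo(
            label, frozenset(ids), support_high, phyla_counts, clade_roots[label]
        )
    return stree, CladePartition(labels, clades, stree)


def generate_clade_alignment(
    n_clades: int = 4,
    members_per_clade: int = 5,
    n_background: int = 3,
    length: int = 250,
    divergence: float = 0.05,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str], dict[str, dict]]:
    """A gap-free alignment with clade structure for tree-building tests.

    Members of a clade are a shared founder with ``divergence`` substitutions
    per site; founders and background sequences are mutually random.
    Returns (alignment, truth labels, leaf metadata).
    """
    rng = np.random.default_rng(seed)
    alignment: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    metadata: dict[str, dict] = {}
    for c in range(n_clades):
        founder = "".join(rng.choice(list(AA20), size=length))
        for j in range(members_per_clade):
            name = f"C{c + 1:02d}_{j:02d}"
            seq = mutate_protein(rng, founder, round(divergence * length))
            alignment.append((name, seq))
            labels[name] = str(c + 1)
            metadata[name] = {"phylum": f"Phylum_{c + 1}", "crispr_associated": True}
    for b in range(n_background):
        name = f"BG_{b:02d}"
        alignment.append((name, "".join(rng.choice(list(AA20), size=length))))
        labels[name] = "unassigned"
        metadata[name] = {"phylum": "Other", "crispr_associated": False}
    return alignment, labels, metadata
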