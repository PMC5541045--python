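"""File formats: FASTA, GFF3 feature tables, TSV summaries.

FASTA goes through Biopython.  GFF3 is written and read with a minimal
nine-column implementation: the only features this pipeline exchanges are
CDS rows (genes) and ``repeat_region`` rows with ``direct_repeat``/``spacer``
children, and translations are reconstructed from the genome sequence on
read.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .arrays import CrisprArray
from .loci import GeneFeature, Locus


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _gff_row(contig, source, ftype, start, end, score, strand, attrs) -> str:
    a = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{contig}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{a}"


def write_gff3(
    path: str | Path,
    genes: list[GeneFeature] = (),
    arrays: list[CrisprArray] = (),
) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            _gff_row(
                g.contig, "rtcrispr", "CDS", g.start, g.end, ".", g.strand,
                {"ID": g.locus_tag},
            )
        )
    for i, arr in enumerate(arrays):
        aid = f"array{i}_{arr.contig}_{arr.start}"
        lines.append(
            _gff_row(
                arr.contig, "rtcrispr", "repeat_region", arr.start, arr.end, ".", ".",
                {
                    "ID": aid,
                    "orientation": arr.orientation,
                    "band": arr.band,
                    "criterion": arr.criterion,
                },
            )
        )
        for (s, e), _seq in arr.repeats:
            lines.append(
                _gff_row(arr.contig, "rtcrispr", "direct_repeat", s, e, ".", ".",
                         {"Parent": aid})
            )
        for (s, e), _seq in arr.spacers:
            lines.append(
                _gff_row(arr.contig, "rtcrispr", "spacer", s, e, ".", ".",
                         {"Parent": aid})
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_genes_gff3(path: str | Path, contigs: dict[str, str]) -> list[GeneFeature]:
    """Read CDS features, reconstructing translations from the genome."""
    genes = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9 or parts[2] != "CDS":
            continue
        contig, _src, _t, start, end, _score, strand = parts[:7]
        attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
        start_i, end_i = int(start), int(end)
        seq = contigs[contig][start_i - 1 : end_i]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        translation = str(Seq(seq[:-3]).translate(table=11))
        genes.append(
            GeneFeature(
                contig, start_i, end_i, strand,
                attrs.get("ID", f"cds_{start_i}"), translation,
            )
        )
    return genes


ARRAY_COLUMNS = [
    "contig", "start", "end", "n_repeats", "repeat_consensus",
    "orientation", "band", "criterion",
]
LOCUS_COLUMNS = [
    "contig", "start", "end", "rt_tag", "n_cas_genes", "n_arrays",
    "rt_linked_array", "fusion_class", "subtype", "clade", "architecture",
]


def arrays_table(arrays: list[CrisprArray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": a.contig,
                "start": a.start,
                "end": a.end,
                "n_repeats": a.n_repeats,
                "repeat_consensus": a.repeat_consensus,
                "orientation": a.orientation,
                "band": a.band,
                "criterion": a.criterion,
            }
            for a in arrays
        ],
        columns=ARRAY_COLUMNS,
    )


def loci_table(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": l.contig,
                "start": l.start,
                "end": l.end,
                "rt_tag": l.rt_feature.locus_tag,
                "n_cas_genes": len(l.features),
                "n_arrays": len(l.arrays),
                "rt_linked_array": l.rt_linked_array,
                "fusion_class": l.fusion_class,
                "subtype": l.subtype,
                "clade": l.clade,
                "architecture": l.architecture,
            }
            for l in loci
        ],
        columns=LOCUS_COLUMNS,
    )
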