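"""Cas-family consensus profiles and subtype signature definitions.

The package ships a small synthetic consensus-profile library (one
consensus amino-acid sequence per Cas family plus the RT domain) and a
synthetic oriented direct-repeat table.  Both are stand-ins constructed
for desk-scale runs: the profile sequences carry no biological signal,
but planted genes in the synthetic genomes are derived from them, so
profile search behaves exactly like a consensus-based annotation step.

Type III effector subtype signatures follow the Csm/Cmr split: csm2-csm5
indicate subtype III-A/D, cmr1 and cmr3-cmr6 indicate III-B/C.  cas10 is
shared by both effector complexes and is deliberately not discriminative.
"""

from __future__ import annotations

from importlib import resources

from Bio import SeqIO

from .arrays import RepeatDB

# families whose confident presence pins the effector subtype
CSM_SIGNATURES = frozenset({"csm2", "csm3", "csm4", "csm5"})
CMR_SIGNATURES = frozenset({"cmr1", "cmr3", "cmr4", "cmr5", "cmr6"})
SUBTYPE_SIGNATURES = CSM_SIGNATURES | CMR_SIGNATURES

ADAPTATION_FAMILIES = frozenset({"cas1", "cas2", "cas6"})
RT_FAMILY = "RT"


def load_profiles() -> list[tuple[str, str]]:
    """The shipped synthetic consensus-profile library as (family, sequence)."""
    ref = resources.files("rtcrispr.data").joinpath("synthetic_cas_profiles.faa")
    with ref.open() as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def load_repeat_db() -> RepeatDB:
    """The shipped synthetic oriented direct-repeat table."""
    ref = resources.files("rtcrispr.data").joinpath("synthetic_repeat_db.tsv")
    entries = []
    with ref.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            if line.strip():
                parts = line.rstrip("\n").split("\t")
                entries.append(
                    (parts[idx["repeat"]], parts[idx["orientation"]], parts[idx["family"]])
                )
    return RepeatDB(entries)


def profile_dict() -> dict[str, str]:
    return dict(load_profiles())
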