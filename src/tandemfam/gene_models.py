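"""Gene models: typed region partitions of tandem-family members and their I/O.

A gene is partitioned into up to six region classes — promoter, 5'-UTR,
signal-peptide coding region (SPCR), intron(s), mature-protein coding region
(MPCR) and 3'-UTR — given as intervals on a parent sequence.  Coordinates are
0-based half-open internally and 1-based inclusive in GFF3, the standard
convention for each representation.

Region kinds are encoded in the GFF3 ``type`` column with Sequence Ontology
terms where one exists (``five_prime_UTR``, ``intron``, ``three_prime_UTR``)
and ``CDS`` with a ``part=signal_peptide|mature`` attribute for the SPCR/MPCR
split; the promoter uses ``promoter``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class GeneModelError(ValueError):
    """Raised for structurally invalid gene models or annotations."""


class RegionKind(str, Enum):
    PROMOTER = "promoter"
    UTR5 = "utr5"
    SPCR = "spcr"
    INTRON = "intron"
    MPCR = "mpcr"
    UTR3 = "utr3"
    INTERGENIC = "intergenic"


#: transcript-order rank used to sort extracted regions promoter -> utr3
_KIND_ORDER = {
    RegionKind.PROMOTER: 0,
    RegionKind.UTR5: 1,
    RegionKind.SPCR: 2,
    RegionKind.INTRON: 3,
    RegionKind.MPCR: 4,
    RegionKind.UTR3: 5,
    RegionKind.INTERGENIC: 6,
}

#: kinds that may occur at most once per gene
_SINGLETON_KINDS = {RegionKind.PROMOTER, RegionKind.UTR5, RegionKind.UTR3}

# GFF3 type-column encoding (SO terms where they exist)
_GFF_TYPE = {
    RegionKind.PROMOTER: "promoter",
    RegionKind.UTR5: "five_prime_UTR",
    RegionKind.SPCR: "CDS",
    RegionKind.MPCR: "CDS",
    RegionKind.INTRON: "intron",
    RegionKind.UTR3: "three_prime_UTR",
    RegionKind.INTERGENIC: "intergenic_region",
}


@dataclass(frozen=True)
class Region:
    """A typed interval on a parent sequence (0-based half-open)."""

    kind: RegionKind
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not isinstance(self.kind, RegionKind):
            object.__setattr__(self, "kind", RegionKind(self.kind))
        if self.start < 0 or self.start >= self.end:
            raise GeneModelError(
                f"invalid region interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise GeneModelError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """One gene's region partition on its parent sequence."""

    gene_id: str
    parent_seq_id: str
    regions: list[Region]
    strand: str = "+"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"{self.gene_id}: invalid strand {self.strand!r}")
        counts: dict[RegionKind, int] = {}
        for r in self.regions:
            counts[r.kind] = counts.get(r.kind, 0) + 1
        for kind in _SINGLETON_KINDS:
            if counts.get(kind, 0) > 1:
                raise GeneModelError(
                    f"{self.gene_id}: more than one {kind.value} region"
                )
        ordered = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise GeneModelError(
                    f"{self.gene_id}: overlapping regions "
                    f"{a.kind.value}[{a.start},{a.end}) and "
                    f"{b.kind.value}[{b.start},{b.end})"
                )
        self.regions = ordered

    def regions_of(self, kind: RegionKind | str) -> list[Region]:
        kind = RegionKind(kind)
        return [r for r in self.regions if r.kind == kind]

    def span(self) -> tuple[int, int]:
        return self.regions[0].start, self.regions[-1].end


@dataclass
class FamilySet:
    """A gene family: members plus their per-region extracted sequences.

    ``members`` maps gene_id -> (GeneModel, {RegionKind: sequence}); region
    sequences are in transcript (sense) orientation, so minus-strand genes are
    reverse-complemented on extraction.
    """

    family_id: str
    members: dict[str, tuple[GeneModel, dict[RegionKind, str]]] = field(
        default_factory=dict
    )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.members)

    def region_seqs(self, kind: RegionKind | str) -> dict[str, str]:
        """Per-member concatenated sequence of all regions of ``kind``."""
        kind = RegionKind(kind)
        out = {}
        for gid, (_, seqs) in self.members.items():
            if kind in seqs:
                out[gid] = seqs[kind]
        return out

    def shared_kinds(self, min_members: int = 2) -> list[RegionKind]:
        counts: dict[RegionKind, int] = {}
        for _, seqs in self.members.values():
            for kind in seqs:
                counts[kind] = counts.get(kind, 0) + 1
        return [k for k in _KIND_ORDER if counts.get(k, 0) >= min_members]


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_region_seqs(
    model: GeneModel, parent_seq: str
) -> dict[RegionKind, str]:
    """Extract per-kind region sequences in transcript orientation.

    Multiple regions of the same kind (e.g. several introns) are concatenated
    in transcript order.  Minus-strand regions are reverse-complemented.
    """
    pieces: dict[RegionKind, list[str]] = {}
    order = model.regions if model.strand == "+" else list(reversed(model.regions))
    for r in order:
        if r.end > len(parent_seq):
            raise GeneModelError(
                f"{model.gene_id}: region {r.kind.value}[{r.start},{r.end}) "
                f"beyond parent sequence of length {len(parent_seq)}"
            )
        sub = parent_seq[r.start:r.end]
        if model.strand == "-":
            sub = _revcomp(sub)
        pieces.setdefault(r.kind, []).append(sub)
    return {k: "".join(v) for k, v in pieces.items()}


def extract_coding(
    model: GeneModel, parent_seq: str
) -> tuple[str, str, str]:
    """Splice the coding sequence and translate it.

    Returns ``(spcr_seq, mpcr_seq, protein)`` where protein is the standard
    genetic-code translation of SPCR+MPCR with introns removed.  A terminal
    stop is accepted (rendered ``*``); an internal stop raises with the codon
    position.  When the SPCR length is not a multiple of 3 the split codon
    belongs to the SPCR nucleotide partition, while protein-level reporting of
    the signal peptide covers only the full SPCR codons.
    """
    seqs = extract_region_seqs(model, parent_seq)
    if RegionKind.SPCR not in seqs or RegionKind.MPCR not in seqs:
        raise GeneModelError(f"{model.gene_id}: SPCR and MPCR regions required")
    spcr, mpcr = seqs[RegionKind.SPCR], seqs[RegionKind.MPCR]
    coding = spcr + mpcr
    if len(coding) % 3:
        raise GeneModelError(
            f"{model.gene_id}: coding length {len(coding)} not a multiple of 3"
        )
    protein = str(Seq(coding).translate())
    internal = protein[:-1].find("*")
    if internal != -1:
        raise GeneModelError(
            f"{model.gene_id}: internal stop codon at codon {internal + 1}"
        )
    return spcr, mpcr, protein


def signal_peptide_length(spcr_len: int) -> int:
    """Number of full signal-peptide codons in an SPCR of ``spcr_len`` nt."""
    return spcr_len // 3


# ---------------------------------------------------------------------------
# GFF3 + FASTA I/O
# ---------------------------------------------------------------------------

def _parse_attributes(attr_col: str) -> dict[str, str]:
    out = {}
    for item in attr_col.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def _gff_kind(ftype: str, attrs: dict[str, str]) -> RegionKind | None:
    if ftype == "promoter":
        return RegionKind.PROMOTER
    if ftype == "five_prime_UTR":
        return RegionKind.UTR5
    if ftype == "intron":
        return RegionKind.INTRON
    if ftype == "three_prime_UTR":
        return RegionKind.UTR3
    if ftype == "intergenic_region":
        return RegionKind.INTERGENIC
    if ftype == "CDS":
        part = attrs.get("part", "")
        if part == "signal_peptide":
            return RegionKind.SPCR
        if part == "mature":
            return RegionKind.MPCR
        raise GeneModelError(
            f"CDS feature needs part=signal_peptide|mature, got {part!r}"
        )
    return None


def read_family(
    fasta_path: str | Path,
    gff_path: str | Path,
    family_id: str = "family",
) -> FamilySet:
    """Load a family from a multi-FASTA and a GFF3 region annotation.

    GFF3 coordinates (1-based inclusive) are converted to 0-based half-open.
    Features are grouped into genes by their ``Parent`` attribute.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    genes: dict[str, dict] = {}
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GeneModelError(f"malformed GFF3 line: {line!r}")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr = cols
            attrs = _parse_attributes(attr)
            kind = _gff_kind(ftype, attrs)
            if kind is None:
                continue
            gene_id = attrs.get("Parent") or attrs.get("gene_id")
            if gene_id is None:
                raise GeneModelError(f"feature without Parent/gene_id: {line!r}")
            if seqid not in seqs:
                raise GeneModelError(
                    f"gene {gene_id}: parent sequence {seqid!r} missing from FASTA"
                )
            entry = genes.setdefault(
                gene_id, {"parent": seqid, "strand": strand, "regions": []}
            )
            if entry["parent"] != seqid:
                raise GeneModelError(f"gene {gene_id} spans multiple sequences")
            entry["regions"].append(
                Region(kind, int(start) - 1, int(end), strand)
            )
    fam = FamilySet(family_id)
    for gene_id, entry in genes.items():
        model = GeneModel(gene_id, entry["parent"], entry["regions"], entry["strand"])
        region_seqs = extract_region_seqs(model, seqs[model.parent_seq_id])
        fam.members[gene_id] = (model, region_seqs)
    return fam


def write_family(
    fam: FamilySet,
    parent_seqs: dict[str, str],
    fasta_path: str | Path,
    gff_path: str | Path,
) -> None:
    """Write parent sequences as FASTA (60-col wrap) and regions as GFF3."""
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in parent_seqs.items()
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, (model, _) in fam.members.items():
            for r in model.regions:
                attrs = [f"Parent={gene_id}"]
                if r.kind == RegionKind.SPCR:
                    attrs.append("part=signal_peptide")
                elif r.kind == RegionKind.MPCR:
                    attrs.append("part=mature")
                fh.write(
                    "\t".join(
                        [
                            model.parent_seq_id,
                            "tandemfam",
                            _GFF_TYPE[r.kind],
                            str(r.start + 1),
                            str(r.end),
                            ".",
                            model.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


def write_manifest(path: str | Path, families: dict[str, Iterable[str]]) -> None:
    """Write a family manifest JSON mapping family_id -> gene_ids."""
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in families.items()}, fh, indent=2)
        fh.write("\n")
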