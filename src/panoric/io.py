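"""File formats shared across the pipeline.

Chromosomes are single circular FASTA records whose ID is the strain name.
Gene annotations are GFF3 (1-based inclusive coordinates, ``ID=`` attribute
matching the gene identifiers used in the orthology table). Prophage and
genomic-island calls are BED intervals (0-based half-open) with the source
tool in column 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REGION_SOURCES = ("phaster", "alienhunter", "islandviewer")
#: which region type each prediction tool reports
SOURCE_TYPES = {"phaster": "phage", "alienhunter": "GI", "islandviewer": "GI"}


@dataclass
class GeneRecord:
    """One annotated gene on a circular chromosome."""

    gene_id: str
    strain: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"
    name: str | None = None  # e.g. "parA"

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class RegionAnnotation:
    """A prophage or genomic-island interval (0-based half-open)."""

    start: int
    end: int
    region_type: str  # "phage" | "GI"
    source: str  # "phaster" | "alienhunter" | "islandviewer"
    strain: str | None = None

    def __post_init__(self) -> None:
        if self.source not in REGION_SOURCES:
            raise ValueError(
                f"unknown region source {self.source!r}; expected one of {REGION_SOURCES}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, strain: str, sequence: str) -> None:
    rec = SeqRecord(Seq(sequence), id=strain, description="circular chromosome")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path: str | Path) -> tuple[str, str]:
    """Return (strain id, sequence) of a single-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one chromosome record, got {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path: str | Path, strain: str, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.name:
                attrs += f";Name={g.name}"
            fh.write(
                "\t".join(
                    [
                        strain,
                        "panoric",
                        "gene",
                        str(g.start + 1),  # GFF3 is 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path, strain: str | None = None) -> list[GeneRecord]:
    """Read gene records from a GFF3 file, sorted by position."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        name = feat.attributes.get("Name", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                strain=strain or feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                name=name,
            )
        )
    genes.sort(key=lambda g: (g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# BED regions
# ---------------------------------------------------------------------------

def write_bed(path: str | Path, regions: Iterable[RegionAnnotation]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.strain}\t{r.start}\t{r.end}\t{r.source}\n")


def read_bed(path: str | Path) -> list[RegionAnnotation]:
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: BED line needs >=4 fields: {line!r}")
            strain, start, end, source = fields[:4]
            regions.append(
                RegionAnnotation(
                    start=int(start),
                    end=int(end),
                    region_type=SOURCE_TYPES.get(source, "GI"),
                    source=source,
                    strain=strain,
                )
            )
    return regions


# ---------------------------------------------------------------------------
# Simulation truth
# ---------------------------------------------------------------------------

def write_truth(path: str | Path, truth_dict: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
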