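"""Pan-genome orthology tables: parsing, core/accessory classification, ortholog scores.

The on-disk format is the Proteinortho tab-separated dialect: a header line
``# Species<TAB>Genes<TAB>Alg.-Conn.<TAB><strain1>...`` followed by one row per
protein family, with per-strain members comma-separated and absent strains
marked ``*``.

The *ortholog score* of a gene in a focal strain is the number of OTHER
strains that have at least one ortholog (member of the same family), so the
maximum is ``n_strains - 1``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_PO_FIXED_COLS = ["# Species", "Genes", "Alg.-Conn."]


@dataclass
class OrthologFamily:
    """One pan-genome protein family."""

    family_id: str
    members: dict[str, list[str]]  # strain -> gene ids (>=2 => in-strain paralogs)
    connectivity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.connectivity <= 1.0:
            raise ValueError(f"connectivity must be in [0,1], got {self.connectivity}")
        self.members = {s: list(g) for s, g in self.members.items() if g}

    @property
    def n_species(self) -> int:
        return len(self.members)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.members.values())

    @property
    def has_paralogs(self) -> bool:
        return any(len(g) >= 2 for g in self.members.values())


@dataclass
class PanGenome:
    """An ordered strain set with its ortholog families and a gene index."""

    strains: list[str]
    families: list[OrthologFamily]
    gene_index: dict[str, tuple[str, str]] = field(default_factory=dict)  # gene -> (strain, family)

    def __post_init__(self) -> None:
        strain_set = set(self.strains)
        if not self.gene_index:
            for fam in self.families:
                for strain, genes in fam.members.items():
                    if strain not in strain_set:
                        raise ValueError(
                            f"family {fam.family_id} references unknown strain {strain!r}"
                        )
                    for g in genes:
                        if g in self.gene_index:
                            raise ValueError(
                                f"gene {g!r} appears in families "
                                f"{self.gene_index[g][1]!r} and {fam.family_id!r}"
                            )
                        self.gene_index[g] = (strain, fam.family_id)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    def family_by_id(self, family_id: str) -> OrthologFamily:
        if not hasattr(self, "_fam_map"):
            self._fam_map = {f.family_id: f for f in self.families}
        return self._fam_map[family_id]


# ---------------------------------------------------------------------------
# Proteinortho dialect
# ---------------------------------------------------------------------------

def read_proteinortho(path: str | Path) -> PanGenome:
    """Parse a Proteinortho-dialect TSV into a :class:`PanGenome`.

    Raises ``ValueError`` on a malformed header, a row whose declared
    species/gene counts contradict its members, or a gene id that occurs in
    more than one family.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_PO_FIXED_COLS)] != _PO_FIXED_COLS:
            raise ValueError(
                f"{path}: not a Proteinortho table; header starts with {header[:3]!r}"
            )
        strains = header[len(_PO_FIXED_COLS):]
        if not strains:
            raise ValueError(f"{path}: header lists no strain columns")
        families: list[OrthologFamily] = []
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}: row {i + 2} has {len(fields)} columns, expected {len(header)}"
                )
            n_species, n_genes = int(fields[0]), int(fields[1])
            connectivity = float(fields[2])
            members: dict[str, list[str]] = {}
            for strain, cell in zip(strains, fields[3:]):
                if cell == "*" or not cell:
                    continue
                members[strain] = cell.split(",")
            fam = OrthologFamily(
                family_id=f"F{len(families):05d}", members=members, connectivity=connectivity
            )
            if fam.n_species != n_species or fam.n_genes != n_genes:
                raise ValueError(
                    f"{path}: row {i + 2} declares {n_species} species / {n_genes} genes "
                    f"but lists {fam.n_species} / {fam.n_genes}"
                )
            families.append(fam)
    return PanGenome(strains=strains, families=families)


def write_proteinortho(path: str | Path, pan: PanGenome) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PO_FIXED_COLS + pan.strains) + "\n")
        for fam in pan.families:
            cells = [
                ",".join(fam.members[s]) if s in fam.members else "*" for s in pan.strains
            ]
            fh.write(
                "\t".join([str(fam.n_species), str(fam.n_genes), f"{fam.connectivity:g}"] + cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Classification (core / soft-core / accessory)
# ---------------------------------------------------------------------------

def soft_core_threshold(n_strains: int, soft_core_fraction: float = 0.95) -> int:
    """Minimum strain count for a soft-core family (ceiling rule: 0.95 x 109 -> 104)."""
    if not 0.0 < soft_core_fraction <= 1.0:
        raise ValueError(f"soft_core_fraction must be in (0,1], got {soft_core_fraction}")
    return math.ceil(soft_core_fraction * n_strains)


def classify_families(
    pan: PanGenome,
    soft_core_fraction: float = 0.95,
    connectivity_min: float = 0.9,
) -> tuple[pd.DataFrame, int]:
    """Label every family core / soft_core / accessory and flag paralogs & connectivity.

    Returns ``(table, soft_core_threshold)``. ``core`` families are present in
    every strain; ``soft_core`` in at least ``ceil(fraction * n_strains)``
    strains (core families are also soft-core); the rest are ``accessory``.
    """
    if not pan.families:
        raise ValueError("empty pan-genome")
    thr = soft_core_threshold(pan.n_strains, soft_core_fraction)
    rows = []
    for fam in pan.families:
        core = fam.n_species == pan.n_strains
        soft = fam.n_species >= thr
        label = "core" if core else ("soft_core" if soft else "accessory")
        rows.append(
            {
                "family_id": fam.family_id,
                "n_species": fam.n_species,
                "n_genes": fam.n_genes,
                "connectivity": fam.connectivity,
                "label": label,
                "is_core": core,
                "is_soft_core": soft,
                "has_paralogs": fam.has_paralogs,
                "high_connectivity": fam.connectivity >= connectivity_min,
            }
        )
    return pd.DataFrame(rows), thr


def pangenome_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """One-row summary with the five headline family counts of a pan-genome
    dataset: total families, core and soft-core (paralogs included), core
    without paralogs, and core without paralogs at high connectivity."""
    c = classification
    return pd.DataFrame(
        [
            {
                "n_families": len(c),
                "core_incl_paralogs": int(c["is_core"].sum()),
                "soft_core_incl_paralogs": int(c["is_soft_core"].sum()),
                "core_no_paralogs": int((c["is_core"] & ~c["has_paralogs"]).sum()),
                "core_no_paralogs_high_conn": int(
                    (c["is_core"] & ~c["has_paralogs"] & c["high_connectivity"]).sum()
                ),
            }
        ]
    )


# ---------------------------------------------------------------------------
# Ortholog scores
# ---------------------------------------------------------------------------

def ortholog_scores(
    pan: PanGenome,
    focal_strain: str,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene ortholog score for one focal strain.

    ``gene_ids`` optionally supplies the annotated gene list (e.g. from GFF3);
    genes missing from the orthology table are scored 0 and flagged
    ``in_table=False`` with a warning, so window indexing stays aligned with
    the chromosome.
    """
    if focal_strain not in pan.strains:
        raise ValueError(f"unknown strain {focal_strain!r}")
    if gene_ids is None:
        gene_ids = [g for g, (s, _) in pan.gene_index.items() if s == focal_strain]
    rows = []
    n_missing = 0
    for g in gene_ids:
        hit = pan.gene_index.get(g)
        if hit is None or hit[0] != focal_strain:
            n_missing += 1
            rows.append({"gene_id": g, "family_id": None, "ortholog_score": 0, "in_table": False})
            continue
        fam = pan.family_by_id(hit[1])
        score = sum(1 for s in fam.members if s != focal_strain)
        rows.append(
            {"gene_id": g, "family_id": fam.family_id, "ortholog_score": score, "in_table": True}
        )
    if n_missing:
        logger.warning(
            "%d/%d genes of %s absent from the orthology table; scored 0",
            n_missing, len(gene_ids), focal_strain,
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One strain per genus
# ---------------------------------------------------------------------------

def reduce_one_per_genus(
    pan: PanGenome, genus_map: dict[str, str], seed: int = 0
) -> PanGenome:
    """Keep one (seeded-random) strain per genus and re-tally families.

    Mirrors the robustness re-analysis that corrects for over-represented
    genera: families are restricted to the kept strains, their species/gene
    counts recomputed, and families left empty are dropped.
    """
    missing = [s for s in pan.strains if s not in genus_map]
    if missing:
        raise ValueError(f"genus_map does not cover strains: {missing}")
    rng = np.random.default_rng(seed)
    by_genus: dict[str, list[str]] = {}
    for s in pan.strains:  # preserve strain order within genus
        by_genus.setdefault(genus_map[s], []).append(s)
    kept: set[str] = set()
    for genus in sorted(by_genus):
        members = by_genus[genus]
        kept.add(members[int(rng.integers(len(members)))])
    new_strains = [s for s in pan.strains if s in kept]
    new_families = []
    for fam in pan.families:
        members = {s: g for s, g in fam.members.items() if s in kept}
        if not members:
            continue
        new_families.append(
            OrthologFamily(
                family_id=fam.family_id, members=members, connectivity=fam.connectivity
            )
        )
    return PanGenome(strains=new_strains, families=new_families)
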