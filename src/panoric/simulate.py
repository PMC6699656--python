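"""Synthetic multi-strain cohorts with planted positional structure.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without external genomes:

* a pan-genome whose families carry a configurable strain-occupancy mixture
  (core, soft-core, accessory), with a tunable fraction of paralogous families;
* per-strain circular gene orders in which the expected ortholog score of a
  gene varies linearly with its normalized distance from a true oriC
  (slope ``positional_bias_beta``), realised by rank-matching family
  occupancies to noisy linear position scores — this keeps gene counts exact;
* circular nucleotide sequences whose cumulative G-C disparity attains its
  extremum at the true oriC (strand-compositional skew switching sign at oriC
  and terC), with DnaA 9-mers planted in the oriC intergenic gap, parA/parB
  genes flanking it, and compositionally distinct phage / genomic-island
  regions placed by a tunable distance distribution.

Every strain carries exactly ``genes_per_strain`` genes, paralog copies
included: paralogous families are chosen before the occupancy matrix is
realised and contribute two gene slots in their duplicate-carrier strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GeneRecord, RegionAnnotation
from .oric import DNAA_MOTIFS
from .pangenome import OrthologFamily, PanGenome

_PLACEMENTS = ("uniform", "near_ter", "near_ori")


@dataclass
class SimulationConfig:
    """Study-design knobs of the synthetic cohort.

    ``conservation_mixture`` lists ``(occupancy_fraction, weight)`` pairs: each
    family draws its carrier-strain fraction from this mixture (weights sum
    to 1). ``positional_bias_beta`` is the expected change in mean ortholog
    score per unit normalized oriC distance (negative = conserved genes cluster
    at oriC). ``skew_amplitude`` in [0,1] scales the replichore G/C asymmetry.
    """

    n_strains: int = 20
    n_families: int = 2000
    genes_per_strain: int = 1000
    genome_length: int = 2_000_000
    conservation_mixture: list[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 0.25), (0.95, 0.05), (0.5, 0.20), (0.25, 0.20), (0.05, 0.30)]
    )
    positional_bias_beta: float = 0.0
    skew_amplitude: float = 0.3
    background_gc: float = 0.6
    n_dnaa_boxes: int = 6
    phage_placement: str = "uniform"
    gi_placement: str = "uniform"
    n_phage_per_strain: int = 3
    n_gi_per_strain: int = 4
    region_length_range: tuple[int, int] = (15_000, 30_000)
    paralog_fraction: float = 0.05
    low_connectivity_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("need at least 2 strains")
        w_total = sum(w for _, w in self.conservation_mixture)
        if abs(w_total - 1.0) > 1e-8:
            raise ValueError(f"mixture weights must sum to 1, got {w_total}")
        for f, _ in self.conservation_mixture:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"occupancy fraction {f} outside [0,1]")
        if not 0.0 <= self.skew_amplitude <= 1.0:
            raise ValueError(f"skew_amplitude must be in [0,1], got {self.skew_amplitude}")
        if self.n_families < self.genes_per_strain:
            raise ValueError(
                "infeasible: n_families < genes_per_strain "
                f"({self.n_families} < {self.genes_per_strain}); a strain cannot carry "
                "more distinct families than exist"
            )
        if self.genome_length < self.genes_per_strain * 200:
            raise ValueError(
                "genome_length too small: need >= 200 bp per gene slot "
                f"({self.genome_length} < {self.genes_per_strain * 200})"
            )
        for p in (self.phage_placement, self.gi_placement):
            if p not in _PLACEMENTS:
                raise ValueError(f"placement {p!r} not in {_PLACEMENTS}")

    @property
    def slot_length(self) -> float:
        return self.genome_length / self.genes_per_strain

    def strain_names(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_strains)]


@dataclass
class SimulationTruth:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    true_beta: float
    true_oric: dict[str, int]
    family_occupancy: dict[str, int]
    regions: dict[str, list[RegionAnnotation]]
    dnaa_positions: dict[str, list[int]]

    def to_dict(self) -> dict:
        return {
            "true_beta": self.true_beta,
            "true_oric": self.true_oric,
            "family_occupancy": self.family_occupancy,
            "regions": {
                s: [[r.start, r.end, r.region_type, r.source] for r in rs]
                for s, rs in self.regions.items()
            },
            "dnaa_positions": self.dnaa_positions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        return cls(
            true_beta=d["true_beta"],
            true_oric={s: int(v) for s, v in d["true_oric"].items()},
            family_occupancy={f: int(v) for f, v in d["family_occupancy"].items()},
            regions={
                s: [
                    RegionAnnotation(start=a, end=b, region_type=t, source=src, strain=s)
                    for a, b, t, src in rs
                ]
                for s, rs in d["regions"].items()
            },
            dnaa_positions={s: [int(p) for p in ps] for s, ps in d["dnaa_positions"].items()},
        )


# ---------------------------------------------------------------------------
# Pan-genome with linear positional bias
# ---------------------------------------------------------------------------

def _draw_occupancies(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Carrier-strain count per family, adjusted so the grand total of gene
    slots (including planned paralog duplicates) is exactly
    n_strains * genes_per_strain."""
    n, G, F = config.n_strains, config.genes_per_strain, config.n_families
    fracs = np.array([f for f, _ in config.conservation_mixture])
    weights = np.array([w for _, w in config.conservation_mixture])
    comp = rng.choice(len(fracs), size=F, p=weights)
    k = np.clip(np.rint(fracs[comp] * n).astype(int), 1, n)
    n_core = int(np.sum(k == n))
    if n_core > G:
        raise ValueError(
            f"infeasible: {n_core} core families demanded but each strain has only "
            f"{G} gene slots"
        )
    n_dup = int(round(config.paralog_fraction * F))
    target = n * G - n_dup
    if not F <= target <= F * n:
        raise ValueError(
            "infeasible: total gene slots cannot match occupancy mixture "
            f"(target {target}, families {F}, strains {n})"
        )
    delta = target - int(k.sum())
    step = 1 if delta > 0 else -1
    guard = 0
    while delta != 0:
        i = int(rng.integers(F))
        if (step > 0 and k[i] < n) or (step < 0 and k[i] > 1):
            k[i] += step
            delta -= step
        guard += 1
        if guard > 100 * F * n:
            raise ValueError("occupancy adjustment failed to converge")
    return k


def _assign_carriers(
    k: np.ndarray, n_dup: int, config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[list[int]], np.ndarray]:
    """Realise a 0/1 strain-by-family occupancy with exact per-strain gene
    budgets (Gale-Ryser style greedy: fill strains with the largest remaining
    capacity first). Returns per-family carrier lists and, per family, the
    strain index of its paralog duplicate (-1 = no duplicate)."""
    n, G, F = config.n_strains, config.genes_per_strain, config.n_families
    dup_families = rng.choice(F, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    is_dup = np.zeros(F, dtype=bool)
    is_dup[dup_families] = True
    capacity = np.full(n, G, dtype=int)
    # paralog families first (their carrier needs 2 free slots), then by demand
    order = np.lexsort((-k, ~is_dup))
    carriers: list[list[int]] = [[] for _ in range(F)]
    dup_strain = np.full(F, -1, dtype=int)
    for f in order:
        need = int(k[f])
        # strains with largest remaining capacity; random tie-break
        noise = rng.random(n)
        pick = np.lexsort((noise, -capacity))[:need]
        if capacity[pick[-1]] < 1:
            raise ValueError("carrier assignment infeasible; relax the mixture or sizes")
        capacity[pick] -= 1
        carriers[f] = sorted(int(s) for s in pick)
        if is_dup[f]:
            avail = pick[capacity[pick] >= 1]
            if len(avail) == 0:
                raise ValueError("paralog placement infeasible; lower paralog_fraction")
            ds = int(avail[np.argmax(capacity[avail])])
            capacity[ds] -= 1
            dup_strain[f] = ds
    if capacity.any():
        raise ValueError("carrier assignment did not exhaust gene slots")
    return carriers, dup_strain


def _gene_slots(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Gene (start, end) per slot: each slot holds one gene covering the middle
    60%, leaving 20% intergenic margin on each side."""
    G = config.genes_per_strain
    slot = config.slot_length
    i = np.arange(G)
    starts = np.rint(i * slot + 0.2 * slot).astype(int)
    ends = np.rint(i * slot + 0.8 * slot).astype(int)
    return starts, ends


def simulate_pangenome(
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], PanGenome, SimulationTruth]:
    """Generate per-strain gene catalogs, the ortholog family set and truth.

    Within each strain the multiset of family occupancies is rank-matched to a
    noisy linear score over gene positions, so the expected ortholog score at
    normalized oriC distance d is ``a + true_beta * d``. The noise variance is
    calibrated (``var(score) - beta^2 var(d)``) so the realised regression
    slope matches ``positional_bias_beta`` rather than being attenuated by the
    rank transform.
    """
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(4)
    rng_occ = np.random.default_rng(ss[0])
    rng_assign = np.random.default_rng(ss[1])
    rng_oric = np.random.default_rng(ss[2])
    rng_place = np.random.default_rng(ss[3])

    k = _draw_occupancies(config, rng_occ)
    n_dup = int(round(config.paralog_fraction * config.n_families))
    carriers, dup_strain = _assign_carriers(k, n_dup, config, rng_assign)
    strains = config.strain_names()
    fam_ids = [f"F{i:05d}" for i in range(config.n_families)]

    L, G = config.genome_length, config.genes_per_strain
    starts, ends = _gene_slots(config)
    mids = (starts + ends) / 2.0
    # oriC sits at a slot boundary, in the middle of an intergenic gap
    oric_slot = rng_oric.integers(G, size=config.n_strains)
    orics = np.rint(oric_slot * config.slot_length).astype(int) % L

    # per-strain family lists (paralog duplicates appear twice)
    strain_fams: dict[str, list[int]] = {s: [] for s in strains}
    for f, cs in enumerate(carriers):
        for si in cs:
            strain_fams[strains[si]].append(f)
        if dup_strain[f] >= 0:
            strain_fams[strains[dup_strain[f]]].append(f)

    catalogs: dict[str, pd.DataFrame] = {}
    members: dict[int, dict[str, list[str]]] = {f: {} for f in range(config.n_families)}
    beta = config.positional_bias_beta
    for si, strain in enumerate(strains):
        fams = np.array(strain_fams[strain])
        scores = k[fams] - 1.0  # ortholog score of a gene = carriers minus focal
        offset = (mids - orics[si]) % L
        d = np.minimum(offset, L - offset) / (L / 2)
        fam_at_slot = _place_with_bias(fams, scores, d, beta, rng_place)
        gene_ids = [f"{strain}_{i:05d}" for i in range(G)]
        catalogs[strain] = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "family_id": [fam_ids[f] for f in fam_at_slot],
                "start": starts,
                "end": ends,
                "strand": np.where(np.arange(G) % 2 == 0, "+", "-"),
                "name": [None] * G,
            }
        )
        for i in range(G):
            members[fam_at_slot[i]].setdefault(strain, []).append(gene_ids[i])
        _mark_par_genes(catalogs[strain], orics[si], L)

    rng_conn = np.random.default_rng(root.spawn(1)[0])
    families = []
    for f in range(config.n_families):
        low = rng_conn.random() < config.low_connectivity_fraction
        conn = round(float(rng_conn.uniform(0.3, 0.9) if low else rng_conn.uniform(0.92, 1.0)), 4)
        families.append(
            OrthologFamily(family_id=fam_ids[f], members=members[f], connectivity=conn)
        )
    pan = PanGenome(strains=strains, families=families)
    truth = SimulationTruth(
        true_beta=beta,
        true_oric={s: int(orics[i]) for i, s in enumerate(strains)},
        family_occupancy={fam_ids[f]: int(k[f]) for f in range(config.n_families)},
        regions={s: [] for s in strains},
        dnaa_positions={s: [] for s in strains},
    )
    return catalogs, pan, truth


def _place_with_bias(
    fams: np.ndarray,
    scores: np.ndarray,
    d: np.ndarray,
    beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Order one strain's families around the circle by rank-matching their
    occupancy scores to noisy linear targets ``beta * d + sigma * z``.

    The rank transform attenuates the realised regression slope relative to
    ``beta`` when the score distribution is non-Gaussian, so ``sigma`` is
    calibrated by bisection until the gene-level OLS slope of the placed
    scores on distance matches ``beta`` (slopes steeper than the comonotone
    maximum are clamped there — the detection floor of the construction).
    """
    G = len(d)
    z = rng.normal(size=G)
    tie = rng.random(G)
    fam_order = fams[np.lexsort((tie, scores))]
    s_sorted = scores[np.lexsort((tie, scores))]
    dc = d - d.mean()
    denom = float(dc @ dc)

    def placed_slope(sigma: float) -> tuple[float, np.ndarray]:
        target = beta * d + sigma * z
        slot_order = np.argsort(target, kind="stable")
        s_at_slot = np.empty(G)
        s_at_slot[slot_order] = s_sorted
        return float(dc @ s_at_slot) / denom, slot_order

    sigma_scale = float(scores.std()) + 1e-9
    if beta == 0.0:
        _, slot_order = placed_slope(sigma_scale)  # pure noise: random order
    else:
        lo, hi = 0.0, 100.0 * sigma_scale
        slope_lo, slot_order = placed_slope(lo)
        if abs(slope_lo) <= abs(beta):  # |beta| above the comonotone maximum
            pass
        else:
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                slope_mid, order_mid = placed_slope(mid)
                if abs(slope_mid) >= abs(beta):
                    lo, slot_order = mid, order_mid
                else:
                    hi = mid
                if abs(slope_mid - beta) < 1e-4 * max(abs(beta), 1.0):
                    break
    fam_at_slot = np.empty(G, dtype=int)
    fam_at_slot[slot_order] = fam_order
    return fam_at_slot


def _mark_par_genes(catalog: pd.DataFrame, oric: int, length: int) -> None:
    """Name the genes flanking the oriC gap parA (clockwise) and parB."""
    mids = ((catalog["start"] + catalog["end"]) / 2).to_numpy()
    cw = (mids - oric) % length
    catalog.loc[int(np.argmin(cw)), "name"] = "parA"
    ccw = (oric - mids) % length
    catalog.loc[int(np.argmin(ccw)), "name"] = "parB"


# ---------------------------------------------------------------------------
# Sequences with planted oriC signals
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_sequence(
    catalog: pd.DataFrame,
    oric: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    regions: list[RegionAnnotation] | None = None,
) -> tuple[str, list[int]]:
    """One circular chromosome with replichore-switching G/C skew, DnaA boxes
    planted in the oriC intergenic gap, and compositionally distinct planted
    regions. Returns ``(sequence, dnaa_box_positions)``."""
    if not 0.0 <= config.skew_amplitude <= 1.0:
        raise ValueError("skew_amplitude outside [0,1]")
    L = config.genome_length
    gc, sk = config.background_gc, config.skew_amplitude
    at_sk = 0.5 * sk

    offset = (np.arange(L) - oric) % L
    plus = offset < L // 2  # clockwise (right) replichore: G- and T-rich
    seq = np.empty(L, dtype=np.uint8)
    for mask, sign in ((plus, 1.0), (~plus, -1.0)):
        p = np.array(
            [
                (1 - gc) / 2 * (1 - at_sk * sign),  # A
                gc / 2 * (1 - sk * sign),  # C
                gc / 2 * (1 + sk * sign),  # G
                (1 - gc) / 2 * (1 + at_sk * sign),  # T
            ]
        )
        p /= p.sum()
        seq[mask] = _BASES[rng.choice(4, size=int(mask.sum()), p=p)]

    # planted phage/GI regions: GC-poor but G/C- and A/T-balanced
    for r in regions or []:
        gc_r = max(gc - 0.15, 0.2)
        p = np.array([(1 - gc_r) / 2, gc_r / 2, gc_r / 2, (1 - gc_r) / 2])
        seq[r.start: r.end] = _BASES[rng.choice(4, size=r.end - r.start, p=p)]

    # DnaA boxes in the oriC gap, centred on the true origin
    motif = np.frombuffer(DNAA_MOTIFS[0].encode(), dtype=np.uint8)
    spacing = 12
    span = config.n_dnaa_boxes * (len(motif) + spacing)
    box_positions = []
    start0 = oric - span // 2
    for b in range(config.n_dnaa_boxes):
        s = start0 + b * (len(motif) + spacing)
        idx = (np.arange(s, s + len(motif))) % L
        seq[idx] = motif
        box_positions.append(int(s % L))
    return seq.tobytes().decode("ascii"), box_positions


# ---------------------------------------------------------------------------
# Planted phage / genomic-island regions
# ---------------------------------------------------------------------------

def _sample_distance(placement: str, size: int, rng: np.random.Generator) -> np.ndarray:
    if placement == "uniform":
        return rng.uniform(0, 1, size)
    if placement == "near_ter":
        return rng.beta(5.0, 1.5, size)
    return rng.beta(1.5, 5.0, size)  # near_ori


def simulate_regions(
    oric: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    strain: str,
) -> list[RegionAnnotation]:
    """Plant phage and GI intervals at normalized oriC distances drawn from
    the configured placement distributions.

    Per-strain region counts are Poisson around the configured means: strains
    genuinely differ in prophage load, and fixed totals would make the
    per-third counts artificially dependent. Intervals never wrap the linear
    coordinate origin (redrawn on wrap) so they stay representable in BED."""
    L = config.genome_length
    n_gi = config.n_gi_per_strain
    specs = [
        ("phage", "phaster", config.phage_placement,
         int(rng.poisson(config.n_phage_per_strain))),
        ("GI", "alienhunter", config.gi_placement, int(rng.poisson((n_gi + 1) / 2))),
        ("GI", "islandviewer", config.gi_placement, int(rng.poisson(n_gi / 2))),
    ]
    out: list[RegionAnnotation] = []
    lo, hi = config.region_length_range
    for rtype, source, placement, count in specs:
        placed = 0
        while placed < count:
            d = float(_sample_distance(placement, 1, rng)[0])
            side = 1 if rng.random() < 0.5 else -1
            length = int(rng.integers(lo, hi + 1))
            mid = (oric + side * d * (L / 2)) % L
            start = int(mid - length / 2)
            if start < 0 or start + length > L:
                continue  # avoid wrapping the coordinate origin
            # keep the oriC gap itself clean
            if min((mid - oric) % L, (oric - mid) % L) < length / 2 + 2000:
                continue
            out.append(
                RegionAnnotation(
                    start=start, end=start + length, region_type=rtype, source=source,
                    strain=strain,
                )
            )
            placed += 1
    out.sort(key=lambda r: r.start)
    return out


# ---------------------------------------------------------------------------
# Whole-cohort convenience + fixture writing
# ---------------------------------------------------------------------------

@dataclass
class CohortSimulation:
    config: SimulationConfig
    catalogs: dict[str, pd.DataFrame]
    pan: PanGenome
    truth: SimulationTruth
    sequences: dict[str, str] = field(default_factory=dict)

    def gene_records(self, strain: str) -> list[GeneRecord]:
        return [
            GeneRecord(
                gene_id=gid,
                strain=strain,
                start=int(s),
                end=int(e),
                strand=st,
                name=nm,
            )
            for gid, s, e, st, nm in zip(
                self.catalogs[strain]["gene_id"],
                self.catalogs[strain]["start"],
                self.catalogs[strain]["end"],
                self.catalogs[strain]["strand"],
                self.catalogs[strain]["name"],
            )
        ]


def simulate_cohort(config: SimulationConfig, with_sequences: bool = True) -> CohortSimulation:
    """Full cohort: pan-genome, planted regions and (optionally) sequences."""
    catalogs, pan, truth = simulate_pangenome(config)
    sim = CohortSimulation(config=config, catalogs=catalogs, pan=pan, truth=truth)
    seq_seeds = np.random.SeedSequence(config.seed + 1_000_003).spawn(config.n_strains)
    for i, strain in enumerate(pan.strains):
        rng = np.random.default_rng(seq_seeds[i])
        regions = simulate_regions(truth.true_oric[strain], config, rng, strain)
        truth.regions[strain] = regions
        if with_sequences:
            seq, boxes = simulate_sequence(
                catalogs[strain], truth.true_oric[strain], config, rng, regions
            )
            sim.sequences[strain] = seq
            truth.dnaa_positions[strain] = boxes
    return sim


def write_fixture_set(sim: CohortSimulation, outdir) -> dict:
    """Write FASTA + GFF3 per strain, the orthology TSV, per-source BEDs and
    the truth file; everything round-trips through the package's readers."""
    from pathlib import Path

    from . import io as pio
    from .pangenome import write_proteinortho

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"strains": {}, "proteinortho": str(outdir / "families.proteinortho.tsv")}
    write_proteinortho(manifest["proteinortho"], sim.pan)
    for strain in sim.pan.strains:
        entry = {}
        genes = sim.gene_records(strain)
        gff = outdir / f"{strain}.gff3"
        pio.write_gff3(gff, strain, genes)
        entry["gff3"] = str(gff)
        if strain in sim.sequences:
            fasta = outdir / f"{strain}.fasta"
            pio.write_fasta(fasta, strain, sim.sequences[strain])
            entry["fasta"] = str(fasta)
        manifest["strains"][strain] = entry
    by_source: dict[str, list[RegionAnnotation]] = {}
    for strain in sim.pan.strains:
        for r in sim.truth.regions[strain]:
            by_source.setdefault(r.source, []).append(r)
    manifest["beds"] = {}
    for source, regions in sorted(by_source.items()):
        bed = outdir / f"{source}.bed"
        pio.write_bed(bed, regions)
        manifest["beds"][source] = str(bed)
    truth_path = outdir / "truth.json"
    pio.write_truth(truth_path, sim.truth.to_dict())
    manifest["truth"] = str(truth_path)
    return manifest
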