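"""Parameter-recovery experiments on synthetic cohorts.

These drive the package's self-validation: simulate cohorts with known
positional structure, run the estimation pipeline, and measure how well the
planted parameters (conservation slope, oriC position, region placement) are
recovered. Cohort sizes default to 12 strains x 1,000 genes on 2 Mb
chromosomes — large enough for stable window statistics, small enough that a
full sweep runs in minutes on one core.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .oric import call_oric, called_oric
from .pangenome import ortholog_scores
from .positional import (
    ChromosomeFrame,
    fit_models,
    segment_analysis,
    thirds_region_analysis,
    window_series,
)
from .simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_pangenome,
    simulate_regions,
)

#: study-scale cohort used throughout the recovery experiments
COHORT_KWARGS = dict(
    n_strains=12, n_families=2000, genes_per_strain=1000, genome_length=2_000_000
)


def frames_from_pangenome(catalogs, pan, truth, regions: bool = False) -> list[ChromosomeFrame]:
    """Chromosome frames using the generator's true oriC (no sequences needed)."""
    frames = []
    for strain in pan.strains:
        cat = catalogs[strain]
        scores = ortholog_scores(pan, strain, list(cat["gene_id"]))
        frames.append(
            ChromosomeFrame(
                strain=strain,
                length=truth_length(cat),
                oric=truth.true_oric[strain],
                gene_ids=list(cat["gene_id"]),
                midpoints=((cat["start"] + cat["end"]) / 2).to_numpy(),
                scores=scores["ortholog_score"].to_numpy(dtype=float),
                regions=truth.regions.get(strain, []) if regions else [],
            )
        )
    return frames


def truth_length(catalog) -> int:
    # slots tile the genome evenly; last slot ends 0.2 slot before L
    slot = catalog["start"].iloc[1] - catalog["start"].iloc[0] if len(catalog) > 1 else 0
    return int(round((catalog["end"].iloc[-1] + 0.2 * slot)))


def slope_recovery_experiment(
    beta: float,
    n_seeds: int = 20,
    base_seed: int = 0,
    alpha: float = 0.05,
    window_size: int = 20,
    n_permutations: int = 499,
    cohort_kwargs: dict | None = None,
) -> dict:
    """Simulate ``n_seeds`` cohorts with conservation slope ``beta`` and fit
    every strain. Returns the fraction of strains whose fitted slope sign
    matches ``beta`` (for beta != 0), the fraction called significant, and the
    mean fitted slope."""
    kwargs = dict(COHORT_KWARGS, **(cohort_kwargs or {}))
    slopes, signs, sigs = [], [], []
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=base_seed * 1000 + i, positional_bias_beta=beta, **kwargs)
        catalogs, pan, truth = simulate_pangenome(cfg)
        frames = frames_from_pangenome(catalogs, pan, truth)
        for j, fr in enumerate(frames):
            series = window_series(fr, window_size=window_size)
            fit = fit_models(
                series, alpha=alpha, n_permutations=n_permutations,
                seed=base_seed * 100_000 + i * 100 + j,
            )
            slopes.append(fit.slope)
            sigs.append(fit.significant)
            if beta != 0:
                signs.append(np.sign(fit.slope) == np.sign(beta))
    return {
        "n_strains": len(slopes),
        "mean_slope": float(np.mean(slopes)),
        "sign_match_rate": float(np.mean(signs)) if signs else float("nan"),
        "significant_rate": float(np.mean(sigs)),
    }


def oric_recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    signal: bool = True,
    tolerance_frac: float = 0.01,
    genome_length: int = 2_000_000,
) -> dict:
    """Call oriC on simulated chromosomes and compare against the truth.

    With ``signal=True`` (skew 0.3, 6 DnaA boxes, parAB flanking), success is a
    call within ``tolerance_frac`` of the genome length; with ``signal=False``
    (no skew, no boxes) success is an ambiguous call."""
    n_hit = n_ambiguous = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_strains=2,
            n_families=1200,
            genes_per_strain=1000,
            genome_length=genome_length,
            skew_amplitude=0.3 if signal else 0.0,
            n_dnaa_boxes=6 if signal else 0,
            seed=base_seed * 1000 + 37 + i,
        )
        sim = simulate_cohort(cfg)
        strain = sim.pan.strains[0]
        candidates = call_oric(sim.sequences[strain], sim.gene_records(strain))
        pos = called_oric(candidates)
        if pos is None:
            n_ambiguous += 1
            continue
        truth_pos = sim.truth.true_oric[strain]
        err = min(abs(pos - truth_pos), genome_length - abs(pos - truth_pos))
        if err <= tolerance_frac * genome_length:
            n_hit += 1
    return {
        "n_seeds": n_seeds,
        "recovery_rate": n_hit / n_seeds,
        "ambiguous_rate": n_ambiguous / n_seeds,
    }


def segment_enrichment_experiment(
    beta: float, seed: int = 0, n_segments: int = 8, cohort_kwargs: dict | None = None
) -> dict:
    """Segment analysis of one cohort with strong positional clustering.

    Returns the segment with the maximal cohort-mean ortholog score and how
    many of the other segments Tukey HSD separates from segment 1 (for
    oriC-clustering) or from the top segment."""
    kwargs = dict(COHORT_KWARGS, **(cohort_kwargs or {}))
    cfg = SimulationConfig(seed=seed, positional_bias_beta=beta, **kwargs)
    catalogs, pan, truth = simulate_pangenome(cfg)
    frames = frames_from_pangenome(catalogs, pan, truth)
    table, anova_p, tukey = segment_analysis(frames, n_segments=n_segments)
    means = table.groupby("segment")["mean_score"].mean()
    top_segment = int(means.idxmax())
    n_separated = 0
    if len(tukey):
        for _, row in tukey.iterrows():
            g1, g2 = int(row["group1"]), int(row["group2"])
            if 1 in (g1, g2) and bool(row["reject"]):
                n_separated += 1
    return {
        "n_strains": kwargs["n_strains"],
        "top_segment": top_segment,
        "anova_p": float(anova_p),
        "segment1_tukey_separations": n_separated,
        "segment_means": means.to_dict(),
    }


def thirds_placement_experiment(
    placement: str,
    n_sims: int = 1,
    base_seed: int = 0,
    n_strains: int = 12,
    genome_length: int = 2_000_000,
    alpha: float = 0.05,
) -> dict:
    """Plant phage/GI regions with the given placement and test thirds
    enrichment. Over ``n_sims`` cohorts, reports how often the phage-count
    ANOVA is significant and (for the last cohort) whether third 3 is
    separated from both others by Tukey."""
    n_sig = 0
    third3_enriched = False
    for i in range(n_sims):
        rng_root = np.random.SeedSequence(base_seed * 10_000 + 71 + i)
        frames = []
        for j, child in enumerate(rng_root.spawn(n_strains)):
            rng = np.random.default_rng(child)
            cfg = SimulationConfig(
                n_strains=2,
                n_families=10,
                genes_per_strain=5,
                genome_length=genome_length,
                phage_placement=placement,
                gi_placement=placement,
            )
            oric = int(rng.integers(genome_length))
            regions = simulate_regions(oric, cfg, rng, strain=f"S{j:03d}")
            frames.append(
                ChromosomeFrame(
                    strain=f"S{j:03d}",
                    length=genome_length,
                    oric=oric,
                    gene_ids=["g0", "g1"],
                    midpoints=np.array([0.0, genome_length / 2]),
                    scores=np.array([1.0, 1.0]),
                    regions=regions,
                )
            )
        per_strain, tests = thirds_region_analysis(frames)
        phage = tests[(tests["source"] == "phaster") & (tests["measure"] == "n_regions")]
        anova_sig = len(phage) > 0 and float(phage["anova_p"].iloc[0]) < alpha
        if anova_sig:
            n_sig += 1
        sep = phage[phage["reject"].fillna(False).astype(bool)] if len(phage) else phage
        pairs = {
            (int(r["group1"]), int(r["group2"]))
            for _, r in sep.iterrows()
            if r["group1"] is not None
        }
        counts = per_strain[per_strain["source"] == "phaster"]
        by_third = counts.groupby("third")["n_regions"].mean()
        third3_max = len(by_third) == 3 and by_third.idxmax() == 3
        # enrichment toward terC: significant overall, third 3 carries the
        # maximal mean and Tukey separates it from the oriC-proximal third
        third3_enriched = anova_sig and third3_max and (1, 3) in pairs
    return {
        "n_sims": n_sims,
        "n_strains": n_strains,
        "significant_rate": n_sig / n_sims,
        "third3_enriched": third3_enriched,
    }
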