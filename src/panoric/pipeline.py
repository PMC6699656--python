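"""End-to-end pipeline: inputs (real or simulated) -> tables and a run report.

Stage order follows the analysis design: parse orthology -> classify families
-> call oriC per strain (ambiguous calls exclude a strain from positional
statistics but not from the pan-genome tallies) -> ortholog scores -> sliding
window fits -> cohort slope analysis -> segment analysis -> thirds phage/GI
analysis. Every output table carries its parameter provenance in ``#`` header
comments, and a fixed seed makes the whole run byte-identical.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .oric import OriCParams, call_oric, called_oric
from .pangenome import (
    classify_families,
    ortholog_scores,
    pangenome_summary,
    read_proteinortho,
)
from .positional import (
    ChromosomeFrame,
    fit_models,
    segment_analysis,
    slope_population_analysis,
    thirds_region_analysis,
    window_series,
)
from .simulate import SimulationConfig, simulate_cohort, write_fixture_set

logger = logging.getLogger("panoric")


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one of ``simulate`` /
    ``inputs`` must be given."""

    outdir: str = "panoric_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    fasta_dir: str | None = None
    gff_dir: str | None = None
    proteinortho: str | None = None
    beds: list[str] = field(default_factory=list)
    window_size: int = 20
    window_step: int = 1
    alpha: float = 0.05
    soft_core_fraction: float = 0.95
    connectivity_min: float = 0.9
    n_segments: int = 8
    n_permutations: int = 999
    oric_params: OriCParams = field(default_factory=OriCParams)
    make_plots: bool = False

    def __post_init__(self) -> None:
        has_real = self.proteinortho is not None
        if self.simulate is not None and has_real:
            raise ValueError("configure either real inputs or simulate, not both")
        if self.simulate is None and not has_real:
            raise ValueError("no inputs: set either real input paths or a simulate block")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulate", None)
        inputs = d.pop("inputs", {}) or {}
        params = d.pop("parameters", {}) or {}
        oric_kwargs = {}
        for key in ("min_boxes", "step", "window", "ambiguity_margin", "flatness_factor"):
            if key in params:
                oric_kwargs[key] = params.pop(key)
        return cls(
            simulate=SimulationConfig(**sim) if sim is not None else None,
            fasta_dir=inputs.get("fasta_dir"),
            gff_dir=inputs.get("gff_dir"),
            proteinortho=inputs.get("proteinortho"),
            beds=list(inputs.get("beds", [])),
            oric_params=OriCParams(**oric_kwargs),
            **params,
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _write_table(df: pd.DataFrame, path: Path, provenance: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# panoric {__version__}\n")
        for k, v in provenance.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the report manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    root = logging.getLogger("panoric")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {"version": __version__, "seed": config.seed, "tables": {}}
    prov = {
        "seed": config.seed,
        "window_size": config.window_size,
        "alpha": config.alpha,
        "soft_core_fraction": config.soft_core_fraction,
        "connectivity_min": config.connectivity_min,
        "n_segments": config.n_segments,
    }
    try:
        # -------------------------------------------------- inputs
        if config.simulate is not None:
            stage = "simulate"
            logger.info("simulating cohort: %s", config.simulate)
            sim_cfg = config.simulate
            if sim_cfg.seed != config.seed:
                sim_cfg = replace(sim_cfg, seed=config.seed)
            sim = simulate_cohort(sim_cfg)
            inputs = write_fixture_set(sim, outdir / "inputs")
            proteinortho_path = inputs["proteinortho"]
            strain_files = inputs["strains"]
            bed_paths = list(inputs["beds"].values())
            manifest["inputs"] = inputs
        else:
            stage = "collect-inputs"
            proteinortho_path = config.proteinortho
            fasta_dir = Path(config.fasta_dir) if config.fasta_dir else None
            gff_dir = Path(config.gff_dir) if config.gff_dir else None
            strain_files = {}
            if fasta_dir and gff_dir:
                for fasta in sorted(fasta_dir.glob("*.fasta")):
                    strain = fasta.stem
                    gff = gff_dir / f"{strain}.gff3"
                    if gff.exists():
                        strain_files[strain] = {"fasta": str(fasta), "gff3": str(gff)}
            bed_paths = list(config.beds)

        # -------------------------------------------------- pan-genome
        stage = "pangenome"
        pan = read_proteinortho(proteinortho_path)
        classification, thr = classify_families(
            pan, config.soft_core_fraction, config.connectivity_min
        )
        _write_table(classification, outdir / "classification.tsv", prov)
        summary = pangenome_summary(classification)
        summary.insert(0, "n_strains", pan.n_strains)
        summary.insert(1, "soft_core_threshold", thr)
        _write_table(summary, outdir / "pangenome_summary.tsv", prov)
        manifest["tables"]["classification"] = str(outdir / "classification.tsv")
        manifest["tables"]["pangenome_summary"] = str(outdir / "pangenome_summary.tsv")

        # -------------------------------------------------- oriC per strain
        stage = "oric"
        regions_by_strain: dict[str, list] = {}
        for bed in bed_paths:
            for r in pio.read_bed(bed):
                regions_by_strain.setdefault(r.strain, []).append(r)
        oric_rows = []
        frames: list[ChromosomeFrame] = []
        ambiguous_strains, called_strains = [], []
        for strain, files in sorted(strain_files.items()):
            if "fasta" not in files:
                continue
            sid, seq = pio.read_fasta(files["fasta"])
            genes = pio.read_gff3(files["gff3"], strain=strain)
            candidates = call_oric(seq, genes, config.oric_params)
            for rank, c in enumerate(candidates[:5]):
                oric_rows.append(
                    {
                        "strain": strain, "rank": rank, "status": c.status,
                        "position": c.position, "start": c.start, "end": c.end,
                        "dnaa_box_count": c.dnaa_box_count,
                        "max_mismatch_used": c.max_mismatch_used,
                        "dist_to_disparity_extremum": c.dist_to_disparity_extremum,
                        "local_gc_excess": round(c.local_gc_excess, 6),
                        "dist_to_parAB": c.dist_to_parAB,
                        "composite_score": round(c.composite_score, 6),
                    }
                )
            pos = called_oric(candidates)
            if pos is None:
                ambiguous_strains.append(strain)
                logger.info("oriC ambiguous for %s; excluded from positional stats", strain)
                continue
            called_strains.append(strain)
            scores = ortholog_scores(pan, strain, [g.gene_id for g in genes])
            score_map = dict(zip(scores["gene_id"], scores["ortholog_score"]))
            frames.append(
                ChromosomeFrame(
                    strain=strain,
                    length=len(seq),
                    oric=pos,
                    gene_ids=[g.gene_id for g in genes],
                    midpoints=np.array([g.midpoint for g in genes]),
                    scores=np.array([score_map[g.gene_id] for g in genes], dtype=float),
                    regions=regions_by_strain.get(strain, []),
                )
            )
        oric_cols = [
            "strain", "rank", "status", "position", "start", "end", "dnaa_box_count",
            "max_mismatch_used", "dist_to_disparity_extremum", "local_gc_excess",
            "dist_to_parAB", "composite_score",
        ]
        _write_table(pd.DataFrame(oric_rows, columns=oric_cols), outdir / "oric_calls.tsv", prov)
        manifest["tables"]["oric_calls"] = str(outdir / "oric_calls.tsv")

        # -------------------------------------------------- window fits
        stage = "window-fits"
        fits = {}
        fit_rows = []
        for i, fr in enumerate(frames):
            series = window_series(fr, config.window_size, config.window_step)
            fit = fit_models(
                series,
                alpha=config.alpha,
                n_permutations=config.n_permutations,
                seed=config.seed + 7919 * (i + 1),
            )
            fits[fr.strain] = fit
            fit_rows.append(
                {
                    "strain": fr.strain, "n_windows": fit.n_windows,
                    "slope": round(fit.slope, 6), "intercept": round(fit.intercept, 6),
                    "p_value": fit.p_value, "p_value_ols": fit.p_value_ols,
                    "r_squared": round(fit.r_squared, 6),
                    "quadratic_better": fit.quadratic_better,
                    "significant": fit.significant,
                }
            )
        fit_cols = [
            "strain", "n_windows", "slope", "intercept", "p_value", "p_value_ols",
            "r_squared", "quadratic_better", "significant",
        ]
        _write_table(pd.DataFrame(fit_rows, columns=fit_cols), outdir / "window_fits.tsv", prov)
        manifest["tables"]["window_fits"] = str(outdir / "window_fits.tsv")

        # -------------------------------------------------- cohort slope analysis
        stage = "slope-population"
        if len(fits) >= 2:
            qq, slope_summary = slope_population_analysis(fits, alpha=config.alpha)
            _write_table(qq, outdir / "slope_qq.tsv", prov)
            manifest["tables"]["slope_qq"] = str(outdir / "slope_qq.tsv")
            manifest["slope_summary"] = slope_summary
        else:
            manifest["slope_summary"] = {
                "n_strains": len(fits),
                "n_significant_negative": 0,
                "n_significant_positive": 0,
            }

        # -------------------------------------------------- segments
        stage = "segments"
        if frames:
            seg_table, seg_anova_p, seg_tukey = segment_analysis(frames, config.n_segments)
            _write_table(seg_table, outdir / "segments.tsv", prov)
            _write_table(seg_tukey, outdir / "segment_tukey.tsv", prov)
            manifest["tables"]["segments"] = str(outdir / "segments.tsv")
            manifest["tables"]["segment_tukey"] = str(outdir / "segment_tukey.tsv")
            manifest["segment_anova_p"] = seg_anova_p

        # -------------------------------------------------- thirds
        stage = "thirds"
        if frames and any(fr.regions for fr in frames):
            thirds, thirds_tests = thirds_region_analysis(frames)
            _write_table(thirds, outdir / "thirds.tsv", prov)
            _write_table(thirds_tests, outdir / "thirds_tests.tsv", prov)
            manifest["tables"]["thirds"] = str(outdir / "thirds.tsv")
            manifest["tables"]["thirds_tests"] = str(outdir / "thirds_tests.tsv")

        # -------------------------------------------------- summary + manifest
        stage = "summary"
        manifest["strains"] = {
            "total": len(strain_files) or pan.n_strains,
            "oric_called": len(called_strains),
            "oric_ambiguous": len(ambiguous_strains),
            "ambiguous_strains": ambiguous_strains,
        }
        cohort = summarize_cohort(manifest)
        _write_table(cohort, outdir / "cohort_summary.tsv", prov)
        manifest["tables"]["cohort_summary"] = str(outdir / "cohort_summary.tsv")

        if config.make_plots:
            stage = "plots"
            from . import plotting

            manifest["plots"] = plotting.make_report_plots(outdir, frames, fits, config)

        manifest["platform"] = {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        logger.info("pipeline complete: %d strains called, %d ambiguous",
                    len(called_strains), len(ambiguous_strains))
    except Exception as exc:  # annotate the failing stage, as promised
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return manifest


def summarize_cohort(manifest: dict) -> pd.DataFrame:
    """Headline cohort counts: strains with a called vs ambiguous oriC and
    strains with significantly negative / positive conservation slopes."""
    strains = manifest.get("strains", {})
    slopes = manifest.get("slope_summary", {})
    called = int(strains.get("oric_called", 0))
    sig_neg = int(slopes.get("n_significant_negative", 0))
    sig_pos = int(slopes.get("n_significant_positive", 0))
    return pd.DataFrame(
        [
            {
                "n_strains_total": int(strains.get("total", 0)),
                "oric_called": called,
                "oric_ambiguous": int(strains.get("oric_ambiguous", 0)),
                "significant_negative_slope": sig_neg,
                "significant_positive_slope": sig_pos,
                "non_significant_slope": called - sig_neg - sig_pos,
            }
        ]
    )
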