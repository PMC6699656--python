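"""Positional statistics along the oriC-terC replication axis.

Positions on a circular chromosome are summarised by their circular distance
to oriC, normalised by the half-genome length so a relative distance of 0 is
oriC and 1 is terC. The conservation profile is the mean ortholog score in
sliding windows of (by default) 20 genes, regressed on the window's relative
distance; per-strain slopes are compared across a cohort (sign counts, QQ
against a fitted normal). Chromosome-level contrasts use eight equal segments
(segment 1 centred on oriC, numbering clockwise) and, for prophage/genomic
island calls, three distance bins ("thirds"), with one-way ANOVA and Tukey HSD
across per-strain summaries.

Significance of a single strain's slope uses a gene-level permutation test:
under the null of no positional structure, ortholog scores are exchangeable
across gene positions, so permuting scores and recomputing the window-mean
slope gives an exact reference distribution. Naive OLS p-values on overlapping
window means are anti-conservative (window means are strongly autocorrelated)
and are reported only descriptively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import RegionAnnotation

THIRD_BINS = (1 / 3, 2 / 3)  # normalized-distance breaks between chromosome thirds


# ---------------------------------------------------------------------------
# Circular geometry
# ---------------------------------------------------------------------------

def circular_distance(
    position: float, oric: float, length: float
) -> tuple[float, float, str]:
    """Circular distance from ``position`` to ``oric`` on a chromosome of
    ``length`` bp.

    Returns ``(distance_bp, normalized, replichore)`` where ``normalized`` is
    the distance divided by half the genome (0 at oriC, 1 at terC) and
    ``replichore`` is ``"right"`` for the clockwise arc from oriC (increasing
    coordinates) and ``"left"`` otherwise.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    offset = (position - oric) % length
    dist = min(offset, length - offset)
    replichore = "right" if offset <= length / 2 else "left"
    return dist, dist / (length / 2), replichore


@dataclass
class ChromosomeFrame:
    """Everything positional about one strain's chromosome."""

    strain: str
    length: int
    oric: int
    gene_ids: list[str]
    midpoints: np.ndarray  # bp, sorted ascending
    scores: np.ndarray  # ortholog score per gene, same order
    regions: list[RegionAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.midpoints) != len(self.scores):
            raise ValueError("midpoints and scores differ in length")
        order = np.argsort(self.midpoints, kind="stable")
        self.midpoints = self.midpoints[order]
        self.scores = self.scores[order]
        self.gene_ids = [self.gene_ids[i] for i in order]
        if not (0 <= self.oric < self.length):
            raise ValueError("oric outside [0, length)")

    @property
    def n_genes(self) -> int:
        return len(self.scores)

    def normalized_distances(self) -> np.ndarray:
        offset = (self.midpoints - self.oric) % self.length
        dist = np.minimum(offset, self.length - offset)
        return dist / (self.length / 2)


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

@dataclass
class WindowSeries:
    """Mean ortholog score and oriC distance for circular sliding gene windows."""

    mean_score: np.ndarray
    midpoint_distance: np.ndarray  # normalized distance of the window's middle gene
    window_size: int
    step: int
    # gene-level payload enabling the permutation slope test
    gene_scores: np.ndarray | None = None
    gene_distances: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return len(self.mean_score)


def window_series(frame: ChromosomeFrame, window_size: int = 20, step: int = 1) -> WindowSeries:
    """Circular sliding windows of ``window_size`` genes advancing by ``step``."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = frame.n_genes
    if n < window_size:
        raise ValueError(f"need >= {window_size} genes, have {n}")
    d = frame.normalized_distances()
    starts = np.arange(0, n, step)
    idx = (starts[:, None] + np.arange(window_size)[None, :]) % n
    means = frame.scores[idx].mean(axis=1)
    mid_idx = idx[:, window_size // 2]  # the window's middle gene
    return WindowSeries(
        mean_score=means,
        midpoint_distance=d[mid_idx],
        window_size=window_size,
        step=step,
        gene_scores=frame.scores.copy(),
        gene_distances=d,
    )


# ---------------------------------------------------------------------------
# Linear / quadratic fits
# ---------------------------------------------------------------------------

@dataclass
class SlopeFit:
    """OLS fit of window mean score on normalized oriC distance."""

    slope: float
    intercept: float
    p_value: float  # permutation p if gene-level data available, else OLS p
    p_value_ols: float
    r_squared: float
    quadratic: tuple[float, float, float]  # c + b*d + a*d^2 -> (a, b, c)
    quadratic_better: bool  # lower AIC than the linear model
    significant: bool
    alpha: float
    n_windows: int


def fit_models(
    series: WindowSeries,
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int = 0,
) -> SlopeFit:
    """Fit linear and quadratic models of mean window score vs distance.

    The slope's two-sided significance is assessed by permuting gene scores
    across positions (exact under exchangeability) when the series carries its
    gene-level payload; otherwise the OLS p-value is used.
    """
    y = np.asarray(series.mean_score, dtype=float)
    x = np.asarray(series.midpoint_distance, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 windows")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in window distances")
    X1 = sm.add_constant(x)
    lin = sm.OLS(y, X1).fit()
    slope, intercept = float(lin.params[1]), float(lin.params[0])
    p_ols = float(lin.pvalues[1])
    X2 = sm.add_constant(np.column_stack([x, x**2]))
    quad = sm.OLS(y, X2).fit()

    if series.gene_scores is not None and series.gene_distances is not None:
        p_val = _permutation_slope_p(series, slope, n_permutations, seed)
    else:
        p_val = p_ols
    return SlopeFit(
        slope=slope,
        intercept=intercept,
        p_value=p_val,
        p_value_ols=p_ols,
        r_squared=float(lin.rsquared),
        quadratic=(float(quad.params[2]), float(quad.params[1]), float(quad.params[0])),
        # require a clear AIC advantage (>2); a perfect linear fit can't be beaten
        quadratic_better=bool(
            lin.aic - quad.aic > 2.0 and lin.ssr > 1e-12 * max(1.0, float(y @ y))
        ),
        significant=bool(p_val < alpha),
        alpha=alpha,
        n_windows=len(y),
    )


def _permutation_slope_p(
    series: WindowSeries, observed_slope: float, n_permutations: int, seed: int
) -> float:
    """Permute gene scores over positions and recompute the window-mean slope.

    The window-mean slope is linear in the gene scores: slope = v . s with a
    fixed weight vector v (OLS hat weights pushed through the window-averaging
    operator), so each permutation costs one dot product.
    """
    s = series.gene_scores
    n = len(s)
    w, step = series.window_size, series.step
    x = series.midpoint_distance
    xc = x - x.mean()
    a = xc / float(xc @ xc)  # OLS weights: slope = a . window_means
    # push through window averaging: v[j] = sum over windows containing j of a_w / w
    v = np.zeros(n)
    starts = np.arange(0, n, step)
    for k in range(w):
        np.add.at(v, (starts + k) % n, a / w)
    rng = np.random.default_rng(seed)
    perm = np.empty(n_permutations)
    sp = s.copy()
    for b in range(n_permutations):
        rng.shuffle(sp)
        perm[b] = v @ sp
    more_extreme = int(np.sum(np.abs(perm) >= abs(observed_slope) - 1e-12))
    return (1 + more_extreme) / (n_permutations + 1)


# ---------------------------------------------------------------------------
# Cohort-level slope analysis
# ---------------------------------------------------------------------------

def slope_population_analysis(
    fits: dict[str, SlopeFit], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """QQ table of per-strain slopes against a fitted normal, plus sign counts.

    Returns ``(qq_table, summary)``. The QQ table pairs sorted observed slopes
    with theoretical quantiles of Normal(mean, sd) of the observed slopes
    (Blom plotting positions). ``summary`` carries counts of strains with
    negative / positive and significantly negative / positive slopes, and a
    Kolmogorov-Smirnov normality check (conservative, parameters estimated).
    """
    if len(fits) < 2:
        raise ValueError("need fits for at least 2 strains")
    strains = sorted(fits)
    slopes = np.array([fits[s].slope for s in strains])
    order = np.argsort(slopes, kind="stable")
    mean, sd = float(slopes.mean()), float(slopes.std(ddof=1))
    n = len(slopes)
    pp = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    degenerate = sd == 0
    theo = np.full(n, mean) if degenerate else stats.norm.ppf(pp, loc=mean, scale=sd)
    qq = pd.DataFrame(
        {
            "strain": [strains[i] for i in order],
            "observed_slope": slopes[order],
            "theoretical_quantile": theo,
            "significant": [fits[strains[i]].significant for i in order],
        }
    )
    if degenerate:
        ks_stat, within_band = float("nan"), False
    else:
        ks_stat = float(stats.kstest(slopes, "norm", args=(mean, sd)).statistic)
        within_band = ks_stat < 1.358 / np.sqrt(n)  # 5% simultaneous KS band
    summary = {
        "n_strains": n,
        "mean_slope": mean,
        "sd_slope": sd,
        "n_negative": int(np.sum(slopes < 0)),
        "n_positive": int(np.sum(slopes > 0)),
        "n_significant_negative": int(
            sum(1 for s in strains if fits[s].significant and fits[s].slope < 0)
        ),
        "n_significant_positive": int(
            sum(1 for s in strains if fits[s].significant and fits[s].slope > 0)
        ),
        "degenerate": bool(degenerate),
        "ks_statistic": ks_stat,
        "normal_within_ks_band": bool(within_band),
    }
    return qq, summary


# ---------------------------------------------------------------------------
# Eight-segment analysis
# ---------------------------------------------------------------------------

def _anova_p(groups: list[np.ndarray]) -> float:
    """One-way ANOVA p-value; degenerate all-equal data counts as no signal."""
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0
    return float(stats.f_oneway(*groups).pvalue)


def segment_index(
    position: float, oric: float, length: float, n_segments: int = 8, centered: bool = True
) -> int:
    """1-based segment of a position; segment 1 surrounds oriC (boundaries at
    oric +/- L/(2*n_segments)) and numbering proceeds clockwise. With
    ``centered=False`` segment 1 instead starts exactly at oriC."""
    seg_len = length / n_segments
    shift = seg_len / 2 if centered else 0.0
    return int(((position - oric + shift) % length) // seg_len) + 1


def segment_analysis(
    frames: list[ChromosomeFrame],
    n_segments: int = 8,
    centered: bool = True,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Mean/SD ortholog score in equal chromosome segments, ANOVA and Tukey HSD.

    Per-strain segment means are the replicate unit (per-gene pooling would
    pseudo-replicate). Returns ``(segment_table, anova_p, tukey_table)``.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if not frames:
        raise ValueError("no chromosome frames")
    rows = []
    for fr in frames:
        segs = np.array(
            [segment_index(m, fr.oric, fr.length, n_segments, centered) for m in fr.midpoints]
        )
        for k in range(1, n_segments + 1):
            mask = segs == k
            rows.append(
                {
                    "strain": fr.strain,
                    "segment": k,
                    "mean_score": float(fr.scores[mask].mean()) if mask.any() else np.nan,
                    "sd_score": float(fr.scores[mask].std(ddof=0)) if mask.any() else np.nan,
                    "n_genes": int(mask.sum()),
                }
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_score"])
    groups = [g["mean_score"].to_numpy() for _, g in valid.groupby("segment")]
    if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
        anova_p = _anova_p(groups)
        if np.ptp(valid["mean_score"].to_numpy()) > 0:
            tk = pairwise_tukeyhsd(
                valid["mean_score"].to_numpy(), valid["segment"].to_numpy(), alpha=0.05
            )
            tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        else:
            tukey = pd.DataFrame()
    else:
        anova_p = float("nan")
        tukey = pd.DataFrame()
    return table, anova_p, tukey


# ---------------------------------------------------------------------------
# Chromosome-thirds phage / genomic-island analysis
# ---------------------------------------------------------------------------

def region_third(region: RegionAnnotation, oric: float, length: float) -> int:
    """Assign a region to a chromosome third (1..3, increasing oriC distance)
    by the normalized distance of its midpoint."""
    _, d, _ = circular_distance(region.midpoint % length, oric, length)
    if d <= THIRD_BINS[0]:
        return 1
    if d <= THIRD_BINS[1]:
        return 2
    return 3


def thirds_region_analysis(
    frames: list[ChromosomeFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and DNA proportion of phage/GI regions in chromosome thirds.

    Each third bundles the two arcs at the same normalized distance band on
    both replichores (each third covers L/3 bp in total). Returns
    ``(per_strain_table, test_table)`` where the test table holds a one-way
    ANOVA p and Tukey HSD pairs across thirds, separately per source tool.
    """
    sources = sorted({r.source for fr in frames for r in fr.regions})
    rows = []
    for fr in frames:
        for src in sources:
            counts = {1: 0, 2: 0, 3: 0}
            bp = {1: 0.0, 2: 0.0, 3: 0.0}
            for r in fr.regions:
                if r.source != src:
                    continue
                if not 0 < r.length <= fr.length:
                    raise ValueError(
                        f"region {r.start}-{r.end} invalid on {fr.strain} (L={fr.length})"
                    )
                t = region_third(r, fr.oric, fr.length)
                counts[t] += 1
                bp[t] += r.length
            for t in (1, 2, 3):
                rows.append(
                    {
                        "strain": fr.strain,
                        "source": src,
                        "third": t,
                        "n_regions": counts[t],
                        "dna_proportion": bp[t] / (fr.length / 3),
                    }
                )
    per_strain = pd.DataFrame(rows)
    tests = []
    for src in sources:
        sub = per_strain[per_strain["source"] == src]
        for measure in ("n_regions", "dna_proportion"):
            groups = [g[measure].to_numpy(dtype=float) for _, g in sub.groupby("third")]
            if len(groups) == 3 and all(len(g) >= 2 for g in groups):
                anova_p = _anova_p(groups)
                if np.ptp(np.concatenate(groups)) == 0:
                    tests.append(
                        {
                            "source": src, "measure": measure, "anova_p": anova_p,
                            "group1": None, "group2": None, "meandiff": 0.0,
                            "p_adj": 1.0, "reject": False,
                        }
                    )
                    continue
                tk = pairwise_tukeyhsd(
                    sub[measure].to_numpy(dtype=float), sub["third"].to_numpy(), alpha=0.05
                )
                tdf = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
                for _, trow in tdf.iterrows():
                    tests.append(
                        {
                            "source": src,
                            "measure": measure,
                            "anova_p": anova_p,
                            "group1": trow["group1"],
                            "group2": trow["group2"],
                            "meandiff": float(trow["meandiff"]),
                            "p_adj": float(trow["p-adj"]),
                            "reject": bool(trow["reject"]),
                        }
                    )
    return per_strain, pd.DataFrame(tests)
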