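"""Origin-of-replication calling on circular bacterial chromosomes.

Replication-associated mutational asymmetry leaves a strand-compositional
footprint: the cumulative G-C disparity along one strand has extrema at oriC
and terC. The caller combines four signals, mirroring the curation criteria
commonly applied to Ori-Finder output:

1. proximity to the cumulative G-C disparity extremum,
2. location within a local GC-content minimum,
3. density of DnaA boxes (9-mers, up to 1-2 mismatches) in intergenic regions,
4. proximity to the chromosome-partitioning genes parA/parB.

Candidate origins are intergenic regions carrying a minimum number of DnaA
boxes, ranked by a weighted composite of the normalized criteria. The cumulative
curve is linearly detrended so that extremum locations are exactly equivariant
under rotation of the (arbitrary) linear coordinate origin, and the extremum
type (min vs max) is selected automatically so the call is invariant to
assembly orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneRecord

#: DnaA box 9-mers: the E. coli perfect box and two alternatives.
DNAA_MOTIFS = ("TTATCCACA", "TGTTTCACG", "TGTGGATAT")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Disparity curves
# ---------------------------------------------------------------------------

@dataclass
class DisparityCurve:
    """Cumulative nucleotide-disparity and windowed GC profiles of one chromosome."""

    positions: np.ndarray  # bp grid (0, step, ..., L-step)
    cumulative_gc: np.ndarray  # running sum of (G - C) up to each grid position
    cumulative_at: np.ndarray  # running sum of (A - T)
    window_gc: np.ndarray  # GC fraction in circular windows centred on grid points
    step: int
    window: int
    length: int
    gc_min_position: int  # extrema of the detrended cumulative (G - C)
    gc_max_position: int
    gc_disparity_range: float  # detrended max - min
    flat: bool  # True when the curve is indistinguishable from noise
    mean_gc: float

    def detrended_gc(self) -> np.ndarray:
        total = self.cumulative_gc[-1] + 0.0
        # extend trend to the full circle so the endpoint matches the total sum
        return self.cumulative_gc - self.positions * (total / max(self.length - self.step, 1))


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)


def disparity_curves(
    sequence: str,
    step: int = 100,
    window: int = 1000,
    flatness_factor: float = 5.0,
) -> DisparityCurve:
    """Compute cumulative (G-C) and (A-T) disparity plus windowed GC content.

    The sequence is treated as circular; windows wrap. ``flat`` is set when the
    detrended cumulative (G-C) range does not exceed ``flatness_factor`` times
    the range expected from an unskewed random sequence of the same base
    composition (Brownian-bridge scale, ``sigma * sqrt(L)``).
    """
    L = len(sequence)
    if window > L:
        raise ValueError(f"window ({window}) exceeds sequence length ({L})")
    if step < 1 or step > L:
        raise ValueError(f"step must be in [1, {L}]")
    arr = _encode(sequence)
    is_g = arr == ord("G")
    is_c = arr == ord("C")
    is_a = arr == ord("A")
    is_t = arr == ord("T")

    gc_step = (is_g.astype(np.int64) - is_c.astype(np.int64)).cumsum()
    at_step = (is_a.astype(np.int64) - is_t.astype(np.int64)).cumsum()
    positions = np.arange(0, L - (L % step) if L % step else L, step, dtype=np.int64)
    # cumulative sum of bases strictly before each grid position (starts at 0)
    cum_gc = np.concatenate([[0], gc_step[positions[1:] - 1]]).astype(float)
    cum_at = np.concatenate([[0], at_step[positions[1:] - 1]]).astype(float)

    # circular windowed GC fraction centred on each grid point
    gc01 = (is_g | is_c).astype(np.float64)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(np.concatenate([gc01, gc01]))])
    starts = (positions - half) % L
    window_gc = (csum[starts + window] - csum[starts]) / window

    total = gc_step[-1]
    detrended = cum_gc - positions * (total / L)
    rng_val = float(detrended.max() - detrended.min())
    p_gc = float(gc01.mean())
    sigma = np.sqrt(max(p_gc - (total / L) ** 2, 1e-12))
    flat = rng_val <= flatness_factor * sigma * np.sqrt(L)
    return DisparityCurve(
        positions=positions,
        cumulative_gc=cum_gc,
        cumulative_at=cum_at,
        window_gc=window_gc,
        step=step,
        window=window,
        length=L,
        gc_min_position=int(positions[int(np.argmin(detrended))]),
        gc_max_position=int(positions[int(np.argmax(detrended))]),
        gc_disparity_range=rng_val,
        flat=bool(flat),
        mean_gc=p_gc,
    )


# ---------------------------------------------------------------------------
# DnaA box scan
# ---------------------------------------------------------------------------

def find_dnaa_boxes(
    sequence: str,
    motifs: tuple[str, ...] = DNAA_MOTIFS,
    max_mismatch: int = 1,
) -> list[tuple[int, str, str, int]]:
    """All circular positions (both strands) within Hamming distance
    ``max_mismatch`` of any motif.

    Returns ``(position, strand, motif, mismatches)`` tuples where ``position``
    is the 0-based start of the site on the forward strand and each hit reports
    its best-matching motif. ``N`` bases mismatch every motif.
    """
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    for m in motifs:
        if len(m) != 9 or set(m) - set("ACGT"):
            raise ValueError(f"motif {m!r} must be a 9-mer over ACGT")
    L = len(sequence)
    if L < 9:
        return []
    arr = _encode(sequence + sequence[:8])  # circular extension
    k = 9
    best_mm = np.full((L, 2), k + 1, dtype=np.int8)  # per strand
    best_motif = np.zeros((L, 2), dtype=np.int8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)[:L]
    for mi, motif in enumerate(motifs):
        for si, m in enumerate((motif, revcomp(motif))):
            mm = (windows != _encode(m)).sum(axis=1).astype(np.int8)
            better = mm < best_mm[:, si]
            best_mm[better, si] = mm[better]
            best_motif[better, si] = mi
    hits = []
    for si, strand in enumerate("+-"):
        pos = np.nonzero(best_mm[:, si] <= max_mismatch)[0]
        for p in pos:
            hits.append((int(p), strand, motifs[best_motif[p, si]], int(best_mm[p, si])))
    hits.sort()
    return hits


# ---------------------------------------------------------------------------
# oriC calling
# ---------------------------------------------------------------------------

@dataclass
class OriCParams:
    """Knobs of the origin caller; weights follow the curation criteria order."""

    step: int = 100
    window: int = 1000
    min_boxes: int = 3
    mismatch_passes: tuple[int, ...] = (1, 2)  # retry with 2 if pass 1 finds nothing
    ambiguity_margin: float = 0.10  # runner-up within this fraction of top score
    flatness_factor: float = 5.0
    motifs: tuple[str, ...] = DNAA_MOTIFS
    weights: dict = field(
        default_factory=lambda: {"boxes": 0.40, "disparity": 0.30, "local_gc": 0.15, "parab": 0.15}
    )


@dataclass
class OriCCandidate:
    """A candidate origin (an intergenic interval) with its per-criterion scores."""

    start: int
    end: int
    position: int  # interval midpoint, bp
    dnaa_box_count: int
    max_mismatch_used: int
    dist_to_disparity_extremum: int
    local_gc_excess: float  # window GC minus genome mean (negative = GC-poor)
    dist_to_parAB: int | None
    composite_score: float = 0.0
    status: str = "alternative"  # called | alternative | ambiguous


def _circ_dist(a: int, b: int, L: int) -> int:
    d = abs(a - b) % L
    return min(d, L - d)


def intergenic_regions(genes: list[GeneRecord], length: int) -> list[tuple[int, int]]:
    """Circular complement of the (merged) gene intervals; (start, end) pairs
    where end may exceed ``length`` for the interval wrapping the origin."""
    if not genes:
        raise ValueError("no genes; cannot derive intergenic regions")
    iv = sorted((g.start % length, g.start % length + (g.end - g.start)) for g in genes)
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if s2 > e1:
            gaps.append((e1, s2))
    # wrap-around gap between the last gene end and the first gene start
    last_end = merged[-1][1]
    first_start = merged[0][0]
    if last_end < length + first_start and (length - last_end) + first_start > 0:
        if last_end < length or first_start > last_end - length:
            gaps.append((last_end, length + first_start))
    if not gaps:
        raise ValueError("gene annotation leaves no intergenic regions")
    return gaps


def call_oric(
    sequence: str,
    genes: list[GeneRecord],
    params: OriCParams | None = None,
) -> list[OriCCandidate]:
    """Rank intergenic regions as origin candidates; top gets status ``called``
    unless the signal is ambiguous (flat disparity curve, no region reaching
    ``min_boxes`` DnaA hits, or a runner-up within the ambiguity margin)."""
    params = params or OriCParams()
    L = len(sequence)
    curve = disparity_curves(sequence, params.step, params.window, params.flatness_factor)
    gaps = intergenic_regions(genes, L)

    hits, mm_used, reached_min = [], params.mismatch_passes[-1], False
    for mm in params.mismatch_passes:
        hits = find_dnaa_boxes(sequence, params.motifs, mm)
        counts = _count_hits_in_gaps(hits, gaps, L)
        if counts.max(initial=0) >= params.min_boxes:
            mm_used, reached_min = mm, True
            break
    counts = _count_hits_in_gaps(hits, gaps, L)

    if reached_min:
        cand_idx = [i for i, c in enumerate(counts) if c >= params.min_boxes]
    else:  # fall back to every gap with at least one hit, else all gaps
        cand_idx = [i for i, c in enumerate(counts) if c >= 1] or list(range(len(gaps)))

    par_genes = [
        g for g in genes if g.name and g.name.lower().startswith(("para", "parb"))
    ]
    have_par = len(par_genes) > 0
    weights = dict(params.weights)
    if not have_par:
        weights.pop("parab")
        total_w = sum(weights.values())
        weights = {k: v / total_w for k, v in weights.items()}

    detr = curve.detrended_gc()
    candidates = []
    for i in cand_idx:
        s, e = gaps[i]
        mid = ((s + e) // 2) % L
        # assembly orientation is arbitrary: score against the closer extremum type
        d_min = _circ_dist(mid, curve.gc_min_position, L)
        d_max = _circ_dist(mid, curve.gc_max_position, L)
        gi = int(round(mid / params.step)) % len(curve.window_gc)
        candidates.append(
            OriCCandidate(
                start=s % L,
                end=e,
                position=mid,
                dnaa_box_count=int(counts[i]),
                max_mismatch_used=mm_used,
                dist_to_disparity_extremum=min(d_min, d_max),
                local_gc_excess=float(curve.window_gc[gi] - curve.mean_gc),
                dist_to_parAB=(
                    min(_circ_dist(int(g.midpoint), mid, L) for g in par_genes)
                    if have_par
                    else None
                ),
            )
        )

    # pick one extremum type: the one closer to the box-richest candidate
    best_box = max(candidates, key=lambda c: c.dnaa_box_count)
    use_min = _circ_dist(best_box.position, curve.gc_min_position, L) <= _circ_dist(
        best_box.position, curve.gc_max_position, L
    )
    extremum = curve.gc_min_position if use_min else curve.gc_max_position
    for c in candidates:
        c.dist_to_disparity_extremum = _circ_dist(c.position, extremum, L)

    _score_candidates(candidates, weights, L)
    candidates.sort(key=lambda c: (-c.composite_score, c.position))

    ambiguous = curve.flat or not reached_min
    if not ambiguous and len(candidates) > 1:
        top, second = candidates[0].composite_score, candidates[1].composite_score
        if top <= 0 or (top - second) < params.ambiguity_margin * top:
            ambiguous = True
    if ambiguous:
        for c in candidates:
            c.status = "ambiguous"
    else:
        candidates[0].status = "called"
        for c in candidates[1:]:
            c.status = "alternative"
    return candidates


def _count_hits_in_gaps(hits, gaps, L) -> np.ndarray:
    counts = np.zeros(len(gaps), dtype=int)
    if not hits:
        return counts
    pos = np.array([h[0] for h in hits])
    for i, (s, e) in enumerate(gaps):
        in_gap = (pos >= s) & (pos < e)
        if e > L:  # wrapped gap
            in_gap |= pos < (e - L)
        counts[i] = int(in_gap.sum())
    return counts


def _score_candidates(candidates: list[OriCCandidate], weights: dict, L: int) -> None:
    if not candidates:
        return
    max_boxes = max(c.dnaa_box_count for c in candidates)
    gc_vals = [c.local_gc_excess for c in candidates]
    gc_lo, gc_hi = min(gc_vals), max(gc_vals)
    for c in candidates:
        score = 0.0
        if "boxes" in weights:
            score += weights["boxes"] * (c.dnaa_box_count / max_boxes if max_boxes else 0.0)
        if "disparity" in weights:
            score += weights["disparity"] * (1.0 - c.dist_to_disparity_extremum / (L / 2))
        if "local_gc" in weights:
            # GC-poorer than the alternatives scores higher
            rel = 0.5 if gc_hi == gc_lo else (gc_hi - c.local_gc_excess) / (gc_hi - gc_lo)
            score += weights["local_gc"] * rel
        if "parab" in weights and c.dist_to_parAB is not None:
            score += weights["parab"] * (1.0 - c.dist_to_parAB / (L / 2))
        c.composite_score = score


def called_oric(candidates: list[OriCCandidate]) -> int | None:
    """Position of the called origin, or None if the call is ambiguous."""
    for c in candidates:
        if c.status == "called":
            return c.position
    return None
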