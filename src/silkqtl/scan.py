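"""Genome scanning: background-marker selection, 1D main-effect scan,
2D epistasis scan, permutation thresholds, and full-model assembly.

The procedure follows composite interval mapping adapted to the achiasmate
F2.  Stage by stage:

1. every pair of adjacent markers is tested (per-sex additive/dominance
   marker effects) against a sex-means-only model; marginally significant
   pairs are screened by forward selection on conditional F and backward
   elimination ("ghost peak" control);
2. a genome-wide 1D walk tests putative-QTL per-sex additive/dominance
   terms with the selected marker pairs as background; cofactors on the
   tested chromosome are dropped from the conditioning set, because the
   intact maternal gamete correlates same-chromosome markers at any
   distance and they would absorb the tested QTL;
3. all marker-interval pairs are screened for per-sex epistatic marker
   effects, then a 2D walk around the selected pairs tests putative
   QTL-pair epistasis, conditioning on the other pairs' marker epistasis
   and the main effects of the QTLs from the 1D scan;
4. the detected positions define a full mixed model with fixed QTL main
   and epistatic effects and random sex / QTL-by-sex terms.

Screening thresholds are comparison-wise permutation quantiles; the 1D
and 2D declaration thresholds are genome-wide 100(1-alpha)% quantiles of
the per-permutation maximum F.  Phenotypes are always shuffled within sex
so the permutation null preserves the sex structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .condprob import (
    AchiasmateImpossibleError,
    coefficient_table,
    genotype_posteriors,
    split_recomb,
)
from .genmap import haldane_to_recomb
from .linmod import DesignMatrices, NestedFTester, fit_mixed_model

__all__ = [
    "ModelVariant",
    "BackgroundSelection",
    "ScanProfile",
    "DetectedQTL",
    "PairSelection",
    "DetectedEpistasis",
    "PipelineResult",
    "select_background_markers",
    "scan_main",
    "select_interval_pairs",
    "scan_epistasis",
    "assemble_full_model",
    "fit_full_model",
    "run_pipeline",
]


@dataclass(frozen=True)
class ModelVariant:
    """A mapping strategy: which coefficient backend, and whether the
    epistasis stages run.

    I  - achiasmate coefficients, with epistasis (the silkworm model);
    II - chiasmate coefficients, with epistasis (the traditional F2 model);
    III - achiasmate coefficients, main effects only.

    ``design`` is injectable so the backends can be swapped for testing.
    """

    tag: str
    design: str
    epistasis: bool

    _TABLE = {
        "I": ("achiasmate", True),
        "II": ("chiasmate", True),
        "III": ("achiasmate", False),
    }

    @classmethod
    def from_tag(cls, tag):
        if isinstance(tag, cls):
            return tag
        try:
            design, epi = cls._TABLE[tag]
        except KeyError:
            raise ValueError(f"unknown model variant {tag!r}") from None
        return cls(tag=tag, design=design, epistasis=epi)

    def with_design(self, design):
        return replace(self, design=design)


# ---------------------------------------------------------------------------
# coefficient construction
# ---------------------------------------------------------------------------


def _per_sex(cols, sexind):
    """Interleave coefficient columns with the two sex indicators."""
    out = []
    for z in cols:
        out.append(z * sexind[:, 0])
        out.append(z * sexind[:, 1])
    return np.column_stack(out)


def _marker_block(pop, design, c, t):
    """8 per-sex columns: A/D effects of the two markers of interval t."""
    zA, zD = pop.marker_coeffs(design)
    lo = pop.chrom_slice(c).start
    sexind = pop.sex_indicator()
    jl, jr = lo + t, lo + t + 1
    return _per_sex([zA[:, jl], zD[:, jl], zA[:, jr], zD[:, jr]], sexind)


def _epi_marker_block(pop, design, iv1, iv2):
    """16 per-sex columns: epistatic products of the right markers and of
    the left markers of two intervals."""
    zA, zD = pop.marker_coeffs(design)
    offsets = pop.map.marker_offsets()
    sexind = pop.sex_indicator()
    cols = []
    for side in (1, 0):  # right markers, then left markers
        j1 = int(offsets[iv1[0]]) + iv1[1] + side
        j2 = int(offsets[iv2[0]]) + iv2[1] + side
        a1, d1, a2, d2 = zA[:, j1], zD[:, j1], zA[:, j2], zD[:, j2]
        cols += [a1 * a2, a1 * d2, d1 * a2, d1 * d2]
    return _per_sex(cols, sexind)


def qtl_coeffs_at(pop, design, c, t, pos_cM):
    """Per-individual (x_A, x_D) for a putative QTL at ``pos_cM`` in
    marker interval ``t`` of chromosome ``c``.

    Conditions on the interval's flanking markers through the
    design-appropriate conditional law; individuals with a missing flank
    fall back to the multipoint genotype posterior with the QTL inserted
    as an unobserved pseudo-locus.
    """
    chrom = pop.map.chromosomes[c]
    left_pos, right_pos = chrom.positions[t], chrom.positions[t + 1]
    if not (left_pos <= pos_cM <= right_pos):
        raise ValueError(f"position {pos_cM} outside interval {t}")
    r = haldane_to_recomb(right_pos - left_pos)
    r1 = min(haldane_to_recomb(pos_cM - left_pos), r)
    r2 = split_recomb(r, r1)
    XA, XD = coefficient_table(design, r1, r2)
    sl = pop.chrom_slice(c)
    gl = pop.geno[:, sl.start + t].astype(int)
    gr = pop.geno[:, sl.start + t + 1].astype(int)
    ok = (gl >= 0) & (gr >= 0)
    xA = np.zeros(pop.n)
    xD = np.zeros(pop.n)
    xA[ok] = XA[gl[ok], gr[ok]]
    xD[ok] = XD[gl[ok], gr[ok]]
    bad = ok & (np.isnan(xA) | np.isnan(xD))
    if bad.any():
        raise AchiasmateImpossibleError(
            f"{int(bad.sum())} individuals carry flanking genotypes that are "
            "impossible under the achiasmate design"
        )
    for i in np.nonzero(~ok)[0]:
        positions = np.append(chrom.positions, pos_cM)
        order = np.argsort(positions, kind="stable")
        row = np.append(pop.geno[i, sl], -1)[order]
        qloc = int(np.nonzero(order == len(chrom.positions))[0][0])
        post = genotype_posteriors(positions[order], row, design)[qloc]
        xA[i] = post[2] - post[0]
        xD[i] = 0.5 * post[1] - 0.5 * (post[0] + post[2])
    return xA, xD


def _qtl_block(pop, design, c, t, pos_cM):
    """4 per-sex columns for a putative QTL's additive/dominance terms."""
    xA, xD = qtl_coeffs_at(pop, design, c, t, pos_cM)
    return _per_sex([xA, xD], pop.sex_indicator())


def _permuted_responses(pop, n_perm, rng):
    """(n, n_perm) matrix of phenotypes shuffled within each sex stratum."""
    Y = np.empty((pop.n, n_perm))
    idx1 = np.nonzero(pop.sex == 1)[0]
    idx2 = np.nonzero(pop.sex == 2)[0]
    for k in range(n_perm):
        col = pop.y.copy()
        for idx in (idx1, idx2):
            if len(idx):
                col[idx] = pop.y[idx[rng.permutation(len(idx))]]
        Y[:, k] = col
    return Y


def _all_intervals(gmap):
    return [(c, t) for c, chrom in enumerate(gmap.chromosomes)
            for t in range(chrom.n_markers - 1)]


def _forward_select(y, base_X, candidates, blocks, threshold, max_selected):
    """Greedy forward selection of candidate blocks by conditional F.

    Starting from the base design, repeatedly adds the candidate with the
    largest conditional F among those exceeding the threshold.  Joint
    selection keeps redundant (collinear) candidates out — important here
    because achiasmate marker genotypes are correlated chromosome-wide
    through the intact maternal gamete.
    """
    chosen = []
    remaining = list(candidates)
    while remaining and len(chosen) < max_selected:
        base = np.hstack([base_X] + [blocks[c] for c in chosen]) \
            if chosen else base_X
        tester = NestedFTester(base)
        prep = tester.prepare(y)
        fs = [tester.f_stats(blocks[c], prep)[0] for c in remaining]
        best = int(np.argmax(fs))
        if fs[best] <= threshold:
            break
        chosen.append(remaining.pop(best))
    return chosen


def _stepwise_eliminate(y, base_X, blocks, threshold):
    """Backward elimination: drop the weakest conditional-F block until all
    remaining blocks exceed the threshold.  Never drops the last block if
    it is the strongest (the highest-F block survives by construction)."""
    keep = list(range(len(blocks)))
    while keep:
        fs = []
        for i in keep:
            others = [blocks[j] for j in keep if j != i]
            tester = NestedFTester(np.hstack([base_X] + others)
                                   if others else base_X)
            prep = tester.prepare(y)
            F, _ = tester.f_stats(blocks[i], prep)
            fs.append(F)
        weakest = int(np.argmin(fs))
        if fs[weakest] >= threshold or len(keep) == 1 and fs[0] >= threshold:
            break
        if len(keep) == 1:
            keep = []
            break
        keep.pop(weakest)
    return keep


# ---------------------------------------------------------------------------
# stage 1: background marker selection
# ---------------------------------------------------------------------------


@dataclass
class BackgroundSelection:
    intervals: list            # (chrom_index, interval_index)
    threshold: float
    f_stats: pd.DataFrame      # per candidate interval
    alpha: float
    n_perm: int
    seed: int


def select_background_markers(pop, variant, alpha=0.05, n_perm=1000, seed=0,
                              max_selected=12):
    """Select marker intervals with significant per-sex A/D effects.

    Every adjacent marker pair is tested against the sex-means-only model.
    This is a screening stage, so the threshold is comparison-wise: the
    (1-alpha) quantile of the pooled per-candidate permutation F
    distribution (genome-wide control happens later, at QTL declaration).
    Marginally significant intervals then enter a stepwise model search —
    forward selection by conditional F, capped at ``max_selected``, then
    backward elimination ("ghost peak" control).  Joint selection matters:
    achiasmate marker coefficients are correlated chromosome-wide, so
    marginal selection alone would retain blankets of redundant cofactors
    that absorb the very QTLs the scan must find.  An empty selection is a
    valid outcome.
    """
    variant = ModelVariant.from_tag(variant)
    for chrom in pop.map.chromosomes:
        if chrom.n_markers < 2:
            raise ValueError(
                f"chromosome {chrom.name} has fewer than 2 markers"
            )
    rng = np.random.default_rng(seed)
    intervals = _all_intervals(pop.map)
    X_sex = pop.sex_indicator()
    tester = NestedFTester(X_sex)
    prep_obs = tester.prepare(pop.y)
    Yperm = _permuted_responses(pop, n_perm, rng)
    prep_perm = tester.prepare(Yperm)

    blocks = {iv: _marker_block(pop, variant.design, *iv) for iv in intervals}
    f_obs = np.empty(len(intervals))
    f_perm = np.empty((len(intervals), n_perm))
    for k, iv in enumerate(intervals):
        f_obs[k], _ = tester.f_stats(blocks[iv], prep_obs)
        f_perm[k], _ = tester.f_stats(blocks[iv], prep_perm)
    threshold = float(np.quantile(f_perm.ravel(), 1 - alpha))

    order = np.argsort(-f_obs)
    marginal = [intervals[k] for k in order if f_obs[k] > threshold]
    selected = _forward_select(pop.y, X_sex, marginal, blocks, threshold,
                               max_selected)
    kept = _stepwise_eliminate(pop.y, X_sex, [blocks[iv] for iv in selected],
                               threshold)
    selected = sorted(selected[i] for i in kept)

    table = pd.DataFrame({
        "chrom": [pop.map.chromosomes[c].name for c, _ in intervals],
        "interval": [t for _, t in intervals],
        "F": f_obs,
        "selected": [iv in selected for iv in intervals],
    })
    return BackgroundSelection(intervals=selected, threshold=threshold,
                               f_stats=table, alpha=alpha, n_perm=n_perm,
                               seed=seed)


# ---------------------------------------------------------------------------
# stage 2: 1D scan for main-effect QTLs
# ---------------------------------------------------------------------------


@dataclass
class DetectedQTL:
    chrom: str
    pos_cM: float
    interval: tuple            # (chrom_index, interval_index)
    F: float
    a_by_sex: np.ndarray       # scan-stage per-sex additive estimates
    d_by_sex: np.ndarray

    @property
    def a(self):
        return float(np.mean(self.a_by_sex))

    @property
    def d(self):
        return float(np.mean(self.d_by_sex))

    def label(self):
        return f"{self.chrom}@{self.pos_cM:g}"


@dataclass
class ScanProfile:
    table: pd.DataFrame        # chrom, pos_cM, F
    threshold: float
    step_cM: float
    alpha: float
    n_perm: int
    seed: int


def _interval_grid(chrom, t, step_cM, include_right):
    left, right = chrom.positions[t], chrom.positions[t + 1]
    grid = list(np.arange(left, right - 1e-9, step_cM))
    if include_right:
        grid.append(float(right))
    return grid


def scan_main(pop, variant, background, step_cM=1.0, alpha=0.05,
              n_perm=1000, seed=0, genome_wide=True, window_cM=None):
    """1D genome scan for main-effect QTLs.

    At each grid position the per-sex additive/dominance terms of the
    putative QTL (coefficients from the variant's conditional-probability
    backend) are tested against the background model.  Background
    intervals on the tested chromosome contribute no marker terms to the
    conditioning set: because the maternal gamete is transmitted without
    crossing-over, marker coefficients are correlated chromosome-wide
    (never below ~0.5) and a same-chromosome cofactor at any distance
    would absorb the tested QTL.  Passing a finite ``window_cM`` narrows
    the exclusion to cofactors within that distance instead (the usual
    chiasmate-CIM convention).  The threshold is the genome-wide
    (1-alpha) quantile of the per-permutation maximum F over the whole
    grid; peaks above it are pruned by backward elimination.

    The walk is genome-wide by default (background markers only control
    residual variance); ``genome_wide=False`` restricts it to the selected
    intervals.
    """
    variant = ModelVariant.from_tag(variant)
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    rng = np.random.default_rng(seed)
    bg_intervals = list(background.intervals) if background else []
    scan_intervals = bg_intervals if (bg_intervals and not genome_wide) \
        else _all_intervals(pop.map)
    X_sex = pop.sex_indicator()
    bg_blocks = {iv: _marker_block(pop, variant.design, *iv)
                 for iv in bg_intervals}
    Yperm = _permuted_responses(pop, n_perm, rng)

    def near(iv, c, lo, hi):
        c2, t2 = iv
        if c2 != c:
            return False
        if window_cM is None:
            return True
        p = pop.map.chromosomes[c2].positions
        return p[t2 + 1] >= lo and p[t2] <= hi

    rows = []
    perm_max = np.zeros(n_perm)
    by_chrom_last = {}
    for c, t in scan_intervals:
        by_chrom_last[c] = max(by_chrom_last.get(c, -1), t)
    for c, t in scan_intervals:
        p = pop.map.chromosomes[c].positions
        w = np.inf if window_cM is None else window_cM
        lo, hi = p[t] - w, p[t + 1] + w
        cond = [bg_blocks[iv] for iv in bg_intervals
                if not near(iv, c, lo, hi)]
        tester = NestedFTester(np.hstack([X_sex] + cond) if cond else X_sex)
        prep_obs = tester.prepare(pop.y)
        prep_perm = tester.prepare(Yperm)
        chrom = pop.map.chromosomes[c]
        for pos in _interval_grid(chrom, t, step_cM, t == by_chrom_last[c]):
            block = _qtl_block(pop, variant.design, c, t, pos)
            F, _ = tester.f_stats(block, prep_obs)
            Fp, _ = tester.f_stats(block, prep_perm)
            perm_max = np.maximum(perm_max, Fp)
            rows.append((c, t, chrom.name, pos, F))
    threshold = float(np.quantile(perm_max, 1 - alpha)) if rows else np.inf

    table = pd.DataFrame(rows, columns=["c", "t", "chrom", "pos_cM", "F"])
    detections = _call_peaks(pop, variant, table, threshold, X_sex,
                             bg_blocks, bg_intervals, window_cM)
    profile = ScanProfile(
        table=table[["chrom", "pos_cM", "F"]].copy(), threshold=threshold,
        step_cM=step_cM, alpha=alpha, n_perm=n_perm, seed=seed)
    return profile, detections


def _call_peaks(pop, variant, table, threshold, X_sex, bg_blocks,
                bg_intervals, window_cM=None):
    """Local maxima above threshold, separation-filtered and then jointly
    pruned by backward elimination."""
    candidates = []
    for c, sub in table.groupby("c", sort=False):
        sub = sub.sort_values("pos_cM").reset_index()
        F = sub["F"].to_numpy()
        for k in range(len(sub)):
            left_ok = k == 0 or F[k] > F[k - 1]
            right_ok = k == len(sub) - 1 or F[k] >= F[k + 1]
            if F[k] > threshold and left_ok and right_ok:
                candidates.append((F[k], c, int(sub["t"][k]),
                                   float(sub["pos_cM"][k])))
    candidates.sort(reverse=True)
    accepted = []
    for Fk, c, t, pos in candidates:
        chrom = pop.map.chromosomes[c]
        min_sep = float(chrom.positions[t + 1] - chrom.positions[t])
        if any(ac == c and abs(apos - pos) < min_sep
               for _, ac, _, apos in accepted):
            continue
        accepted.append((Fk, c, t, pos))

    blocks = [_qtl_block(pop, variant.design, c, t, pos)
              for _, c, t, pos in accepted]

    def near_peak(iv):
        c2, t2 = iv
        if window_cM is None:
            return any(ac == c2 for _, ac, _, _ in accepted)
        p = pop.map.chromosomes[c2].positions
        return any(ac == c2 and p[t2 + 1] >= apos - window_cM
                   and p[t2] <= apos + window_cM
                   for _, ac, _, apos in accepted)

    free_bg = [bg_blocks[iv] for iv in bg_intervals if not near_peak(iv)]
    base = np.hstack([X_sex] + free_bg) if free_bg else X_sex
    kept = _stepwise_eliminate(pop.y, base, blocks, threshold)

    detections = []
    for i in kept:
        Fk, c, t, pos = accepted[i]
        others = [blocks[j] for j in kept if j != i]
        X_fit = np.hstack([base] + others + [blocks[i]])
        beta = np.linalg.lstsq(X_fit, pop.y, rcond=None)[0][-4:]
        detections.append(DetectedQTL(
            chrom=pop.map.chromosomes[c].name, pos_cM=pos, interval=(c, t),
            F=Fk, a_by_sex=beta[[0, 1]], d_by_sex=beta[[2, 3]]))
    detections.sort(key=lambda d: (d.interval[0], d.pos_cM))
    return detections


# ---------------------------------------------------------------------------
# stage 3: epistasis
# ---------------------------------------------------------------------------


@dataclass
class PairSelection:
    pairs: list                # ((c1, t1), (c2, t2))
    threshold: float
    f_stats: pd.DataFrame
    alpha: float
    n_perm: int
    seed: int


def select_interval_pairs(pop, variant, background, alpha=0.05, n_perm=1000,
                          seed=0, max_pairs=12):
    """Select marker-interval pairs with significant per-sex epistatic
    marker effects, conditioning on the background main-effect markers.

    A screening stage: the threshold is comparison-wise (pooled
    per-candidate permutation quantile); marginally significant pairs are
    pruned by forward selection on conditional F (at most ``max_pairs``)
    and backward elimination, keeping the 2D stage's conditioning set
    estimable.  Genome-wide control happens in the 2D scan's own max-F
    permutation threshold.
    """
    variant = ModelVariant.from_tag(variant)
    rng = np.random.default_rng(seed)
    intervals = _all_intervals(pop.map)
    bg_intervals = list(background.intervals) if background else []
    bg = [_marker_block(pop, variant.design, *iv) for iv in bg_intervals]
    X_sex = pop.sex_indicator()
    base = np.hstack([X_sex] + bg) if bg else X_sex
    tester = NestedFTester(base)
    prep_obs = tester.prepare(pop.y)
    Yperm = _permuted_responses(pop, n_perm, rng)
    prep_perm = tester.prepare(Yperm)

    pairs = [(intervals[i], intervals[j])
             for i in range(len(intervals))
             for j in range(i + 1, len(intervals))]
    f_obs = np.empty(len(pairs))
    blocks = {}
    perm_sample = np.empty((len(pairs), n_perm))
    for k, pair in enumerate(pairs):
        block = _epi_marker_block(pop, variant.design, *pair)
        blocks[pair] = block
        f_obs[k], _ = tester.f_stats(block, prep_obs)
        perm_sample[k], _ = tester.f_stats(block, prep_perm)
    threshold = float(np.quantile(perm_sample.ravel(), 1 - alpha))

    order = np.argsort(-f_obs)
    marginal = [pairs[k] for k in order if f_obs[k] > threshold]
    selected = _forward_select(pop.y, base, marginal, blocks, threshold,
                               max_pairs)
    kept = _stepwise_eliminate(pop.y, base, [blocks[p] for p in selected],
                               threshold)
    selected = sorted(selected[i] for i in kept)
    table = pd.DataFrame({
        "pair": [f"{p[0]}x{p[1]}" for p in pairs],
        "F": f_obs,
        "selected": [p in selected for p in pairs],
    })
    return PairSelection(pairs=selected, threshold=threshold, f_stats=table,
                         alpha=alpha, n_perm=n_perm, seed=seed)


@dataclass
class DetectedEpistasis:
    chrom_i: str
    pos_i: float
    chrom_j: str
    pos_j: float
    intervals: tuple           # ((c1, t1), (c2, t2))
    F: float
    aa_by_sex: np.ndarray
    ad_by_sex: np.ndarray
    da_by_sex: np.ndarray
    dd_by_sex: np.ndarray

    @property
    def aa(self):
        return float(np.mean(self.aa_by_sex))

    @property
    def ad(self):
        return float(np.mean(self.ad_by_sex))

    @property
    def da(self):
        return float(np.mean(self.da_by_sex))

    @property
    def dd(self):
        return float(np.mean(self.dd_by_sex))


def _epi_qtl_block(pop, sexind, coeffs_i, coeffs_j):
    (xAi, xDi), (xAj, xDj) = coeffs_i, coeffs_j
    return _per_sex([xAi * xAj, xAi * xDj, xDi * xAj, xDi * xDj], sexind)


def _axis_grid(pop, design, c, t, step_cM, expand):
    """Grid of ((c, t'), pos, coeffs) over interval t +- ``expand``."""
    chrom = pop.map.chromosomes[c]
    ts = range(max(t - expand, 0), min(t + expand, chrom.n_markers - 2) + 1)
    out = []
    for t2 in ts:
        include_right = t2 == max(ts)
        for pos in _interval_grid(chrom, t2, step_cM, include_right):
            out.append(((c, t2), pos,
                        qtl_coeffs_at(pop, design, c, t2, pos)))
    return out


def scan_epistasis(pop, variant, pairs, detected_main, step_cM=1.0,
                   alpha=0.05, n_perm=1000, seed=0, expand_intervals=1):
    """2D scan for epistatic QTL pairs around the selected interval pairs.

    For each selected pair the four per-sex epistatic terms of the
    putative QTL pair are tested on a 2D grid over the pair's intervals
    (each axis widened by ``expand_intervals`` neighboring intervals, so a
    near-miss in pair screening still reaches the true peak), conditioning
    on the other selected pairs' marker epistasis terms and the main
    effects of the QTLs detected in 1D.  Conditioning pairs whose
    intervals fall inside the scanned region are dropped so they cannot
    absorb the tested epistasis.  The threshold is the genome-wide
    (1-alpha) quantile of the per-permutation maximum F over all scanned
    grids.  Variant III skips the stage entirely.
    """
    variant = ModelVariant.from_tag(variant)
    if not variant.epistasis or not pairs or not pairs.pairs:
        return []
    rng = np.random.default_rng(seed)
    X_sex = pop.sex_indicator()
    main_blocks = [_qtl_block(pop, variant.design, *q.interval, q.pos_cM)
                   for q in detected_main]
    pair_blocks = {p: _epi_marker_block(pop, variant.design, *p)
                   for p in pairs.pairs}
    Yperm = _permuted_responses(pop, n_perm, rng)

    results = []
    perm_max = np.zeros(n_perm)
    for pair in pairs.pairs:
        (c1, t1), (c2, t2) = pair
        axis1 = _axis_grid(pop, variant.design, c1, t1, step_cM,
                           expand_intervals)
        axis2 = _axis_grid(pop, variant.design, c2, t2, step_cM,
                           expand_intervals)
        region = {iv for iv, _, _ in axis1} | {iv for iv, _, _ in axis2}
        others = [pair_blocks[p] for p in pairs.pairs
                  if p != pair and not (set(p) & region)]
        base = np.hstack([X_sex] + others + main_blocks)
        tester = NestedFTester(base)
        prep_obs = tester.prepare(pop.y)
        prep_perm = tester.prepare(Yperm)
        best = None
        for iv1, p1, co1 in axis1:
            for iv2, p2, co2 in axis2:
                block = _epi_qtl_block(pop, X_sex, co1, co2)
                F, _ = tester.f_stats(block, prep_obs)
                Fp, _ = tester.f_stats(block, prep_perm)
                perm_max = np.maximum(perm_max, Fp)
                if best is None or F > best[0]:
                    best = (F, (iv1, p1), (iv2, p2), block)
        results.append((pair, best))
    threshold = float(np.quantile(perm_max, 1 - alpha))

    detected = []
    for pair, (F, hit1, hit2, block) in results:
        if F <= threshold:
            continue
        detected.append((F, (hit1[0], hit2[0]), hit1[1], hit2[1], block))

    # backward elimination across detected pairs
    base_all = np.hstack([X_sex] + main_blocks) if main_blocks else X_sex
    kept = _stepwise_eliminate(pop.y, base_all, [d[4] for d in detected],
                               threshold)
    out = []
    for i in kept:
        F, pair, p1, p2, block = detected[i]
        (c1, t1), (c2, t2) = pair
        others = [detected[j][4] for j in kept if j != i]
        X_fit = np.hstack([base_all] + others + [block])
        beta = np.linalg.lstsq(X_fit, pop.y, rcond=None)[0][-8:]
        out.append(DetectedEpistasis(
            chrom_i=pop.map.chromosomes[c1].name, pos_i=p1,
            chrom_j=pop.map.chromosomes[c2].name, pos_j=p2,
            intervals=pair, F=F,
            aa_by_sex=beta[[0, 1]], ad_by_sex=beta[[2, 3]],
            da_by_sex=beta[[4, 5]], dd_by_sex=beta[[6, 7]]))
    return out


# ---------------------------------------------------------------------------
# stage 4: full model
# ---------------------------------------------------------------------------


def assemble_full_model(pop, variant, detected_main, detected_epi=()):
    """Design matrices of the full mixed model implied by the detections.

    Fixed block: mean, additive/dominance per detected QTL, and the four
    epistatic effects per detected pair.  Random blocks: sex, plus the
    QTL-by-sex and epistasis-by-sex interaction terms, with coefficients
    the products of the genetic coefficients and the sex indicators.  With
    no detections this degenerates to a mean + sex model.
    """
    variant = ModelVariant.from_tag(variant)
    n = pop.n
    sexind = pop.sex_indicator()
    coeffs = [qtl_coeffs_at(pop, variant.design, *q.interval, q.pos_cM)
              for q in detected_main]

    X_cols, x_labels = [np.ones(n)], ["mu"]
    for q, (xA, xD) in zip(detected_main, coeffs):
        X_cols += [xA, xD]
        x_labels += [f"a[{q.label()}]", f"d[{q.label()}]"]
    epi_coeffs = []
    for e in detected_epi:
        (c1, t1), (c2, t2) = e.intervals
        xAi, xDi = qtl_coeffs_at(pop, variant.design, c1, t1, e.pos_i)
        xAj, xDj = qtl_coeffs_at(pop, variant.design, c2, t2, e.pos_j)
        epi_coeffs.append((xAi, xDi, xAj, xDj))
        tag = f"{e.chrom_i}@{e.pos_i:g}x{e.chrom_j}@{e.pos_j:g}"
        X_cols += [xAi * xAj, xAi * xDj, xDi * xAj, xDi * xDj]
        x_labels += [f"aa[{tag}]", f"ad[{tag}]", f"da[{tag}]", f"dd[{tag}]"]
    X = np.column_stack(X_cols)

    U_list, u_terms, u_levels = [sexind.copy()], ["S"], [["s1", "s2"]]

    def add_term(name, per_unit_cols, unit_tags):
        cols, labels = [], []
        for z, tag in zip(per_unit_cols, unit_tags):
            for h in (0, 1):
                cols.append(z * sexind[:, h])
                labels.append(f"{name.lower()}[{tag},s{h + 1}]")
        if cols:
            U_list.append(np.column_stack(cols))
            u_terms.append(name)
            u_levels.append(labels)

    qtags = [q.label() for q in detected_main]
    add_term("AS", [c[0] for c in coeffs], qtags)
    add_term("DS", [c[1] for c in coeffs], qtags)
    etags = [f"{e.chrom_i}@{e.pos_i:g}x{e.chrom_j}@{e.pos_j:g}"
             for e in detected_epi]
    add_term("AAS", [c[0] * c[2] for c in epi_coeffs], etags)
    add_term("ADS", [c[0] * c[3] for c in epi_coeffs], etags)
    add_term("DAS", [c[1] * c[2] for c in epi_coeffs], etags)
    add_term("DDS", [c[1] * c[3] for c in epi_coeffs], etags)

    return DesignMatrices(X=X, x_labels=x_labels, U_list=U_list,
                          u_terms=u_terms, u_level_labels=u_levels)


def fit_full_model(pop, variant, detected_main, detected_epi=(),
                   n_iter=11_000, burn_in=1_000, seed=0, alpha=0.05):
    """Assemble and fit the full mixed model (REML/GLS/AUP-initialized
    Gibbs sampling); returns the FitReport."""
    dm = assemble_full_model(pop, variant, detected_main, detected_epi)
    return fit_mixed_model(pop.y, dm, n_iter=n_iter, burn_in=burn_in,
                           seed=seed, alpha=alpha)


# ---------------------------------------------------------------------------
# whole pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    variant: ModelVariant
    background: BackgroundSelection
    profile: ScanProfile
    qtls: list
    pair_selection: PairSelection
    epistases: list
    fit: object                # FitReport or None
    seed: int


def run_pipeline(pop, variant, alpha=0.05, step_cM=1.0, n_perm=1000,
                 gibbs_iter=11_000, gibbs_burn=1_000, seed=0,
                 fit=True):
    """Background selection -> 1D scan -> 2D epistasis scan -> full model.

    Stage seeds are derived deterministically from ``seed``; permutation
    thresholds are recomputed per stage.
    """
    variant = ModelVariant.from_tag(variant)
    s_bg, s_scan, s_pairs, s_epi, s_fit = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(5)
    ]
    background = select_background_markers(pop, variant, alpha=alpha,
                                           n_perm=n_perm, seed=s_bg)
    profile, qtls = scan_main(pop, variant, background, step_cM=step_cM,
                              alpha=alpha, n_perm=n_perm, seed=s_scan)
    pair_selection, epistases = None, []
    if variant.epistasis:
        pair_selection = select_interval_pairs(pop, variant, background,
                                               alpha=alpha, n_perm=n_perm,
                                               seed=s_pairs)
        epistases = scan_epistasis(pop, variant, pair_selection, qtls,
                                   step_cM=step_cM, alpha=alpha,
                                   n_perm=n_perm, seed=s_epi)
    report = None
    if fit:
        report = fit_full_model(pop, variant, qtls, epistases,
                                n_iter=gibbs_iter, burn_in=gibbs_burn,
                                seed=s_fit, alpha=alpha)
    return PipelineResult(variant=variant, background=background,
                          profile=profile, qtls=qtls,
                          pair_selection=pair_selection,
                          epistases=epistases, fit=report, seed=seed)
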