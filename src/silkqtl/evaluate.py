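"""Model evaluation: achiasmate-vs-chiasmate coefficient differences and
Monte-Carlo power/bias/FDR studies of the mapping strategies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .condprob import (
    ACHIASMATE_IMPOSSIBLE,
    coefficient_table,
    split_recomb,
)
from .scan import ModelVariant, run_pipeline
from .simulate import simulate_f2

__all__ = [
    "DiffCurve",
    "QTLArchitecture",
    "SimulationReport",
    "coefficient_difference",
    "match_detections",
    "match_epistases",
    "run_simulation_study",
]

_CLASS_NAMES = {2: "MM", 1: "Mm", 0: "mm"}

#: the seven flanking-marker classes that segregate in an achiasmate F2
FEASIBLE_CLASSES = tuple(
    (gl, gr) for gl in (2, 1, 0) for gr in (2, 1, 0)
    if (gl, gr) not in ACHIASMATE_IMPOSSIBLE
)


@dataclass
class DiffCurve:
    """Coefficient differences between the achiasmate and chiasmate laws.

    For a fixed whole-interval recombination fraction ``r``, the QTL
    position sweeps ``r1`` over a grid in (0, r) with ``r2`` from the
    no-interference constraint.  For each feasible flanking class i the
    absolute difference ``D_i = |x_a - x_c|`` and the relative difference
    ``R_i = |x_a - x_c| / |x_a|`` (undefined, and excluded, where the
    achiasmate coefficient is zero) are recorded for both the additive and
    the dominance coefficient.
    """

    r: float
    r1: np.ndarray                     # grid, shape (G,)
    classes: tuple                     # feasible class labels
    abs_additive: np.ndarray           # (n_classes, G)
    abs_dominance: np.ndarray
    rel_additive: np.ndarray           # NaN where undefined
    rel_dominance: np.ndarray

    def envelope(self, which, kind="max"):
        arr = getattr(self, which)
        fn = np.nanmax if kind == "max" else np.nanmin
        return fn(arr, axis=0)

    def summary(self):
        """Global extrema over classes and the r1 grid."""
        out = {}
        for which in ("abs_additive", "abs_dominance",
                      "rel_additive", "rel_dominance"):
            arr = getattr(self, which)
            out[f"max_{which}"] = float(np.nanmax(arr))
            out[f"min_{which}"] = float(np.nanmin(arr))
            flat = np.nanmax(arr, axis=0)
            out[f"argmax_r1_{which}"] = float(self.r1[int(np.nanargmax(flat))])
        return out

    def to_frame(self):
        """Long-format table ``r1, metric, class, value``."""
        rows = []
        for which in ("abs_additive", "abs_dominance",
                      "rel_additive", "rel_dominance"):
            arr = getattr(self, which)
            for ci, cls in enumerate(self.classes):
                for g, r1 in enumerate(self.r1):
                    rows.append((r1, which, cls, arr[ci, g]))
        return pd.DataFrame(rows, columns=["r1", "metric", "class", "value"])


def coefficient_difference(r, grid_points=1000):
    """Sweep the QTL through a marker interval and compare the two laws.

    ``r`` is the recombination fraction across the interval; the grid has
    ``grid_points`` interior points.  Only the seven achiasmate-feasible
    flanking classes enter the comparison.
    """
    if not (0.0 < r < 0.5):
        raise ValueError("interval recombination fraction must be in (0, 0.5)")
    if grid_points < 100:
        raise ValueError("grid_points must be at least 100")
    r1_grid = np.linspace(0.0, r, grid_points + 2)[1:-1]
    nC, G = len(FEASIBLE_CLASSES), len(r1_grid)
    DA = np.empty((nC, G))
    DD = np.empty((nC, G))
    RA = np.full((nC, G), np.nan)
    RD = np.full((nC, G), np.nan)
    for g, r1 in enumerate(r1_grid):
        r2 = float(split_recomb(r, r1))
        XAa, XDa = coefficient_table("achiasmate", r1, r2)
        XAc, XDc = coefficient_table("chiasmate", r1, r2)
        for ci, (gl, gr) in enumerate(FEASIBLE_CLASSES):
            da = abs(XAa[gl, gr] - XAc[gl, gr])
            dd = abs(XDa[gl, gr] - XDc[gl, gr])
            DA[ci, g], DD[ci, g] = da, dd
            if abs(XAa[gl, gr]) > 1e-12:
                RA[ci, g] = da / abs(XAa[gl, gr])
            if abs(XDa[gl, gr]) > 1e-12:
                RD[ci, g] = dd / abs(XDa[gl, gr])
    labels = tuple(f"{_CLASS_NAMES[gl]}/{_CLASS_NAMES[gr]}"
                   for gl, gr in FEASIBLE_CLASSES)
    return DiffCurve(r=float(r), r1=r1_grid, classes=labels,
                     abs_additive=DA, abs_dominance=DD,
                     rel_additive=RA, rel_dominance=RD)


# ---------------------------------------------------------------------------
# detection matching and the simulation study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLArchitecture:
    """True (or estimated) genetic architecture used for scoring."""

    qtls: tuple
    epistases: tuple = ()

    @classmethod
    def from_config(cls, cfg):
        return cls(qtls=tuple(cfg.qtls), epistases=tuple(cfg.epistases))

    def main_effect_qtls(self):
        return [q for q in self.qtls if q.a != 0.0 or q.d != 0.0]


def match_detections(true_arch, detections, window_cM=10.0):
    """Greedy matching of detections to true main-effect QTLs.

    Detections are taken in descending F; each matches the nearest
    still-unmatched true QTL on the same chromosome within ``window_cM``.
    Unmatched detections are false positives.  Returns a list of
    ``(detection, matched_qtl_or_None)`` in the greedy order.
    """
    if window_cM <= 0:
        raise ValueError("window_cM must be positive")
    available = list(true_arch.main_effect_qtls())
    out = []
    for det in sorted(detections, key=lambda d: -d.F):
        near = [q for q in available
                if q.chrom == det.chrom and abs(q.pos_cM - det.pos_cM) <= window_cM]
        if near:
            best = min(near, key=lambda q: abs(q.pos_cM - det.pos_cM))
            available.remove(best)
            out.append((det, best))
        else:
            out.append((det, None))
    return out


def match_epistases(true_arch, detections, window_cM=10.0):
    """Greedy matching of 2D detections to true epistatic pairs.

    A detection matches a pair when both of its positions fall within
    ``window_cM`` of the pair's two QTLs (on the right chromosomes, in
    either order).
    """
    qtl_by_id = {q.id: q for q in true_arch.qtls}
    available = list(true_arch.epistases)
    out = []
    for det in sorted(detections, key=lambda d: -d.F):
        hit = None
        for e in available:
            qi, qj = qtl_by_id[e.qtl_i], qtl_by_id[e.qtl_j]
            direct = (det.chrom_i == qi.chrom and det.chrom_j == qj.chrom
                      and abs(det.pos_i - qi.pos_cM) <= window_cM
                      and abs(det.pos_j - qj.pos_cM) <= window_cM)
            swapped = (det.chrom_i == qj.chrom and det.chrom_j == qi.chrom
                       and abs(det.pos_i - qj.pos_cM) <= window_cM
                       and abs(det.pos_j - qi.pos_cM) <= window_cM)
            if direct or swapped:
                hit = (e, not direct and swapped)
                break
        if hit:
            available.remove(hit[0])
            out.append((det, hit[0], hit[1]))
        else:
            out.append((det, None, False))
    return out


@dataclass
class SimulationReport:
    """Power, bias and FDR of the mapping strategies over replicates."""

    qtl_table: pd.DataFrame
    epi_table: pd.DataFrame
    fdr: dict
    n_reps: int
    seed: int
    settings: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def power(self, variant, qtl_id):
        row = self.qtl_table[(self.qtl_table["variant"] == variant)
                             & (self.qtl_table["qtl"] == qtl_id)]
        return float(row["power"].iloc[0])

    def estimate(self, variant, qtl_id, what="a_mean"):
        row = self.qtl_table[(self.qtl_table["variant"] == variant)
                             & (self.qtl_table["qtl"] == qtl_id)]
        return float(row[what].iloc[0])


def _full_model_effects(fit, detection):
    """(a, d) estimates of one detected QTL from the full-model report."""
    label = detection.label()
    try:
        return (fit.fixed_estimate(f"a[{label}]"),
                fit.fixed_estimate(f"d[{label}]"))
    except KeyError:
        return detection.a, detection.d


def run_simulation_study(cfg, variants=("I", "II"), n_reps=50, seed=0,
                         n_perm=200, gibbs_iter=2000, gibbs_burn=500,
                         step_cM=1.0, window_cM=10.0, alpha=0.05,
                         fit=True):
    """Monte-Carlo study: simulate, map with each variant, score.

    Per replicate the same simulated population and the same pipeline seed
    are analyzed by every variant, so variant contrasts are paired.  Power
    is the fraction of replicates in which a true QTL (or pair) is
    matched; FDR pools false detections over replicates; bias/SD of
    positions and effects are over detecting replicates.  Replicate
    failures are logged, not raised.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    variants = [ModelVariant.from_tag(v) for v in variants]
    arch = QTLArchitecture.from_config(cfg)
    truth_qtls = arch.main_effect_qtls()
    rep_seeds = [int(s.generate_state(1)[0] % (2**31))
                 for s in np.random.SeedSequence(seed).spawn(n_reps)]

    records = {v.tag: {q.id: {"pos": [], "a": [], "d": []} for q in truth_qtls}
               for v in variants}
    epi_records = {v.tag: {(e.qtl_i, e.qtl_j): {"pos_i": [], "pos_j": [],
                                                "aa": [], "ad": [],
                                                "da": [], "dd": []}
                           for e in arch.epistases}
                   for v in variants}
    counts = {v.tag: {"false": 0, "total": 0} for v in variants}
    failures = []

    for rep, rseed in enumerate(rep_seeds):
        pop = simulate_f2(cfg, seed=rseed)
        for v in variants:
            try:
                res = run_pipeline(pop, v, alpha=alpha, step_cM=step_cM,
                                   n_perm=n_perm, gibbs_iter=gibbs_iter,
                                   gibbs_burn=gibbs_burn, seed=rseed,
                                   fit=fit)
            except Exception as err:  # pragma: no cover - defensive logging
                failures.append({"rep": rep, "variant": v.tag,
                                 "error": repr(err)})
                continue
            matches = match_detections(arch, res.qtls, window_cM)
            counts[v.tag]["total"] += len(matches)
            for det, qtl in matches:
                if qtl is None:
                    counts[v.tag]["false"] += 1
                    continue
                a_est, d_est = (_full_model_effects(res.fit, det)
                                if res.fit is not None else (det.a, det.d))
                rec = records[v.tag][qtl.id]
                rec["pos"].append(det.pos_cM)
                rec["a"].append(a_est)
                rec["d"].append(d_est)
            if v.epistasis:
                for det, epi, swapped in match_epistases(arch, res.epistases,
                                                         window_cM):
                    if epi is None:
                        continue
                    rec = epi_records[v.tag][(epi.qtl_i, epi.qtl_j)]
                    pi, pj = ((det.pos_j, det.pos_i) if swapped
                              else (det.pos_i, det.pos_j))
                    rec["pos_i"].append(pi)
                    rec["pos_j"].append(pj)
                    effs = {"aa": det.aa, "ad": det.ad,
                            "da": det.da, "dd": det.dd}
                    if swapped:
                        effs["ad"], effs["da"] = effs["da"], effs["ad"]
                    for k, val in effs.items():
                        rec[k].append(val)

    def mstats(vals):
        if not vals:
            return np.nan, np.nan
        arr = np.asarray(vals, dtype=float)
        return float(arr.mean()), (float(arr.std(ddof=1))
                                   if len(arr) > 1 else np.nan)

    qtl_rows = []
    for v in variants:
        for q in truth_qtls:
            rec = records[v.tag][q.id]
            k = len(rec["pos"])
            power = k / n_reps
            pos_m, pos_s = mstats(rec["pos"])
            a_m, a_s = mstats(rec["a"])
            d_m, d_s = mstats(rec["d"])
            qtl_rows.append({
                "variant": v.tag, "qtl": q.id, "chrom": q.chrom,
                "pos_true": q.pos_cM, "a_true": q.a, "d_true": q.d,
                "power": power,
                "power_se": float(np.sqrt(power * (1 - power) / n_reps)),
                "pos_mean": pos_m, "pos_sd": pos_s,
                "a_mean": a_m, "a_sd": a_s, "d_mean": d_m, "d_sd": d_s,
                "n_detected": k,
            })
    epi_rows = []
    for v in variants:
        for e in arch.epistases:
            rec = epi_records[v.tag][(e.qtl_i, e.qtl_j)]
            k = len(rec["aa"])
            power = k / n_reps
            row = {"variant": v.tag, "pair": f"{e.qtl_i}-{e.qtl_j}",
                   "power": power,
                   "power_se": float(np.sqrt(power * (1 - power) / n_reps))}
            for key, true_val in (("aa", e.aa), ("ad", e.ad),
                                  ("da", e.da), ("dd", e.dd)):
                m, s = mstats(rec[key])
                row[f"{key}_true"], row[f"{key}_mean"], row[f"{key}_sd"] = \
                    true_val, m, s
            for key in ("pos_i", "pos_j"):
                m, s = mstats(rec[key])
                row[f"{key}_mean"], row[f"{key}_sd"] = m, s
            epi_rows.append(row)

    fdr = {}
    for v in variants:
        tot = counts[v.tag]["total"]
        fdr[v.tag] = counts[v.tag]["false"] / tot if tot else np.nan
    return SimulationReport(
        qtl_table=pd.DataFrame(qtl_rows),
        epi_table=pd.DataFrame(epi_rows),
        fdr=fdr, n_reps=n_reps, seed=seed,
        settings={"n_perm": n_perm, "gibbs_iter": gibbs_iter,
                  "gibbs_burn": gibbs_burn, "step_cM": step_cM,
                  "window_cM": window_cM, "alpha": alpha, "fit": fit},
        failures=failures,
    )
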