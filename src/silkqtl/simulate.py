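"""Simulation of achiasmate (and chiasmate) F2 populations.

Gametogenesis: each individual receives one maternal gamete that is an
intact parental haplotype (no crossing-over in female meiosis; probability
1/2 per chromosome) and one paternal gamete generated by a first-order
Markov walk along the chromosome with per-interval recombination fractions
from Haldane's map function (no interference).  QTLs are inserted as
pseudo-loci into the walk so marker and QTL genotypes are jointly
consistent.  The chiasmate mode replaces the intact maternal gamete with a
second independent recombinant walk.

The phenotype model adds, to a population mean, fixed additive/dominance
effects per QTL (coefficients +1/0/-1 and +0.5/-0.5 from the true QTL
genotype), fixed digenic epistatic effects (coefficient products), a random
sex effect, random QTL-by-sex and epistasis-by-sex interaction deviations
(one value per sex level, constrained to sum to zero across the two
sexes unless explicit realized values are supplied), and Gaussian residual
noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cross import CrossPopulation
from .genmap import GeneticMap, haldane_to_recomb, uniform_map

__all__ = [
    "QTLSpec",
    "EpistasisSpec",
    "VarianceComponents",
    "SexInteractionEffects",
    "ScenarioConfig",
    "simulate_f2",
    "simulate_null",
    "silkworm_scenario",
    "variance_audit",
]

#: residual standard deviation of the built-in silkworm scenario, calibrated
#: by a large-n variance audit so the genetic fraction of the phenotypic
#: variance is ~50% (see variance_audit and docs/methods.md).
SILKWORM_RESIDUAL_SD = 5.34


@dataclass(frozen=True)
class QTLSpec:
    """One simulated QTL: position plus additive/dominance effects."""

    id: str
    chrom: str
    pos_cM: float
    a: float = 0.0
    d: float = 0.0


@dataclass(frozen=True)
class EpistasisSpec:
    """Digenic epistatic effects between two QTLs (by id)."""

    qtl_i: str
    qtl_j: str
    aa: float = 0.0
    ad: float = 0.0
    da: float = 0.0
    dd: float = 0.0

    def __post_init__(self):
        if self.qtl_i == self.qtl_j:
            raise ValueError("epistasis requires two distinct QTLs")


@dataclass(frozen=True)
class VarianceComponents:
    """Variances of the sex-structured random terms and the residual."""

    var_s: float = 0.0
    var_as: float = 0.0
    var_ds: float = 0.0
    var_aas: float = 0.0
    var_ads: float = 0.0
    var_das: float = 0.0
    var_dds: float = 0.0
    var_e: float = 1.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SexInteractionEffects:
    """Realized per-sex random-effect values (rows = sex 1, sex 2).

    ``s`` has shape (2,); ``a_s``/``d_s`` have shape (2, n_qtls) and
    ``aa_s``/``ad_s``/``da_s``/``dd_s`` shape (2, n_pairs), ordered as in
    the scenario's QTL/epistasis lists.
    """

    s: np.ndarray
    a_s: np.ndarray
    d_s: np.ndarray
    aa_s: np.ndarray
    ad_s: np.ndarray
    da_s: np.ndarray
    dd_s: np.ndarray


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to generate one F2 population."""

    map: GeneticMap
    qtls: tuple = ()
    epistases: tuple = ()
    variance: VarianceComponents = field(default_factory=VarianceComponents)
    n: int = 300
    sex_ratio: float = 0.5
    mu: float = 10.0
    design: str = "achiasmate"
    sex_effects: SexInteractionEffects = None
    seed: int = None

    def __post_init__(self):
        object.__setattr__(self, "qtls", tuple(self.qtls))
        object.__setattr__(self, "epistases", tuple(self.epistases))
        if self.n <= 0:
            raise ValueError("population size must be positive")
        if not (0.0 < self.sex_ratio < 1.0):
            raise ValueError("sex_ratio must lie strictly between 0 and 1")
        ids = [q.id for q in self.qtls]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate QTL ids")
        for e in self.epistases:
            if e.qtl_i not in ids or e.qtl_j not in ids:
                raise ValueError(f"epistasis refers to unknown QTL: {e}")
        for q in self.qtls:
            chrom = self.map.chrom(q.chrom)
            lo, hi = chrom.span
            if not (lo <= q.pos_cM <= hi):
                raise ValueError(
                    f"QTL {q.id} at {q.pos_cM} cM outside chromosome "
                    f"{q.chrom} span [{lo}, {hi}]"
                )

    def with_(self, **kwargs):
        return replace(self, **kwargs)


def _simulate_chromosome_gametes(rng, rs, n, mode):
    """Allele matrix (n x L) of one gamete along a chromosome.

    ``mode='intact'`` transmits one of the two parental haplotypes whole;
    ``mode='recomb'`` is a Markov walk with flip probabilities ``rs``.
    """
    L = len(rs) + 1
    if mode == "intact":
        hap = rng.integers(0, 2, size=n)
        return np.repeat(hap[:, None], L, axis=1)
    alleles = np.empty((n, L), dtype=np.int64)
    alleles[:, 0] = rng.integers(0, 2, size=n)
    if L > 1:
        flips = rng.random((n, L - 1)) < rs[None, :]
        alleles[:, 1:] = alleles[:, [0]] ^ np.cumsum(flips, axis=1) % 2
    return alleles


def _sum_to_zero_pair(rng, variance):
    """Realized (value_sex1, value_sex2) with value_sex2 = -value_sex1.

    Each level is marginally N(0, variance); the two-level constraint
    mirrors the deviation-coding of a two-level random classification.
    """
    v = rng.normal(0.0, np.sqrt(variance)) if variance > 0 else 0.0
    return np.array([v, -v])


def _realize_sex_effects(rng, cfg):
    nq, ne = len(cfg.qtls), len(cfg.epistases)
    vc = cfg.variance

    def draw(var, count):
        if count == 0:
            return np.zeros((2, 0))
        return np.column_stack([_sum_to_zero_pair(rng, var) for _ in range(count)])

    return SexInteractionEffects(
        s=_sum_to_zero_pair(rng, vc.var_s),
        a_s=draw(vc.var_as, nq),
        d_s=draw(vc.var_ds, nq),
        aa_s=draw(vc.var_aas, ne),
        ad_s=draw(vc.var_ads, ne),
        da_s=draw(vc.var_das, ne),
        dd_s=draw(vc.var_dds, ne),
    )


def simulate_f2(cfg, seed=None, keep_truth=True):
    """Generate one F2 population under a scenario configuration.

    Reproducible: the same config and seed give bitwise-identical output.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cfg.n

    # augmented loci: markers plus QTL pseudo-loci, per chromosome
    qtl_geno = {}
    marker_cols = []
    for c, chrom in enumerate(cfg.map.chromosomes):
        qtls_here = [q for q in cfg.qtls if q.chrom == chrom.name]
        positions = list(chrom.positions)
        is_marker = [True] * len(positions)
        owners = [None] * len(positions)
        for q in qtls_here:
            positions.append(q.pos_cM)
            is_marker.append(False)
            owners.append(q.id)
        order = np.argsort(positions, kind="stable")
        positions = np.asarray(positions)[order]
        is_marker = np.asarray(is_marker)[order]
        owners = [owners[k] for k in order]
        rs = haldane_to_recomb(np.diff(positions))

        female_mode = "intact" if cfg.design == "achiasmate" else "recomb"
        female = _simulate_chromosome_gametes(rng, rs, n, female_mode)
        male = _simulate_chromosome_gametes(rng, rs, n, "recomb")
        geno = female + male  # codes 0/1/2

        marker_cols.append(geno[:, is_marker])
        for k, owner in enumerate(owners):
            if owner is not None:
                qtl_geno[owner] = geno[:, k]

    geno = np.concatenate(marker_cols, axis=1) if marker_cols else np.empty((n, 0))

    n_sex1 = int(round(n * cfg.sex_ratio))
    sex = np.concatenate([np.ones(n_sex1, dtype=int), np.full(n - n_sex1, 2)])

    # fixed genetic contributions from true QTL genotypes
    xA = {q.id: qtl_geno[q.id].astype(float) - 1.0 for q in cfg.qtls}
    xD = {q.id: np.where(qtl_geno[q.id] == 1, 0.5, -0.5) for q in cfg.qtls}
    g_fixed = np.zeros(n)
    for q in cfg.qtls:
        g_fixed += xA[q.id] * q.a + xD[q.id] * q.d
    for e in cfg.epistases:
        g_fixed += (
            xA[e.qtl_i] * xA[e.qtl_j] * e.aa
            + xA[e.qtl_i] * xD[e.qtl_j] * e.ad
            + xD[e.qtl_i] * xA[e.qtl_j] * e.da
            + xD[e.qtl_i] * xD[e.qtl_j] * e.dd
        )

    eff = cfg.sex_effects
    if eff is None:
        eff = _realize_sex_effects(rng, cfg)
    h = sex - 1  # 0/1 index into the sex rows of the realized effects
    g_sex = eff.s[h].astype(float).copy()
    for k, q in enumerate(cfg.qtls):
        g_sex += xA[q.id] * eff.a_s[h, k] + xD[q.id] * eff.d_s[h, k]
    for l, e in enumerate(cfg.epistases):
        g_sex += (
            xA[e.qtl_i] * xA[e.qtl_j] * eff.aa_s[h, l]
            + xA[e.qtl_i] * xD[e.qtl_j] * eff.ad_s[h, l]
            + xD[e.qtl_i] * xA[e.qtl_j] * eff.da_s[h, l]
            + xD[e.qtl_i] * xD[e.qtl_j] * eff.dd_s[h, l]
        )

    resid = rng.normal(0.0, np.sqrt(cfg.variance.var_e), size=n) \
        if cfg.variance.var_e > 0 else np.zeros(n)
    y = cfg.mu + g_fixed + g_sex + resid

    truth = None
    if keep_truth:
        truth = {
            "config": cfg,
            "qtl_geno": {k: v.copy() for k, v in qtl_geno.items()},
            "sex_effects": eff,
            "g_fixed": g_fixed,
            "g_sex": g_sex,
            "residual": resid,
            "seed": seed,
        }
    return CrossPopulation(
        map=cfg.map, geno=geno, sex=sex, y=y, design=cfg.design, truth=truth
    )


def simulate_null(map, n, var_e=1.0, seed=None, design="achiasmate", mu=10.0):
    """Population with realistic genotype segregation but pure-noise phenotype."""
    cfg = ScenarioConfig(
        map=map, qtls=(), epistases=(),
        variance=VarianceComponents(var_e=var_e),
        n=n, mu=mu, design=design,
    )
    return simulate_f2(cfg, seed=seed)


def silkworm_scenario(n=300, seed=None, design="achiasmate", residual_sd=None):
    """The built-in 5-chromosome / 7-QTL silkworm study scenario.

    Five 100-cM chromosomes with 11 markers at 10-cM spacing; seven QTLs
    with fixed additive/dominance effects, three epistatic pairs, and
    fixed realized QTL-by-sex interaction values (equal populations of the
    two sexes).  The residual SD default is calibrated so the genetic
    fraction of phenotypic variance is about one half.
    """
    gmap = uniform_map(n_chrom=5, n_markers=11, spacing_cM=10.0)
    qtls = (
        QTLSpec("Q1", "1", 44.0, a=3.88, d=-2.3),
        QTLSpec("Q2", "2", 45.0, a=-2.4, d=1.9),
        QTLSpec("Q3", "3", 50.0, a=3.2, d=2.1),
        QTLSpec("Q4", "4", 73.0, a=-2.8, d=-1.9),
        QTLSpec("Q5", "5", 15.0, a=1.9, d=0.0),
        QTLSpec("Q6", "2", 75.0, a=0.0, d=0.0),
        QTLSpec("Q7", "4", 24.0, a=0.0, d=0.0),
    )
    epistases = (
        EpistasisSpec("Q1", "Q7", aa=3.09, da=2.34),
        EpistasisSpec("Q3", "Q5", aa=2.6, ad=-2.1, dd=3.2),
        EpistasisSpec("Q6", "Q7", aa=-3.7, dd=-1.9),
    )
    # realized per-sex interaction values (rows: sex 1, sex 2; columns follow
    # the QTL / epistasis order above)
    sex_effects = SexInteractionEffects(
        s=np.zeros(2),
        a_s=np.array([
            [0.0, -1.7, -1.6, 0.0, 0.0, 0.0, 0.0],
            [0.0, 1.7, 1.6, 0.0, 0.0, 0.0, 0.0],
        ]),
        d_s=np.array([
            [0.0, 0.0, -1.5, 1.6, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.4, -1.6, 0.0, 0.0, 0.0],
        ]),
        aa_s=np.array([[0.0, -1.0, 0.0], [0.0, 1.4, 0.0]]),
        ad_s=np.array([[1.7, 1.6, 0.0], [-2.0, -2.0, 0.0]]),
        da_s=np.array([[0.0, 0.0, 1.7], [0.0, 0.0, -2.0]]),
        dd_s=np.array([[0.0, 0.0, 1.8], [0.0, 0.0, -2.0]]),
    )
    sd = SILKWORM_RESIDUAL_SD if residual_sd is None else residual_sd
    variance = VarianceComponents(
        var_s=0.0, var_as=5.0, var_ds=5.0,
        var_aas=5.0, var_ads=5.0, var_das=5.0, var_dds=5.0,
        var_e=sd * sd,
    )
    return ScenarioConfig(
        map=gmap, qtls=qtls, epistases=epistases, variance=variance,
        n=n, sex_ratio=0.5, mu=10.0, design=design,
        sex_effects=sex_effects, seed=seed,
    )


def variance_audit(cfg, n=100_000, seed=0):
    """Realized variance decomposition of a scenario at large n.

    Returns the empirical variances of the fixed-genetic, sex-interaction
    and residual phenotype components plus their fractions of the total.
    Used to calibrate the residual variance of the built-in scenario.
    """
    pop = simulate_f2(cfg.with_(n=n), seed=seed)
    t = pop.truth
    parts = {
        "genetic": float(np.var(t["g_fixed"])),
        "gxs": float(np.var(t["g_sex"])),
        "residual": float(np.var(t["residual"])),
    }
    total = float(np.var(t["g_fixed"] + t["g_sex"] + t["residual"]))
    fractions = {k: v / total for k, v in parts.items()}
    return {"variances": parts, "total": total, "fractions": fractions}
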