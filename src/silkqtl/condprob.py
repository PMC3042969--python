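"""Conditional QTL-genotype probabilities given flanking markers.

The silkworm F2 design is *achiasmate*: the female F1 transmits one of her
two parental chromosomes intact (no crossing-over), while the male F1
produces ordinary recombinant gametes.  An F2 individual therefore carries
one intact maternal haplotype plus one recombinant paternal haplotype,
which changes the conditional distribution of an unobserved QTL genotype
given flanking-marker genotypes relative to the standard (chiasmate) F2.

Notation: for a putative QTL Q between flanking markers M+ (left) and M-
(right), ``r1`` is the recombination fraction M+..Q, ``r2`` is Q..M-, and
``r`` the fraction across the whole interval; ``s* = 1 - r*``.  Under no
interference, ``r = r1(1-r2) + r2(1-r1)``.

Genotype coding: ``MM = 2``, ``Mm = 1``, ``mm = 0``, missing = ``-1``.
Additive coefficient ``x_A = P(QQ) - P(qq)`` (coding +1/0/-1); dominance
coefficient ``x_D = 0.5 P(Qq) - 0.5 (P(QQ) + P(qq))`` (coding +0.5 for the
heterozygote, -0.5 for either homozygote).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genmap import haldane_to_recomb

__all__ = [
    "MM",
    "HET",
    "mm",
    "MISSING",
    "FlankingContext",
    "CondProb",
    "CoeffPair",
    "EpistasisCoeffs",
    "AchiasmateImpossibleError",
    "MissingGenotypeError",
    "split_recomb",
    "cond_prob_achiasmate",
    "cond_prob_chiasmate",
    "conditional_table",
    "coefficient_table",
    "coefficients",
    "epistasis_coefficients",
    "two_point_probs",
    "genotype_posteriors",
    "expected_marker_coeffs",
]

MM, HET, mm = 2, 1, 0
MISSING = -1

#: marker classes that cannot occur in an achiasmate F2 for linked markers:
#: the intact maternal haplotype fixes both marker alleles to the same
#: parental origin, so opposite homozygotes at the two flanks are impossible.
ACHIASMATE_IMPOSSIBLE = frozenset({(MM, mm), (mm, MM)})


class AchiasmateImpossibleError(ValueError):
    """Marker class cannot segregate in an achiasmate F2 (data/design mismatch)."""


class MissingGenotypeError(ValueError):
    """Flanking genotype is missing where an observed genotype is required."""


def split_recomb(r, r1):
    """Recombination fraction ``r2`` of the right sub-interval.

    Solves the no-interference composition ``r = r1(1-r2) + r2(1-r1)``
    for ``r2``.  Under Haldane's map function this agrees exactly with
    converting the remaining map distance.
    """
    r = np.asarray(r, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 > r + 1e-12):
        raise ValueError("r1 must not exceed r")
    return (r - r1) / (1.0 - 2.0 * r1)


@dataclass(frozen=True)
class CondProb:
    """P(QQ), P(Qq), P(qq) for one flanking-marker class."""

    pQQ: float
    pQq: float
    pqq: float

    def __post_init__(self):
        total = self.pQQ + self.pQq + self.pqq
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"conditional probabilities sum to {total}, not 1")

    def as_array(self):
        return np.array([self.pQQ, self.pQq, self.pqq])


@dataclass(frozen=True)
class CoeffPair:
    """Expected additive and dominance coefficients of one locus."""

    xA: float
    xD: float


@dataclass(frozen=True)
class EpistasisCoeffs:
    """Products of two loci's additive/dominance coefficients."""

    xAA: float
    xAD: float
    xDA: float
    xDD: float


@dataclass(frozen=True)
class FlankingContext:
    """Flanking-marker genotypes and the recombination geometry around a QTL."""

    left: int
    right: int
    r1: float
    r2: float

    def __post_init__(self):
        for name, value in (("r1", self.r1), ("r2", self.r2)):
            if not (0.0 <= value <= 0.5):
                raise ValueError(f"{name}={value} outside [0, 0.5]")

    @property
    def r(self):
        return self.r1 * (1 - self.r2) + self.r2 * (1 - self.r1)

    @property
    def s1(self):
        return 1.0 - self.r1

    @property
    def s2(self):
        return 1.0 - self.r2

    @property
    def s(self):
        return 1.0 - self.r


def _achiasmate_rows(r1, r2):
    """Dict (left, right) -> (pQQ, pQq, pqq); infeasible classes absent.

    Derived from gamete enumeration: the maternal gamete is one of the two
    intact parental haplotypes (probability 1/2 each); the paternal gamete
    follows the no-interference three-locus distribution.
    """
    s1, s2 = 1.0 - r1, 1.0 - r2
    r = r1 * s2 + r2 * s1
    s = 1.0 - r
    return {
        (MM, MM): (s1 * s2 / s, r1 * r2 / s, 0.0),
        (MM, HET): (s1 * r2 / r, r1 * s2 / r, 0.0),
        (HET, MM): (r1 * s2 / r, s1 * r2 / r, 0.0),
        (HET, HET): (r1 * r2 / (2 * s), s1 * s2 / s, r1 * r2 / (2 * s)),
        (HET, mm): (0.0, s1 * r2 / r, r1 * s2 / r),
        (mm, HET): (0.0, r1 * s2 / r, s1 * r2 / r),
        (mm, mm): (0.0, r1 * r2 / s, s1 * s2 / s),
    }


def _chiasmate_rows(r1, r2):
    """Dict (left, right) -> (pQQ, pQq, pqq) for the standard F2 design."""
    s1, s2 = 1.0 - r1, 1.0 - r2
    r = r1 * s2 + r2 * s1
    s = 1.0 - r
    sr = s * r
    s2r2 = s * s + r * r
    return {
        (MM, MM): (s1 * s1 * s2 * s2 / (s * s), 2 * s1 * s2 * r1 * r2 / (s * s),
                   r1 * r1 * r2 * r2 / (s * s)),
        (MM, HET): (s1 * s2 * s1 * r2 / sr,
                    (s1 * s2 * r1 * s2 + r1 * r2 * s1 * r2) / sr,
                    r1 * r2 * r1 * s2 / sr),
        (MM, mm): (s1 * s1 * r2 * r2 / (r * r), 2 * r1 * s1 * r2 * s2 / (r * r),
                   r1 * r1 * s2 * s2 / (r * r)),
        (HET, MM): (s1 * s2 * r1 * s2 / sr,
                    (s1 * s2 * s1 * r2 + r1 * r2 * r1 * s2) / sr,
                    r1 * r2 * s1 * r2 / sr),
        (HET, HET): (2 * s1 * s2 * r1 * r2 / s2r2,
                     (s1 * s1 * s2 * s2 + r1 * r1 * r2 * r2
                      + s1 * s1 * r2 * r2 + r1 * r1 * s2 * s2) / s2r2,
                     2 * s1 * s2 * r1 * r2 / s2r2),
        (HET, mm): (r1 * r2 * s1 * r2 / sr,
                    (s1 * s2 * s1 * r2 + r1 * r2 * r1 * s2) / sr,
                    s1 * s2 * r1 * s2 / sr),
        (mm, MM): (r1 * r1 * s2 * s2 / (r * r), 2 * r1 * s1 * r2 * s2 / (r * r),
                   s1 * s1 * r2 * r2 / (r * r)),
        (mm, HET): (r1 * r2 * r1 * s2 / sr,
                    (s1 * s2 * r1 * s2 + r1 * r2 * s1 * r2) / sr,
                    s1 * s2 * s1 * r2 / sr),
        (mm, mm): (r1 * r1 * r2 * r2 / (s * s), 2 * s1 * s2 * r1 * r2 / (s * s),
                   s1 * s1 * s2 * s2 / (s * s)),
    }


def _check_observed(ctx):
    if ctx.left not in (MM, HET, mm) or ctx.right not in (MM, HET, mm):
        raise MissingGenotypeError(
            f"flanking genotypes must be observed; got ({ctx.left}, {ctx.right})"
        )


def cond_prob_achiasmate(ctx):
    """Conditional QTL-genotype probabilities in an achiasmate F2.

    Degenerate sub-intervals (``r1 == 0`` or ``r2 == 0``) place the QTL on
    a marker and return the corresponding point mass where defined.
    """
    _check_observed(ctx)
    key = (ctx.left, ctx.right)
    if key in ACHIASMATE_IMPOSSIBLE:
        raise AchiasmateImpossibleError(
            f"marker class {key} cannot occur in an achiasmate F2 "
            "(opposite homozygotes at linked flanking markers)"
        )
    rows = _achiasmate_rows(*_degenerate_safe(ctx))
    return CondProb(*rows[key])


def cond_prob_chiasmate(ctx):
    """Conditional QTL-genotype probabilities in a standard (chiasmate) F2."""
    _check_observed(ctx)
    rows = _chiasmate_rows(*_degenerate_safe(ctx))
    return CondProb(*rows[(ctx.left, ctx.right)])


_EPS_R = 1e-14


def _degenerate_safe(ctx):
    # r1 = r2 = 0 makes class denominators vanish; nudge off the boundary so
    # the coincident-locus limit (a point mass) is returned exactly to 1e-12.
    r1 = max(float(ctx.r1), _EPS_R)
    r2 = max(float(ctx.r2), _EPS_R)
    return r1, r2


def conditional_table(design, r1, r2):
    """(3, 3, 3) array: P[left, right, (qq, Qq, QQ) reversed-index].

    ``P[gl, gr, k]`` is the probability of QTL genotype code ``k`` (0 = qq,
    1 = Qq, 2 = QQ) given flanking codes; achiasmate-impossible classes are
    NaN.  Used as a vectorized lookup during genome scans.
    """
    r1, r2 = max(float(r1), _EPS_R), max(float(r2), _EPS_R)
    if design == "achiasmate":
        rows = _achiasmate_rows(r1, r2)
    elif design == "chiasmate":
        rows = _chiasmate_rows(r1, r2)
    else:
        raise ValueError(f"unknown design {design!r}")
    table = np.full((3, 3, 3), np.nan)
    for (gl, gr), (pQQ, pQq, pqq) in rows.items():
        table[gl, gr] = (pqq, pQq, pQQ)
    return table


def coefficients(cp):
    """Expected additive/dominance coefficients from a conditional law."""
    xA = cp.pQQ - cp.pqq
    xD = 0.5 * cp.pQq - 0.5 * (cp.pQQ + cp.pqq)
    return CoeffPair(xA=xA, xD=xD)


def coefficient_table(design, r1, r2):
    """(3, 3) arrays (XA, XD) of expected coefficients per flanking class."""
    table = conditional_table(design, r1, r2)
    xA = table[..., 2] - table[..., 0]
    xD = 0.5 * table[..., 1] - 0.5 * (table[..., 0] + table[..., 2])
    return xA, xD


def epistasis_coefficients(ci, cj):
    """Coefficients of the four digenic epistatic effects: products of
    the two loci's additive/dominance coefficients."""
    return EpistasisCoeffs(
        xAA=ci.xA * cj.xA,
        xAD=ci.xA * cj.xD,
        xDA=ci.xD * cj.xA,
        xDD=ci.xD * cj.xD,
    )


def two_point_probs(design, geno, rho):
    """P(qq, Qq, QQ) given a single linked marker at recombination ``rho``."""
    rho = max(float(rho), _EPS_R)
    s = 1.0 - rho
    if design == "achiasmate":
        rows = {
            MM: (s, rho, 0.0),
            HET: (rho / 2, s, rho / 2),
            mm: (0.0, rho, s),
        }
    else:
        rows = {
            MM: (s * s, 2 * s * rho, rho * rho),
            HET: (s * rho, s * s + rho * rho, rho * s),
            mm: (rho * rho, 2 * rho * s, s * s),
        }
    pQQ, pQq, pqq = rows[geno]
    return np.array([pqq, pQq, pQQ])


# ---------------------------------------------------------------------------
# Multipoint genotype posteriors (missing-marker imputation)
# ---------------------------------------------------------------------------


def _forward_backward(n_states, init, transitions, emit):
    """Posterior state probabilities of a small HMM (positions x states)."""
    L = emit.shape[0]
    alpha = np.empty((L, n_states))
    a = init * emit[0]
    norm = a.sum()
    if norm == 0:
        return None
    alpha[0] = a / norm
    log_lik = np.log(norm)
    for j in range(1, L):
        a = (alpha[j - 1] @ transitions[j - 1]) * emit[j]
        norm = a.sum()
        if norm == 0:
            return None
        alpha[j] = a / norm
        log_lik += np.log(norm)
    beta = np.ones(n_states)
    post = np.empty((L, n_states))
    post[L - 1] = alpha[L - 1]
    for j in range(L - 2, -1, -1):
        beta = transitions[j] @ (beta * emit[j + 1])
        beta /= beta.max()
        p = alpha[j] * beta
        post[j] = p / p.sum()
    return post, log_lik


def genotype_posteriors(positions, geno_row, design):
    """P(genotype | observed markers) at every locus of one chromosome.

    ``positions`` are locus cM positions, ``geno_row`` the per-locus codes
    of one individual (``MISSING`` allowed).  Full multipoint conditioning:

    * achiasmate — a chromosome-wide latent indicator of which maternal
      haplotype was transmitted, combined with a first-order Markov chain
      for the paternal allele along the chromosome;
    * chiasmate — a joint four-state Markov chain for the two gametes.

    Returns an (L, 3) array of P(code 0, 1, 2).  A fully missing chromosome
    yields the marginal 1:2:1 at every locus.
    """
    positions = np.asarray(positions, dtype=float)
    geno_row = np.asarray(geno_row)
    L = len(positions)
    rs = haldane_to_recomb(np.diff(positions)) if L > 1 else np.empty(0)
    observed = geno_row >= 0
    if not observed.any():
        return np.tile([0.25, 0.5, 0.25], (L, 1))

    if design == "achiasmate":
        # maternal allele f is constant (1 for the dominant-parent haplotype);
        # paternal allele m follows the recombination chain.
        trans = [np.array([[1 - r, r], [r, 1 - r]]) for r in rs]
        total = np.zeros((L, 3))
        weight = []
        branch_posts = []
        for f in (1, 0):
            emit = np.ones((L, 2))
            for j in np.nonzero(observed)[0]:
                m = geno_row[j] - f
                emit[j] = 0.0
                if m in (0, 1):
                    emit[j, m] = 1.0
            result = _forward_backward(2, np.array([0.5, 0.5]), trans, emit)
            branch_posts.append((f, result))
            weight.append(0.0 if result is None else np.exp(result[1]))
        weight = np.asarray(weight) * 0.5
        weight /= weight.sum()
        for (f, result), w in zip(branch_posts, weight):
            if result is None:
                continue
            post = result[0]  # (L, 2) over paternal allele
            for m in (0, 1):
                total[np.arange(L), f + m] += w * post[:, m]
        return total

    if design == "chiasmate":
        # joint state (f, m): both gametes recombine with the same fractions
        states = [(0, 0), (0, 1), (1, 0), (1, 1)]
        trans = []
        for r in rs:
            k = np.array([[1 - r, r], [r, 1 - r]])
            trans.append(np.kron(k, k))
        emit = np.ones((L, 4))
        codes = np.array([f + m for f, m in states])
        for j in np.nonzero(observed)[0]:
            emit[j] = (codes == geno_row[j]).astype(float)
        result = _forward_backward(4, np.full(4, 0.25), trans, emit)
        if result is None:
            raise ValueError("observed genotypes have zero probability")
        post = result[0]
        out = np.zeros((L, 3))
        for k, code in enumerate(codes):
            out[:, code] += post[:, k]
        return out

    raise ValueError(f"unknown design {design!r}")


def expected_marker_coeffs(pop, marker_id, design=None):
    """Per-individual expected marker coefficients (zeta_A, zeta_D).

    Observed genotypes map to ``zeta_A`` in {1, 0, -1} and ``zeta_D`` in
    {-0.5, 0.5}.  Missing genotypes get expectations from the multipoint
    genotype posterior conditioned on the individual's observed markers on
    that chromosome (design-appropriate transition structure).  Individuals
    with a fully missing chromosome fall back to the marginal 1:2:1
    expectation (0, 0), with a warning.
    """
    design = design or pop.design
    c, j = pop.map.locate(marker_id)
    lo, hi = pop.map.marker_offsets()[c], pop.map.marker_offsets()[c + 1]
    geno = pop.geno[:, lo:hi]
    g = geno[:, j]
    zA = np.where(g >= 0, g - 1.0, 0.0)
    zD = np.where(g == HET, 0.5, -0.5)
    zD[g < 0] = 0.0
    positions = pop.map.chromosomes[c].positions
    missing_rows = np.nonzero(g < 0)[0]
    warned = False
    for i in missing_rows:
        row = geno[i]
        if not (row >= 0).any() and not warned:
            warnings.warn(
                "fully missing chromosome: using marginal 1:2:1 expectation",
                stacklevel=2,
            )
            warned = True
        post = genotype_posteriors(positions, row, design)[j]
        zA[i] = post[2] - post[0]
        zD[i] = 0.5 * post[1] - 0.5 * (post[0] + post[2])
    return zA, zD
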