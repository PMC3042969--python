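import numpy as np
import pytest

from silkqtl.genmap import Chromosome, GeneticMap, haldane_to_recomb
from silkqtl.simulate import (
    QTLSpec,
    ScenarioConfig,
    VarianceComponents,
    silkworm_scenario,
    simulate_f2,
)


def male_gamete_probs(r1, r2):
    """No-interference three-locus gamete distribution of a recombinant
    parent: dict (allele_left, allele_Q, allele_right) -> probability."""
    probs = {}
    for a in (0, 1):
        for q in (0, 1):
            for b in (0, 1):
                p = 0.5
                p *= r1 if a != q else (1 - r1)
                p *= r2 if q != b else (1 - r2)
                probs[(a, q, b)] = p
    return probs


def enumerate_conditional(design, r1, r2):
    """Brute-force conditional law P(QTL geno | marker class) by summing
    over all female x male gamete combinations.

    Independent of the closed-form implementation: builds the joint
    distribution of (left marker, QTL, right marker) genotypes from the
    gamete processes and conditions on the marker class.
    """
    male = male_gamete_probs(r1, r2)
    if design == "achiasmate":
        female = {(1, 1, 1): 0.5, (0, 0, 0): 0.5}
    else:
        female = male
    joint = {}
    for fg, pf in female.items():
        for mg, pm in male.items():
            gl, gq, gr = (fg[0] + mg[0], fg[1] + mg[1], fg[2] + mg[2])
            joint[(gl, gr, gq)] = joint.get((gl, gr, gq), 0.0) + pf * pm
    out = {}
    for gl in (0, 1, 2):
        for gr in (0, 1, 2):
            total = sum(joint.get((gl, gr, gq), 0.0) for gq in (0, 1, 2))
            if total > 0:
                out[(gl, gr)] = np.array(
                    [joint.get((gl, gr, gq), 0.0) / total for gq in (2, 1, 0)]
                )  # order: P(QQ), P(Qq), P(qq)
    return out


@pytest.fixture(scope="session")
def tiny_map():
    """Two chromosomes, few markers, uneven spacing."""
    return GeneticMap(chromosomes=(
        Chromosome("1", ("m1_1", "m1_2", "m1_3", "m1_4"),
                   np.array([0.0, 10.0, 25.0, 40.0])),
        Chromosome("2", ("m2_1", "m2_2", "m2_3"),
                   np.array([0.0, 15.0, 30.0])),
    ))


@pytest.fixture(scope="session")
def strong_qtl_config(tiny_map):
    """One strong QTL per chromosome; modest noise; no sex interactions."""
    return ScenarioConfig(
        map=tiny_map,
        qtls=(QTLSpec("qA", "1", 18.0, a=2.5, d=-1.0),
              QTLSpec("qB", "2", 12.0, a=-2.0, d=0.8)),
        variance=VarianceComponents(var_e=4.0),
        n=250,
        mu=5.0,
    )


@pytest.fixture(scope="session")
def strong_pop(strong_qtl_config):
    return simulate_f2(strong_qtl_config, seed=101)


@pytest.fixture(scope="session")
def silkworm_pop():
    """One replicate of the built-in 5-chromosome / 7-QTL scenario."""
    return simulate_f2(silkworm_scenario(), seed=2024)


__all__ = ["male_gamete_probs", "enumerate_conditional"]
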