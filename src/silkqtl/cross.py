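"""The F2 cross-population container tying genotypes, sexes and phenotypes
to a genetic map."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .condprob import HET, expected_marker_coeffs
from .genmap import GeneticMap

__all__ = ["CrossPopulation"]


@dataclass
class CrossPopulation:
    """Marker genotypes, sex labels and phenotypes of one F2 population.

    ``geno`` is individuals x markers with codes 2 (MM), 1 (Mm), 0 (mm) and
    -1 (missing); marker columns follow ``map.marker_ids`` order.  ``sex``
    holds labels 1/2.  ``design`` records the gametogenesis model the
    population segregates under ("achiasmate" or "chiasmate") and selects
    the default conditional-probability backend for imputation.

    ``truth``, present for simulated populations, records the generating
    architecture (true QTL genotypes, realized random effects) for test
    harnesses; it is never used by the mapping procedure itself.
    """

    map: GeneticMap
    geno: np.ndarray
    sex: np.ndarray
    y: np.ndarray
    design: str = "achiasmate"
    ids: tuple = None
    truth: dict = None
    _coeff_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.y = np.asarray(self.y, dtype=float)
        n, m = self.geno.shape
        if m != self.map.n_markers:
            raise ValueError(
                f"genotype matrix has {m} columns but the map has "
                f"{self.map.n_markers} markers"
            )
        if len(self.sex) != n or len(self.y) != n:
            raise ValueError("sex/phenotype length does not match genotypes")
        levels = set(np.unique(self.sex).tolist())
        if not levels <= {1, 2}:
            raise ValueError(f"sex labels must be in {{1, 2}}; got {sorted(levels)}")
        if self.design not in ("achiasmate", "chiasmate"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.ids is None:
            self.ids = tuple(f"ind{i + 1}" for i in range(n))
        else:
            self.ids = tuple(self.ids)
            if len(self.ids) != n:
                raise ValueError("ids length does not match genotypes")

    @property
    def n(self):
        return self.geno.shape[0]

    def sex_indicator(self):
        """(n, 2) indicator matrix of the two sex levels."""
        return np.column_stack([(self.sex == 1).astype(float),
                                (self.sex == 2).astype(float)])

    def chrom_slice(self, c):
        offsets = self.map.marker_offsets()
        return slice(int(offsets[c]), int(offsets[c + 1]))

    def marker_coeffs(self, design=None):
        """(ZA, ZD): n x markers expected marker-effect coefficients.

        Observed genotypes use the exact coding (zeta_A in {1, 0, -1},
        zeta_D in {-0.5, 0.5}); missing cells carry multipoint expectations
        under ``design`` (defaults to the population's own design).
        Cached per design.
        """
        design = design or self.design
        if design not in self._coeff_cache:
            if (self.geno >= 0).all():
                zA = self.geno.astype(float) - 1.0
                zD = np.where(self.geno == HET, 0.5, -0.5)
            else:
                cols_A, cols_D = [], []
                for marker in self.map.marker_ids:
                    a, d = expected_marker_coeffs(self, marker, design)
                    cols_A.append(a)
                    cols_D.append(d)
                zA = np.column_stack(cols_A)
                zD = np.column_stack(cols_D)
            self._coeff_cache[design] = (zA, zD)
        return self._coeff_cache[design]
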