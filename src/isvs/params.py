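"""Simulation parameters for ISVS cohort experiments.

The population model is parameterised the way recessive-disease gene
screens are usually described:

* ``disease_prevalence`` (f1) — frequency of the disease in the general
  population.
* ``gene_fraction`` (f2) — fraction of disease cases attributable to
  bi-allelic variants in the gene under study.
* their product f3 = f1 * f2 is the general-population frequency of
  bi-allelic individuals, so under Hardy-Weinberg the cumulative
  pathogenic allele frequency is q = sqrt(f3).

``cohort_size`` is the number of ascertained *disease* patients, of whom
an expected fraction f2 owe their disease to the gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace


class ParameterError(ValueError):
    """A simulation parameter is outside its admissible domain."""


@dataclass(frozen=True)
class SimParams:
    """Configuration of one simulated ISVS experiment batch.

    Defaults describe a hearing-loss-style screen: 2000 ascertained
    patients, disease prevalence 1/1000, 2% of cases caused by the gene,
    10 distinct pathogenic and 20 distinct non-pathogenic rare variants,
    allele-frequency spectra drawn from Beta(0.5, 10) and rescaled.
    """

    cohort_size: int = 2000
    disease_prevalence: float = 0.001
    gene_fraction: float = 0.02
    n_pathogenic: int = 10
    n_nonpathogenic: int = 20
    cum_nonpath_freq: float = 0.05
    beta_alpha: float = 0.5
    beta_beta: float = 10.0
    n_sims: int = 1000
    master_seed: int = 0
    population_proportions: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not isinstance(self.cohort_size, int) or self.cohort_size < 1:
            raise ParameterError("cohort_size must be a positive integer")
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ParameterError("disease_prevalence must lie in (0, 1)")
        if not 0.0 < self.gene_fraction <= 1.0:
            raise ParameterError("gene_fraction must lie in (0, 1]")
        if not isinstance(self.n_pathogenic, int) or self.n_pathogenic < 1:
            raise ParameterError("n_pathogenic must be a positive integer")
        if not isinstance(self.n_nonpathogenic, int) or self.n_nonpathogenic < 0:
            raise ParameterError("n_nonpathogenic must be a non-negative integer")
        if not 0.0 <= self.cum_nonpath_freq < 1.0:
            raise ParameterError("cum_nonpath_freq must lie in [0, 1)")
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ParameterError("beta spectrum shape parameters must be positive")
        if not isinstance(self.n_sims, int) or self.n_sims < 1:
            raise ParameterError("n_sims must be a positive integer")
        props = tuple(float(p) for p in self.population_proportions)
        object.__setattr__(self, "population_proportions", props)
        if len(props) == 0 or any(p < 0 for p in props):
            raise ParameterError("population_proportions must be non-negative")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ParameterError("population_proportions must sum to 1")
        f3 = self.biallelic_pop_freq
        if not 0.0 < f3 < 1.0:
            raise ParameterError("f1 * f2 must lie in (0, 1)")
        if math.sqrt(f3) + self.cum_nonpath_freq >= 1.0:
            raise ParameterError(
                "cumulative pathogenic (sqrt(f1*f2)) plus non-pathogenic "
                "allele frequency must stay below 1"
            )

    @property
    def biallelic_pop_freq(self) -> float:
        """f3: general-population frequency of bi-allelic individuals."""
        return self.disease_prevalence * self.gene_fraction

    @property
    def cum_path_freq(self) -> float:
        """q: cumulative pathogenic allele frequency, sqrt(f1*f2)."""
        return math.sqrt(self.biallelic_pop_freq)

    @property
    def n_populations(self) -> int:
        return len(self.population_proportions)

    @property
    def n_variants(self) -> int:
        return self.n_pathogenic + self.n_nonpathogenic

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            f.name: (list(v) if isinstance(v := getattr(self, f.name), tuple) else v)
            for f in fields(self)
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimParams":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        clean = dict(data)
        if "population_proportions" in clean:
            clean["population_proportions"] = tuple(clean["population_proportions"])
        return cls(**clean)


FIELD_NAMES = tuple(f.name for f in fields(SimParams))
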