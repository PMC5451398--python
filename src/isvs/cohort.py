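"""Synthetic recessive-disease cohorts with phased variant carriage.

A cohort is a matrix of phased genotypes over ``m`` pathogenic and ``k``
non-pathogenic rare variants. Patients whose disease is caused by the
gene carry pathogenic variants on both haplotypes (homozygous or
compound heterozygous); the remaining patients carry pathogenic alleles
only at general-population rates, conditioned on *not* being bi-allelic.
Every patient additionally carries each non-pathogenic variant on each
haplotype independently at its population allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterError, SimParams

PATHOGENIC = "pathogenic"
NON_PATHOGENIC = "non-pathogenic"

GENE_CAUSED = "gene_caused"
OTHER_CAUSE = "other_cause"


def sample_spectrum(
    n_variants: int,
    alpha: float,
    beta: float,
    target_cum: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample an allele-frequency spectrum rescaled to a cumulative total.

    Draws ``n_variants`` values from Beta(alpha, beta) and rescales them
    so that their sum equals ``target_cum`` exactly (up to float
    round-off below 1e-12). The Beta(0.5, 10) default of the simulator
    produces the heavily skewed spectra typical of rare disease alleles:
    one or two common-ish variants and a long tail of very rare ones.
    """
    if not isinstance(n_variants, (int, np.integer)) or n_variants < 1:
        raise ParameterError("n_variants must be a positive integer")
    if not 0.0 < target_cum < 1.0:
        raise ParameterError("target_cum must lie in (0, 1)")
    if alpha <= 0 or beta <= 0:
        raise ParameterError("beta shape parameters must be positive")
    draws = rng.beta(alpha, beta, size=int(n_variants))
    # a draw of exactly 0.0 would produce a frequency-0 variant; redraw
    while np.any(draws <= 0.0):
        zero = draws <= 0.0
        draws[zero] = rng.beta(alpha, beta, size=int(zero.sum()))
    freqs = draws * (target_cum / draws.sum())
    # force the invariant sum == target_cum despite float rounding
    freqs[-1] += target_cum - freqs.sum()
    return freqs


@dataclass(frozen=True)
class AlleleSpectrum:
    """Per-population allele frequencies of the simulated variant set.

    ``freqs`` has shape (n_populations, n_variants); variant order is all
    pathogenic variants first, then all non-pathogenic ones.
    """

    variant_ids: tuple[str, ...]
    classes: tuple[str, ...]
    freqs: np.ndarray
    cum_path_target: float
    cum_nonpath_target: float

    def __post_init__(self) -> None:
        freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "freqs", freqs)
        n_var = len(self.variant_ids)
        if len(self.classes) != n_var or freqs.shape[1] != n_var:
            raise ParameterError("variant_ids, classes and freqs disagree in length")
        if np.any(freqs <= 0.0) or np.any(freqs >= 1.0):
            raise ParameterError("allele frequencies must lie in (0, 1)")
        path = self.pathogenic_mask
        for g in range(freqs.shape[0]):
            if abs(freqs[g, path].sum() - self.cum_path_target) > 1e-12:
                raise ParameterError("pathogenic frequencies do not sum to target")
            if self.cum_nonpath_target > 0 and abs(
                freqs[g, ~path].sum() - self.cum_nonpath_target
            ) > 1e-12:
                raise ParameterError("non-pathogenic frequencies do not sum to target")

    @property
    def pathogenic_mask(self) -> np.ndarray:
        return np.array([c == PATHOGENIC for c in self.classes], dtype=bool)

    @property
    def n_populations(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_variants(self) -> int:
        return self.freqs.shape[1]


def sample_spectra(params: SimParams, rng: np.random.Generator) -> AlleleSpectrum:
    """Sample pathogenic + non-pathogenic spectra for every population.

    Each population receives an independently sampled spectrum over the
    same variant identities, rescaled to the same cumulative targets, so
    that in mixture cohorts the variant set is shared but frequencies
    differ between populations.
    """
    m, k = params.n_pathogenic, params.n_nonpathogenic
    ids = tuple(f"P{i + 1}" for i in range(m)) + tuple(f"B{j + 1}" for j in range(k))
    classes = (PATHOGENIC,) * m + (NON_PATHOGENIC,) * k
    rows = []
    for _ in range(params.n_populations):
        p = sample_spectrum(m, params.beta_alpha, params.beta_beta, params.cum_path_freq, rng)
        if k > 0:
            r = sample_spectrum(
                k, params.beta_alpha, params.beta_beta, params.cum_nonpath_freq, rng
            )
            rows.append(np.concatenate([p, r]))
        else:
            rows.append(p)
    return AlleleSpectrum(
        variant_ids=ids,
        classes=classes,
        freqs=np.vstack(rows),
        cum_path_target=params.cum_path_freq,
        cum_nonpath_target=params.cum_nonpath_freq if k > 0 else 0.0,
    )


@dataclass
class Cohort:
    """Phased carriage matrix for one simulated disease cohort.

    ``maternal`` and ``paternal`` are (N, V) boolean arrays; a patient is
    *bi-allelic pathogenic* when both haplotypes carry at least one
    pathogenic variant, which by construction is equivalent to the
    ``gene_caused`` label.
    """

    maternal: np.ndarray
    paternal: np.ndarray
    gene_caused: np.ndarray
    population_index: np.ndarray
    spectrum: AlleleSpectrum

    @property
    def n_patients(self) -> int:
        return self.maternal.shape[0]

    @property
    def n_variants(self) -> int:
        return self.maternal.shape[1]

    @property
    def carriers(self) -> np.ndarray:
        """(N, V) boolean: carries >=1 copy of the variant."""
        return self.maternal | self.paternal

    @property
    def biallelic_pathogenic(self) -> np.ndarray:
        """(N,) boolean: pathogenic variant on both haplotypes."""
        path = self.spectrum.pathogenic_mask
        return self.maternal[:, path].any(axis=1) & self.paternal[:, path].any(axis=1)

    @property
    def cause_labels(self) -> np.ndarray:
        return np.where(self.gene_caused, GENE_CAUSED, OTHER_CAUSE)


def build_cohort(
    params: SimParams, spectrum: AlleleSpectrum, rng: np.random.Generator
) -> Cohort:
    """Generate one cohort of ``params.cohort_size`` disease patients.

    Each patient is gene-caused with probability ``gene_fraction``; those
    patients receive one pathogenic allele per haplotype, drawn from the
    pathogenic spectrum of their population. Other-cause patients draw
    per-haplotype Bernoulli carriage of each pathogenic variant at its
    population frequency and are rejection-resampled until not
    bi-allelic. Non-pathogenic carriage is Bernoulli per haplotype per
    variant for everyone.
    """
    if spectrum.n_populations != params.n_populations:
        raise ParameterError("spectrum population count does not match params")
    if spectrum.n_variants != params.n_variants:
        raise ParameterError("spectrum variant count does not match params")

    n = params.cohort_size
    v = params.n_variants
    path_idx = np.where(spectrum.pathogenic_mask)[0]
    nonpath_idx = np.where(~spectrum.pathogenic_mask)[0]

    if params.n_populations == 1:
        pop = np.zeros(n, dtype=np.int64)
    else:
        pop = rng.choice(
            params.n_populations, size=n, p=np.asarray(params.population_proportions)
        )
    gene_caused = rng.random(n) < params.gene_fraction

    maternal = np.zeros((n, v), dtype=bool)
    paternal = np.zeros((n, v), dtype=bool)

    for g in range(params.n_populations):
        p_freqs = spectrum.freqs[g, path_idx]
        probs = p_freqs / p_freqs.sum()

        caused = np.where(gene_caused & (pop == g))[0]
        if caused.size:
            mat_allele = rng.choice(path_idx.size, size=caused.size, p=probs)
            pat_allele = rng.choice(path_idx.size, size=caused.size, p=probs)
            maternal[caused, path_idx[mat_allele]] = True
            paternal[caused, path_idx[pat_allele]] = True

        other = np.where(~gene_caused & (pop == g))[0]
        if other.size:
            mat_c = rng.random((other.size, path_idx.size)) < p_freqs
            pat_c = rng.random((other.size, path_idx.size)) < p_freqs
            bad = mat_c.any(axis=1) & pat_c.any(axis=1)
            while bad.any():
                nb = int(bad.sum())
                mat_c[bad] = rng.random((nb, path_idx.size)) < p_freqs
                pat_c[bad] = rng.random((nb, path_idx.size)) < p_freqs
                bad = mat_c.any(axis=1) & pat_c.any(axis=1)
            maternal[np.ix_(other, path_idx)] = mat_c
            paternal[np.ix_(other, path_idx)] = pat_c

        if nonpath_idx.size:
            members = np.where(pop == g)[0]
            r_freqs = spectrum.freqs[g, nonpath_idx]
            maternal[np.ix_(members, nonpath_idx)] = (
                rng.random((members.size, nonpath_idx.size)) < r_freqs
            )
            paternal[np.ix_(members, nonpath_idx)] = (
                rng.random((members.size, nonpath_idx.size)) < r_freqs
            )

    return Cohort(
        maternal=maternal,
        paternal=paternal,
        gene_caused=gene_caused,
        population_index=pop,
        spectrum=spectrum,
    )
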