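"""Assessment of observed variant tables from a real disease cohort.

Given, per variant, the patient and control het/hom carrier counts and
the list of partner variants found in its carriers, this module computes
allele frequencies, patient-vs-control Fisher exact tests, and the
simulation-calibrated pathogenicity evidence: the (x, y) cell counts of
the calibration table, the empirical pathogenicity probability, and the
SVM likelihood ratio. Phase is unknown in patients, so co-occurring
variants are presumed in trans; a homozygote is its own in-trans
partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .classify import CellTable, PathogenicityModel, likelihood_ratio
from .params import ParameterError

WILD_TYPE = "wt"


@dataclass(frozen=True)
class ObservedVariantRecord:
    """One observed variant's carrier and allele counts.

    ``partners`` maps partner-variant labels (the second variant found
    in each carrier; ``"wt"`` for carriers with none) to carrier counts.
    The number of bi-allelic carriers ``y`` is derived from the partner
    list as the number of carriers with a non-wild-type partner, unless
    given explicitly via ``n_biallelic``.
    """

    variant_id: str
    het_patients: int
    hom_patients: int
    allele_sum_patients: int
    het_controls: int = 0
    hom_controls: int = 0
    allele_sum_controls: int = 0
    partners: dict[str, int] = field(default_factory=dict)
    n_biallelic: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "het_patients",
            "hom_patients",
            "allele_sum_patients",
            "het_controls",
            "hom_controls",
            "allele_sum_controls",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.mut_alleles_patients > self.allele_sum_patients:
            raise ParameterError("patient mutated alleles exceed tested alleles")
        if self.allele_sum_controls and self.mut_alleles_controls > self.allele_sum_controls:
            raise ParameterError("control mutated alleles exceed tested alleles")
        if self.allele_sum_patients % 2 or self.allele_sum_controls % 2:
            raise ParameterError("allele sums must be even (two alleles per subject)")
        if self.partners and sum(self.partners.values()) != self.x:
            raise ParameterError(
                f"{self.variant_id}: partner counts must sum to the carrier count"
            )
        if self.y > self.x:
            raise ParameterError(f"{self.variant_id}: bi-allelic count exceeds carriers")

    @property
    def x(self) -> int:
        """Total carriers among patients (het + hom)."""
        return self.het_patients + self.hom_patients

    @property
    def y(self) -> int:
        """Carriers with a second (presumed in-trans) variant, homs included."""
        if self.n_biallelic is not None:
            return self.n_biallelic
        return sum(n for pid, n in self.partners.items() if pid != WILD_TYPE)

    @property
    def mut_alleles_patients(self) -> int:
        return self.het_patients + 2 * self.hom_patients

    @property
    def mut_alleles_controls(self) -> int:
        return self.het_controls + 2 * self.hom_controls


def allele_frequency(het: int, hom: int, allele_sum: int) -> float:
    """Percent mutated alleles: 100 * (het + 2*hom) / allele_sum, 2 decimals."""
    if allele_sum <= 0:
        raise ParameterError("allele_sum must be positive")
    if het < 0 or hom < 0:
        raise ParameterError("carrier counts must be non-negative")
    return round(100.0 * (het + 2 * hom) / allele_sum, 2)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p sums the hypergeometric probabilities of all tables with
    the observed margins whose point probability does not exceed the
    observed one (within a 1e-12 relative tolerance on the comparison).
    One-sided p is the upper tail in the enrichment direction of cell
    ``a`` (e.g. mutated alleles among patients).
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ParameterError("cell counts must be non-negative integers")
    n = a + b + c + d
    if n <= 0:
        raise ParameterError("the table must contain at least one observation")
    row1 = a + b
    col1 = a + c
    k_min = max(0, col1 - (c + d))
    k_max = min(col1, row1)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = float(hypergeom.pmf(a, n, row1, col1))
    if sided == "two":
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    elif sided == "one":
        p = float(pmf[support >= a].sum())
    else:
        raise ParameterError("sided must be 'one' or 'two'")
    if p > 1.0 - 1e-12:  # whole support included; absorb float round-off
        p = 1.0
    return p


def assess_variants(
    records: list[ObservedVariantRecord],
    table: CellTable,
    model: PathogenicityModel | None = None,
    *,
    sided: str = "two",
) -> pd.DataFrame:
    """Score observed variants against the simulation calibration.

    Per variant: patient/control allele frequencies, Fisher exact p on
    allele counts, the calibration table's observed and cumulative
    (x, y) cell counts, the empirical pathogenicity probability, and the
    SVM likelihood ratio (recomputed from ``model`` when given, else
    looked up from the table's exported ``svm_lr`` values). Variants
    whose carriers show no in-trans partner (y = 0) are flagged
    unsupported.
    """
    rows = []
    for rec in records:
        x, y = rec.x, rec.y
        obs = table.observed(x, y)
        cum = table.cumulative(x, y)
        prob = table.prob_pathogenic(x, y)
        if model is not None:
            lr = float(np.asarray(likelihood_ratio(model, x, y)).ravel()[0])
        else:
            lr = table.svm_lr.get((x, y), np.nan)
        fisher_p = fisher_exact_2x2(
            rec.mut_alleles_patients,
            rec.allele_sum_patients - rec.mut_alleles_patients,
            rec.mut_alleles_controls,
            rec.allele_sum_controls - rec.mut_alleles_controls,
            sided=sided,
        ) if rec.allele_sum_controls > 0 else np.nan
        rows.append(
            {
                "variant_id": rec.variant_id,
                "x": x,
                "y": y,
                "pat_allele_freq": allele_frequency(
                    rec.het_patients, rec.hom_patients, rec.allele_sum_patients
                ),
                "ctl_allele_freq": (
                    allele_frequency(rec.het_controls, rec.hom_controls, rec.allele_sum_controls)
                    if rec.allele_sum_controls > 0
                    else np.nan
                ),
                "fisher_p": fisher_p,
                "n_pat": obs[0] if obs else np.nan,
                "n_nonpat": obs[1] if obs else np.nan,
                "cum_pat": cum[0] if cum else np.nan,
                "cum_nonpat": cum[1] if cum else np.nan,
                "empirical_prob": prob if prob is not None else np.nan,
                "svm_lr": lr,
                "unsupported": y == 0,
            }
        )
    return pd.DataFrame(rows)
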