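"""The iterative sequencing and variant screening (ISVS) search.

One ISVS experiment starts from a single sequenced proband with a
bi-allelic pathogenic genotype. Each subsequent cycle (i) screens the
whole cohort for every newly revealed variant, and (ii) sequences the
full gene in every newly identified carrier, revealing all of their
variants. The search terminates when sequencing reveals no variant that
has not already been screened. The set of variants it can ever reach is
exactly the connected component of the seed patient in the bipartite
patient-variant carrier graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort


class ConsistencyError(ValueError):
    """A run result does not belong to the cohort it is evaluated against."""


@dataclass
class ISVSResult:
    """Outcome of one simulated ISVS experiment.

    ``screened``, ``detected`` are boolean masks over variants;
    ``sequenced`` is a boolean mask over patients. ``steps`` counts
    screen+sequence cycles: the seed's own sequencing is step 0 and the
    terminal cycle (whose sequencing reveals nothing new) is counted,
    since its cohort-wide screen was still performed.
    """

    steps: int
    screened: np.ndarray
    sequenced: np.ndarray
    detected: np.ndarray
    seed_patient: int | None
    trace: list[dict] = field(default_factory=list)

    @property
    def degenerate(self) -> bool:
        """True when the cohort contained no bi-allelic proband to seed from."""
        return self.seed_patient is None

    def candidate_explained(self, cohort: Cohort) -> np.ndarray:
        """Sequenced patients with two detected variants in trans (or one hom)."""
        det = self.detected
        mat = cohort.maternal[:, det].any(axis=1)
        pat = cohort.paternal[:, det].any(axis=1)
        return self.sequenced & mat & pat


@dataclass(frozen=True)
class RunMetrics:
    """Per-run performance summary of one ISVS experiment."""

    success: bool
    pat_fraction_detected: float
    mut_fraction_detected: float
    steps: int
    sequenced_sample_nr: int
    screened_vars_nr: int
    degenerate: bool = False


def run_isvs(cohort: Cohort, rng: np.random.Generator) -> ISVSResult:
    """Simulate one ISVS experiment on a cohort.

    The seed proband is chosen uniformly among bi-allelic pathogenic
    patients (the only random element). Screening is assumed perfect: it
    identifies every carrier, heterozygous or homozygous, of the assayed
    variant. A cohort without any bi-allelic patient yields a degenerate
    result (no seed, zero steps) rather than an error, mirroring a real
    experiment that cannot start without a proband.
    """
    n, v = cohort.n_patients, cohort.n_variants
    carriers = cohort.carriers
    biallelic = cohort.biallelic_pathogenic
    candidates = np.where(biallelic)[0]
    if candidates.size == 0:
        return ISVSResult(
            steps=0,
            screened=np.zeros(v, dtype=bool),
            sequenced=np.zeros(n, dtype=bool),
            detected=np.zeros(v, dtype=bool),
            seed_patient=None,
        )

    seed = int(rng.choice(candidates))
    sequenced = np.zeros(n, dtype=bool)
    sequenced[seed] = True
    detected = carriers[seed].copy()
    screened = np.zeros(v, dtype=bool)
    steps = 0
    trace: list[dict] = []

    while True:
        new_vars = detected & ~screened
        if not new_vars.any():
            break
        screened |= new_vars
        found = carriers[:, new_vars].any(axis=1)
        new_patients = found & ~sequenced
        sequenced |= new_patients
        if new_patients.any():
            detected |= carriers[new_patients].any(axis=0)
        steps += 1
        trace.append(
            {
                "step": steps,
                "screened_variants": np.where(new_vars)[0].tolist(),
                "sequenced_patients": np.where(new_patients)[0].tolist(),
            }
        )

    return ISVSResult(
        steps=steps,
        screened=screened,
        sequenced=sequenced,
        detected=detected,
        seed_patient=seed,
        trace=trace,
    )


def evaluate_run(
    cohort: Cohort, result: ISVSResult, *, all_pathogenic_denominator: bool = False
) -> RunMetrics:
    """Score one ISVS run against the cohort's ground truth.

    ``success`` requires every truly bi-allelic pathogenic patient to
    have been sequenced. ``mut_fraction_detected`` divides by the number
    of pathogenic variants with at least one carrier in the cohort;
    set ``all_pathogenic_denominator`` to divide by all pathogenic
    variants instead. Degenerate runs (no proband) are vacuously
    successful and report NaN fractions so that averages can skip them.
    """
    if result.sequenced.shape[0] != cohort.n_patients or (
        result.detected.shape[0] != cohort.n_variants
    ):
        raise ConsistencyError("result dimensions do not match cohort")

    if result.degenerate:
        return RunMetrics(
            success=True,
            pat_fraction_detected=float("nan"),
            mut_fraction_detected=float("nan"),
            steps=0,
            sequenced_sample_nr=0,
            screened_vars_nr=0,
            degenerate=True,
        )

    biallelic = cohort.biallelic_pathogenic
    n_biallelic = int(biallelic.sum())
    n_found = int((biallelic & result.sequenced).sum())

    path = cohort.spectrum.pathogenic_mask
    if all_pathogenic_denominator:
        present = path
    else:
        present = path & cohort.carriers.any(axis=0)
    n_present = int(present.sum())
    n_detected = int((present & result.detected).sum())

    return RunMetrics(
        success=n_found == n_biallelic,
        pat_fraction_detected=n_found / n_biallelic,
        mut_fraction_detected=(n_detected / n_present) if n_present else float("nan"),
        steps=result.steps,
        sequenced_sample_nr=int(result.sequenced.sum()),
        screened_vars_nr=int(result.screened.sum()),
    )
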