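"""Deterministic hand-built objects shared by tests, docs and the CLI.

``tmprss3_observed`` encodes the published TMPRSS3 screen of a Polish
sensorineural-hearing-loss cohort (2247 patients, 13 rare variants):
per variant, the patient and control het/hom carrier counts, the
numbers of tested alleles, and the partner variants found in each
carrier ("wt" = no second variant). The two toy cohorts exercise the
ISVS engine on graphs whose reachability is obvious by construction.
"""

from __future__ import annotations

import numpy as np

from .assess import ObservedVariantRecord
from .cohort import NON_PATHOGENIC, PATHOGENIC, AlleleSpectrum, Cohort

# variant_id, het_pat, hom_pat, allele_sum_pat, het_ctl, hom_ctl,
# allele_sum_ctl, partner list "id:count;..."
_TMPRSS3_ROWS = [
    ("p.H70Tfs*19", 20, 3, 4376, 0, 0, 1058,
     "p.A138E:7;p.M448T:4;p.H70Tfs*19:3;p.C194Mfs*17:3;wt:3;p.S124L:1;c.953-5A>G:1;p.D334Mfs*24:1"),
    ("p.A138E", 17, 2, 4604, 2, 0, 1918,
     "p.H70Tfs*19:7;wt:3;p.A138E:2;p.C73Y:1;p.R109W:1;p.S124L:1;p.C194Mfs*17:1;c.953-5A>G:1;p.D334Mfs*24:1;p.M448T:1"),
    ("p.M448T", 10, 0, 4596, 0, 0, 1222,
     "p.H70Tfs*19:4;c.953-5A>G:2;p.S124L:1;p.A138E:1;c.782+2T>A:1;p.A426T:1"),
    ("p.S124L", 5, 0, 4524, 0, 0, 1046,
     "p.H70Tfs*19:1;p.A138E:1;p.L325Q:1;p.M448T:1;wt:1"),
    ("p.C194Mfs*17", 4, 0, 4594, 2, 0, 1932, "p.H70Tfs*19:3;p.A138E:1"),
    ("c.953-5A>G", 4, 0, 4560, 0, 0, 1058, "p.M448T:2;p.H70Tfs*19:1;p.A138E:1"),
    ("p.R109W", 2, 0, 4506, 0, 0, 998, "p.A138E:1;p.R436G:1"),
    ("p.D334Mfs*24", 2, 0, 4618, 0, 0, 1080, "p.H70Tfs*19:1;p.A138E:1"),
    ("p.C73Y", 1, 0, 4562, 0, 0, 1046, "p.A138E:1"),
    ("c.782+2T>A", 1, 0, 4206, 0, 0, 1042, "p.M448T:1"),
    ("p.L325Q", 1, 0, 4566, 0, 0, 1018, "p.S124L:1"),
    ("p.A426T", 1, 0, 4104, 0, 0, 1112, "p.M448T:1"),
    ("p.R436G", 1, 0, 4604, 0, 0, 986, "p.R109W:1"),
]

TMPRSS3_COHORT_SIZE = 2247
TMPRSS3_CARRIERS = 43  # patients with >=1 rare TMPRSS3 variant


def parse_partner_list(text: str) -> dict[str, int]:
    """Parse a semicolon-separated 'id:count' partner list into a dict."""
    partners: dict[str, int] = {}
    if not text or text in ("-", "."):
        return partners
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        pid, _, count = item.rpartition(":")
        partners[pid.strip()] = partners.get(pid.strip(), 0) + int(count)
    return partners


def tmprss3_records() -> list[ObservedVariantRecord]:
    """The 13 observed TMPRSS3 variant records of the validation cohort."""
    return [
        ObservedVariantRecord(
            variant_id=vid,
            het_patients=het_p,
            hom_patients=hom_p,
            allele_sum_patients=sum_p,
            het_controls=het_c,
            hom_controls=hom_c,
            allele_sum_controls=sum_c,
            partners=parse_partner_list(partners),
        )
        for vid, het_p, hom_p, sum_p, het_c, hom_c, sum_c, partners in _TMPRSS3_ROWS
    ]


def uniform_spectrum(n_path: int, n_nonpath: int) -> AlleleSpectrum:
    """Flat spectrum over n_path pathogenic + n_nonpath benign variants."""
    m, k = n_path, n_nonpath
    ids = tuple(f"P{i + 1}" for i in range(m)) + tuple(f"B{j + 1}" for j in range(k))
    classes = (PATHOGENIC,) * m + (NON_PATHOGENIC,) * k
    path = np.full(m, 0.004 / m)
    nonpath = np.full(k, 0.05 / k) if k else np.empty(0)
    return AlleleSpectrum(
        variant_ids=ids,
        classes=classes,
        freqs=np.concatenate([path, nonpath])[None, :],
        cum_path_target=float(path.sum()),
        cum_nonpath_target=float(nonpath.sum()) if k else 0.0,
    )


def cohort_from_genotypes(genotypes: list[list[str]], spectrum: AlleleSpectrum) -> Cohort:
    """Build a cohort from phased "m|p" genotype strings (tests, docs)."""
    n, v = len(genotypes), spectrum.n_variants
    mat = np.zeros((n, v), dtype=bool)
    pat = np.zeros((n, v), dtype=bool)
    for i, row in enumerate(genotypes):
        for j, gt in enumerate(row):
            a, _, b = gt.partition("|")
            mat[i, j] = a == "1"
            pat[i, j] = b == "1"
    path = spectrum.pathogenic_mask
    gene_caused = mat[:, path].any(axis=1) & pat[:, path].any(axis=1)
    return Cohort(
        maternal=mat,
        paternal=pat,
        gene_caused=gene_caused,
        population_index=np.zeros(n, dtype=np.int64),
        spectrum=spectrum,
    )


def single_homozygote() -> Cohort:
    """One patient, homozygous for the single pathogenic variant."""
    return cohort_from_genotypes([["1|1"]], uniform_spectrum(1, 0))


def two_components() -> Cohort:
    """Two disconnected carrier components in a 6-patient, 4-variant cohort.

    Component A: patient 0 (bi-allelic P1/P2) shares P1 with patient 1,
    who also carries B1 shared with patient 2. Component B: patients 3
    and 4 are bi-allelic for P3/P4 only; patient 5 carries nothing.
    An ISVS run seeded in one component can never reach the other.
    """
    spectrum = uniform_spectrum(4, 1)  # P1..P4, B1
    genotypes = [
        # P1   P2    P3    P4    B1
        ["1|0", "0|1", "0|0", "0|0", "0|0"],  # 0: bi-allelic, seed component A
        ["0|1", "0|0", "0|0", "0|0", "1|0"],  # 1: carrier of P1 and B1
        ["0|0", "0|0", "0|0", "0|0", "0|1"],  # 2: carrier of B1 only
        ["0|0", "0|0", "1|1", "0|0", "0|0"],  # 3: bi-allelic hom P3
        ["0|0", "0|0", "1|0", "0|1", "0|0"],  # 4: bi-allelic P3/P4
        ["0|0", "0|0", "0|0", "0|0", "0|0"],  # 5: no variants
    ]
    return cohort_from_genotypes(genotypes, spectrum)


def make_fixture(name: str):
    """Return a named deterministic fixture object.

    ``single_homozygote`` and ``two_components`` are toy cohorts;
    ``tmprss3_observed`` is the observed real-cohort variant table.
    """
    fixtures = {
        "single_homozygote": single_homozygote,
        "two_components": two_components,
        "tmprss3_observed": tmprss3_records,
    }
    if name not in fixtures:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(fixtures)}")
    return fixtures[name]()
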