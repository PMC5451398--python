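"""Configuration files, tabular import/export and run manifests.

Tab-separated values (header row, UTF-8, '.' decimal) are the canonical
tabular format; JSON holds nested traces and manifests; configs may be
JSON or YAML with keys exactly matching the simulation parameter names.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assess import ObservedVariantRecord
from .cohort import Cohort
from .fixtures import parse_partner_list
from .params import ParameterError, SimParams


class ConfigError(ValueError):
    """A configuration file could not be read or parsed."""


def load_config(path: str | Path) -> SimParams:
    """Load and validate simulation parameters from a JSON or YAML file.

    An empty file yields the full default parameter set; unknown keys
    are rejected. Missing file, parse failure and validation failure
    raise FileNotFoundError, ConfigError and ParameterError respectively.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must contain a mapping of parameter names")
    return SimParams.from_dict(data)


def save_config(params: SimParams, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Wide genotype table: one row per patient, phased 'm|p' genotypes."""
    n = cohort.n_patients
    data = {
        "patient_id": np.arange(n),
        "cause_label": cohort.cause_labels,
        "population_index": cohort.population_index,
    }
    for j, vid in enumerate(cohort.spectrum.variant_ids):
        mat = cohort.maternal[:, j].astype(int).astype(str)
        pat = cohort.paternal[:, j].astype(int).astype(str)
        data[vid] = np.char.add(np.char.add(mat, "|"), pat)
    return pd.DataFrame(data)


def write_cohort_tsv(cohort: Cohort, path: str | Path) -> None:
    write_tsv(cohort_to_frame(cohort), path)


def write_trace_json(trace: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(trace, indent=2) + "\n", encoding="utf-8")


def read_observed_variants(path: str | Path) -> list[ObservedVariantRecord]:
    """Read an observed-variant TSV into assessment records.

    Expected columns: variant_id, het_pat, hom_pat, allele_sum_pat,
    het_ctl, hom_ctl, allele_sum_ctl, partners (semicolon-separated
    'id:count' list; empty or 'wt:n' entries allowed).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"partners": str}).fillna({"partners": ""})
    records = []
    for row in frame.itertuples():
        records.append(
            ObservedVariantRecord(
                variant_id=str(row.variant_id),
                het_patients=int(row.het_pat),
                hom_patients=int(row.hom_pat),
                allele_sum_patients=int(row.allele_sum_pat),
                het_controls=int(row.het_ctl),
                hom_controls=int(row.hom_ctl),
                allele_sum_controls=int(row.allele_sum_ctl),
                partners=parse_partner_list(str(row.partners)),
            )
        )
    return records


def observed_variants_to_frame(records: list[ObservedVariantRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "variant_id": rec.variant_id,
                "het_pat": rec.het_patients,
                "hom_pat": rec.hom_patients,
                "allele_sum_pat": rec.allele_sum_patients,
                "het_ctl": rec.het_controls,
                "hom_ctl": rec.hom_controls,
                "allele_sum_ctl": rec.allele_sum_controls,
                "partners": ";".join(f"{k}:{v}" for k, v in rec.partners.items()),
            }
        )
    return pd.DataFrame(rows)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str | Path, params: SimParams, files: list[str | Path]) -> Path:
    """Write manifest.json with config snapshot, seed and output checksums."""
    outdir = Path(outdir)
    manifest = {
        "tool_version": __version__,
        "master_seed": params.master_seed,
        "config": params.to_dict(),
        "created": datetime.now(timezone.utc).isoformat(),
        "checksums": {Path(f).name: sha256_of(f) for f in files},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return path
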