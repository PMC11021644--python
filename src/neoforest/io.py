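"""Tab-separated input/output for peptide tables, expression and survival.

The peptide TSV carries one row per neopeptide candidate with required
id/sequence/core/label columns plus optional external-predictor
columns.  Missing values are empty fields or "NA"; "-" is additionally
accepted in the expression column (the convention of upstream peptide
extraction when no transcript is assessable).
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
import pandas as pd

from .context import MutationRNACounts, PatientProfile
from .peptides import ExternalPredictions, PeptideRecord

REQUIRED_COLUMNS = (
    "peptide_id",
    "patient_id",
    "mut_seq",
    "wt_seq",
    "hla",
    "core9",
    "core_start",
    "label",
)

_EXTERNAL_COLUMNS = {
    "RankEL": "rank_el_mut",
    "RankEL_wt": "rank_el_wt",
    "RankBA": "rank_ba_mut",
    "Stability": "stability",
    "NetMHCExp": "netmhc_exp",
    "Prime": "prime",
    "Foreignness": "foreignness",
    "Expression": "expression",
    "VarAlFreq": "var_al_frac",
    "CelPrev": "cel_prev",
    "PrioScore": "prio_score",
}

NA_VALUES = ["", "NA"]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        if value.strip() in ("", "NA", "-"):
            return None
        return float(value)
    return float(value)


def read_peptide_table(path) -> list[PeptideRecord]:
    df = pd.read_csv(
        path, sep="\t", na_values=NA_VALUES, keep_default_na=False, dtype={"wt_seq": str}
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table lacks required columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            ext = ExternalPredictions(
                **{
                    attr: _opt_float(getattr(row, col))
                    for col, attr in _EXTERNAL_COLUMNS.items()
                    if col in df.columns
                }
            )
            wt = row.wt_seq
            if isinstance(wt, float) or wt in ("", "NA", None) or pd.isna(wt):
                wt = None
            records.append(
                PeptideRecord(
                    peptide_id=str(row.peptide_id),
                    patient_id=str(row.patient_id),
                    mut_seq=str(row.mut_seq),
                    wt_seq=wt,
                    hla=str(row.hla),
                    core9=str(row.core9),
                    core_start=int(row.core_start),
                    label=int(row.label),
                    external=ext,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {i + 2}: {exc}") from exc
    return records


def write_peptide_table(records, path) -> None:
    rows = []
    for r in records:
        row = {
            "peptide_id": r.peptide_id,
            "patient_id": r.patient_id,
            "mut_seq": r.mut_seq,
            "wt_seq": r.wt_seq if r.wt_seq is not None else "NA",
            "hla": r.hla,
            "core9": r.core9,
            "core_start": r.core_start,
            "label": r.label,
        }
        for col, attr in _EXTERNAL_COLUMNS.items():
            row[col] = getattr(r.external, attr)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_expression_matrix(path) -> dict[str, PatientProfile]:
    """Gene x patient TSV (first column = gene symbol) into profiles."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=NA_VALUES)
    return {
        str(pat): PatientProfile(
            patient_id=str(pat),
            expression=df[pat].dropna().to_dict(),
        )
        for pat in df.columns
    }


def write_expression_matrix(profiles: dict[str, PatientProfile], path) -> None:
    genes = sorted({g for p in profiles.values() for g in p.expression})
    df = pd.DataFrame(
        {pid: [p.expression.get(g) for g in genes] for pid, p in profiles.items()},
        index=pd.Index(genes, name="gene"),
    )
    df.to_csv(path, sep="\t", na_rep="NA")


def read_rna_counts(path) -> dict[str, MutationRNACounts]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.peptide_id): MutationRNACounts(
            str(r.peptide_id), int(r.n_variant_reads), int(r.n_coverage_reads)
        )
        for r in df.itertuples(index=False)
    }


def write_rna_counts(counts: dict[str, MutationRNACounts], path) -> None:
    pd.DataFrame(
        [
            {
                "peptide_id": c.peptide_id,
                "n_variant_reads": c.n_variant_reads,
                "n_coverage_reads": c.n_coverage_reads,
            }
            for c in counts.values()
        ]
    ).to_csv(path, sep="\t", index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("patient_id", "time", "event") if c not in df.columns]
    if missing:
        raise ValueError(f"survival table lacks columns: {missing}")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serialisable: {type(obj)}")
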