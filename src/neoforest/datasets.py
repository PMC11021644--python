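"""Feature-matrix assembly, mean imputation and correlation filtering.

The assembled table has one row per neopeptide and one column per
feature; per-peptide sequence descriptors, per-mutation RNA support and
per-patient TME covariates are joined on peptide and patient ids.
Missing entries stay missing until training time, when they are filled
with the *training-fold* mean so that no test statistic leaks into the
model.

Highly inter-correlated features hurt both the trainability and the
interpretability of random forests, so pairs with |Spearman rho| at or
above a threshold (default 0.7) are pruned down to the member with the
better univariate partial AUC against the labels.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .context import MutationRNACounts, PatientProfile, compute_tme_features
from .peptides import PeptideRecord, compute_peptide_features

logger = logging.getLogger(__name__)

ID_COLUMNS = ("peptide_id", "patient_id", "label")

#: the 22-feature default set of the full feature model
IMPROVE_FEATURES: tuple[str, ...] = (
    "SelfSim",
    "DAI",
    "CelPrev",
    "Expression",
    "Foreignness",
    "PrioScore",
    "RankBA",
    "RankEL",
    "Stability",
    "NetMHCExp",
    "PropHydroAro",
    "Prime",
    "HydroCore",
    "Aro",
    "PropAro",
    "CysRed",
    "PropSmall",
    "PropAcidic",
    "Inst",
    "PropBasic",
    "pI",
    "mw",
)

#: sequence-only variant: drops the genomics-pipeline features that an
#: external benchmark set cannot provide
IMPROVE_SIMPLE_FEATURES: tuple[str, ...] = tuple(
    f for f in IMPROVE_FEATURES if f not in ("PrioScore", "CelPrev")
)

#: full set extended with the patient-level TME covariates
IMPROVE_TME_FEATURES: tuple[str, ...] = IMPROVE_FEATURES + (
    "CYT",
    "MCPmean",
    "HLAexp",
)

FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "improve": IMPROVE_FEATURES,
    "improve_simple": IMPROVE_SIMPLE_FEATURES,
    "improve_tme": IMPROVE_TME_FEATURES,
}

FEATURE_CATEGORIES: dict[str, str] = {
    "SelfSim": "pMHC",
    "DAI": "pMHC",
    "RankEL": "pMHC",
    "RankBA": "pMHC",
    "Stability": "pMHC",
    "NetMHCExp": "pMHC",
    "Prime": "pMHC",
    "Foreignness": "pMHC",
    "CelPrev": "mutation-quality",
    "Expression": "mutation-quality",
    "VarAlFreq": "mutation-quality",
    "ValMutRNACoef": "mutation-quality",
    "PrioScore": "mutation-quality",
    "HydroAll": "physicochemical",
    "HydroCore": "physicochemical",
    "PropHydroAro": "physicochemical",
    "Aro": "physicochemical",
    "PropAro": "physicochemical",
    "PropSmall": "physicochemical",
    "PropAcidic": "physicochemical",
    "PropBasic": "physicochemical",
    "CysRed": "physicochemical",
    "Inst": "physicochemical",
    "pI": "physicochemical",
    "mw": "physicochemical",
    "CYT": "TME",
    "MCPmean": "TME",
    "HLAexp": "TME",
}


def resolve_feature_set(name_or_list: str | Sequence[str]) -> list[str]:
    if isinstance(name_or_list, str):
        try:
            return list(FEATURE_SETS[name_or_list])
        except KeyError:
            raise KeyError(
                f"unknown feature set {name_or_list!r}; "
                f"known: {sorted(FEATURE_SETS)}"
            ) from None
    return list(name_or_list)


def assemble(
    records: Sequence[PeptideRecord],
    profiles: Mapping[str, PatientProfile] | None = None,
    rna_counts: Mapping[str, MutationRNACounts] | None = None,
    marker_sets=None,
) -> pd.DataFrame:
    """Join peptide, mutation-context and patient features into one table.

    Rows are indexed positionally; ``peptide_id`` must be unique.  A
    record whose patient has no expression profile simply carries
    missing TME columns.
    """
    if not records:
        raise ValueError("no peptide records to assemble")
    ids = [r.peptide_id for r in records]
    dup = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate peptide ids: {dup}")

    tme_cache: dict[str, dict] = {}
    if profiles:
        for pid, prof in profiles.items():
            tme_cache[pid] = compute_tme_features(prof, marker_sets=marker_sets)

    rows = []
    for rec in records:
        row: dict = {
            "peptide_id": rec.peptide_id,
            "patient_id": rec.patient_id,
            "label": rec.label,
            "mut_seq": rec.mut_seq,
        }
        row.update(compute_peptide_features(rec))
        if rna_counts and rec.peptide_id in rna_counts:
            cnt = rna_counts[rec.peptide_id]
            row["ValMutRNACoef"] = cnt.n_variant_reads / (cnt.n_coverage_reads + 100)
        else:
            row["ValMutRNACoef"] = None
        row.update(tme_cache.get(rec.patient_id, {"CYT": None, "MCPmean": None, "HLAexp": None}))
        rows.append(row)
    table = pd.DataFrame(rows)

    feature_cols = [c for c in table.columns if c not in ID_COLUMNS + ("mut_seq",)]
    miss = table[feature_cols].isna().mean()
    for feat, rate in miss.items():
        if rate > 0:
            logger.info("feature %s missing in %.1f%% of rows", feat, 100 * rate)
    return table


def impute_mean(
    train_table: pd.DataFrame,
    apply_table: pd.DataFrame,
    features: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Fill missing feature values with training-set means.

    Means are estimated on ``train_table`` only and written into a copy
    of ``apply_table``; applying a fold's means to its own rows is
    idempotent on complete tables.
    """
    means = train_table[list(features)].mean()
    empty = means.index[means.isna()].tolist()
    if empty:
        raise ValueError(f"features entirely missing in training data: {empty}")
    out = apply_table.copy()
    out[list(features)] = out[list(features)].fillna(means)
    return out, means


def _univariate_pauc(scores: pd.Series, labels: pd.Series, fpr_max: float) -> float:
    """Orientation-free single-feature partial AUC (best of both signs)."""
    mask = scores.notna()
    s = scores[mask].to_numpy(float)
    y = labels[mask].to_numpy()
    if len(np.unique(y)) < 2 or len(np.unique(s)) < 2:
        return 0.0
    return max(
        metrics.partial_auc(s, y, fpr_max),
        metrics.partial_auc(-s, y, fpr_max),
    )


def correlation_filter(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    features: Sequence[str],
    threshold: float = 0.7,
    fpr_max: float = 0.1,
) -> list[str]:
    """Drop one member of every feature pair with |Spearman rho| >= threshold.

    The member with the lower univariate partial AUC against the labels
    is discarded; the highest-correlation pair is resolved first, and
    exact performance ties drop the later feature in name order, so the
    result does not depend on input column order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    features = sorted(features)
    if len(features) < 2:
        return list(features)
    labels = pd.Series(np.asarray(labels), index=table.index)
    corr = table[features].corr(method="spearman").abs()
    perf = {f: _univariate_pauc(table[f], labels, fpr_max) for f in features}

    retained = list(features)
    while True:
        violating = []
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                rho = corr.loc[a, b]
                if np.isfinite(rho) and rho >= threshold:
                    violating.append((rho, a, b))
        if not violating:
            return retained
        violating.sort(key=lambda t: (-t[0], t[1], t[2]))
        _, a, b = violating[0]
        if perf[a] > perf[b]:
            drop = b
        elif perf[b] > perf[a]:
            drop = a
        else:
            drop = max(a, b)  # later in canonical name order
        logger.info("correlation filter: dropping %s (|rho| with %s >= %.2f)",
                    drop, a if drop == b else b, threshold)
        retained.remove(drop)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA", ""])
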