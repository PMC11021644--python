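"""Leakage-aware cross-validation folds for multi-patient peptide screens.

Two leakage channels matter in neoepitope data: peptides from one
patient share that patient's covariates, and near-identical immunogenic
peptides recur across patients (shared mutations).  Folds therefore
keep (i) all peptides of a patient together and (ii) all patients who
own motif-sharing immunogenic peptides together.  Motif sharing means
two sequences contain an identical contiguous k-mer (default k = 6).
Non-immunogenic peptides simply inherit their patient's fold; any
training-set peptide whose exact mutant sequence also occurs in the
test fold is removed from training.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .peptides import PeptideRecord

DEFAULT_MOTIF_K = 6


@dataclass
class PartitionAssignment:
    fold_of: dict[str, int]          # peptide_id -> fold
    n_folds: int
    component_of: dict[str, int]     # patient_id -> component id

    def folds(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_folds)]
        for pid, f in self.fold_of.items():
            out[f].append(pid)
        return out


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_motif(seq_a: str, seq_b: str, k: int = DEFAULT_MOTIF_K) -> bool:
    """True iff the two sequences share any identical contiguous k-mer."""
    if k < 1:
        raise ValueError("motif length k must be >= 1")
    return bool(_kmers(seq_a, k) & _kmers(seq_b, k))


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_patients(
    records: Sequence[PeptideRecord], k: int = DEFAULT_MOTIF_K
) -> dict[str, int]:
    """Connected components of the patient graph induced by shared motifs.

    Edges join patients owning immunogenic peptides that share a k-mer;
    components are numbered by first appearance of a member patient.
    """
    patients = []
    seen = set()
    for r in records:
        if r.patient_id not in seen:
            seen.add(r.patient_id)
            patients.append(r.patient_id)
    uf = _UnionFind(patients)

    kmer_owners: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.label == 1:
            for km in _kmers(r.mut_seq, k):
                kmer_owners[km].add(r.patient_id)
    for owners in kmer_owners.values():
        owners = sorted(owners)
        for other in owners[1:]:
            uf.union(owners[0], other)

    component_of: dict[str, int] = {}
    root_id: dict[str, int] = {}
    for p in patients:
        root = uf.find(p)
        if root not in root_id:
            root_id[root] = len(root_id)
        component_of[p] = root_id[root]
    return component_of


def assign_partitions(
    records: Sequence[PeptideRecord],
    n_folds: int = 5,
    k: int = DEFAULT_MOTIF_K,
    seed: int = 0,
) -> PartitionAssignment:
    """Greedy balanced fold assignment of patient components.

    Components are placed largest-first into the currently smallest
    fold; the seed only permutes the order in which equally full folds
    are considered, so the grouping constraints hold for every seed.
    """
    component_of = cluster_patients(records, k)
    n_components = len(set(component_of.values()))
    if n_folds > n_components:
        raise ValueError(
            f"{n_components} patient components cannot fill {n_folds} folds; "
            "use fewer folds or a shorter motif length"
        )

    comp_size: dict[int, int] = defaultdict(int)
    for r in records:
        comp_size[component_of[r.patient_id]] += 1

    rng = np.random.default_rng(seed)
    fold_order = rng.permutation(n_folds)
    fold_sizes = np.zeros(n_folds, dtype=int)
    fold_of_component: dict[int, int] = {}
    for comp in sorted(comp_size, key=lambda c: (-comp_size[c], c)):
        target = min(fold_order, key=lambda f: fold_sizes[f])
        fold_of_component[comp] = int(target)
        fold_sizes[target] += comp_size[comp]

    fold_of = {
        r.peptide_id: fold_of_component[component_of[r.patient_id]]
        for r in records
    }
    return PartitionAssignment(fold_of, n_folds, component_of)


def dedup_train(
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    sequences: Mapping[str, str],
) -> list[str]:
    """Drop training rows whose mutant sequence occurs verbatim in the test fold.

    Duplicates *within* the training fold are untouched; only
    train/test sequence identity is a leak.
    """
    test_seqs = {sequences[i] for i in test_ids}
    return [i for i in train_ids if sequences[i] not in test_seqs]
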