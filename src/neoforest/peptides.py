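"""Sequence-derived descriptors of mutant neopeptides.

A neopeptide candidate is an 8-12-mer carrying a somatic mutation, paired
with the corresponding wild-type peptide (absent for frameshifts) and a
predicted 9-residue MHC-I binding core.  The descriptors computed here
summarise the physicochemistry of the peptide and of its TCR-facing
stretch (core positions 4-8, away from the MHC anchors), the change in
predicted presentation caused by the mutation (DAI), and the sequence
similarity between the mutant and its wild-type counterpart.

External predictor outputs (percentile ranks, stability, expression,
clonality, ...) are consumed as pre-computed columns and passed through
unchanged; nothing here re-runs an MHC binding predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils import ProtParamData

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: wildcard residue marking the inserted core position of 8-mer ligands;
#: scored 0 on hydrophobicity scales and excluded from class counts
WILDCARD = "X"

#: Kyte-Doolittle hydropathy scale (via biopython)
KYTE_DOOLITTLE: Mapping[str, float] = dict(ProtParamData.kd)

# residue classes used for proportion features
HYDRO_ARO = frozenset("VIYFWL")
AROMATIC = frozenset("FWY")
SMALL = frozenset("AGSTCPND")  # Taylor "small" grouping
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")

#: EMBOSS pKa values used for the isoelectric point
EMBOSS_PKA = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

DEFAULT_ANCHORS = frozenset({2, 9})  # core positions (1-based)


class InvalidPeptideError(ValueError):
    """Raised when a sequence violates the 8-12-mer / alphabet contract."""


@dataclass
class ExternalPredictions:
    """Pre-computed predictor outputs attached to one neopeptide.

    Ranks are NetMHCpan-style percentile ranks (lower = stronger
    predicted presentation); fractions live in [0, 1].  Any slot may be
    None when the upstream tool could not be run.
    """

    rank_el_mut: Optional[float] = None
    rank_el_wt: Optional[float] = None
    rank_ba_mut: Optional[float] = None
    stability: Optional[float] = None
    netmhc_exp: Optional[float] = None
    prime: Optional[float] = None
    foreignness: Optional[float] = None
    expression: Optional[float] = None
    var_al_frac: Optional[float] = None
    cel_prev: Optional[float] = None
    prio_score: Optional[float] = None


@dataclass
class PeptideRecord:
    """One neopeptide candidate from a patient's screening library."""

    peptide_id: str
    patient_id: str
    mut_seq: str
    hla: str
    core9: str
    core_start: int
    label: int
    wt_seq: Optional[str] = None
    external: ExternalPredictions = field(default_factory=ExternalPredictions)

    def __post_init__(self) -> None:
        validate_sequence(self.mut_seq)
        if self.wt_seq is not None:
            validate_sequence(self.wt_seq)
        if len(self.core9) != 9:
            raise InvalidPeptideError(
                f"{self.peptide_id}: binding core must have 9 residues, "
                f"got {self.core9!r}"
            )
        if self.label not in (0, 1):
            raise InvalidPeptideError(f"{self.peptide_id}: label must be 0/1")


def validate_sequence(seq: str) -> None:
    if not 8 <= len(seq) <= 12:
        raise InvalidPeptideError(f"peptide length {len(seq)} outside [8, 12]: {seq!r}")
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise InvalidPeptideError(f"non-standard residues {sorted(bad)} in {seq!r}")


def non_anchor_subsequence(core9: str) -> str:
    """TCR-facing stretch of the binding core: positions 4-8 (1-based).

    Anchor residues (typically core positions 2 and 9) are buried in the
    MHC groove; the returned 5-mer is the solvent-exposed middle.
    """
    if len(core9) != 9:
        raise InvalidPeptideError(f"binding core must have 9 residues, got {core9!r}")
    return core9[3:8]


def hydrophobicity_mean(seq: str, scale: Mapping[str, float] | None = None) -> float:
    """Mean per-residue hydropathy (Kyte-Doolittle by default).

    The wildcard residue contributes 0, matching its role as an
    uninformative inserted position in 8-mer binding cores.
    """
    if not seq:
        raise InvalidPeptideError("empty sequence")
    scale = KYTE_DOOLITTLE if scale is None else scale
    total = 0.0
    for aa in seq:
        if aa == WILDCARD:
            continue
        try:
            total += scale[aa]
        except KeyError:
            raise InvalidPeptideError(f"residue {aa!r} missing from scale") from None
    return total / len(seq)


def class_proportion(seq: str, residue_class: Iterable[str]) -> float:
    """Fraction of residues belonging to a physicochemical class.

    Wildcard positions are excluded from both numerator and denominator.
    """
    residues = [aa for aa in seq if aa != WILDCARD]
    if not residues:
        raise InvalidPeptideError("empty sequence")
    members = frozenset(residue_class)
    return sum(aa in members for aa in residues) / len(residues)


def cys_count(seq: str) -> int:
    """Number of cysteines in the peptide (reduction-sensitive residues)."""
    return seq.count("C")


def instability_index(seq: str) -> float:
    """Guruprasad instability index from dipeptide weight values."""
    if len(seq) < 2:
        raise InvalidPeptideError("instability index needs >= 2 residues")
    return ProteinAnalysis(seq).instability_index()


def molecular_weight(seq: str) -> float:
    """Average (isotope-weighted) molecular weight in Daltons."""
    validate_alphabet(seq)
    return ProteinAnalysis(seq).molecular_weight()


def validate_alphabet(seq: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise InvalidPeptideError(f"non-standard residues {sorted(bad)} in {seq!r}")


def _net_charge(seq: str, ph: float, pka: Mapping[str, float]) -> float:
    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka["Nterm"]) - neg(pka["Cterm"])
    for aa in seq:
        if aa in ("K", "R", "H"):
            charge += pos(pka[aa])
        elif aa in ("D", "E", "C", "Y"):
            charge -= neg(pka[aa])
    return charge


def isoelectric_point(
    seq: str, pka: Mapping[str, float] | None = None, tol: float = 1e-3
) -> float:
    """pH of zero net charge, from Henderson-Hasselbalch with EMBOSS pKas.

    The net charge is strictly decreasing in pH, so bisection on [0, 14]
    always converges.
    """
    pka = EMBOSS_PKA if pka is None else pka
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dai(
    rank_el_wt: Optional[float],
    rank_el_mut: Optional[float],
    sign: str = "wt_minus_mut",
) -> Optional[float]:
    """Differential agretopicity index: change in presentation rank.

    With the default orientation a positive DAI means the mutation
    improved predicted MHC presentation (mutant rank below wild-type
    rank).  Returns None when the wild-type rank is unavailable
    (frameshift peptides), to be mean-imputed downstream.
    """
    if rank_el_wt is None or rank_el_mut is None:
        return None
    if rank_el_wt < 0 or rank_el_mut < 0:
        raise ValueError("percentile ranks must be >= 0")
    delta = rank_el_wt - rank_el_mut
    return delta if sign == "wt_minus_mut" else -delta


@lru_cache(maxsize=1)
def _blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    return {
        (a, b): float(mat[a, b]) for a in mat.alphabet for b in mat.alphabet
    }


def self_similarity(
    mut_seq: str,
    wt_seq: Optional[str],
    k_max: int = 3,
    matrix: Mapping[tuple[str, str], float] | None = None,
) -> Optional[float]:
    """Normalised string-kernel similarity between mutant and wild type.

    K(a, b) sums, over k = 1..k_max and over every pair of one k-mer from
    a and one from b, the product of substitution-matrix scores at
    aligned positions; the reported value is
    K(a, b) / sqrt(K(a, a) * K(b, b)), which is 1 for identical
    sequences.  Returns None when no wild-type peptide exists.
    """
    if wt_seq is None:
        return None
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    matrix = _blosum62() if matrix is None else matrix

    def kernel(a: str, b: str) -> float:
        s = np.array([[matrix[(x, y)] for y in b] for x in a], dtype=float)
        total = 0.0
        prod = s
        total += prod.sum()
        for k in range(2, k_max + 1):
            if prod.shape[0] < 2 or prod.shape[1] < 2:
                break
            prod = prod[:-1, :-1] * s[k - 1 :, k - 1 :]
            total += prod.sum()
        return total

    kab = kernel(mut_seq, wt_seq)
    kaa = kernel(mut_seq, mut_seq)
    kbb = kernel(wt_seq, wt_seq)
    return kab / math.sqrt(kaa * kbb)


def mutation_position(
    mut_seq: str, wt_seq: str, core_start: int, core9: str
) -> str:
    """Core-relative position (P1..P9) of a missense mutation, or "OC".

    "OC" (outside core) marks mutations falling in the part of a long
    peptide that protrudes from the predicted binding register.
    """
    if len(mut_seq) != len(wt_seq):
        raise ValueError("missense records require equal-length sequences")
    mismatches = [i for i, (a, b) in enumerate(zip(mut_seq, wt_seq)) if a != b]
    if len(mismatches) != 1:
        raise ValueError(
            f"expected exactly one substitution, found {len(mismatches)}"
        )
    pos = mismatches[0]
    if core_start <= pos < core_start + 9:
        return f"P{pos - core_start + 1}"
    return "OC"


def classify_binder(
    rank_el_mut: float,
    rank_el_wt: float,
    mut_pos: str,
    binder_threshold: float = 2.0,
    anchors: frozenset[int] = DEFAULT_ANCHORS,
) -> str:
    """Conserved binder (CB) vs improved binder (IB) classification.

    CB: the wild-type peptide is itself presented (wt rank below the
    binder threshold) and the mutation sits outside the MHC anchors, so
    tolerance against the wild type may blunt recognition.  IB: the
    mutation hits an anchor and improves predicted binding.
    """
    anchor_names = {f"P{i}" for i in anchors}
    if mut_pos in anchor_names and rank_el_mut < rank_el_wt:
        return "IB"
    if rank_el_wt < binder_threshold and mut_pos not in anchor_names:
        return "CB"
    return "other"


#: names of the sequence-derived feature slots, in canonical order
SEQUENCE_FEATURES = (
    "HydroAll",
    "HydroCore",
    "PropHydroAro",
    "Aro",
    "PropAro",
    "PropSmall",
    "PropAcidic",
    "PropBasic",
    "CysRed",
    "Inst",
    "pI",
    "mw",
    "DAI",
    "SelfSim",
)

#: external predictor columns passed through to the model
EXTERNAL_FEATURES = (
    "RankEL",
    "RankBA",
    "Stability",
    "NetMHCExp",
    "Prime",
    "Foreignness",
    "Expression",
    "VarAlFreq",
    "CelPrev",
    "PrioScore",
)


def compute_peptide_features(
    record: PeptideRecord,
    hydro_scale: Mapping[str, float] | None = None,
    dai_sign: str = "wt_minus_mut",
    k_max: int = 3,
) -> dict[str, Optional[float]]:
    """All per-peptide feature slots for one record.

    Slots that need an unavailable input (wild-type sequence for DAI and
    SelfSim on frameshifts, missing predictor columns) come back as None
    and are mean-imputed during model training.
    """
    non_anchor = non_anchor_subsequence(record.core9)
    ext = record.external
    feats: dict[str, Optional[float]] = {
        "HydroAll": hydrophobicity_mean(record.mut_seq, hydro_scale),
        "HydroCore": hydrophobicity_mean(non_anchor, hydro_scale),
        "PropHydroAro": class_proportion(record.mut_seq, HYDRO_ARO),
        "Aro": class_proportion(record.mut_seq, AROMATIC),
        "PropAro": class_proportion(non_anchor, AROMATIC),
        "PropSmall": class_proportion(non_anchor, SMALL),
        "PropAcidic": class_proportion(non_anchor, ACIDIC),
        "PropBasic": class_proportion(non_anchor, BASIC),
        "CysRed": float(cys_count(record.mut_seq)),
        "Inst": instability_index(record.mut_seq),
        "pI": isoelectric_point(record.mut_seq),
        "mw": molecular_weight(record.mut_seq),
        "DAI": dai(ext.rank_el_wt, ext.rank_el_mut, sign=dai_sign),
        "SelfSim": self_similarity(record.mut_seq, record.wt_seq, k_max=k_max),
        "RankEL": ext.rank_el_mut,
        "RankBA": ext.rank_ba_mut,
        "Stability": ext.stability,
        "NetMHCExp": ext.netmhc_exp,
        "Prime": ext.prime,
        "Foreignness": ext.foreignness,
        "Expression": ext.expression,
        "VarAlFreq": ext.var_al_frac,
        "CelPrev": ext.cel_prev,
        "PrioScore": ext.prio_score,
    }
    return feats
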