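"""ProtParam-equivalent sequence descriptors.

Molecular weight (average isotopic masses), theoretical pI (Bjellqvist pKa
set, bisection on the Henderson-Hasselbalch net charge), GRAVY
(Kyte-Doolittle mean hydropathy), the Guruprasad instability index (DIWV
dipeptide weights), and residue-class composition under a configurable,
disjoint-cover class scheme. Constant tables come from Biopython's ProtParam
data so they match the ProtParam web tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import IsoelectricPoint as _IP
from Bio.SeqUtils.ProtParamData import DIWV, kd

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = set(STANDARD_RESIDUES)
WATER_MASS = 18.0153

MW_THRESHOLD_DA = 50_000.0
INSTABILITY_THRESHOLD = 40.0
GRAVY_THRESHOLD = 0.0

# --- fast lookup tables -----------------------------------------------------
_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _aa in enumerate(STANDARD_RESIDUES):
    _INDEX[ord(_aa)] = _i

_RESIDUE_MASS = np.array(
    [protein_weights[aa] - WATER_MASS for aa in STANDARD_RESIDUES]
)
_KD = np.array([kd[aa] for aa in STANDARD_RESIDUES])
_DIWV = np.array(
    [[DIWV[a].get(b, 1.0) for b in STANDARD_RESIDUES] for a in STANDARD_RESIDUES]
)


def encode(sequence: str) -> np.ndarray:
    """Map a validated sequence to residue indices (0..19)."""
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    idx = _INDEX[arr]
    if (idx < 0).any():
        pos = int(np.argmax(idx < 0))
        raise ValueError(
            f"non-standard residue {sequence[pos]!r} at position {pos + 1}"
        )
    return idx


def _check(sequence: str, min_len: int = 1) -> np.ndarray:
    if len(sequence) < min_len:
        raise ValueError(f"sequence length {len(sequence)} < required {min_len}")
    return encode(sequence)


# --- descriptors ------------------------------------------------------------


def compute_mw(sequence: str) -> float:
    """Average-isotopic molecular weight in daltons (residue masses + one water)."""
    idx = _check(sequence)
    return float(_RESIDUE_MASS[idx].sum() + WATER_MASS)


def compute_gravy(sequence: str) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value per residue."""
    idx = _check(sequence)
    return float(_KD[idx].mean())


def compute_instability(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of DIWV dipeptide weights."""
    idx = _check(sequence, min_len=2)
    return float(10.0 / len(sequence) * _DIWV[idx[:-1], idx[1:]].sum())


def classify_stability(instability_index: float) -> str:
    """stable below 40; the boundary itself counts as unstable."""
    if instability_index < 0:
        raise ValueError("instability index must be >= 0")
    return "stable" if instability_index < INSTABILITY_THRESHOLD else "unstable"


def classify_mw(mw_da: float) -> str:
    """low below 50 kDa; the boundary itself counts as high."""
    return "low" if mw_da < MW_THRESHOLD_DA else "high"


def classify_hydropathy(gravy: float) -> str:
    """hydrophilic below 0; the boundary itself counts as hydrophobic."""
    return "hydrophilic" if gravy < GRAVY_THRESHOLD else "hydrophobic"


# --- isoelectric point ------------------------------------------------------


@dataclass(frozen=True)
class PKaSet:
    """pKa values for the charge model.

    Defaults are the Bjellqvist set as used by ProtParam, including the
    residue-specific terminal adjustments.
    """

    positive: dict = field(
        default_factory=lambda: dict(_IP.positive_pKs)
    )  # Nterm, K, R, H
    negative: dict = field(
        default_factory=lambda: dict(_IP.negative_pKs)
    )  # Cterm, D, E, C, Y
    nterm_by_residue: dict = field(default_factory=lambda: dict(_IP.pKnterminal))
    cterm_by_residue: dict = field(default_factory=lambda: dict(_IP.pKcterminal))


DEFAULT_PKA = PKaSet()


def _ionizable_groups(sequence: str, pka_set: PKaSet) -> list:
    """(count, pKa, sign) for every ionizable group present in the sequence."""
    positive = dict(pka_set.positive)
    negative = dict(pka_set.negative)
    positive["Nterm"] = pka_set.nterm_by_residue.get(sequence[0], positive["Nterm"])
    negative["Cterm"] = pka_set.cterm_by_residue.get(sequence[-1], negative["Cterm"])
    groups = []
    for name, pka in positive.items():
        n = 1 if name == "Nterm" else sequence.count(name)
        if n:
            groups.append((n, pka, 1.0))
    for name, pka in negative.items():
        n = 1 if name == "Cterm" else sequence.count(name)
        if n:
            groups.append((n, pka, -1.0))
    return groups


def _charge(groups, ph: float) -> float:
    return sum(
        sign * n / (1.0 + 10 ** (sign * (ph - pka))) for n, pka, sign in groups
    )


def charge_at_ph(sequence: str, ph: float, pka_set: PKaSet = DEFAULT_PKA) -> float:
    """Net charge from Henderson-Hasselbalch sums over termini and side chains."""
    _check(sequence)
    return _charge(_ionizable_groups(sequence, pka_set), ph)


def compute_pi(sequence: str, pka_set: PKaSet = DEFAULT_PKA, tol: float = 1e-3) -> float:
    """pH in [0, 14] where the net charge crosses zero, by bisection.

    The charge is strictly decreasing in pH, positive at pH 0 and negative at
    pH 14 (both termini are always ionizable), so a root always exists.
    """
    _check(sequence)
    groups = _ionizable_groups(sequence, pka_set)
    lo, hi = 0.0, 14.0
    if _charge(groups, lo) < 0 or _charge(groups, hi) > 0:
        raise ValueError("net charge does not cross zero on [0, 14]")
    while hi - lo > tol / 2:
        mid = 0.5 * (lo + hi)
        if _charge(groups, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --- residue-class composition ----------------------------------------------


@dataclass(frozen=True)
class ClassScheme:
    """Residue classes for composition fractions.

    polar, nonpolar, positive and negative must be a disjoint cover of the 20
    standard residues; aromatic may overlap the partition and is reported
    separately. The default follows common biochemical usage (the exact sets
    behind published composition figures are tool-dependent); alternative
    schemes can be passed anywhere a scheme is accepted.
    """

    aromatic: frozenset = frozenset("FWY")
    positive: frozenset = frozenset("KRH")
    negative: frozenset = frozenset("DE")
    polar: frozenset = frozenset("STNQCYG")
    nonpolar: frozenset = frozenset("AVLIPMFW")

    def __post_init__(self):
        parts = [self.polar, self.nonpolar, self.positive, self.negative]
        union = frozenset().union(*parts)
        if union != frozenset(STANDARD_RESIDUES) or sum(map(len, parts)) != 20:
            raise ValueError(
                "polar/nonpolar/positive/negative must partition the 20 standard residues"
            )
        if not self.aromatic <= frozenset(STANDARD_RESIDUES):
            raise ValueError("aromatic must be a subset of the 20 standard residues")


DEFAULT_SCHEME = ClassScheme()


def compute_composition(sequence: str, scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Residue-class fractions: aromatic plus the four partition classes."""
    _check(sequence)
    n = len(sequence)
    out = {}
    for name in ("aromatic", "polar", "nonpolar", "positive", "negative"):
        members = getattr(scheme, name)
        out[f"frac_{name}"] = sum(sequence.count(aa) for aa in members) / n
    return out


# --- profile container ------------------------------------------------------


@dataclass
class PhysicochemProfile:
    """Full per-protein descriptor vector consumed by the correlation screen."""

    protein_id: str
    mw_da: float
    pi: float
    gravy: float
    instability_index: float
    frac_aromatic: float
    frac_polar: float
    frac_nonpolar: float
    frac_positive: float
    frac_negative: float
    n_ca_sites: int = 0
    n_ox_motifs: int = 0
    ss_helix: float = 0.0
    ss_strand: float = 0.0
    ss_turn: float = 0.0
    ss_coil: float = 1.0
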