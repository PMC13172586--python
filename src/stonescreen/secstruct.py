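"""Four-state secondary-structure fractions (helix, strand, turn, coil).

Two routes are supported. The built-in predictor assigns each residue the
argmax of window-averaged residue propensities — a deliberately simple,
fully reproducible stand-in for alignment-database tools such as SOPMA, and
not a reimplementation of them. For analyses that must match a specific
external predictor, its output can be imported verbatim via
:func:`import_ss`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .ingest import ProteinRecord
from .physchem import STANDARD_RESIDUES, encode

STATES = ("helix", "strand", "turn", "coil")
_STATE_LETTERS = {"H": "helix", "E": "strand", "T": "turn", "C": "coil"}
DEFAULT_WINDOW = 17


@dataclass(frozen=True)
class SSFractions:
    protein_id: str
    helix: float
    strand: float
    turn: float
    coil: float
    source: str = "builtin"  # builtin | imported

    def __post_init__(self):
        total = self.helix + self.strand + self.turn + self.coil
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"secondary-structure fractions sum to {total}, not 1")


def load_propensities(path=None) -> pd.DataFrame:
    """Propensity table: one row per residue, columns helix/strand/turn/coil."""
    if path is None:
        path = resources.files("stonescreen.data") / "ss_propensities.tsv"
    df = pd.read_csv(path, sep="\t", comment="#").set_index("residue")
    missing = set(STANDARD_RESIDUES) - set(df.index)
    if missing or list(df.columns) != list(STATES):
        raise ValueError("propensity table must cover all 20 residues x 4 states")
    return df.loc[list(STANDARD_RESIDUES)]


_DEFAULT_TABLE = None


def default_propensities() -> pd.DataFrame:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_propensities()
    return _DEFAULT_TABLE


def predict_ss(record: ProteinRecord, window: int = DEFAULT_WINDOW,
               propensities: pd.DataFrame | None = None) -> SSFractions:
    """Window-averaged propensity prediction.

    Each residue gets the state with the highest mean propensity over a
    centred window (truncated at the termini); ties break in the fixed order
    helix > strand > turn > coil. Fractions are state counts over length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    table = propensities if propensities is not None else default_propensities()
    idx = encode(record.sequence)
    L = idx.size
    w_eff = min(window, L if L % 2 == 1 else L - 1)
    kernel = np.ones(max(w_eff, 1))
    counts = np.convolve(np.ones(L), kernel, mode="same")
    means = np.empty((len(STATES), L))
    for s, state in enumerate(STATES):
        vals = table[state].to_numpy()[idx]
        means[s] = np.convolve(vals, kernel, mode="same") / counts
    # argmax returns the first maximal index, which is the tie-break order
    assigned = np.argmax(means, axis=0)
    fracs = np.bincount(assigned, minlength=4) / L
    return SSFractions(record.protein_id, *map(float, fracs), source="builtin")


def fractions_from_states(protein_id: str, states: str, source="imported") -> SSFractions:
    """Fractions from a per-residue H/E/T/C state string."""
    counts = {s: 0 for s in STATES}
    for ch in states:
        if ch not in _STATE_LETTERS:
            raise ValueError(f"unknown state letter {ch!r} (expected H/E/T/C)")
        counts[_STATE_LETTERS[ch]] += 1
    n = len(states)
    if n == 0:
        raise ValueError("empty state string")
    return SSFractions(protein_id, counts["helix"] / n, counts["strand"] / n,
                       counts["turn"] / n, counts["coil"] / n, source=source)


def import_ss(path) -> list:
    """Import externally computed secondary-structure fractions.

    Accepts either a TSV with columns protein_id/helix/strand/turn/coil
    (fractions renormalized when their sum lies within [0.98, 1.02], an
    error otherwise) or a FASTA-like file of per-residue H/E/T/C state
    strings (``>id`` headers, wrapped state lines allowed).
    """
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        out = []
        pid, chunks = None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if pid is not None:
                        out.append(fractions_from_states(pid, "".join(chunks)))
                    pid, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line)
        if pid is not None:
            out.append(fractions_from_states(pid, "".join(chunks)))
        return out
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["protein_id", *STATES]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"secondary-structure TSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        vals = np.array([row.helix, row.strand, row.turn, row.coil], dtype=float)
        total = vals.sum()
        if not 0.98 <= total <= 1.02:
            raise ValueError(
                f"protein {row.protein_id!r}: fractions sum to {total:.4f}, "
                "outside [0.98, 1.02]"
            )
        vals = vals / total
        out.append(SSFractions(row.protein_id, *map(float, vals), source="imported"))
    return out
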