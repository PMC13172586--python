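"""Crystal-assay activity quantification.

Raw readouts (crystal count per field, crystal size, aggregate count,
adherent crystals) from blank, negative-control (lysozyme) and fraction
conditions are converted into per-fraction promoting-activity percentages:

    activity_i = 100 * (metric_fraction,i - mean(metric_reference)) / mean(metric_reference)

averaged over replicates with SEM. Positive values are promotion, negative
inhibition. Replicates are treated as independent experiments (no pairing to
specific reference replicates). This percent-change-versus-control form is a
documented reconstruction of the assay quantification; the reference
defaults to the lysozyme negative control, with the blank selectable for
sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import ASSAYS


@dataclass(frozen=True)
class ActivityResult:
    """Promoting activity of one fraction in one assay, in percent."""

    fraction_id: str
    assay: str
    activity_pct: float
    sem_pct: float  # NaN when fewer than 2 replicates
    n_replicates: int


def compute_activity(readouts, assay: str, reference: str = "negative_control") -> list:
    """Per-fraction promoting-activity percentages for one assay."""
    if reference not in ("negative_control", "blank"):
        raise ValueError(f"reference must be negative_control|blank, got {reference!r}")
    rows = [r for r in readouts if r.assay == assay]
    ref_vals = np.array([r.metric_value for r in rows if r.condition == reference])
    if ref_vals.size == 0:
        raise ValueError(f"assay {assay!r}: no {reference} replicates")
    ref_mean = ref_vals.mean()
    if ref_mean <= 0:
        raise ValueError(f"assay {assay!r}: reference mean {ref_mean} is not positive")
    by_fraction: dict[str, list[float]] = {}
    for r in rows:
        if r.condition == "fraction":
            by_fraction.setdefault(r.fraction_id, []).append(r.metric_value)
    if not by_fraction:
        raise ValueError(f"assay {assay!r}: no fraction replicates")
    out = []
    for fraction_id, vals in by_fraction.items():
        acts = 100.0 * (np.asarray(vals) - ref_mean) / ref_mean
        sem = float(acts.std(ddof=1) / np.sqrt(acts.size)) if acts.size > 1 else float("nan")
        out.append(
            ActivityResult(fraction_id, assay, float(acts.mean()), sem, acts.size)
        )
    return out


def compute_activity_panel(readouts, reference: str = "negative_control") -> pd.DataFrame:
    """Activity table for all assays present: one row per fraction.

    Columns are a MultiIndex (assay, {activity_pct, sem_pct, n}).
    """
    assays_present = [a for a in ASSAYS if any(r.assay == a for r in readouts)]
    if not assays_present:
        raise ValueError("no assay readouts")
    frames = {}
    for assay in assays_present:
        results = compute_activity(readouts, assay, reference=reference)
        frames[assay] = pd.DataFrame(
            {
                "activity_pct": {r.fraction_id: r.activity_pct for r in results},
                "sem_pct": {r.fraction_id: r.sem_pct for r in results},
                "n": {r.fraction_id: r.n_replicates for r in results},
            }
        )
    panel = pd.concat(frames, axis=1)
    panel.index.name = "fraction_id"
    return panel.sort_index()


def tidy_replicates(readouts) -> pd.DataFrame:
    """Replicate-level tidy table for downstream significance testing.

    Emits one row per readout (assay/condition/fraction_id/replicate/value);
    performs no test itself. Duplicate replicate indices are an error.
    """
    df = pd.DataFrame(
        [
            (r.assay, r.condition, r.fraction_id, r.replicate, r.metric_value)
            for r in readouts
        ],
        columns=["assay", "condition", "fraction_id", "replicate", "metric_value"],
    )
    if df.empty:
        return df
    if df.duplicated(["assay", "condition", "fraction_id", "replicate"]).any():
        raise ValueError("duplicate replicate id in readouts")
    return df
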