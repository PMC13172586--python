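"""Abundance weighting, the Spearman/Benjamini-Hochberg correlation screen,
and per-fraction descriptive summaries.

The screen's default unit of analysis is the pooled protein-in-fraction
entry: each identified protein contributes its abundance-weighted descriptor
(weight x descriptor) and the abundance-weighted activity of its fraction
(weight x fraction activity). Fraction-level percentage properties (e.g. the
share of high-MW proteins) are intrinsically per-fraction and are correlated
against the per-fraction activities. A correlation is significant when the
Benjamini-Hochberg adjusted p-value is below 0.05 AND |rs| exceeds 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ingest import FractionTable
from .physchem import (
    GRAVY_THRESHOLD,
    INSTABILITY_THRESHOLD,
    MW_THRESHOLD_DA,
)

ALPHA = 0.05
RS_THRESHOLD = 0.8

#: per-protein descriptor columns correlated at the pooled entry level
ENTRY_PROPERTIES = (
    "n_ca_sites",
    "n_ox_motifs",
    "mw_da",
    "instability_index",
    "gravy",
    "frac_aromatic",
    "frac_polar",
    "frac_nonpolar",
    "frac_positive",
    "frac_negative",
    "ss_helix",
    "ss_strand",
    "ss_turn",
    "ss_coil",
)

#: fraction-level percentage properties (computed by summarize_fractions)
FRACTION_PROPERTIES = (
    "pct_ca_binding",
    "pct_ox_binding",
    "pct_low_mw",
    "pct_high_mw",
    "pct_stable",
    "pct_unstable",
    "pct_hydrophilic",
    "pct_hydrophobic",
)

#: report row order: binding, MW, stability, hydropathicity, composition, SS
SCREEN_ORDER = (
    "pct_ca_binding",
    "n_ca_sites",
    "pct_ox_binding",
    "n_ox_motifs",
    "mw_da",
    "pct_low_mw",
    "pct_high_mw",
    "instability_index",
    "pct_stable",
    "pct_unstable",
    "gravy",
    "pct_hydrophilic",
    "pct_hydrophobic",
    "frac_aromatic",
    "frac_polar",
    "frac_nonpolar",
    "frac_positive",
    "frac_negative",
    "ss_helix",
    "ss_strand",
    "ss_turn",
    "ss_coil",
)


def normalize_abundance(table: FractionTable) -> FractionTable:
    """Set per-fraction weights: intensity over the fraction's total intensity."""
    entries = table.entries.copy()
    totals = entries.groupby("fraction_id")["intensity"].transform("sum")
    zero = entries.loc[totals <= 0, "fraction_id"].unique()
    if len(zero):
        raise ValueError(f"fraction(s) with zero total intensity: {sorted(zero)}")
    entries["weight"] = entries["intensity"] / totals
    return FractionTable(fraction_ids=list(table.fraction_ids), entries=entries)


@dataclass(frozen=True)
class SpearmanResult:
    rs: float
    p: float
    n: int
    ok: bool = True  # False when either input is constant (rs undefined)


def spearman(x, y, method: str = "t") -> SpearmanResult:
    """Spearman rank correlation with mid-rank tie handling.

    rs is the Pearson correlation of mid-ranks. The two-sided p-value uses
    the t approximation with n-2 degrees of freedom (``method="t"``) or, for
    n <= 9, exhaustive permutation of one ranking (``method="exact"``).
    Constant inputs yield a flagged, NaN result rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(np.nan, np.nan, n, ok=False)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rs) >= 1.0:
            p = 0.0
        else:
            t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    elif method == "exact":
        if n > 9:
            raise ValueError("exact permutation p-value supported only for n <= 9")
        perms = np.array(list(permutations(range(n))), dtype=np.int64)
        rs_null = np.array(
            [np.corrcoef(rx, ry[p_])[0, 1] for p_ in perms]
        )
        p = float(np.mean(np.abs(rs_null) >= abs(rs) - 1e-12))
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpearmanResult(rs, min(p, 1.0) if p > 0 else p, n)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_weighted_entries(table: FractionTable, profiles: pd.DataFrame,
                           panel: pd.DataFrame) -> pd.DataFrame:
    """Pooled protein-in-fraction entries with abundance-weighted columns.

    One row per (protein, fraction): the normalized weight, ``aw_<prop>`` =
    weight x descriptor for every entry-level descriptor, and
    ``aw_act_<assay>`` = weight x that fraction's activity percentage.
    """
    if not table.has_weights:
        raise ValueError("fraction table has no weights; run normalize_abundance first")
    entries = table.entries[["protein_id", "fraction_id", "weight"]].copy()
    missing_profiles = sorted(set(entries["protein_id"]) - set(profiles.index))
    if missing_profiles:
        raise ValueError(f"proteins without profiles: {missing_profiles[:10]}")
    missing_fracs = sorted(set(entries["fraction_id"]) - set(panel.index))
    if missing_fracs:
        raise ValueError(f"fractions without activity panel: {missing_fracs}")
    props = profiles.loc[entries["protein_id"], list(ENTRY_PROPERTIES)].to_numpy()
    w = entries["weight"].to_numpy()[:, None]
    aw = pd.DataFrame(
        props * w, columns=[f"aw_{c}" for c in ENTRY_PROPERTIES], index=entries.index
    )
    for assay in panel.columns.get_level_values(0).unique():
        act = panel[(assay, "activity_pct")]
        entries[f"aw_act_{assay}"] = (
            entries["fraction_id"].map(act).to_numpy() * entries["weight"].to_numpy()
        )
    return pd.concat([entries, aw], axis=1)


def summarize_fractions(profiles: pd.DataFrame, table: FractionTable) -> pd.DataFrame:
    """Per-fraction descriptive summary (figure-style).

    For each fraction: protein count, mean and SEM of every descriptor, the
    threshold splits (MW 50 kDa, instability 40, GRAVY 0) and the
    calcium-/oxalate-binder percentages. SEM is NaN for single-protein
    fractions.
    """
    rows = []
    for fraction_id in table.fraction_ids:
        pids = table.entries.loc[
            table.entries["fraction_id"] == fraction_id, "protein_id"
        ]
        if pids.empty:
            raise ValueError(f"fraction {fraction_id!r} is empty")
        sub = profiles.loc[pids]
        row = {"fraction_id": fraction_id, "n_proteins": len(sub)}
        for col in ENTRY_PROPERTIES + ("pi",):
            if col not in sub.columns:
                continue
            vals = sub[col].to_numpy(dtype=float)
            row[f"mean_{col}"] = vals.mean()
            row[f"sem_{col}"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
        mw = sub["mw_da"].to_numpy()
        ii = sub["instability_index"].to_numpy()
        gv = sub["gravy"].to_numpy()
        row["pct_low_mw"] = 100.0 * np.mean(mw < MW_THRESHOLD_DA)
        row["pct_high_mw"] = 100.0 * np.mean(mw >= MW_THRESHOLD_DA)
        row["pct_stable"] = 100.0 * np.mean(ii < INSTABILITY_THRESHOLD)
        row["pct_unstable"] = 100.0 * np.mean(ii >= INSTABILITY_THRESHOLD)
        row["pct_hydrophilic"] = 100.0 * np.mean(gv < GRAVY_THRESHOLD)
        row["pct_hydrophobic"] = 100.0 * np.mean(gv >= GRAVY_THRESHOLD)
        row["pct_ca_binding"] = 100.0 * np.mean(sub["n_ca_sites"] >= 1)
        row["pct_ox_binding"] = 100.0 * np.mean(sub["n_ox_motifs"] >= 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("fraction_id")


def correlation_screen(table: FractionTable, profiles: pd.DataFrame,
                       panel: pd.DataFrame, unit: str = "pooled",
                       bh_family: str = "screen", method: str = "t",
                       alpha: float = ALPHA,
                       rs_threshold: float = RS_THRESHOLD) -> pd.DataFrame:
    """Full property x activity Spearman screen with BH adjustment.

    Per-protein descriptors are correlated at the pooled entry level
    (``unit="pooled"``, the default) or, for sensitivity analysis, at the
    fraction level using abundance-weighted fraction means
    (``unit="fraction"``). Fraction-level percentage properties always use
    the per-fraction activities. ``bh_family`` is either ``screen`` (one
    family over all tests, the default) or ``per_activity``. Cells with a
    constant input are reported with NaN rs and excluded from adjustment.
    """
    if unit not in ("pooled", "fraction"):
        raise ValueError(f"unknown unit {unit!r}")
    if bh_family not in ("screen", "per_activity"):
        raise ValueError(f"unknown bh_family {bh_family!r}")
    assays = list(panel.columns.get_level_values(0).unique())
    entries = build_weighted_entries(table, profiles, panel)
    summary = summarize_fractions(profiles, table)
    frac_act = {a: panel[(a, "activity_pct")].reindex(summary.index) for a in assays}

    records = []
    for prop in SCREEN_ORDER:
        for assay in assays:
            if prop in ENTRY_PROPERTIES and unit == "pooled":
                x = entries[f"aw_{prop}"]
                y = entries[f"aw_act_{assay}"]
                kind = "entry"
            elif prop in ENTRY_PROPERTIES:  # fraction-level sensitivity mode
                grouped = entries.groupby("fraction_id")[f"aw_{prop}"].sum()
                x = grouped.reindex(summary.index)
                y = frac_act[assay]
                kind = "fraction"
            else:
                x = summary[prop]
                y = frac_act[assay]
                kind = "fraction"
            res = spearman(x, y, method=method)
            records.append(
                {
                    "property": prop,
                    "assay": assay,
                    "unit": kind,
                    "n": res.n,
                    "rs": res.rs,
                    "p": res.p,
                    "ok": res.ok,
                }
            )
    screen = pd.DataFrame(records)
    screen["p_adj"] = np.nan
    if bh_family == "screen":
        groups = [screen.index[screen["ok"]]]
    else:
        groups = [
            screen.index[screen["ok"] & (screen["assay"] == a)] for a in assays
        ]
    for idx in groups:
        if len(idx):
            screen.loc[idx, "p_adj"] = benjamini_hochberg(
                np.clip(screen.loc[idx, "p"], np.nextafter(0, 1), 1.0)
            )
    screen["significant"] = (
        screen["ok"]
        & (screen["p_adj"] < alpha)
        & (screen["rs"].abs() > rs_threshold)
    )
    return screen


def screen_matrix(screen: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long screen into the report matrix (property rows, assay columns)."""
    mat = screen.pivot(index="property", columns="assay",
                       values=["rs", "p_adj", "significant"])
    return mat.reindex([p for p in SCREEN_ORDER if p in mat.index])
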