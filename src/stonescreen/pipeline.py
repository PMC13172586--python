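"""End-to-end orchestration: profiles, activities, screen, manifests.

These functions are the library form of the command-line subcommands: they
read validated inputs, run every stage, and write plain TSV reports plus a
JSON run manifest (input checksums, configuration snapshot, tool version,
seed) into each output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assays import compute_activity_panel, tidy_replicates
from .binding_motifs import count_calcium_sites, count_oxalate_motifs
from .ingest import (
    read_abundance_table,
    read_assay_table,
    read_fasta,
    read_motif_file,
    read_uniprot_features,
)
from .physchem import (
    DEFAULT_SCHEME,
    compute_composition,
    compute_gravy,
    compute_instability,
    compute_mw,
    compute_pi,
)
from .secstruct import DEFAULT_WINDOW, predict_ss
from .stats import correlation_screen, normalize_abundance, screen_matrix, summarize_fractions

log = logging.getLogger(__name__)

#: run configuration defaults; every key is echoed into the manifest
CONFIG_DEFAULTS = {
    "unknown_policy": "reject",  # FASTA residues outside the 20 standard ones
    "intensity_column": None,  # MaxQuant quantity column (None = plain layout)
    "overlap": "all_starts",  # motif scan mode
    "window": DEFAULT_WINDOW,  # secondary-structure window width (odd)
    "reference": "negative_control",  # activity reference condition
    "unit": "pooled",  # correlation unit: pooled entries or fraction means
    "bh_family": "screen",  # BH adjustment family
    "spearman_method": "t",
    "alpha": 0.05,
    "rs_threshold": 0.8,
}

PROFILE_COLUMNS = [
    "protein_id", "length", "mw_da", "pi", "gravy", "instability_index",
    "frac_aromatic", "frac_polar", "frac_nonpolar", "frac_positive",
    "frac_negative", "n_ca_sites", "n_ox_motifs",
    "ss_helix", "ss_strand", "ss_turn", "ss_coil",
]


def load_config(path=None) -> dict:
    """Run configuration: YAML-style ``key: value`` text over full defaults."""
    config = dict(CONFIG_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(config)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        config.update(user)
    return config


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, inputs: dict, config: dict, seed=None) -> Path:
    manifest = {
        "tool": "stonescreen",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "inputs": {
            name: {"path": str(path), "sha256": _sha256(path)}
            for name, path in inputs.items()
        },
    }
    path = Path(outdir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def build_profiles(records, patterns, feature_sets=None, scheme=DEFAULT_SCHEME,
                   window: int = DEFAULT_WINDOW, overlap: str = "all_starts",
                   ss_fractions=None) -> pd.DataFrame:
    """One full descriptor row per protein, indexed by protein_id.

    ``feature_sets`` supplies UniProt annotations for calcium-site counting
    (proteins without one count zero sites). ``ss_fractions`` (a list of
    imported SSFractions) overrides the built-in secondary-structure
    predictor for the proteins it covers.
    """
    features_by_id = {fs.protein_id: fs for fs in (feature_sets or [])}
    ss_by_id = {s.protein_id: s for s in (ss_fractions or [])}
    rows = []
    for rec in records:
        comp = compute_composition(rec.sequence, scheme)
        ss = ss_by_id.get(rec.protein_id) or predict_ss(rec, window=window)
        fs = features_by_id.get(rec.protein_id)
        rows.append(
            {
                "protein_id": rec.protein_id,
                "length": len(rec.sequence),
                "mw_da": compute_mw(rec.sequence),
                "pi": compute_pi(rec.sequence),
                "gravy": compute_gravy(rec.sequence),
                "instability_index": compute_instability(rec.sequence),
                **comp,
                "n_ca_sites": count_calcium_sites(fs) if fs else 0,
                "n_ox_motifs": count_oxalate_motifs(rec, patterns, overlap=overlap),
                "ss_helix": ss.helix,
                "ss_strand": ss.strand,
                "ss_turn": ss.turn,
                "ss_coil": ss.coil,
            }
        )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS).set_index("protein_id")


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profiles table missing columns {sorted(missing)}")
    return df.set_index("protein_id")


def run_profile(fasta, motifs, out, uniprot=None, config=None) -> Path:
    """Read inputs, compute all per-protein descriptors, write profiles.tsv."""
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(fasta, unknown_policy=cfg["unknown_policy"])
    patterns = read_motif_file(motifs)
    feature_sets = read_uniprot_features(uniprot) if uniprot else []
    profiles = build_profiles(
        records, patterns, feature_sets, window=cfg["window"], overlap=cfg["overlap"]
    )
    log.info("profiled %d proteins", len(profiles))
    path = outdir / "profiles.tsv"
    profiles.reset_index().to_csv(path, sep="\t", index=False)
    inputs = {"fasta": fasta, "motifs": motifs}
    if uniprot:
        inputs["uniprot"] = uniprot
    write_manifest(outdir, inputs, cfg)
    return path


def run_activities(assay_table, out, config=None) -> Path:
    """Compute per-fraction promoting-activity percentages, write activities.tsv."""
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    readouts = read_assay_table(assay_table)
    panel = compute_activity_panel(readouts, reference=cfg["reference"])
    flat = panel.stack(level=0, future_stack=True).reset_index().rename(
        columns={"level_1": "assay"}
    )
    path = outdir / "activities.tsv"
    flat.to_csv(path, sep="\t", index=False)
    tidy_replicates(readouts).to_csv(outdir / "replicates.tsv", sep="\t", index=False)
    write_manifest(outdir, {"assays": assay_table}, cfg)
    return path


def run_screen(profiles, abundance, assay_table, out, config=None) -> dict:
    """Full correlation screen; writes the report tables and a manifest.

    Outputs: screen_long.tsv (one row per property x assay cell),
    screen_matrix.tsv (report-shaped), significant.tsv, and
    fraction_summary.tsv.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    prof = read_profiles(profiles)
    table = read_abundance_table(abundance, intensity_column=cfg["intensity_column"])
    readouts = read_assay_table(assay_table)

    table_proteins = set(table.entries["protein_id"])
    missing = table_proteins - set(prof.index)
    extra = set(prof.index) - table_proteins
    if missing:
        raise ValueError(
            f"id mismatch: {len(missing)} abundance proteins lack profiles "
            f"(e.g. {sorted(missing)[:5]}); {len(extra)} profiles unused"
        )

    table = normalize_abundance(table)
    panel = compute_activity_panel(readouts, reference=cfg["reference"])
    screen = correlation_screen(
        table, prof, panel, unit=cfg["unit"], bh_family=cfg["bh_family"],
        method=cfg["spearman_method"], alpha=cfg["alpha"],
        rs_threshold=cfg["rs_threshold"],
    )
    summary = summarize_fractions(prof, table)

    paths = {
        "screen_long": outdir / "screen_long.tsv",
        "screen_matrix": outdir / "screen_matrix.tsv",
        "significant": outdir / "significant.tsv",
        "fraction_summary": outdir / "fraction_summary.tsv",
    }
    screen.to_csv(paths["screen_long"], sep="\t", index=False)
    screen_matrix(screen).to_csv(paths["screen_matrix"], sep="\t")
    screen.loc[screen["significant"]].to_csv(paths["significant"], sep="\t", index=False)
    summary.reset_index().to_csv(paths["fraction_summary"], sep="\t", index=False)
    write_manifest(
        outdir,
        {"profiles": profiles, "abundance": abundance, "assays": assay_table},
        cfg,
    )
    n_sig = int(screen["significant"].sum())
    log.info("screen: %d/%d significant correlations", n_sig, len(screen))
    return paths
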