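"""Seeded synthetic study inputs: proteome, annotations, abundances, assays.

The generator emulates the structure of a fractionated urinary-proteome
study: 9 anion-exchange fractions with 10, 12, 71, 71, 60, 55, 25, 38 and 6
proteins, log-normal within-fraction abundances, a subset of proteins with
injected calcium-binding BINDING features and oxalate-motif-matching
substrings, and four crystal assays measured in 3 replicates against blank
and lysozyme negative controls.

Statistical structure is planted at the level the correlation screen
analyses: for a planted (descriptor, assay, strength) link, the fraction's
true activity is a strictly increasing function of its abundance-weighted
descriptor mean, blended with an independent random component by
``strength`` and read out with Gaussian replicate noise. Assays without a
planted link draw fraction activities around zero, independent of every
descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_motifs, physchem, secstruct
from .ingest import (
    ASSAYS,
    AssayReadout,
    Feature,
    FractionTable,
    ProteinRecord,
    UniProtFeatureSet,
    read_motif_file,
    write_abundance_table,
    write_assay_table,
)
from .prosite import MotifPattern
from .stats import ENTRY_PROPERTIES

DEFAULT_COUNTS = (10, 12, 71, 71, 60, 55, 25, 38, 6)

#: planted-link activity ranges, percent (promotion scale of each assay)
PLANTED_RANGES = {
    "crystallization": (-20.0, 25.0),
    "growth": (10.0, 70.0),
    "aggregation": (150.0, 320.0),
    "adhesion": (40.0, 60.0),
}

#: reference-condition baseline readout per assay (assay-specific units)
BASELINES = {
    "crystallization": 100.0,  # crystals per field
    "growth": 25.0,  # crystal size, um
    "aggregation": 10.0,  # aggregates per field
    "adhesion": 50.0,  # adherent crystals per field
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_fractions: int = 9
    proteins_per_fraction: tuple = DEFAULT_COUNTS
    length_range: tuple = (80, 7000)
    abundance_mu: float = 10.0  # log-scale location of intensities
    abundance_sigma: float = 2.0  # log-scale spread (orders of magnitude, MS-like)
    planted_links: tuple = (
        ("mw_da", "aggregation", 0.9),
        ("mw_da", "adhesion", 0.9),
    )
    noise_sd: float = 5.0  # replicate noise, activity percentage points
    null_activity_sd: float = 15.0  # fraction-activity spread for unplanted assays
    replicate_count: int = 3
    ca_binder_prob: float = 0.18
    ca_sites_mean: float = 2.0  # extra Poisson sites beyond the first
    ox_binder_prob: float = 0.9
    ox_copies_mean: float = 2.0  # injected motif copies per binder (Poisson)

    def __post_init__(self):
        if self.n_fractions != len(self.proteins_per_fraction):
            raise ValueError("proteins_per_fraction must have n_fractions entries")
        if any(c < 1 for c in self.proteins_per_fraction):
            raise ValueError("all fraction protein counts must be positive")
        if not (1 <= self.length_range[0] <= self.length_range[1]):
            raise ValueError("bad length_range")
        for desc, assay, strength in self.planted_links:
            if assay not in ASSAYS:
                raise ValueError(f"planted link references unknown assay {assay!r}")
            if desc not in ("pi",) + tuple(ENTRY_PROPERTIES):
                raise ValueError(f"planted link references unknown descriptor {desc!r}")
            if not 0.0 <= strength <= 1.0:
                raise ValueError("link strength must lie in [0, 1]")
        if self.noise_sd < 0 or self.null_activity_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")


@dataclass
class SyntheticProteome:
    records: list  # ProteinRecord
    feature_sets: list  # UniProtFeatureSet, one per record
    fraction_table: FractionTable  # raw intensities, weights unset


def load_background(path=None) -> tuple:
    """Residue background frequencies (residues, probabilities)."""
    if path is None:
        path = resources.files("stonescreen.data") / "residue_background.tsv"
    df = pd.read_csv(path, sep="\t", comment="#")
    freqs = df.set_index("residue")["frequency"]
    freqs = freqs / freqs.sum()
    return list(freqs.index), freqs.to_numpy()


def default_motifs() -> list:
    return read_motif_file(resources.files("stonescreen.data") / "oxalate_motifs.txt")


def _realize_motif(pattern: MotifPattern, rng, residues, probs) -> str:
    """A concrete string matching the pattern (minimum repeat counts)."""
    out = []
    for elem in pattern.elements:
        allowed = sorted(elem.allowed)
        for _ in range(elem.min_repeat):
            if len(allowed) == 20:  # wildcard: draw from background
                out.append(residues[rng.choice(len(residues), p=probs)])
            else:
                out.append(allowed[rng.integers(len(allowed))])
    return "".join(out)


def generate_proteome(config: SimulationConfig, patterns=None) -> SyntheticProteome:
    """Sequences, calcium-binding feature fixtures and raw abundances."""
    rng = np.random.default_rng(config.seed)
    patterns = list(patterns) if patterns is not None else default_motifs()
    residues, probs = load_background()
    max_motif = max((p.min_length for p in patterns), default=0)
    if max_motif > config.length_range[0]:
        raise ValueError(
            f"motif length {max_motif} exceeds minimum sequence length "
            f"{config.length_range[0]}"
        )
    alphabet = np.array(list(residues))
    records, feature_sets, rows = [], [], []
    fraction_ids = [f"SFQ{i + 1}" for i in range(config.n_fractions)]
    for frac_id, count in zip(fraction_ids, config.proteins_per_fraction):
        for j in range(count):
            pid = f"{frac_id}_P{j + 1:03d}"
            L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
            seq = rng.choice(alphabet, size=L, p=probs)
            # inject oxalate-motif matches into designated binders
            if patterns and rng.random() < config.ox_binder_prob:
                n_copies = 1 + rng.poisson(max(config.ox_copies_mean - 1, 0.0))
                for _ in range(n_copies):
                    pat = patterns[rng.integers(len(patterns))]
                    s = _realize_motif(pat, rng, residues, probs)
                    start = int(rng.integers(0, L - len(s) + 1))
                    seq[start : start + len(s)] = list(s)
            sequence = "".join(seq)
            records.append(ProteinRecord(pid, sequence, f"synthetic protein {pid}"))
            # calcium-binding feature fixture
            fs = UniProtFeatureSet(protein_id=pid)
            if rng.random() < config.ca_binder_prob:
                n_sites = 1 + rng.poisson(config.ca_sites_mean)
                for _ in range(n_sites):
                    start = int(rng.integers(1, L))
                    end = min(L, start + int(rng.integers(0, 3)))
                    fs.features.append(Feature("BINDING", start, end, "Ca(2+)"))
            feature_sets.append(fs)
            intensity = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
            rows.append((pid, frac_id, intensity))
    table = FractionTable(
        fraction_ids=fraction_ids,
        entries=pd.DataFrame(rows, columns=["protein_id", "fraction_id", "intensity"]),
    )
    return SyntheticProteome(records, feature_sets, table)


def _descriptor_values(proteome: SyntheticProteome, name: str, patterns) -> dict:
    """Per-protein descriptor values for planted-link construction."""
    vals = {}
    ss_cache = {}
    for rec, fs in zip(proteome.records, proteome.feature_sets):
        if name == "mw_da":
            v = physchem.compute_mw(rec.sequence)
        elif name == "gravy":
            v = physchem.compute_gravy(rec.sequence)
        elif name == "instability_index":
            v = physchem.compute_instability(rec.sequence)
        elif name == "pi":
            v = physchem.compute_pi(rec.sequence)
        elif name.startswith("frac_"):
            v = physchem.compute_composition(rec.sequence)[name]
        elif name.startswith("ss_"):
            if rec.protein_id not in ss_cache:
                ss_cache[rec.protein_id] = secstruct.predict_ss(rec)
            v = getattr(ss_cache[rec.protein_id], name[3:])
        elif name == "n_ox_motifs":
            v = binding_motifs.count_oxalate_motifs(rec, patterns)
        elif name == "n_ca_sites":
            v = binding_motifs.count_calcium_sites(fs)
        else:
            raise ValueError(f"unknown descriptor {name!r}")
        vals[rec.protein_id] = float(v)
    return vals


def _fraction_weighted_means(proteome: SyntheticProteome, values: dict) -> pd.Series:
    entries = proteome.fraction_table.entries
    totals = entries.groupby("fraction_id")["intensity"].transform("sum")
    w = entries["intensity"] / totals
    aw = w * entries["protein_id"].map(values)
    return aw.groupby(entries["fraction_id"]).sum().reindex(
        proteome.fraction_table.fraction_ids
    )


def generate_assays(config: SimulationConfig, proteome: SyntheticProteome,
                    patterns=None) -> list:
    """Raw replicate readouts for all four assays, blank and negative control.

    Planted assays order their fraction-level true activities by the
    fraction's abundance-weighted descriptor mean (min-max scaled), blended
    with an independent uniform component by the link strength; unplanted
    assays draw activities from N(0, null_activity_sd). Replicate readouts
    are the reference baseline scaled by (1 + activity/100) with Gaussian
    noise of ``noise_sd`` percentage points.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    patterns = list(patterns) if patterns is not None else default_motifs()
    links = {}
    for desc, assay, strength in config.planted_links:
        if assay in links:
            raise ValueError(f"multiple planted links for assay {assay!r}")
        links[assay] = (desc, strength)
    fraction_ids = proteome.fraction_table.fraction_ids
    readouts = []
    for assay in ASSAYS:
        baseline = BASELINES[assay]
        if assay in links:
            desc, strength = links[assay]
            means = _fraction_weighted_means(
                proteome, _descriptor_values(proteome, desc, patterns)
            )
            span = means.max() - means.min()
            scaled = (
                (means - means.min()) / span
                if span > 0
                else pd.Series(0.5, index=means.index)
            )
            u = rng.uniform(size=len(fraction_ids))
            lo, hi = PLANTED_RANGES[assay]
            acts = lo + (hi - lo) * (strength * scaled.to_numpy() + (1 - strength) * u)
        else:
            acts = rng.normal(0.0, config.null_activity_sd, size=len(fraction_ids))
        for rep in range(1, config.replicate_count + 1):
            for condition, scale in (("blank", 0.9), ("negative_control", 1.0)):
                value = baseline * scale * (1 + rng.normal(0, config.noise_sd) / 100)
                readouts.append(
                    AssayReadout(assay, condition, "", rep, max(value, 0.0))
                )
        for frac_id, act in zip(fraction_ids, acts):
            for rep in range(1, config.replicate_count + 1):
                value = baseline * (1 + (act + rng.normal(0, config.noise_sd)) / 100)
                readouts.append(
                    AssayReadout(assay, "fraction", frac_id, rep, max(value, 0.0))
                )
    return readouts


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    proteome: SyntheticProteome
    readouts: list


def generate_dataset(config: SimulationConfig, patterns=None) -> SyntheticDataset:
    proteome = generate_proteome(config, patterns=patterns)
    readouts = generate_assays(config, proteome, patterns=patterns)
    return SyntheticDataset(config, proteome, readouts)


# ---------------------------------------------------------------------------
# writers (emit exactly the formats the ingest module consumes)


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id} {rec.description}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def write_uniprot_features(feature_sets, records, path) -> None:
    lengths = {r.protein_id: len(r.sequence) for r in records}
    with open(path, "w") as fh:
        for fs in feature_sets:
            fh.write(f"ID   {fs.protein_id}   Unreviewed; {lengths[fs.protein_id]} AA.\n")
            for f in fs.features:
                span = str(f.start) if f.start == f.end else f"{f.start}..{f.end}"
                fh.write(f"FT   {f.kind:<16}{span}\n")
                if f.label:
                    qualifier = "ligand" if f.kind == "BINDING" else "note"
                    fh.write(f"FT   {'':<16}/{qualifier}=\"{f.label}\"\n")
            fh.write("//\n")


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write all study inputs; returns the path of each written file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "proteins.fasta",
        "uniprot": outdir / "uniprot_features.txt",
        "abundance": outdir / "abundance.tsv",
        "assays": outdir / "assays.tsv",
    }
    write_fasta(dataset.proteome.records, paths["fasta"])
    write_uniprot_features(
        dataset.proteome.feature_sets, dataset.proteome.records, paths["uniprot"]
    )
    write_abundance_table(dataset.proteome.fraction_table, paths["abundance"])
    write_assay_table(dataset.readouts, paths["assays"])
    return paths
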