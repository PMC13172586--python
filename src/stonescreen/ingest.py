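"""Input readers and the pipeline data model.

All external inputs — protein FASTA, a MaxQuant-style relative-abundance
table, UniProt flat-text feature annotations, a PROSITE-syntax motif file,
and raw crystal-assay readout tables — are validated here into plain
dataclasses before any computation happens. Writers are provided for the
tabular types so that synthetic datasets round-trip exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .prosite import MotifPattern, parse_pattern

log = logging.getLogger(__name__)

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = set(STANDARD_RESIDUES)
# Ambiguity/rare codes removed under the skip_residue policy.
NONSTANDARD_CODES = set("BJOUXZ")

ASSAYS = ("crystallization", "growth", "aggregation", "adhesion")
CONDITIONS = ("blank", "negative_control", "fraction")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, uppercase standard-residue sequence, description."""

    protein_id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass
class FractionTable:
    """Protein-in-fraction intensities, optionally normalized to weights.

    ``entries`` holds columns protein_id, fraction_id, intensity and (after
    :func:`stonescreen.stats.normalize_abundance`) weight. Fraction order is
    the order of ``fraction_ids``.
    """

    fraction_ids: list
    entries: pd.DataFrame

    def __post_init__(self):
        required = {"protein_id", "fraction_id", "intensity"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"FractionTable entries missing columns {sorted(missing)}")
        if "weight" not in self.entries.columns:
            self.entries = self.entries.assign(weight=np.nan)
        if (self.entries["intensity"] < 0).any():
            raise ValueError("negative intensity in FractionTable")
        dup = self.entries.duplicated(["protein_id", "fraction_id"])
        if dup.any():
            pairs = self.entries.loc[dup, ["protein_id", "fraction_id"]].values[:3]
            raise ValueError(f"duplicate (protein, fraction) pairs, e.g. {pairs.tolist()}")
        unknown = set(self.entries["fraction_id"]) - set(self.fraction_ids)
        if unknown:
            raise ValueError(f"entries reference unknown fractions {sorted(unknown)}")

    @property
    def has_weights(self) -> bool:
        return bool(self.entries["weight"].notna().all()) and len(self.entries) > 0


@dataclass(frozen=True)
class Feature:
    """A UniProt feature relevant to calcium binding."""

    kind: str  # BINDING | DOMAIN | CA_BIND
    start: int
    end: int
    label: str = ""  # ligand for BINDING, description for DOMAIN

    def __post_init__(self):
        if self.kind not in ("BINDING", "DOMAIN", "CA_BIND"):
            raise ValueError(f"unsupported feature kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad feature span {self.start}..{self.end}")


@dataclass
class UniProtFeatureSet:
    protein_id: str
    features: list = field(default_factory=list)


@dataclass(frozen=True)
class AssayReadout:
    """One raw replicate measurement from one crystal assay."""

    assay: str
    condition: str
    fraction_id: str
    replicate: int
    metric_value: float

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "fraction" and not self.fraction_id:
            raise ValueError("fraction readout without fraction_id")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if not np.isfinite(self.metric_value) or self.metric_value < 0:
            raise ValueError(f"metric_value must be finite and >= 0, got {self.metric_value}")


# ---------------------------------------------------------------------------
# Readers


def read_fasta(path, unknown_policy: str = "reject") -> list:
    """Read protein records from FASTA.

    unknown_policy: ``reject`` errors on any residue outside the 20 standard
    ones (with its position); ``skip_residue`` silently drops them and logs
    the total count.
    """
    if unknown_policy not in ("reject", "skip_residue"):
        raise ValueError(f"unknown_policy must be reject|skip_residue, got {unknown_policy!r}")
    records, seen = [], set()
    n_skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate id {pid}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"protein {pid!r}: empty sequence")
        bad_positions = [i for i, aa in enumerate(seq) if aa not in _STANDARD_SET]
        if bad_positions:
            if unknown_policy == "reject":
                i = bad_positions[0]
                raise ValueError(
                    f"protein {pid!r}: non-standard residue {seq[i]!r} at position {i + 1}"
                )
            n_skipped += len(bad_positions)
            seq = "".join(aa for aa in seq if aa in _STANDARD_SET)
            if not seq:
                raise ValueError(f"protein {pid!r}: empty sequence after residue skipping")
        records.append(ProteinRecord(pid, seq, rec.description))
    if n_skipped:
        log.info("read_fasta: skipped %d non-standard residues", n_skipped)
    return records


def read_abundance_table(path, intensity_column: str | None = None) -> FractionTable:
    """Read a protein x fraction intensity table, wide or long.

    Long layout requires columns protein_id / fraction_id / intensity (or the
    name given by ``intensity_column``). Wide layout has a protein-id column
    followed by one numeric column per fraction; when ``intensity_column`` is
    given, only columns named ``"<intensity_column> <fraction>"`` are used
    (MaxQuant style, e.g. ``iBAQ SFQ1``). Zero or missing intensities are
    omitted; negatives are an error.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("abundance table needs at least two columns")
    cols = list(df.columns)
    if "fraction_id" in cols:  # long
        value_col = intensity_column or "intensity"
        for c in ("protein_id", "fraction_id", value_col):
            if c not in cols:
                raise ValueError(f"long abundance table missing column {c!r}")
        entries = df[["protein_id", "fraction_id", value_col]].rename(
            columns={value_col: "intensity"}
        )
        fraction_ids = list(dict.fromkeys(df["fraction_id"]))
    else:  # wide
        id_col = cols[0]
        if intensity_column:
            prefix = intensity_column + " "
            frac_cols = [c for c in cols[1:] if c.startswith(prefix)]
            frac_names = [c[len(prefix):] for c in frac_cols]
        else:
            frac_cols = cols[1:]
            frac_names = frac_cols
        if not frac_cols:
            raise ValueError("no recognizable fraction columns in abundance table")
        long = df.melt(
            id_vars=[id_col], value_vars=frac_cols,
            var_name="fraction_id", value_name="intensity",
        )
        long["fraction_id"] = long["fraction_id"].map(dict(zip(frac_cols, frac_names)))
        long = long.rename(columns={id_col: "protein_id"})
        entries = long
        fraction_ids = frac_names
    entries["intensity"] = pd.to_numeric(entries["intensity"], errors="raise")
    if (entries["intensity"].dropna() < 0).any():
        raise ValueError("negative intensity in abundance table")
    entries = entries[entries["intensity"].fillna(0) > 0].reset_index(drop=True)
    return FractionTable(fraction_ids=list(fraction_ids), entries=entries)


def write_abundance_table(table: FractionTable, path) -> None:
    """Write a FractionTable in long layout (protein_id/fraction_id/intensity)."""
    table.entries[["protein_id", "fraction_id", "intensity"]].to_csv(
        path, sep="\t", index=False
    )


def read_uniprot_features(path) -> list:
    """Parse FT lines from UniProt flat-text entries.

    Captures BINDING (with its /ligand qualifier), DOMAIN (with its /note
    description) and legacy CA_BIND features; all other kinds are ignored.
    Entry ids come from the ID line's first token.
    """
    sets: list[UniProtFeatureSet] = []
    current: UniProtFeatureSet | None = None
    pending: dict | None = None  # feature being assembled

    def flush():
        nonlocal pending
        if pending is not None and pending["kind"] in ("BINDING", "DOMAIN", "CA_BIND"):
            current.features.append(
                Feature(pending["kind"], pending["start"], pending["end"],
                        pending["label"])
            )
        pending = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("ID "):
                current = UniProtFeatureSet(protein_id=line.split()[1])
                sets.append(current)
            elif line.startswith("//"):
                if current is not None:
                    flush()
                current = None
            elif line.startswith("FT"):
                if current is None:
                    raise ValueError(f"line {lineno}: FT line outside an entry")
                body = line[2:]
                key = body[:19].strip()
                rest = body[19:].strip() if len(body) > 19 else ""
                if key:  # new feature
                    flush()
                    span = rest.replace("..", ":")
                    try:
                        if ":" in span:
                            a, b = span.split(":")
                            start, end = int(a), int(b)
                        else:
                            start = end = int(span)
                    except ValueError:
                        raise ValueError(
                            f"line {lineno}: cannot parse feature span {rest!r}"
                        ) from None
                    pending = {"kind": key, "start": start, "end": end, "label": ""}
                else:  # continuation / qualifier
                    if pending is None:
                        raise ValueError(f"line {lineno}: FT continuation without a feature")
                    if rest.startswith("/ligand=") or rest.startswith("/note="):
                        pending["label"] = rest.split("=", 1)[1].strip('"')
                    elif not rest.startswith("/"):
                        # wrapped description text (legacy entries)
                        pending["label"] = (pending["label"] + " " + rest.strip('"')).strip()
    if current is not None:
        flush()
    return sets


def read_motif_file(path) -> list:
    """Read ``name<TAB>pattern`` motif lines; '#' comments and blanks allowed."""
    patterns: list[MotifPattern] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'name<TAB>pattern'")
            name, text = parts
            patterns.append(parse_pattern(text, name=name))
    return patterns


_ASSAY_COLUMNS = ["assay", "condition", "fraction_id", "replicate", "metric_value"]


def read_assay_table(path) -> list:
    """Read raw assay readouts from a tidy TSV.

    Columns: assay / condition / fraction_id / replicate / metric_value.
    Replicate indices must be unique within (assay, condition, fraction_id).
    """
    df = pd.read_csv(path, sep="\t", dtype={"fraction_id": str},
                     float_precision="round_trip")
    missing = set(_ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"assay table missing columns {sorted(missing)}")
    df["fraction_id"] = df["fraction_id"].fillna("")
    readouts = [
        AssayReadout(r.assay, r.condition, r.fraction_id, int(r.replicate),
                     float(r.metric_value))
        for r in df.itertuples()
    ]
    key = df[["assay", "condition", "fraction_id", "replicate"]]
    if key.duplicated().any():
        first = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate replicate index: {first}")
    return readouts


def write_assay_table(readouts, path) -> None:
    pd.DataFrame(
        [
            (r.assay, r.condition, r.fraction_id, r.replicate, r.metric_value)
            for r in readouts
        ],
        columns=_ASSAY_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
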