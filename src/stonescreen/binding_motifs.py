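"""Oxalate-binding motif scanning and calcium-binding site counting.

Oxalate-binding potential is assessed by scanning sequences against a
PROSITE-syntax motif set (the shipped default is a synthetic placeholder to
be replaced with the OxaBIND patterns for real analyses). Calcium-binding
potential is counted from UniProt feature annotations: BINDING features with
a Ca(2+) ligand, DOMAIN features described as calcium-binding, and legacy
CA_BIND features.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .ingest import ProteinRecord, UniProtFeatureSet
from .prosite import match_ends, to_regex


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive


def scan_motifs(record: ProteinRecord, patterns, overlap: str = "all_starts") -> list:
    """All motif matches in a sequence.

    ``all_starts`` reports every (start, end) span whose substring satisfies
    the pattern — including overlapping matches and, for variable-range
    elements, every achievable match length. ``non_overlapping`` takes the
    shortest match at each leftmost start and resumes scanning after it
    (greedy left-to-right), per pattern. Hits are sorted by (start, motif
    name, end).
    """
    if overlap not in ("all_starts", "non_overlapping"):
        raise ValueError(f"unknown overlap mode {overlap!r}")
    seq = record.sequence
    hits: list[MotifHit] = []
    for pat in patterns:
        if overlap == "all_starts" and pat.fixed_length:
            # fast path: fixed-length patterns via an overlapped regex scan
            rx = re.compile(f"(?=({to_regex(pat)}))")
            width = pat.min_length
            for m in rx.finditer(seq):
                hits.append(MotifHit(record.protein_id, pat.name, m.start() + 1,
                                     m.start() + width))
            continue
        pos = 0
        while pos <= len(seq) - pat.min_length:
            ends = match_ends(seq, pos, pat.elements)
            if overlap == "all_starts":
                for end in ends:
                    hits.append(MotifHit(record.protein_id, pat.name, pos + 1, end))
                pos += 1
            else:
                if ends:
                    hits.append(MotifHit(record.protein_id, pat.name, pos + 1, ends[0]))
                    pos = ends[0]
                else:
                    pos += 1
    hits.sort(key=lambda h: (h.start, h.motif_name, h.end))
    return hits


def count_oxalate_motifs(record: ProteinRecord, patterns,
                         overlap: str = "all_starts") -> int:
    """Total motif hits; a protein is oxalate-binding iff the count is >= 1."""
    return len(scan_motifs(record, patterns, overlap=overlap))


def _merge_spans(spans) -> int:
    """Count contiguous groups after merging overlapping/adjacent intervals."""
    if not spans:
        return 0
    spans = sorted(spans)
    groups = 1
    _, cur_end = spans[0]
    for start, end in spans[1:]:
        if start > cur_end + 1:
            groups += 1
            cur_end = end
        else:
            cur_end = max(cur_end, end)
    return groups


def count_calcium_sites(features: UniProtFeatureSet,
                        ligand: str = "Ca(2+)",
                        domain_keyword: str = "calcium-binding") -> int:
    """Calcium-binding site count from UniProt features.

    BINDING features carrying the calcium ligand and legacy CA_BIND regions
    are pooled and de-duplicated by merging overlapping/adjacent spans (a
    contiguous ligand group counts once); calcium-binding DOMAIN features
    each add one.
    """
    ca_spans = [
        (f.start, f.end)
        for f in features.features
        if (f.kind == "BINDING" and ligand in f.label) or f.kind == "CA_BIND"
    ]
    n_domains = sum(
        1
        for f in features.features
        if f.kind == "DOMAIN" and domain_keyword.lower() in f.label.lower()
    )
    return _merge_spans(ca_spans) + n_domains


def summarize_binding(ca_counts, ox_counts) -> dict:
    """Fraction-level binding summary.

    Percentages are over all proteins in the fraction; mean sites/motifs per
    protein are over binders only (count >= 1), with SEM. When a fraction has
    no binders the mean is reported as 0.0 with ``no_binders`` flagged.
    """
    ca = np.asarray(list(ca_counts), dtype=float)
    ox = np.asarray(list(ox_counts), dtype=float)
    if ca.size == 0 or ox.size == 0:
        raise ValueError("empty fraction")

    def _binder_stats(counts):
        binders = counts[counts >= 1]
        pct = 100.0 * binders.size / counts.size
        if binders.size == 0:
            return pct, 0.0, np.nan, True
        mean = float(binders.mean())
        sem = float(binders.std(ddof=1) / np.sqrt(binders.size)) if binders.size > 1 else np.nan
        return pct, mean, sem, False

    pct_ca, mean_ca, sem_ca, ca_empty = _binder_stats(ca)
    pct_ox, mean_ox, sem_ox, ox_empty = _binder_stats(ox)
    return {
        "pct_ca_binding": pct_ca,
        "mean_ca_sites": mean_ca,
        "sem_ca_sites": sem_ca,
        "no_ca_binders": ca_empty,
        "pct_ox_binding": pct_ox,
        "mean_ox_motifs": mean_ox,
        "sem_ox_motifs": sem_ox,
        "no_ox_binders": ox_empty,
    }
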