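"""Read-abundance quantification and contamination profiling.

Counts stringently mapped reads per reference from SAM alignments,
expresses viral load as a per-mille fraction of total reads, normalizes
feature counts to TPM, selects informative samples, and builds COI-based
contamination profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam


@dataclass(frozen=True)
class AbundanceRecord:
    sample_id: str
    reference_id: str
    mapped_reads: int
    total_reads: int

    @property
    def fraction_permille(self) -> float:
        return viral_fraction(self.mapped_reads, self.total_reads)


@dataclass(frozen=True)
class CoiEntryFraction:
    coi_id: str
    mapped_reads: int
    percent_of_coi_mapped: float


def count_mapped(alignments, min_len_frac: float = 0.9,
                 min_sim_frac: float = 0.9) -> dict[str, int]:
    """Count reads mapped to each reference under fraction thresholds.

    A primary alignment counts for its reference iff
    ``aligned_length / read_length >= min_len_frac`` and
    ``(aligned_length - NM) / aligned_length >= min_sim_frac``.  Each read
    contributes at most once (secondary/supplementary alignments are
    ignored); reads lacking an NM tag are skipped with a warning.

    ``alignments`` may be a SAM/BAM path or an open ``pysam.AlignmentFile``.
    """
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), "r")
    counts: dict[str, int] = {}
    for read in alignments:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        read_len = read.infer_read_length() or read.query_length
        aligned = read.query_alignment_length
        if not read_len or not aligned:
            continue
        try:
            nm = read.get_tag("NM")
        except KeyError:
            warnings.warn(f"read {read.query_name} lacks NM tag; skipped")
            continue
        if (aligned / read_len >= min_len_frac
                and (aligned - nm) / aligned >= min_sim_frac):
            counts[read.reference_name] = counts.get(read.reference_name, 0) + 1
    return counts


def viral_fraction(mapped: int, total: int) -> float:
    """Mapped reads over total reads, per mille."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if mapped > total:
        raise ValueError("mapped reads exceed total reads")
    return mapped / total * 1000.0


def select_informative(records: Iterable[AbundanceRecord],
                       min_viral_reads: int = 1000) -> list[str]:
    """Samples whose summed viral mapped reads reach ``min_viral_reads``."""
    per_sample: dict[str, int] = {}
    for r in records:
        per_sample[r.sample_id] = per_sample.get(r.sample_id, 0) + r.mapped_reads
    return sorted(s for s, n in per_sample.items() if n >= min_viral_reads)


def tpm(counts: Mapping[str, float],
        lengths: Mapping[str, float]) -> dict[str, float]:
    """Transcripts-per-million normalization.

    ``rate_i = count_i / length_i``; ``TPM_i = rate_i / sum(rate) * 1e6``.
    All-zero counts yield all-zero TPM.
    """
    missing = set(counts) - set(lengths)
    if missing:
        raise ValueError(f"no length for features: {sorted(missing)[:3]}")
    if any(lengths[f] <= 0 for f in counts):
        raise ValueError("feature lengths must be positive")
    rates = {f: counts[f] / lengths[f] for f in counts}
    total = sum(rates.values())
    if total == 0:
        return {f: 0.0 for f in counts}
    return {f: r / total * 1e6 for f, r in rates.items()}


def coi_profile(coi_counts: Mapping[str, int],
                report_min_percent: float = 0.01) -> list[CoiEntryFraction]:
    """Percent of COI-mapped reads per entry, descending, above a floor."""
    total = sum(coi_counts.values())
    if total == 0:
        warnings.warn("no COI-mapped reads; empty profile")
        return []
    entries = [CoiEntryFraction(cid, n, n / total * 100.0)
               for cid, n in coi_counts.items()
               if n / total * 100.0 >= report_min_percent]
    entries.sort(key=lambda e: (-e.percent_of_coi_mapped, e.coi_id))
    return entries


def abundance_matrix(records: Sequence[AbundanceRecord]):
    """Samples x references table of counts and per-mille fractions."""
    import pandas as pd
    df = pd.DataFrame([{
        "sample_id": r.sample_id, "reference_id": r.reference_id,
        "mapped_reads": r.mapped_reads, "total_reads": r.total_reads,
        "fraction_permille": r.fraction_permille} for r in records])
    return df
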