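"""Low-frequency SNP calling on viral genomes and ADAR-footprint selection.

Builds per-position pileups from SAM alignments, emits variant calls under
joint coverage / count / frequency / context-quality thresholds, selects
the ADAR-compatible (A-to-G) subset, and annotates and summarizes the 5'
neighbor base of each call.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from ._codons import BASES

_BASE_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class SiteCall:
    """A pileup-derived variant call (0-based position).

    ``coverage`` counts reads locally aligned across the site (deletions
    excluded); ``mean_context_quality`` is the mean base quality over the
    5-base window centered on the site, averaged over the reads supporting
    the alternate base.
    """
    reference_id: str
    pos: int
    ref_base: str
    alt_base: str
    coverage: int
    alt_count: int
    frequency: float
    mean_context_quality: float
    neighbor_5p: str = "edge"
    in_cds: bool | None = None

    @property
    def adar_compatible(self) -> bool:
        return self.ref_base == "A" and self.alt_base == "G"


def _pileup_arrays(alignments, ref_len: int, ref_id: str, window: int,
                   strict_qualities: bool):
    """Per-position base counts and summed window-mean qualities."""
    counts = np.zeros((4, ref_len), dtype=np.int64)
    qsums = np.zeros((4, ref_len), dtype=np.float64)
    warned = False
    for read in alignments:
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.reference_name != ref_id):
            continue
        seq = read.query_sequence
        quals = read.query_qualities
        if quals is None:
            if strict_qualities:
                raise ValueError(f"read {read.query_name} lacks base qualities")
            if not warned:
                warnings.warn("missing base qualities; context-quality "
                              "filter treated as passing")
                warned = True
        pairs = read.get_aligned_pairs(matches_only=True)
        qpos_of = {r: q for q, r in pairs}
        for qpos, rpos in pairs:
            if rpos >= ref_len:
                raise ValueError("alignment extends past the reference")
            bi = _BASE_IDX.get(seq[qpos])
            if bi is None:
                continue
            counts[bi, rpos] += 1
            if quals is None:
                qsums[bi, rpos] += np.inf
            else:
                ctx = [quals[qpos_of[r]] for r in range(rpos - window,
                                                        rpos + window + 1)
                       if r in qpos_of]
                qsums[bi, rpos] += float(np.mean(ctx))
    return counts, qsums


def call_snps(alignments, reference: Mapping[str, str] | str,
              min_freq: float = 0.01, min_cov: int = 50,
              min_count: int = 5, min_context_q: float = 30.0,
              context_window: int = 2,
              cds_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
              strict_qualities: bool = False) -> list[SiteCall]:
    """Call per-position alternate bases meeting all thresholds.

    For every reference position and alternate base, a call is emitted iff
    coverage >= ``min_cov``, alternate count >= ``min_count``, alternate
    frequency >= ``min_freq`` (computed per alternate base over locally
    aligned reads), and the mean quality of the ``2*context_window + 1``
    bases centered on the site, averaged over supporting reads, is
    >= ``min_context_q``.  5' neighbors are annotated from the reference.

    ``reference`` maps reference ids to sequences (or is a FASTA path);
    ``cds_intervals`` optionally maps reference ids to 0-based half-open
    ORF intervals used to set ``in_cds``.
    """
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        from Bio import SeqIO
        reference = {r.id: str(r.seq).upper()
                     for r in SeqIO.parse(str(reference), "fasta")}
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        alignments = pysam.AlignmentFile(str(alignments), "r")
    reads = list(alignments)
    calls: list[SiteCall] = []
    for ref_id, ref_seq in reference.items():
        counts, qsums = _pileup_arrays(reads, len(ref_seq), ref_id,
                                       context_window, strict_qualities)
        coverage = counts.sum(axis=0)
        for pos in np.nonzero(coverage >= min_cov)[0]:
            ref_base = ref_seq[pos]
            for bi, alt in enumerate(BASES):
                if alt == ref_base:
                    continue
                n_alt = int(counts[bi, pos])
                if n_alt < min_count:
                    continue
                freq = n_alt / int(coverage[pos])
                if freq < min_freq:
                    continue
                mean_q = qsums[bi, pos] / n_alt
                if mean_q < min_context_q:
                    continue
                in_cds = None
                if cds_intervals is not None:
                    in_cds = any(s <= pos < e
                                 for s, e in cds_intervals.get(ref_id, ()))
                calls.append(SiteCall(
                    reference_id=ref_id, pos=int(pos), ref_base=ref_base,
                    alt_base=alt, coverage=int(coverage[pos]),
                    alt_count=n_alt, frequency=freq,
                    mean_context_quality=float(mean_q),
                    neighbor_5p=ref_seq[pos - 1] if pos > 0 else "edge",
                    in_cds=in_cds))
    calls.sort(key=lambda c: (c.reference_id, c.pos, c.alt_base))
    return calls


def select_adar(calls: Iterable[SiteCall], include_tc: bool = False,
                cds_only: bool = False) -> list[SiteCall]:
    """The ADAR-compatible subset: A->G calls on the reported strand
    (optionally also T->C as antisense evidence)."""
    out = []
    for c in calls:
        if cds_only and c.in_cds is False:
            continue
        if c.adar_compatible or (include_tc and c.ref_base == "T"
                                 and c.alt_base == "C"):
            out.append(c)
    return out


def annotate_neighbor(call: SiteCall,
                      reference: Mapping[str, str]) -> SiteCall:
    """Set ``neighbor_5p`` from the reference base at ``pos - 1``."""
    seq = reference[call.reference_id]
    if not 0 <= call.pos < len(seq):
        raise ValueError("call position outside the reference")
    nb = seq[call.pos - 1] if call.pos > 0 else "edge"
    return replace(call, neighbor_5p=nb)


def neighbor_distribution(calls: Sequence[SiteCall]) -> dict[str, float]:
    """Fraction of calls per 5' neighbor base; edge cases excluded."""
    if not calls:
        raise ValueError("no calls provided")
    inner = [c for c in calls if c.neighbor_5p in _BASE_IDX]
    if not inner:
        raise ValueError("no calls with a defined 5' neighbor")
    return {b: sum(1 for c in inner if c.neighbor_5p == b) / len(inner)
            for b in BASES}


def calls_table(calls: Sequence[SiteCall]):
    """VCF-like TSV-ready table (1-based positions)."""
    import pandas as pd
    return pd.DataFrame([{
        "reference_id": c.reference_id, "pos": c.pos + 1,
        "ref": c.ref_base, "alt": c.alt_base, "coverage": c.coverage,
        "alt_count": c.alt_count, "frequency": c.frequency,
        "mean_context_quality": c.mean_context_quality,
        "neighbor_5p": c.neighbor_5p, "adar": c.adar_compatible,
        "in_cds": c.in_cds} for c in calls])
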