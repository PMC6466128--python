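"""Small-RNA evidence for virus host assignment.

Merges read pairs into fragments, profiles fragment sizes over the
15-50 nt window (with the Dicer 20-22 nt and PIWI 29-30 nt bands),
assigns fragments to viral contigs/ORFs by exact or near-exact matching,
and correlates per-ORF fragment counts with expression to separate RNA
degradation products from genuine RNAi-derived small RNAs: degradation
fragments track transcript abundance (high r-squared), virus-derived
small RNAs do not and are size-focused instead.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._codons import revcomp


@dataclass
class SizeProfile:
    histogram: dict[int, int] = field(default_factory=dict)
    mode_length: int | None = None
    frac_20_22: float = 0.0
    frac_29_30: float = 0.0
    n_profiled: int = 0
    n_excluded: int = 0


@dataclass(frozen=True)
class OrfSrnaEvidence:
    orf_id: str
    srna_count: int
    expression: float


def merge_pairs(r1: Sequence[str], r2: Sequence[str],
                min_overlap: int = 10) -> tuple[list[str], int]:
    """Join read pairs into fragments by maximal exact 3' overlap.

    ``r2`` is reverse-complemented; the longest suffix of R1 equal to a
    prefix of the reverse-complemented R2 (>= ``min_overlap`` nt) defines
    the join.  Pairs without such an overlap are dropped.  Returns
    ``(fragments, n_dropped)``.
    """
    if len(r1) != len(r2):
        raise ValueError("R1/R2 read counts differ")
    fragments: list[str] = []
    dropped = 0
    for a, b in zip(r1, r2):
        rc = revcomp(b)
        best = 0
        for k in range(min(len(a), len(rc)), min_overlap - 1, -1):
            if a[-k:] == rc[:k]:
                best = k
                break
        if best:
            fragments.append(a + rc[best:])
        else:
            dropped += 1
    return fragments, dropped


def size_profile(fragments: Sequence[str] | Sequence[int],
                 min_len: int = 15, max_len: int = 50) -> SizeProfile:
    """Length histogram over [min_len, max_len] with band fractions.

    Accepts sequences or raw lengths.  ``frac_20_22`` / ``frac_29_30``
    are the fractions of profiled fragments in the Dicer- and PIWI-typical
    bands; the mode is the smallest most-frequent length.
    """
    lengths = [len(f) if isinstance(f, str) else int(f) for f in fragments]
    kept = [l for l in lengths if min_len <= l <= max_len]
    prof = SizeProfile(n_profiled=len(kept),
                       n_excluded=len(lengths) - len(kept))
    if not kept:
        warnings.warn("no fragments in the profiled length range")
        return prof
    hist = {l: 0 for l in range(min_len, max_len + 1)}
    for l in kept:
        hist[l] += 1
    prof.histogram = hist
    prof.mode_length = min((l for l in hist), key=lambda l: (-hist[l], l))
    prof.frac_20_22 = sum(hist.get(l, 0) for l in (20, 21, 22)) / len(kept)
    prof.frac_29_30 = sum(hist.get(l, 0) for l in (29, 30)) / len(kept)
    return prof


def _occurrences(fragment: str, target: str, max_mismatch: int) -> list[int]:
    """Start positions where ``fragment`` matches ``target``."""
    m, L = len(fragment), len(target)
    if m == 0 or m > L:
        return []
    if max_mismatch == 0:
        out, i = [], target.find(fragment)
        while i != -1:
            out.append(i)
            i = target.find(fragment, i + 1)
        return out
    tgt = np.frombuffer(target.encode(), dtype=np.uint8)
    frg = np.frombuffer(fragment.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(tgt, m)
    mism = (windows != frg).sum(axis=1)
    return list(np.nonzero(mism <= max_mismatch)[0])


def match_fragments(fragments: Sequence[str], targets: Mapping[str, str],
                    orf_intervals: Mapping[str, Sequence[tuple[str, int, int]]]
                    | None = None,
                    max_mismatch: int = 0,
                    ) -> tuple[dict[str, int], dict[str, int]]:
    """Assign fragments to targets (either strand) and to ORF intervals.

    A fragment counts once per target containing it (plus or minus strand)
    within ``max_mismatch`` substitutions; per-ORF counts use 0-based
    half-open intervals ``(orf_id, start, end)`` per target, a fragment
    counting once per ORF that any of its match intervals overlaps.
    Returns ``(per_target_counts, per_orf_counts)``.
    """
    per_target = {t: 0 for t in targets}
    per_orf: dict[str, int] = {}
    if orf_intervals:
        for ivs in orf_intervals.values():
            for orf_id, _, _ in ivs:
                per_orf.setdefault(orf_id, 0)
    for frag in fragments:
        rc = revcomp(frag)
        for tid, tseq in targets.items():
            occ = _occurrences(frag, tseq, max_mismatch)
            if rc != frag:
                occ = sorted(set(occ) | set(_occurrences(rc, tseq, max_mismatch)))
            if not occ:
                continue
            per_target[tid] += 1
            if orf_intervals:
                for orf_id, s, e in orf_intervals.get(tid, ()):
                    if any(i < e and i + len(frag) > s for i in occ):
                        per_orf[orf_id] += 1
    return per_target, per_orf


def degradation_test(per_orf: Sequence[OrfSrnaEvidence]) -> float:
    """Squared Pearson correlation of per-ORF small-RNA counts vs expression.

    High r-squared indicates degradation-derived fragments (counts track
    transcript abundance); low r-squared together with a high 20-22 nt
    fraction indicates RNAi-derived small RNAs.  Requires >= 3 ORFs and
    non-constant vectors.
    """
    if len(per_orf) < 3:
        raise ValueError("need at least 3 ORFs with defined expression")
    counts = np.array([e.srna_count for e in per_orf], dtype=float)
    expr = np.array([e.expression for e in per_orf], dtype=float)
    if counts.std() == 0 or expr.std() == 0:
        raise ValueError("zero variance in counts or expression")
    r, _ = stats.pearsonr(counts, expr)
    return float(r * r)
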