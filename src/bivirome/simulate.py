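"""Synthetic input generation for the virome pipeline.

Every downstream stage (screening, abundance, SNP calling, motif
under-representation, small-RNA profiling) consumes files this module can
produce: coding sequences with a controllable dinucleotide bias, read
pileups with injected A-to-G edits carrying a 5' neighbor preference, and
small-RNA libraries in degradation-like or RNAi-like (Dicer/PIWI) modes.
All generators are deterministic given their seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import SENSE_CODONS, STOP_CODONS, revcomp

_STOPS = sorted(STOP_CODONS)

#: 5' neighbor preferences of edited adenosines used as simulation defaults
#: (fractions of edited sites per 5' base; an ADAR-like T/A preference).
DEFAULT_NEIGHBOR_PREFS = {"A": 0.31, "T": 0.42, "C": 0.12, "G": 0.15}


class ConfigurationError(ValueError):
    """Raised when simulation parameters cannot be normalized/validated."""


def _normalize(weights: Mapping[str, float], what: str) -> dict[str, float]:
    if any(v < 0 for v in weights.values()):
        raise ConfigurationError(f"negative weight in {what}")
    total = float(sum(weights.values()))
    if not math.isfinite(total) or total <= 0:
        raise ConfigurationError(f"{what} does not sum to a positive value")
    return {k: v / total for k, v in weights.items()}


@dataclass
class SimulationConfig:
    """Bundle of generator parameters; see individual generators for use.

    ``edit_rate`` is the fraction of eligible reference adenosines that
    receive an injected edit; ``edit_freq_range`` is the per-site alternate
    allele frequency window; ``coverage`` is the mean read depth of the
    simulated pileup; ``srna_mode`` selects degradation-like or RNAi-like
    small-RNA libraries.
    """

    seed: int = 0
    codon_usage: dict[str, float] | None = None
    edit_rate: float = 0.05
    neighbor_prefs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEIGHBOR_PREFS))
    coverage: float = 100.0
    error_rate: float = 0.0
    srna_mode: str = "degradation"
    srna_size_sd: float = 1.0
    n_fragments: int = 10000
    edit_freq_range: tuple[float, float] = (0.02, 0.20)
    read_length: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.edit_rate <= 1.0:
            raise ConfigurationError("edit_rate must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigurationError("error_rate must be in [0, 1]")
        if self.srna_mode not in ("degradation", "dicer21", "piwi30"):
            raise ConfigurationError(f"unknown srna_mode {self.srna_mode!r}")
        lo, hi = self.edit_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigurationError("edit_freq_range must be within [0, 1]")
        self.neighbor_prefs = _normalize(self.neighbor_prefs, "neighbor_prefs")
        if self.codon_usage is not None:
            self.codon_usage = _normalize(self.codon_usage, "codon_usage")


def _sense_usage(codon_usage: Mapping[str, float] | None) -> tuple[list[str], np.ndarray]:
    """Sense-codon alphabet and normalized probabilities (stops removed)."""
    if codon_usage is None:
        codons = list(SENSE_CODONS)
        probs = np.full(len(codons), 1.0 / len(codons))
        return codons, probs
    usage = {c: w for c, w in codon_usage.items() if c not in STOP_CODONS and w > 0}
    usage = _normalize(usage, "codon_usage (sense codons)")
    codons = sorted(usage)
    return codons, np.array([usage[c] for c in codons])


def gen_cds(n_codons: int, codon_usage: Mapping[str, float] | None = None,
            seed: int = 0) -> str:
    """An ATG-initiated CDS of ``3 * n_codons`` nt ending in a stop codon.

    ``n_codons`` counts all codons including the start and the terminal
    stop; internal codons are drawn i.i.d. from ``codon_usage`` (uniform
    over the 61 sense codons by default).
    """
    if n_codons < 2:
        raise ValueError("n_codons must be >= 2 (start + stop)")
    codons, probs = _sense_usage(codon_usage)
    rng = np.random.default_rng(seed)
    middle = rng.choice(len(codons), size=n_codons - 2, p=probs)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(codons[i] for i in middle) + stop


def _motif_first_bases(motif: str) -> set[str]:
    if motif == "WA":
        return {"A", "T"}
    if motif in ("AA", "CA", "GA", "TA"):
        return {motif[0]}
    raise ValueError(f"unsupported motif {motif!r}")


def _new_motifs(prev_base: str, codon: str, next_first: str | None,
                first: set[str]) -> int:
    """Motif occurrences ``codon`` creates in its local context.

    Counts pairs inside ``prev_base + codon`` plus the downstream junction
    pair ``(codon[-1], next_first)`` when the next first base is known.
    """
    s = prev_base + codon + (next_first or "")
    return sum(1 for i in range(len(s) - 1) if s[i] in first and s[i + 1] == "A")


def gen_depleted_cds(n_codons: int, motif: str, strength: float,
                     seed: int = 0,
                     codon_usage: Mapping[str, float] | None = None) -> str:
    """A CDS whose synonymous codon choices avoid creating ``motif``.

    Amino-acid content follows the same marginal as :func:`gen_cds`.  A
    provisional codon is drawn per position from ``codon_usage``; each is
    then re-drawn within its synonymous family with the probability of a
    codon creating ``k`` motif occurrences — codon-internal, across the
    junction with the previous codon, or across the junction with the
    (provisional) next codon — damped by ``(1 - strength)**k``.  The
    one-codon lookahead matters: junction occurrences are the component a
    third-position permutation test can detect, so depletion must remove
    them, not only the codon-internal ones.  At strength 0 this reduces to
    the :func:`gen_cds` distribution; at strength 1 motif-creating codons
    are used only when every synonym creates one (then a minimal-count
    synonym is kept).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    first = _motif_first_bases(motif)
    codons, probs = _sense_usage(codon_usage)
    weight_of = dict(zip(codons, probs))
    by_aa: dict[str, list[str]] = {}
    from ._codons import CODON_TO_AA
    for c in codons:
        by_aa.setdefault(CODON_TO_AA[c], []).append(c)

    rng = np.random.default_rng(seed)
    provisional = [codons[i]
                   for i in rng.choice(len(codons), size=max(0, n_codons - 2),
                                       p=probs)]
    out = ["ATG"]
    prev = "G"
    for t, draft in enumerate(provisional):
        nxt = provisional[t + 1][0] if t + 1 < len(provisional) else None
        family = by_aa[CODON_TO_AA[draft]]
        counts = [_new_motifs(prev, c, nxt, first) for c in family]
        w = np.array([weight_of[c] * (1.0 - strength) ** k
                      for c, k in zip(family, counts)])
        if w.sum() <= 0:  # strength == 1 and every synonym creates the motif
            kmin = min(counts)
            w = np.array([weight_of[c] if k == kmin else 0.0
                          for c, k in zip(family, counts)])
        chosen = family[rng.choice(len(family), p=w / w.sum())]
        out.append(chosen)
        prev = chosen[-1]
    stop_counts = [_new_motifs(prev, s, None, first) for s in _STOPS]
    w = np.array([(1.0 - strength) ** k for k in stop_counts])
    if w.sum() <= 0:
        kmin = min(stop_counts)
        w = np.array([1.0 if k == kmin else 0.0 for k in stop_counts])
    out.append(_STOPS[rng.choice(len(_STOPS), p=w / w.sum())])
    return "".join(out)


def random_sequence(length: int, seed: int = 0,
                    probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)) -> str:
    """Uniform-ish random nucleotide sequence (test/reference scaffolds)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=length, p=np.asarray(probs))])


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``fractions``."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def gen_edited_pileup(reference: str, config: SimulationConfig,
                      reference_id: str = "ref1"):
    """Simulate a read pileup over ``reference`` with injected A-to-G edits.

    Returns ``(sam_text, truth)`` where ``sam_text`` is a complete SAM file
    (header + single-end, full-length-match alignments tiling the reference
    at roughly ``config.coverage`` depth) and ``truth`` is a DataFrame of
    injected sites (0-based ``pos``, ``neighbor_5p``, ``injected_freq``,
    realized ``coverage``/``alt_count``/``realized_freq``).

    Edited sites are drawn from adenosines in the fully tiled interior of
    the reference, allocated across 5'-neighbor classes proportionally to
    ``config.neighbor_prefs`` (largest-remainder rounding, uniform within a
    class).  Each edited site converts ``round(freq * coverage_at_site)``
    covering reads to G, so the realized alternate fraction matches the
    injected one within rounding.  Sequencing errors are uniform random
    substitutions at ``config.error_rate`` per base.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    rng = np.random.default_rng(config.seed)
    L = len(reference)
    read_len = min(config.read_length, L)
    n_reads = int(round(config.coverage * L / read_len))
    starts = np.sort(rng.integers(0, L - read_len + 1, size=n_reads))

    # eligible edited sites: interior A with a defined 5' neighbor
    lo, hi = max(1, read_len - 1), max(1, L - read_len)
    eligible = [i for i in range(lo, hi + 1) if reference[i] == "A"]
    truth_rows = []
    edited: dict[int, float] = {}
    if eligible:
        by_nb: dict[str, list[int]] = {}
        for i in eligible:
            by_nb.setdefault(reference[i - 1], []).append(i)
        total_edits = int(round(config.edit_rate * len(eligible)))
        nbs = sorted(by_nb)
        prefs = np.array([config.neighbor_prefs.get(b, 0.0) for b in nbs])
        if prefs.sum() > 0 and total_edits > 0:
            alloc = _largest_remainder(total_edits, prefs / prefs.sum())
            for b, k in zip(nbs, alloc):
                k = min(k, len(by_nb[b]))
                for i in rng.choice(by_nb[b], size=k, replace=False):
                    flo, fhi = config.edit_freq_range
                    edited[int(i)] = float(rng.uniform(flo, fhi))
    elif reference.count("A") == 0:
        import warnings
        warnings.warn("reference contains no adenosine; truth table is empty")

    reads = [list(reference[s:s + read_len]) for s in starts]
    # realize each edit as an exact count of alternate reads
    cover = [np.nonzero((starts <= pos) & (starts + read_len > pos))[0]
             for pos in edited]
    for (pos, freq), idx in zip(edited.items(), cover):
        n_cov = len(idx)
        n_alt = int(round(freq * n_cov))
        alt_idx = rng.choice(idx, size=n_alt, replace=False) if n_alt else []
        for ri in alt_idx:
            reads[ri][pos - starts[ri]] = "G"
        truth_rows.append({
            "reference_id": reference_id, "pos": pos, "ref_base": "A",
            "alt_base": "G", "neighbor_5p": reference[pos - 1],
            "injected_freq": freq, "coverage": n_cov, "alt_count": n_alt,
            "realized_freq": n_alt / n_cov if n_cov else 0.0,
        })

    if config.error_rate > 0:
        other = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}
        for r in reads:
            hits = np.nonzero(rng.random(len(r)) < config.error_rate)[0]
            for j in hits:
                r[j] = other[r[j]][rng.integers(3)]

    lines = ["@HD\tVN:1.6\tSO:coordinate",
             f"@SQ\tSN:{reference_id}\tLN:{L}"]
    qual = "I" * read_len
    for i, (s, r) in enumerate(zip(starts, reads)):
        seq = "".join(r)
        nm = sum(1 for a, b in zip(seq, reference[s:s + read_len]) if a != b)
        lines.append("\t".join([
            f"read{i:06d}", "0", reference_id, str(s + 1), "60",
            f"{read_len}M", "*", "0", "0", seq, qual, f"NM:i:{nm}"]))
    truth = pd.DataFrame(truth_rows, columns=[
        "reference_id", "pos", "ref_base", "alt_base", "neighbor_5p",
        "injected_freq", "coverage", "alt_count", "realized_freq"])
    if not truth.empty:
        truth = truth.sort_values("pos", kind="stable").reset_index(drop=True)
    return "\n".join(lines) + "\n", truth


def gen_srna_library(viral_orfs: Sequence[tuple[str, float]],
                     config: SimulationConfig) -> pd.DataFrame:
    """Simulate a 15-50 nt small-RNA fragment library from viral ORFs.

    ``viral_orfs`` is a list of ``(sequence, expression_weight)``.  In
    ``degradation`` mode fragment counts per ORF are multinomial with
    probabilities proportional to expression and lengths uniform on
    [15, 50]; in ``dicer21``/``piwi30`` modes the source ORF is uniform
    (independent of expression) and lengths are Normal(21 or 30,
    ``srna_size_sd``) truncated to [15, 50].  Fragments are substrings of
    their source ORF, on either strand.  Returns a DataFrame with columns
    fragment_id, sequence, orf_index, length, strand.
    """
    if not viral_orfs:
        raise ConfigurationError("viral_orfs must be non-empty")
    weights = np.array([w for _, w in viral_orfs], dtype=float)
    if (weights < 0).any():
        raise ConfigurationError("expression weights must be >= 0")
    if weights.sum() <= 0:
        raise ConfigurationError("all expression weights are zero")
    rng = np.random.default_rng(config.seed)
    n = config.n_fragments
    min_len, max_len = 15, 50

    if config.srna_mode == "degradation":
        orf_idx = rng.choice(len(viral_orfs), size=n, p=weights / weights.sum())
        lengths = rng.integers(min_len, max_len + 1, size=n)
    else:
        mean = 21.0 if config.srna_mode == "dicer21" else 30.0
        orf_idx = rng.integers(0, len(viral_orfs), size=n)
        lengths = np.empty(n, dtype=int)
        need = np.ones(n, dtype=bool)
        while need.any():  # truncated normal by rejection
            draw = np.rint(rng.normal(mean, config.srna_size_sd,
                                      size=int(need.sum()))).astype(int)
            ok = (draw >= min_len) & (draw <= max_len)
            idx = np.nonzero(need)[0]
            lengths[idx[ok]] = draw[ok]
            need[idx[ok]] = False

    rows = []
    for i in range(n):
        seq = viral_orfs[int(orf_idx[i])][0]
        length = int(min(lengths[i], len(seq)))
        start = int(rng.integers(0, len(seq) - length + 1))
        frag = seq[start:start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        rows.append({"fragment_id": f"frag{i:06d}", "sequence": frag,
                     "orf_index": int(orf_idx[i]), "length": length,
                     "strand": strand})
    return pd.DataFrame(rows, columns=["fragment_id", "sequence", "orf_index",
                                       "length", "strand"])


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs or a gen_srna_library frame as FASTA."""
    if isinstance(records, pd.DataFrame):
        records = [
            (f"{r.fragment_id}|orf={r.orf_index}|strand={r.strand}", r.sequence)
            for r in records.itertuples()]
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
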