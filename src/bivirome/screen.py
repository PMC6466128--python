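"""Viral-candidate screening of transcriptome contigs.

Implements the decision cascade used to call RNA-virus candidates from an
assembly: six-frame ORF prediction with a minimum length in codons,
evidence filtering from external search-tool tables (BLAST tabular /
HMMER domtblout), host-genome subtraction, greedy identity clustering of
the candidate proteins, completeness classification of candidate genomes,
and polyA-tail detection.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import STOP_CODONS, revcomp, translate

#: PFAM accessions of viral RNA-dependent RNA polymerase domains used as
#: the marker-gene route for RNA-virus detection.
VRDRP_ACCESSIONS = frozenset(
    {"PF00680", "PF00978", "PF00998", "PF02123", "PF07925", "PF04197"})

_VALID_CONTIG = re.compile(r"^[ACGTN]*$")


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a contig (0-based half-open coordinates)."""
    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    complete: bool
    protein: str


@dataclass(frozen=True)
class EvidenceHit:
    query_id: str
    subject_id: str
    evalue: float
    source: str  # "blastp" or "hmmer"
    domain_acc: str = ""


@dataclass
class ViralCandidate:
    contig_id: str
    length: int
    orfs: list[Orf] = field(default_factory=list)
    evidence: list[EvidenceHit] = field(default_factory=list)
    host_matched: bool = False
    completeness: str = "partial"
    polya: bool = False
    cluster_rep: str = ""


def find_orfs(contig: str, min_codons: int = 100,
              contig_id: str = "") -> list[Orf]:
    """Six-frame scan for maximal ORFs encoding >= ``min_codons`` residues.

    A complete ORF runs ATG..stop entirely inside the contig (the earliest
    ATG after the previous in-frame stop; the stop codon is not counted
    towards ``min_codons`` and is excluded from the protein).  ATG-initiated
    open ranges that run off the contig edge without a stop are reported
    with ``complete=False``.
    """
    contig = contig.upper()
    if len(contig) < 3:
        raise ValueError("contig shorter than one codon")
    if not _VALID_CONTIG.match(contig):
        raise ValueError("contig contains non-ACGTN characters")
    orfs: list[Orf] = []
    L = len(contig)
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        for frame in range(3):
            start_atg = None
            for pos in range(frame, len(seq) - 2, 3):
                codon = seq[pos:pos + 3]
                if start_atg is None and codon == "ATG":
                    start_atg = pos
                elif codon in STOP_CODONS and start_atg is not None:
                    n_aa = (pos - start_atg) // 3
                    if n_aa >= min_codons:
                        s, e = start_atg, pos + 3
                        if strand == "-":
                            s, e = L - e, L - s
                        orfs.append(Orf(contig_id, s, e, strand, frame, True,
                                        translate(seq[start_atg:pos])))
                    start_atg = None
                elif codon in STOP_CODONS:
                    start_atg = None
            if start_atg is not None:  # open range to the contig edge
                end = start_atg + 3 * ((len(seq) - start_atg) // 3)
                n_aa = (end - start_atg) // 3
                if n_aa >= min_codons:
                    s, e = start_atg, end
                    if strand == "-":
                        s, e = L - e, L - s
                    orfs.append(Orf(contig_id, s, e, strand, frame, False,
                                    translate(seq[start_atg:end])))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def filter_evidence(hits: Iterable[EvidenceHit],
                    evalue_cutoff: float = 1e-50,
                    min_hits: int = 5,
                    domain_evalue: float = 1e-5,
                    vrdrp_accessions: frozenset[str] = VRDRP_ACCESSIONS,
                    ) -> set[str]:
    """Queries passing the similarity-evidence filter.

    A query is kept when it has >= ``min_hits`` blastp alignments (distinct
    subjects) at E-value <= ``evalue_cutoff``, or at least one HMMER hit to
    a viral RdRp PFAM domain at E-value <= ``domain_evalue``.
    """
    blast_subjects: dict[str, set[str]] = {}
    kept: set[str] = set()
    for h in hits:
        if h.source == "blastp" and h.evalue <= evalue_cutoff:
            blast_subjects.setdefault(h.query_id, set()).add(h.subject_id)
        elif h.source == "hmmer" and h.evalue <= domain_evalue:
            acc = h.domain_acc.split(".")[0]
            if acc in vrdrp_accessions:
                kept.add(h.query_id)
    kept.update(q for q, subs in blast_subjects.items() if len(subs) >= min_hits)
    return kept


def subtract_host(candidates: set[str], host_hits: Iterable[EvidenceHit],
                  evalue_cutoff: float = 1e-5) -> set[str]:
    """Remove candidates with a host-genome match at the cutoff."""
    matched = {h.query_id for h in host_hits if h.evalue <= evalue_cutoff}
    return set(candidates) - matched


def _lcs_length(a: str, b: str) -> int:
    """Longest common subsequence length = maximal matched positions of a
    global alignment with no mismatch/gap penalties."""
    if not a or not b:
        return 0
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(len(b) + 1, dtype=np.int32)
    for ch in a.encode("ascii"):
        cur = np.empty_like(prev)
        cur[0] = 0
        match = prev[:-1] + (bb == ch)
        np.maximum(match, prev[1:], out=cur[1:])
        np.maximum.accumulate(cur, out=cur)
        prev = cur
    return int(prev[-1])


def pairwise_identity(a: str, b: str) -> float:
    """Matched positions over the shorter sequence length (cd-hit style)."""
    if not a or not b:
        return 0.0
    return _lcs_length(a, b) / min(len(a), len(b))


def cluster_by_identity(seqs: Sequence[str],
                        threshold: float = 0.90) -> list[list[int]]:
    """Greedy longest-first clustering at an identity threshold.

    Sequences are processed longest first (ties broken lexicographically);
    each joins the first existing representative with identity >= the
    threshold, else founds a new cluster.  Returns clusters as lists of
    input indices, the representative first.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), seqs[i]))
    clusters: list[list[int]] = []
    for i in order:
        for cl in clusters:
            if pairwise_identity(seqs[i], seqs[cl[0]]) >= threshold:
                cl.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def classify_completeness(length: int, orfs: Sequence[Orf],
                          min_length: int = 5000) -> str:
    """'nearly_complete' iff the contig exceeds ``min_length`` nt and
    carries at least one complete ORF, else 'partial'."""
    if length > min_length and any(o.complete for o in orfs):
        return "nearly_complete"
    return "partial"


def detect_polya(contig: str, min_run: int = 15,
                 max_nonA_frac: float = 0.1, max_window: int = 200) -> bool:
    """True when a 3'-terminal window of >= ``min_run`` nt is almost all A.

    Scans terminal windows from ``min_run`` up to ``max_window`` nt and
    accepts if any has a non-A fraction <= ``max_nonA_frac``.
    """
    contig = contig.upper()
    upper = min(len(contig), max_window)
    for k in range(min_run, upper + 1):
        tail = contig[-k:]
        if (k - tail.count("A")) / k <= max_nonA_frac:
            return True
    return False


# ---------------------------------------------------------------------------
# External-table readers and report writers

_BLAST6_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def read_blast_tab(path) -> list[EvidenceHit]:
    """Read BLAST tabular output (outfmt 6 default columns) as blastp hits."""
    df = pd.read_csv(path, sep="\t", names=_BLAST6_COLS, comment="#")
    return [EvidenceHit(r.qseqid, r.sseqid, float(r.evalue), "blastp")
            for r in df.itertuples()]


def read_domtbl(path) -> list[EvidenceHit]:
    """Read HMMER ``--domtblout`` (hmmscan orientation: the sequence is the
    query, the PFAM model the target); uses the per-domain i-Evalue."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            hits.append(EvidenceHit(query_id=f[3], subject_id=f[0],
                                    evalue=float(f[11]), source="hmmer",
                                    domain_acc=f[1]))
    return hits


def screen_contigs(contigs: Mapping[str, str],
                   hits: Iterable[EvidenceHit],
                   host_hits: Iterable[EvidenceHit] = (),
                   min_orf_codons: int = 100,
                   evalue_cutoff: float = 1e-50,
                   min_hits: int = 5,
                   cluster_threshold: float = 0.90,
                   min_contig_len: int = 200) -> list[ViralCandidate]:
    """Run the full screening cascade over a contig set.

    Evidence query ids must be ORF/protein ids of the form
    ``<contig_id>.<n>`` or plain contig ids; candidates are contigs whose
    evidence survives filtering and host subtraction.  Candidate proteins
    (longest complete ORF per contig, else longest ORF) are clustered and
    each candidate is annotated with its cluster representative.
    """
    hits = list(hits)
    kept_queries = subtract_host(
        filter_evidence(hits, evalue_cutoff, min_hits), host_hits)
    kept_contigs = {q.split(".")[0] for q in kept_queries}
    candidates = []
    for cid, seq in contigs.items():
        if cid not in kept_contigs or len(seq) < min_contig_len:
            continue
        orfs = find_orfs(seq, min_orf_codons, contig_id=cid)
        cand = ViralCandidate(
            contig_id=cid, length=len(seq), orfs=orfs,
            evidence=[h for h in hits if h.query_id.split(".")[0] == cid],
            completeness=classify_completeness(len(seq), orfs),
            polya=detect_polya(seq))
        candidates.append(cand)
    proteins = []
    for cand in candidates:
        pool = [o for o in cand.orfs if o.complete] or cand.orfs
        proteins.append(max(pool, key=lambda o: len(o.protein)).protein
                        if pool else "")
    if candidates:
        for cl in cluster_by_identity(proteins, cluster_threshold):
            rep = candidates[cl[0]].contig_id
            for i in cl:
                candidates[i].cluster_rep = rep
    return candidates


def candidates_table(candidates: Sequence[ViralCandidate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "contig_id": c.contig_id, "length": c.length,
        "n_orfs": len(c.orfs),
        "n_complete_orfs": sum(o.complete for o in c.orfs),
        "completeness": c.completeness, "polya": c.polya,
        "cluster_rep": c.cluster_rep,
    } for c in candidates])


def orfs_to_gff3(orfs: Sequence[Orf]) -> str:
    """GFF3 text for ORF annotations (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for i, o in enumerate(orfs):
        attrs = f"ID=orf{i};complete={str(o.complete).lower()}"
        lines.append("\t".join([
            o.contig_id or ".", "bivirome", "ORF", str(o.start + 1),
            str(o.end), ".", o.strand, "0", attrs]))
    return "\n".join(lines) + "\n"
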