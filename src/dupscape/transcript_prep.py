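"""Transcript-level preparation rules.

Four bespoke rules operate before any clustering:

* translation of the longest ORF over 6 frames (or a hinted frame), with
  the first-methionine trim applied when the ORF is stop-bounded at both
  ends and the post-M remainder is at least 75% of the ORF;
* completeness classification (5'-complete iff an in-frame stop lies
  upstream of the ORF; 3'-complete iff the ORF ends at a stop);
* a within-species redundancy merge: single-linkage clustering of pairs
  matching at >= 98% identity over a match of >= 50 bp, keeping the
  longest member as representative;
* a cross-species contamination filter: within near-identical clusters
  (99% identity / 99% coverage, single linkage across species), members
  whose species-summed abundance is below 1% of the cluster maximum are
  flagged.

Identity is matches over aligned columns of the best local alignment
(end overhangs excluded); coverage is the aligned span over the shorter
sequence's length.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Optional, Sequence

from Bio import Align
from Bio.Seq import Seq

from .core_io import AbundanceTable, ProteinRecord, SearchThresholds, Transcript
from .molecular_rates import _GENETIC_CODE

logger = logging.getLogger("dupscape")

__all__ = [
    "translate_longest_orf",
    "classify_completeness",
    "merge_redundant",
    "filter_cross_species_contaminants",
]

_FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def _stranded(seq: str, frame: int) -> str:
    return seq if frame > 0 else str(Seq(seq).reverse_complement())


def _translate(codon: str) -> str:
    return _GENETIC_CODE.get(codon, "X")  # N/ambiguity -> X, never a stop


def _frame_peptide(seq: str, frame: int) -> tuple[str, int]:
    """Translated string for one frame and the nt offset of its first codon."""
    s = _stranded(seq, frame)
    off = abs(frame) - 1
    usable = (len(s) - off) // 3
    pep = "".join(_translate(s[off + 3 * i: off + 3 * i + 3]) for i in range(usable))
    return pep, off


def _orfs_in_frame(seq: str, frame: int):
    """Yield (aa, aa_start, aa_end, bounded5, bounded3) stop-free stretches."""
    pep, _ = _frame_peptide(seq, frame)
    start = 0
    for i, aa in enumerate(pep + "*"):
        if aa == "*":
            if i > start:
                yield pep[start:i], start, i, start > 0, i < len(pep)
            start = i + 1


def translate_longest_orf(
    t: Transcript,
    frame_hint: Optional[int] = None,
    min_orf_aa: int = 30,
    m_trim_frac: float = 0.75,
) -> Optional[ProteinRecord]:
    """Translate the longest open reading frame of a transcript.

    Searches the hinted frame only when given, else all 6 frames.  Ties go
    to the earlier frame in (+1,+2,+3,-1,-2,-3) order, then the 5'-most
    start.  ORFs shorter than ``min_orf_aa`` drop the record (None, with a
    logged reason).  When the ORF is stop-bounded at both ends and the
    stretch from its first M is at least ``m_trim_frac`` of its length, the
    record is trimmed to that M.
    """
    if len(t.sequence) < 3:
        raise ValueError(f"transcript {t.id}: shorter than one codon")
    frames = (frame_hint,) if frame_hint is not None else _FRAME_ORDER
    best = None  # (aa, frame, aa_start, bounded5, bounded3)
    for frame in frames:
        for aa, a0, a1, b5, b3 in _orfs_in_frame(t.sequence, frame):
            if best is None or len(aa) > len(best[0]):
                best = (aa, frame, a0, b5, b3)
    if best is None or len(best[0]) < min_orf_aa:
        logger.info("dropping %s: no ORF >= %d aa", t.id, min_orf_aa)
        return None
    aa, frame, a0, b5, b3 = best
    off = abs(frame) - 1
    trimmed = False
    if b5 and b3 and "M" in aa:
        m_idx = aa.index("M")
        if (len(aa) - m_idx) / len(aa) >= m_trim_frac:
            aa = aa[m_idx:]
            a0 += m_idx
            trimmed = True
    rec = ProteinRecord(
        transcript_id=t.id,
        frame=frame,
        aa_sequence=aa,
        five_prime_complete=b5,
        three_prime_complete=b3,
        trimmed_to_first_M=trimmed,
        species=t.species,
        orf_start=off + 3 * a0,
        orf_end=off + 3 * (a0 + len(aa)),
    )
    return rec


def classify_completeness(
    p: ProteinRecord, t: Transcript, m_at_start_complete: bool = False
) -> tuple[bool, bool]:
    """Recompute (5'-complete, 3'-complete) from the ORF coordinates.

    5'-complete iff an in-frame stop codon exists upstream of the ORF start
    (optionally also when the ORF starts with M at the transcript 5' end);
    3'-complete iff the codon just past the ORF is an in-frame stop.
    """
    s = _stranded(t.sequence, p.frame)
    five = False
    for pos in range(p.orf_start - 3, -1, -3):
        if _translate(s[pos:pos + 3]) == "*":
            five = True
            break
    if not five and m_at_start_complete:
        five = p.aa_sequence.startswith("M") and p.orf_start <= abs(p.frame) - 1 + 2
    codon_after = s[p.orf_end:p.orf_end + 3]
    three = len(codon_after) == 3 and _translate(codon_after) == "*"
    return five, three


# ---------------------------------------------------------------------------
# Pairwise identity machinery (shared by the merge and contamination rules)
# ---------------------------------------------------------------------------

def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -7
    a.extend_gap_score = -2
    return a


def _local_identity(s1: str, s2: str) -> tuple[float, int, int]:
    """(identity fraction, aligned columns, non-gap aligned columns)."""
    aligner = _nt_aligner()
    try:
        aln = next(iter(aligner.align(s1, s2)))
    except StopIteration:
        return 0.0, 0, 0
    c = aln.counts()
    cols = c.gaps + c.identities + c.mismatches
    if cols == 0:
        return 0.0, 0, 0
    return c.identities / cols, cols, c.identities + c.mismatches


def _kmer_candidates(
    seqs: dict[str, str], k: int = 16
) -> set[tuple[str, str]]:
    """Pairs of ids sharing at least one exact k-mer (alignment prefilter)."""
    index: dict[str, set] = defaultdict(set)
    for sid, s in seqs.items():
        for i in range(0, max(len(s) - k + 1, 1)):
            index[s[i:i + k]].add(sid)
    pairs: set[tuple[str, str]] = set()
    for ids in index.values():
        if len(ids) < 2:
            continue
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.add((ids[i], ids[j]))
    return pairs


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)

    def clusters(self) -> dict[str, list]:
        out: dict[str, list] = defaultdict(list)
        for x in self.parent:
            out[self.find(x)].append(x)
        return {k: sorted(v) for k, v in out.items()}


def merge_redundant(
    transcripts: Sequence[Transcript],
    thresholds: Optional[SearchThresholds] = None,
) -> tuple[list[list[str]], list[Transcript]]:
    """Single-linkage redundancy merge within one species.

    Pairs whose best local alignment reaches the identity threshold over a
    match of at least ``min_match_bp`` are linked; each cluster keeps its
    longest member (ties: lexicographically smallest id) as representative.
    Returns (clusters as sorted id lists, representatives).
    """
    if thresholds is None:
        thresholds = SearchThresholds(identity_pct=98.0, min_match_bp=50)
    species = {t.species for t in transcripts}
    if len(species) > 1:
        raise ValueError(f"merge_redundant expects one species, got {sorted(species)}")
    by_id = {t.id: t for t in transcripts}
    if len(by_id) != len(transcripts):
        raise ValueError("duplicate transcript ids")
    uf = _UnionFind(by_id)
    seqs = {t.id: t.sequence for t in transcripts}
    for a, b in sorted(_kmer_candidates(seqs)):
        ident, cols, _ = _local_identity(seqs[a], seqs[b])
        if cols >= thresholds.min_match_bp and ident * 100.0 >= thresholds.identity_pct:
            uf.union(a, b)
    clusters = sorted(uf.clusters().values())
    reps = [
        by_id[min(c, key=lambda i: (-len(by_id[i].sequence), i))] for c in clusters
    ]
    logger.info("redundancy merge: %d transcripts -> %d clusters",
                len(transcripts), len(clusters))
    return clusters, reps


def filter_cross_species_contaminants(
    transcripts: Sequence[Transcript],
    abundance: AbundanceTable,
    thresholds: Optional[SearchThresholds] = None,
    abundance_frac: float = 0.01,
) -> set:
    """Flag probable cross-species contaminants.

    Transcripts of different species are linked (single linkage) when their
    best local alignment reaches 99% identity and covers 99% of the shorter
    sequence.  Within each multi-species cluster, members whose
    species-summed abundance is below ``abundance_frac`` of the cluster
    maximum are flagged; the maximum itself never is.  Single-species
    clusters are ignored.  A transcript missing from the abundance table is
    an error naming it.
    """
    if thresholds is None:
        thresholds = SearchThresholds(identity_pct=99.0, coverage_pct=99.0)
    by_id = {t.id: t for t in transcripts}
    for t in transcripts:
        if t.id not in abundance:
            raise KeyError(f"transcript {t.id!r} missing from abundance table")
    uf = _UnionFind(by_id)
    seqs = {t.id: t.sequence for t in transcripts}
    for a, b in sorted(_kmer_candidates(seqs)):
        ident, cols, nongap = _local_identity(seqs[a], seqs[b])
        shorter = min(len(seqs[a]), len(seqs[b]))
        coverage = nongap / shorter if shorter else 0.0
        if (
            ident * 100.0 >= thresholds.identity_pct
            and coverage * 100.0 >= thresholds.coverage_pct
        ):
            uf.union(a, b)
    flagged: set = set()
    for members in uf.clusters().values():
        sp = {by_id[m].species for m in members}
        if len(sp) < 2:
            continue
        sums = {m: abundance.species_sum(m, by_id[m].species) for m in members}
        top = max(sums, key=lambda m: (sums[m], m))
        cut = abundance_frac * sums[top]
        for m in members:
            if m != top and sums[m] < cut:
                flagged.add(m)
    logger.info("contamination filter flagged %d/%d transcripts",
                len(flagged), len(transcripts))
    return flagged
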