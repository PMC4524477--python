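"""Homolog clustering across species and alignment-trimming rules.

Clusters are single-linkage over pairwise protein similarity (mirroring
BLASTCLUST semantics): a pair links when the best local alignment reaches
70% amino-acid identity and covers 60% of the shorter sequence, by
default.  The built-in scorer is exact local alignment with BLOSUM62 and
affine gaps — adequate at desk scale; precomputed pair tables from an
external search can be supplied instead.

Alignment trimming follows two rules: (1) clusters are trimmed to the
column window bounded by the shortest of the per-species longest members;
(2) sequences with gaps in more than 25% of the retained columns are
removed.  A gap-heavy column filter (a stand-in for trimAl's strictplus)
then removes columns above a 20% gap fraction while always keeping
single-residue-state columns.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord, SearchThresholds, Transcript
from .molecular_rates import _GENETIC_CODE
from .transcript_prep import _UnionFind, _stranded

logger = logging.getLogger("dupscape")

__all__ = [
    "HomologyCluster",
    "protein_pair_scores",
    "cluster_homologs",
    "require_species",
    "attach_outgroup",
    "trim_cluster_alignment",
    "strict_column_filter",
    "back_translate",
]


@dataclass
class HomologyCluster:
    id: str
    members: list  # list of (protein id, species)
    stage: str = "blastclust_like"  # | "plus_outgroup" | "plus_arachnids"
    alignment: Optional[dict] = None

    def species_census(self) -> dict:
        out: dict[str, int] = {}
        for _, sp in self.members:
            out[sp] = out.get(sp, 0) + 1
        return out

    def member_ids(self) -> list:
        return [m for m, _ in self.members]


def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def protein_pair_scores(s1: str, s2: str) -> tuple[float, float, float]:
    """(identity %, coverage %, score) of the best local protein alignment."""
    aligner = _aa_aligner()
    try:
        aln = max(aligner.align(s1, s2), key=lambda a: a.score)
    except (StopIteration, ValueError):
        return 0.0, 0.0, 0.0
    c = aln.counts()
    cols = c.gaps + c.identities + c.mismatches
    if cols == 0:
        return 0.0, 0.0, 0.0
    ident = 100.0 * c.identities / cols
    nongap = c.identities + c.mismatches
    coverage = 100.0 * nongap / min(len(s1), len(s2))
    return ident, coverage, float(aln.score)


def cluster_homologs(
    proteins: Sequence[ProteinRecord],
    thresholds: Optional[SearchThresholds] = None,
    pair_table: Optional[Sequence[tuple]] = None,
) -> list[HomologyCluster]:
    """Single-linkage homolog clustering of translated proteins.

    ``pair_table`` rows are (qid, sid, identity_pct, coverage_pct, score)
    from an external search; when absent, all pairs are scored with the
    built-in aligner.  Order-invariant and idempotent: ids are processed
    sorted.
    """
    if thresholds is None:
        thresholds = SearchThresholds(identity_pct=70.0, coverage_pct=60.0)
    by_id = {p.transcript_id: p for p in proteins}
    uf = _UnionFind(by_id)
    if pair_table is not None:
        for row in pair_table:
            qid, sid, ident, cov = row[0], row[1], float(row[2]), float(row[3])
            if qid in by_id and sid in by_id and qid != sid:
                if ident >= thresholds.identity_pct and cov >= thresholds.coverage_pct:
                    uf.union(qid, sid)
    else:
        ids = sorted(by_id)
        for a, b in itertools.combinations(ids, 2):
            ident, cov, _ = protein_pair_scores(
                by_id[a].aa_sequence, by_id[b].aa_sequence
            )
            if ident >= thresholds.identity_pct and cov >= thresholds.coverage_pct:
                uf.union(a, b)
    clusters = []
    for k, members in enumerate(sorted(uf.clusters().values())):
        clusters.append(
            HomologyCluster(
                id=f"cl{k}",
                members=[(m, by_id[m].species) for m in members],
            )
        )
    logger.info("clustered %d proteins into %d clusters", len(by_id), len(clusters))
    return clusters


def require_species(
    clusters: Sequence[HomologyCluster], required: set
) -> list[HomologyCluster]:
    """Keep clusters containing at least one member of every required species."""
    kept = [c for c in clusters if required <= set(dict(c.members).values())]
    logger.info("species requirement %s: %d -> %d clusters",
                sorted(required), len(clusters), len(kept))
    return kept


def attach_outgroup(
    clusters: Sequence[HomologyCluster],
    outgroup_proteins: Sequence[ProteinRecord],
    focal_proteins: Sequence[ProteinRecord],
    focal_species: set,
    min_score: float = 50.0,
    scorer: Callable[[str, str], tuple] = protein_pair_scores,
) -> list[HomologyCluster]:
    """Attach outgroup sequences to clusters by best-per-species agreement.

    An outgroup protein joins a cluster only when, for *every* focal
    species, its best-scoring focal match belongs to that same cluster and
    passes ``min_score`` (a score-threshold substitute for a search
    e-value cutoff).  Outgroup proteins whose per-species best matches
    disagree across clusters stay unattached (logged).
    """
    by_id = {p.transcript_id: p for p in focal_proteins}
    cluster_of: dict[str, int] = {}
    for ci, c in enumerate(clusters):
        for m, _ in c.members:
            cluster_of[m] = ci
    out = [
        HomologyCluster(c.id, list(c.members), stage="plus_outgroup",
                        alignment=c.alignment)
        for c in clusters
    ]
    for og in outgroup_proteins:
        target: Optional[int] = None
        ok = True
        for sp in sorted(focal_species):
            candidates = [p for p in by_id.values() if p.species == sp]
            if not candidates:
                ok = False
                break
            best = max(
                candidates,
                key=lambda p: (scorer(og.aa_sequence, p.aa_sequence)[2], p.transcript_id),
            )
            score = scorer(og.aa_sequence, best.aa_sequence)[2]
            if score < min_score or best.transcript_id not in cluster_of:
                ok = False
                break
            ci = cluster_of[best.transcript_id]
            if target is None:
                target = ci
            elif target != ci:
                ok = False
                logger.info("outgroup %s: best matches span clusters; unattached",
                            og.transcript_id)
                break
        if ok and target is not None:
            out[target].members.append((og.transcript_id, og.species))
    return out


# ---------------------------------------------------------------------------
# Alignment trimming
# ---------------------------------------------------------------------------

def _nongap_window(seq: str) -> Optional[tuple[int, int]]:
    first = None
    last = None
    for i, ch in enumerate(seq):
        if ch != "-":
            if first is None:
                first = i
            last = i
    if first is None:
        return None
    return first, last + 1


def trim_cluster_alignment(
    alignment: dict[str, str],
    species_of: dict[str, str],
    max_gap_frac: float = 0.25,
) -> Optional[tuple[dict[str, str], list]]:
    """Trim to per-species-longest boundaries, then drop gap-heavy members.

    The trim window is the intersection of the first-to-last non-gap
    columns of each species' longest member — i.e. bounded by the shortest
    of the per-species longest sequences.  After trimming, sequences whose
    gap fraction over the retained columns exceeds ``max_gap_frac`` are
    removed (terminal and internal gaps both count).  Returns (trimmed
    alignment, removed ids), or None when the window is empty (cluster
    dropped, logged).
    """
    if not alignment:
        return None
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    by_species: dict[str, list] = {}
    for sid in alignment:
        by_species.setdefault(species_of[sid], []).append(sid)
    lo, hi = 0, next(iter(lengths))
    for sp, sids in sorted(by_species.items()):
        longest = min(sids, key=lambda s: (-len(alignment[s].replace("-", "")), s))
        win = _nongap_window(alignment[longest])
        if win is None:
            logger.info("cluster dropped: all-gap longest member for %s", sp)
            return None
        lo, hi = max(lo, win[0]), min(hi, win[1])
    if lo >= hi:
        logger.info("cluster dropped: empty trim window")
        return None
    trimmed = {sid: s[lo:hi] for sid, s in alignment.items()}
    removed = []
    kept = {}
    for sid, s in sorted(trimmed.items()):
        gap_frac = s.count("-") / len(s)
        if gap_frac > max_gap_frac:
            removed.append(sid)
        else:
            kept[sid] = s
    if removed:
        logger.info("trim removed %d gap-heavy members", len(removed))
    return kept, removed


def strict_column_filter(
    alignment: dict[str, str],
    max_gap_frac: float = 0.20,
    return_columns: bool = False,
):
    """Drop columns whose gap fraction exceeds the threshold.

    Columns where every non-gap residue is the same single state are always
    retained regardless of gaps.  With ``return_columns`` the kept column
    indices are also returned, so a parallel codon alignment can be
    filtered consistently.
    """
    if not alignment:
        return ({}, []) if return_columns else {}
    sids = sorted(alignment)
    ncol = len(alignment[sids[0]])
    n = len(sids)
    kept_cols = []
    for j in range(ncol):
        col = [alignment[s][j] for s in sids]
        gaps = col.count("-")
        states = {c for c in col if c != "-"}
        if len(states) == 1 or gaps / n <= max_gap_frac:
            kept_cols.append(j)
    out = {s: "".join(alignment[s][j] for j in kept_cols) for s in alignment}
    if return_columns:
        return out, kept_cols
    return out


def back_translate(
    alignment_aa: dict[str, str],
    coding_nt: dict[str, str],
) -> dict[str, str]:
    """Replace aligned amino acids with their underlying codons.

    ``coding_nt`` maps each sequence id to the in-frame coding nucleotides
    of its full peptide (e.g. the ORF slice of the transcript).  The
    alignment's ungapped residues must be a contiguous block of that
    peptide (boundary-trimmed alignments are; apply column filters to the
    codon alignment afterwards, via ``strict_column_filter``'s column
    indices).  Gaps become ``---`` triplets; every emitted codon is checked
    against its residue, with errors naming the sequence and column.
    """
    out: dict[str, str] = {}
    for sid, row in alignment_aa.items():
        nt = coding_nt[sid]
        peptide = "".join(
            _GENETIC_CODE.get(nt[i:i + 3], "X") for i in range(0, len(nt) - 2, 3)
        )
        ungapped = row.replace("-", "")
        start = peptide.find(ungapped)
        if start < 0:
            start = 0  # let the per-column check name the offending column
        codons = []
        k = start
        for col, ch in enumerate(row):
            if ch == "-":
                codons.append("---")
                continue
            codon = nt[3 * k: 3 * k + 3]
            aa = _GENETIC_CODE.get(codon, "X")
            if aa != ch and ch != "X":
                raise ValueError(
                    f"back_translate: {sid}: codon {codon} at column {col} "
                    f"translates to {aa}, expected {ch}"
                )
            codons.append(codon)
            k += 1
        out[sid] = "".join(codons)
    return out


def transcript_coding_nt(t: Transcript, p: ProteinRecord) -> str:
    """The ORF nucleotide slice of a transcript, on the ORF's strand."""
    return _stranded(t.sequence, p.frame)[p.orf_start:p.orf_end]
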