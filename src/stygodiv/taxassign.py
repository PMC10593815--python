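"""Identity-based taxonomic assignment calibrated by a barcoding-gap analysis.

The assignment rule mirrors standard COI barcoding practice: a query (Sanger
barcode or metabarcoding ASV) is assigned to the species of its best-identity
reference, provided the alignment covers at least ``coverage_min`` percent of
the query and the identity exceeds ``identity_min`` percent. The identity
threshold itself is calibrated from the reference database with a barcoding-gap
analysis: if the largest within-species pairwise distance is smaller than the
smallest between-species distance, any identity cutoff inside that gap
separates conspecific from heterospecific matches, and the gap midpoint is
suggested.

Alignment model
---------------
``align_identity`` computes an overlap (semi-global) alignment with unit
scores: match +1, mismatch -1, gap -1, and free end gaps on both sequences, so
a short amplicon contained in a full-length barcode aligns without penalty for
the reference overhangs, and junk query ends reduce query coverage instead of
identity. Identity is the fraction of matched columns among all aligned query
columns (gap columns included); coverage is the fraction of query bases inside
the aligned region. Ties in the dynamic program are broken deterministically
(diagonal, then query-gap-consuming, then reference-consuming moves; end cell:
last-row cells first, at the smallest column).

For kingdom-level screening of non-target ASVs, ``classify_placements``
consumes phylogenetic-placement output (taxon, likelihood weight ratio) and
keeps the best placement only when its LWR exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

from .io_formats import SequenceRecord, ValidationError

__all__ = [
    "AlignmentHit",
    "Assignment",
    "GapReport",
    "PlacementRecord",
    "align_identity",
    "barcoding_gap_analysis",
    "assign_sequences",
    "classify_placements",
]

ASSIGNED = "assigned"
UNASSIGNED = "unassigned"
AMBIGUOUS = "ambiguous"

_UNAMBIGUOUS = set("ACGTU")


@dataclass(frozen=True)
class AlignmentHit:
    """Best-scoring overlap alignment of one query against one reference."""

    query_id: str
    reference_id: str
    species: str | None
    identity: float  # percent over aligned query columns
    query_coverage: float  # percent of query bases inside the aligned region
    score: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValidationError(f"identity {self.identity} out of [0, 100]")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValidationError(f"coverage {self.query_coverage} out of [0, 100]")


@dataclass(frozen=True)
class Assignment:
    query_id: str
    status: str  # assigned | unassigned | ambiguous
    species: str | None = None
    best_identity: float | None = None
    best_coverage: float | None = None
    n_tied_species: int = 0

    def __post_init__(self) -> None:
        if (self.species is not None) != (self.status == ASSIGNED):
            raise ValidationError(
                f"{self.query_id}: species must be set iff status is 'assigned'"
            )


@dataclass(frozen=True)
class GapReport:
    """Extremes of the intra/inter-specific distance distributions."""

    max_intraspecific_distance: float  # percent
    min_interspecific_distance: float  # percent
    gap_exists: bool
    suggested_identity_threshold: float | None  # percent, midpoint of the gap
    n_intra_pairs: int
    n_inter_pairs: int
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class PlacementRecord:
    asv_id: str
    taxon: str
    lwr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lwr <= 1.0):
            raise ValidationError(
                f"placement for {self.asv_id}: LWR {self.lwr} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# Alignment kernel
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


@njit(cache=True)
def _overlap_align(q: np.ndarray, r: np.ndarray):  # pragma: no cover - numba
    """Overlap alignment; returns (score, matches, aligned_cols, q_bases).

    Scores: match +1, mismatch -1, gap -1; end gaps free on both sequences.
    Tie-breaks (must match the test oracle): recurrence prefers diagonal, then
    up (consume query), then left (consume reference); the end cell is the
    first maximum scanning the last row left-to-right, then the last column
    top-to-bottom.
    """
    n, m = len(q), len(r)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = 1 if qi == r[j - 1] else -1
            best = H[i - 1, j - 1] + s
            up = H[i - 1, j] - 1
            if up > best:
                best = up
            left = H[i, j - 1] - 1
            if left > best:
                best = left
            H[i, j] = best
    # end cell: last row (small j first), then last column (small i first)
    ei, ej = n, 0
    best_score = H[n, 0]
    for j in range(1, m + 1):
        if H[n, j] > best_score:
            best_score = H[n, j]
            ei, ej = n, j
    for i in range(0, n):
        if H[i, m] > best_score:
            best_score = H[i, m]
            ei, ej = i, m
    # traceback
    matches = 0
    cols = 0
    qbases = 0
    i, j = ei, ej
    while i > 0 and j > 0:
        s = 1 if q[i - 1] == r[j - 1] else -1
        if H[i, j] == H[i - 1, j - 1] + s:
            if s == 1:
                matches += 1
            cols += 1
            qbases += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] - 1:
            cols += 1
            qbases += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best_score, matches, cols, qbases


def align_identity(query: SequenceRecord, reference: SequenceRecord) -> AlignmentHit:
    """Align ``query`` against ``reference`` and report identity and coverage.

    Raises :class:`ValidationError` if either sequence consists solely of
    ambiguity codes (nothing alignable).
    """
    for rec in (query, reference):
        if not any(c in _UNAMBIGUOUS for c in rec.sequence):
            raise ValidationError(
                f"sequence {rec.id!r} contains only ambiguity codes"
            )
    score, matches, cols, qbases = _overlap_align(
        _encode(query.sequence), _encode(reference.sequence)
    )
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * qbases / len(query.sequence)
    return AlignmentHit(
        query_id=query.id,
        reference_id=reference.id,
        species=reference.species,
        identity=identity,
        query_coverage=coverage,
        score=int(score),
    )


# ---------------------------------------------------------------------------
# Barcoding gap
# ---------------------------------------------------------------------------

def barcoding_gap_analysis(refdb: Sequence[SequenceRecord]) -> GapReport:
    """Partition all pairwise distances (100 - identity) of a species-labelled
    reference database into intra- and inter-specific sets and report the gap.

    The suggested identity threshold is the midpoint of the gap,
    ``100 - (max_intra + min_inter) / 2``, strictly inside
    ``(100 - min_inter, 100 - max_intra)`` whenever the gap exists.
    """
    labelled = [r for r in refdb if r.species]
    species = {r.species for r in labelled}
    if len(species) < 2 or len(labelled) < 2:
        raise ValidationError(
            "barcoding gap analysis needs at least two species and two sequences"
        )
    warnings = tuple(
        f"species {sp!r} has a single sequence (no intraspecific pairs)"
        for sp in sorted(species)
        if sum(r.species == sp for r in labelled) < 2
    )
    intra: list[float] = []
    inter: list[float] = []
    for a_idx in range(len(labelled)):
        for b_idx in range(a_idx + 1, len(labelled)):
            a, b = labelled[a_idx], labelled[b_idx]
            dist = 100.0 - align_identity(a, b).identity
            (intra if a.species == b.species else inter).append(dist)
    if not intra:
        raise ValidationError(
            "no intraspecific pairs at all: the barcoding gap is undefined"
        )
    max_intra = max(intra)
    min_inter = min(inter)
    gap_exists = min_inter > max_intra
    suggested = 100.0 - (max_intra + min_inter) / 2.0 if gap_exists else None
    return GapReport(
        max_intraspecific_distance=max_intra,
        min_interspecific_distance=min_inter,
        gap_exists=gap_exists,
        suggested_identity_threshold=suggested,
        n_intra_pairs=len(intra),
        n_inter_pairs=len(inter),
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def assign_sequences(
    queries: Sequence[SequenceRecord],
    refdb: Sequence[SequenceRecord],
    identity_min: float = 94.0,
    coverage_min: float = 99.0,
    tie_tol: float = 1e-9,
    prescreen_kmer: int | None = 11,
) -> list[Assignment]:
    """Assign each query to the species of its best-identity reference.

    Hits covering less than ``coverage_min`` percent of the query are
    discarded; among the rest only identities strictly above ``identity_min``
    qualify. When two or more distinct species tie at the top identity (within
    ``tie_tol``) the query is reported ``ambiguous`` rather than picking one
    arbitrarily: an assignment is a claim about species presence.

    ``prescreen_kmer`` skips the quadratic alignment for query/reference pairs
    sharing no exact k-mer (the classic seed heuristic); queries near the
    identity threshold always share many, so the screen cannot change results,
    only skip hopeless references. Set to ``None`` to disable.
    """
    if not refdb:
        raise ValidationError("empty reference database")
    if not (0.0 < identity_min <= 100.0 and 0.0 < coverage_min <= 100.0):
        raise ValidationError("thresholds must lie in (0, 100]")
    ref_kmers = None
    if prescreen_kmer:
        ref_kmers = [_kmer_set(r.sequence, prescreen_kmer) for r in refdb]
    results: list[Assignment] = []
    for query in queries:
        q_kmers = _kmer_set(query.sequence, prescreen_kmer) if prescreen_kmer else None
        hits: list[AlignmentHit] = []
        for idx, ref in enumerate(refdb):
            if ref_kmers is not None and not (q_kmers & ref_kmers[idx]):
                continue
            hit = align_identity(query, ref)
            if hit.query_coverage >= coverage_min:
                hits.append(hit)
        qualifying = [h for h in hits if h.identity > identity_min]
        if not qualifying:
            results.append(Assignment(query.id, UNASSIGNED))
            continue
        best = max(h.identity for h in qualifying)
        top = [h for h in qualifying if h.identity >= best - tie_tol]
        top_species = {h.species for h in top}
        if len(top_species) > 1:
            results.append(
                Assignment(
                    query.id,
                    AMBIGUOUS,
                    best_identity=best,
                    best_coverage=max(h.query_coverage for h in top),
                    n_tied_species=len(top_species),
                )
            )
        else:
            winner = max(top, key=lambda h: h.identity)
            results.append(
                Assignment(
                    query.id,
                    ASSIGNED,
                    species=winner.species,
                    best_identity=winner.identity,
                    best_coverage=winner.query_coverage,
                    n_tied_species=1,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Phylogenetic-placement decision rule
# ---------------------------------------------------------------------------

def classify_placements(
    placements: Iterable[PlacementRecord], lwr_min: float = 0.5
) -> dict[str, str]:
    """Per ASV, keep the taxon with the highest likelihood weight ratio, but
    only when that LWR is strictly greater than ``lwr_min``; otherwise the ASV
    is classified ``"unassigned"``.
    """
    best: dict[str, PlacementRecord] = {}
    for p in placements:
        cur = best.get(p.asv_id)
        if cur is None or p.lwr > cur.lwr:
            best[p.asv_id] = p
    return {
        asv: (p.taxon if p.lwr > lwr_min else UNASSIGNED) for asv, p in best.items()
    }
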