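from __future__ import annotations

import numpy as np
import pytest

import stygodiv as sg
from stygodiv.io_formats import ValidationError
from stygodiv.synthetic import generate_reference_db, sample_within_species_queries
from stygodiv.taxassign import AMBIGUOUS, ASSIGNED, UNASSIGNED, PlacementRecord

from helpers import overlap_align_oracle


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------------------
# align_identity
# ---------------------------------------------------------------------------

def test_self_alignment_is_perfect(rng):
    seq = _rand_seq(rng, 200)
    hit = sg.align_identity(
        sg.SequenceRecord("q", seq), sg.SequenceRecord("r", seq, species="X")
    )
    assert hit.identity == 100.0
    assert hit.query_coverage == 100.0
    assert hit.species == "X"


def test_substitutions_lower_identity_exactly(rng):
    """200-nt query with 12 interior substitutions: identity 94.0, coverage 100."""
    ref = _rand_seq(rng, 200)
    q = list(ref)
    pos = rng.choice(np.arange(10, 190), size=12, replace=False)
    for p in pos:
        q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
    hit = sg.align_identity(
        sg.SequenceRecord("q", "".join(q)), sg.SequenceRecord("r", ref)
    )
    assert hit.identity == pytest.approx(94.0)
    assert hit.query_coverage == pytest.approx(100.0)


def test_containment_alignment(rng):
    """100-nt query inside a 658-nt reference with 1 interior mismatch:
    identity 99.0, coverage 100 (reference overhangs are free)."""
    ref = _rand_seq(rng, 658)
    q = list(ref[300:400])
    q[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[50]]
    hit = sg.align_identity(
        sg.SequenceRecord("q", "".join(q)), sg.SequenceRecord("r", ref)
    )
    assert hit.identity == pytest.approx(99.0)
    assert hit.query_coverage == pytest.approx(100.0)


def test_ambiguity_only_sequence_rejected():
    with pytest.raises(ValidationError, match="ambiguity"):
        sg.align_identity(
            sg.SequenceRecord("q", "NNNN"), sg.SequenceRecord("r", "ACGT")
        )


def test_alignment_agrees_with_pure_python_dp(rng):
    """Implementation vs an independently written quadratic DP with the same
    declared tie-break rules, on random pairs up to 60 nt."""
    from stygodiv.taxassign import _encode, _overlap_align

    for _ in range(200):
        n = int(rng.integers(1, 61))
        m = int(rng.integers(1, 61))
        q, r = _rand_seq(rng, n), _rand_seq(rng, m)
        score, matches, cols, qb = _overlap_align(_encode(q), _encode(r))
        o_score, o_matches, o_cols, o_qb = overlap_align_oracle(q, r)
        assert (score, matches, cols, qb) == (o_score, o_matches, o_cols, o_qb)


def test_adding_a_reference_never_lowers_best_identity(rng):
    refs = [
        sg.SequenceRecord(f"r{i}", _rand_seq(rng, 80), species=f"S{i}")
        for i in range(4)
    ]
    q = sg.SequenceRecord("q", _rand_seq(rng, 60))
    best3 = max(sg.align_identity(q, r).identity for r in refs[:3])
    best4 = max(sg.align_identity(q, r).identity for r in refs)
    assert best4 >= best3


# ---------------------------------------------------------------------------
# Barcoding gap
# ---------------------------------------------------------------------------

def test_gap_on_two_clean_species_at_10_percent(rng):
    """Two species of identical sequences, exactly 10% apart: max intra 0,
    min inter 10, suggested threshold 95."""
    base = _rand_seq(rng, 100)
    other = list(base)
    for p in range(5, 100, 10):  # 10 scattered substitutions
        other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
    refs = [
        sg.SequenceRecord("a1", base, species="SpA"),
        sg.SequenceRecord("a2", base, species="SpA"),
        sg.SequenceRecord("b1", "".join(other), species="SpB"),
        sg.SequenceRecord("b2", "".join(other), species="SpB"),
    ]
    gap = sg.barcoding_gap_analysis(refs)
    assert gap.max_intraspecific_distance == 0.0
    assert gap.min_interspecific_distance == pytest.approx(10.0)
    assert gap.gap_exists
    assert gap.suggested_identity_threshold == pytest.approx(95.0)


def test_overlapping_distributions_have_no_gap(rng):
    base = _rand_seq(rng, 100)
    def mutated(positions):
        out = list(base)
        for p in positions:
            out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
        return "".join(out)
    # interior substitutions only, so end-trimming cannot shift distances
    refs = [
        sg.SequenceRecord("a1", base, species="SpA"),
        sg.SequenceRecord("a2", mutated([11, 15, 19, 23, 27, 31]), species="SpA"),
        sg.SequenceRecord("b1", mutated([12, 16, 20, 24, 28]), species="SpB"),
        sg.SequenceRecord("b2", mutated([12, 16, 20, 24, 28]), species="SpB"),
    ]
    gap = sg.barcoding_gap_analysis(refs)
    assert not gap.gap_exists
    assert gap.suggested_identity_threshold is None


def test_gap_analysis_needs_intra_pairs(rng):
    refs = [
        sg.SequenceRecord("a1", _rand_seq(rng, 50), species="SpA"),
        sg.SequenceRecord("b1", _rand_seq(rng, 50), species="SpB"),
    ]
    with pytest.raises(ValidationError, match="undefined"):
        sg.barcoding_gap_analysis(refs)


def test_single_sequence_species_warned(rng):
    refs = [
        sg.SequenceRecord("a1", _rand_seq(rng, 50), species="SpA"),
        sg.SequenceRecord("a2", _rand_seq(rng, 50), species="SpA"),
        sg.SequenceRecord("b1", _rand_seq(rng, 50), species="SpB"),
    ]
    gap_or_err = None
    try:
        gap_or_err = sg.barcoding_gap_analysis(refs)
    except ValidationError:
        pytest.fail("a lone-sequence species must warn, not fail")
    assert any("SpB" in w for w in gap_or_err.warnings)


# ---------------------------------------------------------------------------
# assign_sequences
# ---------------------------------------------------------------------------

def _ref_with_identity(rng, identity: float, species: str, length=200):
    """Reference such that a fixed query aligns at exactly `identity`%."""
    ref = _rand_seq(rng, length)
    n_subs = round((100 - identity) / 100 * length)
    q = list(ref)
    step = length // (n_subs + 1)
    for k in range(n_subs):
        p = (k + 1) * step
        q[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[p]]
    return "".join(q), ref


@pytest.mark.parametrize(
    "identity, expected_status",
    [(96.5, ASSIGNED), (99.5, ASSIGNED), (94.0, UNASSIGNED)],
)
def test_assignment_identity_rule_is_strictly_above(rng, identity, expected_status):
    qseq, refseq = _ref_with_identity(rng, identity, "SpA")
    result, = sg.assign_sequences(
        [sg.SequenceRecord("q", qseq)],
        [sg.SequenceRecord("r", refseq, species="SpA")],
    )
    assert result.status == expected_status
    if expected_status == ASSIGNED:
        assert result.species == "SpA"
        assert result.best_identity == pytest.approx(identity, abs=0.05)


def test_tie_between_species_is_ambiguous(rng):
    q = _rand_seq(rng, 100)
    sub = list(q)
    sub[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[50]]
    refs = [
        sg.SequenceRecord("r1", "".join(sub), species="SpA"),
        sg.SequenceRecord("r2", "".join(sub), species="SpB"),
    ]
    result, = sg.assign_sequences([sg.SequenceRecord("q", q)], refs)
    assert result.status == AMBIGUOUS
    assert result.n_tied_species == 2
    assert result.species is None


def test_empty_reference_db_rejected():
    with pytest.raises(ValidationError, match="empty"):
        sg.assign_sequences([sg.SequenceRecord("q", "ACGT")], [])


def test_every_reference_assigns_to_its_own_species(study):
    """Self-consistency sweep: each database sequence, used as a query,
    assigns to its own species at 100% identity."""
    results = sg.assign_sequences(study.refdb, study.refdb)
    for rec, res in zip(study.refdb, results):
        assert res.status == ASSIGNED
        assert res.species == rec.species
        assert res.best_identity == pytest.approx(100.0)


def test_gap_calibrated_threshold_recovers_held_out_queries(study):
    gap = sg.barcoding_gap_analysis(study.refdb)
    queries = sample_within_species_queries(
        study.centroids, study.params, seed=99, n_per_species=2
    )
    results = sg.assign_sequences(
        [sg.SequenceRecord(q.id, q.sequence) for q in queries],
        study.refdb,
        identity_min=gap.suggested_identity_threshold,
    )
    for q, res in zip(queries, results):
        assert res.status == ASSIGNED
        assert res.species == q.species


# ---------------------------------------------------------------------------
# Placement rule
# ---------------------------------------------------------------------------

def test_placement_rule_argmax_then_strict_threshold():
    placements = [
        PlacementRecord("asv1", "Protozoa", 0.8),
        PlacementRecord("asv2", "Chromista", 0.5),  # exactly 0.5 -> unassigned
        PlacementRecord("asv3", "Protozoa", 0.4),
        PlacementRecord("asv3", "Metazoa", 0.6),
    ]
    out = sg.classify_placements(placements)
    assert out == {"asv1": "Protozoa", "asv2": "unassigned", "asv3": "Metazoa"}


def test_placement_lwr_out_of_bounds_rejected():
    with pytest.raises(ValidationError):
        PlacementRecord("asv1", "Protozoa", 1.2)
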