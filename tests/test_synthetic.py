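from __future__ import annotations

import numpy as np
import pytest

import stygodiv as sg
from stygodiv.io_formats import ValidationError
from stygodiv.synthetic import generate_reference_db, sample_within_species_queries


# ---------------------------------------------------------------------------
# Parameter validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        {"occupancy_prob": 1.5},
        {"jump_rate": 1.0},
        {"inter_divergence_min": 2.0, "intra_divergence_max": 3.0},
        {"duration_range": (0, 10)},
        {"capture_rate": -1.0},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValidationError):
        sg.SimulationParams(seed=0, **kwargs)


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

def test_reference_db_divergences_by_brute_force(default_params):
    """Every within-species pair stays inside the intra bound and every
    between-species pair beyond the inter bound, re-measured from scratch."""
    records, truth, centroids = generate_reference_db(default_params, seed=11)
    assert len(records) == 6 * default_params.seqs_per_species
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            dist = 100.0 - sg.align_identity(a, b).identity
            if a.species == b.species:
                assert dist <= default_params.intra_divergence_max + 1e-9
            else:
                assert dist >= default_params.inter_divergence_min - 1e-9


def test_reference_db_gap_contains_standard_threshold(default_params):
    records, _, _ = generate_reference_db(default_params, seed=11)
    gap = sg.barcoding_gap_analysis(records)
    assert gap.gap_exists
    assert (
        100.0 - gap.min_interspecific_distance
        < 94.0
        < 100.0 - gap.max_intraspecific_distance
    )


def test_reference_db_requires_two_species_and_two_seqs():
    params = sg.SimulationParams(seed=0, species_pool=("only one",))
    with pytest.raises(ValidationError):
        generate_reference_db(params)
    params = sg.SimulationParams(seed=0, seqs_per_species=1)
    with pytest.raises(ValidationError):
        generate_reference_db(params)


def test_reference_db_deterministic_fasta(tmp_path, default_params):
    for sub in ("a", "b"):
        records, _, _ = generate_reference_db(default_params, seed=3)
        sg.write_fasta(records, tmp_path / f"{sub}.fasta")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()


# ---------------------------------------------------------------------------
# Occupancy
# ---------------------------------------------------------------------------

def test_occupancy_boundaries():
    all_in = sg.generate_occupancy(sg.SimulationParams(seed=0, occupancy_prob=1.0))
    assert all_in.to_numpy().all()
    none_in = sg.generate_occupancy(sg.SimulationParams(seed=0, occupancy_prob=0.0))
    assert not none_in.to_numpy().any()


def test_occupancy_monte_carlo_mean():
    """Mean cell occupancy over many seeds within 3 binomial SE of the
    Bernoulli probability."""
    params = sg.SimulationParams(seed=0, occupancy_prob=0.3)
    n_seeds = 10_000
    cells = params.n_sites * len(params.species_pool)
    total = sum(
        sg.generate_occupancy(params, seed=s).to_numpy().sum()
        for s in range(n_seeds)
    )
    mean = total / (n_seeds * cells)
    se = np.sqrt(0.3 * 0.7 / (n_seeds * cells))
    assert abs(mean - 0.3) < 3 * se


# ---------------------------------------------------------------------------
# Citizen science
# ---------------------------------------------------------------------------

def test_zero_capture_rate_yields_no_specimens(default_params):
    occ = sg.generate_occupancy(default_params, seed=5)
    params = sg.SimulationParams(seed=0, capture_rate=0.0)
    specimens, _ = sg.simulate_citizen_science(occ, params, seed=5)
    assert specimens == []


def test_empty_occupancy_yields_no_specimens():
    params = sg.SimulationParams(seed=0, occupancy_prob=0.0, capture_rate=5.0)
    occ = sg.generate_occupancy(params, seed=5)
    specimens, _ = sg.simulate_citizen_science(occ, params, seed=5)
    assert specimens == []


def test_poisson_capture_mean_across_seeds():
    """With rate 1/day and a fixed 46-day window, the mean capture count per
    occupied pair converges on 46 within 3 Monte-Carlo SE."""
    params = sg.SimulationParams(
        seed=0,
        capture_rate=1.0,
        duration_range=(46, 46),
        occupancy_prob=1.0,
        n_sites=2,
        species_pool=("Sp A", "Sp B"),
    )
    occ = sg.generate_occupancy(params, seed=1)
    n_seeds = 1000
    counts = []
    for s in range(n_seeds):
        specimens, _ = sg.simulate_citizen_science(occ, params, seed=s)
        counts.append(len(specimens) / 4)  # 4 occupied pairs
    mean = np.mean(counts)
    se = np.sqrt(46 / (4 * n_seeds))
    assert abs(mean - 46) < 3 * se


def test_specimen_dates_are_weekly_check_dates(study):
    """Captures are batched to check dates: collection dates form a small set
    per site, all within the sampling window."""
    per_site: dict[str, set] = {}
    for rec in study.specimens:
        per_site.setdefault(rec.site_id, set()).add(rec.collection_date)
    for site, dates in per_site.items():
        assert len(dates) <= study.effort.durations[site] // 7 + 2


def test_edna_date_is_a_collection_week(study):
    for site, d in study.effort.edna_dates.items():
        assert d is not None


# ---------------------------------------------------------------------------
# eDNA counts
# ---------------------------------------------------------------------------

def _small_params(**kw) -> sg.SimulationParams:
    base = dict(
        seed=0,
        n_sites=4,
        species_pool=("Sp A", "Sp B", "Sp C"),
        occupancy_prob=0.5,
        n_background_asvs=10,
        reads_per_replicate_mean=500.0,
    )
    base.update(kw)
    return sg.SimulationParams(**base)


@pytest.fixture(scope="module")
def small_centroids():
    params = _small_params()
    _, _, centroids = generate_reference_db(params, seed=2)
    return centroids


def test_no_jumps_leaves_unused_and_controls_empty(small_centroids):
    params = _small_params(jump_rate=0.0)
    occ = sg.generate_occupancy(params, seed=3)
    table, truth = sg.simulate_edna_counts(occ, small_centroids, params, seed=3)
    assert table.counts[table.unused_columns].to_numpy().sum() == 0
    assert table.counts[table.control_columns].to_numpy().sum() == 0
    assert truth.jumped_reads.to_numpy().sum() == 0


def test_jump_step_conserves_reads(small_centroids):
    params0 = _small_params(jump_rate=0.0)
    params1 = _small_params(jump_rate=0.05)
    occ = sg.generate_occupancy(params0, seed=3)
    t0, _ = sg.simulate_edna_counts(occ, small_centroids, params0, seed=3)
    t1, _ = sg.simulate_edna_counts(occ, small_centroids, params1, seed=3)
    assert t0.total_reads == t1.total_reads


def test_jumped_read_count_matches_binomial_expectation(small_centroids):
    params = _small_params(jump_rate=0.002, reads_per_replicate_mean=5000.0)
    occ = sg.generate_occupancy(params, seed=3)
    table, truth = sg.simulate_edna_counts(occ, small_centroids, params, seed=3)
    total = table.total_reads
    jumped = truth.jumped_reads.to_numpy().sum()
    expected = total * 0.002
    assert abs(jumped - expected) < 3 * np.sqrt(expected)


def test_no_artifacts_when_rate_zero(small_centroids):
    params = _small_params(pcr_error_asv_rate=0.0)
    occ = sg.generate_occupancy(params, seed=3)
    _, truth = sg.simulate_edna_counts(occ, small_centroids, params, seed=3)
    assert truth.artifact_asvs == set()


def test_artifacts_are_singletons_before_contamination(small_centroids):
    params = _small_params(jump_rate=0.0, pcr_error_asv_rate=5.0)
    occ = sg.generate_occupancy(params, seed=3)
    table, truth = sg.simulate_edna_counts(occ, small_centroids, params, seed=3)
    for asv in truth.artifact_asvs:
        assert (table.counts.loc[asv] > 0).sum() == 1


def test_simulation_bit_identical_under_fixed_seed(small_centroids):
    params = _small_params(jump_rate=0.01)
    occ = sg.generate_occupancy(params, seed=3)
    t1, tr1 = sg.simulate_edna_counts(occ, small_centroids, params, seed=9)
    t2, tr2 = sg.simulate_edna_counts(occ, small_centroids, params, seed=9)
    assert (t1.counts.to_numpy() == t2.counts.to_numpy()).all()
    assert tr1.true_asv_species == tr2.true_asv_species
    assert (tr1.jumped_reads.to_numpy() == tr2.jumped_reads.to_numpy()).all()


def test_generated_table_passes_validation_roundtrip(study, tmp_path):
    sg.write_count_table(study.table, tmp_path / "c.tsv", tmp_path / "m.tsv")
    back = sg.read_count_table(tmp_path / "c.tsv", tmp_path / "m.tsv")
    assert (back.counts.to_numpy() == study.table.counts.to_numpy()).all()


def test_study_structure_matches_design(study):
    p = study.params
    assert len(study.table.used_columns) == p.n_sites * p.replicates_per_site
    assert len(study.table.unused_columns) == p.n_unused_combos
    assert len(study.table.control_columns) == p.n_controls
    assert set(study.truth.true_asv_species.values()) <= (
        set(p.species_pool) | {"background", "artifact"}
    )
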