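"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates a groundwater biodiversity study design: 20 spring
catchment boxes each sampled by citizen scientists (weekly net checks over
7-71 days, specimens barcoded) and by a single eDNA sampling event sequenced
in 4 filters x 5 tagged PCR groups = 20 replicates per site, with 8 unused
index combinations and 8 negative controls on the sequencing run.

Planted ground truth:

* a reference barcode database with a controlled barcoding gap (within-species
  divergence bounded above, between-species divergence bounded below, verified
  post hoc on the generated sequences);
* true site x species occupancy, per-day Poisson specimen captures batched to
  weekly check dates, and an eDNA read table in which every read can be traced:
  species ASVs at occupied sites, a background community of non-target ASVs
  (the bulk of the library, as in real runs), singleton-replicate PCR-error
  ASVs derived from a locally present parent sequence, and index-jumped reads
  reassigned to uniformly random other columns;
* all of it bit-reproducible under a fixed seed.

What this does **not** emulate: sequence-level read errors and chimeras, eDNA
transport between sites, taxonomic mixtures per ASV, or seasonal dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io_formats import (
    EffortTable,
    ReadCountTable,
    ReplicateMeta,
    SequenceRecord,
    SpecimenRecord,
    ValidationError,
)
from . import taxassign

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "StudyData",
    "generate_reference_db",
    "sample_within_species_queries",
    "generate_occupancy",
    "simulate_citizen_science",
    "simulate_edna_counts",
    "simulate_study",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_SPECIES_POOL = (
    "Niphargus sim. A",
    "Niphargus sim. B",
    "Niphargus sim. C",
    "Niphargus sim. D",
    "Niphargus sim. E",
    "Crangonyx sim. F",
)


@dataclass(frozen=True)
class SimulationParams:
    """Study-design knobs of the generator; defaults encode the emulated study.

    Units: ``capture_rate`` is expected captures per occupied site-species per
    day; ``duration_range`` is inclusive day bounds; divergences are percent
    distances; ``jump_rate`` is the per-read probability of reassignment to a
    uniformly random other column; ``pcr_error_asv_rate`` is the expected
    number of artifact ASVs per site.
    """

    n_sites: int = 20
    n_filters: int = 4
    n_pcr_tags: int = 5
    n_unused_combos: int = 8
    n_controls: int = 8
    species_pool: tuple[str, ...] = DEFAULT_SPECIES_POOL
    occupancy_prob: float = 0.25
    capture_rate: float = 0.35
    duration_range: tuple[int, int] = (7, 71)
    reads_per_replicate_mean: float = 5000.0
    reads_per_replicate_dispersion: float = 1.8
    jump_rate: float = 0.002
    pcr_error_asv_rate: float = 3.0
    artifact_reads_mean: float = 25.0
    dropout: float = 0.3
    edna_site_detection: float = 0.35
    n_background_asvs: int = 80
    background_site_prob: float = 0.35
    background_depth_median: float = 600.0
    background_depth_sigma: float = 0.8
    background_depth_min: float = 150.0
    background_depth_max: float = 8000.0
    intra_divergence_max: float = 2.0
    inter_divergence_min: float = 8.0
    ref_seq_length: int = 658
    asv_length: int = 205
    seqs_per_species: int = 3
    start_date: date = date(2021, 3, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "occupancy_prob": self.occupancy_prob,
            "dropout": self.dropout,
            "edna_site_detection": self.edna_site_detection,
            "background_site_prob": self.background_site_prob,
        }
        for name, p in probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} {p} outside [0, 1]")
        if not (0.0 <= self.jump_rate < 1.0):
            raise ValidationError(f"jump_rate {self.jump_rate} outside [0, 1)")
        if self.inter_divergence_min <= self.intra_divergence_max:
            raise ValidationError(
                "inter_divergence_min must exceed intra_divergence_max "
                "(the barcoding gap exists by construction)"
            )
        lo, hi = self.duration_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"bad duration_range {self.duration_range}")
        for name in (
            "n_sites", "n_filters", "n_pcr_tags", "n_unused_combos",
            "n_controls", "n_background_asvs", "seqs_per_species",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.capture_rate < 0 or self.pcr_error_asv_rate < 0:
            raise ValidationError("rates must be >= 0")

    @property
    def sites(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]

    @property
    def replicates_per_site(self) -> int:
        return self.n_filters * self.n_pcr_tags


@dataclass
class SimulationTruth:
    """Everything the generator planted, for recovery checks."""

    occupancy: pd.DataFrame  # site x species booleans
    edna_site_presence: pd.DataFrame  # site x species booleans (planted reads)
    true_asv_species: dict[str, str]  # ASV -> species | "background" | "artifact"
    asv_sequences: dict[str, str]
    jumped_reads: pd.DataFrame  # reassigned-in reads per (ASV, replicate)
    artifact_asvs: set[str]
    artifact_sites: dict[str, str]  # artifact ASV -> site of origin


@dataclass
class StudyData:
    """One complete simulated study (all pipeline inputs plus the truth)."""

    params: SimulationParams
    refdb: list[SequenceRecord]
    refdb_truth: pd.DataFrame
    centroids: dict[str, str]
    occupancy: pd.DataFrame
    specimens: list[SpecimenRecord]
    effort: EffortTable
    table: ReadCountTable
    truth: SimulationTruth


# ---------------------------------------------------------------------------
# Reference database with a controlled barcoding gap
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _NT[rng.integers(0, 4, size=length)]

def _mutate(rng: np.random.Generator, seq: np.ndarray, n_subs: int) -> np.ndarray:
    out = seq.copy()
    if n_subs == 0:
        return out
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = _NT[_NT != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out

def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def generate_reference_db(
    params: SimulationParams, seed: int | None = None, max_retries: int = 20
) -> tuple[list[SequenceRecord], pd.DataFrame, dict[str, str]]:
    """Species-labelled barcode database with a barcoding gap by construction.

    Each species descends from a centroid obtained by mutating a shared root;
    sequences within a species carry at most ``intra_divergence_max / 2``
    percent substitutions from the centroid, so intraspecific distances stay
    below ``intra_divergence_max``. Between-species divergence is verified
    post hoc with the same aligner the gap analysis uses and the whole set is
    redrawn (bounded retries) if any pair comes out too similar.

    Returns ``(records, truth_table, centroids)``.
    """
    if len(params.species_pool) < 2:
        raise ValidationError("need at least two species in the pool")
    if params.seqs_per_species < 2:
        raise ValidationError("need at least two sequences per species")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    L = params.ref_seq_length
    # aim pairwise inter-centroid divergence at ~1.4x the floor
    m = max(1, round(0.7 * params.inter_divergence_min / 100.0 * L))
    intra_subs_max = max(1, math.floor(params.intra_divergence_max / 100.0 * L / 2))
    for _ in range(max_retries):
        root = _random_seq(rng, L)
        centroids = {sp: _mutate(rng, root, m) for sp in params.species_pool}
        records: list[SequenceRecord] = []
        rows = []
        for sp_idx, sp in enumerate(params.species_pool):
            for k in range(params.seqs_per_species):
                n_subs = int(rng.integers(0, intra_subs_max + 1))
                seq = _mutate(rng, centroids[sp], n_subs)
                rec = SequenceRecord(
                    id=f"REF{sp_idx + 1:02d}_{k + 1}",
                    sequence=_to_str(seq),
                    species=sp,
                )
                records.append(rec)
                rows.append(
                    {"sequence_id": rec.id, "species": sp, "subs_from_centroid": n_subs}
                )
        ok = True
        species_list = list(params.species_pool)
        for i in range(len(species_list)):
            for j in range(i + 1, len(species_list)):
                a = SequenceRecord("a", _to_str(centroids[species_list[i]]))
                b = SequenceRecord("b", _to_str(centroids[species_list[j]]))
                identity = taxassign.align_identity(a, b).identity
                if 100.0 - identity < params.inter_divergence_min + 2 * (
                    100.0 * intra_subs_max / L
                ):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            truth = pd.DataFrame(rows)
            return records, truth, {sp: _to_str(c) for sp, c in centroids.items()}
    raise ValidationError(
        "could not satisfy the divergence constraints after "
        f"{max_retries} retries; loosen intra/inter bounds"
    )


def sample_within_species_queries(
    centroids: dict[str, str],
    params: SimulationParams,
    seed: int,
    n_per_species: int = 1,
) -> list[SequenceRecord]:
    """Held-out queries drawn from each species' centroid, within the
    intraspecific divergence budget (for threshold-recovery checks)."""
    rng = np.random.default_rng(seed)
    L = params.ref_seq_length
    intra_subs_max = max(1, math.floor(params.intra_divergence_max / 100.0 * L / 2))
    out = []
    for sp_idx, (sp, cent) in enumerate(centroids.items()):
        arr = np.frombuffer(cent.encode("ascii"), dtype=np.uint8)
        for k in range(n_per_species):
            n_subs = int(rng.integers(0, intra_subs_max + 1))
            out.append(
                SequenceRecord(
                    id=f"QUERY{sp_idx + 1:02d}_{k + 1}",
                    sequence=_to_str(_mutate(rng, arr, n_subs)),
                    species=sp,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Occupancy and citizen science
# ---------------------------------------------------------------------------

def generate_occupancy(params: SimulationParams, seed: int | None = None) -> pd.DataFrame:
    """Independent Bernoulli(occupancy_prob) per (site, species) cell."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    draws = rng.random((params.n_sites, len(params.species_pool)))
    return pd.DataFrame(
        draws < params.occupancy_prob,
        index=params.sites,
        columns=list(params.species_pool),
    )


def simulate_citizen_science(
    occupancy: pd.DataFrame,
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[list[SpecimenRecord], EffortTable]:
    """Weekly net checks: per occupied (site, species), captures are Poisson
    with mean ``capture_rate x duration``, dated uniformly in the window and
    batched to the next weekly check date. The eDNA sampling date is one of
    the site's check dates, drawn at random.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    lo, hi = params.duration_range
    durations: dict[str, int] = {}
    edna_dates: dict[str, date] = {}
    check_dates: dict[str, list[date]] = {}
    for site in occupancy.index:
        duration = int(rng.integers(lo, hi + 1))
        durations[site] = duration
        start = params.start_date + timedelta(days=int(rng.integers(0, 60)))
        checks = [
            start + timedelta(days=d)
            for d in range(7, duration + 7, 7)
        ]
        # the final check closes the window even if the duration is not a
        # multiple of seven days
        if checks[-1] < start + timedelta(days=duration):
            checks.append(start + timedelta(days=duration))
        check_dates[site] = checks
        edna_dates[site] = checks[int(rng.integers(0, len(checks)))]
    specimens: list[SpecimenRecord] = []
    counter = 0
    for site in occupancy.index:
        start = check_dates[site][0] - timedelta(days=7)
        duration = durations[site]
        for species in occupancy.columns:
            if not occupancy.at[site, species]:
                continue
            n = int(rng.poisson(params.capture_rate * duration))
            if n == 0:
                continue
            offsets = np.sort(rng.integers(0, duration, size=n))
            for off in offsets:
                caught = check_dates[site][0] - timedelta(days=7) + timedelta(
                    days=int(off)
                )
                batched = next(
                    (c for c in check_dates[site] if c >= caught),
                    check_dates[site][-1],
                )
                counter += 1
                specimens.append(
                    SpecimenRecord(
                        specimen_id=f"IND{counter:04d}",
                        site_id=site,
                        collection_date=batched,
                        species=species,
                    )
                )
    effort = EffortTable(durations, dict(edna_dates))
    return specimens, effort


# ---------------------------------------------------------------------------
# eDNA read table
# ---------------------------------------------------------------------------

def _nb_draws(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    """Negative binomial with mean ``mean`` and shape ``dispersion`` (k)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _replicate_frame(params: SimulationParams) -> list[ReplicateMeta]:
    replicates = [
        ReplicateMeta(
            replicate_id=f"{site}-F{f + 1}-P{p + 1}",
            status="used",
            site_id=site,
            filter_id=f"{site}-F{f + 1}",
            pcr_tag=f"P{p + 1}",
        )
        for site in [f"S{i + 1:02d}" for i in range(params.n_sites)]
        for f in range(params.n_filters)
        for p in range(params.n_pcr_tags)
    ]
    replicates += [
        ReplicateMeta(replicate_id=f"UNUSED-{u + 1}", status="unused")
        for u in range(params.n_unused_combos)
    ]
    replicates += [
        ReplicateMeta(replicate_id=f"CTRL-{c + 1}", status="control")
        for c in range(params.n_controls)
    ]
    return replicates


def simulate_edna_counts(
    occupancy: pd.DataFrame,
    refdb_centroids: dict[str, str],
    params: SimulationParams,
    seed: int | None = None,
) -> tuple[ReadCountTable, SimulationTruth]:
    """Simulate the replicated read table with planted contamination.

    Steps: (1) species ASVs receive negative-binomial reads in each used
    replicate of occupied sites where the sampling captured the species' DNA
    (site-level ``edna_site_detection``, then per-replicate ``dropout``);
    a background community of non-target ASVs is laid down the same way with
    heterogeneous per-ASV depths; (2) PCR-error artifact ASVs (sequence =
    a locally present parent ASV with one or two substitutions) are injected
    into exactly one replicate each at low depth; (3) every read is
    independently reassigned with probability ``jump_rate`` to a uniformly
    random other column, unused and control columns included. Reads are
    conserved by the jump step.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    replicates = _replicate_frame(params)
    if not any(r.status == "used" for r in replicates):
        raise ValidationError("zero used replicates")
    columns = [r.replicate_id for r in replicates]
    col_idx = {c: i for i, c in enumerate(columns)}
    site_cols = {
        site: [r.replicate_id for r in replicates if r.site_id == site]
        for site in occupancy.index
    }
    species_list = list(occupancy.columns)
    asv_ids: list[str] = []
    asv_seq: dict[str, str] = {}
    asv_species: dict[str, str] = {}
    rows: list[np.ndarray] = []
    n_cols = len(columns)

    edna_present = pd.DataFrame(
        False, index=occupancy.index, columns=species_list
    )
    # --- species ASVs ----------------------------------------------------
    for sp_idx, species in enumerate(species_list):
        cent = np.frombuffer(refdb_centroids[species].encode("ascii"), dtype=np.uint8)
        start = (len(cent) - params.asv_length) // 2
        window = cent[start : start + params.asv_length]
        n_subs = int(rng.integers(0, 2))
        seq = _to_str(_mutate(rng, window, n_subs))
        asv_id = f"ASV{len(asv_ids) + 1:04d}"
        row = np.zeros(n_cols, dtype=np.int64)
        for site in occupancy.index:
            if not occupancy.at[site, species]:
                continue
            if rng.random() >= params.edna_site_detection:
                continue
            cols = [col_idx[c] for c in site_cols[site]]
            detected = rng.random(len(cols)) >= params.dropout
            counts = _nb_draws(
                rng,
                params.reads_per_replicate_mean,
                params.reads_per_replicate_dispersion,
                len(cols),
            )
            counts = np.where(detected, counts, 0)
            if counts.sum() > 0:
                edna_present.at[site, species] = True
            row[cols] += counts
        asv_ids.append(asv_id)
        asv_seq[asv_id] = seq
        asv_species[asv_id] = species
        rows.append(row)

    # --- background community -------------------------------------------
    for b in range(params.n_background_asvs):
        asv_id = f"ASV{len(asv_ids) + 1:04d}"
        seq = _to_str(_random_seq(rng, params.asv_length))
        depth = float(
            np.clip(
                params.background_depth_median
                * math.exp(rng.normal(0.0, params.background_depth_sigma)),
                params.background_depth_min,
                params.background_depth_max,
            )
        )
        row = np.zeros(n_cols, dtype=np.int64)
        present_sites = [
            site
            for site in occupancy.index
            if rng.random() < params.background_site_prob
        ]
        for site in present_sites:
            cols = [col_idx[c] for c in site_cols[site]]
            detected = rng.random(len(cols)) >= params.dropout
            counts = _nb_draws(
                rng, depth, params.reads_per_replicate_dispersion, len(cols)
            )
            row[cols] += np.where(detected, counts, 0)
        asv_ids.append(asv_id)
        asv_seq[asv_id] = seq
        asv_species[asv_id] = "background"
        rows.append(row)

    matrix = np.vstack(rows) if rows else np.zeros((0, n_cols), dtype=np.int64)

    # --- PCR-error artifacts (exactly one replicate each, pre-jump) ------
    artifact_asvs: set[str] = set()
    artifact_sites: dict[str, str] = {}
    artifact_rows: list[np.ndarray] = []
    for site in occupancy.index:
        n_art = int(rng.poisson(params.pcr_error_asv_rate))
        cols = [col_idx[c] for c in site_cols[site]]
        for _ in range(n_art):
            site_totals = matrix[:, cols].sum(axis=1)
            parents = np.flatnonzero(site_totals > 0)
            if len(parents) == 0:
                continue
            parent = asv_ids[int(rng.choice(parents))]
            parr = np.frombuffer(asv_seq[parent].encode("ascii"), dtype=np.uint8)
            seq = _to_str(_mutate(rng, parr, int(rng.integers(1, 3))))
            asv_id = f"ASV{len(asv_ids) + len(artifact_rows) + 1:04d}"
            row = np.zeros(n_cols, dtype=np.int64)
            target = cols[int(rng.integers(0, len(cols)))]
            row[target] = 1 + rng.poisson(max(params.artifact_reads_mean - 1, 0))
            artifact_rows.append(row)
            asv_seq[asv_id] = seq
            asv_species[asv_id] = "artifact"
            artifact_asvs.add(asv_id)
            artifact_sites[asv_id] = site
    if artifact_rows:
        asv_ids += [a for a in asv_seq if a not in asv_ids]
        matrix = np.vstack([matrix, np.vstack(artifact_rows)])

    # --- index jumps: conserve reads, reassign uniformly ------------------
    jumped = np.zeros_like(matrix)
    if params.jump_rate > 0 and matrix.sum() > 0:
        leaving = rng.binomial(matrix, params.jump_rate)
        matrix = matrix - leaving
        for a, c in zip(*np.nonzero(leaving)):
            n_jump = int(leaving[a, c])
            pvals = np.full(n_cols, 1.0 / (n_cols - 1))
            pvals[c] = 0.0
            dest = rng.multinomial(n_jump, pvals)
            matrix[a] += dest
            jumped[a] += dest

    counts = pd.DataFrame(matrix, index=asv_ids, columns=columns)
    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    table = ReadCountTable(counts, replicates)
    truth = SimulationTruth(
        occupancy=occupancy.copy(),
        edna_site_presence=edna_present,
        true_asv_species={a: asv_species[a] for a in counts.index},
        asv_sequences={a: asv_seq[a] for a in counts.index},
        jumped_reads=pd.DataFrame(jumped, index=asv_ids, columns=columns).loc[keep],
        artifact_asvs={a for a in artifact_asvs if a in set(counts.index)},
        artifact_sites={
            a: s for a, s in artifact_sites.items() if a in set(counts.index)
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# Whole-study convenience wrapper
# ---------------------------------------------------------------------------

def simulate_study(params: SimulationParams) -> StudyData:
    """Generate one complete study from ``params.seed``: reference database,
    occupancy, citizen-science specimens with effort, and the eDNA read table
    with its planted truth. Sub-stage seeds are derived deterministically.
    """
    ss = np.random.SeedSequence(params.seed)
    s_ref, s_occ, s_cs, s_edna = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)
    ]
    refdb, refdb_truth, centroids = generate_reference_db(params, seed=s_ref)
    occupancy = generate_occupancy(params, seed=s_occ)
    specimens, effort = simulate_citizen_science(occupancy, params, seed=s_cs)
    table, truth = simulate_edna_counts(occupancy, centroids, params, seed=s_edna)
    return StudyData(
        params=params,
        refdb=refdb,
        refdb_truth=refdb_truth,
        centroids=centroids,
        occupancy=occupancy,
        specimens=specimens,
        effort=effort,
        table=table,
        truth=truth,
    )
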