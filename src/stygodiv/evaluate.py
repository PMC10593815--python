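"""Recovery and calibration measurements on simulated studies.

These functions quantify, against the generator's planted ground truth, how
well the correction pipeline and the statistics behave under the emulated
study design: how many planted PCR-error occurrences the filters remove, how
often negative controls end read-free, how much true signal survives, whether
eDNA detections stay nested within the citizen-science ones, and whether the
tests hold their nominal type-I error under independent nulls.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .cooccur import cooccur_exact_test, pearson_log_correlation
from .decontam import decontaminate
from .detection import build_detection_matrix, compare_detections
from .io_formats import SequenceRecord, ValidationError
from .synthetic import SimulationParams, simulate_study
from .taxassign import assign_sequences

__all__ = [
    "decontamination_recovery",
    "detection_congruence_rates",
    "pearson_type_i_rate",
    "cooccurrence_type_i_rate",
]


def decontamination_recovery(
    params: SimulationParams, seeds: Sequence[int]
) -> dict[str, float]:
    """Run the full correction on one simulated study per seed and score it
    against the planted truth.

    Returns aggregate fractions: ``artifact_removed`` (planted artifact
    site-occurrences with zero reads left at their site), ``controls_clean``
    (seeds whose negative controls are all read-free), and ``retention``
    (occupied site-species pairs with planted eDNA reads that keep at least
    one ASV of their species after correction).
    """
    art_removed = art_total = 0
    clean_seeds = 0
    retained = present_total = 0
    for seed in seeds:
        study = simulate_study(replace(params, seed=seed))
        corrected, _, _, controls = decontaminate(study.table)
        clean_seeds += controls.all_clean
        site_groups = study.table.site_groups
        idx = set(corrected.counts.index)
        for asv, site in study.truth.artifact_sites.items():
            art_total += 1
            if asv not in idx:
                art_removed += 1
            elif corrected.counts.loc[asv, site_groups[site]].sum() == 0:
                art_removed += 1
        species_asvs: dict[str, list[str]] = {}
        for asv, sp in study.truth.true_asv_species.items():
            if sp in study.params.species_pool:
                species_asvs.setdefault(sp, []).append(asv)
        planted = study.truth.occupancy & study.truth.edna_site_presence
        for species in planted.columns:
            asvs = [a for a in species_asvs.get(species, []) if a in idx]
            for site in planted.index:
                if not planted.at[site, species]:
                    continue
                present_total += 1
                if asvs and corrected.counts.loc[asvs, site_groups[site]].sum().sum() > 0:
                    retained += 1
    return {
        "artifact_removed": art_removed / art_total if art_total else 1.0,
        "controls_clean": clean_seeds / len(seeds),
        "retention": retained / present_total if present_total else 1.0,
        "n_artifact_occurrences": art_total,
        "n_planted_pairs": present_total,
    }


def detection_congruence_rates(
    params: SimulationParams, seeds: Sequence[int]
) -> dict[str, float]:
    """Per-seed detection comparison of the two methods on corrected data.

    ``edna_nested`` is the fraction of seeds in which every eDNA detection is
    also an all-dates citizen-science detection; ``cs_dominates`` the fraction
    in which citizen-science-only detections outnumber eDNA-only ones in the
    same-date comparison. Mean union proportions are returned alongside.
    """
    nested = dominates = 0
    props = np.zeros(3)
    for seed in seeds:
        study = simulate_study(replace(params, seed=seed))
        corrected, _, _, _ = decontaminate(study.table)
        queries = [
            SequenceRecord(a, study.truth.asv_sequences[a])
            for a in corrected.counts.index
        ]
        assignments = assign_sequences(queries, study.refdb)
        sites = list(study.occupancy.index)
        species = list(study.occupancy.columns)
        edna = build_detection_matrix(
            "edna", "corrected", sites, species,
            table=corrected, assignments=assignments,
        )
        cs_all = build_detection_matrix(
            "citizen_science", "all_dates", sites, species,
            specimens=study.specimens, effort=study.effort,
        )
        cs_same = build_detection_matrix(
            "citizen_science", "same_date", sites, species,
            specimens=study.specimens, effort=study.effort,
        )
        rep_all = compare_detections(cs_all, edna)
        nested += rep_all.n_b_only == 0
        rep_same = compare_detections(cs_same, edna)
        dominates += rep_same.n_a_only > rep_same.n_b_only
        if rep_all.n_union:
            props += np.array(rep_all.proportions)
    n = len(seeds)
    return {
        "edna_nested": nested / n,
        "cs_dominates": dominates / n,
        "mean_prop_both": props[0] / n,
        "mean_prop_cs_only": props[1] / n,
        "mean_prop_edna_only": props[2] / n,
    }


def pearson_type_i_rate(
    n_reps: int = 10_000, n: int = 20, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of independent-null replicates with p < alpha."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        hits += pearson_log_correlation(x, y).p_value < alpha
    return hits / n_reps


def cooccurrence_type_i_rate(
    n_reps: int = 1_000,
    n_sites: int = 20,
    p1: float = 0.35,
    p2: float = 0.35,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of independent Bernoulli occupancy pairs classified positive
    or negative (the exact test is conservative on discrete support, so this
    sits at or below alpha)."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        a = rng.random(n_sites) < p1
        b = rng.random(n_sites) < p2
        t = cooccur_exact_test(a, b, alpha=alpha)
        hits += t.classification != "none"
    return hits / n_reps
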