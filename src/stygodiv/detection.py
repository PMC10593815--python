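"""Site x species detection matrices and congruence between survey methods.

A detection matrix records, for one method and one mode, whether each species
was detected at each site. Citizen-science detections come from assigned
specimens (either only those collected at the site's eDNA sampling date, or
from the whole sampling window); eDNA detections come from ASVs assigned to a
species, using either the corrected or the raw read table. Congruence between
two matrices partitions the union of detections into both / first-only /
second-only, with proportions over the union (Venn semantics).

Citizen-science abundance is normalised by effort: individuals per day,
because sampling windows differ by an order of magnitude between sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    EffortTable,
    ReadCountTable,
    SpecimenRecord,
    ValidationError,
)
from .taxassign import ASSIGNED, Assignment

__all__ = [
    "DetectionMatrix",
    "CongruenceReport",
    "build_detection_matrix",
    "compare_detections",
    "effort_normalized_abundance",
]

CS_MODES = ("same_date", "all_dates")
EDNA_MODES = ("corrected", "raw")


@dataclass
class DetectionMatrix:
    """Boolean site x species presence for one method and mode."""

    present: pd.DataFrame  # sites x species, bool
    method: str  # citizen_science | edna
    mode: str

    def __post_init__(self) -> None:
        legal = {"citizen_science": CS_MODES, "edna": EDNA_MODES}
        if self.method not in legal:
            raise ValidationError(f"unknown method {self.method!r}")
        if self.mode not in legal[self.method]:
            raise ValidationError(
                f"mode {self.mode!r} is not legal for method {self.method!r}"
            )
        self.present = self.present.astype(bool)

    @property
    def sites(self) -> list[str]:
        return list(self.present.index)

    @property
    def species(self) -> list[str]:
        return list(self.present.columns)

    @property
    def detections(self) -> set[tuple[str, str]]:
        rows, cols = np.nonzero(self.present.to_numpy())
        return {
            (self.present.index[r], self.present.columns[c])
            for r, c in zip(rows, cols)
        }


@dataclass
class CongruenceReport:
    n_both: int
    n_a_only: int
    n_b_only: int
    a_method: str
    b_method: str
    cells: pd.DataFrame  # site, species, category

    @property
    def n_union(self) -> int:
        return self.n_both + self.n_a_only + self.n_b_only

    @property
    def proportions(self) -> tuple[float, float, float]:
        """(both, a_only, b_only) over the union; all zero when empty."""
        u = self.n_union
        if u == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_both / u, self.n_a_only / u, self.n_b_only / u)


def build_detection_matrix(
    method: str,
    mode: str,
    sites: Sequence[str],
    species: Sequence[str],
    specimens: Sequence[SpecimenRecord] | None = None,
    effort: EffortTable | None = None,
    table: ReadCountTable | None = None,
    assignments: Sequence[Assignment] | Mapping[str, str] | None = None,
) -> DetectionMatrix:
    """Build the detection matrix for one method.

    citizen_science: a species is detected at a site iff at least one assigned
    specimen was collected there (``same_date``: only specimens whose weekly
    collection date equals the site's eDNA sampling date; ``all_dates``: any).
    Specimens that could not be assigned to a species are excluded.

    edna: a species is detected at a site iff at least one read of an ASV
    assigned to it occurs in a used replicate of that site in the supplied
    (corrected or raw) table. ``assignments`` is either the output of
    ``assign_sequences`` or a plain ``{asv_id: species}`` mapping.
    """
    present = pd.DataFrame(False, index=list(sites), columns=list(species))
    if method == "citizen_science":
        if specimens is None:
            raise ValidationError("citizen_science mode needs specimens")
        if mode == "same_date":
            if effort is None:
                raise ValidationError("same_date mode needs the effort table")
            missing = [
                s for s in sites if effort.edna_dates.get(s) is None
            ]
            if missing:
                raise ValidationError(
                    f"same_date requested but sites lack an eDNA date: {missing}"
                )
        for rec in specimens:
            if rec.species is None or rec.species not in present.columns:
                continue
            if rec.site_id not in present.index:
                continue
            if mode == "same_date" and rec.collection_date != effort.edna_dates.get(
                rec.site_id
            ):
                continue
            present.at[rec.site_id, rec.species] = True
        return DetectionMatrix(present, "citizen_science", mode)

    if method == "edna":
        if table is None or assignments is None:
            raise ValidationError("edna mode needs a read table and assignments")
        if isinstance(assignments, Mapping):
            asv_to_species = dict(assignments)
        else:
            asv_to_species = {
                a.query_id: a.species for a in assignments if a.status == ASSIGNED
            }
        site_groups = table.site_groups
        for asv, sp in asv_to_species.items():
            if sp not in present.columns or asv not in table.counts.index:
                continue
            row = table.counts.loc[asv]
            for site in present.index:
                cols = site_groups.get(site, [])
                if cols and row[cols].sum() > 0:
                    present.at[site, sp] = True
        return DetectionMatrix(present, "edna", mode)

    raise ValidationError(f"unknown method {method!r}")


def compare_detections(a: DetectionMatrix, b: DetectionMatrix) -> CongruenceReport:
    """Classify every (site, species) cell in the union of detections as
    both / a-only / b-only."""
    if a.sites != b.sites or a.species != b.species:
        raise ValidationError(
            "detection matrices must share the same site and species universes"
        )
    av = a.present.to_numpy()
    bv = b.present.to_numpy()
    both = av & bv
    a_only = av & ~bv
    b_only = bv & ~av
    records = []
    for mask, label in ((both, "both"), (a_only, "a_only"), (b_only, "b_only")):
        for r, c in zip(*np.nonzero(mask)):
            records.append(
                {
                    "site_id": a.present.index[r],
                    "species": a.present.columns[c],
                    "category": label,
                }
            )
    cells = pd.DataFrame(records, columns=["site_id", "species", "category"])
    return CongruenceReport(
        n_both=int(both.sum()),
        n_a_only=int(a_only.sum()),
        n_b_only=int(b_only.sum()),
        a_method=f"{a.method}:{a.mode}",
        b_method=f"{b.method}:{b.mode}",
        cells=cells,
    )


def effort_normalized_abundance(
    specimens: Sequence[SpecimenRecord],
    effort: EffortTable,
    include_unassigned: bool = False,
) -> pd.DataFrame:
    """Per-site individuals, sampling duration, individuals per day, and
    species richness.

    Unassignable specimens (no species label) are excluded from richness and,
    by default, from the totals as well; set ``include_unassigned`` to count
    them in the totals.
    """
    totals: dict[str, int] = {site: 0 for site in effort.durations}
    richness_sets: dict[str, set[str]] = {site: set() for site in effort.durations}
    for rec in specimens:
        if rec.site_id not in effort.durations:
            raise ValidationError(
                f"specimen {rec.specimen_id!r}: site {rec.site_id!r} has no "
                f"sampling duration"
            )
        if rec.species is not None:
            totals[rec.site_id] += 1
            richness_sets[rec.site_id].add(rec.species)
        elif include_unassigned:
            totals[rec.site_id] += 1
    rows = []
    for site, days in effort.durations.items():
        rows.append(
            {
                "site_id": site,
                "individuals_total": totals[site],
                "duration_days": days,
                "per_day": totals[site] / days,
                "species_richness": len(richness_sets[site]),
            }
        )
    return pd.DataFrame(rows).set_index("site_id")
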