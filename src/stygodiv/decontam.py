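"""Decontamination of a replicated metabarcoding ASV table.

Two correction steps, applied in a fixed order:

1. **Index-jump filter.** During demultiplexing a small fraction of reads is
   attributed to the wrong index combination ("index-jump" or "tag-jump").
   Deliberately unused index combinations in the demultiplexing sheet receive
   only such misassigned reads, so they gauge the severity of the process: for
   every ASV *a* and unused combination *u*, the proportion
   ``p(a, u) = counts(a, u) / R(a)`` (with ``R(a)`` the whole-dataset total of
   the ASV, unused and control columns included) is an observed jump
   proportion, and the maximum over all such cells is the threshold. Any cell
   of the table whose proportion does not exceed the threshold is then zeroed
   -- those reads are indistinguishable from jumps.

2. **Replicate-consistency filter.** Each site is sequenced in many replicates
   (by default 4 filters x 5 tagged PCR groups = 20). A PCR error arises in
   one reaction, so an ASV observed in fewer than ``min_replicates`` of a
   site's replicates (an absolute count, robust to sites with fewer
   replicates) is removed from that site. Negative controls are pooled into
   one replicate group of their own and cleaned by the same rule, mirroring a
   protocol in which controls are processed exactly like samples; a genuine
   contaminant would recur across controls, while an isolated single-column
   control read is demultiplexing noise.

``check_negative_controls`` verifies the end state: a successful correction
leaves every negative control read-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ReadCountTable, ValidationError

__all__ = [
    "JumpThreshold",
    "FilterReport",
    "ControlReport",
    "estimate_index_jump_threshold",
    "estimate_per_asv_thresholds",
    "apply_index_jump_filter",
    "apply_replicate_filter",
    "check_negative_controls",
    "decontaminate",
]


@dataclass(frozen=True)
class JumpThreshold:
    """The maximum observed jump proportion, with its provenance."""

    value: float
    source_asv: str | None = None
    source_replicate: str | None = None
    capped_warning: bool = False
    sanity_cap: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"jump threshold {self.value} outside [0, 1]")


@dataclass
class FilterReport:
    """Accounting of one correction step: exact read and ASV bookkeeping."""

    step: str
    asvs_in: int
    asvs_out: int
    reads_in: int
    reads_out: int
    removed_cells: list[tuple[str, str, int]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.asvs_out > self.asvs_in or self.reads_out > self.reads_in:
            raise ValidationError("filter cannot create ASVs or reads")

    @property
    def reads_removed(self) -> int:
        return self.reads_in - self.reads_out


@dataclass(frozen=True)
class ControlReport:
    per_control: dict[str, int]
    all_clean: bool
    dirty_controls: tuple[str, ...]


# ---------------------------------------------------------------------------
# Threshold estimation
# ---------------------------------------------------------------------------

def estimate_index_jump_threshold(
    table: ReadCountTable, sanity_cap: float = 0.05
) -> JumpThreshold:
    """Global maximum of ``counts(a, u) / R(a)`` over every ASV ``a`` and
    unused replicate ``u``; zero when all unused cells are empty.

    ``R(a)`` is the ASV's whole-dataset total (all columns). A threshold above
    ``sanity_cap`` is flagged with a warning rather than rejected: a
    pathological value (e.g. an ASV found only in an unused combination)
    would otherwise silently erase the dataset.
    """
    unused = table.unused_columns
    if not unused:
        raise ValidationError(
            "no replicates with status 'unused': supply a manual JumpThreshold"
        )
    totals = table.asv_totals.to_numpy().astype(float)
    nonzero = totals > 0
    if not nonzero.any():
        return JumpThreshold(0.0, sanity_cap=sanity_cap)
    sub = table.counts.loc[nonzero, unused].to_numpy().astype(float)
    props = sub / totals[nonzero, None]
    best = float(props.max(initial=0.0))
    if best == 0.0:
        return JumpThreshold(0.0, sanity_cap=sanity_cap)
    r, c = np.argwhere(props == best)[0]  # first in (ASV, column) order
    return JumpThreshold(
        value=best,
        source_asv=str(table.counts.index[np.flatnonzero(nonzero)[r]]),
        source_replicate=unused[c],
        capped_warning=best > sanity_cap,
        sanity_cap=sanity_cap,
    )


def estimate_per_asv_thresholds(table: ReadCountTable) -> pd.Series:
    """Per-ASV variant: the maximum unused-column proportion of each ASV.

    Offered behind a flag; the global threshold is the default reading of a
    single dataset-wide correction value.
    """
    unused = table.unused_columns
    if not unused:
        raise ValidationError(
            "no replicates with status 'unused': supply manual thresholds"
        )
    totals = table.asv_totals.astype(float)
    props = table.counts[unused].div(totals.where(totals > 0, np.nan), axis=0)
    return props.max(axis=1).fillna(0.0)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _report(
    step: str,
    before: pd.DataFrame,
    after: pd.DataFrame,
    removed_mask: np.ndarray,
    warnings: list[str],
) -> FilterReport:
    rows, cols = np.nonzero(removed_mask)
    values = before.to_numpy()
    removed = [
        (str(before.index[r]), str(before.columns[c]), int(values[r, c]))
        for r, c in zip(rows, cols)
    ]
    return FilterReport(
        step=step,
        asvs_in=before.shape[0],
        asvs_out=int((after.sum(axis=1) > 0).sum()),
        reads_in=int(values.sum()),
        reads_out=int(after.to_numpy().sum()),
        removed_cells=removed,
        warnings=warnings,
    )


def _drop_empty_rows(counts: pd.DataFrame) -> pd.DataFrame:
    return counts.loc[counts.sum(axis=1) > 0]


def apply_index_jump_filter(
    table: ReadCountTable,
    threshold: JumpThreshold | pd.Series,
    totals: pd.Series | None = None,
) -> tuple[ReadCountTable, FilterReport]:
    """Zero every cell whose read proportion does not exceed the threshold.

    For each ASV ``a`` and replicate ``s`` the cell is removed when
    ``counts(a, s) / R(a) <= threshold`` (strictly "more than" survives). By
    default ``R(a)`` is recomputed from ``table``; pass the pre-filter
    ``totals`` to re-apply a correction with frozen denominators, which makes
    the filter idempotent. ``threshold`` may be a per-ASV Series.
    """
    counts = table.counts
    if totals is None:
        totals = table.asv_totals
    totals = totals.reindex(counts.index).fillna(0).astype(float)
    if isinstance(threshold, JumpThreshold):
        thr = np.full(len(counts), threshold.value, dtype=float)
        warnings = (
            [
                f"threshold {threshold.value:.6g} exceeds sanity cap "
                f"{threshold.sanity_cap:g}; the correction may erase most of "
                f"the dataset"
            ]
            if threshold.capped_warning
            else []
        )
    else:
        thr = threshold.reindex(counts.index).fillna(0.0).to_numpy(dtype=float)
        if np.any(thr < 0):
            raise ValidationError("negative per-ASV threshold")
        warnings = []
    if np.any(thr < 0):
        raise ValidationError("negative threshold")
    values = counts.to_numpy()
    denom = np.where(totals.to_numpy() > 0, totals.to_numpy(), np.inf)
    props = values / denom[:, None]
    removed_mask = (values > 0) & (props <= thr[:, None])
    new_values = np.where(removed_mask, 0, values)
    new_counts = _drop_empty_rows(
        pd.DataFrame(new_values, index=counts.index, columns=counts.columns)
    )
    out = ReadCountTable(new_counts, list(table.replicates))
    return out, _report("index_jump", counts, new_counts, removed_mask, warnings)


def apply_replicate_filter(
    table: ReadCountTable,
    min_replicates: int = 2,
    include_controls: bool = True,
) -> tuple[ReadCountTable, FilterReport]:
    """Within each site, zero every ASV occupying fewer than ``min_replicates``
    of the site's replicates (absolute count, not a fraction of the site's
    replicate total, so sites with missing filters are treated consistently).

    With ``include_controls`` the pooled negative-control columns form one
    additional replicate group and are cleaned by the same rule.
    """
    counts = table.counts
    warnings: list[str] = []
    groups = dict(table.site_groups)
    if include_controls and table.control_columns:
        groups["__controls__"] = table.control_columns
    removed_mask = np.zeros(counts.shape, dtype=bool)
    values = counts.to_numpy()
    col_index = {c: i for i, c in enumerate(counts.columns)}
    for group, cols in groups.items():
        if len(cols) < 2:
            warnings.append(
                f"group {group!r} has a single replicate: the rule would zero "
                f"everything observed once; group left untouched"
            )
            continue
        idx = [col_index[c] for c in cols]
        sub = values[:, idx]
        occupied = (sub > 0).sum(axis=1)
        kill_rows = (occupied > 0) & (occupied < min_replicates)
        removed_mask[np.ix_(kill_rows, idx)] = sub[kill_rows] > 0
    new_values = np.where(removed_mask, 0, values)
    new_counts = _drop_empty_rows(
        pd.DataFrame(new_values, index=counts.index, columns=counts.columns)
    )
    out = ReadCountTable(new_counts, list(table.replicates))
    return out, _report("replicate", counts, new_counts, removed_mask, warnings)


def check_negative_controls(table: ReadCountTable) -> ControlReport:
    """Per-control read totals after correction; does not modify the table."""
    controls = table.control_columns
    per_control = {c: int(table.counts[c].sum()) for c in controls}
    dirty = tuple(c for c, n in per_control.items() if n > 0)
    return ControlReport(
        per_control=per_control, all_clean=not dirty, dirty_controls=dirty
    )


def decontaminate(
    table: ReadCountTable,
    threshold: JumpThreshold | pd.Series | None = None,
    min_replicates: int = 2,
    include_controls: bool = True,
    sanity_cap: float = 0.05,
) -> tuple[ReadCountTable, JumpThreshold | pd.Series, list[FilterReport], ControlReport]:
    """Full correction: estimate the jump threshold (unless supplied), apply
    the index-jump filter, then the replicate filter, then verify controls.

    The order is fixed -- the two filters do not commute: the replicate filter
    judges occupancy patterns that the jump filter has already cleaned of
    misassigned reads.
    """
    if threshold is None:
        threshold = estimate_index_jump_threshold(table, sanity_cap=sanity_cap)
    t1, rep1 = apply_index_jump_filter(table, threshold)
    t2, rep2 = apply_replicate_filter(
        t1, min_replicates=min_replicates, include_controls=include_controls
    )
    controls = check_negative_controls(t2)
    return t2, threshold, [rep1, rep2], controls
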