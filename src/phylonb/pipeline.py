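"""Cohort-style end-to-end workflow.

Mirrors the analysis applied to large 16S cohorts: filter OTUs by
prevalence and by family size, split the retained OTUs into batches of
at most a few hundred OTUs ordered by family abundance (a memory /
runtime constraint of whole-posterior fitting), fit the hierarchical
model per batch for one standardized food item, and concatenate
per-OTU association tables with a Bonferroni correction across
batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchical import ModelSpec, fit_bhm, summarize_associations
from .io import UNCLASSIFIED, CountMatrix, CovariateVector, FamilyMap, standardize

__all__ = ["BatchPlan", "filter_otus", "make_batches", "run_food_item"]


@dataclass
class BatchPlan:
    """Partition of the retained OTUs into fitting batches."""

    batches: list[list[str]]
    family_batches: dict[str, list[int]] = field(default_factory=dict)
    max_otus_per_batch: int = 200

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def all_otus(self) -> list[str]:
        return [o for b in self.batches for o in b]

    def validate(self, otu_ids) -> None:
        flat = self.all_otus()
        if len(flat) != len(set(flat)):
            raise ValueError("batches overlap")
        if set(flat) != set(otu_ids):
            raise ValueError("batches do not cover the OTU set")


def filter_otus(
    counts: CountMatrix,
    fam: FamilyMap,
    prevalence: float = 0.2,
    min_family_size: int = 5,
    totals: str = "original",
) -> tuple[CountMatrix, FamilyMap]:
    """Prevalence filter, then family-size filter.

    Keeps OTUs with a nonzero count in at least ``prevalence`` of the
    subjects, then keeps OTUs whose identified family still has at
    least ``min_family_size`` members (so each OTU shares its family
    with at least ``min_family_size - 1`` others); unclassified
    families never pass the second filter.  ``totals`` controls
    whether library sizes keep their pre-filter values (default) or
    are recomputed over the retained OTUs.
    """
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    if min_family_size < 1:
        raise ValueError("min_family_size must be >= 1")
    n_subj = counts.n_subjects
    present = (counts.counts > 0).sum(axis=0)
    keep1 = [
        o for o, p in zip(counts.otu_ids, present) if p >= prevalence * n_subj
    ]
    sizes: dict[str, int] = {}
    for o in keep1:
        sizes[fam.mapping[o]] = sizes.get(fam.mapping[o], 0) + 1
    keep2 = [
        o
        for o in keep1
        if fam.mapping[o] != UNCLASSIFIED and sizes[fam.mapping[o]] >= min_family_size
    ]
    if not keep2:
        raise ValueError("no OTUs retained after filtering")
    out = counts.select_otus(keep2, totals=totals)
    return out, fam.restrict(keep2)


def make_batches(
    counts: CountMatrix, fam: FamilyMap, max_otus_per_batch: int = 200
) -> BatchPlan:
    """Pack families into batches ordered by average abundance.

    Families are sorted by descending mean relative abundance (mean
    over subjects of the family's share of the library) and packed
    greedily; a family is only split across batches when it alone
    exceeds the cap.
    """
    rel = counts.counts / counts.totals[:, None]
    fam_of = [fam.mapping[o] for o in counts.otu_ids]
    fam_names = list(dict.fromkeys(fam_of))
    fam_abund = {
        f: rel[:, [i for i, g in enumerate(fam_of) if g == f]].sum(axis=1).mean()
        for f in fam_names
    }
    ordered = sorted(fam_names, key=lambda f: (-fam_abund[f], f))

    batches: list[list[str]] = [[]]
    family_batches: dict[str, list[int]] = {}
    for f in ordered:
        members = [o for o, g in zip(counts.otu_ids, fam_of) if g == f]
        if len(members) > max_otus_per_batch:
            # oversized family: fill the current batch, then dedicated ones
            chunks = []
            pos = 0
            while pos < len(members):
                room = max_otus_per_batch - len(batches[-1])
                if room == 0:
                    batches.append([])
                    room = max_otus_per_batch
                chunks.append(members[pos : pos + room])
                pos += room
                batches[-1].extend(chunks[-1])
            family_batches[f] = sorted(
                {i for i, b in enumerate(batches) if set(b) & set(members)}
            )
        else:
            if len(batches[-1]) + len(members) > max_otus_per_batch:
                batches.append([])
            batches[-1].extend(members)
            family_batches[f] = [len(batches) - 1]
    plan = BatchPlan(
        batches=[b for b in batches if b],
        family_batches=family_batches,
        max_otus_per_batch=max_otus_per_batch,
    )
    plan.validate(counts.otu_ids)
    return plan


def run_food_item(
    counts: CountMatrix,
    fam: FamilyMap,
    x: CovariateVector,
    plan: BatchPlan | None = None,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Fit the hierarchical model batch-wise for one food item.

    ``x`` is standardized if it is not already.  The returned table has
    one row per retained OTU with the significance flag Bonferroni-
    corrected for the number of batches.
    """
    spec = spec or ModelSpec()
    if not x.standardized:
        x = standardize(x)
    if plan is None:
        plan = make_batches(counts, fam)
    plan.validate(counts.otu_ids)

    tables = []
    for b_idx, batch in enumerate(plan.batches):
        sub = counts.select_otus(batch, totals="original")
        fit = fit_bhm(sub, fam.restrict(batch), x, spec)
        tab = summarize_associations(fit, n_batches=plan.n_batches)
        tab.insert(0, "batch", b_idx)
        tab["fit_warnings"] = "; ".join(fit.warnings)
        tables.append(tab)
    out = pd.concat(tables, ignore_index=True)
    order = {o: i for i, o in enumerate(counts.otu_ids)}
    return out.sort_values("otu_id", key=lambda s: s.map(order), ignore_index=True)
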