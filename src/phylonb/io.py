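"""Readers, writers and validated containers for the tabular inputs.

The tool works from three tab-separated files: an OTU count table
(subjects x OTUs), a taxonomy table mapping each OTU to a phylogenetic
family (either an explicit ``family`` column or a Greengenes-style
lineage string with an ``f__`` token), and a table of per-subject food
item scores.  BIOM files are deliberately not supported; export to TSV
first.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

UNCLASSIFIED = "unclassified"

__all__ = [
    "CountMatrix",
    "FamilyMap",
    "CovariateVector",
    "read_counts",
    "write_counts",
    "read_taxonomy",
    "read_covariates",
    "standardize",
    "UNCLASSIFIED",
]


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


@dataclass
class CountMatrix:
    """Subjects x OTUs count table with per-subject sequencing depths.

    Parameters
    ----------
    subject_ids, otu_ids : list of str
        Unique row/column identifiers.
    counts : ndarray of shape (n_subjects, n_otus)
        Non-negative integer OTU counts ``Y``.
    totals : ndarray of shape (n_subjects,), optional
        Library sizes ``z_i`` used as the regression offset.  When
        omitted they are computed as row sums of ``counts``.  Kept
        separate from the counts so that filtering OTUs can preserve the
        original sequencing depth.
    """

    subject_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    totals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D subjects x OTUs array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at subject {self.subject_ids[i]!r}, "
                f"OTU {self.otu_ids[j]!r}"
            )
        n, p = self.counts.shape
        if len(self.subject_ids) != n or len(self.otu_ids) != p:
            raise FormatError("identifier lists do not match count dimensions")
        if len(set(self.subject_ids)) != n:
            raise FormatError("duplicate subject identifiers")
        if len(set(self.otu_ids)) != p:
            raise FormatError("duplicate OTU identifiers")
        if self.totals is None:
            self.totals = self.counts.sum(axis=1).astype(np.int64)
        else:
            self.totals = np.asarray(self.totals)
        if (self.totals <= 0).any():
            bad = self.subject_ids[int(np.argmax(self.totals <= 0))]
            raise FormatError(f"non-positive library size for subject {bad!r}")

    @property
    def n_subjects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def select_otus(self, keep: list[str], *, totals: str = "original") -> "CountMatrix":
        """Return a copy restricted to ``keep`` OTUs (order preserved).

        ``totals='original'`` keeps the pre-filter library sizes (the
        offset represents sequencing depth); ``totals='recompute'``
        replaces them with row sums over the retained OTUs.
        """
        idx = [self.otu_ids.index(o) for o in keep]
        counts = self.counts[:, idx]
        if totals == "original":
            new_totals = self.totals.copy()
        elif totals == "recompute":
            new_totals = counts.sum(axis=1)
        else:
            raise ValueError("totals must be 'original' or 'recompute'")
        return CountMatrix(list(self.subject_ids), list(keep), counts, new_totals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.subject_ids, columns=self.otu_ids)


@dataclass
class FamilyMap:
    """OTU -> phylogenetic family assignment defining the shrinkage groups."""

    mapping: dict[str, str]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for fam in self.mapping.values():
            seen.setdefault(fam, None)
        return list(seen)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_of(self, otu_id: str) -> str:
        return self.mapping[otu_id]

    def indices_for(self, otu_ids: list[str]) -> np.ndarray:
        """Zero-based family index per OTU, in first-appearance order."""
        missing = [o for o in otu_ids if o not in self.mapping]
        if missing:
            raise FormatError(f"OTUs without family assignment: {missing[:5]}")
        order: dict[str, int] = {}
        idx = np.empty(len(otu_ids), dtype=np.int64)
        for k, o in enumerate(otu_ids):
            fam = self.mapping[o]
            idx[k] = order.setdefault(fam, len(order))
        return idx

    def restrict(self, otu_ids: list[str]) -> "FamilyMap":
        return FamilyMap({o: self.mapping[o] for o in otu_ids})

    def collapsed(self, label: str = "all") -> "FamilyMap":
        """All OTUs in one family (the no-phylogeny comparator)."""
        return FamilyMap({o: label for o in self.mapping})


@dataclass
class CovariateVector:
    """Per-subject score of one food item (one FFQ column)."""

    subject_ids: list[str]
    values: np.ndarray
    name: str = "x"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.subject_ids) != self.values.shape[0]:
            raise FormatError("subject ids do not match covariate length")
        if self.standardized:
            if abs(self.values.mean()) > 1e-8 or abs(self.values.std(ddof=1) - 1) > 1e-8:
                raise FormatError("covariate flagged standardized but is not")

    def align(self, subject_ids: list[str]) -> "CovariateVector":
        pos = {s: k for k, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in pos]
        if missing:
            raise FormatError(f"subjects without covariate value: {missing[:5]}")
        idx = [pos[s] for s in subject_ids]
        return replace(self, subject_ids=list(subject_ids), values=self.values[idx])


def standardize(x: CovariateVector) -> CovariateVector:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    sd = x.values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"covariate {x.name!r} has zero variance")
    vals = (x.values - x.values.mean()) / sd
    return replace(x, values=vals, standardized=True)


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    return df


def read_counts(path, orientation: str = "subjects_rows") -> CountMatrix:
    """Read a TSV count table.

    ``orientation`` says whether rows are subjects (default) or OTUs;
    both layouts occur in the wild.
    """
    if orientation not in ("subjects_rows", "otus_rows"):
        raise ValueError("orientation must be 'subjects_rows' or 'otus_rows'")
    df = _read_tsv(path)
    if orientation == "otus_rows":
        df = df.T
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise FormatError(f"non-numeric entries in count table {path}")
    frac = np.mod(body, 1) != 0
    if frac.any():
        i, j = np.argwhere(frac)[0]
        raise FormatError(
            f"non-integer count {body[i, j]!r} at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return CountMatrix(
        [str(s) for s in df.index], [str(o) for o in df.columns], body.astype(np.int64)
    )


def write_counts(cm: CountMatrix, path, orientation: str = "subjects_rows") -> None:
    df = cm.to_frame()
    if orientation == "otus_rows":
        df = df.T
    df.to_csv(path, sep="\t", index_label="id")


_F_TOKEN = re.compile(r"(?:^|;)\s*f__([^;]*)")


def parse_family(lineage: str) -> str:
    """Extract the family from a Greengenes-style lineage string."""
    m = _F_TOKEN.search(lineage)
    if m is None:
        raise FormatError(f"no f__ token in lineage {lineage!r}")
    name = m.group(1).strip()
    return name if name else UNCLASSIFIED


def read_taxonomy(path) -> FamilyMap:
    """Read an OTU -> family table.

    Accepts either a two-column (otu, family) file or a table with a
    lineage/taxonomy column holding the full ``k__...;f__...`` string.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str).fillna("")
    df.iloc[:, 0] = df.iloc[:, 0].astype(str)
    cols = {c.lower(): c for c in df.columns}
    mapping: dict[str, str] = {}
    if "family" in cols:
        for otu, fam in zip(df.iloc[:, 0], df[cols["family"]]):
            fam = fam.strip()
            mapping[otu] = fam if fam else UNCLASSIFIED
    else:
        lineage_col = None
        for key in ("lineage", "taxonomy", "taxon"):
            if key in cols:
                lineage_col = cols[key]
                break
        if lineage_col is None:
            if df.shape[1] < 2:
                raise FormatError("taxonomy table needs a family or lineage column")
            lineage_col = df.columns[1]
        for otu, lin in zip(df.iloc[:, 0], df[lineage_col]):
            if "f__" in lin:
                mapping[otu] = parse_family(lin)
            elif ";" not in lin and lin.strip():
                # plain label in an unnamed second column
                mapping[otu] = lin.strip()
            else:
                raise FormatError(f"OTU {otu!r} has no family information")
    if len(mapping) != len(df):
        raise FormatError("duplicate OTU ids in taxonomy table")
    return FamilyMap(mapping)


def write_taxonomy(fam: FamilyMap, path) -> None:
    pd.DataFrame(
        {"otu_id": list(fam.mapping), "family": list(fam.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_covariates(path) -> dict[str, CovariateVector]:
    """Read the food-item score table; one CovariateVector per column."""
    df = _read_tsv(path)
    subjects = [str(s) for s in df.index]
    return {
        str(c): CovariateVector(subjects, df[c].to_numpy(dtype=float), name=str(c))
        for c in df.columns
    }


def write_covariates(covs: dict[str, CovariateVector], path) -> None:
    first = next(iter(covs.values()))
    df = pd.DataFrame({name: c.values for name, c in covs.items()}, index=first.subject_ids)
    df.to_csv(path, sep="\t", index_label="subject_id")
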