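"""Canonical data model for connectome flavors, matrices, edge vectors and cohorts.

A "flavor" is one combination of parcellation (atlas), modality (structural or
functional connectivity) and estimation method — e.g. Pearson FC on an
86-region atlas, or probabilistic-tractography SC on a 439-region atlas.
Every symmetric region x region matrix is handled internally as its strict
upper triangle stacked into an edge vector, in row-major (i < j) order with
0-based region indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FlavorSpec",
    "ConnectomeMatrix",
    "EdgeVectorSet",
    "CohortTable",
    "count_edges",
    "edge_index",
    "vectorize_upper",
    "devectorize_upper",
    "enumerate_paths",
    "validate_cohort",
    "read_matrix",
    "write_matrix",
    "read_cohort_tsv",
    "write_cohort_tsv",
]

SYMMETRY_TOL = 1e-8

COHORT_COLUMNS = [
    "subject_id", "age", "sex", "cog_total", "cog_fluid", "cog_cryst",
    "cog_early", "family_id", "zygosity", "split", "retest_of",
]


class ValidationError(ValueError):
    """Raised when a connectome object violates its structural invariants."""


def count_edges(n_regions: int) -> int:
    """Number of unique region pairs (strict upper triangle) for an atlas.

    An atlas with ``n`` regions yields ``n (n - 1) / 2`` pairwise connectivity
    estimates, e.g. 3655 for 86 regions and 96141 for 439 regions.
    """
    n = int(n_regions)
    if n < 2:
        raise ValidationError(f"an atlas needs at least 2 regions, got {n_regions}")
    return n * (n - 1) // 2


def edge_index(n_regions: int) -> list[tuple[int, int]]:
    """Ordered (row, col) pairs of the strict upper triangle, row-major."""
    iu = np.triu_indices(n_regions, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


@dataclass(frozen=True)
class FlavorSpec:
    """Identity of one connectome flavor.

    Parameters
    ----------
    name:
        Unique string id, e.g. ``"FS86_FC"`` or ``"coco439_SCpr"``.
    modality:
        ``"SC"`` or ``"FC"``.
    atlas:
        Parcellation name.
    n_regions:
        Number of atlas regions (>= 2).
    fc_variant:
        Required for FC: ``"pearson"``, ``"gsr"`` or ``"pcorr"``.
    sc_variant:
        Required for SC: ``"det"`` or ``"prob"``.
    """

    name: str
    modality: str
    atlas: str
    n_regions: int
    fc_variant: str | None = None
    sc_variant: str | None = None

    def __post_init__(self):
        if self.modality not in ("SC", "FC"):
            raise ValidationError(f"modality must be SC or FC, got {self.modality!r}")
        count_edges(self.n_regions)  # validates n_regions
        if self.modality == "FC":
            if self.fc_variant not in ("pearson", "gsr", "pcorr"):
                raise ValidationError(
                    f"FC flavor {self.name!r} needs fc_variant in "
                    f"{{pearson,gsr,pcorr}}, got {self.fc_variant!r}")
        else:
            if self.sc_variant not in ("det", "prob"):
                raise ValidationError(
                    f"SC flavor {self.name!r} needs sc_variant in {{det,prob}}, "
                    f"got {self.sc_variant!r}")

    @property
    def n_edges(self) -> int:
        return count_edges(self.n_regions)


@dataclass
class ConnectomeMatrix:
    """One subject's symmetric region x region connectivity matrix."""

    subject_id: str
    flavor: FlavorSpec
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = self.flavor.n_regions
        if v.shape != (n, n):
            raise ValidationError(
                f"{self.subject_id}/{self.flavor.name}: expected shape "
                f"({n},{n}), got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{self.subject_id}/{self.flavor.name}: non-finite entries")
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise ValidationError(
                f"{self.subject_id}/{self.flavor.name}: matrix asymmetric beyond "
                f"{SYMMETRY_TOL}")
        self.values = v

    def validate_range(self):
        """Check modality-specific value ranges (FC in [-1,1], SC >= 0)."""
        off = self.values[~np.eye(self.values.shape[0], dtype=bool)]
        if self.flavor.modality == "FC":
            if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
                raise ValidationError(
                    f"{self.subject_id}/{self.flavor.name}: FC entries outside [-1,1]")
        else:
            if off.size and off.min() < -1e-12:
                raise ValidationError(
                    f"{self.subject_id}/{self.flavor.name}: negative SC entries")


def vectorize_upper(m: ConnectomeMatrix | np.ndarray) -> np.ndarray:
    """Stack the strict upper triangle of a symmetric matrix into a vector.

    The diagonal is discarded; ordering is row-major over pairs (i, j), i < j.
    """
    if isinstance(m, ConnectomeMatrix):
        v = m.values
    else:
        v = np.asarray(m, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"expected a square matrix, got shape {v.shape}")
        if np.max(np.abs(v - v.T)) > SYMMETRY_TOL:
            raise ValidationError("matrix asymmetric beyond tolerance")
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu].copy()


def devectorize_upper(vec: np.ndarray, n_regions: int,
                      diagonal_fill: float = 0.0) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector.

    Inverse of :func:`vectorize_upper` off the diagonal; the diagonal is set
    to ``diagonal_fill`` (1.0 is the natural choice for correlation matrices,
    0.0 for streamline counts).
    """
    vec = np.asarray(vec, dtype=float).ravel()
    ne = count_edges(n_regions)
    if vec.size != ne:
        raise ValidationError(
            f"edge vector length {vec.size} does not match n_regions={n_regions} "
            f"(expected {ne})")
    out = np.full((n_regions, n_regions), 0.0)
    iu = np.triu_indices(n_regions, k=1)
    out[iu] = vec
    out = out + out.T
    np.fill_diagonal(out, diagonal_fill)
    return out


@dataclass
class EdgeVectorSet:
    """Subjects x edges data matrix for one flavor.

    ``data[s]`` is subject ``subject_ids[s]``'s edge vector, ordered by
    ``edge_index`` (fixed per flavor).
    """

    flavor: FlavorSpec
    subject_ids: list[str]
    data: np.ndarray
    edge_index: list[tuple[int, int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("EdgeVectorSet.data must be 2-D (subjects x edges)")
        if self.data.shape[1] != self.flavor.n_edges:
            raise ValidationError(
                f"{self.flavor.name}: data has {self.data.shape[1]} columns, "
                f"expected {self.flavor.n_edges} edges")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValidationError("subject_ids length does not match data rows")
        if self.edge_index is None:
            self.edge_index = edge_index(self.flavor.n_regions)
        elif list(self.edge_index) != edge_index(self.flavor.n_regions):
            raise ValidationError(
                f"{self.flavor.name}: edge_index is not the row-major strict "
                "upper triangle")

    @property
    def n_subj(self) -> int:
        return self.data.shape[0]

    def subset(self, subject_ids: list[str]) -> "EdgeVectorSet":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in subject_ids]
        return EdgeVectorSet(self.flavor, list(subject_ids), self.data[idx])

    def matrix(self, subject_id: str, diagonal_fill: float | None = None) -> ConnectomeMatrix:
        """Subject's edge vector as a full ConnectomeMatrix."""
        if diagonal_fill is None:
            diagonal_fill = 1.0 if self.flavor.modality == "FC" else 0.0
        row = self.data[self.subject_ids.index(subject_id)]
        vals = devectorize_upper(row, self.flavor.n_regions, diagonal_fill)
        return ConnectomeMatrix(subject_id, self.flavor, vals)


def enumerate_paths(flavors: list[FlavorSpec | str]) -> list[dict]:
    """All ordered (source, target) flavor pairs, self-pairs included.

    For F flavors this yields F^2 paths: F autoencoder paths (source ==
    target) and F(F-1) transcoder paths. 15 flavors give 225 paths.
    """
    names = [f.name if isinstance(f, FlavorSpec) else str(f) for f in flavors]
    if not names:
        raise ValidationError("need at least one flavor")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate flavor names: {dupes}")
    return [
        {"source": a, "target": b, "autoencoder": a == b}
        for a in names for b in names
    ]


@dataclass
class CohortTable:
    """Subject demographics, family structure and train/val/test splits.

    Wraps a DataFrame with columns ``subject_id, age, sex, cog_total,
    cog_fluid, cog_cryst, cog_early, family_id, zygosity, split, retest_of``.
    Splits must be family-disjoint: sibling leakage across splits inflates
    identifiability estimates.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COHORT_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def subjects(self, split: str | None = None, include_retest: bool = False) -> list[str]:
        t = self.table
        if not include_retest:
            t = t[t["retest_of"].isna() | (t["retest_of"] == "")]
        if split is not None:
            t = t[t["split"] == split]
        return t["subject_id"].tolist()

    def row(self, subject_id: str) -> pd.Series:
        m = self.table[self.table["subject_id"] == subject_id]
        if m.empty:
            raise KeyError(subject_id)
        return m.iloc[0]


def validate_cohort(cohort: CohortTable | pd.DataFrame) -> dict:
    """Check split/family integrity of a cohort table.

    Returns a report dict with keys ``passed``, ``duplicate_ids``,
    ``families_spanning_splits``, ``missing_fields``, ``unknown_splits``.
    The critical check is that no family appears in more than one of
    train/val/test (related subjects across splits leak identity information).
    """
    t = cohort.table if isinstance(cohort, CohortTable) else cohort
    report: dict = {"passed": True, "duplicate_ids": [],
                    "families_spanning_splits": [], "missing_fields": [],
                    "unknown_splits": []}
    missing = [c for c in COHORT_COLUMNS if c not in t.columns]
    if missing:
        report["missing_fields"] = missing
        report["passed"] = False
        return report
    ids = t["subject_id"]
    dupes = sorted(ids[ids.duplicated()].unique().tolist())
    if dupes:
        report["duplicate_ids"] = dupes
        report["passed"] = False
    bad_split = sorted(set(t["split"]) - {"train", "val", "test"})
    if bad_split:
        report["unknown_splits"] = bad_split
        report["passed"] = False
    spanning = []
    for fam, grp in t.groupby("family_id"):
        if pd.isna(fam) or fam == "":
            continue
        if grp["split"].nunique() > 1:
            spanning.append(str(fam))
    if spanning:
        report["families_spanning_splits"] = sorted(spanning)
        report["passed"] = False
    return report


# ---------------------------------------------------------------------------
# plain-text I/O


def write_matrix(path: str | Path, m: ConnectomeMatrix | np.ndarray) -> None:
    vals = m.values if isinstance(m, ConnectomeMatrix) else np.asarray(m, dtype=float)
    np.savetxt(path, vals, fmt="%.10g")


def read_matrix(path: str | Path, flavor: FlavorSpec | None = None,
                subject_id: str | None = None) -> np.ndarray | ConnectomeMatrix:
    """Read a whitespace/comma-delimited square matrix text file."""
    path = Path(path)
    try:
        vals = np.loadtxt(path)
    except ValueError:
        vals = np.loadtxt(path, delimiter=",")
    if flavor is None:
        return vals
    if subject_id is None:
        subject_id = path.stem.split("_")[0]
    return ConnectomeMatrix(subject_id, flavor, vals)


def write_cohort_tsv(path: str | Path, cohort: CohortTable) -> None:
    cohort.table.to_csv(path, sep="\t", index=False, columns=COHORT_COLUMNS)


def read_cohort_tsv(path: str | Path) -> CohortTable:
    t = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "family_id": str,
                                           "retest_of": str, "zygosity": str})
    return CohortTable(t)


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
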