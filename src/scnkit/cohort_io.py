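"""Cohort table and adjacency I/O.

The pipeline's input is one wide table: per-subject metadata columns
(``subject_id, group, age, sex, tiv``) followed by one column per brain
region holding that region's gray matter volume in mm^3.  Region column
order defines the node index order used by every downstream artifact
(correlation matrices, metric vectors, edge lists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

#: metadata columns every cohort table must provide (before remapping)
METADATA_COLUMNS = ("subject_id", "group", "age", "sex", "tiv")

#: the conventional AAL-derived region count; other counts only warn
EXPECTED_N_REGIONS = 90


@dataclass
class RegionalVolumeTable:
    """Validated per-subject regional gray matter volumes plus covariates.

    Parameters
    ----------
    subject_id
        Unique subject identifiers, one per row of ``volumes``.
    group
        Two-level group label per subject.
    age
        Age in years (non-negative).
    sex
        Binary sex code in {0, 1}.
    tiv
        Total intracranial volume in mm^3 (strictly positive).
    volumes
        ``(n_subjects, n_regions)`` array of regional volumes, mm^3,
        strictly positive.
    region_labels
        Unique, ordered region names; order fixes the node index order.
    """

    subject_id: list[str]
    group: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    tiv: np.ndarray
    volumes: np.ndarray
    region_labels: list[str]

    def __post_init__(self):
        self.group = np.asarray(self.group, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        self.tiv = np.asarray(self.tiv, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.subject_id = [str(s) for s in self.subject_id]
        self.region_labels = [str(r) for r in self.region_labels]
        _validate_table(self)

    @property
    def n_subjects(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_regions(self) -> int:
        return self.volumes.shape[1]

    @property
    def group_labels(self) -> tuple:
        """The two group labels, in sorted order."""
        return tuple(sorted(set(self.group)))

    def group_mask(self, label) -> np.ndarray:
        return self.group == label

    def covariate_matrix(self, names: tuple[str, ...]) -> np.ndarray:
        """Stack the named covariate columns into an (n_subjects, k) array."""
        cols = {"age": self.age, "sex": self.sex, "tiv": self.tiv}
        missing = [n for n in names if n not in cols]
        if missing:
            raise SchemaError(f"unknown covariate(s): {missing}")
        return np.column_stack([cols[n] for n in names])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "group": self.group,
                "age": self.age,
                "sex": self.sex.astype(int),
                "tiv": self.tiv,
            }
        )
        vols = pd.DataFrame(self.volumes, columns=self.region_labels, index=df.index)
        return pd.concat([df, vols], axis=1)


def _validate_table(t: RegionalVolumeTable) -> None:
    n, p = t.volumes.shape
    if len(t.subject_id) != n or len({*t.subject_id}) != n:
        raise CohortValidationError("subject_id must be unique, one per row")
    if len(t.region_labels) != p:
        raise CohortValidationError("region_labels length does not match volumes")
    if len(set(t.region_labels)) != p:
        dupes = sorted({r for r in t.region_labels if t.region_labels.count(r) > 1})
        raise CohortValidationError(f"duplicate region labels: {dupes}")
    for name, arr in (("age", t.age), ("sex", t.sex), ("tiv", t.tiv)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise CohortValidationError(
                f"missing/non-finite {name} for subject {t.subject_id[bad[0]]}"
            )
    bad = np.argwhere(~np.isfinite(t.volumes))
    if bad.size:
        i, j = bad[0]
        raise CohortValidationError(
            f"missing/non-finite volume for subject {t.subject_id[i]}, "
            f"region {t.region_labels[j]}"
        )
    bad = np.argwhere(t.volumes <= 0)
    if bad.size:
        i, j = bad[0]
        raise CohortValidationError(
            f"non-positive volume for subject {t.subject_id[i]}, "
            f"region {t.region_labels[j]}"
        )
    if np.any(t.tiv <= 0):
        i = int(np.flatnonzero(t.tiv <= 0)[0])
        raise CohortValidationError(f"non-positive TIV for subject {t.subject_id[i]}")
    if np.any(t.age < 0):
        i = int(np.flatnonzero(t.age < 0)[0])
        raise CohortValidationError(f"negative age for subject {t.subject_id[i]}")
    if not set(np.unique(t.sex)) <= {0.0, 1.0}:
        raise CohortValidationError("sex must be coded 0/1 (remap strings on read)")
    groups = sorted(set(t.group))
    if len(groups) != 2:
        raise CohortValidationError(
            f"expected exactly two group labels, found {len(groups)}: {groups}"
        )
    if p != EXPECTED_N_REGIONS:
        warnings.warn(
            f"cohort has {p} regions (conventional AAL parcellation has "
            f"{EXPECTED_N_REGIONS}); proceeding — the method is atlas-agnostic",
            stacklevel=3,
        )


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    sex_codes: tuple[str, str] = ("0", "1"),
) -> RegionalVolumeTable:
    """Read and validate a wide cohort table.

    Parameters
    ----------
    path
        CSV (comma) or TSV (tab, by extension) file with a header row.
    schema
        Optional mapping from the standard metadata names
        (``subject_id, group, age, sex, tiv``) to the file's column names.
        Unmapped metadata names default to themselves.  Every column not
        mapped to metadata is treated as a region; file order is kept.
    sex_codes
        Pair of string codes mapped to (0, 1), e.g. ``("M", "F")``.
        Numeric 0/1 columns pass through unchanged.
    """
    path = Path(path)
    schema = {**{c: c for c in METADATA_COLUMNS}, **(schema or {})}
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [schema[c] for c in METADATA_COLUMNS if schema[c] not in df.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s) in {path.name}: {missing}")
    meta_cols = {schema[c] for c in METADATA_COLUMNS}
    region_cols = [c for c in df.columns if c not in meta_cols]
    if not region_cols:
        raise SchemaError(f"no region columns found in {path.name}")

    sex_raw = df[schema["sex"]]
    if sex_raw.dtype == object:
        lo, hi = sex_codes
        mapped = sex_raw.astype(str).str.strip().map({lo: 0.0, hi: 1.0})
        if mapped.isna().any():
            bad = sex_raw[mapped.isna()].iloc[0]
            raise CohortValidationError(
                f"sex code {bad!r} not in configured pair {sex_codes}"
            )
        sex = mapped.to_numpy()
    else:
        sex = sex_raw.to_numpy(dtype=float)

    vols = df[region_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return RegionalVolumeTable(
        subject_id=df[schema["subject_id"]].astype(str).tolist(),
        group=df[schema["group"]].to_numpy(dtype=object),
        age=df[schema["age"]].to_numpy(dtype=float),
        sex=sex,
        tiv=df[schema["tiv"]].to_numpy(dtype=float),
        volumes=vols,
        region_labels=region_cols,
    )


def write_cohort(table: RegionalVolumeTable, path) -> None:
    """Write a cohort table as CSV/TSV (separator chosen by extension)."""
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# adjacency I/O


def write_adjacency(net, path, dialect: str = "edge-list") -> None:
    """Write a binary network.

    ``edge-list``: one undirected edge per line as two tab-separated node
    labels with i < j by node index, preceded by a ``# nodes:`` header line
    carrying the full ordered label list (so empty graphs and isolated
    nodes round-trip).  ``dense``: labeled N x N 0/1 CSV matrix.
    """
    path = Path(path)
    labels = net.node_labels
    if dialect == "edge-list":
        i, j = np.nonzero(np.triu(net.a, 1))
        with open(path, "w") as fh:
            fh.write("# nodes:\t" + "\t".join(labels) + "\n")
            for a, b in zip(i, j):
                fh.write(f"{labels[a]}\t{labels[b]}\n")
    elif dialect == "dense":
        pd.DataFrame(net.a.astype(int), index=labels, columns=labels).to_csv(path)
    else:
        raise ValueError(f"unknown adjacency dialect: {dialect!r}")


def read_adjacency(path, dialect: str = "edge-list"):
    """Read a binary network written by :func:`write_adjacency`."""
    from .network import BinaryNetwork

    path = Path(path)
    if dialect == "edge-list":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("# nodes:"):
                raise SchemaError(f"{path.name}: missing '# nodes:' header line")
            labels = header.split("\t")[1:]
            index = {lab: k for k, lab in enumerate(labels)}
            a = np.zeros((len(labels), len(labels)), dtype=np.int8)
            for line in fh:
                u, v = line.rstrip("\n").split("\t")
                a[index[u], index[v]] = a[index[v], index[u]] = 1
        return BinaryNetwork(a=a, node_labels=labels)
    if dialect == "dense":
        df = pd.read_csv(path, index_col=0)
        return BinaryNetwork(
            a=df.to_numpy(dtype=np.int8), node_labels=[str(c) for c in df.columns]
        )
    raise ValueError(f"unknown adjacency dialect: {dialect!r}")
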