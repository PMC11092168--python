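"""Multi-view datasets with possibly incomplete views.

A *view* is one feature representation (e.g. an OTU table produced by one
preprocessing pipeline) of a shared set of individuals.  Views are allowed
to be *incomplete*: each view j covers a subset ``N_j`` of the full sample
set ``N = union_j N_j``.  Missingness is expressed purely by a sample being
absent from a view's table — an in-row missing value is an error, never
silently imputed (imputation is an explicit baseline operation, see
:mod:`mvboost.baselines`).

Samples are identified by string identifier, not by row position; views may
list their samples in any order.  Class labels are encoded internally as the
positive integers ``1..C`` so that ``0`` can serve as the artificial
"no prediction" label for samples absent from a view.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MvBoostError",
    "ParseError",
    "IntegrityError",
    "ParameterError",
    "UnpredictableError",
    "ViewTable",
    "LabelEncoding",
    "MultiViewDataset",
    "read_view_table",
    "write_view_table",
    "read_labels",
    "write_labels",
    "read_manifest",
    "write_manifest",
    "load_dataset",
    "assemble_dataset",
    "restrict_to_samples",
]


class MvBoostError(Exception):
    """Base class for errors raised by mvboost."""


class ParseError(MvBoostError):
    """A file could not be parsed under the named dialect."""


class IntegrityError(MvBoostError):
    """A structural invariant of the data model is violated."""


class ParameterError(MvBoostError, ValueError):
    """An algorithm parameter is outside its valid range."""


class UnpredictableError(MvBoostError):
    """An instance is absent from every view used by the ensemble."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class ViewTable:
    """One feature table: samples (rows) x features (columns).

    Wraps a numeric :class:`pandas.DataFrame` whose index holds the sample
    identifiers and whose columns hold the feature identifiers.  A view may
    be empty (zero rows) only as the result of restricting a dataset; an
    empty view is flagged via :attr:`is_empty`.
    """

    view_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("ViewTable.data must be a pandas DataFrame")
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise IntegrityError(
                f"view {self.view_id!r}: duplicate sample identifier(s) {dups}"
            )
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise IntegrityError(
                f"view {self.view_id!r}: duplicate feature identifier(s) {dups}"
            )
        if self.data.shape[1] < 1:
            raise IntegrityError(f"view {self.view_id!r}: needs at least one feature")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"view {self.view_id!r}: non-numeric cell ({exc})"
            ) from None
        if self.data.isna().any().any():
            bad = np.argwhere(self.data.isna().to_numpy())
            r, c = bad[0]
            raise IntegrityError(
                f"view {self.view_id!r}: missing value at sample "
                f"{self.data.index[r]!r}, feature {self.data.columns[c]!r}; "
                "missingness must be expressed by omitting the sample row"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def is_empty(self) -> bool:
        return self.data.shape[0] == 0

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def contains(self, sample_id: str) -> bool:
        return sample_id in self.data.index

    def row(self, sample_id: str) -> np.ndarray:
        return self.data.loc[sample_id].to_numpy(dtype=float)

    def subset(self, keep: Iterable[str]) -> "ViewTable":
        keep = set(keep)
        idx = [s for s in self.data.index if s in keep]
        return ViewTable(self.view_id, self.data.loc[idx].copy())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ViewTable({self.view_id!r}, {self.n_samples} samples x "
            f"{self.n_features} features)"
        )


@dataclass(frozen=True)
class LabelEncoding:
    """Bijection between external labels and the internal classes ``1..C``.

    Class ``0`` is reserved for the artificial "unknown prediction" label of
    samples absent from a view and never corresponds to a real class.
    """

    classes: tuple  # external labels, position c-1 holds class c

    @classmethod
    def fit(cls, labels: Iterable) -> "LabelEncoding":
        uniq = sorted(set(labels), key=lambda v: (str(type(v)), v))
        return cls(classes=tuple(uniq))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def encode(self, labels: Iterable) -> np.ndarray:
        lut = {lab: c + 1 for c, lab in enumerate(self.classes)}
        try:
            return np.array([lut[v] for v in labels], dtype=int)
        except KeyError as exc:
            raise IntegrityError(f"unknown label {exc.args[0]!r}") from None

    def decode(self, codes: Iterable[int]) -> list:
        out = []
        for c in codes:
            c = int(c)
            if not 1 <= c <= len(self.classes):
                raise IntegrityError(f"internal class code {c} out of range")
            out.append(self.classes[c - 1])
        return out


@dataclass
class MultiViewDataset:
    """K view tables plus a shared label map over ``N = union_j N_j``.

    ``all_samples`` is ordered by first appearance across views (view order,
    then row order within a view).  ``y`` holds the internal class codes
    ``1..C`` aligned to ``all_samples``.
    """

    views: list[ViewTable]
    labels: dict  # external: sample_id -> label
    encoding: LabelEncoding
    all_samples: list[str]
    y: np.ndarray = field(repr=False)
    _masks: dict = field(default_factory=dict, repr=False)

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def n_samples(self) -> int:
        return len(self.all_samples)

    @property
    def n_classes(self) -> int:
        return self.encoding.n_classes

    @property
    def view_ids(self) -> list[str]:
        return [v.view_id for v in self.views]

    def view(self, view_id: str) -> ViewTable:
        for v in self.views:
            if v.view_id == view_id:
                return v
        raise KeyError(view_id)

    def membership_mask(self, j: int) -> np.ndarray:
        """Boolean mask over ``all_samples``: True where sample is in view j."""
        if j not in self._masks:
            present = set(self.views[j].sample_ids)
            self._masks[j] = np.array(
                [s in present for s in self.all_samples], dtype=bool
            )
        return self._masks[j]

    def is_complete(self) -> bool:
        return all(self.membership_mask(j).all() for j in range(self.n_views))

    def __repr__(self) -> str:  # pragma: no cover
        shapes = ", ".join(
            f"{v.view_id}:{v.n_samples}x{v.n_features}" for v in self.views
        )
        return (
            f"MultiViewDataset({self.n_samples} samples, "
            f"{self.n_classes} classes, views=[{shapes}])"
        )


# ---------------------------------------------------------------------------
# Assembly and restriction
# ---------------------------------------------------------------------------


def assemble_dataset(
    views: Sequence[ViewTable],
    labels: Mapping[str, object],
    allow_empty_views: bool = False,
) -> MultiViewDataset:
    """Combine view tables and a label map into a :class:`MultiViewDataset`.

    Every sample appearing in any view must have a label; labels are encoded
    to the internal classes ``1..C``.
    """
    if len(views) < 1:
        raise IntegrityError("a dataset needs at least one view")
    ids = [v.view_id for v in views]
    if len(set(ids)) != len(ids):
        raise IntegrityError(f"duplicate view ids: {ids}")
    if not allow_empty_views:
        for v in views:
            if v.is_empty:
                raise IntegrityError(f"view {v.view_id!r} is empty")

    all_samples: list[str] = []
    seen: set[str] = set()
    for v in views:
        for s in v.sample_ids:
            if s not in seen:
                seen.add(s)
                all_samples.append(s)

    missing = [s for s in all_samples if s not in labels]
    if missing:
        raise IntegrityError(f"unlabeled sample(s): {missing}")

    sub_labels = {s: labels[s] for s in all_samples}
    enc = LabelEncoding.fit(sub_labels.values())
    y = enc.encode(sub_labels[s] for s in all_samples)
    return MultiViewDataset(
        views=list(views),
        labels=sub_labels,
        encoding=enc,
        all_samples=all_samples,
        y=y,
    )


def restrict_to_samples(
    ds: MultiViewDataset, keep: Iterable[str]
) -> MultiViewDataset:
    """Intersect every view with ``keep`` (a subset of ``N``).

    Views that become empty are retained (flagged via ``is_empty``) so the
    view index structure is preserved, e.g. across cross-validation folds.
    Idempotent and independent of view order.
    """
    keep = set(keep)
    unknown = keep - set(ds.all_samples)
    if unknown:
        raise IntegrityError(f"samples not in dataset: {sorted(unknown)}")
    if not keep:
        raise IntegrityError("keep set is disjoint from the dataset")
    views = [v.subset(keep) for v in ds.views]
    labels = {s: ds.labels[s] for s in ds.all_samples if s in keep}
    # keep the parent's encoding: folds must share the class code space
    all_samples = [s for s in ds.all_samples if s in keep]
    y = ds.encoding.encode(labels[s] for s in all_samples)
    return MultiViewDataset(
        views=views,
        labels=labels,
        encoding=ds.encoding,
        all_samples=all_samples,
        y=y,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_DIALECT_SEP = {"tsv": "\t", "csv": ","}


def read_view_table(
    path: str | Path,
    dialect: str = "tsv",
    orientation: str = "samples_as_rows",
    view_id: str | None = None,
) -> ViewTable:
    """Read a feature table from TSV/CSV (header row + id column) or BIOM.

    BIOM tables (1.0 JSON or 2.x HDF5) store observations (features) as rows
    and samples as columns; the ``orientation`` argument is ignored for them.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    vid = view_id if view_id is not None else path.stem
    if dialect == "biom":
        df = _read_biom(path)
    elif dialect in _DIALECT_SEP:
        try:
            df = pd.read_csv(path, sep=_DIALECT_SEP[dialect], index_col=0)
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from None
        if orientation == "features_as_rows":
            df = df.T
        elif orientation != "samples_as_rows":
            raise ParameterError(f"unknown orientation {orientation!r}")
        _check_numeric(df, path)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return ViewTable(vid, df)


def _check_numeric(df: pd.DataFrame, path: Path) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}"
            )


def _read_biom(path: Path) -> pd.DataFrame:
    """Minimal BIOM reader: 1.0 (JSON) and 2.x (HDF5, CSR by observation)."""
    import h5py

    if h5py.is_hdf5(path):
        with h5py.File(path, "r") as f:
            obs_ids = [x.decode() if isinstance(x, bytes) else str(x)
                       for x in f["observation/ids"][:]]
            samp_ids = [x.decode() if isinstance(x, bytes) else str(x)
                        for x in f["sample/ids"][:]]
            data = f["observation/matrix/data"][:]
            indices = f["observation/matrix/indices"][:]
            indptr = f["observation/matrix/indptr"][:]
        from scipy.sparse import csr_matrix

        mat = csr_matrix(
            (data, indices, indptr), shape=(len(obs_ids), len(samp_ids))
        ).toarray()
        return pd.DataFrame(mat.T, index=samp_ids, columns=obs_ids)

    try:
        doc = json.loads(path.read_text())
    except Exception as exc:
        raise ParseError(f"{path}: not HDF5 and not JSON ({exc})") from None
    obs_ids = [r["id"] for r in doc["rows"]]
    samp_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    else:
        mat[:, :] = np.asarray(doc["data"], dtype=float)
    return pd.DataFrame(mat.T, index=samp_ids, columns=obs_ids)


def write_view_table(
    table: ViewTable, path: str | Path, dialect: str = "tsv"
) -> None:
    if dialect not in _DIALECT_SEP:
        raise ParameterError(f"unknown dialect {dialect!r}")
    table.data.to_csv(Path(path), sep=_DIALECT_SEP[dialect])


def read_labels(path: str | Path) -> dict:
    """Two-column TSV (sample_id, label); a header line is tolerated."""
    df = pd.read_csv(Path(path), sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 0] in ("sample_id", "sample", "#sample_id"):
        df = df.iloc[1:]
    if df[0].duplicated().any():
        dups = df[0][df[0].duplicated()].tolist()
        raise IntegrityError(f"{path}: duplicate sample id(s) {dups}")
    return dict(zip(df[0], df[1]))


def write_labels(labels: Mapping[str, object], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s, lab in labels.items():
            fh.write(f"{s}\t{lab}\n")


def read_manifest(path: str | Path) -> list[dict]:
    """View manifest: JSON or YAML list of {view_id, path, dialect, orientation}."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if isinstance(doc, dict) and "views" in doc:
        doc = doc["views"]
    if not isinstance(doc, list):
        raise ParseError(f"{path}: manifest must be a list of view entries")
    out = []
    for i, entry in enumerate(doc):
        if "path" not in entry:
            raise ParseError(f"{path}: manifest entry {i} lacks field 'path'")
        out.append(
            {
                "view_id": entry.get("view_id", Path(entry["path"]).stem),
                "path": entry["path"],
                "dialect": entry.get("dialect", "tsv"),
                "orientation": entry.get("orientation", "samples_as_rows"),
            }
        )
    return out


def write_manifest(entries: Sequence[Mapping], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"views": list(entries)}, fh, indent=2)
        fh.write("\n")


def load_dataset(
    manifest_path: str | Path, labels_path: str | Path
) -> MultiViewDataset:
    """Load views listed in a manifest plus a label table into one dataset."""
    base = Path(manifest_path).parent
    views = []
    for entry in read_manifest(manifest_path):
        p = Path(entry["path"])
        if not p.is_absolute():
            p = base / p
        views.append(
            read_view_table(
                p,
                dialect=entry["dialect"],
                orientation=entry["orientation"],
                view_id=entry["view_id"],
            )
        )
    labels = read_labels(labels_path)
    return assemble_dataset(views, labels)
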