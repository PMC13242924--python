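"""Element-level codec for the AnnData on-disk (H5AD) format.

Each element stored in an H5AD container is an HDF5 dataset or group
tagged with two attributes, ``encoding-type`` and ``encoding-version``,
that determine how its payload is interpreted.  This module implements a
bidirectional codec for every encoding in the closed registry below:

====================  =========================================  ===========
encoding-type         in-memory value                            stored as
====================  =========================================  ===========
array                 :class:`numpy.ndarray` (numeric/boolean)   dataset
string-array          ndarray of ``str`` (object dtype)          vlen-UTF-8 dataset
string                ``str``                                    0-d dataset
numeric-scalar        ``int`` / ``float`` / ``bool``             0-d dataset
csr_matrix            :class:`scipy.sparse.csr_matrix`           group(data, indices, indptr)
csc_matrix            :class:`scipy.sparse.csc_matrix`           group(data, indices, indptr)
categorical           :class:`pandas.Categorical`                group(codes, categories)
nullable-integer      pandas ``Int64`` extension array           group(values, mask)
nullable-boolean      pandas ``boolean`` extension array         group(values, mask)
dataframe             :class:`pandas.DataFrame`                  group, one child per column
dict                  ``dict``                                   group, recursive
====================  =========================================  ===========

Scalars decode to native Python scalars (never 0-d arrays), so they
re-encode as scalars.  Missing values translate on read: categorical
code ``-1`` and a ``True`` nullable mask both become the host missing
value (``NaN`` / ``pd.NA``); floating-point ``NaN`` passes through
untouched so float round-trips are bit-exact.

Files lacking the encoding attributes (written before the attributes
were standardised) are handled by a configurable *legacy policy*:
``"infer"`` (default) deduces the encoding from the HDF5 structure with
a warning, ``"error"`` raises.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ElementValidationError, EncodingError

__all__ = [
    "ENCODING_REGISTRY",
    "EncodedElement",
    "SparseTriple",
    "WriteOptions",
    "detect_encoding",
    "read_element",
    "write_element",
    "read_dense",
    "read_sparse",
    "write_sparse",
    "read_categorical",
    "write_categorical",
    "read_nullable",
    "write_nullable",
    "read_dataframe",
    "write_dataframe",
    "read_mapping",
    "write_mapping",
]

#: Version string written for each encoding.  These match the versions
#: emitted by the current reference implementation so files interoperate
#: bit-for-bit at the attribute level.
ENCODING_REGISTRY: dict[str, str] = {
    "anndata": "0.1.0",
    "raw": "0.1.0",
    "array": "0.2.0",
    "string-array": "0.2.0",
    "string": "0.2.0",
    "numeric-scalar": "0.2.0",
    "dict": "0.1.0",
    "dataframe": "0.2.0",
    "categorical": "0.2.0",
    "csr_matrix": "0.1.0",
    "csc_matrix": "0.1.0",
    "nullable-integer": "0.1.0",
    "nullable-boolean": "0.1.0",
}

_VERSION_RE = re.compile(r"^\d+(\.\d+)*$")

#: Reserved index name used on disk when a dataframe's index is unnamed.
DEFAULT_INDEX_KEY = "_index"


@dataclass(frozen=True)
class EncodedElement:
    """Descriptor of an on-disk element: its encoding tag, version and
    (optionally) decoded payload."""

    encoding_type: str
    encoding_version: str
    payload: object | None = None

    def __post_init__(self):
        if self.encoding_type not in ENCODING_REGISTRY:
            raise EncodingError("", f"unknown encoding-type '{self.encoding_type}'")
        if not _VERSION_RE.match(self.encoding_version):
            raise EncodingError(
                "", f"encoding-version '{self.encoding_version}' is not dotted numerals"
            )


@dataclass
class WriteOptions:
    """Options applied to every dataset created by the writer.

    compression:
        HDF5 filter name, or ``None`` to disable.  gzip level 4 by
        default; scalar and empty datasets are always written unfiltered
        (HDF5 cannot chunk them).
    """

    compression: str | None = "gzip"
    compression_opts: int | None = 4

    def dataset_kwargs(self, shape) -> dict:
        if self.compression is None or any(n == 0 for n in shape) or shape == ():
            return {}
        return {
            "compression": self.compression,
            "compression_opts": self.compression_opts,
        }


# ---------------------------------------------------------------------------
# small helpers


def _path_of(loc) -> str:
    try:
        return loc.name or "/"
    except Exception:  # pragma: no cover - detached object
        return "/"


def _decode_attr(value):
    """HDF5 attribute values may surface as bytes depending on how the
    producing library stored them; normalise to str."""
    if isinstance(value, bytes):
        return value.decode("utf-8")
    if isinstance(value, np.ndarray):
        return [_decode_attr(v) for v in value.tolist()]
    return value


def _is_string_dataset(ds: h5py.Dataset) -> bool:
    return h5py.check_string_dtype(ds.dtype) is not None


def _write_encoding_attrs(loc, encoding_type: str) -> None:
    loc.attrs["encoding-type"] = encoding_type
    loc.attrs["encoding-version"] = ENCODING_REGISTRY[encoding_type]


def _string_values(arr: np.ndarray) -> np.ndarray:
    """Object-dtype array of Python str, any shape."""
    out = np.empty(arr.shape, dtype=object)
    flat = out.reshape(-1)
    for i, v in enumerate(np.asarray(arr).reshape(-1)):
        flat[i] = v.decode("utf-8") if isinstance(v, bytes) else str(v)
    return out


# ---------------------------------------------------------------------------
# encoding detection


def _infer_encoding(loc) -> str:
    """Structural inference for legacy elements with no encoding attributes."""
    if isinstance(loc, h5py.Dataset):
        if _is_string_dataset(loc):
            return "string" if loc.shape == () else "string-array"
        return "numeric-scalar" if loc.shape == () else "array"
    keys = set(loc.keys())
    if {"data", "indices", "indptr"} <= keys:
        fmt = _decode_attr(loc.attrs.get("h5sparse_format", "csr"))
        return "csc_matrix" if fmt == "csc" else "csr_matrix"
    if {"codes", "categories"} <= keys:
        return "categorical"
    if {"values", "mask"} <= keys:
        values = loc["values"]
        if values.dtype.kind == "b" or h5py.check_enum_dtype(values.dtype):
            return "nullable-boolean"
        return "nullable-integer"
    if DEFAULT_INDEX_KEY in loc.attrs:
        return "dataframe"
    return "dict"


def detect_encoding(loc, legacy_policy: str = "infer") -> EncodedElement:
    """Read the encoding descriptor of an HDF5 dataset or group.

    Returns an :class:`EncodedElement` with ``payload=None``.  When the
    encoding attributes are absent the *legacy policy* applies:
    ``"infer"`` deduces the type from structure (with a warning),
    ``"error"`` raises an :class:`EncodingError` naming the path.
    """
    path = _path_of(loc)
    enc = loc.attrs.get("encoding-type")
    if enc is None:
        if legacy_policy == "error":
            raise EncodingError(path, "element has no encoding-type attribute")
        inferred = _infer_encoding(loc)
        warnings.warn(
            f"{path}: no encoding-type attribute; inferred '{inferred}' from structure",
            stacklevel=2,
        )
        return EncodedElement(inferred, ENCODING_REGISTRY[inferred])
    enc = _decode_attr(enc)
    if enc not in ENCODING_REGISTRY:
        raise EncodingError(path, f"unknown encoding-type '{enc}'")
    version = _decode_attr(loc.attrs.get("encoding-version", ENCODING_REGISTRY[enc]))
    try:
        return EncodedElement(enc, version)
    except EncodingError as exc:
        raise EncodingError(path, str(exc)) from None


# ---------------------------------------------------------------------------
# dense arrays, strings, scalars


def read_dense(ds: h5py.Dataset) -> np.ndarray:
    """Read an array-encoded dataset with its logical on-disk shape.

    Element ``[i, j]`` of the result equals on-disk element ``[i, j]``
    regardless of the producing language's storage order (HDF5 stores
    row-major; h5py preserves the logical indexing).
    """
    if _is_string_dataset(ds):
        return _string_values(ds.asstr()[()]) if ds.size else np.empty(ds.shape, dtype=object)
    return ds[()]


def _read_string_scalar(ds: h5py.Dataset) -> str:
    v = ds[()]
    return v.decode("utf-8") if isinstance(v, bytes) else str(v)


def _read_numeric_scalar(ds: h5py.Dataset):
    v = ds[()]
    if isinstance(v, np.generic):
        return v.item()
    return v


# ---------------------------------------------------------------------------
# sparse matrices


@dataclass
class SparseTriple:
    """data/indices/indptr representation of a CSR or CSC matrix.

    ``orientation`` is ``"CSR"`` (indptr over rows) or ``"CSC"`` (indptr
    over columns).  :meth:`validate` checks the structural invariants and
    raises a path-addressed error on the first violation.
    """

    data: np.ndarray
    indices: np.ndarray
    indptr: np.ndarray
    shape: tuple[int, int]
    orientation: str  # "CSR" | "CSC"

    @property
    def major_dim(self) -> int:
        return self.shape[0] if self.orientation == "CSR" else self.shape[1]

    @property
    def minor_dim(self) -> int:
        return self.shape[1] if self.orientation == "CSR" else self.shape[0]

    def validate(self, path: str = "") -> None:
        if self.orientation not in ("CSR", "CSC"):
            raise ElementValidationError(path, f"bad orientation '{self.orientation}'")
        nr, nc = self.shape
        if nr < 0 or nc < 0:
            raise ElementValidationError(path, f"negative shape {self.shape}")
        if len(self.indptr) != self.major_dim + 1:
            raise ElementValidationError(
                path,
                f"indptr has length {len(self.indptr)}, expected major_dim+1 = {self.major_dim + 1}",
            )
        if len(self.indptr) and self.indptr[0] != 0:
            raise ElementValidationError(path, "indptr does not start at 0")
        if np.any(np.diff(self.indptr) < 0):
            raise ElementValidationError(path, "indptr is not non-decreasing")
        if len(self.data) != len(self.indices):
            raise ElementValidationError(
                path, f"data length {len(self.data)} != indices length {len(self.indices)}"
            )
        if len(self.indptr) and self.indptr[-1] != len(self.data):
            raise ElementValidationError(
                path, f"indptr[-1] = {self.indptr[-1]} != nnz = {len(self.data)}"
            )
        if len(self.indices) and (
            self.indices.min() < 0 or self.indices.max() >= self.minor_dim
        ):
            raise ElementValidationError(
                path, f"index out of range for minor dimension {self.minor_dim}"
            )

    def to_scipy(self):
        cls = sparse.csr_matrix if self.orientation == "CSR" else sparse.csc_matrix
        return cls((self.data, self.indices, self.indptr), shape=self.shape)

    def toarray(self) -> np.ndarray:
        """Dense expansion by direct definition of the compressed layout
        (independent of scipy), used as the brute-force oracle."""
        out = np.zeros(self.shape, dtype=self.data.dtype if len(self.data) else float)
        for major in range(self.major_dim):
            for k in range(self.indptr[major], self.indptr[major + 1]):
                minor = self.indices[k]
                if self.orientation == "CSR":
                    out[major, minor] += self.data[k]
                else:
                    out[minor, major] += self.data[k]
        return out

    @classmethod
    def from_scipy(cls, m) -> "SparseTriple":
        if sparse.issparse(m) and m.format == "csc":
            orientation = "CSC"
            m = sparse.csc_matrix(m)
        else:
            orientation = "CSR"
            m = sparse.csr_matrix(m)
        return cls(m.data, m.indices, m.indptr, tuple(m.shape), orientation)


def read_sparse(group: h5py.Group) -> SparseTriple:
    """Decode a sparse group (``data``/``indices``/``indptr`` datasets plus
    a ``shape`` attribute) into a validated :class:`SparseTriple`."""
    path = _path_of(group)
    desc = detect_encoding(group)
    if desc.encoding_type not in ("csr_matrix", "csc_matrix"):
        raise EncodingError(path, f"not a sparse element: {desc.encoding_type}")
    for name in ("data", "indices", "indptr"):
        if name not in group:
            raise EncodingError(path, f"sparse group missing dataset '{name}'")
    shape_attr = group.attrs.get("shape", group.attrs.get("h5sparse_shape"))
    if shape_attr is None:
        raise EncodingError(path, "sparse group missing 'shape' attribute")
    triple = SparseTriple(
        data=group["data"][()],
        indices=np.asarray(group["indices"][()], dtype=np.int64),
        indptr=np.asarray(group["indptr"][()], dtype=np.int64),
        shape=tuple(int(n) for n in np.asarray(shape_attr)),
        orientation="CSR" if desc.encoding_type == "csr_matrix" else "CSC",
    )
    triple.validate(path)
    return triple


def write_sparse(parent: h5py.Group, key: str, matrix, orientation: str | None = None,
                 options: WriteOptions | None = None) -> None:
    """Write a sparse (or dense) matrix as a CSR/CSC group.

    scipy matrices keep their own orientation unless one is forced;
    dense input requires (or defaults to) CSR.  Indices and indptr are
    stored as 64-bit integers.
    """
    options = options or WriteOptions()
    if sparse.issparse(matrix):
        if orientation is None:
            orientation = "CSC" if matrix.format == "csc" else "CSR"
    else:
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise EncodingError(key, f"sparse write needs a 2-d matrix, got ndim={matrix.ndim}")
        orientation = orientation or "CSR"
    m = sparse.csr_matrix(matrix) if orientation == "CSR" else sparse.csc_matrix(matrix)
    m.sort_indices()
    triple = SparseTriple.from_scipy(m)
    triple.validate(key)
    grp = parent.create_group(key, track_order=True)
    _write_encoding_attrs(grp, "csr_matrix" if orientation == "CSR" else "csc_matrix")
    grp.attrs["shape"] = np.asarray(triple.shape, dtype=np.int64)
    grp.create_dataset("data", data=triple.data, **options.dataset_kwargs(triple.data.shape))
    grp.create_dataset("indices", data=triple.indices.astype(np.int64),
                       **options.dataset_kwargs(triple.indices.shape))
    grp.create_dataset("indptr", data=triple.indptr.astype(np.int64),
                       **options.dataset_kwargs(triple.indptr.shape))


# ---------------------------------------------------------------------------
# categoricals


def read_categorical(group: h5py.Group) -> pd.Categorical:
    """Decode a categorical group; code ``-1`` becomes a missing value."""
    path = _path_of(group)
    for name in ("codes", "categories"):
        if name not in group:
            raise EncodingError(path, f"categorical group missing '{name}'")
    codes = np.asarray(group["codes"][()])
    categories = read_dense(group["categories"])
    ordered = bool(_decode_attr(group.attrs.get("ordered", False)))
    if len(categories) != len(set(categories.tolist())):
        raise ElementValidationError(path, "categories contain duplicates")
    if codes.size and (codes.min() < -1 or codes.max() >= len(categories)):
        raise ElementValidationError(
            path, f"categorical code out of range for {len(categories)} categories"
        )
    return pd.Categorical.from_codes(codes, categories=categories.tolist(), ordered=ordered)


def write_categorical(parent: h5py.Group, key: str, cat: pd.Categorical,
                      options: WriteOptions | None = None) -> None:
    options = options or WriteOptions()
    grp = parent.create_group(key, track_order=True)
    _write_encoding_attrs(grp, "categorical")
    grp.attrs["ordered"] = bool(cat.ordered)
    codes = np.asarray(cat.codes)
    ds = grp.create_dataset("codes", data=codes, **options.dataset_kwargs(codes.shape))
    _write_encoding_attrs(ds, "array")
    _write_array(grp, "categories", np.asarray(cat.categories), options)


# ---------------------------------------------------------------------------
# nullable integer / boolean


def read_nullable(group: h5py.Group):
    """Decode a nullable-integer or nullable-boolean group into the
    corresponding pandas masked extension array."""
    path = _path_of(group)
    for name in ("values", "mask"):
        if name not in group:
            raise EncodingError(path, f"nullable group missing '{name}'")
    values = np.asarray(group["values"][()])
    mask = np.asarray(group["mask"][()], dtype=bool)
    if len(values) != len(mask):
        raise ElementValidationError(
            path, f"values length {len(values)} != mask length {len(mask)}"
        )
    desc = detect_encoding(group)
    if desc.encoding_type == "nullable-boolean" or values.dtype.kind == "b":
        return pd.arrays.BooleanArray(values.astype(bool), mask)
    return pd.arrays.IntegerArray(values.astype(np.int64), mask)


def write_nullable(parent: h5py.Group, key: str, arr, options: WriteOptions | None = None) -> None:
    options = options or WriteOptions()
    arr = pd.array(arr)
    is_bool = arr.dtype.kind == "b"
    mask = np.asarray(arr.isna(), dtype=bool)
    values = arr.to_numpy(dtype=bool if is_bool else np.int64, na_value=False if is_bool else 0)
    grp = parent.create_group(key, track_order=True)
    _write_encoding_attrs(grp, "nullable-boolean" if is_bool else "nullable-integer")
    ds = grp.create_dataset("values", data=values, **options.dataset_kwargs(values.shape))
    _write_encoding_attrs(ds, "array")
    ds = grp.create_dataset("mask", data=mask, **options.dataset_kwargs(mask.shape))
    _write_encoding_attrs(ds, "array")


# ---------------------------------------------------------------------------
# dataframes


def read_dataframe(group: h5py.Group, legacy_policy: str = "infer") -> pd.DataFrame:
    """Decode a dataframe group: the index column named by the ``_index``
    attribute plus one child element per column, restored in the order
    recorded by the ``column-order`` attribute."""
    path = _path_of(group)
    index_key = _decode_attr(group.attrs.get(DEFAULT_INDEX_KEY))
    if index_key is None:
        raise EncodingError(path, "dataframe group missing '_index' attribute")
    if index_key not in group:
        raise EncodingError(path, f"index column '{index_key}' not found")
    order = group.attrs.get("column-order")
    if order is None:
        order = [k for k in group.keys() if k != index_key]
    else:
        order = [str(c) for c in _decode_attr(order)]
    columns = {}
    for col in order:
        if col not in group:
            raise EncodingError(path, f"column '{col}' listed in column-order but absent")
        values = read_element(group[col], legacy_policy=legacy_policy)
        if len(values) != group[index_key].shape[0]:
            raise ElementValidationError(
                f"{path}/{col}",
                f"column length {len(values)} != index length {group[index_key].shape[0]}",
            )
        columns[col] = values
    index = pd.Index(read_element(group[index_key], legacy_policy=legacy_policy))
    df = pd.DataFrame(columns, index=index, columns=order)
    df.index.name = None if index_key == DEFAULT_INDEX_KEY else index_key
    return df


def write_dataframe(parent: h5py.Group, key: str, df: pd.DataFrame,
                    options: WriteOptions | None = None) -> None:
    options = options or WriteOptions()
    path = f"{_path_of(parent)}/{key}".replace("//", "/")
    cols = [str(c) for c in df.columns]
    if len(set(cols)) != len(cols):
        raise EncodingError(path, "duplicate column names")
    index_key = df.index.name if df.index.name else DEFAULT_INDEX_KEY
    if index_key in cols:
        raise EncodingError(path, f"index name '{index_key}' collides with a column")
    grp = parent.create_group(key, track_order=True)
    _write_encoding_attrs(grp, "dataframe")
    grp.attrs[DEFAULT_INDEX_KEY] = index_key
    grp.attrs.create("column-order", data=np.asarray(cols, dtype=object),
                     dtype=h5py.string_dtype())
    index_values = np.asarray([str(v) for v in df.index], dtype=object)
    _write_array(grp, index_key, index_values, options)
    for col in df.columns:
        series = df[col]
        if len(series) != len(df.index):  # pragma: no cover - pandas guarantees
            raise EncodingError(f"{path}/{col}", "column length mismatch")
        _write_column(grp, str(col), series, options)


def _write_column(grp: h5py.Group, name: str, series: pd.Series, options: WriteOptions) -> None:
    dtype = series.dtype
    if isinstance(dtype, pd.CategoricalDtype):
        write_categorical(grp, name, pd.Categorical(series), options)
    elif isinstance(dtype, (pd.Int64Dtype, pd.Int32Dtype, pd.Int16Dtype, pd.Int8Dtype,
                            pd.BooleanDtype)):
        write_nullable(grp, name, series.array, options)
    else:
        _write_array(grp, name, series.to_numpy(), options)


# ---------------------------------------------------------------------------
# mappings


def read_mapping(group: h5py.Group, legacy_policy: str = "infer") -> dict:
    """Recursively decode a dict-encoded group, preserving key order as
    encountered (creation order when the file records it)."""
    return {
        key: read_element(group[key], legacy_policy=legacy_policy) for key in group.keys()
    }


def write_mapping(parent: h5py.Group, key: str, mapping: dict,
                  options: WriteOptions | None = None, _seen: frozenset = frozenset()) -> None:
    options = options or WriteOptions()
    if id(mapping) in _seen:
        raise EncodingError(key, "cycle detected in mapping")
    seen = _seen | {id(mapping)}
    grp = parent.create_group(key, track_order=True)
    _write_encoding_attrs(grp, "dict")
    for k, v in mapping.items():
        if isinstance(v, dict):
            write_mapping(grp, str(k), v, options, seen)
        else:
            write_element(grp, str(k), v, options)


# ---------------------------------------------------------------------------
# generic dispatch


def read_element(loc, legacy_policy: str = "infer"):
    """Decode any element by its encoding descriptor."""
    desc = detect_encoding(loc, legacy_policy=legacy_policy)
    t = desc.encoding_type
    if t in ("array", "string-array"):
        return read_dense(loc)
    if t == "string":
        return _read_string_scalar(loc)
    if t == "numeric-scalar":
        return _read_numeric_scalar(loc)
    if t in ("csr_matrix", "csc_matrix"):
        return read_sparse(loc).to_scipy()
    if t == "categorical":
        return read_categorical(loc)
    if t in ("nullable-integer", "nullable-boolean"):
        return read_nullable(loc)
    if t == "dataframe":
        return read_dataframe(loc, legacy_policy=legacy_policy)
    if t in ("dict", "raw"):
        return read_mapping(loc, legacy_policy=legacy_policy)
    raise EncodingError(_path_of(loc), f"no decoder for '{t}'")  # pragma: no cover


def _write_array(parent: h5py.Group, key: str, arr: np.ndarray,
                 options: WriteOptions) -> None:
    arr = np.asarray(arr)
    if arr.dtype.kind in ("U", "O", "T"):
        data = np.asarray([str(v) for v in arr.reshape(-1)], dtype=object).reshape(arr.shape)
        ds = parent.create_dataset(key, data=data, dtype=h5py.string_dtype(),
                                   **options.dataset_kwargs(arr.shape))
        _write_encoding_attrs(ds, "string-array")
    else:
        ds = parent.create_dataset(key, data=arr, **options.dataset_kwargs(arr.shape))
        _write_encoding_attrs(ds, "array")


def write_element(parent: h5py.Group, key: str, value,
                  options: WriteOptions | None = None) -> None:
    """Encode a value under ``parent[key]``, dispatching on its type."""
    options = options or WriteOptions()
    if isinstance(value, dict):
        write_mapping(parent, key, value, options)
    elif isinstance(value, pd.DataFrame):
        write_dataframe(parent, key, value, options)
    elif isinstance(value, pd.Categorical):
        write_categorical(parent, key, value, options)
    elif isinstance(value, (pd.arrays.IntegerArray, pd.arrays.BooleanArray)):
        write_nullable(parent, key, value, options)
    elif sparse.issparse(value):
        write_sparse(parent, key, value, options=options)
    elif isinstance(value, str):
        ds = parent.create_dataset(key, data=value, dtype=h5py.string_dtype())
        _write_encoding_attrs(ds, "string")
    elif isinstance(value, (bool, int, float, np.bool_, np.integer, np.floating)):
        ds = parent.create_dataset(key, data=value)
        _write_encoding_attrs(ds, "numeric-scalar")
    elif isinstance(value, np.str_):
        ds = parent.create_dataset(key, data=str(value), dtype=h5py.string_dtype())
        _write_encoding_attrs(ds, "string")
    elif isinstance(value, (np.ndarray, list, tuple, pd.Index, pd.Series)):
        _write_array(parent, key, np.asarray(value), options)
    else:
        raise EncodingError(key, f"no encoder for values of type {type(value).__name__}")
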