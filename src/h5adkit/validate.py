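"""Conformance validation of H5AD files.

Walks every element of a file and checks the structural rules of the
on-disk format: encoding attributes present and recognised, sparse
triples internally consistent, categorical codes in range, nullable
masks aligned, dataframe columns aligned with their index, and the
root-level axis dimensions mutually consistent.  Violations are
collected (never raised) so one pass reports every problem, each
addressed by its path and a stable rule id.  The file is never mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from . import codec

__all__ = ["Violation", "ValidationReport", "validate_file"]


@dataclass(frozen=True)
class Violation:
    path: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def conformant(self) -> bool:
        return not self.violations

    def add(self, path: str, rule: str, message: str) -> None:
        self.violations.append(Violation(path or "/", rule, message))


_STRUCTURAL = {"dict", "dataframe", "raw", "anndata"}
_ROOT_SLOTS = ("X", "layers", "obs", "var", "obsm", "varm", "obsp", "varp", "uns", "raw")


def _encoding_of(loc, report: ValidationReport) -> str | None:
    path = loc.name or "/"
    enc = loc.attrs.get("encoding-type")
    if enc is None:
        report.add(path, "missing-encoding-attr", "no encoding-type attribute")
        return codec._infer_encoding(loc)
    enc = codec._decode_attr(enc)
    if enc not in codec.ENCODING_REGISTRY:
        report.add(path, "unknown-encoding", f"unknown encoding-type '{enc}'")
        return None
    version = loc.attrs.get("encoding-version")
    if version is not None and not codec._VERSION_RE.match(codec._decode_attr(version)):
        report.add(path, "bad-version",
                   f"encoding-version '{codec._decode_attr(version)}' is not dotted numerals")
    return enc


def _check_sparse(grp: h5py.Group, enc: str, report: ValidationReport) -> None:
    path = grp.name
    missing = [n for n in ("data", "indices", "indptr") if n not in grp]
    if missing:
        report.add(path, "sparse-structure", f"missing datasets: {missing}")
        return
    shape_attr = grp.attrs.get("shape", grp.attrs.get("h5sparse_shape"))
    if shape_attr is None:
        report.add(path, "missing-shape-attr", "sparse group has no 'shape' attribute")
        return
    shape = tuple(int(n) for n in np.asarray(shape_attr))
    indptr = np.asarray(grp["indptr"][()])
    nnz = grp["data"].shape[0]
    major = shape[0] if enc == "csr_matrix" else shape[1]
    minor = shape[1] if enc == "csr_matrix" else shape[0]
    if len(indptr) != major + 1:
        report.add(path, "indptr-length",
                   f"indptr length {len(indptr)} != major dimension + 1 = {major + 1}")
        return
    if len(indptr) and indptr[0] != 0:
        report.add(path, "indptr-values", "indptr does not start at 0")
    if np.any(np.diff(indptr) < 0):
        report.add(path, "indptr-values", "indptr is not non-decreasing")
    if grp["indices"].shape[0] != nnz:
        report.add(path, "sparse-structure",
                   f"indices length {grp['indices'].shape[0]} != data length {nnz}")
    if len(indptr) and indptr[-1] != nnz:
        report.add(path, "indptr-values", f"indptr[-1] = {indptr[-1]} != nnz = {nnz}")
    indices = np.asarray(grp["indices"][()])
    if indices.size and (indices.min() < 0 or indices.max() >= minor):
        report.add(path, "index-range",
                   f"index out of range for minor dimension {minor}")


def _check_categorical(grp: h5py.Group, report: ValidationReport) -> None:
    path = grp.name
    missing = [n for n in ("codes", "categories") if n not in grp]
    if missing:
        report.add(path, "categorical-structure", f"missing datasets: {missing}")
        return
    codes = np.asarray(grp["codes"][()])
    n_cat = grp["categories"].shape[0]
    if codes.size and (codes.min() < -1 or codes.max() >= n_cat):
        report.add(path, "code-range",
                   f"categorical code out of range for {n_cat} categories")
    cats = codec.read_dense(grp["categories"]).tolist()
    if len(cats) != len(set(map(str, cats))):
        report.add(path, "duplicate-categories", "categories contain duplicates")


def _check_nullable(grp: h5py.Group, report: ValidationReport) -> None:
    path = grp.name
    missing = [n for n in ("values", "mask") if n not in grp]
    if missing:
        report.add(path, "nullable-structure", f"missing datasets: {missing}")
        return
    nv, nm = grp["values"].shape[0], grp["mask"].shape[0]
    if nv != nm:
        report.add(path, "mask-length", f"values length {nv} != mask length {nm}")


def _element_length(loc) -> int | None:
    """First-dimension length of an element, for alignment checks."""
    if isinstance(loc, h5py.Dataset):
        return loc.shape[0] if loc.shape else None
    enc = loc.attrs.get("encoding-type")
    enc = codec._decode_attr(enc) if enc is not None else codec._infer_encoding(loc)
    if enc in ("csr_matrix", "csc_matrix"):
        shape = loc.attrs.get("shape", loc.attrs.get("h5sparse_shape"))
        return int(np.asarray(shape)[0]) if shape is not None else None
    if enc == "categorical" and "codes" in loc:
        return loc["codes"].shape[0]
    if enc in ("nullable-integer", "nullable-boolean") and "values" in loc:
        return loc["values"].shape[0]
    if enc == "dataframe":
        index_key = codec._decode_attr(loc.attrs.get(codec.DEFAULT_INDEX_KEY, "_index"))
        return loc[index_key].shape[0] if index_key in loc else None
    return None


def _check_dataframe(grp: h5py.Group, report: ValidationReport) -> None:
    path = grp.name
    index_key = codec._decode_attr(grp.attrs.get(codec.DEFAULT_INDEX_KEY))
    if index_key is None:
        report.add(path, "dataframe-structure", "missing '_index' attribute")
        return
    if index_key not in grp:
        report.add(path, "dataframe-structure", f"index column '{index_key}' absent")
        return
    n = grp[index_key].shape[0]
    order = grp.attrs.get("column-order")
    if order is None:
        report.add(path, "missing-column-order", "no 'column-order' attribute")
        columns = [k for k in grp.keys() if k != index_key]
    else:
        columns = [str(c) for c in codec._decode_attr(order)]
    for col in columns:
        if col not in grp:
            report.add(path, "dataframe-structure",
                       f"column '{col}' listed in column-order but absent")
            continue
        length = _element_length(grp[col])
        if length is not None and length != n:
            report.add(f"{path}/{col}", "column-length",
                       f"column length {length} != index length {n}")
        _walk(grp[col], report)


def _walk(loc, report: ValidationReport) -> None:
    enc = _encoding_of(loc, report)
    if enc is None:
        return
    if enc in ("csr_matrix", "csc_matrix"):
        _check_sparse(loc, enc, report)
    elif enc == "categorical":
        _check_categorical(loc, report)
    elif enc in ("nullable-integer", "nullable-boolean"):
        _check_nullable(loc, report)
    elif enc == "dataframe":
        _check_dataframe(loc, report)
    elif enc in ("dict", "raw", "anndata"):
        for key in loc.keys():
            _walk(loc[key], report)
    elif enc in ("string", "numeric-scalar"):
        if loc.shape != ():
            report.add(loc.name, "scalar-shape",
                       f"scalar encoding on dataset of shape {loc.shape}")


def _shape_2d(loc) -> tuple | None:
    if isinstance(loc, h5py.Dataset):
        return loc.shape if len(loc.shape) == 2 else None
    shape = loc.attrs.get("shape", loc.attrs.get("h5sparse_shape"))
    if shape is not None:
        return tuple(int(n) for n in np.asarray(shape))
    return None


def _check_root_dims(f: h5py.File, report: ValidationReport) -> None:
    def axis_len(df_path):
        if df_path not in f:
            return None
        return _element_length(f[df_path])

    n_obs, n_var = axis_len("obs"), axis_len("var")
    if n_obs is None or n_var is None:
        return

    def expect(path, want, axes: str):
        if path not in f:
            return
        got = _shape_2d(f[path]) if len(axes) == 2 else (_element_length(f[path]),)
        want_t = want if len(axes) == 2 else (want[0],)
        if got is not None and None not in got and tuple(got) != tuple(want_t):
            report.add(f[path].name, "axis-dims",
                       f"expected {'shape' if len(axes) == 2 else 'first dimension'} "
                       f"{want_t}, got {tuple(got)}")

    expect("X", (n_obs, n_var), "ov")
    for slot, dims in (("layers", (n_obs, n_var)), ("obsp", (n_obs, n_obs)),
                       ("varp", (n_var, n_var))):
        if slot in f:
            for key in f[slot].keys():
                expect(f"{slot}/{key}", dims, "xy")
    for slot, n in (("obsm", n_obs), ("varm", n_var)):
        if slot in f:
            for key in f[slot].keys():
                expect(f"{slot}/{key}", (n,), "o")
    if "raw" in f:
        n_var_raw = axis_len("raw/var")
        if n_var_raw is not None:
            expect("raw/X", (n_obs, n_var_raw), "ov")
            if "raw/varm" in f:
                for key in f["raw/varm"].keys():
                    expect(f"raw/varm/{key}", (n_var_raw,), "o")


def validate_file(path) -> ValidationReport:
    """Check one file against every structural rule of the format.

    Returns a report; raises ``OSError`` only when the file itself is
    unreadable (that is an error, not a violation).
    """
    report = ValidationReport()
    with h5py.File(path, "r") as f:
        for slot in ("obs", "var"):
            if slot not in f:
                report.add("/", "root-layout", f"required root group '{slot}' is missing")
        for child in f.keys():
            if child in _ROOT_SLOTS:
                _walk(f[child], report)
        _check_root_dims(f, report)
    return report
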