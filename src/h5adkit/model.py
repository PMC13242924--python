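"""In-memory annotated-data container and its file-backed counterpart.

The container follows the AnnData layout: a central observations ×
variables matrix ``X`` plus aligned slots —

* ``layers``: alternative matrices of the same shape as ``X``
* ``obs`` / ``var``: per-observation / per-variable metadata tables
* ``obsm`` / ``varm``: multidimensional annotations whose first axis is
  the obs (resp. var) axis, e.g. embeddings and loadings
* ``obsp`` / ``varp``: square pairwise matrices over each axis
* ``uns``: arbitrarily nested unstructured metadata
* ``raw``: an optional pre-filtering snapshot sharing observations but
  possibly carrying a different (usually larger) feature set

All shape invariants are enforced by :meth:`AnnDataContainer.validate`,
which is also run whenever a slot is replaced.  The container has
reference semantics: every handle to it sees mutations made through any
other handle (plain Python object identity; no copy-on-access).
"""

from __future__ import annotations

import copy as _copy
import os
from collections.abc import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ContainerValidationError, EncodingError

__all__ = ["AnnDataContainer", "Raw", "BackedH5AD"]


def _default_index(n: int) -> pd.Index:
    return pd.Index([str(i) for i in range(n)])


def _shape_of(m) -> tuple:
    return tuple(m.shape)


class Raw:
    """Pre-filtering snapshot: matrix + feature table (+ feature
    annotations), sharing the parent's observations."""

    def __init__(self, X, var: pd.DataFrame, varm: dict | None = None):
        self.X = X
        self.var = var
        self.varm = dict(varm or {})

    @property
    def n_var(self) -> int:
        return len(self.var)

    def copy(self) -> "Raw":
        return Raw(_copy_matrix(self.X), self.var.copy(deep=True),
                   {k: _copy_matrix(v) for k, v in self.varm.items()})


def _copy_matrix(m):
    if m is None:
        return None
    if sparse.issparse(m):
        return m.copy()
    if isinstance(m, (pd.DataFrame, pd.Series, pd.Categorical)):
        return m.copy()
    if isinstance(m, np.ndarray):
        return m.copy()
    return _copy.deepcopy(m)


class AnnDataContainer:
    """Annotated observations × variables data matrix with aligned slots.

    Parameters default to empty collections; ``obs``/``var`` default to
    empty tables whose index provides ``obs_names``/``var_names`` (they
    are the same data, not copies).  Dimension checks run on
    construction and again on every slot replacement.
    """

    _SLOTS = ("X", "layers", "obs", "var", "obsm", "varm", "obsp", "varp", "uns", "raw")

    def __init__(self, X=None, obs: pd.DataFrame | None = None,
                 var: pd.DataFrame | None = None, *, layers=None, obsm=None,
                 varm=None, obsp=None, varp=None, uns=None, raw=None, shape=None):
        if obs is None:
            n_obs = (shape[0] if shape is not None
                     else (X.shape[0] if X is not None else 0))
            obs = pd.DataFrame(index=_default_index(n_obs))
        if var is None:
            n_var = (shape[1] if shape is not None
                     else (X.shape[1] if X is not None else 0))
            var = pd.DataFrame(index=_default_index(n_var))
        self._obs = obs
        self._var = var
        self._X = X
        self._layers = dict(layers or {})
        self._obsm = dict(obsm or {})
        self._varm = dict(varm or {})
        self._obsp = dict(obsp or {})
        self._varp = dict(varp or {})
        self._uns = dict(uns or {})
        self._raw = raw
        self.validate()

    # -- dimensions ---------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self._obs)

    @property
    def n_var(self) -> int:
        return len(self._var)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_obs, self.n_var)

    @property
    def obs_names(self) -> pd.Index:
        return self._obs.index

    @obs_names.setter
    def obs_names(self, names) -> None:
        if len(names) != self.n_obs:
            raise ContainerValidationError(
                "obs_names", f"expected {self.n_obs} names, got {len(names)}")
        self._obs.index = pd.Index([str(n) for n in names])

    @property
    def var_names(self) -> pd.Index:
        return self._var.index

    @var_names.setter
    def var_names(self, names) -> None:
        if len(names) != self.n_var:
            raise ContainerValidationError(
                "var_names", f"expected {self.n_var} names, got {len(names)}")
        self._var.index = pd.Index([str(n) for n in names])

    # -- slots (replacement re-validates immediately) -----------------------

    def _set(self, attr: str, value) -> None:
        old = getattr(self, attr)
        setattr(self, attr, value)
        try:
            self.validate()
        except ContainerValidationError:
            setattr(self, attr, old)
            raise

    X = property(lambda self: self._X,
                 lambda self, v: self._set("_X", v))
    obs = property(lambda self: self._obs,
                   lambda self, v: self._set("_obs", v))
    var = property(lambda self: self._var,
                   lambda self, v: self._set("_var", v))
    layers = property(lambda self: self._layers,
                      lambda self, v: self._set("_layers", dict(v)))
    obsm = property(lambda self: self._obsm,
                    lambda self, v: self._set("_obsm", dict(v)))
    varm = property(lambda self: self._varm,
                    lambda self, v: self._set("_varm", dict(v)))
    obsp = property(lambda self: self._obsp,
                    lambda self, v: self._set("_obsp", dict(v)))
    varp = property(lambda self: self._varp,
                    lambda self, v: self._set("_varp", dict(v)))
    uns = property(lambda self: self._uns,
                   lambda self, v: self._set("_uns", dict(v)))
    raw = property(lambda self: self._raw,
                   lambda self, v: self._set("_raw", v))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Assert every dimension constraint; raises naming the first
        violated slot with expected and actual dimensions."""
        n_obs, n_var = self.n_obs, self.n_var
        if not isinstance(self._obs, pd.DataFrame):
            raise ContainerValidationError("obs", "must be a DataFrame")
        if not isinstance(self._var, pd.DataFrame):
            raise ContainerValidationError("var", "must be a DataFrame")
        if self._X is not None:
            if len(self._X.shape) != 2 or _shape_of(self._X) != (n_obs, n_var):
                raise ContainerValidationError(
                    "X", f"expected shape {(n_obs, n_var)}, got {_shape_of(self._X)}")
        for name, m in self._layers.items():
            if _shape_of(m) != (n_obs, n_var):
                raise ContainerValidationError(
                    "layers", f"'{name}' expected shape {(n_obs, n_var)}, got {_shape_of(m)}")
        for slot, coll, dim in (("obsm", self._obsm, n_obs), ("varm", self._varm, n_var)):
            for name, m in coll.items():
                if len(m.shape) < 1 or m.shape[0] != dim:
                    raise ContainerValidationError(
                        slot, f"'{name}' expected first dimension {dim}, got {_shape_of(m)}")
        for slot, coll, dim in (("obsp", self._obsp, n_obs), ("varp", self._varp, n_var)):
            for name, m in coll.items():
                if _shape_of(m) != (dim, dim):
                    raise ContainerValidationError(
                        slot, f"'{name}' expected shape {(dim, dim)}, got {_shape_of(m)}")
        if not isinstance(self._uns, dict):
            raise ContainerValidationError("uns", "must be a dict")
        if self._raw is not None:
            r = self._raw
            n_var_raw = r.n_var
            if r.X is not None and _shape_of(r.X) != (n_obs, n_var_raw):
                raise ContainerValidationError(
                    "raw", f"raw.X expected shape {(n_obs, n_var_raw)}, got {_shape_of(r.X)}")
            for name, m in r.varm.items():
                if m.shape[0] != n_var_raw:
                    raise ContainerValidationError(
                        "raw", f"raw.varm '{name}' expected first dimension {n_var_raw}, "
                               f"got {_shape_of(m)}")

    # -- subsetting ---------------------------------------------------------

    def _resolve(self, selector, names: pd.Index, axis: str) -> np.ndarray:
        if selector is None:
            return np.arange(len(names))
        if isinstance(selector, slice):
            return np.arange(len(names))[selector]
        sel = list(selector)
        if len(sel) == 0:
            return np.array([], dtype=int)
        if all(isinstance(s, (bool, np.bool_)) for s in sel):
            mask = np.asarray(sel, dtype=bool)
            if len(mask) != len(names):
                raise ContainerValidationError(
                    axis, f"boolean selector length {len(mask)} != axis length {len(names)}")
            return np.flatnonzero(mask)
        if all(isinstance(s, (int, np.integer)) for s in sel):
            idx = np.asarray(sel, dtype=int)
            if idx.size and (idx.min() < -len(names) or idx.max() >= len(names)):
                raise ContainerValidationError(axis, f"index out of range for {len(names)}")
            return idx % len(names) if idx.size else idx
        # name-based selection
        locs = []
        for s in sel:
            hit = np.flatnonzero(names == s)
            if hit.size == 0:
                raise ContainerValidationError(axis, f"unknown name '{s}'")
            locs.extend(hit.tolist())
        return np.asarray(locs, dtype=int)

    def subset(self, obs_selector=None, var_selector=None) -> "AnnDataContainer":
        """Slice every slot consistently along the obs and var axes.

        Selectors may be ``None`` (keep all), slices, integer sequences,
        boolean masks, or name sequences resolved against
        ``obs_names``/``var_names``.  ``uns`` passes through unchanged;
        ``raw`` is sliced on the obs axis only (it keeps its own
        features).  The result is a new, validated container.
        """
        oi = self._resolve(obs_selector, self.obs_names, "obs")
        vi = self._resolve(var_selector, self.var_names, "var")

        def mat(m, rows, cols=None):
            if m is None:
                return None
            if isinstance(m, pd.DataFrame):
                return m.iloc[rows].copy()
            out = m[rows]
            if cols is not None:
                out = out[:, cols]
            return out.copy() if hasattr(out, "copy") else out

        raw = None
        if self._raw is not None:
            raw = Raw(mat(self._raw.X, oi), self._raw.var, dict(self._raw.varm))
        return AnnDataContainer(
            X=mat(self._X, oi, vi),
            obs=self._obs.iloc[oi].copy(),
            var=self._var.iloc[vi].copy(),
            layers={k: mat(m, oi, vi) for k, m in self._layers.items()},
            obsm={k: mat(m, oi) for k, m in self._obsm.items()},
            varm={k: mat(m, vi) for k, m in self._varm.items()},
            obsp={k: mat(m, oi, oi) for k, m in self._obsp.items()},
            varp={k: mat(m, vi, vi) for k, m in self._varp.items()},
            uns=self._uns,
            raw=raw,
        )

    def __getitem__(self, key):
        if isinstance(key, tuple):
            obs_sel, var_sel = key
        else:
            obs_sel, var_sel = key, None
        return self.subset(obs_sel, var_sel)

    def copy(self) -> "AnnDataContainer":
        return AnnDataContainer(
            X=_copy_matrix(self._X),
            obs=self._obs.copy(deep=True),
            var=self._var.copy(deep=True),
            layers={k: _copy_matrix(m) for k, m in self._layers.items()},
            obsm={k: _copy_matrix(m) for k, m in self._obsm.items()},
            varm={k: _copy_matrix(m) for k, m in self._varm.items()},
            obsp={k: _copy_matrix(m) for k, m in self._obsp.items()},
            varp={k: _copy_matrix(m) for k, m in self._varp.items()},
            uns=_copy.deepcopy(self._uns),
            raw=self._raw.copy() if self._raw is not None else None,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"AnnDataContainer n_obs × n_var = {self.n_obs} × {self.n_var}"]
        for slot in ("layers", "obsm", "varm", "obsp", "varp", "uns"):
            keys = list(getattr(self, slot))
            if keys:
                parts.append(f"    {slot}: {', '.join(map(repr, keys))}")
        if self._raw is not None:
            parts.append(f"    raw: {self._raw.n_var} features")
        return "\n".join(parts)


class BackedH5AD:
    """Read-only, lazily materialised view of an H5AD file.

    Metadata slots (``obs``, ``var``, ``uns`` and the axis names) are
    decoded eagerly at construction without touching any matrix
    dataset; matrix slots stay on disk until requested through
    :meth:`slot` or :meth:`to_memory`.  Every matrix materialisation is
    appended to :attr:`matrix_reads`, which doubles as the laziness
    instrumentation used by the test-suite.
    """

    MATRIX_SLOTS = ("X", "layers", "obsm", "varm", "obsp", "varp", "raw")

    def __init__(self, path, legacy_policy: str = "infer"):
        from . import codec

        self.path = str(path)
        self.mode = "r"
        self.legacy_policy = legacy_policy
        self.matrix_reads: list[str] = []
        self._cache: dict[str, object] = {}
        with h5py.File(self.path, "r") as f:
            if "obs" not in f or "var" not in f:
                raise EncodingError(
                    "/", f"'{self.path}' lacks the obs/var groups of an AnnData root layout")
            self.obs = codec.read_dataframe(f["obs"], legacy_policy)
            self.var = codec.read_dataframe(f["var"], legacy_policy)
            self.uns = codec.read_mapping(f["uns"], legacy_policy) if "uns" in f else {}
            self._present = [s for s in self.MATRIX_SLOTS if s in f]

    @property
    def obs_names(self) -> pd.Index:
        return self.obs.index

    @property
    def var_names(self) -> pd.Index:
        return self.var.index

    @property
    def loaded(self) -> Sequence[str]:
        return ("obs", "var", "uns")

    @property
    def pending(self) -> Sequence[str]:
        return tuple(s for s in self._present if s not in self._cache)

    def _open(self) -> h5py.File:
        try:
            return h5py.File(self.path, "r")
        except (FileNotFoundError, OSError) as exc:
            raise FileNotFoundError(
                f"backing file '{self.path}' is no longer readable") from exc

    def slot(self, name: str):
        """Materialise one matrix slot (logged in :attr:`matrix_reads`)."""
        from . import codec, io

        if name not in self.MATRIX_SLOTS:
            raise KeyError(name)
        if name in self._cache:
            return self._cache[name]
        if name not in self._present:
            value = None if name in ("X", "raw") else {}
            self._cache[name] = value
            return value
        self.matrix_reads.append(name)
        with self._open() as f:
            if name == "X":
                value = codec.read_element(f["X"], self.legacy_policy)
            elif name == "raw":
                value = io._read_raw(f["raw"], self.legacy_policy)
            else:
                value = codec.read_mapping(f[name], self.legacy_policy)
        self._cache[name] = value
        return value

    @property
    def X(self):
        return self.slot("X")

    def to_memory(self) -> AnnDataContainer:
        """Materialise everything; deep-equal to a direct in-memory read
        of the same file."""
        from . import io

        if not os.path.exists(self.path):
            raise FileNotFoundError(f"backing file '{self.path}' has been deleted or moved")
        self.matrix_reads.append("<all>")
        return io.read_h5ad(self.path, mode="memory", legacy_policy=self.legacy_policy)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"BackedH5AD('{self.path}', {len(self.obs)} obs × {len(self.var)} var, "
                f"pending={list(self.pending)})")
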