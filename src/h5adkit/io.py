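"""Whole-file H5AD assembly: read a file into a container (in memory or
backed), write a container to a new file.

The root layout follows the AnnData on-disk specification: recognised
root groups are ``X``, ``layers``, ``obs``, ``var``, ``obsm``, ``varm``,
``obsp``, ``varp``, ``uns`` and ``raw``.  Unrecognised root children are
decoded anyway, surfaced with a warning and retained under a reserved
key inside ``uns`` so no data is silently dropped.

Writing is atomic at file granularity: the file is assembled under a
temporary name in the target directory and moved into place only on
success, so a failed write leaves no partial file behind.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import h5py
import numpy as np

from . import codec
from .codec import WriteOptions
from .errors import EncodingError
from .model import AnnDataContainer, BackedH5AD, Raw

__all__ = ["read_h5ad", "write_h5ad", "ReadOptions", "ORPHAN_UNS_KEY"]

#: uns key under which unrecognised root children are stashed on read.
ORPHAN_UNS_KEY = ".orphans"

_ROOT_SLOTS = ("X", "layers", "obs", "var", "obsm", "varm", "obsp", "varp", "uns", "raw")
_DICT_SLOTS = ("layers", "obsm", "varm", "obsp", "varp", "uns")


@dataclass
class ReadOptions:
    """How :func:`read_h5ad` interprets a file.

    mode:
        ``"memory"`` decodes everything eagerly; ``"backed"`` returns a
        :class:`~h5adkit.model.BackedH5AD` that defers matrix slots.
    legacy_policy:
        ``"infer"`` or ``"error"`` — handling of elements lacking
        encoding attributes (see :mod:`h5adkit.codec`).
    include:
        Optional whitelist of matrix slot names; ``obs``/``var`` are
        always read.
    """

    mode: str = "memory"
    legacy_policy: str = "infer"
    include: tuple | None = None

    def __post_init__(self):
        if self.mode not in ("memory", "backed"):
            raise ValueError(f"mode must be 'memory' or 'backed', got '{self.mode}'")


def _read_raw(group: h5py.Group, legacy_policy: str) -> Raw:
    X = codec.read_element(group["X"], legacy_policy) if "X" in group else None
    var = codec.read_dataframe(group["var"], legacy_policy)
    varm = codec.read_mapping(group["varm"], legacy_policy) if "varm" in group else {}
    return Raw(X=X, var=var, varm=varm)


def read_h5ad(path, mode: str = "memory", legacy_policy: str = "infer",
              include=None, options: ReadOptions | None = None):
    """Read an H5AD file.

    Returns an :class:`AnnDataContainer` in ``"memory"`` mode or a
    :class:`BackedH5AD` in ``"backed"`` mode.  The decoded container
    always passes :meth:`~AnnDataContainer.validate`.
    """
    opts = options or ReadOptions(mode=mode, legacy_policy=legacy_policy,
                                  include=tuple(include) if include else None)
    if opts.mode == "backed":
        return BackedH5AD(path, legacy_policy=opts.legacy_policy)

    def wanted(slot: str) -> bool:
        return opts.include is None or slot in opts.include

    with h5py.File(path, "r") as f:
        if "obs" not in f or "var" not in f:
            raise EncodingError("/", f"'{path}' lacks the obs/var groups of an "
                                     "AnnData root layout")
        slots: dict = {}
        slots["obs"] = codec.read_dataframe(f["obs"], opts.legacy_policy)
        slots["var"] = codec.read_dataframe(f["var"], opts.legacy_policy)
        if "X" in f and wanted("X"):
            slots["X"] = codec.read_element(f["X"], opts.legacy_policy)
        for slot in _DICT_SLOTS:
            if slot in f and wanted(slot):
                slots[slot] = codec.read_mapping(f[slot], opts.legacy_policy)
        if "raw" in f and wanted("raw"):
            slots["raw"] = _read_raw(f["raw"], opts.legacy_policy)
        orphans = {}
        for child in f.keys():
            if child not in _ROOT_SLOTS:
                warnings.warn(f"unrecognised root element '/{child}' retained under "
                              f"uns['{ORPHAN_UNS_KEY}']", stacklevel=2)
                orphans[child] = codec.read_element(f[child], opts.legacy_policy)
        if orphans:
            slots.setdefault("uns", {})[ORPHAN_UNS_KEY] = orphans
    return AnnDataContainer(**slots)


def write_h5ad(adata: AnnDataContainer, path, *, overwrite: bool = False,
               options: WriteOptions | None = None) -> None:
    """Write a container to a new H5AD file.

    The container is validated before any byte is written; an existing
    file at ``path`` is refused unless ``overwrite=True``.  ``X`` keeps
    its in-memory representation (sparse stays sparse in its
    orientation, dense stays dense); ``raw`` is written only when
    present.
    """
    adata.validate()
    path = str(path)
    options = options or WriteOptions()
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"'{path}' exists; pass overwrite=True to replace it")
    tmp = f"{path}.tmp-{os.getpid()}"
    try:
        with h5py.File(tmp, "w", track_order=True) as f:
            f.attrs["encoding-type"] = "anndata"
            f.attrs["encoding-version"] = codec.ENCODING_REGISTRY["anndata"]
            if adata.X is not None:
                codec.write_element(f, "X", adata.X, options)
            codec.write_dataframe(f, "obs", adata.obs, options)
            codec.write_dataframe(f, "var", adata.var, options)
            for slot in _DICT_SLOTS:
                codec.write_mapping(f, slot, getattr(adata, slot), options)
            if adata.raw is not None:
                grp = f.create_group("raw", track_order=True)
                grp.attrs["encoding-type"] = "raw"
                grp.attrs["encoding-version"] = codec.ENCODING_REGISTRY["raw"]
                if adata.raw.X is not None:
                    codec.write_element(grp, "X", adata.raw.X, options)
                codec.write_dataframe(grp, "var", adata.raw.var, options)
                codec.write_mapping(grp, "varm", adata.raw.varm, options)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise
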