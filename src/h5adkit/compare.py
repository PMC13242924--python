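"""Deep equality for decoded values and containers.

Comparison is *logical*: a matrix compares by its values (plus its
representation — dense vs CSR vs CSC — which round-trips must
preserve), tables by column order, names, values and categorical
structure, mappings recursively with key order.  Floating-point NaN
compares equal to NaN (no arithmetic happens in the codec, so
round-trips are bit-exact and an absolute tolerance of 0 is the
default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["values_equal", "value_diff", "container_diff", "containers_equal"]


def _matrix_repr(m) -> str:
    if sparse.issparse(m):
        return m.format
    return "dense"


def _array_diff(a: np.ndarray, b: np.ndarray, atol: float) -> str | None:
    if a.shape != b.shape:
        return f"shape {a.shape} != {b.shape}"
    if a.size == 0:
        return None
    if a.dtype.kind in ("U", "O", "S", "T") or b.dtype.kind in ("U", "O", "S", "T"):
        av = np.asarray([str(x) for x in np.asarray(a).reshape(-1)])
        bv = np.asarray([str(x) for x in np.asarray(b).reshape(-1)])
        if not np.array_equal(av, bv):
            return "string values differ"
        return None
    a = np.asarray(a)
    b = np.asarray(b)
    if a.dtype.kind == "f" or b.dtype.kind == "f":
        af, bf = a.astype(float), b.astype(float)
        both_nan = np.isnan(af) & np.isnan(bf)
        close = np.abs(af - bf) <= atol if atol else af == bf
        if not np.all(both_nan | close):
            return "numeric values differ"
        return None
    if not np.array_equal(a, b):
        return "values differ"
    return None


def value_diff(a, b, atol: float = 0.0, ignore_key_order: bool = False) -> str | None:
    """Return a human-readable reason the two values differ, or None.

    ``ignore_key_order`` relaxes mapping comparison to set-of-keys
    semantics, for cross-implementation checks against writers that do
    not record creation order.
    """
    if a is None or b is None:
        return None if a is b else "one side is missing"
    if sparse.issparse(a) or sparse.issparse(b):
        if not (sparse.issparse(a) and sparse.issparse(b)):
            return f"representation {_matrix_repr(a)} != {_matrix_repr(b)}"
        if a.format != b.format:
            return f"sparse format {a.format} != {b.format}"
        return _array_diff(np.asarray(a.todense()), np.asarray(b.todense()), atol)
    if isinstance(a, pd.DataFrame) or isinstance(b, pd.DataFrame):
        if not (isinstance(a, pd.DataFrame) and isinstance(b, pd.DataFrame)):
            return "type mismatch (dataframe vs other)"
        return _frame_diff(a, b, atol)
    if isinstance(a, pd.Categorical) or isinstance(b, pd.Categorical):
        if not (isinstance(a, pd.Categorical) and isinstance(b, pd.Categorical)):
            return "type mismatch (categorical vs other)"
        if list(a.categories) != list(b.categories):
            return "categories differ"
        if bool(a.ordered) != bool(b.ordered):
            return "ordered flag differs"
        if not np.array_equal(np.asarray(a.codes), np.asarray(b.codes)):
            return "codes differ"
        return None
    if isinstance(a, (pd.arrays.IntegerArray, pd.arrays.BooleanArray)) or isinstance(
            b, (pd.arrays.IntegerArray, pd.arrays.BooleanArray)):
        try:
            a_arr, b_arr = pd.array(a), pd.array(b)
        except (TypeError, ValueError):
            return "type mismatch (nullable vs other)"
        if len(a_arr) != len(b_arr):
            return f"length {len(a_arr)} != {len(b_arr)}"
        am, bm = a_arr.isna(), b_arr.isna()
        if not np.array_equal(np.asarray(am), np.asarray(bm)):
            return "missingness masks differ"
        if len(a_arr) and not (a_arr[~am] == b_arr[~bm]).all():
            return "unmasked values differ"
        return None
    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)):
            return "type mismatch (mapping vs other)"
        keys_a, keys_b = list(map(str, a)), list(map(str, b))
        if ignore_key_order:
            keys_a, keys_b = sorted(keys_a), sorted(keys_b)
        if keys_a != keys_b:
            return f"keys {keys_a} != {keys_b}"
        for k in a:
            reason = value_diff(a[k], b[k], atol, ignore_key_order)
            if reason:
                return f"[{k}] {reason}"
        return None
    if isinstance(a, np.ndarray) or isinstance(b, np.ndarray):
        return _array_diff(np.asarray(a), np.asarray(b), atol)
    if isinstance(a, str) or isinstance(b, str):
        return None if str(a) == str(b) else "strings differ"
    if isinstance(a, float) or isinstance(b, float):
        af, bf = float(a), float(b)
        if np.isnan(af) and np.isnan(bf):
            return None
        return None if abs(af - bf) <= atol else "scalars differ"
    return None if a == b else f"scalars differ ({a!r} != {b!r})"


def _frame_diff(a: pd.DataFrame, b: pd.DataFrame, atol: float) -> str | None:
    if list(map(str, a.columns)) != list(map(str, b.columns)):
        return f"column order {list(a.columns)} != {list(b.columns)}"
    if list(map(str, a.index)) != list(map(str, b.index)):
        return "row index differs"
    if (a.index.name or None) != (b.index.name or None):
        return f"index name {a.index.name!r} != {b.index.name!r}"
    for col in a.columns:
        sa, sb = a[col], b[col]
        if isinstance(sa.dtype, pd.CategoricalDtype) or isinstance(
                sb.dtype, pd.CategoricalDtype):
            reason = value_diff(pd.Categorical(sa), pd.Categorical(sb), atol)
        elif isinstance(sa.array, (pd.arrays.IntegerArray, pd.arrays.BooleanArray)) or \
                isinstance(sb.array, (pd.arrays.IntegerArray, pd.arrays.BooleanArray)):
            reason = value_diff(sa.array, sb.array, atol)
        else:
            reason = _array_diff(sa.to_numpy(), sb.to_numpy(), atol)
        if reason:
            return f"column '{col}': {reason}"
    return None


def values_equal(a, b, atol: float = 0.0) -> bool:
    return value_diff(a, b, atol) is None


def container_diff(a, b, atol: float = 0.0, ignore_key_order: bool = False) -> list[str]:
    """Slot-by-slot comparison of two containers; returns a list of
    mismatch descriptions (empty when deep-equal)."""
    problems: list[str] = []

    def check(path, reason):
        if reason:
            problems.append(f"{path}: {reason}")

    check("X", value_diff(a.X, b.X, atol, ignore_key_order))
    check("obs", value_diff(a.obs, b.obs, atol, ignore_key_order))
    check("var", value_diff(a.var, b.var, atol, ignore_key_order))
    for slot in ("layers", "obsm", "varm", "obsp", "varp"):
        da, db = getattr(a, slot), getattr(b, slot)
        keys_a, keys_b = list(da), list(db)
        if ignore_key_order:
            keys_a, keys_b = sorted(keys_a), sorted(keys_b)
        if keys_a != keys_b:
            check(slot, f"keys {keys_a} != {keys_b}")
            continue
        for k in da:
            check(f"{slot}/{k}", value_diff(da[k], db[k], atol, ignore_key_order))
    check("uns", value_diff(a.uns, b.uns, atol, ignore_key_order))
    if (a.raw is None) != (b.raw is None):
        check("raw", "present on one side only")
    elif a.raw is not None:
        check("raw/X", value_diff(a.raw.X, b.raw.X, atol, ignore_key_order))
        check("raw/var", value_diff(a.raw.var, b.raw.var, atol, ignore_key_order))
        check("raw/varm", value_diff(a.raw.varm, b.raw.varm, atol, ignore_key_order))
    return problems


def containers_equal(a, b, atol: float = 0.0) -> bool:
    return not container_diff(a, b, atol)
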