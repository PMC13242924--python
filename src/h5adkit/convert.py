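"""Slot-mapped conversion between the AnnData container and the two R
single-cell layouts, SingleCellExperiment (SCE) and Seurat v5.

The layouts differ structurally and in matrix orientation: AnnData is
observation-by-feature (cells as rows), while SCE and Seurat are
feature-by-cell.  Every matrix slot is therefore transposed on the way
over and transposed back on the way home.  The default slot mapping is

======== ==============  ===================
AnnData  SCE             Seurat v5
======== ==============  ===================
X,layers assays          layers
raw      altExp          (no slot — stashed)
obs      colData         cell-level metadata
var      rowData         feature-level metadata
obsm     reducedDims     reductions
varm     reducedDims     reductions (loadings)
obsp     colPairs        graphs
varp     rowPairs        (no slot — stashed)
uns      metadata        misc
======== ==============  ===================

Seurat has no slot for ``varp`` (pairwise feature annotations) or for a
``raw`` matrix with a different feature set; under the default
``warn_and_stash`` policy these travel under a reserved key inside
``misc`` so the reverse conversion can restore them.  Every conversion
returns a :class:`LossReport` accounting for each populated source
slot: mapped, stashed, dropped or renamed — nothing is dropped
silently.

The target layouts are represented by plain in-memory dataclasses
mirroring the R objects' slot structure (assays/colData/... and
layers/reductions/graphs/...), so conversions are testable without an R
session; serialising them to R-native files is delegated to the target
ecosystems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ConversionError
from .model import AnnDataContainer, Raw

__all__ = [
    "ConversionMap",
    "LossReport",
    "SCELayout",
    "SCEReducedDim",
    "SCEAltExp",
    "SeuratLayout",
    "SeuratAssay",
    "SeuratReduction",
    "default_map",
    "to_sce",
    "from_sce",
    "to_seurat",
    "from_seurat",
    "STASH_KEY",
    "DROP",
    "STASH",
]

#: Reserved key inside metadata/misc under which slot payloads with no
#: first-class destination are stashed.
STASH_KEY = ".stashed_slots"

DROP = "DROP"
STASH = "stash"

AD_SLOTS = ("X", "layers", "obs", "var", "obsm", "varm", "obsp", "varp", "uns", "raw")

_SCE_TOKENS = {"assays", "colData", "rowData", "reducedDims", "colPairs", "rowPairs",
               "metadata", "altExp", STASH, DROP}
_SEURAT_TOKENS = {"layers", "cell_metadata", "feature_metadata", "reductions", "graphs",
                  "misc", STASH, DROP}

_DEFAULT_ENTRIES = {
    "to_sce": {
        "X": "assays", "layers": "assays", "obs": "colData", "var": "rowData",
        "obsm": "reducedDims", "varm": "reducedDims", "obsp": "colPairs",
        "varp": "rowPairs", "uns": "metadata", "raw": "altExp",
    },
    "to_seurat": {
        "X": "layers", "layers": "layers", "obs": "cell_metadata",
        "var": "feature_metadata", "obsm": "reductions", "varm": "reductions",
        "obsp": "graphs", "varp": STASH, "uns": "misc", "raw": STASH,
    },
}
_DEFAULT_ENTRIES["from_sce"] = _DEFAULT_ENTRIES["to_sce"]
_DEFAULT_ENTRIES["from_seurat"] = _DEFAULT_ENTRIES["to_seurat"]


@dataclass
class ConversionMap:
    """Per-slot source → destination mapping with user overrides.

    entries:
        One destination token (or ``DROP``/``stash``) per AnnData slot.
    renames:
        Key-level overrides, e.g. ``{"obsm/X_pca": "pca_custom"}`` sends
        that single entry to a custom destination name and suppresses
        the default naming.
    unmapped_policy:
        What happens to payloads with no destination slot:
        ``warn_and_stash`` (default), ``warn_and_drop`` or ``error``.
    """

    direction: str
    entries: dict[str, str] = field(default_factory=dict)
    renames: dict[str, str] = field(default_factory=dict)
    unmapped_policy: str = "warn_and_stash"

    def __post_init__(self):
        if self.direction not in _DEFAULT_ENTRIES:
            raise ConversionError(f"unknown direction '{self.direction}'")
        merged = dict(_DEFAULT_ENTRIES[self.direction])
        merged.update(self.entries)
        self.entries = merged
        self.validate()

    def validate(self) -> None:
        valid = _SCE_TOKENS if self.direction.endswith("sce") else _SEURAT_TOKENS
        for slot in AD_SLOTS:
            if slot not in self.entries:
                raise ConversionError(f"map is missing slot '{slot}'")
            dest = self.entries[slot]
            if dest not in valid:
                raise ConversionError(
                    f"'{dest}' is not a valid destination for {self.direction}")
        if self.unmapped_policy not in ("warn_and_stash", "warn_and_drop", "error"):
            raise ConversionError(f"unknown unmapped_policy '{self.unmapped_policy}'")

    def dest_name(self, slot_key: str, default: str) -> str:
        return self.renames.get(slot_key, default)


def default_map(direction: str) -> ConversionMap:
    """The default slot mapping for a direction."""
    return ConversionMap(direction=direction)


@dataclass
class LossReport:
    """Accounting of where every populated source slot went.

    ``mapped`` lists slots placed in a first-class destination;
    ``stashed`` records ``(slot_path, destination_path)`` for payloads
    parked under the reserved stash key; ``dropped`` records
    ``(slot_path, reason)``; ``renamed`` records ``(old, new)`` name
    repairs and key normalisations.
    """

    mapped: list = field(default_factory=list)
    dropped: list = field(default_factory=list)
    stashed: list = field(default_factory=list)
    renamed: list = field(default_factory=list)

    def accounted_slots(self) -> set:
        top = lambda s: s.split("/")[0]
        return ({top(s) for s in self.mapped}
                | {top(s) for s, _ in self.dropped}
                | {top(s) for s, _ in self.stashed})


# ---------------------------------------------------------------------------
# target layouts


@dataclass
class SCEReducedDim:
    """A reduced-dimension entry: cells × k embedding with optional
    features × k loadings attached."""

    embedding: object
    loadings: object | None = None


@dataclass
class SCEAltExp:
    """Alternative experiment (used for the pre-filtering ``raw``
    snapshot): its own feature set over the same cells."""

    assays: dict = field(default_factory=dict)  # feature × cell matrices
    row_data: pd.DataFrame = None
    row_matrices: dict = field(default_factory=dict)  # per-feature annotations


@dataclass
class SCELayout:
    """Feature-by-cell container mirroring SingleCellExperiment slots."""

    assays: dict = field(default_factory=dict)
    col_data: pd.DataFrame = None
    row_data: pd.DataFrame = None
    reduced_dims: dict = field(default_factory=dict)
    col_pairs: dict = field(default_factory=dict)
    row_pairs: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)
    alt_exps: dict = field(default_factory=dict)


@dataclass
class SeuratReduction:
    """Dimensional reduction: cells × k embeddings, optional
    features × k loadings."""

    embeddings: object
    loadings: object | None = None


@dataclass
class SeuratAssay:
    layers: dict = field(default_factory=dict)  # feature × cell matrices
    feature_metadata: pd.DataFrame = None


@dataclass
class SeuratLayout:
    """Feature-by-cell container mirroring the Seurat v5 slot structure."""

    assays: dict = field(default_factory=dict)
    active_assay: str = "RNA"
    cell_metadata: pd.DataFrame = None
    reductions: dict = field(default_factory=dict)
    graphs: dict = field(default_factory=dict)
    misc: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers


def _t(m):
    """Transpose a matrix slot; sparse stays sparse (CSR ↔ CSC swap,
    undone by the reverse transpose), dense stays dense."""
    if m is None:
        return None
    return m.T


def populated_slots(obj) -> set:
    """The source slots of an object that actually hold content."""
    if isinstance(obj, AnnDataContainer):
        slots = {"obs", "var"}
        if obj.X is not None:
            slots.add("X")
        if obj.raw is not None:
            slots.add("raw")
        for name in ("layers", "obsm", "varm", "obsp", "varp", "uns"):
            if getattr(obj, name):
                slots.add(name)
        return slots
    if isinstance(obj, SCELayout):
        slots = {"colData", "rowData"}
        for token, coll in (("assays", obj.assays), ("reducedDims", obj.reduced_dims),
                            ("colPairs", obj.col_pairs), ("rowPairs", obj.row_pairs),
                            ("metadata", obj.metadata), ("altExp", obj.alt_exps)):
            if coll:
                slots.add(token)
        return slots
    if isinstance(obj, SeuratLayout):
        slots = {"cell_metadata", "feature_metadata"}
        if any(a.layers for a in obj.assays.values()):
            slots.add("layers")
        for token, coll in (("reductions", obj.reductions), ("graphs", obj.graphs),
                            ("misc", obj.misc)):
            if coll:
                slots.add(token)
        return slots
    raise TypeError(type(obj))


def _x_layer_name(X) -> str:
    """Naming heuristic for the unnamed central matrix in feature-by-cell
    targets: 'counts' when integer-valued, else 'data'."""
    values = X.data if sparse.issparse(X) else np.asarray(X)
    values = np.asarray(values)
    if values.size == 0 or values.dtype.kind in ("i", "u", "b"):
        return "counts"
    if values.dtype.kind == "f" and np.all(np.isfinite(values)) and \
            np.array_equal(values, np.round(values)):
        return "counts"
    return "data"


def _norm_key(key: str) -> str:
    return key[2:] if key.startswith("X_") else key


def _coerce_obsm(slot: str, key: str, value, report: LossReport, stash: dict):
    """A multidimensional annotation must become a numeric matrix; numeric
    tables are coerced (with a warning), mixed-type tables are stashed."""
    if isinstance(value, pd.DataFrame):
        if all(pd.api.types.is_numeric_dtype(dt) for dt in value.dtypes):
            warnings.warn(f"{slot}['{key}']: numeric table coerced to a matrix",
                          stacklevel=3)
            return value.to_numpy()
        stash.setdefault(slot, {})[key] = value
        report.stashed.append((f"{slot}/{key}", f"{STASH_KEY}/{slot}/{key}"))
        warnings.warn(f"{slot}['{key}']: mixed-type table has no matrix form; stashed",
                      stacklevel=3)
        return None
    return value


def _handle_unmapped(policy: str, slot: str, payload, stash: dict,
                     report: LossReport, target: str) -> None:
    if policy == "error":
        raise ConversionError(f"slot '{slot}' has no destination in the {target} layout")
    if policy == "warn_and_drop":
        report.dropped.append((slot, f"no destination in the {target} layout"))
        warnings.warn(f"slot '{slot}' has no {target} destination; dropped", stacklevel=3)
        return
    stash[slot] = payload
    report.stashed.append((slot, f"{STASH_KEY}/{slot}"))
    warnings.warn(f"slot '{slot}' has no {target} destination; stashed under "
                  f"'{STASH_KEY}'", stacklevel=3)


def _unique_names(names, report: LossReport, fix_underscores: bool) -> list[str]:
    """Repair names for ecosystems that forbid underscores/duplicates;
    every repair is recorded as a rename."""
    out, seen = [], {}
    for name in names:
        fixed = str(name).replace("_", "-") if fix_underscores else str(name)
        if fixed in seen:
            seen[fixed] += 1
            candidate = f"{fixed}.{seen[fixed]}"
            while candidate in seen:
                seen[fixed] += 1
                candidate = f"{fixed}.{seen[fixed]}"
            fixed = candidate
        seen.setdefault(fixed, 0)
        if fixed != str(name):
            report.renamed.append((str(name), fixed))
        out.append(fixed)
    return out


# ---------------------------------------------------------------------------
# AnnData → SCE


def to_sce(adata: AnnDataContainer, cmap: ConversionMap | None = None, *,
           x_assay_name: str | None = None) -> tuple[SCELayout, LossReport]:
    """Convert a container to the SingleCellExperiment layout.

    Every assay is the transpose of its source matrix (features become
    rows).  ``varm`` entries whose key matches an ``obsm`` key (after
    stripping a leading ``X_``) attach as loadings of that reduced
    dimension; unmatched entries are stashed in ``metadata``.
    """
    adata.validate()
    cmap = cmap or default_map("to_sce")
    report = LossReport()
    stash: dict = {}
    sce = SCELayout(col_data=adata.obs.copy(), row_data=adata.var.copy(),
                    metadata=dict(adata.uns))
    report.mapped += ["obs", "var"]
    if adata.uns:
        report.mapped.append("uns")

    populated = populated_slots(adata)
    for slot in ("obs", "var", "uns"):
        populated.discard(slot)

    for slot in sorted(populated, key=AD_SLOTS.index):
        dest = cmap.entries[slot]
        payload = getattr(adata, slot) if slot != "X" else adata.X
        if dest == DROP:
            report.dropped.append((slot, "dropped by map"))
            continue
        if dest == STASH:
            _handle_unmapped(cmap.unmapped_policy, slot, payload, stash, report, "SCE")
            continue
        if slot == "X":
            name = cmap.dest_name("X", x_assay_name or _x_layer_name(adata.X))
            sce.assays[name] = _t(adata.X)
            report.mapped.append("X")
        elif slot == "layers":
            for key, m in adata.layers.items():
                name = cmap.dest_name(f"layers/{key}", key)
                if name in sce.assays:
                    raise ConversionError(f"assay name collision on '{name}'")
                sce.assays[name] = _t(m)
            report.mapped.append("layers")
        elif slot == "obsm":
            for key, value in adata.obsm.items():
                value = _coerce_obsm("obsm", key, value, report, stash)
                if value is None:
                    continue
                name = cmap.dest_name(f"obsm/{key}", key)
                if name != key:
                    report.renamed.append((f"obsm/{key}", name))
                sce.reduced_dims[name] = SCEReducedDim(embedding=value)
            report.mapped.append("obsm")
        elif slot == "varm":
            matched_any = False
            for key, value in adata.varm.items():
                target = None
                for rd_key in sce.reduced_dims:
                    if _norm_key(key).lower() == _norm_key(rd_key).lower():
                        target = rd_key
                        break
                if target is not None and sce.reduced_dims[target].loadings is None:
                    sce.reduced_dims[target].loadings = value
                    matched_any = True
                    if target != key:
                        stash.setdefault("varm_keys", {})[target] = key
                else:
                    stash.setdefault("varm", {})[key] = value
                    report.stashed.append((f"varm/{key}", f"{STASH_KEY}/varm/{key}"))
                    warnings.warn(f"varm['{key}'] matches no reduced dimension; stashed",
                                  stacklevel=2)
            if matched_any:
                report.mapped.append("varm")
        elif slot == "obsp":
            for key, m in adata.obsp.items():
                sce.col_pairs[cmap.dest_name(f"obsp/{key}", key)] = m
            report.mapped.append("obsp")
        elif slot == "varp":
            for key, m in adata.varp.items():
                sce.row_pairs[cmap.dest_name(f"varp/{key}", key)] = m
            report.mapped.append("varp")
        elif slot == "raw":
            sce.alt_exps[cmap.dest_name("raw", "raw")] = SCEAltExp(
                assays={"X": _t(adata.raw.X)} if adata.raw.X is not None else {},
                row_data=adata.raw.var.copy(),
                row_matrices=dict(adata.raw.varm),
            )
            report.mapped.append("raw")
    if stash:
        sce.metadata[STASH_KEY] = stash
    return sce, report


def from_sce(sce: SCELayout, cmap: ConversionMap | None = None, *,
             x_assay: str | None = None,
             alt_exp_as_raw: str = "raw") -> tuple[AnnDataContainer, LossReport]:
    """Convert an SCE-layout object back to a container (inverse of
    :func:`to_sce` on its image).

    ``x_assay`` selects which assay becomes ``X`` (default: the first);
    the remaining assays become layers.  ``alt_exp_as_raw`` names the
    alternative experiment restored as ``raw``; any other altExp has no
    AnnData counterpart and is stashed into ``uns`` with a warning.
    """
    cmap = cmap or default_map("from_sce")
    report = LossReport()
    metadata = dict(sce.metadata)
    stash = metadata.pop(STASH_KEY, {})
    stash = dict(stash) if isinstance(stash, dict) else stash  # never mutate input
    varm_key_map = stash.pop("varm_keys", {}) if isinstance(stash, dict) else {}

    X, layers = None, {}
    if sce.assays:
        x_name = x_assay if x_assay is not None else next(iter(sce.assays))
        if x_name not in sce.assays:
            raise ConversionError(f"assay '{x_name}' not found; have "
                                  f"{list(sce.assays)}")
        X = _t(sce.assays[x_name])
        layers = {k: _t(m) for k, m in sce.assays.items() if k != x_name}
        report.mapped.append("assays")

    obsm, varm = {}, {}
    for key, rd in sce.reduced_dims.items():
        obsm[key] = rd.embedding
        if rd.loadings is not None:
            varm[varm_key_map.get(key, key)] = rd.loadings
    if sce.reduced_dims:
        report.mapped.append("reducedDims")
    raw = None
    for name, alt in sce.alt_exps.items():
        if name == alt_exp_as_raw:
            raw = Raw(X=_t(next(iter(alt.assays.values()))) if alt.assays else None,
                      var=alt.row_data.copy(), varm=dict(alt.row_matrices))
            report.mapped.append("altExp")
        else:
            stash.setdefault("altExp", {})[name] = alt
            report.stashed.append((f"altExp/{name}", f"{STASH_KEY}/altExp/{name}"))
            warnings.warn(f"altExp '{name}' is ambiguous in the AnnData layout "
                          f"(not the raw snapshot); stashed", stacklevel=2)

    uns = metadata
    obsp = dict(sce.col_pairs)
    varp = dict(sce.row_pairs)
    # restore stashed AnnData slots written by to_sce
    if isinstance(stash, dict):
        for slot, target in (("layers", layers), ("obsm", obsm), ("varm", varm),
                             ("obsp", obsp), ("varp", varp)):
            if slot in stash:
                target.update(stash.pop(slot))
        if "X" in stash and X is None:
            X = stash.pop("X")
        if "raw" in stash and raw is None:
            r = stash.pop("raw")
            if isinstance(r, Raw):
                raw = r
            elif isinstance(r, dict):
                raw = Raw(X=r.get("X"), var=r.get("var"), varm=r.get("varm", {}))
        if stash:
            uns[STASH_KEY] = stash
    if sce.col_pairs:
        report.mapped.append("colPairs")
    if sce.row_pairs:
        report.mapped.append("rowPairs")
    if metadata or uns:
        report.mapped.append("metadata")
    report.mapped += ["colData", "rowData"]

    adata = AnnDataContainer(X=X, obs=sce.col_data.copy(), var=sce.row_data.copy(),
                             layers=layers, obsm=obsm, varm=varm, obsp=obsp,
                             varp=varp, uns=uns, raw=raw)
    return adata, report


# ---------------------------------------------------------------------------
# AnnData → Seurat


def to_seurat(adata: AnnDataContainer, cmap: ConversionMap | None = None, *,
              x_layer_name: str | None = None,
              assay_name: str = "RNA") -> tuple[SeuratLayout, LossReport]:
    """Convert a container to the Seurat v5 layout.

    Matrices are transposed (features as rows).  Cell and feature names
    are repaired to the target ecosystem's rules (no underscores, no
    duplicates); every repair is recorded in ``LossReport.renamed`` and
    the original names travel in the stash so the reverse conversion
    can restore them.  ``varp`` (and ``raw``, whose feature set differs)
    have no first-class Seurat slot and are stashed under ``misc``.
    """
    adata.validate()
    if adata.n_var == 0:
        raise ConversionError("the Seurat layout requires at least one feature")
    cmap = cmap or default_map("to_seurat")
    report = LossReport()
    stash: dict = {}

    cell_names = _unique_names(adata.obs_names, report, fix_underscores=True)
    feature_names = _unique_names(adata.var_names, report, fix_underscores=True)
    if cell_names != [str(n) for n in adata.obs_names]:
        stash["cell_names"] = [str(n) for n in adata.obs_names]
    if feature_names != [str(n) for n in adata.var_names]:
        stash["feature_names"] = [str(n) for n in adata.var_names]

    cell_metadata = adata.obs.copy()
    cell_metadata.index = pd.Index(cell_names)
    feature_metadata = adata.var.copy()
    feature_metadata.index = pd.Index(feature_names)

    obj = SeuratLayout(active_assay=assay_name, cell_metadata=cell_metadata,
                       misc=dict(adata.uns))
    assay = SeuratAssay(feature_metadata=feature_metadata)
    obj.assays[assay_name] = assay
    report.mapped += ["obs", "var"]
    if adata.uns:
        report.mapped.append("uns")

    populated = populated_slots(adata) - {"obs", "var", "uns"}
    for slot in sorted(populated, key=AD_SLOTS.index):
        dest = cmap.entries[slot]
        payload = getattr(adata, slot)
        if dest == DROP:
            report.dropped.append((slot, "dropped by map"))
            continue
        if dest == STASH:
            if slot == "raw":
                payload = {"X": adata.raw.X, "var": adata.raw.var,
                           "varm": dict(adata.raw.varm)}
            _handle_unmapped(cmap.unmapped_policy, slot, payload, stash, report,
                             "Seurat")
            continue
        if slot == "X":
            name = cmap.dest_name("X", x_layer_name or _x_layer_name(adata.X))
            assay.layers[name] = _t(adata.X)
            report.mapped.append("X")
        elif slot == "layers":
            for key, m in adata.layers.items():
                name = cmap.dest_name(f"layers/{key}", key)
                if name in assay.layers:
                    raise ConversionError(f"layer name collision on '{name}'")
                assay.layers[name] = _t(m)
            report.mapped.append("layers")
        elif slot == "obsm":
            for key, value in adata.obsm.items():
                value = _coerce_obsm("obsm", key, value, report, stash)
                if value is None:
                    continue
                red_key = cmap.dest_name(f"obsm/{key}", _norm_key(key))
                if red_key != key:
                    report.renamed.append((f"obsm/{key}", red_key))
                    stash.setdefault("obsm_keys", {})[red_key] = key
                obj.reductions[red_key] = SeuratReduction(embeddings=value)
            report.mapped.append("obsm")
        elif slot == "varm":
            matched_any = False
            for key, value in adata.varm.items():
                target = None
                for red_key in obj.reductions:
                    if _norm_key(key).lower() == _norm_key(red_key).lower():
                        target = red_key
                        break
                if target is not None and obj.reductions[target].loadings is None:
                    obj.reductions[target].loadings = value
                    matched_any = True
                    if target != key:
                        stash.setdefault("varm_keys", {})[target] = key
                else:
                    stash.setdefault("varm", {})[key] = value
                    report.stashed.append((f"varm/{key}", f"{STASH_KEY}/varm/{key}"))
                    warnings.warn(f"varm['{key}'] matches no reduction; stashed",
                                  stacklevel=2)
            if matched_any:
                report.mapped.append("varm")
        elif slot == "obsp":
            for key, m in adata.obsp.items():
                obj.graphs[cmap.dest_name(f"obsp/{key}", key)] = m
            report.mapped.append("obsp")
    if stash:
        obj.misc[STASH_KEY] = stash
    return obj, report


def from_seurat(obj: SeuratLayout, cmap: ConversionMap | None = None, *,
                assay: str | None = None,
                x_layer: str | None = None) -> tuple[AnnDataContainer, LossReport]:
    """Convert a Seurat-layout object back to a container.

    AnnData is single-modality: an object carrying several assays needs
    an explicit ``assay`` choice, otherwise the conversion fails naming
    the candidates.  The layer selected as ``X`` mirrors the forward
    heuristic: ``counts`` if present, else ``data``, else the first
    layer.  Stashed ``varp``/``raw`` payloads and recorded name repairs
    are restored from the reserved ``misc`` key.
    """
    cmap = cmap or default_map("from_seurat")
    report = LossReport()
    if len(obj.assays) > 1 and assay is None:
        raise ConversionError(
            "object has multiple assays; choose one of: " + ", ".join(obj.assays))
    assay_name = assay or (obj.active_assay if obj.active_assay in obj.assays
                           else next(iter(obj.assays)))
    if assay_name not in obj.assays:
        raise ConversionError(f"assay '{assay_name}' not found; have {list(obj.assays)}")
    sa = obj.assays[assay_name]

    misc = dict(obj.misc)
    stash = misc.pop(STASH_KEY, {})
    stash = dict(stash) if isinstance(stash, dict) else stash  # never mutate input
    obsm_key_map = stash.pop("obsm_keys", {}) if isinstance(stash, dict) else {}
    varm_key_map = stash.pop("varm_keys", {}) if isinstance(stash, dict) else {}

    X, layers = None, {}
    if sa.layers:
        if x_layer is None:
            for candidate in ("counts", "data"):
                if candidate in sa.layers:
                    x_layer = candidate
                    break
            else:
                x_layer = next(iter(sa.layers))
        if x_layer not in sa.layers:
            raise ConversionError(f"layer '{x_layer}' not found; have {list(sa.layers)}")
        X = _t(sa.layers[x_layer])
        layers = {k: _t(m) for k, m in sa.layers.items() if k != x_layer}
        report.mapped.append("layers")

    obsm, varm = {}, {}
    for red_key, red in obj.reductions.items():
        obsm[obsm_key_map.get(red_key, red_key)] = red.embeddings
        if red.loadings is not None:
            varm[varm_key_map.get(red_key, red_key)] = red.loadings
    if obj.reductions:
        report.mapped.append("reductions")
    obsp = dict(obj.graphs)
    if obj.graphs:
        report.mapped.append("graphs")

    obs = obj.cell_metadata.copy()
    var = sa.feature_metadata.copy()
    varp, raw = {}, None
    if isinstance(stash, dict):
        if "varp" in stash:
            varp = dict(stash.pop("varp"))
        if "raw" in stash:
            r = stash.pop("raw")
            raw = Raw(X=r.get("X"), var=r.get("var"), varm=r.get("varm", {}))
        for slot, target in (("varm", varm), ("obsm", obsm), ("obsp", obsp),
                             ("layers", layers)):
            if slot in stash:
                target.update(stash.pop(slot))
        if "cell_names" in stash:
            obs.index = pd.Index(stash.pop("cell_names"))
        if "feature_names" in stash:
            var.index = pd.Index(stash.pop("feature_names"))
        if stash:
            misc[STASH_KEY] = stash
    if misc:
        report.mapped.append("misc")
    report.mapped += ["cell_metadata", "feature_metadata"]

    adata = AnnDataContainer(X=X, obs=obs, var=var, layers=layers, obsm=obsm,
                             varm=varm, obsp=obsp, varp=varp, uns=misc, raw=raw)
    return adata, report
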