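# Methods

## The on-disk model

An H5AD file is an HDF5 container whose root carries the AnnData layout:
a central observations × variables matrix `X`, alternative matrices of
the same shape (`layers`), per-axis metadata tables (`obs`, `var`),
per-axis multidimensional annotations (`obsm`, `varm`), square pairwise
matrices (`obsp`, `varp`), nested unstructured metadata (`uns`) and an
optional pre-filtering snapshot (`raw`) that shares observations but may
carry a different feature set. Every element — down to individual
dataframe columns — is tagged with `encoding-type` and
`encoding-version` attributes that determine its interpretation.

h5adkit implements a closed registry of eleven element encodings plus
the two structural tags (`anndata` root, `raw`). The version strings
written (`csr_matrix`/`csc_matrix`/`dict`/nullables at 0.1.0, the rest
at 0.2.0) match those emitted by the current reference implementation,
verified by inspecting files it produces; the registry is a single
constant (`codec.ENCODING_REGISTRY`) so new versions are one-line
extensions.

### Codec conventions

- **Sparse matrices** are stored as `data`/`indices`/`indptr` datasets
  plus a `shape` attribute. `indices` and `indptr` are written as 64-bit
  integers; any integer width is accepted on read. A `SparseTriple`
  value object carries the invariants (indptr length = major dim + 1,
  starts at 0, non-decreasing, ends at nnz, indices < minor dim) and a
  deliberately naive `toarray()` that expands by the definition of the
  compressed layout — this is the brute-force oracle the tests compare
  scipy-backed round trips against, and it is kept independent of the
  code path it checks.
- **Missing values** translate on read: categorical code −1 and a `True`
  nullable mask both become the host missing value (`NaN` / `pd.NA`).
  Floating-point `NaN` is *not* converted to a nullable mask in either
  direction: no arithmetic is performed anywhere in the codec, so float
  round trips are bit-exact, and that wins over mask normalisation.
- **Strings** are written as variable-length UTF-8; fixed-length string
  datasets are accepted on read, never produced.
- **Scalars** decode to native Python scalars (never 0-d or length-1
  arrays), so they re-encode as scalars.
- **Mapping key order** is preserved: files are written with HDF5
  creation-order tracking, and groups are iterated in that order on
  read. Writers that do not record creation order (see
  *Interoperability*) surface keys in HDF5's default name order.
- **Legacy files** lacking encoding attributes are handled by a
  configurable policy: `infer` (default) deduces the encoding from the
  HDF5 structure — including the older `h5sparse_format`/`h5sparse_shape`
  convention — with a warning; `error` refuses. Unknown `encoding-type`
  strings are always rejected with a path-addressed error rather than
  guessed at.
- **Compression**: gzip level 4 on every non-scalar, non-empty dataset
  by default; `WriteOptions(compression=None)` disables it; reads accept
  whatever filters the HDF5 layer supports.
- **Integer categories and codes** keep their stored width on read;
  nullable integers widen to 64-bit (`Int64`) because that is the
  on-disk width — a round trip of a narrower nullable dtype therefore
  returns `Int64` with identical values.

## The container

`AnnDataContainer` enforces all dimension constraints simultaneously;
`validate()` names the first violated slot with expected and actual
dimensions, and runs again on every slot replacement (a failed
assignment leaves the container unchanged; there is no deferred
validation mode). Mutating the *inside* of a slot dict bypasses the
setter and is only caught at the next `validate()`/`write_h5ad()` —
accepted as the cost of exposing plain dicts.

`obs_names`/`var_names` are views of the obs/var table indexes — the
same data, not copies. Duplicate names are permitted in the container
(the format permits them); converters enforce target-ecosystem rules.

Subsetting accepts index, boolean and name selectors, slices every
aligned slot consistently (both axes of `obsp`/`varp`), passes `uns`
through, slices `raw` on the obs axis only, and satisfies the
composition law `subset(subset(a, i), j) == subset(a, i[j])` per axis.
Name selectors on duplicated names select *all* matches.

Backed mode (`read_h5ad(..., mode="backed")`) is read-only: `obs`,
`var`, `uns` and the axis names are decoded at open time without
touching any matrix dataset; matrix slots materialise on demand and are
cached. Every materialisation is appended to `matrix_reads`, which the
test suite uses as laziness instrumentation. Writing always targets a
new file; there is no in-place editing.

## Conversions

Default slot maps follow the standard correspondence between the three
ecosystems (assays/colData/rowData/reducedDims/colPairs/rowPairs/
metadata/altExp for SCE; layers/metadata tables/reductions/graphs/misc
for Seurat). The target layouts are plain Python dataclasses mirroring
the R objects' slots; serialising them to R-native files is the target
ecosystems' job. Design points the slot table leaves open, decided
here:

- **X naming**: the central matrix is unnamed in AnnData but must be a
  named assay/layer in the targets. It becomes `counts` when
  integer-valued (every entry equals its rounding), else `data`;
  overridable. The reverse conversion mirrors the heuristic (`counts`,
  then `data`, then the first layer).
- **varm pairing**: the slot table maps `varm` to reducedDims/reductions
  but gives no pairing rule. A `varm` entry attaches as loadings of the
  reduction whose key matches after stripping a leading `X_` prefix,
  case-insensitively; unmatched entries are stashed.
- **Stashing**: slots with no first-class destination (`varp` and `raw`
  for Seurat, unmatched `varm`, mixed-type table-valued `obsm` entries)
  are parked under the reserved key `.stashed_slots` in
  `metadata`/`misc`, with a warning and a `LossReport.stashed` record.
  The reverse conversions restore them, making the round trip the
  identity. The default `unmapped_policy` is `warn_and_stash`
  (alternatives: `warn_and_drop`, `error`).
- **Name repair** applies to Seurat targets only (its ecosystem forbids
  underscores and duplicate names): underscores become dashes,
  duplicates get `.N` suffixes, every repair is recorded in
  `LossReport.renamed`, and the original names travel in the stash so
  `from_seurat` restores them exactly. SCE targets are never repaired.
- **raw → Seurat**: the slot table places unfiltered matrices in Seurat
  layers, but a raw snapshot with a different feature set cannot share
  the assay's feature axis; it is stashed instead (a documented lossy
  mapping, visible in the LossReport).
- **altExp ambiguity**: only the altExp named `raw` (configurable) is
  reverse-mapped to the raw slot; any other altExp has no unambiguous
  AnnData counterpart and is stashed into `uns` with a warning.
- **Conservation**: for every conversion, each populated source slot
  appears in exactly one of mapped / stashed / dropped — checked
  corpus-wide by the tests.

## Validator and diff

`validate_file` walks every element and reports *all* violations
(path, stable rule id, message) instead of stopping at the first:
missing/unknown/bogus encoding attributes, malformed versions, sparse
triple inconsistencies, out-of-range categorical codes, duplicate
categories, mask/values length mismatches, dataframe column/index
misalignment, scalar-encoded non-scalar datasets, and root-level axis
dimension conflicts. An unreadable file raises instead of producing a
report.

`diff_files` compares decoded elements. Containers recurse (root,
mappings, dataframes, raw); everything else is a leaf compared
logically. Float comparison is exact by default (`atol=0`) because the
codec performs no arithmetic; `NaN` equals `NaN`. A matrix stored dense
in one file and sparse in the other compares by expanded values unless
`strict_encoding=True`, in which case it is a `type_mismatch`. The diff
is symmetric up to mirrored `missing_left`/`missing_right` kinds.

## Fixture corpus

The generator produces deterministic containers from a seed and a set
of feature toggles (matrix representation, layers, raw, categoricals,
nullable columns, nested `uns` to depth 6, embedding/loading pairs,
pairwise matrices, empty slots, unicode, missing values, duplicate and
underscore-bearing names). Counts are Poisson-like integers, embeddings
standard normal; sizes in the named corpus range from 0 × 0 to 50 × 20.
These sizes keep the whole suite in seconds while still exercising every
encoding; a coverage test asserts that the written corpus contains every
encoding-type in the registry.

What the corpus does *not* emulate: biological structure, large-scale
data, ragged/awkward arrays, multimodal containers, or files produced
by arbitrary third-party writers. Passing tests therefore demonstrate
format correctness and interoperability with the reference
implementation at desk scale, not performance or robustness to
malformed foreign files beyond the planted-defect set.

## Interoperability

Cross-implementation tests round-trip every corpus fixture through the
reference AnnData implementation (our file → their read → their write →
our read) and semantically diff the file pairs in both directions. Two
benign representational deviations of the reference writer are
documented and tolerated, and nothing else:

1. it coerces string columns with repeated values to categoricals
   (values unchanged, representation changed);
2. it does not record mapping key creation order, so key order is
   compared as sets in cross-implementation checks.

## Known limitations

- Zarr backing, container concatenation and multimodal containers are
  out of scope.
- Backed mode materialises whole slots; sliced on-disk reads are not
  offered.
- A non-string or `RangeIndex` table index is stringified on write (the
  format stores indexes as string arrays), so such an index round-trips
  as strings.
- Nullable integer widths narrower than 64-bit widen on round trip (see
  above).
- Unsigned 64-bit values above the signed range are not specially
  handled.
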