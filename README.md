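# h5adkit

A native Python toolkit for the **H5AD** file format — the HDF5-based
serialization of the AnnData container that has become the de facto
exchange format for single-cell transcriptomics data. h5adkit implements
the AnnData on-disk specification directly on top of `h5py`: it reads
and writes every element encoding itself (arrays, CSR/CSC sparse
matrices, dataframes, categoricals, nullable integer/boolean vectors,
strings, scalars, nested mappings), with no dependency on the reference
`anndata` implementation.

It is aimed at people who need to *work with the format itself* rather
than just load a matrix: pipeline authors moving data between the
scverse, Bioconductor and Seurat ecosystems, and tool developers who
need to verify that the files their software produces interoperate.

What it provides:

- **`AnnDataContainer`** — an observations × variables container with the
  standard aligned slots (`X`, `layers`, `obs`, `var`, `obsm`, `varm`,
  `obsp`, `varp`, `uns`, `raw`), validated shape invariants, consistent
  subsetting, and reference semantics.
- **`read_h5ad` / `write_h5ad`** — whole-file I/O, in memory or *backed*
  (metadata decoded eagerly, matrices left on disk until materialised).
  Writes are atomic: a failed write leaves no partial file.
- **Converters** — bidirectional, slot-mapped conversion to
  SingleCellExperiment-style and Seurat v5-style layouts, with sensible
  defaults, per-slot overrides, and a `LossReport` that accounts for
  every populated slot (mapped, stashed, renamed or dropped — never
  silently lost). Matrices are transposed to the target ecosystems'
  feature-by-cell orientation; slots with no counterpart (e.g. `varp`
  in Seurat) travel under a reserved stash key so the reverse
  conversion can restore them.
- **Conformance tools** — `validate_file` checks every structural rule
  of the format and reports path-addressed violations; `diff_files`
  compares two files *semantically* (decoded elements, not bytes), so
  benign differences between HDF5 bindings never register.
- **Fixture generator** — a deterministic corpus of synthetic containers
  covering every encoding and edge case, used by the whole test suite.
- **CLI** — `h5adkit validate | diff | info | convert`.

## Worked example

```python
import h5adkit as hk

spec = hk.FixtureSpec(n_obs=100, n_var=40, seed=7, features=frozenset(
    {"sparse_csr_X", "categoricals", "obsm_varm_pair", "obsp", "varp", "nested_uns"}))
adata = hk.generate(spec)
print(adata)
# AnnDataContainer n_obs × n_var = 100 × 40
#     obsm: 'X_pca', 'X_umap'
#     varm: 'pca', 'PCs_extra'
#     obsp: 'distances', 'connectivities'
#     varp: 'gene_correlation'
#     uns: 'generator', 'seed', 'params', 'colors'

hk.write_h5ad(adata, "pbmc_like.h5ad")
back = hk.read_h5ad("pbmc_like.h5ad")
print("round-trip differences:", hk.container_diff(adata, back))
# round-trip differences: []

sce, report = hk.to_sce(adata)
print(list(sce.assays), next(iter(sce.assays.values())).shape)
# ['counts'] (40, 100)        # transposed: features as rows, named by the
#                             # counts/data heuristic (X is integer-valued)

seurat, report = hk.to_seurat(adata)
print(list(seurat.reductions), report.stashed)
# ['pca', 'umap'] [('varm/PCs_extra', '.stashed_slots/varm/PCs_extra'),
#                  ('varp', '.stashed_slots/varp')]
# the "X_" prefix is stripped from reduction keys; varm entries matching a
# reduction attach as loadings; varp has no Seurat slot and is stashed
# (and recovered by hk.from_seurat).

print(hk.validate_file("pbmc_like.h5ad").conformant)
# True
```

From the shell:

```bash
$ h5adkit info pbmc_like.h5ad
/X      csr_matrix (100, 40)
/obs    dataframe
/obs/celltype   categorical
...
$ h5adkit diff pbmc_like.h5ad pbmc_like.h5ad
files are semantically equal      # exit code 0; 1 on differences, 2 on I/O errors
```

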