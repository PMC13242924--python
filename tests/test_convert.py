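"""Conversion to and from the SingleCellExperiment and Seurat layouts:
default slot maps, transposition, stashes, renames and round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

import h5adkit as hk
from h5adkit.convert import STASH, STASH_KEY, populated_slots
from h5adkit.errors import ConversionError


def full_fixture():
    return hk.generate(hk.FixtureSpec(n_obs=20, n_var=8, seed=5, features=frozenset({
        "sparse_csr_X", "layers", "raw", "categoricals", "nullable_cols",
        "nested_uns", "obsm_varm_pair", "obsp", "varp"})))


# ---------------------------------------------------------------------------
# default maps


def test_default_map_to_sce_matches_slot_table():
    m = hk.default_map("to_sce").entries
    assert m["X"] == m["layers"] == "assays"
    assert m["raw"] == "altExp"
    assert m["obs"] == "colData" and m["var"] == "rowData"
    assert m["obsm"] == m["varm"] == "reducedDims"
    assert m["obsp"] == "colPairs" and m["varp"] == "rowPairs"
    assert m["uns"] == "metadata"


def test_default_map_to_seurat_matches_slot_table():
    m = hk.default_map("to_seurat").entries
    assert m["X"] == m["layers"] == "layers"
    assert m["obs"] == "cell_metadata" and m["var"] == "feature_metadata"
    assert m["obsm"] == m["varm"] == "reductions"
    assert m["obsp"] == "graphs"
    assert m["uns"] == "misc"
    assert m["varp"] == STASH  # no Seurat slot for pairwise feature matrices


def test_map_rejects_bad_destination():
    with pytest.raises(ConversionError, match="not a valid destination"):
        hk.ConversionMap(direction="to_sce", entries={"obsp": "graphs"})


# ---------------------------------------------------------------------------
# AnnData → SCE


def test_assays_are_transposed_feature_by_cell():
    a = hk.AnnDataContainer(X=np.arange(15, dtype=float).reshape(3, 5))
    sce, _ = hk.to_sce(a)
    assay = next(iter(sce.assays.values()))
    assert assay.shape == (5, 3)
    # transposition invariant, element for element
    for i in range(5):
        for j in range(3):
            assert assay[i, j] == a.X[j, i]


def test_x_assay_naming_heuristic():
    counts = hk.AnnDataContainer(X=np.ones((2, 2)))
    sce, _ = hk.to_sce(counts)
    assert list(sce.assays) == ["counts"]
    floats = hk.AnnDataContainer(X=np.full((2, 2), 0.5))
    sce, _ = hk.to_sce(floats)
    assert list(sce.assays) == ["data"]


def test_raw_becomes_alt_experiment():
    a = full_fixture()
    sce, report = hk.to_sce(a)
    assert "raw" in sce.alt_exps
    alt = sce.alt_exps["raw"]
    assert next(iter(alt.assays.values())).shape == (a.raw.n_var, a.n_obs)
    assert list(alt.row_data.index) == list(a.raw.var.index)
    assert "raw" in report.mapped


def test_metadata_only_container_converts():
    a = hk.AnnDataContainer(obs=pd.DataFrame({"x": [1, 2]}, index=["a", "b"]),
                            var=pd.DataFrame(index=["g"]))
    sce, _ = hk.to_sce(a)
    assert sce.assays == {}
    assert list(sce.col_data["x"]) == [1, 2]
    assert list(sce.row_data.index) == ["g"]


def test_colpair_roundtrips_to_obsp():
    a = full_fixture()
    sce, _ = hk.to_sce(a)
    assert set(sce.col_pairs) == set(a.obsp)
    back, _ = hk.from_sce(sce)
    for k in a.obsp:
        assert hk.values_equal(back.obsp[k], a.obsp[k])


def test_from_sce_x_assay_choice():
    a = hk.AnnDataContainer(X=np.ones((2, 2)),
                            layers={"two": np.full((2, 2), 2.0),
                                    "three": np.full((2, 2), 3.0)})
    sce, _ = hk.to_sce(a)
    assert len(sce.assays) == 3
    back, _ = hk.from_sce(sce, x_assay="two")
    assert back.X[0, 0] == 2.0
    assert set(back.layers) == {"counts", "three"}


def test_sce_roundtrip_full_fixture():
    a = full_fixture()
    sce, _ = hk.to_sce(a)
    back, _ = hk.from_sce(sce)
    assert hk.container_diff(a, back) == []


def test_unmatched_varm_stashes_with_warning():
    a = hk.AnnDataContainer(X=np.zeros((3, 2)),
                            varm={"orphan": np.zeros((2, 4))})
    with pytest.warns(UserWarning, match="orphan"):
        sce, report = hk.to_sce(a)
    assert sce.metadata[STASH_KEY]["varm"]["orphan"].shape == (2, 4)
    assert ("varm/orphan", f"{STASH_KEY}/varm/orphan") in report.stashed
    back, _ = hk.from_sce(sce)
    assert "orphan" in back.varm


def test_matched_varm_attaches_as_loadings():
    a = hk.AnnDataContainer(X=np.zeros((3, 2)),
                            obsm={"X_pca": np.zeros((3, 2))},
                            varm={"pca": np.ones((2, 2))})
    sce, _ = hk.to_sce(a)
    assert sce.reduced_dims["X_pca"].loadings is not None
    back, _ = hk.from_sce(sce)
    assert "pca" in back.varm and "X_pca" in back.obsm


def test_numeric_table_obsm_coerced_mixed_stashed():
    emb = pd.DataFrame({"d1": [0.1, 0.2], "d2": [0.3, 0.4]}, index=["a", "b"])
    mixed = pd.DataFrame({"d1": [0.1, 0.2], "lab": ["x", "y"]}, index=["a", "b"])
    a = hk.AnnDataContainer(X=np.zeros((2, 1)),
                            obsm={"num": emb, "mix": mixed})
    with pytest.warns(UserWarning):
        sce, report = hk.to_sce(a)
    assert isinstance(sce.reduced_dims["num"].embedding, np.ndarray)
    assert "mix" not in sce.reduced_dims
    assert any(s == "obsm/mix" for s, _ in report.stashed)


def test_rename_override_suppresses_default():
    a = hk.AnnDataContainer(X=np.zeros((3, 2)), obsm={"X_pca": np.zeros((3, 2))})
    cmap = hk.ConversionMap(direction="to_sce", renames={"obsm/X_pca": "pca_custom"})
    sce, report = hk.to_sce(a, cmap)
    assert list(sce.reduced_dims) == ["pca_custom"]
    assert ("obsm/X_pca", "pca_custom") in report.renamed


def test_drop_and_policy_variants():
    a = full_fixture()
    cmap = hk.ConversionMap(direction="to_sce", entries={"obsp": "DROP"})
    sce, report = hk.to_sce(a, cmap)
    assert sce.col_pairs == {}
    assert ("obsp", "dropped by map") in report.dropped

    cmap = hk.ConversionMap(direction="to_seurat",
                            unmapped_policy="error")
    with pytest.raises(ConversionError, match="varp"):
        hk.to_seurat(a, cmap)

    cmap = hk.ConversionMap(direction="to_seurat",
                            unmapped_policy="warn_and_drop")
    with pytest.warns(UserWarning):
        obj, report = hk.to_seurat(a, cmap)
    assert STASH_KEY not in obj.misc or "varp" not in obj.misc.get(STASH_KEY, {})
    assert any(s == "varp" for s, _ in report.dropped)


# ---------------------------------------------------------------------------
# AnnData → Seurat


def test_obsp_becomes_graph():
    a = full_fixture()
    obj, _ = hk.to_seurat(a)
    for k, m in a.obsp.items():
        assert hk.values_equal(obj.graphs[k], m)


def test_uns_lands_in_misc_deep_equal():
    a = full_fixture()
    obj, _ = hk.to_seurat(a)
    misc = {k: v for k, v in obj.misc.items() if k != STASH_KEY}
    assert hk.values_equal(misc, a.uns)


def test_varp_stashed_under_misc_with_warning():
    a = full_fixture()
    with pytest.warns(UserWarning, match="varp"):
        obj, report = hk.to_seurat(a)
    assert "varp" not in vars(obj)  # no first-class slot exists at all
    assert set(obj.misc[STASH_KEY]["varp"]) == set(a.varp)
    assert any(s == "varp" for s, _ in report.stashed)


def test_seurat_roundtrip_full_fixture_recovers_varp():
    a = full_fixture()
    obj, _ = hk.to_seurat(a)
    back, _ = hk.from_seurat(obj)
    assert hk.container_diff(a, back) == []


def test_reduction_with_loadings_roundtrip():
    a = hk.AnnDataContainer(X=np.zeros((4, 3)),
                            obsm={"X_pca": np.ones((4, 2))},
                            varm={"pca": np.ones((3, 2))})
    obj, report = hk.to_seurat(a)
    assert list(obj.reductions) == ["pca"]  # "X_" prefix stripped
    assert obj.reductions["pca"].loadings is not None
    assert ("obsm/X_pca", "pca") in report.renamed
    back, _ = hk.from_seurat(obj)
    assert set(back.obsm) == {"X_pca"} and set(back.varm) == {"pca"}


def test_seurat_name_repairs_are_recorded_and_reversible():
    obs = pd.DataFrame(index=["cell_1", "cell_1", "ok"])
    var = pd.DataFrame(index=["gene_a", "gene-b"])
    a = hk.AnnDataContainer(X=np.zeros((3, 2)), obs=obs, var=var)
    obj, report = hk.to_seurat(a)
    assert list(obj.cell_metadata.index) == ["cell-1", "cell-1.1", "ok"]
    assert list(obj.assays["RNA"].feature_metadata.index) == ["gene-a", "gene-b"]
    assert ("cell_1", "cell-1") in report.renamed
    assert ("cell_1", "cell-1.1") in report.renamed
    back, _ = hk.from_seurat(obj)
    assert list(back.obs_names) == ["cell_1", "cell_1", "ok"]


def test_zero_feature_container_rejected_for_seurat():
    a = hk.AnnDataContainer(obs=pd.DataFrame(index=["c"]), var=pd.DataFrame())
    with pytest.raises(ConversionError, match="at least one feature"):
        hk.to_seurat(a)


def test_multiple_assays_need_explicit_choice():
    a = hk.AnnDataContainer(X=np.ones((2, 2)))
    obj, _ = hk.to_seurat(a)
    from h5adkit.convert import SeuratAssay
    obj.assays["ADT"] = SeuratAssay(layers={"counts": np.ones((1, 2))},
                                    feature_metadata=pd.DataFrame(index=["p1"]))
    with pytest.raises(ConversionError) as exc:
        hk.from_seurat(obj)
    assert "RNA" in str(exc.value) and "ADT" in str(exc.value)
    back, _ = hk.from_seurat(obj, assay="RNA")
    assert back.shape == (2, 2)


def test_from_seurat_layer_selection_mirrors_heuristic():
    a = hk.AnnDataContainer(X=np.ones((2, 2)),
                            layers={"lognorm": np.zeros((2, 2))})
    obj, _ = hk.to_seurat(a)
    assert set(obj.assays["RNA"].layers) == {"counts", "lognorm"}
    back, _ = hk.from_seurat(obj)
    assert back.X[0, 0] == 1.0 and set(back.layers) == {"lognorm"}


def test_categorical_columns_preserve_category_order():
    cat = pd.Categorical(["hi", "lo"], categories=["lo", "hi"], ordered=True)
    a = hk.AnnDataContainer(X=np.zeros((2, 1)),
                            obs=pd.DataFrame({"grade": cat}, index=["a", "b"]))
    sce, _ = hk.to_sce(a)
    assert list(sce.col_data["grade"].cat.categories) == ["lo", "hi"]
    obj, _ = hk.to_seurat(a)
    assert obj.cell_metadata["grade"].cat.ordered


# ---------------------------------------------------------------------------
# conservation & matrix identity across the corpus


@pytest.mark.parametrize("name", [n for n, _ in hk.corpus()])
def test_loss_report_conservation(name, corpus_containers):
    """Every populated source slot is accounted for: mapped, stashed or
    dropped — in all four conversion directions."""
    a = corpus_containers[name]
    sce, r = hk.to_sce(a)
    assert populated_slots(a) <= r.accounted_slots()
    back, r2 = hk.from_sce(sce)
    assert populated_slots(sce) <= r2.accounted_slots()
    if a.n_var > 0:
        obj, r3 = hk.to_seurat(a)
        assert populated_slots(a) <= r3.accounted_slots()
        back2, r4 = hk.from_seurat(obj)
        assert populated_slots(obj) <= r4.accounted_slots()


@pytest.mark.parametrize("name", [n for n, _ in hk.corpus()])
def test_roundtrip_identity_both_targets(name, corpus_containers):
    a = corpus_containers[name]
    back_sce, _ = hk.from_sce(hk.to_sce(a)[0])
    assert hk.container_diff(a, back_sce) == []
    if a.n_var > 0:
        back_seu, _ = hk.from_seurat(hk.to_seurat(a)[0])
        assert hk.container_diff(a, back_seu) == []


def test_every_converted_matrix_is_exact_transpose():
    a = full_fixture()
    sce, _ = hk.to_sce(a)
    srcs = {"counts": a.X, **a.layers}
    for name, assay in sce.assays.items():
        src = srcs[name]
        sd = np.asarray(src.todense()) if sparse.issparse(src) else np.asarray(src)
        ad = np.asarray(assay.todense()) if sparse.issparse(assay) else np.asarray(assay)
        np.testing.assert_array_equal(ad, sd.T)
    obj, _ = hk.to_seurat(a)
    for name, layer in obj.assays["RNA"].layers.items():
        src = srcs[name]
        sd = np.asarray(src.todense()) if sparse.issparse(src) else np.asarray(src)
        ld = np.asarray(layer.todense()) if sparse.issparse(layer) else np.asarray(layer)
        np.testing.assert_array_equal(ld, sd.T)
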