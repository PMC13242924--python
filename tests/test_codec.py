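"""Element-level codec: encodings, sparse triples, categoricals,
nullables, dataframes, mappings and scalars."""

import h5py
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from h5adkit import codec
from h5adkit.compare import values_equal
from h5adkit.errors import ElementValidationError, EncodingError


@pytest.fixture
def h5file(tmp_path):
    with h5py.File(tmp_path / "t.h5", "w", track_order=True) as f:
        yield f


# ---------------------------------------------------------------------------
# encoding detection


def test_detect_encoding_reads_reference_written_attributes(tmp_path):
    """Descriptors come from the encoding attributes of a file produced
    by the reference implementation."""
    anndata = pytest.importorskip("anndata")
    a = anndata.AnnData(X=sparse.random(4, 3, density=0.5, format="csr",
                                        random_state=0))
    path = tmp_path / "ref.h5ad"
    a.write_h5ad(path)
    with h5py.File(path) as f:
        desc = codec.detect_encoding(f["X"])
        assert desc.encoding_type == "csr_matrix"
        assert desc.encoding_version == "0.1.0"
        desc = codec.detect_encoding(f["obs/_index"])
        assert desc.encoding_type == "string-array"


def test_detect_encoding_legacy_policies(h5file):
    ds = h5file.create_dataset("bare", data=np.arange(3))
    with pytest.warns(UserWarning, match="inferred 'array'"):
        desc = codec.detect_encoding(ds, legacy_policy="infer")
    assert desc.encoding_type == "array"
    with pytest.raises(EncodingError, match="/bare"):
        codec.detect_encoding(ds, legacy_policy="error")


def test_unknown_encoding_type_is_a_structured_error(h5file):
    ds = h5file.create_dataset("weird", data=np.arange(3))
    ds.attrs["encoding-type"] = "bogus"
    ds.attrs["encoding-version"] = "0.1.0"
    with pytest.raises(EncodingError) as exc:
        codec.detect_encoding(ds)
    assert "/weird" in str(exc.value) and "bogus" in str(exc.value)


def test_legacy_sparse_inference_uses_h5sparse_attrs(h5file):
    g = h5file.create_group("m")
    g.create_dataset("data", data=np.array([1.0]))
    g.create_dataset("indices", data=np.array([0]))
    g.create_dataset("indptr", data=np.array([0, 1, 1]))
    g.attrs["h5sparse_format"] = "csc"
    g.attrs["h5sparse_shape"] = [2, 2]
    with pytest.warns(UserWarning):
        triple = codec.read_sparse(g)
    assert triple.orientation == "CSC"


# ---------------------------------------------------------------------------
# dense arrays


def test_read_dense_shapes(h5file):
    one = h5file.create_dataset("one", data=np.array([7]))
    codec._write_encoding_attrs(one, "array")
    assert codec.read_dense(one).tolist() == [7]
    empty = h5file.create_dataset("empty", data=np.empty((0,)))
    assert codec.read_dense(empty).shape == (0,)
    mat = h5file.create_dataset("mat", data=np.arange(6).reshape(2, 3))
    out = codec.read_dense(mat)
    assert out.shape == (2, 3)
    assert out[1, 2] == 5


def test_dense_logical_indexing_matches_reference_writer(tmp_path):
    """Element [i, j] equals the source regardless of which implementation
    wrote the file."""
    anndata = pytest.importorskip("anndata")
    X = np.arange(12, dtype=np.float64).reshape(3, 4)
    a = anndata.AnnData(X=X.copy())
    path = tmp_path / "ref.h5ad"
    a.write_h5ad(path)
    with h5py.File(path) as f:
        np.testing.assert_array_equal(codec.read_dense(f["X"]), X)


def test_fixed_length_strings_accepted_on_read(h5file):
    ds = h5file.create_dataset("s", data=np.array([b"ab", b"cd"], dtype="S2"))
    codec._write_encoding_attrs(ds, "string-array")
    assert codec.read_dense(ds).tolist() == ["ab", "cd"]


# ---------------------------------------------------------------------------
# sparse


def test_read_sparse_expansion_examples(h5file):
    g = h5file.create_group("m")
    codec._write_encoding_attrs(g, "csr_matrix")
    g.attrs["shape"] = [2, 3]
    g.create_dataset("data", data=np.array([1.0, 2.0, 3.0]))
    g.create_dataset("indices", data=np.array([0, 2, 1]))
    g.create_dataset("indptr", data=np.array([0, 2, 3]))
    triple = codec.read_sparse(g)
    np.testing.assert_array_equal(triple.toarray(), [[1, 0, 2], [0, 3, 0]])

    z = h5file.create_group("z")
    codec._write_encoding_attrs(z, "csr_matrix")
    z.attrs["shape"] = [2, 3]
    z.create_dataset("data", data=np.empty(0))
    z.create_dataset("indices", data=np.empty(0, dtype=np.int64))
    z.create_dataset("indptr", data=np.array([0, 0, 0]))
    np.testing.assert_array_equal(codec.read_sparse(z).toarray(), np.zeros((2, 3)))


def test_write_sparse_produces_canonical_triple(h5file):
    codec.write_sparse(h5file, "zero", np.zeros((2, 3)), orientation="CSR")
    g = h5file["zero"]
    assert g["indptr"][()].tolist() == [0, 0, 0]
    assert g["data"].shape == (0,)

    codec.write_sparse(h5file, "m", np.array([[1.0, 0, 2], [0, 3, 0]]),
                       orientation="CSR")
    g = h5file["m"]
    assert g["data"][()].tolist() == [1, 2, 3]
    assert g["indices"][()].tolist() == [0, 2, 1]
    assert g["indptr"][()].tolist() == [0, 2, 3]
    assert g["indices"].dtype == np.int64


@pytest.mark.parametrize("orientation", ["CSR", "CSC"])
@pytest.mark.parametrize("density", [0.0, 0.1, 0.5, 1.0])
def test_sparse_roundtrip_matches_dense_oracle(tmp_path, orientation, density):
    """Round-trip expansion equals the brute-force dense conversion for
    seeded random matrices in both orientations at several densities."""
    rng = np.random.default_rng(int(density * 10) + (0 if orientation == "CSR" else 100))
    with h5py.File(tmp_path / "s.h5", "w") as f:
        for i in range(25):
            dense = rng.random((13, 7))
            dense[rng.random((13, 7)) >= density] = 0.0
            m = sparse.csr_matrix(dense) if orientation == "CSR" else \
                sparse.csc_matrix(dense)
            codec.write_sparse(f, f"m{i}", m, orientation=orientation)
            triple = codec.read_sparse(f[f"m{i}"])
            triple.validate()
            assert triple.orientation == orientation
            np.testing.assert_array_equal(triple.toarray(), dense)


def test_sparse_invariant_violations_are_path_addressed(h5file):
    g = h5file.create_group("bad")
    codec._write_encoding_attrs(g, "csr_matrix")
    g.attrs["shape"] = [2, 3]
    g.create_dataset("data", data=np.array([1.0]))
    g.create_dataset("indices", data=np.array([5]))  # >= minor_dim
    g.create_dataset("indptr", data=np.array([0, 1, 1]))
    with pytest.raises(ElementValidationError, match="/bad"):
        codec.read_sparse(g)


# ---------------------------------------------------------------------------
# categoricals


def test_categorical_roundtrip_and_missing_code(h5file):
    cat = pd.Categorical(["A", "B", "A", None], categories=["A", "B"])
    assert cat.codes[-1] == -1
    codec.write_categorical(h5file, "c", cat)
    out = codec.read_categorical(h5file["c"])
    assert list(out[:3]) == ["A", "B", "A"]
    assert pd.isna(out[3])
    assert list(out.categories) == ["A", "B"]
    assert not out.ordered


def test_categorical_missing_code_matches_reference_convention(tmp_path):
    """The reference implementation also writes missing entries as code -1."""
    anndata = pytest.importorskip("anndata")
    obs = pd.DataFrame({"c": pd.Categorical(["A", None])}, index=["c0", "c1"])
    a = anndata.AnnData(obs=obs, shape=(2, 0))
    path = tmp_path / "ref.h5ad"
    a.write_h5ad(path)
    with h5py.File(path) as f:
        assert f["obs/c/codes"][()].tolist() == [0, -1]
        out = codec.read_categorical(f["obs/c"])
    assert out[0] == "A" and pd.isna(out[1])


def test_empty_and_ordered_categoricals_roundtrip(h5file):
    empty = pd.Categorical([], categories=["x", "y"])
    codec.write_categorical(h5file, "e", empty)
    out = codec.read_categorical(h5file["e"])
    assert len(out) == 0 and list(out.categories) == ["x", "y"]

    ordered = pd.Categorical(["lo", "hi"], categories=["lo", "hi"], ordered=True)
    codec.write_categorical(h5file, "o", ordered)
    assert codec.read_categorical(h5file["o"]).ordered


def test_categorical_out_of_range_code_rejected(h5file):
    g = h5file.create_group("c")
    codec._write_encoding_attrs(g, "categorical")
    g.attrs["ordered"] = False
    g.create_dataset("codes", data=np.array([0, 7], dtype=np.int8))
    codec._write_array(g, "categories", np.asarray(["A", "B"], dtype=object),
                       codec.WriteOptions())
    with pytest.raises(ElementValidationError, match="out of range"):
        codec.read_categorical(g)


# ---------------------------------------------------------------------------
# nullable vectors


def test_nullable_integer_decode(h5file):
    arr = pd.arrays.IntegerArray(np.array([1, 2, 3], dtype=np.int64),
                                 np.array([False, True, False]))
    codec.write_nullable(h5file, "n", arr)
    out = codec.read_nullable(h5file["n"])
    assert out[0] == 1 and out[2] == 3 and pd.isna(out[1])


def test_all_masked_nullable(h5file):
    arr = pd.arrays.IntegerArray(np.zeros(4, dtype=np.int64), np.ones(4, dtype=bool))
    codec.write_nullable(h5file, "n", arr)
    out = codec.read_nullable(h5file["n"])
    assert len(out) == 4 and out.isna().all()


def test_nullable_boolean_roundtrip_vs_reference_file(tmp_path):
    anndata = pytest.importorskip("anndata")
    col = pd.array([True, None, False], dtype="boolean")
    obs = pd.DataFrame({"b": col}, index=["c0", "c1", "c2"])
    a = anndata.AnnData(obs=obs, shape=(3, 0))
    path = tmp_path / "ref.h5ad"
    a.write_h5ad(path)
    with h5py.File(path) as f:
        out = codec.read_nullable(f["obs/b"])
    assert values_equal(out, col)


def test_nullable_length_mismatch_rejected(h5file):
    g = h5file.create_group("n")
    codec._write_encoding_attrs(g, "nullable-integer")
    g.create_dataset("values", data=np.arange(3))
    g.create_dataset("mask", data=np.zeros(2, dtype=bool))
    with pytest.raises(ElementValidationError, match="mask length"):
        codec.read_nullable(g)


# ---------------------------------------------------------------------------
# dataframes


def test_zero_column_dataframe_keeps_index(h5file):
    df = pd.DataFrame(index=pd.Index(["c1", "c2"]))
    codec.write_dataframe(h5file, "df", df)
    out = codec.read_dataframe(h5file["df"])
    assert list(out.index) == ["c1", "c2"] and out.shape == (2, 0)


def test_mixed_column_dataframe_roundtrips(h5file):
    df = pd.DataFrame(
        {
            "celltype": pd.Categorical(["a", "b", "a", "b", "a"]),
            "n_genes": np.arange(5),
            "qc": pd.array([True, None, False, True, None], dtype="boolean"),
        },
        index=[f"c{i}" for i in range(5)],
    )
    codec.write_dataframe(h5file, "df", df)
    out = codec.read_dataframe(h5file["df"])
    assert values_equal(out, df)


def test_column_order_is_preserved_not_alphabetised(h5file):
    df = pd.DataFrame({"b": [1, 2], "a": [3, 4]}, index=["r0", "r1"])
    codec.write_dataframe(h5file, "df", df)
    out = codec.read_dataframe(h5file["df"])
    assert list(out.columns) == ["b", "a"]


def test_duplicate_column_names_rejected(h5file):
    df = pd.DataFrame(np.zeros((2, 2)), columns=["x", "x"], index=["a", "b"])
    with pytest.raises(EncodingError, match="duplicate column"):
        codec.write_dataframe(h5file, "df", df)


def test_named_index_roundtrips(h5file):
    df = pd.DataFrame({"v": [1]}, index=pd.Index(["r"], name="barcode"))
    codec.write_dataframe(h5file, "df", df)
    out = codec.read_dataframe(h5file["df"])
    assert out.index.name == "barcode"


# ---------------------------------------------------------------------------
# mappings and scalars


def test_mapping_roundtrips(h5file):
    payload = {"params": {"k": 15, "method": "umap"}, "colors":
               np.asarray(["#aaa", "#bbb"], dtype=object)}
    codec.write_mapping(h5file, "uns", payload)
    assert values_equal(codec.read_mapping(h5file["uns"]), payload)

    codec.write_mapping(h5file, "empty", {})
    assert codec.read_mapping(h5file["empty"]) == {}

    deep = {"1": {"2": {"3": {"4": {"5": {"6": "leaf"}}}}}}
    codec.write_mapping(h5file, "deep", deep)
    assert codec.read_mapping(h5file["deep"]) == deep


def test_mapping_cycle_is_an_error(h5file):
    d = {"a": {}}
    d["a"]["loop"] = d
    with pytest.raises(EncodingError, match="cycle"):
        codec.write_mapping(h5file, "uns", d)


def test_mapping_key_order_preserved(h5file):
    payload = {"zeta": 1, "alpha": 2, "mid": 3}
    codec.write_mapping(h5file, "uns", payload)
    assert list(codec.read_mapping(h5file["uns"])) == ["zeta", "alpha", "mid"]


@pytest.mark.parametrize("value,encoding", [
    (7, "numeric-scalar"),
    (2.5, "numeric-scalar"),
    (True, "numeric-scalar"),
    ("hello", "string"),
])
def test_scalars_reencode_as_scalars(h5file, value, encoding):
    codec.write_element(h5file, "v", value)
    assert codec.detect_encoding(h5file["v"]).encoding_type == encoding
    out = codec.read_element(h5file["v"])
    assert out == value and not isinstance(out, np.ndarray)
    assert h5file["v"].shape == ()
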