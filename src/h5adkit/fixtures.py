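"""Deterministic synthetic fixtures.

Every test in the package runs on containers produced here — no
external dataset is downloaded.  :func:`generate` builds a container
from a :class:`FixtureSpec` (a size, a seed and a set of feature
toggles); :func:`corpus` enumerates a fixed, named collection of specs
that jointly covers every encoding in the codec registry plus the
enumerated edge cases (empty axes, missing X, unicode, all-missing
columns, duplicate and underscore-bearing names).

Values are drawn from simple distributions — Poisson-like integers for
count matrices, standard normals for embeddings.  Nothing here aims at
biological realism: the corpus exercises the *format*, and determinism
(same spec + seed → deep-equal container) is the only distributional
property the tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .model import AnnDataContainer, Raw

__all__ = ["FixtureSpec", "generate", "corpus", "TOGGLES"]

TOGGLES = frozenset({
    "dense_X", "sparse_csr_X", "sparse_csc_X", "layers", "raw", "categoricals",
    "nullable_cols", "nested_uns", "obsm_varm_pair", "obsp", "varp", "empty_slots",
    "unicode_strings", "missing_values", "duplicate_names", "underscore_names",
})

_X_TOGGLES = ("dense_X", "sparse_csr_X", "sparse_csc_X")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic container."""

    n_obs: int = 50
    n_var: int = 20
    seed: int = 0
    features: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        unknown = set(self.features) - TOGGLES
        if unknown:
            raise ValueError(f"unknown fixture toggles: {sorted(unknown)}")
        if sum(t in self.features for t in _X_TOGGLES) > 1:
            raise ValueError("at most one X toggle may be set")
        if self.n_obs < 0 or self.n_var < 0:
            raise ValueError("dimensions must be non-negative")


def _spec(n_obs=50, n_var=20, seed=0, *features) -> FixtureSpec:
    return FixtureSpec(n_obs=n_obs, n_var=n_var, seed=seed,
                       features=frozenset(features))


def _names(prefix: str, n: int, spec: FixtureSpec) -> list[str]:
    sep = "_" if "underscore_names" in spec.features else ""
    names = [f"{prefix}{sep}{i}" for i in range(n)]
    if "duplicate_names" in spec.features and n >= 2:
        names[1] = names[0]
    return names


def _counts(rng, shape, fmt: str | None):
    if fmt is None:
        return rng.poisson(1.5, size=shape).astype(np.float64)
    m = sparse.random(*shape, density=0.3, format="csr", random_state=rng,
                      data_rvs=lambda n: rng.poisson(2.0, n).astype(np.float64) + 1.0)
    return m.asformat(fmt)


def generate(spec: FixtureSpec) -> AnnDataContainer:
    """Build the container described by ``spec``.

    Deterministic for a fixed seed; the output always passes
    :meth:`~h5adkit.model.AnnDataContainer.validate` and every toggled
    feature is discoverable by slot inspection.
    """
    rng = np.random.default_rng(spec.seed)
    n_obs, n_var = spec.n_obs, spec.n_var
    feats = spec.features
    unicode_on = "unicode_strings" in feats

    obs = pd.DataFrame(index=pd.Index(_names("cell", n_obs, spec)))
    obs["n_genes"] = rng.integers(100, 5000, n_obs)
    score = rng.random(n_obs)
    if "missing_values" in feats and n_obs:
        score[:: max(n_obs // 3, 1)] = np.nan
    obs["score"] = score
    obs["batch"] = np.asarray(
        [("δείγμα" if unicode_on else "sample") + str(i % 2) for i in range(n_obs)],
        dtype=object)
    if "categoricals" in feats:
        labels = ["Tζcell" if unicode_on else "T cell", "B cell", "NK"]
        codes = rng.integers(0, len(labels), n_obs)
        if "missing_values" in feats and n_obs:
            codes[:: max(n_obs // 4, 1)] = -1
        obs["celltype"] = pd.Categorical.from_codes(codes, categories=labels)
        obs["grade"] = pd.Categorical.from_codes(
            rng.integers(0, 3, n_obs), categories=["low", "mid", "high"], ordered=True)
    if "nullable_cols" in feats:
        qc = rng.random(n_obs) > 0.5
        hits = rng.integers(0, 10, n_obs)
        mask = (rng.random(n_obs) < 0.25) if "missing_values" in feats \
            else np.zeros(n_obs, dtype=bool)
        if "missing_values" in feats and n_obs:
            all_missing = np.ones(n_obs, dtype=bool)
            obs["dropout"] = pd.arrays.BooleanArray(np.zeros(n_obs, dtype=bool),
                                                    all_missing)
        obs["qc_pass"] = pd.arrays.BooleanArray(qc, mask.copy())
        obs["n_hits"] = pd.arrays.IntegerArray(hits.astype(np.int64), mask.copy())

    var = pd.DataFrame(index=pd.Index(_names("gene", n_var, spec)))
    var["symbol"] = np.asarray([f"SYM{i}" for i in range(n_var)], dtype=object)
    var["dispersion"] = rng.normal(size=n_var)
    var["highly_variable"] = rng.random(n_var) > 0.5

    X = None
    if "dense_X" in feats:
        X = _counts(rng, (n_obs, n_var), None)
    elif "sparse_csr_X" in feats:
        X = _counts(rng, (n_obs, n_var), "csr")
    elif "sparse_csc_X" in feats:
        X = _counts(rng, (n_obs, n_var), "csc")

    layers = {}
    if "layers" in feats:
        layers["logcounts"] = rng.normal(size=(n_obs, n_var))
        layers["spliced"] = sparse.random(n_obs, n_var, density=0.2, format="csr",
                                          random_state=rng)

    obsm, varm = {}, {}
    if "obsm_varm_pair" in feats:
        k = 5
        obsm["X_pca"] = rng.normal(size=(n_obs, k))
        obsm["X_umap"] = rng.normal(size=(n_obs, 2))
        varm["pca"] = rng.normal(size=(n_var, k))       # pairs with X_pca
        varm["PCs_extra"] = rng.normal(size=(n_var, 3))  # pairs with nothing
    if "empty_slots" in feats:
        obsm["empty"] = np.zeros((n_obs, 0))

    obsp = {}
    if "obsp" in feats:
        obsp["distances"] = sparse.random(n_obs, n_obs, density=0.1, format="csr",
                                          random_state=rng)
        obsp["connectivities"] = rng.random((n_obs, n_obs))
    varp = {}
    if "varp" in feats:
        varp["gene_correlation"] = rng.normal(size=(n_var, n_var))

    uns: dict = {"generator": "h5adkit.fixtures", "seed": int(spec.seed)}
    if "nested_uns" in feats:
        uns["params"] = {
            "k": 15,
            "method": "umap",
            "rate": 0.5,
            "flag": True,
            "weights": rng.normal(size=4),
            "level2": {"level3": {"level4": {"level5": {"level6": "deep leaf"}}}},
        }
        uns["colors"] = np.asarray(["#aaaaaa", "#bbbbbb"], dtype=object)
        if unicode_on:
            uns["τίτλος"] = "σμίκρυνση διαστάσεων"
    if "empty_slots" in feats:
        uns["empty_dict"] = {}

    raw = None
    if "raw" in feats:
        n_var_raw = n_var + 5
        raw_var = pd.DataFrame(index=pd.Index([f"gene{i}" for i in range(n_var_raw)]))
        raw_var["kept"] = np.arange(n_var_raw) < n_var
        raw = Raw(X=_counts(rng, (n_obs, n_var_raw), "csr"), var=raw_var,
                  varm={"loadings": rng.normal(size=(n_var_raw, 3))})

    return AnnDataContainer(X=X, obs=obs, var=var, layers=layers, obsm=obsm,
                            varm=varm, obsp=obsp, varp=varp, uns=uns, raw=raw)


def corpus() -> list[tuple[str, FixtureSpec]]:
    """The fixed, named fixture corpus used by every test suite.

    Covers each encoding in isolation, everything combined, and each
    enumerated edge case.  Its size and contents are stable across runs.
    """
    all_content = ("sparse_csr_X", "layers", "raw", "categoricals", "nullable_cols",
                   "nested_uns", "obsm_varm_pair", "obsp", "varp", "empty_slots",
                   "unicode_strings", "missing_values")
    return [
        ("minimal_no_X", _spec(10, 8, 11)),
        ("dense_X", _spec(30, 12, 12, "dense_X")),
        ("sparse_csr", _spec(30, 12, 13, "sparse_csr_X")),
        ("sparse_csc", _spec(30, 12, 14, "sparse_csc_X")),
        ("layers", _spec(20, 10, 15, "dense_X", "layers")),
        ("raw_snapshot", _spec(20, 10, 16, "sparse_csr_X", "raw")),
        ("categoricals", _spec(40, 8, 17, "dense_X", "categoricals")),
        ("nullable_columns", _spec(40, 8, 18, "dense_X", "nullable_cols")),
        ("nested_uns", _spec(10, 6, 19, "dense_X", "nested_uns")),
        ("obsm_varm", _spec(25, 10, 20, "dense_X", "obsm_varm_pair")),
        ("obsp", _spec(25, 10, 21, "dense_X", "obsp")),
        ("varp", _spec(25, 10, 22, "dense_X", "varp")),
        ("empty_slots", _spec(12, 6, 23, "dense_X", "empty_slots")),
        ("unicode", _spec(12, 6, 24, "dense_X", "unicode_strings", "categoricals")),
        ("missing_values", _spec(30, 8, 25, "dense_X", "missing_values",
                                 "categoricals", "nullable_cols")),
        ("everything", FixtureSpec(n_obs=50, n_var=20, seed=1,
                                   features=frozenset(all_content))),
        ("zero_obs", _spec(0, 8, 26, "dense_X", "categoricals", "nullable_cols")),
        ("zero_var", _spec(10, 0, 27, "dense_X")),
        ("zero_by_zero", _spec(0, 0, 28)),
        ("duplicate_names", _spec(10, 6, 29, "dense_X", "duplicate_names")),
        ("underscore_names", _spec(10, 6, 30, "dense_X", "underscore_names")),
    ]
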