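"""Core multivariate pattern analysis.

Three ingredients, combined in 10-fold cross-validation per run:

* **Searchlight Fisher-ratio voxel selection.**  A searchlight of radius
  sqrt(2) voxel units (center + 6 face + 12 edge neighbours = 19 voxels) is
  centred at every masked voxel; within the neighbourhood the Fisher
  discriminant ratio J of the two categories is computed from the training
  trials and assigned to the center.  The K voxels with the highest J are
  selected (K = 1500 by default).

* **Cosine reproducibility.**  On the held-out fold (8 trials, 4 per
  class), the mean pairwise cosine over the 12 same-class pairs
  (r_within) and the 16 cross-class pairs (r_between) are combined into
  the reproducibility ratio R = r_within / r_between.

* **Linear SVM decoding** (C = 1) of the trial category from the selected
  voxels, with the per-fold weight map kept for group localization.

Numerics: with two classes, J along the Fisher direction w =
(S_W + lambda*I)^-1 (m1 - m2) equals the quadratic form
Delta' (S_W + lambda*I)^-1 Delta, which is what we evaluate.  Writing the
within-class scatter as the total scatter minus a rank-one term,
S_W = S_T - gamma * Delta Delta' with gamma = n1*n2/n, gives via
Sherman-Morrison J = u / (1 - alpha*u) with u = Delta' A^-1 Delta,
A = S_T/(n-2) + lambda*I and alpha = gamma/(n-2).  A is label-free, so its
inverse is precomputed once per fold and reused across label permutations.
The ridge is lambda = ridge_scale * tr(S_T/(n-2))/p, also label-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn import config_context
from sklearn.svm import SVC

from .preprocess import TrialPatternSet

DEFAULT_RADIUS = np.sqrt(2.0)
DEFAULT_K = 1500
RIDGE_SCALE = 1e-6
#: |r_between| below this leaves the fold's ratio undefined.  The mean
#: cosine over the 16 cross-class pairs of a test fold has sampling noise
#: of roughly this size, so a smaller denominator carries no information
#: and its ratio would be arbitrarily large.
EPS_BETWEEN = 0.05


class MvpaError(ValueError):
    pass


@dataclass(frozen=True)
class SearchlightSpec:
    radius_voxels: float
    offsets: np.ndarray  # (m, 3) int, lexicographically sorted, contains origin


def searchlight_offsets(radius_voxels: float = DEFAULT_RADIUS) -> SearchlightSpec:
    """All integer offsets within a Euclidean ball of the given radius."""
    if radius_voxels < 0:
        raise MvpaError("radius must be nonnegative")
    r = int(np.floor(radius_voxels))
    axis = np.arange(-r, r + 1)
    grid = np.stack(np.meshgrid(axis, axis, axis, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = (grid**2).sum(axis=1) <= radius_voxels**2 + 1e-12
    offs = grid[keep]
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return SearchlightSpec(radius_voxels=float(radius_voxels), offsets=offs[order])


def _neighborhood_table(
    voxel_index: np.ndarray, mask_shape, spec: SearchlightSpec
) -> np.ndarray:
    """(V, m) table of pattern-column neighbours per center; -1 where the
    searchlight is truncated by the mask/voxel set."""
    V = len(voxel_index)
    flat = np.ravel_multi_index(voxel_index.T, mask_shape)
    lookup = np.full(int(np.prod(mask_shape)), -1, dtype=np.int64)
    lookup[flat] = np.arange(V)
    m = len(spec.offsets)
    nb = np.full((V, m), -1, dtype=np.int64)
    shape = np.asarray(mask_shape)
    for j, off in enumerate(spec.offsets):
        pos = voxel_index + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        nb[ok, j] = lookup[np.ravel_multi_index(pos[ok].T, mask_shape)]
    return nb


@dataclass
class FisherRatioMap:
    values: np.ndarray  # (V,) J >= 0
    voxel_index: np.ndarray
    degenerate: np.ndarray  # bool flags for all-constant neighbourhoods


@dataclass
class FoldReproducibility:
    r_within: float
    r_between: float
    ratio: float
    undefined: bool = False


@dataclass
class ReproducibilityResult:
    per_fold: list[FoldReproducibility]
    mean_r_within: float
    mean_r_between: float
    mean_ratio: float
    n_undefined: int = 0


@dataclass
class DecodingResult:
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    weight_maps: np.ndarray  # (n_folds, V); unselected voxels are zero
    selected: list[np.ndarray] = field(default_factory=list)


def pair_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unordered same-class and cross-class index pairs.

    For the standard 4 + 4 test fold this yields 6 pairs per class, 12
    same-class pairs in total and 16 cross-class pairs.
    """
    labels = np.asarray(labels)
    n = len(labels)
    ii, jj = np.triu_indices(n, k=1)
    same = labels[ii] == labels[jj]
    within = np.stack([ii[same], jj[same]], axis=1)
    between = np.stack([ii[~same], jj[~same]], axis=1)
    return within, between


def reproducibility(
    patterns: np.ndarray,
    labels: np.ndarray,
    form: str = "ratio",
    eps: float = EPS_BETWEEN,
) -> FoldReproducibility:
    """Within/between-class mean cosine similarity and their ratio.

    ``patterns`` holds one test fold: 8 trials, 4 per class.  The
    reproducibility index of a pair is the cosine of the angle between the
    two pattern vectors.  When |r_between| < eps the ratio is undefined and
    flagged (the difference form has no such degeneracy).
    """
    X = np.asarray(patterns, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(labels) != X.shape[0]:
        raise MvpaError("patterns must be (n_trials, K) with matching labels")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts[0] != counts[1]:
        raise MvpaError("need exactly two balanced classes in the test fold")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise MvpaError("zero-norm pattern vector")
    U = X / norms[:, None]
    C = U @ U.T
    within, between = pair_indices(labels)
    r_w = float(C[within[:, 0], within[:, 1]].mean())
    r_b = float(C[between[:, 0], between[:, 1]].mean())
    if form == "difference":
        return FoldReproducibility(r_w, r_b, r_w - r_b)
    if form != "ratio":
        raise MvpaError(f"unknown reproducibility form {form!r}")
    if abs(r_b) < eps:
        return FoldReproducibility(r_w, r_b, np.nan, undefined=True)
    return FoldReproducibility(r_w, r_b, r_w / r_b)


def summarize_folds(per_fold: list[FoldReproducibility]) -> ReproducibilityResult:
    ok = [f for f in per_fold if not f.undefined]
    n_undef = len(per_fold) - len(ok)
    if n_undef:
        warnings.warn(
            f"{n_undef} fold(s) with near-zero between-class reproducibility "
            "excluded from the fold average"
        )
    if not ok:
        return ReproducibilityResult(per_fold, np.nan, np.nan, np.nan, n_undef)
    return ReproducibilityResult(
        per_fold,
        mean_r_within=float(np.mean([f.r_within for f in ok])),
        mean_r_between=float(np.mean([f.r_between for f in ok])),
        mean_ratio=float(np.mean([f.ratio for f in ok])),
        n_undefined=n_undef,
    )


class SearchlightFisher:
    """Batched searchlight Fisher-ratio computation with label-free caches."""

    def __init__(
        self,
        patterns: np.ndarray,
        voxel_index: np.ndarray,
        mask_shape,
        spec: SearchlightSpec | None = None,
        ridge_scale: float = RIDGE_SCALE,
        dtype=np.float64,
    ):
        self.spec = spec or searchlight_offsets()
        self.X = np.asarray(patterns, dtype=dtype)
        self.V = self.X.shape[1]
        self.voxel_index = voxel_index
        nb = _neighborhood_table(voxel_index, mask_shape, self.spec)
        self.nbp = np.where(nb < 0, self.V, nb)  # pad -> extra zero column
        self.ridge_scale = ridge_scale
        self._Xp = np.concatenate(
            [self.X, np.zeros((self.X.shape[0], 1), dtype=self.X.dtype)], axis=1
        )
        # per-trial neighbourhood outer products are accumulated lazily
        self._sum_all = None
        self._scat_all = None

    def _gather(self, rows) -> np.ndarray:
        return self._Xp[rows][:, self.nbp]  # (n, V, m)

    def _totals(self):
        if self._scat_all is None:
            G = self._gather(slice(None))
            self._scat_all = np.einsum("tvm,tvp->vmp", G, G, optimize=True)
            self._sum_all = G.sum(axis=0)
        return self._scat_all, self._sum_all

    def fold_cache(self, train_rows: np.ndarray) -> dict:
        """Invert the ridged total-scatter matrices of the training trials."""
        n = len(train_rows)
        if n < 4:
            raise MvpaError("need >= 2 trials per class to compute scatter")
        all_rows = np.arange(self.X.shape[0])
        test_rows = np.setdiff1d(all_rows, train_rows)
        if len(test_rows) <= len(train_rows) // 4:
            scat_all, sum_all = self._totals()
            Gt = self._gather(test_rows)
            scat = scat_all - np.einsum("tvm,tvp->vmp", Gt, Gt, optimize=True)
            s = sum_all - Gt.sum(axis=0)
        else:
            G = self._gather(train_rows)
            scat = np.einsum("tvm,tvp->vmp", G, G, optimize=True)
            s = G.sum(axis=0)
        mean = s / n
        scat = scat - n * np.einsum("vm,vp->vmp", mean, mean)
        scat /= n - 2  # covariance scale, pooled dof
        m = scat.shape[-1]
        tr = np.einsum("vmm->v", scat)
        p_valid = np.maximum((self.nbp < self.V).sum(axis=1), 1)
        lam = self.ridge_scale * tr / p_valid + 1e-12
        degenerate = tr < 1e-10
        eye = np.eye(m, dtype=scat.dtype)
        A = scat + lam[:, None, None].astype(scat.dtype) * eye
        A[degenerate] = eye
        return {
            "Ainv": np.linalg.inv(A),
            "train_rows": np.asarray(train_rows),
            "n": n,
            "degenerate": degenerate,
        }

    def ratios(self, cache: dict, labels: np.ndarray) -> FisherRatioMap:
        """Fisher ratio map for one labeling, using a fold cache."""
        rows = cache["train_rows"]
        y = np.asarray(labels)[rows]
        classes = np.unique(y)
        if len(classes) != 2:
            raise MvpaError("need exactly two classes")
        n1, n2 = (y == classes[0]).sum(), (y == classes[1]).sum()
        if min(n1, n2) < 2:
            raise MvpaError("need >= 2 trials per class")
        d_full = (
            self.X[rows][y == classes[0]].mean(axis=0)
            - self.X[rows][y == classes[1]].mean(axis=0)
        )
        d = np.concatenate([d_full, [0.0]])[self.nbp]  # (V, m)
        t = (cache["Ainv"] @ d[:, :, None])[:, :, 0]
        u = (d * t).sum(axis=1)
        alpha = (n1 * n2 / cache["n"]) / (cache["n"] - 2)
        J = u / np.maximum(1.0 - alpha * u, 1e-12)
        J = np.where(cache["degenerate"], 0.0, np.maximum(J, 0.0))
        return FisherRatioMap(values=J, voxel_index=self.voxel_index,
                              degenerate=cache["degenerate"])


def fisher_ratio_map(
    patterns: TrialPatternSet | np.ndarray,
    labels: np.ndarray,
    spec: SearchlightSpec | None = None,
    voxel_index: np.ndarray | None = None,
    mask_shape=None,
    ridge_scale: float = RIDGE_SCALE,
) -> FisherRatioMap:
    """Searchlight Fisher-ratio map from a full training set."""
    if isinstance(patterns, TrialPatternSet):
        voxel_index = patterns.voxel_index
        mask_shape = patterns.mask_shape
        patterns = patterns.patterns
    sl = SearchlightFisher(patterns, voxel_index, mask_shape, spec, ridge_scale)
    cache = sl.fold_cache(np.arange(patterns.shape[0]))
    return sl.ratios(cache, labels)


def select_top_k(fmap: FisherRatioMap | np.ndarray, K: int,
                 voxel_index: np.ndarray | None = None) -> np.ndarray:
    """Columns of the K highest Fisher ratios; ties broken by lexicographic
    voxel coordinate for determinism."""
    if isinstance(fmap, FisherRatioMap):
        values, voxel_index = fmap.values, fmap.voxel_index
    else:
        values = np.asarray(fmap)
    if K > len(values):
        raise MvpaError(f"K={K} exceeds the {len(values)} masked voxels")
    vi = voxel_index
    order = np.lexsort((vi[:, 2], vi[:, 1], vi[:, 0], -values))
    return np.sort(order[:K])


class CvEngine:
    """Fold-wise selection + SVM machinery, reusable across relabelings.

    Voxel selection and classifier training only ever see the 72 training
    trials of the current fold; the 8 held-out trials are used for the
    reproducibility statistics and the accuracy.  ``selection_scope="all"``
    deliberately breaks this (selection on all trials) and exists solely so
    tests can demonstrate the leakage inflation.
    """

    def __init__(
        self,
        pattern_set: TrialPatternSet,
        K: int = DEFAULT_K,
        spec: SearchlightSpec | None = None,
        C: float = 1.0,
        ridge_scale: float = RIDGE_SCALE,
        selection_scope: str = "fold",
        dtype=np.float32,
    ):
        if selection_scope not in ("fold", "all"):
            raise MvpaError("selection_scope must be 'fold' or 'all'")
        self.ps = pattern_set
        self.K = K
        self.C = C
        self.selection_scope = selection_scope
        # float32 suffices for voxel ranking; reproducibility and the SVM
        # run on the original float64 patterns
        self.sl = SearchlightFisher(
            pattern_set.patterns, pattern_set.voxel_index, pattern_set.mask_shape,
            spec, ridge_scale, dtype=dtype,
        )
        self.folds = np.unique(pattern_set.fold_assignment)
        self._caches = {}
        all_rows = np.arange(pattern_set.n_trials)
        for k in self.folds:
            train = all_rows[pattern_set.fold_assignment != k]
            self._caches[k] = self.sl.fold_cache(train)
        if selection_scope == "all":
            self._cache_all = self.sl.fold_cache(all_rows)

    def run(
        self,
        labels: np.ndarray,
        compute_repro: bool = True,
        ratio_form: str = "ratio",
    ) -> tuple[ReproducibilityResult | None, DecodingResult]:
        labels = np.asarray(labels)
        X = self.ps.patterns
        V = self.ps.n_voxels
        accs, wmaps, sels, per_fold = [], [], [], []
        with config_context(assume_finite=True, skip_parameter_validation=True):
            for k in self.folds:
                cache = self._caches[k]
                train = cache["train_rows"]
                test = np.flatnonzero(self.ps.fold_assignment == k)
                if self.selection_scope == "all":
                    fmap = self.sl.ratios(self._cache_all, labels)
                else:
                    fmap = self.sl.ratios(cache, labels)
                sel = select_top_k(fmap, self.K)
                clf = SVC(kernel="linear", C=self.C)
                clf.fit(X[np.ix_(train, sel)], labels[train])
                coef = clf.coef_.ravel()
                # manual scoring (decision function of a fitted linear SVM)
                dec_val = X[np.ix_(test, sel)] @ coef + clf.intercept_[0]
                pred = np.where(dec_val > 0, clf.classes_[1], clf.classes_[0])
                accs.append(float(np.mean(pred == labels[test])))
                w = np.zeros(V)
                w[sel] = coef
                wmaps.append(w)
                sels.append(sel)
                if compute_repro:
                    per_fold.append(
                        reproducibility(X[np.ix_(test, sel)], labels[test],
                                        form=ratio_form)
                    )
        dec = DecodingResult(
            per_fold_accuracy=np.array(accs),
            mean_accuracy=float(np.mean(accs)),
            weight_maps=np.array(wmaps),
            selected=sels,
        )
        rep = summarize_folds(per_fold) if compute_repro else None
        return rep, dec


def crossvalidated_mvpa(
    pattern_set: TrialPatternSet,
    feature: str,
    K: int = DEFAULT_K,
    spec: SearchlightSpec | None = None,
    C: float = 1.0,
    ratio_form: str = "ratio",
    selection_scope: str = "fold",
) -> tuple[ReproducibilityResult, DecodingResult]:
    """10-fold cross-validated reproducibility ratio and decoding accuracy
    for one semantic feature of one run."""
    engine = CvEngine(pattern_set, K=K, spec=spec, C=C, selection_scope=selection_scope)
    rep, dec = engine.run(pattern_set.labels(feature), ratio_form=ratio_form)
    return rep, dec
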