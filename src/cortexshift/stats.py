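"""Permutation-based group inference on surface maps, with TFCE and FWE.

Vertex-wise tests (one-sample t, two-sample t, one-way F) are combined
with threshold-free cluster enhancement and family-wise error correction
through the permutation distribution of the maximum enhanced statistic —
the same logic as PALM-style analysis, re-implemented here for surface
metric maps.  One-sample tests use sign-flipping of subject maps; group
comparisons permute group labels; the identity permutation is always
included, so no corrected p-value can fall below 1/(P+1).

Global summaries get one-way ANOVA with Tukey HSD pairwise comparisons and
Cohen's d; ROI tables get one-way MANOVA (Pillai's trace) per metric and
per-ROI pairwise t-tests with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._tfce import tfce_map, tfce_max_batch
from .meshcore import MetricMap, SurfaceMesh, vertex_areas

__all__ = [
    "TfceParams",
    "PermutationScheme",
    "StatReport",
    "one_sample_t_map",
    "anova_f_map",
    "tfce_enhance",
    "permutation_fwe",
    "global_anova_tukey",
    "cohens_d",
    "roi_group_tests",
]


@dataclass
class TfceParams:
    """TFCE exponents and integration resolution.

    ``H`` weights height, ``E`` cluster extent (surface-data convention
    H=2, E=1); the integral uses ``n_steps`` equal steps up to the map
    maximum (``dh`` = max/n_steps).
    """

    H: float = 2.0
    E: float = 1.0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0 or self.n_steps < 1:
            raise ValueError("invalid TFCE parameters")


@dataclass
class PermutationScheme:
    """How the permutation null is built.

    ``kind`` is ``sign_flip`` (one-sample) or ``label_permutation``;
    ``n_permutations`` counts random permutations in addition to the
    identity.  When the full permutation group is small (2^n <= 4096 for
    sign flips, <= 10,000 label assignments) it is enumerated exhaustively.
    """

    kind: str = "sign_flip"
    n_permutations: int = 1000
    seed: int = 0
    exhaustive: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("sign_flip", "label_permutation"):
            raise ValueError("kind must be sign_flip or label_permutation")
        if self.n_permutations < 100 and not self.exhaustive:
            raise ValueError("need at least 100 permutations (or exhaustive)")


@dataclass
class StatReport:
    stat_map: MetricMap
    tfce_map: MetricMap
    fwe_p_map: MetricMap
    tables: dict = field(default_factory=dict)
    n_permutations: int = 0
    details: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# vertex-wise statistics (vectorized over vertices)


def _stack(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=float)
    return np.vstack([m.values if isinstance(m, MetricMap) else np.asarray(m) for m in maps])


def one_sample_t_map(maps, mask=None) -> MetricMap:
    """Per-vertex one-sample t = mean / (sd / sqrt(n)); zero-variance vertices get t=0."""
    X = _stack(maps)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    t = np.zeros(X.shape[1])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    if not ok.all():
        warnings.warn("zero-variance vertices flagged with t=0", stacklevel=2)
    if mask is not None:
        m = mask.values if hasattr(mask, "values") else np.asarray(mask, bool)
        t[~m] = 0.0
    return MetricMap(t, units="statistic")


def _f_from_groups(groups: list[np.ndarray]) -> np.ndarray:
    ns = np.array([g.shape[0] for g in groups], dtype=float)
    k = len(groups)
    N = ns.sum()
    means = np.vstack([g.mean(axis=0) for g in groups])
    grand = (means * ns[:, None]).sum(axis=0) / N
    ss_between = ((means - grand) ** 2 * ns[:, None]).sum(axis=0)
    ss_within = sum(((g - m) ** 2).sum(axis=0) for g, m in zip(groups, means))
    msb = ss_between / (k - 1)
    msw = ss_within / (N - k)
    F = np.zeros_like(msb)
    ok = msw > 0
    F[ok] = msb[ok] / msw[ok]
    return F


def anova_f_map(groups: dict[str, object], mask=None) -> MetricMap:
    """Per-vertex one-way F across >= 2 groups; zero within-variance flagged as 0."""
    gs = [_stack(v) for v in groups.values()]
    if len(gs) < 2 or any(g.shape[0] < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    F = _f_from_groups(gs)
    if mask is not None:
        m = mask.values if hasattr(mask, "values") else np.asarray(mask, bool)
        F[~m] = 0.0
    return MetricMap(F, units="statistic")


# ---------------------------------------------------------------------------
# TFCE


def _masked_adjacency(mesh: SurfaceMesh, mask: np.ndarray):
    e = mesh.edges()
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    e = e[keep]
    both = np.vstack([e, e[:, ::-1]])
    order = np.argsort(both[:, 0], kind="stable")
    src = both[order, 0]
    dst = both[order, 1]
    indptr = np.concatenate(
        [[0], np.cumsum(np.bincount(src, minlength=mesh.n_vertices))]
    ).astype(np.int64)
    return indptr, dst.astype(np.int64)


def tfce_enhance(
    stat_map,
    mesh: SurfaceMesh,
    vertex_area_map=None,
    params: TfceParams | None = None,
    mask=None,
) -> MetricMap:
    """Threshold-free cluster enhancement of a signed statistic map.

    Positive and negative tails are enhanced separately (the negative tail
    on the negated map, re-negated).  Cluster extent is the vertex-area sum
    of the edge-connected component, restricted to the mask.
    """
    params = params or TfceParams()
    values = stat_map.values if isinstance(stat_map, MetricMap) else np.asarray(stat_map, float)
    va = (
        vertex_area_map.values
        if isinstance(vertex_area_map, MetricMap)
        else np.asarray(vertex_area_map, float)
        if vertex_area_map is not None
        else vertex_areas(mesh).values
    )
    m = (
        np.ones(mesh.n_vertices, bool)
        if mask is None
        else (mask.values if hasattr(mask, "values") else np.asarray(mask, bool))
    )
    vals = np.where(m, np.nan_to_num(values), 0.0)
    indptr, indices = _masked_adjacency(mesh, m)
    out = tfce_map(vals, indptr, indices, va, params.E, params.H, params.n_steps)
    return MetricMap(out, mesh.name, "statistic")


# ---------------------------------------------------------------------------
# permutations


def _sign_matrix(n: int, scheme: PermutationScheme) -> np.ndarray:
    exhaustive = scheme.exhaustive
    if exhaustive is None:
        exhaustive = 2**n <= 4096
    if exhaustive:
        if 2**n < 20:
            raise ValueError("too few subjects for >= 20 distinct permutations")
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        S = 1.0 - 2.0 * bits
        # put the identity (all +1) first
        idx = np.flatnonzero((S == 1).all(axis=1))[0]
        S[[0, idx]] = S[[idx, 0]]
        return S
    rng = np.random.default_rng(scheme.seed)
    S = 1.0 - 2.0 * rng.integers(0, 2, size=(scheme.n_permutations + 1, n))
    S[0] = 1.0
    return S


def _label_assignments(ns: list[int], scheme: PermutationScheme) -> np.ndarray:
    """(P, N) arrays of group indices; row 0 is the observed assignment."""
    N = sum(ns)
    base = np.concatenate([np.full(n, i) for i, n in enumerate(ns)])
    total = math.factorial(N)
    for n in ns:
        total //= math.factorial(n)
    exhaustive = scheme.exhaustive
    if exhaustive is None:
        exhaustive = total <= 10_000
    if exhaustive:
        if total < 20:
            raise ValueError("too few subjects for >= 20 distinct permutations")
        perms = sorted(set(itertools.permutations(base)))
        A = np.array(perms, dtype=np.int64)
        idx = int(np.flatnonzero((A == base).all(axis=1))[0])
        A[[0, idx]] = A[[idx, 0]]
        return A
    rng = np.random.default_rng(scheme.seed)
    A = np.empty((scheme.n_permutations + 1, N), dtype=np.int64)
    A[0] = base
    for p in range(1, scheme.n_permutations + 1):
        A[p] = base[rng.permutation(N)]
    return A


def _perm_t_one_sample(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    mean = (S @ X) / n
    ssq = (X**2).sum(axis=0)
    var = (ssq[None, :] - n * mean**2) / (n - 1)
    sd = np.sqrt(np.clip(var, 0.0, None))
    t = np.zeros_like(mean)
    np.divide(mean, sd / np.sqrt(n), out=t, where=sd > 0)
    return t


def _perm_stats_labels(X: np.ndarray, A: np.ndarray, k: int, statistic: str) -> np.ndarray:
    """Two-sample t or one-way F maps for each label assignment row."""
    N, V = X.shape
    X2 = X**2
    out = np.empty((A.shape[0], V))
    for p in range(A.shape[0]):
        lab = A[p]
        if statistic == "t":
            g0 = lab == 0
            n1 = int(g0.sum())
            n2 = N - n1
            s1 = X[g0].sum(axis=0)
            s2 = X[~g0].sum(axis=0)
            q1 = X2[g0].sum(axis=0)
            q2 = X2[~g0].sum(axis=0)
            m1, m2 = s1 / n1, s2 / n2
            sp2 = (q1 - n1 * m1**2 + q2 - n2 * m2**2) / (N - 2)
            denom = np.sqrt(np.clip(sp2, 0.0, None) * (1.0 / n1 + 1.0 / n2))
            t = np.zeros(V)
            np.divide(m1 - m2, denom, out=t, where=denom > 0)
            out[p] = t
        else:
            groups = [X[lab == g] for g in range(k)]
            out[p] = _f_from_groups(groups)
    return out


def permutation_fwe(
    data,
    test: str,
    mesh: SurfaceMesh,
    mask=None,
    tfce_params: TfceParams | None = None,
    scheme: PermutationScheme | None = None,
    tail: str | None = None,
) -> StatReport:
    """Vertex-wise permutation inference with TFCE and FWE correction.

    Parameters
    ----------
    data
        For ``test="one_sample"``: an ``(n, V)`` array (or list of maps) of
        subject change maps.  For ``"pairwise"`` (two-sample) and
        ``"anova"``: a dict mapping group label to such an array.
    test
        ``one_sample`` (sign-flipping), ``pairwise`` (two-group label
        permutation t) or ``anova`` (label-permutation one-way F).
    tail
        ``less``/``greater``/``two``; defaults: one-sample tests for loss
        (``less``), pairwise is two-tailed, F is inherently one-tailed.

    The corrected p-value at v is the fraction of permutations (identity
    included) whose maximum TFCE over the mask reaches the observed TFCE
    at v.
    """
    tfce_params = tfce_params or TfceParams()
    m = (
        np.ones(mesh.n_vertices, bool)
        if mask is None
        else (mask.values if hasattr(mask, "values") else np.asarray(mask, bool))
    )
    va = vertex_areas(mesh).values
    indptr, indices = _masked_adjacency(mesh, m)

    if test == "one_sample":
        X = np.nan_to_num(_stack(data))
        X[:, ~m] = 0.0
        scheme = scheme or PermutationScheme("sign_flip")
        S = _sign_matrix(X.shape[0], scheme)
        stats_all = _perm_t_one_sample(X, S)
        tail = tail or "less"
    elif test in ("pairwise", "anova"):
        if not isinstance(data, dict):
            raise ValueError("group tests need a dict of group -> maps")
        names = list(data.keys())
        gs = [np.nan_to_num(_stack(data[g])) for g in names]
        if test == "pairwise" and len(gs) != 2:
            raise ValueError("pairwise test needs exactly two groups")
        X = np.vstack(gs)
        X[:, ~m] = 0.0
        scheme = scheme or PermutationScheme("label_permutation")
        if scheme.kind != "label_permutation":
            scheme = PermutationScheme(
                "label_permutation", scheme.n_permutations, scheme.seed, scheme.exhaustive
            )
        A = _label_assignments([g.shape[0] for g in gs], scheme)
        stat_kind = "t" if test == "pairwise" else "f"
        stats_all = _perm_stats_labels(X, A, len(gs), stat_kind)
        tail = tail or ("two" if test == "pairwise" else "greater")
    else:
        raise ValueError(f"unknown test {test!r}")

    obs = stats_all[0]
    if tail == "less":
        signed = -stats_all
        two_sided = False
    elif tail == "greater":
        signed = stats_all
        two_sided = False
    elif tail == "two":
        signed = stats_all
        two_sided = True
    else:
        raise ValueError("tail must be less, greater or two")

    obs_tfce_signed = tfce_map(
        signed[0], indptr, indices, va, tfce_params.E, tfce_params.H, tfce_params.n_steps
    )
    obs_mag = np.abs(obs_tfce_signed) if two_sided else np.clip(obs_tfce_signed, 0.0, None)
    null_max = tfce_max_batch(
        np.ascontiguousarray(signed),
        indptr, indices, va,
        tfce_params.E, tfce_params.H, tfce_params.n_steps,
        1 if two_sided else 0,
    )
    P = len(null_max)
    fwe_p = (null_max[None, :] >= obs_mag[:, None]).sum(axis=1) / P
    fwe_p = np.clip(fwe_p, 1.0 / P, 1.0)
    fwe_p[~m] = 1.0

    return StatReport(
        stat_map=MetricMap(obs, mesh.name, "statistic"),
        tfce_map=MetricMap(obs_tfce_signed if not two_sided else obs_tfce_signed, mesh.name,
                           "statistic"),
        fwe_p_map=MetricMap(fwe_p, mesh.name, "p"),
        n_permutations=P,
        details={"tail": tail, "test": test},
    )


# ---------------------------------------------------------------------------
# global and ROI tables


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference with the pooled-SD denominator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if sp == 0:
        return 0.0
    return float((x.mean() - y.mean()) / sp)


def global_anova_tukey(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with Tukey HSD pairwise p-values and Cohen's d.

    ``groups`` maps label -> 1-D array of one global measure per subject.
    Returns the overall F and p plus a pairwise table.
    """
    names = list(groups.keys())
    arrays = [np.asarray(groups[g], float) for g in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2")
    if all(np.allclose(a, arrays[0].mean()) for a in arrays) and all(
        a.var() == 0 for a in arrays
    ):
        F, p = 0.0, 1.0
    else:
        F, p = sps.f_oneway(*arrays)
        if not np.isfinite(F):
            F, p = 0.0, 1.0
    tuk = sps.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "mean_diff": arrays[i].mean() - arrays[j].mean(),
                "tukey_p": float(tuk.pvalue[i, j]),
                "cohens_d": cohens_d(arrays[i], arrays[j]),
            }
        )
    return {"F": float(F), "p": float(p), "pairwise": pd.DataFrame(rows)}


def _pillai_trace(Y: np.ndarray, labels: np.ndarray) -> float:
    """Pillai's trace for a one-way design: tr(H (H + E)^-1)."""
    groups = np.unique(labels)
    grand = Y.mean(axis=0)
    H = np.zeros((Y.shape[1], Y.shape[1]))
    E = np.zeros_like(H)
    for g in groups:
        Yg = Y[labels == g]
        d = (Yg.mean(axis=0) - grand)[:, None]
        H += len(Yg) * (d @ d.T)
        R = Yg - Yg.mean(axis=0)
        E += R.T @ R
    HE = H + E
    return float(np.trace(H @ np.linalg.pinv(HE)))


def roi_group_tests(roi_table: pd.DataFrame, metrics=("d_thick_log2", "d_area_log2", "d_vol_log2")) -> dict:
    """MANOVA across ROIs per metric, plus Bonferroni pairwise per-ROI t-tests.

    The response matrix for each metric is subjects x ROIs.  If there are
    fewer subjects than ROIs + groups, the highest-variance ROI subset is
    used (with a warning).  The Bonferroni factor is the number of ROI
    tests times the number of group pairs.
    """
    from statsmodels.multivariate.manova import MANOVA

    out: dict = {"manova": {}, "pairwise": None}
    groups = sorted(roi_table["group"].unique())
    pair_rows = []
    for metric in metrics:
        wide = roi_table.pivot_table(index=["subject_id", "group"], columns="roi", values=metric)
        wide = wide.dropna(axis=1)
        labels = np.array([g for (_, g) in wide.index])
        Y = wide.to_numpy()
        n, r = Y.shape
        max_r = n - len(groups) - 1
        if r > max_r:
            warnings.warn(
                f"{metric}: reducing ROI set from {r} to {max_r} (n too small for MANOVA)",
                stacklevel=2,
            )
            keep = np.argsort(Y.var(axis=0))[::-1][:max_r]
            Y = Y[:, sorted(keep)]
            wide = wide.iloc[:, sorted(keep)]
            r = Y.shape[1]
        try:
            df = pd.DataFrame(Y, columns=[f"roi{c}" for c in wide.columns])
            df["group"] = labels
            mv = MANOVA.from_formula(
                " + ".join(df.columns[:-1]) + " ~ group", data=df
            ).mv_test()
            tab = mv.results["group"]["stat"]
            out["manova"][metric] = {
                "pillai": float(tab.loc["Pillai's trace", "Value"]),
                "F": float(tab.loc["Pillai's trace", "F Value"]),
                "p": float(tab.loc["Pillai's trace", "Pr > F"]),
            }
        except Exception as exc:  # singular within-covariance and friends
            warnings.warn(f"MANOVA fell back to direct Pillai computation: {exc}", stacklevel=2)
            out["manova"][metric] = {"pillai": _pillai_trace(Y, labels), "F": np.nan, "p": np.nan}

        rois = list(wide.columns)
        n_tests = len(rois) * math.comb(len(groups), 2) * len(metrics)
        for roi in rois:
            col = wide[roi]
            for ga, gb in itertools.combinations(groups, 2):
                a = col[labels == ga].to_numpy()
                b = col[labels == gb].to_numpy()
                t, p = sps.ttest_ind(a, b)
                pair_rows.append(
                    {
                        "metric": metric,
                        "roi": roi,
                        "group_a": ga,
                        "group_b": gb,
                        "t": float(t),
                        "p_raw": float(p),
                        "p_bonferroni": min(1.0, float(p) * n_tests),
                        "cohens_d": cohens_d(a, b),
                    }
                )
    out["pairwise"] = pd.DataFrame(pair_rows)
    return out
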