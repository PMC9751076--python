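"""Recursive standardized path analysis of stability drivers.

The model links sown richness (SR_log) to community stability through the
windowed biodiversity effects and the stability components: richness
drives the windowed complementarity (CE) and selection (SE) effects and
productivity (ANPP); CE, SE and ANPP drive population stability
(CVpop_inv); richness, CE and SE drive asynchrony (Async); and asynchrony
together with population stability determine community stability
(CommStab). Residuals of CE and SE, and of Async and CVpop_inv, are
allowed to covary.

Because the system is recursive (acyclic) and every disturbance is
uncorrelated with its equation's regressors, the standardized coefficients
are estimated equation-wise: each endogenous node is regressed on its
parents by ordinary least squares on standardized data. For such systems
the equation-wise estimates coincide with full-information SEM point
estimates when the free residual covariances involve only terminal
disturbances; a test verifies that Wright-style implied correlations
reproduce observed correlations on model-generated data. Inference is by
nonparametric bootstrap over plots (rows), which also propagates to
indirect effects (products of chain coefficients) and to between-window
coefficient differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPSILON_MINMAX = 1e-3

NODES = ("SR_log", "CE", "SE", "ANPP", "CVpop_inv", "Async", "CommStab")

_DEFAULT_EDGES = (
    ("SR_log", "CE"),
    ("SR_log", "SE"),
    ("SR_log", "ANPP"),
    ("CE", "ANPP"),
    ("SE", "ANPP"),
    ("SR_log", "CVpop_inv"),
    ("CE", "CVpop_inv"),
    ("SE", "CVpop_inv"),
    ("ANPP", "CVpop_inv"),
    ("SR_log", "Async"),
    ("CE", "Async"),
    ("SE", "Async"),
    ("CVpop_inv", "CommStab"),
    ("Async", "CommStab"),
)

_DEFAULT_RESID_COV = (("CE", "SE"), ("Async", "CVpop_inv"))


@dataclass(frozen=True)
class PathModelSpec:
    """Directed acyclic path model: nodes, edges, free residual covariances."""

    nodes: tuple[str, ...] = NODES
    edges: tuple[tuple[str, str], ...] = _DEFAULT_EDGES
    residual_covariances: tuple[tuple[str, str], ...] = _DEFAULT_RESID_COV

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge ({a}, {b}) references an undeclared node")
        self.topological_order()  # raises on cycles

    def parents(self, node: str) -> list[str]:
        return [a for a, b in self.edges if b == node]

    def endogenous(self) -> list[str]:
        return [n for n in self.topological_order() if self.parents(n)]

    def topological_order(self) -> list[str]:
        indeg = {n: 0 for n in self.nodes}
        for _, b in self.edges:
            indeg[b] += 1
        order, queue = [], [n for n in self.nodes if indeg[n] == 0]
        while queue:
            n = queue.pop(0)
            order.append(n)
            for a, b in self.edges:
                if a == n:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        queue.append(b)
        if len(order) != len(self.nodes):
            raise ValueError("path model graph contains a cycle")
        return order

    def all_paths(self, source: str, target: str) -> list[tuple[tuple[str, str], ...]]:
        """All directed edge chains from source to target."""
        out: list[tuple[tuple[str, str], ...]] = []

        def walk(node: str, trail: tuple[tuple[str, str], ...]) -> None:
            if node == target:
                out.append(trail)
                return
            for a, b in self.edges:
                if a == node:
                    walk(b, trail + ((a, b),))

        walk(source, ())
        return out


def default_path_spec() -> PathModelSpec:
    """The default stability path model (see module docstring)."""
    return PathModelSpec()


def default_chains() -> dict[str, tuple[tuple[str, str], ...]]:
    """Named indirect-effect chains from richness to community stability."""
    spec = default_path_spec()
    chains = {}
    for trail in spec.all_paths("SR_log", "CommStab"):
        label = "->".join([trail[0][0]] + [b for _, b in trail])
        chains[label] = trail
    return chains


def minmax_log(values: np.ndarray, epsilon: float = EPSILON_MINMAX) -> np.ndarray:
    """Min-max scale to [0, 1], clamp below at epsilon, then log.

    Keeps the order of values while making a sign-mixed, heavy-tailed
    effect usable under a log transform.
    """
    v = np.asarray(values, dtype=float)
    span = np.nanmax(v) - np.nanmin(v)
    if span == 0:
        raise ValueError("cannot min-max scale a constant column")
    scaled = np.clip((v - np.nanmin(v)) / span, epsilon, None)
    return np.log(scaled)


def assemble_window_nodes(
    window_metrics: pd.DataFrame, window_effects: pd.DataFrame
) -> pd.DataFrame:
    """Merge stability metrics and windowed effects into raw node columns."""
    merged = window_metrics.merge(
        window_effects[["plot_id", "CE", "SE", "window_ANPP_sum", "outlier_flag"]],
        on="plot_id",
        how="inner",
    )
    # row ids carry the window span so group comparisons can verify that
    # two groups use disjoint (plot, year) observations
    end = merged["window_start"] + merged["width"] - 1
    row_id = merged["plot_id"].astype(str) + "|y" + merged["window_start"].astype(str) + "-" + end.astype(str)
    return pd.DataFrame(
        {
            "plot_id": row_id,
            "SR_raw": merged["N_sown"],
            "CE_raw": merged["CE"],
            "SE_raw": merged["SE"],
            "ANPP_raw": merged["window_ANPP_sum"],
            "CVpop_inv_raw": merged["pop_stability"],
            "Async_raw": merged["asynchrony"],
            "CommStab_raw": merged["stability"],
            "outlier_flag": merged["outlier_flag"].astype(bool),
        }
    )


def prepare_path_data(
    raw: pd.DataFrame, epsilon: float = EPSILON_MINMAX, drop_outliers: bool = True
) -> pd.DataFrame:
    """Transform and standardize raw node columns for path fitting.

    Transforms: SR = log(sown richness); CommStab, CVpop_inv and ANPP are
    log-transformed; CE is min-max scaled to [ε, 1] then log-transformed;
    SE and Async enter untransformed. Every node is then standardized to
    mean 0, SD 1. Rows with any undefined value are dropped and counted in
    the ``attrs['n_dropped']`` of the result.

    Raises
    ------
    ValueError
        If fewer than 10 usable rows remain or a node has zero variance.
    """
    df = raw
    if drop_outliers and "outlier_flag" in df:
        df = df[~df["outlier_flag"].astype(bool)]
    with np.errstate(invalid="ignore", divide="ignore"):
        nodes = pd.DataFrame(
            {
                "SR_log": np.log(df["SR_raw"].to_numpy(dtype=float)),
                "CE": minmax_log(df["CE_raw"].to_numpy(dtype=float), epsilon),
                "SE": df["SE_raw"].to_numpy(dtype=float),
                "ANPP": np.log(df["ANPP_raw"].to_numpy(dtype=float)),
                "CVpop_inv": np.log(df["CVpop_inv_raw"].to_numpy(dtype=float)),
                "Async": df["Async_raw"].to_numpy(dtype=float),
                "CommStab": np.log(df["CommStab_raw"].to_numpy(dtype=float)),
            },
            index=df.index,
        )
    keep = np.isfinite(nodes.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    nodes = nodes[keep]
    if len(nodes) < 10:
        raise ValueError(f"only {len(nodes)} usable rows; need >= 10 for identification")
    sd = nodes.std(ddof=1)
    zero_var = sd[sd == 0].index.tolist()
    if zero_var:
        raise ValueError(f"zero variance node(s): {zero_var}")
    out = (nodes - nodes.mean()) / sd
    out.attrs["n_dropped"] = n_dropped
    if "plot_id" in raw:
        out.insert(0, "plot_id", raw.loc[nodes.index, "plot_id"])
    return out


def _standardize(mat: np.ndarray) -> np.ndarray:
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    return (mat - mu) / sd


def _equationwise(mat: np.ndarray, cols: dict[str, int], spec: PathModelSpec) -> np.ndarray:
    """Standardized edge coefficients, one per spec edge, via per-equation OLS."""
    coefs = np.empty(len(spec.edges))
    for node in spec.endogenous():
        parents = spec.parents(node)
        X = mat[:, [cols[p] for p in parents]]
        cond = np.linalg.cond(X.T @ X)
        if cond > 1e8:
            raise ValueError(f"collinear parents {parents} of {node} (condition number {cond:.3g})")
        beta, *_ = np.linalg.lstsq(X, mat[:, cols[node]], rcond=None)
        for p, b in zip(parents, beta):
            coefs[spec.edges.index((p, node))] = b
    return coefs


@dataclass
class PathResult:
    """Fitted recursive path model for one window/group."""

    label: str
    spec: PathModelSpec
    edges: pd.DataFrame  # src, dst, coef, ci_lo, ci_hi, p
    r2: dict[str, float]
    residual_cov: dict[tuple[str, str], float]
    boot: np.ndarray  # n_boot × n_edges replicate coefficients
    n: int
    row_ids: tuple = ()

    def coef(self, src: str, dst: str) -> float:
        return float(self.edges.set_index(["src", "dst"]).loc[(src, dst), "coef"])

    def implied_correlations(self, source: str = "SR_log") -> dict[str, float]:
        """Wright-style implied correlation of each node with the source.

        Computed recursively in topological order:
        r(S, Y) = Σ_parents β_{p→Y} · r(S, p), with r(S, S) = 1. Valid
        because every disturbance is uncorrelated with the source.
        """
        implied = {source: 1.0}
        for node in self.spec.topological_order():
            if node == source or not self.spec.parents(node):
                continue
            implied[node] = sum(
                self.coef(p, node) * implied[p] for p in self.spec.parents(node)
            )
        return implied

    def total_effect(self, source: str, target: str) -> float:
        """Direct plus all indirect effects of source on target."""
        return float(
            sum(
                np.prod([self.coef(a, b) for a, b in trail])
                for trail in self.spec.all_paths(source, target)
            )
        )


class PathModel:
    """Fit-shaped front end for the recursive path analysis.

    Parameters
    ----------
    spec : PathModelSpec
        The acyclic model; defaults to the stability model.
    n_boot : int
        Bootstrap replicates for CIs and p-values (>= 1000 recommended).
    seed : int
        Bootstrap seed; fixed seed gives exactly reproducible inference.
    """

    def __init__(self, spec: PathModelSpec | None = None, n_boot: int = 1000, seed: int = 0):
        self.spec = spec or default_path_spec()
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, data: pd.DataFrame, label: str = "") -> PathResult:
        """Fit the model on a standardized node table (rows = plots)."""
        spec = self.spec
        node_cols = [n for n in spec.nodes]
        mat = data[node_cols].to_numpy(dtype=float)
        cols = {n: k for k, n in enumerate(node_cols)}
        n = mat.shape[0]

        coefs = _equationwise(mat, cols, spec)

        r2 = {}
        resid = {}
        for node in spec.endogenous():
            parents = spec.parents(node)
            X = mat[:, [cols[p] for p in parents]]
            beta = np.array([coefs[spec.edges.index((p, node))] for p in parents])
            e = mat[:, cols[node]] - X @ beta
            resid[node] = e
            r2[node] = 1.0 - e.var(ddof=0) / mat[:, cols[node]].var(ddof=0)
        residual_cov = {}
        for a, b in spec.residual_covariances:
            ea = resid.get(a, mat[:, cols[a]])
            eb = resid.get(b, mat[:, cols[b]])
            residual_cov[(a, b)] = float(np.cov(ea, eb, ddof=1)[0, 1])

        rng = np.random.default_rng(self.seed)
        boot = np.empty((self.n_boot, len(spec.edges)))
        for r in range(self.n_boot):
            idx = rng.integers(0, n, size=n)
            sample = mat[idx]
            if (sample.std(axis=0) == 0).any():  # degenerate resample: redraw
                idx = rng.integers(0, n, size=n)
                sample = mat[idx]
            boot[r] = _equationwise(_standardize(sample), cols, spec)

        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        p = 2 * np.minimum((boot <= 0).mean(axis=0), (boot >= 0).mean(axis=0))
        edges = pd.DataFrame(
            {
                "src": [a for a, _ in spec.edges],
                "dst": [b for _, b in spec.edges],
                "coef": coefs,
                "ci_lo": lo,
                "ci_hi": hi,
                "p": np.minimum(p, 1.0),
            }
        )
        row_ids = tuple(data["plot_id"]) if "plot_id" in data else tuple(data.index)
        return PathResult(
            label=label, spec=spec, edges=edges, r2=r2,
            residual_cov=residual_cov, boot=boot, n=n, row_ids=row_ids,
        )


def fit_paths(
    data: pd.DataFrame,
    spec: PathModelSpec | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    label: str = "",
) -> PathResult:
    """Functional wrapper over :class:`PathModel`. See its docstring."""
    return PathModel(spec=spec, n_boot=n_boot, seed=seed).fit(data, label=label)


def indirect_effects(
    result: PathResult, chains: dict[str, tuple[tuple[str, str], ...]] | None = None
) -> pd.DataFrame:
    """Indirect effects (products of chain coefficients) with bootstrap CIs.

    Each chain's effect is the product of its standardized edge
    coefficients; the CI is obtained by recomputing the product within
    every bootstrap replicate of the fit.
    """
    chains = default_chains() if chains is None else chains
    spec = result.spec
    rows = []
    for name, trail in chains.items():
        idx = []
        for edge in trail:
            if edge not in spec.edges:
                raise ValueError(f"chain {name!r} references edge {edge} absent from the model")
            idx.append(spec.edges.index(edge))
        effect = float(np.prod([result.edges["coef"].iloc[i] for i in idx]))
        boot_prod = result.boot[:, idx].prod(axis=1)
        lo, hi = np.percentile(boot_prod, [2.5, 97.5])
        p = 2 * min((boot_prod <= 0).mean(), (boot_prod >= 0).mean())
        rows.append(
            {
                "label": result.label, "chain": name, "length": len(trail),
                "effect": effect, "ci_lo": lo, "ci_hi": hi, "p": min(p, 1.0),
            }
        )
    return pd.DataFrame(rows)


def _letters_from_adjacency(names: list[str], same: np.ndarray) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not distinguishable.

    Brute-force maximal cliques of the "not significantly different" graph;
    group counts here are tiny (typically 3 windows).
    """
    from itertools import combinations

    k = len(names)
    cliques: list[frozenset[int]] = []
    for size in range(k, 0, -1):
        for subset in combinations(range(k), size):
            if all(same[i, j] for i, j in combinations(subset, 2)):
                fs = frozenset(subset)
                if not any(fs < c for c in cliques):
                    cliques.append(fs)
    cliques = sorted({c for c in cliques if not any(c < d for d in cliques)}, key=min)
    letters = {n: "" for n in names}
    for letter, cl in zip("abcdefghij", cliques):
        for i in sorted(cl):
            letters[names[i]] += letter
    return letters


def compare_groups(results: list[PathResult]) -> pd.DataFrame:
    """Pairwise differences of edge coefficients between fitted groups.

    Groups must be fitted on disjoint observations: row ids of the form
    ``plot|yA-B`` (as produced by :func:`assemble_window_nodes`) expand to
    their (plot, year) pairs, so the same plots measured in
    non-overlapping windows count as disjoint, while overlapping windows
    are rejected. Differences use the two groups' independent bootstrap
    distributions. Letter groupings are derived at α = 0.05, unadjusted:
    groups sharing a letter are not significantly different on that edge.
    """
    import re

    def expand(row_id) -> set:
        m = re.match(r"^(.*)\|y(\d+)-(\d+)$", str(row_id))
        if m:
            return {(m.group(1), y) for y in range(int(m.group(2)), int(m.group(3)) + 1)}
        return {(str(row_id), None)}

    if len(results) < 2:
        raise ValueError("need at least two fitted groups to compare")
    obs = [set().union(*(expand(r) for r in res.row_ids)) for res in results]
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            if obs[i] & obs[j]:
                raise ValueError(
                    f"groups {results[i].label!r} and {results[j].label!r} share rows; "
                    "between-group comparison assumes independent samples"
                )
    spec = results[0].spec
    rows = []
    names = [r.label for r in results]
    for e_idx, (src, dst) in enumerate(spec.edges):
        same = np.eye(len(results), dtype=bool)
        for i in range(len(results)):
            for j in range(i + 1, len(results)):
                bi, bj = results[i].boot[:, e_idx], results[j].boot[:, e_idx]
                m = min(len(bi), len(bj))
                diff = bi[:m] - bj[:m]
                lo, hi = np.percentile(diff, [2.5, 97.5])
                p = min(2 * min((diff <= 0).mean(), (diff >= 0).mean()), 1.0)
                same[i, j] = same[j, i] = p >= 0.05
                rows.append(
                    {
                        "src": src, "dst": dst,
                        "group_a": names[i], "group_b": names[j],
                        "coef_a": results[i].edges["coef"].iloc[e_idx],
                        "coef_b": results[j].edges["coef"].iloc[e_idx],
                        "difference": results[i].edges["coef"].iloc[e_idx]
                        - results[j].edges["coef"].iloc[e_idx],
                        "ci_lo": lo, "ci_hi": hi, "p": p,
                    }
                )
        letters = _letters_from_adjacency(names, same)
        for row in rows[-(len(results) * (len(results) - 1) // 2):]:
            row["letters_a"] = letters[row["group_a"]]
            row["letters_b"] = letters[row["group_b"]]
    return pd.DataFrame(rows)


def indirect_trends(
    chain_tables: pd.DataFrame, time: str = "window_index", time_transform: str = "linear"
) -> pd.DataFrame:
    """Regress per-window indirect effects on the window index.

    ``chain_tables`` concatenates :func:`indirect_effects` outputs over
    windows with a window-index column; at least 3 windows are required.
    """
    from divstab.slopes import _fit

    rows = []
    for chain, sub in chain_tables.groupby("chain"):
        sub = sub[np.isfinite(sub["effect"])]
        if len(sub) < 3:
            raise ValueError(f"chain {chain!r}: need >= 3 windows for a trend, got {len(sub)}")
        t = sub[time].to_numpy(dtype=float)
        if time_transform == "log":
            t = np.log(t - t.min() + 1.0)
        res = _fit(t, sub["effect"].to_numpy(dtype=float))
        rows.append(
            {
                "chain": chain, "trend": res["b"], "intercept": res["intercept"],
                "stderr": res["stderr"], "p": res["p"], "r2": res["r2"], "n": res["n"],
            }
        )
    return pd.DataFrame(rows)
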