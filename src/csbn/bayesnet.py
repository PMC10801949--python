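"""Discrete Bayesian networks: structure learning, CPTs, inference.

Structure is learned by tabu search over single-edge additions, deletions
and reversals scored by the decomposable BIC for multinomial networks,
subject to whitelist (forced) and blacklist (forbidden) edge constraints.
Robustness comes from nonparametric-bootstrap model averaging: the fraction
of bootstrap networks containing each arc is its strength, and
high-strength arcs become the whitelist of a final learning pass.

Parameters are maximum-likelihood conditional frequencies; queries are
answered by likelihood weighting (forward sampling with evidence nodes
clamped and weighted by their conditional probability).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cohort_io import Cohort

__all__ = [
    "DAG",
    "CPT",
    "DiscreteBN",
    "StructureConstraints",
    "ArcStrengths",
    "encode_categorical",
    "score_dag",
    "learn_structure_tabu",
    "bootstrap_arc_strengths",
    "average_model",
    "fit_parameters_mle",
    "likelihood_weighting_query",
    "dag_to_csv",
    "dag_from_csv",
    "constraints_from_csv",
]

logger = logging.getLogger(__name__)

TABU_LENGTH = 10
STAGNATION_PATIENCE = 15


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph over named nodes."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self):
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop {u}->{v}")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge {u}->{v} references unknown node")
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, x: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == x))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))


@dataclass
class CPT:
    """Conditional probability table of one node given its parents.

    ``table`` has one row per parent-level combination (row index is the
    C-order ravel of parent level indices) and one column per node level;
    rows sum to 1.
    """

    node: str
    parents: tuple[str, ...]
    levels: tuple[str, ...]
    parent_levels: tuple[tuple[str, ...], ...]
    table: np.ndarray

    def __post_init__(self):
        cards = tuple(len(l) for l in self.parent_levels)
        expected_rows = int(np.prod(cards)) if cards else 1
        if self.table.shape != (expected_rows, len(self.levels)):
            raise ValueError(f"{self.node}: CPT shape {self.table.shape} mismatch")
        if np.any(self.table < 0) or np.any(self.table > 1):
            raise ValueError(f"{self.node}: probabilities outside [0,1]")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.node}: CPT rows must sum to 1")

    def row_index(self, parent_idx: np.ndarray) -> np.ndarray:
        """Row index for (n, n_parents) integer parent assignments."""
        if not self.parents:
            return np.zeros(len(parent_idx), dtype=int)
        cards = tuple(len(l) for l in self.parent_levels)
        return np.ravel_multi_index(tuple(parent_idx.T), cards)


@dataclass
class DiscreteBN:
    """A DAG plus one CPT per node."""

    dag: DAG
    cpts: dict[str, CPT]
    levels: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for node {node}")
            if self.cpts[node].parents != self.dag.parents(node):
                raise ValueError(f"CPT parents disagree with DAG for {node}")


@dataclass(frozen=True)
class StructureConstraints:
    """Forced-present (whitelist) and forbidden (blacklist) edges."""

    whitelist: frozenset[tuple[str, str]] = frozenset()
    blacklist: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self):
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ValueError(f"edges both white- and blacklisted: {sorted(overlap)}")

    def restricted_to(self, nodes) -> "StructureConstraints":
        keep = lambda es: frozenset(
            (u, v) for u, v in es if u in nodes and v in nodes
        )
        return StructureConstraints(keep(self.whitelist), keep(self.blacklist))


@dataclass
class ArcStrengths:
    """Bootstrap inclusion fraction per ordered node pair."""

    strength: dict[tuple[str, str], float]
    B: int
    nodes: tuple[str, ...] = ()

    def direction_agreement(self, u: str, v: str) -> float:
        """Fraction of networks containing either orientation that chose
        u -> v; 0.5 when the arc never appeared."""
        f, b = self.strength.get((u, v), 0.0), self.strength.get((v, u), 0.0)
        return 0.5 if f + b == 0 else f / (f + b)


# ---------------------------------------------------------------------------
# data encoding and scoring


def encode_categorical(cohort: Cohort, variables: list[str]) -> tuple[np.ndarray, dict]:
    """Integer-code categorical columns; returns (N, k) int matrix and the
    per-variable level tuples. Rows with missing values are rejected."""
    levels = {}
    cols = []
    for name in variables:
        spec = cohort.spec(name)
        if spec.kind != "categorical":
            raise ValueError(f"{name}: BN variables must be categorical")
        col = cohort.df[name]
        if col.isna().any():
            raise ValueError(f"{name}: missing values present; use complete cases")
        lut = {lev: i for i, lev in enumerate(spec.levels)}
        cols.append(col.astype(str).map(lut).to_numpy(dtype=np.int64))
        levels[name] = tuple(spec.levels)
    return np.column_stack(cols), levels


class _Scorer:
    """Cached per-family BIC scores on an integer-coded data matrix."""

    def __init__(self, data: np.ndarray, cards: np.ndarray):
        self.data = data
        self.cards = cards
        self.N = data.shape[0]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        if key in self._cache:
            return self._cache[key]
        r = int(self.cards[v])
        q = int(np.prod(self.cards[list(parents)])) if parents else 1
        # joint cell index over (parents, node)
        idx = self.data[:, v].copy()
        stride = r
        for p in parents:
            idx += self.data[:, p] * stride
            stride *= int(self.cards[p])
        counts = np.bincount(idx, minlength=r * q).astype(float).reshape(q, r)
        rowsums = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(np.nansum(counts * (np.log(counts) - np.log(rowsums))))
        penalty = 0.5 * math.log(self.N) * (r - 1) * q
        score = ll - penalty
        self._cache[key] = score
        return score


def score_dag(cohort: Cohort, dag: DAG) -> float:
    """Total BIC of a DAG on complete-case data: sum of family scores."""
    data, levels = encode_categorical(cohort, list(dag.nodes))
    cards = np.array([len(levels[n]) for n in dag.nodes])
    pos = {n: i for i, n in enumerate(dag.nodes)}
    scorer = _Scorer(data, cards)
    return sum(
        scorer.family_score(pos[v], tuple(sorted(pos[u] for u in dag.parents(v))))
        for v in dag.nodes
    )


# ---------------------------------------------------------------------------
# tabu structure search


def _has_path(parent_sets, start, goal, n):
    """True if `goal` is reachable from `start` following child links."""
    # parent_sets: list of sets; edge u->v iff u in parent_sets[v]
    children = [[] for _ in range(n)]
    for v in range(n):
        for u in parent_sets[v]:
            children[u].append(v)
    stack, seen = [start], {start}
    while stack:
        x = stack.pop()
        if x == goal:
            return True
        for c in children[x]:
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def learn_structure_tabu(
    cohort: Cohort,
    constraints: StructureConstraints | None = None,
    score: str = "bic",
    seed: int = 0,
    max_iter: int | None = None,
) -> DAG:
    """Tabu search maximizing the BIC over DAGs.

    Starts from the whitelist-only graph and repeatedly applies the best
    non-tabu single-edge move (add / delete / reverse), keeping a tabu list
    of the last 10 inverse moves; the best-scoring DAG visited is returned.
    Deterministic for a given input (ties broken by lexicographic move
    order); ``seed`` is accepted for interface symmetry with the bootstrap.

    Whitelisted edges are never removed, blacklisted edges never added.
    """
    if score != "bic":
        raise ValueError(f"unsupported score {score!r}")
    variables = cohort.covariate_names
    constraints = (constraints or StructureConstraints()).restricted_to(set(variables))
    data, levels = encode_categorical(cohort, variables)
    cards = np.array([len(levels[n]) for n in variables])
    n = len(variables)
    pos = {v: i for i, v in enumerate(variables)}
    scorer = _Scorer(data, cards)

    white = {(pos[u], pos[v]) for u, v in constraints.whitelist}
    black = {(pos[u], pos[v]) for u, v in constraints.blacklist}

    parent_sets: list[set] = [set() for _ in range(n)]
    for u, v in white:
        parent_sets[v].add(u)
    # whitelist feasibility
    try:
        DAG(
            tuple(variables),
            frozenset((variables[u], variables[v]) for u, v in white),
        )
    except ValueError as err:
        raise ValueError(f"infeasible constraints: {err}") from err

    def fam(v):
        return scorer.family_score(v, tuple(sorted(parent_sets[v])))

    def fam_with(v, parents):
        return scorer.family_score(v, tuple(sorted(parents)))

    current = sum(fam(v) for v in range(n))
    best_score = current
    best_edges = {(u, v) for v in range(n) for u in parent_sets[v]}

    if max_iter is None:
        max_iter = 10 * n * n
    tabu: list[tuple] = []
    stagnation = 0

    for _ in range(max_iter):
        moves = []  # (delta, kind, u, v)
        edges = [(u, v) for v in range(n) for u in sorted(parent_sets[v])]
        present = set(edges)
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                if (u, v) in present:
                    continue
                if (u, v) in black:
                    continue
                if _has_path(parent_sets, v, u, n):
                    continue
                delta = fam_with(v, parent_sets[v] | {u}) - fam(v)
                moves.append((delta, "add", u, v))
        for u, v in sorted(present):
            if (u, v) in white:
                continue
            delta = fam_with(v, parent_sets[v] - {u}) - fam(v)
            moves.append((delta, "del", u, v))
            if (v, u) not in black:
                parent_sets[v].discard(u)
                cyc = _has_path(parent_sets, u, v, n)
                parent_sets[v].add(u)
                if not cyc:
                    d = (
                        fam_with(v, parent_sets[v] - {u})
                        + fam_with(u, parent_sets[u] | {v})
                        - fam(v)
                        - fam(u)
                    )
                    moves.append((d, "rev", u, v))
        if not moves:
            break
        moves.sort(key=lambda m: (-m[0], m[1], m[2], m[3]))
        chosen = None
        for delta, kind, u, v in moves:
            move_id = (kind, u, v)
            aspiration = current + delta > best_score + 1e-12
            if move_id in tabu and not aspiration:
                continue
            chosen = (delta, kind, u, v)
            break
        if chosen is None:
            break
        delta, kind, u, v = chosen
        if kind == "add":
            parent_sets[v].add(u)
            tabu.append(("del", u, v))
        elif kind == "del":
            parent_sets[v].discard(u)
            tabu.append(("add", u, v))
        else:
            parent_sets[v].discard(u)
            parent_sets[u].add(v)
            tabu.append(("rev", v, u))
        tabu = tabu[-TABU_LENGTH:]
        current += delta
        if current > best_score + 1e-12:
            best_score = current
            best_edges = {(a, b) for b in range(n) for a in parent_sets[b]}
            stagnation = 0
        else:
            stagnation += 1
            if stagnation >= STAGNATION_PATIENCE:
                break

    return DAG(
        tuple(variables),
        frozenset((variables[u], variables[v]) for u, v in best_edges),
    )


def bootstrap_arc_strengths(
    cohort: Cohort,
    constraints: StructureConstraints | None = None,
    B: int = 200,
    seed: int = 0,
) -> ArcStrengths:
    """Learn structure on B nonparametric bootstrap resamples; an arc's
    strength is the fraction of resampled networks containing it."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[tuple[str, str], int] = {}
    for _ in range(B):
        idx = rng.integers(0, cohort.N, size=cohort.N)
        boot = cohort.subset(idx)
        dag = learn_structure_tabu(boot, constraints)
        for edge in dag.edges:
            counts[edge] = counts.get(edge, 0) + 1
    strengths = {edge: c / B for edge, c in counts.items()}
    return ArcStrengths(strengths, B, tuple(cohort.covariate_names))


def average_model(strengths: ArcStrengths, threshold: float = 0.5) -> StructureConstraints:
    """Arcs with strength >= threshold become the whitelist for the final
    structure-learning pass.

    If both orientations of a pair qualify, the stronger one is kept
    (majority direction). Remaining cycles are broken by dropping the
    lowest-strength arc on each cycle.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    chosen: dict[tuple[str, str], float] = {}
    for (u, v), s in strengths.strength.items():
        if s < threshold:
            continue
        rev = strengths.strength.get((v, u), 0.0)
        if rev >= threshold:
            if (s, (v, u)) < (rev, (u, v)):  # keep majority; ties lexicographic
                continue
        chosen[(u, v)] = s
    g = nx.DiGraph()
    g.add_edges_from(chosen)
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: (chosen[(e[0], e[1])], e))
        logger.info("average_model: dropping cyclic arc %s (strength %.3f)",
                    weakest[:2], chosen[(weakest[0], weakest[1])])
        g.remove_edge(*weakest[:2])
        del chosen[(weakest[0], weakest[1])]
    return StructureConstraints(whitelist=frozenset(chosen))


# ---------------------------------------------------------------------------
# edge-list CSV interchange


def dag_to_csv(dag: DAG, path) -> None:
    """Write edges as a two-column CSV (from, to), sorted."""
    import pandas as pd

    pd.DataFrame(sorted(dag.edges), columns=["from", "to"]).to_csv(path, index=False)


def dag_from_csv(path, nodes=None) -> DAG:
    """Read a DAG from a (from, to) edge-list CSV; isolated nodes may be
    supplied via ``nodes``."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    edges = frozenset((r["from"], r["to"]) for _, r in df.iterrows())
    all_nodes = set(nodes or ())
    for u, v in edges:
        all_nodes |= {u, v}
    return DAG(tuple(sorted(all_nodes)), edges)


def constraints_from_csv(whitelist_path=None, blacklist_path=None) -> StructureConstraints:
    """Build constraints from (from, to) edge-list CSV files."""
    import pandas as pd

    def read(path):
        if path is None:
            return frozenset()
        df = pd.read_csv(path, dtype=str)
        return frozenset((r["from"], r["to"]) for _, r in df.iterrows())

    return StructureConstraints(read(whitelist_path), read(blacklist_path))


# ---------------------------------------------------------------------------
# parameters and inference


def fit_parameters_mle(dag: DAG, cohort: Cohort) -> DiscreteBN:
    """CPT entries as conditional relative frequencies; parent
    configurations never observed get the uniform distribution."""
    data, levels = encode_categorical(cohort, list(dag.nodes))
    pos = {n: i for i, n in enumerate(dag.nodes)}
    cpts = {}
    for node in dag.nodes:
        parents = dag.parents(node)
        r = len(levels[node])
        cards = tuple(len(levels[p]) for p in parents)
        q = int(np.prod(cards)) if cards else 1
        if parents:
            pidx = np.ravel_multi_index(
                tuple(data[:, pos[p]] for p in parents), cards
            )
        else:
            pidx = np.zeros(data.shape[0], dtype=int)
        counts = np.bincount(pidx * r + data[:, pos[node]], minlength=q * r)
        counts = counts.reshape(q, r).astype(float)
        rowsum = counts.sum(axis=1, keepdims=True)
        empty = rowsum[:, 0] == 0
        if empty.any():
            logger.info("fit_parameters_mle: %d unobserved parent configs for %s "
                        "set to uniform", int(empty.sum()), node)
            counts[empty] = 1.0
            rowsum = counts.sum(axis=1, keepdims=True)
        table = counts / rowsum
        cpts[node] = CPT(node, parents, levels[node],
                         tuple(levels[p] for p in parents), table)
    return DiscreteBN(dag, cpts, levels)


def _forward_samples(bn: DiscreteBN, evidence_idx: dict[str, int],
                     samples: int, rng) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Likelihood-weighting sample matrix: evidence clamped, weights
    accumulate the evidence conditionals."""
    order = bn.dag.topological_order()
    assign: dict[str, np.ndarray] = {}
    logw = np.zeros(samples)
    for node in order:
        cpt = bn.cpts[node]
        if cpt.parents:
            pmat = np.column_stack([assign[p] for p in cpt.parents])
            rows = cpt.row_index(pmat)
        else:
            rows = np.zeros(samples, dtype=int)
        probs = cpt.table[rows]  # (samples, r)
        if node in evidence_idx:
            k = evidence_idx[node]
            assign[node] = np.full(samples, k, dtype=int)
            with np.errstate(divide="ignore"):
                logw += np.log(probs[:, k])
        else:
            u = rng.random(samples)
            cdf = np.cumsum(probs, axis=1)
            assign[node] = (u[:, None] > cdf[:, :-1]).sum(axis=1)
    return assign, np.exp(logw)


def likelihood_weighting_query(
    bn: DiscreteBN,
    query: tuple[str, str],
    evidence: dict[str, str] | None = None,
    samples: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Estimate P(query node = level | evidence) with its Monte-Carlo SE.

    Evidence nodes are clamped and each sample weighted by the product of
    evidence conditionals given its sampled parents (likelihood weighting).
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    evidence = dict(evidence or {})
    qnode, qlevel = query
    if qlevel not in bn.levels[qnode]:
        raise ValueError(f"unknown level {qlevel!r} for node {qnode!r}")
    ev_idx = {}
    for node, level in evidence.items():
        if level not in bn.levels[node]:
            raise ValueError(f"unknown level {level!r} for node {node!r}")
        ev_idx[node] = bn.levels[node].index(level)
    rng = np.random.default_rng(seed)
    assign, w = _forward_samples(bn, ev_idx, samples, rng)
    wsum = w.sum()
    if wsum == 0:
        raise ValueError("evidence has zero probability under the network")
    x = (assign[qnode] == bn.levels[qnode].index(qlevel)).astype(float)
    p = float((w * x).sum() / wsum)
    se = float(np.sqrt(np.sum((w / wsum) ** 2 * (x - p) ** 2)))
    return p, se
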