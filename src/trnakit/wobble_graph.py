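"""Decoding-potential graph over sense anticodons.

The graph has one vertex per sense anticodon (stop-codon anticodons are never
vertices).  A directed arc ``s -> t`` with a wobble label means the anticodon
``s``, suitably modified at position 34, can decode the cognate codon of
``t`` -- i.e. ``s`` can replace ``t`` during translation.  Arc direction is
compensator -> compensated.  The arc set depends only on the genetic code;
an existing/missing repertoire partition annotates vertices.

Wobble labels are written anticodon-base-first (position 34 : codon third
position).  A at position 34 is read as inosine for the I:C and I:A rules.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import GeneticCode, codon_of

#: label -> (wobble base of the compensating anticodon, wobble base of the
#: replaced anticodon).
WOBBLE_RULES: dict[str, tuple[str, str]] = {
    "G:U": ("G", "A"),
    "U:G": ("T", "C"),
    "I:C": ("A", "G"),
    "I:A": ("A", "T"),
}

GROUP_MODES = ("per_arc", "merged_inosine", "component")


@dataclass(frozen=True, order=True)
class Arc:
    source: str
    target: str
    label: str
    nonsynonymous: bool


@dataclass(frozen=True)
class DecodingPotentialGraph:
    """Vertices, labelled arcs and the existing/missing vertex partition."""

    vertices: tuple
    arcs: tuple
    existing: frozenset
    code: GeneticCode

    @property
    def missing(self) -> frozenset:
        return frozenset(self.vertices) - self.existing

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for v in self.vertices:
            g.add_node(v, existing=v in self.existing)
        for a in self.arcs:
            g.add_edge(a.source, a.target, label=a.label, nonsynonymous=a.nonsynonymous)
        return g

    def edge_table(self) -> pd.DataFrame:
        """Edge list with columns source, target, label, nonsynonymous (0/1)."""
        return pd.DataFrame(
            [(a.source, a.target, a.label, int(a.nonsynonymous)) for a in self.arcs],
            columns=["source", "target", "label", "nonsynonymous"],
        )

    def vertex_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(v, int(v in self.existing)) for v in self.vertices],
            columns=["anticodon", "existing"],
        )


def build_graph(code: GeneticCode, existing: Iterable[str] = ()) -> DecodingPotentialGraph:
    """Construct the decoding-potential graph for ``code``.

    ``existing`` flags the repertoire's anticodons; every member must be a
    sense anticodon under ``code``.
    """
    existing = frozenset(existing)
    vertices = tuple(sorted(code.sense_anticodons))
    bad = sorted(a for a in existing if a not in vertices)
    if bad:
        raise ValueError(f"not sense anticodons under this code: {bad}")
    vset = set(vertices)
    arcs = []
    for s in vertices:
        for label, (src_w, tgt_w) in WOBBLE_RULES.items():
            if s[0] != src_w:
                continue
            t = tgt_w + s[1:]
            if t in vset:
                nonsyn = code.aa(codon_of(s)) != code.aa(codon_of(t))
                arcs.append(Arc(s, t, label, nonsyn))
    return DecodingPotentialGraph(vertices, tuple(sorted(arcs)), existing, code)


def nonsynonymous_arcs(
    g: DecodingPotentialGraph,
    code: GeneticCode | None = None,
    occurring_only: bool = False,
) -> list:
    """Arcs whose source and target cognate codons encode different amino acids.

    With ``occurring_only`` the list is restricted to replacements that can
    actually occur given the repertoire, i.e. arcs whose source anticodon is
    flagged existing.
    """
    code = code or g.code
    out = [
        a
        for a in g.arcs
        if code.aa(codon_of(a.source)) != code.aa(codon_of(a.target))
        and (not occurring_only or a.source in g.existing)
    ]
    return sorted(out)


def compensated_missing(g: DecodingPotentialGraph, labels: Iterable[str]) -> set:
    """Missing vertices with an incoming arc (label in ``labels``) from an
    existing vertex."""
    labels = set(labels)
    unknown = labels - set(WOBBLE_RULES)
    if unknown:
        raise ValueError(f"unknown wobble labels: {sorted(unknown)}")
    missing = g.missing
    return {
        a.target
        for a in g.arcs
        if a.label in labels and a.source in g.existing and a.target in missing
    }


def _check_nonneg(name: str, mapping: Mapping[str, float]) -> None:
    neg = {k: v for k, v in mapping.items() if v < 0}
    if neg:
        raise ValueError(f"negative {name} counts: {neg}")


def group_by_arcs(
    g: DecodingPotentialGraph,
    copy_number: Mapping[str, float],
    codon_usage: Mapping[str, float],
    mode: str = "per_arc",
) -> pd.DataFrame:
    """Group gene copy numbers and codon usage by the arcs of the graph.

    Returns one row per group with columns ``group_id, label, members,
    copies, usage``.  ``copy_number`` is keyed by anticodon (absent = 0);
    ``codon_usage`` is keyed by codon, looked up at each anticodon's cognate
    codon.  Anticodons with no incident arc form singleton rows in every
    mode.

    Modes
    -----
    per_arc
        One row per arc; sums over {source, target}.
    merged_inosine
        The I:C and I:A arcs sharing a source are merged into a single row
        (their counts come from the same inosine-modified anticodon) before
        summation; other arcs behave as in ``per_arc``.
    component
        One row per weakly connected component; each anticodon counted once,
        so totals are conserved.
    """
    if mode not in GROUP_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {GROUP_MODES}")
    _check_nonneg("copy_number", copy_number)
    _check_nonneg("codon_usage", codon_usage)

    def cn(a: str) -> float:
        return copy_number.get(a, 0)

    def cu(a: str) -> float:
        return codon_usage.get(codon_of(a), 0)

    def row(group_id, label, members):
        members = tuple(members)
        return {
            "group_id": group_id,
            "label": label,
            "members": members,
            "copies": sum(cn(m) for m in members),
            "usage": sum(cu(m) for m in members),
        }

    rows = []
    incident = {a.source for a in g.arcs} | {a.target for a in g.arcs}
    singletons = [v for v in g.vertices if v not in incident]

    if mode == "per_arc":
        for a in g.arcs:
            rows.append(row(f"{a.source}->{a.target}", a.label, (a.source, a.target)))
    elif mode == "merged_inosine":
        by_source: dict[str, list] = {}
        for a in g.arcs:
            if a.label in ("I:C", "I:A"):
                by_source.setdefault(a.source, []).append(a)
            else:
                rows.append(row(f"{a.source}->{a.target}", a.label, (a.source, a.target)))
        for src in sorted(by_source):
            arcs = sorted(by_source[src])
            if len(arcs) == 1:
                a = arcs[0]
                rows.append(row(f"{a.source}->{a.target}", a.label, (a.source, a.target)))
            else:
                targets = [a.target for a in arcs]
                rows.append(
                    row(
                        f"{src}->" + "+".join(targets),
                        "+".join(a.label for a in arcs),
                        (src, *targets),
                    )
                )
    else:  # component
        und = nx.Graph()
        und.add_nodes_from(g.vertices)
        und.add_edges_from((a.source, a.target) for a in g.arcs)
        for comp in nx.connected_components(und):
            members = tuple(sorted(comp))
            if len(members) > 1:
                rows.append(row("|".join(members), "component", members))
        singletons = [v for v in g.vertices if not und.degree[v]]

    for v in singletons:
        rows.append(row(v, "singleton", (v,)))

    out = pd.DataFrame(rows, columns=["group_id", "label", "members", "copies", "usage"])
    return out.sort_values("group_id", kind="stable", ignore_index=True)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    degenerate: bool = False


def pearson_with_p(
    x: Sequence[float], y: Sequence[float], log_transform: bool = False
) -> CorrelationResult:
    """Pearson r with two-sided p from the t transform (n-2 df).

    Zero variance in either vector yields a flagged NaN result rather than
    an exception.  ``log_transform`` applies log10(x + 1) to both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if log_transform:
        x = np.log10(x + 1.0)
        y = np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), x.size, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size))


def brute_force_arcs(code: GeneticCode) -> set:
    """Independent arc enumerator over all ordered anticodon pairs x 4 rules.

    Kept here for reuse by the command-line self-check; the test suite
    carries its own copy so the two routes stay independent.
    """
    antis = sorted(code.sense_anticodons)
    out = set()
    for s, t in itertools.product(antis, antis):
        if s[1:] != t[1:]:
            continue
        for label, (sw, tw) in WOBBLE_RULES.items():
            if s[0] == sw and t[0] == tw:
                out.add((s, t, label))
    return out
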