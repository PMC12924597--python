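"""Correlation-clique network discovery and group-wise network statistics.

Builds a Pearson correlation graph over proteins (edge iff |r| strictly
exceeds a threshold, 0.7 by default), enumerates maximal cliques within a
size band, greedily selects weakly-overlapping cliques as named networks
(A, B, C, …), compares intra-network correlation between sample groups with
a permutation test on Fisher-z transformed correlations, and performs
hypergeometric over-representation analysis against user-supplied gene sets.

The over-representation universe defaults to the detected proteins, not the
whole proteome — the background is the analysis's biggest lever and is an
explicit argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from string import ascii_uppercase

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .proteome_core import AbundanceTable, bh_adjust

log = logging.getLogger(__name__)


def pearson_corr_matrix(t: AbundanceTable) -> pd.DataFrame:
    """Protein × protein Pearson correlation of a complete abundance table.

    Zero-variance proteins get r = 0 against everything (with a warning) and
    1 on the diagonal.
    """
    if not t.is_complete():
        raise ValueError("table contains missing values; impute first")
    if t.n_samples < 3:
        raise ValueError("need at least 3 samples")
    x = t.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d zero-variance proteins; their correlations set to 0",
                    int(degenerate.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=t.values.index, columns=t.values.index)


def build_graph(corr: pd.DataFrame, threshold: float = 0.7) -> nx.Graph:
    """Correlation graph: nodes = proteins, edge iff |r| > threshold (strict)."""
    ids = list(corr.index)
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(ids)
    r = corr.to_numpy()
    n = len(ids)
    iu, ju = np.nonzero(np.triu(np.abs(r) > threshold, k=1))
    for i, j in zip(iu, ju):
        g.add_edge(ids[i], ids[j], r=float(r[i, j]))
    log.info("correlation graph: %d nodes, %d edges (|r| > %g)",
             n, g.number_of_edges(), threshold)
    return g


@dataclass
class CliqueNetwork:
    """A maximal clique of the correlation graph, optionally labelled."""

    members: tuple[str, ...]
    mean_abs_r: float
    label: str | None = None

    @property
    def size(self) -> int:
        return len(self.members)


def _clique_mean_abs_r(g: nx.Graph, members: tuple[str, ...]) -> float:
    rs = [abs(g[u][v]["r"])
          for i, u in enumerate(members) for v in members[i + 1:]]
    return float(np.mean(rs)) if rs else 0.0


def enumerate_maximal_cliques(g: nx.Graph, min_size: int = 8,
                              max_size: int = 20) -> list[CliqueNetwork]:
    """Maximal cliques (Bron–Kerbosch with pivoting) within [min_size, max_size].

    Cliques are returned sorted by size then mean |r| descending, members
    sorted, so the ordering is deterministic.
    """
    out = []
    for clique in nx.find_cliques(g):
        if min_size <= len(clique) <= max_size:
            members = tuple(sorted(clique))
            out.append(CliqueNetwork(members=members,
                                     mean_abs_r=_clique_mean_abs_r(g, members)))
    out.sort(key=lambda c: (-c.size, -c.mean_abs_r, c.members))
    return out


def _jaccard(a: tuple[str, ...], b: tuple[str, ...]) -> float:
    sa, sb = set(a), set(b)
    return len(sa & sb) / len(sa | sb)


def select_networks(cliques: list[CliqueNetwork], max_networks: int = 3,
                    max_overlap: float = 0.5) -> list[CliqueNetwork]:
    """Greedy selection of weakly-overlapping cliques by descending mean |r|.

    A clique is accepted if its Jaccard overlap with every already-accepted
    network is ≤ max_overlap; accepted networks are labelled A, B, C, …
    """
    ranked = sorted(cliques, key=lambda c: (-c.mean_abs_r, -c.size, c.members))
    selected: list[CliqueNetwork] = []
    for c in ranked:
        if len(selected) >= max_networks:
            break
        if all(_jaccard(c.members, s.members) <= max_overlap for s in selected):
            selected.append(CliqueNetwork(members=c.members,
                                          mean_abs_r=c.mean_abs_r,
                                          label=ascii_uppercase[len(selected)]))
    return selected


def _mean_fisher_z(x: np.ndarray) -> float:
    """Mean Fisher-z of pairwise Pearson correlations over rows of x.

    Constant rows make pairs degenerate; those pairs are skipped.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = r[iu]
    ok = np.isfinite(vals)
    if not ok.all():
        log.warning("%d degenerate correlation pairs skipped", int((~ok).sum()))
    vals = np.clip(vals[ok], -1 + 1e-12, 1 - 1e-12)
    if vals.size == 0:
        return 0.0
    return float(np.arctanh(vals).mean())


def intra_network_test(t: AbundanceTable, net: CliqueNetwork,
                       n_perm: int = 999, seed: int = 0,
                       group_order: tuple[str, str] | None = None
                       ) -> tuple[float, float]:
    """Permutation test for a group difference in intra-network correlation.

    Statistic: mean Fisher-z of within-clique pairwise Pearson r in group 1
    minus the same in group 2 (groups in order of first appearance unless
    ``group_order`` is given).  The null is built by permuting sample group
    labels; two-sided p = (1 + #{|null| ≥ |obs|}) / (n_perm + 1).
    """
    labels = t.group_labels()
    if group_order is None:
        if len(labels) != 2:
            raise ValueError("intra-network test needs exactly two groups")
        g1, g2 = labels
    else:
        g1, g2 = group_order
    s1 = [t.sample_ids.index(s) for s in t.samples_in_group(g1)]
    s2 = [t.sample_ids.index(s) for s in t.samples_in_group(g2)]
    if len(s1) < 3 or len(s2) < 3:
        raise ValueError("each group needs at least 3 samples")
    x = t.values.loc[list(net.members)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("table contains missing values; impute first")
    obs = _mean_fisher_z(x[:, s1]) - _mean_fisher_z(x[:, s2])
    rng = np.random.default_rng(seed)
    all_idx = np.array(s1 + s2)
    n1 = len(s1)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        stat = _mean_fisher_z(x[:, perm[:n1]]) - _mean_fisher_z(x[:, perm[n1:]])
        if abs(stat) >= abs(obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return obs, p


# -- over-representation ----------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <TAB> description <TAB> members…"""
    sets: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {ln}: expected >= 3 fields")
        sets[parts[0]] = set(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path,
              description: str = "na") -> None:
    lines = [f"{name}\t{description}\t" + "\t".join(sorted(members))
             for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def ora_enrichment(query: set[str], genesets: dict[str, set[str]],
                   universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene sets are intersected with the universe first; p is the upper-tail
    probability of observing at least the overlap by drawing |query| proteins
    from the universe.  BH adjustment across sets.  Result ordering is
    independent of the input listing order (sorted by p, then name).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name in sorted(genesets):
        members = genesets[name] & universe
        k = len(query & members)
        if members:
            p = float(stats.hypergeom.sf(k - 1, m, len(members), n_query))
        else:
            p = 1.0
        rows.append({"set": name, "set_size": len(members), "overlap": k,
                     "p": min(1.0, p)})
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
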