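"""Antagonistic selectional pleiotropy statistics.

A gene deletion is antagonistic when it is significantly beneficial under at
least one inhibitor and significantly deleterious under at least one other.
This module summarizes per-gene directional profiles, the pairwise
inhibitor antagonistic-proportion matrix, and exclusive (UpSet-style) set
intersections of antagonist sets against a focal inhibitor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffit import FitnessTable

RULES = ("both-significant", "union-signed")


@dataclass
class GeneDirectionSummary:
    per_gene: pd.DataFrame       # n_beneficial, n_deleterious,
                                 # prop_beneficial, gene_class
    cumulative: pd.DataFrame     # k, beneficial_only, deleterious_only, either


def _direction_counts(fitness: FitnessTable) -> pd.DataFrame:
    t = fitness.table
    ben = (t[t["direction"] == "beneficial"].groupby("gene").size())
    dele = (t[t["direction"] == "deleterious"].groupby("gene").size())
    genes = sorted(t["gene"].unique())
    df = pd.DataFrame(index=pd.Index(genes, name="gene"))
    df["n_beneficial"] = ben.reindex(genes).fillna(0).astype(int)
    df["n_deleterious"] = dele.reindex(genes).fillna(0).astype(int)
    return df


def gene_direction_profile(fitness: FitnessTable) -> GeneDirectionSummary:
    """Per-gene directional counts, beneficial proportion, and class.

    ``prop_beneficial`` divides by the number of inhibitors where the gene
    was significant in either direction (NaN when never significant). The
    cumulative table counts genes significant in >= k inhibitors under three
    regimes: only-beneficial, only-deleterious, and either direction.
    """
    df = _direction_counts(fitness)
    total = df["n_beneficial"] + df["n_deleterious"]
    df["prop_beneficial"] = np.where(total > 0, df["n_beneficial"] / total,
                                     np.nan)
    cls = np.full(len(df), "nonsignificant", dtype=object)
    cls[(df["n_beneficial"] >= 1) & (df["n_deleterious"] == 0)] = "beneficial-only"
    cls[(df["n_beneficial"] == 0) & (df["n_deleterious"] >= 1)] = "deleterious-only"
    cls[(df["n_beneficial"] >= 1) & (df["n_deleterious"] >= 1)] = "antagonistic"
    df["gene_class"] = cls

    kmax = int(total.max()) if len(df) else 0
    rows = []
    for k in range(1, max(kmax, 1) + 1):
        rows.append({
            "k": k,
            "beneficial_only": int(((df["gene_class"] == "beneficial-only")
                                    & (df["n_beneficial"] >= k)).sum()),
            "deleterious_only": int(((df["gene_class"] == "deleterious-only")
                                     & (df["n_deleterious"] >= k)).sum()),
            "either": int((total >= k).sum()),
        })
    return GeneDirectionSummary(per_gene=df, cumulative=pd.DataFrame(rows))


def _signed_sets(fitness: FitnessTable) -> dict[str, pd.DataFrame]:
    """Per-inhibitor frame indexed by gene with significance flag and sign."""
    out = {}
    for inh, part in fitness.table.groupby("inhibitor"):
        out[inh] = part.set_index("gene")[["log2_effect", "significant"]]
    return out


def pairwise_antagonistic_proportion(fitness: FitnessTable,
                                     rule: str = "both-significant"
                                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Antagonistic proportion of the union of significant deletions for each
    inhibitor pair.

    ``both-significant`` (default): antagonists are genes significant in both
    inhibitors with opposite log2-effect signs. ``union-signed``: genes
    significant in at least one of the pair whose point estimates have
    opposite (nonzero) signs in the two inhibitors. The denominator is always
    the union of significant genes of the pair; empty unions give NaN with a
    flag. Matrix is symmetric with zero diagonal.
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    by_inh = _signed_sets(fitness)
    inhibitors = sorted(by_inh)
    if len(inhibitors) < 2:
        raise ValueError("need >= 2 inhibitors")
    n = len(inhibitors)
    mat = np.zeros((n, n))
    empty = np.zeros((n, n), dtype=bool)
    for a in range(n):
        for b in range(a + 1, n):
            da, db = by_inh[inhibitors[a]], by_inh[inhibitors[b]]
            sig_a = set(da.index[da["significant"]])
            sig_b = set(db.index[db["significant"]])
            union = sig_a | sig_b
            if not union:
                mat[a, b] = mat[b, a] = np.nan
                empty[a, b] = empty[b, a] = True
                continue
            if rule == "both-significant":
                cand = sig_a & sig_b
            else:
                cand = union
            k = 0
            for g in cand:
                ea = da.at[g, "log2_effect"] if g in da.index else np.nan
                eb = db.at[g, "log2_effect"] if g in db.index else np.nan
                if np.isfinite(ea) and np.isfinite(eb) and ea * eb < 0:
                    k += 1
            mat[a, b] = mat[b, a] = k / len(union)
    idx = pd.Index(inhibitors, name="inhibitor")
    return (pd.DataFrame(mat, index=idx, columns=inhibitors),
            pd.DataFrame(empty, index=idx, columns=inhibitors))


def antagonist_set(fitness: FitnessTable, a: str, b: str) -> set[str]:
    """Genes significant in both inhibitors with opposite-signed effects."""
    by_inh = _signed_sets(fitness)
    da, db = by_inh[a], by_inh[b]
    out = set()
    for g in set(da.index[da["significant"]]) & set(db.index[db["significant"]]):
        if da.at[g, "log2_effect"] * db.at[g, "log2_effect"] < 0:
            out.add(g)
    return out


def focal_intersections(fitness: FitnessTable, focal: str,
                        others: list[str]) -> pd.DataFrame:
    """Exclusive (UpSet) intersection sizes of antagonist sets vs a focal
    inhibitor.

    For each other inhibitor ``o``, ``S_o`` is the set of genes significant
    in both the focal inhibitor and ``o`` with opposite signs. Each gene in
    the union is counted once, under the membership pattern matching exactly
    the sets it belongs to. Returns one row per non-empty pattern plus the
    per-set totals in the ``set_total`` column (repeated per member set).
    """
    if focal in others:
        raise ValueError("focal inhibitor cannot appear in others")
    present = set(fitness.table["inhibitor"].unique())
    missing = ({focal} | set(others)) - present
    if missing:
        raise ValueError(f"inhibitors not in fitness table: {sorted(missing)}")
    sets = {o: antagonist_set(fitness, focal, o) for o in others}
    union = set().union(*sets.values()) if sets else set()
    patterns: dict[tuple[bool, ...], list[str]] = {}
    for g in sorted(union):
        key = tuple(g in sets[o] for o in others)
        patterns.setdefault(key, []).append(g)
    rows = []
    for key, genes in sorted(patterns.items(),
                             key=lambda kv: (-len(kv[1]), kv[0])):
        rows.append({
            "pattern": "".join("1" if m else "0" for m in key),
            "members": ";".join(o for o, m in zip(others, key) if m),
            "size": len(genes),
            "genes": ";".join(genes),
        })
    out = pd.DataFrame(rows, columns=["pattern", "members", "size", "genes"])
    out.attrs["set_totals"] = {o: len(sets[o]) for o in others}
    out.attrs["union_size"] = len(union)
    return out
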